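# srtqc

Quality assessment and benchmarking for imaging-based spatially resolved
transcriptomics (SRT) data — Xenium-style decoded-transcript tables and
cell-by-gene matrices.

Imaging-based SRT platforms report every decoded mRNA read with a 3D
position (x, y, z in µm), a gene identity and a phred-scaled quality
value (qv), plus a segmentation-derived assignment of reads to cells.
Analysts must then answer a chain of questions that this package turns
into reusable, tested computations:

* **Is the data any good?** Read/cell QC filters (qv > 20, ≥ 10 reads
  per cell) and dataset summaries (`srtqc.io`).
* **Is the signal specific, and is the segmentation trustworthy?**
  Negative marker purity (NMP) and negative co-expression purity (NCP)
  against an annotated scRNA-seq reference (`srtqc.specificity`), plus
  mask expansion, read assignment, majority-vote typing and summary
  metrics for arbitrary segmentation outputs (`srtqc.segmentation`).
* **How sensitive is the assay?** Per-gene detection-efficiency ratios
  via positive-cell medians, area-normalized pseudobulk ratios and
  centroid-distance read profiles (`srtqc.efficiency`).
* **How far should nuclear masks be expanded?** The optimal-expansion
  algorithm: distance-binned read compositions correlated against
  nuclear and tissue-background signatures (`srtqc.expansion`).
* **Which preprocessing workflow should I use?** Workflow execution
  with cluster-count-matched resolution tuning, partition similarity
  metrics (ARI/VI/NMI/FMI), imputation metrics (PCC/SSIM/RMSE/JS) and
  control-probe false-positive rates (`srtqc.workflows`).
* **Are cells overlapping in z?** A segmentation-free z-coherence score
  from Gaussian-KDE gene-expression vector fields (`srtqc.zcoherence`).
* **How do I test any of this without gigabytes of data?** A simulator
  that builds Xenium-like matrices from an annotated reference and
  spatial point-cloud fixtures with full ground truth
  (`srtqc.simulate`).

## The core metrics

**Negative marker purity.** A gene g is a *negative marker* for cell
type c when it is expressed in < 0.5 % of type-c cells in the scRNA-seq
reference. With x̄<sub>g,c</sub> the mean raw expression of g in type c,
the cell-type-balanced ratio is

    X̄_{g,c} = x̄_{g,c} / Σ_{c'} x̄_{g,c'}

and X̄<sub>neg</sub> is the mean of X̄<sub>g,c</sub> over all negative
(g, c) pairs. Then

    NMP = 1 − (X̄_neg^{sp} − X̄_neg^{sc})   if X̄_neg^{sp} > X̄_neg^{sc}, else 1.

Mis-segmentation leaks reads of negative markers into cell types that
should not express them, pushing NMP below 1. A permutation rescaling
maps the mean NMP of 20 random label permutations to 0 (maximum stays 1).

**Negative co-expression purity.** Gene pairs that are never
co-expressed in reference cells (co-positive fraction < 0.5 %) should
stay non-coexpressed in situ; NCP is the fraction that do. Non-specific
(background) reads drive it down.

**z-coherence.** Reads are split into top/bottom z-halves per 2-µm xy
bin; each half yields a per-gene Gaussian-KDE vector field (2.5 px/µm,
2.5 µm bandwidth). Both fields are projected into a PCA latent space
(fit on local maxima of the full field, ≥ 80 % variance) and compared
per pixel by cosine similarity. Nuclei with mean similarity < 0.2 over
valid pixels (field norm ≥ 5) are flagged as likely z-overlaps.

## Worked example

```python
import numpy as np
from srtqc import io, simulate, specificity, efficiency

# an annotated reference and its Xenium-like transformation
ref = simulate.simulate_reference(n_types=5, n_genes=200,
                                  cells_per_type=400, seed=1)
mat, truth = simulate.simulate_xenium_like(ref, n_top=50, seed=1)
mat.obs["cell_type"] = ref.obs["cell_type"].to_numpy()

res = specificity.scaled_nmp(mat, ref, n_perm=20, seed=1)
print(f"raw NMP    {res.raw:.4f}")
print(f"baseline   {res.baseline:.4f}")
print(f"scaled NMP {res.scaled:.4f}")
```

prints (seed 1):

```
raw NMP    0.9867
baseline   0.7998
scaled NMP 0.9335
```

The raw NMP of 0.9867 says that, after cell-type balancing, negative
markers carry ~1.3 % excess expression in cell types that should not
express them — the footprint of the simulated 10 % mis-segmented cells.
The baseline 0.7998 is what random cell-type assignment scores; the
scaled value 0.9335 places the matrix 93 % of the way from "random
labels" to "perfectly clean".

The CLI mirrors the main entry points:

```bash
srtqc simulate --seed 0 --n-cells 16 --out-dir fixtures/
srtqc qc --transcripts fixtures/transcripts.csv --qv-min 20 --min-reads 10 --out summary.json
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computations from scratch on simulated data:
the Xenium-like pipeline with NMP/NCP, gene-efficiency recovery against
known per-gene efficiencies, the best-path preprocessing workflow
(library-size 100 → log → scale → all PCs → 16-neighbor graph → Louvain,
resolution tuned to the reference cluster count), optimal-expansion
radius recovery on disk-cell fixtures, and two-layer z-coherence
flagging. It prints a JSON summary of the computed quantities and
writes the results object to `--out`.
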