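# phenoprof

High-throughput, image-based screens perturb cells by the thousands —
siRNA knockdowns, compound libraries — and photograph them in multi-channel
fluorescence. Turning those images into biology requires three steps:
finding the cells, measuring them, and condensing thousands of single-cell
measurements per perturbation into a *phenotypic profile* discriminative
enough that perturbations with related function end up with similar
profiles. `phenoprof` is a scriptable library and CLI for that pipeline,
aimed at screeners and image-analysis researchers who want each stage
available as a plain Python function with a testable contract.

## What it implements

**Segmentation** is a two-step seeded watershed. Nuclei are detected on
the DNA channel with an h-dome transform (background flattening by
grayscale reconstruction), Otsu thresholding, a Laplacian-of-Gaussian blob
gate, and a distance-transform watershed to split touching nuclei. Cells
are then grown from the nuclei by a seeded watershed on an inverted
composite of the cytoplasmic channels, restricted to an Otsu foreground:
one cell per nucleus, nucleus inside its cell, by construction.

**Regions and features.** Each cell is decomposed into eight subcellular
regions (whole cell, nucleus, nuclear boundary, inner nucleus,
peri-nucleus, cytoplasm, cytoplasmic boundary, inner cytoplasm) by disc
erosions/dilations of the two masks. Features are combinatorial over
(type, marker, region): morphology, intensity statistics, region-level
intensity fractions and ratios, and pixel-level intensity correlations,
named by the grammar `type[_submeasure]:markers:regions`, e.g.
`fraction_total_intensity:ERK:dna_region-cell_region`.

**Profiles.** Per treatment: the feature-wise **mean** profile; the
**PCA** profile (scores of the treatment-level matrix keeping 95% of
variance); and the SVM-based **d-profile** — the unit normal
w/‖w‖₂ of a linear SVM hyperplane separating treated cells from
negative-control cells in standardized feature space, which automatically
down-weights features that vary strongly but identically in treated and
control cells.

**Evaluation.** Segmentation accuracy against reference masks via the
boundary error E = (1/|B|) Σ_{b∈B} min_{b′∈B′} ‖b−b′‖₂ and the Rand
error 1 − (c+d)/C(N,2); profile discriminability via cosine dissimilarity
d(g,h) = 1 − g·h/(‖g‖‖h‖), the average maximum intra-group dissimilarity
D_intra, and the n-nearest-neighbour inter-group dissimilarity
D_inter(n) = (2/(N(N−1))) Σ_j Σ_{k≠j} E(W_jk(n)).

**Synthetic data.** Seeded generators produce ground-truthed multi-channel
scenes and feature populations with planted group structure (4 groups x 8
treatments, informative features shifted by a chosen effect size, plus
high-variance nuisance features), so every stage is testable without
external data. See `docs/methods.md` for parameters, rationale and
limitations.

## Worked example

```python
import numpy as np
from phenoprof import (SceneSpec, generate_scene, segment_frame,
                       boundary_error, rand_error, extract_features)

scene = SceneSpec(seed=42, n_cells=20)
stack, truth = generate_scene(scene)          # images + ground-truth masks
seg = segment_frame(stack)                    # two-step seeded watershed
print(f"planted cells: {truth.n_cells}, recovered: {seg.n_cells}")
print(f"boundary error vs truth: {boundary_error(truth.cells, seg.cells):.3f} px")
print(f"Rand error vs truth:     {rand_error(truth.cells, seg.cells):.4f}")

config = {
    "morphology": {"regions": ["cell_region", "dna_region"]},
    "intensity": {"markers": ["DNA"], "regions": ["dna_region"]},
    "fraction_total_intensity": {
        "markers": ["Actin"], "regions": ["dna_region", "cell_region"]},
}
table = extract_features(seg, stack, config)
print(f"feature table: {table.n_cells} cells x {table.n_features} features")
j = table.feature_names.index(
    "fraction_total_intensity:Actin:dna_region-cell_region")
print(f"median nuclear fraction of actin: {np.median(table.values[:, j]):.3f}")
```

prints

```
planted cells: 20, recovered: 20
boundary error vs truth: 0.173 px
Rand error vs truth:     0.0069
feature table: 20 cells x 24 features
median nuclear fraction of actin: 0.310
```

All 20 planted cells are recovered; the recovered outlines sit within a
fifth of a pixel of the true ones on average, and pixel-pair label
agreement with the truth is above 99%. The 24 columns are the
deterministic expansion of the feature configuration (2x8 morphology +
7 DNA intensity + 1 nested fraction), and the nuclear actin fraction is
well below 1 because actin is cytoplasmic — the nucleus holds about a
third of the cell's area and hence of its diffuse actin signal.

## Command line

```sh
phenoprof simulate --out plate --wells A01,A02,A03 --frames 4 --seed 5
phenoprof segment  --config plate/config.yaml --workers 4
phenoprof export   --store plate/results.h5 --features-csv features.csv
phenoprof evaluate --manual plate/truth --auto masks/ --metric both
phenoprof profile  --store results.h5 --config run.yaml --method dprofile
phenoprof profile-eval --store results.h5 --method dprofile -n 5 -n 10 -n 30
```

Each (well, frame) is an independent job; results are written by a single
writer in sorted order, so the HDF5 store is bit-identical for any worker
count, and a corrupt frame is recorded under `/meta/failed` without
aborting the run.

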