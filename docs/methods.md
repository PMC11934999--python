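# Methods

## Problem and model

Spatial transcriptomics (ST) platforms such as 10x Visium measure gene
expression at capture spots that each cover several cells, while scRNA-seq
resolves single cells but discards their positions. `spotmap` links the
two: given a single-cell count matrix C (m cells × g genes), a spot count
matrix S (w spots × g genes) and spot coordinates, it learns an m × w
row-stochastic mapping matrix M whose entry M_ij scores how well cell i
matches spot j, and reads explicit assignments off M in two modes:

* **regular** — every spot j receives its expected number of cells N_j
  (the N_j cells with the highest column scores; a cell may serve several
  spots or none), reconstructing the spot's single-cell composition;
* **greedy** — every cell goes to its row-argmax spot, assigning a
  location to the whole single-cell atlas.

M is the row softmax of free logits, optimized with Adam to minimize

    L = Σ_ij KL(C_i ‖ S_j) M_ij  +  Σ_ij D_ij M_ij
        + λ (1/w) Σ_j | N_j − Σ_i M_ij |

with three terms: expression similarity (KL divergence between the
gene-probability profiles of cell and spot), embedding similarity
(D_ij = 1 − PCC between graph-attention-autoencoder embeddings of cell i
and spot j), and the cell-quantity constraint tying each spot's column
mass to its expected cell count. λ defaults to 0.1; the quantity term
stays useful even for greedy extraction, where it discourages all cells
from collapsing onto a few spots.

## Pipeline stages and their assumptions

**Preprocessing.** Genes detected in ≤ 1 cell (or ≤ 1 spot) are removed
from each matrix independently, then both are restricted to their common
genes (sorted lexicographically so the column order is reproducible
regardless of input order — the filter-then-intersect order is a
convention of this package), and each row is normalized to counts per
million and log2(1 + x). Both cost terms consume this layer; for the KL
term the normalized rows are ε-smoothed (ε = 1e-10) and renormalized to
probability vectors. KL is directed cell→spot, following the argument
order of the objective.

**Cells per spot.** By default the two-anchor UMI rule: per-spot totals
T_j are transformed to u_j = log2(1 + 1e6·T_j/Σ T), a line is fitted
through (u_min, 1) and (u_median, mean_cells), evaluated at every u_j,
rounded half-up and clipped to ≥ 1. `mean_cells` defaults to 5 (a typical
Visium occupancy). Per-spot totals give a single scalar each, so "CPM per
spot" is interpreted as each spot's share of the section's total UMIs
scaled to one million. Nucleus counts from external H&E segmentation can
be substituted (`cells_per_spot_from_counts`; zeros are raised to 1 so
every spot stays mappable), as can a constant.

**Graphs and embeddings.** Cells are connected to their k = 15 nearest
cells by Euclidean distance in the normalized expression space; spots to
their k = 6 spatially nearest spots (the hexagonal Visium packing has six
neighbors). Every node's neighborhood includes itself and ties break to
the lower index. Each modality is embedded by its own graph attention
autoencoder with identical widths (input → 512 → 30, ELU): per layer,
edge scores r_ij = sigmoid(v_s'σ(Wh_i) + v_t'σ(Wh_j)) are softmax-
normalized over each neighborhood and the new representation is the
attention-weighted sum of transformed neighbors. The decoder mirrors the
encoder with transpose-tied weights and separately learned attention
vectors, and training minimizes the summed squared reconstruction error
of the normalized expression (Adam, lr 1e-4, 500 epochs by default;
float32 parameters). The two embeddings are made *dimensionally*
comparable by sharing the architecture; they are not trained jointly.
Ablation on the simulation benchmark shows the KL term carries most of
the mapping signal while the embedding term contributes a mild
regularization — consistent with independently trained latent spaces
being aligned only loosely.

**Mapping optimization.** Logits start at log(N_j/ΣN) plus Gaussian
jitter (sd 0.01, seeded), so the initial column masses already equal the
expected cell counts. Adam (lr 0.01, 1,000 epochs, λ = 0.1) minimizes the
objective; the best-seen iterate is kept, so the final loss never exceeds
the initial one. Gradients flow through a small reverse-mode autodiff
engine written on numpy (`spotmap._autograd`), which also trains the
GATE; every operation is verified against central finite differences in
the test suite. Extraction ties break to the lower index everywhere.

## Synthetic data and what it does (not) show

The generator emulates an annotated bead-resolution dataset: each cell
type has a negative-binomial program (shared lognormal baseline, a
marker block multiplied 6-fold, library size 2,000 counts, gamma-Poisson
dispersion 0.3, lognormal size factors) and occupies a Gaussian patch on
the unit square (or a gradient along x). Cells are binned into
square-grid spots whose side is searched until the realized mean cells
per occupied spot is within 10% of the target (5, 15 or 30); spot
expression is the exact sum of member counts, so binning conserves
counts and yields an exact cell→spot truth table. Technical noise between
platforms is emulated by multiplying, per cell, a uniformly chosen
floor(pt·g) genes by 2^z with z ~ N(0,1) and re-rounding to non-negative
integers (applied to raw counts; an additive reading could produce
negative counts and is rejected). The gene subset is drawn per cell.

Because a binned spot literally contains its member cells' counts, the
identity signal is stronger than in real cross-platform data; passing the
benchmark demonstrates that the optimizer and extraction recover a
recoverable mapping under controlled noise, not that real Visium/scRNA
pairs will reach the same precision. The generator also omits ambient
RNA, segmentation errors, platform-specific gene detection dropouts and
batch effects.

## Benchmark problem sizes

The packaged benchmark (`spotmap.benchmark.noise_robustness_benchmark`)
uses 8 cell types × 190 cells (1,520 cells), 400 genes with 12 markers
per type, mean 5 cells per spot (~300 spots) and noise levels 5/10/25%,
with the GATEs trained for 120 epochs and the spot embedding reused
across noise levels (the ST side is unchanged). These sizes keep a full
three-level run at a few minutes on one CPU while exercising every
stage; median per-type Pmap is insensitive to longer GATE training on
this data. The score is the median across types of per-type Pmap, and
the headline number is the minimum of the three medians.

## Numerical choices and degenerate inputs

* Softmaxes (attention and mapping rows) are max-shifted; the shift is
  treated as a constant in the backward pass.
* The |·| in the quantity term uses the sign subgradient (0 at 0).
* Zero-variance embedding rows get Pearson distance 1 (uncorrelated) with
  a warning; zero-variance proportion rows give a missing PCC.
* Duplicate spot coordinates make spatial neighbors ill-defined; ties
  break by index with a warning.
* All-zero expression rows are rejected before normalization; degenerate
  UMI anchors (min = median) fall back to a constant cell count with a
  warning inside the model, or raise when the estimator is called
  directly.
* A fixed master seed derives the GATE seed, the mapping-jitter seed and
  all simulation seeds, making every fit bit-reproducible.

## Known limitations

* Cost matrices are dense m × w; the intended scale is m·w ≲ 10⁷.
* Single-head attention and full-batch training only; atlas-scale inputs
  would need neighbor sampling.
* The two GATEs are trained independently; a shared or jointly aligned
  latent space might strengthen the embedding term.
* Regular extraction duplicates cells freely when ΣN_j > m, which biases
  downstream expression analyses; greedy mapping is the recommended mode
  for such cases.
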