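# Methods

This note documents the generative model implemented in `multiomesim`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Kinetic model of expression

Each gene in each cell is governed by the two-state promoter model with
activation rate `k_on`, deactivation rate `k_off`, synthesis rate `s`, and
degradation rate `d`. In the stationary ("Beta-Poisson") mode, `d` is
fixed at 1 and the count is drawn as `y ~ Beta(k_on, k_off)`,
`x ~ Poisson(y*s)`. The intrinsic-noise weight `sigma_i` (default 1)
returns `sigma_i*x + (1-sigma_i)*s*k_on/(k_on+k_off)`: at 0 the
deterministic stationary mean, at 1 a pure sample; intermediate values are
real-valued. This is the knob for studying how transcriptional-burst noise
degrades downstream analyses.

In velocity mode the dynamics are integrated explicitly per cell. The
promoter cycle has length `L = eta_L*(1/k_on + 1/k_off)`, divided into
`m = ceil(L / min(1/k_on, 1/k_off))` Euler steps (capped at 100 — the
log-normal parameter pools put a small mass on extreme `k_on/k_off` ratios
where `m` would explode without changing the dynamics materially). Per
step the promoter switches with probabilities `p_on = k_on*L/m`,
`p_off = k_off*L/m` (clipped to [0,1] — the per-step hazard reading, the
only one that yields probabilities), spliced counts update as
`xs += (L/m)*(beta*xu - d*xs)` and unspliced counts as
`xu += (L/m)*(s - beta*xu)` while on and `xu -= (L/m)*beta*xu` while off,
clamped at zero (the Euler step can otherwise go negative). Cells inherit
their predecessor's counts along the tree; root cells are initialised with
the documented closed forms (`xs = s*k_on*beta/(k_on+k_off)`,
`xu = s*k_on*d/(k_on+k_off)`; a `steady_state_init` switch provides the
stationary alternative with the rates in the denominators). The emitted
velocity is exactly `v = beta*xu - d*xs`; kNN-averaged velocity uses a
Gaussian kernel with `k = ceil(n_cell/50)` and per-cell bandwidth equal to
the median neighbor distance.

Per-gene splicing and degradation rates are `N(beta_mean, beta_sd)` and
`N(d_mean, d_sd)` truncated at 1e-3 (defaults 1.0 ± 0.1: rates of order
one in mRNA-lifetime units).

## Identity factors and identity vectors

Every kinetic parameter matrix starts as a product CIF × GIV of per-cell
identity factors (rows) and per-gene weights (columns), one independent
pair per parameter. Both are segmented as `[nd | diff | tf | lig]`:

- **nd** (non-differential): i.i.d. `N(1, sigma_cif)` — shared cellular
  heterogeneity. The unit mean keeps products centered on positive mass;
  rank scaling (below) makes the location choice largely immaterial.
- **diff** (differential): in continuous mode a Brownian motion along the
  differentiation tree with per-unit-length standard deviation
  `sigma_cif`; cells sharing ancestry share increments, so the covariance
  of two cells equals `sigma_cif^2` times their shared root-path length.
  In discrete mode only the tree tips are used: each tip's anchor is a
  Brownian tip value at a *fixed unit* per-length scale and cells are
  jittered around it with `N(0, sigma_cif)`. The fixed anchor scale is
  deliberate: if the anchor walk also scaled with `sigma_cif` the
  geometry would be scale-free and `sigma_cif` could not tighten or
  loosen cluster boundaries, which is its documented purpose. `n_diff =
  max(1, round(r_d*n_cif))`; larger `r_d` gives crisper tree structure.
- **tf**: length = number of TFs. For `k_on`/`k_off` both the CIF segment
  (`N(1, sigma_cif)`) and the GIV segment (zeros) are neutral — the
  network acts on synthesis only (an optional flag injects it into
  `k_on`/`k_off` as well). For `s`, the GIV segment is the GRN effect
  matrix (gene × TF regulation strengths) and the CIF segment tracks TF
  expression (below).
- **lig**: spatial mode only; length = n_ligands × n_neighbor-slots.

GIV entries outside the structured blocks are sparse Gaussians: zero with
probability `p0_G` (default 0.7) else `N(0, 1)`. The diff-GIV of the `s`
parameter couples the network into the trajectory: each TF gene receives
two randomly chosen diff dimensions set to 1.0 (comparable in scale to
sampled columns), each pure target's column is the TF-column matrix times
the effect-matrix column (targets inherit their regulators' diff weights,
combined by strength), and a gene that is both TF and target averages the
two. Target-hood follows the edge list, so a zero-effect edge still marks
its target. Whether the two chosen dimensions are disjoint across TFs is
not constrained (sampled independently per TF).

## Rank-based scaling and reference pools

Raw CIF × GIV products are on an arbitrary scale. They are mapped onto
empirical reference pools by rank: draw `n` values from the pool, sort,
and write them back in the rank order of the raw matrix (stable tie
break). The packaged pools are synthetic log-normals with a distinct fixed
shape per parameter — `k_on`: LN(-1, 1), `k_off`: LN(0.5, 1), `s`:
LN(3, 1) — chosen once so that with `d = 1` the burst fraction has median
~0.3 and mean expression is a few counts per gene (UMI-scale sparsity);
the accessibility pool is 70% zeros with LN(0.5, 1) open values. Users can
substitute any empirical pool; the scaling consumes only a sample. Pools
are generated deterministically from fixed internal seeds, so they are a
versioned part of the package rather than data files.

Where values must be produced row-by-row (the sequential expression pass),
a frozen monotone quantile map (`QuantileScaler`) is fitted once against
the pool on a representative raw matrix and then applied per cell; it
agrees with full-matrix rank scaling up to interpolation at repeated
values. Freezing it before the pass means the sequential feedback cannot
shift the global parameter distribution.

## Chromatin accessibility and its effect on expression

Accessibility is generated before expression: the `k_on` CIF matrix times
a region-identity-vector matrix (sparse Gaussian, zero probability
`p0_R`), rank-scaled onto the accessibility pool, plus `N(0,
0.05*pool_sd)` intrinsic noise applied to open entries only (noise on the
zeros would erase the pool's zero fraction) and truncated at zero. A
binary region-to-gene matrix assigns each gene 1–3 *consecutive* regions
with probabilities `region_dist` (default (0.1, 0.5, 0.4)); genes claim
consecutive blocks left-to-right, leftover regions stay gene-free. An
optional second tree lets the accessibility modality follow a different
population structure than RNA.

`k_on` couples the modalities: the accessibility channel is `atac @ Z`
with zeros backfilled by the CIF channel rescaled below the smallest
non-zero accessibility value (closed chromatin stays ordered but
uniformly small), and the final ordering is a convex blend of the two
channels' ranks with weight `E_a` (default 0.5) on accessibility, then
rank-scaled onto the `k_on` pool. The blend reproduces the endpoints
(`E_a = 0`: pure CIF; `E_a = 1`: pure accessibility) and gives a
correlation between expression and single-region accessibility that is
monotone in `E_a`, averaging ≈0.2 over the default parameter grid.

## Sequential generation and the regulatory network

Cells are simulated in tree order: branch by branch from the root, shallow
to deep; each cell's predecessor is its nearest upstream cell (branch
heads inherit from the deepest cell of the nearest populated ancestor
branch; root-adjacent cells use a Gaussian initial TF state). The TF
segment of a cell's `s`-CIF is `x_i/(x_i + mean(x))` over the
predecessor's TF counts (zero when all TFs are silent — a silent TF exerts
no effect).

Within a cell, regulation is synchronous: the TF genes are drawn first
(their synthesis seeded by the predecessor's TF state) and the rest of the
transcriptome responds to the cell's *own* TF counts. This is a deliberate
design choice: with independent Beta-Poisson draws, a strictly lagged
chain (targets responding only to the previous cell) provably leaves zero
same-cell TF-target correlation — the burst noise of the previous cell is
independent of the current cell's TF draw — which would make the emitted
data useless for network-recovery benchmarking. Biologically, regulation
acts within a cell; the cross-cell chain models the temporal inheritance
of regulatory state. With this scheme, a plain correlation-ranking
predictor recovers the input network at ~3.5–4× the random-baseline AUPRC
on true counts at full intrinsic noise.

A cell-specific network mode evolves the edge list along pseudotime: per
cell, each edge is deleted with probability `change_rate` and a new random
TF→gene pair (effect drawn from the empirical pool of existing effects) is
born with the same probability; per-cell ground truth is recorded.

The packaged `synthetic_benchmark_grn` (100 genes, 10 TFs, 150 edges,
Uniform(1, 5) effects, hub-weighted TF choice, ~10% TF-to-TF edges) is a
synthetic stand-in at the scale of curated benchmark networks.

## Spatial simulation and cell-cell interactions

Spatial mode runs `n_steps` (default `n_cell`) time steps on a square grid
with `ceil(grid_factor*n_cell)` sites (default 250% of the cell count).
One newborn cell per step enters at the tree root and is placed, with
probability `p_n`, on a free site adjacent to a cell of its own (destined)
type; otherwise uniformly at random. Neighborhoods are the 4-site von
Neumann ring (slots labelled 1–4; diagonal cells are not neighbors) and a
cell keeps at most `n_nbs` interaction neighbors. Each cell walks a
randomly chosen root-to-tip path, one increment (`tree depth / n_steps`)
per step; its differential CIF is pinned at its final position for all
steps, so the trajectory survives into the final snapshot. Only the final
step is emitted, as in real spatial data; because cells are born at
different steps, all developmental stages are present at the end.

Interactions come from a user-supplied ligand-receptor table (ligand gene,
receptor gene, effect). Type-pair-level ground truth samples 3–6 rows per
unordered pair of distinct types, over *all* tree node types (cells pass
through ancestor types while developing). During the steps, the gating
between two neighbors uses their current types; the emitted pair-level
ground truth uses final types. A cell's ligand CIF carries its neighbors'
ligand expression from the previous step, normalised per ligand as
`x/(x + mean-over-cells)` — a saturating Michaelis-Menten-like transform.
(A within-cell normalisation across ligands was rejected: it makes ligands
compete in the denominator and induces spurious negative correlations in
non-interacting pairs.) The enabled effects multiply these values into the
receptor's raw `s`.

Two further choices shape the emitted snapshot. First, counts carry
short-term memory: each step blends the previous value with the new draw
with weight `STEP_RELAX = 1 - e^{-1}` (one step = one mRNA lifetime), so
transcripts persist while the cell develops; this, with dynamic-type
gating, is what leaves the small residual correlation in neighbor pairs
whose interaction belonged to an earlier type pair. Second, the final
emission is synchronous — ligands are drawn first, then TFs (receptors
that are TFs see the emitted ligand counts), then the rest of the
transcriptome — so there is no one-step lag between the emitted ligand
counts and the receptor response. Without this, the measured
ligand-receptor correlation is attenuated twice by independent draws and
drops to a third of its mechanistic value. Measured on the default
configuration (500 cells, 500 genes, 3-leaf tree, `sigma_cif = 0.1`),
interacting neighbor pairs average ≈0.10–0.15 correlation, non-interacting
neighbors ≈0.03, non-neighbors ≈0.

In spatial+velocity mode the full kinetic model is run once per cell from
its initial state at the final-step parameters; cross-step kinetic
inheritance is not simulated (a known simplification).

## Technical noise and batches

Observed counts are produced by a three-stage chain per cell: binomial
capture of each transcript at efficiency `alpha ~ N(0.1, 0.02)` (clipped
to (0, 1]); 2 rounds of stochastic amplification (each molecule duplicated
with probability 0.7 per round); multinomial allocation of the cell's
sequencing depth `~N(1e5, 3000)` across amplified molecules. With the UMI
protocol, reads collapse back to distinct captured molecules through an
occupancy approximation (`P(seen) = 1 - (1 - 1/captured)^reads`); the
non-UMI protocol reports reads directly. Optional per-gene and per-cell
capture-efficiency multipliers allow housekeeping-style tuning. The
amplification constants are package choices; they reproduce the expected
qualitative behaviour (observed zero fraction decreases with `alpha`,
library size grows with depth, per-gene zero fraction anti-correlates
with mean).

Batch effects split cells round-robin into `n_batch` batches; for gene
`j`, a center `mu_j ~ N(0,1)` is drawn and each batch's shift is
`Uniform(mu_j - e_b, mu_j + e_b)`; counts are multiplied by `exp(shift)`
(log-additive, keeping counts non-negative) and re-rounded. True-count
ground truth is never modified. The observed accessibility matrix is a
per-entry Bernoulli thinning at `atac_obs_prob` (default 0.3).

## Metrics

`metrics` implements the scoring statistics used for validation and
benchmarking: pseudotime R² (squared Pearson correlation), per-cell kNN
purity (Jaccard of k-neighborhoods under true vs inferred pseudotime,
default k = 50), graph connectivity (mean largest-connected-component
fraction per cell type on a k = 15 NN graph of the top principal
components of log1p counts), batch average silhouette width (mean of
1 − |silhouette| on batch labels within each cell type), mean per-cell
velocity cosine similarity, and per-cell/per-gene count summaries.

## Randomness and determinism

One global seed drives named sub-streams (population, cif, giv, riv, atac,
kinetics, scale, expression, noise, batch, spatial, grn, velocity), so
enabling or disabling one stage does not perturb the others; two runs with
the same configuration are bit-identical across all output files.

## What the synthetic data does not emulate

- Kinetic-parameter pools are synthetic log-normals, not fits to a real
  dataset; absolute parameter values (and anything that depends on them,
  like absolute count magnitudes) are only order-of-magnitude realistic.
  Tests passing on these pools show the machinery is correct, not that
  any particular real tissue is matched.
- No doublets, ambient RNA, read-level errors, cell-cycle phases, or
  multi-allele dynamics.
- The accessibility modality has no genome coordinates or fragment-level
  structure; regions are abstract.
- Spatial tissue is a square grid with at most four interaction partners;
  no migration after placement and no secreted-ligand diffusion.
- The alternative impulse model for trajectory factors is not
  implemented.
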