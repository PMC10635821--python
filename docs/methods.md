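# Methods

## Covariance templates

A template encodes the expected cell–cell covariance of a topological
signal; downstream algorithms consume only its eigendecomposition
(`TemplateSpectrum`).

**Cyclic.** Cells equally spaced on a circle with neighbor correlation
α have covariance C_kj = α^min((j−k) mod n, (k−j) mod n) — symmetric
circulant with unit diagonal.  The eigenvalue of frequency i is the
cosine transform of the first row, Σ_j α^min(j, n−j)·cos(2πji/n)
(computed as the real FFT of the first row, well defined for odd and
even n alike), and the eigenvector entries are
√(2/n)·cos(2πis/n − π/4).  The −π/4 phase folds each frequency's cosine
and sine modes into one real orthonormal basis and is kept as a fixed
convention: cyclic spectra are doubly degenerate (frequencies i and
n−i tie), and re-orthogonalizing numerically would make outputs depend
on LAPACK details.  Ties are ordered by ascending frequency.

**Linear.** A chain has the Kac–Murdock–Szegő covariance α^|i−j|.  The
classical approximation λ_i = (1−α²)/(1+α²−2α·cos((i+1)π/(n+1))) is
exposed for spectrum matching; its relative error versus the exact
eigenvalues falls from ~27% at n=10 to ~1.8% at n=200 (α=0.7), and is
below 5% at n=100 for α ≤ 0.7.  Eigen*vectors* for the linear template
are always obtained by numerical decomposition of the KMS matrix.

**Cluster / block-circulant / spatial.** The cluster template is 1 on
the diagonal, `within_corr` within a label, 0 across labels (PSD for
`within_corr` ≤ 1).  The block-circulant template stacks circulant
blocks with a constant cross-block correlation and rejects indefinite
combinations.  The spatial template builds the k-nearest-neighbor graph
on 2D coordinates (mutual-edge union, Euclidean weights), takes
all-pairs shortest-path distances d, and forms exp(−d²/(2σ²)) with σ
defaulting to the median nonzero distance.  A heat kernel of graph
distances need not be PSD, so eigenvalues below zero are clipped to
zero for affinity inputs; declared covariances with eigenvalues below
−1e−8 are rejected instead.

**Top-component removal.** The largest-eigenvalue component (the
constant vector, for the cyclic template) captures the mean offset and
carries no ordering information; reconstruction and masking operate on
the spectrum with it removed (`drop_top`).

## Synthetic data

The cyclic generator emulates binary ON/OFF dynamics: a random root
cell in {0,1}^p, q forward steps each flipping k distinct uniformly
chosen genes, then a return phase flipping k genes per step among those
still differing from the root (all remaining ones when fewer than k are
left — the model is silent on the remainder step) until the cycle
closes; the final duplicate of the root is emitted once.  Feasibility
requires k·q ≤ p.  Under a Markovian approximation the correlation of
cells m steps apart is exp(−2mk/p), which the Monte-Carlo tests verify;
it also supplies the matched α for a simulation.  The linear generator
is the same walk without a return phase (n cells, k flips per step).
Optional Gaussian noise (sd `noise_sd`) is added after binary
generation; rows are shuffled with a recorded permutation so that
reconstruction starts from unordered input.

Two structural properties of this model matter for interpretation.
First, genes that are never flipped over the whole cycle (probability
(1−k/p)^q per gene in the forward phase, e.g. ~45% at p=250, k=5,
q=50) are constant and carry no signal by construction; gene-inference
evaluations therefore use the *non-constant* cyclic genes as the
informative class.  Second, the binary amplitude is 1, so signal
strengths elsewhere are calibrated relative to that.

The composite generator overlays a cyclic half (p genes) with a
cluster half: cells are assigned uniformly at random to `n_clusters`
clusters (default 4), and each cluster's disjoint gene block is ON at
amplitude `cluster_strength` (default 0.5) for its members.  The
defaults, together with noise sd 0.3 in the disentanglement
evaluations, put the two signals at comparable salience, so that
neither plain KMeans task (clusters, or 6 cyclic phase bins) is
saturated on the raw data — the regime where enhancement and filtering
have something to disentangle, analogous to entangled temporal and
spatial programs in real tissue.  What these simulations do **not**
emulate: count noise (negative binomial sampling), library-size
variation, dropout, batch structure, or continuous expression dynamics;
passing tests demonstrate the spectral machinery, not robustness to
those properties of real data.

## Preprocessing and α estimation

Standard preprocessing (zero-gene removal, per-cell total-count
normalization to the median total, log1p, dispersion-based selection of
the top `n_hvg` = 2000 genes) is delegated to scanpy and is
deterministic.  Two L2 scalings matter: cells are scaled to unit norm
before reconstruction so the empirical cell–cell covariance has
constant diagonal like the templates; genes are scaled to unit norm
before gene inference so scores are relative.  All-zero vectors are
left at zero with a warning.

α is estimated by grid search (default 0.05…0.95, step 0.01): for each
candidate, the theoretical eigenvalues are first broadened to the
*expected p-sample spectrum* (two fixed-seed Wishart draws with the
candidate population spectrum — deterministic given the inputs), then
both spectra are sorted, truncated to min(n, p) values, normalized to
unit sum and compared in L2.  The broadening matters: against the raw
population spectrum the fit is biased upward by finite-gene sampling
(α = 0.3 fitted as 0.40 at n = 200, p = 1000); with it, recovery is
within ±0.01 at α ∈ {0.3, 0.6}.

## Ordering optimizer

The relaxed problem maximizes the convex quadratic
f(E) = trace(C·E·G·Eᵀ) (G = AAᵀ) over doubly stochastic E.  Details
that were open and how they were fixed:

- **Step size** — "auto" is 1/L with L = 2·λmax(C)·λmax(G), λmax(G) by
  power iteration.
- **Initialization** — the Birkhoff barycenter (uniform 1/n) plus
  seeded noise of sd 0.01/n.
- **Noise** — Gaussian on the gradient, sd = `noise_sd` × mean|grad|,
  decaying as 1/√t.  A single decaying schedule deterministically traps
  at locally maximal vertices on small instances, so after a main phase
  (60% of the iteration budget, with an early-convergence check of
  patience 25) the remaining budget is spent in 50-iteration annealing
  cycles: each cycle mixes the iterate toward a random doubly
  stochastic matrix with a random weight in [0,1] and restarts the
  noise clock.
- **Projection** — Bregmanian bi-stochastication: alternate the
  closed-form Frobenius projection onto {row sums = column sums = 1}
  with clipping of negatives until the maximum violation is below
  1e−9 (error after 10,000 alternations).
- **Rounding** — greedy: rows in ascending order, each taking the
  still-free column with the largest entry, ties to the lowest index.
  Rounding happens every 10 iterations as well as at the end, and the
  best-scoring permutation seen anywhere is returned, so the result is
  never worse than the initialization.  (Rounding only once at the end
  discards good intermediate vertices for free.)
- **Truncation** — `TemplateSpectrum.truncate(m)` caps the retained
  eigenpairs for large n; all retained pairs are used by default.
- **Symmetry** — for cyclic templates every circular shift and
  reflection of a solution scores identically; orderings are therefore
  evaluated by circular rank correlation after alignment over the 2n
  equivalent transforms.

With defaults (1000 iterations) the planted ordering of noiseless cyclic
toy data (n ≈ 90–100, p = 500, k = 5) is recovered at circular rank
correlation ≥ 0.9 in 10/10 seeds; on n ≤ 6 instances the rounded
objective reaches ≥ 95% of the exhaustive-search optimum (2000
iterations, three independent instance streams checked).

Prior knowledge can replace reconstruction entirely: with per-cell
low-resolution labels (e.g. sampling times), cells are sorted by label
with seeded random order within ties.

## Masks

**Gene inference.** The objective Σ_i λ_i‖(AD)ᵀv_i‖² − γ‖D‖₁ separates
per gene into w_j·d_j² − γ·d_j with w_j the template energy of gene
column j, so the box-constrained minimum is the closed form
d_j = clip(γ/(2w_j), 0, 1), with d_j = 1 for a zero-energy column when
γ > 0 (and 0 when γ = 0).  The closed form replaces iterative descent —
same optimum, exact degenerate cases.  Default γ maximizes the Otsu
between-class variance of the resulting d values over the 5-point grid
{0.25, 0.5, 1, 2, 4} × 2·median(w): γ sets how many genes are masked,
and the bimodality criterion picks the split the data supports.  In the
enhancement workflow, genes with complement ≥ 0.5 are retained
(hardened mask; threshold exposed), matching the remove-the-rest reading
of the workflow; the soft product A·(I−D) is also available.

**Enhancement** (non-convex maximization) uses projected stochastic
gradient ascent from F = all-ones with seeded noise, box-clipping to
[0,1], step 1/L with L = 2·λmax(C)·max A², and returns the best
iterate.  Default γ = 0 — sparsity pressure is usually unnecessary
because the gene mask has already removed uninformative columns.

**Filtering** (convex minimization) uses deterministic projected
gradient descent from F = all-ones at the same step bound, which makes
the objective provably non-increasing; stopping at relative change
< 1e−6.  Default γ is the median of |∂S/∂F| at F = 1 — the balance
point at which entries whose template-aligned gradient exceeds γ are
driven down while the rest are retained.  (A γ proportional to
λmax × mean squared *row* norm was tried first and is off-scale for
unit-norm cells: it exceeds the per-entry gradient ~25-fold and pins
F at 1.)  Two degeneracies are worth knowing: entries where A_ij = 0
have zero gradient and keep their initial F value (harmless — the
product A∘F is zero regardless), and directions in the null space of
the dropped-top covariance are unpenalized, so "γ=0 drives F to 0"
holds exactly only for strictly positive data under a full
positive-definite spectrum.

## Evaluation

Ordered cells sit at angles 2πj/n.  Circular summaries report the mean
direction and variance (1 − resultant length) of nonnegative per-cell
weights; gene-set summaries sum the member columns per cell and min-max
normalize to [0,1] before the circular statistics (the normalization
convention is a package choice).  Uniform or antipodally balanced
weights give variance 1; concentrated weights give 0.

The projection proportion Σ_i ‖Aᵀv_i‖²/‖A‖²_F over the retained
(unit-weighted) eigenvectors is the package's convergence-quality
score: it is 1 when all columns lie in the retained span, m/n in
expectation for isotropic data with m of n eigenvectors retained, rises
under enhancement and falls under filtering.  No universal pass/fail
threshold is attached — the score depends on how much of the data's
variance genuinely belongs to the target topology.

ARI/silhouette/Calinski–Harabasz against reference labels are thin
wrappers over scikit-learn with seeded KMeans.

## Known limitations

- The ordering optimizer is stochastic; on weak or noisy signals
  different seeds can return orderings of different quality.  The
  objective trace and the projection proportion are the provided
  diagnostics.
- The Birkhoff relaxation cost is O(n²) memory and O(n³) per iteration;
  beyond a few thousand cells, use prior-knowledge ordering or spectrum
  truncation.
- Enhancement masks are per-entry and can fit noise aligned with the
  template when the signal-to-noise ratio is low; the gene-inference
  hardening step is the main guard.
- Templates assume equally spaced cells along the topology; strongly
  nonuniform sampling densities distort the match.
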