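# Methods

`musclenet` implements a network view of muscle coordination during the
sit-to-stand (STS) movement: surface EMG from eight muscles is reduced to
muscle synergies by non-negative matrix factorization (NMF), the trial-to-
trial variation of the spatial synergy weights is modelled as a Gaussian
graphical model (GGM) over muscles, and the resulting sparse partial-
correlation network is summarized by centrality, bootstrap stability and
DeltaCon similarity. This note records the model, the parameters that
matter, the design choices that were genuinely open, and what the synthetic
data can and cannot show.

## Synergy model and envelope extraction

Muscle activity is modelled as `M ≈ W C`, with `M` the muscles × time
activation envelope matrix, `W ≥ 0` the spatial weights (muscles × k) and
`C ≥ 0` the temporal activation profiles (k × time). Envelopes are obtained
from raw EMG by:

1. **Zero-phase Butterworth bandpass, 80–200 Hz, order 4.** `filter_order`
   is passed to `scipy.signal.butter` as its design order N (a 2N-pole
   bandpass); forward–backward application (`sosfiltfilt`) doubles the
   effective order and cancels phase, so the nominal band edges sit at
   −6 dB. Tones at 140 Hz pass within 1 dB; 10 Hz is attenuated by far more
   than 40 dB.
2. **SSA removal of the ECG artifact** on the trunk channels (RA, ESL).
   The signal is embedded in an L × K Hankel trajectory matrix with window
   `ssa_window_s` (default 0.25 s ≈ twice the QRS width), decomposed by a
   truncated randomized SVD (20 components), and each rank-1 component is
   reconstructed by diagonal averaging. A component is classified cardiac
   when the dominant frequency of its rectified-and-smoothed envelope falls
   in `cardiac_band` (0.7–2.5 Hz, covering 42–150 bpm); the sum of cardiac
   components is subtracted. The short window matters: beat-to-beat jitter
   makes the trajectory matrix of a spike train effectively high-rank at
   1 s windows (the leading subspace then captures <10 % of the artifact),
   whereas at 0.25 s the QRS shape is a local feature and >99 % of a pure
   ECG is removed. SSA runs before rectification because cancellation must
   act on the signed signal.
3. **Full-wave rectification and a centered 0.2 s moving average** (edges
   average over the available samples).
4. **Amplitude normalization per subject and muscle** over all of that
   subject's trials (both conditions pooled), making the per-muscle maximum
   exactly 1 and removing anthropometric and electrode-impedance factors.
   The plausible alternative — one global factor per subject — would leave
   between-muscle amplitude differences in place; per-muscle is what makes
   `W` comparable across muscles and is the convention implemented.
5. **Time normalization** of the onset–offset epoch onto an inclusive
   0–100 % grid (101 points) by linear interpolation.

## NMF and the number of synergies

NMF minimizes the Frobenius reconstruction error by Lee–Seung
multiplicative updates, batched over 20 random restarts with per-step
relative tolerance 1e-6 (VAF tables use 3 restarts at tolerance 1e-4 and at
most 600 iterations — at the 8 × 101 problem size the resulting VAF differs
from the tight-tolerance optimum by far less than the between-k gaps the
selection criterion reads, and the VAF table dominates the cost of the
selection studies); the objective is non-increasing by construction. The scale
indeterminacy is fixed by normalizing each row of `C` to unit maximum,
absorbing amplitude into `W` so spatial weights are comparable across
trials — the property the network stage depends on.

Fit quality is the variance accounted for,
`VAF = 1 − Σ e²/Σ M²` with `e = M − WC`, computed per trial. The synergy
count is chosen by a significant-difference criterion: a Kruskal–Wallis
test compares the per-trial VAF distributions across candidate k = 1..7;
if it rejects, Dunn post-hoc comparisons (pooled tie-corrected ranks, no
multiplicity correction by default, Holm available) test each k > 1 against
k = 1, and the smallest significantly different k wins. With no significant
comparison the count falls back to 1 with a warning flag.

A structural property of this criterion is worth knowing: if the VAF
columns separate perfectly by k (every trial's VAF strictly ordered, no
overlap between columns), the Dunn z for the adjacent comparison (2 vs 1)
is a constant determined by the design alone — 30 observations in 7 groups
give z = 1.91, p = 0.056 — so the adjacent column is *never* significant no
matter how large the effect. Significance of k = 2 therefore requires the
k ≥ 2 columns to overlap across trials, which in real data is supplied by
execution-to-execution variability. The synthetic generator reproduces
exactly this mechanism (below).

Whether to run NMF per trial, per subject, or on concatenated data is not
dictated by the model; per-trial decompositions are used (they provide the
per-trial VAF distributions the criterion needs), with spatial weights
pooled across trials after aligning each trial's columns to a reference
decomposition (NMF on the condition's time-concatenated envelopes) by
optimal-assignment cosine matching.

## Gaussian graphical model over muscles

Rows of the pooled weight matrix (one spatial weight vector per trial, 30
rows per condition-synergy at the study design of 6 subjects × 5 trials)
are treated as observations of an 8-variate Gaussian. The input to
estimation is the Pearson correlation matrix (location/scale invariant, so
edges are unit-free partial correlations). The graphical lasso

    Θ̂ = argmax  ln|Θ| − tr(SΘ) − ρ‖Θ‖₁,off

is solved by warm-started Friedman block coordinate descent with an inner
lasso; the off-diagonal-only penalty keeps the partial-correlation scale of
edges. Convergence combines a cheap change-in-W criterion with a duality-
gap confirmation (`tr(SΘ) − p + Σρ|θ|` vanishes at the optimum), which
keeps accuracy under ill-conditioned resampled inputs. A penalty path of
100 log-spaced values runs from ρ_max (the largest off-diagonal |S|, above
which the graph is empty) down to 0.01 ρ_max.

Model selection uses the extended Bayesian information criterion with
hyperparameter γ = 0.5 (the selection hyperparameter, not the glasso
penalty):

    EBIC(E) = −2 lnL(Θ̂(E)) + |E| log n + 4 |E| γ log p

where `Θ̂(E)` is the **maximized** likelihood of edge set E — i.e. the
unpenalized MLE refit restricted to the support proposed at each penalty
(computed with the same solver using a 0/∞ penalty matrix) — and
`lnL = (n/2)[ln|Θ| − tr(SΘ)]` up to a constant. Scoring the refit rather
than the shrunken path estimate matters: the penalized estimate trades
likelihood for shrinkage, which drags the EBIC minimum toward small
penalties and admits spurious weak edges (on the chain-graph benchmark the
refit-scored criterion recovers the support exactly at n ≥ 100, where the
shrinkage-scored variant plateaus at F1 ≈ 0.78). Ties break toward the
sparser model; the reported precision matrix and partial correlations are
the winning refit. Edges below 1e-8 in magnitude count as absent.

At the study's n = 30, edges need |partial correlation| ≳ 0.5 to overcome
the EBIC penalty — weaker planted structure is honestly reported as absent,
which is the criterion working as designed, not a failure to converge.

## Centrality

Degree (fraction of neighbors present), betweenness and closeness on
shortest paths with edge length 1/|w| (the psychometric-network convention;
the method's sources do not state a distance map), and strength Σ|w| — the
absolute-value convention treats negative partial correlations as
connections; the literal signed sum is available as an option. Closeness on
disconnected graphs uses the within-component score scaled by
(component−1)/(n−1); isolated nodes score 0. Each measure is also reported
as a z-score across the 8 nodes (sample SD; zero-variance measures get a
flagged all-zero column).

## Bootstrap stability

Non-parametric case bootstrap: rows (subject-trials, exchangeable) are
resampled with replacement, and each replicate runs the *entire* selection
(path, refits, EBIC). The significance level is tied to the replicate count
by α = 2/Nb (0.01 at the default Nb = 200); overriding α requires an
explicit flag. Per edge: percentile interval [α/2, 1−α/2], bootstrap mean
and sample value, ordered by descending sample weight. Difference tests
form the bootstrap distribution of pairwise differences (edges, or nodes
per centrality measure, on raw values — z-scoring is affine per measure and
cannot change a difference's sign pattern) and flag pairs whose percentile
interval excludes 0. Replicates with constant columns are redrawn (max 10);
replicates where no model on the path converges (e.g. near-collinear
resamples) are excluded and counted. Replicate fits cap coordinate-descent
sweeps at 120 — pathological resamples are better excluded than polished.

## DeltaCon similarity

Each network's node affinity is the exact fast-belief-propagation matrix
`S = (I + ε²D − εA)⁻¹` with A = |partial correlations| (DeltaCon is defined
for non-negative adjacency), D the weighted degree diagonal, and shared
ε = 1/(1 + max degree over both graphs); at 8 nodes the exact inverse is
preferred over the approximate algorithm. Distance is the rootED (Matusita)
norm between element-wise square roots of the two affinities, and
similarity = 1/(1 + d) ∈ (0, 1]. The paired contrast sim(A,B) − sim(C,D) is
reported as a raw difference and left to the user to interpret.

## Synthetic data: what it emulates

No recordings ship with the package; the generator stands in for the
laboratory protocol with the following structure, chosen once to mirror how
this kind of data behaves:

- **Design**: 6 subjects × 5 trials × 2 conditions, 8 channels at 1000 Hz,
  3 s trials with the movement epoch spanning the central 80 %.
- **Synergies**: synergy 1 is a whole-body extension drive — every muscle
  loads on it, and its temporal profile carries a tonic plateau (0.6 of
  burst peak) under a broad burst; later synergies dominate disjoint
  round-robin muscle subsets with narrower, staggered bursts. Synergy 1 is
  scaled so it carries `dominant_share` (default 0.8) of the planted
  envelope energy, cross terms included. Because non-negative envelope
  matrices are intrinsically close to rank-1, the realized one-synergy VAF
  sits above the energy share (≈0.92–0.96), reproducing the >0.9 VAF floor
  characteristic of STS data.
- **Carriers**: per-channel 20–450 Hz band-limited noise, unit RMS,
  amplitude-modulated by the planted envelope; white measurement noise at
  `snr_db` (default 20 dB, with 4 dB per-trial recording-quality jitter); per-subject log-normal gain (removed by
  normalization).
- **ECG**: QRS-like template train at `heart_rate_bpm` (default 75) with
  3 % beat jitter, added to RA and ESL at `ecg_amplitude` × channel RMS.
- **Motor variability**: per-trial log-normal jitter of the spatial weights
  (SD 0.06) and burst timing/width jitter; a per-trial global effort scale
  (log-normal, SD 0.25) raises or lowers all muscles together — invisible
  to the scale-invariant VAF, but the source of the strong positive
  co-variation of spatial weights across trials that gives the
  coordination network its edges.
- **Execution quality**: per-trial slow (<2 Hz) multiplicative gain drift
  per muscle, with a half-normal per-trial scale (`drift_sd`, default 0.13,
  capped at 0.15). This is the model violation that makes some trials
  "sloppier" than others. It is load-bearing: it spreads the per-trial VAF
  so that the above-k_true columns overlap, which is precisely what lets
  the significant-difference criterion distinguish a two-synergy condition
  (k = 2 significant against k = 1) from a three-synergy condition (k = 2
  *not* significant, k = 3 significant) — the qualitative self-/robot-STS
  contrast.

What passing tests on this data do **not** show: robustness to real-world
artifacts the generator omits (motion artifacts, electrode lift-off,
crosstalk between neighboring muscles, non-stationary heart rate, force-
platform synchronization error), correctness of the 80–200 Hz band choice
for other populations, or behavior when the synergy model itself is a poor
fit (e.g. pathological coordination). The Gaussian weight-observation
generator exists separately so the network stage can be validated against
a *known* precision matrix rather than against NMF output.

## Numerical choices and degenerate inputs

- NMF: ε = 1e-12 guards divisions; empty/negative inputs and invalid k are
  rejected; the all-zero matrix has undefined VAF and is an error.
- Identical data in every Kruskal–Wallis group returns H = 0, p = 1 rather
  than an error (no evidence of a difference).
- glasso: ρ = 0 short-circuits to matrix inversion; collinear observation
  columns (|r| > 0.9999) raise a non-convergence error — the likelihood is
  unbounded there; divergence of the constrained refit (singular resampled
  S with a dense support) is detected and the support skipped.
- Percentile CIs use linear order-statistic interpolation; at Nb = 200 the
  0.5 % quantile sits at the order-statistic resolution limit, so widening
  Nb changes bounds by less than 1/Nb.
- Seeds: one base seed fans out to per-stage streams through
  `numpy.random.SeedSequence`; every stochastic function takes its seed
  explicitly and identical inputs are bit-reproducible.

## Problem sizes used in validation

Desk-scale studies run at the study's own design: synergy-count recovery
uses 50 simulated replicates of 30 trials per condition (VAF tables over
k = 1..7 with 5 NMF restarts per fit); support recovery uses 20 seeds at
n ∈ {30, 100, 500} on an 8-node chain precision; bootstrap coverage uses
200-replicate bootstraps on 4-node networks with strong (0.6) planted
partial correlations, where a 12-point penalty path is ample. These sizes
are the package's validation defaults and are deliberately modest; all
scale linearly if larger studies are wanted.

## Known limitations

- The significant-difference criterion inherits the block-rank ceiling
  described above: with fewer candidate k or fewer trials the adjacent
  comparison can be structurally unreachable; the report object exposes the
  full Dunn table so users can see the margins.
- EBIC at n = 30 is conservative by design; absence of an edge is not
  evidence of conditional independence at weak effect sizes.
- SSA classification keys on envelope periodicity alone; cardiac-rhythm
  EMG bursts (e.g. cycling at 75 rpm) would be misclassified. For STS this
  is not a realistic failure mode.
- The bootstrap treats subject-trials as exchangeable, ignoring the
  within-subject correlation structure; a hierarchical bootstrap is out of
  scope.
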