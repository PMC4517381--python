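# Methods

## The multi-brain network model

A group hyperscanning session yields one hemodynamic (HbO) recording per
participant. After preprocessing, each participant is reduced to a
single ROI-averaged time series on a shared clock and rate; the
multi-brain network (MBN) is the graph whose nodes are participants (one
ROI per brain) and whose edge weights are pairwise inter-brain
synchronization values. Thresholding the K × K connection matrix at τ
(strict `>`, signed values by default, so anticorrelations never form
edges at a positive τ; an `absolute` option exists) yields a simple
undirected graph whose topology is summarized by efficiency, betweenness
and related indices.

### Graph indices

For a graph *G* with *N* nodes, shortest-path lengths *l_ij* (BFS;
disconnected pairs have *l* = ∞ and contribute 1/∞ = 0), shortest-path
counts σ_jk, and σ_jk(i) counting shortest j–k paths through interior
node i:

- nodal global efficiency: E_i = (1/(N−1)) Σ_{j≠i} 1/l_ij
- nodal local efficiency: the efficiency of the subgraph induced by i's
  neighbors, Σ over ordered neighbor pairs of 1/l (paths confined to
  the subgraph), normalized by N_Gi (N_Gi − 1); defined as 0 for nodes
  with fewer than two neighbors (no pairs to average — consistent with
  the zero entries printed for degree-1 participants in the worked
  example)
- network global efficiency: the same sum over all ordered pairs,
  normalized by N(N−1); algebraically the mean of the nodal values
  (asserted exactly in the tests)
- network local efficiency: mean over nodes of nodal local efficiency
  (the neighbor-subgraph efficiency and the nodal local efficiency are
  one quantity here)
- betweenness: B_i = Σ over **unordered** pairs {j,k}, j≠i≠k, of
  σ_jk(i)/σ_jk (fractional counting). σ_jk(i) is computed from the BFS
  factorization σ_jk(i) = σ_ji σ_ik when l_ji + l_ik = l_jk.
- degree, clustering coefficient (triangle fraction), characteristic
  path length (mean l over connected unordered pairs; on a disconnected
  graph computed over connected pairs with a warning flag), degree
  assortativity (Pearson correlation of end-point degrees over both
  edge orientations; NaN with a warning when degenerate).

**Why unordered, fractional betweenness.** The index set "j≠i≠k" leaves
ordered-vs-unordered ambiguous. Unordered fractional counting satisfies
the identity Σ_i B_i = Σ over connected unordered pairs of (l_jk − 1),
and the published nine-person table obeys exactly this identity
(betweenness row sums to 30.0; the reconstructed graph's path lengths
give the same value); ordered counting would double it. The identity is
asserted on random graphs in the test suite.

## Reconstruction of the nine-person worked example

The published demonstration reports, for a nine-person drumming session,
the MBN's degree, betweenness, local-efficiency and global-efficiency
rows plus the two network efficiencies, but not the graph itself in
machine-readable form (and the raw recordings are not deposited). The
`table1` module treats the table as a constraint-satisfaction problem:

1. enumerate every simple labeled graph realizing the printed degree
   sequence (3,5,5,1,4,5,3,5,1) — backtracking in label order where each
   node's unmet degree is satisfied among later nodes, pruned by the
   Erdős–Gallai condition on the residual sequence; the space holds
   2,982 labeled graphs;
2. keep graphs whose betweenness row matches within ±0.05 and whose
   local-efficiency row matches within ±0.005 — half the printed
   rounding unit (one decimal and two decimals respectively); two
   graphs survive, mirror images under exchanging the two degree-1
   participants' attachment points;
3. verify the **held-out** rows — the nodal global efficiencies and the
   network global/local efficiencies, which were never used as
   constraints — on the survivors. Exactly one survivor reproduces all
   held-out values within ±0.005 (max deviation 0.0046); the check
   passes when at least one solution does, and the solution count is
   always reported rather than uniqueness being presumed.

Splitting the table into constraint rows (degree, betweenness, local
efficiency) and held-out rows (the global efficiencies) makes the
reconstruction a genuine prediction test instead of circular fitting.
Candidate filtering uses fast integer-bitmask BFS; every survivor is
re-verified through the regular metrics path, which remains the deciding
implementation.

## Preprocessing chain

Order: align → resample → low-pass → ROI-average.

- **Alignment**: session time = local timestamp + instrument clock
  offset; session zero is the earliest offset-applied time in the
  group; all recordings are trimmed to the overlap window
  [max of starts, min of ends] (padding is never invented — complete
  pairwise overlap is what correlation needs). Offsets are taken as
  exact; no drift estimation.
- **Resampling** (55.5 → 10 Hz is a non-integer ratio, so integer
  decimation does not apply): order-8 zero-phase Butterworth anti-alias
  filter with cutoff at 80 % of the target Nyquist, then cubic-spline
  evaluation on the uniform target grid. A group shares one grid so all
  outputs have identical start, rate and length. Upsampling is refused.
- **Low-pass**: order-4 Butterworth at 2.5 Hz applied forward–backward
  (zero phase, squared magnitude). The testable contract is the
  response, not the realization: DC passes within 1e−9, a sine at half
  the cutoff retains ≥ 99 % amplitude, a sine at 1.8× the cutoff
  retains ≤ 1 %.
- **ROI average**: unweighted per-timepoint mean of the ROI's channels.

Filtering follows down-sampling here; both orders satisfy the stated
cutoffs, and filtering on the 10 Hz grid is cheaper and makes the
2.5 Hz contract meaningful on the grid the correlations use.

## Synchrony measures

- **Pearson** (default, used by the worked example): product-moment
  correlation of the full-session series; whole-session correlation is
  the default and windowing (`window=(length_s, step_s)`) is opt-in.
- **Coherence**: Welch magnitude-squared coherence (Hann, 50 % overlap,
  ≥ 2 segments, default 8) averaged over a band, default 0.01–0.5 Hz
  (the slow hemodynamic range). Segment averaging gives unrelated
  signals an expected coherence of ≈ 1/n_segments — asserted in tests.
- **Mutual information**: plug-in estimate from the joint equal-width
  8 × 8 histogram, in nats, no bias correction.
- **Granger**: directed log-ratio statistic ln(RSS_restricted/RSS_full)
  per direction at model order `max_lag` (OLS with intercept).
  Directed matrices are never thresholded implicitly; collapse with
  `symmetrize_directed` (max/mean/min) first, as an explicit choice.

## Synthetic group generator

The generator emulates the demonstration's acquisition so the pipeline's
hardest plumbing (two clocks, two rates) is exercised by default: nine
participants, the first four on a 10 Hz instrument (offset 0 s), five on
a 55.5 Hz instrument (offset 1.3 s), 600 s, eight channels over two ROIs
(four per ROI), one coupled ROI.

Signal model, per participant u:

    core_u(t) = β · Σ_{(u,v) planted} s_uv(t) + pink_u(t)
    roi_u = gamma_kernel * core_u          (convolution)
    channel_c = roi_u(t_c) + ε_c           (independent per channel)

- each planted edge owns one shared latent source s_uv: Gaussian noise
  band-passed to 0.03–0.5 Hz, unit variance. Edge-wise sources (rather
  than one group-wide source) make the planted *topology* recoverable,
  not merely group-level synchrony;
- pink noise (1/f, σ = 0.3) models slow physiological background;
- the hemodynamic kernel is a gamma density peaking at 6 s
  (shape 6, scale 1.2), unit DC gain;
- channel noise is flat-spectrum with per-sample σ = 1.0 ·
  √(rate/10 Hz) — a fixed spectral density referenced to a 10 Hz
  bandwidth, so both instruments carry the same in-band noise power
  after down-sampling, as an instrument noise floor does;
- the second ROI receives an independent uncoupled slow signal;
- all shared sources live on a master grid at the fastest rate with a
  40 s warm-up absorbing the kernel transient, spline-evaluated at each
  participant's own sample times; determinism is guaranteed by spawning
  one child generator per source from a single seed sequence.

**Coupling calibration.** The correlation across an edge whose endpoints
have planted degree d is r = β²·var(s) / (β²·d·var(s) + var(n)), capped
at 1/d as β → ∞ (a degree-d node shares only 1/d of its coupled variance
with any one partner). `calibrate_coupling` inverts the worst case
d = d_max: β² = r·var(n) / (var(s)(1 − r·d_max)), and refuses targets
r ≥ 1/d_max. The effective variances var(s), var(n) are measured by
pushing one seeded realization of each component through the exact
kernel/resampling/filter chain (a simulation-validated approximation;
the chain's combined transfer function has no tidy closed form). The
default planted graph is therefore a pairing (d_max = 1), the densest
topology compatible with a 0.7 target edge correlation.

**What the generator does and does not emulate.** It reproduces the
multi-rate/multi-clock acquisition, hemodynamic autocorrelation,
channel-level replication and planted pairwise coupling. It does not
model motion artifacts, systemic physiology (cardiac, respiratory,
Mayer waves), HbR, optode geometry or nonstationary coupling. Passing
recovery tests therefore show the *pipeline* is correct and calibrated
— that thresholded full-session correlations recover a planted
stationary coupling structure — not that τ = 0.5 is an appropriate
threshold for any particular real dataset.

## Problem sizes and numerical choices

- Recovery checks run the full pipeline at the default study
  conditions: 600 s sessions, 100 seeds for the calibrated-coupling
  recovery (mean edge accuracy ≥ 0.95 required) and 100 uncoupled
  seeds (≥ 99 % empty graphs at τ = 0.5; mean |r| < 0.05 over the
  first 50).
- Path-structure correctness is checked against exhaustive simple-path
  enumeration on 500 random graphs of ≤ 6 nodes, and against networkx
  as an independent implementation on larger random graphs.
- Matrix files store 17 significant digits so write→read round trips
  are bit-exact. Connection matrices for symmetric measures must be
  *exactly* symmetric (the builder mirrors each pair); externally
  produced near-symmetric matrices must be symmetrized explicitly.
- Correlations are clamped to [−1, 1] against floating-point overshoot;
  zero-variance series are an error rather than NaN.
- Ties at the threshold are excluded (strict `>`), so τ = 0.5 with a
  correlation of exactly 0.5 yields no edge.
- Uniform sampling is verified (1 % tolerance on timestamp increments)
  before any frequency-domain operation.

## Known limitations

- The reconstruction tolerances assume the published table was rounded,
  not truncated.
- Whether the published betweenness used fractional or integer path
  counting cannot be fully settled from one-decimal values; fractional
  unordered counting is adopted on the strength of the sum identity.
- The Granger statistic is the raw log-ratio, not an F-test with
  p-values; no inferential edge test (and no multiple-comparison
  correction across edges) is provided.
- `all_pairs_paths` stores σ_jk(i) densely (O(K³) memory) — fine for
  group-sized networks (tens of nodes), wasteful for hundreds.
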