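# Methods

## The kinetic model

A ternary elongation complex (TEC) is tracked by its transcript length
`L`, a pure birth chain on `{58, …, 231}` (1-based nucleotides from the
transcription start, the "+58/+231" convention; no strand handling).
Three rate rules define the generator:

- **Release from the stall.** The 58-nt state empties at rate
  `k_release` (s⁻¹). The transition out of 58 is the release event itself
  (it adds nucleotide 59), so the stalled fraction is exactly
  `e^{−k_release·t}` for *any* landscape — the identity the half-life
  estimator inverts, and an analytic anchor for tests.
- **Stepping.** Every other addition `L → L+1` occurs at `k_step` (nt/s),
  divided by the barrier factor `β ≥ 1` of the position being stepped
  into when that position is a barrier encounter. `β` is an effective
  escape parameter: waiting for a downstream histone dimer to yield is
  subsumed into it rather than modeled as a separate dissociation
  process, because binned length data constrain only the effective escape
  rate. Backtracked states are likewise not modeled explicitly.
- **Absorption.** +231 is absorbing (full-length product).

TFS enters as two multipliers: `tfs_release_mult` (> 1) scales
`k_release` up, and `tfs_barrier_mult` (≥ 1) divides `β`, floored so the
effective stepping rate never exceeds the barrier-free `k_step`.

Barrier-encounter positions derive from geometry: the polymerase leading
edge runs `leading_edge_offset` nt ahead of the RNA 3' end, so the first
collision with a dimer whose footprint starts at template coordinate
`hps_start` happens at transcript position `hps_start −
leading_edge_offset`, and every `dimer_footprint` (30 nt) thereafter.
The offset is a free parameter anchored so the default first encounter is
exactly +70, the observed prominent pause — the exact register of the
polymerase on the positioning sequence is not otherwise constrained.
With `first_only` (the default) only the first barrier carries `β > 1`,
reflecting the observation that downstream encounters do not pause
appreciably.

## Simulation and the exact oracle

Dwell times are exponential with state-dependent rates, so ensembles are
sampled exactly: per-molecule arrival times at each length are cumulative
sums of independent exponentials and the length at an observation time is
a binary search — no time discretization anywhere. Molecules are drawn
in fixed 10 000-molecule blocks, each block on its own child stream of
the master seed (results for a given `(seed, n)` are independent of block
execution order). Replicate and condition seeds derive from one master
seed, so study tables are byte-identical on rerun.

`transient_distribution` integrates the same generator exactly via the
dense matrix exponential of the 174-state bidiagonal `Q` (scipy
`expm`; milliseconds at this size). It is the oracle for every sampler
test: total-variation agreement under default constants, chi-square
goodness of fit (states pooled to expected counts ≥ 5) under diffuse
ones, monotonicity of mean length in time and in `β`. In the
instant-release limit the post-release stepping is a Poisson process, so
length = `59 + Poisson(k_step·t)` truncated at the end — note the one
step contributed by the release transition itself.

## Generator defaults (the simulated study)

Chosen once as a realistic emulation of the assay; they are illustrative
parameters of the synthetic study, not measured quantities, and
measured condition-specific rates are not claimed to be recovered.

- `k_step = 12 nt/s`: a fast hyperthermophilic polymerase; free-template
  transcripts reach +231 within the earliest timepoints, as in the
  qualitative time course.
- `k_release`: anchored at `0.005 s⁻¹` for WT chromatin (t½ ≈ 139 s) and
  scaled per condition by the relative half-life structure of the assay's
  summary table, so the synthetic study reproduces that table's *shape*;
  `tfs_release_mult` is the −TFS/+TFS half-life ratio per condition (all
  > 1: TFS promotes release).
- `β` per variant: ordered by the qualitative rate ranking (free 1,
  T55L 15, R20S 18, E3A 20, WT 60, G52K 100, E34A 400, G17D 600,
  E19K 900, E19K/G52K 5000 — the last giving a mean first-barrier dwell
  of ~400 s, a near-complete +70 capture over the standard window).
- `tfs_barrier_mult = 2` for E19K and G17D (whose +70 pause TFS
  relieves), 1 elsewhere — including the double mutant, whose pause is
  TFS-resistant.
- Observation times 15/30/60/120/240 s (extended protocol adds 480 and
  960 s); 4 replicates without TFS, 3 with; default 1000–2000 molecules
  per replicate, a scale at which replicate scatter is visible but
  estimator recovery stays within a few percent.

What the generator does *not* emulate: sequence-specific pausing on free
DNA, histone exchange dynamics, partially non-restarting TEC
subpopulations (release is a single exponential, so the two-point
half-life is exact here; on real gels bin-1 decay can be biphasic and the
estimator then reports an average), and 2-D gel artifacts. Passing tests
therefore demonstrate the correctness of the quantification machinery,
not the biological fidelity of any particular parameter value.

## Densitometry and binning

The synthesizer renders each length as a Gaussian band (area = gain ×
fraction, integrated per pixel via the normal CDF, tails cut at 6σ) at
the pixel given by a mobility model. Default mobility is linear in
length (12 px/nt over a 3000-px lane, i.e. a ~30 cm scan at 100 µm/px)
to match calibration by straight-line regression; a log-length mode
exists because denaturing-gel mobility is classically log-linear, and
fitting the wrong law is surfaced by structured calibration residuals
rather than hidden.

Quantification mirrors the manual workflow: marker peaks located by
prominence-thresholded local maxima with 3-point parabolic sub-pixel
refinement; ordinary least squares of pixel on (log) length, inverted
analytically; background removed by a morphological opening (running
minimum then matching running maximum, default width 201 px — a plain
running minimum leaves a constant offset under sloped baselines, the
opening does not); lane intensity integrated between the pixel images of
the bin edges with fractional-pixel precision and normalized to the lane
total within the template's range, so fractions are invariant to
exposure scaling. Whether to quantify raw or background-subtracted
volumes is a genuine ambiguity; both are supported, default subtracted.

The seven-bin scheme is a convention (the exact experimental edges are
not published): bin 1 = {58} (stalled complexes, midpoint pinned at 58),
bins 2–7 partition (58, 231] at 87/116/145/174/202, midpoints at the
interval centers (bin 7: 216.5, the "theoretical length" of full-length
products). Pixel integration uses half-integer boundaries (58.5, 87.5,
…) so each integer length's band center lies strictly inside its bin;
intervals are half-open on the increasing-length side to guarantee a
partition. The scheme is fully configurable.

## Statistics

- `L̄(t) = Σ f_b·m_b`; average rate `r = mean_t[(L̄(t)−58)/t]`. This is
  the published formula implemented verbatim; it is biased low once
  transcripts saturate at +231 (the length increase plateaus while `t`
  grows), and we document rather than correct the bias. Relative rates
  are ratios to the histone-free mean (the presentation is ambiguous
  between ratio and difference; the ratio is implemented).
- Pause kinetics: `k = ln(C1/C2)/(t2−t1)`, `t½ = ln 2/k`, with C1, C2
  the replicate-mean bin-1 fractions at 15 and 240 s (tabulated
  convention). `C2 ≥ C1` yields a flagged undefined half-life (NaN),
  never a negative number, and such conditions are excluded from
  relative tables. The reference (WT, −TFS) relative entry is set to
  1.00 identically rather than computed as `x/x`.
- Replicate summaries: mean and SE (`sd/√n`, ddof 1); SE is flagged
  undefined below two replicates. Default replicate handling computes a
  statistic per replicate and summarizes; a `mean_percentage` mode
  averages fractions first (figure parity) — the two agree exactly for
  the rate statistic, which is linear in the fractions on a fixed time
  grid.

## Numerical choices and edge cases

Fractions must sum to 1 within 1e-6 per lane (renormalized after exact
integration); oracle probabilities are clipped at 0 and renormalized
after `expm` (negative entries only at round-off scale). Calibration
with two markers is the interpolating line with `r² ≡ 1`. Degenerate
inputs raise: non-monotonic peak/length pairings, calibrations not
covering the bin scheme, empty bundles, zero starting-material signal,
`t = 0` rows in rate computation, non-positive C1/C2.

Problem sizes in the shipped tests and the acceptance script — 10⁵
molecules for half-life recovery, 10⁴ for goodness of fit, 2000 per
replicate for study tables — were chosen so each check's Monte-Carlo
error sits comfortably inside its tolerance while the whole suite runs
in seconds.

## Known limitations

Single-exponential release cannot represent mixed stalled populations;
the rate statistic is estimator-faithful rather than an unbiased nt/s;
variant `β` values are ranked, not fitted; no 2-D image analysis (lane
traces only); no statistical comparisons between conditions are
performed (none are defined for this pipeline).
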