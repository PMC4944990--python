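# Methods

## The compliance model

Social psychophysiological compliance (SPC) is operationalised as the
Pearson product-moment correlation between the windowed HRV feature
vectors of the two members of a collaborating dyad, and at the
classroom level as μ_true, the arithmetic mean of the per-dyad
correlations for one feature and one window length. The underlying
assumptions are:

- R-peak timing is extracted reliably enough that beat-level artifact
  filtering (band 300–2000 ms, >30% deviation from the running median
  of the previous 10 accepted intervals) leaves a representative
  normal-to-normal series. Rejected intervals are dropped, never
  interpolated, and a rejection breaks adjacency for rMSSD's successive
  differences.
- The features — HR = 60000/mean(NN) bpm, SDNN = sample SD (ddof = 1)
  ms, rMSSD = root mean square of adjacent successive differences ms —
  are stable at window lengths of 60 s and above, which is why the
  analysis sweeps 60–300 s rather than using frequency-domain measures
  that need longer stationary stretches.
- Windows advance by length − overlap with overlap = length/3 (so the
  step is two thirds of the window). The alternative reading
  "step = length/3" is supported via the configurable `overlap_s`.
  Windows with fewer than `min_beats` (default 10) intervals are
  flagged invalid, and dyad correlations use pairwise-complete windows
  only; a dyad needs ≥3 jointly valid, non-constant windows or it is
  excluded (with a warning) and counted.

## The class-restricted permutation null

The inferential contrast is not "is μ_true nonzero" but "is μ_true
larger than what the shared room produces". Second members are
re-paired with first members uniformly at random within each class;
first members stay fixed, the true pairing stays in the support, and
each draw's shuffled mean μ_r is one sample from the null. Because
every admissible pair is an entry of a per-class (first × second)
correlation matrix, the matrices are computed once and 10000 draws are
nearly free. From the draws: the 95% CI is the empirical 2.5/97.5
percentile pair (linear interpolation, for bit-reproducibility), and
the two-tailed p-value is

    p = min(1, 2 · min tail (1 + #{tail}) / (N + 1)),

the +1 smoothing being standard Monte-Carlo practice (p is never 0,
and the test is exactly valid under exchangeability). Holm–Bonferroni
is applied across the three features within one window length by
default; the family is configurable to all feature × window tests. For
small layouts an exact enumerator over all block permutations serves as
the oracle the Monte-Carlo null must converge to.

## The workload regression

Per-dyad compliance r is modelled by ordinary least squares on the six
dyad-summed self-report items (mental demand, temporal demand,
performance, effort, frustration, navigating concentration; the
physical-demand TLX item is not collected as irrelevant to seated
work). With n dyads the residual df is n − 7; 95% CIs are t-based
(matching standard linear-model summaries) and adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 8). At the study scale (n = 19) the
design needs full rank and at least 8 dyads; both are checked with
explicit errors.

## The synthetic classroom generator

The generator emulates the statistical structure the analysis assumes,
not ECG morphology. Per participant the k-th interbeat interval is

    IBI_k = 60000 / HR(t_k) + σ(t_k) · ε_k,   ε_k ~ N(0, 1)

with beat times the cumulative sums (clipped to 301–1999 ms, so the
series is inside the artifact band by construction). Its three
ingredients map one-to-one onto the phenomena the analysis must
separate:

- **Classroom-common drift.** HR(t) = HR₀ + slope·t with a shared slope
  (default −0.05 bpm/min ≈ −4.5 bpm over 90 min, gradual relaxation)
  expressed by a `trend_participation` fraction of dyads (default 0.8);
  HR₀ is per-participant (SD 3 bpm). This makes HR vectors correlate
  highly for *any* same-room pairing — the confound the restricted null
  is designed to absorb.
- **Dyad-coupled dispersion.** σ(t) = noise_sd · exp(g·z(t) − g²/2)
  with g = 0.5 and z(t) = √κ·u(t) + √(1−κ)·v(t), where u is shared by
  the dyad and v is private; both are unit-variance Ornstein–Uhlenbeck
  paths on a 1 s grid with a 120 s timescale (the simplest stationary
  process with controllable window-scale autocorrelation). Coupling κ
  enters *only* through dispersion, never the mean IBI, so SDNN
  compliance is pairing-specific while HR correlation is not — the
  dissociation the analysis is built to detect. The −g²/2 term keeps
  E[σ] at `noise_sd` (default 15 ms).
- **Reports.** Items are Gaussians rounded and clipped to the 0–10
  integer scale, centred on population norms typical of a demanding
  classroom session (MD 6.0/2.05, TD 6.0/1.88, Pe 6.4/2.50, Ef 6.3/2.62,
  Fr 4.2/2.91, Na 8.1/1.69). Temporal demand alone depends on coupling:
  the expected dyad TD *sum* has slope `tlx_temporal_effect` (default
  −6) in κ, centred on the classroom-mean κ so the population mean is
  preserved.

Defaults are the emulated study conditions: 4 classes of 5/5/5/4 dyads
(38 participants), 5400 s sessions, 800 ms base IBI, and per-dyad κ
spread evenly over [0.1, 0.9] when not specified. One
`numpy.random.default_rng(seed)` stream drives the whole classroom, so
identical configs are bitwise-reproducible.

What the generator does **not** emulate: PQRST morphology (the ECG
synthesizer is a Gaussian-bump train over noise and baseline wander,
adequate for exercising the peak detector, nothing more), respiration
and respiratory sinus arrhythmia, EDA, ectopic-beat physiology,
movement artifacts, sensor dropout, or pre-acquaintance between dyad
members. Passing tests therefore show that the statistics behave
correctly when their assumptions hold — calibrated type-I error,
power against genuine dispersion coupling, sign recovery of the
workload effect — not that real classroom ECG satisfies those
assumptions.

A quirk worth knowing: with dyad-level trend participation π, the
fraction of dyads whose two members *both* show a negative fitted HR
trend settles near π + (1 − π)/4 (≈0.85 at the 0.8 default), because
non-trending participants' fitted slopes are sign-symmetric noise.

## Numerical choices

- R-peak detector: 2nd-order Butterworth band-pass 5–30 Hz (capped at
  0.9·Nyquist), squared gradient integrated over 150 ms, per-10 s-block
  threshold at 30% of the block's 99.5th envelope percentile, 250 ms
  refractory, candidates refined to the raw-signal maximum within
  ±40 ms. Flat or candidate-free signals return an empty beat series or
  raise, per the `on_flat` switch.
- Correlations are clamped to [−1, 1] after the dot-product form;
  constant series are NaN-flagged rather than raising.
- Stage outputs are written with %.17g so that file-piped stage
  composition (`features` → `compliance` → `permtest` → `regress`)
  is byte-identical to the one-shot pipeline; readers parse floats with
  Python's correctly-rounded `float()`.
- Permutation substreams are namespaced per (feature, window) from the
  single pipeline seed, so results do not depend on execution order.
- The artifact filter has a vectorised fast path used only when it can
  prove a sequential pass would reject nothing; otherwise the exact
  sequential rule runs.

## Problem sizes used in the test suite

Calibration properties run at deliberately modest scales chosen as the
smallest that still pin the behaviour down: type-I error uses 200
uncoupled classrooms of 2 classes × 5 dyads with 25-minute sessions and
500 permutations (the binomial 95% band around α = 0.05 is then
±0.030); power uses 20 full-scale default classrooms at κ = 0.8 (a
calibration run rejected in all 20 with every p at the Monte-Carlo
floor, so the frozen 0.8 floor is conservative); the zero-coupling mean
uses 100 classrooms of 3 dyads; sign recovery of the temporal-demand
effect uses 50 full-scale classrooms (47/50 negative at calibration).

## Known limitations

- The artifact-exclusion rule is one defensible short-term-HRV choice
  among several; thresholds are configurable because participant-level
  exclusion criteria in field data are study-specific.
- The Monte-Carlo p-value's resolution is 2/(N+1); with few dyads per
  class the null support itself is coarse, and the exact enumerator is
  preferable below ~5 dyads per class.
- rMSSD is implemented as the *root* mean square of successive
  differences (the canonical definition); the windowed quantities are
  internally consistent under translation and scaling of NN deviations.
- The regression treats dyads as independent observations, as the
  study-scale n = 19 does not support room-level random effects.
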