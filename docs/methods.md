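# Methods notes

This note records the modeling assumptions, parameter choices and
numerical conventions behind `laminargc`, in the order the pipeline runs.

## Synthetic laminar recordings

The generator emulates the structure of a two-probe laminar attention
experiment: per-trial epochs of `n_samples` points at `fs` (defaults 512
at 1017.375 Hz, i.e. 503.25 ms), two probes of 16 contacts at 150 µm
spacing, and trials split evenly across attend-RF / OUT1 / OUT2
conditions.

A session's latent dynamics are built in three layers:

1. **Band-limited oscillators.** Each oscillator is fresh white noise
   band-pass filtered per trial (two second-order Butterworth sections,
   a 4-pole filter) around its per-condition center frequency, normalized
   to unit RMS, and mixed onto one probe's contacts through a depth
   profile.  Filtered noise rather than sinusoids gives spectra with
   realistic peak widths.  Condition effects enter as per-condition
   amplitude gains and center-frequency offsets.
2. **Directed couplings.** Couplings are finite-lag linear terms; the
   channels evolve as `x_t = Σ_k A_k x_{t−k} + u_t` where `A_k` holds the
   coupling gains and `u_t` the oscillator-plus-noise innovations.  The
   latent system is therefore exactly a vector autoregression, making GC
   recovery analytically meaningful; an unstable specification (companion
   spectral radius ≥ 1) is rejected up front, naming the strongest
   coupling.
3. **1/f background.** Per-channel noise is white noise spectrally shaped
   to a 1/f^α power profile (α configurable, default 1), normalized to
   the configured SD in µV.

Stimulus-onset epochs additionally carry an **evoked potential**: a CSD
profile with a unit sink at the configured granular contact and balancing
return sources, pushed through the disc forward model and scaled to a
peak amplitude in µV, under a Gaussian temporal envelope (latency 40 ms,
SD 10 ms by default).  A multiunit-envelope tensor with the shortest
response latency at the sink contact accompanies such epochs.  Pre-dimming
epochs carry no evoked component — time-locked transients survive trial
shuffling and would contaminate GC nulls, which is why the pipeline (like
the experimental design it mirrors) computes spectra and GC on the
pre-dimming window and alignment on the stimulus-locked window.

Randomness: one seed per session; trial content comes from per-trial
counter-split substreams (`SeedSequence(seed).spawn`), so reordering
trials cannot change their content, and identical seed + config gives
bit-identical output.

What the generator does **not** emulate: eye movements and microsaccades,
spiking point processes, nonstationarities within an epoch beyond the
evoked transient, moving vs. stationary stimulus differences, and the
across-session heterogeneity of real recordings.  Passing tests therefore
demonstrate estimator correctness and calibration on in-model data, not
robustness to every artifact of real LFPs.

## Preprocessing

Bipolar derivations are adjacent-contact first differences, superficial
minus deep, assigned to the parents' midpoint depth; derivations never
span probes.  This cancels probe-common signal exactly (up to floating
point) and sharpens spatial specificity.  Epoch extraction is a pure
view — no filtering or detrending; per-trial mean removal happens where
spectra and VARs are fitted.  The baseline window runs from 200 ms before
to 30 ms after stimulus onset (234 samples at the default rate); baseline
spectra are computed on that shorter window with the same taper family
and linearly interpolated onto the analysis frequency grid.

## Inverse CSD and laminar alignment

The conduction matrix F integrates the uniform-disc kernel
`(sqrt(Δz²+R²) − |Δz|)/2σ` (R = 500 µm, σ = 0.4 S/m) against the cardinal
cubic-spline basis through the contact depths (natural boundary
conditions; 40-point trapezoid quadrature per inter-contact interval,
with the kernel's |Δz| kink always on a grid node).  `compute_icsd`
inverts exactly this matrix, so any CSD in the spline span round-trips to
machine precision; σ scales magnitudes only, never the spatial profile.
The inverse is smoothed along depth with a Gaussian of SD 200 µm
(reflection padding at the grid edges).

Sink detection: per depth, onset is the first time inside a 20–100 ms
post-stimulus search window at which the smoothed CSD falls below
−0.25 × |global peak sink|; the earliest onset wins, ties going to the
larger sink.  Both the threshold fraction and the window are exposed as
parameters, as no standard convention exists.  MUA latency uses baseline
mean + 3 SD with a 5-sample sustained-crossing requirement (single-sample
noise excursions otherwise dominate when baselines are quiet).  When the
two disagree the CSD sink wins and a warning is logged.

Compartment ranges (mm from the layer-IV reference, positive =
superficial): V1 — supragranular 0.25–1, granular within 0.25,
infragranular 0.25–0.75 below; V4 — supragranular 0.1–1, granular within
0.1, infragranular 0.1–0.75 below.  Outer bounds are closed and the
granular bound open (so ±0.25 mm in V1 is supra-/infragranular, not
granular); contacts outside all ranges are `unassigned` and excluded from
compartment pooling.

## Spectral estimation

Defaults K = 3, TW = 2, N = 512; K ≤ 2TW−1 is enforced (leakage bound).
Power is scaled so its frequency integral equals the signal variance.
Coherence pools all taper–trial cross-spectral products jointly before
forming the ratio; the estimator's small-sample bias for independent
signals is ≈ 1/(K·n_trials), which the test-suite checks against that
analytic value.  Pair order is canonicalized so C_ij and C_ji are
bitwise identical.  Sliding spectrograms right-align windows to the
event so the last window ends at t = 0; 20 ms steps over a 1006.5 ms
span give 26 windows.  Band averages exclude DC and Nyquist bins and use
lower-inclusive/upper-exclusive edges (last band upper-inclusive).  Peak
localization applies an optional 3-bin moving average (default on) and
resolves ties to the lower frequency, flagging flat spectra and
band-edge maxima.

## Conditional Granger causality

VAR fits use multi-trial least squares on per-trial demeaned epochs with
lag-stacked covariances pooled across trials; when no order is fixed, BIC
is evaluated over 1..p_max (default 20) on a common sample.  Guards: an
effective-sample ratio ≥ 10 × order × dim², a conditioning-number check
on the lag covariance (an exactly duplicated channel raises), companion
spectral radius < 1, and a ridge of 1e−8·trace/dim on the innovation
covariance when it loses positive definiteness (logged).

Spectral conditional GC follows the Geweke two-model partition method:
full model on (Y, X, Z) and reduced model on (Y, Z) at the same order;
the full innovations are decorrelated from Y's, the reduced transfer is
embedded (identity on X) and inverted against the full transfer, and
`f(λ) = ln(Σ_R[yy] / |Q_yy|²Σ[yy])`.  Negative bins are numerical
artifacts of the two-model method, clipped at zero and counted (a
warning fires above 1% of bins; near-null pairs routinely clip many bins
of magnitude ~1e−4).  The frequency average of f equals the time-domain
GC (Geweke's integral identity), verified against an analytic oracle
whose reduced innovation variance comes from the Kolmogorov–Szegő
formula on the closed-form spectrum.

Conditioning sets: for a within-probe pair, the remaining derivations of
that probe; between probes, the remaining derivations of both; capped
(default 8) to the channels nearest in depth to the pair's midpoint, for
dimensionality control.  The cap and policy are configuration, and the
set used is recorded per pair.

Shuffle nulls permute the source channel's trial order relative to the
target; the conditioning set stays with the target, so the null preserves
everything except source-target alignment.  The reduced model is
unaffected by the permutation and reused across shuffles.  Defaults: 200
shuffles, 95th percentile, seeded; per-band thresholds are percentiles of
band-averaged null cGC.  Because the observed statistic of a genuinely
null pair is calibrated against its own 95th-percentile threshold, about
5% of null comparisons exceed it by construction — the chain-conditioning
check (X→Z→Y with no direct link) passes in ~95% of replicates in
expectation, not deterministically.

## Attention statistics

OUT pooling subsamples min(n_OUT1, n_OUT2) trials from each away
condition (seeded).  Trial counts are balanced between RF and pooled OUT
before trial-count-sensitive estimators (coherence, GC).  The MI is
computed on raw (nonnegative) power for spectrograms; z-scored power can
be signed, which makes the ratio ill-behaved, so the z-variant is opt-in.
Wilcoxon signed-rank tests treat the session as the statistical unit;
tests with fewer than 5 non-tied pairs are skipped and flagged;
Benjamini–Hochberg step-up runs within each frequency-band family at
q = 0.05.  Dominance matrices assign significant pairs the session-mean
strength of the dominant direction with an antisymmetric sign pattern.
cGC normalization divides each subject-group/pool by its maximum
band-averaged cGC across the five bands.  A single-factor
repeated-measures ANOVA over the RF/OUT1/OUT2 triplet is available as a
secondary check before pooling.

## Validation problem sizes

The self-validation experiments (`laminargc.validation`, also run by
`scripts/acceptance.py`) use: 16 depths for the iCSD round trip; a
bivariate VAR(1) with (a, b, c) = (0.5, 0.7, 0.4) at 200 trials × 512
samples for the GC oracle; 50 replicates of a 3-channel, 60-trial,
256-sample white-innovation chain with 100 shuffles for conditioning
soundness; 20 two-probe no-effect sessions of 120 trials for MI null
calibration; and 100 trials/condition for the +4 Hz gamma peak-shift
recovery.  These sizes keep each experiment well-powered for its stated
tolerance while the whole battery completes in well under half an hour.

## Known limitations

- Parametric (VAR-based) GC only; nonparametric spectral-factorization,
  state-space and time-varying GC are out of scope, as are other directed
  measures (PDC, DTF) and phase-based connectivity.
- The spline iCSD assumes an isotropic homogeneous medium and
  disc-shaped sources; kernel/δ-source variants and histological layer
  boundaries are not implemented.
- The two-model spectral cGC is biased near zero (hence the clipping);
  interpretation should always be relative to the shuffle null, never to
  zero.
- Compartment boundary inclusivity and the sink-onset criterion are
  conventions chosen here, documented above, and exposed as parameters.
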