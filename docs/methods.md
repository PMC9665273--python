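# Methods

This note documents the models, conventions, and design decisions behind
`physiofc`, in the order data flow through the package.

## Physiological phases

Pulse peaks on the plethysmography trace stand in for ECG R waves.  The
cardiac phase is piecewise linear: φ_c(t) = 2π (t − t_k)/(t_{k+1} − t_k)
for t between successive peaks, reset to 0 at each peak.  The respiratory
phase is anchored at troughs (end-expiration, φ_r = 0) and peaks
(end-inspiration): inspiration maps linearly onto (0, π], expiration onto
[−π, 0).  The value at the breath peak is the circular boundary ±π;
internally the phase is built as an unwrapped ramp (π per half-breath)
and wrapped to (−π, π], so cos(mφ_r) and sin(mφ_r) are continuous across
the peak.  A literal reading in which expiration restarts at 0⁻ would
make cos φ_r jump at every breath peak; the circular convention preserves
the same phase ranges as sets while keeping the regressors usable.

Extremum detection uses a local-maximum scan (scipy `find_peaks`) with a
minimum separation (0.4 s cardiac, 1.5 s respiratory — conservative
bounds on physiological rates) and a prominence floor of 25% of the
trace's interquartile amplitude.  Frames before the first or after the
last detected event extrapolate the nearest interval's duration and are
flagged in the output.  Phases are sampled once per volume at the frame
midpoint; slice-wise phase sampling is out of scope.

Recording quality is classified in precedence order: *missing* (channel
absent), *dropout* (exact flatline runs ≥ 1 s covering > 10% of the
trace), *noisy* (cycle-interval coefficient of variation > 0.35,
high-frequency residual power fraction > 0.15 above a channel-specific
ceiling, or peak-amplitude CV > 0.40, which catches amplitude-modulation
from a badly positioned sensor), else *clean*.  The thresholds are
configurable; the defaults are deliberately conservative so that clean
simulated traces classify clean and each simulated failure mode lands in
its intended category.

## BOLD conditioning

The first 12 volumes (pre-equilibrium magnetization) are discarded, then
each series is despiked: samples deviating more than k = 4 MAD-units
from a centered running median (window 11 frames) are compressed through
a smooth saturating map, F + s·tanh((d − F)/s), which bounds any spike at
one MAD-unit past the fence while leaving sub-fence samples bit-exact.
The MAD unit is the normal-consistent robust scale (1.4826 × the median
absolute deviation from the running median), so the fence sits at ~4
robust standard deviations; a raw-MAD fence (~2.7 SD) would routinely
clip ordinary signal extremes.  Zero-dispersion rows pass through
unchanged.

Percent signal change (ΔBOLD) is 100·(x − mean)/mean per series.  Drift
and motion are removed in one orthogonal projection onto Legendre
polynomials of orders 0–5 over the scan interval (an orthogonal,
numerically stable basis spanning the same space as raw monomials;
order 5 over ~590 s targets drift below ~0.005 Hz) plus the six
mean-centred rigid-body motion parameters.  The design is rank-checked,
the residual is orthogonal to every column, and the projection is
idempotent.

Motion outliers are flagged volume-wise when the Euclidean norm of the
frame-to-frame derivative of the six parameters exceeds 0.4, with
rotations converted to arc length on a 50 mm sphere (the standard
enorm-style criterion).  The inequality is strict; flags are reported but
not applied — whether flagged frames should be censored is left to the
caller, and censoring is off by default.

Pipeline order: discard → despike → [RETROICOR] → percent change →
projection for the regression arm; discard → despike → percent change →
projection → bandpass for the filtering arm.

## RETROICOR

The design holds cos(mφ_c), sin(mφ_c), cos(mφ_r), sin(mφ_r) for
m = 1..order (default 2, the convention of the standard implementations;
1–4 supported).  Coefficients are estimated jointly by OLS — a single
projection, order-independent — rather than per channel sequentially.
The fit carries an implicit intercept because the phase regressors have
nonzero temporal means and the correction runs on raw, not-yet-demeaned
series; only the phase-regressor contribution is subtracted, so the mean
level survives for the subsequent normalization.  Omitting the intercept
is not a formality: without it the fit soaks the signal baseline into
the regressors and injects a large shared artifact into every series.

Correcting at order 2 cannot remove harmonics a real signal may carry at
order 3+; the test suite demonstrates the residual third-harmonic power
explicitly as a documented limitation of fixed-order correction.

## Bandpass grid

Band edges are exact powers of two internally (2⁻⁷ = 0.0078125 Hz is
displayed as "0.008"), inclusive on both sides.  Filtering is ideal
DFT-bin selection: components with f_lo ≤ f ≤ f_hi are kept, everything
else — including the DC term — is zeroed, and the series is inverse
transformed.  This matches the frequency-bin-removal framing used for
degrees-of-freedom accounting, is exactly idempotent and linear-phase,
and needs no transient or ripple tuning.  No taper is applied: series
reaching the filter are already detrended and demeaned.  The
degrees-of-freedom cost of a band is 2 per retained positive-frequency
bin (the real-valued Nyquist bin counts once); the package makes no
claim to reproduce any particular published dof figure, whose derivation
is not specified.

## Connectivity

The node set is 83 regions: 82 cortical/subcortical grey-matter parcels
(41 per hemisphere) plus one composite ascending-arousal-network
brainstem node, giving C(83,2) = 3403 unordered pairs.  The packaged node
table doubles 39 standard parcel names across hemispheres and adds
ventral diencephalon and cerebellar cortex to reach 82; it is a
synthetic-but-plausible stand-in, and any table with unique ids works.
Region series are unweighted voxel means; regions overlapping a lesion
mask by more than a configurable fraction (default: any overlap) are
masked, as are constant or NaN series (with a warning).  Pearson r is
clipped at |r| = 1 − 1e−12 before the Fisher transform z = atanh(r);
saturated pairs are flagged.

## Pipeline comparison statistics

Per region pair, a two-sided paired t-test compares the Fisher-z values
of the two arms across subjects; zero-variance differences produce ±inf/0
or 0/1 sentinels rather than NaNs.  Multiple comparisons are corrected
with Benjamini–Hochberg step-up FDR (the package's fixed choice of FDR
procedure), with NaN pairs excluded from the family.  The
correlation-versus-band curve is the Pearson correlation, across pairs,
of group-mean z from the RETROICOR arm against each bandpass arm.
Agreement per pair is ICC(2,1) — two-way random effects, absolute
agreement, single measures — computed from the ANOVA mean squares,
vectorized across all 3403 pairs; significance is the F-test
MSR/MSE on (n−1, (n−1)(k−1)) df, again BH-FDR corrected.  A consistency
variant (ICC(3,1)) is available behind a flag.  Pairs with zero
between-subject variance return a NaN sentinel and leave the FDR family.

Feasibility triage partitions subjects in precedence order: unusable
fMRI → any physiological channel absent ("incomplete") → any channel not
clean ("poor quality") → retained.  Percentages of incomplete/poor/
retained are reported relative to the subjects with usable fMRI.

## Synthetic data

The generator emulates the target acquisition — 482 volumes at
TR 1.25 s (602.5 s), physio at 50 samples/s (a configurable default; PMU
hardware rates vary and are rarely reported) — and stores the exact
decomposition of the observed percent signal:

observed = neural + contamination + drift + spikes + noise.

*Physio traces.*  Per-cycle rates are drawn N(1.0, 0.05) Hz cardiac and
N(0.3, 0.03) Hz respiratory.  The cardiac waveform is an asymmetric
pulse (raised-cosine upstroke over the first 15% of the cycle, then
exponential decay), so peak detection is non-trivial; the respiratory
waveform is a raised cosine per breath.  Traces cover the scan plus one
cycle of padding, and the true event times are stored.

*Neural.*  Band-limited to [0.008, 0.125] Hz by DFT-bin shaping of white
Gaussian series, then coloured so that the empirical inter-regional
correlation equals the target exactly (whiten-then-colour — the standard
variance-reduction construction; it satisfies the "correct in
expectation" contract while removing neural sampling noise from
ground-truth comparisons).  The default target has lobe-like blocks
(+0.35), homotopic pairs (+0.25) over a 0.10 baseline, projected to the
nearest positive-semidefinite correlation matrix.  Amplitude 1
percent-signal unit.

*Contamination.*  An order-2 (optionally order-3, for model-mismatch
experiments) Fourier series in the true phases, with per-region random
amplitudes scaled to 0.5 %-units.  Sampled at frame times, the ~1 Hz
cardiac component folds to 0.2 Hz and the harmonics to 0.2–0.4 Hz, all
above the neural band.

*Noise, drift, spikes, motion.*  Thermal noise defaults to 0.05 %-units:
region averaging over hundreds of voxels shrinks spatially incoherent
noise by roughly the square root of the voxel count, while the spatially
coherent neural and physiological components survive; the generator
models region-level series, not voxels.  Drift is a random (or supplied)
Legendre series of orders 1–5, 0.3 %-units per coefficient.  Motion
spikes arrive as a Poisson process (1 per 100 frames, 4 %-unit
amplitudes) shared across regions, with matching step jumps in the
motion parameters; the smooth motion component lives below 0.005 Hz
(slow settling), the same band the polynomial detrend targets.

*Identifiability.*  Two construction choices make the stored components
exactly recoverable.  First, neural and drift are orthogonalized
in-sample against the intercept-augmented contamination design, so OLS
on the true phases returns the contamination exactly and "residual =
neural + drift" holds to machine precision on noise-free data; without
this, the random in-sample overlap between neural and 8 regressors at
470 frames is ~0.1 RMS and variance attribution is ambiguous.  Second,
the percent-signal components are generated on the retained
(post-discard) frame grid, and the 12 discarded volumes are synthesized
as pre-equilibrium junk (elevated, decaying baseline) — mirroring why
early volumes are discarded in practice and aligning the neural band
with the analysis-grid DFT bins.

*Failure modes.*  `corrupt_physio` implements the catalogued modes:
absent channel, intermittent loss (non-overlapping flatline segments),
broadband motion noise at a target SNR, and slow amplitude modulation
from a badly positioned sensor.  `generate_cohort` draws a usable-fMRI
flag and one failure mode per channel independently per subject.

*What the generator does not model.*  No hemodynamic response or
neurovascular coupling; no image-domain motion (motion exists only as
parameter traces and spike amplitudes); no low-frequency physiological
processes (respiratory volume, CO₂, heart-rate variability) inside the
neural band; frequency-flat inter-regional mixing (every sub-band of the
neural range carries the same correlation structure); homogeneous noise
levels across subjects.  Passing tests therefore show that the pipelines
behave correctly when their assumptions hold, not that RETROICOR and
bandpass filtering are interchangeable on arbitrary real data — in
particular, contamination below 0.125 Hz would defeat both corrections.

## Study-scale checks and their conditions

The published group-level comparison cannot be re-run (the imaging data
are not publicly shareable), so the equivalence findings are validated
as properties of synthetic cohorts: 10 subjects, 83 regions, 470
retained frames, order-2 contamination aliased above 0.125 Hz.  Under
these conditions the correlation-versus-band curve attains its maximum
at 0.008–0.125 Hz and the paired t-test yields zero FDR rejections in
~96% of seeded cohorts (the residual rejections are always a single pair
whose microscopic but cross-subject-consistent difference — bandpass
removes out-of-band thermal noise, regression does not — meets a
near-degenerate difference variance).  Motion spikes are excluded from
these cohorts because broadband spikes are not "noise above the neural
band": filtering attenuates them while regression cannot, a genuine
asymmetry between the methods that the equivalence conditions
deliberately avoid; spikes stay on by default everywhere else.

Conditioning is not free: projecting out 12 nuisance directions (6
Legendre, 6 motion) from 470 frames perturbs the maximum absolute
pairwise correlation against ground truth by up to ~0.07 across 3403
pairs (median ~0.007).  This is a dimensional cost of nuisance
regression, not an implementation defect, and the regression tests bound
it at 0.1 (max) / 0.02 (median).

## Numerical conventions

Seeds propagate through `numpy.random.SeedSequence.spawn`, so every
generator output is bit-reproducible from a single integer.  Fisher-z
clipping at |r| = 1 − 1e−12; residual-orthogonality tolerances 1e−8
relative; degenerate inputs (flat traces, constant regions, rank-deficient
designs, zero-variance differences) raise typed errors or produce
documented sentinels rather than NaNs.  File outputs are plain TSV/JSON
(NIfTI for volumes); run manifests record the config hash, seed, package
version, and per-subject warnings, and identical config + seed produce
bit-identical outputs.
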