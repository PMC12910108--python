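# Methods

`polku` simulates and analyzes two-color alternating-laser-excitation (ALEX)
single-molecule experiments on DNA polymerase λ binding a surface-tethered
primer-template junction, with or without the Ku70/80 heterodimer pre-loaded
on the DNA end, plus the two bulk assays that accompany them (primer-extension
gel densitometry and microscale-thermophoresis titrations). This note records
the models, the tunable parameters, and the design choices made where the
procedure was genuinely open.

## Time base and channels

One frame is one 200 ms excitation cycle alternating a green (donor) and a
red (acceptor) laser; the three recorded channels per cycle are `F_DD`
(donor excitation → donor emission, the Cy3B-labeled DNA), `F_DA` (donor
excitation → acceptor emission, the FRET channel) and `F_AA` (acceptor
excitation → acceptor emission, the Cy5-labeled polymerase). Both channels of
a cycle share one timestamp; the 1 s ≡ five-frames equivalence used by the
event rules fixes this convention. Trajectories are background-corrected
intensities, as produced by the imaging stage; the simulator's `background`
field (default 10 photons/frame/channel) emulates residual background and
keeps the 50-photon event threshold far above it.

## Trajectory simulators

**Colocalization** (`simulate_colocalization`). Each molecule is a binder
with probability `bound_fraction`. Binders wait an Exponential(1/`k_bind`)
time before first binding, stay bound Exponential(`tau_dwell`), and rebind
after further Exponential(1/`k_bind`) gaps. While bound, `F_AA` emits
Poisson(`photon_budget`) per frame (500 by default, tenfold above the
50-photon threshold, fiftyfold above background); the DNA channel is
constant-bright until the donor's single-step photobleach
(Exponential(`bleach_tau_donor`), 200 s default — dyes under oxygen-scavenged
TIRF illumination survive minutes).

**FRET incorporation** (`simulate_fret`). A binder binds once (the primer is
consumed by extension, so rebinding at the initial FRET level would not be
physical). On binding, the FRET efficiency starts at `e_start` (0.6) and
drops by `delta_e_per_nt` (0.1) at each incorporation; the `n_nucleotides`
(4) per-nucleotide waiting times are Exponential(`t_incorporation`/`n`), so
the total incorporation time has mean `t_incorporation` and a gamma shape.
After the last incorporation the molecule stays bound Exponential(`tau_dwell`)
at the final level. Ideal channel rates while observable are
`F_DD = (1−E)·B`, `F_DA_ideal = γ·E·B`, `F_AA = B`; the recorded FRET channel
adds donor leakage `l·F_DD` and direct excitation `d·F_AA` before Poisson
sampling. The acceptor bleach clock starts at binding (the dye is only
illuminated at the spot once immobilized); the donor clock runs from frame 0.
Defaults `l = 0.1`, `d = 0.05`, `γ = 1.2` are typical ALEX values.

State is piecewise constant in continuous time and integrated over each
frame, so events beginning or ending mid-frame contribute fractional
intensity exactly as on a camera. `noiseless=True` returns expected rates,
which the exactness tests rely on. All randomness flows from one
`numpy.random.SeedSequence` per scenario, spawned per molecule, so results
are reproducible and independent of iteration order.

**What the generator does not emulate**: dye blinking, diffusing background
molecules, stage drift within a trajectory (drift is exercised in the imaging
module), heterogeneous per-molecule brightness or starting efficiency,
non-exponential (multi-step) nucleotide chemistry, and polymerase
translocation without incorporation. Passing recovery tests therefore show
the estimators are correct for the stated stochastic model at realistic
photon budgets — not that the pipeline is robust to every pathology of real
movies.

## Imaging stages

Rendering integrates a 2-D Gaussian PSF over each pixel (error-function
differences), conserving photons to the truncation window; the default PSF
σ = 1 px keeps ~99% of a spot's photons inside the 3 px integration disc.
Detection finds local maxima of a lightly smoothed frame above
median + 5·robust-σ (or an absolute floor), refines them to intensity-weighted
centroids, and discards candidates with circularity (4πA/P² of the half-maximum
mask) below 0.7, corrected intensity below 50 photons, or a neighbor within
5 px (both members of a close pair are dropped, since their photometry is
mutually contaminated). Channel registration is a least-squares affine fit to
fiducial pairs; drift is phase cross-correlation against the temporal median
of the first ten frames, reported relative to frame 0. Intensity extraction
sums a 3 px disc and subtracts the annulus (5–7 px) background level scaled
by the disc area; the background level is an upper-clipped mean (pixels above
median + 5√median excluded) — as robust to bleed-in from bright neighbors as
a median, but without the median's fraction-of-a-photon bias on discrete
counts, which would otherwise integrate to several photons across the disc.
Colocalization maps DNA positions through the affine transform and accepts a
partner spot within 2 px (≈ 2 PSF σ; chosen so that pure-background frames
pair with <1% of DNA spots).

## FRET corrections

Corrections follow the standard ALEX order: `F_corr = F_DA − l·F_DD − d·F_AA`,
then `E = F_corr/(F_corr + γ·F_DD)`. With the simulator's distortion model
this inverts exactly (the noiseless tests assert machine-precision recovery).
Leakage and direct excitation are estimated from single-dye calibration sets
as background-subtracted channel ratios; γ from the corrected acceptor drop
over the donor rise across acceptor-photobleach transitions (median over
molecules; fallback 1.0 with a warning below five usable transitions).
Photobleaching is a single changepoint maximizing the two-segment mean-shift
objective, accepted only when the pre-step mean is above, and the post-step
mean below, background + 2√background; frames at or after a detected step are
excluded rather than imputed. Frames are additionally invalid without an
acceptor present (`F_AA` below the 50-photon presence threshold — under ALEX
the red channel directly reports acceptor presence) or when the corrected
denominator is non-positive; efficiencies are tolerated in [−0.2, 1.2] and
flagged outside [0, 1].

## Event calling

**Colocalization events** are maximal runs of `F_AA` frames above 50 photons;
runs separated by fewer than three sub-threshold frames are merged (reading
the minimum-separation rule as a merge keeps dwell mass; a discard flag is
not provided because merging is strictly more conservative for dwell
estimation), and merged events shorter than two frames are discarded.
Durations are `n_frames × 0.2 s`.

**FRET events** are runs of valid frames with E in [0.3, 0.8] lasting at
least five frames (1 s) and less than 20 s with negative OLS slope.
Out-of-band interruptions shorter than the 1 s minimum duration (gaps of up
to four valid frames) are bridged: the final staircase level (E = 0.3) sits
exactly on the band floor, so per-frame shot noise (σ_E ≈ 0.02–0.03 at a
500-photon budget) throws roughly half its frames out of band, and without
bridging the recovered incorporation dwell is clipped ~10–15% low. Events
whose run is terminated by loss of observability (the following frame is
invalid, or the movie ends) are flagged `ends_at_signal_loss`; dwell
statistics exclude them, since their duration is censored by photobleaching,
dissociation or the recording window rather than by the end of the FRET
decrease.

**Magnitude (ΔE).** The default estimator pools plateau levels: the starting
level is the mean of the frames within half a nucleotide step (0.05) of the
maximum adjacent-pair mean in the event's first second, and the final level
the corresponding minimum-side pool over the settled frames just after the
run (the final incorporation carries E below the band floor, so frames after
the run must be consulted; frames straddling a binding, dissociation or
bleach are skipped because they record mixed efficiencies). Endpoint- and
fitted-slope-based estimates remain available via `delta_mode`. An endpoint
difference computed strictly inside the band cannot exceed ~0.3 for a
staircase starting at 0.6 with a 0.3 floor, so it cannot reproduce a
four-step magnitude of 0.4; the plateau estimator can, which is why it is
the default.

## Fitting

*Binding*: the empirical cumulative fraction bound (censored molecules in the
denominator only) is fit to `A·(1 − e^(−kt))` by least squares; if every
binder arrives in the same frame the rate is reported at the optimizer bound
with a saturation note. *Dwells*: the primary estimator is the left-truncated
exponential MLE `τ̂ = mean − cutoff`, with an optional geometric
(frame-quantization) correction used for colocalization dwells recorded as
whole frames; a Freedman–Diaconis binned least-squares mode mirrors
histogram fitting and is always reported alongside. For FRET incorporation
dwells the cutoff is not subtracted: those durations are sums of several
per-nucleotide exponentials (gamma-like, not memoryless), so the exponential
truncation correction would bias τ low, while the 1 s minimum removes under
1% (4.7 s condition) to ~9% (2.4 s condition) of the mass. *Magnitudes*: the
sample mean/SD is the bin-free estimate; the pipeline reports the binned
Gaussian histogram fit (minimum ten bins, mean constrained to the data range)
as the headline μ because events whose first incorporation falls within the
opening frames, or whose final level is clipped, form a left tail of censored
magnitudes that deflates the mean by ~0.05 while the histogram fit tracks the
modal magnitude; both numbers appear in the result (`mu`, `mu_mean`).
Standard errors come from a seeded nonparametric bootstrap (default 200
resamples in the pipeline; any count can be requested). μ divided by the
0.1-per-nucleotide calibration converts to nucleotides incorporated.

Known bias: with frame-quantized band runs, complete incorporation events
lose ~0.3 s at the boundaries (mixed entry/exit frames; trailing frames of
the E = 0.3 level measured below the floor), so the recovered 4.7 s dwell
centers near 4.5 s — within the uncertainty printed for that quantity. This
is a property of the band-run event definition itself, not of the estimator.

## Bulk assays

Gel lanes carry four densitometry boxes (unreacted, 1–5 nt, 6–15 nt, whole
lane); fractions are box/lane and sum to 1 with the unboxed residual. The
extension time course summarizes each lane as a weighted mean of
representative per-box nucleotide counts — bin midpoints 0 / 3 / 10.5, a
choice the box scheme leaves open — with box fractions renormalized over the
three boxes. The paired generator draws per-molecule counts from
Poisson(rate·t) clipped at the 15-nt template and adds multiplicative
lognormal densitometry noise.

MST titrations use the 1:1 isotherm with ligand depletion,
`fb = ((K_D + L + T) − √((K_D + L + T)² − 4LT))/(2T)`, and a linear response
map `R = R_free + (R_bound − R_free)·fb`, so the fit is agnostic to the sign
of the fluorescence change (the default synthetic curves decrease on
binding). The default series is a 19-point two-fold dilution from 200 μM
(≈ 0.763 nM at the bottom) against a 50 nM target; fits require at least
eight concentrations spanning three orders of magnitude, warn on
non-monotone responses (total backtrack above half the response span), and
fail rather than report a K_D stuck at a parameter bound. The vendor
normalization from raw thermophoresis to fraction bound is not public; the
linear R_free/R_bound map stands in for it.

## Orchestration and problem sizes

`run_pipeline` executes simulate → calibrate → correct → call → fit per
condition and reports fold changes between matching ±Ku conditions, a config
hash, and versions; one configured seed fans out to per-condition, per-stage
children via `SeedSequence` spawn keys, so reruns are bit-identical and
stages can be reproduced in isolation. Shipped condition fixtures use the
fitted kinetic values of each experimental condition as ground truth.
Recovery analyses use 300 molecules per FRET condition and 500 per
colocalization condition over a 180 s window — enough for ~100–150 FRET
events and ~1500 binding events, which puts estimator noise well below the
tolerances being checked; the test suite uses smaller sets where only
correctness of plumbing is at stake.

## Limitations

Dissociation and acceptor photobleaching are indistinguishable at frame
resolution (both end the red signal), so the censoring flag keys on the
validity boundary rather than on the bleach changepoint specifically. The
γ estimator needs acceptor-bleach transitions with a live donor; movies
without them fall back to γ = 1. The magnitude estimator loses information
when the first incorporation occurs within the opening frames of an event —
at 5 frames/s nothing can recover a level that was never sampled — which is
the main reason the sample-mean μ sits below the histogram-fit μ.
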