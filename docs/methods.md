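# Methods

`lacdqf` models a CH-selective double-quantum-filtered (DQF) semi-LASER
¹H-MRS experiment for lactate in exercising human muscle at 7 T, and the
analysis chain that turns its interleaved single-shot spectra into three
physiological/physical parameters: the post-exercise lactate clearance
half-time t½, the apparent transverse relaxation time T₂, and the apparent
scalar coupling J of the lactate doublet (scalar coupling plus the
orientation-dependent residual dipolar contribution of muscle fibers).

## Spin model and sequence simulation

Lactate is treated as a weakly coupled spin system: the methine proton
(I, 4.10 ppm) coupled to the three equivalent methyl protons (S₃,
1.31 ppm), with the two-spin IS reduction available for cross-checks. The
secular Hamiltonian

    H = Σₖ 2π δₖ I_kz + Σ_(I,S) 2π J I_z S_z      [rad/s]

is diagonal in the Zeeman product basis, so free evolution is a phase map
on the density matrix. The weak-coupling approximation is safe at 7 T:
Δδ·ν₀ ≈ 830 Hz ≫ J ≈ 17 Hz. Couplings among the equivalent methyl protons
have no observable effect and are omitted.

The DQF block is simulated as: 90° excitation → τ₁ spin echo (adiabatic
refocusing pairs idealized as exact 180° rotations; J evolves for the full
τ₁) → DQF entry pulse → coherence-order +2 projection and τ_m evolution →
CH-selective 90° exit pulse → order +1 projection → τ₂ spin echo →
detection via Tr(ρ F⁺). The unbalanced filter gradients (moment ratio 1:2)
act on the spin dynamics purely as a pathway filter, so they are modeled
as coherence-order projections rather than explicit spatial integrals.
One bookkeeping subtlety: the CH-selective exit pulse acts on I only and
therefore cannot lower the S coherence; the +2 pathway leaves the exit
pulse at order +1, and it is the τ₂ echo's refocusing pulse that inverts
it to the detectable −1. Selecting +2 during τ_m and +1 after the exit
pulse is exactly the pathway the 1:2 gradient pair refocuses.

Relaxation is deliberately *not* simulated inside the sequence. T₂ enters
the package only through the signal model of the synthetic generator and
the kinetic fits, mirroring its role as a fitted rather than simulated
quantity.

### Shaped pulses

Shaped pulses are sampled envelopes propagated piecewise-constantly
(midpoint sampling, second-order convergent; doubling the default 512
samples changes reported flip angles by < 0.03%). The pulse carrier offset
is carried as a per-sample phase ramp, so chemical-shift evolution during
the pulse is exact within the discretization.

The CH-selective DQF pulse is a **5-lobe sinc of 4.0 ms**: the envelope
`sinc(2 f₀ t)` with f₀ chosen so the central lobe plus two side lobes per
side exactly span the stated duration (f₀ = 750 Hz; truncation at the
third zero coincides with the pulse edges; no apodization window). This is
the standard reading of "n-lobe sinc of duration T". We considered the
alternative of rescaling the envelope so the simulated profile FWHM equals
the nominal 1.7 kHz bandwidth label, but that convention is inconsistent
with the pulse's other published characteristics (residual CH₃ flip of
~1.4°, CH/CH₃ selectivity of ~63, ~580 Hz transition band), all of which
the duration-spanning convention reproduces; the nominal bandwidth label
evidently follows a different width definition (the simulated FWHM is
~1.4 kHz). The carrier is placed by the rule `offset = ½ · (1/duration) ·
0.97 · 4`, putting the CH resonance at the pass-band edge; flip angles at
arbitrary offsets come from full Bloch propagation, with stop-band defined
as < 5% flipped (transverse) magnetization.

The Gaussian comparison pulse is truncated at ±2.5σ with σ calibrated by
bisection so its profile FWHM matches a requested bandwidth (by default
the sinc's measured FWHM), making the sinc/Gaussian comparison a
matched-bandwidth one. Its published selectivity ratio is not reproduced
by this construction; only the qualitative statement (the sinc's
transition band is narrower at matched width) is asserted.

## Synthetic data generator

The generator is the package's stand-in for the in vivo experiment (no
acquired data are distributed with the study). Its defaults are the study
conditions: interleaved schedule with TR = 4 s and 300 measurements, τ₁
starting at 22.8 ms and incrementing by 10 ms up to a 500 ms cap (48
distinct values), τ_m = 10.6 ms, τ₂ = 35 ms; ground-truth kinetics at the
cohort means t½ = 162 s (t_clear = 162/ln 2 ≈ 233.7 s), T₂ = 138 ms,
J = 16.6 Hz; single-shot SNR 24.

Amplitude programs. Fixed-tag shots follow the mono-exponential clearance
`a·exp(−t/t_clear) + b` in wall time. Pre-cap incremented shots follow the
combined decay `a·sin(πJτ₁)·exp(−(τ₁ − τ₁_fixed)/t_comb) + b` in τ₁, with
the sine taking J in Hz and τ₁ in ms through a single /1000 conversion,
and `1/t_comb = 1/T₂ + c/t_clear`, `c = 2TR/τ_inc = 0.8`, because τ₁
advances linearly in wall time (one increment per 2 TR). Past the τ₁ cap
the J/T₂ factor freezes at the capped value while clearance continues in
wall time (the strict "Eq.-2-in-τ₁" reading would freeze the amplitude
entirely, which is unphysical); capped shots are flagged and excluded from
the combined fit either way.

Each shot renders, in the time domain: the lactate Voigt doublet at
1.3 ppm (default shape: Gaussian FWHM 6 Hz, Lorentzian FWHM 5 Hz, area
ratio 1, splitting = ground-truth J, per-peak phases 0), a Lorentzian
lipid residue at 1.5 ppm with amplitude 0.3·a₀ and opposite (180°) phase,
and creatine reference singlets at 3.03 and 3.91 ppm with constant
amplitudes. Sampling: 1024 complex points at 4 kHz spectral width about a
water-referenced carrier (axis −2 to 11.4 ppm).

Noise is complex white Gaussian, calibrated analytically so that the
standard SNR measurement (lactate peak height over the 7–9 ppm noise SD,
after 10 Hz apodization and 2× zero-filling, averaged over the first ten
shots) returns the target; Monte-Carlo realization lands within a few
percent. A linear frequency drift (default 1 Hz/min — a plausible scanner
figure, not a measured one) and Bernoulli motion outliers (default
probability 0.01 per shot; 3× line broadening plus 50% amplitude drop)
emulate the main nuisance structure of post-exercise leg data.

Two backends: the default parametric backend writes the amplitude
programs directly; the physics backend replaces the sin(πJτ₁) factor of
incremented shots with the amplitude simulated by the density-matrix DQF
model (they agree to machine precision for an ideal IS system, which is
the cross-validation the backend exists for).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: B₀/B₁ inhomogeneity and lineshape asymmetry,
eddy currents, chemical-shift displacement between metabolites, partially
suppressed water, extracellular lactate or threonine, non-white noise,
and lipid residues that vary shot-to-shot.

## Spectral fitting

Preprocessing: exponential apodization (default 10 Hz), first-point
halving (the DFT otherwise adds an amplitude-proportional flat baseline),
zero-filling (default 2×), FFT, and zero-order phasing. Spectra are
stored in descending-ppm order. Each spectrum is then frequency- and
phase-corrected from the 3.03 ppm creatine singlet (sub-bin position by
parabolic interpolation of the magnitude peak; phase from the peak's
complex angle); shots whose reference peak is below 3× the noise SD are
flagged and left uncorrected rather than failed.

Lipid residue: the doublet fitted in a first pass is subtracted from each
spectrum, the residual is averaged over the series, and one complex
Lorentzian (free amplitude, position within 1.5 ± 0.05 ppm, width, phase)
is fitted in the 1.5 ± 0.1 ppm window and subtracted from every shot. The
series-average is used because the residue does not clear physiologically
while per-spectrum fits inject amplitude-correlated errors into the
kinetic time-courses; a per-spectrum mode exists for data where the
residue genuinely varies. A no-op guard requires an interior magnitude
peak near 1.5 ppm above 2× the noise SD, so the smooth tail of the
lactate doublet is never mistaken for a residue.

Constant-shape Voigt fit. The doublet lineshape — two per-peak phases,
Gaussian and Lorentzian FWHM, peak area ratio, splitting — is one
property of the whole series; only amplitude (summed doublet area, which
may be *negative*: the J-modulation inverts the doublet past τ₁ = 1/J)
and center frequency vary per spectrum. Voigt lines are evaluated exactly
via the Faddeeva function, in the conjugate convention that matches the
spectrum of a causal FID. Per spectrum, the amplitude–frequency pair is
found on a constant-step meshgrid (frequency: ±0.05 ppm around 1.3 ppm at
quarter-resolution steps; amplitude: 64 steps symmetric about zero up to
1.5× a robust series maximum) against the summed squared difference on
the real part in the 1.3 ± 0.1 ppm window. The shared shape is found by
uniform random sampling (default 256 candidates; bounds: phases ±90°,
widths 1–30 Hz, ratio 0.5–2, splitting 5–25 Hz), one refinement pass that
halves the ranges around the incumbent, and — a necessary addition — a
bounded simplex descent from the best few candidates: random search alone
cannot localize six parameters to sub-Hz splitting precision, and the
cost surface contains a degenerate basin where a narrow-splitting
dispersion pair mimics the merged doublet. Candidate shapes are ranked by
the amplitude-profiled (continuous) cost so that amplitude-grid
quantization noise does not randomize the selection, and the reported
amplitudes are the continuous least-squares optimum at the winning grid
frequency for the same reason. The exhaustive meshgrid operation itself
is kept bit-equivalent to a brute-force double loop and verified against
one.

Quality metrics: single-shot SNR per the acquisition convention above,
and the lipid-suppression factor as the magnitude-area ratio in
1.51 ± 0.1 ppm between an unfiltered and a DQF spectrum (flagged rather
than reported when the DQF area is numerically zero, as for an ideal
filter on uncoupled spins).

## Kinetics

The fixed-tag amplitude course is fitted by `a·exp(−t/t_clear) + b`
(t½ = ln 2·t_clear) and the pre-cap incremented course by
`a·sin(πJτ₁)·exp(−(τ₁ − τ₁_fixed)/t_comb) + b`, both by bounded nonlinear
least squares. The initial amplitude a is confined to mean ± SD of the
first five points corrected for decay/J-modulation with one round of
initial-guess parameters; the "initial guess" is one unconstrained fit
(falling back to heuristics), which makes the constraint exact in the
noiseless limit. The combined fit is warm-started at the splitting-derived
J and multi-started over J ± 30% to avoid locking onto the wrong
modulation lobe; a τ₁ span shorter than 1/(2J) raises an explicit
unidentifiability error. T₂ follows from
`1/T₂ = 1/t_comb − c/t_clear` with `c = 2TR/τ_inc`, with delta-method
error propagation; a non-positive derived rate is flagged unphysical, not
raised.

Uncertainty: subsample bootstrap — 50% downsampling *without* replacement
(the with-replacement variant would duplicate points), default 1000
refits; the 95% CI is the 2.5/97.5 percentile band and the scalar "error"
used by the exclusion rule is the 95th percentile of |full-sample −
subsample| (the upper-percentile reading of an ambiguous convention,
documented here once). Bootstrap refits of the combined model are
warm-started at the full-sample optimum. Exclusion is cohort-derived in
leave-one-out form: a dataset is flagged when its bootstrap error
deviates from the other datasets' mean by more than 3× their SD (a global
3·SD threshold degenerates for identical errors and is inflated past a
single gross outlier by that outlier itself). Splitting-derived and
time-course-derived J estimates are compared by a two-sided Mann–Whitney
U test (exact null for small tie-free samples). The method-comparison
ratio fits both interleaved series freely, refits with the clearance time
fixed to the mean of the two, and reports the ratio of initial
amplitudes with a paired-subsample bootstrap CI.

## Numerical and scale choices

Synthetic-recovery experiments run 20 independent seeds of the full
300-shot pipeline (~2 s per seed for the spectral fit; bootstrap with
1000 refits adds ~4 s). Noiseless closure of generator → spectral fit →
kinetics recovers t½, T₂ and J to relative error < 10⁻³; at SNR 24 the
20-seed means sit within ~1% of the generating values. The Larmor
frequency at 7 T is fixed at 297.22 MHz and every ppm↔Hz conversion flows
through one function pair. All stochastic stages (generator, shape
sampling, bootstrap) take explicit integer seeds and are bit-reproducible
under them.

## Known limitations

- Adiabatic refocusing is idealized; slice profiles, B₁ maps and
  chemical-shift displacement are handled only as closed-form geometry,
  not simulated spatially.
- The apparent J is a single scalar input; orientation distributions and
  multi-compartment (intra/extracellular) lactate are out of scope.
- The constant-shape assumption is exactly true of the generator by
  construction; on real data it is an approximation whose residual cost
  the fit does not model.
- The splitting becomes weakly identifiable when the total linewidth
  approaches the splitting and the series is short; the shape search then
  needs the series-level cost of a full-length acquisition to pin it.
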