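# Methods

This note documents the models `moltenfit` implements, the assumptions
behind its synthetic-data generators, the numerical choices that matter,
and what the parameter-recovery tests do and do not demonstrate about
real instrument data.

## Equilibrium binding (quadratic isotherm)

A fluorescently labeled species A (total concentration A₀, µM) is
titrated with partner T (total T₀, µM). Because A₀ is comparable to the
dissociation constant, ligand depletion is non-negligible and the bound
fraction must be the exact root of the mass-action quadratic
(A₀−x)(T₀−x) = K_D·x:

    f_b(T₀) = [A₀ + T₀ + K_D − √((A₀+T₀+K_D)² − 4·A₀·T₀)] / (2·A₀)

evaluated in the conjugate form 2·T₀/(S + √(S² − 4A₀T₀)) to avoid
catastrophic cancellation when K_D ≫ A₀ (the naive form loses about
seven significant digits there; the conjugate form matches a bisection
solution of the mass-action equation to 1e−9 relative everywhere, which
is property-tested). The observable is

    r(T₀) = r_A + (r_AT − r_A) · f_b(T₀)

with r_A and r_AT the anisotropies of free and saturated A, soft-bounded
to the one-photon physical range [−0.2, 0.4]. Fitting uses
Levenberg–Marquardt with a data-driven start (r_A from the lowest point,
r_AT from the highest, K_D from the half-change concentration) and five
perturbed restarts. Uncertainties come from a seeded nonparametric
bootstrap over points (default 200 resamples) — more robust than the
covariance matrix near the stoichiometric regime, at the cost of wide
intervals when a single curve genuinely carries little information.

Identifiability under realistic noise: with 12 points, anisotropy
contrast 0.08 and per-point noise 0.004 (averaged over three
replicates), the Cramér–Rao bound on K_D is ≈13% relative, and the
least-squares estimator attains it. Single-curve K_D estimates at these
settings therefore scatter by roughly ±13% (1σ); this is an information
limit of the assay design, not an optimizer artifact (outlying fits have
lower residual sums than the truth).

## Denaturation transitions

Unfolding exposes tryptophans to solvent and red-shifts the emission
maximum λ_max. The profile λ_max(D) versus denaturant D (M) is fitted
with the two-asymptote sigmoid

    λ(D) = λ_N + (λ_U − λ_N) / (1 + exp((x − D)/a))

so λ_N is the low-denaturant (native) asymptote — the exponent sign is
chosen so the curve rises with D, the direction every unfolding profile
shows. The width a (M) is reported together with the midpoint slope
(λ_U − λ_N)/(4a); a fit with a > 0.25 × span(D) is flagged
low-cooperativity (the molten-globule signature), the threshold being
configurable. Asymptotes are bounded within one observed dynamic range
of the data so that a shallow transition cannot trade an unbounded
amplitude against an unbounded width. Non-monotone profiles (ANS
emission of a globular control that transiently populates a
molten-globule state) use the area-parameterized Gaussian peak
y = y₀ + A·exp(−4ln2(x−x_c)²/w²)/(w√(π/4ln2)) instead; a monotone
profile given to the Gaussian model is an error that points the user to
the sigmoid.

λ_max extraction: the spectrum is smoothed with a local quadratic
(Savitzky–Golay) filter; the estimate is the vertex of a quadratic
fitted over the window centred on the smoothed argmax. The full-window
vertex has far lower variance than a three-point parabola through
smoothed values when the band is broad. The default window is 7 points
(narrow bands); for tryptophan-like bands (~59 nm FWHM on a 1 nm grid) a
window of ~51 points is appropriate and is what the recovery pipeline
uses. Band asymmetry makes the vertex estimate slightly biased, but the
bias is identical for every spectrum in a series (the band shape does
not change, only its position and amplitude), so it cancels exactly in
the fitted shift λ_U − λ_N. Extraction is equivariant under intensity
scaling and invariant under additive offsets (property-tested).

## Stern–Volmer quenching

Collisional quenching: ratio = 1 + K_SV·[Q], intercept pinned at 1
because the ratios are self-normalized (a free-intercept variant exists
behind a flag). Static + collisional quenching uses the product form
(1 + K_dyn[Q])(1 + K_static[Q]) rather than a raw quadratic polynomial:
its coefficients are the physically interpretable constants, and the raw
polynomial expansion is still serialized as a diagnostic. Model
comparison uses AICc (the series have 6–11 points). Mechanism
classification calls a static component when the steady-state initial
slope exceeds the lifetime K_SV by a configurable factor (default 1.3 —
a pragmatic default, not a literature constant) or when AICc prefers the
product model for the intensity ratios but not the lifetime ratios.
Inner-filter correction F·10^((A_ex+A_em)/2) is provided; corrections
with total absorbance above 2 warn.

## TCSPC reconvolution and anisotropy decay

The decay model is the causal discrete convolution of the unit-area IRF
with Σᵢ Aᵢ·exp(−t/τᵢ) on the channel grid (default channel width
0.055 ns), with a sub-channel IRF shift applied by linear interpolation
and bounded to ±10 channels. The convolution uses FFT for long
histograms and matches a brute-force O(n²) double loop to 1e−10
relative (property-tested). Minimization is Poisson-weighted least
squares with Neyman weights 1/max(obs, 1) — the convention of standard
reconvolution software — rather than an exact Poisson likelihood.

χ²_red is computed over a fit range, by default the contiguous channel
block where the 11-channel-smoothed counts stay at or above 20. A 200 ns
window at a few-ns lifetime is mostly empty channels that contribute
nothing to the statistic but would inflate the degrees of freedom and
deflate χ²_red several-fold; cropping the range is exactly what an
operator of commercial TCSPC software does. Calibration: over 100
Poisson replicates of a correct single-exponential model at peak 10⁴
counts, mean χ²_red is ≈1.04 (tested to lie in [0.9, 1.1]).

Mean lifetimes are reported both amplitude-weighted (ΣAτ/ΣA) and
intensity-weighted (ΣAτ²/ΣAτ); the amplitude-weighted value is the
default, and the intensity-weighted one is never smaller (Chebyshev
ordering, property-tested). Component-count selection accepts n+1
components only for a >5% χ²_red improvement with all amplitudes
positive, tie-breaking toward fewer components.

Anisotropy is constructed channel-wise as
r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) with first-order Poisson error
propagation, masking channels whose denominator falls below 20 counts,
and tail-fitted with r(t) = r∞ + Σᵢ Aᵢ·exp(−t/θᵢ) by weighted least
squares over a window that must start after the IRF-dominated rise
(≥ 1 IRF FWHM past the peak in the recovery pipeline; windows shorter
than θ/3 warn). The G-factor is a user input defaulting to 1. Fitting
the constructed r(t) rather than globally fitting both polarized decays
mirrors common practice; global polarized analysis is out of scope.

The hydrated-sphere expectation θ = η·M·(ν̄+h)/(R·T) uses
ν̄ = 0.73 cm³/g, hydration h = 0.23 cm³/g, η = 1.002 mPa·s and
T = 293 K by default (standard protein values at 20 °C, all
overridable); it is linear in M and η and inverse in T. For an 86.5 kDa
protein it gives ≈34 ns.

## Sequence profiling and CD

The 20-letter alphabet is partitioned into disorder-promoting
(A,G,R,D,H,Q,K,S,E,P) and order-promoting (W,F,Y,I,M,L,V,N,C,T)
classes; the scheme is injectable but the fractions under the default
partition always sum to 1. Percentages round half up to integer to match
the granularity at which such compositions are usually quoted; raw
ratios are always retained. Average (not monoisotopic) masses follow the
ProtParam convention via biopython; ε₂₈₀ = 5500·nW + 1490·nY +
125·n_cystine with cystine pairs defaulting to 0 (reduced protein).
Windowed class-fraction profiles use odd windows only.

CD conversion: [θ](λ) = θ_mdeg·MRW/(10·l·c) with MRW = mass/(n−1)
(per-peptide-bond convention, directly overridable). The
([θ]₂₀₀, [θ]₂₂₂) point is read by linear interpolation — spectra are
sampled at ≤1 nm, where higher-order interpolation changes nothing
material. Conformational classification is point-in-polygon (closed
regions: boundary counts as inside) against named regions supplied as
data. The packaged region file is an approximate, clearly labelled
synthetic transcription of the published cluster positions on the
double-wavelength plane; quantitative work should replace it with
measured boundaries, and classification with no regions at all is an
error rather than a silent default.

## Synthetic-data generators

Each generator embeds its ground truth in container metadata and is
deterministic given (seed, parameters):

* titrations — exact isotherm plus additive Gaussian noise on r;
* spectral series — an emission band (asymmetric log-normal by default,
  mode exactly at the nominal center, width 25 nm ≈ 59 nm FWHM;
  Gaussian available) whose center follows the sigmoid, with optional
  linear-in-D amplitude attenuation (default 0.1/M in the recovery
  pipeline, emulating the intensity loss seen on unfolding) and
  additive per-point noise;
* quench series — the product model with multiplicative noise;
* IRF — a deterministic rounded Gaussian histogram (default FWHM 1 ns);
* decays — IRF-convolved multi-exponentials scaled to a target peak
  count, per-channel Poisson sampled;
* polarized decays — I_∥ ∝ I(t)(1+2r(t))/3 and I_⊥ ∝ I(t)(1−r(t))/3/G,
  each convolved with the IRF then Poisson sampled. Dividing the
  perpendicular channel by G at generation is the package's single
  self-consistent convention, so analysis-side multiplication by G
  restores balance; r(0) > 0.4 is rejected as unphysical.

What the generators do **not** emulate: wavelength-dependent detector
sensitivity, detector afterpulsing and dead time, background dark
counts, scattered-light contamination of the IRF, photobleaching, and
any systematic (non-random) deviation between model and sample — e.g. a
real protein whose unfolding is not two-state. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
statistical model, not robustness to instrument systematics.

## Recovery-pipeline problem sizes and protocols

The end-to-end checks simulate assays at the scale a real campaign
uses: 12-point titrations (0–40 or 0–120 µM) with anisotropy noise
0.004; 11-point denaturant series (0–4 M in 0.4 M steps) with additive
spectral noise at 2% of the native peak; 6-point quench series (0–0.5 M)
with 1% multiplicative noise; 3641-channel decays (0.055 ns/channel,
200 ns) at peak 10⁴ counts and polarized decays at peak 10⁵. Titration
and spectral recoveries average three replicate datasets before fitting,
matching the standard triplicate (mean ± SD, n = 3) reporting protocol
of such experiments; single-replicate fits of the binding assay sit at
the ≈13% information limit derived above, so replicate averaging is what
makes a 20%-level recovery reliable.

## Known limitations

* No global/target analysis across decays or constructs; every dataset
  is fitted independently.
* No thermodynamic ΔG/m-value extraction from transitions; the sigmoid
  describes the observable, not a linear-extrapolation free-energy
  model.
* Stern–Volmer analysis does not fit sphere-of-action models or extract
  bimolecular rate constants.
* Bootstrap intervals on small curves can be very wide and heavy-tailed;
  they are standard deviations over resampled fits, not profile-
  likelihood intervals.
* The CD classification is only as good as the region polygons supplied;
  the packaged set is approximate by construction.
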