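# Methods

## Scope and model

`dfskit` analyses single-molecule AFM force spectroscopy data of
receptor–ligand bonds: force–distance curves collected while a
functionalized tip approaches and retracts from a substrate, possibly on
a force-volume raster. The pipeline is

1. curve pre-processing (baseline, contact point),
2. rupture-event detection on retract segments,
3. adhesion statistics (Gaussian force distributions, adhesion maps),
4. contact-time kinetics of the interaction frequency, and
5. a two-regime (Friddle–Noy–de Yoreo) fit of the dynamic force
   spectrum, yielding energy-landscape parameters.

### Two-regime mean rupture force

The mean rupture force of a single bond loaded at rate *r* (pN/s) is
modelled by the interpolation

    F(r) = f_eq + f_β · ln(1 + e^(−γ) · r / (k_off · f_β))

with equilibrium force `f_eq` (pN; the plateau where bond rupture and
reformation balance, i.e. the lowest force that breaks the bond), thermal
force `f_β = k_B·T/x_t` (pN; sets the slope of the kinetic regime
F ∼ ln r), dissociation rate `k_off` (s⁻¹, evaluated at `f_eq`), and
Euler's constant γ = 0.577. Derived quantities are exact identities of
the fitted triple:

- barrier width `x_t = k_B·T / f_β` (reported in Å),
- binding free energy `|ΔG| = f_eq² / (2·k_c)` in pN·nm
  (k_c = cantilever spring constant), converted to kcal/mol
  (6.9477 pN·nm per kcal/mol) and reported negative,
- bond lifetime `τ₀ = 1/k_off` (reported in ms).

ΔG depends on the cantilever stiffness; when no k_c is supplied the value
is omitted with a warning rather than guessed, because typical probe
stiffnesses span a factor of two (10–20 pN/nm) and ΔG scales with 1/k_c.

The model is single-barrier and mean-force only. Multi-barrier
landscapes, heterogeneous bonds, and maximum-likelihood fitting of the
full rupture-force distribution are out of scope.

### Fitting

`FNdYModel` performs Levenberg–Marquardt least squares of F(r) on
per-event (r, F) points or on bin summaries. The three parameters are
fitted on a log scale so every iterate is positive; confidence intervals
are mapped back through the exponential (multiplicative intervals, which
also keeps them positive). Numerical choices:

- iteration cap 500 function evaluations; the chi-square change
  tolerance is nominally 1e−15, which is below double-precision
  resolution and therefore clamped to machine epsilon;
- initialisation is deterministic and data-driven: f_eq⁰ = weakest
  observed force, f_β⁰ = slope of F vs ln r over the top decade of rates,
  k_off⁰ solved from the model at the median point;
- 99 % confidence intervals use the linearised covariance with
  t-quantiles (df = n − 3); the 99 % prediction band adds the residual
  variance;
- log-parameters are clipped at ±60 inside the residual function so a
  weakly identified direction cannot overflow `exp`;
- fewer than 5 distinct rates, or a span under one decade, triggers a
  "poorly conditioned" warning (the CLI refuses outright below 3 distinct
  rates).

**Identifiability.** For parameter sets whose crossover rate
`k_off·f_β` lies above the measured loading-rate range, the spectrum is
mostly in the near-equilibrium regime where
F ≈ f_eq + e^(−γ)·r/k_off and f_β enters only through second-order
curvature. f_eq and k_off are then recovered tightly (sub-percent and a
few percent respectively at ~2000 ruptures), while the relative standard
error of f_β is of order 100 % — a property of the measurement design,
not of the optimiser. This matches the large published relative
uncertainties on x_t (∝ 1/f_β) for such bonds. Binning does not add
information; with coarse bins the (geometric-mean rate, mean force)
summaries additionally acquire O(0.1 pN) curvature bias that the
ill-conditioned f_β direction amplifies enormously, so exact
binned/unbinned equivalence only holds when every distinct rate gets its
own bin.

## Synthetic data

All generators take an explicit seed (no global random state), emit a
ground-truth sidecar, and are bit-reproducible.

**Rupture forces.** A bond pulled at constant rate with a Bell-type
escape rate referenced to f_eq (and a hard floor at f_eq, rebinding
treated as instantaneous) has first-passage survival
`S(F) = exp(−(1/a)(e^((F−f_eq)/f_β) − 1))` and mean excess
`f_β·e^(1/a)E₁(1/a)`. That exact mean coincides with the interpolation
formula only asymptotically; in the crossover region the two differ by
up to ~20 % of F. Since the package's purpose is to fit the
interpolation model, the simulator calibrates the effective scale per
loading rate — solving `e^(1/a')E₁(1/a') = ln(1 + e^(−γ)a)` — so that
the ensemble mean rupture force equals the model curve at every rate
while the skewed first-passage shape (and hence realistic scatter) is
preserved. Sampling is inverse-CDF: `F = f_eq + f_β·ln(1 + a'·E)` with
E ~ Exp(1). `e^x·E₁(x)` is evaluated by `scipy.special.exp1` below
x = 50 and by its asymptotic series beyond.

**Force curves.** Approach/retract cycles with a linear contact ramp to
the setpoint (default 500 pN), white Gaussian force noise (default
σ = 5 pN), and embedded events modelled as linear tether loading
(constant effective stiffness, default 2 pN/nm) to −F at the stated
distance followed by instantaneous release. Defaults: retract speed
1 µm/s (instrument range 1–6), sampling 2000 Hz, scan range 600 nm,
cantilever 10 pN/nm, 20 °C. Worm-like-chain stretch shapes, instrument
drift, hydrodynamic drag, and multiple parallel bonds are deliberately
not simulated; event detection does not depend on the stretch shape.

**Maps.** Per-pixel Bernoulli adhesion with circular patches of elevated
probability on a uniform background (emulating chitin-rich bud-scar
patches on a yeast cell). Event forces are Gaussian (default 83 ± 25 pN)
clipped below 30 pN so embedded events stay ≥ 6 noise SD; distances are
uniform in 30–150 nm. Map curves use a 300 nm range at 1000 Hz to keep
1024-pixel grids cheap.

**Contact-time series.** Adhesive counts per contact time are
Binomial(n, f_max·t/(k_half+t)).

What passing these closed-loop tests does *not* show: robustness to
drift, multi-bond ruptures, non-linear tether compliance, or baseline
shapes other than linear tilt — real instrument data can violate all of
these.

## Pre-processing and event detection

- **Baseline**: a line (force vs height) fitted to the final 30 % of the
  retract is subtracted from the whole curve. Noise is estimated as
  1.4826·MAD/√2 of the first differences of the window — first
  differences because a tether ramp inside the window would inflate a
  residual-based estimate and mask its own presence. Windows containing
  excursions > 5σ are shrunk (×0.75, warning) until clean; below 16
  samples the correction fails. The correction is idempotent.
- **Contact point**: the approach height where force first exceeds
  3σ for 5 consecutive samples; equivariant under height translation.
- **Events**: a centred moving median (window 7) is used only for
  localisation; rupture forces are read from the raw channel at the
  localised index so magnitudes are not attenuated. Candidate minima are
  contiguous runs below −(threshold_sigma)·σ (default 4σ), merged within
  min_separation (default 10 nm, keeping the deeper dip — "essentially
  single events"), and must recover toward baseline by the event depth
  (minus 2σ noise allowance) within min_separation. The instantaneous
  loading rate is the |slope| of force vs time over the 20 samples
  before rupture — a measured per-event rate, not the nominal k_c·v.
  Events inside the distance window (default 20–500 nm, the union of
  published specific-event ranges) are flagged specific. With these
  defaults the practical detection floor is ≈ 6σ after median
  attenuation; 30 pN events at σ = 5 pN are borderline.
- **Frequencies**: a curve counts as adhesive if it has ≥ 1 specific
  event (per-curve, not per-event, accounting); blocking controls are
  summarised as absolute drop and after/before ratio, "blocked" below a
  0.5 ratio cutoff.

## Adhesion statistics and kinetics

Force histograms use 10 pN bins over [0, 300] pN (extended to cover the
data) and a least-squares Gaussian fit to the binned counts — the
convention behind "μ ± σ pN" figures; a sample-moment ("mle") mode is
available. Below 30 events only the histogram is reported. Binning
convolves the distribution with the bin width (σ² inflated by w²/12,
0.4 % at the defaults), which is why exact-shape recovery tests use
narrow bins.

Adhesion maps reduce each pixel to (event?, max specific rupture force);
max is the least lossy scalar consistent with binary published maps
(first/sum are selectable). Missing pixels are distinct from
measured-but-silent pixels.

Contact-time kinetics fits `f(t) = f_max·t/(k_half + t)`. The
double-reciprocal linearisation (OLS of 1/f on 1/t, zero-frequency
points excluded with a warning) is the conventional default; the direct
nonlinear fit is always computed as a cross-check because the reciprocal
transform distorts the error structure, and a > 25 % k_half discrepancy
triggers a warning. At n = 64 curves per time point the half-saturation
time has a typical (median) sampling error of ~25 % for realistic time
grids — estimates at that depth are indicative, not precise; f_max is
much better determined.

## Default study conditions

Simulation defaults mirror the instrument conditions the package
targets: 12 log-spaced loading rates in [100, 20000] pN/s, ~170 ruptures
per rate (~2000 per spectrum), 32 × 32 force-volume grids, 500 pN
setpoint, 20 °C. Test and acceptance problem sizes (2000 draws per rate
for Monte-Carlo checks, 20 replicates for recovery medians, 200 curves
for detection quality) were chosen to make sampling error small relative
to the tolerances they accompany.

## Known limitations

- f_β (hence x_t) is weakly identified whenever the kinetic regime is
  barely entered; report its confidence interval, not just the point
  estimate.
- Event detection assumes an approximately linear baseline and
  well-separated events; overlapping tether loads (multi-bond) are not
  deconvolved.
- The piezo height vs tip–sample separation distinction is carried only
  as a metadata flag (`height_mode`); at the 20–500 nm rupture distances
  targeted here the difference is second-order, but it is not corrected.
- ΔG inherits the k_c calibration uncertainty linearly.
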