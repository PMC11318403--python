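# Methods

## The measurement problem

Dynamic PET during spontaneous inhalation of oxygen-15-labelled gases gives
access to three haemodynamic/metabolic parameters of brain tissue without any
intravenous line: cerebral blood flow (CBF, here denoted *f*), the oxygen
extraction fraction (OEF), and — through their product with the arterial
oxygen content — the cerebral metabolic rate of oxygen (CMRO2).  Three scans
contribute: an [15O]O2 inhalation scan (oxygen delivery and extraction), an
[15O]CO2 inhalation scan (carbonic-anhydrase conversion makes this an
arterial [15O]water input, i.e. a pure flow tracer), and an optional [15O]CO
scan (carboxyhaemoglobin stays intravascular, giving cerebral blood volume,
CBV).  `oxykin` implements the quantification chain for these scans plus a
synthetic-study generator used for validation.

All computation uses minutes for time and kBq/ml for activity.  Tissue
density is taken as 1 g/ml, so ml-of-tissue and grams are interchangeable in
reported units (ml/min/g for flow).

## Arterial input functions and the metabolite model

The total-blood input function A_t(t) is image-derived: the left-ventricle
(LV) blood-pool TAC, with frame means placed at frame midpoints and
interpolated linearly (`interpolate_lv_tac`).  A zero anchor at t = 0 is
prepended when the curve rises from baseline, and the outer frame edges are
padded with constant values so the curve covers the full scan span.

During [15O]O2 inhalation part of the label circulates as metabolized
[15O]water.  Its arterial concentration is modelled with one first-order
production rate k_w [1/min]:

    A_w(t) = k_w · ∫0^t A_t(s) e^{-k_w (t-s)} ds,     A_o(t) = A_t(t) − A_w(t).

The split conserves activity by construction; `AifSet` enforces
A_t = A_w + A_o to 1e-10 at every grid point.  For the [15O]CO2 scan the
arterial activity is already water, so its input is the LV TAC itself.

## Convolution scheme

Every compartment response is a convolution with an exponential kernel.
`expconv` treats the input as piecewise linear between its samples and
integrates each segment against the kernel in closed form, accumulating with
the one-step recursion I(t_{j+1}) = e^{-kΔ} I(t_j) + segment integral.  The
result is exact (to rounding) for piecewise-linear inputs at any grid
spacing and any rate up to the k ≈ 10 min^-1 used here; no FFT and no
quadrature error enter.  On uniform grids the recursion is evaluated as a
first-order IIR filter (`scipy.signal.lfilter`); non-uniform grids fall back
to an explicit loop.  Generator grids use a 1-s step, so curves that are not
piecewise linear (exponentials) are represented with relative error well
below 1e-4.

## Tissue models

Both inhalation scans follow a one-tissue compartment model in which *f* is
defined as the blood-to-tissue flux of water (appropriate in the
high-flow/limited-extraction regime of the small-animal brain) and
p = 0.91 is the tissue-to-blood partition coefficient of water (used as
printed; dimensionally a ml/g value with unit density).  With vascular
fractions V_o and V_w:

    O2 scan:   C(t) = (1−V_o)·OEF·f·[A_o ⊗ e^{−(f/p)t}] + (1−V_w)·f·[A_w ⊗ e^{−(f/p)t}]
                      + V_o·A_o(t) + V_w·A_w(t)
    CO2 scan:  C(t) = f·[A_w ⊗ e^{−(f/p)t}] + V_w·A_w(t)

The vascular fractions derive from CBV under a fixed venous volume share
F_vein = 0.835, the venous side carrying oxygen already depleted by
extraction:

    V_o = CBV·{1 − F_vein + (1 − OEF)·F_vein},     V_w = CBV·(1 − F_vein).

V_w ≈ CBV·0.165 is ~0.008 ml/ml and is neglected in the default fitting
configuration; a flag (`use_vw`) restores it in both the forward model and
the generator, and the two are kept consistent so that noise-free
generate→fit round trips are exact.  CBV comes from the CO scan as the
duration-weighted tissue/LV activity ratio over a configurable window (full
scan by default; no small-vessel haematocrit correction is applied).  A
single CBV (mean of the two hemispheric values) is used for both VOIs by
default.

Model TACs are compared with measured data as frame means: the continuous
model curve is averaged over each frame by trapezoidal quadrature on a
sub-grid of ≤ 1 s, which is exact for piecewise-linear curves and converged
to < 0.01% for the smooth curves used here.

## Decay handling

All model equations operate on decay-corrected activities.  Uncorrected
input TACs (the longitudinal experiment stores them uncorrected to preserve
count precision) are converted on load using λ = ln 2 / 2.0373 min ≈
0.3402 min^-1 for oxygen-15.  For frame data the conversion factor is the
exact frame mean of the decay exponential over [start, end), not its
midpoint value, so round trips are identities.  The alternative of absorbing
λ into every kernel rate was considered and rejected as the default: it
changes every printed equation while producing the same estimates.

## Estimating k_w from blood samples

Manual arterial samples (0.1 ml, 4–5 draws at 30-s intervals from 30 s
after inhalation onset) are counted in a well counter for whole blood and
for plasma.  The chain is: counts / counting duration / sample mass →
decay-correct to scan start (e^{+λ·draw time}) → well-counter/PET
cross-calibration factor → divide plasma by the plasma/whole-blood
[15O]water concentration ratio → whole-blood-equivalent water curve;
oxygen = whole blood − water (clamped at zero with a warning count).
k_w is then the bounded least-squares minimizer of the squared differences
between the model water curve (metabolite model driven by the image-derived
LV input) and the measured water samples, search range [0.01, 3] min^-1,
restarted from {0.1, 0.33, 1.0}.  Samples are unweighted (equal volumes and
similar count statistics); draws are treated as instantaneous and no
delay/dispersion correction is applied, since none is part of the protocol.
The SSE is numerically unimodal in k_w for the saturating-ramp inputs used
here, and noise-free recovery is exact to < 0.1%.

## Joint CBF/OEF estimation

OEF and f are estimated simultaneously by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) on the
concatenated frame residuals of the paired O2 and CO2 scans, unweighted by
default.  Options: frame-duration weights (√duration, useful when frame
lengths vary within a scan) and an O2-scan weight (0 reduces the problem to
a CO2-only flow fit).  Bounds are f ∈ [0.05, 10] ml/min/g and OEF ∈ [0, 1];
the start is (1.0, 0.5) with a fallback multi-start grid
{0.5, 2, 4} × {0.2, 0.7} engaged when the first solve fails, pins a
parameter at a bound, or leaves more than a quarter of the data variance
unexplained.  V_o is recomputed from the current OEF iterate at every
residual evaluation, keeping the vascular term consistent with the
extraction estimate.  Estimates pinned at a bound are flagged unconverged
(boundary OEF values are quality failures, not physiology).  CMRO2 is
reported as [O2]a·f·OEF exactly, with [O2]a = 1.39 ml/g × Hb × SaO2.
Haemoglobin concentration (default 0.15 g/ml) and SaO2 (default 0.98) are
study inputs.

## k_w sensitivity

Because one cohort-level k_w is applied to all sessions, the pipeline
quantifies how a misspecified k_w propagates: for perturbations π the O2
arterial split is rebuilt at k_w(1+π) and the joint fit repeated; percent
changes of f and CMRO2 relative to the π = 0 fit are reported.  On
protocol-scale synthetic sessions (f ≈ 1.25 ml/min/g, the top of the
maturation range) ±20% perturbations move CBF by ~±3% and CMRO2 by ~∓8%,
smoothly and monotonically through zero.  The effect grows with flow; above
f ≈ 2 ml/min/g (outside this protocol's physiological range) CMRO2 shifts
can exceed 10%.

## Synthetic data

The generator replaces the (undeposited) animal scans and defines the
conditions under which the pipeline is validated.

*Input functions.* Continuous inhalation is modelled as a saturating ramp,
A_t(t) = plateau·(1 − e^{−(t−onset)/rise}) during gas supply and exponential
washout afterwards.  The default rise constant (8 min for the 8-min
O2/CO2 inhalations) is chosen so that, at k_w = 0.33, the oxygen component
levels off after ~3 min (< 20% further growth) while the total keeps rising
(~2× between 3 and 8 min) and the water component overtakes the oxygen
component mid-inhalation — the characteristic shape of a
continuous-inhalation arterial curve.  Within this metabolite model the
end-of-inhalation water fraction cannot fall below ~0.65 at k_w = 0.33 for
any rising input, a known structural property.  Plateau levels (order
100 kBq/ml) affect only noise realism.

*Blood samples.* Raw counts are produced by inverting the normalization
chain at the true water/oxygen split and multiplied by unit-mean lognormal
noise of configurable CV, so the zero-noise chain is exactly invertible.

*Dynamic scans.* Frame TACs come from the forward models with additive
Gaussian noise, SD = scale/√(frame duration in minutes) — a count-statistics
surrogate (longer frames average more decays); Poisson resampling is out of
scope.  The scale may be given per scan; the cohort default (1 kBq/ml at
1-min frames, ~3% of the tissue-TAC peak) represents good-quality data.

*Longitudinal cohort.* Controls mature multiplicatively between postnatal
days 9 and 23: 2.5-fold in f and 2-fold in CMRO2 (so OEF drifts by the 0.8
quotient); the defaults start at f = 0.5 ml/min/g and OEF = 0.55 at day 0.
The injured hemisphere of the hypoxic-ischaemia group follows a depression
factor ramping down to its day-2 nadir (default 0.35) with linear recovery
(default 0.04/day), and a transient OEF elevation peaking at day 2 (default
×1.3, decayed by day 7).  Per-animal lognormal scale factors (CV 0.08) are
drawn once per animal and applied to all its sessions, preserving
longitudinal ratios.  Every dataset is exactly reproducible from its seed.

What the generator does *not* emulate: image reconstruction and its
correlated voxel noise, delay/dispersion between LV and brain, physiological
drift within a session, and motion.  Passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated noise
model, not robustness to all features of real scans.

## Validation results computed by the test suite

- Closed-form agreement of the convolution and forward models (exact for
  piecewise-linear inputs; ≤ 0.1% for smooth inputs on a 0.5-s grid).
- Conservation of the arterial split to 1e-10.
- Mean recovered k_w within ±0.02 min^-1 of the generating 0.33 min^-1
  under the blood-sampling protocol with 3% count noise (8 replicates);
  `scripts/acceptance.py` recomputes this quantity.
- Joint-fit recovery over f ∈ {0.5, 1, 2, 4} × OEF ∈ {0.2, 0.4, 0.6}: exact
  (≤ 1%) at zero noise.  At 5% frame noise the median |OEF error| stays
  ≤ 0.05 in all cells, and the median relative CBF error is ~5% at
  f = 0.5 and ~8% at f = 1, but grows to ~12% at f = 2 and ~25% at f = 4:
  with f/p ≥ 2.2 min^-1 the tissue equilibrates within a fraction of a
  1-min frame, so the TAC shape carries little flow information under a
  slowly varying inhalation input.  This is an identifiability property of
  the protocol, not of the optimizer (zero-noise recovery is exact), and is
  asserted as such in the acceptance suite, where the high-flow cells fail
  the nominal 10% bound.
- End-to-end cohort behaviour: ipsilateral CBF and CMRO2 group means are
  minimal at day 2, control maturation is monotone, and the configured
  2.5× day-14/day-0 control CBF ratio is recovered within sampling error.

## Known limitations

- One cohort-level k_w and one CBV are applied to all sessions, as in the
  protocol; per-session values are supported but not default.
- The CO2-scan input (LV TAC = water) ignores any residual [15O]CO2 in
  blood at early times.
- OEF at a bound (0 or 1) is flagged rather than interpreted.
- High-flow sessions (f ≳ 2 ml/min/g) carry large CBF variance under frame
  noise (see above); the physiological range of the neonatal-rat protocol
  (f ≈ 0.3–1.5 ml/min/g) is well identified.
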