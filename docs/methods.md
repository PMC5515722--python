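# Methods

## Scope and model

The package implements macroscale (organ-level) absorbed-dose estimation
for alpha-emitter-labeled antibodies from sacrifice-design biodistribution
data. The dose model is the standard mean-absorbed-dose formalism
D̄ = Ã·Δ·φ/m restricted to alpha emissions: photons, electrons and recoil
nuclei are neglected, doses are reported as absorbed dose (no RBE
weighting), and the absorbed fraction φ defaults to 1 (alpha ranges of
50–100 µm are small against organ dimensions). Microscale heterogeneity —
which can make the organ-mean dose a poor predictor of biologic effect in
spleen, thymus, kidney cortex and tumor — is explicitly out of scope; the
per-organ outputs are organ means.

## Decay-chain energy constants

Δ, the mean alpha energy per nuclear transition, is computed from an
embedded, versioned decay-data table (`data/alpha_decay_data.csv`: member
nuclide, mean alpha energy in MeV, alphas per parent decay) under secular
equilibrium: every daughter in the local chain decays where and as often
as the parent. Branching is folded into effective yields — ²¹³Bi
contributes its 2.2% alpha branch directly and the 8.38-MeV ²¹³Po alpha at
the 97.8% beta-branch yield; ²¹²Pb (a beta emitter) contributes through
²¹²Bi (36%) and ²¹²Po (64%); ²¹¹At through its 42% direct alpha and the
²¹¹Po alpha on the 58% EC branch. Energies are carried in MeV and
converted once (1 MeV = 1.602176634×10⁻¹³ J). The table's values are
standard evaluated decay data rounded to ~4 significant figures; the two
chain sums relevant to ²²⁵Ac work (4.40×10⁻¹² J/(Bq·s) full chain,
1.33×10⁻¹² for the ²¹³Bi sub-chain) emerge from the table rather than
being stored. Daughter relocation is ignored everywhere except the
explicit kidney free-²¹³Bi term.

## Pharmacokinetic fitting

Organ curves are fitted with 1- or 2-term exponential models by least
squares. Internally the fit uses variable projection: for trial rates the
amplitudes are the exact linear (or non-negative) least-squares solution,
so the nonlinear search runs over log-rates only, started from
curve-peeling estimates (log-linear tail from the last two points, strip,
log-linear remainder) plus a small deterministic grid, and polished on the
full parameter vector. Rates are bounded to half-lives in [0.05, 5000] h;
a fit pinned at the slow boundary means the curve does not decay and is
rejected rather than integrated. Model order defaults to 2 with automatic
fallback to 1 when the 2-term fit is degenerate (rate ratio < 1.2 or a
fractional amplitude < 1%). Weighting defaults to inverse-variance when
per-point SDs are available, else unweighted; uptake tissues may be fitted
with a signed fast term (`nonnegative=False`), but percent/half-life
summaries are defined only for non-negative amplitudes.

## Time-integrated activity

Two routes, recorded per organ because the choice is a property of the
data:

* **fit**: Ã = Σ Aᵢ/λᵢ in closed form (agrees with adaptive quadrature to
  <0.01%, asserted by test).
* **hybrid**: trapezoid over the measured span plus the analytic tail
  c_k/λ_tail with λ_tail the log-linear slope of the last two samples.

Three edge rules are fixed here and tested:

1. *Leading edge.* The span from injection to the first sample (1 h in the
   default design) is filled by back-extrapolating the first-segment
   log-linear slope, floored at the first measured value: a decaying first
   segment (blood) extrapolates upward so the distribution phase is not
   discarded; a rising first segment (uptake organs) contributes a
   constant c₁ — no activity is invented before the first sample.
2. *Non-decreasing tail.* A tissue still accumulating at the last sample
   has no defined biological clearance rate; the biological level is held
   constant and the integral is terminated by physical decay alone. The
   result is flagged `conservative-tail`: an upper bound, which is the
   safe direction when the output feeds a prescription.
3. *Decay convention.* Measured %IA/g is treated as decay-corrected
   (biological). Physical decay is applied explicitly and exactly once —
   in `substitute_radionuclide` (closed form Σ Aᵢ/(λᵢ+λ_phys), or
   pointwise e^(−λ_phys·t) weighting before the hybrid rule) or in the
   flagged flat-tail fallback. This prevents double-counting decay and
   makes TIA provably monotone non-increasing in λ_phys, which is what
   makes the ²²⁵Ac/²¹²Pb/²¹¹At comparison meaningful.

Plain trapezoid (not log-trapezoid) integrates the measured span. On the
sparse 5-point schedule this overestimates convex decaying curves by
roughly 15–20%, which is why the pipeline prefers the fit route and treats
the hybrid route as the fallback it is.

## Kidney free-²¹³Bi

Both decay constants of a kidney counting series are known physics
(²¹³Bi: 45.6 min; parent: 10 d), so the "double exponential fit" is a
2-parameter non-negative linear least-squares problem on
interval-integrated expected counts — no nonlinear search, no local
minima. The free-daughter concentration at sacrifice is the fast
amplitude; identifiability requires the series to span at least one fast
half-life (error below; flagged `short-series` below three). The free-Bi
curve across sacrifice times is integrated with the same hybrid rule as
any tissue and dosed with the sub-chain Δ; parent and free components are
stored separately and sum exactly to the kidney total.

## Units and prescription

The single dose-conversion constant is assembled symbolically
(0.01 fraction/% × 3600 s/h × 10³ g/kg × 10³ mGy/Gy × 10³ Bq/kBq) and
anchored by a dimensional-analysis test (4660 %IA·h/g × 4.40×10⁻¹²
J/(Bq·s) → 738 mGy/kBq). Raw coefficients are kept unrounded;
report convention is 3 significant figures for coefficients and 2 for
prescriptions (`round_sig`). The prescription is min over limited organs
of limit/coefficient, with the binding organ recorded and all organ doses
evaluated at the prescribed activity; the marrow coefficient is 0.36 × the
blood coefficient (rapid-equilibration assumption for intact antibody).

## Synthetic study generator

The generator emulates the sacrifice design: schedule (1, 6, 24, 72,
144 h), 3–5 animals per time, 13 tissues, per-time mean/SD/n summaries.
Inter-animal variation is multiplicative lognormal with CV 0.15 (default),
centred to be mean-unbiased — concentrations are positive and biological
scatter scales with the mean. Well-counter noise is Poisson on exact
interval-integrated expected counts; counting background defaults to zero
(a constant background term exists but is off by default). The default
organ library is qualitatively antibody-like: biexponential blood
(63%/6 h + 37%/19 h at 30 %IA/g), uptake phases (negative fast term) in
liver, spleen, thymus and tumor, low muscle background. Terminal
half-lives are kept within ~2× the 144-h observation window so that the
terminal slope is identifiable from the design — tissues whose terminal
half-life far exceeds the sampling window cannot have their TIA recovered
by *any* estimator from these data, and the liver entry (300 h) is
deliberately left near that edge. What the generator does **not**
reproduce: receptor saturation and protein-dose dependence, correlated
inter-organ noise within an animal, decay-correction error, weighing and
pipetting error, and tumor-growth dilution. Passing recovery tests
therefore demonstrate estimator correctness under the stated noise model,
not robustness to every systematic error of a real study.

## Problem sizes and numerical choices

Monte-Carlo guarantees are asserted at the study's own scale: 200
replicate cohorts (n = 5, CV = 15%) for blood-parameter and end-to-end
dose recovery (medians within 10 percentage points / 25% / 10%
respectively), 100 replicate counting series for the free/supported split
(every replicate within 5 percentage points at ≥10⁴ counts). Quadrature
oracles integrate to infinity with adaptive quadrature. All randomness
flows through `numpy.random.default_rng` seeds; fixing the seed fixes
every generated value.

## Known limitations

* Organ masses are not used (all outputs are per-gram or per-administered-
  activity); converting to organ dose requires masses the caller supplies.
* The hybrid route's leading-edge and flat-tail rules are conventions; the
  flat-tail fallback in particular is an upper bound, not an estimate.
* Curve stripping assumes exactly two components with known rates;
  a third contaminant activity would be absorbed into the amplitudes.
* The marrow rule is a fixed scalar; it does not model marrow cellularity
  or blood-to-marrow concentration ratios beyond the 0.36 factor.
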