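# Methods

## The reactivity model

The package's core is a linear free-energy relationship between the
logarithm of the bimolecular rate constant of a tetrazine–TCO IEDDA
cycloaddition and its electronically computed activation energy,

    ln k = a · ΔE‡ + b,

with k in M⁻¹ s⁻¹ and ΔE‡ in kJ/mol. The linear form is what
transition-state theory predicts when the computed electronic barrier
tracks the free-energy barrier up to an additive, substituent-
independent term (entropic and thermal contributions being nearly
constant across a homologous series). The model is calibrated by
ordinary least squares of ln k on ΔE‡ and makes no claim outside its
validity domain: aryl/alkyl-substituted 1,2,4,5-tetrazines reacting with
*trans*-cyclooctene in anhydrous 1,4-dioxane at 298.15 K, barriers from
M06-2X/6-311+G(d,p) gas-phase electronic energies. The fitted model
object records temperature, solvent and the training barrier range
[−6.57, 6.78] kJ/mol, and predictions outside that range are flagged as
extrapolations.

### Activation energies

ΔE‡ = E(TS) − E(Tz) − E(TCO), all total electronic energies in hartree,
converted with 1 hartree = 2625.499639 kJ/mol (CODATA 2018; all physical
constants — R, k_B, h — live in one table at the top of
`tzreact/iedda.py`). The barrier is purely electronic: no zero-point,
thermal or entropic corrections, so negative (submerged) barriers are
legitimate and occur in the training set (−6.57 kJ/mol for the fastest
tetrazine). The API says activation *energy* throughout and never free
energy; Eyring conversions between k and ΔG‡ are provided separately
(`eyring_delta_g` / `eyring_rate`, 1 M standard state) and are exact
inverses of each other.

### Stopped-flow kinetics

Under pseudo-first-order conditions (TCO in large excess, default screen
≥ 20-fold), the tetrazine absorbance near 535 nm decays as a one-phase
exponential

    y(t) = (y0 − plateau) · exp(−k_obs · t) + plateau,

and k = k_obs / c(TCO). The three-parameter (y0, plateau, k_obs)
parameterisation matches the convention of common kinetics software, so
fitted values are directly comparable with instrument-vendor output.
Fitting is nonlinear least squares (scipy's Levenberg–Marquardt) started
from plateau₀ = min(signal), y0₀ = first signal value, and k₀ from the
log-linear slope of the baseline-subtracted signal over the first half
of the trace (offset ε = 10⁻⁹·max|signal| guards the logarithm). A
constant, rising, or otherwise non-decaying trace yields
`converged=False` with `k_obs = NaN` — never a silent number. The caller
must tag which concentration is in excess; the package never guesses
from magnitudes, because a mis-tagged excess species silently scales k.
Replicates are aggregated as mean ± sample SD with no outlier rejection.

### Calibration and prediction

`calibrate` is OLS of ln k on ΔE‡ (statsmodels), requiring ≥ 3 points
and non-zero barrier variance; it reports slope, intercept, R²,
coefficient standard errors, and the sufficient statistics (x̄, S_xx,
residual SE) for prediction intervals. Natural logarithms throughout —
the law is an exponential in e — so the intercept is a ln(M⁻¹ s⁻¹)
number. Points are unweighted: the calibration data carry no usable
per-point replicate variances. 95 % prediction intervals use the OLS
prediction variance s²(1 + 1/n + (x − x̄)²/S_xx) with a t quantile at
n − 2 degrees of freedom, exponentiated; a hand-built model without the
sufficient statistics degrades to a point estimate rather than
inventing an interval.

On the packaged data the calibration accepts either the published
2-decimal barriers with published rates, or the full chain recomputed
from hartree energies and k_obs/c(TCO); both reproduce slope −0.1963 to
−0.1965 and intercept 1.460, comfortably inside each other's standard
errors.

### The FMO screen

`fmo_gap` returns tetrazine LUMO+1 minus dienophile HOMO. For
aryl/alkyl tetrazines the unoccupied orbital with the right symmetry
for the inverse-electron-demand interaction is the tetrazine's LUMO+1,
interacting with the HOMO of the electron-rich dienophile; descriptions
of this interaction sometimes attribute the low-lying unoccupied
orbital to the dienophile, which is physically inconsistent for an
inverse-electron-demand reaction, and the implementation follows the
consistent reading. `correlate_descriptor` (simple linear regression,
slope/intercept/R²) quantifies how poorly any single orbital energy
predicts the rates — the negative result that motivates the
barrier-based model. Orbital energies default to eV and every file
declares its unit; there is no silent conversion.

## The packaged dataset

Ten aryl/alkyl tetrazines, TCO, and the ten transition states for their
cycloadditions (total electronic energies in hartree), plus the ten
stopped-flow measurements (k_obs, mixing concentrations of both
species, and the published second-order k), as two plain CSVs under
`tzreact/data/` with a provenance column. In the published energy
table the E(TS) and ΔE‡ columns are typeset run together for six rows;
five of those splits are digit-ambiguous, so their E(TS) values are
reconstructed to be consistent with the published ΔE‡ and flagged
`provenance=reconstructed` (the remaining rows are `printed`).
`load_fixture` verifies integrity on every load: species counts
(10/1/10), referential consistency of the rate table, and that every
recomputed barrier matches its published value within ±0.01 kJ/mol —
the print-rounding of the hartree inputs.

One measurement (the 5.12 M⁻¹ s⁻¹ reaction) was run at only ~19-fold
TCO excess and fails the default ≥ 20 pseudo-first-order screen; the
data are kept as measured and the screen reports it honestly.

## Synthetic-data generators

`simulate_trace` emulates a stopped-flow acquisition as the exact
one-phase decay plus i.i.d. Gaussian noise per time point (Beer–Lambert
signal with photometric noise). Defaults used across the validation
studies mirror the measured reactions: y0 = 0.5 AU, plateau = 0.05 AU,
k_obs from the measured range (0.002–0.031 s⁻¹), 200–300 points over
~5 pseudo-first-order half-lives, noise SD 0.002 AU (≈ 0.4 % of full
scale, typical for a photodiode stopped-flow). It does not emulate
mixing dead time, drift, correlated noise or biexponential behaviour,
so passing recovery tests shows the estimator is correct for the stated
model, not that real traces are free of those artefacts.

`simulate_second_order` is the exact closed-form bimolecular decay
(distinct- and equal-concentration branches, mass balance holding to
1e−12) and serves as the independent oracle for the pseudo-first-order
approximation: exponential fits to exact bimolecular traces recover k
with error falling monotonically over excess ratios 5 → 10 → 20 → 40,
about 1 % at 40-fold — the regime the measurements were designed for.

`simulate_calibration` draws barriers uniformly over the training range
and adds Gaussian residuals to ln k (residual SD 0.1, matching the
calibration's observed scatter); 500-replicate studies confirm the OLS
estimates are unbiased. All generators take an explicit seed and are
deterministic given it.

## Numerical choices

* Hartree→kJ/mol fixed at 2625.499639; published-barrier comparisons
  use round-half-even to 2 decimals with ±0.01 kJ/mol slack for the
  inputs' own print rounding.
* Decay-fit convergence is the solver's own status plus sanity checks
  (finite k_obs > 0, y0 > plateau); anything else is a loud failure.
* Simulation problem sizes (200–300 points per trace, 100–500 Monte
  Carlo replicates) are chosen so each study resolves its effect well
  below the tolerance it checks while the whole suite stays desk-scale.
* CSV: UTF-8, comma-separated, mandatory header, `#` comments,
  scientific notation accepted, round-trip float parsing. Model files
  are versioned flat key = value text (`tzreact-model/1`) with
  `repr`-precision floats, so save/load round-trips bit-for-bit. XYZ
  files follow the standard dialect (count, comment, atom lines);
  the reader tolerates tabs and trailing blank lines, the writer emits
  6-decimal coordinates.

## Limitations

* The model is a correlation over one substituent family, one
  dienophile, one solvent and one temperature; nothing constrains its
  behaviour for bis-aryl tetrazines, other dienophile classes, aqueous
  media or other temperatures beyond the extrapolation flag.
* ΔE‡ quality is inherited from the user's electronic-structure
  calculations; the package performs no quantum chemistry and cannot
  detect a wrong transition state.
* Prediction intervals assume i.i.d. Gaussian residuals in ln k, which
  ten points can suggest but not establish.
* The published LUMO+1 correlation (R² = 0.07) cannot be recomputed
  here because the underlying orbital energies are available only as a
  figure; the FMO screen is therefore exercised on synthetic and
  user-supplied orbital data.
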