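# Methods

This note documents the models behind each analysis stage, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Thermal unfolding (CD melts)

**Model.** Two-state equilibrium unfolding with a temperature-dependent
equilibrium constant from the van't Hoff relation, no heat-capacity
term (ΔCp = 0):

    K(T) = exp[ −ΔHm · (1 − T/Tm) / (R·T) ]      (T, Tm in kelvin)
    Y(T) = [ (a_n + b_n·T) + (a_u + b_u·T) · K(T) ] / (1 + K(T))

Six free parameters: midpoint `Tm` (reported in °C), van't Hoff
enthalpy `ΔHm` (kJ/mol, positive for unfolding), and linear folded /
unfolded baselines written against °C. The fraction unfolded
f = K/(1+K) equals 1/2 exactly at Tm, is strictly increasing in T for
ΔHm > 0, and is computed through a logistic of ln K so extreme
temperatures cannot overflow.

**Fitting.** Raw (unnormalized) signal is fitted directly — the
baselines absorb any multiplicative scale, so Tm and ΔHm are
scale-equivariant and a separate normalization step would be redundant
(normalized f is computed from the fitted baselines only for
plotting). Initialization is deterministic: baselines by ordinary least
squares on the outer 15% of the temperature range, Tm₀ at the extreme
derivative of a 5-point-smoothed trace, and ΔHm₀ from the apparent
10–90% width via ΔHm ≈ R·Tm²·ln 81 / width (clipped to
[20, 1500] kJ/mol, falling back to 300 kJ/mol when no width is
measurable). Optimization is Levenberg–Marquardt (lmfit) with
Tm bounded to the observed span and ΔHm to [1, 3000] kJ/mol; standard
errors come from the covariance at the optimum. A trace whose
edge-baseline separation is within noise (5σ of the edge-fit residuals,
with a 0.1%-of-range absolute floor) raises a "no transition detected"
error rather than returning a meaningless fit; a non-converged fit is
flagged and withholds its parameters.

**DSF.** Differential scanning fluorimetry melts are fitted with a
Boltzmann sigmoid between the same linear baselines; the reported DSF
Tm is the inflection point. This is an independent Tm estimator, not
the van't Hoff model — no enthalpy is reported from DSF. `delta_tm`
computes ligand-induced thermal shifts Tm(holo) − Tm(apo) from two
curves of the same modality. Monotone-decreasing DSF traces are
rejected (the supported assay shape is a rising transition).

## Chemical (GdnHCl) unfolding

**Two-state model.** Linear extrapolation (Santoro–Bolen form): the
unfolding free energy is ΔG(D) = ΔG_H2O − m·D, so
K(D) = exp[−(ΔG_H2O − m·D)/RT] at the fixed assay temperature
298.15 K, with the same two-baseline signal construction as the thermal
model. The midpoint is Cm = ΔG_H2O/m.

**Three-state model.** Sequential N↔I↔U with independent linear free
energies (ΔG1, m1) and (ΔG2, m2). Populations are computed in log space
(`logaddexp`), so pN + pI + pU = 1 to machine precision for any
parameter values. The intermediate contributes a fraction `z_i` of the
native spectral amplitude:

    Y = (a_n + b_n·D)·(pN + z_i·pI) + (a_u + b_u·D)·pU

`z_i` is constrained to its physical range [0, 1] (a fraction of the
native amplitude). Nine parameters are fitted in total. In the limit
K1→∞ with z_i = 1 the model reduces exactly to the two-state curve in
(ΔG2, m2), which is exploited below.

**Fitting.** The two-state fit is a single bounded trust-region
least-squares solve from a deterministic heuristic start (edge
baselines, midpoint crossing for Cm₀, logistic slope for m₀). The
three-state fit is multi-modal, so it uses a deterministic 27-point
start grid over (ΔG1, ΔG2, z_i) scaled from the two-state solution with
baselines seeded from it; starts are ranked by initial residual sum of
squares and the best nine are polished, plus one start embedding the
two-state solution itself (K1→∞, z_i=1), which guarantees the nesting
property RSS(three) ≤ RSS(two) up to optimizer tolerance. Standard
errors come from the jacobian at the optimum. Replicate titrations are
pooled (pointwise mean on a shared grid) before fitting, matching the
averaged-scan convention of plate fluorimetry. A residual-outlier
diagnostic (|standardized residual| > 3.5) flags anomalous excursions —
such as the transient fluorescence collapse EphB3 shows near 1 M
GdnHCl — without removing or modelling them.

**Model selection.** AICc with k counting the fitted parameters plus
the error variance:

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1),  k = 7 (two-state), 10 (three-state)

Akaike weights are reported as percentages that sum to 100 exactly.
AICc is undefined (raises) when n ≤ k+1.

**A known property, documented deliberately.** On data truly generated
from the two-state model, the three-state alternative's gain in RSS is
stochastically larger than a naive 3-extra-parameter χ² argument
suggests, because the intermediate's parameters are unidentified under
the two-state truth (a boundary/non-identifiability effect familiar
from mixture-model likelihood-ratio testing). With 61 points and
0.5%-amplitude noise the two-state model wins the AICc comparison in
roughly 85–90% of replicates, not essentially always; a globally
optimized three-state fit occasionally absorbs enough noise to win.
Users comparing nested unfolding models should treat borderline Akaike
probabilities (say 50–95%) as inconclusive rather than as evidence of
an intermediate. The strong, well-separated intermediate case is
unambiguous: the three-state probability exceeds 99.99%.

## Steady-state kinetics

Initial velocities are the ordinary-least-squares slope of the longest
time window anchored at t = 0 whose linear fit reaches R² ≥ 0.99 (at
least 4 points); a perfectly constant signal is an exact zero-slope
line, and a course with no qualifying window raises "nonlinear time
course". This windowing keeps substrate depletion out of the rate: at
curvatures gentle enough that depletion stays below ~7% across the full
course the slope is within ~4% of the analytic initial derivative; at
strong curvature the accepted window shrinks. Note the R² ≥ 0.99
criterion is a practical linearity screen, not a depletion bound — a
saturating course can stay above R² = 0.99 while biasing the slope by
~10%, so assay designs should keep depletion low rather than rely on
the screen.

Rates are calibrated to nmol ADP·min⁻¹ through a dataset-level scalar
(luminescence units per nmol; 1.0 for synthetic data) and scaled per mg
enzyme using the in-reaction enzyme mass: 25 nM final concentration
(50 nM stock mixed 1:1) in 4 μl, times the construct molar mass.
Michaelis–Menten regression v = Vmax·S/(Km+S) is by bounded
least squares; a fit whose Km estimate exceeds the top assayed
concentration is flagged "Km poorly constrained". Turnover:
kcat [s⁻¹] = Vmax [nmol·min⁻¹·mg⁻¹]·M [g/mol]/6×10⁷, with the exact
inverse for the round trip.

**Construct molar masses.** The published kinetic table prints kcat and
Vmax but not the masses used to link them. The package stores
*effective* masses back-derived per enzyme (M = kcat·6×10⁷/Vmax):
33,922 (EphB1), 36,959 (EphB2), 33,770 (EphB3), 39,281 (EphB4), 33,659
(EphB3-C717G) g/mol. All five constructs are ~298 residues (kinase
domain plus an N-terminal GSS cloning remnant), i.e. ≈33.5 kDa by
sequence length, so the EphB1/EphB3/EphB3-C717G values are physically
consistent (~1%), while the EphB2 and EphB4 printed pairs imply masses
10–17% heavier than any plausible construct — an internal inconsistency
of the published table. Using the effective masses keeps each row's
kcat↔Vmax conversion exact; users supplying their own `EnzymeSpec`
should use true sequence masses. Relatedly, the published text calls
the EphB2 turnover "30% greater" than EphB1's while the printed values
give a 1.39× ratio; the printed table is treated as authoritative.

## Dose-response profiling

The dosing scheme is 11 half-log steps down from the top dose plus a
twelfth point a whole log below the eleventh (default top dose 100 μM).
Percent inhibition is anchored on the plate's control-well means — 0%
at the max (DMSO) controls, 100% at the min (fully inhibited)
controls — making the normalization idempotent and the IC50 invariant
under any multiplicative rescaling of the raw luminescence. Min
controls may be supplied from a designated reference compound's plateau
wells (the "artificial minimum" convention) — the container does not
care where the wells came from.

The pooled normalized points (replicates are pooled into a single fit)
are fitted with a four-parameter logistic,
inhibition(c) = bottom + (top−bottom)/(1+(IC50/c)^hill), with IC50
optimized in log space, hill a free parameter bounded to (0, 5] (the
source protocol does not state a fixed slope; the bound prevents
pathological step fits), and top/bottom loosely bounded. Because of
this parameterization the fitted IC50 is exactly the concentration at
the top/bottom midpoint. A curve whose fitted value at the top dose
stays below 50% absolute inhibition is reported as a bound
("> top dose"), never extrapolated. Fits at or below twice the assay's
tight-binding floor (25 nM, roughly half the enzyme concentration) are
flagged as unresolved in potency and left uncorrected — no
Morrison-type tight-binding correction is applied. The selectivity
report expresses each enzyme's IC50 as a fold over the most potently
inhibited enzyme per compound, propagating censored fits as lower
bounds.

## Synthetic-data generator

The generator evaluates the forward model owned by each analysis module
on a sampling grid and adds seeded Gaussian noise; it shares no fitting
code, so generate→fit round trips genuinely exercise the estimators.
Defaults copy the assay protocols: 1 °C pitch from 20–80 °C for melts,
0.1 M steps from 0–6 M GdnHCl, time points every 20 min from 0–140 min
with an 8-point 0–5 mM ATP design (two-fold dilutions from 5 mM plus a
zero), and 12-point half-log dosing with 11 max and 11 min control
wells.

Noise is additive Gaussian by default; a proportional
(constant-CV) variant covers luminescence data whose error scales with
signal, and is the default for the kinetics and plate presets (3% CV).
Default noise magnitudes — 1% of transition amplitude for melts, 0.5%
for titrations, 3% CV for luminescence — were chosen once so that
recovery scatter is comparable to the published standard errors; they
are a calibration choice, as no replicate-level noise magnitudes are
published. Seeds are mandatory and the same seed reproduces a dataset
bit for bit. Kinetics luminescence is clipped at zero after noise (a
photon count cannot be negative); at the default noise levels this only
trims tails at the t = 0 column.

`published_presets()` carries one recipe per published table row (4 thermal,
5 kinetics, 35 inhibitor×enzyme) with truth values exactly as printed.
The single printed IC50 *bound* (">100" for Afatinib×EphB3) is
simulated at 10× the bound so the out-of-window reporting path is
exercised; the printed string is preserved in the truth record. No
chemical-unfolding or DSF presets exist because the tables print no
generating parameters for those assays; `demo_recipes()` provides
representative conditions instead (complete unfolding by ~3 M GdnHCl;
an intermediate populated near 2 M; a rising DSF melt at the EphB2
midpoint).

**What the generator does not emulate** — and hence what passing
recovery tests do not show about real data: plate-geometry artifacts
(edge effects, dispense errors), correlated or drifting baselines,
photobleaching, the anomalous non-monotone fluorescence excursion real
EphB3 shows near 1 M GdnHCl (handled only as an outlier diagnostic),
substrate depletion beyond the linear window, and full spectral scans
(only the analyzed 1-D traces are produced).

## Pipeline

`charkit run config.yaml` executes any subset of
{thermal, dsf, chemical, kinetics, ic50} on input CSVs and/or named
presets. Stages are isolated: one stage's failure is collected and
reported without touching the others. All numeric output is written
with 6 significant figures, so identical config + seed reproduces
reports byte for byte; the run log records seeds, warnings
(non-convergence, bounds, tight binding) and errors.

## Problem sizes used in validation

Recovery experiments in the test suite and acceptance script use 100
seeds per Monte-Carlo estimate (mean for Tm/ΔHm/Km, median for IC50),
200 replicates for the model-selection win-rate experiment, 61-point
titrations, and the full 44-preset catalogue for the plate-recovery
sweep. These sizes make the Monte-Carlo standard error a small fraction
of each comparison tolerance while keeping the full suite to a few
minutes on one core.

## Known limitations

- No ΔG(T) extrapolation to 25 °C from thermal melts (requires ΔCp,
  which the six-parameter model omits by construction).
- Chemical unfolding is equilibrium-only; no unfolding/refolding
  kinetics, and no global fitting across proteins (each curve is fitted
  independently).
- Michaelis–Menten treats each substrate at fixed co-substrate; no
  bisubstrate ternary-complex mechanism, no phosphorylation-state or
  juxtamembrane autoinhibition modelling.
- No Cheng–Prusoff Ki conversion of IC50s (the ATP-at-Km convention
  varies per enzyme) and no ITC isotherm fitting.
- The model-selection win rate on truly two-state data (~85–90%, above)
  is an inherent property of AICc with a nested nonlinear alternative,
  not a tunable of this implementation.
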