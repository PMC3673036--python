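"""Equilibrium chemical (GdnHCl) unfolding: two- and three-state models
with small-sample Akaike model selection.

Two-state linear-extrapolation model (Santoro–Bolen style).  The
unfolding free energy is linear in denaturant molarity D, so the
folded↔unfolded equilibrium constant at the assay temperature (298.15 K)
is

    K(D) = exp[ −(ΔG_H2O − m·D) / (R·T) ]

and the observed fluorescence interpolates two linear baselines,
Y = [(a_n + b_n·D) + (a_u + b_u·D)·K] / (1 + K).  The midpoint Cm is
ΔG_H2O / m.

Three-state sequential model N ↔ I ↔ U with one intermediate:

    K1 = exp[−(ΔG1 − m1·D)/RT]      K2 = exp[−(ΔG2 − m2·D)/RT]
    pN = 1/(1 + K1 + K1·K2),  pI = K1·pN,  pU = K1·K2·pN

The intermediate contributes a fraction ``z_i`` of the native spectral
amplitude: Y = (a_n + b_n·D)·(pN + z_i·pI) + (a_u + b_u·D)·pU.

Model selection uses AICc with k counting the fitted parameters plus the
error variance; Akaike weights are reported as percentages summing to
100.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.special import expit

from .constants import R_GAS, T_CHEM
from .data import DenaturationCurve
from .thermal import _edge_baselines, _smooth

__all__ = [
    "ChemParams2",
    "ChemParams3",
    "ChemicalUnfolding",
    "ChemicalUnfoldingResults",
    "ModelComparison",
    "two_state_model",
    "three_state_model",
    "three_state_populations",
    "fit_chemical",
    "compare_models",
    "pool_replicates",
    "aicc",
]

_RT = R_GAS * T_CHEM  # J/mol


@dataclass(frozen=True)
class ChemParams2:
    """dg_h2o and m_value in kJ/mol and kJ·mol⁻¹·M⁻¹; linear baselines."""

    dg_h2o: float
    m_value: float
    a_n: float = 1.0
    b_n: float = 0.0
    a_u: float = 0.0
    b_u: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.dg_h2o, self.m_value, self.a_n, self.b_n, self.a_u, self.b_u]
        if not np.all(np.isfinite(vals)):
            raise ValueError("chemical parameters must be finite")

    @property
    def cm(self) -> float:
        """Denaturant midpoint Cm = ΔG_H2O / m (M)."""
        return self.dg_h2o / self.m_value


@dataclass(frozen=True)
class ChemParams3:
    """Sequential N↔I↔U parameters; z_i is the intermediate's amplitude
    as a fraction of the native amplitude (dimensionless)."""

    dg1: float
    m1: float
    dg2: float
    m2: float
    a_n: float = 1.0
    b_n: float = 0.0
    a_u: float = 0.0
    b_u: float = 0.0
    z_i: float = 0.5

    def __post_init__(self) -> None:
        vals = [self.dg1, self.m1, self.dg2, self.m2,
                self.a_n, self.b_n, self.a_u, self.b_u, self.z_i]
        if not np.all(np.isfinite(vals)):
            raise ValueError("chemical parameters must be finite")


def two_state_model(D, params: ChemParams2) -> np.ndarray:
    """Evaluate the two-state linear-extrapolation curve at molarities D."""
    D = np.asarray(D, dtype=float)
    f = expit(-(params.dg_h2o * 1e3 - params.m_value * 1e3 * D) / _RT)
    return (params.a_n + params.b_n * D) * (1.0 - f) + (params.a_u + params.b_u * D) * f


def three_state_populations(D, dg1, m1, dg2, m2):
    """Populations (pN, pI, pU) of the sequential three-state scheme.

    Computed through log-space accumulation so extreme free energies do
    not overflow; pN + pI + pU = 1 to machine precision.
    """
    D = np.asarray(D, dtype=float)
    l1 = -(dg1 * 1e3 - m1 * 1e3 * D) / _RT  # ln K1
    l2 = -(dg2 * 1e3 - m2 * 1e3 * D) / _RT  # ln K2
    # log of (1 + K1 + K1 K2)
    log_denom = np.logaddexp(0.0, np.logaddexp(l1, l1 + l2))
    pN = np.exp(-log_denom)
    pI = np.exp(l1 - log_denom)
    pU = np.exp(l1 + l2 - log_denom)
    return pN, pI, pU


def three_state_model(D, params: ChemParams3) -> np.ndarray:
    """Evaluate the sequential three-state unfolding curve at molarities D."""
    D = np.asarray(D, dtype=float)
    pN, pI, pU = three_state_populations(D, params.dg1, params.m1, params.dg2, params.m2)
    y_n = params.a_n + params.b_n * D
    y_u = params.a_u + params.b_u * D
    return y_n * (pN + params.z_i * pI) + y_u * pU


def _func2(D, dg_h2o, m_value, a_n, b_n, a_u, b_u):
    return two_state_model(D, ChemParams2(dg_h2o, m_value, a_n, b_n, a_u, b_u))


def _func3(D, dg1, m1, dg2, m2, a_n, b_n, a_u, b_u, z_i):
    return three_state_model(D, ChemParams3(dg1, m1, dg2, m2, a_n, b_n, a_u, b_u, z_i))


class ChemicalUnfolding:
    """Model object for equilibrium chaotrope unfolding.

    Parameters
    ----------
    curve : DenaturationCurve
        Fluorescence titration to fit (≥ 12 points spanning the
        baseline–transition–baseline range).
    n_states : int
        2 for the linear-extrapolation two-state model, 3 for the
        sequential intermediate model.
    """

    # deterministic multi-start design for the 8(+1)-parameter model
    _N_POLISH = 9

    def __init__(self, curve: DenaturationCurve, n_states: int = 2):
        if n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if n_states == 3 and len(curve) < 10:
            raise ValueError("three-state fits need at least 10 points")
        self.curve = curve
        self.n_states = n_states

    @classmethod
    def from_arrays(cls, denaturant, fluorescence, n_states: int = 2):
        return cls(DenaturationCurve(denaturant, fluorescence), n_states=n_states)

    def _two_state_guess(self) -> ChemParams2:
        D = self.curve.denaturant
        y = _smooth(self.curve.fluorescence)
        (a_n0, b_n0), (a_u0, b_u0), _ = _edge_baselines(D, y)
        yn = a_n0 + b_n0 * D
        yu = a_u0 + b_u0 * D
        denom = yn - yu
        denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
        fapp = np.clip((yn - y) / denom, 0.0, 1.0)
        i_mid = int(np.argmin(np.abs(fapp - 0.5)))
        cm0 = float(D[i_mid]) if D[i_mid] > 0 else float(np.median(D))
        # slope of f at Cm gives m/(4RT)
        df = np.gradient(fapp, D)
        slope = float(df[i_mid])
        m0 = 4.0 * _RT * slope / 1e3 if slope > 0 else 10.0
        m0 = float(np.clip(m0, 1.0, 40.0))
        return ChemParams2(m0 * cm0, m0, a_n0, b_n0, a_u0, b_u0)

    def _fit_two(self) -> "ChemicalUnfoldingResults":
        from scipy.optimize import least_squares

        g = self._two_state_guess()
        D, y = self.curve.denaturant, self.curve.fluorescence

        def resid(theta):
            return _func2(D, *theta) - y

        lo = np.array([-50.0, 0.05, -np.inf, -np.inf, -np.inf, -np.inf])
        hi = np.array([200.0, 80.0, np.inf, np.inf, np.inf, np.inf])
        x0 = np.clip([g.dg_h2o, g.m_value, g.a_n, g.b_n, g.a_u, g.b_u], lo, hi)
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            x_scale="jac", max_nfev=20000)
        names = ("dg_h2o", "m_value", "a_n", "b_n", "a_u", "b_u")
        return ChemicalUnfoldingResults._from_least_squares(
            self, sol, names, n_states=2, ydata=y
        )

    def _fit_three(self) -> "ChemicalUnfoldingResults":
        from scipy.optimize import least_squares

        fit2 = ChemicalUnfolding(self.curve, 2)._fit_two()
        p2 = fit2.params if fit2.converged else self._two_state_guess()
        D, y = self.curve.denaturant, self.curve.fluorescence

        # theta = (dg1, m1, dg2, m2, a_n, b_n, a_u, b_u, z_i)
        def resid(theta):
            return _func3(D, *theta) - y

        # z_i is the intermediate's fraction of the native amplitude,
        # so it is constrained to its physical range [0, 1]
        lo = np.array([-100.0, 0.01, -100.0, 0.01, -np.inf, -np.inf,
                       -np.inf, -np.inf, 0.0])
        hi = np.array([200.0, 80.0, 200.0, 80.0, np.inf, np.inf,
                       np.inf, np.inf, 1.0])
        base = (p2.a_n, p2.b_n, p2.a_u, p2.b_u)
        m0 = float(np.clip(p2.m_value, 5.0, 30.0))
        dg0 = float(np.clip(p2.dg_h2o, 5.0, 60.0))
        starts = [
            np.array([f1 * dg0, m0, f2 * dg0, m0, *base, z])
            for f1 in (0.5, 1.0, 1.5)
            for f2 in (0.7, 1.3, 2.0)
            for z in (0.25, 0.5, 0.75)
        ]
        # embedded two-state limit (K1 → ∞, z=1): guarantees the nesting
        # property RSS(three) ≤ RSS(two)
        embedded = np.array([-60.0, 0.1, p2.dg_h2o, p2.m_value, *base, 1.0])

        ranked = sorted(starts, key=lambda s: float(np.sum(resid(s) ** 2)))
        best_sol, best_rss = None, np.inf
        for x0 in [*ranked[: self._N_POLISH], embedded]:
            sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                                method="trf", x_scale="jac", max_nfev=20000)
            rss = float(np.sum(sol.fun**2))
            if rss < best_rss:
                best_sol, best_rss = sol, rss

        names = ("dg1", "m1", "dg2", "m2", "a_n", "b_n", "a_u", "b_u", "z_i")
        return ChemicalUnfoldingResults._from_least_squares(
            self, best_sol, names, n_states=3, ydata=y
        )

    def fit(self) -> "ChemicalUnfoldingResults":
        return self._fit_two() if self.n_states == 2 else self._fit_three()


class ChemicalUnfoldingResults:
    """Estimates, uncertainties and diagnostics from a chemical-unfolding fit."""

    def __init__(self, model: ChemicalUnfolding, out: lmfit.model.ModelResult, n_states: int):
        self.model = model
        self.n_states = n_states
        self.converged = bool(out.success)
        self.nobs = int(out.ndata)
        self._residual = np.asarray(out.residual, dtype=float)
        self.rss = float(np.sum(self._residual**2))
        self._ydata = np.asarray(out.data, dtype=float)
        self.k_free = len([p for p in out.params.values() if p.vary])
        names2 = ("dg_h2o", "m_value", "a_n", "b_n", "a_u", "b_u")
        names3 = ("dg1", "m1", "dg2", "m2", "a_n", "b_n", "a_u", "b_u", "z_i")
        names = names2 if n_states == 2 else names3
        if self.converged:
            vals = {n: out.params[n].value for n in names}
            self.params = ChemParams2(**vals) if n_states == 2 else ChemParams3(**vals)
            self.bse = {
                n: (float(out.params[n].stderr) if out.params[n].stderr is not None else np.nan)
                for n in names
            }
        else:
            self.params = None
            self.bse = {n: np.nan for n in names}

    @classmethod
    def _from_least_squares(cls, model, sol, names, n_states, ydata):
        """Build results from a scipy ``least_squares`` solution; standard
        errors come from the jacobian at the optimum."""
        self = object.__new__(cls)
        self.model = model
        self.n_states = n_states
        self.converged = bool(sol.success)
        self._residual = np.asarray(sol.fun, dtype=float)
        self._ydata = np.asarray(ydata, dtype=float)
        self.nobs = self._residual.size
        self.rss = float(np.sum(self._residual**2))
        self.k_free = len(names)
        if self.converged:
            vals = dict(zip(names, (float(v) for v in sol.x)))
            self.params = ChemParams2(**vals) if n_states == 2 else ChemParams3(**vals)
            dof = max(self.nobs - self.k_free, 1)
            s2 = self.rss / dof
            jtj = sol.jac.T @ sol.jac
            try:
                cov = s2 * np.linalg.pinv(jtj)
                se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            except np.linalg.LinAlgError:
                se = np.full(len(names), np.nan)
            self.bse = dict(zip(names, (float(v) for v in se)))
        else:
            self.params = None
            self.bse = {n: np.nan for n in names}
        return self

    @property
    def rsquared(self) -> float:
        ss_tot = float(np.sum((self._ydata - self._ydata.mean()) ** 2))
        if ss_tot == 0:
            return 1.0 if self.rss == 0 else 0.0
        return 1.0 - self.rss / ss_tot

    def predict(self, D=None) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("fit did not converge; parameters withheld")
        if D is None:
            D = self.model.curve.denaturant
        fn = two_state_model if self.n_states == 2 else three_state_model
        return fn(D, self.params)

    def outlier_mask(self, threshold: float = 3.5) -> np.ndarray:
        """Flag residual outliers (|standardized residual| > threshold).

        Intended as a diagnostic for anomalous signal excursions such as
        the transient fluorescence collapse EphB3 shows near 1 M GdnHCl;
        flagged points are reported, never removed or modeled.
        """
        r = self._residual
        sd = np.std(r, ddof=min(self.k_free, r.size - 1))
        if sd == 0:
            return np.zeros_like(r, dtype=bool)
        return np.abs(r / sd) > threshold

    def summary(self) -> str:
        head = f"{self.n_states}-state chemical unfolding"
        lines = [head,
                 f"  sample: {self.model.curve.sample_id or '<unnamed>'}"
                 f"   n = {self.nobs}   converged = {self.converged}"]
        if self.converged and self.n_states == 2:
            lines += [
                f"  dG_H2O = {self.params.dg_h2o:8.2f} ± {self.bse['dg_h2o']:.2f} kJ/mol",
                f"  m      = {self.params.m_value:8.2f} ± {self.bse['m_value']:.2f} kJ/mol/M",
                f"  Cm     = {self.params.cm:8.3f} M",
            ]
        elif self.converged:
            lines += [
                f"  dG1 = {self.params.dg1:8.2f} kJ/mol   m1 = {self.params.m1:6.2f}",
                f"  dG2 = {self.params.dg2:8.2f} kJ/mol   m2 = {self.params.m2:6.2f}",
                f"  z_i = {self.params.z_i:6.3f}",
            ]
        if self.converged:
            lines.append(f"  RSS = {self.rss:.4g}   R² = {self.rsquared:.5f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.denaturant, c.fluorescence, "o", ms=3, label="data")
        if self.converged:
            grid = np.linspace(c.denaturant[0], c.denaturant[-1], 300)
            ax.plot(grid, self.predict(grid), "-", label=f"{self.n_states}-state fit")
        ax.set_xlabel("GdnHCl (M)")
        ax.set_ylabel("fluorescence at 345 nm")
        ax.legend()
        return ax


def fit_chemical(curve: DenaturationCurve, model: str = "two") -> ChemicalUnfoldingResults:
    """Fit *curve* with the ``"two"``- or ``"three"``-state model."""
    n = {"two": 2, "three": 3, "2": 2, "3": 3}.get(str(model))
    if n is None:
        raise ValueError(f"unknown model {model!r}; expected 'two' or 'three'")
    return ChemicalUnfolding(curve, n_states=n).fit()


def pool_replicates(curves) -> DenaturationCurve:
    """Pointwise mean of replicate titrations sharing one denaturant grid."""
    curves = list(curves)
    D0 = curves[0].denaturant
    for c in curves[1:]:
        if not np.allclose(c.denaturant, D0):
            raise ValueError("replicates must share the denaturant grid to be pooled")
    y = np.mean([c.fluorescence for c in curves], axis=0)
    return DenaturationCurve(D0, y, sample_id=curves[0].sample_id,
                             metadata={"pooled_from": len(curves)})


# ---------------------------------------------------------------------------
# model selection


def aicc(rss: float, n: int, k_free: int) -> float:
    """Small-sample-corrected Akaike criterion for a least-squares fit.

    ``k = k_free + 1`` counts the fitted parameters plus the error
    variance: AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1).
    """
    k = k_free + 1
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for k={k} parameters")
    if rss <= 0:
        rss = np.finfo(float).tiny
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass(frozen=True)
class ModelComparison:
    """AICc values and Akaike-weight probabilities (percent) for the
    two- vs three-state comparison; probabilities sum to 100."""

    aicc_two: float
    aicc_three: float
    prob_two: float
    prob_three: float

    @property
    def preferred(self) -> str:
        return "three-state" if self.prob_three > self.prob_two else "two-state"


def compare_models(fit2: ChemicalUnfoldingResults,
                   fit3: ChemicalUnfoldingResults) -> ModelComparison:
    """Akaike-weight comparison of two- and three-state fits of one dataset."""
    if fit2.n_states != 2 or fit3.n_states != 3:
        raise ValueError("compare_models expects (two-state fit, three-state fit)")
    if fit2.nobs != fit3.nobs:
        raise ValueError("fits must be on the same data (unequal n)")
    a2 = aicc(fit2.rss, fit2.nobs, fit2.k_free)
    a3 = aicc(fit3.rss, fit3.nobs, fit3.k_free)
    amin = min(a2, a3)
    w2 = np.exp(-(a2 - amin) / 2.0)
    w3 = np.exp(-(a3 - amin) / 2.0)
    tot = w2 + w3
    return ModelComparison(a2, a3, 100.0 * w2 / tot, 100.0 * w3 / tot)
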