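"""Two-state van't Hoff thermal unfolding and DSF melt analysis.

The core model is the six-parameter equilibrium unfolding curve used for
CD melts monitored at 222 nm.  With temperatures converted to kelvin
inside the exponential, the folded↔unfolded equilibrium constant is

    K(T) = exp[ −ΔHm · (1 − T/Tm) / (R·T) ]        (T, Tm in kelvin)

and the observed signal is a population-weighted average of two linear
baselines (written against temperature in °C, matching the plotted axis):

    Y(T) = [ (a_n + b_n·T) + (a_u + b_u·T) · K(T) ] / (1 + K(T))

so the fraction unfolded f = K/(1+K) is exactly 1/2 at T = Tm, and ΔHm
(kJ/mol) is the van't Hoff enthalpy at the midpoint.  No heat-capacity
term is included (ΔCp fixed at 0).

DSF melts are handled by a Boltzmann sigmoid with the same linear
pre/post baselines; its inflection point is reported as the DSF Tm, and
``delta_tm`` measures ligand-induced thermal shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .constants import R_GAS
from .data import MeltCurve

__all__ = [
    "ThermalParams",
    "ThermalUnfolding",
    "ThermalUnfoldingResults",
    "NoTransitionError",
    "thermal_model",
    "fraction_unfolded",
    "fit_thermal",
    "dsf_tm",
    "delta_tm",
]

_KELVIN = 273.15


class NoTransitionError(ValueError):
    """Raised when a melt trace contains no detectable unfolding transition."""


@dataclass(frozen=True)
class ThermalParams:
    """Six parameters of the van't Hoff melt curve.

    tm: midpoint of unfolding, °C.  dhm: van't Hoff enthalpy at Tm, kJ/mol
    (positive for an unfolding transition).  a_n/b_n and a_u/b_u:
    intercept and slope of the folded and unfolded baselines (signal
    units, signal units per °C).
    """

    tm: float
    dhm: float
    a_n: float = 1.0
    b_n: float = 0.0
    a_u: float = 0.0
    b_u: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.tm, self.dhm, self.a_n, self.b_n, self.a_u, self.b_u]
        if not np.all(np.isfinite(vals)):
            raise ValueError("thermal parameters must be finite")


def fraction_unfolded(T, tm: float, dhm: float) -> np.ndarray:
    """Fraction unfolded f(T) = K/(1+K) for the two-state transition.

    Computed through the log-odds for numerical stability far from Tm.
    """
    T = np.asarray(T, dtype=float)
    if not (np.isfinite(tm) and np.isfinite(dhm)):
        raise ValueError("tm and dhm must be finite")
    TK = T + _KELVIN
    TmK = tm + _KELVIN
    lnK = -dhm * 1e3 * (1.0 - TK / TmK) / (R_GAS * TK)
    # f = K/(1+K) = expit(lnK)
    from scipy.special import expit

    return expit(lnK)


def thermal_model(T, params: ThermalParams) -> np.ndarray:
    """Evaluate the six-parameter melt curve at temperatures T (°C)."""
    T = np.asarray(T, dtype=float)
    f = fraction_unfolded(T, params.tm, params.dhm)
    y_n = params.a_n + params.b_n * T
    y_u = params.a_u + params.b_u * T
    return y_n * (1.0 - f) + y_u * f


def _model_func(T, tm, dhm, a_n, b_n, a_u, b_u):
    f = fraction_unfolded(T, tm, dhm)
    return (a_n + b_n * T) * (1.0 - f) + (a_u + b_u * T) * f


def _boltzmann_func(T, tm, width, a_n, b_n, a_u, b_u):
    from scipy.special import expit

    f = expit((T - tm) / width)
    return (a_n + b_n * T) * (1.0 - f) + (a_u + b_u * T) * f


def _smooth(y: np.ndarray, window: int = 5) -> np.ndarray:
    if y.size < window:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def _edge_baselines(T: np.ndarray, y: np.ndarray, frac: float = 0.15):
    """OLS lines through the outer *frac* of the temperature span.

    Returns ((a_n, b_n), (a_u, b_u), noise_sd) with noise_sd the pooled
    residual standard deviation of the two edge fits.
    """
    span = T[-1] - T[0]
    lo = T <= T[0] + frac * span
    hi = T >= T[-1] - frac * span
    res_all = []
    coefs = []
    for mask in (lo, hi):
        b, a = np.polyfit(T[mask], y[mask], 1)
        coefs.append((a, b))
        res_all.append(y[mask] - (a + b * T[mask]))
    noise = float(np.std(np.concatenate(res_all)))
    return coefs[0], coefs[1], noise


class ThermalUnfolding:
    """Model object for the six-parameter van't Hoff melt fit.

    Parameters
    ----------
    curve : MeltCurve
        The melt trace to fit.  The trace must span the transition; a
        flat or featureless trace raises :class:`NoTransitionError` at
        fit time.

    The fit is performed on the raw (unnormalized) signal — the linear
    baselines absorb any multiplicative scale, so Tm and ΔHm estimates
    are scale-equivariant.  Initialization is deterministic: Tm from the
    extreme slope of a lightly smoothed trace, baselines from the outer
    15% of the temperature range, and ΔHm from the apparent transition
    width through the van't Hoff width relation.
    """

    def __init__(self, curve: MeltCurve):
        self.curve = curve

    @classmethod
    def from_arrays(cls, temperature, signal, modality: str = "CD") -> "ThermalUnfolding":
        return cls(MeltCurve(temperature, signal, modality=modality))

    # -- initialization -----------------------------------------------------

    def _initial_guess(self) -> ThermalParams:
        T = self.curve.temperature
        y = _smooth(self.curve.signal)
        (a_n0, b_n0), (a_u0, b_u0), noise = _edge_baselines(T, y)
        dy = np.gradient(y, T)
        interior = slice(2, T.size - 2)
        i0 = interior.start + int(np.argmax(np.abs(dy[interior])))
        tm0 = float(T[i0])

        amp = abs((a_u0 + b_u0 * tm0) - (a_n0 + b_n0 * tm0))
        scale = float(np.ptp(self.curve.signal))
        if amp <= max(5.0 * noise, 1e-3 * scale, 1e-12):
            raise NoTransitionError(
                "no transition detected: baseline separation is within noise"
            )

        # apparent 10–90% width → van't Hoff enthalpy, ΔHm ≈ R·Tm²·ln81/width
        fapp = ((a_n0 + b_n0 * T) - y) / ((a_n0 + b_n0 * T) - (a_u0 + b_u0 * T))
        fapp = np.clip(fapp, 0.0, 1.0)
        try:
            t10 = T[np.argmax(fapp >= 0.1)]
            t90 = T[np.argmax(fapp >= 0.9)]
            width = float(t90 - t10)
        except ValueError:
            width = 0.0
        TmK = tm0 + _KELVIN
        if width > 0.5:
            dhm0 = R_GAS * TmK**2 * np.log(81.0) / width / 1e3
        else:
            dhm0 = 300.0
        dhm0 = float(np.clip(dhm0, 20.0, 1500.0))
        return ThermalParams(tm0, dhm0, a_n0, b_n0, a_u0, b_u0)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "ThermalUnfoldingResults":
        start = self._initial_guess()
        T = self.curve.temperature
        y = self.curve.signal
        model = lmfit.Model(_model_func, independent_vars=["T"])
        p = model.make_params(
            tm=dict(value=start.tm, min=float(T[0]), max=float(T[-1])),
            dhm=dict(value=start.dhm, min=1.0, max=3000.0),
            a_n=start.a_n,
            b_n=start.b_n,
            a_u=start.a_u,
            b_u=start.b_u,
        )
        out = model.fit(y, p, T=T)
        return ThermalUnfoldingResults(self, out)


class ThermalUnfoldingResults:
    """Estimates and diagnostics from a :class:`ThermalUnfolding` fit."""

    _names = ("tm", "dhm", "a_n", "b_n", "a_u", "b_u")

    def __init__(self, model: ThermalUnfolding, out: lmfit.model.ModelResult):
        self.model = model
        self._out = out
        self.converged = bool(out.success)
        self.nobs = int(out.ndata)
        self.rss = float(np.sum(out.residual**2))
        if self.converged:
            self.params = ThermalParams(**{n: out.params[n].value for n in self._names})
            self.bse = {
                n: (float(out.params[n].stderr) if out.params[n].stderr is not None else np.nan)
                for n in self._names
            }
        else:  # parameters withheld on non-convergence
            self.params = None
            self.bse = {n: np.nan for n in self._names}

    @property
    def tm(self) -> float:
        self._require_converged()
        return self.params.tm

    @property
    def dhm(self) -> float:
        self._require_converged()
        return self.params.dhm

    @property
    def rsquared(self) -> float:
        return float(self._out.rsquared)

    def _require_converged(self) -> None:
        if not self.converged:
            raise RuntimeError("fit did not converge; parameters withheld")

    def predict(self, T=None) -> np.ndarray:
        self._require_converged()
        if T is None:
            T = self.model.curve.temperature
        return thermal_model(T, self.params)

    def fraction_unfolded(self, T=None) -> np.ndarray:
        """Baseline-normalized unfolded fraction (for plotting)."""
        self._require_converged()
        if T is None:
            T = self.model.curve.temperature
        return fraction_unfolded(T, self.params.tm, self.params.dhm)

    def summary(self) -> str:
        lines = [
            "Two-state van't Hoff thermal unfolding",
            f"  sample: {self.model.curve.sample_id or '<unnamed>'}"
            f"   n = {self.nobs}   converged = {self.converged}",
        ]
        if self.converged:
            lines += [
                f"  Tm   = {self.params.tm:9.3f} ± {self.bse['tm']:.3f} °C",
                f"  dHm  = {self.params.dhm:9.2f} ± {self.bse['dhm']:.2f} kJ/mol",
                f"  folded baseline:   {self.params.a_n:.4g} + {self.params.b_n:.4g}·T",
                f"  unfolded baseline: {self.params.a_u:.4g} + {self.params.b_u:.4g}·T",
                f"  RSS = {self.rss:.4g}   R² = {self.rsquared:.5f}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.temperature, c.signal, "o", ms=3, label="data")
        if self.converged:
            tgrid = np.linspace(c.temperature[0], c.temperature[-1], 300)
            ax.plot(tgrid, self.predict(tgrid), "-", label="fit")
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel(f"signal ({c.modality})")
        ax.legend()
        return ax


def fit_thermal(curve: MeltCurve) -> ThermalUnfoldingResults:
    """Convenience wrapper: fit the six-parameter melt model to *curve*."""
    return ThermalUnfolding(curve).fit()


# ---------------------------------------------------------------------------
# DSF


class BoltzmannMelt:
    """Boltzmann sigmoid with linear baselines, for DSF melt traces."""

    def __init__(self, curve: MeltCurve):
        if curve.modality != "DSF":
            raise ValueError("BoltzmannMelt expects a DSF-modality curve")
        self.curve = curve

    def fit(self) -> "ThermalUnfoldingResults":
        T = self.curve.temperature
        y = self.curve.signal
        ys = _smooth(y)
        (a_n0, b_n0), (a_u0, b_u0), noise = _edge_baselines(T, ys)
        dy = np.gradient(ys, T)
        interior = slice(2, T.size - 2)
        i0 = interior.start + int(np.argmax(dy[interior]))
        tm0 = float(T[i0])
        amp = (a_u0 + b_u0 * tm0) - (a_n0 + b_n0 * tm0)
        scale = float(np.ptp(y))
        if amp <= max(5.0 * noise, 1e-3 * scale, 1e-12):
            raise NoTransitionError(
                "no rising transition detected in DSF trace "
                "(monotone-decreasing or flat signal)"
            )
        model = lmfit.Model(_boltzmann_func, independent_vars=["T"])
        p = model.make_params(
            tm=dict(value=tm0, min=float(T[0]), max=float(T[-1])),
            width=dict(value=2.0, min=0.05, max=30.0),
            a_n=a_n0,
            b_n=b_n0,
            a_u=a_u0,
            b_u=b_u0,
        )
        out = model.fit(y, p, T=T)
        res = object.__new__(ThermalUnfoldingResults)
        res.model = self
        res._out = out
        res.converged = bool(out.success)
        res.nobs = int(out.ndata)
        res.rss = float(np.sum(out.residual**2))
        res.params = None
        res.bse = {}
        if res.converged:
            res.bse = {
                n: (float(out.params[n].stderr) if out.params[n].stderr is not None else np.nan)
                for n in ("tm", "width", "a_n", "b_n", "a_u", "b_u")
            }
        res.__class__ = BoltzmannMeltResults
        return res


class BoltzmannMeltResults(ThermalUnfoldingResults):
    """Results of a DSF Boltzmann melt fit; ``tm`` is the inflection point."""

    @property
    def tm(self) -> float:
        self._require_converged()
        return float(self._out.params["tm"].value)

    @property
    def dhm(self) -> float:
        raise AttributeError("a Boltzmann DSF fit has no van't Hoff enthalpy")

    def _require_converged(self) -> None:
        if not self.converged:
            raise RuntimeError("fit did not converge; parameters withheld")

    def predict(self, T=None) -> np.ndarray:
        self._require_converged()
        if T is None:
            T = self.model.curve.temperature
        vals = {n: self._out.params[n].value for n in self._out.params}
        return _boltzmann_func(np.asarray(T, dtype=float), **vals)

    def summary(self) -> str:
        lines = [
            "Boltzmann DSF melt",
            f"  sample: {self.model.curve.sample_id or '<unnamed>'}"
            f"   n = {self.nobs}   converged = {self.converged}",
        ]
        if self.converged:
            lines.append(
                f"  Tm = {self.tm:9.3f} ± {self.bse.get('tm', float('nan')):.3f} °C"
            )
        return "\n".join(lines)


def dsf_tm(curve: MeltCurve) -> float:
    """DSF melting temperature: inflection of a Boltzmann sigmoid fit (°C)."""
    res = BoltzmannMelt(curve).fit()
    if not res.converged:
        raise RuntimeError("DSF melt fit did not converge")
    return res.tm


def delta_tm(apo: MeltCurve, holo: MeltCurve) -> float:
    """Compound-induced thermal shift ΔTm = Tm(holo) − Tm(apo), in °C.

    DSF curves are fitted with the Boltzmann sigmoid, CD curves with the
    van't Hoff model; both curves must share a modality.
    """
    if apo.modality != holo.modality:
        raise ValueError("apo and holo curves must share a modality")
    if apo.modality == "DSF":
        return dsf_tm(holo) - dsf_tm(apo)
    fa, fh = fit_thermal(apo), fit_thermal(holo)
    return fh.tm - fa.tm
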