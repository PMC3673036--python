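"""Steady-state enzyme kinetics: initial rates, Michaelis–Menten fits and
turnover-number bookkeeping.

Initial velocities are extracted from stopped-assay luminescence time
courses as the ordinary-least-squares slope of the longest initial
window whose linear fit has R² ≥ 0.99 (≥ 4 points including t = 0),
which keeps substrate depletion out of the rate estimate.  Rates are
calibrated to nmol ADP·min⁻¹ and scaled per mg enzyme, then fitted to

    v(S) = Vmax · S / (Km + S)

by nonlinear least squares.  The turnover number follows from the
specific activity and construct molar mass:

    kcat [s⁻¹] = Vmax [nmol·min⁻¹·mg⁻¹] · M [g/mol] / 6×10⁷

and kcat/Km (s⁻¹·μM⁻¹) is the specificity constant used to compare
enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .data import EnzymeSpec, KineticsDataset

__all__ = [
    "EnzymeSpec",
    "InitialRate",
    "initial_rate",
    "mm_rate",
    "MichaelisMenten",
    "MMResults",
    "kcat_from_vmax",
    "vmax_from_kcat",
    "specificity_table",
]


@dataclass(frozen=True)
class InitialRate:
    """Slope (signal units/min) of the accepted initial-linear window."""

    slope: float
    n_points: int
    r_squared: float


def _ols_line(t: np.ndarray, y: np.ndarray):
    b, a = np.polyfit(t, y, 1)
    resid = y - (a + b * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    scale = max(float(np.abs(y).max()), 1.0)
    if ss_tot < (1e-9 * scale) ** 2:
        # constant signal: a zero-slope line is an exact description
        r2 = 1.0 if ss_res < (1e-9 * scale) ** 2 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(b), r2


def initial_rate(time, signal, r2_min: float = 0.99, min_points: int = 4) -> InitialRate:
    """Initial velocity from a time course, in signal units per minute.

    Scans windows anchored at t = 0 from the full course downward and
    returns the slope of the longest window whose linear fit reaches
    ``r2_min``.  Raises ``ValueError("nonlinear time course")`` when no
    window of ``min_points`` qualifies.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size != y.size or t.size < min_points:
        raise ValueError(f"need at least {min_points} time points")
    if not np.isclose(t[0], 0.0):
        raise ValueError("time course must start at t=0")
    for j in range(t.size, min_points - 1, -1):
        slope, r2 = _ols_line(t[:j], y[:j])
        if r2 >= r2_min:
            return InitialRate(slope, j, r2)
    raise ValueError("nonlinear time course: no initial window reaches R² ≥ "
                     f"{r2_min}")


def mm_rate(S, km: float, vmax: float) -> np.ndarray:
    """Michaelis–Menten velocity v = Vmax·S/(Km+S)."""
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S)


def kcat_from_vmax(vmax: float, molar_mass: float) -> float:
    """Turnover number (s⁻¹) from specific activity (nmol·min⁻¹·mg⁻¹)."""
    if vmax < 0 or molar_mass <= 0:
        raise ValueError("vmax must be ≥ 0 and molar_mass > 0")
    return vmax * molar_mass / 6e7


def vmax_from_kcat(kcat: float, molar_mass: float) -> float:
    """Specific activity (nmol·min⁻¹·mg⁻¹) from turnover number (s⁻¹)."""
    if kcat < 0 or molar_mass <= 0:
        raise ValueError("kcat must be ≥ 0 and molar_mass > 0")
    return kcat * 6e7 / molar_mass


def _mm_func(S, km, vmax):
    return vmax * S / (km + S)


class MichaelisMenten:
    """Michaelis–Menten model for calibrated initial-rate data.

    Parameters
    ----------
    concentrations : array
        Varied-substrate concentrations (μM for ATP, μg/ml for
        poly-(Glu:Tyr)); at least 6 points spanning below and above Km.
    rates : array
        Specific activities in nmol·min⁻¹·mg⁻¹ (use
        :meth:`from_dataset` to calibrate raw time courses).
    enzyme : EnzymeSpec, optional
        Supplies the molar mass for the kcat conversion.
    """

    def __init__(self, concentrations, rates, enzyme: EnzymeSpec | None = None):
        self.conc = np.asarray(concentrations, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.conc.size != self.rates.size:
            raise ValueError("concentrations and rates must have equal length")
        if self.conc.size < 6:
            raise ValueError("need at least 6 substrate concentrations")
        if np.any(self.rates < -1e-9 * max(self.rates.max(), 1.0)):
            raise ValueError("negative rates rejected")
        self.enzyme = enzyme

    @classmethod
    def from_dataset(cls, ds: KineticsDataset) -> "MichaelisMenten":
        """Extract initial rates from time courses and calibrate them.

        Luminescence slopes (units/min) are divided by the calibration
        (units per nmol ADP) and by the per-reaction enzyme mass (mg) to
        give specific activities.
        """
        if ds.enzyme is None:
            raise ValueError("dataset must carry an EnzymeSpec for calibration")
        slopes = np.array(
            [initial_rate(ds.time_points, ds.signal[i]).slope
             for i in range(ds.concentrations.size)]
        )
        specific = slopes / ds.calibration / ds.enzyme.mass_per_reaction_mg
        return cls(ds.concentrations, specific, enzyme=ds.enzyme)

    def fit(self) -> "MMResults":
        vmax0 = float(self.rates.max()) * 1.2 or 1.0
        half = vmax0 / 2.4
        pos = self.conc > 0
        km0 = float(self.conc[pos][np.argmin(np.abs(self.rates[pos] - half))]) \
            if pos.any() else 1.0
        km0 = max(km0, 1e-6)
        model = lmfit.Model(_mm_func, independent_vars=["S"])
        p = model.make_params(
            km=dict(value=km0, min=1e-9),
            vmax=dict(value=vmax0, min=0.0),
        )
        out = model.fit(self.rates, p, S=self.conc)
        return MMResults(self, out)


class MMResults:
    """Km, Vmax and kcat estimates with uncertainties and diagnostics."""

    def __init__(self, model: MichaelisMenten, out: lmfit.model.ModelResult):
        self.model = model
        self._out = out
        self.converged = bool(out.success)
        self.nobs = int(out.ndata)
        self.km = float(out.params["km"].value)
        self.vmax = float(out.params["vmax"].value)
        self.bse = {
            n: (float(out.params[n].stderr) if out.params[n].stderr is not None else np.nan)
            for n in ("km", "vmax")
        }
        self.rss = float(np.sum(out.residual**2))
        self.warnings: list[str] = []
        if model.conc.max() < self.km:
            self.warnings.append("Km poorly constrained: top concentration below Km estimate")

    @property
    def rsquared(self) -> float:
        return float(self._out.rsquared)

    @property
    def kcat(self) -> float:
        """Turnover number in s⁻¹ (requires an EnzymeSpec)."""
        if self.model.enzyme is None:
            raise AttributeError("kcat needs an EnzymeSpec with a molar mass")
        return kcat_from_vmax(self.vmax, self.model.enzyme.molar_mass)

    @property
    def specificity(self) -> float:
        """Specificity constant kcat/Km in s⁻¹·μM⁻¹."""
        return self.kcat / self.km

    def predict(self, S=None) -> np.ndarray:
        if S is None:
            S = self.model.conc
        return mm_rate(S, self.km, self.vmax)

    def summary(self) -> str:
        name = self.model.enzyme.name if self.model.enzyme else "<enzyme>"
        lines = [
            "Michaelis–Menten fit",
            f"  enzyme: {name}   n = {self.nobs}   converged = {self.converged}",
            f"  Km   = {self.km:9.1f} ± {self.bse['km']:.1f}",
            f"  Vmax = {self.vmax:9.1f} ± {self.bse['vmax']:.1f} nmol/min/mg",
        ]
        if self.model.enzyme is not None:
            lines.append(f"  kcat = {self.kcat:9.3f} s⁻¹   kcat/Km = {self.specificity:.5f}")
        lines.append(f"  R² = {self.rsquared:.5f}")
        for w in self.warnings:
            lines.append(f"  WARNING: {w}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.conc, self.model.rates, "o", label="rates")
        grid = np.linspace(0, self.model.conc.max(), 200)
        ax.plot(grid, self.predict(grid), "-", label="MM fit")
        ax.set_xlabel("substrate")
        ax.set_ylabel("v (nmol/min/mg)")
        ax.legend()
        return ax


def specificity_table(fits: dict) -> pd.DataFrame:
    """Specificity constants kcat/Km per enzyme plus the max/min fold-spread.

    *fits* maps enzyme name → :class:`MMResults` or ``(kcat, km)`` tuple.
    The returned frame has columns ``kcat, km, specificity`` and carries
    ``df.attrs['fold_spread']`` = max/min of the specificity constants.
    """
    if len(fits) < 2:
        raise ValueError("need at least two enzymes to compare")
    rows = {}
    for name, fit in fits.items():
        if isinstance(fit, MMResults):
            kcat, km = fit.kcat, fit.km
        else:
            kcat, km = fit
        rows[name] = {"kcat": kcat, "km": km, "specificity": kcat / km}
    df = pd.DataFrame.from_dict(rows, orient="index")
    spec = df["specificity"]
    df.attrs["fold_spread"] = float(spec.max() / spec.min())
    return df
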