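"""Inhibitor dose-response profiling: plate normalization and 4PL IC50 fits.

Compounds are dosed over 12 points — 11 half-log steps down from the top
dose, then one whole-log step — and each plate carries ≥ 11 max (DMSO,
0% inhibition) and min (fully inhibited, 100%) control wells.  Raw
luminescence is normalized to percent inhibition against the control
means, and the pooled points are fitted with a four-parameter logistic

    inhibition(c) = bottom + (top − bottom) / (1 + (IC50/c)^hill)

so the fitted IC50 is exactly the concentration at the top/bottom
midpoint.  Curves that never reach 50% inhibition inside the dose window
are reported as bounds ("> top dose") rather than extrapolated; IC50
estimates at or below twice the assay's tight-binding floor (~25 nM) are
flagged as unresolvable in potency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import lmfit

from .data import DoseResponsePlate

__all__ = [
    "dose_series",
    "normalize",
    "four_param_logistic",
    "DoseResponse",
    "IC50Results",
    "fit_ic50",
    "selectivity_report",
    "TIGHT_BINDING_LIMIT_UM",
]

#: assay potency floor, μM (≈ half the in-reaction enzyme concentration)
TIGHT_BINDING_LIMIT_UM = 0.025


def dose_series(top: float) -> np.ndarray:
    """The 12-point dosing scheme from a top dose (μM), decreasing.

    Points 1–11 step down by half-log intervals (×10^−1/2); point 12 is a
    whole log below point 11.
    """
    if top <= 0:
        raise ValueError("top dose must be positive")
    c = top * 10.0 ** (-0.5 * np.arange(11))
    return np.append(c, c[-1] / 10.0)


def normalize(plate: DoseResponsePlate) -> np.ndarray:
    """Percent inhibition per sample well, anchored on the control means.

    0% at the max-control mean (uninhibited), 100% at the min-control
    mean.  Returns an array shaped like ``plate.raw_signal``.
    """
    mean_max = float(plate.max_controls.mean())
    mean_min = float(plate.min_controls.mean())
    if mean_max <= mean_min:
        raise ValueError(
            "degenerate controls: max-control mean must exceed min-control mean"
        )
    return 100.0 * (mean_max - plate.raw_signal) / (mean_max - mean_min)


def four_param_logistic(c, ic50: float, hill: float = 1.0,
                        top: float = 100.0, bottom: float = 0.0) -> np.ndarray:
    """4PL inhibition curve; monotone increasing in c for hill > 0."""
    c = np.asarray(c, dtype=float)
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    with np.errstate(divide="ignore"):
        logratio = np.where(c > 0, np.log(ic50) - np.log(c), np.inf)
    frac = np.where(np.isinf(logratio), 0.0,
                    1.0 / (1.0 + np.exp(hill * np.where(np.isinf(logratio), 0.0, logratio))))
    return bottom + (top - bottom) * frac


def _fpl_func(c, lg_ic50, hill, top, bottom):
    return four_param_logistic(c, 10.0**lg_ic50, hill, top, bottom)


class DoseResponse:
    """4PL dose-response model on normalized percent-inhibition data.

    Build from pooled ``(concentration, inhibition)`` points, or from a
    plate via :meth:`from_plate` (which normalizes against the controls
    and pools replicate wells into a single fit).
    """

    def __init__(self, concentrations, inhibition,
                 compound: str = "", enzyme: str = ""):
        self.conc = np.asarray(concentrations, dtype=float)
        self.inhibition = np.asarray(inhibition, dtype=float)
        if self.conc.size != self.inhibition.size:
            raise ValueError("concentration and inhibition lengths differ")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")
        self.compound = compound
        self.enzyme = enzyme

    @classmethod
    def from_plate(cls, plate: DoseResponsePlate) -> "DoseResponse":
        inh = normalize(plate)
        n_rep = inh.shape[0]
        conc = np.tile(plate.concentrations, n_rep)
        return cls(conc, inh.ravel(), compound=plate.compound, enzyme=plate.enzyme)

    def fit(self) -> "IC50Results":
        lg = np.log10(self.conc)
        mid = 0.5 * (self.inhibition.max() + self.inhibition.min())
        lg0 = float(lg[np.argmin(np.abs(self.inhibition - mid))])
        model = lmfit.Model(_fpl_func, independent_vars=["c"])
        p = model.make_params(
            lg_ic50=dict(value=lg0, min=lg.min() - 3.0, max=lg.max() + 3.0),
            hill=dict(value=1.0, min=1e-3, max=5.0),
            top=dict(value=float(self.inhibition.max()), min=-50.0, max=200.0),
            bottom=dict(value=float(self.inhibition.min()), min=-100.0, max=150.0),
        )
        out = model.fit(self.inhibition, p, c=self.conc)
        return IC50Results(self, out)


class IC50Results:
    """Fitted 4PL parameters, R², and in-window/bound status."""

    def __init__(self, model: DoseResponse, out: lmfit.model.ModelResult):
        self.model = model
        self._out = out
        self.converged = bool(out.success)
        self.nobs = int(out.ndata)
        self.ic50 = float(10.0 ** out.params["lg_ic50"].value)
        self.hill = float(out.params["hill"].value)
        self.top = float(out.params["top"].value)
        self.bottom = float(out.params["bottom"].value)
        self.rss = float(np.sum(out.residual**2))
        self.top_dose = float(model.conc.max())
        # does the fitted curve reach 50% absolute inhibition in-window?
        pred_top = four_param_logistic(self.top_dose, self.ic50, self.hill,
                                       self.top, self.bottom)
        self.censored = bool(pred_top < 50.0)
        self.tight_binding = bool(self.ic50 <= 2.0 * TIGHT_BINDING_LIMIT_UM)

    @property
    def rsquared(self) -> float:
        return float(self._out.rsquared)

    @property
    def value(self) -> float:
        """Point estimate in μM; RuntimeError when only a bound is known."""
        if self.censored:
            raise RuntimeError(f"IC50 > top dose; only the bound {self.bound!r} is known")
        return self.ic50

    @property
    def bound(self) -> str | None:
        """``'> <top dose>'`` when the curve stays under 50% in-window."""
        return f"> {self.top_dose:g}" if self.censored else None

    def predict(self, c=None) -> np.ndarray:
        if c is None:
            c = self.model.conc
        return four_param_logistic(c, self.ic50, self.hill, self.top, self.bottom)

    def summary(self) -> str:
        label = self.bound if self.censored else f"{self.ic50:.4g} μM"
        lines = [
            "Four-parameter logistic dose-response fit",
            f"  compound: {self.model.compound or '<compound>'}"
            f"   enzyme: {self.model.enzyme or '<enzyme>'}   n = {self.nobs}",
            f"  IC50 = {label}   hill = {self.hill:.3f}",
            f"  top = {self.top:.2f}%   bottom = {self.bottom:.2f}%   R² = {self.rsquared:.4f}",
        ]
        if self.tight_binding:
            lines.append("  WARNING: at/below the assay tight-binding limit (~25 nM); "
                         "potency not resolvable")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.model.conc, self.model.inhibition, "o", ms=4, label="wells")
        grid = np.geomspace(self.model.conc.min(), self.model.conc.max(), 200)
        ax.semilogx(grid, self.predict(grid), "-", label="4PL fit")
        ax.set_xlabel("compound (μM)")
        ax.set_ylabel("inhibition (%)")
        ax.legend()
        return ax


def fit_ic50(concentrations, inhibition, **kw) -> IC50Results:
    """Convenience wrapper: 4PL fit of a percent-inhibition series."""
    return DoseResponse(concentrations, inhibition, **kw).fit()


def selectivity_report(fits: dict) -> pd.DataFrame:
    """Fold-selectivity table across enzymes for each compound.

    *fits* maps compound → {enzyme → IC50Results or float μM}.  Each
    enzyme's IC50 is expressed as a fold over the most potently
    inhibited enzyme for that compound.  Censored fits propagate as
    lower bounds (``is_lower_bound`` True).
    """
    rows = []
    for compound, per_enzyme in fits.items():
        vals = {}
        bounds = {}
        for enzyme, fit in per_enzyme.items():
            if isinstance(fit, IC50Results):
                vals[enzyme] = fit.ic50
                bounds[enzyme] = fit.censored
            else:
                vals[enzyme] = float(fit)
                bounds[enzyme] = False
        if len(vals) < 2:
            raise ValueError(f"compound {compound!r}: need ≥ 2 enzymes")
        uncensored = {e: v for e, v in vals.items() if not bounds[e]}
        ref = min(uncensored.values()) if uncensored else min(vals.values())
        for enzyme, v in vals.items():
            rows.append({
                "compound": compound,
                "enzyme": enzyme,
                "ic50_uM": v,
                "fold_vs_best": v / ref,
                "is_lower_bound": bounds[enzyme],
            })
    return pd.DataFrame(rows)
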