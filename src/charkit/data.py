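"""Domain data containers and tidy-CSV input/output.

Every analysis stage consumes one of four container types:

* :class:`MeltCurve` — a temperature-indexed optical melt trace (CD
  ellipticity at 222 nm, or DSF fluorescence).
* :class:`DenaturationCurve` — intrinsic tryptophan fluorescence at
  345 nm against GdnHCl molarity.
* :class:`KineticsDataset` — stopped-assay luminescence time courses on
  a substrate-concentration grid.
* :class:`DoseResponsePlate` — a 384-well-style 12-point compound
  titration with max/min control wells.

Containers validate their own invariants on construction and carry a free
``metadata`` dict (used by the synthetic generator to record truth
parameters and seeds).

The tidy curve CSV dialect is one row per observation with columns
``dataset_id, replicate, x, y``; a plain two-column ``(x, y)`` file with a
one-line header is also accepted.  Kinetics and dose-response plates use
the long plate dialects documented on their readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeltCurve",
    "DenaturationCurve",
    "KineticsDataset",
    "DoseResponsePlate",
    "EnzymeSpec",
    "read_curves",
    "write_curves",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "read_plate_csv",
    "write_plate_csv",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class MeltCurve:
    """A thermal melt trace: optical signal vs temperature in °C."""

    temperature: np.ndarray
    signal: np.ndarray
    modality: str = "CD"  # "CD" (mdeg at 222 nm) or "DSF" (fluorescence)
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = _as_float_array(self.temperature, "temperature")
        self.signal = _as_float_array(self.signal, "signal")
        if self.temperature.size != self.signal.size:
            raise ValueError("temperature and signal must have equal length")
        if self.temperature.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperature must be strictly increasing")
        if self.modality not in ("CD", "DSF"):
            raise ValueError(f"unknown modality {self.modality!r}; expected 'CD' or 'DSF'")

    def __len__(self) -> int:
        return self.temperature.size


@dataclass
class DenaturationCurve:
    """A chaotrope titration: fluorescence at 345 nm vs GdnHCl molarity."""

    denaturant: np.ndarray
    fluorescence: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.denaturant = _as_float_array(self.denaturant, "denaturant")
        self.fluorescence = _as_float_array(self.fluorescence, "fluorescence")
        if self.denaturant.size != self.fluorescence.size:
            raise ValueError("denaturant and fluorescence must have equal length")
        if self.denaturant.size < 12:
            raise ValueError("denaturation curve needs at least 12 points")
        if np.any(self.denaturant < 0):
            raise ValueError("denaturant molarity must be non-negative")
        if not np.all(np.diff(self.denaturant) > 0):
            raise ValueError("denaturant must be strictly increasing")

    def __len__(self) -> int:
        return self.denaturant.size


@dataclass(frozen=True)
class EnzymeSpec:
    """Identity and assay bookkeeping for one kinase-domain construct.

    ``molar_mass`` (g/mol) links specific activity (nmol·min⁻¹·mg⁻¹) to
    turnover (s⁻¹).  ``assay_conc`` is the final in-reaction enzyme
    concentration in nM; ``reaction_volume_ul`` the reaction volume in μl.
    """

    name: str
    molar_mass: float
    assay_conc: float = 25.0
    reaction_volume_ul: float = 4.0

    def __post_init__(self) -> None:
        if not 25_000.0 <= self.molar_mass <= 45_000.0:
            raise ValueError(
                f"molar_mass {self.molar_mass} g/mol outside the plausible "
                "range [25000, 45000] for these kinase-domain constructs"
            )
        if self.assay_conc <= 0 or self.reaction_volume_ul <= 0:
            raise ValueError("assay_conc and reaction_volume_ul must be positive")

    @property
    def mass_per_reaction_mg(self) -> float:
        """Enzyme mass per reaction in mg (conc × volume × molar mass)."""
        moles = self.assay_conc * 1e-9 * self.reaction_volume_ul * 1e-6
        return moles * self.molar_mass * 1e3


@dataclass
class KineticsDataset:
    """Stopped-assay luminescence time courses on a concentration grid.

    ``signal`` has shape ``(n_concentrations, n_time_points)`` and is
    proportional to ADP produced; ``calibration`` converts luminescence
    units to nmol ADP.
    """

    varied_substrate: str  # "ATP" (μM) or "polyGT" (μg/ml)
    concentrations: np.ndarray
    time_points: np.ndarray
    signal: np.ndarray
    enzyme: EnzymeSpec | None = None
    calibration: float = 1.0
    fixed_cosubstrate: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = _as_float_array(self.concentrations, "concentrations")
        self.time_points = _as_float_array(self.time_points, "time_points")
        self.signal = np.asarray(self.signal, dtype=float)
        if self.varied_substrate not in ("ATP", "polyGT"):
            raise ValueError("varied_substrate must be 'ATP' or 'polyGT'")
        if self.signal.shape != (self.concentrations.size, self.time_points.size):
            raise ValueError(
                "signal must have shape (n_concentrations, n_time_points); "
                f"got {self.signal.shape}"
            )
        if np.any(self.signal < 0):
            raise ValueError("luminescence signal must be non-negative")
        if not np.isclose(self.time_points.min(), 0.0):
            raise ValueError("time course must include a t=0 point")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive (units per nmol ADP)")


@dataclass
class DoseResponsePlate:
    """A 12-point compound titration with max/min control wells.

    Concentrations are strictly decreasing (half-log dosing from the top
    dose); ``raw_signal`` is ``(n_replicates, 12)`` luminescence.
    Max controls anchor 0% inhibition (DMSO only), min controls 100%
    (fully inhibited, or the designated artificial minimum).
    """

    compound: str
    enzyme: str
    concentrations: np.ndarray
    raw_signal: np.ndarray
    max_controls: np.ndarray
    min_controls: np.ndarray
    dmso_fraction: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = _as_float_array(self.concentrations, "concentrations")
        self.raw_signal = np.atleast_2d(np.asarray(self.raw_signal, dtype=float))
        self.max_controls = _as_float_array(self.max_controls, "max_controls")
        self.min_controls = _as_float_array(self.min_controls, "min_controls")
        if self.concentrations.size != 12:
            raise ValueError("dose-response plates use a 12-point series")
        if not np.all(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be strictly decreasing (top dose first)")
        if self.raw_signal.shape[1] != 12:
            raise ValueError("raw_signal must have 12 columns (one per dose)")
        if self.max_controls.size == 0 or self.min_controls.size == 0:
            raise ValueError("max and min control wells are required")


# ---------------------------------------------------------------------------
# tidy curve CSV


def write_curves(
    curves: Sequence[MeltCurve | DenaturationCurve],
    path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    """Write curves in the tidy dialect ``dataset_id, replicate, x, y``.

    Replicate numbers are taken from each curve's ``metadata['replicate']``
    when present.  If *meta_path* is given, a JSON sidecar with each
    curve's metadata is written alongside.
    """
    rows = []
    meta: dict[str, dict] = {}
    for i, curve in enumerate(curves):
        if isinstance(curve, MeltCurve):
            x, y = curve.temperature, curve.signal
        else:
            x, y = curve.denaturant, curve.fluorescence
        ds = curve.sample_id or f"curve{i}"
        rep = int(curve.metadata.get("replicate", i))
        rows.append(
            pd.DataFrame({"dataset_id": ds, "replicate": rep, "x": x, "y": y})
        )
        meta[f"{ds}/{rep}"] = _jsonable(curve.metadata)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def read_curves(
    path: str | Path,
    kind: str = "melt",
    modality: str = "CD",
) -> list[MeltCurve] | list[DenaturationCurve]:
    """Read tidy or two-column curve CSVs.

    *kind* selects the container: ``"melt"`` → :class:`MeltCurve` (with
    *modality*), ``"denaturation"`` → :class:`DenaturationCurve`.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "dataset_id" not in cols:
        if len(cols) != 2:
            raise ValueError(
                f"{path}: expected tidy (dataset_id, replicate, x, y) or "
                "two-column (x, y) CSV"
            )
        df = df.rename(columns={cols[0]: "x", cols[1]: "y"})
        df["dataset_id"] = Path(path).stem
        df["replicate"] = 0
    out = []
    for (ds, rep), grp in df.groupby(["dataset_id", "replicate"], sort=True):
        grp = grp.sort_values("x")
        meta = {"replicate": int(rep)}
        if kind == "melt":
            out.append(
                MeltCurve(grp["x"].values, grp["y"].values, modality=modality,
                          sample_id=str(ds), metadata=meta)
            )
        elif kind == "denaturation":
            out.append(
                DenaturationCurve(grp["x"].values, grp["y"].values,
                                  sample_id=str(ds), metadata=meta)
            )
        else:
            raise ValueError(f"unknown curve kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# kinetics plate CSV: well, substrate_conc, time_min, signal


def write_kinetics_csv(ds: KineticsDataset, path: str | Path) -> None:
    rows = []
    for i, c in enumerate(ds.concentrations):
        for j, t in enumerate(ds.time_points):
            rows.append((f"c{i:02d}t{j:02d}", c, t, ds.signal[i, j]))
    pd.DataFrame(rows, columns=["well", "substrate_conc", "time_min", "signal"]).to_csv(
        path, index=False
    )


def read_kinetics_csv(
    path: str | Path,
    varied_substrate: str = "ATP",
    enzyme: EnzymeSpec | None = None,
    calibration: float = 1.0,
) -> KineticsDataset:
    df = pd.read_csv(path)
    need = {"substrate_conc", "time_min", "signal"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: kinetics CSV needs columns {sorted(need)}")
    conc = np.sort(df["substrate_conc"].unique())
    times = np.sort(df["time_min"].unique())
    grid = df.pivot_table(index="substrate_conc", columns="time_min",
                          values="signal", aggfunc="mean")
    grid = grid.reindex(index=conc, columns=times)
    if grid.isna().any().any():
        raise ValueError(f"{path}: incomplete concentration × time grid")
    return KineticsDataset(
        varied_substrate=varied_substrate,
        concentrations=conc,
        time_points=times,
        signal=grid.values,
        enzyme=enzyme,
        calibration=calibration,
    )


# ---------------------------------------------------------------------------
# dose-response plate CSV: well, role, conc_uM, signal


def write_plate_csv(plate: DoseResponsePlate, path: str | Path) -> None:
    rows = []
    w = 0
    for r in range(plate.raw_signal.shape[0]):
        for c, s in zip(plate.concentrations, plate.raw_signal[r]):
            rows.append((f"S{w:03d}", "sample", c, s))
            w += 1
    for s in plate.max_controls:
        rows.append((f"MAX{w:03d}", "max_ctrl", np.nan, s))
        w += 1
    for s in plate.min_controls:
        rows.append((f"MIN{w:03d}", "min_ctrl", np.nan, s))
        w += 1
    pd.DataFrame(rows, columns=["well", "role", "conc_uM", "signal"]).to_csv(
        path, index=False
    )


def read_plate_csv(
    path: str | Path, compound: str = "", enzyme: str = ""
) -> DoseResponsePlate:
    df = pd.read_csv(path)
    need = {"well", "role", "conc_uM", "signal"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: plate CSV needs columns {sorted(need)}")
    samples = df[df["role"] == "sample"].copy()
    conc = np.sort(samples["conc_uM"].unique())[::-1]
    reps = []
    for _, grp in samples.groupby(samples.groupby("conc_uM").cumcount()):
        grp = grp.sort_values("conc_uM", ascending=False)
        if grp.shape[0] == conc.size:
            reps.append(grp["signal"].values)
    if not reps:
        raise ValueError(f"{path}: no complete 12-point sample series found")
    return DoseResponsePlate(
        compound=compound or str(df.get("compound", pd.Series([""]))[0]),
        enzyme=enzyme,
        concentrations=conc,
        raw_signal=np.vstack(reps),
        max_controls=df.loc[df["role"] == "max_ctrl", "signal"].values,
        min_controls=df.loc[df["role"] == "min_ctrl", "signal"].values,
    )
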