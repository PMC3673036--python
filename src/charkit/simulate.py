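"""Synthetic instrument-shaped datasets for every analysis stage.

The generator evaluates the forward model owned by each analysis module
(van't Hoff melt, two/three-state chemical unfolding, Michaelis–Menten
time courses, 4PL dose-response plates) on a sampling grid and perturbs
it with seeded Gaussian noise, so the whole pipeline can be exercised
and validated by parameter-recovery experiments without any instrument
data.  Default grids copy the assay protocols: 1 °C pitch from 20–80 °C
for melts, 0–6 M GdnHCl from the two stock buffers, eight reaction time
points from 0–140 min, and 12-point half-log compound dosing.

Noise is additive Gaussian by default (``sigma`` in the signal's own
units); a proportional variant (``sigma`` = coefficient of variation)
is available for luminescence data whose error scales with signal.
Seeds are mandatory — there is no hidden global RNG, and a fixed seed
reproduces datasets bit for bit.

``published_presets()`` returns one runnable recipe per published table row
(4 thermal, 5 kinetics, 35 inhibitor×enzyme cells); ``demo_recipes()``
adds representative chemical-unfolding and DSF conditions for which the
tables print no generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chemical import ChemParams2, ChemParams3, three_state_model, two_state_model
from .data import (DenaturationCurve, DoseResponsePlate, EnzymeSpec,
                   KineticsDataset, MeltCurve)
from .doseresponse import dose_series, four_param_logistic
from .kinetics import mm_rate
from .presets import ENZYMES, IC50_TABLE, KINETICS_TABLE, THERMAL_TABLE
from .thermal import ThermalParams, thermal_model

__all__ = [
    "NoiseSpec",
    "KineticsTruth",
    "DoseResponseTruth",
    "GeneratorRecipe",
    "generate",
    "published_presets",
    "demo_recipes",
    "STAGES",
    "ATP_GRID",
    "TIME_POINTS_MIN",
]

STAGES = ("thermal", "dsf", "chemical2", "chemical3", "kinetics", "dose_response")

#: default 8-point ATP design spanning 0–5 mM (μM)
ATP_GRID = np.array([0.0, 78.125, 156.25, 312.5, 625.0, 1250.0, 2500.0, 5000.0])

#: reaction sampling times (min)
TIME_POINTS_MIN = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 140.0])


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded Gaussian perturbation of a generated signal.

    kind ``"additive-gaussian"``: sigma in signal units.
    kind ``"proportional-gaussian"``: sigma is the coefficient of
    variation; each point is scaled by (1 + sigma·N(0,1)).
    """

    sigma: float
    seed: int
    kind: str = "additive-gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind not in ("additive-gaussian", "proportional-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # always draws, so replicate streams stay aligned at sigma=0
        eps = rng.standard_normal(np.shape(y))
        if self.sigma == 0:
            return np.array(y, dtype=float, copy=True)
        if self.kind == "additive-gaussian":
            return y + self.sigma * eps
        return y * (1.0 + self.sigma * eps)


@dataclass(frozen=True)
class KineticsTruth:
    """Generating parameters for a kinetics time-course grid."""

    km: float  # units of the varied substrate (μM ATP / μg/ml polyGT)
    vmax: float  # nmol·min⁻¹·mg⁻¹
    enzyme: EnzymeSpec
    varied_substrate: str = "ATP"
    calibration: float = 1.0  # luminescence units per nmol ADP

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("km and vmax must be positive")


@dataclass(frozen=True)
class DoseResponseTruth:
    """Generating parameters for a 12-point dose-response plate."""

    ic50: float  # μM
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    max_level: float = 20000.0  # uninhibited luminescence
    min_level: float = 1000.0  # fully inhibited luminescence
    n_max_controls: int = 11
    n_min_controls: int = 11
    printed: str | None = None  # as-published value when it is a bound

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.max_level <= self.min_level:
            raise ValueError("max_level must exceed min_level")
        if self.n_max_controls < 1 or self.n_min_controls < 1:
            raise ValueError("plates need max and min control wells")


@dataclass(frozen=True)
class GeneratorRecipe:
    """Everything needed to generate one synthetic dataset.

    ``grid`` is the sampling axis (°C / M / μM / μg/ml), strictly
    increasing; kinetics recipes also carry ``time_points`` (min).
    """

    stage: str
    truth: object
    grid: np.ndarray
    noise: NoiseSpec
    replicates: int = 1
    time_points: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be a 1-D axis with ≥ 2 points")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")
        if self.stage in ("chemical2", "chemical3", "kinetics", "dose_response") \
                and self.grid[0] < 0:
            raise ValueError(f"{self.stage} grid outside model validity: "
                             "negative concentrations")
        if self.stage == "kinetics":
            if self.time_points is None:
                object.__setattr__(self, "time_points", TIME_POINTS_MIN.copy())
            tp = np.asarray(self.time_points, dtype=float)
            object.__setattr__(self, "time_points", tp)
            if not np.isclose(tp.min(), 0.0):
                raise ValueError("kinetics time points must include t=0")
        expected = {
            "thermal": ThermalParams, "dsf": ThermalParams,
            "chemical2": ChemParams2, "chemical3": ChemParams3,
            "kinetics": KineticsTruth, "dose_response": DoseResponseTruth,
        }[self.stage]
        if not isinstance(self.truth, expected):
            raise ValueError(f"stage {self.stage!r} needs a {expected.__name__} truth")

    def with_noise(self, sigma: float | None = None, seed: int | None = None,
                   kind: str | None = None) -> "GeneratorRecipe":
        ns = NoiseSpec(
            sigma=self.noise.sigma if sigma is None else sigma,
            seed=self.noise.seed if seed is None else seed,
            kind=self.noise.kind if kind is None else kind,
        )
        return replace(self, noise=ns)


def _meta(recipe: GeneratorRecipe, rep: int) -> dict:
    return {
        "stage": recipe.stage,
        "truth": recipe.truth,
        "seed": recipe.noise.seed,
        "sigma": recipe.noise.sigma,
        "noise_kind": recipe.noise.kind,
        "replicate": rep,
        "name": recipe.name,
    }


def generate(recipe: GeneratorRecipe) -> list:
    """Generate ``recipe.replicates`` datasets (forward model + noise).

    Returns a list of stage-appropriate containers: ``MeltCurve`` for
    thermal/dsf, ``DenaturationCurve`` for chemical stages,
    ``KineticsDataset`` for kinetics and ``DoseResponsePlate`` for
    dose_response.  Replicates differ only by their noise draws.
    """
    rng = np.random.default_rng(recipe.noise.seed)
    out = []
    for rep in range(recipe.replicates):
        out.append(_generate_one(recipe, rng, rep))
    return out


def _generate_one(recipe: GeneratorRecipe, rng: np.random.Generator, rep: int):
    stage, truth, grid, noise = recipe.stage, recipe.truth, recipe.grid, recipe.noise
    meta = _meta(recipe, rep)
    sid = recipe.name or stage

    if stage in ("thermal", "dsf"):
        y = noise.apply(thermal_model(grid, truth), rng)
        return MeltCurve(grid, y, modality="CD" if stage == "thermal" else "DSF",
                         sample_id=sid, metadata=meta)

    if stage in ("chemical2", "chemical3"):
        fn = two_state_model if stage == "chemical2" else three_state_model
        y = noise.apply(fn(grid, truth), rng)
        return DenaturationCurve(grid, y, sample_id=sid, metadata=meta)

    if stage == "kinetics":
        v_specific = mm_rate(grid, truth.km, truth.vmax)  # nmol/min/mg
        v_reaction = v_specific * truth.enzyme.mass_per_reaction_mg  # nmol/min
        clean = truth.calibration * np.outer(v_reaction, recipe.time_points)
        sig = noise.apply(clean, rng)
        # luminescence cannot go negative; clipping only trims noise tails
        return KineticsDataset(
            varied_substrate=truth.varied_substrate,
            concentrations=grid,
            time_points=recipe.time_points,
            signal=np.clip(sig, 0.0, None),
            enzyme=truth.enzyme,
            calibration=truth.calibration,
            metadata=meta,
        )

    # dose_response: grid held ascending in the recipe, plates are dosed
    # top-first
    conc = grid[::-1]
    inh = four_param_logistic(conc, truth.ic50, truth.hill, truth.top, truth.bottom)
    span = truth.max_level - truth.min_level
    clean = truth.max_level - span * inh / 100.0
    wells = noise.apply(clean, rng)
    max_ctrl = noise.apply(np.full(truth.n_max_controls, truth.max_level), rng)
    min_ctrl = noise.apply(np.full(truth.n_min_controls, truth.min_level), rng)
    parts = recipe.name.split(".")
    enz = parts[0] if len(parts) >= 2 else ""
    cmpd = parts[1] if len(parts) >= 2 else ""
    return DoseResponsePlate(
        compound=cmpd,
        enzyme=enz,
        concentrations=conc,
        raw_signal=wells,
        max_controls=max_ctrl,
        min_controls=min_ctrl,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# preset catalogue


def _thermal_recipe(name: str, tm: float, dhm: float, seed: int = 0,
                    sigma: float = 0.01) -> GeneratorRecipe:
    return GeneratorRecipe(
        stage="thermal",
        truth=ThermalParams(tm=tm, dhm=dhm, a_n=1.0, b_n=0.0, a_u=0.0, b_u=0.0),
        grid=np.arange(20.0, 81.0, 1.0),
        noise=NoiseSpec(sigma=sigma, seed=seed),
        name=name,
    )


def published_presets() -> dict[str, GeneratorRecipe]:
    """One runnable recipe per published table row.

    Keys: ``"<enzyme>.thermal"`` (4), ``"<enzyme>.kinetics"`` (5, ATP
    varied) and ``"<enzyme>.<compound>.ic50"`` (35).  Truth values are
    the printed ones; the single printed IC50 *bound* (">100") is
    simulated at 10× the bound so the out-of-window behaviour is
    reproduced, with the printed string kept in ``truth.printed``.
    """
    presets: dict[str, GeneratorRecipe] = {}
    for enzyme, (tm, _, dhm, _) in THERMAL_TABLE.items():
        key = f"{enzyme}.thermal"
        presets[key] = _thermal_recipe(key, tm, dhm)

    for enzyme, row in KINETICS_TABLE.items():
        key = f"{enzyme}.kinetics"
        presets[key] = GeneratorRecipe(
            stage="kinetics",
            truth=KineticsTruth(km=row["km_atp"], vmax=row["vmax"],
                                enzyme=ENZYMES[enzyme]),
            grid=ATP_GRID.copy(),
            noise=NoiseSpec(sigma=0.03, seed=0, kind="proportional-gaussian"),
            time_points=TIME_POINTS_MIN.copy(),
            name=key,
        )

    top = 100.0
    grid = np.sort(dose_series(top))
    for compound, per_enzyme in IC50_TABLE.items():
        for enzyme, (ic50, _r2) in per_enzyme.items():
            key = f"{enzyme}.{compound}.ic50"
            if isinstance(ic50, str):  # printed bound, e.g. ">100"
                bound = float(ic50.lstrip("> "))
                truth = DoseResponseTruth(ic50=10.0 * bound, printed=ic50)
            else:
                truth = DoseResponseTruth(ic50=float(ic50))
            presets[key] = GeneratorRecipe(
                stage="dose_response",
                truth=truth,
                grid=grid.copy(),
                noise=NoiseSpec(sigma=0.03, seed=0, kind="proportional-gaussian"),
                name=key,
            )
    return presets


def demo_recipes() -> dict[str, GeneratorRecipe]:
    """Representative recipes for stages without printed truth tables.

    Chemical-unfolding parameters are chosen to mimic the observed
    behaviour (complete unfolding by ~3 M GdnHCl; a partially stable
    intermediate near 2 M for the three-state case); the DSF demo uses a
    rising melt at the EphB2 midpoint.
    """
    grid_m = np.round(np.arange(0.0, 6.05, 0.1), 10)
    return {
        "demo.chemical2": GeneratorRecipe(
            stage="chemical2",
            truth=ChemParams2(dg_h2o=20.0, m_value=10.0,
                              a_n=1.0, b_n=-0.01, a_u=0.1, b_u=0.0),
            grid=grid_m,
            noise=NoiseSpec(sigma=0.005, seed=0),
            name="demo.chemical2",
        ),
        "demo.chemical3": GeneratorRecipe(
            stage="chemical3",
            truth=ChemParams3(dg1=15.0, m1=12.0, dg2=35.0, m2=10.0,
                              a_n=1.0, b_n=-0.01, a_u=0.1, b_u=0.0, z_i=0.5),
            grid=grid_m,
            noise=NoiseSpec(sigma=0.005, seed=0),
            name="demo.chemical3",
        ),
        "demo.dsf": GeneratorRecipe(
            stage="dsf",
            truth=ThermalParams(tm=53.9, dhm=154.2,
                                a_n=0.1, b_n=0.0, a_u=1.0, b_u=0.0),
            grid=np.arange(20.0, 81.0, 1.0),
            noise=NoiseSpec(sigma=0.005, seed=0),
            name="demo.dsf",
        ),
    }
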