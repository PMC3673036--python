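"""Configuration-driven orchestration of the characterization stages.

A :class:`RunConfig` (flat YAML) names the stages to run — any subset of
``thermal, dsf, chemical, kinetics, ic50`` — and, per stage, input CSV
paths and/or preset names from the synthetic catalogue.  ``run`` executes
each stage in isolation (one stage's failure never touches another's
numbers), writes a per-stage report CSV plus a combined characterization
summary (enzyme × {Tm, ΔHm, model probabilities, Km, kcat, Vmax,
per-compound IC50}), and logs seeds and per-fit convergence.  All numeric
output is written with 6 significant figures so that identical config +
seed reproduces reports byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemical, doseresponse, kinetics, simulate, thermal
from .data import read_curves, read_kinetics_csv, read_plate_csv
from .presets import ENZYMES

__all__ = ["RunConfig", "PipelineResult", "run"]

STAGE_NAMES = ("thermal", "dsf", "chemical", "kinetics", "ic50")

log = logging.getLogger("charkit")


@dataclass
class RunConfig:
    """Stages to run, their inputs/presets, seed and output directory."""

    stages: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "charkit_out"
    calibration: float = 1.0

    def __post_init__(self) -> None:
        for name in self.stages:
            if name not in STAGE_NAMES:
                raise ValueError(f"unknown stage {name!r}; expected one of {STAGE_NAMES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            stages=raw.get("stages", {}) or {},
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "charkit_out")),
            calibration=float(raw.get("calibration", 1.0)),
        )


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    reports: dict
    errors: dict

    @property
    def ok(self) -> bool:
        return not self.errors


def _catalogue():
    cat = simulate.published_presets()
    cat.update(simulate.demo_recipes())
    return cat


def _stage_items(spec: dict, config: RunConfig, stage_key: str):
    """Yield ('input'|'preset', name, payload) for one stage config."""
    spec = spec or {}
    cat = _catalogue()
    for path in spec.get("inputs", []) or []:
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
        yield "input", str(path), path
    for name in spec.get("presets", []) or []:
        if name not in cat:
            raise KeyError(f"unknown preset {name!r}")
        recipe = cat[name].with_noise(seed=config.seed)
        yield "preset", name, recipe


def _enzyme_of(sample: str) -> str:
    return sample.split(".")[0].split("/")[-1]


# --- stage runners ---------------------------------------------------------


def _run_thermal(spec, config) -> pd.DataFrame:
    rows = []
    for kind, name, payload in _stage_items(spec, config, "thermal"):
        curves = (read_curves(payload, kind="melt", modality="CD")
                  if kind == "input" else simulate.generate(payload))
        for curve in curves:
            res = thermal.fit_thermal(curve)
            if not res.converged:
                log.warning("thermal fit did not converge: %s", curve.sample_id)
            rows.append({
                "sample": curve.sample_id or name,
                "replicate": curve.metadata.get("replicate", 0),
                "tm_C": res.tm if res.converged else np.nan,
                "tm_se": res.bse.get("tm", np.nan),
                "dhm_kJ_mol": res.dhm if res.converged else np.nan,
                "dhm_se": res.bse.get("dhm", np.nan),
                "rss": res.rss,
                "converged": res.converged,
            })
    return pd.DataFrame(rows).sort_values(["sample", "replicate"]).reset_index(drop=True)


def _run_dsf(spec, config) -> pd.DataFrame:
    rows = []
    for kind, name, payload in _stage_items(spec, config, "dsf"):
        curves = (read_curves(payload, kind="melt", modality="DSF")
                  if kind == "input" else simulate.generate(payload))
        for curve in curves:
            tm = thermal.dsf_tm(curve)
            rows.append({
                "sample": curve.sample_id or name,
                "replicate": curve.metadata.get("replicate", 0),
                "tm_C": tm,
            })
    return pd.DataFrame(rows).sort_values(["sample", "replicate"]).reset_index(drop=True)


def _run_chemical(spec, config) -> pd.DataFrame:
    rows = []
    groups: dict[str, list] = {}
    for kind, name, payload in _stage_items(spec, config, "chemical"):
        curves = (read_curves(payload, kind="denaturation")
                  if kind == "input" else simulate.generate(payload))
        for c in curves:
            groups.setdefault(c.sample_id or name, []).append(c)
    for sample in sorted(groups):
        pooled = chemical.pool_replicates(groups[sample])
        fit2 = chemical.fit_chemical(pooled, "two")
        fit3 = chemical.fit_chemical(pooled, "three")
        comp = chemical.compare_models(fit2, fit3)
        if not (fit2.converged and fit3.converged):
            log.warning("chemical fit convergence issue: %s", sample)
        rows.append({
            "sample": sample,
            "n_replicates": len(groups[sample]),
            "dg_h2o_kJ_mol": fit2.params.dg_h2o,
            "m_value": fit2.params.m_value,
            "cm_M": fit2.params.cm,
            "dg1_kJ_mol": fit3.params.dg1,
            "dg2_kJ_mol": fit3.params.dg2,
            "z_i": fit3.params.z_i,
            "aicc_two": comp.aicc_two,
            "aicc_three": comp.aicc_three,
            "prob_two_pct": comp.prob_two,
            "prob_three_pct": comp.prob_three,
            "preferred": comp.preferred,
            "n_outliers": int(fit3.outlier_mask().sum()),
        })
    return pd.DataFrame(rows)


def _run_kinetics(spec, config) -> pd.DataFrame:
    rows = []
    for kind, name, payload in _stage_items(spec, config, "kinetics"):
        if kind == "input":
            enzyme_name = (spec or {}).get("enzyme", "")
            enzyme = ENZYMES.get(enzyme_name)
            if enzyme is None:
                raise KeyError(f"kinetics input {payload}: unknown enzyme "
                               f"{enzyme_name!r}; set stages.kinetics.enzyme")
            datasets = [read_kinetics_csv(payload, enzyme=enzyme,
                                          calibration=config.calibration)]
        else:
            datasets = simulate.generate(payload)
        for ds in datasets:
            res = kinetics.MichaelisMenten.from_dataset(ds).fit()
            for w in res.warnings:
                log.warning("%s: %s", name, w)
            rows.append({
                "sample": name,
                "substrate": ds.varied_substrate,
                "km": res.km,
                "km_se": res.bse["km"],
                "vmax_nmol_min_mg": res.vmax,
                "vmax_se": res.bse["vmax"],
                "kcat_s": res.kcat,
                "specificity": res.specificity,
                "r_squared": res.rsquared,
                "converged": res.converged,
            })
    return pd.DataFrame(rows).sort_values("sample").reset_index(drop=True)


def _run_ic50(spec, config) -> pd.DataFrame:
    rows = []
    for kind, name, payload in _stage_items(spec, config, "ic50"):
        plates = ([read_plate_csv(payload)] if kind == "input"
                  else simulate.generate(payload))
        for plate in plates:
            res = doseresponse.DoseResponse.from_plate(plate).fit()
            if res.censored:
                log.warning("%s: IC50 beyond top dose (%s)", name, res.bound)
            if res.tight_binding:
                log.warning("%s: near the tight-binding limit", name)
            rows.append({
                "enzyme": plate.enzyme or _enzyme_of(name),
                "compound": plate.compound or name,
                "ic50_uM": np.nan if res.censored else res.ic50,
                "bound": res.bound or "",
                "hill": res.hill,
                "r_squared": res.rsquared,
                "censored": res.censored,
                "tight_binding": res.tight_binding,
            })
    return pd.DataFrame(rows).sort_values(["compound", "enzyme"]).reset_index(drop=True)


_RUNNERS = {
    "thermal": _run_thermal,
    "dsf": _run_dsf,
    "chemical": _run_chemical,
    "kinetics": _run_kinetics,
    "ic50": _run_ic50,
}


def _build_summary(reports: dict) -> pd.DataFrame:
    """Wide enzyme × metrics table assembled from the stage reports."""
    per_enzyme: dict[str, dict] = {}

    def slot(enzyme):
        return per_enzyme.setdefault(enzyme, {})

    if "thermal" in reports and not reports["thermal"].empty:
        g = reports["thermal"].assign(enzyme=lambda d: d["sample"].map(_enzyme_of))
        agg = g.groupby("enzyme").agg(tm=("tm_C", "mean"), dhm=("dhm_kJ_mol", "mean"))
        for enzyme, r in agg.iterrows():
            slot(enzyme)["Tm_C"] = r["tm"]
            slot(enzyme)["dHm_kJ_mol"] = r["dhm"]
    if "dsf" in reports and not reports["dsf"].empty:
        g = reports["dsf"].assign(enzyme=lambda d: d["sample"].map(_enzyme_of))
        for enzyme, r in g.groupby("enzyme").agg(tm=("tm_C", "mean")).iterrows():
            slot(enzyme)["Tm_DSF_C"] = r["tm"]
    if "chemical" in reports and not reports["chemical"].empty:
        for _, r in reports["chemical"].iterrows():
            e = _enzyme_of(r["sample"])
            slot(e)["prob_two_pct"] = r["prob_two_pct"]
            slot(e)["prob_three_pct"] = r["prob_three_pct"]
    if "kinetics" in reports and not reports["kinetics"].empty:
        for _, r in reports["kinetics"].iterrows():
            e = _enzyme_of(r["sample"])
            slot(e)["Km_ATP_uM"] = r["km"]
            slot(e)["kcat_s"] = r["kcat_s"]
            slot(e)["Vmax_nmol_min_mg"] = r["vmax_nmol_min_mg"]
    if "ic50" in reports and not reports["ic50"].empty:
        for _, r in reports["ic50"].iterrows():
            e = r["enzyme"]
            comp = str(r["compound"]).split(".")[1] if "." in str(r["compound"]) \
                else str(r["compound"])
            val = r["bound"] if r["censored"] else r["ic50_uM"]
            slot(e)[f"IC50_{comp}_uM"] = val
    if not per_enzyme:
        return pd.DataFrame()
    df = pd.DataFrame.from_dict(per_enzyme, orient="index").sort_index()
    df.index.name = "enzyme"
    return df


def run(config: RunConfig) -> PipelineResult:
    """Execute the configured stages; never raises on a stage failure."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("charkit run: seed=%d stages=%s", config.seed, sorted(config.stages))

    reports: dict[str, pd.DataFrame] = {}
    errors: dict[str, str] = {}
    try:
        for stage in STAGE_NAMES:
            if stage not in config.stages:
                continue
            try:
                reports[stage] = _RUNNERS[stage](config.stages[stage], config)
                path = outdir / f"{stage}_report.csv"
                reports[stage].to_csv(path, index=False, float_format="%.6g")
                log.info("stage %s: %d rows -> %s", stage, len(reports[stage]), path)
            except Exception as exc:  # stage isolation contract
                errors[stage] = f"{type(exc).__name__}: {exc}"
                log.error("stage %s failed: %s", stage, errors[stage])
        summary = _build_summary(reports)
        summary.to_csv(outdir / "summary.csv", float_format="%.6g")
    finally:
        log.removeHandler(handler)
        handler.close()
    return PipelineResult(summary=summary, reports=reports, errors=errors)
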