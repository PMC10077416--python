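"""Full-study orchestration: simulate plans, run LET → vRBE → metrics.

For every configured plan the study simulates (or loads) per-beam dose and
LET grids, combines the LET grids by relative-dose weighting, applies the
5%-of-maximum dose threshold, computes fixed-RBE-1.1 and McNamara
variable-RBE weighted doses for each configured α/β, and extracts the
comparison metrics for every configured structure:

* Dmean and near-maximum D0.1cc per dose flavour,
* LET D0.1cc and LET mean (thresholded composite LET),
* V5Gy / V10Gy,
* Δdose (vRBE − fixed 1.1) mean and D0.1cc, and Δdose ≥ 3 Gy(RBE) volumes,
* the (≥80% dose ∧ ≥6 keV/μm) overlap volume with its component structures,
* the CTV coverage criterion (D98% ≥ 95% of prescription).

Results come back as one long-format table (plan, structure, flavour,
metric, value, units) plus DVH curves on a common dose axis, and can be
written to CSV / two-column DVH text files / portable grid files.  Given a
config and seed the outputs are byte-reproducible; generation itself is
deterministic, the seed only feeds optional phantom noise.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dose_metrics, let_ops, phantom_sim, pipeline_io
from .dose_metrics import DVHCurve, StructureTooSmallError
from .grids import VoxelGrid
from .phantom_sim import DepthCurveParams, Phantom, PlanDose
from .rbe_models import FractionationScheme, RBEParameters, vrbe_weighted_dose

__all__ = [
    "StudyConfig",
    "StudyReport",
    "default_config",
    "load_config",
    "run_study",
    "sensitivity_report",
]

log = logging.getLogger("protonlet.study")

TOO_SMALL = "structure too small"


@dataclass
class StudyConfig:
    """Validated study configuration (see ``config/default_study.yaml``)."""

    raw: dict

    def __post_init__(self) -> None:
        if not self.raw.get("plans"):
            raise ValueError("config must define at least one plan")
        if not self.rbe_alpha_betas and self.raw["rbe"].get("fixed_rbe") is None:
            raise ValueError("config must define at least one RBE setting")

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def prescription(self) -> FractionationScheme:
        p = self.raw["prescription"]
        return FractionationScheme(float(p["total_dose_gy"]), int(p["n_fractions"]))

    @property
    def curve_params(self) -> DepthCurveParams:
        b = self.raw["beam_model"]
        return DepthCurveParams(
            plateau_dose=b["plateau_dose"],
            peak_width_mm=b["peak_width_mm"],
            straggling_sigma_mm=b["straggling_sigma_mm"],
            let_plateau=b["let_plateau_kevum"],
            let_scale=b["let_scale_kevum_mm"],
            let_softening_mm=b["let_softening_mm"],
            let_cap=b["let_cap_kevum"],
        )

    @property
    def rbe_alpha_betas(self) -> list[float]:
        return [float(v) for v in self.raw["rbe"].get("alpha_beta_gy", [])]

    def rbe_params(self, alpha_beta: float) -> RBEParameters:
        coeff = self.raw["rbe"].get("coefficients", {})
        return RBEParameters(
            alpha_beta=alpha_beta,
            c1=float(coeff.get("c1", 0.99064)),
            c2=float(coeff.get("c2", 0.35605)),
            c3=float(coeff.get("c3", 1.1012)),
            c4=float(coeff.get("c4", 0.0038703)),
        )

    @property
    def fixed_rbe(self) -> float:
        return float(self.raw["rbe"].get("fixed_rbe", 1.1))

    @property
    def metrics(self) -> dict:
        return self.raw["metrics"]

    @property
    def plans(self) -> list[dict]:
        return list(self.raw["plans"])


def default_config() -> StudyConfig:
    """The shipped default study (three-to-four beam arrangements)."""
    text = (importlib.resources.files("protonlet") / "config" / "default_study.yaml").read_text()
    return StudyConfig(yaml.safe_load(text))


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig(yaml.safe_load(fh))


@dataclass
class PlanResult:
    """Everything computed for one plan."""

    name: str
    plan_dose: PlanDose
    composite_dose: VoxelGrid
    mixed_let: VoxelGrid          # thresholded
    flavours: dict[str, VoxelGrid]
    included: dict[str, np.ndarray]
    deltas: dict[str, VoxelGrid]
    coverage: dict


@dataclass
class StudyReport:
    """Long-format metric table, DVH curves and per-plan grids."""

    config: StudyConfig
    metrics: pd.DataFrame
    dvhs: dict[tuple[str, str, str], DVHCurve]
    plans: dict[str, PlanResult]
    phantom: Phantom
    errors: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path, write_grids: bool = False) -> Path:
        """Write the metric table, DVH files and (optionally) grid files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        dvh_dir = outdir / "dvh"
        dvh_dir.mkdir(exist_ok=True)
        for (plan, structure, flavour), curve in self.dvhs.items():
            fn = dvh_dir / f"{plan}_{structure}_{flavour}.tsv".replace("/", "-")
            np.savetxt(fn, np.column_stack([curve.dose_axis, curve.volume_axis]),
                       header="dose\tvolume_pct", fmt="%.6g", delimiter="\t")
        if write_grids:
            grid_dir = outdir / "grids"
            grid_dir.mkdir(exist_ok=True)
            for name, pr in self.plans.items():
                pipeline_io.write_grid(pr.composite_dose, grid_dir / f"{name}_dose.pgrid")
                pipeline_io.write_grid(pr.mixed_let, grid_dir / f"{name}_let.pgrid")
                for flavour, grid in pr.flavours.items():
                    pipeline_io.write_grid(grid, grid_dir / f"{name}_{flavour}.pgrid")
        return outdir


def _flavour_name(alpha_beta: float) -> str:
    return f"vRBE_ab{alpha_beta:g}"


def _run_plan(cfg: StudyConfig, phantom: Phantom, plan_spec: Mapping[str, Any]) -> PlanResult:
    name = str(plan_spec["name"])
    p = cfg.curve_params
    planning = cfg.raw.get("planning", {})
    beams = [
        phantom_sim.plan_beam(
            phantom,
            float(angle),
            p,
            layer_spacing_mm=planning.get("layer_spacing_mm", 3.0),
            range_margin_mm=planning.get("range_margin_mm", 3.0),
            aperture_margin_mm=planning.get("aperture_margin_mm", 12.0),
            penumbra_sigma_mm=planning.get("penumbra_sigma_mm", 5.0),
        )
        for angle in plan_spec["angles"]
    ]
    plan_dose = phantom_sim.assemble_plan(phantom, beams, cfg.prescription, p)
    composite = plan_dose.composite_dose()
    frac = float(cfg.metrics["dose_threshold_fraction"])
    log.info("plan %s: LET threshold at %.0f%% of composite max dose", name, 100 * frac)
    mixed = let_ops.threshold_let(plan_dose.mixed_let(), composite, frac, phantom.body_mask)

    fixed_vals = cfg.fixed_rbe * composite.values
    fixed = composite.like(fixed_vals, quantity="dose_Gy_rbe",
                           provenance=f"fixed_rbe={cfg.fixed_rbe}")
    flavours: dict[str, VoxelGrid] = {"fixed1.1": fixed}
    included: dict[str, np.ndarray] = {"fixed1.1": np.ones(composite.shape, bool)}
    deltas: dict[str, VoxelGrid] = {}
    for ab in cfg.rbe_alpha_betas:
        fname = _flavour_name(ab)
        grid, incl = vrbe_weighted_dose(composite, mixed, cfg.prescription, cfg.rbe_params(ab))
        flavours[fname] = grid
        included[fname] = incl
        deltas[fname] = dose_metrics.delta_dose_map(grid, fixed, incl)

    coverage = dose_metrics.coverage_check(
        composite, phantom.structure("ctv"), cfg.prescription.total_dose
    )
    return PlanResult(name, plan_dose, composite, mixed, flavours, included, deltas, coverage)


def _plan_metrics(cfg: StudyConfig, phantom: Phantom, pr: PlanResult,
                  rows: list, dvhs: dict) -> None:
    m = cfg.metrics
    hot_cc = float(m["hot_volume_cc"])
    n_bins = int(m["dvh_bins"])
    dvh_max = 1.5 * cfg.prescription.total_dose
    structures = [phantom.structure(s) for s in m["structures"]]

    def add(structure, flavour, metric, value, units, note=""):
        rows.append({
            "plan": pr.name, "structure": structure, "flavour": flavour,
            "metric": metric, "value": value, "units": units, "note": note,
        })

    def guarded(fn, *args, **kw):
        try:
            return fn(*args, **kw), ""
        except StructureTooSmallError:
            return float("nan"), TOO_SMALL

    add("ctv", "physical", "D98", pr.coverage["d98"], "Gy")
    add("ctv", "physical", "coverage_pass", float(pr.coverage["pass"]), "bool")

    for sm in structures:
        v, note = guarded(dose_metrics.d_volume, pr.mixed_let, sm, hot_cc)
        add(sm.name, "MC", "LET_D0.1cc", v, "keV/um", note)
        v, note = guarded(dose_metrics.mean_in_mask, pr.mixed_let, sm)
        add(sm.name, "MC", "LET_mean", v, "keV/um", note)

        for flavour, grid in pr.flavours.items():
            v, note = guarded(dose_metrics.mean_in_mask, grid, sm)
            add(sm.name, flavour, "Dmean", v, "Gy(RBE)", note)
            v, note = guarded(dose_metrics.d_volume, grid, sm, hot_cc)
            add(sm.name, flavour, "D0.1cc", v, "Gy(RBE)", note)
            for level in m["v_dose_levels_gy"]:
                v, note = guarded(dose_metrics.v_dose, grid, sm, float(level))
                add(sm.name, flavour, f"V{level:g}Gy", v, "%", note)
            try:
                dvhs[(pr.name, sm.name, flavour)] = dose_metrics.dvh(
                    grid, sm, n_bins, dose_max=dvh_max)
            except StructureTooSmallError:
                pass

        for fname, delta in pr.deltas.items():
            v, note = guarded(dose_metrics.mean_in_mask, delta, sm)
            add(sm.name, fname, "delta_Dmean", v, "Gy(RBE)", note)
            v, note = guarded(dose_metrics.d_volume, delta, sm, hot_cc)
            add(sm.name, fname, "delta_D0.1cc", v, "Gy(RBE)", note)
            thr = float(m["delta_dose_threshold_gy_rbe"])
            add(sm.name, fname, f"vol_delta_ge{thr:g}",
                dose_metrics.volume_above(delta, thr, sm), "cc")

    thr = float(m["delta_dose_threshold_gy_rbe"])
    log.info("plan %s: delta-dose volume threshold %.1f Gy(RBE)", pr.name, thr)
    for fname, delta in pr.deltas.items():
        add("body", fname, f"vol_delta_ge{thr:g}_total",
            dose_metrics.volume_above(delta, thr), "cc")

    ov = dose_metrics.overlap_volume(
        pr.composite_dose, pr.mixed_let,
        float(m["overlap_dose_fraction"]), float(m["overlap_let_kevum"]),
        phantom.body_mask, {sm.name: sm for sm in structures if sm.name != "body"},
    )
    log.info("plan %s: overlap rule >=%.0f%% dose and >=%.1f keV/um",
             pr.name, 100 * float(m["overlap_dose_fraction"]), float(m["overlap_let_kevum"]))
    add("body", "MC", "overlap_cc", ov["volume_cc"], "cc",
        ",".join(ov["component_structures"]))


def run_study(config: StudyConfig | Mapping | None = None,
              seed: int | None = None) -> StudyReport:
    """Run every configured plan through the full analysis chain.

    A failing plan is logged and skipped (recorded in ``report.errors``);
    the other plans still run.  ``seed`` overrides the config seed.
    """
    if config is None:
        config = default_config()
    if not isinstance(config, StudyConfig):
        config = StudyConfig(dict(config))
    if seed is not None:
        config.raw["seed"] = int(seed)
    rng = np.random.default_rng(config.seed)  # reserved for phantom noise
    del rng

    phantom = phantom_sim.build_phantom(config.raw)
    rows: list[dict] = []
    dvhs: dict[tuple[str, str, str], DVHCurve] = {}
    plans: dict[str, PlanResult] = {}
    errors: dict[str, str] = {}
    for plan_spec in config.plans:
        name = str(plan_spec["name"])
        try:
            pr = _run_plan(config, phantom, plan_spec)
            _plan_metrics(config, phantom, pr, rows, dvhs)
            plans[name] = pr
        except Exception as exc:  # noqa: BLE001 - isolate per-plan failures
            log.error("plan %s failed: %s", name, exc)
            errors[name] = str(exc)
    metrics = pd.DataFrame(rows, columns=["plan", "structure", "flavour",
                                          "metric", "value", "units", "note"])
    metrics.attrs["seed"] = config.seed
    return StudyReport(config, metrics, dvhs, plans, phantom, errors)


def sensitivity_report(report: StudyReport, structure: str | None = None,
                       plan: str | None = None) -> pd.DataFrame:
    """Per-dose-bin DVH spread (max − min volume %) across the α/β settings.

    Fixed-RBE flavours are excluded from the spread.  The returned frame has
    ``dose`` and ``spread_pct`` columns; ``attrs['max_spread_dose']`` holds
    the dose bin where the spread peaks.
    """
    sens = report.config.raw.get("sensitivity", {})
    structure = structure or sens.get("structure")
    plan = plan or sens.get("plan")
    curves = [
        c for (p, s, f), c in report.dvhs.items()
        if p == plan and s == structure and f.startswith("vRBE_ab")
    ]
    if not curves:
        raise ValueError(f"no variable-RBE DVHs for plan={plan!r}, structure={structure!r}")
    dose = curves[0].dose_axis
    vols = np.stack([c.volume_axis for c in curves])
    spread = vols.max(axis=0) - vols.min(axis=0)
    df = pd.DataFrame({"dose": dose, "spread_pct": spread})
    df.attrs["max_spread_dose"] = float(dose[int(np.argmax(spread))])
    df.attrs["n_alpha_beta"] = len(curves)
    return df
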