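"""End-to-end orchestration: simulate -> metrics -> filter -> analyze.

One global seed deterministically spawns per-stage seeds, so a full run is
reproducible and each stage can be rerun in isolation from its on-disk
inputs.  Every stage writes plain CSV artifacts into the run directory and
is recorded, with record counts and wall time, in ``manifest.json``
(keyed by a hash of the canonical config, so the manifest hash changes iff
the configuration changes).

The pipeline's default filter grid is deliberately lighter (24-point
grids, 3x3 candidate sets) than the filter module's own default, so a
default desk-scale run of a 20-per-arm trial completes in minutes; both
are fully configurable from the YAML config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, bayes, metrics, synthetic

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "validate_config",
    "run_pipeline",
    "default_filter_config",
]

STAGES = ("simulate", "metrics", "filter", "analyze")


class PipelineStageError(RuntimeError):
    """A stage failed; partial artifacts are left in the run directory."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_filter_config() -> bayes.FilterConfig:
    """Desk-scale filter grid used by default pipeline runs."""
    return bayes.FilterConfig(
        n_mu=24,
        n_logvmu=24,
        n_logsd=24,
        kmu_candidates=tuple(np.logspace(-3, 0, 3)),
        vsd_candidates=tuple(np.logspace(-3, 0, 3)),
    )


@dataclass
class PipelineConfig:
    """Typed configuration of one pipeline run."""

    seed: int
    design: synthetic.TrialDesign = field(default_factory=synthetic.TrialDesign)
    filter_config: bayes.FilterConfig = field(default_factory=default_filter_config)
    weekday_covariate: bool = False
    fixed_transform_bounds: dict | None = None
    grid_check: bool = False

    def to_dict(self) -> dict:
        d = {
            "seed": int(self.seed),
            "weekday_covariate": bool(self.weekday_covariate),
            "fixed_transform_bounds": self.fixed_transform_bounds,
            "grid_check": bool(self.grid_check),
            "design": dataclasses.asdict(self.design),
            "filter": dataclasses.asdict(self.filter_config),
        }
        d["design"]["day_range"] = [int(x) for x in self.design.day_range]
        f = d["filter"]
        for k in ("mu_bounds", "logvmu_bounds", "logsd_bounds"):
            f[k] = [float(x) for x in f[k]]
        for k in ("kmu_candidates", "vsd_candidates"):
            f[k] = [float(x) for x in f[k]]
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _coerce_design(d: dict) -> synthetic.TrialDesign:
    kw = dict(d)
    if "day_range" in kw:
        kw["day_range"] = tuple(int(x) for x in kw["day_range"])
    for k in ("effect_m10_by_week", "effect_onset_by_week",
              "effect_volatility_by_week", "effect_is_by_week"):
        if k in kw and kw[k] is not None:
            kw[k] = {int(w): float(v) for w, v in kw[k].items()}
    return synthetic.TrialDesign(**kw)


def _coerce_filter(d: dict) -> bayes.FilterConfig:
    kw = dict(d)
    for k in ("mu_bounds", "logvmu_bounds", "logsd_bounds"):
        if k in kw:
            kw[k] = tuple(float(x) for x in kw[k])
    for k in ("kmu_candidates", "vsd_candidates"):
        if k in kw:
            kw[k] = tuple(float(x) for x in kw[k])
    return bayes.FilterConfig(**kw)


def validate_config(raw_text: str) -> tuple[PipelineConfig | None, list[str]]:
    """Parse YAML config text into a typed config, collecting every
    violation rather than stopping at the first."""
    violations: list[str] = []
    try:
        data = yaml.safe_load(raw_text) or {}
    except yaml.YAMLError as err:
        return None, [f"unparseable YAML: {err}"]
    if not isinstance(data, dict):
        return None, ["config must be a mapping"]

    if "seed" not in data or data["seed"] is None:
        violations.append("seed is required")
    elif not isinstance(data["seed"], int):
        violations.append("seed must be an integer")

    design_d = data.get("design", {}) or {}
    if design_d.get("n_per_arm", 2) < 2:
        violations.append("design.n_per_arm must be >= 2 (n_per_arm >= 2)")
    rate = design_d.get("missing_day_rate", 0.0)
    if not (0 <= rate < 1):
        violations.append("design.missing_day_rate must be in [0, 1)")
    dr = design_d.get("day_range")
    if dr is not None and not (dr[0] <= 0 <= dr[1]):
        violations.append("design.day_range must contain day 0")
    filt_d = data.get("filter", {}) or {}
    for k in ("n_mu", "n_logvmu", "n_logsd"):
        if filt_d.get(k, 8) < 8:
            violations.append(f"filter.{k} must be >= 8")

    design = None
    filt = None
    if not violations:
        try:
            design = _coerce_design(design_d)
        except (TypeError, ValueError) as err:
            violations.append(f"design: {err}")
        try:
            filt = _coerce_filter(filt_d)
        except (TypeError, ValueError) as err:
            violations.append(f"filter: {err}")
    if violations:
        return None, violations
    return (
        PipelineConfig(
            seed=int(data["seed"]),
            design=design,
            filter_config=filt,
            weekday_covariate=bool(data.get("weekday_covariate", False)),
            fixed_transform_bounds=data.get("fixed_transform_bounds"),
            grid_check=bool(data.get("grid_check", False)),
        ),
        [],
    )


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    seed = _stage_seeds(config.seed)["simulate"]
    design = dataclasses.replace(config.design, seed=seed)
    ds = synthetic.simulate_trial(design)
    ds.to_csv(outdir / "trial.csv", outdir / "participants.csv", outdir / "latent.csv")
    hourly = synthetic.hourly_activity(ds, seed=seed + 1)
    hourly.to_csv(outdir / "hourly.csv", index=False)
    return {
        "outputs": ["trial.csv", "participants.csv", "latent.csv", "hourly.csv"],
        "records": int(len(ds.days)),
    }


def _load_dataset(outdir: Path) -> synthetic.TrialDataset:
    return synthetic.TrialDataset.from_csv(
        outdir / "trial.csv", outdir / "participants.csv", outdir / "latent.csv"
    )


def stage_metrics(config: PipelineConfig, outdir: Path) -> dict:
    ds = _load_dataset(outdir)
    hourly = pd.read_csv(outdir / "hourly.csv")
    cols = ["id", "day", "valid", "m10", "l5", "m10_onset", "l5_onset"]
    ds.days[cols].to_csv(outdir / "metrics.csv", index=False)

    rows = []
    for pid, sub in ds.days.groupby("id", sort=True):
        h_p = hourly[hourly["id"] == pid]
        for period in analysis.PHASES:
            day_set = [
                int(r.day) for r in sub.itertuples() if analysis.assign_phase(int(r.day)) == period
            ]
            recs = [
                metrics.CircadianDay(
                    day=int(r.day), valid=bool(r.valid),
                    m10_amount=r.m10, m10_onset=r.m10_onset,
                    l5_amount=r.l5, l5_onset=r.l5_onset,
                )
                for r in sub.itertuples() if int(r.day) in day_set
            ]
            h_sub = h_p[h_p["day"].isin(day_set)].sort_values(["day", "hour"])
            stats_ = metrics.summarize_period(recs, period, h_sub["activity"].to_numpy())
            rows.append(
                {
                    "id": pid,
                    "period": period,
                    "ra": stats_.relative_amplitude,
                    "is": stats_.interdaily_stability,
                    "iv": stats_.intradaily_variability,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "rhythm.csv", index=False)
    return {"outputs": ["metrics.csv", "rhythm.csv"], "records": len(rows)}


def stage_filter(config: PipelineConfig, outdir: Path) -> dict:
    ds = _load_dataset(outdir)
    fixed = None
    if config.fixed_transform_bounds:
        fixed = {k: tuple(v) for k, v in config.fixed_transform_bounds.items()}
    bundle = bayes.fit_series_bundle(
        ds, config.filter_config, day_range=config.design.day_range, fixed_bounds=fixed
    )
    first, last = config.design.day_range
    day_grid = np.arange(first, last + 1)
    frames = []
    for (pid, meas), est in sorted(bundle.items()):
        if est is None:
            continue
        f = est.to_frame()
        f.insert(0, "day", day_grid)
        f.insert(0, "measure", meas)
        f.insert(0, "id", pid)
        f["tmin"] = est.spec.min
        f["tmax"] = est.spec.max
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "estimates.csv", index=False)
    return {"outputs": ["estimates.csv"], "records": int(sum(len(f) for f in frames))}


def load_estimates(outdir: Path) -> dict:
    """Rebuild the per-(id, measure) estimates bundle from estimates.csv."""
    df = pd.read_csv(outdir / "estimates.csv")
    bundle = {}
    for (pid, meas), sub in df.groupby(["id", "measure"], sort=True):
        sub = sub.sort_values("day")
        bundle[(int(pid), meas)] = bayes.FilterEstimates(
            mu=sub["mu_hat"].to_numpy(),
            log_vmu=sub["logvmu_hat"].to_numpy(),
            log_sd=sub["logsd_hat"].to_numpy(),
            spread_mu=sub["spread_mu"].to_numpy(),
            spread_logvmu=sub["spread_logvmu"].to_numpy(),
            spread_logsd=sub["spread_logsd"].to_numpy(),
            missing=sub["missing"].to_numpy() != 0,
            spec=bayes.TransformSpec(float(sub["tmin"].iloc[0]), float(sub["tmax"].iloc[0])),
        )
    return bundle


def stage_analyze(config: PipelineConfig, outdir: Path) -> dict:
    ds = _load_dataset(outdir)
    bundle = load_estimates(outdir)
    table = analysis.build_long_table(ds, bundle)
    rhythm = pd.read_csv(outdir / "rhythm.csv").rename(columns={"is": "is_"})
    rhythm = rhythm.merge(ds.participants, on="id").rename(columns={"period": "phase"})

    fits: dict[str, analysis.ModelFit] = {}
    fits["activity_level"] = analysis.fit_activity_model(
        table, role="level", weekday_covariate=config.weekday_covariate
    )
    fits["activity_onset"] = analysis.fit_activity_model(
        table, role="onset", weekday_covariate=config.weekday_covariate
    )
    fits["variability_level"] = analysis.fit_variability_model(
        table, source="level", weekday_covariate=config.weekday_covariate
    )
    fits["variability_onset"] = analysis.fit_variability_model(
        table, source="onset", weekday_covariate=config.weekday_covariate
    )
    for outcome in ("ra", "is", "iv"):
        try:
            fits[f"rhythm_{outcome}"] = analysis.fit_rhythm_model(
                rhythm, outcome, weekday_covariate=False
            )
        except (ValueError, RuntimeError) as err:
            fits[f"rhythm_{outcome}"] = None  # type: ignore[assignment]

    results = []
    report = []
    for name, fit in fits.items():
        if fit is None:
            report.append(f"[{name}] not estimable\n")
            continue
        for r in fit.estimates.itertuples():
            results.append(
                {"model": name, "term": r.term, "B": r.B, "se": r.se,
                 "t": r.t, "df": r.df, "p": r.p, "d": r.d}
            )
        report.append(f"[{name}] formula: {fit.formula}")
        report.append(f"[{name}] converged: {fit.converged}")
        for r in fit.contrasts.itertuples():
            report.append(
                f"[{name}] {r.term}: B={r.B:.3f} t={r.t:.3f} p={r.p:.4g} d={r.d:.3f}"
            )
        report.append("")
    report.append(analysis.NO_ADJUSTMENT_CAVEAT)
    report.append(analysis.D_CONVENTION)
    pd.DataFrame(results).to_csv(outdir / "results.csv", index=False)
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return {"outputs": ["results.csv", "report.txt"], "records": len(results)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "metrics": stage_metrics,
    "filter": stage_filter,
    "analyze": stage_analyze,
}


def run_pipeline(config: PipelineConfig, outdir, stages=STAGES, log=None) -> dict:
    """Run the requested stages in order, writing a manifest at the end.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts written so far are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())
    manifest = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "stages": [],
    }
    for name in stages:
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[name](config, outdir)
        except Exception as err:
            _write_manifest(outdir, manifest)
            raise PipelineStageError(name, err) from err
        info = {"stage": name, **info, "seconds": round(time.perf_counter() - t0, 3)}
        manifest["stages"].append(info)
        if log is not None:
            log(f"stage={name} records={info['records']} seconds={info['seconds']}")
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
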