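"""Scenario orchestration: generate -> analyze -> report.

Runs one scenario (a preset, several seeds) or a sweep over field angles,
persisting per-seed artifacts before aggregation so partial failures never
silently bias the summary.  Replicates are reported as mean +/- standard
error at the seed level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dihedrals, occupancy, permeation
from .presets import PresetParams, get_preset
from .sf_model import SFGeometry, default_geometry
from .synthetic import render_frames, simulate_timeline

__all__ = ["ScenarioConfig", "ScenarioResult", "SweepReport", "run_scenario", "sweep"]

log = logging.getLogger("kperm")

ANALYSES = ("flux", "density", "states", "mechanism", "dihedrals")


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: a preset (or explicit parameters), seeds, analyses."""

    preset: str | PresetParams
    seeds: tuple[int, ...] = (1,)
    analyses: tuple[str, ...] = ("flux",)
    frame_interval_ns: float | None = None
    duration_us: float | None = None
    expected_events: float | None = None
    outdir: str | Path | None = None
    reproducible: bool = True

    def __post_init__(self) -> None:
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")
        if not self.analyses:
            raise ValueError(f"no analyses requested; choose from {ANALYSES}")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; choose from {ANALYSES}")

    def params(self) -> PresetParams:
        p = self.preset if isinstance(self.preset, PresetParams) else get_preset(self.preset)
        overrides = {}
        if self.duration_us is not None:
            overrides["duration_us"] = self.duration_us
        if self.expected_events is not None:
            overrides["expected_events"] = self.expected_events
        if self.frame_interval_ns is not None:
            overrides["frame_interval_ns"] = self.frame_interval_ns
        return replace(p, **overrides) if overrides else p

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "seeds" in kwargs:
            kwargs["seeds"] = tuple(int(s) for s in kwargs["seeds"])
        if "analyses" in kwargs:
            kwargs["analyses"] = tuple(kwargs["analyses"])
        return cls(**kwargs)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    per_seed: list[dict]
    failures: list[dict]
    summary: dict


def _mean_se(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, float)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return float(arr.mean()), se


def _analyze_seed(
    params: PresetParams, seed: int, analyses: tuple[str, ...], geom: SFGeometry
) -> dict:
    timeline = simulate_timeline(params, seed)
    traj = render_frames(timeline, geom, seed=seed)
    out: dict = {"seed": seed, "n_ground_truth_events": timeline.n_events()}
    events = None
    if "flux" in analyses or "mechanism" in analyses:
        events = [
            e for e in permeation.detect_events(traj, geom) if e.direction == "outward"
        ]
    if "flux" in analyses:
        n = len(events)
        out["n_events"] = n
        out["flux_per_us"] = permeation.flux(n, params.duration_us)
        out["current_pA"] = permeation.current_pA(n, params.duration_us)
    if "states" in analyses:
        rep = occupancy.exotic_fraction(traj, geom, interval=5.0)
        out["exotic_fraction"] = rep.exotic_fraction
        out["exotic_s4s3_fraction"] = rep.exotic_s4s3_fraction
        out["exotic_s3s2_fraction"] = rep.exotic_s3s2_fraction
    if "mechanism" in analyses:
        labels = [occupancy.classify_mechanism(e, traj, geom) for e in events]
        n_lab = max(len(labels), 1)
        for lab in ("direct", "soft", "mixed", "insufficient"):
            out[f"mechanism_{lab}_fraction"] = labels.count(lab) / n_lab
    if "density" in analyses:
        prof = occupancy.density_profile(traj, geom)
        out["site_occupancy"] = prof.site_occupancy
        out["mean_sf_ions"] = prof.mean_sf_ions
    if "dihedrals" in analyses:
        variances = []
        for chain in "ABCD":
            series = dihedrals.phi_series(traj, "GLY77", chain)
            variances.append(dihedrals.circular_summary(series).variance)
        out["gly77_circular_variance"] = float(np.mean(variances))
    return out


def run_scenario(config: ScenarioConfig, geom: SFGeometry | None = None) -> ScenarioResult:
    """Run every seed of a scenario and aggregate mean +/- SE summaries.

    A failure in one seed is logged and reported in the summary; the other
    seeds still run.  With ``outdir`` set, per-seed JSON records and the
    summary are written (deterministic content, no timestamps)."""
    geom = geom or default_geometry()
    params = config.params()
    per_seed: list[dict] = []
    failures: list[dict] = []
    for seed in config.seeds:
        try:
            per_seed.append(_analyze_seed(params, seed, config.analyses, geom))
        except Exception as exc:  # pragma: no cover - defensive per spec
            log.exception("seed %d failed", seed)
            failures.append({"seed": seed, "error": f"{type(exc).__name__}: {exc}"})

    summary: dict = {
        "preset": params.name,
        "theta_deg": None if params.field is None else params.field.theta,
        "duration_us": params.duration_us,
        "n_seeds": len(per_seed),
        "n_failed": len(failures),
    }
    scalar_keys = sorted(
        {
            k
            for rec in per_seed
            for k, v in rec.items()
            if k != "seed" and isinstance(v, (int, float))
        }
    )
    for key in scalar_keys:
        vals = [rec[key] for rec in per_seed if key in rec]
        mean, se = _mean_se(vals)
        summary[f"{key}_mean"] = mean
        summary[f"{key}_se"] = se

    result = ScenarioResult(config=config, per_seed=per_seed, failures=failures, summary=summary)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec in per_seed:
            (outdir / f"seed_{rec['seed']}.json").write_text(
                json.dumps(rec, indent=2, sort_keys=True) + "\n"
            )
        payload = {"summary": summary, "failures": failures, "config_preset": params.name,
                   "seeds": list(config.seeds), "analyses": list(config.analyses)}
        (outdir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return result


@dataclass
class SweepReport:
    """Consolidated per-angle table with monotonicity diagnostics."""

    rows: list[dict]
    diagnostics: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "sweep.tsv", sep="\t", index=False)
        (outdir / "sweep.json").write_text(
            json.dumps({"rows": self.rows, "diagnostics": self.diagnostics},
                       indent=2, sort_keys=True) + "\n"
        )


def sweep(configs: list[ScenarioConfig], geom: SFGeometry | None = None) -> SweepReport:
    """Run several scenarios (a theta sweep, optionally with no_field) and
    consolidate the per-angle summaries.

    Reports whether flux peaks at theta = 0 deg and bottoms at
    theta = 90 deg, and whether the theta = 90 deg flux sits below the
    no-field flux.  Mixed durations across scenarios trigger a warning;
    fluxes are always per-us rates so rows stay comparable."""
    if len(configs) < 2:
        raise ValueError("a sweep needs at least two scenarios")
    durations = {c.params().duration_us for c in configs}
    if len(durations) > 1:
        warnings.warn(
            "scenarios have mixed durations; comparing per-us fluxes", stacklevel=2
        )

    results = [run_scenario(c, geom) for c in configs]
    rows = []
    for res in results:
        s = res.summary
        rows.append(
            {
                "preset": s["preset"],
                "theta_deg": s["theta_deg"],
                "n_seeds": s["n_seeds"],
                **{k: v for k, v in s.items() if k.endswith(("_mean", "_se"))},
            }
        )
    rows.sort(key=lambda r: (r["theta_deg"] is None, r["theta_deg"]))

    diag: dict = {}
    with_theta = [r for r in rows if r["theta_deg"] is not None and "flux_per_us_mean" in r]
    no_field = [r for r in rows if r["theta_deg"] is None and "flux_per_us_mean" in r]
    if with_theta:
        best = max(with_theta, key=lambda r: r["flux_per_us_mean"])
        worst = min(with_theta, key=lambda r: r["flux_per_us_mean"])
        diag["flux_max_at_theta0"] = best["theta_deg"] == 0.0
        diag["flux_min_at_theta90"] = worst["theta_deg"] == 90.0
        if no_field:
            theta90 = [r for r in with_theta if r["theta_deg"] == 90.0]
            if theta90:
                diag["theta90_below_no_field"] = (
                    theta90[0]["flux_per_us_mean"] < no_field[0]["flux_per_us_mean"]
                )
    return SweepReport(rows=rows, diagnostics=diag)
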