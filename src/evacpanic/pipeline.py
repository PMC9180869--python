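"""Simulate → analyze → report orchestration.

The three stages are plain functions over on-disk artifacts so a whole run
is reproducible from a config file and a master seed:

* :func:`run_simulate` writes a synthetic cohort (recordings + manifest),
* :func:`run_analyze` computes every per-participant indicator into one
  long-form metric table,
* :func:`run_report` turns the metric table into per-family mean/SD/p-value
  contrast tables (CSV) plus a Markdown report.

Every stage writes an effective-config snapshot next to its outputs, and
none of the outputs embed timestamps, so fixed-seed reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import emotion, eye, fnirs, stats, synth
from .timeline import SessionTimeline, build_timeline

log = logging.getLogger("evacpanic")

METRIC_FAMILIES = {
    "basic_emotions": [f"shift_{t}" for t in emotion.BASIC_EMOTIONS],
    "sam": [f"shift_{t}" for t in emotion.SAM_DIMENSIONS],
    "pupil": ["dilation_amplitude"],
    "ratios": ["r_fixation", "r_saccade"],
    "entropy": ["gaze_entropy"],
    "beta": [f"beta_ch{j}" for j in range(1, 9)],
}


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs, serializable to YAML."""

    seed: int = 0
    n_participants: int = 56
    baseline_n: int = 10
    bin_size: float = 10.0
    plane: tuple = eye.DEFAULT_PLANE
    band: tuple = (0.01, 0.1)
    fit_mode: str = "joint"
    alpha: float = 0.05
    paired: bool = True
    holm: bool = False

    def cohort_config(self) -> synth.CohortConfig:
        return synth.CohortConfig(
            n_participants=self.n_participants, seed=self.seed
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v
                 for k, v in dataclasses.asdict(self).items()},
                sort_keys=True,
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("plane", "band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _snapshot(config: PipelineConfig, out_dir: Path) -> None:
    config.to_yaml(out_dir / "effective_config.yaml")


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Write a synthetic cohort; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulating cohort of %d (seed %d) into %s",
             config.n_participants, config.seed, out)
    manifest = synth.simulate_cohort(config.cohort_config(), out)
    _snapshot(config, out)
    return manifest


def analyze_participant(
    eye_rec: eye.EyeRecording,
    fnirs_rec: fnirs.FnirsRecording,
    timeline: SessionTimeline,
    config: PipelineConfig,
) -> list[dict]:
    """All physiological indicators for one participant (long-form rows)."""
    rows = []
    eye_df = eye.eye_metrics(
        eye_rec, timeline,
        baseline_n=config.baseline_n,
        bin_size=config.bin_size,
        plane=config.plane,
    )
    rows += eye_df.to_dict("records")
    est = fnirs.fit_session(
        fnirs_rec, timeline, band=config.band, mode=config.fit_mode
    )
    for scen in synth.STIMULI:
        for j, b in enumerate(est.by_scenario(scen), start=1):
            rows.append(
                {"scenario": scen, "metric": f"beta_ch{j}", "value": float(b)}
            )
    return rows


def run_analyze(
    cohort_dir: str | Path, config: PipelineConfig, out_dir: str | Path
) -> pd.DataFrame:
    """Compute the cohort metric table from an on-disk cohort.

    Participants whose recordings fail to load or analyze are skipped and
    listed in ``errors.log``; the run continues.
    """
    cohort = Path(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        manifest = json.loads((cohort / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise PipelineError(f"unreadable cohort manifest in {cohort}: {exc}")
    if not manifest.get("participants"):
        raise PipelineError(f"cohort in {cohort} lists no participants")

    all_rows: list[dict] = []
    failures: list[str] = []
    for part in manifest["participants"]:
        pid = part["id"]
        try:
            timeline = build_timeline(part["sequence"])
            eye_rec = eye.EyeRecording.from_frame(
                pd.read_csv(cohort / part["eye"]), rate=timeline.eye_rate
            )
            fnirs_rec = fnirs.FnirsRecording.from_frame(
                pd.read_csv(cohort / part["fnirs"]), rate=timeline.fnirs_rate
            )
            rows = analyze_participant(eye_rec, fnirs_rec, timeline, config)
        except Exception as exc:  # corrupt file: log, keep going
            log.error("participant %s failed: %s", pid, exc)
            failures.append(f"{pid}: {exc}")
            continue
        for r in rows:
            r["participant"] = pid
        all_rows += rows

    if not all_rows:
        raise PipelineError("no participant could be analyzed")
    metrics = pd.DataFrame(all_rows)[["participant", "scenario", "metric", "value"]]

    emo_path = cohort / manifest.get("emotions", "emotions.csv")
    if emo_path.exists():
        shifts = emotion.shift_table(pd.read_csv(emo_path))
        # failed participants are excluded wholesale, not just their recordings
        shifts = shifts[shifts["participant"].isin(metrics["participant"].unique())]
        metrics = pd.concat([metrics, shifts], ignore_index=True)
    else:
        log.warning("no questionnaire file in cohort; emotion shifts skipped")

    metrics = metrics.sort_values(
        ["participant", "metric", "scenario"], kind="mergesort"
    ).reset_index(drop=True)
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    (out / "errors.log").write_text("".join(f"{f}\n" for f in failures))
    _snapshot(config, out)
    return metrics


def run_report(
    metrics: str | Path | pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict[str, stats.ContrastTable]:
    """Contrast tables and a Markdown report, one family per indicator group.

    For each family (basic emotions, SAM, pupil, ratios, entropy, β) a
    means table, an SD table and a p-value table are written as CSV, and
    assembled into ``report.md`` with significant contrasts (p < α) in
    bold.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.read_csv(metrics)

    results: dict[str, stats.ContrastTable] = {}
    md: list[str] = ["# Scenario-contrast report", ""]
    for family, names in METRIC_FAMILIES.items():
        sub = metrics[metrics["metric"].isin(names)]
        if sub.empty:
            log.warning("metric family %r absent; skipped", family)
            continue
        table = stats.scenario_contrasts(
            sub, alpha=config.alpha, paired=config.paired, holm=config.holm
        )
        results[family] = table
        table.summary.to_csv(
            out / f"{family}_summary.csv", index=False, float_format="%.6g"
        )
        table.contrasts.to_csv(
            out / f"{family}_contrasts.csv", index=False, float_format="%.6g"
        )
        md += _family_markdown(family, table)
    if not results:
        raise PipelineError("no known metric family present in the metric table")
    (out / "report.md").write_text("\n".join(md) + "\n")
    _snapshot(config, out)
    return results


def _family_markdown(family: str, table: stats.ContrastTable) -> list[str]:
    md = [f"## {family}", ""]
    mean_wide = table.summary.pivot(index="scenario", columns="metric",
                                    values="mean").round(3)
    sd_wide = table.summary.pivot(index="scenario", columns="metric",
                                  values="sd").round(3)
    md += ["### Means", "", mean_wide.to_markdown(), ""]
    md += ["### Standard deviations", "", sd_wide.to_markdown(), ""]
    md += [f"### p-values (bold: p < {table.alpha:g})", ""]
    pv = table.contrasts.copy()
    pv["cell"] = [
        f"**{p:.3f}**" if sig else f"{p:.3f}"
        for p, sig in zip(pv["p"], pv["significant"])
    ]
    pv["contrast"] = pv["scenario_a"] + "-" + pv["scenario_b"]
    p_wide = pv.pivot(index="contrast", columns="metric", values="cell")
    md += [p_wide.to_markdown(), ""]
    return md
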