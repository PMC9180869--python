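"""Scenario-contrast statistics for the cohort indicator tables.

Every indicator is measured within-participant under all scenarios
(repeated measures), so contrasts between scenarios use the paired t-test
on within-participant differences by default; an independent-samples
variant is available behind a switch for sensitivity analysis.  Results are
reported as per-scenario means and sample standard deviations plus a
p-value per contrast pair, flagged significant at α = 0.05 — no
multiple-testing correction by default, with an optional Holm adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


DEFAULT_CONTRASTS = [
    ("Roaming", "Alarm"),
    ("Roaming", "Smoke"),
    ("Roaming", "Flame"),
    ("Alarm", "Smoke"),
    ("Alarm", "Flame"),
    ("Smoke", "Flame"),
]


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on matched per-participant values.

    Returns ``(t, p)`` with p from the t distribution on n−1 degrees of
    freedom.  Degenerate zero-variance differences yield p = 1 when the
    mean difference is 0 and p = 0 otherwise (with a warning), the limiting
    behaviour of the statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    n = d.size
    if n < 2:
        raise StatsError(f"need ≥ 2 complete pairs, got {n}")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        warnings.warn("zero variance of nonzero differences; p → 0 limit")
        return float(np.inf) if d.mean() > 0 else float(-np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def independent_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided independent-samples (pooled-variance) t-test, for sensitivity."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ContrastTable:
    """Per-metric scenario summaries and pairwise contrast statistics.

    ``summary``: metric, scenario, n, mean, sd (sample SD, n−1).
    ``contrasts``: metric, scenario_a, scenario_b, n_pairs, t, p, significant.
    """

    summary: pd.DataFrame
    contrasts: pd.DataFrame
    alpha: float


def scenario_contrasts(
    table: pd.DataFrame,
    contrasts: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    *,
    paired: bool = True,
    holm: bool = False,
) -> ContrastTable:
    """Mean/SD summaries and pairwise tests for a long-form metric table.

    Parameters
    ----------
    table : DataFrame
        Columns ``participant, scenario, metric, value``; one value per
        (participant, scenario, metric).
    contrasts : list of (scenario, scenario), optional
        Pairs to test.  By default every pair of ``DEFAULT_CONTRASTS`` whose
        two scenarios both carry values for the metric — so indicators
        without a Roaming measurement (shifts, dilation amplitude, β) get
        only the three stimulus-pair contrasts, while the ratios and gaze
        entropy are also contrasted against Roaming.
    alpha : float
        Significance level for flagging; p-values themselves are reported
        unadjusted unless ``holm`` is set.
    paired : bool
        Paired (within-participant) t-test when True, else pooled-variance
        independent test.
    holm : bool
        Apply a Holm step-down adjustment within each metric.
    """
    required = {"participant", "scenario", "metric", "value"}
    if not required <= set(table.columns):
        raise StatsError(f"metric table must have columns {sorted(required)}")
    if not 0.0 <= alpha <= 1.0:
        raise StatsError("alpha must lie in [0, 1]")
    dup = table.duplicated(["participant", "scenario", "metric"])
    if dup.any():
        raise StatsError("multiple values per (participant, scenario, metric)")

    summary_rows = []
    contrast_rows = []
    test = paired_t if paired else independent_t
    for metric, sub in table.groupby("metric", sort=True):
        wide = sub.pivot(index="participant", columns="scenario", values="value")
        have = set(wide.columns)
        for scen in [s for s in ("Roaming", "Alarm", "Smoke", "Flame") if s in have]:
            vals = wide[scen].dropna()
            summary_rows.append(
                {
                    "metric": metric,
                    "scenario": scen,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                }
            )
        pairs = contrasts if contrasts is not None else [
            p for p in DEFAULT_CONTRASTS if set(p) <= have
        ]
        metric_rows = []
        for sa, sb in pairs:
            if sa not in have or sb not in have:
                raise StatsError(f"metric {metric!r} lacks scenario {sa!r} or {sb!r}")
            pair = wide[[sa, sb]].dropna()
            t, p = test(pair[sa].to_numpy(), pair[sb].to_numpy())
            metric_rows.append(
                {
                    "metric": metric,
                    "scenario_a": sa,
                    "scenario_b": sb,
                    "n_pairs": int(len(pair)),
                    "t": t,
                    "p": p,
                }
            )
        if holm and metric_rows:
            ps = np.array([r["p"] for r in metric_rows])
            order = np.argsort(ps)
            m = len(ps)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * ps[idx])
                adj[idx] = min(1.0, running)
            for r, pa in zip(metric_rows, adj):
                r["p"] = float(pa)
        for r in metric_rows:
            r["significant"] = bool(r["p"] < alpha)
        contrast_rows.extend(metric_rows)

    return ContrastTable(
        summary=pd.DataFrame(
            summary_rows, columns=["metric", "scenario", "n", "mean", "sd"]
        ),
        contrasts=pd.DataFrame(
            contrast_rows,
            columns=["metric", "scenario_a", "scenario_b", "n_pairs",
                     "t", "p", "significant"],
        ),
        alpha=alpha,
    )
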