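"""Nonparametric group-level statistics.

Mirrors the study's statistical layer: controls are averaged over their
repeat scans, groups are compared with a Kruskal–Wallis omnibus followed by
pairwise two-sample Wilcoxon rank-sum tests (normal approximation with
continuity correction by default; exact enumeration for small samples),
ordered-recovery trends use Kendall's tau-b, and 2x2 categorical tables use
Fisher's exact test (two-sided, sum of probabilities no larger than the
observed table's).  No multiplicity correction is applied by default,
matching the original reporting; Holm adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import ParameterError


class UndefinedStatistic(ValueError):
    """The statistic is undefined for this input (e.g. all values tied)."""


@dataclass
class StatResult:
    method: str
    statistic: float
    p_value: float
    df: int | None = None
    group_sizes: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)


#: Ordinal codings for the trend test, worst outcome highest.
ORDINAL_SHORT = {"Control": 0, "AR": 1, "EMCS": 1, "AR'": 1, "No AR": 2}
ORDINAL_LONG = {"Control": 0, "EMCS": 1, "AR'": 2, "No AR": 3}

GROUPS_SHORT = ("Control", "AR", "No AR")
GROUPS_LONG = ("Control", "EMCS", "AR'", "No AR")


def control_aggregate(
    table: pd.DataFrame, control_group: str = "Control"
) -> pd.DataFrame:
    """Collapse repeat scans to one value per participant per metric.

    Controls (and any participant with repeat scans) are averaged over
    their scans; the result has one row per (participant, metric).
    """
    required = {"participant_id", "group", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"metric table missing columns {sorted(missing)}")
    out = (
        table.groupby(["participant_id", "group", "metric"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    return out


def kruskal_wallis(*groups) -> StatResult:
    """Kruskal–Wallis rank-sum test with tie correction; chi-square p."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ParameterError("need >= 2 nonempty groups")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        raise UndefinedStatistic("all values identical; H is undefined")
    h, p = sps.kruskal(*samples)
    return StatResult(
        method="kruskal-wallis",
        statistic=float(h),
        p_value=float(p),
        df=len(samples) - 1,
        group_sizes=tuple(s.size for s in samples),
    )


def wilcoxon_rank_sum(
    x, y, method: str = "approximate", continuity: bool = True
) -> StatResult:
    """Two-sample Wilcoxon rank-sum test.

    ``approximate``: normal approximation with tie-corrected variance and
    (by default) continuity correction.  ``exact``: enumeration over all
    rank assignments (small samples, no ties).
    Reports W = rank sum of ``x`` in the pooled ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    if method == "approximate":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=continuity,
        )
    elif method == "exact":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        raise ParameterError(f"unknown Wilcoxon method {method!r}")
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return StatResult(
        method=f"wilcoxon-rank-sum-{method}",
        statistic=w,
        p_value=float(res.pvalue),
        group_sizes=(x.size, y.size),
        extra={"U": float(res.statistic)},
    )


def kendall_tau(ordinal, values) -> StatResult:
    """Kendall's tau-b of metric values against ordered group codes,
    two-sided p from the tie-adjusted normal approximation."""
    ordinal = np.asarray(ordinal, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.unique(ordinal).size < 2:
        raise UndefinedStatistic("all ordinal codes tied; tau is undefined")
    res = sps.kendalltau(ordinal, values, variant="b", method="asymptotic")
    return StatResult(
        method="kendall-tau-b",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(ordinal.size,),
    )


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    Degenerate tables (a zero margin) carry no information and return p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.array_equal(t, t.astype(np.int64)):
        raise ParameterError("table must be 2x2 non-negative integers")
    t = t.astype(np.int64)
    margins = list(t.sum(axis=0)) + list(t.sum(axis=1))
    if min(margins) == 0:
        return StatResult(
            method="fisher-exact",
            statistic=float("nan"),
            p_value=1.0,
            extra={"odds_ratio": float("nan"), "degenerate": True},
        )
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return StatResult(
        method="fisher-exact",
        statistic=float(odds),
        p_value=float(p),
        extra={"odds_ratio": float(odds)},
    )


def holm_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def run_group_analysis(
    metrics: pd.DataFrame,
    design: str = "short",
    continuity: bool = True,
    holm: bool = False,
) -> pd.DataFrame:
    """Per metric: Kruskal–Wallis omnibus, all pairwise Wilcoxon post-hocs,
    and the ordered Kendall trend.  ``metrics`` must already be aggregated
    (one value per participant per metric).

    In the short-term design, EMCS and AR' participants are pooled into AR.
    """
    if design == "short":
        group_names, ordinal = GROUPS_SHORT, ORDINAL_SHORT
        mapping = {"EMCS": "AR", "AR'": "AR"}
    elif design == "long":
        group_names, ordinal = GROUPS_LONG, ORDINAL_LONG
        mapping = {}
    else:
        raise ParameterError(f"unknown design {design!r}")
    df = metrics.copy()
    df["group"] = df["group"].replace(mapping)
    present = set(df["group"])
    absent = [g for g in group_names if g not in present]
    if absent:
        raise ParameterError(f"design {design!r} missing groups {absent}")

    rows = []
    for metric, sub in df.groupby("metric", sort=False):
        samples = {g: sub.loc[sub["group"] == g, "value"].to_numpy() for g in group_names}
        kw = kruskal_wallis(*samples.values())
        rows.append((metric, "omnibus", kw))
        for i in range(len(group_names)):
            for j in range(i + 1, len(group_names)):
                a, b = group_names[i], group_names[j]
                res = wilcoxon_rank_sum(
                    samples[a], samples[b], method="approximate",
                    continuity=continuity,
                )
                rows.append((metric, f"{a} vs {b}", res))
        codes = sub["group"].map(ordinal).to_numpy()
        kt = kendall_tau(codes, sub["value"].to_numpy())
        rows.append((metric, "ordered trend", kt))

    out = pd.DataFrame(
        {
            "metric": [r[0] for r in rows],
            "comparison": [r[1] for r in rows],
            "method": [r[2].method for r in rows],
            "statistic": [r[2].statistic for r in rows],
            "df": [r[2].df for r in rows],
            "p": [r[2].p_value for r in rows],
        }
    )
    if holm:
        out["p_holm"] = np.nan
        for metric in out["metric"].unique():
            sel = (out["metric"] == metric) & out["method"].str.startswith(
                "wilcoxon"
            )
            out.loc[sel, "p_holm"] = holm_adjust(out.loc[sel, "p"].to_numpy())
    return out
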