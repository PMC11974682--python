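"""Integration of tail metrics with transcript stability and translation.

Differential transcript-accumulation and differential-translation result
tables are produced upstream (negative-binomial Wald tests and translational
efficiency models respectively) and consumed here as tab-separated tables
with transcript id, log2 fold change, p and Benjamini-Hochberg q columns.
Transcripts are grouped as up / down / others at a q threshold —
down-regulated transcripts are read as unstable through spermiogenesis, and
up-regulated ones as stable — and tail metrics are compared across groups
with a Kruskal-Wallis test followed by Bonferroni-adjusted pairwise
rank-sum tests, or related to a second metric with an ordinary
least-squares fit plus per-group medians.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "LABEL_TABLE_COLUMNS",
    "GroupComparisonResult",
    "AssociationSummary",
    "classify_transcripts",
    "grouped_distribution_test",
    "association",
    "call_tent5c_targets",
    "intersect_targets",
]

#: Default column dialect of external differential-result tables.
LABEL_TABLE_COLUMNS: dict[str, str] = {
    "transcript_id": "transcript_id",
    "log2fc": "log2fc",
    "p_value": "pvalue",
    "q_value": "qvalue",
}

GROUP_ORDER = ("up", "others", "down")


def classify_transcripts(
    table: pd.DataFrame,
    q_threshold: float = 0.05,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Label transcripts up / down / others from a differential-result table.

    ``up`` requires ``q <= q_threshold`` and ``log2fc > 0``; ``down``
    requires ``q <= q_threshold`` and ``log2fc < 0``; everything else
    (including q exactly missing) is ``others``.  Returns transcript_id,
    log2fc, p_value, q_value, group.
    """
    columns = dict(LABEL_TABLE_COLUMNS if columns is None else columns)
    for logical in ("transcript_id", "log2fc"):
        if columns[logical] not in table.columns:
            raise ValueError(f"label table is missing column {columns[logical]!r}")
    if columns["q_value"] not in table.columns:
        raise ValueError(
            f"label table is missing the adjusted-p column {columns['q_value']!r}; "
            "compute Benjamini-Hochberg q-values upstream before classification"
        )
    out = pd.DataFrame(
        {
            "transcript_id": table[columns["transcript_id"]].astype(str),
            "log2fc": pd.to_numeric(table[columns["log2fc"]]),
            "p_value": pd.to_numeric(table[columns["p_value"]])
            if columns["p_value"] in table.columns
            else np.nan,
            "q_value": pd.to_numeric(table[columns["q_value"]]),
        }
    )
    sig = out["q_value"] <= q_threshold
    out["group"] = np.where(
        sig & (out["log2fc"] > 0), "up", np.where(sig & (out["log2fc"] < 0), "down", "others")
    )
    counts = out["group"].value_counts().to_dict()
    log.info("classified transcripts: %s", counts)
    return out


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis comparison of a metric across transcript groups."""

    group_sizes: dict[str, int]
    kw_statistic: float
    kw_p: float
    pairwise: dict[tuple[str, str], float]
    pairwise_raw: dict[tuple[str, str], float] = field(default_factory=dict)
    group_medians: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Kruskal-Wallis group comparison", "=" * 40]
        lines.append(f"H = {self.kw_statistic:.4g}, p = {self.kw_p:.4g}")
        for g, n in self.group_sizes.items():
            lines.append(f"  {g:>8}: n = {n}, median = {self.group_medians.get(g, float('nan')):.4g}")
        lines.append("Pairwise rank-sum tests (Bonferroni-adjusted):")
        for (a, b), p in self.pairwise.items():
            lines.append(f"  {a} vs {b}: p = {p:.4g}")
        return "\n".join(lines)


def grouped_distribution_test(
    metric: pd.Series, labels: pd.DataFrame | pd.Series
) -> GroupComparisonResult:
    """Compare a per-transcript metric across up/down/others groups.

    ``metric`` is indexed by transcript id; ``labels`` is either a Series of
    group names indexed by transcript id or a frame from
    :func:`classify_transcripts`.  Transcripts absent from the labels
    default to group ``"others"``; groups with fewer than two members are
    excluded with a warning.  The omnibus test is Kruskal-Wallis (average
    ranks for ties, chi-square approximation); post-hoc pairwise tests are
    two-sided Wilcoxon rank-sum tests Bonferroni-adjusted over all pairs.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("transcript_id")["group"]
    metric = metric.dropna()
    groups = labels.reindex(metric.index).fillna("others")
    by_group: dict[str, np.ndarray] = {}
    for name, vals in metric.groupby(groups):
        if len(vals) < 2:
            log.warning("group %r has < 2 members; excluded from the comparison", name)
            continue
        by_group[str(name)] = vals.to_numpy(float)
    if len(by_group) < 2:
        raise ValueError("need at least two non-empty groups")
    ordered = [g for g in GROUP_ORDER if g in by_group] + sorted(
        set(by_group) - set(GROUP_ORDER)
    )
    samples = [by_group[g] for g in ordered]
    try:
        kw_stat, kw_p = sps.kruskal(*samples)
    except ValueError:  # all values identical
        kw_stat, kw_p = 0.0, 1.0
    pairs = list(itertools.combinations(ordered, 2))
    pairwise_raw: dict[tuple[str, str], float] = {}
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        p = sps.ranksums(by_group[a], by_group[b]).pvalue
        pairwise_raw[(a, b)] = float(p)
        pairwise[(a, b)] = min(1.0, float(p) * len(pairs))
    return GroupComparisonResult(
        group_sizes={g: len(by_group[g]) for g in ordered},
        kw_statistic=float(kw_stat),
        kw_p=float(kw_p),
        pairwise=pairwise,
        pairwise_raw=pairwise_raw,
        group_medians={g: float(np.median(by_group[g])) for g in ordered},
    )


@dataclass
class AssociationSummary:
    """Ordinary least-squares association between two per-transcript metrics."""

    slope: float
    intercept: float
    stderr: float
    r_value: float
    p_value: float
    n: int
    group_medians: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.slope)

    def summary(self) -> str:
        if not self.defined:
            return f"OLS fit undefined (zero variance in x), n = {self.n}"
        lines = [
            f"OLS fit: y = {self.slope:.4g} x + {self.intercept:.4g} "
            f"(se = {self.stderr:.3g}, r = {self.r_value:.3f}, p = {self.p_value:.3g}, n = {self.n})"
        ]
        for g, (mx, my) in self.group_medians.items():
            lines.append(f"  {g:>8}: median x = {mx:.4g}, median y = {my:.4g}")
        return "\n".join(lines)


def association(
    x: pd.Series, y: pd.Series, labels: pd.DataFrame | pd.Series | None = None
) -> AssociationSummary:
    """OLS slope/intercept between two transcript metrics, with group medians.

    Only transcripts with finite values of both metrics enter the fit (at
    least three are required).  If ``x`` has zero variance the slope is
    undefined and reported as NaN.  When labels are given, the median of
    both metrics is reported within each group.
    """
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    df = df[np.isfinite(df["x"]) & np.isfinite(df["y"])]
    if len(df) < 3:
        raise ValueError("association requires at least 3 finite (x, y) pairs")
    if np.ptp(df["x"].to_numpy()) == 0:
        log.warning("zero variance in x: slope undefined")
        res = AssociationSummary(np.nan, np.nan, np.nan, np.nan, np.nan, len(df))
    else:
        fit = sps.linregress(df["x"], df["y"])
        res = AssociationSummary(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            stderr=float(fit.stderr),
            r_value=float(fit.rvalue),
            p_value=float(fit.pvalue),
            n=len(df),
        )
    if labels is not None:
        if isinstance(labels, pd.DataFrame):
            labels = labels.set_index("transcript_id")["group"]
        groups = labels.reindex(df.index).fillna("others")
        for g, sub in df.groupby(groups):
            res.group_medians[str(g)] = (
                float(sub["x"].median()),
                float(sub["y"].median()),
            )
    return res


def call_tent5c_targets(
    differential: pd.DataFrame, direction: str = "-"
) -> pd.DataFrame:
    """Transcripts whose tails change significantly in the given direction.

    With the default ``direction="-"`` this returns the transcripts whose
    poly(A) tails are significantly shorter in the second condition of the
    differential table — the operational definition of a poly(A) polymerase
    target when the comparison is wild type versus a catalytically dead
    mutant.  Sorted by effect size (most extreme delta first) then p-value.
    """
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    hits = differential[differential["class"] == direction].copy()
    hits = hits.sort_values(
        ["delta", "p_value"], ascending=[direction == "-", True], kind="stable"
    )
    return hits.reset_index(drop=True)


def intersect_targets(*target_tables: pd.DataFrame) -> list[str]:
    """Transcripts called as targets in every table (cross-study intersection)."""
    sets = [set(t["transcript_id"]) for t in target_tables]
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)
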