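"""Per-transcript poly(A) tail statistics.

The statistics implemented here follow the standard downstream treatment of
signal-level tail estimates from direct RNA sequencing of spermatogenic
cells: transcripts are prefiltered (at least ``min_reads`` reads in at least
``min_replicates`` replicates of one condition), the mean tail length of
each transcript is computed per replicate and compared between conditions
with a two-tailed Welch t-test on the replicate means, and the occupancy of
named tail-length windows — [30, 120) nt reported as "~60-nt" tails and
[120, 210) nt reported as "~150-nt" tails — is expressed as a percentage of
each transcript's reads.  Global tail-length distributions are summarised as
per-replicate histograms with a locally weighted polynomial (degree-2,
tricube-weight) smooth per condition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "TailWindow",
    "WINDOW_60NT",
    "WINDOW_150NT",
    "DEFAULT_WINDOWS",
    "DensityProfile",
    "prefilter_transcripts",
    "summarize_tails",
    "differential_mean_tail",
    "window_fraction_change",
    "tail_length_density",
]


@dataclass(frozen=True)
class TailWindow:
    """A half-open tail-length interval [lower, upper) in nucleotides."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window {self.name!r}: lower must be < upper")

    def contains(self, tails: np.ndarray) -> np.ndarray:
        return (tails >= self.lower) & (tails < self.upper)

    @property
    def column(self) -> str:
        return f"pct_{self.name}"


#: Reads with tails in [30, 120) nt, reported as "~60-nt" poly(A) tails.
WINDOW_60NT = TailWindow("~60-nt", 30.0, 120.0)
#: Reads with tails in [120, 210) nt, reported as "~150-nt" poly(A) tails.
WINDOW_150NT = TailWindow("~150-nt", 120.0, 210.0)
DEFAULT_WINDOWS: tuple[TailWindow, ...] = (WINDOW_60NT, WINDOW_150NT)

_GROUP = ["transcript_id", "condition", "replicate"]


def _check_windows(windows: Sequence[TailWindow]) -> tuple[TailWindow, ...]:
    windows = tuple(windows)
    for i, a in enumerate(windows):
        for b in windows[i + 1 :]:
            if a.lower < b.upper and b.lower < a.upper:
                raise ValueError(f"windows {a.name!r} and {b.name!r} overlap")
    return windows


def prefilter_transcripts(
    records: pd.DataFrame, min_reads: int = 10, min_replicates: int = 2
) -> list[str]:
    """Transcripts with >= ``min_reads`` reads in >= ``min_replicates``
    replicates of at least one condition.

    Operates on filtered, fully labelled read records.  Returns a sorted
    list of transcript ids.
    """
    if records.empty:
        return []
    counts = records.groupby(_GROUP, observed=True).size()
    enough = (counts >= min_reads).groupby(level=["transcript_id", "condition"]).sum()
    kept = enough[enough >= min_replicates].index.get_level_values("transcript_id")
    return sorted(set(kept))


def summarize_tails(
    records: pd.DataFrame, windows: Sequence[TailWindow] = DEFAULT_WINDOWS
) -> pd.DataFrame:
    """Per transcript x condition x replicate read counts, mean tail length
    and tail-window percentages.

    ``pct_<window>`` is 100 x (reads with lower <= tail < upper) / n_reads.
    Groups without reads simply do not appear.
    """
    windows = _check_windows(windows)
    work = records[_GROUP + ["tail_length"]].copy()
    for w in windows:
        work[w.column] = w.contains(work["tail_length"].to_numpy(float))
    agg = {"tail_length": ["size", "mean"]}
    agg.update({w.column: "sum" for w in windows})
    g = work.groupby(_GROUP, observed=True).agg(agg)
    out = pd.DataFrame(
        {
            "n_reads": g[("tail_length", "size")].astype(int),
            "mean_tail": g[("tail_length", "mean")],
        }
    )
    for w in windows:
        out[w.column] = 100.0 * g[(w.column, "sum")] / out["n_reads"]
    return out.reset_index()


def _welch_from_stats(
    mean_a: np.ndarray,
    var_a: np.ndarray,
    n_a: np.ndarray,
    mean_b: np.ndarray,
    var_b: np.ndarray,
    n_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch two-sample two-tailed t-test from summary statistics.

    Degenerate groups (both variances zero) get p = 1 when the means agree
    and p = 0 otherwise, so constant synthetic fixtures remain classifiable.
    """
    mean_a, var_a, n_a = (np.asarray(x, float) for x in (mean_a, var_a, n_a))
    mean_b, var_b, n_b = (np.asarray(x, float) for x in (mean_b, var_b, n_b))
    delta = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        sa, sb = var_a / n_a, var_b / n_b
        se = np.sqrt(sa + sb)
        t = delta / se
        df = (sa + sb) ** 2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = (var_a == 0) & (var_b == 0)
    with np.errstate(invalid="ignore"):
        p = np.where(degenerate, np.where(delta == 0.0, 1.0, 0.0), p)
        t = np.where(degenerate & (delta == 0.0), 0.0, t)
        t = np.where(degenerate & (delta != 0.0), np.sign(delta) * np.inf, t)
    return t, p


def differential_mean_tail(
    summaries: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    level: str = "replicate",
    records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differential mean poly(A) tail length between two conditions.

    The default (``level="replicate"``) compares the per-replicate mean tail
    lengths of each transcript with a Welch two-sample two-tailed t-test, so
    the biological replicate — not the read — is the unit of inference.
    ``level="read"`` instead pools all reads per condition (an exploratory
    variant).  Transcripts are classified ``"+"`` (longer in B), ``"-"``
    (shorter in B) when ``p <= alpha``, else ``"ns"``; transcripts with fewer
    than two replicates (or reads) per condition are reported as
    ``"not_testable"``.  Benjamini-Hochberg ``q_value`` over all testable
    transcripts is reported alongside but does not drive the default class.

    Returns a frame with columns transcript_id, n_a, n_b, mean_a, mean_b,
    delta (B - A), t_stat, p_value, q_value, class.
    """
    if level == "replicate":
        src = summaries
        value = "mean_tail"
    elif level == "read":
        if records is None:
            raise ValueError("level='read' requires the read records")
        src = records
        value = "tail_length"
    else:
        raise ValueError(f"unknown level {level!r}")

    sub = src[src["condition"].isin([condition_a, condition_b])]
    g = sub.groupby(["transcript_id", "condition"], observed=True)[value].agg(
        ["count", "mean", "var"]
    )
    wide = g.unstack("condition")
    for cond in (condition_a, condition_b):
        if ("count", cond) not in wide.columns:
            wide[("count", cond)] = 0
            wide[("mean", cond)] = np.nan
            wide[("var", cond)] = np.nan
    n_a = wide[("count", condition_a)].fillna(0).to_numpy(float)
    n_b = wide[("count", condition_b)].fillna(0).to_numpy(float)
    mean_a = wide[("mean", condition_a)].to_numpy(float)
    mean_b = wide[("mean", condition_b)].to_numpy(float)
    var_a = wide[("var", condition_a)].to_numpy(float)
    var_b = wide[("var", condition_b)].to_numpy(float)

    testable = (n_a >= 2) & (n_b >= 2)
    t = np.full(len(wide), np.nan)
    p = np.full(len(wide), np.nan)
    if testable.any():
        t[testable], p[testable] = _welch_from_stats(
            mean_a[testable], var_a[testable], n_a[testable],
            mean_b[testable], var_b[testable], n_b[testable],
        )
    q = np.full(len(wide), np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]

    delta = mean_b - mean_a
    cls = np.where(
        ~testable,
        "not_testable",
        np.where(
            (p <= alpha) & (delta > 0),
            "+",
            np.where((p <= alpha) & (delta < 0), "-", "ns"),
        ),
    )
    out = pd.DataFrame(
        {
            "transcript_id": wide.index,
            "n_a": n_a.astype(int),
            "n_b": n_b.astype(int),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta": delta,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "class": cls,
        }
    ).reset_index(drop=True)
    return out


def window_fraction_change(
    summaries: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    window: TailWindow | str = WINDOW_60NT,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-transcript fold change of a tail-window occupancy between conditions.

    For each transcript present in both conditions, the replicate window
    percentages are averaged per condition and the log2 fold change is
    computed with a small pseudocount (percentage points) guarding against
    empty windows::

        lfc = log2((mean%_B + pc) / (mean%_A + pc))
    """
    col = window.column if isinstance(window, TailWindow) else f"pct_{window}"
    if col not in summaries.columns:
        raise ValueError(f"summaries lack window column {col!r}")
    m = (
        summaries[summaries["condition"].isin([condition_a, condition_b])]
        .groupby(["transcript_id", "condition"], observed=True)[col]
        .mean()
        .unstack("condition")
    )
    if condition_a not in m.columns or condition_b not in m.columns:
        return pd.DataFrame(columns=["transcript_id", "mean_pct_a", "mean_pct_b", "log2fc"])
    m = m.dropna(subset=[condition_a, condition_b])
    lfc = np.log2((m[condition_b] + pseudocount) / (m[condition_a] + pseudocount))
    return pd.DataFrame(
        {
            "transcript_id": m.index,
            "mean_pct_a": m[condition_a].to_numpy(),
            "mean_pct_b": m[condition_b].to_numpy(),
            "log2fc": lfc.to_numpy(),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# tail-length density profiles


@dataclass
class DensityProfile:
    """Binned tail-length distribution of one condition.

    ``per_replicate_percent`` holds one row per replicate (percentages per
    bin, summing to 100); ``smoothed`` is the locally weighted polynomial
    regression curve fitted through all replicate points on the same grid.
    """

    condition: str
    bin_centers: np.ndarray
    per_replicate_percent: pd.DataFrame
    smoothed: np.ndarray
    bin_width: float


def _local_poly_smooth(
    x: np.ndarray,
    y: np.ndarray,
    eval_x: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    At each evaluation point the ``ceil(span * n)`` nearest observations are
    fitted with a weighted degree-``degree`` polynomial; the fitted value at
    the point is returned.  This is the classic LOESS estimator; a local
    quadratic is used so that peak heights are not flattened.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(len(eval_x))
    for i, x0 in enumerate(np.asarray(eval_x, float)):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        t = x[idx] - x0
        design = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def tail_length_density(
    records: pd.DataFrame,
    bin_width: float = 5.0,
    x_max: float = 350.0,
    span: float = 0.3,
    weighting: str = "read",
) -> dict[str, DensityProfile]:
    """Tail-length histograms per replicate plus a smoothed condition curve.

    Per replicate, tail lengths are binned on [0, ``x_max``) (``bin_width``
    nt bins; longer tails are counted in the last bin so percentages always
    sum to 100).  ``weighting="read"`` weights every read equally;
    ``weighting="transcript"`` computes each transcript's own histogram
    percentage first and averages those, weighting every transcript equally.
    The condition curve is a degree-2 tricube-weighted local regression
    through the per-replicate bin percentages.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if weighting not in ("read", "transcript"):
        raise ValueError(f"unknown weighting {weighting!r}")
    edges = np.arange(0.0, x_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    profiles: dict[str, DensityProfile] = {}
    for condition, cond_df in records.groupby("condition", observed=True):
        rows = {}
        for replicate, rep_df in cond_df.groupby("replicate", observed=True):
            tails = np.clip(rep_df["tail_length"].to_numpy(float), 0.0, edges[-1] - 1e-9)
            if weighting == "read":
                counts, _ = np.histogram(tails, bins=edges)
                rows[replicate] = 100.0 * counts / counts.sum()
            else:
                per_tx = []
                for _, tx_df in rep_df.groupby("transcript_id", observed=True):
                    tx_tails = np.clip(
                        tx_df["tail_length"].to_numpy(float), 0.0, edges[-1] - 1e-9
                    )
                    c, _ = np.histogram(tx_tails, bins=edges)
                    per_tx.append(100.0 * c / c.sum())
                rows[replicate] = np.mean(per_tx, axis=0)
        rep_pct = pd.DataFrame.from_dict(rows, orient="index", columns=centers)
        rep_pct.index.name = "replicate"
        x_all = np.tile(centers, len(rep_pct))
        y_all = rep_pct.to_numpy().ravel()
        smoothed = _local_poly_smooth(x_all, y_all, centers, span=span)
        profiles[str(condition)] = DensityProfile(
            condition=str(condition),
            bin_centers=centers,
            per_replicate_percent=rep_pct,
            smoothed=smoothed,
            bin_width=bin_width,
        )
    return profiles
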