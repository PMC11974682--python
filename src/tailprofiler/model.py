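"""Model/results interface tying the pipeline stages together.

:class:`TailProfile` is built from a fully labelled read-record frame (or
directly from the on-disk tail/demux tables); ``fit()`` applies the
transcript prefilter and computes the per-replicate summaries, returning a
:class:`TailProfileResults` from which condition comparisons, window-change
tables, density profiles and plots are derived.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ingest, integrate, tailprofile
from .ingest import BarcodeMap, FilterReport
from .tailprofile import DEFAULT_WINDOWS, DensityProfile, TailWindow

__all__ = ["TailProfile", "TailProfileResults", "DifferentialTailResults"]


class TailProfile:
    """Per-transcript poly(A) tail profile model of a labelled read set.

    Parameters
    ----------
    records
        Fully labelled read records (one row per read with ``transcript_id``,
        ``tail_length``, ``condition`` and ``replicate`` columns), normally
        the output of the ingest pipeline.
    windows
        Named half-open tail-length windows; defaults to the "~60-nt"
        ([30, 120) nt) and "~150-nt" ([120, 210) nt) windows.
    min_reads, min_replicates
        Transcript prefilter: keep transcripts with at least ``min_reads``
        reads in at least ``min_replicates`` replicates of one condition.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        windows: Sequence[TailWindow] = DEFAULT_WINDOWS,
        min_reads: int = 10,
        min_replicates: int = 2,
    ) -> None:
        required = {"transcript_id", "tail_length", "condition", "replicate"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records lack column(s): {', '.join(sorted(missing))}")
        self.records = records
        self.windows = tuple(windows)
        self.min_reads = int(min_reads)
        self.min_replicates = int(min_replicates)
        self.filter_report: FilterReport | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, **kwargs) -> "TailProfile":
        return cls(records, **kwargs)

    @classmethod
    def from_files(
        cls,
        tail_paths: Mapping[str, str | Path],
        demux_paths: Mapping[str, str | Path],
        barcode_maps: Mapping[str, BarcodeMap],
        design: Mapping[str, tuple[str, int]],
        min_confidence: float = 0.85,
        require_pass: bool = True,
        **kwargs,
    ) -> "TailProfile":
        """Build the model from per-condition tail and demux tables on disk."""
        frames = []
        report = FilterReport(0, 0, {})
        for condition, tail_path in tail_paths.items():
            recs = ingest.parse_tail_table(tail_path)
            demux = (
                ingest.parse_demux_table(demux_paths[condition])
                if condition in demux_paths
                else None
            )
            kept, rep = ingest.merge_and_filter(
                recs, demux, min_confidence=min_confidence, require_pass=require_pass
            )
            frames.append(ingest.assign_labels(kept, barcode_maps[condition], design))
            report = report + rep
        model = cls(pd.concat(frames, ignore_index=True), **kwargs)
        model.filter_report = report
        return model

    @classmethod
    def from_simulation(cls, dataset, min_confidence: float = 0.85, **kwargs) -> "TailProfile":
        """Build the model from a :class:`~tailprofiler.synthdata.SimulatedDataset`."""
        records, report = dataset.to_records(min_confidence=min_confidence)
        model = cls(records, **kwargs)
        model.filter_report = report
        return model

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "TailProfileResults":
        kept = tailprofile.prefilter_transcripts(
            self.records, self.min_reads, self.min_replicates
        )
        used = self.records[self.records["transcript_id"].isin(kept)]
        summaries = tailprofile.summarize_tails(used, self.windows)
        return TailProfileResults(self, summaries, kept, used)


@dataclass
class DifferentialTailResults:
    """Differential mean-tail comparison between two conditions."""

    condition_a: str
    condition_b: str
    alpha: float
    table: pd.DataFrame

    @property
    def class_counts(self) -> dict[str, int]:
        return self.table["class"].value_counts().to_dict()

    def targets(self, direction: str = "-") -> pd.DataFrame:
        """Transcripts significantly changed in the given direction."""
        return integrate.call_tent5c_targets(self.table, direction)

    def summary(self, top: int = 10) -> str:
        counts = self.class_counts
        tested = len(self.table[self.table["class"] != "not_testable"])
        lines = [
            f"Differential poly(A) tail length: {self.condition_b} vs {self.condition_a}",
            "=" * 64,
            f"transcripts tested: {tested} (alpha = {self.alpha}, Welch t-test on replicate means)",
            f"longer (+): {counts.get('+', 0)}   shorter (-): {counts.get('-', 0)}   "
            f"ns: {counts.get('ns', 0)}   not testable: {counts.get('not_testable', 0)}",
            "",
            f"{'transcript':<16}{'mean_A':>9}{'mean_B':>9}{'delta':>9}{'t':>9}{'p':>11}  class",
        ]
        show = self.table.reindex(
            self.table["p_value"].sort_values(na_position="last").index
        ).head(top)
        for _, r in show.iterrows():
            lines.append(
                f"{r['transcript_id']:<16}{r['mean_a']:>9.2f}{r['mean_b']:>9.2f}"
                f"{r['delta']:>9.2f}{r['t_stat']:>9.3f}{r['p_value']:>11.3g}  {r['class']}"
            )
        return "\n".join(lines)


class TailProfileResults:
    """Fitted per-transcript tail summaries and derived comparisons."""

    def __init__(
        self,
        model: TailProfile,
        summaries: pd.DataFrame,
        kept_transcripts: list[str],
        records_used: pd.DataFrame,
    ) -> None:
        self.model = model
        self.summaries = summaries
        self.kept_transcripts = kept_transcripts
        self._records = records_used

    @property
    def conditions(self) -> list[str]:
        return sorted(self.summaries["condition"].unique())

    def summary(self) -> str:
        lines = [
            "Poly(A) tail profile",
            "=" * 48,
            f"transcripts kept by prefilter (>= {self.model.min_reads} reads in "
            f">= {self.model.min_replicates} replicates of one condition): "
            f"{len(self.kept_transcripts)}",
            f"reads used: {len(self._records)}",
        ]
        if self.model.filter_report is not None:
            lines.append(f"ingest filter: {self.model.filter_report}")
        g = self.summaries.groupby("condition")
        lines.append("")
        header = f"{'condition':<12}{'replicates':>11}{'reads':>10}{'mean tail (nt)':>16}"
        for w in self.model.windows:
            header += f"{w.name + ' %':>12}"
        lines.append(header)
        for cond, sub in g:
            reads = int(sub["n_reads"].sum())
            mean_tail = float(
                np.average(sub["mean_tail"], weights=sub["n_reads"])
            )
            row = (
                f"{cond:<12}{sub['replicate'].nunique():>11}{reads:>10}"
                f"{mean_tail:>16.2f}"
            )
            for w in self.model.windows:
                row += f"{np.average(sub[w.column], weights=sub['n_reads']):>12.2f}"
            lines.append(row)
        return "\n".join(lines)

    # -- derived analyses --------------------------------------------------
    def compare(
        self, condition_a: str, condition_b: str, alpha: float = 0.05,
        level: str = "replicate",
    ) -> DifferentialTailResults:
        """Welch-test the per-replicate mean tails of B against A."""
        table = tailprofile.differential_mean_tail(
            self.summaries, condition_a, condition_b, alpha=alpha,
            level=level, records=self._records,
        )
        return DifferentialTailResults(condition_a, condition_b, alpha, table)

    def window_change(
        self,
        condition_a: str,
        condition_b: str,
        window: TailWindow | str | None = None,
        pseudocount: float = 0.1,
    ) -> pd.DataFrame:
        window = window if window is not None else self.model.windows[0]
        return tailprofile.window_fraction_change(
            self.summaries, condition_a, condition_b, window, pseudocount
        )

    def density(
        self, bin_width: float = 5.0, x_max: float = 350.0, span: float = 0.3,
        weighting: str = "read",
    ) -> dict[str, DensityProfile]:
        return tailprofile.tail_length_density(
            self._records, bin_width=bin_width, x_max=x_max, span=span,
            weighting=weighting,
        )

    def plot_density(
        self, conditions: Sequence[str] | None = None, ax=None, **density_kwargs
    ):
        """Bar-plus-smooth tail-length distribution plot per condition."""
        import matplotlib.pyplot as plt

        profiles = self.density(**density_kwargs)
        conditions = conditions or sorted(profiles)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for cond in conditions:
            prof = profiles[cond]
            mean_pct = prof.per_replicate_percent.mean(axis=0)
            ax.bar(
                prof.bin_centers, mean_pct, width=prof.bin_width * 0.9,
                alpha=0.3, label=f"{cond}",
            )
            ax.plot(prof.bin_centers, prof.smoothed, lw=2)
        ax.set_xlabel("poly(A) tail length (nt)")
        ax.set_ylabel("reads (%)")
        ax.legend()
        return ax
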