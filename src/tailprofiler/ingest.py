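"""Read-level ingestion for nanopore direct-RNA poly(A) tail profiling.

This module consumes the two tab-separated tables produced upstream of the
analysis — the per-read tail-length estimates emitted by a signal-level tail
estimator (``polya``-style, one row per read with a ``qc_tag`` column) and the
per-read barcode calls emitted by a neural demultiplexer (read id, barcode,
assignment confidence) — joins them, applies the read-level quality filters,
and attaches sample / condition / replicate or terminal-modification-class
labels through barcode maps.

Reads survive filtering only when their tail segmentation passed QC
(``qc_tag == "PASS"``), they have a barcode call, and the demultiplexing
confidence is strictly above the threshold (default 0.85).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "TableFormatError",
    "ConfigurationError",
    "BarcodeMap",
    "FilterReport",
    "TAIL_TABLE_COLUMNS",
    "DEMUX_TABLE_COLUMNS",
    "TERMINAL_MOD_CLASSES",
    "MOD_CLASSES",
    "parse_tail_table",
    "parse_demux_table",
    "tail_records_from_frame",
    "demux_from_frame",
    "merge_and_filter",
    "assign_labels",
    "load_barcode_map",
    "load_design",
]


class TableFormatError(ValueError):
    """An input table does not conform to the expected column dialect."""


class ConfigurationError(ValueError):
    """A barcode map or design table is inconsistent with the data."""


#: Default tail-table dialect: logical field -> column name as written by the
#: signal-level estimator's ``polya`` command.  Extra columns (position,
#: adapter coordinates, read rate, ...) are ignored.
TAIL_TABLE_COLUMNS: dict[str, str] = {
    "read_id": "readname",
    "transcript_id": "contig",
    "tail_length": "polya_length",
    "qc_tag": "qc_tag",
}

#: Default demultiplexing-table dialect (one row per read-to-barcode call).
DEMUX_TABLE_COLUMNS: dict[str, str] = {
    "read_id": "ReadID",
    "barcode": "Barcode",
    "confidence": "Confidence",
}

#: Recognised 3'-terminal modification classes.
MOD_CLASSES = ("polyA_only", "mono_U", "oligo_U", "guanylated", "unknown")

#: Fixed barcode -> terminal-class correspondence of the splint-duplex mix
#: used for terminal-modification libraries: BC1 captures unmodified poly(A)
#: ends, BC2 mono-uridylated, BC3 oligo-uridylated and BC4 guanylated ends.
TERMINAL_MOD_CLASSES: dict[str, str] = {
    "BC1": "polyA_only",
    "BC2": "mono_U",
    "BC3": "oligo_U",
    "BC4": "guanylated",
}

#: Canonical column set of a fully labelled read-record frame.
RECORD_COLUMNS = [
    "read_id",
    "transcript_id",
    "tail_length",
    "qc_tag",
    "qc_pass",
    "barcode",
    "demux_confidence",
    "sample_id",
    "condition",
    "replicate",
    "mod_class",
]


@dataclass(frozen=True)
class BarcodeMap:
    """Maps barcodes either to sample ids or to terminal-modification classes.

    Parameters
    ----------
    mode
        ``"sample_multiplex"`` (barcode -> sample id, resolved to condition
        and replicate through a design table) or ``"terminal_modification"``
        (barcode -> 3'-end class).
    entries
        Barcode -> target mapping.  In ``terminal_modification`` mode the
        four barcodes must map exactly as BC1 -> polyA_only, BC2 -> mono_U,
        BC3 -> oligo_U and BC4 -> guanylated.
    """

    mode: str
    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("sample_multiplex", "terminal_modification"):
            raise ConfigurationError(f"unknown barcode-map mode {self.mode!r}")
        if self.mode == "terminal_modification":
            if dict(self.entries) != TERMINAL_MOD_CLASSES:
                raise ConfigurationError(
                    "terminal_modification maps are fixed to "
                    f"{TERMINAL_MOD_CLASSES!r}; got {dict(self.entries)!r}"
                )


#: The canonical terminal-modification barcode map.
TERMINAL_MOD_MAP = BarcodeMap("terminal_modification", dict(TERMINAL_MOD_CLASSES))


@dataclass
class FilterReport:
    """Accounting of reads dropped by :func:`merge_and_filter`.

    ``dropped`` counts each removed read exactly once under the first reason
    that applied, in the order invalid_tail, qc_fail, no_demux,
    low_confidence; the counts sum to ``n_input - n_kept``.
    """

    n_input: int
    n_kept: int
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept

    def __add__(self, other: "FilterReport") -> "FilterReport":
        merged = dict(self.dropped)
        for k, v in other.dropped.items():
            merged[k] = merged.get(k, 0) + v
        return FilterReport(self.n_input + other.n_input, self.n_kept + other.n_kept, merged)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(f"{k}={v}" for k, v in sorted(self.dropped.items()))
        return f"kept {self.n_kept}/{self.n_input} reads ({parts})"


def tail_records_from_frame(
    frame: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Normalise a raw tail-estimate table into partial read records.

    Row order is preserved; rows with unparseable tail lengths or a
    ``qc_tag`` other than ``PASS`` are retained but flagged (filtering is a
    separate step).  Duplicate read ids keep the first occurrence.
    """
    columns = dict(TAIL_TABLE_COLUMNS if columns is None else columns)
    missing = [c for c in columns.values() if c not in frame.columns]
    if missing:
        raise TableFormatError(
            f"tail table is missing mandatory column(s): {', '.join(missing)}"
        )
    out = pd.DataFrame(
        {
            "read_id": frame[columns["read_id"]].astype(str),
            "transcript_id": frame[columns["transcript_id"]].astype(str),
            "tail_length": pd.to_numeric(frame[columns["tail_length"]], errors="coerce"),
            "qc_tag": frame[columns["qc_tag"]].astype(str),
        }
    )
    out["qc_pass"] = out["qc_tag"] == "PASS"
    n_bad = int((~(out["tail_length"] >= 0)).sum())
    if n_bad:
        log.info("%d rows with missing/negative tail length (flagged, not dropped)", n_bad)
    dup = out["read_id"].duplicated()
    if dup.any():
        log.warning("%d duplicate read ids in tail table; keeping first occurrence", int(dup.sum()))
        out = out[~dup]
    return out.reset_index(drop=True)


def parse_tail_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Parse a tab-separated per-read tail-length table.

    Returns a frame with columns ``read_id, transcript_id, tail_length,
    qc_tag, qc_pass``.  An empty file yields an empty frame with a warning.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        log.warning("tail table %s is empty", path)
        return pd.DataFrame(columns=["read_id", "transcript_id", "tail_length", "qc_tag", "qc_pass"])
    return tail_records_from_frame(raw, columns)


def demux_from_frame(
    frame: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Normalise a raw demultiplexing table to one row per read id.

    Duplicate read ids are resolved by keeping the highest-confidence call;
    exact confidence ties keep the first row and log a warning.
    """
    columns = dict(DEMUX_TABLE_COLUMNS if columns is None else columns)
    missing = [c for c in columns.values() if c not in frame.columns]
    if missing:
        raise TableFormatError(
            f"demux table is missing mandatory column(s): {', '.join(missing)}"
        )
    out = pd.DataFrame(
        {
            "read_id": frame[columns["read_id"]].astype(str),
            "barcode": frame[columns["barcode"]].astype(str),
            "demux_confidence": pd.to_numeric(frame[columns["confidence"]], errors="coerce"),
        }
    )
    conf = out["demux_confidence"]
    bad = conf.notna() & ((conf < 0) | (conf > 1))
    if bad.any():
        raise TableFormatError(
            f"{int(bad.sum())} demux confidence value(s) outside [0, 1]"
        )
    if out["read_id"].duplicated().any():
        log.warning("duplicate read ids in demux table; keeping highest confidence")
        # stable sort so that equal-confidence duplicates keep the first row
        out = out.sort_values("demux_confidence", ascending=False, kind="stable")
        out = out[~out["read_id"].duplicated()]
        out = out.sort_index()
    return out.reset_index(drop=True)


def parse_demux_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Parse a tab-separated demultiplexing table (read id, barcode, confidence)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        log.warning("demux table %s is empty", path)
        return pd.DataFrame(columns=["read_id", "barcode", "demux_confidence"])
    return demux_from_frame(raw, columns)


def merge_and_filter(
    records: pd.DataFrame,
    demux: pd.DataFrame | None,
    min_confidence: float = 0.85,
    require_pass: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Join tail records with barcode calls and apply the read-level filters.

    A read survives when (in order of evaluation) its tail length is a
    finite non-negative number, its tail segmentation passed QC (if
    ``require_pass``), it has a barcode call, and its demultiplexing
    confidence is strictly greater than ``min_confidence``.  When ``demux``
    is None (an unmultiplexed library) the barcode-related filters are
    skipped and barcode columns are left unset.

    Returns the surviving records together with a :class:`FilterReport`
    counting reads dropped per reason.  The operation is idempotent.
    """
    merged = records.copy()
    # drop any stale demux columns so that re-merging is idempotent
    merged = merged.drop(columns=["barcode", "demux_confidence"], errors="ignore")
    if demux is not None:
        merged = merged.merge(
            demux[["read_id", "barcode", "demux_confidence"]], on="read_id", how="left"
        )
    else:
        merged["barcode"] = pd.NA
        merged["demux_confidence"] = float("nan")

    n_input = len(merged)
    dropped: dict[str, int] = {}
    alive = pd.Series(True, index=merged.index)

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal alive
        hit = mask & alive
        dropped[reason] = int(hit.sum())
        alive = alive & ~mask

    _drop(~(merged["tail_length"] >= 0), "invalid_tail")
    if require_pass:
        _drop(~merged["qc_pass"], "qc_fail")
    if demux is not None:
        _drop(merged["barcode"].isna(), "no_demux")
        _drop(~(merged["demux_confidence"] > min_confidence), "low_confidence")

    kept = merged[alive].reset_index(drop=True)
    report = FilterReport(n_input=n_input, n_kept=len(kept), dropped=dropped)
    log.info("%s", report)
    return kept, report


def assign_labels(
    records: pd.DataFrame,
    barcode_map: BarcodeMap,
    design: Mapping[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Attach sample/condition/replicate or modification-class labels.

    In ``sample_multiplex`` mode each barcode resolves to a sample id and the
    ``design`` mapping (sample id -> (condition, replicate)) provides the
    experimental coordinates; a sample referenced by the map but absent from
    the design raises :class:`ConfigurationError`.  In
    ``terminal_modification`` mode each barcode resolves to a 3'-end class.
    Barcodes absent from the map are labelled ``"unknown"`` and counted.
    """
    out = records.copy()
    barcodes = out["barcode"].astype("string")
    if barcode_map.mode == "sample_multiplex":
        if design is None:
            raise ConfigurationError("sample_multiplex labelling requires a design table")
        missing = [s for s in barcode_map.entries.values() if s not in design]
        if missing:
            raise ConfigurationError(
                f"design table is missing sample(s): {', '.join(sorted(missing))}"
            )
        sample = barcodes.map(dict(barcode_map.entries))
        n_unknown = int((sample.isna() & barcodes.notna()).sum())
        out["sample_id"] = sample.fillna("unknown")
        out["condition"] = out["sample_id"].map(
            {s: cr[0] for s, cr in design.items()}
        )
        out["replicate"] = out["sample_id"].map(
            {s: int(cr[1]) for s, cr in design.items()}
        ).astype("Int64")
        out["mod_class"] = "unknown"
    else:
        mod = barcodes.map(dict(barcode_map.entries))
        n_unknown = int((mod.isna() & barcodes.notna()).sum())
        out["mod_class"] = mod.fillna("unknown")
        for col in ("sample_id", "condition"):
            if col not in out.columns:
                out[col] = pd.NA
        if "replicate" not in out.columns:
            out["replicate"] = pd.NA
    if n_unknown:
        log.warning("%d reads carry barcodes absent from the map (labelled unknown)", n_unknown)
    out.attrs["n_unknown_barcode"] = n_unknown
    return out


def load_barcode_map(path: str | Path) -> BarcodeMap:
    """Load a barcode map from a small YAML file with keys ``mode``, ``entries``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return BarcodeMap(mode=doc["mode"], entries=dict(doc["entries"]))


def load_design(path: str | Path) -> dict[str, tuple[str, int]]:
    """Load a design table (sample -> condition/replicate) from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {
        str(sample): (str(spec["condition"]), int(spec["replicate"]))
        for sample, spec in doc.items()
    }
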