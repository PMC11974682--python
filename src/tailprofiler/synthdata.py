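"""Synthetic read-level and count-level data with known generative truth.

The generator emulates the statistical structure of direct-RNA poly(A)
profiling of sorted spermatogenic cells so every stage of the pipeline can
be exercised without sequencing data:

* per-transcript tail lengths drawn from two/three-component truncated
  normal mixtures (components near 60, 150 and 180 nt) with additive
  measurement noise, emulating spermatocyte (60-dominant), round-spermatid
  (150-dominant) and elongating-spermatid (150-dominant with an elevated
  60-nt fraction) regimes;
* negative-binomial read counts per transcript and replicate, so the
  >= 10-reads prefilter is exercised on both sides;
* planted QC-failure and low-demultiplexing-confidence reads;
* a terminal-modification library in which reads are assigned one of ten
  barcoded splint-duplex classes at the bench mix proportions (BC1 duplex
  ~90 %, BC2 ~3 %, four BC3 duplexes, four BC4 duplexes);
* differential-accumulation / translation result tables drawn around
  planted up/down effects, with Benjamini-Hochberg q-values.

All randomness flows from one master seed through numpy's PCG64 generator;
child streams are spawned from ``SeedSequence(seed)`` in a fixed documented
order (one per condition x replicate, in the order they are listed), so
regeneration from the same (truth, seed) is bit-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import ingest
from .ingest import BarcodeMap, FilterReport
from .tailprofile import TailWindow

log = logging.getLogger(__name__)

__all__ = [
    "TailMixtureSpec",
    "TranscriptTruth",
    "SyntheticTruth",
    "SimulatedDataset",
    "DuplexClass",
    "ModLibrarySpec",
    "TERMINAL_MOD_MIX",
    "mixture_60_dominant",
    "mixture_150_dominant",
    "simulate_tail_reads",
    "simulate_mod_library",
    "emit_count_tables",
    "null_truth",
    "recovery_truth",
    "make_spermiogenesis_scenario",
    "Scenario",
]


# ---------------------------------------------------------------------------
# tail-length mixtures


@dataclass(frozen=True)
class TailMixtureSpec:
    """A mixture of zero-truncated normal tail-length components.

    ``components`` is a tuple of (mean nt, sd nt, weight) triples; weights
    must be non-negative and sum to 1 (within 1e-9).  Sampled tails are
    truncated at zero, then perturbed with additive normal measurement noise
    (``noise_sd`` nt, emulating signal-level estimator scatter) and clipped
    at zero again.
    """

    components: tuple[tuple[float, float, float], ...]
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        weights = np.array([w for _, _, w in self.components], float)
        if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be >= 0 and sum to 1")
        if any(sd <= 0 for _, sd, _ in self.components):
            raise ValueError("component sds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # -- sampling ----------------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        weights = np.array([w for _, _, w in self.components], float)
        comp = rng.choice(len(weights), size=n, p=weights)
        tails = np.empty(n, float)
        for i, (mean, sd, _) in enumerate(self.components):
            mask = comp == i
            tails[mask] = _truncated_normal(mean, sd, int(mask.sum()), rng)
        if self.noise_sd > 0:
            tails = tails + rng.normal(0.0, self.noise_sd, n)
        return np.maximum(tails, 0.0)

    # -- analytic window mass ---------------------------------------------
    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Density of the zero-truncated mixture (before measurement noise)."""
        x = np.asarray(x, float)
        out = np.zeros_like(x)
        for mean, sd, w in self.components:
            z_mass = sps.norm.sf(0.0, loc=mean, scale=sd)
            out += w * sps.norm.pdf(x, loc=mean, scale=sd) / z_mass
        return np.where(x >= 0, out, 0.0)

    def window_mass(self, window: TailWindow, n_grid: int = 8001) -> float:
        """Probability that an observed (noisy, clipped) tail falls in the window.

        Computed by numerical integration of the truncated-mixture density
        against the normal measurement-noise kernel; exact to quadrature
        accuracy, independent of any sampling code path.
        """
        if self.noise_sd == 0:  # exact truncated-normal CDF difference
            lo = max(window.lower, 0.0)
            mass = 0.0
            for mean, sd, w in self.components:
                z = sps.norm.sf(0.0, loc=mean, scale=sd)
                mass += w * (
                    sps.norm.cdf(window.upper, mean, sd) - sps.norm.cdf(lo, mean, sd)
                ) / z
            return float(mass)
        hi = max(mean + 10 * sd for mean, sd, _ in self.components) + 10 * self.noise_sd
        grid = np.linspace(0.0, hi, n_grid)
        dens = self.pdf(grid)
        upper_c = sps.norm.cdf((window.upper - grid) / self.noise_sd)
        if window.lower > 0:
            lower_c = sps.norm.cdf((window.lower - grid) / self.noise_sd)
        else:  # the clip at zero folds all negative observations into the window
            lower_c = 0.0
        return float(np.trapezoid(dens * (upper_c - lower_c), grid))

    def to_dict(self) -> dict:
        return {"components": [list(c) for c in self.components], "noise_sd": self.noise_sd}

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TailMixtureSpec":
        return cls(
            components=tuple(tuple(float(v) for v in c) for c in doc["components"]),
            noise_sd=float(doc.get("noise_sd", 5.0)),
        )


def _truncated_normal(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated normal draws by rejection (components sit far from 0)."""
    out = rng.normal(mean, sd, n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def mixture_60_dominant(weight: float = 0.9, noise_sd: float = 5.0) -> TailMixtureSpec:
    """Spermatocyte-like regime: short (~60 nt) tails dominate."""
    return TailMixtureSpec(((60.0, 15.0, weight), (150.0, 20.0, 1.0 - weight)), noise_sd)


def mixture_150_dominant(weight: float = 0.9, noise_sd: float = 5.0) -> TailMixtureSpec:
    """Round-spermatid-like regime: long (~150 nt) tails dominate."""
    return TailMixtureSpec(((60.0, 15.0, 1.0 - weight), (150.0, 20.0, weight)), noise_sd)


# ---------------------------------------------------------------------------
# generative truth


@dataclass
class TranscriptTruth:
    """Generative parameters of one transcript."""

    transcript_id: str
    mixtures: dict[str, TailMixtureSpec]
    nb_mean: float = 50.0
    nb_dispersion: float = 0.3  # var = mean + dispersion * mean**2; 0 -> fixed counts
    stability: str = "others"
    translation: str = "others"
    tent5c_target: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixtures"] = {c: m.to_dict() for c, m in self.mixtures.items()}
        return d

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TranscriptTruth":
        doc = dict(doc)
        doc["mixtures"] = {
            c: TailMixtureSpec.from_dict(m) for c, m in doc["mixtures"].items()
        }
        return cls(**doc)


@dataclass
class SyntheticTruth:
    """Truth manifest for a simulated dataset.

    Serialised alongside every generated dataset; regeneration from the same
    (truth, seed) pair is bit-identical.
    """

    transcripts: list[TranscriptTruth]
    conditions: list[str]
    n_replicates: int = 3
    qc_fail_rate: float = 0.05
    low_conf_rate: float = 0.05
    seed: int = 0

    def by_id(self) -> dict[str, TranscriptTruth]:
        return {t.transcript_id: t for t in self.transcripts}

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "n_replicates": self.n_replicates,
            "qc_fail_rate": self.qc_fail_rate,
            "low_conf_rate": self.low_conf_rate,
            "seed": self.seed,
            "transcripts": [t.to_dict() for t in self.transcripts],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SyntheticTruth":
        return cls(
            transcripts=[TranscriptTruth.from_dict(t) for t in doc["transcripts"]],
            conditions=list(doc["conditions"]),
            n_replicates=int(doc["n_replicates"]),
            qc_fail_rate=float(doc["qc_fail_rate"]),
            low_conf_rate=float(doc["low_conf_rate"]),
            seed=int(doc["seed"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# read-level simulation


@dataclass
class SimulatedDataset:
    """In-memory simulated dataset in the exact dialects the ingest step reads."""

    tail_tables: dict[str, pd.DataFrame]
    demux_tables: dict[str, pd.DataFrame]
    barcode_maps: dict[str, BarcodeMap]
    design: dict[str, tuple[str, int]]
    truth: SyntheticTruth

    def to_records(
        self, min_confidence: float = 0.85, require_pass: bool = True
    ) -> tuple[pd.DataFrame, FilterReport]:
        """Run the standard ingest pipeline (merge, filter, label) in memory."""
        frames = []
        report = FilterReport(0, 0, {})
        for condition in self.truth.conditions:
            recs = ingest.tail_records_from_frame(self.tail_tables[condition])
            demux = ingest.demux_from_frame(self.demux_tables[condition])
            kept, rep = ingest.merge_and_filter(
                recs, demux, min_confidence=min_confidence, require_pass=require_pass
            )
            labelled = ingest.assign_labels(kept, self.barcode_maps[condition], self.design)
            frames.append(labelled)
            report = report + rep
        records = pd.concat(frames, ignore_index=True)
        return records, report

    def write(self, out_dir: str | Path, float_format: str = "%.6f") -> dict:
        """Write tail/demux tables, barcode maps, design and truth manifest.

        Returns (and writes) a manifest listing every file produced.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files: dict[str, dict[str, str]] = {"tails": {}, "demux": {}}
        for condition in self.truth.conditions:
            tail_path = out_dir / f"{condition}.tails.tsv"
            demux_path = out_dir / f"{condition}.demux.tsv"
            self.tail_tables[condition].to_csv(
                tail_path, sep="\t", index=False, float_format=float_format
            )
            self.demux_tables[condition].to_csv(
                demux_path, sep="\t", index=False, float_format=float_format
            )
            files["tails"][condition] = tail_path.name
            files["demux"][condition] = demux_path.name
        with open(out_dir / "barcode_maps.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    c: {"mode": m.mode, "entries": dict(m.entries)}
                    for c, m in self.barcode_maps.items()
                },
                fh,
            )
        with open(out_dir / "design.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    s: {"condition": c, "replicate": r}
                    for s, (c, r) in self.design.items()
                },
                fh,
            )
        self.truth.to_json(out_dir / "truth.json")
        manifest = {
            "files": files,
            "barcode_maps": "barcode_maps.yaml",
            "design": "design.yaml",
            "truth": "truth.json",
            "conditions": list(self.truth.conditions),
            "seed": self.truth.seed,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest


def _nb_counts(
    means: np.ndarray, dispersions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts with var = mean + dispersion * mean^2."""
    means = np.asarray(means, float)
    dispersions = np.asarray(dispersions, float)
    counts = np.empty(len(means), dtype=int)
    fixed = dispersions <= 0
    counts[fixed] = np.round(means[fixed]).astype(int)
    if (~fixed).any():
        r = 1.0 / dispersions[~fixed]
        p = r / (r + means[~fixed])
        counts[~fixed] = rng.negative_binomial(r, p)
    return counts


def _sample_tails_pooled(
    specs: Sequence[TailMixtureSpec], counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample tails for many transcripts, pooling identical mixture specs.

    Draws are made per distinct spec (in first-appearance order) and handed
    back in transcript order, which keeps large homogeneous simulations fast
    while remaining fully deterministic.
    """
    groups: dict[TailMixtureSpec, list[int]] = {}
    for i, spec in enumerate(specs):
        groups.setdefault(spec, []).append(i)
    pieces: dict[int, np.ndarray] = {}
    for spec, idxs in groups.items():
        total = int(counts[idxs].sum())
        draws = spec.sample(total, rng)
        offset = 0
        for i in idxs:
            pieces[i] = draws[offset : offset + counts[i]]
            offset += counts[i]
    return np.concatenate([pieces[i] for i in range(len(specs))]) if specs else np.empty(0)


def simulate_tail_reads(
    truth: SyntheticTruth, seed: int | None = None, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Generate tail-estimate and demux tables for every condition of a truth.

    Per condition x replicate: read counts per transcript are drawn from the
    negative-binomial spec, tail lengths from the condition's mixture, a
    ``round(qc_fail_rate * n)``-sized random subset is tagged as a failed
    tail segmentation, and a disjoint ``round(low_conf_rate * n)``-sized
    subset receives a demultiplexing confidence below the 0.85 filter
    threshold (all other reads draw confidences in [0.90, 1.00)).  Each
    replicate is encoded as one barcode (BC1..BCn) of a sample-multiplexed
    library, so the full barcode-map / design labelling path is exercised.
    """
    if seed is None:
        seed = truth.seed
    streams = np.random.SeedSequence(seed).spawn(
        len(truth.conditions) * truth.n_replicates
    )
    tail_tables: dict[str, pd.DataFrame] = {}
    demux_tables: dict[str, pd.DataFrame] = {}
    barcode_maps: dict[str, BarcodeMap] = {}
    design: dict[str, tuple[str, int]] = {}
    stream_i = 0
    for condition in truth.conditions:
        tail_parts, demux_parts = [], []
        entries = {}
        for rep in range(1, truth.n_replicates + 1):
            rng = np.random.default_rng(streams[stream_i])
            stream_i += 1
            specs = [t.mixtures[condition] for t in truth.transcripts]
            means = np.array([t.nb_mean for t in truth.transcripts])
            disps = np.array([t.nb_dispersion for t in truth.transcripts])
            counts = _nb_counts(means, disps, rng)
            tails = _sample_tails_pooled(specs, counts, rng)
            n = int(counts.sum())
            tx_ids = np.repeat([t.transcript_id for t in truth.transcripts], counts)
            read_ids = np.array(
                [f"{condition}_r{rep}_{i:07d}" for i in range(n)], dtype=object
            )
            perm = rng.permutation(n)
            n_fail = int(round(truth.qc_fail_rate * n))
            n_low = int(round(truth.low_conf_rate * n))
            fail_idx = perm[:n_fail]
            low_idx = perm[n_fail : n_fail + n_low]
            qc_tag = np.full(n, "PASS", dtype=object)
            qc_tag[fail_idx] = "ADAPTER"
            conf = rng.uniform(0.90, 1.0, n)
            conf[low_idx] = rng.uniform(0.30, 0.85, len(low_idx))
            barcode = f"BC{rep}"
            sample = f"{condition}_rep{rep}"
            entries[barcode] = sample
            design[sample] = (condition, rep)
            tail_parts.append(
                pd.DataFrame(
                    {
                        "readname": read_ids,
                        "contig": tx_ids,
                        "position": 0,
                        "leader_start": 10.0,
                        "adapter_start": 25.0,
                        "polya_start": 40.0,
                        "transcript_start": 40.0 + np.round(tails, 2),
                        "read_rate": 70.0,
                        "polya_length": tails,
                        "qc_tag": qc_tag,
                    }
                )
            )
            demux_parts.append(
                pd.DataFrame(
                    {"ReadID": read_ids, "Barcode": barcode, "Confidence": conf}
                )
            )
        tail_tables[condition] = pd.concat(tail_parts, ignore_index=True)
        demux_tables[condition] = pd.concat(demux_parts, ignore_index=True)
        barcode_maps[condition] = BarcodeMap("sample_multiplex", entries)
    ds = SimulatedDataset(tail_tables, demux_tables, barcode_maps, design, truth)
    if out_dir is not None:
        ds.write(out_dir)
    return ds


# ---------------------------------------------------------------------------
# terminal-modification duplex library


@dataclass(frozen=True)
class DuplexClass:
    """One annealed splint-duplex species of the terminal-modification mix."""

    name: str
    barcode: str
    proportion: float  # percent, as printed on the bench recipe


@dataclass(frozen=True)
class ModLibrarySpec:
    """Duplex-mix composition of a terminal-modification library.

    Printed proportions are renormalised to sum to 1 (the bench recipe sums
    to slightly over 100 % from rounding).
    """

    duplexes: tuple[DuplexClass, ...]

    def probabilities(self) -> np.ndarray:
        p = np.array([d.proportion for d in self.duplexes], float)
        if (p < 0).any() or p.sum() <= 0:
            raise ValueError("duplex proportions must be non-negative with positive sum")
        return p / p.sum()


#: The ten-duplex bench mix: one duplex captures unmodified poly(A) ends
#: (BC1, 90 %), one mono-uridylated ends (BC2, 3 %), four capture
#: oligo-uridylated ends (BC3) and four capture guanylated ends (BC4).
TERMINAL_MOD_MIX = ModLibrarySpec(
    (
        DuplexClass("Annealed oligo_1", "BC1", 90.0),
        DuplexClass("Annealed oligo_2", "BC2", 3.0),
        DuplexClass("Annealed oligo_3", "BC3", 2.40),
        DuplexClass("Annealed oligo_4", "BC3", 0.45),
        DuplexClass("Annealed oligo_5", "BC3", 0.08),
        DuplexClass("Annealed oligo_6", "BC3", 0.08),
        DuplexClass("Annealed oligo_7", "BC4", 3.0),
        DuplexClass("Annealed oligo_8", "BC4", 0.75),
        DuplexClass("Annealed oligo_9", "BC4", 0.20),
        DuplexClass("Annealed oligo_10", "BC4", 0.05),
    )
)


def simulate_mod_library(
    spec: ModLibrarySpec, n_reads: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign reads to splint-duplex classes multinomially.

    Returns ``(demux_table, truth_table)``: the demux table is in the
    standard ReadID/Barcode/Confidence dialect (the barcode is the duplex's
    barcode class); the truth table keeps the duplex identity per read.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = spec.probabilities()
    idx = rng.choice(len(p), size=n_reads, p=p)
    read_ids = np.array([f"mod_{i:07d}" for i in range(n_reads)], dtype=object)
    barcodes = np.array([d.barcode for d in spec.duplexes], dtype=object)[idx]
    duplexes = np.array([d.name for d in spec.duplexes], dtype=object)[idx]
    conf = rng.uniform(0.90, 1.0, n_reads)
    demux = pd.DataFrame({"ReadID": read_ids, "Barcode": barcodes, "Confidence": conf})
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "duplex": duplexes,
            "barcode": barcodes,
            "mod_class": [ingest.TERMINAL_MOD_CLASSES[b] for b in barcodes],
        }
    )
    return demux, truth


# ---------------------------------------------------------------------------
# external-style count/result tables


def emit_count_tables(
    truth: SyntheticTruth,
    seed: int,
    effect_size: float = 2.0,
    effect_se: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-accumulation and differential-translation result tables.

    Each transcript's observed log2 fold change is drawn around its planted
    effect (+``effect_size`` for up, -``effect_size`` for down, 0 for
    others) with standard error ``effect_se``; the two-sided p-value is the
    normal tail probability of the observed effect against that error, and
    q is Benjamini-Hochberg over all transcripts.  Returned tables use the
    standard transcript_id / log2fc / pvalue / qvalue dialect.
    """
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tables = []
    for attr in ("stability", "translation"):
        planted = np.array(
            [
                effect_size if getattr(t, attr) == "up"
                else -effect_size if getattr(t, attr) == "down"
                else 0.0
                for t in truth.transcripts
            ]
        )
        observed = planted + rng.normal(0.0, effect_se, len(planted))
        z = observed / effect_se
        p = 2.0 * sps.norm.sf(np.abs(z))
        q = multipletests(p, method="fdr_bh")[1]
        tables.append(
            pd.DataFrame(
                {
                    "transcript_id": [t.transcript_id for t in truth.transcripts],
                    "log2fc": observed,
                    "pvalue": p,
                    "qvalue": q,
                }
            )
        )
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
# canned scenarios


def null_truth(
    n_transcripts: int = 2000,
    conditions: Sequence[str] = ("A", "B"),
    n_replicates: int = 3,
    reads_per_replicate: float = 50.0,
    mixture: TailMixtureSpec | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Identical tail mixtures in every condition (type-I error checks).

    Counts are fixed at ``reads_per_replicate`` so the null rejection rate
    is not confounded by prefilter attrition.
    """
    mixture = mixture or mixture_150_dominant()
    transcripts = [
        TranscriptTruth(
            transcript_id=f"tx{i:05d}",
            mixtures={c: mixture for c in conditions},
            nb_mean=reads_per_replicate,
            nb_dispersion=0.0,
        )
        for i in range(n_transcripts)
    ]
    return SyntheticTruth(
        transcripts, list(conditions), n_replicates=n_replicates,
        qc_fail_rate=0.0, low_conf_rate=0.0, seed=seed,
    )


def recovery_truth(
    n_transcripts: int = 400,
    reads_per_replicate: float = 200.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> SyntheticTruth:
    """Mixture-weight recovery scenario: half of the transcripts 60-dominant,
    half 150-dominant, fixed read depth, single condition."""
    m60, m150 = mixture_60_dominant(), mixture_150_dominant()
    transcripts = [
        TranscriptTruth(
            transcript_id=f"tx{i:05d}",
            mixtures={"RS": m60 if i % 2 == 0 else m150},
            nb_mean=reads_per_replicate,
            nb_dispersion=0.0,
        )
        for i in range(n_transcripts)
    ]
    return SyntheticTruth(
        transcripts, ["RS"], n_replicates=n_replicates,
        qc_fail_rate=0.0, low_conf_rate=0.0, seed=seed,
    )


@dataclass
class Scenario:
    """A full spermiogenesis-like fixture set: reads, truth and external-style tables."""

    truth: SyntheticTruth
    dataset: SimulatedDataset
    accumulation_table: pd.DataFrame
    translation_table: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict:
        out_dir = Path(out_dir)
        manifest = self.dataset.write(out_dir)
        self.accumulation_table.to_csv(
            out_dir / "differential_accumulation.tsv", sep="\t", index=False
        )
        self.translation_table.to_csv(
            out_dir / "differential_translation.tsv", sep="\t", index=False
        )
        manifest["accumulation_table"] = "differential_accumulation.tsv"
        manifest["translation_table"] = "differential_translation.tsv"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest


SENTINEL_TARGETS = ("Odf1-like", "Smcp-like", "Insl3-like")


def make_spermiogenesis_scenario(
    seed: int,
    n_transcripts: int = 1000,
    n_targets: int = 10,
    reads_mean: float = 50.0,
    nb_dispersion: float = 0.3,
    frac_lengthening: float = 0.8,
    frac_shortening: float = 0.01,
) -> Scenario:
    """Assemble the full spermiogenesis-like fixture set.

    Four conditions are simulated: ``PD`` (spermatocyte-like, 60-dominant
    tails), ``RS`` (round-spermatid-like, 150-dominant for the planted
    majority of lengthening transcripts), ``ES`` (elongating-spermatid-like,
    150 tails retained with an elevated 60-nt fraction, resolved by planted
    stability class) and ``ES_dcat`` (a catalytically-dead-polymerase
    genotype identical to ``ES`` except for a small planted target set —
    including the sentinels Odf1-like, Smcp-like and Insl3-like — whose
    mixture weight flips from 150- to 60-dominant).  Matching
    differential-accumulation and differential-translation tables are drawn
    from the planted stability/translation classes.
    """
    ss = np.random.SeedSequence(seed)
    truth_seed, reads_seed, tables_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    rng = np.random.default_rng(truth_seed)

    m60 = mixture_60_dominant()
    m150 = mixture_150_dominant()
    m150_elev = TailMixtureSpec(((60.0, 15.0, 0.35), (150.0, 20.0, 0.65)))
    m_half = TailMixtureSpec(((60.0, 15.0, 0.5), (150.0, 20.0, 0.5)))

    names = [f"tx{i:05d}" for i in range(n_transcripts - len(SENTINEL_TARGETS))]
    names += list(SENTINEL_TARGETS)
    target_ids = set(names[-(len(SENTINEL_TARGETS)) :])
    extra = max(0, n_targets - len(target_ids))
    target_ids |= set(rng.choice(names[: -len(SENTINEL_TARGETS)], size=extra, replace=False))

    lengthening = rng.random(n_transcripts) < frac_lengthening
    shortening = (~lengthening) & (rng.random(n_transcripts) < frac_shortening / (1 - frac_lengthening))
    stability = rng.choice(["up", "others", "down"], size=n_transcripts, p=[0.3, 0.5, 0.2])
    translation = rng.choice(["up", "others", "down"], size=n_transcripts, p=[0.25, 0.5, 0.25])

    transcripts: list[TranscriptTruth] = []
    for i, name in enumerate(names):
        is_target = name in target_ids
        if lengthening[i] or is_target:
            pd_mix, rs_mix = m60, m150
        elif shortening[i]:
            pd_mix, rs_mix = m150, m60
        else:
            pd_mix = rs_mix = m60
        if rs_mix is m150:
            es_mix = (
                m150 if is_target
                else m150_elev if stability[i] == "up"
                else m60 if stability[i] == "down"
                else m_half
            )
        else:
            es_mix = rs_mix
        es_dcat_mix = m60 if is_target else es_mix
        transcripts.append(
            TranscriptTruth(
                transcript_id=name,
                mixtures={"PD": pd_mix, "RS": rs_mix, "ES": es_mix, "ES_dcat": es_dcat_mix},
                nb_mean=reads_mean,
                nb_dispersion=nb_dispersion,
                stability=str(stability[i]),
                translation=str(translation[i]),
                tent5c_target=is_target,
            )
        )
    truth = SyntheticTruth(
        transcripts,
        conditions=["PD", "RS", "ES", "ES_dcat"],
        n_replicates=3,
        qc_fail_rate=0.05,
        low_conf_rate=0.05,
        seed=seed,
    )
    dataset = simulate_tail_reads(truth, seed=reads_seed)
    accum, transl = emit_count_tables(truth, seed=tables_seed)
    return Scenario(truth, dataset, accum, transl)
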