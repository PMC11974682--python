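import io

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

from tailprofiler import synthdata


def make_records(rows):
    """Build a labelled read-record frame from (transcript, tail, condition, replicate) tuples."""
    df = pd.DataFrame(rows, columns=["transcript_id", "tail_length", "condition", "replicate"])
    df.insert(0, "read_id", [f"r{i}" for i in range(len(df))])
    df["qc_tag"] = "PASS"
    df["qc_pass"] = True
    return df


def tail_table_text(rows):
    """Render rows of (readname, contig, polya_length, qc_tag) as a full-dialect tail table."""
    header = (
        "readname\tcontig\tposition\tleader_start\tadapter_start\tpolya_start\t"
        "transcript_start\tread_rate\tpolya_length\tqc_tag"
    )
    lines = [header]
    for name, contig, length, qc in rows:
        lines.append(f"{name}\t{contig}\t0\t10.0\t25.0\t40.0\t100.0\t70.0\t{length}\t{qc}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def tiny_tail_file(tmp_path):
    def _write(rows, name="tails.tsv"):
        path = tmp_path / name
        path.write_text(tail_table_text(rows))
        return path

    return _write


@pytest.fixture
def tiny_demux_file(tmp_path):
    def _write(rows, name="demux.tsv"):
        lines = ["ReadID\tBarcode\tConfidence"]
        lines += [f"{r}\t{b}\t{c}" for r, b, c in rows]
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def scenario_small():
    """A small spermiogenesis-like scenario reused across tests (read-only)."""
    return synthdata.make_spermiogenesis_scenario(seed=11, n_transcripts=80, n_targets=6)
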