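"""File formats: FASTA, tab-separated expression tables, metadata sidecars.

Expression tables are genes x columns TSV with a header naming each column
``<experiment>_<arm>_<replicate>`` (arm is ``treatment`` or ``control``),
the layout the synthetic generator writes.
"""

from __future__ import annotations

import json
import warnings as _warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_expression",
    "write_expression",
    "write_metadata",
]

_ARMS = ("treatment", "control")


class FastaParseError(ValueError):
    """Malformed FASTA input, carrying the offending line number."""


def read_fasta(path, preserve_case: bool = False) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Sequences are uppercased on read unless ``preserve_case``; empty
    sequences and text before the first header are rejected with the line
    number.  An empty file yields an empty list.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected a '>' header, got "
                        f"{line.strip()[:30]!r}"
                    )
                break
        else:
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.description or rec.id, seq if preserve_case else seq.upper()))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write (id, sequence) pairs (or SeqRecords) as FASTA."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            seqrecs.append(rec)
        else:
            rid, seq = rec
            name = rid.split()[0]
            seqrecs.append(SeqRecord(Seq(seq), id=name, description=rid[len(name):].strip()))
    with Path(path).open("w") as fh:
        for rec in seqrecs:
            fh.write(f">{rec.id}" + (f" {rec.description}" if rec.description else "") + "\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_expression(experiments: dict, path) -> None:
    """Write per-experiment (treatment, control) DataFrames as one TSV."""
    pieces = []
    for treat, ctrl in experiments.values():
        pieces.extend([treat, ctrl])
    table = pd.concat(pieces, axis=1)
    table.index.name = "gene"
    table.to_csv(path, sep="\t")


def read_expression(path, lenient: bool = False) -> dict:
    """Parse an expression TSV into per-experiment replicate matrices.

    Columns are grouped by the ``<experiment>_<arm>_<rep>`` convention.
    Unknown arm tokens and duplicate column names are errors (with
    ``lenient`` unknown columns are dropped with a warning); an experiment
    missing either arm is always an error naming the experiment.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    cols = list(table.columns)
    dupes = {c for c in cols if cols.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicate column names: {sorted(dupes)}")
    grouped: dict[str, dict[str, list[str]]] = {}
    for col in cols:
        parts = col.rsplit("_", 2)
        if len(parts) != 3 or parts[1] not in _ARMS:
            if lenient:
                _warnings.warn(f"ignoring unrecognized column {col!r}", stacklevel=2)
                continue
            raise ValueError(
                f"column {col!r} does not parse as <experiment>_<arm>_<rep> "
                f"with arm in {_ARMS}"
            )
        exp, arm, _ = parts
        grouped.setdefault(exp, {}).setdefault(arm, []).append(col)
    out = {}
    for exp, arms in grouped.items():
        for arm in _ARMS:
            if arm not in arms:
                raise ValueError(f"experiment {exp!r} is missing its {arm} arm")
        out[exp] = (table[arms["treatment"]], table[arms["control"]])
    return out


def write_metadata(path, **fields) -> None:
    """JSON metadata sidecar (config, seed, versions) for reproducibility."""
    import srokit

    meta = {"srokit_version": srokit.__version__, **fields}
    with Path(path).open("w") as fh:
        json.dump(meta, fh, indent=1, default=str)
        fh.write("\n")
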