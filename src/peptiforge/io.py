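"""Shared format readers and writers: FASTA, delimited tables, JSON reports.

Delimited dialect is comma by default and tab for ``.tsv``/``.tab``
extensions; a header row is mandatory.  FASTA goes through Biopython's
SeqIO, so wrapped and single-line records are both accepted and ids are
preserved on round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .proteolysis import Peptide, ProteinRecord


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file (validates the alphabet)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), source=rec.description))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    """Write protein or peptide records to FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_table(path, required=None) -> pd.DataFrame:
    """Read a delimited table; raise if required columns are missing."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"table {path} missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=False)


def peptides_to_frame(peptides) -> pd.DataFrame:
    """Tabulate digestion fragments: sequence, parent_id, start, end, length."""
    return pd.DataFrame(
        {
            "sequence": [p.sequence for p in peptides],
            "parent_id": [p.parent_id for p in peptides],
            "start": [p.start for p in peptides],
            "end": [p.end for p in peptides],
            "length": [p.length for p in peptides],
        }
    )


def write_json_report(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
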