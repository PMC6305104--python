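"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices travel as TSV with a ``feature_id`` first column and sample IDs in the
header; sample metadata as TSV with one row per sample; sequences as FASTA
(Biopython). UTR FASTA headers are ``SYMBOL|isoform`` or
``SYMBOL|isoform|assembly``; mature miRNA headers are miRBase style
(``hsa-miR-###``, first whitespace-delimited token is the name).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import PairedExpressionSet

METADATA_COLUMNS = ["sample_id", "subject_id", "tissue", "age", "sex", "msi"]

UTR_HEADER_RE = re.compile(r"^(?P<gene>[^|]+)\|(?P<isoform>[^|]+?)(?:\|(?P<assembly>[^|]+))?$")


def write_matrix(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_id_list(path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_id_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def paired_set_from_files(matrix_path, metadata_path) -> PairedExpressionSet:
    values = read_matrix(matrix_path)
    meta = read_metadata(metadata_path).set_index("sample_id")
    return PairedExpressionSet(
        values=values,
        subject_of=meta["subject_id"].astype(str),
        tissue_of=meta["tissue"],
    )


def read_mirna_fasta(path) -> dict[str, str]:
    """Mature miRNA FASTA -> {name: RNA sequence} (order preserved)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_mirna_fasta(catalog: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in catalog.items()]
    SeqIO.write(records, str(path), "fasta")


def read_utr_fasta(path, header_re: re.Pattern | str = UTR_HEADER_RE):
    """UTR FASTA -> list of (gene, isoform, assembly, sequence) tuples."""
    if isinstance(header_re, str):
        header_re = re.compile(header_re)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = header_re.match(rec.id)
        if m is None:
            raise ValueError(f"UTR header {rec.id!r} does not match the expected SYMBOL|isoform[|assembly] pattern")
        out.append((m["gene"], m["isoform"], m.groupdict().get("assembly") or "", str(rec.seq).upper()))
    return out


def write_utr_fasta(records, path) -> None:
    """``records``: iterable of (gene, isoform, assembly, sequence)."""
    seqrecs = []
    for gene, isoform, assembly, seq in records:
        header = f"{gene}|{isoform}" + (f"|{assembly}" if assembly else "")
        seqrecs.append(SeqRecord(Seq(seq), id=header, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")
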