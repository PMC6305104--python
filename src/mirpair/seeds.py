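"""Seed-match detection between mature miRNAs and mRNA 3' UTRs.

A seed site is an exact Watson-Crick reverse complement of the miRNA's
5'-proximal seed found on the UTR sense strand (the strand the miRNA binds).
Two conventions are shipped:

``literal``
    Seeds are the first six, seven or eight nucleotides of the mature miRNA
    (positions 1..k); site types ``p1-6``, ``p1-7``, ``p1-8``.
``canonical``
    The field-standard tiers anchored at miRNA position 2: ``6mer``
    (positions 2-7), ``7mer-m8`` (2-8), ``7mer-A1`` (2-7 plus an adenine
    opposite position 1) and ``8mer`` (2-8 plus the A1 adenine).

Within one convention, a lower-tier call at the same anchor (the UTR position
of the 6-nt core) is suppressed in favor of the longest site, so a planted
8-nt site is reported exactly once. No G:U wobble, mismatches or context
scoring; ``N`` in a UTR never matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

RNA_ALPHABET = set("ACGU")
DNA_ALPHABET = set("ACGTN")
_RC = {"A": "T", "C": "G", "G": "C", "U": "A"}

LITERAL_TYPES = ("p1-8", "p1-7", "p1-6")  # precedence order, longest first
CANONICAL_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass
class MatureMiRNA:
    """A mature miRNA: miRBase-style name and 5'->3' RNA sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if "T" in seq:
            warnings.warn(f"{self.name}: DNA-alphabet sequence, converting T->U", stacklevel=2)
            seq = seq.replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: invalid symbols {sorted(bad)}")
        if len(seq) < 9:
            raise ValueError(f"{self.name}: mature sequence shorter than 9 nt")
        self.sequence = seq


@dataclass
class UTRRecord:
    """One 3' UTR sequence: gene symbol, isoform ID, assembly tag, DNA 5'->3'."""

    gene: str
    isoform: str
    assembly: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.gene}|{self.isoform}: empty UTR sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.gene}|{self.isoform}: invalid symbols {sorted(bad)}")
        self.sequence = seq


@dataclass(frozen=True)
class SeedMatch:
    """One detected site; ``utr_start``/``utr_end`` are a 0-based half-open interval."""

    mirna: str
    gene: str
    isoform: str
    assembly: str
    site_type: str
    utr_start: int
    utr_end: int


def extract_seed(mirna: MatureMiRNA, k: int, mode: str = "literal") -> str:
    """The seed subsequence (RNA, 5'->3') used to build site patterns.

    Literal mode returns positions 1..k; canonical mode returns positions
    2..k+1 (k in {6, 7}), the 6mer / 7mer-m8 cores. ``k`` must be 6, 7 or 8.
    """
    if k not in (6, 7, 8):
        raise ValueError("seed length k must be 6, 7 or 8")
    seq = mirna.sequence
    if mode == "literal":
        if len(seq) < k:
            raise ValueError("mature sequence shorter than the requested seed")
        return seq[:k]
    if mode == "canonical":
        if k == 8:
            raise ValueError("canonical 8-nt sites add the A1 anchor to the 2-8 core; request k=7")
        return seq[1 : k + 1]
    raise ValueError("mode must be 'literal' or 'canonical'")


def seed_site(seed: str) -> str:
    """Reverse complement of an RNA seed as DNA, read 5'->3' on the UTR strand."""
    bad = set(seed.upper()) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid RNA symbols {sorted(bad)}")
    return "".join(_RC[c] for c in reversed(seed.upper()))


def site_patterns(mirna: MatureMiRNA, mode: str = "literal") -> list[tuple[str, str, int]]:
    """(site_type, UTR pattern, core offset) per site type, precedence order.

    The core offset locates the 6-nt core inside the pattern; matches whose
    cores coincide share an anchor for suppression purposes.
    """
    s = mirna.sequence
    if mode == "literal":
        out = []
        for t, k in zip(LITERAL_TYPES, (8, 7, 6)):
            out.append((t, seed_site(s[:k]), k - 6))
        return out
    if mode == "canonical":
        core6 = seed_site(s[1:7])  # positions 2-7
        core7 = seed_site(s[1:8])  # positions 2-8
        return [
            ("8mer", core7 + "A", 1),
            ("7mer-m8", core7, 1),
            ("7mer-A1", core6 + "A", 0),
            ("6mer", core6, 0),
        ]
    raise ValueError("mode must be 'literal' or 'canonical'")


def _occurrences(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_seed_matches(utr: UTRRecord, mirna: MatureMiRNA, mode: str = "literal") -> list[SeedMatch]:
    """All exact seed sites of ``mirna`` in ``utr`` under one convention.

    Longest-site precedence: when two site types share an anchor (same 6-nt
    core position) only the higher tier is reported. Output is sorted by
    position.
    """
    best: dict[int, tuple[int, str, int, int]] = {}  # anchor -> (precedence, type, start, end)
    for prec, (stype, pattern, off) in enumerate(site_patterns(mirna, mode)):
        for start in _occurrences(utr.sequence, pattern):
            anchor = start + off
            if anchor not in best or prec < best[anchor][0]:
                best[anchor] = (prec, stype, start, start + len(pattern))
    return [
        SeedMatch(mirna.name, utr.gene, utr.isoform, utr.assembly, stype, start, end)
        for _, stype, start, end in (best[a] for a in sorted(best))
    ]


def has_seed_match(mirna: MatureMiRNA, gene: str, utr_db, mode: str = "literal") -> bool:
    """True if any isoform in any assembly of ``gene`` carries any site.

    ``utr_db`` maps gene symbols to lists of :class:`UTRRecord`. A gene
    without UTRs yields False with a warning (recorded as "no UTR available").
    """
    records = utr_db.get(gene, [])
    if not records:
        warnings.warn(f"no UTR available for gene {gene!r}", stacklevel=2)
        return False
    return any(find_seed_matches(u, mirna, mode) for u in records)


class SeedMatcher:
    """Batch seed scanning over a UTR catalog and a miRNA catalog."""

    def __init__(self, mode: str = "literal"):
        if mode not in ("literal", "canonical"):
            raise ValueError("mode must be 'literal' or 'canonical'")
        self.mode = mode

    @staticmethod
    def build_utr_db(utr_records) -> dict[str, list[UTRRecord]]:
        db: dict[str, list[UTRRecord]] = {}
        for rec in utr_records:
            if not isinstance(rec, UTRRecord):
                rec = UTRRecord(*rec)
            db.setdefault(rec.gene, []).append(rec)
        return db

    def scan(self, utr_records, mirnas) -> pd.DataFrame:
        """BED-like site table sorted by (gene, mirna, position)."""
        mirnas = [m if isinstance(m, MatureMiRNA) else MatureMiRNA(*m) for m in mirnas]
        rows = []
        for rec in utr_records:
            if not isinstance(rec, UTRRecord):
                rec = UTRRecord(*rec)
            for m in mirnas:
                for hit in find_seed_matches(rec, m, self.mode):
                    rows.append(
                        {
                            "gene": hit.gene,
                            "isoform": hit.isoform,
                            "assembly": hit.assembly,
                            "utr_start": hit.utr_start,
                            "utr_end": hit.utr_end,
                            "strand": ".",
                            "mirna": hit.mirna,
                            "site_type": hit.site_type,
                        }
                    )
        cols = ["gene", "isoform", "assembly", "utr_start", "utr_end", "strand", "mirna", "site_type"]
        df = pd.DataFrame(rows, columns=cols)
        return df.sort_values(["gene", "mirna", "utr_start", "isoform"], kind="mergesort").reset_index(drop=True)

    def match_matrix(self, utr_records, mirnas) -> pd.DataFrame:
        """Gene x miRNA boolean table: any site on any isoform/assembly."""
        mirnas = [m if isinstance(m, MatureMiRNA) else MatureMiRNA(*m) for m in mirnas]
        db = self.build_utr_db(utr_records)
        genes = sorted(db)
        names = [m.name for m in mirnas]
        data = {
            m.name: [any(find_seed_matches(u, m, self.mode) for u in db[g]) for g in genes] for m in mirnas
        }
        return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=names)
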