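"""Readers/writers and the shared data model for sequences, hits, intervals and trees.

Coordinates are 1-based inclusive everywhere inside the package (the BLAST
convention); BED export converts to 0-based half-open.  Sequences are stored
as uppercase DNA over the alphabet ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO as _BioSeqIO

__all__ = [
    "SeqRecord",
    "Hit",
    "Interval",
    "INTERVAL_KINDS",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "read_hits",
    "write_hits",
    "read_newick",
    "write_newick",
    "write_bed",
    "read_bed",
    "write_gff3",
    "revcomp",
    "encode",
    "decode",
]

INTERVAL_KINDS = frozenset({"TE", "LTR", "domain", "gene", "exclusion", "region"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# A=0 C=1 G=2 T=3 N=4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass
class SeqRecord:
    """A named DNA sequence, optionally tagged with the taxon it came from."""

    id: str
    seq: str
    taxon: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be nonempty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3, anything else=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _CODE_BASE[codes].tobytes().decode("ascii")


@dataclass
class Hit:
    """One local-alignment match between a query and a target contig.

    ``pct_identity`` counts mismatches and gap columns against identity
    (``100 * matches / alignment_columns``).  Target coordinates always
    satisfy ``t_start <= t_end``; a minus-strand placement is recorded in
    ``strand``.
    """

    query_id: str
    target_id: str
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: float
    evalue: float | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            self.t_start, self.t_end = self.t_end, self.t_start
            self.strand = "-" if self.strand == "+" else "+"
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")

    @property
    def t_interval(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)


@dataclass
class Interval:
    """A labelled 1-based inclusive interval on a target contig."""

    target_id: str
    start: int
    end: int
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.kind not in INTERVAL_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start) + 1)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _from_bio(records, fmt: str, taxon: str | None) -> list[SeqRecord]:
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        out.append(SeqRecord(id=rec.id, seq=str(rec.seq), taxon=taxon, description=desc))
    return out


def read_fasta(path: str | Path, taxon: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file; order preserved, lowercase uppercased.

    The description after the first whitespace is kept in ``description``
    but is not part of the id.  Duplicate ids raise; an empty file returns
    an empty list with a warning.
    """
    recs = _from_bio(_BioSeqIO.parse(str(path), "fasta"), "fasta", taxon)
    if not recs:
        warnings.warn(f"no sequences in {path}", stacklevel=2)
    return recs


def read_fastq(path: str | Path, taxon: str | None = None) -> list[SeqRecord]:
    """Read FASTQ reads; base qualities are ignored."""
    recs = _from_bio(_BioSeqIO.parse(str(path), "fastq"), "fastq", taxon)
    if not recs:
        warnings.warn(f"no sequences in {path}", stacklevel=2)
    return recs


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular hits (12-column, outfmt-6 dialect)


def read_hits(path: str | Path, dialect: str = "blast6") -> list[Hit]:
    """Parse 12-column tab-separated local-alignment records.

    Columns: query, target, pct_identity, aln_len, mismatches, gap_opens,
    q_start, q_end, t_start, t_end, evalue, score.  Minus-strand records
    (t_start > t_end) are normalized with the strand retained.
    """
    if dialect != "blast6":
        raise ValueError(f"unknown hits dialect {dialect!r}")
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                hits.append(
                    Hit(
                        query_id=parts[0],
                        target_id=parts[1],
                        pct_identity=float(parts[2]),
                        aln_len=int(parts[3]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        t_start=int(parts[8]),
                        t_end=int(parts[9]),
                        evalue=float(parts[10]),
                        score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return hits


def write_hits(hits: Iterable[Hit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (bit-stable)."""
    with open(path, "w") as fh:
        for h in hits:
            t_start, t_end = h.t_start, h.t_end
            if h.strand == "-":
                t_start, t_end = t_end, t_start
            mism = int(round(h.aln_len * (100.0 - h.pct_identity) / 100.0))
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.target_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_len),
                        str(mism),
                        "0",
                        str(h.q_start),
                        str(h.q_end),
                        str(t_start),
                        str(t_end),
                        f"{h.evalue:.2e}" if h.evalue is not None else "0",
                        f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees (dendropy is the in-memory tree container)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths at 6 decimals.

    Raises on unlabeled or duplicate leaf labels so the file round-trips.
    """
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None or lab == "" for lab in labels):
        raise ValueError("tree has an unlabeled leaf")
    if len(set(labels)) != len(labels):
        raise ValueError("tree has duplicate leaf labels")
    text = tree.as_string(
        schema="newick",
        real_value_format_specifier=".6f",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    with open(path, "w") as fh:
        fh.write(text + "\n")


# ---------------------------------------------------------------------------
# Intervals: BED (0-based half-open on disk) and GFF3 (1-based)


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.target_id}\t{iv.start - 1}\t{iv.end}\t{iv.label or iv.kind}\n")


def read_bed(path: str | Path, kind: str = "region") -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            out.append(
                Interval(
                    target_id=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    kind=kind,
                    label=parts[3] if len(parts) > 3 else "",
                )
            )
    return out


def write_gff3(intervals: Iterable[Interval], path: str | Path, source: str = "htt") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            ftype = {"TE": "mobile_genetic_element", "LTR": "long_terminal_repeat",
                     "domain": "polypeptide_domain", "gene": "gene",
                     "exclusion": "region", "region": "region"}[iv.kind]
            attrs = f"Name={iv.label}" if iv.label else "."
            fh.write(
                f"{iv.target_id}\t{source}\t{ftype}\t{iv.start}\t{iv.end}\t.\t+\t.\t{attrs}\n"
            )
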