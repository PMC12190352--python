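"""Genomic file formats and sequence primitives.

Every coordinate inside this package is 0-based, half-open, on the forward
strand of the named contig.  The single place where the GFF3 convention
(1-based, inclusive) appears is the GFF3 writer/reader in this module; BED
is natively 0-based half-open and needs no conversion.

Minus-strand features store contig-forward coordinates; extracting their
sequence applies reverse complementation.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable


class GenomicIOError(ValueError):
    """Malformed file content or an invalid coordinate/sequence argument."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _codon in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_codon] = "*"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig-anchored span: 0-based half-open [start, end) with strand."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise GenomicIOError(
                f"invalid interval {self.contig_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise GenomicIOError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise GenomicIOError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise GenomicIOError(f"record {self.id}: empty sequence")


@dataclass
class Gff3Feature:
    """One GFF3 row; ``attributes`` is an ordered key->value map."""

    interval: GenomicInterval
    so_type: str
    source: str = "vdjannot"
    score: float | None = None
    phase: int | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


# --------------------------------------------------------------------------
# sequence utilities
# --------------------------------------------------------------------------


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    if not seq:
        raise GenomicIOError("cannot reverse-complement an empty sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate with the standard nuclear code.

    The trailing partial codon is dropped; any codon containing N yields X;
    stop codons are rendered as ``*``.
    """
    if frame not in (0, 1, 2):
        raise GenomicIOError(f"frame must be 0, 1 or 2, got {frame}")
    s = seq.upper()[frame:]
    aa = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        if "N" in codon:
            aa.append("X")
        else:
            try:
                aa.append(_CODON_TO_AA[codon])
            except KeyError:
                raise GenomicIOError(f"untranslatable codon {codon!r}") from None
    return "".join(aa)


def extract_sequence(contig_seq: str, interval: GenomicInterval) -> str:
    """Strand-aware subsequence: minus-strand intervals come back revcomp'ed."""
    if interval.end > len(contig_seq):
        raise GenomicIOError(
            f"interval {interval.start}-{interval.end} exceeds contig length "
            f"{len(contig_seq)}"
        )
    sub = contig_seq[interval.start : interval.end]
    return revcomp(sub) if interval.strand == "-" else sub


def gap_runs(seq: str) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of N in ``seq`` (assembly gaps)."""
    runs = []
    start = None
    for i, base in enumerate(seq):
        if base == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def read_fasta(path: str | Path, *, map_ambiguous_to_n: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into uppercased records; U is mapped to T.

    Characters outside {A,C,G,T,N} are rejected with the offending record id
    unless ``map_ambiguous_to_n`` is set, in which case IUPAC ambiguity codes
    collapse to N.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomicIOError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if map_ambiguous_to_n:
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise GenomicIOError(
                f"record {rec.id}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        raise GenomicIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id + " "):
                    desc = desc[len(rec.id) + 1 :]
                header = f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    """Write BED6: tab-separated, sorted by (contig, start), score in [0,1000]."""
    recs = sorted(records, key=lambda r: (r.interval.contig_id, r.interval.start, r.interval.end, r.name))
    with open(path, "w") as fh:
        for r in recs:
            score = int(round(min(1000.0, max(0.0, r.score))))
            iv = r.interval
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{r.name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read BED3-BED6; track/browser/comment lines are skipped; strand defaults +."""
    out: list[BedRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GenomicIOError(f"line {lineno}: BED needs >=3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise GenomicIOError(
                    f"line {lineno}: non-integer BED coordinates {cols[1]!r}/{cols[2]!r}"
                ) from None
            name = cols[3] if len(cols) > 3 else "."
            try:
                score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            except ValueError:
                raise GenomicIOError(f"line {lineno}: non-numeric BED score {cols[4]!r}") from None
            strand = cols[5] if len(cols) > 5 else "+"
            out.append(BedRecord(GenomicInterval(cols[0], start, end, strand), name, score))
    return out


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

# Characters that must be percent-encoded inside GFF3 attribute values.
_GFF3_ESCAPE = {
    "%": "%25",
    ";": "%3B",
    "=": "%3D",
    "&": "%26",
    ",": "%2C",
    "\t": "%09",
    "\n": "%0A",
}


def _escape_attr(value: str) -> str:
    return "".join(_GFF3_ESCAPE.get(c, c) for c in value)


def _unescape_attr(value: str) -> str:
    return urllib.parse.unquote(value)


def _feature_sort_key(feat: Gff3Feature) -> tuple:
    return (feat.interval.contig_id, feat.interval.start, feat.feature_id or "")


def write_gff3(
    features: Sequence[Gff3Feature],
    sequence_regions: Mapping[str, int],
    path: str | Path,
) -> None:
    """Emit a GFF3 document.

    The first line is exactly ``##gff-version 3``; one ``##sequence-region``
    pragma per contig; coordinates converted to 1-based inclusive; children
    always follow their parents; ordering is deterministic by
    (contig, start, ID).
    """
    by_id: dict[str, Gff3Feature] = {}
    for f in features:
        fid = f.feature_id
        if fid is not None:
            if fid in by_id:
                raise GenomicIOError(f"duplicate GFF3 feature ID {fid!r}")
            by_id[fid] = f
    children: dict[str, list[Gff3Feature]] = {}
    roots: list[Gff3Feature] = []
    for f in features:
        if f.so_type == "CDS" and f.phase is None:
            raise GenomicIOError(f"CDS feature {f.feature_id!r} lacks a phase")
        parent = f.parent
        if parent is None:
            roots.append(f)
        else:
            if parent not in by_id:
                raise GenomicIOError(f"dangling Parent reference {parent!r}")
            children.setdefault(parent, []).append(f)

    lines = ["##gff-version 3"]
    for contig in sorted(sequence_regions):
        lines.append(f"##sequence-region {contig} 1 {sequence_regions[contig]}")

    def emit(feat: Gff3Feature) -> None:
        iv = feat.interval
        score = "." if feat.score is None else f"{feat.score:g}"
        phase = "." if feat.phase is None else str(feat.phase)
        attrs = ";".join(
            f"{_escape_attr(k)}={_escape_attr(v)}" for k, v in feat.attributes.items()
        )
        lines.append(
            "\t".join(
                [
                    iv.contig_id,
                    feat.source,
                    feat.so_type,
                    str(iv.start + 1),
                    str(iv.end),
                    score,
                    iv.strand,
                    phase,
                    attrs or ".",
                ]
            )
        )
        fid = feat.feature_id
        if fid is not None:
            for child in sorted(children.get(fid, []), key=_feature_sort_key):
                emit(child)

    for root in sorted(roots, key=_feature_sort_key):
        emit(root)
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    """Parse a GFF3 document back to 0-based half-open features.

    Requires the version pragma on the first line; every feature line must
    have exactly 9 tab-separated columns; Parent references must resolve.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("##gff-version 3"):
        raise GenomicIOError("missing ##gff-version 3 pragma on line 1")
    feats: list[Gff3Feature] = []
    ids: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GenomicIOError(f"line {lineno}: expected 9 columns, got {len(cols)}")
        contig, source, so_type, start_s, end_s, score_s, strand, phase_s, attr_s = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GenomicIOError(f"line {lineno}: non-integer coordinates") from None
        score = None if score_s == "." else float(score_s)
        phase = None if phase_s == "." else int(phase_s)
        attributes: dict[str, str] = {}
        if attr_s != ".":
            for pair in attr_s.split(";"):
                if not pair:
                    continue
                if "=" not in pair:
                    raise GenomicIOError(f"line {lineno}: malformed attribute {pair!r}")
                k, v = pair.split("=", 1)
                attributes[_unescape_attr(k)] = _unescape_attr(v)
        feat = Gff3Feature(
            GenomicInterval(contig, start1 - 1, end1, strand),
            so_type,
            source,
            score,
            phase,
            attributes,
        )
        if feat.feature_id is not None:
            ids.add(feat.feature_id)
        feats.append(feat)
    for f in feats:
        if f.parent is not None and f.parent not in ids:
            raise GenomicIOError(f"dangling Parent reference {f.parent!r}")
    return feats
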