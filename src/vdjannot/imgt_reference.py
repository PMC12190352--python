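"""IMGT/LIGM-DB flat-file parsing into a reference gene set.

The EMBL-style feature table (FT block) of a LIGM-DB record carries the
annotation that seeds every downstream search: exon-level features such as
L-PART1, V-EXON, J-REGION and the constant-region exon labels, plus
conserved-residue markers (1st-CYST, 2nd-CYST, J-TRP/J-PHE).  LIGM-DB
formatting is not fully standardized, so parsing is deliberately tolerant:
unrecognized labels are kept as passthrough notes and never abort a run,
and every skipped gene is reported in the parse log.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import Align
from Bio.Align import substitution_matrices

from .genomic_io import (
    BedRecord,
    GenomicInterval,
    GenomicIOError,
    SequenceRecord,
    extract_sequence,
    translate,
    write_bed,
    write_fasta,
)

logger = logging.getLogger(__name__)


class FlatFileError(ValueError):
    """Unparseable flat-file syntax (location grammar, sequence block)."""


# Label lexicon: which FT labels assemble which segment type.  This is an
# explicit, extensible policy; anything outside it becomes a passthrough note.
V_LABELS = ("L-PART1", "L-PART2", "V-EXON", "V-REGION")
D_LABELS = ("D-REGION",)
J_LABELS = ("J-REGION",)
C_LABELS = (
    "C-REGION", "CH1", "H", "H1", "H2", "H3", "H4", "CH2", "CH3", "CH4",
    "CH-S", "M", "M1", "M2", "EX1", "EX2", "EX3", "EX4", "EX4UTR",
)
CONSERVED_LABELS = {
    "1st-CYST": "first_cys",
    "2nd-CYST": "second_cys",
    "J-TRP": "j_trp_phe",
    "J-PHE": "j_trp_phe",
}
# Non-coding within an otherwise coding exon list.
NONCODING_LABELS = frozenset({"EX4UTR"})

_EXON_LABELS = {lab: "V" for lab in V_LABELS}
_EXON_LABELS.update({lab: "D" for lab in D_LABELS})
_EXON_LABELS.update({lab: "J" for lab in J_LABELS})
_EXON_LABELS.update({lab: "C" for lab in C_LABELS})

LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRG", "TRD")


# --------------------------------------------------------------------------
# flat-file (EMBL/IMGT) parsing
# --------------------------------------------------------------------------


@dataclass
class RawFeature:
    """One FT entry: label, location parts, strand, qualifiers, partial flag."""

    label: str
    parts: list[tuple[int, int]]  # 0-based half-open, contig-forward
    strand: str
    qualifiers: dict[str, str] = field(default_factory=dict)
    partial: bool = False

    @property
    def start(self) -> int:
        return min(p[0] for p in self.parts)

    @property
    def end(self) -> int:
        return max(p[1] for p in self.parts)


@dataclass
class FlatFile:
    accession: str
    features: list[RawFeature]
    sequence: str | None


def _split_top_level(expr: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for c in expr:
        if c == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise FlatFileError(f"unbalanced parentheses in {expr!r}")
            cur.append(c)
    if depth != 0:
        raise FlatFileError(f"unbalanced parentheses in {expr!r}")
    parts.append("".join(cur))
    return parts


def _parse_location(expr: str, label: str) -> tuple[list[tuple[int, int]], str, bool]:
    """Parse an EMBL location expression.

    Supports n..m, single-base n, complement(...), join(...)/order(...),
    nesting, and fuzzy markers < and > (stripped; reported via the partial
    flag).  Returns (parts, strand, partial) with parts 0-based half-open.
    """
    expr = expr.replace(" ", "")
    partial = "<" in expr or ">" in expr
    clean = expr.replace("<", "").replace(">", "")

    def walk(e: str, strand: str) -> list[tuple[tuple[int, int], str]]:
        if e.startswith("complement(") and e.endswith(")"):
            flipped = "-" if strand == "+" else "+"
            return walk(e[len("complement(") : -1], flipped)
        for op in ("join(", "order("):
            if e.startswith(op) and e.endswith(")"):
                out = []
                for piece in _split_top_level(e[len(op) : -1]):
                    out.extend(walk(piece, strand))
                return out
        m = re.fullmatch(r"(\d+)(?:\.\.(\d+))?", e)
        if not m:
            raise FlatFileError(f"feature {label}: bad location {e!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo or lo < 1:
            raise FlatFileError(f"feature {label}: bad bounds in {e!r}")
        return [((lo - 1, hi), strand)]

    located = walk(clean, "+")
    strands = {s for _, s in located}
    if len(strands) != 1:
        raise FlatFileError(f"feature {label}: mixed strands in one location")
    return [iv for iv, _ in located], strands.pop(), partial


def parse_flatfile(text: str) -> FlatFile:
    """Parse an EMBL/IMGT flat file into its raw feature table and sequence."""
    accession = ""
    features: list[RawFeature] = []
    seq_lines: list[str] = []
    in_seq = False
    pending_label: str | None = None
    pending_loc: str = ""
    pending_quals: list[str] = []

    def flush() -> None:
        nonlocal pending_label, pending_loc, pending_quals
        if pending_label is None:
            return
        parts, strand, partial = _parse_location(pending_loc, pending_label)
        quals: dict[str, str] = {}
        for q in pending_quals:
            body = q.lstrip("/")
            if "=" in body:
                k, v = body.split("=", 1)
                quals[k] = v.strip().strip('"')
            else:
                quals[body] = "true"
        features.append(RawFeature(pending_label, parts, strand, quals, partial))
        pending_label, pending_loc, pending_quals = None, "", []

    for raw in text.splitlines():
        if raw.startswith("//"):
            break
        if in_seq:
            seq_lines.append(re.sub(r"[\d\s]", "", raw))
            continue
        if raw.startswith("ID"):
            body = raw[2:].strip()
            accession = body.split(";")[0].strip()
        elif raw.startswith("SQ"):
            flush()
            in_seq = True
        elif raw.startswith("FT"):
            content = raw[2:]
            stripped = content.strip()
            if not stripped:
                continue
            # A new feature starts when the label column (before col ~16) is
            # populated; continuations are deeply indented.
            is_new = len(content) > 3 and not content[:16].isspace()
            if is_new:
                flush()
                bits = stripped.split(None, 1)
                pending_label = bits[0]
                pending_loc = bits[1] if len(bits) > 1 else ""
            elif stripped.startswith("/"):
                pending_quals.append(stripped)
            elif pending_quals:
                pending_quals[-1] += " " + stripped
            else:
                pending_loc += stripped
    flush()
    sequence = "".join(seq_lines).upper().replace("U", "T") or None
    return FlatFile(accession, features, sequence)


# --------------------------------------------------------------------------
# reference gene set
# --------------------------------------------------------------------------


@dataclass
class ReferenceGene:
    """A reference segment with exon substructure and extracted sequences.

    The full span (first exon start to last exon end, introns included) is
    the search query downstream; ``coding_seq`` is the spliced concatenation
    of coding exons in strand order.  ``conserved_positions`` are 0-based
    nucleotide offsets of codon starts within ``coding_seq``.
    """

    name: str
    allele: str
    segment_type: str
    locus: str
    strand: str
    exons: list[tuple[str, GenomicInterval]]  # ordered along the strand
    full_span: GenomicInterval
    exon_seqs: list[tuple[str, str]]
    full_seq: str
    coding_seq: str
    conserved_positions: dict[str, int] = field(default_factory=dict)
    functionality_label: str | None = None
    frame: int = 0
    notes: list[str] = field(default_factory=list)
    partial: bool = False

    @property
    def label(self) -> str:
        return f"{self.name}*{self.allele}"

    def coding_exons(self) -> list[tuple[str, GenomicInterval]]:
        return [(lab, iv) for lab, iv in self.exons if lab not in NONCODING_LABELS]

    def exon_offsets(self) -> list[tuple[str, int, int]]:
        """Exon spans as offsets within the strand-oriented full sequence."""
        out = []
        for lab, iv in self.exons:
            if self.strand == "+":
                off = iv.start - self.full_span.start
            else:
                off = self.full_span.end - iv.end
            out.append((lab, off, off + iv.length))
        return out

    def coding_offset_to_full_offset(self, coff: int) -> int:
        """Map an offset in coding_seq to an offset in full_seq."""
        acc = 0
        for lab, s, e in self.exon_offsets():
            if lab in NONCODING_LABELS:
                continue
            if coff < acc + (e - s):
                return s + (coff - acc)
            acc += e - s
        raise GenomicIOError(f"{self.label}: coding offset {coff} out of range")


@dataclass
class ReferenceGeneSet:
    genes: list[ReferenceGene]
    source_accession: str
    locus: str
    parse_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.allele_index: dict[str, str] = {}
        self.coding_index: dict[str, str] = {}
        for g in self.genes:
            self.allele_index.setdefault(g.full_seq.upper(), g.label)
            self.coding_index.setdefault(g.coding_seq.upper(), g.label)

    def by_type(self, segment_type: str) -> list[ReferenceGene]:
        return [g for g in self.genes if g.segment_type == segment_type]

    def get(self, label: str) -> ReferenceGene:
        for g in self.genes:
            if g.label == label:
                return g
        raise KeyError(label)


def _gene_key(feat: RawFeature) -> tuple[str, str] | None:
    allele_q = feat.qualifiers.get("IMGT_allele") or feat.qualifiers.get("allele")
    gene_q = feat.qualifiers.get("gene")
    if allele_q and "*" in allele_q:
        name, allele = allele_q.split("*", 1)
        return name, allele
    if gene_q:
        allele = allele_q if allele_q else "01"
        return gene_q, allele
    return None


_PROTEIN_ALIGNER: Align.PairwiseAligner | None = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        a.mode = "global"
        _PROTEIN_ALIGNER = a
    return _PROTEIN_ALIGNER


def _transfer_conserved(gene: ReferenceGene, donors: list[ReferenceGene], log: list[str]) -> None:
    """Locate conserved residues by protein alignment to the closest donor
    gene that carries them; leave unset (check skipped downstream) when no
    mapping lands on the expected residue."""
    aa_query = translate(gene.coding_seq)
    best = None
    for donor in donors:
        if not donor.conserved_positions:
            continue
        aa_donor = translate(donor.coding_seq)
        if not aa_donor or not aa_query:
            continue
        score = _protein_aligner().score(aa_donor, aa_query)
        if best is None or score > best[0]:
            best = (score, donor, aa_donor)
    if best is None:
        return
    _, donor, aa_donor = best
    aln = _protein_aligner().align(aa_donor, aa_query)[0]
    donor_to_query: dict[int, int] = {}
    for (ds, de), (qs, qe) in zip(*aln.aligned):
        for k in range(de - ds):
            donor_to_query[ds + k] = qs + k
    expect = {"first_cys": "C", "second_cys": "C", "j_trp_phe": "WF"}
    for key, noff in donor.conserved_positions.items():
        q_aa = donor_to_query.get(noff // 3)
        if q_aa is None or q_aa >= len(aa_query):
            continue
        if aa_query[q_aa] in expect[key]:
            gene.conserved_positions[key] = q_aa * 3
        else:
            log.append(f"{gene.label}: transferred {key} lands on {aa_query[q_aa]}, skipped")


def build_gene_set(
    flat: FlatFile,
    genome: SequenceRecord | None = None,
    locus: str = "IGH",
) -> ReferenceGeneSet:
    """Group raw features into ReferenceGene records and extract sequences."""
    if genome is None:
        if flat.sequence is None:
            raise GenomicIOError("flat file has no SQ block and no genome was given")
        genome = SequenceRecord(flat.accession or "reference", flat.sequence)
    log: list[str] = []

    groups: dict[tuple[str, str], dict] = {}
    orphans: list[RawFeature] = []
    ordinals: dict[str, int] = {}
    for feat in flat.features:
        if feat.label in _EXON_LABELS or feat.label in CONSERVED_LABELS:
            key = _gene_key(feat)
            if key is None:
                if feat.label in CONSERVED_LABELS:
                    orphans.append(feat)
                    continue
                ordinals[feat.label] = ordinals.get(feat.label, 0) + 1
                key = (f"{feat.label}.{ordinals[feat.label]}", "01")
                log.append(f"unnamed {feat.label} feature; assigned {key[0]}")
            grp = groups.setdefault(key, {"exons": [], "conserved": [], "quals": {}})
            if feat.label in CONSERVED_LABELS:
                grp["conserved"].append(feat)
            else:
                grp["exons"].append(feat)
            grp["quals"].update(feat.qualifiers)
        else:
            log.append(f"passthrough label {feat.label} at {feat.start}-{feat.end}")

    # Attach unnamed conserved-residue features by containment.
    for feat in orphans:
        placed = False
        for key, grp in groups.items():
            if not grp["exons"]:
                continue
            lo = min(f.start for f in grp["exons"])
            hi = max(f.end for f in grp["exons"])
            if lo <= feat.start and feat.end <= hi:
                grp["conserved"].append(feat)
                placed = True
                break
        if not placed:
            log.append(f"orphan conserved feature {feat.label} at {feat.start} dropped")

    genes: list[ReferenceGene] = []
    for (name, allele), grp in groups.items():
        exon_feats: list[RawFeature] = grp["exons"]
        if not exon_feats:
            log.append(f"{name}*{allele}: zero locatable exons, skipped")
            continue
        seg_types = {_EXON_LABELS[f.label] for f in exon_feats}
        if len(seg_types) != 1:
            log.append(f"{name}*{allele}: mixed segment-type labels, skipped")
            continue
        strands = {f.strand for f in exon_feats}
        if len(strands) != 1:
            log.append(f"{name}*{allele}: mixed strands, skipped")
            continue
        strand = strands.pop()
        segment_type = seg_types.pop()

        exon_ivs: list[tuple[str, GenomicInterval]] = []
        for f in exon_feats:
            for s, e in f.parts:
                if e > len(genome.seq):
                    log.append(f"{name}*{allele}: {f.label} outside genome, skipped")
                    break
                exon_ivs.append((f.label, GenomicInterval(genome.id, s, e, strand)))
        if not exon_ivs:
            continue
        exon_ivs.sort(key=lambda x: x[1].start, reverse=(strand == "-"))
        span = GenomicInterval(
            genome.id,
            min(iv.start for _, iv in exon_ivs),
            max(iv.end for _, iv in exon_ivs),
            strand,
        )
        full_seq = extract_sequence(genome.seq, span)
        exon_seqs = [(lab, extract_sequence(genome.seq, iv)) for lab, iv in exon_ivs]
        coding_seq = "".join(s for lab, s in exon_seqs if lab not in NONCODING_LABELS)

        gene = ReferenceGene(
            name=name,
            allele=allele,
            segment_type=segment_type,
            locus=locus,
            strand=strand,
            exons=exon_ivs,
            full_span=span,
            exon_seqs=exon_seqs,
            full_seq=full_seq,
            coding_seq=coding_seq,
            functionality_label=grp["quals"].get("IMGT_note") or grp["quals"].get("functionality"),
            partial=any(f.partial for f in exon_feats),
        )

        # conserved positions: genomic codon location -> offset in coding_seq
        for cf in grp["conserved"]:
            key = CONSERVED_LABELS[cf.label]
            c_s, c_e = cf.parts[0]
            coff = None
            acc = 0
            for lab, iv in exon_ivs:
                if lab in NONCODING_LABELS:
                    continue
                if iv.start <= c_s and c_e <= iv.end:
                    # offset of the codon's first transcribed base
                    coff = acc + (c_s - iv.start if strand == "+" else iv.end - c_e)
                    break
                acc += iv.length
            if coff is None:
                log.append(f"{gene.label}: conserved {cf.label} outside coding exons")
                continue
            codon_aa = translate(gene.coding_seq[coff : coff + 3]) if coff + 3 <= len(gene.coding_seq) else ""
            expected = "C" if key.endswith("cys") else "WF"
            if codon_aa and codon_aa in expected:
                gene.conserved_positions[key] = coff
            else:
                log.append(f"{gene.label}: {cf.label} codon translates to {codon_aa!r}, dropped")

        if segment_type == "J" and "j_trp_phe" in gene.conserved_positions:
            gene.frame = gene.conserved_positions["j_trp_phe"] % 3
        genes.append(gene)

    # Fallback conserved positions by protein alignment.
    for seg, keys in (("V", ("first_cys", "second_cys")), ("J", ("j_trp_phe",))):
        pool = [g for g in genes if g.segment_type == seg]
        donors = [g for g in pool if all(k in g.conserved_positions for k in keys)]
        for g in pool:
            if not g.conserved_positions and donors:
                _transfer_conserved(g, donors, log)
                if g.segment_type == "J" and "j_trp_phe" in g.conserved_positions:
                    g.frame = g.conserved_positions["j_trp_phe"] % 3

    genes.sort(key=lambda g: (g.full_span.start, g.label))
    gs = ReferenceGeneSet(genes, flat.accession, locus, log)
    for entry in log:
        logger.debug("parse log: %s", entry)
    return gs


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------


def gene_set_to_bed(gene_set: ReferenceGeneSet) -> list[BedRecord]:
    """One BED line per exon plus one per full gene span; names encode
    gene|allele|label."""
    records: list[BedRecord] = []
    for g in gene_set.genes:
        for lab, iv in g.exons:
            records.append(BedRecord(iv, f"{g.name}|{g.allele}|{lab}", 0))
        records.append(BedRecord(g.full_span, f"{g.name}|{g.allele}|span", 0))
    return records


def write_reference(gene_set: ReferenceGeneSet, outdir: str | Path) -> None:
    """Write BED + FASTA (full spans and exons) + JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(gene_set_to_bed(gene_set), outdir / "reference.bed")
    spans = [SequenceRecord(g.label.replace("*", "_"), g.full_seq) for g in gene_set.genes]
    write_fasta(spans, outdir / "genes.fasta")
    exon_records = [
        SequenceRecord(f"{g.label.replace('*', '_')}|{i}|{lab}", seq)
        for g in gene_set.genes
        for i, (lab, seq) in enumerate(g.exon_seqs)
    ]
    write_fasta(exon_records, outdir / "exons.fasta")
    meta = {
        "source_accession": gene_set.source_accession,
        "locus": gene_set.locus,
        "genes": [
            {
                "name": g.name,
                "allele": g.allele,
                "segment_type": g.segment_type,
                "strand": g.strand,
                "span": [g.full_span.contig_id, g.full_span.start, g.full_span.end],
                "exons": [[lab, iv.start, iv.end] for lab, iv in g.exons],
                "conserved_positions": g.conserved_positions,
                "frame": g.frame,
                "partial": g.partial,
            }
            for g in gene_set.genes
        ],
        "parse_log": gene_set.parse_log,
    }
    (outdir / "reference.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_reference_dir(refdir: str | Path, locus: str | None = None) -> ReferenceGeneSet:
    """Rebuild a ReferenceGeneSet from a directory written by write_reference."""
    refdir = Path(refdir)
    meta = json.loads((refdir / "reference.json").read_text())
    from .genomic_io import read_fasta

    spans = {r.id: r.seq for r in read_fasta(refdir / "genes.fasta")}
    exons = {r.id: r.seq for r in read_fasta(refdir / "exons.fasta")}
    genes = []
    for gm in meta["genes"]:
        key = f"{gm['name']}_{gm['allele']}"
        strand = gm["strand"]
        exon_ivs = [
            (lab, GenomicInterval(gm["span"][0], s, e, strand)) for lab, s, e in gm["exons"]
        ]
        exon_seqs = [
            (lab, exons[f"{key}|{i}|{lab}"]) for i, (lab, _, _) in enumerate(gm["exons"])
        ]
        coding = "".join(s for lab, s in exon_seqs if lab not in NONCODING_LABELS)
        genes.append(
            ReferenceGene(
                name=gm["name"],
                allele=gm["allele"],
                segment_type=gm["segment_type"],
                locus=meta["locus"],
                strand=strand,
                exons=exon_ivs,
                full_span=GenomicInterval(gm["span"][0], gm["span"][1], gm["span"][2], strand),
                exon_seqs=exon_seqs,
                full_seq=spans[key],
                coding_seq=coding,
                conserved_positions={k: int(v) for k, v in gm["conserved_positions"].items()},
                frame=gm.get("frame", 0),
                partial=gm.get("partial", False),
            )
        )
    return ReferenceGeneSet(genes, meta["source_accession"], locus or meta["locus"], meta.get("parse_log", []))
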