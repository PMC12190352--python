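"""Synthetic IG/TR locus fixtures with exact ground truth.

Real immunogenetic loci mix dozens of short, similar V/D/J segments with
multi-exon constant genes whose introns reach kilobase scale.  This module
builds miniature loci with the same anatomy and a fully known truth set:

* a reference gene set, emitted both as in-memory objects and as a
  syntactically valid IMGT/EMBL-style flat file (so the flat-file parser is
  exercised end to end);
* RSS training windows drawn around a fixed heptamer/spacer/nonamer
  consensus with independent substitution noise (low in the conserved
  heptamer/nonamer, higher in the spacer);
* target contigs with planted, optionally mutated, gene copies flanked by
  RSS of the locus-appropriate spacer classes, plus truth annotations.

Every mutation operator applies exactly one defect per gene, so each
planted gene maps unambiguously to an expected functionality call.
Identical spec + seed always reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genomic_io import GenomicInterval, Gff3Feature, SequenceRecord, revcomp
from .imgt_reference import (
    NONCODING_LABELS,
    ReferenceGene,
    ReferenceGeneSet,
    build_gene_set,
    parse_flatfile,
)
from .rss_ric import RssCandidate, window_length

BASES = "ACGT"
HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
# Fixed spacer consensus strings (arbitrary but constant, like a trained
# model's implicit consensus).
SPACER12 = "CTACAGACTGGA"
SPACER23 = "GTAGTACTCCAGGAGGAAGCATT"

_NONSTOP_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]

OPERATORS = (
    "none",
    "introduce_stop",
    "delete_start",
    "frameshift_del1",
    "scramble_rss",
    "gc_donor",
    "mutate_cys",
    "insert_n_gap",
)

EXPECTED_CALL = {
    "none": ("functional", None, False),
    "introduce_stop": ("pseudogene", "INTERNAL_STOP", False),
    "delete_start": ("pseudogene", "NO_START", False),
    "frameshift_del1": ("pseudogene", "FRAMESHIFT", False),
    "scramble_rss": ("ORF", "RSS_MISSING", False),
    "gc_donor": ("ORF", "NONCANONICAL_SPLICE", False),
    "mutate_cys": ("ORF", "MISSING_CONSERVED_CYS", False),
    "insert_n_gap": (None, None, True),
}

# which operators are meaningful for which segment type
OPERATOR_SEGMENTS = {
    "introduce_stop": ("V", "J", "C"),
    "delete_start": ("V",),
    "frameshift_del1": ("V", "J", "C"),
    "scramble_rss": ("V", "D", "J"),
    "gc_donor": ("V", "C"),
    "mutate_cys": ("V",),
    "insert_n_gap": ("V", "C"),
}


@dataclass
class LocusSpec:
    """Counts, length ranges and composition of one synthetic locus."""

    locus: str = "IGH"
    n_v: int = 8
    n_d: int = 4
    n_j: int = 6
    n_c: int = 2
    seed: int = 0
    v_coding_range: tuple[int, int] = (270, 310)
    l_part1_range: tuple[int, int] = (45, 60)
    v_intron_range: tuple[int, int] = (80, 150)
    d_range: tuple[int, int] = (10, 35)
    j_range: tuple[int, int] = (45, 65)
    c_exon_count_range: tuple[int, int] = (2, 4)
    c_exon_range: tuple[int, int] = (100, 330)
    c_intron_range: tuple[int, int] = (100, 2000)
    intergenic_range: tuple[int, int] = (500, 5000)
    gc_content: float = 0.5
    rss_conserved_noise: float = 0.02
    rss_spacer_noise: float = 0.12


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _rint(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


# --------------------------------------------------------------------------
# RSS sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RssSampler:
    """Draws RSS windows around the heptamer/spacer/nonamer consensus."""

    spacer_class: int
    conserved_noise: float = 0.02
    spacer_noise: float = 0.12

    @property
    def spacer(self) -> str:
        return SPACER12 if self.spacer_class == 12 else SPACER23

    @property
    def consensus(self) -> str:
        return HEPTAMER + self.spacer + NONAMER

    def sample(self, rng: np.random.Generator) -> str:
        out = []
        for i, base in enumerate(self.consensus):
            rate = (
                self.conserved_noise
                if i < len(HEPTAMER) or i >= len(HEPTAMER) + len(self.spacer)
                else self.spacer_noise
            )
            if rng.random() < rate:
                out.append(BASES[int(rng.integers(0, 4))])
            else:
                out.append(base)
        return "".join(out)


def generate_rss_training(
    spacer_class: int,
    n: int = 500,
    seed: int = 0,
    conserved_noise: float = 0.02,
    spacer_noise: float = 0.12,
) -> list[str]:
    """n windows of length 16+spacer sampled around the consensus."""
    sampler = RssSampler(spacer_class, conserved_noise, spacer_noise)
    rng = np.random.default_rng([seed, spacer_class, 911])
    windows = [sampler.sample(rng) for _ in range(n)]
    assert all(len(w) == window_length(spacer_class) for w in windows)
    return windows


# --------------------------------------------------------------------------
# reference synthesis
# --------------------------------------------------------------------------


@dataclass
class GeneDesign:
    name: str
    allele: str
    segment_type: str
    # ordered pieces in gene orientation: ("exon", label, seq) or ("intron", None, seq)
    pieces: list[tuple[str, str | None, str]]
    conserved: dict[str, int] = field(default_factory=dict)  # coding nt offsets
    frame: int = 0

    @property
    def full_seq(self) -> str:
        return "".join(seq for _, _, seq in self.pieces)

    @property
    def coding_seq(self) -> str:
        return "".join(seq for kind, _, seq in self.pieces if kind == "exon")

    def exon_offsets(self) -> list[tuple[str, int, int]]:
        out, pos = [], 0
        for kind, label, seq in self.pieces:
            if kind == "exon":
                out.append((label, pos, pos + len(seq)))
            pos += len(seq)
        return out


def _make_v(rng: np.random.Generator, name: str, spec: LocusSpec) -> GeneDesign:
    lp1_codons = _rint(rng, (spec.l_part1_range[0] // 3, spec.l_part1_range[1] // 3))
    lp1 = "ATG" + _random_codons(rng, lp1_codons - 1)
    intron_len = _rint(rng, spec.v_intron_range)
    intron = "GT" + _random_seq(rng, intron_len - 4, spec.gc_content) + "AG"
    vex_codons = _rint(rng, ((spec.v_coding_range[0] + 2) // 3, spec.v_coding_range[1] // 3))
    vexon = _random_codons(rng, vex_codons)
    total_codons = lp1_codons + vex_codons
    cys1 = lp1_codons + 7
    cys2 = total_codons - 11
    coding = lp1 + vexon
    coding = (
        coding[: cys1 * 3]
        + ("TGT" if rng.random() < 0.5 else "TGC")
        + coding[cys1 * 3 + 3 : cys2 * 3]
        + ("TGT" if rng.random() < 0.5 else "TGC")
        + coding[cys2 * 3 + 3 :]
    )
    lp1 = coding[: lp1_codons * 3]
    vexon = coding[lp1_codons * 3 :]
    return GeneDesign(
        name,
        "01",
        "V",
        [("exon", "L-PART1", lp1), ("intron", None, intron), ("exon", "V-EXON", vexon)],
        conserved={"first_cys": cys1 * 3, "second_cys": cys2 * 3},
    )


def _make_d(rng: np.random.Generator, name: str, spec: LocusSpec) -> GeneDesign:
    seq = _random_seq(rng, _rint(rng, spec.d_range), spec.gc_content)
    return GeneDesign(name, "01", "D", [("exon", "D-REGION", seq)])


def _make_j(rng: np.random.Generator, name: str, spec: LocusSpec) -> GeneDesign:
    j_len = _rint(rng, spec.j_range)
    frame = int(rng.integers(0, 3))
    m = (j_len - frame) // 3
    tail = j_len - frame - 3 * m
    body = _random_codons(rng, m)
    wf_codon = m - 4
    motif = "TGG" if rng.random() < 0.5 else "TTC"
    body = body[: wf_codon * 3] + motif + body[wf_codon * 3 + 3 :]
    seq = _random_seq(rng, frame, spec.gc_content) + body + _random_seq(rng, tail, spec.gc_content)
    return GeneDesign(
        name,
        "01",
        "J",
        [("exon", "J-REGION", seq)],
        conserved={"j_trp_phe": frame + wf_codon * 3},
        frame=frame,
    )


def _make_c(rng: np.random.Generator, name: str, spec: LocusSpec) -> GeneDesign:
    n_ex = _rint(rng, spec.c_exon_count_range)
    lens = [_rint(rng, spec.c_exon_range) for _ in range(n_ex)]
    total = sum(lens)
    lens[-1] -= total % 3
    total = sum(lens)
    coding = _random_codons(rng, total // 3)
    pieces: list[tuple[str, str | None, str]] = []
    pos = 0
    for i, ln in enumerate(lens):
        pieces.append(("exon", f"CH{i + 1}", coding[pos : pos + ln]))
        pos += ln
        if i < n_ex - 1:
            intron_len = _rint(rng, spec.c_intron_range)
            pieces.append(("intron", None, "GT" + _random_seq(rng, intron_len - 4, spec.gc_content) + "AG"))
    return GeneDesign(name, "01", "C", pieces)


def make_designs(spec: LocusSpec, rng: np.random.Generator) -> list[GeneDesign]:
    designs: list[GeneDesign] = []
    for i in range(spec.n_v):
        designs.append(_make_v(rng, f"{spec.locus}V1-{i + 1}", spec))
    for i in range(spec.n_d):
        designs.append(_make_d(rng, f"{spec.locus}D1-{i + 1}", spec))
    for i in range(spec.n_j):
        designs.append(_make_j(rng, f"{spec.locus}J1-{i + 1}", spec))
    for i in range(spec.n_c):
        designs.append(_make_c(rng, f"{spec.locus}C{i + 1}", spec))
    return designs


@dataclass
class SyntheticReference:
    spec: LocusSpec
    designs: list[GeneDesign]
    genome: SequenceRecord
    flatfile_text: str
    # gene-oriented planted spans on the reference genome (label -> (start, end, strand))
    spans: dict[str, tuple[int, int, str]]

    def gene_set(self) -> ReferenceGeneSet:
        flat = parse_flatfile(self.flatfile_text)
        return build_gene_set(flat, locus=self.spec.locus)


def _format_location(parts: list[tuple[int, int]], strand: str) -> str:
    segs = [f"{s + 1}..{e}" for s, e in parts]
    body = segs[0] if len(segs) == 1 else "join(" + ",".join(segs) + ")"
    return f"complement({body})" if strand == "-" else body


def _flatfile_lines(accession: str, features: list[tuple[str, str, dict[str, str]]], seq: str) -> str:
    lines = [f"ID   {accession}; SV 1; linear; genomic DNA; STD; SYN; {len(seq)} BP."]
    lines.append("FH   Key             Location/Qualifiers")
    for label, location, quals in features:
        lines.append(f"FT   {label:<16}{location}")
        for k, v in quals.items():
            lines.append(f'FT                   /{k}="{v}"')
    lines.append(f"SQ   Sequence {len(seq)} BP;")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"     {grouped:<66}{min(i + 60, len(seq))}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def generate_reference(spec: LocusSpec) -> SyntheticReference:
    """Lay the designed genes onto a reference contig and emit the matching
    IMGT-style flat file (some genes on the minus strand, one C gene as a
    join() feature, to exercise the location grammar)."""
    rng = np.random.default_rng([spec.seed, 101])
    designs = make_designs(spec, rng)
    chunks: list[str] = []
    pos = 0
    ft: list[tuple[str, str, dict[str, str]]] = []
    spans: dict[str, tuple[int, int, str]] = {}
    first_c = True
    for design in designs:
        gap = _rint(rng, (300, 800))
        chunks.append(_random_seq(rng, gap, spec.gc_content))
        pos += gap
        strand = "-" if rng.random() < 0.3 else "+"
        gseq = design.full_seq
        glen = len(gseq)
        chunks.append(gseq if strand == "+" else revcomp(gseq))
        g_start = pos
        pos += glen
        quals = {"gene": design.name, "IMGT_allele": f"{design.name}*{design.allele}"}

        def genomic(a: int, b: int) -> tuple[int, int]:
            # gene-oriented offsets -> contig-forward coordinates
            if strand == "+":
                return g_start + a, g_start + b
            return g_start + glen - b, g_start + glen - a

        exon_feats = design.exon_offsets()
        if design.segment_type == "C" and first_c:
            parts = [genomic(s, e) for _, s, e in exon_feats]
            parts.sort()
            ft.append(("C-REGION", _format_location(parts, strand), dict(quals)))
            first_c = False
        else:
            for label, s, e in exon_feats:
                ft.append((label, _format_location([genomic(s, e)], strand), dict(quals)))
        for key, coff in design.conserved.items():
            # offset within coding -> offset within full gene (exons only here
            # for V: L-PART1 then V-EXON with the intron between)
            acc = 0
            for label, s, e in exon_feats:
                if coff < acc + (e - s):
                    full_off = s + (coff - acc)
                    break
                acc += e - s
            label = {"first_cys": "1st-CYST", "second_cys": "2nd-CYST"}.get(key)
            if label is None:
                label = "J-TRP" if design.coding_seq[coff : coff + 3] == "TGG" else "J-PHE"
            ft.append((label, _format_location([genomic(full_off, full_off + 3)], strand), dict(quals)))
        spans[f"{design.name}*{design.allele}"] = (g_start, g_start + glen, strand)
    tail = _rint(rng, (300, 800))
    chunks.append(_random_seq(rng, tail, spec.gc_content))
    genome_seq = "".join(chunks)
    accession = f"SYN{spec.locus}{spec.seed:04d}"
    text = _flatfile_lines(accession, ft, genome_seq)
    return SyntheticReference(spec, designs, SequenceRecord(accession, genome_seq), text, spans)


# --------------------------------------------------------------------------
# planting with mutations
# --------------------------------------------------------------------------


@dataclass
class TruthRecord:
    name: str  # gene*allele
    segment_type: str
    strand: str
    span: GenomicInterval
    exons: list[tuple[str, GenomicInterval]]
    rss: list[RssCandidate]
    operator: str
    expected_functionality: str | None
    expected_reason: str | None
    expected_withheld: bool


@dataclass
class PlantedLocus:
    contig: SequenceRecord
    truth: list[TruthRecord]
    rules_locus: str

    def truth_gff3(self) -> list[Gff3Feature]:
        feats: list[Gff3Feature] = []
        for i, t in enumerate(sorted(self.truth, key=lambda t: t.span.start), start=1):
            gid = f"truth{i:04d}"
            so = {"V": "V_gene_segment", "D": "D_gene_segment", "J": "J_gene_segment", "C": "C_gene_segment"}
            attrs = {"ID": gid, "Name": t.name, "operator": t.operator}
            if t.expected_functionality:
                attrs["functionality"] = t.expected_functionality
            feats.append(Gff3Feature(t.span, so[t.segment_type], attributes=attrs))
            for j, (lab, iv) in enumerate(t.exons, start=1):
                feats.append(
                    Gff3Feature(iv, "exon", attributes={"ID": f"{gid}.exon{j}", "Parent": gid, "Name": lab})
                )
            for j, r in enumerate(t.rss, start=1):
                feats.append(
                    Gff3Feature(
                        r.interval,
                        "recombination_signal_sequence",
                        attributes={"ID": f"{gid}.rss{j}", "spacer_length": str(r.spacer_class)},
                    )
                )
        return feats


class _PlantError(ValueError):
    pass


def _apply_operator(
    gene: ReferenceGene,
    operator: str,
    rng: np.random.Generator,
    n_gap_len: int = 200,
) -> tuple[str, list[tuple[str, int, int]], bool]:
    """Apply one mutation operator to the gene-oriented full sequence.

    Returns (sequence, exon offsets, scramble_rss_flag); offsets track any
    length change so truth intervals stay exact.
    """
    seq = gene.full_seq
    offsets = gene.exon_offsets()
    if operator in ("none", "scramble_rss"):
        return seq, offsets, operator == "scramble_rss"
    if operator not in EXPECTED_CALL:
        raise _PlantError(f"unknown operator {operator!r}")
    if operator in OPERATOR_SEGMENTS and gene.segment_type not in OPERATOR_SEGMENTS[operator]:
        raise _PlantError(f"{operator} not applicable to {gene.segment_type} gene {gene.label}")

    def coding_to_full(coff: int) -> int:
        return gene.coding_offset_to_full_offset(coff)

    if operator == "introduce_stop":
        if gene.segment_type == "V":
            c1 = gene.conserved_positions["first_cys"] // 3
            c2 = gene.conserved_positions["second_cys"] // 3
            codon = (c1 + c2) // 2
            coff = codon * 3
        elif gene.segment_type == "J":
            coff = gene.frame + 6  # third in-frame codon, upstream of the W/F
        else:
            coff = 30
        f = coding_to_full(coff)
        seq = seq[:f] + "TAA" + seq[f + 3 :]
        return seq, offsets, False
    if operator == "delete_start":
        f = coding_to_full(2)
        seq = seq[:f] + "C" + seq[f + 1 :]  # ATG -> ATC
        return seq, offsets, False
    if operator == "frameshift_del1":
        if gene.segment_type == "V":
            coff = gene.conserved_positions["second_cys"] - 30
        elif gene.segment_type == "J":
            coff = gene.frame + 9
        else:
            coff = 50
        f = coding_to_full(coff)
        seq = seq[:f] + seq[f + 1 :]
        new_offsets = []
        for lab, s, e in offsets:
            new_offsets.append(
                (lab, s - (1 if s > f else 0), e - (1 if e > f else 0))
            )
        return seq, new_offsets, False
    if operator == "gc_donor":
        lab0, s0, e0 = offsets[0]
        if len(offsets) < 2:
            raise _PlantError(f"gc_donor needs a multi-exon gene, got {gene.label}")
        # donor GT begins right after the first exon
        seq = seq[:e0] + "GC" + seq[e0 + 2 :]
        return seq, offsets, False
    if operator == "mutate_cys":
        coff = gene.conserved_positions["second_cys"]
        f = coding_to_full(coff)
        seq = seq[:f] + "GG" + seq[f + 2 :]  # TGT/TGC -> GGT/GGC (Gly)
        return seq, offsets, False
    if operator == "insert_n_gap":
        # middle of the last coding exon
        lab, s, e = offsets[-1]
        mid = (s + e) // 2
        seq = seq[:mid] + "N" * n_gap_len + seq[mid:]
        new_offsets = []
        for off_lab, os_, oe in offsets:
            ns = os_ + (n_gap_len if os_ > mid else 0)
            ne = oe + (n_gap_len if oe > mid else 0)
            new_offsets.append((off_lab, ns, ne))
        return seq, new_offsets, False
    raise _PlantError(operator)


def plant_locus(
    spec: LocusSpec,
    reference: ReferenceGeneSet,
    mutations: dict[str, str] | None = None,
    contig_id: str = "target",
    rss_noise_scale: float = 1.0,
) -> PlantedLocus:
    """Place reference genes (optionally mutated) with flanking RSS into
    fresh background; returns the contig plus exact truth records.

    ``mutations`` maps gene label (name*allele) -> operator.  Planted RSS
    are drawn from the same sampler family as the training windows, so they
    are detectable at the default trained threshold; ``rss_noise_scale``
    > 1 probes threshold sensitivity.
    """
    from .annotator import DEFAULT_LOCUS_RULES, required_flanks

    mutations = mutations or {}
    unknown = set(mutations) - {g.label for g in reference.genes}
    if unknown:
        raise _PlantError(f"mutations reference unknown genes: {sorted(unknown)}")
    rules = DEFAULT_LOCUS_RULES[spec.locus]
    rng = np.random.default_rng([spec.seed, 202])
    samplers = {
        cls: RssSampler(
            cls,
            min(1.0, spec.rss_conserved_noise * rss_noise_scale),
            min(1.0, spec.rss_spacer_noise * rss_noise_scale),
        )
        for cls in (12, 23)
    }

    order = {"V": 0, "D": 1, "J": 2, "C": 3}
    genes = sorted(reference.genes, key=lambda g: (order[g.segment_type], g.label))

    chunks: list[str] = []
    pos = 0
    truth: list[TruthRecord] = []
    for gene in genes:
        gap = _rint(rng, spec.intergenic_range)
        chunks.append(_random_seq(rng, gap, spec.gc_content))
        pos += gap
        operator = mutations.get(gene.label, "none")
        gseq, offsets, scramble = _apply_operator(gene, operator, rng)
        strand = "-" if rng.random() < 0.4 else "+"

        flanks = required_flanks(gene.segment_type, rules)
        w5 = w3 = None
        if "5p" in flanks:
            w5 = samplers[flanks["5p"]].sample(rng)
        if "3p" in flanks:
            w3 = samplers[flanks["3p"]].sample(rng)
        if scramble:
            # scramble the single required flank for V/J; the 3' flank for D
            target = "3p" if w3 is not None else "5p"
            win = w3 if target == "3p" else w5
            shuffled = win
            for _ in range(10):
                perm = rng.permutation(len(win))
                shuffled = "".join(win[i] for i in perm)
                if shuffled != win:
                    break
            if target == "3p":
                w3 = shuffled
            else:
                w5 = shuffled

        asm = (revcomp(w5) if w5 else "") + gseq + (w3 if w3 else "")
        off5 = len(w5) if w5 else 0
        M = len(asm)
        chunk = asm if strand == "+" else revcomp(asm)
        P = pos
        chunks.append(chunk)
        pos += M

        def to_contig(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return P + a, P + b
            return P + M - b, P + M - a

        g_s, g_e = to_contig(off5, off5 + len(gseq))
        span = GenomicInterval(contig_id, g_s, g_e, strand)
        exons = []
        for lab, s, e in offsets:
            es, ee = to_contig(off5 + s, off5 + e)
            exons.append((lab, GenomicInterval(contig_id, es, ee, strand)))
        rss_records: list[RssCandidate] = []
        if w5:
            a, b = to_contig(0, off5)
            orient = "-" if strand == "+" else "+"
            if not scramble or (w3 is not None):
                rss_records.append(
                    RssCandidate(GenomicInterval(contig_id, a, b, orient), flanks["5p"], 0.0)
                )
        if w3:
            a, b = to_contig(off5 + len(gseq), M)
            orient = "+" if strand == "+" else "-"
            scrambled_3p = scramble and w3 is not None
            if not scrambled_3p:
                rss_records.append(
                    RssCandidate(GenomicInterval(contig_id, a, b, orient), flanks["3p"], 0.0)
                )
        expected_func, expected_reason, withheld = EXPECTED_CALL[operator]
        truth.append(
            TruthRecord(
                name=gene.label,
                segment_type=gene.segment_type,
                strand=strand,
                span=span,
                exons=exons,
                rss=rss_records,
                operator=operator,
                expected_functionality=expected_func,
                expected_reason=expected_reason,
                expected_withheld=withheld,
            )
        )
    tail = _rint(rng, spec.intergenic_range)
    chunks.append(_random_seq(rng, tail, spec.gc_content))
    return PlantedLocus(SequenceRecord(contig_id, "".join(chunks)), truth, spec.locus)


# --------------------------------------------------------------------------
# reference divergence (annotation-transfer analogue)
# --------------------------------------------------------------------------


def mutate_reference(reference: ReferenceGeneSet, rate: float, seed: int) -> ReferenceGeneSet:
    """Apply i.i.d. substitutions at the given rate to every reference gene
    sequence, emulating transfer of annotations from a diverged species."""
    rng = np.random.default_rng([seed, 303])
    new_genes = []
    for gene in reference.genes:
        seq = list(gene.full_seq)
        for i in range(len(seq)):
            if seq[i] != "N" and rng.random() < rate:
                choices = [b for b in BASES if b != seq[i]]
                seq[i] = choices[int(rng.integers(0, 3))]
        full = "".join(seq)
        exon_seqs = [(lab, full[s:e]) for lab, s, e in gene.exon_offsets()]
        coding = "".join(s for (lab, s) in exon_seqs if lab not in NONCODING_LABELS)
        new_genes.append(
            replace(
                gene,
                exon_seqs=exon_seqs,
                full_seq=full,
                coding_seq=coding,
            )
        )
    return ReferenceGeneSet(new_genes, reference.source_accession, reference.locus, list(reference.parse_log))
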