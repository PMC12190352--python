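"""Candidate verification, functionality classification, allele naming,
and GFF3 emission.

A recovered candidate gene is put through the checks that define the
standard immunogenetics functionality taxonomy:

* RSS matching -- a V, D or J segment must carry a recombination signal
  sequence of the locus-appropriate spacer class on each required flank.
* Splice verification -- every intron of a multi-exon gene (V leader
  intron, constant-gene introns) must begin with the canonical GT donor
  and end with the canonical AG acceptor.
* Coding checks -- internal stop codons; the ATG start codon (V genes
  only); reading-frame preservation relative to the reference; the two
  invariant cysteines of V regions and the invariant tryptophan or
  phenylalanine of J regions.

Classification precedence: any pseudogene-class defect (internal stop,
frameshift, missing start) makes the gene a pseudogene; otherwise any
ORF-class defect (missing RSS, non-canonical splice, missing invariant
residue) makes it an ORF; otherwise it is functional.  Candidates that are
incomplete -- coding coverage below a threshold or assembly-gap Ns inside
the projected coding region -- are withheld from output and logged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

from .genomic_io import (
    GenomicInterval,
    GenomicIOError,
    Gff3Feature,
    SequenceRecord,
    revcomp,
    translate,
)
from .homology import (
    ChainedCandidate,
    DEFAULT_SEARCH_PARAMS,
    SearchParams,
    chain_hits,
    search,
    select_candidates,
)
from .imgt_reference import NONCODING_LABELS, ReferenceGene, ReferenceGeneSet
from .rss_ric import RssCandidate

logger = logging.getLogger(__name__)

SEGMENT_ORDER = ("V", "D", "J", "C")

SO_TYPES = {
    "V": "V_gene_segment",
    "D": "D_gene_segment",
    "J": "J_gene_segment",
    "C": "C_gene_segment",
}

# reason codes
PSEUDOGENE_CODES = frozenset({"INTERNAL_STOP", "FRAMESHIFT", "NO_START"})
ORF_CODES = frozenset(
    {"RSS_MISSING", "NONCANONICAL_SPLICE", "MISSING_CONSERVED_CYS", "MISSING_CONSERVED_WF"}
)


@dataclass(frozen=True)
class LocusRules:
    """Which RSS spacer classes flank each recombining segment type."""

    locus: str
    v_spacer: int
    j_spacer: int
    d_spacers: tuple[int, int] | None = None  # (5' flank, 3' flank)

    @property
    def has_d(self) -> bool:
        return self.d_spacers is not None


# Standard immunogenetics spacer assignments per locus; overridable.
DEFAULT_LOCUS_RULES: dict[str, LocusRules] = {
    "IGH": LocusRules("IGH", v_spacer=23, j_spacer=23, d_spacers=(12, 12)),
    "IGK": LocusRules("IGK", v_spacer=12, j_spacer=23),
    "IGL": LocusRules("IGL", v_spacer=23, j_spacer=12),
    "TRA": LocusRules("TRA", v_spacer=23, j_spacer=12),
    "TRB": LocusRules("TRB", v_spacer=23, j_spacer=12, d_spacers=(12, 23)),
    "TRD": LocusRules("TRD", v_spacer=23, j_spacer=12, d_spacers=(12, 23)),
    "TRG": LocusRules("TRG", v_spacer=23, j_spacer=12),
}


@dataclass
class AnnotationParams:
    rss_tolerance: int = 3
    completeness_min: float = 0.95
    max_intron: int = 16000
    query_gap_slack: int = 50
    overlap_frac: float = 0.5
    search_params: dict[str, SearchParams] = field(
        default_factory=lambda: dict(DEFAULT_SEARCH_PARAMS)
    )
    engine: str = "builtin"
    # a D candidate with no matched RSS on either flank is indistinguishable
    # from a chance short match and is withheld rather than reported
    require_d_rss: bool = True


@dataclass
class VerificationReport:
    rss_found: dict[str, RssCandidate | None] = field(default_factory=dict)
    splice_ok: bool = True
    introns: list[tuple[str, str]] = field(default_factory=list)  # (donor, acceptor)
    start_codon_ok: bool | None = None
    internal_stop: bool = False
    first_stop_offset: int | None = None
    frameshift: bool = False
    conserved_ok: dict[str, bool] = field(default_factory=dict)
    complete: bool = True
    completeness: float = 1.0
    gap_overlap: int = 0

    @property
    def all_rss_found(self) -> bool:
        return all(v is not None for v in self.rss_found.values())


@dataclass
class AnnotatedFeature:
    candidate: ChainedCandidate
    functionality: str  # functional | ORF | pseudogene
    reasons: list[str]
    assigned_name: str
    matched_rss: list[RssCandidate]
    report: VerificationReport
    coding_seq: str
    frame: int = 0


@dataclass
class WithheldRecord:
    reference_gene: str
    span: GenomicInterval
    cause: str


@dataclass
class AnnotationResult:
    features: list[AnnotatedFeature]
    withheld: list[WithheldRecord]
    gff3: list[Gff3Feature]
    sequence_regions: dict[str, int]


# --------------------------------------------------------------------------
# RSS matching
# --------------------------------------------------------------------------


def required_flanks(segment_type: str, rules: LocusRules) -> dict[str, int]:
    """Map flank name ('5p'/'3p' in gene orientation) -> spacer class."""
    if segment_type == "V":
        return {"3p": rules.v_spacer}
    if segment_type == "J":
        return {"5p": rules.j_spacer}
    if segment_type == "D":
        if rules.d_spacers is None:
            return {}
        return {"5p": rules.d_spacers[0], "3p": rules.d_spacers[1]}
    return {}


def _flank_geometry(candidate: ChainedCandidate, flank: str) -> tuple[int, str]:
    """Contig coordinate of the coding boundary for a flank, and the RSS
    orientation expected there.

    For a plus-strand gene the 3' flank RSS reads heptamer-first left to
    right ('+' orientation, heptamer at window start) and the 5' flank RSS
    lies on the reverse strand ('-', heptamer at window end); a
    minus-strand gene mirrors both.
    """
    exons = [iv for lab, iv in candidate.exon_map if lab not in NONCODING_LABELS]
    if not exons:
        raise GenomicIOError(f"{candidate.reference_gene}: empty exon map")
    lo = min(iv.start for iv in exons)
    hi = max(iv.end for iv in exons)
    if candidate.strand == "+":
        if flank == "3p":
            return hi, "+"
        return lo, "-"
    if flank == "3p":
        return lo, "-"
    return hi, "+"


def match_rss(
    candidate: ChainedCandidate,
    rss: list[RssCandidate],
    rules: LocusRules,
    tolerance: int = 3,
) -> dict[str, RssCandidate | None]:
    """For each required flank, the best-scoring RSS of the right spacer
    class and orientation whose heptamer edge lies within ``tolerance`` nt
    of the gene boundary; ties go to the smaller start coordinate."""
    result: dict[str, RssCandidate | None] = {}
    for flank, spacer in required_flanks(candidate.segment_type, rules).items():
        boundary, orientation = _flank_geometry(candidate, flank)
        eligible = [
            c
            for c in rss
            if c.spacer_class == spacer
            and c.interval.strand == orientation
            and c.interval.contig_id == candidate.span.contig_id
            and abs(c.heptamer_boundary - boundary) <= tolerance
        ]
        if eligible:
            result[flank] = min(eligible, key=lambda c: (-c.score, c.interval.start))
        else:
            result[flank] = None
    return result


# --------------------------------------------------------------------------
# splice and coding verification
# --------------------------------------------------------------------------


def _strand_space_exons(candidate: ChainedCandidate, contig_len: int) -> list[tuple[str, int, int]]:
    """Exon spans as offsets on the strand the gene reads."""
    out = []
    for lab, iv in candidate.exon_map:
        if candidate.strand == "+":
            out.append((lab, iv.start, iv.end))
        else:
            out.append((lab, contig_len - iv.end, contig_len - iv.start))
    return out


def verify_splice(candidate: ChainedCandidate, contig: SequenceRecord) -> tuple[bool, list[tuple[str, str]]]:
    """Check GT donor / AG acceptor for every intron of a multi-exon
    candidate; single-exon candidates vacuously pass."""
    tseq = contig.seq if candidate.strand == "+" else revcomp(contig.seq)
    exons = _strand_space_exons(candidate, len(contig.seq))
    observed: list[tuple[str, str]] = []
    ok = True
    for (_, _, e_prev), (_, s_next, _) in zip(exons, exons[1:]):
        donor = tseq[e_prev : e_prev + 2]
        acceptor = tseq[s_next - 2 : s_next]
        observed.append((donor, acceptor))
        if donor != "GT" or acceptor != "AG":
            ok = False
    return ok, observed


def candidate_coding_seq(candidate: ChainedCandidate, contig: SequenceRecord) -> str:
    tseq = contig.seq if candidate.strand == "+" else revcomp(contig.seq)
    exons = _strand_space_exons(candidate, len(contig.seq))
    return "".join(tseq[s:e] for lab, s, e in exons if lab not in NONCODING_LABELS)


def _full_offset_to_coding_offset(candidate: ChainedCandidate, t_pos: int, contig_len: int) -> int | None:
    """Map a strand-space target position into the candidate coding seq."""
    acc = 0
    for lab, s, e in _strand_space_exons(candidate, contig_len):
        if lab in NONCODING_LABELS:
            continue
        if s <= t_pos < e:
            return acc + (t_pos - s)
        acc += e - s
    return None


def check_coding(
    candidate: ChainedCandidate,
    contig: SequenceRecord,
    reference_gene: ReferenceGene,
    report: VerificationReport,
) -> VerificationReport:
    """Populate start/stop/frameshift/conserved-residue checks.

    The reading frame is taken from the reference: frame 0 at the ATG of
    L-PART1 for V genes, frame 0 for C genes, and the frame that puts the
    invariant W/F codon in frame for J genes.
    """
    from .homology import _project  # shared block projection

    coding = candidate_coding_seq(candidate, contig)
    seg = reference_gene.segment_type
    frame = reference_gene.frame

    if seg == "V":
        report.start_codon_ok = coding[:3] == "ATG"

    # D segments have no fixed reading frame (all three are used after
    # rearrangement), so stop/frameshift checks do not apply to them.
    if seg != "D":
        report.frameshift = (len(coding) - len(reference_gene.coding_seq)) % 3 != 0
        aa = translate(coding, frame) if len(coding) > frame + 2 else ""
        stops = [i for i, c in enumerate(aa) if c == "*"]
        if seg == "C":
            stops = [i for i in stops if i < len(aa) - 1]  # terminal stop is natural
        if stops:
            report.internal_stop = True
            report.first_stop_offset = stops[0]

    # conserved residues, projected through the chain alignment
    expect = {"first_cys": "C", "second_cys": "C", "j_trp_phe": "WF"}
    contig_len = len(contig.seq)
    for key, ref_coff in reference_gene.conserved_positions.items():
        q_full = reference_gene.coding_offset_to_full_offset(ref_coff)
        try:
            t_pos, _ = _project(candidate.blocks, q_full)
        except ValueError:
            report.conserved_ok[key] = False
            continue
        c_off = _full_offset_to_coding_offset(candidate, t_pos, contig_len)
        if c_off is None or c_off + 3 > len(coding):
            report.conserved_ok[key] = False
            continue
        codon = coding[c_off : c_off + 3]
        aa_res = translate(codon) if "N" not in codon else "X"
        report.conserved_ok[key] = aa_res in expect[key]

    report.completeness = candidate.completeness
    report.gap_overlap = candidate.gap_overlap
    return report


# --------------------------------------------------------------------------
# classification and naming
# --------------------------------------------------------------------------


def classify(report: VerificationReport, segment_type: str) -> tuple[str, list[str]]:
    """Pure function VerificationReport -> (functionality, reasons)."""
    reasons: list[str] = []
    if report.internal_stop:
        reasons.append("INTERNAL_STOP")
    if report.frameshift:
        reasons.append("FRAMESHIFT")
    if segment_type == "V" and report.start_codon_ok is False:
        reasons.append("NO_START")
    if not report.all_rss_found:
        reasons.append("RSS_MISSING")
    if not report.splice_ok:
        reasons.append("NONCANONICAL_SPLICE")
    if segment_type == "V" and not all(
        report.conserved_ok.get(k, True) for k in ("first_cys", "second_cys")
    ):
        reasons.append("MISSING_CONSERVED_CYS")
    if segment_type == "J" and not report.conserved_ok.get("j_trp_phe", True):
        reasons.append("MISSING_CONSERVED_WF")

    if any(r in PSEUDOGENE_CODES for r in reasons):
        return "pseudogene", reasons
    if any(r in ORF_CODES for r in reasons):
        return "ORF", reasons
    return "functional", reasons


def assign_name(
    seq: str,
    allele_index: dict[str, str],
    base_name: str,
    taken: set[str] | None = None,
) -> str:
    """Exact match in the allele index keeps the reference name; a novel
    sequence gets base gene name + '*' + the first 4 lowercase hex chars of
    its SHA-1 digest (collisions disambiguated with a numeric suffix)."""
    if not seq:
        raise GenomicIOError("cannot name an empty sequence")
    seq = seq.upper()
    exact = allele_index.get(seq)
    if exact is not None:
        return exact
    digest = hashlib.sha1(seq.encode("ascii")).hexdigest()[:4].lower()
    name = f"{base_name}*{digest}"
    if taken is not None:
        candidate = name
        n = 2
        while candidate in taken:
            candidate = f"{name}_{n}"
            n += 1
        if candidate != name:
            logger.warning("allele-name collision on %s; using %s", name, candidate)
        return candidate
    return name


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def annotate_locus(
    reference: ReferenceGeneSet,
    contig: SequenceRecord,
    rss_candidates: list[RssCandidate],
    rules: LocusRules | None = None,
    params: AnnotationParams | None = None,
) -> AnnotationResult:
    """Run the full search -> chain -> select -> verify -> classify -> name
    pipeline for one contig, in segment order V, D, J, C."""
    if not reference.genes:
        raise GenomicIOError("empty reference gene set")
    rules = rules or DEFAULT_LOCUS_RULES.get(reference.locus)
    if rules is None:
        raise GenomicIOError(f"no locus rules for {reference.locus!r}")
    params = params or AnnotationParams()

    features: list[AnnotatedFeature] = []
    withheld: list[WithheldRecord] = []

    for seg in SEGMENT_ORDER:
        genes = reference.by_type(seg)
        if not genes:
            continue
        if seg == "D" and not rules.has_d:
            continue
        hits = search(
            reference,
            contig,
            params.search_params,
            segment_type=seg,
            engine=params.engine,
        )
        chains: list[ChainedCandidate] = []
        by_gene_strand: dict[tuple[str, str], list] = {}
        for h in hits:
            by_gene_strand.setdefault((h.reference_gene, h.strand), []).append(h)
        for (gene_label, strand), gh in sorted(by_gene_strand.items()):
            ref_gene = reference.get(gene_label)
            chains.extend(
                chain_hits(
                    gh,
                    max_intron=params.max_intron,
                    query_gap_slack=params.query_gap_slack,
                    reference_gene=ref_gene,
                    contig=contig,
                )
            )
        selected = select_candidates(chains, overlap_frac=params.overlap_frac)

        for cand in selected:
            ref_gene = reference.get(cand.reference_gene)
            report = VerificationReport()
            report.rss_found = match_rss(cand, rss_candidates, rules, params.rss_tolerance)
            report.splice_ok, report.introns = verify_splice(cand, contig)
            check_coding(cand, contig, ref_gene, report)
            report.complete = (
                report.completeness >= params.completeness_min and report.gap_overlap == 0
            )
            logger.debug(
                "%s at %s:%d-%d(%s): rss=%s splice=%s stop=%s fs=%s compl=%.3f gaps=%d",
                cand.reference_gene, cand.span.contig_id, cand.span.start,
                cand.span.end, cand.strand, report.all_rss_found, report.splice_ok,
                report.internal_stop, report.frameshift, report.completeness,
                report.gap_overlap,
            )
            if not report.complete:
                cause = (
                    f"gap_overlap={report.gap_overlap}"
                    if report.gap_overlap
                    else f"completeness={report.completeness:.3f}"
                )
                withheld.append(WithheldRecord(cand.reference_gene, cand.span, cause))
                logger.info("withheld %s at %d-%d: %s", cand.reference_gene, cand.span.start, cand.span.end, cause)
                continue
            if (
                seg == "D"
                and params.require_d_rss
                and report.rss_found
                and not any(v is not None for v in report.rss_found.values())
            ):
                withheld.append(WithheldRecord(cand.reference_gene, cand.span, "no_flanking_rss"))
                continue
            functionality, reasons = classify(report, seg)
            coding = candidate_coding_seq(cand, contig)
            taken = {f.assigned_name for f in features}
            name = assign_name(coding, reference.coding_index, ref_gene.name, taken)
            features.append(
                AnnotatedFeature(
                    candidate=cand,
                    functionality=functionality,
                    reasons=reasons,
                    assigned_name=name,
                    matched_rss=[r for r in report.rss_found.values() if r is not None],
                    report=report,
                    coding_seq=coding,
                    frame=ref_gene.frame,
                )
            )

    features.sort(key=lambda f: (f.candidate.span.start, f.assigned_name))
    gff3 = build_gff3(features, contig)
    return AnnotationResult(
        features=features,
        withheld=withheld,
        gff3=gff3,
        sequence_regions={contig.id: len(contig.seq)},
    )


def build_gff3(features: list[AnnotatedFeature], contig: SequenceRecord) -> list[Gff3Feature]:
    """Gene features with exon/CDS children plus linked RSS features, with
    deterministic IDs in coordinate order."""
    out: list[Gff3Feature] = []
    rss_seen: dict[tuple, str] = {}
    ordered = sorted(features, key=lambda f: (f.candidate.span.start, f.assigned_name))
    for i, feat in enumerate(ordered, start=1):
        cand = feat.candidate
        gid = f"gene{i:04d}"
        attrs = {
            "ID": gid,
            "Name": feat.assigned_name,
            "functionality": feat.functionality,
        }
        if feat.reasons:
            attrs["notes"] = ",".join(feat.reasons)
        out.append(Gff3Feature(cand.span, SO_TYPES[cand.segment_type], attributes=attrs))
        exons = list(cand.exon_map)
        cum_coding = -_frame_of(feat)
        for j, (lab, iv) in enumerate(exons, start=1):
            out.append(
                Gff3Feature(
                    iv,
                    "exon",
                    attributes={"ID": f"{gid}.exon{j}", "Parent": gid, "Name": lab},
                )
            )
            if lab not in NONCODING_LABELS:
                phase = (3 - (cum_coding % 3)) % 3 if cum_coding >= 0 else -cum_coding
                out.append(
                    Gff3Feature(
                        iv,
                        "CDS",
                        phase=phase,
                        attributes={"ID": f"{gid}.cds{j}", "Parent": gid},
                    )
                )
                cum_coding += iv.length
        for rss in feat.matched_rss:
            key = (rss.interval.start, rss.interval.end, rss.interval.strand, rss.spacer_class)
            if key in rss_seen:
                continue
            rid = f"rss{len(rss_seen) + 1:04d}"
            rss_seen[key] = rid
            out.append(
                Gff3Feature(
                    rss.interval,
                    "recombination_signal_sequence",
                    score=round(rss.score, 3),
                    attributes={
                        "ID": rid,
                        "spacer_length": str(rss.spacer_class),
                        "associated_gene": gid,
                    },
                )
            )
    return out


def _frame_of(feat: AnnotatedFeature) -> int:
    return feat.frame


def write_annotation(result: AnnotationResult, path) -> None:
    from .genomic_io import write_gff3

    write_gff3(result.gff3, result.sequence_regions, path)
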