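"""RSS matching, verification, classification, naming, orchestration."""

import hashlib

import pytest

from vdjannot.annotator import (
    DEFAULT_LOCUS_RULES,
    VerificationReport,
    annotate_locus,
    assign_name,
    classify,
    match_rss,
    verify_splice,
)
from vdjannot.genomic_io import GenomicIOError, GenomicInterval, revcomp
from vdjannot.rss_ric import RssCandidate
from vdjannot.synthetic_locus import plant_locus


RULES = DEFAULT_LOCUS_RULES["IGH"]


def _v_candidate(annotation):
    return next(
        f.candidate for f in annotation.features if f.candidate.segment_type == "V"
    )


# ---------------------------------------------------------------- match_rss


def test_v_rss_matched_at_coding_end(annotation, planted):
    for feat in annotation.features:
        cand = feat.candidate
        if cand.segment_type in ("V", "J"):
            assert len(feat.matched_rss) == 1
        elif cand.segment_type == "D":
            assert len(feat.matched_rss) == 2
        else:
            assert feat.matched_rss == []


def test_rss_outside_tolerance_is_no_match(annotation):
    cand = _v_candidate(annotation)
    exons = [iv for _, iv in cand.exon_map]
    if cand.strand == "+":
        boundary = max(iv.end for iv in exons)
        near = RssCandidate(GenomicInterval("target", boundary, boundary + 39, "+"), 23, -1.0)
        far = RssCandidate(GenomicInterval("target", boundary + 50, boundary + 89, "+"), 23, -1.0)
    else:
        boundary = min(iv.start for iv in exons)
        near = RssCandidate(GenomicInterval("target", boundary - 39, boundary, "-"), 23, -1.0)
        far = RssCandidate(GenomicInterval("target", boundary - 89, boundary - 50, "-"), 23, -1.0)
    assert match_rss(cand, [near], RULES, tolerance=3)["3p"] == near
    assert match_rss(cand, [far], RULES, tolerance=3)["3p"] is None


def test_rss_tie_broken_by_score_then_start(annotation):
    cand = _v_candidate(annotation)
    exons = [iv for _, iv in cand.exon_map]
    if cand.strand == "+":
        b = max(iv.end for iv in exons)
        low = RssCandidate(GenomicInterval("target", b, b + 39, "+"), 23, -9.0)
        high = RssCandidate(GenomicInterval("target", b + 2, b + 41, "+"), 23, -1.0)
        tied = RssCandidate(GenomicInterval("target", b + 1, b + 40, "+"), 23, -1.0)
    else:
        b = min(iv.start for iv in exons)
        low = RssCandidate(GenomicInterval("target", b - 39, b, "-"), 23, -9.0)
        high = RssCandidate(GenomicInterval("target", b - 41, b - 2, "-"), 23, -1.0)
        tied = RssCandidate(GenomicInterval("target", b - 40, b - 1, "-"), 23, -1.0)
    assert match_rss(cand, [low, high], RULES)["3p"] == high
    assert match_rss(cand, [tied, high], RULES)["3p"] == min(
        [tied, high], key=lambda c: c.interval.start
    )


# ------------------------------------------------------------- verify_splice


def test_splice_verification_on_real_candidates(annotation, planted):
    for feat in annotation.features:
        ok, introns = verify_splice(feat.candidate, planted.contig)
        assert ok
        for donor, acceptor in introns:
            assert donor == "GT" and acceptor == "AG"
        n_exons = len(feat.candidate.exon_map)
        assert len(introns) == n_exons - 1


# ---------------------------------------------------------------- classify


def _report(**kwargs):
    r = VerificationReport(rss_found={"3p": RssCandidate(GenomicInterval("c", 0, 28), 12, 0.0)})
    r.start_codon_ok = True
    for k, v in kwargs.items():
        setattr(r, k, v)
    return r


def test_classification_precedence_table():
    assert classify(_report(), "V") == ("functional", [])
    func, reasons = classify(_report(rss_found={"3p": None}), "V")
    assert func == "ORF" and reasons == ["RSS_MISSING"]
    func, reasons = classify(_report(internal_stop=True, rss_found={"3p": None}), "V")
    assert func == "pseudogene" and "INTERNAL_STOP" in reasons
    assert classify(_report(frameshift=True), "C")[0] == "pseudogene"
    assert classify(_report(start_codon_ok=False), "V")[0] == "pseudogene"
    assert classify(_report(start_codon_ok=False), "J")[0] == "functional"
    assert classify(_report(splice_ok=False), "V")[0] == "ORF"
    assert classify(_report(conserved_ok={"first_cys": False}), "V")[0] == "ORF"
    assert classify(_report(conserved_ok={"j_trp_phe": False}), "J")[0] == "ORF"


def test_classification_is_pure_and_deterministic():
    r = _report(splice_ok=False, internal_stop=True)
    first = classify(r, "V")
    for _ in range(5):
        assert classify(r, "V") == first


# -------------------------------------------------------------------- naming


def _pure_python_sha1(data: bytes) -> str:
    """Independent SHA-1 oracle (RFC 3174 reference algorithm)."""
    h = [0x67452301, 0xEFCDAB89, 0x98BADCFE, 0x10325476, 0xC3D2E1F0]
    ml = len(data) * 8
    data += b"\x80" + b"\x00" * ((56 - (len(data) + 1) % 64) % 64) + ml.to_bytes(8, "big")
    rol = lambda n, b: ((n << b) | (n >> (32 - b))) & 0xFFFFFFFF
    for chunk_start in range(0, len(data), 64):
        w = [int.from_bytes(data[chunk_start + 4 * i : chunk_start + 4 * i + 4], "big") for i in range(16)]
        for i in range(16, 80):
            w.append(rol(w[i - 3] ^ w[i - 8] ^ w[i - 14] ^ w[i - 16], 1))
        a, b, c, d, e = h
        for i in range(80):
            if i < 20:
                f, k = (b & c) | (~b & d), 0x5A827999
            elif i < 40:
                f, k = b ^ c ^ d, 0x6ED9EBA1
            elif i < 60:
                f, k = (b & c) | (b & d) | (c & d), 0x8F1BBCDC
            else:
                f, k = b ^ c ^ d, 0xCA62C1D6
            a, b, c, d, e = (rol(a, 5) + f + e + k + w[i]) & 0xFFFFFFFF, a, rol(b, 30), c, d
        h = [(x + y) & 0xFFFFFFFF for x, y in zip(h, (a, b, c, d, e))]
    return "".join(f"{x:08x}" for x in h)


def test_known_allele_keeps_reference_name(gene_set):
    gene = gene_set.genes[0]
    assert assign_name(gene.coding_seq, gene_set.coding_index, gene.name) == gene.label


def test_novel_allele_suffix_is_sha1_prefix(gene_set):
    seq = "ATGGTACGTACGTTTACG"
    name = assign_name(seq, gene_set.coding_index, "IGHV1-1")
    expected = _pure_python_sha1(seq.encode())[:4]
    assert expected == hashlib.sha1(seq.encode()).hexdigest()[:4]
    assert name == f"IGHV1-1*{expected}"


def test_distinct_sequences_get_distinct_names_with_collision_rule(gene_set):
    taken = set()
    names = []
    for seq in ("ATGAAATTTGGG", "ATGCCCGGGAAA", "ATGAAATTTGGG"):
        n = assign_name(seq, {}, "X", taken)
        taken.add(n)
        names.append(n)
    assert names[0] != names[1]
    assert names[2] == names[0] + "_2"  # same hash, forced suffix
    with pytest.raises(GenomicIOError):
        assign_name("", {}, "X")


# ------------------------------------------------------------- orchestration


def test_all_planted_genes_recovered_exactly(annotation, planted):
    by_span = {(t.span.start, t.span.end, t.segment_type): t for t in planted.truth}
    assert len(annotation.features) == len(planted.truth)
    assert annotation.withheld == []
    for feat in annotation.features:
        cand = feat.candidate
        key = (cand.span.start, cand.span.end, cand.segment_type)
        truth = by_span.pop(key)
        assert feat.functionality == "functional"
        assert feat.assigned_name == truth.name
        assert cand.strand == truth.strand
        assert sorted((lab, iv) for lab, iv in cand.exon_map) == sorted(
            (lab, iv) for lab, iv in truth.exons
        )
    assert by_span == {}


def test_annotation_strand_symmetry(small_spec, small_gene_set, models):
    """Annotating the reverse complement yields the mirror-image gene set."""
    from vdjannot.genomic_io import SequenceRecord
    from vdjannot.rss_ric import scan

    plant = plant_locus(small_spec, small_gene_set)
    fwd = plant.contig
    rev = SequenceRecord(fwd.id, revcomp(fwd.seq))
    L = len(fwd.seq)
    res_f = annotate_locus(small_gene_set, fwd, scan(models[12], models[23], fwd))
    res_r = annotate_locus(small_gene_set, rev, scan(models[12], models[23], rev))
    mirror = {
        (L - f.candidate.span.end, L - f.candidate.span.start,
         "-" if f.candidate.strand == "+" else "+", f.assigned_name, f.functionality)
        for f in res_r.features
    }
    original = {
        (f.candidate.span.start, f.candidate.span.end, f.candidate.strand,
         f.assigned_name, f.functionality)
        for f in res_f.features
    }
    assert original == mirror


def test_gff3_emission_is_deterministic_and_reparseable(annotation, tmp_path):
    from vdjannot.annotator import write_annotation
    from vdjannot.genomic_io import read_gff3, write_gff3

    p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
    write_annotation(annotation, p1)
    feats = read_gff3(p1)
    write_gff3(feats, annotation.sequence_regions, p2)
    assert p1.read_text() == p2.read_text()
    gene_rows = [f for f in feats if f.so_type.endswith("_gene_segment")]
    assert len(gene_rows) == len(annotation.features)
    assert all("functionality" in f.attributes for f in gene_rows)


def test_empty_reference_fails(planted):
    from vdjannot.imgt_reference import ReferenceGeneSet

    empty = ReferenceGeneSet([], "X", "IGH")
    with pytest.raises(GenomicIOError):
        annotate_locus(empty, planted.contig, [])
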