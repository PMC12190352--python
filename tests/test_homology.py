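"""Local search, hit chaining against a brute-force oracle, selection."""

import itertools

import numpy as np
import pytest

from vdjannot.genomic_io import GenomicInterval, SequenceRecord, revcomp
from vdjannot.homology import (
    ChainedCandidate,
    DEFAULT_SEARCH_PARAMS,
    LocalHit,
    SearchParams,
    blastn_search,
    chain_hits,
    fallback_align,
    search,
    select_candidates,
)


def _mk_hit(q0, q1, t0, t1, bit, gene="G*01", strand="+", contig_len=100_000):
    if strand == "+":
        iv = GenomicInterval("c", t0, t1, "+")
    else:
        iv = GenomicInterval("c", contig_len - t1, contig_len - t0, "-")
    return LocalHit(
        reference_gene=gene,
        query_start=q0,
        query_end=q1,
        interval=iv,
        percent_identity=100.0,
        bit_score=bit,
        e_value=0.0,
        t_start=t0,
        t_end=t1,
        blocks=[(q0, t0, min(q1 - q0, t1 - t0))],
    )


# ---------------------------------------------------------------- alignment


def test_exact_substring_gives_full_identity_hit():
    rng = np.random.default_rng(0)
    query = "".join(rng.choice(list("ACGT"), size=120))
    target = "".join(rng.choice(list("ACGT"), size=400)) + query + "".join(rng.choice(list("ACGT"), size=400))
    hits = fallback_align(query, target)
    top = max(hits, key=lambda h: h.bit_score)
    assert top.percent_identity == 100.0
    assert (top.query_start, top.query_end) == (0, len(query))
    assert top.t_start == 400 and top.t_end == 400 + len(query)


def test_single_mismatch_identity_arithmetic():
    rng = np.random.default_rng(1)
    query = "".join(rng.choice(list("ACGT"), size=20))
    mutated = query[:10] + ("A" if query[10] != "A" else "C") + query[11:]
    target = "GG" * 30 + mutated + "GG" * 30
    hits = fallback_align(query, target, params=SearchParams(word_size=7, min_raw_score=10))
    top = max(hits, key=lambda h: h.bit_score)
    assert top.percent_identity == pytest.approx(95.0)


def test_minus_strand_hit_is_mirrored():
    rng = np.random.default_rng(2)
    query = "".join(rng.choice(list("ACGT"), size=150))
    bg1 = "".join(rng.choice(list("ACGT"), size=300))
    bg2 = "".join(rng.choice(list("ACGT"), size=300))
    fwd_target = bg1 + query + bg2
    rev_target = revcomp(fwd_target)
    fwd_top = max(fallback_align(query, fwd_target), key=lambda h: h.bit_score)
    rev_top = max(fallback_align(query, rev_target), key=lambda h: h.bit_score)
    L = len(fwd_target)
    assert fwd_top.strand == "+" and rev_top.strand == "-"
    assert (rev_top.interval.start, rev_top.interval.end) == (
        L - fwd_top.interval.end,
        L - fwd_top.interval.start,
    )
    assert rev_top.bit_score == pytest.approx(fwd_top.bit_score)


def test_pure_background_yields_no_hits(gene_set):
    rng = np.random.default_rng(3)
    contig = SequenceRecord("bg", "".join(rng.choice(list("ACGT"), size=30_000)))
    hits = search(gene_set, contig, segment_type="V")
    assert hits == []


def test_blastn_and_builtin_agree_on_top_hits(gene_set, planted):
    """The external engine and the builtin aligner place the best V hits at
    the same coordinates (+-2 nt)."""
    params = DEFAULT_SEARCH_PARAMS["V"]
    genes = gene_set.by_type("V")[:5]
    bh = blastn_search([(g.label, g.full_seq) for g in genes], planted.contig, params)
    for g in genes:
        builtin_top = max(
            fallback_align(g.full_seq, planted.contig.seq, g.label, planted.contig.id, params),
            key=lambda h: h.bit_score,
        )
        blast_top = max(
            (h for h in bh if h.reference_gene == g.label), key=lambda h: h.bit_score
        )
        assert blast_top.strand == builtin_top.strand
        assert abs(blast_top.interval.start - builtin_top.interval.start) <= 2
        assert abs(blast_top.interval.end - builtin_top.interval.end) <= 2


# ------------------------------------------------------------------ chaining


def _bruteforce_best_chain(hits, max_intron=16000, query_gap_slack=50):
    """Exhaustive maximisation of summed bit score over strictly co-linear
    subsets satisfying the gap constraints."""
    best_score, best_set = 0.0, ()
    n = len(hits)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            sub = sorted((hits[i] for i in combo), key=lambda h: h.query_start)
            ok = True
            for a, b in zip(sub, sub[1:]):
                if (
                    b.query_start < a.query_end
                    or b.t_start < a.t_end
                    or b.t_start - a.t_end > max_intron
                    or b.query_start - a.query_end > query_gap_slack
                ):
                    ok = False
                    break
            if ok:
                s = sum(h.bit_score for h in sub)
                if s > best_score:
                    best_score, best_set = s, tuple(id(h) for h in sub)
    return best_score, best_set


def test_two_exon_hits_chain_across_short_gap():
    h1 = _mk_hit(0, 300, 1000, 1300, 100.0)
    h2 = _mk_hit(320, 640, 1600, 1920, 110.0)
    chains = chain_hits([h1, h2], max_intron=16000)
    assert len(chains) == 1
    assert chains[0].score == pytest.approx(210.0)
    assert chains[0].span == GenomicInterval("c", 1000, 1920, "+")


def test_gap_beyond_max_intron_splits_chain():
    h1 = _mk_hit(0, 300, 1000, 1300, 100.0)
    h2 = _mk_hit(320, 640, 21400, 21720, 110.0)
    chains = chain_hits([h1, h2], max_intron=16000)
    assert len(chains) == 2
    assert all(len(c.hits) == 1 for c in chains)


def test_out_of_order_middle_hit_excluded():
    h1 = _mk_hit(0, 100, 1000, 1100, 50.0)
    bad = _mk_hit(105, 205, 500, 600, 40.0)  # target goes backwards
    h3 = _mk_hit(110, 210, 1400, 1500, 60.0)
    chains = chain_hits([h1, bad, h3])
    top = chains[0]
    assert {h.query_start for h in top.hits} == {0, 110}
    assert top.score == pytest.approx(110.0)


@pytest.mark.parametrize("trial", range(20))
def test_chaining_matches_bruteforce_oracle(trial):
    rng = np.random.default_rng(trial + 100)
    n = int(rng.integers(2, 9))
    hits = []
    for _ in range(n):
        q0 = int(rng.integers(0, 900))
        q1 = q0 + int(rng.integers(20, 200))
        t0 = int(rng.integers(0, 40_000))
        t1 = t0 + (q1 - q0)
        hits.append(_mk_hit(q0, q1, t0, t1, float(rng.integers(10, 200))))
    oracle_score, oracle_ids = _bruteforce_best_chain(hits)
    chains = chain_hits(hits)
    top = chains[0]
    assert top.score == pytest.approx(oracle_score)
    assert tuple(id(h) for h in sorted(top.hits, key=lambda h: h.query_start)) == oracle_ids
    # every hit lands in exactly one chain
    assert sorted(id(h) for c in chains for h in c.hits) == sorted(id(h) for h in hits)


# ----------------------------------------------------------------- selection


def _chain_of(hit, seg="V", gene="G*01", completeness=1.0):
    c = ChainedCandidate(
        reference_gene=gene,
        segment_type=seg,
        hits=[hit],
        span=hit.interval,
        strand=hit.strand,
        score=hit.bit_score,
        completeness=completeness,
    )
    c.exon_map = [("X", hit.interval)]
    return c


def test_allele_tie_resolution_prefers_score_then_name():
    a = _chain_of(_mk_hit(0, 300, 1000, 1300, 100.0), gene="IGHV1-1*02")
    b = _chain_of(_mk_hit(0, 300, 1000, 1300, 100.0), gene="IGHV1-1*01")
    kept = select_candidates([a, b])
    assert [c.reference_gene for c in kept] == ["IGHV1-1*01"]
    c = _chain_of(_mk_hit(0, 300, 1000, 1300, 120.0), gene="IGHV1-1*02")
    kept = select_candidates([b, c])
    assert [k.reference_gene for k in kept] == ["IGHV1-1*02"]


def test_nonoverlapping_and_subthreshold_overlap_kept():
    a = _chain_of(_mk_hit(0, 300, 1000, 1300, 100.0), gene="A*01")
    b = _chain_of(_mk_hit(0, 300, 5000, 5300, 90.0), gene="B*01")
    c = _chain_of(_mk_hit(0, 300, 1180, 1480, 80.0), gene="C*01")  # 40% overlap with a
    kept = select_candidates([a, b, c])
    assert {k.reference_gene for k in kept} == {"A*01", "B*01", "C*01"}


def test_selection_is_permutation_invariant():
    rng = np.random.default_rng(9)
    chains = []
    for i in range(8):
        t0 = int(rng.integers(0, 5000))
        score = float(rng.integers(20, 150))
        chains.append(
            _chain_of(_mk_hit(0, 200, t0, t0 + 200, score, gene=f"G{i}*01"), gene=f"G{i}*01")
        )
    ref = select_candidates(chains)
    for perm in range(5):
        rng.shuffle(chains)
        got = select_candidates(list(chains))
        assert [(c.reference_gene, c.span) for c in got] == [
            (c.reference_gene, c.span) for c in ref
        ]
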