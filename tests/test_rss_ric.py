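"""RIC model training, scoring, scanning, and BED exchange."""

import math

import numpy as np
import pytest

from vdjannot.genomic_io import GenomicInterval, SequenceRecord, revcomp
from vdjannot.rss_ric import (
    RicModel,
    RicError,
    RssCandidate,
    bed_to_candidates,
    candidates_to_bed,
    ric_score,
    scan,
    train_ric,
    window_length,
)
from vdjannot.synthetic_locus import RssSampler, generate_rss_training


def _oracle_score(training, order, pseudocount, window):
    """Independent brute-force sum of per-position log conditional
    probabilities, counting contexts explicitly."""
    total = 0.0
    for i in range(len(window)):
        k = min(i, order)
        ctx = window[i - k : i]
        n_match = sum(1 for t in training if t[i - k : i] == ctx and t[i] == window[i])
        n_ctx = sum(1 for t in training if t[i - k : i] == ctx)
        denom = n_ctx + 4 * pseudocount
        if denom == 0:
            return float("-inf")
        p = (n_match + pseudocount) / denom
        if p == 0:
            return float("-inf")
        total += math.log(p)
    return total


def _random_windows(rng, n, length):
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


# ------------------------------------------------------------------ training


def test_single_window_pseudocount_zero():
    w = "A" * 28
    model = train_ric([w], 12, order=0, pseudocount=0.0)
    assert ric_score(model, w) == 0.0
    assert ric_score(model, "C" + w[1:]) == float("-inf")


def test_two_windows_half_probability_at_differing_position():
    w1 = "A" * 28
    w2 = "C" + "A" * 27
    model = train_ric([w1, w2], 12, order=0, pseudocount=0.0)
    assert ric_score(model, w1) == pytest.approx(math.log(0.5), abs=1e-12)


def test_order0_pseudocount_estimates_match_counting():
    rng = np.random.default_rng(42)
    training = _random_windows(rng, 50, 28)
    model = train_ric(training, 12, order=0, pseudocount=1.0)
    for i in range(28):
        for b, code in zip("ACGT", range(4)):
            count = sum(1 for t in training if t[i] == b)
            expected = (count + 1) / (len(training) + 4)
            assert math.exp(model.log_probs[i][0, code]) == pytest.approx(expected, abs=1e-12)


def test_training_input_validation():
    with pytest.raises(RicError):
        train_ric([], 12)
    with pytest.raises(RicError):
        train_ric(["A" * 28, "A" * 27], 12)
    with pytest.raises(RicError):
        train_ric(["N" * 28], 12)


# ------------------------------------------------------------------- scoring


@pytest.mark.parametrize("order", [0, 1, 2])
def test_ric_score_equals_bruteforce_oracle(order):
    rng = np.random.default_rng(order + 7)
    training = _random_windows(rng, 40, 28)
    model = train_ric(training, 12, order=order, pseudocount=0.7)
    for window in _random_windows(rng, 60, 28):
        assert ric_score(model, window) == pytest.approx(
            _oracle_score(training, order, 0.7, window), abs=1e-12
        )


def test_window_with_n_is_unscorable(models):
    w = "N" + "A" * 27
    assert ric_score(models[12], w) == float("-inf")
    with pytest.raises(RicError):
        ric_score(models[12], "A" * 10)


def test_monotonicity_adding_identical_window():
    rng = np.random.default_rng(3)
    training = _random_windows(rng, 20, 28)
    w = training[0]
    for order in (0, 1):
        m1 = train_ric(training, 12, order=order, pseudocount=1.0)
        m2 = train_ric(training + [w], 12, order=order, pseudocount=1.0)
        assert ric_score(m2, w) >= ric_score(m1, w) - 1e-12


# ------------------------------------------------------------------ scanning


def test_scan_completeness_with_threshold_minus_inf():
    rng = np.random.default_rng(5)
    training = _random_windows(rng, 10, 28)
    model = train_ric(training, 12, order=1)
    L = 500
    contig = SequenceRecord("c", "".join(rng.choice(list("ACGT"), size=L)))
    cands = scan(model, None, contig, min_score={12: float("-inf")})
    assert len(cands) == 2 * (L - 28 + 1)


def test_scan_recovers_planted_consensus(models):
    rng = np.random.default_rng(11)
    sampler = RssSampler(12)
    background = "".join(rng.choice(list("ACGT"), size=5000))
    planted_at = 2471
    seq = background[:planted_at] + sampler.consensus + background[planted_at:]
    cands = scan(models[12], None, SequenceRecord("c", seq))
    plus = [c for c in cands if c.interval.strand == "+"]
    assert any(c.interval.start == planted_at for c in plus)


def test_scan_strand_symmetry(models):
    rng = np.random.default_rng(13)
    sampler = RssSampler(12)
    seq = (
        "".join(rng.choice(list("ACGT"), size=1000))
        + sampler.consensus
        + "".join(rng.choice(list("ACGT"), size=1000))
    )
    fwd = scan(models[12], None, SequenceRecord("c", seq))
    rev = scan(models[12], None, SequenceRecord("c", revcomp(seq)))
    L = len(seq)
    mirrored = {
        (L - c.interval.end, L - c.interval.start, "-" if c.interval.strand == "+" else "+", round(c.score, 9))
        for c in rev
    }
    original = {
        (c.interval.start, c.interval.end, c.interval.strand, round(c.score, 9)) for c in fwd
    }
    assert original == mirrored


# -------------------------------------------------------------- BED exchange


def test_bed_score_affine_endpoints(models):
    m = models[12]
    iv = GenomicInterval("c1", 100, 128, "+")
    at_threshold = RssCandidate(iv, 12, m.threshold)
    at_zero = RssCandidate(iv, 12, 0.0)
    recs = candidates_to_bed([at_threshold, at_zero], models)
    assert recs[0].score == pytest.approx(0.0)
    assert recs[1].score == pytest.approx(1000.0)


def test_bed_round_trip_preserves_interval_strand_class(models, tmp_path):
    from vdjannot.genomic_io import read_bed, write_bed

    cands = [
        RssCandidate(GenomicInterval("c1", 10, 38, "+"), 12, models[12].threshold / 2),
        RssCandidate(GenomicInterval("c1", 200, 239, "-"), 23, models[23].threshold / 3),
    ]
    p = tmp_path / "rss.bed"
    write_bed(candidates_to_bed(cands, models), p)
    back = bed_to_candidates(read_bed(p), models)
    assert [(c.interval, c.spacer_class) for c in back] == [
        (c.interval, c.spacer_class) for c in cands
    ]
    for a, b in zip(back, cands):
        # score survives quantisation to within one BED score unit
        assert a.score == pytest.approx(b.score, abs=abs(models[a.spacer_class].threshold) / 1000 + 1e-9)


def test_heptamer_boundary_orientation():
    plus = RssCandidate(GenomicInterval("c", 50, 78, "+"), 12, 0.0)
    minus = RssCandidate(GenomicInterval("c", 50, 78, "-"), 12, 0.0)
    assert plus.heptamer_boundary == 50
    assert minus.heptamer_boundary == 78


# ------------------------------------------------------------- serialization


def test_model_json_round_trip(models, tmp_path):
    p = tmp_path / "m12.json"
    models[12].save(p)
    back = RicModel.load(p)
    assert back.spacer_class == 12
    assert back.threshold == models[12].threshold
    assert back.order == models[12].order
    for a, b in zip(back.log_probs, models[12].log_probs):
        assert np.allclose(a, b)
    w = RssSampler(12).consensus
    assert ric_score(back, w) == pytest.approx(ric_score(models[12], w), abs=1e-12)
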