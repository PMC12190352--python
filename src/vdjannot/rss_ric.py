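"""Recombination-information-content (RIC) models of RSS.

A recombination signal sequence is a conserved heptamer, a 12 or 23 nt
spacer, and a nonamer; RAG binding requires one 12- and one 23-spacer RSS
(the 12/23 rule).  The heptamer and nonamer are only loosely conserved, so
candidate RSS are found with a statistical scoring model rather than by
alignment.

The model implemented here is a position-wise conditional (order-k chain)
model over the fixed-length window heptamer+spacer+nonamer (28 nt for the
12-spacer class, 39 nt for the 23-spacer class): position i conditions on
the min(i, order) immediately preceding window positions, and the score of
a window is the summed log conditional probability of its bases.  Order 0
reduces to a position weight matrix; order 1 is the default.  Scores are
log-probabilities, hence <= 0; the reporting threshold defaults to the
minimum training-set score minus a safety margin, guaranteeing training-set
recall while remaining user-tunable (models trained on one species can miss
real RSS in a distant one).

Any window containing N is unscorable (-inf) and never reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genomic_io import BedRecord, GenomicInterval, SequenceRecord, revcomp

HEPTAMER_LEN = 7
NONAMER_LEN = 9
MODEL_FORMAT_VERSION = 1

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class RicError(ValueError):
    pass


def window_length(spacer_class: int) -> int:
    if spacer_class not in (12, 23):
        raise RicError(f"spacer class must be 12 or 23, got {spacer_class}")
    return HEPTAMER_LEN + spacer_class + NONAMER_LEN


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise RicError(f"non-ACGTN character {exc.args[0]!r}") from None


@dataclass
class RicModel:
    """Per-position nucleotide dependence model for one spacer class.

    ``log_probs[i]`` has shape (4**k_i, 4) with k_i = min(i, order); row
    index encodes the k_i preceding bases as sum_j base[i-1-j] * 4**j.
    """

    spacer_class: int
    order: int
    pseudocount: float
    log_probs: list[np.ndarray]
    threshold: float
    training_n: int

    @property
    def window_length(self) -> int:
        return window_length(self.spacer_class)

    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "spacer_class": self.spacer_class,
            "order": self.order,
            "pseudocount": self.pseudocount,
            "threshold": self.threshold,
            "training_n": self.training_n,
            "log_probs": [
                [[None if not math.isfinite(x) else x for x in row] for row in table]
                for table in self.log_probs
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "RicModel":
        d = json.loads(text)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise RicError(f"unsupported model format {d.get('format_version')!r}")
        tables = [
            np.array(
                [[-np.inf if x is None else x for x in row] for row in table],
                dtype=float,
            )
            for table in d["log_probs"]
        ]
        return cls(
            spacer_class=int(d["spacer_class"]),
            order=int(d["order"]),
            pseudocount=float(d["pseudocount"]),
            log_probs=tables,
            threshold=float(d["threshold"]),
            training_n=int(d["training_n"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RicModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class RssCandidate:
    """A reportable RSS window.

    ``strand`` encodes orientation: '+' means the heptamer sits at
    ``interval.start`` (a gene segment would end there, to the left); '-'
    means the motif lies on the reverse strand with the heptamer at
    ``interval.end`` (a gene segment would start there, to the right).
    ``heptamer_boundary`` is that gene-abutting contig coordinate.
    """

    interval: GenomicInterval
    spacer_class: int
    score: float

    @property
    def heptamer_boundary(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end


def _context_index(codes: Sequence[int], i: int, order: int) -> int:
    k = min(i, order)
    idx = 0
    for j in range(1, k + 1):
        idx += int(codes[i - j]) * 4 ** (j - 1)
    return idx


def train_ric(
    training_windows: Sequence[str],
    spacer_class: int,
    order: int = 1,
    pseudocount: float = 1.0,
    threshold_margin: float = 5.0,
) -> RicModel:
    """Estimate per-position conditional probabilities by relative frequency
    with an additive pseudocount; threshold = min training score - margin."""
    if not training_windows:
        raise RicError("empty training set")
    w = window_length(spacer_class)
    lengths = {len(x) for x in training_windows}
    if lengths != {w}:
        raise RicError(f"training windows must all have length {w}, got {sorted(lengths)}")
    if pseudocount < 0:
        raise RicError("pseudocount must be >= 0")
    mats = []
    for win in training_windows:
        codes = encode(win)
        if (codes >= 4).any():
            raise RicError("training windows must be over A/C/G/T only")
        mats.append(codes)
    data = np.stack(mats)  # (n, w)

    log_probs: list[np.ndarray] = []
    for i in range(w):
        k = min(i, order)
        counts = np.full((4**k, 4), pseudocount, dtype=float)
        ctx = np.zeros(len(data), dtype=np.int64)
        for j in range(1, k + 1):
            ctx += data[:, i - j] * 4 ** (j - 1)
        np.add.at(counts, (ctx, data[:, i]), 1.0)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(counts) - np.log(totals)
        lp[np.isnan(lp)] = -np.inf  # context never observed, pseudocount 0
        log_probs.append(lp)

    model = RicModel(spacer_class, order, pseudocount, log_probs, threshold=0.0, training_n=len(data))
    train_scores = [ric_score(model, win) for win in training_windows]
    model.threshold = min(train_scores) - threshold_margin
    return model


def ric_score(model: RicModel, window: str) -> float:
    """Summed log conditional probability of one window; N anywhere -> -inf."""
    if len(window) != model.window_length:
        raise RicError(
            f"window length {len(window)} != model window length {model.window_length}"
        )
    codes = encode(window)
    if (codes >= 4).any():
        return float("-inf")
    total = 0.0
    for i in range(model.window_length):
        idx = _context_index(codes, i, model.order)
        total += float(model.log_probs[i][idx, codes[i]])
        if total == float("-inf"):
            return total
    return total


def _score_all_windows(model: RicModel, codes: np.ndarray) -> np.ndarray:
    """Vectorised score of every window start position on one strand."""
    w = model.window_length
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    safe = np.where(codes < 4, codes, 0)
    total = np.zeros(n)
    for i, table in enumerate(model.log_probs):
        k = min(i, model.order)
        ctx = np.zeros(n, dtype=np.int64)
        for j in range(1, k + 1):
            ctx += safe[i - j : i - j + n] * 4 ** (j - 1)
        total += table[ctx, safe[i : i + n]]
    has_n = np.convolve((codes >= 4).astype(np.int64), np.ones(w, dtype=np.int64), "valid") > 0
    total[has_n] = -np.inf
    return total


def scan(
    model12: RicModel | None,
    model23: RicModel | None,
    contig: SequenceRecord,
    min_score: dict[int, float] | None = None,
) -> list[RssCandidate]:
    """Score every window on both strands against both models; report
    candidates at or above each model's threshold (overridable per class),
    sorted by (start, strand, spacer_class)."""
    out: list[RssCandidate] = []
    L = len(contig.seq)
    fwd = encode(contig.seq)
    rev = encode(revcomp(contig.seq))
    for model in (model12, model23):
        if model is None:
            continue
        w = model.window_length
        thr = model.threshold if min_score is None else min_score.get(model.spacer_class, model.threshold)
        fscores = _score_all_windows(model, fwd)
        for p in np.nonzero(fscores >= thr)[0]:
            out.append(
                RssCandidate(
                    GenomicInterval(contig.id, int(p), int(p) + w, "+"),
                    model.spacer_class,
                    float(fscores[p]),
                )
            )
        rscores = _score_all_windows(model, rev)
        for p in np.nonzero(rscores >= thr)[0]:
            start = L - (int(p) + w)
            out.append(
                RssCandidate(
                    GenomicInterval(contig.id, start, start + w, "-"),
                    model.spacer_class,
                    float(rscores[p]),
                )
            )
    out.sort(key=lambda c: (c.interval.start, c.interval.strand, c.spacer_class))
    return out


# --------------------------------------------------------------------------
# BED exchange (interoperable with third-party RSS predictors)
# --------------------------------------------------------------------------


def _to_bed_score(score: float, threshold: float) -> float:
    if threshold >= 0:
        return 1000.0
    frac = (score - threshold) / (0.0 - threshold)
    return min(1000.0, max(0.0, frac * 1000.0))


def candidates_to_bed(candidates: Iterable[RssCandidate], models: dict[int, RicModel]) -> list[BedRecord]:
    """BED6 with name RSS12/RSS23 and the RIC score affinely rescaled from
    [threshold, 0] onto [0, 1000] (quantised to integers on write)."""
    recs = []
    for c in candidates:
        thr = models[c.spacer_class].threshold
        recs.append(BedRecord(c.interval, f"RSS{c.spacer_class}", _to_bed_score(c.score, thr)))
    return recs


def bed_to_candidates(records: Iterable[BedRecord], models: dict[int, RicModel]) -> list[RssCandidate]:
    """Inverse of candidates_to_bed; accepts any conforming BED (including
    third-party predictor output); RIC scores come back quantised."""
    out = []
    for r in records:
        name = r.name.upper()
        if name.startswith("RSS12"):
            cls = 12
        elif name.startswith("RSS23"):
            cls = 23
        elif r.interval.length == window_length(12):
            cls = 12
        elif r.interval.length == window_length(23):
            cls = 23
        else:
            raise RicError(f"cannot infer spacer class for BED record {r.name!r} len {r.interval.length}")
        thr = models[cls].threshold
        score = thr + (min(1000.0, max(0.0, r.score)) / 1000.0) * (0.0 - thr) if thr < 0 else 0.0
        out.append(RssCandidate(r.interval, cls, score))
    out.sort(key=lambda c: (c.interval.start, c.interval.strand, c.spacer_class))
    return out
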