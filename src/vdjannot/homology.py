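"""Similarity search and hit chaining for gene-segment discovery.

Candidate gene segments are located by local alignment of each reference
full-gene sequence (introns included) against the target contig, on both
strands.  Constant genes of the IGH/TRA/TRB loci carry kilobase-scale
introns whose sequence can diverge much faster than the exons, so a single
contiguous local alignment cannot be relied on: co-linear local hits are
chained into one gene model, tolerating low-identity interior introns up to
a configurable intron-length bound.

Two engines are available behind the same interface:

* ``builtin`` -- a seed-and-extend aligner (exact k-mer seeding, diagonal
  band clustering, gapped extension with Biopython's PairwiseAligner in
  local mode).  It is self-contained, deterministic, and gates hits on raw
  alignment score, identity and query coverage.
* ``blastn`` -- NCBI BLAST+ invoked with tabular output (outfmt 6); any
  tool emitting the same fields can be slotted in.

Coordinate conventions: hits carry both a contig-forward GenomicInterval
and strand-space offsets (coordinates on the strand the gene reads, i.e.
offsets into revcomp(contig) for minus-strand hits), which make chaining
and exon projection strand-agnostic.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from .genomic_io import GenomicInterval, SequenceRecord, revcomp
from .imgt_reference import ReferenceGene, ReferenceGeneSet, NONCODING_LABELS

logger = logging.getLogger(__name__)

# Karlin-Altschul-style constants for the builtin scoring (match 2,
# mismatch -3, gap open -5, gap extend -2); the e-value is an estimate for
# reporting, not a gate, for the builtin engine.
_LAMBDA = 0.625
_K = 0.41
_LN2 = math.log(2.0)


class EngineError(RuntimeError):
    """External alignment engine failed to run."""


@dataclass(frozen=True)
class SearchParams:
    word_size: int = 11
    min_identity: float = 60.0
    max_evalue: float = 1e-10
    min_raw_score: int = 50
    min_coverage: float = 0.0


# Short D segments need relaxed significance but near-full coverage.
DEFAULT_SEARCH_PARAMS: dict[str, SearchParams] = {
    "V": SearchParams(),
    "J": SearchParams(),
    "C": SearchParams(),
    "D": SearchParams(word_size=7, min_identity=80.0, max_evalue=10.0, min_raw_score=16, min_coverage=0.9),
}


@dataclass
class LocalHit:
    """One local alignment between a reference gene and the contig."""

    reference_gene: str  # "name*allele"
    query_start: int
    query_end: int
    interval: GenomicInterval  # contig-forward
    percent_identity: float
    bit_score: float
    e_value: float
    t_start: int  # strand-space
    t_end: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)  # (q, t, len), strand-space

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class ChainedCandidate:
    """Co-linear chained hits forming one candidate gene model."""

    reference_gene: str
    segment_type: str
    hits: list[LocalHit]
    span: GenomicInterval  # contig-forward
    strand: str
    score: float  # summed bit score
    exon_map: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    completeness: float = 0.0
    gap_overlap: int = 0
    contig_length: int = 0

    @property
    def blocks(self) -> list[tuple[int, int, int]]:
        merged: list[tuple[int, int, int]] = []
        for h in self.hits:
            merged.extend(h.blocks)
        return sorted(merged)


# --------------------------------------------------------------------------
# builtin seed-and-extend aligner
# --------------------------------------------------------------------------

_DNA_ALIGNER: Align.PairwiseAligner | None = None


def _dna_aligner() -> Align.PairwiseAligner:
    global _DNA_ALIGNER
    if _DNA_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -5
        a.extend_gap_score = -2
        a.mode = "local"
        _DNA_ALIGNER = a
    return _DNA_ALIGNER


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _seed_matches(query: str, index: dict[str, list[int]], k: int) -> list[tuple[int, int]]:
    """(diagonal, query_pos) pairs for every exact k-mer match."""
    out = []
    for q in range(len(query) - k + 1):
        kmer = query[q : q + k]
        for t in index.get(kmer, ()):
            out.append((t - q, q))
    return out


def _cluster_seeds(
    matches: list[tuple[int, int]], k: int, band: int = 32, max_q_gap: int = 200
) -> list[tuple[int, int, int, int]]:
    """Group seeds into diagonal bands -> (qlo, qhi, tlo, thi) windows.

    Seeds are walked in query order; a seed joins a cluster when it sits
    within ``band`` of the cluster's diagonal and within ``max_q_gap`` of
    its last seed, so small indels (nearby diagonals) stay in one window
    while repeats elsewhere in the target start their own.
    """
    if not matches:
        return []
    by_q = sorted((q, d) for d, q in matches)
    # cluster state: [last_q, diag_lo, diag_hi, qlo, qhi, tlo, thi]
    clusters: list[list[int]] = []
    for q, d in by_q:
        t = q + d
        placed = False
        for cl in clusters:
            if q - cl[0] <= max_q_gap and cl[1] - band <= d <= cl[2] + band:
                cl[0] = q
                cl[1] = min(cl[1], d)
                cl[2] = max(cl[2], d)
                cl[3] = min(cl[3], q)
                cl[4] = max(cl[4], q)
                cl[5] = min(cl[5], t)
                cl[6] = max(cl[6], t)
                placed = True
                break
        if not placed:
            clusters.append([q, d, d, q, q, t, t])
    return [(cl[3], cl[4] + k, cl[5], cl[6] + k) for cl in clusters]


def _alignment_to_hit(
    aln,
    qoff: int,
    toff: int,
    qname: str,
    qlen: int,
    tlen_total: int,
    contig_id: str,
    strand: str,
) -> LocalHit:
    blocks: list[tuple[int, int, int]] = []
    matches = mismatches = 0
    # we call PairwiseAligner.align(target_window, query): aligned[0]
    # indexes the target window, aligned[1] the query
    qseq, tseq = aln.query, aln.target
    for (t_s, t_e), (q_s, q_e) in zip(aln.aligned[0], aln.aligned[1]):
        blocks.append((qoff + q_s, toff + t_s, t_e - t_s))
        for a, b in zip(tseq[t_s:t_e], qseq[q_s:q_e]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
    aligned_cols = matches + mismatches
    q_lo = qoff + int(aln.aligned[1][0][0])
    q_hi = qoff + int(aln.aligned[1][-1][1])
    t_lo = toff + int(aln.aligned[0][0][0])
    t_hi = toff + int(aln.aligned[0][-1][1])
    raw = float(aln.score)
    bit = (_LAMBDA * raw - math.log(_K)) / _LN2
    evalue = qlen * tlen_total * math.pow(2.0, -bit)
    if strand == "+":
        interval = GenomicInterval(contig_id, t_lo, t_hi, "+")
    else:
        interval = GenomicInterval(contig_id, tlen_total - t_hi, tlen_total - t_lo, "-")
    pid = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    return LocalHit(
        reference_gene=qname,
        query_start=q_lo,
        query_end=q_hi,
        interval=interval,
        percent_identity=pid,
        bit_score=bit,
        e_value=evalue,
        t_start=t_lo,
        t_end=t_hi,
        blocks=blocks,
    )


def _align_window(
    query: str,
    tseq: str,
    qlo: int,
    qhi: int,
    tlo: int,
    thi: int,
    qname: str,
    tlen_total: int,
    contig_id: str,
    strand: str,
    min_raw: float,
    depth: int = 0,
) -> list[LocalHit]:
    """Locally align one seed-cluster window; recurse on the flanks so that
    several co-linear local maxima (e.g. exons split by a divergent intron)
    each yield a hit."""
    margin = 30
    qlo_m, qhi_m = max(0, qlo - margin), min(len(query), qhi + margin)
    tlo_m, thi_m = max(0, tlo - margin), min(len(tseq), thi + margin)
    qwin = query[qlo_m:qhi_m]
    twin = tseq[tlo_m:thi_m]
    if len(qwin) < 4 or len(twin) < 4:
        return []
    alns = _dna_aligner().align(twin.replace("N", "n"), qwin)
    if len(alns) == 0 or alns.score < min_raw:
        return []
    aln = alns[0]
    hit = _alignment_to_hit(aln, qlo_m, tlo_m, qname, len(query), tlen_total, contig_id, strand)
    hits = [hit]
    if depth < 4:
        # flanks not consumed by this alignment may hold further co-linear hits
        left_q, left_t = hit.query_start - qlo_m, hit.t_start - tlo_m
        if left_q >= 12 and left_t >= 12:
            hits.extend(
                _align_window(
                    query, tseq, qlo_m, hit.query_start, tlo_m, hit.t_start,
                    qname, tlen_total, contig_id, strand, min_raw, depth + 1,
                )
            )
        right_q, right_t = qhi_m - hit.query_end, thi_m - hit.t_end
        if right_q >= 12 and right_t >= 12:
            hits.extend(
                _align_window(
                    query, tseq, hit.query_end, qhi_m, hit.t_end, thi_m,
                    qname, tlen_total, contig_id, strand, min_raw, depth + 1,
                )
            )
    return hits


def fallback_align(
    query: str,
    target: str,
    qname: str = "query",
    contig_id: str = "target",
    params: SearchParams = SearchParams(),
    both_strands: bool = True,
) -> list[LocalHit]:
    """Engine-free local search of one query against one target sequence."""
    hits: list[LocalHit] = []
    L = len(target)
    strands = [("+", target)]
    if both_strands:
        strands.append(("-", revcomp(target)))
    for strand, tseq in strands:
        index = _kmer_index(tseq, params.word_size)
        matches = _seed_matches(query, index, params.word_size)
        for qlo, qhi, tlo, thi in _cluster_seeds(matches, params.word_size):
            hits.extend(
                _align_window(
                    query, tseq, qlo, qhi, tlo, thi, qname, L, contig_id,
                    strand, params.min_raw_score,
                )
            )
    # dedupe identical spans produced by overlapping clusters
    seen = set()
    unique = []
    for h in sorted(hits, key=lambda h: (-h.bit_score, h.query_start, h.t_start)):
        key = (h.strand, h.query_start, h.query_end, h.t_start, h.t_end)
        if key in seen:
            continue
        seen.add(key)
        unique.append(h)
    gated = [
        h
        for h in unique
        if h.percent_identity >= params.min_identity
        and (h.query_end - h.query_start) >= params.min_coverage * len(query)
    ]
    gated.sort(key=lambda h: (h.strand, h.query_start, h.t_start))
    return gated


# --------------------------------------------------------------------------
# external engine (NCBI blastn, tabular output)
# --------------------------------------------------------------------------

_OUTFMT = "6 qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"


def blastn_search(
    queries: Sequence[tuple[str, str]],
    contig: SequenceRecord,
    params: SearchParams,
    blastn_path: str = "blastn",
) -> list[LocalHit]:
    """Run NCBI blastn in subject mode and parse outfmt 6 into LocalHits."""
    if shutil.which(blastn_path) is None:
        raise EngineError(f"{blastn_path} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "q.fa"
        spath = Path(tmp) / "s.fa"
        with open(qpath, "w") as fh:
            for name, seq in queries:
                fh.write(f">{name}\n{seq}\n")
        spath.write_text(f">{contig.id}\n{contig.seq}\n")
        cmd = [
            blastn_path, "-task", "blastn", "-query", str(qpath), "-subject", str(spath),
            "-word_size", str(params.word_size), "-evalue", str(params.max_evalue),
            "-reward", "2", "-penalty", "-3", "-gapopen", "5", "-gapextend", "2",
            "-dust", "no", "-soft_masking", "false", "-outfmt", _OUTFMT,
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise EngineError(f"blastn failed: {proc.stderr.strip()}")
        out = proc.stdout
    L = len(contig.seq)
    hits: list[LocalHit] = []
    for line in out.splitlines():
        cols = line.split("\t")
        if len(cols) != 12:
            continue
        qname, _, pident, length, _, _, qstart, qend, sstart, send, evalue, bit = cols
        qs, qe = int(qstart) - 1, int(qend)
        ss, se = int(sstart), int(send)
        if ss <= se:
            strand = "+"
            t_lo, t_hi = ss - 1, se
            interval = GenomicInterval(contig.id, t_lo, t_hi, "+")
        else:
            strand = "-"
            fwd_lo, fwd_hi = se - 1, ss
            t_lo, t_hi = L - fwd_hi, L - fwd_lo  # strand-space
            interval = GenomicInterval(contig.id, fwd_lo, fwd_hi, "-")
        hits.append(
            LocalHit(
                reference_gene=qname,
                query_start=qs,
                query_end=qe,
                interval=interval,
                percent_identity=float(pident),
                bit_score=float(bit),
                e_value=float(evalue),
                t_start=t_lo,
                t_end=t_hi,
                blocks=[(qs, t_lo, min(qe - qs, t_hi - t_lo))],
            )
        )
    hits = [h for h in hits if h.percent_identity >= params.min_identity and h.e_value <= params.max_evalue]
    hits.sort(key=lambda h: (h.reference_gene, h.strand, h.query_start, h.t_start))
    return hits


def search(
    reference: ReferenceGeneSet,
    contig: SequenceRecord,
    params_by_type: dict[str, SearchParams] | None = None,
    segment_type: str | None = None,
    engine: str = "builtin",
) -> list[LocalHit]:
    """Find local hits for every reference gene (optionally one segment type)."""
    params_by_type = params_by_type or DEFAULT_SEARCH_PARAMS
    genes = reference.genes if segment_type is None else reference.by_type(segment_type)
    hits: list[LocalHit] = []
    if engine == "builtin":
        for gene in genes:
            params = params_by_type.get(gene.segment_type, SearchParams())
            hits.extend(
                fallback_align(gene.full_seq, contig.seq, gene.label, contig.id, params)
            )
    elif engine == "blastn":
        by_params: dict[str, list[tuple[str, str]]] = {}
        for gene in genes:
            by_params.setdefault(gene.segment_type, []).append((gene.label, gene.full_seq))
        for seg, queries in sorted(by_params.items()):
            params = params_by_type.get(seg, SearchParams())
            seg_hits = blastn_search(queries, contig, params)
            qlens = {name: len(seq) for name, seq in queries}
            hits.extend(
                h for h in seg_hits
                if (h.query_end - h.query_start) >= params.min_coverage * qlens[h.reference_gene]
            )
    else:
        raise EngineError(f"unknown engine {engine!r}")
    return hits


# --------------------------------------------------------------------------
# chaining
# --------------------------------------------------------------------------


def _chain_compatible(a: LocalHit, b: LocalHit, max_intron: int, query_gap_slack: int) -> bool:
    """May hit b follow hit a in a chain?  Strictly increasing in query and
    target, target gap bounded by the intron allowance, query gap small."""
    if b.query_start < a.query_end or b.t_start < a.t_end:
        return False
    if b.t_start - a.t_end > max_intron:
        return False
    if b.query_start - a.query_end > query_gap_slack:
        return False
    return True


def chain_hits(
    hits: Sequence[LocalHit],
    max_intron: int = 16000,
    query_gap_slack: int = 50,
    reference_gene: ReferenceGene | None = None,
    contig: SequenceRecord | None = None,
) -> list[ChainedCandidate]:
    """Maximal-scoring co-linear chains (dynamic programming over hits
    sorted by query start); every hit joins at most one chain; unchainable
    hits become single-hit candidates.

    When the reference gene and contig are supplied, each chain also gets
    its exon projection, completeness, and N-gap count.
    """
    remaining = sorted(hits, key=lambda h: (h.query_start, h.t_start, -h.bit_score))
    chains: list[list[LocalHit]] = []
    while remaining:
        n = len(remaining)
        best_score = [h.bit_score for h in remaining]
        back: list[int | None] = [None] * n
        for i in range(n):
            for j in range(i):
                if _chain_compatible(remaining[j], remaining[i], max_intron, query_gap_slack):
                    cand = best_score[j] + remaining[i].bit_score
                    if cand > best_score[i] + 1e-12:
                        best_score[i] = cand
                        back[i] = j
        end = max(range(n), key=lambda i: (best_score[i], -remaining[i].query_start))
        chain_idx = []
        k: int | None = end
        while k is not None:
            chain_idx.append(k)
            k = back[k]
        chain_idx.reverse()
        chains.append([remaining[i] for i in chain_idx])
        used = set(chain_idx)
        remaining = [h for i, h in enumerate(remaining) if i not in used]

    out = []
    for chain in chains:
        out.append(_build_candidate(chain, reference_gene, contig))
    out.sort(key=lambda c: (-c.score, c.span.start))
    return out


def _project(blocks: list[tuple[int, int, int]], q: int) -> tuple[int, bool]:
    """Map a query offset through aligned blocks to a strand-space target
    offset.  Returns (target, exact); inexact positions use the nearest
    aligned position with offset interpolation inside the gap."""
    prev = None
    for bq, bt, ln in blocks:
        if bq <= q <= bq + ln:
            return bt + (q - bq), True
        if bq + ln <= q:
            prev = (bq, bt, ln)
        else:
            nxt = (bq, bt, ln)
            if prev is None:
                return max(0, nxt[1] - (nxt[0] - q)), False
            d_prev = q - (prev[0] + prev[2])
            d_next = nxt[0] - q
            if d_prev <= d_next:
                return prev[1] + prev[2] + d_prev, False
            return nxt[1] - d_next, False
    if prev is not None:
        return prev[1] + prev[2] + (q - (prev[0] + prev[2])), False
    raise ValueError("no aligned blocks to project through")


def _snap_splice(tseq: str, pos: int, motif: str, side: str, radius: int = 6) -> int:
    """Nearest GT/AG adjustment: for a donor ('after' side) look for the
    motif starting at the returned position; for an acceptor ('before')
    look for the motif ending at the returned position."""
    best = pos
    best_d = radius + 1
    for d in range(-radius, radius + 1):
        p = pos + d
        if side == "after":
            window = tseq[p : p + 2]
        else:
            window = tseq[p - 2 : p]
        if window == motif and abs(d) < best_d:
            best, best_d = p, abs(d)
    return best


def _build_candidate(
    chain: list[LocalHit],
    reference_gene: ReferenceGene | None,
    contig: SequenceRecord | None,
) -> ChainedCandidate:
    first, last = chain[0], chain[-1]
    strand = first.strand
    contig_id = first.interval.contig_id
    span = GenomicInterval(
        contig_id,
        min(h.interval.start for h in chain),
        max(h.interval.end for h in chain),
        strand,
    )
    cand = ChainedCandidate(
        reference_gene=first.reference_gene,
        segment_type=reference_gene.segment_type if reference_gene else "",
        hits=list(chain),
        span=span,
        strand=strand,
        score=sum(h.bit_score for h in chain),
    )
    if reference_gene is None or contig is None:
        return cand
    cand.contig_length = len(contig.seq)
    tseq = contig.seq if strand == "+" else revcomp(contig.seq)
    blocks = cand.blocks
    L = len(contig.seq)

    exon_map: list[tuple[str, GenomicInterval]] = []
    offsets = reference_gene.exon_offsets()
    n_exons = len(offsets)
    for i, (lab, q_s, q_e) in enumerate(offsets):
        t_s, exact_s = _project(blocks, q_s)
        t_e, exact_e = _project(blocks, q_e)
        if not exact_s and i > 0:
            t_s = _snap_splice(tseq, t_s, "AG", side="before")
        if not exact_e and i < n_exons - 1:
            t_e = _snap_splice(tseq, t_e, "GT", side="after")
        t_s = max(0, min(t_s, len(tseq)))
        t_e = max(0, min(t_e, len(tseq)))
        if t_e <= t_s:
            continue
        if strand == "+":
            iv = GenomicInterval(contig_id, t_s, t_e, "+")
        else:
            iv = GenomicInterval(contig_id, L - t_e, L - t_s, "-")
        exon_map.append((lab, iv))
    cand.exon_map = exon_map

    # completeness: fraction of reference coding positions covered by blocks
    coding_ranges = [
        (s, e) for lab, s, e in offsets if lab not in NONCODING_LABELS
    ]
    total = sum(e - s for s, e in coding_ranges)
    covered = 0
    for s, e in coding_ranges:
        for bq, _, ln in blocks:
            covered += max(0, min(e, bq + ln) - max(s, bq))
    cand.completeness = covered / total if total else 0.0

    # N bases inside the projected coding region
    n_count = 0
    for lab, iv in exon_map:
        if lab in NONCODING_LABELS:
            continue
        n_count += contig.seq[iv.start : iv.end].count("N")
    cand.gap_overlap = n_count
    return cand


def select_candidates(
    chains: Iterable[ChainedCandidate],
    overlap_frac: float = 0.5,
) -> list[ChainedCandidate]:
    """Greedy non-overlap selection within each segment type: best summed
    bit score wins, ties broken by completeness then reference name; a
    chain is rejected when its coding projection overlaps an accepted
    chain of the same type by more than ``overlap_frac`` of the shorter."""
    by_type: dict[str, list[ChainedCandidate]] = {}
    for c in chains:
        by_type.setdefault(c.segment_type, []).append(c)
    accepted: list[ChainedCandidate] = []
    for seg in sorted(by_type):
        pool = sorted(
            by_type[seg],
            key=lambda c: (-c.score, -c.completeness, c.reference_gene, c.span.start),
        )
        kept: list[ChainedCandidate] = []
        for cand in pool:
            span = _coding_span(cand)
            clash = False
            for acc in kept:
                aspan = _coding_span(acc)
                ov = span.overlap(aspan)
                if ov > overlap_frac * min(span.length, aspan.length):
                    clash = True
                    break
            if not clash:
                kept.append(cand)
        accepted.extend(kept)
    accepted.sort(key=lambda c: (c.span.contig_id, c.span.start, c.reference_gene))
    return accepted


def _coding_span(cand: ChainedCandidate) -> GenomicInterval:
    ivs = [iv for lab, iv in cand.exon_map if lab not in NONCODING_LABELS]
    if not ivs:
        return cand.span
    return GenomicInterval(
        cand.span.contig_id,
        min(iv.start for iv in ivs),
        max(iv.end for iv in ivs),
        cand.strand,
    )
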