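# Methods

This note documents the models, algorithms and numerical choices behind
`vdjannot`, what the synthetic fixtures do and do not emulate, and the
design decisions taken where more than one reasonable option existed.

## Coordinate model

All coordinates inside the package are 0-based half-open on the forward
strand of the named contig; minus-strand features keep contig-forward
coordinates and their sequence is reverse-complemented on extraction.
Conversion to GFF3's 1-based inclusive convention happens only in the GFF3
writer/reader, so there is exactly one place where an off-by-one can live.
BED is written natively. GFF3 attribute values percent-encode
`% ; = & , TAB NL`; output ordering is deterministic by
(contig, start, ID) with children following their parents, which makes
re-emission byte-identical.

## Reference extraction

The EMBL/IMGT feature-table parser supports the location grammar
`n..m`, `n`, `complement(...)`, `join(...)`/`order(...)` with nesting, and
the fuzzy markers `<`/`>` (stripped, recorded as a partial flag).
LIGM-DB formatting is not fully standardized, so the label lexicon is an
explicit, extensible policy: V genes assemble from
{L-PART1, L-PART2, V-EXON, V-REGION}, D from D-REGION, J from J-REGION,
C from {C-REGION, CH1…CH4, H, H1–H4, CH-S, M, M1, M2, EX1…EX4, EX4UTR};
EX4UTR is treated as non-coding. Anything else becomes a passthrough note
in the parse log — unknown labels never abort a run. Features are grouped
into genes by their `gene`/`IMGT_allele` qualifiers; unnamed
conserved-residue features attach by containment; genes with zero
locatable exons are skipped and logged.

Conserved positions (the two V-region cysteines and the J-region
tryptophan/phenylalanine) are taken from `1st-CYST`/`2nd-CYST`/`J-TRP`/
`J-PHE` features when present and validated by translation. When a gene
lacks them, they are transferred by global protein alignment (BLOSUM62,
gap −11/−1) from the highest-scoring donor gene of the same type that has
them; a transferred position is kept only if the aligned residue actually
is C (or W/F). If no mapping survives, the positions stay unset and the
residue check is simply skipped for that gene — the gene can still be
classified on every other criterion. The J reading frame is derived from
the W/F codon offset modulo 3.

## RIC model

The RSS scorer is a position-wise conditional model over the fixed-length
window heptamer+spacer+nonamer (28 nt for the 12-spacer class, 39 nt for
the 23-spacer class). Position *i* conditions on the `min(i, order)`
immediately preceding window positions; order 0 is a PWM, order 1 is the
default (the simplest dependence structure beyond independence, and the
cheapest to estimate reliably from a few hundred training windows).
Probabilities are relative frequencies with an additive pseudocount
(default 1.0) per position/context; the score of a window is the summed
log conditional probability, so scores are ≤ 0 and the consensus of a
single-window pseudocount-0 model scores exactly 0.

The reporting threshold defaults to the minimum training-set score minus a
margin of 5 nats. This guarantees recall of the training set itself and
leaves headroom for windows drawn from the same distribution, while
keeping the per-window false-positive rate on random background far below
10⁻³ (the conserved heptamer/nonamer positions alone put a random window
tens of nats below threshold). The threshold is per-model and
user-overridable — a model trained on one species can genuinely miss RSS
in a distant one, and loosening the threshold is the intended knob.
Windows containing N are unscorable (−∞) and never reported; assembly
gaps are handled downstream by the completeness/withholding logic, not by
the scanner. Spacer-length polymorphism (±1 nt) is not modelled; windows
are fixed-length. Known limitation.

Models serialise to versioned JSON (all tables, order, pseudocount,
threshold, training size), so a trained model is a shippable artifact.
Candidate exchange uses BED6 with the RIC score mapped affinely from
[threshold, 0] onto [0, 1000]; any external RSS predictor whose output is
reformatted to this BED contract can replace the built-in scanner.

## Homology search and chaining

Searches use the *entire* reference gene sequence, introns included.
This is what makes multi-exon C genes and very short D genes tractable:
C exons are anchored by their surrounding gene context, and a D segment of
10–35 nt is found as a complete unit rather than assembled from pieces.

Two engines sit behind one interface. The built-in engine is
seed-and-extend: exact k-mer seeding against an index of the contig
(word size 11 for V/J/C, 7 for D), clustering of seeds into diagonal
bands (band 32 nt, query gap ≤ 200 nt — wide enough that the two
diagonals flanking a small indel stay in one cluster), then gapped local
alignment of each cluster window (match 2, mismatch −3, gap open −5,
extend −2) with recursive re-alignment of unconsumed flanks so that
several co-linear local maxima each yield a hit. Per the engine contract,
the built-in aligner gates on raw alignment score (≥ 50 for V/J/C — about
a 25-bp perfect match — and ≥ 16 for D), identity (≥ 60% V/J/C, ≥ 80% D)
and query coverage (≥ 90% for D); the e-value it reports is a
Karlin–Altschul-style estimate for information only. NCBI `blastn`
(tabular output, subject mode) is available as an external engine and
gates on e-value (10⁻¹⁰ for V/J/C, 10 for D) as usual.

Hits for one gene and strand are chained by dynamic programming into
maximal-scoring co-linear chains: consecutive hits must strictly increase
in query and target, with target gap ≤ 16 kb (kilobase-scale introns plus
headroom) and query gap ≤ 50 nt. Chains are extracted best-first; each
hit joins at most one chain. This deliberately tolerates low-identity
interior introns — the chain joins the flanking exon hits instead of
requiring one contiguous alignment. For ≤ 10 hits the chain equals
exhaustive co-linear subset maximisation (tested against that oracle).

Reference exon boundaries are projected onto the target through the
chain's aligned blocks; positions falling in unaligned gaps interpolate
from the nearest aligned position and are then snapped to the nearest
GT (donor) or AG (acceptor) within ±6 nt — but only when the boundary was
not exactly aligned, so perfect matches keep exact coordinates.
Candidate completeness is the fraction of reference coding positions
covered by aligned blocks; Ns inside the projected coding region are
counted as gap overlap.

Overlap resolution is greedy within each segment type: chains sorted by
(summed score desc, completeness desc, reference name asc) are accepted
unless their coding projection overlaps an accepted chain of the same
type by more than half the shorter projection. Sorting keys make the
selection deterministic and permutation-invariant.

## Verification and classification

Required RSS flanks follow the 12/23 rule with the standard per-locus
spacer table (IGH V23/D12,12/J23; IGK V12/J23; IGL V23/J12; TRA V23/J12;
TRB and TRD V23/D12,23/J12; TRG V23/J12), all overridable. A flank
matches the highest-scoring candidate RSS of the correct spacer class and
orientation whose heptamer edge lies within 3 nt of the coding boundary
(heptamers abut coding ends biologically; the small tolerance absorbs
projection error). Splice verification checks GT/AG at every intron of a
multi-exon candidate; single-exon candidates pass vacuously. Coding
checks run on the spliced exon concatenation: ATG start (V only),
internal stops (in the reference-derived frame; a C gene's final codon
may be a natural stop), frameshift as a coding-length difference not
divisible by 3, and the conserved residues at positions projected through
the alignment. D segments are exempt from stop/frameshift checks: they
have no fixed reading frame in the germline, all three being used after
rearrangement.

Classification is a pure function of the verification report with strict
precedence: internal stop, frameshift or missing start ⇒ **pseudogene**;
otherwise missing RSS, non-canonical splice or missing invariant residue
⇒ **ORF**; otherwise **functional**. Stop codons that might be excised
during rearrangement are still pseudogene — no rescue heuristic.
Candidates with completeness < 0.95 or any N inside the projected coding
region are withheld from output entirely and logged with coordinates and
cause. One additional policy: a D candidate with *no* matched RSS on
either flank is withheld rather than reported as ORF. D queries are so
short that chance matches passing the relaxed gates are expected about
once per 100 kb; requiring at least one flanking RSS (the defining
feature of a D segment) removes them, while a D with exactly one matched
flank still classifies as ORF via RSS_MISSING.

Allele naming hashes the uppercase, ungapped *coding* nucleotide sequence
(exons concatenated, no introns): an exact match against the reference
coding index keeps the reference `gene*allele` name; otherwise the name
is the base gene name plus `*` and the first four lowercase hex
characters of the SHA-1 digest. Four hex characters can collide;
collisions are logged and disambiguated with a numeric suffix. The coding
sequence is the allele-defining unit, so two candidates differing only in
introns share a name by design.

The pipeline runs segment types in the order V, D, J, C with no masking
between stages; overlap resolution applies only within a type.

## Synthetic fixtures

The generator builds loci with the anatomy the pipeline must handle:
V genes as ATG-initiated L-PART1 (45–60 nt), a GT/AG leader intron
(80–150 nt) and a V exon (270–310 nt) with TGT/TGC codons at the two
conserved positions; D segments of 10–35 nt; J segments of 45–65 nt with
an in-frame TGG/TTC at the conserved position and a random reading-frame
phase; C genes of 2–4 exons (100–330 nt each, splits not codon-aligned)
with GT/AG introns of 100–2000 nt. Intergenic spacers are uniform
500–5000 nt of i.i.d. background (configurable GC, default 0.5).
Coding regions are sampled codon-wise from the 61 sense codons, so
planted genes are stop-free by construction. About a third of reference
genes are emitted on the minus strand, and one C gene uses a `join()`
location, to exercise the parser; planted genes take a random strand.

RSS training windows and planted RSS come from the same sampler: the
consensus heptamer CACAGTG and nonamer ACAAAAACC around a fixed spacer,
with substitution noise 0.02 in heptamer/nonamer and 0.12 in the spacer
(conserved elements vary little in nature, spacers a lot). Training uses
500 windows. Because planted RSS are drawn from the training
distribution, they are detectable at the default threshold; a noise-scale
parameter exists to probe threshold sensitivity.

Mutation operators apply exactly one defect per gene so each planted gene
maps unambiguously to an expected call: `introduce_stop`, `delete_start`
(ATG→ATC), `frameshift_del1`, `scramble_rss` (one required flank
shuffled), `gc_donor` (first intron GT→GC), `mutate_cys` (second Cys→Gly),
`insert_n_gap` (200 Ns mid-exon). Truth records track every interval
through length-changing operators.

What the fixtures do *not* emulate: real V-family sequence homology
(synthetic genes are mutually unrelated, so cross-gene competition and
allele confusion are under-tested), indel-rich divergence (the divergence
experiment is substitution-only), segmental duplication, haplotype
diversity, and realistic base composition. Passing the plant-and-recover
suite therefore demonstrates coordinate bookkeeping, chaining,
verification and classification correctness — not recall on a real
diverged genome, which depends on alignment sensitivity that only real
data can measure.

## Problem sizes and determinism

The shipped measurements use ten replicate loci of ~80–110 kb with
20 genes each (8 V, 4 D, 6 J, 2 C) for plant-and-recover, two loci for
the mutation matrix and for each point of the divergence curve
(substitution rates 0, 0.05, 0.10, 0.20 applied to the reference before
search), 100 kb of background for the RSS false-positive rate, and
20 random instances for the chaining oracle. All randomness flows from
explicit seeds through `numpy.random.default_rng`; identical spec + seed
reproduces byte-identical contigs, flat files and GFF3.

## Known limitations

* Order-k RIC is this package's instantiation of an RSS dependence model;
  no parity with any previously published RSS scorer's numeric scores is
  claimed, and published thresholds do not transfer.
* The built-in aligner's e-values are rough estimates; its gates are raw
  score, identity and coverage.
* Fixed-length RSS windows (no spacer polymorphism).
* No iterative search, no multiple-reference merging, no masking between
  segment stages, no haplotype phasing, no IMGT unique-numbering
  alignment.
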