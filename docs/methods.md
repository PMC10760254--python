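# Methods

## The synthetic study system

The generator (`svdissect.synthgenome`) emulates a family segregating a
complex rearrangement of the distal short arm of a chromosome: a ~2.6 Mb
reference region carries three duplication intervals

    dup1 346,084–700,056 (353,973 bp)
    dup2 788,363–864,099 ( 75,737 bp)
    dup3 2,271,746–2,351,089 ( 79,344 bp)

and the derivative homolog realises the signed segment word

    +S0 +D1 +D2 +INS:SINE -D3 -S2 -D2 -S1 -D1 +D3 +S3

where S* are the single-copy intervals between the duplications. This word
is the structure consistent with all of the study's constraints at once:
each duplication appears exactly twice, the inter-duplication segments
once, there are exactly three novel adjacencies (dup1-end→dup2-start, the
read-through fusion; dup2-end→SINE→inverted dup3-end; dup1-start→
dup3-start) over six breakpoints (two per duplication), and the maximal
inverted run spans 346,084–2,351,089 = 2,005,006 bp contiguously. The
insertion is a fixed 500 bp Alu-consensus-like element ending in a polyA
tail ("~500 bp" reported; 500 chosen as the round value). polyA/polyT
simple repeats are planted on the reference flanks of the dup2/dup3 distal
breakpoints so the insertion junction shows polyA/T microhomology.

Gene models are schematic stand-ins: a dock8-like gene truncated by dup1's
left boundary, a kank1-like gene whose promoter and exons 1–2 lie inside
dup1 (later exons in S1 — which is why the derivative's forward copy of the
gene is truncated after its exon-2 donor), and a dmrt1-like gene with exon
1 left of dup2 and exons 2–9 inside dup2. Between dup2's start and the
dmrt1-like exon 2 sits a 48-nt cassette flanked by a consensus-perfect
acceptor (…ag) and donor (gt…) context; its sequence is fixed, and a
three-frame scan shows a stop codon (TGA, offset 41) in exactly one frame.
The kank1-like ATG is placed so the CDS length up to the end of exon 2 is
≡ 1 (mod 3): translation enters the cassette with codons starting at
cassette offset 2 — the frame containing the TGA. The dmrt1-like exon-1
CDS length is ≡ 0 (mod 3), so its annotated exon-2 entry phase (0) differs
from the fusion's entry phase (1) with or without the 48-nt cassette
(48 ≡ 0 mod 3): the read-through is out of frame either way.

Six heterozygous SNV markers are planted 100–150 bp from the breakpoints,
inside the duplicated intervals. The alternative allele is carried by the
derivative homolog. This phasing reproduces the read-pair categories the
analysis relies on: the intact homolog gives concordant/reference pairs
(category 1), the derivative's junction-adjacent copy gives
discordant/alternative pairs (category 2), and the derivative's second,
reference-adjacent copy of each duplicated segment gives
concordant/alternative pairs (category 3) — evidence that both homologs
retain a reference-structure copy of the breakend region.

### Simulation models and defaults

* Paired-end DNA reads: fragments uniform across homologs proportional to
  length; pair count = round(total_length × coverage / (2 × read_length));
  FR geometry, fragment length ~ Normal(400, 60) bp, read length 150 bp,
  coverage 20×, i.i.d. substitution errors at 0.1%. No indel or
  quality-score model, no GC bias — so mapping is strictly diagonal and
  the aligner needs no gapped alignment.
* Probe track: one probe per 1,000 bp, mean log2(CN/2) (0 for CN2, 0.585
  for CN3), Gaussian noise with sd 0.06 — a high-quality custom
  tiling-array regime. Real 180K-style arrays are noisier and sparser;
  passing tests show boundary recovery at probe resolution, not robustness
  to array artefacts (waves, dye bias), which are not modelled.
* RNA reads: error-free, single-end, stranded, sampled from transcript
  sense strands only; expression is a relative weight, not a count model.
* Pedigree fixture: five generations; 11 genotyped affected members (all
  carriers), 11 genotyped unaffected members (all non-carriers), plus
  untested members (founder, spouses, and the youngest generation's
  affected children). Only the printed counts are preserved — the real
  family's topology is not enumerable from the text.

All randomness flows from one integer seed through fixed per-stage
offsets; two runs with the same seed are byte-identical.

## Stage-by-stage notes

### CNV calling

A call is a maximal run of ≥ `min_probes` (default 3) consecutive probes
above `gain_threshold` (+0.3) or below `loss_threshold` (−0.3); the source
array software's actual threshold is unpublished, so ±0.3 is a stand-in
halfway between 0 and log2(3/2). Two same-state runs separated by exactly
one sub-threshold probe are merged (`bridge_gap = 1`): with hundreds of
probes per duplication, a single noise dip would otherwise split a call
(at noise sd 0.1 the probability of at least one dip inside the 354-probe
dup1 is ≈ 0.5 per run). Run formation itself remains strictly
consecutive; the call interval spans the first to last aberrant probe,
which converges to the true boundary within one probe spacing as noise
vanishes. Gains are reported as x3 and losses as x1 under the diploid
assumption; mosaic states are out of scope.

### Alignment

Exact k-mer anchors (k = 21, k-mers with > 50 reference hits dropped) are
grouped per (strand, diagonal) — valid because the error model is
substitution-only — and each group is extended base-by-base while the read
matches the reference. Blocks ≥ 25 bp with ≥ 3 anchors become alignment
records: the longest is primary, others supplementary; ties break by
leftmost reference position. Up to 10 bp of read-coordinate overlap
between blocks is tolerated (microhomology). A vectorised fast path
places reads whose two terminal k-mers agree on one unique diagonal
(accepting ≤ 8% mismatches after full verification); the rest go through
full chaining. Pairs are concordant iff FR-oriented with insert within
mean ± 4 sd — 4 sd keeps the false-discordant rate per cohort far below
the clustering threshold. No mapping-quality model and no indel CIGARs:
this is a functional stand-in for a production mapper, adequate because
the simulation honours its assumptions.

### Junction detection

Split-read candidates cluster only when both breakends and the
supplementary locus/strand agree within 10 bp; discordant-pair candidates
cluster within insert_mean + 4 sd (mate coordinates scatter over the
fragment length), with the breakend estimated by the innermost mate
coordinate and refined to the soft-clip consensus position when ≥ 2
clipped reads agree exactly. Pairs with one unmapped mate are clustered by
their anchored mate and treated as insertion evidence: two facing clusters
are fused into one junction candidate when the clipped tails and orphaned
mates from both sides assemble into a single contig. The pass filter is an
OR of the two arms — ≥ 4 case splits with 0 control splits, or ≥ 5 case
discordant pairs with ≤ 1 in the control — because an insertion longer
than the fragment length is invisible to split reads (every read crossing
the boundary clips into novel sequence) yet fully supported by anchored
pairs. With fragment length 400 ± 60 and a 500 bp insertion, both-mapped
pairs across the insertion essentially cannot occur; counting anchored
pairs on the discordant arm is how the event actually presents.

Insertion assembly is greedy overlap layout (minimum overlap 20 bp, seeds
matched exactly, overlaps verified at ≤ 10% mismatch) with per-column
majority vote; only clips attached exactly at the refined breakend are
used, because a read whose extension stopped early at a sequencing error
would drag flank bases into the contig. Side-B tails delimit the contig's
3' end. The assembled length is exact for error-free reads up to the
microhomology ambiguity of the breakend itself (±2 bp observed), and a
junction whose tails continue straight into the partner's reference flank
(within a ±10 bp shift) is reported clean. Fewer than 3 informative reads
yield an empty result with a warning.

Microhomology is measured as the maximal breakpoint slide: bases by which
the junction can move right (reference continuation past breakend A equals
the sequence entering B) plus left (flank ending at A equals B's upstream
context), reported in breakend A's orientation. The clustering window
(10 bp) must exceed observed microhomology lengths; the planted polyA runs
are kept at 8 bp.

### Reconstruction

Junction cuts are base-precise; CNV edges only probe-precise. A CNV edge
within one probe spacing (+ window) of a junction cut is absorbed by it —
the breakpoints "match the boundaries" of the CNV segments — rather than
averaged, which would create sliver segments with impossible copy numbers.
Copy number on the rearranged homolog is the called total minus one intact
homolog (justified by the category-3 pair evidence). The walk search is
exact DFS over (segment, orientation, remaining-copy multiset, used-edge
mask) states with dead-state memoisation, capped at 64 solutions with an
explicit truncation flag; an independent brute-force enumerator over all
orderings and orientations serves as the oracle for small graphs. Every
unflagged novel edge must be used at least once (each junction was
observed); edges may be reused up to copy-number consistency.

Multiple words typically satisfy the evidence (six for the default data) —
short reads cannot phase distant segment orientations, which in the
emulated study required an orthogonal long-molecule technology. Ambiguity
is therefore surfaced, and the proposed structure is the word maximising
the largest reference-contiguous inverted block: junction geometry proves
inverted sequence is present, and one inversion event is the parsimonious
reading. An inverted block is only counted while consecutive '-' segments
are reference neighbours — a novel-edge jump starts a new block, so
reported spans are genuinely contiguous inverted sequence.

### Fusion transcripts

The learned splice model used in the emulated study is replaced by
packaged position-weight matrices: a 9-mer donor (MAG|GTRAGT-like) and a
17-position acceptor (polypyrimidine tract + YAG| + exon start), scored as
log-odds against a uniform background and normalised to a 0–0.99 scale; a
hard GT/AG dinucleotide requirement applies. Annotated exon boundaries are
additionally emitted at score 1.0 (predicted sites match known junctions
inside annotated genes), so motif-only evidence never outranks
annotation. The default chaining threshold (0.97 of the consensus
log-odds) is chosen from the matrices' information content: at 0.97 the
expected chance-site rate on random sequence is ~10⁻⁵·⁵ per bp for donors
and ~10⁻⁷·⁷ for acceptors, i.e. well below one spurious acceptor across
the ~350 kb the fusion chain traverses, while planted consensus-perfect
contexts always pass at 0.99. Raising the threshold above 0.99 drops the
cassette and yields the 10-exon skip variant, which stays frame-
incompatible.

Transcripts chain greedily from each forward-strand promoter — nearest
qualifying donor, then nearest qualifying acceptor — until an annotated
terminal exon; no isoform lattice is built because the emulated analysis
reports a single chained structure. ORFs translate from the kank1-like
annotated ATG with the standard nuclear code; the report records the first
in-frame stop (exon index, offset, codon), per-exon entry phases, frame
compatibility against the downstream gene's annotated phase, and NMD by
the canonical rule: predicted decay iff the stop ends ≥ 50 nt upstream of
the final exon–exon junction. RNA verification counts reads spanning each
junction with ≥ 8 nt overhang on both sides, located by exact search in
sense then antisense orientation (simulated RNA reads are error-free).

### Segregation

Counts are restricted to genotyped individuals of known affection status;
perfect co-segregation requires every genotyped affected individual to
carry the variant, no genotyped unaffected carrier, and at least one
genotyped affected individual. No LOD score is computed — the underlying
observation is a count, and inventing a penetrance model would add nothing
the fixture can test. The transmission check flags carrier children whose
parents are both genotyped non-carriers.

## Problem sizes and determinism

The default end-to-end run uses the full 2.6 Mb region at 20× case and
control coverage (~380,000 and ~347,000 pairs) and completes in well under
a minute on one CPU; the test suite reuses a single session-wide run and
adds reduced-scale property checks (100 kb specificity cohorts across ten
seeds, 60 kb concordance checks, toy graphs for the walk oracle). The
acceptance script runs the same full-scale study with error-free reads,
matching the condition under which the insertion consensus is defined to
be exact.

## Known limitations

* The aligner handles substitutions only; indel-bearing or low-complexity
  real data would need a production mapper behind the same interfaces.
* Discordant-pair counts depend on the insert-size model; libraries with
  heavy-tailed inserts would need a robust concordance window.
* The splice PWMs are deliberately high-specificity stand-ins; they are
  not a trained model, and chance near-consensus sites can still appear in
  random sequence (~1 donor per ~100 kb at threshold 0.97 — harmless
  unless inside a transcribed exon, ~2% of runs).
* Reconstruction assumes a single reference region and one intact
  homolog; translocations and mosaic states are out of scope.
* The pedigree fixture preserves printed counts, not the real topology;
  transmission statistics beyond counts are illustrative.
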