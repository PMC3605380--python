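# Methods

This note documents the models and procedures behind `plastidkit`, the
defaults that matter, what the synthetic data does and does not emulate,
and the design choices made where the design was genuinely open.

## The assembly problem

A plastome is a circular molecule with the canonical quadripartite layout
LSC–IRb–SSC–IRa (IRa = reverse complement of IRb; the package linearizes
at LSC base 1, so the IRa/LSC junction is the circular origin). Two facts
shape the whole workflow:

* **The IR collapses under short-read de novo assembly.** The two copies
  share every canonical k-mer, so a de Bruijn assembler emits the repeat
  once, flanked by branch points at the four junctions. A correct
  assembler therefore produces roughly three plastome unitigs (LSC-like,
  SSC-like, one IR), not a closed genome.
* **A single linear reference cannot order both IR copies.** Mapping
  contigs to one linear reference places the collapsed IR once. Splitting
  the reference into two overlapping halves — half A: base 1 through IRb
  into the SSC; half B: from just inside IRb to the end of IRa — lets the
  same IR contig be used in both copies, one per half.

## Synthetic data generator (`synthsim`)

The generator defines the study conditions every test and the acceptance
script run under:

| parameter | default | rationale |
|---|---|---|
| read length | 100 bp | paired-end short-read standard |
| insert size | 460 ± 50 bp | library geometry; SD chosen as a typical short-insert spread |
| per-base error | 0 (tests: 0.002) | uniform substitution model |
| chloroplast fraction | 0.05 | plastome reads as a small minority of a total-DNA library |
| pool size | 4 equimolar haplotypes | singleton variant ⇒ exactly 25% pooled frequency |
| scaffold-reference divergence | 10% substitutions + 0.5% short (1–10 bp) indels | emulates a cross-family relative qualitatively; no measured figure exists, so this stays configurable |

Fragments start uniformly on the circle (pairs may span the origin), come
off either strand, and mate 2 is the reverse complement of the fragment
end; qualities are constant at the Phred score implied by the error rate.
Everything is deterministic per seed.

One deliberate construction detail: the first/last bases of both
single-copy regions are constrained so the planted IR is *maximal* — a
chance complementary base at a junction would otherwise let the detected
repeat extend one base into a single-copy region and shift every junction
coordinate by luck of the draw.

Not emulated: GC- or position-dependent error profiles, indel sequencing
errors, organellar heteroplasmy, nuclear copies of plastid DNA (NUPTs),
and non-uniform fragment start positions. Passing tests therefore show
that the *algorithms* are correct under clean but realistically structured
data; they do not certify performance on libraries whose artifacts violate
these assumptions.

Planted variants are placed in single-copy regions at least a read length
away from IR junctions. A variant planted in only one IR copy would be
diluted toward half its nominal frequency, because reads from the repeat
match both copies and are assigned at random; single-copy placement
mirrors where verified chloroplast SNPs live in practice.

## Read preparation (`readprep`)

Trimming is the modified-Mott running sum: each base scores
`p_limit − p_err(base)` and the retained read is the maximal-sum
contiguous segment (ties: leftmost start, then longest), followed by a
50 bp minimum-length filter. The quality limit (default 0.05) is snapped
to its integer Phred equivalent (13, via `floor(−10·log₁₀ p)`), so a base
at exactly Q13 scores zero rather than infinitesimally negative — this
makes the stated equivalence "limit 0.05 ≡ Phred 13" hold exactly (an
all-Q13 read is retained in full). Whether the original platform applied
a whole-read average or a running sum is not documented; the running sum
is the documented behaviour of the trimming tool this reproduces, and
users should be aware of the choice.

Subsampling keeps every *n*-th pair starting at index 0 — deterministic,
no RNG — which scales coverage by 1/n for half/quarter/eighth datasets.

## Assembly (`assembler`)

Canonical-k-mer de Bruijn graph; odd k only (no self-reverse-complement
k-mers); unitigs are maximal non-branching paths, reported in their
lexicographically smaller orientation, sorted by length. Cleaning:

* **Coverage cutoff**: k-mers seen once are dropped when the mean count of
  *non-singleton* k-mers exceeds 10. Judging depth on non-singletons
  matters because sequencing errors and non-plastome background contribute
  an enormous singleton cloud that would otherwise mask genuinely deep
  coverage.
* **Tips** shorter than 2k whose junction has a competing branch are
  removed; **bubbles** (unitig pairs sharing both end junctions) resolve
  to the deeper branch.

"Two independent assemblies" are realized as one engine at two k values
(defaults 55 and 71 in the pipeline); the overlap between the two contig
sets provides the mutual confirmation that two different assemblers would.
Paired-end distances are not used for repeat resolution — pairs only ever
matter downstream — which is a known fidelity gap versus assemblers that
thread pairs through the graph.

Occasionally a low-coverage junction (a dropped k-mer at a branch) lets a
unitig "hop through the mirror" — e.g. continue from IRb directly into
the reverse complement of the SSC, which is a perfectly real genomic
sequence read in the other orientation. The scaffolder is built to
tolerate such junction-hopping contigs (see below).

## Chloroplast binning (`cpbin`)

Exact-word seeding (word 11) on both strands, ungapped X-drop extension
(match +1, mismatch −2, X-drop 20), Karlin–Altschul statistics:
λ is the positive root of Σ pᵢpⱼe^(λsᵢⱼ) = 1 and K comes from the lattice
renewal series; for (+1, −2) this yields (1.33, 0.621), matching the
published ungapped nucleotide values. E = K·m·n·e^(−λS), computed in log
space; the "E-value of zero" gate keeps contigs with E ≤ 1e-180
(configurable).

Because the extension is ungapped, a diverged-but-homologous contig
fragments into co-linear segments at every indel. Segments on the same
strand are therefore *chained* (gaps ≤ 100 bp in both coordinates, one
join penalty of 20 per link — more than any chance seed hit contributes,
so unrelated hits cannot stack) and the summed chain score feeds the
E-value. This is the ungapped analogue of sum statistics; a gapped search
reaches the same verdict by a different route.

Detection floor: a perfect 300 bp match scores 300, giving E ≈ 1e-167 —
above the 1e-180 gate. The gate is intentionally conservative (it is a
*binary* contamination filter, not a sensitivity instrument); in practice
contigs from ~600 bp up against a ≤15%-diverged relative pass cleanly,
and short true fragments can always be rescued by loosening the threshold.

## Scaffolding (`scaffolder`)

Coordinates are 1-based inclusive throughout; the reference never
contributes a consensus base.

**Placement.** Contigs are located by chunk voting: 250 bp chunks are
infix-aligned (edit distance) against each half, each best location votes
for a projected start of the whole oriented contig, and each candidate
window is refined with a geometry-matched slice alignment plus an anchored
gapped boundary extension. Slices are matched in size deliberately:
edit-distance paths will smear a long unmatched overhang across the true
alignment as cheap mismatches, so overhanging junk is kept to ≤30 bp per
clipped boundary. Placements need ≥70% identity over ≥100 aligned bases
(the 0.7 default reflects a distant reference; configurable). A contig
overlapping the IR legitimately places on both halves, and partial
placements (junction spanners, the IRb remnant of half B) are first-class.

**Per-half consensus.** The reference orders and orients; splicing then
happens in *contig space*, where agreeing contigs are exactly identical:

1. placements are laid out by reference start;
2. each next contig is joined by an exact suffix–prefix splice when one
   exists (it always does for agreeing contigs), else by a tolerant
   alignment splice; a contig that should overlap but cannot be spliced is
   dropped rather than concatenated (misplacement is more likely than a
   genuine gap);
3. unaligned contig tails are never trusted blindly — the previous
   contig's clipped tail is held *pending* and admitted exactly as far as
   the next contig's splice confirms it (this recovers junction bases that
   failed to align against the diverged reference, while excluding
   junction-hopping continuations);
4. every placed contig casts per-column votes over the stretch it covers;
   the final half sequence is the column-majority rebuild — ties emit the
   lexicographically smallest base and are logged as ambiguous, a '−'
   majority drops the column, and majority insertions are spliced in;
5. disjoint neighbours are concatenated with the position recorded as a
   zero-length gap.

An earlier design voted in reference-column space; it was abandoned
because alignment-path jitter against an indel-bearing diverged reference
put equally-optimal gap placements in different columns for different
contigs, corrupting junction regions. Contig-space stitching removes the
reference from the comparison entirely.

**Merge and circular closure.** Half B's head (IRb remnant + SSC context,
which occurs exactly once in half A) anchors the junction; the merged
sequence keeps each overlap base once. The circular origin is then
repaired from the contig that spans it: that contig's clipped prefix is
the IRa tail, the far side of the origin, and exact 32-mer anchors on both
sides let its own bases replace the junction stretch (alignment paths are
deliberately *not* trusted here, for the smear reason above). Finally the
sequence is rotation-normalized so IRa ends at the last base, and the
quadripartite annotation is re-derived by `detect_ir` — maximal
reverse-complement interval pair via word seeding against the reverse
complement and ungapped maximal extension, verified against a brute-force
oracle in the tests. IRa/IRb disagreements up to 0.1% would be logged
(`ir_mismatches`); on clean data the count is zero.

## Pooled SNP detection (`popsnp`)

Reads are placed by best edit distance over both strands; all equal-best
locations are found, so an IR-internal read reports two sites and is
assigned uniformly at random (seeded) under `match_mode="random"`, or
discarded under `"unique"`. Acceptance uses the optimized stringency:
aligned_length/read_length ≥ 0.8 (length fraction) and
matches/aligned_length ≥ 0.9 (similarity); the earlier 0.8/0.9-swapped
combination is available by passing those values. Pileups count A/C/G/T
and deletion per column; bases below Q13 (the trim limit) do not vote.
Frequencies are raw count fractions with no quality weighting.

A SNP is called where depth ≥ `min_cov` and a non-reference base reaches
`count/depth ≥ mvf`; deletions are never called. Defaults mvf 0.2,
min_cov 10. Statistical note: at ~200× a 25%-frequency singleton clears
the 20% threshold with ≈95% probability per site (the threshold sits
about 1.6 binomial SD below the mean), so across ten planted sites a run
recovers 8–10 of them depending on the seed, always with zero false calls
at 0.2% error — the acceptance script reports whatever it measures.
Fixed differences between pools use a 99% consistency cutoff
(configurable; no canonical figure exists). Indels are out of scope for
calling.

## Chlorotype networks (`haplonet`)

Individuals with identical allele strings group into chlorotypes (first
occurrence order; individuals with missing alleles are dropped; a locus
blacklist supports excluding homopolymer-adjacent SNPs upstream). The
median-joining network uses ε-relaxed minimum-spanning links (a link is
feasible when its weight is within ε of the smallest weight connecting
the two components), quasi-medians (per-locus majority of connected
triplets, ties spawning all variants) added greedily whenever they
strictly shorten the minimum spanning length, iterated to a fixpoint,
and median vectors of degree ≤ 1 pruned. ε defaults to 0, under which
tree-like data yields exactly the minimum spanning tree. The original
algorithm's maximum-parsimony cleanup pass is not implemented; on small
ε and low-homoplasy data it makes no difference, which is the regime
chloroplast SNP sets occupy.

## Pipeline (`pipeline`)

`run_all` executes trim → dual-k assembly → bin → two-half scaffold →
map → call → compare, persists every intermediate as plain standard
formats (FASTA, GFF3, BED, TSV, SAM, VCF, JSON), embeds the config digest
and seed as provenance, aborts with the failing stage's name, and is
byte-deterministic under a fixed config+seed. `subsample_experiment`
re-runs assembly/binning/mapping on every-n-th subsamples and reports
coverage, a full-genome-tiling flag, and SNP recovery against truth.

## Problem sizes

The test suite and acceptance script use 8–11.5 kb quadripartite genomes
(e.g. LSC 7000 / SSC 1500 / IR 1500) at the study's coverages — 50× for
assembly experiments, 214×/208× for the two-pool SNP experiment — which
preserves every structural feature of the full-size problem (collapsed
IR, four junctions, circular origin, minority plastome fraction) at
desk-scale cost. Full-length genomes (159,514 bp and 160,129 bp region
geometries) are exercised where only structure and arithmetic matter
(construction, IR detection, reference splitting).

## Known limitations

* Ungapped binning cannot rescue very short (<~500 bp) diverged fragments
  at the default E-gate; loosen `evalue_zero` if they matter.
* Read mapping is edit-distance-based with post-hoc local trimming rather
  than a scored local aligner; reads spanning the circular origin of a
  linear consensus are rejected rather than split-mapped, costing a thin
  coverage dip at the ends.
* The SSC orientation isomer (flip-flop) is not resolved; the consensus
  reports the orientation the scaffold reference implies.
* Gap filling by local reassembly, indel calling, and base-quality
  recalibration are out of scope.
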