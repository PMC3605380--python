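# plastidkit

Assemble a complete chloroplast genome from ordinary whole-genome shotgun
short reads — no chloroplast isolation, no close reference — then detect
SNPs in pooled samples and summarize them as chlorotype networks.

Chloroplast (plastid) genomes are circular, typically ~120–160 kb, and
quadripartite: a large single-copy region (LSC), inverted repeat b (IRb),
a small single-copy region (SSC), and inverted repeat a (IRa), where
IRa = reverse-complement(IRb). The two identical-but-inverted repeats
defeat naive short-read assembly (they collapse into one contig) and
defeat naive reference mapping against a single linear reference (only one
copy can be placed). Yet chloroplast DNA is abundant enough that ~5% of a
total-DNA shotgun library is plastome at deep effective coverage, so the
genome is recoverable *in silico* with the right workflow. `plastidkit`
implements that workflow end to end:

1. **Trim** reads (modified-Mott running sum at error-probability limit
   0.05 ≡ Phred 13, minimum length 50 bp).
2. **Assemble de novo twice** — one de Bruijn unitig engine run at two
   k-mer sizes plays the role of two independent assemblers; overlap
   between the two contig sets confirms the assembly. External contig
   FASTA can be dropped in instead.
3. **Bin contigs** as chloroplast by seed-and-extend local alignment
   against a plastome database, keeping contigs whose Karlin–Altschul
   expectation underflows ("E-value of zero", operationally E ≤ 1e-180);
   `E = K·m·n·e^(−λS)` with (λ, K) computed for the chosen score scheme
   (λ solves Σᵢⱼ pᵢpⱼe^(λsᵢⱼ) = 1).
4. **Scaffold against a distant reference split into two overlapping
   halves** — half A from base 1 across IRb into the SSC, half B from just
   inside IRb to the end of IRa — so contigs covering the IR are used in
   *both* copies. Per half, placed contigs are stitched with per-column
   vote-majority conflict resolution (the reference never contributes a
   base); the halves are merged across their overlap, the circular origin
   is repaired from the contig that spans it, and the quadripartite
   structure and four junctions are re-derived de novo.
5. **Map pooled reads back** (similarity ≥ 0.9, length fraction ≥ 0.8,
   equal-best repeat hits placed at random) and **call SNPs** with a
   minimum variant frequency (mvf) and minimum coverage. With pools of
   four equimolar individuals a singleton variant sits near 25%
   frequency, so mvf 20% with coverage ≥ 10 retrieves real pool variants
   while suppressing error-driven calls.
6. **Build chlorotypes** (per-individual concatenated SNP alleles) and a
   **median-joining network** (ε-relaxed minimum-spanning links plus
   quasi-median vectors that shorten the network).

A built-in simulator generates everything needed to exercise the pipeline
without downloads: random quadripartite genomes, diverged relatives (to
stand in for a distant scaffold reference), equimolar pools with planted
variants, and paired-end reads (100 bp, ~460 bp inserts, optional uniform
error and non-plastome background).

## Worked example

```python
import plastidkit as pk
from plastidkit import assembler

# an 11.5 kb quadripartite genome: LSC 7000, IR 1500, SSC 1500
genome = pk.make_genome(7000, 1500, 1500, seed=1)
# a 10%-diverged relative plays the distant scaffold reference
reference = pk.diverge(genome, sub_rate=0.10, indel_rate=0.005, seed=101)

cfg = pk.SimConfig(n_pairs=2875, seed=201, cp_fraction=1.0)  # ~50x
pairs = pk.simulate_reads([pk.Haplotype(base_genome=genome)], cfg)
reads = [r for p in pairs for r in p]

contigs = []
for k in (55, 71):                       # "two independent assemblies"
    contigs += pk.assemble(reads, k, min_contig_len=200)
stats = assembler.assembly_stats([c for c in contigs if c.k == 55])
print(f"k=55: {stats.n_contigs} contigs, N50 {stats.n50}, longest {stats.max_len}")

kept, hits = pk.bin_contigs(contigs, [("relative", reference.sequence)])
print(f"{len(kept)}/{len(contigs)} contigs with an E-value of zero")

pair = pk.split_reference(reference, ssc_overhang=700, overlap=700)
placements = pk.place_contigs(kept, pair)
consensus = pk.consensus_and_merge(placements, kept, pair, min_ir_len=200)
print(f"consensus: {len(consensus.sequence)} bp,",
      "identical to truth:", consensus.sequence == genome.sequence)
print("regions:", consensus.annotation.region_lengths())
```

prints

```
k=55: 3 contigs, N50 7108, longest 7108
6/6 contigs with an E-value of zero
consensus: 11500 bp, identical to truth: True
regions: {'LSC': 7000, 'IRb': 1500, 'SSC': 1500, 'IRa': 1500}
```

Three contigs per k is the expected shape: the LSC, the SSC (each with
short inverted-repeat overhangs) and one *collapsed* inverted repeat. The
two-half scaffold then duplicates the IR, the merged consensus matches the
generating genome base for base, and the four junctions — J(LSC,IRb) at
7000/7001 through J(IRa,LSC) at 11500/1, the circular origin — are
recovered exactly.

The same stages are exposed as a CLI for file-based work
(`plastidkit simulate | trim | subsample | assemble | bin | scaffold |
map | call | network | run | subsample-experiment`), reading and writing
FASTA, paired FASTQ, TSV, GFF3/BED, SAM and VCF; `run` accepts a YAML
config with any pipeline parameter.

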