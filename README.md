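# mitograph

**Plant mitochondrial genome assembly from low-coverage long accurate reads:
from whole-genome sequencing data to a simplified organelle assembly graph and
the complete set of repeat-mediated circular conformations.**

Plant mitogenomes are hard to assemble: they recombine across repeats,
integrate plastid DNA (MTPT) and horizontally transferred segments, and exist
*in vivo* as a population of alternative arrangements rather than one master
circle. Conventional assemblers either break contigs at repeat-mediated
branches or keep only the best-supported path, losing every alternative
conformation. `mitograph` instead keeps every branch, separates organelle
from nuclear sequence by read depth, and enumerates **all** arrangements the
final graph supports.

It is aimed at researchers assembling plant organelle genomes from
whole-genome HiFi-grade reads without mitochondrial DNA isolation, and ships
a seeded synthetic-data generator so the entire workflow is testable without
any external downloads.

## Method

1. **Read preparation** — optional subsampling to a base budget; reads
   longer than 30 kb are cut into 20 kb pieces.
2. **Contig graph** — a compacted de Bruijn graph over canonical *k*-mers
   (*k* = 31, counts ≥ 2). Unitigs become contigs with depth = mean *k*-mer
   multiplicity; a link joins two oriented contig ends wherever they abut
   through a (k−1)-mer junction, with support = reads spanning the junction.
   Repeat-mediated branches are preserved, never resolved. Junction overlaps
   are split half-and-half so contigs abut bluntly: a walk's sequence is the
   plain concatenation of its oriented contigs (GFA links carry `0M`).
3. **Seed selection** — contigs are screened against a database of conserved
   mitochondrial protein-coding genes (the canonical 24-gene set
   *atp1*…*nad9*; any FASTA is accepted). Seeds must satisfy contig length
   > 500 bp, identity > 85 % and gene coverage > 90 %.
4. **Recruitment** — breadth-first search from the seeds keeps everything
   reachable; nothing is filtered at this stage.
5. **Simplification** — iterated to a fixpoint: drop contigs at ≤ 2× the
   nuclear background depth (readsize/genomesize); drop plastid-class
   contigs (> 3× the mitochondrial median) whose neighbours are all
   plastid-class, reserving MTPT-like bridges that touch mito-class contigs;
   drop links with support below one fifth of the shallower end contig (or
   below the absolute `--minLink` floor); drop isolated non-circular tips.
   Seed contigs are exempt from every depth gate.
6. **Conformations** — contig copy numbers come from depth ratios refined by
   link degrees; "all possible conformations" is formalised as the set of
   **cycle covers** of the copy-number multigraph: every contig used exactly
   `copies` times, all adjacencies realised by links, strand-consistent.
   A direct repeat yields the master circle plus the two-subcircle
   decomposition; an inverted repeat yields two single-circle isomers. Each
   conformation is exported as FASTA (one record per circle) and GFA.

## Worked example

Generate the default planted fixture (60 kb mitogenome with one 2 kb direct
repeat and a 1 kb plastid insertion, 30 kb plastome at 100×, ten 50 kb
nuclear sequences at 2×) and assemble it:

```bash
mitograph simulate --seed 11 --out fixture
# 434 reads written to fixture

mitograph autoMito --reads fixture/reads.fasta --pcg-db fixture/pcg_db.fasta \
    --genomesize 500000 --seed 11 --out asm
# 2 conformation(s); outputs in asm
```

`asm/conformation_summary.tsv` shows both arrangements the direct repeat
supports — the 60 kb master circle and its decomposition into two subgenomic
circles produced by recombination across the repeat:

```
conformation  cycle    length  circular
1             cycle_1  60000   True
2             cycle_1  30000   True
2             cycle_2  30000   True
```

`conformation_1.fasta` holds the master circle
(`>conformation_1_cycle_1 length=60000 circular=true`), which matches the
planted mitogenome base for base up to rotation and strand. The run report
records per-stage tallies — 30 assembled contigs recruit down to a 5-contig
master graph (three single-copy arcs, the repeat at copy number 2, and the
retained MTPT contig at stacked mito+plastid depth), with the one pure-plastid
contig removed:

```
seed_contigs: 3   recruited_contigs: 6   plastid_removed: 1   master_contigs: 5
copy_numbers: {ctg03: 1, ctg09: 1, ctg20: 1, ctg27: 2, ctg30: 1}
```

`graphBuild` mode enters the same pipeline from an existing contig graph
(`PMATContigGraph.txt` dialect + contig FASTA) with manual or database-derived
seeds, and `mitograph titrate` reruns the pipeline on nested subsamples
(default tiers 200 Mb / 500 Mb / 1 Gb) to find the minimal data volume that
still yields a circularised mitogenome.

## Contig-table dialect

External graphs can be converted to the documented exchange format: `C`
rows `C <id> <length> <depth>` and `L` rows
`L <id1> <head|tail> <id2> <head|tail> <support>` (tab separated), with
contig sequences in a companion FASTA.

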