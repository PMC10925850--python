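# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitograph`, and what the synthetic test bed does and does not show
about real data.

## Assembly model

The contig-graph stage is a compacted de Bruijn graph over canonical k-mers.
The design goal is not a general-purpose assembler but the specific contract
the downstream organelle workflow needs: *every repeat-mediated branching
structure is preserved, and per-contig read depths are recorded faithfully*,
because branch topology plus depth is what separates and disentangles the
organelle genomes. With high-accuracy long reads (HiFi-grade, or corrected
CLR/ONT) and the read-fragmentation step, unitigs of a k-mer graph satisfy
this contract: substitution errors are removed by the k-mer count floor, and
every genuine branch survives compaction because compaction merges only
junctions with unique extensions on both sides.

Conventions and tunables:

- **k = 31** (odd, 15–31). Odd k rules out palindromic k-mers, which would
  otherwise make strand canonicalisation ambiguous, and lets the (k−1)-mer
  junction overlap be split symmetrically. The upper bound comes from packing
  a (k+1)-mer into 64 bits, 2 bits per base, for vectorised counting.
- **min_kmer_count = 2** removes singleton noise k-mers. At the 20×
  mitochondrial depths the workflow targets, the chance of a true k-mer
  appearing only once is negligible; at ≤ 5× it is the dominant cause of
  broken circles (exploited deliberately in the titration experiment).
- **Blunt joins.** A unitig's first/last (k−1) bases overlap its neighbours'
  across each junction. Every contig end that terminates at a junction is
  trimmed by (k−1)/2 bases, assigning half of the shared junction sequence to
  each side. Consequences: an exported walk is the plain concatenation of
  oriented contig sequences (GFA `L` lines carry `0M`), the length of a
  circular walk is exactly the sum of its oriented contig lengths, and a
  correct cycle cover reconstructs the underlying circle base-for-base.
  Contig ends without any link (dead ends) are not trimmed.
- **Link support** is the number of read occurrences of the junction-spanning
  (k+1)-mer (canonical, counted over all reads). A read crossing the same
  junction twice would be counted twice; with read lengths far below genome
  sizes this distinction is immaterial.
- **Determinism.** Contigs are named in sorted order of their lexicographically
  minimal k-mer; all traversals use sorted tie-breaks; identical inputs give
  identical graphs, byte for byte on disk.
- **Stored strand** of a contig is the lexicographically smaller of the
  sequence and its reverse complement.

## Seed selection

Seed contigs are identified by homology to conserved mitochondrial
protein-coding genes (PCGs). The shipped manifest is the canonical 24-gene
core set (atp1, atp4, atp6, atp8, atp9, ccmB, ccmC, ccmFc, ccmFn, cob, cox1,
cox2, cox3, matR, mttB, nad1–nad7, nad4L, nad9); gene sequences themselves
are user-supplied (or synthetic in tests) — the package does not redistribute
database content. In plastome mode (`--type pt`) a plastid gene manifest is
used instead and the plastid-removal stage is skipped.

The search is a hermetic seed-and-extend aligner: exact 15-mer anchors on
both strands, diagonal clustering (band 100 bp), then a global alignment of
the clustered span scored with edlib. Identity is matches over alignment
columns; coverage is the aligned span over the *gene* length — gene-side
coverage was chosen because contigs are typically much longer than a single
gene, making contig-side coverage > 90 % unsatisfiable. Hits are reported at
≥ 50 % identity over ≥ 100 columns; the seed gates themselves are strict
inequalities: length > 500 bp, identity > 85 %, coverage > 90 %.

## Depth model and simplification

Two landmarks drive classification: the nuclear background depth, estimated
as `readsize / genomesize`, and the mitochondrial median, the median depth of
seed contigs. Contigs at ≤ `nuclear_mult` (default 2) × nuclear background
are nuclear-class; contigs above `plastid_mult` (default 3) × the mito median
are plastid-class; the band between is mitochondrial. The plastid multiplier
is a configurable design choice — the underlying biology only guarantees
"plastid depth well above mitochondrial"; 3× separates cleanly whenever
plastid:mito depth exceeds about 4:1, which matches observed organelle depth
ratios across land plants.

The depth gate *keeps* contigs above twice the nuclear background and removes
those at or below it. Removing the low-depth side is the only direction
consistent with the tool's purpose (organelle contigs always sit above
nuclear background in whole-genome data) and with the observed depth
separation of the three genomes; the multiplier is exposed as
`--nuclear-mult`.

Plastid resolution evaluates classes simultaneously: a plastid-class contig
is removed only when every linked neighbour is also plastid-class. A
plastid-class contig touching a mito-class neighbour is *reserved* as a
candidate mitochondrial plastid insertion (MTPT): a genuine MTPT segment
receives reads from both organelles, so its depth is the *sum* of the two
and always clears the plastid gate, while its flanks in the mitogenome are
ordinary mito-depth contigs. The reserved set is carried through to the
conformation stage and exempted from the median-spread noise gate there for
the same reason.

Weak links are pruned when support falls below `weak_ratio` (default 1/5) of
the shallower end contig's depth — the minimum is the conservative reading of
"both ends" — or below the absolute `--minLink` floor. Tip removal follows
the literal definition: a tip is a contig linked to nothing and not circular
via a self-link; classic dead-end clipping (removing contigs attached by only
one end) is available behind `trim_dead_ends` but off by default, since
aggressive clipping can delete genuine linear fragments of incomplete
assemblies. The full pass (nuclear → plastid → weak links → tips) iterates to
a fixpoint and is idempotent; seed contigs are exempt from all depth gates.

## Copy numbers and conformations

The single-copy baseline is the median depth of gene-bearing contigs after a
spread-4 noise gate (non-hit, non-reserved contigs more than 4-fold from the
median are removed; the spread is configurable). Copy numbers start from
`max(1, round(depth / baseline))` and are then refined by connections:

- a contig whose link degree on one side exceeds the depth estimate is raised
  to that degree (depth underestimates repeats whose copies differ little);
- a contig *without* a self-link is assigned its busiest-end link degree
  outright — such a contig cannot be entered more ways than it has distinct
  links, and this cap is what keeps a depth-stacked MTPT contig (mito +
  plastid coverage, ~6× baseline) at its true single mitochondrial copy;
- self-linked contigs (tandem-repeat topology) keep the depth estimate, since
  a tandem array genuinely revisits the same link.

The cost of the cap is that a whole-genome-doubling-like case (two copies of
a two-contig circle with no extra links) collapses to the smaller circle;
that case is inherently ambiguous from depth and topology alone and the
conservative (smaller) solution is preferred.

"All possible conformations" is formalised as the set of **strand-consistent
cycle covers** of the copy-number multigraph. This is the only reading that
simultaneously yields the master circle *and* the subgenomic-circle
alternative of a direct repeat, and the two isomers of an inverted repeat.
Enumeration is exhaustive depth-first search starting from the longest
single-copy contig (ties by id); a closed cycle either completes the cover or
recurses into a new cycle started at the smallest remaining contig. Cycles
are circular DNA molecules, so each cycle is canonicalised up to rotation and
reverse complement and a conformation is an unordered multiset of cycles;
deduplication and output ordering (fewest cycles first, then canonical form)
are exact. Enumeration truncates at `max_out` (default 100) distinct
conformations or a state budget, with a logged warning — repeat-dense graphs
can be combinatorially explosive and are better disentangled manually from
the exported master GFA. If no cycle cover exists the simplified graph itself
is exported conservatively, with contigs flagged circular only when
self-linked.

An independent test oracle enumerates cycle covers a completely different
way — perfect matchings of contig-copy end slots constrained by links,
decomposed into closed walks — and the two agree exactly on hundreds of
random multigraphs.

## Synthetic data generator

The generator emulates the mixture a whole-genome long-read run presents to
an organelle assembler. Defaults define the reference study conditions:
a 60 kb circular mitogenome carrying one 2 kb repeat pair (direct by default,
two exact copies), four 800 bp conserved genes and a 1 kb plastid-derived
insertion whose sequence occurs *exactly* in both organelles; a 30 kb
circular plastome at 100×; ten 50 kb linear nuclear sequences at 2×. Reads
are 12 ± 3 kb (min 1 kb), sampled across the origin for circular sources,
with substitution-only errors (default 0, at most 2 %). Structural draws and
error draws use separate seeded streams so error rate can vary without
changing read placement. The nuclear background is simulated at 2× rather
than 1× so the 2× nuclear gate is exercised on both sides.

What passing tests show: branch-preserving assembly, depth-based separation,
MTPT reservation and exhaustive conformation enumeration work end to end,
and the exported master circle reconstructs the planted genome exactly.
What they do not show: robustness to indel-rich reads (substitution-only
errors keep the de Bruijn stage honest; indels are out of scope), diverged
repeat copies, chimeric reads, or real MTPTs that have mutated since
transfer (an exact shared segment is the hardest case for depth logic but
the easiest for the graph). At these toy proportions organelle reads
dominate the read set, so `readsize/genomesize` overestimates the nuclear
background noticeably (organelles are a negligible fraction of a real run);
seed protection makes the pipeline insensitive to this, but per-contig
*class labels* in the report can name low-depth mito arcs "nuclear" at toy
scale.

## Titration experiment

`run_titrate` subsamples the read set to nested tiers (defaults 200 Mb /
500 Mb / 1 Gb), reruns the full pipeline per tier with a tier-derived seed,
and reports contig count, assembled bases, whether the graph circularised
(≥ 1 complete cycle cover), and reference k-mer coverage when a reference is
given. A tier exceeding the available data runs on everything, with a note.

The test fixture for the titration is deliberately sized so that the 2 Mb
tier fails and the 5 Mb tier succeeds: five 50 kb nuclear sequences, mito at
25×, 3 kb reads (total ≈ 5.0 Mb, so 2 Mb ≈ 10× and 5 Mb ≈ 25× mitochondrial
coverage), run with `--minLink 11`. At 10× the weakest of the six
mitochondrial junction links almost surely falls under the absolute support
floor (link support ≈ coverage, and the minimum of six ~Poisson(10) draws is
nearly always < 11), breaking circularity, while at 25× all junctions clear
it comfortably. Both outcomes are stochastic at the margins — the minimum
link support has noticeable dispersion — so a small fraction of random
fixture seeds can flip either tier; the shipped tests pin a fixture seed, and
the pipeline is fully deterministic given the seed.

## Numerical and degenerate-input conventions

- Copy-number rounding is `int(x + 0.5)` (half away from zero), not banker's
  rounding.
- Median depths use the standard median (mean of central pair for even
  counts).
- Subsampling sorts reads by id before the seeded shuffle, so selection is
  independent of input order; the last selected read may overshoot the base
  target; a target at or above the total returns the input unchanged.
- Fragmentation conserves bases exactly; a trailing piece shorter than
  `min_tail` (default 1 kb) is appended to the previous piece. The 30 kb
  threshold is strict (`> 30 kb` is fragmented, 30 kb is not).
- Empty read sets, empty gene databases, zero-byte sequence files, links to
  unknown contigs and S-lines without sequence are explicit errors; a
  no-seed outcome directs the user to graphBuild-mode manual seeding.
- All RNGs are `numpy.random.default_rng` seeded from the run seed; no
  output embeds timestamps, so identical seeds give byte-identical outputs.

## Known limitations

- The assembler stands in for the branch-preserving overlap assembler used
  upstream in the original workflow; it requires high-accuracy reads and
  k ≤ 31. CLR/ONT error correction is out of scope (reads are expected
  pre-corrected).
- Alignment-based seed search is anchor-driven: genes diverged beyond ~50 %
  identity or split across many short contigs will not anchor.
- Conformation enumeration is exponential in repeat multiplicity by nature;
  the output cap plus the exported master GFA are the escape hatch.
- The titration's circularisation verdict is topological (a complete cycle
  cover exists); it does not re-map reads to validate junctions.
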