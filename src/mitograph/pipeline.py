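"""End-to-end assembly workflows.

``run_automito`` is the one-step path: read preparation, contig-graph
construction, seed selection from the conserved-gene database, BFS
recruitment, depth-based simplification, and conformation export.
``run_graphbuild`` enters the same pipeline after the assembly stage from an
externally supplied contig table + FASTA, with seeds given explicitly or
derived from the gene database.  ``run_titrate`` reruns the full pipeline on
nested subsamples of the input to find the minimal data volume that still
yields a circularised mitogenome.

Every output is deterministic for a fixed seed: no timestamps, sorted
records, seeded subsampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import assembly, conform, io, readprep, seeds, simplify
from .core import AssemblyGraph, MitographError, NoSeedsError, SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_TITRATION_TIERS = (200_000_000, 500_000_000, 1_000_000_000)


@dataclass
class RunConfig:
    """Everything a run needs; mirrored verbatim into the run report."""

    reads: Optional[str] = None
    contig_table: Optional[str] = None
    contig_fasta: Optional[str] = None
    pcg_db: Optional[str] = None
    seed_ids: Optional[List[str]] = None
    genome_type: str = "mt"            # mt | pt
    genomesize: Optional[float] = None
    readsize: Optional[float] = None
    sample_bases: Optional[int] = None
    seed: int = 0
    outdir: str = "mitograph_out"
    # module parameter blocks
    break_threshold: int = 30_000
    break_step: int = 20_000
    break_min_tail: int = 1_000
    k: int = 31
    min_kmer_count: int = 2
    min_seed_len: int = 500
    min_seed_identity: float = 85.0
    min_seed_coverage: float = 90.0
    nuclear_mult: float = 2.0
    plastid_mult: float = 3.0
    weak_ratio: float = 0.2
    min_link: int = 0
    trim_dead_ends: bool = False
    spread: float = 4.0
    max_conformations: int = 100
    titration_tiers: List[int] = field(
        default_factory=lambda: list(DEFAULT_TITRATION_TIERS)
    )
    reference: Optional[str] = None

    def params_dict(self) -> Dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class RunResult:
    """Handles on every stage product, for tests and reporting."""

    outdir: Path
    raw_graph: AssemblyGraph
    recruited_graph: AssemblyGraph
    master_graph: AssemblyGraph
    target_graph: Optional[AssemblyGraph]
    conformations: List[conform.Conformation]
    seeds: Set[str]
    reserved: Set[str]
    classes: Dict[str, str]
    copy_numbers: Optional[conform.CopyNumberTable]
    report: Dict

    @property
    def circularized(self) -> bool:
        return bool(self.conformations)

    def master_sequences(self) -> List[str]:
        """Cycle sequences of the first (master-first ordered) conformation."""
        if not self.conformations:
            return []
        g = self.target_graph if self.target_graph is not None else self.master_graph
        return [conform.cycle_sequence(c, g) for c in self.conformations[0].cycles]


def _prepare_reads(cfg: RunConfig) -> Tuple[List[SeqRecord], int]:
    reads = io.read_sequences(cfg.reads)
    total = sum(len(r) for r in reads)
    if cfg.sample_bases:
        reads = readprep.subsample_reads(
            reads, readprep.SamplingSpec(cfg.sample_bases, cfg.seed)
        )
    frag = readprep.FragmentationSpec(
        cfg.break_threshold, cfg.break_step, cfg.break_min_tail
    )
    reads = readprep.fragment_long_reads(reads, frag)
    sampled = sum(len(r) for r in reads)
    logger.info("prepared %d reads, %d bases (of %d input)", len(reads), sampled, total)
    return reads, sampled


def _select_seeds(
    cfg: RunConfig, graph: AssemblyGraph
) -> Tuple[Set[str], List[seeds.SeedHit]]:
    if cfg.seed_ids:
        missing = set(cfg.seed_ids) - graph.contigs.keys()
        if missing:
            raise MitographError(f"unknown seed contigs: {sorted(missing)}")
        return set(cfg.seed_ids), []
    if not cfg.pcg_db:
        raise MitographError("either seed ids or a --pcg-db FASTA is required")
    db = io.read_sequences(cfg.pcg_db)
    unknown = seeds.validate_gene_names(db, cfg.genome_type)
    if unknown:
        logger.warning(
            "%d database gene names outside the %s manifest (e.g. %s)",
            len(unknown), cfg.genome_type, unknown[0],
        )
    hits = seeds.search_pcg_hits(list(graph.contigs.values()), db)
    th = seeds.SeedThresholds(
        cfg.min_seed_len, cfg.min_seed_identity, cfg.min_seed_coverage
    )
    chosen = seeds.filter_candidate_seeds(hits, graph.contigs, th)
    if not chosen:
        raise NoSeedsError(
            "no candidate seed contig passed the gene gates; "
            "use graphBuild mode to select seeds manually"
        )
    return chosen, hits


def _downstream(
    cfg: RunConfig,
    graph: AssemblyGraph,
    readsize: float,
    outdir: Path,
    stage_tallies: Dict,
) -> RunResult:
    """Seed selection through conformation export (shared by both modes)."""
    seed_set, hits = _select_seeds(cfg, graph)
    stage_tallies["seed_contigs"] = len(seed_set)

    recruited = simplify.extend_seeds_bfs(graph, seed_set)
    stage_tallies["recruited_contigs"] = recruited.n_contigs
    stage_tallies["recruited_links"] = recruited.n_links

    if cfg.genomesize is None:
        raise MitographError("--genomesize is required to model the nuclear depth")
    nuclear_depth = simplify.estimate_nuclear_depth(cfg.genomesize, readsize)
    from statistics import median

    mito_median = float(median(recruited.contigs[s].depth for s in sorted(seed_set)))
    dm = simplify.DepthModel(
        nuclear_depth, mito_median, cfg.nuclear_mult, cfg.plastid_mult
    )
    pp = simplify.PruneParams(cfg.weak_ratio, cfg.min_link)
    master, simp_stats, reserved = simplify.simplify_graph(
        recruited,
        dm,
        pp,
        protected=seed_set,
        skip_plastid=cfg.genome_type == "pt",
        trim_dead_ends=cfg.trim_dead_ends,
    )
    stage_tallies.update(simp_stats)
    stage_tallies["master_contigs"] = master.n_contigs
    stage_tallies["master_links"] = master.n_links

    io.write_gfa(master, outdir / "PMAT_master.gfa")
    classes = simplify.classify_by_depth(master, dm)
    simplify.write_classification_tsv(master, classes, outdir / "contig_classes.tsv")

    target_graph = None
    copy_numbers = None
    conformations: List[conform.Conformation] = []
    if cfg.seed_ids and not hits:
        # explicit seeds without a database: treat seed contigs as hit contigs
        hits = [seeds.SeedHit(s, "manual", 100.0, 100.0, 0) for s in sorted(seed_set)]
    try:
        target_graph, target_median = conform.select_target_contigs(
            master, hits, cfg.spread, protected=frozenset(seed_set | reserved)
        )
        copy_numbers = conform.estimate_copy_numbers(target_graph, target_median)
        conformations = conform.enumerate_conformations(
            target_graph, copy_numbers, cfg.max_conformations
        )
    except NoSeedsError:
        logger.warning("no gene-bearing contig survived simplification")
    export_graph = target_graph if target_graph is not None else master
    conform.export_conformations(conformations, export_graph, outdir)
    stage_tallies["conformations"] = len(conformations)
    stage_tallies["circularized"] = bool(conformations)

    report = {
        "parameters": cfg.params_dict(),
        "readsize": readsize,
        "stages": stage_tallies,
        "copy_numbers": copy_numbers.copies if copy_numbers else {},
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return RunResult(
        outdir=outdir,
        raw_graph=graph,
        recruited_graph=recruited,
        master_graph=master,
        target_graph=target_graph,
        conformations=conformations,
        seeds=seed_set,
        reserved=reserved,
        classes=classes,
        copy_numbers=copy_numbers,
        report=report,
    )


def run_automito(cfg: RunConfig) -> RunResult:
    """One-step assembly from raw reads to exported conformations."""
    if not cfg.reads:
        raise MitographError("autoMito requires --reads")
    if cfg.genomesize is None:
        raise MitographError("autoMito requires --genomesize")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tallies: Dict = {}
    reads, sampled_bases = _prepare_reads(cfg)
    tallies["reads_used"] = len(reads)
    tallies["bases_used"] = sampled_bases
    readsize = cfg.readsize if cfg.readsize else float(sampled_bases)

    params = assembly.AssemblyParams(cfg.k, cfg.min_kmer_count)
    graph = assembly.build_contig_graph(reads, params)
    tallies["assembled_contigs"] = graph.n_contigs
    tallies["assembled_links"] = graph.n_links
    io.write_contig_table(
        graph, outdir / "PMATContigGraph.txt", outdir / "PMATAllContigs.fna"
    )
    io.write_gfa(graph, outdir / "assembly_raw.gfa")
    return _downstream(cfg, graph, readsize, outdir, tallies)


def run_graphbuild(cfg: RunConfig) -> RunResult:
    """Enter the pipeline from an existing contig table + contig FASTA."""
    if not cfg.contig_table or not cfg.contig_fasta:
        raise MitographError("graphBuild requires --contig-table and --contig-fasta")
    if not cfg.seed_ids and not cfg.pcg_db:
        raise MitographError("graphBuild requires seed ids or a --pcg-db FASTA")
    if cfg.readsize is None:
        raise MitographError("graphBuild requires --readsize to model nuclear depth")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = io.read_contig_table(cfg.contig_table, cfg.contig_fasta)
    tallies = {
        "assembled_contigs": graph.n_contigs,
        "assembled_links": graph.n_links,
    }
    io.write_gfa(graph, outdir / "assembly_raw.gfa")
    return _downstream(cfg, graph, float(cfg.readsize), outdir, tallies)


def _reference_kmer_coverage(contig_seqs: Sequence[str], reference: str, k: int = 31) -> float:
    """Percent of reference k-mers present in the assembled contigs."""
    from .assembly import _encode_seq, _window_codes

    ref_f, ref_r = _window_codes(_encode_seq(reference + reference[: k - 1]), k)
    ref = np.minimum(ref_f, ref_r)
    if len(ref) == 0:
        return 0.0
    chunks = []
    for s in contig_seqs:
        f, r = _window_codes(_encode_seq(s), k)
        if len(f):
            chunks.append(np.minimum(f, r))
    if not chunks:
        return 0.0
    have = np.unique(np.concatenate(chunks))
    return 100.0 * float(np.isin(np.unique(ref), have).mean())


def run_titrate(cfg: RunConfig) -> pd.DataFrame:
    """Rerun the pipeline per data tier; report circularisation per tier."""
    if not cfg.reads:
        raise MitographError("titrate requires --reads")
    reads = io.read_sequences(cfg.reads)
    total = sum(len(r) for r in reads)
    tiers = cfg.titration_tiers or list(DEFAULT_TITRATION_TIERS)
    reference = None
    if cfg.reference:
        reference = io.read_sequences(cfg.reference)[0].seq
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tier in enumerate(tiers):
        note = ""
        if tier >= total:
            note = f"tier exceeds available data ({total} bases); using all reads"
            logger.warning(note)
        tier_cfg = RunConfig(**{**cfg.params_dict(), "titration_tiers": list(tiers)})
        tier_cfg.sample_bases = min(tier, total)
        tier_cfg.seed = cfg.seed + i
        tier_cfg.outdir = str(outdir / f"tier_{tier}")
        row = {
            "tier_bases": tier,
            "used_bases": min(tier, total),
            "contigs": 0,
            "assembled_bp": 0,
            "circularized": False,
            "note": note,
        }
        try:
            res = run_automito(tier_cfg)
            g = res.target_graph if res.target_graph is not None else res.master_graph
            row["contigs"] = g.n_contigs
            row["assembled_bp"] = sum(c.length for c in g)
            row["circularized"] = res.circularized
            if reference is not None:
                seqs = (
                    res.master_sequences()
                    if res.circularized
                    else [c.seq for c in g if c.seq]
                )
                row["reference_coverage_pct"] = round(
                    _reference_kmer_coverage(seqs, reference, cfg.k), 2
                )
        except (NoSeedsError, MitographError) as exc:
            row["note"] = (note + "; " if note else "") + f"pipeline stopped: {exc}"
            logger.warning("tier %d failed: %s", tier, exc)
        rows.append(row)
    cols = ["tier_bases", "used_bases", "contigs", "assembled_bp", "circularized", "note"]
    if reference is not None:
        cols.insert(5, "reference_coverage_pct")
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df = df[cols]
    df.to_csv(outdir / "titration.tsv", sep="\t", index=False)
    return df
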