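"""End-to-end orchestration: simulate/load -> annotate -> similarity ->
taxonomy -> pangenome -> AMG/codon statistics.

Every run writes its outputs plus a manifest (config echo and SHA-256 of
each product) into the output directory, so any stage can be re-run in
isolation and byte-identical reproduction can be checked. The pipeline is
single-threaded and fully deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_analytics as aa
from . import genome_io, orf_consensus, pangenome, similarity, taxonomy
from .genome_io import GenomeRecord
from .orf_consensus import ConsensusConfig
from .similarity import AlignParams
from .synthetic_phage import (
    SimConfig,
    simulate_amg_table,
    simulate_family_set,
    simulate_predictor_calls,
)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]

log = logging.getLogger("pancomp")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All thresholds and inputs of one pipeline run.

    Either ``sim`` (generate a synthetic collection) or ``fasta`` (load
    genomes; optionally calls/hits/AMG tables) must be set. Defaults
    reproduce the standard demarcation and clustering thresholds
    (95/70 percent similarity, 30% identity / 80% coverage clustering,
    soft core at >95% prevalence).
    """

    sim: SimConfig | None = None
    fasta: str | None = None
    calls: str | None = None
    hits: str | None = None
    amg_table: str | None = None
    outdir: str = "pancomp_out"
    seed: int = 0
    n_predictors: int = 8
    species_threshold: float = 95.0
    genus_threshold: float = 70.0
    min_id: float = 0.30
    min_cov: float = 0.80
    soft_core_fraction: float = 0.95
    k: int = 13
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig(**d["sim"])
        if d.get("consensus") is not None:
            d["consensus"] = ConsensusConfig(**d["consensus"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RunReport:
    outdir: str
    outputs: dict[str, str]
    summary: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(outdir: Path, level: str) -> None:
    log.setLevel(level.upper())
    log.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    fileh = logging.FileHandler(outdir / "run.log", mode="w")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (stream, fileh):
        h.setFormatter(fmt)
        log.addHandler(h)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    outputs: dict[str, str] = {}
    summary: dict = {"seed": config.seed}

    def _register(name: str, path: Path) -> None:
        outputs[name] = str(path)

    stage = "inputs"
    try:
        truth = None
        calls = None
        hits = None
        amg_rows = None
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            genomes, truth = simulate_family_set(sim_cfg)
            calls = simulate_predictor_calls(truth, config.n_predictors, sim_cfg)
            amg_rows = simulate_amg_table(truth, sim_cfg)
            genome_io.write_fasta(genomes, outdir / "genomes.fasta")
            truth.labels_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
            genome_io.write_feature_table(calls, outdir / "calls.tsv")
            amg_rows.to_csv(outdir / "amg_annotations.tsv", sep="\t", index=False)
            _register("genomes", outdir / "genomes.fasta")
            _register("truth", outdir / "truth.tsv")
            _register("calls", outdir / "calls.tsv")
            _register("amg_annotations", outdir / "amg_annotations.tsv")
        elif config.fasta:
            genomes = genome_io.read_fasta(config.fasta)
            if config.calls:
                calls = genome_io.read_feature_table(config.calls)
            if config.hits:
                hits = orf_consensus.read_hits_table(config.hits)
            if config.amg_table:
                amg_rows = pd.read_csv(config.amg_table, sep="\t")
        else:
            raise ValueError("config needs either sim parameters or a fasta path")
        log.info("inputs: %d genomes", len(genomes))
        summary["n_genomes"] = len(genomes)

        stage = "annotate"
        genes = []
        if calls is not None:
            genes = orf_consensus.consensus_annotate(
                calls,
                genomes,
                hits=hits,
                n_predictors=config.n_predictors,
                config=config.consensus,
            )
            genome_io.write_features_gff3(
                genes, outdir / "genes.gff3", {g.genome_id: g.length_bp for g in genomes}
            )
            _register("genes", outdir / "genes.gff3")
            summary["n_consensus_genes"] = len(genes)
            log.info("annotate: %d consensus genes", len(genes))

        stage = "similarity"
        params = AlignParams(k=config.k)
        mat, ids = similarity.similarity_matrix(genomes, params)
        similarity.matrix_to_dataframe(mat, ids).to_csv(outdir / "similarity_matrix.tsv", sep="\t")
        _register("similarity_matrix", outdir / "similarity_matrix.tsv")
        summary["mean_offdiag_similarity"] = float(
            np.round(mat[~np.eye(len(ids), dtype=bool)].mean(), 4)
        )
        log.info("similarity: %d x %d matrix", len(ids), len(ids))

        stage = "taxonomy"
        part = taxonomy.rank_partition(
            mat, ids, config.species_threshold, config.genus_threshold
        )
        part.to_frame().to_csv(outdir / "rank_partition.tsv", sep="\t", index=False)
        _register("rank_partition", outdir / "rank_partition.tsv")
        summary["n_genus_clusters"] = len(set(part.genus.values()))
        summary["n_species_clusters"] = len(set(part.species.values()))
        tree = None
        if len(ids) >= 3:
            tree = taxonomy.nj_tree(taxonomy.similarity_to_distance(mat), ids)
            (outdir / "tree.nwk").write_text(str(tree))
            _register("tree", outdir / "tree.nwk")
        log.info(
            "taxonomy: %d genera / %d species",
            summary["n_genus_clusters"],
            summary["n_species_clusters"],
        )

        stage = "pangenome"
        if genes:
            gdict = {g.genome_id: g for g in genomes}
            proteins = []
            for i, gene in enumerate(genes):
                if (gene.end - gene.start + 1) % 3:
                    continue
                proteins.append(
                    genome_io.translate_orf(
                        gdict[gene.genome_id],
                        gene.start,
                        gene.end,
                        gene.strand,
                        gene_id=f"{gene.genome_id}|gene{i:05d}",
                    )
                )
            clusters = pangenome.cluster_proteins(proteins, config.min_id, config.min_cov)
            clusters.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            pm = pangenome.presence_matrix(
                clusters, [g.genome_id for g in genomes], config.soft_core_fraction
            )
            pm.matrix.to_csv(outdir / "presence.tsv", sep="\t")
            core = pangenome.soft_core(pm)
            pd.DataFrame(
                {
                    "cluster_id": sorted(core.clusters),
                }
            ).to_csv(outdir / "core_summary.tsv", sep="\t", index=False)
            for name in ("clusters", "presence", "core_summary"):
                _register(name, outdir / f"{name}.tsv")
            summary["n_clusters"] = clusters.n_clusters
            summary["n_soft_core"] = core.count
            summary["core_pct_of_proteome"] = round(core.percent_of_proteome, 2)
            log.info(
                "pangenome: %d clusters, %d soft-core (%.1f%% of mean proteome)",
                clusters.n_clusters,
                core.count,
                core.percent_of_proteome,
            )

        stage = "amg"
        if amg_rows is not None:
            records = aa.filter_amgs(amg_rows)
            counts = aa.amg_counts(records, [g.genome_id for g in genomes])
            counts.rename("n_amgs").to_csv(outdir / "amg_counts.tsv", sep="\t")
            _register("amg_counts", outdir / "amg_counts.tsv")
            sizes = pd.Series({g.genome_id: g.length_bp for g in genomes})
            sizes = sizes[counts.index]
            stats_report: dict = {"n_curated_amgs": len(records)}
            if sizes.nunique() > 1 and len(sizes) >= 3:
                slope, intercept, r2, p = aa.linear_fit(sizes.values, counts.values)
                stats_report["size_vs_amg"] = {
                    "slope_per_bp": slope,
                    "intercept": intercept,
                    "r_squared": r2,
                    "p_value": p,
                }
            with_amg = sizes[counts > 0]
            without = sizes[counts == 0]
            if len(with_amg) >= 2 and len(without) >= 2:
                t, p = aa.two_group_t(with_amg.values, without.values)
                stats_report["genome_size_by_amg_presence"] = {"t": t, "p_value": p}
            with open(outdir / "stats_report.json", "w") as fh:
                json.dump(stats_report, fh, indent=2, sort_keys=True)
            _register("stats_report", outdir / "stats_report.json")
            summary["n_curated_amgs"] = len(records)
            log.info("amg: %d curated records", len(records))

        stage = "summary"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _register("summary", outdir / "summary.json")
        manifest = {
            "config": config.to_dict(),
            "outputs": {name: _sha256(Path(p)) for name, p in sorted(outputs.items())},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:  # partial outputs stay on disk for inspection
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    return RunReport(str(outdir), outputs, summary)
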