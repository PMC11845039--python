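"""Orthologue clustering, gene presence/absence and soft-core computation.

Proteins are grouped into orthologue clusters by greedy centroid clustering
at 30% identity and 80% bidirectional coverage (the thresholds used for
phage core-gene analyses), longest sequence first, each protein joining the
first centroid it matches and founding a new cluster otherwise. The
cluster-by-genome presence matrix then yields the *soft-core genome*: the
clusters present in more than ``fraction`` (default 0.95, strict) of the
genomes, a tolerance that absorbs the occasional missed or misannotated
gene in real collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import overlap_align
from .genome_io import ProteinSeq

__all__ = [
    "ClusterTable",
    "GenePresenceMatrix",
    "protein_pair_identity",
    "cluster_proteins",
    "presence_matrix",
    "soft_core",
    "SoftCoreSummary",
    "shared_orthologue_fraction",
]


def protein_pair_identity(p1: ProteinSeq | str, p2: ProteinSeq | str) -> tuple[float, float, float]:
    """(identity, coverage_1, coverage_2) under the canonical overlap DP."""
    s1 = p1.aa_sequence if isinstance(p1, ProteinSeq) else p1
    s2 = p2.aa_sequence if isinstance(p2, ProteinSeq) else p2
    res = overlap_align(s1, s2)
    cov1, cov2 = res.coverage(len(s1), len(s2))
    return res.identity, cov1, cov2


@dataclass
class ClusterTable:
    """Disjoint, exhaustive orthologue clusters with their centroids."""

    members: dict[str, list[str]]  # cluster_id -> member gene ids
    centroids: dict[str, str]  # cluster_id -> centroid gene id
    gene_to_cluster: dict[str, str]
    proteins: dict[str, ProteinSeq]

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cid, self.centroids[cid], gid)
            for cid, genes in self.members.items()
            for gid in genes
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "centroid", "member"])


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_proteins(
    proteins: list[ProteinSeq], min_id: float = 0.30, min_cov: float = 0.80
) -> ClusterTable:
    """Greedy centroid clustering, longest-first, ties by gene_id.

    A protein joins the earliest-founded centroid it matches at
    >= ``min_id`` identity with >= ``min_cov`` coverage of *both* sequences,
    and founds a new cluster otherwise. A cheap length-ratio and shared
    4-mer prescreen skips alignments that cannot reach the thresholds.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    ids = [p.gene_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id among proteins")
    order = sorted(proteins, key=lambda p: (-len(p.aa_sequence), p.gene_id))
    centroid_list: list[tuple[str, ProteinSeq, set[str]]] = []  # (cluster_id, seq, kmers)
    members: dict[str, list[str]] = {}
    centroids: dict[str, str] = {}
    gene_to_cluster: dict[str, str] = {}
    for p in order:
        assigned = None
        pk = _kmer_set(p.aa_sequence)
        for cid, cent, ck in centroid_list:
            la, lb = len(p.aa_sequence), len(cent.aa_sequence)
            if min(la, lb) / max(la, lb) < min_cov * 0.9:
                continue
            if min(la, lb) >= 60 and not (pk & ck):
                continue
            ident, cov1, cov2 = protein_pair_identity(p, cent)
            if ident >= min_id and cov1 >= min_cov and cov2 >= min_cov:
                assigned = cid
                break
        if assigned is None:
            cid = f"cluster{len(centroid_list):05d}"
            centroid_list.append((cid, p, pk))
            members[cid] = [p.gene_id]
            centroids[cid] = p.gene_id
            gene_to_cluster[p.gene_id] = cid
        else:
            members[assigned].append(p.gene_id)
            gene_to_cluster[p.gene_id] = assigned
    return ClusterTable(members, centroids, gene_to_cluster, {p.gene_id: p for p in proteins})


@dataclass
class GenePresenceMatrix:
    """Binary cluster x genome matrix plus per-genome proteome sizes."""

    matrix: pd.DataFrame  # rows cluster_id, columns genome_id, values 0/1
    genome_gene_counts: pd.Series  # proteins per genome (multi-copies counted)
    soft_core_fraction: float = 0.95

    @property
    def prevalence(self) -> pd.Series:
        return self.matrix.mean(axis=1)

    @property
    def soft_core_flags(self) -> pd.Series:
        return self.prevalence > self.soft_core_fraction


def presence_matrix(
    clusters: ClusterTable,
    genomes: list[str] | None = None,
    soft_core_fraction: float = 0.95,
) -> GenePresenceMatrix:
    """Presence/absence of each cluster in each genome."""
    gene_genome = {gid: p.genome_id for gid, p in clusters.proteins.items()}
    for gid in clusters.gene_to_cluster:
        if gid not in gene_genome:
            raise KeyError(f"gene {gid!r} has no genome of origin")
    genome_ids = sorted(genomes) if genomes is not None else sorted(set(gene_genome.values()))
    unknown = set(gene_genome.values()) - set(genome_ids)
    if unknown:
        raise KeyError(f"genes from genomes not in the genome set: {sorted(unknown)}")
    cluster_ids = sorted(clusters.members)
    mat = pd.DataFrame(0, index=cluster_ids, columns=genome_ids, dtype=int)
    counts = pd.Series(0, index=genome_ids, dtype=int)
    for cid, genes in clusters.members.items():
        for gid in genes:
            g = gene_genome[gid]
            mat.loc[cid, g] = 1
            counts[g] += 1
    return GenePresenceMatrix(mat, counts, soft_core_fraction)


@dataclass(frozen=True)
class SoftCoreSummary:
    clusters: frozenset[str]
    count: int
    mean_proteome_size: float
    percent_of_proteome: float


def soft_core(matrix: GenePresenceMatrix, fraction: float | None = None) -> SoftCoreSummary:
    """Clusters present in more than ``fraction`` of the genomes (strict >).

    The core percentage is reported relative to the mean number of genes
    per genome, as family core-gene shares are usually quoted.
    """
    frac = matrix.soft_core_fraction if fraction is None else fraction
    prev = matrix.prevalence
    core = frozenset(prev.index[prev > frac])
    mean_size = float(matrix.genome_gene_counts.mean())
    pct = 100.0 * len(core) / mean_size if mean_size else float("nan")
    return SoftCoreSummary(core, len(core), mean_size, pct)


def shared_orthologue_fraction(
    matrix: GenePresenceMatrix,
    set_a: set[str],
    set_b: set[str],
    fraction: float | None = None,
) -> tuple[int, float]:
    """Soft-core clusters shared by two disjoint genome sets.

    Both soft-cores are computed on the joint clustering restricted to each
    set's genomes; the returned fraction is relative to set A's mean
    proteome size.
    """
    if not set_a or not set_b:
        raise ValueError("both genome sets must be non-empty")
    if set_a & set_b:
        raise ValueError(f"genome sets overlap: {sorted(set_a & set_b)}")
    missing = (set_a | set_b) - set(matrix.matrix.columns)
    if missing:
        raise KeyError(f"genomes not in matrix: {sorted(missing)}")
    frac = matrix.soft_core_fraction if fraction is None else fraction
    prev_a = matrix.matrix[sorted(set_a)].mean(axis=1)
    prev_b = matrix.matrix[sorted(set_b)].mean(axis=1)
    core_a = set(prev_a.index[prev_a > frac])
    core_b = set(prev_b.index[prev_b > frac])
    n_shared = len(core_a & core_b)
    mean_a = float(matrix.genome_gene_counts[sorted(set_a)].mean())
    return n_shared, (n_shared / mean_a if mean_a else float("nan"))
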