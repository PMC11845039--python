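"""ICTV-style rank assignment, distance trees and family-proposal checks.

Species and genus relations follow the intergenomic-similarity demarcation
used for tailed phages: pairs at >= 95% similarity are the same species
(and genus); pairs at >= 70% and < 95% are the same genus, different
species; pairs below 70% are different genera. Whole-collection partitions
use single-linkage connected components at those thresholds, which is the
only linkage under which pairwise statements and partitions stay
consistent.

Candidate new families are evaluated on three criteria: (a) a substantial
soft-core (default >= 10% of the mean proteome), (b) monophyly -- the
candidate set forms a clan (a single edge of the unrooted tree separates it
from everything else), and (c) no soft-core orthologues shared with any
neighbouring family.

Trees are built by neighbour joining on (100 - S)/100 distances, or on
p-distances from concatenated marker alignments produced by the module's
own progressive aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .alignment import overlap_align
from .pangenome import GenePresenceMatrix, shared_orthologue_fraction, soft_core

__all__ = [
    "SPECIES_THRESHOLD",
    "GENUS_THRESHOLD",
    "RankPartition",
    "FamilyProposal",
    "assign_rank_pair",
    "rank_partition",
    "select_marker_hits",
    "nj_tree",
    "is_clan",
    "propose_family",
    "progressive_align",
    "concatenate_alignments",
    "alignment_distance_matrix",
    "similarity_to_distance",
]

SPECIES_THRESHOLD = 95.0
GENUS_THRESHOLD = 70.0


def assign_rank_pair(
    similarity: float,
    species_threshold: float = SPECIES_THRESHOLD,
    genus_threshold: float = GENUS_THRESHOLD,
) -> str:
    """Relation of one genome pair from its intergenomic similarity (%)."""
    if not (0 <= similarity <= 100):
        raise ValueError(f"similarity must be in [0, 100], got {similarity}")
    if similarity >= species_threshold:
        return "same_species"
    if similarity >= genus_threshold:
        return "same_genus_new_species"
    return "distinct_genus"


@dataclass(frozen=True)
class RankPartition:
    species: dict[str, str]  # genome -> species cluster label
    genus: dict[str, str]  # genome -> genus cluster label
    species_threshold: float = SPECIES_THRESHOLD
    genus_threshold: float = GENUS_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, self.species[g], self.genus[g]) for g in sorted(self.species)],
            columns=["genome_id", "species_cluster", "genus_cluster"],
        )


def _components(mat: np.ndarray, ids: list[str], threshold: float) -> dict[str, str]:
    adj = csr_matrix(mat >= threshold)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for gid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(gid)
    out: dict[str, str] = {}
    for members in groups.values():
        rep = min(members)  # deterministic label: lexicographically smallest
        for m in members:
            out[m] = rep
    return out


def rank_partition(
    mat: np.ndarray,
    ids: list[str],
    species_threshold: float = SPECIES_THRESHOLD,
    genus_threshold: float = GENUS_THRESHOLD,
) -> RankPartition:
    """Single-linkage genus and species partitions from a similarity matrix."""
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] != mat.shape[1] or mat.shape[0] != len(ids):
        raise ValueError("matrix shape does not match the genome id list")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    genus = _components(mat, ids, genus_threshold)
    species = _components(mat, ids, species_threshold)
    return RankPartition(species, genus, species_threshold, genus_threshold)


def select_marker_hits(hits: pd.DataFrame, max_evalue: float = 1e-3) -> pd.DataFrame:
    """Best marker-gene hit per (genome, marker).

    Rows with e-value >= ``max_evalue`` are discarded (strictly lower
    survives); among the rest the minimal e-value per (genome, marker) is
    kept, ties broken by gene id.
    """
    required = {"genome", "marker", "e_value", "gene"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    if hits.empty:
        return hits.copy()
    if (hits["e_value"] <= 0).any():
        raise ValueError("e-values must be positive")
    kept = hits[hits["e_value"] < max_evalue]
    if kept.empty:
        return kept.copy()
    kept = kept.sort_values(["genome", "marker", "e_value", "gene"], kind="stable")
    return kept.groupby(["genome", "marker"], as_index=False).first()


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def similarity_to_distance(mat: np.ndarray) -> np.ndarray:
    """(100 - S)/100: identical genomes at distance 0, unrelated near 1."""
    return (100.0 - np.asarray(mat, dtype=float)) / 100.0


def nj_tree(distances: np.ndarray, ids: list[str]) -> TreeNode:
    """Neighbour-joining tree; negative branch lengths are clamped to zero."""
    d = np.asarray(distances, dtype=float)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    dm = DistanceMatrix(d, ids)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def is_clan(tree: TreeNode, tips: set[str]) -> bool:
    """Whether ``tips`` is separated from all other leaves by a single edge.

    This is monophyly on an unrooted tree: the set is a clade under some
    rooting iff some bipartition of the tree equals (tips, complement).
    """
    leaves = {t.name for t in tree.tips()}
    unknown = set(tips) - leaves
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)}")
    tips = set(tips)
    if not tips:
        raise ValueError("empty tip set")
    if len(tips) == 1 or tips == leaves:
        return True
    for node in tree.traverse(include_self=True):
        below = {t.name for t in node.tips(include_self=True)}
        if below == tips or leaves - below == tips:
            return True
    return False


# ---------------------------------------------------------------------------
# family proposal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyProposal:
    candidates: frozenset[str]
    n_core: int
    core_pct: float
    criterion_a: bool
    criterion_b: bool
    shared_core_with_neighbors: dict[str, int]
    criterion_c: bool
    verdict: bool

    def to_dict(self) -> dict:
        return {
            "candidates": sorted(self.candidates),
            "n_core": self.n_core,
            "core_pct": self.core_pct,
            "criterion_a_core_share": self.criterion_a,
            "criterion_b_monophyly": self.criterion_b,
            "criterion_c_no_shared_core": self.criterion_c,
            "shared_core_with_neighbors": dict(self.shared_core_with_neighbors),
            "verdict": self.verdict,
        }


def propose_family(
    candidates: set[str],
    neighbors: list[set[str]],
    matrix: GenePresenceMatrix,
    tree: TreeNode,
    min_core_pct: float = 10.0,
) -> FamilyProposal:
    """Evaluate the three family-proposal criteria for a candidate set."""
    candidates = set(candidates)
    for nb in neighbors:
        if candidates & nb:
            raise ValueError("candidate and neighbor sets must be disjoint")
    sub_prev = matrix.matrix[sorted(candidates)].mean(axis=1)
    core = set(sub_prev.index[sub_prev > matrix.soft_core_fraction])
    mean_size = float(matrix.genome_gene_counts[sorted(candidates)].mean())
    core_pct = 100.0 * len(core) / mean_size if mean_size else 0.0
    crit_a = core_pct >= min_core_pct
    crit_b = is_clan(tree, candidates)
    shared: dict[str, int] = {}
    for i, nb in enumerate(neighbors):
        n_shared, _ = shared_orthologue_fraction(matrix, candidates, set(nb))
        shared[f"neighbor{i}"] = n_shared
    crit_c = all(v == 0 for v in shared.values())
    return FamilyProposal(
        frozenset(candidates), len(core), core_pct, crit_a, crit_b, shared, crit_c,
        crit_a and crit_b and crit_c,
    )


# ---------------------------------------------------------------------------
# marker alignment (desk-scale progressive star alignment)
# ---------------------------------------------------------------------------

def _nw_pair(a: str, b: str) -> tuple[str, str]:
    """Global alignment (match 1, mismatch/gap -1), deterministic traceback."""
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    H[:, 0] = -np.arange(m + 1)
    H[0, :] = -np.arange(n + 1)
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    idx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = np.where(eb == ea[i - 1], 1, -1).astype(np.int32)
        T = np.empty(n + 1, dtype=np.int32)
        T[0] = H[i - 1, 0] - 1
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] - 1, out=T[1:])
        H[i] = np.maximum.accumulate(T + idx) - idx
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else -1):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] - 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def progressive_align(seqs: dict[str, str]) -> dict[str, str]:
    """Center-star multiple alignment: everything aligned to the longest
    sequence, with gaps opened in the center propagated to all rows."""
    if not seqs:
        return {}
    if len(seqs) == 1:
        return dict(seqs)
    center_id = max(seqs, key=lambda k: (len(seqs[k]), k))
    center = seqs[center_id]
    aligned: dict[str, str] = {center_id: center}
    for sid in sorted(k for k in seqs if k != center_id):
        a_cent, a_new = _nw_pair(aligned[center_id].replace("-", ""), seqs[sid])
        # re-thread existing gap columns of the running center alignment
        merged_center: list[str] = []
        merged_new: list[str] = []
        rows = {k: [] for k in aligned if k != center_id}
        old_center = aligned[center_id]
        oi = 0  # index into old (gapped) center
        for cc, cn in zip(a_cent, a_new):
            if cc == "-":
                merged_center.append("-")
                merged_new.append(cn)
                for k in rows:
                    rows[k].append("-")
            else:
                while old_center[oi] == "-":
                    merged_center.append("-")
                    merged_new.append("-")
                    for k in rows:
                        rows[k].append(aligned[k][oi])
                    oi += 1
                merged_center.append(cc)
                merged_new.append(cn)
                for k in rows:
                    rows[k].append(aligned[k][oi])
                oi += 1
        while oi < len(old_center):
            merged_center.append(old_center[oi])
            merged_new.append("-")
            for k in rows:
                rows[k].append(aligned[k][oi])
            oi += 1
        aligned = {center_id: "".join(merged_center), sid: "".join(merged_new)}
        for k, row in rows.items():
            aligned[k] = "".join(row)
    return aligned


def concatenate_alignments(alignments: list[dict[str, str]]) -> dict[str, str]:
    """End-to-end concatenation; taxa missing from a block get all-gap rows."""
    taxa = sorted({t for aln in alignments for t in aln})
    out = {t: [] for t in taxa}
    for aln in alignments:
        width = max((len(s) for s in aln.values()), default=0)
        for t in taxa:
            out[t].append(aln.get(t, "-" * width))
    return {t: "".join(parts) for t, parts in out.items()}


def alignment_distance_matrix(aligned: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """p-distance: 1 - fraction of identical columns (both-gap columns skipped)."""
    ids = sorted(aligned)
    arrs = {t: np.frombuffer(aligned[t].encode(), dtype=np.uint8) for t in ids}
    gap = ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            used = ~((a == gap) & (b == gap))
            total = int(used.sum())
            same = int(((a == b) & used).sum())
            d[i, j] = d[j, i] = 1.0 - same / total if total else 0.0
    return d, ids
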