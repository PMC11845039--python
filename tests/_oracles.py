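"""Independent brute-force reference implementations used only by tests.

Each oracle re-implements a contract from scratch (pure Python, exhaustive
where feasible) so the package's optimized paths can be checked against an
algorithmically independent computation.
"""

from __future__ import annotations

from collections import deque


# ---------------------------------------------------------------------------
# free-end-gap alignment oracle (same convention as pancomp.alignment,
# implemented as a plain quadratic DP with explicit tie-break rules)
# ---------------------------------------------------------------------------

def overlap_align_oracle(a: str, b: str) -> dict:
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] - 1, H[i][j - 1] - 1)
    best = (H[m][0], m, m, 0)
    for j in range(n + 1):
        cand = (H[m][j], m + j, m, j)
        if cand > best:
            best = cand
    for i in range(m + 1):
        cand = (H[i][n], i + n, i, n)
        if cand > best:
            best = cand
    score, _, i, j = best
    if score <= 0:
        return {"matches": 0, "columns": 0, "identity": 0.0, "score": 0}
    a_end, b_end = i, j
    matches = columns = 0
    while i > 0 and j > 0:
        s = 1 if a[i - 1] == b[j - 1] else -1
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += s == 1
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return {
        "matches": matches,
        "columns": columns,
        "identity": matches / columns,
        "score": score,
        "a_span": (i + 1, a_end),
        "b_span": (j + 1, b_end),
    }


# ---------------------------------------------------------------------------
# single-linkage protein clustering oracle (union-find over all pairs)
# ---------------------------------------------------------------------------

def single_linkage_oracle(proteins, pair_fn, min_id: float, min_cov: float):
    """Partition as a frozenset of frozensets of gene ids."""
    ids = [p.gene_id for p in proteins]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, p in enumerate(proteins):
        for q in proteins[i + 1 :]:
            ident, c1, c2 = pair_fn(p, q)
            if ident >= min_id and c1 >= min_cov and c2 >= min_cov:
                parent[find(p.gene_id)] = find(q.gene_id)
    groups: dict[str, set[str]] = {}
    for gid in ids:
        groups.setdefault(find(gid), set()).add(gid)
    return frozenset(frozenset(g) for g in groups.values())


# ---------------------------------------------------------------------------
# clan (unrooted monophyly) oracle: collect every edge bipartition by BFS
# ---------------------------------------------------------------------------

def all_bipartition_sides(tree) -> set[frozenset]:
    """Sides of every edge of an unrooted skbio tree, both orientations."""
    # adjacency over nodes
    adj: dict[int, list] = {}
    nodes = list(tree.traverse(include_self=True))
    for node in nodes:
        for child in node.children:
            adj.setdefault(id(node), []).append(node)  # placeholder init
    # rebuild properly with objects
    adj = {id(n): [] for n in nodes}
    obj = {id(n): n for n in nodes}
    for node in nodes:
        for child in node.children:
            adj[id(node)].append(id(child))
            adj[id(child)].append(id(node))
    leaves = frozenset(t.name for t in tree.tips())
    sides: set[frozenset] = set()
    for node in nodes:
        for nb in adj[id(node)]:
            # tips reachable from `node` without crossing the edge (node, nb)
            seen = {id(node)}
            q = deque([id(node)])
            tips = set()
            while q:
                cur = q.popleft()
                cn = obj[cur]
                if not cn.children:
                    tips.add(cn.name)
                for nxt in adj[cur]:
                    if nxt != nb and nxt not in seen:
                        seen.add(nxt)
                        q.append(nxt)
            sides.add(frozenset(tips))
    sides.add(leaves)
    return sides


def is_clan_oracle(tree, tips: set) -> bool:
    return frozenset(tips) in all_bipartition_sides(tree)


# ---------------------------------------------------------------------------
# AMG filter truth table oracle
# ---------------------------------------------------------------------------

def amg_keep_oracle(rank: str, flags: set[str]) -> bool:
    return rank in {"A", "B", "C"} and "M" in flags and not (flags & {"V", "B", "T"})


# ---------------------------------------------------------------------------
# dereplication oracle: longest-first greedy over a precomputed pair graph
# ---------------------------------------------------------------------------

def dereplicate_oracle(genomes, pair_fn, id_thr: float, cov_thr: float):
    order = sorted(genomes, key=lambda g: (-g.length_bp, g.genome_id))
    reps = []
    mapping = {}
    for g in order:
        home = None
        for rep in reps:
            ident, mean_cov = pair_fn(g, rep)
            if ident * 100 >= id_thr and mean_cov * 100 >= cov_thr:
                home = rep
                break
        if home is None:
            reps.append(g)
            mapping[g.genome_id] = g.genome_id
        else:
            mapping[g.genome_id] = home.genome_id
    return [r.genome_id for r in reps], mapping
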