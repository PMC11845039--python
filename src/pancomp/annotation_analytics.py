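"""Codon/amino-acid usage bias, AMG curation, and association statistics.

Codon usage is compared phage-vs-host by subtracting the host's codon
frequencies from the phage's (the difference vector sums to zero) and by
cosine similarity of the two frequency vectors.

AMG (auxiliary metabolic gene) curation follows the standard DRAM-v-style
rule set: keep a row iff its confidence rank is C or better (A best), its
flags include the metabolic flag 'M', and none of the disqualifying flags
V (viral-like), B (besides a viral-like gene) or T (transposon) are
present. The F flag (gene at a genome end) never causes removal, and
unknown flags are passed through without effect.

Association statistics mirror the usual genome-size analyses: ordinary
least squares of AMG count on genome size (R^2 and the slope F-test
p-value) and an unpaired pooled-variance two-sample t-test for group
genome-size comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ProteinSeq

__all__ = [
    "CODONS",
    "AMINO_ACIDS",
    "CodonUsageProfile",
    "AMGRecord",
    "codon_usage",
    "usage_difference",
    "cosine_similarity",
    "amino_acid_usage",
    "filter_amgs",
    "amg_counts",
    "linear_fit",
    "two_group_t",
]

CODONS = ["".join(c) for c in product("ACGT", repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = ("TAA", "TAG", "TGA")
AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")
VALID_RANKS = frozenset("ABCDE")
KEEP_RANKS = frozenset("ABC")
DISQUALIFYING_FLAGS = frozenset("VBT")


@dataclass(frozen=True)
class CodonUsageProfile:
    owner_id: str
    counts: np.ndarray  # 64-vector, order = CODONS (lexicographic ACGT)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (64,) or (c < 0).any():
            raise ValueError("counts must be a nonnegative 64-vector")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        """Normalized frequencies; NaN vector when the profile is empty."""
        t = self.total
        if t == 0:
            return np.full(64, np.nan)
        return self.counts / t

    @property
    def defined(self) -> bool:
        return self.total > 0


def codon_usage(
    coding_seqs: list[str], owner_id: str = "", drop_stop: bool = True
) -> CodonUsageProfile:
    """Accumulate codon counts over in-frame coding sequences.

    Each sequence must have length divisible by 3. The terminal stop codon
    of each sequence is excluded by default; codons with ambiguous bases
    are skipped.
    """
    counts = np.zeros(64)
    for seq in coding_seqs:
        s = seq.upper()
        if len(s) % 3 != 0:
            raise ValueError(f"sequence length {len(s)} not divisible by 3")
        end = len(s)
        if drop_stop and end >= 3 and s[end - 3 : end] in STOP_CODONS:
            end -= 3
        for i in range(0, end, 3):
            idx = _CODON_INDEX.get(s[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    return CodonUsageProfile(owner_id, counts)


def usage_difference(phage: CodonUsageProfile, host: CodonUsageProfile) -> np.ndarray:
    """phage.freqs - host.freqs; sums to zero for defined profiles."""
    if not phage.defined or not host.defined:
        raise ValueError("both profiles must contain at least one codon")
    return phage.freqs - host.freqs


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def amino_acid_usage(proteins: list[ProteinSeq | str]) -> np.ndarray:
    """20-vector of amino-acid frequencies over all proteins, stops excluded."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for p in proteins:
        seq = p.aa_sequence if isinstance(p, ProteinSeq) else p
        for aa in seq:
            if aa in counts:
                counts[aa] += 1
                total += 1
    if total == 0:
        raise ValueError("no standard amino acids in input")
    return np.array([counts[aa] / total for aa in AMINO_ACIDS])


# ---------------------------------------------------------------------------
# AMG curation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AMGRecord:
    gene_id: str
    genome_id: str
    rank: str
    flags: frozenset[str]
    category: str = ""


def filter_amgs(rows: pd.DataFrame) -> list[AMGRecord]:
    """Curate a DRAM-v-style annotation table down to confident AMGs.

    Keep iff rank in {A, B, C} AND 'M' in flags AND no flag in {V, B, T}.
    'F' and unknown flags never cause removal. Raises on rank symbols
    outside A-E.
    """
    required = {"gene_id", "genome_id", "auxiliary_score", "amg_flags"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    out: list[AMGRecord] = []
    for r in rows.itertuples():
        rank = str(r.auxiliary_score).strip().upper()
        if rank not in VALID_RANKS:
            raise ValueError(f"unknown rank symbol {rank!r} for gene {r.gene_id}")
        raw = r.amg_flags
        flags = frozenset() if pd.isna(raw) else frozenset(str(raw).strip().upper()) - {""}
        if rank not in KEEP_RANKS:
            continue
        if "M" not in flags or flags & DISQUALIFYING_FLAGS:
            continue
        out.append(
            AMGRecord(
                str(r.gene_id),
                str(r.genome_id),
                rank,
                flags,
                str(getattr(r, "category", "")),
            )
        )
    return out


def amg_counts(records: list[AMGRecord], genome_ids: list[str]) -> pd.Series:
    """Curated-AMG count per genome (zero for genomes without records)."""
    s = pd.Series(0, index=sorted(genome_ids), dtype=int)
    for rec in records:
        if rec.genome_id in s.index:
            s[rec.genome_id] += 1
    return s


# ---------------------------------------------------------------------------
# association statistics
# ---------------------------------------------------------------------------

def linear_fit(x, y) -> tuple[float, float, float, float]:
    """OLS of y on x: (slope, intercept, r_squared, p_value).

    The p-value is the slope F-test, which for simple regression equals the
    two-sided t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def two_group_t(x, y) -> tuple[float, float]:
    """Unpaired pooled-variance two-sample t-test, two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)
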