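"""Consensus ORF calling from multiple gene predictors.

Calls from several ORF-prediction programs are merged into stop-anchored
candidates (predictors typically disagree on the start codon, rarely on the
stop), and each candidate is scored on six evidence criteria, one point
each:

1. caller support  -- called by at least half of the predictors;
2. gene length     -- at least ``min_length_bp`` (default 120 bp);
3. gene overlap    -- overlap with any better-supported candidate at most
                      ``max_overlap_bp`` (default 30 bp);
4. homology        -- a hit in the supplied homology table below
                      ``homology_evalue`` (default 1e-3);
5. coding potential -- in-frame hexamer log-odds against a uniform
                      background is positive (undefined, hence false,
                      below 60 bp);
6. operon context  -- a same-strand neighbouring candidate within
                      ``operon_distance_bp`` (default 50 bp).

Candidates scoring >= 3 are kept; candidates scoring 0-2 are rescued only
if they have a homology hit or support from >= 2 callers, and dropped
otherwise. The hexamer background is trained per genome on its own
high-confidence candidates (majority caller support).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import FeatureCall, GenomeRecord, reverse_complement

__all__ = [
    "ConsensusConfig",
    "OrfCandidate",
    "ConsensusGene",
    "CRITERIA",
    "merge_predictions",
    "HexamerModel",
    "train_hexamer_model",
    "coding_potential",
    "score_from_criteria",
    "score_gene",
    "consensus_annotate",
    "read_hits_table",
]

CRITERIA = (
    "caller_support",
    "length_ok",
    "overlap_ok",
    "homology_hit",
    "coding_potential_ok",
    "in_operon",
)

HITS_COLUMNS = ["genome_id", "start", "end", "strand", "e_value", "subject_desc"]


@dataclass(frozen=True)
class ConsensusConfig:
    min_length_bp: int = 120
    max_overlap_bp: int = 30
    homology_evalue: float = 1e-3
    operon_distance_bp: int = 50
    min_coding_len_bp: int = 60
    keep_score: int = 3
    rescue_min_callers: int = 2
    hexamer_pseudocount: float = 1.0


@dataclass(frozen=True)
class OrfCandidate:
    """Stop-anchored merge of predictor calls for one putative gene.

    ``stop_coordinate`` is the strand-oriented 3' end (the `end` column on
    '+', the `start` column on '-'); ``start``/``end`` span the longest
    called extent (most-upstream start).
    """

    genome_id: str
    start: int
    end: int
    strand: str
    stop_coordinate: int
    supporting_callers: frozenset[str]

    @property
    def candidate_length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsensusGene:
    genome_id: str
    start: int
    end: int
    strand: str
    supporting_callers: frozenset[str]
    criteria: dict[str, bool]
    score: int
    verdict: str  # kept | rescued | dropped
    call_type: str = "CDS"

    def gff_attributes(self) -> str:
        crit = ",".join(name for name in CRITERIA if self.criteria[name])
        return (
            f"score={self.score};verdict={self.verdict};"
            f"callers={len(self.supporting_callers)};criteria={crit or 'none'}"
        )

    @property
    def caller_id(self) -> str:
        return "consensus"


def merge_predictions(calls: list[FeatureCall]) -> list[OrfCandidate]:
    """Group CDS calls by (genome, strand, stop coordinate)."""
    groups: dict[tuple[str, str, int], list[FeatureCall]] = {}
    for c in calls:
        if c.call_type != "CDS":
            continue
        stop = c.end if c.strand == "+" else c.start
        groups.setdefault((c.genome_id, c.strand, stop), []).append(c)
    out = []
    for (genome_id, strand, stop), members in sorted(groups.items()):
        starts = [m.start for m in members]
        ends = [m.end for m in members]
        out.append(
            OrfCandidate(
                genome_id,
                min(starts),
                max(ends),
                strand,
                stop,
                frozenset(m.caller_id for m in members),
            )
        )
    out.sort(key=lambda c: (c.genome_id, c.start, c.end, c.strand))
    return out


# ---------------------------------------------------------------------------
# hexamer coding-potential model
# ---------------------------------------------------------------------------

_BASE_IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


def _hexamer_counts(seq: str) -> np.ndarray:
    """In-frame (step 3) hexamer counts; windows containing N are skipped."""
    counts = np.zeros(4096, dtype=np.float64)
    raw = seq.encode()
    for i in range(0, len(raw) - 5, 3):
        code = 0
        ok = True
        for b in raw[i : i + 6]:
            v = _BASE_IDX.get(b)
            if v is None:
                ok = False
                break
            code = (code << 2) | v
        if ok:
            counts[code] += 1
    return counts


@dataclass
class HexamerModel:
    log_odds: np.ndarray  # 4096-vector, log2 p_coding(h) / (1/4096)

    def score(self, seq: str) -> float | None:
        """Mean per-hexamer log-odds; None if no valid hexamer."""
        counts = _hexamer_counts(seq)
        n = counts.sum()
        if n == 0:
            return None
        return float((counts * self.log_odds).sum() / n)


def train_hexamer_model(
    coding_seqs: list[str], pseudocount: float = 1.0
) -> HexamerModel:
    counts = np.zeros(4096, dtype=np.float64)
    for s in coding_seqs:
        counts += _hexamer_counts(s)
    probs = (counts + pseudocount) / (counts.sum() + pseudocount * 4096)
    return HexamerModel(np.log2(probs * 4096))


def coding_potential(
    seq: str, model: HexamerModel, min_len_bp: int = 60
) -> float | None:
    """Hexamer log-odds score of a candidate sequence; None below min length."""
    if len(seq) < min_len_bp:
        return None
    return model.score(seq)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_from_criteria(criteria: dict[str, bool]) -> int:
    return sum(bool(criteria[name]) for name in CRITERIA)


@dataclass
class EvidenceContext:
    """Everything score_gene needs: genomes, candidate context, hits, model."""

    genomes: dict[str, GenomeRecord]
    candidates: list[OrfCandidate]
    n_predictors: int
    hits: pd.DataFrame | None = None
    config: ConsensusConfig = field(default_factory=ConsensusConfig)
    models: dict[str, HexamerModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_genome: dict[str, list[OrfCandidate]] = {}
        for c in self.candidates:
            self.by_genome.setdefault(c.genome_id, []).append(c)
        for lst in self.by_genome.values():
            lst.sort(key=lambda c: (c.start, c.end))
        if not self.models:
            self._train_models()

    def _train_models(self) -> None:
        majority = math.ceil(self.n_predictors / 2)
        for genome_id, cands in self.by_genome.items():
            genome = self.genomes.get(genome_id)
            if genome is None:
                continue
            train = [
                self.candidate_sequence(c)
                for c in cands
                if len(c.supporting_callers) >= majority
            ]
            if not train:  # fall back on every candidate
                train = [self.candidate_sequence(c) for c in cands]
            self.models[genome_id] = train_hexamer_model(
                train, self.config.hexamer_pseudocount
            )

    def candidate_sequence(self, cand: OrfCandidate) -> str:
        genome = self.genomes[cand.genome_id]
        sub = genome.sequence[cand.start - 1 : cand.end]
        return sub if cand.strand == "+" else reverse_complement(sub)

    def has_hit(self, cand: OrfCandidate) -> bool:
        if self.hits is None or self.hits.empty:
            return False
        h = self.hits
        sel = (
            (h["genome_id"] == cand.genome_id)
            & (h["strand"] == cand.strand)
            & (h["start"] <= cand.end)
            & (h["end"] >= cand.start)
            & (h["e_value"] < self.config.homology_evalue)
        )
        return bool(sel.any())


def _overlap_bp(a: OrfCandidate, b: OrfCandidate) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def score_gene(cand: OrfCandidate, evidence: EvidenceContext) -> ConsensusGene:
    """Score one candidate on the six criteria."""
    cfg = evidence.config
    if cand.genome_id not in evidence.genomes:
        raise KeyError(f"genome {cand.genome_id!r} not in evidence context")
    neighbors = [c for c in evidence.by_genome.get(cand.genome_id, []) if c is not cand]

    caller_support = len(cand.supporting_callers) >= math.ceil(evidence.n_predictors / 2)
    length_ok = cand.candidate_length_bp >= cfg.min_length_bp
    overlap_ok = all(
        _overlap_bp(cand, other) <= cfg.max_overlap_bp
        for other in neighbors
        if len(other.supporting_callers) > len(cand.supporting_callers)
    )
    homology_hit = evidence.has_hit(cand)
    model = evidence.models.get(cand.genome_id)
    pot = (
        coding_potential(
            evidence.candidate_sequence(cand), model, cfg.min_coding_len_bp
        )
        if model is not None
        else None
    )
    coding_ok = pot is not None and pot > 0
    in_operon = any(
        other.strand == cand.strand
        and (
            0 <= other.start - cand.end - 1 <= cfg.operon_distance_bp
            or 0 <= cand.start - other.end - 1 <= cfg.operon_distance_bp
        )
        for other in neighbors
    )
    criteria = {
        "caller_support": caller_support,
        "length_ok": length_ok,
        "overlap_ok": overlap_ok,
        "homology_hit": homology_hit,
        "coding_potential_ok": coding_ok,
        "in_operon": in_operon,
    }
    score = score_from_criteria(criteria)
    if score >= cfg.keep_score:
        verdict = "kept"
    elif homology_hit or len(cand.supporting_callers) >= cfg.rescue_min_callers:
        verdict = "rescued"
    else:
        verdict = "dropped"
    return ConsensusGene(
        cand.genome_id,
        cand.start,
        cand.end,
        cand.strand,
        cand.supporting_callers,
        criteria,
        score,
        verdict,
    )


def consensus_annotate(
    calls: list[FeatureCall],
    genomes: list[GenomeRecord],
    hits: pd.DataFrame | None = None,
    n_predictors: int | None = None,
    config: ConsensusConfig | None = None,
    include_dropped: bool = False,
) -> list[ConsensusGene]:
    """Merge, score and filter multi-predictor calls into consensus genes."""
    config = config or ConsensusConfig()
    candidates = merge_predictions(calls)
    n_pred = n_predictors or len({c.caller_id for c in calls}) or 1
    ctx = EvidenceContext(
        {g.genome_id: g for g in genomes}, candidates, n_pred, hits, config
    )
    scored = [score_gene(c, ctx) for c in candidates]
    if not include_dropped:
        scored = [g for g in scored if g.verdict != "dropped"]
    scored.sort(key=lambda g: (g.genome_id, g.start, g.end))
    return scored


def read_hits_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HITS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
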