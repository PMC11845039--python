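from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest

from pancomp.genome_io import FeatureCall, GenomeRecord
from pancomp.orf_consensus import (
    CRITERIA,
    ConsensusConfig,
    EvidenceContext,
    OrfCandidate,
    coding_potential,
    consensus_annotate,
    merge_predictions,
    score_from_criteria,
    score_gene,
    train_hexamer_model,
)
from pancomp.synthetic_phage import (
    SimConfig,
    simulate_family_set,
    simulate_predictor_calls,
)

from conftest import random_dna


class TestMergePredictions:
    def test_stop_anchored_merge(self):
        calls = [
            FeatureCall("g", 100, 400, "+", "c1"),
            FeatureCall("g", 130, 400, "+", "c2"),
            FeatureCall("g", 100, 400, "+", "c3"),
        ]
        cands = merge_predictions(calls)
        assert len(cands) == 1
        assert cands[0].supporting_callers == frozenset({"c1", "c2", "c3"})
        assert cands[0].start == 100  # most-upstream called start
        assert cands[0].stop_coordinate == 400

    def test_opposite_strands_not_merged(self):
        calls = [
            FeatureCall("g", 100, 400, "+", "c1"),
            FeatureCall("g", 100, 400, "-", "c2"),
        ]
        assert len(merge_predictions(calls)) == 2

    def test_minus_strand_stop_is_start_coordinate(self):
        calls = [
            FeatureCall("g", 100, 400, "-", "c1"),
            FeatureCall("g", 100, 370, "-", "c2"),  # jittered 5' end
        ]
        cands = merge_predictions(calls)
        assert len(cands) == 1
        assert cands[0].stop_coordinate == 100
        assert cands[0].end == 400

    def test_non_cds_ignored(self):
        calls = [FeatureCall("g", 1, 70, "+", "c1", "tRNA")]
        assert merge_predictions(calls) == []

    def test_noiseless_simulation_one_candidate_per_gene(self):
        cfg = SimConfig(
            n_families=1, genera_per_family=1, species_per_genus=1,
            genomes_per_species=2, genome_length_bp=12000, gene_length_mean_bp=600,
            predictor_sensitivity=1.0, predictor_fp_per_genome=0.0,
            start_jitter_prob=0.0, genome_length_cv=0.0, seed=13,
        )
        _, truth = simulate_family_set(cfg)
        calls = simulate_predictor_calls(truth, 8, cfg)
        cands = merge_predictions(calls)
        n_genes = sum(len(v) for v in truth.genes.values())
        assert len(cands) == n_genes
        assert all(len(c.supporting_callers) == 8 for c in cands)


class TestCodingPotential:
    def test_sequences_from_model_score_positive(self, rng):
        """Sequences drawn from a biased hexamer source score positive under
        the model trained on that source (Monte-Carlo)."""
        biased = lambda n: "".join(
            ["ATGGCA", "GCAGAA", "AAAGCT"][int(rng.integers(0, 3))] for _ in range(n // 6)
        )
        train = [biased(300) for _ in range(50)]
        model = train_hexamer_model(train)
        scores = [coding_potential(biased(120), model) for _ in range(200)]
        assert np.mean(scores) > 1.0

    def test_uniform_random_scores_near_zero_under_uniform_model(self, rng):
        """A model trained on uniform-random sequence is the null: scoring
        fresh uniform sequence gives mean log-odds ~0."""
        model = train_hexamer_model([random_dna(rng, 3000) for _ in range(60)])
        scores = [coding_potential(random_dna(rng, 300), model) for _ in range(300)]
        assert abs(np.mean(scores)) < 0.1

    def test_short_sequence_undefined(self, rng):
        model = train_hexamer_model([random_dna(rng, 300)])
        assert coding_potential(random_dna(rng, 59), model) is None


class TestScoreGene:
    def _ctx(self, rng, n_candidates=3):
        genome = GenomeRecord("g", random_dna(rng, 5000))
        cands = [
            OrfCandidate("g", 1 + 700 * i, 600 + 700 * i, "+", 600 + 700 * i,
                         frozenset({f"c{j}" for j in range(4)}))
            for i in range(n_candidates)
        ]
        return EvidenceContext({"g": genome}, cands, 8)

    def test_score_counts_true_criteria_all_64_combinations(self):
        """score equals the number of satisfied criteria for every one of
        the 2^6 evidence combinations (exhaustive enumeration)."""
        for bits in product([False, True], repeat=6):
            criteria = dict(zip(CRITERIA, bits))
            assert score_from_criteria(criteria) == sum(bits)

    def test_all_true_scores_six(self, rng):
        genome_seq = random_dna(rng, 3000)
        gene = "ATG" + "GCAGAA" * 149 + "TAA"  # 900 bp, hexamer-regular
        seq = genome_seq[:100] + gene + genome_seq[100:]
        genome = GenomeRecord("g", seq)
        cand = OrfCandidate("g", 101, 1000, "+", 1000, frozenset({f"c{i}" for i in range(8)}))
        neighbor = OrfCandidate("g", 1010, 1600, "+", 1600, frozenset({"c0"}))
        hits = pd.DataFrame(
            [("g", 101, 1000, "+", 1e-20, "terminase")],
            columns=["genome_id", "start", "end", "strand", "e_value", "subject_desc"],
        )
        ctx = EvidenceContext({"g": genome}, [cand, neighbor], 8, hits)
        scored = score_gene(cand, ctx)
        assert scored.score == 6
        assert scored.verdict == "kept"

    def test_all_false_scores_zero(self, rng):
        genome = GenomeRecord("g", random_dna(rng, 3000))
        strong = OrfCandidate("g", 500, 1400, "+", 1400, frozenset({f"c{i}" for i in range(8)}))
        # 90 bp single-caller call buried inside the strong gene, no hit
        weak = OrfCandidate("g", 600, 689, "+", 689, frozenset({"c0"}))
        ctx = EvidenceContext({"g": genome}, [strong, weak], 8)
        scored = score_gene(weak, ctx)
        assert scored.criteria["caller_support"] is False
        assert scored.criteria["length_ok"] is False
        assert scored.criteria["overlap_ok"] is False
        assert scored.criteria["homology_hit"] is False
        assert scored.verdict == "dropped"

    def test_unknown_genome_raises(self, rng):
        ctx = self._ctx(rng)
        stray = OrfCandidate("missing", 1, 300, "+", 300, frozenset({"c1"}))
        with pytest.raises(KeyError):
            score_gene(stray, ctx)


class TestVerdictRules:
    def _scored(self, score, has_hit, n_callers):
        """Drive the verdict logic through consensus_annotate-equivalent rules."""
        cfg = ConsensusConfig()
        if score >= cfg.keep_score:
            return "kept"
        if has_hit or n_callers >= cfg.rescue_min_callers:
            return "rescued"
        return "dropped"

    @pytest.mark.parametrize(
        "score,has_hit,n_callers,expected",
        [
            (3, False, 1, "kept"),  # >= 3 kept regardless of evidence
            (6, True, 8, "kept"),
            (1, True, 1, "rescued"),  # low score survives on a homology hit
            (2, False, 2, "rescued"),  # or on >= 2 supporting callers
            (2, False, 1, "dropped"),
            (0, False, 1, "dropped"),
        ],
    )
    def test_keep_rescue_drop(self, score, has_hit, n_callers, expected):
        assert self._scored(score, has_hit, n_callers) == expected

    def test_monotonicity_adding_hit_never_drops(self, rng):
        """A candidate that is kept or rescued stays so when a homology hit
        is added (the hit can only raise the score and enable rescue)."""
        genome = GenomeRecord("g", random_dna(rng, 4000))
        cands = [
            OrfCandidate("g", 100, 699, "+", 699, frozenset({"c0"})),
            OrfCandidate("g", 1000, 1899, "+", 1899, frozenset({"c0", "c1", "c2"})),
        ]
        hits = pd.DataFrame(
            [("g", 100, 699, "+", 1e-10, "x"), ("g", 1000, 1899, "+", 1e-10, "y")],
            columns=["genome_id", "start", "end", "strand", "e_value", "subject_desc"],
        )
        order = {"dropped": 0, "rescued": 1, "kept": 2}
        for cand in cands:
            without = score_gene(cand, EvidenceContext({"g": genome}, list(cands), 8))
            withhit = score_gene(cand, EvidenceContext({"g": genome}, list(cands), 8, hits))
            assert order[withhit.verdict] >= order[without.verdict]


class TestConsensusAnnotate:
    def test_noiseless_exact_recovery(self):
        cfg = SimConfig(
            n_families=1, genera_per_family=1, species_per_genus=1,
            genomes_per_species=3, genome_length_bp=10000, gene_length_mean_bp=600,
            predictor_sensitivity=1.0, predictor_fp_per_genome=0.0,
            start_jitter_prob=0.0, genome_length_cv=0.0, seed=21,
        )
        genomes, truth = simulate_family_set(cfg)
        calls = simulate_predictor_calls(truth, 8, cfg)
        genes = consensus_annotate(calls, genomes, n_predictors=8)
        got = {(g.genome_id, g.start, g.end, g.strand) for g in genes}
        want = {
            (t.genome_id, t.start, t.end, t.strand)
            for glist in truth.genes.values()
            for t in glist
        }
        assert got == want

    def test_single_caller_false_positives_mostly_dropped(self):
        """At sensitivity 0.9 with ~2 single-caller false ORFs per genome and
        no homology table, false candidates are dropped at a high rate."""
        cfg = SimConfig(
            n_families=1, genera_per_family=1, species_per_genus=1,
            genomes_per_species=3, genome_length_bp=10000, gene_length_mean_bp=600,
            predictor_sensitivity=0.9, predictor_fp_per_genome=2.0,
            genome_length_cv=0.0, seed=22,
        )
        genomes, truth = simulate_family_set(cfg)
        true_stops = {
            (t.genome_id, t.strand, t.end if t.strand == "+" else t.start)
            for glist in truth.genes.values()
            for t in glist
        }
        n_false = n_dropped = 0
        for seed in range(10):
            calls = simulate_predictor_calls(truth, 8, cfg, seed=seed)
            genes = consensus_annotate(
                calls, genomes, n_predictors=8, include_dropped=True
            )
            for g in genes:
                stop = g.end if g.strand == "+" else g.start
                if (g.genome_id, g.strand, stop) not in true_stops:
                    n_false += 1
                    n_dropped += g.verdict == "dropped"
        assert n_false > 0
        assert n_dropped / n_false >= 0.9
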