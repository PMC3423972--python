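"""Trial enumeration, subcluster extraction, and consensus ranking."""

import numpy as np
import pytest

from chemoconsensus import (
    ChemGenMatrix,
    CutK,
    IdentifierError,
    LINKAGES,
    MEASURES,
    MinSize,
    ParameterError,
    SimParams,
    TrialSpec,
    cluster,
    consensus_rank,
    default_min_size,
    enumerate_trials,
    generate,
    pairwise_distance,
    parse_policy,
    signature_subcluster,
)


class TestEnumerateTrials:
    def test_full_grid_is_28(self):
        trials = enumerate_trials(MEASURES, LINKAGES)
        assert len(trials) == 28
        assert len(set(trials)) == 28

    def test_single_pair(self):
        assert enumerate_trials(["euclidean"], ["single"]) == [
            TrialSpec("euclidean", "single")
        ]

    def test_excluding_nine_leaves_nineteen(self):
        exclude = enumerate_trials(MEASURES[:3], LINKAGES[:3])  # any 9 pairs
        trials = enumerate_trials(MEASURES, LINKAGES, exclude)
        assert len(trials) == 19
        assert not set(exclude) & set(trials)

    def test_measures_major_order(self):
        trials = enumerate_trials(MEASURES[:2], LINKAGES[:2])
        assert [str(t) for t in trials] == [
            f"{MEASURES[0]}:{LINKAGES[0]}", f"{MEASURES[0]}:{LINKAGES[1]}",
            f"{MEASURES[1]}:{LINKAGES[0]}", f"{MEASURES[1]}:{LINKAGES[1]}",
        ]

    def test_unknown_names_rejected(self):
        with pytest.raises(ParameterError):
            enumerate_trials(["euclidean", "mystery"], LINKAGES)
        with pytest.raises(ParameterError):
            enumerate_trials(MEASURES, ["ward"])
        with pytest.raises(ParameterError):
            enumerate_trials([], LINKAGES)


class TestSignatureSubcluster:
    @pytest.fixture()
    def line_tree(self):
        vals = np.array([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0]])
        m = ChemGenMatrix(["sig", "near", "far"], ["g0", "g1"], vals)
        return cluster(pairwise_distance(m, "euclidean"), "single")

    def test_cut_k_block(self, line_tree):
        assert signature_subcluster(line_tree, "sig", CutK(2)) == {"sig", "near"}

    def test_min_size_one_is_signature_alone(self, line_tree):
        assert signature_subcluster(line_tree, "sig", MinSize(1)) == {"sig"}

    def test_min_size_n_is_everything(self, line_tree):
        assert signature_subcluster(line_tree, "sig", MinSize(3)) == {
            "sig", "near", "far"
        }

    def test_min_size_two_walks_one_level(self, line_tree):
        assert signature_subcluster(line_tree, "sig", MinSize(2)) == {"sig", "near"}

    def test_missing_signature_rejected(self, line_tree):
        with pytest.raises(IdentifierError):
            signature_subcluster(line_tree, "ghost", MinSize(2))

    def test_policy_parsing(self):
        assert parse_policy("min_size:8") == MinSize(8)
        assert parse_policy("cut_k:5") == CutK(5)
        with pytest.raises(ParameterError):
            parse_policy("nearest:3")

    def test_default_window_scales_with_n(self):
        assert default_min_size(20) == 2
        assert default_min_size(100) == 5
        assert default_min_size(3000) == 150


class TestConsensusRank:
    def test_duplicate_profile_always_co_clusters(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=(8, 30))
        vals[1] = vals[0]  # compound "twin" duplicates the signature
        ids = ["sig", "twin"] + [f"c{i}" for i in range(6)]
        m = ChemGenMatrix(ids, [f"g{j}" for j in range(30)], vals)
        trials = enumerate_trials(MEASURES, LINKAGES)
        r = consensus_rank(m, "sig", trials, MinSize(2))
        assert r.frequency["twin"] == 1.0
        assert r.frequency["sig"] == 1.0
        assert r.top(1) == ["twin"]

    def test_single_trial_min_size_one(self, planted_screen):
        m, truth = planted_screen
        r = consensus_rank(m, truth.signature_id,
                           [TrialSpec("euclidean", "average")], MinSize(1))
        assert r.trials_run == 1
        for c, f in r.frequency.items():
            assert f == (1.0 if c == truth.signature_id else 0.0)

    @pytest.mark.parametrize("seed", [0, 11, 23])
    def test_planted_module_tops_ranking(self, seed):
        """With a tight subcluster window the planted trio is recovered."""
        m, truth = generate(SimParams(seed=seed))
        trials = enumerate_trials(MEASURES, LINKAGES)
        r = consensus_rank(m, truth.signature_id, trials, MinSize(4))
        expected = sorted(truth.module_compound_ids - {truth.signature_id})
        assert sorted(r.top(3)) == expected

    def test_frequencies_bounded_and_signature_is_one(self, planted_screen):
        m, truth = planted_screen
        trials = enumerate_trials(MEASURES[:3], LINKAGES)
        r = consensus_rank(m, truth.signature_id, trials, MinSize(5))
        assert r.frequency[truth.signature_id] == 1.0
        assert all(0.0 <= f <= 1.0 for f in r.frequency.values())
        assert r.trials_run == len(trials)

    def test_adding_a_trial_moves_frequencies_by_at_most_one_slot(self, planted_screen):
        m, truth = planted_screen
        base = enumerate_trials(MEASURES, LINKAGES)[:10]
        extra = base + [TrialSpec("cityblock", "centroid")]
        r1 = consensus_rank(m, truth.signature_id, base, MinSize(6))
        r2 = consensus_rank(m, truth.signature_id, extra, MinSize(6))
        bound = 1.0 / r2.trials_run + 1e-12
        for c in m.compound_ids:
            assert abs(r1.frequency[c] - r2.frequency[c]) <= bound

    def test_relabeling_equivariance(self, planted_screen):
        m, truth = planted_screen
        relabel = {c: f"X_{c}" for c in m.compound_ids}
        m2 = ChemGenMatrix([relabel[c] for c in m.compound_ids],
                           m.gene_ids, m.values, m.mask)
        trials = enumerate_trials(MEASURES[:4], LINKAGES[:2])
        r1 = consensus_rank(m, truth.signature_id, trials, MinSize(6))
        r2 = consensus_rank(m2, relabel[truth.signature_id], trials, MinSize(6))
        for c in m.compound_ids:
            assert r1.frequency[c] == r2.frequency[relabel[c]]

    def test_degenerate_trial_skipped_and_excluded_from_denominator(self):
        # two compounds share no genes -> euclidean/cityblock trials degenerate
        vals = np.array([
            [0.1, 0.2, np.nan, np.nan],
            [np.nan, np.nan, 0.3, 0.4],
            [0.1, 0.3, 0.2, 0.5],
        ])
        m = ChemGenMatrix(["sig", "b", "c"], list("wxyz"), vals)
        trials = enumerate_trials(["euclidean", "centered_corr"], ["single"])
        r = consensus_rank(m, "sig", trials, MinSize(2))
        assert [str(t) for t in r.skipped] == ["euclidean:single"]
        assert r.trials_run == 1
        assert set(r.per_trial_members) == {TrialSpec("centered_corr", "single")}

    def test_missing_signature_rejected(self, planted_screen):
        m, _ = planted_screen
        with pytest.raises(IdentifierError):
            consensus_rank(m, "nope", enumerate_trials(MEASURES[:1], LINKAGES[:1]))

    def test_ranking_frame_schema(self, planted_screen):
        m, truth = planted_screen
        r = consensus_rank(m, truth.signature_id,
                           enumerate_trials(MEASURES[:2], LINKAGES[:2]), MinSize(4))
        df = r.to_frame()
        assert list(df.columns) == ["rank", "compound_id", "frequency", "n_trials"]
        assert len(df) == len(m.compound_ids)
        assert df["frequency"].is_monotonic_decreasing
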