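"""Consensus-line selection, ranks, and threshold combinators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from docktriage import (ConfigError, DataError, ScoreCloud, ThresholdSpec,
                        apply_threshold, cloud_for_drug, cloud_for_protein,
                        compute_ranks, consensus_select)

from conftest import random_matrix
from oracles import oracle_consensus, oracle_ranks

COARSE_SLOPES = -np.arange(1.0, 40.5, 1.0)
COARSE_INTERCEPTS = -np.arange(0.0, 401.0, 5.0)


def make_cloud(rng, n):
    icm = -rng.uniform(0, 60, n)
    pmf = -rng.uniform(0, 300, n)
    return ScoreCloud(ids=[f"d{i}" for i in range(n)], icm=icm, pmf=pmf)


class TestConsensusSelect:
    def test_full_fraction_selects_every_point(self):
        rng = np.random.default_rng(0)
        cloud = make_cloud(rng, 30)
        line = consensus_select(cloud, 1.0)
        assert set(line.selected_ids) == set(cloud.ids)

    def test_two_outliers_selected_at_fraction_point_two(self):
        """The jointly good-scoring tail is kept, the dense bulk eliminated."""
        rng = np.random.default_rng(1)
        icm = np.array([-60.0, -55.0] + list(-15 + rng.uniform(-2, 2, 8)))
        pmf = np.array([-200.0, -180.0] + list(-60 + rng.uniform(-5, 5, 8)))
        ids = [f"d{i}" for i in range(10)]
        cloud = ScoreCloud(ids=ids, icm=icm, pmf=pmf)
        line = consensus_select(cloud, 0.2, COARSE_SLOPES, COARSE_INTERCEPTS)
        assert set(line.selected_ids) == {"d0", "d1"}
        _, _, oracle_sel, _ = oracle_consensus(ids, icm, pmf, 0.2,
                                               COARSE_SLOPES,
                                               COARSE_INTERCEPTS)
        assert oracle_sel == {"d0", "d1"}

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        cloud = make_cloud(rng, n)
        frac = float(rng.choice([0.05, 0.1, 0.25]))
        line = consensus_select(cloud, frac, COARSE_SLOPES, COARSE_INTERCEPTS)
        s, c, sel, dens = oracle_consensus(cloud.ids, cloud.icm, cloud.pmf,
                                           frac, COARSE_SLOPES,
                                           COARSE_INTERCEPTS)
        assert set(line.selected_ids) == sel
        assert line.eliminated_density == pytest.approx(dens, rel=1e-3, abs=1e-9)

    def test_selected_count_tracks_target_fraction(self):
        rng = np.random.default_rng(5)
        cloud = make_cloud(rng, 400)
        for frac in (0.05, 0.01):
            line = consensus_select(cloud, frac)
            assert line.n_selected == pytest.approx(round(frac * 400), abs=2)

    def test_empty_cloud_errors_and_tiny_fraction_warns(self):
        with pytest.raises(DataError):
            ScoreCloud(ids=[], icm=[], pmf=[])
        rng = np.random.default_rng(2)
        cloud = make_cloud(rng, 20)
        with pytest.warns(UserWarning, match="single best point"):
            line = consensus_select(cloud, 0.001)
        assert line.n_selected >= 1

    def test_invalid_fraction_rejected(self):
        rng = np.random.default_rng(3)
        cloud = make_cloud(rng, 10)
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ConfigError):
                consensus_select(cloud, bad)


class TestRanks:
    def test_single_cell_matrix_ranks_one(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 1, 1)
        ranks = compute_ranks(m)
        assert ranks.drug_rank.iloc[0, 0] == 1
        assert ranks.protein_rank_icm.iloc[0, 0] == 1
        assert ranks.protein_rank_pmf.iloc[0, 0] == 1

    def test_tie_breaks_lexicographically(self):
        from docktriage import ScoreMatrix
        icm = pd.DataFrame([[-40.0, -35.0, -35.0, -10.0]], index=["p"],
                           columns=["d1", "d2", "d3", "d4"])
        m = ScoreMatrix(icm=icm, pmf=icm * 3, provenance=pd.DataFrame())
        ranks = compute_ranks(m)
        assert list(ranks.drug_rank.loc["p"]) == [1, 2, 3, 4]

    def test_drug_ranks_are_exact_permutations(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 50, 80)
        ranks = compute_ranks(m)
        for protein in m.proteins:
            assert sorted(ranks.drug_rank.loc[protein]) == list(range(1, 81))
        for drug in m.drugs:
            assert sorted(ranks.protein_rank_icm[drug]) == list(range(1, 51))
            assert sorted(ranks.protein_rank_pmf[drug]) == list(range(1, 51))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 8, 12)
        ranks = compute_ranks(m)
        expect = oracle_ranks(m.icm, "row")
        for (p, d), r in expect.items():
            assert ranks.drug_rank.at[p, d] == r
        expect_icm = oracle_ranks(m.icm, "col")
        expect_pmf = oracle_ranks(m.pmf, "col")
        for (d, p), r in expect_icm.items():
            assert ranks.protein_rank_icm.at[p, d] == r
        for (d, p), r in expect_pmf.items():
            assert ranks.protein_rank_pmf.at[p, d] == r

    def test_ranks_skip_missing_pairs(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 4, 6)
        m.icm.iloc[0, 0] = np.nan
        m.pmf.iloc[0, 0] = np.nan
        ranks = compute_ranks(m)
        assert np.isnan(ranks.drug_rank.iloc[0, 0])
        assert sorted(ranks.drug_rank.iloc[0].dropna()) == list(range(1, 6))


class TestApplyThreshold:
    def test_single_pair_passing_plain_icm_cutoff(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 3, 4)
        m.icm.iloc[:, :] = -10.0
        m.icm.iloc[1, 2] = -31.0
        predicted = apply_threshold(ThresholdSpec(icm_max=-30.0), m)
        assert predicted == {(m.proteins[1], m.drugs[2])}

    def test_drug_rank_one_gives_one_pair_per_protein(self):
        rng = np.random.default_rng(12)
        m = random_matrix(rng, 25, 40)
        ranks = compute_ranks(m)
        predicted = apply_threshold(ThresholdSpec(drug_rank_max=1), m, ranks)
        assert len(predicted) == 25
        assert len({p for p, _ in predicted}) == 25

    def test_rank_one_intersection_matches_argmin_oracle(self):
        rng = np.random.default_rng(13)
        m = random_matrix(rng, 30, 50)
        ranks = compute_ranks(m)
        predicted = apply_threshold(
            ThresholdSpec(drug_rank_max=1, protein_rank_max=1), m, ranks)
        per_protein_best = {(p, m.icm.loc[p].idxmin()) for p in m.proteins}
        per_drug_best = ({(m.icm[d].idxmin(), d) for d in m.drugs}
                         | {(m.pmf[d].idxmin(), d) for d in m.drugs})
        assert predicted == per_protein_best & per_drug_best

    def test_protein_rank_passes_under_either_basis(self):
        from docktriage import ScoreMatrix
        icm = pd.DataFrame([[-40.0], [-20.0]], index=["pA", "pB"],
                           columns=["d"])
        pmf = pd.DataFrame([[-100.0], [-250.0]], index=["pA", "pB"],
                           columns=["d"])
        m = ScoreMatrix(icm=icm, pmf=pmf, provenance=pd.DataFrame())
        ranks = compute_ranks(m)
        predicted = apply_threshold(ThresholdSpec(protein_rank_max=1), m,
                                    ranks)
        # pA is rank 1 by icm, pB is rank 1 by pmf: both pass
        assert predicted == {("pA", "d"), ("pB", "d")}

    def test_known_binder_worst_icm_cutoff(self, small_matrix, small_known):
        from docktriage import compute_ranks as cr
        spec = ThresholdSpec(known_cutoff=("worst", "icm"))
        predicted = apply_threshold(spec, small_matrix, known=small_known)
        for protein in small_matrix.proteins:
            binders = [d for (p, d) in small_known.pairs if p == protein]
            if not binders:
                assert not any(p == protein for p, _ in predicted)
                continue
            cutoff = max(small_matrix.icm.at[protein, d] for d in binders)
            expect = {(protein, d) for d in small_matrix.drugs
                      if small_matrix.icm.at[protein, d] <= cutoff}
            assert {pd_ for pd_ in predicted if pd_[0] == protein} == expect

    def test_spec_without_criteria_rejected(self):
        with pytest.raises(ConfigError):
            ThresholdSpec()

    @pytest.mark.parametrize("loose,tight", [
        (ThresholdSpec(icm_max=-20.0), ThresholdSpec(icm_max=-30.0)),
        (ThresholdSpec(drug_rank_max=10), ThresholdSpec(drug_rank_max=3)),
        (ThresholdSpec(rank_sum_max=20), ThresholdSpec(rank_sum_max=4)),
        (ThresholdSpec(icm_max=-20.0),
         ThresholdSpec(icm_max=-20.0, pmf_max=-100.0)),
    ])
    def test_tightening_a_criterion_never_enlarges_the_set(self, loose,
                                                           tight):
        rng = np.random.default_rng(17)
        m = random_matrix(rng, 15, 30)
        ranks = compute_ranks(m)
        assert apply_threshold(tight, m, ranks) <= apply_threshold(loose, m,
                                                                   ranks)

    def test_consensus_criterion_selects_per_cloud(self, small_matrix):
        spec = ThresholdSpec(consensus_fraction=0.1)
        predicted = apply_threshold(spec, small_matrix,
                                    slope_grid=COARSE_SLOPES,
                                    intercept_grid=COARSE_INTERCEPTS)
        for protein in small_matrix.proteins:
            cloud = cloud_for_protein(small_matrix, protein)
            line = consensus_select(cloud, 0.1, COARSE_SLOPES,
                                    COARSE_INTERCEPTS)
            assert {d for p, d in predicted if p == protein} == \
                set(line.selected_ids)


def test_cloud_views_are_transposes(small_matrix):
    protein = small_matrix.proteins[0]
    drug = small_matrix.drugs[0]
    row = cloud_for_protein(small_matrix, protein)
    col = cloud_for_drug(small_matrix, drug)
    assert row.axis_label == "per-protein"
    assert col.axis_label == "per-drug"
    assert row.icm[row.ids.index(drug)] == col.icm[col.ids.index(protein)]
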