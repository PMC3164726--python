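"""PPV / enrichment arithmetic, sweeps, comparison tables."""

import math

import numpy as np
import pytest

from docktriage import (ConfigError, KnownInteractions, ThresholdSpec,
                        apply_threshold, compute_ranks, evaluate,
                        evaluate_counts, format_ef, format_ppv,
                        make_comparison_table, threshold_sweep)

from conftest import random_matrix


class TestEvaluateCounts:
    def test_full_universe_is_the_random_baseline(self):
        res = evaluate_counts(1000, 10, 1000, 10)
        assert res.ppv == pytest.approx(1.0)
        assert res.ef_random == pytest.approx(1.0)

    def test_standard_score_cutoff_row_arithmetic(self):
        # 104,625 predicted, 1116 known of 1,164,492 docked pairs
        res = evaluate_counts(104625, 1116, 1164492, 1116)
        assert round(res.ppv, 1) == 1.1
        assert round(res.ef_random) == 11

    def test_enrichment_from_unrounded_chain(self):
        # 22 known of 45 predicted; chaining printed roundings would give
        # 488, the unrounded ratio gives the correct 510
        res = evaluate_counts(45, 22, 1164492, 1116)
        assert res.ef_random == pytest.approx(510.1, abs=0.05)
        assert format_ef(res.ef_random) == "510"

    def test_small_cloud_enrichment(self):
        # 6 known of 18 predicted within a 4621-drug cloud holding 14 known
        res = evaluate_counts(18, 6, 4621, 14)
        assert round(res.ef_random) == 110

    def test_empty_prediction_set_is_not_applicable(self):
        res = evaluate_counts(0, 0, 100, 5)
        assert math.isnan(res.ppv) and math.isnan(res.ef_random)
        assert format_ppv(res.ppv) == "n/a"

    def test_internal_consistency_of_emitted_ratios(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_total = int(rng.integers(10, 10000))
            n_known = int(rng.integers(1, n_total + 1))
            n_pred = int(rng.integers(1, n_total + 1))
            k = int(rng.integers(0, min(n_pred, n_known) + 1))
            res = evaluate_counts(n_pred, k, n_total, n_known)
            assert res.ppv == pytest.approx(100 * k / n_pred)
            assert res.ef_random == pytest.approx(
                (k / n_pred) / (n_known / n_total))

    def test_count_invariants_enforced(self):
        from docktriage import DataError
        with pytest.raises(DataError):
            evaluate_counts(5, 6, 100, 10)
        with pytest.raises(DataError):
            evaluate_counts(200, 5, 100, 10)


def test_evaluate_counts_sets_and_proteins(small_matrix, small_known):
    predicted = {(p, d) for p, d in small_known.pairs}
    res = evaluate(predicted, small_known, small_matrix.n_pairs)
    assert res.n_predicted == len(small_known.pairs)
    assert res.n_known_in_predicted == len(small_known.pairs)
    assert res.ppv == pytest.approx(100.0)
    assert res.n_proteins_in_predicted == len({p for p, _ in
                                               small_known.pairs})


class TestFormatting:
    def test_ppv_one_decimal(self):
        assert format_ppv(10.297) == "10.3%"
        assert format_ppv(0.0958) == "0.1%"

    def test_ef_one_decimal_below_twenty_integer_above(self):
        assert format_ef(12.64) == "12.6"
        assert format_ef(19.96) == "20.0"
        assert format_ef(20.4) == "20"
        assert format_ef(107.4) == "107"


class TestThresholdSweep:
    def test_predicted_size_monotone_as_icm_tightens(self, small_matrix,
                                                     small_ranks,
                                                     small_known):
        cutoffs = [-20.0, -25.0, -30.0, -35.0, -40.0]
        points = threshold_sweep(small_matrix, small_ranks, small_known,
                                 "icm", cutoffs)
        sizes = [res.n_predicted for _, res in points]
        assert sizes == sorted(sizes, reverse=True)

    def test_ppv_improves_toward_tight_cutoffs_with_planted_binders(
            self, small_matrix, small_ranks, small_known):
        points = threshold_sweep(small_matrix, small_ranks, small_known,
                                 "icm", [-15.0, -40.0])
        loose = points[0][1]
        tight = points[-1][1]
        assert tight.ppv >= loose.ppv

    def test_equal_sizes_deduplicated_to_higher_ppv(self, small_matrix,
                                                    small_ranks,
                                                    small_known):
        # -200 and -250 both predict nothing passes... use two very tight
        # cutoffs guaranteed to coincide
        points = threshold_sweep(small_matrix, small_ranks, small_known,
                                 "icm", [-500.0, -600.0])
        assert len(points) == 1

    def test_unknown_family_rejected(self, small_matrix, small_ranks,
                                     small_known):
        with pytest.raises(ConfigError):
            threshold_sweep(small_matrix, small_ranks, small_known,
                            "nonsense", [1])


class TestComparisonTable:
    def test_single_trivial_spec_row(self, small_matrix, small_ranks,
                                     small_known):
        # a cutoff of 0 keeps every docked pair: the random baseline
        table = make_comparison_table(small_matrix, small_ranks, small_known,
                                      [ThresholdSpec(icm_max=0.0)])
        assert len(table) == 1
        assert table.loc[0, "ef_random"] == pytest.approx(1.0)

    def test_rows_sorted_by_increasing_enrichment(self, small_matrix,
                                                  small_ranks, small_known):
        specs = [ThresholdSpec(icm_max=-35.0), ThresholdSpec(icm_max=0.0),
                 ThresholdSpec(drug_rank_max=1)]
        table = make_comparison_table(small_matrix, small_ranks, small_known,
                                      specs)
        efs = table["ef_random"].fillna(-np.inf)
        assert list(efs) == sorted(efs)

    def test_counts_match_independent_set_recount(self, small_matrix,
                                                  small_ranks, small_known):
        specs = [ThresholdSpec(icm_max=-30.0), ThresholdSpec(drug_rank_max=2),
                 ThresholdSpec(icm_max=-25.0, protein_rank_max=3)]
        table = make_comparison_table(small_matrix, small_ranks, small_known,
                                      specs)
        for spec in specs:
            predicted = apply_threshold(spec, small_matrix, small_ranks,
                                        small_known)
            row = table[table["threshold"] == spec.describe()].iloc[0]
            assert row["n_predicted"] == len(predicted)
            assert row["n_known_in_predicted"] == len(predicted
                                                      & small_known.pairs)

    def test_empty_spec_list_rejected(self, small_matrix, small_ranks,
                                      small_known):
        with pytest.raises(ConfigError):
            make_comparison_table(small_matrix, small_ranks, small_known, [])
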