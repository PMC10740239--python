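"""Pair scoring, blocking, clustering and pairwise evaluation."""

import numpy as np
import pandas as pd
import pytest

import labcascade as lc
from labcascade.linkage import (LinkageConfig, block_candidates, cluster_records,
                                dob_similarity, evaluate_linkage, name_similarity,
                                score_pair, score_pairs)


def rec(**kw):
    base = dict(given_name="Thabo", family_name="Nkosi", dob="1970-06-15",
                sex="M", province="GP", facility="GP-D1-F1")
    base.update(kw)
    return base


class TestScorePair:
    def test_identical_records_score_one(self):
        assert score_pair(rec(), rec()) == pytest.approx(1.0)

    def test_fully_disjoint_records_score_zero(self):
        a = rec()
        b = rec(given_name="Zweli", family_name="Pule", dob="1985-01-02",
                sex="F", province="WC", facility="WC-D1-F2")
        # names on disjoint letter sets -> similarity 0
        assert score_pair(a, b) == pytest.approx(0.0)

    def test_single_field_mismatch_weighted_sum(self):
        # all fields equal except province: 1 - 0.05 = 0.95
        assert score_pair(rec(), rec(province="KZN")) == pytest.approx(0.95)

    def test_symmetry(self):
        a, b = rec(), rec(given_name="Thab", dob="1970-06-16", province="KZN")
        assert score_pair(a, b) == pytest.approx(score_pair(b, a))

    def test_dob_partial_credit_single_component(self):
        assert dob_similarity("1970-06-15", "1970-06-16") == 0.5
        assert dob_similarity("1970-06-15", "1971-07-15") == 0.0
        assert dob_similarity("1970-06-15", "1970-06-15",
                              partial_credit=False) == 1.0
        assert dob_similarity("1970-06-15", "1970-06-16",
                              partial_credit=False) == 0.0

    def test_name_similarity_normalized_edit_distance(self):
        assert name_similarity("Nkosi", "Nkosi") == 1.0
        assert name_similarity("Nkosi", "Nkosl") == pytest.approx(1 - 1 / 5)
        assert name_similarity("", "Nkosi") == 0.0


def _frame(rows):
    df = pd.DataFrame([rec(record_id=f"r{k}", **r) for k, r in enumerate(rows)])
    df = df.rename(columns={"facility": "facility_id"})
    df["dob"] = pd.to_datetime(df["dob"])
    return df


class TestBlocking:
    def test_same_dob_and_sex_is_candidate(self):
        df = _frame([{}, {"family_name": "Zulu", "given_name": "Anna"}])
        assert len(block_candidates(df)) == 1

    def test_disjoint_blocks_yield_no_pairs(self):
        df = _frame([{}, {"dob": "1951-02-03", "family_name": "Zulu"}])
        assert len(block_candidates(df)) == 0

    def test_identical_records_all_pairs(self):
        n = 7
        df = _frame([{} for _ in range(n)])
        assert len(block_candidates(df)) == n * (n - 1) // 2


class TestClustering:
    def test_no_edges_all_singletons(self):
        df = _frame([{}, {"dob": "1951-02-03", "family_name": "Zulu",
                          "given_name": "Pear"}])
        mapping = cluster_records(df)
        assert mapping["cluster_id"].nunique() == 2

    def test_transitive_chain_merges_without_refinement(self):
        df = _frame([{}, {}, {}])
        pairs = np.array([[0, 1], [1, 2], [0, 2]])
        scores = np.array([0.9, 0.9, 0.2])
        cfg = LinkageConfig(match_threshold=0.8, refine_components=False)
        mapping = cluster_records(df, cfg, pairs=pairs, scores=scores)
        assert mapping["cluster_id"].nunique() == 1

    def test_refinement_splits_inconsistent_component(self):
        df = _frame([{}, {}, {}])
        pairs = np.array([[0, 1], [1, 2], [0, 2]])
        scores = np.array([0.95, 0.9, 0.2])
        cfg = LinkageConfig(match_threshold=0.8, refine_components=True,
                            max_component_inconsistency=0.25)
        mapping = cluster_records(df, cfg, pairs=pairs, scores=scores)
        # 1/3 of internal candidate pairs are below threshold -> split
        assert mapping["cluster_id"].nunique() == 2

    def test_output_always_partitions_input(self, small_cohort):
        _cfg, records, _truth = small_cohort
        sub = records.head(500).reset_index(drop=True)
        mapping = cluster_records(sub)
        assert sorted(mapping["record_id"]) == sorted(sub["record_id"])
        assert not mapping["record_id"].duplicated().any()

    def test_clean_extract_recovers_truth_partition(self, small_cohort):
        _cfg, records, truth = small_cohort
        mapping = cluster_records(records.reset_index(drop=True))
        ev = evaluate_linkage(mapping, truth.record_map)
        assert ev.sensitivity == 1.0 and ev.ppv == 1.0

    def test_lower_threshold_never_loses_true_pairs(self):
        cfg = lc.SimConfig(n_patients=300, seed=21)
        cfg.corruption = lc.CorruptionSpec(p_char_edit=0.05, p_dob_error=0.03)
        records, truth = lc.generate_cohort(cfg)
        records = lc.corrupt_identities(records, cfg.corruption, seed=22)
        records = records.reset_index(drop=True)
        link_cfg = LinkageConfig(refine_components=False)
        pairs = block_candidates(records, link_cfg)
        scores = score_pairs(records, pairs, link_cfg)
        tps = []
        for thr in (0.95, 0.9, 0.85, 0.8, 0.7, 0.5):
            c = LinkageConfig(match_threshold=thr, refine_components=False)
            mapping = cluster_records(records, c, pairs=pairs, scores=scores)
            tps.append(evaluate_linkage(mapping, truth.record_map)
                       .n_true_positive_pairs)
        assert tps == sorted(tps)


class TestEvaluation:
    def test_perfect_clustering(self):
        truth = pd.DataFrame({"record_id": list("abcd"),
                              "true_patient_id": ["p1", "p1", "p2", "p2"]})
        mapping = pd.DataFrame({"record_id": list("abcd"),
                                "cluster_id": ["c1", "c1", "c2", "c2"]})
        ev = evaluate_linkage(mapping, truth)
        assert ev.sensitivity == 1.0 and ev.ppv == 1.0

    def test_all_singletons_degenerate_ppv(self):
        truth = pd.DataFrame({"record_id": list("abc"),
                              "true_patient_id": ["p1", "p1", "p2"]})
        mapping = pd.DataFrame({"record_id": list("abc"),
                                "cluster_id": ["c1", "c2", "c3"]})
        ev = evaluate_linkage(mapping, truth)
        assert ev.sensitivity == 0.0
        assert ev.ppv == 1.0 and ev.degenerate_ppv
        assert ev.n_predicted_pairs == 0

    def test_partial_recovery_counts_pairs(self):
        # truth {a,b,c}: 3 true pairs; predicted {a,b},{c}: 1 TP pair
        truth = pd.DataFrame({"record_id": list("abc"),
                              "true_patient_id": ["p1"] * 3})
        mapping = pd.DataFrame({"record_id": list("abc"),
                                "cluster_id": ["c1", "c1", "c2"]})
        ev = evaluate_linkage(mapping, truth)
        assert ev.sensitivity == pytest.approx(1 / 3)
        assert ev.ppv == 1.0
        assert (ev.n_true_pairs, ev.n_predicted_pairs,
                ev.n_true_positive_pairs) == (3, 1, 1)

    def test_non_partition_rejected(self):
        truth = pd.DataFrame({"record_id": list("ab"),
                              "true_patient_id": ["p1", "p1"]})
        mapping = pd.DataFrame({"record_id": ["a"], "cluster_id": ["c1"]})
        with pytest.raises(ValueError, match="partition"):
            evaluate_linkage(mapping, truth)
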