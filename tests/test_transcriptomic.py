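"""Consensome construction: binning, discovery counts, CPV, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from consensome import (
    ConsensomeSelector,
    ContractError,
    TranscriptomicConsensome,
    VocabularyError,
    bin_experiments,
    build_transcriptomic_consensome,
    consensome_pvalue,
    consensus_fold_change,
    count_discoveries,
    rank_and_percentile,
)

from conftest import make_table


def binom_upper_tail(E, N, p0):
    """Independent oracle: exhaustive enumeration of the binomial pmf."""
    return sum(math.comb(N, k) * p0**k * (1 - p0) ** (N - k) for k in range(E, N + 1))


def meta_frame(rows):
    cols = [
        "experiment_id",
        "dataset_id",
        "node_symbols",
        "node_family",
        "node_class",
        "node_category",
        "species",
        "system",
        "organ",
        "perturbation_type",
    ]
    return pd.DataFrame(rows, columns=cols)


META = meta_frame(
    [
        ("E1", "D1", "Ppara", "PPARs", "Nuclear", "receptor", "mouse", "Metabolic", "Liver", "agonist"),
        ("E2", "D1", "Pparg", "PPARs", "Nuclear", "receptor", "mouse", "Metabolic", "Liver", "knockout"),
        ("E3", "D2", "Esr1", "ERs", "Nuclear", "receptor", "mouse", "Reproductive", "Mammary gland", "agonist"),
    ]
)


class TestBinExperiments:
    def test_family_selector(self):
        ids = bin_experiments(META, ConsensomeSelector(node_family="PPARs", species="mouse"))
        assert ids == ["E1", "E2"]

    def test_pan_node_biosample_selector(self):
        ids = bin_experiments(META, ConsensomeSelector(system="Metabolic", organ="Liver", species="mouse"))
        assert ids == ["E1", "E2"]

    def test_no_match_is_empty_not_error(self):
        ids = bin_experiments(META, ConsensomeSelector(node_family="PPARs", organ="Mammary gland"))
        assert ids == []

    def test_unknown_family_is_vocabulary_error(self):
        with pytest.raises(VocabularyError, match="GPCRs"):
            bin_experiments(META, ConsensomeSelector(node_family="GPCRs"))

    def test_multi_node_modes(self):
        meta = meta_frame(
            [("E1", "D1", "A;B", "FamA;FamB", "C", "receptor", "mouse", "S", "O", "knockout")]
        )
        assert bin_experiments(meta, ConsensomeSelector(node_family="FamB")) == ["E1"]
        assert bin_experiments(meta, ConsensomeSelector(node_family="FamB"), multi_node="primary_family_only") == []
        assert bin_experiments(meta, ConsensomeSelector(node_family="FamA"), multi_node="primary_family_only") == ["E1"]


class TestCountDiscoveries:
    def _evidence(self, p_by_gene):
        """p_by_gene: {gene: [p per experiment]} -> long evidence frame."""
        rows = []
        for gene, ps in p_by_gene.items():
            for i, p in enumerate(ps):
                rows.append({"gene_id": gene, "experiment_id": f"E{i}", "p": p})
        return pd.DataFrame(rows)

    def test_counts_and_rate(self):
        ev = self._evidence({"G1": [0.01, 0.2, 0.04] + [0.5] * 7})
        out = count_discoveries(ev).iloc[0]
        assert (out["n_discoveries"], out["n_experiments"], out["discovery_rate"]) == (2, 10, 0.2)

    def test_missing_experiments_excluded_from_n(self):
        ev = self._evidence({"G1": [0.01, 0.01, 0.01, 0.5, 0.5, 0.5]})
        out = count_discoveries(ev).iloc[0]
        assert (out["n_discoveries"], out["n_experiments"]) == (3, 6)

    def test_boundary_p_is_a_discovery(self):
        # the threshold is "0.05 or less", boundary inclusive
        ev = self._evidence({"G1": [0.05]})
        out = count_discoveries(ev).iloc[0]
        assert (out["n_discoveries"], out["n_experiments"], out["discovery_rate"]) == (1, 1, 1.0)


class TestConsensomePvalue:
    @pytest.mark.parametrize(
        "E, N, expected",
        [
            (0, 10, 1.0),
            (1, 1, 0.05),
            (2, 10, 1 - 0.95**10 - 10 * 0.05 * 0.95**9),  # 0.0861384
        ],
    )
    def test_reference_values(self, E, N, expected):
        assert consensome_pvalue(E, N, 0.05) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle_up_to_n_25(self):
        for N in range(0, 26):
            for E in range(0, N + 1):
                assert consensome_pvalue(E, N, 0.05) == pytest.approx(
                    binom_upper_tail(E, N, 0.05), abs=1e-12
                )

    def test_strictly_decreasing_in_discoveries(self):
        cpv = consensome_pvalue(np.arange(0, 21), 20, 0.05)
        assert np.all(np.diff(cpv) < 0)

    def test_more_trials_same_successes_weakens_evidence(self):
        for E in (1, 3, 5):
            for N in range(E, 30):
                assert consensome_pvalue(E, N, 0.05) < consensome_pvalue(E, N + 1, 0.05)

    def test_contract_violations(self):
        with pytest.raises(ContractError):
            consensome_pvalue(5, 4, 0.05)


class TestConsensusFoldChange:
    @pytest.mark.parametrize(
        "folds, expected",
        [
            ([2.0, 0.5], 2.0),   # both map to 2 under max(F, 1/F)
            ([4.0, 1.0], 2.0),   # sqrt(4 * 1)
            ([1.0], 1.0),
        ],
    )
    def test_reference_values(self, folds, expected):
        assert consensus_fold_change(folds) == pytest.approx(expected, rel=1e-12)

    @given(st.lists(st.floats(-8, 8), min_size=1, max_size=10))
    def test_direction_invariance_and_lower_bound(self, log2fs):
        folds = [2.0**x for x in log2fs]
        fg = consensus_fold_change(folds)
        assert fg >= 1.0
        assert consensus_fold_change([1 / f for f in folds]) == pytest.approx(fg, rel=1e-12)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ContractError):
            consensus_fold_change([])
        with pytest.raises(ContractError):
            consensus_fold_change([2.0, 0.0])


class TestRankAndPercentile:
    def test_average_rank_on_ties(self):
        rows = pd.DataFrame({"gene_id": ["a", "b", "c"], "cpv": [1e-5, 1e-5, 0.3]})
        out = rank_and_percentile(rows)
        assert out["rank"].tolist() == [1.5, 1.5, 3.0]

    def test_percentile_extremes(self):
        rows = pd.DataFrame({"gene_id": [f"g{i:03d}" for i in range(200)], "cpv": np.linspace(0.001, 1, 200)})
        out = rank_and_percentile(rows)
        assert out["percentile"].iloc[0] == pytest.approx(99.5)
        assert out["percentile"].iloc[-1] == 0.0

    def test_tie_output_order_deterministic_by_gene_id(self):
        rows = pd.DataFrame({"gene_id": ["z", "a", "m"], "cpv": [0.5, 0.5, 0.5]})
        out = rank_and_percentile(rows)
        assert out["gene_id"].tolist() == ["a", "m", "z"]


class TestTranscriptomicConsensome:
    def _five_experiment_corpus(self):
        tables = []
        for e in range(5):
            tables.append(
                make_table(
                    f"E{e}",
                    [
                        ("ps_hit", "HIT", 2.0, 0.01),
                        ("ps_null", "NULL1", 1.05, 0.6),
                        ("ps_nul2", "NULL2", 0.95, 0.8),
                    ],
                )
            )
        return tables

    def test_fully_recurrent_gene_tops_the_table(self):
        cons, _ = build_transcriptomic_consensome(self._five_experiment_corpus())
        top = cons.iloc[0]
        assert top["gene_id"] == "HIT" and top["rank"] == 1.0
        assert top["cpv"] == pytest.approx(0.05**5, rel=1e-9)

    def test_all_null_corpus_ties_at_middle_rank(self):
        tables = [make_table(f"E{e}", [("a", "G1", 1.0, 0.9), ("b", "G2", 1.0, 0.8)]) for e in range(3)]
        cons, _ = build_transcriptomic_consensome(tables)
        assert (cons["cpv"] == 1.0).all()
        assert (cons["rank"] == (len(cons) + 1) / 2).all()

    def test_stamp_counts(self):
        meta = meta_frame(
            [
                ("E1", "D1", "N", "F", "C", "receptor", "mouse", "S", "O", "agonist"),
                ("E2", "D1", "N", "F", "C", "receptor", "mouse", "S", "O", "agonist"),
                ("E3", "D2", "N", "F", "C", "receptor", "mouse", "S", "O", "agonist"),
                ("E4", "D2", "N", "F", "C", "receptor", "mouse", "S", "O", "agonist"),
            ]
        )
        rows = [(f"ps{i}", f"G{i}", 1.2, 0.5) for i in range(10)]
        tables = [make_table(e, rows) for e in ("E1", "E2", "E3", "E4")]
        _, stamp = build_transcriptomic_consensome(tables, meta)
        assert (stamp.n_datapoints, stamp.n_experiments, stamp.n_datasets) == (40, 4, 2)

    def test_alpha_monotonicity(self):
        tables = self._five_experiment_corpus()
        strict, _ = build_transcriptomic_consensome(tables, alpha=0.001)
        loose, _ = build_transcriptomic_consensome(tables, alpha=0.05)
        merged = strict.set_index("gene_id")["n_discoveries"]
        for gene, e_loose in loose.set_index("gene_id")["n_discoveries"].items():
            assert merged[gene] <= e_loose

    def test_empty_selection_warns_and_yields_empty(self):
        tables = self._five_experiment_corpus()
        meta = meta_frame(
            [("E0", "D1", "N", "F", "C", "receptor", "mouse", "S", "Elsewhere", "agonist")]
            + [(f"E{e}", "D1", "N", "F2", "C", "receptor", "mouse", "S", "O", "agonist") for e in range(1, 5)]
        )
        # both facets are in the vocabulary, but no experiment carries both
        est = TranscriptomicConsensome(selector=ConsensomeSelector(node_family="F2", organ="Elsewhere"))
        with pytest.warns(UserWarning, match="no experiments"):
            est.fit(tables, meta)
        assert len(est.consensome_) == 0 and est.stamp_.n_experiments == 0

    def test_significant_only_fc_flag(self):
        tables = [
            make_table("E1", [("a", "G1", 4.0, 0.01)]),
            make_table("E2", [("a", "G1", 1.0, 0.9)]),
        ]
        all_fc, _ = build_transcriptomic_consensome(tables)
        sig_fc, _ = build_transcriptomic_consensome(tables, significant_only_fc=True)
        assert all_fc["consensus_fc"].iloc[0] == pytest.approx(2.0, rel=1e-12)  # sqrt(4 * 1)
        assert sig_fc["consensus_fc"].iloc[0] == pytest.approx(4.0, rel=1e-12)

    def test_bh_column_present_and_not_used_for_ranking(self):
        cons, _ = build_transcriptomic_consensome(self._five_experiment_corpus())
        assert "cpv_bh" in cons.columns
        assert cons["rank"].is_monotonic_increasing
        assert (cons["cpv_bh"] >= cons["cpv"] - 1e-15).all()

    def test_estimator_clone_and_params(self):
        est = TranscriptomicConsensome(alpha=0.01, p0=0.02)
        cloned = clone(est)
        assert cloned.get_params()["alpha"] == 0.01 and cloned.get_params()["p0"] == 0.02

    def test_cpv_auc_separates_truth_from_null(self, default_corpus):
        from sklearn.metrics import roc_auc_score

        tables, meta, truth = default_corpus
        cons, _ = build_transcriptomic_consensome(tables, meta)
        y = cons["gene_id"].isin(truth.members).to_numpy()
        auc = roc_auc_score(y, -cons["cpv"].to_numpy())
        assert auc > 0.9

    def test_truth_ranks_beat_null_ranks(self, default_corpus):
        tables, meta, truth = default_corpus
        cons, _ = build_transcriptomic_consensome(tables, meta)
        is_true = cons["gene_id"].isin(truth.members)
        assert cons.loc[is_true, "rank"].median() < cons.loc[~is_true, "rank"].median()
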