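"""PLS target weighting, OC_Score computation, cutoff and screening."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from ocscreen.pls import (ORAL_CANCER_ICD10, OCScoreRecord, TargetWeights,
                          TrainingMatrix, build_training_matrix, derive_cutoff,
                          fit_target_weights, oc_score, read_target_weights,
                          read_training_matrix, score_distribution,
                          screen_compounds, write_target_weights,
                          write_training_matrix)
from ocscreen.synthetic import SyntheticConfig, generate_training_matrix


def random_matrix(rng, n_rows=30, n_cols=8, p=0.3):
    presence = (rng.random((n_rows, n_cols)) < p).astype(np.uint8)
    classes = rng.choice([1, 0, -1], size=n_rows)
    return TrainingMatrix([f"r{i}" for i in range(n_rows)], classes, presence,
                          [f"G{j}" for j in range(n_cols)])


def closed_form_weights(matrix: TrainingMatrix) -> np.ndarray:
    """Independent oracle: unit-normalized centered cross-covariance X'y."""
    X = matrix.presence.astype(float)
    y = matrix.classes.astype(float)
    w = (X - X.mean(0)).T @ (y - y.mean())
    return w / np.linalg.norm(w)


class TestFitTargetWeights:
    def test_matches_closed_form_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            n_rows = int(rng.integers(10, 101))
            n_cols = int(rng.integers(2, 51))
            m = random_matrix(rng, n_rows, n_cols)
            if len(np.unique(m.classes)) < 2 or not m.presence.any():
                continue
            try:
                fit = fit_target_weights(m, loo=False)
            except ValueError:
                continue  # degenerate draw (zero covariance)
            w = np.array([fit.weights[t] for t in m.target_ids])
            assert np.abs(w - closed_form_weights(m)).max() < 1e-10

    def test_matches_sklearn_pls_up_to_sign(self, rng):
        m = random_matrix(rng, 40, 12)
        fit = fit_target_weights(m, loo=False)
        w = np.array([fit.weights[t] for t in m.target_ids])
        sk = PLSRegression(n_components=1, scale=False).fit(
            m.presence.astype(float), m.classes.astype(float))
        ws = sk.x_weights_[:, 0]
        if np.dot(ws, w) < 0:
            ws = -ws
        assert np.abs(w - ws).max() < 1e-10

    def test_unit_norm_and_single_column(self):
        m = TrainingMatrix(["a", "b", "c", "d"], [1, 1, -1, -1],
                           [[1], [1], [0], [0]], ["G1"])
        fit = fit_target_weights(m, loo=False)
        assert abs(fit.weights["G1"]) == pytest.approx(1.0)
        assert fit.weights["G1"] > 0  # aligned with the response

    def test_zero_covariance_column_gets_zero_weight(self):
        presence = np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=np.uint8)
        m = TrainingMatrix(["a", "b", "c", "d"], [1, 0, 1, 0], presence,
                           ["const", "signal"])
        fit = fit_target_weights(m, loo=False)
        assert fit.weights["const"] == pytest.approx(0.0)

    def test_all_zero_column_warns_and_gets_zero(self):
        presence = np.array([[0, 1], [0, 0], [0, 1], [0, 0]], dtype=np.uint8)
        m = TrainingMatrix(["a", "b", "c", "d"], [1, 0, 1, 0], presence,
                           ["dead", "signal"])
        with pytest.warns(UserWarning, match="all-zero"):
            fit = fit_target_weights(m, loo=False)
        assert fit.weights["dead"] == 0.0

    def test_constant_response_rejected(self):
        m = TrainingMatrix(["a", "b"], [1, 1], [[1], [0]], ["G1"])
        with pytest.raises(ValueError, match="constant"):
            fit_target_weights(m)

    def test_loo_rmsep_reported(self, rng):
        fit = fit_target_weights(random_matrix(rng, 25, 6))
        assert fit.rmsep_loo is not None and fit.rmsep_loo > 0


class TestOCScore:
    def test_empty_target_set_scores_zero(self):
        rec = oc_score([], TargetWeights({"a": 1.0}))
        assert rec.oc_score == 0.0

    def test_additive_over_disjoint_target_sets(self):
        w = TargetWeights({"a": 0.5, "b": -0.2, "c": 0.1})
        combined = oc_score(["a", "b", "c"], w).oc_score
        assert combined == pytest.approx(
            oc_score(["a"], w).oc_score + oc_score(["b", "c"], w).oc_score)

    def test_unmapped_targets_contribute_zero_and_are_counted(self):
        w = TargetWeights({"a": 0.5})
        rec = oc_score(["a", "mystery1", "mystery2"], w)
        assert rec.oc_score == pytest.approx(0.5)
        assert rec.n_unmapped == 2

    def test_positive_weight_target_never_decreases_score(self, rng):
        w = TargetWeights({f"G{i}": float(v) for i, v in
                           enumerate(rng.normal(size=20))})
        positives = [g for g, v in w.weights.items() if v > 0]
        base = oc_score(["G0", "G1"], w).oc_score
        for g in positives:
            if g in ("G0", "G1"):
                continue
            assert oc_score(["G0", "G1", g], w).oc_score >= base


class TestCutoffAndScreening:
    def test_cutoff_is_rounded_class_mean(self):
        assert derive_cutoff([0.6699, 0.6699]) == 0.67
        assert derive_cutoff([0.6699], decimals=4) == 0.6699
        assert derive_cutoff([0.5, 0.5, 0.5]) == 0.5

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            derive_cutoff([])

    def test_screening_boundary_is_inclusive(self):
        records = [OCScoreRecord("at", (), 0.67), OCScoreRecord("below", (), 0.6699),
                   OCScoreRecord("above", (), 1.2)]
        kept = screen_compounds(records, 0.67)
        assert [r.compound_id for r in kept] == ["at", "above"]

    def test_empty_input_empty_output(self):
        assert screen_compounds([], 0.67) == []


class TestScoreDistribution:
    def test_single_score_group_collapses_to_that_value(self):
        df = score_distribution([OCScoreRecord("a", (), 0.3, group="g")])
        assert (df.loc["g"] == 0.3).all()

    def test_quartiles_and_mean(self):
        recs = [OCScoreRecord(f"c{i}", (), float(v), group="g")
                for i, v in enumerate([1, 2, 3, 4])]
        row = score_distribution(recs).loc["g"]
        assert row["Median"] == 2.5 and row["Mean"] == 2.5
        assert row["1st Quartile"] == 1.75 and row["3rd Quartile"] == 3.25

    def test_groups_are_separate_rows(self):
        recs = [OCScoreRecord("a", (), 1.0, group="oral"),
                OCScoreRecord("b", (), -1.0, group="others")]
        df = score_distribution(recs)
        assert set(df.index) == {"oral", "others"}


class TestBuildTrainingMatrix:
    def drug_table(self, rows):
        return pd.DataFrame(rows, columns=["DrugName", "ICD10", "Targets"])

    def test_multi_indication_compound_emits_two_rows(self):
        table = self.drug_table([("resv", "C00.1,C18", "10,20")])
        m = build_training_matrix([table])
        assert m.record_ids == ["resv", "resv"]
        assert sorted(m.classes) == [0, 1]

    def test_oral_codes_define_class_one(self):
        table = self.drug_table([
            ("oral_only", "C06", "1"),
            ("other_cancer", "C50", "2"),
            ("noncancer", "I10", "3"),
        ])
        m = build_training_matrix([table])
        by_id = dict(zip(m.record_ids, m.classes))
        assert by_id == {"oral_only": 1, "other_cancer": 0, "noncancer": -1}

    def test_extra_prior_instance_appends_class_one_row(self):
        table = self.drug_table([("d", "C50", "1,2")])
        m = build_training_matrix([table], extra_instances=[("prior", ["2", "9"])])
        assert m.record_ids[-1] == "prior"
        assert m.classes[-1] == 1
        assert set(m.target_ids) == {"1", "2", "9"}

    def test_no_target_rows_excluded(self, caplog):
        table = self.drug_table([("empty", "C00", ""), ("ok", "C00", "5")])
        m = build_training_matrix([table])
        assert m.record_ids == ["ok"]

    def test_oral_code_set_covers_lip_to_oral_cavity(self):
        assert ORAL_CANCER_ICD10 == {"C00", "C01", "C02", "C03", "C04", "C05", "C06"}


class TestRoundTrips:
    def test_training_matrix_tsv_round_trip(self, tmp_path, rng):
        m = random_matrix(rng, 12, 5)
        p = tmp_path / "matrix.tsv"
        write_training_matrix(m, p)
        back = read_training_matrix(p)
        assert back.record_ids == m.record_ids
        assert (back.classes == m.classes).all()
        assert (back.presence == m.presence).all()
        assert back.target_ids == m.target_ids

    def test_weights_tsv_round_trip(self, tmp_path):
        w = TargetWeights({"19": -0.001570518, "10062": 0.003148697})
        p = tmp_path / "weights.tsv"
        write_target_weights(w, p)
        back = read_target_weights(p)
        assert back.weights == pytest.approx(w.weights)


def test_planted_signal_targets_receive_top_weights():
    """Parameter recovery: strong planted signal puts the signal targets'
    weights above the 95th percentile of background weights (fixed seeds)."""
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        cfg = SyntheticConfig(seed=seed, n_oral=50, n_cancer=60, n_other=60,
                              background_rate=0.05, signal_strength=0.9)
        matrix, signal = generate_training_matrix(cfg)
        fit = fit_target_weights(matrix, loo=False)
        w = fit.weights
        background = [w[t] for t in matrix.target_ids if t not in signal]
        threshold = np.quantile(background, 0.95)
        if all(w[t] > max(threshold, 0.0) for t in signal):
            hits += 1
    assert hits >= 95
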