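"""Evaluation battery: discretization, MAE, weighted kappa, weighted P/R/F1."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from nashscore.evaluation import (
    discretize,
    evaluate_scores,
    mae,
    quadratic_weighted_kappa,
    reports_frame,
    weighted_prf,
)


def brute_force_qwk(pred, truth, levels):
    """Independent oracle: build O and E explicitly and sum the double loop."""
    levels = list(levels)
    k = len(levels)
    n = len(pred)
    o = [[0.0] * k for _ in range(k)]
    for t, p in zip(truth, pred):
        o[levels.index(t)][levels.index(p)] += 1
    row = [sum(o[i]) for i in range(k)]
    col = [sum(o[i][j] for i in range(k)) for j in range(k)]
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (i - j) ** 2 / max(k - 1, 1) ** 2
            num += w * o[i][j]
            den += w * row[i] * col[j] / n
    return 1.0 if den == 0 else 1.0 - num / den


class TestDiscretize:
    @pytest.mark.parametrize(("x", "s", "expected"), [(2.5, 4, 3), (0.49, 4, 0), (4.0, 4, 4), (1.5, 3, 2), (-0.2, 4, 0), (8.7, 8, 8)])
    def test_round_half_up_and_clip(self, x, s, expected):
        assert discretize(x, s) == expected

    def test_vectorized(self):
        np.testing.assert_array_equal(discretize(np.array([0.5, 1.49, 3.99]), 3), [1, 1, 3])


class TestMae:
    def test_perfect_fit(self):
        assert mae([1.0, 2.0, 0.0], [1, 2, 0]) == 0.0

    def test_arithmetic(self):
        assert mae([1.0, 2.0], [0, 4]) == pytest.approx(1.5)

    def test_shift_property(self, rng):
        t = rng.integers(0, 5, 50).astype(float)
        assert mae(t + 0.37, t) == pytest.approx(0.37)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([], [])


class TestQuadraticWeightedKappa:
    def test_perfect_agreement(self):
        v = [0, 1, 2, 3, 4, 1, 2]
        assert quadratic_weighted_kappa(v, v, range(5)) == pytest.approx(1.0)

    def test_anti_diagonal_two_level(self):
        assert quadratic_weighted_kappa([1, 1, 0, 0], [0, 0, 1, 1], [0, 1]) == pytest.approx(-1.0)

    def test_constant_equal_raters_defined_one(self):
        assert quadratic_weighted_kappa([2, 2, 2], [2, 2, 2], range(5)) == 1.0

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            k = int(rng.integers(2, 10))
            n = int(rng.integers(5, 500))
            levels = list(range(k))
            t = rng.integers(0, k, n)
            p = rng.integers(0, k, n)
            ours = quadratic_weighted_kappa(p, t, levels)
            oracle = brute_force_qwk(p.tolist(), t.tolist(), levels)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_library_implementation(self, rng):
        t = rng.integers(0, 5, 200)
        p = rng.integers(0, 5, 200)
        ours = quadratic_weighted_kappa(p, t, range(5))
        theirs = cohen_kappa_score(t, p, labels=list(range(5)), weights="quadratic")
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_normalization_cancels(self, rng):
        # unnormalized (i-j)^2 weights yield the same kappa as (i-j)^2/S^2
        t = rng.integers(0, 4, 100)
        p = rng.integers(0, 4, 100)
        k = 4
        o = np.zeros((k, k))
        for ti, pi in zip(t, p):
            o[ti, pi] += 1
        e = np.outer(o.sum(1), o.sum(0)) / o.sum()
        ii, jj = np.meshgrid(range(k), range(k), indexing="ij")
        w_raw = (ii - jj) ** 2
        unnorm = 1 - (w_raw * o).sum() / (w_raw * e).sum()
        assert quadratic_weighted_kappa(p, t, range(4)) == pytest.approx(unnorm, abs=1e-12)

    def test_out_of_level_rejected(self):
        with pytest.raises(ValueError):
            quadratic_weighted_kappa([0, 5], [0, 1], range(5))


class TestWeightedPrf:
    def test_perfect(self):
        v = [0, 1, 2, 2, 1]
        assert weighted_prf(v, v, range(3)) == (1.0, 1.0, 1.0)

    def test_constant_prediction_recall(self):
        truth = np.repeat(np.arange(5), 20)
        pred = np.full(100, 2)
        _, recall, _ = weighted_prf(pred, truth, range(5))
        assert recall == pytest.approx(0.2)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            t = rng.integers(0, 4, 60)
            p = rng.integers(0, 4, 60)
            prec, rec, f1 = weighted_prf(p, t, range(4))
            # brute-force per-class computation
            e_prec = e_rec = e_f1 = 0.0
            for lvl in range(4):
                tp = np.sum((p == lvl) & (t == lvl))
                pp = np.sum(p == lvl)
                ap = np.sum(t == lvl)
                pr = tp / pp if pp else 0.0
                rc = tp / ap if ap else 0.0
                f = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
                e_prec += ap / len(t) * pr
                e_rec += ap / len(t) * rc
                e_f1 += ap / len(t) * f
            assert prec == pytest.approx(e_prec, abs=1e-12)
            assert rec == pytest.approx(e_rec, abs=1e-12)
            assert f1 == pytest.approx(e_f1, abs=1e-12)

    def test_weighted_recall_equals_accuracy(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 8))
            n = int(rng.integers(5, 300))
            t = rng.integers(0, k, n)
            p = rng.integers(0, k, n)
            _, recall, _ = weighted_prf(p, t, range(k))
            assert recall == pytest.approx(np.mean(p == t), abs=1e-12)


class TestEvaluateScores:
    @staticmethod
    def _records(rng, n=40):
        rows = []
        for feat, s_max in [("ballooning", 2), ("inflammation", 3), ("steatosis", 3), ("fibrosis", 4)]:
            truth = rng.integers(0, s_max + 1, n)
            ai = np.clip(truth + rng.normal(0, 0.3, n), 0, s_max)
            rows.extend(
                {"slide_id": f"s{i}", "feature": feat, "truth": float(t), "ai_score": float(a)}
                for i, (t, a) in enumerate(zip(truth, ai))
            )
        return pd.DataFrame(rows)

    def test_report_rows_and_nas(self, rng):
        reports = evaluate_scores(self._records(rng))
        features = [r.feature for r in reports]
        assert features == ["ballooning", "inflammation", "steatosis", "fibrosis", "NAS"]
        nas_row = reports[-1]
        assert nas_row.n == 40
        frame = reports_frame(reports)
        assert list(frame.columns)[:2] == ["feature", "dataset"]

    def test_missing_truth_excluded_from_n(self, rng):
        records = self._records(rng)
        records.loc[(records["feature"] == "fibrosis") & (records["slide_id"] == "s0"), "truth"] = np.nan
        reports = evaluate_scores(records, include_nas=False)
        fib = next(r for r in reports if r.feature == "fibrosis")
        assert fib.n == 39

    def test_confusion_totals_match_n(self, rng):
        for rep in evaluate_scores(self._records(rng), include_nas=False):
            assert rep.confusion.sum() == rep.n
            assert rep.confusion.shape[0] == rep.confusion.shape[1]

    def test_reemission_is_byte_identical(self, rng, tmp_path):
        records = self._records(rng)
        f1 = reports_frame(evaluate_scores(records))
        f2 = reports_frame(evaluate_scores(records))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        f1.to_csv(p1, index=False)
        f2.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_mae_discretization_bound(self, rng):
        t = rng.integers(0, 5, 200).astype(float)
        ai = np.clip(t + rng.normal(0, 0.6, 200), 0, 4)
        cont = mae(ai, t)
        disc = mae(np.asarray(discretize(ai, 4), dtype=float), t)
        assert disc >= 0.0
        assert abs(cont - disc) <= 0.5
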