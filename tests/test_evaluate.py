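import numpy as np
import pytest

from scxfer.evaluate import classification_metrics, deg_score, stability_test
from scxfer.matrix import ExpressionMatrix

# ---------------------------------------------------------------------------
# textbook-formula oracles, independent of sklearn


def oracle_prf(y, yhat):
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn else 0.0
    return prec, rec, f1


def oracle_auroc(y, prob):
    """Exhaustive threshold sweep with trapezoidal interpolation."""
    thresholds = np.unique(prob)[::-1]
    pts = [(0.0, 0.0)]
    P, N = (y == 1).sum(), (y == 0).sum()
    for t in thresholds:
        yhat = prob >= t
        pts.append((np.sum(yhat & (y == 0)) / N, np.sum(yhat & (y == 1)) / P))
    pts.append((1.0, 1.0))
    pts = sorted(set(pts))
    return float(np.trapezoid([p[1] for p in pts], [p[0] for p in pts]))


def oracle_ap(y, prob):
    """AP = sum_n (R_n - R_{n-1}) P_n over descending score thresholds."""
    order = np.argsort(-prob, kind="stable")
    y_sorted = y[order]
    prob_sorted = prob[order]
    P = y.sum()
    ap, prev_r = 0.0, 0.0
    tp = fp = 0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and prob_sorted[j] == prob_sorted[i]:
            tp += y_sorted[j]
            fp += 1 - y_sorted[j]
            j += 1
        r = tp / P
        p = tp / (tp + fp)
        ap += (r - prev_r) * p
        prev_r = r
        i = j
    return float(ap)


def oracle_ari(a, b):
    from scipy.special import comb

    cats_a, cats_b = np.unique(a), np.unique(b)
    nij = np.array([[np.sum((a == i) & (b == j)) for j in cats_b] for i in cats_a])
    ni, nj, n = nij.sum(1), nij.sum(0), nij.sum()
    sum_ij = comb(nij, 2).sum()
    sum_i, sum_j = comb(ni, 2).sum(), comb(nj, 2).sum()
    expected = sum_i * sum_j / comb(n, 2)
    max_idx = 0.5 * (sum_i + sum_j)
    if max_idx == expected:
        return 1.0
    return float((sum_ij - expected) / (max_idx - expected))


def oracle_ami(a, b):
    """AMI with arithmetic mean normalization and exact hypergeometric EMI."""
    from scipy.special import gammaln

    cats_a, cats_b = np.unique(a), np.unique(b)
    n = len(a)
    nij = np.array([[np.sum((a == i) & (b == j)) for j in cats_b] for i in cats_a])
    ai, bj = nij.sum(1), nij.sum(0)
    mi = 0.0
    for i in range(len(cats_a)):
        for j in range(len(cats_b)):
            if nij[i, j] > 0:
                mi += (nij[i, j] / n) * np.log(n * nij[i, j] / (ai[i] * bj[j]))
    h_a = -np.sum((ai / n) * np.log(ai / n))
    h_b = -np.sum((bj / n) * np.log(bj / n))
    emi = 0.0
    for i in range(len(cats_a)):
        for j in range(len(cats_b)):
            lo = max(1, ai[i] + bj[j] - n)
            hi = min(ai[i], bj[j])
            for k in range(lo, hi + 1):
                log_p = (
                    gammaln(ai[i] + 1) + gammaln(bj[j] + 1)
                    + gammaln(n - ai[i] + 1) + gammaln(n - bj[j] + 1)
                    - gammaln(n + 1) - gammaln(k + 1)
                    - gammaln(ai[i] - k + 1) - gammaln(bj[j] - k + 1)
                    - gammaln(n - ai[i] - bj[j] + k + 1)
                )
                emi += np.exp(log_p) * (k / n) * np.log(n * k / (ai[i] * bj[j]))
    denom = 0.5 * (h_a + h_b) - emi
    if denom == 0:
        return 1.0
    return float((mi - emi) / denom)


def check_against_oracles(y, prob, atol=1e-10):
    rep = classification_metrics(y, prob)
    yhat = (prob > 0.5).astype(int)
    prec, rec, f1 = oracle_prf(y, yhat)
    assert rep.precision == pytest.approx(prec, abs=atol)
    assert rep.recall == pytest.approx(rec, abs=atol)
    assert rep.f1 == pytest.approx(f1, abs=atol)
    assert rep.auroc == pytest.approx(oracle_auroc(y, prob), abs=atol)
    assert rep.ap == pytest.approx(oracle_ap(y, prob), abs=atol)
    assert rep.ari == pytest.approx(oracle_ari(y, yhat), abs=atol)
    assert rep.ami == pytest.approx(oracle_ami(y, yhat), abs=atol)


class TestClassificationMetrics:
    def test_direct_substitution_example(self):
        # TP=8, FP=2, FN=2 -> precision = recall = F1 = 0.8
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        prob = np.array([0.9] * 8 + [0.9] * 2 + [0.1] * 2 + [0.1] * 8)
        rep = classification_metrics(y, prob)
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    def test_perfect_prediction_all_ones(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = classification_metrics(y, y.astype(float))
        assert all(
            v == pytest.approx(1.0)
            for v in rep.as_dict().values()
        )

    def test_random_vectors_match_oracles(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(20, 80))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            prob = rng.random(n)
            check_against_oracles(y, prob)

    def test_identical_partitions_ari_one(self):
        y = np.random.default_rng(1).integers(0, 2, 100)
        y[0], y[1] = 0, 1
        rep = classification_metrics(y, y.astype(float))
        assert rep.ari == pytest.approx(1.0)

    def test_independent_partitions_ari_near_zero(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 1000)
        prob = rng.random(1000)
        rep = classification_metrics(y, prob)
        assert abs(rep.ari) < 0.1

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        prob = rng.random(60)
        rep = classification_metrics(y, prob)
        if rep.precision + rep.recall > 0:
            hm = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            assert rep.f1 == pytest.approx(hm, abs=1e-10)

    def test_single_class_truth_warns_nan(self):
        with pytest.warns(UserWarning, match="single-class"):
            rep = classification_metrics(np.ones(5, dtype=int), np.full(5, 0.8))
        assert np.isnan(rep.auroc) and np.isnan(rep.ap)

    def test_ami_ari_symmetric(self):
        from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

        rng = np.random.default_rng(4)
        a, b = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        assert adjusted_rand_score(a, b) == adjusted_rand_score(b, a)
        assert adjusted_mutual_info_score(a, b) == pytest.approx(
            adjusted_mutual_info_score(b, a), abs=1e-12
        )


class TestDEGScore:
    def _matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.random((60, 120))
        group = np.zeros(60, dtype=bool)
        group[:25] = True
        vals[:25, :15] += 2.0  # planted program in the group
        vals = (vals - vals.min(0)) / (vals.max(0) - vals.min(0))
        return (
            ExpressionMatrix(
                vals,
                [f"c{i}" for i in range(60)],
                [f"g{j}" for j in range(120)],
                stage="scaled",
            ),
            group,
        )

    def test_score_in_unit_interval(self):
        X, group = self._matrix()
        s = deg_score(X, group, n_top=10, seed=0)
        assert s.min() >= 0 and s.max() <= 1

    def test_planted_program_separates_groups(self):
        X, group = self._matrix()
        s = deg_score(X, group, n_top=10, seed=0)
        assert np.median(s[group]) > np.median(s[~group])

    def test_deterministic_given_seed(self):
        X, group = self._matrix()
        np.testing.assert_array_equal(
            deg_score(X, group, seed=3), deg_score(X, group, seed=3)
        )


class TestStability:
    def _data(self):
        rng = np.random.default_rng(5)
        X = ExpressionMatrix(
            rng.random((100, 10)),
            [f"c{i}" for i in range(100)],
            [f"g{j}" for j in range(10)],
            stage="scaled",
        )
        y = np.array([1] * 60 + [0] * 40)
        return X, y

    def test_subsample_sizes_and_ratio(self):
        X, y = self._data()
        seen = []

        def pipeline(Xs, ys):
            seen.append(ys)
            return ys.astype(float)

        stability_test(pipeline, X, y, n_repeats=5, frac=0.8, seed=0)
        for ys in seen:
            assert len(ys) == 80
            assert abs((ys == 1).sum() - 48) <= 1 and abs((ys == 0).sum() - 32) <= 1

    def test_constant_predictor_zero_sd(self):
        X, y = self._data()
        out = stability_test(lambda Xs, ys: ys.astype(float), X, y, n_repeats=6, seed=1)
        assert out["f1"]["sd"] == 0.0 and out["f1"]["mean"] == 1.0

    def test_fraction_too_small_rejected(self):
        X, y = self._data()
        y = np.array([1] + [0] * 99)
        with pytest.raises(ValueError):
            stability_test(lambda Xs, ys: ys.astype(float), X, y, frac=0.5)
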