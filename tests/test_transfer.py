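import numpy as np
import pytest

from scxfer.matrix import ExpressionMatrix
from scxfer.networks import NetConfig
from scxfer.transfer import (
    ClusterLabels,
    KernelSpec,
    LossWeights,
    TrainSchedule,
    cluster_cells,
    cluster_regularizer,
    fit,
    joint_loss,
    mmd,
)


class TestMMD:
    def test_identical_sets_zero(self):
        Z = np.random.default_rng(0).normal(size=(50, 8))
        assert mmd(Z, Z) <= 1e-9

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        A, B = rng.normal(size=(30, 5)), rng.normal(size=(40, 5))
        assert mmd(A, B) == pytest.approx(mmd(B, A), abs=1e-12)

    def test_two_point_closed_form(self):
        sigma, r = 1.3, 2.0
        A = np.array([[0.0, 0.0]])
        B = np.array([[r, 0.0]])
        expected = 2.0 - 2.0 * np.exp(-(r**2) / (2 * sigma**2))
        got = mmd(A, B, KernelSpec(bandwidths=[sigma]))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_shifted_exceeds_null(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.normal(0, 1, size=(100, 2))
            B = rng.normal(0, 1, size=(100, 2))
            C = rng.normal(3, 1, size=(100, 2))
            assert mmd(A, C) > mmd(A, B)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(20, 4)), rng.normal(size=(25, 4))
        perm = rng.permutation(len(A))
        assert mmd(A, B) == pytest.approx(mmd(A[perm], B), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            mmd(np.ones((3, 4)), np.ones((3, 5)))


def scaled_em(values, prefix="c"):
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(0), values.max(0)
    values = (values - lo) / np.where(hi - lo == 0, 1, hi - lo)
    n, p = values.shape
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(n)],
        [f"g{j}" for j in range(p)],
        stage="scaled",
    )


class TestClustering:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (100, 20)), rng.normal(8, 1, (100, 20))])
        em = scaled_em(X)
        labels = cluster_cells(em, seed=0)
        assert labels.n_clusters == 2
        codes = labels.codes_for(em.sample_ids)
        from sklearn.metrics import adjusted_rand_score

        truth = np.array([0] * 100 + [1] * 100)
        assert adjusted_rand_score(truth, codes) == 1.0

    def test_user_labels_passthrough(self):
        em = scaled_em(np.random.default_rng(1).random((10, 5)))
        user = {c: i % 3 for i, c in enumerate(em.sample_ids)}
        labels = cluster_cells(em, labels=user)
        assert labels.assignment == user and labels.n_clusters == 3

    def test_deterministic(self):
        em = scaled_em(np.random.default_rng(2).random((60, 10)))
        a = cluster_cells(em, seed=4)
        b = cluster_cells(em, seed=4)
        assert a.assignment == b.assignment

    def test_too_few_cells(self):
        em = scaled_em(np.random.default_rng(3).random((5, 4)))
        with pytest.raises(ValueError, match="cells"):
            cluster_cells(em, n_neighbors=15)


class TestRegularizer:
    def _labels(self, codes):
        ids = [f"c{i}" for i in range(len(codes))]
        return ids, ClusterLabels({c: int(k) for c, k in zip(ids, codes)},
                                  n_clusters=len(set(codes)))

    def test_identical_members_give_minus_n_clusters(self):
        Z = np.vstack([np.tile([1.0, 2.0], (3, 1)), np.tile([0.0, 5.0], (4, 1))])
        ids, labels = self._labels([0] * 3 + [1] * 4)
        assert cluster_regularizer(Z, labels, ids) == pytest.approx(-2.0)

    def test_orthogonal_pair_zero(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        ids, labels = self._labels([0, 0])
        assert cluster_regularizer(Z, labels, ids) == pytest.approx(0.0)

    def test_singleton_contributes_zero(self):
        Z = np.array([[3.0, 4.0]])
        ids, labels = self._labels([0])
        assert cluster_regularizer(Z, labels, ids) == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(30, 6))
        codes = rng.integers(0, 4, 30)
        ids, labels = self._labels(codes)
        got = cluster_regularizer(Z, labels, ids)
        expected = 0.0
        for c in np.unique(codes):
            idx = np.flatnonzero(codes == c)
            if len(idx) < 2:
                continue
            sims = []
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    u, v = Z[idx[a]], Z[idx[b]]
                    sims.append(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            expected -= np.mean(sims)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_orthogonal_rotation(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(20, 5))
        codes = rng.integers(0, 3, 20)
        ids, labels = self._labels(codes)
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert cluster_regularizer(Z @ Q, labels, ids) == pytest.approx(
            cluster_regularizer(Z, labels, ids), abs=1e-10
        )


class TestJointLoss:
    def _setup(self):
        rng = np.random.default_rng(7)
        cfg = NetConfig(n_genes=20, encoder_hidden=[12], bottleneck_dim=6,
                        predictor_hidden=[4], dropout=0.0)
        from scxfer.networks import build_bundle

        bundle = build_bundle(cfg, seed=0)
        Xb = rng.random((15, 20))
        yb = rng.integers(0, 2, 15)
        Xs = rng.random((12, 20))
        ids = [f"c{i}" for i in range(12)]
        clusters = ClusterLabels({c: i % 2 for i, c in enumerate(ids)}, 2)
        return bundle, Xb, yb, Xs, clusters, ids

    def test_zero_weights_reduce_to_classification(self):
        bundle, Xb, yb, Xs, clusters, ids = self._setup()
        from scxfer.networks import classification_loss, predict_bulk

        total, comp = joint_loss(
            bundle, Xb, yb, Xs, clusters, ids, LossWeights(alpha=0.0, beta=0.0)
        )
        expected = classification_loss(predict_bulk(bundle.E_b, bundle.P, Xb), yb)
        assert total == pytest.approx(expected, abs=1e-12)

    def test_components_sum_to_total(self):
        bundle, Xb, yb, Xs, clusters, ids = self._setup()
        w = LossWeights(alpha=0.7, beta=0.3)
        total, comp = joint_loss(bundle, Xb, yb, Xs, clusters, ids, w)
        assert total == pytest.approx(
            comp["loss_class"] + w.alpha * comp["loss_mmd"] + w.beta * comp["loss_reg"],
            abs=1e-10,
        )


class TestFit:
    def _data(self, seed=0):
        from scxfer.synthetic import generate
        from scxfer.io import qc_and_normalize_sc, scale_bulk, align_gene_spaces
        from scxfer.bulk import waterfall_binarize

        bulk, resp, sc, truth = generate(
            n_lines=80, n_cells=80, n_genes=120, n_sig=10, seed=seed
        )
        sc_s = qc_and_normalize_sc(sc, min_genes=20)
        b_s, sc_s = align_gene_spaces(scale_bulk(bulk), sc_s)
        wf = waterfall_binarize(resp.auc_pairs())
        y = np.array([wf.labels[s] for s in b_s.sample_ids])
        return b_s, y, sc_s, truth

    def test_same_seed_identical_run(self):
        b_s, y, sc_s, _ = self._data()
        cfg = NetConfig(n_genes=b_s.n_genes, encoder_hidden=[32], bottleneck_dim=8,
                        predictor_hidden=[8])
        sched = TrainSchedule(pretrain_epochs=3, dann_epochs=3, batch_size=40)
        user = {c: 0 for c in sc_s.sample_ids}
        from scxfer.transfer import cluster_cells

        cl = cluster_cells(sc_s, labels=user)
        b1, log1 = fit((b_s, y), sc_s, cfg, schedule=sched, seed=42, clusters=cl)
        b2, log2 = fit((b_s, y), sc_s, cfg, schedule=sched, seed=42, clusters=cl)
        for ma, mb in zip(b1.all_models(), b2.all_models()):
            for wa, wb in zip(ma.get_weights(), mb.get_weights()):
                np.testing.assert_array_equal(wa, wb)
        assert log1 == log2

    def test_epoch_totals_equal_component_sums(self):
        b_s, y, sc_s, _ = self._data(seed=1)
        cfg = NetConfig(n_genes=b_s.n_genes, encoder_hidden=[32], bottleneck_dim=8,
                        predictor_hidden=[8])
        sched = TrainSchedule(pretrain_epochs=2, dann_epochs=4, batch_size=40)
        w = LossWeights(alpha=0.25, beta=0.1)
        _, log = fit((b_s, y), sc_s, cfg, weights=w, schedule=sched, seed=0)
        stage4 = [r for r in log if r.get("stage") == 4]
        assert len(stage4) == 4
        for r in stage4:
            assert r["total"] == pytest.approx(
                r["loss_class"] + w.alpha * r["loss_mmd"] + w.beta * r["loss_reg"],
                abs=1e-10,
            )

    def test_single_class_labels_rejected(self):
        b_s, y, sc_s, _ = self._data(seed=2)
        cfg = NetConfig(n_genes=b_s.n_genes, encoder_hidden=[16], bottleneck_dim=4,
                        predictor_hidden=[4])
        with pytest.raises(ValueError, match="single class"):
            fit((b_s, np.zeros_like(y)), sc_s, cfg)
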