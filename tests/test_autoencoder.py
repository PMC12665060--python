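import numpy as np
import pytest

import mtis
from mtis.autoencoder import (
    SizeFactors,
    TrainConfig,
    _loss_and_grads,
    decode_heads,
    forward,
    normalize_counts,
)


class TestNormalization:
    def test_size_factors_from_totals(self):
        x = np.zeros((3, 2), dtype=int)
        x[0, 0], x[1, 0], x[2, 0] = 100, 200, 300
        _, sf, _ = normalize_counts(x)
        np.testing.assert_allclose(sf.factor, [0.5, 1.0, 1.5])

    def test_identical_cells_normalize_identically(self):
        x = np.array([[3, 1, 4], [3, 1, 4], [0, 2, 2]])
        norm, _, _ = normalize_counts(x)
        np.testing.assert_allclose(norm[0], norm[1])

    def test_zero_cell_with_stored_stats_stays_zero_before_zscore(self):
        train = np.array([[2, 3, 4], [1, 5, 2]])
        _, _, stats = normalize_counts(train)
        with pytest.warns(UserWarning):
            norm, _, _ = normalize_counts(
                np.zeros((1, 3), dtype=int),
                center=stats["center"],
                scale=stats["scale"],
                median_total=5.0,
            )
        # all-zero counts stay zero through log1p, then only the stored
        # z-scoring shifts them
        np.testing.assert_allclose(norm[0], -stats["center"] / stats["scale"])

    def test_zero_variance_gene_warns_scale_one(self):
        x = np.array([[1, 5], [1, 2], [1, 9]])
        x[:, 0] = [2, 2, 2]
        # gene 0 constant only before size-factor division is not enough;
        # make totals equal so it stays constant after normalization
        x = np.array([[2, 5], [2, 5], [2, 5]])
        with pytest.warns(UserWarning):
            _, _, stats = normalize_counts(x)
        np.testing.assert_allclose(stats["scale"], [1.0, 1.0])


class TestForward:
    def test_zero_weights_propagate_zeros(self):
        w = {
            "W1": np.zeros((3, 4)), "b1": np.zeros(4),
            "W2": np.zeros((4, 1)), "b2": np.zeros(1),
            "W3": np.zeros((1, 4)), "b3": np.zeros(4),
        }
        m, dc = forward(np.random.default_rng(0).normal(size=(5, 3)), w, TrainConfig())
        assert np.all(m == 0) and np.all(dc == 0)

    def test_hand_computed_two_gene_toy(self):
        w = {
            "W1": np.array([[1.0, 0.0], [0.0, 1.0]]), "b1": np.zeros(2),
            "W2": np.array([[1.0], [-1.0]]), "b2": np.zeros(1),
            "W3": np.array([[1.0, -1.0]]), "b3": np.zeros(2),
        }
        # norm [1,-1]: h1 = relu([1,-1]) = [1,0]; m = relu(1*1 + 0*-1) = 1;
        # dc = relu([1,-1]) = [1,0]
        m, dc = forward(np.array([[1.0, -1.0]]), w, TrainConfig(hidden=2))
        assert m[0] == pytest.approx(1.0)
        np.testing.assert_allclose(dc, [[1.0, 0.0]])

    def test_duplicated_rows_duplicate_outputs(self, smoke_model, smoke_data):
        cg, _, _ = smoke_data
        x = np.vstack([cg.counts[:1], cg.counts[:1]])
        out = smoke_model.transform(x)
        assert out[0, 0] == pytest.approx(out[1, 0])


class TestDecodeHeads:
    @staticmethod
    def _zero_head_weights(q=3, hidden=4):
        return {
            "Wk": np.zeros((hidden, q)), "bk": np.zeros(q),
            "Wr": np.zeros((hidden, q)), "br": np.zeros(q),
            "Wp": np.zeros((hidden, q)), "bp": np.zeros(q),
        }

    def test_zero_dc_literal(self):
        w = self._zero_head_weights()
        sf = SizeFactors(np.array([4.0, 8.0]), median_total=4.0)
        params = decode_heads(np.zeros((2, 4)), sf, w, mode="literal")
        np.testing.assert_allclose(params.dispersion, 1.0)
        np.testing.assert_allclose(params.dropout, 0.5)
        np.testing.assert_allclose(params.mean[:, 0], [0.5, 1.0])  # 0.5 * s_c

    def test_zero_dc_dca(self):
        w = self._zero_head_weights()
        sf = SizeFactors(np.array([4.0, 8.0]), median_total=4.0)
        params = decode_heads(np.zeros((2, 4)), sf, w, mode="dca")
        np.testing.assert_allclose(params.mean[:, 0], [1.0, 2.0])  # s_c
        np.testing.assert_allclose(params.dispersion, 1.0)
        np.testing.assert_allclose(params.dropout, 0.5)

    def test_dropout_identical_across_modes(self):
        rng = np.random.default_rng(3)
        w = self._zero_head_weights()
        for k in ("Wk", "Wr", "Wp"):
            w[k] = rng.normal(size=w[k].shape)
        dc = rng.normal(size=(6, 4)) ** 2
        sf = np.ones(6)
        lit = decode_heads(dc, sf, w, mode="literal")
        dca = decode_heads(dc, sf, w, mode="dca")
        np.testing.assert_allclose(lit.dropout, dca.dropout)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            decode_heads(np.zeros((1, 4)), np.ones(1), self._zero_head_weights(), "x")


class TestGradients:
    @pytest.mark.parametrize("head_mode", ["dca", "literal"])
    @pytest.mark.parametrize("bottleneck", ["relu", "linear"])
    def test_analytic_gradients_match_finite_differences(self, head_mode, bottleneck):
        """The hand-derived backprop equals central finite differences."""
        rng = np.random.default_rng(42)
        n, q, hidden = 6, 3, 4
        config = TrainConfig(
            hidden=hidden, head_mode=head_mode, bottleneck_activation=bottleneck
        )
        x = rng.poisson(3.0, size=(n, q)).astype(float)
        norm = rng.normal(size=(n, q))
        s = np.exp(rng.normal(0, 0.2, size=n))
        w = {
            "W1": rng.normal(0, 0.5, (q, hidden)), "b1": rng.normal(0, 0.1, hidden),
            "W2": rng.normal(0, 0.5, (hidden, 1)), "b2": rng.normal(0, 0.1, 1),
            "W3": rng.normal(0, 0.5, (1, hidden)), "b3": rng.normal(0, 0.1, hidden),
            "Wk": rng.normal(0, 0.5, (hidden, q)), "bk": rng.normal(0, 0.1, q),
            "Wr": rng.normal(0, 0.5, (hidden, q)), "br": rng.normal(0, 0.1, q),
            "Wp": rng.normal(0, 0.5, (hidden, q)), "bp": rng.normal(0, 0.1, q),
        }
        _, grads = _loss_and_grads(x, norm, s, w, config)
        eps = 1e-6
        for key in w:
            flat = w[key].ravel()
            idx = rng.choice(flat.size, size=min(5, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = _loss_and_grads(x, norm, s, w, config)
                flat[i] = orig - eps
                lm, _ = _loss_and_grads(x, norm, s, w, config)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[key].ravel()[i]
                assert analytic == pytest.approx(numeric, abs=1e-6, rel=1e-4), key


class TestTraining:
    def test_zero_epochs_returns_initialization(self, smoke_data):
        cg, _, _ = smoke_data
        est = mtis.MTISEncoder(epochs=0, random_state=5).fit(cg)
        assert est.loss_history_.size == 0
        assert np.isfinite(est.transform(cg)).all()

    def test_same_seed_bit_identical(self, smoke_data):
        cg, _, _ = smoke_data
        a = mtis.MTISEncoder(epochs=25, random_state=11).fit(cg)
        b = mtis.MTISEncoder(epochs=25, random_state=11).fit(cg)
        np.testing.assert_array_equal(a.loss_history_, b.loss_history_)
        for k in a.weights_:
            np.testing.assert_array_equal(a.weights_[k], b.weights_[k])
        np.testing.assert_array_equal(a.transform(cg), b.transform(cg))

    def test_loss_decreases_on_default_simulation(self):
        cfg = mtis.SimConfig(seed=1)  # 300 cells x 20 genes defaults
        cg, _, _ = mtis.simulate_dataset(cfg)
        est = mtis.MTISEncoder(random_state=1).fit(cg)
        assert est.loss_history_[-1] < est.loss_history_[0]
        first10 = np.median(est.loss_history_[:10])
        last10 = np.median(est.loss_history_[-10:])
        assert last10 <= first10

    def test_loss_threshold_stops_early(self, smoke_data):
        cg, _, _ = smoke_data
        est = mtis.MTISEncoder(
            epochs=200, loss_threshold=1e9, random_state=0
        ).fit(cg)
        assert est.loss_history_.size == 1


class TestEncode:
    def test_shape_and_finiteness(self, smoke_model, smoke_data):
        cg, _, _ = smoke_data
        table = smoke_model.mtis_table(cg)
        assert list(table.columns) == ["cell_id", "mtis"]
        assert len(table) == cg.n_cells
        assert np.isfinite(table["mtis"]).all()
        assert (table["mtis"] >= 0).all()  # relu bottleneck

    def test_identical_cells_identical_scores(self, smoke_model, smoke_data):
        cg, _, _ = smoke_data
        dup = mtis.CellGeneMatrix(
            ["a", "b"], cg.gene_symbols, np.vstack([cg.counts[3], cg.counts[3]])
        )
        t = smoke_model.mtis_table(dup)
        assert t["mtis"][0] == pytest.approx(t["mtis"][1])

    def test_gene_set_mismatch_raises(self, smoke_model, smoke_data):
        cg, _, _ = smoke_data
        wrong = mtis.CellGeneMatrix(
            cg.cell_ids, [f"X{j}" for j in range(cg.n_genes)], cg.counts
        )
        with pytest.raises(ValueError, match="gene set"):
            smoke_model.transform(wrong)


class TestPersistence:
    def test_json_checkpoint_round_trip(self, smoke_model, smoke_data, tmp_path):
        cg, _, _ = smoke_data
        path = smoke_model.save(tmp_path / "model.json")
        back = mtis.MTISEncoder.load(path)
        np.testing.assert_array_equal(back.transform(cg), smoke_model.transform(cg))

    def test_sklearn_get_set_params(self):
        est = mtis.MTISEncoder(epochs=5)
        params = est.get_params()
        assert params["epochs"] == 5
        est.set_params(head_mode="literal")
        assert est.head_mode == "literal"
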