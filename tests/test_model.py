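import dataclasses
import filecmp

import numpy as np
import pytest

from conftest import build_model, random_model
from exprembed.io import ExpressionMatrix
from exprembed.model import (
    EmbeddingConfig,
    batch_gradients,
    export_projector,
    init_model,
    load_model,
    lr_find,
    mse,
    predict_cell,
    predict_matrix,
    save_model,
    train,
)
from exprembed.simulate import SynthConfig, generate


def log2_matrix(values):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return ExpressionMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(k)],
        values=values,
        is_log2=True,
    )


def loop_predict(model):
    """Independent per-cell double loop (oracle)."""
    n, k = len(model.sample_ids), len(model.gene_ids)
    out = np.empty((n, k))
    for i in range(n):
        for a in range(k):
            acc = 0.0
            for j in range(model.dim):
                acc += model.G[a, j] * model.S[i, j]
            out[i, a] = acc + model.b_gene[a] + model.b_sample[i]
    return out


def noiseless_rank3(seed=5):
    cfg = SynthConfig(
        n_samples=60,
        k_genes=80,
        latent_rank=3,
        n_groups=3,
        noise_sd=0.0,
        modules=(),
        seed=seed,
    )
    expr, _ = generate(cfg)
    return expr


class TestInit:
    def test_seeded_determinism(self):
        expr = log2_matrix(np.ones((3, 4)))
        cfg = EmbeddingConfig(dim=5, seed=1)
        m1, m2 = init_model(expr, cfg), init_model(expr, cfg)
        np.testing.assert_array_equal(m1.G, m2.G)
        np.testing.assert_array_equal(m1.S, m2.S)
        np.testing.assert_array_equal(m1.b_gene, m2.b_gene)
        np.testing.assert_array_equal(m1.b_sample, m2.b_sample)

    def test_uniform_bounds_and_shapes(self):
        expr = log2_matrix(np.ones((2, 3)))
        model = init_model(expr, EmbeddingConfig(dim=4, seed=0))
        assert model.G.shape == (3, 4) and model.S.shape == (2, 4)
        for arr in (model.G, model.S, model.b_gene, model.b_sample):
            assert np.all(np.abs(arr) <= 0.05)

    def test_different_seeds_differ(self):
        expr = log2_matrix(np.ones((3, 4)))
        m1 = init_model(expr, EmbeddingConfig(dim=5, seed=1))
        m2 = init_model(expr, EmbeddingConfig(dim=5, seed=2))
        assert not np.array_equal(m1.G, m2.G)


class TestPredict:
    def test_hand_arithmetic(self):
        model = build_model(G=[[1.0, 2.0]], S=[[3.0, 4.0]], b_gene=[0.5], b_sample=[-0.5])
        assert predict_cell(model, 0, 0) == pytest.approx(11.0)

    def test_zero_vectors_leave_biases(self):
        model = build_model(G=[[0.0, 0.0]], S=[[0.0, 0.0]], b_gene=[2.0], b_sample=[3.0])
        assert predict_cell(model, 0, 0) == pytest.approx(5.0)

    def test_index_out_of_range(self):
        model = build_model(G=[[1.0]], S=[[1.0]])
        with pytest.raises(IndexError):
            predict_cell(model, 1, 0)
        with pytest.raises(IndexError):
            predict_cell(model, 0, 5)

    def test_matrix_equals_cell_loop(self, rng):
        model = random_model(rng, n_samples=10, n_genes=8, dim=6)
        pm = predict_matrix(model)
        assert np.max(np.abs(pm - loop_predict(model))) <= 1e-12
        for i in range(10):
            for a in range(8):
                assert abs(pm[i, a] - predict_cell(model, i, a)) <= 1e-12

    def test_rank1_outer_product(self):
        u = np.array([[1.0], [2.0], [3.0]])  # samples
        v = np.array([[4.0], [5.0]])  # genes
        model = build_model(G=v, S=u)
        np.testing.assert_allclose(predict_matrix(model), u @ v.T)

    def test_all_zero_model(self):
        model = build_model(G=np.zeros((3, 2)), S=np.zeros((2, 2)))
        np.testing.assert_array_equal(predict_matrix(model), np.zeros((2, 3)))


class TestMse:
    def test_exact_prediction_gives_zero(self, rng):
        model = random_model(rng, 4, 5, 3)
        expr = log2_matrix(np.abs(predict_matrix(model)))
        model.b_gene += 0.0
        expr.values = predict_matrix(model)
        assert mse(model, expr) == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset_squared(self, rng):
        model = random_model(rng, 4, 5, 3)
        expr = log2_matrix(np.abs(predict_matrix(model)) * 0 + 1)
        expr.values = predict_matrix(model) + 0.7
        assert mse(model, expr) == pytest.approx(0.49)

    def test_equals_loop(self, rng):
        model = random_model(rng, 6, 7, 4)
        vals = rng.normal(size=(6, 7))
        expr = log2_matrix(np.zeros((6, 7)))
        expr.values = vals
        pm = loop_predict(model)
        expected = np.mean([(pm[i, a] - vals[i, a]) ** 2 for i in range(6) for a in range(7)])
        assert mse(model, expr) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self, rng):
        model = random_model(rng, 4, 5, 3)
        with pytest.raises(ValueError):
            mse(model, log2_matrix(np.zeros((3, 5))))


class TestGradients:
    def test_matches_central_finite_differences(self, rng):
        model = random_model(rng, n_samples=4, n_genes=5, dim=3, scale=0.5)
        bsz = 8
        si = rng.integers(0, 4, bsz)
        gi = rng.integers(0, 5, bsz)
        y = rng.normal(size=bsz)

        def batch_loss(m):
            pred = (
                np.einsum("ij,ij->i", m.G[gi], m.S[si]) + m.b_gene[gi] + m.b_sample[si]
            )
            return np.mean((pred - y) ** 2)

        dG, dS, dbg, dbs = batch_gradients(model, si, gi, y)
        eps = 1e-6
        for arr, grad in ((model.G, dG), (model.S, dS), (model.b_gene, dbg), (model.b_sample, dbs)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = batch_loss(model)
                arr[idx] = orig - eps
                lm = batch_loss(model)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(grad[idx]), 1e-8)
                assert abs(fd - grad[idx]) / denom <= 1e-5


class TestTrain:
    def test_epochs_zero_is_init(self):
        expr = noiseless_rank3()
        cfg = EmbeddingConfig(dim=3, epochs=0, seed=7)
        model, report = train(expr, cfg)
        ref = init_model(expr, cfg)
        np.testing.assert_array_equal(model.G, ref.G)
        np.testing.assert_array_equal(model.S, ref.S)
        assert report.train_mse == [] and report.val_mse == []

    def test_seeded_repeatability(self):
        expr = noiseless_rank3()
        cfg = EmbeddingConfig(dim=3, epochs=2, seed=3)
        m1, r1 = train(expr, cfg)
        m2, r2 = train(expr, cfg)
        np.testing.assert_array_equal(m1.G, m2.G)
        np.testing.assert_array_equal(m1.S, m2.S)
        assert r1.train_mse == r2.train_mse

    def test_noiseless_rank3_converges_100x(self):
        expr = noiseless_rank3()
        cfg = EmbeddingConfig(dim=3, epochs=30, seed=7, learning_rate=2e-2)
        model, report = train(expr, cfg)
        assert report.train_mse[-1] < 0.01 * report.train_mse[0]

    def test_nonfinite_loss_advises_lower_lr(self):
        expr = noiseless_rank3()
        cfg = EmbeddingConfig(dim=3, epochs=5, seed=7, learning_rate=1e160)
        with pytest.raises(FloatingPointError, match="lower learning rate"):
            train(expr, cfg)

    def test_constant_shift_absorbed_by_biases(self):
        # noise keeps both runs at a stable loss floor, so the comparison is
        # between floors rather than between oscillations around zero
        cfg0 = SynthConfig(
            n_samples=60, k_genes=80, latent_rank=3, n_groups=3,
            noise_sd=0.3, modules=(), seed=5,
        )
        expr, _ = generate(cfg0)
        cfg = EmbeddingConfig(dim=3, epochs=30, seed=7, learning_rate=2e-2)
        _, base = train(expr, cfg)
        shifted = ExpressionMatrix(
            list(expr.sample_ids), list(expr.gene_ids), expr.values + 2.0,
            is_log2=True,
        )
        _, moved = train(shifted, cfg)
        assert moved.train_mse[-1] <= 1.1 * base.train_mse[-1]

    def test_exchange_symmetry_full_batch(self):
        """Transposing the matrix and swapping gene/sample roles (with the
        initial weights mapped accordingly) gives the same loss trajectory
        under full-batch training."""
        expr = noiseless_rank3()
        n_cells = expr.n_samples * expr.n_genes
        cfg = EmbeddingConfig(
            dim=3, epochs=5, seed=7, batch_size=n_cells, validation_fraction=0.0
        )
        init = init_model(expr, cfg)
        transposed = ExpressionMatrix(
            sample_ids=list(expr.gene_ids),
            gene_ids=list(expr.sample_ids),
            values=expr.values.T.copy(),
            is_log2=True,
        )
        init_t = build_model(
            G=init.S,
            S=init.G,
            b_gene=init.b_sample,
            b_sample=init.b_gene,
            gene_ids=list(expr.sample_ids),
            sample_ids=list(expr.gene_ids),
        )
        init_t = dataclasses.replace(init_t, config=cfg)
        _, rep_a = train(expr, cfg, initial_model=init)
        _, rep_b = train(transposed, cfg, initial_model=init_t)
        np.testing.assert_allclose(rep_a.train_mse, rep_b.train_mse, rtol=1e-12)

    def test_heldout_recovery_on_lowrank_noiseless(self):
        cfg = SynthConfig(
            n_samples=80, k_genes=120, latent_rank=3, n_groups=3, noise_sd=0.0,
            modules=(), seed=9,
        )
        expr, _ = generate(cfg)
        ec = EmbeddingConfig(dim=5, epochs=40, seed=9, learning_rate=1e-2)
        model, report = train(expr, ec)
        assert report.val_mse[-1] < 0.02  # small floor when noiseless


class TestLrFind:
    def test_curve_contract(self):
        expr = noiseless_rank3()
        cfg = EmbeddingConfig(dim=3, seed=7)
        res = lr_find(expr, cfg, lr_min=1e-5, lr_max=1.0, steps=40)
        assert len(res.losses) <= 40
        assert np.all(np.diff(np.log(res.rates)) > 0)
        ratios = res.rates[1:] / res.rates[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert res.suggested_lr > 0

    def test_invalid_range_rejected(self):
        expr = noiseless_rank3()
        with pytest.raises(ValueError):
            lr_find(expr, EmbeddingConfig(dim=3), lr_min=1.0, lr_max=0.5)

    def test_suggested_rate_beats_lr_max(self):
        expr = noiseless_rank3()
        cfg = EmbeddingConfig(dim=3, seed=7, epochs=10)
        res = lr_find(expr, cfg, lr_min=1e-5, lr_max=5.0, steps=60)
        good = dataclasses.replace(cfg, learning_rate=res.suggested_lr)
        _, rep_good = train(expr, good)
        try:
            bad = dataclasses.replace(cfg, learning_rate=5.0)
            _, rep_bad = train(expr, bad)
            bad_final = rep_bad.train_mse[-1]
        except FloatingPointError:
            bad_final = float("inf")
        assert rep_good.train_mse[-1] < bad_final


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        model = random_model(rng, 5, 7, 3)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert back.gene_ids == model.gene_ids
        assert back.sample_ids == model.sample_ids
        np.testing.assert_array_equal(back.G, model.G)
        np.testing.assert_array_equal(back.b_sample, model.b_sample)

    def test_byte_identical_across_runs(self, tmp_path):
        expr = noiseless_rank3()
        cfg = EmbeddingConfig(dim=3, epochs=2, seed=3)
        for d in ("a", "b"):
            model, report = train(expr, cfg)
            save_model(model, tmp_path / d, report)
        for name in ("gene_vectors.tsv", "sample_vectors.tsv", "biases.tsv", "config.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_projector_export_format(self, rng, tmp_path):
        model = random_model(rng, 4, 6, 3)
        export_projector(model, tmp_path, space="gene")
        vec_lines = (tmp_path / "gene_vectors.tsv").read_text().splitlines()
        meta_lines = (tmp_path / "gene_metadata.tsv").read_text().splitlines()
        assert len(vec_lines) == 6 and len(meta_lines) == 6  # no headers
        assert all(len(line.split("\t")) == 3 for line in vec_lines)
        assert meta_lines == model.gene_ids


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dim": 0},
            {"batch_size": 0},
            {"init_half_range": 0.0},
            {"validation_fraction": 0.6},
            {"learning_rate": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EmbeddingConfig(**kwargs)
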