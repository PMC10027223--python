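"""Encoder/decoder equation oracles and training contracts of the autoencoder."""

import numpy as np
import pytest

from combosyn.data import CellLineGraphSet, Label, SynergyDataset, SynergyRecord, SynergyType
from combosyn.embedding import (EncoderParams, MultiChannelGraphAutoencoder,
                                bilinear_decode, common_fuse, encoder_layer,
                                fuse_layers, reconstruction_loss, total_loss)


def random_graphs(rng, n, p=0.5):
    """Random three-channel graph set: each measured pair gets one channel."""
    A = np.zeros((3, n, n))
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                t = rng.integers(0, 3)
                A[t, i, j] = A[t, j, i] = 1.0
                pairs.add((i, j))
    return CellLineGraphSet("c", A, pairs)


def encoder_layer_loop(graphs, H_prev, params, layer):
    """Per-node double-loop transcription of the layer update rule."""
    n = graphs.n_drugs
    d = params.self_weights[layer].shape[1]
    out = np.zeros((n, d))
    for i in range(n):
        acc = H_prev[i] @ params.self_weights[layer]
        for t, W in params.channel_weights[layer].items():
            nbrs = np.nonzero(graphs.A[t][i])[0]
            if len(nbrs) == 0:
                continue
            for j in nbrs:
                acc = acc + (params.channel_attention[t] / len(nbrs)) * (H_prev[j] @ W)
        out[i] = np.maximum(acc, 0.0)
    return out


class TestEncoderLayer:
    @pytest.mark.parametrize("n,d0,d,seed", [(4, 3, 2, 0), (6, 4, 4, 1),
                                             (5, 2, 3, 2), (6, 4, 2, 3)])
    def test_matches_per_node_loop(self, n, d0, d, seed):
        rng = np.random.default_rng(seed)
        graphs = random_graphs(rng, n)
        H = rng.normal(size=(n, d0))
        params = EncoderParams(
            channel_weights=[{t: rng.normal(size=(d0, d)) for t in range(3)}],
            self_weights=[rng.normal(size=(d0, d))],
            channel_attention={t: rng.normal() for t in range(3)},
            layer_attention=np.ones(1))
        got = encoder_layer(graphs, H, params, 0)
        want = encoder_layer_loop(graphs, H, params, 0)
        assert np.allclose(got, want, atol=1e-10)

    def test_isolated_drug_sees_only_self_term(self, rng):
        n, d = 3, 2
        A = np.zeros((3, n, n))
        A[0, 0, 1] = A[0, 1, 0] = 1.0   # drug 2 is isolated
        graphs = CellLineGraphSet("c", A, {(0, 1)})
        H = rng.normal(size=(n, d))
        W0 = rng.normal(size=(d, d))
        params = EncoderParams([{0: rng.normal(size=(d, d))}], [W0],
                               {0: 1.0}, np.ones(1))
        out = encoder_layer(graphs, H, params, 0)
        assert np.allclose(out[2], np.maximum(H[2] @ W0, 0.0))

    def test_single_edge_identity_weights(self):
        # 2 drugs, one synergistic edge, identity weights: both nodes get (1, 1)
        A = np.zeros((3, 2, 2))
        A[0] = [[0, 1], [1, 0]]
        graphs = CellLineGraphSet("c", A, {(0, 1)})
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        params = EncoderParams([{0: np.eye(2)}], [np.eye(2)], {0: 1.0}, np.ones(1))
        out = encoder_layer(graphs, H, params, 0)
        assert np.allclose(out, [[1.0, 1.0], [1.0, 1.0]])

    def test_zero_weights_zero_output(self, rng):
        graphs = random_graphs(rng, 4)
        H = rng.normal(size=(4, 3))
        params = EncoderParams([{t: np.zeros((3, 2)) for t in range(3)}],
                               [np.zeros((3, 2))], {t: 1.0 for t in range(3)},
                               np.ones(1))
        assert np.all(encoder_layer(graphs, H, params, 0) == 0.0)


class TestFusions:
    def test_one_hot_layer_attention(self, rng):
        Ms = [rng.normal(size=(4, 3)) for _ in range(3)]
        assert np.allclose(fuse_layers(Ms, (1, 0, 0)), Ms[0])

    def test_generic_beta_vs_loop(self, rng):
        M1, M2 = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        got = fuse_layers([M1, M2], (2.0, -1.0))
        want = np.array([[2 * M1[i, j] - M2[i, j] for j in range(2)]
                         for i in range(5)])
        assert np.allclose(got, want)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            fuse_layers([rng.normal(size=(2, 2))], (1.0, 1.0))

    def test_common_fuse_single_cell_line(self, rng):
        M = rng.normal(size=(4, 3))
        assert np.allclose(common_fuse([M], [1.0]), M)

    def test_common_fuse_vs_loop(self, rng):
        Ms = [rng.normal(size=(3, 2)) for _ in range(3)]
        alpha = [0.2, -1.3, 0.8]
        want = sum(a * M for a, M in zip(alpha, Ms))
        assert np.allclose(common_fuse(Ms, alpha), want)


class TestBilinearDecode:
    def test_scalar_case(self):
        H = np.array([[1.0]])
        S = bilinear_decode(H, H, np.array([1.0]), np.array([[1.0]]))
        assert S[0, 0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)
        assert S[0, 0] == pytest.approx(0.731059, abs=1e-6)

    def test_zero_embeddings_give_half(self, rng):
        H = np.zeros((4, 3))
        S = bilinear_decode(H, H, rng.normal(size=3), rng.normal(size=(3, 3)))
        assert np.allclose(S, 0.5)

    def test_symmetry_and_range(self, rng):
        H = rng.normal(size=(5, 3))
        S = bilinear_decode(H, H, rng.normal(size=3), rng.normal(size=(3, 3)))
        assert np.allclose(S, S.T)
        assert np.all((S > 0) & (S < 1))

    def test_matches_elementwise_formula(self, rng):
        H, D, B = rng.normal(size=(4, 2)), rng.normal(size=2), rng.normal(size=(2, 2))
        S = bilinear_decode(H, H, D, B)
        for i in range(4):
            for j in range(4):
                fwd = 1 / (1 + np.exp(-(H[i] * D) @ B @ (H[j] * D)))
                bwd = 1 / (1 + np.exp(-(H[j] * D) @ B @ (H[i] * D)))
                assert S[i, j] == pytest.approx(0.5 * (fwd + bwd), abs=1e-10)

    def test_nonfinite_params_rejected(self, rng):
        H = rng.normal(size=(2, 2))
        with pytest.raises(ValueError):
            bilinear_decode(H, H, np.array([np.nan, 1.0]), np.eye(2))


class TestLosses:
    def test_perfect_scores_zero_loss(self, rng):
        graphs = random_graphs(rng, 5)
        scores = {t: graphs.A[t].astype(float) for t in range(3)}
        assert reconstruction_loss(graphs, scores) == 0.0

    def test_half_scores_hand_value(self):
        A = np.zeros((3, 2, 2))
        A[0] = [[0, 1], [1, 0]]
        graphs = CellLineGraphSet("c", A, {(0, 1)})
        scores = {t: np.full((2, 2), 0.5) for t in range(3)}
        # (1-.5)^2 + (0-.5)^2 + (0-.5)^2 over the single measured pair
        assert reconstruction_loss(graphs, scores) == pytest.approx(0.75)

    def test_no_measured_pairs(self):
        graphs = CellLineGraphSet("c", np.zeros((3, 3, 3)), set())
        assert reconstruction_loss(graphs, {t: np.ones((3, 3)) for t in range(3)}) == 0.0

    def test_loss_vs_loop_transcription(self, rng):
        graphs = random_graphs(rng, 6)
        scores = {t: rng.random((6, 6)) for t in range(3)}
        for t in scores:
            scores[t] = 0.5 * (scores[t] + scores[t].T)
        want = 0.0
        for t in range(3):
            terms = [(graphs.A[t][i, j] - scores[t][i, j]) ** 2
                     for (i, j) in graphs.measured_pairs]
            want += sum(terms) / len(graphs.measured_pairs)
        assert reconstruction_loss(graphs, scores) == pytest.approx(want, abs=1e-10)

    def test_total_loss_is_plain_sum(self):
        assert total_loss(0.0, []) == 0.0
        assert total_loss(1.5, [0.25, 0.25]) == pytest.approx(2.0)
        assert total_loss(0.7, [0.1]) == pytest.approx(0.8)


def tiny_dataset():
    recs = []
    scores = {("a", "b"): 40.0, ("a", "c"): 35.0, ("b", "c"): 10.0,
              ("a", "d"): -5.0, ("c", "d"): 12.0, ("b", "d"): 33.0}
    for cell in ("c1", "c2"):
        for (x, y), s in scores.items():
            s = s if cell == "c1" else s - 8.0
            from combosyn.data import classify_synergy
            recs.append(SynergyRecord(x, y, cell, s, SynergyType.LOEWE,
                                      classify_synergy(s, SynergyType.LOEWE)))
    return SynergyDataset.from_records(recs)


class TestTraining:
    def test_loss_decreases_and_trace_finite(self, small_fingerprints, small_dataset):
        ds, _ = small_dataset
        gae = MultiChannelGraphAutoencoder(embedding_dim=8, epochs=200,
                                           learning_rate=5e-3, seed=0)
        gae.fit(ds, small_fingerprints)
        trace = [t["total"] for t in gae.loss_trace_]
        assert np.isfinite(trace).all()
        assert gae.final_loss_["total"] < trace[0]

    def test_same_seed_identical_trace(self, small_fingerprints, small_dataset):
        ds, _ = small_dataset
        runs = []
        for _ in range(2):
            gae = MultiChannelGraphAutoencoder(embedding_dim=8, epochs=50,
                                               seed=5).fit(ds, small_fingerprints)
            runs.append([t["total"] for t in gae.loss_trace_])
        assert np.allclose(runs[0], runs[1], atol=1e-6)

    def test_syn_only_ablation(self, small_fingerprints, small_dataset):
        ds, _ = small_dataset
        gae = MultiChannelGraphAutoencoder(embedding_dim=8, epochs=100,
                                           channels="syn", seed=0)
        gae.fit(ds, small_fingerprints)
        keys = {k[0:1] + k[2:3] for k in gae.params_ if k[0] == "enc_W"}
        assert keys == {("enc_W", 0)}   # channels 1, 2 have no parameters
        assert gae.final_loss_["total"] < gae.loss_trace_[0]["total"]

    def test_total_loss_is_common_plus_specific(self, small_fingerprints, small_dataset):
        ds, _ = small_dataset
        gae = MultiChannelGraphAutoencoder(embedding_dim=4, epochs=5,
                                           seed=1).fit(ds, small_fingerprints)
        for entry in gae.loss_trace_:
            assert entry["total"] == pytest.approx(
                entry["common"] + sum(entry["specific"].values()), abs=1e-9)

    def test_estimator_forward_matches_functional_ops(self):
        """The fitted specific embeddings equal the functional encoder chain."""
        from combosyn.data import build_cell_line_graphs, featurize_drugs
        ds = tiny_dataset()
        fp = featurize_drugs(None, ds.drugs, n_bits=8, seed=3)
        gae = MultiChannelGraphAutoencoder(embedding_dim=4, n_layers=2,
                                           epochs=3, seed=3).fit(ds, fp)
        P = gae.params_
        for cell in ds.cell_lines:
            graphs = build_cell_line_graphs(ds, cell)
            params = EncoderParams(
                channel_weights=[{t: P[("enc_W", cell, t, l)].data
                                  for t in range(3)} for l in range(2)],
                self_weights=[P[("enc_W0", cell, l)].data for l in range(2)],
                channel_attention={t: float(P[("alpha", cell, t)].data)
                                   for t in range(3)},
                layer_attention=P[("beta", cell)].data)
            H = fp.F
            layers = []
            for l in range(2):
                H = encoder_layer(graphs, H, params, l)
                layers.append(H)
            H_spe = fuse_layers(layers, params.layer_attention)
            assert np.allclose(H_spe, gae.embeddings_.specific[cell], atol=1e-8)

    def test_gradients_match_finite_differences(self):
        """Joint-objective gradients check out against central differences."""
        from combosyn.data import featurize_drugs
        ds = tiny_dataset()
        fp = featurize_drugs(None, ds.drugs, n_bits=6, seed=2)
        gae = MultiChannelGraphAutoencoder(embedding_dim=3, n_layers=2,
                                           epochs=0, seed=2).fit(ds, fp)
        P = gae.params_

        def loss_value():
            total, *_ = gae._forward(P, gae.graph_sets_, gae._A_norm_,
                                     gae._masks_, gae._H0_)
            return float(total.data)

        for p in P.values():
            p.grad = None
        total, *_ = gae._forward(P, gae.graph_sets_, gae._A_norm_,
                                 gae._masks_, gae._H0_)
        total.backward()

        rng = np.random.default_rng(0)
        keys = list(P)
        checked = 0
        while checked < 20:
            key = keys[rng.integers(len(keys))]
            p = P[key]
            idx = tuple(rng.integers(s) for s in p.data.shape)
            eps = 1e-5
            p.data[idx] += eps
            hi = loss_value()
            p.data[idx] -= 2 * eps
            lo = loss_value()
            p.data[idx] += eps
            num = (hi - lo) / (2 * eps)
            ana = p.grad[idx] if p.grad is not None else 0.0
            denom = max(abs(num), abs(ana), 1e-4)
            assert abs(num - ana) / denom < 1e-3, (key, idx, num, ana)
            checked += 1

    def test_divergence_raises_with_epoch(self, small_fingerprints, small_dataset):
        ds, _ = small_dataset
        gae = MultiChannelGraphAutoencoder(embedding_dim=8, epochs=50,
                                           learning_rate=1e80, seed=0)
        with pytest.raises(FloatingPointError, match="epoch"):
            gae.fit(ds, small_fingerprints)

    def test_missing_cell_line_falls_back_to_common(self, small_fingerprints,
                                                    small_dataset):
        ds, _ = small_dataset
        held_out = ds.cell_lines[-1]
        train = [i for i in range(len(ds.records))
                 if ds.records[i].cell_line != held_out]
        gae = MultiChannelGraphAutoencoder(embedding_dim=4, epochs=10,
                                           seed=0).fit(ds, small_fingerprints,
                                                       train_records=train)
        assert held_out not in gae.embeddings_.specific
        M, substituted = gae.embeddings_.specific_or_common(held_out)
        assert substituted and np.allclose(M, gae.embeddings_.common)

    def test_checkpoint_roundtrip(self, tmp_path, small_fingerprints, small_dataset):
        ds, _ = small_dataset
        gae = MultiChannelGraphAutoencoder(embedding_dim=4, epochs=5,
                                           seed=0).fit(ds, small_fingerprints)
        gae.save(tmp_path / "ckpt")
        import json
        manifest = json.loads((tmp_path / "ckpt" / "manifest.json").read_text())
        assert manifest["config"]["embedding_dim"] == 4
        arrays = np.load(tmp_path / "ckpt" / "params.npz")
        for key, tensor in gae.params_.items():
            assert np.array_equal(arrays["|".join(map(str, key))], tensor.data)
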