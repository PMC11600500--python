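"""The attention module: normalisation, locality, invariance, determinism."""

import numpy as np
import pytest

from rnaqa.autodiff import Tensor
from rnaqa.features import edge_features, knn_graph, nucleotide_features
from rnaqa.frames import frames_from_structure, stack_frames
from rnaqa.network import (
    ModelConfig,
    attention_weights,
    forward,
    init_model,
    ipa_layer,
    parameter_count,
    predict,
    save_params,
    load_params,
    structure_inputs,
)
from conftest import random_rotation


def _state(structure, config, seed=0):
    params = init_model(config, seed)
    node, edge, nbr, R, t = structure_inputs(structure, config)
    s = Tensor(node @ params["node_proj_W"].data + params["node_proj_b"].data)
    e = Tensor(np.einsum("lkp,pc->lkc", edge, params["pair_proj_W"].data)
               + params["pair_proj_b"].data)
    return params, s, e, Tensor(R), Tensor(t), nbr


def test_init_is_deterministic_and_seed_sensitive(tiny_config):
    a = init_model(tiny_config, 5)
    b = init_model(tiny_config, 5)
    c = init_model(tiny_config, 6)
    assert all(np.array_equal(a[k].data, b[k].data) for k in a)
    assert any(not np.array_equal(a[k].data, c[k].data) for k in a)


def test_parameter_count_independent_of_k(tiny_config):
    from dataclasses import replace

    n = parameter_count(tiny_config)
    assert n == parameter_count(replace(tiny_config, K=3))
    assert n > 0


def test_attention_rows_sum_to_one(helix20, tiny_config):
    params, s, e, R, t, nbr = _state(helix20, tiny_config, seed=1)
    a = attention_weights(params, 0, tiny_config, s, e, R, t, nbr)
    assert a.data.shape == (20, 6, tiny_config.n_heads)
    np.testing.assert_allclose(a.data.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(a.data >= 0)


def test_zero_parameters_give_uniform_attention(helix20, tiny_config):
    params, s, e, R, t, nbr = _state(helix20, tiny_config, seed=1)
    for k, p in params.items():
        if k.startswith("l0."):
            p.data = np.zeros_like(p.data)
    a = attention_weights(params, 0, tiny_config, s, e, R, t, nbr)
    np.testing.assert_allclose(a.data, 1.0 / nbr.shape[1], atol=1e-12)


def test_attention_matches_scalar_hand_evaluation(tiny_config):
    """L=2 toy: recompute one row of attention logits with plain scalar
    arithmetic straight from the update rule."""
    from rnaqa.synthetic import make_native

    s2 = make_native(2, seed=0)
    config = ModelConfig(n_layers=1, n_heads=1, hidden=4,
                         n_query_points=1, n_value_points=1, K=2)
    params, s, e, R, t, nbr = _state(s2, config, seed=3)
    a = attention_weights(params, 0, config, s, e, R, t, nbr)

    ch = config.head_width
    i = 0
    logits = []
    for m, j in enumerate(nbr[i]):
        q = s.data[i] @ params["l0.q_W"].data
        k = s.data[j] @ params["l0.k_W"].data
        qk = float(q @ k) / np.sqrt(ch)
        b = float((e.data[i, m] @ params["l0.bias_W"].data + params["l0.bias_b"].data)[0])
        qp = R.data[i] @ (s.data[i] @ params["l0.qp_W"].data) + t.data[i]
        kp = R.data[j] @ (s.data[j] @ params["l0.kp_W"].data) + t.data[j]
        gamma = params["l0.gamma"].data[0]
        sq = float(((qp - kp) ** 2).sum())
        logits.append(config.w_L * (qk + b - gamma * config.w_C / 2.0 * sq))
    expected = np.exp(logits - np.max(logits))
    expected /= expected.sum()
    np.testing.assert_allclose(a.data[i, :, 0], expected, atol=1e-10)


def test_single_nucleotide_point_outputs_equal_point_values():
    """L=1: attention is the self edge, so the point output returns to the
    local frame unchanged (T^-1 o T o v = v)."""
    from rnaqa.synthetic import make_native
    from rnaqa.autodiff import einsum

    s1_struct = make_native(2, seed=0)
    config = ModelConfig(n_layers=1, n_heads=1, hidden=4,
                         n_query_points=1, n_value_points=1, K=1)
    params, s, e, R, t, nbr = _state(s1_struct, config, seed=4)
    a = attention_weights(params, 0, config, s, e, R, t, nbr)
    np.testing.assert_allclose(a.data, 1.0, atol=1e-12)  # single self edge

    vp_local = (s.data @ params["l0.vp_W"].data).reshape(2, 1, 1, 3)
    vp_global = np.einsum("lxy,lhpy->lhpx", R.data, vp_local) + t.data[:, None, None, :]
    op_g = np.einsum("lmh,lmhvx->lhvx", a.data, vp_global[nbr])
    op_local = np.einsum("lyx,lhvy->lhvx", R.data, op_g - t.data[:, None, None, :])
    np.testing.assert_allclose(op_local, vp_local, atol=1e-9)


def test_single_layer_locality(helix20):
    """With one IPA layer, pNuL_i depends only on nucleotides in N(i)."""
    config = ModelConfig(n_layers=1, n_heads=2, hidden=16,
                         n_query_points=2, n_value_points=2, K=5)
    params = init_model(config, seed=2)
    node, edge, nbr, R, t = structure_inputs(helix20, config)
    base = forward(params, config, node, edge, nbr, R, t).data

    i = 0
    outside = [j for j in range(helix20.L) if j not in set(nbr[i])]
    j = outside[-1]
    node2 = node.copy()
    node2[j] = node2[j] + 10.0  # large feature perturbation out of N(i)
    out = forward(params, config, node2, edge, nbr, R, t).data
    assert abs(out[i] - base[i]) < 1e-9
    assert abs(out[j] - base[j]) > 1e-3  # it does change its own score


def test_reduces_to_edge_biased_attention_without_points(helix20, tiny_config):
    """Zeroing the point maps must reproduce a minimal softmax attention
    computed independently with plain numpy."""
    params, s, e, R, t, nbr = _state(helix20, tiny_config, seed=5)
    for k in ("l0.qp_W", "l0.kp_W", "l0.gamma"):
        params[k].data = np.zeros_like(params[k].data)
    a = attention_weights(params, 0, tiny_config, s, e, R, t, nbr)

    H, ch = tiny_config.n_heads, tiny_config.head_width
    q = (s.data @ params["l0.q_W"].data).reshape(-1, H, ch)
    k_ = (s.data @ params["l0.k_W"].data).reshape(-1, H, ch)
    bias = e.data @ params["l0.bias_W"].data + params["l0.bias_b"].data
    logits = (np.einsum("lhc,lmhc->lmh", q, k_[nbr]) / np.sqrt(ch) + bias) * tiny_config.w_L
    ex = np.exp(logits - logits.max(axis=1, keepdims=True))
    np.testing.assert_allclose(a.data, ex / ex.sum(axis=1, keepdims=True), atol=1e-10)


def test_pnul_in_open_unit_interval_and_pmol_is_mean(helix20, tiny_config):
    params = init_model(tiny_config, seed=6)
    pred = predict(helix20, params, tiny_config)
    assert np.all((pred.pnul > 0) & (pred.pnul < 1))
    assert pred.pmol == pytest.approx(pred.pnul.mean(), abs=1e-9)


def test_se3_invariance_of_prediction(helix20, tiny_config):
    rng = np.random.default_rng(7)
    params = init_model(tiny_config, seed=7)
    base = predict(helix20, params, tiny_config).pnul
    for _ in range(5):
        moved = helix20.transformed(random_rotation(rng), rng.normal(size=3) * 40)
        np.testing.assert_allclose(predict(moved, params, tiny_config).pnul, base,
                                   atol=1e-4)


def test_renumbering_leaves_output_unchanged(tmp_path, helix20, tiny_config):
    """Shifting residue numbers (same geometry, same order) must not change
    the prediction: features depend on order, not on author numbering."""
    from rnaqa.structure_io import read_structure, write_pdb, RNAStructure, Nucleotide

    renum = RNAStructure("renum", "A", [
        Nucleotide(nt.index, nt.code, dict(nt.atoms)) for nt in helix20.nucleotides])
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_pdb(helix20, p1)
    # renumber by +100 in the file
    text = p1.read_text()
    out = []
    for line in text.splitlines():
        if line.startswith("ATOM"):
            resseq = int(line[22:26]) + 100
            line = line[:22] + f"{resseq:4d}" + line[26:]
        out.append(line)
    p2.write_text("\n".join(out) + "\n")
    params = init_model(tiny_config, seed=8)
    a = predict(read_structure(p1), params, tiny_config).pnul
    b = predict(read_structure(p2), params, tiny_config).pnul
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_dropout_only_active_in_training_mode(helix20, tiny_config):
    params = init_model(tiny_config, seed=9)
    node, edge, nbr, R, t = structure_inputs(helix20, tiny_config)
    det1 = forward(params, tiny_config, node, edge, nbr, R, t).data
    det2 = forward(params, tiny_config, node, edge, nbr, R, t).data
    np.testing.assert_array_equal(det1, det2)
    tr = forward(params, tiny_config, node, edge, nbr, R, t,
                 rng=np.random.default_rng(0)).data
    assert not np.array_equal(det1, tr)


def test_save_load_round_trip(tmp_path, helix20, tiny_config):
    params = init_model(tiny_config, seed=10)
    path = tmp_path / "w.npz"
    save_params(params, tiny_config, path, seed=10)
    params2, config2, seed = load_params(path)
    assert config2 == tiny_config and seed == 10
    np.testing.assert_array_equal(predict(helix20, params, tiny_config).pnul,
                                  predict(helix20, params2, config2).pnul)
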