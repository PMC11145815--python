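"""Forward-pass contracts: determinism, invariances, hand-computed oracles,
ablation structure, serialization."""

import numpy as np
import pytest
import scipy.sparse as sp

from deeplip.autodiff import Tensor
from deeplip.complex_graph import GraphConfig
from deeplip.errors import ConfigError, ShapeError
from deeplip.model import (AffinityNetwork, AttentionFusion, DescriptorTower,
                           InteractionGGNN, ModelConfig, Normalization,
                           TrainedModel, ablation_forward, assemble_batch,
                           deeplip_forward, featurize_samples)
from deeplip.nn import GRUUpdate
from deeplip.structure_io import Bond, ComplexSample, Ligand
from deeplip.model import _TypedMessages


@pytest.fixture(scope="module")
def untrained_model(small_dataset):
    samples, _, _ = small_dataset
    feats = featurize_samples(samples[:10])
    config = ModelConfig()
    net = AffinityNetwork(config, seed=7)
    norm = Normalization.fit(feats)
    return TrainedModel(config, net, norm, GraphConfig(), 7), feats


def shuffle_ligand(sample: ComplexSample, seed=0) -> ComplexSample:
    rng = np.random.default_rng(seed)
    lig = sample.ligand
    perm = rng.permutation(len(lig.atoms))
    inv = np.argsort(perm)
    atoms = [lig.atoms[p] for p in perm]
    bonds = [Bond(int(inv[b.i]), int(inv[b.j]), b.order) for b in lig.bonds]
    return ComplexSample(Ligand(atoms, bonds, name=lig.name), sample.pocket,
                         label=sample.label, id=sample.id)


def test_prediction_deterministic_and_finite(untrained_model, small_dataset):
    model, _ = untrained_model
    sample = small_dataset[0][0]
    p1 = deeplip_forward(sample, model)
    p2 = deeplip_forward(sample, model)
    assert p1 == p2
    assert np.isfinite(p1)


def test_prediction_invariant_to_atom_order(untrained_model, small_dataset):
    model, _ = untrained_model
    for sample in small_dataset[0][:3]:
        base = deeplip_forward(sample, model)
        shuffled = deeplip_forward(shuffle_ligand(sample, seed=3), model)
        assert abs(base - shuffled) < 1e-5


def test_attention_rows_sum_to_one_and_uniform_for_equal_tokens(rng):
    cfg = ModelConfig(token_dim=8)
    fusion = AttentionFusion(cfg, rng, dtype=np.float64)
    tokens = rng.normal(size=(4, 3, 8))
    _, w = fusion(Tensor(tokens), return_weights=True)
    assert np.allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)
    same = np.broadcast_to(tokens[:, :1, :], tokens.shape).copy()
    _, w_eq = fusion(Tensor(same), return_weights=True)
    assert np.allclose(w_eq.data, 1.0 / 3.0, atol=1e-9)


def test_attention_matches_hand_computation(rng):
    cfg = ModelConfig(token_dim=2)
    fusion = AttentionFusion(cfg, rng, dtype=np.float64)
    eye = np.eye(2)
    for lin in (fusion.wq, fusion.wk, fusion.wv):
        lin.weight.data = eye.copy()
        lin.bias.data = np.zeros(2)
    x = np.array([[[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]])
    out = fusion(Tensor(x)).data.reshape(3, 2)
    scores = (x[0] @ x[0].T) / np.sqrt(2)
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    weights = e / e.sum(axis=1, keepdims=True)
    assert np.allclose(out, weights @ x[0], atol=1e-12)


def test_gated_step_zero_edges_reduces_to_gru_of_zero_message(rng):
    dim = 3
    msg = _TypedMessages(("covalent:single",), dim, rng, dtype=np.float64)
    gru = GRUUpdate(dim, rng, dtype=np.float64)
    h = rng.normal(size=(4, dim))
    empty = {"covalent:single": sp.csr_matrix((4, 4))}
    m = msg(Tensor(h), empty)
    assert np.allclose(m.data, 0.0)
    out = gru(Tensor(h), m).data
    # hand GRU with zero message
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    z = sig(h @ gru.Uz.data + gru.bz.data)
    r = sig(h @ gru.Ur.data + gru.br.data)
    n = np.tanh((r * h) @ gru.Un.data + gru.bn.data)
    assert np.allclose(out, (1 - z) * h + z * n, atol=1e-12)


def test_gated_step_scalar_path_graph_hand_computation(rng):
    """1-dim states on a 3-node path: message then gated update by hand."""
    dim = 1
    msg = _TypedMessages(("noncovalent",), dim, rng, dtype=np.float64)
    gru = GRUUpdate(dim, rng, dtype=np.float64)
    w = 0.5
    msg.W0.data = np.array([[w]])
    for gate in ("z", "r", "n"):
        getattr(gru, f"W{gate}").data = np.array([[1.0]])
        getattr(gru, f"U{gate}").data = np.array([[0.25]])
        getattr(gru, f"b{gate}").data = np.array([0.1])
    # path 0-1-2, both directions
    adj = {"noncovalent": sp.csr_matrix(
        (np.ones(4), ([0, 1, 1, 2], [1, 0, 2, 1])), shape=(3, 3))}
    h = np.array([[1.0], [2.0], [-1.0]])
    out = gru(Tensor(h), msg(Tensor(h), adj)).data
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    expect = np.zeros(3)
    messages = [w * 2.0, w * (1.0 - 1.0), w * 2.0]
    for i in range(3):
        hm, hi = messages[i], h[i, 0]
        z = sig(1.0 * hm + 0.25 * hi + 0.1)
        r = sig(1.0 * hm + 0.25 * hi + 0.1)
        n = np.tanh(1.0 * hm + 0.25 * (r * hi) + 0.1)
        expect[i] = (1 - z) * hi + z * n
    assert np.allclose(out.ravel(), expect, atol=1e-12)


def test_gated_step_permutation_equivariance(rng):
    dim = 4
    msg = _TypedMessages(("noncovalent",), dim, rng, dtype=np.float64)
    gru = GRUUpdate(dim, rng, dtype=np.float64)
    n = 6
    a = sp.random(n, n, density=0.4, random_state=3, format="csr")
    a = ((a + a.T) > 0).astype(float).tocsr()
    a.setdiag(0)
    a.eliminate_zeros()
    h = rng.normal(size=(n, dim))
    out = gru(Tensor(h), msg(Tensor(h), {"noncovalent": a})).data
    perm = rng.permutation(n)
    p = sp.csr_matrix((np.ones(n), (np.arange(n), perm)), shape=(n, n))
    a_p = (p @ a @ p.T).tocsr()
    out_p = gru(Tensor(h[perm]),
                msg(Tensor(h[perm]), {"noncovalent": a_p})).data
    assert np.allclose(out_p, out[perm], atol=1e-10)


def test_typed_messages_rejects_unknown_edge_type(rng):
    msg = _TypedMessages(("noncovalent",), 2, rng)
    with pytest.raises(ConfigError):
        msg(Tensor(np.zeros((2, 2))), {"hydrogen-bond": sp.csr_matrix((2, 2))})


def test_tower_zero_weights_give_projection_bias(rng):
    cfg = ModelConfig()
    tower = DescriptorTower(196, cfg, rng, dtype=np.float64)
    tower.eval()
    for _, p in tower.named_parameters():
        p.data = np.zeros_like(p.data)
    out = tower(Tensor(np.zeros((2, 196))))
    assert np.allclose(out.data, 0.0)
    tower.proj.bias.data = np.full(cfg.token_dim, 0.7)
    assert np.allclose(tower(Tensor(np.zeros((2, 196)))).data, 0.7)


def test_tower_rejects_wrong_length(rng):
    tower = DescriptorTower(196, ModelConfig(), rng)
    with pytest.raises(ShapeError):
        tower(Tensor(np.zeros((2, 147))))


def test_ablations_are_strict_parameter_subsets():
    full = AffinityNetwork(ModelConfig(), seed=0).n_parameters()
    for variant in ("DeepLI", "DeepIP", "DeepLP"):
        sub = AffinityNetwork(ModelConfig(variant=variant), seed=0)
        assert sub.n_parameters() < full
        names = {n.split(".")[0] for n, _ in sub.named_parameters()}
        if variant == "DeepLP":
            assert "ggnn" not in names
        if variant == "DeepLI":
            assert "poc_tower" not in names
        if variant == "DeepIP":
            assert "lig_tower" not in names


def test_deeplp_ignores_coordinates(small_dataset):
    samples, _, _ = small_dataset
    sample = samples[0]
    feats = featurize_samples([sample], need_graph=False)
    config = ModelConfig(variant="DeepLP")
    net = AffinityNetwork(config, seed=1)
    model = TrainedModel(config, net, Normalization.fit(feats),
                         GraphConfig(), 1)
    base = ablation_forward("DeepLP", sample, model)
    jittered_atoms = [type(a)(a.element, a.coords + 0.5, a.formal_charge)
                      for a in sample.ligand.atoms]
    jittered = ComplexSample(
        Ligand(jittered_atoms, sample.ligand.bonds, name=sample.ligand.name),
        sample.pocket, label=sample.label, id=sample.id)
    assert ablation_forward("DeepLP", jittered, model) == pytest.approx(
        base, abs=1e-7)


def test_deepli_ignores_pocket_sequence(small_dataset):
    samples, _, _ = small_dataset
    sample = samples[2]
    config = ModelConfig(variant="DeepLI")
    feats = featurize_samples([sample])
    net = AffinityNetwork(config, seed=1)
    model = TrainedModel(config, net, Normalization.fit(feats),
                         GraphConfig(), 1)
    base = ablation_forward("DeepLI", sample, model)
    mutated_pocket = type(sample.pocket)(
        residues=[type(r)("ALA", r.chain, r.seqno, r.icode)
                  for r in sample.pocket.residues],
        atoms=sample.pocket.atoms)
    mutated = ComplexSample(sample.ligand, mutated_pocket,
                            label=sample.label, id=sample.id)
    assert ablation_forward("DeepLI", mutated, model) == pytest.approx(
        base, abs=1e-7)


def test_variant_mismatch_raises(untrained_model, small_dataset):
    model, _ = untrained_model
    sample = small_dataset[0][0]
    with pytest.raises(ConfigError):
        ablation_forward("DeepLP", sample, model)
    with pytest.raises(ConfigError):
        ablation_forward("NotAVariant", sample, model)


def test_save_load_roundtrip(tmp_path, untrained_model, small_dataset):
    model, feats = untrained_model
    samples = small_dataset[0][:5]
    before = model.predict(samples)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = TrainedModel.load(path)
    after = loaded.predict(samples)
    assert np.allclose(before, after, atol=1e-6)
    assert loaded.config == model.config
    assert loaded.lig_registry_version == model.lig_registry_version


def test_config_validation():
    with pytest.raises(ConfigError):
        ModelConfig(variant="DeepXX")
    with pytest.raises(ConfigError):
        ModelConfig(k1=0)
    with pytest.raises(ConfigError):
        ModelConfig(token_dim=10, n_heads=3)
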