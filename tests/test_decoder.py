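"""Graph-Transformer decoder: DMPN, aggregation, residual, invariances."""

import numpy as np
import pytest

from conftest import path_graph, permute_graph
from molmae import nn
from molmae._autodiff import Tensor
from molmae.batching import GraphBatch
from molmae.decoder import (
    DecoderState,
    GraphTransformerDecoder,
    agg2node_agg2edge,
    dmpn_step,
)
from molmae.encoder import GraphEncoder
from molmae.exceptions import ConfigurationError, ContractError
from molmae.molio import parse_smiles
from molmae.objectives import sce


def _identity_linears(dim):
    rng = np.random.default_rng(0)
    msg = nn.Linear(3 * dim, dim, rng)
    # select only the neighbor block h_u from [h_v ; h_u ; e]
    w = np.zeros((3 * dim, dim))
    w[dim:2 * dim] = np.eye(dim)
    msg.weight.data = w
    msg.bias.data = np.zeros(dim)
    upd = nn.Linear(dim, dim, rng)
    upd.weight.data = np.eye(dim)
    upd.bias.data = np.zeros(dim)
    return msg, upd


class TestDMPNStep:
    def test_path_graph_neighbor_sums(self):
        g = path_graph(3)
        batch = GraphBatch.single(g)
        msg, upd = _identity_linears(1)
        h = Tensor(np.array([[1.0], [2.0], [3.0]]))
        e = Tensor(np.zeros((batch.n_edges, 1)))
        state = dmpn_step(DecoderState(h, e), batch, msg, upd,
                          activation=lambda x: x)
        np.testing.assert_allclose(state.node_h.data, [[2.0], [4.0], [2.0]])

    def test_edgeless_graph_aggregates_to_zero(self):
        g = path_graph(1)
        batch = GraphBatch.single(g)
        msg, upd = _identity_linears(1)
        state = dmpn_step(DecoderState(Tensor([[5.0]]), Tensor(np.zeros((0, 1)))),
                          batch, msg, upd, activation=lambda x: x)
        np.testing.assert_allclose(state.node_h.data, [[0.0]])

    def test_uninitialized_state_rejected(self):
        batch = GraphBatch.single(path_graph(2))
        msg, upd = _identity_linears(1)
        with pytest.raises(ContractError):
            dmpn_step(DecoderState(None, None), batch, msg, upd)

    def test_permutation_equivariance(self):
        g = parse_smiles("CCOc1ccccc1")
        perm = np.random.default_rng(1).permutation(g.n_nodes)
        g_p = permute_graph(g, perm)
        rng = np.random.default_rng(2)
        msg = nn.Linear(3 * 4, 4, rng)
        upd = nn.Linear(4, 4, rng)
        h = np.random.default_rng(3).normal(size=(g.n_nodes, 4))
        e = np.zeros((g.n_edges, 4))
        out = dmpn_step(DecoderState(Tensor(h), Tensor(e)),
                        GraphBatch.single(g), msg, upd).node_h.data
        out_p = dmpn_step(DecoderState(Tensor(h[np.argsort(perm)]), Tensor(e)),
                          GraphBatch.single(g_p), msg, upd).node_h.data
        np.testing.assert_allclose(out_p[perm], out, atol=1e-8)


class TestAggregation:
    def test_path_graph_node_sums(self):
        batch = GraphBatch.single(path_graph(3))
        ones = Tensor(np.ones((3, 1)))
        m_node, m_edge = agg2node_agg2edge(ones, batch)
        np.testing.assert_allclose(m_node.data, [[1.0], [2.0], [1.0]])

    def test_edge_message_is_endpoint_sum(self):
        g = parse_smiles("CCO")
        batch = GraphBatch.single(g)
        h = Tensor(np.arange(3, dtype=float).reshape(3, 1))
        _, m_edge = agg2node_agg2edge(h, batch)
        src, dst = batch.edge_index
        np.testing.assert_allclose(m_edge.data[:, 0],
                                   h.data[src, 0] + h.data[dst, 0])

    def test_isolated_node_gets_zero_message(self):
        batch = GraphBatch.single(path_graph(1))
        m_node, _ = agg2node_agg2edge(Tensor([[3.0]]), batch)
        np.testing.assert_allclose(m_node.data, [[0.0]])


class TestDecoder:
    def test_head_divisibility_enforced(self):
        GraphTransformerDecoder(latent_dim=8, out_dim=8, hidden_dim=64, n_heads=2)
        with pytest.raises(ConfigurationError):
            GraphTransformerDecoder(latent_dim=8, out_dim=8, hidden_dim=64,
                                    n_heads=3)

    def test_residual_identity_limit(self, benzene):
        """With the message/attention/FFN projections zeroed, the output is
        exactly the projected long-range residual of the inputs."""
        dec = GraphTransformerDecoder(latent_dim=8, out_dim=5, hidden_dim=8,
                                      seed=0)
        for layer in dec.layers:
            layer.upd.weight.data[:] = 0.0
            layer.upd.bias.data[:] = 0.0
            layer.attn.v_proj.weight.data[:] = 0.0
            layer.attn.v_proj.bias.data[:] = 0.0
            layer.attn.out_proj.weight.data[:] = 0.0
            layer.attn.out_proj.bias.data[:] = 0.0
        dec.node_ffn.fc2.weight.data[:] = 0.0
        dec.node_ffn.fc2.bias.data[:] = 0.0
        batch = GraphBatch.single(benzene)
        latent = Tensor(np.random.default_rng(1).normal(size=(6, 8)))
        z, _ = dec.decode(latent, batch)
        expected = dec.out_proj(dec.node_norm(dec.node_res(latent))).data
        np.testing.assert_allclose(z.data, expected, atol=1e-10)

    def test_removing_long_range_residual_changes_output(self, benzene):
        batch = GraphBatch.single(benzene)
        latent = Tensor(np.random.default_rng(2).normal(size=(6, 8)))
        z_with, _ = GraphTransformerDecoder(
            latent_dim=8, out_dim=4, hidden_dim=8, seed=3).decode(latent, batch)
        dec_no = GraphTransformerDecoder(latent_dim=8, out_dim=4, hidden_dim=8,
                                         seed=3, long_range_residual=False)
        z_without, _ = dec_no.decode(latent, batch)
        assert np.abs(z_with.data - z_without.data).max() > 1e-6

    def test_equivariance_and_graph_vector_invariance(self):
        g = parse_smiles("CCOc1ccc(N)cc1")
        perm = np.random.default_rng(4).permutation(g.n_nodes)
        enc = GraphEncoder(hidden_dim=8, depth=2, seed=0)
        dec = GraphTransformerDecoder(latent_dim=8, out_dim=6, hidden_dim=8,
                                      seed=1)
        z, vec = dec.decode(enc(GraphBatch.single(g)), GraphBatch.single(g))
        g_p = permute_graph(g, perm)
        z_p, vec_p = dec.decode(enc(GraphBatch.single(g_p)),
                                GraphBatch.single(g_p))
        np.testing.assert_allclose(z_p.data[perm], z.data, atol=1e-6)
        np.testing.assert_allclose(vec_p.data, vec.data, atol=1e-6)

    def test_can_overfit_single_graph_reconstruction(self, benzene):
        """Expressiveness: one attention layer suffices to drive the SCE on a
        fixed graph below 1e-3."""
        rng = np.random.default_rng(5)
        batch = GraphBatch.single(benzene)
        latent = Tensor(rng.normal(size=(6, 8)))
        target = rng.normal(size=(6, 6))
        dec = GraphTransformerDecoder(latent_dim=8, out_dim=6, hidden_dim=16,
                                      seed=6)
        opt = nn.Adam(dec.parameters(), lr=1e-2)
        loss = None
        for _ in range(400):
            z, _ = dec.decode(latent, batch)
            loss = sce(target, z, gamma=2.0)
            if loss.item() < 1e-3:
                break
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert loss.item() < 1e-3
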