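from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from infofrag.substrates import (
    BLOCKCATCH_LAYOUT,
    NBACK_LAYOUT,
    START_CODON,
    BrainLayout,
    Connectome,
    MarkovBrain,
    MarkovGate,
    RNNBrain,
    connectome_of,
    decode_markov_brain,
    decode_rnn,
    load_brain,
    load_genome,
    random_genome,
    save_genome,
    seed_start_codons,
)


def handwritten_xor_gene(layout: BrainLayout) -> np.ndarray:
    """A gene encoding a 2-in/2-out gate whose first output is XOR of the
    inputs (second output pads a spare node)."""
    in_a = layout.t0_ids.index("m1")
    in_b = layout.t0_ids.index("m2")
    out = layout.t1_ids.index("o1")
    pad = layout.t1_ids.index("m8")
    gene = [
        *START_CODON,
        0,  # 0 % 3 + 2 = 2 inputs
        0,  # 2 outputs
        in_a, in_b, 0, 0,   # input addresses (last two unused)
        out, pad, 0, 0,     # output addresses (last two unused)
        0, 0,  # row 00 -> (0, 0)
        1, 0,  # row 01 -> (1, 0)
        1, 0,  # row 10 -> (1, 0)
        0, 0,  # row 11 -> (0, 0)
    ]
    return np.array(gene, dtype=np.uint8)


class TestMarkovDecode:
    def test_seeded_genome_yields_at_least_six_gates(self, rng):
        g = seed_start_codons(random_genome(rng), n_codons=6)
        brain = decode_markov_brain(g, NBACK_LAYOUT)
        assert len(brain.gates) >= 6

    def test_codonless_genome_is_inert(self):
        g = np.zeros(3000, dtype=np.uint8)
        brain = decode_markov_brain(g, NBACK_LAYOUT)
        assert brain.gates == []
        np.testing.assert_array_equal(
            brain.update(np.ones(NBACK_LAYOUT.n_t0, dtype=np.uint8)),
            np.zeros(NBACK_LAYOUT.n_t1, dtype=np.uint8),
        )

    def test_handwritten_gene_decodes_to_xor_gate(self):
        layout = NBACK_LAYOUT
        g = np.concatenate([np.zeros(100, np.uint8), handwritten_xor_gene(layout),
                            np.zeros(100, np.uint8)])
        brain = decode_markov_brain(g, layout)
        assert len(brain.gates) == 1
        gate = brain.gates[0]
        assert gate.in_ids == (layout.t0_ids.index("m1"), layout.t0_ids.index("m2"))
        assert gate.table[:, 0].tolist() == [0, 1, 1, 0]

    def test_truncated_trailing_gene_is_skipped(self):
        layout = NBACK_LAYOUT
        gene = handwritten_xor_gene(layout)
        g = np.concatenate([gene, gene[: len(gene) - 4]])
        brain = decode_markov_brain(g, layout)
        assert len(brain.gates) == 1

    @given(data=st.binary(min_size=0, max_size=400))
    def test_decode_is_total_on_arbitrary_bytes(self, data):
        g = np.frombuffer(data, dtype=np.uint8)
        brain = decode_markov_brain(g, BLOCKCATCH_LAYOUT)
        out = brain.update(np.zeros(BLOCKCATCH_LAYOUT.n_t0, dtype=np.uint8))
        assert out.shape == (BLOCKCATCH_LAYOUT.n_t1,)


class TestMarkovUpdate:
    def xor_brain(self):
        layout = NBACK_LAYOUT
        g = handwritten_xor_gene(layout)
        return decode_markov_brain(g, layout), layout

    @pytest.mark.parametrize(
        "m1, m2, expected", [(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)]
    )
    def test_xor_truth_table(self, m1, m2, expected):
        brain, layout = self.xor_brain()
        t0 = np.zeros(layout.n_t0, dtype=np.uint8)
        t0[layout.t0_ids.index("m1")] = m1
        t0[layout.t0_ids.index("m2")] = m2
        assert brain.update(t0)[layout.t1_ids.index("o1")] == expected

    def test_colliding_writes_combine_by_or(self):
        layout = BrainLayout(n_inputs=2, n_outputs=2, n_memory=2)
        write0 = MarkovGate((0, 0), (0, 0), np.zeros((4, 2), np.uint8))
        write1 = MarkovGate((1, 1), (0, 0), np.ones((4, 2), np.uint8))
        brain = MarkovBrain(layout, [write0, write1])
        assert brain.update(np.array([1, 1, 0, 0], dtype=np.uint8))[0] == 1

    def test_update_is_a_pure_function(self, rng):
        g = seed_start_codons(random_genome(rng))
        brain = decode_markov_brain(g, NBACK_LAYOUT)
        t0 = rng.integers(0, 2, NBACK_LAYOUT.n_t0).astype(np.uint8)
        np.testing.assert_array_equal(brain.update(t0), brain.update(t0))

    def test_nonbinary_symbols_rejected(self):
        brain, layout = self.xor_brain()
        with pytest.raises(ValueError, match="binary"):
            brain.update(np.full(layout.n_t0, 2, dtype=np.uint8))

    def test_gate_arity_validated(self):
        with pytest.raises(ValueError, match="arities"):
            MarkovGate((0,), (1, 2), np.zeros((2, 2), np.uint8))


class TestRNN:
    def test_midpoint_bytes_give_near_zero_parameters(self):
        layout = NBACK_LAYOUT
        g = np.full((layout.n_t0 + 1) * layout.n_t1, 128, dtype=np.uint8)
        brain = decode_rnn(g, layout)
        assert np.all(np.abs(brain.weights) < 0.01)
        assert np.all(np.abs(brain.biases) < 0.02)

    def test_byte_extremes_map_to_range_limits(self):
        layout = BrainLayout(n_inputs=1, n_outputs=1, n_memory=0)
        g = np.array([0, 255], dtype=np.uint8)  # one weight, one bias
        brain = decode_rnn(g, layout)
        assert brain.weights[0, 0] == pytest.approx(-1.0)
        assert brain.biases[0] == pytest.approx(3.0)

    def test_parameter_count_is_t0_plus_one_times_t1(self):
        layout = BLOCKCATCH_LAYOUT
        needed = (layout.n_t0 + 1) * layout.n_t1
        with pytest.raises(ValueError, match="too short"):
            decode_rnn(np.zeros(needed - 1, np.uint8), layout)
        brain = decode_rnn(np.zeros(needed, np.uint8), layout)
        assert brain.weights.size + brain.biases.size == needed

    def test_threshold_discretization(self):
        layout = BrainLayout(n_inputs=1, n_outputs=1, n_memory=0)
        zero = RNNBrain(layout, np.zeros((1, 1)), np.zeros(1))
        assert zero.update(np.array([1.0]))[0] == 0  # tanh(0) = 0 -> 0
        biased = RNNBrain(layout, np.zeros((1, 1)), np.array([3.0]))
        assert biased.update(np.array([0.0]))[0] == 1  # tanh(3) ~ 0.995 -> 1
        unit = RNNBrain(layout, np.ones((1, 1)), np.zeros(1))
        assert unit.update(np.array([1.0]))[0] == 1  # tanh(1) ~ 0.762 -> 1

    def test_finite_state_map_on_binary_inputs(self):
        rng = np.random.default_rng(4)
        layout = BrainLayout(n_inputs=2, n_outputs=1, n_memory=3)
        g = random_genome(rng, (layout.n_t0 + 1) * layout.n_t1)
        brain = decode_rnn(g, layout)
        t0 = rng.integers(0, 2, (8, layout.n_t0)).astype(float)
        out = brain.update(t0)
        assert set(np.unique(out)) <= {0, 1}
        np.testing.assert_array_equal(out, brain.update(t0))


class TestConnectome:
    def test_single_xor_gate_wires_two_links_into_o5(self):
        from infofrag.fixtures import make_xor_delay

        conn = connectome_of(make_xor_delay())
        into_o5 = {s for (s, t) in conn.links if t == "o5"}
        assert into_o5 == {"m2", "m7"}

    def test_inert_brain_has_empty_connectome(self):
        brain = MarkovBrain(NBACK_LAYOUT, [])
        assert connectome_of(brain).links == frozenset()

    def test_dense_rnn_is_complete_bipartite(self):
        layout = BrainLayout(n_inputs=1, n_outputs=1, n_memory=1)
        brain = RNNBrain(layout, np.full((2, 2), 0.5), np.zeros(2))
        assert len(connectome_of(brain).links) == 4

    def test_zero_weights_do_not_wire(self):
        layout = BrainLayout(n_inputs=1, n_outputs=1, n_memory=1)
        w = np.array([[0.5, 0.0], [0.0, 0.0]])
        conn = connectome_of(RNNBrain(layout, w, np.zeros(2)))
        assert conn.links == frozenset({("i1", "o1")})


class TestSerialization:
    def test_brain_json_round_trip(self, rng, tmp_path):
        g = seed_start_codons(random_genome(rng))
        brain = decode_markov_brain(g, NBACK_LAYOUT)
        brain.save(tmp_path / "b.json")
        back = load_brain(tmp_path / "b.json")
        t0 = rng.integers(0, 2, (10, NBACK_LAYOUT.n_t0)).astype(np.uint8)
        np.testing.assert_array_equal(brain.update(t0), back.update(t0))

    def test_genome_hex_round_trip(self, rng, tmp_path):
        g = random_genome(rng, 500)
        save_genome(g, tmp_path / "g.hex")
        np.testing.assert_array_equal(load_genome(tmp_path / "g.hex"), g)

    def test_connectome_round_trip(self, tmp_path):
        conn = Connectome(frozenset({("i1", "o1"), ("m1", "m2")}))
        conn.save(tmp_path / "c.json")
        assert Connectome.load(tmp_path / "c.json") == conn
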