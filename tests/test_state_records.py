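from __future__ import annotations

import numpy as np
import pytest

from conftest import make_random_recording
from infofrag.state_records import (
    Lifetime,
    StateRecording,
    NodeSchema,
    PairedTable,
    ProbabilityTable,
    RecordingError,
    estimate_probabilities,
    load_recording,
    pair_states,
    save_recording,
    trim_late_lifetime,
)


class TestLifetimeInvariants:
    def test_memory_needs_one_extra_row(self):
        with pytest.raises(RecordingError, match="L\\+1"):
            Lifetime(
                inputs=np.zeros((3, 1), int),
                outputs=np.zeros((3, 1), int),
                memory=np.zeros((3, 1), int),  # should be 4 rows
                world=np.zeros((3, 0), int),
            )

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(RecordingError, match="equal row counts"):
            Lifetime(
                inputs=np.zeros((3, 1), int),
                outputs=np.zeros((2, 1), int),
                memory=np.zeros((4, 1), int),
                world=np.zeros((3, 0), int),
            )


class TestRoundTrip:
    def test_save_load_is_identity(self, rng, tmp_path):
        rec = make_random_recording(rng)
        path = tmp_path / "rec.tsv"
        save_recording(rec, path)
        back = load_recording(path)
        assert back.schema == rec.schema
        assert len(back.lifetimes) == len(rec.lifetimes)
        for a, b in zip(rec.lifetimes, back.lifetimes):
            np.testing.assert_array_equal(a.inputs, b.inputs)
            np.testing.assert_array_equal(a.outputs, b.outputs)
            np.testing.assert_array_equal(a.memory, b.memory)
            np.testing.assert_array_equal(a.world, b.world)

    def test_broken_memory_chain_reported_with_location(self, rng, tmp_path):
        rec = make_random_recording(rng, n_lifetimes=1, n_updates=5)
        path = tmp_path / "rec.tsv"
        save_recording(rec, path)
        lines = path.read_text().splitlines()
        # corrupt one memory-after cell so before/after chaining breaks
        header = lines[0].split("\t")
        col = header.index("m1_next")
        cells = lines[2].split("\t")
        cells[col] = str(1 - int(cells[col]))
        lines[2] = "\t".join(cells)
        path.write_text("\n".join(lines))
        with pytest.raises(RecordingError, match="lifetime 0, update 1"):
            load_recording(path)

    def test_undeclared_columns_rejected(self, rng, tmp_path):
        rec = make_random_recording(rng, n_lifetimes=1, n_updates=3)
        path = tmp_path / "rec.tsv"
        save_recording(rec, path)
        schema = NodeSchema(inputs=("i1",), outputs=("o1",), memory=("m1",))
        with pytest.raises(RecordingError, match="undeclared"):
            load_recording(path, schema=schema)


class TestPairing:
    def test_rows_pool_across_lifetimes(self, rng):
        # 4 lifetimes of 20 updates pool to 80 joint-state rows
        rec = make_random_recording(rng, n_lifetimes=4, n_updates=20)
        table = pair_states(rec, ["i1", "m1"], ["o1", "m2"])
        assert table.n_rows == 80

    def test_copied_node_matches_its_source_in_every_row(self):
        # memory-after m1 latches the update's input, so in every paired row
        # the m1 feature equals the i1 predictor
        rng = np.random.default_rng(7)
        schema = NodeSchema(inputs=("i1",), outputs=(), memory=("m1",))
        lifetimes = []
        for _ in range(3):
            x = rng.integers(0, 2, 10)
            lifetimes.append(
                Lifetime(
                    inputs=x.reshape(-1, 1),
                    outputs=np.zeros((10, 0), int),
                    memory=np.concatenate([[0], x]).reshape(-1, 1),
                    world=np.zeros((10, 0), int),
                )
            )
        rec = StateRecording(schema, lifetimes)
        table = pair_states(rec, ["i1"], ["m1"])
        np.testing.assert_array_equal(table.data[:, 0], table.data[:, 1])

    def test_unknown_ids_and_empty_recording_rejected(self, rng):
        rec = make_random_recording(rng)
        with pytest.raises(KeyError):
            pair_states(rec, ["nope"], ["o1"])
        with pytest.raises(KeyError):
            pair_states(rec, ["i1"], ["i1"])  # inputs are not features
        empty = StateRecording(rec.schema, [])
        with pytest.raises(RecordingError):
            pair_states(empty, ["i1"], ["o1"])

    def test_world_features_pair_against_memory(self, rng):
        rec = make_random_recording(rng, n_world=2)
        table = pair_states(rec, ["m1", "m2"], ["w1", "w2"])
        assert table.n_rows == rec.n_rows
        assert table.feature_ids == ("w1", "w2")


class TestTrimming:
    def test_late_lifetime_quarter_of_80_is_20(self, rng):
        rec = make_random_recording(rng, n_lifetimes=4, n_updates=20)
        trimmed = trim_late_lifetime(rec, 0.25)
        assert trimmed.n_rows == 20
        # the kept rows are the *last* ones of each lifetime
        for orig, kept in zip(rec.lifetimes, trimmed.lifetimes):
            np.testing.assert_array_equal(kept.inputs, orig.inputs[-5:])
            np.testing.assert_array_equal(kept.memory, orig.memory[-6:])

    def test_full_fraction_is_identity(self, rng):
        rec = make_random_recording(rng)
        trimmed = trim_late_lifetime(rec, 1.0)
        assert trimmed.n_rows == rec.n_rows

    def test_round_half_up_on_31_updates(self, rng):
        rec = make_random_recording(rng, n_lifetimes=1, n_updates=31)
        assert trim_late_lifetime(rec, 0.25).n_rows == 8

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, rng, bad):
        rec = make_random_recording(rng)
        with pytest.raises(ValueError):
            trim_late_lifetime(rec, bad)

    def test_monotone_in_fraction(self, rng):
        rec = make_random_recording(rng, n_lifetimes=3, n_updates=17)
        sizes = [trim_late_lifetime(rec, f).n_rows for f in (0.1, 0.3, 0.6, 1.0)]
        assert sizes == sorted(sizes)
        assert all(s <= rec.n_rows for s in sizes)


class TestProbabilityEstimation:
    def test_weekly_weather_frequencies(self):
        # rainy x4, snowy x2, sunny x1 over a seven-day observation
        # (symbols interned: 0=rainy, 1=snowy, 2=sunny)
        days = [0, 0, 2, 0, 1, 1, 0]
        table = PairedTable(("weather",), (), np.array(days).reshape(-1, 1))
        probs = estimate_probabilities(table, ["weather"])
        assert sorted(probs.probs, reverse=True) == pytest.approx([4 / 7, 2 / 7, 1 / 7])

    def test_single_state_has_probability_one(self):
        table = PairedTable(("a",), (), np.ones((9, 1), int))
        probs = estimate_probabilities(table, ["a"])
        assert probs.n == 1 and probs.probs[0] == 1.0

    def test_uniform_joint_support(self, xor_table):
        probs = estimate_probabilities(xor_table, ["A", "B"])
        assert probs.n == 4
        np.testing.assert_allclose(probs.probs, 0.25)

    def test_marginal_of_joint_equals_direct_estimate(self, rng):
        rec = make_random_recording(rng)
        table = pair_states(rec, ["i1", "i2", "m1"], ["o1"])
        joint = estimate_probabilities(table, ["i1", "i2"])
        direct = estimate_probabilities(table, ["i1"])
        marginal: dict = {}
        for state, p in zip(joint.states, joint.probs):
            marginal[state[:1]] = marginal.get(state[:1], 0.0) + p
        for state, p in zip(direct.states, direct.probs):
            assert marginal[state] == pytest.approx(p, abs=1e-12)

    def test_empty_inputs_rejected(self, xor_table):
        with pytest.raises(ValueError):
            estimate_probabilities(xor_table, [])
        empty = PairedTable(("A",), (), np.zeros((0, 1), int))
        with pytest.raises(ValueError):
            estimate_probabilities(empty, ["A"])

    def test_probability_table_invariants(self):
        with pytest.raises(ValueError):
            ProbabilityTable.from_probs([0.5, 0.6])
        with pytest.raises(ValueError):
            ProbabilityTable.from_probs([1.0, 0.0])
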