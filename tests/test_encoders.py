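"""PSSM-RT feature blocks against naive oracles and closed forms."""

import numpy as np
import pytest

from conftest import make_instance, random_instance, uniform_instance
from pssmrt.encoders import (
    DEFAULT_PROPERTY_TABLE,
    PropertyTable,
    assemble_pssm_rt,
    encode_conservation,
    encode_multi_relationships,
    encode_pair_relationships,
    encode_physicochemical,
    encode_sequence_features,
)
from pssmrt.pssm import AA_INDEX, PSSM_COLUMNS


def naive_pair_block(inst):
    """Triple nested loop over (context position j, r1, r2)."""
    w, half = inst.window_size, inst.half
    out = np.zeros((20, 20))
    for r1 in range(20):
        for r2 in range(20):
            for j in range(w):
                if j == half:
                    continue
                out[r1, r2] += inst.window[half, r2] * inst.window[j, r1]
    return out.ravel()


class TestPairRelationships:
    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(100):
            w = int(rng.choice([3, 5, 7, 9, 11, 13, 15]))
            inst = random_instance(rng, w)
            np.testing.assert_allclose(
                encode_pair_relationships(inst), naive_pair_block(inst), atol=1e-9
            )

    @pytest.mark.parametrize("w,c", [(3, 0.5), (5, 0.3), (13, 0.9)])
    def test_uniform_closed_form(self, w, c):
        block = encode_pair_relationships(uniform_instance(w, c))
        np.testing.assert_allclose(block, (w - 1) * c * c, atol=1e-12)

    def test_fully_padded_context_is_zero(self):
        window = np.zeros((3, 20))
        window[1] = 0.7
        inst = make_instance(window, pad=np.array([True, False, True]))
        assert np.all(encode_pair_relationships(inst) == 0)

    def test_spec_worked_example(self):
        # w=3: target has S(C)=0.8; context rows have S(A)=0.6 and 0.4
        window = np.zeros((3, 20))
        window[1, AA_INDEX["C"]] = 0.8
        window[0, AA_INDEX["A"]] = 0.6
        window[2, AA_INDEX["A"]] = 0.4
        block = encode_pair_relationships(make_instance(window))
        entry = block[AA_INDEX["A"] * 20 + AA_INDEX["C"]]
        assert entry == pytest.approx(0.8 * (0.6 + 0.4), abs=1e-12)

    def test_window_reversal_invariance(self, rng):
        inst = random_instance(rng, 9)
        rev = make_instance(inst.window[::-1].copy(), inst.residues[::-1], inst.pad_mask[::-1])
        np.testing.assert_allclose(
            encode_pair_relationships(inst), encode_pair_relationships(rev), atol=1e-12
        )

    def test_bounds(self, rng):
        for w in (3, 9, 15):
            block = encode_pair_relationships(random_instance(rng, w))
            assert np.all(block >= 0) and np.all(block <= w - 1)


class TestMultiRelationships:
    def test_uniform_closed_form(self):
        left, right = encode_multi_relationships(uniform_instance(5, 0.5))
        np.testing.assert_allclose(left, 1.5)
        np.testing.assert_allclose(right, 1.5)

    def test_left_flank_fully_padded(self):
        window = np.zeros((3, 20))
        window[1] = 0.6
        window[2] = 0.2
        inst = make_instance(window, pad=np.array([True, False, False]))
        left, right = encode_multi_relationships(inst)
        np.testing.assert_allclose(left, window[1])
        np.testing.assert_allclose(right, window[1] + window[2])

    def test_reversal_swaps_left_right(self, rng):
        inst = random_instance(rng, 7)
        rev = make_instance(inst.window[::-1].copy(), inst.residues[::-1], inst.pad_mask[::-1])
        l1, r1 = encode_multi_relationships(inst)
        l2, r2 = encode_multi_relationships(rev)
        np.testing.assert_allclose(l1, r2, atol=1e-12)
        np.testing.assert_allclose(r1, l2, atol=1e-12)

    def test_bounds(self, rng):
        for w in (3, 11):
            left, right = encode_multi_relationships(random_instance(rng, w))
            bound = (w + 1) / 2
            assert np.all(left >= 0) and np.all(left <= bound)
            assert np.all(right >= 0) and np.all(right <= bound)


class TestAssembly:
    @pytest.mark.parametrize("w,total", [(3, 500), (5, 540), (13, 700), (15, 740)])
    def test_dimension_formula(self, rng, w, total):
        fv = assemble_pssm_rt(random_instance(rng, w))
        assert len(fv.values) == 20 * w + 440 == total
        a, b = fv.schema.offset("pair")
        assert b - a == 400

    def test_conservation_flattening(self):
        inst = uniform_instance(3, 0.5)
        block = encode_conservation(inst)
        assert block.shape == (60,)
        assert np.all(block == 0.5)

    def test_schema_offsets_round_trip(self, rng):
        fv = assemble_pssm_rt(random_instance(rng, 5))
        rebuilt = np.concatenate(
            [fv.block(n) for n in ("conservation", "pair", "multi_left", "multi_right")]
        )
        np.testing.assert_array_equal(rebuilt, fv.values)
        assert len(fv.schema.slot_names()) == len(fv.values)


class TestSequenceFeatures:
    def test_identical_residue_composition(self):
        inst = make_instance(np.full((3, 20), 0.5), residues="AAA")
        fv = encode_sequence_features(inst)
        comp = fv.values[:20]
        assert comp[AA_INDEX["A"]] == 1.0
        assert comp.sum() == 1.0

    def test_target_identity_one_hot(self):
        inst = make_instance(np.full((3, 20), 0.5), residues="ARG")
        one_hot = encode_sequence_features(inst).values[-20:]
        assert one_hot[AA_INDEX["R"]] == 1.0
        assert one_hot.sum() == 1.0

    def test_missing_tracks_emit_zeros(self):
        inst = make_instance(np.full((3, 20), 0.5), residues="ARG")
        fv = encode_sequence_features(inst)
        w = 3
        ss_and_acc = fv.values[20 : 20 + 4 * w]
        assert np.all(ss_and_acc == 0)

    def test_tracks_placed_at_window_positions(self):
        inst = make_instance(np.full((3, 20), 0.5), residues="ARG")
        ss = np.tile([1.0, 0.0, 0.0], (3, 1))  # all-helix chain of length 3
        acc = np.array([0.1, 0.2, 0.3])
        fv = encode_sequence_features(inst, ss=ss, acc=acc, chain_length=3)
        ss_block = fv.values[20:29].reshape(3, 3)
        assert np.all(ss_block[:, 0] == 1.0)
        np.testing.assert_allclose(fv.values[29:32], acc)

    def test_track_length_mismatch(self):
        inst = make_instance(np.full((3, 20), 0.5), residues="ARG")
        with pytest.raises(ValueError, match="length"):
            encode_sequence_features(inst, ss=np.zeros((5, 3)), chain_length=3)


class TestPhysicochemical:
    def test_constant_window_repeats_group(self):
        inst = make_instance(np.full((3, 20), 0.5), residues="GGG")
        vals = encode_physicochemical(inst).values.reshape(3, 8)
        assert np.array_equal(vals[0], vals[1]) and np.array_equal(vals[1], vals[2])

    def test_minmax_endpoints(self):
        # tryptophan has the largest mass and Wiener index of the 20
        inst = make_instance(np.full((3, 20), 0.5), residues="WWW")
        vals = encode_physicochemical(inst).values.reshape(3, 8)
        names = list(DEFAULT_PROPERTY_TABLE.table.columns)
        assert vals[0, names.index("molecular_mass")] == 1.0
        assert vals[0, names.index("wiener_index")] == 1.0
        scaled = DEFAULT_PROPERTY_TABLE.scaled()
        assert scaled.min() == 0.0 and scaled.max() == 1.0

    def test_padding_and_x_emit_zeros(self):
        inst = make_instance(
            np.zeros((3, 20)), residues="-X-", pad=np.array([True, False, True])
        )
        assert np.all(encode_physicochemical(inst).values == 0)

    def test_missing_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PropertyTable(DEFAULT_PROPERTY_TABLE.table.drop(index="W"))
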