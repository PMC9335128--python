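import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phagefs as pf
from phagefs.encoders import (
    cksaap_names,
    ctd_names,
    default_grouping_table,
    read_grouping_table,
    write_grouping_table,
)

sequences = st.text(alphabet=pf.AMINO_ACIDS, min_size=3, max_size=60)


class TestAAC:
    def test_uniform_four_residues(self):
        fv = pf.encode_aac(pf.ProteinSequence("x", "ACDE"))
        d = dict(zip(fv.names, fv.values))
        for aa in "ACDE":
            assert d[f"AAC:{aa}"] == 0.25
        assert sum(v for n, v in d.items() if n[-1] not in "ACDE") == 0

    def test_single_residue_sequence(self):
        fv = pf.encode_aac(pf.ProteinSequence("x", "AAAA"))
        assert fv.values[0] == 1.0
        assert fv.values[1:].sum() == 0

    @settings(deadline=None)
    @given(sequences)
    def test_twenty_components_summing_to_one(self, s):
        fv = pf.encode_aac(pf.ProteinSequence("h", s))
        assert len(fv) == 20
        assert math.isclose(fv.values.sum(), 1.0, abs_tol=1e-12)


class TestGroupingTable:
    def test_default_table_is_valid_and_versioned(self):
        table = default_grouping_table()
        assert len(table.properties) == 8
        assert table.version

    def test_tsv_round_trip(self, tmp_path):
        table = default_grouping_table()
        path = tmp_path / "groups.tsv"
        write_grouping_table(table, path)
        back = read_grouping_table(path)
        assert {p: dict(m) for p, m in back.groups.items()} == {
            p: dict(m) for p, m in table.groups.items()
        }

    def test_incomplete_coverage_rejected(self):
        groups = {
            p: {aa: 1 for aa in pf.AMINO_ACIDS}
            for p in default_grouping_table().properties
        }
        with pytest.raises(ValueError, match="groups must be exactly"):
            pf.GroupingTable(groups)


class TestCTD:
    def test_homogeneous_sequence_no_transitions(self):
        fv = pf.encode_ctd(pf.ProteinSequence("x", "AAAA"))
        d = dict(zip(fv.names, fv.values))
        # A is in exactly one group per property: that C component is 1,
        # and no adjacent pair ever crosses groups.
        for prop in default_grouping_table().properties:
            cs = [d[f"CTD:{prop}:C:{g}"] for g in (1, 2, 3)]
            assert sorted(cs) == [0.0, 0.0, 1.0]
            for a, b in ((1, 2), (1, 3), (2, 3)):
                assert d[f"CTD:{prop}:T:{a}-{b}"] == 0.0

    def test_alternating_group_pattern_transition_one(self):
        # K (charge group 1) and D (charge group 3) alternate: all three
        # adjacent pairs cross groups 1<->3.
        fv = pf.encode_ctd(pf.ProteinSequence("x", "KDKD"))
        d = dict(zip(fv.names, fv.values))
        assert d["CTD:charge:T:1-3"] == 1.0
        assert d["CTD:charge:T:1-2"] == 0.0
        assert d["CTD:charge:T:2-3"] == 0.0

    def test_168_components_d_in_unit_interval(self, all_residue_seq):
        fv = pf.encode_ctd(all_residue_seq)
        assert len(fv) == 168
        d_vals = [v for n, v in zip(fv.names, fv.values) if ":D:" in n]
        assert all(0.0 <= v <= 1.0 for v in d_vals)

    def test_length_one_errors(self):
        with pytest.raises(ValueError, match="transition"):
            pf.encode_ctd(pf.ProteinSequence("x", "A"))

    @settings(deadline=None, max_examples=30)
    @given(sequences)
    def test_composition_and_transition_invariants(self, s):
        seq = pf.ProteinSequence("h", s)
        fv = pf.encode_ctd(seq)
        d = dict(zip(fv.names, fv.values))
        table = default_grouping_table()
        L = len(seq)
        for prop in table.properties:
            c_sum = sum(d[f"CTD:{prop}:C:{g}"] for g in (1, 2, 3))
            assert math.isclose(c_sum, 1.0, abs_tol=1e-12)
            t_sum = sum(
                d[f"CTD:{prop}:T:{a}-{b}"] for a, b in ((1, 2), (1, 3), (2, 3))
            )
            # cross-group pairs / (L-1) can be at most 1
            assert 0.0 <= t_sum <= 1.0 + 1e-12
            g = [table.groups[prop][aa] for aa in seq.residues]
            n_cross = sum(1 for a, b in zip(g, g[1:]) if a != b)
            assert math.isclose(t_sum, n_cross / (L - 1), abs_tol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(sequences)
    def test_distribution_monotone_within_group(self, s):
        fv = pf.encode_ctd(pf.ProteinSequence("h", s))
        d = dict(zip(fv.names, fv.values))
        for prop in default_grouping_table().properties:
            for g in (1, 2, 3):
                qs = [
                    d[f"CTD:{prop}:D:{g}:{q}"]
                    for q in ("first", "25", "50", "75", "100")
                ]
                assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


class TestCKSAAP:
    def test_acac_k1_golden(self):
        # 1-spaced pairs: (A,A) at positions 1-3 and (C,C) at 2-4, over L=4
        fv = pf.encode_cksaap(pf.ProteinSequence("x", "ACAC"), k=1)
        d = dict(zip(fv.names, fv.values))
        assert d["CKSAAP1:A_A"] == 0.25
        assert d["CKSAAP1:C_C"] == 0.25
        assert sum(fv.values) == 0.5
        assert len(fv) == 400

    def test_absent_pair_is_zero(self):
        fv = pf.encode_cksaap(pf.ProteinSequence("x", "ACAC"), k=1)
        d = dict(zip(fv.names, fv.values))
        assert d["CKSAAP1:W_W"] == 0.0

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="length >= 4"):
            pf.encode_cksaap(pf.ProteinSequence("x", "ACD"), k=2)

    @settings(deadline=None, max_examples=30)
    @given(sequences, st.integers(min_value=0, max_value=3))
    def test_total_mass_invariant(self, s, k):
        if len(s) < k + 2:
            return
        seq = pf.ProteinSequence("h", s)
        L = len(seq)
        fv = pf.encode_cksaap(seq, k=k)
        assert math.isclose(fv.values.sum(), (L - k - 1) / L, abs_tol=1e-12)
        # pair-count normalization sums to exactly 1
        fv2 = pf.encode_cksaap(seq, k=k, pair_norm=True)
        assert math.isclose(fv2.values.sum(), 1.0, abs_tol=1e-12)


class TestEncodeDataset:
    def test_aac_matrix_shape(self, tiny_data):
        mat = pf.encode_dataset(tiny_data, "aac")
        assert mat.values.shape == (len(tiny_data), 20)
        np.testing.assert_array_equal(mat.labels, tiny_data.labels)

    def test_concatenation_is_698_dimensional(self, tiny_data):
        mat = pf.encode_concatenated(tiny_data)
        assert mat.n_components == 20 + 168 + 400 + 110 == 698
        assert len(set(mat.names)) == 698

    def test_error_names_offending_sequence(self):
        data = pf.LabeledDataset(
            [pf.ProteinSequence("ok", "ACDKMV"),
             pf.ProteinSequence("short", "AC")],
            [1, 0],
        )
        with pytest.raises(ValueError, match="short"):
            pf.encode_dataset(data, "cksaap", k=1)

    def test_deterministic(self, tiny_data):
        a = pf.encode_dataset(tiny_data, "ctd")
        b = pf.encode_dataset(tiny_data, "ctd")
        np.testing.assert_array_equal(a.values, b.values)
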