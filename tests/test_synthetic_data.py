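"""The bond grammar: label sampling, bond-map rules, embedding synthesis."""

import collections

import numpy as np
import pytest

from secmap.seqio import DSSP8, reduce_dssp8_to_dssp3
from secmap.synthetic_data import (MIN_LENGTHS, SynthConfig, build_bond_map,
                                   generate_dataset, sample_labels,
                                   synthesize_embeddings)


def runs_of(labels):
    out, start = [], 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((labels[start], start, i))
            start = i
    return out


class TestSampleLabels:
    def test_degenerate_distribution_gives_all_coil(self):
        cfg = SynthConfig(length=12, state_weights={"C": 1.0})
        labels = sample_labels(cfg, np.random.default_rng(0))
        assert labels == "C" * 12

    def test_fixed_seed_reproduces(self):
        cfg = SynthConfig(length=40)
        a = sample_labels(cfg, np.random.default_rng(5))
        b = sample_labels(cfg, np.random.default_rng(5))
        assert a == b

    def test_minimum_run_lengths_hold_over_many_samples(self):
        cfg = SynthConfig(length=48)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            labels = sample_labels(cfg, rng)
            assert len(labels) == 48
            assert set(labels) <= set(DSSP8.symbols)
            for state, a, b in runs_of(labels):
                # C also absorbs truncated tail runs, so it has no minimum
                if state != "C":
                    assert b - a >= MIN_LENGTHS[state], (labels, state, a, b)


class TestBuildBondMap:
    def test_alpha_helix_bonds_enumerated(self):
        # oracle: every (i, j) with j = i + 4 and both inside the H-run
        bonds = build_bond_map("HHHHHH")
        expected = np.zeros((6, 6), dtype=bool)
        for i, j in [(0, 4), (1, 5)]:
            expected[i, j] = expected[j, i] = True
        np.testing.assert_array_equal(bonds, expected)

    def test_short_3_helix_has_no_room_for_bonds(self):
        assert not build_bond_map("GGG").any()

    def test_3_helix_bonds_at_distance_3(self):
        bonds = build_bond_map("GGGG")
        assert bonds[0, 3] and bonds[3, 0]
        assert bonds.sum() == 2

    def test_coil_contributes_no_bonds(self):
        assert not build_bond_map("CCCC").any()

    def test_strand_pairs_bond_antiparallel(self):
        # two 3-residue strands separated by a coil linker
        labels = "EEECCEEE"
        bonds = build_bond_map(labels)
        assert bonds[0, 7] and bonds[1, 6] and bonds[2, 5]

    def test_lone_strand_has_no_partner(self):
        assert not build_bond_map("EEEE").any()

    def test_turn_bonds_i_plus_3(self):
        bonds = build_bond_map("TCCCC")
        assert bonds[0, 3]

    def test_symmetry_and_zero_diagonal_property(self):
        cfg = SynthConfig(length=64)
        rng = np.random.default_rng(1)
        for _ in range(50):
            bonds = build_bond_map(sample_labels(cfg, rng))
            np.testing.assert_array_equal(bonds, bonds.T)
            assert not bonds.diagonal().any()


class TestSynthesizeEmbeddings:
    def test_signal_off_means_bond_independence(self):
        cfg = SynthConfig(length=16, bond_signal=0.0, noise=0.3, seed=0)
        seq = "ACDEFGHIKLMNPQRS"
        bonds_a = build_bond_map("HHHHHHHHHHHHHHHH")
        bonds_b = np.zeros((16, 16), dtype=bool)
        ea = synthesize_embeddings(seq, bonds_a, cfg, np.random.default_rng(9))
        eb = synthesize_embeddings(seq, bonds_b, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(ea.values, eb.values)

    def test_bonded_pairs_have_larger_inner_products(self):
        cfg = SynthConfig(length=64, bond_signal=4.0, noise=0.0)
        rng = np.random.default_rng(2)
        for _ in range(10):
            labels = sample_labels(cfg, rng)
            bonds = build_bond_map(labels)
            if not bonds.any() or bonds.all():
                continue
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=64))
            emb = synthesize_embeddings(seq, bonds, cfg, rng).values
            gram = emb @ emb.T
            off = ~np.eye(64, dtype=bool)
            assert gram[bonds].mean() > gram[off & ~bonds].mean()

    def test_fixed_seed_bit_identical(self):
        cfg = SynthConfig(length=8)
        bonds = build_bond_map("HHHHHHHH")
        a = synthesize_embeddings("ACDEFGHI", bonds, cfg, np.random.default_rng(1))
        b = synthesize_embeddings("ACDEFGHI", bonds, cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_small_dimension_rejected(self):
        with pytest.raises(ValueError, match="embed_dim"):
            SynthConfig(embed_dim=4)


class TestGenerateDataset:
    def test_counts_shapes_and_reduction(self, tiny_dataset):
        config, records, embeddings = tiny_dataset
        assert len(records) == config.n_proteins
        for rec in records:
            assert len(rec.dssp8) == len(rec.sequence) == config.length
            assert rec.dssp3 == reduce_dssp8_to_dssp3(rec.dssp8)
            assert embeddings[rec.id].values.shape == (config.length,
                                                       config.embed_dim)

    def test_round_trip_through_csv_and_container(self, tiny_dataset, tmp_path):
        from secmap.embeddings import load_embeddings, save_embeddings
        from secmap.seqio import read_dataset_csv, write_dataset_csv
        _, records, embeddings = tiny_dataset
        write_dataset_csv(records, tmp_path / "d.csv")
        save_embeddings(embeddings, tmp_path / "e.h5")
        back = read_dataset_csv(tmp_path / "d.csv")
        assert back == records
        loaded = load_embeddings(tmp_path / "e.h5", [r.id for r in back], back)
        for pid in embeddings:
            np.testing.assert_array_equal(loaded[pid].values,
                                          embeddings[pid].values)

    def test_reproducible_from_seed(self):
        cfg = SynthConfig(n_proteins=3, length=16, seed=7)
        ra, ea = generate_dataset(cfg)
        rb, eb = generate_dataset(cfg)
        assert ra == rb
        for pid in ea:
            np.testing.assert_array_equal(ea[pid].values, eb[pid].values)

    def test_class_frequencies_track_segment_weights(self):
        """Residue frequencies over 200 proteins reflect state_weights scaled
        by expected segment length; check rank order of the big classes."""
        cfg = SynthConfig(n_proteins=200, length=64, seed=5)
        records, _ = generate_dataset(cfg)
        counts = collections.Counter("".join(r.dssp8 for r in records))
        total = sum(counts.values())
        freq = {s: counts.get(s, 0) / total for s in "HECTGSB"}
        # H has the largest weight*length product, then E/C
        assert freq["H"] > freq["E"]
        assert freq["H"] > freq["C"] > freq["T"] > freq["G"] > freq["B"]
        # every grammar state actually occurs
        assert min(freq.values()) > 0
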