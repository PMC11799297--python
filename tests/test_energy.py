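"""Contact maps, binding energies, decoys, Z-scores, thresholds, labeling."""

import numpy as np
import pandas as pd
import pytest

import tcrmotif.energy as en
from tcrmotif.io import PeptideRecord


def _coords(rows):
    return pd.DataFrame(rows, columns=["chain", "residue_index", "residue_type", "x", "y", "z"])


def _single_contact_map(pos=1, tcr_type="W", e=2.0, peptide_type="F"):
    J = en.EnergyMatrix.zeros()
    J.values[en.AA_TO_INDEX[tcr_type], en.AA_TO_INDEX[peptide_type]] = e
    cmap = en.ContactMap((en.Contact(1, tcr_type, pos),))
    return cmap, J


class TestContactMap:
    @pytest.mark.parametrize("dist,expected", [(8.5, 1), (8.6, 0)])
    def test_cutoff_is_inclusive(self, dist, expected):
        coords = _coords(
            [
                ("tcr", 1, "W", 0.0, 0.0, 0.0),
                ("peptide", 1, "A", dist, 0.0, 0.0),
            ]
        )
        cmap = en.compute_contact_map(coords, r_max=8.5)
        assert len(cmap) == expected

    def test_missing_chain_rejected(self):
        coords = _coords([("tcr", 1, "W", 0.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="both"):
            en.compute_contact_map(coords)

    def test_duplicate_contacts_rejected(self):
        c = en.Contact(1, "W", 2)
        with pytest.raises(ValueError, match="duplicate"):
            en.ContactMap((c, en.Contact(1, "A", 2)))


class TestBindingEnergy:
    def test_empty_contact_map_gives_zero(self):
        assert en.binding_energy("ACDEF", en.ContactMap(()), en.EnergyMatrix.zeros()) == 0.0

    def test_single_contact_term(self):
        cmap, J = _single_contact_map(pos=3)
        assert en.binding_energy("AAFAA", cmap, J) == 2.0
        assert en.binding_energy("AAAAA", cmap, J) == 0.0

    def test_contact_beyond_length_rejected(self):
        cmap, J = _single_contact_map(pos=9)
        with pytest.raises(ValueError, match="beyond peptide length"):
            en.binding_energy("AAA", cmap, J)

    def test_linear_in_disjoint_contact_sets(self):
        rng = np.random.default_rng(0)
        J = en.EnergyMatrix(rng.normal(size=(20, 20)))
        pep = "ACDEFGHIKLMNP"
        c1 = en.ContactMap((en.Contact(1, "W", 2), en.Contact(2, "F", 5)))
        c2 = en.ContactMap((en.Contact(3, "K", 7), en.Contact(4, "A", 11)))
        union = en.ContactMap(c1.contacts + c2.contacts)
        assert en.binding_energy(pep, union, J) == pytest.approx(
            en.binding_energy(pep, c1, J) + en.binding_energy(pep, c2, J)
        )

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(1)
        J = en.EnergyMatrix(rng.normal(size=(20, 20)))
        cmap = en.ContactMap((en.Contact(1, "W", 1), en.Contact(2, "C", 3)))
        peps = en.generate_decoys("AAAA", n=25, seed=5)
        batch = en.binding_energies(peps, cmap, J)
        assert np.allclose(batch, [en.binding_energy(p, cmap, J) for p in peps])


class TestDecoys:
    def test_count_and_length(self):
        decoys = en.generate_decoys("A" * 13, n=1000, seed=0)
        assert len(decoys) == 1000
        assert all(len(d) == 13 for d in decoys)

    def test_deterministic(self):
        assert en.generate_decoys("ACD", n=1, seed=7) == en.generate_decoys("ACD", n=1, seed=7)

    def test_per_position_frequencies_uniform(self):
        decoys = en.generate_decoys("A" * 5, n=10_000, seed=2)
        se = np.sqrt(0.05 * 0.95 / 10_000)
        for pos in range(5):
            counts = pd.Series([d[pos] for d in decoys]).value_counts(normalize=True)
            assert (counts - 0.05).abs().max() <= 3 * se


class TestZScores:
    def test_hand_computed_case(self):
        zs = en.z_scores(np.array([6.0, 2.0, 4.0]), np.array([0.0, 0.0, 4.0, 4.0]))
        assert zs.decoy_mean == 2.0
        assert zs.decoy_sd == 2.0
        assert zs.z.tolist() == [2.0, 0.0, 1.0]

    def test_decoy_ensemble_standardizes_itself(self):
        rng = np.random.default_rng(3)
        d = rng.normal(5, 2, size=500)
        zs = en.z_scores(d, d)
        assert abs(zs.z.mean()) < 1e-10
        assert abs(zs.z.std(ddof=0) - 1) < 1e-10

    def test_degenerate_ensemble_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            en.z_scores(np.array([1.0]), np.array([2.0, 2.0]))


class TestFindThreshold:
    def test_symmetric_point_masses(self):
        res = en.find_threshold(np.full(100, 3.0), np.full(100, -3.0))
        assert res.z_threshold == pytest.approx(0.0, abs=1e-12)

    def test_threshold_is_midpoint_of_peaks(self):
        rng = np.random.default_rng(4)
        res = en.find_threshold(rng.normal(4, 0.3, 1000), rng.normal(0, 0.3, 1000))
        assert res.z_threshold == pytest.approx((res.peak_strong + res.peak_weak) / 2)

    def test_gaussian_simulation_near_zero(self):
        rng = np.random.default_rng(5)
        res = en.find_threshold(rng.normal(3, 0.5, 10_000), rng.normal(-3, 0.5, 10_000), bins=50)
        assert abs(res.z_threshold) <= 0.3  # two bin widths over the pooled range

    def test_degenerate_pooled_sample_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            en.find_threshold(np.ones(5), np.ones(5))


class TestReadThresholdAndLabels:
    def test_mapping_hand_example(self):
        cases = list(zip([5.0, 4.0, 3.0, 2.0, 1.0], [100, 80, 60, 2, 1]))
        assert en.map_threshold_to_reads(cases, 2.5) == 60

    def test_mapping_boundaries(self):
        cases = list(zip([5.0, 1.0], [100, 7]))
        assert en.map_threshold_to_reads(cases, 0.0) == 7  # below min Z
        assert en.map_threshold_to_reads(cases, 4.0) == 100  # single case above
        with pytest.raises(ValueError, match="no case"):
            en.map_threshold_to_reads(cases, 9.0)

    def test_label_boundary_inclusive(self):
        recs = [
            PeptideRecord("a", "AAA", 10),
            PeptideRecord("b", "AAA", 9),
            PeptideRecord("c", "AAA", 0),
        ]
        labeled = en.label_peptides(recs, 10)
        assert [r.label for r in labeled] == [1, 0, 0]

    def test_undersample_contract(self):
        recs = [PeptideRecord(f"s{i}", "AAA", 10, label=1) for i in range(10)] + [
            PeptideRecord(f"w{i}", "AAA", 0, label=0) for i in range(1000)
        ]
        balanced = en.undersample(recs, seed=1)
        assert sum(r.label == 1 for r in balanced) == 10
        assert sum(r.label == 0 for r in balanced) == 10
        assert balanced == en.undersample(recs, seed=1)
        assert balanced != en.undersample(recs, seed=2)

    def test_undersample_degenerate_weak_class(self, caplog):
        recs = [PeptideRecord(f"s{i}", "AAA", 10, label=1) for i in range(5)] + [
            PeptideRecord("w0", "AAA", 0, label=0)
        ]
        balanced = en.undersample(recs, seed=0)
        assert sum(r.label == 0 for r in balanced) == 1
        with pytest.raises(ValueError):
            en.undersample([PeptideRecord("w0", "AAA", 0, label=0)], seed=0)
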