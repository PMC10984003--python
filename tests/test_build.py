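import numpy as np
import pytest

import fibrilcg as fc
from fibrilcg.build import N_STAGGER, hex_lattice_sites
from fibrilcg.parameters import SPECIES_COLLAGEN, SPECIES_END

from conftest import axial_density_period


def test_nominal_diameter_gives_155_molecules(reference_model):
    """A 200-nm nominal cross-section holds 155 tropocollagen molecules."""
    assert reference_model.molecules_in_cross_section() == 155
    assert len(set(reference_model.lane_id[reference_model.lane_id >= 0])) == 155


def test_molecule_has_218_beads_and_40_end_particles_per_end(reference_model):
    """Each lane carries 218 collagen beads plus 40 strengthened beads per end."""
    m = reference_model
    for lane in (0, 77, 154):
        sel = m.lane_id == lane
        assert int(np.sum(m.species[sel] == SPECIES_COLLAGEN)) == 218
        ends = m.positions[sel & (m.species == SPECIES_END), 0]
        lo, hi = m.gauge_bounds()
        assert int(np.sum(ends < lo)) == 40
        assert int(np.sum(ends > hi)) == 40


def test_axial_banding_period_equals_D(reference_model):
    """Density autocorrelation of the built model peaks at the D-period."""
    D = reference_model.meta["D"]
    period = axial_density_period(reference_model)
    assert period == pytest.approx(D, abs=10.0)


def test_gap_fraction_of_period(reference_model):
    """Gap length over D is 0.6 within one particle spacing / D."""
    m = reference_model
    d = m.positions[m.gap_pairs[:, 1], 0] - m.positions[m.gap_pairs[:, 0], 0]
    frac = d / m.meta["D"]
    assert np.all(np.abs(frac - 0.6) <= 14.0 / m.meta["D"])


def test_stagger_rule_nearest_neighbors_differ():
    """Adjacent lattice sites always get different axial offsets."""
    sites, stag = hex_lattice_sites(155, 16.52)
    from scipy.spatial import cKDTree

    tree = cKDTree(sites)
    pairs = tree.query_pairs(16.52 * 1.01, output_type="ndarray")
    assert len(pairs) > 300
    assert np.all(stag[pairs[:, 0]] != stag[pairs[:, 1]])
    assert set(stag) == set(range(N_STAGGER))


def test_every_lane_is_cut_into_two_fragments_with_one_gap(mini7x5):
    """The 0.2 D window offset cuts every lane's molecule at both boundaries."""
    m = mini7x5
    assert len(m.gap_pairs) == 7  # one interior gap per lane
    for lane in range(7):
        mols = set(m.mol_id[(m.lane_id == lane) & (m.mol_id >= 0)])
        assert len(mols) == 2


def test_min_distance_invariant(mini7x5, ff):
    from scipy.spatial import cKDTree

    dmin = 0.5 * min(p.sigma for p in ff.pairs.values())
    tree = cKDTree(mini7x5.positions)
    assert len(tree.query_pairs(dmin)) == 0


def test_build_at_rest_has_zero_bond_and_angle_energy(mini7, ff):
    e = fc.total_energy(mini7, ff)
    assert abs(e["E_bond"]) < 1e-9
    assert abs(e["E_angle"]) < 1e-9
    assert e["E_total"] == pytest.approx(
        e["E_bond"] + e["E_angle"] + e["E_nonbonded"])


def test_backbone_span_mismatch_rejected(ff):
    straight = fc.generate_backbone(218, 14.0)  # span 3038 != 4.4 D
    with pytest.raises(ValueError, match="inconsistent"):
        fc.build_fibril(fc.FibrilLayout(n_molecules=7), backbone=straight,
                        forcefield=ff)


def test_empty_cross_section_rejected(ff):
    with pytest.raises(ValueError):
        fc.build_fibril(fc.FibrilLayout(cross_section_radius=10.0),
                        forcefield=ff)


def test_model_roundtrip_bit_exact(tmp_path, mini7):
    p = tmp_path / "model.txt"
    fc.save_model(mini7, p)
    m2 = fc.load_model(p)
    assert np.array_equal(m2.positions, mini7.positions)
    assert np.array_equal(m2.species, mini7.species)
    assert np.array_equal(m2.bonds, mini7.bonds)
    assert np.array_equal(m2.phi0, mini7.phi0)
    assert np.array_equal(m2.gap_pairs, mini7.gap_pairs)
    assert m2.meta == mini7.meta


def test_periodic_build_wraps_molecules(ff):
    m = fc.build_fibril(fc.FibrilLayout(n_molecules=7, n_periods=5),
                        strengthen_ends=False, periodic=True, forcefield=ff)
    assert m.box.periodic_x
    # one molecule per lane per 5-D box, each with one wrap-aware gap
    assert m.n_molecules == 7
    assert len(m.gap_pairs) == 7
    # bonds reconnect the cut: rest energy is still zero
    e = fc.total_energy(m, ff)
    assert abs(e["E_bond"]) < 1e-9


def test_gap_length_measure_invariances(mini7x5):
    """Axial gap length is translation invariant and scales affinely."""
    gp = mini7x5.gap_pairs
    d0 = mini7x5.positions[gp[:, 1], 0] - mini7x5.positions[gp[:, 0], 0]
    shifted = mini7x5.positions + np.array([123.4, -5.0, 8.0])
    d1 = shifted[gp[:, 1], 0] - shifted[gp[:, 0], 0]
    np.testing.assert_allclose(d1, d0, atol=1e-9)
    stretched = mini7x5.positions.copy()
    stretched[:, 0] *= 1.25
    d2 = stretched[gp[:, 1], 0] - stretched[gp[:, 0], 0]
    np.testing.assert_allclose(d2, 1.25 * d0, rtol=1e-12)


def test_fixture_presets(ff):
    m7 = fc.make_fixture(fc.FixtureSpec("mini_fibril_7"), forcefield=ff)
    assert m7.molecules_in_cross_section() == 7
    assert m7.meta["n_periods"] == 2
    m19 = fc.make_fixture(fc.FixtureSpec("mini_fibril_19"), forcefield=ff)
    assert m19.molecules_in_cross_section() == 19
    d = fc.make_fixture(fc.FixtureSpec("dimer"), forcefield=ff)
    assert d.n_particles == 2
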