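"""Volume geometry, mass conversion, ladders, and SES specific volume."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crafruk.volumetry import (
    AfmMassEstimator,
    AfmPeak,
    dna_segment_volume,
    elliptic_cylinder_volume,
    mw_to_volume,
    net_protein_volume,
    protein_monomer_mass,
    reference_ladder,
    ses_volume,
    specific_volume_from_structure,
    volume_to_mw,
)


@pytest.mark.parametrize(
    "h, wl, wo, expected",
    [
        (1.0, 2.0, 2.0, math.pi),
        (2.5, 8.0, 6.0, 30 * math.pi),
    ],
)
def test_elliptic_cylinder_closed_forms(h, wl, wo, expected):
    assert elliptic_cylinder_volume(h, wl, wo) == pytest.approx(expected, rel=1e-12)


def test_width_swap_symmetry():
    assert elliptic_cylinder_volume(1.7, 9.0, 4.0) == elliptic_cylinder_volume(1.7, 4.0, 9.0)


@pytest.mark.parametrize(
    "h, w, expected",
    [(1.5, 1.0, 1.0), (0.5, 6.0, 12.0), (1e-12, 3.0, 6e-12)],
)
def test_dna_segment_closed_forms(h, w, expected):
    assert dna_segment_volume(h, w) == pytest.approx(expected, rel=1e-9)


def test_nonpositive_geometry_rejected():
    with pytest.raises(ValueError):
        elliptic_cylinder_volume(0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        dna_segment_volume(1.0, -2.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    s=st.floats(0.1, 10.0),
    h=st.floats(0.2, 5.0),
    wl=st.floats(1.0, 40.0),
    wo=st.floats(1.0, 40.0),
)
def test_volumes_are_cubic_in_length_scale(s, h, wl, wo):
    v1 = elliptic_cylinder_volume(h, wl, wo)
    assert elliptic_cylinder_volume(s * h, s * wl, s * wo) == pytest.approx(s**3 * v1, rel=1e-9)
    v2 = dna_segment_volume(h, wl)
    assert dna_segment_volume(s * h, s * wl) == pytest.approx(s**3 * v2, rel=1e-9)


class TestMassConversion:
    def test_unit_analysis_oracle(self):
        # 67 nm^3 at 0.67 ml/g is 1e-19 g, i.e. 1e-19 * N_A Da
        assert volume_to_mw(67.0, 0.67) == pytest.approx(1e-19 * 6.02214076e23, rel=1e-12)

    def test_zero_volume(self):
        assert volume_to_mw(0.0) == 0.0

    @pytest.mark.parametrize("v", [1.0, 50.0, 500.0])
    def test_round_trip(self, v):
        assert mw_to_volume(volume_to_mw(v)) == pytest.approx(v, rel=1e-12)

    def test_linear_in_volume_inverse_in_density(self):
        assert volume_to_mw(10.0, 0.67) == pytest.approx(2 * volume_to_mw(5.0, 0.67))
        assert volume_to_mw(10.0, 0.335) == pytest.approx(2 * volume_to_mw(10.0, 0.67))

    def test_invalid_specific_volume(self):
        with pytest.raises(ValueError):
            volume_to_mw(1.0, 0.0)


class TestNetVolume:
    def test_free_peak_keeps_gross(self):
        gross, dna, net, ok = net_protein_volume(AfmPeak("p", 2.5, 8.0, 6.0))
        assert dna == 0.0 and net == gross and ok

    def test_bound_peak_subtracts_dna(self):
        gross, dna, net, ok = net_protein_volume(
            AfmPeak("p", 2.5, 8.0, 6.0, dna_bound=True, h_dna=0.5, w_dna=6.0)
        )
        assert gross == pytest.approx(30 * math.pi)
        assert dna == pytest.approx(12.0)
        assert net == pytest.approx(30 * math.pi - 12.0)
        assert ok

    def test_dna_exceeding_gross_is_flagged_not_clamped(self):
        gross, dna, net, ok = net_protein_volume(
            AfmPeak("p", 0.2, 2.0, 2.0, dna_bound=True, h_dna=2.0, w_dna=6.0)
        )
        assert not ok and net < 0

    def test_bound_without_dna_measurements_rejected(self):
        with pytest.raises(ValueError, match="require h_dna"):
            AfmPeak("p", 1.0, 2.0, 2.0, dna_bound=True)


class TestReferenceLadder:
    def test_printed_ladder_masses(self):
        lad = reference_ladder()
        assert lad.entries["Cra homodimer"] == 75998
        assert lad.entries["FruK homodimer"] == 67512
        assert lad.entries["(dimer)2 Cra-FruK"] == 143510
        assert lad.entries["(dimer)3 Cra-FruK-Cra"] == 219508

    def test_entries_are_integer_monomer_combinations(self):
        lad = reference_ladder({"Cra": 37999.0, "FruK": 33756.0})
        for name, mass in lad.entries.items():
            comp = lad.compositions[name]
            assert mass == sum(n * {"Cra": 37999.0, "FruK": 33756.0}[sp] for sp, n in comp.items())
            assert all(isinstance(n, int) and n > 0 for n in comp.values())

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            reference_ladder({"Cra": -1.0})


class TestAfmMassEstimator:
    def test_mass_table_round_trip(self, afm_sheet):
        out = AfmMassEstimator().fit().transform(afm_sheet)
        # 5% dimension noise: masses near truth but not exact
        rel = np.abs(out["mass_da"] - out["true_mass_da"]) / out["true_mass_da"]
        assert np.median(rel) < 0.2

    def test_missing_dna_column_rejected(self):
        df = pd.DataFrame(
            {
                "peak_id": ["a"],
                "h_nm": [1.0],
                "w_long_nm": [4.0],
                "w_orth_nm": [3.0],
                "dna_bound": [True],
            }
        )
        with pytest.raises(ValueError, match="h_dna_nm"):
            AfmMassEstimator().fit().transform(df)

    def test_flagged_rows_dropped_by_default(self):
        df = pd.DataFrame(
            {
                "peak_id": ["bad", "good"],
                "h_nm": [0.1, 2.0],
                "w_long_nm": [1.0, 8.0],
                "w_orth_nm": [1.0, 6.0],
                "dna_bound": [True, False],
                "h_dna_nm": [2.0, np.nan],
                "w_dna_nm": [6.0, np.nan],
            }
        )
        out = AfmMassEstimator().fit().transform(df)
        assert list(out["peak_id"]) == ["good"]
        kept = AfmMassEstimator(drop_flagged=False).fit().transform(df)
        assert kept["flagged"].tolist() == [True, False]
        assert np.isnan(kept.loc[0, "mass_da"])


def _mc_ses_volume(coords, radius, probe, n_samples=150_000, n_dirs=600, seed=0):
    """Monte-Carlo oracle for the solvent-excluded volume of equal spheres.

    A point is solvent-excluded iff the probe ball around it lies inside
    the union of inflated spheres; for overlapping spheres it suffices to
    check the probe ball's boundary (the solvent region is connected to
    infinity, so any intrusion crosses the boundary sphere).
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    R = radius + probe
    lo = coords.min(axis=0) - R
    hi = coords.max(axis=0) + R
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    box = np.prod(hi - lo)
    # Fibonacci sphere directions
    i = np.arange(n_dirs)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1 - 2 * (i + 0.5) / n_dirs
    r_xy = np.sqrt(1 - z * z)
    dirs = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])

    inside = np.zeros(n_samples, dtype=bool)
    d_center = np.linalg.norm(pts[:, None, :] - coords[None], axis=2).min(axis=1)
    cand = d_center <= R  # must at least be in the inflated union
    idx = np.flatnonzero(cand)
    for s in range(0, idx.size, 2000):
        block = idx[s : s + 2000]
        shell = pts[block][:, None, :] + probe * dirs[None, :, :]
        d = np.linalg.norm(shell[:, :, None, :] - coords[None, None], axis=3).min(axis=2)
        inside[block] = np.all(d <= R, axis=1)
    return box * inside.mean()


class TestSesVolume:
    def test_isolated_sphere_identity(self):
        """SES of a single atom is its vdW sphere for any probe."""
        v = ses_volume(np.zeros((1, 3)), ["C"], probe_radius=1.4, grid_spacing=0.15)
        analytic = 4 / 3 * math.pi * 1.7**3
        assert v == pytest.approx(analytic, rel=0.04)

    def test_two_spheres_match_monte_carlo_oracle(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        v_grid = ses_volume(coords, ["C", "C"], probe_radius=1.4, grid_spacing=0.25)
        v_mc = _mc_ses_volume(coords, radius=1.7, probe=1.4)
        assert v_grid == pytest.approx(v_mc, rel=0.01)

    def test_refinement_converges(self):
        coords = np.zeros((1, 3))
        analytic = 4 / 3 * math.pi * 1.7**3
        coarse = ses_volume(coords, ["C"], 1.4, 0.6)
        fine = ses_volume(coords, ["C"], 1.4, 0.15)
        assert abs(fine - analytic) < abs(coarse - analytic)

    def test_unknown_element_names_it(self):
        with pytest.raises(KeyError, match="Xx"):
            ses_volume(np.zeros((1, 3)), ["Xx"])


class TestSpecificVolume:
    def test_single_atom_specific_volume_matches_hand_calc(self):
        # one carbon: v = (4/3) pi 1.7^3 A^3 over 12.011 Da
        sv, ses = specific_volume_from_structure(
            np.zeros((1, 3)), ["C"], probe_radius=1.4, grid_spacing=0.15
        )
        expected = (4 / 3 * math.pi * 1.7**3 * 1e-24) / (12.011 / 6.02214076e23)
        assert sv == pytest.approx(expected, rel=0.04)

    def test_synthetic_globule_lands_in_protein_density_range(self, rng):
        """A synthetic globule with protein-like composition and packing
        (jittered heavy-atom lattice, hydrogens folded into the mass)
        should give a specific volume near the 0.7 ml/g scale of real
        proteins."""
        from crafruk.volumetry import _mass_from_elements

        grid = np.arange(-11.0, 11.01, 2.4)
        xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
        heavy = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        heavy = heavy[np.linalg.norm(heavy, axis=1) <= 10.0]
        heavy += rng.normal(0, 0.15, heavy.shape)
        elements = rng.choice(["C", "C", "C", "N", "O"], size=len(heavy)).tolist()
        mass = _mass_from_elements(elements) + 1.008 * len(heavy)
        sv, _ = specific_volume_from_structure(
            heavy, elements, resolved_mass_da=mass, grid_spacing=0.4
        )
        assert 0.55 < sv < 0.85

    def test_pdb_reader_path(self, tmp_path):
        # minimal synthetic PDB: two atoms
        pdb = tmp_path / "synthetic_dimer.pdb"
        pdb.write_text(
            "ATOM      1  C   ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  O   ALA A   1       1.500   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        sv, ses = specific_volume_from_structure(str(pdb), grid_spacing=0.25)
        assert ses > 0 and sv > 0

    def test_requires_resolved_mass_positive(self):
        with pytest.raises(ValueError):
            specific_volume_from_structure(np.zeros((1, 3)), ["C"], resolved_mass_da=-5.0)


def test_protein_monomer_mass_matches_residue_arithmetic():
    # Gly-Gly: 2 x 75.0669 - 18.0153 (one peptide bond's water)
    assert protein_monomer_mass("GG") == pytest.approx(2 * 75.0669 - 18.0153, abs=0.05)
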