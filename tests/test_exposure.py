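"""Radial scoring, Shrake–Rupley SASA, and chain classification."""

import math

import numpy as np
import pytest

from ribosurf import (
    Atom,
    Chain,
    ConfigurationError,
    CoreModel,
    DegenerateSeparationError,
    FixtureSpec,
    RadiusLookupError,
    Residue,
    SasaParams,
    Structure,
    canonical_frame,
    classify_chains,
    compute_core,
    exposure_ratio,
    make_burial_fixture,
    make_shell_assembly,
    radial_score,
    shrake_rupley_sasa,
    sphere_points,
)
from ribosurf.exposure import _sasa_per_atom


def _ca_chain(cid, coords):
    return Chain(cid, [
        Residue("ALA", i + 1, [Atom("CA", "C", xyz)], "protein")
        for i, xyz in enumerate(coords)
    ])


# ---------------------------------------------------------------------------
# core
# ---------------------------------------------------------------------------

class TestComputeCore:
    def test_degenerate_centroid(self):
        st = Structure("x", [_ca_chain("A", [[1, 2, 3]] * 4)])
        core = compute_core(st)
        np.testing.assert_allclose(core.centers[0], [1, 2, 3])

    def test_two_point_symmetry(self):
        st = Structure("x", [_ca_chain("A", [[0, 0, 0]]), _ca_chain("B", [[2, 0, 0]])])
        core = compute_core(st)
        np.testing.assert_allclose(core.centers[0], [1, 0, 0])

    def test_shell_fixture_center_near_origin(self):
        st, _ = make_shell_assembly(FixtureSpec(n_internal=4, n_surface=30, seed=5,
                                                atoms_per_chain=40))
        core = compute_core(st)
        # surface directions are uniform, so the centroid stays near the origin
        assert np.linalg.norm(core.centers[0]) < 0.5 * core.norm_radius * 0.2
        assert core.norm_radius > 0

    def test_rna_only_without_rna_errors(self):
        st = Structure("x", [_ca_chain("A", [[0, 0, 0]] * 4)])
        with pytest.raises(ConfigurationError):
            compute_core(st, mode="rna_only")

    def test_per_subunit_has_two_centers(self):
        chains = [
            _ca_chain("A", np.random.default_rng(0).normal(size=(5, 3)) + [50, 0, 0]),
            _ca_chain("B", np.random.default_rng(1).normal(size=(5, 3)) + [50, 2, 0]),
            _ca_chain("C", np.random.default_rng(2).normal(size=(5, 3)) - [50, 0, 0]),
            _ca_chain("D", np.random.default_rng(3).normal(size=(5, 3)) - [50, 2, 0]),
        ]
        core = compute_core(Structure("x", chains), mode="per_subunit")
        assert core.centers.shape == (2, 3)
        xs = sorted(core.centers[:, 0])
        assert xs[0] < -40 and xs[1] > 40


class TestRadialScore:
    def test_chain_at_center_scores_zero(self):
        core = CoreModel("assembly", np.array([[5.0, 5.0, 5.0]]), 10.0)
        assert radial_score(_ca_chain("A", [[5, 5, 5]] * 3), core) == 0.0

    def test_chain_at_norm_radius_scores_one(self):
        core = CoreModel("assembly", np.array([[0.0, 0.0, 0.0]]), 10.0)
        chain = _ca_chain("A", [[10, 0, 0], [0, 10, 0], [0, 0, 10]])
        assert radial_score(chain, core) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        st, _ = make_shell_assembly(FixtureSpec(seed=11, n_internal=3, n_surface=5))
        core = compute_core(st)
        for chain in st.chains:
            dists = []
            for res in chain.residues:
                ca = next(a for a in res.atoms if a.name == "CA")
                best = min(
                    math.sqrt(sum((ca.coord[k] - c[k]) ** 2 for k in range(3)))
                    for c in core.centers
                )
                dists.append(best)
            expected = float(np.median(dists)) / core.norm_radius
            assert radial_score(chain, core) == expected


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def naive_sasa(coords, radii, params):
    """All-pairs Shrake–Rupley oracle sharing the point set, no spatial index."""
    n = len(coords)
    neighbor_lists = [np.array([j for j in range(n) if j != i]) for i in range(n)]
    return _sasa_per_atom(np.asarray(coords, float), np.asarray(radii, float),
                          params, neighbor_lists=neighbor_lists)


class TestShrakeRupley:
    def test_isolated_carbon_analytic(self):
        analytic = 4 * math.pi * 3.1**2
        atom = Atom("C", "C", [0, 0, 0])
        a100 = shrake_rupley_sasa([atom], [atom], SasaParams(n_points=100))[0]
        a960 = shrake_rupley_sasa([atom], [atom], SasaParams(n_points=960))[0]
        assert abs(a100 - analytic) / analytic < 0.02
        assert abs(a960 - analytic) / analytic < 0.005

    def test_two_overlapping_atoms_symmetric_and_reduced(self):
        a = Atom("C", "C", [0, 0, 0.9])
        b = Atom("C", "C", [0, 0, -0.9])
        areas = shrake_rupley_sasa([a, b], [a, b], SasaParams(n_points=960))
        isolated = 4 * math.pi * 3.1**2
        assert areas[0] == pytest.approx(areas[1], rel=0.02)
        assert areas[0] < isolated
        assert areas[1] < isolated

    def test_monotone_burial_property(self, rng):
        params = SasaParams(n_points=100)
        coords = rng.normal(scale=3, size=(15, 3))
        radii = np.full(15, 1.7)
        base = _sasa_per_atom(coords, radii, params)
        more = np.vstack([coords, rng.normal(scale=3, size=(10, 3))])
        grown = _sasa_per_atom(more, np.full(25, 1.7), params)[:15]
        assert np.all(grown <= base + 1e-12)

    def test_missing_element_radius_names_element(self):
        params = SasaParams(radii_table={"C": 1.7})
        atom = Atom("FE", "Fe", [0, 0, 0])
        with pytest.raises(RadiusLookupError, match="Fe"):
            shrake_rupley_sasa([atom], [atom], params)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_grid_path_matches_allpairs_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        coords = canonical_frame(rng.normal(scale=6, size=(n, 3)))
        radii = rng.choice([1.52, 1.55, 1.7, 1.8], size=n)
        params = SasaParams(n_points=100)
        fast = _sasa_per_atom(coords, radii, params)
        slow = naive_sasa(coords, radii, params)
        np.testing.assert_array_equal(fast, slow)

    def test_sphere_points_are_unit_and_deterministic(self):
        pts = sphere_points(200)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, sphere_points(200))

    def test_cross_check_against_biotite(self, rng):
        """Independent SASA implementation agrees on a random atom cluster."""
        biotite_struct = pytest.importorskip("biotite.structure")
        coords = rng.normal(scale=4, size=(30, 3))
        arr = biotite_struct.AtomArray(30)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 30)
        arr.atom_name = np.array(["CA"] * 30)
        arr.res_name = np.array(["ALA"] * 30)
        arr.res_id = np.arange(1, 31)
        arr.chain_id = np.array(["A"] * 30)
        ref = biotite_struct.sasa(arr, probe_radius=1.4, point_number=960,
                                  vdw_radii="Single").sum()
        atoms = [Atom("CA", "C", xyz) for xyz in coords]
        ours = shrake_rupley_sasa(atoms, atoms, SasaParams(n_points=960)).sum()
        assert ours == pytest.approx(ref, rel=0.03)


class TestExposureRatio:
    def test_chain_alone_is_unity(self):
        st, _ = make_shell_assembly(FixtureSpec(seed=2, n_internal=1, n_surface=1))
        chain = st.chains[0]
        solo = Structure("solo", [chain])
        assert exposure_ratio(chain, solo) == pytest.approx(1.0)

    def test_fully_caged_chain_is_buried(self):
        st = make_burial_fixture(seed=0)
        assert exposure_ratio(st.get_chain("T"), st) < 0.05

    def test_thinned_cage_re_exposes(self):
        dense = make_burial_fixture(seed=0)
        thin = make_burial_fixture(seed=0, cage_points=4)
        r_dense = exposure_ratio(dense.get_chain("T"), dense)
        r_thin = exposure_ratio(thin.get_chain("T"), thin)
        assert r_thin > r_dense


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassifyChains:
    def test_fixture_truth_recovered(self, shell_assembly):
        st, truth = shell_assembly
        exposures = classify_chains(st)
        assert {e.chain_id: e.label for e in exposures} == truth

    def test_fixed_threshold_boundaries(self, shell_assembly):
        st, _ = shell_assembly
        assert all(e.label == "surface" for e in classify_chains(st, threshold=0.0,
                                                                 compute_sasa=False))
        assert all(e.label == "internal" for e in classify_chains(
            st, threshold=float("inf"), compute_sasa=False))

    def test_identical_scores_degenerate_error(self):
        # two chains mirrored through the origin: identical radial scores
        st = Structure("x", [
            _ca_chain("A", [[10, 0, 0]] * 4),
            _ca_chain("B", [[-10, 0, 0]] * 4),
        ])
        with pytest.raises(DegenerateSeparationError):
            classify_chains(st, compute_sasa=False)

    def test_output_sorted_and_margins_consistent(self, shell_assembly):
        st, _ = shell_assembly
        exposures = classify_chains(st, compute_sasa=False)
        ids = [e.chain_id for e in exposures]
        assert ids == sorted(ids)
        for e in exposures:
            assert e.margin == pytest.approx(abs(e.radial_score - exposures.threshold))
            assert (e.radial_score >= exposures.threshold) == (e.label == "surface")
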