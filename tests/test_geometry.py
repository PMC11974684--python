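"""Domain geometry: centres of mass, contacts, residue pairs, KDE."""

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from cas12akin.geometry import (
    DOMAIN_PRESETS,
    DomainDefinition,
    ElementError,
    FrameEnsemble,
    SelectionError,
    center_of_mass,
    com_distance_series,
    contact_count,
    contact_residue_pairs,
    contact_series,
    infer_element,
    kde_density,
)
from cas12akin.synthetic import EnsembleSpec, generate_ensemble

TOY_DOMAINS = DomainDefinition("toy", rec2=(1, 10), nuc=(100, 110))


def _ensemble(coords, res_ids, elements=None, names=None):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n = coords.shape[1]
    if elements is None:
        elements = ["C"] * n
    if names is None:
        names = [f"{el}{i}" for i, el in enumerate(elements)]
    return FrameEnsemble(coords=coords, res_ids=np.asarray(res_ids),
                         atom_names=np.asarray(names, dtype=object),
                         elements=np.asarray(elements, dtype=object))


class TestDomainDefinition:
    @pytest.mark.parametrize(
        "name,rec2,nuc",
        [
            ("FnCas12a", (340, 591), (1079, 1254)),
            ("LbCas12a", (283, 521), (998, 1179)),
            ("AsCas12a", (321, 526), (1067, 1262)),
        ],
    )
    def test_orthologue_presets(self, name, rec2, nuc):
        preset = DOMAIN_PRESETS[name]
        assert (preset.rec2, preset.nuc) == (rec2, nuc)

    def test_rejects_overlapping_ranges(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainDefinition("bad", rec2=(1, 100), nuc=(50, 200))

    def test_rejects_empty_range(self):
        with pytest.raises(ValueError, match="empty"):
            DomainDefinition("bad", rec2=(10, 5), nuc=(100, 200))


class TestCenterOfMass:
    def test_single_atom(self):
        ens = _ensemble([[0.0, 0.0, 0.0]], [1])
        assert center_of_mass(ens, (1, 1), frame=0) == pytest.approx([0, 0, 0])

    def test_two_equal_masses_average(self):
        ens = _ensemble([[0, 0, 0], [2, 0, 0]], [1, 1])
        assert center_of_mass(ens, (1, 1), frame=0) == pytest.approx([1, 0, 0])

    def test_mass_weighting_carbon_oxygen(self):
        ens = _ensemble([[0, 0, 0], [1, 0, 0]], [1, 1], elements=["C", "O"])
        x = center_of_mass(ens, (1, 1), frame=0)[0]
        assert x == pytest.approx(15.999 / (12.011 + 15.999))
        assert x == pytest.approx(0.5712, abs=1e-4)

    def test_geometric_weighting_ignores_mass(self):
        ens = _ensemble([[0, 0, 0], [1, 0, 0]], [1, 1], elements=["C", "O"])
        assert center_of_mass(ens, (1, 1), weighting="geometric", frame=0)[0] == pytest.approx(0.5)

    def test_empty_selection_raises_with_range_named(self):
        ens = _ensemble([[0, 0, 0]], [1])
        with pytest.raises(SelectionError, match="500-600"):
            center_of_mass(ens, (500, 600))


class TestComDistance:
    def test_three_four_five_triangle(self):
        ens = _ensemble([[0, 0, 0], [3, 4, 0]], [1, 100])
        d = com_distance_series(ens, TOY_DOMAINS)
        assert d[0] == pytest.approx(5.0)

    def test_symmetric_in_the_two_ranges(self):
        ens = _ensemble(np.random.default_rng(0).normal(size=(6, 3)), [1, 1, 5, 100, 105, 110])
        swapped = DomainDefinition("swap", rec2=TOY_DOMAINS.nuc, nuc=TOY_DOMAINS.rec2)
        assert com_distance_series(ens, TOY_DOMAINS)[0] == pytest.approx(
            com_distance_series(ens, swapped)[0]
        )

    def test_identical_ranges_give_zero(self):
        ens = _ensemble([[1, 2, 3], [4, 5, 6]], [1, 5])
        same = DomainDefinition("same", rec2=(1, 5), nuc=(6, 9))
        ens2 = _ensemble([[1, 2, 3], [1, 2, 3]], [1, 6])
        assert com_distance_series(ens2, same)[0] == pytest.approx(0.0)


class TestContactCount:
    @pytest.mark.parametrize("dx,expected", [(3.4, 1), (3.5, 0), (3.6, 0)])
    def test_strict_cutoff_boundary(self, dx, expected):
        ens = _ensemble([[0, 0, 0], [dx, 0, 0]], [1, 100])
        assert contact_count(ens, TOY_DOMAINS) == expected

    def test_hydrogen_excluded_even_when_close(self):
        ens = _ensemble([[0, 0, 0], [3.4, 0, 0]], [1, 100], elements=["H", "C"])
        assert contact_count(ens, TOY_DOMAINS) == 0

    def test_matches_brute_force_on_random_frames(self, fn_domains):
        spec = EnsembleSpec(n_frames=100, distance_mean=9.0, distance_sd=1.5, seed=13)
        ens = generate_ensemble(spec, fn_domains)
        heavy = ens.heavy_mask()
        ma = ens.select(fn_domains.rec2) & heavy
        mb = ens.select(fn_domains.nuc) & heavy
        for f in range(ens.n_frames):
            a, b = ens.coords[f, ma], ens.coords[f, mb]
            d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
            assert contact_count(ens, fn_domains, frame=f) == int(np.sum(d2 < 3.5**2))

    def test_rigid_motion_leaves_distances_and_contacts_unchanged(self, contact_rich_ensemble, fn_domains):
        ens = contact_rich_ensemble
        rng = np.random.default_rng(21)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        shift = rng.uniform(-50, 50, size=3)
        moved = FrameEnsemble(coords=ens.coords @ rot.T + shift, res_ids=ens.res_ids,
                              atom_names=ens.atom_names, elements=ens.elements)
        d0 = com_distance_series(ens, fn_domains)
        d1 = com_distance_series(moved, fn_domains)
        assert np.max(np.abs(d0 - d1)) < 1e-9
        s0 = contact_series(ens, fn_domains)
        s1 = contact_series(moved, fn_domains)
        assert np.array_equal(s0.contacts, s1.contacts)

    def test_ambiguous_atom_name_raises(self):
        ens = _ensemble([[0, 0, 0], [1, 0, 0]], [1, 100], elements=["", ""], names=["C1", "123"])
        with pytest.raises(ElementError):
            contact_count(ens, TOY_DOMAINS)


class TestContactResiduePairs:
    def test_always_touching_pair_listed_first_with_fraction_one(self):
        frames = np.tile(np.array([[0.0, 0, 0], [2.0, 0, 0], [30.0, 0, 0]]), (4, 1, 1))
        ens = FrameEnsemble(coords=frames, res_ids=np.array([5, 100, 108]),
                            atom_names=np.array(["C1", "C2", "C3"], dtype=object),
                            elements=np.array(["C", "C", "C"], dtype=object))
        pairs = contact_residue_pairs(ens, TOY_DOMAINS)
        assert pairs[0] == (5, 100, 1.0)

    def test_no_contacts_gives_empty_list(self, fn_domains):
        ens = generate_ensemble(
            EnsembleSpec(n_frames=3, distance_mean=80.0, distance_sd=0.0, seed=1), fn_domains)
        assert contact_residue_pairs(ens, fn_domains) == []

    def test_partial_occupancy_fraction(self):
        # residue pair within cutoff in 2 of 3 frames -> fraction 2/3
        base = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        far = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        ens = FrameEnsemble(coords=np.stack([base, base, far]), res_ids=np.array([3, 105]),
                            atom_names=np.array(["C1", "C2"], dtype=object),
                            elements=np.array(["C", "C"], dtype=object))
        pairs = contact_residue_pairs(ens, TOY_DOMAINS, min_frame_fraction=0.1)
        assert pairs == [(3, 105, pytest.approx(2 / 3))]

    def test_threshold_filters_rare_pairs(self):
        base = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        far = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        ens = FrameEnsemble(coords=np.stack([base] + [far] * 9), res_ids=np.array([3, 105]),
                            atom_names=np.array(["C1", "C2"], dtype=object),
                            elements=np.array(["C", "C"], dtype=object))
        assert contact_residue_pairs(ens, TOY_DOMAINS, min_frame_fraction=0.2) == []


class TestElementInference:
    @pytest.mark.parametrize("name,element", [("CA", "C"), ("1HB2", "H"), ("OD1", "O"), ("N", "N")])
    def test_leading_letter_after_digit_stripping(self, name, element):
        assert infer_element(name) == element

    @pytest.mark.parametrize("name", ["123", "", "'"])
    def test_unresolvable_names_raise(self, name):
        with pytest.raises(ElementError):
            infer_element(name)


class TestKde:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        grid, density = kde_density(rng.normal(10.0, 2.0, 500))
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_samples_give_symmetric_density(self):
        grid = np.linspace(-3, 3, 301)
        _, density = kde_density(np.array([-1.0, 1.0]), grid=grid)
        assert np.max(np.abs(density - density[::-1])) < 1e-12

    def test_peak_recovery_on_seeded_normal(self):
        rng = np.random.default_rng(123)
        grid, density = kde_density(rng.normal(43.5, 1.0, 5000))
        assert abs(grid[np.argmax(density)] - 43.5) < 0.2

    def test_matches_scipy_gaussian_kde(self):
        # independent reference: scipy's KDE with the same Scott bandwidth
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, 400)
        grid = np.linspace(-4, 4, 201)
        _, mine = kde_density(x, grid=grid)
        ref = gaussian_kde(x, bw_method="scott")(grid)
        assert np.max(np.abs(mine - ref)) < 1e-10

    def test_zero_variance_suggests_override_and_override_works(self):
        x = np.full(10, 5.0)
        with pytest.raises(ValueError, match="bandwidth"):
            kde_density(x)
        grid, density = kde_density(x, bandwidth=0.5)
        assert grid[np.argmax(density)] == pytest.approx(5.0, abs=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kde_density([1.0])
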