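"""Level-set initialization, energies, evolution and phase extraction."""
import numpy as np
import pytest

import plasmaseg as ps
from plasmaseg import levelset as ls


class TestInitPhis:
    def test_grid_of_circles_geometry(self):
        state = ls.init_phis((64, 64), radius=6, spacing=16)
        # 4x4 lattice with centers at 8, 24, 40, 56; phi1 at a center = +radius
        for r in (8, 24, 40, 56):
            for c in (8, 24, 40, 56):
                assert state.phi1[r, c] == pytest.approx(6.0)

    def test_positive_area_matches_circle_count(self):
        state = ls.init_phis((64, 64), radius=6, spacing=16)
        area = np.sum(state.phi1 > 0)
        assert area == pytest.approx(16 * np.pi * 36, rel=0.05)

    def test_deterministic(self):
        a = ls.init_phis((48, 40), radius=5, spacing=12)
        b = ls.init_phis((48, 40), radius=5, spacing=12)
        assert np.array_equal(a.phi1, b.phi1) and np.array_equal(a.phi2, b.phi2)

    def test_fields_differ_by_offset(self):
        state = ls.init_phis((64, 64), radius=6, spacing=16)
        assert not np.array_equal(state.phi1, state.phi2)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            ls.init_phis((32, 32), radius=16, spacing=20)


class TestHeaviside:
    def test_half_at_zero(self):
        assert ls.heaviside_eps(0.0, 1.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("z", [-7.3, -1.0, 0.4, 12.0])
    def test_odd_symmetry(self, z):
        assert ls.heaviside_eps(z, 1.5) + ls.heaviside_eps(-z, 1.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("z", [-3.0, 0.0, 2.0])
    def test_delta_is_derivative(self, z):
        h = 1e-6
        num = (ls.heaviside_eps(z + h, 1.5) - ls.heaviside_eps(z - h, 1.5)) / (2 * h)
        assert num == pytest.approx(ls.delta_eps(z, 1.5), abs=1e-6)


class TestEnergy:
    @staticmethod
    def _flat_maps(shape, pval=1.0, dval=0.0):
        pm = {r: np.full(shape, pval) for r in ps.REGION_NAMES}
        dm = {r: np.full(shape, dval) for r in ps.REGION_NAMES}
        return pm, dm

    def test_all_terms_off_gives_zero(self):
        pm, dm = self._flat_maps((4, 4), pval=0.37, dval=5.0)
        params = ls.LevelSetParams(eta1=0, eta2=0, alpha1=0, alpha2=0, beta1=0, beta2=0)
        state = ls.init_phis((4, 4), radius=1, spacing=3)
        e, _ = ls.energy_total(state, pm, dm, params)
        assert e == 0.0

    def test_unit_probabilities_zero_probability_energy(self):
        pm, dm = self._flat_maps((2, 2), pval=1.0, dval=3.0)
        state = ls.LevelSetState(np.array([[1.0, -1], [2, -2]]), np.array([[1.0, 1], [-1, -1]]))
        _, terms = ls.energy_total(state, pm, dm, ls.LevelSetParams())
        assert terms["E_p"] == pytest.approx(0.0)

    def test_matches_brute_force_sum(self, rng):
        """Hand-summed per-pixel energy on a 4x4 field equals the module's."""
        shape = (4, 4)
        pm = {r: rng.uniform(0.1, 1.0, size=shape) for r in ps.REGION_NAMES}
        dm = {r: rng.uniform(0.0, 9.0, size=shape) for r in ps.REGION_NAMES}
        phi1 = rng.normal(size=shape)
        phi2 = rng.normal(size=shape)
        params = ls.LevelSetParams(eta1=1.3, eta2=0.7, alpha1=0.2, alpha2=0.1)
        state = ls.LevelSetState(phi1, phi2)

        eps = params.eps
        brute = 0.0
        for i in range(4):
            for j in range(4):
                h1 = 0.5 * (1 + (2 / np.pi) * np.arctan(phi1[i, j] / eps))
                h2 = 0.5 * (1 + (2 / np.pi) * np.arctan(phi2[i, j] / eps))
                mem = {
                    "nucleus": h1 * h2,
                    "cytoplasm": h1 * (1 - h2),
                    "background": (1 - h1) * h2,
                    "unstained": (1 - h1) * (1 - h2),
                }
                for r in ps.REGION_NAMES:
                    brute += params.eta1 * (-np.log(pm[r][i, j])) * mem[r]
                    brute += params.eta2 * dm[r][i, j] * mem[r]
                brute += params.alpha1 * h1 + params.alpha2 * h2
        # length terms need the discrete gradient; compute them with numpy
        h1f = 0.5 * (1 + (2 / np.pi) * np.arctan(phi1 / eps))
        h2f = 0.5 * (1 + (2 / np.pi) * np.arctan(phi2 / eps))
        for hf, beta in ((h1f, params.beta1), (h2f, params.beta2)):
            gy, gx = np.gradient(hf)
            brute += beta * np.sum(np.hypot(gy, gx))

        e, _ = ls.energy_total(state, pm, dm, params)
        assert e == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        pm, dm = self._flat_maps((4, 4))
        state = ls.init_phis((6, 6), radius=1, spacing=3)
        with pytest.raises(ValueError):
            ls.energy_total(state, pm, dm, ls.LevelSetParams())


class TestReinitialize:
    @staticmethod
    def _circle_sdf(shape, center, radius):
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return radius - np.hypot(rr - center[0], cc - center[1])

    def test_circle_sdf_is_fixed_point(self):
        phi = self._circle_sdf((64, 64), (32, 32), 15)
        out = ls.reinitialize(phi)
        assert np.max(np.abs(out - phi)) <= 1.0

    def test_scaled_field_renormalized(self):
        phi = self._circle_sdf((64, 64), (32, 32), 15)
        out = ls.reinitialize(3.0 * phi)
        assert np.array_equal(out > 0, phi > 0)      # zero set preserved
        assert np.max(np.abs(out - phi)) <= 1.0      # gradient renormalized

    def test_single_sign_unchanged(self):
        phi = np.ones((8, 8))
        assert np.array_equal(ls.reinitialize(phi), phi)

    def test_idempotent_within_one_pixel(self):
        phi = self._circle_sdf((48, 48), (20, 25), 10) * 2.7
        once = ls.reinitialize(phi)
        twice = ls.reinitialize(once)
        assert np.max(np.abs(twice - once)) <= 1.0

    def test_gradient_near_unit_away_from_interface(self):
        phi = ls.reinitialize(self._circle_sdf((96, 96), (48, 48), 30) * 5)
        gy, gx = np.gradient(phi)
        mag = np.hypot(gy, gx)
        far = np.abs(phi) > 2
        frac = np.mean((mag[far] > 0.8) & (mag[far] < 1.2))
        assert frac >= 0.95


class TestEvolve:
    def test_single_optimal_phase_wins_everywhere(self):
        shape = (64, 64)
        good = np.full(shape, 0.3)
        bad = np.full(shape, 1e-6)
        pm = {"nucleus": good, "cytoplasm": bad, "background": bad, "unstained": bad}
        dm = {
            "nucleus": np.zeros(shape),
            "cytoplasm": np.full(shape, 100.0),
            "background": np.full(shape, 100.0),
            "unstained": np.full(shape, 100.0),
        }
        state = ls.init_phis(shape, radius=5, spacing=15)
        state = ls.evolve(state, pm, dm, ls.LevelSetParams(n_iter=500, tol=0.0))
        assert np.mean((state.phi1 > 0) & (state.phi2 > 0)) >= 0.99

    def test_energy_descends_between_reinits(self, scene_maps):
        pmaps, dimgs = scene_maps
        params = ls.LevelSetParams(n_iter=200, tol=0.0, reinit_every=20)
        state = ls.init_phis(pmaps["nucleus"].shape, radius=5, spacing=15)
        state = ls.evolve(state, pmaps, dimgs, params)
        E = [row["E"] for row in state.energy_log]
        for k in range(1, len(E)):
            if k % params.reinit_every == 0:
                continue  # re-initialization may bump the energy
            assert E[k] <= E[k - 1] + 0.01 * abs(E[k - 1])

    def test_huge_length_penalty_shrinks_interface(self, rng):
        shape = (48, 48)
        pm = {r: np.full(shape, 0.5) for r in ps.REGION_NAMES}
        dm = {r: rng.uniform(0, 1, size=shape) for r in ps.REGION_NAMES}
        params = ls.LevelSetParams(beta1=1e4, beta2=1e4, n_iter=120, tol=0.0)
        state0 = ls.init_phis(shape, radius=5, spacing=12)

        def interface_len(phi):
            h = ls.heaviside_eps(phi, params.eps)
            gy, gx = np.gradient(h)
            return np.sum(np.hypot(gy, gx))

        state = ls.evolve(state0, pm, dm, params)
        assert interface_len(state.phi1) <= interface_len(state0.phi1)

    def test_deterministic(self, scene_maps):
        pmaps, dimgs = scene_maps
        params = ls.LevelSetParams(n_iter=30, tol=0.0)
        a = ls.evolve(ls.init_phis((128, 128), 5, 15), pmaps, dimgs, params)
        b = ls.evolve(ls.init_phis((128, 128), 5, 15), pmaps, dimgs, params)
        assert np.array_equal(a.phi1, b.phi1) and np.array_equal(a.phi2, b.phi2)

    def test_nan_maps_rejected(self):
        shape = (8, 8)
        pm = {r: np.full(shape, 0.5) for r in ps.REGION_NAMES}
        dm = {r: np.zeros(shape) for r in ps.REGION_NAMES}
        dm["cytoplasm"][0, 0] = np.nan
        with pytest.raises(RuntimeError, match="cytoplasm"):
            ls.evolve(ls.init_phis(shape, 2, 5), pm, dm, ls.LevelSetParams(n_iter=5))


class TestPhaseMask:
    def test_uniform_signs(self):
        state = ls.LevelSetState(np.ones((4, 4)), -np.ones((4, 4)))
        mask = ls.extract_phase_mask(state)
        assert np.all(mask == ls.PHASE_CYTOPLASM)

    def test_quadrant_mapping(self):
        phi1 = np.block([[np.ones((2, 2)), np.ones((2, 2))],
                         [-np.ones((2, 2)), -np.ones((2, 2))]])
        phi2 = np.block([[np.ones((2, 2)), -np.ones((2, 2))],
                         [np.ones((2, 2)), -np.ones((2, 2))]])
        mask = ls.extract_phase_mask(ls.LevelSetState(phi1, phi2))
        assert np.all(mask[:2, :2] == ls.PHASE_NUCLEUS)
        assert np.all(mask[:2, 2:] == ls.PHASE_CYTOPLASM)
        assert np.all(mask[2:, :2] == ls.PHASE_BACKGROUND)
        assert np.all(mask[2:, 2:] == ls.PHASE_UNSTAINED)

    def test_labels_partition_image(self, rng):
        state = ls.LevelSetState(rng.normal(size=(16, 16)), rng.normal(size=(16, 16)))
        mask = ls.extract_phase_mask(state)
        assert np.isin(mask, [0, 1, 2, 3]).all()
        stained = ls.stained_mask_from_phases(mask)
        assert np.array_equal(stained, state.phi1 > 0)


class TestPostfilter:
    def test_small_component_removed(self):
        mask = np.zeros((32, 32), bool)
        mask[2:4, 2:7] = True  # 10 px
        out = ls.postfilter_components(mask, np.zeros_like(mask), min_component_px=50)
        assert not out.any()

    def test_scant_cytoplasm_component_removed(self):
        mask = np.zeros((40, 40), bool)
        mask[5:30, 5:25] = True            # 500 px component
        nuc = np.zeros_like(mask)
        nuc[5:30, 5:25] = True
        nuc[5, 5:15] = False               # leave 10 px of cytoplasm
        out = ls.postfilter_components(mask, nuc, min_component_px=0, min_cytoplasm_px=100)
        assert not out.any()

    def test_zero_thresholds_keep_everything(self, rng):
        mask = rng.uniform(size=(24, 24)) > 0.6
        out = ls.postfilter_components(mask, np.zeros_like(mask), 0, 0)
        assert np.array_equal(out, mask)
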