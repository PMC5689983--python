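import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomovsm.beam_model import (BeamModel, ConeProfile, FocalSpot, JawProfile,
                                build_open_field_fluence,
                                build_projection_fluence,
                                leaf_filtered_profile, lot_coefficients,
                                sample_particles)
from tomovsm.spectrum import EnergySpectrum
from tomovsm.synth import make_picket_fence_plan

from conftest import centered_pulse_oracle

frac = st.floats(min_value=0.0, max_value=1.0)


class TestLotCoefficients:
    @pytest.mark.parametrize("triple,expected", [
        ((0.0, 1.0, 0.0), (0.0, 1.0, 0.0, 0.0)),   # lone open leaf: all close-close
        ((0.3, 0.8, 0.5), (0.3, 0.3, 0.2, 0.0)),
        ((0.9, 0.5, 0.2), (0.2, 0.0, 0.0, 0.3)),   # a2 clamped at zero
    ])
    def test_examples(self, triple, expected):
        assert tuple(lot_coefficients(*triple)) == pytest.approx(expected)

    def test_examples_match_pulse_oracle(self):
        for triple in [(0.0, 1.0, 0.0), (0.3, 0.8, 0.5), (0.9, 0.5, 0.2)]:
            oracle = centered_pulse_oracle(*triple, n_steps=100_000)
            closed = np.array(list(lot_coefficients(*triple)))
            assert np.abs(oracle - closed).max() < 2.0 / 100_000

    @given(frac, frac, frac)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conservation_and_nonnegativity(self, sp, si, sn):
        a = list(lot_coefficients(sp, si, sn))
        assert all(v >= 0 for v in a)
        assert sum(a) == pytest.approx(si, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lot_coefficients(0.5, 1.2, 0.5)


class TestLeafFilteredProfile:
    def test_all_open_is_unity_inside_field(self, model):
        f = model.filters
        x = f.x_tangent  # stored nodes: no interpolation of sharp edges
        inside = (x >= f.leaf_edges_tangent[0]) & (x < f.leaf_edges_tangent[-1])
        lf = leaf_filtered_profile(np.ones(64), f, x)
        assert np.allclose(lf[inside], 1.0, atol=1e-12)
        assert np.all(lf[~inside] == 0.0)

    def test_all_closed_is_zero(self, model):
        x = model.cone.x_tangent
        assert np.all(leaf_filtered_profile(np.zeros(64), model.filters, x) == 0)

    def test_single_open_leaf_uses_close_close_filter(self, model):
        """One open leaf with closed neighbours transmits its f_cc profile."""
        f = model.filters
        row = np.zeros(64)
        row[20] = 1.0
        lf = leaf_filtered_profile(row, f, f.x_tangent)
        assert np.allclose(lf, f.f_cc[20], atol=1e-12)

    def test_wrong_row_length_rejected(self, model):
        with pytest.raises(ValueError):
            leaf_filtered_profile(np.ones(63), model.filters,
                                  model.cone.x_tangent)

    def test_nonnegative_for_random_rows(self, model):
        rng = np.random.default_rng(3)
        for _ in range(5):
            row = rng.random(64)
            lf = leaf_filtered_profile(row, model.filters,
                                       model.cone.x_tangent)
            assert np.all(lf >= 0)


class TestFluenceMaps:
    def test_identity_profiles_give_unity_map(self):
        x = np.linspace(-0.1, 0.1, 21)
        y = np.linspace(-0.05, 0.05, 11)
        cone = ConeProfile(x, np.ones_like(x))
        jaw = JawProfile(2.5, x, y, np.ones((21, 11)))
        fmap = build_open_field_fluence(cone, jaw)
        assert np.allclose(fmap.value, 1.0)

    def test_triangular_cone_product(self):
        x = np.linspace(-0.3, 0.3, 601)
        cone = ConeProfile(x, np.clip(1 - np.abs(x) / 0.3, 0, None))
        y = np.linspace(-0.05, 0.05, 11)
        jaw = JawProfile(2.5, x, y, np.ones((x.size, y.size)))
        fmap = build_open_field_fluence(cone, jaw)
        ix = np.argmin(np.abs(x - 0.15))
        assert fmap.value[ix, 5] == pytest.approx(0.5, abs=1e-9)

    def test_all_open_equals_open_field_elementwise(self, model):
        of = build_open_field_fluence(model.cone, model.jaw(5.0))
        pf = build_projection_fluence(np.ones(64), model.filters,
                                      model.cone, model.jaw(5.0))
        assert np.array_equal(of.value, pf.value)

    def test_all_closed_gives_zero_map(self, model):
        pf = build_projection_fluence(np.zeros(64), model.filters,
                                      model.cone, model.jaw(2.5))
        assert pf.total == 0.0

    def test_picket_fence_stripes_alternate(self, model):
        """The picket row yields alternating high/low stripes with a period
        of two leaf pitches over each strictly alternating block."""
        row = make_picket_fence_plan().projections[0].lot
        pf = build_projection_fluence(row, model.filters, model.cone,
                                      model.jaw(2.5))
        iy = np.argmin(np.abs(pf.y_tangent))
        prof = pf.value[:, iy]
        edges = model.filters.leaf_edges_tangent
        centers = 0.5 * (edges[:-1] + edges[1:])
        means = np.array([
            prof[(pf.x_tangent >= edges[i]) & (pf.x_tangent < edges[i + 1])].mean()
            for i in range(64)])
        cone_at = model.cone(centers)
        rel = means / cone_at
        open_mask = row > 0
        assert rel[open_mask].min() > 2 * rel[~open_mask].max()

    def test_zero_outside_jaw_support(self, model):
        """Fluence vanishes outside the jaw-limited field support."""
        jaw = model.jaw(1.0)
        fmap = build_open_field_fluence(model.cone, jaw)
        # far beyond the penumbra the profile is numerically zero
        far_y = np.abs(fmap.y_tangent) > 1.0 / 85.0 / 2 + 5 * 0.0018
        assert np.all(fmap.value[:, far_y] < 1e-6)
        # off the stored grid the jaw evaluates to exactly zero
        assert np.all(jaw(0.0, jaw.y_tangent.max() + 0.01) == 0.0)
        assert np.all(fmap.value >= 0.0)


class TestParticleSampling:
    def _uniform_map(self, n=41):
        from tomovsm.beam_model import FluenceMap
        x = np.linspace(-0.1, 0.1, n)
        y = np.linspace(-0.02, 0.02, 9)
        return FluenceMap(x, y, np.ones((n, 9)))

    def test_point_source_single_cell_is_axial(self):
        from tomovsm.beam_model import FluenceMap
        fmap = FluenceMap(np.array([0.0]), np.array([0.0]),
                          np.array([[1.0]]))
        spot = FocalSpot(0.0, 0.0, 1.0)
        rng = np.random.default_rng(0)
        [p] = sample_particles(fmap, spot, EnergySpectrum(), 85.0, 30.0, rng, 1)
        # cell has zero nominal width, so jitter stays tiny
        assert abs(p.direction[0]) < 1e-6 and abs(p.direction[1]) < 1e-6
        assert p.direction[2] == pytest.approx(-1.0, abs=1e-9)

    def test_uniform_map_marginals(self):
        """Sampled (x, y) cell occupancies of a uniform map are uniform
        within 3-sigma binomial fluctuations."""
        fmap = self._uniform_map()
        rng = np.random.default_rng(5)
        states = sample_particles(fmap, FocalSpot(0, 0, 1), EnergySpectrum(),
                                  85.0, 30.0, rng, 50_000)
        xt = np.array([s.position[0] / 30.0 for s in states])
        nx = fmap.x_tangent.size
        edges = np.linspace(xt.min() - 1e-9, xt.max() + 1e-9, nx + 1)
        counts, _ = np.histogram(xt, edges)
        n = len(states)
        p = 1.0 / nx
        sigma = np.sqrt(n * p * (1 - p))
        assert np.abs(counts - n * p).max() <= 3.5 * sigma

    def test_penumbra_grows_with_focal_spot(self):
        """The fluence penumbra at isocenter widens monotonically with the
        primary Gaussian width of the focal spot."""
        from tomovsm.beam_model import FluenceMap
        x = np.linspace(-0.02, 0.02, 41)
        y = np.array([0.0])
        fmap = FluenceMap(x, y, np.where(np.abs(x) <= 0.01, 1.0, 0.0)[:, None])
        spreads = []
        for sigma1 in (0.0, 2.0, 6.0):
            rng = np.random.default_rng(42)
            states = sample_particles(fmap, FocalSpot(sigma1, sigma1, 1.0),
                                      EnergySpectrum(), 85.0, 30.0, rng, 8000)
            # project to the isocenter plane (z = 0)
            xs = []
            for s in states:
                t = s.position[2] / -s.direction[2]
                xs.append(s.position[0] + t * s.direction[0])
            xs = np.array(xs)
            spreads.append(np.percentile(np.abs(xs), 95))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_empty_map_rejected(self):
        from tomovsm.beam_model import FluenceMap
        fmap = FluenceMap(np.array([0.0]), np.array([0.0]), np.array([[0.0]]))
        with pytest.raises(ValueError):
            sample_particles(fmap, FocalSpot(), EnergySpectrum(), 85.0, 30.0,
                             np.random.default_rng(0), 1)


class TestBeamModelIO:
    def test_round_trip(self, model, tmp_path):
        model.save(tmp_path / "model")
        back = BeamModel.load(tmp_path / "model")
        assert np.allclose(back.cone.value, model.cone.value)
        assert sorted(back.jaws) == sorted(model.jaws)
        assert np.allclose(back.jaws[2.5].value, model.jaws[2.5].value)
        assert np.allclose(back.filters.f_cc, model.filters.f_cc)
        assert back.spectrum.e_max == pytest.approx(model.spectrum.e_max)
        assert back.focal_spot == model.focal_spot

    def test_missing_jaw_label(self, model):
        with pytest.raises(KeyError):
            model.jaw(3.0)
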