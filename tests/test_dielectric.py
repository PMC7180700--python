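import cmath
import math

import numpy as np
import pytest

from hnphantom import (CLNSpec, ColeColeParams, ConfigError, DebyeParams,
                       DielectricRegistry, VoxelVolume, build_bounds,
                       debye_to_cole_cole, evaluate_cole_cole,
                       map_intensity_to_properties, mixed_tissue_bounds)
from hnphantom import labels as L
from hnphantom.dielectric import CLN_CURVE_FOR_LABEL, EPS0, check_frequency

GHZ = 1e9
FREQ_GRID = np.arange(1.0, 10.05, 0.1) * GHZ  # 1-10 GHz, 0.1 GHz step


@pytest.fixture(scope="module")
def registry():
    return DielectricRegistry.default()


def oracle_cole_cole(params, f):
    """Independent evaluation using scalar cmath arithmetic and the
    log/exp definition of the fractional power."""
    w = 2.0 * math.pi * f
    eps = complex(params.eps_inf, 0.0)
    for de, tau, alpha in params.poles:
        if de > 0:
            denom = 1.0 + cmath.exp((1.0 - alpha) * cmath.log(1j * w * tau))
            eps += de / denom
    if params.sigma_s > 0:
        eps += params.sigma_s / (1j * w * EPS0)
    return eps.real, -w * EPS0 * eps.imag


class TestEvaluateColeCole:
    def test_matches_independent_oracle_on_all_registry_tissues(self, registry):
        freqs = np.linspace(1.0, 10.0, 20) * GHZ
        checked = 0
        for name, model in registry.models.items():
            if not hasattr(model, "nominal"):
                continue  # the composite mixed model has no single spectrum
            for f in freqs:
                eps, sig = evaluate_cole_cole(model.nominal, f)
                eps_o, sig_o = oracle_cole_cole(model.nominal, f)
                assert eps == pytest.approx(eps_o, rel=1e-10)
                assert sig == pytest.approx(sig_o, rel=1e-10)
                checked += 1
        assert checked >= 8 * 20  # 4 tissues + 4 node curves, 20 frequencies

    def test_dispersion_free_limit(self):
        params = ColeColeParams(eps_inf=5.0, poles=((0, 1, 0),) * 4, sigma_s=0.0)
        for f in (1 * GHZ, 5 * GHZ, 10 * GHZ):
            eps, sig = evaluate_cole_cole(params, f)
            assert eps == pytest.approx(5.0)
            assert sig == pytest.approx(0.0, abs=1e-15)

    def test_debye_static_limit(self):
        params = debye_to_cole_cole(DebyeParams(eps_inf=4.0, delta_eps=30.0,
                                                tau=10e-12, sigma_s=0.5))
        eps, sig = evaluate_cole_cole(params, 1.0)  # f -> 0 limit
        assert eps == pytest.approx(34.0, rel=1e-9)
        assert sig == pytest.approx(0.5, rel=1e-9)

    def test_positive_finite_over_band(self, registry):
        for name in ("skin", "bone", "fat", "muscle"):
            eps, sig = evaluate_cole_cole(registry.model(name).nominal, FREQ_GRID)
            assert np.isfinite(eps).all() and np.isfinite(sig).all()
            assert (eps > 0).all() and (sig >= 0).all()

    def test_nonpositive_frequency_rejected(self, registry):
        with pytest.raises(ConfigError):
            evaluate_cole_cole(registry.model("fat").nominal, 0.0)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ConfigError):
            ColeColeParams(eps_inf=0.5, poles=((0, 1, 0),) * 4, sigma_s=0)
        with pytest.raises(ConfigError):
            ColeColeParams(eps_inf=2, poles=((1, -1e-12, 0),) + ((0, 1, 0),) * 3, sigma_s=0)
        with pytest.raises(ConfigError):
            ColeColeParams(eps_inf=2, poles=((1, 1e-12, 1.0),) + ((0, 1, 0),) * 3, sigma_s=0)


class TestDebyeEmbedding:
    @pytest.mark.parametrize("f", [1 * GHZ, 5 * GHZ, 10 * GHZ])
    def test_equals_closed_form_debye(self, f):
        """The Debye curve embedded as pole 1 of the 4-pole model reproduces
        the closed-form Debye expression to machine precision."""
        d = DebyeParams(eps_inf=6.0, delta_eps=48.0, tau=10e-12, sigma_s=0.6)
        eps, sig = evaluate_cole_cole(debye_to_cole_cole(d), f)
        w = 2 * math.pi * f
        closed = d.eps_inf + d.delta_eps / (1 + 1j * w * d.tau) + d.sigma_s / (1j * w * EPS0)
        assert eps == pytest.approx(closed.real, rel=1e-14)
        assert sig == pytest.approx(-w * EPS0 * closed.imag, rel=1e-14)

    def test_null_pole_gives_flat_spectrum(self):
        d = DebyeParams(eps_inf=3.0, delta_eps=0.0, tau=1e-12, sigma_s=0.2)
        eps1, sig1 = evaluate_cole_cole(debye_to_cole_cole(d), 1 * GHZ)
        eps2, sig2 = evaluate_cole_cole(debye_to_cole_cole(d), 10 * GHZ)
        assert eps1 == pytest.approx(3.0) and eps2 == pytest.approx(3.0)
        assert sig1 == pytest.approx(0.2) and sig2 == pytest.approx(0.2)

    def test_four_distinct_node_curves_registered(self, registry):
        curves = registry.cln_curves()
        assert len(curves) == 4
        spectra = {name: evaluate_cole_cole(m.nominal, 3 * GHZ)
                   for name, m in curves.items()}
        assert len({tuple(np.round(v, 9)) for v in spectra.values()}) == 4


class TestBounds:
    def test_five_percent_ratio_exact(self, registry):
        for name in ("fat", "muscle", "bone"):
            model = registry.model(name)
            for f in np.linspace(1, 10, 10) * GHZ:
                eps, sig = model.nominal_at(f)
                (elo, slo), (ehi, shi) = model.bounds_at(f)
                assert ehi / eps == pytest.approx(1.05, rel=1e-12)
                assert shi / sig == pytest.approx(1.05, rel=1e-12)
                assert elo / eps == pytest.approx(0.95, rel=1e-12)
                assert slo / sig == pytest.approx(0.95, rel=1e-12)

    def test_zero_fraction_degenerates_to_nominal(self, registry):
        nominal = registry.model("fat").nominal
        lower, upper = build_bounds(nominal, 3 * GHZ, fraction=0.0)
        assert lower == upper == evaluate_cole_cole(nominal, 3 * GHZ)

    def test_skin_has_no_bounds(self, registry):
        skin = registry.model("skin")
        assert not skin.has_bounds
        lo, hi = skin.bounds_at(5 * GHZ)
        assert lo == hi == skin.nominal_at(5 * GHZ)

    def test_ordering_lower_nominal_upper_over_band(self, registry):
        for name in ("bone", "fat", "muscle"):
            model = registry.model(name)
            eps, sig = model.nominal_at(FREQ_GRID)
            (elo, slo), (ehi, shi) = model.bounds_at(FREQ_GRID)
            assert (elo <= eps).all() and (eps <= ehi).all()
            assert (slo <= sig).all() and (sig <= shi).all()
            assert (elo >= 1 * 0.95).all() and (slo >= 0).all()


class TestMixedTissue:
    def test_composite_of_muscle_upper_and_fat_lower(self, registry):
        mixed = registry.model("mixed")
        for f in (1 * GHZ, 3.7 * GHZ, 10 * GHZ):
            (elo, slo), (ehi, shi) = mixed.bounds_at(f)
            meps, msig = registry.model("muscle").nominal_at(f)
            feps, fsig = registry.model("fat").nominal_at(f)
            assert ehi == pytest.approx(1.05 * meps, rel=1e-12)
            assert shi == pytest.approx(1.05 * msig, rel=1e-12)
            assert elo == pytest.approx(0.95 * feps, rel=1e-12)
            assert slo == pytest.approx(0.95 * fsig, rel=1e-12)

    def test_bounds_ordered_across_band(self, registry):
        mixed = mixed_tissue_bounds(registry.model("muscle"), registry.model("fat"))
        (elo, slo), (ehi, shi) = mixed.bounds_at(FREQ_GRID)
        assert (elo < ehi).all() and (slo < shi).all()

    def test_requires_bounded_inputs(self, registry):
        with pytest.raises(ConfigError):
            mixed_tissue_bounds(registry.model("skin"), registry.model("fat"))


class TestFrequencyGate:
    def test_band_is_inclusive(self):
        assert check_frequency(1 * GHZ) == 1 * GHZ
        assert check_frequency(10 * GHZ) == 10 * GHZ

    @pytest.mark.parametrize("f", [0.9 * GHZ, 10.001 * GHZ, 100 * GHZ])
    def test_out_of_band_rejected(self, f):
        with pytest.raises(ConfigError, match="GHz"):
            check_frequency(f)


def loop_oracle(intensity, labels, registry, f):
    """Naive per-voxel reimplementation of the intensity mapping."""
    stats = {}
    for tissue, code in L.SEGMENTED_TISSUES.items():
        sel = labels == code
        if sel.any():
            stats[code] = (tissue, float(intensity[sel].min()), float(intensity[sel].max()))
    eps = np.ones(labels.shape)
    sig = np.zeros(labels.shape)
    skin_val = registry.model("skin").nominal_at(f)
    cln_vals = {code: registry.model(curve).nominal_at(f)
                for code, curve in CLN_CURVE_FOR_LABEL.items()}
    for idx in np.ndindex(labels.shape):
        code = int(labels[idx])
        if code == L.BACKGROUND:
            continue
        if code == L.SKIN:
            eps[idx], sig[idx] = skin_val
        elif code in cln_vals:
            eps[idx], sig[idx] = cln_vals[code]
        else:
            tissue, imin, imax = stats[code]
            (elo, slo), (ehi, shi) = registry.model(tissue).bounds_at(f)
            t = 0.5 if imax == imin else (intensity[idx] - imin) / (imax - imin)
            eps[idx] = elo + t * (ehi - elo)
            sig[idx] = slo + t * (shi - slo)
    return eps, sig


@pytest.fixture(scope="module")
def phantom(small_neck):
    from hnphantom import compute_level_boundaries, place_clns
    from hnphantom.synthetic_anatomy import apply_skin

    vol, truth, mask = small_neck
    labels = apply_skin(truth.with_data(truth.data.copy()), mask)
    levels = compute_level_boundaries(mask)
    labels = place_clns(labels, mask, [CLNSpec(3.0, "II"),
                                       CLNSpec(3.0, "V", state="metastasized")],
                        levels, seed=9).labels
    return vol, labels


class TestIntensityMapping:
    def test_matches_per_voxel_loop_oracle(self, phantom, registry):
        vol, labels = phantom
        f = 3 * GHZ
        eps, sig = map_intensity_to_properties(vol, labels, registry, f)
        eps_o, sig_o = loop_oracle(vol.data, labels.data, registry, f)
        np.testing.assert_allclose(eps.data, eps_o, rtol=1e-12, atol=0)
        np.testing.assert_allclose(sig.data, sig_o, rtol=1e-12, atol=0)

    def test_extreme_intensities_hit_the_bound_curves(self, phantom, registry):
        vol, labels = phantom
        f = 5 * GHZ
        eps, sig = map_intensity_to_properties(vol, labels, registry, f)
        sel = labels.data == L.MUSCLE
        vals = vol.data[sel]
        (elo, slo), (ehi, shi) = registry.model("muscle").bounds_at(f)
        assert eps.data[sel][np.argmax(vals)] == pytest.approx(ehi, rel=1e-12)
        assert eps.data[sel][np.argmin(vals)] == pytest.approx(elo, rel=1e-12)
        assert sig.data[sel][np.argmax(vals)] == pytest.approx(shi, rel=1e-12)

    def test_midpoint_intensity_maps_to_mean_of_bounds(self, registry):
        labels = np.full((3, 1, 1), L.FAT, dtype=np.int16)
        inten = np.array([0.2, 0.5, 0.8]).reshape(3, 1, 1)
        eps, sig = map_intensity_to_properties(
            VoxelVolume(inten, (1, 1, 1)), VoxelVolume(labels, (1, 1, 1), role="label"),
            registry, 3 * GHZ)
        (elo, slo), (ehi, shi) = registry.model("fat").bounds_at(3 * GHZ)
        assert eps.data[1, 0, 0] == pytest.approx((elo + ehi) / 2, rel=1e-12)
        assert sig.data[1, 0, 0] == pytest.approx((slo + shi) / 2, rel=1e-12)

    def test_monotone_within_tissue(self, phantom, registry):
        vol, labels = phantom
        eps, _ = map_intensity_to_properties(vol, labels, registry, 3 * GHZ)
        for code in (L.FAT, L.MUSCLE, L.MIXED):
            sel = labels.data == code
            order = np.argsort(vol.data[sel])
            mapped = eps.data[sel][order]
            assert (np.diff(mapped) >= -1e-12).all()

    def test_degenerate_constant_tissue_gets_midpoint(self, registry):
        labels = np.full((2, 2, 1), L.FAT, dtype=np.int16)
        inten = np.full((2, 2, 1), 0.4)
        eps, _ = map_intensity_to_properties(
            VoxelVolume(inten, (1, 1, 1)), VoxelVolume(labels, (1, 1, 1), role="label"),
            registry, 3 * GHZ)
        (elo, _), (ehi, _) = registry.model("fat").bounds_at(3 * GHZ)
        np.testing.assert_allclose(eps.data, (elo + ehi) / 2)

    def test_background_is_free_space(self, phantom, registry):
        vol, labels = phantom
        eps, sig = map_intensity_to_properties(vol, labels, registry, 3 * GHZ)
        bg = labels.data == L.BACKGROUND
        assert (eps.data[bg] == 1.0).all() and (sig.data[bg] == 0.0).all()

    def test_out_of_band_frequency_rejected(self, phantom, registry):
        vol, labels = phantom
        with pytest.raises(ConfigError, match="GHz"):
            map_intensity_to_properties(vol, labels, registry, 11 * GHZ)


class TestCurveFamily:
    def test_stage3_family_has_seven_members(self, registry):
        family = registry.curve_family()
        assert len(family) == 7
        assert ("skin", "nominal") in family
        for tissue in ("bone", "fat", "muscle"):
            assert (tissue, "lower") in family and (tissue, "upper") in family
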