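import numpy as np
import pytest

from verdictbrain.fitting import (
    FitConfig,
    extracellular_fa,
    fa_from_eigenvalues,
    fit_adc,
    fit_noddi_voxel,
    fit_voxel,
    fit_volume,
    normalize_signal,
    _noddi_signal,
    _scheme_indices,
)
from verdictbrain.phantom import simulate_voxel_signals
from verdictbrain.scheme import select_shells
from verdictbrain.tissue_models import apply_fwe, make_model

TRUE = {
    "fic": 0.4, "fvasc": 0.1, "fees": 0.5, "ffw": 0.15, "R": 8.0,
    "d_par": 1.5e-9, "d_perp": 0.6e-9, "theta": 1.1, "phi": 0.4,
}


@pytest.fixture(scope="module")
def zas_fwe():
    return apply_fwe(
        make_model("Zeppelin", "AstroSticks", dv_mode="fixed", fwe=True), TRUE["ffw"]
    )


class TestNormalization:
    def test_t2_decay_cancels_exactly(self, protocol, weighted):
        raw = simulate_voxel_signals([TRUE], protocol, snr=np.inf, t2_ms=65.0)
        atten, wsch = normalize_signal(raw, protocol)
        pure = simulate_voxel_signals([TRUE], protocol, snr=np.inf, t2_ms=1e12, s0=1.0)
        assert np.allclose(atten[0], pure[0][protocol.weighted], atol=1e-12)
        assert np.array_equal(wsch.b, weighted.b)

    def test_missing_b0_te_is_named(self, protocol):
        keep = ~(protocol.is_b0 & (protocol.te == 78.0))
        broken = protocol.subset(np.nonzero(keep)[0])
        raw = np.ones((2, len(broken)))
        with pytest.raises(ValueError, match="78"):
            normalize_signal(raw, broken)

    def test_all_b0_gives_ones(self, protocol):
        raw = np.full((3, len(protocol)), 500.0)
        atten, _ = normalize_signal(raw, protocol)
        assert np.allclose(atten, 1.0)

    def test_noise_clip_with_sigma(self, protocol):
        raw = np.full((1, len(protocol)), 100.0)
        raw[0, 0] = 150.0  # attenuation 1.5 before clipping
        atten, _ = normalize_signal(raw, protocol, sigma=0.1)
        assert atten.max() <= 1.3 + 1e-12


class TestFitVoxel:
    def test_noise_free_self_consistency(self, protocol, weighted, zas_fwe):
        raw = simulate_voxel_signals([TRUE], protocol, snr=np.inf)
        atten, wsch = normalize_signal(raw, protocol)
        fit = fit_voxel(zas_fwe, atten[0], wsch, FitConfig(n_restarts=4, seed=1))
        assert fit.converged
        assert fit.fractions["fic"] == pytest.approx(TRUE["fic"], abs=1e-3)
        assert fit.fractions["fvasc"] == pytest.approx(TRUE["fvasc"], abs=1e-3)
        assert fit.params["R"] == pytest.approx(TRUE["R"], rel=5e-2)
        assert fit.params["ec_d_par"] == pytest.approx(TRUE["d_par"], rel=5e-2)

    def test_constant_signal_hits_boundary(self, weighted):
        m = make_model("Zeppelin", "AstroSticks", dv_mode="fixed")
        fit = fit_voxel(m, np.ones(len(weighted)), weighted,
                        FitConfig(n_restarts=3, seed=0))
        assert fit.converged
        # all-restricted (tiny radius) or zero-diffusivity boundary solution
        assert fit.rss < 1e-3

    def test_restarts_never_worsen_best_rss(self, protocol, weighted, zas_fwe):
        raw = simulate_voxel_signals([TRUE], protocol, snr=50, seed=3)
        atten, wsch = normalize_signal(raw, protocol)
        rss = [
            fit_voxel(zas_fwe, atten[0], wsch, FitConfig(n_restarts=n, seed=7)).rss
            for n in (1, 2, 4)
        ]
        assert rss[0] >= rss[1] >= rss[2]

    def test_result_reports_simplex_feasible_fractions(self, protocol, weighted, zas_fwe):
        raw = simulate_voxel_signals([TRUE], protocol, snr=20, seed=5)
        atten, wsch = normalize_signal(raw, protocol)
        fit = fit_voxel(zas_fwe, atten[0], wsch, FitConfig(n_restarts=2, seed=2))
        s = fit.fractions["fic"] + fit.fractions["fvasc"] + fit.fractions["fees"]
        assert s == pytest.approx(1.0, abs=1e-6)
        assert all(v >= -1e-9 for v in fit.fractions.values())


class TestFitVolume:
    def test_single_voxel_mask_and_determinism(self, protocol, zas_fwe):
        raw4d = simulate_voxel_signals([TRUE] * 4, protocol, snr=50, seed=2).reshape(
            2, 2, 1, -1
        )
        atten, wsch = normalize_signal(raw4d, protocol)
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 1, 0] = True
        ffw_map = np.full(mask.shape, TRUE["ffw"])
        cfg = FitConfig(n_restarts=2, seed=11)
        maps1, res1 = fit_volume(zas_fwe, atten, mask, wsch, cfg, ffw_map=ffw_map)
        assert np.isfinite(maps1["fic"]).sum() == 1
        assert np.isnan(maps1["fic"][0, 0, 0])
        maps2, _ = fit_volume(zas_fwe, atten, mask, wsch, cfg, ffw_map=ffw_map)
        for k in maps1:
            assert np.array_equal(maps1[k], maps2[k], equal_nan=True)

    def test_mask_shape_mismatch(self, protocol, zas_fwe):
        raw4d = np.ones((2, 2, 1, len(protocol)))
        atten, wsch = normalize_signal(raw4d, protocol)
        with pytest.raises(ValueError):
            fit_volume(zas_fwe, atten, np.ones((3, 2, 1), bool), wsch)


class TestAdc:
    def test_isotropic_exact(self, protocol):
        adc_true = 1.0e-3  # mm²/s
        raw = np.exp(-protocol.b * adc_true)[None, :] * 1000.0
        adc = fit_adc(raw, protocol)
        assert adc[0] == pytest.approx(adc_true, rel=1e-12)

    def test_missing_shell_raises(self, protocol):
        sub = select_shells(protocol, "noddi_shells")
        raw = np.ones((1, len(sub)))
        with pytest.raises(ValueError):
            fit_adc(raw, sub)

    def test_anisotropic_matches_directional_average(self, protocol):
        raw = simulate_voxel_signals(
            [dict(TRUE, fic=0.0, fvasc=0.0, fees=1.0, ffw=0.0)], protocol, snr=np.inf
        )
        sel = protocol.weighted & np.isclose(protocol.b, 1000.0)
        te = protocol.te[sel][0]
        s0 = raw[0, protocol.is_b0 & (protocol.te == te)].mean()
        expected = np.mean(np.log(s0 / raw[0, sel])) / 1000.0
        assert fit_adc(raw, protocol)[0] == pytest.approx(expected, rel=1e-12)


class TestNoddi:
    def test_pure_free_water(self, protocol):
        nd = select_shells(protocol, "noddi_shells")
        idx = _scheme_indices(protocol, nd)
        raw = simulate_voxel_signals(
            [dict(TRUE, fic=0.0, fvasc=0.0, fees=0.0, ffw=1.0)], protocol, snr=np.inf
        )
        atten, wsch = normalize_signal(raw[:, idx], nd)
        fiso, _, _, _ = fit_noddi_voxel(atten[0], wsch, FitConfig(n_restarts=3, seed=0))
        assert fiso == pytest.approx(1.0, abs=0.01)

    def test_zero_fiso_dispersion_recovery(self, protocol):
        nd = select_shells(protocol, "noddi_shells")
        wsch = nd.subset(np.nonzero(nd.weighted)[0])
        y = _noddi_signal([0.0, 0.6, 4.0, 1.2, 0.3], wsch, 48, 32)
        fiso, odi, _, _ = fit_noddi_voxel(y, wsch, FitConfig(n_restarts=4, seed=1))
        assert fiso < 0.05
        assert odi == pytest.approx(2 / np.pi * np.arctan(0.25), abs=0.05)


class TestFa:
    def test_limits_and_closed_form(self):
        assert fa_from_eigenvalues(1e-9, 1e-9, 1e-9) == 0.0
        assert fa_from_eigenvalues(1e-9, 0.0, 0.0) == pytest.approx(1.0)
        lam = np.array([1.7e-9, 0.3e-9, 0.3e-9])
        mean = lam.mean()
        brute = np.sqrt(1.5 * np.sum((lam - mean) ** 2) / np.sum(lam**2))
        assert fa_from_eigenvalues(*lam) == pytest.approx(brute, rel=1e-12)

    def test_extracellular_fa_requires_anisotropic_kind(self):
        maps = {"ec_d_par": np.array(1.5e-9), "ec_d_perp": np.array(0.5e-9)}
        m = make_model("Zeppelin", "Ball")
        assert extracellular_fa(m, maps) > 0.5
        with pytest.raises(ValueError):
            extracellular_fa(make_model("Stick", "Ball"), maps)
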