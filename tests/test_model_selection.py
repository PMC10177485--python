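import numpy as np
import pytest

from verdictbrain.fitting import FitConfig, FitResult, normalize_signal, _scheme_indices
from verdictbrain.model_selection import (
    CascadeConfig,
    compute_aicc,
    degeneracy_metric,
    run_cascade,
    stage1_high_b,
    stage2_full_signal,
    stage3_fa_odi,
)
from verdictbrain.phantom import make_phantom, simulate_signal, simulate_voxel_signals
from verdictbrain.scheme import build_reference_protocol, select_shells
from verdictbrain.tissue_models import make_model


class TestAicc:
    def test_closed_form(self):
        assert compute_aicc(1.0, 100, 5) == pytest.approx(-449.879, abs=5e-4)

    def test_penalty_monotone_on_tied_rss(self):
        assert compute_aicc(0.5, 131, 8) > compute_aicc(0.5, 131, 7)

    def test_degenerate_sample_size(self):
        with pytest.raises(ValueError):
            compute_aicc(1.0, 6, 5)
        with pytest.raises(ValueError):
            compute_aicc(0.0, 100, 5)

    def test_rescaling_identity(self):
        # AICc(λ²·RSS) − AICc(RSS) = n·ln(λ²) exactly
        n, k, lam2 = 131, 7, 3.7
        delta = compute_aicc(lam2 * 0.2, n, k) - compute_aicc(0.2, n, k)
        assert delta == pytest.approx(n * np.log(lam2), rel=1e-12)

    def test_nested_models_on_noise_free_data(self):
        # when RSS ties, the smaller model never ranks worse
        assert compute_aicc(1e-12, 131, 7) < compute_aicc(1e-12 + 1e-25, 131, 9)


class TestDegeneracyMetric:
    def test_counting(self):
        fiso = np.array([0.6] * 10 + [0.2] * 5)
        fvasc = np.array([0.95] * 3 + [0.1] * 7 + [0.99] * 5)
        assert degeneracy_metric(fvasc, fiso) == pytest.approx(30.0)

    def test_empty_denominator_is_missing(self):
        assert np.isnan(degeneracy_metric(np.array([1.0]), np.array([0.1])))

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        fvasc, fiso = rng.random(50), rng.random(50)
        perm = rng.permutation(50)
        assert degeneracy_metric(fvasc, fiso) == degeneracy_metric(
            fvasc[perm], fiso[perm]
        )

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            degeneracy_metric(np.zeros(3), np.zeros(4))


@pytest.fixture(scope="module")
def high_b_voxels():
    """Two noise-free voxels generated by a Zeppelin+Sphere composition,
    restricted to the high-b stage-1 subset."""
    scheme = build_reference_protocol()
    sub = select_shells(scheme, "high_b_stage1")
    idx = _scheme_indices(scheme, sub)
    tabs = [
        {"fic": 0.4, "fvasc": 0.0, "fees": 0.6, "ffw": 0.0, "R": 8.0,
         "d_par": 1.6e-9, "d_perp": 0.6e-9, "theta": 1.0, "phi": 0.3},
        {"fic": 0.3, "fvasc": 0.0, "fees": 0.7, "ffw": 0.0, "R": 9.0,
         "d_par": 1.4e-9, "d_perp": 0.5e-9, "theta": 0.6, "phi": -0.8},
    ]
    raw = simulate_voxel_signals(tabs, scheme, snr=np.inf)
    return normalize_signal(raw[:, idx], sub)


class TestStage1:
    def test_single_candidate_survives(self, high_b_voxels):
        atten, wsch = high_b_voxels
        table, survivors = stage1_high_b(
            [make_model("Zeppelin")], atten, wsch, FitConfig(n_restarts=2, seed=0)
        )
        assert survivors == ["Zeppelin"]
        assert len(table) == 1

    def test_generating_family_beats_stick(self, high_b_voxels):
        atten, wsch = high_b_voxels
        table, survivors = stage1_high_b(
            [make_model("Zeppelin"), make_model("Stick")],
            atten, wsch, FitConfig(n_restarts=3, seed=0), keep_top_families=1,
        )
        assert table.iloc[0]["family"] == "Zeppelin"
        assert survivors == ["Zeppelin"]

    def test_empty_candidates(self, high_b_voxels):
        atten, wsch = high_b_voxels
        with pytest.raises(ValueError):
            stage1_high_b([], atten, wsch)


class TestStage2:
    def test_fwe_with_zero_ffw_matches_plain(self):
        scheme = build_reference_protocol()
        tab = {"fic": 0.45, "fvasc": 0.1, "fees": 0.45, "ffw": 0.0, "R": 8.0,
               "d_par": 1.5e-9, "d_perp": 0.7e-9, "theta": 1.0, "phi": 0.2}
        raw = simulate_voxel_signals([tab, tab], scheme, snr=50, seed=4)
        atten, wsch = normalize_signal(raw, scheme)
        candidates = [
            make_model("Zeppelin", "AstroSticks", dv_mode="fixed", fwe=False),
            make_model("Zeppelin", "AstroSticks", dv_mode="fixed", fwe=True),
        ]
        table, fits = stage2_full_signal(
            candidates, atten, wsch, np.array(["core", "core"]),
            np.zeros(2), FitConfig(n_restarts=2, seed=0),
        )
        a = table[table.fwe]["mean_aicc"].iloc[0]
        b = table[~table.fwe]["mean_aicc"].iloc[0]
        assert a == pytest.approx(b, abs=1e-6)


def _fake_fit(model, fa_like):
    """FitResult carrying only the extracellular shape parameters."""
    d_par = 1.5e-9
    # invert FA for an axially symmetric tensor to get d_perp
    # FA(d_par, d_perp): solved numerically for the test's synthetic FA
    from scipy.optimize import brentq
    from verdictbrain.fitting import fa_from_eigenvalues

    d_perp = brentq(
        lambda dp: fa_from_eigenvalues(d_par, dp, dp) - fa_like, 1e-12, d_par - 1e-15
    )
    params = {"ec_d_par": d_par, "ec_d_perp": d_perp}
    return FitResult(params=params, fractions={}, rss=1.0, n=131, k=7,
                     converged=True, n_restarts=1, best_restart=0)


class TestStage3:
    def test_perfect_linear_gives_minus_one(self):
        model = make_model("Zeppelin", "AstroSticks", dv_mode="fixed")
        odi = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        fa = 0.8 - 0.9 * odi
        fits = {model.label: [_fake_fit(model, f) for f in fa]}
        table = stage3_fa_odi(
            [model], fits, odi,
            region_labels=np.array(["core"] * 6),
            subroi_labels=np.arange(6),
        )
        assert table["r"].iloc[0] == pytest.approx(-1.0, abs=1e-6)

    def test_constant_odi_reports_missing(self):
        model = make_model("Zeppelin", "AstroSticks", dv_mode="fixed")
        fits = {model.label: [_fake_fit(model, f) for f in (0.2, 0.4, 0.6)]}
        table = stage3_fa_odi(
            [model], fits, np.full(3, 0.3),
            region_labels=np.array(["core"] * 3), subroi_labels=np.arange(3),
        )
        assert np.isnan(table["r"].iloc[0])

    def test_too_few_subrois(self):
        model = make_model("Zeppelin", "AstroSticks", dv_mode="fixed")
        fits = {model.label: [_fake_fit(model, 0.3)] * 4}
        with pytest.raises(ValueError, match="sub-ROI"):
            stage3_fa_odi(
                [model], fits, np.linspace(0.1, 0.4, 4),
                region_labels=np.array(["core"] * 4),
                subroi_labels=np.array([0, 0, 1, 1]),
            )


@pytest.fixture(scope="module")
def tiny_setup():
    scheme = build_reference_protocol()
    ph = make_phantom(seed=0)
    raw = simulate_signal(ph, scheme, snr=50, seed=5)
    masks = {"core": ph.mask("core"), "periphery": ph.mask("periphery")}
    cfg = CascadeConfig(
        extracellular_candidates=("Zeppelin",),
        vascular_candidates=("AstroSticks",),
        dv_modes=("fixed",),
        fwe_options=(True,),
        keep_top_families=1,
        n_voxels_per_region=3,
        n_voxels_stage1=3,
        n_subrois=3,
        fit=FitConfig(n_restarts=1, maxiter=80),
        noddi_fit=FitConfig(n_restarts=1, maxiter=80),
        seed=3,
    )
    return raw, scheme, masks, cfg


class TestCascade:
    def test_grid_of_one_selects_it_and_reports_all_stages(self, tiny_setup):
        raw, scheme, masks, cfg = tiny_setup
        report = run_cascade(raw, scheme, masks, cfg)
        assert report.selected == "Zeppelin–AstroSticks–Sphere with fixed dv with FWE"
        assert not report.stage1.empty
        assert not report.stage2.empty
        assert set(report.degeneracy) == {report.selected}

    def test_rerun_same_seed_is_byte_identical(self, tiny_setup):
        raw, scheme, masks, cfg = tiny_setup
        a = run_cascade(raw, scheme, masks, cfg).to_json()
        b = run_cascade(raw, scheme, masks, cfg).to_json()
        assert a == b

    def test_missing_mask_errors(self, tiny_setup):
        raw, scheme, masks, cfg = tiny_setup
        with pytest.raises(ValueError, match="periphery"):
            run_cascade(raw, scheme, {"core": masks["core"]}, cfg)
        empty = {"core": masks["core"], "periphery": np.zeros_like(masks["core"])}
        with pytest.raises(ValueError, match="periphery"):
            run_cascade(raw, scheme, empty, cfg)
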