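"""AICc-based cascade selection of the brain-tumour VERDICT model.

The cascade screens a grid of candidate tissue models in four stages:

1. *High-b extracellular screen* — two-compartment (extracellular + Sphere)
   models are fitted to high-b data only (b > 200 s/mm², excluding the four
   lowest-b shells, which are dominated by pseudo-diffusion) and ranked by
   mean AICc; only the top extracellular families survive.
2. *Full-signal comparison* — survivors gain a vascular compartment (Ball or
   AstroSticks; dv bounded or fixed) and are fitted to the full signal with
   and without free-water elimination; paired per-voxel AICc differences are
   tested with the Wilcoxon signed-rank test.
3. *Anisotropy screen* — ROI-mean extracellular FA of each model is
   correlated (Pearson) against ROI-mean NODDI ODI, the dispersion gold
   standard; for each Zeppelin/Tensor pair the stronger |r| is flagged.
4. *Degeneracy screen* — the percentage of voxels with fvasc > 0.9 among
   voxels with NODDI fiso > 0.5 (where vascularity should be negligible)
   quantifies pseudo-diffusion/free-water ambiguity.

The final rule is explicit: lowest overall mean AICc among models whose
degeneracy percentage is below a configurable threshold.

AICc uses the Gaussian least-squares form with σ profiled out and constant
terms omitted (they cancel in within-dataset comparisons):

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    FitConfig,
    FitResult,
    fit_noddi_voxel,
    fit_voxel,
    fa_from_eigenvalues,
    normalize_signal,
    _scheme_indices,
)
from .scheme import (
    PRESET_HIGH_B_STAGE1,
    PRESET_NODDI,
    AcquisitionScheme,
    select_shells,
)
from .tissue_models import TissueModel, make_model

__all__ = [
    "compute_aicc",
    "CascadeConfig",
    "SelectionReport",
    "stage1_high_b",
    "stage2_full_signal",
    "stage3_fa_odi",
    "degeneracy_metric",
    "run_cascade",
]


def compute_aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a Gaussian LS fit."""
    if rss <= 0:
        raise ValueError("RSS must be positive")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass
class CascadeConfig:
    """Candidate grid and screening rules for :func:`run_cascade`."""

    extracellular_candidates: tuple = (
        "Zeppelin", "Tensor", "Cylinder", "Stick", "WatsonSticks",
    )
    vascular_candidates: tuple = ("Ball", "AstroSticks")
    dv_modes: tuple = ("bounded", "fixed")
    fwe_options: tuple = (False, True)
    keep_top_families: int = 2
    degeneracy_threshold_pct: float = 5.0
    fvasc_cut: float = 0.9
    fiso_cut: float = 0.5
    n_voxels_per_region: int = 12
    n_voxels_stage1: int = 8
    n_subrois: int = 4
    fit: FitConfig = field(default_factory=lambda: FitConfig(n_restarts=3, maxiter=200))
    noddi_fit: FitConfig = field(
        default_factory=lambda: FitConfig(n_restarts=3, maxiter=150)
    )
    seed: int = 0


@dataclass
class SelectionReport:
    """All intermediate cascade tables plus the selected model."""

    stage1: pd.DataFrame
    stage2: pd.DataFrame
    fa_odi: pd.DataFrame
    degeneracy: dict
    selected: str
    survivors: list
    seed: int

    def to_json(self) -> str:
        doc = {
            "selected": self.selected,
            "survivors": list(self.survivors),
            "seed": int(self.seed),
            "stage1": self.stage1.to_dict(orient="records"),
            "stage2": self.stage2.to_dict(orient="records"),
            "fa_odi": self.fa_odi.to_dict(orient="records"),
            "degeneracy": {k: _jsonable(v) for k, v in self.degeneracy.items()},
        }
        return json.dumps(doc, indent=1, default=_jsonable)

    def save(self, outdir) -> None:
        """JSON report plus TSV tables (AICc by model/region; FA–ODI r)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "selection_report.json").write_text(self.to_json())
        self.stage1.to_csv(outdir / "stage1_aicc.tsv", sep="\t", index=False)
        aicc_tab = self.stage2.pivot_table(
            index="model", columns=["region", "fwe"], values="mean_aicc"
        )
        aicc_tab.to_csv(outdir / "aicc_by_model.tsv", sep="\t")
        self.fa_odi.to_csv(outdir / "fa_odi_correlations.tsv", sep="\t", index=False)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


# -- stage 1 ----------------------------------------------------------------


def stage1_high_b(
    candidates: list[TissueModel],
    attenuation: np.ndarray,
    scheme: AcquisitionScheme,
    fit_config: FitConfig | None = None,
    keep_top_families: int = 2,
):
    """Rank non-vascular candidates on high-b data by mean AICc.

    ``attenuation`` is (V, N) high-b normalized data.  Returns the ranking
    table and the surviving extracellular kinds (families of the
    ``keep_top_families`` best models).
    """
    if not candidates:
        raise ValueError("empty candidate list")
    fit_config = fit_config or FitConfig(n_restarts=3, maxiter=200)
    rows = []
    for model in candidates:
        aiccs = []
        for v in range(attenuation.shape[0]):
            cfg = _voxel_config(fit_config, v)
            fit = fit_voxel(model, attenuation[v], scheme, cfg)
            aiccs.append(compute_aicc(max(fit.rss, 1e-300), fit.n, fit.k))
        rows.append(
            {"model": model.name, "family": model.extracellular,
             "mean_aicc": float(np.mean(aiccs))}
        )
    table = pd.DataFrame(rows).sort_values("mean_aicc", ignore_index=True)
    survivors = []
    for fam in table["family"]:
        if fam not in survivors:
            survivors.append(fam)
        if len(survivors) == min(keep_top_families, len(table)):
            break
    return table, survivors


# -- stage 2 ----------------------------------------------------------------


def stage2_full_signal(
    candidates: list[TissueModel],
    attenuation: np.ndarray,
    scheme: AcquisitionScheme,
    region_labels: np.ndarray,
    ffw: np.ndarray,
    fit_config: FitConfig | None = None,
):
    """Fit full-signal candidates per voxel; mean AICc per model per region,
    with a paired Wilcoxon signed-rank test of each FWE/no-FWE pair.

    Returns (table, fits) where fits maps model label -> list of FitResult.
    """
    fit_config = fit_config or FitConfig(n_restarts=3, maxiter=200)
    regions = [str(r) for r in np.unique(region_labels)]
    for r in regions:
        if not np.any(region_labels == r):  # pragma: no cover - defensive
            raise ValueError(f"region {r!r} has no voxels")
    fits: dict[str, list[FitResult]] = {}
    voxel_aicc: dict[str, np.ndarray] = {}
    for model in candidates:
        res = []
        for v in range(attenuation.shape[0]):
            cfg = _voxel_config(fit_config, v)
            w = float(ffw[v]) if model.fwe else None
            fit = fit_voxel(model, attenuation[v], scheme, cfg, ffw=w)
            fit.aicc = compute_aicc(max(fit.rss, 1e-300), fit.n, fit.k)
            res.append(fit)
        fits[model.label] = res
        voxel_aicc[model.label] = np.array([f.aicc for f in res])
    rows = []
    for model in candidates:
        lbl = model.label
        counterpart = _fwe_counterpart(model, candidates)
        for region in regions:
            sel = region_labels == region
            mean_aicc = float(voxel_aicc[lbl][sel].mean())
            p = np.nan
            better = False
            if counterpart is not None:
                a, b = voxel_aicc[lbl][sel], voxel_aicc[counterpart.label][sel]
                diff = a - b
                if np.allclose(diff, 0.0, atol=1e-6):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(a, b).pvalue)
                better = bool(p < 0.05 and a.mean() < b.mean())
            rows.append(
                {"model": model.name, "label": lbl, "region": region,
                 "fwe": model.fwe, "dv_mode": model.dv_mode,
                 "vascular": model.vascular, "mean_aicc": mean_aicc,
                 "wilcoxon_p_vs_pair": p, "significantly_lower": better}
            )
    return pd.DataFrame(rows), fits


def _fwe_counterpart(model: TissueModel, candidates):
    for other in candidates:
        if (
            other.fwe != model.fwe
            and other.extracellular == model.extracellular
            and other.vascular == model.vascular
            and other.dv_mode == model.dv_mode
        ):
            return other
    return None


# -- stage 3 ----------------------------------------------------------------


def stage3_fa_odi(
    models: list[TissueModel],
    fits: dict,
    odi: np.ndarray,
    region_labels: np.ndarray,
    subroi_labels: np.ndarray,
):
    """Pearson r between sub-ROI-mean extracellular FA and mean NODDI ODI.

    Needs >= 3 sub-ROIs per region; a zero-variance ODI yields a missing r
    (reported as NaN), never 0.  For each Zeppelin/Tensor pair the stronger
    |r| is flagged.
    """
    rows = []
    for model in models:
        if model.extracellular not in ("Zeppelin", "Tensor"):
            continue
        res = fits[model.label]
        if model.extracellular == "Zeppelin":
            fa = np.array([
                fa_from_eigenvalues(
                    f.params["ec_d_par"], f.params["ec_d_perp"], f.params["ec_d_perp"]
                )
                for f in res
            ])
        else:
            fa = np.array([
                fa_from_eigenvalues(
                    f.params["ec_lam1"], f.params["ec_lam2"], f.params["ec_lam3"]
                )
                for f in res
            ])
        for region in np.unique(region_labels):
            sel = region_labels == region
            sub = subroi_labels[sel]
            groups = np.unique(sub)
            if len(groups) < 3:
                raise ValueError(
                    f"region {region!r}: need >=3 sub-ROI observations, got {len(groups)}"
                )
            fa_means = np.array([fa[sel][sub == g].mean() for g in groups])
            odi_means = np.array([odi[sel][sub == g].mean() for g in groups])
            if np.std(odi_means) < 1e-12 or np.std(fa_means) < 1e-12:
                r = np.nan
            else:
                r = float(stats.pearsonr(fa_means, odi_means).statistic)
            rows.append(
                {"label": model.label, "model": model.name, "region": str(region),
                 "extracellular": model.extracellular, "fwe": model.fwe,
                 "dv_mode": model.dv_mode, "vascular": model.vascular, "r": r}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["stronger_of_pair"] = False
    group_cols = ["region", "fwe", "dv_mode", "vascular"]
    for _, grp in table.groupby(group_cols):
        finite = grp.dropna(subset=["r"])
        if len(finite) >= 2:
            best = finite["r"].abs().idxmax()
            table.loc[best, "stronger_of_pair"] = True
    return table


# -- stage 4 ----------------------------------------------------------------


def degeneracy_metric(
    fvasc: np.ndarray, fiso: np.ndarray, mask: np.ndarray | None = None,
    fvasc_cut: float = 0.9, fiso_cut: float = 0.5,
) -> float:
    """Percent of voxels with fvasc > 0.9 among those with fiso > 0.5.

    Returns NaN (missing) when no voxel passes the fiso cut.  Invariant to
    voxel ordering.
    """
    fvasc = np.asarray(fvasc, dtype=float)
    fiso = np.asarray(fiso, dtype=float)
    if fvasc.shape != fiso.shape:
        raise ValueError("fvasc and fiso grids do not match")
    if mask is None:
        mask = np.ones(fvasc.shape, dtype=bool)
    if np.asarray(mask).shape != fvasc.shape:
        raise ValueError("mask grid does not match maps")
    denom = (fiso > fiso_cut) & mask & np.isfinite(fvasc)
    if not denom.any():
        return float("nan")
    num = denom & (fvasc > fvasc_cut)
    return 100.0 * float(num.sum()) / float(denom.sum())


# -- cascade orchestration --------------------------------------------------


def _voxel_config(base: FitConfig, voxel_index: int) -> FitConfig:
    seed = int(
        np.random.SeedSequence((base.seed, int(voxel_index))).generate_state(1)[0]
        % (2**31)
    )
    return FitConfig(
        n_restarts=base.n_restarts, seed=seed, maxiter=base.maxiter, ftol=base.ftol
    )


def build_candidate_grid(config: CascadeConfig, families) -> list[TissueModel]:
    grid = []
    for ec in families:
        for vasc in config.vascular_candidates:
            for dv_mode in config.dv_modes:
                for fwe in config.fwe_options:
                    grid.append(make_model(ec, vasc, dv_mode=dv_mode, fwe=fwe))
    return grid


def run_cascade(
    raw: np.ndarray,
    scheme: AcquisitionScheme,
    masks: dict,
    config: CascadeConfig | None = None,
) -> SelectionReport:
    """Execute the four-stage cascade on a 4D dataset.

    ``masks`` must provide binary "core" and "periphery" volumes.  Voxels are
    subsampled per region (seeded) to keep full-grid fits tractable; all
    randomness derives from ``config.seed``, so reruns are byte-identical.
    """
    config = config or CascadeConfig()
    for name in ("core", "periphery"):
        if name not in masks:
            raise ValueError(f"missing region mask {name!r}")
        if not np.asarray(masks[name]).any():
            raise ValueError(f"region mask {name!r} is empty")
    rng = np.random.default_rng(config.seed)
    grid_shape = np.asarray(masks["core"]).shape
    flat_idx, region_labels = [], []
    for name in ("core", "periphery"):
        idx = np.nonzero(np.asarray(masks[name]).ravel())[0]
        take = min(config.n_voxels_per_region, len(idx))
        chosen = np.sort(rng.choice(idx, size=take, replace=False))
        flat_idx.extend(chosen)
        region_labels.extend([name] * take)
    flat_idx = np.array(flat_idx)
    region_labels = np.array(region_labels)
    vox_ijk = np.unravel_index(flat_idx, grid_shape)
    raw_vox = np.asarray(raw, float)[vox_ijk]  # (V, N)

    # deterministic sub-ROI parcels for the anisotropy screen
    subroi_labels = np.zeros(len(flat_idx), dtype=int)
    for name in ("core", "periphery"):
        sel = np.nonzero(region_labels == name)[0]
        subroi_labels[sel] = np.arange(len(sel)) % config.n_subrois

    # stage 1: high-b extracellular screen
    s1_scheme = select_shells(scheme, PRESET_HIGH_B_STAGE1)
    s1_idx = _scheme_indices(scheme, s1_scheme)
    n_s1 = min(config.n_voxels_stage1, len(flat_idx))
    s1_rows = np.unique(np.linspace(0, len(flat_idx) - 1, n_s1).astype(int))
    s1_atten, s1_wscheme = normalize_signal(raw_vox[s1_rows][:, s1_idx], s1_scheme)
    s1_candidates = [make_model(ec) for ec in config.extracellular_candidates]
    try:
        stage1_table, survivors = stage1_high_b(
            s1_candidates, s1_atten, s1_wscheme, config.fit, config.keep_top_families
        )
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 1 (high-b screen) failed: {e}") from e

    # NODDI on the dense shells (free-water fraction + dispersion standard)
    noddi_scheme = select_shells(scheme, PRESET_NODDI)
    nd_idx = _scheme_indices(scheme, noddi_scheme)
    nd_atten, nd_wscheme = normalize_signal(raw_vox[:, nd_idx], noddi_scheme)
    fiso = np.zeros(len(flat_idx))
    odi = np.zeros(len(flat_idx))
    for v in range(len(flat_idx)):
        cfg = _voxel_config(config.noddi_fit, v)
        fiso[v], odi[v], _, _ = fit_noddi_voxel(nd_atten[v], nd_wscheme, cfg)

    # stage 2: full-signal grid
    atten, wscheme = normalize_signal(raw_vox, scheme)
    grid = build_candidate_grid(config, survivors)
    try:
        stage2_table, fits = stage2_full_signal(
            grid, atten, wscheme, region_labels, fiso, config.fit
        )
    except Exception as e:
        raise RuntimeError(f"stage 2 (full-signal AICc) failed: {e}") from e

    # stage 3: FA-ODI correlations
    try:
        fa_odi_table = stage3_fa_odi(grid, fits, odi, region_labels, subroi_labels)
    except Exception as e:
        raise RuntimeError(f"stage 3 (FA-ODI screen) failed: {e}") from e

    # stage 4: degeneracy percentages
    degeneracy = {}
    for model in grid:
        fvasc = np.array([f.fractions.get("fvasc", 0.0) for f in fits[model.label]])
        degeneracy[model.label] = degeneracy_metric(
            fvasc, fiso, fvasc_cut=config.fvasc_cut, fiso_cut=config.fiso_cut
        )

    # selection: lowest overall mean AICc among models passing the screen
    overall = stage2_table.groupby("label")["mean_aicc"].mean()
    passing = [
        lbl for lbl in overall.index
        if not (degeneracy.get(lbl, np.nan) > config.degeneracy_threshold_pct)
    ]
    pool = passing or list(overall.index)
    selected = overall.loc[pool].idxmin()
    return SelectionReport(
        stage1=stage1_table,
        stage2=stage2_table,
        fa_odi=fa_odi_table,
        degeneracy=degeneracy,
        selected=selected,
        survivors=survivors,
        seed=config.seed,
    )
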