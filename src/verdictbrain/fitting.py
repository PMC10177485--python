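"""Voxelwise constrained model fitting.

Fitting operates on *normalized attenuation*: every weighted measurement is
divided by the mean b=0 acquired at the same echo time, which cancels T2
weighting under the shared-T2 / no-exchange assumption and makes multi-TE
data fittable by T2-free kernels.

The objective is Gaussian least squares on the attenuation, minimised by a
bounded, linearly constrained local optimizer (SLSQP: bound and simplex
feasibility at every iterate) with seeded Latin-hypercube multi-restart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from . import compartments as cpt
from .constants import FREE_WATER_DIFFUSIVITY
from .scheme import PRESET_NODDI, AcquisitionScheme, select_shells
from .tissue_models import TissueModel

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "normalize_signal",
    "fit_voxel",
    "fit_volume",
    "fit_adc",
    "fit_noddi_fwe",
    "extracellular_fa",
    "fa_from_eigenvalues",
]

_EPS_CLIP = 1e-6


@dataclass
class FitConfig:
    """Optimizer settings.

    n_restarts includes one deterministic mid-bounds start; the remainder are
    Latin-hypercube draws seeded by ``seed`` (so fits are reproducible and
    order independent).
    """

    n_restarts: int = 10
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-10


@dataclass
class FitResult:
    """Outcome of one voxel fit; never silently dropped on failure."""

    params: dict
    fractions: dict
    rss: float
    n: int
    k: int
    converged: bool
    n_restarts: int
    best_restart: int
    aicc: float | None = None
    x: np.ndarray = field(default=None, repr=False)


# -- normalization ----------------------------------------------------------


def normalize_signal(
    raw: np.ndarray, scheme: AcquisitionScheme, sigma: float | None = None
):
    """Divide each weighted measurement by the mean b=0 at its TE.

    Parameters
    ----------
    raw : (..., N) array
        Raw signal, last axis matching ``scheme``.
    sigma : float, optional
        Noise standard deviation relative to b=0; when given, the output is
        clipped to [1e-6, 1 + 3 sigma] (noisy attenuations above unity are
        clipped, not rejected).

    Returns
    -------
    attenuation : (..., n_weighted) array
    weighted_scheme : AcquisitionScheme
        The scheme restricted to weighted records, in original order.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-1] != len(scheme):
        raise ValueError(
            f"signal last axis {raw.shape[-1]} does not match scheme length {len(scheme)}"
        )
    te_r = np.round(scheme.te, 6)
    w = scheme.weighted
    b0_mean = {}
    for te in np.unique(te_r[~w]):
        b0_mean[te] = raw[..., (~w) & (te_r == te)].mean(axis=-1)
    atten = np.empty(raw.shape[:-1] + (int(w.sum()),), dtype=float)
    for j, i in enumerate(np.nonzero(w)[0]):
        te = te_r[i]
        if te not in b0_mean:
            raise ValueError(f"no b=0 record at TE={te} ms for a weighted measurement")
        with np.errstate(invalid="ignore", divide="ignore"):
            atten[..., j] = raw[..., i] / b0_mean[te]
    hi = 1.0 + 3.0 * sigma if sigma is not None else np.inf
    atten = np.clip(atten, _EPS_CLIP, hi)
    return atten, scheme.subset(np.nonzero(w)[0])


# -- voxel fitting ----------------------------------------------------------


def _constraints(model: TissueModel):
    """Simplex and parameter-ordering inequality constraints (g(x) >= 0)."""
    n_frac = len(model.fraction_names())
    cons = [
        {"type": "ineq", "fun": lambda x, n=n_frac: 1.0 - np.sum(x[:n])},
    ]
    names = model.param_names()

    def pair(a, b):
        ia, ib = names.index(a), names.index(b)
        cons.append({"type": "ineq", "fun": lambda x, ia=ia, ib=ib: x[ia] - x[ib]})

    for prefix, kind in (
        ("ec", model.extracellular),
        ("ec2", model.extracellular2),
    ):
        if kind == "Zeppelin":
            pair(f"{prefix}_d_par", f"{prefix}_d_perp")
        elif kind == "Tensor":
            pair(f"{prefix}_lam1", f"{prefix}_lam2")
            pair(f"{prefix}_lam2", f"{prefix}_lam3")
    return cons


def _feasible(x, model: TissueModel, frac_cap: float = 0.98):
    """Project a vector to the feasible set; ``frac_cap`` < 1 keeps starting
    points strictly inside the simplex, while final iterates use 1.0 so
    boundary optima are preserved."""
    x = np.array(x, dtype=float)
    n_frac = len(model.fraction_names())
    x[:n_frac] = np.clip(x[:n_frac], 0.0, 1.0)
    s = x[:n_frac].sum()
    if s > frac_cap:
        x[:n_frac] *= frac_cap / s
    names = model.param_names()
    for prefix, kind in (("ec", model.extracellular), ("ec2", model.extracellular2)):
        if kind == "Zeppelin":
            ia, ib = names.index(f"{prefix}_d_par"), names.index(f"{prefix}_d_perp")
            if x[ib] > x[ia]:
                x[ia], x[ib] = x[ib], x[ia]
        elif kind == "Tensor":
            idx = [names.index(f"{prefix}_lam{i}") for i in (1, 2, 3)]
            x[idx] = np.sort(x[idx])[::-1]
    return x


def _starting_points(model: TissueModel, config: FitConfig, seed: int):
    lo, hi = map(np.array, zip(*model.scaled_bounds()))
    mid = _feasible(lo + 0.45 * (hi - lo), model)
    starts = [mid]
    n_lhs = max(config.n_restarts - 1, 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
        for u in sampler.random(n_lhs):
            starts.append(_feasible(lo + u * (hi - lo), model))
    return starts


def fit_voxel(
    model: TissueModel,
    attenuation: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
    ffw: float | None = None,
) -> FitResult:
    """Constrained least-squares fit of one voxel's attenuation vector.

    Multi-restart; the best-RSS restart wins; deterministic given
    ``config.seed``.  If no restart converges the best attempt is still
    returned with ``converged=False``.
    """
    config = config or FitConfig()
    y = np.asarray(attenuation, dtype=float)
    if y.shape != (len(scheme),):
        raise ValueError("attenuation length does not match scheme")
    bounds = model.scaled_bounds()
    cons = _constraints(model)

    def objective(x):
        r = model.signal_from_vector(x, scheme, ffw=ffw) - y
        return float(r @ r)

    best = None
    best_i = -1
    any_ok = False
    starts = _starting_points(model, config, config.seed)
    for i, x0 in enumerate(starts):
        try:
            res = minimize(
                objective,
                x0,
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": config.maxiter, "ftol": config.ftol},
            )
        except Exception:  # optimizer blow-up on one restart is not fatal
            continue
        x_fin = _feasible(res.x, model, frac_cap=1.0)
        rss = objective(x_fin)
        any_ok = any_ok or bool(res.success)
        if best is None or rss < best[0]:
            best = (rss, x_fin)
            best_i = i
    if best is None:  # every restart raised
        x_fin = starts[0]
        best = (objective(x_fin), x_fin)
        best_i = 0
        any_ok = False
    rss, x = best
    params = model.vector_to_params(x)
    fr = {n: params[n] for n in model.fraction_names()}
    fr["fees"] = max(1.0 - sum(fr.values()), 0.0)
    if model.fwe:
        fr["ffw"] = model.fwe_ffw if ffw is None else ffw
    return FitResult(
        params=params,
        fractions=fr,
        rss=rss,
        n=len(y),
        k=len(bounds),
        converged=any_ok,
        n_restarts=len(starts),
        best_restart=best_i,
        x=x,
    )


# -- volume fitting ---------------------------------------------------------


def fit_volume(
    model: TissueModel,
    attenuation: np.ndarray,
    mask: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
    ffw_map: np.ndarray | None = None,
):
    """Apply :func:`fit_voxel` over a masked grid.

    ``attenuation`` is (X, Y, Z, n_weighted) normalized data.  Per-voxel
    restart seeds are derived from (config.seed, flat voxel index), so the
    output is identical regardless of evaluation order.

    Returns
    -------
    maps : dict of (X, Y, Z) arrays
        One map per free parameter plus fees, rss and converged; NaN outside
        the mask.
    results : dict
        flat-index -> FitResult.
    """
    config = config or FitConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != attenuation.shape[:-1]:
        raise ValueError("mask shape does not match signal grid")
    if model.fwe and ffw_map is not None and ffw_map.shape != mask.shape:
        raise ValueError("ffw map shape does not match grid")
    names = model.param_names() + ["fees", "rss", "converged"]
    maps = {n: np.full(mask.shape, np.nan) for n in names}
    results = {}
    idxs = np.nonzero(mask.ravel())[0]
    for count, flat in enumerate(idxs):
        ijk = np.unravel_index(flat, mask.shape)
        vox_cfg = FitConfig(
            n_restarts=config.n_restarts,
            seed=int(np.random.SeedSequence((config.seed, int(flat))).generate_state(1)[0] % (2**31)),
            maxiter=config.maxiter,
            ftol=config.ftol,
        )
        ffw = float(ffw_map[ijk]) if (model.fwe and ffw_map is not None) else None
        fit = fit_voxel(model, attenuation[ijk], scheme, vox_cfg, ffw=ffw)
        results[int(flat)] = fit
        for n, v in fit.params.items():
            maps[n][ijk] = v
        maps["fees"][ijk] = fit.fractions["fees"]
        maps["rss"][ijk] = fit.rss
        maps["converged"][ijk] = float(fit.converged)
        if count % 200 == 199:
            logger.info("fit_volume %s: %d/%d voxels", model.label, count + 1, len(idxs))
    return maps, results


# -- ADC --------------------------------------------------------------------


def fit_adc(raw: np.ndarray, scheme: AcquisitionScheme, b_shell: float = 1000.0):
    """Monoexponential ADC (mm²/s) from the b = 1000 s/mm² shell.

    Per voxel, ADC is the mean over shell directions of ln(S0/S)/b, with S0
    the mean b=0 at the shell's TE.
    """
    sel = scheme.weighted & np.isclose(scheme.b, b_shell)
    if not sel.any():
        raise ValueError(f"scheme has no b={b_shell:g} s/mm² shell")
    te = np.round(scheme.te[sel][0], 6)
    b0_sel = scheme.is_b0 & (np.round(scheme.te, 6) == te)
    raw = np.asarray(raw, dtype=float)
    s0 = raw[..., b0_sel].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logatt = np.log(raw[..., sel] / s0[..., None])
    adc = -logatt.mean(axis=-1) / b_shell  # mm²/s since b is s/mm²
    return np.clip(adc, 0.0, None)


# -- NODDI free-water elimination -------------------------------------------

#: NODDI intrinsic neurite parallel diffusivity, m²/s.
NODDI_D_PAR = 1.7e-9

_NODDI_BOUNDS = [
    (0.0, 1.0),  # fiso
    (0.0, 1.0),  # nu_ic (neurite fraction of the tissue part)
    (0.05, 64.0),  # kappa
    (0.0, np.pi),  # theta
    (-np.pi, np.pi),  # phi
]


def _noddi_signal(x, scheme, n_polar=24, n_azim=16):
    fiso, nu, kappa, theta, phi = x
    mu = cpt.angles_to_unit(theta, phi)
    s_ic = cpt.watson_sticks_signal(NODDI_D_PAR, kappa, mu, scheme, n_polar, n_azim)
    d_perp = NODDI_D_PAR * (1.0 - nu)  # tortuosity coupling
    s_ec = np.exp(-scheme.b_si * d_perp) * cpt.watson_sticks_signal(
        NODDI_D_PAR - d_perp, kappa, mu, scheme, n_polar, n_azim
    )
    s_tissue = nu * s_ic + (1.0 - nu) * s_ec
    return (1.0 - fiso) * s_tissue + fiso * cpt.ball_signal(
        FREE_WATER_DIFFUSIVITY, scheme
    )


def fit_noddi_voxel(
    attenuation: np.ndarray, scheme: AcquisitionScheme, config: FitConfig | None = None
):
    """Fit the NODDI model to one voxel; returns (fiso, odi, kappa, rss)."""
    config = config or FitConfig(n_restarts=4, maxiter=200)
    y = np.asarray(attenuation, dtype=float)

    def objective(x):
        r = _noddi_signal(x, scheme) - y
        return float(r @ r)

    lo, hi = map(np.array, zip(*_NODDI_BOUNDS))
    starts = [np.array([0.2, 0.5, 2.0, np.pi / 2, 0.0])]
    sampler = qmc.LatinHypercube(d=5, seed=config.seed)
    for u in sampler.random(max(config.n_restarts - 1, 0)):
        starts.append(lo + u * (hi - lo))
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=_NODDI_BOUNDS,
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        rss = objective(res.x)
        if best is None or rss < best[0]:
            best = (rss, res.x)
    rss, x = best
    return float(x[0]), cpt.odi_from_kappa(float(x[2])), float(x[2]), rss


def fit_noddi_fwe(
    raw: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
):
    """NODDI fit on the two dense shells; returns (fiso map, ODI map).

    The fiso map is the free-water fraction subsequently pinned per voxel in
    FWE tissue-model fits; ODI is the dispersion gold standard used by the
    cascade's anisotropy screen.
    """
    noddi_scheme = select_shells(scheme, PRESET_NODDI)
    sub = _scheme_indices(scheme, noddi_scheme)
    atten, wscheme = normalize_signal(np.asarray(raw, float)[..., sub], noddi_scheme)
    grid = atten.shape[:-1]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match signal grid")
    fiso = np.full(grid, np.nan)
    odi = np.full(grid, np.nan)
    base_seed = (config.seed if config else 0)
    for flat in np.nonzero(mask.ravel())[0]:
        ijk = np.unravel_index(flat, grid)
        vox_cfg = FitConfig(
            n_restarts=(config.n_restarts if config else 4),
            seed=int(np.random.SeedSequence((base_seed, int(flat))).generate_state(1)[0] % (2**31)),
            maxiter=(config.maxiter if config else 200),
        )
        f, o, _, _ = fit_noddi_voxel(atten[ijk], wscheme, vox_cfg)
        fiso[ijk] = f
        odi[ijk] = o
    return fiso, odi


def _scheme_indices(full: AcquisitionScheme, sub: AcquisitionScheme) -> np.ndarray:
    """Indices of ``sub``'s records within ``full`` (matching all fields)."""
    key_full = np.stack(
        [full.b, full.te, full.delta, full.Delta, full.directions[:, 0],
         full.directions[:, 1], full.directions[:, 2], full.shell], axis=1
    )
    out = []
    for row in zip(sub.b, sub.te, sub.delta, sub.Delta, sub.directions[:, 0],
                   sub.directions[:, 1], sub.directions[:, 2], sub.shell):
        match = np.nonzero(np.all(np.isclose(key_full, np.array(row)), axis=1))[0]
        out.append(int(match[0]))
    return np.array(out)


# -- derived anisotropy -----------------------------------------------------


def fa_from_eigenvalues(lam1, lam2, lam3):
    """Fractional anisotropy of a diffusion tensor with the given eigenvalues."""
    lam = np.stack(np.broadcast_arrays(
        np.asarray(lam1, float), np.asarray(lam2, float), np.asarray(lam3, float)
    ), axis=-1)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def extracellular_fa(model: TissueModel, maps: dict) -> np.ndarray:
    """FA map of the fitted extracellular compartment (Zeppelin or Tensor)."""
    if model.extracellular == "Zeppelin":
        return fa_from_eigenvalues(maps["ec_d_par"], maps["ec_d_perp"], maps["ec_d_perp"])
    if model.extracellular == "Tensor":
        return fa_from_eigenvalues(maps["ec_lam1"], maps["ec_lam2"], maps["ec_lam3"])
    raise ValueError(
        f"extracellular FA requires Zeppelin or Tensor, got {model.extracellular}"
    )
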