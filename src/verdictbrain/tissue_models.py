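"""Multi-compartment VERDICT tissue models for brain tumours.

A tissue model composes a restricted intracellular Sphere with one (or two)
extracellular compartments and optionally a vascular pseudo-diffusion
compartment.  The canonical model name lists the extracellular compartment
first, then the vascular one, then the restricted one (e.g.
``Zeppelin–AstroSticks–Sphere``).

The vascular pseudo-diffusivity dv is either *bounded* (free parameter,
dv ≥ 3×10⁻⁹ m²/s for Ball, dv ≥ 9×10⁻⁹ m²/s for AstroSticks) or *fixed*
(1.5×10⁻⁸ m²/s for Ball, 4×10⁻⁸ m²/s for AstroSticks).

Free-water elimination (FWE) adds a Ball compartment at 3×10⁻⁹ m²/s whose
signal fraction ffw is fixed per voxel (supplied externally, typically from a
NODDI fit), so an FWE model has exactly the same number of free parameters as
its non-FWE counterpart:

    S = (1 - ffw)·(fic·S_sphere + fees·S_ec + fvasc·S_vasc) + ffw·S_fw
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import compartments as cpt
from .constants import FREE_WATER_DIFFUSIVITY
from .scheme import AcquisitionScheme

__all__ = [
    "TissueModel",
    "make_model",
    "model_signal",
    "apply_fwe",
    "count_free_parameters",
    "DEFAULT_BOUNDS",
    "DV_BOUND",
    "DV_FIXED",
    "EXTRACELLULAR_KINDS",
    "VASCULAR_KINDS",
]

EXTRACELLULAR_KINDS = ("Zeppelin", "Tensor", "Cylinder", "Stick", "WatsonSticks")
VASCULAR_KINDS = ("Ball", "AstroSticks")

#: Lower bound on the pseudo-diffusivity dv (m²/s) in bounded mode.
DV_BOUND = {"Ball": 3.0e-9, "AstroSticks": 9.0e-9}
#: Fixed dv value (m²/s) in fixed mode.
DV_FIXED = {"Ball": 1.5e-8, "AstroSticks": 4.0e-8}

#: Default fitting bounds.  Diffusivities m²/s, radii µm, angles rad.
DEFAULT_BOUNDS = {
    "d": (0.1e-9, 3.0e-9),  # extracellular diffusivities / eigenvalues
    "R": (0.1, 20.0),  # sphere radius, µm
    "R_cyl": (0.1, 20.0),
    "kappa": (0.0, 64.0),
    "dv_max": 1.0e-7,
    "theta": (0.0, np.pi),
    "phi": (-np.pi, np.pi),
    "psi": (0.0, np.pi),
}

#: Default fixed intracellular diffusivity (m²/s), standard VERDICT practice.
DEFAULT_DIC = 0.9e-9

# per-kind extracellular parameter names (order defines the vector layout)
_EC_PARAMS = {
    "Zeppelin": ("d_par", "d_perp", "theta", "phi"),
    "Tensor": ("lam1", "lam2", "lam3", "theta", "phi", "psi"),
    "Cylinder": ("d", "R_cyl", "theta", "phi"),
    "Stick": ("d", "theta", "phi"),
    "WatsonSticks": ("d", "kappa", "theta", "phi"),
}


class ModelError(ValueError):
    """Invalid model composition or parameters."""


@dataclass(frozen=True)
class TissueModel:
    """Compartment composition plus constraint configuration.

    ``fwe_ffw`` is ``None`` until :func:`apply_fwe` pins the per-voxel
    free-water fraction; the FWE *flag* alone already defines the model
    family (and its parameter count, which FWE never changes).
    """

    extracellular: str
    vascular: str | None = None
    dv_mode: str = "bounded"  # "bounded" | "fixed"
    fwe: bool = False
    extracellular2: str | None = None
    dic: float = DEFAULT_DIC
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fwe_ffw: float | None = None

    # -- naming -------------------------------------------------------------

    @property
    def name(self) -> str:
        parts = [self.extracellular]
        if self.extracellular2:
            parts.append(self.extracellular2)
        if self.vascular:
            parts.append(self.vascular)
        parts.append("Sphere")
        return "–".join(parts)

    @property
    def label(self) -> str:
        lbl = self.name
        if self.vascular and self.dv_mode == "fixed":
            lbl += " with fixed dv"
        if self.fwe:
            lbl += " with FWE"
        return lbl

    # -- parameter vector layout -------------------------------------------

    @property
    def n_compartments(self) -> int:
        return 1 + 1 + (self.extracellular2 is not None) + (self.vascular is not None)

    def fraction_names(self) -> list[str]:
        """Free fraction parameters: all but the extracellular fraction,
        which is 1 minus the rest (fees closes the simplex)."""
        names = ["fic"]
        if self.extracellular2:
            names.append("fec2")
        if self.vascular:
            names.append("fvasc")
        return names

    def kernel_param_names(self) -> list[str]:
        names = [f"ec_{p}" for p in _EC_PARAMS[self.extracellular]]
        if self.extracellular2:
            names += [f"ec2_{p}" for p in _EC_PARAMS[self.extracellular2]]
        if self.vascular and self.dv_mode == "bounded":
            names.append("dv")
        names.append("R")
        return names

    def param_names(self) -> list[str]:
        return self.fraction_names() + self.kernel_param_names()

    def param_bounds(self) -> list[tuple[float, float]]:
        b = self.bounds
        out: list[tuple[float, float]] = [(0.0, 1.0)] * len(self.fraction_names())
        for name in self.kernel_param_names():
            key = name.split("_", 1)[-1] if name.startswith(("ec_", "ec2_")) else name
            if key in ("d", "d_par", "d_perp", "lam1", "lam2", "lam3"):
                out.append(b["d"])
            elif key == "R":
                out.append(b["R"])
            elif key == "R_cyl":
                out.append(b["R_cyl"])
            elif key == "kappa":
                out.append(b["kappa"])
            elif key == "dv":
                out.append((DV_BOUND[self.vascular], b["dv_max"]))
            elif key in ("theta", "phi", "psi"):
                out.append(b[key])
            else:  # pragma: no cover
                raise ModelError(f"unknown parameter {name}")
        return out

    def param_scales(self) -> np.ndarray:
        """Unit scale per parameter: the optimizer works on x where
        SI value = x * scale, so diffusivities (m²/s) are fitted in
        µm²/ms (scale 1e-9) and everything is O(1)."""
        scales = []
        for name in self.param_names():
            key = name.split("_", 1)[-1] if name.startswith(("ec_", "ec2_")) else name
            diffusive = key in ("d", "d_par", "d_perp", "lam1", "lam2", "lam3", "dv")
            scales.append(1e-9 if diffusive else 1.0)
        return np.array(scales)

    def scaled_bounds(self) -> list[tuple[float, float]]:
        return [
            (lo / s, hi / s)
            for (lo, hi), s in zip(self.param_bounds(), self.param_scales())
        ]

    def dv_value(self, params: dict) -> float | None:
        if self.vascular is None:
            return None
        if self.dv_mode == "fixed":
            return DV_FIXED[self.vascular]
        return params["dv"]

    # -- signal -------------------------------------------------------------

    def _ec_signal(self, prefix: str, kind: str, p: dict, scheme) -> np.ndarray:
        g = lambda name: p[f"{prefix}_{name}"]
        if kind == "Zeppelin":
            d_par, d_perp = g("d_par"), g("d_perp")
            if d_perp > d_par:  # feasibility slack during optimization
                d_par = d_perp
            mu = cpt.angles_to_unit(g("theta"), g("phi"))
            return cpt.zeppelin_signal(d_par, d_perp, mu, scheme)
        if kind == "Tensor":
            lam = np.array([g("lam1"), g("lam2"), g("lam3")])
            frame = cpt.tensor_frame(g("theta"), g("phi"), g("psi"))
            proj2 = (scheme.directions @ frame) ** 2
            return np.exp(-scheme.b_si * (proj2 @ lam))
        if kind == "Cylinder":
            mu = cpt.angles_to_unit(g("theta"), g("phi"))
            return cpt.cylinder_signal(g("d"), g("R_cyl"), mu, scheme)
        if kind == "Stick":
            mu = cpt.angles_to_unit(g("theta"), g("phi"))
            return cpt.stick_signal(g("d"), mu, scheme)
        if kind == "WatsonSticks":
            mu = cpt.angles_to_unit(g("theta"), g("phi"))
            return cpt.watson_sticks_signal(g("d"), g("kappa"), mu, scheme)
        raise ModelError(f"unknown extracellular kind {kind}")

    def signal(
        self, params: dict, scheme: AcquisitionScheme, ffw: float | None = None
    ) -> np.ndarray:
        """Normalized model attenuation for a parameter dict.

        ``params`` holds the free parameters (see :meth:`param_names`);
        fractions must lie on the simplex within 1e-6.  ``ffw`` overrides the
        model-pinned free-water fraction.
        """
        fr = [params[n] for n in self.fraction_names()]
        total = float(np.sum(fr))
        if total > 1.0 + 1e-6 or min(fr) < -1e-6:
            raise ModelError("fractions off the simplex")
        fees = max(1.0 - total, 0.0)
        sig = fees * self._ec_signal("ec", self.extracellular, params, scheme)
        sig = sig + params["fic"] * cpt.sphere_signal(self.dic, params["R"], scheme)
        if self.extracellular2:
            sig = sig + params["fec2"] * self._ec_signal(
                "ec2", self.extracellular2, params, scheme
            )
        if self.vascular:
            dv = self.dv_value(params)
            if self.vascular == "Ball":
                sv = cpt.ball_signal(dv, scheme)
            else:
                sv = cpt.astrosticks_signal(dv, scheme)
            sig = sig + params["fvasc"] * sv
        if self.fwe:
            w = self.fwe_ffw if ffw is None else ffw
            if w is None:
                raise ModelError("FWE model evaluated without a free-water fraction")
            if not 0.0 <= w <= 1.0:
                raise ModelError(f"ffw={w} outside [0, 1]")
            sig = (1.0 - w) * sig + w * cpt.ball_signal(FREE_WATER_DIFFUSIVITY, scheme)
        return sig

    def signal_from_vector(
        self, x: np.ndarray, scheme: AcquisitionScheme, ffw: float | None = None
    ) -> np.ndarray:
        """Signal from a *scaled* parameter vector (see :meth:`param_scales`)."""
        return self.signal(self.vector_to_params(x), scheme, ffw=ffw)

    def vector_to_params(self, x) -> dict:
        """Scaled vector -> SI parameter dict."""
        x = np.asarray(x, dtype=float) * self.param_scales()
        return dict(zip(self.param_names(), x))

    def params_to_vector(self, params: dict) -> np.ndarray:
        """SI parameter dict -> scaled vector."""
        return np.array([params[n] for n in self.param_names()]) / self.param_scales()

    # -- serialization ------------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "extracellular": self.extracellular,
            "extracellular2": self.extracellular2,
            "vascular": self.vascular,
            "dv_mode": self.dv_mode,
            "fwe": self.fwe,
            "dic": float(self.dic),
            "bounds": {
                k: (list(v) if isinstance(v, (tuple, list)) else float(v))
                for k, v in self.bounds.items()
            },
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TissueModel":
        doc = yaml.safe_load(text)
        bounds = {
            k: (tuple(v) if isinstance(v, list) else float(v))
            for k, v in doc.get("bounds", {}).items()
        }
        return make_model(
            doc["extracellular"],
            doc.get("vascular"),
            dv_mode=doc.get("dv_mode", "bounded"),
            fwe=doc.get("fwe", False),
            extracellular2=doc.get("extracellular2"),
            dic=doc.get("dic", DEFAULT_DIC),
            bounds=bounds or None,
        )


def make_model(
    extracellular: str,
    vascular: str | None = None,
    dv_mode: str = "bounded",
    fwe: bool = False,
    extracellular2: str | None = None,
    dic: float = DEFAULT_DIC,
    bounds: dict | None = None,
) -> TissueModel:
    """Build a validated tissue model with canonical name and default bounds."""
    if extracellular not in EXTRACELLULAR_KINDS:
        raise ModelError(
            f"invalid extracellular compartment {extracellular!r}; "
            f"expected one of {EXTRACELLULAR_KINDS}"
        )
    if extracellular2 is not None and extracellular2 not in EXTRACELLULAR_KINDS:
        raise ModelError(f"invalid second extracellular compartment {extracellular2!r}")
    if vascular is not None and vascular not in VASCULAR_KINDS:
        raise ModelError(
            f"invalid vascular compartment {vascular!r}; expected one of {VASCULAR_KINDS}"
        )
    if dv_mode not in ("bounded", "fixed"):
        raise ModelError(f"invalid dv mode {dv_mode!r}")
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    return TissueModel(
        extracellular=extracellular,
        vascular=vascular,
        dv_mode=dv_mode,
        fwe=fwe,
        extracellular2=extracellular2,
        dic=dic,
        bounds=merged,
    )


def model_signal(
    model: TissueModel, params: dict, scheme: AcquisitionScheme, ffw: float | None = None
) -> np.ndarray:
    """Functional alias for :meth:`TissueModel.signal`."""
    return model.signal(params, scheme, ffw=ffw)


def apply_fwe(model: TissueModel, ffw: float) -> TissueModel:
    """Pin the free-water fraction of an FWE model to a per-voxel constant.

    The returned model fits with ffw held fixed, so its free-parameter count
    equals the non-FWE counterpart's.
    """
    if not 0.0 <= ffw <= 1.0:
        raise ModelError(f"ffw={ffw} outside [0, 1]")
    return replace(model, fwe=True, fwe_ffw=float(ffw))


def count_free_parameters(model: TissueModel) -> int:
    """Number of free parameters k: (compartments − 1) fractions plus every
    non-fixed kernel parameter and orientation angle.  FWE never changes k."""
    return len(model.param_names())
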