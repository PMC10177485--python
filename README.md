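# verdictbrain

Multi-compartment diffusion-MRI modelling of brain tumours in the VERDICT
framework (Vascular, Extracellular and Restricted DIffusion for Cytometry
in Tumours).

Conventional dMRI reduces a tumour voxel to a single apparent diffusion
coefficient, which overlaps heavily between tumour types.  `verdictbrain`
instead decomposes the signal of a rich multi-shell, multi-TE,
multi-diffusion-time acquisition into biologically meaningful
compartments — restricted water in tumour cells (Sphere, radius R),
hindered extracellular water (Zeppelin/Tensor/Stick/Cylinder/Watson-sticks),
pseudo-diffusing blood in microvessels (Ball or AstroSticks with
pseudo-diffusivity d_v), and free water — and estimates their signal
fractions f_ic, f_ees, f_vasc, f_fw per voxel:

    S = (1 − f_fw)·( f_ic·S_sphere + f_ees·S_ec + f_vasc·S_vasc ) + f_fw·e^(−b·3×10⁻⁹)

The package is aimed at quantitative-MRI researchers who want to fit,
compare and stress-test such models: it ships the analytic PGSE signal
kernels (including the Gaussian-phase-distribution kernels for restricted
spheres and cylinders), constrained voxelwise least-squares fitting, a
NODDI-based free-water-elimination step that adds a fourth compartment
*without* extra free parameters, AICc-based cascade model selection, a
ground-truth synthetic phantom, and ROI-level group statistics.

## Worked example

```python
import numpy as np
from verdictbrain import (build_reference_protocol, make_model, apply_fwe,
                          normalize_signal, fit_voxel, FitConfig, compute_aicc)
from verdictbrain.phantom import make_phantom, simulate_signal

scheme = build_reference_protocol()
print(f"protocol: {scheme.n_weighted} weighted measurements over "
      f"{len(scheme.shells)} shells, {int(scheme.is_b0.sum())} b=0 volumes")

phantom = make_phantom(seed=0)                      # 32^3 GBM-like lesion
raw = simulate_signal(phantom, scheme, snr=50, seed=1)
atten, wscheme = normalize_signal(raw, scheme)

model = apply_fwe(make_model("Zeppelin", "AstroSticks",
                             dv_mode="fixed", fwe=True), ffw=0.12)
ijk = tuple(map(int, np.argwhere(phantom.mask("core"))[40]))
fit = fit_voxel(model, atten[ijk], wscheme, FitConfig(n_restarts=6, seed=0))
aicc = compute_aicc(fit.rss, fit.n, fit.k)
print(f"voxel {ijk}: fic={fit.fractions['fic']:.3f} "
      f"fees={fit.fractions['fees']:.3f} fvasc={fit.fractions['fvasc']:.3f} "
      f"R={fit.params['R']:.1f} um  AICc={aicc:.1f}")
true = {k: float(phantom.params[k][ijk]) for k in ("fic", "fees", "fvasc", "R")}
print("truth:", {k: round(v, 3) for k, v in true.items()})
```

prints

```
protocol: 131 weighted measurements over 12 shells, 9 b=0 volumes
voxel (16, 19, 15): fic=0.427 fees=0.457 fvasc=0.116 R=7.6 um  AICc=-905.3
truth: {'fic': 0.425, 'fees': 0.484, 'fvasc': 0.091, 'R': 7.592}
```

The fitted tumour-core voxel recovers the intracellular fraction within
0.002 and the cell-size parameter within 0.1 µm of the ground truth at
SNR 50; the vascular fraction — the hardest compartment, carried mainly by
the four b ≤ 110 s/mm² shells — is recovered within 0.03.  The AICc value
is what the cascade uses to rank this model against the other
extracellular/vascular combinations.

The built-in acquisition scheme is the 12-shell protocol the models were
designed for: ten 3-direction shells from b = 50 to 3500 s/mm² with
shell-specific TE (43–123 ms), δ (5–20 ms) and Δ (20–90 ms), plus dense
38- and 63-direction shells at b = 711 and 3000 s/mm² used by the NODDI
free-water-elimination fit.

A command line wraps the same functionality for file-based runs
(`verdictbrain simulate | fit | select | stats`), reading and writing
NIfTI volumes, FSL-style bval/bvec with a JSON timing sidecar, and a YAML
run configuration.

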