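# reffmap

Effective intra-axonal radius mapping from ultra-high-b diffusion MRI.

At diffusion weightings of b ≳ 7 ms/μm² the extra-axonal water signal in
white matter is suppressed and the powder-averaged (spherical-mean) signal of
the intra-axonal compartment follows the stick power law
S̄(b) = β·b^(−1/2). A finite axon caliber adds a small radial diffusivity
Da⊥, bending the decay to S̄(b) = β·b^(−1/2)·exp(−b·Da⊥); in the long-pulse
(Neuman) regime Da⊥ maps to the tail-weighted effective axon radius

    r_eff = ((48/7) · δ · (Δ − δ/3) · D0 · Da⊥)^(1/4),

equal to (⟨r⁶⟩/⟨r²⟩)^(1/4) over the radius distribution in the
small-attenuation limit. Resolving Da⊥ requires head-gradient hardware at
200–300 mT/m; at 300 mT/m, 60 directions and SNR 20 the smallest robustly
detectable r_eff is ≈1.4 μm.

`reffmap` is a tested, desk-scale implementation of the full analysis chain
for researchers working on axon-diameter contrast: restricted-diffusion
forward models (Neuman closed form, van Gelderen series, matrix formalism,
and a random-walk oracle), a ground-truthed synthetic complex dMRI
generator, decorrelated-phase real-valued rectification, voxelwise
gradient-nonlinearity b-matrix correction, spherical-harmonic powder
averaging, nonlinear radius fitting, and test-retest repeatability
statistics (CoV, ICC, Bland–Altman, RPC, Spearman, left–right asymmetry).

## Worked example

```python
import numpy as np
from reffmap import (CylinderEnsemble, DetectabilityConfig, neuman_kappa,
                     resolution_limit, powder_average)
from reffmap.reff_fit import fit_powder_decay, reff_from_daperp

# detectability limit of the 300 mT/m configuration
kappa = neuman_kappa(g=300.0, delta=18.8, D0=2.0)          # 0.004415 um^-4
r_min = resolution_limit(DetectabilityConfig(SNR=20, n_dir=60, z=2.576), kappa)
print(r_min)                                               # 1.3931 um

# powder-averaged decay of a gamma cylinder ensemble on the 4-shell protocol
ens = CylinderEnsemble(k=2.0, s=0.5)                       # radii 0.25-5 um
b = np.array([7.0, 18.0, 25.0, 30.0])                      # ms/um^2
S = powder_average(ens, b, delta=18.8, Delta=26.8)
print(S)            # [0.2265 0.1328 0.1090 0.0973]

beta, da_perp, diag = fit_powder_decay(b, S)
print(da_perp)                                             # 0.005233 um^2/ms
print(reff_from_daperp(da_perp, 18.8, 26.8, 2.0))          # 2.294 um
print(ens.effective_radius())                              # 2.537 um
```

The fitted 2.29 μm sits below the ensemble's moment-ratio radius 2.54 μm:
the thickest axons are fully attenuated at these b-values and drop out of
the fit — an intrinsic property of the estimator for broad distributions,
quantified in `docs/methods.md`.

The end-to-end pipeline (simulate → phase-rectify → gradient-correct →
spherical mean → fit → parcel statistics) is scriptable:

```sh
reffmap all --outdir run1 --preset retest --snr 25 --seed 3 --coil magnus_like
cat run1/fit/fit_report.json
```

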