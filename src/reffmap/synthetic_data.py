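"""Ground-truthed synthetic complex multi-shell dMRI sessions.

The generator emulates the study conditions of an ultra-high-b axon-radius
protocol on a head-only high-performance gradient system:

* multi-shell PGSE protocols — ``feasibility`` (b = 7, 11, 13, 16, 21, 25,
  30 ms/um^2 x 60 directions + 8 interspersed b=0) and ``retest``
  (b = 7, 18, 25, 30 x 60 + 5 b=0), both at delta/Delta = 18.8/26.8 ms;
* white matter as gamma-distributed impermeable cylinders (radius
  distribution truncated to 0.25-5 um, i.e. diameters 0.5-10 um) with
  Watson orientation dispersion, grey matter and CSF as isotropic Gaussian
  compartments;
* spatial gradient non-linearity applied through a coil model (the signal
  is computed at the locally achieved b-value and rotated direction);
* a smooth low-order polynomial image phase and independent complex
  Gaussian channel noise at a configurable b=0 SNR;
* repeated sessions with small multiplicative perturbations of the
  ground-truth radial diffusivity map for test-retest studies.

Everything is deterministic given the seeds recorded in the session
metadata, and ground-truth maps are carried alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .forward_model import (
    CylinderEnsemble,
    Protocol,
    cylinder_perp_table,
    distribution_reff,
    g_for_b,
)
from .gnl_correction import GradientCoilModel, evaluate_gradient_tensor
from .reff_fit import daperp_from_reff


__all__ = [
    "MAGNUS_300",
    "MAGNUS_200",
    "generate_directions",
    "protocol_preset",
    "volume_table",
    "PhantomSpec",
    "SessionSpec",
    "SimulatedSession",
    "default_phantom",
    "simulate_session",
    "make_retest_pair",
    "sample_watson",
]

# the two hardware configurations explored by the study protocols
MAGNUS_300 = {"g_max": 300.0, "delta": 18.8, "Delta": 26.8}
MAGNUS_200 = {"g_max": 200.0, "delta": 21.4, "Delta": 31.3}


def generate_directions(n: int, seed: int = 42, n_iter: int = 300) -> np.ndarray:
    """n unit vectors spread by electrostatic repulsion with antipodal symmetry.

    Charges interact with both the partner and its antipode (so v and -v are
    equivalent); tangential gradient descent with a decaying step, fully
    deterministic given the seed.
    """
    if n < 3:
        raise ValueError("need at least 3 directions")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.05
    for it in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            d = v[:, None, :] - sign * v[None, :, :]  # (n, n, 3)
            dist2 = np.einsum("ijk,ijk->ij", d, d)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:
                dist2[dist2 < 1e-12] = np.inf  # own antipode for n odd cases
            force += np.einsum("ij,ijk->ik", dist2**-1.5, d)
        # project tangentially and take a small step
        force -= np.einsum("ik,ik->i", force, v)[:, None] * v
        v += step * force / np.maximum(np.linalg.norm(force, axis=1, keepdims=True), 1e-12)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        step *= 0.985
    # canonical hemisphere (z >= 0) for reproducibility of signs
    flip = v[:, 2] < 0
    v[flip] *= -1
    return v


def protocol_preset(name: str, seed: int = 42) -> Protocol:
    """Named acquisition presets used throughout the package.

    ``feasibility``: 7 shells x 60 directions + 8 b=0 (428 volumes);
    ``retest``: 4 shells x 60 directions + 5 b=0 (245 volumes).  Both share
    delta/Delta = 18.8/26.8 ms (constant gradient duration and separation
    across shells, so diffusion-time dependence is not a confound).
    """
    presets = {
        "feasibility": ([7.0, 11.0, 13.0, 16.0, 21.0, 25.0, 30.0], 8),
        "retest": ([7.0, 18.0, 25.0, 30.0], 5),
    }
    if name not in presets:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    shells, n_b0 = presets[name]
    dirs = generate_directions(60, seed=seed)
    return Protocol(
        shells=shells,
        directions=[dirs] * len(shells),
        n_b0=n_b0,
        delta=MAGNUS_300["delta"],
        Delta=MAGNUS_300["Delta"],
        g_nominal=MAGNUS_300["g_max"],
        name=name,
    )


def volume_table(protocol: Protocol):
    """Flatten a protocol into per-volume (bvals, bvecs) with interspersed b=0.

    b=0 volumes are placed at evenly spaced positions in the series, the
    remaining slots are filled shell by shell.
    """
    n_vol = protocol.n_volumes
    bvals = np.zeros(n_vol)
    bvecs = np.zeros((n_vol, 3))
    b0_pos = np.unique(
        np.round(np.linspace(0, n_vol - 1, protocol.n_b0)).astype(int)
    )
    dwi_pos = np.setdiff1d(np.arange(n_vol), b0_pos)
    k = 0
    for b, dirs in zip(protocol.shells, protocol.directions):
        for d in dirs:
            bvals[dwi_pos[k]] = b
            bvecs[dwi_pos[k]] = d
            k += 1
    return bvals, bvecs


def sample_watson(mu: np.ndarray, kappa: float, n: int, rng) -> np.ndarray:
    """Sample axes from a Watson distribution about mean axis mu.

    Inverse-CDF sampling of u = cos(angle) with density ~ exp(kappa u^2) on
    [0, 1] (axial symmetry), uniform azimuth, rotated to mu.  ``mu`` may be
    (..., 3) for per-voxel axes; returns (..., n, 3).
    """
    mu = np.asarray(mu, dtype=float)
    lead = mu.shape[:-1]
    grid = np.linspace(0.0, 1.0, 2048)
    pdf = np.exp(kappa * (grid**2 - 1.0))
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    u = np.interp(rng.random(lead + (n,)), cdf, grid)
    phi = rng.random(lead + (n,)) * 2.0 * np.pi
    st = np.sqrt(1.0 - u**2)
    local = np.stack([st * np.cos(phi), st * np.sin(phi), u], axis=-1)
    # rotate local z to mu
    z = np.zeros(lead + (3,))
    z[..., 2] = 1.0
    axis = np.cross(z, mu)
    axis_n = np.linalg.norm(axis, axis=-1, keepdims=True)
    small = axis_n[..., 0] < 1e-12
    axis = np.where(axis_n > 1e-12, axis / np.maximum(axis_n, 1e-12), axis)
    cosang = np.clip(mu[..., 2], -1.0, 1.0)
    sinang = np.sqrt(np.clip(1.0 - cosang**2, 0.0, None))
    # Rodrigues rotation applied to each sample
    k_ = axis[..., None, :]
    c = cosang[..., None, None]
    s = sinang[..., None, None]
    rotated = (
        local * c
        + np.cross(np.broadcast_to(k_, local.shape), local) * s
        + k_ * np.sum(k_ * local, axis=-1, keepdims=True) * (1.0 - c)
    )
    # where mu ~ +-z the rotation axis is degenerate: keep local (mu=+z) or flip
    rotated = np.where(small[..., None, None], local * np.sign(cosang)[..., None, None], rotated)
    return rotated


@dataclass
class PhantomSpec:
    """Digital phantom: tissue maps, ensemble parameters, orientations, parcels."""

    shape: tuple
    voxel_size: tuple
    origin_offset: np.ndarray  # mm, position of the volume center in coil frame
    prob_wm: np.ndarray
    prob_gm: np.ndarray
    prob_csf: np.ndarray
    k_map: np.ndarray
    s_map: np.ndarray
    fiber_dirs: np.ndarray  # (x, y, z, 3)
    fiber_samples: np.ndarray  # (x, y, z, K, 3) Watson-dispersed axes
    parcels: np.ndarray
    parcel_table: pd.DataFrame
    dispersion_kappa: float = 16.0
    D0: float = 2.0
    D_gm: float = 1.0
    D_csf: float = 3.0
    support: tuple = (0.25, 5.0)
    n_radii: int = 128
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        center = (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.voxel_size)
        aff[:3, 3] = np.asarray(self.origin_offset) - center
        return aff

    def positions_mm(self) -> np.ndarray:
        """Voxel-center coordinates in the coil frame, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return idx * np.asarray(self.voxel_size) + self.affine[:3, 3]

    def true_reff(self) -> np.ndarray:
        """Ground-truth effective radius map (um) from the (k, s) maps."""
        out = np.zeros(self.shape)
        wm = self.k_map > 0
        ks = np.stack([self.k_map[wm], self.s_map[wm]], axis=1)
        vals = np.array(
            [distribution_reff(k, s, support=self.support) for k, s in ks]
        )
        out[wm] = vals
        return out


@dataclass
class SessionSpec:
    """One simulated acquisition: protocol preset, noise level, seeds, fields."""

    preset: str = "retest"
    snr: float = 20.0
    seed: int = 0
    perturbation: float = 0.0
    phase_amplitude: float = np.pi
    dispersion_samples: int = 32

    def __post_init__(self):
        if not (self.snr > 0):
            raise ValueError("SNR must be > 0 (use np.inf for noiseless)")


@dataclass
class SimulatedSession:
    """Simulated complex dMRI volume plus gradient table and ground truth."""

    data: np.ndarray  # complex, (*shape, n_volumes)
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray
    phantom: PhantomSpec
    spec: SessionSpec
    sigma: float
    b_local: np.ndarray  # (*shape, n_volumes) locally achieved b
    bvec_local: np.ndarray  # (*shape, n_volumes, 3)
    truth_reff: np.ndarray
    truth_daperp: np.ndarray
    s0_map: np.ndarray
    protocol: Protocol

    def write(self, outdir):
        """Write NIfTI volumes, FSL bval/bvec, parcels, truth and a sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aff = self.affine

        def save(name, arr):
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), aff),
                     str(outdir / name))

        save("dwi_real.nii", self.data.real)
        save("dwi_imag.nii", self.data.imag)
        save("truth_reff.nii", self.truth_reff)
        save("truth_daperp.nii", self.truth_daperp)
        save("prob_wm.nii", self.phantom.prob_wm)
        save("prob_gm.nii", self.phantom.prob_gm)
        save("prob_csf.nii", self.phantom.prob_csf)
        save("b_local.nii", self.b_local)
        nib.save(
            nib.Nifti1Image(self.phantom.parcels.astype(np.int16), aff),
            str(outdir / "parcels.nii"),
        )
        np.savetxt(outdir / "dwi.bval", self.bvals[None], fmt="%.3f")
        np.savetxt(outdir / "dwi.bvec", self.bvecs.T, fmt="%.8f")
        self.phantom.parcel_table.to_csv(outdir / "parcels.tsv", sep="\t", index=False)
        sidecar = {
            "preset": self.spec.preset,
            "snr": None if np.isinf(self.spec.snr) else self.spec.snr,
            "seed": self.spec.seed,
            "phantom_seed": self.phantom.seed,
            "sigma": self.sigma,
            "delta": self.protocol.delta,
            "Delta": self.protocol.Delta,
            "files": sorted(p.name for p in outdir.glob("*.nii")),
        }
        (outdir / "session.json").write_text(json.dumps(sidecar, indent=1))


def default_phantom(
    shape=(32, 32, 12),
    voxel_size=(2.2, 2.2, 2.2),
    origin_offset=(0.0, 0.0, 0.0),
    k_base: float = 2.0,
    s_base: float = 0.35,
    dispersion_kappa: float = 16.0,
    asymmetry: dict | None = None,
    s_multipliers=None,
    s_heterogeneity: float = 0.03,
    n_dispersion: int = 32,
    seed: int = 0,
) -> PhantomSpec:
    """Geometric phantom: WM core with 6 left/right parcel pairs, GM shell, CSF.

    Per parcel pair the gamma scale ``s`` is stepped over 0.8-1.3 x
    ``s_base`` so parcels span a range of effective radii; ``asymmetry``
    maps pair index -> left/right scale ratio (default: pair 2 has 5%
    larger s on the left).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    nx, ny, nz = shape
    u, v, w = np.meshgrid(
        *[np.linspace(-1, 1, s) for s in shape], indexing="ij"
    )
    head = (u / 0.97) ** 2 + (v / 0.97) ** 2 + (w / 0.97) ** 2 <= 1.0
    inner = (u / 0.68) ** 2 + (v / 0.68) ** 2 + (w / 0.75) ** 2 <= 1.0
    csf_blob = (u / 0.16) ** 2 + (v / 0.22) ** 2 + (w / 0.3) ** 2 <= 1.0

    prob_wm = np.where(inner & ~csf_blob, 0.92, 0.0)
    prob_gm = np.where(head & ~inner, 0.88, 0.0)
    prob_csf = np.where(csf_blob, 0.96, 0.0)
    from scipy import ndimage

    prob_wm = ndimage.gaussian_filter(prob_wm, 0.7)
    prob_gm = ndimage.gaussian_filter(prob_gm, 0.7)
    prob_csf = ndimage.gaussian_filter(prob_csf, 0.7)
    tot = prob_wm + prob_gm + prob_csf
    over = tot > 1.0
    for p in (prob_wm, prob_gm, prob_csf):
        p[over] /= tot[over]
    for p in (prob_wm, prob_gm, prob_csf):
        p[~head] = 0.0

    wm_mask = prob_wm > 0.55
    # parcels: hemisphere by sign of u, 3 bands in v x 2 bands in w -> 6 pairs
    band_v = np.clip(np.digitize(v, [-1 / 3, 1 / 3]), 0, 2)
    band_w = (w > 0).astype(int)
    pair = band_v * 2 + band_w  # 0..5
    hemi = (u >= 0).astype(int)  # 0 = left, 1 = right
    parcels = np.where(wm_mask, 10 * (pair + 1) + hemi + 1, 0)
    rows = []
    for p_ix in range(6):
        for h_ix, h in enumerate(("L", "R")):
            rows.append(
                {
                    "parcel_id": 10 * (p_ix + 1) + h_ix + 1,
                    "name": f"wm_parcel_{p_ix + 1}_{h}",
                    "pair": p_ix + 1,
                    "hemisphere": h,
                }
            )
    parcel_table = pd.DataFrame(rows)

    s_map = np.zeros(shape)
    mult = (
        np.array([0.8, 0.9, 1.0, 1.1, 1.2, 1.3])
        if s_multipliers is None
        else np.asarray(s_multipliers, dtype=float)
    )
    asymmetry = {2: 1.05} if asymmetry is None else asymmetry
    for p_ix in range(6):
        for h_ix in range(2):
            sel = wm_mask & (pair == p_ix) & (hemi == h_ix)
            s_val = s_base * mult[p_ix]
            ratio = asymmetry.get(p_ix + 1, 1.0)
            if h_ix == 0:  # left
                s_val *= ratio
            s_map[sel] = s_val
    # partial-volume WM rim outside the parcelled core still needs an ensemble
    s_map[(prob_wm > 0) & (s_map == 0)] = s_base
    # mild smooth heterogeneity within parcels
    bump = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
    bump /= max(np.abs(bump).max(), 1e-12)
    s_map *= 1.0 + s_heterogeneity * bump
    k_map = np.where(prob_wm > 0, k_base, 0.0)

    # smoothly varying fiber orientation, roughly along y
    az = 0.5 * np.sin(np.pi * u)
    el = 0.4 * w
    fiber = np.stack(
        [np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)], axis=-1
    )
    fiber /= np.linalg.norm(fiber, axis=-1, keepdims=True)
    samples = sample_watson(fiber, dispersion_kappa, n_dispersion, rng)

    return PhantomSpec(
        shape=shape,
        voxel_size=tuple(voxel_size),
        origin_offset=np.asarray(origin_offset, dtype=float),
        prob_wm=prob_wm,
        prob_gm=prob_gm,
        prob_csf=prob_csf,
        k_map=k_map,
        s_map=s_map,
        fiber_dirs=fiber,
        fiber_samples=samples,
        parcels=parcels,
        parcel_table=parcel_table,
        dispersion_kappa=dispersion_kappa,
        seed=seed,
    )


def _phase_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth random 3-D polynomial phase (order <= 3), |phase| <= amplitude."""
    coords = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    phase = np.zeros(shape)
    for px in range(4):
        for py in range(4 - px):
            for pz in range(4 - px - py):
                c = rng.normal()
                phase += c * coords[0] ** px * coords[1] ** py * coords[2] ** pz
    m = np.abs(phase).max()
    if m > 0:
        phase *= amplitude / m
    return phase


def _wm_signal_tables(phantom: PhantomSpec, protocol: Protocol, g_margin=1.3):
    """Per-WM-voxel ensemble-averaged perpendicular signal table over g.

    Returns (wm_index_array, E, g_grid) with E of shape (n_wm, n_g):
    E[v, j] = sum_r w_vr * S_perp(r, g_j), where w_vr are the r^2-weighted
    truncated-gamma weights of voxel v's ensemble.
    """
    wm = np.flatnonzero(phantom.k_map.ravel() > 0)
    base = CylinderEnsemble(
        k=2.0, s=0.35, D0=phantom.D0, support=phantom.support, n_radii=phantom.n_radii
    )
    radii, _ = base.radius_grid()
    g_max = g_for_b(max(protocol.shells), protocol.delta, protocol.Delta) * g_margin
    g_grid = np.linspace(0.0, g_max, 49)
    tab = cylinder_perp_table(
        radii, g_grid, protocol.delta, protocol.Delta, phantom.D0
    )  # (R, G)

    from scipy import stats as sps

    k = phantom.k_map.ravel()[wm]
    s = phantom.s_map.ravel()[wm]
    pdf = sps.gamma.pdf(radii[None, :], a=k[:, None], scale=s[:, None])
    w = pdf * radii[None, :] ** 2
    w[:, 0] *= 0.5
    w[:, -1] *= 0.5
    w /= w.sum(axis=1, keepdims=True)
    E = w @ tab  # (n_wm, G)
    return wm, E, g_grid


def simulate_session(
    phantom: PhantomSpec,
    spec: SessionSpec,
    coil: GradientCoilModel | None = None,
) -> SimulatedSession:
    """Forward-simulate one complex multi-shell session on the phantom.

    Per voxel and volume the noiseless signal is the tissue mixture of the
    dispersed cylinder-ensemble signal (WM, evaluated at the locally
    achieved gradient), and isotropic Gaussian decays (GM/CSF), times
    ``exp(i phase(x))``; complex channel noise has standard deviation
    ``mean WM b=0 signal / SNR``.
    """
    protocol = protocol_preset(spec.preset)
    bvals, bvecs = volume_table(protocol)
    n_vol = len(bvals)
    shape = phantom.shape
    n_vox = int(np.prod(shape))
    rng = np.random.default_rng(spec.seed)

    pos = phantom.positions_mm().reshape(-1, 3)
    if coil is not None:
        L = evaluate_gradient_tensor(coil, pos)  # (V, 3, 3)
    else:
        L = np.broadcast_to(np.eye(3), (n_vox, 3, 3))

    # local gradient table
    g_eff = np.einsum("vij,nj->vni", L, bvecs)  # (V, N, 3)
    g_norm = np.linalg.norm(g_eff, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        bvec_local = np.where(
            g_norm[..., None] > 0, g_eff / np.maximum(g_norm[..., None], 1e-12), 0.0
        )
    b_local = bvals[None, :] * g_norm**2

    p_wm = phantom.prob_wm.ravel()
    p_gm = phantom.prob_gm.ravel()
    p_csf = phantom.prob_csf.ravel()
    s0 = 1.0 * p_wm + 0.9 * p_gm + 1.1 * p_csf

    wm_idx, E, g_grid = _wm_signal_tables(phantom, protocol)
    dg = g_grid[1] - g_grid[0]
    axes = phantom.fiber_samples.reshape(n_vox, -1, 3)[wm_idx]  # (W, K, 3)
    n_k = axes.shape[1]
    shell_g = {b: g_for_b(b, protocol.delta, protocol.Delta) for b in protocol.shells}

    signal = np.empty((n_vox, n_vol))
    for j in range(n_vol):
        b = bvals[j]
        if b <= 0:
            signal[:, j] = s0
            continue
        bl = b_local[:, j]
        iso = p_gm * np.exp(-bl * phantom.D_gm) + p_csf * np.exp(-bl * phantom.D_csf)
        # WM: dispersion average at local gradient amplitude/direction
        gv = shell_g[b] * g_norm[wm_idx, j]  # (W,)
        cos_t = np.einsum("wkd,wd->wk", axes, bvec_local[wm_idx, j])  # (W, K)
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
        gp = gv[:, None] * sin_t
        t = np.clip(gp / dg, 0.0, len(g_grid) - 1.0 - 1e-9)
        i0 = t.astype(int)
        f = t - i0
        lo = np.take_along_axis(E, i0, axis=1)
        hi = np.take_along_axis(E, np.minimum(i0 + 1, len(g_grid) - 1), axis=1)
        s_perp = lo * (1.0 - f) + hi * f
        s_par = np.exp(-bl[wm_idx, None] * cos_t**2 * phantom.D0)
        s_wm = (s_perp * s_par).mean(axis=1)
        sig = iso.copy()
        sig[wm_idx] += p_wm[wm_idx] * s_wm
        signal[:, j] = sig * np.where(s0 > 0, 1.0, 0.0)

    phase = _phase_field(shape, spec.phase_amplitude, rng).ravel()
    clean = signal * np.exp(1j * phase)[:, None]

    wm_s0 = s0[p_wm > 0.55]
    sigma = 0.0 if np.isinf(spec.snr) else float(wm_s0.mean() / spec.snr)
    if sigma > 0:
        noise = rng.normal(scale=sigma, size=(n_vox, n_vol, 2))
        data = clean + noise[..., 0] + 1j * noise[..., 1]
    else:
        data = clean

    truth_reff = phantom.true_reff()
    truth_daperp = daperp_from_reff(
        truth_reff, protocol.delta, protocol.Delta, phantom.D0
    )

    return SimulatedSession(
        data=data.reshape(shape + (n_vol,)),
        bvals=bvals,
        bvecs=bvecs,
        affine=phantom.affine,
        phantom=phantom,
        spec=spec,
        sigma=sigma,
        b_local=b_local.reshape(shape + (n_vol,)),
        bvec_local=bvec_local.reshape(shape + (n_vol, 3)),
        truth_reff=truth_reff,
        truth_daperp=truth_daperp,
        s0_map=s0.reshape(shape),
        protocol=protocol,
    )


def perturb_phantom(phantom: PhantomSpec, scale: float, rng) -> PhantomSpec:
    """Multiplicative lognormal perturbation of the ground-truth Da_perp map.

    Da_perp scales with the fourth power of the effective radius, and the
    effective radius is proportional to the gamma scale s at fixed shape k,
    so a factor f on Da_perp maps to f**(1/4) on s.
    """
    if scale < 0:
        raise ValueError("perturbation scale must be >= 0")
    if scale == 0:
        return phantom
    f = rng.lognormal(mean=0.0, sigma=scale, size=phantom.s_map.shape)
    return replace(phantom, s_map=phantom.s_map * f**0.25)


def make_retest_pair(
    phantom: PhantomSpec,
    spec: SessionSpec,
    perturbation: float | None = None,
    seeds=(1, 2),
    coil: GradientCoilModel | None = None,
):
    """Two sessions of the same phantom for test-retest analysis.

    Session B gets fresh noise and (optionally) a lognormal perturbation of
    the ground-truth radial-diffusivity map, emulating physiological change
    between visits; ``perturbation=0`` repeats identical ground truth with
    new noise only.
    """
    if perturbation is None:
        perturbation = spec.perturbation
    spec_a = replace(spec, seed=seeds[0])
    spec_b = replace(spec, seed=seeds[1])
    sess_a = simulate_session(phantom, spec_a, coil=coil)
    rng = np.random.default_rng(seeds[1] + 77_000)
    phantom_b = perturb_phantom(phantom, perturbation, rng)
    sess_b = simulate_session(phantom_b, spec_b, coil=coil)
    return sess_a, sess_b
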