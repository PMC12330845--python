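"""End-to-end orchestration: configuration, stage execution, manifests.

Stages run in the fixed order

    simulate -> preprocess -> gnl -> mean -> fit -> stats

(any contiguous suffix may start from existing files on disk).  Each stage
reads its inputs from the run directory, writes its products into a
subdirectory, and the run manifest records config hash, seeds and SHA-256
hashes of every product, so reruns with identical configs are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import io as rio
from .forward_model import DetectabilityConfig, neuman_kappa, resolution_limit
from .gnl_correction import (
    GradientCoilModel,
    correct_bvec_bval,
    evaluate_gradient_tensor,
    magnus_like_coil,
)
from .preprocess_real import PhaseFilterConfig, background_stats, rectify_volume
from .reff_fit import fit_volume
from .repeatability import parcel_summary, asymmetry_table, tissue_masks
from .spherical_mean import PowderDecay, powder_decay

log = logging.getLogger("reffmap")

STAGE_ORDER = ["simulate", "preprocess", "gnl", "mean", "fit", "stats"]


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: Tuple[int, int, int] = (32, 32, 12)
    voxel_size: Tuple[float, float, float] = (2.2, 2.2, 2.2)
    origin_offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    k_base: float = 2.0
    s_base: float = 0.35
    dispersion_kappa: float = 16.0
    seed: int = 0


class RunConfig(BaseModel):
    """Single-document configuration for a pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    outdir: str
    stages: List[str] = STAGE_ORDER
    preset: str = "retest"
    snr: Optional[float] = 20.0  # None = noiseless
    seed: int = 0
    coil: str = "none"  # none | magnus_like | path to coefficient table
    gnl_correction: bool = True
    phantom: PhantomConfig = PhantomConfig()
    kernel_size: int = 3
    lmax: int = 6
    sh_reg: float = 0.0
    shell_spread_tol: float = 0.05
    D0: float = 2.0
    detect_snr: float = 20.0
    detect_z: float = 2.576
    fit_kernel: str = "powerlaw"

    @classmethod
    def from_json(cls, path):
        return cls.model_validate_json(Path(path).read_text())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _coil_from_config(cfg: RunConfig) -> GradientCoilModel | None:
    if cfg.coil == "none":
        return None
    if cfg.coil == "magnus_like":
        return magnus_like_coil()
    return GradientCoilModel.from_table(cfg.coil)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    bad = [s for s in config.stages if s not in STAGE_ORDER]
    if bad:
        raise ValueError(f"unknown stages {bad}; valid: {STAGE_ORDER}")
    order = [s for s in STAGE_ORDER if s in config.stages]
    if [s for s in config.stages if s in STAGE_ORDER] != order:
        raise ValueError(f"stages must respect the order {STAGE_ORDER}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "files": {},
    }
    for stage in order:
        t0 = time.time()
        log.info("stage %s ...", stage)
        products = _STAGE_FUNCS[stage](config, outdir)
        for p in products:
            manifest["files"][str(p.relative_to(outdir))] = _sha256(p)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    cfg_json = config.model_dump_json()
    manifest["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _require(outdir: Path, rel: str, stage: str, needed_by: str) -> Path:
    p = outdir / rel
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' requires {rel} produced by stage "
            f"'{stage}'; run that stage first"
        )
    return p


def _stage_simulate(cfg: RunConfig, outdir: Path):
    from .synthetic_data import SessionSpec, default_phantom, simulate_session

    ph = default_phantom(
        shape=cfg.phantom.shape,
        voxel_size=cfg.phantom.voxel_size,
        origin_offset=cfg.phantom.origin_offset,
        k_base=cfg.phantom.k_base,
        s_base=cfg.phantom.s_base,
        dispersion_kappa=cfg.phantom.dispersion_kappa,
        seed=cfg.phantom.seed,
    )
    snr = np.inf if cfg.snr is None else cfg.snr
    sess = simulate_session(
        ph, SessionSpec(preset=cfg.preset, snr=snr, seed=cfg.seed),
        coil=_coil_from_config(cfg),
    )
    d = outdir / "simulate"
    sess.write(d)
    return sorted(d.iterdir())


def _stage_preprocess(cfg: RunConfig, outdir: Path):
    import pandas as pd

    real_p = _require(outdir, "simulate/dwi_real.nii", "simulate", "preprocess")
    imag_p = _require(outdir, "simulate/dwi_imag.nii", "simulate", "preprocess")
    re, aff = rio.load_nifti(real_p)
    im, _ = rio.load_nifti(imag_p)
    cplx = re + 1j * im
    pf = PhaseFilterConfig(kernel_size=cfg.kernel_size)
    out_real = np.empty_like(re)
    out_imag = np.empty_like(re)
    bg = ~(np.abs(cplx).mean(axis=-1) > 1e-6)
    qc_rows = []
    for j in range(cplx.shape[-1]):
        r, i, _ = rectify_volume(cplx[..., j], pf)
        out_real[..., j] = r
        out_imag[..., j] = i
        if bg.any():
            qc_rows.append({"volume": j, **background_stats(r, i, bg)})
    d = outdir / "preprocess"
    d.mkdir(exist_ok=True)
    rio.save_nifti(out_real, aff, d / "real.nii")
    rio.save_nifti(out_imag, aff, d / "imag_residual.nii")
    pd.DataFrame(qc_rows).to_csv(d / "qc_background.tsv", sep="\t", index=False)
    return sorted(d.iterdir())


def _stage_gnl(cfg: RunConfig, outdir: Path):
    bval_p = _require(outdir, "simulate/dwi.bval", "simulate", "gnl")
    bvec_p = _require(outdir, "simulate/dwi.bvec", "simulate", "gnl")
    real_p = _require(outdir, "simulate/dwi_real.nii", "simulate", "gnl")
    bvals, bvecs = rio.read_bval_bvec(bval_p, bvec_p)
    data, aff = rio.load_nifti(real_p)
    shape = data.shape[:3]
    coil = _coil_from_config(cfg) if cfg.gnl_correction else None

    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float).reshape(-1, 3)
    pos = idx @ aff[:3, :3].T + aff[:3, 3]
    if coil is None:
        b_local = np.broadcast_to(bvals, (len(pos), len(bvals))).copy()
        vec_local = np.broadcast_to(bvecs, (len(pos),) + bvecs.shape).copy()
    else:
        L = evaluate_gradient_tensor(coil, pos)
        dwi = bvals > 0.5
        b_local = np.tile(bvals, (len(pos), 1))
        vec_local = np.tile(bvecs, (len(pos), 1, 1))
        bl, gl = correct_bvec_bval(bvals[dwi], bvecs[dwi], L[:, None, :, :])
        b_local[:, dwi] = bl
        vec_local[:, dwi, :] = gl
    d = outdir / "gnl"
    d.mkdir(exist_ok=True)
    rio.save_nifti(b_local.reshape(shape + (len(bvals),)), aff, d / "b_local.nii")
    rio.save_nifti(
        vec_local.reshape(shape + (len(bvals), 3)), aff, d / "bvec_local.nii"
    )
    return sorted(d.iterdir())


def _stage_mean(cfg: RunConfig, outdir: Path):
    import pandas as pd

    real_p = _require(outdir, "preprocess/real.nii", "preprocess", "mean")
    bval_p = _require(outdir, "simulate/dwi.bval", "simulate", "mean")
    bvec_p = _require(outdir, "simulate/dwi.bvec", "simulate", "mean")
    data, aff = rio.load_nifti(real_p)
    bvals, bvecs = rio.read_bval_bvec(bval_p, bvec_p)
    shape = data.shape[:3]
    b_local_p = outdir / "gnl" / "b_local.nii"
    b_local = None
    if b_local_p.exists():
        b_local, _ = rio.load_nifti(b_local_p)
        b_local = b_local.reshape(-1, len(bvals))
    decay = powder_decay(
        data.reshape(-1, data.shape[-1]),
        bvals,
        bvecs,
        b_local=b_local,
        lmax=cfg.lmax,
        reg=cfg.sh_reg,
        spread_tol=cfg.shell_spread_tol,
    )
    d = outdir / "mean"
    d.mkdir(exist_ok=True)
    n_sh = len(decay.shells)
    rio.save_nifti(
        decay.s_mean.reshape(shape + (n_sh * 2,)), aff, d / "spherical_mean.nii"
    )
    rio.save_nifti(decay.b_eff.reshape(shape + (n_sh * 2,)), aff, d / "b_eff.nii")
    rio.save_nifti(decay.s_b0.reshape(shape), aff, d / "s_b0.nii")
    stats = []
    for si, b in enumerate(decay.shells):
        be = decay.b_eff[:, si, :]
        be = be[np.isfinite(be)]
        stats.append(
            {
                "shell_b": b,
                "b_eff_mean": float(be.mean()),
                "b_eff_min": float(be.min()),
                "b_eff_max": float(be.max()),
            }
        )
    pd.DataFrame(stats).to_csv(d / "shells.tsv", sep="\t", index=False)
    np.savetxt(d / "shells.txt", decay.shells, fmt="%.6g")
    return sorted(d.iterdir())


def _stage_fit(cfg: RunConfig, outdir: Path):
    from .synthetic_data import MAGNUS_300

    mean_p = _require(outdir, "mean/spherical_mean.nii", "mean", "fit")
    beff_p = _require(outdir, "mean/b_eff.nii", "mean", "fit")
    s_mean, aff = rio.load_nifti(mean_p)
    b_eff, _ = rio.load_nifti(beff_p)
    shells = np.loadtxt(outdir / "mean" / "shells.txt", ndmin=1)
    shape = s_mean.shape[:3]
    n_sh = len(shells)
    decay = PowderDecay(
        shells=shells,
        b_eff=b_eff.reshape(-1, n_sh, 2),
        s_mean=s_mean.reshape(-1, n_sh, 2),
        s_b0=np.full(int(np.prod(shape)), np.nan),
    )
    wm_p = outdir / "simulate" / "prob_wm.nii"
    if wm_p.exists():
        p_wm, _ = rio.load_nifti(wm_p)
        mask = (p_wm > 0.55).reshape(-1)
    else:
        mask = np.isfinite(decay.s_mean[:, :, 0]).all(axis=1)
    delta, Delta = MAGNUS_300["delta"], MAGNUS_300["Delta"]
    meta_p = outdir / "simulate" / "session.json"
    if meta_p.exists():
        meta = json.loads(meta_p.read_text())
        delta, Delta = meta.get("delta", delta), meta.get("Delta", Delta)
    kappa = neuman_kappa(MAGNUS_300["g_max"], delta, cfg.D0)
    r_min = resolution_limit(
        DetectabilityConfig(SNR=cfg.detect_snr, n_dir=60, z=cfg.detect_z), kappa
    )
    maps = fit_volume(
        decay, delta, Delta, D0=cfg.D0, mask=mask, r_min=r_min,
        kernel=cfg.fit_kernel,
    )
    flagged = float(np.mean(~maps.converged[mask]))
    if flagged > 0.10:
        log.warning("%.1f%% of masked voxels failed to converge", 100 * flagged)
    d = outdir / "fit"
    d.mkdir(exist_ok=True)
    import dataclasses

    maps_3d = dataclasses.replace(
        maps,
        da_perp=maps.da_perp.reshape(shape),
        r_eff=maps.r_eff.reshape(shape),
        beta=maps.beta.reshape(shape),
        residual_norm=maps.residual_norm.reshape(shape),
        converged=maps.converged.reshape(shape),
        below_limit=maps.below_limit.reshape(shape),
        mask=maps.mask.reshape(shape),
    )
    maps_3d.to_nifti(d, aff)
    report = {
        "resolution_limit_um": r_min,
        "n_fitted": int(mask.sum()),
        "fraction_nonconverged": flagged,
        "median_reff": float(np.nanmedian(maps.r_eff[mask])),
    }
    (d / "fit_report.json").write_text(json.dumps(report, indent=1))
    return sorted(d.iterdir())


def _stage_stats(cfg: RunConfig, outdir: Path):
    import pandas as pd

    reff_p = _require(outdir, "fit/r_eff.nii", "fit", "stats")
    parcels_p = _require(outdir, "simulate/parcels.nii", "simulate", "stats")
    table_p = _require(outdir, "simulate/parcels.tsv", "simulate", "stats")
    wm_p = _require(outdir, "simulate/prob_wm.nii", "simulate", "stats")
    gm_p = outdir / "simulate" / "prob_gm.nii"
    csf_p = outdir / "simulate" / "prob_csf.nii"
    r_eff, _ = rio.load_nifti(reff_p)
    parcels, _ = rio.load_nifti(parcels_p)
    parcels = parcels.astype(int)
    table = pd.read_csv(table_p, sep="\t")
    p_wm, _ = rio.load_nifti(wm_p)
    p_gm, _ = rio.load_nifti(gm_p)
    p_csf, _ = rio.load_nifti(csf_p)
    wm, _, _ = tissue_masks(p_wm, p_gm, p_csf)
    summary = parcel_summary(r_eff, parcels, table, mask=wm)
    asym = asymmetry_table(
        summary[summary.hemisphere == "L"], summary[summary.hemisphere == "R"]
    )
    d = outdir / "stats"
    d.mkdir(exist_ok=True)
    summary.to_csv(d / "parcel_summary.tsv", sep="\t", index=False)
    asym.to_csv(d / "asymmetry.tsv", sep="\t", index=False)
    return sorted(d.iterdir())


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "gnl": _stage_gnl,
    "mean": _stage_mean,
    "fit": _stage_fit,
    "stats": _stage_stats,
}
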