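"""Spherical-harmonic representation and rotationally invariant spherical mean.

Per shell, the direction-resolved signal is expanded in an orthonormal real,
symmetric (even-order) spherical-harmonic basis by linear least squares; the
spherical mean is the zeroth-order coefficient divided by ``2 sqrt(pi)``
(the value of Y00 times the sphere average).  This removes the effect of
intra-voxel orientation dispersion without modelling it.

Voxelwise gradient-nonlinearity correction makes the effective b-value vary
across directions *within* a nominal shell.  Inside a single shell that
variation cannot be separated from orientation anisotropy (the local-b
pattern ||L g||^2 is itself a smooth order-2 function on the sphere and is
collinear with the SH basis), so no within-shell binning can identify it.
Instead each shell's spherical mean is paired with a *sensitivity-weighted*
effective b: to first order, S_mean_measured = S_bar(b*) with
b* = sum_q w_q b_q / sum_q w_q and w_q proportional to each direction's
contribution to the b-sensitivity of the mean, approximated by the measured
signal (directions with no surviving signal carry no b information).  A
residual-spread warning is emitted when the within-shell spread exceeds a
tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "ShBasis",
    "PowderDecay",
    "fit_sh",
    "spherical_mean_from_coeffs",
    "powder_decay",
]


def _real_sym_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Real symmetric SH design matrix (n_dir, n_coeff), even orders only."""
    v = np.asarray(directions, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.real)
    return np.stack(cols, axis=1)


def _lb_penalty(lmax: int) -> np.ndarray:
    """Diagonal Laplace-Beltrami weights l(l+1) per coefficient."""
    diags = []
    for l in range(0, lmax + 1, 2):
        diags.extend([l * (l + 1)] * (2 * l + 1))
    return np.asarray(diags, dtype=float)


@dataclass
class ShBasis:
    """Sampling scheme + real symmetric SH design matrix.

    Signals are assumed antipodally symmetric (only even orders enter).
    ``n_coeff = (lmax+1)(lmax+2)/2``; for the default lmax=6 and 60
    directions the system is comfortably overdetermined (28 coefficients).
    """

    directions: np.ndarray
    lmax: int = 6
    reg: float = 0.0

    def __post_init__(self):
        if self.lmax % 2 != 0:
            raise ValueError("lmax must be even")
        self.directions = np.asarray(self.directions, dtype=float)
        self.Y = _real_sym_basis(self.directions, self.lmax)
        if self.Y.shape[0] < self.Y.shape[1]:
            raise ValueError(
                f"underdetermined basis: {self.Y.shape[0]} directions for "
                f"{self.Y.shape[1]} coefficients (lmax={self.lmax})"
            )
        self.condition_number = float(np.linalg.cond(self.Y))
        A = self.Y.T @ self.Y
        if self.reg > 0:
            A = A + self.reg * np.diag(_lb_penalty(self.lmax) ** 2)
        if np.linalg.cond(A) > 1e10:
            raise np.linalg.LinAlgError(
                f"rank-deficient SH basis (condition number "
                f"{self.condition_number:.3g}); use more directions or "
                f"lower lmax"
            )
        self._solver = np.linalg.solve(A, self.Y.T)  # (n_coeff, n_dir)

    @property
    def n_coeff(self) -> int:
        return self.Y.shape[1]


def fit_sh(signals: np.ndarray, basis: ShBasis) -> np.ndarray:
    """Least-squares SH coefficients for signals (..., n_dir) -> (..., n_coeff)."""
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != basis.Y.shape[0]:
        raise ValueError("signal count must equal direction count")
    return signals @ basis._solver.T


def spherical_mean_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """Sphere average from SH coefficients: c00 / (2 sqrt(pi))."""
    coeffs = np.asarray(coeffs, dtype=float)
    return coeffs[..., 0] / (2.0 * np.sqrt(np.pi))


@dataclass
class PowderDecay:
    """Per-voxel spherical-mean decay: (b_eff, S_bar) pairs per shell bin.

    Arrays have shape (n_voxels, n_shells, n_bins); the default pipeline
    uses one bin per shell (the second slot stays NaN and exists so callers
    can carry alternative binnings).  ``shells`` holds the nominal shell
    b-values; ``s_b0`` the arithmetic mean of the non-diffusion volumes
    (QC only, not used in the decay fit).
    """

    shells: np.ndarray
    b_eff: np.ndarray
    s_mean: np.ndarray
    s_b0: np.ndarray

    def pairs(self, voxel: int):
        """(b, S_bar) arrays for one voxel with NaN bins dropped."""
        b = self.b_eff[voxel].ravel()
        s = self.s_mean[voxel].ravel()
        good = np.isfinite(b) & np.isfinite(s)
        return b[good], s[good]


def powder_decay(
    signals: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    b_local: np.ndarray | None = None,
    lmax: int = 6,
    reg: float = 0.0,
    spread_tol: float = 0.05,
    b0_thresh: float = 0.5,
) -> PowderDecay:
    """Shell-wise spherical means for a stack of voxels.

    Parameters
    ----------
    signals : (n_voxels, n_volumes)
        Real-valued signals (spatial dimensions flattened by the caller).
    bvals, bvecs : (n_volumes,), (n_volumes, 3)
        Nominal gradient table; volumes with ``bval <= b0_thresh`` are
        treated as b=0.
    b_local : (n_voxels, n_volumes), optional
        Voxelwise effective b-values after gradient-nonlinearity correction.
        Each shell's spherical mean is paired with the signal-weighted mean
        of its local b-values; a warning is emitted if the within-shell
        spread exceeds ``spread_tol`` anywhere (the first-order weighting
        is less accurate there).
    """
    signals = np.asarray(signals, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    n_vox, n_vol = signals.shape
    if bvals.shape[0] != n_vol or bvecs.shape[0] != n_vol:
        raise ValueError("gradient table does not match the number of volumes")

    is_b0 = bvals <= b0_thresh
    shell_bs = np.unique(bvals[~is_b0])
    s_b0 = (
        signals[:, is_b0].mean(axis=1) if np.any(is_b0) else np.full(n_vox, np.nan)
    )

    b_eff = np.full((n_vox, len(shell_bs), 2), np.nan)
    s_mean = np.full((n_vox, len(shell_bs), 2), np.nan)

    for si, b in enumerate(shell_bs):
        idx = np.flatnonzero(np.abs(bvals - b) < 1e-9)
        dirs = bvecs[idx]
        basis = ShBasis(dirs, lmax=lmax, reg=reg)
        shell_sig = signals[:, idx]
        coeffs = fit_sh(shell_sig, basis)
        s_mean[:, si, 0] = spherical_mean_from_coeffs(coeffs)
        if b_local is None:
            b_eff[:, si, 0] = b
        else:
            bl = np.asarray(b_local, dtype=float)[:, idx]
            spread = (bl.max(axis=1) - bl.min(axis=1)) / bl.mean(axis=1)
            if np.any(spread > spread_tol):
                warnings.warn(
                    f"within-shell local-b spread exceeds {spread_tol:.0%} "
                    f"for {int((spread > spread_tol).sum())} voxels at "
                    f"b={b:g}; first-order effective-b weighting in use",
                    RuntimeWarning,
                    stacklevel=2,
                )
            w = np.clip(shell_sig, 0.0, None)
            tot = w.sum(axis=1)
            good = tot > 0
            b_eff[good, si, 0] = (w[good] * bl[good]).sum(axis=1) / tot[good]
            b_eff[~good, si, 0] = bl[~good].mean(axis=1)

    return PowderDecay(shells=shell_bs, b_eff=b_eff, s_mean=s_mean, s_b0=s_b0)
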