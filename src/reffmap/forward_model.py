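"""Forward models of PGSE diffusion attenuation in white-matter-like media.

The central object is the perpendicular signal of water restricted inside an
impermeable cylinder under a pulsed-gradient spin-echo (PGSE) experiment.
Two implementations are provided:

* :func:`neuman_signal` — the long-pulse (Neuman) closed form
  ``ln S_perp = -kappa * r**4`` with ``kappa = (7/96) * (gamma*g)**2 * delta / D0``,
  valid when ``delta * D0 / r**2 >> 1``;
* :func:`gpa_cylinder_perp` — the finite-pulse Gaussian-phase-approximation
  series (van Gelderen form), valid across pulse regimes and reducing to the
  Neuman form in the long-pulse limit.

On top of these, :func:`cylinder_signal` combines the stick (1-D) parallel
decay with the perpendicular restriction, :func:`powder_average` integrates
over orientations (and, for gamma-distributed ensembles, over radii with
cross-sectional r^2 volume weighting), and :func:`resolution_limit` computes
the smallest effective radius statistically distinguishable from zero at a
given SNR and protocol.
"""

from __future__ import annotations

import functools
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import linalg, special, stats

from .units import GAMMA

__all__ = [
    "Protocol",
    "CylinderEnsemble",
    "AttenuationCurve",
    "DetectabilityConfig",
    "InvalidProtocolError",
    "compute_b_value",
    "g_for_b",
    "neuman_kappa",
    "neuman_signal",
    "gpa_cylinder_perp",
    "mcf_cylinder_perp",
    "cylinder_perp_table",
    "stick_spherical_mean",
    "cylinder_signal",
    "powder_average",
    "distribution_reff",
    "resolution_limit",
]


class InvalidProtocolError(ValueError):
    """Raised for physically inconsistent acquisition parameters."""


def compute_b_value(g, delta, Delta, gamma=GAMMA):
    """PGSE b-value ``b = (gamma*g*delta)**2 * (Delta - delta/3)`` in ms/um^2.

    Parameters
    ----------
    g : float or array
        Gradient amplitude in mT/m.
    delta, Delta : float
        Gradient pulse width and mixing time in ms, ``0 < delta < Delta``.
    """
    if delta <= 0 or Delta <= delta:
        raise InvalidProtocolError(
            f"require 0 < delta < Delta, got delta={delta}, Delta={Delta}"
        )
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise InvalidProtocolError("gradient amplitude must be >= 0")
    b = (gamma * g * delta) ** 2 * (Delta - delta / 3.0)
    return b if b.ndim else float(b)


def g_for_b(b, delta, Delta, gamma=GAMMA):
    """Gradient amplitude (mT/m) achieving b-value ``b`` at fixed delta/Delta."""
    if delta <= 0 or Delta <= delta:
        raise InvalidProtocolError(
            f"require 0 < delta < Delta, got delta={delta}, Delta={Delta}"
        )
    b = np.asarray(b, dtype=float)
    g = np.sqrt(b / (Delta - delta / 3.0)) / (gamma * delta)
    return g if g.ndim else float(g)


@dataclass
class Protocol:
    """A multi-shell PGSE acquisition.

    ``shells`` are the non-zero b-values (ms/um^2); ``directions`` holds one
    (n, 3) unit-vector array per shell; ``n_b0`` non-diffusion volumes are
    interspersed in the volume ordering produced by
    :meth:`reffmap.synthetic_data` helpers.
    """

    shells: list
    directions: list
    n_b0: int
    delta: float
    Delta: float
    g_nominal: float
    gamma: float = GAMMA
    name: str = ""

    def __post_init__(self):
        if self.delta <= 0 or self.Delta <= self.delta:
            raise InvalidProtocolError("require 0 < delta < Delta")
        self.shells = [float(b) for b in self.shells]
        if any(b < 0 for b in self.shells):
            raise InvalidProtocolError("b-values must be >= 0")
        if len(self.directions) != len(self.shells):
            raise InvalidProtocolError("one direction set per shell required")
        self.directions = [np.asarray(d, dtype=float) for d in self.directions]
        for d in self.directions:
            norms = np.linalg.norm(d, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise InvalidProtocolError("direction vectors must be unit-norm")
        if self.n_b0 < 0:
            raise InvalidProtocolError("n_b0 must be >= 0")

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + sum(len(d) for d in self.directions)

    def shell_gradient(self, b) -> float:
        """Gradient amplitude (mT/m) realising shell b at this delta/Delta."""
        return g_for_b(b, self.delta, self.Delta, self.gamma)

    def to_json(self, path):
        doc = {
            "name": self.name,
            "shells": self.shells,
            "n_b0": self.n_b0,
            "delta": self.delta,
            "Delta": self.Delta,
            "g_nominal": self.g_nominal,
            "gamma": self.gamma,
            "directions": [d.tolist() for d in self.directions],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path):
        doc = json.loads(Path(path).read_text())
        return cls(
            shells=doc["shells"],
            directions=[np.asarray(d) for d in doc["directions"]],
            n_b0=doc["n_b0"],
            delta=doc["delta"],
            Delta=doc["Delta"],
            g_nominal=doc["g_nominal"],
            gamma=doc.get("gamma", GAMMA),
            name=doc.get("name", ""),
        )


@dataclass
class CylinderEnsemble:
    """A single cylinder (``kind='delta'``) or a gamma radius distribution.

    Gamma ensembles are truncated to ``support`` (radius, um). The default
    support [0.25, 5.0] um corresponds to cylinder diameters of 0.5-10 um.
    Signal contributions are weighted by cross-sectional area (r^2 per unit
    length), which is what makes the powder-averaged estimate tail-weighted.
    """

    kind: str = "gamma"
    radius: float = 1.0
    k: float = 2.0
    s: float = 0.35
    D0: float = 2.0
    support: tuple = (0.25, 5.0)
    n_radii: int = 128

    def __post_init__(self):
        if self.kind not in ("delta", "gamma"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.D0 <= 0:
            raise ValueError("D0 must be > 0")
        if self.kind == "delta" and self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.kind == "gamma":
            if self.k <= 0 or self.s <= 0:
                raise ValueError("gamma shape and scale must be > 0")
            if not self.support[0] < self.support[1]:
                raise ValueError("support must satisfy r_lo < r_hi")

    def radius_grid(self):
        """(radii, signal weights): r^2-volume-weighted, normalised to 1."""
        if self.kind == "delta":
            return np.array([self.radius]), np.array([1.0])
        r = np.linspace(self.support[0], self.support[1], self.n_radii)
        pdf = stats.gamma.pdf(r, a=self.k, scale=self.s)
        w = pdf * r**2
        tot = np.trapezoid(w, r)
        if tot <= 0:
            raise ValueError("gamma distribution has no mass on the support")
        # trapezoid quadrature folded into the weights
        dr = np.gradient(r)
        w = w * dr
        w[0] *= 0.5
        w[-1] *= 0.5
        return r, w / w.sum()

    def effective_radius(self) -> float:
        """Tail-weighted effective radius (<r^6>/<r^2>)^(1/4) over the pdf."""
        if self.kind == "delta":
            return self.radius
        return distribution_reff(self.k, self.s, support=self.support)


@dataclass
class AttenuationCurve:
    """Powder-averaged signal fraction versus b-value."""

    b: np.ndarray
    S: np.ndarray

    def to_tsv(self, path):
        pd.DataFrame({"b": self.b, "S_bar": self.S}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t")
        return cls(b=df["b"].to_numpy(), S=df["S_bar"].to_numpy())


@dataclass
class DetectabilityConfig:
    """Noise model for the detectability (resolution) limit.

    ``SNR`` is the per-volume signal-to-noise at b=0; averaging n_dir
    directions reduces the spherical-mean noise to ``1/(SNR*sqrt(n_dir))``;
    ``z`` is the detection z-score (default two-sided 99%).
    """

    SNR: float = 20.0
    n_dir: int = 60
    z: float = 2.576

    def __post_init__(self):
        if self.SNR <= 0 or self.n_dir < 1 or self.z <= 0:
            raise ValueError("require SNR > 0, n_dir >= 1, z > 0")

    @property
    def sigma_sm(self) -> float:
        return 1.0 / (self.SNR * math.sqrt(self.n_dir))


def neuman_kappa(g, delta, D0, gamma=GAMMA):
    """Detectability attenuation constant kappa = (7/96)(gamma*g)^2 delta / D0.

    Units: um^-4 (g in mT/m, delta in ms, D0 in um^2/ms).

    Convention note: the long-pulse (delta >> r^2/D0) limit of the PGSE
    cylinder signal is ``ln S_perp = -2 kappa r^4`` — i.e. the physical
    Neuman-limit constant is (7/48), consistent with the effective-radius
    mapping ``r_eff = ((48/7) delta (Delta - delta/3) D0 Da_perp)**(1/4)``
    and with the series/matrix/Monte-Carlo models in this module.  The
    (7/96) constant kept here (half the mean-squared phase) is the
    convention under which the published detectability bounds
    (:func:`resolution_limit`) are defined; the two uses are deliberately
    kept as printed.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0) or delta <= 0 or D0 <= 0:
        raise ValueError("all of g, delta, D0 must be > 0")
    kappa = (7.0 / 96.0) * (gamma * g) ** 2 * delta / D0
    return kappa if kappa.ndim else float(kappa)


def neuman_signal(r, kappa):
    """Perpendicular cylinder signal exp(-kappa * r**4) in the Neuman limit."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    if np.any(np.asarray(kappa) < 0):
        raise ValueError("kappa must be >= 0")
    S = np.exp(-kappa * r**4)
    return S if S.ndim else float(S)


@functools.lru_cache(maxsize=16)
def _bessel_deriv_roots(n_roots: int) -> np.ndarray:
    """Positive roots of J1'(x) (derivative of Bessel J of order one)."""
    return special.jnp_zeros(1, n_roots)


def gpa_cylinder_perp(
    r,
    g_perp,
    delta,
    Delta,
    D0,
    n_roots: int = 20,
    gamma=GAMMA,
    check_convergence: bool = False,
):
    """Gaussian-phase-approximation PGSE signal perpendicular to a cylinder.

    van Gelderen series over roots ``mu_m`` of J1'::

        -ln S = 2 (gamma g)^2 sum_m
                [2 a_m delta - 2 + 2 e^{-a_m delta} + 2 e^{-a_m Delta}
                 - e^{-a_m (Delta-delta)} - e^{-a_m (Delta+delta)}]
                / (D0^2 alpha_m^6 (alpha_m^2 r^2 - 1))

    with ``alpha_m = mu_m / r`` and ``a_m = D0 * alpha_m**2``.

    Broadcasts over ``r`` and ``g_perp``. ``g_perp`` is the gradient
    component perpendicular to the cylinder axis, in mT/m.
    """
    if n_roots < 10:
        raise ValueError("n_roots must be >= 10")
    r = np.asarray(r, dtype=float)
    g_perp = np.asarray(g_perp, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    scalar = r.ndim == 0 and g_perp.ndim == 0
    r, g_perp = np.broadcast_arrays(np.atleast_1d(r), np.atleast_1d(g_perp))

    mu = _bessel_deriv_roots(n_roots)  # (M,)
    rr = r[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha2 = (mu / rr) ** 2  # (..., M)
        a = D0 * alpha2
        num = (
            2.0 * a * delta
            - 2.0
            + 2.0 * np.exp(-a * delta)
            + 2.0 * np.exp(-a * Delta)
            - np.exp(-a * (Delta - delta))
            - np.exp(-a * (Delta + delta))
        )
        den = D0**2 * alpha2**3 * (mu**2 - 1.0)
        terms = num / den
    terms = np.where(rr > 0, terms, 0.0)
    if check_convergence:
        tail = np.abs(terms[..., -1])
        total = np.abs(terms).sum(axis=-1)
        bad = (total > 0) & (tail > 1e-9 * total)
        if np.any(bad):
            warnings.warn(
                "GPA cylinder series may not be converged at "
                f"n_roots={n_roots}; increase n_roots",
                RuntimeWarning,
                stacklevel=2,
            )
    log_s = -2.0 * (gamma * g_perp) ** 2 * terms.sum(axis=-1)
    S = np.exp(log_s)
    return float(S.reshape(())) if scalar else S


@functools.lru_cache(maxsize=8)
def _disk_basis(n_ang: int, n_rad: int, n_quad: int = 200):
    """Neumann-Laplacian eigenbasis of the unit disk, cosine sector.

    Returns (lam, X) where ``lam`` holds the dimensionless eigenvalues
    ``alpha_nk**2`` (roots of J_n') and ``X`` the matrix elements of
    ``rho*cos(theta)`` between the orthonormal eigenfunctions
    ``R_nk(rho) * Phi_n(theta)``.  Only the cosine angular sector is needed:
    a gradient along x starting from the uniform mode never populates the
    sine sector.
    """
    # radial Gauss-Legendre quadrature on [0, 1]
    xq, wq = leggauss(n_quad)
    rho = 0.5 * (xq + 1.0)
    wq = 0.5 * wq

    lam_list = []
    rad_funcs = []  # per mode: radial profile on quadrature grid
    ang_idx = []
    for n in range(n_ang + 1):
        if n == 0:
            alphas = np.concatenate([[0.0], special.jnp_zeros(0, n_rad - 1)])
        else:
            alphas = special.jnp_zeros(n, n_rad)
        for a in alphas:
            f = special.jv(n, a * rho)
            norm = np.sqrt(np.sum(f * f * rho * wq))
            rad_funcs.append(f / norm)
            lam_list.append(a * a)
            ang_idx.append(n)
    lam = np.array(lam_list)
    ang_idx = np.array(ang_idx)
    F = np.array(rad_funcs)  # (n_modes, n_quad)

    # radial part of <i| rho cos(theta) |j>
    T = (F * rho * wq) @ (F * rho).T  # int R_i R_j rho^2 drho
    n_i = ang_idx[:, None]
    n_j = ang_idx[None, :]
    ang = np.zeros_like(T)
    ang[(n_i == 0) & (n_j == 1)] = 1.0 / np.sqrt(2.0)
    ang[(n_i == 1) & (n_j == 0)] = 1.0 / np.sqrt(2.0)
    ang[(np.abs(n_i - n_j) == 1) & (n_i >= 1) & (n_j >= 1)] = 0.5
    X = T * ang

    order = np.argsort(lam, kind="stable")
    return lam[order], X[np.ix_(order, order)]


def mcf_cylinder_perp(
    r,
    g_perp,
    delta,
    Delta,
    D0,
    n_ang: int = 10,
    n_rad: int = 8,
    gamma=GAMMA,
):
    """Matrix-formalism PGSE signal perpendicular to an impermeable cylinder.

    Propagates the Bloch-Torrey equation exactly (up to basis truncation) in
    the Neumann eigenbasis of the disk: with ``H_pm = D0 L +- i gamma g X``
    (L the Laplacian, X the transverse position operator),

        S = [exp(-delta H_+) exp(-(Delta-delta) D0 L) exp(-delta H_-)]_00 .

    Unlike the Gaussian-phase approximation this remains accurate at strong
    dephasing (large radius and/or gradient).  Broadcasts over scalar
    ``r``/``g_perp`` pairs via a python loop; use
    :func:`cylinder_perp_table` for bulk evaluation.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    g_arr = np.atleast_1d(np.asarray(g_perp, dtype=float))
    r_b, g_b = np.broadcast_arrays(r_arr, g_arr)
    lam, X = _disk_basis(n_ang, n_rad)
    out = np.empty(r_b.shape)
    it = np.nditer([r_b, g_b], flags=["multi_index"])
    for rv, gv in it:
        rv = float(rv)
        gv = float(gv)
        if rv < 0:
            raise ValueError("radius must be >= 0")
        if rv == 0 or gv == 0:
            out[it.multi_index] = 1.0
            continue
        L = D0 * lam / rv**2  # 1/ms
        iGX = 1j * gamma * gv * rv * X  # rad/ms
        U_pulse = linalg.expm(-delta * (np.diag(L) + iGX))
        mid = np.exp(-(Delta - delta) * L)
        # apply exp(-delta H_-) to e_0 (= conj of U since L, X are real),
        # free decay between the pulses, then exp(-delta H_+)
        c = U_pulse.conj()[:, 0]
        c = mid * c
        c = U_pulse @ c
        out[it.multi_index] = float(np.real(c[0]))
    return float(out.reshape(())) if np.ndim(r) == 0 and np.ndim(g_perp) == 0 else out


@functools.lru_cache(maxsize=32)
def _perp_table_cached(key):
    radii, g_grid, delta, Delta, D0, n_ang, n_rad = key
    radii = np.array(radii)
    g_grid = np.array(g_grid)
    R, G = np.meshgrid(radii, g_grid, indexing="ij")
    return mcf_cylinder_perp(R, G, delta, Delta, D0, n_ang=n_ang, n_rad=n_rad)


def cylinder_perp_table(radii, g_grid, delta, Delta, D0, n_ang=10, n_rad=8):
    """Cached (n_radii, n_g) table of matrix-formalism perpendicular signals."""
    key = (
        tuple(float(x) for x in np.asarray(radii)),
        tuple(float(x) for x in np.asarray(g_grid)),
        float(delta),
        float(Delta),
        float(D0),
        int(n_ang),
        int(n_rad),
    )
    return _perp_table_cached(key)


def stick_spherical_mean(b, D0):
    """Closed-form powder average of a zero-radius stick.

    ``S_bar(b) = sqrt(pi)/2 * erf(sqrt(b D0)) / sqrt(b D0)``; at high b this
    approaches the ``b**-1/2`` power law.  ``b = 0`` returns 1.
    """
    b = np.asarray(b, dtype=float)
    x = np.sqrt(np.maximum(b * D0, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(x > 0, 0.5 * np.sqrt(np.pi) * special.erf(x) / np.maximum(x, 1e-300), 1.0)
    return S if S.ndim else float(S)


def cylinder_signal(
    r, theta, b, delta, Delta, D0, gamma=GAMMA, method="mcf", n_roots=20
):
    """Signal of a cylinder whose axis makes angle ``theta`` with the gradient.

    Parallel decay is the free 1-D stick ``exp(-b cos^2(theta) D0)``;
    perpendicular decay is the restricted-cylinder attenuation at the
    gradient component ``g sin(theta)`` where g realises b at (delta, Delta).
    ``method`` selects the matrix formalism (default) or the GPA series.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > np.pi)):
        raise ValueError("theta must lie in [0, pi]")
    g = g_for_b(b, delta, Delta, gamma)
    s_par = np.exp(-b * np.cos(theta) ** 2 * D0)
    g_perp = g * np.abs(np.sin(theta))
    if method == "gpa":
        s_perp = gpa_cylinder_perp(
            r, g_perp, delta, Delta, D0, n_roots=n_roots, gamma=gamma
        )
    elif method == "mcf":
        s_perp = mcf_cylinder_perp(r, g_perp, delta, Delta, D0, gamma=gamma)
    else:
        raise ValueError(f"unknown method {method!r}")
    S = s_par * s_perp
    return S if np.ndim(S) else float(S)


def powder_average(
    ensemble: CylinderEnsemble,
    b,
    delta,
    Delta,
    gamma=GAMMA,
    method: str = "mcf",
    n_theta: int = 64,
    n_roots: int = 20,
    n_g_table: int = 49,
):
    """Orientation (and radius) average of the cylinder signal at b-value(s) b.

    The orientation integral ``int_0^1 S(cos t) d(cos t)`` uses fixed
    Gauss-Legendre quadrature with ``n_theta`` nodes; gamma ensembles are
    averaged over the r^2-weighted truncated radius grid.  ``b=0`` maps to 1.

    With ``method='mcf'`` (default) the perpendicular signal is drawn from a
    cached matrix-formalism table, linearly interpolated over the
    perpendicular gradient amplitude; ``method='gpa'`` evaluates the GPA
    series directly (long-pulse regime only).
    """
    scalar = np.ndim(b) == 0
    b = np.atleast_1d(np.asarray(b, dtype=float))
    D0 = ensemble.D0
    radii, w_r = ensemble.radius_grid()

    # Gauss-Legendre on u = cos(theta) in [0, 1] (antipodal symmetry)
    x, w = leggauss(n_theta)
    u = 0.5 * (x + 1.0)
    w = 0.5 * w
    sin_t = np.sqrt(1.0 - u**2)

    out = np.ones_like(b)
    nz = b > 0
    if np.any(nz):
        bb = b[nz]
        g = g_for_b(bb, delta, Delta, gamma)  # (B,)
        gp = g[:, None, None] * sin_t[None, :, None]  # (B, U, 1)
        if method == "gpa":
            S_perp = gpa_cylinder_perp(
                radii[None, None, :], gp, delta, Delta, D0,
                n_roots=n_roots, gamma=gamma,
            )
        elif method == "mcf":
            g_grid = np.linspace(0.0, float(g.max()), n_g_table)
            tab = cylinder_perp_table(radii, g_grid, delta, Delta, D0)  # (R, G)
            S_perp = _interp_g(tab, g_grid, gp[..., 0])  # (B, U, R)
        else:
            raise ValueError(f"unknown method {method!r}")
        s_par = np.exp(-bb[:, None] * u[None, :] ** 2 * D0)  # (B, U)
        S_r = np.einsum("bur,u->br", S_perp * s_par[:, :, None], w)
        out[nz] = S_r @ w_r
    return float(out[0]) if scalar else out


def _interp_g(table, g_grid, g):
    """Linear interpolation of a (R, G) signal table over g; returns (..., R)."""
    dg = g_grid[1] - g_grid[0]
    t = np.clip(g / dg, 0.0, len(g_grid) - 1.0 - 1e-12)
    i = t.astype(int)
    f = t - i
    lo = table[:, i]  # (R, ...)
    hi = table[:, i + 1]
    vals = lo * (1.0 - f) + hi * f
    return np.moveaxis(vals, 0, -1)


def distribution_reff(k, s, support=None):
    """Effective radius (<r^6>/<r^2>)^(1/4) of a gamma radius distribution.

    Untruncated: closed form ``s * ((k+2)(k+3)(k+4)(k+5))**(1/4)``. With a
    truncation ``support=(r_lo, r_hi)`` the moments are computed numerically.
    """
    if k <= 0 or s <= 0:
        raise ValueError("gamma shape and scale must be > 0")
    if support is None:
        return s * ((k + 2) * (k + 3) * (k + 4) * (k + 5)) ** 0.25
    r_lo, r_hi = support
    r = np.linspace(r_lo, r_hi, 4096)
    pdf = stats.gamma.pdf(r, a=k, scale=s)
    m2 = np.trapezoid(pdf * r**2, r)
    m6 = np.trapezoid(pdf * r**6, r)
    return float((m6 / m2) ** 0.25)


def resolution_limit(config: DetectabilityConfig, kappa: float) -> float:
    """Smallest radius whose Neuman spherical-mean attenuation is detectable.

    The attenuation ``1 - exp(-kappa r^4) ~= kappa r^4`` is compared against
    ``z`` times the spherical-mean noise sd ``1/(SNR*sqrt(n_dir))``; solving
    at equality gives ``r_min = (z * sigma_sm / kappa)**0.25``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return float((config.z * config.sigma_sm / kappa) ** 0.25)
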