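"""Tissue masking, parcel summaries and test-retest statistics.

Implements the agreement statistics used for test-retest radius mapping:
Bland-Altman limits of agreement, the reproducibility coefficient
(RPC = 1.96 x SD of the paired differences), within-subject coefficient of
variation, two-way random-effects absolute-agreement single-measure
intraclass correlation ICC(2,1), Spearman rank correlation, and left/right
parcel asymmetry indices.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "tissue_masks",
    "parcel_summary",
    "bland_altman",
    "rpc",
    "cov_within_subject",
    "icc",
    "asymmetry_table",
    "repeatability_report",
]

WM_THRESH = 0.55
GM_THRESH = 0.8
CSF_THRESH = 0.9


def tissue_masks(prob_wm, prob_gm, prob_csf):
    """Boolean (WM, GM, CSF) masks from posterior probability maps.

    Strict thresholds (p > 0.55 WM, p > 0.8 GM, p > 0.9 CSF) guard against
    partial-volume voxels; overlaps are resolved with priority
    CSF > GM > WM so the returned masks are mutually disjoint.
    """
    arrs = [np.asarray(p, dtype=float) for p in (prob_wm, prob_gm, prob_csf)]
    if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
        raise ValueError("probability map shapes must match")
    for a in arrs:
        if np.any((a < 0) | (a > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
    wm = arrs[0] > WM_THRESH
    gm = arrs[1] > GM_THRESH
    csf = arrs[2] > CSF_THRESH
    gm &= ~csf
    wm &= ~csf & ~gm
    return wm, gm, csf


def parcel_summary(
    value_map, parcels, parcel_table: pd.DataFrame, mask=None
) -> pd.DataFrame:
    """Mean/SD/voxel-count of a map per labelled parcel.

    Parcels with no voxels (after masking) are dropped.
    """
    value_map = np.asarray(value_map, dtype=float)
    parcels = np.asarray(parcels)
    if value_map.shape != parcels.shape:
        raise ValueError("map and label shapes must match")
    sel = np.ones(value_map.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    rows = []
    for row in parcel_table.itertuples():
        m = sel & (parcels == row.parcel_id) & np.isfinite(value_map)
        if not m.any():
            continue
        vals = value_map[m]
        rows.append(
            {
                "parcel_id": row.parcel_id,
                "name": row.name,
                "hemisphere": getattr(row, "hemisphere", ""),
                "pair": getattr(row, "pair", np.nan),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_voxels": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def bland_altman(x, y):
    """Bland-Altman agreement of paired measurements.

    Differences d = y - x; returns (mean_diff, sd_diff, loa_low, loa_high)
    with limits of agreement mean(d) +- 1.96 * SD(d) (sample SD, ddof=1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired arrays of equal length >= 2")
    d = y - x
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return md, sd, md - 1.96 * sd, md + 1.96 * sd


def rpc(differences, grand_mean=None):
    """Reproducibility coefficient 1.96 * SD(differences).

    Returns (rpc_abs, rpc_percent); the percent form is relative to
    ``grand_mean`` and reported as NaN when the mean is zero/absent.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    r = 1.96 * float(d.std(ddof=1))
    if grand_mean is None or grand_mean == 0:
        return r, float("nan")
    return r, 100.0 * r / float(grand_mean)


def cov_within_subject(x, y):
    """Within-subject coefficient of variation (percent) for paired data.

    Root-mean-square form: CoV = 100 * sqrt(mean(d_i^2) / 2) / grand mean,
    the standard test-retest definition (each pair contributes its own
    within-pair variance d^2/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("need paired arrays of equal length")
    gm = float(np.mean((x + y) / 2.0))
    if gm == 0:
        raise ZeroDivisionError("grand mean is zero; CoV undefined")
    d = y - x
    return 100.0 * np.sqrt(np.mean(d**2) / 2.0) / gm


def icc(values):
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``values`` is (n_subjects, k_sessions).  Mean-squares decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN for degenerate (zero total variance) input.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) x (sessions >= 2) table")
    n, k = v.shape
    grand = v.mean()
    row_m = v.mean(axis=1)
    col_m = v.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((v - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or not np.isfinite(denom):
        return float("nan")
    return float((msr - mse) / denom)


def asymmetry_table(summary_l: pd.DataFrame, summary_r: pd.DataFrame) -> pd.DataFrame:
    """Left/right asymmetry per parcel pair: index 2(L-R)/(L+R) and raw L-R.

    Inputs are parcel summaries (from :func:`parcel_summary`) restricted to
    one hemisphere each, matched on the ``pair`` column; pairs missing a
    hemisphere are skipped.
    """
    rows = []
    r_by_pair = {row.pair: row for row in summary_r.itertuples()}
    for row in summary_l.itertuples():
        other = r_by_pair.get(row.pair)
        if other is None:
            continue
        l_mean, r_mean = row.mean, other.mean
        denom = l_mean + r_mean
        rows.append(
            {
                "pair": row.pair,
                "left_mean": l_mean,
                "right_mean": r_mean,
                "difference": l_mean - r_mean,
                "asymmetry_index": 2.0 * (l_mean - r_mean) / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)


def repeatability_report(
    map_a,
    map_b,
    parcels,
    parcel_table: pd.DataFrame,
    mask,
) -> dict:
    """Parcel-based test-retest report for two radius maps.

    Returns a dict with a per-parcel DataFrame (session means), and summary
    statistics over parcels: Bland-Altman, CoV, RPC (absolute and percent),
    ICC(2,1) and Spearman rank correlation.
    """
    sum_a = parcel_summary(map_a, parcels, parcel_table, mask=mask)
    sum_b = parcel_summary(map_b, parcels, parcel_table, mask=mask)
    merged = sum_a.merge(
        sum_b, on=["parcel_id", "name", "hemisphere", "pair"], suffixes=("_a", "_b")
    )
    x = merged["mean_a"].to_numpy()
    y = merged["mean_b"].to_numpy()
    md, sd, lo, hi = bland_altman(x, y)
    grand = float(np.mean((x + y) / 2.0))
    rpc_abs, rpc_pct = rpc(y - x, grand_mean=grand)
    rho, pval = stats.spearmanr(x, y)
    report = {
        "parcels": merged,
        "mean_diff": md,
        "sd_diff": sd,
        "loa": (lo, hi),
        "cov_percent": cov_within_subject(x, y),
        "rpc": rpc_abs,
        "rpc_percent": rpc_pct,
        "icc": icc(np.stack([x, y], axis=1)),
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "grand_mean": grand,
    }
    return report


def report_to_tsv(report: dict, path):
    """Flatten a repeatability report into a TSV of (statistic, value) rows."""
    rows = [
        ("mean_diff", report["mean_diff"]),
        ("sd_diff", report["sd_diff"]),
        ("loa_low", report["loa"][0]),
        ("loa_high", report["loa"][1]),
        ("cov_percent", report["cov_percent"]),
        ("rpc", report["rpc"]),
        ("rpc_percent", report["rpc_percent"]),
        ("icc", report["icc"]),
        ("spearman_rho", report["spearman_rho"]),
        ("spearman_p", report["spearman_p"]),
        ("grand_mean", report["grand_mean"]),
    ]
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        path, sep="\t", index=False
    )
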