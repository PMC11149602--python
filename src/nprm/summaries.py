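"""Region-level aggregation and cross-method statistical comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import TissueBasisSet
from .fit import FlatFits
from .image import KineticMaps, embed

__all__ = [
    "voi_aggregate",
    "voi_mean_tacs",
    "wrss_compare",
    "paired_wilcoxon",
    "WilcoxonResult",
    "se_loglinear",
    "SeLoglinearFit",
    "delay_map",
]

KINETIC_NAMES = ("V_b", "V_d", "K_d", "K_i", "MTT", "Ext")


def voi_mean_tacs(tac_matrix: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    """Mean curve per VOI label (label 0 = background, skipped)."""
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out[int(lab)] = tac_matrix[labels == lab].mean(axis=0)
    return out


def voi_aggregate(
    maps: KineticMaps,
    voi_labels: np.ndarray,
    method: str = "voxel-NP",
    study_id: str = "study",
) -> pd.DataFrame:
    """Unweighted VOI means of voxel parameters, one row per VOI.

    WRSS is summed over member voxels when present in the maps.
    """
    if voi_labels.shape != maps.mask.shape:
        raise ValueError("VOI label geometry does not match the maps")
    rows = []
    for lab in np.unique(voi_labels):
        if lab == 0:
            continue
        sel = (voi_labels == lab) & maps.mask
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"VOI label {lab} is empty within the body mask")
        row = {"study_id": study_id, "voi_label": int(lab), "method": method, "voxel_count": n}
        for name in maps.keys():
            vals = maps[name][sel]
            if name == "wrss":
                row["wrss"] = float(np.nansum(vals))
            else:
                row[name] = float(np.nanmean(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def wrss_compare(table: pd.DataFrame, reference: str = "voxel-NP") -> pd.DataFrame:
    """Percent misfit deviation of each method from the reference, per VOI.

    Returns one row per (study, voi, method != reference) with
    100 * (WRSS_method - WRSS_ref) / WRSS_ref; zero-reference pairs are
    excluded and counted in the ``n_excluded`` attribute column.
    """
    wide = table.pivot_table(
        index=["study_id", "voi_label"], columns="method", values="wrss"
    )
    if reference not in wide.columns:
        raise ValueError(f"reference method {reference!r} missing from table")
    rows = []
    n_excluded = 0
    for (study, voi), r in wide.iterrows():
        ref = r[reference]
        for method in wide.columns:
            if method == reference or pd.isna(r[method]):
                continue
            if ref == 0 or pd.isna(ref):
                n_excluded += 1
                continue
            rows.append(
                {
                    "study_id": study,
                    "voi_label": voi,
                    "method": method,
                    "wrss_ref": ref,
                    "wrss": r[method],
                    "pct_deviation": 100.0 * (r[method] - ref) / ref,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ - W-: positive when y tends to exceed x... sign of (x - y) ranks
    p_value: float
    n_used: int
    method: str
    all_zero: bool = False


def _exact_signed_rank_p(w_plus: float, n: int) -> float:
    """Two-sided exact p for W+ with untied integer ranks 1..n (DP over the
    2^n sign-pattern distribution)."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: total + 1 - r]
    counts /= 2.0**n
    w = int(round(w_plus))
    cdf = counts[: w + 1].sum()
    sf = counts[w:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def paired_wilcoxon(x, y) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on differences x - y.

    Zero differences are dropped; the statistic is W+ - W- computed on the
    signed ranks of |d|.  The null is exact for n <= 25 without rank ties,
    otherwise a normal approximation with continuity and tie corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", all_zero=True)
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = w_plus - w_minus
    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        p = _exact_signed_rank_p(w_plus, n)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = float(np.sum(ranks**2)) / 4.0
        z_num = w_plus - mean
        z = (z_num - 0.5 * np.sign(z_num)) / np.sqrt(var) if var > 0 else 0.0
        from scipy.stats import norm

        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(statistic, p, n, method)


@dataclass
class SeLoglinearFit:
    coefficients: pd.Series
    predictions_log: np.ndarray
    predictions: np.ndarray
    corr_log: float
    corr_raw: float
    rank_deficient: bool


def se_loglinear(
    df: pd.DataFrame,
    value_cols: tuple[str, ...] = ("value",),
    eps: float = 1e-6,
) -> SeLoglinearFit:
    """Log-linear regression of bootstrap SEs on VOI type and fit covariates.

    Expects columns ``se`` (> 0), ``voi_type``, ``wrms`` (> 0) plus the
    kinetic-magnitude columns named in ``value_cols`` (entered as
    log(|v| + eps)).  Returns coefficients, per-row predictions on both
    scales, and log-/raw-scale correlations.
    """
    if df["se"].le(0).any():
        raise ValueError("all SEs must be positive")
    types = sorted(df["voi_type"].unique())
    if len(types) < 2:
        raise ValueError("need at least 2 VOI types")
    y = np.log(df["se"].to_numpy(dtype=float))
    cols = {"intercept": np.ones(len(df))}
    for t in types[1:]:
        cols[f"voi[{t}]"] = (df["voi_type"] == t).to_numpy(dtype=float)
    cols["log_wrms"] = np.log(df["wrms"].to_numpy(dtype=float))
    for vc in value_cols:
        cols[f"log_{vc}"] = np.log(np.abs(df[vc].to_numpy(dtype=float)) + eps)
    X = np.column_stack(list(cols.values()))
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    rank_deficient = np.linalg.matrix_rank(X) < X.shape[1]
    pred_log = fit.predict(X)
    pred = np.exp(pred_log)
    with np.errstate(invalid="ignore"):
        corr_log = float(np.corrcoef(y, pred_log)[0, 1]) if len(df) > 1 else np.nan
        corr_raw = float(np.corrcoef(df["se"], pred)[0, 1]) if len(df) > 1 else np.nan
    return SeLoglinearFit(
        coefficients=pd.Series(fit.params, index=list(cols.keys())),
        predictions_log=pred_log,
        predictions=pred,
        corr_log=corr_log,
        corr_raw=corr_raw,
        rank_deficient=rank_deficient,
    )


def delay_map(
    fits: FlatFits,
    basis: TissueBasisSet,
    mask: np.ndarray | None = None,
    reference_labels: np.ndarray | None = None,
    reference_label: int | None = None,
) -> np.ndarray:
    """Amplitude-weighted total delay delta + sum_k a_k Delta_k / sum_k a_k.

    Voxels with all-zero amplitudes are NaN.  If a reference VOI is given
    the map is centered so that its mean delay is zero.
    """
    total_alpha = fits.alpha.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        basis_part = np.where(
            total_alpha > 0, (fits.alpha @ basis.delays_s) / total_alpha, np.nan
        )
    d = fits.delay_s + basis_part
    d[~fits.ok] = np.nan
    if mask is None:
        flat = d
    else:
        flat = None
    if reference_label is not None:
        if reference_labels is None or mask is None:
            raise ValueError("reference centering needs mask and reference labels")
        ref_sel = reference_labels[mask] == reference_label
        if not np.any(ref_sel):
            raise ValueError(f"reference VOI {reference_label} is empty")
        d = d - np.nanmean(d[ref_sel])
    if mask is not None:
        return embed(mask, d)
    return d
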