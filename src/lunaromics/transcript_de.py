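"""Count preprocessing and negative-binomial differential expression.

Two deliberately distinct NB test pipelines are provided so a downstream
rank-sum consensus has genuinely different inputs:

* :func:`nb_wald_test` - median-of-ratios size factors, NB log-link GLM, Wald z.
* :func:`nb_lrt_test`  - TMM normalization factors, NB GLM likelihood ratio
  against the pooled-mean null.

Both share method-of-moments dispersion estimation with lowess-trend
shrinkage (:func:`fit_dispersions`) and Benjamini-Hochberg adjustment
(:func:`bh_adjust`).  These are simplified re-implementations of the count-DE
methodology that standard packages provide; they make no attempt to reproduce
any published package's output numerically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design import Comparison, StudyDesign

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def collapse_technical_replicates(counts: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Sum lane-level columns into one column per biological sample."""
    lanes = design.lane_map().set_index("lane_id")
    unknown = [c for c in counts.columns if c not in lanes.index]
    if unknown:
        raise ValueError(f"lanes with no design entry: {unknown}")
    sample_of = lanes.loc[counts.columns, "sample_id"]
    collapsed = counts.T.groupby(sample_of.values).sum().T
    order = [s for s in design.biological_samples["sample_id"] if s in collapsed.columns]
    return collapsed[order]


def filter_spike_artifacts(
    counts: pd.DataFrame,
    flagged_sample: str,
    cohort_samples: list[str],
    factor: float = 10.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove features whose counts spike in one sample of a replicate cohort.

    A feature is removed when ``count(flagged) >= factor * sum(cohort)`` and
    the flagged count is positive (the zero-count guard keeps all-zero rows).
    """
    if flagged_sample in cohort_samples:
        raise ValueError("flagged sample must not be part of the cohort")
    flagged = counts[flagged_sample]
    cohort = counts[list(cohort_samples)].sum(axis=1)
    remove = (flagged >= factor * cohort) & (flagged > 0)
    removed_ids = counts.index[remove].tolist()
    return counts.loc[~remove], removed_ids


def remove_flagged_ids(counts: pd.DataFrame, id_list) -> pd.DataFrame:
    """Drop rows whose feature IDs appear in ``id_list`` (absent IDs ignored)."""
    ids = set(id_list)
    absent = ids - set(counts.index)
    if absent:
        logger.info("%d flagged IDs not present in the matrix; ignored", len(absent))
    out = counts.loc[~counts.index.isin(ids)]
    if out.empty:
        logger.warning("all features removed by flagged-ID filter")
    return out


def select_top_expressed(counts: pd.DataFrame, n: int) -> pd.DataFrame:
    """The ``n`` features with the highest mean raw count across all samples.

    Ties at the boundary are broken lexicographically by feature ID (smaller
    ID kept); output ordering is deterministic and row-order invariant.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(counts):
        raise ValueError(f"n={n} exceeds feature count {len(counts)}")
    means = counts.mean(axis=1)
    order = sorted(counts.index, key=lambda f: (-means[f], f))
    return counts.loc[order[:n]]


# ---------------------------------------------------------------------------
# normalization factors
# ---------------------------------------------------------------------------

def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (each sample vs the geometric-mean
    pseudo-reference over features non-zero in every sample)."""
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has non-zero counts in all samples; "
            "use a pseudo-reference fallback or filter samples"
        )
    sub = mat[all_pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _tmm_pair(y: np.ndarray, n_lib: float, ref: np.ndarray, n_ref: float,
              logratio_trim: float = 0.3, abs_trim: float = 0.05) -> float:
    """Trimmed weighted mean of per-feature log2 ratios of one sample vs ref."""
    pos = (y > 0) & (ref > 0)
    y, ref = y[pos], ref[pos]
    if len(y) == 0:
        return 1.0
    m = np.log2((y / n_lib) / (ref / n_ref))
    a = 0.5 * np.log2((y / n_lib) * (ref / n_ref))
    w = (n_lib - y) / (n_lib * y) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, reference_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, rescaled to geometric
    mean 1 (composition factors; library depth is handled separately as an
    offset in the tests)."""
    mat = counts.to_numpy(dtype=float)
    if not (mat > 0).all(axis=1).any():
        raise ValueError(
            "no feature has non-zero counts in all samples; "
            "use a pseudo-reference fallback or filter samples"
        )
    lib = mat.sum(axis=0)
    if reference_sample is None:
        # sample whose 75th count quantile (depth-scaled) is closest to the mean
        uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference_sample)
    ref = mat[:, ref_idx]
    n_ref = lib[ref_idx]
    factors = np.array([_tmm_pair(mat[:, j], lib[j], ref, n_ref) for j in range(mat.shape[1])])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_size_factors(counts: pd.DataFrame, tmm: pd.Series) -> pd.Series:
    """Library size x TMM composition factor, rescaled to geometric mean 1."""
    lib = counts.sum(axis=0).astype(float)
    eff = lib * tmm
    eff = eff / np.exp(np.mean(np.log(eff)))
    return eff.rename("size_factor")


# ---------------------------------------------------------------------------
# dispersion model
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    """Per-feature raw, trend and shrunken NB dispersions.

    ``table`` columns: mean, raw, trend, shrunken (NaN for untestable
    features); ``weight`` is the shrinkage weight toward the trend.
    """

    table: pd.DataFrame
    weight: float

    def shrunken(self) -> pd.Series:
        return self.table["shrunken"]


def fit_dispersions(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: list[list[str]],
    weight: float = 0.5,
) -> DispersionModel:
    """Method-of-moments NB dispersions with lowess-trend shrinkage.

    Per feature the within-group moments of size-factor-normalized counts give
    a raw dispersion ``(var - shot_noise) / mean^2`` pooled across groups
    (clipped at 0), where the shot-noise term ``mean * avg(1/size factor)``
    is the exact Poisson contribution of normalized counts; a lowess trend of
    raw dispersion versus log mean is fitted (non-robust, so the trend tracks
    the conditional mean of the skewed raw estimates rather than their
    median) and the shrunken value is ``weight * trend + (1 - weight) * raw``.
    All-zero features are reported NaN and excluded from testing.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    norm = counts / factors
    n_feat = len(counts)
    raw = np.full(n_feat, np.nan)
    num = np.zeros(n_feat)
    den = np.zeros(n_feat)
    for grp in groups:
        sub = norm[grp].to_numpy(dtype=float)
        if sub.shape[1] < 2:
            raise ValueError("each group needs >=2 replicates for dispersion estimation")
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        shot = m * np.mean(1.0 / factors[grp].to_numpy(dtype=float))
        ok = m > 0
        w = sub.shape[1] - 1
        num[ok] += w * (v[ok] - shot[ok]) / m[ok] ** 2
        den[ok] += w
    mean_all = norm[[s for grp in groups for s in grp]].mean(axis=1).to_numpy()
    testable = (den > 0) & (mean_all > 0)
    raw[testable] = np.clip(num[testable] / den[testable], 0.0, None)

    trend = np.full(n_feat, np.nan)
    x = np.log(mean_all[testable])
    y = raw[testable]
    if testable.sum() >= 10:
        fit = lowess(y, x, frac=0.5, it=0, return_sorted=False)
        trend[testable] = np.clip(fit, 1e-8, None)
    else:
        trend[testable] = max(float(np.mean(y)), 1e-8) if testable.any() else np.nan

    shrunk = np.full(n_feat, np.nan)
    shrunk[testable] = weight * trend[testable] + (1 - weight) * raw[testable]
    table = pd.DataFrame(
        {"mean": mean_all, "raw": raw, "trend": trend, "shrunken": shrunk},
        index=counts.index,
    )
    return DispersionModel(table=table, weight=weight)


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized over features)
# ---------------------------------------------------------------------------

_MIN_BETA = -50.0


def _nb_fit_mean(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-12):
    """MLE of a single log-mean with log(size factor) offsets.

    Model: y_gj ~ NB(mu_gj = e^{beta_g} sf_j, dispersion alpha_g), solved by
    Newton-Raphson on the score sum_j k (y - mu) / (mu + k), k = 1/alpha;
    alpha_g = 0 features use the closed-form Poisson solution.  Returns
    (beta, fisher_info, loglik_kernel) arrays over features.
    """
    y = np.asarray(y, dtype=float)
    sf = np.asarray(sf, dtype=float)
    tot = y.sum(axis=1)
    beta = np.log(np.clip(tot, 0.5, None) / sf.sum())
    beta = np.clip(beta, _MIN_BETA, None)

    poisson = alpha <= 0
    nb = ~poisson
    if nb.any():
        k = 1.0 / alpha[nb]
        b = beta[nb].copy()
        yn = y[nb]
        for _ in range(max_iter):
            mu = np.exp(b)[:, None] * sf[None, :]
            score = (k[:, None] * (yn - mu) / (mu + k[:, None])).sum(axis=1)
            info = (k[:, None] * mu / (mu + k[:, None])).sum(axis=1)
            step = score / np.clip(info, 1e-12, None)
            step = np.clip(step, -5.0, 5.0)
            b = np.clip(b + step, _MIN_BETA, 50.0)
            if np.max(np.abs(step)) < tol:
                break
        beta[nb] = b

    mu = np.exp(beta)[:, None] * sf[None, :]
    info = np.empty_like(beta)
    ll = np.empty_like(beta)
    if poisson.any():
        info[poisson] = mu[poisson].sum(axis=1)
        ll[poisson] = (y[poisson] * np.log(np.clip(mu[poisson], 1e-300, None)) - mu[poisson]).sum(axis=1)
    if nb.any():
        k = (1.0 / alpha[nb])[:, None]
        mun = mu[nb]
        info[nb] = (k * mun / (mun + k)).sum(axis=1)
        ll[nb] = (
            y[nb] * np.log(np.clip(mun, 1e-300, None) / (mun + k))
            + k * np.log(k / (mun + k))
        ).sum(axis=1)
    return beta, info, ll


def _prepare_test(counts, comparison, factors, dispersions, weight):
    if factors is None:
        raise ValueError("size factors are required")
    a_cols, b_cols = list(comparison.group_a), list(comparison.group_b)
    ya = counts[a_cols].to_numpy(dtype=float)
    yb = counts[b_cols].to_numpy(dtype=float)
    sfa = factors[a_cols].to_numpy(dtype=float)
    sfb = factors[b_cols].to_numpy(dtype=float)
    if dispersions is None:
        dispersions = fit_dispersions(counts, factors, [a_cols, b_cols], weight=weight)
    alpha = dispersions.shrunken().to_numpy(dtype=float)
    testable = np.isfinite(alpha)
    return ya, yb, sfa, sfb, np.where(testable, alpha, 0.0), testable


def _assemble_result(counts, comparison, ya, yb, sfa, sfb, log2fc, p, testable, method):
    base_a = (ya / sfa[None, :]).mean(axis=1)
    base_b = (yb / sfb[None, :]).mean(axis=1)
    # pseudo-count fold change for display when a group mean is zero
    zero = (base_a == 0) | (base_b == 0)
    if zero.any():
        disp_fc = np.log2((base_a + 0.5) / (base_b + 0.5))
        log2fc = np.where(zero, disp_fc, log2fc)
    p = np.where(testable, p, np.nan)
    res = pd.DataFrame(
        {
            "feature_id": counts.index,
            "baseMeanA": base_a,
            "baseMeanB": base_b,
            "log2FC": log2fc,
            "p": p,
            "padj": bh_adjust(p),
            "mean_expression": (np.concatenate([ya / sfa[None, :], yb / sfb[None, :]], axis=1)).mean(axis=1),
            "method": method,
        }
    ).set_index("feature_id")
    res.attrs["comparison"] = comparison.name
    res.attrs["factor"] = comparison.factor
    return res


def nb_wald_test(
    counts: pd.DataFrame,
    comparison: Comparison,
    factors: pd.Series | None = None,
    dispersions: DispersionModel | None = None,
    shrinkage_weight: float = 0.5,
) -> pd.DataFrame:
    """NB GLM Wald test of group A vs group B (median-of-ratios route).

    Per feature, group log-means are fitted by Newton-Raphson with
    log(size-factor) offsets; Wald z = (beta_A - beta_B) / SE with SE^2 the
    sum of inverse Fisher informations.  The two-sided p refers z to a
    Student t with the residual degrees of freedom (n_A + n_B - 2), a
    small-sample correction that keeps the tail calibrated with estimated
    dispersions at few replicates.  log2FC is reported as A relative to B,
    BH adjusted within the tested set.
    """
    if factors is None:
        factors = size_factors_median_ratio(counts)
    ya, yb, sfa, sfb, alpha, testable = _prepare_test(
        counts, comparison, factors, dispersions, shrinkage_weight
    )
    beta_a, info_a, _ = _nb_fit_mean(ya, sfa, alpha)
    beta_b, info_b, _ = _nb_fit_mean(yb, sfb, alpha)
    se = np.sqrt(1.0 / np.clip(info_a, 1e-12, None) + 1.0 / np.clip(info_b, 1e-12, None))
    z = (beta_a - beta_b) / se
    df_resid = max(ya.shape[1] + yb.shape[1] - 2, 1)
    p = 2.0 * stats.t.sf(np.abs(z), df_resid)
    log2fc = (beta_a - beta_b) / LOG2
    res = _assemble_result(counts, comparison, ya, yb, sfa, sfb, log2fc, p, testable, "nb_wald")
    res["stat"] = z
    return res


def nb_lrt_test(
    counts: pd.DataFrame,
    comparison: Comparison,
    factors: pd.Series | None = None,
    dispersions: DispersionModel | None = None,
    shrinkage_weight: float = 0.5,
) -> pd.DataFrame:
    """NB GLM likelihood-ratio test of group A vs group B (TMM route).

    The full model fits separate group means, the null a shared mean.  The
    signed square root of the LR statistic is referred to a Student t with
    the residual degrees of freedom (equivalently an F(1, n-2) reference for
    the LR statistic itself), the same small-sample correction as in the
    Wald route; asymptotically this coincides with the chi^2(1) reference.
    Size factors default to library size times TMM composition factors,
    making this a genuinely different pipeline from :func:`nb_wald_test`.
    """
    if factors is None:
        factors = effective_size_factors(counts, tmm_factors(counts))
    ya, yb, sfa, sfb, alpha, testable = _prepare_test(
        counts, comparison, factors, dispersions, shrinkage_weight
    )
    beta_a, _, ll_a = _nb_fit_mean(ya, sfa, alpha)
    beta_b, _, ll_b = _nb_fit_mean(yb, sfb, alpha)
    y_all = np.concatenate([ya, yb], axis=1)
    sf_all = np.concatenate([sfa, sfb])
    _, _, ll_0 = _nb_fit_mean(y_all, sf_all, alpha)
    lr = np.clip(2.0 * (ll_a + ll_b - ll_0), 0.0, None)
    df_resid = max(ya.shape[1] + yb.shape[1] - 2, 1)
    p = 2.0 * stats.t.sf(np.sqrt(lr), df_resid)
    log2fc = (beta_a - beta_b) / LOG2
    res = _assemble_result(counts, comparison, ya, yb, sfa, sfb, log2fc, p, testable, "nb_lrt")
    res["lr_stat"] = lr
    return res


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaNs are allowed: they are excluded from the adjustment (they do not count
    toward m) and reinserted as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        sub = p[mask]
        m = len(sub)
        order = np.argsort(sub, kind="stable")
        q = sub[order] * m / np.arange(1, m + 1)
        adj = np.minimum(np.minimum.accumulate(q[::-1])[::-1], 1.0)
        restored = np.empty(m)
        restored[order] = adj
        out[mask] = restored
    return out
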