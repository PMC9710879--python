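"""Two-group negative-binomial differential expression on raw counts.

The pipeline follows the standard bulk RNA-seq recipe: median-of-ratios size
factors, a low-count filter on summed normalized counts, a per-gene
method-of-moments dispersion estimate, a per-gene NB GLM fitted by
iteratively reweighted least squares, a Wald test on the group coefficient,
and Benjamini-Hochberg adjustment. Genes with adjusted p below ``alpha``
(default 0.10) are flagged as differentially expressed (DEGs). No dispersion
shrinkage or fold-change moderation is applied.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from generescue.constants import GENOTYPES

DISPERSION_FLOOR = 1e-8
#: fixed column order of the DE table (TSV contract)
DE_COLUMNS = [
    "baseMean", "log2FC", "lfcSE", "stat", "pvalue", "padj", "isDEG", "direction",
]


def _as_count_array(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    if arr.size == 0:
        raise ValueError("count matrix is empty")
    if (arr < 0).any():
        raise ValueError("count matrix contains negative entries")
    return arr.astype(float)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, s_j is the median over reference genes (genes with
    strictly positive counts in every sample) of count_gj divided by the
    geometric mean of gene g across samples.
    """
    arr = _as_count_array(counts)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has all-positive counts; filter samples or genes before "
            "computing size factors"
        )
    logs = np.log(arr[positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Counts divided by their sample size factors."""
    sf = sf.reindex(counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    return counts / sf


def filter_low_counts(
    counts: pd.DataFrame, sf: pd.Series, threshold: float = 10.0
) -> pd.Index:
    """Genes whose normalized counts summed across samples reach ``threshold``.

    Genes with fewer than ``threshold`` summed normalized counts are dropped
    from downstream testing.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    total = normalize_counts(counts, sf).sum(axis=1)
    return counts.index[total >= threshold]


def estimate_dispersion(counts: pd.DataFrame, sf: pd.Series) -> pd.Series:
    """Method-of-moments NB dispersion per gene.

    alpha = max(floor, (v - m) / m^2) with m, v the mean and (ddof=1)
    variance of normalized counts; zero-mean genes get the floor with a
    warning. The estimate is marginal over all samples; for a two-group
    contrast :func:`run_de` pools the within-group moments instead so group
    mean differences do not inflate the dispersion.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersion")
    norm = normalize_counts(counts, sf).to_numpy()
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    alpha = np.full(m.shape, DISPERSION_FLOOR)
    ok = m > 0
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} gene(s) with zero mean set to the dispersion floor",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha[ok] = np.maximum(DISPERSION_FLOOR, (v[ok] - m[ok]) / m[ok] ** 2)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _pooled_dispersion(
    norm: np.ndarray, group_masks: list[np.ndarray]
) -> np.ndarray:
    """Within-group moment dispersion pooled across contrast groups.

    Residual variance about the group means (pooled, ddof = groups) against
    the grand mean: alpha = max(floor, (v_within - m) / m^2).
    """
    n_total = sum(int(mask.sum()) for mask in group_masks)
    ss = np.zeros(norm.shape[0])
    for mask in group_masks:
        sub = norm[:, mask]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n_total - len(group_masks)
    if df <= 0:
        raise ValueError("each contrast group needs at least 2 samples")
    v = ss / df
    cols = np.concatenate([np.flatnonzero(m) for m in group_masks])
    m = norm[:, cols].mean(axis=1)
    alpha = np.full(m.shape, DISPERSION_FLOOR)
    ok = m > 0
    alpha[ok] = np.maximum(DISPERSION_FLOOR, (v[ok] - m[ok]) / m[ok] ** 2)
    return alpha


def dispersion_trend(
    counts: np.ndarray,
    sf: np.ndarray,
    group_masks: list[np.ndarray],
) -> tuple[float, float]:
    """Fit the dispersion trend alpha(mu) = a0 + a1/mu across genes.

    Maximizes the negative-binomial likelihood of all genes jointly over the
    two trend coefficients, with group means plugged in for the per-gene
    means and a Cox-Reid adjustment (-0.5 log det of the weighted
    information per gene) correcting the bias from estimating those means.
    With only a handful of replicates per group, gene-wise dispersion
    estimates are far too noisy to test against; the two-parameter trend
    borrows strength across all genes.
    """
    norm = counts / sf[None, :]
    mu_hat = np.zeros_like(norm)
    for mask in group_masks:
        mu_hat[:, mask] = norm[:, mask].mean(axis=1, keepdims=True)
    mu = np.maximum(mu_hat * sf[None, :], 1e-8)
    m = np.maximum(norm.mean(axis=1), 1e-8)

    def negll(p: np.ndarray) -> float:
        a0, a1 = np.exp(p)
        alpha = np.maximum(a0 + a1 / m, DISPERSION_FLOOR)[:, None]
        r = 1.0 / alpha
        ll = (
            gammaln(counts + r) - gammaln(r)
            + r * np.log(r / (r + mu))
            + counts * np.log(mu / (r + mu) + 1e-300)
        ).sum()
        w = mu / (1.0 + alpha * mu)
        cr = 0.0
        for mask in group_masks:
            cr += np.log(np.maximum(w[:, mask].sum(axis=1), 1e-12)).sum()
        return -(ll - 0.5 * cr)

    sol = minimize(
        negll,
        x0=[np.log(0.05), np.log(1.0)],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-2},
    )
    a0, a1 = np.exp(sol.x)
    return float(a0), float(a1)


def fitted_dispersions(
    counts: np.ndarray,
    sf: np.ndarray,
    group_masks: list[np.ndarray],
    outlier_sds: float = 2.0,
) -> np.ndarray:
    """Per-gene dispersions: trend value, or gene-wise for outliers.

    Genes whose gene-wise moment estimate exceeds the fitted trend by more
    than ``outlier_sds`` robust SDs of the log-ratio distribution keep their
    gene-wise value, so genuinely hyper-variable genes are not tested with an
    optimistic trend dispersion.
    """
    norm = counts / sf[None, :]
    a_gene = _pooled_dispersion(norm, group_masks)
    a0, a1 = dispersion_trend(counts, sf, group_masks)
    m = np.maximum(norm.mean(axis=1), 1e-8)
    trend = np.maximum(a0 + a1 / m, DISPERSION_FLOOR)
    log_ratio = np.log(np.maximum(a_gene, DISPERSION_FLOOR)) - np.log(trend)
    scale = 1.4826 * np.median(np.abs(log_ratio - np.median(log_ratio)))
    out = np.where(log_ratio > outlier_sds * max(scale, 1e-6), a_gene, trend)
    return out


def _irls_nb(
    counts: np.ndarray,
    sf: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS fit of log mu_j = log s_j + b0 + b1 x_j per gene.

    Weights w = mu / (1 + alpha mu) (NB variance mu + alpha mu^2 with the
    canonical log link). Returns (b0, b1, se_b1, converged).
    """
    n_genes, n_samples = counts.shape
    offset = np.log(sf)[None, :]

    # moment initialisation from group means with a half-count fallback
    mut = x.astype(bool)
    norm = counts / sf[None, :]
    mean_wt = norm[:, ~mut].mean(axis=1)
    mean_mut = norm[:, mut].mean(axis=1)
    b0 = np.log(np.maximum(mean_wt, 0.5))
    b1 = np.log(np.maximum(mean_mut, 0.5)) - b0

    xb = x[None, :]
    converged = np.zeros(n_genes, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * xb
        mu = np.exp(offset + eta)
        mu = np.clip(mu, 1e-10, 1e12)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta + (counts - mu) / mu
        sw = w.sum(axis=1)
        swx = w[:, mut].sum(axis=1)  # x is 0/1 so sum w x = sum w x^2
        swz = (w * z).sum(axis=1)
        swxz = (w[:, mut] * z[:, mut]).sum(axis=1)
        det = sw * swx - swx**2
        det = np.where(det <= 0, np.nan, det)
        new_b0 = (swx * swz - swx * swxz) / det
        new_b1 = (sw * swxz - swx * swz) / det
        step = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        converged |= step < tol
        if converged.all():
            break

    eta = b0[:, None] + b1[:, None] * xb
    mu = np.clip(np.exp(offset + eta), 1e-10, 1e12)
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = w[:, mut].sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(sw / det)
    return b0, b1, se_b1, converged


def wald_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    sf: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test for mutant-vs-reference (log2FC > 0 = up in mutant).

    ``contrast`` is (mutant_genotype, reference_genotype); the reference is
    conventionally "WT" so fold changes share the effect-ratio orientation.
    Genes where one group is all zeros are refit on counts + 0.5 and flagged
    ``fc_infinite``.
    """
    mutant, reference = contrast
    for g in (mutant, reference):
        if g not in set(samples["genotype"]):
            raise ValueError(f"genotype {g!r} absent from the sample table")
    keep = samples.index[samples["genotype"].isin([mutant, reference])]
    sub = counts[keep]
    x = (samples.loc[keep, "genotype"] == mutant).to_numpy().astype(float)
    if (x == 1).sum() < 2 or (x == 0).sum() < 2:
        raise ValueError("both contrast groups need at least 2 samples")
    sf_arr = sf.reindex(keep).to_numpy(dtype=float)
    alpha = dispersions.reindex(sub.index).to_numpy(dtype=float)
    arr = _as_count_array(sub)

    mut = x.astype(bool)
    zero_group = (arr[:, mut].sum(axis=1) == 0) | (arr[:, ~mut].sum(axis=1) == 0)
    fit_arr = np.where(zero_group[:, None], arr + 0.5, arr)

    b0, b1, se_b1, converged = _irls_nb(fit_arr, sf_arr, x, alpha)

    ln2 = math.log(2.0)
    log2fc = b1 / ln2
    lfc_se = se_b1 / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se_b1
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)  # degenerate fits
    base_mean = (arr / sf_arr[None, :]).mean(axis=1)

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": lfc_se,
            "stat": z,
            "pvalue": pvalue,
            "fc_infinite": zero_group,
            "converged": converged,
        },
        index=sub.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = 0.10,
    filter_threshold: float = 10.0,
) -> pd.DataFrame:
    """Full DE pipeline for one mutant-vs-WT contrast.

    Size factors come from the full matrix (all samples inform the
    normalization); the low-count filter is applied before testing;
    dispersions come from the Cox-Reid-fitted trend over the two contrast
    groups (see :func:`fitted_dispersions`); DEG flag is padj < alpha with
    direction from the sign of log2FC.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    unknown = set(samples["genotype"]) - set(GENOTYPES)
    if unknown:
        raise ValueError(
            f"unknown genotype labels {sorted(unknown)}; allowed: {GENOTYPES}"
        )
    sf = size_factors(counts)
    kept = filter_low_counts(counts, sf, filter_threshold)
    sub = counts.loc[kept]

    mutant, reference = contrast
    keep_samples = samples.index[samples["genotype"].isin([mutant, reference])]
    arr = sub[keep_samples].to_numpy(dtype=float)
    sf_arr = sf.reindex(keep_samples).to_numpy(dtype=float)
    masks = [
        (samples.loc[keep_samples, "genotype"] == g).to_numpy()
        for g in (reference, mutant)
    ]
    alpha_disp = pd.Series(fitted_dispersions(arr, sf_arr, masks), index=sub.index)

    res = wald_test(sub, samples, sf, alpha_disp, contrast)
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    res["isDEG"] = res["padj"] < alpha
    direction = np.where(res["log2FC"] > 0, "up", "down")
    res["direction"] = np.where(res["isDEG"], direction, "")
    return res[DE_COLUMNS + ["fc_infinite", "converged"]]
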