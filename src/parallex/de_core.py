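"""Differential expression: median-of-ratios normalization, dispersion
estimation, per-gene negative-binomial Wald tests, and BH correction.

The model is the standard bulk RNA-seq NB log-linear model: counts
K_gj ~ NB(mean = s_j * q_gj, dispersion = alpha_g) with log q_gj linear in a
two-level group indicator.  Size factors s_j are the median across genes of
the ratio of a sample's count to the gene's geometric mean.  Dispersions
are method-of-moments estimates shrunk toward a parametric mean-dispersion
trend a0/mu + a1.  The reported log2 fold change is the maximum-likelihood
estimate (no shrinkage prior); significance is a two-sided Wald test with
Benjamini-Hochberg correction after an independent-filtering scan on mean
normalized count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

LN2 = np.log(2.0)

STATUS_TESTED = "tested"
STATUS_LOW_TOTAL = "filtered_low_total"
STATUS_INDEPENDENT = "filtered_independent"


class NormalizationError(ValueError):
    pass


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene with a positive count in every sample, divide each
    sample's count by the gene's geometric mean; the sample's size factor
    is the median of those ratios.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has positive counts in all samples; cannot compute "
            "median-of-ratios size factors (check for empty samples or an "
            "extremely sparse matrix)"
        )
    logs = np.log(values[positive])
    log_geomean = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersions


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.Series | np.ndarray,
    prior_var: float = 0.25,
) -> pd.DataFrame:
    """Per-gene dispersion: raw method-of-moments, trend fit, shrunk final.

    Raw: from the pooled within-group variance of normalized counts,
    alpha_raw = (var - mu * mean(1/s)) / mu^2, floored at 1e-8.  Trend:
    alpha(mu) = a0/mu + a1 fit by non-negative least squares with outlier
    trimming.  Final: precision-weighted combination of log raw and log
    trend, except that raw estimates far above the trend are kept as-is
    (dispersion outliers).
    """
    design = np.asarray(design)
    groups = pd.unique(design)
    values = counts.to_numpy(dtype=float)
    s = size_factors.to_numpy(dtype=float)
    q = values / s

    n = values.shape[1]
    n_groups = len(groups)
    df = n - n_groups
    if df < 1:
        raise ValueError(
            "need at least 2 samples per group to estimate dispersions; use "
            "a pooled dispersion mode for single-sample groups"
        )

    sse = np.zeros(values.shape[0])
    for g in groups:
        mask = design == g
        if mask.sum() < 2:
            raise ValueError(
                f"group {g!r} has a single sample; use pooled dispersion mode"
            )
        qg = q[:, mask]
        sse += ((qg - qg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var_within = sse / df
    mu = q.mean(axis=1)
    mean_inv_s = np.mean(1.0 / s)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_within - mu * mean_inv_s) / mu**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.maximum(raw, 1e-8)

    a0, a1 = _fit_dispersion_trend(mu, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 / np.maximum(mu, 1e-12) + a1, a1)
    trend = np.maximum(trend, 1e-8)

    var_log_raw = 2.0 / df  # rough sampling variance of log alpha_raw
    w = var_log_raw / (var_log_raw + prior_var)
    log_final = (1.0 - w) * np.log(raw) + w * np.log(trend)
    final = np.exp(log_final)
    # dispersion outliers: keep raw when far above the trend
    outlier = np.log(raw) > np.log(trend) + 2.0 * np.sqrt(prior_var + var_log_raw)
    final[outlier] = raw[outlier]
    final = np.clip(final, 1e-8, 20.0)

    return pd.DataFrame(
        {"mean": mu, "raw": raw, "trend": trend, "final": final},
        index=counts.index,
    )


def _fit_dispersion_trend(mu: np.ndarray, raw: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0/mu + a1 (a0, a1 >= 0) with iterative trimming."""
    use = (raw > 1e-7) & (mu > 0)
    if use.sum() < 10:
        fallback = float(np.median(raw[raw > 1e-7])) if (raw > 1e-7).any() else 1e-8
        return 0.0, max(fallback, 1e-8)
    x, y = 1.0 / mu[use], raw[use]
    keep = np.ones(len(y), dtype=bool)
    coef = np.array([0.0, np.median(y)])
    for _ in range(6):
        A = np.column_stack([x[keep], np.ones(keep.sum())])
        coef, _ = optimize.nnls(A, y[keep])
        fit = coef[0] * x + coef[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = y / np.maximum(fit, 1e-12)
        new_keep = (ratio > 1e-2) & (ratio < 1e2)
        if new_keep.sum() < 10 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return float(coef[0]), float(max(coef[1], 0.0))


# ---------------------------------------------------------------------------
# NB GLM fit (two-group design), vectorized across genes


def _fit_nb_two_group(
    y: np.ndarray,
    s: np.ndarray,
    is_b: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS fit of log mu = b0 + b1*I(group B) + log s per gene.

    Returns (b0, b1, se_b1) in natural-log units.  ``y`` is (genes,
    samples), ``alpha`` the per-gene NB dispersion.
    """
    logs = np.log(s)[None, :]
    xb = is_b.astype(float)[None, :]
    qa = (y[:, ~is_b] / s[~is_b]).mean(axis=1)
    qb = (y[:, is_b] / s[is_b]).mean(axis=1)
    b0 = np.log(np.maximum(qa, 1e-8))
    b1 = np.log(np.maximum(qb, 1e-8)) - b0
    alpha_col = alpha[:, None]
    ridge = 1e-12

    se_b1 = np.full(len(y), np.nan)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * xb + logs, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha_col * mu)
        z = (eta - logs) + (y - mu) / mu
        wz = w * z
        sw = w.sum(axis=1)
        swx = w[:, is_b].sum(axis=1)
        swz = wz.sum(axis=1)
        swxz = wz[:, is_b].sum(axis=1)
        det = sw * swx - swx**2 + ridge
        new_b1 = (sw * swxz - swx * swz) / det
        new_b0 = (swz - swx * new_b1) / np.maximum(sw, ridge)
        new_b0 = np.clip(new_b0, -30.0, 30.0)
        new_b1 = np.clip(new_b1, -30.0, 30.0)
        delta = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        if delta.max(initial=0.0) < tol:
            break
    eta = np.clip(b0[:, None] + b1[:, None] * xb + logs, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha_col * mu)
    sw = w.sum(axis=1)
    swx = w[:, is_b].sum(axis=1)
    det = sw * swx - swx**2 + ridge
    se_b1 = np.sqrt(np.maximum(sw / det, 0.0))
    return b0, b1, se_b1


# ---------------------------------------------------------------------------
# BH


def adjust_bh(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    padj_(i) = min over j >= i of p_(j) * m / j, capped at 1; a gene is
    significant when padj <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    padj = np.empty(m)
    padj[order] = ranked
    return padj, padj <= alpha


# ---------------------------------------------------------------------------
# contrast test


@dataclass
class ContrastResult:
    """DE table plus the bookkeeping of one two-group contrast."""

    table: pd.DataFrame
    contrast: tuple[str, str]
    alpha: float
    size_factors: pd.Series
    independent_filter_threshold: float

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table.status == STATUS_TESTED]

    @property
    def significant(self) -> pd.DataFrame:
        t = self.tested
        return t[t.padj <= self.alpha]


def test_contrast(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    stage: str | None = None,
    independent_filtering: bool = True,
    min_total_count: int = 2,
) -> ContrastResult:
    """Wald test of differential expression between two species groups.

    ``contrast`` is (reference, treatment): the log2 fold change is the
    treatment group relative to the reference (specialist relative to
    generalist in the intended use).  Genes whose total count across the
    selected samples is below ``min_total_count`` get status
    ``filtered_low_total``; independent filtering scans mean-normalized-
    count thresholds over the 0-95% quantile grid (5% steps) and keeps the
    one maximizing BH discoveries at ``alpha``, marking sub-threshold genes
    ``filtered_independent``.
    """
    ref, trt = contrast
    known = set(samples.species)
    for grp in (ref, trt):
        if grp not in known:
            raise ValueError(f"unknown group label {grp!r}; sample sheet has {sorted(known)}")
    sel = samples[samples.species.isin([ref, trt])]
    if stage is not None:
        if stage not in set(samples.stage):
            raise ValueError(f"stage {stage!r} absent from sample sheet")
        sel = sel[sel.stage == stage]
    for grp in (ref, trt):
        if not (sel.species == grp).any():
            raise ValueError(f"group {grp!r} has no samples at stage {stage!r}")
    missing_cols = set(sel.sample_id) - set(counts.columns)
    if missing_cols:
        raise ValueError(f"count matrix lacks sample columns {sorted(missing_cols)}")

    sub = counts[sel.sample_id.tolist()]
    is_b = (sel.species == trt).to_numpy()

    total = sub.sum(axis=1).to_numpy()
    low = total < min_total_count
    keep = ~low

    sf = compute_size_factors(sub)
    disp = estimate_dispersions(sub.loc[keep], sf, sel.species.to_numpy())

    y = sub.loc[keep].to_numpy(dtype=float)
    s = sf.to_numpy()
    b0, b1, se = _fit_nb_two_group(y, s, is_b, disp["final"].to_numpy())
    base_mean = (y / s).mean(axis=1)
    lfc = b1 / LN2
    lfc_se = se / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, b1 / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    n_genes = len(counts)
    table = pd.DataFrame(
        {
            "base_mean": np.full(n_genes, np.nan),
            "log2fc": np.full(n_genes, np.nan),
            "lfc_se": np.full(n_genes, np.nan),
            "stat": np.full(n_genes, np.nan),
            "pvalue": np.full(n_genes, np.nan),
            "padj": np.full(n_genes, np.nan),
            "status": np.where(low, STATUS_LOW_TOTAL, STATUS_TESTED).astype(object),
        },
        index=counts.index,
    )
    table.loc[keep, "base_mean"] = base_mean
    table.loc[keep, "log2fc"] = lfc
    table.loc[keep, "lfc_se"] = lfc_se
    table.loc[keep, "stat"] = stat
    table.loc[keep, "pvalue"] = pvalue

    threshold = 0.0
    if keep.any():
        if independent_filtering:
            threshold = _independent_filter_threshold(base_mean, pvalue, alpha)
        passed = base_mean >= threshold
        padj_vals, _ = adjust_bh(pvalue[passed], alpha)
        padj = np.full(len(pvalue), np.nan)
        padj[passed] = padj_vals
        table.loc[keep, "padj"] = padj
        statuses = table.loc[keep, "status"].to_numpy(dtype=object)
        statuses[~passed] = STATUS_INDEPENDENT
        table.loc[keep, "status"] = statuses

    return ContrastResult(
        table=table,
        contrast=contrast,
        alpha=alpha,
        size_factors=sf,
        independent_filter_threshold=float(threshold),
    )


def _independent_filter_threshold(
    base_mean: np.ndarray, pvalue: np.ndarray, alpha: float
) -> float:
    """Mean-count threshold maximizing BH discoveries (0-95% quantile grid)."""
    quantiles = np.arange(0.0, 1.0, 0.05)
    thresholds = np.quantile(base_mean, quantiles)
    best_t, best_n = thresholds[0], -1
    for t in thresholds:
        mask = base_mean >= t
        if not mask.any():
            continue
        _, sig = adjust_bh(pvalue[mask], alpha)
        n = int(sig.sum())
        if n > best_n:
            best_t, best_n = t, n
    return float(best_t)


def write_de_table(result: ContrastResult, path) -> None:
    out = result.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
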