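"""Pleiotropy-proxy comparison between parallel- and divergent-expression
gene sets.

For each of three per-gene count metrics (associated GO biological
processes, protein-protein interactions, developmental stages expressed),
a negative-binomial regression of the count on the group indicator
(divergent vs parallel, log link) gives a log rate ratio with a two-sided
Wald p-value.  When the dispersion estimate collapses to the Poisson
boundary the fit falls back to a Poisson GLM and is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

METRICS = ("n_processes", "n_ppi", "n_stages")
GROUPS = ("parallel", "divergent")


@dataclass
class GlmResult:
    """Per-metric NB regression summaries (divergent relative to parallel)."""

    table: pd.DataFrame  # metric log_rate_ratio se pvalue dispersion model converged

    def to_dict(self) -> dict:
        return self.table.set_index("metric").to_dict(orient="index")


def _validate_table(table: pd.DataFrame, metrics: tuple[str, ...]) -> None:
    groups = set(table.group)
    if groups != set(GROUPS):
        raise ValueError(f"group column must contain exactly {GROUPS}, got {sorted(groups)}")
    for g in GROUPS:
        if (table.group == g).sum() < 2:
            raise ValueError(f"need >= 2 genes in group {g!r}")
    for m in metrics:
        y = table[m].to_numpy()
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError(f"metric {m!r} must hold non-negative integer counts")


def compare_pleiotropy(
    table: pd.DataFrame, metrics: tuple[str, ...] = METRICS
) -> GlmResult:
    """Fit one NB GLM per metric: count ~ 1 + I(group == divergent).

    Returns the log rate ratio (divergent vs parallel), its standard
    error, the two-sided Wald p-value, the estimated NB2 dispersion, and
    whether a Poisson fallback was used.
    """
    _validate_table(table, metrics)
    x = (table.group == "divergent").to_numpy(dtype=float)
    X = sm.add_constant(x)
    rows = []
    for metric in metrics:
        y = table[metric].to_numpy(dtype=float)
        rows.append(_fit_one(y, X, metric))
    return GlmResult(table=pd.DataFrame(rows))


def _fit_one(y: np.ndarray, X: np.ndarray, metric: str) -> dict:
    res, alpha, converged = None, np.nan, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            nb = sm.NegativeBinomial(y, X, loglike_method="nb2")
            res = nb.fit(disp=0, maxiter=200)
            alpha = float(res.params[-1])
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = None
    boundary = res is None or not converged or alpha < 1e-4 or not np.isfinite(alpha)
    if boundary:
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        return {
            "metric": metric,
            "log_rate_ratio": float(glm.params[1]),
            "se": float(glm.bse[1]),
            "pvalue": float(glm.pvalues[1]),
            "dispersion": 0.0,
            "model": "poisson_fallback",
            "converged": True,
        }
    return {
        "metric": metric,
        "log_rate_ratio": float(res.params[1]),
        "se": float(res.bse[1]),
        "pvalue": float(res.pvalues[1]),
        "dispersion": alpha,
        "model": "negative_binomial",
        "converged": converged,
    }
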