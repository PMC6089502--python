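"""Parallelism statistics between two differential-expression contrasts.

Overlap enrichment is a one-sided hypergeometric (Fisher) upper-tail test
of significance-at-alpha membership against a shared background universe.
Direction concordance tallies, among genes significant in both contrasts,
how many move the same way in both specialists.  The null for the
concordant count is Binomial(n_overlap, 1/2), assessed both by Monte-Carlo
permutation (with the +1 correction, so the empirical p is never zero) and
by the exact binomial tail.  The down-sampling procedure re-runs both
contrasts on subsampled groups to check that the concordant fraction is
robust to the smaller specialist sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de_core import ContrastResult, test_contrast

logger = logging.getLogger(__name__)


@dataclass
class OverlapTable:
    """2x2 gene-overlap counts against a background of N genes."""

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    def __post_init__(self) -> None:
        cells = (self.n_both, self.n_a_only, self.n_b_only, self.n_neither)
        if any(c < 0 for c in cells):
            raise ValueError("overlap cells must be non-negative")

    @property
    def background(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither

    @property
    def n_a(self) -> int:
        return self.n_both + self.n_a_only

    @property
    def n_b(self) -> int:
        return self.n_both + self.n_b_only

    def to_dict(self) -> dict:
        return {
            "n_both": self.n_both,
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "n_neither": self.n_neither,
            "background": self.background,
        }


@dataclass
class DirectionSummary:
    """Direction tallies among genes significant in both contrasts."""

    n_overlap: int
    n_same: int
    n_opposite: int
    n_up_both: int
    n_down_both: int

    def __post_init__(self) -> None:
        if self.n_same + self.n_opposite != self.n_overlap:
            raise ValueError("n_same + n_opposite must equal n_overlap")
        if self.n_up_both + self.n_down_both != self.n_same:
            raise ValueError("n_up_both + n_down_both must equal n_same")

    def to_dict(self) -> dict:
        return {
            "n_overlap": self.n_overlap,
            "n_same": self.n_same,
            "n_opposite": self.n_opposite,
            "n_up_both": self.n_up_both,
            "n_down_both": self.n_down_both,
        }


@dataclass
class PermutationResult:
    """Monte-Carlo null summary for the direction-concordance statistic."""

    n_permutations: int
    observed: int
    empirical_p: float
    exact_p: float
    null_mean: float
    null_sd: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "exact_p": self.exact_p,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "seed": self.seed,
        }


@dataclass
class DownsampleReport:
    """Per-permutation DE/overlap tallies from the down-sampling procedure."""

    permutations: pd.DataFrame
    targets: dict
    seed: int
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            prop = self.permutations.proportion_same.dropna()
            self.summary = {
                "median_n_both": float(self.permutations.n_both.median()),
                "median_proportion_same": float(prop.median()) if len(prop) else float("nan"),
                "q05_proportion_same": float(prop.quantile(0.05)) if len(prop) else float("nan"),
                "q95_proportion_same": float(prop.quantile(0.95)) if len(prop) else float("nan"),
            }


# ---------------------------------------------------------------------------


def hypergeom_overlap_p(background: int, n_a: int, n_b: int, n_both: int) -> float:
    """Upper-tail P(X >= n_both), X ~ Hypergeom(N=background, K=n_a, n=n_b)."""
    if background <= 0:
        raise ValueError("empty background universe")
    if n_a > background or n_b > background or n_both > min(n_a, n_b):
        raise ValueError("inconsistent overlap counts")
    return float(stats.hypergeom.sf(n_both - 1, background, n_a, n_b))


def _shared_universe(de_a: ContrastResult, de_b: ContrastResult) -> pd.Index:
    genes_a = de_a.tested.index
    genes_b = de_b.tested.index
    return genes_a.intersection(genes_b)


def overlap_fisher(
    de_a: ContrastResult,
    de_b: ContrastResult,
    alpha: float | None = None,
    background: int | None = None,
) -> tuple[OverlapTable, float]:
    """Overlap of significance calls between two contrasts + enrichment p.

    The background defaults to the genes tested in both contrasts;
    ``background`` can override it with a fixed universe size N (>= the
    union of significant genes).
    """
    alpha_a = alpha if alpha is not None else de_a.alpha
    alpha_b = alpha if alpha is not None else de_b.alpha
    universe = _shared_universe(de_a, de_b)
    if len(universe) == 0:
        raise ValueError("no shared tested genes between the two contrasts")
    sig_a = set(de_a.tested.index[de_a.tested.padj <= alpha_a]) & set(universe)
    sig_b = set(de_b.tested.index[de_b.tested.padj <= alpha_b]) & set(universe)
    n_both = len(sig_a & sig_b)
    n_a_only = len(sig_a - sig_b)
    n_b_only = len(sig_b - sig_a)
    n = background if background is not None else len(universe)
    n_neither = n - n_both - n_a_only - n_b_only
    if n_neither < 0:
        raise ValueError("background smaller than the union of significant genes")
    table = OverlapTable(n_both, n_a_only, n_b_only, n_neither)
    p = hypergeom_overlap_p(table.background, table.n_a, table.n_b, table.n_both)
    return table, p


def summarize_directions(
    de_a: ContrastResult, de_b: ContrastResult, alpha: float | None = None
) -> DirectionSummary:
    """Tally same/opposite LFC signs among genes significant in both.

    Requires the same sign convention in both contrasts (specialist
    relative to generalist).  Genes with an LFC of exactly zero in either
    contrast are excluded from the tallies with a logged warning.
    """
    alpha_a = alpha if alpha is not None else de_a.alpha
    alpha_b = alpha if alpha is not None else de_b.alpha
    universe = _shared_universe(de_a, de_b)
    if len(universe) == 0:
        raise ValueError("mismatched gene universes: no shared tested genes")
    ta = de_a.tested.loc[de_a.tested.index.intersection(universe)]
    tb = de_b.tested.loc[de_b.tested.index.intersection(universe)]
    both = ta.index[ta.padj <= alpha_a].intersection(tb.index[tb.padj <= alpha_b])
    lfc_a = ta.loc[both, "log2fc"].to_numpy()
    lfc_b = tb.loc[both, "log2fc"].to_numpy()
    zero = (lfc_a == 0) | (lfc_b == 0)
    if zero.any():
        logger.warning(
            "%d overlapping gene(s) with a log2 fold change of exactly 0 "
            "excluded from direction tallies",
            int(zero.sum()),
        )
    lfc_a, lfc_b = lfc_a[~zero], lfc_b[~zero]
    same = np.sign(lfc_a) == np.sign(lfc_b)
    up_both = same & (lfc_a > 0)
    down_both = same & (lfc_a < 0)
    return DirectionSummary(
        n_overlap=int(len(lfc_a)),
        n_same=int(same.sum()),
        n_opposite=int((~same).sum()),
        n_up_both=int(up_both.sum()),
        n_down_both=int(down_both.sum()),
    )


def permute_direction_null(
    n_overlap: int,
    n_same: int,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Binomial(n_overlap, 1/2) permutation null for the concordant count.

    Empirical one-sided p = (1 + #{draws >= n_same}) / (1 + n_permutations);
    the exact tail P(X >= n_same) is reported alongside for cross-checking.
    """
    if not 0 <= n_same <= n_overlap:
        raise ValueError("need 0 <= n_same <= n_overlap")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n_overlap, 0.5, size=n_permutations)
    empirical = (1 + int((draws >= n_same).sum())) / (1 + n_permutations)
    exact = float(stats.binom.sf(n_same - 1, n_overlap, 0.5)) if n_overlap else 1.0
    return PermutationResult(
        n_permutations=n_permutations,
        observed=n_same,
        empirical_p=float(empirical),
        exact_p=exact,
        null_mean=float(draws.mean()),
        null_sd=float(draws.std()),
        seed=seed,
    )


def downsample_concordance(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    target_generalist: int,
    target_snail: int,
    n_permutations: int = 1_000,
    alpha: float = 0.05,
    stage: str | None = None,
    seed: int = 0,
    specialist_a: str = "snail_eater",
    specialist_b: str = "scale_eater",
    generalist: str = "generalist",
) -> DownsampleReport:
    """Down-sampling robustness check for the concordant fraction.

    Each permutation subsamples generalists and the first specialist
    without replacement to the target sizes (matching the second
    specialist's sample size), re-runs both contrasts, and records the
    per-permutation DE counts, overlap, and proportion of same-direction
    genes among the overlap.
    """
    sel = samples if stage is None else samples[samples.stage == stage]
    gen_ids = sel.sample_id[sel.species == generalist].tolist()
    a_ids = sel.sample_id[sel.species == specialist_a].tolist()
    b_ids = sel.sample_id[sel.species == specialist_b].tolist()
    if target_generalist > len(gen_ids) or target_snail > len(a_ids):
        raise ValueError("down-sampling targets exceed available samples")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_permutations):
        gen_sub = list(rng.choice(gen_ids, size=target_generalist, replace=False))
        a_sub = list(rng.choice(a_ids, size=target_snail, replace=False))
        keep = gen_sub + a_sub + b_ids
        sub_samples = sel[sel.sample_id.isin(keep)]
        sub_counts = counts[sub_samples.sample_id.tolist()]
        de_a = test_contrast(
            sub_counts, sub_samples, (generalist, specialist_a), alpha=alpha
        )
        de_b = test_contrast(
            sub_counts, sub_samples, (generalist, specialist_b), alpha=alpha
        )
        n_de_a = len(de_a.significant)
        n_de_b = len(de_b.significant)
        try:
            direction = summarize_directions(de_a, de_b, alpha=alpha)
            n_both = direction.n_overlap
            prop_same = direction.n_same / n_both if n_both else np.nan
        except ValueError:
            n_both, prop_same = 0, np.nan
        records.append(
            {
                "n_de_a": n_de_a,
                "n_de_b": n_de_b,
                "n_both": n_both,
                "proportion_same": prop_same,
            }
        )
    report = DownsampleReport(
        permutations=pd.DataFrame(records),
        targets={"generalist": target_generalist, "snail_eater": target_snail},
        seed=seed,
    )
    return report
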