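"""Composite-likelihood-ratio scan for hard selective sweeps.

A scaffold is sectioned into equal windows; the null model says each
window's folded site-frequency spectrum matches the scaffold-wide (or a
user-supplied neutral) spectrum Phi.  The sweep alternative transforms Phi
through a star-genealogy hitchhiking model: at distance d from the sweep
position, each of the n_p sampled lineages escapes the sweep independently
with probability p_e = 1 - exp(-alpha * d); escaped lineages retain their
original alleles (a without-replacement draw from the pre-sweep sample
configuration), while non-escaped lineages coalesce onto the sweeping
haplotype and inherit its allele in a single Bernoulli draw at the
pre-sweep minor frequency.  The resulting count is folded and conditioned
on polymorphism.  The window CLR is 2 * (max over the alpha grid of the
composite log likelihood minus the background log likelihood), floored at
zero; outliers are windows above a per-scaffold CLR percentile.

In the all-escape limit (large alpha, p_e -> 1) every lineage keeps its
allele, so the transformed spectrum equals Phi exactly -- the neutral end
of the grid recovers the null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, VariantTable

DEFAULT_ALPHA_GRID = np.geomspace(1e-7, 1e-1, 25)


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum at projection size n_p.

    ``counts`` holds (possibly fractional, after hypergeometric projection)
    site counts over minor-allele classes 1..n_p//2; ``probs`` is the
    normalized spectrum Phi.
    """

    n_p: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n_p < 4:
            raise ValueError("projection size n_p must be >= 4")
        if len(self.counts) != self.n_p // 2:
            raise ValueError("counts must cover classes 1..n_p//2")
        if np.any(self.counts < 0):
            raise ValueError("class counts must be non-negative")

    @property
    def probs(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("empty spectrum")
        return self.counts / total

    @property
    def n_classes(self) -> int:
        return self.n_p // 2


def fold(count: int | np.ndarray, n_p: int) -> int | np.ndarray:
    """Minor-allele class of an allele count out of n_p."""
    return np.minimum(count, n_p - count)


def site_minor_counts(variants: VariantTable) -> tuple[np.ndarray, np.ndarray]:
    """(called allele count, alt allele count) per site."""
    g = variants.genotypes
    called = g != MISSING
    m = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    return m.astype(np.int64), alt.astype(np.int64)


def folded_sfs(variants: VariantTable, n_p: int | None = None) -> FoldedSFS:
    """Folded SFS with hypergeometric projection to ``n_p`` alleles.

    Sites whose called allele count m is below n_p are excluded
    (unprojectable); a site with alt count c contributes to class
    fold(j, n_p) the probability that a draw of n_p alleles without
    replacement from (c alt, m - c ref) contains j alt copies, and the
    mass landing in class 0 (monomorphic after projection) is dropped.
    """
    if n_p is None:
        n_p = 2 * variants.n_samples
    if n_p < 4:
        raise ValueError("projection size n_p must be >= 4")
    m, alt = site_minor_counts(variants)
    counts = np.zeros(n_p // 2)
    j = np.arange(n_p + 1)
    folded_class = fold(j, n_p)
    for mi, ci in zip(m, alt):
        if mi < n_p:
            continue
        if mi == n_p:
            cls = int(fold(int(ci), n_p))
            if cls > 0:
                counts[cls - 1] += 1.0
            continue
        pmf = stats.hypergeom.pmf(j, mi, ci, n_p)
        for cls in range(1, n_p // 2 + 1):
            counts[cls - 1] += pmf[folded_class == cls].sum()
    return FoldedSFS(n_p=n_p, counts=counts)


# ---------------------------------------------------------------------------
# sweep spectrum transform


def sweep_transition_matrix(background: FoldedSFS) -> np.ndarray:
    """T[k, c]: folded-class distribution given k escaped lineages.

    Marginalizes the pre-sweep class b ~ Phi, the escaped derived count
    j ~ Hypergeom(n_p, b, k), and the collapsed lineage's Bernoulli(b/n_p)
    allele.  Column 0 carries the monomorphic mass; columns 1..n_p//2 the
    polymorphic folded classes.  Rows sum to 1.
    """
    n_p = background.n_p
    phi = background.probs
    ncls = n_p // 2
    T = np.zeros((n_p + 1, ncls + 1))
    for b in range(1, ncls + 1):
        pb = b / n_p
        w_b = phi[b - 1]
        if w_b == 0:
            continue
        for k in range(n_p + 1):
            j_lo = max(0, k - (n_p - b))
            j_hi = min(b, k)
            j = np.arange(j_lo, j_hi + 1)
            pj = stats.hypergeom.pmf(j, n_p, b, k)
            tot_derived = fold(j + (n_p - k), n_p)
            tot_plain = fold(j, n_p)
            np.add.at(T[k], tot_derived, w_b * pj * pb)
            np.add.at(T[k], tot_plain, w_b * pj * (1.0 - pb))
    return T


def sweep_class_distribution(
    background: FoldedSFS, p_escape: np.ndarray
) -> np.ndarray:
    """P_alpha(class | polymorphic) per site for escape probabilities p_e.

    Returns an array (n_sites, n_p//2) of conditional folded-class
    probabilities; exact (no grid interpolation).
    """
    n_p = background.n_p
    T = sweep_transition_matrix(background)
    p_e = np.clip(np.atleast_1d(np.asarray(p_escape, dtype=float)), 1e-12, 1.0)
    k = np.arange(n_p + 1)
    W = stats.binom.pmf(k[None, :], n_p, p_e[:, None])
    D = W @ T
    poly = np.clip(1.0 - D[:, 0], 1e-300, None)
    return D[:, 1:] / poly[:, None]


@dataclass
class SweepScan:
    """Per-window CLR results for one scaffold."""

    windows: pd.DataFrame  # scaffold start end midpoint n_snps clr alpha_hat eligible
    scaffold: str
    n_p: int
    alpha_grid: np.ndarray
    threshold: float | None = None


def sweep_clr_scan(
    variants: VariantTable,
    background: FoldedSFS | None = None,
    n_windows: int = 1_000,
    alpha_grid: np.ndarray | None = None,
    min_snps: int = 5,
    scaffold_length: int | None = None,
) -> SweepScan:
    """CLR scan of one scaffold against the background spectrum.

    The scaffold is split into ``n_windows`` equal windows; each window
    with at least ``min_snps`` complete-call sites gets CLR = max(0,
    2 * max_alpha [l(alpha) - l0]) where l(alpha) sums log sweep-class
    probabilities at the window midpoint and l0 sums log Phi.  The
    background defaults to the scaffold's own folded spectrum; a supplied
    (e.g. bottleneck-corrected) spectrum overrides it and must use the
    same projection size.
    """
    scafs = pd.unique(variants.scaffold)
    if len(scafs) != 1:
        raise ValueError("sweep_clr_scan expects variants from a single scaffold")
    scaffold = str(scafs[0])
    if variants.n_snps == 0:
        raise ValueError("empty scaffold")
    alpha_grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    n_p = 2 * variants.n_samples

    length = scaffold_length or int(variants.pos.max())
    if length <= 10_000:
        raise ValueError(
            f"scaffold {scaffold} is {length} bp (<= 10 kb); skipped from scanning"
        )

    m, alt = site_minor_counts(variants)
    complete = m == n_p
    pos = variants.pos[complete]
    cls = np.asarray(fold(alt[complete], n_p))
    poly = (cls > 0) & (cls <= n_p // 2)
    pos, cls = pos[poly], cls[poly]

    if background is None:
        background = folded_sfs(variants, n_p=n_p)
    if background.n_p != n_p:
        raise ValueError(
            f"background spectrum projection ({background.n_p}) does not match "
            f"the sample allele count ({n_p})"
        )
    phi = background.probs
    if (phi > 0).sum() < 2:
        raise ValueError("background spectrum needs at least 2 occupied classes")
    log_phi = np.log(np.clip(phi, 1e-300, None))

    T = sweep_transition_matrix(background)
    k_arr = np.arange(n_p + 1)

    edges = np.linspace(0, length, n_windows + 1)
    win_idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_windows - 1)

    rows = []
    for w in range(n_windows):
        start, end = edges[w], edges[w + 1]
        mid = 0.5 * (start + end)
        in_w = win_idx == w
        n_snps = int(in_w.sum())
        if n_snps < min_snps:
            rows.append(
                {
                    "scaffold": scaffold,
                    "start": start,
                    "end": end,
                    "midpoint": mid,
                    "n_snps": n_snps,
                    "clr": 0.0,
                    "alpha_hat": np.nan,
                    "eligible": False,
                }
            )
            continue
        d = np.abs(pos[in_w] - mid)
        c = cls[in_w]
        l0 = log_phi[c - 1].sum()
        best_ll, best_alpha = -np.inf, np.nan
        for alpha in alpha_grid:
            p_e = np.clip(1.0 - np.exp(-alpha * d), 1e-12, 1.0)
            W = stats.binom.pmf(k_arr[None, :], n_p, p_e[:, None])
            D = W @ T
            polymass = np.clip(1.0 - D[:, 0], 1e-300, None)
            probs = np.clip(D[np.arange(n_snps), c] / polymass, 1e-300, None)
            ll = np.log(probs).sum()
            if ll > best_ll:
                best_ll, best_alpha = ll, alpha
        clr = max(0.0, 2.0 * (best_ll - l0))
        rows.append(
            {
                "scaffold": scaffold,
                "start": start,
                "end": end,
                "midpoint": mid,
                "n_snps": n_snps,
                "clr": clr,
                "alpha_hat": best_alpha if clr > 0 else np.nan,
                "eligible": True,
            }
        )
    return SweepScan(
        windows=pd.DataFrame(rows),
        scaffold=scaffold,
        n_p=n_p,
        alpha_grid=alpha_grid,
    )


def flag_outlier_windows(
    scan: SweepScan, percentile: float = 95.0, min_eligible: int = 20
) -> SweepScan:
    """Flag windows whose CLR exceeds the per-scaffold percentile.

    The threshold is taken over eligible windows only; windows strictly
    above it are flagged.  Scaffolds with fewer than ``min_eligible``
    eligible windows are reported unscannable.
    """
    eligible = scan.windows.eligible.to_numpy()
    if eligible.sum() < min_eligible:
        raise ValueError(
            f"scaffold {scan.scaffold}: only {int(eligible.sum())} eligible "
            f"windows (< {min_eligible}); unscannable"
        )
    clrs = scan.windows.clr.to_numpy()
    threshold = float(np.percentile(clrs[eligible], percentile))
    scan.windows["flagged"] = eligible & (clrs > threshold)
    scan.threshold = threshold
    return scan
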