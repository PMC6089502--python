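"""Synthetic study generators with recorded ground truth.

Each simulator is a pure, seeded function of its config: expression studies
(negative-binomial counts with configurable gene classes), two-population
genotype panels (Balding-Nichols differentiation plus forced fixed
differences), sweep-distorted scaffolds (star-genealogy hitchhiking on the
folded neutral spectrum), gene models, and over-dispersed pleiotropy count
tables.  The defaults mirror the study design being emulated: three species
(one generalist, two trophic specialists) at two larval stages, with most
genes unaffected and shared differential expression overwhelmingly
concordant in direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GeneModel, VariantTable

GENERALIST = "generalist"
SNAIL_EATER = "snail_eater"
SCALE_EATER = "scale_eater"
SPECIES = (GENERALIST, SNAIL_EATER, SCALE_EATER)
STAGES = ("8-10dpf", "17-20dpf")

GENE_CLASSES = (
    "null",
    "parallel_up",
    "parallel_down",
    "snail_only",
    "scale_only",
    "opposite",
)

#: Default sampling design: samples per (species, stage).  Scale-eater
#: groups are smaller at both stages, which is what the down-sampling
#: robustness procedure exercises.
DEFAULT_DESIGN: dict[tuple[str, str], int] = {
    (GENERALIST, "8-10dpf"): 6,
    (SNAIL_EATER, "8-10dpf"): 6,
    (SCALE_EATER, "8-10dpf"): 3,
    (GENERALIST, "17-20dpf"): 6,
    (SNAIL_EATER, "17-20dpf"): 6,
    (SCALE_EATER, "17-20dpf"): 2,
}

#: Default gene-class mix: most genes null, shared DE mostly concordant,
#: more specialist-specific DE in the scale-eater contrast.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "null": 0.88,
    "parallel_up": 0.02,
    "parallel_down": 0.03,
    "snail_only": 0.01,
    "scale_only": 0.055,
    "opposite": 0.005,
}


class ConfigurationError(ValueError):
    """Raised for invalid simulator configuration."""


def largest_remainder_counts(fractions: Sequence[float], total: int) -> np.ndarray:
    """Partition ``total`` into integer counts proportional to ``fractions``.

    Deterministic largest-remainder (Hamilton) rounding; ties broken by
    position, so the partition is reproducible.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-12:
        raise ConfigurationError("fractions must be non-negative and sum to 1")
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    shortfall = total - counts.sum()
    if shortfall:
        remainders = raw - counts
        # stable: largest remainder first, earlier index wins ties
        order = np.lexsort((np.arange(len(fractions)), -remainders))
        counts[order[:shortfall]] += 1
    return counts


# ---------------------------------------------------------------------------
# expression study


@dataclass
class ExpressionSimConfig:
    """Configuration of the synthetic RNA-seq count study.

    ``class_fractions`` give proportions over the six gene classes;
    ``lfc_magnitude`` is the |log2 fold change| for affected genes;
    ``base_mean_log_params`` are (meanlog, sdlog) of the log-normal
    baseline expression; ``dispersion_params`` are the (a0, a1) of the
    mean-dispersion trend alpha(mu) = a0/mu + a1; ``depth_sigma`` is the
    sdlog of the per-sample log-normal depth factor.
    """

    n_genes: int = 20_000
    samples_per_group: int | Mapping | None = None
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    lfc_magnitude: float = 2.0
    base_mean_log_params: tuple[float, float] = (4.0, 1.5)
    dispersion_params: tuple[float, float] = (2.0, 0.05)
    depth_sigma: float = 0.3
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.lfc_magnitude <= 0:
            raise ConfigurationError("lfc_magnitude must be > 0")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown gene classes: {sorted(unknown)}")
        fracs = [self.class_fractions.get(c, 0.0) for c in GENE_CLASSES]
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-12:
            raise ConfigurationError("class_fractions must sum to 1 +- 1e-12")
        for n in self._design().values():
            if n < 1:
                raise ConfigurationError("samples_per_group entries must be >= 1")

    def _design(self) -> dict[tuple[str, str], int]:
        if self.samples_per_group is None:
            return {
                k: v for k, v in DEFAULT_DESIGN.items() if k[1] in self.stages
            }
        if isinstance(self.samples_per_group, int):
            return {
                (sp, st): self.samples_per_group
                for sp in SPECIES
                for st in self.stages
            }
        design = {}
        for key, n in dict(self.samples_per_group).items():
            if isinstance(key, str):  # per-species count, all stages
                for st in self.stages:
                    design[(key, st)] = int(n)
            else:
                design[tuple(key)] = int(n)
        return design


def simulate_expression_study(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate counts, a sample sheet, and per-gene truth.

    Counts[g, j] ~ NB(mean = baseline_g * 2^lfc(class_g, species_j) *
    depth_j, dispersion = trend(baseline_g)).  Truth records the class
    label and the true log2 fold changes of each specialist contrast
    (specialist relative to generalist).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    counts_per_class = largest_remainder_counts(
        [config.class_fractions.get(c, 0.0) for c in GENE_CLASSES], n
    )
    labels = np.repeat(np.array(GENE_CLASSES, dtype=object), counts_per_class)
    labels = labels[rng.permutation(n)]

    L = config.lfc_magnitude
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc_snail = np.zeros(n)
    lfc_scale = np.zeros(n)
    lfc_snail[labels == "parallel_up"] = L
    lfc_scale[labels == "parallel_up"] = L
    lfc_snail[labels == "parallel_down"] = -L
    lfc_scale[labels == "parallel_down"] = -L
    m = labels == "snail_only"
    lfc_snail[m] = signs[m] * L
    m = labels == "scale_only"
    lfc_scale[m] = signs[m] * L
    m = labels == "opposite"
    lfc_snail[m] = signs[m] * L
    lfc_scale[m] = -signs[m] * L

    meanlog, sdlog = config.base_mean_log_params
    base = rng.lognormal(meanlog, sdlog, size=n)
    a0, a1 = config.dispersion_params
    disp = a0 / base + a1

    design = config._design()
    rows = []
    for (species, stage), size in sorted(design.items()):
        for i in range(size):
            rows.append(
                {
                    "sample_id": f"{species}_{stage.replace('-', '')}_{i + 1}",
                    "species": species,
                    "lake": ("crescent_pond", "little_lake")[i % 2],
                    "stage": stage,
                    "generation": "F2",
                }
            )
    samples = pd.DataFrame(rows)
    depth = rng.lognormal(0.0, config.depth_sigma, size=len(samples))

    lfc_by_species = {GENERALIST: np.zeros(n), SNAIL_EATER: lfc_snail, SCALE_EATER: lfc_scale}
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, row in samples.iterrows():
        mu = base * 2.0 ** lfc_by_species[row.species] * depth[j]
        r = 1.0 / disp
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    genes = [f"gene_{i + 1:05d}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples.sample_id.tolist())
    counts_df.index.name = "feature_id"
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "class_label": labels,
            "lfc_snail": lfc_snail,
            "lfc_scale": lfc_scale,
        }
    )
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# genotype study


@dataclass
class GenotypeSimConfig:
    """Two-population biallelic SNP panel under the Balding-Nichols model."""

    n_snps: int = 10_000
    samples_per_pop: int = 20
    F_model: float = 0.1
    n_fixed: int = 0
    missing_rate: float = 0.0
    scaffold_length: int = 1_000_000
    scaffold: str = "scaffold_1"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.F_model < 1:
            raise ConfigurationError("F_model must be in [0, 1)")
        if self.n_fixed > self.n_snps:
            raise ConfigurationError("n_fixed must be <= n_snps")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.n_snps < 1 or self.samples_per_pop < 1:
            raise ConfigurationError("n_snps and samples_per_pop must be >= 1")
        if self.n_snps > self.scaffold_length:
            raise ConfigurationError("more SNPs than scaffold positions")


def simulate_genotype_study(
    config: GenotypeSimConfig,
) -> tuple[VariantTable, pd.DataFrame, dict]:
    """Simulate genotypes for two populations plus forced fixed differences.

    Ancestral frequencies are Uniform(0.05, 0.95); each population draws its
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) (identical to the ancestral
    frequency when F = 0); diploid genotypes are Binomial(2, p_pop).
    ``n_fixed`` random loci are overwritten with alt frequency 1 in pop1 and
    0 in pop2.  Missing genotypes are masked uniformly at ``missing_rate``.
    Truth records the fixed positions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_snps, config.samples_per_pop

    pos = np.sort(rng.choice(config.scaffold_length, size=n, replace=False)) + 1
    p_anc = rng.uniform(0.05, 0.95, size=n)
    F = config.F_model
    if F > 0:
        shape = (1.0 - F) / F
        pA = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        pB = rng.beta(p_anc * shape, (1 - p_anc) * shape)
    else:
        pA = p_anc.copy()
        pB = p_anc.copy()

    gA = rng.binomial(2, pA[:, None], size=(n, m)).astype(np.int8)
    gB = rng.binomial(2, pB[:, None], size=(n, m)).astype(np.int8)

    fixed_idx = np.sort(rng.choice(n, size=config.n_fixed, replace=False))
    gA[fixed_idx] = 2
    gB[fixed_idx] = 0

    genotypes = np.concatenate([gA, gB], axis=1)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    bases = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4

    samples = [f"pop1_{i + 1}" for i in range(m)] + [f"pop2_{i + 1}" for i in range(m)]
    variants = VariantTable(
        scaffold=np.full(n, config.scaffold, dtype=object),
        pos=pos,
        ref=bases[ref_i],
        alt=bases[alt_i],
        genotypes=genotypes,
        samples=samples,
    )
    pops = pd.DataFrame(
        {
            "sample_id": samples,
            "population": ["pop1"] * m + ["pop2"] * m,
        }
    )
    truth = {"fixed_positions": pos[fixed_idx].tolist()}
    return variants, pops, truth


# ---------------------------------------------------------------------------
# sweep scaffolds


@dataclass
class SweepSimConfig:
    """One scaffold of polymorphic sites, optionally distorted by a sweep."""

    scaffold_length: int = 100_000
    n_sites: int = 2_000
    n_alleles: int = 20
    sweep_center: int | None = None
    sweep_alpha_true: float = 1e-4
    scaffold: str = "scaffold_1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_alleles < 4:
            raise ConfigurationError("need at least 4 sampled alleles")
        if self.n_alleles % 2:
            raise ConfigurationError("n_alleles must be even (diploid samples)")
        if self.sweep_center is not None and not (
            1 <= self.sweep_center <= self.scaffold_length
        ):
            raise ConfigurationError("sweep_center outside scaffold")
        if self.n_sites > self.scaffold_length:
            raise ConfigurationError("more sites than scaffold positions")
        if self.sweep_alpha_true <= 0:
            raise ConfigurationError("sweep_alpha_true must be > 0")


def neutral_folded_spectrum(n_alleles: int) -> np.ndarray:
    """Folded standard-neutral spectrum over minor classes 1..n/2.

    Class i has weight (1/i + 1/(n-i)), halved when i = n - i, then
    normalized.
    """
    i = np.arange(1, n_alleles // 2 + 1)
    w = 1.0 / i + 1.0 / (n_alleles - i)
    w[i == n_alleles - i] /= 2.0
    return w / w.sum()


def simulate_sweep_scaffold(
    config: SweepSimConfig,
) -> tuple[VariantTable, dict]:
    """Simulate per-site folded minor-allele classes along one scaffold.

    Neutral sites draw their folded class from the standard neutral
    spectrum.  With a sweep at ``sweep_center``, a site at distance d lets
    each of the n sampled lineages escape the sweep independently with
    probability 1 - exp(-alpha * d); escaped lineages retain their original
    alleles (a without-replacement draw from the pre-sweep configuration)
    while the non-escaped lineages coalesce onto the sweeping haplotype and
    inherit its allele in a single Bernoulli(minor frequency) draw.  Sites
    monomorphic after the sweep are dropped.  Genotypes pair alleles at
    random into n/2 diploid samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_alleles
    phi = neutral_folded_spectrum(n)
    classes_avail = np.arange(1, n // 2 + 1)

    pos = np.sort(rng.choice(config.scaffold_length, size=config.n_sites, replace=False)) + 1
    b = rng.choice(classes_avail, size=config.n_sites, p=phi)

    if config.sweep_center is None:
        minor = b
        keep = np.ones(config.n_sites, dtype=bool)
    else:
        d = np.abs(pos - config.sweep_center)
        p_escape = 1.0 - np.exp(-config.sweep_alpha_true * d)
        k = rng.binomial(n, p_escape)
        j = rng.hypergeometric(b, n - b, k)  # escaped lineages carrying minor allele
        collapsed = rng.random(config.n_sites) < b / n
        total = j + np.where(collapsed, n - k, 0)
        minor = np.minimum(total, n - total)
        keep = (minor > 0) & (minor <= n // 2)

    pos, minor = pos[keep], minor[keep]
    n_kept = len(pos)

    genotypes = np.zeros((n_kept, n // 2), dtype=np.int8)
    for s in range(n_kept):
        slots = np.zeros(n, dtype=np.int8)
        slots[rng.choice(n, size=minor[s], replace=False)] = 1
        genotypes[s] = slots.reshape(-1, 2).sum(axis=1)

    bases = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, size=n_kept)
    alt_i = (ref_i + rng.integers(1, 4, size=n_kept)) % 4
    variants = VariantTable(
        scaffold=np.full(n_kept, config.scaffold, dtype=object),
        pos=pos,
        ref=bases[ref_i],
        alt=bases[alt_i],
        genotypes=genotypes,
        samples=[f"s{i + 1}" for i in range(n // 2)],
    )
    truth = {
        "sweep_center": config.sweep_center,
        "sweep_alpha_true": config.sweep_alpha_true,
        "scaffold_length": config.scaffold_length,
        "n_alleles": n,
    }
    return variants, truth


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(
    n_genes: int,
    scaffold_length: int,
    scaffold: str = "scaffold_1",
    gene_ids: Sequence[str] | None = None,
    exons_per_gene: tuple[int, int] = (2, 6),
    exon_length: tuple[int, int] = (100, 400),
    intron_length: tuple[int, int] = (200, 2_000),
    seed: int = 0,
    anchor_positions: Sequence[int] | None = None,
) -> list[GeneModel]:
    """Place non-overlapping multi-exon gene models on one scaffold.

    When ``anchor_positions`` is given, the first genes are placed so that
    each anchor falls inside the gene span (useful for seeding known
    cis-variant / gene intersections).
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    genes: list[GeneModel] = []
    occupied: list[tuple[int, int]] = []

    def build(start: int, gid: str) -> GeneModel | None:
        n_ex = rng.integers(exons_per_gene[0], exons_per_gene[1] + 1)
        exons = []
        cur = start
        for _ in range(n_ex):
            length = int(rng.integers(exon_length[0], exon_length[1] + 1))
            exons.append((cur, cur + length - 1))
            cur += length + int(rng.integers(intron_length[0], intron_length[1] + 1))
        if exons[-1][1] > scaffold_length:
            return None
        return GeneModel(gid, scaffold, exons, strand=rng.choice(["+", "-"]))

    def overlaps(span: tuple[int, int]) -> bool:
        return any(s <= span[1] and span[0] <= e for s, e in occupied)

    anchor_positions = list(anchor_positions or [])
    for gi, gid in enumerate(gene_ids[:n_genes]):
        placed = None
        for _ in range(200):
            if gi < len(anchor_positions):
                anchor = anchor_positions[gi]
                start = max(1, anchor - int(rng.integers(200, 2_000)))
            else:
                start = int(rng.integers(1, max(2, scaffold_length - 5_000)))
            cand = build(start, gid)
            if cand is None or overlaps((cand.start, cand.end)):
                continue
            if gi < len(anchor_positions) and not (
                cand.start <= anchor_positions[gi] <= cand.end
            ):
                continue
            placed = cand
            break
        if placed is not None:
            genes.append(placed)
            occupied.append((placed.start, placed.end))
    return sorted(genes, key=lambda g: g.start)


# ---------------------------------------------------------------------------
# pleiotropy tables


def simulate_pleiotropy_table(
    n_per_group: int,
    rate_ratio: float = 1.0,
    dispersion: float = 0.5,
    seed: int = 0,
    base_means: tuple[float, float, float] = (8.0, 12.0, 5.0),
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-gene pleiotropy-proxy counts for two gene groups.

    Three metrics (biological processes, PPIs, developmental stages) are
    drawn NB2 with variance mu + dispersion * mu^2; the "divergent" group
    mean is ``rate_ratio`` times the "parallel" group mean for every metric.
    """
    if n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    if rate_ratio <= 0 or dispersion < 0:
        raise ConfigurationError("rate_ratio must be > 0 and dispersion >= 0")
    rng = np.random.default_rng(seed)
    groups = ["parallel"] * n_per_group + ["divergent"] * n_per_group
    mult = np.array([1.0] * n_per_group + [rate_ratio] * n_per_group)
    data = {"gene_id": [f"gene_{i + 1:05d}" for i in range(2 * n_per_group)], "group": groups}
    for name, mu0 in zip(("n_processes", "n_ppi", "n_stages"), base_means):
        mu = mu0 * mult
        if dispersion > 0:
            r = 1.0 / dispersion
            data[name] = rng.negative_binomial(r, r / (r + mu))
        else:
            data[name] = rng.poisson(mu)
    truth = {"rate_ratio": rate_ratio, "log_rate_ratio": float(np.log(rate_ratio))}
    return pd.DataFrame(data), truth
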