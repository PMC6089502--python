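"""Pipeline orchestration: input validation, evidence intersection, and the
end-to-end run that chains simulation, differential expression,
concordance, Fst/regions, sweep scanning, intersection, and pleiotropy
into a single seeded, reproducible report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import de_core, pleiotropy, popgen, sweep_scan, synthetic_data
from .io import (
    VariantTable,
    read_counts,
    read_gff3,
    read_pleiotropy_table,
    read_population_file,
    read_sample_table,
    read_vcf,
    write_counts,
    write_gff3,
    write_pleiotropy_table,
    write_population_file,
    write_sample_table,
    write_vcf,
)

logger = logging.getLogger(__name__)

PROXIMAL_CATEGORIES = ("exonic", "intronic", "within_10kb")


@dataclass
class CandidateIntersection:
    """One DE gene carrying fixed variation in its region."""

    gene_id: str
    contrasts: list[str]
    stages: list[str]
    fixed_snps: list[dict]  # scaffold, pos, category
    sweep_flagged: bool

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "contrasts": self.contrasts,
            "stages": self.stages,
            "fixed_snps": self.fixed_snps,
            "sweep_flagged": self.sweep_flagged,
        }


def intersect_candidates(
    de_results: dict[str, de_core.ContrastResult],
    regions: popgen.RegionAssignment,
    fixed_positions: set[tuple[str, int]],
    scan: sweep_scan.SweepScan | None = None,
    alpha: float | None = None,
) -> list[CandidateIntersection]:
    """DE genes with >= 1 fixed SNP in their region (exonic/intronic/10 kb).

    ``de_results`` maps labels like ``"snail_eater@8-10dpf"`` to contrast
    results; distal fixed SNPs never produce a record.  When a sweep scan
    is given, a candidate is sweep-flagged if any of its fixed SNPs falls
    in a flagged window.
    """
    if regions.pairs.empty:
        return []
    de_scaffolds = set(regions.pairs.scaffold)
    if scan is not None:
        if scan.scaffold not in de_scaffolds:
            raise ValueError(
                f"coordinate-system mismatch: sweep scan scaffold {scan.scaffold!r} "
                f"absent from region assignment scaffolds {sorted(de_scaffolds)}"
            )
        if "flagged" not in scan.windows.columns:
            scan = sweep_scan.flag_outlier_windows(scan)

    sig_by_label: dict[str, set] = {}
    for label, res in de_results.items():
        a = alpha if alpha is not None else res.alpha
        sig_by_label[label] = set(res.tested.index[res.tested.padj <= a])

    pairs = regions.pairs
    fixed_mask = [
        (scaf, int(p)) in fixed_positions
        for scaf, p in zip(pairs.scaffold, pairs.pos)
    ]
    fixed_pairs = pairs[np.array(fixed_mask, dtype=bool)] if len(pairs) else pairs
    fixed_pairs = fixed_pairs[fixed_pairs.category.isin(PROXIMAL_CATEGORIES)]

    records = []
    for gene_id, gene_pairs in fixed_pairs.groupby("gene_id"):
        labels = [lab for lab, sig in sig_by_label.items() if gene_id in sig]
        if not labels:
            continue
        snps = gene_pairs[["scaffold", "pos", "category"]].to_dict(orient="records")
        flagged = False
        if scan is not None:
            win = scan.windows[scan.windows.flagged]
            for snp in snps:
                if snp["scaffold"] != scan.scaffold:
                    continue
                hit = (win.start <= snp["pos"]) & (snp["pos"] <= win.end)
                if hit.any():
                    flagged = True
                    break
        contrasts = sorted({lab.split("@")[0] for lab in labels})
        stages = sorted({lab.split("@")[1] for lab in labels if "@" in lab})
        records.append(
            CandidateIntersection(
                gene_id=str(gene_id),
                contrasts=contrasts,
                stages=stages,
                fixed_snps=snps,
                sweep_flagged=flagged,
            )
        )
    return sorted(records, key=lambda r: r.gene_id)


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict) -> list[str]:
    """Schema checks on input files; returns actionable issue strings."""
    issues: list[str] = []
    counts = samples = None
    if "counts" in paths:
        try:
            counts = read_counts(paths["counts"])
        except Exception as exc:
            issues.append(f"counts: {exc}")
    if "samples" in paths:
        try:
            samples = read_sample_table(paths["samples"])
        except Exception as exc:
            issues.append(f"samples: {exc}")
    if counts is not None and samples is not None:
        missing = set(counts.columns) - set(samples.sample_id)
        if missing:
            issues.append(
                f"samples: count columns missing from sample sheet: {sorted(missing)}"
            )
        extra = set(samples.sample_id) - set(counts.columns)
        if extra:
            issues.append(
                f"samples: sheet rows without a count column: {sorted(extra)}"
            )
    if "vcf" in paths:
        try:
            from cyvcf2 import VCF

            n_multi = 0
            vcf = VCF(str(paths["vcf"]))
            for rec in vcf:
                if len(rec.ALT) != 1:
                    n_multi += 1
            vcf.close()
            if n_multi:
                issues.append(
                    f"vcf: {n_multi} multi-allelic record(s) will be skipped"
                )
        except Exception as exc:
            issues.append(f"vcf: {exc}")
    if "gff" in paths:
        try:
            read_gff3(paths["gff"])
        except Exception as exc:
            issues.append(f"gff: {exc}")
    if "pops" in paths:
        try:
            read_population_file(paths["pops"])
        except Exception as exc:
            issues.append(f"pops: {exc}")
    if "pleiotropy" in paths:
        try:
            read_pleiotropy_table(paths["pleiotropy"])
        except Exception as exc:
            issues.append(f"pleiotropy: {exc}")
    return issues


# ---------------------------------------------------------------------------
# full pipeline


DEFAULT_CONFIG = {
    "alpha": 0.05,
    "stage": "8-10dpf",
    "direction_permutations": 10_000,
    "fst_permutations": 100,
    "fst_percentile": 99.0,
    "sweep_windows": 100,
    "sweep_percentile": 95.0,
    "region_window": 10_000,
    "seeds": {"simulate": 1, "direction": 2, "fst": 3},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in user.items():
        if key == "seeds" and isinstance(value, dict):
            config["seeds"].update(value)
        else:
            config[key] = value
    return config


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full analysis and write a JSON + TSV report bundle.

    With a ``simulate`` section the inputs are generated (and written) from
    the synthetic module; otherwise paths to counts/samples/VCF/pops/GFF/
    pleiotropy files are read.  All randomness flows from the named
    per-stage seeds, so a rerun with the same config is bit-identical.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alpha = config["alpha"]
    stage = config["stage"]
    report: dict = {"config": config, "stages": {}}

    # ------------------------------------------------------------------ data
    if "simulate" in config:
        sim = config["simulate"]
        seed = config["seeds"]["simulate"]
        expr_cfg = synthetic_data.ExpressionSimConfig(
            **{**sim.get("expression", {}), "seed": seed}
        )
        counts, samples, expr_truth = synthetic_data.simulate_expression_study(expr_cfg)
        geno_cfg = synthetic_data.GenotypeSimConfig(
            **{**sim.get("genotypes", {}), "seed": seed + 1}
        )
        variants, pops, geno_truth = synthetic_data.simulate_genotype_study(geno_cfg)
        genes = synthetic_data.simulate_gene_models(
            n_genes=sim.get("n_gene_models", 50),
            scaffold_length=geno_cfg.scaffold_length,
            scaffold=geno_cfg.scaffold,
            gene_ids=list(counts.index),
            seed=seed + 2,
            anchor_positions=geno_truth["fixed_positions"][
                : sim.get("n_anchored_genes", 10)
            ],
        )
        plei, plei_truth = synthetic_data.simulate_pleiotropy_table(
            n_per_group=sim.get("pleiotropy_n_per_group", 200),
            rate_ratio=sim.get("pleiotropy_rate_ratio", 1.0),
            seed=seed + 3,
        )
        write_counts(counts, outdir / "counts.tsv")
        write_sample_table(samples, outdir / "samples.csv")
        write_vcf(variants, outdir / "genotypes.vcf")
        write_population_file(pops, outdir / "populations.tsv")
        write_gff3(genes, outdir / "genes.gff3")
        write_pleiotropy_table(plei, outdir / "pleiotropy.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "expression_classes": expr_truth.class_label.value_counts().to_dict(),
                    "fixed_positions": geno_truth["fixed_positions"],
                    "pleiotropy": plei_truth,
                },
                fh,
                indent=1,
            )
    else:
        counts = read_counts(config["counts"])
        samples = read_sample_table(config["samples"])
        variants = read_vcf(config["vcf"])
        pops = read_population_file(config["pops"])
        genes = read_gff3(config["gff"])
        plei = read_pleiotropy_table(config["pleiotropy"]) if "pleiotropy" in config else None

    # ---------------------------------------------------------------- DE
    de_results: dict[str, de_core.ContrastResult] = {}
    for specialist in ("snail_eater", "scale_eater"):
        label = f"{specialist}@{stage}"
        res = de_core.test_contrast(
            counts, samples, ("generalist", specialist), alpha=alpha, stage=stage
        )
        de_core.write_de_table(res, outdir / f"de_{specialist}_{stage}.tsv")
        de_results[label] = res
        report["stages"][f"de_{specialist}"] = {
            "n_tested": len(res.tested),
            "n_significant": len(res.significant),
            "filter_threshold": res.independent_filter_threshold,
        }

    # ------------------------------------------------------- concordance
    de_a = de_results[f"snail_eater@{stage}"]
    de_b = de_results[f"scale_eater@{stage}"]
    table, fisher_p = conc.overlap_fisher(de_a, de_b, alpha=alpha)
    direction = conc.summarize_directions(de_a, de_b, alpha=alpha)
    perm = conc.permute_direction_null(
        direction.n_overlap,
        direction.n_same,
        n_permutations=config["direction_permutations"],
        seed=config["seeds"]["direction"],
    )
    report["stages"]["concordance"] = {
        "overlap": table.to_dict(),
        "fisher_p": fisher_p,
        "direction": direction.to_dict(),
        "permutation": perm.to_dict(),
    }

    # ------------------------------------------------------------- popgen
    filtered, filter_report = popgen.filter_variants(variants)
    pop_names = sorted(pops.population.unique())
    pop_a = pops.sample_id[pops.population == pop_names[0]].tolist()
    pop_b = pops.sample_id[pops.population == pop_names[1]].tolist()
    pop_a = [s for s in pop_a if s in filtered.samples]
    pop_b = [s for s in pop_b if s in filtered.samples]
    # fixed calls use the unfiltered table: fixed differences have MAF ~0.5
    # pooled but the MAF filter is frequency-agnostic here; keep them.
    fst = popgen.weir_cockerham_fst(variants, pop_a, pop_b)
    fixed_mask = popgen.identify_fixed(fst)
    null = popgen.fst_permutation_threshold(
        filtered if filtered.n_snps else variants,
        (len(pop_a), len(pop_b)),
        n_permutations=config["fst_permutations"],
        percentile=config["fst_percentile"],
        seed=config["seeds"]["fst"],
    )
    fst.table["fixed"] = fixed_mask
    fst.table.to_csv(outdir / "fst.tsv", sep="\t", index=False)
    with open(outdir / "fst_threshold.json", "w") as fh:
        json.dump(null.to_dict(), fh, indent=1)
    fixed_positions = {
        (str(s), int(p))
        for s, p in zip(fst.table.scaffold[fixed_mask], fst.table.pos[fixed_mask])
    }
    report["stages"]["popgen"] = {
        "filter": filter_report,
        "n_fixed": int(fixed_mask.sum()),
        "fst_threshold": null.threshold,
        "n_outliers": int(np.nansum(fst.fst > null.threshold)),
    }

    # ------------------------------------------------------------ regions
    regions = popgen.assign_snp_regions(
        variants, genes, window=config["region_window"]
    )
    regions.per_snp.to_csv(outdir / "snp_regions.tsv", sep="\t", index=False)
    fixed_idx = np.flatnonzero(fixed_mask)
    fixed_cats = regions.per_snp.category.iloc[fixed_idx]
    report["stages"]["regions"] = {
        "fixed_by_category": {
            c: int((fixed_cats == c).sum()) for c in popgen.REGION_CATEGORIES
        }
    }

    # -------------------------------------------------------------- sweep
    scan = None
    try:
        scan = sweep_scan.sweep_clr_scan(
            variants,
            n_windows=config["sweep_windows"],
            scaffold_length=config.get("scaffold_length"),
        )
        scan = sweep_scan.flag_outlier_windows(
            scan, percentile=config["sweep_percentile"]
        )
        scan.windows.to_csv(outdir / "sweep_windows.tsv", sep="\t", index=False)
        report["stages"]["sweep"] = {
            "threshold": scan.threshold,
            "n_flagged": int(scan.windows.flagged.sum()),
            "n_eligible": int(scan.windows.eligible.sum()),
        }
    except ValueError as exc:
        logger.warning("sweep scan skipped: %s", exc)
        report["stages"]["sweep"] = {"skipped": str(exc)}

    # ------------------------------------------------------ intersection
    candidates = intersect_candidates(
        de_results, regions, fixed_positions, scan=scan, alpha=alpha
    )
    with open(outdir / "candidates.json", "w") as fh:
        json.dump([c.to_dict() for c in candidates], fh, indent=1)
    report["stages"]["candidates"] = {
        "n_candidates": len(candidates),
        "n_sweep_flagged": sum(c.sweep_flagged for c in candidates),
    }

    # -------------------------------------------------------- pleiotropy
    if plei is not None:
        glm = pleiotropy.compare_pleiotropy(plei)
        report["stages"]["pleiotropy"] = glm.to_dict()

    # ------------------------------------------------- printed-counts mode
    if "headline_counts" in config:
        hc = config["headline_counts"]
        report["headline"] = headline_statistics(
            background=hc["background"],
            n_a=hc["n_a"],
            n_b=hc["n_b"],
            n_both=hc["n_both"],
            n_same=hc["n_same"],
            n_permutations=hc.get("n_permutations", 10_000),
            seed=config["seeds"]["direction"],
        )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    return report


def headline_statistics(
    background: int,
    n_a: int,
    n_b: int,
    n_both: int,
    n_same: int,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Overlap, direction-null, and headline-percentage statistics from
    printed contingency counts."""
    fisher_p = conc.hypergeom_overlap_p(background, n_a, n_b, n_both)
    perm = conc.permute_direction_null(
        n_both, n_same, n_permutations=n_permutations, seed=seed
    )
    percent_same = 100.0 * n_same / n_a if n_a else float("nan")
    return {
        "fisher_p": fisher_p,
        "direction_permutation": perm.to_dict(),
        "percent_same_direction_of_smaller_list": percent_same,
        "percent_same_rounded": int(round(percent_same)),
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
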