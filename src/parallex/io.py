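"""Readers and writers for the pipeline's on-disk formats.

Counts are a TSV with the feature id in the first column and one column per
sample; the sample sheet is a CSV with columns (sample_id, species, lake,
stage, generation); genotypes are VCF 4.2 with GT fields (parsed with
cyvcf2); gene models are GFF3 gene/exon features (parsed with gffutils);
pleiotropy tables are TSV.  Coordinates follow each format's convention:
VCF and GFF3 are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing diploid call

SAMPLE_COLUMNS = ["sample_id", "species", "lake", "stage", "generation"]
PLEIOTROPY_COLUMNS = ["gene_id", "group", "n_processes", "n_ppi", "n_stages"]


@dataclass
class GeneModel:
    """A gene with its exon structure on one scaffold (1-based inclusive)."""

    gene_id: str
    scaffold: str
    exons: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for start, end in self.exons:
            if end < start:
                raise ValueError(
                    f"gene {self.gene_id}: malformed exon interval [{start}, {end}]"
                )
        self.exons = sorted(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


@dataclass
class VariantTable:
    """Biallelic SNP genotypes: one row per site, one column per sample.

    Genotypes are alt-allele dosages in {0, 1, 2} with ``MISSING`` (-1) for
    no-calls.  Positions are 1-based and strictly increasing within each
    scaffold.
    """

    scaffold: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scaffold = np.asarray(self.scaffold, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[0] != len(self.pos):
            raise ValueError("genotypes must be (n_snps, n_samples)")
        if not self.samples:
            self.samples = [f"s{i}" for i in range(self.genotypes.shape[1])]
        if len(self.samples) != self.genotypes.shape[1]:
            raise ValueError("sample names do not match genotype columns")
        for scaf in pd.unique(self.scaffold):
            p = self.pos[self.scaffold == scaf]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def take_samples(self, names: list[str]) -> "VariantTable":
        idx = [self.samples.index(n) for n in names]
        return dataclasses.replace(
            self, genotypes=self.genotypes[:, idx], samples=list(names)
        )

    def take_sites(self, mask: np.ndarray) -> "VariantTable":
        return dataclasses.replace(
            self,
            scaffold=self.scaffold[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
            samples=list(self.samples),
        )


# ---------------------------------------------------------------------------
# counts / sample sheet


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.values < 0).any():
        raise ValueError(f"{path}: negative count entries")
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate feature or sample ids")
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return samples


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=parallex
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(variants: VariantTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for scaf in pd.unique(variants.scaffold):
            length = int(variants.pos[variants.scaffold == scaf].max())
            fh.write(f"##contig=<ID={scaf},length={length + 10_000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.samples)
            + "\n"
        )
        for i in range(variants.n_snps):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in variants.genotypes[i])
            fh.write(
                f"{variants.scaffold[i]}\t{variants.pos[i]}\t.\t{variants.ref[i]}\t"
                f"{variants.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> VariantTable:
    """Read biallelic SNPs from a VCF; multi-allelic records are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    scaf, pos, ref, alt, gts = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        scaf.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        gts.append(g)
    vcf.close()
    return VariantTable(
        scaffold=np.array(scaf, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.array(gts, dtype=np.int8)
        if gts
        else np.empty((0, len(samples)), dtype=np.int8),
        samples=samples,
    )


def read_population_file(path: str | Path) -> pd.DataFrame:
    pops = pd.read_csv(path, sep=None, engine="python")
    if not {"sample_id", "population"} <= set(pops.columns):
        raise ValueError(f"{path}: need columns sample_id, population")
    return pops


def write_population_file(pops: pd.DataFrame, path: str | Path) -> None:
    pops.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tparallex\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tparallex\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path),
            tmp.name,
            force=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
        genes = []
        for gene in db.features_of_type("gene"):
            exons = [
                (e.start, e.end) for e in db.children(gene, featuretype="exon")
            ]
            if not exons:
                exons = [(gene.start, gene.end)]
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    scaffold=gene.seqid,
                    exons=exons,
                    strand=gene.strand or "+",
                )
            )
    return genes


# ---------------------------------------------------------------------------
# pleiotropy table


def read_pleiotropy_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(PLEIOTROPY_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: pleiotropy table missing columns {sorted(missing)}")
    return table


def write_pleiotropy_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
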