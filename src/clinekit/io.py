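"""Dataset containers, readers/writers, and locus filters.

Genotypes are stored as counts of the ALT allele in {0, 1, 2}, with -1 as
the missing sentinel (never conflated with homozygous reference). Locus
metadata travels alongside the code matrix: contig id, locus class
(``control`` vs ``candidate``), and the two allele labels, so allele
polarity can be flipped downstream without re-reading files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

LOCUS_META_COLS = ["locus", "contig", "klass", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x loci ALT-allele counts with locus metadata."""

    codes: np.ndarray                  # int8, shape (n_ind, n_loci), -1 missing
    individuals: list[str]
    loci: pd.DataFrame                 # columns LOCUS_META_COLS

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        if self.codes.shape[0] != len(self.individuals):
            raise ValueError("row count != number of individuals")
        if self.codes.shape[1] != len(self.loci):
            raise ValueError("column count != number of loci")
        valid = np.isin(self.codes, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype codes must be in {0,1,2} or missing")
        missing_cols = [c for c in LOCUS_META_COLS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"locus metadata lacks columns {missing_cols}")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def locus_ids(self) -> np.ndarray:
        return self.loci["locus"].to_numpy()

    def subset_loci(self, mask_or_ids) -> "GenotypeMatrix":
        """Restrict to a boolean mask, integer index, or list of locus ids."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer):
            idx = np.flatnonzero(arr) if arr.dtype == bool else arr
        else:
            pos = pd.Index(self.loci["locus"])
            idx = pos.get_indexer(arr)
            if (idx < 0).any():
                missing = arr[idx < 0]
                raise KeyError(f"unknown locus ids: {list(missing[:5])}")
        return GenotypeMatrix(self.codes[:, idx], list(self.individuals),
                              self.loci.iloc[idx])

    def by_class(self, klass: str) -> "GenotypeMatrix":
        return self.subset_loci((self.loci["klass"] == klass).to_numpy())

    def minor_allele_frequencies(self) -> np.ndarray:
        """Overall MAF per locus, computed over non-missing alleles."""
        codes = self.codes
        obs = codes != MISSING
        alt = np.where(obs, codes, 0).sum(axis=0)
        n_alleles = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_alt = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return np.minimum(p_alt, 1.0 - p_alt)


def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop loci with minor-allele frequency below ``threshold`` (inclusive keep)."""
    if not (0.0 <= threshold <= 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    if threshold == 0.0:
        return g
    maf = g.minor_allele_frequencies()
    keep = np.nan_to_num(maf, nan=-1.0) >= threshold
    return g.subset_loci(keep)


# ---------------------------------------------------------------------------
# 0/1/2 matrix format (TSV) + locus metadata sidecar
# ---------------------------------------------------------------------------

def write_genotype_matrix(g: GenotypeMatrix, path: str | Path,
                          meta_path: str | Path | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(g.codes, index=pd.Index(g.individuals, name="individual"),
                      columns=g.loci["locus"])
    df.to_csv(path, sep="\t")
    if meta_path is None:
        meta_path = path.with_suffix(".loci.tsv")
    g.loci[LOCUS_META_COLS].to_csv(meta_path, sep="\t", index=False)


def read_genotype_matrix(path: str | Path,
                         meta_path: str | Path | None = None) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if meta_path is None:
        meta_path = path.with_suffix(".loci.tsv")
    if Path(meta_path).exists():
        loci = pd.read_csv(meta_path, sep="\t", dtype={"contig": str})
    else:
        loci = pd.DataFrame({
            "locus": df.columns, "contig": df.columns,
            "klass": "candidate", "ref": "A", "alt": "G",
        })
    codes = df.to_numpy()
    codes = np.where(pd.isna(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(codes, [str(i) for i in df.index], loci)


# ---------------------------------------------------------------------------
# VCF (biallelic SNPs)
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, klass_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; multi-allelic records are skipped.

    ALT-allele copies are counted; ``./.`` becomes the missing code. The
    locus class defaults to ``candidate`` unless ``klass_map`` (locus id ->
    class) says otherwise.
    """
    from cyvcf2 import VCF  # local import: optional dependency

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    cols, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            log.warning("skipping multi-allelic locus %s", rec.ID or rec.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        locus = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        klass = (klass_map or {}).get(locus, "candidate")
        cols.append(col.astype(np.int8))
        meta.append((locus, rec.CHROM, klass, rec.REF, rec.ALT[0]))
    codes = (np.column_stack(cols) if cols
             else np.empty((len(individuals), 0), dtype=np.int8))
    loci = pd.DataFrame(meta, columns=LOCUS_META_COLS)
    return GenotypeMatrix(codes, individuals, loci)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with one record per locus (contig as CHROM)."""
    gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Locus class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in pd.unique(g.loci["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individuals) + "\n")
        pos_within = {}
        for j, row in g.loci.iterrows():
            pos_within[row["contig"]] = pos_within.get(row["contig"], 0) + 1
            gts = "\t".join(gt_strings[int(c)] for c in g.codes[:, j])
            fh.write(f"{row['contig']}\t{pos_within[row['contig']]}\t{row['locus']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\tPASS\t"
                     f"CLASS={row['klass']}\tGT\t{gts}\n")


def read_genotypes(path: str | Path, format: str = "matrix", **kw) -> GenotypeMatrix:
    """Dispatch to :func:`read_vcf` or :func:`read_genotype_matrix`."""
    if format == "vcf":
        return read_vcf(path, **kw)
    if format == "matrix":
        return read_genotype_matrix(path, **kw)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_population_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    required = {"population", "latitude", "longitude", "elevation", "n"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"population panel lacks columns {sorted(missing)}")
    if panel["population"].duplicated().any():
        raise ValueError("duplicate population ids in panel")
    if (panel["n"] < 1).any():
        raise ValueError("population sample sizes must be >= 1")
    return panel


def read_climate_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path)
    required = {"individual", "population", "block", "location"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    return pheno


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(genotypes: GenotypeMatrix, panel: pd.DataFrame,
                     climate: pd.DataFrame, phenotypes: pd.DataFrame,
                     pop_of_individual: dict[str, str] | None = None) -> ValidationReport:
    """Cross-check ids across tables; fatal on genotype/phenotype mismatch."""
    from .config import CLIMATE_VARS

    rep = ValidationReport()
    pops = set(panel["population"].astype(str))
    geno_ids = set(genotypes.individuals)
    pheno_ids = set(phenotypes["individual"].astype(str))

    orphans = pheno_ids - geno_ids
    if orphans:
        rep.errors.append(
            f"{len(orphans)} phenotyped individuals absent from genotypes "
            f"(e.g. {sorted(orphans)[:3]})")
    bad_pops = set(phenotypes["population"].astype(str)) - pops
    if bad_pops:
        rep.errors.append(f"phenotype rows reference unknown populations: "
                          f"{sorted(bad_pops)[:5]}")
    if pop_of_individual is not None:
        unassigned = geno_ids - set(pop_of_individual)
        if unassigned:
            rep.errors.append(f"{len(unassigned)} genotyped individuals lack a "
                              "population assignment")
    clim_pops = set(climate["population"].astype(str)) if "population" in climate else set()
    lost = pops - clim_pops
    if lost:
        rep.warnings.append(f"{len(lost)} populations have no climate row")
    absent_vars = [v for v in CLIMATE_VARS if v not in climate.columns]
    if absent_vars:
        rep.warnings.append(f"climate table missing variables: {absent_vars}")

    codes = genotypes.codes
    rep.summary = {
        "n_individuals": genotypes.n_individuals,
        "n_loci": genotypes.n_loci,
        "missing_rate": float((codes == MISSING).mean()) if codes.size else 0.0,
        "class_counts": genotypes.loci["klass"].value_counts().to_dict(),
        "n_populations": len(pops),
    }
    return rep
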