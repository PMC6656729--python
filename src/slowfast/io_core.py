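"""Readers, writers and core containers for genotype, ancestry, trait and climate data.

Accessions are treated as fully selfing, homozygous lines: a diploid
homozygous call collapses to a haploid 0/1 alternate-allele dosage.
Heterozygous calls — unexpected in such a panel — become missing and are
counted, never silently imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ADMIXED_LABEL = "Admixed"

SNP_META_COLUMNS = ["chrom", "pos", "id", "intergenic"]


class GenotypeParseError(ValueError):
    """Raised for malformed or unsupported genotype records."""


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs haploid-equivalent dosage matrix.

    Attributes
    ----------
    samples : list of str
        Ordered accession identifiers (no duplicates).
    snps : pandas.DataFrame
        One row per SNP with columns ``chrom`` (str), ``pos`` (1-based int),
        ``id`` (str) and ``intergenic`` (bool). Positions are strictly
        increasing within each chromosome.
    dosage : numpy.ndarray, shape (n_samples, n_snps)
        Float array of alternate-allele indicators in {0, 1, NaN}.
    n_het_converted : int
        Number of heterozygous input calls converted to missing.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray
    n_het_converted: int = 0

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample identifiers")
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("dosage values must be 0, 1 or missing")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``keep`` (in the given order)."""
        idx = {s: i for i, s in enumerate(self.samples)}
        rows = [idx[s] for s in keep]
        return GenotypeMatrix(
            samples=list(keep),
            snps=self.snps.reset_index(drop=True),
            dosage=self.dosage[rows],
            n_het_converted=self.n_het_converted,
        )


@dataclass
class QMatrix:
    """Per-accession ancestry fractions over k clusters."""

    samples: list[str]
    q: np.ndarray  # (n_samples, k)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.samples):
            raise ValueError("q must be (n_samples, k)")
        if np.any(self.q < -1e-9) or np.any(self.q > 1 + 1e-9):
            raise ValueError("ancestry fractions must lie in [0, 1]")
        sums = self.q.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"ancestry rows must sum to 1 (first offender: sample "
                f"{self.samples[bad[0]]}, sum={sums[bad[0]]:.6g})"
            )

    @property
    def k(self) -> int:
        return self.q.shape[1]


def read_genotype_matrix(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a TSV dosage matrix.

    VCF records must be bi-allelic SNPs with diploid genotypes; homozygous
    calls collapse to haploid 0/1, heterozygous or missing calls become NaN.
    The TSV dialect is one row per sample, one column per SNP id, with a
    sidecar ``<stem>.snps.tsv`` holding chrom, pos, id, intergenic.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    intergenic: list[bool] = []
    columns: list[np.ndarray] = []
    n_het = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"multi-allelic site {var.ID or f'{var.CHROM}:{var.POS}'} not supported"
            )
        # gt_types: 0=hom-ref, 1=het, 2=missing, 3=hom-alt
        gt = np.asarray(var.gt_types)
        col = np.full(gt.shape, np.nan)
        col[gt == 0] = 0.0
        col[gt == 3] = 1.0
        n_het += int((gt == 1).sum())
        columns.append(col)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        intergenic.append(bool(var.INFO.get("INTERGENIC", False)))
    vcf.close()
    if not columns:
        raise GenotypeParseError(f"no variant records in {path}")
    snps = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "id": ids, "intergenic": intergenic}
    )
    if n_het:
        logger.warning("converted %d heterozygous calls to missing", n_het)
    return GenotypeMatrix(
        samples=samples,
        snps=snps,
        dosage=np.column_stack(columns),
        n_het_converted=n_het,
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".snps.tsv")


def _read_tsv(path: Path) -> GenotypeMatrix:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise GenotypeParseError(f"missing SNP metadata sidecar {sidecar}")
    snps = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str, "id": str})
    missing_cols = set(SNP_META_COLUMNS) - set(snps.columns)
    if missing_cols:
        raise GenotypeParseError(f"sidecar lacks columns {sorted(missing_cols)}")
    snps = snps[SNP_META_COLUMNS].copy()
    snps["intergenic"] = snps["intergenic"].astype(int).astype(bool)
    if list(mat.columns) != list(snps["id"]):
        raise GenotypeParseError("TSV columns do not match sidecar SNP ids")
    return GenotypeMatrix(
        samples=[str(s) for s in mat.index],
        snps=snps,
        dosage=mat.to_numpy(dtype=float),
    )


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dosage dialect plus its ``<stem>.snps.tsv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(g.dosage, index=g.samples, columns=g.snps["id"])
    df.to_csv(path, sep="\t", index_label="sample")
    meta = g.snps.copy()
    meta["intergenic"] = meta["intergenic"].astype(int)
    meta.to_csv(_sidecar_path(path), sep="\t", index=False)


def read_qmatrix(path: str | Path) -> QMatrix:
    """Read an ancestry-fraction table (TSV: sample column then k clusters)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return QMatrix(samples=[str(s) for s in df.index], q=df.to_numpy(dtype=float))


def write_qmatrix(q: QMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        q.q, index=q.samples, columns=[f"cluster_{i + 1}" for i in range(q.k)]
    )
    df.to_csv(path, sep="\t", index_label="sample")


def assign_populations(q: QMatrix, threshold: float = 0.5) -> pd.Series:
    """Assign each accession to its majority ancestry cluster.

    An accession is labelled ``group_<j>`` if cluster j carries strictly more
    than ``threshold`` of its genome, else it is labelled Admixed and is
    excluded from downstream differentiation statistics.
    """
    argmax = np.argmax(q.q, axis=1)
    frac = q.q[np.arange(len(q.samples)), argmax]
    labels = np.where(
        frac > threshold,
        np.array([f"group_{j + 1}" for j in argmax]),
        ADMIXED_LABEL,
    )
    return pd.Series(labels, index=pd.Index(q.samples, name="sample"), name="population")


def non_admixed(labels: pd.Series) -> pd.Series:
    """Subset of a population assignment without the Admixed accessions."""
    return labels[labels != ADMIXED_LABEL]


TRAIT_COLUMNS = ["genotype_id", "replicate_id", "site_id", "trait", "value"]

#: traits kept on their natural scale (rates that may be ~0); all other
#: traits must be strictly positive so they admit a log10 transform.
LOG_EXEMPT_TRAITS = frozenset({"RGR"})


def validate_trait_table(t: pd.DataFrame) -> pd.DataFrame:
    """Validate the long-format trait table contract and return it."""
    missing = set(TRAIT_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"trait table lacks columns {sorted(missing)}")
    vals = t["value"].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("trait values must be finite")
    positive_required = ~t["trait"].isin(LOG_EXEMPT_TRAITS)
    if (vals[positive_required.to_numpy()] <= 0).any():
        bad = t.loc[positive_required & (t["value"] <= 0), "trait"].unique()
        raise ValueError(f"non-positive values for log-transformable traits {list(bad)}")
    return t


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return validate_trait_table(pd.read_csv(path, dtype={"genotype_id": str}))


def genotype_means(t: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows to one arithmetic-mean row per (genotype, trait).

    Returns a long table with ``replicate_id`` fixed to ``"mean"``; the raw
    measurement scale is preserved (any log transform happens downstream).
    """
    validate_trait_table(t)
    grouped = (
        t.groupby(["genotype_id", "trait"], sort=False)
        .agg(value=("value", "mean"), site_id=("site_id", "first"))
        .reset_index()
    )
    grouped["replicate_id"] = "mean"
    return grouped[TRAIT_COLUMNS]


def trait_means_wide(t: pd.DataFrame) -> pd.DataFrame:
    """Genotype-mean trait matrix: one row per genotype, one column per trait."""
    gm = genotype_means(t)
    return gm.pivot(index="genotype_id", columns="trait", values="value")


def read_climate_table(path: str | Path) -> pd.DataFrame:
    """Read a per-site climate table (CSV, first column = site id)."""
    df = pd.read_csv(path, index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("climate table contains non-finite values")
    return df
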