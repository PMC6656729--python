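"""Population-genetic differentiation for haploid (fully selfing) panels.

Implements the Weir & Cockerham (1984) moment estimator of F_ST specialized
to haploid allele indicators, a PLINK-style sliding-window LD pruner, a
label-permutation significance test, the intergenic "neutral F_ST" benchmark
(median of the significant intergenic per-SNP values), and the realized
relationship (kinship) matrix from standardized SNP dosages.

Because the accessions are homozygous at essentially all loci, each genome is
treated as a single haploid allele draw; the WC84 variance components then
reduce to a one-way ANOVA of the 0/1 allele indicators:

    MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)           (among populations)
    MSG = sum_i n_i p_i (1 - p_i) / (N - r)             (within populations)
    a   = (MSP - MSG) / n_c,   b = MSG,   theta = a / (a + b)

with n_c = (N - sum n_i^2 / N) / (r - 1). theta may be negative for
undifferentiated SNPs and is deliberately not clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io_core import ADMIXED_LABEL, GenotypeMatrix

logger = logging.getLogger(__name__)


def _encode_labels(
    g: GenotypeMatrix, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align labels to g.samples, drop Admixed, return (rows, codes, pop names)."""
    lab = labels.reindex(g.samples)
    keep = lab.notna() & (lab != ADMIXED_LABEL)
    rows = np.where(keep.to_numpy())[0]
    kept = lab.iloc[rows]
    pops = sorted(kept.unique())
    code_map = {p: i for i, p in enumerate(pops)}
    codes = kept.map(code_map).to_numpy(dtype=np.int64)
    return rows, codes, pops


def _wc_components(
    dosage: np.ndarray, codes: np.ndarray, n_pops: int, min_calls: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP WC84 haploid variance components (a, b); NaN where undefined.

    Populations contribute at a SNP only if they have >= min_calls non-missing
    calls there; a SNP needs >= 2 contributing populations and a polymorphic
    pooled sample, otherwise both components are NaN.
    """
    dosage = np.asarray(dosage, dtype=float)
    onehot = np.zeros((dosage.shape[0], n_pops))
    onehot[np.arange(dosage.shape[0]), codes] = 1.0
    called = ~np.isnan(dosage)
    x = np.where(called, dosage, 0.0)
    n = onehot.T @ called  # (k, m) non-missing calls per pop
    alt = onehot.T @ x  # (k, m) alternate-allele counts per pop

    usable = n >= min_calls
    n = np.where(usable, n, 0.0)
    alt = np.where(usable, alt, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1.0), 0.0)

    r = usable.sum(axis=0).astype(float)  # populations per SNP
    N = n.sum(axis=0)
    defined = (r >= 2) & (N - r > 0)
    # guard against division by zero on undefined SNPs
    r_safe = np.where(defined, r, 2.0)
    N_safe = np.where(defined, N, 4.0)

    p_bar = np.where(N > 0, (n * p).sum(axis=0) / np.maximum(N, 1.0), np.nan)
    msp = (n * (p - p_bar) ** 2).sum(axis=0) / (r_safe - 1.0)
    msg = (n * p * (1.0 - p)).sum(axis=0) / (N_safe - r_safe)
    n_c = (N_safe - (n**2).sum(axis=0) / N_safe) / (r_safe - 1.0)

    a = (msp - msg) / n_c
    b = msg
    # monomorphic pooled sample: a + b == 0 -> undefined, flagged not 0
    defined &= (a + b) != 0.0
    a = np.where(defined, a, np.nan)
    b = np.where(defined, b, np.nan)
    return a, b


def snp_fst(g: GenotypeMatrix, labels: pd.Series) -> pd.Series:
    """Per-SNP Weir-Cockerham theta-hat; NaN where the estimator is undefined."""
    rows, codes, pops = _encode_labels(g, labels)
    if len(pops) < 2:
        raise ValueError("need >= 2 non-admixed populations")
    a, b = _wc_components(g.dosage[rows], codes, len(pops))
    with np.errstate(invalid="ignore"):
        theta = a / (a + b)
    return pd.Series(theta, index=g.snps["id"].to_numpy(), name="theta")


def multilocus_fst(
    g: GenotypeMatrix, labels: pd.Series, snp_subset: np.ndarray | None = None
) -> dict:
    """Multilocus theta-hat: ratio of sums (primary) and mean of per-SNP values.

    Also returns a pairwise population matrix of ratio-of-sums estimates.
    ``snp_subset`` (boolean mask or integer index over SNPs) restricts the
    computation, e.g. to an LD-pruned set.
    """
    rows, codes, pops = _encode_labels(g, labels)
    if len(pops) < 2:
        raise ValueError("need >= 2 non-admixed populations")
    dosage = g.dosage[rows]
    if snp_subset is not None:
        dosage = dosage[:, snp_subset]

    def _combine(dos: np.ndarray, cod: np.ndarray, k: int) -> tuple[float, float]:
        a, b = _wc_components(dos, cod, k)
        ok = ~np.isnan(a)
        if not ok.any():
            raise ValueError("no SNP with a defined theta-hat")
        ratio = float(a[ok].sum() / (a[ok] + b[ok]).sum())
        with np.errstate(invalid="ignore"):
            mean = float(np.nanmean(a / (a + b)))
        return ratio, mean

    ratio, mean = _combine(dosage, codes, len(pops))
    pairwise = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for p1, p2 in combinations(range(len(pops)), 2):
        sel = np.isin(codes, (p1, p2))
        sub_codes = (codes[sel] == p2).astype(np.int64)
        try:
            pr, _ = _combine(dosage[sel], sub_codes, 2)
        except ValueError:
            pr = np.nan
        pairwise.loc[pops[p1], pops[p2]] = pairwise.loc[pops[p2], pops[p1]] = pr
    return {
        "theta_ratio_of_sums": ratio,
        "theta_mean_per_snp": mean,
        "pairwise": pairwise,
    }


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.1,
    window_kb: float = 50.0,
    step_snps: int = 50,
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns indices of retained SNPs.

    A SNP is dropped when any earlier retained SNP on the same chromosome
    within window_kb has squared Pearson correlation of dosages >= r2_max
    (pairwise complete-case over non-missing calls). Every within-window pair
    of retained SNPs is therefore guaranteed below the threshold — a slightly
    stricter sweep than the classic step-advanced window, which can let
    boundary-straddling pairs survive. step_snps is accepted for interface
    familiarity and only sets the internal scan chunk size; it does not
    change the result. Zero-variance SNPs correlate with nothing and are
    kept. Deterministic for a fixed input order.
    """
    m = g.n_snps
    kept = np.ones(m, dtype=bool)
    chrom = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    span = window_kb * 1000.0

    d = g.dosage
    mask = ~np.isnan(d)
    filled = np.where(mask, d, 0.0)
    window_start = 0
    for j in range(1, m):
        while chrom[window_start] != chrom[j] or pos[j] - pos[window_start] > span:
            window_start += 1
        prev = np.where(kept[window_start:j])[0] + window_start
        if prev.size == 0:
            continue
        mj = mask[:, j].astype(float)
        xj = filled[:, j]
        mp = mask[:, prev].astype(float)
        xp = filled[:, prev]
        npair = mj @ mp
        sx = xj @ mp  # sum of x_j over shared calls
        sy = mj @ xp  # sum of x_prev over shared calls
        sxx = (xj**2) @ mp
        syy = mj @ (xp**2)
        sxy = xj @ xp
        with np.errstate(invalid="ignore", divide="ignore"):
            n_ok = np.maximum(npair, 1.0)
            cov = sxy - sx * sy / n_ok
            var_x = sxx - sx**2 / n_ok
            var_y = syy - sy**2 / n_ok
            r2 = cov**2 / (var_x * var_y)
        r2 = np.where(np.isfinite(r2), r2, 0.0)  # zero-variance -> uncorrelated
        if np.any(r2 >= r2_max):
            kept[j] = False
    return np.where(kept)[0]


def fst_permutation_null(
    g: GenotypeMatrix,
    labels: pd.Series,
    n_perm: int = 1000,
    q: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Permutation null for per-SNP theta-hat.

    Population labels are shuffled jointly across all SNPs once per iteration
    (preserving between-SNP dependence and per-population sample sizes); a SNP
    is significant when its observed theta-hat exceeds the q-quantile of its
    own permutation distribution.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; the %g-quantile will be unstable", n_perm, q)
    rng = np.random.default_rng(seed)
    rows, codes, pops = _encode_labels(g, labels)
    dosage = g.dosage[rows]
    k = len(pops)
    a, b = _wc_components(dosage, codes, k)
    with np.errstate(invalid="ignore"):
        observed = a / (a + b)

    null = np.empty((n_perm, g.n_snps))
    for it in range(n_perm):
        perm = rng.permutation(codes)
        pa, pb = _wc_components(dosage, perm, k)
        with np.errstate(invalid="ignore"):
            null[it] = pa / (pa + pb)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # SNPs undefined under every permutation (e.g. monomorphic) stay NaN
        warnings.filterwarnings("ignore", message="All-NaN slice")
        null_q = np.nanquantile(null, q, axis=0)
    significant = ~np.isnan(observed) & ~np.isnan(null_q) & (observed > null_q)
    return pd.DataFrame(
        {
            "id": g.snps["id"].to_numpy(),
            "theta": observed,
            "null_q": null_q,
            "significant": significant,
        }
    ).set_index("id")


def neutral_fst(per_snp: pd.DataFrame, snps: pd.DataFrame) -> float:
    """Median theta-hat over the significant intergenic SNPs.

    ``per_snp`` is the output of :func:`fst_permutation_null`; ``snps`` is the
    SNP metadata carrying the ``intergenic`` flag.
    """
    meta = snps.set_index("id")
    joined = per_snp.join(meta["intergenic"])
    sel = joined["significant"] & joined["intergenic"].astype(bool)
    if not sel.any():
        raise ValueError(
            "no significant intergenic SNP: check the intergenic flags in the "
            "SNP metadata and the permutation settings"
        )
    return float(joined.loc[sel, "theta"].median())


@dataclass
class FstResult:
    """Bundled F_ST analysis: per-SNP table, multilocus estimates, benchmark."""

    per_snp: pd.DataFrame
    multilocus: dict
    neutral_fst: float


def fst_analysis(
    g: GenotypeMatrix,
    labels: pd.Series,
    n_perm: int = 1000,
    q: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> FstResult:
    """Full differentiation analysis on one genotype panel."""
    per_snp = fst_permutation_null(g, labels, n_perm=n_perm, q=q, seed=seed)
    return FstResult(
        per_snp=per_snp,
        multilocus=multilocus_fst(g, labels),
        neutral_fst=neutral_fst(per_snp, g.snps),
    )


def kinship_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Realized relationship matrix from standardized SNP dosages.

    Each polymorphic SNP column is standardized to mean 0 and unit variance
    over its non-missing calls (missing entries contribute 0, i.e. the mean);
    K_ij is the cross-product divided by the number of SNPs called in both
    samples. Under this standardization the diagonal averages ~1.
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = g.dosage
    mask = ~np.isnan(d)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(d, axis=0)
        sd = np.nanstd(d, axis=0)
    poly = mask.any(axis=0) & (sd > 0)
    if not poly.any():
        raise ValueError("no polymorphic SNP")
    z = np.where(mask[:, poly], (d[:, poly] - mean[poly]) / sd[poly], 0.0)
    m_pair = mask[:, poly].astype(float) @ mask[:, poly].T.astype(float)
    if np.any(m_pair == 0):
        raise ValueError("a sample pair shares no called SNP")
    k = (z @ z.T) / m_pair
    return pd.DataFrame(k, index=g.samples, columns=g.samples)
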