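"""Synthetic data with the statistical structure the analysis assumes.

Genotypes follow the Balding-Nichols island model: each SNP has an ancestral
frequency p ~ Uniform(ancestral_freq_range) and per-population frequencies
Beta(p (1-F)/F, (1-p)(1-F)/F), so that the expected differentiation equals
the target F. Accessions are fully homozygous, hence sampled as haploid
Bernoulli draws. Admixed accessions are equal two-population mixtures (each
SNP drawn from one of two parent populations), so no ancestry fraction
exceeds 0.5 and the strict >50% assignment rule labels them Admixed.

Phenotypes decompose genotype values into population effects (variance
sigma2_B, of which a fraction c_true is genetic) and within-population
deviations (variance sigma2_W, of which h2_true is genetic); replicate noise
is scaled so that a replicate ANOVA across genotypes recovers h2_true.
Growth series are noisy logistic curves; climate tables couple one causal
variable linearly to a supplied slow-fast score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenotypeMatrix, QMatrix, TRAIT_COLUMNS

#: bioclim-style variable names; the first two are the headline pair.
CLIMATE_VARS = ["MAT", "MAR"] + [f"bio{i}" for i in range(3, 20)]


@dataclass
class SimGenoParams:
    """Study-scale defaults: 5 lineages, ~20% admixed, target F_ST 0.1."""

    n_pops: int = 5
    pop_sizes: tuple[int, ...] = (60, 60, 60, 60, 60)
    n_snps: int = 5000
    fst_target: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    frac_intergenic: float = 0.5
    frac_admixed: float = 0.2
    n_chroms: int = 5
    ld_block_size: int = 1  # >1 duplicates adjacent SNPs (with flips) to create LD
    ld_flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if any(s < 2 for s in self.pop_sizes):
            raise ValueError("each population needs >= 2 accessions")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0.0 <= self.frac_admixed < 1.0:
            raise ValueError("frac_admixed must be in [0, 1)")


def simulate_genotypes(p: SimGenoParams) -> tuple[GenotypeMatrix, QMatrix]:
    """Balding-Nichols genotypes plus the matching ancestry-fraction matrix.

    The number of admixed accessions is frac_admixed of the final panel:
    n_admixed = round(frac_admixed * sum(pop_sizes) / (1 - frac_admixed)).
    """
    rng = np.random.default_rng(p.seed)
    n_core = int(sum(p.pop_sizes))
    n_adm = int(round(p.frac_admixed * n_core / (1.0 - p.frac_admixed)))

    n_base = p.n_snps if p.ld_block_size <= 1 else -(-p.n_snps // p.ld_block_size)
    lo, hi = p.ancestral_freq_range
    anc = rng.uniform(lo, hi, size=n_base)
    F = p.fst_target
    if F <= 1e-12:
        pop_freq = np.tile(anc, (p.n_pops, 1))
    else:
        a = anc * (1.0 - F) / F
        b = (1.0 - anc) * (1.0 - F) / F
        pop_freq = rng.beta(a, b, size=(p.n_pops, n_base))

    if p.ld_block_size > 1:
        # block-duplication LD: each base SNP copied with a small flip rate
        reps = np.full(n_base, p.ld_block_size)
        pop_freq = np.repeat(pop_freq, reps, axis=1)[:, : p.n_snps]
        base_of = np.repeat(np.arange(n_base), reps)[: p.n_snps]
    else:
        base_of = np.arange(p.n_snps)
    n_snps = pop_freq.shape[1]

    codes = np.repeat(np.arange(p.n_pops), p.pop_sizes)
    core = (rng.random((n_core, n_snps)) < pop_freq[codes]).astype(float)
    if p.ld_block_size > 1:
        first = np.searchsorted(base_of, base_of)  # index of each block's first copy
        core_dup = core[:, first]
        flips = rng.random(core.shape) < p.ld_flip_prob
        copy = np.where(flips, 1.0 - core_dup, core_dup)
        is_copy = np.arange(n_snps) != first
        core = np.where(is_copy, copy, core)

    q_core = np.zeros((n_core, p.n_pops))
    q_core[np.arange(n_core), codes] = 1.0

    # admixed accessions: equal mixtures of two distinct populations, so the
    # maximum ancestry fraction is exactly 0.5 (never assignable)
    adm_rows = []
    q_adm = np.zeros((n_adm, p.n_pops))
    for i in range(n_adm):
        p1, p2 = rng.choice(p.n_pops, size=2, replace=False)
        src = np.where(rng.random(n_snps) < 0.5, p1, p2)
        freqs = pop_freq[src, np.arange(n_snps)]
        adm_rows.append((rng.random(n_snps) < freqs).astype(float))
        q_adm[i, [p1, p2]] = 0.5
    dosage = np.vstack([core] + ([np.vstack(adm_rows)] if n_adm else []))

    samples = [f"acc_{i + 1:04d}" for i in range(n_core + n_adm)]
    per_chrom = -(-n_snps // p.n_chroms)
    chroms, positions = [], []
    for c in range(p.n_chroms):
        m = min(per_chrom, n_snps - c * per_chrom)
        if m <= 0:
            break
        chroms += [f"chr{c + 1}"] * m
        positions += list(np.cumsum(rng.integers(200, 2000, size=m)))
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"snp_{j + 1:06d}" for j in range(n_snps)],
            "intergenic": rng.random(n_snps) < p.frac_intergenic,
        }
    )
    g = GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)
    q = QMatrix(samples=samples, q=np.vstack([q_core, q_adm]))
    return g, q


@dataclass
class SimPhenoParams:
    """Variance structure of the P_ST model; defaults give a plug-in ratio 0.3."""

    sigma2_B: float = 3.0
    sigma2_W: float = 7.0
    c_true: float = 1.0
    h2_true: float = 1.0
    n_reps: int = 4
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_B < 0 or self.sigma2_W < 0:
            raise ValueError("variances must be >= 0")
        if not 0 < self.h2_true <= 1:
            raise ValueError("h2_true must be in (0, 1]")
        if not 0 <= self.c_true <= 1:
            raise ValueError("c_true must be in [0, 1]")
        if self.h2_true < 1 and self.n_reps < 2:
            raise ValueError("heritability < 1 needs >= 2 replicates to be estimable")


def simulate_phenotypes(p: SimPhenoParams, labels: pd.Series) -> pd.DataFrame:
    """Replicate-level trait table with the requested variance decomposition.

    Genotype value = population effect (variance sigma2_B, split c_true
    genetic / 1-c_true environmental) + within-population deviation (variance
    sigma2_W, split h2_true genetic / 1-h2_true environmental). Replicates
    add noise scaled from the realized genotype-value variance so a replicate
    ANOVA across genotypes targets h2_true. Values are offset to stay
    positive (log10-transformable); the offset is variance-neutral.
    """
    from .io_core import ADMIXED_LABEL

    rng = np.random.default_rng(p.seed)
    lab = labels[labels != ADMIXED_LABEL]
    pops = sorted(lab.unique())
    if len(pops) < 2:
        raise ValueError("need >= 2 non-admixed populations")
    codes = lab.map({name: i for i, name in enumerate(pops)}).to_numpy()
    n = len(lab)

    b = rng.normal(0, np.sqrt(p.c_true * p.sigma2_B), len(pops)) + rng.normal(
        0, np.sqrt((1 - p.c_true) * p.sigma2_B), len(pops)
    )
    d = rng.normal(0, np.sqrt(p.h2_true * p.sigma2_W), n) + rng.normal(
        0, np.sqrt((1 - p.h2_true) * p.sigma2_W), n
    )
    value = b[codes] + d

    if p.h2_true < 1:
        v_g = float(np.var(value, ddof=1))
        sigma_e = np.sqrt(v_g * (1 - p.h2_true) / p.h2_true)
    else:
        sigma_e = 0.0
    reps = value[:, None] + rng.normal(0, sigma_e, (n, p.n_reps))
    offset = 10.0 * max(
        1.0, np.sqrt(p.sigma2_B + p.sigma2_W + sigma_e**2)
    ) - min(0.0, reps.min())

    rows = pd.DataFrame(
        {
            "genotype_id": np.repeat(lab.index.to_numpy(), p.n_reps),
            "replicate_id": np.tile([f"rep_{j + 1}" for j in range(p.n_reps)], n),
            "site_id": np.repeat(lab.index.to_numpy(), p.n_reps),
            "trait": p.trait,
            "value": (reps + offset).ravel(),
        }
    )
    return rows[TRAIT_COLUMNS]


@dataclass
class GrowthParams:
    """Logistic rosette growth; defaults mimic a 30-day greenhouse series."""

    K: float = 2000.0  # mm2
    r: float = 0.25  # 1/d
    t0: float = 15.0  # d
    noise_sd: float = 0.02  # fraction of K
    n_days: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r <= 0:
            raise ValueError("K and r must be positive")
        if not 0 < self.t0 < self.n_days:
            raise ValueError("t0 must lie inside the observation window")


def simulate_growth_series(p: GrowthParams, n_plants: int) -> pd.DataFrame:
    """Daily rosette areas, logistic + Gaussian noise, truncated at 0.

    Truncation keeps areas physical; at the default 2% noise it is a
    negligible, slightly non-Gaussian perturbation of the early tail.
    """
    rng = np.random.default_rng(p.seed)
    days = np.arange(1, p.n_days + 1, dtype=float)
    clean = p.K / (1.0 + np.exp(-p.r * (days - p.t0)))
    noise = rng.normal(0.0, p.noise_sd * p.K, size=(n_plants, p.n_days))
    areas = np.maximum(clean[None, :] + noise, 0.0)
    return pd.DataFrame(
        {
            "plant_id": np.repeat([f"plant_{i + 1:03d}" for i in range(n_plants)], p.n_days),
            "day": np.tile(days, n_plants),
            "area": areas.ravel(),
        }
    )


def coupling_for_target_r(
    target_r: float, score_sd: float, noise_sd: float
) -> float:
    """Slope giving a population Pearson correlation target_r for the causal
    climate variable: r = s*sd / sqrt(s^2 sd^2 + noise^2)."""
    if not -1 < target_r < 1:
        raise ValueError("target_r must be in (-1, 1)")
    return target_r * noise_sd / (score_sd * np.sqrt(1.0 - target_r**2))


def simulate_climate(
    scores: pd.Series,
    coupling: float,
    noise_sd: float = 1.0,
    n_vars: int = 19,
    causal_var: str = "MAR",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site climate table with one causal variable linearly coupled to the
    slow-fast score; the remaining variables are independent standard normals."""
    rng = np.random.default_rng(seed)
    names = CLIMATE_VARS[:n_vars]
    if causal_var not in names:
        names = [causal_var] + [v for v in names if v != causal_var][: n_vars - 1]
    s = scores.to_numpy(dtype=float)
    out = pd.DataFrame(
        rng.normal(size=(len(scores), n_vars)), index=scores.index, columns=names
    )
    out[causal_var] = coupling * s + rng.normal(0.0, noise_sd, len(scores))
    out.index.name = "site_id"
    return out
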