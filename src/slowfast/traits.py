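"""Growth-curve fitting, RGR extraction, trait axes (PCA) and scaling fits.

The rosette growth model is the 3-parameter logistic
A(t) = K / (1 + exp(-r (t - t0))). Its inflection sits at t0 where A = K/2
and dA/dt = r K / 4, so the relative growth rate at inflection is

    RGR = (dA/dt) / A |_{t0} = r / 2      [mm2 mm-2 d-1]

Trait syndromes (leaf-economics and slow-fast axes) are PC1 of a
correlation-matrix PCA of log10-transformed genotype means (RGR stays on its
natural scale), oriented so that the mass-per-area loading is positive: a
high score means a conservative/slow phenotype. Leaf-to-plant scaling uses
standardized major axis (SMA) regression, with an optional kinship-aware GLS
check of ordinary least-squares slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class GrowthCurveFit:
    K: float  # asymptotic area, mm2
    r: float  # logistic rate, 1/d
    t0: float  # inflection time, d
    rss: float
    converged: bool


def logistic(t: np.ndarray, K: float, r: float, t0: float) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (t - t0)))


def fit_logistic_growth(days: np.ndarray, areas: np.ndarray) -> GrowthCurveFit:
    """Least-squares logistic fit to a rosette-area time series.

    Initialization: K0 = max area, t0_0 = time of half-max crossing, r0 from
    the early-phase log-linear slope. A fit that fails to converge, or whose
    asymptote runs far beyond the data (no plateau observed), is flagged
    converged=False; parameters are still reported.
    """
    days = np.asarray(days, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if days.size < 5:
        raise ValueError("need >= 5 time points")
    k0 = float(areas.max())
    if k0 <= 0:
        raise ValueError("areas must contain positive values")
    above = days[areas >= 0.5 * k0]
    t00 = float(above[0]) if above.size else float(np.median(days))
    early = (areas > 0.01 * k0) & (areas < 0.8 * k0)
    if early.sum() >= 2:
        slope = np.polyfit(days[early], np.log(areas[early]), 1)[0]
        r0 = float(np.clip(slope, 1e-3, 5.0))
    else:
        r0 = 0.2
    try:
        popt, _ = optimize.curve_fit(
            logistic,
            days,
            areas,
            p0=(k0, r0, t00),
            bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
        ok = True
    except RuntimeError:
        popt, ok = (k0, r0, t00), False
    K, r, t0 = (float(v) for v in popt)
    rss = float(((areas - logistic(days, K, r, t0)) ** 2).sum())
    # a trustworthy sigmoid needs its plateau inside the observation window:
    # the fitted curve must reach 90% of the asymptote by the last time point
    if K > 10.0 * k0 or logistic(days.max(), K, r, t0) < 0.9 * K:
        ok = False
        logger.warning("logistic fit did not plateau within the series")
    return GrowthCurveFit(K=K, r=r, t0=t0, rss=rss, converged=ok)


def rgr_at_inflection(fit: GrowthCurveFit) -> float:
    """Relative growth rate at the inflection point: r/2 for the logistic."""
    if not fit.converged:
        raise ValueError("growth fit did not converge; RGR not reliable")
    return fit.r / 2.0


def fit_growth_table(series: pd.DataFrame) -> pd.DataFrame:
    """Fit every plant in a long (plant_id, day, area) table.

    Returns one row per plant: K, r, t0, RGR (NaN if unconverged), converged.
    """
    rows = []
    for plant, grp in series.groupby("plant_id", sort=False):
        fit = fit_logistic_growth(grp["day"].to_numpy(), grp["area"].to_numpy())
        rows.append(
            {
                "plant_id": plant,
                "K": fit.K,
                "r": fit.r,
                "t0": fit.t0,
                "RGR": fit.r / 2.0 if fit.converged else np.nan,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("plant_id")


@dataclass
class AxisScores:
    axis_name: str
    loadings: pd.Series
    scores: pd.Series
    var_explained: float


def pca_axis(
    means_wide: pd.DataFrame,
    traits: list[str],
    axis_name: str = "axis",
    log10_all_but: frozenset[str] | set[str] = frozenset({"RGR"}),
    orient_trait: str | None = None,
) -> AxisScores:
    """PC1 of a correlation-matrix PCA over transformed genotype means.

    All traits except those in ``log10_all_but`` are log10 transformed;
    genotypes with any missing trait are dropped (complete-case, logged).
    The axis is oriented so the loading of ``orient_trait`` (default: the
    first trait whose name contains 'LMA', else the first trait) is positive,
    i.e. high scores = conservative/slow syndrome.
    """
    if len(traits) < 2:
        raise ValueError("need >= 2 traits")
    x = means_wide[traits].dropna()
    dropped = len(means_wide) - len(x)
    if dropped:
        logger.info("PCA: dropped %d genotypes with incomplete traits", dropped)
    if len(x) < 3:
        raise ValueError("need >= 3 complete-case genotypes")
    vals = x.to_numpy(dtype=float).copy()
    for j, tr in enumerate(traits):
        if tr not in log10_all_but:
            if np.any(vals[:, j] <= 0):
                raise ValueError(f"trait {tr!r} has non-positive values; cannot log10")
            vals[:, j] = np.log10(vals[:, j])
    sd = vals.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = traits[int(np.where(sd == 0)[0][0])]
        raise ValueError(f"trait {bad!r} is constant")
    z = (vals - vals.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())

    if orient_trait is None:
        lma_like = [t for t in traits if "lma" in t.lower()]
        orient_trait = lma_like[0] if lma_like else traits[0]
    sign = np.sign(loadings[traits.index(orient_trait)]) or 1.0
    loadings = loadings * sign
    scores = z @ loadings
    return AxisScores(
        axis_name=axis_name,
        loadings=pd.Series(loadings, index=traits, name="loading"),
        scores=pd.Series(scores, index=x.index, name=f"{axis_name}_score"),
        var_explained=var_explained,
    )


@dataclass
class SmaFit:
    slope: float
    intercept: float
    r: float
    slope_ci: tuple[float, float]
    n: int

    @property
    def slope_differs_from_1(self) -> bool:
        lo, hi = self.slope_ci
        return not (lo <= 1.0 <= hi)


def sma_fit(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> SmaFit:
    """Standardized major axis regression of y on x.

    slope = sign(r) * s_y / s_x, intercept through the means. The slope CI is
    the standard correlation-based construction: with
    B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2), the interval is
    slope * (sqrt(B + 1) +/- sqrt(B)). Degenerate (|r| = 1) data give a
    point interval at the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    fcrit = stats.f.ppf(1 - alpha, 1, n - 2)
    b = fcrit * (1.0 - r**2) / (n - 2)
    lo = slope * (np.sqrt(b + 1.0) - np.sqrt(b))
    hi = slope * (np.sqrt(b + 1.0) + np.sqrt(b))
    if lo > hi:  # negative slopes: keep the interval ordered
        lo, hi = hi, lo
    return SmaFit(slope=float(slope), intercept=intercept, r=r,
                  slope_ci=(float(lo), float(hi)), n=n)


@dataclass
class GlsFit:
    slope: float
    se: float
    ols_slope: float
    ols_se: float

    @property
    def differs_from_ols(self) -> bool:
        """Slope shift beyond twice the combined standard errors."""
        return abs(self.slope - self.ols_slope) > 2.0 * float(
            np.hypot(self.se, self.ols_se)
        )


def gls_kinship_fit(
    y: np.ndarray, x: np.ndarray, K: np.ndarray, nugget: float = 1e-6
) -> GlsFit:
    """GLS slope of y ~ x with residual covariance proportional to the kinship.

    The covariance is K plus a scaled-identity nugget (ridge jitter raised, and
    logged, until K + delta*I is positive definite). Used as the relatedness-
    aware check that an OLS trait-trait slope is not driven by population
    structure: the fit "differs" when the GLS and OLS slopes are more than
    two combined standard errors apart.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    K = np.asarray(K, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("kinship matrix does not match the sample size")
    scale = float(np.mean(np.diag(K))) or 1.0
    delta = nugget * scale
    for _ in range(30):
        try:
            np.linalg.cholesky(K + delta * np.eye(n))
            break
        except np.linalg.LinAlgError:
            delta *= 10.0
    else:
        raise ValueError("kinship covariance singular even after jitter")
    if delta > nugget * scale:
        logger.info("kinship jitter raised to %.3g for positive definiteness", delta)

    X = sm.add_constant(x)
    gls = sm.GLS(y, X, sigma=K + delta * np.eye(n)).fit()
    ols = sm.OLS(y, X).fit()
    return GlsFit(
        slope=float(gls.params[1]),
        se=float(gls.bse[1]),
        ols_slope=float(ols.params[1]),
        ols_se=float(ols.bse[1]),
    )
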