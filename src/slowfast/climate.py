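"""Climate-trait association: correlation screen, bidirectional stepwise AIC
model selection, repeated cross-validated predictive r2, and gridded
prediction of axis scores.

The stepwise selector and the cross-validation loop are built on plain
least squares (numpy lstsq) because selection must be re-run inside every
training fold — the no-leakage contract — which makes fit speed matter.
AIC follows the Gaussian-likelihood convention
AIC = n log(2 pi RSS / n) + n + 2 (p + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def climate_correlations(scores: pd.Series, climate: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p of an axis score against every climate variable.

    Genotypes absent from either table are dropped (count logged). No
    multiplicity correction is applied; the number of variables significant
    at 0.05 is reported in the result's ``attrs["n_significant"]``.
    """
    joined = climate.join(scores.rename("_score"), how="inner").dropna()
    dropped = max(len(scores), len(climate)) - len(joined)
    if dropped > 0:
        logger.info("correlation screen: %d unmatched rows dropped", dropped)
    if len(joined) < 10:
        raise ValueError("need >= 10 matched genotype-site pairs")
    rows = []
    for var in climate.columns:
        r, p = stats.pearsonr(joined[var], joined["_score"])
        rows.append({"variable": var, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows).set_index("variable")
    out.attrs["n_significant"] = int((out["p"] < 0.05).sum())
    return out


def _aic(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Gaussian AIC and coefficients of an OLS fit with intercept column in X."""
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = y.size
    rss = float(resid @ resid)
    rss = max(rss, 1e-300)
    aic = n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (X.shape[1] + 1)
    return aic, coef


def _drop_collinear(X: pd.DataFrame, tol: float = 1e-8) -> list[str]:
    """Greedy left-to-right rank filter; returns the retained column names."""
    kept: list[str] = []
    basis = np.ones((len(X), 1))
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        proj, _, _, _ = np.linalg.lstsq(basis, v, rcond=None)
        resid = v - basis @ proj
        denom = float(v @ v) or 1.0
        if float(resid @ resid) / denom > tol:
            kept.append(col)
            basis = np.column_stack([basis, v])
        else:
            logger.warning("dropping collinear climate variable %r", col)
    return kept


@dataclass
class ClimateModel:
    response: str
    selected_vars: list[str]
    coefficients: pd.Series  # intercept under "const"
    aic: float
    cv_r2: float | None = None
    var_ranges: pd.DataFrame | None = field(default=None, repr=False)


def _stepwise_select(y: np.ndarray, X: np.ndarray, names: list[str]) -> list[int]:
    """Bidirectional stepwise AIC from the full model; ties break by column order."""
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    current = list(range(p))
    best_aic, _ = _aic(y, Xc[:, [0] + [j + 1 for j in current]])
    improved = True
    while improved:
        improved = False
        best_move: tuple[str, int] | None = None
        move_aic = best_aic
        for j in current:  # drops
            cols = [0] + [k + 1 for k in current if k != j]
            aic, _ = _aic(y, Xc[:, cols])
            if aic < move_aic - 1e-10:
                move_aic, best_move = aic, ("drop", j)
        for j in range(p):  # adds
            if j in current:
                continue
            cols = [0] + [k + 1 for k in sorted(current + [j])]
            aic, _ = _aic(y, Xc[:, cols])
            if aic < move_aic - 1e-10:
                move_aic, best_move = aic, ("add", j)
        if best_move is not None:
            kind, j = best_move
            current = [k for k in current if k != j] if kind == "drop" else sorted(current + [j])
            best_aic = move_aic
            improved = True
    # never return a model worse than the empty one
    empty_aic, _ = _aic(y, Xc[:, [0]])
    if empty_aic < best_aic:
        current, best_aic = [], empty_aic
    return current


def stepwise_aic(
    scores: pd.Series, climate: pd.DataFrame, response: str = "SFC"
) -> ClimateModel:
    """Bidirectional stepwise linear-model selection minimizing AIC.

    Starts from the full model over all (non-collinear) climate variables.
    Deterministic given the data: candidate moves are scanned in column
    order and ties keep the incumbent.
    """
    joined = climate.join(scores.rename("_y"), how="inner").dropna()
    names = _drop_collinear(joined[climate.columns])
    n = len(joined)
    if n <= 3 * len(names):
        raise ValueError(f"need n > 3x candidate variables ({n} vs {len(names)})")
    y = joined["_y"].to_numpy(dtype=float)
    X = joined[names].to_numpy(dtype=float)
    sel_idx = _stepwise_select(y, X, names)
    selected = [names[j] for j in sel_idx]
    Xs = np.column_stack([np.ones(n)] + [X[:, j] for j in sel_idx])
    aic, coef = _aic(y, Xs)
    coefficients = pd.Series(coef, index=["const"] + selected, name="coef")
    ranges = joined[selected].agg(["min", "max"]) if selected else pd.DataFrame()
    return ClimateModel(
        response=response,
        selected_vars=selected,
        coefficients=coefficients,
        aic=float(aic),
        var_ranges=ranges,
    )


def repeated_cv_r2(
    scores: pd.Series,
    climate: pd.DataFrame,
    k: int = 10,
    reps: int = 10,
    seed: int | np.random.Generator = 0,
    selector: str = "stepwise",
) -> dict:
    """Repeated k-fold cross-validated predictive accuracy.

    ``selector`` is "stepwise" (selection re-run inside every training fold —
    no information leaks from the held-out fold), "full" (all variables), or
    "empty". Per repetition the out-of-fold predictions are pooled; the
    headline metric is the squared Pearson correlation of pooled predictions
    with the observed scores, averaged over repetitions; 1 - SSE/SST is also
    reported.
    """
    joined = climate.join(scores.rename("_y"), how="inner").dropna()
    n = len(joined)
    if n < 2 * k:
        raise ValueError("need n >= 2k")
    rng = np.random.default_rng(seed)
    names = _drop_collinear(joined[climate.columns])
    y = joined["_y"].to_numpy(dtype=float)
    X = joined[names].to_numpy(dtype=float)

    r2_corr, r2_sse = [], []
    for _ in range(reps):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        pred = np.full(n, np.nan)
        for test_idx in folds:
            train = np.setdiff1d(order, test_idx)
            if np.std(y[train]) == 0:
                logger.warning("constant response in a training fold; repetition skipped")
                break
            if selector == "stepwise":
                sel = _stepwise_select(y[train], X[train], names)
            elif selector == "full":
                sel = list(range(len(names)))
            elif selector == "empty":
                sel = []
            else:
                raise ValueError(f"unknown selector {selector!r}")
            Xtr = np.column_stack([np.ones(train.size)] + [X[train, j] for j in sel])
            _, coef = _aic(y[train], Xtr)
            Xte = np.column_stack([np.ones(test_idx.size)] + [X[test_idx, j] for j in sel])
            pred[test_idx] = Xte @ coef
        if np.isnan(pred).any():
            continue
        if np.std(pred) == 0:
            r2_corr.append(0.0)
        else:
            r2_corr.append(float(np.corrcoef(pred, y)[0, 1] ** 2))
        sst = float(((y - y.mean()) ** 2).sum())
        r2_sse.append(1.0 - float(((y - pred) ** 2).sum()) / sst)
    if not r2_corr:
        raise ValueError("no usable cross-validation repetition")
    return {
        "cv_r2": float(np.mean(r2_corr)),
        "cv_r2_sse": float(np.mean(r2_sse)),
        "k": k,
        "reps": len(r2_corr),
    }


def predict_grid(model: ClimateModel, grid: pd.DataFrame) -> pd.DataFrame:
    """Apply the fitted linear predictor row-wise to a climate grid.

    Returns predicted scores plus an ``extrapolation`` flag for rows where a
    selected variable falls outside its training range.
    """
    missing = [v for v in model.selected_vars if v not in grid.columns]
    if missing:
        raise ValueError(f"grid lacks selected variables {missing}")
    pred = np.full(len(grid), model.coefficients["const"], dtype=float)
    for var in model.selected_vars:
        pred = pred + model.coefficients[var] * grid[var].to_numpy(dtype=float)
    extrap = np.zeros(len(grid), dtype=bool)
    if model.var_ranges is not None and len(model.var_ranges):
        for var in model.selected_vars:
            v = grid[var].to_numpy(dtype=float)
            extrap |= (v < model.var_ranges.loc["min", var]) | (
                v > model.var_ranges.loc["max", var]
            )
    return pd.DataFrame(
        {"predicted_score": pred, "extrapolation": extrap}, index=grid.index
    )
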