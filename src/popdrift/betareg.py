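"""Nested beta regressions of mean ancestry assignment on Ne and time.

The response is a mean assignment probability in (0,1): either a wild
population analog's assignment to its eventual distinct cluster, or its
assignment to the hatchery-analog cluster.  The mean model is a beta
regression with logit link and constant precision phi; candidate models are
the five nested combinations of generations (Gen), effective size (Ne) and
their interaction, ranked by small-sample AICc with Akaike weights and a
pseudo-R-squared (squared correlation between the linear predictor and the
logit-transformed response, zero for the null model by construction).
Maximum-likelihood fitting is delegated to statsmodels' BetaModel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

#: The five nested candidate models, in Table order (most to least complex).
NESTED_MODELS: dict[str, tuple[str, ...]] = {
    "gen_x_ne": ("gen", "ne", "gen:ne"),
    "gen_plus_ne": ("gen", "ne"),
    "gen_only": ("gen",),
    "ne_only": ("ne",),
    "null": (),
}

_COEF_NAMES = {"const": "beta0", "gen": "beta1", "ne": "beta2", "gen:ne": "beta3"}


@dataclass
class DriftRegressionFit:
    """One fitted beta regression with information-criterion bookkeeping."""

    model: str
    coefficients: dict[str, float]  # beta0..beta3 subset
    phi: float
    loglik: float
    df: int  # mean coefficients + 1 (phi)
    aicc: float
    pseudo_r2: float
    n: int
    delta_aicc: float = np.nan
    akaike_weight: float = np.nan
    converged: bool = True
    _result: object = None


def squeeze_unit_interval(y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Nudge boundary responses into (0,1) via (y*(n-1)+0.5)/n.

    Applied only when some y touches 0 or 1; returns (y, was_applied).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        n = len(y)
        return (y * (n - 1) + 0.5) / n, True
    return y, False


def _design(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for t in terms:
        if t == "gen:ne":
            X[t] = data["gen"] * data["ne"]
        else:
            X[t] = data[t]
    return X


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_beta(
    y: np.ndarray, design: pd.DataFrame, model_name: str = "custom"
) -> DriftRegressionFit:
    """Maximum-likelihood beta regression (logit mean link, constant phi).

    ``design`` must contain a ``const`` column.  Raises if y leaves (0,1)
    or the optimizer fails to converge.
    """
    y = np.asarray(y, dtype=float)
    bad = np.nonzero((y <= 0) | (y >= 1))[0]
    if bad.size:
        raise ValueError(f"response outside (0,1) at rows {bad.tolist()}")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    model = BetaModel(y, design)
    with np.errstate(all="ignore"):
        res = model.fit(disp=False, maxiter=2000, method="bfgs")
        if not res.mle_retvals.get("converged", True):
            res = model.fit(disp=False, maxiter=5000, method="nm",
                            start_params=res.params)
    params = np.asarray(res.params)
    k = len(params)  # mean coefficients + precision
    n = len(y)
    coef = {}
    for name, val in zip(design.columns, params[:-1]):
        coef[_COEF_NAMES.get(name, name)] = float(val)
    phi = float(np.exp(params[-1]))  # BetaModel uses a log link for precision
    eta = design.to_numpy() @ params[:-1]
    if design.shape[1] > 1 and np.std(eta) > 0:
        r = np.corrcoef(eta, np.log(y / (1 - y)))[0, 1]
        pr2 = float(r**2)
    else:
        pr2 = 0.0
    return DriftRegressionFit(
        model=model_name,
        coefficients=coef,
        phi=phi,
        loglik=float(res.llf),
        df=k,
        aicc=aicc(float(res.llf), k, n),
        pseudo_r2=pr2,
        n=n,
        converged=bool(res.mle_retvals.get("converged", True)),
        _result=res,
    )


def model_table(dataset: pd.DataFrame, response: str = "y") -> pd.DataFrame:
    """Fit the five nested models and rank them by AICc.

    ``dataset`` needs columns ``gen``, ``ne`` and the response (mean
    assignment in (0,1); boundary values are nudged inward and noted).
    Returns one row per model with beta0..beta3, phi, df, loglik, aicc,
    delta_aicc, akaike weight and pseudo-R2, sorted by AICc.
    """
    y, _ = squeeze_unit_interval(dataset[response].to_numpy())
    fits: list[DriftRegressionFit] = []
    for name, terms in NESTED_MODELS.items():
        X = _design(dataset, terms)
        try:
            fits.append(fit_beta(y, X, model_name=name))
        except (ValueError, np.linalg.LinAlgError) as e:
            fits.append(
                DriftRegressionFit(name, {}, np.nan, np.nan, len(terms) + 2,
                                   np.inf, np.nan, len(y), converged=False)
            )
    aiccs = np.array([f.aicc for f in fits])
    best = aiccs.min()
    deltas = aiccs - best
    rel = np.exp(-0.5 * deltas)
    weights = rel / rel.sum()
    rows = []
    for f, d, w in zip(fits, deltas, weights):
        f.delta_aicc = float(d)
        f.akaike_weight = float(w)
        row = {"model": f.model}
        for b in ("beta0", "beta1", "beta2", "beta3"):
            row[b] = f.coefficients.get(b, np.nan)
        row.update(
            phi=f.phi, df=f.df, loglik=f.loglik, aicc=f.aicc,
            delta_aicc=f.delta_aicc, weight=f.akaike_weight,
            pseudo_r2=f.pseudo_r2,
        )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    out.attrs["fits"] = {f.model: f for f in fits}
    return out


def predict_surface(
    fit: DriftRegressionFit, ne_grid: np.ndarray, gen_grid: np.ndarray
) -> pd.DataFrame:
    """Predicted mean assignment over an (Ne, generation) grid.

    Inverse-logit of the fitted linear predictor; long-format output with
    columns ne, gen, predicted.
    """
    rows = []
    c = fit.coefficients
    for ne in np.asarray(ne_grid, dtype=float):
        for gen in np.asarray(gen_grid, dtype=float):
            eta = (
                c.get("beta0", 0.0)
                + c.get("beta1", 0.0) * gen
                + c.get("beta2", 0.0) * ne
                + c.get("beta3", 0.0) * gen * ne
            )
            rows.append({"ne": ne, "gen": gen, "predicted": 1.0 / (1.0 + np.exp(-eta))})
    return pd.DataFrame(rows)
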