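"""Best-subsets multiple linear regression with small-sample criteria.

The selection pipeline used by every phase of the biomass workflow:

1. :func:`pearson_prefilter` — drop one member of every predictor pair with
   |r| above a threshold (default 0.85), keeping the member better
   correlated with the response,
2. :func:`best_subsets` — exhaustive enumeration of predictor subsets up to
   a maximum size; per size the best subset by R^2 is retained with its
   adjusted R^2, predicted R^2 (from PRESS), Mallows Cp, AICc, BIC and RMSE;
   the overall winner is the subset with the lowest AICc,
3. :func:`kfold_cv` — seeded k-fold cross-validation of the chosen model.

Criteria definitions (n observations, p predictors, k = p + 2 estimated
quantities including intercept and error variance):

    Cp   = SSE / MSE_full - n + 2 (p + 1)
    AICc = n ln(SSE / n) + 2k + 2k(k+1) / (n - k - 1)
    BIC  = n ln(SSE / n) + k ln(n)

AICc and BIC are defined up to additive constants; only rankings matter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_CANDIDATE_FEATURES = 25


@dataclass
class SubsetModel:
    """One fitted candidate linear model with its selection criteria."""

    predictors: tuple
    intercept: float
    coefficients: dict  # name -> coefficient
    n: int
    p: int
    sse: float
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    cp: float
    aicc: float
    bic: float
    rmse: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in X.columns]
        if missing:
            raise ValueError(f"feature table missing predictor columns {missing}")
        out = np.full(len(X), self.intercept)
        for name in self.predictors:
            out = out + self.coefficients[name] * X[name].to_numpy(float)
        return out


# ---------------------------------------------------------------------------
# collinearity prefilter
# ---------------------------------------------------------------------------


def pearson_prefilter(
    features: pd.DataFrame, response, threshold: float = 0.85
) -> list[str]:
    """Iteratively drop one member of each highly correlated predictor pair.

    Pairs are visited in descending |r|; the member with the lower absolute
    Pearson correlation with the response is dropped (ties keep the
    alphabetically first name).  Constant (zero-variance) features are
    dropped up front with a warning.  Deterministic.
    """
    y = np.asarray(response, dtype=float)
    names = [c for c in features.columns if c != "cell_id"]
    X = features[names].to_numpy(float)
    sd = X.std(axis=0)
    constant = [n for n, s in zip(names, sd) if s == 0 or not np.isfinite(s)]
    if constant:
        warnings.warn(f"dropping constant features: {constant}")
    retained = [n for n in names if n not in constant]
    if len(retained) < 2:
        return retained

    def corr_with_y(name):
        v = features[name].to_numpy(float)
        return abs(np.corrcoef(v, y)[0, 1])

    while True:
        sub = features[retained].to_numpy(float)
        r = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(r, 0.0)
        # offending pairs sorted by descending |r|, ties by names
        pairs = [
            (abs(r[i, j]), retained[i], retained[j])
            for i in range(len(retained))
            for j in range(i + 1, len(retained))
            if abs(r[i, j]) > threshold
        ]
        if not pairs:
            break
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, a, b = pairs[0]
        ra, rb = corr_with_y(a), corr_with_y(b)
        if ra > rb:
            drop = b
        elif rb > ra:
            drop = a
        else:  # tie: keep the alphabetically first name
            drop = max(a, b)
        retained.remove(drop)
        if len(retained) < 2:
            break
    return retained


# ---------------------------------------------------------------------------
# OLS and criteria
# ---------------------------------------------------------------------------


def independent_columns(X: pd.DataFrame, names) -> list[str]:
    """Greedily keep columns that increase the rank of [1, X].

    Guards against exact linear dependences that pairwise correlation
    screening cannot see (e.g. a set of fractions summing to one).
    """
    n = len(X)
    cur = np.ones((n, 1))
    kept = []
    rank = 1
    for name in names:
        cand = np.column_stack([cur, X[name].to_numpy(float)])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(name)
            cur = cand
            rank = r
    return kept


def _design(X: pd.DataFrame | np.ndarray, names=None):
    if isinstance(X, pd.DataFrame):
        names = [c for c in X.columns if c != "cell_id"] if names is None else list(names)
        A = X[names].to_numpy(float)
    else:
        A = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(A.shape[1])] if names is None else list(names)
    return A, names


def fit_ols(X, y, names=None) -> dict:
    """Ordinary least squares with intercept.

    Returns a dict with intercept, coefficients (name -> value), fitted,
    residuals, SSE, SST, R^2, adjusted R^2, RMSE (= sqrt(SSE/n)) and the
    hat-matrix diagonal.  Raises on rank deficiency, naming the columns
    involved.
    """
    A, names = _design(X, names)
    y = np.asarray(y, dtype=float)
    n, p = A.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    D = np.column_stack([np.ones(n), A])
    rank = np.linalg.matrix_rank(D)
    if rank < p + 1:
        # identify columns that do not increase the rank when added
        offending = []
        cur = np.ones((n, 1))
        for j, name in enumerate(names):
            cand = np.column_stack([cur, A[:, j]])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(cur):
                offending.append(name)
            else:
                cur = cand
        raise ValueError(f"design matrix is rank deficient; offending columns {offending}")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    fitted = D @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if sst > 0 else np.nan
    q, _ = np.linalg.qr(D)
    leverage = (q**2).sum(axis=1)
    return {
        "names": names,
        "intercept": float(beta[0]),
        "coefficients": {nm: float(b) for nm, b in zip(names, beta[1:])},
        "beta": beta,
        "fitted": fitted,
        "residuals": resid,
        "leverage": leverage,
        "n": n,
        "p": p,
        "sse": sse,
        "sst": sst,
        "r2": r2,
        "adj_r2": adj_r2,
        "rmse": float(np.sqrt(sse / n)),
    }


def press_pred_r2(fit: dict) -> tuple[float, float]:
    """PRESS and predicted R^2 from leave-one-out leverages.

    PRESS = sum_i (e_i / (1 - h_ii))^2; pred-R^2 = 1 - PRESS/SST.  Undefined
    (NaN) when any leverage equals 1.
    """
    h = fit["leverage"]
    if np.any(h >= 1.0 - 1e-12):
        return np.nan, np.nan
    press = float(((fit["residuals"] / (1.0 - h)) ** 2).sum())
    pred_r2 = 1.0 - press / fit["sst"] if fit["sst"] > 0 else np.nan
    return press, pred_r2


def info_criteria(sse: float, n: int, p: int, full_model_mse: float) -> tuple[float, float, float]:
    """(Cp, AICc, BIC) for a subset with error sum of squares ``sse``.

    ``full_model_mse`` is SSE_full / (n - P - 1) for the model with all P
    candidate predictors.  AICc is NaN when n <= k + 1 (k = p + 2).
    """
    k = p + 2
    cp = sse / full_model_mse - n + 2 * (p + 1)
    if sse <= 0:
        # perfect fit: both log-likelihood criteria diverge to -inf, so a
        # noiseless model is always preferred (smallest such size wins ties)
        return float(cp), -np.inf, -np.inf
    if n > k + 1:
        aicc = n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc = np.nan
    bic = n * np.log(sse / n) + k * np.log(n)
    return float(cp), float(aicc), float(bic)


def _subset_model(X: pd.DataFrame, y, names, full_mse) -> SubsetModel:
    fit = fit_ols(X, y, names)
    press, pred_r2 = press_pred_r2(fit)
    cp, aicc, bic = info_criteria(fit["sse"], fit["n"], fit["p"], full_mse)
    return SubsetModel(
        predictors=tuple(names),
        intercept=fit["intercept"],
        coefficients=fit["coefficients"],
        n=fit["n"],
        p=fit["p"],
        sse=fit["sse"],
        r2=fit["r2"],
        adj_r2=fit["adj_r2"],
        pred_r2=pred_r2,
        press=press,
        cp=cp,
        aicc=aicc,
        bic=bic,
        rmse=fit["rmse"],
    )


# ---------------------------------------------------------------------------
# best subsets
# ---------------------------------------------------------------------------


@dataclass
class SelectionTable:
    """Per-size best candidate models and the lowest-AICc selection."""

    models: list  # SubsetModel, one per subset size
    selected_index: int
    candidate_names: tuple

    @property
    def selected(self) -> SubsetModel:
        return self.models[self.selected_index]

    def to_frame(self) -> pd.DataFrame:
        """The selection table in report layout (one row per subset size)."""
        rows = []
        for i, m in enumerate(self.models):
            row = {
                "Vars": m.p,
                "R2": m.r2,
                "adj_R2": m.adj_r2,
                "pred_R2": m.pred_r2,
                "Cp": m.cp,
                "RMSE": m.rmse,
                "AICc": m.aicc,
                "BIC": m.bic,
                "selected": i == self.selected_index,
            }
            for name in self.candidate_names:
                row[name] = "X" if name in m.predictors else ""
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        df = self.to_frame()
        num = df.copy()
        for c in ("R2", "adj_R2", "pred_R2"):
            num[c] = num[c].map(lambda v: f"{v:.2f}")
        for c in ("Cp", "RMSE", "AICc", "BIC"):
            num[c] = num[c].map(lambda v: f"{v:.3f}")
        num["selected"] = np.where(df["selected"], "<==", "")
        return num.to_string(index=False)


def best_subsets(
    X: pd.DataFrame,
    y,
    max_size: int = 10,
    candidates: list | None = None,
) -> SelectionTable:
    """Exhaustive best-subsets search; lowest AICc wins.

    For each subset size 1..max_size the subset with the highest R^2 (=
    lowest SSE) is retained with all criteria; the selected model is the
    per-size winner with the lowest AICc.  Refuses more than
    ``MAX_CANDIDATE_FEATURES`` candidates (tighten the prefilter instead).
    """
    names = candidates or [c for c in X.columns if c != "cell_id"]
    if len(names) > MAX_CANDIDATE_FEATURES:
        raise ValueError(
            f"{len(names)} candidate features exceed the combinatorial guard of "
            f"{MAX_CANDIDATE_FEATURES}; tighten the correlation prefilter"
        )
    y = np.asarray(y, dtype=float)
    n = len(y)
    max_size = min(max_size, len(names), max(n - 3, 1))

    full_fit = fit_ols(X, y, names)
    full_mse = full_fit["sse"] / (n - len(names) - 1)
    if full_mse <= 0:
        full_mse = np.finfo(float).tiny  # perfectly noiseless data

    # scan subsets on the centered Gram matrix: SSE(S) = Syy - g_S' G_SS^-1 g_S
    A = X[names].to_numpy(float)
    Ac = A - A.mean(axis=0)
    yc = y - y.mean()
    G = Ac.T @ Ac
    g = Ac.T @ yc
    syy = float(yc @ yc)
    P = len(names)
    models = []
    for size in range(1, max_size + 1):
        combos = np.array(list(itertools.combinations(range(P), size)))
        Gs = G[combos[:, :, None], combos[:, None, :]]  # (m, k, k)
        gs = g[combos]  # (m, k)
        try:
            beta = np.linalg.solve(Gs, gs[..., None])[..., 0]
            sse = syy - np.einsum("mk,mk->m", gs, beta)
        except np.linalg.LinAlgError:
            # a singular subset in the batch: fall back to per-combo lstsq
            sse = np.empty(len(combos))
            for i, cols in enumerate(combos):
                b = np.linalg.lstsq(Gs[i], gs[i], rcond=None)[0]
                sse[i] = syy - float(gs[i] @ b)
        best_combo = [names[j] for j in combos[int(np.argmin(sse))]]
        # refit the per-size winner exactly for coefficients and criteria
        models.append(_subset_model(X, y, best_combo, full_mse))

    aiccs = [np.inf if np.isnan(m.aicc) else m.aicc for m in models]
    selected = int(np.argmin(aiccs))  # -inf (perfect fit) wins; first wins ties
    return SelectionTable(models, selected, tuple(names))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def kfold_cv(X, y, predictors, k: int = 10, seed: int = 0) -> dict:
    """Seeded k-fold cross-validation of an OLS model.

    Folds are near-equal (sizes differ by at most one).  Returns pooled
    out-of-fold RMSE, rRMSE (%), bias (mean predicted - observed), R^2 of
    the pooled prediction table, and the per-observation predictions.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n]; got k={k}, n={n}")
    A, names = _design(X, predictors)
    p = A.shape[1]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    if n - max(len(f) for f in folds) <= p + 1:
        raise ValueError(
            f"training folds would hold {n - max(len(f) for f in folds)} rows "
            f"for {p} predictors"
        )
    pred = np.empty(n)
    for fold in folds:
        train = np.setdiff1d(order, fold)
        D = np.column_stack([np.ones(train.size), A[train]])
        beta, *_ = np.linalg.lstsq(D, y[train], rcond=None)
        pred[fold] = np.column_stack([np.ones(fold.size), A[fold]]) @ beta
    resid = pred - y
    rmse = float(np.sqrt((resid**2).mean()))
    mean_obs = y.mean()
    return {
        "rmse": rmse,
        "rrmse": 100.0 * rmse / mean_obs if mean_obs != 0 else np.nan,
        "bias": float(resid.mean()),
        "r2": 1.0 - float((resid**2).sum() / ((y - mean_obs) ** 2).sum()),
        "predictions": pred,
    }
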