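"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and coded separately from the package
so that agreement is evidence of correctness, not shared bugs.
"""

import itertools
import math

import numpy as np

PERCENTILE_LEVELS = (1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99)


def naive_percentile(values, q):
    """Linear-interpolation percentile from first principles."""
    v = sorted(values)
    n = len(v)
    pos = (q / 100.0) * (n - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def naive_cell_metrics(first_h, all_h, threshold=2.0, k=0.5):
    """All canopy metrics for one cell, computed the slow way."""
    out = {}
    for q in PERCENTILE_LEVELS:
        out[f"H{q}"] = naive_percentile(list(first_h), q)
    lo, hi = min(all_h), max(all_h)
    for i in range(1, 10):
        if hi - lo <= 0:
            out[f"D{i}"] = 0.0
        else:
            b = lo + (hi - lo) * i / 10.0
            out[f"D{i}"] = sum(1 for h in all_h if h > b) / len(all_h)
    n = len(all_h)
    mean = sum(all_h) / n
    var = sum((h - mean) ** 2 for h in all_h) / (n - 1)
    out["Hvar"] = var
    out["Hstd"] = math.sqrt(var)
    m2 = sum((h - mean) ** 2 for h in all_h) / n
    out["Hskew"] = (sum((h - mean) ** 3 for h in all_h) / n) / m2**1.5
    out["Hkurtosis"] = (sum((h - mean) ** 4 for h in all_h) / n) / m2**2
    med = naive_percentile(list(all_h), 50)
    out["Hmd"] = naive_percentile([abs(h - med) for h in all_h], 50)
    fmean = sum(first_h) / len(first_h)
    out["Hmean"] = fmean
    out["Hcv"] = out["Hstd"] / fmean
    above = [h for h in all_h if h > threshold]
    out["Hmax"] = max(above) if above else 0.0
    out["CC"] = sum(1 for h in first_h if h > threshold) / len(first_h)
    gf = sum(1 for h in all_h if h <= threshold) / n
    out["GF"] = gf
    rng = hi - lo
    out["CRR"] = (mean - lo) / rng if rng > 0 else 0.0
    out["LAI"] = -math.log(max(gf, 1.0 / (n + 1))) / k
    return out


def ols_pinv(X, y):
    """OLS through the explicit pseudo-inverse normal equations."""
    D = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    beta = np.linalg.pinv(D.T @ D) @ D.T @ np.asarray(y, float)
    resid = y - D @ beta
    return beta, float(resid @ resid)


def criteria_from_sse(sse, n, p, full_mse):
    """Cp / AICc / BIC recomputed independently from an SSE table."""
    k = p + 2
    cp = sse / full_mse - n + 2 * (p + 1)
    aicc = n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    bic = n * math.log(sse / n) + k * math.log(n)
    return cp, aicc, bic


def exhaustive_best_subsets(X, y, max_size):
    """Brute-force enumeration: per size, the lowest-SSE subset + criteria.

    Uses statsmodels for every subset fit; returns a list of dicts.
    """
    import statsmodels.api as sm

    names = list(X.columns)
    y = np.asarray(y, float)
    n = len(y)
    full = sm.OLS(y, sm.add_constant(X[names].to_numpy(float))).fit()
    full_mse = full.ssr / (n - len(names) - 1)
    rows = []
    for size in range(1, max_size + 1):
        best = None
        for combo in itertools.combinations(names, size):
            fit = sm.OLS(y, sm.add_constant(X[list(combo)].to_numpy(float))).fit()
            if best is None or fit.ssr < best[0]:
                best = (fit.ssr, combo, fit)
        sse, combo, fit = best
        cp, aicc, bic = criteria_from_sse(sse, n, size, full_mse)
        # Minitab-style predicted R^2 through the hat diagonal
        infl = fit.get_influence()
        press = float(((fit.resid / (1 - infl.hat_matrix_diag)) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        rows.append(
            {
                "size": size,
                "predictors": tuple(combo),
                "sse": sse,
                "r2": fit.rsquared,
                "adj_r2": fit.rsquared_adj,
                "pred_r2": 1 - press / sst,
                "cp": cp,
                "aicc": aicc,
                "bic": bic,
                "rmse": math.sqrt(sse / n),
            }
        )
    return rows
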