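"""Diversity-function statistics: curve fits with AIC selection, richness-bin
tests, the sliding-window key-taxa screen, and the Loreau-Hector partition.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FitResult",
    "fit_diversity_function",
    "richness_bin_tests",
    "paired_bin_tests",
    "scaled_comparison",
    "sliding_window_screen",
    "BiodiversityPartition",
    "loreau_hector_partition",
    "regression_with_density",
]

FAMILIES = ("linear", "loglinear", "hyperbolic")


@dataclasses.dataclass
class FitResult:
    """Least-squares fits of the three candidate diversity-function curves.

    ``fits`` maps family -> dict(params, aic, cov, rss); ``selected`` is the
    least-AIC family, with ties (dAIC <= 2) resolved toward the simpler family
    in the order linear < log-linear < hyperbolic. ``band`` holds the
    Monte-Carlo 95% confidence band (grid, low, high) when requested.
    """

    fits: dict
    selected: str
    band: dict | None = None

    def predict(self, x, family: str | None = None) -> np.ndarray:
        family = family or self.selected
        return _MODELS[family](np.asarray(x, dtype=float), *self.fits[family]["params"])


def _linear(x, a, b):
    return a + b * x


def _loglinear(x, a, b):
    return a + b * np.log(x)


def _hyperbolic(x, v, k):
    return v * x / (k + x)


_MODELS = {"linear": _linear, "loglinear": _loglinear, "hyperbolic": _hyperbolic}


def _gaussian_aic(rss: float, n: int, k_params: int) -> float:
    # + 1 free parameter for the error variance
    return n * np.log(2 * np.pi * rss / n) + n + 2 * (k_params + 1)


def fit_diversity_function(
    x,
    y,
    families: Sequence[str] = FAMILIES,
    n_mc: int = 5000,
    band: bool = False,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> FitResult:
    """Fit linear, log-linear and hyperbolic curves and select by least AIC.

    Linear: y = a + b x; log-linear: y = a + b ln x (requires x > 0);
    hyperbolic: y = V x / (K + x) (Michaelis-Menten shape). A family whose fit
    fails to converge is dropped with a warning. The optional 95% band is
    computed by Monte-Carlo draws from the asymptotic parameter covariance of
    the selected family.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least four points")
    fits: dict = {}
    for family in families:
        try:
            if family == "linear":
                X = np.column_stack([np.ones(n), x])
                params, rss = _ols(X, y)
                cov = _ols_cov(X, rss, n)
            elif family == "loglinear":
                if np.any(x <= 0):
                    raise ValueError("log-linear fit requires x > 0")
                X = np.column_stack([np.ones(n), np.log(x)])
                params, rss = _ols(X, y)
                cov = _ols_cov(X, rss, n)
            else:
                p0 = (float(np.max(y)), float(np.median(x)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    params, cov = optimize.curve_fit(
                        _hyperbolic, x, y, p0=p0, maxfev=20000
                    )
                rss = float(np.sum((y - _hyperbolic(x, *params)) ** 2))
            if not np.all(np.isfinite(params)):
                raise RuntimeError("non-finite parameters")
            # floor the RSS at numerical-noise level so that exact
            # (zero-residual) fits of different families tie instead of
            # ranking on rounding error
            rss_floor = 1e-12 * n * (float(np.mean(y**2)) + 1e-30)
            fits[family] = {
                "params": tuple(float(p) for p in params),
                "rss": float(rss),
                "aic": float(_gaussian_aic(max(rss, rss_floor), n, len(params))),
                "cov": np.asarray(cov, dtype=float),
            }
        except Exception as exc:  # noqa: BLE001 - non-convergence is not fatal
            warnings.warn(f"{family} fit dropped: {exc}", stacklevel=2)
    if not fits:
        raise RuntimeError("all curve families failed to fit")
    best_aic = min(f["aic"] for f in fits.values())
    selected = next(
        fam for fam in FAMILIES if fam in fits and fits[fam]["aic"] <= best_aic + 2.0
    )
    result = FitResult(fits=fits, selected=selected)
    if band:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        if grid is None:
            grid = np.linspace(x.min(), x.max(), 50)
        f = fits[selected]
        cov = np.atleast_2d(f["cov"])
        if not np.all(np.isfinite(cov)):
            cov = np.zeros_like(cov)
        draws = rng.multivariate_normal(f["params"], cov, size=n_mc, method="svd")
        curves = np.stack([_MODELS[selected](grid, *d) for d in draws])
        low, high = np.percentile(curves, [2.5, 97.5], axis=0)
        result.band = {"grid": grid, "low": low, "high": high}
    return result


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    params, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ params) ** 2))
    return params, rss


def _ols_cov(X: np.ndarray, rss: float, n: int) -> np.ndarray:
    dof = max(n - X.shape[1], 1)
    return rss / dof * np.linalg.inv(X.T @ X)


DEFAULT_BINS = ((None, 12), (12, 26), (26, None))


def _bin_mask(richness: np.ndarray, lo, hi) -> np.ndarray:
    mask = np.ones(len(richness), dtype=bool)
    if lo is not None:
        mask &= richness > lo
    if hi is not None:
        mask &= richness <= hi
    return mask


def _bin_label(lo, hi) -> str:
    if lo is None:
        return f"<= {hi}"
    if hi is None:
        return f"> {lo}"
    return f"({lo}, {hi}]"


def richness_bin_tests(
    values,
    richness,
    null_value: float = 1.0,
    bins=DEFAULT_BINS,
    min_n: int = 3,
) -> pd.DataFrame:
    """One-sample two-tailed t-tests of ``values`` against ``null_value`` per
    richness bin (default bins: N <= 12, 12 < N <= 26, N > 26). Bins with fewer
    than ``min_n`` communities are reported but skipped (NaN statistics).
    """
    values = np.asarray(values, dtype=float)
    richness = np.asarray(richness, dtype=float)
    rows = []
    for lo, hi in bins:
        mask = _bin_mask(richness, lo, hi) & np.isfinite(values)
        v = values[mask]
        row = {"bin": _bin_label(lo, hi), "n": int(len(v)), "mean": float(np.mean(v)) if len(v) else np.nan}
        if len(v) >= min_n:
            if np.std(v, ddof=1) == 0:
                # degenerate sample: no spread, t defined by the mean alone
                t, p = (0.0, 1.0) if np.isclose(v[0], null_value) else (np.inf, 0.0)
            else:
                t, p = sps.ttest_1samp(v, null_value)
            row.update({"t": float(t), "dof": len(v) - 1, "p": float(p), "skipped": False})
        else:
            row.update({"t": np.nan, "dof": np.nan, "p": np.nan, "skipped": True})
        rows.append(row)
    return pd.DataFrame(rows)


def paired_bin_tests(
    values_a,
    values_b,
    richness,
    bins=DEFAULT_BINS,
    alternative: str = "greater",
    min_n: int = 3,
) -> pd.DataFrame:
    """Paired comparisons of two functions per richness bin.

    Reports a two-tailed paired t-test and a one-tailed Wilcoxon signed-rank
    test (the paired analogue of the rank-sum test) of a against b, pairing by
    position (community).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    richness = np.asarray(richness, dtype=float)
    rows = []
    for lo, hi in bins:
        mask = _bin_mask(richness, lo, hi) & np.isfinite(a) & np.isfinite(b)
        va, vb = a[mask], b[mask]
        row = {"bin": _bin_label(lo, hi), "n": int(len(va))}
        if len(va) >= min_n:
            t, tp = sps.ttest_rel(va, vb)
            diff = va - vb
            if np.allclose(diff, 0):
                wp = 1.0
            else:
                _, wp = sps.wilcoxon(va, vb, alternative=alternative, zero_method="wilcox")
            row.update({"t": float(t), "p_t": float(tp), "p_wilcoxon": float(wp), "skipped": False})
        else:
            row.update({"t": np.nan, "p_t": np.nan, "p_wilcoxon": np.nan, "skipped": True})
        rows.append(row)
    return pd.DataFrame(rows)


def scaled_comparison(fit_a: FitResult, fit_b: FitResult, grid) -> dict:
    """Paired two-tailed t-test of two fitted curves scaled to max 1.

    Each curve is evaluated on the common grid and divided by its own maximum,
    so curves that differ only by a scale factor compare as identical.
    """
    grid = np.asarray(grid, dtype=float)
    ya = fit_a.predict(grid)
    yb = fit_b.predict(grid)
    ma, mb = np.max(np.abs(ya)), np.max(np.abs(yb))
    if ma == 0 or mb == 0:
        raise ValueError("cannot scale a curve with zero maximum")
    sa, sb = ya / ma, yb / mb
    if np.allclose(sa, sb):
        return {"t": 0.0, "p": 1.0, "mean_diff": 0.0}
    t, p = sps.ttest_rel(sa, sb)
    return {"t": float(t), "p": float(p), "mean_diff": float(np.mean(sa - sb))}


def _tie_sums(x: np.ndarray) -> tuple[float, float, float]:
    _, counts = np.unique(x, return_counts=True)
    t = counts.astype(float)
    return (
        float(np.sum(t * (t - 1) * (2 * t + 5))),
        float(np.sum(t * (t - 1))),
        float(np.sum(t * (t - 1) * (t - 2))),
    )


def _prepare_tau_side(b: np.ndarray) -> tuple:
    m = len(b)
    iu = np.triu_indices(m, 1)
    sb = np.sign(b[:, None] - b[None, :])[iu]
    return m, iu, sb, float(np.sum(sb == 0)), _tie_sums(b)


def _tau_b_prepared(a: np.ndarray, prep: tuple) -> tuple[float, float]:
    m, iu, sb, n2, (vu, u1, u2) = prep
    sa = np.sign(a[:, None] - a[None, :])[iu]
    s = float(sa @ sb)
    n0 = m * (m - 1) / 2.0
    n1 = float(np.sum(sa == 0))
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return float("nan"), float("nan")
    tau = s / denom
    vt, t1, t2 = _tie_sums(a)
    v0 = m * (m - 1) * (2 * m + 5)
    var_s = (v0 - vt - vu) / 18.0
    if m > 2:
        var_s += t2 * u2 / (9.0 * m * (m - 1) * (m - 2))
    var_s += t1 * u1 / (2.0 * m * (m - 1))
    if var_s <= 0:
        return tau, float("nan")
    z = s / np.sqrt(var_s)
    return tau, float(math.erfc(abs(z) / math.sqrt(2.0)))


def kendall_tau_b(a, b) -> tuple[float, float]:
    """Kendall tau-b with a tie-corrected asymptotic two-sided p-value.

    Direct pairwise implementation (the screen calls this thousands of times
    on windows of 5-40 communities, where library call overhead dominates).
    tau-b = S / sqrt((n0 - n1)(n0 - n2)) with S the concordant-discordant
    difference and n1/n2 the tied-pair counts; the p-value uses the standard
    tie-corrected variance of S under the null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return _tau_b_prepared(a, _prepare_tau_side(b))


def sliding_window_screen(
    abundances: pd.DataFrame,
    function_values: pd.Series,
    richness: pd.Series,
    function_name: str = "function",
    widths: Sequence[int] = tuple(range(2, 11)),
    step: int = 1,
    q_threshold: float = 0.05,
    min_n: int = 5,
    min_presence: int = 3,
    pool_all: bool = False,
) -> pd.DataFrame:
    """Screen for key taxa: Kendall correlations in richness sliding windows.

    For every window of ``width`` consecutive richness values and every taxon
    present in at least ``min_presence`` of the >= ``min_n`` communities in the
    window, computes Kendall tau-b between the taxon's relative abundance and
    the community function. p-values are Benjamini-Hochberg adjusted within
    each (function, width) stratum (or pooled across widths with
    ``pool_all``); rows with q < ``q_threshold`` are flagged as hits.
    """
    samples = abundances.index
    f = function_values.loc[samples].to_numpy(dtype=float)
    r = richness.loc[samples].to_numpy(dtype=float)
    A = abundances.to_numpy(dtype=float)
    taxa = list(abundances.columns)
    records = []
    r_lo, r_hi = int(np.min(r)), int(np.max(r))
    for width in widths:
        for lo in range(r_lo, r_hi - width + 2, step):
            hi = lo + width - 1
            idx = np.where((r >= lo) & (r <= hi))[0]
            if len(idx) < min_n:
                continue
            fw = f[idx]
            if (fw == fw[0]).all():
                continue
            prep = _prepare_tau_side(fw)
            sub = A[idx]
            present = (sub > 0).sum(axis=0)
            for j in np.where(present >= min_presence)[0]:
                av = sub[:, j]
                if (av == av[0]).all():
                    continue
                tau, p = _tau_b_prepared(av, prep)
                if np.isnan(tau) or np.isnan(p):
                    continue
                records.append(
                    {
                        "taxon_id": taxa[j],
                        "function": function_name,
                        "window_lo": lo,
                        "window_hi": hi,
                        "width": width,
                        "n": int(len(idx)),
                        "tau": float(tau),
                        "p": float(p),
                    }
                )
    out = pd.DataFrame(
        records,
        columns=["taxon_id", "function", "window_lo", "window_hi", "width", "n", "tau", "p"],
    )
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["hit"] = pd.Series(dtype=bool)
        return out
    out["q"] = np.nan
    strata = [((function_name,), out.index)] if pool_all else [
        (key, idx) for key, idx in out.groupby("width").groups.items()
    ]
    for _, idx in strata:
        out.loc[idx, "q"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    out["hit"] = out["q"] < q_threshold
    out["direction"] = np.where(out["tau"] > 0, "positive", "negative")
    return out


@dataclasses.dataclass
class BiodiversityPartition:
    """Loreau-Hector decomposition of the net biodiversity effect.

    net = N * mean(dRY) * mean(M) + N * cov(dRY, M) (population covariance):
    the first term is the complementarity effect, the second the selection
    effect; dRY_i is the deviation of observed from expected relative yield.
    """

    net: float
    complementarity: float
    selection: float
    delta_ry: pd.Series
    monoculture: pd.Series


def loreau_hector_partition(
    observed,
    monoculture,
    expected_relative_yields,
) -> BiodiversityPartition:
    """Partition the net biodiversity effect into complementarity + selection."""
    obs = pd.Series(observed, dtype=float)
    mono = pd.Series(monoculture, dtype=float).loc[obs.index]
    exp_ry = pd.Series(expected_relative_yields, dtype=float).loc[obs.index]
    if np.any(mono <= 0):
        raise ValueError("monoculture functions must be positive")
    if not np.isclose(exp_ry.sum(), 1.0):
        raise ValueError("expected relative yields must sum to 1")
    d_ry = obs / mono - exp_ry
    n = len(obs)
    m = mono.to_numpy()
    d = d_ry.to_numpy()
    complementarity = n * d.mean() * m.mean()
    selection = n * float(np.mean((d - d.mean()) * (m - m.mean())))
    net = float(obs.sum() - (exp_ry * mono).sum())
    return BiodiversityPartition(
        net=net,
        complementarity=float(complementarity),
        selection=float(selection),
        delta_ry=d_ry,
        monoculture=mono,
    )


def regression_with_density(
    function_values,
    richness,
    initial_density,
) -> pd.DataFrame:
    """OLS of function on richness + log10(initial cell density), type-II tests.

    Confirms that a diversity-function relationship survives adjustment for
    inoculum density. Returns one row per predictor with the coefficient and
    the type-II sum-of-squares F statistic and p-value.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {
            "f": np.asarray(function_values, dtype=float),
            "richness": np.asarray(richness, dtype=float),
            "log_density": np.log10(np.asarray(initial_density, dtype=float)),
        }
    )
    if len(df) <= 3:
        raise ValueError("need more observations than predictors + 1")
    if np.isclose(np.corrcoef(df["richness"], df["log_density"])[0, 1] ** 2, 1.0):
        raise np.linalg.LinAlgError("collinear predictors")
    model = ols("f ~ richness + log_density", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = anova_lm(model, typ=2)
    out = table.loc[["richness", "log_density"], ["sum_sq", "F", "PR(>F)"]].copy()
    out["coef"] = model.params.loc[["richness", "log_density"]]
    out = out.rename(columns={"PR(>F)": "p"})
    # a flat response carries no evidence for either predictor
    tol = 1e-12 * len(df) * (float(np.mean(df["f"] ** 2)) + 1e-30)
    flat = out["sum_sq"] < tol
    out.loc[flat, ["F", "p"]] = [0.0, 1.0]
    return out
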