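"""Two-enhancer expression models and BIC-based model comparison.

Expression of a gene controlled by a pair of enhancers is measured by
RT-qPCR in four genotypes obtained by CRISPR excision: wild type (both
enhancers intact), each single knockout, and the double knockout.  With
binary indicators ``x1, x2`` (1 = intact, 0 = excised) three generative
models for the mean expression are compared:

* additive      ``mu = b0 + b1*x1 + b2*x2`` — enhancers act independently
  and their activities sum;
* exponential   ``mu = exp(b0 + b1*x1 + b2*x2)`` — enhancers act
  multiplicatively (synergy, or antagonism for negative coefficients);
* logistic      ``mu = g / (1 + exp(-(b0 + b1*x1 + b2*x2)))`` — each
  enhancer independently lowers an energy threshold gating transcription,
  ``g`` being the maximum attainable expression.

All three carry additive Gaussian noise with constant variance; ``sigma``
is profiled by maximum likelihood and counted as a free parameter in the
BIC (k*ln(n) - 2*logL).  Families within 2 BIC units of the minimum are
reported jointly as the best set, since a difference below 2 is not
considered decisive.

Raw measurements are first divided by the mean wild-type expression of
their own transdifferentiation batch (:func:`normalize_to_wt`) so that
batch-to-batch scale differences cancel and the wild-type mean is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConvergenceError, DataError

FAMILIES = ("additive", "exponential", "logistic")

#: genotypes in the fixed two-enhancer design, (x1, x2)
GENOTYPES = ((1, 1), (1, 0), (0, 1), (0, 0))

_SIGMA_FLOOR = 1e-12


def model_mean(model: str, b0: float, b1: float, b2: float,
               x1, x2, g: float | None = None):
    """Mean expression mu(x1, x2) under one model family."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    eta = b0 + b1 * x1 + b2 * x2
    if model == "additive":
        return eta
    if model == "exponential":
        return np.exp(np.clip(eta, -745.0, 709.0))
    if model == "logistic":
        if g is None:
            raise DataError("logistic model requires the maximum-expression term g")
        return g / (1.0 + np.exp(-np.clip(eta, -709.0, 709.0)))
    raise DataError(f"unknown model family {model!r}; expected one of {FAMILIES}")


@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood fit of one model family.

    ``sigma`` is the ML residual standard deviation, ``n_params`` counts
    sigma as a free parameter (4 for additive/exponential, 5 for logistic).
    """

    model: str
    b0: float
    b1: float
    b2: float
    sigma: float
    logl: float
    n_obs: int
    n_params: int
    bic: float
    g: float | None = None

    def mean(self, x1, x2):
        return model_mean(self.model, self.b0, self.b1, self.b2, x1, x2, self.g)

    def to_dict(self) -> dict:
        d = {
            "model": self.model, "b0": self.b0, "b1": self.b1, "b2": self.b2,
            "sigma": self.sigma, "logl": self.logl, "n_obs": self.n_obs,
            "n_params": self.n_params, "bic": self.bic,
        }
        if self.model == "logistic":
            d["g"] = self.g
        return d


@dataclass(frozen=True)
class ModelSelection:
    """BIC comparison of the three families against the additive reference."""

    fits: Mapping[str, ModelFit]
    delta_bic: Mapping[str, float]
    best_set: frozenset[str]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "fits": {m: f.to_dict() for m, f in self.fits.items()},
            "delta_bic": dict(self.delta_bic),
            "best_set": sorted(self.best_set),
            "threshold": self.threshold,
        }


def _as_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    return pd.DataFrame(observations)


def normalize_to_wt(observations, expression_col: str = "expression") -> pd.DataFrame:
    """Divide each measurement by the mean WT (x1=1, x2=1) value of its batch.

    Returns a copy with the ``expression`` column rescaled; genotype and
    replicate labels are preserved.  The operation is idempotent: after one
    pass every batch WT mean is 1.
    """
    df = _as_frame(observations).copy()
    for col in ("batch", "x1", "x2", expression_col):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
    if not df["x1"].isin((0, 1)).all() or not df["x2"].isin((0, 1)).all():
        raise DataError("enhancer states x1, x2 must be binary (0 = excised, 1 = intact)")
    out = []
    for batch, grp in df.groupby("batch", sort=False):
        wt = grp[(grp["x1"] == 1) & (grp["x2"] == 1)][expression_col]
        if wt.empty:
            raise DataError(f"batch {batch!r} has no wild-type (x1=1, x2=1) observation "
                            "to normalize against")
        wt_mean = float(wt.mean())
        if wt_mean <= 0:
            raise DataError(f"batch {batch!r} has a non-positive wild-type mean "
                            f"({wt_mean}); normalization is degenerate")
        g = grp.copy()
        g[expression_col] = g[expression_col] / wt_mean
        out.append(g)
    return pd.concat(out).loc[df.index]


def _profile_loglik(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Residual SD and Gaussian log-likelihood with sigma profiled out."""
    n = y.size
    rss = float(np.sum((y - mu) ** 2))
    sigma = max(np.sqrt(rss / n), _SIGMA_FLOOR)
    logl = -0.5 * n * np.log(2.0 * np.pi * sigma ** 2) - rss / (2.0 * sigma ** 2)
    return sigma, float(logl)


def _finish(model: str, beta: Sequence[float], g: float | None,
            y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> ModelFit:
    b0, b1, b2 = (float(b) for b in beta)
    mu = model_mean(model, b0, b1, b2, x1, x2, g)
    sigma, logl = _profile_loglik(y, mu)
    n_params = 5 if model == "logistic" else 4
    n = y.size
    bic = n_params * np.log(n) - 2.0 * logl
    return ModelFit(model=model, b0=b0, b1=b1, b2=b2, sigma=sigma, logl=logl,
                    n_obs=int(n), n_params=n_params, bic=float(bic),
                    g=None if g is None else float(g))


def _group_means(y, x1, x2) -> dict[tuple[int, int], float]:
    means = {}
    for gx1, gx2 in GENOTYPES:
        sel = (x1 == gx1) & (x2 == gx2)
        if sel.any():
            means[(gx1, gx2)] = float(y[sel].mean())
    return means


def _design_rows(keys):
    return np.array([[1.0, k[0], k[1]] for k in keys])


def fit_model(data, model: str, seed: int = 0, n_restarts: int = 10,
              expression_col: str = "expression") -> ModelFit:
    """Fit one family by maximum likelihood under Gaussian constant-variance noise.

    The additive family has a closed-form (least-squares) optimum.  The
    exponential and logistic families are fitted by nonlinear least squares
    with informed initial values plus ``n_restarts`` seeded random restarts;
    the result is deterministic given ``data`` and ``seed``.
    """
    if model not in FAMILIES:
        raise DataError(f"unknown model family {model!r}; expected one of {FAMILIES}")
    df = _as_frame(data)
    y = df[expression_col].to_numpy(dtype=float)
    x1 = df["x1"].to_numpy(dtype=float)
    x2 = df["x2"].to_numpy(dtype=float)
    n_params = 5 if model == "logistic" else 4
    if y.size < n_params:
        raise DataError(f"{model} model needs at least {n_params} observations, got {y.size}")
    n_genotypes = len({(a, b) for a, b in zip(x1, x2)})
    if n_genotypes < 3:
        raise DataError(f"need at least 3 distinct genotypes, got {n_genotypes}")

    if model == "additive":
        X = np.column_stack([np.ones_like(x1), x1, x2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return _finish(model, beta, None, y, x1, x2)

    rng = np.random.default_rng(seed)
    means = _group_means(y, x1, x2)
    keys = list(means)
    X_grp = _design_rows(keys)
    m = np.array([means[k] for k in keys])

    if model == "exponential":
        def residuals(p):
            return y - model_mean("exponential", *p, x1, x2)

        starts = []
        if (m > 0).all():
            beta0, *_ = np.linalg.lstsq(X_grp, np.log(m), rcond=None)
            starts.append(beta0)
        else:
            # some group mean non-positive: log-linear init undefined
            starts.append(np.zeros(3))
        for _ in range(n_restarts):
            starts.append(starts[0] + rng.normal(0.0, 0.5, size=3))
        best = None
        for p0 in starts:
            try:
                res = optimize.least_squares(residuals, p0, method="lm",
                                             ftol=1e-10, xtol=1e-10, max_nfev=5000)
            except Exception:
                continue
            if not np.isfinite(res.cost):
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise ConvergenceError("exponential fit failed to converge in "
                                   f"{len(starts)} starts (n={y.size})")
        return _finish(model, best.x, None, y, x1, x2)

    # logistic: parameters (g, b0, b1, b2), g > 0
    def residuals(p):
        return y - model_mean("logistic", p[1], p[2], p[3], x1, x2, g=p[0])

    ymax = float(y.max())
    g0 = 1.05 * ymax if ymax > 0 else 1.0
    frac = np.clip(m / g0, 1e-6, 1.0 - 1e-6)
    beta0, *_ = np.linalg.lstsq(X_grp, np.log(frac / (1.0 - frac)), rcond=None)
    starts = [np.concatenate([[g0], beta0])]
    for _ in range(n_restarts):
        starts.append(np.concatenate([
            [g0 * np.exp(rng.normal(0.0, 0.3))],
            beta0 + rng.normal(0.0, 0.5, size=3),
        ]))
    # When the data are log-additive the logistic optimum runs away to
    # g -> infinity (the family degenerates to the exponential one); a
    # generous cap keeps the optimizer finite without constraining any
    # realistic saturation level.
    g_cap = 1e3 * max(1.0, ymax)
    lower = np.array([1e-9, -np.inf, -np.inf, -np.inf])
    upper = np.array([g_cap, np.inf, np.inf, np.inf])
    best = None
    # restarts get a short budget to sort the basins; the winner is polished
    for p0 in starts:
        p0 = np.clip(p0, lower, upper)
        try:
            res = optimize.least_squares(residuals, p0, bounds=(lower, upper),
                                         ftol=1e-10, xtol=1e-10, max_nfev=300)
        except Exception:
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ConvergenceError(f"logistic fit failed to converge in {len(starts)} starts")
    polished = optimize.least_squares(residuals, best.x, bounds=(lower, upper),
                                      ftol=1e-10, xtol=1e-10, max_nfev=2000)
    if np.isfinite(polished.cost) and polished.cost <= best.cost:
        best = polished
    g, b0, b1, b2 = best.x
    return _finish(model, (b0, b1, b2), g, y, x1, x2)


def fit_all_models(data, seed: int = 0, **kwargs) -> dict[str, ModelFit]:
    """Fit all three families on the same data."""
    return {m: fit_model(data, m, seed=seed, **kwargs) for m in FAMILIES}


def select_models(fits: Mapping[str, ModelFit] | Iterable[ModelFit],
                  threshold: float = 2.0) -> ModelSelection:
    """Compare fits by BIC; report the set of families within ``threshold`` of the best.

    Delta-BIC is reported against the additive fit as the reference point.
    """
    if not isinstance(fits, Mapping):
        fits = {f.model: f for f in fits}
    if "additive" not in fits:
        raise DataError("an additive fit is required as the BIC reference point")
    n_obs = {f.n_obs for f in fits.values()}
    if len(n_obs) != 1:
        raise DataError(f"fits were computed on different data sets (n_obs = {sorted(n_obs)})")
    ref = fits["additive"].bic
    delta = {m: f.bic - ref for m, f in fits.items()}
    best_bic = min(f.bic for f in fits.values())
    best = frozenset(m for m, f in fits.items() if f.bic <= best_bic + threshold)
    return ModelSelection(fits=dict(fits), delta_bic=delta, best_set=best,
                          threshold=float(threshold))


def predict_quantiles(fit: ModelFit, x1: int, x2: int,
                      quantiles: Sequence[float]) -> np.ndarray:
    """Quantiles of the Gaussian predictive distribution N(mu(x1, x2), sigma^2)."""
    q = np.asarray(quantiles, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise DataError("quantiles must lie strictly inside (0, 1)")
    mu = float(fit.mean(x1, x2))
    return stats.norm.ppf(q, loc=mu, scale=fit.sigma)


def coefficient_summary(*fits: ModelFit) -> dict[str, dict]:
    """Per-model enhancer coefficients, their ratio b1/b2 and activator/antagonist flags.

    A negative coefficient marks the enhancer as an antagonist (it dampens
    expression); b2 == 0 yields an undefined-ratio flag instead of an error.
    """
    def role(b: float) -> str:
        return "activator" if b > 0 else ("antagonist" if b < 0 else "neutral")

    out = {}
    for f in fits:
        defined = f.b2 != 0.0
        out[f.model] = {
            "b1": f.b1,
            "b2": f.b2,
            "ratio": f.b1 / f.b2 if defined else float("nan"),
            "ratio_defined": defined,
            "enhancer1": role(f.b1),
            "enhancer2": role(f.b2),
        }
    return out
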