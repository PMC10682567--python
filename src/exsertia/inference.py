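"""GLM fitting, Wald inference, prediction surfaces, marginal means, contrasts.

Binomial (logit) and Poisson (log) generalized linear models are fitted by
iteratively reweighted least squares with the coefficient covariance taken
as the inverse Fisher information at the optimum. Inference is Wald-type on
the normal reference distribution. Prediction surfaces and estimated
marginal means are computed on the linear-predictor scale — eta with a
symmetric 95% interval from SE(eta) = sqrt(x' Sigma x) — and then
inverse-linked, giving intervals that are asymmetric on the response scale
and always inside the admissible range. Pairwise species contrasts are
adjusted by the single-step multivariate-normal method (the GLM analogue of
the Tukey test): the adjusted p of one contrast is the probability that the
maximum absolute component of a multivariate normal vector with the
contrasts' correlation matrix exceeds that contrast's |z|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from exsertia.covariates import (
    DesignMatrix,
    REFERENCE_SPECIES,
    StandardizationParams,
)

FAMILIES = ("binomial", "poisson")
#: fixed confidence level for every interval
CONFIDENCE = 0.95
_ZCRIT = float(stats.norm.ppf(0.5 + CONFIDENCE / 2.0))
#: fixed seed for the Monte-Carlo multivariate-normal adjustment
TUKEY_SEED = 20231127

MAX_ITER = 50
#: |eta| beyond which a fitted logit model is treated as quasi-separated
SEPARATION_ETA = 30.0


class FitError(RuntimeError):
    pass


@dataclass(slots=True)
class GlmFit:
    """A converged GLM fit: point estimates, covariance, and metadata."""

    model: str
    family: str
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    llf: float
    n: int
    converged: bool
    n_iter: int
    pearson_chi2_over_df: float
    fruit_mean: float
    species_levels: Optional[list[str]] = None

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)

    def linkinv(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return np.exp(eta)


def fit_glm(design: DesignMatrix, family: Optional[str] = None) -> GlmFit:
    """Fit a binomial-logit or Poisson-log GLM to a design matrix.

    The family defaults to binomial for the binary models and Poisson for
    the count models. Raises on non-convergence within 50 IRLS iterations,
    on rank-deficient designs, and on quasi-separation (any fitted |eta|
    above 30, where a logit fit is numerically unbounded).
    """
    if family is None:
        family = "poisson" if design.model.endswith("_count") else "binomial"
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(design.response, dtype=float)
    X = design.X
    if family == "binomial" and not np.all(np.isin(y, (0.0, 1.0))):
        raise FitError("binomial response must be coded 0/1")
    if family == "poisson" and (np.any(y < 0) or np.any(y != np.round(y))):
        raise FitError("poisson response must be non-negative integers")
    rank = np.linalg.matrix_rank(np.asarray(X, dtype=float))
    if rank < X.shape[1]:
        raise FitError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]} columns)")

    fam = (sm.families.Binomial() if family == "binomial"
           else sm.families.Poisson())
    res = sm.GLM(y, X, family=fam).fit(maxiter=MAX_ITER, tol=1e-10)
    n_iter = res.fit_history.get("iteration", MAX_ITER)
    converged = bool(getattr(res, "converged", n_iter < MAX_ITER))
    if not converged:
        raise FitError(f"IRLS did not converge in {MAX_ITER} iterations")
    eta = np.asarray(X, dtype=float) @ np.asarray(res.params, dtype=float)
    if np.any(np.abs(eta) > SEPARATION_ETA):
        raise FitError(
            "quasi-separation detected (|linear predictor| > "
            f"{SEPARATION_ETA:g}); remove the separating predictor or pool "
            "sparse categories"
        )
    cov = pd.DataFrame(np.asarray(res.cov_params(), dtype=float),
                       index=X.columns, columns=X.columns)
    df_resid = max(len(y) - X.shape[1], 1)
    species_levels = None
    if design.species is not None:
        present = sorted(set(design.species))
        species_levels = ([REFERENCE_SPECIES] if REFERENCE_SPECIES in present
                          else []) + [s for s in present if s != REFERENCE_SPECIES]
    return GlmFit(
        model=design.model,
        family=family,
        params=pd.Series(np.asarray(res.params, dtype=float), index=X.columns),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=X.columns),
        cov=cov,
        llf=float(res.llf),
        n=len(y),
        converged=True,
        n_iter=int(n_iter),
        pearson_chi2_over_df=float(res.pearson_chi2) / df_resid,
        fruit_mean=design.fruit_mean,
        species_levels=species_levels,
    )


def wald_table(fit: GlmFit) -> pd.DataFrame:
    """Per-coefficient estimates, SEs, z statistics, and two-sided p values."""
    z = fit.params / fit.bse
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "term": fit.terms,
        "beta": fit.params.values,
        "se": fit.bse.values,
        "z": z.values,
        "p": p,
    }).set_index("term")


def _eta_and_se(fit: GlmFit, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta = fit.params.values
    sigma = fit.cov.values
    eta = rows @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", rows, sigma, rows))
    return eta, se


def predict_surface(
    fit: GlmFit,
    focal: str,
    grid: Sequence[float],
    params: Mapping[str, StandardizationParams],
    held: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Predicted response over a raw-scale grid of one focal predictor.

    Every non-focal standardized predictor is held at its fitting-subset
    mean (z = 0) and the fruiting indicator at the fitting-subset fruiting
    proportion, unless overridden in ``held`` (raw scale for standardized
    columns). Grid values outside the fitting-subset range of the focal
    predictor are predicted but flagged ``extrapolated``.
    """
    if focal not in fit.terms:
        raise ValueError(f"focal predictor {focal!r} not in the model "
                         f"(terms: {fit.terms})")
    if focal.startswith("z_") and focal not in params:
        raise ValueError(f"no standardization parameters for {focal!r}")
    grid = np.asarray(grid, dtype=float)
    rows = np.zeros((len(grid), len(fit.terms)))
    columns = {t: j for j, t in enumerate(fit.terms)}
    rows[:, columns["const"]] = 1.0
    if "fruit" in columns:
        rows[:, columns["fruit"]] = fit.fruit_mean
    if held:
        for name, raw in held.items():
            if name not in columns:
                raise ValueError(f"held predictor {name!r} not in the model")
            value = params[name].apply([raw])[0] if name in params else raw
            rows[:, columns[name]] = value
    if focal in params:
        sp = params[focal]
        rows[:, columns[focal]] = sp.apply(grid)
        extrapolated = ((grid < sp.raw_min) | (grid > sp.raw_max)
                        if sp.raw_min is not None else np.zeros(len(grid), bool))
    else:
        rows[:, columns[focal]] = grid
        extrapolated = np.zeros(len(grid), bool)
    eta, se = _eta_and_se(fit, rows)
    return pd.DataFrame({
        focal: grid,
        "eta": eta,
        "se_eta": se,
        "mean": fit.linkinv(eta),
        "lower": fit.linkinv(eta - _ZCRIT * se),
        "upper": fit.linkinv(eta + _ZCRIT * se),
        "extrapolated": extrapolated,
    })


def _species_rows(fit: GlmFit) -> tuple[list[str], np.ndarray]:
    if not fit.species_levels:
        raise ValueError("estimated marginal means require a species model")
    rows = np.zeros((len(fit.species_levels), len(fit.terms)))
    columns = {t: j for j, t in enumerate(fit.terms)}
    rows[:, columns["const"]] = 1.0
    if "fruit" in columns:
        rows[:, columns["fruit"]] = fit.fruit_mean
    for i, sp in enumerate(fit.species_levels):
        col = f"species_{sp}"
        if col in columns:
            rows[i, columns[col]] = 1.0
    return fit.species_levels, rows


def marginal_means(
    fit: GlmFit,
    params: Optional[Mapping[str, StandardizationParams]] = None,
) -> pd.DataFrame:
    """Estimated marginal means by species on the response scale.

    Each species is evaluated at its own indicator configuration with day
    of year at its (group-centered) mean, fruiting at the pooled fruiting
    proportion, and — in count models — the visible-flower count at its
    mean; 95% intervals are built on the link scale and inverse-linked.
    """
    levels, rows = _species_rows(fit)
    eta, se = _eta_and_se(fit, rows)
    return pd.DataFrame({
        "species": levels,
        "eta": eta,
        "se_eta": se,
        "mean": fit.linkinv(eta),
        "lower": fit.linkinv(eta - _ZCRIT * se),
        "upper": fit.linkinv(eta + _ZCRIT * se),
    }).set_index("species")


def tukey_contrasts(
    fit: GlmFit,
    adjust: str = "mvn",
    n_draws: int = 100_000,
    seed: int = TUKEY_SEED,
) -> pd.DataFrame:
    """All pairwise species contrasts with multiplicity-adjusted p values.

    Contrasts are differences of estimated marginal means on the link
    scale. ``adjust="mvn"`` uses the single-step multivariate-normal
    adjustment with the equicoordinate probability estimated by seeded
    Monte Carlo (adjusted p is monotone above the raw p by construction);
    ``adjust="bonferroni"`` is the deterministic fallback.
    """
    if adjust not in ("mvn", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    levels, rows = _species_rows(fit)
    if len(levels) < 2:
        raise ValueError("need at least 2 species levels for contrasts")
    pairs = list(itertools.combinations(range(len(levels)), 2))
    L = np.array([rows[i] - rows[j] for i, j in pairs])
    C = L @ fit.cov.values @ L.T
    variances = np.diag(C)
    if np.any(variances <= 0):
        raise FitError("singular contrast covariance")
    estimates = L @ fit.params.values
    se = np.sqrt(variances)
    z = estimates / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    m = len(pairs)
    if adjust == "bonferroni":
        p_adj = np.minimum(1.0, m * p_raw)
        method = "bonferroni"
    else:
        corr = C / np.outer(se, se)
        # sample via eigendecomposition: the contrast space has rank k-1 < m,
        # so the correlation matrix is rank-deficient and Cholesky would fail
        w, v = np.linalg.eigh((corr + corr.T) / 2.0)
        rot = v * np.sqrt(np.clip(w, 0.0, None))
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_draws, m)) @ rot.T
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([np.mean(maxabs >= abs(zj)) for zj in z])
        p_adj = np.minimum(1.0, np.maximum(p_adj, p_raw))
        method = f"mvn(single-step, {n_draws} draws, seed {seed})"
    return pd.DataFrame({
        "contrast": [f"{levels[i]} - {levels[j]}" for i, j in pairs],
        "estimate": estimates,
        "se": se,
        "z": z,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "method": method,
    }).set_index("contrast")
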