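"""Precision-weighted linear modeling of log-CPM with moderated t-statistics.

The mean-variance relationship of log-CPM from counts is estimated by
lowess on (average log-count, sqrt(residual sd)) and converted into
per-observation inverse-variance weights; each gene is then fit by
weighted least squares on a group-means design. Residual variances are
shrunk toward a common prior estimated across genes by fitting a scaled-F
distribution by the method of moments, yielding moderated t-statistics
with augmented degrees of freedom. Multiple testing is controlled per
contrast by the Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
import statsmodels.api as sm

from .design import StudyDesign
from .io import CountMatrix
from .normalization import NormFactors

_SQRT_SD_FLOOR = 1e-4  # keeps weights finite on zero-residual genes


@dataclass
class WeightedLogExpr:
    """log2-CPM matrix with per-observation precision weights."""

    logcpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray  # average log2 count grid of the lowess curve
    trend_y: np.ndarray  # fitted sqrt(residual sd) on that grid
    design: StudyDesign

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValueError("weights must be strictly positive and finite")


@dataclass
class ModelFit:
    """Per-gene weighted group-means fit, optionally eBayes-moderated."""

    coefficients: pd.DataFrame      # genes x groups, log2-CPM scale
    stdev_unscaled: pd.DataFrame    # genes x groups, se per unit sigma
    sigma: pd.Series                # residual sd per gene
    df_residual: float
    amean: pd.Series                # average log2-CPM per gene
    design: StudyDesign
    prior_df: float | None = None
    prior_var: float | None = None
    post_var: pd.Series | None = None

    @property
    def moderated(self) -> bool:
        return self.post_var is not None


def _group_index(design: StudyDesign) -> dict[str, np.ndarray]:
    sids = design.sample_ids
    return {
        g: np.array([sids.index(s) for s in design.samples_in(g)], dtype=int)
        for g in design.groups
    }


def log_cpm(m: CountMatrix, nf: NormFactors | None = None) -> pd.DataFrame:
    """Offset-stabilized log2-CPM: log2((count+0.5)/(eff_lib+1) * 1e6)."""
    lib = (nf.effective_lib_sizes if nf is not None else m.lib_sizes).astype(float)
    lib = lib.reindex(m.sample_ids)
    return np.log2((m.counts + 0.5).div(lib + 1.0, axis=1) * 1e6)


def _fit_groups(
    y: np.ndarray, w: np.ndarray, groups: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted group means per gene; returns (coef, u, sigma, df).

    ``u`` is the squared unscaled standard error 1/sum(w) per group. On a
    group-indicator design, weighted least squares decouples into
    independent weighted means, so this is the exact WLS solution.
    """
    n_genes = y.shape[0]
    n_groups = len(groups)
    coef = np.empty((n_genes, n_groups))
    u = np.empty((n_genes, n_groups))
    rss = np.zeros(n_genes)
    for k, idx in enumerate(groups.values()):
        wk = w[:, idx]
        yk = y[:, idx]
        sw = wk.sum(axis=1)
        mk = (wk * yk).sum(axis=1) / sw
        coef[:, k] = mk
        u[:, k] = 1.0 / sw
        rss += (wk * (yk - mk[:, None]) ** 2).sum(axis=1)
    df = y.shape[1] - n_groups
    if df < 1:
        raise ValueError("no residual degrees of freedom: need n_samples > n_groups")
    sigma = np.sqrt(rss / df)
    return coef, u, sigma, float(df)


def voom_transform(
    m: CountMatrix,
    nf: NormFactors | None = None,
    design: StudyDesign | None = None,
    span: float = 0.5,
) -> WeightedLogExpr:
    """Attach mean-variance precision weights to log-CPM.

    A first unweighted group-means fit supplies residual standard
    deviations; ``sqrt(sd)`` is regressed on average log2-count by lowess
    (span 0.5) and the curve, evaluated at each observation's fitted
    log2-count, is raised to the power -4 to give inverse-variance
    weights.
    """
    design = design or m.design
    for age in design.sgn_age_order:
        if len(design.samples_in(age)) < 2:
            raise ValueError(f"SGN age {age!r} needs >=2 replicates for residual df")
    lib = (nf.effective_lib_sizes if nf is not None else m.lib_sizes).astype(float)
    lib = lib.reindex(m.sample_ids).to_numpy()
    y = log_cpm(m, nf)
    groups = _group_index(design)
    coef, _, sigma, _ = _fit_groups(y.to_numpy(), np.ones(y.shape), groups)

    # average log2 count per gene and sqrt residual sd form the trend
    sx = y.to_numpy().mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = sm.nonparametric.lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]
    # collapse duplicate x for interpolation
    ux, inv = np.unique(lx, return_inverse=True)
    uy = np.bincount(inv, weights=ly) / np.bincount(inv)

    # fitted log2 count per observation
    fitted_logcpm = np.empty(y.shape)
    for k, idx in enumerate(groups.values()):
        fitted_logcpm[:, idx] = coef[:, [k]]
    fitted_logcount = fitted_logcpm + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, ux, uy)
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, _SQRT_SD_FLOOR)
    w = pred_sqrt_sd ** -4.0
    return WeightedLogExpr(
        logcpm=y,
        weights=pd.DataFrame(w, index=y.index, columns=y.columns),
        trend_x=ux,
        trend_y=np.maximum(uy, _SQRT_SD_FLOOR),
        design=design,
    )


def fit_model(w: WeightedLogExpr, design: StudyDesign | None = None) -> ModelFit:
    """Per-gene weighted least squares on the group-means design."""
    design = design or w.design
    groups = _group_index(design)
    coef, u, sigma, df = _fit_groups(
        w.logcpm.to_numpy(), w.weights.to_numpy(), groups
    )
    idx = w.logcpm.index
    return ModelFit(
        coefficients=pd.DataFrame(coef, index=idx, columns=list(groups)),
        stdev_unscaled=pd.DataFrame(np.sqrt(u), index=idx, columns=list(groups)),
        sigma=pd.Series(sigma, index=idx),
        df_residual=df,
        amean=w.logcpm.mean(axis=1),
        design=design,
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma is positive; cannot invert non-positive value")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Returns ``(df2, scale)`` — the prior degrees of freedom d0 and prior
    variance s0^2 such that s^2 ~ s0^2 * F(df1, d0). df2 is ``inf`` when
    the observed spread of log-variances does not exceed what sampling
    alone explains.
    """
    z = np.log(s2)
    ok = np.isfinite(z)
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive variances to fit the prior")
    z = z[ok]
    e = z - digamma(df1 / 2.0) + math.log(df1 / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, df1 / 2.0))
    if evar > 0:
        df2 = 2.0 * trigamma_inverse(evar)
        s0 = math.exp(emean + float(digamma(df2 / 2.0)) - math.log(df2 / 2.0))
    else:
        df2 = math.inf
        s0 = math.exp(emean)
    return df2, s0


def ebayes_moderate(
    fit: ModelFit,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> ModelFit:
    """Shrink residual variances toward an across-gene prior.

    The prior ``(d0, s0^2)`` is estimated by :func:`fit_f_dist` unless
    supplied explicitly (``prior_df=0`` disables shrinkage; ``inf``
    replaces every variance by the prior). The posterior variance is the
    df-weighted blend ``(d0*s0^2 + d*s^2) / (d0 + d)``.
    """
    s2 = fit.sigma.to_numpy() ** 2
    d = fit.df_residual
    if prior_df is None:
        if len(s2) < 10:
            raise ValueError("moment estimation of the prior needs >=10 genes")
        d0, s0 = fit_f_dist(s2, d)
        if math.isinf(d0):
            warnings.warn(
                "all sample variances consistent with a single value; "
                "prior df is infinite and variances are fully shrunk"
            )
    else:
        d0 = prior_df
        s0 = prior_var if prior_var is not None else float(np.median(s2))
    if math.isinf(d0):
        post = np.full_like(s2, s0)
    elif d0 == 0:
        post = s2.copy()
    else:
        post = (d0 * s0 + d * s2) / (d0 + d)
    return ModelFit(
        coefficients=fit.coefficients,
        stdev_unscaled=fit.stdev_unscaled,
        sigma=fit.sigma,
        df_residual=d,
        amean=fit.amean,
        design=fit.design,
        prior_df=d0,
        prior_var=s0,
        post_var=pd.Series(post, index=fit.sigma.index),
    )


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def contrast_name(group_a: str, group_b: str) -> str:
    return f"{group_a}_vs_{group_b}"


def pairwise_contrasts(
    fit: ModelFit,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Moderated t-tests for group differences.

    One row per gene per pair; ``log2FC = coef(A) - coef(B)``; q-values
    are BH-adjusted within each contrast independently. ``pairs=None``
    emits all unordered group pairs.
    """
    if not fit.moderated:
        raise ValueError("run ebayes_moderate before computing contrasts")
    if pairs is None:
        gs = list(fit.design.groups)
        pairs = [(gs[i], gs[j]) for i in range(len(gs)) for j in range(i + 1, len(gs))]
    for a, b in pairs:
        for g in (a, b):
            if g not in fit.coefficients.columns:
                raise ValueError(f"unknown group {g!r} in contrast ({a}, {b})")
    d_total = fit.df_residual + (0.0 if math.isinf(fit.prior_df) else fit.prior_df)
    d_total = min(d_total, 1e6)  # t converges to normal; avoid inf df
    post_sd = np.sqrt(fit.post_var.to_numpy())
    frames = []
    for a, b in pairs:
        diff = (fit.coefficients[a] - fit.coefficients[b]).to_numpy()
        se_unscaled = np.sqrt(
            fit.stdev_unscaled[a].to_numpy() ** 2 + fit.stdev_unscaled[b].to_numpy() ** 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / (se_unscaled * post_sd)
        t = np.where(diff == 0, 0.0, t)
        p = 2.0 * stats.t.sf(np.abs(t), d_total)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": fit.coefficients.index,
                    "contrast": contrast_name(a, b),
                    "group_a": a,
                    "group_b": b,
                    "log2FC": diff,
                    "t": t,
                    "p": p,
                    "q": adjust_bh(p),
                    "mean_expr": fit.amean.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
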