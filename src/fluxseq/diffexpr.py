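"""Negative-binomial GLM differential expression with a fold-change
threshold test.

The model for gene g is counts ~ NB(mu, phi_g) with log link,
log mu = X beta + offset, Var = mu + phi mu^2. Dispersions are estimated
per gene by Cox-Reid adjusted profile likelihood and shrunk toward a
smooth mean-dispersion trend. Significance against a minimum biologically
meaningful effect (default +/-20% fold change, tau = log2 1.2) uses a
TREAT-style composite-null Wald test: for estimate b with standard error
s, p = P(T > (|b|-tau)/s) + P(T > (|b|+tau)/s), where T is a t reference
whose degrees of freedom add the dispersion-shrinkage prior weight to the
residual df (a moderated-t analogue). tau = 0 recovers the ordinary
two-sided Wald test. Multiplicity is controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm, t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import NumericalError, ValidationError
from .types import CONTROL, CountMatrix

LOG2 = np.log(2.0)
PHI_FLOOR = 1e-8
DEFAULT_FC_THRESHOLD = 1.2
DEFAULT_PRIOR_WEIGHT = 10.0


@dataclass
class DEResult:
    """Per-gene statistics for one contrast (treatment vs control within a
    cell line at one time point)."""

    cell_line: str
    treatment: str
    time_h: float
    table: pd.DataFrame  # index gene_id; log2FC, se, p, p_fdr, dispersion, converged

    @property
    def contrast(self) -> tuple[str, str, float]:
        return (self.cell_line, self.treatment, self.time_h)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table.p_fdr < alpha]


# ----------------------------------------------------------- dispersions

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-10)
    if phi < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def _fit_group_means(y, exp_off, group_idx, phi):
    """Per-group NB MLE of the mean on the offset scale (Newton on beta)."""
    mu = np.empty_like(y, dtype=float)
    for idx in group_idx:
        yi, ei = y[idx], exp_off[idx]
        tot = yi.sum()
        if tot == 0:
            mu[idx] = 1e-10
            continue
        beta = np.log(tot / ei.sum())
        for _ in range(25):
            m = np.exp(beta) * ei
            w = 1.0 + phi * m
            score = np.sum((yi - m) / w)
            info = np.sum(m / w)
            step = score / max(info, 1e-12)
            beta += np.clip(step, -5, 5)
            if abs(step) < 1e-10:
                break
        mu[idx] = np.exp(beta) * ei
    return mu


def _apl(phi: float, y, exp_off, group_idx) -> float:
    """Cox-Reid adjusted profile log-likelihood of the dispersion."""
    mu = _fit_group_means(y, exp_off, group_idx, phi)
    ll = _nb_loglik(y, mu, phi)
    adj = 0.0
    for idx in group_idx:
        w = np.sum(mu[idx] / (1.0 + phi * mu[idx]))
        adj += 0.5 * np.log(max(w, 1e-12))
    return ll - adj


def estimate_dispersions(
    cm: CountMatrix,
    groups: list[str] | pd.Series | None = None,
    offsets: pd.DataFrame | None = None,
    prior_weight: float = DEFAULT_PRIOR_WEIGHT,
) -> pd.DataFrame:
    """Per-gene NB dispersion with mean-trend shrinkage.

    ``groups`` assigns each sample to an experimental group (defaults to
    cell_line/treatment/time); each group needs >= 2 replicates. Returns a
    DataFrame with ``dispersion_raw`` (CR-adjusted MLE), ``dispersion_trend``
    (lowess trend on the mean) and ``dispersion`` (log-scale weighted
    average of the two, weight ``prior_weight`` on the trend versus the
    residual df on the raw estimate).
    """
    table = cm.sample_table()
    if groups is None:
        groups = (
            table.cell_line + "/" + table.treatment + "/" + table.time_h.astype(str)
        ).to_list()
    groups = list(groups)
    if len(groups) != len(cm.samples):
        raise ValidationError("groups length does not match samples")
    labels = pd.Series(groups)
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValidationError(f"group {small.index[0]!r} has fewer than 2 replicates")
    group_idx = [np.flatnonzero((labels == g).to_numpy()) for g in sizes.index]
    resid_df = len(groups) - len(group_idx)

    log_off = np.log(cm.library_sizes.to_numpy(dtype=float))
    if offsets is not None:
        log_off = log_off[None, :] + LOG2 * offsets.loc[cm.genes, cm.sample_ids].to_numpy()
    else:
        log_off = np.broadcast_to(log_off, (len(cm.genes), len(groups)))
    counts = cm.counts.to_numpy(dtype=float)

    raw = np.empty(len(cm.genes))
    for g in range(counts.shape[0]):
        y = counts[g]
        exp_off = np.exp(log_off[g] - log_off[g].mean())
        res = minimize_scalar(
            lambda lp: -_apl(np.exp(lp), y, exp_off, group_idx),
            bounds=(np.log(PHI_FLOOR), np.log(50.0)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        raw[g] = max(np.exp(res.x), PHI_FLOOR)

    mean_count = counts.mean(axis=1)
    log_mean = np.log(mean_count + 0.5)
    log_raw = np.log(np.maximum(raw, 1e-6))
    trend = lowess(log_raw, log_mean, frac=0.5, return_sorted=False)
    if np.isnan(trend).any():  # degenerate x spread
        trend = np.full_like(log_raw, log_raw.mean())
    w_raw = float(resid_df)
    shrunk = np.exp((w_raw * log_raw + prior_weight * trend) / (w_raw + prior_weight))
    return pd.DataFrame(
        {
            "dispersion_raw": raw,
            "dispersion_trend": np.maximum(np.exp(trend), PHI_FLOOR),
            "dispersion": np.maximum(shrunk, PHI_FLOOR),
            "mean_count": mean_count,
        },
        index=cm.genes,
    )


# ----------------------------------------------------------------- NB GLM

def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if phi < 1e-10:
        return float(2.0 * np.sum(term1 - (y - mu)))
    return float(
        2.0 * np.sum(term1 - (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu)))
    )


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    phi: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict:
    """IRLS fit of an NB log-linear model with fixed dispersion.

    Returns coefficients on the natural-log scale, their standard errors,
    a convergence flag, the deviance and residual df. phi = 0 is a Poisson
    fit. Raises on a rank-deficient design.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("design matrix is not full rank")
    if offset is None:
        offset = np.zeros(n)
    eta = np.log(np.maximum(y, y.mean() / 6 + 1e-4)) - offset
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    dev = np.inf
    converged = False
    XtWX = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        XtWX = XtW @ X
        try:
            beta_new = np.linalg.solve(XtWX, XtW @ z)
        except np.linalg.LinAlgError:
            break
        beta = beta_new
        mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
        dev_new = nb_deviance(y, mu, phi)
        if abs(dev_new - dev) / (abs(dev_new) + 0.1) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if XtWX is None:
        raise NumericalError("IRLS produced no iterations")
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return {
        "coef": beta,
        "se": se,
        "converged": bool(converged),
        "deviance": float(dev),
        "resid_df": n - p,
    }


# ------------------------------------------------------------- inference

def test_de_threshold(
    log2fc: np.ndarray,
    se: np.ndarray,
    tau_log2: float = float(np.log2(DEFAULT_FC_THRESHOLD)),
    df: float | None = None,
) -> np.ndarray:
    """Composite-null Wald p-value against |log2FC| <= tau.

    p = P(T > (|b|-tau)/s) + P(T > (|b|+tau)/s); T is Student t with
    ``df`` degrees of freedom, or standard normal when df is None/inf.
    """
    if tau_log2 < 0:
        raise ValidationError("tau_log2 must be >= 0")
    log2fc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    if (se <= 0).any() or np.isnan(se).any():
        raise ValidationError("standard errors must be positive")
    sf = norm.sf if df is None or np.isinf(df) else (lambda q: t_dist.sf(q, df))
    b = np.abs(log2fc)
    p = sf((b - tau_log2) / se) + sf((b + tau_log2) / se)
    return np.minimum(p, 1.0)


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(
    cm: CountMatrix,
    cell_line: str,
    treatment: str,
    time_h: float,
    dispersions: pd.DataFrame | pd.Series,
    offsets: pd.DataFrame | None = None,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    prior_weight: float = DEFAULT_PRIOR_WEIGHT,
) -> DEResult:
    """Treatment-vs-control DE for one cell line at one time point.

    Fits an intercept + treatment NB GLM per gene with log-library-size
    (plus optional GC/length) offsets and the supplied shrunken
    dispersions, then applies the fold-change threshold test and BH FDR.
    Genes whose fit does not converge are reported with p = 1.
    """
    if fc_threshold < 1.0:
        raise ValidationError("fc_threshold must be >= 1 (a fold change)")
    table = cm.sample_table()
    mask = (
        (table.cell_line == cell_line)
        & (table.time_h == time_h)
        & table.treatment.isin([CONTROL, treatment])
    )
    ids = list(table.index[mask])
    if not ids:
        raise ValidationError(f"no samples for {cell_line}/{treatment}/{time_h}h")
    sub = cm.subset_samples(ids)
    treated = (sub.sample_table().treatment == treatment).to_numpy(dtype=float)
    if treated.sum() < 2 or (1 - treated).sum() < 2:
        raise ValidationError(
            f"contrast {cell_line}/{treatment}/{time_h}h needs >=2 replicates per group"
        )
    X = np.column_stack([np.ones_like(treated), treated])

    if isinstance(dispersions, pd.DataFrame):
        phi = dispersions["dispersion"]
    else:
        phi = dispersions
    phi = phi.reindex(sub.genes)
    if phi.isna().any():
        raise ValidationError("dispersions missing for some genes")

    log_off = np.log(sub.library_sizes.to_numpy(dtype=float))
    off_mat = np.broadcast_to(log_off, (len(sub.genes), len(ids))).copy()
    if offsets is not None:
        off_mat += LOG2 * offsets.loc[sub.genes, sub.sample_ids].to_numpy()

    counts = sub.counts.to_numpy(dtype=float)
    n_genes = counts.shape[0]
    log2fc = np.zeros(n_genes)
    se = np.full(n_genes, np.nan)
    converged = np.zeros(n_genes, dtype=bool)
    resid_df = X.shape[0] - X.shape[1]
    for g in range(n_genes):
        y = counts[g]
        if y.sum() == 0:
            continue
        fit = fit_nb_glm(y, X, offset=off_mat[g], phi=float(phi.iloc[g]))
        log2fc[g] = fit["coef"][1] / LOG2
        se[g] = fit["se"][1] / LOG2
        converged[g] = fit["converged"] and np.isfinite(fit["se"][1]) and fit["se"][1] > 0

    tau = float(np.log2(fc_threshold))
    p = np.ones(n_genes)
    ok = converged
    if ok.any():
        p[ok] = test_de_threshold(log2fc[ok], se[ok], tau, df=resid_df + prior_weight)
    out = pd.DataFrame(
        {
            "log2FC": log2fc,
            "se": se,
            "p": p,
            "p_fdr": adjust_bh(p),
            "dispersion": phi.to_numpy(),
            "converged": converged,
        },
        index=sub.genes,
    )
    out.index.name = "gene_id"
    return DEResult(cell_line, treatment, time_h, out)
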