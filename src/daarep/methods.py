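"""Elementary differential abundance methods with a uniform result record.

Each ``run_*`` function returns one row per taxon with columns

    estimate, se, ci_low, ci_high, direction, p, q, status

where ``estimate`` is on the method's own scale (log odds ratio for the
ordinal and logistic models, log fold-change of relative abundance for the
log-linear model), ``direction`` is the sign of the estimate (positive =
more abundant in the case group), ``p`` is the unadjusted P-value and ``q``
its Benjamini–Hochberg FDR adjustment.  ``status`` is ``ok``, ``degenerate``
(no information in the taxon, reported with p = 1) or ``failed``
(non-convergence; excluded from downstream significance calls).

Methods:

- ``orm``        — ordinal (proportional odds) regression on TSS proportions;
                   with no covariates its P-values essentially coincide with
                   the two-sided Wilcoxon rank-sum test.
- ``logtss-lm``  — linear model on log-transformed TSS proportions; with no
                   covariates this is the pooled two-sample t-test.
- ``logr``       — logistic regression on presence/absence of the taxon.
- ``nb-glm``     — naive negative-binomial GLM on raw counts with a
                   log-library-size offset; included as a consistency foil,
                   not as a recommended method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .datasets import CountDataset, DataError
from .ordinal import fit_proportional_odds
from .preprocess import binarize, log_transform, tss_normalize

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["estimate", "se", "ci_low", "ci_high", "direction", "p", "q", "status"]

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_FAILED = "failed"


def adjust_fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns adjusted values capped at 1, monotone in the input ranks and
    never smaller than the input elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise DataError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design(dataset: CountDataset, covariate_names, intercept: bool) -> np.ndarray:
    """Design matrix with the group indicator (case = 1) in the first
    modelled column, followed by the requested covariates."""
    cols = [dataset.case_mask().astype(float)]
    for name in covariate_names:
        if name not in dataset.metadata.columns:
            raise DataError(f"covariate {name!r} not found in metadata")
        col = dataset.metadata[name]
        if not np.issubdtype(col.dtype, np.number):
            col = pd.Categorical(col).codes.astype(float)
        cols.append(np.asarray(col, dtype=float))
    X = np.column_stack(cols)
    if intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    return X


def _empty_results(taxon_ids: pd.Index) -> pd.DataFrame:
    out = pd.DataFrame(
        index=pd.Index(taxon_ids, name="taxon_id"), columns=RESULT_COLUMNS, dtype=object
    )
    for c in RESULT_COLUMNS[:-1]:
        out[c] = np.nan
    out["status"] = STATUS_OK
    return out


def _finalize(out: pd.DataFrame) -> pd.DataFrame:
    """Set directions, attach BH q-values, coerce dtypes."""
    for c in RESULT_COLUMNS[:-1]:
        out[c] = pd.to_numeric(out[c])
    ok = out["status"] == STATUS_OK
    est = out.loc[ok, "estimate"]
    # estimates at numerical zero are ties: direction 0, never replicated/conflicting
    out.loc[ok, "direction"] = np.where(np.abs(est) < 1e-12, 0.0, np.sign(est))
    out.loc[out["status"] == STATUS_DEGENERATE, "direction"] = 0
    usable = out["status"] != STATUS_FAILED
    if usable.any():
        out.loc[usable, "q"] = adjust_fdr_bh(out.loc[usable, "p"].to_numpy())
    n_failed = int((~usable).sum())
    if n_failed:
        logger.warning("%d taxa failed to fit and are excluded downstream", n_failed)
    return out


def _wald(estimate: float, se: float, ci_level: float) -> tuple[float, float, float]:
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(estimate) / se)
    else:
        p = 1.0 if estimate == 0 else 0.0
    return p, estimate - z * se, estimate + z * se


def run_orm(
    dataset: CountDataset,
    covariate_names=(),
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Proportional-odds (ordinal) regression per taxon on TSS proportions.

    The distinct proportion values of a taxon form the ordered response
    categories (ties share a category); the reported estimate is the group
    log odds ratio with Wald inference.
    """
    relab = tss_normalize(dataset).to_numpy()
    X = _design(dataset, covariate_names, intercept=False)
    out = _empty_results(dataset.taxon_ids)
    est = np.full(len(out), np.nan)
    se = np.full(len(out), np.nan)
    pvals = np.full(len(out), np.nan)
    status = np.full(len(out), STATUS_OK, dtype=object)
    for i in range(relab.shape[0]):
        y = relab[i]
        if np.all(y == y[0]):
            est[i], se[i], pvals[i] = 0.0, np.nan, 1.0
            status[i] = STATUS_DEGENERATE
            continue
        fit = fit_proportional_odds(y, X)
        if not fit.converged:
            status[i] = STATUS_FAILED
            continue
        est[i], se[i] = fit.beta[0], fit.se[0]
        pvals[i] = 2.0 * stats.norm.sf(abs(est[i]) / se[i]) if se[i] > 0 else np.nan
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    out["estimate"], out["se"], out["p"] = est, se, pvals
    out["ci_low"], out["ci_high"] = est - z * se, est + z * se
    out["status"] = status
    return _finalize(out)


def run_linear_logtss(
    dataset: CountDataset,
    covariate_names=(),
    ci_level: float = 0.95,
    pseudo_policy: str = "half-min-nonzero",
) -> pd.DataFrame:
    """OLS of log-transformed TSS proportions on group (+ covariates).

    With no covariates the group coefficient equals the difference of group
    means of the log values and the P-value equals the pooled-variance
    two-sample t-test.  The estimate is a log fold-change of relative
    abundance (geometric-mean scale).
    """
    Y = log_transform(tss_normalize(dataset), pseudo_policy=pseudo_policy).to_numpy().T
    X = _design(dataset, covariate_names, intercept=True)
    n, k = X.shape
    out = _empty_results(dataset.taxon_ids)
    dof = n - k
    if dof <= 0:
        out["status"] = STATUS_FAILED
        logger.warning("zero residual degrees of freedom (n=%d, k=%d)", n, k)
        return _finalize(out)
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y  # (k, T)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / dof
    est = B[1]  # group coefficient (column 0 is the intercept)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = est / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    tq = stats.t.ppf(0.5 + ci_level / 2.0, dof)
    out["estimate"], out["se"], out["p"] = est, se, p
    out["ci_low"], out["ci_high"] = est - tq * se, est + tq * se
    degen = (se < 1e-12) & (np.abs(est) < 1e-12)
    out.loc[degen, ["estimate", "p"]] = [0.0, 1.0]
    out.loc[degen, "status"] = STATUS_DEGENERATE
    return _finalize(out)


def _batched_logistic(Y: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Newton/IRLS logistic fits for many responses sharing one design.

    ``Y`` is (T, n) in {0,1}, ``X`` is (n, k) including the intercept.
    Returns (beta (T,k), se (T,k), converged (T,)).
    """
    T, n = Y.shape
    k = X.shape[1]
    beta = np.zeros((T, k))
    pbar = np.clip(Y.mean(axis=1), 1e-6, 1 - 1e-6)
    beta[:, 0] = np.log(pbar / (1 - pbar))
    active = np.ones(T, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(beta[active] @ X.T, -30, 30)  # (Ta, n)
        mu = expit(eta)
        score = (Y[active] - mu) @ X  # (Ta, k)
        W = np.clip(mu * (1 - mu), 1e-10, None)
        info = np.einsum("tn,nj,nl->tjl", W, X, X)
        step = np.linalg.solve(info, score[..., None])[..., 0]
        beta[active] = beta[active] + step
        done = np.max(np.abs(score), axis=1) < tol
        idx = np.where(active)[0]
        active[idx[done]] = False
    converged = ~active
    eta = np.clip(beta @ X.T, -30, 30)
    mu = expit(eta)
    W = np.clip(mu * (1 - mu), 1e-10, None)
    info = np.einsum("tn,nj,nl->tjl", W, X, X)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0, None))
    return beta, se, converged


def run_logr(
    dataset: CountDataset,
    covariate_names=(),
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Logistic regression of taxon presence/absence on group (+ covariates).

    The estimate is the group log odds ratio of presence with Wald inference.
    Taxa whose presence does not vary, or for which a group has 0% or 100%
    presence (exact separation of the group term), are reported degenerate.
    """
    Y = binarize(dataset).to_numpy().astype(float)
    X = _design(dataset, covariate_names, intercept=True)
    case = dataset.case_mask()
    out = _empty_results(dataset.taxon_ids)

    prev_case = Y[:, case].mean(axis=1)
    prev_ctrl = Y[:, ~case].mean(axis=1)
    degen = (
        np.isin(prev_case, (0.0, 1.0)) | np.isin(prev_ctrl, (0.0, 1.0))
    )
    fit_idx = np.where(~degen)[0]
    est = np.zeros(len(out))
    se = np.full(len(out), np.nan)
    p = np.ones(len(out))
    status = np.where(degen, STATUS_DEGENERATE, STATUS_OK).astype(object)
    if len(fit_idx):
        beta, bse, conv = _batched_logistic(Y[fit_idx], X)
        est[fit_idx] = beta[:, 1]
        se[fit_idx] = bse[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            p[fit_idx] = 2.0 * stats.norm.sf(np.abs(beta[:, 1]) / bse[:, 1])
        status[fit_idx[~conv]] = STATUS_FAILED
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    out["estimate"], out["se"], out["p"] = est, se, p
    out["ci_low"], out["ci_high"] = est - z * se, est + z * se
    out.loc[degen, ["ci_low", "ci_high"]] = np.nan
    out.loc[degen, "estimate"] = 0.0
    out["status"] = status
    return _finalize(out)


def run_nb_glm(
    dataset: CountDataset,
    covariate_names=(),
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Naive negative-binomial regression of raw counts on group.

    Uses a log library-size offset; dispersion estimated per taxon by
    maximum likelihood.  Included as a documented inconsistency foil — its
    unadjusted P-values are known to be anti-conservative on null
    microbiome-like data.
    """
    from statsmodels.discrete.discrete_model import NegativeBinomial

    X = _design(dataset, covariate_names, intercept=True)
    offset = np.log(dataset.library_sizes.to_numpy().astype(float))
    counts = dataset.counts.to_numpy()
    out = _empty_results(dataset.taxon_ids)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    for i, taxon in enumerate(out.index):
        y = counts[i]
        if np.all(y == 0):
            out.loc[taxon, ["estimate", "p", "status"]] = [0.0, 1.0, STATUS_DEGENERATE]
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = NegativeBinomial(y, X, offset=offset).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False):
                raise RuntimeError("no convergence")
            est, bse = res.params[1], res.bse[1]
            if not np.isfinite(est) or not np.isfinite(bse) or bse <= 0:
                raise RuntimeError("non-finite estimate")
        except Exception:
            out.loc[taxon, "status"] = STATUS_FAILED
            continue
        out.loc[taxon, ["estimate", "se", "p"]] = [est, bse, 2.0 * stats.norm.sf(abs(est) / bse)]
        out.loc[taxon, ["ci_low", "ci_high"]] = [est - z * bse, est + z * bse]
    return _finalize(out)


# ---------------------------------------------------------------------------
# method registry and dispatch


@dataclass(frozen=True)
class MethodSpec:
    """Declarative description of a DAA method."""

    name: str
    input_representation: str  # relative_abundance | log_relative_abundance | presence_absence | raw_counts
    supports_covariates: bool
    provides_ci: bool
    runner: Callable | None = None


REGISTRY: dict[str, MethodSpec] = {
    "orm": MethodSpec("orm", "relative_abundance", True, True, run_orm),
    "logtss-lm": MethodSpec("logtss-lm", "log_relative_abundance", True, True, run_linear_logtss),
    "logr": MethodSpec("logr", "presence_absence", True, True, run_logr),
    "nb-glm": MethodSpec("nb-glm", "raw_counts", True, True, run_nb_glm),
}

ELEMENTARY_METHODS = ("orm", "logtss-lm", "logr")


def read_external_results(path, preadjusted: bool = False) -> pd.DataFrame:
    """Load a third-party method's per-taxon results from a TSV table.

    Required columns: ``taxon_id``, ``estimate``, ``p``; optional ``se``,
    ``ci_low``, ``ci_high``, ``q``.  Unless ``preadjusted`` (the method
    carries its own multiplicity adjustment), q-values are recomputed by BH.
    """
    table = pd.read_csv(path, sep="\t")
    for col in ("taxon_id", "estimate", "p"):
        if col not in table.columns:
            raise DataError(f"external result table {path} lacks required column {col!r}")
    table = table.set_index("taxon_id")
    out = _empty_results(table.index)
    out["estimate"] = table["estimate"]
    out["p"] = table["p"]
    for col in ("se", "ci_low", "ci_high"):
        if col in table.columns:
            out[col] = table[col]
    if preadjusted:
        if "q" not in table.columns:
            raise DataError("preadjusted external table must carry a 'q' column")
        out["q"] = table["q"]
        for c in RESULT_COLUMNS[:-1]:
            out[c] = pd.to_numeric(out[c])
        out["direction"] = np.sign(out["estimate"])
        return out
    return _finalize(out)


def run_method(
    method: str | MethodSpec,
    dataset: CountDataset,
    covariate_names=(),
    ci_level: float = 0.95,
    external_path=None,
    external_preadjusted: bool = False,
) -> pd.DataFrame:
    """Dispatch a registered method (or load an external result table)."""
    if external_path is not None:
        return read_external_results(external_path, preadjusted=external_preadjusted)
    if isinstance(method, MethodSpec):
        spec = method
    else:
        if method not in REGISTRY:
            raise KeyError(f"unknown method {method!r}; registered: {sorted(REGISTRY)}")
        spec = REGISTRY[method]
    if spec.runner is None:
        raise DataError(f"method {spec.name!r} has no runner and no external table was given")
    return spec.runner(dataset, covariate_names=covariate_names, ci_level=ci_level)
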