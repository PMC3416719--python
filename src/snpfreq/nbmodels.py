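"""Negative-binomial regression of per-contig SNP counts with AIC selection.

The response (a contig's SNP, transition, or transversion count) is modelled
as NB2: y_i ~ NegBin(mu_i, alpha) with log mu_i = beta . x_i and variance
mu_i + alpha * mu_i^2.  Four candidate mean structures are compared; every
candidate carries an intercept and the coding-class indicator (C/NC):

    M1  intercept + LENGTH + DEPTH + C/NC   (the full model)
    M2  intercept + DEPTH + C/NC
    M3  intercept + LENGTH + C/NC           (the "SNPs/kb" surrogate)
    M4  intercept + C/NC

Candidates are ranked by AIC = -2 logL + 2k, where k counts the regression
coefficients plus the jointly estimated dispersion alpha.  Relative support
is expressed as Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)
(computed in log space so weights survive delta ~ 1500 without underflow) and
as evidence ratios w_i / w_j.  The fitted model predicts the standardized SNP
frequency: the expected count at a reference contig length and depth, the
depth-aware replacement for SNPs-per-kb.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "FitResult",
    "SelectionRow",
    "SelectionTable",
    "Prediction",
    "RESPONSES",
    "COVARIATE_COLUMNS",
    "candidate_specs",
    "fit_nb",
    "akaike_weights",
    "model_selection",
    "evidence_ratio",
    "predict_count",
    "run_full_selection",
    "FitError",
]

RESPONSES = ("snp", "ti", "tv")
_RESPONSE_COLUMN = {"snp": "n_snp", "ti": "n_ti", "tv": "n_tv"}
COVARIATE_COLUMNS = {"length": "length", "depth": "depth", "cnc": "cnc"}

ALPHA_FLOOR = 1e-8  # dispersion at/below this is a Poisson-limit fit
_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class FitError(RuntimeError):
    """A negative-binomial fit failed; the message carries diagnostics."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate mean structure: a response and its covariates.

    The intercept is implicit and the coding indicator ``cnc`` is part of
    every candidate.
    """

    name: str
    response: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}, "
                             f"got {self.response!r}")
        unknown = [c for c in self.covariates if c not in COVARIATE_COLUMNS]
        if unknown:
            raise ValueError(f"unknown covariates {unknown}")
        if "cnc" not in self.covariates:
            raise ValueError("every candidate model includes the coding "
                             "indicator 'cnc'")

    @property
    def response_column(self) -> str:
        return _RESPONSE_COLUMN[self.response]


def candidate_specs(response: str) -> list[ModelSpec]:
    """The four candidate models for a response, full model first."""
    return [
        ModelSpec("M1", response, ("length", "depth", "cnc")),
        ModelSpec("M2", response, ("depth", "cnc")),
        ModelSpec("M3", response, ("length", "cnc")),
        ModelSpec("M4", response, ("cnc",)),
    ]


@dataclass(frozen=True)
class FitResult:
    """A converged NB2 maximum-likelihood fit.

    ``beta`` maps coefficient names (``intercept`` plus covariates) to
    estimates on the log-link scale.  ``cov`` is the coefficient covariance
    (excluding alpha) when available; confidence limits are Wald,
    estimate +- 1.96 se.
    """

    spec: ModelSpec
    beta: dict[str, float]
    se: dict[str, float] | None
    ci95: dict[str, tuple[float, float]] | None
    wald_p: dict[str, float] | None
    alpha: float
    loglik: float
    aic: float
    n: int
    cov: np.ndarray | None = None
    data_hash: str | None = None
    poisson_limit: bool = False  # alpha hit the floor: effectively Poisson

    @property
    def k(self) -> int:
        """Parameter count entering AIC: coefficients plus the dispersion."""
        return len(self.beta) + 1


def _design(records: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = ["intercept"] + list(spec.covariates)
    X = np.column_stack(
        [np.ones(len(records))]
        + [records[COVARIATE_COLUMNS[c]].to_numpy(dtype=float)
           for c in spec.covariates])
    y = records[spec.response_column].to_numpy()
    return X, y, names


def _records_hash(records: pd.DataFrame, response_column: str) -> str:
    h = hashlib.sha256()
    for col in ["length", "depth", "cnc", response_column]:
        h.update(np.ascontiguousarray(
            records[col].to_numpy(dtype=float)).tobytes())
    return h.hexdigest()[:16]


def fit_nb(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood NB2 fit of one candidate model.

    Raises :class:`FitError` on non-convergence (with the optimizer trace) and
    :class:`ValueError` on degenerate input (too few records, non-integer or
    all-zero response).
    """
    import statsmodels.api as sm

    X, y, names = _design(records, spec)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError(f"{spec.name}/{spec.response}: response must be "
                         f"nonnegative integer counts")
    y = y.astype(int)
    if len(records) <= X.shape[1] + 1:
        raise ValueError(f"{spec.name}/{spec.response}: need more records "
                         f"({len(records)}) than parameters ({X.shape[1] + 1})")
    if y.sum() == 0:
        raise ValueError(f"{spec.name}/{spec.response}: response is all zero; "
                         f"an NB2 (or even Poisson) rate cannot be estimated")

    import warnings

    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    # Poisson fit seeds the mean structure; helps the joint (beta, alpha) search
    start = np.append(sm.Poisson(y, X).fit(disp=0).params, 0.1)
    res = None
    trace: list[str] = []
    for method, maxiter in (("bfgs", 500), ("nm", 5000)):
        try:
            # convergence is verified below via mle_retvals; the line search
            # visits extreme parameters, so optimizer noise is silenced here
            with warnings.catch_warnings(), \
                    np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                warnings.simplefilter("ignore")
                cand = model.fit(start_params=start, method=method,
                                 maxiter=maxiter, disp=0)
            converged = bool(cand.mle_retvals.get("converged", False))
            trace.append(f"{method}: llf={cand.llf:.6f} converged={converged}")
            if converged:
                res = cand
                break
            if res is None or cand.llf > res.llf:
                res = cand
            start = cand.params  # warm-restart the next optimizer
        except Exception as exc:  # singular hessian etc.
            trace.append(f"{method}: {exc!r}")
    if res is None:
        raise FitError(f"{spec.name}/{spec.response}: NB2 fit failed; "
                       f"trace: {'; '.join(trace)}")
    if not res.mle_retvals.get("converged", False):
        raise FitError(f"{spec.name}/{spec.response}: NB2 fit did not "
                       f"converge; trace: {'; '.join(trace)}")

    params = np.asarray(res.params, dtype=float)
    beta = dict(zip(names, params[:-1]))
    alpha = float(params[-1])
    poisson_limit = alpha <= ALPHA_FLOOR
    alpha = max(alpha, ALPHA_FLOOR)

    try:
        # near the Poisson limit the hessian in alpha can be singular
        se_arr = np.asarray(res.bse, dtype=float)[:len(names)]
        cov = np.asarray(res.cov_params(), dtype=float)[:len(names), :len(names)]
    except (ValueError, np.linalg.LinAlgError):
        se_arr = np.full(len(names), np.nan)
        cov = None
    if not np.all(np.isfinite(se_arr)):
        se = ci95 = wald_p = None
        cov = None
    else:
        se = dict(zip(names, se_arr))
        ci95 = {nm: (beta[nm] - _Z95 * se[nm], beta[nm] + _Z95 * se[nm])
                for nm in names}
        wald_p = {nm: float(2 * norm.sf(abs(beta[nm] / se[nm])))
                  if se[nm] > 0 else float("nan") for nm in names}

    k = len(names) + 1  # alpha is an estimated parameter
    return FitResult(spec=spec, beta=beta, se=se, ci95=ci95, wald_p=wald_p,
                     alpha=alpha, loglik=float(res.llf),
                     aic=float(-2.0 * res.llf + 2.0 * k), n=len(records),
                     cov=cov, data_hash=_records_hash(records, spec.response_column),
                     poisson_limit=poisson_limit)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def akaike_weights(delta_aic: Sequence[float]) -> np.ndarray:
    """Akaike weights from AIC differences, stable for deltas up to ~1500.

    w_i = exp(-delta_i/2) normalised over candidates; computed in log space
    so a delta of 465 yields ~1e-101 rather than underflowing to zero.
    """
    d = np.asarray(delta_aic, dtype=float)
    if d.size == 0:
        raise ValueError("no AIC differences supplied")
    logw = -d / 2.0
    return np.exp(logw - logsumexp(logw))


@dataclass(frozen=True)
class SelectionRow:
    model: str
    covariates: tuple[str, ...]
    k: int
    aic: float
    delta_aic: float
    weight: float


@dataclass(frozen=True)
class SelectionTable:
    """AIC ranking of candidate fits, best (delta = 0) first."""

    response: str
    rows: tuple[SelectionRow, ...]

    def weight(self, model: str) -> float:
        for row in self.rows:
            if row.model == model:
                return row.weight
        raise KeyError(f"no candidate named {model!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model": r.model, "covariates": "+".join(r.covariates), "k": r.k,
            "aic": r.aic, "delta_aic": r.delta_aic, "weight": r.weight,
        } for r in self.rows])


def model_selection(fits: Sequence[FitResult]) -> SelectionTable:
    """Rank candidate fits of one response on one dataset by AIC."""
    if len(fits) < 1:
        raise ValueError("no fits supplied")
    responses = {f.spec.response for f in fits}
    if len(responses) != 1:
        raise ValueError(f"fits mix responses: {sorted(responses)}")
    hashes = {f.data_hash for f in fits}
    ns = {f.n for f in fits}
    if len(hashes) != 1 or len(ns) != 1:
        raise ValueError("fits were made on differing data (hash/n mismatch)")

    aics = np.array([f.aic for f in fits])
    deltas = aics - aics.min()
    weights = akaike_weights(deltas)
    order = np.argsort(aics, kind="stable")
    rows = tuple(
        SelectionRow(model=fits[i].spec.name,
                     covariates=fits[i].spec.covariates, k=fits[i].k,
                     aic=float(aics[i]), delta_aic=float(deltas[i]),
                     weight=float(weights[i]))
        for i in order)
    return SelectionTable(response=responses.pop(), rows=rows)


def evidence_ratio(w_i: float, w_j: float) -> float:
    """How many times better supported model i is than model j: w_i / w_j.

    A zero denominator returns ``inf`` (an underflowed weight, not an error).
    """
    if w_j < 0 or w_i < 0:
        raise ValueError("Akaike weights cannot be negative")
    if w_j == 0.0:
        return float("inf")
    return w_i / w_j


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prediction:
    """Expected count with a delta-method Wald 95% interval on the mean."""

    mean: float
    ci95: tuple[float, float] | None


def predict_count(fit: FitResult, *, length: float | None = None,
                  depth: float | None = None, cnc: int | None = None,
                  ) -> Prediction:
    """Standardized SNP frequency: expected count at the given covariates.

    Every covariate of the fitted model must be supplied; the interval is
    exp(beta.x +- 1.96 sqrt(x' Sigma x)) when the coefficient covariance is
    available, else ``None``.
    """
    supplied = {"length": length, "depth": depth, "cnc": cnc}
    x = [1.0]
    for c in fit.spec.covariates:
        if supplied[c] is None:
            raise ValueError(f"model {fit.spec.name} requires covariate {c!r}")
        x.append(float(supplied[c]))
    x = np.asarray(x)
    eta = float(np.dot(list(fit.beta.values()), x))
    mean = float(np.exp(eta))
    ci = None
    if fit.cov is not None:
        half = _Z95 * float(np.sqrt(x @ fit.cov @ x))
        ci = (float(np.exp(eta - half)), float(np.exp(eta + half)))
    return Prediction(mean=mean, ci95=ci)


def published_fit(beta: Mapping[str, float], response: str = "snp",
                  name: str = "M1") -> FitResult:
    """Wrap externally reported full-model coefficients for prediction.

    ``beta`` maps intercept/length/depth/cnc to log-link estimates; no
    covariance, likelihood or dispersion accompanies such a table, so the
    result supports :func:`predict_count` point estimates only.
    """
    covs = tuple(c for c in ("length", "depth", "cnc") if c in beta)
    spec = ModelSpec(name, response, covs)
    ordered = {"intercept": float(beta["intercept"])}
    ordered.update({c: float(beta[c]) for c in covs})
    return FitResult(spec=spec, beta=ordered, se=None, ci95=None, wald_p=None,
                     alpha=float("nan"), loglik=float("nan"),
                     aic=float("nan"), n=0)


# ---------------------------------------------------------------------------
# full selection across responses
# ---------------------------------------------------------------------------

def run_full_selection(records: pd.DataFrame,
                       responses: Iterable[str] = RESPONSES,
                       ) -> dict[str, tuple[SelectionTable, FitResult, list[FitResult]]]:
    """Fit all four candidates for each response and rank them.

    Returns, per response, the selection table, the best fit, and all four
    fits.  Fit failures are re-raised annotated with (response, model).
    """
    out: dict[str, tuple[SelectionTable, FitResult, list[FitResult]]] = {}
    for response in responses:
        fits = []
        for spec in candidate_specs(response):
            try:
                fits.append(fit_nb(records, spec))
            except (ValueError, FitError) as exc:
                raise type(exc)(
                    f"[response={response}, model={spec.name}] {exc}") from exc
        table = model_selection(fits)
        best = next(f for f in fits if f.spec.name == table.rows[0].model)
        out[response] = (table, best, fits)
    return out
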