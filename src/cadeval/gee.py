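"""Generalized estimating equations for with/without-CAD performance ratios.

The estimand is a ratio of proportions: for a binary "correct" outcome y
on clustered reads, the marginal mean model is ``log mu = b0 + b1*arm``
(arm 0 = without CAD, 1 = with CAD), so ``exp(b1)`` is the with-CAD to
without-CAD ratio of the metric.  Estimation solves the estimating
equations

    sum_i  D_i' V_i^{-1} (y_i - mu_i) = 0

by iteratively reweighted scoring, where ``D_i = d mu_i / d beta``,
``V_i = A_i^{1/2} R(alpha) A_i^{1/2}`` with the binary variance
``A_i = diag(mu(1-mu))`` and a working correlation R that is either
independence or exchangeable.  The exchangeable alpha is the usual moment
estimator of standardized-residual cross-products (same degrees-of-freedom
conventions as statsmodels, which the test suite uses as an independent
cross-check).  Inference uses the robust sandwich covariance
``A^{-1} B A^{-1}``, which stays valid when the working correlation is
misspecified.  Significance is judged two-sided at the 5% level; the
95% Wald interval is ``exp(b1 -/+ 1.959964 se)``.

Clusters default to readers: each reader contributes many correlated case
outcomes in both arms, and the paired re-read of each case by the same
reader is absorbed into the reader cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .classify import CaseOutcome

__all__ = [
    "OutcomeRecord",
    "GeeSpec",
    "GeeFit",
    "SeparationError",
    "build_outcome_records",
    "fit_gee",
    "fit_gee_arrays",
    "ratio_ci",
    "format_p",
]

Z975 = 1.959964  # two-sided 95% normal quantile


class SeparationError(ValueError):
    """An arm's outcomes are all 0 or all 1; the log-link fit is degenerate."""


@dataclass(frozen=True)
class OutcomeRecord:
    """One binary outcome: was this reader-arm-case read correct?"""

    reader_id: str
    image_id: str
    arm: int
    y: int

    def __post_init__(self) -> None:
        if self.arm not in (0, 1):
            raise ValueError("arm must be 0 (without CAD) or 1 (with CAD)")
        if self.y not in (0, 1):
            raise ValueError("y must be binary")


@dataclass(frozen=True)
class GeeSpec:
    """Estimation options.  Link is log and the variance is binary, fixed."""

    working_correlation: Literal["independence", "exchangeable"] = "exchangeable"
    cluster_by: Literal["reader", "reader_image"] = "reader"
    max_iterations: int = 100
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.working_correlation not in ("independence", "exchangeable"):
            raise ValueError(f"unknown correlation {self.working_correlation!r}")
        if self.cluster_by not in ("reader", "reader_image"):
            raise ValueError(f"unknown clustering {self.cluster_by!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class GeeFit:
    """A fitted log-link marginal model for a two-arm comparison."""

    beta0: float
    beta1: float
    robust_cov: np.ndarray
    ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    converged: bool
    n_clusters: int
    alpha_hat: Optional[float] = None

    @property
    def se_log_ratio(self) -> float:
        return float(np.sqrt(self.robust_cov[1, 1]))


# ---------------------------------------------------------------------------
# record construction

_POSITIVE_CALL = {"TP": True, "FP": True, "TN": False}


def _called_positive(outcome: CaseOutcome) -> bool:
    if outcome.state in _POSITIVE_CALL:
        return _POSITIVE_CALL[outcome.state]
    # FN: positive call iff the reader drew (non-matching) boxes
    return outcome.fp_lesion_count > 0


def build_outcome_records(
    outcomes: Mapping[tuple[str, str], Sequence[CaseOutcome]],
    metric: str,
) -> list[OutcomeRecord]:
    """Binary outcome records for one metric.

    ``outcomes`` maps ``(reader_id, arm_label)`` with arm labels
    ``pre_cad``/``post_cad`` to case outcomes.  Subsets and coding:

    * sensitivity — malignant cases; y = 1 iff TP
    * specificity — normal cases; y = 1 iff TN
    * accuracy — all cases; y = 1 iff TP or TN
    * ppv — cases the reader called positive in that arm; y = 1 iff TP
    * npv — cases called negative in that arm; y = 1 iff TN

    The PPV/NPV subsets are arm-dependent by construction (the set of
    positive calls changes when readers revise with the CAD).
    """
    arm_code = {"pre_cad": 0, "post_cad": 1}
    records: list[OutcomeRecord] = []
    for (reader_id, arm_label), outs in sorted(outcomes.items()):
        if arm_label not in arm_code:
            raise ValueError(f"unknown arm label {arm_label!r}")
        arm = arm_code[arm_label]
        for o in outs:
            if metric == "sensitivity":
                if o.state not in ("TP", "FN"):
                    continue
                y = int(o.state == "TP")
            elif metric == "specificity":
                if o.state not in ("TN", "FP"):
                    continue
                y = int(o.state == "TN")
            elif metric == "accuracy":
                y = int(o.state in ("TP", "TN"))
            elif metric == "ppv":
                if not _called_positive(o):
                    continue
                y = int(o.state == "TP")
            elif metric == "npv":
                if _called_positive(o):
                    continue
                y = int(o.state == "TN")
            else:
                raise ValueError(f"unknown metric {metric!r}")
            records.append(OutcomeRecord(reader_id, o.image_id, arm, y))
    for arm_label, arm in arm_code.items():
        if not any(r.arm == arm for r in records):
            raise ValueError(f"metric {metric!r}: empty subset in arm {arm_label}")
    return records


# ---------------------------------------------------------------------------
# fitting

def _exchangeable_alpha(
    resid: np.ndarray, cluster_slices: list[slice], p: int
) -> float:
    """Moment estimator of the exchangeable correlation.

    Pearson-residual cross-products, with ``p`` (the number of mean
    parameters) subtracted from both the scale and pair-count denominators
    — the same conventions as statsmodels' Exchangeable structure.
    """
    n = resid.size
    scale = float(resid @ resid) / (n - p)
    num = 0.0
    n_pairs = 0.0
    for sl in cluster_slices:
        e = resid[sl]
        num += (e.sum() ** 2 - float(e @ e)) / 2.0
        n_pairs += 0.5 * e.size * (e.size - 1)
    if n_pairs <= p or scale <= 0:
        return 0.0
    return num / scale / (n_pairs - p)


def _solve_exchangeable(
    rhs: np.ndarray, sd: np.ndarray, alpha: float
) -> np.ndarray:
    """Return V^{-1} rhs for V = S ((1-a)I + a J) S with S = diag(sd)."""
    k = sd.size
    x1 = rhs / sd[:, None] if rhs.ndim == 2 else rhs / sd
    c = alpha / (1.0 - alpha) / (1.0 + alpha * (k - 1))
    if rhs.ndim == 2:
        y = x1 / (1.0 - alpha) - c * x1.sum(axis=0)
    else:
        y = x1 / (1.0 - alpha) - c * x1.sum()
    return y / sd[:, None] if rhs.ndim == 2 else y / sd


def fit_gee_arrays(
    y: np.ndarray,
    arm: np.ndarray,
    clusters: np.ndarray,
    spec: GeeSpec = GeeSpec(),
) -> GeeFit:
    """Fit the two-arm log-link GEE on plain arrays.

    ``clusters`` holds a cluster label per observation.  Raises
    :class:`SeparationError` when either arm's outcomes are constant.
    """
    y = np.asarray(y, dtype=float)
    arm = np.asarray(arm, dtype=float)
    clusters = np.asarray(clusters)
    if y.size != arm.size or y.size != clusters.size:
        raise ValueError("y, arm and clusters must have equal length")
    for a in (0, 1):
        ya = y[arm == a]
        if ya.size == 0:
            raise ValueError(f"no observations in arm {a}")
        if ya.min() == ya.max():
            raise SeparationError(
                f"outcomes in arm {a} are all {int(ya[0])}; "
                "the log-link ratio is not estimable"
            )

    # sort by cluster so each cluster is a contiguous slice
    order = np.argsort(clusters, kind="stable")
    y, arm, clusters = y[order], arm[order], clusters[order]
    labels, starts = np.unique(clusters, return_index=True)
    bounds = np.append(np.sort(starts), y.size)
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(labels.size)]
    n_clusters = labels.size
    if n_clusters < 2:
        raise ValueError("GEE needs at least 2 clusters")

    X = np.column_stack([np.ones_like(arm), arm])
    p = X.shape[1]
    eps = 1e-10

    p0 = float(np.clip(y[arm == 0].mean(), eps, 1 - eps))
    p1 = float(np.clip(y[arm == 1].mean(), eps, 1 - eps))
    beta = np.array([math.log(p0), math.log(p1) - math.log(p0)])

    alpha = 0.0
    converged = False
    for _ in range(spec.max_iterations):
        mu = np.clip(np.exp(X @ beta), eps, 1.0 - eps)
        var = mu * (1.0 - mu)
        sd = np.sqrt(var)
        resid = (y - mu) / sd
        if spec.working_correlation == "exchangeable":
            alpha = _exchangeable_alpha(resid, slices, p)
            alpha = float(np.clip(alpha, -0.999, 0.999))
        G = np.zeros((p, p))
        g = np.zeros(p)
        for sl in slices:
            D = mu[sl, None] * X[sl]  # d mu / d beta under the log link
            r = y[sl] - mu[sl]
            if spec.working_correlation == "independence":
                ViD = D / var[sl, None]
                Vir = r / var[sl]
            else:
                ViD = _solve_exchangeable(D, sd[sl], alpha)
                Vir = _solve_exchangeable(r, sd[sl], alpha)
            G += D.T @ ViD
            g += D.T @ Vir
        delta = np.linalg.solve(G, g)
        beta = beta + delta
        if np.max(np.abs(delta)) < spec.tolerance * (1.0 + np.max(np.abs(beta))):
            converged = True
            break

    # sandwich covariance at the final beta
    mu = np.clip(np.exp(X @ beta), eps, 1.0 - eps)
    var = mu * (1.0 - mu)
    sd = np.sqrt(var)
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    for sl in slices:
        D = mu[sl, None] * X[sl]
        r = y[sl] - mu[sl]
        if spec.working_correlation == "independence":
            ViD = D / var[sl, None]
            Vir = r / var[sl]
        else:
            ViD = _solve_exchangeable(D, sd[sl], alpha)
            Vir = _solve_exchangeable(r, sd[sl], alpha)
        A += D.T @ ViD
        u = D.T @ Vir
        B += np.outer(u, u)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry

    ratio = math.exp(beta[1])
    se = math.sqrt(max(cov[1, 1], 0.0))
    if se > 0:
        lo, hi = math.exp(beta[1] - Z975 * se), math.exp(beta[1] + Z975 * se)
        pval = 2.0 * float(norm.sf(abs(beta[1]) / se))
    else:  # degenerate interval
        lo = hi = ratio
        pval = 1.0 if beta[1] == 0.0 else 0.0
    return GeeFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        robust_cov=cov,
        ratio=ratio,
        ci_lower=lo,
        ci_upper=hi,
        p_value=pval,
        converged=converged,
        n_clusters=n_clusters,
        alpha_hat=alpha if spec.working_correlation == "exchangeable" else None,
    )


def fit_gee(records: Sequence[OutcomeRecord], spec: GeeSpec = GeeSpec()) -> GeeFit:
    """Fit the two-arm GEE from outcome records, clustering per ``spec``."""
    if not records:
        raise ValueError("no outcome records")
    y = np.array([r.y for r in records], dtype=float)
    arm = np.array([r.arm for r in records], dtype=float)
    if spec.cluster_by == "reader":
        clusters = np.array([r.reader_id for r in records])
    else:
        clusters = np.array([f"{r.reader_id}|{r.image_id}" for r in records])
    return fit_gee_arrays(y, arm, clusters, spec)


def ratio_ci(fit: GeeFit) -> tuple[float, float, float, float]:
    """(ratio, lower, upper, p_value) from a converged fit."""
    if not fit.converged:
        raise ValueError("GEE fit did not converge; interval not reported")
    if fit.se_log_ratio == 0.0:
        raise ValueError("degenerate interval: zero robust standard error")
    return (fit.ratio, fit.ci_lower, fit.ci_upper, fit.p_value)


def format_p(p: float, floor: float = 0.001) -> str:
    """Display form of a p-value, floored at '< 0.001'."""
    if p < floor:
        return f"< {floor}"
    return f"{p:.3f}"
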