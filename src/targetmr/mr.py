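"""Wald-ratio and inverse-variance-weighted causal estimation.

The single-instrument Wald ratio divides the genetic association with the
outcome by the genetic association with the exposure; its standard error
uses the first-order delta method (outcome SE divided by |exposure beta|).
Multiple independent instruments are meta-analysed by inverse-variance
weighting: fixed effects for three instruments or fewer, multiplicative
random effects (SE inflated by ``max(1, sqrt(Q/(k-1)))`` with Cochran's Q)
for four or more.  Correlated instruments are combined by generalized least
squares with the full LD-derived covariance of the outcome associations.

Binary outcomes analysed by linear regression are mapped to the log-odds
scale by dividing beta and SE by ``mu * (1 - mu)`` where ``mu`` is the case
fraction.  All drug-mimicking estimates can be reported per SD *decrease* in
the exposure biomarker by an explicit sign convention, never implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .gwas_io import AssociationRecord, LDMatrix

__all__ = [
    "MREstimate",
    "ExposureConvention",
    "LogisticEffect",
    "NumericalError",
    "wald_ratio",
    "ivw",
    "ivw_correlated",
    "rescale",
    "linear_to_logistic",
    "difference_z_test",
]

_Z975 = stats.norm.ppf(0.975)


class NumericalError(RuntimeError):
    """A linear-algebra step failed beyond the tolerated jitter."""


@dataclass
class MREstimate:
    """A causal-effect estimate with its normal-theory uncertainty."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    method: str  # wald | ivw_fixed | ivw_random | ivw_correlated
    n_snps: int
    q_stat: Optional[float] = None
    scale: str = "SD"

    @classmethod
    def from_beta_se(
        cls,
        beta: float,
        se: float,
        method: str,
        n_snps: int,
        q_stat: Optional[float] = None,
        scale: str = "SD",
    ) -> "MREstimate":
        z = beta / se if se > 0 else math.inf * np.sign(beta)
        p = float(2.0 * stats.norm.sf(abs(z))) if se > 0 else 0.0
        return cls(
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - _Z975 * se),
            ci_high=float(beta + _Z975 * se),
            # floor against underflow so p stays in (0, 1]
            pvalue=min(max(p, 1e-320), 1.0),
            method=method,
            n_snps=n_snps,
            q_stat=q_stat,
            scale=scale,
        )

    @property
    def odds_ratio(self) -> float:
        """exp(beta); meaningful when the estimate is on a log-odds scale."""
        return math.exp(self.beta)


@dataclass
class ExposureConvention:
    """Sign convention for reporting drug-mimicking effects.

    Drug effects are conventionally expressed per SD *decrease* in the
    exposure biomarker (mimicking inhibition); flipping the direction
    negates the effect and swaps the CI bounds.
    """

    direction: str = "per_sd_decrease"  # or per_sd_increase
    exposure_trait: str = "LDL-cholesterol"

    def __post_init__(self) -> None:
        if self.direction not in ("per_sd_decrease", "per_sd_increase"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def apply(self, est: MREstimate) -> MREstimate:
        """Convert a per-SD-increase estimate to this convention."""
        if self.direction == "per_sd_increase":
            return est
        return rescale(est, -1.0, est.scale)


@dataclass
class LogisticEffect:
    """Log-odds-scale effect obtained from a linear-scale binary-trait beta."""

    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float


def wald_ratio(exp: AssociationRecord, out: AssociationRecord, scale: str = "SD") -> MREstimate:
    """Single-instrument causal estimate: outcome beta over exposure beta.

    The records must already be harmonized to the same effect allele.  The
    SE is the first-order delta-method approximation ``out.se / |exp.beta|``
    (exposure-side sampling error is neglected, appropriate for strong
    instruments).
    """
    if exp.beta == 0:
        raise ZeroDivisionError(
            f"Wald ratio undefined: exposure beta is 0 for {exp.variant_id}"
        )
    beta = out.beta / exp.beta
    se = out.se / abs(exp.beta)
    return MREstimate.from_beta_se(beta, se, method="wald", n_snps=1, scale=scale)


def ivw(
    ratios: Sequence[MREstimate],
    random_effects: Optional[bool] = None,
    random_effects_min_snps: int = 4,
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of single-SNP Wald ratios.

    Weights are ``1/se^2``.  With ``random_effects=None`` the model follows
    the instrument count: fixed effects for up to ``random_effects_min_snps
    - 1`` instruments, multiplicative random effects from
    ``random_effects_min_snps`` up, in which the fixed-effects SE is
    inflated by ``max(1, sqrt(Q/(k-1)))``.  Cochran's Q is always reported.
    """
    if not ratios:
        raise ValueError("ivw requires at least one ratio estimate")
    betas = np.array([r.beta for r in ratios], dtype=float)
    ses = np.array([r.se for r in ratios], dtype=float)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    k = len(ratios)
    q = float(np.sum(w * (betas - beta) ** 2))
    use_random = random_effects if random_effects is not None else k >= random_effects_min_snps
    if use_random and k >= 2:
        phi = max(1.0, math.sqrt(q / (k - 1)))
        se = se_fixed * phi
        method = "ivw_random"
    else:
        se = se_fixed
        method = "ivw_fixed"
    scale = ratios[0].scale
    return MREstimate.from_beta_se(beta, se, method=method, n_snps=k, q_stat=q, scale=scale)


def _solve_with_jitter(omega: np.ndarray, name: str) -> np.ndarray:
    """Cholesky inverse of ``omega`` with escalating diagonal jitter."""
    base = np.mean(np.diag(omega))
    for eps in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            chol = np.linalg.cholesky(omega + eps * base * np.eye(omega.shape[0]))
        except np.linalg.LinAlgError:
            continue
        inv_chol = np.linalg.solve(chol, np.eye(omega.shape[0]))
        return inv_chol.T @ inv_chol
    raise NumericalError(f"covariance matrix {name} is singular beyond jitter tolerance")


def ivw_correlated(
    exp_betas: Sequence[float],
    out_betas: Sequence[float],
    out_ses: Sequence[float],
    rho: Union[LDMatrix, np.ndarray],
    scale: str = "SD",
) -> MREstimate:
    """IVW for correlated instruments via generalized least squares.

    The outcome associations have covariance ``Omega_ij = se_i * se_j *
    rho_ij`` under the LD correlation ``rho``; the causal effect solves the
    GLS regression of outcome betas on exposure betas through the origin:
    ``beta = (X' Omega^-1 X)^-1 X' Omega^-1 y`` with matching SE.  With
    ``rho = I`` this reproduces fixed-effects IVW of the Wald ratios
    exactly.  A singular ``Omega`` (e.g. duplicated variants) is ridged by
    escalating diagonal jitter before failing.
    """
    x = np.asarray(exp_betas, dtype=float)
    y = np.asarray(out_betas, dtype=float)
    s = np.asarray(out_ses, dtype=float)
    r = rho.r if isinstance(rho, LDMatrix) else np.asarray(rho, dtype=float)
    if not (x.shape == y.shape == s.shape and r.shape == (x.size, x.size)):
        raise ValueError("dimension mismatch between betas, ses and correlation matrix")
    omega = np.outer(s, s) * r
    omega_inv = _solve_with_jitter(omega, "Omega (outcome associations)")
    precision = float(x @ omega_inv @ x)
    if precision <= 0:
        raise NumericalError("non-positive GLS precision; check exposure betas")
    beta = float(x @ omega_inv @ y) / precision
    se = precision**-0.5
    return MREstimate.from_beta_se(
        beta, se, method="ivw_correlated", n_snps=x.size, scale=scale
    )


def rescale(est: MREstimate, factor: float, new_scale: str) -> MREstimate:
    """Multiply an estimate (beta, SE, CI) by ``factor``; p is unchanged.

    Used e.g. to convert a lifespan log protection ratio to approximate life
    years (factor 10) or to flip the exposure direction (factor -1, which
    swaps the CI bounds).
    """
    if factor == 0:
        raise ValueError("rescale factor must be nonzero")
    lo, hi = est.ci_low * factor, est.ci_high * factor
    if factor < 0:
        lo, hi = hi, lo
    return replace(
        est,
        beta=est.beta * factor,
        se=est.se * abs(factor),
        ci_low=lo,
        ci_high=hi,
        scale=new_scale,
    )


def linear_to_logistic(beta: float, se: float, mu: float) -> LogisticEffect:
    """Approximate log odds ratio from a linear-model beta for a binary trait.

    For a binary outcome with case fraction ``mu`` analysed by linear
    regression, the log OR is approximately ``beta / (mu * (1 - mu))`` with
    the SE scaled identically; the OR and its normal-theory 95% CI follow by
    exponentiation.  The divisor is isolated here so any refinement of the
    approximation is a one-line change.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError(f"case fraction must be in (0, 1), got {mu}")
    denom = mu * (1.0 - mu)
    log_or = beta / denom
    se_log_or = se / denom
    return LogisticEffect(
        log_or=log_or,
        se=se_log_or,
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - _Z975 * se_log_or),
        ci_high=math.exp(log_or + _Z975 * se_log_or),
    )


def difference_z_test(a: MREstimate, b: MREstimate) -> tuple[float, float]:
    """Two-sided z-test for the difference between two independent estimates.

    Used for sex differences and for contrasts between drug targets; both
    estimates must be on the same scale.
    """
    if a.scale != b.scale:
        raise ValueError(f"estimates on different scales: {a.scale!r} vs {b.scale!r}")
    z = (a.beta - b.beta) / math.sqrt(a.se**2 + b.se**2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p
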