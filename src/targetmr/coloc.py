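"""Enumeration-based Bayesian colocalization of two traits in a cis region.

For each variant and each trait an approximate Bayes factor (Wakefield's
closed form) measures the evidence for association from the marginal beta,
its SE and a prior effect variance.  Assuming at most one causal variant per
trait, enumerating the possible configurations yields posterior
probabilities for five hypotheses:

- H0: no association with either trait
- H1/H2: association with trait 1 / trait 2 only
- H3: both traits associated, two distinct causal variants
- H4: both traits associated, one shared causal variant

All arithmetic is carried out in log space with log-sum-exp.  Default priors
are 1e-4 per variant per trait and 1e-5 for a shared variant; a sensitivity
grid over the shared prior is provided because PP4 is sensitive to it.  The
"conditional" colocalization probability PP4/(PP3+PP4) — the probability of
a shared variant given that some variant is associated with the outcome —
is reported alongside, as power to detect colocalization is otherwise low
for weakly associated outcomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gwas_io import EmptyInputError, LDMatrix, SummaryDataset, harmonize
from .instruments import GeneRegion
from .mr import linear_to_logistic

logger = logging.getLogger(__name__)

__all__ = [
    "ColocConfig",
    "ColocResult",
    "wakefield_labf",
    "coloc_abf",
    "conditional_coloc_prob",
    "coloc_sensitivity",
    "default_prior_variance",
]

HYPOTHESES = ("PP0", "PP1", "PP2", "PP3", "PP4")


@dataclass
class ColocConfig:
    """Priors and window for enumeration colocalization.

    ``p1``/``p2`` are the prior probabilities that any given variant is
    causal for trait 1 / trait 2; ``p12`` that it is causal for both.
    ``w1``/``w2`` are prior effect variances; when ``None`` they default per
    trait type (see :func:`default_prior_variance`).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    window_bp: int = 100_000
    w1: Optional[float] = None
    w2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("per-variant priors must sum below 1")


def default_prior_variance(trait_type: str, sd_y: Optional[float] = None) -> float:
    """Prior variance of a true effect: (0.2*sdY)^2 for quantitative traits
    (sdY=1 for standardized traits), 0.15^2 on the log-odds scale for binary
    traits."""
    if trait_type == "quantitative":
        return (0.2 * (sd_y if sd_y is not None else 1.0)) ** 2
    return 0.15**2


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities and per-variant evidence."""

    pp: dict[str, float]
    labf1: np.ndarray
    labf2: np.ndarray
    variant_ids: list[str]
    top_shared_variant: str
    conditional_pp4: Optional[float]
    n_variants: int
    p12: float
    shared_posterior: np.ndarray = field(repr=False, default=None)  # per-variant H4 posterior

    def as_row(self) -> dict:
        row = {"n_variants": self.n_variants, **self.pp}
        row["conditional_pp4"] = self.conditional_pp4
        row["top_shared_variant"] = self.top_shared_variant
        row["p12"] = self.p12
        return row


def wakefield_labf(beta: float, se: float, w: float) -> float:
    """Log approximate Bayes factor for one variant-trait association.

    With ``V = se^2``, shrinkage ``r = w / (V + w)`` and ``Z = beta / se``:
    ``lABF = 0.5 * (log(1 - r) + r * Z^2)``.  Larger values favour a true
    association; ``w = 0`` gives 0 (prior mass on the null effect size).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if w < 0:
        raise ValueError("prior variance must be non-negative")
    v = se * se
    r = w / (v + w)
    z = beta / se
    return 0.5 * (math.log1p(-r) + r * z * z)


def _labf_vector(ds: SummaryDataset, variant_ids: Sequence[str], w: Optional[float]) -> np.ndarray:
    """Per-variant lABFs, mapping linear-scale binary traits to log-odds first."""
    if w is None:
        w = default_prior_variance(
            "quantitative" if not ds.is_binary else "binary", ds.sd_y
        )
    out = np.empty(len(variant_ids))
    mu = ds.mu() if ds.trait_type == "binary_linear" else None
    if ds.trait_type == "binary_linear" and mu is None:
        raise ValueError(
            f"{ds.trait_id}: binary_linear trait needs a case fraction for the "
            "log-odds conversion before ABF computation"
        )
    for i, vid in enumerate(variant_ids):
        rec = ds.records[vid]
        beta, se = rec.beta, rec.se
        if mu is not None:
            eff = linear_to_logistic(beta, se, mu)
            beta, se = eff.log_or, eff.se
        out[i] = wakefield_labf(beta, se, w)
    return out


def _posteriors(
    labf1: np.ndarray, labf2: np.ndarray, p1: float, p2: float, p12: float
) -> dict[str, float]:
    """Hypothesis posteriors from per-variant log-ABFs, all in log space.

    Unnormalized log posterior masses: H0 = 0; H1 = log p1 + L1;
    H2 = log p2 + L2; H3 = log p1 + log p2 + log(exp(L1 + L2) - exp(L12));
    H4 = log p12 + L12 — where L1, L2 and L12 are log-sum-exp sums of
    labf1, labf2 and labf1+labf2.  The H3 difference is evaluated with
    log1p(-exp(.)); negative round-off is clamped to -inf (exactly so for a
    single-variant region, where H3 is impossible).
    """
    l1 = float(logsumexp(labf1))
    l2 = float(logsumexp(labf2))
    l12 = float(logsumexp(labf1 + labf2))
    h = np.empty(5)
    h[0] = 0.0
    h[1] = math.log(p1) + l1
    h[2] = math.log(p2) + l2
    # sum over i != j equals exp(l1 + l2) - exp(l12); guard round-off.
    gap = l12 - (l1 + l2)
    if len(labf1) == 1 or gap >= 0:
        h[3] = -np.inf
    else:
        h[3] = math.log(p1) + math.log(p2) + l1 + l2 + math.log1p(-math.exp(gap))
    h[4] = math.log(p12) + l12
    pp = np.exp(h - logsumexp(h))
    pp /= pp.sum()
    return dict(zip(HYPOTHESES, pp.tolist()))


def coloc_abf(
    region1: SummaryDataset,
    region2: SummaryDataset,
    window: Optional[GeneRegion] = None,
    cfg: Optional[ColocConfig] = None,
) -> ColocResult:
    """Colocalize two traits over the shared variants of a cis region.

    The datasets are harmonized (trait 2 aligned to trait 1's alleles) and
    restricted to ``window`` (gene body +/- flank, default flank 100 kb,
    inclusive bounds) when given.  Variants with missing or invalid SE in
    either trait have already been excluded at read time; binary traits on
    the linear scale are converted to log-odds before ABF computation (this
    conversion is logged).
    """
    cfg = cfg or ColocConfig()
    pair = harmonize(region1, region2)
    ids = pair.variant_ids
    if window is not None:
        ids = [
            v
            for v in ids
            if window.contains(pair.exposure.records[v].chrom, pair.exposure.records[v].pos)
        ]
    if not ids:
        raise EmptyInputError(
            f"no overlapping variants between {region1.trait_id} and {region2.trait_id}"
            + (" within window" if window is not None else "")
        )
    if region1.trait_type == "binary_linear" or region2.trait_type == "binary_linear":
        logger.info(
            "coloc %s vs %s: linear-scale binary trait(s) converted to log-odds",
            region1.trait_id,
            region2.trait_id,
        )
    labf1 = _labf_vector(pair.exposure, ids, cfg.w1)
    labf2 = _labf_vector(pair.outcome, ids, cfg.w2)
    return _result_from_labfs(labf1, labf2, ids, cfg.p1, cfg.p2, cfg.p12)


def _result_from_labfs(
    labf1: np.ndarray,
    labf2: np.ndarray,
    ids: Sequence[str],
    p1: float,
    p2: float,
    p12: float,
) -> ColocResult:
    pp = _posteriors(labf1, labf2, p1, p2, p12)
    joint = labf1 + labf2
    shared_post = np.exp(joint - logsumexp(joint))
    shared_post /= shared_post.sum()
    top = ids[int(np.argmax(shared_post))]
    denom = pp["PP3"] + pp["PP4"]
    cond = pp["PP4"] / denom if denom > 0 else None
    return ColocResult(
        pp=pp,
        labf1=labf1,
        labf2=labf2,
        variant_ids=list(ids),
        top_shared_variant=top,
        conditional_pp4=cond,
        n_variants=len(ids),
        p12=p12,
        shared_posterior=shared_post,
    )


def conditional_coloc_prob(result: ColocResult) -> Optional[float]:
    """PP4 / (PP3 + PP4): shared-variant probability conditional on the
    outcome having a causal variant in the region.  ``None`` (flagged
    missing) when PP3 + PP4 = 0."""
    denom = result.pp["PP3"] + result.pp["PP4"]
    if denom == 0:
        return None
    return result.pp["PP4"] / denom


def coloc_sensitivity(
    region1: SummaryDataset,
    region2: SummaryDataset,
    cfg: Optional[ColocConfig] = None,
    p12_grid: Sequence[float] = (1e-5, 1e-6),
    window: Optional[GeneRegion] = None,
) -> pd.DataFrame:
    """Posterior probabilities across a grid of shared-variant priors.

    The per-variant lABFs are computed once and reused for every prior.
    Returns one row per ``p12`` with PP0..PP4, the conditional probability
    and the top shared variant.
    """
    cfg = cfg or ColocConfig()
    base = coloc_abf(region1, region2, window=window, cfg=cfg)
    rows = []
    for p12 in p12_grid:
        res = _result_from_labfs(
            base.labf1, base.labf2, base.variant_ids, cfg.p1, cfg.p2, p12
        )
        rows.append(res.as_row())
    return pd.DataFrame(rows)
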