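"""Phenome-wide association scan with FDR control.

A PheWAS applies one genetic instrument (or a small correlated set) across a
catalog of phenotype GWAS.  The catalog is first filtered by a fixed rule
order — duplicates, excluded categories, availability, then case/sample-size
thresholds (binary phenotypes need at least 100 cases; continuous or ordered
phenotypes at least 10,000 samples; thresholds are strict, so boundary
values are included) — with per-rule exclusion counts logged flowchart
style.  Each surviving phenotype gets a Wald/IVW estimate on the per-SD-
decrease exposure scale, binary phenotypes are mapped from the linear to the
log-odds scale, and the Benjamini-Hochberg step-up procedure controls the
FDR across each scan (each sex stratum is corrected separately).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .gwas_io import LDMatrix, SummaryDataset, find_proxy
from .instruments import Instrument
from .mr import ExposureConvention, MREstimate, ivw, linear_to_logistic, wald_ratio, difference_z_test

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeMeta",
    "PheWASResult",
    "FilterLog",
    "filter_phenotypes",
    "bh_fdr",
    "run_phewas",
    "compare_strata",
    "manhattan_table",
]


@dataclass
class PhenotypeMeta:
    """Catalog entry for one phenotype GWAS."""

    pheno_id: str
    description: str = ""
    value_type: str = "continuous"  # binary | continuous | ordinal
    n: int = 0
    n_cases: Optional[int] = None
    category: str = ""
    sex_stratum: str = "both"  # both | female | male
    available: bool = True
    sumstats_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value_type == "binary" and self.n_cases is None:
            raise ValueError(f"{self.pheno_id}: binary phenotype requires n_cases")


@dataclass
class FilterLog:
    """Ordered per-rule exclusion counts, flowchart style."""

    n_input: int = 0
    n_duplicates: int = 0
    n_excluded_category: int = 0
    n_unavailable: int = 0
    n_too_few_cases: int = 0
    n_too_small: int = 0
    n_included: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_phenotypes(
    catalog: Sequence[PhenotypeMeta],
    exclusion_categories: Sequence[str] = (),
    min_cases: int = 100,
    min_n: int = 10_000,
) -> tuple[list[PhenotypeMeta], FilterLog]:
    """Apply the phenotype inclusion rules in a fixed order.

    Rules run duplicates -> category exclusions -> availability -> case /
    sample thresholds; each phenotype is excluded by the *first* violated
    rule, so the per-rule counts sum to the number excluded.  Thresholds are
    strict: a binary phenotype with exactly ``min_cases`` cases and a
    continuous phenotype with exactly ``min_n`` samples are included.
    """
    log = FilterLog(n_input=len(catalog))
    excl = set(exclusion_categories)
    seen: set[str] = set()
    included: list[PhenotypeMeta] = []
    for meta in catalog:
        if meta.pheno_id in seen:
            log.n_duplicates += 1
            continue
        seen.add(meta.pheno_id)
        if meta.category in excl:
            log.n_excluded_category += 1
            continue
        if not meta.available:
            log.n_unavailable += 1
            continue
        if meta.value_type == "binary":
            if meta.n_cases < min_cases:
                log.n_too_few_cases += 1
                continue
        elif meta.n < min_n:
            log.n_too_small += 1
            continue
        included.append(meta)
    log.n_included = len(included)
    logger.info("phenotype filter: %s", log.as_dict())
    return included, log


def bh_fdr(pvalues: Sequence[float], q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags.

    ``qvalue_j = min_{i >= rank(j)} m * p_(i) / i`` capped at 1; a test is
    rejected iff its q-value is at most ``q_level``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, qvalues, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return qvalues, reject


@dataclass
class PheWASResult:
    pheno_id: str
    estimate: MREstimate
    pvalue: float
    qvalue: Optional[float] = None
    significant: bool = False
    category: str = ""
    value_type: str = "continuous"


def _estimate_one(
    instruments: Sequence[Instrument],
    ds: SummaryDataset,
    ld: Optional[LDMatrix],
    r2_proxy: float,
) -> Optional[MREstimate]:
    """Per-SD-increase estimate for one phenotype, or None if no instrument
    variant (or proxy) is present."""
    ratios = []
    for inst in instruments:
        vid = inst.variant_id
        rec = ds.records.get(vid)
        if rec is None and ld is not None and vid in ld:
            hit = find_proxy(vid, ld, available=set(ds.records), r2_min=r2_proxy)
            if hit is not None:
                proxy_id, r = hit
                rec = ds.records[proxy_id]
                if r < 0:
                    rec = replace(rec, beta=-rec.beta, eaf=1.0 - rec.eaf)
        if rec is None:
            continue
        ratios.append(wald_ratio(inst.record, rec))
    if not ratios:
        return None
    return ratios[0] if len(ratios) == 1 else ivw(ratios)


def run_phewas(
    instruments: Union[Instrument, Sequence[Instrument]],
    phenome: Sequence[tuple[PhenotypeMeta, SummaryDataset]],
    exposure_scale: Optional[ExposureConvention] = None,
    q_level: float = 0.05,
    ld: Optional[LDMatrix] = None,
    r2_proxy: float = 0.8,
) -> tuple[list[PheWASResult], list[str]]:
    """Scan one instrument (set) across a phenome.

    For each phenotype the instrument variant (or an LD proxy with ``r^2 >
    r2_proxy`` when ``ld`` is given) is looked up in the phenotype GWAS; the
    Wald ratio (IVW across multiple instruments) is computed, binary
    phenotypes are converted from the linear to the log-odds scale, and the
    estimate is expressed per SD decrease in the exposure.  BH-FDR is then
    applied across all returned p-values of this scan.  Phenotypes whose
    datasets carry none of the instrument variants are skipped and listed in
    the returned skip log; results + skips conserve the input count.
    """
    if isinstance(instruments, Instrument):
        instruments = [instruments]
    if not phenome:
        raise ValueError("empty phenome")
    convention = exposure_scale or ExposureConvention()
    results: list[PheWASResult] = []
    skipped: list[str] = []
    for meta, ds in phenome:
        est = _estimate_one(instruments, ds, ld, r2_proxy)
        if est is None:
            skipped.append(meta.pheno_id)
            continue
        if ds.trait_type == "binary_linear":
            mu = ds.mu()
            if mu is None:
                skipped.append(meta.pheno_id)
                logger.warning("%s: binary phenotype without case fraction; skipped",
                               meta.pheno_id)
                continue
            eff = linear_to_logistic(est.beta, est.se, mu)
            est = MREstimate.from_beta_se(
                eff.log_or, eff.se, method=est.method, n_snps=est.n_snps,
                q_stat=est.q_stat, scale="log-odds",
            )
        est = convention.apply(est)
        results.append(
            PheWASResult(
                pheno_id=meta.pheno_id,
                estimate=est,
                pvalue=est.pvalue,
                category=meta.category,
                value_type=meta.value_type,
            )
        )
    if skipped:
        logger.info("phewas: skipped %d phenotype(s) missing the instrument", len(skipped))
    if results:
        qvalues, reject = bh_fdr([r.pvalue for r in results], q_level=q_level)
        for r, q, rej in zip(results, qvalues, reject):
            r.qvalue = float(q)
            r.significant = bool(rej)
    return results, skipped


def compare_strata(
    results_a: Sequence[PheWASResult],
    results_b: Sequence[PheWASResult],
    label: str = "strata",
) -> pd.DataFrame:
    """Two-sided z-tests for estimate differences between matched phenotypes.

    Phenotypes present in only one stratum are dropped with a log entry.
    """
    by_a = {r.pheno_id: r for r in results_a}
    by_b = {r.pheno_id: r for r in results_b}
    shared = [pid for pid in by_a if pid in by_b]
    unmatched = (set(by_a) | set(by_b)) - set(shared)
    if unmatched:
        logger.warning("compare_strata (%s): %d unmatched phenotype(s) dropped",
                       label, len(unmatched))
    rows = []
    for pid in shared:
        z, p = difference_z_test(by_a[pid].estimate, by_b[pid].estimate)
        rows.append({"pheno_id": pid, "z": z, "p_diff": p})
    return pd.DataFrame(rows, columns=["pheno_id", "z", "p_diff"])


def manhattan_table(results: Sequence[PheWASResult]) -> pd.DataFrame:
    """Plot-ready table for a Manhattan view of a PheWAS.

    One row per phenotype with category, -log10(p), the significance flag
    and the association direction (+/-), sorted by category then p so
    category blocks are contiguous.
    """
    if not results:
        raise ValueError("no results to tabulate")
    rows = [
        {
            "pheno_id": r.pheno_id,
            "category": r.category,
            "neg_log10_p": -math.log10(r.pvalue),
            "significant": r.significant,
            "direction": "+" if r.estimate.beta >= 0 else "-",
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["category", "neg_log10_p"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
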