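"""Cis instrument selection for drug-target Mendelian randomization.

Genetic mimics of a drug are variants in or near (default +/- 1 Mb) the gene
encoding the drug's target that are robustly associated with the exposure
biomarker (default genome-wide significance, p < 5e-8), common (MAF > 1%),
and mutually independent (pairwise r^2 < 0.001 after greedy p-ordered
clumping).  Instrument strength is screened with the single-SNP F-statistic
approximation (beta/se)^2; F <= 10 flags a potentially weak instrument.

Published named-SNP instrument lists are supported as an alternative to
selection via :func:`instruments_from_list`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .gwas_io import AssociationRecord, LDMatrix, SummaryDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRegion",
    "Instrument",
    "WEAK_F_THRESHOLD",
    "f_statistic",
    "select_instruments",
    "instruments_from_list",
]

#: F-statistics at or below this value flag possible weak-instrument bias.
WEAK_F_THRESHOLD = 10.0


@dataclass
class GeneRegion:
    """A gene body with a symmetric cis flank, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    flank: int = 1_000_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.flank < 0:
            raise ValueError(f"{self.gene}: negative flank")

    @property
    def window_start(self) -> int:
        return max(1, self.start - self.flank)

    @property
    def window_end(self) -> int:
        return self.end + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.window_start <= pos <= self.window_end


@dataclass
class Instrument:
    """An exposure-scale association selected as a genetic instrument."""

    record: AssociationRecord
    f_stat: float

    @property
    def weak(self) -> bool:
        return self.f_stat <= WEAK_F_THRESHOLD

    @property
    def variant_id(self) -> str:
        return self.record.variant_id


def f_statistic(record: AssociationRecord) -> float:
    """Single-SNP instrument-strength approximation ``(beta/se)^2``."""
    if record.se <= 0:
        raise ValueError("se must be positive")
    return (record.beta / record.se) ** 2


def select_instruments(
    exposure: SummaryDataset,
    region: GeneRegion,
    ld: LDMatrix,
    maf_min: float = 0.01,
    p_max: float = 5e-8,
    r2_clump: float = 0.001,
) -> list[Instrument]:
    """Select independent cis instruments for ``region`` from exposure GWAS.

    Candidates are restricted to the flanked region, MAF (``min(eaf,
    1-eaf)``, always derived from eaf) strictly above ``maf_min`` and
    p-value strictly below ``p_max``.  Greedy clumping then walks candidates
    in ascending p-value order (ties broken by larger ``|beta|/se``, then by
    variant ID) and keeps a variant iff its r^2 with every already-kept
    variant is below ``r2_clump``.  The output set is therefore pairwise
    independent at the r^2 ceiling and invariant to the input row order.

    Candidates missing from the LD matrix are dropped with a warning (their
    independence cannot be established).  An empty result is returned with a
    warning rather than raising, so callers can fall back to a named SNP
    list.
    """
    candidates = [
        rec
        for rec in exposure.records.values()
        if region.contains(rec.chrom, rec.pos)
        and rec.maf > maf_min
        and rec.pvalue < p_max
    ]
    in_ld = [rec for rec in candidates if rec.variant_id in ld]
    if len(in_ld) < len(candidates):
        dropped = sorted(r.variant_id for r in candidates if r.variant_id not in ld)
        logger.warning("%s: %d candidate(s) absent from LD matrix: %s",
                       region.gene, len(dropped), dropped)
    in_ld.sort(key=lambda r: (r.pvalue, -abs(r.beta) / r.se, r.variant_id))

    kept: list[AssociationRecord] = []
    for rec in in_ld:
        if all(ld.r2(rec.variant_id, k.variant_id) < r2_clump for k in kept):
            kept.append(rec)
    if not kept:
        logger.warning("%s: no instruments pass filters (MAF>%g, p<%g)",
                       region.gene, maf_min, p_max)
    return [Instrument(rec, f_statistic(rec)) for rec in kept]


def instruments_from_list(
    exposure: SummaryDataset,
    snp_list: Sequence[str],
    ld: Optional[LDMatrix] = None,
    r2_proxy: float = 0.8,
) -> list[Instrument]:
    """Build instruments from a published named-SNP list.

    SNPs absent from the exposure dataset are replaced by their best LD
    proxy (r^2 > ``r2_proxy``) when an LD matrix is given, else skipped with
    a warning.
    """
    from .gwas_io import find_proxy

    out: list[Instrument] = []
    for vid in snp_list:
        rec = exposure.records.get(vid)
        if rec is None and ld is not None and vid in ld:
            hit = find_proxy(vid, ld, available=set(exposure.records), r2_min=r2_proxy)
            if hit is not None:
                rec = exposure.records[hit[0]]
                logger.info("instrument %s unavailable; using proxy %s (r=%.3f)",
                            vid, hit[0], hit[1])
        if rec is None:
            logger.warning("instrument %s not found in exposure dataset; skipped", vid)
            continue
        out.append(Instrument(rec, f_statistic(rec)))
    return out
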