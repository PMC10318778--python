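"""Reading, validation and harmonization of GWAS summary statistics.

Summary statistics are exchanged as delimited text tables (tab-separated by
default, transparently gzip-compressed) with one row per variant carrying the
marginal association of that variant with a trait: effect/other allele, the
effect-allele frequency, the estimated beta with its standard error, a
two-sided p-value and the sample size.  LD is exchanged as a square table of
signed correlations ``r`` with a variant-ID header.

Harmonization aligns an outcome dataset onto the allele coding of an exposure
dataset: when the outcome reports the swapped allele pair the beta is negated
and the frequency reflected; strand flips are resolved by complementing
alleles before the swap test; palindromic (A/T, C/G) variants are handled by
a configurable policy because strand cannot be resolved from alleles alone.
Variants missing from the outcome can be replaced by an LD proxy (default
``r^2 > 0.8``), with the outcome beta sign-flipped when the LD correlation is
negative.

Coordinates are 1-based inclusive; the genome-build label is carried as
opaque metadata and no liftover is attempted.  Variants are matched by rsID,
never by position.  Every rejected row and dropped variant is counted and
logged; nothing is discarded silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "SummaryDataset",
    "LDMatrix",
    "HarmonizedPair",
    "ProxyChoice",
    "ConfigurationError",
    "EmptyInputError",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "harmonize",
    "find_proxy",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "n_cases",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigurationError(ValueError):
    """A run/configuration problem (missing column, bad mapping, bad path)."""


class EmptyInputError(ValueError):
    """An input yielded zero usable records."""


def _complement(allele: str) -> Optional[str]:
    """Reverse-strand representation of a single-nucleotide allele.

    Indel alleles (length != 1 or not ACGT) have no complement here; they are
    matched by exact string only.
    """
    return _COMPLEMENT.get(allele)


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand is ambiguous."""
    return _complement(a1) == a2


@dataclass
class AssociationRecord:
    """Marginal association of one variant with one trait.

    ``beta`` is per effect-allele copy on the trait scale of the source GWAS
    (SD units for standardized quantitative traits; linear-scale risk
    difference for binary traits analysed by linear regression).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float
    n_cases: Optional[float] = None

    @property
    def maf(self) -> float:
        """Minor-allele frequency, derived from the effect-allele frequency."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def z(self) -> float:
        return self.beta / self.se

    def invariant_violations(self, p_tol_log10: float = 1.0) -> list[str]:
        """Return human-readable invariant violations (empty when valid).

        The p-value is checked for consistency with ``|beta/se|`` under a
        two-sided normal reference; ``p_tol_log10`` is the allowed
        discrepancy in orders of magnitude (source GWAS may have used a t
        reference or rounded the p-value, so the check is deliberately loose).
        """
        bad: list[str] = []
        if not (self.se > 0) or not math.isfinite(self.se):
            bad.append("se must be > 0")
        if not (0.0 <= self.eaf <= 1.0):
            bad.append("eaf outside [0, 1]")
        if self.effect_allele == self.other_allele:
            bad.append("effect_allele equals other_allele")
        if not (0.0 < self.pvalue <= 1.0):
            bad.append("pvalue outside (0, 1]")
        if not math.isfinite(self.beta):
            bad.append("beta not finite")
        if not bad and self.pvalue < 1.0:
            p_ref = 2.0 * stats.norm.sf(abs(self.beta / self.se))
            if p_ref > 0 and abs(math.log10(self.pvalue) - math.log10(p_ref)) > p_tol_log10:
                bad.append("pvalue inconsistent with |beta/se| under normal reference")
        return bad


@dataclass
class SummaryDataset:
    """GWAS summary statistics for one trait, keyed by variant rsID."""

    trait_id: str
    trait_type: str = "quantitative"  # quantitative | binary_linear | binary_logistic
    records: dict[str, AssociationRecord] = field(default_factory=dict)
    sd_y: Optional[float] = None
    case_fraction: Optional[float] = None
    build: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary_linear", "binary_logistic"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __getitem__(self, variant_id: str) -> AssociationRecord:
        return self.records[variant_id]

    @property
    def is_binary(self) -> bool:
        return self.trait_type.startswith("binary")

    def mu(self) -> Optional[float]:
        """Case fraction for binary traits: explicit, or derived as n_cases/n."""
        if self.case_fraction is not None:
            return self.case_fraction
        if self.is_binary:
            fracs = [
                r.n_cases / r.n
                for r in self.records.values()
                if r.n_cases is not None and r.n > 0
            ]
            if fracs:
                return float(np.median(fracs))
        return None

    def add(self, record: AssociationRecord) -> None:
        if record.variant_id in self.records:
            raise ConfigurationError(f"duplicate variant_id {record.variant_id!r}")
        self.records[record.variant_id] = record

    def subset(self, variant_ids: Iterable[str]) -> "SummaryDataset":
        out = replace(self, records={})
        for vid in variant_ids:
            out.records[vid] = self.records[vid]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(r, c) for c in CANONICAL_COLUMNS}
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class LDMatrix:
    """Signed LD correlation matrix ``r`` over an ordered set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.variant_ids), len(self.variant_ids)):
            raise ConfigurationError("LD matrix shape does not match variant list")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != len(self.variant_ids):
            raise ConfigurationError("duplicate variant ids in LD matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.corr(a, b) ** 2

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])

    def validate(self, tol: float = 1e-8, psd_tol: float = 1e-6) -> None:
        """Raise ValueError unless symmetric, unit-diagonal, |r|<=1 and PSD."""
        r = self.r
        if not np.allclose(r, r.T, atol=tol):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=tol):
            raise ValueError("LD matrix diagonal not 1")
        if np.any(np.abs(r) > 1.0 + tol):
            raise ValueError("LD correlation outside [-1, 1]")
        w = np.linalg.eigvalsh((r + r.T) / 2.0)
        if w.min() < -psd_tol:
            raise ValueError(f"LD matrix not positive semi-definite (min eig {w.min():.3g})")


@dataclass
class ProxyChoice:
    """Record of a proxy substitution made during harmonization."""

    requested: str
    proxy: str
    r: float
    sign_flipped: bool


@dataclass
class HarmonizedPair:
    """Exposure/outcome datasets aligned to a common allele coding.

    After harmonization, for every shared variant the exposure and outcome
    ``effect_allele`` strings are identical, so Wald ratios can be formed
    directly.
    """

    exposure: SummaryDataset
    outcome: SummaryDataset
    variant_ids: list[str]
    proxy_log: list[ProxyChoice] = field(default_factory=list)
    drop_log: list[tuple[str, str]] = field(default_factory=list)  # (variant, reason)


# ---------------------------------------------------------------------------
# File I/O


_DEFAULT_COLUMN_MAP = {c: c for c in CANONICAL_COLUMNS}


def read_summary_stats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_id: Optional[str] = None,
    trait_type: str = "quantitative",
    sd_y: Optional[float] = None,
    case_fraction: Optional[float] = None,
    sep: Optional[str] = None,
    p_tol_log10: float = 1.0,
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a :class:`SummaryDataset`.

    Parameters
    ----------
    column_map
        Maps canonical field names (``variant_id``, ``beta``, ...) to the
        column names used in the file.  Unmapped canonical names default to
        themselves; ``n_cases`` is optional.
    sep
        Field separator; by default tab is tried, then comma.  Gzip input is
        detected from the ``.gz`` suffix.

    Rows violating record invariants (non-positive SE, frequency outside
    [0, 1], identical alleles, p-value inconsistent with beta/se) are
    rejected and counted in the log, never silently kept.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        df = pd.read_csv(path, sep="\t", compression="infer")
        if df.shape[1] == 1:
            df = pd.read_csv(path, sep=",", compression="infer")
    else:
        df = pd.read_csv(path, sep=sep, compression="infer")

    required = [c for c in CANONICAL_COLUMNS if c != "n_cases"]
    missing = [cmap[c] for c in required if cmap[c] not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mapped column(s) {missing} in {path}")
    has_cases = cmap["n_cases"] in df.columns

    ds = SummaryDataset(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        sd_y=sd_y,
        case_fraction=case_fraction,
    )
    n_rejected = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        n_cases = row[cmap["n_cases"]] if has_cases else None
        if n_cases is not None and (isinstance(n_cases, float) and math.isnan(n_cases)):
            n_cases = None
        rec = AssociationRecord(
            variant_id=str(row[cmap["variant_id"]]),
            chrom=str(row[cmap["chrom"]]),
            pos=int(row[cmap["pos"]]),
            effect_allele=str(row[cmap["effect_allele"]]).upper(),
            other_allele=str(row[cmap["other_allele"]]).upper(),
            eaf=float(row[cmap["eaf"]]),
            beta=float(row[cmap["beta"]]),
            se=float(row[cmap["se"]]),
            pvalue=float(row[cmap["pvalue"]]),
            n=float(row[cmap["n"]]),
            n_cases=float(n_cases) if n_cases is not None else None,
        )
        bad = rec.invariant_violations(p_tol_log10=p_tol_log10)
        if bad or rec.variant_id in ds.records:
            n_rejected += 1
            logger.debug("rejected %s: %s", rec.variant_id, bad or ["duplicate id"])
            continue
        ds.add(rec)
    if n_rejected:
        logger.info("%s: rejected %d/%d rows failing invariants", path, n_rejected, len(df))
    if not ds.records:
        raise EmptyInputError(f"no valid summary-statistics rows in {path}")
    return ds


def write_summary_stats(dataset: SummaryDataset, path) -> None:
    """Write a dataset in the canonical column order (TSV, gzip by suffix)."""
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def read_ld_matrix(path, sep: str = "\t", validate: bool = True) -> LDMatrix:
    """Read a square correlation table with a variant-ID header row/column."""
    df = pd.read_csv(path, sep=sep, index_col=0, compression="infer")
    ids = [str(v) for v in df.columns]
    if list(map(str, df.index)) != ids:
        raise ConfigurationError(f"LD matrix row/column headers disagree in {path}")
    ld = LDMatrix(ids, df.to_numpy(dtype=float))
    if validate:
        ld.validate()
    return ld


def write_ld_matrix(ld: LDMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Harmonization


def find_proxy(
    variant_id: str,
    ld: LDMatrix,
    available: Iterable[str],
    r2_min: float = 0.8,
    positions: Optional[Mapping[str, int]] = None,
) -> Optional[tuple[str, float]]:
    """Best LD proxy for ``variant_id`` among ``available`` variants.

    Returns ``(proxy_id, r)`` for the available variant maximizing ``r^2``,
    requiring ``r^2 > r2_min``; ties are broken by smaller genomic distance
    (when ``positions`` is given) then lexicographic ID.  The caller must
    negate the proxy's outcome beta when ``r < 0``.  Returns ``None`` when no
    candidate clears the threshold.
    """
    if variant_id not in ld:
        raise KeyError(f"{variant_id} not present in LD matrix")
    best: Optional[tuple[float, float, str]] = None  # (-r2, distance, id)
    best_r = 0.0
    for cand in available:
        if cand == variant_id or cand not in ld:
            continue
        r = ld.corr(variant_id, cand)
        r2 = r * r
        if r2 <= r2_min:
            continue
        dist = math.inf
        if positions is not None and variant_id in positions and cand in positions:
            dist = abs(positions[cand] - positions[variant_id])
        key = (-r2, dist, cand)
        if best is None or key < best:
            best = key
            best_r = r
    if best is None:
        return None
    return best[2], best_r


def _align_outcome_record(
    exp: AssociationRecord,
    out: AssociationRecord,
    palindrome_policy: str,
    maf_ambiguous: float,
) -> tuple[Optional[AssociationRecord], Optional[str]]:
    """Align one outcome record to the exposure allele coding.

    Returns ``(aligned_record, None)`` or ``(None, drop_reason)``.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if is_palindromic(ea, oa):
        if palindrome_policy == "drop":
            return None, "palindromic (policy drop)"
        if {o_ea, o_oa} != {ea, oa}:
            return None, "allele mismatch (palindromic)"
        if palindrome_policy == "freq":
            if exp.maf > maf_ambiguous or out.maf > maf_ambiguous:
                return None, f"palindromic with MAF > {maf_ambiguous} (ambiguous)"
            # Strand cannot be resolved from allele labels, so the physical
            # effect allele is inferred from frequency alone: same side of
            # 0.5 in both datasets means the same allele.
            if (exp.eaf < 0.5) == (out.eaf < 0.5):
                return replace(out, effect_allele=ea, other_allele=oa), None
            return (
                replace(
                    out, effect_allele=ea, other_allele=oa, beta=-out.beta, eaf=1.0 - out.eaf
                ),
                None,
            )
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")

    if (o_ea, o_oa) == (ea, oa):
        return out, None
    if (o_ea, o_oa) == (oa, ea):
        return (
            replace(out, effect_allele=ea, other_allele=oa, beta=-out.beta, eaf=1.0 - out.eaf),
            None,
        )
    # Strand flip: complement the outcome alleles, then re-run the swap test.
    c_ea, c_oa = _complement(o_ea), _complement(o_oa)
    if c_ea is not None and c_oa is not None:
        if (c_ea, c_oa) == (ea, oa):
            return replace(out, effect_allele=ea, other_allele=oa), None
        if (c_ea, c_oa) == (oa, ea):
            return (
                replace(
                    out, effect_allele=ea, other_allele=oa, beta=-out.beta, eaf=1.0 - out.eaf
                ),
                None,
            )
    return None, f"allele mismatch ({ea}/{oa} vs {o_ea}/{o_oa})"


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: Optional[LDMatrix] = None,
    palindrome_policy: str = "freq",
    maf_ambiguous: float = 0.42,
    r2_proxy: float = 0.8,
) -> HarmonizedPair:
    """Align outcome summary statistics onto the exposure allele coding.

    Variants are matched by rsID.  Outcome records with swapped alleles have
    their beta negated and eaf reflected; strand flips are resolved by
    complementing before the swap test.  ``palindrome_policy`` is ``"freq"``
    (drop when MAF > ``maf_ambiguous`` in either dataset, else align by
    frequency) or ``"drop"`` (drop all palindromic variants).

    When ``ld`` is supplied, exposure variants missing from the outcome are
    replaced by their best available proxy with ``r^2 > r2_proxy`` and the
    substitution recorded in ``proxy_log``.  When the proxy is also present
    in the exposure dataset, *both* sides are substituted by the proxy's
    associations (keeping the Wald ratio unbiased, with the sign handled by
    ordinary allele alignment); otherwise only the outcome side is
    substituted, negating the proxy's beta when the LD correlation is
    negative — this single-sided form attenuates the ratio by at most the
    LD correlation.  Either way the records are keyed under the requested
    variant's ID.
    """
    if not exposure.records or not outcome.records:
        raise EmptyInputError("harmonize requires non-empty exposure and outcome datasets")

    shared: list[str] = []
    aligned: dict[str, AssociationRecord] = {}
    exp_override: dict[str, AssociationRecord] = {}
    proxy_log: list[ProxyChoice] = []
    drop_log: list[tuple[str, str]] = []
    out_ids = set(outcome.records)

    for vid, exp_rec in exposure.records.items():
        if vid in outcome.records:
            rec, reason = _align_outcome_record(
                exp_rec, outcome.records[vid], palindrome_policy, maf_ambiguous
            )
            if rec is None:
                drop_log.append((vid, reason))
                continue
            shared.append(vid)
            aligned[vid] = rec
            continue
        if ld is not None and vid in ld:
            positions = {
                r.variant_id: r.pos for r in exposure.records.values() if r.variant_id in ld
            }
            hit = find_proxy(vid, ld, available=out_ids, r2_min=r2_proxy, positions=positions)
            if hit is not None:
                proxy_id, r = hit
                prox_out = outcome.records[proxy_id]
                prox_exp = exposure.records.get(proxy_id)
                if prox_exp is not None:
                    # Proxy present in both datasets: substitute the pair of
                    # proxy associations (unbiased; allele alignment handles
                    # the sign) under the requested variant's ID.
                    rec, reason = _align_outcome_record(
                        prox_exp, prox_out, palindrome_policy, maf_ambiguous
                    )
                    if rec is not None:
                        shared.append(vid)
                        exp_override[vid] = replace(prox_exp, variant_id=vid)
                        aligned[vid] = replace(rec, variant_id=vid)
                        proxy_log.append(
                            ProxyChoice(vid, proxy_id, r, rec.beta == -prox_out.beta
                                        and prox_out.beta != 0)
                        )
                        continue
                # Proxy only usable on the outcome side: substitute its
                # outcome association, negating when LD correlation r < 0.
                flip = r < 0
                aligned[vid] = replace(
                    prox_out,
                    variant_id=vid,
                    chrom=exp_rec.chrom,
                    pos=exp_rec.pos,
                    effect_allele=exp_rec.effect_allele,
                    other_allele=exp_rec.other_allele,
                    beta=-prox_out.beta if flip else prox_out.beta,
                    eaf=1.0 - prox_out.eaf if flip else prox_out.eaf,
                )
                shared.append(vid)
                proxy_log.append(ProxyChoice(vid, proxy_id, r, flip))
                continue
        drop_log.append((vid, "absent from outcome, no proxy"))

    if drop_log:
        logger.info(
            "harmonize %s vs %s: dropped %d variant(s)",
            exposure.trait_id,
            outcome.trait_id,
            len(drop_log),
        )
    exp_sub = exposure.subset([v for v in shared if v not in exp_override])
    exp_sub.records.update(exp_override)
    exp_sub.records = {v: exp_sub.records[v] for v in shared}
    out_aligned = replace(outcome, records={v: aligned[v] for v in shared})
    return HarmonizedPair(
        exposure=exp_sub,
        outcome=out_aligned,
        variant_ids=shared,
        proxy_log=proxy_log,
        drop_log=drop_log,
    )
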