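"""Synthetic GWAS summary statistics with known ground truth.

Every pipeline stage is validated against data generated here, so the
generators are first-class, tested code.  The statistical model mirrors the
structure of the large public summary-statistics resources the pipeline is
designed for: for a cis region of ``m`` variants with LD correlation ``R``
(AR(1) decay by default), genotypes are treated as standardized and the
marginal effects implied by joint causal effects ``b`` are ``R @ b``.  The
observed betas of one GWAS are a single draw from ``MVN(R @ b, sigma^2 R /
n)``, with per-variant SE ``sigma / sqrt(n)`` (``sigma^2 = 1`` for
standardized quantitative traits, ``mu (1 - mu)`` for binary traits
analysed on the linear scale).  Binary causal effects are specified on the
log-odds scale and planted on the linear scale as ``effect * mu * (1 -
mu)``, so the odds-ratio transformation can be exercised round trip.

Generators are deterministic given their seed and share no global state;
the optional allele-frequency-scaled SE mode (``1 / sqrt(2 n f (1 - f))``)
adds realism for I/O tests but is off by default for analytic transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .gwas_io import AssociationRecord, LDMatrix, SummaryDataset
from .instruments import Instrument, f_statistic
from .phewas import PhenotypeMeta

__all__ = [
    "SyntheticRegionConfig",
    "TwoSampleConfig",
    "PhenomeSim",
    "make_ld_matrix",
    "simulate_region_stats",
    "simulate_two_sample",
    "simulate_phenome",
    "simulate_coloc_pair",
    "write_study_fixture",
]

_P_FLOOR = 1e-320  # keep p-values inside (0, 1] despite underflow

# Non-palindromic allele pairs only, so default fixtures never hit the
# strand-ambiguity policy unless a test asks for it.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class SyntheticRegionConfig:
    """Generative truth for one cis region of one trait."""

    m: int = 50
    rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal: Sequence[tuple[int, float]] = ()
    n: int = 100_000
    trait_type: str = "quantitative"
    case_fraction: Optional[float] = None
    seed: int = 0
    trait_id: str = "trait"
    chrom: str = "17"
    start: int = 7_000_000
    spacing: int = 2_000
    variant_offset: int = 100_000
    allow_palindromic: bool = False
    freq_scaled_se: bool = False
    #: when set, the variant scaffold (ids, alleles, eaf) is drawn from this
    #: seed so several traits can share one region layout while their
    #: sampling noise differs via ``seed``.
    scaffold_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if any(i >= self.m or i < 0 for i, _ in self.causal):
            raise ValueError("causal index out of range")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.trait_type.startswith("binary") and self.case_fraction is None:
            raise ValueError("binary trait requires case_fraction")


@dataclass
class TwoSampleConfig:
    """Truth model for two-sample MR with independent instruments."""

    theta: float = 0.0
    k: int = 5
    exp_effects: Optional[Sequence[float]] = None
    n_exp: int = 100_000
    n_out: int = 100_000
    pleiotropy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("sample sizes must be positive")
        if self.exp_effects is not None and len(self.exp_effects) != self.k:
            raise ValueError("exp_effects length must equal k")


@dataclass
class _Scaffold:
    """Shared per-region variant layout (ids, positions, alleles, eaf)."""

    variant_ids: list[str]
    chrom: str
    pos: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    eaf: np.ndarray


def _make_scaffold(
    rng: np.random.Generator,
    m: int,
    chrom: str,
    start: int,
    spacing: int,
    maf_range: tuple[float, float],
    variant_offset: int,
    allow_palindromic: bool,
) -> _Scaffold:
    pairs = _ALLELE_PAIRS + (_PALINDROMIC_PAIRS if allow_palindromic else ())
    choice = rng.integers(0, len(pairs), size=m)
    maf = rng.uniform(maf_range[0], maf_range[1], size=m)
    # Report the effect allele on either side of 0.5 at random.
    flip = rng.random(m) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    return _Scaffold(
        variant_ids=[f"rs{variant_offset + j}" for j in range(m)],
        chrom=chrom,
        pos=start + spacing * np.arange(m),
        effect_alleles=[pairs[c][0] for c in choice],
        other_alleles=[pairs[c][1] for c in choice],
        eaf=eaf,
    )


def make_ld_matrix(m: int, rho: float, variant_ids: Optional[Sequence[str]] = None) -> LDMatrix:
    """AR(1) LD matrix ``r_ij = rho^|i-j|`` (positive definite for rho < 1)."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    ids = list(variant_ids) if variant_ids is not None else [f"rs{100_000 + j}" for j in range(m)]
    return LDMatrix(ids, r)


def _draw_marginals(
    rng: np.random.Generator,
    chol: np.ndarray,
    beta_marg: np.ndarray,
    se: float,
) -> np.ndarray:
    """One region-wide draw from MVN(beta_marg, se^2 * R) with R = LL'."""
    z = rng.standard_normal(beta_marg.size)
    return beta_marg + se * (chol @ z)


def _pvalues(betas: np.ndarray, ses: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(betas / ses))
    return np.clip(p, _P_FLOOR, 1.0)


def _dataset_from_arrays(
    scaffold: _Scaffold,
    betas: np.ndarray,
    ses: np.ndarray,
    n: int,
    trait_id: str,
    trait_type: str,
    case_fraction: Optional[float],
) -> SummaryDataset:
    pvals = _pvalues(betas, ses)
    n_cases = round(case_fraction * n) if case_fraction is not None else None
    ds = SummaryDataset(trait_id=trait_id, trait_type=trait_type, case_fraction=case_fraction)
    for j, vid in enumerate(scaffold.variant_ids):
        ds.records[vid] = AssociationRecord(
            variant_id=vid,
            chrom=scaffold.chrom,
            pos=int(scaffold.pos[j]),
            effect_allele=scaffold.effect_alleles[j],
            other_allele=scaffold.other_alleles[j],
            eaf=float(scaffold.eaf[j]),
            beta=float(betas[j]),
            se=float(ses[j]),
            pvalue=float(pvals[j]),
            n=float(n),
            n_cases=float(n_cases) if n_cases is not None else None,
        )
    return ds


def _causal_vector(cfg: SyntheticRegionConfig) -> np.ndarray:
    b = np.zeros(cfg.m)
    for idx, eff in cfg.causal:
        if cfg.trait_type.startswith("binary"):
            mu = cfg.case_fraction
            b[idx] += eff * mu * (1.0 - mu)  # log-odds effect planted on linear scale
        else:
            b[idx] += eff
    return b


def simulate_region_stats(cfg: SyntheticRegionConfig) -> tuple[SummaryDataset, LDMatrix]:
    """Simulate one trait's marginal summary statistics over a cis region.

    Marginal truth is ``R @ b`` for joint causal effects ``b``; the observed
    betas are one multivariate-normal draw with covariance ``sigma^2 R / n``
    and the SEs are ``sigma / sqrt(n)`` (optionally allele-frequency scaled).
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    scaffold_rng = (
        np.random.default_rng(cfg.scaffold_seed) if cfg.scaffold_seed is not None else rng
    )
    scaffold = _make_scaffold(
        scaffold_rng, cfg.m, cfg.chrom, cfg.start, cfg.spacing, cfg.maf_range,
        cfg.variant_offset, cfg.allow_palindromic,
    )
    ld = make_ld_matrix(cfg.m, cfg.rho, scaffold.variant_ids)
    sigma2 = 1.0
    if cfg.trait_type.startswith("binary"):
        sigma2 = cfg.case_fraction * (1.0 - cfg.case_fraction)
    beta_marg = ld.r @ _causal_vector(cfg)
    chol = np.linalg.cholesky(ld.r)
    if cfg.freq_scaled_se:
        # Per-allele scale: SE depends on allele frequency.
        ses = np.sqrt(sigma2 / (2.0 * cfg.n * scaffold.eaf * (1.0 - scaffold.eaf)))
        betas = beta_marg + ses * (chol @ rng.standard_normal(cfg.m))
    else:
        # Standardized-genotype scale: constant SE, covariance sigma^2 R / n.
        se = math.sqrt(sigma2 / cfg.n)
        ses = np.full(cfg.m, se)
        betas = _draw_marginals(rng, chol, beta_marg, se)
    ds = _dataset_from_arrays(
        scaffold, betas, ses, cfg.n, cfg.trait_id, cfg.trait_type, cfg.case_fraction
    )
    return ds, ld


def simulate_two_sample(cfg: TwoSampleConfig) -> tuple[SummaryDataset, SummaryDataset]:
    """Simulate exposure and outcome GWAS for ``k`` independent instruments.

    True exposure effects default to an even spread over [0.08, 0.15] SD;
    the outcome truth is ``theta * true_exposure_effect`` plus an optional
    fixed per-instrument direct (pleiotropic) effect drawn ``N(0,
    pleiotropy_sd^2)``.  Both observed betas carry sampling noise with SE
    ``1/sqrt(n)``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = (
        np.asarray(cfg.exp_effects, dtype=float)
        if cfg.exp_effects is not None
        else np.linspace(0.08, 0.15, cfg.k)
    )
    se_x = 1.0 / math.sqrt(cfg.n_exp)
    se_y = 1.0 / math.sqrt(cfg.n_out)
    pleio = rng.normal(0.0, cfg.pleiotropy_sd, size=cfg.k) if cfg.pleiotropy_sd > 0 else np.zeros(cfg.k)
    bx = truth + se_x * rng.standard_normal(cfg.k)
    by = cfg.theta * truth + pleio + se_y * rng.standard_normal(cfg.k)
    # Instruments on separate chromosomes' worth of spacing: independent.
    scaffold = _make_scaffold(
        rng, cfg.k, chrom="1", start=10_000_000, spacing=5_000_000,
        maf_range=(0.1, 0.5), variant_offset=200_000, allow_palindromic=False,
    )
    exp = _dataset_from_arrays(scaffold, bx, np.full(cfg.k, se_x), cfg.n_exp,
                               "exposure", "quantitative", None)
    out = _dataset_from_arrays(scaffold, by, np.full(cfg.k, se_y), cfg.n_out,
                               "outcome", "quantitative", None)
    return exp, out


@dataclass
class PhenomeSim:
    """A simulated phenome scan with its generative truth."""

    catalog: list[PhenotypeMeta]
    phenome: list[tuple[PhenotypeMeta, SummaryDataset]]
    truth: np.ndarray            # true effect per phenotype (0 for null)
    is_null: np.ndarray          # boolean mask
    instrument: Instrument
    exposure: SummaryDataset

    @property
    def datasets(self) -> list[SummaryDataset]:
        return [ds for _, ds in self.phenome]


_CATEGORIES = (
    "circulatory", "endocrine", "digestive", "respiratory", "neoplasms",
    "musculoskeletal", "biomarkers", "physical measures", "cognitive function",
)


def simulate_phenome(
    n_phenos: int = 2_000,
    frac_null: float = 0.9,
    effect_sd: float = 0.02,
    binary_fraction: float = 0.5,
    n: int = 100_000,
    seed: int = 0,
    mu: float = 0.1,
    exposure_beta: float = 0.1,
    n_exp: int = 800_000,
) -> PhenomeSim:
    """Simulate a single-instrument phenome with known null labels.

    Each phenotype carries one marginal association of the instrument
    variant.  A fraction ``frac_null`` of true effects is exactly zero; the
    rest are drawn ``N(0, effect_sd^2)``.  Continuous phenotypes plant the
    effect directly as the marginal beta (SD units, SE ``1/sqrt(n)``);
    binary phenotypes treat the drawn effect as a log odds ratio planted on
    the linear scale as ``effect * mu * (1 - mu)`` with SE ``sqrt(mu (1 -
    mu) / n)``, exercising the odds-ratio transformation.  Returns the
    catalog, the per-phenotype datasets, the truth labels, and the exposure
    instrument (effect ``exposure_beta`` SD per allele, SE ``1 /
    sqrt(n_exp)``).
    """
    rng = np.random.default_rng(seed)
    is_null = rng.random(n_phenos) < frac_null
    truth = np.where(is_null, 0.0, rng.normal(0.0, effect_sd, size=n_phenos))
    is_binary = rng.random(n_phenos) < binary_fraction

    se_x = 1.0 / math.sqrt(n_exp)
    bx = exposure_beta + se_x * rng.standard_normal()
    inst_rec = AssociationRecord(
        variant_id="rs1000001", chrom="17", pos=7_101_000,
        effect_allele="A", other_allele="G", eaf=0.25,
        beta=float(bx), se=se_x, pvalue=float(_pvalues(np.array([bx]), np.array([se_x]))[0]),
        n=float(n_exp),
    )
    exposure = SummaryDataset(trait_id="exposure", trait_type="quantitative")
    exposure.add(inst_rec)
    instrument = Instrument(inst_rec, f_statistic(inst_rec))

    denom = mu * (1.0 - mu)
    se_cont = 1.0 / math.sqrt(n)
    se_bin = math.sqrt(denom / n)
    beta_true = np.where(is_binary, truth * denom, truth)
    ses = np.where(is_binary, se_bin, se_cont)
    betas = beta_true + ses * rng.standard_normal(n_phenos)
    pvals = _pvalues(betas, ses)

    catalog: list[PhenotypeMeta] = []
    phenome: list[tuple[PhenotypeMeta, SummaryDataset]] = []
    n_cases = round(mu * n)
    for i in range(n_phenos):
        binary = bool(is_binary[i])
        meta = PhenotypeMeta(
            pheno_id=f"pheno_{i:05d}",
            description=f"synthetic phenotype {i}",
            value_type="binary" if binary else "continuous",
            n=n,
            n_cases=n_cases if binary else None,
            category=_CATEGORIES[i % len(_CATEGORIES)],
        )
        ds = SummaryDataset(
            trait_id=meta.pheno_id,
            trait_type="binary_linear" if binary else "quantitative",
            case_fraction=mu if binary else None,
        )
        ds.records[inst_rec.variant_id] = AssociationRecord(
            variant_id=inst_rec.variant_id, chrom=inst_rec.chrom, pos=inst_rec.pos,
            effect_allele=inst_rec.effect_allele, other_allele=inst_rec.other_allele,
            eaf=inst_rec.eaf, beta=float(betas[i]), se=float(ses[i]),
            pvalue=float(pvals[i]), n=float(n),
            n_cases=float(n_cases) if binary else None,
        )
        catalog.append(meta)
        phenome.append((meta, ds))
    return PhenomeSim(
        catalog=catalog, phenome=phenome, truth=truth, is_null=is_null,
        instrument=instrument, exposure=exposure,
    )


def simulate_coloc_pair(
    shared: bool,
    m: int = 50,
    rho: float = 0.9,
    n1: int = 50_000,
    n2: int = 50_000,
    effect: float = 0.05,
    seed: int = 0,
    max_r2_distinct: float = 0.1,
) -> tuple[SummaryDataset, SummaryDataset, LDMatrix]:
    """Simulate a pair of regional GWAS with a shared or distinct causal variant.

    Both traits use the same variant scaffold and LD matrix.  With
    ``shared=True`` one causal index drives both traits; with
    ``shared=False`` two indices with pairwise ``r^2 < max_r2_distinct``
    (redrawn until satisfied) drive one trait each.
    """
    if not shared and m < 2:
        raise ValueError("distinct-causal simulation needs m >= 2")
    rng = np.random.default_rng(seed)
    scaffold = _make_scaffold(rng, m, "17", 7_000_000, 2_000, (0.05, 0.5),
                              100_000, allow_palindromic=False)
    ld = make_ld_matrix(m, rho, scaffold.variant_ids)
    c1 = int(rng.integers(0, m))
    if shared:
        c2 = c1
    else:
        while True:
            c2 = int(rng.integers(0, m))
            if c2 != c1 and ld.r[c1, c2] ** 2 < max_r2_distinct:
                break
    chol = np.linalg.cholesky(ld.r)
    out = []
    for causal_idx, n in ((c1, n1), (c2, n2)):
        b = np.zeros(m)
        b[causal_idx] = effect
        se = 1.0 / math.sqrt(n)
        betas = _draw_marginals(rng, chol, ld.r @ b, se)
        out.append(
            _dataset_from_arrays(
                scaffold, betas, np.full(m, se), n,
                f"trait{len(out) + 1}", "quantitative", None,
            )
        )
    return out[0], out[1], ld


# ---------------------------------------------------------------------------
# On-disk study fixture


def write_study_fixture(
    directory,
    seed: int = 0,
    m: int = 60,
    n_exp: int = 400_000,
    n_outcomes: int = 8,
    n_phenos: int = 200,
    theta_mortality: float = -0.3,
    mu: float = 0.1,
) -> "Path":
    """Write a complete, internally consistent synthetic study to disk.

    Emits the same TSV dialects the readers accept -- an exposure biomarker
    GWAS covering two drug-target regions, a mortality outcome and a panel
    of a-priori outcomes sharing the primary region's LD (so MR and
    colocalization are both exercised), a phenome catalog with per-phenotype
    single-variant files (including a few rows designed to be excluded by
    the catalog filter), LD matrices, and a YAML run configuration.  Returns
    the config path.

    Outcome truths alternate null and non-null; causal outcome effects are
    proportional to the exposure's causal effects so that the shared-variant
    colocalization hypothesis is true for non-null outcomes.
    """
    from pathlib import Path

    import yaml

    from .gwas_io import write_ld_matrix, write_summary_stats
    from .instruments import GeneRegion, select_instruments

    directory = Path(directory)
    (directory / "phenos").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # Primary drug-target region (A) and a second region (B) 5 Mb away.
    scaf_a = _make_scaffold(rng, m, "17", 7_000_000, 2_000, (0.05, 0.5),
                            100_000, allow_palindromic=False)
    scaf_b = _make_scaffold(rng, 20, "17", 12_000_000, 2_000, (0.05, 0.5),
                            300_000, allow_palindromic=False)
    ld_a = make_ld_matrix(m, 0.9, scaf_a.variant_ids)
    ld_b = make_ld_matrix(20, 0.9, scaf_b.variant_ids)
    chol_a = np.linalg.cholesky(ld_a.r)
    chol_b = np.linalg.cholesky(ld_b.r)

    # Exposure biomarker: two independent causal signals in region A
    # (indices 32 apart have r^2 < 0.001 under AR(1) rho = 0.9), one in B.
    b_exp_a = np.zeros(m)
    b_exp_a[m // 6] = -0.15
    b_exp_a[m // 6 + 40] = -0.10
    b_exp_b = np.zeros(20)
    b_exp_b[10] = -0.12
    se_exp = 1.0 / math.sqrt(n_exp)
    exp_beta_a = _draw_marginals(rng, chol_a, ld_a.r @ b_exp_a, se_exp)
    exp_beta_b = _draw_marginals(rng, chol_b, ld_b.r @ b_exp_b, se_exp)
    exposure = _dataset_from_arrays(scaf_a, exp_beta_a, np.full(m, se_exp), n_exp,
                                    "LDL-cholesterol", "quantitative", None)
    exp_b = _dataset_from_arrays(scaf_b, exp_beta_b, np.full(20, se_exp), n_exp,
                                 "LDL-cholesterol", "quantitative", None)
    exposure.records.update(exp_b.records)
    write_summary_stats(exposure, directory / "exposure.tsv")
    write_ld_matrix(ld_a, directory / "ld_A.tsv")
    write_ld_matrix(ld_b, directory / "ld_B.tsv")

    gene_a = GeneRegion("GENEA", "17", 7_050_000, 7_060_000, flank=1_000_000)
    drug_b_snp = scaf_b.variant_ids[10]

    def _two_region_outcome(trait_id, theta, n_out, trait_type="quantitative",
                            case_fraction=None):
        """Outcome stats over both regions with causal effects theta * b_exp."""
        sigma2 = 1.0 if case_fraction is None else case_fraction * (1.0 - case_fraction)
        scale = sigma2 if case_fraction is not None else 1.0
        se_out = math.sqrt(sigma2 / n_out)
        beta_a = _draw_marginals(rng, chol_a, ld_a.r @ (theta * b_exp_a * scale), se_out)
        beta_b = _draw_marginals(rng, chol_b, ld_b.r @ (theta * b_exp_b * scale), se_out)
        ds = _dataset_from_arrays(scaf_a, beta_a, np.full(m, se_out), n_out,
                                  trait_id, trait_type, case_fraction)
        ds_b = _dataset_from_arrays(scaf_b, beta_b, np.full(20, se_out), n_out,
                                    trait_id, trait_type, case_fraction)
        ds.records.update(ds_b.records)
        return ds

    # Mortality (log protection ratio scale) shares the exposure's causal
    # variants in both regions.
    mortality = _two_region_outcome("lifespan", theta_mortality, 1_000_000)
    write_summary_stats(mortality, directory / "mortality.tsv")

    # A-priori outcome panel over region A: alternating null / non-null,
    # with every third outcome binary on the linear scale.
    outcome_cfgs = []
    for i in range(n_outcomes):
        null = i % 2 == 1
        binary = i % 3 == 2
        theta = 0.0 if null else float(rng.uniform(0.2, 0.5) * rng.choice([-1, 1]))
        tid = f"outcome_{i:02d}"
        ds = _two_region_outcome(tid, theta, 350_000,
                                 "binary_linear" if binary else "quantitative",
                                 mu if binary else None)
        write_summary_stats(ds, directory / f"{tid}.tsv")
        cfg = {"trait_id": tid, "path": f"{tid}.tsv",
               "trait_type": "binary_linear" if binary else "quantitative"}
        if binary:
            cfg["case_fraction"] = mu
        outcome_cfgs.append(cfg)

    # Phenome keyed on the instruments selected from region A.
    insts = select_instruments(exposure, gene_a, ld_a)
    inst_recs = [inst.record for inst in insts]
    n_ph = 100_000
    cat_rows = []
    is_null = rng.random(n_phenos) < 0.9
    theta_ph = np.where(is_null, 0.0, rng.normal(0.0, 0.3, size=n_phenos))
    is_binary = rng.random(n_phenos) < 0.4
    for i in range(n_phenos):
        binary = bool(is_binary[i])
        sigma2 = mu * (1.0 - mu) if binary else 1.0
        se_ph = math.sqrt(sigma2 / n_ph)
        pid = f"pheno_{i:04d}"
        ds = SummaryDataset(trait_id=pid,
                            trait_type="binary_linear" if binary else "quantitative",
                            case_fraction=mu if binary else None)
        for rec in inst_recs:
            b_true = theta_ph[i] * rec.beta * (sigma2 if binary else 1.0)
            b = float(b_true + se_ph * rng.standard_normal())
            ds.records[rec.variant_id] = AssociationRecord(
                variant_id=rec.variant_id, chrom=rec.chrom, pos=rec.pos,
                effect_allele=rec.effect_allele, other_allele=rec.other_allele,
                eaf=rec.eaf, beta=b, se=se_ph,
                pvalue=float(_pvalues(np.array([b]), np.array([se_ph]))[0]),
                n=float(n_ph),
                n_cases=float(round(mu * n_ph)) if binary else None,
            )
        path = f"phenos/{pid}.tsv"
        write_summary_stats(ds, directory / path)
        cat_rows.append({
            "pheno_id": pid, "description": f"synthetic phenotype {i}",
            "value_type": "binary" if binary else "continuous",
            "n": n_ph, "n_cases": round(mu * n_ph) if binary else "",
            "category": _CATEGORIES[i % len(_CATEGORIES)],
            "sex_stratum": "both", "sumstats_path": path,
        })
    # Rows the catalog filter must exclude: a duplicate, an excluded
    # category, a binary phenotype with too few cases, a small continuous one.
    cat_rows.append(dict(cat_rows[0]))
    cat_rows.append({"pheno_id": "pheno_excl_cat", "description": "excluded category",
                     "value_type": "continuous", "n": n_ph, "n_cases": "",
                     "category": "socioeconomic", "sex_stratum": "both",
                     "sumstats_path": cat_rows[0]["sumstats_path"]})
    cat_rows.append({"pheno_id": "pheno_few_cases", "description": "too few cases",
                     "value_type": "binary", "n": n_ph, "n_cases": 99,
                     "category": "circulatory", "sex_stratum": "both",
                     "sumstats_path": cat_rows[0]["sumstats_path"]})
    cat_rows.append({"pheno_id": "pheno_small_n", "description": "too small",
                     "value_type": "continuous", "n": 9_999, "n_cases": "",
                     "category": "biomarkers", "sex_stratum": "both",
                     "sumstats_path": cat_rows[0]["sumstats_path"]})
    import pandas as pd

    pd.DataFrame(cat_rows).to_csv(directory / "phenome_catalog.tsv", sep="\t", index=False)

    config = {
        "seed": seed,
        "out_dir": "results",
        "q_level": 0.05,
        "exposure": {"trait_id": "LDL-cholesterol", "path": "exposure.tsv",
                     "trait_type": "quantitative"},
        "exposure_scale": {"direction": "per_sd_decrease",
                           "exposure_trait": "LDL-cholesterol"},
        "drug_targets": [
            {"name": "drugA",
             "gene": {"gene": "GENEA", "chrom": "17", "start": 7_050_000,
                      "end": 7_060_000, "flank": 1_000_000},
             "ld_matrix": "ld_A.tsv"},
            {"name": "drugB", "snp_list": [drug_b_snp], "ld_matrix": "ld_B.tsv"},
        ],
        "mortality": {"trait_id": "lifespan", "path": "mortality.tsv",
                      "trait_type": "quantitative", "rescale_factor": 10,
                      "scale": "life-years"},
        "outcomes": outcome_cfgs,
        "phenome_catalog": "phenome_catalog.tsv",
        "phenome_exclude_categories": ["socioeconomic"],
        "coloc": {"p1": 1.0e-4, "p2": 1.0e-4, "p12": 1.0e-5,
                  "window_bp": 100_000, "sensitivity_p12": [1.0e-6]},
        "coloc_gene": {"gene": "GENEA", "chrom": "17", "start": 7_050_000,
                       "end": 7_060_000},
    }
    config_path = directory / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
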