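"""Config-driven orchestration of the four study stages.

Stage 1 estimates the effect of each genetically mimicked drug on all-cause
mortality (lifespan scale: the log protection ratio is multiplied by 10 to
give approximate life years).  Stage 2 runs the drug-target MR across a
panel of a-priori outcomes with BH-FDR within the panel, plus two-sided
z-tests contrasting each drug against the reference (first-listed) drug.
Stage 3 is the PheWAS over a phenotype catalog, corrected per sex stratum.
Stage 4 queues every significant outcome for enumeration colocalization of
the exposure biomarker against the outcome in the cis window, including a
prior-sensitivity grid.

The mortality stage uses a plain 0.05 significance gate; the a-priori panel
and the PheWAS use BH-FDR.  All results are written as TSV with a JSON
mirror, together with skip/drop logs and a config fingerprint, so a rerun
with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .coloc import ColocConfig, coloc_sensitivity
from .gwas_io import (
    ConfigurationError,
    LDMatrix,
    SummaryDataset,
    harmonize,
    read_ld_matrix,
    read_summary_stats,
)
from .instruments import GeneRegion, Instrument, instruments_from_list, select_instruments
from .mr import (
    ExposureConvention,
    MREstimate,
    ivw,
    ivw_correlated,
    linear_to_logistic,
    rescale,
    difference_z_test,
    wald_ratio,
)
from .phewas import PhenotypeMeta, bh_fdr, filter_phenotypes, run_phewas

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "DrugTargetConfig", "DatasetConfig",
           "run_study", "forest_table", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class DatasetConfig:
    """One outcome (or the exposure) summary-statistics file with metadata."""

    trait_id: str
    path: str
    trait_type: str = "quantitative"
    case_fraction: Optional[float] = None
    category: str = ""

    def load(self, base: Path) -> SummaryDataset:
        return read_summary_stats(
            base / self.path,
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            case_fraction=self.case_fraction,
        )


@dataclass
class DrugTargetConfig:
    """Instrument specification for one genetically mimicked drug."""

    name: str
    gene: Optional[GeneRegion] = None
    snp_list: Optional[list[str]] = None
    ld_matrix: Optional[str] = None
    correlated: bool = False  # combine instruments by GLS with the LD matrix

    def __post_init__(self) -> None:
        if self.gene is None and not self.snp_list:
            raise ConfigurationError(f"{self.name}: needs a gene region or a snp_list")
        if self.correlated and not self.ld_matrix:
            raise ConfigurationError(f"{self.name}: correlated instruments need an LD matrix")


@dataclass
class RunConfig:
    """Full study configuration (see ``RunConfig.from_file`` for the schema)."""

    exposure: DatasetConfig
    drug_targets: list[DrugTargetConfig]
    mortality: Optional[DatasetConfig] = None
    mortality_rescale: float = 10.0
    mortality_scale: str = "life-years"
    outcomes: list[DatasetConfig] = field(default_factory=list)
    phenome_catalog: Optional[str] = None
    phenome_exclude_categories: list[str] = field(default_factory=list)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    coloc_sensitivity_p12: list[float] = field(default_factory=lambda: [1e-6])
    coloc_gene: Optional[GeneRegion] = None
    q_level: float = 0.05
    out_dir: str = "results"
    seed: int = 0
    exposure_scale: ExposureConvention = field(default_factory=ExposureConvention)
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if not 0.0 < self.q_level < 1.0:
            raise ConfigurationError("q_level must lie in (0, 1)")
        if not self.drug_targets:
            raise ConfigurationError("at least one drug target is required")

    @classmethod
    def from_dict(cls, d: dict, base_dir: Path = Path(".")) -> "RunConfig":
        def _region(rd: Optional[dict]) -> Optional[GeneRegion]:
            if rd is None:
                return None
            return GeneRegion(
                gene=rd["gene"], chrom=str(rd["chrom"]), start=int(rd["start"]),
                end=int(rd["end"]), flank=int(rd.get("flank", 1_000_000)),
            )

        drugs = [
            DrugTargetConfig(
                name=dd["name"],
                gene=_region(dd.get("gene")),
                snp_list=dd.get("snp_list"),
                ld_matrix=dd.get("ld_matrix"),
                correlated=bool(dd.get("correlated", False)),
            )
            for dd in d["drug_targets"]
        ]
        coloc_d = dict(d.get("coloc", {}))
        sens = coloc_d.pop("sensitivity_p12", [1e-6])
        mort = d.get("mortality")
        return cls(
            exposure=DatasetConfig(**d["exposure"]),
            drug_targets=drugs,
            mortality=DatasetConfig(
                **{k: v for k, v in mort.items() if k not in ("rescale_factor", "scale")}
            ) if mort else None,
            mortality_rescale=float(mort.get("rescale_factor", 10.0)) if mort else 10.0,
            mortality_scale=mort.get("scale", "life-years") if mort else "life-years",
            outcomes=[DatasetConfig(**od) for od in d.get("outcomes", [])],
            phenome_catalog=d.get("phenome_catalog"),
            phenome_exclude_categories=list(d.get("phenome_exclude_categories", [])),
            coloc=ColocConfig(**coloc_d),
            coloc_sensitivity_p12=list(sens),
            coloc_gene=_region(d.get("coloc_gene")),
            q_level=float(d.get("q_level", 0.05)),
            out_dir=d.get("out_dir", "results"),
            seed=int(d.get("seed", 0)),
            exposure_scale=ExposureConvention(**d.get("exposure_scale", {})),
            base_dir=base_dir,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        cfg = cls.from_dict(d, base_dir=path.parent)
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        paths = [self.exposure.path]
        paths += [dt.ld_matrix for dt in self.drug_targets if dt.ld_matrix]
        if self.mortality:
            paths.append(self.mortality.path)
        paths += [o.path for o in self.outcomes]
        if self.phenome_catalog:
            paths.append(self.phenome_catalog)
        missing = [p for p in paths if not (self.base_dir / p).exists()]
        if missing:
            raise ConfigurationError(f"missing input file(s): {missing}")

    def fingerprint(self) -> str:
        """Hash of the scientific configuration (inputs, priors, seed) and
        package version; deliberately independent of output location."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("base_dir", None)
        blob = json.dumps(d, default=str, sort_keys=True)
        return hashlib.sha256((blob + __version__).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage result tables plus logs, fingerprint and seed."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    logs: dict[str, object] = field(default_factory=dict)
    fingerprint: str = ""
    seed: int = 0

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        mirror: dict[str, object] = {"fingerprint": self.fingerprint, "seed": self.seed}
        for name, table in self.tables.items():
            table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
            mirror[name] = table.to_dict(orient="records")
        mirror["logs"] = self.logs
        with open(out_dir / "report.json", "w") as fh:
            json.dump(mirror, fh, indent=1, default=str)


def _estimate_to_row(est: MREstimate, **extra) -> dict:
    row = dict(extra)
    row.update(
        method=est.method, n_snps=est.n_snps, beta=est.beta, se=est.se,
        ci_low=est.ci_low, ci_high=est.ci_high, pvalue=est.pvalue,
        q_stat=est.q_stat, scale=est.scale,
    )
    return row


def _mr_one_outcome(
    instruments: Sequence[Instrument],
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    convention: ExposureConvention,
    ld: Optional[LDMatrix] = None,
    correlated: bool = False,
) -> Optional[MREstimate]:
    """Drug-target MR of one outcome; None when no instrument is usable."""
    inst_ids = [i.variant_id for i in instruments]
    exp_sub = exposure.subset([v for v in inst_ids if v in exposure])
    if not exp_sub.records:
        return None
    try:
        pair = harmonize(exp_sub, outcome, ld=ld)
    except Exception:
        return None
    if not pair.variant_ids:
        return None
    if correlated and ld is not None and len(pair.variant_ids) > 1:
        sub = ld.subset([v for v in pair.variant_ids if v in ld])
        ids = sub.variant_ids
        est = ivw_correlated(
            [pair.exposure[v].beta for v in ids],
            [pair.outcome[v].beta for v in ids],
            [pair.outcome[v].se for v in ids],
            sub,
        )
    else:
        ratios = [
            wald_ratio(pair.exposure[v], pair.outcome[v]) for v in pair.variant_ids
        ]
        est = ratios[0] if len(ratios) == 1 else ivw(ratios)
    if outcome.trait_type == "binary_linear":
        mu = outcome.mu()
        if mu is None:
            raise ConfigurationError(f"{outcome.trait_id}: binary outcome without case fraction")
        eff = linear_to_logistic(est.beta, est.se, mu)
        est = MREstimate.from_beta_se(
            eff.log_or, eff.se, method=est.method, n_snps=est.n_snps,
            q_stat=est.q_stat, scale="log-odds",
        )
    return convention.apply(est)


def _build_instruments(
    drug: DrugTargetConfig, exposure: SummaryDataset, ld: Optional[LDMatrix]
) -> list[Instrument]:
    if drug.snp_list:
        return instruments_from_list(exposure, drug.snp_list, ld=ld)
    if ld is None:
        raise ConfigurationError(f"{drug.name}: region selection requires an LD matrix")
    return select_instruments(exposure, drug.gene, ld)


def run_study(config: RunConfig) -> RunReport:
    """Execute the four study stages and write all result tables.

    Any stage failure aborts with a :class:`StageError`; partial outputs are
    retained alongside a ``FAILED_<stage>`` marker file.
    """
    out_dir = config.base_dir / config.out_dir
    report = RunReport(fingerprint=config.fingerprint(), seed=config.seed)
    stage = "setup"
    try:
        exposure = config.exposure.load(config.base_dir)
        ld_by_drug: dict[str, Optional[LDMatrix]] = {}
        inst_by_drug: dict[str, list[Instrument]] = {}
        inst_rows = []
        for drug in config.drug_targets:
            ld = read_ld_matrix(config.base_dir / drug.ld_matrix) if drug.ld_matrix else None
            ld_by_drug[drug.name] = ld
            insts = _build_instruments(drug, exposure, ld)
            inst_by_drug[drug.name] = insts
            for inst in insts:
                inst_rows.append(
                    {"drug": drug.name, "variant_id": inst.variant_id,
                     "beta_exposure": inst.record.beta, "se_exposure": inst.record.se,
                     "eaf": inst.record.eaf, "f_stat": inst.f_stat, "weak": inst.weak}
                )
        report.tables["instruments"] = pd.DataFrame(inst_rows)
        primary = config.drug_targets[0]
        convention = config.exposure_scale
        significant_outcomes: list[DatasetConfig] = []

        stage = "mortality"
        if config.mortality is not None:
            mort_ds = config.mortality.load(config.base_dir)
            rows = []
            for drug in config.drug_targets:
                est = _mr_one_outcome(
                    inst_by_drug[drug.name], exposure, mort_ds, convention,
                    ld=ld_by_drug[drug.name], correlated=drug.correlated,
                )
                if est is None:
                    report.logs.setdefault("mortality_skips", []).append(drug.name)
                    continue
                est = rescale(est, config.mortality_rescale, config.mortality_scale)
                rows.append(_estimate_to_row(
                    est, drug=drug.name, outcome=config.mortality.trait_id,
                    significant=est.pvalue < 0.05,
                ))
            report.tables["mortality"] = pd.DataFrame(rows)
            if rows and any(
                r["significant"] for r in rows if r["drug"] == primary.name
            ):
                significant_outcomes.append(config.mortality)

        stage = "apriori"
        apriori_est: dict[tuple[str, str], MREstimate] = {}
        if config.outcomes:
            rows = []
            outcome_ds = {o.trait_id: o.load(config.base_dir) for o in config.outcomes}
            skips: list[str] = []
            for drug in config.drug_targets:
                drug_rows = []
                for ocfg in config.outcomes:
                    est = _mr_one_outcome(
                        inst_by_drug[drug.name], exposure, outcome_ds[ocfg.trait_id],
                        convention, ld=ld_by_drug[drug.name], correlated=drug.correlated,
                    )
                    if est is None:
                        skips.append(f"{drug.name}:{ocfg.trait_id}")
                        continue
                    apriori_est[(drug.name, ocfg.trait_id)] = est
                    drug_rows.append(_estimate_to_row(
                        est, drug=drug.name, outcome=ocfg.trait_id,
                        category=ocfg.category,
                    ))
                if drug_rows:
                    q, rej = bh_fdr([r["pvalue"] for r in drug_rows], config.q_level)
                    for r, qv, rj in zip(drug_rows, q, rej):
                        r["qvalue"] = float(qv)
                        r["significant"] = bool(rj)
                rows.extend(drug_rows)
            report.tables["apriori"] = pd.DataFrame(rows)
            report.logs["apriori_skips"] = skips
            for r in rows:
                if r["drug"] == primary.name and r["significant"]:
                    significant_outcomes.extend(
                        o for o in config.outcomes if o.trait_id == r["outcome"]
                    )
            diff_rows = []
            for drug in config.drug_targets[1:]:
                for ocfg in config.outcomes:
                    a = apriori_est.get((drug.name, ocfg.trait_id))
                    b = apriori_est.get((primary.name, ocfg.trait_id))
                    if a is None or b is None or a.scale != b.scale:
                        continue
                    z, p = difference_z_test(a, b)
                    diff_rows.append(
                        {"outcome": ocfg.trait_id, "drug": drug.name,
                         "reference": primary.name, "z": z, "p_diff": p}
                    )
            report.tables["apriori_diff"] = pd.DataFrame(diff_rows)

        stage = "phewas"
        phewas_sig: list[tuple[DatasetConfig, Path]] = []
        if config.phenome_catalog:
            cat_path = config.base_dir / config.phenome_catalog
            cat = pd.read_csv(cat_path, sep="\t")
            metas = [
                PhenotypeMeta(
                    pheno_id=str(r.pheno_id),
                    description=str(getattr(r, "description", "")),
                    value_type=str(r.value_type),
                    n=int(r.n),
                    n_cases=int(r.n_cases) if pd.notna(getattr(r, "n_cases", None)) else None,
                    category=str(getattr(r, "category", "")),
                    sex_stratum=str(getattr(r, "sex_stratum", "both")),
                    sumstats_path=str(r.sumstats_path),
                )
                for r in cat.itertuples(index=False)
            ]
            included, flog = filter_phenotypes(metas, config.phenome_exclude_categories)
            report.logs["phenotype_filter"] = flog.as_dict()
            for stratum in sorted({m.sex_stratum for m in included}):
                strat = [m for m in included if m.sex_stratum == stratum]
                phenome = []
                for meta in strat:
                    ds = read_summary_stats(
                        cat_path.parent / meta.sumstats_path,
                        trait_id=meta.pheno_id,
                        trait_type="binary_linear" if meta.value_type == "binary" else "quantitative",
                        case_fraction=(meta.n_cases / meta.n) if meta.value_type == "binary" else None,
                    )
                    phenome.append((meta, ds))
                results, skipped = run_phewas(
                    inst_by_drug[primary.name], phenome, exposure_scale=convention,
                    q_level=config.q_level, ld=ld_by_drug[primary.name],
                )
                rows = [
                    _estimate_to_row(
                        r.estimate, pheno_id=r.pheno_id, category=r.category,
                        qvalue=r.qvalue, significant=r.significant,
                    )
                    for r in results
                ]
                report.tables[f"phewas_{stratum}"] = pd.DataFrame(rows)
                report.logs[f"phewas_{stratum}_skips"] = skipped
                if len(results) + len(skipped) != len(strat):
                    raise StageError(
                        f"phewas ({stratum}): results + skips != scanned phenotypes"
                    )
                meta_by_id = {m.pheno_id: m for m in strat}
                if stratum == "both":
                    for r in results:
                        if not r.significant:
                            continue
                        meta = meta_by_id[r.pheno_id]
                        phewas_sig.append((
                            DatasetConfig(
                                trait_id=meta.pheno_id,
                                path=meta.sumstats_path,
                                trait_type=("binary_linear" if meta.value_type == "binary"
                                            else "quantitative"),
                                case_fraction=(meta.n_cases / meta.n
                                               if meta.value_type == "binary" else None),
                                category=meta.category,
                            ),
                            cat_path.parent,
                        ))

        stage = "coloc"
        coloc_queue: list[tuple[DatasetConfig, Path]] = [
            (o, config.base_dir) for o in significant_outcomes
        ] + phewas_sig
        rows = []
        window = config.coloc_gene
        if window is not None:
            window = GeneRegion(window.gene, window.chrom, window.start, window.end,
                                flank=config.coloc.window_bp)
        grid = [config.coloc.p12] + [
            p for p in config.coloc_sensitivity_p12 if p != config.coloc.p12
        ]
        for ocfg, base in coloc_queue:
            ds = ocfg.load(base)
            try:
                table = coloc_sensitivity(
                    exposure, ds, cfg=config.coloc, p12_grid=grid, window=window
                )
            except Exception as exc:
                report.logs.setdefault("coloc_skips", []).append(
                    f"{ocfg.trait_id}: {exc}"
                )
                continue
            table.insert(0, "outcome", ocfg.trait_id)
            rows.append(table)
        report.tables["coloc"] = (
            pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=["outcome", "n_variants", *["PP%d" % i for i in range(5)],
                                       "conditional_pp4", "top_shared_variant", "p12"])
        )
        report.logs["coloc_queued"] = [o.trait_id for o, _ in coloc_queue]
        report.logs["phewas_significant"] = [o.trait_id for o, _ in phewas_sig]

        stage = "write"
        report.write(out_dir)
        return report
    except Exception as exc:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"FAILED_{stage}").write_text(str(exc))
        try:
            report.write(out_dir)
        except Exception:  # keep the original failure primary
            pass
        if isinstance(exc, StageError):
            raise
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def forest_table(estimates: dict[tuple[str, str], MREstimate]) -> pd.DataFrame:
    """Forest-plot-ready rows for (drug, outcome) -> estimate mappings.

    Binary (log-odds scale) outcomes additionally carry OR columns.  All
    estimates must share one exposure convention; the caller guarantees this
    by constructing them through a single :class:`ExposureConvention`.
    """
    if not estimates:
        raise ValueError("no estimates to tabulate")
    scales_by_outcome: dict[str, set[str]] = {}
    for (_, outcome), est in estimates.items():
        scales_by_outcome.setdefault(outcome, set()).add(est.scale)
    mixed = {o: s for o, s in scales_by_outcome.items() if len(s) > 1}
    if mixed:
        raise ValueError(f"mixed scales within outcome(s): {mixed}")
    rows = []
    for (drug, outcome), est in estimates.items():
        row = _estimate_to_row(est, drug=drug, outcome=outcome)
        if est.scale == "log-odds":
            row["odds_ratio"] = est.odds_ratio
            row["or_ci_low"] = math.exp(est.ci_low)
            row["or_ci_high"] = math.exp(est.ci_high)
        rows.append(row)
    return pd.DataFrame(rows)
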