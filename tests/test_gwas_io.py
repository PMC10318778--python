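"""Summary-statistics I/O, allele harmonization and proxy lookup."""

import gzip

import numpy as np
import pytest

from targetmr.gwas_io import (
    AssociationRecord,
    ConfigurationError,
    EmptyInputError,
    LDMatrix,
    SummaryDataset,
    find_proxy,
    harmonize,
    read_ld_matrix,
    read_summary_stats,
    write_ld_matrix,
    write_summary_stats,
)
from targetmr.mr import ivw, wald_ratio
from targetmr.synthetic import SyntheticRegionConfig, simulate_region_stats

HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn"


def _row(vid, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, p=None, n=10000, pos=100):
    if p is None:
        from scipy.stats import norm

        p = 2 * norm.sf(abs(beta / se)) if se > 0 else 0.5
    return f"{vid}\t1\t{pos}\t{ea}\t{oa}\t{eaf}\t{beta}\t{se}\t{p}\t{n}"


def rec(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, n=10000, pos=100, **kw):
    from scipy.stats import norm

    p = kw.pop("pvalue", 2 * norm.sf(abs(beta / se)))
    return AssociationRecord(vid, "1", pos, ea, oa, eaf, beta, se, p, n, **kw)


def dataset(records, trait_id="t", **kw):
    ds = SummaryDataset(trait_id=trait_id, **kw)
    for r in records:
        ds.add(r)
    return ds


class TestReadSummaryStats:
    def test_parses_all_valid_rows(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("\n".join([HEADER, _row("rs1"), _row("rs2"), _row("rs3")]))
        ds = read_summary_stats(path, trait_id="x")
        assert len(ds) == 3
        assert ds["rs2"].beta == pytest.approx(0.1)
        assert ds["rs2"].effect_allele == "A"

    def test_rejects_rows_violating_invariants(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("\n".join([HEADER, _row("rs1"), _row("rs2", se=0.0)]))
        ds = read_summary_stats(path)
        assert len(ds) == 1 and "rs2" not in ds

    def test_gzip_input_identical_to_plain(self, tmp_path):
        text = "\n".join([HEADER, _row("rs1"), _row("rs2", beta=-0.05, eaf=0.8)])
        plain = tmp_path / "s.tsv"
        plain.write_text(text)
        gz = tmp_path / "s.tsv.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(text)
        a, b = read_summary_stats(plain), read_summary_stats(gz)
        assert list(a.records) == list(b.records)
        for vid in a.records:
            assert a[vid] == b[vid]

    def test_missing_mapped_column_is_config_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("\n".join([HEADER, _row("rs1")]))
        with pytest.raises(ConfigurationError):
            read_summary_stats(path, column_map={"beta": "effect_size"})

    def test_zero_valid_rows_raises(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("\n".join([HEADER, _row("rs1", se=0.0)]))
        with pytest.raises(EmptyInputError):
            read_summary_stats(path)

    def test_column_map_and_roundtrip(self, tmp_path):
        ds, _ = simulate_region_stats(SyntheticRegionConfig(m=8, seed=3))
        out = tmp_path / "w.tsv"
        write_summary_stats(ds, out)
        back = read_summary_stats(out, trait_id=ds.trait_id)
        assert list(back.records) == list(ds.records)
        for vid in ds.records:
            assert back[vid].beta == pytest.approx(ds[vid].beta)


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = dataset([rec("rs1", "A", "G", beta=0.10)])
        out = dataset([rec("rs1", "G", "A", beta=-0.05, eaf=0.7)], trait_id="o")
        pair = harmonize(exp, out)
        aligned = pair.outcome["rs1"]
        assert aligned.effect_allele == "A"
        assert aligned.beta == pytest.approx(0.05)
        assert aligned.eaf == pytest.approx(0.3)

    def test_identical_coding_unchanged(self):
        exp = dataset([rec("rs1")])
        out = dataset([rec("rs1", beta=-0.02)], trait_id="o")
        pair = harmonize(exp, out)
        assert pair.outcome["rs1"].beta == pytest.approx(-0.02)

    def test_strand_flip_resolved_by_complement(self):
        exp = dataset([rec("rs1", "A", "G", beta=0.10)])
        # T/C is the reverse-strand coding of A/G: same physical allele.
        out = dataset([rec("rs1", "T", "C", beta=0.04)], trait_id="o")
        pair = harmonize(exp, out)
        assert pair.outcome["rs1"].beta == pytest.approx(0.04)
        assert pair.outcome["rs1"].effect_allele == "A"

    def test_palindromic_high_maf_dropped(self):
        exp = dataset([rec("rs1", "A", "T", eaf=0.45)])
        out = dataset([rec("rs1", "A", "T", eaf=0.45)], trait_id="o")
        pair = harmonize(exp, out, maf_ambiguous=0.42)
        assert pair.variant_ids == []
        assert any("palindromic" in reason for _, reason in pair.drop_log)

    def test_palindromic_low_maf_aligned_by_frequency(self):
        exp = dataset([rec("rs1", "A", "T", eaf=0.10, beta=0.2)])
        # Outcome labels the other side: frequency says opposite allele.
        out = dataset([rec("rs1", "A", "T", eaf=0.90, beta=0.05)], trait_id="o")
        pair = harmonize(exp, out)
        assert pair.outcome["rs1"].beta == pytest.approx(-0.05)

    def test_palindromic_policy_drop(self):
        exp = dataset([rec("rs1", "A", "T", eaf=0.10)])
        out = dataset([rec("rs1", "A", "T", eaf=0.10)], trait_id="o")
        pair = harmonize(exp, out, palindrome_policy="drop")
        assert pair.variant_ids == []

    def test_incompatible_alleles_dropped_with_reason(self):
        exp = dataset([rec("rs1", "A", "G")])
        out = dataset([rec("rs1", "A", "C")], trait_id="o")
        pair = harmonize(exp, out)
        assert pair.variant_ids == []
        assert "mismatch" in pair.drop_log[0][1]

    def test_idempotence_on_shared_variants(self):
        ds, _ = simulate_region_stats(SyntheticRegionConfig(m=15, seed=5))
        out, _ = simulate_region_stats(SyntheticRegionConfig(m=15, seed=6))
        first = harmonize(ds, out)
        second = harmonize(first.exposure, first.outcome)
        assert second.variant_ids == first.variant_ids
        for vid in first.variant_ids:
            assert second.outcome[vid] == first.outcome[vid]

    def test_allele_flip_invariance_of_mr_estimate(self, small_two_sample):
        """Recoding every outcome record to the swapped representation
        leaves the IVW estimate unchanged."""
        from dataclasses import replace

        exp, out = small_two_sample

        def estimate(outcome):
            pair = harmonize(exp, outcome)
            return ivw(
                [wald_ratio(pair.exposure[v], pair.outcome[v]) for v in pair.variant_ids]
            )

        flipped = SummaryDataset(trait_id="o")
        for v, r in out.records.items():
            flipped.records[v] = replace(
                r,
                effect_allele=r.other_allele,
                other_allele=r.effect_allele,
                beta=-r.beta,
                eaf=1.0 - r.eaf,
            )
        a, b = estimate(out), estimate(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)


class TestFindProxy:
    def _ld(self, r12, r13=0.0, r23=0.0):
        r = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
        return LDMatrix(["rs1", "rs2", "rs3"], r)

    def test_high_r2_proxy_returned(self):
        ld = self._ld(0.995)
        assert find_proxy("rs1", ld, available={"rs2"}) == ("rs2", pytest.approx(0.995))

    def test_negative_r_flags_sign_flip_for_caller(self):
        ld = self._ld(-0.95)
        proxy_id, r = find_proxy("rs1", ld, available={"rs2"})
        assert proxy_id == "rs2" and r < 0

    def test_below_threshold_returns_none(self):
        ld = self._ld(np.sqrt(0.5))
        assert find_proxy("rs1", ld, available={"rs2"}) is None

    def test_tie_broken_by_distance_then_id(self):
        r = np.array([[1.0, 0.95, 0.95], [0.95, 1.0, 0.9], [0.95, 0.9, 1.0]])
        ld = LDMatrix(["rs1", "rs2", "rs3"], r)
        pos = {"rs1": 100, "rs2": 5000, "rs3": 200}
        assert find_proxy("rs1", ld, available={"rs2", "rs3"}, positions=pos)[0] == "rs3"
        assert find_proxy("rs1", ld, available={"rs2", "rs3"})[0] == "rs2"

    def test_proxy_wald_ratio_matches_direct(self):
        """On a simulated region the Wald ratio via an r^2>0.8 proxy agrees
        with the direct-variant ratio within 3 Monte-Carlo SEs."""
        n_rep, causal = 400, 3
        diffs = []
        for seed in range(n_rep):
            cfg = dict(m=8, rho=0.95, n=200_000, causal=[(causal, 0.08)],
                       scaffold_seed=777)
            exp, ld = simulate_region_stats(SyntheticRegionConfig(seed=seed, **cfg))
            out, _ = simulate_region_stats(
                SyntheticRegionConfig(seed=10_000 + seed, **cfg)
            )
            vid = ld.variant_ids[causal]
            direct = wald_ratio(exp[vid], out[vid]).beta
            trimmed = out.subset([v for v in out.records if v != vid])
            pair = harmonize(exp, trimmed, ld=ld)
            assert pair.proxy_log and pair.proxy_log[0].r ** 2 > 0.8
            via_proxy = wald_ratio(pair.exposure[vid], pair.outcome[vid]).beta
            diffs.append(via_proxy - direct)
        diffs = np.asarray(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(n_rep)
        assert abs(diffs.mean()) < 3 * mc_se + 1e-12


class TestLDMatrixIO:
    def test_roundtrip(self, tmp_path):
        from targetmr.synthetic import make_ld_matrix

        ld = make_ld_matrix(5, 0.6)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.variant_ids == ld.variant_ids
        np.testing.assert_allclose(back.r, ld.r)

    def test_validation_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]])).validate()

    def test_validation_rejects_non_psd(self):
        r = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            LDMatrix(["a", "b", "c"], r).validate()
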