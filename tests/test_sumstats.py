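"""Reading, validation, instrument selection, and allele harmonization."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import summr
from summr.simulate import SimConfig, simulate_two_sample
from summr.sumstats import (AssociationRecord, NoInstrumentsError, harmonize,
                            read_summary_stats, select_instruments,
                            write_summary_stats)


def _write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadSummaryStats:
    HEADER = ["SNP", "EA", "OA", "BETA", "SE"]
    CMAP = {"SNP": "snp_id", "EA": "effect_allele", "OA": "other_allele",
            "BETA": "beta", "SE": "se"}

    def test_identity_read_through(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_tsv(f, self.HEADER, [["rs1", "a", "g", 0.02, 0.005],
                                    ["rs2", "C", "T", -0.01, 0.004],
                                    ["rs3", "G", "A", 0.03, 0.006]])
        recs = read_summary_stats(f, column_map=self.CMAP)
        assert [r.snp_id for r in recs] == ["rs1", "rs2", "rs3"]
        assert [r.beta for r in recs] == [0.02, -0.01, 0.03]
        assert recs[0].effect_allele == "A"  # upper-cased
        assert recs[0].eaf is None and recs[0].pval is None

    def test_zero_se_row_excluded_and_logged(self, tmp_path, caplog):
        f = tmp_path / "s.tsv"
        _write_tsv(f, self.HEADER, [["rs1", "A", "G", 0.02, 0.005],
                                    ["rs2", "C", "T", -0.01, 0.0],
                                    ["rs3", "G", "A", 0.03, 0.006]])
        with caplog.at_level(logging.WARNING, logger="summr.sumstats"):
            recs = read_summary_stats(f, column_map=self.CMAP)
        assert [r.snp_id for r in recs] == ["rs1", "rs3"]
        assert any("row 2" in m for m in caplog.messages)

    def test_missing_mandatory_column_raises(self, tmp_path):
        f = tmp_path / "s.tsv"
        _write_tsv(f, ["SNP", "EA", "BETA", "SE"],
                   [["rs1", "A", 0.02, 0.005]])
        with pytest.raises(KeyError, match="other_allele"):
            read_summary_stats(f, column_map=self.CMAP)

    def test_roundtrip_random_table(self, tmp_path):
        study = simulate_two_sample(SimConfig(seed=3))
        f = tmp_path / "rt.tsv"
        write_summary_stats(study.exposure, f)
        back = read_summary_stats(f)
        assert len(back) == len(study.exposure)
        for a, b in zip(study.exposure, back):
            assert a.snp_id == b.snp_id
            assert a.beta == pytest.approx(b.beta)
            assert a.se == pytest.approx(b.se)
            assert a.eaf == pytest.approx(b.eaf)

    def test_missing_eaf_column_degrades_to_dropping_palindromes(self, tmp_path):
        f1 = tmp_path / "exp.tsv"
        f2 = tmp_path / "out.tsv"
        rows = [["rs1", "A", "T", 0.02, 0.005], ["rs2", "C", "G", 0.01, 0.004],
                ["rs3", "A", "G", 0.03, 0.006]]
        _write_tsv(f1, self.HEADER, rows)
        _write_tsv(f2, self.HEADER, rows)
        exp = read_summary_stats(f1, column_map=self.CMAP)
        out = read_summary_stats(f2, column_map=self.CMAP)
        hs = harmonize(exp, out, palindrome_policy="infer_by_eaf")
        assert hs.table["snp_id"].tolist() == ["rs3"]
        assert set(hs.dropped["reason"]) == {"palindromic, ambiguous eaf"}


class TestSelectInstruments:
    def test_threshold_filter(self, record_factory):
        recs = [record_factory(snp_id=f"rs{i}", pval=p)
                for i, p in enumerate([1e-9, 1e-7, 1e-12])]
        kept = select_instruments(recs, 5e-8)
        assert [r.snp_id for r in kept] == ["rs0", "rs2"]

    def test_duplicates_collapse_to_smallest_p(self, record_factory):
        recs = [record_factory(snp_id="rs1", pval=1e-9),
                record_factory(snp_id="rs1", pval=1e-10)]
        kept = select_instruments(recs)
        assert len(kept) == 1 and kept[0].pval == 1e-10

    def test_count_matches_brute_force(self, record_factory, rng):
        ps = rng.uniform(0, 1, 100)
        recs = [record_factory(snp_id=f"rs{i}", pval=p) for i, p in enumerate(ps)]
        thresh = 0.3
        kept = select_instruments(recs, thresh)
        assert len(kept) == int((ps < thresh).sum())

    def test_empty_selection_raises(self, record_factory):
        with pytest.raises(NoInstrumentsError):
            select_instruments([record_factory(pval=0.5)], 5e-8)


class TestHarmonize:
    def test_swapped_alleles_negate_outcome(self, record_factory):
        exp = [record_factory(effect_allele="A", other_allele="G", beta=0.02)]
        out = [record_factory(effect_allele="G", other_allele="A", beta=0.10, eaf=0.7)]
        hs = harmonize(exp, out)
        assert hs.table.loc[0, "beta_outcome"] == pytest.approx(-0.10)
        assert hs.table.loc[0, "eaf_outcome"] == pytest.approx(0.3)

    def test_strand_complement_aligned(self, record_factory):
        exp = [record_factory(effect_allele="A", other_allele="G", beta=0.02)]
        out = [record_factory(effect_allele="T", other_allele="C", beta=0.10)]
        hs = harmonize(exp, out)
        assert hs.table.loc[0, "beta_outcome"] == pytest.approx(0.10)

    def test_palindromic_ambiguous_eaf_dropped(self, record_factory):
        exp = [record_factory(effect_allele="A", other_allele="T", eaf=0.50)]
        out = [record_factory(effect_allele="A", other_allele="T", eaf=0.50)]
        hs = harmonize(exp, out, palindrome_policy="infer_by_eaf")
        assert hs.n_snp == 0
        assert hs.dropped.loc[0, "reason"] == "palindromic, ambiguous eaf"

    def test_palindromic_oriented_by_eaf(self, record_factory):
        exp = [record_factory(effect_allele="A", other_allele="T", eaf=0.2)]
        # Outcome reports the same variant from the other strand: its "A" is
        # the exposure's T, so the frequencies disagree.
        out = [record_factory(effect_allele="A", other_allele="T", beta=0.1, eaf=0.8)]
        hs = harmonize(exp, out, palindrome_policy="infer_by_eaf")
        assert hs.table.loc[0, "beta_outcome"] == pytest.approx(-0.1)

    def test_irreconcilable_alleles_dropped_with_reason(self, record_factory):
        exp = [record_factory(effect_allele="A", other_allele="G")]
        out = [record_factory(effect_allele="A", other_allele="C")]
        hs = harmonize(exp, out)
        assert hs.n_snp == 0
        assert hs.dropped.loc[0, "reason"] == "allele mismatch"

    def test_every_snp_accounted_for(self, record_factory):
        study = simulate_two_sample(SimConfig(seed=5, palindromic_fraction=0.2))
        hs = harmonize(study.exposure, study.outcome)
        all_ids = {r.snp_id for r in study.exposure}
        assert set(hs.table["snp_id"]) | set(hs.dropped["snp_id"]) == all_ids
        assert not (set(hs.table["snp_id"]) & set(hs.dropped["snp_id"]))

    def test_swapped_representation_is_invisible_downstream(self):
        """Randomly allele-swapping 30% of outcome rows must not change IVW."""
        cfg = SimConfig(k=200, theta=0.25, seed=11, swap_fraction=0.3)
        swapped = simulate_two_sample(cfg)
        import dataclasses
        truth = simulate_two_sample(dataclasses.replace(cfg, swap_fraction=0.0))
        est_sw = summr.ivw(harmonize(swapped.exposure, swapped.outcome)).estimate
        est_tr = summr.ivw(harmonize(truth.exposure, truth.outcome)).estimate
        assert est_sw == pytest.approx(est_tr, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(flips=st.lists(st.booleans(), min_size=8, max_size=8))
    def test_outcome_recoding_invariance(self, flips):
        """Flipping any outcome row's allele representation (swap alleles,
        negate beta, mirror EAF) leaves the harmonized table unchanged."""
        study = simulate_two_sample(SimConfig(k=8, theta=0.3, seed=23,
                                              swap_fraction=0.0))
        base = harmonize(study.exposure, study.outcome)
        recoded = []
        for rec, flip in zip(study.outcome, flips):
            if flip:
                rec = AssociationRecord(
                    snp_id=rec.snp_id, effect_allele=rec.other_allele,
                    other_allele=rec.effect_allele, beta=-rec.beta, se=rec.se,
                    eaf=None if rec.eaf is None else 1 - rec.eaf,
                    pval=rec.pval, n=rec.n)
            recoded.append(rec)
        alt = harmonize(study.exposure, recoded)
        np.testing.assert_allclose(
            alt.table[["beta_exposure", "beta_outcome"]].to_numpy(),
            base.table[["beta_exposure", "beta_outcome"]].to_numpy(), atol=1e-15)

    def test_harmonization_idempotent_on_retained_rows(self, record_factory):
        study = simulate_two_sample(SimConfig(seed=9, swap_fraction=0.4))
        hs1 = harmonize(study.exposure, study.outcome)
        # Rebuild record lists from the harmonized table (all on the exposure
        # allele now) and harmonize again: nothing should change.
        exp_by_id = {r.snp_id: r for r in study.exposure}
        out2 = [AssociationRecord(
            snp_id=row.snp_id, effect_allele=exp_by_id[row.snp_id].effect_allele,
            other_allele=exp_by_id[row.snp_id].other_allele,
            beta=row.beta_outcome, se=row.se_outcome, eaf=row.eaf_outcome)
            for row in hs1.table.itertuples()]
        hs2 = harmonize([exp_by_id[s] for s in hs1.table["snp_id"]], out2)
        np.testing.assert_allclose(hs2.table["beta_outcome"].to_numpy(),
                                   hs1.table["beta_outcome"].to_numpy(), atol=1e-15)

    def test_written_table_has_fixed_column_order(self, tmp_path, record_factory):
        exp = [record_factory()]
        out = [record_factory(beta=0.1)]
        hs = harmonize(exp, out)
        f = tmp_path / "h.tsv"
        hs.write(f)
        header = f.read_text().splitlines()[0].split("\t")
        assert header == ["snp_id", "beta_exposure", "se_exposure",
                          "beta_outcome", "se_outcome", "eaf_exposure",
                          "eaf_outcome", "keep_flag", "drop_reason"]


class TestRecordValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(se=0.0), dict(se=-1.0), dict(eaf=1.5), dict(pval=0.0),
        dict(effect_allele="A", other_allele="A"), dict(effect_allele="N"),
    ])
    def test_invalid_records_rejected(self, record_factory, kwargs):
        with pytest.raises(ValueError):
            record_factory(**kwargs).validate()
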