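"""Cross segregation rules, wild male-specificity, and truth comparisons."""

import numpy as np
import pytest

from parshift.segregation import (
    STATUS_ABSENT,
    STATUS_ALL_MALES,
    STATUS_GE_K_MALES,
    STATUS_IN_FEMALES,
    call_cross_ysnps,
    classify_sharing,
    gene_ysnp_summary,
    sharing_category,
    wild_allele_status,
)
from parshift.types import GenotypeTable, Role, Sample, Sex, Species


def make_cross(father, mother, sons, daughters, extra=()):
    """Build a one-site GenotypeTable plus matching sample sheet."""
    ids, genos, samples = [], [], []
    fam = "f1"
    ids.append("fa"); genos.append(father)
    samples.append(Sample("fa", Species.A, Sex.M, Role.FATHER, fam))
    ids.append("mo"); genos.append(mother)
    samples.append(Sample("mo", Species.A, Sex.F, Role.MOTHER, fam))
    for i, g in enumerate(sons):
        ids.append(f"s{i}"); genos.append(g)
        samples.append(Sample(f"s{i}", Species.A, Sex.M, Role.SON, fam))
    for i, g in enumerate(daughters):
        ids.append(f"d{i}"); genos.append(g)
        samples.append(Sample(f"d{i}", Species.A, Sex.F, Role.DAUGHTER, fam))
    for sid, g, sp, sex in extra:
        ids.append(sid); genos.append(g)
        samples.append(Sample(sid, sp, sex, Role.WILD))
    table = GenotypeTable("g1", np.array([10]), np.array([b"A"]), np.array([b"T"]),
                          np.array([genos], dtype=np.int8), ids)
    return table, samples


class TestCrossCalls:
    def test_textbook_pattern_calls_alt_y_allele(self):
        table, samples = make_cross(1, 0, [1] * 12, [0] * 12)
        (call,) = call_cross_ysnps(table, samples)
        assert call.y_allele == "alt"
        assert call.position == 10

    def test_ref_can_be_the_y_allele(self):
        table, samples = make_cross(1, 2, [1] * 12, [2] * 12)
        (call,) = call_cross_ysnps(table, samples)
        assert call.y_allele == "ref"

    def test_one_carrier_daughter_blocks_the_call(self):
        table, samples = make_cross(1, 0, [1] * 12, [0] * 11 + [1])
        assert call_cross_ysnps(table, samples) == []

    def test_missing_son_below_threshold_blocks_the_call(self):
        sons = [1] * 9 + [-1] * 3
        table, samples = make_cross(1, 0, sons, [0] * 12)
        assert call_cross_ysnps(table, samples, min_sons=10) == []

    def test_homozygous_father_never_calls(self):
        table, samples = make_cross(2, 0, [1] * 12, [1] * 12)
        assert call_cross_ysnps(table, samples) == []

    def test_missing_mother_is_uncallable(self):
        table, samples = make_cross(1, -1, [1] * 12, [0] * 12)
        assert call_cross_ysnps(table, samples) == []

    def test_no_father_raises(self):
        table = GenotypeTable("g1", np.array([0]), np.array([b"A"]), np.array([b"T"]),
                              np.array([[0]], dtype=np.int8), ["w1"])
        samples = [Sample("w1", Species.A, Sex.M, Role.WILD)]
        with pytest.raises(ValueError, match="father"):
            call_cross_ysnps(table, samples)


class TestWildStatus:
    def wild_panel(self, male_genos, female_genos):
        extra = [(f"wm{i}", g, Species.A, Sex.M) for i, g in enumerate(male_genos)]
        extra += [(f"wf{i}", g, Species.A, Sex.F) for i, g in enumerate(female_genos)]
        return make_cross(1, 0, [1] * 12, [0] * 12, extra=extra)

    def test_three_of_seven_males_no_females_is_lenient(self):
        table, samples = self.wild_panel([1, 1, 1, 0, 0, 0, 0], [0] * 7)
        status, counts = wild_allele_status(table, samples, Species.A, 0, "alt", k=2)
        assert status == STATUS_GE_K_MALES
        assert counts == (3, 7, 0, 7)

    def test_all_seven_males_is_strict(self):
        table, samples = self.wild_panel([1] * 7, [0] * 7)
        status, _ = wild_allele_status(table, samples, Species.A, 0, "alt", k=2)
        assert status == STATUS_ALL_MALES

    def test_any_female_carrier_overrides(self):
        table, samples = self.wild_panel([1, 1, 0, 0, 0, 0, 0], [1] + [0] * 6)
        status, _ = wild_allele_status(table, samples, Species.A, 0, "alt", k=2)
        assert status == STATUS_IN_FEMALES

    def test_single_carrier_male_is_absent_at_k2(self):
        table, samples = self.wild_panel([1, 0, 0, 0, 0, 0, 0], [0] * 7)
        status, _ = wild_allele_status(table, samples, Species.A, 0, "alt", k=2)
        assert status == STATUS_ABSENT


class TestSharing:
    def build(self, a_males, a_females, b_males, b_females, c_male, c_female):
        extra = [(f"awm{i}", g, Species.A, Sex.M) for i, g in enumerate(a_males)]
        extra += [(f"awf{i}", g, Species.A, Sex.F) for i, g in enumerate(a_females)]
        extra += [(f"bwm{i}", g, Species.B, Sex.M) for i, g in enumerate(b_males)]
        extra += [(f"bwf{i}", g, Species.B, Sex.F) for i, g in enumerate(b_females)]
        extra += [("cm", c_male, Species.C, Sex.M), ("cf", c_female, Species.C, Sex.F)]
        table, samples = make_cross(1, 0, [1] * 12, [0] * 12, extra=extra)
        calls = call_cross_ysnps(table, samples)
        return classify_sharing(calls, table, samples)

    def test_male_specific_everywhere_is_shared_ancient(self):
        (call,) = self.build([1] * 7, [0] * 7, [1] * 7, [0] * 7, 1, 0)
        assert sharing_category(call) == "shared_ancient"
        assert call.male_specific(Species.A, strict=True)

    def test_a_only_is_the_mid_region_signature(self):
        (call,) = self.build([1] * 7, [0] * 7, [0] * 7, [1, 1, 0, 0, 0, 0, 0], 0, 0)
        assert sharing_category(call) == "A_specific"

    def test_present_in_a_females_reported_separately(self):
        (call,) = self.build([1, 1, 0, 0, 0, 0, 0], [1] + [0] * 6, [0] * 7, [0] * 7, 0, 0)
        assert sharing_category(call) == "in_females_A"

    def test_lenient_set_contains_strict_set(self, default_dataset):
        ds = default_dataset
        for table in ds.tables[::7]:
            calls = call_cross_ysnps(table, ds.samples)
            classify_sharing(calls, table, ds.samples)
            for c in calls:
                for sp in (Species.A, Species.B):
                    if c.male_specific(sp, strict=True):
                        assert c.male_specific(sp, strict=False)


class TestTruthComparison:
    def test_sexlinked_calls_equal_planted_father_xy_differences(self, default_dataset):
        """In sex-linked regimes the cross calls must be exactly the
        father's X/Y fixed differences; in PAR genes any call requires a
        recombination-free transmission pattern across all progeny."""
        ds = default_dataset
        phases = ds.truth.paternal_phase
        for table in ds.tables:
            calls = call_cross_ysnps(table, ds.samples)
            regime = ds.truth.regimes[table.gene_id]
            planted = ds.truth.father_xy_diffs[table.gene_id]
            if regime in ("mid", "right"):
                called = {c.position: c.y_allele for c in calls}
                # zero false positives: every call is a planted difference
                assert all(planted.get(p) == a for p, a in called.items())
                # every miss is explained by the mother carrying the Y allele
                # (the father->sons pattern is then not diagnostic)
                j = {sid: k for k, sid in enumerate(table.sample_ids)}
                for p, a in planted.items():
                    if p in called:
                        continue
                    i = int(np.searchsorted(table.positions, p))
                    mo = table.geno[i, j["A_mother"]]
                    carries = mo >= 1 if a == "alt" else 0 <= mo <= 1
                    assert carries or mo < 0
            elif calls:
                sons = [p for p in phases if p.startswith("A_son")]
                daus = [p for p in phases if p.startswith("A_dau")]
                assert all(phases[p][table.gene_id] == "Y" for p in sons)
                assert all(phases[p][table.gene_id] == "X" for p in daus)

    def test_no_call_in_par_gene_with_recombinant_son(self, default_dataset):
        ds = default_dataset
        phases = ds.truth.paternal_phase
        sons = [p for p in phases if p.startswith("A_son")]
        for table in ds.tables:
            if ds.truth.regimes[table.gene_id] != "left":
                continue
            if any(phases[p][table.gene_id] == "X" for p in sons):
                assert call_cross_ysnps(table, ds.samples) == []


class TestSummary:
    def test_empty_gene_rows_are_zero(self, default_dataset):
        ds = default_dataset
        calls = {t.gene_id: [] for t in ds.tables}
        df = gene_ysnp_summary(calls, ds.annotations)
        assert (df.drop(columns="map_pos_cM") == 0).all().all()
        assert list(df.index) == [f"g{i + 1:03d}" for i in range(57)]

    def test_counts_equal_per_snp_sums(self, default_dataset):
        ds = default_dataset
        calls_by_gene = {}
        for table in ds.tables[:10]:
            calls = call_cross_ysnps(table, ds.samples)
            classify_sharing(calls, table, ds.samples)
            calls_by_gene[table.gene_id] = calls
        df = gene_ysnp_summary(calls_by_gene, {g: ds.annotations[g] for g in calls_by_gene})
        for gene, calls in calls_by_gene.items():
            assert df.loc[gene, "n_cross"] == len(calls)
            assert df.loc[gene, "A_lenient"] == sum(c.male_specific(Species.A) for c in calls)
            assert df.loc[gene, "A_strict"] == sum(c.male_specific(Species.A, strict=True) for c in calls)
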