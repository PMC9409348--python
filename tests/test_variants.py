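"""Genotype-pattern filters, merge semantics and site-list statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexvarscan.depth import DepthMatrix
from sexvarscan.variants import (
    MergedSite,
    VariantClass,
    VariantFormatError,
    VariantRecord,
    classify_variant,
    filter_quality,
    interspecies_fixed_variants,
    merge_samples,
    per_segment_counts,
    sex_associated_variants,
    variant_class_proportions,
    variant_spacing_stats,
)


def rec(pos=100, qual=50.0, gt="1/1", sample="s1", contig="c1", ref="A", alt="G"):
    return VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt, qual=qual,
                         genotype=gt, sample=sample)


def site(contig, pos, genotypes, ref="A", alt="G"):
    return MergedSite(contig=contig, pos=pos, ref=ref, alt=alt, genotypes=genotypes)


def uniform_matrix(samples, length=1000, depth=5, contig="c1"):
    return DepthMatrix(
        samples=list(samples),
        depth={contig: np.full((len(samples), length), depth, dtype=np.int64)},
    )


class TestQualityFilter:
    def test_boundary_strictly_greater(self):
        records = [rec(qual=30.0), rec(qual=30.01), rec(qual=29.99), rec(qual=100.0)]
        kept = list(filter_quality(records))
        assert [r.qual for r in kept] == [30.01, 100.0]  # order preserved

    def test_retained_set_equals_planted_pass_set(self, cohort, all_merged_filtered):
        t = cohort.truth
        keys = {(s.contig, s.pos) for s in all_merged_filtered}
        assert keys & t.decoy_sites == set()
        assert keys == t.fixed_sites | t.sex_sites | t.noise_sites


class TestMerge:
    def test_all_hom_alt(self):
        streams = {f"s{i}": [rec(sample=f"s{i}")] for i in range(10)}
        (m,) = merge_samples(streams)
        assert (m.ac, m.an, m.af) == (20, 20, 1.0)

    def test_one_sample_absent(self):
        streams = {f"s{i}": [rec(sample=f"s{i}")] for i in range(9)}
        streams["s9"] = []
        (m,) = merge_samples(streams)
        assert (m.ac, m.an, m.af) == (18, 18, 1.0)
        assert m.genotypes["s9"] is None

    def test_conflicting_ref_positions_excluded(self, caplog):
        streams = {
            "s1": [rec(sample="s1", ref="A", alt="G")],
            "s2": [rec(sample="s2", ref="C", alt="G", pos=100)],
            "s3": [rec(sample="s3", pos=200)],
        }
        with caplog.at_level("WARNING"):
            merged = merge_samples(streams)
        assert [m.pos for m in merged] == [200]
        assert "conflicting REF" in caplog.text

    def test_site_count_matches_truth_union(self, cohort, all_merged_filtered):
        t = cohort.truth
        expected = t.fixed_sites | t.sex_sites | t.noise_sites
        assert {(s.contig, s.pos) for s in all_merged_filtered} == expected


class TestInterspeciesFixed:
    def test_all_ten_hom_alt_included(self):
        m = site("c1", 5, {f"s{i}": "1/1" for i in range(10)})
        assert interspecies_fixed_variants([m]) == [m]

    def test_one_het_excluded(self):
        gts = {f"s{i}": "1/1" for i in range(9)}
        gts["s9"] = "0/1"
        assert interspecies_fixed_variants([site("c1", 5, gts)]) == []

    def test_missing_genotype_disqualifies(self):
        gts = {f"s{i}": "1/1" for i in range(9)}
        gts["s9"] = None
        assert interspecies_fixed_variants([site("c1", 5, gts)]) == []

    def test_recovers_planted_fixed_sites(self, cohort, all_merged_filtered):
        found = {
            (s.contig, s.pos)
            for s in interspecies_fixed_variants(all_merged_filtered, n_samples=10)
        }
        assert found == cohort.truth.fixed_sites

    def test_monotone_in_min_qual(self, cohort):
        from conftest import read_records

        samples = cohort.male_samples + cohort.female_samples
        prev = None
        for q in (0.0, 30.0, 60.0, 90.0):
            merged = merge_samples(
                {s: read_records(cohort, s, True, min_qual=q) for s in samples}, samples
            )
            found = {(s.contig, s.pos) for s in interspecies_fixed_variants(merged)}
            if prev is not None:
                assert found <= prev
            prev = found


MALES = [f"m{i}" for i in range(5)]
FEMALES = [f"f{i}" for i in range(5)]


def male_site(pos=100, gt="1/1"):
    return site("c1", pos, {s: gt for s in MALES})


class TestSexAssociated:
    def matrix(self, depth=5):
        return uniform_matrix(MALES + FEMALES, depth=depth)

    def test_recordless_females_reported(self):
        out = sex_associated_variants([male_site()], [], self.matrix())
        assert [s.pos for s in out] == [100]

    def test_female_hom_alt_disqualifies_even_low_qual(self):
        f = site("c1", 100, {s: ("1/1" if s == "f0" else None) for s in FEMALES})
        out = sex_associated_variants([male_site()], [f], self.matrix())
        assert out == []

    def test_female_het_and_ref_allowed(self):
        f = site("c1", 100, {"f0": "0/1", "f1": "0/0", "f2": None, "f3": None, "f4": None})
        out = sex_associated_variants([male_site()], [f], self.matrix())
        assert [s.pos for s in out] == [100]
        assert out[0].genotypes["f0"] == "0/1"

    def test_depth_boundary_strictly_greater_than_two(self):
        assert sex_associated_variants([male_site()], [], self.matrix(depth=2)) == []
        assert len(sex_associated_variants([male_site()], [], self.matrix(depth=3))) == 1

    def test_one_male_not_hom_alt_disqualifies(self):
        m = site("c1", 100, {**{s: "1/1" for s in MALES[:-1]}, "m4": "0/1"})
        assert sex_associated_variants([m], [], self.matrix()) == []

    def test_missing_depth_contig_is_hard_error(self):
        m = site("c9", 100, {s: "1/1" for s in MALES})
        with pytest.raises(KeyError, match="depth matrix"):
            sex_associated_variants([m], [], self.matrix())

    def test_recovers_planted_sex_sites_exactly(
        self, cohort, depth_matrix, male_merged, female_merged_unfiltered
    ):
        out = sex_associated_variants(male_merged, female_merged_unfiltered, depth_matrix)
        assert {(s.contig, s.pos) for s in out} == cohort.truth.sex_sites

    def test_monotone_in_depth_gate(
        self, depth_matrix, male_merged, female_merged_unfiltered
    ):
        prev = None
        for gate in (0, 2, 5, 15, 25):
            out = sex_associated_variants(
                male_merged, female_merged_unfiltered, depth_matrix,
                min_depth_exclusive=gate,
            )
            found = {(s.contig, s.pos) for s in out}
            if prev is not None:
                assert found <= prev
            prev = found


class TestClassify:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", VariantClass.SNP),
            ("A", "AT", VariantClass.INSERTION),
            ("ACT", "A", VariantClass.DELETION),
            ("AC", "GT", VariantClass.MNP_OTHER),
            ("TA", "CA", VariantClass.MNP_OTHER),  # no shared first base
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_variant(ref, alt) == expected

    def test_non_acgt_rejected(self):
        with pytest.raises(VariantFormatError):
            classify_variant("A", "N")

    def test_proportions_sum_to_100(self):
        sites = [site("c1", i + 1, {"s": "1/1"}, ref="A", alt="G") for i in range(90)]
        sites += [site("c1", 200 + i, {"s": "1/1"}, ref="A", alt="AT") for i in range(10)]
        props = variant_class_proportions(sites)
        assert props["SNP"] == 90.0 and props["insertion"] == 10.0
        assert sum(props.values()) == 100.0


class TestSpacing:
    def test_worked_example(self):
        stats = variant_spacing_stats([("c1", 100), ("c1", 200), ("c1", 350)])
        assert stats.distances == {"c1": [100, 150]}
        assert stats.mean_distance == 125.0

    def test_single_variant_per_contig_mean_absent(self):
        stats = variant_spacing_stats([(f"c{i}", 10) for i in range(5)])
        assert stats.n_distances == 0 and stats.mean_distance is None

    def test_matches_bruteforce(self, cohort):
        sites = sorted(cohort.truth.fixed_sites | cohort.truth.sex_sites)
        stats = variant_spacing_stats(sites)
        # oracle: all consecutive pairs per contig, computed directly
        expected = []
        by_contig = {}
        for c, p in sites:
            by_contig.setdefault(c, []).append(p)
        for c, ps in by_contig.items():
            ps = sorted(set(ps))
            expected += [b - a for a, b in zip(ps, ps[1:])]
        assert stats.n_distances == len(expected)
        assert stats.mean_distance == pytest.approx(sum(expected) / len(expected))
        assert all(d > 0 for ds in stats.distances.values() for d in ds)


class TestSegments:
    def test_worked_example_partial_last_window(self):
        counts = per_segment_counts(
            [("c1", 5), ("c1", 10_005), ("c1", 10_006)], {"c1": 25_000}
        )
        assert counts.counts["c1"].tolist() == [1, 2, 0]
        assert counts.mean_including_empty == 1.0
        assert counts.mean_excluding_empty == 1.5

    def test_no_variants(self):
        counts = per_segment_counts([], {"c1": 25_000})
        assert counts.counts["c1"].tolist() == [0, 0, 0]
        assert counts.mean_excluding_empty is None

    def test_site_beyond_contig_rejected(self):
        with pytest.raises(ValueError, match="beyond contig length"):
            per_segment_counts([("c1", 30_000)], {"c1": 25_000})

    def test_conservation_on_cohort(self, cohort, sim_config):
        sites = sorted(cohort.truth.sex_sites)
        counts = per_segment_counts(sites, sim_config.contig_lengths)
        assert counts.total_variants == len(sites)

    @given(
        positions=st.lists(st.integers(min_value=1, max_value=50_000), max_size=60),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, positions):
        sites = [("c1", p) for p in positions]
        counts = per_segment_counts(sites, {"c1": 50_000})
        assert counts.total_variants == len(sites)
        if counts.n_nonempty_windows < counts.n_windows and positions:
            assert counts.mean_including_empty <= counts.mean_excluding_empty
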