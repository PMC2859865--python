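import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovicnv import delpoly as dp
from bovicnv import synthetic_data as sd
from bovicnv.array_io import PedigreePair, SampleQC, compute_sample_qc
from conftest import make_marker_map, make_table, true_six_genotype


class TestMendelError:
    @pytest.mark.parametrize(
        "sire, steer, expected",
        [
            ("BB", "AA", True),  # the worked deletion artefact: B/- sire, A/- steer
            ("AA", "BB", True),
            ("AA", "AA", False),
            ("AB", "AA", False),
            ("AB", "BB", False),
            ("AB", "AB", False),
            ("BB", "AB", False),
        ],
    )
    def test_only_opposite_homozygotes_flagged(self, sire, steer, expected):
        assert dp.mendel_error(sire, steer) is expected

    def test_nc_input_rejected(self):
        with pytest.raises(ValueError, match="pre-filter"):
            dp.mendel_error("NC", "AA")


class TestPcErrorFrequencies:
    def build(self, sire_col, steer_cols):
        n_m = 1
        markers = make_marker_map(n_m)
        n = 1 + len(steer_cols)
        gt = np.array([[sire_col]] + [[g] for g in steer_cols], dtype=object)
        lrr = np.zeros((n, n_m))
        baf = np.full((n, n_m), 0.5)
        r = np.ones((n, n_m))
        table = make_table(lrr, baf, r, gt, markers)
        pairs = [PedigreePair("S1", f"S{i + 2}") for i in range(len(steer_cols))]
        return table, pairs

    def test_nine_errors_over_156_pairs(self):
        steers = ["AA"] * 9 + ["BB"] * 147  # sire BB: 9 opposite-homozygote duos
        table, pairs = self.build("BB", steers)
        (stat,) = dp.pc_error_frequencies(table, pairs)
        assert stat.n_pairs_informative == 156
        assert stat.n_errors == 9
        assert stat.pc_error_freq == pytest.approx(9 / 156)
        assert round(stat.pc_error_freq, 3) == 0.058

    def test_all_nc_marker_has_missing_frequency(self):
        table, pairs = self.build("NC", ["NC", "NC"])
        (stat,) = dp.pc_error_frequencies(table, pairs)
        assert stat.n_pairs_informative == 0
        assert stat.pc_error_freq is None

    def test_nc_pairs_not_informative(self):
        table, pairs = self.build("BB", ["AA", "NC", "BB"])
        (stat,) = dp.pc_error_frequencies(table, pairs)
        assert stat.n_pairs_informative == 2
        assert stat.n_errors == 1


class TestSelectCandidates:
    def stats(self, freqs):
        return [
            dp.MendelMarkerStat(f"m{i}", 1000, round(f * 1000))
            for i, f in enumerate(freqs)
        ]

    def test_strict_threshold_boundary(self):
        sel = dp.select_candidates(self.stats([0.058, 0.030, 0.031, 0.0]))
        assert sel == ["m0", "m2"]

    def test_inclusive_variant(self):
        sel = dp.select_candidates(self.stats([0.030]), strict=False)
        assert sel == ["m0"]

    def test_empty_and_missing(self):
        assert dp.select_candidates([]) == []
        stats = [dp.MendelMarkerStat("m0", 0, 0)]
        assert dp.select_candidates(stats) == []


class TestSixGenotypeClassifier:
    def test_all_diploid_marker_has_no_cluster_evidence(self):
        rng = np.random.default_rng(0)
        n = 60
        markers = make_marker_map(1)
        baf = rng.choice([0.0, 0.5, 1.0], (n, 1)) + rng.normal(0, 0.02, (n, 1))
        table = make_table(
            rng.normal(0, 0.1, (n, 1)),
            np.clip(baf, 0, 1),
            rng.normal(1.0, 0.05, (n, 1)),
            np.full((n, 1), "AB", object),
            markers,
        )
        res = dp.classify_six_genotypes(table, markers.marker_ids[0])
        assert res.cluster_evidence is False
        assert set(res.labels.unique()) <= {"AA", "AB", "BB"}

    def test_near_zero_intensity_is_null_del(self):
        markers = make_marker_map(1)
        r = np.array([[1.0]] * 20 + [[0.01]])
        baf = np.array([[0.0]] * 10 + [[1.0]] * 10 + [[0.4]])
        table = make_table(
            np.zeros((21, 1)), baf, r, np.full((21, 1), "AA", object), markers
        )
        res = dp.classify_six_genotypes(table, markers.marker_ids[0])
        assert res.labels.iloc[-1] == "null_del"

    def test_too_few_samples_gives_missing_classification(self, small_table):
        params = dp.SixGenotypeParams(min_called=10)
        res = dp.classify_six_genotypes(small_table, small_table.markers.marker_ids[0], params)
        assert res.labels.empty and res.cluster_evidence is False

    def test_agreement_with_simulation_truth_at_common_deletion(self):
        spec = sd.CNVEventSpec(1, 1_000_000, 2_000_000, 1, 0.2)
        cfg = sd.SimulationConfig(
            seed=17, n_sires=10, n_steers=190, n_chromosomes=1, n_markers=100,
            event_specs=[spec],
        )
        ds = sd.simulate_dataset(cfg)
        for marker in ds.markers.markers_in(1, spec.start, spec.end):
            res = dp.classify_six_genotypes(ds.table, marker)
            truth = pd.Series(
                [true_six_genotype(ds, s, marker) for s in res.labels.index],
                index=res.labels.index,
            )
            assert (res.labels == truth).mean() >= 0.95
            assert res.cluster_evidence


class TestPairwiseScan:
    def table_with_ratio(self, r_target, r_ref=None):
        markers = make_marker_map(len(r_target))
        n_m = len(r_target)
        r = np.array([r_target, r_ref or [3.2] * n_m])
        return make_table(
            np.zeros((2, n_m)),
            np.full((2, n_m), 0.5),
            r,
            np.full((2, n_m), "AB", object),
            markers,
        )

    def test_deletion_side_hit(self):
        table = self.table_with_ratio([1.0, 3.2, 6.4])
        hits = dp.pairwise_scan(table, "S1", "S2")
        assert len(hits) == 1
        assert hits[0].log2_ratio == pytest.approx(np.log2(1.0 / 3.2))
        assert hits[0].is_deletion_side

    def test_equal_and_double_intensity_below_threshold(self):
        table = self.table_with_ratio([3.2, 6.4])
        assert dp.pairwise_scan(table, "S1", "S2") == []

    def test_missing_intensity_skipped(self):
        table = self.table_with_ratio([np.nan, 0.1])
        hits = dp.pairwise_scan(table, "S1", "S2")
        assert [h.marker_id for h in hits] == [table.markers.marker_ids[1]]

    def test_target_equals_reference_rejected(self):
        table = self.table_with_ratio([1.0])
        with pytest.raises(ValueError):
            dp.pairwise_scan(table, "S1", "S1")

    def test_swap_symmetry_flips_ratio_sign(self):
        table = self.table_with_ratio([0.2, 1.0, 9.9])
        fwd = {h.marker_id: h.log2_ratio for h in dp.pairwise_scan(table, "S1", "S2")}
        rev = {h.marker_id: h.log2_ratio for h in dp.pairwise_scan(table, "S2", "S1")}
        assert fwd.keys() == rev.keys()
        for m in fwd:
            assert fwd[m] == pytest.approx(-rev[m])

    def test_reference_selection_prefers_lowest_noise(self):
        qc = [SampleQC("a", 0.25, 1.0), SampleQC("b", 0.05, 1.0), SampleQC("c", 0.4, 1.0)]
        assert dp.select_reference_sample(qc) == "b"


class TestMergeMethods:
    def test_dual_catalogue_counts(self):
        shared = [f"BOTH{i}" for i in range(95)]
        a = shared + [f"HER{i}" for i in range(256)]  # |A| = 351
        b = shared + [f"PW{i}" for i in range(97)]  # |B| = 192
        merged = dp.merge_methods(a, b)
        assert len(merged) == 448
        assert sum(d.methods == {"heritability", "pairwise"} for d in merged) == 95

    def test_disjoint_inputs_add(self):
        merged = dp.merge_methods(["m1"], ["m2", "m3"])
        assert len(merged) == 3

    def test_identical_inputs_all_both_flagged(self):
        merged = dp.merge_methods(["m1", "m2"], ["m2", "m1"])
        assert len(merged) == 2
        assert all(d.methods == {"heritability", "pairwise"} for d in merged)

    @settings(deadline=None, max_examples=60)
    @given(
        st.sets(st.integers(0, 60)),
        st.sets(st.integers(0, 60)),
    )
    def test_inclusion_exclusion_identity(self, a, b):
        if not a and not b:
            return
        merged = dp.merge_methods([f"m{i}" for i in a], [f"m{i}" for i in b])
        assert len(merged) == len(a) + len(b) - len(a & b)


class TestAncillaryFlags:
    def test_exact_hwe_proportions_have_p_near_one(self):
        assert dp.marker_hwe_chi2(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit(self):
        from scipy import stats as ss
        p = dp.marker_hwe_chi2(50, 0, 50)
        assert p == pytest.approx(ss.chi2.sf(100, 1))
        assert p < 1e-20

    def test_monomorphic_marker_has_missing_p(self):
        assert dp.marker_hwe_chi2(100, 0, 0) is None

    def test_missing_rate_counts_nc_fraction(self):
        col = pd.Series(["AA"] * 12 + ["NC"] * 3)
        assert dp.marker_missing_rate(col) == pytest.approx(0.2)


class TestPairQC:
    def test_concordant_families_pass_filter(self, cohort):
        kept = dp.filter_pairs(cohort.table, cohort.pedigree, min_concordance=0.99)
        assert kept == cohort.pedigree

    def test_shuffled_pairs_fail_concordance(self, cohort):
        # pair a sire with an unrelated steer: errors appear genome-wide
        bogus = [PedigreePair("SIRE001", "STEER0002")]
        conc = dp.pair_heritability_concordance(cohort.table, bogus)
        real = dp.pair_heritability_concordance(cohort.table, cohort.pedigree[:1])
        assert list(conc.values())[0] < list(real.values())[0]
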