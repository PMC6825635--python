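import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microvasc as mv
from microvasc.errors import ConsistencyError, DegenerateInputError, ParameterError
from microvasc.reference_data import (
    UTUC_PILOT_ROWS,
    load_utuc_pilot_features,
    utuc_pilot_summaries,
)

SP = (5.0, 5.0, 5.0)


class TestSectionDensities:
    def test_half_positive_section_is_fifty(self):
        a = np.zeros((1, 4, 4), dtype=bool)
        a[0, :2, :] = True
        s = mv.section_densities(mv.BinaryMask(a, SP))
        assert s.densities.tolist() == [50.0]

    def test_empty_mask_all_zero(self):
        s = mv.section_densities(mv.BinaryMask(np.zeros((5, 3, 3), dtype=bool), SP))
        assert s.n_sections == 5
        assert (s.densities == 0).all()

    def test_seeded_random_mask_matches_direct_count(self, rng):
        a = rng.random((8, 6, 7)) < 0.3
        s = mv.section_densities(mv.BinaryMask(a, SP))
        for k in range(8):
            assert s.densities[k] == 100.0 * a[k].sum() / (6 * 7)

    def test_tissue_mask_denominator_and_dropped_sections(self, rng):
        a = rng.random((4, 5, 5)) < 0.5
        tissue = np.ones((4, 5, 5), dtype=bool)
        tissue[2] = False  # section 2 has no tissue: dropped
        s = mv.section_densities(mv.BinaryMask(a, SP), mv.BinaryMask(tissue, SP))
        assert s.n_sections == 3
        with pytest.raises(ConsistencyError):
            mv.section_densities(
                mv.BinaryMask(a, SP),
                mv.BinaryMask(np.ones((3, 5, 5), dtype=bool), SP),
            )
        with pytest.raises(DegenerateInputError):
            mv.section_densities(
                mv.BinaryMask(a, SP),
                mv.BinaryMask(np.zeros((4, 5, 5), dtype=bool), SP),
            )


class TestHeterogeneityFeatures:
    def test_constant_series_undefined_moments(self):
        f = mv.heterogeneity_features(mv.SectionDensitySeries(np.full(10, 25.0)))
        assert f.variance == 0.0
        assert np.isnan(f.skewness) and np.isnan(f.kurtosis)

    def test_too_few_sections_rejected(self):
        with pytest.raises(DegenerateInputError):
            mv.heterogeneity_features(mv.SectionDensitySeries(np.array([1.0, 2.0, 3.0])))

    def test_variance_on_fraction_scale(self):
        # densities 10% and 30%: population variance of (0.1, 0.3) is 0.01
        f = mv.heterogeneity_features(
            mv.SectionDensitySeries(np.array([10.0, 30.0, 10.0, 30.0]))
        )
        assert f.mean_density == pytest.approx(20.0)
        assert f.variance == pytest.approx(0.01)

    def test_gaussian_moments_recovered(self):
        r = mv.generate_density_series(100_000, "gaussian", {"mu": 20, "sigma": 5}, seed=42)
        f = mv.heterogeneity_features(r.series)
        assert abs(f.skewness - r.theoretical_skewness) <= 0.05
        assert abs(f.kurtosis - r.theoretical_excess_kurtosis) <= 0.1

    def test_exponential_moments_recovered(self):
        r = mv.generate_density_series(200_000, "exponential", {"mean": 5}, seed=42)
        f = mv.heterogeneity_features(r.series)
        assert abs(f.skewness - 2.0) <= 0.15
        assert abs(f.kurtosis - 6.0) <= 0.8

    def test_moment_inequality_holds(self, rng):
        # excess kurtosis >= skewness^2 - 2 for any distribution
        for _ in range(10):
            d = rng.random(50) * 100
            f = mv.heterogeneity_features(mv.SectionDensitySeries(d))
            assert f.kurtosis >= f.skewness**2 - 2 - 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariances(self, seed):
        """Permutation invariance; shift changes only the mean; positive
        scaling leaves the standardized moments unchanged."""
        rng = np.random.default_rng(seed)
        d = rng.random(40) * 50 + 1
        base = mv.heterogeneity_features(mv.SectionDensitySeries(d))
        perm = mv.heterogeneity_features(
            mv.SectionDensitySeries(rng.permutation(d))
        )
        assert perm.variance == pytest.approx(base.variance)
        assert perm.skewness == pytest.approx(base.skewness)
        assert perm.kurtosis == pytest.approx(base.kurtosis)
        shifted = mv.heterogeneity_features(mv.SectionDensitySeries(d + 10))
        assert shifted.mean_density == pytest.approx(base.mean_density + 10)
        assert shifted.variance == pytest.approx(base.variance)
        assert shifted.skewness == pytest.approx(base.skewness)
        assert shifted.kurtosis == pytest.approx(base.kurtosis)
        scaled = mv.heterogeneity_features(mv.SectionDensitySeries(d * 1.5))
        assert scaled.skewness == pytest.approx(base.skewness)
        assert scaled.kurtosis == pytest.approx(base.kurtosis)


class TestSummaries:
    def test_sample_summary_copies_published_row_verbatim(self):
        sid, label, dens, var, kurt, skew, radius, n = UTUC_PILOT_ROWS[0]
        s = utuc_pilot_summaries()[0]
        row = s.as_row()
        assert row["sample_id"] == sid and row["label"] == label
        assert row["cd34_density"] == dens
        assert row["variance"] == var
        assert row["kurtosis"] == kurt
        assert row["skewness"] == skew
        assert row["vessel_radius_um"] == radius
        assert row["n_sections"] == n

    def test_missing_graph_gives_nan_radius(self):
        f = mv.HeterogeneityFeatures(10.0, 0.001, 1.0, 0.5, 100)
        s = mv.summarize_sample("x", "TaG1", f, None)
        assert np.isnan(s.mean_vessel_radius_um)

    def test_empty_label_rejected(self):
        f = mv.HeterogeneityFeatures(10.0, 0.001, 1.0, 0.5, 100)
        with pytest.raises(ParameterError):
            mv.summarize_sample("x", "", f)


class TestAggregation:
    def test_single_summary_is_identity(self):
        s = utuc_pilot_summaries()[0]
        g = mv.aggregate_group([s], "TaG1")
        assert g.n_samples == 1
        assert g.kurtosis == s.features.kurtosis
        assert g.vessel_radius_um == s.mean_vessel_radius_um

    def test_published_group_means(self):
        summaries = utuc_pilot_summaries()
        ta = mv.aggregate_group([s for s in summaries if s.label == "TaG1"], "TaG1")
        t3 = mv.aggregate_group([s for s in summaries if s.label == "T3G3"], "T3G3")
        assert ta.kurtosis == pytest.approx((2.870 + 4.865) / 2)  # 3.8675
        assert t3.kurtosis == pytest.approx((16.09 + 23.01) / 2)  # 19.55
        assert ta.n_samples == t3.n_samples == 2

    def test_idempotence_of_identical_summaries(self):
        s = utuc_pilot_summaries()[2]
        g = mv.aggregate_group([s, s, s], "T3G3")
        for key in ("cd34_density", "variance", "kurtosis", "skewness"):
            assert g.as_row()[key] == pytest.approx(s.as_row()[key])

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mv.aggregate_group([], "x")


class TestCompareGroups:
    def test_invasive_exceeds_superficial_in_heterogeneity(self):
        summaries = utuc_pilot_summaries()
        ta = mv.aggregate_group([s for s in summaries if s.label == "TaG1"], "TaG1")
        t3 = mv.aggregate_group([s for s in summaries if s.label == "T3G3"], "T3G3")
        table = mv.compare_groups(ta, t3).set_index("feature")
        assert table.loc["kurtosis", "difference"] > 0
        assert table.loc["skewness", "difference"] > 0

    def test_identical_groups_zero_difference(self):
        s = utuc_pilot_summaries()[0]
        g = mv.aggregate_group([s], "TaG1")
        table = mv.compare_groups(g, g)
        assert (table["difference"] == 0).all()


def test_reference_table_shape():
    df = load_utuc_pilot_features()
    assert list(df.columns) == mv.summaries_to_frame(utuc_pilot_summaries()).columns.tolist()
    assert len(df) == 4
    assert df["label"].tolist() == ["TaG1", "TaG1", "T3G3", "T3G3"]
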