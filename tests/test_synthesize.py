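"""Generator calibration, rasterization accuracy, and population sampling."""

import numpy as np
import pandas as pd
import pytest

from conftest import caliper_oracle, depression_oracle, square_contour
from sporemorph import (
    InfeasibleConcavityError,
    PopulationConfig,
    SporeContour,
    SporeShapeParams,
    generate_contour,
    load_preset,
    mediterraneensis_like,
    pulverulentus_like,
    rasterize,
    sample_population,
)


class TestGenerateContour:
    @pytest.mark.parametrize("target", [0.0, 0.02, 0.04, 0.08])
    def test_concavity_calibration_against_shoelace_oracle(self, target):
        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, target))
        assert abs(depression_oracle(c.vertices) / 100.0 - target) <= 5e-4

    @pytest.mark.parametrize("family", ["ellipsoid", "subamygdaliform", "amygdaliform"])
    def test_caliper_length_and_width_match_request(self, family):
        p = SporeShapeParams(family, 12.29, 4.87, 0.7, 0.3, 0.03)
        c = generate_contour(p)
        assert caliper_oracle(c.vertices) == pytest.approx(12.29, rel=0.01)
        # width = full y-extent for these axis-aligned silhouettes
        w = c.vertices[:, 1].max() - c.vertices[:, 1].min()
        assert w == pytest.approx(4.87, rel=0.01)

    def test_zero_target_gives_exactly_convex_shape(self):
        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, 0.0))
        assert depression_oracle(c.vertices) == pytest.approx(0.0, abs=1e-9)

    def test_pulverulentus_fixture_in_pronounced_regime(self):
        # the amygdaliform species-mean silhouette must exceed the 3% bound
        assert depression_oracle(pulverulentus_like().vertices) > 3.0

    def test_mediterraneensis_fixture_in_shallow_regime(self):
        assert depression_oracle(mediterraneensis_like().vertices) < 2.5

    def test_deterministic_for_fixed_inputs(self):
        p = SporeShapeParams("amygdaliform", 12, 5, 0.5, 0.2, 0.035)
        a, b = generate_contour(p), generate_contour(p)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_infeasible_target_names_attainable_range(self):
        with pytest.raises(InfeasibleConcavityError, match="attainable"):
            generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, 0.2, 0.2))

    def test_amygdaliform_floor_concavity_is_reported(self):
        # the apiculus makes a perfectly convex amygdaliform shape impossible
        with pytest.raises(InfeasibleConcavityError) as exc:
            generate_contour(SporeShapeParams("amygdaliform", 12.29, 4.87, 0.7, 0.3, 0.0))
        assert exc.value.attainable_min > 0


class TestRasterize:
    def test_square_pixel_count_recovers_area(self):
        mask = rasterize(SporeContour(square_contour(10.0)), 0.1)
        assert mask.area_um2 == pytest.approx(100.0, rel=0.02)

    def test_ellipse_mask_area_matches_analytic(self):
        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.0, 0, 0.0))
        mask = rasterize(c, 0.02)
        assert mask.area_um2 == pytest.approx(np.pi * 12 * 5 / 4, rel=0.01)

    def test_halving_scale_at_least_halves_area_error(self):
        # error averaged over sub-pixel grid offsets (at any single offset
        # the signed pixel-count error can accidentally cancel)
        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, 0.04))
        truth = c.area_um2

        def mean_err(s):
            errs = []
            for k in range(8):
                off = np.array([k / 8 * s, k / 8 * s * 0.61803])
                moved = SporeContour(c.vertices + off, None)
                errs.append(abs(rasterize(moved, s).area_um2 - truth))
            return np.mean(errs)

        e = {s: mean_err(s) for s in (0.08, 0.04, 0.02)}
        assert e[0.04] <= 0.6 * e[0.08]
        assert e[0.02] <= 0.6 * e[0.04]

    def test_too_coarse_scale_errors(self):
        c = generate_contour(SporeShapeParams("ellipsoid", 12, 5, 0.3, 0, 0.0))
        with pytest.raises(ValueError, match="foreground"):
            rasterize(c, 2.0)


class TestSamplePopulation:
    def test_degenerate_sds_give_identical_spores(self):
        cfg = PopulationConfig(
            "x", mean_L=12.0, sd_L_between=0.0, mean_W=5.0, sd_W_between=0.0,
            concavity_log_sd=0.0, p_collections=3, m_basidiomes=2, n_per_basidiome=4,
        )
        df = sample_population(cfg)
        assert df["length_um"].nunique() == 1
        assert df["width_um"].nunique() == 1
        assert (df["length_um"] == 12.0).all()

    def test_same_seed_reproduces_dataset_exactly(self):
        cfg = load_preset("mediterraneensis", seed=7, p_collections=3)
        pd.testing.assert_frame_equal(sample_population(cfg), sample_population(cfg))

    def test_mediterraneensis_grand_mean_length_recovered(self):
        # mean of collection-average lengths within 3 SEM of the preset 12.67
        cfg = load_preset("mediterraneensis", seed=11)
        df = sample_population(cfg)
        means = df.groupby("collection_id")["length_um"].mean()
        sem = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 12.67) < 3 * sem

    def test_hierarchy_counts(self):
        df = sample_population(load_preset("poikilochromus", seed=1, p_collections=4))
        assert df["collection_id"].nunique() == 4
        assert df.groupby("collection_id")["basidiome_id"].nunique().eq(10).all()
        assert len(df) == 4 * 10 * 5

    def test_truncation_resampling_warns_when_frequent(self):
        cfg = PopulationConfig(
            "bad", mean_L=2.0, sd_L_between=1.5, mean_W=1.0, sd_W_between=0.8,
            p_collections=5, m_basidiomes=2, n_per_basidiome=10, seed=3,
        )
        with pytest.warns(UserWarning, match="resamples"):
            df = sample_population(cfg)
        assert (df["width_um"] > 0).all()
        assert (df["length_um"] > df["width_um"]).all()
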