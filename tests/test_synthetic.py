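import numpy as np
import pandas as pd
import pytest

from citrusect.regions import DISJOINT_REGIONS, REGION_NAMES
from citrusect.synthetic import (
    FruitSpec,
    TraitModel,
    default_trait_models,
    generate_traits,
    ground_truth_features,
    render_fruit,
    sample_population,
)


class TestFruitSpec:
    def test_default_valid(self):
        FruitSpec().validate()

    def test_overlapping_rings_rejected(self):
        with pytest.raises(ValueError, match="center_radius"):
            FruitSpec(flavedo_thickness=0.5, albedo_thickness=0.4, center_radius=0.2)

    def test_degcenter_capacity(self):
        with pytest.raises(ValueError, match="degcenter_frac"):
            FruitSpec(center_radius=0.1, degcenter_frac=0.05)

    def test_degalbedo_capacity(self):
        with pytest.raises(ValueError, match="degalbedo_frac"):
            FruitSpec(albedo_thickness=0.02, degalbedo_frac=0.5)

    def test_fraction_range(self):
        with pytest.raises(ValueError, match="outside"):
            FruitSpec(fruit_radius=1.4)

    def test_locule_count_positive(self):
        with pytest.raises(ValueError, match="locule_count"):
            FruitSpec(locule_count=0)


class TestRenderFruit:
    def test_no_degcenter_gives_empty_mask(self, rng):
        _, masks = render_fruit(FruitSpec(degcenter_frac=0.0), rng)
        assert masks.area("DegCenter") == 0

    def test_no_seeds_gives_empty_mask(self, rng):
        _, masks = render_fruit(FruitSpec(seed_count=0), rng)
        assert masks.area("Seed") == 0

    def test_locule_components_match_spec(self, rng):
        spec = FruitSpec(locule_count=10, seed_count=0)
        _, masks = render_fruit(spec, rng)
        from skimage.measure import label

        assert label(masks["Flesh"]).max() == 10

    def test_flavedo_fraction_within_tolerance(self, default_fruit):
        spec, _, masks = default_fruit
        frac = masks.area("Flavedo") / masks.area("Whole")
        expected = 1 - (1 - spec.flavedo_thickness) ** 2
        assert abs(frac - expected) <= 0.02

    def test_all_region_fractions_near_truth(self, default_fruit):
        spec, _, masks = default_fruit
        truth = ground_truth_features(spec)
        whole = masks.area("Whole")
        for region in ("Flavedo", "Albedo", "DegAlbedo", "Flesh", "Center", "DegCenter"):
            assert abs(masks.area(region) / whole - truth[f"{region} area"]) <= 0.02

    def test_masks_disjoint_and_contained(self, default_fruit):
        _, _, masks = default_fruit
        masks.validate()

    def test_partition_sums_to_whole(self, default_fruit):
        """The 7 sub-regions plus septa exactly tile the whole fruit."""
        _, image, masks = default_fruit
        union = np.zeros(masks.shape, dtype=bool)
        total = 0
        for r in REGION_NAMES[1:]:
            union |= masks[r]
            total += masks.area(r)
        septa = masks["Whole"] & ~union
        assert total + septa.sum() == masks.area("Whole")
        # septa pixels are rendered in the cavity color (near-white)
        assert septa.any() and (image[septa] > 200).all()

    def test_background_uniform(self, default_fruit):
        _, image, masks = default_fruit
        bg = image[~masks["Whole"]]
        assert (bg == bg[0]).all()


class TestSamplePopulation:
    def test_cardinality(self):
        ds = sample_population(2, 1, 1, rng=np.random.default_rng(1), image_size=96)
        assert len(ds.images) == 2 and len(ds.masks) == 2 and len(ds.table) == 2

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            sample_population(0, 1, 1)

    def test_zero_jitter_fixes_genotype_features(self):
        ds = sample_population(
            2, 1, 3, rng=np.random.default_rng(2), jitter=0.0, render=False,
            year_effects={},
        )
        for _, grp in ds.table.groupby("genotype"):
            assert grp["DegCenter area"].nunique() == 1
            assert grp["Whole area"].nunique() == 1

    def test_deterministic_under_seed(self, tmp_path):
        a = sample_population(3, 2, 1, rng=np.random.default_rng(5), render=False)
        b = sample_population(3, 2, 1, rng=np.random.default_rng(5), render=False)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.table.to_csv(pa, index=False)
        b.table.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_year_effect_shifts_degradation(self):
        ds = sample_population(
            20, 2, 2, rng=np.random.default_rng(3), render=False, jitter=0.0
        )
        by_year = ds.table.groupby("year")["DegCenter area"].mean()
        assert by_year[1] > by_year[0]

    def test_inverted_prior_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            sample_population(
                2, 1, 1, spec_prior={"fruit_radius": (0.9, 0.7)}, render=False
            )


class TestGenerateTraits:
    def _truth(self, n=60, seed=0):
        return sample_population(
            n, 1, 1, rng=np.random.default_rng(seed), render=False
        ).table

    def test_exact_linear_when_noiseless(self):
        truth = self._truth()
        model = TraitModel(
            name="Peeling",
            intercept=2.0,
            coefficients={"DegCenter area": -30.0, "Whole area": 3.0},
            genotype_sd=0.0,
            residual_sd=1e-12,
        )
        out = generate_traits(truth, model, rng=np.random.default_rng(0))
        expected = 2.0 - 30.0 * truth["DegCenter area"] + 3.0 * truth["Whole area"]
        np.testing.assert_allclose(out["continuous"].to_numpy(), expected, atol=1e-6)

    def test_zero_coefficients_break_feature_link(self):
        truth = self._truth(n=150)
        model = TraitModel(name="t", intercept=1.0, coefficients={},
                           genotype_sd=0.3, residual_sd=0.3)
        out = generate_traits(truth, model, rng=np.random.default_rng(1))
        r = np.corrcoef(out["continuous"], truth["DegCenter area"])[0, 1]
        assert abs(r) < 0.2

    def test_ols_recovers_coefficient_signs(self):
        truth = self._truth(n=200, seed=4)
        out = generate_traits(truth, default_trait_models()[0],
                              rng=np.random.default_rng(2))
        X = truth[["DegCenter area", "DegAlbedo area", "Whole area"]].to_numpy()
        X = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(X, out["continuous"].to_numpy(), rcond=None)
        assert beta[1] < 0 and beta[2] < 0 and beta[3] > 0

    def test_ordinal_categories_in_range(self):
        out = generate_traits(self._truth(), rng=np.random.default_rng(3))
        assert out["ordinal"].between(1, 5).all()

    def test_binary_partitions(self):
        out = generate_traits(self._truth(), rng=np.random.default_rng(3))
        for _, grp in out.groupby("trait"):
            assert set(grp["binary"].unique()) == {0, 1}
            # median rule: balanced split
            assert abs(grp["binary"].mean() - 0.5) < 0.1

    def test_tails_rule_drops_middle(self):
        truth = self._truth(n=100)
        model = TraitModel(name="t", intercept=0.0,
                           coefficients={"Whole area": 5.0},
                           binary_rule="tails", tail_quantiles=(0.4, 0.6))
        out = generate_traits(truth, model, rng=np.random.default_rng(5))
        assert len(out) < 100
        assert set(out["binary"].unique()) == {0, 1}

    def test_missing_feature_column_is_schema_error(self):
        truth = self._truth().drop(columns=["DegCenter area"])
        with pytest.raises(KeyError, match="DegCenter area"):
            generate_traits(truth, default_trait_models()[0],
                            rng=np.random.default_rng(0))

    def test_cutpoints_must_increase(self):
        with pytest.raises(ValueError, match="cutpoints"):
            TraitModel(name="x", intercept=0, coefficients={},
                       cutpoints=(1.0, 1.0, 2.0, 3.0))


class TestGroundTruthFeatures:
    def test_exactly_21_features(self):
        from citrusect.features import FEATURE_NAMES

        truth = ground_truth_features(FruitSpec())
        assert tuple(truth) == FEATURE_NAMES

    def test_area_features_in_unit_interval(self):
        truth = ground_truth_features(FruitSpec())
        for name, v in truth.items():
            if name.endswith("area") and name != "Whole area":
                assert 0.0 <= v <= 1.0
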