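"""Nucleus classification chain: mid-Z, glia rule, thresholds, proportions."""

import numpy as np
import pandas as pd
import pytest

from checkfish.catfish import (
    NucleusClassifier,
    ThresholdError,
    classify_nuclei,
    derive_thresholds,
    filter_glia,
    region_proportions,
    select_mid_z,
)
from checkfish.synth import CatfishSimConfig, simulate_catfish_population


def nuclei_frame(n=20, **overrides):
    """A minimal well-formed nuclei table for rule-level tests."""
    base = pd.DataFrame(
        {
            "animal_id": ["a1"] * n,
            "treatment": ["control"] * n,
            "environment": ["A1A2"] * n,
            "region": ["CA1"] * n,
            "slide_id": ["s1"] * n,
            "z_centroid_fraction": np.full(n, 0.5),
            "size": np.full(n, 180.0),
            "elongation": np.full(n, 1.3),
            "counterstain_brightness": np.full(n, 100.0),
            "intensity_e1_channel": np.full(n, 0.0),
            "intensity_e2_channel": np.full(n, 0.0),
            "exemplar_weakest_e1": [False] * n,
            "exemplar_weakest_e2": [False] * n,
        }
    )
    for k, v in overrides.items():
        base[k] = v
    return base


def thresholds_frame(thr1=10.0, thr2=10.0, slide="s1", region="CA1"):
    return pd.DataFrame(
        [
            {"slide_id": slide, "region": region, "channel": "e1", "threshold": thr1},
            {"slide_id": slide, "region": region, "channel": "e2", "threshold": thr2},
        ]
    )


class TestSelectMidZ:
    def test_full_band_retains_everything(self):
        nuc = nuclei_frame(z_centroid_fraction=np.linspace(0, 0.999, 20))
        assert select_mid_z(nuc, band=1.0)["included_mid_z"].all()

    def test_21_slice_stack_mid_band_slices(self):
        # slice centre fractions (i + 0.5)/21 inside [0.4, 0.6):
        # 8.5/21 = 0.4048 .. 12.5/21 = 0.5952, i.e. 0-based slices 8-12
        z = (np.arange(21) + 0.5) / 21
        nuc = nuclei_frame(n=21, z_centroid_fraction=z)
        kept = np.flatnonzero(select_mid_z(nuc, band=0.20)["included_mid_z"])
        assert kept.tolist() == [8, 9, 10, 11, 12]

    def test_half_open_boundaries(self):
        nuc = nuclei_frame(n=2, z_centroid_fraction=[0.4, 0.6])
        inc = select_mid_z(nuc, band=0.20)["included_mid_z"]
        assert inc.tolist() == [True, False]

    def test_band_retains_matching_fraction_of_uniform_nuclei(self):
        rng = np.random.default_rng(0)
        n = 20_000
        nuc = nuclei_frame(n=n, z_centroid_fraction=rng.random(n))
        for band in (0.2, 0.5):
            frac = select_mid_z(nuc, band=band)["included_mid_z"].mean()
            se = np.sqrt(band * (1 - band) / n)
            assert abs(frac - band) < 3 * se

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            select_mid_z(nuclei_frame(), band=0.0)


class TestDeriveThresholds:
    def test_threshold_is_minimum_exemplar_intensity(self):
        nuc = nuclei_frame(n=3,
                           intensity_e1_channel=[12.1, 13.0, 15.2],
                           exemplar_weakest_e1=[True, True, True],
                           intensity_e2_channel=[20.0, 21.0, 22.0],
                           exemplar_weakest_e2=[True, True, True])
        thr = derive_thresholds(nuc).set_index("channel")["threshold"]
        assert thr["e1"] == pytest.approx(12.1)
        assert thr["e2"] == pytest.approx(20.0)

    def test_single_exemplar_defines_threshold(self):
        nuc = nuclei_frame(n=2,
                           intensity_e1_channel=[14.0, 30.0],
                           exemplar_weakest_e1=[True, False],
                           intensity_e2_channel=[9.0, 9.0],
                           exemplar_weakest_e2=[True, False])
        thr = derive_thresholds(nuc).set_index("channel")["threshold"]
        assert thr["e1"] == pytest.approx(14.0)

    def test_home_cage_exemplars_never_contribute(self):
        nuc = nuclei_frame(n=4,
                           environment=["A1A2", "A1A2", "HC", "HC"],
                           intensity_e1_channel=[15.0, 16.0, 1.0, 1.0],
                           exemplar_weakest_e1=[True, True, True, True],
                           intensity_e2_channel=[15.0, 16.0, 1.0, 1.0],
                           exemplar_weakest_e2=[True, True, True, True])
        thr = derive_thresholds(nuc).set_index("channel")["threshold"]
        assert thr["e1"] == pytest.approx(15.0)

    def test_no_exemplars_anywhere_raises(self):
        with pytest.raises(ThresholdError, match="exemplar"):
            derive_thresholds(nuclei_frame())

    def test_classification_in_unthresholded_group_raises_with_group_name(self):
        nuc = nuclei_frame(n=2, exemplar_weakest_e1=[True, False],
                           exemplar_weakest_e2=[True, False],
                           intensity_e1_channel=[12.0, 0.0],
                           intensity_e2_channel=[12.0, 0.0])
        thr = derive_thresholds(nuc)
        other = nuclei_frame(n=2, slide_id="s2")
        with pytest.raises(ThresholdError, match="s2"):
            classify_nuclei(other, thr)


class TestFilterGlia:
    def test_identical_nuclei_are_never_flagged(self):
        nuc = nuclei_frame(n=30)
        out = filter_glia(nuc, thresholds_frame())
        assert (out["cell_type"] == "neuron").all()

    def test_high_ieg_signal_vetoes_glia_call(self):
        n = 30
        nuc = nuclei_frame(
            n=n,
            size=[60.0] * 10 + [180.0] * 20,
            elongation=[2.5] * 10 + [1.3] * 20,
            intensity_e1_channel=[50.0] * 5 + [0.0] * 25,
        )
        out = filter_glia(nuc, thresholds_frame(), size_quantile=0.4)
        # the five small, elongated but IEG-bright nuclei stay neurons
        assert (out.loc[:4, "cell_type"] == "neuron").all()
        assert (out.loc[5:9, "cell_type"] == "putative_glia").all()

    def test_small_slide_emits_quantile_warning(self):
        with pytest.warns(UserWarning, match="unstable"):
            filter_glia(nuclei_frame(n=5), thresholds_frame())

    def test_simulated_glia_fraction_recovered(self):
        cfg = CatfishSimConfig(
            n_animals={("control", "A1A2"): 2}, regions=("CA1",),
            n_nuclei_per_region=500, glia_fraction=0.2, seed=9,
        )
        nuc = simulate_catfish_population(cfg)
        thr = derive_thresholds(nuc)
        out = filter_glia(nuc, thr)
        flagged = (out["cell_type"] == "putative_glia").mean()
        assert flagged == pytest.approx(0.20, abs=0.03)


class TestClassifyAndProportions:
    def test_zero_intensities_are_negative(self):
        out = classify_nuclei(nuclei_frame(n=3), thresholds_frame())
        assert (out["iEG_class"] == "negative").all()

    def test_intensity_exactly_at_threshold_is_positive(self):
        nuc = nuclei_frame(n=1, intensity_e1_channel=[10.0])
        out = classify_nuclei(nuc, thresholds_frame(thr1=10.0))
        assert out["iEG_class"].iloc[0] == "homer_pos"

    def test_four_way_classes(self):
        nuc = nuclei_frame(n=4,
                           intensity_e1_channel=[0, 12, 0, 12],
                           intensity_e2_channel=[0, 0, 12, 12])
        out = classify_nuclei(nuc, thresholds_frame())
        assert out["iEG_class"].tolist() == ["negative", "homer_pos", "arc_pos", "double_pos"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        nuc = nuclei_frame(n=200, intensity_e1_channel=rng.uniform(0, 30, 200))
        pos_frac = []
        for thr in (5.0, 10.0, 20.0):
            out = classify_nuclei(nuc, thresholds_frame(thr1=thr))
            pos_frac.append(out["iEG_class"].isin(["homer_pos", "double_pos"]).mean())
        assert pos_frac[0] >= pos_frac[1] >= pos_frac[2]

    def test_proportions_worked_example(self):
        cls = ["negative"] * 60 + ["homer_pos"] * 20 + ["arc_pos"] * 15 + ["double_pos"] * 5
        nuc = nuclei_frame(n=100)
        nuc["included"] = True
        nuc["iEG_class"] = cls
        props = region_proportions(nuc).iloc[0]
        assert props["p_negative"] == pytest.approx(0.60)
        assert props["p_homer_pos"] == pytest.approx(0.20)
        assert props["p_arc_pos"] == pytest.approx(0.15)
        assert props["p_double_pos"] == pytest.approx(0.05)
        assert props["p_e1"] == pytest.approx(0.25)
        assert props["p_e2"] == pytest.approx(0.20)
        assert props["n_included"] == 100

    def test_all_negative_population(self):
        nuc = nuclei_frame(n=10)
        nuc["included"] = True
        nuc["iEG_class"] = "negative"
        props = region_proportions(nuc).iloc[0]
        assert props["p_negative"] == 1.0 and props["p_double_pos"] == 0.0

    def test_fractions_sum_to_one_and_counts_conserved(self):
        cfg = CatfishSimConfig(n_nuclei_per_region=400, seed=10)
        nuc = simulate_catfish_population(cfg)
        classified = NucleusClassifier().fit_predict(nuc)
        assert len(classified) == len(nuc)  # filtering marks, never drops
        props = region_proportions(classified)
        psum = props[["p_negative", "p_homer_pos", "p_arc_pos", "p_double_pos"]].sum(axis=1)
        assert np.allclose(psum, 1.0, atol=1e-12)
        nsum = props[["n_negative", "n_homer_pos", "n_arc_pos", "n_double_pos"]].sum(axis=1)
        assert (nsum == props["n_included"]).all()

    def test_zero_included_yields_missing_record_with_warning(self):
        nuc = nuclei_frame(n=5)
        nuc["included"] = False
        nuc["iEG_class"] = np.nan
        with pytest.warns(UserWarning, match="zero included"):
            props = region_proportions(nuc)
        assert props["n_included"].iloc[0] == 0
        assert np.isnan(props["p_negative"].iloc[0])


class TestNucleusClassifierEstimator:
    def test_sklearn_param_protocol(self):
        clf = NucleusClassifier(band=0.4)
        assert clf.get_params()["band"] == 0.4
        clf.set_params(band=0.2, elongation_cut=2.0)
        assert clf.get_params()["elongation_cut"] == 2.0

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError, match="fitted"):
            NucleusClassifier().predict(nuclei_frame())

    def test_latent_label_agreement_on_separated_population(self):
        # 4+ SD separation between positive and negative intensity
        # distributions: derived thresholds recover latent labels >= 99%
        cfg = CatfishSimConfig(
            n_animals={("control", "A1A2"): 2}, regions=("CA1",),
            n_nuclei_per_region=500, glia_fraction=0.0, seed=11,
        )
        nuc = simulate_catfish_population(cfg)
        out = NucleusClassifier(band=1.0).fit_predict(nuc)
        inc = out[out["included"]]
        agree1 = (inc["iEG_class"].isin(["homer_pos", "double_pos"]) == inc["latent_active_e1"]).mean()
        agree2 = (inc["iEG_class"].isin(["arc_pos", "double_pos"]) == inc["latent_active_e2"]).mean()
        assert agree1 >= 0.99 and agree2 >= 0.99
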