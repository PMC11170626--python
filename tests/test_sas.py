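"""SAS-map thresholds, region classification, and consensus pairs."""
import numpy as np
import pandas as pd
import pytest

from epichem.errors import ContractError, DegenerateDistributionError
from epichem.sas import (
    REGIONS,
    classify_regions,
    compute_thresholds,
    consensus_pairs,
    sas_points,
)


def _pair_table(structural, activity, kinds=("maccs",)):
    n = len(structural)
    data = {"id_i": np.zeros(n, int), "id_j": np.arange(1, n + 1)}
    for k in kinds:
        data[f"sim_{k}"] = np.asarray(structural, dtype=float)
    data["activity_similarity"] = np.asarray(activity, dtype=float)
    data["activity_undefined"] = np.zeros(n, dtype=bool)
    return pd.DataFrame(data)


class TestThresholds:
    def test_mean_plus_two_sample_sd(self):
        th = compute_thresholds({"maccs": np.array([0.2, 0.2, 0.2, 0.2, 0.8])})
        assert th.structural["maccs"] == pytest.approx(0.32 + 2 * 0.26832815729, abs=1e-6)

    def test_constant_distribution_is_error(self):
        with pytest.raises(DegenerateDistributionError):
            compute_thresholds({"maccs": np.full(10, 0.4)})

    def test_cap_at_one_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            th = compute_thresholds({"maccs": np.array([0.0, 1.0])})
        assert th.structural["maccs"] == 1.0 and th.capped["maccs"]

    def test_bad_activity_threshold(self):
        with pytest.raises(ContractError):
            compute_thresholds({"maccs": np.array([0.1, 0.2])}, activity_threshold=0.0)


class TestClassification:
    def test_region_definitions(self):
        table = _pair_table([0.95, 0.95, 0.10, 0.10], [1.0, 0.05, 0.0, 0.5])
        th = compute_thresholds({"maccs": np.array([0.0, 0.2, 0.4, 0.43])})  # ~0.86
        cls = classify_regions(table, th)
        assert list(cls.table["region_maccs"]) == ["II", "IV", "III", "I"]

    def test_boundary_strictness(self):
        """Region II/IV need structural strictly above the threshold; activity
        exactly 0.1 belongs to the low-activity side."""
        th = compute_thresholds({"maccs": np.array([0.1, 0.2, 0.3, 0.6])})
        t = th.structural["maccs"]
        table = _pair_table([t, np.nextafter(t, 1)], [0.1, 0.1])
        cls = classify_regions(table, th)
        assert list(cls.table["region_maccs"]) == ["III", "IV"]

    def test_regions_partition_all_pairs(self, small_synthetic):
        from epichem import activity, fingerprints

        am = activity.ActivityMatrix.from_library(small_synthetic)
        pt = fingerprints.pairwise_table(small_synthetic, activity_matrix=am.matrix)
        kinds = list(fingerprints.FINGERPRINT_KINDS)
        th = compute_thresholds({k: pt[f"sim_{k}"].to_numpy() for k in kinds})
        cls = classify_regions(pt, th)
        n = len(small_synthetic)
        for k in kinds:
            assert sum(cls.region_counts(k).values()) == n * (n - 1) // 2

    def test_raising_activity_threshold_moves_only_II_to_IV_and_I_to_III(self, small_synthetic):
        from epichem import activity, fingerprints

        am = activity.ActivityMatrix.from_library(small_synthetic)
        pt = fingerprints.pairwise_table(small_synthetic, kinds=("ecfp4",), activity_matrix=am.matrix)
        sims = {"ecfp4": pt["sim_ecfp4"].to_numpy()}
        low = classify_regions(pt, compute_thresholds(sims, activity_threshold=0.1))
        high = classify_regions(pt, compute_thresholds(sims, activity_threshold=0.4))
        moved = low.table["region_ecfp4"] + ">" + high.table["region_ecfp4"]
        allowed = {"I>I", "II>II", "III>III", "IV>IV", "II>IV", "I>III"}
        assert set(moved.unique()) <= allowed

    def test_missing_column_is_contract_error(self):
        table = _pair_table([0.5], [0.5]).drop(columns=["activity_similarity"])
        th = compute_thresholds({"maccs": np.array([0.1, 0.5])})
        with pytest.raises(ContractError):
            classify_regions(table, th)


class TestConsensus:
    def test_pair_must_hold_region_under_all_fingerprints(self):
        kinds = ("maccs", "ecfp4")
        table = _pair_table([0.99, 0.99], [0.9, 0.9], kinds=kinds)
        # second pair misses the cut under ecfp4 only
        table.loc[1, "sim_ecfp4"] = 0.2
        th = compute_thresholds(
            {k: np.array([0.1, 0.2, 0.3, 0.35]) for k in kinds}  # threshold ~0.59
        )
        cls = classify_regions(table, th)
        cons = consensus_pairs(cls, "II")
        assert len(cons) == 1 and cons["id_j"].iloc[0] == 1

    def test_sorted_by_mean_structural_descending(self):
        table = _pair_table([0.90, 0.99], [0.9, 0.9])
        th = compute_thresholds({"maccs": np.array([0.1, 0.2, 0.3, 0.35])})
        cons = consensus_pairs(classify_regions(table, th), "II")
        assert cons["mean_structural_similarity"].is_monotonic_decreasing

    def test_names_attached_from_library(self, small_synthetic):
        from epichem import activity, fingerprints

        am = activity.ActivityMatrix.from_library(small_synthetic)
        pt = fingerprints.pairwise_table(small_synthetic, activity_matrix=am.matrix)
        kinds = list(fingerprints.FINGERPRINT_KINDS)
        th = compute_thresholds({k: pt[f"sim_{k}"].to_numpy() for k in kinds})
        cons = consensus_pairs(classify_regions(pt, th), "IV", small_synthetic)
        assert {"name_i", "name_j", "profile_incomplete"} <= set(cons.columns)


def test_sas_points_shape(small_synthetic):
    from epichem import activity, fingerprints

    am = activity.ActivityMatrix.from_library(small_synthetic)
    pt = fingerprints.pairwise_table(small_synthetic, kinds=("maccs",), activity_matrix=am.matrix)
    th = compute_thresholds({"maccs": pt["sim_maccs"].to_numpy()})
    points = sas_points(classify_regions(pt, th), "maccs")
    n = len(small_synthetic)
    assert len(points) == n * (n - 1) // 2
    assert set(points["region"].unique()) <= set(REGIONS)
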