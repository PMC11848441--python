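"""Well-level screen analysis: normalization, feature selection,
distance-to-control hit calling and assay QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from morphotraj.io_qc import aggregate_profiles
from morphotraj.profiling import (
    FeatureSelection,
    assay_qc,
    call_hits,
    distance_to_control,
    robust_z_normalize,
    select_features,
    zprime,
)
from morphotraj.simulate import (
    AtlasSimConfig,
    CompoundEffect,
    PlateSimConfig,
    Treatment,
    simulate_plate,
)


def _profiles(values: dict, roles=None, plate="P1"):
    n = len(next(iter(values.values())))
    base = {
        "plate": plate,
        "well": [f"A{i+1}" for i in range(n)],
        "role": roles if roles is not None else ["sample"] * n,
        "compound": "none",
        "dose": 0.0,
        "timepoint": 1,
        "replicate": 1,
        "n_cells": 10,
    }
    return pd.DataFrame({**base, **{k: np.asarray(v, dtype=float) for k, v in values.items()}})


class TestRobustZ:
    def test_reference_median_maps_to_zero(self):
        prof = _profiles({"f_a": [1, 2, 3, 4, 5], "f_b": [10, 20, 30, 40, 50]})
        z, model = robust_z_normalize(prof)
        assert z["f_a"].median() == pytest.approx(0.0)
        assert z["f_b"].median() == pytest.approx(0.0)

    def test_hand_computed_outlier_z(self):
        # reference [1,2,3,4,100]: median 3, MAD 1 -> z(100) = 97 / 1.4826
        prof = _profiles({"f_a": [1, 2, 3, 4, 100]})
        z, _ = robust_z_normalize(prof)
        assert z["f_a"].iloc[-1] == pytest.approx(97 / 1.4826, rel=1e-12)
        assert z["f_a"].iloc[-1] == pytest.approx(65.43, abs=0.01)

    def test_constant_feature_dropped_and_logged(self):
        prof = _profiles({"f_a": [1, 2, 3, 4], "f_flat": [7, 7, 7, 7]})
        z, model = robust_z_normalize(prof)
        assert "f_flat" not in z.columns
        assert model.dropped == ["f_flat"]

    def test_negative_control_mode_centers_on_controls(self):
        roles = ["undifferentiated_control"] * 4 + ["treatment"] * 2
        prof = _profiles({"f_a": [1, 2, 3, 4, 50, 60]}, roles=roles)
        z, model = robust_z_normalize(prof, mode="negative_controls")
        assert z.loc[z["role"] == "undifferentiated_control", "f_a"].median() == pytest.approx(0.0)
        assert model.mode == "negative_controls"

    def test_plate_without_references_rejected(self):
        roles = ["treatment"] * 4
        prof = _profiles({"f_a": [1, 2, 3, 4]}, roles=roles)
        with pytest.raises(ValueError, match="no reference wells"):
            robust_z_normalize(prof, mode="negative_controls")


class TestFeatureSelection:
    def test_duplicate_column_keeps_first(self):
        prof = _profiles({"f_a": [1, 2, 3, 4], "f_b": [1, 2, 3, 4]})
        sel = select_features(prof)
        assert sel.retained == ["f_a"]
        assert sel.dropped["f_b"] == "high-correlation"

    def test_negated_feature_dropped(self):
        prof = _profiles({"f_a": [1, 2, 3, 4], "f_neg": [-1, -2, -3, -4]})
        sel = select_features(prof)
        assert sel.retained == ["f_a"]

    def test_independent_features_all_retained(self, rng):
        prof = _profiles({f"f_{i}": rng.normal(size=200) for i in range(10)})
        sel = select_features(prof, corr_threshold=0.9)
        assert len(sel.retained) == 10

    def test_retained_and_dropped_disjoint(self):
        with pytest.raises(ValueError):
            FeatureSelection(retained=["a"], dropped={"a": "missing"})


class TestDistances:
    def _ctrl_profiles(self, rng, n_ctrl=6, n_other=4, n_feat=8, shift=0.0):
        n = n_ctrl + n_other
        roles = ["differentiated_control"] * n_ctrl + ["treatment"] * n_other
        vals = {}
        for j in range(n_feat):
            base = rng.normal(size=n)
            base[n_ctrl:] += shift
            vals[f"f_{j}"] = base
        return _profiles(vals, roles=roles)

    def test_well_equal_to_centroid_has_zero_distances(self, rng):
        prof = self._ctrl_profiles(rng)
        feats = [c for c in prof.columns if c.startswith("f_")]
        centroid = prof.loc[prof["role"] == "differentiated_control", feats].median()
        prof.loc[len(prof) - 1, feats] = centroid.to_numpy()
        sel = select_features(prof)
        d = distance_to_control(prof, sel)
        assert d["d_P"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert d["d_E"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated_profile_has_pearson_distance_two(self, rng):
        prof = self._ctrl_profiles(rng)
        feats = [c for c in prof.columns if c.startswith("f_")]
        centroid = prof.loc[prof["role"] == "differentiated_control", feats].median()
        prof.loc[len(prof) - 1, feats] = (-(centroid - centroid.mean())).to_numpy()
        sel = FeatureSelection(retained=feats)
        d = distance_to_control(prof, sel)
        assert d["d_P"].iloc[-1] == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_profile_has_pearson_distance_one(self):
        # five control wells whose per-feature median is exactly (1, 1, -1, -1);
        # the query (1, -1, 1, -1) is orthogonal to it after centering -> d_P = 1
        c = np.array([1.0, 1.0, -1.0, -1.0])
        wells = [c, c + [0.1, 0, 0, 0], c - [0.1, 0, 0, 0], c + [0, 0.1, 0, 0], c - [0, 0.1, 0, 0]]
        q = np.array([1.0, -1.0, 1.0, -1.0])
        mat = np.vstack(wells + [q])
        feats = {f"f_{j}": mat[:, j] for j in range(4)}
        roles = ["differentiated_control"] * 5 + ["treatment"]
        prof = _profiles(feats, roles=roles)
        sel = FeatureSelection(retained=list(feats))
        d = distance_to_control(prof, sel)
        assert d["d_P"].iloc[-1] == pytest.approx(1.0, abs=1e-12)

    def test_pearson_distance_affine_invariant(self, rng):
        prof = self._ctrl_profiles(rng, shift=1.0)
        sel = select_features(prof)
        d0 = distance_to_control(prof, sel)
        scaled = prof.copy()
        scaled[sel.retained] = 3.0 * scaled[sel.retained] + 7.0
        d1 = distance_to_control(scaled, sel)
        np.testing.assert_allclose(d0["d_P"], d1["d_P"], atol=1e-10)

    def test_zero_variance_profile_names_the_well(self, rng):
        prof = self._ctrl_profiles(rng)
        feats = [c for c in prof.columns if c.startswith("f_")]
        prof.loc[2, feats] = 5.0
        sel = FeatureSelection(retained=feats)
        with pytest.raises(ValueError, match="A3"):
            distance_to_control(prof, sel)


class TestHitCalls:
    @pytest.mark.parametrize(
        "d_p,d_e,expected",
        [
            (0.85, 1.6, True),   # both below threshold
            (0.90, 1.6, False),  # boundary d_P: strict inequality
            (0.85, 1.8, False),  # d_E above: conjunction required
            (0.95, 1.9, False),  # both above
            (0.85, 1.7, False),  # boundary d_E
        ],
    )
    def test_threshold_grid(self, d_p, d_e, expected):
        d = pd.DataFrame({"plate": "P", "well": ["A1"], "role": "treatment",
                          "d_P": [d_p], "d_E": [d_e]})
        assert call_hits(d)["is_hit"].iloc[0] == expected

    @given(
        d_p=st.floats(0, 2), d_e=st.floats(0, 5),
        drop_p=st.floats(0, 1), drop_e=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_hit_calls_monotone(self, d_p, d_e, drop_p, drop_e):
        """Lowering either distance never un-hits a well."""
        d = pd.DataFrame({"plate": "P", "well": ["A1", "A2"], "role": "treatment",
                          "d_P": [d_p, d_p * (1 - drop_p)], "d_E": [d_e, d_e * (1 - drop_e)]})
        hits = call_hits(d)["is_hit"]
        assert (not hits.iloc[0]) or hits.iloc[1]


class TestAssayQc:
    def test_zprime_closed_form(self):
        pos = np.array([9.5, 10.5, 10.0, 10.0])  # mean 10, sd 0.5 by construction
        pos = 10 + 0.5 * (pos - pos.mean()) / pos.std(ddof=1)
        neg = 0 + 0.5 * np.array([-1, 1, 0, 0]) / np.std([-1, 1, 0, 0], ddof=1)
        assert zprime(pos, neg) == pytest.approx(1 - 3 * (0.5 + 0.5) / 10, rel=1e-12)

    def test_zprime_zero_sd_is_one(self):
        assert zprime(np.full(4, 2.0), np.full(4, 5.0)) == pytest.approx(1.0)

    def test_zprime_equal_means_flagged_nan(self):
        assert np.isnan(zprime(np.array([1.0, 2.0]), np.array([2.0, 1.0])))

    def test_zprime_matches_brute_force(self, rng):
        pos = rng.normal(10, 1, size=30)
        neg = rng.normal(2, 0.5, size=30)
        brute = 1 - 3 * (np.std(pos, ddof=1) + np.std(neg, ddof=1)) / abs(pos.mean() - neg.mean())
        assert zprime(pos, neg) == pytest.approx(brute, abs=1e-12)

    def test_full_qc_on_separated_controls(self):
        """Widely separated control classes: classifier reaches accuracy 1
        and CV matches the hand formula."""
        cfg = AtlasSimConfig(n_timepoints=20, cells_per_timepoint=60, n_features=60,
                             noise_sd=0.2, seed=21)
        plate_cfg = PlateSimConfig(cells_per_well=80, seed=22)
        table, _ = simulate_plate(cfg, plate_cfg)
        profiles = aggregate_profiles(table, "well")
        z, _ = robust_z_normalize(profiles)
        sel = select_features(z)
        d = distance_to_control(z, sel)
        qc = assay_qc(d, z, sel, seed=0)
        assert qc.classifier_accuracy == 1.0
        assert (qc.classifier_report["f1"] == 1.0).all()
        for role, block in d.groupby("role"):
            v = block["d_P"].to_numpy()
            expected_cv = 100 * v.std(ddof=1) / v.mean()
            assert qc.cv_percent[role] == pytest.approx(expected_cv, abs=1e-12)
        assert np.isfinite(list(qc.zprime_per_plate.values())[0])
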