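"""Feature-space training and Euclidean distance scoring."""

import numpy as np
import pytest

from organoidscreen import (TrainingError, ValidationError,
                            score_plate, score_well, score_wells,
                            train_feature_space)
from organoidscreen.morphometry import WellProfile

N_FEATURES = 600
PLANTED = ["feat_007", "feat_123", "feat_456"]


def synth_profiles(rng, n_control=8, n_high=8, shift_sd=5.0,
                   planted=PLANTED, n_features=N_FEATURES, dose=100.0):
    """Two-class noise profiles with a known planted mean shift."""
    names = [f"feat_{i:03d}" for i in range(n_features)]
    profiles = []
    for i in range(n_control):
        feats = dict(zip(names, rng.normal(0, 1, n_features)))
        profiles.append(WellProfile(
            well_id=f"ctrl{i}", n_organoids=5, features=feats,
            metadata={"compound": "DMSO", "dose_nM": 0.0,
                      "role": "control"}))
    for i in range(n_high):
        feats = dict(zip(names, rng.normal(0, 1, n_features)))
        for p in planted:
            feats[p] += shift_sd
        profiles.append(WellProfile(
            well_id=f"high{i}", n_organoids=5, features=feats,
            metadata={"compound": "CX", "dose_nM": dose,
                      "role": "treated"}))
    return profiles


class TestTraining:
    def test_planted_features_recovered_in_top10(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            sel = train_feature_space(synth_profiles(rng), k=10)
            if all(p in sel.selected_features for p in PLANTED):
                hits += 1
        assert hits >= 95

    def test_selection_size_and_positive_sds(self):
        rng = np.random.default_rng(1)
        sel = train_feature_space(synth_profiles(rng), k=10)
        assert len(sel.selected_features) == 10
        assert all(sel.train_sd[f] > 0 for f in sel.selected_features)

    def test_null_data_trains_deterministically(self):
        rng = np.random.default_rng(2)
        profiles = synth_profiles(rng, shift_sd=0.0)
        s1 = train_feature_space(profiles, k=10)
        s2 = train_feature_space(profiles, k=10)
        assert s1.selected_features == s2.selected_features
        # overfit separation on pure noise is far below a 5-SD planted shift
        rng = np.random.default_rng(2)
        planted = train_feature_space(synth_profiles(rng, shift_sd=5.0),
                                      k=10)
        assert s1.separation < planted.separation / 2

    def test_k_equal_to_feature_count_selects_all(self):
        rng = np.random.default_rng(3)
        profiles = synth_profiles(rng, n_features=20,
                                  planted=["feat_001"])
        sel = train_feature_space(profiles, k=20)
        assert sorted(sel.selected_features) == sorted(
            f"feat_{i:03d}" for i in range(20))

    def test_k_exceeding_features_rejected(self):
        rng = np.random.default_rng(4)
        profiles = synth_profiles(rng, n_features=5, planted=["feat_001"])
        with pytest.raises(ValidationError):
            train_feature_space(profiles, k=10)

    def test_too_few_training_wells_rejected(self):
        rng = np.random.default_rng(5)
        profiles = synth_profiles(rng, n_control=1, n_high=8)
        with pytest.raises(TrainingError):
            train_feature_space(profiles, k=10)

    def test_pc1_strategy_supported(self):
        rng = np.random.default_rng(6)
        sel = train_feature_space(synth_profiles(rng), k=10,
                                  strategy="pc1")
        assert sel.component_index == 0

    def test_degenerate_wells_excluded_from_training(self):
        rng = np.random.default_rng(7)
        profiles = synth_profiles(rng)
        profiles.append(WellProfile(
            well_id="empty", n_organoids=0,
            features={f"feat_{i:03d}": 0.0 for i in range(N_FEATURES)},
            metadata={"compound": "DMSO", "dose_nM": 0.0,
                      "role": "control"}))
        sel = train_feature_space(profiles, k=10)
        assert "empty" not in sel.training_wells["control"]


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(10)
    profiles = synth_profiles(rng)
    return profiles, train_feature_space(profiles, k=10)


class TestScoring:
    def test_profile_at_control_centroid_scores_zero(self, trained):
        profiles, sel = trained
        feats = {f: sel.train_mean[f]
                 + sel.control_centroid[f] * sel.train_sd[f]
                 for f in sel.selected_features}
        # fill the rest with anything; only selected features matter
        prof = WellProfile("at_centroid", 5, feats,
                           {"compound": "CX", "dose_nM": 1.0})
        assert score_well(prof, sel).distance == pytest.approx(0.0,
                                                               abs=1e-12)

    def test_one_sigma_displacement_scores_one(self, trained):
        _, sel = trained
        feats = {f: sel.train_mean[f]
                 + sel.control_centroid[f] * sel.train_sd[f]
                 for f in sel.selected_features}
        f0 = sel.selected_features[0]
        feats[f0] += sel.train_sd[f0]
        prof = WellProfile("plus_sigma", 5, feats, {})
        assert score_well(prof, sel).distance == pytest.approx(1.0)

    def test_distance_matches_bruteforce_oracle(self, trained):
        profiles, sel = trained
        rng = np.random.default_rng(11)
        for _ in range(20):
            feats = {f: rng.normal(0, 3) for f in sel.selected_features}
            prof = WellProfile("rand", 5, feats, {})
            expected = np.sqrt(sum(
                ((feats[f] - sel.train_mean[f]) / sel.train_sd[f]
                 - sel.control_centroid[f]) ** 2
                for f in sel.selected_features))
            assert score_well(prof, sel).distance == pytest.approx(
                expected, abs=1e-9)

    def test_missing_selected_feature_rejected(self, trained):
        _, sel = trained
        prof = WellProfile("partial", 5,
                           {sel.selected_features[0]: 1.0}, {})
        with pytest.raises(ValidationError):
            score_well(prof, sel)

    def test_rescaling_a_raw_feature_leaves_distances_unchanged(self):
        rng = np.random.default_rng(12)
        profiles = synth_profiles(rng)
        sel = train_feature_space(profiles, k=10)
        base = {p.well_id: score_well(p, sel).distance for p in profiles}

        target = sel.selected_features[0]
        scaled = []
        for p in profiles:
            feats = dict(p.features)
            feats[target] *= 37.5
            scaled.append(WellProfile(p.well_id, p.n_organoids, feats,
                                      dict(p.metadata)))
        sel2 = train_feature_space(scaled, k=10)
        for p in scaled:
            assert score_well(p, sel2).distance == pytest.approx(
                base[p.well_id], rel=1e-9)


class TestPlateSummary:
    def test_identical_replicates_have_zero_sd(self):
        rng = np.random.default_rng(13)
        profiles = synth_profiles(rng)
        sel = train_feature_space(profiles, k=10)
        clones = [WellProfile(f"c{i}", 5, dict(profiles[-1].features),
                              {"compound": "CX", "dose_nM": 50.0})
                  for i in range(8)]
        table = score_plate(clones, sel)
        assert len(table) == 1
        assert table.loc[0, "sd_distance"] == pytest.approx(0.0)
        assert table.loc[0, "n"] == 8

    def test_mean_distance_monotone_for_linear_feature_response(self):
        # wells whose planted features move linearly with dose
        rng = np.random.default_rng(14)
        names = [f"feat_{i:03d}" for i in range(80)]
        def make(dose, shift, wid):
            feats = dict(zip(names, rng.normal(0, 1, len(names))))
            for p in ("feat_003", "feat_017"):
                feats[p] += shift
            return WellProfile(wid, 5, feats,
                               {"compound": "CX", "dose_nM": dose,
                                "role": "treated" if dose else "control"})
        profiles = [make(0.0, 0.0, f"c{i}") for i in range(6)]
        for j, (dose, shift) in enumerate(
                [(1, 1.0), (10, 3.0), (100, 6.0)]):
            profiles += [make(dose, shift, f"d{dose}_{i}")
                         for i in range(6)]
        for p in profiles[:6]:
            p.metadata.update({"compound": "DMSO", "dose_nM": 0.0,
                               "role": "control"})
        sel = train_feature_space(profiles, k=5)
        table = score_plate(profiles, sel)
        treated = table[table["compound"] == "CX"].sort_values("dose_nM")
        means = treated["mean_distance"].to_numpy()
        assert (np.diff(means) > 0).all()
        ctrl = table[table["compound"] == "DMSO"]["mean_distance"].iloc[0]
        assert ctrl < means[-1]
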