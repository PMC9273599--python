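"""Synthetic-cohort generator: determinism, planted structure, round trips."""

import numpy as np
import pandas as pd
import pytest

from primarysite.features.copynumber import compute_arm_copy_number
from primarysite.features.extract import extract_cohort_features, extract_sample_features
from primarysite.features.signatures import synthetic_catalog
from primarysite.simulate import (
    ClassArchetype,
    SyntheticCohortConfig,
    example_cohort_config,
    generate_feature_cohort,
    generate_raw_inputs,
    make_toy_genome,
    random_profiles,
    write_raw_inputs,
)


class TestFeatureCohort:
    def test_deterministic_given_config_and_seed(self):
        config = example_cohort_config(2, 10)
        X1, t1 = generate_feature_cohort(config, seed=5)
        X2, t2 = generate_feature_cohort(config, seed=5)
        pd.testing.assert_frame_equal(X1.data, X2.data)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        config = example_cohort_config(2, 10)
        X1, _ = generate_feature_cohort(config, seed=5)
        X2, _ = generate_feature_cohort(config, seed=6)
        assert not X1.data.equals(X2.data)

    def test_perfect_marker_separates_classes(self):
        config = example_cohort_config(2, 20)
        config.classes[0].bool_prevalence = {"viral_ins.HPV": 1.0}
        config.classes[1].bool_prevalence = {"viral_ins.HPV": 0.0}
        X, truth = generate_feature_cohort(config, seed=7)
        marker = X.data["viral_ins.HPV"]
        a = truth["class"] == config.classes[0].name
        assert (marker[a.to_numpy()] == 1).all()
        assert (marker[(~a).to_numpy()] == 0).all()

    def test_gender_constraints_respected(self):
        config = example_cohort_config(4, 15)
        X, truth = generate_feature_cohort(config, seed=8)
        assert (truth.loc[truth["class"] == "ProstateLike", "gender"] == "male").all()
        assert (truth.loc[truth["class"] == "CervixLike", "gender"] == "female").all()

    def test_rmd_draw_converges_to_planted_profile(self):
        """Law of large numbers: at 10k SBS the sample RMD is close in L1."""
        rng = np.random.default_rng(9)
        profile = random_profiles(1, 50, rng)[0]
        draws = rng.multinomial(10_000, profile) / 10_000
        assert np.abs(draws - profile).sum() < 0.05

    def test_invalid_config_reports_offending_fields(self):
        config = example_cohort_config(2, 10)
        config.classes[0].bool_prevalence = {"viral_ins.HPV": 1.5}
        config.classes[1].gender = "both"
        with pytest.raises(ValueError) as err:
            config.validate()
        assert "prevalence" in str(err.value)
        assert "gender" in str(err.value)


@pytest.fixture(scope="module")
def raw_small():
    config = example_cohort_config(2, 4)
    cohort, genome, truth = generate_raw_inputs(config, seed=3)
    return config, cohort, genome, truth


class TestRawInputs:
    def test_deterministic_given_seed(self):
        config = example_cohort_config(1, 2)
        c1, g1, _ = generate_raw_inputs(config, seed=4)
        c2, g2, _ = generate_raw_inputs(config, seed=4)
        assert g1 == g2
        for sid in c1:
            assert c1[sid].mutations == c2[sid].mutations
            assert c1[sid].events == c2[sid].events

    def test_planted_arm_cn_recovered_as_fold_change(self):
        config = example_cohort_config(1, 2)
        config.classes[0].arm_cn = {"1q": 3}
        cohort, genome, _ = generate_raw_inputs(config, seed=5)
        inp = next(iter(cohort.values()))
        result = compute_arm_copy_number(inp.cn_segments, config.arm_table)
        assert result.genome_cn == 2
        assert result.fold_change["1q"] == pytest.approx(1.5)

    def test_pure_planted_signature_recovered(self):
        """A single-signature class round-trips through context counting + NNLS."""
        catalogs = {
            "SBS96": synthetic_catalog("SBS96", 4, seed=21),
            "DBS78": synthetic_catalog("DBS78", 3, seed=22),
            "ID83": synthetic_catalog("ID83", 3, seed=23),
        }
        base = example_cohort_config(1, 3)
        config = SyntheticCohortConfig(
            classes=[
                ClassArchetype(
                    name="PureSig", n_samples=3,
                    rmd_profiles=random_profiles(1, base.n_bins, np.random.default_rng(1)),
                    signature_mix={"SBS2": 1.0},
                    sbs_load_mean=3000.0, dbs_load_mean=0.0, indel_load_mean=0.0,
                )
            ],
            bin_table=base.bin_table,
            arm_table=base.arm_table,
            signature_catalogs=catalogs,
        )
        cohort, genome, _ = generate_raw_inputs(config, seed=6)
        X = extract_cohort_features(cohort, genome, config.feature_catalog())
        assert (X.data["sigs.SBS2"] > 0.95).all()

    def test_extraction_recovers_boolean_prevalence_and_loads(self):
        """Raw-input round trip matches the feature-level generator's means."""
        config = example_cohort_config(2, 30)
        config.classes[0].bool_prevalence = {"viral_ins.HPV": 0.8}
        cohort, genome, truth = generate_raw_inputs(config, seed=7)
        X = extract_cohort_features(cohort, genome, config.feature_catalog())
        cls0 = truth.index[truth["class"] == config.classes[0].name]
        prevalence = X.data.loc[cls0, "viral_ins.HPV"].mean()
        se = np.sqrt(0.8 * 0.2 / len(cls0))
        assert abs(prevalence - 0.8) <= 3 * se + 1e-9
        load = X.data.loc[cls0, "mut_load.snv"].mean()
        expected = config.classes[0].sbs_load_mean
        assert abs(load - expected) <= 3 * np.sqrt(expected / len(cls0)) + 0.02 * expected

    def test_rmd_positions_follow_planted_profile(self, raw_small):
        config, cohort, genome, truth = raw_small
        cls = config.classes[0]
        sid = truth.index[truth["class"] == cls.name][0]
        X = extract_sample_features(cohort[sid], genome, config.feature_catalog())
        rmd = X.filter(like="rmd_bin.").to_numpy()
        # mean planted profile: mixture average of the class profiles
        mean_profile = cls.rmd_profiles.mean(axis=0)
        # cosine similarity of the realized RMD with the planted mean profile
        cos = rmd @ mean_profile / (
            np.linalg.norm(rmd) * np.linalg.norm(mean_profile)
        )
        assert cos > 0.7

    def test_write_raw_inputs_tree(self, raw_small, tmp_path):
        config, cohort, genome, truth = raw_small
        write_raw_inputs(cohort, genome, config, truth, tmp_path / "raw")
        assert (tmp_path / "raw" / "reference.fa").exists()
        assert (tmp_path / "raw" / "rmd_bins.bed").exists()
        sid = next(iter(cohort))
        assert (tmp_path / "raw" / "samples" / sid / "mutations.tsv").exists()

    def test_oversized_mutation_load_rejected(self):
        config = example_cohort_config(1, 1)
        config.classes[0].sbs_load_mean = 10**7
        with pytest.raises(ValueError, match="too small"):
            generate_raw_inputs(config, seed=0)


def test_toy_genome_deterministic_and_sized():
    g1 = make_toy_genome(seed=101)
    g2 = make_toy_genome(seed=101)
    assert g1 == g2
    assert set(g1) == {"1", "2", "3", "4", "X"}
    assert all(set(seq) <= set("ACGT") for seq in g1.values())
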