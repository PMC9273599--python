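"""SV burden encoding, event features and the preliminary association screen."""

import numpy as np
import pandas as pd
import pytest

from primarysite.features.records import EventRecord, SVClusterRecord
from primarysite.features.sv_events import (
    driver_feature_names,
    encode_driver_features,
    encode_fusion_and_viral_features,
    encode_sv_features,
    preliminary_screen_boolean_features,
)


class TestSVFeatures:
    def test_no_clusters_all_zero(self):
        feats = encode_sv_features([])
        assert (feats == 0).all()

    def test_single_deletion_length_bin(self):
        feats = encode_sv_features(
            [SVClusterRecord("c1", "DEL", length_bp=5_000)]
        )
        assert feats["sv.DEL.1e3_1e4"] == 1
        assert feats["sv.load"] == 1

    def test_largest_complex_cluster_breakends(self):
        clusters = [
            SVClusterRecord("c1", "COMPLEX", n_sv=15, n_breakends=30),
            SVClusterRecord("c2", "COMPLEX", n_sv=60, n_breakends=120),
        ]
        feats = encode_sv_features(clusters)
        assert feats["sv.COMPLEX.largest_cluster"] == 120
        assert feats["sv.COMPLEX.0_25"] == 1
        assert feats["sv.COMPLEX.50_100"] == 1

    def test_del_length_bins_sum_to_total_dels(self):
        rng = np.random.default_rng(0)
        clusters = [
            SVClusterRecord(f"c{i}", "DEL", length_bp=int(rng.integers(1, 10**8)))
            for i in range(40)
        ]
        feats = encode_sv_features(clusters)
        del_bins = feats.filter(like="sv.DEL.")
        assert del_bins.sum() == 40

    def test_line_and_double_minutes_counted(self):
        clusters = [
            SVClusterRecord("c1", "LINE"),
            SVClusterRecord("c2", "LINE"),
            SVClusterRecord("c3", "DOUBLE_MINUTE"),
        ]
        feats = encode_sv_features(clusters)
        assert feats["sv.LINE"] == 2
        assert feats["sv.double_minutes"] == 1
        assert feats["sv.load"] == 3


class TestDriverFeatures:
    CATALOG = ("ERBB2", "TP53", "APC")

    def test_amplification_sets_feature(self):
        feats = encode_driver_features(
            [EventRecord("driver", "ERBB2", "amp")], self.CATALOG
        )
        assert feats["gene.ERBB2.amp"] == 1
        assert feats.sum() == 1

    def test_low_likelihood_monoallelic_ignored(self):
        feats = encode_driver_features(
            [EventRecord("driver", "TP53", "monoallelic", 0.85)], self.CATALOG
        )
        assert feats["gene.TP53.monoallelic"] == 0

    def test_high_likelihood_monoallelic_kept(self):
        feats = encode_driver_features(
            [EventRecord("driver", "TP53", "monoallelic", 0.95)], self.CATALOG
        )
        assert feats["gene.TP53.monoallelic"] == 1

    def test_no_events_all_zero_and_catalog_arithmetic(self):
        feats = encode_driver_features([], self.CATALOG)
        assert (feats == 0).all()
        assert len(feats) == len(self.CATALOG) * 4

    def test_gene_outside_catalog_ignored(self, caplog):
        feats = encode_driver_features(
            [EventRecord("driver", "NOTAGENE", "amp")], self.CATALOG
        )
        assert (feats == 0).all()


class TestFusionViralFeatures:
    def test_known_pair(self):
        feats = encode_fusion_and_viral_features(
            [EventRecord("fusion", "TMPRSS2_ERG")],
            known_pairs=("TMPRSS2_ERG",),
        )
        assert feats["fusion.TMPRSS2_ERG"] == 1

    def test_igh_fusion_grouped(self):
        feats = encode_fusion_and_viral_features(
            [EventRecord("fusion", "IGH_BCL2")], known_pairs=()
        )
        assert feats["fusion.IGH"] == 1

    def test_two_promiscuous_partners_set_both_features(self):
        feats = encode_fusion_and_viral_features(
            [EventRecord("fusion", "SLC45A3_MYC")],
            promiscuous=("SLC45A3", "MYC"),
        )
        assert feats["fusion.SLC45A3_*"] == 1
        assert feats["fusion.*_MYC"] == 1

    def test_hpv_strain_mapped_to_category(self):
        feats = encode_fusion_and_viral_features(
            [EventRecord("viral", "human papillomavirus type 16")]
        )
        assert feats["viral_ins.HPV"] == 1

    def test_unmapped_strain_leaves_features_untouched(self):
        feats = encode_fusion_and_viral_features(
            [EventRecord("viral", "bacteriophage lambda")]
        )
        assert (feats.filter(like="viral_ins.") == 0).all()


class TestPreliminaryScreen:
    def _cohort(self, n_a=50, n_b=450):
        labels = pd.Series(
            ["A"] * n_a + ["B"] * n_b,
            index=[f"s{i}" for i in range(n_a + n_b)],
        )
        return labels

    def test_perfect_association_retained(self):
        labels = self._cohort()
        X = pd.DataFrame(
            {"fusion.X_Y": [1] * 50 + [0] * 450}, index=labels.index
        )
        retained, stats = preliminary_screen_boolean_features(X, labels)
        assert retained == ["fusion.X_Y"]
        row = stats[(stats["feature"] == "fusion.X_Y") & (stats["class"] == "A")]
        assert row["p_value"].iloc[0] < 1e-10
        assert row["cramers_v"].iloc[0] > 0.9

    def test_absent_feature_dropped(self):
        labels = self._cohort()
        X = pd.DataFrame({"gene.G.amp": [0] * 500}, index=labels.index)
        retained, _ = preliminary_screen_boolean_features(X, labels)
        assert retained == []

    def test_uniform_prevalence_dropped(self):
        labels = self._cohort(250, 250)
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            {"viral_ins.HPV": rng.random(500) < 0.3}, index=labels.index
        ).astype(int)
        retained, _ = preliminary_screen_boolean_features(X, labels)
        assert retained == []

    def test_gene_level_retention_keeps_sibling_driver_types(self):
        labels = self._cohort()
        X = pd.DataFrame(
            {
                "gene.G1.amp": [1] * 50 + [0] * 450,  # strongly associated
                "gene.G1.deep_del": [0] * 495 + [1] * 5,  # weak on its own
                "gene.G2.amp": [0] * 495 + [1] * 5,  # weak, different gene
            },
            index=labels.index,
        )
        retained, _ = preliminary_screen_boolean_features(X, labels)
        assert "gene.G1.amp" in retained
        assert "gene.G1.deep_del" in retained  # carried by its gene
        assert "gene.G2.amp" not in retained

    def test_driver_candidate_arithmetic_for_full_catalog(self):
        """A 462-gene catalog yields 1848 candidate driver features."""
        genes = [f"G{i:03d}" for i in range(462)]
        assert len(driver_feature_names(genes)) == 1848

    def test_retained_gene_arithmetic(self):
        """203 passing genes x 4 driver types -> 812 retained features."""
        n_genes = 462
        n_pass = 203
        labels = self._cohort(60, 240)
        rng = np.random.default_rng(3)
        cols = {}
        for i in range(n_genes):
            if i < n_pass:
                # one driver type perfectly tracks class A
                cols[f"gene.G{i:03d}.amp"] = [1] * 60 + [0] * 240
            else:
                cols[f"gene.G{i:03d}.amp"] = [0] * 300
            for dtype in ("deep_del", "biallelic", "monoallelic"):
                cols[f"gene.G{i:03d}.{dtype}"] = [0] * 300
        X = pd.DataFrame(cols, index=labels.index)
        retained, _ = preliminary_screen_boolean_features(X, labels)
        assert len(retained) == n_pass * 4 == 812
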