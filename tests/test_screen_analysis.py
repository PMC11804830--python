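"""Normalization, fold changes, site aggregation and QC."""

import numpy as np
import pandas as pd
import pytest

from phosbase.screen_analysis import (
    aggregate_to_sites,
    control_size_factors,
    essential_depletion_qc,
    guide_log2fc,
    quantify_editing,
)
from phosbase.screen_sim import ScreenSimSpec, make_screen_library, simulate_counts


@pytest.fixture(scope="module")
def sim():
    spec = ScreenSimSpec(seed=9)
    lib = make_screen_library(spec)
    counts = simulate_counts(spec, lib)
    classes = lib.set_index("guide_id")["class"]
    mapping = lib.set_index("guide_id")["site"]
    return spec, lib, counts, classes, mapping


class TestSizeFactors:
    def _toy(self):
        counts = pd.DataFrame(
            {"a": [100, 200, 50, 400], "b": [200, 400, 100, 800]},
            index=pd.Index(["g1", "g2", "g3", "g4"], name="guide_id"),
        )
        classes = pd.Series(
            ["intergenic", "non_targeting", "intergenic", "phosphosite"],
            index=counts.index,
        )
        return counts, classes

    def test_scale_equivariance(self):
        counts, classes = self._toy()
        sf = control_size_factors(counts, classes)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        counts, classes = self._toy()
        counts["b"] = counts["a"]
        sf = control_size_factors(counts, classes)
        assert sf["a"] == pytest.approx(sf["b"])

    def test_missing_controls_rejected(self):
        counts, classes = self._toy()
        with pytest.raises(ValueError, match="control"):
            control_size_factors(counts, classes.replace(
                {"intergenic": "phosphosite", "non_targeting": "phosphosite"}
            ))

    def test_normalization_idempotent(self, sim):
        _, _, counts, classes, _ = sim
        sf = control_size_factors(counts, classes)
        renorm = control_size_factors(counts / sf, classes)
        assert np.allclose(renorm, renorm.mean(), rtol=0.02)

    def test_normalized_control_median_lfc_near_zero(self, sim):
        _, _, counts, classes, _ = sim
        lfc = guide_log2fc(counts, classes, "post", "pre")
        ctrl = lfc[classes.isin(("intergenic", "non_targeting"))]
        assert abs(ctrl.median()) < 0.05


class TestGuideLog2fc:
    def test_equal_counts_zero(self):
        counts = pd.DataFrame({"a": [100, 7], "b": [100, 7]},
                              index=["g1", "g2"])
        classes = pd.Series(["intergenic", "intergenic"], index=counts.index)
        lfc = guide_log2fc(counts, classes, "a", "b")
        assert np.allclose(lfc, 0.0)

    def test_zero_counts_finite(self):
        counts = pd.DataFrame({"a": [0, 100], "b": [0, 100]},
                              index=["g1", "g2"])
        classes = pd.Series(["intergenic", "intergenic"], index=counts.index)
        lfc = guide_log2fc(counts, classes, "a", "b")
        assert np.isfinite(lfc).all()
        assert lfc["g1"] == pytest.approx(0.0)

    def test_missing_sample_rejected(self):
        counts = pd.DataFrame({"a": [1]}, index=["g1"])
        classes = pd.Series(["intergenic"], index=counts.index)
        with pytest.raises(KeyError):
            guide_log2fc(counts, classes, "a", "nope")


class TestAggregateToSites:
    def test_null_site_high_p(self):
        rng = np.random.default_rng(0)
        guides = pd.Series(0.0, index=[f"g{i}" for i in range(3)])
        ctrl_vals = pd.Series(rng.normal(0, 0.3, 200),
                              index=[f"c{i}" for i in range(200)])
        stats = aggregate_to_sites(
            pd.concat([guides, ctrl_vals]),
            pd.Series("S1", index=guides.index),
            list(ctrl_vals.index),
            n_perm=2000,
            seed=1,
        )
        assert stats.loc[0, "p_value"] > 0.5

    def test_p_lower_bound(self, sim):
        _, lib, counts, classes, mapping = sim
        lfc = guide_log2fc(counts, classes, "post", "pre")
        phospho = mapping[classes.reindex(mapping.index) == "phosphosite"]
        controls = classes[classes.isin(("intergenic", "non_targeting"))].index
        n_perm = 2000
        stats = aggregate_to_sites(lfc, phospho, list(controls), n_perm, seed=1)
        assert (stats["p_value"] >= 1.0 / (n_perm + 1)).all()
        assert (stats["p_value"] <= 1.0).all()

    def test_bh_monotone_in_p(self, sim):
        _, lib, counts, classes, mapping = sim
        lfc = guide_log2fc(counts, classes, "post", "pre")
        phospho = mapping[classes.reindex(mapping.index) == "phosphosite"]
        controls = classes[classes.isin(("intergenic", "non_targeting"))].index
        stats = aggregate_to_sites(lfc, phospho, list(controls), 2000, seed=1)
        s = stats.sort_values("p_value")
        assert (s["fdr"].diff().dropna() >= -1e-12).all()

    def test_planted_sites_reach_low_fdr(self, sim):
        spec, lib, counts, classes, mapping = sim
        lfc = guide_log2fc(counts, classes, "post", "pre")
        phospho = mapping[classes.reindex(mapping.index) == "phosphosite"]
        controls = classes[classes.isin(("intergenic", "non_targeting"))].index
        stats = aggregate_to_sites(lfc, phospho, list(controls), 10_000, seed=1)
        planted = [f"SITE_{i + 1:03d}" for i in range(spec.n_planted_sites)]
        got = stats.set_index("site_id").loc[planted, "fdr"]
        assert (got < 0.05).all()


class TestDepletionQc:
    def test_planted_depletion_passes(self, sim):
        _, _, counts, classes, _ = sim
        lfc = guide_log2fc(counts, classes, "post", "pre")
        qc = essential_depletion_qc(lfc, classes)
        assert qc["status"] == "PASS"
        assert qc["median_log2fc_essential"] < -1.5

    def test_null_simulation_fails(self):
        spec = ScreenSimSpec(seed=9, planted_log2fc=0.0)
        lib = make_screen_library(spec)
        counts = simulate_counts(spec, lib)
        classes = lib.set_index("guide_id")["class"]
        lfc = guide_log2fc(counts, classes, "post", "pre")
        assert essential_depletion_qc(lfc, classes)["status"] == "FAIL"

    def test_missing_class_not_evaluable(self):
        lfc = pd.Series([0.1, -0.1], index=["g1", "g2"])
        classes = pd.Series(["intergenic", "non_targeting"], index=lfc.index)
        assert essential_depletion_qc(lfc, classes)["status"] == "not evaluable"


class TestQuantifyEditing:
    def test_simple_fraction(self):
        ref = "CCAACC"
        reads = ["CCGACC"] * 80 + ["CCAACC"] * 20
        frac = quantify_editing(reads, [2, 3], ref)
        assert frac[2] == pytest.approx(0.80)
        assert frac[3] == pytest.approx(0.0)

    def test_all_unedited(self):
        ref = "AAAA"
        frac = quantify_editing(["AAAA"] * 10, [0, 1, 2, 3], ref)
        assert all(v == 0.0 for v in frac.values())

    def test_mixed_positions_hand_tally(self):
        # hand-tallied: pos1 edited in 2/4 reads, pos4 edited in 1/4,
        # one read has N at pos 4 (excluded from coverage there: 1/3)
        ref = "CATCAG"
        reads = ["CGTCAG", "CGTCGG", "CATCAG", "CATCNG"]
        frac = quantify_editing(reads, [1, 4], ref)
        assert frac[1] == pytest.approx(2 / 4)
        assert frac[4] == pytest.approx(1 / 3)

    def test_requires_reads(self):
        with pytest.raises(ValueError):
            quantify_editing([], [0], "A")
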