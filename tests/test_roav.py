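"""OAV/ROAV scoring, key-flavor classification, and the flavor network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flavoromics.profile import GroupProfile
from flavoromics.roav import (
    ROAVResult,
    ThresholdEntry,
    build_flavor_network,
    classify_roav,
    compute_oav,
    compute_roav,
    descriptor_weights,
    format_roav,
    network_to_edge_list,
    roav_report,
)


def _profile(means, group="g"):
    tbl = pd.DataFrame({"mean": pd.Series(means, dtype=float), "sd": 0.0, "n": 4})
    return GroupProfile(group=group, table=tbl)


@pytest.fixture
def group_results(rs_profile, rr_profile, thresholds):
    return {
        "RS": compute_roav(compute_oav(rs_profile, thresholds), group="RS"),
        "RR": compute_roav(compute_oav(rr_profile, thresholds), group="RR"),
    }


class TestOAV:
    def test_direct_quotients(self, rr_profile, rs_profile, thresholds):
        oav_rr = compute_oav(rr_profile, thresholds)
        assert oav_rr.loc["ethyl butanoate", "oav"] == pytest.approx(3.97 / 0.0009)
        oav_rs = compute_oav(rs_profile, thresholds)
        assert oav_rs.loc["nonanal", "oav"] == pytest.approx(0.81 / 0.0011)

    def test_absent_compound_zero(self, rs_profile, thresholds):
        oav = compute_oav(rs_profile, thresholds)
        assert oav.loc["ethyl butanoate", "oav"] == 0.0  # not detected in RS

    def test_missing_threshold_flagged_not_dropped(self, rr_profile, thresholds):
        oav = compute_oav(rr_profile, thresholds)
        assert "δ-cadinene" in oav.index
        assert np.isnan(oav.loc["δ-cadinene", "oav"])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="caryophyllene"):
            ThresholdEntry(compound="caryophyllene", threshold=0.0)


class TestROAV:
    def test_published_values(self, group_results):
        rr = group_results["RR"].table
        rs = group_results["RS"].table
        assert rr.loc["ethyl hexanoate", "roav"] == pytest.approx(24.76, abs=0.05)
        assert rs.loc["nonanal", "roav"] == 100.0
        assert rs.loc["β-ocimene", "roav"] == pytest.approx(3.75, abs=0.05)

    def test_max_is_exactly_100(self, group_results):
        for res in group_results.values():
            roavs = res.table["roav"].dropna()
            assert roavs.max() == 100.0
            assert ((roavs >= 0) & (roavs <= 100)).all()

    def test_all_zero_oav_rejected(self, thresholds):
        p = _profile({"styrene": 0.0, "unthresholded": 100.0})
        with pytest.raises(ValueError, match="no odor-active"):
            compute_roav(compute_oav(p, thresholds), group="g")

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale, rs_profile, thresholds):
        """ROAV is a ratio statistic: rescaling all contents changes nothing."""
        base = compute_roav(compute_oav(rs_profile, thresholds), group="RS")
        scaled_tbl = rs_profile.table.copy()
        scaled_tbl["mean"] = scaled_tbl["mean"] * scale
        scaled_profile = GroupProfile(group="RS", table=scaled_tbl)
        scaled = compute_roav(compute_oav(scaled_profile, thresholds), group="RS")
        np.testing.assert_allclose(
            scaled.table["roav"].to_numpy(dtype=float),
            base.table["roav"].to_numpy(dtype=float),
            rtol=1e-9,
        )

    def test_matches_brute_force_oracle(self, thresholds):
        """Pipeline ROAV equals an independent first-principles loop to 1e-12."""
        rng = np.random.default_rng(42)
        entries = [e for e in thresholds][:8]
        contents = {e.compound: float(rng.uniform(0.1, 40)) for e in entries}
        res = compute_roav(compute_oav(_profile(contents), entries), group="g")
        # oracle: direct loop over OAV = C/T then ROAV = 100*OAV/max
        oavs = {c: contents[c] / e.threshold for c, e in zip(contents, entries)}
        m = max(oavs.values())
        for c, o in oavs.items():
            assert res.table.loc[c, "roav"] == pytest.approx(100 * o / m, abs=1e-12)


class TestClassification:
    def test_published_key_counts(self, group_results):
        assert classify_roav(group_results["RR"])["n_key"] == 6
        assert classify_roav(group_results["RS"])["n_key"] == 8

    def test_key_list_sorted_descending(self, group_results):
        keys = group_results["RS"].key_compounds["roav"]
        assert keys.is_monotonic_decreasing
        assert keys.index[0] == "nonanal"

    def test_all_below_one_gives_empty_keys(self):
        tbl = pd.DataFrame(
            {"content": [1.0, 0.5], "threshold": [10.0, 10.0],
             "oav": [0.1, 0.05], "roav": [0.9, 0.45],
             "category": ["modifier", "modifier"]},
            index=pd.Index(["a", "b"], name="compound"),
        )
        out = classify_roav(ROAVResult(group="g", table=tbl))
        assert out["key"] == [] and out["n_modifier"] == 2

    def test_display_formatting(self):
        assert format_roav(0.05) == "<0.1"
        assert format_roav(0.0) == "<0.1"
        assert format_roav(24.756) == "24.76"
        assert format_roav(float("nan")) == "-"


class TestFlavorNetwork:
    def test_published_sweet_hub(self, group_results, thresholds):
        """RS 'sweet' collects styrene, caryophyllene, α-ionone, β-ocimene."""
        net = build_flavor_network(group_results["RS"], thresholds)
        w = descriptor_weights(net)
        # printed ROAVs sum to 31.74; recomputed contents give the same
        # within the 2-decimal input rounding (4 compounds x ±0.05)
        assert w["sweet"] == pytest.approx(31.74, abs=0.2)
        assert set(net.neighbors("sweet")) == {
            "styrene", "caryophyllene", "α-ionone", "β-ocimene"
        }

    def test_bipartite_and_conservation(self, group_results, thresholds):
        net = build_flavor_network(group_results["RR"], thresholds)
        kinds = {n: a["kind"] for n, a in net.nodes(data=True)}
        for u, v in net.edges():
            assert {kinds[u], kinds[v]} == {"compound", "descriptor"}
        # descriptor weights conserve: sum = sum over compounds of roav*degree
        total_desc = descriptor_weights(net).sum()
        total_comp = sum(
            a["roav"] * net.degree(n)
            for n, a in net.nodes(data=True)
            if a["kind"] == "compound"
        )
        assert total_desc == pytest.approx(total_comp)

    def test_only_key_compounds_enter(self, group_results, thresholds):
        net = build_flavor_network(group_results["RS"], thresholds)
        comp_nodes = {n for n, a in net.nodes(data=True) if a["kind"] == "compound"}
        assert comp_nodes == set(group_results["RS"].key_compounds.index)

    def test_single_compound_single_descriptor(self):
        entries = [ThresholdEntry("a", 0.01, odor_descriptors=("fruity",))]
        res = compute_roav(compute_oav(_profile({"a": 100.0}), entries), "g")
        net = build_flavor_network(res, entries)
        assert net.number_of_nodes() == 2 and net.number_of_edges() == 1
        assert net.nodes["fruity"]["summed_roav"] == 100.0

    def test_duplicate_descriptor_deduplicated(self):
        entries = [ThresholdEntry("a", 0.01, odor_descriptors=("Sweet", "sweet "))]
        res = compute_roav(compute_oav(_profile({"a": 100.0}), entries), "g")
        net = build_flavor_network(res, entries)
        assert net.number_of_edges() == 1
        assert net.nodes["sweet"]["summed_roav"] == 100.0

    def test_key_without_descriptors_warns_isolated(self):
        entries = [
            ThresholdEntry("a", 0.01, odor_descriptors=()),
            ThresholdEntry("b", 0.02, odor_descriptors=("woody",)),
        ]
        res = compute_roav(compute_oav(_profile({"a": 60.0, "b": 40.0}), entries), "g")
        with pytest.warns(UserWarning, match="no odor descriptors"):
            net = build_flavor_network(res, entries)
        assert net.degree("a") == 0

    def test_edge_list_export(self, group_results, thresholds, tmp_path):
        net = build_flavor_network(group_results["RR"], thresholds)
        edges = network_to_edge_list(net)
        assert set(edges.columns) == {"compound", "descriptor", "weight"}
        assert len(edges) == net.number_of_edges()


def test_roav_report_mirrors_published_layout(group_results, thresholds):
    rep = roav_report([group_results["RS"], group_results["RR"]], thresholds)
    assert len(rep) == 12
    assert rep.loc["ethyl butanoate", "ROAV_RS"] == "<0.1"
    assert rep.loc["ethyl butanoate", "ROAV_RR"] == "100.00"
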