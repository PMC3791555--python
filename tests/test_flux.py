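"""Steady-state flux, workload, efficiency and class-level sharing."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chapflux.datasets import load_workload_table
from chapflux.flux import (
    ProteinRecord,
    class_fractions,
    efficiency,
    flux_table,
    impute_kdeg,
    kdeg_from_half_life,
    substrate_flux,
    substrate_volume,
    synthesis_rate,
    workload_table,
)
from chapflux.interactome import ChaperoneNetwork


class TestKdeg:
    def test_half_life_ln2_gives_unit_rate(self):
        assert kdeg_from_half_life(math.log(2)) == pytest.approx(1.0)

    def test_long_half_life_limit(self):
        assert kdeg_from_half_life(1e12) == pytest.approx(0.0, abs=1e-9)

    def test_typical_half_life(self):
        assert kdeg_from_half_life(43.0) == pytest.approx(0.016120, abs=1e-5)

    def test_dilution_rate_adds(self):
        assert kdeg_from_half_life(43.0, dilution_rate=0.001) == pytest.approx(
            math.log(2) / 43 + 0.001)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kdeg_from_half_life(0.0)


class TestImputation:
    def test_geometric_mean_of_two(self):
        recs = {
            "a": ProteinRecord("a", cpc=1, k_deg=0.01),
            "b": ProteinRecord("b", cpc=1, k_deg=0.04),
            "c": ProteinRecord("c", cpc=1, k_deg=None),
        }
        out = impute_kdeg(recs)
        assert out["c"].k_deg == pytest.approx(0.02, rel=1e-12)

    def test_geometric_mean_closed_form(self):
        recs = {
            "a": ProteinRecord("a", cpc=1, k_deg=0.001),
            "b": ProteinRecord("b", cpc=1, k_deg=0.01),
            "c": ProteinRecord("c", cpc=1, k_deg=0.1),
            "d": ProteinRecord("d", cpc=1, k_deg=None),
        }
        assert impute_kdeg(recs)["d"].k_deg == pytest.approx(0.01, rel=1e-12)

    def test_no_missing_is_identity(self):
        recs = {"a": ProteinRecord("a", cpc=1, k_deg=0.5)}
        assert impute_kdeg(recs) == recs

    def test_observed_values_untouched(self):
        recs = {
            "a": ProteinRecord("a", cpc=2, k_deg=0.3),
            "b": ProteinRecord("b", cpc=5, k_deg=None),
        }
        out = impute_kdeg(recs)
        assert out["a"].k_deg == 0.3
        # total flux over observed proteins is unchanged by imputation
        assert out["a"].k_syn == recs["a"].k_syn

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_kdeg({"a": ProteinRecord("a", cpc=1, k_deg=None)})


def test_synthesis_rate():
    assert synthesis_rate(60_000, 0.01) == 600
    assert synthesis_rate(123.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        synthesis_rate(-1, 0.1)


class TestSubstrateVolume:
    def test_sums_available_abundances(self, toy_network):
        v, n_data, n_targets = substrate_volume(
            toy_network, {"S1": 100.0, "S2": 200.0}, "C1")
        assert v == 300 and n_data == 2 and n_targets == 3

    def test_no_substrates_is_zero(self):
        net = ChaperoneNetwork(chaperones={"C1"}, edges=set())
        assert substrate_volume(net, {}, "C1") == (0.0, 0, 0)

    def test_unknown_chaperone_rejected(self, toy_network):
        with pytest.raises(KeyError):
            substrate_volume(toy_network, {}, "NOPE")


class TestSubstrateFlux:
    def test_full_mode_sums_ksyn(self):
        net = ChaperoneNetwork(chaperones={"C1"},
                               edges={("C1", "S1"), ("C1", "S2")})
        recs = {
            "S1": ProteinRecord("S1", cpc=100, k_deg=0.1),
            "S2": ProteinRecord("S2", cpc=200, k_deg=0.05),
        }
        assert substrate_flux(net, recs, "C1", share_mode="full") == 20

    def test_equal_split_halves_shared_substrates(self):
        net = ChaperoneNetwork(
            chaperones={"C1", "C2"},
            edges={("C1", "S1"), ("C1", "S2"), ("C2", "S1"), ("C2", "S2")})
        recs = {
            "S1": ProteinRecord("S1", cpc=100, k_deg=0.1),
            "S2": ProteinRecord("S2", cpc=200, k_deg=0.05),
        }
        assert substrate_flux(net, recs, "C1") == 10

    def test_unknown_mode_rejected(self, toy_network, toy_records):
        with pytest.raises(ValueError):
            substrate_flux(toy_network, toy_records, "C1", share_mode="half")

    def test_equal_split_conserves_total_flux(self, toy_network, toy_records):
        total = sum(
            substrate_flux(toy_network, toy_records, c)
            for c in toy_network.chaperones)
        expected = sum(toy_records[s].k_syn for s in toy_network.substrates)
        assert total == pytest.approx(expected, rel=1e-12)

    def test_adding_substrate_is_monotone(self, toy_records):
        net = ChaperoneNetwork(chaperones={"C1"}, edges={("C1", "S1")})
        before = substrate_flux(net, toy_records, "C1")
        net.edges.add(("C1", "S2"))
        assert substrate_flux(net, toy_records, "C1") >= before


class TestEfficiency:
    def test_top_chaperone_throughput(self):
        # flux 1 172 700 cpc/min over 85 650 copies → ~13.7/min per copy
        eff, log2_eff = efficiency(1_172_700, 85_650)
        assert eff == pytest.approx(13.69, abs=0.01)
        assert round(eff) == 14

    def test_log2(self):
        eff, log2_eff = efficiency(8_000, 1_000)
        assert eff == 8 and log2_eff == 3

    def test_zero_flux(self):
        eff, log2_eff = efficiency(0.0, 1_000)
        assert eff == 0 and log2_eff is None

    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError):
            efficiency(10.0, 0.0)


class TestWorkloadTable:
    def test_rank_and_tie_break(self):
        net = ChaperoneNetwork(
            chaperones={"c1", "c2", "c3"},
            edges={("c1", "s1"), ("c2", "s2"), ("c3", "s3")})
        recs = {
            "c1": ProteinRecord("c1", cpc=10, k_deg=0.1, chaperone_class="CCT"),
            "c2": ProteinRecord("c2", cpc=10, k_deg=0.1, chaperone_class="CCT"),
            "c3": ProteinRecord("c3", cpc=10, k_deg=0.1, chaperone_class="CCT"),
            "s1": ProteinRecord("s1", cpc=50, k_deg=0.1),
            "s2": ProteinRecord("s2", cpc=90, k_deg=0.1),
            "s3": ProteinRecord("s3", cpc=90, k_deg=0.1),
        }
        tab = workload_table(net, recs)
        assert list(tab["orf"]) == ["c2", "c3", "c1"]

    def test_top_k_larger_than_count(self, toy_network, toy_records):
        tab = workload_table(toy_network, toy_records, top_k=100)
        assert len(tab) == 3

    def test_published_top_row(self):
        tab = load_workload_table()
        top = tab.iloc[0]
        assert top["substrate_flux_cpc_per_min"] == 1_172_700
        assert top["chaperone_class"] == "HSP70"
        assert round(top["substrate_flux_cpc_per_min"]
                     / top["chaperone_cpc"]) == 14


class TestClassFractions:
    def test_single_class_gets_all(self):
        net = ChaperoneNetwork(chaperones={"C1"}, edges={("C1", "S1")})
        recs = {
            "C1": ProteinRecord("C1", cpc=10, k_deg=0.1, chaperone_class="HSP70"),
            "S1": ProteinRecord("S1", cpc=100, k_deg=0.1),
        }
        b = class_fractions(net, recs)
        assert b.class_share["flux"] == {"HSP70": 1.0}

    def test_shared_substrate_split_between_classes(self, toy_records):
        net = ChaperoneNetwork(
            chaperones={"C1", "C2"}, edges={("C1", "S3"), ("C2", "S3")})
        b = class_fractions(net, toy_records)
        assert b.class_share["flux"]["HSP70"] == pytest.approx(0.5)
        assert b.class_share["flux"]["CCT"] == pytest.approx(0.5)

    def test_empty_network_all_zero(self, toy_records):
        net = ChaperoneNetwork(chaperones={"C1"}, edges=set())
        b = class_fractions(net, toy_records)
        for m in ("count", "volume", "flux"):
            assert b.mediated_fraction[m]["all"] == 0.0

    def test_shares_sum_to_one(self, toy_network, toy_records):
        b = class_fractions(toy_network, toy_records)
        for m in ("count", "volume", "flux"):
            assert sum(b.class_share[m].values()) == pytest.approx(1.0, abs=1e-9)

    def test_unclassed_chaperone_rejected(self, toy_network, toy_records):
        recs = dict(toy_records)
        recs["C1"] = ProteinRecord("C1", cpc=1000, k_deg=0.01)
        with pytest.raises(ValueError):
            class_fractions(toy_network, recs)

    def test_essential_cross_fractions(self, toy_network, toy_records):
        b = class_fractions(toy_network, toy_records)
        # only S4 is essential, and it is a substrate
        total = sum(r.k_syn for r in toy_records.values())
        assert b.essential["mediated_essential_flux"] == pytest.approx(
            toy_records["S4"].k_syn / total)
        assert b.essential["unmediated_essential_flux"] == 0.0


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(1e-4, 1.0), min_size=2, max_size=8),
       st.floats(10, 1e5))
def test_flux_conservation_property(kdegs, cpc):
    """Equal-split F_c summed over chaperones equals total substrate k_syn."""
    subs = {f"S{i}": ProteinRecord(f"S{i}", cpc=cpc, k_deg=k)
            for i, k in enumerate(kdegs)}
    edges = set()
    for i, s in enumerate(subs):
        edges.add((f"C{i % 3}", s))
        if i % 2:
            edges.add((f"C{(i + 1) % 3}", s))
    net = ChaperoneNetwork(chaperones={"C0", "C1", "C2"}, edges=edges)
    total = sum(substrate_flux(net, subs, c) for c in net.chaperones)
    expected = sum(subs[s].k_syn for s in net.substrates)
    assert total == pytest.approx(expected, rel=1e-9)
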