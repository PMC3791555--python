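"""Synthetic-data generator: determinism, planted structure, round-trips."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from chapflux import io
from chapflux.flux import impute_kdeg
from chapflux.interactome import build_hq_network, filter_reciprocal
from chapflux.simulate import (
    SimulationConfig,
    SourceConfig,
    generate_interactome,
    generate_proteome,
    generate_srm_replicates,
)
from chapflux.srm import quantify_proteins, round_cpc


def small_config(**overrides) -> SimulationConfig:
    base = dict(seed=5, n_substrates=300,
                class_sizes={"HSP70": 6, "CCT": 4, "HSP40": 6, "PFD": 4})
    base.update(overrides)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            cfg = small_config()
            rec, truth = generate_proteome(cfg)
            srcs = generate_interactome(cfg, rec, truth)
            ms = generate_srm_replicates(cfg, rec)
            io.write_proteome(tmp_path / f"prot_{run}.tsv", rec)
            io.write_edges(tmp_path / f"edges_{run}.tsv",
                           [e for es in srcs.values() for e in es])
            io.write_srm_measurements(tmp_path / f"srm_{run}.tsv", ms)
        for stem in ("prot", "edges", "srm"):
            a = (tmp_path / f"{stem}_a.tsv").read_bytes()
            b = (tmp_path / f"{stem}_b.tsv").read_bytes()
            assert a == b

    def test_different_seed_differs(self):
        rec1, _ = generate_proteome(small_config(seed=1))
        rec2, _ = generate_proteome(small_config(seed=2))
        cpc1 = [r.cpc for r in rec1.values()]
        cpc2 = [r.cpc for r in rec2.values()]
        assert cpc1 != cpc2


class TestProteome:
    def test_no_substrates_gives_chaperones_only(self):
        rec, _ = generate_proteome(small_config(n_substrates=0))
        assert all(r.chaperone_class is not None for r in rec.values())
        assert len(rec) == 20

    def test_abundance_model_median(self):
        cfg = SimulationConfig(seed=9, n_substrates=10_000)
        rec, _ = generate_proteome(cfg)
        subs = [r.cpc for r in rec.values() if r.chaperone_class is None]
        assert np.median(np.log10(subs)) == pytest.approx(3.0, abs=0.05)

    def test_missing_kdeg_fraction(self):
        cfg = SimulationConfig(seed=9, n_substrates=5000)
        rec, _ = generate_proteome(cfg)
        missing = np.mean([r.k_deg is None for r in rec.values()])
        assert missing == pytest.approx(0.2, abs=0.03)

    def test_essential_fraction_planted(self):
        cfg = SimulationConfig(seed=9, n_substrates=5000)
        rec, truth = generate_proteome(cfg)
        frac = np.mean([r.essential for r in rec.values()])
        assert frac == pytest.approx(truth.essential_fraction, abs=0.05)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_proteome(small_config(essential_fraction=1.5))


class TestInteractome:
    def test_perfect_reciprocity_recovers_observed_edges(self):
        cfg = small_config(sources=(
            SourceConfig("biogrid-like", detection_prob=1.0,
                         reciprocity_prob=1.0, n_noise_edges=0),))
        rec, truth = generate_proteome(cfg)
        srcs = generate_interactome(cfg, rec, truth)
        kept = filter_reciprocal(srcs["biogrid-like"])
        pairs = {tuple(sorted((e.bait, e.prey))) for e in kept}
        expected = {tuple(sorted(p)) for p in truth.true_edges}
        assert pairs == expected

    def test_reciprocity_filter_improves_precision(self):
        cfg = small_config(seed=13)
        rec, truth = generate_proteome(cfg)
        srcs = generate_interactome(cfg, rec, truth)
        edges = srcs["biogrid-like"]
        true_pairs = {tuple(sorted(p)) for p in truth.true_edges}

        def precision(es):
            pairs = {tuple(sorted((e.bait, e.prey))) for e in es}
            return len([p for p in pairs if p in true_pairs]) / len(pairs)

        assert precision(filter_reciprocal(edges)) >= precision(edges)

    def test_gamma_zero_degree_uncorrelated(self):
        # the null Spearman over ~60 chaperones has SD ~0.13, so average
        # over replicate simulations to test the planted independence
        rhos = []
        for seed in range(21, 26):
            cfg = SimulationConfig(seed=seed, workload_exponent=0.0)
            rec, truth = generate_proteome(cfg)
            generate_interactome(cfg, rec, truth)
            degree = {}
            for c, s in truth.true_edges:
                degree[c] = degree.get(c, 0) + 1
            chaps = sorted(o for o, r in rec.items() if r.chaperone_class)
            rhos.append(spearmanr(
                [rec[c].cpc for c in chaps],
                [degree.get(c, 0) for c in chaps]).statistic)
        assert abs(np.mean(rhos)) < 0.15

    def test_gamma_one_workload_correlated(self):
        cfg = SimulationConfig(seed=21, workload_exponent=1.0)
        rec, truth = generate_proteome(cfg)
        srcs = generate_interactome(cfg, rec, truth)
        chaps = {o for o, r in rec.items() if r.chaperone_class}
        net = build_hq_network(list(srcs.values()), chaps)
        degrees = {c: len(net.targets(c)) for c in sorted(chaps)}
        rho = spearmanr([rec[c].cpc for c in sorted(chaps)],
                        [degrees[c] for c in sorted(chaps)]).statistic
        assert rho > 0.3


class TestSrmRoundTrip:
    def test_zero_noise_exact_recovery(self):
        cfg = small_config(ratio_cv=0.0, fdr_fail_prob=0.0)
        rec, _ = generate_proteome(cfg)
        ms = generate_srm_replicates(cfg, rec)
        quants = {q.orf: q for q in quantify_proteins(ms)}
        chaps = {o: r for o, r in rec.items() if r.chaperone_class}
        assert set(quants) == set(chaps)
        for orf, r in chaps.items():
            assert quants[orf].qtype == "A"
            assert quants[orf].cpc == round_cpc(r.cpc)

    def test_noisy_recovery_median_error_under_ten_percent(self):
        cfg = SimulationConfig(
            seed=17, n_substrates=0,
            class_sizes={"HSP70": 100, "CCT": 100}, ratio_cv=0.1)
        rec, _ = generate_proteome(cfg)
        ms = generate_srm_replicates(cfg, rec)
        quants = {q.orf: q for q in quantify_proteins(ms)}
        errs = [abs(quants[o].cpc - r.cpc) / r.cpc
                for o, r in rec.items() if quants[o].qtype == "A"]
        assert np.median(errs) < 0.10

    def test_low_abundance_yields_type_b(self):
        cfg = small_config(ratio_cv=0.0, fdr_fail_prob=0.0,
                           chap_cpc_min=0.0, chap_log10_cpc_mean=-2.0,
                           chap_log10_cpc_sd=0.1)
        rec, _ = generate_proteome(cfg)
        ms = generate_srm_replicates(cfg, rec)
        quants = quantify_proteins(ms)
        assert all(q.qtype == "B" for q in quants)
        assert all(q.bound_cpc == 600 for q in quants)


def test_round_trip_through_readers(tmp_path):
    cfg = small_config()
    rec, truth = generate_proteome(cfg)
    srcs = generate_interactome(cfg, rec, truth)
    ms = generate_srm_replicates(cfg, rec)

    io.write_proteome(tmp_path / "p.tsv", rec)
    back = io.read_proteome(tmp_path / "p.tsv")
    assert set(back) == set(rec)
    for orf in rec:
        assert back[orf].loci == rec[orf].loci
        assert back[orf].essential == rec[orf].essential
        if rec[orf].cpc is not None:
            assert back[orf].cpc == pytest.approx(rec[orf].cpc, rel=1e-9)

    all_edges = [e for es in srcs.values() for e in es]
    io.write_edges(tmp_path / "e.tsv", all_edges)
    back_edges = io.read_edges(tmp_path / "e.tsv")
    assert {(e.bait, e.prey, e.source) for e in back_edges} == {
        (e.bait, e.prey, e.source) for e in all_edges}

    io.write_srm_measurements(tmp_path / "m.tsv", ms)
    back_ms = io.read_srm_measurements(tmp_path / "m.tsv")
    assert len(back_ms) == len(ms)
    assert back_ms[0].ratio_light_heavy == pytest.approx(
        ms[0].ratio_light_heavy, rel=1e-9)
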