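"""Generator determinism, construction guarantees and planted recovery."""

import numpy as np
import pandas as pd
import pytest

from ucsig._errors import ConfigError
from ucsig.combine import combine_datasets
from ucsig.cross_species import overlap_species, tally_concordance
from ucsig.sde import call_sde
from ucsig.synth import (
    BundleConfig,
    SynthDEConfig,
    SynthMirnaConfig,
    synth_bundle,
    synth_de,
    synth_loci,
    synth_mirna_de,
    synth_network,
)


def zero_noise_config(**kw):
    return SynthDEConfig(sigma=0.0, **kw)


class TestSynthDE:
    def test_all_null_universe_has_no_significant_gene(self):
        cfg = zero_noise_config(
            n_concordant_up=0, n_concordant_down=0, n_contra=0,
            n_inconsistent=0, n_species_specific=0, n_null=100,
        )
        tables, _ = synth_de(cfg, seed=5)
        for t in tables:
            assert (t.records["padj"] > 0.05).all()

    def test_seed_determinism(self):
        cfg = SynthDEConfig(n_null=50)
        t1, truth1 = synth_de(cfg, seed=9)
        t2, truth2 = synth_de(cfg, seed=9)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.records, b.records)
        assert truth1.classes == truth2.classes

    def test_class_sizes_respected_and_disjoint(self):
        cfg = SynthDEConfig()
        _, truth = synth_de(cfg, seed=1)
        sizes = cfg.class_sizes()
        seen = set()
        for cls, pairs in truth.classes.items():
            assert len(pairs) == sizes[cls]
            ids = {m for m, _ in pairs}
            assert not ids & seen
            seen |= ids

    def test_negative_class_size_rejected(self):
        with pytest.raises(ConfigError):
            synth_de(SynthDEConfig(n_null=-1), seed=0)

    def test_planted_concordant_recovery_through_pipeline_ops(self):
        cfg = zero_noise_config(n_concordant_up=50, n_concordant_down=0, n_contra=0,
                                n_inconsistent=0, n_species_specific=0, n_null=200)
        tables, truth = synth_de(cfg, seed=3)
        mouse = call_sde(tables[0], lfc_min_total=0.0)
        human = combine_datasets(tables[1:])
        ct = overlap_species(mouse, human, truth.orthology)
        got = set(ct.gene_classes["mouse_gene_id"])
        assert got == {m for m, _ in truth.classes["concordant_up"]}
        assert (ct.gene_classes["gene_class"] == "concordant_up").all()

    def test_single_support_genes_excluded_from_combination(self):
        cfg = zero_noise_config(n_single_support=10, n_null=100)
        tables, truth = synth_de(cfg, seed=4)
        human = combine_datasets(tables[1:])
        single_humans = {h for _, h in truth.classes["single_support"]}
        assert not single_humans & (set(human.entries) | human.inconsistent)


class TestSynthMirna:
    def test_borderline_mirnas_only_pass_relaxed_cutoff(self):
        from ucsig.cross_species import relaxed_mirna_overlap

        cfg = SynthMirnaConfig(sigma=0.0)
        tables, truth = synth_mirna_de(cfg, seed=6)
        orth = truth.orthology
        mouse = call_sde(tables[0], lfc_min_total=0.0, fc_min_mirna=1.0)
        from ucsig.combine import combine_mirna

        strict = tally_concordance(
            overlap_species(mouse, combine_mirna(tables[1:]), orth))
        relaxed = tally_concordance(relaxed_mirna_overlap(tables[0], tables[1:], orth))
        n_signal = cfg.n_concordant_up + cfg.n_concordant_down + cfg.n_contra
        assert strict["n_total_common"] == n_signal
        assert relaxed["n_total_common"] == n_signal + cfg.n_borderline

    def test_strict_result_subset_of_relaxed(self):
        from ucsig.combine import combine_mirna
        from ucsig.cross_species import relaxed_mirna_overlap

        tables, truth = synth_mirna_de(SynthMirnaConfig(), seed=8)
        mouse = call_sde(tables[0], lfc_min_total=0.0, fc_min_mirna=1.0)
        strict = overlap_species(mouse, combine_mirna(tables[1:]), truth.orthology)
        relaxed = relaxed_mirna_overlap(tables[0], tables[1:], truth.orthology)
        # relaxing the cutoff can only add genes, except where the wider
        # significance window newly exposes a direction conflict (the gene
        # then moves to the inconsistent partition instead)
        human_relaxed = combine_mirna(tables[1:], padj_max=0.1, strict_padj=True)
        newly_inconsistent = {
            m for m, h, _ in truth.orthology.pairs.itertuples(index=False)
            if h in human_relaxed.inconsistent
        }
        assert set(strict.gene_classes["mouse_gene_id"]) <= (
            set(relaxed.gene_classes["mouse_gene_id"]) | newly_inconsistent)


class TestLociAndNetwork:
    def test_empty_loci(self):
        loci, truth = synth_loci(0, seed=0)
        assert loci == [] and truth == {}

    def test_loci_determinism_and_invariants(self):
        a, _ = synth_loci(100, seed=5)
        b, _ = synth_loci(100, seed=5)
        assert a == b
        assert all(1 <= l.start <= l.end for l in a)

    def test_single_hub_star_dominates(self):
        from ucsig.network_rank import rank_genes

        net = synth_network([f"g{i}" for i in range(10)], 0, ("HUB1",), seed=0,
                            noise_edge_prob=0.0)
        assert rank_genes(net).table.iloc[0]["node"] == "HUB1"

    def test_network_determinism(self):
        import networkx as nx

        g1 = synth_network([f"g{i}" for i in range(20)], 10, ("H",), seed=3)
        g2 = synth_network([f"g{i}" for i in range(20)], 10, ("H",), seed=3)
        assert nx.utils.graphs_equal(g1, g2)

    def test_hub_edges_have_high_confidence(self):
        g = synth_network([f"g{i}" for i in range(20)], 5, ("H",), seed=4)
        hub_confs = {d["confidence"] for _, _, d in g.edges("H", data=True)}
        assert hub_confs == {0.9}


class TestBundle:
    def test_bundle_determinism(self):
        b1 = synth_bundle(seed=11)
        b2 = synth_bundle(seed=11)
        pd.testing.assert_frame_equal(
            b1.colon_tables[0].records, b2.colon_tables[0].records)
        assert b1.expected_core() == b2.expected_core()
        assert b1.planted_fc == b2.planted_fc

    def test_core_planted_in_both_tissues(self):
        cfg = BundleConfig()
        cfg.colon.sigma = 0.0
        cfg.blood.sigma = 0.0
        b = synth_bundle(cfg, seed=13)
        core = b.expected_core()
        assert len(core) >= cfg.n_core_planted
        colon_conc = {m for c in ("concordant_up", "concordant_down")
                      for m, _ in b.colon_truth.classes[c]}
        blood_conc = {m for c in ("concordant_up", "concordant_down")
                      for m, _ in b.blood_truth.classes[c]}
        assert core == colon_conc & blood_conc

    def test_write_bundle_is_readable_back(self, tmp_path):
        from ucsig.pipeline import _read_bundle_dir
        from ucsig.synth import write_bundle

        b = synth_bundle(seed=2)
        write_bundle(b, tmp_path / "bundle")
        back = _read_bundle_dir(tmp_path / "bundle")
        assert len(back.colon_tables) == len(b.colon_tables)
        assert back.planted_fc == b.planted_fc
        assert back.neighbor_truth == b.neighbor_truth
        # undirected edges; on-disk confidence is quantized to 1/1000
        assert {frozenset(e) for e in back.network.edges} == {
            frozenset(e) for e in b.network.edges}
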