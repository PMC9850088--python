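"""Ortholog overlap, concordance classes, tallies and the core set."""

import pandas as pd
import pytest

from ucsig._errors import UsageError
from ucsig.cross_species import (
    core_set,
    overlap_species,
    tally_concordance,
    tally_from_counts,
)
from ucsig.types import ConcordanceTable, OrthologyMap, SDESet


def orth(pairs):
    return OrthologyMap(
        pairs=pd.DataFrame(pairs, columns=["mouse_gene_id", "human_gene_id", "relation"])
    )


def sde(species, entries, tissue="colon", inconsistent=None):
    return SDESet(species=species, tissue=tissue, source="x", entries=entries,
                  inconsistent=inconsistent or set())


class TestOverlap:
    def test_direction_pair_classes(self):
        o = orth([("m1", "h1", "one2one"), ("m2", "h2", "one2one"), ("m3", "h3", "one2one")])
        ct = overlap_species(
            sde("mouse", {"m1": "up", "m2": "down", "m3": "up"}),
            sde("human", {"h1": "up", "h2": "down", "h3": "down"}),
            o,
        )
        got = dict(zip(ct.rows["mouse_gene_id"], ct.rows["pair_class"]))
        assert got == {"m1": "concordant_up", "m2": "concordant_down", "m3": "contra"}

    def test_one2many_counts_mouse_gene_once(self):
        o = orth([("m1", "h1", "one2many"), ("m1", "h2", "one2many")])
        ct = overlap_species(
            sde("mouse", {"m1": "up"}), sde("human", {"h2": "up"}), o
        )
        # only the h2 pair matches; m1 counted once, concordant
        assert len(ct.rows) == 1
        assert list(ct.gene_classes["gene_class"]) == ["concordant_up"]

    def test_one2many_any_concordant_pair_wins(self):
        o = orth([("m1", "h1", "one2many"), ("m1", "h2", "one2many")])
        ct = overlap_species(
            sde("mouse", {"m1": "up"}), sde("human", {"h1": "down", "h2": "up"}), o
        )
        assert len(ct.rows) == 2
        assert list(ct.gene_classes["gene_class"]) == ["concordant_up"]

    def test_inconsistent_genes_excluded_before_overlap(self):
        o = orth([("m1", "h1", "one2one")])
        ct = overlap_species(
            sde("mouse", {"m1": "up"}),
            sde("human", {"h1": "up"}, inconsistent=set()),
            o,
        )
        assert len(ct.rows) == 1
        human = SDESet(species="human", tissue="colon", source="x",
                       entries={}, inconsistent={"h1"})
        ct2 = overlap_species(sde("mouse", {"m1": "up"}), human, o)
        assert len(ct2.rows) == 0

    def test_matches_brute_force_pair_enumeration(self):
        import numpy as np

        rng = np.random.default_rng(11)
        n = 200
        pairs = [(f"m{i}", f"h{i}", "one2one") for i in range(n)]
        m_set = {f"m{i}": rng.choice(["up", "down"]) for i in rng.choice(n, 80, replace=False)}
        h_set = {f"h{i}": rng.choice(["up", "down"]) for i in rng.choice(n, 90, replace=False)}
        ct = overlap_species(sde("mouse", m_set), sde("human", h_set), orth(pairs))
        brute = {
            (m, h)
            for m, hum, _ in pairs
            for h in [hum]
            if m in m_set and h in h_set
        }
        assert set(zip(ct.rows["mouse_gene_id"], ct.rows["human_gene_id"])) == brute

    def test_tissue_mismatch_rejected(self):
        o = orth([("m1", "h1", "one2one")])
        with pytest.raises(UsageError):
            overlap_species(
                sde("mouse", {"m1": "up"}, tissue="colon"),
                sde("human", {"h1": "up"}, tissue="blood"),
                o,
            )

    def test_species_flip_symmetry(self):
        """Flipping all directions on both sides leaves class counts invariant."""
        o = orth([(f"m{i}", f"h{i}", "one2one") for i in range(6)])
        m = {"m0": "up", "m1": "up", "m2": "down", "m3": "down", "m4": "up"}
        h = {"h0": "up", "h1": "down", "h2": "down", "h3": "up", "h4": "up"}
        flip = {"up": "down", "down": "up"}
        t1 = tally_concordance(overlap_species(sde("mouse", m), sde("human", h), o))
        t2 = tally_concordance(
            overlap_species(
                sde("mouse", {k: flip[v] for k, v in m.items()}),
                sde("human", {k: flip[v] for k, v in h.items()}),
                o,
            )
        )
        assert t1["n_contra"] == t2["n_contra"]
        assert t1["n_same_direction"] == t2["n_same_direction"]


class TestTallies:
    @pytest.mark.parametrize(
        "counts,total,same",
        [((1082, 360, 495), 1937, 1442), ((154, 3, 2), 159, 157), ((0, 0, 0), 0, 0)],
    )
    def test_tally_identities(self, counts, total, same):
        t = tally_from_counts(*counts)
        assert t["n_total_common"] == total
        assert t["n_same_direction"] == same

    def test_empty_table_all_zeros(self):
        ct = ConcordanceTable(tissue="colon", rows=pd.DataFrame(),
                              gene_classes=pd.DataFrame(columns=["mouse_gene_id", "gene_class"]))
        assert tally_concordance(ct) == {
            "n_total_common": 0, "n_up_up": 0, "n_down_down": 0,
            "n_contra": 0, "n_same_direction": 0,
        }


class TestCoreSet:
    def ct(self, tissue, classes):
        gene_df = pd.DataFrame(
            [(m, m.replace("m", "h"), c, "up" if c == "concordant_up" else "down")
             for m, c in classes.items()],
            columns=["mouse_gene_id", "human_gene_id", "gene_class", "mouse_dir"],
        )
        return ConcordanceTable(tissue=tissue, rows=pd.DataFrame(columns=["pair_class"]),
                                gene_classes=gene_df)

    def test_concordant_in_both_with_agreement_flag(self):
        colon = self.ct("colon", {"m1": "concordant_up", "m2": "concordant_down",
                                  "m3": "concordant_up"})
        blood = self.ct("blood", {"m1": "concordant_up", "m2": "concordant_up",
                                  "m3": "contra"})
        cs = core_set(colon, blood)
        got = cs.members.set_index("mouse_gene_id")
        # m1 agrees across tissues; m2 is the opposite-direction pattern; m3 (contra) excluded
        assert set(got.index) == {"m1", "m2"}
        assert bool(got.loc["m1", "agreement"]) is True
        assert bool(got.loc["m2", "agreement"]) is False
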