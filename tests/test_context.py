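"""Window arithmetic for neighbors and risk loci; target-set coverage."""

import pytest

from ucsig._errors import UsageError
from ucsig.context import (
    build_target_sets,
    interval_gap,
    lncrna_neighbors,
    risk_locus_proximity,
)
from ucsig.synth import synth_loci, synth_risk_loci, synth_target_map
from ucsig.types import GeneLocus


def locus(gid, start, end, chrom="chr1", biotype="pcg", expressed=True):
    return GeneLocus(gene_id=gid, chrom=chrom, start=start, end=end,
                     biotype=biotype, expressed=expressed)


class TestNeighbors:
    def test_window_arithmetic(self):
        loci = [
            locus("lnc1", 200_000, 201_000, biotype="lncrna"),
            locus("pcgA", 150_000, 151_000),           # gap 48,999 < 100 kb
            locus("pcgB", 150_000, 151_000, chrom="chr2"),  # wrong chromosome
            locus("pcgC", 450_000, 451_000),           # gap > 100 kb
        ]
        nb = lncrna_neighbors(["lnc1"], loci)
        assert nb.neighbors == {"lnc1": {"pcgA"}}

    def test_inclusive_boundary(self):
        # window ends at 201000 + 100000 = 301000
        loci = [
            locus("lnc1", 200_000, 201_000, biotype="lncrna"),
            locus("pcg_in", 301_000, 302_000),
            locus("pcg_out", 301_001, 302_000),
        ]
        nb = lncrna_neighbors(["lnc1"], loci)
        assert nb.neighbors == {"lnc1": {"pcg_in"}}

    def test_unexpressed_pcg_excluded_unless_requested(self):
        loci = [
            locus("lnc1", 200_000, 201_000, biotype="lncrna"),
            locus("pcg_off", 210_000, 211_000, expressed=False),
        ]
        assert lncrna_neighbors(["lnc1"], loci).neighbors == {"lnc1": set()}
        nb = lncrna_neighbors(["lnc1"], loci, expressed_only=False)
        assert nb.neighbors == {"lnc1": {"pcg_off"}}

    def test_missing_lnc_id_is_error(self):
        with pytest.raises(UsageError, match="ghost"):
            lncrna_neighbors(["ghost"], [locus("pcg1", 1, 10)])

    def test_matches_generator_brute_force(self):
        loci, truth = synth_loci(400, seed=9)
        lncs = [l.gene_id for l in loci if l.biotype == "lncrna"]
        nb = lncrna_neighbors(lncs, loci, window_bp=100_000)
        assert nb.neighbors == truth

    def test_window_monotonicity(self):
        loci, _ = synth_loci(150, seed=4)
        lncs = [l.gene_id for l in loci if l.biotype == "lncrna"]
        small = lncrna_neighbors(lncs, loci, window_bp=50_000).neighbors
        big = lncrna_neighbors(lncs, loci, window_bp=200_000).neighbors
        assert all(small[l] <= big[l] for l in lncs)


class TestRiskLoci:
    def test_distance_flagging(self):
        loci = [locus("g1", 590_000, 600_000), locus("g2", 590_000, 600_000, chrom="chr2")]
        risk = [locus("r1", 500_000, 500_000)]
        flagged = risk_locus_proximity(["g1", "g2"], loci, risk)
        assert flagged == {"g1"}  # same coordinates on chr2 do not count

    def test_overlap_is_distance_zero(self):
        loci = [locus("g1", 100, 200)]
        risk = [locus("r1", 150, 160)]
        assert risk_locus_proximity(["g1"], loci, risk, window_bp=0) == {"g1"}

    def test_matches_brute_force_scan(self):
        loci, _ = synth_loci(300, seed=6)
        risk = synth_risk_loci(20, seed=7)
        ids = [l.gene_id for l in loci]
        flagged = risk_locus_proximity(ids, loci, risk, window_bp=100_000)
        brute = set()
        for g in loci:
            for r in risk:
                if g.chrom == r.chrom and interval_gap(g.start, g.end, r.start, r.end) <= 100_000:
                    brute.add(g.gene_id)
        assert flagged == brute

    def test_locus_order_invariance(self):
        loci, _ = synth_loci(100, seed=2)
        risk = synth_risk_loci(10, seed=3)
        ids = [l.gene_id for l in loci]
        a = risk_locus_proximity(ids, loci, risk)
        b = risk_locus_proximity(ids, list(reversed(loci)), list(reversed(risk)))
        assert a == b


class TestTargetSets:
    def test_expressed_filter_and_coverage(self):
        tmap = {"mir1": {"a", "b", "c", "x"}, "mir2": {"x", "y"}}
        ts = build_target_sets(["mir1", "mir2", "mir3"], tmap, {"a", "b", "c"})
        assert ts.targets == {"mir1": {"a", "b", "c"}, "mir2": set(), "mir3": set()}
        assert (ts.n_mirnas_with_targets, ts.n_input) == (1, 3)

    def test_union_matches_generator_truth(self):
        mirnas = [f"mir{i}" for i in range(30)]
        universe = [f"g{i}" for i in range(200)]
        tmap, covered = synth_target_map(mirnas, universe, uncovered_frac=0.3, seed=8)
        ts = build_target_sets(mirnas, tmap, universe)
        assert {m for m, s in ts.targets.items() if s} == covered
        assert ts.n_mirnas_with_targets == len(covered)
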