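"""Anchor building, block chaining (vs an exhaustive oracle), chromosome
pairing, H1/H2 assignment and positional-homoeolog links."""

import itertools

import numpy as np
import pytest

from diploscan.genome_io import GeneModel, GenomeBundle, RepeatFeature
from diploscan.homoeology import (
    AnchorPair,
    assign_groups,
    build_anchors,
    chain_blocks,
    homoeolog_map,
    pair_chromosomes,
)
from diploscan.simulate import SimulationConfig, simulate, truth_partner_links


def _bundle_with_families(n_fam, chroms=("chr1", "chr2"), big_family=0):
    genes, fams, seqs = [], {}, {}
    pos = {c: 0 for c in chroms}
    for c in chroms:
        seqs[c] = "A" * 100_000
    for i in range(n_fam):
        fam = f"f{i:03d}"
        fams[fam] = set()
        for c in chroms:
            gid = f"{fam}_{c}"
            s = pos[c]
            genes.append(GeneModel(gid, c, "+", [(s, s + 90)], [(s, s + 90)], family_id=fam))
            fams[fam].add(gid)
            pos[c] += 100
    if big_family:
        fam = "fbig"
        fams[fam] = set()
        for j in range(big_family):
            c = chroms[j % len(chroms)]
            s = pos[c]
            gid = f"fbig_{j}"
            genes.append(GeneModel(gid, c, "+", [(s, s + 90)], [(s, s + 90)], family_id=fam))
            fams[fam].add(gid)
            pos[c] += 100
    return GenomeBundle(sequences=seqs, genes=genes, families=fams, ploidy=2)


class TestAnchors:
    def test_single_copy_families_become_anchors(self):
        anchors = build_anchors(_bundle_with_families(10))
        assert len(anchors) == 10
        assert all(a.chrom_a != a.chrom_b for a in anchors)

    def test_overdispersed_family_excluded(self):
        bundle = _bundle_with_families(0, big_family=50)
        assert build_anchors(bundle) == []  # 50 > 8 x ploidy = 16

    def test_same_chromosome_pairs_excluded(self):
        bundle = _bundle_with_families(1, chroms=("chr1",), big_family=0)
        g2 = GeneModel("f000_b", "chr1", "+", [(5000, 5090)], [(5000, 5090)], family_id="f000")
        bundle.genes.append(g2)
        bundle.families["f000"].add("f000_b")
        assert build_anchors(bundle) == []


def _anchors(pairs):
    return [
        AnchorPair(f"a{i}", f"b{i}", "c1", "c2", ra, rb) for i, (ra, rb) in enumerate(pairs)
    ]


def _oracle_longest_chain(anchors, max_gap):
    """Exhaustive check over all subsets (n small): longest valid chain in
    either orientation."""
    best = 0
    idx = range(len(anchors))
    for r in range(len(anchors), best, -1):
        for sub in itertools.combinations(idx, r):
            ra = [anchors[i].rank_a for i in sub]
            rb = [anchors[i].rank_b for i in sub]
            order = sorted(range(len(sub)), key=lambda k: ra[k])
            ra_s = [ra[k] for k in order]
            rb_s = [rb[k] for k in order]
            def ok(seq_b, sign):
                for (a1, b1), (a2, b2) in zip(
                    zip(ra_s, seq_b), zip(ra_s[1:], seq_b[1:])
                ):
                    if not (0 < a2 - a1 <= max_gap):
                        return False
                    d = (b2 - b1) * sign
                    if not (0 < d <= max_gap):
                        return False
                return True
            if ok(rb_s, 1) or ok(rb_s, -1):
                return r
    return best


class TestChaining:
    def test_perfect_collinear_single_block(self):
        blocks = chain_blocks(_anchors([(i, i) for i in range(20)]), min_block_size=5)
        assert len(blocks) == 1
        assert blocks[0].score == 20 and blocks[0].orientation == "same"

    def test_reversed_ranks_inverted_block(self):
        blocks = chain_blocks(_anchors([(i, 19 - i) for i in range(20)]), min_block_size=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_internal_inversion_two_blocks(self):
        ranks_b = list(range(5)) + list(range(14, 4, -1)) + list(range(15, 20))
        blocks = chain_blocks(_anchors(list(enumerate(ranks_b))), min_block_size=3)
        sizes = sorted(b.score for b in blocks)
        assert len(blocks) == 2 and all(8 <= s <= 12 for s in sizes)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_exhaustive_chaining_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 13))
        pairs = list(zip(rng.permutation(30)[:n], rng.permutation(30)[:n]))
        anchors = _anchors([(int(a), int(b)) for a, b in pairs])
        blocks = chain_blocks(anchors, min_block_size=1, max_rank_gap=10)
        got = max((b.score for b in blocks), default=0)
        assert got == _oracle_longest_chain(anchors, max_gap=10)

    def test_block_anchor_monotonicity_enforced(self):
        for b in chain_blocks(_anchors([(i, i % 7) for i in range(20)]), min_block_size=2):
            b.check_monotone()


class TestPairing:
    def test_single_block_single_pair(self):
        blocks = chain_blocks(_anchors([(i, i) for i in range(10)]), min_block_size=5)
        assert pair_chromosomes(blocks) == [("c1", "c2")]

    def test_empty_blocks_no_pairs(self):
        assert pair_chromosomes([]) == []

    def test_simulated_pairing_matches_truth(self, rich_sim):
        _, bundles, _ = rich_sim
        hmap = homoeolog_map(bundles["focal"])
        assert hmap.chromosome_pairs == [("chr00A", "chr00B"), ("chr01A", "chr01B")]


class TestGroupAssignment:
    def test_repeat_burden_decides_h2(self):
        reps = [RepeatFeature("cA", 0, 10_000, "LTR/Gypsy", 5.0),
                RepeatFeature("cB", 0, 50_000, "LTR/Gypsy", 5.0)]
        labels = assign_groups([("cA", "cB")], reps)
        assert labels == {"cA": "H1", "cB": "H2"}

    def test_tie_breaks_by_name(self):
        labels = assign_groups([("cA", "cB")], [])
        assert labels == {"cA": "H1", "cB": "H2"}

    def test_input_order_invariance(self):
        reps = [RepeatFeature("cB", 0, 500, "LINE/L1", 1.0),
                RepeatFeature("cA", 0, 900, "LINE/L1", 1.0)]
        l1 = assign_groups([("cA", "cB")], reps)
        l2 = assign_groups([("cA", "cB")], list(reversed(reps)))
        assert l1 == l2 == {"cA": "H2", "cB": "H1"}


class TestLinks:
    def test_no_fractionation_all_linked(self, null_sim):
        _, bundles, truth = null_sim
        hmap = homoeolog_map(bundles["focal"])
        links = truth_partner_links(truth)
        assert all(hmap.gene_links.get(g) == p for g, p in links.items())
        assert "lost" not in hmap.gene_links.values()

    def test_lost_fraction_recovers_f(self):
        f = 0.3
        cfg = SimulationConfig(
            seed=21, n_chromosome_pairs=2, genes_per_chromosome=200,
            fractionation_prob=f,
        )
        bundles, truth = simulate(cfg)
        hmap = homoeolog_map(bundles["focal"])
        a_genes = [r.gene_id for r in truth.itertuples() if r.copy == "A" and r.gene_id]
        lost = sum(hmap.gene_links.get(g) == "lost" for g in a_genes)
        n = len(a_genes)
        se = np.sqrt(f * (1 - f) / n)
        assert abs(lost / n - f) <= 3 * se

    def test_unpaired_scaffold_gene_unplaced(self, null_sim):
        _, bundles, _ = null_sim
        focal = bundles["focal"]
        bundle = GenomeBundle(
            sequences={**focal.sequences, "scaf9": "A" * 1000},
            genes=focal.genes
            + [GeneModel("orphan", "scaf9", "+", [(0, 90)], [(0, 90)], family_id="solo")],
            families={**focal.families, "solo": {"orphan"}},
        )
        hmap = homoeolog_map(bundle)
        assert "orphan" in hmap.unplaced

    def test_links_symmetric(self, rich_sim):
        _, bundles, _ = rich_sim
        hmap = homoeolog_map(bundles["focal"])
        for g, p in hmap.gene_links.items():
            if p != "lost":
                assert hmap.gene_links.get(p) == g
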