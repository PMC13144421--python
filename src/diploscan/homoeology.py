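"""Homoeologous chromosome pairing and positional-homoeolog linking.

Synteny is detected on the gene-rank-order scale: cross-chromosome
same-family gene pairs become anchors, anchors are chained into collinear
blocks by longest increasing/decreasing subsequence dynamic programming,
chromosomes are paired greedily by summed block weight, and each pair is
split into the H1/H2 groups by repeat-affected size (the more repeat-covered
member is H2 by convention; every downstream statistic is invariant to a
label swap).  Genes joined by a block anchor are positional homoeologs; a
gene whose expected partner slot inside a block is empty is "lost"; the rest
are unplaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from diploscan.genome_io import GeneModel, GenomeBundle, RepeatFeature
from diploscan.intervals import total_length


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # same / inverted

    @property
    def score(self) -> int:
        return len(self.anchors)

    def check_monotone(self) -> None:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        assert ra == sorted(ra) and len(set(ra)) == len(ra), "rank_a not strictly increasing"
        if self.orientation == "same":
            assert rb == sorted(rb) and len(set(rb)) == len(rb), "rank_b not strictly increasing"
        else:
            assert rb == sorted(rb, reverse=True) and len(set(rb)) == len(rb), (
                "rank_b not strictly decreasing"
            )


@dataclass
class HomoeologMap:
    chromosome_pairs: list[tuple[str, str]]
    group_labels: dict[str, str]  # chromosome -> H1/H2
    gene_links: dict[str, str]  # gene_id -> partner gene_id or "lost"
    unplaced: set[str] = field(default_factory=set)

    def group_of(self, gene: GeneModel) -> str:
        return self.group_labels.get(gene.chromosome, "unplaced")


def gene_ranks(bundle: GenomeBundle) -> dict[str, tuple[str, int]]:
    """gene_id -> (chromosome, rank along chromosome) for predominant models."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in bundle.predominant_genes():
        by_chrom.setdefault(g.chromosome, []).append(g)
    ranks: dict[str, tuple[str, int]] = {}
    for chrom, gs in by_chrom.items():
        for rank, g in enumerate(sorted(gs, key=lambda g: (g.span, g.gene_id))):
            ranks[g.gene_id] = (chrom, rank)
    return ranks


def build_anchors(bundle: GenomeBundle, max_family_size: int | None = None) -> list[AnchorPair]:
    """Candidate anchors: cross-chromosome same-family gene pairs.

    Families larger than ``max_family_size`` (default 8 x ploidy, the
    overdispersion rule) are promiscuous and contribute no anchors.
    """
    if max_family_size is None:
        max_family_size = 8 * bundle.ploidy
    ranks = gene_ranks(bundle)
    anchors: list[AnchorPair] = []
    for fam in sorted(bundle.families):
        members = sorted(m for m in bundle.families[fam] if m in ranks)
        if len(members) < 2 or len(members) > max_family_size:
            continue
        for i, ga in enumerate(members):
            for gb in members[i + 1 :]:
                (ca, ra), (cb, rb) = ranks[ga], ranks[gb]
                if ca == cb:
                    continue
                if cb < ca:  # canonical orientation by chromosome name
                    ga, gb, ca, cb, ra, rb = gb, ga, cb, ca, rb, ra
                anchors.append(AnchorPair(ga, gb, ca, cb, ra, rb))
    return anchors


def _longest_chain(
    anchors: list[AnchorPair], max_rank_gap: int, decreasing: bool
) -> list[int]:
    """Indices of the longest chain strictly increasing in rank_a and strictly
    increasing (or decreasing) in rank_b with rank gaps <= max_rank_gap."""
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].rank_a, -anchors[i].rank_b if decreasing else anchors[i].rank_b),
    )
    best_len = [1] * len(order)
    prev = [-1] * len(order)
    for oi, i in enumerate(order):
        ai = anchors[i]
        for oj in range(oi):
            j = order[oj]
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            db = (aj.rank_b - ai.rank_b) if decreasing else (ai.rank_b - aj.rank_b)
            if 0 < da <= max_rank_gap and 0 < db <= max_rank_gap:
                if best_len[oj] + 1 > best_len[oi]:
                    best_len[oi] = best_len[oj] + 1
                    prev[oi] = oj
    end = max(range(len(order)), key=lambda oi: best_len[oi], default=-1)
    if end < 0:
        return []
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def chain_blocks(
    anchors: list[AnchorPair], min_block_size: int = 5, max_rank_gap: int = 25
) -> list[SyntenyBlock]:
    """Chain anchors into maximal collinear blocks (each anchor in <= 1 block)."""
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(by_pair):
        remaining = by_pair[(ca, cb)]
        while remaining:
            inc = _longest_chain(remaining, max_rank_gap, decreasing=False)
            dec = _longest_chain(remaining, max_rank_gap, decreasing=True)
            chain, orient = (inc, "same") if len(inc) >= len(dec) else (dec, "inverted")
            if len(chain) < min_block_size:
                break
            chosen = [remaining[i] for i in chain]
            block = SyntenyBlock(ca, cb, sorted(chosen, key=lambda a: a.rank_a), orient)
            block.check_monotone()
            blocks.append(block)
            keep = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in keep]
    return blocks


def pair_chromosomes(blocks: list[SyntenyBlock]) -> list[tuple[str, str]]:
    """Greedy maximum-weight matching on summed block scores; name-order tie-break."""
    weights: dict[tuple[str, str], int] = {}
    for b in blocks:
        weights[(b.chrom_a, b.chrom_b)] = weights.get((b.chrom_a, b.chrom_b), 0) + b.score
    pairs: list[tuple[str, str]] = []
    used: set[str] = set()
    for (ca, cb), _w in sorted(weights.items(), key=lambda kv: (-kv[1], kv[0])):
        if ca in used or cb in used:
            continue
        pairs.append((ca, cb))
        used.update((ca, cb))
    return sorted(pairs)


def assign_groups(
    pairs: list[tuple[str, str]], repeats: list[RepeatFeature]
) -> dict[str, str]:
    """Within each pair, the member with more repeat-covered bp is H2.

    Equal repeat coverage falls back to name order (smaller name is H1);
    the convention is fixed but arbitrary, so downstream statistics must be
    label-swap invariant.
    """
    bp: dict[str, int] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chromosome, []).append(r.interval)
    for chrom, ivs in by_chrom.items():
        bp[chrom] = total_length(ivs)
    labels: dict[str, str] = {}
    for ca, cb in pairs:
        wa, wb = bp.get(ca, 0), bp.get(cb, 0)
        if wa > wb or (wa == wb and ca > cb):
            labels[ca], labels[cb] = "H2", "H1"
        else:
            labels[ca], labels[cb] = "H1", "H2"
    return labels


def link_positional_homoeologs(
    blocks: list[SyntenyBlock],
    bundle: GenomeBundle,
    pairs: list[tuple[str, str]] | None = None,
    repeats: list[RepeatFeature] | None = None,
) -> HomoeologMap:
    """Resolve per-gene links: anchored partner, "lost", or unplaced.

    "Lost" requires flanking anchors on both sides inside a block: a gene
    strictly between two consecutive anchors whose family has no member in
    the corresponding partner-side rank window is called lost.
    """
    if pairs is None:
        pairs = pair_chromosomes(blocks)
    paired = set(pairs)
    labels = assign_groups(pairs, repeats if repeats is not None else bundle.repeats)
    ranks = gene_ranks(bundle)
    rank_to_gene: dict[tuple[str, int], str] = {v: k for k, v in ranks.items()}
    fam_of: dict[str, str] = {}
    for fam, members in bundle.families.items():
        for m in members:
            fam_of[m] = fam

    links: dict[str, str] = {}
    in_pair_blocks = [b for b in blocks if (b.chrom_a, b.chrom_b) in paired]
    # anchors of bigger blocks win conflicts
    for b in sorted(in_pair_blocks, key=lambda b: -b.score):
        for a in b.anchors:
            if a.gene_a not in links and a.gene_b not in links:
                links[a.gene_a] = a.gene_b
                links[a.gene_b] = a.gene_a

    for b in in_pair_blocks:
        for side, chrom, other in (("a", b.chrom_a, b.chrom_b), ("b", b.chrom_b, b.chrom_a)):
            anchor_ranks = [
                (a.rank_a, a.rank_b) if side == "a" else (a.rank_b, a.rank_a) for a in b.anchors
            ]
            anchor_ranks.sort()
            for (r1, p1), (r2, p2) in zip(anchor_ranks, anchor_ranks[1:]):
                plo, phi = min(p1, p2), max(p1, p2)
                for r in range(r1 + 1, r2):
                    gid = rank_to_gene.get((chrom, r))
                    if gid is None or gid in links:
                        continue
                    fam = fam_of.get(gid)
                    present = any(
                        ranks.get(m, (None, -1))[0] == other
                        and plo <= ranks[m][1] <= phi
                        for m in bundle.families.get(fam, ())
                    )
                    if not present:
                        links[gid] = "lost"

    all_genes = {g.gene_id for g in bundle.predominant_genes()}
    unplaced = all_genes - set(links)
    return HomoeologMap(pairs, labels, links, unplaced)


def homoeolog_map(
    bundle: GenomeBundle, min_block_size: int = 5, max_rank_gap: int = 25
) -> HomoeologMap:
    """End-to-end: anchors -> blocks -> chromosome pairs -> H1/H2 -> gene links."""
    anchors = build_anchors(bundle)
    blocks = chain_blocks(anchors, min_block_size=min_block_size, max_rank_gap=max_rank_gap)
    return link_positional_homoeologs(blocks, bundle)
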