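"""Pseudogene detection, disablement calling, DUP/FRAG/PSSD classification,
and fractionation relative to the partner homoeolog.

High-confidence parent genes (identity > 40% and query/subject coverage
> 50% against a curated protein set) are aligned against two kinds of
candidate loci: annotated genes (their positional homoeologs and family
mates) and unannotated, gene-free windows located by exact-seed matching.
Disablement evidence — premature stop codons, frame-shifting indels, a 3'
polyA tail — plus coverage/identity of the affine-gap local alignment
drive the three-way classification:

    PSSD  processed (retrotransposed): intron loss and/or polyA tail
    FRAG  fragmented remnant: low coverage (< 0.5) but high identity
    DUP   duplicated pseudogene retaining gene structure, disabled in place

No call is made without at least one evidence item.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from diploscan.genome_io import GeneModel, GenomeBundle
from diploscan.homoeology import HomoeologMap

_STOPS = {"TAA", "TAG", "TGA"}

#: affine-gap local alignment scoring (match, mismatch, gap open, gap extend)
DEFAULT_SCORING = (2, -3, -5, -2)

#: indels at least this long are treated as structural (introns), not frameshifts
MIN_INTRON = 40

#: polyA rule: >= 24 A within a 30-bp window, within 50 bp of the alignment end
POLYA_SEARCH_BP = 50
POLYA_WINDOW = 30
POLYA_MIN_A = 24

FRAG_COVERAGE = 0.5
FRAG_MIN_IDENTITY = 40.0


@dataclass
class ParentGene:
    gene_id: str
    protein: str
    cds: str
    eligible: bool
    n_cds_segments: int
    chromosome: str
    identity_pct: float = 0.0
    query_coverage: float = 0.0
    subject_coverage: float = 0.0


@dataclass
class Alignment:
    """Local alignment of a parent CDS (query) against a locus (subject)."""

    score: float
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]  # ((ps,pe),(ls,le))
    parent_len: int
    locus_len: int
    coverage: float  # aligned parent bp / parent CDS length
    identity_pct: float  # matches / aligned parent bp
    indels: list[int]  # junction gap lengths (parent- and locus-side)

    @property
    def parent_span(self) -> tuple[int, int]:
        if not self.blocks:
            return (0, 0)
        return (self.blocks[0][0][0], self.blocks[-1][0][1])

    @property
    def locus_span(self) -> tuple[int, int]:
        if not self.blocks:
            return (0, 0)
        return (self.blocks[0][1][0], self.blocks[-1][1][1])


@dataclass
class PseudogeneCall:
    chromosome: str
    start: int
    end: int
    parent_id: str
    coverage: float
    identity_pct: float
    n_premature_stops: int
    n_frameshifts: int
    has_polyA: bool
    pg_class: str  # DUP / FRAG / PSSD
    overlaps_gene_model: bool
    gene_id: str = ""

    @property
    def n_disablements(self) -> int:
        return self.n_premature_stops + self.n_frameshifts + int(self.has_polyA)

    def has_evidence(self) -> bool:
        return self.n_disablements > 0 or self.coverage < 1.0


@dataclass
class FractionationResult:
    gene_id: str
    homoeolog_id: str  # partner gene id, "lost", or "unplaced"
    fractionation_pct: float | None  # None when not computable


def _make_aligner(scoring: tuple[float, float, float, float] = DEFAULT_SCORING) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def translate_cds(cds: str) -> str:
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=False)).rstrip("*")


def select_parents(
    bundle: GenomeBundle, curated_proteins: dict[str, str]
) -> list[ParentGene]:
    """Eligibility per the high-confidence rule: identity > 40% AND query
    coverage > 50% AND subject coverage > 50% (strict inequalities) against
    the best-matching curated protein.

    When a gene's family_id keys into ``curated_proteins`` only that entry is
    compared (the usual case: one curated protein per family); otherwise the
    whole set is searched.
    """
    if not curated_proteins:
        raise ValueError("curated protein set is empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    try:
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    except Exception:  # pragma: no cover
        aligner.match_score, aligner.mismatch_score = 2, -1
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    fam_of = {}
    for fam, members in bundle.families.items():
        for m in members:
            fam_of[m] = fam

    out: list[ParentGene] = []
    for gene in bundle.predominant_genes():
        cds = gene.spliced_cds(bundle.sequences)
        prot = translate_cds(cds)
        fam = gene.family_id or fam_of.get(gene.gene_id)
        candidates = (
            {fam: curated_proteins[fam]} if fam in curated_proteins else curated_proteins
        )
        best = (0.0, 0.0, 0.0)
        for ref in candidates.values():
            if not prot or not ref:
                continue
            aln = aligner.align(prot.replace("*", "X"), ref.replace("*", "X"))[0]
            qa = sum(e - s for s, e in aln.aligned[0])
            matches = sum(
                1
                for (qs, qe), (ss, se) in zip(*aln.aligned)
                for i in range(qe - qs)
                if prot[qs + i : qs + i + 1] == ref[ss + i : ss + i + 1]
            )
            ident = 100.0 * matches / qa if qa else 0.0
            qcov = 100.0 * qa / len(prot)
            scov = 100.0 * qa / len(ref)
            if (ident, qcov, scov) > best:
                best = (ident, qcov, scov)
        ident, qcov, scov = best
        out.append(
            ParentGene(
                gene_id=gene.gene_id,
                protein=prot,
                cds=cds,
                eligible=ident > 40.0 and qcov > 50.0 and scov > 50.0,
                n_cds_segments=len(gene.cds),
                chromosome=gene.chromosome,
                identity_pct=ident,
                query_coverage=qcov,
                subject_coverage=scov,
            )
        )
    return out


def align_parent_to_locus(
    parent_cds: str,
    locus_sequence: str,
    scoring: tuple[float, float, float, float] = DEFAULT_SCORING,
    max_locus_length: int = 200_000,
) -> Alignment:
    """Affine-gap local alignment of a parent CDS against a candidate locus."""
    if not parent_cds or not locus_sequence:
        raise ValueError("empty sequence")
    if len(locus_sequence) > max_locus_length:
        raise ValueError(f"locus exceeds max length {max_locus_length}")
    aligner = _make_aligner(scoring)
    aln = aligner.align(parent_cds.upper(), locus_sequence.upper())[0]
    pb, lb = aln.aligned
    blocks = [((int(p[0]), int(p[1])), (int(l[0]), int(l[1]))) for p, l in zip(pb, lb)]
    aligned_bp = sum(pe - ps for (ps, pe), _ in blocks)
    matches = 0
    pu, lu = parent_cds.upper(), locus_sequence.upper()
    for (ps, pe), (ls, le) in blocks:
        matches += sum(pu[ps + i] == lu[ls + i] for i in range(pe - ps))
    indels = []
    for ((_, pe), (_, le)), ((ps2, _), (ls2, _)) in zip(blocks, blocks[1:]):
        if ps2 - pe > 0:
            indels.append(ps2 - pe)
        if ls2 - le > 0:
            indels.append(ls2 - le)
    return Alignment(
        score=float(aln.score),
        blocks=blocks,
        parent_len=len(parent_cds),
        locus_len=len(locus_sequence),
        coverage=aligned_bp / len(parent_cds),
        identity_pct=100.0 * matches / aligned_bp if aligned_bp else 0.0,
        indels=indels,
    )


def call_disablements(
    alignment: Alignment, parent_cds: str, locus_sequence: str
) -> tuple[int, int, bool]:
    """(premature stops, frameshifts, polyA) from an alignment.

    A premature stop is an in-frame locus stop codon at a parent codon
    strictly before the parent's own stop; a frameshift is a junction indel
    whose length is not a multiple of 3 and shorter than an intron
    (structural gaps >= MIN_INTRON are never frameshifts); polyA is
    >= POLYA_MIN_A adenines in a POLYA_WINDOW-bp window within
    POLYA_SEARCH_BP of the alignment end.
    """
    lu = locus_sequence.upper()
    last_codon = len(parent_cds) // 3 - 1  # parent stop codon index
    stops = 0
    for (ps, pe), (ls, le) in alignment.blocks:
        first = -(-ps // 3)  # first codon fully inside block
        last = pe // 3  # one past last full codon
        for k in range(first, last):
            if k >= last_codon:
                break
            codon = lu[ls + (3 * k - ps) : ls + (3 * k - ps) + 3]
            if codon in _STOPS:
                stops += 1
    frameshifts = sum(1 for d in alignment.indels if d % 3 != 0 and d < MIN_INTRON)
    tail_start = alignment.locus_span[1]
    tail = lu[tail_start : tail_start + POLYA_SEARCH_BP]
    has_polya = False
    if len(tail) >= POLYA_MIN_A:
        for i in range(max(1, len(tail) - POLYA_WINDOW + 1)):
            if tail[i : i + POLYA_WINDOW].count("A") >= POLYA_MIN_A:
                has_polya = True
                break
    return stops, frameshifts, has_polya


def intron_loss(alignment: Alignment, parent_segment_lengths: list[int]) -> bool:
    """True when the alignment spans at least one parent CDS-segment junction
    with no intron-sized locus gap at any spanned junction (processed copy).

    Requires at least half the parent CDS aligned: a fragment that barely
    crosses one junction cannot support an intron-loss claim.
    """
    if len(parent_segment_lengths) < 2 or alignment.coverage < 0.5:
        return False
    boundaries = []
    acc = 0
    for L in parent_segment_lengths[:-1]:
        acc += L
        boundaries.append(acc)
    ps0, pe0 = alignment.parent_span
    spanned = 0
    for b in boundaries:
        if not (ps0 + 3 <= b <= pe0 - 3):
            continue
        spanned += 1
        # locus gap at parent position b
        gap = None
        for (ps, pe), (ls, le) in alignment.blocks:
            if ps < b < pe:
                gap = 0
                break
        if gap is None:
            for ((_, pe), (_, le)), ((ps2, _), (ls2, _)) in zip(
                alignment.blocks, alignment.blocks[1:]
            ):
                if pe <= b <= ps2:
                    gap = ls2 - le
                    break
        if gap is None or gap >= MIN_INTRON:
            return False
    return spanned > 0


def classify(
    coverage: float,
    identity_pct: float,
    has_polyA: bool,
    parent_n_cds_segments: int,
    locus_intron_loss: bool,
    frag_coverage: float = FRAG_COVERAGE,
    frag_min_identity: float = FRAG_MIN_IDENTITY,
) -> str:
    """Deterministic DUP/FRAG/PSSD classification."""
    if has_polyA or (parent_n_cds_segments >= 2 and locus_intron_loss):
        return "PSSD"
    if coverage < frag_coverage and identity_pct >= frag_min_identity:
        return "FRAG"
    return "DUP"


# ---------------------------------------------------------------------------
# Candidate discovery in gene-free windows via exact k-mer seeds

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[b + 32] = i  # lower case


class _SeedIndex:
    """Sorted k-mer index over the gene-free regions of a genome."""

    def __init__(self, bundle: GenomeBundle, k: int = 16):
        self.k = k
        codes_all: list[np.ndarray] = []
        pos_all: list[np.ndarray] = []
        chrom_all: list[np.ndarray] = []
        self.chrom_names: list[str] = []
        spans: dict[str, list[tuple[int, int]]] = {c: [] for c in bundle.sequences}
        for g in bundle.genes:
            spans[g.chromosome].append(g.span)
        for ci, chrom in enumerate(sorted(bundle.sequences)):
            self.chrom_names.append(chrom)
            seq = bundle.sequences[chrom]
            free = self._complement(spans[chrom], len(seq))
            for s, e in free:
                if e - s < k:
                    continue
                codes, ok = self._encode(seq[s:e])
                if codes is None:
                    continue
                idx = np.flatnonzero(ok)
                if len(idx) == 0:
                    continue
                codes_all.append(codes[idx])
                pos_all.append(idx.astype(np.int64) + s)
                chrom_all.append(np.full(len(idx), ci, dtype=np.int32))
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.pos = np.concatenate(pos_all)[order]
            self.chrom = np.concatenate(chrom_all)[order]
        else:
            self.codes = np.empty(0, dtype=np.uint64)
            self.pos = np.empty(0, dtype=np.int64)
            self.chrom = np.empty(0, dtype=np.int32)

    @staticmethod
    def _complement(spans: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
        from diploscan.intervals import merge

        out = []
        cur = 0
        for s, e in merge(spans):
            if s > cur:
                out.append((cur, s))
            cur = max(cur, e)
        if cur < length:
            out.append((cur, length))
        return out

    def _encode(self, seq: str) -> tuple[np.ndarray | None, np.ndarray | None]:
        vals = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
        n = len(vals) - self.k + 1
        if n <= 0:
            return None, None
        codes = np.zeros(n, dtype=np.uint64)
        valid = np.ones(n, dtype=bool)
        for j in range(self.k):
            v = vals[j : j + n]
            codes = (codes << np.uint64(2)) | v.astype(np.uint64)
            valid &= v != 255
        return codes, valid

    def encode_kmer(self, kmer: str) -> int | None:
        vals = _ENC[np.frombuffer(kmer.encode(), dtype=np.uint8)]
        if (vals == 255).any():
            return None
        code = 0
        for v in vals:
            code = (code << 2) | int(v)
        return code

    def lookup(self, kmer: str, cap: int = 100) -> list[tuple[str, int]]:
        code = self.encode_kmer(kmer)
        if code is None or len(self.codes) == 0:
            return []
        lo = np.searchsorted(self.codes, np.uint64(code), side="left")
        hi = np.searchsorted(self.codes, np.uint64(code), side="right")
        hits = [
            (self.chrom_names[self.chrom[i]], int(self.pos[i]))
            for i in range(lo, min(hi, lo + cap))
        ]
        return hits


def _candidate_windows(
    index: _SeedIndex, parent: ParentGene, stride: int = 10
) -> list[tuple[str, int, int]]:
    """Cluster seed hits of a parent CDS into candidate loci."""
    hits: list[tuple[str, int]] = []
    for off in range(0, max(1, len(parent.cds) - index.k + 1), stride):
        for chrom, pos in index.lookup(parent.cds[off : off + index.k]):
            hits.append((chrom, pos))
    if not hits:
        return []
    span_guess = 2 * len(parent.cds) + 2000
    windows: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in hits:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, poss in sorted(by_chrom.items()):
        poss.sort()
        start = prev = poss[0]
        for p in poss[1:]:
            if p - prev > span_guess:
                windows.append((chrom, max(0, start - 100), prev + index.k + 160))
                start = p
            prev = p
        windows.append((chrom, max(0, start - 100), prev + index.k + 160))
    return windows


def scan_pseudogenes(
    bundle: GenomeBundle,
    hmap: HomoeologMap,
    parents: list[ParentGene],
    scoring: tuple[float, float, float, float] = DEFAULT_SCORING,
    min_identity: float = 40.0,
    min_coverage: float = 0.05,
    annotated_truncation_coverage: float = FRAG_COVERAGE,
    unannotated_truncation_coverage: float = 0.95,
) -> list[PseudogeneCall]:
    """Detect pseudogenic loci from the eligible parents.

    Candidates are (a) annotated genes aligned against their positional
    homoeolog (or, failing that, the best eligible family mate) and (b)
    gene-free windows found by exact-seed matches to a parent CDS.  A call
    requires at least one evidence item: stop/frameshift/polyA, or parent
    coverage below the truncation threshold for its candidate kind.
    """
    parent_by_id = {p.gene_id: p for p in parents}
    eligible = {p.gene_id: p for p in parents if p.eligible}
    fam_of: dict[str, str] = {}
    for fam, members in bundle.families.items():
        for m in members:
            fam_of[m] = fam
    eligible_by_family: dict[str, list[ParentGene]] = {}
    for pid, p in eligible.items():
        fam = fam_of.get(pid)
        if fam:
            eligible_by_family.setdefault(fam, []).append(p)

    calls: list[PseudogeneCall] = []
    genes_by_id = {g.gene_id: g for g in bundle.genes}

    # (a) annotated candidates
    for gene in bundle.predominant_genes():
        partner_id = hmap.gene_links.get(gene.gene_id)
        parent: ParentGene | None = None
        if partner_id and partner_id != "lost" and partner_id in eligible:
            parent = eligible[partner_id]
        else:
            fam = fam_of.get(gene.gene_id)
            mates = [p for p in eligible_by_family.get(fam, []) if p.gene_id != gene.gene_id]
            if mates:
                parent = max(mates, key=lambda p: (p.identity_pct, p.gene_id))
        if parent is None:
            continue
        # align the worse copy against the better one only: a disablement in
        # the parent would otherwise flag the intact candidate too
        cand = parent_by_id.get(gene.gene_id)
        if (
            cand is not None
            and cand.eligible
            and (cand.identity_pct, gene.gene_id) > (parent.identity_pct, parent.gene_id)
        ):
            continue
        spliced = gene.spliced_cds(bundle.sequences)
        if not spliced:
            continue
        aln = align_parent_to_locus(parent.cds, spliced, scoring)
        if aln.identity_pct < min_identity or aln.coverage < min_coverage:
            continue
        stops, fs, polya = call_disablements(aln, parent.cds, spliced)
        # a gene model's own genomic context may carry the polyA signature
        if not polya and len(gene.exons) == 1:
            s, e = gene.span
            tail = bundle.sequences[gene.chromosome][e : e + POLYA_SEARCH_BP].upper()
            for i in range(max(1, len(tail) - POLYA_WINDOW + 1)):
                if tail[i : i + POLYA_WINDOW].count("A") >= POLYA_MIN_A:
                    polya = True
                    break
        evidence = stops + fs > 0 or polya or aln.coverage < annotated_truncation_coverage
        if not evidence:
            continue
        cls = classify(
            aln.coverage, aln.identity_pct, polya, parent.n_cds_segments,
            locus_intron_loss=len(gene.exons) == 1,
        )
        s, e = gene.span
        calls.append(
            PseudogeneCall(
                chromosome=gene.chromosome, start=s, end=e, parent_id=parent.gene_id,
                coverage=aln.coverage, identity_pct=aln.identity_pct,
                n_premature_stops=stops, n_frameshifts=fs, has_polyA=polya,
                pg_class=cls, overlaps_gene_model=True, gene_id=gene.gene_id,
            )
        )

    # (b) unannotated gene-free windows
    index = _SeedIndex(bundle)
    window_calls: list[PseudogeneCall] = []
    for pid in sorted(eligible):
        parent = eligible[pid]
        for chrom, ws, we in _candidate_windows(index, parent):
            locus = bundle.sequences[chrom][ws:we]
            if len(locus) < index.k:
                continue
            aln = align_parent_to_locus(parent.cds, locus, scoring)
            if aln.identity_pct < min_identity or aln.coverage < min_coverage:
                continue
            stops, fs, polya = call_disablements(aln, parent.cds, locus)
            evidence = stops + fs > 0 or polya or aln.coverage < unannotated_truncation_coverage
            if not evidence:
                continue
            seg_lens = [min(len(parent.cds), 10**9)]  # fallback single segment
            gm = genes_by_id.get(parent.gene_id)
            if gm is not None:
                seg_lens = [e - s for s, e in gm.cds]
            cls = classify(
                aln.coverage, aln.identity_pct, polya, parent.n_cds_segments,
                locus_intron_loss=intron_loss(aln, seg_lens),
            )
            ls, le = aln.locus_span
            window_calls.append(
                PseudogeneCall(
                    chromosome=chrom, start=ws + ls, end=ws + le, parent_id=parent.gene_id,
                    coverage=aln.coverage, identity_pct=aln.identity_pct,
                    n_premature_stops=stops, n_frameshifts=fs, has_polyA=polya,
                    pg_class=cls, overlaps_gene_model=False,
                )
            )

    # dedupe overlapping window calls (several family parents hit one locus)
    window_calls.sort(key=lambda c: (c.chromosome, c.start, -c.coverage * c.identity_pct))
    kept: list[PseudogeneCall] = []
    for c in window_calls:
        if kept and kept[-1].chromosome == c.chromosome and c.start < kept[-1].end:
            if c.coverage * c.identity_pct > kept[-1].coverage * kept[-1].identity_pct:
                kept[-1] = c
            continue
        kept.append(c)
    calls.extend(kept)
    for c in calls:
        assert c.has_evidence(), f"call without evidence at {c.chromosome}:{c.start}"
    return calls


def compute_fractionation(
    gene: GeneModel,
    hmap: HomoeologMap,
    bundle: GenomeBundle,
    calls: list[PseudogeneCall] | None = None,
    scoring: tuple[float, float, float, float] = DEFAULT_SCORING,
) -> FractionationResult:
    """Percent of the gene's CDS NOT covered by its homoeologous locus.

    0 for an intact partner gene, 100 for a fully absent homoeolog; when the
    partner is "lost" but a pseudogenic region from this gene survives, its
    alignment coverage counts.  Unplaced genes are not computable.
    """
    link = hmap.gene_links.get(gene.gene_id)
    if link is None:
        return FractionationResult(gene.gene_id, "unplaced", None)
    own = gene.spliced_cds(bundle.sequences)
    if link == "lost":
        best = None
        for c in calls or []:
            if c.parent_id == gene.gene_id and not c.overlaps_gene_model:
                if best is None or c.coverage > best.coverage:
                    best = c
        if best is not None:
            return FractionationResult(gene.gene_id, "lost", 100.0 * (1.0 - best.coverage))
        return FractionationResult(gene.gene_id, "lost", 100.0)
    partner = next((g for g in bundle.genes if g.gene_id == link), None)
    if partner is None:
        return FractionationResult(gene.gene_id, link, None)
    other = partner.spliced_cds(bundle.sequences)
    if not own or not other:
        return FractionationResult(gene.gene_id, link, None)
    aln = align_parent_to_locus(own, other, scoring)
    return FractionationResult(gene.gene_id, link, 100.0 * (1.0 - aln.coverage))


def screen_haplotype_confusion(
    calls: list[PseudogeneCall],
    support: dict[tuple[str, int, int], dict] | None,
    max_deletion_bp: int = 1000,
) -> tuple[list[PseudogeneCall], int]:
    """Drop calls without secondary-assembly support or with large deletions.

    ``support`` maps (chromosome, start, end) to {"supported": bool,
    "max_deletion": int}.  Without secondary data the filter is a no-op
    (with a warning) — haplotype confusion then cannot be excluded.
    """
    if support is None:
        warnings.warn("no secondary-assembly alignments supplied; haplotype screen skipped")
        return list(calls), 0
    kept = []
    dropped = 0
    for c in calls:
        rec = support.get((c.chromosome, c.start, c.end), {"supported": False})
        if rec.get("supported") and rec.get("max_deletion", 0) <= max_deletion_bp:
            kept.append(c)
        else:
            dropped += 1
    return kept, dropped
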