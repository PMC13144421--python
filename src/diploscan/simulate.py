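"""Whole-genome-duplication genome simulator with per-gene ground truth.

Emulates a diploidized tetraploid: an ancestral gene complement is duplicated
into two homoeologous chromosome sets (A/B) that diverge by point
substitutions, then degraded by the processes the analysis modules are meant
to recover — fractionation (gene deletion, optionally leaving a decaying
truncated residual), pseudogenization by premature stops or frameshifts,
processed retrocopies with polyA tails, tandem duplications, segmental
inversions, and transposable-element insertions into introns and intergenic
space whose annotated divergences are drawn from one or two amplification
waves.  A diploid outgroup (two haplotypes carrying every ancestral gene)
can be emitted for retention analysis.

Each stochastic process draws from its own seeded stream so that, e.g.,
switching TE simulation on does not perturb gene fates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from diploscan.genome_io import (
    GeneModel,
    GenomeBundle,
    RepeatFeature,
    write_family_table,
    write_fasta,
    write_gff3,
    write_repeatmasker_out,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
# purine<->purine / pyrimidine<->pyrimidine partner for transitions
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

TE_CLASSES = ["LTR/Gypsy", "LTR/Copia", "LINE/L1", "DNA/hAT", "Unknown"]
TE_CLASS_WEIGHTS = [0.40, 0.20, 0.20, 0.10, 0.10]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the simulated diploidization scenario.

    Probabilities are per gene copy; ``fractionation_prob`` applies to the
    B-set copy of each gene and ``fractionation_bias`` is the A:B deletion
    odds ratio (0 = deletion confined to one homoeologous set, 1 = unbiased).
    ``te_wave_ages`` are (mean Kimura %, sd, weight) amplification waves whose
    weights must sum to 1.
    """

    seed: int = 0
    n_chromosome_pairs: int = 2
    genes_per_chromosome: int = 100
    exon_count_mean: float = 4.0
    exon_length_mean: int = 150
    intron_length_mean: int = 200
    intergenic_length_mean: int = 300
    wgd_divergence: float = 0.03
    fractionation_prob: float = 0.0
    fractionation_bias: float = 0.0
    pseudogenization_prob: float = 0.0
    retrocopy_prob: float = 0.0
    tandem_dup_prob: float = 0.0
    residual_prob: float = 0.0
    residual_retained_range: tuple[float, float] = (0.10, 0.45)
    te_insertions_per_intron: float = 0.0
    te_length_mean: float = 400.0
    te_wave_ages: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(3.0, 1.5, 0.7), (25.0, 4.0, 0.3)]
    )
    te_bias_b: float = 1.0
    inversion_rate: float = 0.0
    inversion_genes_range: tuple[int, int] = (5, 30)
    retro_divergence: float = 0.01
    outgroup: bool = True

    def validate(self) -> None:
        for name in (
            "wgd_divergence",
            "fractionation_prob",
            "pseudogenization_prob",
            "retrocopy_prob",
            "tandem_dup_prob",
            "residual_prob",
            "inversion_rate",
            "retro_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.te_insertions_per_intron < 0:
            raise ConfigurationError("te_insertions_per_intron must be >= 0")
        if self.te_wave_ages:
            w = sum(wt for _, _, wt in self.te_wave_ages)
            if abs(w - 1.0) > 1e-9:
                raise ConfigurationError(f"TE wave weights must sum to 1, got {w}")
        if self.n_chromosome_pairs < 1 or self.genes_per_chromosome < 1:
            raise ConfigurationError("need at least one chromosome pair and one gene")
        if self.exon_length_mean < 30 or self.intron_length_mean < 40:
            raise ConfigurationError("exon/intron length means too small for gene geometry")


@dataclass
class TruthRecord:
    """Ground-truth fate of one emitted (or deleted) gene copy."""

    ancestral_gene_id: str
    copy: str  # A / B / retro / tandem
    fate: str  # retained / deleted / pseudogenized / retrocopy / tandem_duplicate
    gene_id: str  # annotated id, "" for unannotated loci
    chromosome: str
    start: int
    end: int
    n_premature_stops: int
    n_frameshifts: int
    has_polyA: bool
    fraction_removed: float  # CDS fraction removed (residuals/deletions)
    n_te_insertions: int
    partner_gene_id: str


@dataclass
class _TEPlan:
    length: int
    divergence: float
    class_label: str
    wave: int


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions at ``rate`` per site with a 2:1 transition:transversion ratio."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit) == 0:
        return seq
    kinds = rng.random(len(hit))
    out = arr.copy()
    for pos, k in zip(hit, kinds):
        base = arr[pos].decode()
        if base not in "ACGT":
            continue
        if k < 2 / 3:
            out[pos] = _TRANSITION[base].encode()
        else:
            tv = _TRANSVERSIONS[base]
            out[pos] = tv[int((k - 2 / 3) * 6) % 2].encode()
    return out.tobytes().decode()


def mutate_cds_segments(
    segs: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    """Substitutions over codon-aligned CDS segments under purifying
    selection: a substitution that would create an internal stop codon is
    reverted, so functional copies stay translatable."""
    out = []
    for k, s in enumerate(segs):
        m = list(mutate(s, rate, rng))
        for i in range(0, len(m) - 2, 3):
            last = k == len(segs) - 1 and i == len(m) - 3
            if not last and "".join(m[i : i + 3]) in _STOPS:
                m[i : i + 3] = s[i : i + 3]
        out.append("".join(m))
    return out


def inject_disablement(
    cds_sequence: str, kind: str, rng: np.random.Generator
) -> tuple[str, dict]:
    """Disable a CDS the way pseudogenes are born.

    ``premature_stop`` converts one internal codon to a stop; ``frameshift``
    inserts or deletes 1-2 bp; ``polyA_retrocopy`` appends a 25-bp polyA tail
    to the (already spliced) CDS.  Returns the mutated sequence and a truth
    annotation {kind, position, delta}.
    """
    n = len(cds_sequence)
    if n < 9 or n % 3 != 0:
        raise ValueError(f"CDS length must be >= 9 and a multiple of 3, got {n}")
    if kind == "premature_stop":
        codon_idx = int(rng.integers(1, n // 3 - 1))  # internal, keep ATG and stop
        stop = _STOPS[int(rng.integers(0, 3))]
        seq = cds_sequence[: 3 * codon_idx] + stop + cds_sequence[3 * codon_idx + 3 :]
        return seq, {"kind": kind, "position": 3 * codon_idx, "delta": 0}
    if kind == "frameshift":
        delta = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
        pos = int(rng.integers(3, n - 3 - abs(delta)))
        if delta > 0:
            ins = _random_seq(rng, delta)
            seq = cds_sequence[:pos] + ins + cds_sequence[pos:]
        else:
            seq = cds_sequence[:pos] + cds_sequence[pos - delta :]
        return seq, {"kind": kind, "position": pos, "delta": delta}
    if kind == "polyA_retrocopy":
        return cds_sequence + "A" * 25, {"kind": kind, "position": n, "delta": 25}
    raise ValueError(f"unknown disablement kind {kind!r}")


def _draw_te(config: SimulationConfig, rng: np.random.Generator) -> _TEPlan:
    waves = config.te_wave_ages
    wi = int(rng.choice(len(waves), p=[w for _, _, w in waves]))
    mean, sd, _ = waves[wi]
    div = max(0.0, float(rng.normal(mean, sd)))
    length = 50 + int(rng.exponential(config.te_length_mean))
    cls = str(rng.choice(TE_CLASSES, p=TE_CLASS_WEIGHTS))
    return _TEPlan(length=length, divergence=round(div, 1), class_label=cls, wave=wi)


def sample_te_landscape(
    config: SimulationConfig,
    rng: np.random.Generator,
    introns: list[tuple[str, int, int]],
) -> list[RepeatFeature]:
    """Place wave-dated TEs inside existing intron/intergenic intervals.

    Per-interval insertion counts are Poisson(lambda); copies are laid end to
    end from the interval start and truncated at the interval boundary, so
    they never overlap exons.
    """
    lam = config.te_insertions_per_intron
    feats: list[RepeatFeature] = []
    for chrom, s, e in introns:
        n = int(rng.poisson(lam)) if lam > 0 else 0
        pos = s
        for _ in range(n):
            te = _draw_te(config, rng)
            end = min(pos + te.length, e)
            if end <= pos:
                break
            feats.append(
                RepeatFeature(chrom, pos, end, te.class_label, te.divergence, name=f"TE_w{te.wave}")
            )
            pos = end
    return feats


# ---------------------------------------------------------------------------


@dataclass
class _AncGene:
    gene_id: str
    cds_segs: list[str]  # per-exon coding chunks (all-coding exons)
    introns: list[str]

    @property
    def cds(self) -> str:
        return "".join(self.cds_segs)


def _make_ancestral_gene(gid: str, config: SimulationConfig, rng: np.random.Generator) -> _AncGene:
    n_ex = 1 + int(rng.poisson(max(config.exon_count_mean - 1, 0)))
    seg_codons = [max(10, int(rng.poisson(config.exon_length_mean / 3))) for _ in range(n_ex)]
    total = sum(seg_codons)
    internal = rng.integers(0, len(_CODONS), total - 2)
    cds = "ATG" + "".join(_CODONS[i] for i in internal) + "TAA"
    segs = []
    off = 0
    for sc in seg_codons:
        segs.append(cds[off : off + 3 * sc])
        off += 3 * sc
    introns = [
        _random_seq(rng, 40 + int(rng.exponential(max(config.intron_length_mean - 40, 1))))
        for _ in range(n_ex - 1)
    ]
    return _AncGene(gid, segs, introns)


def _build_gene_piece(
    cds_segs: list[str],
    introns: list[str],
    te_per_intron: list[list[tuple[int, str, _TEPlan]]],
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int, _TEPlan]]]:
    """Assemble exon/intron pieces with TEs expanded into introns.

    Returns (sequence, exon intervals, repeat intervals) in piece-local
    coordinates.
    """
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    reps: list[tuple[int, int, _TEPlan]] = []
    pos = 0
    for k, seg in enumerate(cds_segs):
        exons.append((pos, pos + len(seg)))
        parts.append(seg)
        pos += len(seg)
        if k < len(introns):
            intron = introns[k]
            cur = 0
            for off, te_seq, te in sorted(te_per_intron[k], key=lambda t: t[0]):
                parts.append(intron[cur:off])
                pos += off - cur
                reps.append((pos, pos + len(te_seq), te))
                parts.append(te_seq)
                pos += len(te_seq)
                cur = off
            parts.append(intron[cur:])
            pos += len(intron) - cur
    return "".join(parts), exons, reps


@dataclass
class _Slot:
    """One unit to lay on a chromosome: spacer then optional locus."""

    kind: str  # gene / residual / retro / empty
    spacer: str
    spacer_tes: list[tuple[int, str, _TEPlan]]
    gene_id: str = ""
    family_id: str = ""
    cds_segs: list[str] = field(default_factory=list)
    introns: list[str] = field(default_factory=list)
    te_per_intron: list[list[tuple[int, str, _TEPlan]]] = field(default_factory=list)
    residual_seq: str = ""
    retro_seq: str = ""
    truth: TruthRecord | None = None
    is_allele: bool = False


def _assemble_chromosome(
    name: str, slots: list[_Slot]
) -> tuple[str, list[GeneModel], list[RepeatFeature], list[TruthRecord]]:
    parts: list[str] = []
    pos = 0
    genes: list[GeneModel] = []
    repeats: list[RepeatFeature] = []
    truth: list[TruthRecord] = []

    def _emit_spacer(slot: _Slot) -> None:
        nonlocal pos
        cur = 0
        for off, te_seq, te in sorted(slot.spacer_tes, key=lambda t: t[0]):
            parts.append(slot.spacer[cur:off])
            pos += off - cur
            repeats.append(
                RepeatFeature(name, pos, pos + len(te_seq), te.class_label, te.divergence,
                              name=f"TE_w{te.wave}")
            )
            parts.append(te_seq)
            pos += len(te_seq)
            cur = off
        parts.append(slot.spacer[cur:])
        pos += len(slot.spacer) - cur

    for slot in slots:
        _emit_spacer(slot)
        if slot.kind == "gene":
            seq, exons, reps = _build_gene_piece(slot.cds_segs, slot.introns, slot.te_per_intron)
            abs_exons = [(pos + s, pos + e) for s, e in exons]
            for s, e, te in reps:
                repeats.append(
                    RepeatFeature(name, pos + s, pos + e, te.class_label, te.divergence,
                                  name=f"TE_w{te.wave}")
                )
            genes.append(
                GeneModel(
                    gene_id=slot.gene_id,
                    chromosome=name,
                    strand="+",
                    exons=abs_exons,
                    cds=list(abs_exons),
                    is_allele=slot.is_allele,
                    family_id=slot.family_id,
                    parent_id=slot.gene_id + ".gene",
                )
            )
            if slot.truth is not None:
                slot.truth.chromosome = name
                slot.truth.start = abs_exons[0][0]
                slot.truth.end = abs_exons[-1][1]
                truth.append(slot.truth)
            pos += len(seq)
            parts.append(seq)
        elif slot.kind == "residual":
            if slot.truth is not None:
                slot.truth.chromosome = name
                slot.truth.start = pos
                slot.truth.end = pos + len(slot.residual_seq)
                truth.append(slot.truth)
            parts.append(slot.residual_seq)
            pos += len(slot.residual_seq)
        elif slot.kind == "retro":
            if slot.truth is not None:
                slot.truth.chromosome = name
                slot.truth.start = pos
                slot.truth.end = pos + len(slot.retro_seq)
                truth.append(slot.truth)
            parts.append(slot.retro_seq)
            pos += len(slot.retro_seq)
        elif slot.kind == "empty":
            if slot.truth is not None:
                slot.truth.chromosome = name
                slot.truth.start = pos
                slot.truth.end = pos
                truth.append(slot.truth)
    return "".join(parts), genes, repeats, truth


def simulate(config: SimulationConfig) -> tuple[dict[str, GenomeBundle], pd.DataFrame]:
    """Run the generative model.

    Returns ``{"focal": bundle, ["outgroup": bundle]}`` and the truth table
    (one row per gene copy, :class:`TruthRecord` schema).  Deterministic for a
    fixed config.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seq_rng, fate_rng, mut_rng, te_rng = (np.random.default_rng(c) for c in ss.spawn(4))

    lo, hi = config.residual_retained_range
    lam = config.te_insertions_per_intron

    slot_lists: dict[str, list[_Slot]] = {}
    genes: list[GeneModel] = []
    repeats: list[RepeatFeature] = []
    truth: list[TruthRecord] = []
    families: dict[str, set[str]] = {}
    retro_requests: list[tuple[_AncGene, tuple[int, str, int]]] = []

    og_slot_lists: dict[str, list[_Slot]] = {}
    og_genes: list[GeneModel] = []
    og_families: dict[str, set[str]] = {}

    for c in range(config.n_chromosome_pairs):
        anc = [
            _make_ancestral_gene(f"anc{c:02d}g{i:03d}", config, seq_rng)
            for i in range(config.genes_per_chromosome)
        ]
        spacers = [
            _random_seq(seq_rng, 100 + int(seq_rng.exponential(config.intergenic_length_mean)))
            for _ in range(config.genes_per_chromosome + 1)
        ]

        # --- per-gene fates (dedicated stream, fixed draw order) -----------
        fates = []
        for g in anc:
            del_b = fate_rng.random() < config.fractionation_prob
            del_a = fate_rng.random() < config.fractionation_prob * config.fractionation_bias
            pseudo_b = fate_rng.random() < config.pseudogenization_prob
            pseudo_kind = "premature_stop" if fate_rng.random() < 0.5 else "frameshift"
            retro = fate_rng.random() < config.retrocopy_prob
            tandem = fate_rng.random() < config.tandem_dup_prob
            res_a = fate_rng.random() < config.residual_prob
            res_b = fate_rng.random() < config.residual_prob
            res_frac_a = lo + (hi - lo) * fate_rng.random()
            res_frac_b = lo + (hi - lo) * fate_rng.random()
            retro_chrom = int(fate_rng.integers(0, config.n_chromosome_pairs))
            retro_copy = "A" if fate_rng.random() < 0.5 else "B"
            retro_slot = int(fate_rng.integers(0, config.genes_per_chromosome))
            tandem_copy = "A" if fate_rng.random() < 0.5 else "B"
            fates.append(
                dict(
                    del_a=del_a, del_b=del_b, pseudo_b=pseudo_b, pseudo_kind=pseudo_kind,
                    retro=retro, tandem=tandem, res_a=res_a, res_b=res_b,
                    res_frac_a=res_frac_a, res_frac_b=res_frac_b,
                    retro_at=(retro_chrom, retro_copy, retro_slot), tandem_copy=tandem_copy,
                )
            )
        for g, fate in zip(anc, fates):
            if fate["retro"]:
                retro_requests.append((g, fate["retro_at"]))

        for copy_label, chrom_name in (("A", f"chr{c:02d}A"), ("B", f"chr{c:02d}B")):
            is_b = copy_label == "B"
            slots: list[_Slot] = []
            for i, (g, fate) in enumerate(zip(anc, fates)):
                fam = g.gene_id
                gid = f"{g.gene_id}_{'H2' if is_b else 'H1'}"
                partner = f"{g.gene_id}_{'H1' if is_b else 'H2'}"
                spacer = spacers[i]
                if is_b:
                    spacer = mutate(spacer, config.wgd_divergence, mut_rng)
                spacer_tes: list[tuple[int, str, _TEPlan]] = []
                n_sp = int(te_rng.poisson(lam * (config.te_bias_b if is_b else 1.0))) if lam > 0 else 0
                for _ in range(n_sp):
                    te = _draw_te(config, te_rng)
                    off = int(te_rng.integers(0, max(len(spacer), 1)))
                    spacer_tes.append((off, _random_seq(te_rng, te.length), te))

                deleted = fate["del_b"] if is_b else fate["del_a"]
                cds_segs = list(g.cds_segs)
                introns = list(g.introns)
                if is_b:
                    if deleted:
                        # decaying residuals accumulate stops freely
                        cds_segs = [mutate(s, config.wgd_divergence, mut_rng) for s in cds_segs]
                    else:
                        cds_segs = mutate_cds_segments(cds_segs, config.wgd_divergence, mut_rng)
                    introns = [mutate(s, config.wgd_divergence, mut_rng) for s in introns]

                if deleted:
                    residual = fate["res_b"] if is_b else fate["res_a"]
                    res_frac = fate["res_frac_b"] if is_b else fate["res_frac_a"]
                    if residual:
                        piece, exons, _ = _build_gene_piece(
                            cds_segs, introns, [[] for _ in introns]
                        )
                        total_cds = sum(e - s for s, e in exons)
                        # cut so the residual keeps res_frac of the CDS
                        # ("highly fragmented": low coverage, high identity)
                        target_cds = max(45, int(res_frac * total_cds))
                        keep = acc = 0
                        for s, e in exons:
                            if acc + (e - s) >= target_cds:
                                keep = s + (target_cds - acc)
                                break
                            acc += e - s
                            keep = e
                        kept_cds = sum(max(0, min(e, keep) - s) for s, e in exons)
                        tr = TruthRecord(
                            g.gene_id, copy_label, "deleted", "", "", -1, -1, 0, 0, False,
                            1.0 - kept_cds / total_cds, 0, partner,
                        )
                        slots.append(
                            _Slot("residual", spacer, spacer_tes, family_id=fam,
                                  residual_seq=piece[:keep], truth=tr)
                        )
                    else:
                        tr = TruthRecord(
                            g.gene_id, copy_label, "deleted", "", "", -1, -1, 0, 0, False,
                            1.0, 0, partner,
                        )
                        slots.append(_Slot("empty", spacer, spacer_tes, truth=tr))
                    continue

                # retained copy: TEs into introns, optional disablement on B
                te_per_intron: list[list[tuple[int, str, _TEPlan]]] = []
                n_te = 0
                for intron in introns:
                    tes: list[tuple[int, str, _TEPlan]] = []
                    k = int(te_rng.poisson(lam * (config.te_bias_b if is_b else 1.0))) if lam > 0 else 0
                    for _ in range(k):
                        te = _draw_te(config, te_rng)
                        off = int(te_rng.integers(0, max(len(intron), 1)))
                        tes.append((off, _random_seq(te_rng, te.length), te))
                    n_te += len(tes)
                    te_per_intron.append(tes)

                n_stop = n_fs = 0
                fate_label = "retained"
                if is_b and fate["pseudo_b"]:
                    fate_label = "pseudogenized"
                    cds = "".join(cds_segs)
                    mutated, info = inject_disablement(cds, fate["pseudo_kind"], mut_rng)
                    if info["kind"] == "premature_stop":
                        n_stop = 1
                    else:
                        n_fs = 1
                    # re-split, absorbing any length change into the containing exon
                    seg_lens = [len(s) for s in cds_segs]
                    if info["delta"] != 0:
                        acc = 0
                        for k, L in enumerate(seg_lens):
                            if info["position"] < acc + L or k == len(seg_lens) - 1:
                                seg_lens[k] = L + info["delta"]
                                break
                            acc += L
                    cds_segs, off = [], 0
                    for L in seg_lens:
                        cds_segs.append(mutated[off : off + L])
                        off += L

                tr = TruthRecord(
                    g.gene_id, copy_label, fate_label, gid, "", -1, -1,
                    n_stop, n_fs, False, 0.0, n_te, partner,
                )
                slots.append(
                    _Slot("gene", spacer, spacer_tes, gene_id=gid, family_id=fam,
                          cds_segs=cds_segs, introns=introns,
                          te_per_intron=te_per_intron, truth=tr)
                )
                families.setdefault(fam, set()).add(gid)

                if fate["tandem"] and fate["tandem_copy"] == copy_label:
                    tid = gid + "t"
                    t_segs = mutate_cds_segments(cds_segs, 0.005, mut_rng)
                    tr_t = TruthRecord(
                        g.gene_id, "tandem", "tandem_duplicate", tid, "", -1, -1,
                        0, 0, False, 0.0, 0, gid,
                    )
                    slots.append(
                        _Slot("gene", _random_seq(seq_rng, 80), [], gene_id=tid,
                              family_id=fam, cds_segs=t_segs, introns=list(introns),
                              te_per_intron=[[] for _ in introns], truth=tr_t)
                    )
                    families.setdefault(fam, set()).add(tid)

            # trailing spacer
            slots.append(_Slot("empty", spacers[-1], []))

            # inversion: reverse a run of slots (gene order rearrangement)
            if is_b and config.inversion_rate > 0 and fate_rng.random() < config.inversion_rate:
                g_lo, g_hi = config.inversion_genes_range
                seg = int(fate_rng.integers(g_lo, g_hi + 1))
                if seg < len(slots) - 1:
                    start = int(fate_rng.integers(0, len(slots) - 1 - seg))
                    slots[start : start + seg] = slots[start : start + seg][::-1]

            slot_lists[chrom_name] = slots

        # --- outgroup: diploid, every ancestral gene on both haplotypes ----
        if config.outgroup:
            for hap in ("a", "b"):
                og_slots: list[_Slot] = []
                for i, g in enumerate(anc):
                    gid = f"{g.gene_id}_O{1 if hap == 'a' else 2}"
                    og_slots.append(
                        _Slot("gene", spacers[i], [], gene_id=gid, family_id=g.gene_id,
                              cds_segs=list(g.cds_segs), introns=list(g.introns),
                              te_per_intron=[[] for _ in g.introns])
                    )
                    og_families.setdefault(g.gene_id, set()).add(gid)
                og_slots.append(_Slot("empty", spacers[-1], []))
                og_slot_lists[f"og{c:02d}{hap}"] = og_slots

    # --- processed retrocopies: spliced CDS + polyA dropped at a random slot
    for g, (rc, rcopy, rslot) in retro_requests:
        target = f"chr{min(rc, config.n_chromosome_pairs - 1):02d}{rcopy}"
        seq = mutate(g.cds, config.retro_divergence, mut_rng) + "A" * 25
        tr = TruthRecord(
            g.gene_id, "retro", "retrocopy", "", "", -1, -1, 0, 0, True, 0.0, 0,
            f"{g.gene_id}_H1",
        )
        slot = _Slot("retro", _random_seq(seq_rng, 120), [], family_id=g.gene_id,
                     retro_seq=seq, truth=tr)
        slots = slot_lists[target]
        slots.insert(min(rslot, len(slots) - 1), slot)

    chromosomes: dict[str, str] = {}
    for name in sorted(slot_lists):
        seq, gs, rs, ts = _assemble_chromosome(name, slot_lists[name])
        chromosomes[name] = seq
        genes.extend(gs)
        repeats.extend(rs)
        truth.extend(ts)

    og_chromosomes: dict[str, str] = {}
    for name in sorted(og_slot_lists):
        seq, gs, _, _ = _assemble_chromosome(name, og_slot_lists[name])
        og_chromosomes[name] = seq
        og_genes.extend(gs)

    focal = GenomeBundle(
        sequences=chromosomes,
        genes=genes,
        repeats=repeats,
        families=families,
        species_label="focal",
        ploidy=2,
    )
    focal.validate()
    bundles = {"focal": focal}
    if config.outgroup:
        og = GenomeBundle(
            sequences=og_chromosomes,
            genes=og_genes,
            repeats=[],
            families=og_families,
            species_label="outgroup",
            ploidy=2,
        )
        og.validate()
        bundles["outgroup"] = og

    truth_df = pd.DataFrame([t.__dict__ for t in truth]).sort_values(
        ["ancestral_gene_id", "copy"]
    ).reset_index(drop=True)
    return bundles, truth_df


def truth_partner_links(truth: pd.DataFrame) -> dict[str, str]:
    """True positional-homoeolog links: gene_id -> partner gene_id or 'lost'."""
    annotated = {r.gene_id: r for r in truth.itertuples() if r.gene_id}
    links: dict[str, str] = {}
    for gid, r in annotated.items():
        if r.copy not in ("A", "B"):
            continue
        links[gid] = r.partner_gene_id if r.partner_gene_id in annotated else "lost"
    return links


def write_simulation(
    outdir: str | Path,
    bundles: dict[str, GenomeBundle],
    truth: pd.DataFrame,
) -> dict[str, Path]:
    """Emit genome.fa, genes.gff3, repeats.out, families.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    focal = bundles["focal"]
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "repeats": outdir / "repeats.out",
        "families": outdir / "families.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(focal.sequences, paths["genome"])
    write_gff3(focal.genes, paths["genes"])
    write_repeatmasker_out(focal.repeats, paths["repeats"])
    fam_rows: dict[str, dict[str, set[str]]] = {}
    for label, bundle in bundles.items():
        for fam, members in bundle.families.items():
            fam_rows.setdefault(fam, {})[label] = set(members)
    write_family_table(fam_rows, paths["families"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if "outgroup" in bundles:
        og = bundles["outgroup"]
        write_fasta(og.sequences, outdir / "outgroup.fa")
        write_gff3(og.genes, outdir / "outgroup.gff3")
        paths["outgroup"] = outdir / "outgroup.fa"
    return paths
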