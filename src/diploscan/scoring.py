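"""Family x homoeologous-group diploidization records.

Per-gene features (intron bp, intronic-repeat bp, their genome-wide
z-scores, fractionation %, disablement counts from overlapping pseudogene
calls) are aggregated per family and group: maximum z-scores over copies,
mean fractionation, summed disablements, and a "highly affected" flag that
is true iff max intronic-repeat z >= 1 or total disablements > 0.  Family
retention against a diploid outgroup follows

    retention = 1 - (#Outgroup - #SpeciesOrGroup) / #Outgroup

with families excluded when the outgroup has no member, and overdispersed
families (more than 8 x ploidy members per species/group) filtered out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from diploscan.genome_io import GenomeBundle, write_feature_matrix
from diploscan.homoeology import HomoeologMap
from diploscan.pseudogenes import PseudogeneCall, compute_fractionation
from diploscan.repeats import intronic_repeat_bp


@dataclass
class GeneFeature:
    gene_id: str
    group: str  # H1 / H2 / unplaced
    family_id: str
    intron_bp: int
    intronic_repeat_bp: int
    intron_z: float
    intronic_repeat_z: float
    fractionation_pct: float | None
    n_disablements: int


@dataclass
class DiploidizationRecord:
    family_id: str
    group: str
    max_intron_z: float
    max_intronic_repeat_z: float
    mean_fractionation_pct: float | None
    total_disablements: int
    highly_affected: bool
    n_genes: int


@dataclass
class FamilyCounts:
    family_id: str
    counts: dict[str, int]  # species_or_group -> gene count
    outgroup_count: int


def zscore_genomewide(values) -> np.ndarray:
    """z_i = (x_i - mean) / sd with sample sd (n-1 denominator).

    The population is every predominant gene model, zeros included; zero
    spread returns all zeros with a warning rather than NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a genome-wide z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero spread; z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def aggregate_family(
    features: list[GeneFeature], family_id: str, group: str
) -> DiploidizationRecord | None:
    """Summarize one family's copies inside one group; None when empty."""
    copies = [f for f in features if f.family_id == family_id and f.group == group]
    if not copies:
        return None
    fr = [f.fractionation_pct for f in copies if f.fractionation_pct is not None]
    max_rep_z = max(f.intronic_repeat_z for f in copies)
    total_dis = sum(f.n_disablements for f in copies)
    return DiploidizationRecord(
        family_id=family_id,
        group=group,
        max_intron_z=max(f.intron_z for f in copies),
        max_intronic_repeat_z=max_rep_z,
        mean_fractionation_pct=float(np.mean(fr)) if fr else None,
        total_disablements=total_dis,
        highly_affected=bool(max_rep_z >= 1.0 or total_dis > 0),
        n_genes=len(copies),
    )


def family_retention(counts: FamilyCounts) -> dict[str, float]:
    """Retention per species/group; requires at least one outgroup member."""
    if counts.outgroup_count < 1:
        raise ValueError(
            f"family {counts.family_id}: outgroup must have at least one gene"
        )
    out = counts.outgroup_count
    return {
        sp: 1.0 - (out - n) / out for sp, n in counts.counts.items()
    }


def filter_overdispersed(count: int, ploidy: int) -> bool:
    """Keep iff count <= 8 x ploidy (drop strictly-more-than, e.g. transposase blooms)."""
    return count <= 8 * ploidy


def define_families(
    orthogroups: dict[str, set[str]], n_species: int
) -> dict[str, set[str]]:
    """Keep orthogroups with at least half of all sampled species present."""
    need = math.ceil(n_species / 2)
    return {og: sp for og, sp in orthogroups.items() if len(sp) >= need}


def gene_features(
    bundle: GenomeBundle,
    hmap: HomoeologMap,
    calls: list[PseudogeneCall],
    compute_fractionation_pct: bool = True,
) -> list[GeneFeature]:
    """Per-gene feature table over all predominant gene models."""
    fam_of: dict[str, str] = {}
    for fam, members in bundle.families.items():
        for m in members:
            fam_of[m] = fam
    genes = sorted(bundle.predominant_genes(), key=lambda g: g.gene_id)
    intron_bp = [sum(e - s for s, e in g.introns) for g in genes]
    rep_by_chrom: dict[str, list] = {}
    for r in bundle.repeats:
        rep_by_chrom.setdefault(r.chromosome, []).append(r)
    rep_bp = [intronic_repeat_bp(g, rep_by_chrom.get(g.chromosome, [])) for g in genes]
    intron_z = zscore_genomewide(intron_bp) if len(genes) > 1 else np.zeros(len(genes))
    rep_z = zscore_genomewide(rep_bp) if len(genes) > 1 else np.zeros(len(genes))

    calls_by_gene: dict[str, int] = {}
    calls_by_chrom: dict[str, list[PseudogeneCall]] = {}
    for c in calls:
        if c.gene_id:
            calls_by_gene[c.gene_id] = calls_by_gene.get(c.gene_id, 0) + c.n_disablements
        calls_by_chrom.setdefault(c.chromosome, []).append(c)

    feats: list[GeneFeature] = []
    for i, g in enumerate(genes):
        ndis = calls_by_gene.get(g.gene_id, 0)
        if ndis == 0:
            s, e = g.span
            for c in calls_by_chrom.get(g.chromosome, []):
                if not c.gene_id and c.start < e and s < c.end:
                    ndis += c.n_disablements
        frac = None
        if compute_fractionation_pct:
            frac = compute_fractionation(g, hmap, bundle, calls).fractionation_pct
        feats.append(
            GeneFeature(
                gene_id=g.gene_id,
                group=hmap.group_of(g),
                family_id=g.family_id or fam_of.get(g.gene_id, ""),
                intron_bp=intron_bp[i],
                intronic_repeat_bp=rep_bp[i],
                intron_z=float(intron_z[i]),
                intronic_repeat_z=float(rep_z[i]),
                fractionation_pct=frac,
                n_disablements=ndis,
            )
        )
    return feats


def score_pipeline(
    bundle: GenomeBundle,
    hmap: HomoeologMap,
    calls: list[PseudogeneCall],
    out_path: str | Path | None = None,
    compute_fractionation_pct: bool = True,
) -> list[DiploidizationRecord]:
    """End-to-end deterministic family x group record table."""
    feats = gene_features(bundle, hmap, calls, compute_fractionation_pct)
    by_key: dict[tuple[str, str], list[GeneFeature]] = {}
    for f in feats:
        if f.family_id:
            by_key.setdefault((f.family_id, f.group), []).append(f)
    records: list[DiploidizationRecord] = []
    for (fam, group) in sorted(by_key):
        rec = aggregate_family(by_key[(fam, group)], fam, group)
        if rec is not None:
            records.append(rec)
    if out_path is not None:
        write_feature_matrix(records, out_path)
    return records
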