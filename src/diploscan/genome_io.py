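"""Genome data model and readers/writers for GFF3, FASTA, RepeatMasker `.out`,
gene-family TSVs and generic feature matrices.

Internal coordinates are 0-based half-open on the forward genomic strand;
conversion to/from the 1-based closed GFF3 and RepeatMasker conventions
happens only at the format boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from diploscan.intervals import gaps, merge, total_length

Interval = tuple[int, int]


class GenomeIOError(ValueError):
    """Structured parse/validation error; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class GeneModel:
    """One mRNA-level gene model.

    ``exons`` and ``cds`` are ordered lists of 0-based half-open intervals in
    genomic (forward-strand) order.  ``gene_id`` identifies the transcript;
    ``parent_id`` the gene feature it belongs to.  ``is_predominant`` marks the
    longest mRNA of its gene (the only one used for scoring); ``is_allele``
    marks alternative-haplotype copies.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    is_allele: bool = False
    family_id: str | None = None
    parent_id: str | None = None
    is_predominant: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GenomeIOError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        ex = sorted(self.exons)
        if ex != self.exons:
            raise GenomeIOError(f"gene {self.gene_id}: exons not sorted in genomic order")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise GenomeIOError(f"gene {self.gene_id}: overlapping exons [{s1},{e1}) and [{s2},{e2})")
        merged = merge(self.exons)
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in merged):
                raise GenomeIOError(f"gene {self.gene_id}: CDS [{cs},{ce}) outside exons")

    @property
    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def introns(self) -> list[Interval]:
        return gaps(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_cds(self, sequences: Mapping[str, str]) -> str:
        """CDS nucleotide sequence, reverse-complemented for minus-strand genes."""
        seq = "".join(sequences[self.chromosome][s:e] for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def genomic_sequence(self, sequences: Mapping[str, str]) -> str:
        s, e = self.span
        return sequences[self.chromosome][s:e]


@dataclass
class RepeatFeature:
    """One masked repeat copy; divergence is the Kimura % distance to consensus."""

    chromosome: str
    start: int
    end: int
    class_label: str
    divergence_pct: float | None = None
    name: str = "rep"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GenomeIOError(f"repeat {self.name}: empty interval [{self.start},{self.end})")
        if self.divergence_pct is not None and self.divergence_pct < 0:
            raise GenomeIOError(f"repeat {self.name}: negative divergence {self.divergence_pct}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeBundle:
    """Sequences, gene models, repeats and family membership of one (pseudo-)haplotype."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    repeats: list[RepeatFeature] = field(default_factory=list)
    families: dict[str, set[str]] = field(default_factory=dict)
    species_label: str = "unnamed"
    ploidy: int = 2

    def validate(self) -> None:
        if self.ploidy < 1:
            raise GenomeIOError(f"ploidy must be >= 1, got {self.ploidy}")
        known = {g.gene_id for g in self.genes}
        for g in self.genes:
            if g.chromosome not in self.sequences:
                raise GenomeIOError(f"gene {g.gene_id}: unknown chromosome {g.chromosome}")
            if g.span[1] > len(self.sequences[g.chromosome]):
                raise GenomeIOError(f"gene {g.gene_id}: extends past end of {g.chromosome}")
        for fam, members in self.families.items():
            missing = members - known
            if missing:
                raise GenomeIOError(f"family {fam}: unknown members {sorted(missing)[:3]}")

    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def predominant_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_predominant]


def mark_predominant(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Flag the longest mRNA (by exonic bp, ties by id) of each gene as predominant."""
    by_parent: dict[str, list[GeneModel]] = {}
    out = list(genes)
    for g in out:
        by_parent.setdefault(g.parent_id or g.gene_id, []).append(g)
    for models in by_parent.values():
        best = max(models, key=lambda m: (m.exonic_length, m.gene_id))
        for m in models:
            m.is_predominant = m is best
    return out


# ---------------------------------------------------------------------------
# GFF3


def _gff3_prescan(path: str | Path) -> None:
    """Line-numbered structural checks gffutils cannot report: every exon/CDS
    must name a Parent defined somewhere in the file."""
    ids: set[str] = set()
    rows: list[tuple[int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"expected 9 tab-separated columns, got {len(cols)}", lineno)
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" in attrs:
                ids.add(attrs["ID"])
            if cols[2] in {"exon", "CDS", "mRNA"}:
                if "Parent" not in attrs:
                    raise GenomeIOError(f"{cols[2]} feature without Parent attribute", lineno)
                rows.append((lineno, cols[2], attrs["Parent"]))
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise GenomeIOError("non-numeric start/end", lineno) from None
            if start < 1 or end < start:
                raise GenomeIOError(f"invalid 1-based closed interval {start}..{end}", lineno)
    for lineno, ftype, parent in rows:
        for p in parent.split(","):
            if p not in ids:
                raise GenomeIOError(f"{ftype} names undefined Parent {p!r}", lineno)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features into one :class:`GeneModel` per mRNA.

    GFF3 1-based closed coordinates become 0-based half-open.  The longest
    mRNA per gene is flagged predominant; ``is_allele`` is taken from an
    ``is_allele=1`` attribute on the gene or mRNA when present.
    """
    _gff3_prescan(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons:
            exons = list(cds)
        parent = next(iter(mrna.attributes.get("Parent", [])), None)
        is_allele = mrna.attributes.get("is_allele", ["0"])[0] == "1"
        if parent is not None and not is_allele:
            try:
                g = db[parent]
                is_allele = g.attributes.get("is_allele", ["0"])[0] == "1"
            except gffutils.FeatureNotFoundError:
                pass
        genes.append(
            GeneModel(
                gene_id=mrna.id,
                chromosome=mrna.seqid,
                strand=mrna.strand if mrna.strand in "+-" else "+",
                exons=exons,
                cds=cds,
                is_allele=is_allele,
                parent_id=parent,
            )
        )
    return mark_predominant(genes)


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS rows, converting back to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.span, g.gene_id)):
            s, e = g.span
            parent = g.parent_id or f"{g.gene_id}.gene"
            allele = ";is_allele=1" if g.is_allele else ""
            fh.write(
                f"{g.chromosome}\tdiploscan\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={parent}{allele}\n"
            )
            fh.write(
                f"{g.chromosome}\tdiploscan\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Parent={parent}{allele}\n"
            )
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\tdiploscan\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (cs, ce) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chromosome}\tdiploscan\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """Parse the whitespace-delimited RepeatMasker `.out` dialect.

    Columns used: div (1), query (4), begin (5), end (6), repeat name (9),
    class/family (10).  Header and blank lines are skipped; 1-based closed
    begin/end become 0-based half-open.
    """
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            cols = line.split()
            if len(cols) < 11 or cols[0] in {"SW", "score"}:
                continue
            try:
                begin, end = int(cols[5]), int(cols[6])
            except ValueError:
                raise GenomeIOError(f"non-numeric begin/end {cols[5]!r}/{cols[6]!r}", lineno) from None
            try:
                div: float | None = float(cols[1])
            except ValueError:
                div = None
            feats.append(
                RepeatFeature(
                    chromosome=cols[4],
                    start=begin - 1,
                    end=end,
                    class_label=cols[10],
                    divergence_pct=div,
                    name=cols[9],
                )
            )
    return feats


def write_repeatmasker_out(repeats: Sequence[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(
            sorted(repeats, key=lambda r: (r.chromosome, r.start, r.end, r.name)), 1
        ):
            div = f"{r.divergence_pct:.1f}" if r.divergence_pct is not None else "*"
            fh.write(
                f"  225 {div:>5} 0.0 0.0  {r.chromosome} {r.start + 1} {r.end} (0) + "
                f"{r.name} {r.class_label} 1 {r.length} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# Family tables


def read_family_table(path: str | Path) -> dict[str, dict[str, set[str]]]:
    """TSV with columns family_id, species_or_group, gene_id ->
    {family_id: {species_or_group: {gene_id, ...}}}.

    Duplicate rows collapse; a gene appearing in two families is an error
    (families must partition genes).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "species_or_group", "gene_id"}
    if not required.issubset(df.columns):
        raise GenomeIOError(f"family table must have columns {sorted(required)}")
    seen: dict[str, str] = {}
    fams: dict[str, dict[str, set[str]]] = {}
    for fam, sp, gene in df[["family_id", "species_or_group", "gene_id"]].itertuples(index=False):
        if gene in seen and seen[gene] != fam:
            raise GenomeIOError(f"gene {gene} listed in families {seen[gene]} and {fam}")
        seen[gene] = fam
        fams.setdefault(fam, {}).setdefault(sp, set()).add(gene)
    return fams


def write_family_table(
    families: Mapping[str, Mapping[str, Iterable[str]]], path: str | Path
) -> None:
    rows = [
        {"family_id": fam, "species_or_group": sp, "gene_id": g}
        for fam in sorted(families)
        for sp in sorted(families[fam])
        for g in sorted(families[fam][sp])
    ]
    pd.DataFrame(rows, columns=["family_id", "species_or_group", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Feature matrices


def write_feature_matrix(records: Sequence[object], path: str | Path) -> None:
    """Write dataclass records (shared schema) as a deterministic TSV."""
    if records:
        first = records[0]
        if not dataclasses.is_dataclass(first):
            raise GenomeIOError("records must be dataclasses")
        columns = [f.name for f in dataclasses.fields(first)]
        rows = [
            {
                k: v if isinstance(v, (str, int, float, bool)) or v is None else str(v)
                for k, v in dataclasses.asdict(r).items()
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=columns).sort_values(columns).reset_index(drop=True)
    else:
        df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
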