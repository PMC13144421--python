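"""Promoter extraction and PWM scanning with exact score-distribution p-values.

Promoters are the 1.5 kb upstream of the annotated TSS (the gene 5' end).
Scanning is a log-odds scan against a 0-order background; p-values come
from the exact distribution of discretized window scores under that
background, computed by dynamic programming over motif columns, so they are
monotone non-increasing in score by construction.  Windows containing N are
hard-masked and never hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from diploscan.genome_io import GeneModel

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: number of discretization bins across the score range for the p-value DP
SCORE_BINS = 1000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix over ACGT with a 0-order background.

    ``matrix`` rows are positions, columns A,C,G,T probabilities; a
    pseudocount mixes in the background before log-odds conversion so zero
    cells stay finite.
    """

    motif_id: str
    matrix: np.ndarray  # (w, 4) probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (w, 4)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("degenerate background: zero-probability letter")
        # pseudocount normalization
        m = self.matrix + self.pseudocount * self.background
        self.matrix = m / m.sum(axis=1, keepdims=True)
        assert np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9)

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    def reverse_complemented(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background.copy(),
            pseudocount=0.0,
        )


@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    offset: int  # window start relative to the TSS (negative = upstream)
    strand: str
    score: float  # log-odds (bits)
    p_value: float


class _ScoreDistribution:
    """Exact distribution of discretized window scores under the background."""

    def __init__(self, lod: np.ndarray, background: np.ndarray, bins: int = SCORE_BINS):
        col_max = lod.max(axis=1)
        col_min = lod.min(axis=1)
        span = float(col_max.sum() - col_min.sum())
        self.delta = span / bins if span > 0 else 1.0
        self.int_scores = np.rint(lod / self.delta).astype(np.int64)  # (w,4)
        lo = self.int_scores.min(axis=1)
        hi = self.int_scores.max(axis=1)
        self.offset = int(lo.sum())
        size = int((hi - lo).sum()) + 1
        pmf = np.zeros(size)
        pmf[0] = 1.0
        length = 1
        for i in range(lod.shape[0]):
            width = int(hi[i] - lo[i])
            new = np.zeros(length + width)
            for letter in range(4):
                sh = int(self.int_scores[i, letter] - lo[i])
                new[sh : sh + length] += background[letter] * pmf[:length]
            pmf = new
            length = len(new)
        # survival function: P(int score >= s)
        self.sf = np.cumsum(pmf[::-1])[::-1]

    def int_score(self, letters: np.ndarray) -> int:
        return int(self.int_scores[np.arange(len(letters)), letters].sum())

    def p_value(self, int_score: int) -> float:
        idx = int_score - self.offset
        if idx <= 0:
            return 1.0
        if idx >= len(self.sf):
            return float(self.sf[-1])
        return float(self.sf[idx])


_LOOKUP = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _LOOKUP[b] = i
    _LOOKUP[b + 32] = i


def scan_pwm(
    promoter: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    gene_id: str = "",
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan one promoter; returns hits with p <= threshold, sorted by offset.

    The promoter string runs 5'->3' and ends at the TSS, so a window starting
    at index i has offset i - len(promoter).
    """
    w = pwm.width
    n = len(promoter)
    if n < w:
        return []
    letters = _LOOKUP[np.frombuffer(promoter.encode(), dtype=np.uint8)]
    hits: list[MotifHit] = []
    strands = [("+", pwm)] + ([("-", pwm.reverse_complemented())] if both_strands else [])
    for strand, mat in strands:
        lod = mat.log_odds()
        dist = _ScoreDistribution(lod, mat.background)
        for i in range(n - w + 1):
            window = letters[i : i + w]
            if (window < 0).any():  # hard-masked / ambiguous bases never hit
                continue
            s_int = dist.int_score(window)
            p = dist.p_value(s_int)
            if p <= p_threshold:
                score = float(lod[np.arange(w), window].sum())
                hits.append(MotifHit(gene_id, pwm.motif_id, i - n, strand, score, p))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def extract_promoter(
    gene: GeneModel, sequences: Mapping[str, str], length: int = 1500
) -> str:
    """The ``length`` bp upstream of the TSS, truncated at contig edges.

    Forward-strand genes take [TSS-length, TSS); reverse-strand genes the
    reverse complement of (TSS, TSS+length].  Case (soft-masking) is
    preserved.
    """
    seq = sequences[gene.chromosome]
    s, e = gene.span
    if gene.strand == "+":
        prom = seq[max(0, s - length) : s]
    else:
        prom = reverse_complement(seq[e : e + length])
    if not prom:
        import warnings

        warnings.warn(f"gene {gene.gene_id} at contig edge: empty promoter")
    return prom


def motif_presence_matrix(
    hits: Sequence[MotifHit],
    gene_groups: Mapping[str, str],
    position_window: tuple[int, int],
    motif_id: str | None = None,
):
    """Presence/absence of a motif within a promoter position window.

    ``position_window`` is the (min_offset, max_offset) range relative to the
    TSS in which a hit counts — the "particular position" is study-specific
    and therefore a required argument.  Returns a DataFrame with rows =
    homoeologous groups, columns = genes, values True/False; suitable for
    spotting the single absent promoter in an otherwise conserved family.
    """
    import pandas as pd

    lo, hi = position_window
    present: dict[str, bool] = {g: False for g in gene_groups}
    for h in sorted(hits, key=lambda h: (h.gene_id, h.offset)):
        if motif_id is not None and h.motif_id != motif_id:
            continue
        if h.gene_id in present and lo <= h.offset <= hi:
            present[h.gene_id] = True
    rows = sorted(set(gene_groups.values()))
    cols = sorted(gene_groups)
    data = {
        g: [present[g] if gene_groups[g] == grp else None for grp in rows] for g in cols
    }
    return pd.DataFrame(data, index=rows, columns=cols)


def read_meme_minimal(path: str | Path) -> list[PWM]:
    """Read PWMs from MEME minimal text format (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    out: list[PWM] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "minimal"):
            matrix = np.array([[m.pwm[b][i] for b in _ALPHABET] for i in range(m.length)])
            bg = np.array([m.background.get(b, 0.25) for b in _ALPHABET])
            out.append(PWM(m.name, matrix, bg / bg.sum()))
    return out


def write_meme_minimal(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(_ALPHABET, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} nsites= 1000000\n"
            )
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
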