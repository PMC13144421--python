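"""Kimura-2-parameter divergence and copy-divergence repeat landscapes.

The K2P model separates transitions (proportion P) and transversions (Q)
and estimates the substitution distance

    K = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

which is finite only on the estimable region 1-2P-Q > 0 and 1-2Q > 0.
Landscapes bin repeat copies by integer Kimura % divergence and express each
(class, bin) as the fraction of the assembly it covers — a proxy for
TE amplification age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from diploscan.genome_io import GeneModel, RepeatFeature
from diploscan.intervals import overlap_bp, total_length

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Divergence outside the estimable region of the K2P estimator."""


@dataclass
class DivergenceEstimate:
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float  # substitutions per site
    n_sites: int  # ungapped columns compared


def kimura2p(copy_sequence: str, consensus_sequence: str) -> DivergenceEstimate:
    """K2P distance between two equal-length aligned sequences.

    Columns where either sequence has a gap or ambiguity character are
    excluded.  Raises :class:`SaturationError` outside the estimable region
    rather than returning NaN.
    """
    if len(copy_sequence) != len(consensus_sequence):
        raise ValueError(
            f"aligned sequences must have equal length "
            f"({len(copy_sequence)} vs {len(consensus_sequence)})"
        )
    ts = tv = n = 0
    for a, b in zip(copy_sequence.upper(), consensus_sequence.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable (ungapped ACGT) columns")
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: P={P:.3f}, Q={Q:.3f} outside estimable region")
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return DivergenceEstimate(P=P, Q=Q, K=0.0 if K == 0 else K, n_sites=n)


@dataclass
class LandscapeBin:
    class_label: str
    kimura_bin: int  # [k, k+1) percent
    genome_fraction: float


@dataclass
class LandscapeResult:
    bins: list[LandscapeBin]
    n_missing_divergence: int

    def as_rows(self) -> list[tuple[str, int, float]]:
        return [(b.class_label, b.kimura_bin, b.genome_fraction) for b in self.bins]


def landscape(
    repeats: list[RepeatFeature], genome_length: int, bin_width: float = 1.0
) -> LandscapeResult:
    """Per (class, divergence bin) genome fraction.

    Overlapping copies of the same class and bin are merged before summation
    so a masked bp counts once; copies without a divergence are excluded and
    tallied in ``n_missing_divergence``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    groups: dict[tuple[str, int], list[tuple[int, int]]] = {}
    missing = 0
    for r in repeats:
        if r.divergence_pct is None:
            missing += 1
            continue
        k = int(r.divergence_pct // bin_width)
        groups.setdefault((r.class_label, k), []).append((r.start, r.end))
    bins = [
        LandscapeBin(cls, k, total_length(ivs) / genome_length)
        for (cls, k), ivs in sorted(groups.items())
    ]
    return LandscapeResult(bins=bins, n_missing_divergence=missing)


def intronic_repeat_bp(gene: GeneModel, repeats: list[RepeatFeature]) -> int:
    """Total bp of repeat coverage within the gene's introns.

    Repeats are merged across classes first (a bp is intronic-repeat once);
    single-exon genes score 0.
    """
    introns = gene.introns
    if not introns:
        return 0
    ivs = [r.interval for r in repeats if r.chromosome == gene.chromosome]
    bp = overlap_bp(introns, ivs)
    assert bp <= sum(e - s for s, e in introns)
    return bp
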