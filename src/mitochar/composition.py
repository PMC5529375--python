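"""Nucleotide composition and strand-skew statistics.

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), computed on the
majority strand for the whole genome and on each gene's reading-direction
sequence for the per-class statistics (protein-coding genes, tRNAs,
rRNAs, A+T-rich region). The ambiguity code ``N`` is counted as neither
AT nor GC.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome_io import AnnotatedGenome, extract_feature_sequence

__all__ = [
    "CompositionStats",
    "base_counts",
    "at_skew",
    "gc_skew",
    "composition_stats",
    "composition_by_class",
    "write_composition_tsv",
]

#: Order in which region classes are reported.
CLASS_ORDER = ("whole_genome", "PCGs", "tRNAs", "rRNAs", "AT_rich_region")

_KLASS_TO_REGION = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs",
                    "control": "AT_rich_region"}


@dataclass(frozen=True)
class CompositionStats:
    """A/T/G/C tallies and derived statistics for one region class."""

    region: str
    size_nt: int
    countA: int
    countT: int
    countG: int
    countC: int

    @property
    def countN(self) -> int:
        return self.size_nt - (self.countA + self.countT + self.countG + self.countC)

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.size_nt if self.size_nt else math.nan

    @property
    def pctA(self) -> float:
        return self._pct(self.countA)

    @property
    def pctT(self) -> float:
        return self._pct(self.countT)

    @property
    def pctG(self) -> float:
        return self._pct(self.countG)

    @property
    def pctC(self) -> float:
        return self._pct(self.countC)

    @property
    def pctAT(self) -> float:
        return self._pct(self.countA + self.countT)

    @property
    def at_skew(self) -> float:
        return at_skew(self.countA, self.countT)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.countG, self.countC)


def base_counts(seq: str) -> tuple[int, int, int, int, int]:
    """Exact (A, T, G, C, N) tallies of a DNA string."""
    c = Counter(seq.upper())
    return c["A"], c["T"], c["G"], c["C"], c["N"]


def at_skew(count_a: int, count_t: int) -> float:
    """(A − T)/(A + T); NaN when A + T = 0."""
    denom = count_a + count_t
    return (count_a - count_t) / denom if denom else math.nan


def gc_skew(count_g: int, count_c: int) -> float:
    """(G − C)/(G + C); NaN when G + C = 0."""
    denom = count_g + count_c
    return (count_g - count_c) / denom if denom else math.nan


def composition_stats(seq: str, region: str = "custom") -> CompositionStats:
    a, t, g, c, _n = base_counts(seq)
    return CompositionStats(region, len(seq), a, t, g, c)


def composition_by_class(genome: AnnotatedGenome) -> list[CompositionStats]:
    """Composition of the whole genome and of each region class.

    The whole genome is counted once on the majority strand. Each class is
    the concatenation of its members' sense-strand sequences; overlapping
    features are counted per feature, not deduplicated. Classes absent
    from the annotation yield size-0 stats with NaN skews.
    """
    pooled: dict[str, list[str]] = {k: [] for k in CLASS_ORDER[1:]}
    for f in genome.features:
        region = _KLASS_TO_REGION.get(f.klass)
        if region is not None:
            pooled[region].append(extract_feature_sequence(genome, f))
    stats = [composition_stats(genome.sequence, "whole_genome")]
    for region in CLASS_ORDER[1:]:
        stats.append(composition_stats("".join(pooled[region]), region))
    return stats


def write_composition_tsv(stats: list[CompositionStats], raw: bool = False) -> str:
    """Table of per-class composition; percentages to 1 decimal and skews
    to 3 decimals unless ``raw`` is set."""
    rows = []
    for s in stats:
        rows.append({
            "region": s.region, "size": s.size_nt,
            "A": s.countA, "T": s.countT, "G": s.countG, "C": s.countC,
            "A_pct": s.pctA, "T_pct": s.pctT, "G_pct": s.pctG, "C_pct": s.pctC,
            "AT_pct": s.pctAT, "AT_skew": s.at_skew, "GC_skew": s.gc_skew,
        })
    df = pd.DataFrame(rows)
    if not raw:
        for col in ("A_pct", "T_pct", "G_pct", "C_pct", "AT_pct"):
            df[col] = df[col].round(1)
        for col in ("AT_skew", "GC_skew"):
            df[col] = df[col].round(3)
    return df.to_csv(sep="\t", index=False, na_rep="NA")
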