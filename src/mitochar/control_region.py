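"""A+T-rich (control) region location and feature detection.

The control region of lepidopteran mitogenomes lies between ``rrnS`` and
``trnM`` and carries two structures this module detects: the conserved
"ATAGA + poly-T" motif just downstream of ``rrnS`` (the putative origin
of minority-strand replication) and tandem-repeat arrays. Repeat
detection is exact-match self-alignment: a span is a tandem array of
period *p* when ``region[i] == region[i-p]`` for every interior
position; arrays whose unit is itself periodic are reported at the
smallest period.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .composition import composition_stats
from .genome_io import AnnotatedGenome, CONTROL_NAME, FeatureRecord

__all__ = [
    "MotifHit",
    "TandemRepeat",
    "ControlRegionNotFound",
    "locate_at_rich_region",
    "find_ataga_polyt",
    "find_tandem_repeats",
    "write_control_region_tsv",
]

# Scan defaults; no published thresholds exist for these structures, so the
# values are chosen to detect the motif (a >=5-nt poly-T tract within 20 nt
# of ATAGA) and biologically typical repeat arrays (unit >=2 nt, >=2 copies,
# >=10 nt of total span). All are overridable per call and on the CLI.
DEFAULT_MIN_POLYT = 5
DEFAULT_WINDOW = 20
DEFAULT_MIN_PERIOD = 2
DEFAULT_MAX_PERIOD = 200
DEFAULT_MIN_COPIES = 2.0
DEFAULT_MIN_SPAN = 10


class ControlRegionNotFound(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    position: int        # 1-based offset of the ATAGA within the region
    motif: str
    polyT_length: int


@dataclass(frozen=True)
class TandemRepeat:
    unit: str
    period: int
    copies: float        # fractional final copy allowed
    start: int           # 1-based inclusive within the region
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def locate_at_rich_region(genome: AnnotatedGenome, min_gap: int = 50) -> FeatureRecord:
    """The annotated control feature, or the longest unannotated gap.

    Falls back to scanning inter-feature gaps on the circular molecule
    when no control feature is annotated; the chosen gap must abut
    ``rrnS`` (the expected upstream neighbour) and be at least
    ``min_gap`` nt, else :class:`ControlRegionNotFound` is raised.
    """
    for f in genome.features:
        if f.klass == "control":
            return f
    feats = genome.features
    if not any(f.name == "rrnS" for f in feats):
        raise ControlRegionNotFound(
            f"{genome.identifier!r} lacks both a control feature and rrnS")
    n = len(genome)
    best: tuple[int, FeatureRecord] | None = None
    for i, prev in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if nxt.start > prev.end:
            start, end = prev.end + 1, nxt.start - 1
            gap = end - start + 1
        else:  # closure across the origin
            start = prev.end + 1 if prev.end < n else 1
            end = nxt.start - 1 if nxt.start > 1 else n
            gap = (n - prev.end) + (nxt.start - 1)
            if gap <= 0:
                continue
            end = start + gap - 1 if start + gap - 1 <= n else (start + gap - 1) - n
        if gap >= min_gap and prev.name == "rrnS" and (best is None or gap > best[0]):
            best = (gap, FeatureRecord(CONTROL_NAME, "control", "F", start, end))
    if best is None:
        raise ControlRegionNotFound(
            f"no unannotated span >= {min_gap} nt abutting rrnS in {genome.identifier!r}")
    return best[1]


def find_ataga_polyt(region: str, min_polyt: int = DEFAULT_MIN_POLYT,
                     window: int = DEFAULT_WINDOW) -> list[MotifHit]:
    """All ATAGA occurrences followed by a poly-T run within ``window`` nt.

    The run must have at least ``min_polyt`` consecutive T and begin no
    more than ``window`` nt downstream of the ATAGA's last base; the
    first qualifying run's length is reported.
    """
    if min_polyt < 1:
        raise ValueError("min_polyt must be >= 1")
    region = region.upper()
    hits = []
    pos = region.find("ATAGA")
    while pos != -1:
        tail_start = pos + 5
        limit = min(len(region), tail_start + window)
        i = tail_start
        while i < limit:
            if region[i] == "T":
                j = i
                while j < len(region) and region[j] == "T":
                    j += 1
                if j - i >= min_polyt:
                    hits.append(MotifHit(pos + 1, "ATAGA", j - i))
                    break
                i = j
            else:
                i += 1
        pos = region.find("ATAGA", pos + 1)
    return hits


def _extend(region: str, start: int, period: int) -> int:
    """Length of the maximal run with region[i] == region[i-period] from
    ``start`` (0-based); the run includes the leading unit."""
    i = start + period
    while i < len(region) and region[i] == region[i - period]:
        i += 1
    return i - start


def _smallest_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


def find_tandem_repeats(region: str,
                        min_period: int = DEFAULT_MIN_PERIOD,
                        max_period: int = DEFAULT_MAX_PERIOD,
                        min_copies: float = DEFAULT_MIN_COPIES,
                        min_span: int = DEFAULT_MIN_SPAN) -> list[TandemRepeat]:
    """Maximal exact tandem arrays by self-alignment scan.

    Every start/period combination is extended while
    ``region[i] == region[i-p]``; arrays are reported at their smallest
    period, must reach ``min_copies`` copies and ``min_span`` nt, and
    arrays contained in (or equal to a sub-array of) a longer reported
    array with the same period are suppressed.
    """
    region = region.upper()
    n = len(region)
    if not (1 <= min_period <= max_period):
        raise ValueError("need 1 <= min_period <= max_period")
    found: list[TandemRepeat] = []
    max_p = min(max_period, n // 2)
    for p in range(min_period, max_p + 1):
        s = 0
        while s + 2 * p <= n:
            run = _extend(region, s, p)
            if run >= 2 * p:
                unit = region[s:s + p]
                if _smallest_period(unit) == p:
                    copies = run / p
                    if copies >= min_copies and run >= min_span:
                        found.append(TandemRepeat(unit, p, round(copies, 2),
                                                  s + 1, s + run))
                s += max(run - 2 * p + 1, 1)
            else:
                s += 1
    # suppress arrays wholly contained in another reported array
    found.sort(key=lambda r: (r.start, -(r.span), r.period))
    kept: list[TandemRepeat] = []
    for r in found:
        if not any(k.start <= r.start and r.end <= k.end and k is not r for k in kept):
            kept.append(r)
    return kept


def write_control_region_tsv(genome: AnnotatedGenome, region: FeatureRecord,
                             sequence: str, hits: list[MotifHit],
                             repeats: list[TandemRepeat]) -> str:
    stats = composition_stats(sequence, CONTROL_NAME)
    rows = [{"genome": genome.identifier, "record": "region",
             "detail": f"{region.start}-{region.end}",
             "value": stats.size_nt},
            {"genome": genome.identifier, "record": "AT_pct",
             "detail": "", "value": round(stats.pctAT, 1)}]
    for h in hits:
        rows.append({"genome": genome.identifier, "record": "motif",
                     "detail": f"{h.motif}@{h.position}", "value": h.polyT_length})
    for r in repeats:
        rows.append({"genome": genome.identifier, "record": "tandem_repeat",
                     "detail": f"{r.unit}@{r.start}-{r.end}", "value": r.copies})
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)
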