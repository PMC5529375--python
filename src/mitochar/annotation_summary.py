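"""Per-gene summary of an annotated mitogenome.

Derives, for every feature in genome order: its size in nucleotides, the
intergenic spacer to the next feature (negative values = overlap, with
circular closure from the last feature back to the first), and — for
protein-coding genes — the start codon and the complete/incomplete stop
codon read from the sequence itself.

Insect mitochondrial CDSs frequently end on a truncated stop (``T`` or
``TA``, completed to UAA by polyadenylation of the transcript); the
classifier recognizes those, and flags genes whose annotated length is
inconsistent with any recognized stop.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import AnnotatedGenome, FeatureRecord, extract_feature_sequence

__all__ = [
    "SummaryRow",
    "CANONICAL_STARTS",
    "feature_length",
    "intergenic_spacer",
    "classify_start_codon",
    "classify_stop_codon",
    "build_summary_table",
    "summary_to_frame",
    "write_summary_tsv",
]

#: Start codons treated as canonical for insect mitochondrial PCGs:
#: the ATN family plus the conserved CGA initiator of cox1.
CANONICAL_STARTS = frozenset({"ATA", "ATT", "ATC", "ATG", "CGA"})

COMPLETE_STOPS = frozenset({"TAA", "TAG"})


@dataclass(frozen=True)
class SummaryRow:
    gene: str
    klass: str
    direction: str
    start: int
    end: int
    size_nt: int
    anticodon: str | None
    start_codon: str | None
    start_canonical: bool | None
    stop_codon: str | None
    stop_flag: bool | None  # True when the stop is inconsistent (OTHER)
    intergenic_nt: int


def feature_length(feature: FeatureRecord, genome_length: int) -> int:
    """Size in nt; wrapped features span start..L plus 1..end."""
    if feature.start > genome_length or feature.end > genome_length:
        raise ValueError(
            f"{feature.name!r} coordinates exceed genome length {genome_length}")
    return feature.length(genome_length)


def intergenic_spacer(prev: FeatureRecord, nxt: FeatureRecord,
                      genome_length: int) -> int:
    """Nucleotides between two consecutive features; negative = overlap.

    The last→first pair of a circular annotation is measured across the
    origin: ``(L - prev.end) + (next.start - 1)``.
    """
    if prev is nxt or (prev.name == nxt.name and prev.start == nxt.start):
        raise ValueError(f"cannot measure a spacer from {prev.name!r} to itself")
    gap = nxt.start - prev.end - 1
    if nxt.start <= prev.start and not prev.wraps:
        # circular closure back past the origin
        gap = (genome_length - prev.end) + (nxt.start - 1)
    return gap


def classify_start_codon(cds: str) -> tuple[str, bool]:
    """First codon of a sense-strand CDS and whether it is canonical."""
    if len(cds) < 3:
        raise ValueError(f"CDS of length {len(cds)} has no start codon")
    codon = cds[:3].upper()
    return codon, codon in CANONICAL_STARTS


def classify_stop_codon(cds: str) -> tuple[str, bool]:
    """Terminal (possibly incomplete) stop codon of a sense-strand CDS.

    Returns one of ``TAA``/``TAG`` (complete), ``T``/``A`` (length ≡ 1
    mod 3) or ``TA`` (length ≡ 2 mod 3), together with an inconsistency
    flag; any other ending is reported as ``OTHER`` with the flag set.
    """
    if len(cds) < 4:
        raise ValueError(f"CDS of length {len(cds)} too short to classify a stop")
    cds = cds.upper()
    rem = len(cds) % 3
    if rem == 0 and cds[-3:] in COMPLETE_STOPS:
        return cds[-3:], False
    if rem == 1 and cds[-1] in ("T", "A"):
        return cds[-1], False
    if rem == 2 and cds[-2:] == "TA":
        return "TA", False
    return "OTHER", True


def build_summary_table(genome: AnnotatedGenome) -> list[SummaryRow]:
    """One SummaryRow per feature in genome order, all columns derived."""
    if not genome.features:
        raise ValueError(f"{genome.identifier!r} has no features to summarize")
    n = len(genome)
    rows = []
    feats = genome.features
    informative = set(genome.sequence) != {"N"}
    for i, f in enumerate(feats):
        if len(feats) > 1:
            gap = intergenic_spacer(f, feats[(i + 1) % len(feats)], n)
        else:
            gap = n - f.length(n)  # single feature: rest of the circle
        start_codon = stop_codon = None
        start_ok = stop_flag = None
        if f.klass == "PCG" and informative:
            cds = extract_feature_sequence(genome, f)
            start_codon, start_ok = classify_start_codon(cds)
            stop_codon, stop_flag = classify_stop_codon(cds)
        rows.append(SummaryRow(
            gene=f.name, klass=f.klass, direction=f.strand,
            start=f.start, end=f.end, size_nt=f.length(n),
            anticodon=f.anticodon,
            start_codon=start_codon, start_canonical=start_ok,
            stop_codon=stop_codon, stop_flag=stop_flag,
            intergenic_nt=gap,
        ))
    return rows


def summary_to_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["location"] = df["start"].astype(str) + "-" + df["end"].astype(str)
    return df[["gene", "klass", "direction", "location", "size_nt", "anticodon",
               "start_codon", "stop_codon", "intergenic_nt", "start_canonical",
               "stop_flag"]]


def write_summary_tsv(rows: list[SummaryRow]) -> str:
    """Render the per-gene summary as a TSV string."""
    df = summary_to_frame(rows)
    out = df[["gene", "direction", "location", "size_nt", "anticodon",
              "start_codon", "stop_codon", "intergenic_nt"]].copy()
    out.columns = ["gene", "direction", "location", "size", "anticodon",
                   "start_codon", "stop_codon", "intergenic_nt"]
    return out.to_csv(sep="\t", index=False, na_rep="")
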