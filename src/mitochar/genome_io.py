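"""Reading, writing and slicing annotated circular mitochondrial genomes.

The central object is :class:`AnnotatedGenome`: an uppercase DNA sequence
(alphabet ``A C G T N``) plus an ordered list of strand-aware
:class:`FeatureRecord` entries. Coordinates are 1-based and inclusive, the
GenBank convention; a feature with ``end < start`` wraps across the origin
of the circular molecule.

Feature names are normalized to canonical mitochondrial gene labels
(``cox1``–``cox3``, ``cob``, ``nad1``–``nad6``, ``nad4L``, ``atp6``,
``atp8``, ``rrnL``, ``rrnS``, the 22 ``trnX`` labels with the Leu/Ser
isoacceptors disambiguated as ``trnL1(CUN)``/``trnL2(UUR)`` →
``trnL1``/``trnL2`` and ``trnS1(AGN)``/``trnS2(UCN)`` →
``trnS1``/``trnS2``, and ``AT_rich_region`` for the control region) so
that downstream gene-order comparison has stable keys.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AnnotatedGenome",
    "FeatureRecord",
    "GenomeParseError",
    "CoordinateError",
    "AlphabetError",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "CONTROL_NAME",
    "canonical_name",
    "parse_genbank",
    "parse_fasta",
    "parse_feature_tsv",
    "write_feature_tsv",
    "write_genbank",
    "reverse_complement",
    "extract_feature_sequence",
]


class GenomeParseError(ValueError):
    """Malformed GenBank/FASTA/TSV input."""


class CoordinateError(ValueError):
    """A feature's coordinates do not fit the sequence."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


#: The 13 mitochondrial protein-coding genes.
PCG_NAMES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4L", "nad6", "cob", "nad1",
)

#: The 22 tRNA genes, Leu/Ser isoacceptors disambiguated.
TRNA_NAMES = (
    "trnM", "trnI", "trnQ", "trnW", "trnC", "trnY", "trnL2", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
)

RRNA_NAMES = ("rrnL", "rrnS")

CONTROL_NAME = "AT_rich_region"

VALID_KLASSES = frozenset({"PCG", "tRNA", "rRNA", "control", "other"})

_DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# One-letter amino-acid code -> trn label stem, for tRNA-Xxx product names.
_AA3_TO_TRN = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P", "THR": "T",
    "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Common GenBank spellings -> canonical labels. Keys are upper-cased and
# stripped of punctuation/whitespace before lookup.
_SYNONYMS: dict[str, str] = {
    # protein-coding genes
    "COX1": "cox1", "COI": "cox1", "CO1": "cox1", "COXI": "cox1",
    "COX2": "cox2", "COII": "cox2", "CO2": "cox2", "COXII": "cox2",
    "COX3": "cox3", "COIII": "cox3", "CO3": "cox3", "COXIII": "cox3",
    "COB": "cob", "CYTB": "cob", "CYB": "cob",
    "ND1": "nad1", "NAD1": "nad1", "NADH1": "nad1",
    "ND2": "nad2", "NAD2": "nad2", "NADH2": "nad2",
    "ND3": "nad3", "NAD3": "nad3", "NADH3": "nad3",
    "ND4": "nad4", "NAD4": "nad4", "NADH4": "nad4",
    "ND4L": "nad4L", "NAD4L": "nad4L", "NADH4L": "nad4L",
    "ND5": "nad5", "NAD5": "nad5", "NADH5": "nad5",
    "ND6": "nad6", "NAD6": "nad6", "NADH6": "nad6",
    "ATP6": "atp6", "ATPASE6": "atp6", "ATPASESUBUNIT6": "atp6",
    "ATP8": "atp8", "ATPASE8": "atp8", "ATPASESUBUNIT8": "atp8",
    # rRNAs
    "RRNL": "rrnL", "LRRNA": "rrnL", "16S": "rrnL", "16SRRNA": "rrnL",
    "16SRIBOSOMALRNA": "rrnL", "LARGESUBUNITRIBOSOMALRNA": "rrnL",
    "RRNS": "rrnS", "SRRNA": "rrnS", "12S": "rrnS", "12SRRNA": "rrnS",
    "12SRIBOSOMALRNA": "rrnS", "SMALLSUBUNITRIBOSOMALRNA": "rrnS",
    # control region
    "ATRICHREGION": CONTROL_NAME, "CONTROLREGION": CONTROL_NAME,
    "DLOOP": CONTROL_NAME, "ATRICH": CONTROL_NAME,
    # disambiguated Leu/Ser tRNAs
    "TRNL1": "trnL1", "TRNL1CUN": "trnL1", "TRNLCUN": "trnL1",
    "TRNALEUCUN": "trnL1", "TRNALEU1": "trnL1",
    "TRNL2": "trnL2", "TRNL2UUR": "trnL2", "TRNLUUR": "trnL2",
    "TRNALEUUUR": "trnL2", "TRNALEU2": "trnL2",
    "TRNS1": "trnS1", "TRNS1AGN": "trnS1", "TRNSAGN": "trnS1",
    "TRNASERAGN": "trnS1", "TRNASER1": "trnS1",
    "TRNS2": "trnS2", "TRNS2UCN": "trnS2", "TRNSUCN": "trnS2",
    "TRNASERUCN": "trnS2", "TRNASER2": "trnS2",
}
# trnM, trnI, ... and tRNA-Met, tRNA-Ile, ... for the unambiguous tRNAs
for _aa3, _letter in _AA3_TO_TRN.items():
    _SYNONYMS[f"TRN{_letter}"] = f"trn{_letter}"
    _SYNONYMS[f"TRNA{_aa3}"] = f"trn{_letter}"

_STRIP_RE = re.compile(r"[\s\-_()+'.]")


def canonical_name(raw: str) -> str:
    """Map a feature name to its canonical label, else return it unchanged."""
    key = _STRIP_RE.sub("", raw).upper()
    return _SYNONYMS.get(key, raw)


def _infer_klass(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == CONTROL_NAME:
        return "control"
    return "other"


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated gene or region on the circular molecule.

    ``start``/``end`` are 1-based inclusive; ``end < start`` marks a
    feature wrapping across the origin. ``strand`` is ``F`` for the
    majority strand and ``R`` for the minority strand.
    """

    name: str
    klass: str
    strand: str
    start: int
    end: int
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.klass not in VALID_KLASSES:
            raise ValueError(f"unknown feature class {self.klass!r} for {self.name!r}")
        if self.strand not in ("F", "R"):
            raise ValueError(f"strand must be F or R, got {self.strand!r} for {self.name!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"coordinates must be >= 1 for {self.name!r}")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """A circular DNA sequence plus its ordered feature annotation."""

    identifier: str
    sequence: str
    features: list[FeatureRecord] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise AlphabetError(f"sequence of {self.identifier!r} contains {sorted(bad)}")
        if len(self.sequence) < 1:
            raise GenomeParseError(f"empty sequence for {self.identifier!r}")
        for f in self.features:
            if f.start > len(self.sequence) or f.end > len(self.sequence):
                raise CoordinateError(
                    f"feature {f.name!r} ({f.start}..{f.end}) lies outside the "
                    f"{len(self.sequence)}-bp sequence of {self.identifier!r}"
                )
        self.features = sorted(self.features, key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> FeatureRecord:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over {A, C, G, T, N}."""
    bad = set(seq.upper()) - _DNA_ALPHABET
    if bad:
        raise AlphabetError(f"cannot complement characters {sorted(bad)}")
    # Bio.Seq handles IUPAC codes too, but the alphabet check above keeps the
    # contract tight; the actual complementation is delegated.
    return str(Seq(seq.upper()).reverse_complement())


def extract_feature_sequence(genome: AnnotatedGenome, feat: FeatureRecord) -> str:
    """Sense-strand (reading-direction) sequence of a feature.

    For minority-strand (``R``) features this is the reverse complement of
    the annotated span. Origin-spanning features concatenate the suffix
    (``start``..L) and prefix (1..``end``) before orientation.
    """
    n = len(genome)
    if feat.start > n or feat.end > n:
        raise CoordinateError(f"{feat.name!r} ({feat.start}..{feat.end}) exceeds length {n}")
    if feat.wraps:
        if not genome.circular:
            raise CoordinateError(
                f"{feat.name!r} wraps the origin but {genome.identifier!r} is linear"
            )
        span = genome.sequence[feat.start - 1:] + genome.sequence[:feat.end]
    else:
        span = genome.sequence[feat.start - 1:feat.end]
    return reverse_complement(span) if feat.strand == "R" else span


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_FEATURE_KEYS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                 "misc_feature": "control", "D-loop": "control"}


def _feature_name(sf: SeqFeature) -> str | None:
    for qual in ("gene", "product", "note", "standard_name"):
        vals = sf.qualifiers.get(qual)
        if vals:
            return str(vals[0])
    return None


def parse_genbank(text: str) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    ``complement(...)`` locations become strand ``R``; a
    ``join(a..L,1..b)`` across the origin becomes a wrapped feature with
    ``end < start``. ``gene`` features that duplicate a CDS/tRNA/rRNA at
    the same locus are skipped in favour of the typed feature.
    """
    if "ORIGIN" not in text:
        raise GenomeParseError("GenBank record has no ORIGIN block")
    try:
        record = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError subclasses
        raise GenomeParseError(f"unparseable GenBank record: {exc}") from exc
    seq = str(record.seq).upper()
    n = len(seq)
    feats: list[FeatureRecord] = []
    seen: set[tuple[str, int, int]] = set()
    for sf in record.features:
        if sf.type == "source":
            continue
        klass = _FEATURE_KEYS.get(sf.type)
        raw = _feature_name(sf)
        if raw is None:
            continue
        name = canonical_name(raw)
        if klass is None and sf.type != "gene":
            continue
        if klass is None or klass == "control":
            # gene features and misc_features fall back to name-based class
            inferred = _infer_klass(name)
            klass = inferred if inferred != "other" else (klass or "other")
        loc = sf.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # origin-spanning join(a..L, 1..b)
            if len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
                start, end = int(parts[1].start) + 1, int(parts[0].end)
            else:
                start, end = int(loc.start) + 1, int(loc.end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        if end > n or start > n:
            raise CoordinateError(f"feature {name!r} ({start}..{end}) outside 1..{n}")
        strand = "R" if loc.strand == -1 else "F"
        anticodon = None
        if klass == "tRNA":
            ac = sf.qualifiers.get("anticodon") or sf.qualifiers.get("codon_recognized")
            if ac:
                m = re.search(r"seq:([acgtu]{3})", str(ac[0]), re.I)
                anticodon = (m.group(1) if m else str(ac[0]))[:3].upper().replace("U", "T")
        key = (name, start, end)
        if key in seen:
            continue
        seen.add(key)
        feats.append(FeatureRecord(name, klass, strand, start, end, anticodon))
    # drop untyped 'gene' duplicates of typed features at the same span
    spans = {(f.start, f.end) for f in feats if f.klass != "other"}
    feats = [f for f in feats if not (f.klass == "other" and (f.start, f.end) in spans)]
    topology = record.annotations.get("topology", "circular")
    return AnnotatedGenome(record.id or record.name, seq, feats,
                           circular=topology != "linear")


def write_genbank(genome: AnnotatedGenome) -> str:
    """Render an :class:`AnnotatedGenome` as a GenBank flat file string."""
    record = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                       name=genome.identifier[:16], description="mitochondrion, complete genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "control": "misc_feature", "other": "misc_feature"}
    n = len(genome)
    for f in genome.features:
        strand = -1 if f.strand == "R" else 1
        if f.wraps:
            loc = CompoundLocation([SimpleLocation(f.start - 1, n, strand),
                                    SimpleLocation(0, f.end, strand)])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["codon_recognized"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=type_of[f.klass], qualifiers=quals))
    out = io.StringIO()
    SeqIO.write(record, out, "genbank")
    return out.getvalue()


def parse_fasta(text: str) -> tuple[str, str]:
    """Return (identifier, sequence) from a single-record FASTA string."""
    try:
        record = SeqIO.read(io.StringIO(text), "fasta")
    except Exception as exc:
        raise GenomeParseError(f"unparseable FASTA: {exc}") from exc
    return record.id, str(record.seq).upper()


# ---------------------------------------------------------------------------
# Feature TSV
# ---------------------------------------------------------------------------

TSV_HEADER = "name\tklass\tstrand\tstart\tend\tanticodon"


def parse_feature_tsv(text: str, sequence: str, identifier: str = "genome") -> AnnotatedGenome:
    """Build an :class:`AnnotatedGenome` from a feature TSV plus a sequence.

    Expected columns: ``name klass strand start end anticodon`` (header
    required; anticodon may be empty). Round-trips with
    :func:`write_feature_tsv`.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:5] != TSV_HEADER.split("\t")[:5]:
        raise GenomeParseError(f"feature TSV must start with header {TSV_HEADER!r}")
    feats = []
    for ln in lines[1:]:
        cols = ln.split("\t")
        if len(cols) < 5:
            raise GenomeParseError(f"feature TSV row has {len(cols)} columns: {ln!r}")
        name, klass, strand = cols[0], cols[1], cols[2]
        if klass not in VALID_KLASSES:
            raise GenomeParseError(f"unknown klass {klass!r} in row {ln!r}")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise GenomeParseError(f"non-integer coordinates in row {ln!r}") from exc
        anticodon = cols[5].strip() or None if len(cols) > 5 else None
        feats.append(FeatureRecord(canonical_name(name), klass, strand, start, end, anticodon))
    return AnnotatedGenome(identifier, sequence, feats)


def write_feature_tsv(genome: AnnotatedGenome) -> str:
    rows = [TSV_HEADER]
    for f in genome.features:
        rows.append(f"{f.name}\t{f.klass}\t{f.strand}\t{f.start}\t{f.end}\t{f.anticodon or ''}")
    return "\n".join(rows) + "\n"
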