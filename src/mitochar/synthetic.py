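"""Synthetic annotated mitogenomes with planted, recorded ground truth.

The generator emits a ~15.3-kb circular genome with the full complement
of 13 protein-coding genes, 22 tRNAs, 2 rRNAs and one A+T-rich region,
arranged per a chosen gene-order template (derived lepidopteran or
ancestral insect). Protein-coding genes begin with a canonical start
(ATN; CGA for cox1), end with a complete TAA or an incomplete T/TA
depending on their length modulo 3, and draw internal codons from a
configurable codon-weight profile. tRNA/rRNA bodies and intergenic
filler are drawn from per-class base frequencies; the control region is
AT-biased filler carrying a planted "ATAGA + poly-T" motif and one
planted tandem-repeat array, and is sanitized so no *other* motif or
qualifying repeat array occurs in it.

Everything the downstream statistics can measure is recorded in
:class:`GroundTruth` as *realized* values tallied from the emitted
sequence, so recovery tests are exact equalities rather than
statistical checks.

Defaults mirror the genome organization of the published hawk-moth
genome used as this package's structural reference: gene lengths,
anticodons and codon weights default to its published values, base
frequencies per class to its published composition, so synthetic
genomes are realistic in size (~15.2 kb), strandedness and bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference_data as ref
from .codon_usage import ALL_CODONS_RNA, count_codons, rna_to_dna
from .control_region import (DEFAULT_MIN_COPIES, DEFAULT_MIN_PERIOD,
                             DEFAULT_MIN_POLYT, DEFAULT_MIN_SPAN,
                             DEFAULT_WINDOW, find_ataga_polyt,
                             find_tandem_repeats)
from .gene_order import (ANCESTRAL_INSECT_ORDER, LEPIDOPTERAN_ORDER,
                         GeneOrder)
from .genome_io import (AnnotatedGenome, CONTROL_NAME, FeatureRecord,
                        reverse_complement, write_feature_tsv, write_genbank)

__all__ = ["SyntheticSpec", "GroundTruth", "generate_genome", "write_fixture"]

_BASES = np.array(list("ATGC"))

# Published per-gene sizes and tRNA anticodons of the reference hawk-moth
# genome; used as structural defaults.
_DEFAULT_LENGTHS = {row[0]: row[4] - row[3] + 1 for row in ref.A_RUBIGINOSA_FEATURES}
_DEFAULT_ANTICODONS = {row[0]: row[5] for row in ref.A_RUBIGINOSA_FEATURES
                       if row[1] == "tRNA"}

# Published per-class base frequencies (A, T, G, C fractions).
def _freqs(comp_row: tuple) -> tuple[float, float, float, float]:
    _size, a, t, g, c = comp_row[:5]
    tot = a + t + g + c
    return (a / tot, t / tot, g / tot, c / tot)


_DEFAULT_CLASS_FREQS = {
    "tRNA": _freqs(ref.A_RUBIGINOSA_COMPOSITION["tRNAs"]),
    "rRNA": _freqs(ref.A_RUBIGINOSA_COMPOSITION["rRNAs"]),
    "control": _freqs(ref.A_RUBIGINOSA_COMPOSITION["AT_rich_region"]),
    "spacer": _freqs(ref.A_RUBIGINOSA_COMPOSITION["whole_genome"]),
}

_TEMPLATES = {"lepidopteran": LEPIDOPTERAN_ORDER,
              "ancestral_insect": ANCESTRAL_INSECT_ORDER}

_STOPS_RNA = ("UAA", "UAG")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome; deterministic given ``seed``."""

    seed: int = 0
    gene_order_template: str | GeneOrder = "lepidopteran"
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_LENGTHS))
    #: RNA-spelled codon weights for PCG internal positions (stops ignored);
    #: defaults to the reference genome's pooled codon counts.
    pcg_codon_weights: dict[str, float] = field(
        default_factory=lambda: dict(ref.A_RUBIGINOSA_CODON_COUNTS))
    class_base_frequencies: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_FREQS))
    #: spacer (nt) after each gene; overlaps are negative values here
    spacers: dict[str, int] = field(default_factory=dict)
    # control-region elements
    motif_offset: int = 40        # 0-based offset of ATAGA within the region
    polyt_length: int = 8
    tandem_unit: str = "TTATAATATTAATTATATAATAA"   # 23 nt, aperiodic, AT-only
    tandem_copies: float = 3.5
    tandem_offset: int = 120      # 0-based offset of the array within the region

    def resolve_template(self) -> GeneOrder:
        if isinstance(self.gene_order_template, GeneOrder):
            return self.gene_order_template
        try:
            return _TEMPLATES[self.gene_order_template]
        except KeyError:
            raise ValueError(
                f"unknown template {self.gene_order_template!r}; "
                f"expected one of {sorted(_TEMPLATES)}") from None

    def validate(self) -> None:
        for name, length in self.gene_lengths.items():
            klass = _klass_of(name)
            if klass == "PCG" and length < 6:
                raise ValueError(f"PCG {name!r} length {length} < 6")
            if length < 1:
                raise ValueError(f"gene {name!r} length {length} < 1")
        cr_len = self.gene_lengths.get(CONTROL_NAME, 0)
        motif_end = self.motif_offset + 5 + self.polyt_length
        tr_span = int(round(len(self.tandem_unit) * self.tandem_copies))
        if self.tandem_copies < 2:
            raise ValueError("tandem_copies must be >= 2")
        if motif_end > self.tandem_offset or self.tandem_offset + tr_span + 1 >= cr_len:
            raise ValueError(
                "control-region elements do not fit: need motif "
                f"[{self.motif_offset},{motif_end}) before the repeat array "
                f"[{self.tandem_offset},{self.tandem_offset + tr_span}) inside {cr_len} nt")
        order = self.resolve_template()
        for name, _sign in order.labels:
            if name not in self.gene_lengths:
                raise ValueError(f"no length given for {name!r}")
        for (name, sign), (nxt, _s2) in zip(order.labels, order.labels[1:]):
            ov = -min(self.spacers.get(name, 0), 0)
            if ov >= self.gene_lengths[name] or ov >= self.gene_lengths[nxt]:
                raise ValueError(
                    f"overlap {ov} between {name!r} and {nxt!r} exceeds a gene length")


def _klass_of(name: str) -> str:
    from .genome_io import PCG_NAMES, RRNA_NAMES, TRNA_NAMES
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == CONTROL_NAME:
        return "control"
    return "other"


@dataclass
class GroundTruth:
    """Realized (post-assembly) values for every downstream statistic."""

    gene_order: GeneOrder
    base_counts_by_class: dict[str, tuple[int, int, int, int]]
    codon_counts: dict[str, int]
    start_codons: dict[str, str]
    stop_codons: dict[str, str]
    control_span: tuple[int, int]
    motif_position: int          # 1-based within the region
    motif_polyt_length: int
    tandem_repeat: dict          # unit, period, copies, start, end (region coords)


def _random_bases(rng: np.random.Generator, n: int,
                  freqs: tuple[float, float, float, float]) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(_BASES, size=n, p=np.asarray(freqs) / sum(freqs)))


def _sample_codons(rng: np.random.Generator, n: int,
                   weights: dict[str, float]) -> list[str]:
    codons = [c for c in ALL_CODONS_RNA if c not in _STOPS_RNA and weights.get(c, 0) > 0]
    w = np.array([weights[c] for c in codons], dtype=float)
    picks = rng.choice(len(codons), size=n, p=w / w.sum())
    return [rna_to_dna(codons[i]) for i in picks]


def _pcg_sequence(rng: np.random.Generator, name: str, length: int,
                  weights: dict[str, float]) -> str:
    stop_len = length % 3 or 3
    stop = {3: "TAA", 1: "T", 2: "TA"}[stop_len]
    start = "CGA" if name == "cox1" else rng.choice(["ATA", "ATT", "ATC", "ATG"])
    n_internal = (length - 3 - stop_len) // 3
    body = "".join(_sample_codons(rng, n_internal, weights))
    return start + body + stop


def _control_sequence(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[str, dict]:
    length = spec.gene_lengths[CONTROL_NAME]
    freqs = spec.class_base_frequencies["control"]
    seq = list(_random_bases(rng, length, freqs))
    # plant the ATAGA + poly-T motif
    motif = "ATAGA" + "T" * spec.polyt_length
    seq[spec.motif_offset:spec.motif_offset + len(motif)] = motif
    after = spec.motif_offset + len(motif)
    if after < length and seq[after] == "T":
        seq[after] = "A"          # keep the planted poly-T run maximal at its length
    # plant the tandem array
    p = len(spec.tandem_unit)
    span = int(round(p * spec.tandem_copies))
    t0 = spec.tandem_offset
    arr = (spec.tandem_unit * (span // p + 1))[:span]
    seq[t0:t0 + span] = arr
    # stop the array from extending into the flanks
    if t0 > 0 and seq[t0 - 1] == seq[t0 - 1 + p]:
        seq[t0 - 1] = "C"
    if t0 + span < length and seq[t0 + span] == seq[t0 + span - p]:
        seq[t0 + span] = "C"
    planted = {"unit": spec.tandem_unit, "period": p,
               "copies": round(span / p, 2), "start": t0 + 1, "end": t0 + span}
    _sanitize_control(seq, spec, planted)
    truth = {"motif_position": spec.motif_offset + 1,
             "motif_polyt_length": spec.polyt_length, "tandem": planted}
    return "".join(seq), truth


def _sanitize_control(seq: list[str], spec: SyntheticSpec, planted: dict) -> None:
    """Break accidental motifs/arrays so only the planted ones qualify."""
    # 0-based positions that must never be mutated: the planted motif with
    # its poly-T run and trailing guard, and the planted array with guards
    protected = set(range(spec.motif_offset,
                          spec.motif_offset + 5 + spec.polyt_length + 1))
    protected |= set(range(planted["start"] - 2, planted["end"] + 1))
    for _ in range(60):
        s = "".join(seq)
        dirty = False
        stuck = False
        for hit in find_ataga_polyt(s, DEFAULT_MIN_POLYT, DEFAULT_WINDOW):
            if hit.position != spec.motif_offset + 1:
                seq[hit.position + 2] = "C"   # the G of the stray ATAGA
                dirty = True
        for rep in find_tandem_repeats(s, DEFAULT_MIN_PERIOD, 200,
                                       DEFAULT_MIN_COPIES, DEFAULT_MIN_SPAN):
            if (rep.start, rep.end) == (planted["start"], planted["end"]):
                continue
            if planted["start"] <= rep.start and rep.end <= planted["end"]:
                continue          # contained in the planted array: suppressed anyway
            # mutate a position of the stray array; a leading-unit position
            # works too (it breaks the match one period downstream), as
            # long as that pairing stays within the array
            for pos in range(rep.start - 1, rep.end):
                breaks_match = (pos >= rep.start - 1 + rep.period
                                or pos + rep.period < rep.end)
                if breaks_match and pos not in protected:
                    seq[pos] = "C" if seq[pos] != "C" else "G"
                    dirty = True
                    break
            else:
                stuck = True
        if stuck:
            break
        if not dirty:
            return
    raise RuntimeError("control-region sanitization did not converge")


def generate_genome(spec: SyntheticSpec) -> tuple[AnnotatedGenome, GroundTruth]:
    """Assemble a genome and its realized ground truth; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    template = spec.resolve_template()
    # start coordinates at the gene following the control region, so the
    # control region sits at the end of the molecule as in real genomes
    rotated = template.rotated_to_anchor()
    ordered = rotated.labels[1:] + rotated.labels[:1]

    pieces: list[tuple[str, int, str]] = []   # (name, sign, sense-strand seq)
    cr_truth: dict = {}
    for name, sign in ordered:
        klass = _klass_of(name)
        length = spec.gene_lengths[name]
        if klass == "PCG":
            s = _pcg_sequence(rng, name, length, spec.pcg_codon_weights)
        elif klass == "control":
            s, cr_truth = _control_sequence(rng, spec)
        else:
            s = _random_bases(rng, length, spec.class_base_frequencies.get(
                klass, _DEFAULT_CLASS_FREQS["spacer"]))
        pieces.append((name, sign, s))

    # place features, honouring per-gene spacers (negative = overlap)
    placements: list[tuple[str, int, int, int]] = []  # name, sign, start, end
    pos = 1
    for name, sign, s in pieces:
        start, end = pos, pos + len(s) - 1
        placements.append((name, sign, start, end))
        pos = end + 1 + spec.spacers.get(name, 0)
    genome_len = placements[-1][3]  # control region is last; no trailing spacer

    buf = ["A"] * genome_len
    # spacer filler first, then feature sequences (later writes win overlaps)
    cursor = 1
    for (_name, _sign, start, end) in placements:
        if start > cursor:
            filler = _random_bases(rng, start - cursor,
                                   spec.class_base_frequencies.get(
                                       "spacer", _DEFAULT_CLASS_FREQS["spacer"]))
            buf[cursor - 1:start - 1] = filler
        cursor = max(cursor, end + 1)
    for (name, sign, start, end), (_n, _s, s) in zip(placements, pieces):
        strand_seq = s if sign > 0 else reverse_complement(s)
        buf[start - 1:end] = strand_seq

    features = []
    for name, sign, start, end in placements:
        klass = _klass_of(name)
        features.append(FeatureRecord(
            name, klass, "F" if sign > 0 else "R", start, end,
            anticodon=_DEFAULT_ANTICODONS.get(name) if klass == "tRNA" else None))
    genome = AnnotatedGenome(f"synthetic_seed{spec.seed}", "".join(buf), features)

    truth = _realize_truth(genome, spec, cr_truth)
    return genome, truth


def _realize_truth(genome: AnnotatedGenome, spec: SyntheticSpec,
                   cr_truth: dict) -> GroundTruth:
    from .composition import base_counts
    from .genome_io import extract_feature_sequence

    by_class: dict[str, list[str]] = {"PCGs": [], "tRNAs": [], "rRNAs": [],
                                      "AT_rich_region": []}
    klass_map = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs",
                 "control": "AT_rich_region"}
    starts: dict[str, str] = {}
    stops: dict[str, str] = {}
    cds_list: list[str] = []
    cr_span = (0, 0)
    for f in genome.features:
        s = extract_feature_sequence(genome, f)
        by_class[klass_map[f.klass]].append(s)
        if f.klass == "PCG":
            cds_list.append(s)
            starts[f.name] = s[:3]
            rem = len(s) % 3
            stops[f.name] = s[-3:] if rem == 0 else s[-rem:]
        if f.klass == "control":
            cr_span = (f.start, f.end)
    counts = {}
    for region, seqs in by_class.items():
        a, t, g, c, _n = base_counts("".join(seqs))
        counts[region] = (a, t, g, c)
    a, t, g, c, _n = base_counts(genome.sequence)
    counts["whole_genome"] = (a, t, g, c)
    order = GeneOrder(tuple((f.name, -1 if f.strand == "R" else 1)
                            for f in genome.features))
    return GroundTruth(
        gene_order=order,
        base_counts_by_class=counts,
        codon_counts=count_codons(cds_list),
        start_codons=starts,
        stop_codons=stops,
        control_span=cr_span,
        motif_position=cr_truth.get("motif_position", 0),
        motif_polyt_length=cr_truth.get("motif_polyt_length", 0),
        tandem_repeat=cr_truth.get("tandem", {}),
    )


def write_fixture(genome: AnnotatedGenome, truth: GroundTruth,
                  directory: str | Path) -> dict[str, Path]:
    """Emit GenBank, feature TSV and ground-truth TSV; returns the paths."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        base = directory / genome.identifier
        gb = base.with_suffix(".gb")
        gb.write_text(write_genbank(genome))
        tsv = base.with_suffix(".features.tsv")
        tsv.write_text(write_feature_tsv(genome))
        fa = base.with_suffix(".fasta")
        fa.write_text(f">{genome.identifier}\n{genome.sequence}\n")
        truth_path = base.with_suffix(".truth.tsv")
        rows = ["section\tkey\tvalue"]
        rows.append("gene_order\torder\t" + str(truth.gene_order))
        for region, (a, t, g, c) in truth.base_counts_by_class.items():
            rows.append(f"base_counts\t{region}\t{json.dumps([a, t, g, c])}")
        rows.append("codon_counts\tpooled\t" + json.dumps(truth.codon_counts))
        for gene, codon in truth.start_codons.items():
            rows.append(f"start_codon\t{gene}\t{codon}")
        for gene, codon in truth.stop_codons.items():
            rows.append(f"stop_codon\t{gene}\t{codon}")
        rows.append("control\tspan\t" + json.dumps(list(truth.control_span)))
        rows.append(f"control\tmotif_position\t{truth.motif_position}")
        rows.append(f"control\tmotif_polyt_length\t{truth.motif_polyt_length}")
        rows.append("control\ttandem_repeat\t" + json.dumps(truth.tandem_repeat))
        truth_path.write_text("\n".join(rows) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write fixture under {directory}: {exc}") from exc
    return {"genbank": gb, "features": tsv, "fasta": fa, "truth": truth_path}
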