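"""Codon counting, RSCU and amino-acid composition under the invertebrate
mitochondrial genetic code (NCBI transl_table 5).

Relative synonymous codon usage of codon *i* in a synonymous family of
size *k* with family total *n* is

    RSCU_i = count_i * k / n

i.e. the observed count divided by the family mean; uniform usage gives
RSCU 1 for every member. Under transl_table 5 the families differ from
the standard code: AGA/AGG encode Ser (an 8-codon Ser family), AUA
encodes Met, UGA encodes Trp, and the stops are exactly UAA/UAG, which
are treated here as their own 2-codon family. Computation uses the DNA
alphabet internally; reported codons use RNA (U) spelling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "INVERTEBRATE_MITO",
    "ALL_CODONS_RNA",
    "count_codons",
    "rscu",
    "aa_composition",
    "build_usage_table",
    "write_usage_tsv",
    "write_aa_composition_tsv",
]

ALL_CODONS_DNA = tuple("".join(p) for p in product("TCAG", repeat=3))
ALL_CODONS_RNA = tuple(c.replace("T", "U") for c in ALL_CODONS_DNA)


def dna_to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def rna_to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A codon→amino-acid mapping with its synonymous-family partition."""

    table_id: int
    codon_to_aa: dict[str, str]  # RNA codons; stop = "*"
    families: dict[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS_RNA:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(self, "families",
                           {aa: tuple(cs) for aa, cs in fams.items()})

    def translate(self, codon: str) -> str:
        """Amino acid (one-letter, stop='*') for a codon in RNA or DNA spelling."""
        return self.codon_to_aa[dna_to_rna(codon)]

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.translate(codon)]


def _code_from_ncbi(table_id: int) -> GeneticCode:
    table = CodonTable.unambiguous_rna_by_id[table_id]
    mapping = {codon: table.forward_table.get(codon, "*") for codon in ALL_CODONS_RNA}
    return GeneticCode(table_id, mapping)


#: transl_table 5, built from the NCBI tables shipped with Biopython.
INVERTEBRATE_MITO = _code_from_ncbi(5)


def count_codons(cds_list: list[str] | tuple[str, ...]) -> dict[str, int]:
    """Pooled codon counts over sense-strand CDSs, RNA-spelled keys.

    Each CDS is read as non-overlapping triplets from position 1; a
    trailing 1–2 nt (an incomplete stop codon) is discarded. Complete
    stop codons are counted like any other codon.
    """
    tally: Counter[str] = Counter()
    for cds in cds_list:
        cds = cds.upper()
        for i in range(0, len(cds) - len(cds) % 3, 3):
            tally[dna_to_rna(cds[i:i + 3])] += 1
    return {codon: tally.get(codon, 0) for codon in ALL_CODONS_RNA}


def rscu(counts: dict[str, int], code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
    """RSCU per codon: count × family size / family total; 0 for every
    member of an unused family."""
    out: dict[str, float] = {}
    for members in code.families.values():
        total = sum(counts.get(c, 0) for c in members)
        k = len(members)
        for c in members:
            out[c] = counts.get(c, 0) * k / total if total else 0.0
    return {codon: out[codon] for codon in ALL_CODONS_RNA}


def aa_composition(counts: dict[str, int], code: GeneticCode = INVERTEBRATE_MITO,
                   split_families: bool = False) -> dict[str, int]:
    """Amino-acid totals from codon counts; stops are excluded.

    With ``split_families`` the two Leu and two Ser codon families are
    reported separately as ``L(UUR)``/``L(CUN)`` and ``S(AGN)``/``S(UCN)``,
    the usual convention for mitochondrial proteomes with separate
    isoacceptor tRNAs.
    """
    split = {
        "UUA": "L(UUR)", "UUG": "L(UUR)",
        "CUU": "L(CUN)", "CUC": "L(CUN)", "CUA": "L(CUN)", "CUG": "L(CUN)",
        "AGU": "S(AGN)", "AGC": "S(AGN)", "AGA": "S(AGN)", "AGG": "S(AGN)",
        "UCU": "S(UCN)", "UCC": "S(UCN)", "UCA": "S(UCN)", "UCG": "S(UCN)",
    }
    out: dict[str, int] = {}
    for codon, n in counts.items():
        aa = code.translate(codon)
        if aa == "*":
            continue
        if split_families and codon in split:
            aa = split[codon]
        out[aa] = out.get(aa, 0) + n
    return out


@dataclass(frozen=True)
class CodonUsageTable:
    counts: dict[str, int]
    rscu: dict[str, float]
    aa_counts: dict[str, int]
    total_codons: int
    code: GeneticCode = INVERTEBRATE_MITO


def build_usage_table(cds_list: list[str] | tuple[str, ...],
                      code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    counts = count_codons(cds_list)
    return CodonUsageTable(
        counts=counts,
        rscu=rscu(counts, code),
        aa_counts=aa_composition(counts, code),
        total_codons=sum(counts.values()),
        code=code,
    )


def write_usage_tsv(table: CodonUsageTable, raw: bool = False) -> str:
    """codon / amino_acid / count / rscu table, RSCU to 2 decimals unless raw."""
    rows = [{"codon": c, "amino_acid": table.code.translate(c),
             "count": table.counts[c],
             "rscu": table.rscu[c] if raw else round(table.rscu[c], 2)}
            for c in ALL_CODONS_RNA]
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def write_aa_composition_tsv(counts: dict[str, int],
                             code: GeneticCode = INVERTEBRATE_MITO) -> str:
    comp = aa_composition(counts, code, split_families=True)
    rows = [{"amino_acid": aa, "count": n}
            for aa, n in sorted(comp.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)
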