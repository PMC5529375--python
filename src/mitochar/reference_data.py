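"""Published reference values for the two Bombycoidea mitogenomes.

Annotation coordinates, per-class composition counts and pooled codon
counts for the hawk moth *Ampelophaga rubiginosa* (GenBank KT153024,
15,282 bp) and the mulberry white caterpillar moth *Rondotia menciana*
(GenBank KT258908, 15,636 bp), as published with those genomes. They
serve as desk-scale inputs: the package's statistics recomputed from
these counts and coordinates must reproduce the published derived values
(sizes, spacers, skews, RSCU) without any sequence download.

Each annotation row is
``(name, klass, strand, start, end, anticodon, start_codon, stop_codon)``
with 1-based inclusive coordinates; ``None`` marks columns that do not
apply to the feature class.
"""

from __future__ import annotations

from .genome_io import AnnotatedGenome, FeatureRecord

__all__ = [
    "A_RUBIGINOSA_LENGTH", "R_MENCIANA_LENGTH",
    "A_RUBIGINOSA_FEATURES", "R_MENCIANA_FEATURES",
    "A_RUBIGINOSA_COMPOSITION", "R_MENCIANA_COMPOSITION",
    "A_RUBIGINOSA_CODON_COUNTS", "R_MENCIANA_CODON_COUNTS",
    "A_RUBIGINOSA_RSCU", "R_MENCIANA_RSCU",
    "reference_feature_records", "reference_genome",
]

A_RUBIGINOSA_LENGTH = 15282
R_MENCIANA_LENGTH = 15636

# name, klass, strand, start, end, anticodon, start_codon, stop_codon
A_RUBIGINOSA_FEATURES = (
    ("trnM", "tRNA", "F", 1, 68, "CAT", None, None),
    ("trnI", "tRNA", "F", 69, 132, "GAT", None, None),
    ("trnQ", "tRNA", "R", 130, 198, "TTG", None, None),
    ("nad2", "PCG", "F", 255, 1266, None, "ATT", "T"),
    ("trnW", "tRNA", "F", 1267, 1334, "TCA", None, None),
    ("trnC", "tRNA", "R", 1327, 1391, "GCA", None, None),
    ("trnY", "tRNA", "R", 1392, 1456, "GTA", None, None),
    ("cox1", "PCG", "F", 1463, 2990, None, "CGA", "T"),
    ("trnL2", "tRNA", "F", 2991, 3058, "TAA", None, None),
    ("cox2", "PCG", "F", 3059, 3740, None, "ATG", "T"),
    ("trnK", "tRNA", "F", 3741, 3811, "CTT", None, None),
    ("trnD", "tRNA", "F", 3814, 3881, "GTC", None, None),
    ("atp8", "PCG", "F", 3882, 4043, None, "ATT", "TAA"),
    ("atp6", "PCG", "F", 4037, 4714, None, "ATG", "TAA"),
    ("cox3", "PCG", "F", 4715, 5506, None, "ATG", "TAA"),
    ("trnG", "tRNA", "F", 5509, 5574, "TCC", None, None),
    ("nad3", "PCG", "F", 5575, 5926, None, "ATT", "T"),
    ("trnA", "tRNA", "F", 5927, 5993, "TGC", None, None),
    ("trnR", "tRNA", "F", 5995, 6058, "TCG", None, None),
    ("trnN", "tRNA", "F", 6059, 6124, "GTT", None, None),
    ("trnS1", "tRNA", "F", 6125, 6186, "GCT", None, None),
    ("trnE", "tRNA", "F", 6196, 6263, "TTC", None, None),
    ("trnF", "tRNA", "R", 6262, 6327, "GAA", None, None),
    ("nad5", "PCG", "R", 6355, 8076, None, "ATT", "A"),
    ("trnH", "tRNA", "R", 8092, 8155, "GTG", None, None),
    ("nad4", "PCG", "R", 8156, 9490, None, "ATG", "TAA"),
    ("nad4L", "PCG", "R", 9491, 9781, None, "ATG", "TAA"),
    ("trnT", "tRNA", "F", 9786, 9851, "TGT", None, None),
    ("trnP", "tRNA", "R", 9851, 9916, "TGG", None, None),
    ("nad6", "PCG", "F", 9923, 10453, None, "ATG", "TAA"),
    ("cob", "PCG", "F", 10460, 11608, None, "ATG", "TAA"),
    ("trnS2", "tRNA", "F", 11608, 11672, "TGA", None, None),
    ("nad1", "PCG", "R", 11694, 12629, None, "ATG", "TAA"),
    ("trnL1", "tRNA", "R", 12630, 12696, "TAG", None, None),
    ("rrnL", "rRNA", "R", 12697, 14040, None, None, None),
    ("trnV", "tRNA", "R", 14041, 14108, "TAC", None, None),
    ("rrnS", "rRNA", "R", 14109, 14883, None, None, None),
    ("AT_rich_region", "control", "F", 14884, 15282, None, None, None),
)

R_MENCIANA_FEATURES = (
    ("trnM", "tRNA", "F", 1, 68, "CAT", None, None),
    ("trnI", "tRNA", "F", 69, 132, "GAT", None, None),
    ("trnQ", "tRNA", "R", 130, 198, "TTG", None, None),
    ("nad2", "PCG", "F", 251, 1264, None, "ATT", "TAA"),
    ("trnW", "tRNA", "F", 1272, 1338, "TCA", None, None),
    ("trnC", "tRNA", "R", 1331, 1394, "GCA", None, None),
    ("trnY", "tRNA", "R", 1395, 1459, "GTA", None, None),
    ("cox1", "PCG", "F", 1469, 2999, None, "CGA", "T"),
    ("trnL2", "tRNA", "F", 3000, 3066, "TAA", None, None),
    ("cox2", "PCG", "F", 3067, 3748, None, "ATG", "T"),
    ("trnK", "tRNA", "F", 3749, 3819, "CTT", None, None),
    ("trnD", "tRNA", "F", 3819, 3884, "GTC", None, None),
    ("atp8", "PCG", "F", 3885, 4046, None, "ATC", "TAA"),
    ("atp6", "PCG", "F", 4040, 4717, None, "ATG", "TAA"),
    ("cox3", "PCG", "F", 4721, 5509, None, "ATG", "TAA"),
    ("trnG", "tRNA", "F", 5512, 5577, "TCC", None, None),
    ("nad3", "PCG", "F", 5575, 5931, None, "ATA", "TAA"),
    ("trnA", "tRNA", "F", 5959, 6032, "TGC", None, None),
    ("trnR", "tRNA", "F", 6043, 6105, "TCG", None, None),
    ("trnN", "tRNA", "F", 6106, 6173, "GTT", None, None),
    ("trnS1", "tRNA", "F", 6180, 6248, "GCT", None, None),
    ("trnE", "tRNA", "F", 6250, 6314, "TTC", None, None),
    ("trnF", "tRNA", "R", 6318, 6385, "GAA", None, None),
    ("nad5", "PCG", "R", 6386, 8124, None, "ATT", "TA"),
    ("trnH", "tRNA", "R", 8125, 8190, "GTG", None, None),
    ("nad4", "PCG", "R", 8201, 9541, None, "ATG", "TAA"),
    ("nad4L", "PCG", "R", 9547, 9837, None, "ATG", "TAA"),
    ("trnT", "tRNA", "F", 9840, 9904, "TGT", None, None),
    ("trnP", "tRNA", "R", 9905, 9970, "TGG", None, None),
    ("nad6", "PCG", "F", 9973, 10503, None, "ATG", "TAA"),
    ("cob", "PCG", "F", 10511, 11665, None, "ATG", "TAA"),
    ("trnS2", "tRNA", "F", 11676, 11727, "TGA", None, None),
    ("nad1", "PCG", "R", 11761, 12699, None, "ATG", "TAA"),
    ("trnL1", "tRNA", "R", 12701, 12770, "TAG", None, None),
    ("rrnL", "rRNA", "R", 12771, 14186, None, None, None),
    ("trnV", "tRNA", "R", 14187, 14252, "TAC", None, None),
    ("rrnS", "rRNA", "R", 14253, 15032, None, None, None),
    ("AT_rich_region", "control", "F", 15033, 15636, None, None, None),
)

# Published per-region composition: region -> (size, A, T, G, C,
#   A%, T%, G%, C%, AT%, AT skew, GC skew), percentages as printed.
A_RUBIGINOSA_COMPOSITION = {
    "whole_genome":   (15282, 6334, 6126, 1144, 1678, 41.4, 40.1, 7.5, 11.0, 81.5, 0.017, -0.189),
    "PCGs":           (11175, 3894, 5090, 1135, 1056, 34.8, 45.5, 10.2, 9.5, 80.3, -0.133, 0.038),
    "tRNAs":          (1461, 602, 589, 116, 154, 41.2, 40.3, 7.9, 10.6, 81.5, 0.011, -0.141),
    "rRNAs":          (2119, 906, 887, 104, 222, 42.8, 41.9, 4.9, 10.4, 84.7, 0.011, -0.362),
    "AT_rich_region": (399, 174, 194, 14, 17, 43.6, 48.6, 3.5, 4.3, 92.2, -0.054, -0.097),
}

R_MENCIANA_COMPOSITION = {
    "whole_genome":   (15636, 6561, 6290, 1122, 1663, 42.0, 40.2, 7.2, 10.6, 82.2, 0.021, -0.194),
    "PCGs":           (11205, 3934, 5107, 1114, 1050, 35.1, 45.6, 9.9, 9.4, 80.7, -0.130, 0.030),
    "tRNAs":          (1460, 606, 588, 115, 151, 41.5, 40.3, 7.9, 10.3, 81.8, 0.015, -0.135),
    "rRNAs":          (2196, 959, 927, 100, 210, 43.7, 42.2, 4.5, 9.6, 85.9, 0.017, -0.355),
    "AT_rich_region": (604, 281, 287, 18, 18, 46.5, 47.5, 3.0, 3.0, 94.0, -0.011, 0.0),
}

# Pooled codon counts over the 13 PCGs (RNA alphabet) and the published
# RSCU values they yield under the invertebrate mitochondrial code.
_AR_TABLE5 = """
UUU F 347 1.88   UCU S 91 2.35    UAU Y 184 1.86  UGU C 31 1.82
UUC F 23 0.12    UCC S 1 0.03     UAC Y 14 0.14   UGC C 3 0.18
UUA L 482 5.32   UCA S 103 2.66   UAA * 10 2      UGA W 91 1.94
UUG L 14 0.15    UCG S 0 0        UAG * 0 0       UGG W 3 0.06
CUU L 26 0.29    CCU P 63 1.98    CAU H 57 1.73   CGU R 13 1
CUC L 2 0.02     CCC P 12 0.38    CAC H 9 0.27    CGC R 0 0
CUA L 20 0.22    CCA P 52 1.64    CAA Q 63 2      CGA R 37 2.85
CUG L 0 0        CCG P 0 0        CAG Q 0 0       CGG R 2 0.15
AUU I 452 1.91   ACU T 83 2.26    AAU N 239 1.85  AGU S 22 0.57
AUC I 22 0.09    ACC T 6 0.16     AAC N 19 0.15   AGC S 0 0
AUA M 276 1.86   ACA T 56 1.52    AAA K 102 1.92  AGA S 92 2.37
AUG M 21 0.14    ACG T 2 0.05     AAG K 4 0.08    AGG S 1 0.03
GUU V 74 2.26    GCU A 75 2.59    GAU D 58 1.9    GGU G 62 1.29
GUC V 1 0.03     GCC A 0 0        GAC D 3 0.1     GGC G 0 0
GUA V 55 1.68    GCA A 40 1.38    GAA E 70 1.87   GGA G 111 2.31
GUG V 1 0.03     GCG A 1 0.03     GAG E 5 0.13    GGG G 19 0.4
"""

_RM_TABLE5 = """
UUU F 369 1.9    UCU S 94 2.39    UAU Y 178 1.87  UGU C 29 1.81
UUC F 20 0.1     UCC S 10 0.25    UAC Y 12 0.13   UGC C 3 0.19
UUA L 478 5.32   UCA S 97 2.47    UAA * 11 2      UGA W 90 1.94
UUG L 14 0.16    UCG S 0 0        UAG * 0 0       UGG W 3 0.06
CUU L 24 0.27    CCU P 60 1.98    CAU H 57 1.73   CGU R 14 1.06
CUC L 3 0.03     CCC P 10 0.33    CAC H 9 0.27    CGC R 0 0
CUA L 19 0.21    CCA P 48 1.59    CAA Q 60 2      CGA R 38 2.87
CUG L 1 0.01     CCG P 3 0.1      CAG Q 0 0       CGG R 1 0.08
AUU I 452 1.9    ACU T 67 1.91    AAU N 246 1.82  AGU S 30 0.76
AUC I 25 0.1     ACC T 6 0.17     AAC N 24 0.18   AGC S 1 0.03
AUA M 285 1.89   ACA T 67 1.91    AAA K 107 1.88  AGA S 82 2.09
AUG M 17 0.11    ACG T 0 0        AAG K 7 0.12    AGG S 0 0
GUU V 66 2.08    GCU A 65 2.39    GAU D 62 1.88   GGU G 52 1.09
GUC V 1 0.03     GCC A 3 0.11     GAC D 4 0.12    GGC G 1 0.02
GUA V 56 1.76    GCA A 39 1.43    GAA E 66 1.83   GGA G 126 2.65
GUG V 4 0.13     GCG A 2 0.07     GAG E 6 0.17    GGG G 11 0.23
"""


def _parse_table5(block: str) -> tuple[dict[str, int], dict[str, float]]:
    counts: dict[str, int] = {}
    rscu: dict[str, float] = {}
    toks = block.split()
    for i in range(0, len(toks), 4):
        codon, _aa, count, value = toks[i], toks[i + 1], toks[i + 2], toks[i + 3]
        counts[codon] = int(count)
        rscu[codon] = float(value)
    assert len(counts) == 64
    return counts, rscu


A_RUBIGINOSA_CODON_COUNTS, A_RUBIGINOSA_RSCU = _parse_table5(_AR_TABLE5)
R_MENCIANA_CODON_COUNTS, R_MENCIANA_RSCU = _parse_table5(_RM_TABLE5)


def reference_feature_records(species: str) -> list[FeatureRecord]:
    """The published annotation of one reference genome as FeatureRecords.

    ``species`` is ``"A_rubiginosa"`` or ``"R_menciana"``.
    """
    rows = {"A_rubiginosa": A_RUBIGINOSA_FEATURES,
            "R_menciana": R_MENCIANA_FEATURES}[species]
    return [FeatureRecord(name, klass, strand, start, end, anticodon)
            for name, klass, strand, start, end, anticodon, _s, _e in rows]


def reference_genome(species: str) -> AnnotatedGenome:
    """The published annotation over a neutral placeholder sequence.

    The deposited nucleotide sequences are not bundled; the placeholder
    (all ``N``) supports every coordinate-arithmetic computation (sizes,
    spacers, gene order, control-region location) but not base counting.
    """
    n = {"A_rubiginosa": A_RUBIGINOSA_LENGTH,
         "R_menciana": R_MENCIANA_LENGTH}[species]
    return AnnotatedGenome(species, "N" * n, reference_feature_records(species))
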