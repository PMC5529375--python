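"""Circular signed gene orders and rearrangement comparison.

A gene order is a circular sequence of signed canonical labels: ``+``
for the majority strand, ``-`` for the minority strand. Rotation is
immaterial (the adjacency set of consecutive ordered pairs, including
the closing pair, is rotation-invariant), and the breakpoint distance
between two orders over the same labels is the number of adjacencies of
one that the other lacks. Signs participate in adjacency identity, so
inversions register as breakpoints.

Two reference arrangements are built in: the ancestral insect order,
with the tRNA cluster ``trnI, -trnQ, trnM`` between the control region
and ``nad2``, and the derived lepidopteran order in which ``trnM`` has
moved ahead of ``trnI`` (``trnM, trnI, -trnQ, nad2``) — the hallmark
rearrangement of ditrysian Lepidoptera.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import AnnotatedGenome, CONTROL_NAME

__all__ = [
    "SignedLabel",
    "GeneOrder",
    "LEPIDOPTERAN_ORDER",
    "ANCESTRAL_INSECT_ORDER",
    "extract_gene_order",
    "adjacency_set",
    "breakpoint_distance",
    "detect_translocated_genes",
    "write_gene_order_tsv",
]

SignedLabel = tuple[str, int]  # (canonical label, +1 or -1)


def _parse_token(tok: str) -> SignedLabel:
    tok = tok.strip()
    if tok.startswith("-"):
        return tok[1:], -1
    return tok.lstrip("+"), +1


def _format_token(lab: SignedLabel) -> str:
    name, sign = lab
    return name if sign > 0 else f"-{name}"


@dataclass(frozen=True)
class GeneOrder:
    """A circular sequence of signed gene labels, normalized by rotation."""

    labels: tuple[SignedLabel, ...]
    anchor: str = CONTROL_NAME

    @classmethod
    def from_tokens(cls, tokens: list[str] | tuple[str, ...],
                    anchor: str = CONTROL_NAME) -> "GeneOrder":
        return cls(tuple(_parse_token(t) for t in tokens), anchor)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.labels]
        dups = sorted({n for n in names if names.count(n) > 1})
        if dups:
            raise ValueError(f"duplicate gene labels in order: {dups}")

    @property
    def names(self) -> frozenset[str]:
        return frozenset(name for name, _ in self.labels)

    def rotated_to_anchor(self) -> "GeneOrder":
        """Rotate so the anchor label (any sign) comes first."""
        for i, (name, _sign) in enumerate(self.labels):
            if name == self.anchor:
                return GeneOrder(self.labels[i:] + self.labels[:i], self.anchor)
        return self

    def without(self, names: set[str]) -> "GeneOrder":
        kept = tuple(l for l in self.labels if l[0] not in names)
        anchor = self.anchor if self.anchor not in names else (kept[0][0] if kept else "")
        return GeneOrder(kept, anchor)

    def __str__(self) -> str:
        return " ".join(_format_token(l) for l in self.rotated_to_anchor().labels)


def extract_gene_order(genome: AnnotatedGenome, anchor: str = CONTROL_NAME) -> GeneOrder:
    """Signed labels of a genome's features in genomic (start) order."""
    labels = tuple((f.name, -1 if f.strand == "R" else +1) for f in genome.features)
    order = GeneOrder(labels, anchor)
    return order


def adjacency_set(order: GeneOrder) -> frozenset[tuple[SignedLabel, SignedLabel]]:
    """Consecutive ordered signed pairs, including the circular closure."""
    labs = order.labels
    if len(labs) < 2:
        raise ValueError("adjacency set of a singleton circular order is undefined")
    return frozenset((labs[i], labs[(i + 1) % len(labs)]) for i in range(len(labs)))


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b``.

    Symmetric for orders over the same label set (they have equally many
    adjacencies). Raises on a label-set mismatch.
    """
    if a.names != b.names:
        only_a = sorted(a.names - b.names)
        only_b = sorted(b.names - a.names)
        raise ValueError(
            f"gene orders differ in label set: only in first {only_a}, "
            f"only in second {only_b}")
    return len(adjacency_set(a) - adjacency_set(b))


def detect_translocated_genes(observed: GeneOrder, reference: GeneOrder) -> set[str]:
    """Labels whose individual removal reconciles the two orders.

    Returns every label L such that deleting L from both circular orders
    leaves identical adjacency sets — the minimal single-gene
    translocation explanation of the difference. Empty when the orders
    already agree.
    """
    if observed.names != reference.names:
        raise ValueError("orders must share a label set")
    if adjacency_set(observed) == adjacency_set(reference):
        return set()
    moved: set[str] = set()
    for name in sorted(observed.names):
        o = observed.without({name})
        r = reference.without({name})
        if len(o.labels) >= 2 and adjacency_set(o) == adjacency_set(r):
            moved.add(name)
    return moved


# The shared pancrustacean backbone downstream of nad2, as carried by both
# reference arrangements; signs follow the majority/minority strand.
_BACKBONE = (
    "trnW -trnC -trnY cox1 trnL2 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 "
    "trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP "
    "nad6 cob trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS"
).split()

#: Derived lepidopteran arrangement: trnM precedes trnI (CR, trnM, trnI, -trnQ, nad2, ...).
LEPIDOPTERAN_ORDER = GeneOrder.from_tokens(
    [CONTROL_NAME, "trnM", "trnI", "-trnQ", "nad2", *_BACKBONE])

#: Ancestral insect arrangement: trnM between trnQ and nad2 (CR, trnI, -trnQ, trnM, nad2, ...).
ANCESTRAL_INSECT_ORDER = GeneOrder.from_tokens(
    [CONTROL_NAME, "trnI", "-trnQ", "trnM", "nad2", *_BACKBONE])


def write_gene_order_tsv(genome_id: str, order: GeneOrder) -> str:
    """One-row report: order string, breakpoints vs both references,
    translocated genes vs the ancestral arrangement (when comparable)."""
    row: dict[str, object] = {"genome": genome_id, "order": str(order)}
    for label, ref in (("vs_ancestral", ANCESTRAL_INSECT_ORDER),
                       ("vs_lepidopteran", LEPIDOPTERAN_ORDER)):
        if order.names == ref.names:
            row[f"breakpoints_{label}"] = breakpoint_distance(order, ref)
        else:
            row[f"breakpoints_{label}"] = "NA"
    if order.names == ANCESTRAL_INSECT_ORDER.names:
        moved = detect_translocated_genes(order, ANCESTRAL_INSECT_ORDER)
        row["translocated_vs_ancestral"] = ",".join(sorted(moved)) or "none"
    else:
        row["translocated_vs_ancestral"] = "NA"
    return pd.DataFrame([row]).to_csv(sep="\t", index=False)
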