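"""Gene-order (synteny) comparison between circular mitogenomes.

Gene orders are signed circular permutations (sign = strand), normalized
by rotating to tRNA-Phe when present (the conventional vertebrate
mitogenome origin) and mapped onto a canonical gene vocabulary so records
annotated with different label dialects (COXI vs COX1, Cyt b vs CYTB, the
duplicated Leu/Ser tRNAs) remain comparable. Rearrangement is quantified
as breakpoint distance — gene adjacencies of one circular order absent
from the other — with strand flips counted separately, so a gene inverted
in place contributes one strand disagreement but no breakpoint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .annotation import MitogenomeRecord


class SyntenyError(ValueError):
    pass


_SYNONYMS = {
    "COXI": "COX1", "COI": "COX1", "CO1": "COX1",
    "COXII": "COX2", "COII": "COX2", "CO2": "COX2",
    "COXIII": "COX3", "COIII": "COX3", "CO3": "COX3",
    "CYTB": "CYTB", "CYT B": "CYTB", "COB": "CYTB",
    "12S": "12S-rRNA", "12S RRNA": "12S-rRNA", "RRNS": "12S-rRNA", "12S-RRNA": "12S-rRNA",
    "16S": "16S-rRNA", "16S RRNA": "16S-rRNA", "RRNL": "16S-rRNA", "16S-RRNA": "16S-rRNA",
    "D-LOOP": "CR", "DLOOP": "CR", "CONTROL REGION": "CR",
}


def canonical_label(name: str) -> str:
    """Map a raw gene label to the canonical vocabulary (sans duplicate
    disambiguation, which needs coordinate context)."""
    key = name.strip().strip("*").upper()
    key = re.sub(r"\s*\d+$", "", key) if key.startswith("TRN") else key
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    if key.startswith("TRN"):
        # normalize tRNA-Xxx / trnX spellings
        aa = re.sub(r"^TRNA?[-_ ]?", "", key).capitalize()
        return f"tRNA-{aa}"
    return key


@dataclass(frozen=True)
class GeneOrder:
    """Rotation-normalized signed circular gene order of one record."""

    record_id: str
    labels: tuple[str, ...]
    strands: tuple[str, ...]

    @property
    def signed(self) -> tuple[str, ...]:
        return tuple(f"{s}{l}" for l, s in zip(self.labels, self.strands))

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SyntenyComparison:
    record_a: str
    record_b: str
    shared_genes: frozenset
    breakpoints: int
    identical: bool
    strand_disagreements: tuple[str, ...]


def gene_order(record: MitogenomeRecord, include_cr: bool = False) -> GeneOrder:
    """Signed gene order of a record, duplicate tRNAs disambiguated by
    coordinate rank (#1, #2) and rotated to start at tRNA-Phe if present,
    else to the lexicographically minimal label."""
    feats = [f for f in record.features if include_cr or f.feature_class != "CR"]
    if len(feats) < 1:
        raise SyntenyError("record has no gene features")
    labels = [canonical_label(f.name) for f in feats]
    seen: dict[str, int] = {}
    for lbl in labels:
        seen[lbl] = seen.get(lbl, 0) + 1
    counters: dict[str, int] = {}
    for i, lbl in enumerate(labels):
        if seen[lbl] > 1:
            counters[lbl] = counters.get(lbl, 0) + 1
            labels[i] = f"{lbl}#{counters[lbl]}"
    if len(set(labels)) != len(labels):
        raise SyntenyError("unresolvable duplicate gene labels")
    strands = [f.strand or "+" for f in feats]
    # rotation normalization
    anchor = None
    for i, lbl in enumerate(labels):
        if lbl == "tRNA-Phe" or lbl.startswith("tRNA-Phe#"):
            anchor = i
            break
    if anchor is None:
        anchor = labels.index(min(labels))
    labels = labels[anchor:] + labels[:anchor]
    strands = strands[anchor:] + strands[:anchor]
    return GeneOrder(record.record_id, tuple(labels), tuple(strands))


def _circular_adjacencies(labels) -> set[tuple[str, str]]:
    """Directed clockwise adjacencies of a circular order. Directed pairs
    make an adjacent transposition cost 3 breakpoints and a full-circle
    reflection non-identical, so breakpoints = 0 iff the orders agree up
    to rotation."""
    n = len(labels)
    if n < 2:
        return set()
    return {(labels[i], labels[(i + 1) % n]) for i in range(n)}


def _rotate_to(labels: list[str], strands: list[str], lbl: str) -> tuple[list[str], list[str]]:
    i = labels.index(lbl)
    return labels[i:] + labels[:i], strands[i:] + strands[:i]


def compare_orders(a: GeneOrder, b: GeneOrder) -> SyntenyComparison:
    """Breakpoint count and strand agreement between two circular orders,
    restricted to the shared gene set."""
    shared = set(a.labels) & set(b.labels)
    if not shared:
        raise SyntenyError("disjoint gene sets")

    def restrict(order: GeneOrder) -> tuple[list[str], list[str]]:
        pairs = [(l, s) for l, s in zip(order.labels, order.strands) if l in shared]
        return [p[0] for p in pairs], [p[1] for p in pairs]

    la, sa = restrict(a)
    lb, sb = restrict(b)
    breakpoints = len(_circular_adjacencies(tuple(la)) - _circular_adjacencies(tuple(lb)))

    strand_a = dict(zip(la, sa))
    strand_b = dict(zip(lb, sb))
    disagreements = tuple(sorted(g for g in shared if strand_a[g] != strand_b[g]))

    # identical order = equal after rotating b onto a's first shared gene
    identical = False
    if len(la) == len(lb):
        lb_rot, _ = _rotate_to(lb, sb, la[0])
        identical = la == lb_rot
    return SyntenyComparison(
        record_a=a.record_id,
        record_b=b.record_id,
        shared_genes=frozenset(shared),
        breakpoints=breakpoints,
        identical=identical,
        strand_disagreements=disagreements,
    )


def synteny_matrix(orders: list[GeneOrder]) -> list[dict]:
    """All-pairs breakpoint/strand comparison rows for a set of genomes."""
    rows = []
    for i, a in enumerate(orders):
        for b in orders[i + 1 :]:
            cmp = compare_orders(a, b)
            rows.append(
                {
                    "record_a": cmp.record_a,
                    "record_b": cmp.record_b,
                    "shared_genes": len(cmp.shared_genes),
                    "breakpoints": cmp.breakpoints,
                    "identical": cmp.identical,
                    "strand_disagreements": len(cmp.strand_disagreements),
                }
            )
    return rows


def layout_table(orders: list[GeneOrder]) -> list[dict]:
    """One row per genome: ordered gene labels with strand marks."""
    return [
        {"record_id": o.record_id, "order": " ".join(o.signed)}
        for o in orders
    ]
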