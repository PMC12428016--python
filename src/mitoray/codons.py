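"""Codon extraction, start/stop tabulation, RSCU, and the effective number
of codons (ENc) under the vertebrate mitochondrial genetic code.

The genetic code defaults to NCBI translation table 2 (vertebrate
mitochondrial: ATA=Met, TGA=Trp, AGA/AGG=stop), the code every vertebrate
mitogenome uses. Under it there are no single-codon amino acids: 12
two-fold, 6 four-fold and 2 six-fold families, so perfectly uniform usage
gives ENc = 60; under the standard code (table 1) the familiar maximum of
61 applies. ENc is Wright's statistic: per-family codon homozygosity
F = (n * sum(p_i^2) - 1) / (n - 1), averaged within each degeneracy class,
with ENc = singles + sum_d K_d / F_bar_d.

Incomplete stop codons — protein genes ending in T or TA, completed to TAA
by post-transcriptional polyadenylation — are reported in the conventional
"T(AA)" / "TA(A)" notation and excluded from usage counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from .annotation import GeneFeature, MitogenomeRecord, extract_region

BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


class CodonError(ValueError):
    pass


@dataclass(frozen=True, eq=False)  # identity hash: instances are interned per table id
class GeneticCode:
    """A codon -> amino acid map plus its synonymous-family partition."""

    table_id: int
    name: str
    forward: dict  # codon -> one-letter amino acid (sense codons only)
    stop_codons: frozenset
    families: dict  # amino acid -> tuple of synonymous codons (sorted)

    @classmethod
    @lru_cache(maxsize=None)
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(table.forward_table)
        families: dict[str, list[str]] = {}
        for codon, aa in forward.items():
            families.setdefault(aa, []).append(codon)
        return cls(
            table_id=table_id,
            name=table.names[0],
            forward=forward,
            stop_codons=frozenset(table.stop_codons),
            families={aa: tuple(sorted(cods)) for aa, cods in sorted(families.items())},
        )

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> str:
        """One-letter amino acid, '*' for stop."""
        if codon in self.stop_codons:
            return "*"
        try:
            return self.forward[codon]
        except KeyError:
            raise CodonError(f"not an unambiguous codon: {codon!r}") from None

    def degeneracy(self, codon: str) -> int:
        return len(self.families[self.translate(codon)])

    @property
    def degeneracy_classes(self) -> dict[int, int]:
        """degeneracy -> number of amino-acid families of that degeneracy."""
        out: dict[int, int] = {}
        for cods in self.families.values():
            out[len(cods)] = out.get(len(cods), 0) + 1
        return out

    @property
    def max_enc(self) -> float:
        """ENc under perfectly uniform usage (61 for the standard code)."""
        return float(sum(d * k for d, k in self.degeneracy_classes.items()))

    @property
    def min_enc(self) -> float:
        """ENc when a single codon per family is used (number of families)."""
        return float(sum(self.degeneracy_classes.values()))


VERTEBRATE_MITO = GeneticCode.from_ncbi_id(2)
STANDARD = GeneticCode.from_ncbi_id(1)


@dataclass
class CodonExtraction:
    """Codons of one protein-coding gene read on its coding strand."""

    gene: str
    codons: list[str]  # complete codons, including a complete terminal stop
    start_codon: str | None
    stop_codon: str  # "TAA", "T(AA)", "TA(A)", or "none"
    incomplete_stop: str | None  # trailing 1-2 nt, or None
    internal_stop_positions: list[int] = field(default_factory=list)

    @property
    def sense_codons(self) -> list[str]:
        """Codons contributing to usage statistics (terminal stop excluded)."""
        if self.codons and self.incomplete_stop is None and self.stop_codon == self.codons[-1]:
            return self.codons[:-1]
        return list(self.codons)


def _incomplete_stop_label(trailing: str) -> str:
    if trailing == "T":
        return "T(AA)"
    if trailing == "TA":
        return "TA(A)"
    return f"{trailing}(?)"


def extract_codons(
    record: MitogenomeRecord,
    feature: GeneFeature,
    code: GeneticCode = VERTEBRATE_MITO,
) -> CodonExtraction:
    """Split a protein-coding gene into codons on its coding strand.

    Light-strand genes are reverse-complemented first. A trailing 1-2 nt
    remainder is recorded as an incomplete stop and excluded from the codon
    list. Internal stop codons trigger a warning listing codon positions.
    """
    if feature.feature_class != "PCG":
        raise CodonError(f"{feature.name}: not a protein-coding gene")
    seq = extract_region(record, feature)
    if len(seq) < 3:
        raise CodonError(f"{feature.name}: length {len(seq)} < one codon")
    n_complete = len(seq) // 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_complete)]
    trailing = seq[3 * n_complete :] or None

    if trailing is not None:
        stop = _incomplete_stop_label(trailing)
    elif code.is_stop(codons[-1]):
        stop = codons[-1]
    else:
        stop = "none"
        warnings.warn(f"{feature.name}: no recognized stop codon (ends {codons[-1]})")

    body = codons[:-1] if (trailing is None and stop != "none") else codons
    internal = [i + 1 for i, c in enumerate(body[1:], start=1) if code.is_stop(c)]
    if internal:
        warnings.warn(f"{feature.name}: internal stop codons at codon positions {internal}")

    return CodonExtraction(
        gene=feature.name,
        codons=codons,
        start_codon=codons[0],
        stop_codon=stop,
        incomplete_stop=trailing,
        internal_stop_positions=internal,
    )


def tabulate_start_stop(
    record: MitogenomeRecord, code: GeneticCode = VERTEBRATE_MITO
) -> dict[str, tuple[str, str]]:
    """Per-gene (start codon, stop codon) over all protein-coding genes,
    with incomplete stops in "T(AA)" notation."""
    out = {}
    for f in record.pcgs:
        ext = extract_codons(record, f, code)
        out[f.name] = (ext.start_codon, ext.stop_codon)
    return out


def count_codons(
    extractions: list[CodonExtraction] | list[list[str]],
    code: GeneticCode = VERTEBRATE_MITO,
) -> dict[str, int]:
    """Aggregate sense-codon counts over genes (stops excluded).

    Start codons are counted literally (a GTG start lands in the Val
    family); terminal stops and incomplete stops never enter the counts.
    """
    counts = {c: 0 for c in ALL_CODONS}
    for item in extractions:
        codons = item.sense_codons if isinstance(item, CodonExtraction) else item
        for c in codons:
            if not code.is_stop(c):
                counts[c] += 1
    return counts


def rscu(counts: dict[str, int], code: GeneticCode = VERTEBRATE_MITO) -> dict[str, float | None]:
    """Relative synonymous codon usage: a codon's count divided by the mean
    count of its synonymous family. A family with zero total usage has no
    defined RSCU (None). Stop codons are excluded."""
    out: dict[str, float | None] = {}
    for aa, family in code.families.items():
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            out[c] = None if total == 0 else counts.get(c, 0) * len(family) / total
    return out


def enc(counts: dict[str, int], code: GeneticCode = VERTEBRATE_MITO) -> float:
    """Wright's effective number of codons from a codon-usage table.

    Family homozygosity F = (n * sum(p_i^2) - 1)/(n - 1) needs n >= 2 and is
    discarded when zero (all observed codons distinct exactly once, which
    carries no bias information). A degeneracy class with no usable family
    borrows: the 3-fold class (standard code Ile) takes the mean of the 2-
    and 4-fold class averages, per Wright's recommendation; any other empty
    class takes the family-weighted mean of the available classes. The
    result is clamped to the code's theoretical maximum.
    """
    singles = code.degeneracy_classes.get(1, 0)
    f_by_class: dict[int, list[float]] = {}
    for aa, family in code.families.items():
        d = len(family)
        if d == 1:
            continue
        ns = [counts.get(c, 0) for c in family]
        n = sum(ns)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in ns)
        f_hat = (n * sum_p2 - 1) / (n - 1)
        if f_hat > 0:
            f_by_class.setdefault(d, []).append(f_hat)
    if not f_by_class:
        raise CodonError("insufficient usage: no synonymous family with computable F")

    means = {d: sum(v) / len(v) for d, v in f_by_class.items()}
    value = float(singles)
    for d, k_families in sorted(code.degeneracy_classes.items()):
        if d == 1:
            continue
        if d in means:
            f_bar = means[d]
        elif d == 3 and 2 in means and 4 in means:
            f_bar = (means[2] + means[4]) / 2
        else:
            weights = {c: len(f_by_class[c]) for c in means}
            f_bar = sum(means[c] * w for c, w in weights.items()) / sum(weights.values())
        value += k_families / f_bar
    return min(value, code.max_enc)


def codon_usage_table(
    record: MitogenomeRecord, code: GeneticCode = VERTEBRATE_MITO
) -> dict:
    """Whole-mitogenome codon usage: counts, RSCU, ENc (whole-genome and
    per-gene), start/stop tabulation, and the total complete codon count."""
    extractions = [extract_codons(record, f, code) for f in record.pcgs]
    counts = count_codons(extractions, code)
    per_gene_enc = {}
    for ext in extractions:
        try:
            per_gene_enc[ext.gene] = enc(count_codons([ext], code), code)
        except CodonError:
            per_gene_enc[ext.gene] = None
    return {
        "counts": counts,
        "rscu": rscu(counts, code),
        "enc": enc(counts, code),
        "per_gene_enc": per_gene_enc,
        "start_stop": {e.gene: (e.start_codon, e.stop_codon) for e in extractions},
        "total_complete_codons": sum(len(e.codons) for e in extractions),
        "total_sense_codons": sum(counts.values()),
        "incomplete_stops": {
            e.gene: e.stop_codon for e in extractions if e.incomplete_stop is not None
        },
    }


def rscu_rows(counts: dict[str, int], code: GeneticCode = VERTEBRATE_MITO) -> list[dict]:
    """Flat RSCU table rows (codon, amino acid, count, RSCU) for writers."""
    values = rscu(counts, code)
    rows = []
    for aa, family in code.families.items():
        for c in family:
            rows.append({"codon": c, "amino_acid": aa, "count": counts.get(c, 0),
                         "rscu": None if values[c] is None else round(values[c], 4)})
    return rows
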