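"""Mitogenome records, feature annotations, and coordinate arithmetic.

Coordinates are 1-based inclusive throughout (the convention of published
mitogenome organization tables); conversion to Biopython's 0-based
half-open locations happens only at the GenBank/FASTA format boundary.

Records are circular by default. A feature may wrap the origin (``wraps``),
in which case its span runs start..genome_length followed by 1..stop; in
practice only the control region does this in vertebrate mitogenomes.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")

#: Alternate spellings seen in feature tables, mapped to the class vocabulary.
_CLASS_ALIASES = {
    "PCG": "PCG",
    "CDS": "PCG",
    "TRNA": "tRNA",
    "RRNA": "rRNA",
    "CR": "CR",
    "D-LOOP": "CR",
    "D_LOOP": "CR",
    "DLOOP": "CR",
    "MISC_FEATURE": "CR",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed feature tables or inconsistent annotations."""


@dataclass
class GeneFeature:
    """One row of a mitogenome organization table.

    ``start``/``stop`` are 1-based inclusive. ``declared_length`` and
    ``declared_spacer`` keep the printed values of the source table so a
    validator can cross-check them against the coordinates; they are never
    used for downstream statistics.
    """

    name: str
    feature_class: str
    strand: str | None  # "+" (heavy), "-" (light), or None (unstated)
    start: int
    stop: int
    declared_length: int | None = None
    declared_spacer: int | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationError(
                f"unknown feature class {self.feature_class!r} for {self.name!r}"
            )
        if self.start < 1:
            raise AnnotationError(f"{self.name}: start must be >= 1")
        if not self.wraps and self.stop < self.start:
            raise AnnotationError(
                f"{self.name}: stop {self.stop} < start {self.start} on a "
                "non-wrapping feature"
            )

    def length(self, genome_length: int | None = None) -> int:
        """Span length in bp computed from the coordinates."""
        if self.wraps:
            if genome_length is None:
                raise AnnotationError(
                    f"{self.name}: genome length needed for a wrapping feature"
                )
            return genome_length - self.start + 1 + self.stop
        return self.stop - self.start + 1

    @property
    def is_gene(self) -> bool:
        return self.feature_class != "CR"


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: sequence plus ordered feature annotations.

    The sequence is optional: a record parsed from an organization table
    alone ("annotation-only mode") still supports all coordinate
    arithmetic and validation.
    """

    record_id: str
    features: list[GeneFeature]
    sequence: str | None = None
    genome_length: int | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.genome_length is None:
                self.genome_length = len(self.sequence)
            elif self.genome_length != len(self.sequence):
                raise AnnotationError(
                    f"{self.record_id}: genome_length {self.genome_length} != "
                    f"sequence length {len(self.sequence)}"
                )
        elif self.genome_length is None and self.features:
            self.genome_length = max(f.stop for f in self.features)
        self.features = sorted(self.features, key=lambda f: (f.start, f.stop))

    def features_of_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.features_of_class("PCG")


@dataclass
class FeatureCheck:
    """Validation result for a single feature row."""

    name: str
    feature_class: str
    strand: str | None
    start: int
    stop: int
    computed_length: int
    declared_length: int | None
    computed_spacer: int | None  # gap to the next feature (circular)
    declared_spacer: int | None
    length_ok: bool
    spacer_ok: bool


@dataclass
class ValidationReport:
    """Coordinate self-consistency report for a mitogenome annotation.

    ``computed_spacer`` of row *i* is ``start(i+1) - stop(i) - 1`` on the
    start-sorted feature list (circular for the last row); negative values
    denote overlap. Declared lengths/spacers are compared but never
    corrected: the coordinates are authoritative downstream.
    """

    record_id: str
    genome_length: int
    rows: list[FeatureCheck]
    class_counts: dict[str, int]
    strand_counts_by_class: dict[str, dict[str, int]]
    overlaps: list[tuple[str, str, int]]  # (name, next name, overlap bp)
    length_discrepancies: list[str]
    spacer_discrepancies: list[str]
    pcg_length_sum_computed: int
    pcg_length_sum_declared: int | None
    notes: list[str] = field(default_factory=list)

    @property
    def strand_counts(self) -> dict[str, int]:
        """Heavy/light tallies over gene rows (CR excluded)."""
        totals = {"+": 0, "-": 0}
        for cls, tally in self.strand_counts_by_class.items():
            if cls == "CR":
                continue
            for strand, n in tally.items():
                totals[strand] = totals.get(strand, 0) + n
        return totals

    @property
    def n_discrepancies(self) -> int:
        return len(self.length_discrepancies)

    def pcg_length_extremes(self) -> tuple[tuple[str, int], tuple[str, int]]:
        pcg = [(r.name, r.computed_length) for r in self.rows if r.feature_class == "PCG"]
        if not pcg:
            raise AnnotationError("no protein-coding genes in report")
        lo = min(pcg, key=lambda x: x[1])
        hi = max(pcg, key=lambda x: x[1])
        return lo, hi


def _parse_coord(token: str, row_name: str) -> int:
    cleaned = token.replace(",", "").strip()
    if not re.fullmatch(r"\d+", cleaned):
        raise AnnotationError(f"malformed coordinate {token!r} in row {row_name!r}")
    return int(cleaned)


def _parse_int_or_none(token: str) -> int | None:
    cleaned = token.replace(",", "").replace("−", "-").strip()
    if cleaned in ("", "-", "."):
        return None
    try:
        return int(cleaned)
    except ValueError:
        return None


def _parse_codons(token: str) -> tuple[str | None, str | None]:
    token = token.strip()
    if token in ("", "-"):
        return None, None
    if "/" in token:
        start, stop = token.split("/", 1)
        return start.strip() or None, stop.strip() or None
    return token, None


def parse_feature_table(table_text: str) -> MitogenomeRecord:
    """Parse a tab-delimited mitogenome organization table.

    Expected columns: Name, Type, Strand, Start, Stop, then optionally
    Intergenic, Length, and a Codons column holding ``start/stop`` codon
    annotations (incomplete stops written ``T(AA)`` / ``TA(A)``). A D-loop
    row is mapped to feature class CR. Thousands separators inside
    coordinates are tolerated and stripped.
    """
    lines = [ln for ln in table_text.splitlines() if ln.strip()]
    if not lines:
        raise AnnotationError("no features: empty table")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if "name" not in header or "start" not in header:
        raise AnnotationError("missing header row (need at least Name/Start columns)")

    def col(row: list[str], *names: str) -> str:
        for n in names:
            if n in header:
                i = header.index(n)
                if i < len(row):
                    return row[i]
        return ""

    features: list[GeneFeature] = []
    for ln in lines[1:]:
        row = ln.split("\t")
        name = col(row, "name").strip().strip("*").strip()
        if not name:
            continue
        raw_class = col(row, "type", "class").strip()
        key = raw_class.upper().replace(" ", "")
        if name.upper() in ("D-LOOP", "DLOOP") and not key:
            key = "CR"
        if key not in _CLASS_ALIASES:
            raise AnnotationError(f"unknown feature class {raw_class!r} in row {name!r}")
        strand = col(row, "strand").strip().replace("−", "-") or None
        if strand not in (None, "+", "-"):
            raise AnnotationError(f"unknown strand {strand!r} in row {name!r}")
        start = _parse_coord(col(row, "start"), name)
        stop = _parse_coord(col(row, "stop", "end"), name)
        start_codon, stop_codon = _parse_codons(
            col(row, "codons", "anticodon and start codon/stop codon")
        )
        features.append(
            GeneFeature(
                name=name,
                feature_class=_CLASS_ALIASES[key],
                strand=strand,
                start=start,
                stop=stop,
                declared_length=_parse_int_or_none(col(row, "length")),
                declared_spacer=_parse_int_or_none(
                    col(row, "intergenic", "intergenic nucleotide")
                ),
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )
    if not features:
        raise AnnotationError("no features: table has a header but no rows")
    return MitogenomeRecord(record_id="feature-table", features=features)


def write_feature_table(record: MitogenomeRecord) -> str:
    """Serialize features back to the tab-delimited table dialect."""
    out = io.StringIO()
    out.write("Name\tType\tStrand\tStart\tStop\tIntergenic\tLength\tCodons\n")
    for f in record.features:
        codons = "-"
        if f.start_codon or f.stop_codon:
            codons = f"{f.start_codon or ''}/{f.stop_codon or ''}"
        out.write(
            "\t".join(
                [
                    f.name,
                    f.feature_class,
                    f.strand or "",
                    str(f.start),
                    str(f.stop),
                    "" if f.declared_spacer is None else str(f.declared_spacer),
                    str(f.declared_length if f.declared_length is not None else f.length(record.genome_length)),
                    codons,
                ]
            )
            + "\n"
        )
    return out.getvalue()


def validate_annotation(record: MitogenomeRecord) -> ValidationReport:
    """Cross-check declared lengths and intergenic spacers against coordinates.

    Report-only: discrepant rows are flagged, never altered. Strand tallies
    are per feature class; heavy/light totals over gene rows are exposed via
    :attr:`ValidationReport.strand_counts`.
    """
    if not record.features:
        raise AnnotationError("cannot validate a record with no features")
    L = record.genome_length
    feats = record.features  # already start-sorted
    rows: list[FeatureCheck] = []
    overlaps: list[tuple[str, str, int]] = []
    length_bad: list[str] = []
    spacer_bad: list[str] = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if i + 1 < len(feats):
            spacer = nxt.start - f.stop - 1
        elif record.circular and L is not None:
            spacer = nxt.start + L - f.stop - 1  # wrap back to the first feature
        else:
            spacer = None
        clen = f.length(L)
        length_ok = f.declared_length is None or f.declared_length == clen
        spacer_ok = f.declared_spacer is None or spacer is None or f.declared_spacer == spacer
        if not length_ok:
            length_bad.append(f.name)
        if not spacer_ok:
            spacer_bad.append(f.name)
        if spacer is not None and spacer < 0:
            overlaps.append((f.name, nxt.name, -spacer))
        rows.append(
            FeatureCheck(
                name=f.name,
                feature_class=f.feature_class,
                strand=f.strand,
                start=f.start,
                stop=f.stop,
                computed_length=clen,
                declared_length=f.declared_length,
                computed_spacer=spacer,
                declared_spacer=f.declared_spacer,
                length_ok=length_ok,
                spacer_ok=spacer_ok,
            )
        )

    class_counts: dict[str, int] = {c: 0 for c in FEATURE_CLASSES}
    strand_by_class: dict[str, dict[str, int]] = {}
    for f in feats:
        class_counts[f.feature_class] += 1
        if f.strand is not None:
            tally = strand_by_class.setdefault(f.feature_class, {"+": 0, "-": 0})
            tally[f.strand] += 1

    pcg_rows = [r for r in rows if r.feature_class == "PCG"]
    pcg_sum = sum(r.computed_length for r in pcg_rows)
    declared = [r.declared_length for r in pcg_rows]
    pcg_sum_declared = sum(declared) if all(d is not None for d in declared) and declared else None

    notes = []
    if pcg_sum_declared is not None and pcg_sum_declared != pcg_sum:
        notes.append(
            f"PCG length sum: computed-from-coordinates {pcg_sum} bp differs "
            f"from declared-column sum {pcg_sum_declared} bp"
        )
    return ValidationReport(
        record_id=record.record_id,
        genome_length=L,
        rows=rows,
        class_counts=class_counts,
        strand_counts_by_class=strand_by_class,
        overlaps=overlaps,
        length_discrepancies=length_bad,
        spacer_discrepancies=spacer_bad,
        pcg_length_sum_computed=pcg_sum,
        pcg_length_sum_declared=pcg_sum_declared,
        notes=notes,
    )


def extract_region(record: MitogenomeRecord, feature: GeneFeature) -> str:
    """Extract a feature's sequence on its coding strand.

    1-based inclusive slicing; light-strand features are returned
    reverse-complemented; wrapping features are concatenated across the
    origin (requires a circular record).
    """
    if record.sequence is None:
        raise AnnotationError("record has no sequence")
    L = len(record.sequence)
    if feature.stop > L or feature.start > L:
        if not record.circular:
            raise AnnotationError(
                f"{feature.name}: coordinates exceed genome length {L} on a "
                "non-circular record"
            )
        raise AnnotationError(f"{feature.name}: coordinates exceed genome length {L}")
    if feature.wraps:
        if not record.circular:
            raise AnnotationError(
                f"{feature.name}: wrapping feature on a non-circular record"
            )
        seq = record.sequence[feature.start - 1 :] + record.sequence[: feature.stop]
    else:
        seq = record.sequence[feature.start - 1 : feature.stop]
    if feature.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# FASTA / GenBank flat-file boundary (Biopython under the hood)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> str:
    """Read a single-record FASTA; the sequence is uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(f"expected exactly one FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    if not seq:
        raise AnnotationError("zero-length sequence")
    return seq


def write_fasta(path: str | Path, record: MitogenomeRecord) -> None:
    if record.sequence is None:
        raise AnnotationError("record has no sequence")
    SeqIO.write(
        SeqRecord(Seq(record.sequence), id=record.record_id, description=""),
        str(path),
        "fasta",
    )


_GENBANK_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}
_CLASS_GENBANK = {v: k for k, v in _GENBANK_CLASS.items()}


def read_genbank_flat(path: str | Path) -> MitogenomeRecord:
    """Read an annotated mitogenome from a GenBank flat file.

    CDS/tRNA/rRNA/D-loop features are kept; coordinates are normalized to
    1-based inclusive. A compound ``join`` location spanning the origin is
    collapsed to a single wrapping feature.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise AnnotationError(f"expected exactly one GenBank record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise AnnotationError("zero-length sequence")
    features: list[GeneFeature] = []
    for ft in rec.features:
        if ft.type not in _GENBANK_CLASS:
            continue
        quals = ft.qualifiers
        name = (quals.get("gene") or quals.get("product") or [ft.type])[0]
        wraps = False
        loc = ft.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # join(a..L,1..b) across the origin -> single wrapping feature
            if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == len(seq):
                wraps = True
                start = int(parts[1].start) + 1
                stop = int(parts[0].end)
            else:
                raise AnnotationError(f"{name}: unsupported compound location {loc}")
        else:
            start = int(loc.start) + 1
            stop = int(loc.end)
        features.append(
            GeneFeature(
                name=name,
                feature_class=_GENBANK_CLASS[ft.type],
                strand="-" if loc.strand == -1 else "+",
                start=start,
                stop=stop,
                start_codon=(quals.get("start_codon") or [None])[0],
                stop_codon=(quals.get("stop_codon") or [None])[0],
                wraps=wraps,
            )
        )
    return MitogenomeRecord(record_id=rec.id, features=features, sequence=seq)


def write_genbank_flat(path: str | Path, record: MitogenomeRecord) -> None:
    """Write a record to a GenBank flat file (round-trips with the reader)."""
    if record.sequence is None:
        raise AnnotationError("record has no sequence")
    L = len(record.sequence)
    rec = SeqRecord(Seq(record.sequence), id=record.record_id, name=record.record_id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, L, strand=strand),
                    SimpleLocation(0, f.stop, strand=strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.stop, strand=strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.start_codon:
            quals["start_codon"] = [f.start_codon]
        if f.stop_codon:
            quals["stop_codon"] = [f.stop_codon]
        rec.features.append(SeqFeature(loc, type=_CLASS_GENBANK[f.feature_class], qualifiers=quals))
    SeqIO.write(rec, str(path), "genbank")
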