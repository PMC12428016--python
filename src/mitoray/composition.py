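"""Base composition, AT/GC content, and strand-skew statistics.

Skews follow the standard strand-asymmetry definitions

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on the heavy (+) strand as deposited. Percentages are computed
over counted A+C+G+T only; N (and other IUPAC ambiguity) bases are tallied
separately and excluded from every denominator. Skews are stored at full
precision; rounding to two decimals is a display concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .annotation import MitogenomeRecord, reverse_complement

_IUPAC = set("ACGTNRYSWKMBDHV")


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts and derived content/skew statistics for one region."""

    a: int
    c: int
    g: int
    t: int
    n_count: int = 0

    @classmethod
    def from_sequence(cls, seq: str) -> "CompositionProfile":
        if not seq:
            raise CompositionError("empty sequence")
        seq = seq.upper()
        counts = {b: 0 for b in "ACGT"}
        ambiguous = 0
        for pos, base in enumerate(seq, start=1):
            if base in counts:
                counts[base] += 1
            elif base in _IUPAC:
                ambiguous += 1
            else:
                raise CompositionError(f"non-IUPAC character {base!r} at position {pos}")
        return cls(a=counts["A"], c=counts["C"], g=counts["G"], t=counts["T"], n_count=ambiguous)

    @classmethod
    def from_percentages(cls, a: float, c: float, g: float, t: float, per: int = 1_000_000) -> "CompositionProfile":
        """Build a profile from printed percentages (e.g. a published
        composition table) by scaling to integer counts per ``per`` bases."""
        return cls(
            a=round(a * per / 100),
            c=round(c * per / 100),
            g=round(g * per / 100),
            t=round(t * per / 100),
        )

    def __add__(self, other: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.n_count + other.n_count,
        )

    @property
    def total(self) -> int:
        """Counted (unambiguous) bases."""
        return self.a + self.c + self.g + self.t

    def fraction(self, base: str) -> float:
        """Percent of counted bases."""
        count = {"A": self.a, "C": self.c, "G": self.g, "T": self.t}[base.upper()]
        return 100.0 * count / self.total

    @property
    def fractions(self) -> dict[str, float]:
        return {b: self.fraction(b) for b in "ACGT"}

    @property
    def at_content(self) -> float:
        return 100.0 * (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return 100.0 * (self.g + self.c) / self.total

    @property
    def at_skew(self) -> float | None:
        if self.a + self.t == 0:
            return None
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float | None:
        if self.g + self.c == 0:
            return None
        return (self.g - self.c) / (self.g + self.c)


def composition_profile(seq: str) -> CompositionProfile:
    """Count bases and derive composition statistics for a sequence."""
    return CompositionProfile.from_sequence(seq)


def skew_stats(profile: CompositionProfile) -> tuple[float | None, float | None]:
    """(AT skew, GC skew) at full precision; ``None`` when a denominator is 0."""
    at, gc = profile.at_skew, profile.gc_skew
    if at is None:
        warnings.warn("AT skew undefined: A + T = 0")
    if gc is None:
        warnings.warn("GC skew undefined: G + C = 0")
    return at, gc


def check_reported_skews(
    profile: CompositionProfile,
    reported_at_skew: float | None,
    reported_gc_skew: float | None,
) -> list[str]:
    """Flag sign disagreements between computed and reported skew values.

    Useful for auditing published composition tables, where a C/G or A/T
    label swap shows up as a skew of the right magnitude but wrong sign.
    Returns human-readable flags (empty list = consistent signs).
    """
    flags = []
    for label, computed, reported in (
        ("AT skew", profile.at_skew, reported_at_skew),
        ("GC skew", profile.gc_skew, reported_gc_skew),
    ):
        if computed is None or reported is None:
            continue
        if computed * reported < 0:
            flags.append(
                f"{label} sign inconsistency: computed {computed:+.4f} from the "
                f"base composition, but {reported:+.2f} reported"
            )
    return flags


def windowed_skew(
    record: MitogenomeRecord, window: int, step: int
) -> list[tuple[int, CompositionProfile]]:
    """Sliding-window composition profiles over a circular genome.

    Windows start every ``step`` bp (1-based start positions); windows
    extending past the end wrap around the origin. Returns
    ``(window_start, profile)`` pairs.
    """
    if record.sequence is None:
        raise CompositionError("record has no sequence")
    if window < 1 or step < 1:
        raise CompositionError("window and step must be >= 1")
    L = len(record.sequence)
    if window > L:
        raise CompositionError(f"window {window} exceeds genome length {L}")
    doubled = record.sequence + record.sequence
    out = []
    for start0 in range(0, L, step):
        out.append((start0 + 1, composition_profile(doubled[start0 : start0 + window])))
    return out


def composition_table(record: MitogenomeRecord) -> list[dict]:
    """One composition row per region: whole genome, each feature class
    present, and the control region; the report-layer surface."""
    from .annotation import extract_region

    rows = []

    def row(region: str, profile: CompositionProfile) -> dict:
        return {
            "region": region,
            **{base: round(profile.fraction(base), 2) for base in "ACGT"},
            "at_content": round(profile.at_content, 2),
            "gc_content": round(profile.gc_content, 2),
            "at_skew": None if profile.at_skew is None else round(profile.at_skew, 4),
            "gc_skew": None if profile.gc_skew is None else round(profile.gc_skew, 4),
            "n_count": profile.n_count,
        }

    rows.append(row("whole_genome", composition_profile(record.sequence)))
    for cls in ("PCG", "rRNA", "tRNA", "CR"):
        feats = record.features_of_class(cls)
        if not feats:
            continue
        merged = None
        for f in feats:
            seq = extract_region(record, f)
            if f.strand == "-":  # class statistics are heavy-strand
                seq = reverse_complement(seq)
            p = composition_profile(seq)
            merged = p if merged is None else merged + p
        rows.append(row(cls, merged))
    return rows
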