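"""Packaged reference data for the *Potamotrygon leopoldi* mitogenome.

Ships the published organization table (38 features: 13 protein-coding
genes, 22 tRNAs, 2 rRNAs, and the control region) and the printed summary
statistics of the deposited record (GenBank OR896919): whole-genome, rRNA
and control-region base composition, reported strand skews, the reported
effective number of codons, and the two control-region tandem-repeat unit
lengths. These drive annotation-only analyses and anchor the synthetic
genome generator's defaults; the full sequence itself is not packaged.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .annotation import MitogenomeRecord, parse_feature_table

_DATA = resources.files("mitoray") / "data"


@lru_cache(maxsize=1)
def printed_values() -> dict:
    """Published summary values for the deposited mitogenome record."""
    with (_DATA / "printed_values.json").open(encoding="utf-8") as fh:
        return json.load(fh)


def feature_table_text() -> str:
    return (_DATA / "leopoldi_feature_table.tsv").read_text(encoding="utf-8")


def leopoldi_record() -> MitogenomeRecord:
    """The published organization table as an annotation-only record."""
    record = parse_feature_table(feature_table_text())
    record.record_id = printed_values()["record_id"]
    return record


def printed_composition_summary(region: str = "whole_genome") -> dict:
    """AT content and skews computed directly from the published percentage
    table of ``region`` ("whole_genome", "rRNA", or "control_region").

    AT/GC content are plain sums of the printed percentages (no
    renormalization, so they reproduce the published figures exactly);
    skews follow (A-T)/(A+T) and (G-C)/(G+C) on the printed values, at full
    precision. ``flags`` lists sign disagreements between the skews implied
    by the printed composition and the separately reported skew values.
    """
    from .composition import CompositionProfile, check_reported_skews

    vals = printed_values()
    pct = vals["composition_percent"][region]
    a, c, g, t = (pct[b] for b in "ACGT")
    reported = vals["reported_skews"] if region == "whole_genome" else {}
    profile = CompositionProfile.from_percentages(a, c, g, t)
    return {
        "percent": pct,
        "at_content": a + t,
        "gc_content": g + c,
        "at_skew": (a - t) / (a + t),
        "gc_skew": (g - c) / (g + c),
        "flags": check_reported_skews(
            profile, reported.get("at_skew"), reported.get("gc_skew")
        ),
    }


def pcg_template() -> list[dict]:
    """Per-gene template (name, strand, coordinate-computed length, codons)
    for the 13 protein-coding genes, in genome order."""
    rec = leopoldi_record()
    return [
        {
            "name": f.name,
            "strand": f.strand,
            "length": f.length(rec.genome_length),
            "start_codon": f.start_codon,
            "stop_codon": f.stop_codon,
        }
        for f in rec.pcgs
    ]
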