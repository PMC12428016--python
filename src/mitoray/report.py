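"""Full mitogenome characterization: one call running every analysis stage
and emitting paper-shaped report tables.

The report is a plain JSON-serializable dictionary; every number in it is
produced by one library operation (no report-layer arithmetic beyond
display rounding: percentages and skews to 2 decimals, ENc to 2 decimals,
round-half-even — full precision lives in the per-module return values).
Stages run independently: a failure in one is recorded under ``errors``
and the rest continue. Two runs with identical inputs, config and seed
produce byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import codons, composition, phylogeny, repeats, selection, synteny
from .annotation import MitogenomeRecord, validate_annotation


@dataclass
class CharacterizeConfig:
    min_repeat_score: int = 30
    repeat_period_range: tuple[int, int] = (2, 500)
    genome_wide_repeats: bool = False
    distance_model: str = "k2p"
    bootstrap_replicates: int = 0
    ingroup: list[str] = field(default_factory=list)
    outgroup: str | None = None
    foreground: str | None = None
    alignments: dict[str, dict[str, str]] | None = None  # gene -> taxon -> seq
    strict: bool = False
    seed: int = 0


def _round2(x: float | None) -> float | None:
    return None if x is None else round(x, 2)


def _validation_section(record: MitogenomeRecord) -> dict:
    rep = validate_annotation(record)
    lo, hi = rep.pcg_length_extremes() if rep.class_counts.get("PCG") else ((None, None), (None, None))
    return {
        "genome_length": rep.genome_length,
        "feature_counts": rep.class_counts,
        "strand_counts": rep.strand_counts,
        "strand_counts_by_class": rep.strand_counts_by_class,
        "pcg_length_sum_computed": rep.pcg_length_sum_computed,
        "pcg_length_sum_declared": rep.pcg_length_sum_declared,
        "pcg_min": {"gene": lo[0], "length": lo[1]},
        "pcg_max": {"gene": hi[0], "length": hi[1]},
        "length_discrepancies": rep.length_discrepancies,
        "spacer_discrepancies": rep.spacer_discrepancies,
        "overlaps": [
            {"feature": a, "next": b, "overlap_bp": o} for a, b, o in rep.overlaps
        ],
        "notes": rep.notes,
        "rows": [
            {
                "name": r.name, "class": r.feature_class, "strand": r.strand,
                "start": r.start, "stop": r.stop,
                "computed_length": r.computed_length,
                "declared_length": r.declared_length,
                "computed_spacer": r.computed_spacer,
                "declared_spacer": r.declared_spacer,
                "length_ok": r.length_ok, "spacer_ok": r.spacer_ok,
            }
            for r in rep.rows
        ],
    }


def _codon_section(record: MitogenomeRecord) -> dict:
    table = codons.codon_usage_table(record)
    return {
        "enc": _round2(table["enc"]),
        "enc_full_precision": table["enc"],
        "per_gene_enc": {g: _round2(v) for g, v in table["per_gene_enc"].items()},
        "total_complete_codons": table["total_complete_codons"],
        "total_sense_codons": table["total_sense_codons"],
        "start_stop": {g: list(v) for g, v in table["start_stop"].items()},
        "incomplete_stops": table["incomplete_stops"],
        "rscu": codons.rscu_rows(table["counts"]),
    }


def characterize(
    records: list[MitogenomeRecord],
    config: CharacterizeConfig | None = None,
) -> dict:
    """Characterize one or more mitogenomes; cross-record stages (synteny,
    phylogeny, selection) run when enough records/alignments are given."""
    cfg = config or CharacterizeConfig()
    if not records:
        raise ValueError("need at least one record")
    report: dict = {"records": {}, "cross": {}, "errors": []}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # per-stage errors collected, run continues
            report["errors"].append({"stage": name, "error": str(exc)})
            if cfg.strict:
                raise
            return None

    for rec in records:
        section: dict = {}
        report["records"][rec.record_id] = section
        val = stage(f"{rec.record_id}:validation", lambda r=rec: _validation_section(r))
        if val is not None:
            section["validation"] = val
            if cfg.strict and (val["length_discrepancies"] or val["spacer_discrepancies"]):
                raise ValueError(
                    f"{rec.record_id}: annotation discrepancies in strict mode: "
                    f"{val['length_discrepancies'] + val['spacer_discrepancies']}"
                )
        if rec.sequence is None:
            section["mode"] = "annotation-only"
            continue
        section["mode"] = "full"
        comp = stage(f"{rec.record_id}:composition", lambda r=rec: composition.composition_table(r))
        if comp is not None:
            section["composition"] = comp
        cu = stage(f"{rec.record_id}:codon_usage", lambda r=rec: _codon_section(r))
        if cu is not None:
            section["codon_usage"] = cu
        reps = stage(
            f"{rec.record_id}:repeats",
            lambda r=rec: repeats.repeat_report(
                r, min_score=cfg.min_repeat_score,
                period_range=cfg.repeat_period_range,
                genome_wide=cfg.genome_wide_repeats,
            ),
        )
        if reps is not None:
            section["repeats"] = reps

    if len(records) >= 2:
        def synteny_stage():
            orders = [synteny.gene_order(r) for r in records]
            return {
                "layout": synteny.layout_table(orders),
                "comparisons": synteny.synteny_matrix(orders),
            }
        syn = stage("synteny", synteny_stage)
        if syn is not None:
            report["cross"]["synteny"] = syn

    with_seq = [r for r in records if r.sequence is not None]
    if len(with_seq) >= 3:
        def phylo_stage():
            aln = [(r.record_id, r.sequence) for r in with_seq]
            dm = phylogeny.pairwise_distances(aln, model=cfg.distance_model)
            if cfg.bootstrap_replicates > 0:
                tree = phylogeny.bootstrap_support(
                    aln, model=cfg.distance_model,
                    replicates=cfg.bootstrap_replicates, seed=cfg.seed,
                )
            else:
                tree = phylogeny.neighbor_joining(dm)
            out = {
                "distance_matrix": dm.to_phylip(),
                "model": dm.model,
                "newick": tree.to_newick(),
                "support": "bootstrap" if cfg.bootstrap_replicates else None,
            }
            if cfg.ingroup and cfg.outgroup:
                mono, clade = phylogeny.is_monophyletic(tree, set(cfg.ingroup), cfg.outgroup)
                out["monophyly"] = {
                    "taxa": sorted(cfg.ingroup),
                    "outgroup": cfg.outgroup,
                    "monophyletic": mono,
                    "clade": sorted(clade),
                }
            return out
        phylo = stage("phylogeny", phylo_stage)
        if phylo is not None:
            report["cross"]["phylogeny"] = phylo

    if cfg.alignments and cfg.foreground:
        def selection_stage():
            results = []
            screens = selection.sitewise_screen(cfg.alignments, cfg.foreground)
            for gene, seqs in cfg.alignments.items():
                background = sorted(t for t in seqs if t != cfg.foreground)
                fg = seqs[cfg.foreground]
                bg = seqs[background[0]]
                to_codons = lambda s: [s[i:i + 3] for i in range(0, len(s) - len(s) % 3, 3)]
                results.append(
                    selection.ng86_pair(to_codons(fg), to_codons(bg), gene=gene)
                )
            return {
                "foreground": cfg.foreground,
                "genes": selection.selection_table(results, screens),
                "site_counts": {s.gene: len(s.flagged_codons) for s in screens},
            }
        sel = stage("selection", selection_stage)
        if sel is not None:
            report["cross"]["selection"] = sel

    return report


def write_report(report: dict, outdir: str | Path) -> list[str]:
    """Serialize a report bundle (JSON + TSV tables + manifest) to a
    directory; returns the file names written."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def dump_json(name: str, obj) -> None:
        (outdir / name).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        written.append(name)

    def dump_tsv(name: str, rows: list[dict]) -> None:
        pd.DataFrame(rows).to_csv(outdir / name, sep="\t", index=False)
        written.append(name)

    dump_json("report.json", report)
    for rec_id, section in report["records"].items():
        safe = rec_id.replace("/", "_")
        if "composition" in section:
            dump_tsv(f"{safe}.composition.tsv", section["composition"])
        if "codon_usage" in section:
            dump_tsv(f"{safe}.rscu.tsv", section["codon_usage"]["rscu"])
        if "repeats" in section:
            dump_tsv(f"{safe}.repeats.tsv", section["repeats"])
        if "validation" in section:
            dump_tsv(f"{safe}.validation.tsv", section["validation"]["rows"])
    cross = report.get("cross", {})
    if "synteny" in cross:
        dump_tsv("synteny.tsv", cross["synteny"]["comparisons"])
        dump_tsv("gene_orders.tsv", cross["synteny"]["layout"])
    if "phylogeny" in cross:
        (outdir / "tree.nwk").write_text(cross["phylogeny"]["newick"] + "\n")
        written.append("tree.nwk")
        (outdir / "distances.phylip").write_text(cross["phylogeny"]["distance_matrix"])
        written.append("distances.phylip")
    if "selection" in cross:
        dump_tsv("dnds.tsv", [
            {**row, "flagged_codons": ",".join(map(str, row["flagged_codons"]))}
            for row in cross["selection"]["genes"]
        ])
    files = sorted(written + ["manifest.json"])
    (outdir / "manifest.json").write_text(
        json.dumps({"files": files}, indent=2, sort_keys=True) + "\n"
    )
    return files
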