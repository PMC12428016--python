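"""Pairwise dN/dS estimation (Nei–Gojobori 1986 counting) and a
foreground-specific substitution screen for mitochondrial protein genes.

The NG86 method counts, for every codon, the fraction of the nine possible
single-nucleotide changes that are synonymous (its synonymous sites S; the
remainder are nonsynonymous sites N, so S + N = 3 per codon) and, for every
differing codon pair, the synonymous/nonsynonymous composition of the
mutational pathways between them, with all pathways weighted equally and
pathways passing through a stop codon disregarded unless every pathway
does. Changes *to* a stop codon count as nonsynonymous in site counting.
Proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected
(d = -3/4 ln(1 - 4p/3)) to dS and dN; omega = dN/dS.

The sitewise screen is a transparent counting analogue of a branch-site
scan: a codon is flagged when a designated foreground sequence carries an
amino acid absent from a background that is itself monomorphic at that
site, and a per-gene binomial enrichment score compares each gene's flag
count against the pooled rate across genes. Counts from such a screen are
method-dependent and are not comparable across tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from math import log

from scipy.stats import binomtest

from .codons import GeneticCode, VERTEBRATE_MITO

_BASES = "ACGT"


class SelectionError(ValueError):
    pass


@lru_cache(maxsize=8)
def _syn_sites(code: GeneticCode) -> dict[str, float]:
    """Synonymous site count per sense codon (sum over positions of the
    fraction of single-base changes that preserve the amino acid)."""
    out = {}
    for codon in code.forward:
        s = 0.0
        for pos in range(3):
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if not code.is_stop(mutant) and code.forward[mutant] == code.forward[codon]:
                    s += 1 / 3
        out[codon] = s
    return out


@lru_cache(maxsize=65536)
def _pair_changes(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons,
    averaged over equally weighted mutational pathways."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and nxt != c2:
                return None  # pathway through a stop codon
            if code.is_stop(cur) or code.is_stop(nxt):
                nd += 1.0
            elif code.forward[cur] == code.forward[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o) for o in permutations(diffs)) if r is not None]
    if not results:  # all pathways blocked; fall back to including them
        results = []
        for order in permutations(diffs):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if (not code.is_stop(cur) and not code.is_stop(nxt)
                        and code.forward[cur] == code.forward[nxt]):
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC-corrected distance; None when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return None
    return -0.75 * log(1 - 4 * p / 3)


@dataclass
class DnDsResult:
    """NG86 pairwise dN/dS summary for one gene."""

    gene: str
    n_codons: int  # comparable (ungapped, stop-free) codons
    S: float  # synonymous sites (averaged over the two sequences)
    N: float
    Sd: float  # synonymous substitutions
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    per_codon: list[tuple[float, float]] = field(default_factory=list)


def _is_comparable(codon: str) -> bool:
    return len(codon) == 3 and all(b in _BASES for b in codon)


def ng86_pair(
    codons_a: list[str],
    codons_b: list[str],
    code: GeneticCode = VERTEBRATE_MITO,
    correct: bool = True,
    gene: str = "",
) -> DnDsResult:
    """NG86 synonymous/nonsynonymous counting between two codon sequences.

    Codon lists must be equal length (aligned); codons containing gaps or
    ambiguity in either sequence are pairwise-deleted. Internal stop codons
    are an error. Symmetric in its arguments.
    """
    if len(codons_a) != len(codons_b):
        raise SelectionError(
            f"codon list length mismatch: {len(codons_a)} vs {len(codons_b)}"
        )
    syn_sites = _syn_sites(code)
    S = N = Sd = Nd = 0.0
    per_codon = []
    n_used = 0
    for c1, c2 in zip(codons_a, codons_b):
        c1, c2 = c1.upper(), c2.upper()
        if not (_is_comparable(c1) and _is_comparable(c2)):
            per_codon.append((0.0, 0.0))
            continue
        if code.is_stop(c1) or code.is_stop(c2):
            raise SelectionError(f"internal stop codon in pair ({c1}, {c2})")
        n_used += 1
        s_sites = (syn_sites[c1] + syn_sites[c2]) / 2
        S += s_sites
        N += 3 - s_sites
        sd, nd = _pair_changes(c1, c2, code)
        Sd += sd
        Nd += nd
        per_codon.append((sd, nd))
    if n_used == 0:
        raise SelectionError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    if correct:
        dS, dN = jukes_cantor(pS), jukes_cantor(pN)
        if dS is None or dN is None:
            warnings.warn(f"{gene or 'pair'}: saturated (p >= 3/4); distances absent")
    else:
        dS, dN = pS, pN
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return DnDsResult(
        gene=gene, n_codons=n_used, S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, dS=dS, dN=dN, omega=omega, per_codon=per_codon,
    )


@dataclass
class GeneScreen:
    gene: str
    flagged_codons: list[int]  # 1-based codon coordinates
    n_screenable: int
    p_value: float | None
    significant: bool


def sitewise_screen(
    alignments: dict[str, dict[str, str]],
    foreground: str,
    code: GeneticCode = VERTEBRATE_MITO,
    alpha: float = 0.05,
) -> list[GeneScreen]:
    """Flag codons where the foreground taxon carries a lineage-specific
    amino acid.

    ``alignments`` maps gene name -> {taxon: codon-aligned nucleotide
    sequence}. A site is screenable when every background codon is
    ungapped, stop-free, and the background is monomorphic at the amino
    acid level; it is flagged when the foreground amino acid differs from
    that background state. Per-gene enrichment is a one-sided binomial test
    of the gene's flag count against the pooled flag rate over all genes
    (no test when only one gene is provided and nothing is flagged).
    """
    per_gene: list[tuple[str, list[int], int]] = []
    for gene, seqs in alignments.items():
        if foreground not in seqs:
            raise SelectionError(f"{gene}: foreground {foreground!r} not in alignment")
        if len(seqs) < 3:
            raise SelectionError(f"{gene}: need >= 3 sequences (foreground + background)")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1 or next(iter(lengths)) % 3 != 0:
            raise SelectionError(f"{gene}: sequences must be codon-aligned and equal length")
        n_codons = next(iter(lengths)) // 3
        fg = seqs[foreground].upper()
        bg = [s.upper() for t, s in sorted(seqs.items()) if t != foreground]
        flagged = []
        screenable = 0
        for i in range(n_codons):
            sl = slice(3 * i, 3 * i + 3)
            bg_codons = [s[sl] for s in bg]
            fg_codon = fg[sl]
            if not all(_is_comparable(c) and not code.is_stop(c) for c in bg_codons):
                continue
            bg_aas = {code.forward[c] for c in bg_codons}
            if len(bg_aas) != 1:
                continue  # background not conserved: not screenable
            screenable += 1
            if not _is_comparable(fg_codon) or code.is_stop(fg_codon):
                continue
            if code.forward[fg_codon] not in bg_aas:
                flagged.append(i + 1)
        per_gene.append((gene, flagged, screenable))

    total_flags = sum(len(f) for _, f, _ in per_gene)
    total_sites = sum(n for _, _, n in per_gene)
    pooled = total_flags / total_sites if total_sites else 0.0
    out = []
    for gene, flagged, screenable in per_gene:
        if screenable == 0 or pooled in (0.0, 1.0) or len(per_gene) < 2:
            p_value = None
        else:
            p_value = binomtest(len(flagged), screenable, pooled, alternative="greater").pvalue
        out.append(
            GeneScreen(
                gene=gene,
                flagged_codons=flagged,
                n_screenable=screenable,
                p_value=p_value,
                significant=p_value is not None and p_value < alpha,
            )
        )
    return out


def selection_table(results: list[DnDsResult], screens: list[GeneScreen] | None = None) -> list[dict]:
    """Per-gene report rows: dN, dS, omega, and flagged codon indices."""
    by_gene = {s.gene: s for s in screens} if screens else {}
    rows = []
    for r in results:
        s = by_gene.get(r.gene)
        rows.append(
            {
                "gene": r.gene,
                "n_codons": r.n_codons,
                "dN": None if r.dN is None else round(r.dN, 6),
                "dS": None if r.dS is None else round(r.dS, 6),
                "omega": None if r.omega is None else round(r.omega, 4),
                "flagged_codons": s.flagged_codons if s else [],
                "n_flagged": len(s.flagged_codons) if s else 0,
            }
        )
    return rows
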