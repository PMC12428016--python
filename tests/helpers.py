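"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions, separately from the
library implementations it checks: exhaustive tandem-repeat scoring,
NG86 site/pathway enumeration, Wright's ENc by direct evaluation, and
additive-matrix construction from random trees.
"""

from __future__ import annotations

import random
from itertools import permutations

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# tandem repeats: exhaustive best-hit per period
# ---------------------------------------------------------------------------

def oracle_best_repeat(
    seq: str,
    min_score: int = 30,
    match: int = 2,
    mismatch: int = -7,
    min_copies: float = 1.8,
    max_period: int | None = None,
):
    """Best tandem-repeat description of a sequence by exhaustion.

    For every period p, every contiguous lag-p self-match segment is scored
    (prefix sums over +match/mismatch), the best segment is extended by one
    template copy, given a column-majority consensus, re-scored against the
    tandem consensus, and end-trimmed to the best-scoring sub-span. Returns
    the best hit as (start0, end0, period, score) with the same selection
    key the library uses (consensus-length-penalized score, then smaller
    period, then earlier start), or None.
    """
    n = len(seq)
    best = None
    pmax = max_period if max_period is not None else n // 2
    for p in range(2, pmax + 1):
        profile = [match if seq[i] == seq[i - p] else mismatch for i in range(p, n)]
        if not profile:
            continue
        # best contiguous segment by prefix-sum exhaustion
        prefix = [0]
        for v in profile:
            prefix.append(prefix[-1] + v)
        seg = None
        for i in range(len(profile)):
            for j in range(i, len(profile)):
                s = prefix[j + 1] - prefix[i]
                if seg is None or s > seg[0]:
                    seg = (s, i, j)
        if seg is None or seg[0] <= 0:
            continue
        _, i, j = seg
        start, end = i, j + p  # include the template copy
        cons = consensus_by_majority(seq, start, end, p)
        contrib = [
            match if seq[k] == cons[(k - start) % p] else mismatch
            for k in range(start, end + 1)
        ]
        # best sub-span of the contributions
        cpre = [0]
        for v in contrib:
            cpre.append(cpre[-1] + v)
        sub = max(
            ((cpre[b + 1] - cpre[a], a, b) for a in range(len(contrib)) for b in range(a, len(contrib))),
            key=lambda x: x[0],
        )
        score, a, b = sub
        s2, e2 = start + a, start + b
        length = e2 - s2 + 1
        if score < min_score or length / p < min_copies:
            continue
        key = (-(score - match * p), p, s2)
        if best is None or key < best[0]:
            best = (key, (s2, e2, p, score))
    return None if best is None else best[1]


def consensus_by_majority(seq: str, start: int, end: int, period: int) -> str:
    cons = []
    for phase in range(period):
        col = [seq[k] for k in range(start + phase, end + 1, period)]
        if not col:
            col = [seq[start + phase - period]]
        counts = sorted(((col.count(b), b) for b in set(col)), key=lambda x: (-x[0], x[1]))
        cons.append(counts[0][1])
    return "".join(cons)


# ---------------------------------------------------------------------------
# NG86: site and pathway enumeration from first principles
# ---------------------------------------------------------------------------

def oracle_ng86(codons_a, codons_b, code):
    """(S, N, Sd, Nd) for two codon lists by direct enumeration."""
    S = N = Sd = Nd = 0.0
    for c1, c2 in zip(codons_a, codons_b):
        for c in (c1, c2):
            s = _oracle_syn_sites(c, code)
            S += s / 2
            N += (3 - s) / 2
        sd, nd = _oracle_pathways(c1, c2, code)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def _oracle_syn_sites(codon: str, code) -> float:
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if not code.is_stop(mut) and code.translate(mut) == code.translate(codon):
                s += 1 / 3
    return s


def _oracle_pathways(c1: str, c2: str, code) -> tuple[float, float]:
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    blocked = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and nxt != c2:
                through_stop = True
            if (not code.is_stop(cur) and not code.is_stop(nxt)
                    and code.translate(cur) == code.translate(nxt)):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else paths).append((sd, nd))
    use = paths or blocked
    return (sum(p[0] for p in use) / len(use), sum(p[1] for p in use) / len(use))


def random_codon_pair(rng: random.Random, code, n_codons: int):
    """A random pair of stop-free codon lists (arbitrary divergence)."""
    sense = sorted(code.forward)
    a = [rng.choice(sense) for _ in range(n_codons)]
    b = []
    for c in a:
        if rng.random() < 0.5:
            b.append(c)
        else:
            b.append(rng.choice(sense))
    return a, b


# ---------------------------------------------------------------------------
# Wright's ENc by literal evaluation on an explicit partition
# ---------------------------------------------------------------------------

def oracle_enc(counts: dict, code) -> float:
    families = {}
    for aa, fam in code.families.items():
        families[aa] = [counts.get(c, 0) for c in fam]
    f_values = {}  # degeneracy -> list of F
    for aa, ns in families.items():
        d = len(ns)
        n = sum(ns)
        if d == 1 or n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            f_values.setdefault(d, []).append(f)
    enc = float(sum(1 for fam in code.families.values() if len(fam) == 1))
    class_sizes = {}
    for fam in code.families.values():
        if len(fam) > 1:
            class_sizes[len(fam)] = class_sizes.get(len(fam), 0) + 1
    means = {d: sum(v) / len(v) for d, v in f_values.items()}
    for d, k in sorted(class_sizes.items()):
        if d in means:
            fbar = means[d]
        elif d == 3 and 2 in means and 4 in means:
            fbar = (means[2] + means[4]) / 2
        else:
            total_w = sum(len(f_values[c]) for c in means)
            fbar = sum(means[c] * len(f_values[c]) for c in means) / total_w
        enc += k / fbar
    return min(enc, sum(d * k for d, k in class_sizes.items()) + sum(
        1 for fam in code.families.values() if len(fam) == 1))


# ---------------------------------------------------------------------------
# random binary trees and their additive distance matrices
# ---------------------------------------------------------------------------

def random_additive_tree(rng: random.Random, n_taxa: int):
    """Random binary topology with positive branch lengths.

    Returns (newick, labels, distance dict (i,j)->d) built by sequential
    leaf attachment; distances are exact path lengths.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # adjacency with branch lengths
    nodes = {0: {}, 1: {}}
    edges = {}

    def connect(u, v, w):
        nodes.setdefault(u, {})[v] = w
        nodes.setdefault(v, {})[u] = w
        edges[frozenset((u, v))] = w

    next_id = [2]
    connect("L0", "L1", round(rng.uniform(0.2, 2.0), 3))
    nodes.pop(0), nodes.pop(1)
    for k in range(2, n_taxa):
        # split a random existing edge with a new internal node
        edge = rng.choice(sorted(edges, key=str))
        u, v = tuple(edge)
        w = edges.pop(edge)
        mid = f"I{next_id[0]}"
        next_id[0] += 1
        del nodes[u][v]
        del nodes[v][u]
        f1 = rng.uniform(0.25, 0.75)
        connect(u, mid, round(w * f1, 6))
        connect(mid, v, round(w - w * f1, 6))
        connect(mid, f"L{k}", round(rng.uniform(0.2, 2.0), 3))

    def path_length(a, b):
        stack = [(a, None, 0.0)]
        while stack:
            cur, prev, dist = stack.pop()
            if cur == b:
                return dist
            for nxt, w in nodes[cur].items():
                if nxt != prev:
                    stack.append((nxt, cur, dist + w))
        raise AssertionError("disconnected tree")

    dists = {}
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            dists[(labels[i], labels[j])] = path_length(f"L{i}", f"L{j}")

    def to_newick(cur, prev):
        children = [n for n in nodes[cur] if n != prev]
        if not children:
            return cur.replace("L", "T")
        inner = ",".join(
            f"{to_newick(c, cur)}:{nodes[cur][c]}" for c in sorted(children, key=str)
        )
        return f"({inner})"

    start = next(n for n in nodes if n.startswith("I")) if n_taxa > 2 else "L0"
    newick = to_newick(start, None) + ";"
    return newick, labels, dists
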