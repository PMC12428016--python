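"""Tandem repeat detection for mitochondrial control regions.

Seed-and-extend strategy over candidate periods: recurring k-mer spacings
nominate periods; for each period p the sequence is self-compared at lag p
and maximal positive-scoring segments (match +2, mismatch -7, the classic
TRF-style weights) are extended into repeat arrays. Each array gets a
column-majority consensus over its period phases and is re-scored and
end-trimmed against a tandem concatenation of that consensus; hits scoring
below the reporting threshold (default 30, the conventional minimum
alignment score) or spanning fewer than ~1.8 copies are discarded.

The alignment model is substitution-only: repeat copies are compared
column-wise without gaps, which suits control-region arrays whose copies
diverge mostly by point substitution. On sequences up to ~300 bp the seed
stage is skipped and every period is scanned exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class RepeatError(ValueError):
    pass


@dataclass(frozen=True)
class TandemRepeatHit:
    """One tandem repeat array.

    Coordinates are 1-based inclusive on the scanned sequence; for circular
    scans ``end`` may exceed the sequence length to denote a span wrapping
    the origin. ``copy_number`` is real-valued (fractional trailing copies
    are reported); ``identity`` is percent agreement with the consensus.
    """

    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    score: int
    identity: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _candidate_periods(seq: str, pmin: int, pmax: int, k: int = 5) -> list[int]:
    """Periods suggested by spacings between identical k-mers."""
    positions: dict[str, int] = {}
    votes: dict[int, int] = {}
    last: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in last:
            d = i - last[kmer]
            if pmin <= d <= pmax:
                votes[d] = votes.get(d, 0) + 1
        last[kmer] = i
    return sorted(p for p, v in votes.items() if v >= 2)


def _positive_segments(scores: np.ndarray, floor: int) -> list[tuple[int, int, int]]:
    """Maximal-scoring segments (start, end, score) of a score array,
    Kadane-style; disjoint segments whose peak reaches ``floor`` are kept."""
    segments = []
    running = 0
    seg_start = 0
    best = 0
    best_at = -1
    for i, s in enumerate(scores):
        running += int(s)
        if running > best:
            best, best_at = running, i
        if running <= 0:
            if best >= floor and best_at >= seg_start:
                segments.append((seg_start, best_at, best))
            running, best, best_at = 0, 0, -1
            seg_start = i + 1
    if best >= floor and best_at >= seg_start:
        segments.append((seg_start, best_at, best))
    return segments


def _consensus(arr: np.ndarray, start: int, end: int, period: int) -> str:
    """Column-majority consensus over the period phases of arr[start:end+1];
    ties break alphabetically."""
    cons = []
    for phase in range(period):
        col = arr[start + phase : end + 1 : period]
        if col.size == 0:
            col = arr[start + phase - period : end + 1 : period]
        bases, counts = np.unique(col, return_counts=True)
        order = np.lexsort((bases, -counts))  # by count desc, then base asc
        cons.append(chr(bases[order[0]]))
    return "".join(cons)


def _score_hit(
    arr: np.ndarray, start: int, end: int, period: int,
    match: int, mismatch: int, max_span: int | None,
) -> TandemRepeatHit | None:
    """Re-score a candidate span against its tandem consensus, trimming the
    ends to the best-scoring sub-span (consensus rotated accordingly)."""
    cons = _consensus(arr, start, end, period)
    cons_codes = np.frombuffer(cons.encode(), dtype=np.uint8)
    idx = (np.arange(start, end + 1) - start) % period
    contrib = np.where(arr[start : end + 1] == cons_codes[idx], match, mismatch)
    # best subarray of contrib (prefix-sum argmin trick)
    prefix = np.concatenate([[0], np.cumsum(contrib)])
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    j = int(np.argmax(gains))
    score = int(gains[j])
    i = int(np.argmin(prefix[: j + 1]))
    s2, e2 = start + i, start + j
    if max_span is not None and e2 - s2 + 1 > max_span:
        e2 = s2 + max_span - 1
        contrib2 = contrib[i : i + max_span]
        score = int(contrib2.sum())
    shift = (s2 - start) % period
    cons = cons[shift:] + cons[:shift]
    length = e2 - s2 + 1
    matches = (score - mismatch * length) / (match - mismatch)
    return TandemRepeatHit(
        start=s2 + 1,
        end=e2 + 1,
        period=period,
        copy_number=round(length / period, 2),
        consensus=cons,
        score=score,
        identity=round(100.0 * matches / length, 2),
    )


def _fundamental_period(consensus: str, pmin: int, threshold: float = 0.75) -> int | None:
    """Smallest divisor d of the consensus length at which the consensus is
    itself tandem-periodic (circular self-identity >= threshold), if any.

    A repeat of true period d also produces candidate arrays at every
    multiple k*d whose consensus is k near-copies of the motif; testing the
    consensus for internal periodicity identifies the fundamental period
    without rescoring every harmonic.
    """
    p = len(consensus)
    for d in range(max(2, pmin), p):
        if p % d:
            continue
        agree = sum(consensus[i] == consensus[(i + d) % p] for i in range(p))
        if agree / p >= threshold:
            return d
    return None


def find_tandem_repeats(
    seq: str,
    min_score: int = 30,
    period_range: tuple[int, int] = (2, 500),
    match: int = 2,
    mismatch: int = -7,
    min_copies: float = 1.8,
    circular: bool = False,
    exhaustive: bool | None = None,
) -> list[TandemRepeatHit]:
    """Detect tandem repeat arrays in a nucleotide sequence.

    Overlapping hits describing the same locus at different periods are
    reduced to the best-scoring one (ties prefer the shorter period, then
    the earlier start). Hits are returned sorted by start coordinate.
    """
    if not seq:
        raise RepeatError("empty sequence")
    seq = seq.upper()
    n = len(seq)
    pmin, pmax = period_range
    if pmin < 1:
        raise RepeatError("minimum period must be >= 1")
    if n < 2 * pmin:
        return []
    work = seq + seq if circular else seq
    pmax_eff = min(pmax, n // 2)
    if exhaustive is None:
        exhaustive = n <= 300
    if exhaustive:
        periods = list(range(pmin, pmax_eff + 1))
    else:
        periods = [p for p in _candidate_periods(work, pmin, pmax_eff) if p <= pmax_eff]

    arr = np.frombuffer(work.encode(), dtype=np.uint8)
    candidates: list[TandemRepeatHit] = []
    # pre-threshold generous: consensus re-scoring can only raise a segment's
    # score (majority consensus beats any single template copy on average)
    floor = max(1, min_score // 2)
    for p in periods:
        profile = np.where(arr[p:] == arr[:-p], match, mismatch)
        for seg_start, seg_end, _ in _positive_segments(profile, floor):
            span_start = seg_start  # profile index i corresponds to work[i + p]
            hit = _score_hit(
                arr, span_start, seg_end + p, p, match, mismatch,
                max_span=n if circular else None,
            )
            if hit is None:
                continue
            # collapse harmonic descriptions to the fundamental period
            d = _fundamental_period(hit.consensus, pmin)
            if d is not None:
                reduced = _score_hit(
                    arr, hit.start - 1, hit.end - 1, d, match, mismatch,
                    max_span=n if circular else None,
                )
                if reduced is not None and reduced.score >= min_score:
                    hit = reduced
            if hit.score >= min_score and hit.copy_number >= min_copies:
                if circular and hit.start > n:
                    continue  # duplicate image in the doubled sequence
                candidates.append(hit)

    # Suppress overlapping descriptions of the same locus. Raw score alone
    # favors period doubling (a 2p consensus memorizes per-copy noise), so
    # the selection key charges each description for its motif length
    # (score minus match * period, a minimum-description-length penalty);
    # the reported score stays the raw alignment score.
    candidates.sort(key=lambda h: (-(h.score - match * h.period), h.period, h.start))
    kept: list[TandemRepeatHit] = []
    for h in candidates:
        redundant = False
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start) + 1
            if ov > 0 and ov >= 0.5 * min(h.span, k.span):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.period))
    return kept


def repeat_report(
    record,
    min_score: int = 30,
    period_range: tuple[int, int] = (2, 500),
    genome_wide: bool = False,
) -> list[dict]:
    """Tandem repeats of a mitogenome's control region (optionally the whole
    genome), with CR-relative coordinates for cross-species layout tables."""
    crs = record.features_of_class("CR")
    if not crs:
        raise RepeatError("record has no annotated control region")
    cr = crs[0]
    from .annotation import extract_region

    rows = []
    if genome_wide:
        hits = find_tandem_repeats(
            record.sequence, min_score=min_score, period_range=period_range, circular=record.circular
        )
        for h in hits:
            inside = cr.start <= h.start and h.end <= cr.stop
            rows.append(_hit_row(h, region="CR" if inside else "genome",
                                 cr_start=h.start - cr.start + 1 if inside else None))
    else:
        cr_seq = extract_region(record, cr)
        for h in find_tandem_repeats(cr_seq, min_score=min_score, period_range=period_range):
            rows.append(_hit_row(h, region="CR", cr_start=h.start,
                                 absolute_start=cr.start + h.start - 1))
    return rows


def _hit_row(h: TandemRepeatHit, region: str, cr_start: int | None, absolute_start: int | None = None) -> dict:
    return {
        "region": region,
        "start": absolute_start if absolute_start is not None else h.start,
        "end": (absolute_start + h.span - 1) if absolute_start is not None else h.end,
        "cr_start": cr_start,
        "period": h.period,
        "copy_number": h.copy_number,
        "identity": h.identity,
        "score": h.score,
        "consensus": h.consensus,
    }
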