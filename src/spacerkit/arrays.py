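"""CRISPR array detection in genomes/contigs.

Two modes share one chaining core: the anchored mode scans for a supplied
repeat on both strands and chains non-overlapping occurrences whose gaps fall
within spacer length bounds; the de novo mode seeds on exact k-mers recurring
at array-like spacing, extends them to a majority-vote repeat consensus, and
then validates by running the anchored chainer with that consensus. Arrays
need at least three spacers; repeat length must be 23-47 and every spacer
26-50 (all configurable).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .seqs import decode, encode, revcomp, window_mismatches


@dataclass(frozen=True)
class ArrayParams:
    repeat_min: int = 23
    repeat_max: int = 47
    spacer_min: int = 26
    spacer_max: int = 50
    min_spacers: int = 3


DEFAULT_PARAMS = ArrayParams()


@dataclass
class CrisprArray:
    target_id: str
    start: int
    end: int
    repeat_consensus: str
    repeat_instances: List[Tuple[Tuple[int, int], int]]  # ((start, end), mismatches)
    spacers: List[str]          # array order, oriented to the repeat strand
    orientation: str            # '+', '-' or 'unknown'

    def validate(self, params: ArrayParams = DEFAULT_PARAMS) -> None:
        if len(self.spacers) < params.min_spacers:
            raise ValueError("array has fewer than the minimum number of spacers")
        if not params.repeat_min <= len(self.repeat_consensus) <= params.repeat_max:
            raise ValueError("repeat length out of bounds")
        for sp in self.spacers:
            if not params.spacer_min <= len(sp) <= params.spacer_max:
                raise ValueError("spacer length out of bounds")
        if len(self.repeat_instances) != len(self.spacers) + 1:
            raise ValueError("repeats and spacers must alternate")


def _full_matches(seq_arr: np.ndarray, repeat: str, max_mismatch: int):
    """Non-overlapping full-length repeat windows on both strands, greedy by
    (mismatches, position)."""
    m = len(repeat)
    candidates = []
    for strand, rep in (("+", repeat), ("-", revcomp(repeat))):
        mism = window_mismatches(seq_arr, encode(rep))
        for start in np.flatnonzero(mism <= max_mismatch):
            candidates.append((int(mism[start]), int(start), strand))
    candidates.sort()
    accepted: List[Tuple[int, int, str, int]] = []  # (start, end, strand, mm)
    taken: List[Tuple[int, int]] = []
    for mm, start, strand in candidates:
        end = start + m
        if any(s < end and start < e for s, e in taken):
            continue
        taken.append((start, end))
        accepted.append((start, end, strand, mm))
    accepted.sort()
    return accepted


def _chain(matches, params: ArrayParams):
    """Split a sorted same-strand match list into maximal runs with in-bounds gaps."""
    runs = []
    current = []
    for match in matches:
        if current:
            gap = match[0] - current[-1][1]
            if not params.spacer_min <= gap <= params.spacer_max:
                runs.append(current)
                current = []
        current.append(match)
    if current:
        runs.append(current)
    return [r for r in runs if len(r) >= params.min_spacers + 1]


def find_arrays_with_repeat(genome: Sequence[Tuple[str, str]], repeat: str,
                            max_mismatch: int = 5,
                            params: ArrayParams = DEFAULT_PARAMS) -> List[CrisprArray]:
    """Anchored array detection: chain repeat occurrences with spacer-sized gaps.

    ``genome`` is an iterable of (target_id, sequence). Spacers are reported in
    array order on the repeat's strand; for '-' arrays that is right-to-left
    on the target with each spacer reverse-complemented.
    """
    if not params.repeat_min <= len(repeat) <= params.repeat_max:
        raise ValueError(f"repeat length {len(repeat)} outside "
                         f"[{params.repeat_min},{params.repeat_max}]")
    arrays: List[CrisprArray] = []
    for tid, tseq in genome:
        seq_arr = encode(tseq)
        matches = _full_matches(seq_arr, repeat, max_mismatch)
        for strand in "+-":
            run_src = [m for m in matches if m[2] == strand]
            for run in _chain(run_src, params):
                spacers = [tseq[a[1]:b[0]] for a, b in zip(run, run[1:])]
                instances = [((s, e), mm) for s, e, _, mm in run]
                if strand == "-":
                    spacers = [revcomp(sp) for sp in reversed(spacers)]
                    instances = list(reversed(instances))
                arr = CrisprArray(target_id=tid, start=run[0][0], end=run[-1][1],
                                  repeat_consensus=repeat if strand == "+" else repeat,
                                  repeat_instances=instances, spacers=spacers,
                                  orientation=strand)
                arr.validate(params)
                arrays.append(arr)
    arrays.sort(key=lambda a: (a.target_id, a.start))
    return arrays


def _extend_seed(tseq: str, positions: List[int], k: int, params: ArrayParams,
                 agreement: float = 0.7, boundary_agreement: float = 0.9) -> Tuple[int, str]:
    """Grow an exact k-mer seed into a repeat consensus by majority vote.

    Extends left then right one column at a time while the column's modal base
    is shared by at least ``agreement`` of the instances and the repeat stays
    within length bounds. Extension columns are then trimmed back from both
    ends while their agreement is below ``boundary_agreement``: with few
    instances a spurious flanking column passes a 70% vote by chance alone,
    whereas true repeat boundary columns are near-perfectly conserved, so the
    stricter boundary rule pins the repeat/spacer border. Returns
    (left_extension, consensus).
    """
    n = len(tseq)
    min_gap = min(positions[i + 1] - positions[i] for i in range(len(positions) - 1))
    max_len = min(params.repeat_max, min_gap - params.spacer_min + k)

    def column_stats(offsets: List[int]) -> Tuple[float, str]:
        bases = [tseq[o] for o in offsets if 0 <= o < n]
        if len(bases) < len(positions):
            return 0.0, ""
        top = max(set(bases), key=lambda b: (bases.count(b), b))
        return bases.count(top) / len(bases), top

    left = 0
    length = k
    while length < max_len:
        frac, _ = column_stats([p - left - 1 for p in positions])
        if frac < agreement:
            break
        left += 1
        length += 1
    right = 0
    while length < max_len:
        frac, _ = column_stats([p + k + right for p in positions])
        if frac < agreement:
            break
        right += 1
        length += 1

    while left > 0:
        frac, _ = column_stats([p - left for p in positions])
        if frac >= boundary_agreement:
            break
        left -= 1
    while right > 0:
        frac, _ = column_stats([p + k + right - 1 for p in positions])
        if frac >= boundary_agreement:
            break
        right -= 1

    cols = []
    for off in range(-left, k + right):
        _, top = column_stats([p + off for p in positions])
        cols.append(top)
    return left, "".join(cols)


def find_arrays_denovo(genome: Sequence[Tuple[str, str]],
                       params: ArrayParams = DEFAULT_PARAMS, k: int = 13,
                       max_mismatch: int = 5) -> List[CrisprArray]:
    """De novo array detection by k-mer seeding and consensus validation.

    Exact k-mers recurring >= 3 times at array-like spacing
    (repeat_min+spacer_min .. repeat_max+spacer_max between consecutive
    occurrences) are extended to a repeat consensus; candidate consensuses are
    then re-scanned with the anchored chainer, which enforces the structural
    bounds. Overlapping candidate arrays are resolved by (most repeat
    instances, fewest total mismatches, longest repeat, position).
    Orientation is 'unknown'.
    """
    gap_lo = params.repeat_min + params.spacer_min
    gap_hi = params.repeat_max + params.spacer_max
    results: List[CrisprArray] = []
    for tid, tseq in genome:
        if len(tseq) < k:
            continue
        index: Dict[str, List[int]] = {}
        for i in range(len(tseq) - k + 1):
            kmer = tseq[i:i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(i)

        consensuses: Dict[str, None] = {}
        for kmer in sorted(index):
            positions = index[kmer]
            if len(positions) < 3:
                continue
            run: List[int] = []
            runs: List[List[int]] = []
            for p in positions:
                if run and not gap_lo <= p - run[-1] <= gap_hi:
                    runs.append(run)
                    run = []
                run.append(p)
            runs.append(run)
            for r in runs:
                if len(r) < 3:
                    continue
                _, consensus = _extend_seed(tseq, r, k, params)
                if params.repeat_min <= len(consensus) <= params.repeat_max:
                    consensuses.setdefault(consensus)

        candidates: List[CrisprArray] = []
        for consensus in consensuses:
            try:
                found = find_arrays_with_repeat([(tid, tseq)], consensus,
                                                max_mismatch=max_mismatch, params=params)
            except ValueError:
                continue
            candidates.extend(found)

        # resolve overlaps: prefer more repeat instances, then the consensus
        # that explains them with fewest total mismatches, then longer repeats
        candidates.sort(key=lambda a: (-len(a.repeat_instances),
                                       sum(mm for _, mm in a.repeat_instances),
                                       -len(a.repeat_consensus), a.start))
        chosen: List[CrisprArray] = []
        for cand in candidates:
            if any(c.start < cand.end and cand.start < c.end for c in chosen):
                continue
            cand.orientation = "unknown"
            chosen.append(cand)
        chosen.sort(key=lambda a: a.start)
        results.extend(chosen)
    results.sort(key=lambda a: (a.target_id, a.start))
    return results


def arrays_to_rows(arrays: Sequence[CrisprArray]) -> List[dict]:
    rows = []
    for i, a in enumerate(arrays, start=1):
        rows.append({"array_id": f"a{i:03d}", "target_id": a.target_id,
                     "start": a.start + 1, "end": a.end,  # 1-based inclusive for TSV
                     "n_repeats": len(a.repeat_instances),
                     "n_spacers": len(a.spacers),
                     "repeat_consensus": a.repeat_consensus,
                     "orientation": a.orientation,
                     "spacers": ",".join(a.spacers)})
    return rows
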