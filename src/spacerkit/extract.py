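"""Quality trimming, repeat anchoring, and spacer extraction.

Repeat matching is an ungapped Hamming scan against the consensus on both
strands; full-length windows are selected greedily by (fewest mismatches,
leftmost) with no overlaps, and primer-truncated terminal repeats are located
by anchored suffix/prefix comparison. Spacers are the inter-repeat gaps within
configured length bounds, orientation-normalized to the repeat's + strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .seqs import FastqRead, encode, hamming, revcomp, window_mismatches
from .simulate import RepeatModel

logger = logging.getLogger(__name__)

TERMINAL_5 = "5'-terminal"
TERMINAL_3 = "3'-terminal"

DEFAULT_LENGTH_BOUNDS = (26, 50)


class MixedStrandError(ValueError):
    """Repeat matches on both strands of one read; the read is not a single array fragment."""


@dataclass(frozen=True)
class RepeatMatch:
    read_id: str
    start: int          # 0-based half-open on the read
    end: int
    strand: str         # '+' or '-'
    mismatches: int
    full: bool          # full repeat window vs primer-truncated terminal match

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class SpacerRecord:
    sequence: str       # normalized to the repeat's + strand
    read_id: str
    site: str
    left_variant: str   # repeat variant id or terminal marker
    right_variant: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TrimStats:
    total: int = 0
    kept: int = 0
    dropped_n: int = 0
    dropped_short: int = 0


def trim_reads(reads: Iterable[FastqRead], min_quality: int = 20,
               min_length: int = 50) -> Tuple[List[FastqRead], TrimStats]:
    """3'-trim low-quality tails, drop reads with Ns or shorter than ``min_length``.

    Trailing bases are removed while the terminal base quality is below
    ``min_quality``; reads still containing an ambiguous base are discarded.
    """
    stats = TrimStats()
    kept: List[FastqRead] = []
    for r in reads:
        stats.total += 1
        seq, quals = r.sequence, r.qualities
        if len(seq) != len(quals):
            raise ValueError(f"malformed record {r.read_id}: sequence/quality length mismatch")
        end = len(seq)
        while end > 0 and quals[end - 1] < min_quality:
            end -= 1
        seq, quals = seq[:end], quals[:end]
        if "N" in seq:
            stats.dropped_n += 1
            continue
        if len(seq) < min_length:
            stats.dropped_short += 1
            continue
        stats.kept += 1
        kept.append(FastqRead(r.read_id, seq, quals))
    logger.info("trim: kept %d/%d (dropped %d with N, %d short)",
                stats.kept, stats.total, stats.dropped_n, stats.dropped_short)
    return kept, stats


def _as_model(repeat) -> RepeatModel:
    return repeat if isinstance(repeat, RepeatModel) else RepeatModel(consensus=repeat)


def find_repeat_matches(sequence: str, repeat, max_mismatch: int = 5,
                        allow_terminal_partial: bool = True,
                        read_id: str = "") -> List[RepeatMatch]:
    """Locate repeat occurrences on both strands of one read.

    Full-length consensus windows within ``max_mismatch`` are selected greedily
    by (mismatches, position, strand) without overlaps. When
    ``allow_terminal_partial``, partial repeats anchored at the read ends
    (>= the shortest primer length) are reported with ``full=False``: at the
    5' end a repeat *suffix*, at the 3' end a repeat *prefix*, per the
    amplification geometry.
    """
    model = _as_model(repeat)
    cons = model.consensus
    m = len(cons)
    seq_arr = encode(sequence)
    oriented = {"+": encode(cons), "-": encode(revcomp(cons))}

    candidates = []
    for strand in "+-":
        mism = window_mismatches(seq_arr, oriented[strand])
        for start in np.flatnonzero(mism <= max_mismatch):
            candidates.append((int(mism[start]), int(start), strand))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    accepted: List[RepeatMatch] = []
    for mm, start, strand in candidates:
        if any(a.overlaps(start, start + m) for a in accepted):
            continue
        accepted.append(RepeatMatch(read_id, start, start + m, strand, mm, True))

    if allow_terminal_partial:
        min_len = model.min_primer_length
        strands = {a.strand for a in accepted} or {"+", "-"}
        for side in ("left", "right"):
            best = None  # (mm, -L, strand)
            for strand in sorted(strands):
                rep = oriented[strand]
                max_l = min(len(sequence), m - 1)
                for L in range(max_l, min_len - 1, -1):
                    if side == "left":
                        start, end = 0, L
                        mm = int(np.count_nonzero(seq_arr[:L] != rep[m - L:]))
                    else:
                        start, end = len(sequence) - L, len(sequence)
                        mm = int(np.count_nonzero(seq_arr[len(sequence) - L:] != rep[:L]))
                    if mm > max_mismatch:
                        continue
                    if any(a.overlaps(start, end) for a in accepted):
                        continue
                    key = (mm, -L, strand)
                    if best is None or key < best[0]:
                        best = (key, RepeatMatch(read_id, start, end, strand, mm, False))
            if best is not None:
                accepted.append(best[1])

    accepted.sort(key=lambda a: a.start)
    return accepted


def extract_spacers(read: str, matches: List[RepeatMatch],
                    length_bounds: Tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
                    repeat: Optional[RepeatModel] = None,
                    site: str = "", read_id: str = "") -> List[SpacerRecord]:
    """Emit the inter-repeat gaps of one read as orientation-normalized spacers.

    Raises :class:`MixedStrandError` when the matches disagree on strand.
    Gaps outside ``length_bounds`` are silently not emitted. Flanking repeat
    variant ids are recorded (terminal markers for primer-truncated ends).
    """
    if not matches:
        return []
    strands = {m.strand for m in matches}
    if len(strands) > 1:
        raise MixedStrandError(f"read {read_id or matches[0].read_id} has mixed-strand repeat matches")
    strand = strands.pop()
    matches = sorted(matches, key=lambda m: m.start)
    rid = read_id or matches[0].read_id
    lo, hi = length_bounds

    def variant_of(match: RepeatMatch) -> str:
        if not match.full:
            window = read[match.start:match.end]
            if strand == "-":
                window = revcomp(window)
            # a suffix match sits at the read 5' end on '+', at the 3' end on '-'
            is_suffix = (match.start == 0) == (strand == "+")
            return TERMINAL_5 if is_suffix else TERMINAL_3
        if repeat is None:
            return "v?"
        window = read[match.start:match.end]
        if strand == "-":
            window = revcomp(window)
        return repeat.variant_id_of(window)

    records: List[SpacerRecord] = []
    for left, right in zip(matches, matches[1:]):
        gap = read[left.end:right.start]
        if not lo <= len(gap) <= hi:
            continue
        if strand == "+":
            records.append(SpacerRecord(gap, rid, site, variant_of(left), variant_of(right)))
        else:
            records.append(SpacerRecord(revcomp(gap), rid, site, variant_of(right), variant_of(left)))
    if strand == "-":
        records.reverse()
    return records


def collect_internal_repeats(read: str, matches: List[RepeatMatch],
                             length_bounds: Tuple[int, int] = DEFAULT_LENGTH_BOUNDS) -> List[str]:
    """Sequences of full repeat matches flanked by emitted spacers on both sides,
    oriented to the repeat's + strand."""
    if len({m.strand for m in matches}) != 1:
        return []
    matches = sorted(matches, key=lambda m: m.start)
    lo, hi = length_bounds
    out = []
    for i in range(1, len(matches) - 1):
        m = matches[i]
        if not m.full:
            continue
        gap_left = m.start - matches[i - 1].end
        gap_right = matches[i + 1].start - m.end
        if lo <= gap_left <= hi and lo <= gap_right <= hi:
            window = read[m.start:m.end]
            out.append(window if m.strand == "+" else revcomp(window))
    return out


def internal_repeat_table(internal_seqs: Iterable[str]) -> pd.DataFrame:
    """Exact-sequence census of internal repeats: (variant_seq, count, frequency)."""
    counts: dict = {}
    for s in internal_seqs:
        counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    rows = [{"variant_seq": s, "count": c, "frequency": c / total if total else 0.0}
            for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["variant_seq", "count", "frequency"])


@dataclass
class ExtractionResult:
    records: List[SpacerRecord] = field(default_factory=list)
    internal_repeats: List[str] = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def spacer_multiset(self) -> dict:
        counts: dict = {}
        for r in self.records:
            counts[r.sequence] = counts.get(r.sequence, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"site": r.site, "read_id": r.read_id, "spacer": r.sequence,
              "length": r.length, "left_variant": r.left_variant,
              "right_variant": r.right_variant} for r in self.records],
            columns=["site", "read_id", "spacer", "length", "left_variant", "right_variant"])


def process_reads(reads: Iterable[FastqRead], repeat: RepeatModel, site: str = "",
                  max_mismatch: int = 5,
                  length_bounds: Tuple[int, int] = DEFAULT_LENGTH_BOUNDS) -> ExtractionResult:
    """Full per-site extraction: anchor repeats, emit spacers, census internal repeats."""
    result = ExtractionResult(stats={
        "reads": 0, "mixed_strand_skipped": 0, "no_match": 0, "spacers": 0})
    for read in reads:
        result.stats["reads"] += 1
        matches = find_repeat_matches(read.sequence, repeat, max_mismatch=max_mismatch,
                                      read_id=read.read_id)
        if not matches:
            result.stats["no_match"] += 1
            continue
        try:
            records = extract_spacers(read.sequence, matches, length_bounds=length_bounds,
                                      repeat=repeat, site=site, read_id=read.read_id)
        except MixedStrandError:
            result.stats["mixed_strand_skipped"] += 1
            logger.debug("skipping mixed-strand read %s", read.read_id)
            continue
        result.records.extend(records)
        result.stats["spacers"] += len(records)
        result.internal_repeats.extend(
            collect_internal_repeats(read.sequence, matches, length_bounds))
    return result
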