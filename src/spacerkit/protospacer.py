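"""Protospacer scanning and PAM inference.

Targets are scanned exhaustively: every full-length ungapped window on both
strands is scored by Hamming distance, replacing the seeded heuristic search a
read-mapping tool would use — strictly more sensitive at spacer-sized query
lengths and fully deterministic. Hits keep their 8-nt flanks oriented on the
protospacer's strand; "downstream" is 3' of the protospacer on that strand.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .seqs import encode, revcomp, window_mismatches

logger = logging.getLogger(__name__)

FLANK = 8
_BASES = "ACGT"

MIN_QUERY_LENGTH = 20


@dataclass(frozen=True)
class ProtospacerHit:
    query_id: str
    target_id: str
    start: int        # 0-based half-open, target + strand coordinates
    end: int
    strand: str
    mismatches: int
    upstream_flank: str    # 5' of the protospacer on its strand, may be < 8 nt at edges
    downstream_flank: str

    @property
    def edge_truncated(self) -> bool:
        return len(self.upstream_flank) < FLANK or len(self.downstream_flank) < FLANK


def scan_protospacers(queries: Sequence[Tuple[str, str]],
                      targets: Iterable[Tuple[str, str]],
                      max_mismatch: int = 4) -> List[ProtospacerHit]:
    """All full-length window matches of each query on both target strands.

    A window is a hit when its Hamming distance to the query is at most
    ``max_mismatch`` (default 4, i.e. hits require < 5 mismatches). ``N`` in a
    target never matches. Queries shorter than 20 nt are rejected.
    """
    targets = list(targets)
    hits: List[ProtospacerHit] = []
    for qid, qseq in queries:
        if len(qseq) < MIN_QUERY_LENGTH:
            raise ValueError(f"query {qid} shorter than {MIN_QUERY_LENGTH} nt")
        q_fwd = encode(qseq)
        q_rev = encode(revcomp(qseq))
        L = len(qseq)
        for tid, tseq in targets:
            t_arr = encode(tseq)
            n = len(tseq)
            for strand, q_arr in (("+", q_fwd), ("-", q_rev)):
                mism = window_mismatches(t_arr, q_arr)
                for start in np.flatnonzero(mism <= max_mismatch):
                    start = int(start)
                    end = start + L
                    left = tseq[max(start - FLANK, 0):start]
                    right = tseq[end:end + FLANK]
                    if strand == "+":
                        up, down = left, right
                    else:
                        up, down = revcomp(right), revcomp(left)
                    hits.append(ProtospacerHit(qid, tid, start, end, strand,
                                               int(mism[start]), up, down))
    hits.sort(key=lambda h: (h.query_id, h.target_id, h.start, h.strand))
    return hits


@dataclass
class PamProfile:
    side: str                 # 'upstream' or 'downstream'
    counts: np.ndarray        # (4, 8) base counts, rows A,C,G,T
    information_content: np.ndarray  # (8,) bits
    n_hits: int

    def column_fractions(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def to_json_dict(self) -> dict:
        return {"side": self.side, "n_hits": self.n_hits,
                "counts": {b: self.counts[i].tolist() for i, b in enumerate(_BASES)},
                "information_content": [round(float(x), 6)
                                        for x in self.information_content]}


def pam_profile(hits: Sequence[ProtospacerHit], side: str = "downstream") -> PamProfile:
    """Position-wise base counts and information content over the 8-nt flank.

    Positions are numbered 1-8 away from the protospacer. IC_j = 2 +
    sum_b p_bj log2 p_bj, no small-sample correction. Only hits with a
    full-length flank on the requested side are used; fewer than 2 is an error.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    flanks = []
    for h in hits:
        f = h.upstream_flank if side == "upstream" else h.downstream_flank
        if len(f) == FLANK and all(c in _BASES for c in f):
            # upstream flanks read 5'->3'; position 1 is adjacent to the protospacer
            flanks.append(f[::-1] if side == "upstream" else f)
    if len(flanks) < 2:
        raise ValueError("insufficient hits: need >= 2 full flanks")
    counts = np.zeros((4, FLANK), dtype=np.int64)
    for f in flanks:
        for j, c in enumerate(f):
            counts[_BASES.index(c), j] += 1
    p = counts / counts.sum(axis=0, keepdims=True)
    ic = np.zeros(FLANK)
    for j in range(FLANK):
        ent = -sum(p[b, j] * math.log2(p[b, j]) for b in range(4) if p[b, j] > 0)
        ic[j] = 2.0 - ent
    return PamProfile(side=side, counts=counts, information_content=ic,
                      n_hits=len(flanks))


def call_pam(profile: PamProfile, ic_min: float = 0.5,
             consensus_fraction: float = 0.5) -> str:
    """Motif over {A,C,G,T,N}: the modal base where the column is informative
    (IC >= ic_min and modal fraction >= consensus_fraction), else N. N's are
    retained at both ends so offsets stay readable."""
    fracs = profile.column_fractions()
    out = []
    for j in range(FLANK):
        b = int(profile.counts[:, j].argmax())
        if (profile.information_content[j] >= ic_min
                and fracs[b, j] >= consensus_fraction):
            out.append(_BASES[b])
        else:
            out.append("N")
    return "".join(out)
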