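"""Radius-certified clustering of spacers by substitution distance.

Spacers are partitioned by length class (substitution counts are undefined
across lengths without alignment); within a class a bisecting k-means over the
sequences runs until every cluster's maximum member-to-consensus Hamming
distance is within the radius (default 5 substitutions). Cluster centers are
per-position count-weighted majority consensus strings, so they remain valid
DNA queries for downstream protospacer searches. The whole procedure is
deterministic: input is canonicalized by (sequence, count), initialization is
farthest-point from the most abundant member, and all ties break by fixed
order.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqs import DNA_ALPHABET, decode, encode

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SpacerCluster:
    cluster_id: str
    site: str
    consensus: str
    members: List[Tuple[str, int]]   # (sequence, count)
    abundance: int
    max_radius: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def consensus_of(sequences: Sequence[Tuple[str, int]]) -> str:
    """Count-weighted per-position majority base; ties break A<C<G<T."""
    if not sequences:
        raise ValueError("empty input")
    L = len(sequences[0][0])
    if any(len(s) != L for s, _ in sequences):
        raise ValueError("sequences must have equal lengths")
    if sum(c for _, c in sequences) < 1:
        raise ValueError("total count must be >= 1")
    X = np.stack([encode(s) for s, _ in sequences])
    w = np.array([c for _, c in sequences], dtype=np.int64)
    counts = np.zeros((4, L), dtype=np.int64)
    for b, byte in enumerate(_BASE_BYTES):
        counts[b] = ((X == byte) * w[:, None]).sum(axis=0)
    best = counts.argmax(axis=0)  # argmax returns the first max: A<C<G<T tie rule
    return "".join(DNA_ALPHABET[b] for b in best)


def _weighted_consensus(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    counts = np.zeros((4, X.shape[1]), dtype=np.int64)
    for b, byte in enumerate(_BASE_BYTES):
        counts[b] = ((X == byte) * w[:, None]).sum(axis=0)
    return _BASE_BYTES[counts.argmax(axis=0)]


def _dists(X: np.ndarray, center: np.ndarray) -> np.ndarray:
    return np.count_nonzero(X != center, axis=1)


def _bisect(X: np.ndarray, w: np.ndarray, idx: np.ndarray, max_iter: int = 100):
    """Split one cluster into two by Lloyd 2-means on Hamming distance.

    Centers start from the most abundant member and the member farthest from
    it; consensus recomputation keeps centers as concrete sequences. Returns
    (idx_a, idx_b), both non-empty.
    """
    sub, subw = X[idx], w[idx]
    seed_a = int(np.argmax(subw))  # canonical order makes this deterministic
    d = _dists(sub, sub[seed_a])
    seed_b = int(np.argmax(d))
    ca, cb = sub[seed_a].copy(), sub[seed_b].copy()
    assign = None
    for _ in range(max_iter):
        da, db = _dists(sub, ca), _dists(sub, cb)
        new_assign = da <= db
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        if assign.all() or not assign.any():
            # degenerate: isolate the farthest point
            assign = np.ones(len(sub), dtype=bool)
            assign[seed_b] = False
            break
        ca = _weighted_consensus(sub[assign], subw[assign])
        cb = _weighted_consensus(sub[~assign], subw[~assign])
    return idx[assign], idx[~assign]


def _cluster_length_class(X: np.ndarray, w: np.ndarray, radius: int):
    """Bisect until certified, then refine by global reassignment and
    certificate-preserving merges. Returns a list of index arrays."""
    n = len(X)
    clusters = [np.arange(n)]
    # Phase 1: split any cluster violating the radius certificate.
    done: List[np.ndarray] = []
    while clusters:
        idx = clusters.pop()
        center = _weighted_consensus(X[idx], w[idx])
        if _dists(X[idx], center).max() <= radius:
            done.append(idx)
            continue
        a, b = _bisect(X, w, idx)
        clusters.extend([b, a])

    # Phase 2: global Lloyd passes (reassign to nearest center), re-splitting
    # if a pass breaks a certificate.
    for _ in range(10):
        done.sort(key=lambda i: int(i.min()))
        centers = np.stack([_weighted_consensus(X[i], w[i]) for i in done])
        dmat = np.stack([_dists(X, c) for c in centers])  # (k, n)
        labels = dmat.argmin(axis=0)
        new = [np.flatnonzero(labels == k) for k in range(len(done))]
        new = [i for i in new if len(i)]
        if len(new) == len(done) and all(np.array_equal(a, b) for a, b in
                                         zip(sorted(new, key=lambda i: int(i.min())),
                                             sorted(done, key=lambda i: int(i.min())))):
            break
        fixed: List[np.ndarray] = []
        pending = list(new)
        while pending:
            idx = pending.pop()
            center = _weighted_consensus(X[idx], w[idx])
            if _dists(X[idx], center).max() <= radius:
                fixed.append(idx)
            else:
                a, b = _bisect(X, w, idx)
                pending.extend([b, a])
        done = fixed

    # Phase 3: greedy certificate-preserving merges (undo over-splitting).
    if len(done) > 1 and len(done) <= 2000:
        done.sort(key=lambda i: int(i.min()))
        merged = True
        while merged and len(done) > 1:
            merged = False
            centers = [_weighted_consensus(X[i], w[i]) for i in done]
            pairs = []
            for a in range(len(done)):
                for b in range(a + 1, len(done)):
                    cd = int(np.count_nonzero(centers[a] != centers[b]))
                    if cd <= 2 * radius:
                        pairs.append((cd, a, b))
            pairs.sort()
            for _, a, b in pairs:
                idx = np.sort(np.concatenate([done[a], done[b]]))
                center = _weighted_consensus(X[idx], w[idx])
                if _dists(X[idx], center).max() <= radius:
                    done = [c for k, c in enumerate(done) if k not in (a, b)] + [idx]
                    merged = True
                    break
    return done


def cluster_spacers(records, radius: int = 5, seed: int = 0) -> List[SpacerCluster]:
    """Cluster spacer records (or plain sequences) into radius-certified groups.

    ``seed`` is accepted for interface stability; the algorithm is fully
    deterministic and does not consume randomness. Output clusters are sorted
    by (descending abundance, consensus) and assigned ids ``c00001``...
    """
    del seed
    seqs: List[str] = []
    site = ""
    for r in records:
        s = getattr(r, "sequence", r)
        site = getattr(r, "site", site) or site
        if not s or any(c not in DNA_ALPHABET for c in s):
            raise ValueError(f"non-ACGT spacer sequence: {s!r}")
        seqs.append(s)
    if not seqs:
        raise ValueError("no records to cluster")

    counts: dict = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    # canonical order: independent of read order
    uniq = sorted(counts.items())

    by_length: dict = {}
    for s, c in uniq:
        by_length.setdefault(len(s), []).append((s, c))

    clusters: List[SpacerCluster] = []
    for L in sorted(by_length):
        items = by_length[L]
        X = np.stack([encode(s) for s, _ in items])
        w = np.array([c for _, c in items], dtype=np.int64)
        for idx in _cluster_length_class(X, w, radius):
            members = [items[i] for i in idx]
            center = _weighted_consensus(X[idx], w[idx])
            radius_seen = int(_dists(X[idx], center).max())
            assert radius_seen <= radius, "radius certificate violated"
            clusters.append(SpacerCluster(
                cluster_id="", site=site, consensus=decode(center),
                members=members, abundance=int(w[idx].sum()),
                max_radius=radius_seen))
    clusters.sort(key=lambda c: (-c.abundance, c.consensus))
    for i, c in enumerate(clusters):
        c.cluster_id = f"c{i + 1:05d}"
    return clusters


def clusters_to_frame(clusters: List[SpacerCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"site": c.site, "cluster_id": c.cluster_id, "consensus": c.consensus,
          "abundance": c.abundance, "n_members": c.n_members,
          "max_radius": c.max_radius} for c in clusters],
        columns=["site", "cluster_id", "consensus", "abundance", "n_members", "max_radius"])


def abundance_vector(clusters: List[SpacerCluster]) -> List[int]:
    return [c.abundance for c in clusters]
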