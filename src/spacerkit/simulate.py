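"""Ground-truthed synthetic community generator.

Produces site spacer pools with an exact overlap design, primer-anchored
amplicon reads (truncated terminal repeats, full internal repeats drawn from a
variant distribution, iid substitution errors), and target genomes with
planted protospacers carrying a PAM at configurable downstream offsets.
Every emitted read is derivable from the returned truth object, and identical
seeds give byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .seqs import DNA_ALPHABET, FastqRead, hamming, mutate, random_dna, revcomp

DEFAULT_LENGTH_WEIGHTS = {28: 1.0, 29: 1.0, 30: 1.0, 31: 1.0}
DEFAULT_SPACERS_PER_FRAGMENT = {1: 0.40, 2: 0.30, 3: 0.15, 4: 0.10, 5: 0.05}

REPEAT_LEN_BOUNDS = (23, 47)
SPACER_LEN_BOUNDS = (26, 50)


class OverlapDesignError(ValueError):
    """Raised when a requested pool overlap design is infeasible."""


@dataclass(frozen=True)
class RepeatModel:
    """A direct-repeat consensus, its natural variants, and the two primers.

    Primers anneal within the repeat: the forward primer is a substring of the
    consensus, the reverse primer a substring of its reverse complement. The
    amplicon therefore starts/ends with primer-truncated partial repeats.
    """

    consensus: str
    variants: tuple = ()  # ((sequence, frequency), ...), frequencies sum to 1
    forward_primer: str = ""
    reverse_primer: str = ""
    primer_mismatches: int = 0

    def __post_init__(self):
        lo, hi = REPEAT_LEN_BOUNDS
        if not lo <= len(self.consensus) <= hi:
            raise ValueError(f"repeat length {len(self.consensus)} outside [{lo},{hi}]")
        if not all(c in DNA_ALPHABET for c in self.consensus):
            raise ValueError("repeat consensus contains ambiguous bases")
        if self.variants:
            total = sum(f for _, f in self.variants)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"variant frequencies sum to {total}, expected 1")
            for seq, _ in self.variants:
                if len(seq) != len(self.consensus):
                    raise ValueError("variant length differs from consensus")
        for primer, where in ((self.forward_primer, self.consensus),
                              (self.reverse_primer, revcomp(self.consensus))):
            if primer and self._best_offset(primer, where)[1] > self.primer_mismatches:
                raise ValueError("primer does not anneal within the repeat")

    @staticmethod
    def _best_offset(primer: str, template: str):
        best = (0, len(primer) + 1)
        for off in range(len(template) - len(primer) + 1):
            mm = hamming(primer, template[off:off + len(primer)])
            if mm < best[1]:
                best = (off, mm)
        return best

    @property
    def variant_table(self) -> tuple:
        """((variant_id, sequence, frequency), ...); defaults to the consensus alone."""
        variants = self.variants or ((self.consensus, 1.0),)
        return tuple((f"v{i + 1}", seq, freq) for i, (seq, freq) in enumerate(variants))

    def variant_id_of(self, sequence: str) -> str:
        """Id of the nearest declared variant (ties to the first listed)."""
        best_id, best_mm = "v1", len(self.consensus) + 1
        for vid, vseq, _ in self.variant_table:
            mm = hamming(sequence, vseq)
            if mm < best_mm:
                best_id, best_mm = vid, mm
        return best_id

    @property
    def left_terminal(self) -> str:
        """Partial repeat at the amplicon 5' end: consensus from the forward
        primer's annealing position to the repeat end."""
        if not self.forward_primer:
            return self.consensus
        off, _ = self._best_offset(self.forward_primer, self.consensus)
        return self.consensus[off:]

    @property
    def right_terminal(self) -> str:
        """Partial repeat at the amplicon 3' end: consensus prefix up to the
        reverse primer's annealing position."""
        if not self.reverse_primer:
            return self.consensus
        off, _ = self._best_offset(self.reverse_primer, revcomp(self.consensus))
        return self.consensus[:len(self.consensus) - off]

    @property
    def min_primer_length(self) -> int:
        lengths = [len(p) for p in (self.forward_primer, self.reverse_primer) if p]
        return min(lengths) if lengths else 15

    @classmethod
    def random(cls, seed: int = 0, length: int = 46,
               variant_freqs: Sequence[float] = (1.0,),
               fwd_len: int = 31, rev_len: int = 25) -> "RepeatModel":
        """Random repeat with primers mimicking the amplification geometry and
        variants differing from the consensus at distinct single positions."""
        rng = np.random.default_rng(seed)
        consensus = random_dna(rng, length)
        variants = [consensus]
        used = set()
        for _ in range(len(variant_freqs) - 1):
            pos = int(rng.integers(5, length - 5))
            while pos in used:
                pos = int(rng.integers(5, length - 5))
            used.add(pos)
            base = consensus[pos]
            alt = [b for b in DNA_ALPHABET if b != base][int(rng.integers(3))]
            prev = variants[-1]
            variants.append(prev[:pos] + alt + prev[pos + 1:])
        fwd_off = 5
        fwd = consensus[fwd_off:fwd_off + fwd_len]
        rev = revcomp(consensus[:rev_len])
        return cls(consensus=consensus,
                   variants=tuple(zip(variants, variant_freqs)),
                   forward_primer=fwd, reverse_primer=rev)


@dataclass(frozen=True)
class SitePools:
    """Per-site pools of unique true spacers with an exact overlap design."""

    site_names: tuple
    pools: Mapping[str, tuple]           # site -> tuple of spacer strings
    overlap_design: Mapping              # frozenset(sites) -> exclusive region size
    abundance_weights: Mapping[str, tuple]  # site -> per-spacer sampling weights

    def pool(self, site: str) -> tuple:
        return self.pools[site]

    def realized_regions(self) -> dict:
        """Exclusive Venn-region sizes computed from the pools by set arithmetic."""
        sets = {s: set(self.pools[s]) for s in self.site_names}
        universe = set().union(*sets.values())
        regions: dict = {}
        for spacer in universe:
            key = frozenset(s for s in self.site_names if spacer in sets[s])
            regions[key] = regions.get(key, 0) + 1
        return regions


@dataclass
class SyntheticTruth:
    """Everything needed to verify downstream recovery of a simulated run."""

    pools: SitePools
    repeat: RepeatModel
    error_rate: float
    seed: int
    reads: list = field(default_factory=list)
    # each read entry: dict(read_id, site, spacers=[...], variants=[...])

    def planted_multiset(self, site: str) -> dict:
        counts: dict = {}
        for entry in self.reads:
            if entry["site"] != site:
                continue
            for sp in entry["spacers"]:
                counts[sp] = counts.get(sp, 0) + 1
        return counts

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "error_rate": self.error_rate,
            "sites": list(self.pools.site_names),
            "pool_sizes": {s: len(self.pools.pools[s]) for s in self.pools.site_names},
            "repeat_consensus": self.repeat.consensus,
            "variants": [[vid, seq, freq] for vid, seq, freq in self.repeat.variant_table],
            "n_reads": len(self.reads),
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsite\tspacers\tvariants\n")
            for entry in self.reads:
                fh.write("{}\t{}\t{}\t{}\n".format(
                    entry["read_id"], entry["site"],
                    ",".join(entry["spacers"]), ",".join(entry["variants"])))

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _normalize_pairwise(pairwise_shared, n_sites: int) -> np.ndarray:
    mat = np.asarray(pairwise_shared, dtype=int)
    if mat.ndim == 0:
        mat = np.full((n_sites, n_sites), int(mat))
    if mat.shape != (n_sites, n_sites):
        raise ValueError(f"pairwise_shared must be {n_sites}x{n_sites}")
    if not np.array_equal(mat, mat.T):
        raise OverlapDesignError("pairwise_shared matrix must be symmetric")
    return mat


def make_site_pools(n_sites: int, pool_sizes: Sequence[int], pairwise_shared,
                    length_weights: Optional[Mapping[int, float]] = None,
                    seed: int = 0, shared_all: int = 0,
                    min_separation: int = 11,
                    site_names: Optional[Sequence[str]] = None) -> SitePools:
    """Draw per-site spacer pools realizing an exact overlap design.

    ``pairwise_shared[i][j]`` is the total number of spacers shared between
    sites i and j (including any in ``shared_all``, the region common to every
    site). Intermediate regions (shared by >2 but not all sites) are not
    modelled. Spacers are sampled uniformly over ACGT with rejection so that
    equal-length spacers are pairwise separated by more than ``min_separation``
    substitutions, making downstream truth clusters unambiguous.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if len(pool_sizes) != n_sites:
        raise ValueError("pool_sizes length must equal n_sites")
    names = tuple(site_names) if site_names else tuple(f"site{i + 1}" for i in range(n_sites))
    mat = _normalize_pairwise(pairwise_shared, n_sites)
    weights = dict(length_weights or DEFAULT_LENGTH_WEIGHTS)

    # Exclusive region sizes from the design.
    regions: dict = {}
    if n_sites == 1:
        regions[frozenset([names[0]])] = pool_sizes[0]
    else:
        all_key = frozenset(names)
        triple = shared_all if n_sites > 2 else 0
        if n_sites == 2:
            triple = 0
        if n_sites > 2 and shared_all:
            regions[all_key] = shared_all
        pair_excl = {}
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                excl = int(mat[i, j]) - triple
                if excl < 0:
                    raise OverlapDesignError(
                        f"pairwise shared {mat[i, j]} for ({names[i]},{names[j]}) "
                        f"is smaller than shared_all={shared_all}")
                if excl:
                    pair_excl[frozenset([names[i], names[j]])] = excl
        regions.update(pair_excl)
        for i, name in enumerate(names):
            shared_i = sum(v for k, v in regions.items() if name in k)
            unique = pool_sizes[i] - shared_i
            if unique < 0:
                raise OverlapDesignError(
                    f"pool size {pool_sizes[i]} for {name} cannot hold "
                    f"{shared_i} shared spacers")
            regions[frozenset([name])] = unique
    for key, size in regions.items():
        for name in key:
            if size > pool_sizes[names.index(name)]:
                raise OverlapDesignError("region exceeds pool size")

    total = sum(regions.values())
    rng = np.random.default_rng(seed)
    lengths = sorted(weights)
    probs = np.array([weights[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    lo, hi = SPACER_LEN_BOUNDS
    for l in lengths:
        if not lo <= l <= hi:
            raise ValueError(f"spacer length {l} outside [{lo},{hi}]")

    universe: list = []
    by_length: dict = {}
    attempts = 0
    while len(universe) < total:
        attempts += 1
        if attempts > 100 * total + 1000:
            raise RuntimeError("rejection sampling failed to separate spacers")
        length = int(rng.choice(lengths, p=probs))
        cand = random_dna(rng, length)
        ok = all(hamming(cand, prev) > min_separation for prev in by_length.get(length, ()))
        if ok:
            universe.append(cand)
            by_length.setdefault(length, []).append(cand)

    # Deterministic region order: by descending cardinality then sorted names.
    ordered = sorted(regions.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    pools: dict = {s: [] for s in names}
    cursor = 0
    for key, size in ordered:
        chunk = universe[cursor:cursor + size]
        cursor += size
        for s in key:
            pools[s].extend(chunk)
    pools = {s: tuple(p) for s, p in pools.items()}
    abundance = {s: tuple(1.0 for _ in pools[s]) for s in names}
    return SitePools(site_names=names, pools=pools,
                     overlap_design={k: v for k, v in regions.items()},
                     abundance_weights=abundance)


def _draw_distribution(dist) -> tuple:
    if isinstance(dist, int):
        dist = {dist: 1.0}
    ks = sorted(dist)
    if any(k < 1 or k > 5 for k in ks):
        raise ValueError("spacers_per_fragment support must be within 1..5")
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps /= ps.sum()
    return ks, ps


def simulate_amplicons(pools: SitePools, repeat: RepeatModel, reads_per_site: int,
                       spacers_per_fragment=None, error_rate: float = 0.0,
                       seed: int = 0, quality: int = 30):
    """Simulate primer-anchored amplicon reads for every site.

    Each read is ``left_terminal + [spacer + internal_repeat]*(k-1) + spacer +
    right_terminal`` with the internal repeats drawn from the declared variant
    frequencies, then iid substitution errors applied. Returns
    ``(reads_by_site, truth)`` where reads are :class:`~spacerkit.seqs.FastqRead`
    with constant Phred ``quality``.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    lo, hi = SPACER_LEN_BOUNDS
    for site in pools.site_names:
        pool = pools.pool(site)
        if not pool:
            raise ValueError(f"empty pool for site {site}")
        for sp in pool:
            if not lo <= len(sp) <= hi:
                raise ValueError(f"spacer length {len(sp)} outside [{lo},{hi}]")

    ks, kp = _draw_distribution(spacers_per_fragment or DEFAULT_SPACERS_PER_FRAGMENT)
    vtable = repeat.variant_table
    vprobs = np.array([f for _, _, f in vtable], dtype=float)
    vprobs /= vprobs.sum()

    root = np.random.SeedSequence(seed)
    site_seeds = root.spawn(len(pools.site_names))
    reads_by_site: dict = {}
    truth = SyntheticTruth(pools=pools, repeat=repeat, error_rate=error_rate, seed=seed)

    for site, ss in zip(pools.site_names, site_seeds):
        rng = np.random.default_rng(ss)
        pool = pools.pool(site)
        w = np.array(pools.abundance_weights[site], dtype=float)
        w /= w.sum()
        reads = []
        for i in range(reads_per_site):
            k = int(np.asarray(ks)[rng.choice(len(ks), p=kp)])
            spacer_idx = rng.choice(len(pool), size=k, p=w)
            spacers = [pool[j] for j in spacer_idx]
            variant_idx = rng.choice(len(vtable), size=max(k - 1, 0), p=vprobs)
            variants = [vtable[j] for j in variant_idx]
            parts = [repeat.left_terminal]
            for j, sp in enumerate(spacers):
                parts.append(sp)
                if j < k - 1:
                    parts.append(variants[j][1])
            parts.append(repeat.right_terminal)
            seq = mutate(rng, "".join(parts), error_rate)
            read_id = f"{site}_r{i:06d}"
            reads.append(FastqRead(read_id, seq, [quality] * len(seq)))
            truth.reads.append({
                "read_id": read_id, "site": site,
                "spacers": spacers, "variants": [v[0] for v in variants],
            })
        reads_by_site[site] = reads
    return reads_by_site, truth


@dataclass(frozen=True)
class PamSpec:
    """PAM motif over {A,C,G,T,N} written at downstream offsets
    ``offset+1 .. offset+len(motif)`` on the protospacer's strand."""

    motif: str
    offset: int = 0

    def __post_init__(self):
        if not all(c in "ACGTN" for c in self.motif):
            raise ValueError("PAM motif must be over ACGTN")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def make_target_genome(protospacers: Sequence, pam: Optional[PamSpec],
                       genome_length: int, seed: int = 0, flank: int = 8,
                       target_id: str = "synthetic_target"):
    """Plant protospacers (random strands) with a PAM in an iid-uniform genome.

    ``protospacers`` may be plain sequences or (id, sequence) pairs. Returns
    ``((target_id, genome), truth)`` where truth lists dicts with query id,
    0-based half-open + strand coordinates, and strand.
    """
    items = [(p if isinstance(p, tuple) else (f"q{i + 1}", p))
             for i, p in enumerate(protospacers)]
    if pam is not None and pam.offset + len(pam.motif) > flank:
        raise ValueError("PAM motif extends beyond the flank window")
    needed = sum(len(s) + 2 * flank for _, s in items)
    if genome_length < needed:
        raise ValueError("genome_length too small for the planted loci and flanks")

    rng = np.random.default_rng(seed)
    genome = np.array(list(random_dna(rng, genome_length)))
    placed: list = []  # (start, end) including flanks
    truth: list = []
    for qid, spacer in items:
        L = len(spacer)
        lo, hi = flank, genome_length - L - flank
        for _ in range(20000):
            start = int(rng.integers(lo, hi + 1))
            span = (start - flank, start + L + flank)
            if all(span[1] <= a or span[0] >= b for a, b in placed):
                break
        else:
            raise RuntimeError("could not place non-overlapping loci")
        placed.append(span)
        strand = "+" if rng.random() < 0.5 else "-"
        written = spacer if strand == "+" else revcomp(spacer)
        genome[start:start + L] = list(written)
        if pam is not None:
            for i, base in enumerate(pam.motif):
                if base == "N":
                    continue
                off = pam.offset + i  # 0-based distance past the protospacer 3' end
                if strand == "+":
                    genome[start + L + off] = base
                else:
                    genome[start - 1 - off] = revcomp(base)
        truth.append({"query_id": qid, "target_id": target_id,
                      "start": start, "end": start + L, "strand": strand})
    return (target_id, "".join(genome)), truth
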