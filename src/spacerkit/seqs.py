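"""Low-level DNA utilities: complementing, Hamming distances, window scans, I/O.

All heavy per-window mismatch counting is done on raw byte arrays with numpy;
``N`` (or any non-ACGT byte) never compares equal to a base, so ambiguous
positions count as mismatches everywhere without special casing.
"""
from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, alphabet: str = DNA_ALPHABET) -> bool:
    return all(c in alphabet for c in seq)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a read-only uint8 byte array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def hamming(a, b) -> int:
    """Hamming distance between two equal-length sequences (str or uint8 arrays)."""
    if isinstance(a, str):
        a = encode(a)
    if isinstance(b, str):
        b = encode(b)
    if a.shape != b.shape:
        raise ValueError(f"unequal lengths: {a.size} vs {b.size}")
    return int(np.count_nonzero(a != b))


def window_mismatches(target: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every full-length window of ``target``.

    Returns an int array of length ``len(target) - len(query) + 1`` (empty when
    the target is shorter than the query).
    """
    n, m = target.size, query.size
    if n < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target, m)
    return np.count_nonzero(windows != query, axis=1)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    """Apply iid per-base substitutions; each error picks one of the 3 other bases."""
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < error_rate
    for i in np.flatnonzero(hit):
        choices = [b for b in DNA_ALPHABET if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O (thin wrappers over Biopython)
# ---------------------------------------------------------------------------

class FastqRead(tuple):
    """(read_id, sequence, phred_qualities) triple."""

    __slots__ = ()

    def __new__(cls, read_id: str, sequence: str, qualities: Sequence[int]):
        return super().__new__(cls, (read_id, sequence, list(qualities)))

    @property
    def read_id(self) -> str:
        return self[0]

    @property
    def sequence(self) -> str:
        return self[1]

    @property
    def qualities(self) -> list:
        return self[2]


def read_fastq(path) -> Iterator[FastqRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield FastqRead(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])


def write_fastq(path, reads: Iterable[FastqRead]) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def read_fasta(path) -> list:
    """Read FASTA into a list of (id, uppercase sequence) tuples."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, entries: Iterable) -> int:
    n = 0
    with open(path, "w") as fh:
        for name, seq in entries:
            SeqIO.write(SeqRecord(Seq(seq), id=name, description=""), fh, "fasta")
            n += 1
    return n
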