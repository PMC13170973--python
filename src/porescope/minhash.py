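"""Reference-free genome-size and coverage estimation via bottom-s MinHash.

A sketch keeps the s smallest 64-bit hashes over the distinct canonical
k-mers of the input (k=27, s=1000 by default), together with each retained
k-mer's multiplicity. Because a well-mixed hash makes the retained k-mers
a uniform random sample of all distinct k-mers:

* the number of distinct k-mers (~ community genome size in bases, for
  k << genome length) is estimated by the k-minimum-values formula
  ``(s - 1) * H / h_s`` with ``H = 2^64`` and ``h_s`` the largest retained
  hash — exact counting is used while the sketch is unsaturated;
* per-k-mer coverage is estimated by the mean multiplicity of the
  retained k-mers, which tracks base coverage scaled by (L - k + 1) / L
  for reads of length L.

For read (FASTQ) input, k-mers seen fewer than m=2 times are excluded
before sketching, suppressing the singleton k-mers that sequencing errors
create; FASTA input uses m=1. The hash is splitmix64 with a fixed seed, so
identical inputs give identical sketches regardless of read order. Parity
with any external sketching tool is not claimed; the estimator is defined
by this module and validated by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List

import numpy as np

from .formats import FastqRead

#: fixed hash seed: sketches are deterministic across runs and machines
HASH_SEED = np.uint64(0x9E3779B97F4A7C15)

#: size of the 64-bit hash space, as a float for the cardinality formula
HASH_SPACE = float(2**64)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class SketchError(ValueError):
    """The input yields no usable k-mers (too short, or all below m copies)."""


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch with per-k-mer multiplicities."""

    k: int
    s: int
    m: int
    hashes: np.ndarray        # uint64, sorted ascending, len <= s
    multiplicities: np.ndarray  # int64, aligned with hashes

    @property
    def saturated(self) -> bool:
        return len(self.hashes) == self.s


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finaliser; a cheap, well-mixed 64-bit hash."""
    z = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        z += np.uint64(0x9E3779B97F4A7C15)
        z ^= z >> np.uint64(30)
        z *= np.uint64(0xBF58476D1CE4E5B9)
        z ^= z >> np.uint64(27)
        z *= np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(31)
    return z


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every length-k window of 2-bit base codes into a uint64."""
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= c[j : j + n]
    return out


def kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Canonical k-mer codes (uint64) for every N-free window of ``sequence``.

    The canonical form is the lexicographic minimum of a k-mer and its
    reverse complement; with the A<C<G<T 2-bit encoding, numeric order on
    packed codes coincides with lexicographic order, so a plain minimum of
    the forward and reverse-complement codes suffices. Requires 2k <= 64.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > 64:
        raise ValueError("k too large for 64-bit packing (k <= 32)")
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[raw]
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    valid_base = codes < 4
    codes = np.where(valid_base, codes, 0).astype(np.uint8)
    fwd = _window_codes(codes, k)
    # revcomp codes: window i of the complemented+reversed sequence,
    # re-reversed, is the reverse complement of forward window i
    comp = (np.uint8(3) - codes)[::-1]
    rev = _window_codes(comp, k)[::-1]
    canonical = np.minimum(fwd, rev)
    ok = (
        np.lib.stride_tricks.sliding_window_view(valid_base, k).all(axis=1)
        if len(valid_base) >= k
        else np.empty(0, dtype=bool)
    )
    return canonical[ok]


def _decode_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _DECODE[code & 3]
        code >>= 2
    return out.decode("ascii")


def canonical_kmers(sequence: str, k: int) -> Iterator[str]:
    """Stream the canonical k-mers of ``sequence`` as strings (N windows skipped)."""
    for code in kmer_codes(sequence, k):
        yield _decode_kmer(int(code), k)


def sketch_sequences(
    sequences: Iterable[str], k: int = 27, s: int = 1000, m: int = 1
) -> Sketch:
    """Sketch an iterable of sequences (FASTA mode default: m=1).

    Sequences are joined with an N separator so no window spans two
    inputs; the sketch is therefore independent of input order.
    """
    joined = "N".join(sequences)
    codes = kmer_codes(joined, k)
    if len(codes) == 0:
        raise SketchError(f"insufficient k-mers: no window of length {k}")
    distinct, counts = np.unique(codes, return_counts=True)
    keep = counts >= m
    distinct, counts = distinct[keep], counts[keep]
    if len(distinct) == 0:
        raise SketchError(
            f"insufficient k-mers: none reached the copy threshold m={m}"
        )
    hashes = splitmix64(distinct ^ HASH_SEED)
    if len(hashes) > s:
        idx = np.argpartition(hashes, s)[:s]
        hashes, counts = hashes[idx], counts[idx]
    order = np.argsort(hashes, kind="stable")
    return Sketch(
        k=k,
        s=s,
        m=m,
        hashes=hashes[order],
        multiplicities=counts[order].astype(np.int64),
    )


def sketch_reads(
    reads: Iterable[FastqRead], k: int = 27, s: int = 1000, m: int = 2
) -> Sketch:
    """Sketch basecalled reads (read mode default: m=2, error suppression)."""
    return sketch_sequences((r.sequence for r in reads), k=k, s=s, m=m)


def estimate_genome_size(sketch: Sketch) -> float:
    """Distinct-k-mer cardinality estimate, in bases.

    Saturated sketches use the k-minimum-values estimator
    ``(s - 1) * H / h_s``; unsaturated sketches already enumerate every
    distinct k-mer, so the exact count is returned.
    """
    if len(sketch.hashes) == 0:
        raise SketchError("empty sketch")
    if not sketch.saturated:
        return float(len(sketch.hashes))
    h_s = float(sketch.hashes[-1])
    if h_s == 0.0:
        raise SketchError("degenerate sketch: zero maximum hash")
    return (sketch.s - 1) * HASH_SPACE / h_s


def estimate_coverage(sketch: Sketch) -> float:
    """Mean multiplicity over retained k-mers: per-k-mer fold coverage."""
    if len(sketch.multiplicities) == 0:
        raise SketchError("empty sketch")
    return float(np.mean(sketch.multiplicities))
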