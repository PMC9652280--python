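"""Canonical k-mer counting, histograms, and coverage thresholding.

A genome (or a read set) is represented by its constituent k-mers — DNA
substrings of fixed odd length ``k`` (default 27) — under *canonical*
identity: a k-mer and its reverse complement are the same object, named by
the lexicographically smaller of the two.  A k-mer is attributed to an
individual's genome when it is seen at least ``T`` times in that
individual's reads; ``T`` is inferred from the k-mer occurrence histogram,
whose low-count peak collects sequencing-error k-mers and whose higher peak
sits at the sequencing coverage of the genome.

k-mers are packed into 64-bit integer codes (2 bits per base, A<C<G<T), so
that numeric order on codes equals lexicographic order on strings; all
per-window work is vectorised with numpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "reverse_complement",
    "canonicalize",
    "encode_kmer",
    "decode_kmer",
    "count_kmers",
    "histogram",
    "infer_threshold",
    "individual_set",
    "KmerTable",
    "ThresholdResult",
    "IndividualKmerSet",
]

# 2-bit base codes; 255 flags anything that is not a concrete A/C/G/T.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(window: str) -> str | None:
    """Canonical form of a k-length window: ``min(window, revcomp(window))``.

    Returns ``None`` when the window contains an ambiguous base (N etc.),
    signalling the caller to skip it.  Idempotent on its own output.
    Uniqueness of the canonical representative requires odd length (an
    even-length window can equal its own reverse complement).
    """
    w = window.upper()
    if any(b not in "ACGT" for b in w):
        return None
    rc = reverse_complement(w)
    return w if w <= rc else rc


def encode_kmer(kmer: str) -> int:
    """Pack an A/C/G/T string into its 2-bit integer code."""
    code = 0
    for b in kmer.upper():
        v = int(_ENC[ord(b)])
        if v > 3:
            raise ValueError(f"ambiguous base {b!r} cannot be encoded")
        code = (code << 2) | v
    return code


def decode_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _DEC[code & 3]
        code >>= 2
    return out.decode()


def _encode_ascii(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes for all k-windows of a 2-bit encoded array.

    Returns ``(codes, valid)`` of length ``n - k + 1``; ``valid`` is False
    for windows containing any non-ACGT symbol (their code is meaningless).
    """
    n = arr.size
    m = n - k + 1
    if m <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    bad = arr > 3
    badcum = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(bad, out=badcum[1:])
    valid = (badcum[k:] - badcum[:-k]) == 0
    a = arr.astype(np.uint64)
    a[bad] = 0  # neutralise so shifts stay in range
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        col = a[j : m + j]
        fwd |= col << np.uint64(2 * (k - 1 - j))
        rev |= (three - col) << np.uint64(2 * j)
    return np.minimum(fwd, rev), valid


def _codes_from_reads(reads: Iterable[str], k: int) -> Iterator[np.ndarray]:
    """Yield arrays of valid canonical window codes, batching reads.

    Reads are concatenated with a separator byte so a whole batch is
    processed in one vectorised pass; windows spanning read boundaries are
    invalidated by the separator.
    """
    batch: list[str] = []
    size = 0
    sep = "N"
    for read in reads:
        batch.append(read)
        size += len(read) + 1
        if size >= 4_000_000:
            arr = _encode_ascii(sep.join(batch))
            codes, valid = _window_codes(arr, k)
            yield codes[valid]
            batch, size = [], 0
    if batch:
        arr = _encode_ascii(sep.join(batch))
        codes, valid = _window_codes(arr, k)
        yield codes[valid]


@dataclass
class KmerTable:
    """Per-sample map canonical k-mer -> occurrence count.

    Stored as a sorted uint64 code array plus a parallel count array;
    string-keyed views are provided for small tables and serialisation.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    sample_id: str = ""

    @classmethod
    def from_dict(cls, k: int, mapping: Mapping[str, int], sample_id: str = "") -> "KmerTable":
        items = sorted((encode_kmer(km), c) for km, c in mapping.items())
        for km in mapping:
            if len(km) != k:
                raise ValueError(f"k-mer {km!r} does not have length {k}")
            if canonicalize(km) != km.upper():
                raise ValueError(f"k-mer {km!r} is not canonical")
        codes = np.array([i for i, _ in items], dtype=np.uint64)
        counts = np.array([c for _, c in items], dtype=np.int64)
        return cls(k=k, codes=codes, counts=counts, sample_id=sample_id)

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str, default: int = 0) -> int:
        canon = canonicalize(kmer)
        if canon is None:
            raise ValueError(f"ambiguous k-mer {kmer!r}")
        code = np.uint64(encode_kmer(canon))
        i = int(np.searchsorted(self.codes, code))
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return default

    def as_dict(self) -> dict[str, int]:
        return {
            decode_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    def histogram(self) -> dict[int, int]:
        return histogram(self)

    def to_tsv(self, path: str | Path) -> None:
        """Write as sorted (k-mer, count) TSV; sorted by k-mer string."""
        with open(path, "w") as fh:
            for c, n in zip(self.codes, self.counts):
                fh.write(f"{decode_kmer(int(c), self.k)}\t{int(n)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int, sample_id: str = "") -> "KmerTable":
        codes: list[int] = []
        counts: list[int] = []
        with open(path) as fh:
            for line in fh:
                km, n = line.rstrip("\n").split("\t")
                codes.append(encode_kmer(km))
                counts.append(int(n))
        order = np.argsort(np.array(codes, dtype=np.uint64), kind="stable")
        return cls(
            k=k,
            codes=np.array(codes, dtype=np.uint64)[order],
            counts=np.array(counts, dtype=np.int64)[order],
            sample_id=sample_id,
        )


def count_kmers(reads: Iterable[str], k: int, sample_id: str = "") -> KmerTable:
    """Count canonical k-mers over all length-k windows of the reads.

    One increment per window not containing an ambiguous base.  ``k`` must
    be odd (so no k-mer equals its own reverse complement and canonical
    identity is unambiguous) and at most 31 (codes fit in 62 bits).  Result
    is independent of read order and internal batching.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd: even k admits self-reverse-complementary k-mers")
    if not 1 < k <= 31:
        raise ValueError("k must satisfy 1 < k <= 31")
    chunks = [c for c in _codes_from_reads(reads, k) if c.size]
    if not chunks:
        return KmerTable(k=k, codes=np.empty(0, dtype=np.uint64),
                         counts=np.empty(0, dtype=np.int64), sample_id=sample_id)
    allcodes = np.concatenate(chunks)
    codes, counts = np.unique(allcodes, return_counts=True)
    return KmerTable(k=k, codes=codes, counts=counts.astype(np.int64), sample_id=sample_id)


def histogram(table: KmerTable) -> dict[int, int]:
    """Occurrence-count histogram: {count c -> number of distinct k-mers}."""
    if table.counts.size == 0:
        return {}
    vals, freqs = np.unique(table.counts, return_counts=True)
    return {int(v): int(f) for v, f in zip(vals, freqs)}


@dataclass(frozen=True)
class ThresholdResult:
    """Inferred k-mer membership threshold T with a confidence flag."""

    threshold: int
    low_confidence: bool = False

    def __int__(self) -> int:
        return self.threshold


def infer_threshold(hist: Mapping[int, int]) -> ThresholdResult:
    """Infer the membership threshold T from a k-mer histogram.

    The histogram of a shotgun read set has a sharp low-count peak of
    sequencing-error k-mers and a broad peak at the genome coverage; T is
    placed in the valley between them: the occurrence count c in
    ``[2, c_peak]`` minimising ``hist(c)``, where ``c_peak`` is the location
    of the histogram maximum over ``c >= 3``.  Ties break toward smaller c.
    A missing count is treated as zero only when both immediate neighbours
    are present (a genuine interior dip); otherwise it is excluded, so the
    unpopulated gap below the coverage peak of a clean histogram is not
    mistaken for a valley.  A histogram with no coverage peak (monotone
    decreasing) yields the fallback T=3 flagged low-confidence.
    """
    if not hist:
        raise ValueError("empty histogram")
    keys = sorted(hist)
    values = [hist[c] for c in keys]
    if any(c < 1 for c in keys):
        raise ValueError("histogram keys must be >= 1")

    high = [c for c in keys if c >= 3]
    monotone = all(values[i] >= values[i + 1] for i in range(len(values) - 1))
    if not high or monotone:
        return ThresholdResult(threshold=3, low_confidence=True)

    peak_height = max(hist[c] for c in high)
    c_peak = min(c for c in high if hist[c] == peak_height)

    present = set(keys)
    best_c: int | None = None
    best_v: int | None = None
    for c in range(2, c_peak + 1):
        if c in present:
            v = hist[c]
        elif (c - 1) in present and (c + 1) in present:
            v = 0
        else:
            continue
        if best_v is None or v < best_v:
            best_c, best_v = c, v
    if best_c is None:  # cannot happen: c_peak itself is present
        return ThresholdResult(threshold=3, low_confidence=True)
    return ThresholdResult(threshold=best_c, low_confidence=False)


@dataclass
class IndividualKmerSet:
    """Thresholded k-mer set of one individual: {x : count(x) >= T}."""

    k: int
    codes: np.ndarray  # sorted uint64
    threshold_used: int
    sample_id: str = ""

    @classmethod
    def from_kmers(cls, k: int, kmers: Iterable[str], threshold_used: int = 1,
                   sample_id: str = "") -> "IndividualKmerSet":
        codes = set()
        for km in kmers:
            canon = canonicalize(km)
            if canon is None or len(canon) != k:
                raise ValueError(f"invalid k-mer {km!r}")
            codes.add(encode_kmer(canon))
        return cls(k=k, codes=np.array(sorted(codes), dtype=np.uint64),
                   threshold_used=threshold_used, sample_id=sample_id)

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        canon = canonicalize(kmer)
        if canon is None:
            return False
        code = np.uint64(encode_kmer(canon))
        i = int(np.searchsorted(self.codes, code))
        return i < self.codes.size and self.codes[i] == code

    @property
    def members(self) -> frozenset[str]:
        """String view; intended for small sets (tests, inspection)."""
        return frozenset(decode_kmer(int(c), self.k) for c in self.codes)


def individual_set(table: KmerTable, threshold: int | ThresholdResult) -> IndividualKmerSet:
    """Threshold a k-mer table into an individual's k-mer set."""
    t = int(threshold)
    if t < 1:
        raise ValueError("threshold must be >= 1")
    mask = table.counts >= t
    return IndividualKmerSet(k=table.k, codes=table.codes[mask].copy(),
                             threshold_used=t, sample_id=table.sample_id)


def genome_kmer_set(genome: Mapping[str, str] | str, k: int) -> IndividualKmerSet:
    """Exact canonical k-mer set of a genome (direct window enumeration)."""
    seqs = [genome] if isinstance(genome, str) else list(genome.values())
    chunks = []
    for seq in seqs:
        codes, valid = _window_codes(_encode_ascii(seq), k)
        chunks.append(codes[valid])
    if chunks:
        codes = np.unique(np.concatenate(chunks))
    else:
        codes = np.empty(0, dtype=np.uint64)
    return IndividualKmerSet(k=k, codes=codes, threshold_used=1, sample_id="genome")
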