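"""Strain-level k-mer aggregation, reference scanning, and variant calling.

Individual k-mer sets from two named strains are aggregated into per-k-mer
counters (i, j): the number of individuals of each strain possessing the
k-mer.  A k-mer belongs to a *strain* when it belongs to at least ``m``
individuals of that strain (default m = 3, a majority rule suited to
panels of roughly 4-10 animals).

The annotated reference is then scanned: every reference k-mer window is
queried against a strain's k-mer set, and a positive query marks all k of
its base pairs as *present* in that strain.  Bases never marked are
*altered base pairs*; a maximal block of consecutive altered base pairs is
a *variant* (substitution run or deletion).  Insertions in the strain leave
every reference base marked but break the k-1 reference windows spanning
the insertion junction, so they are recovered from runs of absent reference
k-mer starts whose footprint contains no altered base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kmers import (
    IndividualKmerSet,
    _encode_ascii,
    _window_codes,
    canonicalize,
    decode_kmer,
    encode_kmer,
)

__all__ = [
    "StrainAggregate",
    "StrainKmerSet",
    "ContigScan",
    "ReferenceScan",
    "VariantCall",
    "aggregate",
    "strain_set",
    "scan_reference",
    "call_altered_runs",
    "call_insertions",
    "write_bed",
    "write_summary_tsv",
]


@dataclass
class StrainAggregate:
    """Per-k-mer (i, j) counters over two strains plus their summary matrix.

    ``codes`` is the sorted union of all individual sets; ``counts_a[x]``
    and ``counts_b[x]`` are the numbers of strain-A / strain-B individuals
    possessing k-mer x.  ``summary[i, j]`` counts k-mers with counters
    (i, j); the (0, 0) cell is structurally zero (such k-mers — the
    complement of the union — are never materialised).
    """

    k: int
    strain_names: tuple[str, str]
    codes: np.ndarray
    counts_a: np.ndarray
    counts_b: np.ndarray
    n_a: int
    n_b: int
    summary: np.ndarray

    def __len__(self) -> int:
        return int(self.codes.size)

    def membership(self) -> dict[str, tuple[int, int]]:
        """String-keyed (i, j) view; intended for small aggregates."""
        return {
            decode_kmer(int(c), self.k): (int(i), int(j))
            for c, i, j in zip(self.codes, self.counts_a, self.counts_b)
        }


def _strain_counts(sets: Sequence[IndividualKmerSet]) -> tuple[np.ndarray, np.ndarray]:
    chunks = [s.codes for s in sets if s.codes.size]
    if not chunks:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return codes, counts.astype(np.int64)


def aggregate(sets_by_strain: Mapping[str, Sequence[IndividualKmerSet]]) -> StrainAggregate:
    """Aggregate individual k-mer sets of two strains into (i, j) counters."""
    if len(sets_by_strain) != 2:
        raise ValueError("aggregate requires exactly two strains")
    (name_a, sets_a), (name_b, sets_b) = sets_by_strain.items()
    ks = {s.k for s in list(sets_a) + list(sets_b)}
    if len(ks) > 1:
        raise ValueError(f"mixed k among individual sets: {sorted(ks)}")
    k = ks.pop() if ks else 0

    codes_a, cnt_a = _strain_counts(sets_a)
    codes_b, cnt_b = _strain_counts(sets_b)
    union = np.union1d(codes_a, codes_b)
    i = np.zeros(union.size, dtype=np.int64)
    j = np.zeros(union.size, dtype=np.int64)
    i[np.searchsorted(union, codes_a)] = cnt_a
    j[np.searchsorted(union, codes_b)] = cnt_b

    n_a, n_b = len(sets_a), len(sets_b)
    summary = np.zeros((n_a + 1, n_b + 1), dtype=np.int64)
    np.add.at(summary, (i, j), 1)
    return StrainAggregate(k=k, strain_names=(name_a, name_b), codes=union,
                           counts_a=i, counts_b=j, n_a=n_a, n_b=n_b, summary=summary)


@dataclass
class StrainKmerSet:
    """k-mers belonging to >= ``min_individuals`` individuals of a strain."""

    name: str
    k: int
    codes: np.ndarray  # sorted uint64
    min_individuals: int

    @classmethod
    def from_kmers(cls, k: int, kmers, name: str = "strain",
                   min_individuals: int = 1) -> "StrainKmerSet":
        codes = set()
        for km in kmers:
            canon = canonicalize(km)
            if canon is None or len(canon) != k:
                raise ValueError(f"invalid k-mer {km!r}")
            codes.add(encode_kmer(canon))
        return cls(name=name, k=k, codes=np.array(sorted(codes), dtype=np.uint64),
                   min_individuals=min_individuals)

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        canon = canonicalize(kmer)
        if canon is None:
            return False
        code = np.uint64(encode_kmer(canon))
        pos = int(np.searchsorted(self.codes, code))
        return pos < self.codes.size and self.codes[pos] == code

    @property
    def members(self) -> frozenset[str]:
        return frozenset(decode_kmer(int(c), self.k) for c in self.codes)


def strain_set(agg: StrainAggregate, strain: str, m: int) -> StrainKmerSet:
    """Select the k-mers belonging to >= m individuals of one strain."""
    if strain == agg.strain_names[0]:
        counts, n = agg.counts_a, agg.n_a
    elif strain == agg.strain_names[1]:
        counts, n = agg.counts_b, agg.n_b
    else:
        raise ValueError(f"unknown strain {strain!r}; have {agg.strain_names}")
    if not 1 <= m <= n:
        raise ValueError(f"m={m} out of range [1, {n}] for strain {strain!r}")
    return StrainKmerSet(name=strain, k=agg.k,
                         codes=agg.codes[counts >= m].copy(), min_individuals=m)


@dataclass
class ContigScan:
    """Masks for one contig of a reference scan.

    presence: per base, True when some strain-present k-mer window covers it.
    absent_start: per window start, True when that reference k-mer is not in
        the strain set (windows with ambiguous bases included).
    unscannable: per base, True when no ambiguity-free window covers it
        (N runs, contig ends shorter than k); such bases are reported apart
        from altered base pairs.
    """

    presence: np.ndarray
    absent_start: np.ndarray
    unscannable: np.ndarray

    @property
    def altered(self) -> np.ndarray:
        return ~self.presence & ~self.unscannable


@dataclass
class ReferenceScan:
    """Presence/absence scan of a reference against one strain's k-mer set."""

    k: int
    strain: str
    contigs: dict[str, ContigScan]

    @property
    def total_altered_bp(self) -> int:
        return int(sum(c.altered.sum() for c in self.contigs.values()))

    @property
    def total_unscannable_bp(self) -> int:
        return int(sum(c.unscannable.sum() for c in self.contigs.values()))


def scan_reference(reference: Mapping[str, str], sset: StrainKmerSet) -> ReferenceScan:
    """Mark reference bases covered by k-mer windows present in the strain.

    A base is present iff some window containing it is ambiguity-free and
    its canonical k-mer belongs to the strain set.  Contigs shorter than k
    have all-false presence and an empty absent-start mask.  Contigs are
    processed independently; output does not depend on their order.
    """
    k = sset.k
    contigs: dict[str, ContigScan] = {}
    for name, seq in reference.items():
        n = len(seq)
        if n < k:
            contigs[name] = ContigScan(
                presence=np.zeros(n, dtype=bool),
                absent_start=np.zeros(0, dtype=bool),
                unscannable=np.ones(n, dtype=bool),
            )
            continue
        arr = _encode_ascii(seq)
        codes, valid = _window_codes(arr, k)
        if sset.codes.size:
            pos = np.searchsorted(sset.codes, codes)
            np.minimum(pos, sset.codes.size - 1, out=pos)
            member = sset.codes[pos] == codes
        else:
            member = np.zeros(codes.size, dtype=bool)
        present_w = valid & member

        def cover(mask: np.ndarray) -> np.ndarray:
            diff = np.zeros(n + 1, dtype=np.int64)
            starts = np.flatnonzero(mask)
            np.add.at(diff, starts, 1)
            np.add.at(diff, starts + k, -1)
            return np.cumsum(diff[:-1]) > 0

        contigs[name] = ContigScan(
            presence=cover(present_w),
            absent_start=~present_w,
            unscannable=~cover(valid),
        )
    return ReferenceScan(k=k, strain=sset.name, contigs=contigs)


@dataclass(frozen=True)
class VariantCall:
    """A called difference on the reference, 0-based half-open coordinates.

    ``altered_run``: maximal block of consecutive altered base pairs
    (length = end - start).  ``insertion``: zero-width junction call
    (end == start) carrying the length of the supporting absent k-mer run.
    """

    contig: str
    start: int
    end: int
    vclass: str
    length: int


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def call_altered_runs(scan: ReferenceScan) -> list[VariantCall]:
    """Maximal runs of altered base pairs, sorted by (contig, start)."""
    calls: list[VariantCall] = []
    for name in sorted(scan.contigs):
        for s, e in _runs(scan.contigs[name].altered):
            calls.append(VariantCall(contig=name, start=s, end=e,
                                     vclass="altered_run", length=e - s))
    return calls


def call_insertions(scan: ReferenceScan) -> list[VariantCall]:
    """Insertion junction calls from absent k-mer runs over present bases.

    A maximal run [rs, re) of absent reference k-mer starts covers the base
    span [rs, re + k - 1).  When that span contains no altered base pair,
    every base is still marked by flanking windows and the run can only be
    explained by sequence inserted in the strain: one zero-width call is
    reported at the junction rs + k - 1, carrying the run length (an
    isolated insertion breaks exactly k - 1 reference windows).  Runs whose
    span overlaps altered bases are already explained by altered_run calls.
    """
    k = scan.k
    calls: list[VariantCall] = []
    for name in sorted(scan.contigs):
        contig = scan.contigs[name]
        altered = contig.altered
        altered_cum = np.zeros(altered.size + 1, dtype=np.int64)
        np.cumsum(altered, out=altered_cum[1:])
        for rs, re in _runs(contig.absent_start):
            span_end = min(re + k - 1, altered.size)
            if altered_cum[span_end] - altered_cum[rs] > 0:
                continue
            junction = rs + k - 1
            calls.append(VariantCall(contig=name, start=junction, end=junction,
                                     vclass="insertion", length=re - rs))
    return calls


def write_bed(calls: Sequence[VariantCall], path: str | Path) -> None:
    """BED5: chrom, start, end, name=vclass, score=length."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.vclass}\t{c.length}\n")


def write_summary_tsv(agg: StrainAggregate, path: str | Path) -> None:
    """Summary matrix as (i, j, k-mer count) rows for all non-empty cells."""
    with open(path, "w") as fh:
        fh.write(f"#i={agg.strain_names[0]}\tj={agg.strain_names[1]}\tkmers\n")
        for i in range(agg.summary.shape[0]):
            for j in range(agg.summary.shape[1]):
                if agg.summary[i, j]:
                    fh.write(f"{i}\t{j}\t{int(agg.summary[i, j])}\n")
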