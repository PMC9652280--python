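"""In-silico PCR and restriction-fragment (RFLP) genotyping.

The PRKAG3 V199I polymorphism of the AMP-activated protein kinase
gamma-3 subunit is genotyped by amplifying a 545 bp product with a printed
primer pair and digesting it with BsaHI (recognition GRCGYC, cutting
GR^CGYC).  The valine allele carries two BsaHI sites in the amplicon and
digests to 317 + 119 + 109 bp; the isoleucine allele ablates the internal
site and digests to 436 + 109 bp; a heterozygote shows the four-band union
436 + 317 + 119 + 109.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .kmers import reverse_complement

__all__ = [
    "PrimerPair",
    "Enzyme",
    "DigestResult",
    "PRKAG3_PRIMERS",
    "BSAHI",
    "GENOTYPE_PATTERNS",
    "NoAmplificationError",
    "AmbiguousProductError",
    "in_silico_pcr",
    "digest",
    "classify_genotype",
    "synthetic_prkag3_template",
    "SyntheticTemplate",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self):
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or any(b not in "ACGT" for b in p.upper()):
                raise ValueError(f"{name} primer must be non-empty over ACGT: {p!r}")


#: The published PRKAG3 genotyping primer pair.
PRKAG3_PRIMERS = PrimerPair(
    forward="ACCAGCAGCCTTAGATCTGGAACAAATGTG",
    reverse="TTCCTTCCTCCGCCTGTCCTCTTCTTACTT",
)


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease: IUPAC recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self):
        if any(b not in _IUPAC for b in self.site.upper()):
            raise ValueError(f"recognition site {self.site!r} has non-IUPAC symbols")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut offset must lie within the recognition site")

    def pattern(self) -> re.Pattern:
        expanded = "".join(
            b if len(_IUPAC[b]) == 1 else "[" + _IUPAC[b] + "]"
            for b in self.site.upper()
        )
        return re.compile(f"(?=({expanded}))")  # lookahead: overlapping sites


#: BsaHI: GRCGYC, cutting GR^CGYC.  The site is its own reverse complement
#: under IUPAC, so scanning the top strand finds every site.
BSAHI = Enzyme(name="BsaHI", site="GRCGYC", cut_offset=2)


class NoAmplificationError(RuntimeError):
    """No primer-pair orientation yields a product within the size limit."""


class AmbiguousProductError(RuntimeError):
    """Several equally short products at distinct loci."""

    def __init__(self, loci: list[tuple[str, int, int]]):
        self.loci = loci
        super().__init__(f"ambiguous amplification: equal-length products at {loci}")


def _match_positions(template: str, primer: str, mismatches: int) -> list[int]:
    if mismatches == 0:
        out, start = [], 0
        while True:
            i = template.find(primer, start)
            if i < 0:
                return out
            out.append(i)
            start = i + 1
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    m = t.size - p.size + 1
    if m <= 0:
        return []
    mis = np.zeros(m, dtype=np.int64)
    for j in range(p.size):
        mis += t[j:m + j] != p[j]
    return [int(i) for i in np.flatnonzero(mis <= mismatches)]


def in_silico_pcr(
    template: str,
    primers: PrimerPair = PRKAG3_PRIMERS,
    max_product: int = 2000,
    mismatches: int = 0,
) -> str:
    """Predict the PCR product of a primer pair on a template.

    The amplicon runs from the start of a forward-primer match to the end
    of a downstream reverse-complemented reverse-primer match; both
    template orientations are searched and the smallest product not
    exceeding ``max_product`` is returned (5'->3' in forward-primer
    orientation).  Primer matching is exact by default; ``mismatches``
    relaxes it per primer.
    """
    t = template.upper()
    candidates: list[tuple[int, str, str, int]] = []  # (length, seq, strand, start)
    for strand, seq in (("+", t), ("-", reverse_complement(t))):
        fwd_hits = _match_positions(seq, primers.forward.upper(), mismatches)
        rev_rc = reverse_complement(primers.reverse.upper())
        rev_hits = _match_positions(seq, rev_rc, mismatches)
        for f in fwd_hits:
            for r in rev_hits:
                end = r + len(rev_rc)
                length = end - f
                if r >= f and length <= max_product:
                    candidates.append((length, seq[f:end], strand, f))
    if not candidates:
        raise NoAmplificationError("no amplification")
    best = min(c[0] for c in candidates)
    shortest = [c for c in candidates if c[0] == best]
    loci = sorted({(strand, start, start + length)
                   for length, _, strand, start in shortest})
    if len(loci) > 1:
        raise AmbiguousProductError(list(loci))
    return shortest[0][1]


@dataclass(frozen=True)
class DigestResult:
    """Fragments of a restriction digest, ordered 5'->3' along the amplicon."""

    fragments: tuple[int, ...]

    @property
    def band_set(self) -> frozenset[int]:
        """Gel semantics: order lost, equal lengths co-migrate."""
        return frozenset(self.fragments)

    @property
    def total(self) -> int:
        return sum(self.fragments)


def digest(amplicon: str, enzyme: Enzyme = BSAHI) -> DigestResult:
    """Fragment lengths after complete digestion of a linear amplicon.

    Cut positions are ``site_start + cut_offset`` for every (overlapping)
    top-strand match of the recognition site; with no site the amplicon is
    returned whole.
    """
    a = amplicon.upper()
    if any(b not in "ACGT" for b in a):
        raise ValueError("amplicon must be a concrete ACGT sequence")
    cuts = sorted({m.start() + enzyme.cut_offset
                   for m in enzyme.pattern().finditer(a)
                   if 0 < m.start() + enzyme.cut_offset < len(a)})
    bounds = [0] + cuts + [len(a)]
    return DigestResult(fragments=tuple(b - a_ for a_, b in zip(bounds, bounds[1:])))


#: Published band patterns (bp) of the PRKAG3 BsaHI digest.
GENOTYPE_PATTERNS: dict[str, frozenset[int]] = {
    "I/I": frozenset({436, 109}),
    "V/V": frozenset({317, 119, 109}),
    "I/V": frozenset({436, 317, 119, 109}),
}


def _bands_match(observed: frozenset[int], pattern: frozenset[int],
                 tolerance: int) -> bool:
    if tolerance == 0:
        return observed == pattern
    if len(observed) != len(pattern):
        return False
    return all(
        abs(o - p) <= tolerance
        for o, p in zip(sorted(observed), sorted(pattern))
    )


def classify_genotype(bands: Iterable[int], tolerance: int = 0) -> str:
    """Classify an observed band set as V/V, I/I, I/V, or unclassified.

    ``bands`` may be the fragments of one digest or the pooled bands of two
    alleles; multiplicity collapses (gel semantics).  ``tolerance`` allows
    per-band length slack for gel-estimated sizes (0 for in-silico input).
    """
    observed = frozenset(int(b) for b in bands)
    if any(b <= 0 for b in observed):
        raise ValueError("band lengths must be positive")
    for genotype, pattern in GENOTYPE_PATTERNS.items():
        if _bands_match(observed, pattern, tolerance):
            return genotype
    return "unclassified"


@dataclass(frozen=True)
class SyntheticTemplate:
    """Synthetic PRKAG3-like genotyping templates (see builder docstring).

    ``template_v`` carries both BsaHI sites (valine-like allele);
    ``template_i`` differs by the single base at ``snp_position`` (template
    coordinate), which ablates the internal site (isoleucine-like allele).
    """

    template_v: str
    template_i: str
    amplicon_start: int
    amplicon_end: int
    snp_position: int


def synthetic_prkag3_template(seed: int = 0, flank: int = 150) -> SyntheticTemplate:
    """Construct a *synthetic* stand-in for the PRKAG3 genotyping template.

    The real template is the GenBank PRKAG3 gene record used for primer
    design; that record is not bundled, so this builder constructs a
    template from the published constraints alone: the printed primer pair
    flanks a 545 bp amplicon whose BsaHI digest yields 317 + 119 + 109 bp,
    and a single-base ablation of the internal site (the V199I-like edit)
    yields 436 + 109 bp.  Cut positions are therefore fixed at 317 and 436
    within the amplicon; filler sequence is random from ``seed`` and
    rejection-sampled so no spurious primer match or BsaHI site exists.
    The synthetic template reproduces the published band arithmetic, not
    the real PRKAG3 sequence.
    """
    fwd = PRKAG3_PRIMERS.forward
    rev_rc = reverse_complement(PRKAG3_PRIMERS.reverse)
    site = "GACGCC"  # one concrete GRCGYC instance
    amplicon_len, cut1, cut2 = 545, 317, 436
    off = BSAHI.cut_offset
    s1, s2 = cut1 - off, cut2 - off  # site start positions in the amplicon
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    for _ in range(500):
        amplicon = (fwd + rand(s1 - len(fwd)) + site
                    + rand(s2 - s1 - len(site)) + site
                    + rand(amplicon_len - len(rev_rc) - s2 - len(site)) + rev_rc)
        assert len(amplicon) == amplicon_len
        left, right = rand(flank), rand(flank)
        template_v = left + amplicon + right
        # the single-base edit: site GACGCC -> GCCGCC is no longer GRCGYC
        snp_in_amp = s1 + 1
        amp_i = amplicon[:snp_in_amp] + "C" + amplicon[snp_in_amp + 1:]
        template_i = left + amp_i + right

        sites_v = {m.start() for m in BSAHI.pattern().finditer(amplicon)}
        sites_i = {m.start() for m in BSAHI.pattern().finditer(amp_i)}
        ok = sites_v == {s1, s2} and sites_i == {s2}
        for tmpl in (template_v, template_i):
            ok = ok and len(_match_positions(tmpl, fwd, 0)) == 1
            ok = ok and len(_match_positions(tmpl, rev_rc, 0)) == 1
            ok = ok and not _match_positions(tmpl, PRKAG3_PRIMERS.reverse, 0)
            ok = ok and not _match_positions(tmpl, reverse_complement(fwd), 0)
        if ok:
            return SyntheticTemplate(
                template_v=template_v, template_i=template_i,
                amplicon_start=flank, amplicon_end=flank + amplicon_len,
                snp_position=flank + snp_in_amp)
    raise RuntimeError("failed to construct a clean synthetic template")
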