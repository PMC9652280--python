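"""Synthetic references, strain genomes with planted variants, reads, and
toy annotations, with machine-readable ground truth.

The generator emulates the study design of a two-strain comparison against
a reference: a random reference genome, per-strain genomes derived from it
by planted substitutions, deletions and insertions (spaced so that their
k-mer signatures do not interact), shotgun reads at configurable coverage
and substitution error rate, and a toy gene/exon annotation.  Everything is
a pure function of the seed.

Planted variants are rejection-sampled so that none of the reference k-mer
windows they disrupt survives in the strain genome — neither as one of the
novel k-mers the edit creates nor through a duplicate copy of the window
elsewhere in the reference; this keeps the presence/absence signature of
every planted event analytically exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kmers import canonicalize, reverse_complement

__all__ = [
    "SimulationConfig",
    "VariantSpec",
    "PlantedVariant",
    "ToyGene",
    "ConfigurationError",
    "make_reference",
    "plant_variants",
    "apply_variants",
    "simulate_reads",
    "make_annotation",
    "simulate_dataset",
    "write_truth_table",
    "read_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Invalid or unsatisfiable simulation configuration."""


@dataclass(frozen=True)
class PlantedVariant:
    """One planted difference of a strain genome vs. the reference.

    ``ref_start`` is 0-based on the reference.  For a substitution of
    length L, ``alt_seq`` (length L) replaces the reference bases
    [ref_start, ref_start+L).  For a deletion, L reference bases are
    removed from the strain.  For an insertion, ``alt_seq`` (length L) is
    inserted in the strain before reference position ``ref_start``.
    """

    contig: str
    ref_start: int
    vclass: str  # substitution | deletion | insertion
    length: int
    alt_seq: str = ""


@dataclass
class VariantSpec:
    """How many variants of each class to plant, and their geometry."""

    n_substitutions: int = 20
    n_deletions: int = 5
    n_insertions: int = 5
    substitution_length: int = 1
    indel_length_range: tuple[int, int] = (2, 10)
    min_spacing: int = 54  # >= 2k for k = 27: signatures cannot interact

    @property
    def total(self) -> int:
        return self.n_substitutions + self.n_deletions + self.n_insertions


@dataclass
class ToyGene:
    """A single-transcript toy gene; coordinates 0-based half-open."""

    gene_id: str
    symbol: str
    contig: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-strain dataset.

    Defaults mirror the deeper of the two sequencing regimes emulated
    (30x coverage, 150 bp reads) at a desk-scale genome, with a Q30-like
    per-base substitution error rate.  The seed fully determines every
    output.  ``variants_a``/``variants_b`` are the shared planted variants
    of each strain relative to the reference; by default strain A carries
    the planted signal and strain B is reference-identical, which makes the
    ground truth of a reference-vs-strain-A scan exactly the strain A
    truth table.
    """

    reference_length: int = 100_000
    n_contigs: int = 1
    gc: float = 0.41
    k: int = 27
    n_individuals_a: int = 4
    n_individuals_b: int = 4
    strain_a: str = "strainA"
    strain_b: str = "strainB"
    coverage: float = 30.0
    read_length: int = 150
    error_rate: float = 0.001
    seed: int = 0
    variants_a: VariantSpec = field(default_factory=VariantSpec)
    variants_b: VariantSpec = field(default_factory=lambda: VariantSpec(0, 0, 0))
    private_variant_rate: float = 0.0  # per-individual private substitutions per bp
    n_genes: int = 8

    def validate(self) -> None:
        numeric = {
            "reference_length": self.reference_length,
            "n_contigs": self.n_contigs,
            "k": self.k,
            "n_individuals_a": self.n_individuals_a,
            "n_individuals_b": self.n_individuals_b,
            "coverage": self.coverage,
            "read_length": self.read_length,
        }
        for name, v in numeric.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.gc <= 1.0:
            raise ConfigurationError(f"gc must be in [0, 1], got {self.gc}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.reference_length < 4 * self.k:
            raise ConfigurationError(
                f"reference_length {self.reference_length} < 4k = {4 * self.k}")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def make_reference(config: SimulationConfig) -> dict[str, str]:
    """Random reference with i.i.d. bases at the configured GC fraction."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    per = config.reference_length // config.n_contigs
    if per < 4 * config.k:
        raise ConfigurationError(
            f"contig length {per} < 4k = {4 * config.k}; reduce n_contigs")
    ref: dict[str, str] = {}
    for i in range(config.n_contigs):
        length = per if i < config.n_contigs - 1 else config.reference_length - per * (config.n_contigs - 1)
        ref[f"contig{i + 1}"] = _random_seq(rng, length, config.gc)
    return ref


def _kmer_set(seq: str, k: int) -> set[str]:
    return {canonicalize(seq[i:i + k]) for i in range(len(seq) - k + 1)}


def _signature_exact(affected: str, context: str, k: int,
                     duplicated: set[str]) -> bool:
    """True when the reference windows over ``affected`` all disappear.

    ``affected`` is the reference substring whose k-mer windows overlap the
    variant; ``context`` is the corresponding strain-side substring.  The
    variant's presence/absence signature is exact iff no affected window
    survives in the strain — neither as one of the novel context k-mers nor
    through a duplicate copy elsewhere in the reference.
    """
    aff = _kmer_set(affected, k)
    if aff & duplicated:
        return False
    return not (aff & _kmer_set(context, k))


def plant_variants(
    reference: Mapping[str, str],
    spec: VariantSpec,
    seed: int,
    k: int = 27,
) -> tuple[dict[str, str], list[PlantedVariant]]:
    """Derive a strain genome from the reference by planting variants.

    Variant positions are drawn per contig (proportionally to length) with
    pairwise separation >= ``spec.min_spacing`` on the reference and at
    least k + max indel length away from contig ends.  Each variant is
    rejection-sampled so that every reference k-mer window it disrupts
    truly disappears from the strain genome (no survival through novel
    junction/alt k-mers or duplicated reference windows).
    Applying the returned truth list to the reference reproduces the strain
    genome exactly; the truth list is sorted by (contig, position).
    """
    rng = np.random.default_rng(seed)
    if spec.total == 0:
        return dict(reference), []

    lo, hi = spec.indel_length_range
    margin = k + max(hi, spec.substitution_length)
    from collections import Counter
    counter: Counter[str] = Counter()
    for seq in reference.values():
        for i in range(len(seq) - k + 1):
            counter[canonicalize(seq[i:i + k])] += 1
    duplicated = {km for km, c in counter.items() if c > 1}

    # distribute variant count over contigs proportionally to usable length
    contigs = list(reference)
    usable = {c: max(0, len(reference[c]) - 2 * margin) for c in contigs}
    total_usable = sum(usable.values())
    if total_usable < spec.total * spec.min_spacing:
        raise ConfigurationError(
            f"cannot place {spec.total} variants with min_spacing={spec.min_spacing}: "
            f"usable reference length {total_usable} is too short")

    classes = (["substitution"] * spec.n_substitutions
               + ["deletion"] * spec.n_deletions
               + ["insertion"] * spec.n_insertions)
    rng.shuffle(classes)
    weights = np.array([usable[c] for c in contigs], dtype=float)
    assignment = rng.choice(len(contigs), size=len(classes), p=weights / weights.sum())

    placed: dict[str, list[int]] = {c: [] for c in contigs}
    truth: list[PlantedVariant] = []
    for vclass, ci in zip(classes, assignment):
        contig = contigs[int(ci)]
        seq = reference[contig]
        for _ in range(2000):
            p = int(rng.integers(margin, len(seq) - margin))
            if any(abs(p - q) < spec.min_spacing for q in placed[contig]):
                continue
            if vclass == "substitution":
                length = spec.substitution_length
                alt = "".join(
                    "ACGT".replace(seq[p + o], "")[rng.integers(3)]
                    for o in range(length)
                )
                affected = seq[p - k + 1:p + length + k - 1]
                context = seq[p - k + 1:p] + alt + seq[p + length:p + length + k - 1]
            elif vclass == "deletion":
                length = int(rng.integers(lo, hi + 1))
                alt = ""
                affected = seq[p - k + 1:p + length + k - 1]
                context = seq[p - k + 1:p] + seq[p + length:p + length + k - 1]
            else:  # insertion
                length = int(rng.integers(lo, hi + 1))
                alt = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
                affected = seq[p - k + 1:p + k - 1]
                context = seq[p - k + 1:p] + alt + seq[p:p + k - 1]
            if _signature_exact(affected, context, k, duplicated):
                placed[contig].append(p)
                truth.append(PlantedVariant(contig, p, vclass, length, alt))
                break
        else:
            raise ConfigurationError(
                f"could not place a {vclass} with min_spacing={spec.min_spacing} "
                f"on contig {contig}: rejection sampling exhausted")

    truth.sort(key=lambda v: (v.contig, v.ref_start))
    return apply_variants(reference, truth), truth


def apply_variants(reference: Mapping[str, str],
                   truth: Sequence[PlantedVariant]) -> dict[str, str]:
    """Apply a truth list to the reference, producing the strain genome."""
    genome = dict(reference)
    by_contig: dict[str, list[PlantedVariant]] = {}
    for v in truth:
        by_contig.setdefault(v.contig, []).append(v)
    for contig, variants in by_contig.items():
        seq = genome[contig]
        for v in sorted(variants, key=lambda v: v.ref_start, reverse=True):
            p = v.ref_start
            if v.vclass == "substitution":
                seq = seq[:p] + v.alt_seq + seq[p + v.length:]
            elif v.vclass == "deletion":
                seq = seq[:p] + seq[p + v.length:]
            elif v.vclass == "insertion":
                seq = seq[:p] + v.alt_seq + seq[p:]
            else:
                raise ValueError(f"unknown variant class {v.vclass!r}")
        genome[contig] = seq
    return genome


def simulate_reads(
    genome: Mapping[str, str] | str,
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
) -> list[str]:
    """Uniform shotgun reads with i.i.d. substitution errors.

    The number of reads is ceil(coverage * genome_length / read_length);
    strands are equiprobable and errors substitute a uniformly chosen
    different base.  Start positions may overhang contig ends and the read
    is clipped to the contig (mimicking the shorter fragments of a library
    at sequence boundaries), so per-base and per-k-mer coverage is uniform
    along the whole contig instead of decaying within a read length of the
    ends.  Single-end only: the downstream k-mer analysis is insensitive
    to read pairing.
    """
    if coverage <= 0:
        raise ConfigurationError(f"coverage must be positive, got {coverage}")
    contigs = {"genome": genome} if isinstance(genome, str) else dict(genome)
    glen = sum(len(s) for s in contigs.values())
    for name, s in contigs.items():
        if read_length > len(s):
            raise ConfigurationError(
                f"read_length {read_length} exceeds contig {name} length {len(s)}")
    rng = np.random.default_rng(seed)
    n_reads = int(np.ceil(coverage * glen / read_length))

    names = list(contigs)
    weights = np.array([len(contigs[c]) + read_length - 1 for c in names], dtype=float)
    which = rng.choice(len(names), size=n_reads, p=weights / weights.sum())
    reads: list[str] = []
    for ci, cname in enumerate(names):
        seq = contigs[cname]
        clen = len(seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        enc = np.zeros(arr.size, dtype=np.uint8)
        for b, v in zip(b"ACGT", range(4)):
            enc[arr == b] = v
        count = int((which == ci).sum())
        if count == 0:
            continue
        starts = rng.integers(-(read_length - 1), clen, size=count)
        strands = rng.integers(0, 2, size=count)
        for s, st in zip(starts, strands):
            lo, hi = max(0, int(s)), min(clen, int(s) + read_length)
            window = enc[lo:hi].copy()
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(window.size) < error_rate)
                if errs.size:
                    window[errs] = (window[errs] + rng.integers(1, 4, size=errs.size)) % 4
            read = _BASES[window].tobytes().decode()
            if st:
                read = reverse_complement(read)
            reads.append(read)
    return reads


def make_annotation(reference: Mapping[str, str],
                    genes: Sequence[ToyGene]) -> str:
    """Render toy genes as GFF3 text (gene/mRNA/exon/CDS per gene).

    Input coordinates are 0-based half-open and converted to GFF3's 1-based
    inclusive convention on output.  Exons double as CDS in these
    single-transcript toy models, so the coding span equals the exon span.
    """
    lines = ["##gff-version 3"]
    for g in genes:
        if g.contig not in reference:
            raise ConfigurationError(f"gene {g.gene_id}: unknown contig {g.contig}")
        clen = len(reference[g.contig])
        if not (0 <= g.start < g.end <= clen):
            raise ConfigurationError(f"gene {g.gene_id}: span outside contig")
        exons = sorted(g.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ConfigurationError(
                    f"gene {g.gene_id}: overlapping exons [{s1},{e1}) and [{s2},{e2})")
        for s, e in exons:
            if not (g.start <= s < e <= g.end):
                raise ConfigurationError(f"gene {g.gene_id}: exon [{s},{e}) outside gene")
        attrs = f"ID={g.gene_id};Name={g.symbol}"
        lines.append("\t".join([g.contig, "kstrain", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]))
        mrna = f"{g.gene_id}.t1"
        lines.append("\t".join([g.contig, "kstrain", "mRNA", str(g.start + 1),
                                str(g.end), ".", g.strand, ".",
                                f"ID={mrna};Parent={g.gene_id}"]))
        for i, (s, e) in enumerate(exons, 1):
            lines.append("\t".join([g.contig, "kstrain", "exon", str(s + 1),
                                    str(e), ".", g.strand, ".",
                                    f"ID={mrna}.exon{i};Parent={mrna}"]))
            lines.append("\t".join([g.contig, "kstrain", "CDS", str(s + 1),
                                    str(e), ".", g.strand, "0",
                                    f"ID={mrna}.cds{i};Parent={mrna}"]))
    return "\n".join(lines) + "\n"


def default_toy_genes(reference: Mapping[str, str], n_genes: int,
                      seed: int) -> list[ToyGene]:
    """Evenly spaced two-exon toy genes over the largest contig."""
    contig = max(reference, key=lambda c: len(reference[c]))
    clen = len(reference[contig])
    rng = np.random.default_rng(seed)
    genes: list[ToyGene] = []
    slot = clen // max(n_genes, 1)
    for i in range(n_genes):
        gstart = i * slot + slot // 10
        glen = min(slot * 8 // 10, 4000)
        if glen < 400:
            break
        e1 = (gstart, gstart + glen * 3 // 10)
        gap = glen // 5
        e2 = (e1[1] + gap, gstart + glen)
        genes.append(ToyGene(
            gene_id=f"gene{i + 1}", symbol=f"G{i + 1}", contig=contig,
            start=gstart, end=gstart + glen, exons=(e1, e2),
            strand="+" if rng.integers(2) else "-",
        ))
    return genes


_TRUTH_HEADER = "contig\tref_start\tvclass\tlength\talt_seq"


def write_truth_table(truth: Sequence[PlantedVariant], path: str | Path) -> None:
    """TSV truth table, 0-based reference coordinates."""
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for v in truth:
            fh.write(f"{v.contig}\t{v.ref_start}\t{v.vclass}\t{v.length}\t{v.alt_seq}\n")


def read_truth_table(path: str | Path) -> list[PlantedVariant]:
    truth: list[PlantedVariant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TRUTH_HEADER:
            raise ValueError(f"unexpected truth table header: {header!r}")
        for line in fh:
            contig, start, vclass, length, alt = (line.rstrip("\n").split("\t") + [""])[:5]
            truth.append(PlantedVariant(contig, int(start), vclass, int(length), alt))
    return truth


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, object]:
    """Generate a complete dataset on disk and return its in-memory parts.

    Writes reference.fa, per-individual FASTQ under <strain>/, toy
    annotation.gff3, and per-strain truth tables.  Returns a dict with the
    reference, strain genomes, truth lists, read manifests and paths.
    """
    from .io import write_fasta, write_fastq  # local import to avoid cycle

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    seed_of = lambda: int(master.integers(0, 2**31))

    reference = make_reference(config)
    ref_path = outdir / "reference.fa"
    write_fasta(reference, ref_path)

    genes = default_toy_genes(reference, config.n_genes, seed_of())
    gff_path = outdir / "annotation.gff3"
    gff_path.write_text(make_annotation(reference, genes))

    result: dict[str, object] = {
        "reference": reference, "genes": genes,
        "reference_path": ref_path, "gff3_path": gff_path,
        "strains": {},
    }
    manifests: dict[str, list[dict[str, object]]] = {}
    for strain, spec, n_ind in (
        (config.strain_a, config.variants_a, config.n_individuals_a),
        (config.strain_b, config.variants_b, config.n_individuals_b),
    ):
        genome, truth = plant_variants(reference, spec, seed_of(), k=config.k)
        truth_path = outdir / f"truth_{strain}.tsv"
        write_truth_table(truth, truth_path)
        sdir = outdir / strain
        sdir.mkdir(exist_ok=True)
        samples = []
        for i in range(1, n_ind + 1):
            ind_genome = genome
            private: list[PlantedVariant] = []
            if config.private_variant_rate > 0:
                n_priv = int(np.round(config.private_variant_rate
                                      * sum(len(s) for s in genome.values())))
                if n_priv:
                    ind_genome, private = plant_variants(
                        genome, VariantSpec(n_priv, 0, 0), seed_of(), k=config.k)
            reads = simulate_reads(ind_genome, config.coverage,
                                   config.read_length, config.error_rate, seed_of())
            sample_id = f"{strain}_{i}"
            fq = sdir / f"{sample_id}.fastq"
            write_fastq(reads, fq, prefix=sample_id)
            samples.append({"sample_id": sample_id, "fastq": fq,
                            "sex": "female" if i % 2 else "male",
                            "private_variants": private})
        manifests[strain] = samples
        result["strains"][strain] = {
            "genome": genome, "truth": truth, "truth_path": truth_path,
            "samples": samples,
        }
    result["manifests"] = manifests
    return result
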