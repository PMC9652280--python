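"""Benchmark utilities: score pipeline output against planted ground truth.

These helpers are deliberately independent of the scanning implementation:
the presence oracle tests each reference window by plain substring search,
and per-gene expectations are derived from the truth table by interval
arithmetic alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import compare as _compare
from . import kmers as _kmers
from .annotate import GeneModel, REGIONS
from .kmers import reverse_complement
from .simulate import PlantedVariant, VariantSpec, make_reference, plant_variants, simulate_reads, SimulationConfig

__all__ = [
    "brute_force_presence",
    "evaluate_planted_recovery",
    "evaluate_noise_robustness",
    "expected_gene_counts",
]


def brute_force_presence(ref_seq: str, strain_seqs: Sequence[str], k: int) -> np.ndarray:
    """Per-base presence by naive substring search (the scan oracle).

    A reference window is present when it, or its reverse complement,
    occurs verbatim in any strain sequence; a base is present when any
    window containing it is present.
    """
    n = len(ref_seq)
    present = np.zeros(n, dtype=bool)
    targets = [(s, reverse_complement(s)) for s in strain_seqs]
    for i in range(n - k + 1):
        w = ref_seq[i:i + k]
        if any(b not in "ACGT" for b in w):
            continue
        if any(w in s or w in rc for s, rc in targets):
            present[i:i + k] = True
    return present


@dataclass
class PlantedRecovery:
    """Scorecard of a reference scan against the planted truth list."""

    n_true: int
    n_recovered: int
    recall: float
    n_altered_calls: int
    n_insertion_calls: int
    false_positive_calls: int
    substitution_exact: int  # planted substitutions called as exactly 1 altered bp
    deletion_exact: int      # planted deletions called as exactly L altered bp, 1 run
    insertion_exact: int     # planted insertions with one junction call of run length k-1
    insertion_altered_bp: int
    total_altered_bp: int
    thresholds: list[int] = field(default_factory=list)


def score_calls(truth: Sequence[PlantedVariant],
                altered: Sequence[_compare.VariantCall],
                insertions: Sequence[_compare.VariantCall],
                k: int) -> PlantedRecovery:
    """Compare called variants with a planted truth list, position-exactly."""
    altered_by_key = {(c.contig, c.start, c.end) for c in altered}
    ins_by_pos = {(c.contig, c.start): c for c in insertions}
    sub_ok = del_ok = ins_ok = recovered = 0
    for v in truth:
        if v.vclass == "substitution":
            hit = (v.contig, v.ref_start, v.ref_start + v.length) in altered_by_key
            sub_ok += hit
            recovered += hit
        elif v.vclass == "deletion":
            hit = (v.contig, v.ref_start, v.ref_start + v.length) in altered_by_key
            del_ok += hit
            recovered += hit
        elif v.vclass == "insertion":
            call = ins_by_pos.get((v.contig, v.ref_start))
            hit = call is not None and call.length == k - 1
            ins_ok += hit
            recovered += hit
    n_true = len(truth)
    false_pos = (len(altered) + len(insertions)) - recovered
    return PlantedRecovery(
        n_true=n_true, n_recovered=recovered,
        recall=recovered / n_true if n_true else 1.0,
        n_altered_calls=len(altered), n_insertion_calls=len(insertions),
        false_positive_calls=false_pos,
        substitution_exact=sub_ok, deletion_exact=del_ok, insertion_exact=ins_ok,
        insertion_altered_bp=sum(c.end - c.start for c in insertions),
        total_altered_bp=sum(c.end - c.start for c in altered),
    )


def evaluate_planted_recovery(
    seed: int,
    reference_length: int = 100_000,
    n_individuals: int = 4,
    coverage: float = 30.0,
    read_length: int = 150,
    error_rate: float = 0.0,
    k: int = 27,
    m: int = 3,
    spec: VariantSpec | None = None,
) -> tuple[PlantedRecovery, dict]:
    """Full single-strain study: plant variants, sequence, scan, score.

    Returns the scorecard plus the intermediate objects (reference, truth,
    scan, calls) for further inspection.
    """
    if spec is None:
        spec = VariantSpec(20, 5, 5, min_spacing=2 * k)
    master = np.random.default_rng(seed)
    sub = lambda: int(master.integers(0, 2**31))
    config = SimulationConfig(reference_length=reference_length, k=k, seed=sub())
    reference = make_reference(config)
    genome, truth = plant_variants(reference, spec, sub(), k=k)

    sets = []
    thresholds = []
    for _ in range(n_individuals):
        reads = simulate_reads(genome, coverage, read_length, error_rate, sub())
        table = _kmers.count_kmers(reads, k)
        t = _kmers.infer_threshold(table.histogram())
        thresholds.append(t.threshold)
        sets.append(_kmers.individual_set(table, t))
    empty = _kmers.IndividualKmerSet(
        k=k, codes=np.empty(0, dtype=np.uint64), threshold_used=1)
    agg = _compare.aggregate({"strainA": sets, "other": [empty]})
    sset = _compare.strain_set(agg, "strainA", m)
    scan = _compare.scan_reference(reference, sset)
    altered = _compare.call_altered_runs(scan)
    insertions = _compare.call_insertions(scan)
    score = score_calls(truth, altered, insertions, k)
    score.thresholds = thresholds
    extras = {"reference": reference, "genome": genome, "truth": truth,
              "aggregate": agg, "strain_set": sset, "scan": scan,
              "altered": altered, "insertions": insertions}
    return score, extras


def evaluate_noise_robustness(
    seed: int,
    reference_length: int = 100_000,
    coverage: float = 30.0,
    read_length: int = 150,
    error_rate: float = 0.01,
    k: int = 27,
) -> dict[str, float]:
    """Error/genomic k-mer separation achieved by the inferred threshold.

    Error-only k-mers are read k-mers absent from the genome; genomic
    k-mers come from direct window enumeration of the genome itself.
    """
    master = np.random.default_rng(seed)
    sub = lambda: int(master.integers(0, 2**31))
    config = SimulationConfig(reference_length=reference_length, k=k, seed=sub())
    genome = make_reference(config)
    reads = simulate_reads(genome, coverage, read_length, error_rate, sub())
    table = _kmers.count_kmers(reads, k)
    t = _kmers.infer_threshold(table.histogram())
    kept = table.counts >= t.threshold

    true_codes = _kmers.genome_kmer_set(genome, k).codes
    is_genomic = np.isin(table.codes, true_codes)
    n_err = int((~is_genomic).sum())
    n_err_kept = int((~is_genomic & kept).sum())
    genomic_kept = np.isin(true_codes, table.codes[kept])
    member = _kmers.individual_set(table, t)
    inter = np.intersect1d(member.codes, true_codes).size
    union = np.union1d(member.codes, true_codes).size
    return {
        "threshold": t.threshold,
        "n_error_kmers": n_err,
        "n_genomic_kmers": int(true_codes.size),
        "error_removal_fraction": 1.0 - (n_err_kept / n_err if n_err else 0.0),
        "genomic_retention_fraction": float(genomic_kept.mean()),
        "jaccard": inter / union if union else 1.0,
    }


def _truth_altered_intervals(truth: Sequence[PlantedVariant]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for v in truth:
        if v.vclass in ("substitution", "deletion"):
            out.setdefault(v.contig, []).append((v.ref_start, v.ref_start + v.length))
    return out


def expected_gene_counts(truth: Sequence[PlantedVariant],
                         genes: Sequence[GeneModel]) -> dict[str, dict[str, tuple[int, int]]]:
    """Per gene and region, the (altered_bp, variants) implied by the truth.

    Pure interval arithmetic on the truth table — substitutions/deletions
    contribute their reference footprint as altered bases and one variant
    per region they overlap; insertions contribute zero altered bases and
    one variant per region whose interior contains the junction.
    Assumes planted variants are spaced widely enough not to merge.
    """
    altered_iv = _truth_altered_intervals(truth)
    expected: dict[str, dict[str, tuple[int, int]]] = {}
    for gene in genes:
        per_region: dict[str, tuple[int, int]] = {}
        for region in REGIONS:
            intervals = gene.region_intervals(region)
            bp = 0
            nvar = 0
            for s, e in altered_iv.get(gene.contig, []):
                ov = sum(max(0, min(e, ie) - max(s, is_)) for is_, ie in intervals)
                bp += ov
                if any(s < ie and e > is_ for is_, ie in intervals):
                    nvar += 1
            for v in truth:
                if v.vclass == "insertion" and v.contig == gene.contig:
                    if any(is_ < v.ref_start < ie for is_, ie in intervals):
                        nvar += 1
            per_region[region] = (bp, nvar)
        expected[gene.gene_id] = per_region
    return expected
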