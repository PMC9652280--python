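"""Per-gene aggregation of altered base pairs and variant calls.

Variant calls and per-base altered masks from a reference scan are
intersected with a GFF3 gene annotation.  For each gene three regions are
counted: the full genomic span, the coding span (first to last coding base
over all transcripts), and the union of exons over all transcripts.  Counts
are also expressed per Mbp of region length, which is the scale on which
genes of different sizes are compared and on which "heavily altered in one
strain, unchanged in the other" gene lists are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

from .compare import ReferenceScan, VariantCall

__all__ = [
    "GeneModel",
    "RegionStats",
    "GeneAlterationRecord",
    "REGIONS",
    "load_annotation",
    "count_by_gene",
    "differential_genes",
    "export_gene_list",
    "records_to_frame",
]

REGIONS = ("gene", "coding", "exons")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its coding span and transcript-union exon intervals.

    All coordinates 0-based half-open (converted from GFF3's 1-based
    inclusive).  ``exons`` is the merged union over all transcripts,
    sorted and non-overlapping.
    """

    gene_id: str
    symbol: str
    contig: str
    strand: str
    start: int
    end: int
    coding_start: int | None
    coding_end: int | None
    exons: tuple[tuple[int, int], ...]

    def region_intervals(self, region: str) -> tuple[tuple[int, int], ...]:
        if region == "gene":
            return ((self.start, self.end),)
        if region == "coding":
            if self.coding_start is None:
                return ()
            return ((self.coding_start, self.coding_end),)
        if region == "exons":
            return self.exons
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def load_annotation(gff3: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into gene models, sorted by (contig, start)."""
    try:
        db = gffutils.create_db(str(gff3), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gstart, gend = g.start - 1, g.end
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        for f in db.children(g, featuretype="exon"):
            exons.append((f.start - 1, f.end))
        for f in db.children(g, featuretype="CDS"):
            if f.start - 1 < gstart or f.end > gend:
                raise ValueError(
                    f"CDS {f.id or f.attributes} at [{f.start},{f.end}] lies outside "
                    f"its gene {g.id} [{g.start},{g.end}]")
            cds.append((f.start - 1, f.end))
        symbol = (g.attributes.get("Name") or g.attributes.get("gene_name") or [g.id])[0]
        genes.append(GeneModel(
            gene_id=g.id, symbol=symbol, contig=g.seqid, strand=g.strand,
            start=gstart, end=gend,
            coding_start=min(s for s, _ in cds) if cds else None,
            coding_end=max(e for _, e in cds) if cds else None,
            exons=_merge_intervals(exons),
        ))
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


@dataclass(frozen=True)
class RegionStats:
    """Counts and per-Mbp rates of one region of one gene."""

    altered_bp: int
    variants: int
    length: int
    altered_bp_per_mbp: float
    variants_per_mbp: float


@dataclass(frozen=True)
class GeneAlterationRecord:
    """Altered-bp/variant counts of one gene against one strain."""

    gene_id: str
    symbol: str
    strain: str
    regions: dict[str, RegionStats]


def _rate(count: int, length: int) -> float:
    return count / length * 1e6 if length else 0.0


def count_by_gene(scan: ReferenceScan, variants: Sequence[VariantCall],
                  genes: Sequence[GeneModel]) -> list[GeneAlterationRecord]:
    """Count altered base pairs and variant calls per gene and region.

    ``altered_bp(r)`` counts altered bases inside region r.  ``variants(r)``
    counts distinct calls intersecting r: an altered run intersects when its
    interval overlaps r (a boundary-straddling call is counted once, and a
    call overlapping two genes is counted in both); a zero-width insertion
    intersects when its junction lies strictly inside r.
    """
    cums: dict[str, np.ndarray] = {}
    for name, contig in scan.contigs.items():
        c = np.zeros(contig.altered.size + 1, dtype=np.int64)
        np.cumsum(contig.altered, out=c[1:])
        cums[name] = c
    by_contig: dict[str, list[VariantCall]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)

    records: list[GeneAlterationRecord] = []
    for gene in genes:
        if gene.contig not in cums:
            raise ValueError(
                f"gene {gene.gene_id} lies on contig {gene.contig!r} absent from the scan")
        cum = cums[gene.contig]
        calls = by_contig.get(gene.contig, [])
        regions: dict[str, RegionStats] = {}
        for region in REGIONS:
            intervals = gene.region_intervals(region)
            length = sum(e - s for s, e in intervals)
            altered = sum(int(cum[e] - cum[s]) for s, e in intervals)
            hit = 0
            for call in calls:
                if call.vclass == "insertion":
                    if any(s < call.start < e for s, e in intervals):
                        hit += 1
                else:
                    if any(call.start < e and call.end > s for s, e in intervals):
                        hit += 1
            regions[region] = RegionStats(
                altered_bp=altered, variants=hit, length=length,
                altered_bp_per_mbp=_rate(altered, length),
                variants_per_mbp=_rate(hit, length),
            )
        records.append(GeneAlterationRecord(
            gene_id=gene.gene_id, symbol=gene.symbol, strain=scan.strain,
            regions=regions))
    return records


def differential_genes(
    records_a: Sequence[GeneAlterationRecord],
    records_b: Sequence[GeneAlterationRecord],
    region: str = "exons",
    metric: str = "variants_per_mbp",
    min_rate: float = 1.0,
    max_rate: float = 0.0,
) -> list[GeneAlterationRecord]:
    """Genes heavily altered in strain A but (nearly) unchanged in strain B.

    Selects genes whose strain-A rate >= ``min_rate`` and strain-B rate
    <= ``max_rate`` for the chosen region and metric, sorted by strain-A
    rate descending.  Swap the record lists for the symmetric call.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if metric not in ("variants_per_mbp", "altered_bp_per_mbp"):
        raise ValueError(f"unknown metric {metric!r}")
    b_by_id = {r.gene_id: r for r in records_b}
    out: list[tuple[float, GeneAlterationRecord]] = []
    for ra in records_a:
        rb = b_by_id.get(ra.gene_id)
        if rb is None:
            raise ValueError(f"gene {ra.gene_id} missing from strain-B records")
        va = getattr(ra.regions[region], metric)
        vb = getattr(rb.regions[region], metric)
        if va >= min_rate and vb <= max_rate:
            out.append((va, ra))
    out.sort(key=lambda t: (-t[0], t[1].gene_id))
    return [r for _, r in out]


def export_gene_list(records_or_symbols: Iterable, path: str | Path | None = None) -> list[str]:
    """Deduplicated, sorted gene-symbol list, one symbol per line.

    Accepts GeneAlterationRecords or plain symbol strings; this is the
    upload format of protein-association query tools.
    """
    symbols = set()
    for item in records_or_symbols:
        sym = item.symbol if isinstance(item, GeneAlterationRecord) else str(item)
        if not sym or any(ch.isspace() for ch in sym):
            raise ValueError(f"invalid gene symbol {sym!r}")
        symbols.add(sym)
    lines = sorted(symbols)
    if path is not None:
        Path(path).write_text("".join(f"{s}\n" for s in lines))
    return lines


def records_to_frame(records: Sequence[GeneAlterationRecord]) -> pd.DataFrame:
    """One row per gene x region x strain, for TSV export."""
    rows = []
    for r in records:
        for region, st in r.regions.items():
            rows.append({
                "gene_id": r.gene_id, "symbol": r.symbol, "strain": r.strain,
                "region": region, "length_bp": st.length,
                "altered_bp": st.altered_bp, "variants": st.variants,
                "altered_bp_per_mbp": st.altered_bp_per_mbp,
                "variants_per_mbp": st.variants_per_mbp,
            })
    return pd.DataFrame(rows)
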