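"""Chromosomal-scale length variation (CSLV) feature extraction.

A CSLV feature is the mean log2 copy-ratio over a fixed genomic span —
typically a quarter of a chromosome (giving 88 features over the 22
autosomes) or a whole chromosome (23 features over 1-22 + X). From per-SNP
l2r matrices the feature is the plain mean of observed probe values inside
the span; from SEG-style segment calls it is the base-pair-weighted mean of
segment means, with unreported (diploid) base pairs contributing the gap
value 0.

Feature columns are named ``<chromosome>_q<index>`` with segment indices
counted from 0, e.g. ``22_q3`` is the distal quarter of chromosome 22.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cslv.io import L2RMatrix, SegmentRecord, normalize_chromosome

__all__ = [
    "SegmentPartition",
    "partition_chromosomes",
    "cslv_from_l2r",
    "cslv_from_segments",
    "assemble_features",
    "ukb_feature_table",
    "tcga_feature_table",
]


@dataclass(frozen=True)
class Span:
    """One partition span, 0-based half-open."""

    chromosome: str
    segment: int
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chromosome}_q{self.segment}"


@dataclass
class SegmentPartition:
    """Equal-width tiling of chromosomes into ``k`` spans each.

    Spans tile [0, length) per chromosome without overlap; widths differ by
    at most 1 bp (remainder base pairs go to the earliest spans).
    """

    spans: list[Span]
    k: int

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            spans = self.spans_for(chrom)
            if spans[0].start != 0:
                raise ValueError(f"{chrom}: partition must start at 0")
            for a, b in zip(spans, spans[1:]):
                if b.start != a.end:
                    raise ValueError(f"{chrom}: partition spans must tile without gaps")
            widths = {s.width for s in spans}
            if max(widths) - min(widths) > 1:
                raise ValueError(f"{chrom}: span widths differ by more than 1 bp")

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for span in self.spans:
            seen.setdefault(span.chromosome, None)
        return list(seen)

    @property
    def feature_names(self) -> list[str]:
        return [span.name for span in self.spans]

    def spans_for(self, chromosome: str) -> list[Span]:
        chromosome = normalize_chromosome(chromosome)
        spans = [s for s in self.spans if s.chromosome == chromosome]
        if not spans:
            raise KeyError(f"chromosome {chromosome!r} not in partition")
        return spans

    def chromosome_length(self, chromosome: str) -> int:
        return self.spans_for(chromosome)[-1].end

    def __len__(self) -> int:
        return len(self.spans)


def _partition_one(chromosome: str, length: int, k: int) -> list[Span]:
    base, remainder = divmod(length, k)
    spans = []
    start = 0
    for i in range(k):
        width = base + (1 if i < remainder else 0)
        spans.append(Span(chromosome, i, start, start + width))
        start += width
    return spans


def partition_chromosomes(
    sizes: Mapping[str, int],
    k: int = 4,
    include_x: bool = False,
    chromosomes: Sequence[str] | None = None,
) -> SegmentPartition:
    """Tile each chromosome into ``k`` equal-width spans.

    Parameters
    ----------
    sizes : mapping of chromosome name to length in bp.
    k : spans per chromosome (4 gives quarter-chromosome features).
    include_x : keep the X chromosome if present in ``sizes``.
    chromosomes : explicit subset/order; unknown names raise ``KeyError``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sizes = {normalize_chromosome(name): int(length) for name, length in sizes.items()}
    if chromosomes is None:
        names = [c for c in sizes if c != "X" or include_x]
    else:
        names = [normalize_chromosome(c) for c in chromosomes]
        unknown = [c for c in names if c not in sizes]
        if unknown:
            raise KeyError(f"unknown chromosome(s) requested: {unknown}")
        if not include_x:
            names = [c for c in names if c != "X"]
    spans: list[Span] = []
    for name in names:
        if sizes[name] <= 0:
            raise ValueError(f"chromosome {name}: non-positive length")
        if sizes[name] < k:
            raise ValueError(f"chromosome {name}: length {sizes[name]} shorter than k={k}")
        spans.extend(_partition_one(name, sizes[name], k))
    return SegmentPartition(spans, k)


def observed_extent_sizes(matrices: Iterable[L2RMatrix]) -> dict[str, int]:
    """Chromosome sizes taken from the largest observed SNP position.

    Alternative to UCSC chrom.sizes when probe coverage, not the assembly,
    should define span boundaries.
    """
    return {m.chromosome: int(m.positions[-1]) for m in matrices}


def cslv_from_l2r(matrix: L2RMatrix, partition: SegmentPartition) -> pd.DataFrame:
    """CSLV features for one chromosome from a per-SNP l2r matrix.

    Each feature is the arithmetic mean of non-missing l2r values at SNPs
    whose position falls in the span; a span with no observed SNPs gets 0
    (the diploid expectation). Returns samples x k DataFrame.
    """
    spans = partition.spans_for(matrix.chromosome)
    pos0 = matrix.positions - 1  # 0-based
    out = np.zeros((matrix.n_samples, len(spans)))
    for j, span in enumerate(spans):
        i0 = np.searchsorted(pos0, span.start, side="left")
        i1 = np.searchsorted(pos0, span.end, side="left")
        block = matrix.values[i0:i1]
        if block.size == 0:
            continue
        observed = ~np.isnan(block)
        counts = observed.sum(axis=0)
        sums = np.where(observed, block, 0.0).sum(axis=0)
        out[:, j] = np.divide(sums, counts, out=np.zeros(matrix.n_samples), where=counts > 0)
    return pd.DataFrame(out, index=pd.Index(matrix.sample_ids, name="sample_id"),
                        columns=[s.name for s in spans])


def _resolve_overlaps(
    records: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Resolve overlapping intervals by later-record precedence.

    Input/output intervals are 0-based half-open (start, end, mean); output
    intervals are disjoint, in no particular order.
    """
    resolved: list[tuple[int, int, float]] = []
    for start, end, mean in records:
        clipped: list[tuple[int, int, float]] = []
        for s, e, m in resolved:
            if e <= start or s >= end:  # no overlap
                clipped.append((s, e, m))
                continue
            if s < start:
                clipped.append((s, start, m))
            if e > end:
                clipped.append((end, e, m))
        clipped.append((start, end, mean))
        resolved = clipped
    return resolved


def cslv_from_segments(
    records: Sequence[SegmentRecord],
    partition: SegmentPartition,
    gap_value: float = 0.0,
    sample_ids: Sequence[str] | None = None,
    policy: str = "weighted",
) -> pd.DataFrame:
    """CSLV features from SEG-style segment records.

    With ``policy="weighted"`` (default) each feature is the base-pair
    weighted mean over the span: sum(overlap_bp * segment_mean) plus
    uncovered_bp * ``gap_value``, divided by span width. Unrecorded base
    pairs are treated as diploid (gap value 0). With ``policy="longest"``
    the feature is the segment mean of the record with the largest overlap
    in the span (``gap_value`` when none overlaps).

    Overlapping records for one sample are resolved by later-record
    precedence (a robustness rule; upstream segmentation emits disjoint
    segments). Records extending beyond the chromosome are clipped with a
    warning. ``sample_ids`` fixes the output row universe; samples without
    records get all-gap features.
    """
    if policy not in ("weighted", "longest"):
        raise ValueError(f"unknown policy {policy!r}")
    if sample_ids is None:
        seen: dict[str, None] = {}
        for rec in records:
            seen.setdefault(rec.sample_id, None)
        sample_ids = list(seen)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample_ids must be unique")

    # bucket records by (sample, chromosome), clipping to chromosome extent
    chrom_set = set(partition.chromosomes)
    buckets: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
    for rec in records:
        if rec.chromosome not in chrom_set:
            continue
        length = partition.chromosome_length(rec.chromosome)
        start, end = rec.interval
        if start >= length:
            warnings.warn(
                f"segment {rec.sample_id}:{rec.chromosome}:{rec.start}-{rec.end} "
                f"lies beyond chromosome length {length}; dropped"
            )
            continue
        if end > length:
            warnings.warn(
                f"segment {rec.sample_id}:{rec.chromosome}:{rec.start}-{rec.end} "
                f"clipped to chromosome length {length}"
            )
            end = length
        buckets.setdefault((rec.sample_id, rec.chromosome), []).append(
            (start, end, rec.segment_mean)
        )

    sample_index = {s: i for i, s in enumerate(sample_ids)}
    values = np.full((len(sample_ids), len(partition.spans)), np.nan)
    span_cols = {id(span): j for j, span in enumerate(partition.spans)}

    for (sample, chrom), recs in buckets.items():
        if sample not in sample_index:
            raise ValueError(f"record for unknown sample {sample!r}")
        row = sample_index[sample]
        pieces = _resolve_overlaps(recs)
        for span in partition.spans_for(chrom):
            j = span_cols[id(span)]
            if policy == "weighted":
                covered = 0
                total = 0.0
                for s, e, m in pieces:
                    ov = min(e, span.end) - max(s, span.start)
                    if ov > 0:
                        covered += ov
                        total += ov * m
                total += (span.width - covered) * gap_value
                values[row, j] = total / span.width
            else:  # longest
                best_ov, best_mean = 0, gap_value
                for s, e, m in pieces:
                    ov = min(e, span.end) - max(s, span.start)
                    if ov > best_ov:
                        best_ov, best_mean = ov, m
                values[row, j] = best_mean

    # spans never touched by any record are fully uncovered
    values = np.where(np.isnan(values), gap_value, values)
    return pd.DataFrame(values, index=pd.Index(list(sample_ids), name="sample_id"),
                        columns=partition.feature_names)


def assemble_features(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Column-concatenate per-chromosome feature tables, aligned by sample id.

    All tables must cover exactly the same sample set; a mismatch raises
    with the symmetric difference listed. Rows follow the first table's
    order.
    """
    if not tables:
        raise ValueError("no feature tables to assemble")
    reference = tables[0].index
    ref_set = set(reference)
    for i, table in enumerate(tables[1:], start=1):
        other = set(table.index)
        if other != ref_set:
            diff = sorted(ref_set.symmetric_difference(other))
            raise ValueError(f"table {i} sample set mismatch; symmetric difference: {diff}")
    aligned = [tables[0]] + [t.reindex(reference) for t in tables[1:]]
    combined = pd.concat(aligned, axis=1)
    if combined.columns.duplicated().any():
        dupes = combined.columns[combined.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes}")
    return combined


def ukb_feature_table(
    matrices: Sequence[L2RMatrix],
    sizes: Mapping[str, int],
    k: int = 4,
) -> pd.DataFrame:
    """UK Biobank-style CSLV table: autosomes only, quarter-chromosome spans.

    With 22 autosomes and k=4 this yields the 88-feature characterization;
    the X chromosome is always excluded on this path.
    """
    partition = partition_chromosomes(sizes, k=k, include_x=False)
    tables = [cslv_from_l2r(m, partition) for m in matrices if m.chromosome != "X"]
    return assemble_features(tables)


def tcga_feature_table(
    records: Sequence[SegmentRecord],
    sizes: Mapping[str, int],
    sample_ids: Sequence[str] | None = None,
    policy: str = "weighted",
) -> pd.DataFrame:
    """TCGA-style CSLV table: whole-chromosome spans on 1-22 + X (23 features)."""
    partition = partition_chromosomes(sizes, k=1, include_x=True)
    return cslv_from_segments(records, partition, sample_ids=sample_ids, policy=policy)
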