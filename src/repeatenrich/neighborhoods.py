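"""Gene neighborhoods and repeat-overlap queries.

Five window kinds are supported, all strand-aware and clipped to the
chromosome: upstream of the TSS, downstream of the TSS, downstream of the
gene end, flanking the TSS on both sides ("around TSS"), and flanking the
whole gene body ("around gene", body excluded).  For the two "around" kinds
the size applies PER SIDE, so the total unclipped footprint is twice the
nominal size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneRecord, RepeatInstance

logger = logging.getLogger(__name__)

__all__ = [
    "KINDS",
    "SIZE_LADDER",
    "NeighborhoodSpec",
    "Region",
    "make_neighborhood",
    "RepeatIndex",
    "repeats_in_region",
    "per_gene_class_composition",
]

KINDS = (
    "upstream_tss",
    "downstream_tss",
    "downstream_gene_end",
    "around_tss",
    "around_gene",
)

#: Recommended window sizes (bp); any positive size is accepted.
SIZE_LADDER = (
    10_000,
    20_000,
    50_000,
    100_000,
    200_000,
    500_000,
    1_000_000,
    1_500_000,
    2_000_000,
    2_500_000,
    3_000_000,
)


@dataclass(frozen=True)
class NeighborhoodSpec:
    kind: str
    size: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown neighborhood kind {self.kind!r}; expected one of {KINDS}")
        if self.size <= 0:
            raise ValueError("neighborhood size must be positive")


@dataclass(frozen=True)
class Region:
    """A concrete genomic window (0-based half-open), optionally owned by a gene."""

    chrom: str
    start: int
    end: int
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def _raw_windows(gene: GeneRecord, spec: NeighborhoodSpec) -> list[tuple[int, int]]:
    s = spec.size
    t = gene.tss
    if spec.kind == "around_tss":
        return [(t - s, t + s)]
    if spec.kind == "around_gene":
        return [(gene.gene_start - s, gene.gene_start), (gene.gene_end, gene.gene_end + s)]
    if gene.strand == "+":
        if spec.kind == "upstream_tss":
            return [(t - s, t)]
        if spec.kind == "downstream_tss":
            return [(t, t + s)]
        return [(gene.gene_end, gene.gene_end + s)]  # downstream_gene_end
    # minus strand: mirror image — upstream extends to higher coordinates
    if spec.kind == "upstream_tss":
        return [(t, t + s)]
    if spec.kind == "downstream_tss":
        return [(t - s, t)]
    return [(gene.gene_start - s, gene.gene_start)]


def make_neighborhood(
    gene: GeneRecord, spec: NeighborhoodSpec, chrom_len: int
) -> list[Region]:
    """Concrete window(s) of ``spec`` for ``gene``, clipped to ``[0, chrom_len)``.

    Returns up to two regions (two for ``around_gene``); a window clipped to
    nothing yields no region.
    """
    if chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    regions = []
    for start, end in _raw_windows(gene, spec):
        start = max(0, start)
        end = min(chrom_len, end)
        if start < end:
            regions.append(Region(gene.chrom, start, end, gene_id=gene.gene_id))
    return regions


class RepeatIndex:
    """Per-chromosome start-sorted index over repeat instances.

    Queries return instances with >=1 bp overlap (``overlap`` rule) or fully
    inside the window (``contained`` rule).  Lookup is a binary search on the
    start coordinate followed by a vectorized end-coordinate mask, which is
    fast enough for the genome-wide background scans.
    """

    def __init__(self, repeats: Sequence[RepeatInstance]) -> None:
        self.repeats = list(repeats)
        names: dict[str, int] = {}
        classes: dict[str, str] = {}
        for r in self.repeats:
            if r.repeat_name not in names:
                names[r.repeat_name] = len(names)
                classes[r.repeat_name] = r.repeat_class
        self.names: list[str] = list(names)
        self.class_of: dict[str, str] = classes
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, r in enumerate(self.repeats):
            by_chrom.setdefault(r.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            idx_arr = np.asarray(idx, dtype=np.int64)
            starts = np.asarray([self.repeats[i].start for i in idx], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            idx_arr = idx_arr[order]
            starts = starts[order]
            ends = np.asarray([self.repeats[i].end for i in idx_arr], dtype=np.int64)
            name_ids = np.asarray(
                [names[self.repeats[i].repeat_name] for i in idx_arr], dtype=np.int64
            )
            self._by_chrom[chrom] = (starts, ends, name_ids, idx_arr)
        self._warned_chroms: set[str] = set()

    def __len__(self) -> int:
        return len(self.repeats)

    def _hits(self, chrom: str, qs: int, qe: int, rule: str) -> np.ndarray:
        """Positions (into the per-chrom sorted arrays) of matching instances."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            if chrom not in self._warned_chroms:
                logger.warning("query on unknown chromosome %r: no repeats indexed there", chrom)
                self._warned_chroms.add(chrom)
            return np.empty(0, dtype=np.int64)
        starts, ends, _, _ = entry
        j = int(np.searchsorted(starts, qe, side="left"))
        if rule == "overlap":
            mask = ends[:j] > qs
        elif rule == "contained":
            mask = (starts[:j] >= qs) & (ends[:j] <= qe)
        else:
            raise ValueError(f"unknown overlap rule {rule!r}")
        return np.nonzero(mask)[0]

    def query(self, region: Region, rule: str = "overlap") -> list[RepeatInstance]:
        """All instances overlapping ``region`` (each reported once)."""
        entry = self._by_chrom.get(region.chrom)
        pos = self._hits(region.chrom, region.start, region.end, rule)
        if entry is None or pos.size == 0:
            return []
        idx = entry[3][pos]
        return [self.repeats[i] for i in idx]

    def name_ids_in(self, chrom: str, start: int, end: int, rule: str = "overlap") -> np.ndarray:
        """Name ids (one per overlapping occurrence) inside a window."""
        entry = self._by_chrom.get(chrom)
        pos = self._hits(chrom, start, end, rule)
        if entry is None or pos.size == 0:
            return np.empty(0, dtype=np.int64)
        return entry[2][pos]

    def genome_wide_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {name: 0 for name in self.names}
        for r in self.repeats:
            counts[r.repeat_name] += 1
        return counts


def repeats_in_region(
    index: RepeatIndex, region: Region, rule: str = "overlap"
) -> list[RepeatInstance]:
    """Instances with >=1 bp overlap with ``region`` (half-open abutment does
    not count).  Unknown chromosome -> empty list with a logged warning."""
    return index.query(region, rule=rule)


def per_gene_class_composition(
    gene: GeneRecord,
    spec: NeighborhoodSpec,
    index: RepeatIndex,
    chrom_len: int,
    rule: str = "overlap",
) -> dict[str, float]:
    """Percentage of neighborhood repeat occurrences per repeat class.

    Percentages sum to 100 whenever any repeat is present; an empty
    neighborhood yields an empty mapping.
    """
    counts: dict[str, int] = {}
    for region in make_neighborhood(gene, spec, chrom_len):
        for inst in index.query(region, rule=rule):
            counts[inst.repeat_class] = counts.get(inst.repeat_class, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {cls: 100.0 * c / total for cls, c in sorted(counts.items())}


def neighborhood_regions(
    genes: Iterable[GeneRecord],
    spec: NeighborhoodSpec,
    chrom_sizes: dict[str, int],
) -> list[Region]:
    """Windows of ``spec`` for every gene (flattened, clipped)."""
    regions: list[Region] = []
    for g in genes:
        try:
            chrom_len = chrom_sizes[g.chrom]
        except KeyError:
            raise KeyError(f"gene {g.gene_id}: no length known for chromosome {g.chrom!r}")
        regions.extend(make_neighborhood(g, spec, chrom_len))
    return regions
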