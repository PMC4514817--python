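"""The three analyses: gene-set, locus, and orthologous gene-set.

Each analysis resolves its inputs, obtains (or reuses) the appropriate
background model, computes observed counts, and runs the binomial screen.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .enrichment import (
    GENE_COUNTS,
    REPEAT_COUNTS,
    WHOLE_GENOME,
    BackgroundModel,
    EnrichmentResult,
    background_gene_counts,
    background_repeat_counts,
    background_whole_genome,
    degenerate_repeats,
    enrich,
    observed_counts,
    observed_counts_regions,
)
from .io_formats import (
    AliasTable,
    GeneRecord,
    OrthologMap,
    read_alias_table,
    read_chrom_sizes,
    read_gene_table,
    read_repeatmasker_out,
)
from .neighborhoods import NeighborhoodSpec, Region, RepeatIndex, per_gene_class_composition

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesBundle",
    "LocusQuery",
    "GeneSetResult",
    "OrthologResult",
    "analyze_gene_set",
    "analyze_locus",
    "analyze_ortholog_sets",
    "parse_locus_string",
]


# ---------------------------------------------------------------------------
# Species bundle
# ---------------------------------------------------------------------------


@dataclass
class SpeciesBundle:
    """One species' gene table, repeat index, chromosome sizes, and alias
    table, with cached background models keyed by (mode, kind, size)."""

    species: str
    genes: list[GeneRecord]
    index: RepeatIndex
    chrom_sizes: dict[str, int]
    aliases: AliasTable = field(default_factory=AliasTable)
    _backgrounds: dict[tuple, BackgroundModel] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(
                    f"species {self.species}: gene {g.gene_id} on unknown chromosome {g.chrom!r}"
                )
        # gene ids, symbols and declared aliases all resolve
        for g in self.genes:
            self.aliases.add(g.gene_id, g.gene_id)
            if g.symbol:
                self.aliases.add(g.symbol, g.gene_id)
            for a in g.aliases:
                self.aliases.add(a, g.gene_id)

    @classmethod
    def load(
        cls,
        species: str,
        genes_path: str | Path,
        repeats_path: str | Path,
        chrom_sizes_path: str | Path,
        alias_path: str | Path | None = None,
    ) -> "SpeciesBundle":
        genes = read_gene_table(genes_path)
        index = RepeatIndex(read_repeatmasker_out(repeats_path))
        sizes = read_chrom_sizes(chrom_sizes_path)
        aliases = read_alias_table(alias_path) if alias_path else AliasTable()
        return cls(species=species, genes=genes, index=index, chrom_sizes=sizes, aliases=aliases)

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def resolve(self, query_ids: Sequence[str]) -> tuple[list[GeneRecord], list[str]]:
        """Map query identifiers to unique gene records; unresolved ids are
        reported, duplicates (after resolution) counted once."""
        seen: set[str] = set()
        resolved: list[GeneRecord] = []
        unresolved: list[str] = []
        for q in query_ids:
            gid = self.aliases.resolve(q)
            if gid is None or gid not in self._by_id:
                unresolved.append(q)
                continue
            if gid not in seen:
                seen.add(gid)
                resolved.append(self._by_id[gid])
        return resolved, unresolved

    def background(self, mode: str, spec: NeighborhoodSpec | None, rule: str = "overlap") -> BackgroundModel:
        """Background model for (mode, spec), computed once and cached."""
        key = (mode, spec.kind if spec else None, spec.size if spec else None, rule)
        if key not in self._backgrounds:
            if mode == GENE_COUNTS:
                model = background_gene_counts(self.genes, self.index, spec, self.chrom_sizes, rule)
            elif mode == REPEAT_COUNTS:
                model = background_repeat_counts(self.genes, self.index, spec, self.chrom_sizes, rule)
            else:
                model = background_whole_genome(self.index)
            self._backgrounds[key] = model
        return self._backgrounds[key]

    def set_background(self, model: BackgroundModel, rule: str = "overlap") -> None:
        spec = model.spec
        key = (model.mode, spec.kind if spec else None, spec.size if spec else None, rule)
        self._backgrounds[key] = model


# ---------------------------------------------------------------------------
# Gene-set analysis
# ---------------------------------------------------------------------------


@dataclass
class GeneSetResult:
    species: str
    results: list[EnrichmentResult]
    untested: list[tuple[str, str]]
    per_gene: dict[str, dict[str, float]]  # gene_id -> class -> percent
    resolved_ids: list[str]
    unresolved_ids: list[str]


def analyze_gene_set(
    query_ids: Sequence[str],
    bundle: SpeciesBundle,
    spec: NeighborhoodSpec,
    mode: str = GENE_COUNTS,
    alpha: float = 0.05,
    pvalue_mode: str = "tail",
    adjust: str = "none",
    rule: str = "overlap",
    compute_per_gene: bool = True,
) -> GeneSetResult:
    """Screen repeats for over-/under-representation around a query gene set.

    Unresolved identifiers are reported, not fatal — unless none resolve.
    """
    genes, unresolved = bundle.resolve(query_ids)
    if not genes:
        raise ValueError(f"no query id resolved; unresolved: {unresolved}")
    if unresolved:
        logger.warning("%d query id(s) did not resolve: %s", len(unresolved), unresolved)
    background = bundle.background(mode, spec, rule)
    observed = observed_counts(genes, bundle.index, spec, mode, bundle.chrom_sizes, rule)
    results = enrich(
        observed,
        background,
        alpha=alpha,
        pvalue_mode=pvalue_mode,
        adjust=adjust,
        class_of=bundle.index.class_of,
    )
    untested = degenerate_repeats(observed, background)
    per_gene: dict[str, dict[str, float]] = {}
    if compute_per_gene:
        for g in genes:
            per_gene[g.gene_id] = per_gene_class_composition(
                g, spec, bundle.index, bundle.chrom_sizes[g.chrom], rule
            )
    return GeneSetResult(
        species=bundle.species,
        results=results,
        untested=untested,
        per_gene=per_gene,
        resolved_ids=[g.gene_id for g in genes],
        unresolved_ids=unresolved,
    )


# ---------------------------------------------------------------------------
# Locus analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusQuery:
    """A chromosomal window to scan, with an optional repeat-class filter."""

    chrom: str
    start: int
    end: int
    classes: frozenset[str] | None = None  # None = all classes

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid locus interval [{self.start},{self.end})")


_LOCUS_RE = re.compile(
    r"^\s*(?:[Cc]hr)?(?P<name>[\w.]+?)(?:\|(?P<contig>[\w.]+))?:(?P<start>\d+)\s*[-–]\s*(?P<end>\d+)\s*$"
)


def parse_locus_string(text: str, classes: frozenset[str] | None = None) -> LocusQuery:
    """Parse ``Chr1:3011498-3120000`` / ``Chr4|NT_113885.1:5000-100000`` /
    ``ChrUn|NT_167210.1:100-150000`` (en dash accepted) into a
    :class:`LocusQuery`.  Input coordinates are 1-based inclusive; a contig
    part names the sequence directly, otherwise the chromosome name is
    normalized to a lower-case ``chr`` prefix."""
    if not text or not text.strip():
        raise ValueError("empty locus string")
    m = _LOCUS_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse locus {text!r}")
    raw_start = int(m.group("start"))
    end = int(m.group("end"))
    if raw_start >= end:
        raise ValueError(f"degenerate locus interval in {text!r}")
    start = raw_start - 1
    chrom = m.group("contig") if m.group("contig") else f"chr{m.group('name')}"
    return LocusQuery(chrom=chrom, start=start, end=end, classes=classes)


def _class_filtered_index(index: RepeatIndex, classes: frozenset[str] | None) -> RepeatIndex:
    if classes is None:
        return index
    return RepeatIndex([r for r in index.repeats if r.repeat_class in classes])


def analyze_locus(
    locus: LocusQuery,
    bundle: SpeciesBundle,
    alpha: float = 0.05,
    pvalue_mode: str = "tail",
    adjust: str = "none",
    rule: str = "overlap",
) -> GeneSetResult:
    """Screen repeats inside a chromosomal window against their whole-genome
    frequencies (repeat-counts statistics only).

    A class filter restricts both the observed tallies and the background to
    the filtered universe, so frequencies remain shares within that universe.
    """
    if locus.chrom not in bundle.chrom_sizes:
        raise ValueError(f"unknown sequence {locus.chrom!r}")
    if locus.end > bundle.chrom_sizes[locus.chrom]:
        raise ValueError(
            f"locus end {locus.end} beyond {locus.chrom} length {bundle.chrom_sizes[locus.chrom]}"
        )
    index = _class_filtered_index(bundle.index, locus.classes)
    region = Region(locus.chrom, locus.start, locus.end)
    observed = observed_counts_regions([region], index, rule)
    if observed.n == 0:
        logger.warning("no repeats found in locus %s:%d-%d", locus.chrom, locus.start, locus.end)
        return GeneSetResult(
            species=bundle.species,
            results=[],
            untested=[],
            per_gene={},
            resolved_ids=[],
            unresolved_ids=[],
        )
    if locus.classes is None:
        background = bundle.background(WHOLE_GENOME, None, rule)
    else:
        background = background_whole_genome(index)
    results = enrich(
        observed,
        background,
        alpha=alpha,
        pvalue_mode=pvalue_mode,
        adjust=adjust,
        class_of=index.class_of,
    )
    untested = degenerate_repeats(observed, background)
    return GeneSetResult(
        species=bundle.species,
        results=results,
        untested=untested,
        per_gene={},
        resolved_ids=[],
        unresolved_ids=[],
    )


# ---------------------------------------------------------------------------
# Orthologous gene-set analysis
# ---------------------------------------------------------------------------


@dataclass
class OrthologResult:
    per_species: dict[str, GeneSetResult]
    common: list[dict]  # repeat_name, direction, species -> p_value
    dropped: dict[str, list[str]]  # species -> query gene ids without orthologs


def analyze_ortholog_sets(
    query_ids: Sequence[str],
    query_bundle: SpeciesBundle,
    other_bundles: Sequence[SpeciesBundle],
    ortholog_map: OrthologMap,
    spec: NeighborhoodSpec,
    mode: str = GENE_COUNTS,
    alpha: float = 0.05,
    pvalue_mode: str = "tail",
    adjust: str = "none",
    rule: str = "overlap",
    ortholog_policy: str = "all",
    require_same_direction: bool = True,
    compute_per_gene: bool = False,
) -> OrthologResult:
    """Run the gene-set screen for the query species and for each ortholog
    set, each against its own species' background, and intersect.

    The common set contains repeats significant in the query species AND in
    at least one other species (same deviation direction unless relaxed).
    With ``ortholog_policy='all'`` every member of a query gene's homology
    group in a target species joins that species' set; ``'first'`` keeps only
    the lexicographically first.
    """
    if ortholog_policy not in ("all", "first"):
        raise ValueError(f"ortholog_policy must be 'all' or 'first', got {ortholog_policy!r}")
    query_result = analyze_gene_set(
        query_ids, query_bundle, spec, mode, alpha, pvalue_mode, adjust, rule,
        compute_per_gene=compute_per_gene,
    )
    per_species: dict[str, GeneSetResult] = {query_bundle.species: query_result}
    dropped: dict[str, list[str]] = {}
    any_orthologs = False
    for other in other_bundles:
        ortho_ids: list[str] = []
        missing: list[str] = []
        for gid in query_result.resolved_ids:
            hits = ortholog_map.orthologs(query_bundle.species, gid, other.species)
            if not hits:
                missing.append(gid)
                continue
            if ortholog_policy == "first":
                hits = hits[:1]
            ortho_ids.extend(hits)
        dropped[other.species] = missing
        if not ortho_ids:
            logger.warning(
                "no query gene has an ortholog in species %s; skipping", other.species
            )
            continue
        any_orthologs = True
        per_species[other.species] = analyze_gene_set(
            ortho_ids, other, spec, mode, alpha, pvalue_mode, adjust, rule,
            compute_per_gene=compute_per_gene,
        )
    if other_bundles and not any_orthologs:
        raise ValueError("no query gene has an ortholog in any selected species")

    sig_query = {
        r.repeat_name: r for r in query_result.results if r.significant
    }
    common: list[dict] = []
    for name, qres in sorted(sig_query.items()):
        support: dict[str, float] = {query_bundle.species: qres.p_value}
        directions: dict[str, str] = {query_bundle.species: qres.direction}
        for sp, res in per_species.items():
            if sp == query_bundle.species:
                continue
            for r in res.results:
                if r.repeat_name == name and r.significant:
                    if require_same_direction and r.direction != qres.direction:
                        continue
                    support[sp] = r.p_value
                    directions[sp] = r.direction
        if len(support) >= 2:
            common.append(
                {
                    "repeat_name": name,
                    "direction": qres.direction,
                    "species": sorted(support),
                    "p_values": support,
                    "directions": directions,
                }
            )
    return OrthologResult(per_species=per_species, common=common, dropped=dropped)
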