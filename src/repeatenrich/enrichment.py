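"""Background frequencies, observed counts, and binomial significance.

The model: a repeat element's genome-wide frequency ``p`` is estimated under
one of three counting modes, and the frequency observed in the query regions
is compared against it with an exact binomial test,

    P(X = k) = C(n, k) p^k (1 - p)^(n - k)

Under *gene counts*, ``n`` is the number of query genes and ``k`` the number
of them with the element at least once in their neighborhood; ``p`` is the
fraction of all genes with the element in the same kind of neighborhood.
Under *repeat counts*, ``n`` is the total number of repeat occurrences in the
query regions and ``k`` the occurrences of the element there; ``p`` is the
element's share of all occurrences (neighborhood-restricted for gene-set
analyses, whole-genome for locus analyses).  The default p-value is the
one-sided tail in the direction of the observed deviation; the point mass
P(X = k) is selectable for literal fidelity to the formula above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import GeneRecord, RepeatInstance
from .neighborhoods import NeighborhoodSpec, Region, RepeatIndex, make_neighborhood

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundModel",
    "ObservedCounts",
    "EnrichmentResult",
    "background_gene_counts",
    "background_repeat_counts",
    "background_whole_genome",
    "observed_counts",
    "observed_counts_regions",
    "binomial_point_pmf",
    "binomial_tail_p",
    "enrich",
    "degenerate_repeats",
    "coverage_fraction",
]

DEFAULT_ALPHA = 0.05

GENE_COUNTS = "gene_counts"
REPEAT_COUNTS = "repeat_counts"
WHOLE_GENOME = "whole_genome_repeat_counts"


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class BackgroundModel:
    """Per-repeat genome-wide frequency under one counting mode.

    ``counts[r]`` is the numerator used for repeat ``r`` and ``denominator``
    the shared denominator, so ``p[r] = counts[r] / denominator``.
    """

    mode: str
    spec: NeighborhoodSpec | None
    p: dict[str, float]
    counts: dict[str, int]
    denominator: int

    def __post_init__(self) -> None:
        for name, prob in self.p.items():
            if not (0.0 <= prob <= 1.0):
                raise ValueError(f"background p[{name!r}]={prob} outside [0,1]")


@dataclass
class ObservedCounts:
    """Observed tallies for the query: ``n`` trials shared by every repeat,
    ``k[r]`` successes for repeat ``r`` (absent repeats have k=0)."""

    mode: str
    n: int
    k: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class EnrichmentResult:
    repeat_name: str
    repeat_class: str
    k: int
    n: int
    observed_freq: float
    expected_freq: float
    ratio: float
    p_value: float
    direction: str  # over | under | none
    significant: bool
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# Background frequencies
# ---------------------------------------------------------------------------


def _gene_presence_ids(
    gene: GeneRecord,
    index: RepeatIndex,
    spec: NeighborhoodSpec,
    chrom_len: int,
    rule: str,
) -> np.ndarray:
    """Distinct repeat-name ids present in a gene's neighborhood."""
    parts = [
        index.name_ids_in(r.chrom, r.start, r.end, rule)
        for r in make_neighborhood(gene, spec, chrom_len)
    ]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def background_gene_counts(
    genes: Sequence[GeneRecord],
    index: RepeatIndex,
    spec: NeighborhoodSpec,
    chrom_sizes: Mapping[str, int],
    rule: str = "overlap",
) -> BackgroundModel:
    """Fraction of all genes carrying each repeat at least once in their
    ``spec`` neighborhood.  Repeats never seen in any neighborhood get p=0
    (and are excluded from testing downstream)."""
    if not genes:
        raise ValueError("background_gene_counts requires at least one gene")
    n_names = len(index.names)
    gene_hits = np.zeros(n_names, dtype=np.int64)
    for g in genes:
        ids = _gene_presence_ids(g, index, spec, chrom_sizes[g.chrom], rule)
        gene_hits[ids] += 1
    total = len(genes)
    counts = {index.names[i]: int(gene_hits[i]) for i in range(n_names)}
    p = {name: c / total for name, c in counts.items()}
    return BackgroundModel(mode=GENE_COUNTS, spec=spec, p=p, counts=counts, denominator=total)


def background_repeat_counts(
    genes: Sequence[GeneRecord],
    index: RepeatIndex,
    spec: NeighborhoodSpec,
    chrom_sizes: Mapping[str, int],
    rule: str = "overlap",
) -> BackgroundModel:
    """Each repeat's share of all repeat occurrences inside the ``spec``
    neighborhoods of ALL genes (denominator is neighborhood-restricted)."""
    if not genes:
        raise ValueError("background_repeat_counts requires at least one gene")
    n_names = len(index.names)
    occ = np.zeros(n_names, dtype=np.int64)
    for g in genes:
        for region in make_neighborhood(g, spec, chrom_sizes[g.chrom]):
            ids = index.name_ids_in(region.chrom, region.start, region.end, rule)
            if ids.size:
                occ += np.bincount(ids, minlength=n_names)
    total = int(occ.sum())
    if total == 0:
        raise ValueError("no repeat occurrences in any gene neighborhood")
    counts = {index.names[i]: int(occ[i]) for i in range(n_names)}
    p = {name: c / total for name, c in counts.items()}
    return BackgroundModel(mode=REPEAT_COUNTS, spec=spec, p=p, counts=counts, denominator=total)


def background_whole_genome(index: RepeatIndex) -> BackgroundModel:
    """Each repeat's share of all repeat occurrences in the entire genome."""
    counts = index.genome_wide_counts()
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty repeat track")
    p = {name: c / total for name, c in counts.items()}
    return BackgroundModel(mode=WHOLE_GENOME, spec=None, p=p, counts=counts, denominator=total)


# ---------------------------------------------------------------------------
# Observed counts
# ---------------------------------------------------------------------------


def observed_counts(
    query_genes: Sequence[GeneRecord],
    index: RepeatIndex,
    spec: NeighborhoodSpec,
    mode: str,
    chrom_sizes: Mapping[str, int],
    rule: str = "overlap",
) -> ObservedCounts:
    """Observed tallies for a query gene set.

    ``gene_counts``: n = number of query genes, k[r] = query genes with >=1
    occurrence of r in their neighborhood.  ``repeat_counts``: n = total
    occurrences of all repeats across all query neighborhoods, k[r] = the
    occurrences of r there (an instance inside two genes' windows counts in
    both).
    """
    if not query_genes:
        raise ValueError("no query genes")
    n_names = len(index.names)
    if mode == GENE_COUNTS:
        hits = np.zeros(n_names, dtype=np.int64)
        for g in query_genes:
            ids = _gene_presence_ids(g, index, spec, chrom_sizes[g.chrom], rule)
            hits[ids] += 1
        k = {index.names[i]: int(hits[i]) for i in range(n_names) if hits[i]}
        return ObservedCounts(mode=GENE_COUNTS, n=len(query_genes), k=k)
    if mode == REPEAT_COUNTS:
        occ = np.zeros(n_names, dtype=np.int64)
        for g in query_genes:
            for region in make_neighborhood(g, spec, chrom_sizes[g.chrom]):
                ids = index.name_ids_in(region.chrom, region.start, region.end, rule)
                if ids.size:
                    occ += np.bincount(ids, minlength=n_names)
        k = {index.names[i]: int(occ[i]) for i in range(n_names) if occ[i]}
        return ObservedCounts(mode=REPEAT_COUNTS, n=int(occ.sum()), k=k)
    raise ValueError(f"unknown counting mode {mode!r}")


def observed_counts_regions(
    regions: Sequence[Region], index: RepeatIndex, rule: str = "overlap"
) -> ObservedCounts:
    """Repeat-counts tallies inside explicit regions (locus mode)."""
    n_names = len(index.names)
    occ = np.zeros(n_names, dtype=np.int64)
    for region in regions:
        ids = index.name_ids_in(region.chrom, region.start, region.end, rule)
        if ids.size:
            occ += np.bincount(ids, minlength=n_names)
    k = {index.names[i]: int(occ[i]) for i in range(n_names) if occ[i]}
    return ObservedCounts(mode=REPEAT_COUNTS, n=int(occ.sum()), k=k)


# ---------------------------------------------------------------------------
# Binomial probabilities
# ---------------------------------------------------------------------------


def _log_pmf(k: np.ndarray, n: int, p: float) -> np.ndarray:
    k = np.asarray(k, dtype=np.float64)
    return (
        gammaln(n + 1.0)
        - gammaln(k + 1.0)
        - gammaln(n - k + 1.0)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


def _check_knp(k: int, n: int, p: float) -> None:
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"degenerate binomial: p={p} (repeat should be excluded from testing)")


def binomial_point_pmf(k: int, n: int, p: float) -> float:
    """Exact binomial point probability C(n,k) p^k (1-p)^(n-k).

    Evaluated in log space; relative accuracy ~1e-12 over n <= 1e3.
    """
    _check_knp(k, n, p)
    return float(np.exp(_log_pmf(np.asarray([k]), n, p)[0]))


def binomial_tail_p(k: int, n: int, p: float, direction: str) -> float:
    """One-sided binomial tail: P(X >= k) for ``over``, P(X <= k) for ``under``.

    Computed by log-space summation of point masses (gammaln + logsumexp)
    rather than the incomplete-beta route, which loses relative accuracy in
    extreme tails.
    """
    _check_knp(k, n, p)
    if direction == "over":
        ks = np.arange(k, n + 1)
    elif direction == "under":
        ks = np.arange(0, k + 1)
    else:
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    val = float(np.exp(logsumexp(_log_pmf(ks, n, p))))
    return min(val, 1.0)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

_COMPATIBLE = {
    GENE_COUNTS: {GENE_COUNTS},
    REPEAT_COUNTS: {REPEAT_COUNTS, WHOLE_GENOME},
}


def degenerate_repeats(
    observed: ObservedCounts, background: BackgroundModel
) -> list[tuple[str, str]]:
    """Repeats that cannot be tested under the binomial model, with reasons."""
    out = []
    for name in sorted(set(background.p) | set(observed.k)):
        p = background.p.get(name)
        if p is None:
            out.append((name, "absent from background"))
        elif p == 0.0:
            out.append((name, "background frequency 0 (never seen in background regions)"))
        elif p == 1.0:
            out.append((name, "background frequency 1 (present everywhere)"))
    return out


def enrich(
    observed: ObservedCounts,
    background: BackgroundModel,
    alpha: float = DEFAULT_ALPHA,
    pvalue_mode: str = "tail",
    adjust: str = "none",
    class_of: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Score every testable repeat against the background.

    One result per repeat with background p strictly inside (0,1); the ratio
    is (k/n)/p, the direction the sign of the deviation, and the p-value the
    one-sided tail toward that deviation (or the point mass when
    ``pvalue_mode='point'``).  With ``adjust='bh'`` Benjamini-Hochberg
    adjusted p-values decide significance instead of the raw ones.  Results
    are sorted by ascending p-value, ties broken by repeat name.
    """
    if background.mode not in _COMPATIBLE.get(observed.mode, ()):
        raise ValueError(
            f"observed mode {observed.mode!r} incompatible with background mode {background.mode!r}"
        )
    if pvalue_mode not in ("tail", "point"):
        raise ValueError(f"pvalue_mode must be 'tail' or 'point', got {pvalue_mode!r}")
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    n = observed.n
    if n <= 0:
        raise ValueError("observed n must be positive")
    excluded = {name for name, _ in degenerate_repeats(observed, background)}
    if excluded:
        logger.info("excluding %d degenerate repeat(s) from testing", len(excluded))
    rows = []
    for name in sorted(background.p):
        if name in excluded:
            continue
        p = background.p[name]
        k = observed.k.get(name, 0)
        obs = k / n
        ratio = obs / p
        if obs > p:
            direction = "over"
        elif obs < p:
            direction = "under"
        else:
            direction = "none"
        if pvalue_mode == "point":
            pval = binomial_point_pmf(k, n, p)
        else:
            pval = binomial_tail_p(k, n, p, "under" if direction == "under" else "over")
        rows.append((name, k, obs, p, ratio, pval, direction))
    if adjust == "bh" and rows:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([r[5] for r in rows], method="fdr_bh")
    else:
        p_adj = [None] * len(rows)
    results = [
        EnrichmentResult(
            repeat_name=name,
            repeat_class=(class_of or {}).get(name, ""),
            k=k,
            n=n,
            observed_freq=obs,
            expected_freq=p,
            ratio=ratio,
            p_value=pval,
            direction=direction,
            significant=(adj if adj is not None else pval) < alpha,
            p_adjusted=adj,
        )
        for (name, k, obs, p, ratio, pval, direction), adj in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.repeat_name))
    return results


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def coverage_fraction(repeats: Iterable[RepeatInstance], genome_size: int) -> float:
    """Percentage of the genome covered by the union of all repeat intervals.

    Overlapping or duplicate instances are merged before summing.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    covered = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return 100.0 * covered / genome_size
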