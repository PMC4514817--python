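"""Independent oracles used by the tests.

Everything here recomputes quantities by a different route than the package:
exact rational arithmetic for binomial probabilities, all-pairs overlap
scans for counting, and a per-base boolean mask for coverage.  None of it
imports the modules it checks beyond plain data types.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Exact binomial probabilities (rational arithmetic)
# ---------------------------------------------------------------------------


def exact_pmf_row(n: int, p: Fraction) -> list[Fraction]:
    """pmf(0..n) by the multiplicative recurrence, exactly."""
    q = 1 - p
    row = [q**n]
    for k in range(n):
        row.append(row[-1] * (n - k) * p / ((k + 1) * q))
    return row


def exact_tails(n: int, p: Fraction) -> tuple[list[Fraction], list[Fraction], list[Fraction]]:
    """(pmf, P(X>=k), P(X<=k)) for k = 0..n, exactly."""
    row = exact_pmf_row(n, p)
    upper = [Fraction(0)] * (n + 2)
    for k in range(n, -1, -1):
        upper[k] = upper[k + 1] + row[k]
    lower = []
    acc = Fraction(0)
    for k in range(n + 1):
        acc += row[k]
        lower.append(acc)
    return row, upper[: n + 1], lower


# ---------------------------------------------------------------------------
# All-pairs overlap counting
# ---------------------------------------------------------------------------


def overlap_matrix(repeats, regions) -> np.ndarray:
    """Boolean (n_repeats x n_regions): >=1 bp overlap, half-open intervals."""
    rs = np.asarray([r.start for r in repeats])[:, None]
    re_ = np.asarray([r.end for r in repeats])[:, None]
    rc = np.asarray([r.chrom for r in repeats])[:, None]
    gs = np.asarray([g.start for g in regions])[None, :]
    ge = np.asarray([g.end for g in regions])[None, :]
    gc = np.asarray([g.chrom for g in regions])[None, :]
    return (rc == gc) & (rs < ge) & (re_ > gs)


def brute_force_gene_counts(genes, repeats, regions_of_gene) -> dict[str, int]:
    """#genes with >=1 occurrence of each repeat name in their regions."""
    names = sorted({r.repeat_name for r in repeats})
    name_idx = {n: i for i, n in enumerate(names)}
    counts = np.zeros(len(names), dtype=int)
    for g in genes:
        regions = regions_of_gene[g.gene_id]
        if not regions:
            continue
        ov = overlap_matrix(repeats, regions)
        hit_any = ov.any(axis=1)
        present = {repeats[i].repeat_name for i in np.nonzero(hit_any)[0]}
        for nm in present:
            counts[name_idx[nm]] += 1
    return {nm: int(counts[name_idx[nm]]) for nm in names}


def brute_force_repeat_counts(repeats, regions) -> dict[str, int]:
    """Occurrences of each repeat name summed over the regions (an instance
    overlapping two regions counts twice)."""
    counts: dict[str, int] = {}
    if not regions or not repeats:
        return counts
    ov = overlap_matrix(repeats, regions)
    per_repeat = ov.sum(axis=1)
    for i, r in enumerate(repeats):
        if per_repeat[i]:
            counts[r.repeat_name] = counts.get(r.repeat_name, 0) + int(per_repeat[i])
    return counts


# ---------------------------------------------------------------------------
# Per-base coverage mask
# ---------------------------------------------------------------------------


def bitmask_coverage_pct(repeats, chrom_sizes: dict[str, int], genome_size: int) -> float:
    covered = 0
    for chrom, L in chrom_sizes.items():
        mask = np.zeros(L, dtype=bool)
        for r in repeats:
            if r.chrom == chrom:
                mask[r.start : r.end] = True
        covered += int(mask.sum())
    return 100.0 * covered / genome_size
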