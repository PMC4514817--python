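"""Readers and writers for the on-disk formats the tool consumes and emits.

All coordinates are 0-based half-open internally.  The two 1-based-inclusive
dialects at the file boundary are RepeatMasker ``.out`` and the gene
annotation TSV; conversion happens here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "RepeatInstance",
    "GeneRecord",
    "AliasTable",
    "OrthologMap",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_gene_table",
    "write_gene_table",
    "read_alias_table",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_summary_tsv",
    "read_summary_tsv",
    "write_background_tsv",
    "read_background_tsv",
    "write_bed6",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatInstance:
    """One annotated repeat occurrence on a chromosome.

    ``start``/``end`` are 0-based half-open.  ``repeat_class`` is the coarse
    category (LINE, SINE, LTR, DNA, Simple_repeat, ...), ``repeat_family``
    the finer subdivision (empty when the annotation gives none).
    """

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    repeat_family: str = ""
    score: int | None = None
    divergence_pct: float | None = None
    rm_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid repeat interval [{self.start},{self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")
        if not self.repeat_name:
            raise FormatError("repeat_name must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its strand-resolved 5'-most TSS and full transcript span.

    ``tss`` follows the half-open convention: for a ``+`` gene it equals
    ``gene_start``; for a ``-`` gene it equals ``gene_end``, so "upstream"
    of a minus-strand TSS is the interval ``[tss, tss + size)``.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    tss: int
    aliases: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.gene_start >= self.gene_end:
            raise FormatError(f"gene {self.gene_id}: gene_start >= gene_end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        expected = self.gene_start if self.strand == "+" else self.gene_end
        if self.tss != expected:
            raise FormatError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"strand {self.strand} span [{self.gene_start},{self.gene_end})"
            )


class AliasTable:
    """Alias -> canonical gene id lookup, exact-match first, case-insensitive
    as a fallback (ambiguous case-folded aliases never resolve by fallback)."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._exact: dict[str, str] = {}
        self._folded: dict[str, str | None] = {}  # None marks ambiguity
        for alias, gene_id in pairs:
            self.add(alias, gene_id)

    def add(self, alias: str, gene_id: str) -> None:
        prev = self._exact.get(alias)
        if prev is not None and prev != gene_id:
            raise FormatError(
                f"alias {alias!r} maps to both {prev!r} and {gene_id!r}"
            )
        self._exact[alias] = gene_id
        low = alias.casefold()
        if low in self._folded and self._folded[low] != gene_id:
            self._folded[low] = None
        else:
            self._folded[low] = gene_id

    def resolve(self, query: str) -> str | None:
        hit = self._exact.get(query)
        if hit is not None:
            return hit
        return self._folded.get(query.casefold())

    def __len__(self) -> int:
        return len(self._exact)


@dataclass
class OrthologMap:
    """Homology groups: group id -> set of (species tag, gene id) members.

    A (species, gene) pair belongs to at most one group.
    """

    groups: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._group_of: dict[tuple[str, str], str] = {}
        for gid, members in self.groups.items():
            for pair in members:
                if pair in self._group_of:
                    raise FormatError(
                        f"gene {pair[1]} of species {pair[0]} appears in groups "
                        f"{self._group_of[pair]} and {gid}"
                    )
                self._group_of[pair] = gid

    def group_of(self, species: str, gene_id: str) -> str | None:
        return self._group_of.get((species, gene_id))

    def orthologs(self, species: str, gene_id: str, target_species: str) -> list[str]:
        """Genes of ``target_species`` sharing a homology group with the query."""
        gid = self.group_of(species, gene_id)
        if gid is None:
            return []
        return sorted(
            g for (sp, g) in self.groups[gid] if sp == target_species and (sp, g) != (species, gene_id)
        )


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query          matching"
    "  repeat           position in repeat\n"
    "score   div. del. ins.  sequence  begin    end       (left)  repeat"
    "           class/family     begin  end    (left)  ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> list[RepeatInstance]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The first three lines (two column-header lines and a blank) are skipped.
    Query coordinates are 1-based inclusive in the file and converted to
    0-based half-open; strand token ``C`` (complement) maps to ``-``.
    The ``class/family`` column is split on its first ``/``.
    """
    path = Path(path)
    out: list[RepeatInstance] = []
    with path.open() as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) < 14:
            raise FormatError(f"{path}:{lineno}: expected >=14 columns, got {len(cols)}")
        try:
            score = int(cols[0])
            div = float(cols[1])
            begin = int(cols[5])
            end = int(cols[6])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
        if begin < 1 or begin > end:
            raise FormatError(f"{path}:{lineno}: bad coordinates begin={begin} end={end}")
        strand = cols[8]
        if strand == "C":
            strand = "-"
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: bad strand token {cols[8]!r}")
        classfam = cols[10]
        if "/" in classfam:
            rclass, rfamily = classfam.split("/", 1)
        else:
            rclass, rfamily = classfam, ""
        rm_id = cols[14] if len(cols) > 14 else None
        out.append(
            RepeatInstance(
                chrom=cols[4],
                start=begin - 1,
                end=end,
                strand=strand,
                repeat_name=cols[9],
                repeat_class=rclass,
                repeat_family=rfamily,
                score=score,
                divergence_pct=div,
                rm_id=rm_id,
            )
        )
    return out


def write_repeatmasker_out(repeats: Iterable[RepeatInstance], path: str | Path) -> None:
    """Write repeats in the ``.out`` dialect so that read -> write -> read is
    the identity on the parsed representation."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(repeats, start=1):
            classfam = (
                f"{r.repeat_class}/{r.repeat_family}" if r.repeat_family else r.repeat_class
            )
            strand = "C" if r.strand == "-" else "+"
            score = r.score if r.score is not None else 0
            div = r.divergence_pct if r.divergence_pct is not None else 0.0
            rm_id = r.rm_id if r.rm_id is not None else str(i)
            fh.write(
                f"{score:>5d} {div:5.1f}  0.0  0.0  {r.chrom}  "
                f"{r.start + 1}  {r.end}  (0)  {strand}  {r.repeat_name}  "
                f"{classfam}  1  {r.end - r.start}  (0)  {rm_id}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation table (one row per transcript)
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "symbol", "chrom", "strand", "tx_start", "tx_end"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a per-transcript gene annotation TSV and collapse to genes.

    File columns (1-based inclusive transcript coordinates):
    ``gene_id  symbol  chrom  strand  tx_start  tx_end``.

    Per gene: span is the min/max over its transcripts, converted to 0-based
    half-open; the TSS is the 5'-most transcript start (minimum start on the
    plus strand, maximum end on the minus strand).  Duplicate identical rows
    are dropped silently; mixed strands or chromosomes within one gene are an
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chrom": str})
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.drop_duplicates()
    genes: list[GeneRecord] = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        strands = grp["strand"].unique()
        if len(strands) > 1:
            raise FormatError(f"gene {gene_id}: transcripts on mixed strands")
        chroms = grp["chrom"].unique()
        if len(chroms) > 1:
            raise FormatError(f"gene {gene_id}: transcripts on multiple chromosomes")
        strand = strands[0]
        if strand not in ("+", "-"):
            raise FormatError(f"gene {gene_id}: invalid strand {strand!r}")
        start = int(grp["tx_start"].min()) - 1
        end = int(grp["tx_end"].max())
        tss = start if strand == "+" else end
        genes.append(
            GeneRecord(
                gene_id=str(gene_id),
                symbol=str(grp["symbol"].iloc[0]),
                chrom=str(chroms[0]),
                strand=strand,
                gene_start=start,
                gene_end=end,
                tss=tss,
            )
        )
    return genes


def write_gene_table(
    genes: Iterable[GeneRecord],
    path: str | Path,
    transcripts: Mapping[str, list[tuple[int, int]]] | None = None,
) -> None:
    """Write the per-transcript TSV.  Without an explicit transcript map each
    gene is emitted as a single transcript covering its span (1-based)."""
    rows = []
    for g in genes:
        txs = (
            transcripts.get(g.gene_id, [(g.gene_start + 1, g.gene_end)])
            if transcripts
            else [(g.gene_start + 1, g.gene_end)]
        )
        for s, e in txs:
            rows.append((g.gene_id, g.symbol, g.chrom, g.strand, s, e))
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Small two/three-column tables
# ---------------------------------------------------------------------------


def read_alias_table(path: str | Path) -> AliasTable:
    """Two-column TSV ``alias<TAB>gene_id`` -> :class:`AliasTable`.

    An alias mapped to two different gene ids is a hard error.
    """
    table = AliasTable()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[0] == "alias":
                continue
            table.add(parts[0], parts[1])
    return table


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """Three-column TSV ``group_id<TAB>species<TAB>gene_id`` (HomoloGene-like)."""
    groups: dict[str, set[tuple[str, str]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1 and parts[0] == "group_id":
                continue
            groups.setdefault(parts[0], set()).add((parts[1], parts[2]))
    return OrthologMap(groups=groups)


def write_ortholog_table(omap: OrthologMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("group_id\tspecies\tgene_id\n")
        for gid in sorted(omap.groups):
            for sp, gene in sorted(omap.groups[gid]):
                fh.write(f"{gid}\t{sp}\t{gene}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV ``chrom<TAB>length`` -> dict."""
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# Reports and caches
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "repeat_name",
    "repeat_class",
    "observed_count",
    "total",
    "observed_freq",
    "expected_freq",
    "ratio",
    "p_value",
    "direction",
    "significant",
]


def write_summary_tsv(results, path: str | Path) -> None:
    """Write the enrichment summary table, sorted by ascending p-value then
    repeat name, floats at 6 significant digits."""
    rows = sorted(results, key=lambda r: (r.p_value, r.repeat_name))
    df = pd.DataFrame(
        [
            (
                r.repeat_name,
                r.repeat_class,
                r.k,
                r.n,
                r.observed_freq,
                r.expected_freq,
                r.ratio,
                r.p_value,
                r.direction,
                r.significant,
            )
            for r in rows
        ],
        columns=SUMMARY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_summary_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_background_tsv(model, path: str | Path) -> None:
    """Serialize a background model for caching: a commented header records
    the counting mode and neighborhood, then ``repeat_name  count  p``."""
    with Path(path).open("w") as fh:
        spec = model.spec
        fh.write(f"# mode={model.mode}\n")
        fh.write(f"# kind={spec.kind if spec else '.'}\tsize={spec.size if spec else '.'}\n")
        fh.write(f"# denominator={model.denominator}\n")
        fh.write("repeat_name\tcount\tp\n")
        for name in sorted(model.p):
            fh.write(f"{name}\t{model.counts[name]}\t{model.p[name]:.17g}\n")


def read_background_tsv(path: str | Path):
    from .enrichment import BackgroundModel
    from .neighborhoods import NeighborhoodSpec

    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    p: dict[str, float] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for token in line[1:].strip().split("\t"):
                    if "=" in token:
                        key, val = token.split("=", 1)
                        meta[key] = val
                continue
            if not line or line.startswith("repeat_name"):
                continue
            name, cnt, prob = line.split("\t")
            counts[name] = int(cnt)
            p[name] = float(prob)
    spec = None
    if meta.get("kind", ".") != ".":
        spec = NeighborhoodSpec(meta["kind"], int(meta["size"]))
    return BackgroundModel(
        mode=meta["mode"], spec=spec, p=p, counts=counts, denominator=int(meta["denominator"])
    )


def write_bed6(regions, path: str | Path, strands: Mapping[str, str] | None = None) -> None:
    """Export regions as BED6 (0-based half-open; name = owning gene id)."""
    with Path(path).open("w") as fh:
        for r in regions:
            strand = (strands or {}).get(r.gene_id, ".")
            name = r.gene_id or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{strand}\n")
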