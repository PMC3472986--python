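"""Raw 49nt reads -> clean 21nt tag counts, plus library-level summaries.

Cleaning applies, in order: (1) trim at the first position where a prefix of
the 3' adaptor (>= a minimum overlap) matches through to the read end;
(2) drop empty reads (adaptor only, nothing before it); (3) drop tags
containing 'N'; (4) keep only tags of exactly 21nt starting with the CATG
anchor; (5) drop tags whose total copy number across the library is 1
(presumed sequencing error). Rules 3-5 commute once rules 1-2 have produced
the tag candidates.

Also provides the Table-1-style library summary (percentages of clean tags,
two decimals, round half up), the copy-number distribution over the standard
bins, and seeded saturation (rarefaction) curves of distinct tags and genes
detected versus tags sampled.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .seq import ANCHOR, TAG_LEN
from .simulate import DEFAULT_ADAPTOR, READ_LENGTH, RawReadSet

#: copy-number bins (inclusive low/high; None = unbounded) used for the
#: distribution of clean-tag expression
DEFAULT_BINS = ((2, 5), (6, 10), (11, 20), (21, 50), (51, 100), (101, None))


@dataclass
class FilterStats:
    """Tally of reads removed by each cleaning rule."""

    raw_total: int = 0
    raw_distinct: int = 0
    n_no_adaptor: int = 0
    n_empty: int = 0
    n_with_n: int = 0
    n_bad_tag: int = 0
    n_singletons: int = 0


@dataclass
class TagCountTable:
    """Distinct clean 21nt tags and their copy numbers for one library."""

    counts: dict[str, int]
    label: str = ""
    stats: FilterStats | None = None

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.counts)

    def validate(self) -> None:
        for tag, c in self.counts.items():
            if len(tag) != TAG_LEN or not tag.startswith(ANCHOR):
                raise ValueError(f"invalid clean tag {tag!r}")
            if c < 2:
                raise ValueError(f"clean tag {tag!r} has copy number {c} < 2")


def trim_adaptor(read: str, adaptor: str, min_overlap: int = 8) -> str | None:
    """Insert sequence before the adaptor, '' for adaptor-only reads.

    The adaptor is located by its leading `min_overlap` bases: the read is
    cut at the first (5'-most) position where they match exactly. Anchoring
    on the prefix rather than the full adaptor keeps reads whose adaptor
    region carries downstream sequencing errors. Returns None when the
    prefix is nowhere found (the adaptor cannot be located, so no tag can be
    delimited). Reads shorter than `min_overlap` past the cut point cannot
    anchor, so a read may also fail when the adaptor only just enters its
    3' end.
    """
    anchor = adaptor[:min_overlap]
    p = read.find(anchor)
    return read[:p] if p != -1 else None


def extract_clean_tags(
    reads: RawReadSet | Iterable[str],
    adaptor: str = DEFAULT_ADAPTOR,
    min_overlap: int = 8,
    min_copy: int = 2,
    label: str = "",
) -> TagCountTable:
    """Apply the five cleaning rules to raw reads; empty input gives an empty table."""
    seqs = reads.reads if isinstance(reads, RawReadSet) else list(reads)
    stats = FilterStats(raw_total=len(seqs), raw_distinct=len(set(seqs)))
    counter: Counter[str] = Counter()
    for i, read in enumerate(seqs):
        if len(read) != READ_LENGTH:
            raise ValueError(f"read {i}: expected {READ_LENGTH}nt, got {len(read)}nt")
        insert = trim_adaptor(read, adaptor, min_overlap)
        if insert is None:
            stats.n_no_adaptor += 1
        elif insert == "":
            stats.n_empty += 1
        elif "N" in insert:
            stats.n_with_n += 1
        elif len(insert) != TAG_LEN or not insert.startswith(ANCHOR):
            stats.n_bad_tag += 1
        else:
            counter[insert] += 1
    singles = [t for t, c in counter.items() if c < min_copy]
    stats.n_singletons = len(singles)
    for t in singles:
        del counter[t]
    return TagCountTable(dict(counter), label=label, stats=stats)


def percent(numerator: int, denominator: int) -> float:
    """100 x numerator/denominator, two decimals, round half up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(int(numerator)) * 100 / Decimal(int(denominator))
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def clean_tag_percentages(
    tallies: Mapping[str, tuple[int, int]], clean_total: int, clean_distinct: int
) -> pd.DataFrame:
    """Percent-of-clean-tag table from (total, distinct) tallies per category."""
    rows = []
    for section, (total, distinct) in tallies.items():
        rows.append(
            (
                section,
                total,
                percent(total, clean_total),
                distinct,
                percent(distinct, clean_distinct),
            )
        )
    return pd.DataFrame(
        rows, columns=["section", "total", "pct_total", "distinct", "pct_distinct"]
    )


@dataclass
class LibrarySummary:
    """Library statistics in the style of a DGE sequencing summary table."""

    label: str
    raw_total: int
    raw_distinct: int
    clean_total: int
    clean_distinct: int
    mapping: pd.DataFrame | None = None  # output of clean_tag_percentages
    genes_mapped: int | None = None
    genes_unambiguous: int | None = None


def library_summary(
    table: TagCountTable,
    raw_total: int,
    raw_distinct: int,
    mapping: pd.DataFrame | None = None,
) -> LibrarySummary:
    """Summarize a clean tag table, optionally with tag->gene mapping tallies.

    `mapping` is a map_tags result frame; its categories are aggregated into
    the all-gene / unambiguous-gene / genome / unknown sections with percent
    of clean tags (total and distinct).
    """
    clean_total, clean_distinct = table.total_clean, table.distinct_clean
    if clean_total <= 0:
        raise ValueError("empty clean tag table cannot be summarized")
    if clean_total > raw_total or clean_distinct > raw_distinct:
        raise ValueError("clean totals cannot exceed raw totals")

    summary = LibrarySummary(table.label, raw_total, raw_distinct, clean_total, clean_distinct)
    if mapping is not None:
        from .mapping import GENE_CATEGORIES, GENOME_CATEGORIES, UNKNOWN

        m = mapping
        cnt = m["count"]
        is_gene = m["category"].isin(GENE_CATEGORIES)
        is_unamb = is_gene & (m["multiplicity"] == "one")
        is_genome = m["category"].isin(GENOME_CATEGORIES)
        is_unknown = m["category"] == UNKNOWN
        tallies = {
            "all_gene": (int(cnt[is_gene].sum()), int(is_gene.sum())),
            "unambiguous_gene": (int(cnt[is_unamb].sum()), int(is_unamb.sum())),
            "genome": (int(cnt[is_genome].sum()), int(is_genome.sum())),
            "unknown": (int(cnt[is_unknown].sum()), int(is_unknown.sum())),
        }
        summary.mapping = clean_tag_percentages(tallies, clean_total, clean_distinct)
        all_genes: set[str] = set()
        for genes in m.loc[is_gene, "genes"]:
            all_genes.update(genes)
        summary.genes_mapped = len(all_genes)
        summary.genes_unambiguous = int(m.loc[is_unamb, "gene"].nunique())
    return summary


def copy_number_distribution(
    table: TagCountTable, bins: tuple[tuple[int, int | None], ...] = DEFAULT_BINS
) -> pd.DataFrame:
    """Per-bin (total tag count, distinct tag count) over copy-number bins.

    Bins must tile [2, inf) without gaps or overlap; totals and distincts
    sum back to the library's clean totals.
    """
    if bins[0][0] != 2:
        raise ValueError("bins must start at copy number 2")
    for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
        if hi1 is None or lo2 != hi1 + 1:
            raise ValueError("bins must tile [2, inf) contiguously")
    if bins[-1][1] is not None:
        raise ValueError("last bin must be unbounded")

    lows = [lo for lo, _ in bins]
    totals = np.zeros(len(bins), dtype=np.int64)
    distinct = np.zeros(len(bins), dtype=np.int64)
    for c in table.counts.values():
        j = int(np.searchsorted(lows, c, side="right")) - 1
        totals[j] += c
        distinct[j] += 1
    labels = [f"{lo}-{hi}" if hi is not None else f">{lo - 1}" for lo, hi in bins]
    return pd.DataFrame(
        {
            "bin": labels,
            "low": [lo for lo, _ in bins],
            "high": [hi for _, hi in bins],
            "total": totals,
            "distinct": distinct,
        }
    )


def saturation_curve(
    source: TagCountTable | Iterable[str],
    grid: Iterable[int] | None = None,
    mapping: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Distinct tags (and genes) detected among the first k sampled tags.

    The occurrence stream is shuffled once (seeded) and scanned; for each
    grid point k the number of distinct tags seen within the first k
    occurrences is reported, and, when a map_tags result is supplied, the
    number of distinct unambiguously-assigned genes as well. Both series are
    non-decreasing and reach the full-library totals at k = stream length.
    """
    if isinstance(source, TagCountTable):
        keys = np.array(list(source.counts.keys()), dtype=object)
        reps = np.fromiter(source.counts.values(), dtype=np.int64, count=len(source.counts))
        stream = np.repeat(keys, reps)
    else:
        stream = np.asarray(list(source), dtype=object)
    n = len(stream)
    if grid is None:
        grid = np.unique(np.linspace(max(1, n // 20), n, num=20, dtype=np.int64))
    grid = np.asarray(list(grid), dtype=np.int64)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    if len(grid) and (grid[-1] > n or grid[0] < 1):
        raise ValueError(f"grid points must lie in [1, {n}]")

    perm = np.random.default_rng(seed).permutation(n)
    stream = stream[perm]
    codes, uniques = pd.factorize(stream)

    def detected(item_codes: np.ndarray, positions: np.ndarray, n_items: int) -> np.ndarray:
        first = np.full(n_items, n, dtype=np.int64)
        np.minimum.at(first, item_codes, positions)
        return np.searchsorted(np.sort(first), grid, side="left")

    out = pd.DataFrame({"tags_sampled": grid})
    out["distinct_tags"] = detected(codes, np.arange(n), len(uniques))
    if mapping is not None:
        gene_of = mapping["gene"]
        tag_gene = pd.Series(uniques).map(gene_of)
        occ_gene = tag_gene.to_numpy(dtype=object)[codes]
        mask = pd.notna(occ_gene)
        gcodes, guniq = pd.factorize(occ_gene[mask])
        out["genes_detected"] = detected(gcodes, np.arange(n)[mask], len(guniq))
    return out
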