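"""Virtual CATG+17 tag library construction and clean-tag mapping.

The mapping index is the set of ALL extractable CATG+17 tags of the
reference gene sequences (sense and antisense) and, optionally, of the
genome. Clean tags are looked up exactly and at Hamming distance 1
(enumerating single-base neighbours against a hash of library keys), with
precedence

    perfect gene match > 1MM gene match > perfect genome match
    > 1MM genome match > unknown.

A tag whose winning gene set holds more than one gene is ambiguous and is
excluded from gene-level counts; a tag hitting the same gene on both strands
counts as sense. Gene expression is the sum of copy numbers of unambiguous
sense tags per gene, normalised to TPM (tags per million clean tags).
Offsets are 0-based positions of the CATG site on the sense strand.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Iterator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import TagCountTable
from .seq import ANCHOR, TAG_LEN, revcomp, tag_at, tag_sites
from .simulate import ReferenceSet

PM_GENE_SENSE = "PM-gene-sense"
PM_GENE_ANTISENSE = "PM-gene-antisense"
MM_GENE_SENSE = "1MM-gene-sense"
MM_GENE_ANTISENSE = "1MM-gene-antisense"
PM_GENOME_1POS = "PM-genome-1pos"
PM_GENOME_NPOS = "PM-genome-npos"
MM_GENOME = "1MM-genome"
UNKNOWN = "unknown"

GENE_CATEGORIES = frozenset({PM_GENE_SENSE, PM_GENE_ANTISENSE, MM_GENE_SENSE, MM_GENE_ANTISENSE})
GENE_SENSE_CATEGORIES = frozenset({PM_GENE_SENSE, MM_GENE_SENSE})
GENE_ANTISENSE_CATEGORIES = frozenset({PM_GENE_ANTISENSE, MM_GENE_ANTISENSE})
GENOME_CATEGORIES = frozenset({PM_GENOME_1POS, PM_GENOME_NPOS, MM_GENOME})
ALL_CATEGORIES = tuple(sorted(GENE_CATEGORIES)) + tuple(sorted(GENOME_CATEGORIES)) + (UNKNOWN,)


@dataclass(frozen=True)
class TagLocus:
    """One occurrence of a tag: target id, strand, sense-strand CATG offset."""

    target: str
    strand: str  # "sense" | "antisense"
    offset: int


class VirtualTagLibrary:
    """Hash from 21nt tag to all loci where it occurs."""

    def __init__(self, entries: dict[str, list[TagLocus]]):
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, tag: str) -> bool:
        return tag in self.entries

    def get(self, tag: str) -> list[TagLocus]:
        return self.entries.get(tag, [])

    def items(self) -> Iterator[tuple[str, list[TagLocus]]]:
        return iter(self.entries.items())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tag, loc.target, loc.strand, loc.offset)
            for tag, loci in sorted(self.entries.items())
            for loc in loci
        ]
        return pd.DataFrame(rows, columns=["tag", "target", "strand", "offset"])


def _scan(entries: dict[str, list[TagLocus]], target: str, seq: str, include_antisense: bool) -> None:
    L = len(seq)
    for i in tag_sites(seq):
        entries[tag_at(seq, i)].append(TagLocus(target, "sense", i))
    if include_antisense:
        rc = revcomp(seq)
        for j in tag_sites(rc):
            # the NlaIII site is palindromic: the anchor occupies sense
            # positions [L-j-4, L-j), so the sense-strand CATG starts there
            entries[tag_at(rc, j)].append(TagLocus(target, "antisense", L - j - len(ANCHOR)))


def build_virtual_tag_library(reference: ReferenceSet, include_antisense: bool = True) -> VirtualTagLibrary:
    """Every extractable CATG+17 tag of every gene, on both strands by default."""
    if not reference.genes:
        raise ValueError("reference has no genes")
    entries: dict[str, list[TagLocus]] = defaultdict(list)
    for gid, seq in reference.genes:
        _scan(entries, gid, seq, include_antisense)
    return VirtualTagLibrary(dict(entries))


def build_genome_tag_library(reference: ReferenceSet, include_antisense: bool = True) -> VirtualTagLibrary:
    """Every extractable CATG+17 tag of the genome sequence (target id 'genome')."""
    if reference.genome is None:
        raise ValueError("reference has no genome sequence")
    entries: dict[str, list[TagLocus]] = defaultdict(list)
    _scan(entries, "genome", reference.genome, include_antisense)
    return VirtualTagLibrary(dict(entries))


def hamming1_neighbors(tag: str, include_anchor: bool = False) -> Iterator[str]:
    """All sequences at Hamming distance exactly 1 from `tag`.

    By default the 4nt CATG anchor is excluded from enumeration: every clean
    tag and every library key begins with CATG, so anchor mismatches cannot
    produce a hit.
    """
    start = 0 if include_anchor else len(ANCHOR)
    for i in range(start, len(tag)):
        for b in "ACGT":
            if b != tag[i]:
                yield tag[:i] + b + tag[i + 1 :]


def map_tags(
    tags: TagCountTable,
    gene_lib: VirtualTagLibrary,
    genome_lib: VirtualTagLibrary | None = None,
    mismatch_in_anchor: bool = False,
) -> pd.DataFrame:
    """Classify every clean tag; one mutually exclusive category per tag.

    Returns a frame indexed by tag with columns count, category,
    multiplicity ('one'/'many' for gene matches, 'n/a' otherwise), gene (the
    assigned gene for unambiguous gene matches) and genes (the full sorted
    gene tuple at the winning precedence level).
    """
    rows = []
    for tag, count in tags.counts.items():
        if len(tag) != TAG_LEN:
            raise ValueError(f"tag {tag!r} is not {TAG_LEN}nt")
        category, gene_set = UNKNOWN, ()
        loci = gene_lib.get(tag)
        mismatched = False
        if not loci:
            loci = [
                loc
                for nb in hamming1_neighbors(tag, include_anchor=mismatch_in_anchor)
                for loc in gene_lib.get(nb)
            ]
            mismatched = True
        if loci:
            gene_set = tuple(sorted({loc.target for loc in loci}))
            sense = any(loc.strand == "sense" for loc in loci)
            if mismatched:
                category = MM_GENE_SENSE if sense else MM_GENE_ANTISENSE
            else:
                category = PM_GENE_SENSE if sense else PM_GENE_ANTISENSE
        elif genome_lib is not None:
            gloci = genome_lib.get(tag)
            if gloci:
                category = PM_GENOME_1POS if len(gloci) == 1 else PM_GENOME_NPOS
            elif any(
                genome_lib.get(nb)
                for nb in hamming1_neighbors(tag, include_anchor=mismatch_in_anchor)
            ):
                category = MM_GENOME
        if category in GENE_CATEGORIES:
            multiplicity = "one" if len(gene_set) == 1 else "many"
        else:
            multiplicity = "n/a"
        gene = gene_set[0] if multiplicity == "one" else None
        rows.append((tag, count, category, multiplicity, gene, gene_set))
    df = pd.DataFrame(
        rows, columns=["tag", "count", "category", "multiplicity", "gene", "genes"]
    )
    return df.set_index("tag")


def gene_counts(
    mapping: pd.DataFrame,
    tags: TagCountTable | None = None,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene unambiguous tag counts (sense), antisense tallied separately.

    count(g) sums the copy numbers of unambiguous sense-strand tags assigned
    to g; antisense-assigned copies are reported in antisense_count but are
    not added to count. `genes` reindexes the result (missing genes get 0).
    """
    counts = (
        mapping["count"]
        if tags is None
        else pd.Series(mapping.index.map(tags.counts), index=mapping.index)
    )
    unamb = mapping["multiplicity"] == "one"
    sense = unamb & mapping["category"].isin(GENE_SENSE_CATEGORIES)
    anti = unamb & mapping["category"].isin(GENE_ANTISENSE_CATEGORIES)
    sense_counts = counts[sense].groupby(mapping.loc[sense, "gene"]).sum()
    anti_counts = counts[anti].groupby(mapping.loc[anti, "gene"]).sum()
    expr = pd.DataFrame({"count": sense_counts, "antisense_count": anti_counts})
    if genes is not None:
        expr = expr.reindex(list(genes))
    expr = expr.fillna(0).astype(np.int64)
    expr.index.name = "gene"
    return expr


def tpm_normalize(expr: pd.DataFrame, clean_total: int) -> pd.DataFrame:
    """Add TPM = count / clean_total x 10^6."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    out = expr.copy()
    out["tpm"] = out["count"] / clean_total * 1e6
    return out


def quantify(
    tags: TagCountTable,
    gene_lib: VirtualTagLibrary,
    genome_lib: VirtualTagLibrary | None = None,
    genes: Iterable[str] | None = None,
    mismatch_in_anchor: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map a clean tag table and return (mapping frame, TPM expression table)."""
    mapping = map_tags(tags, gene_lib, genome_lib, mismatch_in_anchor=mismatch_in_anchor)
    expr = tpm_normalize(gene_counts(mapping, genes=genes), tags.total_clean)
    return mapping, expr
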