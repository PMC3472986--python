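"""Synthetic data generator for two-library restriction-tag (DGE) experiments.

The generator emulates the tag-profiling protocol: poly(A) cDNA is digested
with NlaIII (CATG), the bead-bound 3' fragment keeps the 3'-most CATG site,
and MmeI releases a 21nt tag (CATG + 17nt) that is sequenced as a 49bp read
padded with a 3' adaptor. Two libraries are drawn from the same reference
with a configurable fraction of genes truly differentially expressed at
known fold changes, so every downstream stage can be tested against a truth
table without any external data.

Sequencing artefacts modelled: independent per-base substitution errors
(uniform over the three alternatives, no indels), 'N' base calls,
adaptor-only ("empty") reads, antisense transcription (tags from the
reverse-complement strand) and intergenic transcription (tags from genomic
spacer sequence). Quality scores are not modelled; FASTQ output uses a
constant quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import ONTOLOGIES, AnnotationMap
from .seq import ANCHOR, TAG_LEN, revcomp, tag_at, tag_sites, three_prime_tag

logger = logging.getLogger(__name__)

#: 28nt aperiodic placeholder 3' adaptor (the real adaptor is proprietary);
#: chosen with no internal repeat so that a proper read trims uniquely at
#: position 21 and an adaptor-only read trims at position 0.
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTGAAAAAAA"

READ_LENGTH = 49

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass
class ReferenceSet:
    """Reference gene sequences plus an optional concatenated genome.

    genes: (gene-id, sequence) pairs with unique ids and non-empty A/C/G/T
    sequences. genome: the gene sequences concatenated, optionally separated
    by intergenic spacers (kept in `intergenic` so intergenic tags can be
    simulated).
    """

    genes: list[tuple[str, str]]
    genome: str | None = None
    intergenic: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        if any(not seq for _, seq in self.genes):
            raise ValueError("gene sequences must be non-empty")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]

    def as_dict(self) -> dict[str, str]:
        return dict(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionTruth:
    """Ground-truth expression state of a simulated two-library contrast.

    table: per-gene baseline relative abundance (sums to 1), condition-2
    fold change (exactly 1 for non-DE genes) and the is_de flag, indexed by
    gene id. depth1/depth2 are the target library depths.
    """

    table: pd.DataFrame
    depth1: int
    depth2: int


@dataclass
class RawReadSet:
    """Simulated 49nt raw reads with per-read provenance for testing.

    provenance entries are (class, source) pairs where class is one of
    'sense', 'antisense', 'intergenic' or 'empty' and source is the gene id
    (or '' for artefact classes).
    """

    reads: list[str]
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


def _decode(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode("ascii")


def generate_reference(
    n_genes: int,
    length_range: tuple[int, int] = (200, 2000),
    intergenic_fraction: float = 0.2,
    tag_fraction: float = 0.95,
    seed: int = 0,
) -> ReferenceSet:
    """Random reference transcripts plus a concatenated genome.

    At least ``tag_fraction`` of the genes are guaranteed to carry an
    extractable tag (a CATG with >=17nt downstream); where the random
    sequence lacks one, an anchor is planted at a random valid position.
    When ``intergenic_fraction`` > 0 the genome interleaves random spacers
    so that spacers make up that fraction of the genome.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 25:
        raise ValueError("minimum gene length is 25nt (4nt anchor + 17nt tag + margin)")
    if hi < lo:
        raise ValueError("length_range must be (low, high) with high >= low")
    if not 0.0 <= intergenic_fraction < 1.0:
        raise ValueError("intergenic_fraction must be in [0, 1)")
    if not 0.0 <= tag_fraction <= 1.0:
        raise ValueError("tag_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    seqs = [_decode(rng.integers(0, 4, size=int(L))) for L in lengths]

    n_need = int(np.ceil(tag_fraction * n_genes))
    need_idx = rng.choice(n_genes, size=n_need, replace=False)
    for i in need_idx:
        if three_prime_tag(seqs[i]) is None:
            pos = int(rng.integers(0, len(seqs[i]) - TAG_LEN + 1))
            seqs[i] = seqs[i][:pos] + ANCHOR + seqs[i][pos + len(ANCHOR) :]

    genes = [(f"g{i + 1:05d}", seqs[i]) for i in range(n_genes)]

    spacers: list[str] = []
    if intergenic_fraction > 0:
        total_gene = int(lengths.sum())
        total_spacer = int(round(intergenic_fraction / (1 - intergenic_fraction) * total_gene))
        cuts = rng.multinomial(total_spacer, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
        spacers = [_decode(rng.integers(0, 4, size=int(c))) for c in cuts]
        parts = [spacers[0]]
        for (gid, seq), sp in zip(genes, spacers[1:]):
            parts.append(seq)
            parts.append(sp)
        genome = "".join(parts)
    else:
        genome = "".join(seqs)

    return ReferenceSet(genes, genome, tuple(s for s in spacers if s))


def generate_annotations(
    reference: ReferenceSet,
    n_terms: int = 30,
    n_pathways: int = 15,
    seed: int = 0,
) -> AnnotationMap:
    """Random flat GO-like / pathway-like annotations for the reference.

    Term sizes are geometrically spread between ~3 genes and ~N/5 genes so
    small specific terms and broad ones both occur; terms cycle through the
    three ontologies. Reproducible under `seed`.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if n_pathways < 0:
        raise ValueError("n_pathways must be >= 0")
    rng = np.random.default_rng(seed)
    ids = reference.gene_ids
    N = len(ids)

    def assign(prefix: str, k: int) -> tuple[dict[str, set[str]], list[str]]:
        mapping: dict[str, set[str]] = {g: set() for g in ids}
        labels = []
        if k == 0:
            return mapping, labels
        sizes = np.geomspace(min(3, N), max(3, N // 5), num=k)
        sizes = np.clip(np.round(sizes).astype(int), 1, N)
        for j in range(k):
            label = f"{prefix}{j + 1:04d}"
            labels.append(label)
            for idx in rng.choice(N, size=int(sizes[j]), replace=False):
                mapping[ids[int(idx)]].add(label)
        return mapping, labels

    gene_terms, term_labels = assign("T", n_terms)
    gene_pathways, _ = assign("P", n_pathways)
    term_ontology = {t: ONTOLOGIES[j % len(ONTOLOGIES)] for j, t in enumerate(term_labels)}
    return AnnotationMap(gene_terms, gene_pathways, term_ontology)


def simulate_expression(
    reference: ReferenceSet,
    de_fraction: float = 0.05,
    fold_range: tuple[float, float] = (4.0, 16.0),
    depth1: int = 100_000,
    depth2: int = 100_000,
    seed: int = 0,
    baseline_sigma: float = 1.5,
) -> tuple[ExpressionTruth, pd.Series, pd.Series]:
    """Two-condition expression truth plus multinomial per-gene tag counts.

    Baseline relative abundances are log-normal (sigma 1.5: a few dominant
    transcripts, a long tail of rare ones). A ``de_fraction`` of genes gets a
    fold change drawn log-uniformly from ``fold_range``, inverted for a
    random half (down-regulation); condition-2 probabilities are the
    rescaled, renormalized baselines. Counts are multinomial draws summing
    exactly to depth1 and depth2.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if min(depth1, depth2) < 1000:
        raise ValueError("library depths below 1000 give unstable downstream statistics")
    lo, hi = fold_range
    if de_fraction > 0 and (lo < 2.0 or hi < lo):
        raise ValueError("fold_range must satisfy 2 <= low <= high (reciprocals model down-regulation)")

    rng = np.random.default_rng(seed)
    ids = reference.gene_ids
    n = len(ids)

    baseline = rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n)
    baseline /= baseline.sum()

    folds = np.ones(n)
    is_de = np.zeros(n, dtype=bool)
    n_de = int(round(de_fraction * n))
    if n_de:
        de_idx = rng.choice(n, size=n_de, replace=False)
        f = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_de))
        down = rng.random(n_de) < 0.5
        f[down] = 1.0 / f[down]
        folds[de_idx] = f
        is_de[de_idx] = True

    p2 = baseline * folds
    p2 /= p2.sum()

    counts1 = pd.Series(rng.multinomial(depth1, baseline), index=ids, name="count")
    counts2 = pd.Series(rng.multinomial(depth2, p2), index=ids, name="count")

    table = pd.DataFrame(
        {"baseline": baseline, "fold_change": folds, "is_de": is_de},
        index=pd.Index(ids, name="gene"),
    )
    return ExpressionTruth(table, depth1, depth2), counts1, counts2


def simulate_reads(
    counts,
    reference: ReferenceSet,
    adaptor: str = DEFAULT_ADAPTOR,
    error_rate: float = 0.0,
    n_rate: float = 0.0,
    empty_read_rate: float = 0.01,
    antisense_rate: float = 0.02,
    intergenic_rate: float = 0.02,
    seed: int = 0,
) -> RawReadSet:
    """Turn per-gene tag counts into noisy 49nt raw reads.

    Each count of gene g yields one read: g's 3'-most tag followed by the 3'
    adaptor, padded/truncated to 49nt. Genes without an extractable tag
    contribute no reads (logged). Antisense reads carry the 3'-most tag of
    the reverse-complement sequence; intergenic reads a random tag from a
    genomic spacer; empty reads are adaptor-only. Substitutions and 'N'
    calls are applied per base; reads are shuffled before return.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    for name, rate in (
        ("error_rate", error_rate),
        ("n_rate", n_rate),
        ("empty_read_rate", empty_read_rate),
        ("antisense_rate", antisense_rate),
        ("intergenic_rate", intergenic_rate),
    ):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")

    counts = pd.Series(counts)
    seqs = reference.as_dict()
    unknown = set(counts.index) - set(seqs)
    if unknown:
        raise ValueError(f"counts refer to genes absent from the reference: {sorted(unknown)[:3]}...")

    ss = np.random.SeedSequence(seed)
    r_extra, r_err, r_shuffle = (np.random.default_rng(s) for s in ss.spawn(3))

    def to_read(tag: str) -> str:
        return (tag + adaptor + "A" * READ_LENGTH)[:READ_LENGTH]

    reads: list[str] = []
    prov: list[tuple[str, str]] = []
    for gid, c in counts.items():
        c = int(c)
        if c <= 0:
            continue
        tag = three_prime_tag(seqs[gid])
        if tag is None:
            logger.info("gene %s has no extractable tag; %d counts dropped", gid, c)
            continue
        reads.extend([to_read(tag)] * c)
        prov.extend([("sense", gid)] * c)
    n_sense = len(reads)

    if antisense_rate > 0 and n_sense:
        anti_tags = {}
        for gid in counts.index:
            if counts[gid] > 0:
                t = three_prime_tag(revcomp(seqs[gid]))
                if t is not None:
                    anti_tags[gid] = t
        if anti_tags:
            n_anti = int(r_extra.binomial(n_sense, antisense_rate))
            gids = list(anti_tags)
            w = counts[gids].to_numpy(dtype=float)
            w /= w.sum()
            for gid in r_extra.choice(gids, size=n_anti, p=w):
                reads.append(to_read(anti_tags[gid]))
                prov.append(("antisense", gid))

    if intergenic_rate > 0 and n_sense and reference.intergenic:
        inter_tags = [tag_at(sp, i) for sp in reference.intergenic for i in tag_sites(sp)]
        if inter_tags:
            n_inter = int(r_extra.binomial(n_sense, intergenic_rate))
            for j in r_extra.integers(0, len(inter_tags), size=n_inter):
                reads.append(to_read(inter_tags[int(j)]))
                prov.append(("intergenic", ""))

    if reads and (error_rate > 0 or n_rate > 0):
        mat = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
        mat = mat.reshape(len(reads), READ_LENGTH).copy()
        if error_rate > 0:
            hit = r_err.random(mat.shape) < error_rate
            shift = r_err.integers(1, 4, size=int(hit.sum()))
            mat[hit] = _BASES[(_CODE[mat[hit]] + shift) % 4]
        if n_rate > 0:
            hit = r_err.random(mat.shape) < n_rate
            mat[hit] = ord("N")
        reads = [bytes(row).decode("ascii") for row in mat]

    if empty_read_rate > 0 and reads:
        n_empty = int(r_extra.binomial(len(reads), empty_read_rate))
        empty_read = (adaptor + "A" * READ_LENGTH)[:READ_LENGTH]
        reads.extend([empty_read] * n_empty)
        prov.extend([("empty", "")] * n_empty)

    order = r_shuffle.permutation(len(reads))
    return RawReadSet([reads[i] for i in order], [prov[i] for i in order])
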