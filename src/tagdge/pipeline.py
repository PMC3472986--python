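"""End-to-end convenience driver: simulate two libraries, clean, map, test.

Mirrors a two-condition tag-profiling experiment at desk scale. Each stage
is the public function of its module; this wrapper only wires them together
and keeps the intermediate artefacts for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import de, mapping, preprocess, simulate


@dataclass
class ExperimentResult:
    """All intermediate and final artefacts of a simulated experiment."""

    reference: simulate.ReferenceSet
    truth: simulate.ExpressionTruth
    sim_counts1: pd.Series
    sim_counts2: pd.Series
    tags1: preprocess.TagCountTable
    tags2: preprocess.TagCountTable
    gene_lib: mapping.VirtualTagLibrary
    genome_lib: mapping.VirtualTagLibrary
    mapping1: pd.DataFrame
    mapping2: pd.DataFrame
    expr1: pd.DataFrame
    expr2: pd.DataFrame
    de_table: pd.DataFrame
    de_summary: de.DESummary


def _subseeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def run_two_library_experiment(
    n_genes: int = 1000,
    depth1: int = 100_000,
    depth2: int = 100_000,
    de_fraction: float = 0.05,
    fold_range: tuple[float, float] = (4.0, 16.0),
    error_rate: float = 0.01,
    seed: int = 0,
    fdr_threshold: float = de.DEFAULT_FDR,
    lfc_threshold: float = de.DEFAULT_LFC,
    **read_kwargs,
) -> ExperimentResult:
    """Simulate, preprocess, map and screen a two-library DGE experiment.

    Extra keyword arguments (n_rate, empty_read_rate, antisense_rate,
    intergenic_rate, adaptor) are forwarded to simulate_reads for both
    libraries.
    """
    s_ref, s_expr, s_r1, s_r2 = _subseeds(seed, 4)
    reference = simulate.generate_reference(n_genes, seed=s_ref)
    truth, c1, c2 = simulate.simulate_expression(
        reference,
        de_fraction=de_fraction,
        fold_range=fold_range,
        depth1=depth1,
        depth2=depth2,
        seed=s_expr,
    )
    reads1 = simulate.simulate_reads(c1, reference, error_rate=error_rate, seed=s_r1, **read_kwargs)
    reads2 = simulate.simulate_reads(c2, reference, error_rate=error_rate, seed=s_r2, **read_kwargs)

    adaptor = read_kwargs.get("adaptor", simulate.DEFAULT_ADAPTOR)
    tags1 = preprocess.extract_clean_tags(reads1, adaptor=adaptor, label="library1")
    tags2 = preprocess.extract_clean_tags(reads2, adaptor=adaptor, label="library2")

    gene_lib = mapping.build_virtual_tag_library(reference)
    genome_lib = mapping.build_genome_tag_library(reference)
    mapping1, expr1 = mapping.quantify(tags1, gene_lib, genome_lib, genes=reference.gene_ids)
    mapping2, expr2 = mapping.quantify(tags2, gene_lib, genome_lib, genes=reference.gene_ids)

    table = de.differential_expression(
        expr1["count"], expr2["count"], n1=tags1.total_clean, n2=tags2.total_clean
    )
    table, summary = de.screen_degs(table, fdr_threshold, lfc_threshold)

    return ExperimentResult(
        reference=reference,
        truth=truth,
        sim_counts1=c1,
        sim_counts2=c2,
        tags1=tags1,
        tags2=tags2,
        gene_lib=gene_lib,
        genome_lib=genome_lib,
        mapping1=mapping1,
        mapping2=mapping2,
        expr1=expr1,
        expr2=expr2,
        de_table=table,
        de_summary=summary,
    )
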