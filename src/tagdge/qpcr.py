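"""Relative quantification from qPCR Ct tables (2^-ddCt) and concordance of
qPCR fold changes with sequencing-based log2 ratios.

dCt = Ct_target - Ct_reference per replicate; replicate dCt values are
averaged per gene x sample before ddCt = dCt_sample - dCt_calibrator, and
the relative expression is 2^-ddCt (amplification efficiency assumed exactly
2). The replicate SD is propagated as the SD of replicate-wise folds. The
reference gene (e.g. RNA polymerase II) enters only through Ct_reference.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("gene", "sample", "replicate", "ct_target", "ct_reference")
CT_RANGE = (0.0, 45.0)


def _validate_ct(ct: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    for col in ("ct_target", "ct_reference"):
        bad = ct[ct[col].isna() | (ct[col] <= CT_RANGE[0]) | (ct[col] >= CT_RANGE[1])]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"invalid {col} for gene {row['gene']!r} sample {row['sample']!r}: "
                f"values must lie in (0, 45)"
            )


def ddct_fold_change(ct: pd.DataFrame, calibrator_sample: str) -> pd.DataFrame:
    """Per gene x sample relative expression 2^-ddCt with replicate mean +/- SD.

    The calibrator sample must be present for every gene; its own fold is
    1.0 by construction.
    """
    _validate_ct(ct)
    ct = ct.copy()
    ct["dct"] = ct["ct_target"] - ct["ct_reference"]
    mean_dct = ct.groupby(["gene", "sample"], sort=True)["dct"].mean()

    genes = ct["gene"].unique()
    cal = {}
    for gene in genes:
        try:
            cal[gene] = mean_dct.loc[(gene, calibrator_sample)]
        except KeyError:
            raise ValueError(
                f"calibrator sample {calibrator_sample!r} missing for gene {gene!r}"
            ) from None

    ct["fold_rep"] = 2.0 ** -(ct["dct"] - ct["gene"].map(cal))
    rows = []
    for (gene, sample), grp in ct.groupby(["gene", "sample"], sort=True):
        ddct = mean_dct.loc[(gene, sample)] - cal[gene]
        rows.append(
            (
                gene,
                sample,
                len(grp),
                mean_dct.loc[(gene, sample)],
                ddct,
                2.0**-ddct,
                grp["fold_rep"].std(ddof=1) if len(grp) > 1 else 0.0,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene", "sample", "n_replicates", "delta_ct", "ddct", "fold", "fold_sd"]
    )


def simulate_ct_table(
    fold_changes: Mapping[str, float],
    samples: tuple[str, str] = ("condition1", "condition2"),
    n_replicates: int = 3,
    base_ct_range: tuple[float, float] = (22.0, 30.0),
    reference_ct: float = 20.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Ct table in which sample 2 expresses each gene at the given
    fold relative to sample 1 (one Ct cycle per 2-fold), with N(0, sd) noise
    on every Ct measurement."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene, fold in fold_changes.items():
        base = rng.uniform(*base_ct_range)
        targets = {samples[0]: base, samples[1]: base - np.log2(fold)}
        for sample in samples:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (
                        gene,
                        sample,
                        rep,
                        targets[sample] + rng.normal(0.0, noise_sd),
                        reference_ct + rng.normal(0.0, noise_sd),
                    )
                )
    return pd.DataFrame(rows, columns=list(CT_COLUMNS))


def concordance(dge_lfc, qpcr_lfc) -> tuple[float, float]:
    """(direction agreement fraction, Spearman rank correlation) over shared genes.

    A zero log2 fold change agrees with either direction. Requires at least
    three shared genes.
    """
    s1 = pd.Series(dge_lfc).dropna()
    s2 = pd.Series(qpcr_lfc).dropna()
    shared = s1.index.intersection(s2.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    a = s1.loc[shared].to_numpy(dtype=np.float64)
    b = s2.loc[shared].to_numpy(dtype=np.float64)
    agree = float(np.mean((np.sign(a) == np.sign(b)) | (a == 0) | (b == 0)))
    rho = float(stats.spearmanr(a, b).statistic)
    return agree, rho
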