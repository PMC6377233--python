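"""Relative qPCR quantification and transcript-protein correlation.

Expression of a target gene is quantified relative to the arithmetic mean of
two reference genes: ``dCt = Ct_target - (Ct_ref1 + Ct_ref2)/2`` and the
relative level is ``2^-dCt``.  Group differences are assessed by Shapiro-Wilk
normality checks, Welch's two-sample t-test and BH adjustment across the
assay batch.  Transcript-protein agreement is the Pearson correlation of
log10-transformed matched values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transcript_de import bh_adjust


def average_technical_duplicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of technical duplicate Ct values per (sample, gene)."""
    return ct.groupby(["sample_id", "gene"], as_index=False)["ct"].mean()


def relative_expression(ct_target: float, ct_ref1: float, ct_ref2: float) -> float:
    """2^-dCt with dCt relative to the mean of the two reference genes.

    Missing Ct values propagate as NaN.
    """
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in (ct_target, ct_ref1, ct_ref2)):
        return float("nan")
    dct = ct_target - (ct_ref1 + ct_ref2) / 2.0
    return float(2.0 ** (-dct))


def relative_expression_table(
    ct: pd.DataFrame, reference_genes: tuple[str, str] = ("cdc5", "sams")
) -> pd.DataFrame:
    """Per-sample relative expression of every non-reference gene.

    Technical duplicates are averaged first; samples missing either reference
    gene get NaN.
    """
    avg = average_technical_duplicates(ct)
    wide = avg.pivot(index="sample_id", columns="gene", values="ct")
    r1, r2 = reference_genes
    rows = []
    for sample, row in wide.iterrows():
        for gene in wide.columns:
            if gene in reference_genes:
                continue
            rows.append(
                {
                    "sample_id": sample,
                    "gene": gene,
                    "relative_expression": relative_expression(
                        row.get(gene, float("nan")),
                        row.get(r1, float("nan")),
                        row.get(r2, float("nan")),
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    normality_p_a: float
    normality_p_b: float
    test_p: float
    t_stat: float
    df: float


def group_test(values_a, values_b, min_n_normality: int = 3) -> GroupTestResult:
    """Shapiro-Wilk per group plus Welch's two-sided two-sample t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < min_n_normality or len(b) < min_n_normality:
        raise ValueError("normality testing needs >=3 values per group")
    sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else float("nan")
    sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else float("nan")
    welch = stats.ttest_ind(a, b, equal_var=False)
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.isclose(a.mean(), b.mean()):
        return GroupTestResult(sw_a, sw_b, 1.0, 0.0, float(len(a) + len(b) - 2))
    return GroupTestResult(sw_a, sw_b, float(welch.pvalue), float(welch.statistic), float(welch.df))


def batch_group_tests(assays: dict[str, tuple]) -> pd.DataFrame:
    """Run group_test per assay and BH-adjust the batch of test p-values."""
    rows = []
    for name, (a, b) in assays.items():
        res = group_test(a, b)
        rows.append(
            {
                "assay": name,
                "normality_p_a": res.normality_p_a,
                "normality_p_b": res.normality_p_b,
                "p": res.test_p,
                "t": res.t_stat,
                "df": res.df,
            }
        )
    out = pd.DataFrame(rows).set_index("assay")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def log10_pearson(pairs: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) of log10 transcript vs log10 protein values.

    ``pairs`` needs strictly positive columns ``transcript_value`` and
    ``protein_value``; returns (nan, nan) when either axis is constant.
    """
    t = np.log10(pairs["transcript_value"].to_numpy(dtype=float))
    p = np.log10(pairs["protein_value"].to_numpy(dtype=float))
    if len(t) < 3:
        raise ValueError("need at least 3 matched pairs")
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        return float("nan"), float("nan")
    r, pval = stats.pearsonr(t, p)
    return float(r), float(pval)
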