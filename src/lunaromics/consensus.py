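"""Rank-sum consensus of two DE result lists and the bookkeeping reports.

Two methods' results over the same feature universe are merged by ranking
each list by adjusted p-value (ascending, ties averaged), summing the two
ranks per feature and re-sorting by the rank sum.  Significance is called at
BH 10% in both methods (intersection, default) or in either (union).
The module also computes the summary arithmetic the pipeline reports:
process-set overlap counts/percentages, unisex classification of stage
contrasts, and the top-N stratified enrichment folds.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed-table rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 2) -> float:
    if total <= 0:
        return float("nan")
    return round_half_up(100.0 * count / total, decimals)


def rank_sum_merge(
    res1: pd.DataFrame,
    res2: pd.DataFrame,
    alpha: float = 0.1,
    call_mode: str = "intersection",
) -> pd.DataFrame:
    """Merge two DE results by per-method adjusted-p ranks.

    Features untested (NA adjusted p) in either method are excluded from the
    merge and reported in ``attrs['excluded']``.  Final ordering is ascending
    rank sum, ties broken by feature ID; ``significant`` requires adjusted
    p <= alpha in both methods (``intersection``) or either (``union``);
    direction comes from ``res1``'s fold-change sign, with a ``discordant``
    flag when the two methods disagree in sign.
    """
    if call_mode not in {"intersection", "union"}:
        raise ValueError("call_mode must be 'intersection' or 'union'")
    u1, u2 = set(res1.index), set(res2.index)
    if u1 != u2:
        diff = sorted(u1 ^ u2)
        raise ValueError(f"feature universes differ; symmetric difference: {diff[:20]}")

    df = pd.DataFrame(
        {
            "padj_method1": res1["padj"],
            "padj_method2": res2["padj"].reindex(res1.index),
            "log2fc_method1": res1["log2FC"],
            "log2fc_method2": res2["log2FC"].reindex(res1.index),
        }
    )
    tested = df["padj_method1"].notna() & df["padj_method2"].notna()
    excluded = df.index[~tested].tolist()
    df = df.loc[tested].copy()
    df["rank_method1"] = df["padj_method1"].rank(method="average")
    df["rank_method2"] = df["padj_method2"].rank(method="average")
    df["rank_sum"] = df["rank_method1"] + df["rank_method2"]
    if call_mode == "intersection":
        sig = (df["padj_method1"] <= alpha) & (df["padj_method2"] <= alpha)
    else:
        sig = (df["padj_method1"] <= alpha) | (df["padj_method2"] <= alpha)
    df["significant"] = sig
    df["direction"] = np.where(df["log2fc_method1"] >= 0, "up", "down")
    df["discordant"] = np.sign(df["log2fc_method1"]) * np.sign(df["log2fc_method2"]) < 0
    # ascending rank sum; ties broken lexicographically by feature ID
    df = df.sort_index(kind="stable").sort_values("rank_sum", kind="stable")
    df.attrs["alpha"] = alpha
    df.attrs["call_mode"] = call_mode
    df.attrs["excluded"] = excluded
    return df


def significant_set(consensus: pd.DataFrame) -> set[str]:
    return set(consensus.index[consensus["significant"]])


def classify_unisex(cmp_male: pd.DataFrame, cmp_female: pd.DataFrame) -> tuple[set, set]:
    """Features significant in the same direction in both sex-specific runs
    of a stage contrast; discordant directions are excluded."""
    def calls(tab: pd.DataFrame, direction: str) -> set:
        mask = tab["significant"] & (tab["direction"] == direction) & (~tab["discordant"])
        return set(tab.index[mask])

    unisex_up = calls(cmp_male, "up") & calls(cmp_female, "up")
    unisex_down = calls(cmp_male, "down") & calls(cmp_female, "down")
    return unisex_up, unisex_down


def overlap_report(sets: dict[str, set], universe_size: int) -> dict:
    """Counts and percentages for all processes and their intersections.

    Per-process percentages are relative to the universe; overlap percentages
    are relative to the first-named set of the pair (the reference set).
    """
    union_size = len(set().union(*sets.values())) if sets else 0
    if universe_size < union_size:
        raise ValueError("universe smaller than union of sets")
    report: dict = {"universe_size": universe_size, "processes": {}, "overlaps": {}}
    for name, s in sets.items():
        report["processes"][name] = {"count": len(s), "pct": percentage(len(s), universe_size)}
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = len(sets[a] & sets[b])
            report["overlaps"][f"{a}&{b}"] = {
                "count": inter,
                "pct_of_first": percentage(inter, len(sets[a])),
            }
    if len(names) >= 3:
        inter_all = len(set.intersection(*[sets[n] for n in names]))
        report["overlaps"]["&".join(names)] = {"count": inter_all}
    return report


def stratified_enrichment(
    full_count: int, full_universe: int, top_count: int, top_universe: int
) -> float:
    """Fold enrichment of a DE rate in a top-expressed subset vs the full set.

    Both rates are first rendered as percentages rounded half-up to two
    decimals (the pipeline's printed form), and their ratio is reported to
    one decimal, reproducing the printed-bookkeeping chain.
    """
    if full_universe <= 0 or top_universe <= 0:
        raise ValueError("universes must be positive")
    full_pct = percentage(full_count, full_universe)
    top_pct = percentage(top_count, top_universe)
    return fold_from_percentages(full_pct, top_pct)


def fold_from_percentages(full_pct: float, top_pct: float) -> float:
    """Fold from already-rounded percentage rates (NaN when the base rate is 0)."""
    if full_pct == 0:
        return float("nan")
    return round_half_up(top_pct / full_pct, 1)
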