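"""End-to-end orchestration: simulate -> DE -> consensus -> reports.

``run_pipeline`` executes the stages in order (synthetic data generation,
count preprocessing and NB testing, TMT normalization and protein testing,
rank-sum consensus, soft clustering, term enrichment, qPCR/correlation) and
writes plain TSV/JSON artifacts plus a manifest of input hashes and seeds.
The summary report carries the bookkeeping the analysis prints: per-process
significant counts and percentages, pairwise/triple overlaps, top-N
stratified enrichment folds and replication overlap statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import go_enrich, proteome_de, qpcr_corr, softclust, synth, transcript_de
from .design import Comparison, StudyDesign, default_comparisons, make_study_design, make_tmt_design

logger = logging.getLogger(__name__)

FACTORS = ("maturation", "sex", "lunar")


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``from_yaml`` for the file schema)."""

    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    alpha: float = 0.1
    call_mode: str = "intersection"
    top_n: tuple[int, ...] = (1000, 5000)
    rots_bootstrap: int = 100
    cluster_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    enable_clustering: bool = True
    enable_enrichment: bool = True
    enable_qpcr: bool = True
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.call_mode not in {"intersection", "union"}:
            raise ConfigError("call_mode must be 'intersection' or 'union'")
        if any(n <= 0 for n in self.top_n):
            raise ConfigError("top_n entries must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            sim = synth.SimConfig(**raw.pop("sim", {}))
            return cls(sim=sim, **{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        except (TypeError, synth.ConfigurationError) as exc:
            raise ConfigError(str(exc)) from exc


def replication_overlap(quantifiable_set1, quantifiable_set2) -> tuple[int, float]:
    """How many of set1's members re-pass in set2, as count and percent of set1."""
    s1, s2 = set(quantifiable_set1), set(quantifiable_set2)
    n_overlap = len(s1 & s2)
    pct = cns.percentage(n_overlap, len(s1)) if s1 else float("nan")
    return n_overlap, pct


def _consensus_by_factor(
    results1: dict[str, pd.DataFrame],
    results2: dict[str, pd.DataFrame],
    comparisons: list[Comparison],
    alpha: float,
    call_mode: str,
) -> tuple[dict[str, set], dict[str, pd.DataFrame]]:
    """Merge the two methods per comparison; pool significant calls per factor
    (union across that factor's comparisons)."""
    sets: dict[str, set] = {f: set() for f in FACTORS}
    tables: dict[str, pd.DataFrame] = {}
    for cmp_ in comparisons:
        merged = cns.rank_sum_merge(results1[cmp_.name], results2[cmp_.name], alpha, call_mode)
        tables[cmp_.name] = merged
        sets[cmp_.factor] |= cns.significant_set(merged)
    return sets, tables


def transcript_stage(
    counts: pd.DataFrame,
    design: StudyDesign,
    comparisons: list[Comparison],
    alpha: float,
    call_mode: str,
) -> dict:
    """Collapse TRs, apply the spike-artifact filter, run both NB tests and
    the rank-sum consensus for every comparison."""
    collapsed = transcript_de.collapse_technical_replicates(counts, design)
    flagged, cohort = "IM_NM.2", ["IM_NM.1", "IM_NM.3"]
    if flagged in collapsed.columns and all(c in collapsed.columns for c in cohort):
        collapsed, spike_removed = transcript_de.filter_spike_artifacts(collapsed, flagged, cohort)
    else:
        spike_removed = []
    sf = transcript_de.size_factors_median_ratio(collapsed)
    eff = transcript_de.effective_size_factors(collapsed, transcript_de.tmm_factors(collapsed))
    wald, lrt = {}, {}
    for cmp_ in comparisons:
        groups = [list(cmp_.group_a), list(cmp_.group_b)]
        disp_w = transcript_de.fit_dispersions(collapsed, sf, groups)
        disp_l = transcript_de.fit_dispersions(collapsed, eff, groups)
        wald[cmp_.name] = transcript_de.nb_wald_test(collapsed, cmp_, sf, disp_w)
        lrt[cmp_.name] = transcript_de.nb_lrt_test(collapsed, cmp_, eff, disp_l)
    sets, tables = _consensus_by_factor(wald, lrt, comparisons, alpha, call_mode)
    return {
        "collapsed": collapsed,
        "spike_removed": spike_removed,
        "size_factors": sf,
        "wald": wald,
        "lrt": lrt,
        "consensus": tables,
        "det_sets": sets,
    }


def proteome_stage(
    peptides: pd.DataFrame,
    comparisons: list[Comparison],
    alpha: float,
    call_mode: str,
    rots_bootstrap: int,
    seed: int,
) -> dict:
    """Run the normalization cascade and both protein tests + consensus."""
    matrix, cfs = proteome_de.run_cascade(peptides)
    if matrix.values.empty:
        raise DataError("no quantifiable proteins after filtering")
    samples = matrix.sample_table()
    available = set(samples.columns)
    usable = [
        c for c in comparisons
        if set(c.group_a) <= available and set(c.group_b) <= available
    ]
    limma_like, rots = {}, {}
    params = proteome_de.RotsParams(n_bootstrap=rots_bootstrap, seed=seed)
    for cmp_ in usable:
        limma_like[cmp_.name] = proteome_de.moderated_t_test(samples, cmp_)
        rots[cmp_.name] = proteome_de.rots_test(samples, cmp_, params)
    sets, tables = _consensus_by_factor(limma_like, rots, usable, alpha, call_mode)
    return {
        "matrix": matrix,
        "conversion_factors": cfs,
        "samples": samples,
        "moderated_t": limma_like,
        "rots": rots,
        "consensus": tables,
        "dep_sets": sets,
        "comparisons": usable,
    }


def top_n_stage(
    collapsed: pd.DataFrame,
    design: StudyDesign,
    comparisons: list[Comparison],
    det_sets: dict[str, set],
    top_n: tuple[int, ...],
    alpha: float,
    call_mode: str,
) -> dict:
    """Re-test the top-N expressed transcripts and compute enrichment folds."""
    full_universe = len(collapsed)
    out = {}
    for n in top_n:
        if n > full_universe:
            logger.warning("top_n=%d exceeds universe %d; skipped", n, full_universe)
            continue
        sub = transcript_de.select_top_expressed(collapsed, n)
        sf = transcript_de.size_factors_median_ratio(sub)
        eff = transcript_de.effective_size_factors(sub, transcript_de.tmm_factors(sub))
        wald, lrt = {}, {}
        for cmp_ in comparisons:
            groups = [list(cmp_.group_a), list(cmp_.group_b)]
            wald[cmp_.name] = transcript_de.nb_wald_test(
                sub, cmp_, sf, transcript_de.fit_dispersions(sub, sf, groups)
            )
            lrt[cmp_.name] = transcript_de.nb_lrt_test(
                sub, cmp_, eff, transcript_de.fit_dispersions(sub, eff, groups)
            )
        sets, _ = _consensus_by_factor(wald, lrt, comparisons, alpha, call_mode)
        folds = {
            f: cns.stratified_enrichment(len(det_sets[f]), full_universe, len(sets[f]), n)
            for f in FACTORS
        }
        out[n] = {"counts": {f: len(sets[f]) for f in FACTORS}, "folds": folds}
    return out


def condition_means(values: pd.DataFrame, design: StudyDesign | None = None) -> pd.DataFrame:
    """Mean expression per condition (columns named ``condition.br`` or lane IDs)."""
    cond_of = {c: c.rsplit(".", 1)[0] for c in values.columns}
    return values.T.groupby(pd.Series(cond_of)).mean().T


def cluster_stage(
    values: pd.DataFrame, feature_sets: dict[str, set], c_range, seed: int
) -> dict:
    """Soft-cluster each process's significant features on condition means."""
    means = condition_means(values)
    out = {}
    for factor, ids in feature_sets.items():
        ids = sorted(ids & set(means.index))
        if len(ids) < max(c_range) + 2:
            logger.info("factor %s: too few features (%d) to cluster", factor, len(ids))
            continue
        profiles = softclust.standardize(means.loc[ids])
        if len(profiles) < max(c_range) + 2:
            continue
        c = softclust.select_cluster_count(profiles, c_range)
        m = softclust.estimate_fuzziness(len(profiles), profiles.shape[1])
        members, centroids = softclust.fuzzy_cmeans(profiles, c=c, m=m, seed=seed)
        out[factor] = {"c": c, "m": m, "memberships": members, "centroids": centroids}
    return out


def enrichment_stage(
    feature_sets: dict[str, set],
    ontology,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    universe = go_enrich.build_universe(annotation, ontology)
    known = set(universe.gene_to_terms)
    out = {}
    for factor, ids in feature_sets.items():
        selected = set(ids) & known
        if not selected:
            continue
        out[factor] = {
            d: go_enrich.conditional_enrichment(selected, universe, ontology, alpha, d)
            for d in ("over", "under")
        }
    return out


def correlation_stage(
    collapsed: pd.DataFrame, size_factors: pd.Series, protein_samples: pd.DataFrame
) -> dict:
    """Pearson correlation of log10 mean normalized transcript vs protein values.

    Synthetic transcript and protein IDs are matched positionally (the i-th
    protein to the i-th transcript), standing in for the ORF-to-transcript map
    of a real assembly.
    """
    norm = collapsed / size_factors
    t_mean = norm.mean(axis=1)
    p_mean = protein_samples.mean(axis=1, skipna=True)
    n = min(len(t_mean), len(p_mean))
    pairs = pd.DataFrame(
        {
            "transcript_value": t_mean.iloc[:n].to_numpy(),
            "protein_value": p_mean.iloc[:n].to_numpy(),
        }
    ).dropna()
    pairs = pairs[(pairs > 0).all(axis=1)]
    r, p = qpcr_corr.log10_pearson(pairs)
    return {"r": r, "p": p, "n_pairs": int(len(pairs))}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every enabled stage, write artifacts and return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim.replace(seed=config.seed)

    design = make_study_design(n_br=sim.n_br, n_tr=sim.n_lanes)
    tmt_design = make_tmt_design(n_br=sim.n_br, n_tr=sim.n_tr_ms)
    counts, t_truth = synth.simulate_counts(sim, design)
    peptides, p_truth = synth.simulate_tmt(sim, tmt_design)
    comparisons = default_comparisons(design)

    t_stage = transcript_stage(counts, design, comparisons, config.alpha, config.call_mode)
    p_stage = proteome_stage(
        peptides, comparisons, config.alpha, config.call_mode,
        config.rots_bootstrap, config.seed,
    )

    det_sets, dep_sets = t_stage["det_sets"], p_stage["dep_sets"]
    t_universe = len(t_stage["collapsed"])
    p_universe = len(p_stage["samples"])
    report: dict = {
        "seed": config.seed,
        "call_mode": config.call_mode,
        "alpha": config.alpha,
        "transcripts": cns.overlap_report(det_sets, t_universe),
        "proteins": cns.overlap_report(dep_sets, p_universe),
    }
    report["top_n"] = top_n_stage(
        t_stage["collapsed"], design, comparisons, det_sets,
        tuple(n for n in config.top_n if n <= t_universe),
        config.alpha, config.call_mode,
    )

    if config.enable_clustering:
        clusters = cluster_stage(
            t_stage["collapsed"] / t_stage["size_factors"], det_sets,
            config.cluster_range, config.seed,
        )
        report["clusters"] = {
            f: {"c": v["c"], "m": round(v["m"], 4)} for f, v in clusters.items()
        }
        for factor, v in clusters.items():
            v["memberships"].to_csv(out / f"memberships_{factor}.tsv", sep="\t")
            v["centroids"].to_csv(out / f"centroids_{factor}.tsv", sep="\t")

    if config.enable_enrichment:
        dag, annotation = synth.simulate_ontology(
            min(sim.n_transcripts, 2000), 50, seed=config.seed + 1
        )
        enr = enrichment_stage(det_sets, dag, annotation)
        report["enrichment"] = {
            f: {d: int((tab["p_value"] <= 0.05).sum()) for d, tab in by_dir.items()}
            for f, by_dir in enr.items()
        }
        for factor, by_dir in enr.items():
            for d, tab in by_dir.items():
                tab.to_csv(out / f"enrichment_{factor}_{d}.tsv", sep="\t", index=False)

    if config.enable_qpcr:
        ct = synth.simulate_qpcr(sim)
        rel = qpcr_corr.relative_expression_table(ct)
        rel.to_csv(out / "qpcr_relative_expression.tsv", sep="\t", index=False)
        assays = {}
        conds = ct["condition"].unique()
        if len(conds) == 2:
            for gene, sub in rel.merge(
                ct[["sample_id", "condition"]].drop_duplicates(), on="sample_id"
            ).groupby("gene"):
                a = sub.loc[sub["condition"] == conds[0], "relative_expression"].to_numpy()
                b = sub.loc[sub["condition"] == conds[1], "relative_expression"].to_numpy()
                if len(a) >= 3 and len(b) >= 3:
                    assays[gene] = (a, b)
        if assays:
            qtab = qpcr_corr.batch_group_tests(assays)
            qtab.to_csv(out / "qpcr_tests.tsv", sep="\t")
            report["qpcr"] = {"n_assays": len(qtab), "n_significant": int((qtab["padj"] <= 0.05).sum())}
        report["correlation"] = correlation_stage(
            t_stage["collapsed"], t_stage["size_factors"], p_stage["samples"]
        )

    # truth-ledger diagnostics
    report["truth"] = {
        "transcripts": _truth_metrics(det_sets, t_truth, t_stage["collapsed"].index),
        "proteins": _truth_metrics(dep_sets, p_truth, p_stage["samples"].index),
    }

    # artifacts
    counts.to_csv(out / "counts_raw.tsv", sep="\t")
    t_stage["collapsed"].to_csv(out / "counts_collapsed.tsv", sep="\t")
    t_truth.to_csv(out / "truth_transcripts.tsv", sep="\t", index=False)
    p_truth.to_csv(out / "truth_proteins.tsv", sep="\t", index=False)
    p_stage["samples"].to_csv(out / "protein_matrix_normalized.tsv", sep="\t")
    for name, tab in t_stage["consensus"].items():
        tab.to_csv(out / f"consensus_transcripts_{name}.tsv", sep="\t")
    for name, tab in p_stage["consensus"].items():
        tab.to_csv(out / f"consensus_proteins_{name}.tsv", sep="\t")
    cf = {
        scope: {
            k: (float(v) if np.isscalar(v) else "per_protein")
            for k, v in cfs.factors.items()
        }
        for scope, cfs in p_stage["conversion_factors"].items()
    }
    (out / "conversion_factors.json").write_text(json.dumps(cf, indent=2))

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_json_default))
    manifest = {
        "seed": config.seed,
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report["manifest"] = manifest
    return report


def _truth_metrics(called: dict[str, set], ledger: pd.DataFrame, universe) -> dict:
    universe = set(universe)
    out = {}
    for factor in FACTORS:
        true_ids = set(ledger.loc[ledger["factor"] == factor, "feature_id"]) & universe
        calls = called.get(factor, set())
        tp = len(calls & true_ids)
        out[factor] = {
            "n_true": len(true_ids),
            "n_called": len(calls),
            "recall": tp / len(true_ids) if true_ids else float("nan"),
            "fdp": (len(calls) - tp) / len(calls) if calls else 0.0,
        }
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
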