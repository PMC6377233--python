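"""Synthetic count and TMT-reporter datasets with a known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial transcript counts over the sampled condition grid
(3 maturation stages x 2 sexes x 2 circalunar phases, 3 biological replicates),
technical sequencing lanes as multinomial thinnings of each biological
replicate's counts, and peptide-level isobaric reporter intensities organised
in multiplex sets (5-plex at new moon, free-running full-moon sets carrying a
spiked control channel re-labelled from a new-moon sample).  Every truly
regulated feature is recorded in a truth ledger so that recall, false-discovery
proportion and effect-size recovery can be measured exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .design import (
    SPIKE_SOURCE_BR,
    SPIKE_SOURCE_CONDITION,
    StudyDesign,
    condition_name,
    make_study_design,
    make_tmt_design,
)

FACTORS = ("maturation", "sex", "lunar")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulation parameters; the defaults mirror the study design.

    Fractions of regulated features default to the observed regulated
    fractions (transcripts: maturation 16.52%, sex 1.23%, lunar 0.12%;
    proteins: 65.13%, 1.60%, 24.53%).  ``seed`` fully determines all output;
    per-stream child seeds keep the count, TMT, ontology and qPCR generators
    independent of each other.
    """

    n_transcripts: int = 52_059
    n_proteins: int = 2_290
    de_fraction_maturation: float = 0.1652
    de_fraction_sex: float = 0.0123
    de_fraction_lunar: float = 0.0012
    protein_de_fraction_maturation: float = 0.6513
    protein_de_fraction_sex: float = 0.0160
    protein_de_fraction_lunar: float = 0.2453
    effect_log2fc: float = 2.0
    protein_effect_log2fc: float = 1.0
    nb_dispersion: float = 0.05
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    tmt_noise_sd: float = 0.2
    detection_floor: float = 100.0
    channel_loading_cv: float = 0.10
    run_effect_sd: float = 0.05
    br_noise_sd: float = 0.10
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    abundance_log_mean: float = 7.6
    abundance_log_sd: float = 1.2
    peptides_per_protein_mean: float = 4.0
    unique_peptide_prob: float = 0.9
    n_br: int = 3
    n_lanes: int = 2
    n_tr_ms: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "de_fraction_maturation",
            "de_fraction_sex",
            "de_fraction_lunar",
            "protein_de_fraction_maturation",
            "protein_de_fraction_sex",
            "protein_de_fraction_lunar",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        t_sum = self.de_fraction_maturation + self.de_fraction_sex + self.de_fraction_lunar
        p_sum = (
            self.protein_de_fraction_maturation
            + self.protein_de_fraction_sex
            + self.protein_de_fraction_lunar
        )
        if t_sum > 1.0 + 1e-12 or p_sum > 1.0 + 1e-12:
            raise ConfigurationError("regulated fractions sum to > 1")
        if self.effect_log2fc <= 0 or self.protein_effect_log2fc <= 0:
            raise ConfigurationError("effect log2FCs must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("invalid library_size_range")

    def child_rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stream generator derived from the root seed."""
        streams = ("counts", "tmt", "ontology", "qpcr")
        if stream not in streams:
            raise ValueError(f"unknown stream {stream!r}")
        children = np.random.SeedSequence(self.seed).spawn(len(streams))
        return np.random.default_rng(children[streams.index(stream)])

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _assign_truth(
    rng: np.random.Generator,
    feature_ids: np.ndarray,
    fractions: dict[str, float],
    log2fc: float,
) -> pd.DataFrame:
    """Draw disjoint sets of truly regulated features per factor."""
    n = len(feature_ids)
    order = rng.permutation(n)
    rows = []
    start = 0
    for factor in FACTORS:
        k = int(round(fractions[factor] * n))
        chosen = order[start : start + k]
        start += k
        directions = rng.choice(["up", "down"], size=k)
        for idx, d in zip(chosen, directions):
            rows.append(
                {
                    "feature_id": feature_ids[idx],
                    "factor": factor,
                    "direction": d,
                    "log2fc": log2fc if d == "up" else -log2fc,
                }
            )
    ledger = pd.DataFrame(rows, columns=["feature_id", "factor", "direction", "log2fc"])
    return ledger.sort_values(["factor", "feature_id"]).reset_index(drop=True)


def _effect_matrix(
    ledger: pd.DataFrame, feature_ids: np.ndarray, bio: pd.DataFrame
) -> np.ndarray:
    """Per-(feature, biological sample) multiplicative effect.

    Maturation effects follow a monotone stage gradient (log2 multipliers
    0, 1, 1.5 x the feature's log2FC for IM, PM, M, so consecutive stages
    differ but the full span stays in a realistic range), sex effects apply
    to male samples of sexed stages, lunar effects to FRFM samples.
    """
    index = {f: i for i, f in enumerate(feature_ids)}
    stage_idx = bio["stage"].map({"IM": 0.0, "PM": 1.0, "M": 1.5}).to_numpy()
    is_male = (bio["sex"] == "M").to_numpy(dtype=float)
    is_frfm = (bio["lunar"] == "FRFM").to_numpy(dtype=float)
    log2_eff = np.zeros((len(feature_ids), len(bio)))
    for row in ledger.itertuples(index=False):
        i = index[row.feature_id]
        if row.factor == "maturation":
            log2_eff[i] += row.log2fc * stage_idx
        elif row.factor == "sex":
            log2_eff[i] += row.log2fc * is_male
        else:
            log2_eff[i] += row.log2fc * is_frfm
    return np.exp2(log2_eff)


def simulate_counts(
    config: SimConfig, design: StudyDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a lane-level count matrix and its truth ledger.

    Counts for each biological replicate are NB(mean = baseline x group effect
    x library-size factor, dispersion = ``nb_dispersion``); lanes are
    multinomial splits of the replicate's counts so that collapsing technical
    replicates by sum recovers the replicate draw exactly.

    Returns ``(counts, ledger)`` where ``counts`` is a features x lanes
    DataFrame (lane columns named ``<sample_id>:L<tr>``).
    """
    if design is None:
        design = make_study_design(n_br=config.n_br, n_tr=config.n_lanes)
    bio = design.biological_samples
    grouped = bio.groupby("condition")["br"].nunique()
    if (grouped < 2).any():
        raise ConfigurationError("design needs >=2 biological replicates per condition")

    rng = config.child_rng("counts")
    n = config.n_transcripts
    width = len(str(max(n, 1)))
    feature_ids = np.array([f"TS_{i:0{width}d}" for i in range(1, n + 1)])

    ledger = _assign_truth(
        rng,
        feature_ids,
        {
            "maturation": config.de_fraction_maturation,
            "sex": config.de_fraction_sex,
            "lunar": config.de_fraction_lunar,
        },
        config.effect_log2fc,
    )

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    effects = _effect_matrix(ledger, feature_ids, bio)
    rel = baseline[:, None] * effects
    lo, hi = config.library_size_range
    lib_sizes = rng.integers(lo, hi + 1, size=len(bio)).astype(float)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib_sizes[None, :]

    if config.nb_dispersion == 0:
        br_counts = rng.poisson(mu)
    else:
        r = 1.0 / config.nb_dispersion
        p = r / (r + mu)
        br_counts = rng.negative_binomial(r, p)

    lanes = design.lane_map()
    lane_cols: dict[str, np.ndarray] = {}
    for j, sid in enumerate(bio["sample_id"]):
        sample_lanes = lanes.loc[lanes["sample_id"] == sid, "lane_id"].tolist()
        k = len(sample_lanes)
        if k == 1:
            lane_cols[sample_lanes[0]] = br_counts[:, j]
            continue
        props = rng.dirichlet(np.full(k, 20.0))
        split = rng.multinomial(br_counts[:, j], props)
        for li, lane in enumerate(sample_lanes):
            lane_cols[lane] = split[:, li]

    counts = pd.DataFrame(lane_cols, index=pd.Index(feature_ids, name="feature_id"))
    return counts, ledger


def simulate_tmt(
    config: SimConfig, design: StudyDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long peptide-level reporter-intensity table and truth ledger.

    intensity = protein abundance x peptide efficiency x channel loading x run
    effect x lognormal(0, tmt_noise_sd).  Observations below
    ``detection_floor`` are recorded as missing (row dropped).  The spike
    control channel of each FRFM set replays the referenced NM sample's
    protein abundances.
    """
    if design is None:
        design = make_tmt_design(n_br=config.n_br, n_tr=config.n_tr_ms)
    df = design.samples
    set_sizes = df.groupby("set_id")["channel_label"].nunique()
    if (set_sizes < 4).any() or (set_sizes > 6).any():
        raise ConfigurationError("multiplex sets must have 4-6 channels")
    for s in df["set_id"].unique():
        sub = df[df["set_id"] == s]
        if (sub["lunar"] == "FRFM").any() and not sub["is_spike_control"].any():
            raise ConfigurationError(f"FRFM set {s} lacks a spike-control channel")

    rng = config.child_rng("tmt")
    n = config.n_proteins
    width = len(str(max(n, 1)))
    protein_ids = np.array([f"PROT_{i:0{width}d}" for i in range(1, n + 1)])

    ledger = _assign_truth(
        rng,
        protein_ids,
        {
            "maturation": config.protein_de_fraction_maturation,
            "sex": config.protein_de_fraction_sex,
            "lunar": config.protein_de_fraction_lunar,
        },
        config.protein_effect_log2fc,
    )

    # biological abundance per (protein, biological sample); the spike channel
    # re-uses the abundance of its source sample, so compute per unique
    # (condition, br) first.
    bio = (
        df.loc[~df["is_spike_control"], ["condition", "stage", "sex", "lunar", "br"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    baseline = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, size=n)
    effects = _effect_matrix(ledger, protein_ids, bio)
    br_noise = (
        rng.lognormal(0.0, config.br_noise_sd, size=effects.shape)
        if config.br_noise_sd > 0
        else 1.0
    )
    abundance = baseline[:, None] * effects * br_noise
    bio_key = {(r.condition, r.br): j for j, r in enumerate(bio.itertuples(index=False))}

    # peptide structure per protein
    n_pep = 1 + rng.poisson(max(config.peptides_per_protein_mean - 1.0, 0.0), size=n)
    pep_rows = []
    for i, pid in enumerate(protein_ids):
        for p in range(n_pep[i]):
            pep_rows.append(
                (
                    pid,
                    f"{pid}_pep{p + 1}",
                    bool(rng.random() < config.unique_peptide_prob),
                    float(rng.lognormal(0.0, 0.5)),
                )
            )
    peptides = pd.DataFrame(pep_rows, columns=["protein_id", "peptide_id", "is_unique", "efficiency"])
    prot_index = {p: i for i, p in enumerate(protein_ids)}
    pep_protein_idx = peptides["protein_id"].map(prot_index).to_numpy()
    pep_eff = peptides["efficiency"].to_numpy()

    channels = df[
        ["set_id", "channel_label", "condition", "br", "sample_id", "is_spike_control"]
    ].drop_duplicates(["set_id", "channel_label"])
    loading = {
        (r.set_id, r.channel_label): (
            rng.lognormal(0.0, config.channel_loading_cv) if config.channel_loading_cv > 0 else 1.0
        )
        for r in channels.itertuples(index=False)
    }
    run_effect = {
        (s, tr): (rng.lognormal(0.0, config.run_effect_sd) if config.run_effect_sd > 0 else 1.0)
        for s in df["set_id"].unique()
        for tr in sorted(df["tr"].unique())
    }

    out = []
    n_peptides = len(peptides)
    for ch in channels.itertuples(index=False):
        src = (SPIKE_SOURCE_CONDITION, SPIKE_SOURCE_BR) if ch.is_spike_control else (ch.condition, ch.br)
        ab = abundance[pep_protein_idx, bio_key[src]]
        load = loading[(ch.set_id, ch.channel_label)]
        for tr in sorted(df.loc[df["set_id"] == ch.set_id, "tr"].unique()):
            noise = (
                rng.lognormal(0.0, config.tmt_noise_sd, size=n_peptides)
                if config.tmt_noise_sd > 0
                else 1.0
            )
            intensity = ab * pep_eff * load * run_effect[(ch.set_id, tr)] * noise
            keep = intensity >= config.detection_floor
            if not keep.any():
                continue
            chunk = peptides.loc[keep, ["protein_id", "peptide_id", "is_unique"]].copy()
            chunk["set_id"] = ch.set_id
            chunk["channel_label"] = ch.channel_label
            chunk["condition"] = ch.condition
            chunk["br"] = ch.br
            chunk["tr"] = tr
            chunk["is_spike_control"] = ch.is_spike_control
            chunk["intensity"] = intensity[keep]
            out.append(chunk)
    table = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=[
            "protein_id",
            "peptide_id",
            "is_unique",
            "set_id",
            "channel_label",
            "condition",
            "br",
            "tr",
            "is_spike_control",
            "intensity",
        ]
    )
    return table, ledger


def simulate_ontology(
    n_genes: int, n_terms: int, seed: int, terms_per_gene: tuple[int, int] = (1, 3)
) -> tuple[nx.DiGraph, pd.DataFrame]:
    """A random single-rooted acyclic term hierarchy plus gene annotations.

    Edges point parent -> child.  Every annotated gene maps to at least one
    term; annotations land on non-root terms where possible.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_terms))
    terms = [f"GO_{i:0{width}d}" for i in range(n_terms)]
    dag = nx.DiGraph()
    dag.add_nodes_from(terms)
    for i in range(1, n_terms):
        n_parents = 1 if i == 1 else int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            dag.add_edge(terms[p], terms[i])

    gwidth = len(str(max(n_genes, 1)))
    genes = [f"G_{i:0{gwidth}d}" for i in range(1, n_genes + 1)]
    targets = terms[1:] if n_terms > 1 else terms
    lo, hi = terms_per_gene
    rows = []
    for g in genes:
        k = int(rng.integers(lo, hi + 1))
        for t in rng.choice(len(targets), size=min(k, len(targets)), replace=False):
            rows.append((g, targets[t]))
    annotation = pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates()
    return dag, annotation.reset_index(drop=True)


def simulate_qpcr(
    config: SimConfig,
    genes: tuple[str, ...] = ("fabp", "qpeptin", "dmrt", "sten"),
    conditions: tuple[str, ...] = ("PM_NM_F", "M_NM_F"),
    n_br: int = 5,
    effect_dct: float = 2.0,
) -> pd.DataFrame:
    """Ct tables for target genes plus the two reference genes (cdc5, sams).

    Targets shift by ``effect_dct`` cycles between the two conditions; every
    reaction is run in technical duplicate.
    """
    rng = config.child_rng("qpcr")
    rows = []
    for cond_i, cond in enumerate(conditions):
        for br in range(1, n_br + 1):
            sample = f"{cond}.q{br}"
            base = {"cdc5": 20.0, "sams": 21.0}
            for gene in genes:
                true_ct = 24.0 + (effect_dct * cond_i if gene in genes[: len(genes) // 2] else 0.0)
                true_ct += rng.normal(0.0, 0.3)
                for rep in (1, 2):
                    rows.append((sample, cond, gene, true_ct + rng.normal(0.0, 0.1), rep))
            for ref, ct0 in base.items():
                true_ct = ct0 + rng.normal(0.0, 0.2)
                for rep in (1, 2):
                    rows.append((sample, cond, ref, true_ct + rng.normal(0.0, 0.1), rep))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct", "replicate"])


def write_dataset(out_dir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate and serialise a full synthetic dataset to TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = make_study_design(n_br=config.n_br, n_tr=config.n_lanes)
    tmt_design = make_tmt_design(n_br=config.n_br, n_tr=config.n_tr_ms)
    counts, t_ledger = simulate_counts(config, design)
    peptides, p_ledger = simulate_tmt(config, tmt_design)
    dag, annotation = simulate_ontology(
        min(config.n_transcripts, 2000), 50, seed=int(config.seed) + 1
    )
    qpcr = simulate_qpcr(config)

    paths = {}
    paths["counts"] = out / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t")
    paths["design"] = out / "design.tsv"
    design.samples.to_csv(paths["design"], sep="\t", index=False)
    paths["tmt_design"] = out / "tmt_design.tsv"
    tmt_design.samples.to_csv(paths["tmt_design"], sep="\t", index=False)
    paths["peptides"] = out / "peptides.tsv"
    peptides.to_csv(paths["peptides"], sep="\t", index=False)
    paths["truth_transcripts"] = out / "truth_transcripts.tsv"
    t_ledger.to_csv(paths["truth_transcripts"], sep="\t", index=False)
    paths["truth_proteins"] = out / "truth_proteins.tsv"
    p_ledger.to_csv(paths["truth_proteins"], sep="\t", index=False)
    paths["ontology"] = out / "ontology.tsv"
    with open(paths["ontology"], "w") as fh:
        fh.write("child\tparent\n")
        for parent, child in dag.edges:
            fh.write(f"{child}\t{parent}\n")
    paths["annotation"] = out / "annotation.tsv"
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["qpcr"] = out / "ct.tsv"
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    return paths
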