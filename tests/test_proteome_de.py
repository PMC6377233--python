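"""Normalization cascade contracts and protein-level DE tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lunaromics import design as dz
from lunaromics import proteome_de as pde
from lunaromics import synth


def _peptide_table(rows):
    cols = ["protein_id", "peptide_id", "is_unique", "set_id", "channel_label",
            "condition", "br", "tr", "is_spike_control", "intensity"]
    return pd.DataFrame(rows, columns=cols)


# --- aggregation -------------------------------------------------------------

def test_aggregate_mean_and_missing():
    rows = [
        ("P1", "p1", True, "S1", "C1", "IM_NM", 1, 1, False, 10.0),
        ("P1", "p1", True, "S1", "C1", "IM_NM", 1, 2, False, 20.0),
        ("P1", "p2", True, "S1", "C1", "IM_NM", 1, 1, False, 30.0),
        ("P2", "q1", False, "S1", "C2", "PM_NM_F", 1, 1, False, 5.0),
    ]
    m = pde.aggregate_peptides(_peptide_table(rows))
    assert m.values.loc["P1", "S1|C1"] == pytest.approx(20.0)
    assert np.isnan(m.values.loc["P1", "S1|C2"])  # no observation -> missing
    assert m.unique_peptides["P1"] == 2
    assert m.unique_peptides["P2"] == 0
    assert m.stage == "raw_mean"


def test_aggregate_noise_free_equals_abundance_times_mean_efficiency(tmt_design):
    cfg = synth.SimConfig(
        n_transcripts=10, n_proteins=25, tmt_noise_sd=0.0, channel_loading_cv=0.0,
        run_effect_sd=0.0, br_noise_sd=0.0, detection_floor=0.0, seed=21,
    )
    pep, _ = synth.simulate_tmt(cfg, tmt_design)
    m = pde.aggregate_peptides(pep)
    # within one channel, aggregated value / mean per-peptide intensity == 1
    one = pep[(pep["set_id"] == "NM_BR1") & (pep["channel_label"] == "TMT-126")]
    per_pep = one.groupby(["protein_id", "peptide_id"])["intensity"].mean()
    expected = per_pep.groupby("protein_id").mean()
    got = m.values["NM_BR1|TMT-126"].dropna()
    np.testing.assert_allclose(got[expected.index], expected, rtol=1e-12)


# --- channel sum normalization -----------------------------------------------

def _tiny_matrix(values, channels, set_id="S1", conditions=None, spikes=None):
    cols = [f"{set_id}|{c}" for c in channels]
    vals = pd.DataFrame(values, columns=cols)
    vals.index = [f"P{i+1}" for i in range(len(vals))]
    meta = pd.DataFrame(
        {
            "set_id": set_id,
            "channel_label": channels,
            "condition": conditions or ["IM_NM"] * len(channels),
            "br": 1,
            "is_spike_control": spikes or [False] * len(channels),
        },
        index=pd.Index(cols, name="column"),
    )
    uniq = pd.Series(2, index=vals.index)
    return pde.ProteinMatrix(values=vals, columns=meta, unique_peptides=uniq)


def test_channel_sum_hand_example():
    m = _tiny_matrix([[10.0, 20.0], [30.0, 60.0]], ["C1", "C2"])
    out = pde.channel_sum_normalize(m)
    # sums (40, 80) -> factors (1.5, 0.75); both sums become 60
    np.testing.assert_allclose(out.values.sum(), [60.0, 60.0])
    assert out.stage == "channel_norm"


def test_channel_sum_identity_and_single_channel():
    m = _tiny_matrix([[10.0, 10.0], [30.0, 30.0]], ["C1", "C2"])
    out = pde.channel_sum_normalize(m)
    pd.testing.assert_frame_equal(out.values, m.values)
    single = _tiny_matrix([[10.0], [30.0]], ["C1"])
    out = pde.channel_sum_normalize(single)
    pd.testing.assert_frame_equal(out.values, single.values)


def test_channel_sum_empty_channel_errors():
    m = _tiny_matrix([[10.0, np.nan], [30.0, np.nan]], ["C1", "C2"])
    with pytest.raises(ValueError, match="empty channel"):
        pde.channel_sum_normalize(m)


def test_channel_sums_equal_over_shared_proteins(small_tmt):
    pep, _ = small_tmt
    m = pde.channel_sum_normalize(pde.aggregate_peptides(pep))
    for set_id, meta in m.columns.groupby("set_id"):
        shared = m.values[list(meta.index)].dropna()
        sums = shared.sum()
        np.testing.assert_allclose(sums, sums.iloc[0], rtol=1e-9)


# --- quantifiable filter -----------------------------------------------------

def _detection_rows(protein, cond, br, n_tr, unique=True):
    return [
        (protein, f"{protein}_pep{u}", unique, "S", "C", cond, br, tr, False, 100.0)
        for tr in range(1, n_tr + 1)
        for u in (1, 2)
    ]


def test_filter_quantifiable_rules():
    rows = []
    # P1: 2 unique peptides, BR TR-counts (5, 4, 1) in the only group -> kept
    for br, ntr in [(1, 5), (2, 4), (3, 1)]:
        rows += _detection_rows("P1", "IM_NM", br, ntr)
    # P2: full detection but unique flag False -> dropped
    for br in (1, 2, 3):
        rows += _detection_rows("P2", "IM_NM", br, 5, unique=False)
    # P3: detected in 1 BR only -> dropped
    rows += _detection_rows("P3", "IM_NM", 1, 5)
    det = _peptide_table(rows)
    vals = pd.DataFrame(
        {"S|C": [1.0, 1.0, 1.0]}, index=pd.Index(["P1", "P2", "P3"])
    )
    meta = pd.DataFrame(
        {"set_id": ["S"], "channel_label": ["C"], "condition": ["IM_NM"], "br": [1],
         "is_spike_control": [False]},
        index=pd.Index(["S|C"], name="column"),
    )
    uniq = det[det["is_unique"]].groupby("protein_id")["peptide_id"].nunique()
    m = pde.ProteinMatrix(
        values=vals, columns=meta,
        unique_peptides=uniq.reindex(vals.index, fill_value=0), stage="channel_norm",
    )
    out = pde.filter_quantifiable(m, det)
    assert list(out.values.index) == ["P1"]


# --- median normalization ----------------------------------------------------

def test_channel_median_examples():
    m = _tiny_matrix([[2.0], [4.0], [6.0]], ["C1"])
    m.stage = "channel_norm"
    out = pde.channel_median_normalize(m)
    np.testing.assert_allclose(out.values["S1|C1"], [0.5, 1.0, 1.5])
    const = _tiny_matrix([[7.0], [7.0]], ["C1"])
    const.stage = "channel_norm"
    np.testing.assert_allclose(pde.channel_median_normalize(const).values["S1|C1"], 1.0)


def test_channel_median_ignores_missing():
    m = _tiny_matrix([[2.0], [np.nan], [6.0], [10.0]], ["C1"])
    m.stage = "channel_norm"
    out = pde.channel_median_normalize(m)
    present = np.array([2.0, 6.0, 10.0])
    np.testing.assert_allclose(
        out.values["S1|C1"].dropna(), present / np.median(present)
    )
    # column median over present values is exactly 1 afterwards
    assert out.values["S1|C1"].median(skipna=True) == pytest.approx(1.0)


# --- cascade order and cross-set calibration ---------------------------------

def test_cascade_order_enforced(small_tmt):
    pep, _ = small_tmt
    raw = pde.aggregate_peptides(pep)
    with pytest.raises(pde.NormalizationOrderError):
        pde.channel_median_normalize(raw)  # requires channel_norm first
    with pytest.raises(pde.NormalizationOrderError):
        pde.inter_replicate_normalize(raw)
    with pytest.raises(pde.NormalizationOrderError):
        pde.cross_set_spike_normalize(raw)


def test_inter_replicate_cf_formula(small_tmt):
    pep, _ = small_tmt
    m = pde.channel_median_normalize(
        pde.filter_quantifiable(pde.channel_sum_normalize(pde.aggregate_peptides(pep)), pep)
    )
    out, cf = pde.inter_replicate_normalize(m)
    assert cf.factors["NM_BR1"] == 1.0
    assert cf.factors["FRFM_BR3"] == 1.0
    # post-hoc: all BR-set medians within an experiment equal the reference's
    meds = {}
    for set_id, meta in out.columns.groupby("set_id"):
        meds[set_id] = np.nanmedian(out.values[list(meta.index)].to_numpy())
    assert meds["NM_BR2"] == pytest.approx(meds["NM_BR1"], rel=1e-9)
    assert meds["NM_BR3"] == pytest.approx(meds["NM_BR1"], rel=1e-9)
    assert meds["FRFM_BR1"] == pytest.approx(meds["FRFM_BR3"], rel=1e-9)
    # the formula itself: CF = median(ref set) / median(that set), pre-scaling
    pre = {}
    for set_id, meta in m.columns.groupby("set_id"):
        pre[set_id] = np.nanmedian(m.values[list(meta.index)].to_numpy())
    assert cf.factors["NM_BR2"] == pytest.approx(pre["NM_BR1"] / pre["NM_BR2"], rel=1e-12)


def test_cross_set_spike_example_doubling():
    # spike value 100 in the reference set, 50 in the FRFM set -> values x2
    channels = ["C1", "C2"]
    ref = _tiny_matrix(
        [[100.0, 40.0], [10.0, 4.0]], channels, set_id="NM_BR1",
        conditions=["PM_NM_F", "IM_NM"],
    )
    frfm_cols = [f"FRFM_BR1|{c}" for c in channels]
    frfm_vals = pd.DataFrame([[50.0, 30.0], [5.0, 3.0]], columns=frfm_cols, index=["P1", "P2"])
    frfm_meta = pd.DataFrame(
        {"set_id": "FRFM_BR1", "channel_label": channels,
         "condition": ["PM_NM_F", "IM_FRFM"], "br": 1,
         "is_spike_control": [True, False]},
        index=pd.Index(frfm_cols, name="column"),
    )
    m = pde.ProteinMatrix(
        values=pd.concat([ref.values, frfm_vals], axis=1),
        columns=pd.concat([ref.columns, frfm_meta]),
        unique_peptides=ref.unique_peptides,
        stage="interrep_norm",
    )
    out, cf = pde.cross_set_spike_normalize(m)
    # P1: CF = 100/50 = 2; P2: CF = 10/5 = 2
    np.testing.assert_allclose(out.values["FRFM_BR1|C2"], [60.0, 6.0])
    # reference set unchanged
    np.testing.assert_allclose(out.values["NM_BR1|C1"], [100.0, 10.0])
    # equal spike values -> identity
    m2 = m.copy()
    m2.values.loc[:, "FRFM_BR1|C1"] = m2.values["NM_BR1|C1"]
    out2, _ = pde.cross_set_spike_normalize(m2)
    np.testing.assert_allclose(out2.values["FRFM_BR1|C2"], m2.values["FRFM_BR1|C2"])


def test_cross_set_noise_free_replay_recovers_sample(tmt_design):
    """After the full cascade on noise-free data, the spike-replayed sample's
    protein profile is identical across sets."""
    cfg = synth.SimConfig(
        n_transcripts=10, n_proteins=40, tmt_noise_sd=0.0, channel_loading_cv=0.0,
        run_effect_sd=0.0, br_noise_sd=0.0, detection_floor=0.0, seed=31,
    )
    pep, _ = synth.simulate_tmt(cfg, tmt_design)
    m, _ = pde.run_cascade(pep)
    spike_cols = m.columns.index[m.columns["is_spike_control"]]
    src_col = m.columns.index[
        (~m.columns["is_spike_control"])
        & (m.columns["condition"] == dz.SPIKE_SOURCE_CONDITION)
        & (m.columns["br"] == dz.SPIKE_SOURCE_BR)
    ][0]
    for sc in spike_cols:
        np.testing.assert_allclose(m.values[sc], m.values[src_col], rtol=1e-9)


def test_cascade_scale_equivariance(small_tmt):
    """Multiplying all raw intensities of one set by a constant leaves the
    post-cascade values unchanged."""
    pep, _ = small_tmt
    m1, _ = pde.run_cascade(pep)
    scaled = pep.copy()
    scaled.loc[scaled["set_id"] == "NM_BR2", "intensity"] *= 37.0
    m2, _ = pde.run_cascade(scaled)
    pd.testing.assert_frame_equal(m1.values, m2.values)


def test_cascade_preserves_missingness(small_tmt):
    pep, _ = small_tmt
    raw = pde.filter_quantifiable(pde.channel_sum_normalize(pde.aggregate_peptides(pep)), pep)
    full, _ = pde.run_cascade(pep)
    # per-protein spike CFs can only invalidate, never impute
    assert (raw.values.isna() <= full.values.isna()).all().all()


# --- moderated t -------------------------------------------------------------

def test_moderated_t_hand_example_no_shrinkage():
    """d0 = 0 reduces to the ordinary pooled-variance t: A=(1,2,3), B=(3,4,5)
    on the log2 scale gives t = -2.449 with 4 df."""
    mat = pd.DataFrame(
        {f"A.{i}": [2.0 ** v] for i, v in enumerate((1, 2, 3))}
        | {f"B.{i}": [2.0 ** v] for i, v in enumerate((3, 4, 5))},
        index=["P1"],
    )
    cmp_ = dz.Comparison(name="x", group_a=["A.0", "A.1", "A.2"],
                         group_b=["B.0", "B.1", "B.2"], factor="sex")
    res = pde.moderated_t_test(mat, cmp_, d0_override=0.0)
    assert res["t"].iloc[0] == pytest.approx(-2.449, abs=1e-3)
    fit = res.attrs["ebayes"]
    assert fit.df_total[0] == pytest.approx(4.0)


def test_moderated_t_equals_ordinary_t_when_variances_identical(rng):
    """If every feature has the same sample variance the prior collapses on
    it and moderation changes nothing."""
    a = rng.normal(0, 1, (40, 4))
    a = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, ddof=1, keepdims=True)
    b = rng.normal(0, 1, (40, 4))
    b = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, ddof=1, keepdims=True) + 0.3
    mat = pd.DataFrame(
        2.0 ** np.concatenate([a, b], axis=1),
        columns=[f"A.{i}" for i in range(4)] + [f"B.{i}" for i in range(4)],
    )
    cmp_ = dz.Comparison(name="x", group_a=[f"A.{i}" for i in range(4)],
                         group_b=[f"B.{i}" for i in range(4)], factor="sex")
    res = pde.moderated_t_test(mat, cmp_)
    ordinary = stats.ttest_ind(a, b, axis=1).statistic
    np.testing.assert_allclose(res["t"], ordinary, rtol=1e-6)


def test_moderated_t_min_present_gives_na():
    mat = pd.DataFrame(
        {"A.0": [1.0], "A.1": [np.nan], "A.2": [np.nan], "B.0": [2.0], "B.1": [2.0]},
    )
    cmp_ = dz.Comparison(name="x", group_a=["A.0", "A.1", "A.2"],
                         group_b=["B.0", "B.1"], factor="sex")
    res = pde.moderated_t_test(mat, cmp_)
    assert np.isnan(res["p"].iloc[0])


# --- ROTS --------------------------------------------------------------------

def _lognormal_groups(rng, n_feat, n, sd=0.3, planted=None, fold=8.0):
    base = rng.lognormal(5, 1, n_feat)
    a = base[:, None] * rng.lognormal(0, sd, (n_feat, n))
    b = base[:, None] * rng.lognormal(0, sd, (n_feat, n))
    if planted is not None:
        b[planted] *= fold
    cols_a = [f"A.{i}" for i in range(n)]
    cols_b = [f"B.{i}" for i in range(n)]
    mat = pd.DataFrame(np.concatenate([a, b], axis=1), columns=cols_a + cols_b)
    mat.index = [f"P{i}" for i in range(n_feat)]
    cmp_ = dz.Comparison(name="x", group_a=cols_a, group_b=cols_b, factor="lunar")
    return mat, cmp_


def test_rots_statistic_limits(rng):
    mat, cmp_ = _lognormal_groups(rng, 30, 3)
    la = np.log2(mat[cmp_.group_a].to_numpy())
    lb = np.log2(mat[cmp_.group_b].to_numpy())
    d = pde._rots_stats(la, lb, np.array([1.0]))
    # the scale-free member (last column) is exactly |mean difference|
    np.testing.assert_allclose(
        d[:, -1], np.abs(la.mean(axis=1) - lb.mean(axis=1)), rtol=1e-12
    )
    # a zero-difference feature scores 0 for every member
    mat2 = mat.copy()
    mat2.iloc[0] = 1.0
    la2 = np.log2(mat2[cmp_.group_a].to_numpy())
    lb2 = np.log2(mat2[cmp_.group_b].to_numpy())
    d2 = pde._rots_stats(la2, lb2, np.array([0.0, 1.0]))
    np.testing.assert_allclose(d2[0], 0.0, atol=1e-12)


def test_rots_requires_two_bootstrap_rounds():
    with pytest.raises(ValueError):
        pde.RotsParams(n_bootstrap=1)


def test_rots_ranks_planted_features_top(rng):
    """Two 8-fold planted proteins among 500 nulls must rank in the top 5."""
    mat, cmp_ = _lognormal_groups(rng, 500, 3, planted=[10, 20], fold=8.0)
    res = pde.rots_test(
        mat, cmp_, pde.RotsParams(n_bootstrap=100, seed=7), n_permutations=100
    )
    top5 = set(res.sort_values("d", ascending=False).head(5).index)
    assert {"P10", "P20"} <= top5


def test_rots_and_moderated_t_agree_on_strong_effects(rng):
    """Top-20 membership of the two protein tests overlaps >= 80% when 20
    planted 8-fold effects dominate 500 features."""
    planted = list(range(0, 200, 10))
    mat, cmp_ = _lognormal_groups(rng, 500, 3, planted=planted, fold=8.0)
    rots = pde.rots_test(mat, cmp_, pde.RotsParams(n_bootstrap=60, seed=3), n_permutations=60)
    modt = pde.moderated_t_test(mat, cmp_)
    top_rots = set(rots.sort_values("d", ascending=False).head(20).index)
    top_modt = set(modt.sort_values("p").head(20).index)
    assert len(top_rots & top_modt) >= 16
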