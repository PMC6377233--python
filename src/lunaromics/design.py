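"""Study design: samples, factors and pairwise comparisons.

The sampled design crosses three maturation stages (IM immature, PM premature,
M mature) with sex (F/M; immature animals are unsexed, ``U``) and two circalunar
phases (NM new moon, FRFM free-running full moon).  Mature animals were sampled
only at NM, so the realised conditions are::

    IM_NM, IM_FRFM, PM_NM_F, PM_NM_M, PM_FRFM_F, PM_FRFM_M, M_NM_F, M_NM_M

Each condition has three biological replicates (BR, pools of heads); technical
replicates (TR) are sequencing lanes (counts) or repeated MS runs (TMT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

STAGES = ("IM", "PM", "M")
SEXES = ("F", "M", "U")
LUNAR_PHASES = ("NM", "FRFM")

#: Conditions actually sampled in the study design.
CONDITIONS = (
    "IM_NM",
    "IM_FRFM",
    "PM_NM_F",
    "PM_NM_M",
    "PM_FRFM_F",
    "PM_FRFM_M",
    "M_NM_F",
    "M_NM_M",
)


def condition_name(stage: str, lunar: str, sex: str) -> str:
    if stage == "IM":
        return f"IM_{lunar}"
    return f"{stage}_{lunar}_{sex}"


def sample_name(stage: str, lunar: str, sex: str, br: int) -> str:
    return f"{condition_name(stage, lunar, sex)}.{br}"


@dataclass
class StudyDesign:
    """Sample metadata table driving comparisons and normalization grouping.

    ``samples`` has one row per (biological sample, technical replicate) with
    columns: sample_id, condition, stage, sex, lunar, br, tr, set_id,
    channel_label, is_spike_control.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "stage", "sex", "lunar", "br", "tr"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        self.validate()

    def validate(self) -> None:
        df = self.samples
        bad_stage = set(df["stage"]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stages: {sorted(bad_stage)}")
        if not (df.loc[df["stage"] == "IM", "sex"] == "U").all():
            raise ValueError("immature (IM) samples must have sex == 'U'")
        mature = df[(df["stage"] == "M") & (~df.get("is_spike_control", False))]
        if len(mature) and not (mature["lunar"] == "NM").all():
            raise ValueError("mature (M) samples occur only at NM in this design")

    @property
    def biological_samples(self) -> pd.DataFrame:
        """One row per biological sample (TR structure collapsed)."""
        cols = ["sample_id", "condition", "stage", "sex", "lunar", "br"]
        return self.samples[cols].drop_duplicates("sample_id").reset_index(drop=True)

    def samples_for(self, condition: str) -> list[str]:
        bio = self.biological_samples
        return bio.loc[bio["condition"] == condition, "sample_id"].tolist()

    def lane_map(self) -> pd.DataFrame:
        """Lane/column id -> (sample_id, tr) mapping for count matrices."""
        df = self.samples.copy()
        df["lane_id"] = df["sample_id"] + ":L" + df["tr"].astype(str)
        return df[["lane_id", "sample_id", "tr"]]


def make_study_design(n_br: int = 3, n_tr: int = 2) -> StudyDesign:
    """Default RNA-side design: every sampled condition x ``n_br`` BRs x ``n_tr`` lanes."""
    rows = []
    for cond in CONDITIONS:
        parts = cond.split("_")
        stage = parts[0]
        lunar = parts[1]
        sex = parts[2] if len(parts) == 3 else "U"
        for br in range(1, n_br + 1):
            for tr in range(1, n_tr + 1):
                rows.append(
                    {
                        "sample_id": sample_name(stage, lunar, sex, br),
                        "condition": cond,
                        "stage": stage,
                        "sex": sex,
                        "lunar": lunar,
                        "br": br,
                        "tr": tr,
                        "set_id": "",
                        "channel_label": "",
                        "is_spike_control": False,
                    }
                )
    return StudyDesign(pd.DataFrame(rows))


#: Channel labels of the isobaric 6-plex reagent set.
TMT_CHANNELS = ("TMT-126", "TMT-127", "TMT-128", "TMT-129", "TMT-130", "TMT-131")

#: Sample whose protein material is re-labelled into every FRFM set for
#: cross-set calibration (matches the study's spiked control channel).
SPIKE_SOURCE_CONDITION = "PM_NM_F"
SPIKE_SOURCE_BR = 1


def make_tmt_design(n_br: int = 3, n_tr: int = 5) -> StudyDesign:
    """Default TMT design: per BR one 5-plex NM set and one FRFM set with a spike.

    NM sets carry the five NM conditions; FRFM sets carry the three FRFM
    conditions plus one spike-control channel replaying PM_NM_F BR1.  Each set
    is measured in ``n_tr`` technical MS runs.
    """
    nm_conditions = ["IM_NM", "PM_NM_F", "PM_NM_M", "M_NM_F", "M_NM_M"]
    frfm_conditions = ["IM_FRFM", "PM_FRFM_F", "PM_FRFM_M"]
    rows = []

    def add(cond, br, set_id, channel, spike):
        parts = cond.split("_")
        stage, lunar = parts[0], parts[1]
        sex = parts[2] if len(parts) == 3 else "U"
        sid = sample_name(stage, lunar, sex, br)
        for tr in range(1, n_tr + 1):
            rows.append(
                {
                    "sample_id": sid if not spike else f"{sid}:spike:{set_id}",
                    "condition": cond,
                    "stage": stage,
                    "sex": sex,
                    "lunar": lunar,
                    "br": br,
                    "tr": tr,
                    "set_id": set_id,
                    "channel_label": channel,
                    "is_spike_control": spike,
                }
            )

    for br in range(1, n_br + 1):
        set_id = f"NM_BR{br}"
        for ch, cond in zip(TMT_CHANNELS, nm_conditions):
            add(cond, br, set_id, ch, spike=False)
        set_id = f"FRFM_BR{br}"
        for ch, cond in zip(TMT_CHANNELS, frfm_conditions):
            add(cond, br, set_id, ch, spike=False)
        # the spike channel re-labels PM_NM_F BR1 material into the FRFM set
        add(SPIKE_SOURCE_CONDITION, SPIKE_SOURCE_BR, set_id, TMT_CHANNELS[len(frfm_conditions)], spike=True)
    return StudyDesign(pd.DataFrame(rows))


@dataclass
class Comparison:
    """A pairwise two-group contrast (group A relative to group B)."""

    name: str
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)
    factor: str = ""  # maturation | sex | lunar

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"comparison {self.name}: groups overlap")
        if self.factor not in {"maturation", "sex", "lunar"}:
            raise ValueError(f"comparison {self.name}: unknown factor {self.factor!r}")

    def validate_against(self, design: StudyDesign) -> None:
        known = set(design.biological_samples["sample_id"])
        unknown = (set(self.group_a) | set(self.group_b)) - known
        if unknown:
            raise ValueError(f"comparison {self.name}: unknown samples {sorted(unknown)}")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"comparison {self.name}: each group needs >=2 BRs")


#: (name, condition A, condition B, factor) for the default 14 pairwise
#: comparisons reconstructed from the sampled conditions: maturation contrasts
#: at NM and FRFM, sex contrasts within stage, and NM-vs-FRFM lunar contrasts.
DEFAULT_COMPARISON_SPECS = (
    ("IM_vs_PM_F_NM", "IM_NM", "PM_NM_F", "maturation"),
    ("IM_vs_PM_M_NM", "IM_NM", "PM_NM_M", "maturation"),
    ("PM_F_vs_M_F_NM", "PM_NM_F", "M_NM_F", "maturation"),
    ("PM_M_vs_M_M_NM", "PM_NM_M", "M_NM_M", "maturation"),
    ("IM_vs_M_F_NM", "IM_NM", "M_NM_F", "maturation"),
    ("IM_vs_M_M_NM", "IM_NM", "M_NM_M", "maturation"),
    ("IM_vs_PM_F_FRFM", "IM_FRFM", "PM_FRFM_F", "maturation"),
    ("IM_vs_PM_M_FRFM", "IM_FRFM", "PM_FRFM_M", "maturation"),
    ("PM_F_vs_PM_M_NM", "PM_NM_F", "PM_NM_M", "sex"),
    ("PM_F_vs_PM_M_FRFM", "PM_FRFM_F", "PM_FRFM_M", "sex"),
    ("M_F_vs_M_M_NM", "M_NM_F", "M_NM_M", "sex"),
    ("IM_NM_vs_IM_FRFM", "IM_NM", "IM_FRFM", "lunar"),
    ("PM_F_NM_vs_PM_F_FRFM", "PM_NM_F", "PM_FRFM_F", "lunar"),
    ("PM_M_NM_vs_PM_M_FRFM", "PM_NM_M", "PM_FRFM_M", "lunar"),
)


def default_comparisons(design: StudyDesign) -> list[Comparison]:
    """The default 14 pairwise comparisons, resolved to sample lists."""
    out = []
    for name, cond_a, cond_b, factor in DEFAULT_COMPARISON_SPECS:
        cmp_ = Comparison(
            name=name,
            group_a=design.samples_for(cond_a),
            group_b=design.samples_for(cond_b),
            factor=factor,
        )
        cmp_.validate_against(design)
        out.append(cmp_)
    return out
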