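"""Synthetic labeled daily-health datasets.

Real deployments of this pipeline rely on wearable measurements annotated by
clinicians; none of that data is public, so this module generates labeled
records with the same protocol shape: three health states (health,
sub-health, illness) in equal proportion, a few thousand records per user,
and a stratified 80/20 train/test split.

Each class has a :class:`ClassProfile` of per-measurement means and standard
deviations. Records are drawn from truncated normals bounded by the
standardization ranges, with SP built as DP plus a positive pulse-pressure
gap so SP > DP holds by construction. The profile means are generator
parameters chosen to mimic plausible vitals gradients across the three
states — not clinical claims — and the separation between class means is a
dial: the defaults give well-separated classes; scaling the separation to
zero yields an unlearnable dataset on which any classifier sits at chance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .classifier import LabeledDataset
from .features import (
    DEFAULT_STRIDE_KM,
    DEFAULT_TABLE,
    ActivitySummary,
    BloodPressureSession,
    DailyHealthRecord,
    StandardizationTable,
    expand_record,
)
from .healthmap import build_map, to_image

__all__ = [
    "ClassProfile",
    "GeneratorConfig",
    "DEFAULT_PROFILES",
    "default_profiles",
    "generate_record",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

FAST_SPEED_KM_H = 5.0  # distance credited per hour of fast motion


@dataclass(frozen=True)
class ClassProfile:
    """(mean, sd) per raw measurement for one health state."""

    name: str
    sp: tuple[float, float]           # systolic, mmHg
    pulse_gap: tuple[float, float]    # SP - DP, mmHg (kept positive)
    hr: tuple[float, float]           # bpm
    weight: tuple[float, float]       # kg
    fat: tuple[float, float]          # percent
    temp: tuple[float, float]         # deg C
    step_num: tuple[float, float]     # steps/day
    sleep_len: tuple[float, float]    # h
    fast_motion_time: tuple[float, float]  # h

    def __post_init__(self) -> None:
        for fname in ("sp", "pulse_gap", "hr", "weight", "fat", "temp",
                      "step_num", "sleep_len", "fast_motion_time"):
            mean, sd = getattr(self, fname)
            if sd < 0:
                raise ValueError(f"{fname}: sd must be nonnegative")

    @property
    def dp_mean(self) -> float:
        return self.sp[0] - self.pulse_gap[0]


def default_profiles() -> tuple[ClassProfile, ClassProfile, ClassProfile]:
    """Default vitals gradients for the three health states.

    Blood pressure, heart rate, and temperature rise from health to illness
    while activity and sleep decline; spreads are ~8 mmHg on pressures and
    ~0.3 degC on temperature.
    """
    return (
        ClassProfile(
            name="health",
            sp=(115.0, 8.0), pulse_gap=(40.0, 5.0), hr=(70.0, 5.0),
            weight=(65.0, 3.0), fat=(22.0, 2.0), temp=(36.6, 0.3),
            step_num=(9000.0, 1500.0), sleep_len=(8.0, 0.8),
            fast_motion_time=(1.0, 0.2),
        ),
        ClassProfile(
            name="sub-health",
            sp=(135.0, 8.0), pulse_gap=(47.0, 5.0), hr=(82.0, 5.0),
            weight=(72.0, 3.0), fat=(28.0, 2.0), temp=(37.1, 0.3),
            step_num=(6000.0, 1500.0), sleep_len=(6.5, 0.8),
            fast_motion_time=(0.5, 0.2),
        ),
        ClassProfile(
            name="illness",
            sp=(155.0, 8.0), pulse_gap=(57.0, 5.0), hr=(95.0, 5.0),
            weight=(70.0, 3.0), fat=(30.0, 2.0), temp=(38.2, 0.3),
            step_num=(2500.0, 1500.0), sleep_len=(5.5, 0.8),
            fast_motion_time=(0.1, 0.1),
        ),
    )


DEFAULT_PROFILES = default_profiles()


def scale_separation(
    profiles: tuple[ClassProfile, ...] = DEFAULT_PROFILES, scale: float = 1.0
) -> tuple[ClassProfile, ...]:
    """Shrink class differences toward the across-class average.

    Both means and spreads are interpolated: ``scale=1`` returns the
    profiles unchanged, ``scale=0`` collapses every class onto one common
    distribution, so the labels carry no signal and any classifier sits at
    chance level.
    """
    fields = ("sp", "pulse_gap", "hr", "weight", "fat", "temp",
              "step_num", "sleep_len", "fast_motion_time")
    centers = {
        f: (
            float(np.mean([getattr(p, f)[0] for p in profiles])),
            float(np.mean([getattr(p, f)[1] for p in profiles])),
        )
        for f in fields
    }
    out = []
    for p in profiles:
        updates = {}
        for f in fields:
            mean, sd = getattr(p, f)
            c_mean, c_sd = centers[f]
            updates[f] = (c_mean + scale * (mean - c_mean), c_sd + scale * (sd - c_sd))
        out.append(replace(p, **updates))
    return tuple(out)


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_class: int
    seed: int = 0
    profiles: tuple[ClassProfile, ClassProfile, ClassProfile] = field(
        default_factory=default_profiles
    )
    split_fraction: float = 0.8
    table: StandardizationTable = field(default_factory=lambda: DEFAULT_TABLE)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if len(self.profiles) != 3:
            raise ValueError("exactly three class profiles required")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Truncated-normal draw clamped to [lo, hi]; degenerate sd returns the mean."""
    if sd == 0.0:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_record(
    profile: ClassProfile,
    seed: int | np.random.Generator,
    table: StandardizationTable = DEFAULT_TABLE,
) -> DailyHealthRecord:
    """Draw one daily record from a class profile (deterministic per seed).

    Both blood-pressure sessions are drawn independently from the same
    profile; DP is constructed as SP minus a positive pulse-pressure gap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = table.ranges

    def session() -> BloodPressureSession:
        sp = _draw(rng, *profile.sp, *r["sp"])
        gap = max(_draw(rng, *profile.pulse_gap, 1.0, r["app"][1]), 1.0)
        dp = max(sp - gap, r["dp"][0] + 1.0)
        hr = _draw(rng, *profile.hr, *r["hr"])
        return BloodPressureSession(sp=sp, dp=dp, hr=hr)

    s1, s2 = session(), session()
    weight = _draw(rng, *profile.weight, *r["weight"])
    fat = _draw(rng, *profile.fat, *r["fat"])
    temp1 = _draw(rng, *profile.temp, *r["body_temperature"])
    temp2 = _draw(rng, *profile.temp, *r["body_temperature"])
    steps = int(round(_draw(rng, *profile.step_num, *r["step_num"])))
    sleep = _draw(rng, *profile.sleep_len, 0.0, 24.0)
    fast_time = _draw(rng, *profile.fast_motion_time, 0.0, 24.0)
    fast_time = min(fast_time, 24.0 - sleep)
    activity = ActivitySummary(
        step_num=steps,
        distance=min(steps * DEFAULT_STRIDE_KM, r["distance"][1]),
        fast_motion_time=fast_time,
        fast_motion_distance=min(fast_time * FAST_SPEED_KM_H, r["fast_motion_distance"][1]),
        sleep_len=sleep,
        awake_len=24.0 - sleep,
    )
    return DailyHealthRecord(
        session1=s1, session2=s2, weight=weight, fat=fat,
        temp1=temp1, temp2=temp2, activity=activity,
    )


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Generate the full labeled map dataset with a stratified split.

    Produces exactly ``n_per_class`` maps per class (3*n total), each record
    expanded and standardized into its 6x6 map, and a per-class 80/20 (by
    ``split_fraction``) train/test partition, all deterministic for the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    maps = []
    labels = []
    for label, profile in enumerate(config.profiles):
        for _ in range(config.n_per_class):
            record = generate_record(profile, rng, config.table)
            maps.append(build_map(expand_record(record), config.table).grid)
            labels.append(label)
    maps_arr = np.stack(maps)
    labels_arr = np.array(labels, dtype=int)

    train_parts = []
    test_parts = []
    for label in range(3):
        idx = np.flatnonzero(labels_arr == label)
        perm = rng.permutation(idx)
        n_train = int(round(config.split_fraction * idx.size))
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
        if n_train == 0 or n_train == idx.size:
            warnings.warn(
                f"class {label}: split leaves an empty partition "
                f"({n_train}/{idx.size} train)",
                stacklevel=2,
            )
    return LabeledDataset(
        maps=maps_arr,
        labels=labels_arr,
        train_idx=np.concatenate(train_parts),
        test_idx=np.concatenate(test_parts),
    )


# ---------------------------------------------------------------------------
# On-disk datasets (maps as PGM + manifest CSV)
# ---------------------------------------------------------------------------

def save_dataset(dataset: LabeledDataset, out_dir, config: GeneratorConfig | None = None) -> Path:
    """Write maps as PGM files plus a (map_path, label, split) manifest CSV."""
    from .healthmap import HealthMap

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    split = np.full(len(dataset), "train", dtype=object)
    split[dataset.test_idx] = "test"
    rows = []
    for i in range(len(dataset)):
        name = f"map_{i:05d}.pgm"
        to_image(HealthMap(grid=dataset.maps[i]), out / name)
        rows.append({"map_path": name, "label": int(dataset.labels[i]), "split": split[i]})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if config is not None:
        provenance = {
            "n_per_class": config.n_per_class,
            "seed": config.seed,
            "split_fraction": config.split_fraction,
            "profiles": [p.name for p in config.profiles],
        }
        (out / "config.json").write_text(json.dumps(provenance, indent=2))
    return manifest


def load_dataset(manifest_path) -> LabeledDataset:
    """Load a dataset written by :func:`save_dataset`."""
    from .healthmap import from_image

    manifest = Path(manifest_path)
    df = pd.read_csv(manifest)
    for col in ("map_path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col!r}")
    maps = np.stack(
        [from_image(manifest.parent / p).grid for p in df["map_path"]]
    )
    labels = df["label"].to_numpy(dtype=int)
    if "split" in df.columns:
        test_idx = np.flatnonzero(df["split"].to_numpy() == "test")
        train_idx = np.flatnonzero(df["split"].to_numpy() != "test")
    else:
        train_idx = np.arange(len(df))
        test_idx = np.array([], dtype=int)
    return LabeledDataset(maps=maps, labels=labels, train_idx=train_idx, test_idx=test_idx)
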