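"""Epoch-based featureization of patient timelines.

The preceding 24 h of a patient's record is represented as six consecutive
4-hour epochs, each summarised into a 66-dimensional feature vector (see
:mod:`iwsrisk.schema`).  A sliding window with stride one epoch pairs every
24-hour observation window with a binary label: whether any WAT-1
assessment of at least 3 falls in the following 4-hour epoch.

The full pipeline is: aggregate per-epoch vital statistics and medication
dose features, impute missing vital epochs (one-epoch carry-forward, then
patient mean, then training-cohort mean), assemble fixed-order vectors,
emit sliding windows, and min-max scale to [0, 1] with statistics fitted on
the training split only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    DEFAULT_SCHEMA,
    DOSE_FEATURES,
    DRUGS,
    FEATURE_INDEX,
    N_FEATURES,
    VITAL_STATS,
    VITALS,
    Schema,
)
from .timelines import WAT1_THRESHOLD, PatientTimeline

logger = logging.getLogger(__name__)

MISSING = float("nan")


@dataclass
class VitalSummary:
    """Per-epoch summary statistics of one vital-sign variable.

    When no measurement falls in the epoch all value fields are NaN and
    ``count`` is 0.
    """

    vmin: float = MISSING
    vmax: float = MISSING
    max_delta: float = MISSING
    mean: float = MISSING
    count: int = 0

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.mean)


@dataclass
class MedSummary:
    """Per-epoch dosing features of one medication (all per kg body weight)."""

    current_avg_dose_per_kg: float = 0.0  # mg / kg / h over the epoch
    cumulative_dose_per_kg: float = 0.0  # mg / kg since extubation
    previous_epoch_dose_per_kg: float = 0.0  # mg / kg in the prior epoch
    cumulative_duration_h: float = 0.0  # hours of exposure since extubation


def aggregate_vital_epoch(measurements: list[tuple[float, float]]) -> VitalSummary:
    """Summarise one vital variable within a single epoch.

    ``measurements`` are (timestamp, value) pairs already restricted to the
    epoch's half-open interval.  An empty list yields the missing-sentinel
    summary with count 0.
    """
    if not measurements:
        return VitalSummary()
    values = np.asarray([v for _, v in measurements], dtype=float)
    vmin = float(values.min())
    vmax = float(values.max())
    return VitalSummary(
        vmin=vmin,
        vmax=vmax,
        max_delta=vmax - vmin,
        mean=float(values.mean()),
        count=len(values),
    )


def aggregate_medication_epoch(
    admins: list[tuple[float, float]],
    weight_kg: float,
    epoch_index: int,
    epoch_hours: float = 4.0,
) -> MedSummary:
    """Dosing features for one drug at one epoch.

    ``admins`` are all (timestamp, dose_mg) administrations of the drug for
    the patient (time-ordered); ``epoch_index`` is 1-based.  The current
    average dose is a rate (total epoch dose / weight / epoch length) so
    that sweeps over epoch length stay comparable.  Cumulative exposure
    duration counts whole epochs containing at least one administration.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    if any(d < 0 for _, d in admins):
        raise ValueError("negative dose in administration record")
    start = (epoch_index - 1) * epoch_hours
    end = epoch_index * epoch_hours
    in_epoch = sum(d for t, d in admins if start <= t < end)
    cumulative = sum(d for t, d in admins if t < end)
    prev = sum(d for t, d in admins if start - epoch_hours <= t < start)
    exposed_epochs = len({int(t // epoch_hours) for t, d in admins if t < end and d > 0})
    return MedSummary(
        current_avg_dose_per_kg=in_epoch / (weight_kg * epoch_hours),
        cumulative_dose_per_kg=cumulative / weight_kg,
        previous_epoch_dose_per_kg=prev / weight_kg,
        cumulative_duration_h=exposed_epochs * epoch_hours,
    )


def impute_vitals(
    summaries: list[VitalSummary],
    patient_mean: float | None,
    cohort_mean: float | None = None,
) -> list[VitalSummary]:
    """Fill missing epoch summaries for one patient and one variable.

    Rule: a missing epoch first takes the previous epoch's mean carried
    forward (horizon exactly one epoch, i.e. the previous four hours);
    otherwise the patient's mean over all their measurements of the
    variable; a patient with no measurement anywhere falls back to the
    training-cohort mean.  A carried/fallback value is treated as one
    repeated measurement: min = max = mean = value, max_delta = 0; the
    measurement count stays 0 so sparse observation remains visible.
    """
    out: list[VitalSummary] = []
    for i, s in enumerate(summaries):
        if not s.is_missing:
            out.append(s)
            continue
        if i > 0 and not summaries[i - 1].is_missing:
            fill = summaries[i - 1].mean
        elif patient_mean is not None and not math.isnan(patient_mean):
            fill = patient_mean
        elif cohort_mean is not None and not math.isnan(cohort_mean):
            fill = cohort_mean
            logger.warning("patient lacks any measurement; cohort-mean fallback used")
        else:
            raise ValueError("no value available for imputation")
        out.append(VitalSummary(vmin=fill, vmax=fill, max_delta=0.0, mean=fill, count=0))
    return out


def assemble_feature_vector(
    vital_summaries: dict[str, VitalSummary],
    med_summaries: dict[str, MedSummary],
    age_months: float,
    prior_withdrawal_epochs: int,
    epoch_index: int,
    mech_vent_duration_h: float,
) -> np.ndarray:
    """Build the length-66 epoch vector in schema order.

    ``prior_withdrawal_epochs`` counts epochs before this one flagged
    positive (plus any documented pre-ICU history); ``epoch_index`` is the
    1-based epoch number since extubation.
    """
    missing = [v for v in VITALS if v not in vital_summaries]
    missing += [d for d in DRUGS if d not in med_summaries]
    if missing:
        raise ValueError(f"schema mismatch; missing: {missing}")
    vec = np.empty(N_FEATURES, dtype=float)
    i = 0
    for v in VITALS:
        s = vital_summaries[v]
        vec[i : i + 5] = (s.vmin, s.vmax, s.max_delta, s.mean, s.count)
        i += 5
    for d in DRUGS:
        m = med_summaries[d]
        vec[i : i + 4] = (
            m.current_avg_dose_per_kg,
            m.cumulative_dose_per_kg,
            m.previous_epoch_dose_per_kg,
            m.cumulative_duration_h,
        )
        i += 4
    vec[i : i + 4] = (age_months, prior_withdrawal_epochs, epoch_index, mech_vent_duration_h)
    return vec


@dataclass
class ObservationWindow:
    """Six consecutive epoch vectors plus the next-epoch withdrawal label."""

    patient_id: str
    window_start_epoch_index: int  # 1-based index of the window's first epoch
    epochs: np.ndarray  # (lookback, 66), oldest first
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def epoch_labels(
    timeline: PatientTimeline, n_epochs: int, epoch_hours: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch withdrawal status from WAT-1 assessments.

    Returns (labels, assessed) arrays of length ``n_epochs``; ``labels[e-1]``
    is 1 iff any WAT-1 score >= 3 falls in epoch e's half-open interval,
    and ``assessed`` marks epochs containing at least one assessment.
    """
    labels = np.zeros(n_epochs, dtype=int)
    assessed = np.zeros(n_epochs, dtype=bool)
    for t, score in timeline.wat1_scores:
        e = int(t // epoch_hours)
        if e < n_epochs:
            assessed[e] = True
            if score >= WAT1_THRESHOLD:
                labels[e] = 1
    return labels, assessed


def build_windows(
    patient_id: str,
    epoch_vectors: np.ndarray,
    labels: np.ndarray,
    assessed: np.ndarray | None = None,
    lookback_epochs: int = 6,
    label_missing_wat1: str = "negative",
) -> list[ObservationWindow]:
    """Slide a ``lookback_epochs``-epoch window over one patient's epochs.

    A patient with K epochs yields max(0, K - lookback) windows; window j
    covers epochs j..j+lookback-1 and is labelled from epoch j+lookback.
    With ``label_missing_wat1='exclude'``, prediction epochs without any
    WAT-1 assessment are dropped instead of labelled negative.
    """
    if label_missing_wat1 not in ("negative", "exclude"):
        raise ValueError("label_missing_wat1 must be 'negative' or 'exclude'")
    k = len(epoch_vectors)
    windows: list[ObservationWindow] = []
    for j in range(1, k - lookback_epochs + 1):
        pred_epoch = j + lookback_epochs  # 1-based
        if label_missing_wat1 == "exclude" and assessed is not None:
            if not assessed[pred_epoch - 1]:
                continue
        windows.append(
            ObservationWindow(
                patient_id=patient_id,
                window_start_epoch_index=j,
                epochs=epoch_vectors[j - 1 : j - 1 + lookback_epochs],
                label=int(labels[pred_epoch - 1]),
            )
        )
    return windows


@dataclass
class ScalingStats:
    """Per-feature min-max statistics fitted on the training split."""

    train_min: np.ndarray
    train_max: np.ndarray
    fitted: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_min": self.train_min.tolist(),
                    "train_max": self.train_max.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingStats":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["train_min"]), np.asarray(d["train_max"]))


def fit_minmax(train_matrix: np.ndarray) -> ScalingStats:
    """Fit per-feature min/max on a (n, ..., 66) training array."""
    flat = train_matrix.reshape(-1, train_matrix.shape[-1])
    return ScalingStats(train_min=flat.min(axis=0), train_max=flat.max(axis=0))


def apply_minmax(matrix: np.ndarray, stats: ScalingStats) -> np.ndarray:
    """Scale to [0, 1]: (v - min)/(max - min), clipped; constant features -> 0."""
    if not stats.fitted:
        raise ValueError("scaling stats not fitted")
    rng = stats.train_max - stats.train_min
    safe = np.where(rng > 0, rng, 1.0)
    scaled = (matrix - stats.train_min) / safe
    scaled = np.where(rng > 0, scaled, 0.0)
    return np.clip(scaled, 0.0, 1.0)


def inverse_minmax(scaled: np.ndarray, stats: ScalingStats) -> np.ndarray:
    """Undo min-max scaling (degenerate features return train_min)."""
    rng = stats.train_max - stats.train_min
    return scaled * rng + stats.train_min


@dataclass
class WindowDataset:
    """A stack of observation windows ready for modelling.

    ``X`` has shape (n_windows, lookback, 66); ``y`` is the binary label
    vector; ``patient_ids`` / ``window_starts`` identify each window.
    """

    X: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray
    window_starts: np.ndarray
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, mask: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            self.X[mask], self.y[mask], self.patient_ids[mask], self.window_starts[mask], self.schema
        )

    def to_frame(self) -> pd.DataFrame:
        n, t, d = self.X.shape
        cols = [f"e{ti + 1}_{name}" for ti in range(t) for name in self.schema.names]
        df = pd.DataFrame(self.X.reshape(n, t * d), columns=cols)
        df.insert(0, "patient_id", self.patient_ids)
        df.insert(1, "window_start", self.window_starts)
        df["label"] = self.y
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, lookback_epochs: int = 6) -> "WindowDataset":
        df = pd.read_csv(path, dtype={"patient_id": str})
        feat_cols = [c for c in df.columns if c.startswith("e")]
        n = len(df)
        X = df[feat_cols].to_numpy(dtype=float).reshape(n, lookback_epochs, -1)
        return cls(
            X=X,
            y=df["label"].to_numpy(dtype=int),
            patient_ids=df["patient_id"].to_numpy(),
            window_starts=df["window_start"].to_numpy(dtype=int),
        )


@dataclass
class PreparedCohort:
    """Scaled train/val/test window datasets plus fitted scaling stats."""

    train: WindowDataset
    val: WindowDataset
    test: WindowDataset
    scaling: ScalingStats
    split: dict[str, list[str]]


def _patient_epoch_matrix(
    tl: PatientTimeline,
    n_epochs: int,
    epoch_hours: float,
    cohort_means: dict[str, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (unscaled) epoch vectors, labels, and assessed flags for one patient."""
    labels, assessed = epoch_labels(tl, n_epochs, epoch_hours)

    vital_series: dict[str, list[VitalSummary]] = {}
    for v in VITALS:
        recs = tl.vitals.get(v, [])
        per_epoch: list[list[tuple[float, float]]] = [[] for _ in range(n_epochs)]
        for t, val in recs:
            e = int(t // epoch_hours)
            if e < n_epochs:
                per_epoch[e].append((t, val))
        summaries = [aggregate_vital_epoch(m) for m in per_epoch]
        pmean = float(np.mean([val for _, val in recs])) if recs else None
        vital_series[v] = impute_vitals(summaries, pmean, cohort_means.get(v))

    vectors = np.empty((n_epochs, N_FEATURES), dtype=float)
    prior_positive = 0
    for e in range(1, n_epochs + 1):
        med = {
            d: aggregate_medication_epoch(tl.med_admins.get(d, []), tl.weight_kg, e, epoch_hours)
            for d in DRUGS
        }
        vit = {v: vital_series[v][e - 1] for v in VITALS}
        vectors[e - 1] = assemble_feature_vector(
            vit,
            med,
            age_months=tl.age_months,
            prior_withdrawal_epochs=tl.prior_withdrawal_history + prior_positive,
            epoch_index=e,
            mech_vent_duration_h=tl.mech_vent_duration_h,
        )
        prior_positive += int(labels[e - 1])
    return vectors, labels, assessed


def split_patients(
    patient_ids: list[str],
    seed: int,
    test_fraction: float = 0.2,
    val_fraction: float = 0.2,
) -> dict[str, list[str]]:
    """Patient-level train/val/test split (val carved from the training side)."""
    rng = np.random.default_rng(seed)
    ids = sorted(patient_ids)
    rng.shuffle(ids)
    n_test = int(round(test_fraction * len(ids)))
    test = ids[:n_test]
    rest = ids[n_test:]
    n_val = int(round(val_fraction * len(rest)))
    val = rest[:n_val]
    train = rest[n_val:]
    return {"train": sorted(train), "val": sorted(val), "test": sorted(test)}


def prepare_cohort(
    timelines: dict[str, PatientTimeline],
    epoch_hours: float = 4.0,
    lookback_epochs: int = 6,
    label_missing_wat1: str = "negative",
    seed: int = 0,
    test_fraction: float = 0.2,
    val_fraction: float = 0.2,
) -> PreparedCohort:
    """Run the full featureization pipeline over a cohort of timelines.

    Patients are split before any statistic is fitted: cohort-level
    imputation fallbacks and min-max scaling use training patients only.
    """
    split = split_patients(list(timelines), seed, test_fraction, val_fraction)
    train_set = set(split["train"]) | set(split["val"])

    # training-cohort per-variable means (imputation fallback of last resort)
    cohort_means: dict[str, float] = {}
    for v in VITALS:
        vals = [
            val
            for pid in train_set
            for _, val in timelines[pid].vitals.get(v, [])
        ]
        cohort_means[v] = float(np.mean(vals)) if vals else float("nan")

    per_split: dict[str, list[ObservationWindow]] = {"train": [], "val": [], "test": []}
    for part, pids in split.items():
        for pid in pids:
            tl = timelines[pid]
            n_ep = tl.n_epochs(epoch_hours)
            vectors, labels, assessed = _patient_epoch_matrix(
                tl, n_ep, epoch_hours, cohort_means
            )
            per_split[part].extend(
                build_windows(
                    pid, vectors, labels, assessed, lookback_epochs, label_missing_wat1
                )
            )

    def stack(windows: list[ObservationWindow]) -> WindowDataset:
        if not windows:
            return WindowDataset(
                X=np.empty((0, lookback_epochs, N_FEATURES)),
                y=np.empty(0, dtype=int),
                patient_ids=np.empty(0, dtype=object),
                window_starts=np.empty(0, dtype=int),
            )
        return WindowDataset(
            X=np.stack([w.epochs for w in windows]),
            y=np.asarray([w.label for w in windows], dtype=int),
            patient_ids=np.asarray([w.patient_id for w in windows]),
            window_starts=np.asarray([w.window_start_epoch_index for w in windows]),
        )

    train_ds, val_ds, test_ds = (stack(per_split[p]) for p in ("train", "val", "test"))
    scaling = fit_minmax(train_ds.X) if len(train_ds) else None
    if scaling is None:
        raise ValueError("no training windows produced; cohort too small")
    for ds in (train_ds, val_ds, test_ds):
        ds.X = apply_minmax(ds.X, scaling)
    return PreparedCohort(train=train_ds, val=val_ds, test=test_ds, scaling=scaling, split=split)
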