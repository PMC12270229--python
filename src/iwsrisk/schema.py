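"""Feature schema registry for the 66-dimensional epoch feature vector.

Each 4-hour epoch of a patient timeline is summarised into a fixed-order
vector: five summary statistics for each of six vital signs, four dosing
features for each of eight sedative/opioid medications, and four
patient-level/temporal scalars.  The schema is versioned so an alternative
roster can be swapped in without touching downstream code.
"""

from __future__ import annotations

from dataclasses import dataclass

VITALS: tuple[str, ...] = (
    "temperature",
    "heart_rate",
    "sbp",
    "dbp",
    "respiratory_rate",
    "map",
)

VITAL_STATS: tuple[str, ...] = ("min", "max", "max_delta", "mean", "count")

DRUGS: tuple[str, ...] = (
    "fentanyl",
    "morphine",
    "hydromorphone",
    "methadone",
    "midazolam",
    "dexmedetomidine",
    "lorazepam",
    "propofol",
)

DOSE_FEATURES: tuple[str, ...] = (
    "current_avg_dose_per_kg",
    "cumulative_dose_per_kg",
    "previous_epoch_dose_per_kg",
    "cumulative_duration_h",
)

STATIC_FEATURES: tuple[str, ...] = (
    "age_months",
    "prior_withdrawal_epochs",
    "previous_epochs",
    "mech_vent_duration_h",
)

SCHEMA_VERSION = "1.0"


def feature_names() -> list[str]:
    """Ordered names of all 66 features.

    Order: vitals block (variable-major, statistic-minor), medication block
    (drug-major, dose-feature-minor), then the four scalar features.
    """
    names: list[str] = []
    for v in VITALS:
        for s in VITAL_STATS:
            names.append(f"{v}_{s}")
    for d in DRUGS:
        for f in DOSE_FEATURES:
            names.append(f"{d}_{f}")
    names.extend(STATIC_FEATURES)
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())
N_FEATURES: int = len(FEATURE_NAMES)
FEATURE_INDEX: dict[str, int] = {n: i for i, n in enumerate(FEATURE_NAMES)}

assert N_FEATURES == 66


@dataclass(frozen=True)
class Schema:
    """A named, versioned feature roster."""

    version: str = SCHEMA_VERSION
    names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_features(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature: {name!r}") from None


DEFAULT_SCHEMA = Schema()
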