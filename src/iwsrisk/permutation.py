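"""Permutation-based validation of feature importance.

Two protocols, both applied to the scaled feature matrices the model
actually consumes and both evaluated on raw (uncalibrated) outputs
binarised at the default threshold 0.5:

* global permutation — a feature's whole six-epoch trajectory is shuffled
  across windows (between samples), destroying its association with the
  label while preserving each window's within-trajectory temporal shape
  and the feature's marginal distribution;
* epoch-specific permutation — only the feature's value at one chosen
  epoch is shuffled across windows, probing whether the model leans on
  recent versus distant history.

An optional within-window mode shuffles a feature's values across the six
epochs inside each window instead of across samples.  Labels are never
permuted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import confusion_metrics, roc_pr
from .model import LSTMParams, predict_proba
from .schema import DEFAULT_SCHEMA, Schema


@dataclass(frozen=True)
class PermutationSpec:
    """One permutation experiment: which feature, at what scope, which seed."""

    feature: str
    scope: str = "global"  # 'global' | 'epoch'
    epoch_index: int | None = None  # 1-based, required iff scope == 'epoch'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scope not in ("global", "epoch"):
            raise ValueError("scope must be 'global' or 'epoch'")
        if self.scope == "epoch" and self.epoch_index is None:
            raise ValueError("epoch scope requires epoch_index")

    def label(self) -> str:
        if self.scope == "epoch":
            return f"{self.feature} at time epoch {self.epoch_index}"
        return self.feature


def global_permutation(
    X: np.ndarray, feature: str, seed: int, schema: Schema = DEFAULT_SCHEMA,
    within_window: bool = False,
) -> np.ndarray:
    """Shuffle one feature's trajectories between windows (default) or,
    with ``within_window=True``, across the epochs inside each window.

    Returns a copy; all other features are untouched and the multiset of
    trajectories (or per-window values) is preserved.
    """
    fi = schema.index(feature)
    rng = np.random.default_rng(seed)
    out = X.copy()
    if within_window:
        for n in range(len(out)):
            out[n, :, fi] = rng.permutation(out[n, :, fi])
    else:
        perm = rng.permutation(len(out))
        out[:, :, fi] = out[perm, :, fi]
    return out


def epoch_permutation(
    X: np.ndarray, feature: str, epoch_index: int, seed: int,
    schema: Schema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """Shuffle one (feature, epoch) column across windows; everything else
    is bit-identical."""
    if not 1 <= epoch_index <= X.shape[1]:
        raise ValueError(f"epoch_index must be in 1..{X.shape[1]}")
    fi = schema.index(feature)
    rng = np.random.default_rng(seed)
    out = X.copy()
    perm = rng.permutation(len(out))
    out[:, epoch_index - 1, fi] = out[perm, epoch_index - 1, fi]
    return out


def apply_spec(X: np.ndarray, spec: PermutationSpec, schema: Schema = DEFAULT_SCHEMA) -> np.ndarray:
    if spec.scope == "global":
        return global_permutation(X, spec.feature, spec.seed, schema)
    return epoch_permutation(X, spec.feature, spec.epoch_index, spec.seed, schema)


def _metric_block(params: LSTMParams, X: np.ndarray, y: np.ndarray, threshold: float) -> dict:
    scores = predict_proba(params, X)
    curves = roc_pr(scores, y)
    m = confusion_metrics(scores, y, threshold)
    return {
        "auroc": curves["auroc"],
        "auprc": curves["auprc"],
        "sensitivity": m["sensitivity"],
        "precision": m["precision"],
        "accuracy": m["accuracy"],
        "specificity": m["specificity"],
        "npv": m["npv"],
        "f1": m["f1"],
    }


def permutation_report(
    params: LSTMParams,
    X: np.ndarray,
    y: np.ndarray,
    specs: list[PermutationSpec],
    threshold: float = 0.5,
    schema: Schema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Baseline metric block plus one block (and deltas) per permutation.

    The baseline is computed once on the unpermuted windows; every
    permuted block uses the identical model and threshold.
    """
    base = _metric_block(params, X, y, threshold)
    rows = [{"permuted_feature": "N/A", "scope": None, "seed": None, **base}]
    for spec in specs:
        Xp = apply_spec(X, spec, schema)
        block = _metric_block(params, Xp, y, threshold)
        row = {
            "permuted_feature": spec.label(),
            "scope": spec.scope,
            "seed": spec.seed,
            **block,
        }
        for k, v in block.items():
            row[f"delta_{k}"] = v - base[k]
        rows.append(row)
    return pd.DataFrame(rows)
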