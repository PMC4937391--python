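"""Registration-accuracy metrics for retraction simulations.

Per-landmark forecast error (Euclidean distance between the model-predicted
and measured post-retraction bead positions), prediction accuracy
(100 * (1 - forecast_error / measured displacement)), Dice similarity
coefficient between segmentation masks, and target registration error, plus
the mean +/- SD summaries used in study report tables.  The published swine
study tables ship as package data so their aggregates can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["LandmarkSet", "MetricsReport", "forecast_error",
           "prediction_accuracy", "dice_coefficient",
           "target_registration_error", "summarize", "round_half_up",
           "load_study_table"]


def round_half_up(x, decimals: int = 1):
    """Table-convention rounding: one decimal, ties away from zero."""
    q = Decimal(10) ** -decimals
    if np.ndim(x) == 0:
        return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return np.array([round_half_up(v, decimals) for v in np.ravel(x)]).reshape(
        np.shape(x))


def load_study_table(name: str) -> pd.DataFrame:
    """Published swine study table shipped with the package.

    Names: ``subject1_landmarks``, ``subject_summary``, ``dice``, ``tre``,
    ``model_comparison``.
    """
    ref = resources.files("retractsim") / "data" / f"swine_{name}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _check_ids(ids_a, ids_b):
    if not np.array_equal(np.asarray(ids_a), np.asarray(ids_b)):
        raise ValueError("landmark ids do not match between coordinate sets")


def forecast_error(predicted: np.ndarray, measured: np.ndarray) -> np.ndarray:
    """Per-landmark distance between predicted and measured positions, mm."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    measured = np.atleast_2d(np.asarray(measured, dtype=float))
    if predicted.shape != measured.shape:
        raise ValueError("coordinate arrays differ in shape")
    return np.linalg.norm(predicted - measured, axis=-1)


def prediction_accuracy(pre, predicted, measured,
                        denominator: str = "measured") -> np.ndarray:
    """Per-landmark simulation accuracy, percent.

    accuracy = 100 * (1 - forecast_error / D) with D the measured
    displacement ||measured - pre|| (default) or, behind the switch, the
    predicted displacement ||predicted - pre||.  Landmarks with zero
    denominator displacement yield NaN (flagged, excluded from means).
    """
    pre = np.atleast_2d(np.asarray(pre, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    measured = np.atleast_2d(np.asarray(measured, dtype=float))
    fe = forecast_error(predicted, measured)
    if denominator == "measured":
        d = np.linalg.norm(measured - pre, axis=-1)
    elif denominator == "predicted":
        d = np.linalg.norm(predicted - pre, axis=-1)
    else:
        raise ValueError("denominator must be 'measured' or 'predicted'")
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = 100.0 * (1.0 - fe / d)
    acc = np.where(d > 0, acc, np.nan)
    return acc


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient DSC(%) = 100 * 2|A n B| / (|A| + |B|)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return 100.0 * 2.0 * int((a & b).sum()) / (na + nb)


def target_registration_error(landmarks_a, landmarks_b):
    """Per-landmark distances between two aligned images' landmarks + mean."""
    a = np.atleast_2d(np.asarray(landmarks_a, dtype=float))
    b = np.atleast_2d(np.asarray(landmarks_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("landmark arrays differ in shape")
    tre = np.linalg.norm(a - b, axis=-1)
    return tre, float(tre.mean())


def summarize(values, ddof: int = 1) -> dict:
    """mean +/- SD, min, max of a metric (sample SD by default)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no values to summarize")
    sd = float(v.std(ddof=ddof)) if v.size > 1 else 0.0
    return {"n": int(v.size), "mean": float(v.mean()), "sd": sd,
            "min": float(v.min()), "max": float(v.max())}


@dataclass
class LandmarkSet:
    """Bead landmark coordinates across the three image states, mm."""

    ids: np.ndarray
    pre: np.ndarray
    predicted: np.ndarray | None = None
    measured: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.pre = np.atleast_2d(np.asarray(self.pre, dtype=float))
        for name in ("predicted", "measured"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.atleast_2d(np.asarray(arr, dtype=float))
                if arr.shape != self.pre.shape:
                    raise ValueError(f"{name} coordinates differ in shape")
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"{name} coordinates contain non-finite values")
                setattr(self, name, arr)
        if not np.all(np.isfinite(self.pre)):
            raise ValueError("pre coordinates contain non-finite values")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        rows = {"id": self.ids}
        for state in ("pre", "predicted", "measured"):
            arr = getattr(self, state)
            if arr is not None:
                for c, ax in enumerate("xyz"):
                    rows[f"{state}_{ax}"] = arr[:, c]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        def block(state):
            cols = [f"{state}_{ax}" for ax in "xyz"]
            return df[cols].to_numpy() if all(c in df for c in cols) else None
        return cls(ids=df["id"].to_numpy(), pre=block("pre"),
                   predicted=block("predicted"), measured=block("measured"))


class MetricsReport:
    """Per-landmark and summary accuracy metrics for one simulation."""

    def __init__(self, landmarks: LandmarkSet,
                 dice_pct: float | None = None,
                 accuracy_denominator: str = "measured"):
        if landmarks.predicted is None or landmarks.measured is None:
            raise ValueError("report needs predicted and measured coordinates")
        self.landmarks = landmarks
        self.dice_pct = dice_pct
        lm = landmarks
        self.forecast_error_mm = forecast_error(lm.predicted, lm.measured)
        self.accuracy_pct = prediction_accuracy(
            lm.pre, lm.predicted, lm.measured, accuracy_denominator)
        self.initial_tre_mm, self.initial_tre_mean = \
            target_registration_error(lm.measured, lm.pre)
        self.updated_tre_mm, self.updated_tre_mean = \
            target_registration_error(lm.measured, lm.predicted)
        self.excluded = np.asarray(np.isnan(self.accuracy_pct))

    def per_landmark(self) -> pd.DataFrame:
        lm = self.landmarks
        return pd.DataFrame({
            "id": lm.ids,
            "predicted_displacement_mm":
                np.linalg.norm(lm.predicted - lm.pre, axis=1),
            "measured_displacement_mm":
                np.linalg.norm(lm.measured - lm.pre, axis=1),
            "forecast_error_mm": self.forecast_error_mm,
            "prediction_accuracy_pct": self.accuracy_pct,
            "initial_tre_mm": self.initial_tre_mm,
            "updated_tre_mm": self.updated_tre_mm,
        })

    def summary(self) -> dict:
        out = {
            "forecast_error_mm": summarize(self.forecast_error_mm),
            "prediction_accuracy_pct": summarize(self.accuracy_pct),
            "initial_tre_mm": summarize(self.initial_tre_mm),
            "updated_tre_mm": summarize(self.updated_tre_mm),
            "n_landmarks": len(self.landmarks),
            "n_excluded_zero_displacement": int(self.excluded.sum()),
        }
        if self.dice_pct is not None:
            out["dice_pct"] = float(self.dice_pct)
        return out

    def rounded_summary(self) -> dict:
        """One-decimal (half-up) report values; full precision kept internally."""
        def walk(v):
            if isinstance(v, dict):
                return {k: walk(x) for k, x in v.items()}
            if isinstance(v, float):
                return round_half_up(v, 1)
            return v
        return walk(self.summary())
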