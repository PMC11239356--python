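"""Decode generated images into per-nucleus CD3 calls and tile accuracy.

The model's R channel is thresholded (intensity > 2 on the 0-255
scale) to strip the Gaussian spread, then combined with the tile's
nuclear mask: a nucleus is called CD3+ when strictly more than half of
its pixel area overlaps the predicted CD3 mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labeling import label_nuclei_by_marker
from .simulate import CD3_POS


@dataclass
class CallResult:
    """Per-nucleus CD3 calls for one tile."""

    calls: pd.DataFrame  # id, row, col, label
    n_pos: int
    n_neg: int
    tile_id: str = ""
    accuracy: float | None = None


def extract_pred_mask(generated: np.ndarray, pred_threshold: int = 2) -> np.ndarray:
    """Binary CD3 mask from a generated [0, 1] patch.

    The R channel is rescaled to 0-255; a pixel is positive iff its
    value is strictly greater than ``pred_threshold``.
    """
    generated = np.asarray(generated)
    r = generated[..., 0] if generated.ndim == 3 else generated
    return (r * 255.0 > pred_threshold).astype(np.uint8)


def call_nuclei(pred_mask: np.ndarray, nuclei: np.ndarray, tile_id: str = "") -> CallResult:
    """Majority-overlap CD3 calls: CD3+ iff > half the nucleus is covered."""
    calls = label_nuclei_by_marker(nuclei, pred_mask, rule="majority")
    n_pos = int((calls["label"] == CD3_POS).sum())
    return CallResult(calls=calls, n_pos=n_pos, n_neg=len(calls) - n_pos, tile_id=tile_id)


def tile_accuracy(calls: CallResult | pd.DataFrame, truth: pd.DataFrame) -> float | None:
    """Fraction of nuclei whose call matches the ground-truth label.

    Both tables must cover the same nucleus ids.  A tile without nuclei
    has undefined accuracy and returns ``None`` (excluded from means).
    """
    df = calls.calls if isinstance(calls, CallResult) else calls
    if len(df) == 0 and len(truth) == 0:
        return None
    if set(df["id"]) != set(truth["id"]):
        raise ValueError("call and truth tables cover different nucleus ids")
    merged = df.merge(truth[["id", "label"]], on="id", suffixes=("_call", "_truth"))
    acc = float((merged["label_call"] == merged["label_truth"]).mean())
    if isinstance(calls, CallResult):
        calls.accuracy = acc
    return acc


def call_and_score(
    generated: np.ndarray,
    nuclei: np.ndarray,
    truth: pd.DataFrame,
    pred_threshold: int = 2,
    tile_id: str = "",
) -> CallResult:
    """Convenience: extract mask, call nuclei, and score against truth."""
    result = call_nuclei(extract_pred_mask(generated, pred_threshold), nuclei, tile_id)
    if len(result.calls):
        result.accuracy = tile_accuracy(result, truth)
    return result


def match_calls_by_centroid(
    calls: pd.DataFrame, truth: pd.DataFrame, radius: float
) -> float | None:
    """Centroid-matching accuracy for when prediction and truth use
    different segmentations: each truth nucleus is matched to the
    nearest call centroid within ``radius`` px and agreements counted;
    unmatched truth nuclei count as disagreements."""
    if len(truth) == 0:
        return None
    if len(calls) == 0:
        return 0.0
    cxy = calls[["row", "col"]].to_numpy(float)
    txy = truth[["row", "col"]].to_numpy(float)
    d = np.sqrt(((txy[:, None] - cxy[None]) ** 2).sum(-1))
    nearest = d.argmin(axis=1)
    ok = 0
    for i, j in enumerate(nearest):
        if d[i, j] <= radius and truth["label"].iloc[i] == calls["label"].iloc[j]:
            ok += 1
    return ok / len(truth)
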