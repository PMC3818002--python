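"""Error metrics between estimated and ground-truth oxygen maps."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .core import OxygenMap

__all__ = ["EvaluationReport", "mae", "rmse", "evaluate"]


@dataclass
class EvaluationReport:
    """Summary of one estimator run against ground truth.

    All errors are in mmHg over the evaluated (masked, mutually valid)
    pixels; invalid pixels — where phase recovery failed — are excluded and
    counted separately so least-squares artifacts stay visible instead of
    being hidden or dominating.  wall_time_s is reported for context only.
    """

    mae: float
    rmse: float
    bias: float
    n_valid: int
    n_invalid: int
    method: str = ""
    beta: float = float("nan")
    snr_db: float = float("nan")
    seed: int = -1
    wall_time_s: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


def _effective_mask(
    estimate: OxygenMap, truth: OxygenMap, mask: Optional[np.ndarray]
) -> np.ndarray:
    if estimate.po2.shape != truth.po2.shape:
        raise ValueError("estimate and truth shapes differ")
    sel = estimate.valid_mask & truth.valid_mask
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != truth.po2.shape:
            raise ValueError("mask shape differs from maps")
        sel = sel & mask
    return sel


def mae(
    estimate: OxygenMap, truth: OxygenMap, mask: Optional[np.ndarray] = None
) -> float:
    """Mean absolute error (mmHg) over masked, mutually valid pixels."""
    sel = _effective_mask(estimate, truth, mask)
    if not sel.any():
        raise ValueError("no valid pixels under the given mask")
    return float(np.mean(np.abs(estimate.po2[sel] - truth.po2[sel])))


def rmse(
    estimate: OxygenMap, truth: OxygenMap, mask: Optional[np.ndarray] = None
) -> float:
    """Root-mean-square error (mmHg) over masked, mutually valid pixels."""
    sel = _effective_mask(estimate, truth, mask)
    if not sel.any():
        raise ValueError("no valid pixels under the given mask")
    return float(np.sqrt(np.mean((estimate.po2[sel] - truth.po2[sel]) ** 2)))


def evaluate(
    estimate: OxygenMap,
    truth: OxygenMap,
    mask: Optional[np.ndarray] = None,
    **labels,
) -> EvaluationReport:
    """Full report: MAE, RMSE, bias and valid/invalid pixel counts.

    The default headline metric is over vessel pixels: pass
    ``mask=truth.vessel_mask > 0`` (the pipeline does this unless asked for
    full-map evaluation).
    """
    sel = _effective_mask(estimate, truth, mask)
    if not sel.any():
        raise ValueError("no valid pixels under the given mask")
    diff = estimate.po2[sel] - truth.po2[sel]
    evaluated = mask if mask is not None else np.ones_like(sel)
    n_eval = int(np.asarray(evaluated, dtype=bool).sum())
    return EvaluationReport(
        mae=float(np.mean(np.abs(diff))),
        rmse=float(np.sqrt(np.mean(diff**2))),
        bias=float(np.mean(diff)),
        n_valid=int(sel.sum()),
        n_invalid=n_eval - int(sel.sum()),
        **labels,
    )
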