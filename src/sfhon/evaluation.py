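"""Region-level validation of modeled risk against introduction records.

Predictions and observations are compared at the state/country level:
port-level risks are averaged over each region's ports, min-max scaled to
[0, 1] per model, and scored against the min-max scaled count of first NIS
introductions per region by mean squared error. Pairs of models are compared
with a two-tailed paired t-test on the per-region squared errors, and an
over-/under-estimation breakdown reports the direction of each region's
residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ModelEvaluation:
    model_name: str
    per_region: pd.DataFrame  # region_id, predicted_scaled, observed, squared_error
    mse: float
    n_regions: int
    flags: list = field(default_factory=list)

    def to_dict(self):
        return {
            "model_name": self.model_name,
            "mse": self.mse,
            "n_regions": self.n_regions,
            "flags": self.flags,
            "per_region": self.per_region.to_dict(orient="records"),
        }


def region_risk(port_risks: dict[str, float], region_of: dict[str, str]) -> dict[str, float]:
    """Arithmetic mean of port risks per region.

    Ports without a region are skipped with a warning; regions in
    ``region_of`` that receive no scored ports are omitted.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for port, risk in port_risks.items():
        region = region_of.get(port)
        if region is None:
            log.warning("port %s has no region; skipped in region averaging", port)
            continue
        sums[region] = sums.get(region, 0.0) + risk
        counts[region] = counts.get(region, 0) + 1
    return {r: sums[r] / counts[r] for r in sums}


def minmax_scale(values) -> np.ndarray:
    """Scale to [0, 1] by (x - min) / (max - min); constant input -> zeros."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        log.info("minmax_scale: constant input, returning zeros")
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def normalize_introductions(introductions: pd.DataFrame) -> dict[str, float]:
    """Min-max normalized first-introduction counts per region."""
    scaled = minmax_scale(introductions["n_first_introductions"])
    return dict(zip(introductions["region_id"], scaled))


def evaluate_model(
    predicted: dict[str, float],
    observed: dict[str, float],
    model_name: str = "model",
    scale_predictions: bool = True,
) -> ModelEvaluation:
    """MSE of (scaled) predicted region risk against observed normalized counts.

    The region sets must match exactly; a mismatch raises with the symmetric
    difference. Predictions are min-max scaled per model by default.
    """
    mismatch = set(predicted) ^ set(observed)
    if mismatch:
        raise ValueError(f"region mismatch between predictions and observations: "
                         f"{sorted(mismatch)}")
    regions = sorted(predicted)
    pred = np.array([predicted[r] for r in regions], dtype=float)
    if scale_predictions:
        pred = minmax_scale(pred)
    obs = np.array([observed[r] for r in regions], dtype=float)
    sq = (pred - obs) ** 2
    df = pd.DataFrame({
        "region_id": regions, "predicted_scaled": pred,
        "observed": obs, "squared_error": sq,
    })
    return ModelEvaluation(
        model_name=model_name, per_region=df,
        mse=float(sq.mean()), n_regions=len(regions),
    )


def compare_models(eval_a: ModelEvaluation, eval_b: ModelEvaluation) -> dict:
    """Two-tailed paired t-test on per-region squared errors of two models.

    Returns t, p and the mean error difference (a - b). All-zero differences
    are a degenerate case reported as p = 1 with a flag.
    """
    a = eval_a.per_region.set_index("region_id")["squared_error"]
    b = eval_b.per_region.set_index("region_id")["squared_error"]
    if set(a.index) != set(b.index):
        raise ValueError("models evaluated on different region sets")
    if len(a) < 2:
        raise ValueError("need at least two paired regions")
    b = b.reindex(a.index)
    diff = a.to_numpy() - b.to_numpy()
    if np.allclose(diff, 0.0):
        return {"t": 0.0, "p": 1.0, "mean_diff": 0.0, "degenerate": True}
    t, p = stats.ttest_rel(a.to_numpy(), b.to_numpy())
    return {"t": float(t), "p": float(p), "mean_diff": float(diff.mean()),
            "degenerate": bool(np.isnan(t))}


def direction_report(evaluation: ModelEvaluation) -> dict:
    """Share of regions the model over- and under-estimates.

    Ties count as neither, so the shares may sum below 1.
    """
    pred = evaluation.per_region["predicted_scaled"].to_numpy()
    obs = evaluation.per_region["observed"].to_numpy()
    n = len(pred)
    return {
        "over_share": float((pred > obs).sum() / n),
        "under_share": float((pred < obs).sum() / n),
        "mean_signed_error": float((pred - obs).mean()),
    }
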