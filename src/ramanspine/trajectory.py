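"""Depth-resolved classification of drilling trajectories.

A trained binary model (bone vs spinal cord, or bone vs all soft tissue)
is applied to each spectrum of a depth-ordered trajectory after full
preprocessing.  The detected breach depth is the shallowest step whose
calibrated soft/cord probability exceeds the decision threshold (0.5 by
default); no smoothing across depths is applied, matching per-measurement
classification.  Internally probability 1 means soft tissue / cord;
rendering can flip the orientation so 1 means bone, as the probability-bar
figures are conventionally drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TrainedModel, predict
from .preprocess import InstrumentResponse, PreprocessParams, preprocess_pipeline
from .synth import InvalidArgumentError, Trajectory


@dataclass
class BreachReport:
    depths: np.ndarray
    predicted: np.ndarray           # task-class label per step
    probability_soft: np.ndarray    # calibrated p(soft/cord), 1 = soft
    detected_breach_depth: float | None
    model_task: str
    threshold: float = 0.5


def classify_trajectory(model: TrainedModel, traj: Trajectory,
                        response: InstrumentResponse | None = None,
                        params: PreprocessParams | None = None,
                        threshold: float = 0.5) -> BreachReport:
    """Score every depth step and flag the first supra-threshold soft call."""
    if model.task.name not in ("II", "III"):
        raise InvalidArgumentError("breach detection needs a binary model")
    fps = [preprocess_pipeline(acq, response, params)
           for acq in traj.acquisitions]
    labels, probs = predict(model, fps)
    p_soft = probs[:, -1]           # positive (cord/soft) class is last
    above = np.flatnonzero(p_soft > threshold)
    detected = float(traj.depths[above[0]]) if above.size else None
    return BreachReport(depths=traj.depths.copy(), predicted=labels,
                        probability_soft=p_soft,
                        detected_breach_depth=detected,
                        model_task=model.task.name, threshold=threshold)


def probability_profile(report: BreachReport, orientation: str = "soft"
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Depth-indexed probability series for plotting.

    ``orientation="soft"`` returns the internal convention (1 = soft/cord);
    ``orientation="bone"`` returns 1-p, the figure convention (1 = bone).
    """
    if orientation not in ("soft", "bone"):
        raise InvalidArgumentError("orientation must be 'soft' or 'bone'")
    p = report.probability_soft
    return report.depths.copy(), (p.copy() if orientation == "soft" else 1.0 - p)
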