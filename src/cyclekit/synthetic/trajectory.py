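"""Prescribed CDK2-sensor activity trajectories for simulated cells.

Activity is the cytoplasmic/nuclear sensor ratio.  Each trajectory is a
deterministic piecewise-linear curve: the mother rises toward a pre-mitotic
peak, drops to a post-mitotic baseline at anaphase, and then follows one of
four conventions:

- ``cdk2_increasing``  rises immediately, exceeding the classification
  threshold (0.6) well before two hours post-anaphase.
- ``transient_g0``     stays at baseline, then rises so that it first crosses
  the threshold at a configurable time after anaphase.
- ``prolonged_g0``     stays at baseline for the whole horizon.
- ``g2_arrest``        rises like an increaser but plateaus at the peak
  without a second division.

The shapes are module conventions (the source study reports no numeric sensor
dynamics); only the threshold behaviour at the classification time points is
contractual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FATE_LABELS = ("cdk2_increasing", "transient_g0", "prolonged_g0", "g2_arrest")


@dataclass(frozen=True)
class TrajectoryParams:
    """Shape parameters shared by all fates.

    ``rise_per_min`` is chosen so an increaser reaches 0.8 two hours after
    anaphase (safely above the 0.6 threshold).  ``transient_crossing_min`` is
    the time after anaphase at which a transient-G0 trace first reaches the
    threshold.
    """

    baseline: float = 0.3
    peak: float = 1.0
    threshold: float = 0.6
    pre_mitotic_start: float = 0.5
    rise_per_min: float = (0.8 - 0.3) / 120.0
    transient_crossing_min: float = 360.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline < self.threshold:
            raise ValueError("baseline must lie in [0, threshold)")
        if self.peak <= self.threshold:
            raise ValueError("peak must exceed threshold")
        if self.rise_per_min <= 0:
            raise ValueError("rise_per_min must be positive")


def generate_cdk2_trajectory(
    fate: str,
    anaphase_time: float,
    horizon: float,
    params: TrajectoryParams | None = None,
    step_min: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(times_min, activity)`` sampled every ``step_min`` on [0, horizon].

    ``anaphase_time`` and ``horizon`` are minutes from trace start;
    ``horizon`` must exceed ``anaphase_time``.
    """
    if fate not in FATE_LABELS:
        raise ValueError(f"unknown fate label {fate!r}; expected one of {FATE_LABELS}")
    if horizon <= anaphase_time:
        raise ValueError("horizon must exceed anaphase_time")
    p = params or TrajectoryParams()

    times = np.arange(0.0, horizon + 0.5 * step_min, step_min)
    act = np.empty_like(times)

    # Mother segment: linear ramp toward the pre-mitotic peak.
    pre = times < anaphase_time
    if anaphase_time > 0:
        frac = times[pre] / anaphase_time
        act[pre] = p.pre_mitotic_start + (p.peak - p.pre_mitotic_start) * frac
    dt = times[~pre] - anaphase_time

    if fate == "prolonged_g0":
        post = np.full_like(dt, p.baseline)
    elif fate in ("cdk2_increasing", "g2_arrest"):
        post = np.minimum(p.baseline + p.rise_per_min * dt, p.peak)
    else:  # transient_g0
        # Delay so the threshold is first crossed at transient_crossing_min.
        t0 = p.transient_crossing_min - (p.threshold - p.baseline) / p.rise_per_min
        if p.transient_crossing_min <= 120.0:
            raise ValueError(
                "transient_crossing_min too early: activity would reach the "
                "threshold by two hours post-anaphase"
            )
        post = np.minimum(p.baseline + p.rise_per_min * np.maximum(dt - t0, 0.0), p.peak)
    act[~pre] = post
    return times, act
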