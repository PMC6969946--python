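"""Stimulus designs and simulated observers for the two experiments.

The first experiment presents a near-vertical line slanted in depth about
the horizontal axis: 2 IOVD signs x 7 orientation disparities (-6..+6 deg
in steps of 2) = 14 conditions, all at tilt 0.  The second uses oblique
lines (tilt 45 or 135 deg from vertical) slanted about their tilt axes:
2 x 2 x 7 = 28 conditions, which collapse onto 14 equivalence classes
under x-reflection (a 135-deg line with -IOVD mirrors a 45-deg line with
+IOVD).

Simulated observers respond with the BVN prediction for each condition
plus independent Gaussian angular noise on longitude and latitude,
emulating the probe-adjustment task.  Each condition draws from its own
random substream derived from the master seed by hashing the condition
key, so extending a design does not perturb existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import NoiseParams, design_matrices
from .geometry import StimulusCondition, ViewingGeometry

ORIENTATION_DISPARITIES = (-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0)


def exp1_design() -> list[StimulusCondition]:
    """The 14 line-stimulus conditions of the first experiment.

    Vertical mean orientation (tilt 0), orientation disparity swept from
    -6 to +6 deg in steps of 2, both IOVD signs; image speeds
    3.0 +/- 0.23 deg/s, aperture radius 2.41 deg.
    """
    return [
        StimulusCondition(
            tilt_deg=0.0,
            orientation_disparity_deg=dtheta,
            iovd_sign=s,
            experiment=1,
        )
        for dtheta in ORIENTATION_DISPARITIES
        for s in (-1, 1)
    ]


def exp2_design(collapse_mirror: bool = False) -> list[StimulusCondition]:
    """The 28 oblique conditions of the second experiment.

    Tilts 45 and 135 deg from vertical, same orientation disparities and
    IOVDs as the first experiment.  With ``collapse_mirror`` the 28
    conditions are reduced to the 14 canonical classes (tilt 45) by
    x-reflection, which maps (tilt 135, s) onto (tilt 45, -s) and
    preserves orientation disparity.
    """
    conds = [
        StimulusCondition(
            tilt_deg=tilt,
            orientation_disparity_deg=dtheta,
            iovd_sign=s,
            experiment=2,
        )
        for tilt in (45.0, 135.0)
        for dtheta in ORIENTATION_DISPARITIES
        for s in (-1, 1)
    ]
    if not collapse_mirror:
        return conds
    seen = {}
    for c in conds:
        canon = c if c.tilt_deg <= 90 else c.mirrored()
        seen.setdefault(canon.key(), canon)
    return sorted(
        seen.values(),
        key=lambda c: (c.tilt_deg, c.orientation_disparity_deg, c.iovd_sign),
    )


@dataclass(frozen=True)
class GenerativeObserver:
    """A synthetic observer: BVN generative model plus response noise."""

    noise: NoiseParams
    response_noise_sd_deg: float = 3.0
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_noise_sd_deg < 0:
            raise ValueError("response noise SD must be non-negative")
        if self.n_reps < 1:
            raise ValueError("need at least one repetition per condition")


def _condition_rng(master_seed: int, cond: StimulusCondition) -> np.random.Generator:
    key = (
        f"{cond.experiment}|{cond.tilt_deg:.4f}|"
        f"{cond.orientation_disparity_deg:.4f}|{cond.iovd_sign}"
    )
    sub = zlib.crc32(key.encode())
    return np.random.default_rng(np.random.SeedSequence((master_seed, sub)))


def simulate_observer(
    design: list[StimulusCondition],
    obs: GenerativeObserver,
    geometry: ViewingGeometry,
    observer_id: str = "synthetic",
) -> pd.DataFrame:
    """Simulate a trial table for one observer over a stimulus design.

    Each condition contributes ``n_reps`` rows whose angles are the BVN
    prediction at the observer's noise parameters plus iid Gaussian
    angular noise (deg) on longitude and latitude.  Reproducible under
    the observer's seed; per-condition substreams are order-independent.
    """
    dm = design_matrices(design, geometry)
    pred = dm.predict_angles(obs.noise)
    rows = []
    for cond, (lon, lat) in zip(design, pred):
        rng = _condition_rng(obs.seed, cond)
        jitter = rng.normal(0.0, obs.response_noise_sd_deg, size=(obs.n_reps, 2))
        for rep in range(obs.n_reps):
            rows.append(
                {
                    "observer": observer_id,
                    "experiment": cond.experiment,
                    "tilt_deg": cond.tilt_deg,
                    "orientation_disparity_deg": cond.orientation_disparity_deg,
                    "iovd_sign": cond.iovd_sign,
                    "rep": rep,
                    "longitude_deg": lon + jitter[rep, 0],
                    "latitude_deg": lat + jitter[rep, 1],
                }
            )
    return pd.DataFrame(rows)


def design_table(design: list[StimulusCondition]) -> pd.DataFrame:
    """Design as a tidy table (one row per condition)."""
    return pd.DataFrame(
        [
            {
                "experiment": c.experiment,
                "tilt_deg": c.tilt_deg,
                "orientation_disparity_deg": c.orientation_disparity_deg,
                "iovd_sign": c.iovd_sign,
                "base_speed_deg": c.base_speed_deg,
                "iovd_magnitude_deg": c.iovd_magnitude_deg,
                "aperture_radius_deg": c.aperture_radius_deg,
            }
            for c in design
        ]
    )
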