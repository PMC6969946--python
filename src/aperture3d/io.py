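"""Configuration, provenance, and CSV/JSON round-tripping.

Trial tables travel as UTF-8 CSV with a header row (angles serialized to
6 decimal places); nested results (fits, comparisons, bootstrap
summaries) as JSON.  Every result file carries a provenance block with
the package version, the seed, and a hash of the effective
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .geometry import ViewingGeometry


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run."""

    distance_cm: float = 55.0
    ipd_cm: float = 6.5
    n_boot: int = 1000
    seed: int = 0
    probe_scale_factor: float = 0.6
    response_noise_sd_deg: float = 3.0
    n_reps: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for block in raw.values() if all(isinstance(v, dict) for v in raw.values()) else [raw]:
            flat.update(block)
        known = {k: v for k, v in flat.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @property
    def geometry(self) -> ViewingGeometry:
        return ViewingGeometry(distance_cm=self.distance_cm, ipd_cm=self.ipd_cm)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {
            "package": "aperture3d",
            "version": __version__,
            "config_hash": self.hash(),
            "seed": self.seed,
            "config": asdict(self),
        }


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
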