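"""List-mode event container and its CSV interchange format.

A list-mode set is an ordered table of two-hit Compton events (one Si
scatterer hit, one CdTe absorber hit) plus acquisition metadata.  The
interchange format is a plain CSV with a fixed column set and a YAML sidecar
(``<file>.meta.yaml``) carrying scene name, exposure, seed, and the camera
configuration hash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

COLUMNS = [
    "event_id",
    "E1_keV",
    "E2_keV",
    "x1_mm",
    "y1_mm",
    "z1_mm",
    "x2_mm",
    "y2_mm",
    "z2_mm",
    "scatterer_layer",
    "absorber_layer",
    "truth_label",
    "truth_x_mm",
    "truth_y_mm",
    "truth_z_mm",
]

__all__ = ["COLUMNS", "ListModeSet"]


@dataclass
class ListModeSet:
    """Two-hit list-mode events with acquisition metadata.

    ``df`` holds one row per event with the columns in :data:`COLUMNS`.
    ``truth_label`` is the generating source component ("none" when unknown)
    and ``truth_*_mm`` the emission point (NaN when absent, e.g. for
    continuum events with uncorrelated fake geometry).
    """

    df: pd.DataFrame
    scene_name: str = "unknown"
    exposure_s: float = 0.0
    seed: int | None = None
    camera_hash: str = ""
    created: str = "unset"

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"list-mode table is missing columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    # -- convenience array views -------------------------------------------
    @property
    def e1(self) -> np.ndarray:
        return self.df["E1_keV"].to_numpy(float)

    @property
    def e2(self) -> np.ndarray:
        return self.df["E2_keV"].to_numpy(float)

    @property
    def etot(self) -> np.ndarray:
        return self.e1 + self.e2

    @property
    def r1(self) -> np.ndarray:
        return self.df[["x1_mm", "y1_mm", "z1_mm"]].to_numpy(float)

    @property
    def r2(self) -> np.ndarray:
        return self.df[["x2_mm", "y2_mm", "z2_mm"]].to_numpy(float)

    def subset(self, mask: np.ndarray) -> "ListModeSet":
        """New set with the masked rows, order and metadata preserved."""
        return ListModeSet(
            df=self.df.loc[np.asarray(mask, bool)].reset_index(drop=True),
            scene_name=self.scene_name,
            exposure_s=self.exposure_s,
            seed=self.seed,
            camera_hash=self.camera_hash,
            created=self.created,
        )

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False, float_format="%.6f")
        meta = {
            "scene": self.scene_name,
            "exposure_s": float(self.exposure_s),
            "seed": None if self.seed is None else int(self.seed),
            "camera_hash": self.camera_hash,
            "created": self.created,
            "n_events": int(len(self)),
        }
        with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ListModeSet":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.yaml")
        meta = {}
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = yaml.safe_load(fh) or {}
        return cls(
            df=df,
            scene_name=meta.get("scene", "unknown"),
            exposure_s=float(meta.get("exposure_s", 0.0)),
            seed=meta.get("seed"),
            camera_hash=meta.get("camera_hash", ""),
            created=str(meta.get("created", "unset")),
        )
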