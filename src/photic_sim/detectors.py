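"""Detector tallies and per-angle normalized intensities.

Four detectors are modelled.  Detector-P tallies power through the pupil
opening (a non-interacting monitor at the iris plane).  Detector-N
tallies power that passed through the iris-IOL interspace without ever
interacting with the IOL and continued into the posterior segment on
the nasal (+x) side; ray history is the primary criterion, the nasal
side the secondary guard, so bypassing rays count whether they land on
the retinal hemisphere or leave its 24 mm aperture sideways at extreme
obliquity.  Detector-E tallies power that struck the IOL edge surface
at least once.  Detector-F tallies power landing within the foveal
patch, a 1.5 mm diameter disc around the visual-axis/retina
intersection (chord radius 0.75 mm; geodesic vs chord is negligible at
this size).

Per-angle fractions are referenced to the through-pupil power of the
same angle; the pupil curve itself is referenced to its 0-degree value
and compared against cos^2(theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ray_engine
from .eye_model import EyeScene
from .ray_engine import BundleResult, TerminalRecord

__all__ = [
    "DetectorTally",
    "SweepResult",
    "classify",
    "tally_bundle",
    "normalize",
    "onset_angle",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ["theta_deg", "P_raw", "P_over_P0", "N_frac", "E_frac", "F_frac", "cos2_ref"]


@dataclass
class DetectorTally:
    """Raw per-angle power sums and terminal-status bookkeeping."""

    theta_deg: float
    launched: int = 0
    P_power: float = 0.0
    N_power: float = 0.0
    E_power: float = 0.0
    F_power: float = 0.0
    status_counts: dict[str, int] = field(default_factory=dict)

    def check_energy(self) -> None:
        """Integer energy conservation: statuses partition the launch."""
        total = sum(self.status_counts.get(k, 0) for k in ray_engine.STATUS_NAMES)
        if total != self.launched:
            raise AssertionError(
                f"energy bookkeeping broken at {self.theta_deg} deg: "
                f"{total} != {self.launched}"
            )


def classify(record: TerminalRecord, scene: EyeScene, tally: DetectorTally,
             power: float = 1.0) -> DetectorTally:
    """Add one terminal record to the detector tallies.

    Detector-E counts rays whose history includes an edge hit; a retinal
    terminus can additionally feed Detector-F (within the foveal patch)
    or Detector-N (pupil transit, never touched the IOL, nasal half).
    Pupil transits themselves are tallied by the in-flight monitor and
    are added here from the record's history flag.
    """
    tally.status_counts[record.status] = tally.status_counts.get(record.status, 0) + 1
    if record.pupil_transit:
        tally.P_power += power
    if record.first_edge_hit:
        tally.E_power += power
    if record.status == "terminated_retina" and record.pupil_transit:
        p = np.asarray(record.retinal_point)
        if np.linalg.norm(p - scene.fovea_center) <= scene.fovea_radius_mm:
            tally.F_power += power
        elif not record.hit_iol and p[0] > 0.0:
            tally.N_power += power
    elif (record.status == "escaped" and record.pupil_transit
          and not record.hit_iol and record.terminal_direction[0] > 0.0
          and record.terminal_direction[2] > 0.0):
        # IOL-bypassing ray leaving the retinal aperture sideways, nasal-bound
        tally.N_power += power
    return tally


def tally_bundle(result: BundleResult, scene: EyeScene, theta_deg: float) -> DetectorTally:
    """Build the per-angle tally from a traced bundle (unit ray power)."""
    tally = DetectorTally(theta_deg=theta_deg, launched=len(result.status))
    tally.status_counts = result.status_counts()
    tally.P_power = float(np.sum(result.pupil_transit))
    tally.E_power = float(np.sum(result.first_edge_hit))
    ret = result.retinal_mask & result.pupil_transit
    if np.any(ret):
        pts = result.terminal_points[ret]
        dist = np.linalg.norm(pts - scene.fovea_center[None, :], axis=1)
        foveal = dist <= scene.fovea_radius_mm
        tally.F_power = float(np.sum(foveal))
        bypass = (~result.hit_iol[ret]) & (pts[:, 0] > 0.0) & ~foveal
        tally.N_power = float(np.sum(bypass))
    side = ((result.status == ray_engine.ESCAPED) & result.pupil_transit
            & ~result.hit_iol & (result.terminal_directions[:, 0] > 0.0)
            & (result.terminal_directions[:, 2] > 0.0))
    tally.N_power += float(np.sum(side))
    tally.check_energy()
    return tally


def normalize(tally: DetectorTally, P0: float) -> dict[str, float]:
    """One SweepResult row: fractions of through-pupil power.

    Fractions are NaN (reported missing, never silently zero) where the
    pupil power of the angle — or, for ``P_over_P0``, the reference
    power — is zero.
    """
    P = tally.P_power
    nan = float("nan")
    return {
        "theta_deg": tally.theta_deg,
        "P_raw": P,
        "P_over_P0": P / P0 if P0 > 0 else nan,
        "N_frac": tally.N_power / P if P > 0 else nan,
        "E_frac": tally.E_power / P if P > 0 else nan,
        "F_frac": tally.F_power / P if P > 0 else nan,
        "cos2_ref": math.cos(math.radians(tally.theta_deg)) ** 2,
    }


@dataclass
class SweepResult:
    """Per-angle normalized intensities for one scene variant."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing sweep columns: {missing}")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, columns=CSV_COLUMNS,
                          float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "SweepResult":
        table = pd.read_csv(path)
        for col in CSV_COLUMNS:
            if col in table.columns:
                table[col] = table[col].astype(float)
        return cls(table=table, meta=meta or {})

    def column(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"unknown sweep column {name!r}")
        return self.table[name].to_numpy()


def onset_angle(result: SweepResult, column: str, threshold: float = 0.0) -> float | None:
    """Smallest swept angle whose column value exceeds ``threshold``.

    NaN rows (undefined fractions at zero pupil power) are skipped; the
    default threshold 0 detects the first strictly positive power, i.e.
    at least one detected ray.  Returns None if never exceeded.
    """
    theta = result.column("theta_deg")
    vals = result.column(column)
    above = np.flatnonzero(~np.isnan(vals) & (vals > threshold))
    return float(theta[above[0]]) if above.size else None


def offset_angle_last(result: SweepResult, column: str, threshold: float = 0.0) -> float | None:
    """Largest swept angle whose column value exceeds ``threshold``."""
    theta = result.column("theta_deg")
    vals = result.column(column)
    above = np.flatnonzero(~np.isnan(vals) & (vals > threshold))
    return float(theta[above[-1]]) if above.size else None
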