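"""Point-based (fiducial) rigid registration and marker-distance reporting.

Centers of mass of segmented bone structures act as fiducial markers; the
rigid transform between the ultrasound frame and the CT frame is the
closed-form least-squares (SVD / Procrustes) solution with a proper-rotation
guard.  Marker-distance reports give the Euclidean distance from a
registered fiducial to each manually placed candidate marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ValidationError

__all__ = ["LandmarkSet", "RigidTransform", "rigid_landmark_transform",
           "marker_distances"]


@dataclass
class LandmarkSet:
    """Labeled 3D points [mm] in a named coordinate frame."""

    points: np.ndarray  # (n, 3)
    labels: list[str]
    frame: str = "ultrasound"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValidationError("points must be (n, 3)")
        if self.points.shape[0] < 1:
            raise ValidationError("need at least one point")
        if len(self.labels) != self.points.shape[0]:
            raise ValidationError("labels/points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("labels must be unique")

    @classmethod
    def from_csv(cls, path, frame: str | None = None) -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls(points=df[["x", "y", "z"]].to_numpy(),
                   labels=df["label"].astype(str).tolist(),
                   frame=frame or (df["frame"].iloc[0] if "frame" in df else "unknown"))

    def to_csv(self, path) -> None:
        pd.DataFrame({"label": self.labels, "x": self.points[:, 0],
                      "y": self.points[:, 1], "z": self.points[:, 2],
                      "frame": self.frame}).to_csv(path, index=False)


@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    fre_per_point: np.ndarray = field(default_factory=lambda: np.zeros(0))
    rms_fre: float = 0.0

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation


def rigid_landmark_transform(moving: LandmarkSet, fixed: LandmarkSet) -> RigidTransform:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed``.

    Points are matched by label; needs >= 3 non-collinear pairs.  The SVD
    solution is sign-corrected so the rotation is proper (det = +1).  The
    fiducial registration error (FRE) is the per-point residual norm after
    the transform; ``rms_fre`` is sqrt(mean(FRE^2)).
    """
    common = [lab for lab in moving.labels if lab in set(fixed.labels)]
    if len(common) < 3:
        raise ValidationError("need at least 3 matched point pairs")
    mi = {lab: i for i, lab in enumerate(moving.labels)}
    fi = {lab: i for i, lab in enumerate(fixed.labels)}
    P = moving.points[[mi[lab] for lab in common]]
    Q = fixed.points[[fi[lab] for lab in common]]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(Pc, tol=1e-9 * max(1.0, np.abs(Pc).max())) < 2:
        raise ValidationError("points are collinear; rotation is not determined")
    U, S, Vt = np.linalg.svd(Pc.T @ Qc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    resid = Q - (P @ R.T + t)
    fre = np.linalg.norm(resid, axis=1)
    return RigidTransform(rotation=R, translation=t, fre_per_point=fre,
                          rms_fre=float(np.sqrt(np.mean(fre ** 2))))


def marker_distances(fiducial: np.ndarray, manual_markers: LandmarkSet) -> dict:
    """Euclidean distance [mm] from one fiducial point to every manual
    marker, with mean +/- std and the minimum-distance marker."""
    fid = np.asarray(fiducial, dtype=float).reshape(3)
    d = np.linalg.norm(manual_markers.points - fid, axis=1)
    imin = int(np.argmin(d))
    return {"labels": list(manual_markers.labels),
            "distances_mm": d,
            "mean_mm": float(d.mean()),
            "std_mm": float(d.std(ddof=1)) if d.size > 1 else 0.0,
            "argmin_label": manual_markers.labels[imin],
            "min_mm": float(d[imin])}
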