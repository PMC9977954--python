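"""Principal-axes orientation and distance analytics over ensembles.

The relative orientation of the arrestin with respect to the receptor is
described by aircraft-convention pitch/roll/yaw angles.  For each body a
right-handed frame is built from the principal components of its Cα
coordinates (PC1 = longitudinal, PC2 = vertical, PC3 completes the
frame); the longitudinal sign is fixed toward designated "nose" residues
and the vertical sign toward a reference direction (the membrane normal
by convention).  The three axes are used as aircraft north/east/down
axes: roll about the longitudinal (north), pitch about the transverse
(east), yaw about the vertical (down), with north x east = down.  The
relative rotation expresses the arrestin axes in receptor-frame
components, R = X_receptorᵀ · X_arrestin — a quantity invariant under
any global rigid motion of the whole complex — and

    pitch β = atan2(-R31, sqrt(R11² + R21²))
    roll  γ = atan2(R32 / cos β, R33 / cos β)
    yaw   α = atan2(R21 / cos β, R11 / cos β)

i.e. the ZYX (yaw-pitch-roll) factorization R = Rz(α) Ry(β) Rx(γ).  All
user-facing angles are degrees.  At gimbal lock (|cos β| ~ 0) the roll
is set to 0 and the residual rotation folded into yaw, with a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import (
    ResidueRef,
    Structure,
    StructureError,
    TrajectoryEnsemble,
    superpose,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AxisFrame",
    "NoseDefinition",
    "OrientationAngles",
    "principal_frame",
    "frame_for_body",
    "relative_rotation",
    "euler_angles",
    "rotation_from_angles",
    "ensemble_orientation",
    "distance_trace",
    "contact_persistence",
    "any_contact_persistence",
]

EIGEN_TIE_WARN_RATIO = 0.01  # adjacent-eigenvalue ties within 1% are unstable


@dataclass(frozen=True)
class NoseDefinition:
    """Residues fixing the longitudinal sign, and the vertical reference.

    ``reference_direction`` disambiguates the vertical (PC2) sign; by
    convention it is the membrane normal (or its negation for a body
    whose vertical points to the intracellular side).
    """

    residues: tuple[ResidueRef, ...]
    reference_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("need at least one nose residue")
        if np.linalg.norm(self.reference_direction) == 0:
            raise ValueError("reference direction must be non-zero")


@dataclass(frozen=True)
class AxisFrame:
    """Right-handed orthonormal principal-axes frame of one body."""

    origin: np.ndarray
    longitudinal: np.ndarray
    vertical: np.ndarray
    transverse: np.ndarray

    def __post_init__(self) -> None:
        M = self.matrix
        if not np.allclose(M.T @ M, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        # aircraft handedness: north (longitudinal) x east (transverse)
        # = down (vertical)
        if np.dot(np.cross(self.longitudinal, self.transverse), self.vertical) < 0:
            raise ValueError("frame must be right-handed (north x east = down)")

    @property
    def matrix(self) -> np.ndarray:
        """Axis vectors as columns, ordered north/east/down:
        (longitudinal, transverse, vertical)."""
        return np.column_stack(
            [
                np.asarray(self.longitudinal, dtype=float),
                np.asarray(self.transverse, dtype=float),
                np.asarray(self.vertical, dtype=float),
            ]
        )


@dataclass(frozen=True)
class OrientationAngles:
    """Aircraft pitch/roll/yaw triple, degrees."""

    pitch: float
    roll: float
    yaw: float
    gimbal_locked: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pitch, self.roll, self.yaw)


def principal_frame(
    coords: np.ndarray,
    nose_point: np.ndarray,
    reference_direction: np.ndarray = (0.0, 0.0, 1.0),
) -> AxisFrame:
    """Principal-axes frame of a Cα point cloud.

    PCs of the centered coordinates are sorted by descending eigenvalue.
    The longitudinal axis (PC1) is signed toward ``nose_point``, the
    vertical (PC2) toward ``reference_direction``, and the transverse
    completes a right-handed frame.  Collinear point sets raise; near
    eigenvalue ties (within 1%) only warn, since PC ordering becomes
    unstable there.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a principal frame")
    origin = pts.mean(axis=0)
    centered = pts - origin
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[1] <= 1e-10 * max(evals[0], 1e-30):
        raise StructureError("degenerate principal axes: points are collinear")
    for a, b in ((0, 1), (1, 2)):
        if evals[a] > 0 and (evals[a] - evals[b]) / evals[a] < EIGEN_TIE_WARN_RATIO:
            warnings.warn(
                f"principal-axis eigenvalues {a + 1} and {b + 1} nearly tied; "
                "axis ordering may be unstable",
                RuntimeWarning,
                stacklevel=2,
            )
    longitudinal = evecs[:, 0]
    if np.dot(np.asarray(nose_point, dtype=float) - origin, longitudinal) < 0:
        longitudinal = -longitudinal
    vertical = evecs[:, 1]
    if np.dot(np.asarray(reference_direction, dtype=float), vertical) < 0:
        vertical = -vertical
    # east axis completing the north/east/down frame
    transverse = np.cross(vertical, longitudinal)
    return AxisFrame(origin, longitudinal, vertical, transverse)


def frame_for_body(
    structure: Structure, chain: str, nose: NoseDefinition
) -> AxisFrame:
    """Principal frame of one chain's Cα atoms with nose residues resolved."""
    ca = structure.ca_coordinates(chain)
    nose_pts = np.array(
        [structure.atom_coordinate(r, "CA") for r in nose.residues]
    )
    return principal_frame(ca, nose_pts.mean(axis=0), nose.reference_direction)


def relative_rotation(
    frame_receptor: AxisFrame, frame_arrestin: AxisFrame
) -> np.ndarray:
    """Arrestin orientation relative to the receptor: R = X_recᵀ · X_arr.

    The entries express the arrestin north/east/down axes in receptor
    frame components, so the result is invariant under any global rigid
    transform of the complex.
    """
    Xr = frame_receptor.matrix
    Xa = frame_arrestin.matrix
    R = Xr.T @ Xa
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("input frames are not proper orthonormal frames")
    return R


def euler_angles(R: np.ndarray, tol: float = 1e-8) -> OrientationAngles:
    """Pitch/roll/yaw (degrees) of a proper rotation, ZYX convention."""
    R = np.asarray(R, dtype=float).reshape(3, 3)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("R must be a proper orthonormal rotation")
    beta = np.arctan2(-R[2, 0], np.hypot(R[0, 0], R[1, 0]))
    cb = np.cos(beta)
    if abs(cb) < tol:
        # gimbal lock: fold the indeterminate roll into yaw
        sign = -np.sign(R[2, 0])  # +1 at beta=+90, -1 at beta=-90
        alpha = np.arctan2(-sign * R[0, 1], R[1, 1])
        return OrientationAngles(
            pitch=float(np.degrees(beta)),
            roll=0.0,
            yaw=float(np.degrees(alpha)),
            gimbal_locked=True,
        )
    gamma = np.arctan2(R[2, 1] / cb, R[2, 2] / cb)
    alpha = np.arctan2(R[1, 0] / cb, R[0, 0] / cb)
    return OrientationAngles(
        pitch=float(np.degrees(beta)),
        roll=float(np.degrees(gamma)),
        yaw=float(np.degrees(alpha)),
    )


def rotation_from_angles(pitch: float, roll: float, yaw: float) -> np.ndarray:
    """Compose R = Rz(yaw) · Ry(pitch) · Rx(roll), angles in degrees."""
    b, g, a = np.radians([pitch, roll, yaw])
    ca_, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    Rz = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rx = np.array([[1, 0, 0], [0, cg, -sg], [0, sg, cg]])
    return Rz @ Ry @ Rx


def _ca_rows(topology: Structure, chain: str) -> list[int]:
    return [
        r.atoms["CA"]
        for r in topology.residues
        if r.chain == chain and "CA" in r.atoms
    ]


def ensemble_orientation(
    traj: TrajectoryEnsemble,
    receptor_chain: str,
    arrestin_chain: str,
    receptor_nose: NoseDefinition,
    arrestin_nose: NoseDefinition,
) -> pd.DataFrame:
    """Per-frame pitch/roll/yaw and arrestin RMSD from the first frame.

    Angles describe the arrestin frame relative to the receptor frame,
    recomputed from principal components in every frame.  The RMSD is on
    arrestin Cα after least-squares superposition of the receptor Cα
    onto frame 0, so global drift of the whole complex cancels.
    Columns: frame, pitch_deg, roll_deg, yaw_deg, rmsd_A, gimbal_locked.
    """
    topo = traj.topology
    rec_rows = _ca_rows(topo, receptor_chain)
    arr_rows = _ca_rows(topo, arrestin_chain)
    if len(rec_rows) < 3 or len(arr_rows) < 3:
        raise StructureError("both bodies need at least 3 Cα atoms")
    rec_nose_rows = [topo.residue(r).atoms["CA"] for r in receptor_nose.residues]
    arr_nose_rows = [topo.residue(r).atoms["CA"] for r in arrestin_nose.residues]

    ref_rec = traj.frames[0][rec_rows]
    ref_arr = traj.frames[0][arr_rows]

    records = []
    for k in range(traj.n_frames):
        frame = traj.frames[k]
        try:
            f_rec = principal_frame(
                frame[rec_rows],
                frame[rec_nose_rows].mean(axis=0),
                receptor_nose.reference_direction,
            )
            f_arr = principal_frame(
                frame[arr_rows],
                frame[arr_nose_rows].mean(axis=0),
                arrestin_nose.reference_direction,
            )
        except StructureError as exc:
            raise StructureError(f"frame {k}: {exc}") from exc
        ang = euler_angles(relative_rotation(f_rec, f_arr))
        R, t, _ = superpose(frame[rec_rows], ref_rec)
        arr_fitted = frame[arr_rows] @ R.T + t
        rmsd = float(np.sqrt(np.mean(np.sum((arr_fitted - ref_arr) ** 2, axis=1))))
        records.append((k, ang.pitch, ang.roll, ang.yaw, rmsd, ang.gimbal_locked))
    return pd.DataFrame(
        records,
        columns=["frame", "pitch_deg", "roll_deg", "yaw_deg", "rmsd_A", "gimbal_locked"],
    )


def orientation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Maximal absolute deviation of each angle from its frame-0 value."""
    out = {}
    for col in ("pitch_deg", "roll_deg", "yaw_deg"):
        dev = table[col] - table[col].iloc[0]
        # wrap to (-180, 180]
        dev = (dev + 180.0) % 360.0 - 180.0
        out[f"max_abs_{col.replace('_deg', '')}_deviation_deg"] = float(dev.abs().max())
    out["max_rmsd_A"] = float(table["rmsd_A"].max())
    return pd.DataFrame([out])


def _anchor_rows(topology: Structure, ref: ResidueRef) -> int:
    res = topology.residue(ref)
    name = "CA" if res.name == "GLY" else "CB"
    if name not in res.atoms:
        raise StructureError(f"residue {ref} lacks anchor atom {name}")
    return res.atoms[name]


def distance_trace(
    traj: TrajectoryEnsemble,
    pairs: list[tuple[ResidueRef, ResidueRef]],
    cutoffs: tuple[float, ...] = (10.2, 15.0),
) -> pd.DataFrame:
    """Descriptive statistics of anchor–anchor distances over all frames.

    Per pair: min, quartiles, median, max, the fraction of frames below
    each cutoff, and whether the pair ever comes within each cutoff.
    """
    rows_a = []
    rows_b = []
    for a, b in pairs:
        try:
            rows_a.append(_anchor_rows(traj.topology, a))
            rows_b.append(_anchor_rows(traj.topology, b))
        except StructureError as exc:
            raise StructureError(f"pair ({a}, {b}): {exc}") from exc
    diffs = traj.frames[:, rows_a, :] - traj.frames[:, rows_b, :]  # (F, P, 3)
    dists = np.linalg.norm(diffs, axis=2)
    q25, med, q75 = np.percentile(dists, [25, 50, 75], axis=0)
    data = {
        "pair": [f"{a}-{b}" for a, b in pairs],
        "min_A": dists.min(axis=0),
        "q25_A": q25,
        "median_A": med,
        "q75_A": q75,
        "max_A": dists.max(axis=0),
    }
    for c in cutoffs:
        within = dists <= c
        data[f"fraction_within_{c:g}A"] = within.mean(axis=0)
        data[f"ever_within_{c:g}A"] = within.any(axis=0)
    return pd.DataFrame(data)


def _min_heavy_distance(
    traj: TrajectoryEnsemble, ref_a: ResidueRef, ref_b: ResidueRef
) -> np.ndarray:
    rows_a = traj.topology.residue_heavy_rows(ref_a)
    rows_b = traj.topology.residue_heavy_rows(ref_b)
    if not rows_a or not rows_b:
        raise StructureError(f"no heavy atoms for {ref_a} or {ref_b}")
    pa = traj.frames[:, rows_a, :]
    pb = traj.frames[:, rows_b, :]
    d = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=3)
    return d.min(axis=(1, 2))


def contact_persistence(
    traj: TrajectoryEnsemble,
    pairs: list[tuple[ResidueRef, ResidueRef]],
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Fraction of frames each residue pair is in contact.

    Contact means minimum inter-residue heavy-atom distance below the
    cutoff (default 4.0 Å, a generous salt-bridge/H-bond criterion).
    """
    records = []
    for a, b in pairs:
        md = _min_heavy_distance(traj, a, b)
        records.append((f"{a}-{b}", float((md < cutoff).mean())))
    return pd.DataFrame(records, columns=["pair", "persistence_fraction"])


def any_contact_persistence(
    traj: TrajectoryEnsemble,
    pairs: list[tuple[ResidueRef, ResidueRef]],
    cutoff: float = 4.0,
) -> float:
    """Fraction of frames in which ANY pair of the group is in contact.

    Captures interactions that dynamically switch between partners.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    any_contact = np.zeros(traj.n_frames, dtype=bool)
    for a, b in pairs:
        any_contact |= _min_heavy_distance(traj, a, b) < cutoff
    return float(any_contact.mean())
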