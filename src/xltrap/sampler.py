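"""Rigid-body Metropolis Monte Carlo pose optimization.

One binding partner (the receptor) is held fixed; the other (the
arrestin) is moved as a rigid body over the 6-dimensional pose space of
proper rotations and translations.  The energy is the sum of the
flat-bottom crosslink-restraint penalties and a soft-sphere Cα clash
term.  Proposals are compound moves — a rotation about the mobile
partner's current centroid around a uniformly random axis with a
normally distributed angle, plus a normally distributed translation —
accepted by the Metropolis criterion.

The default temperature kT = 1.0 (weighted Å² units) makes a single
unit-yield restraint violated by 1 Å beyond its wall (E = 1) acceptable
with probability e^-1 ≈ 37%.  An optional adaptive scheme rescales the
step sizes toward a 30–50% acceptance rate.  All randomness flows from
the explicit seed in the configuration; runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .restraints import Restraint
from .structures import Structure, anchor_coordinate

logger = logging.getLogger(__name__)

__all__ = ["Pose", "SamplerConfig", "SamplingResult", "metropolis_accept", "mmc_optimize"]


@dataclass(frozen=True)
class Pose:
    """A rigid transform x -> R x + t applied to the mobile partner."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose_after(self, rotation: np.ndarray, translation: np.ndarray) -> "Pose":
        """New pose applying this pose first, then (rotation, translation)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return Pose(R @ self.rotation, R @ self.translation + t)


@dataclass
class SamplerConfig:
    """Metropolis Monte Carlo settings (desk-scale defaults)."""

    steps: int = 20000
    kT: float = 1.0
    rot_step_deg: float = 6.0
    trans_step_A: float = 1.0
    trials: int = 1
    seed: int = 0
    adaptive: bool = True
    adapt_interval: int = 200
    trace_thin: int = 100
    plateau_average: bool = True
    plateau_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.rot_step_deg <= 0 or self.trans_step_A <= 0:
            raise ValueError("step scales must be positive")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")


@dataclass
class SamplingResult:
    """Per-trial best poses, energies, thinned traces and acceptance."""

    best_poses: list[Pose]
    best_energies: list[float]
    traces: list[np.ndarray]  # (n_records, 2): step, current energy
    acceptance_rates: list[float]
    seed: int

    @property
    def best_trial(self) -> int:
        return int(np.argmin(self.best_energies))

    @property
    def best_pose(self) -> Pose:
        return self.best_poses[self.best_trial]

    @property
    def best_energy(self) -> float:
        return float(self.best_energies[self.best_trial])


def metropolis_accept(delta_e: float, kT: float, u: float) -> bool:
    """Metropolis criterion: always accept downhill, else u < exp(-ΔE/kT)."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    if delta_e <= 0:
        return True
    return u < np.exp(-delta_e / kT)


class _PoseEnergy:
    """Precomputed geometry for fast pose-energy evaluation."""

    def __init__(
        self,
        receptor: Structure,
        mobile: Structure,
        restraints: list[Restraint],
        clash_weight: float,
        clash_r_min: float,
        fallback_calpha: bool = False,
    ) -> None:
        self.fixed_anchors = np.array(
            [anchor_coordinate(receptor, r.receptor, fallback_calpha) for r in restraints]
        ).reshape(-1, 3)
        self.mobile_anchors = np.array(
            [anchor_coordinate(mobile, r.arrestin, fallback_calpha) for r in restraints]
        ).reshape(-1, 3)
        self.weights_sqrt = np.sqrt(np.array([r.weight for r in restraints]))
        self.lo = np.array([r.lo for r in restraints])
        self.hi = np.array([r.hi for r in restraints])
        self.fixed_ca = receptor.ca_coordinates()
        self.mobile_ca = mobile.ca_coordinates()
        self.clash_weight = clash_weight
        self.clash_r_min = clash_r_min

    def __call__(self, pose: Pose) -> float:
        e = 0.0
        if len(self.weights_sqrt):
            moved = pose.apply(self.mobile_anchors)
            d = np.linalg.norm(moved - self.fixed_anchors, axis=1)
            e += float(
                np.sum(
                    self.weights_sqrt
                    * (
                        np.maximum(d - self.hi, 0.0) ** 2
                        + np.maximum(self.lo - d, 0.0) ** 2
                    )
                )
            )
        if self.clash_weight > 0:
            moved_ca = pose.apply(self.mobile_ca)
            dd = cdist(self.fixed_ca, moved_ca)
            ov = np.maximum(self.clash_r_min - dd, 0.0)
            e += self.clash_weight * float(np.sum(ov * ov))
        return e


def _random_rotation(rng: np.random.Generator, scale_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.normal(0.0, scale_deg))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def mmc_optimize(
    receptor: Structure,
    mobile: Structure,
    restraints: list[Restraint],
    config: SamplerConfig,
    clash_weight: float = 1.0,
    clash_r_min: float = 4.0,
    initial_pose: Pose | None = None,
    fallback_calpha: bool = False,
) -> SamplingResult:
    """Optimize the mobile partner's rigid-body pose by Metropolis MC.

    Runs ``config.trials`` independent random walks (trial k is seeded
    with ``seed + k``), each starting from ``initial_pose`` (identity by
    default).  Rotation proposals pivot about the mobile body's current
    centroid.  Returns best pose and energy per trial plus thinned
    energy traces and acceptance rates.

    A flat-bottom restraint landscape has a *plateau* of minimal-energy
    poses rather than a point minimum, and the first plateau pose a walk
    happens to touch lies on the plateau's boundary.  With
    ``plateau_average`` (default) the reported best pose is therefore
    the centroid — mean translation and mean rotation — of all visited
    poses tied with the best energy, which estimates the plateau centre;
    the raw first-best pose is kept instead if the centroid's energy is
    not itself tied (non-convex plateau).
    """
    if not restraints and clash_weight == 0:
        logger.warning("no restraints and no clash term: energy landscape is flat")
    energy_fn = _PoseEnergy(
        receptor, mobile, restraints, clash_weight, clash_r_min, fallback_calpha
    )
    mobile_centroid = energy_fn.mobile_ca.mean(axis=0)
    start = initial_pose if initial_pose is not None else Pose.identity()

    best_poses: list[Pose] = []
    best_energies: list[float] = []
    traces: list[np.ndarray] = []
    acc_rates: list[float] = []

    for trial in range(config.trials):
        rng = np.random.default_rng(config.seed + trial)
        pose = start
        energy = energy_fn(pose)
        best_pose, best_energy = pose, energy
        rot_scale = config.rot_step_deg
        trans_scale = config.trans_step_A
        accepted = 0
        window_accepted = 0
        trace: list[tuple[int, float]] = [(0, energy)]
        plateau_quats: list[np.ndarray] = [Rotation.from_matrix(pose.rotation).as_quat()]
        plateau_trans: list[np.ndarray] = [pose.translation]

        for step in range(1, config.steps + 1):
            dR = _random_rotation(rng, rot_scale)
            dt = rng.normal(0.0, trans_scale, size=3)
            # pivot rotation about the current centroid of the mobile body
            centroid = pose.apply(mobile_centroid[None, :])[0]
            shift = centroid - dR @ centroid + dt
            cand = pose.compose_after(dR, shift)
            cand_energy = energy_fn(cand)
            if metropolis_accept(cand_energy - energy, config.kT, rng.random()):
                pose, energy = cand, cand_energy
                accepted += 1
                window_accepted += 1
                if energy < best_energy - config.plateau_tol:
                    best_pose, best_energy = pose, energy
                    plateau_quats = [Rotation.from_matrix(pose.rotation).as_quat()]
                    plateau_trans = [pose.translation]
                elif energy <= best_energy + config.plateau_tol:
                    plateau_quats.append(Rotation.from_matrix(pose.rotation).as_quat())
                    plateau_trans.append(pose.translation)
            if step % config.trace_thin == 0:
                trace.append((step, energy))
            if config.adaptive and step % config.adapt_interval == 0:
                rate = window_accepted / config.adapt_interval
                if rate > 0.5:
                    rot_scale = min(rot_scale * 1.15, 60.0)
                    trans_scale = min(trans_scale * 1.15, 10.0)
                elif rate < 0.3:
                    rot_scale = max(rot_scale * 0.85, 0.05)
                    trans_scale = max(trans_scale * 0.85, 0.01)
                window_accepted = 0

        if config.plateau_average and len(plateau_quats) > 1:
            mean_rot = Rotation.from_quat(np.array(plateau_quats)).mean().as_matrix()
            mean_trans = np.mean(np.array(plateau_trans), axis=0)
            centroid_pose = Pose(mean_rot, mean_trans)
            centroid_energy = energy_fn(centroid_pose)
            if centroid_energy <= best_energy + config.plateau_tol:
                best_pose, best_energy = centroid_pose, centroid_energy

        best_poses.append(best_pose)
        best_energies.append(float(best_energy))
        traces.append(np.array(trace))
        acc_rates.append(accepted / config.steps)

    return SamplingResult(best_poses, best_energies, traces, acc_rates, config.seed)
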