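"""Seeded generators for pipeline-shaped synthetic inputs.

Every stage of the pipeline gets a generator that produces data with the
statistical structure it assumes, together with the ground truth used to
make it, so each analysis has a recovery test.  All generators are pure
functions of their spec plus seed.

The pseudo-proteins are compact self-avoiding random walks with 3.8 Å
Cα spacing and pseudo-Cβ atoms placed 1.53 Å off the local backbone —
enough realism for anchor geometry, with no pretence of real folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .blots import MEASUREMENT_COLUMNS
from .restraints import DEFAULT_LOWER_WALL, DEFAULT_UPPER_WALL, Restraint
from .sampler import Pose
from .structures import Residue, ResidueRef, Structure, TrajectoryEnsemble
from .orientation import rotation_from_angles

__all__ = [
    "SyntheticComplexSpec",
    "SyntheticBlotSpec",
    "make_toy_complex",
    "simulate_blot_table",
    "simulate_trajectory",
    "random_coil",
]

CA_SPACING = 3.8
CB_LENGTH = 1.53
MIN_SELF_DISTANCE = 4.0


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Recipe for a toy two-body complex with planted crosslinks."""

    n_receptor: int = 40
    n_arrestin: int = 40
    n_pairs: int = 12
    # planted anchor distances are drawn across the whole flat bottom:
    # pairs near the walls are what make the restraints pin the pose
    distance_band: tuple[float, float] = (4.0, 10.2)
    seed: int = 0
    true_pose: Pose | None = None
    yield_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_receptor < 5 or self.n_arrestin < 5:
            raise ValueError("bodies need at least 5 residues")
        lo, hi = self.distance_band
        if not DEFAULT_LOWER_WALL <= lo < hi <= DEFAULT_UPPER_WALL:
            raise ValueError(
                "planted distances must lie within the flat bottom "
                f"[{DEFAULT_LOWER_WALL}, {DEFAULT_UPPER_WALL}] Å"
            )


@dataclass(frozen=True)
class SyntheticBlotSpec:
    """Recipe for a replicate blot table plus background controls."""

    true_yields: tuple[float, ...] = (0.3, 0.25, 0.1, 0.05)
    n_replicates: int = 3
    noise_sd: float = 0.03
    control_mean: float = 0.02
    control_sd: float = 0.01
    control_n: int = 20
    significance_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= y <= 1 for y in self.true_yields):
            raise ValueError("true yields must lie in [0, 1]")
        if self.n_replicates < 1 or self.control_n < 1:
            raise ValueError("replicate counts must be >= 1")


def _self_avoiding_walk(
    n_residues: int,
    rng: np.random.Generator,
    inside,
    start: np.ndarray,
) -> np.ndarray:
    """Self-avoiding Cα walk with 3.8 Å steps confined by ``inside``.

    Any step closer than 4.0 Å to a non-adjacent Cα or leaving the
    confinement region is rejected, with backtracking when the walk
    paints itself into a corner.  Deterministic for a given generator
    state.
    """
    ca = [np.asarray(start, dtype=float)]
    attempts_at = np.zeros(n_residues, dtype=int)
    while len(ca) < n_residues:
        i = len(ca)
        placed = False
        for _ in range(120):
            step = rng.normal(size=3)
            step = CA_SPACING * step / np.linalg.norm(step)
            cand = ca[-1] + step
            if not inside(cand):
                continue
            if len(ca) > 1:
                d = np.linalg.norm(np.array(ca[:-1]) - cand, axis=1)
                if (d < MIN_SELF_DISTANCE).any():
                    continue
            ca.append(cand)
            placed = True
            break
        if not placed:
            attempts_at[i] += 1
            back = min(3 + attempts_at[i], len(ca) - 1)
            del ca[-back:]
            if not ca:
                ca = [np.asarray(start, dtype=float)]
    return np.array(ca)


def _structure_from_ca(
    ca_arr: np.ndarray, chain: str, start_number: int = 1
) -> Structure:
    """Attach pseudo-Cβ atoms (1.53 Å off the local backbone) and wrap
    the trace in a Structure of alanines."""
    n_residues = len(ca_arr)
    cb_arr = np.empty_like(ca_arr)
    for i in range(n_residues):
        lo = max(i - 1, 0)
        hi = min(i + 1, n_residues - 1)
        local = 0.5 * (ca_arr[lo] + ca_arr[hi])
        direction = ca_arr[i] - local
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            direction = ca_arr[i] - ca_arr[max(i - 1, 0)]
            direction = np.cross(direction, [0.0, 0.0, 1.0])
            norm = np.linalg.norm(direction)
            if norm < 1e-6:
                direction, norm = np.array([1.0, 0.0, 0.0]), 1.0
        cb_arr[i] = ca_arr[i] + CB_LENGTH * direction / norm

    residues = []
    atom_names = []
    elements = []
    coords = []
    for i in range(n_residues):
        res = Residue(chain, start_number + i, "", "ALA")
        res.atoms = {"CA": len(coords), "CB": len(coords) + 1}
        residues.append(res)
        atom_names += ["CA", "CB"]
        elements += ["C", "C"]
        coords += [ca_arr[i], cb_arr[i]]
    return Structure(residues, atom_names, elements, np.array(coords))


def random_coil(
    n_residues: int,
    rng: np.random.Generator,
    chain: str = "A",
    start_number: int = 1,
    axis_ratios: tuple[float, float, float] = (2.5, 1.4, 1.0),
) -> Structure:
    """Compact self-avoiding Cα random walk with pseudo-Cβ atoms.

    The walk is confined to a triaxial ellipsoid elongated along x
    (semi-axis ratios ``axis_ratios``), emulating the elongated,
    flattened shapes of the binding partners; three distinct axes keep
    the principal components well separated, as a globular blob would
    have a degenerate axis frame.
    """
    radius = 3.2 * n_residues ** (1 / 3) + 3.0
    ratios = np.asarray(axis_ratios, dtype=float)
    semi = radius * ratios / np.prod(ratios) ** (1 / 3)
    ca_arr = _self_avoiding_walk(
        n_residues, rng, lambda p: np.sum((p / semi) ** 2) <= 1.0, np.zeros(3)
    )
    ca_arr = ca_arr - ca_arr.mean(axis=0)
    return _structure_from_ca(ca_arr, chain, start_number)


def make_toy_complex(
    spec: SyntheticComplexSpec,
) -> tuple[Structure, Structure, Pose, list[Restraint]]:
    """Build a two-body toy complex with crosslinks planted at the truth.

    Returns (receptor, mobile-at-truth, true pose, restraints).  The
    receptor is a coil confined to a bowl-shaped shell that cradles a
    compact mobile coil, so that contact directions span a wide solid
    angle — as in the real complex, where the receptor core and C-tail
    wrap around the arrestin crest and N-domain; crosslinks on a single
    flat patch would leave the docked pose underdetermined.  The mobile
    structure is returned already positioned by the true pose, so
    scoring the combined complex at the truth gives zero restraint
    energy by construction.  Yields decrease with planted distance
    (B = clip(0.6 − 0.04·(d − 4), 0.05, 0.6) plus noise), loosely
    mimicking that tighter contacts crosslink more efficiently.
    """
    rng = np.random.default_rng(spec.seed)
    mobile_radius = 2.64 * spec.n_arrestin ** (1 / 3)  # ≈9 Å at n=40
    r_inner = mobile_radius + 4.0
    r_outer = r_inner + 6.0
    bowl = lambda p: r_inner <= np.linalg.norm(p) <= r_outer and p[1] <= 1.0
    rec_ca = _self_avoiding_walk(
        spec.n_receptor, rng, bowl, np.array([0.0, -(r_inner + 3.0), 0.0])
    )
    receptor = _structure_from_ca(rec_ca, "R")
    blob = lambda p: np.linalg.norm(p) <= mobile_radius
    mob_ca = _self_avoiding_walk(spec.n_arrestin, rng, blob, np.zeros(3))
    mobile_canonical = _structure_from_ca(mob_ca, "A")

    if spec.true_pose is not None:
        pose = spec.true_pose
    else:
        # nudge the mobile body along y until the closest inter-body Cα
        # contact falls in [4.2, 5.5] Å
        y = 0.0
        for _ in range(60):
            d_min = cdist(rec_ca, mob_ca + np.array([0.0, y, 0.0])).min()
            if d_min < 4.2:
                y += 0.3
            elif d_min > 5.5:
                y -= 0.3
            else:
                break
        pose = Pose(np.eye(3), np.array([0.0, y, 0.0]))
    mobile = mobile_canonical.with_coords(pose.apply(mobile_canonical.coords))

    # candidate pairs whose Cβ-Cβ distance at the truth lies in the band
    rec_cb = np.array(
        [receptor.coords[r.atoms["CB"]] for r in receptor.residues]
    )
    mob_cb = np.array([mobile.coords[r.atoms["CB"]] for r in mobile.residues])
    d = cdist(rec_cb, mob_cb)
    lo, hi = spec.distance_band
    cand = np.argwhere((d >= lo) & (d <= hi))
    if len(cand) < spec.n_pairs:
        raise ValueError(
            f"only {len(cand)} candidate pairs within {spec.distance_band} Å; "
            f"cannot plant {spec.n_pairs}"
        )
    # plant pairs spread around the interface (as the real crosslinks tile
    # the whole receptor footprint), not clustered in one patch: stratify
    # candidates by azimuth around the bowl axis and draw one per stratum
    axis_pos = np.arctan2(rec_cb[cand[:, 0], 2], rec_cb[cand[:, 0], 0])
    order = np.argsort(axis_pos)
    strata = np.array_split(order, spec.n_pairs)
    chosen = cand[[s[rng.integers(len(s))] for s in strata if len(s)]]
    if len(chosen) < spec.n_pairs:  # duplicate-free top-up from leftovers
        left = [i for i in order if not any((cand[i] == c).all() for c in chosen)]
        extra = rng.choice(left, size=spec.n_pairs - len(chosen), replace=False)
        chosen = np.vstack([chosen, cand[extra]])

    restraints = []
    for i_rec, i_mob in chosen:
        dist = d[i_rec, i_mob]
        b = np.clip(0.6 - 0.04 * (dist - 4.0), 0.05, 0.6)
        b = float(np.clip(b + rng.normal(0.0, spec.yield_noise_sd), 0.01, 1.0))
        restraints.append(
            Restraint(
                receptor=ResidueRef("R", receptor.residues[i_rec].number),
                arrestin=ResidueRef("A", mobile.residues[i_mob].number),
                weight=b,
            )
        )
    return receptor, mobile, pose, restraints


def simulate_blot_table(
    spec: SyntheticBlotSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate band/total intensity table plus ground-truth labels.

    Per replicate the measured yield is clip(true + N(0, sd), 0, 1);
    band = yield × total with totals drawn uniformly in [800, 1200]
    densitometry units.  Control rows draw from the background-noise
    distribution.  A pair's ground-truth label is positive when its true
    yield exceeds the control mean by the stated margin.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    labels = []
    for p, true_yield in enumerate(spec.true_yields):
        pair_id = f"pair_{p:04d}"
        for rep in range(spec.n_replicates):
            y = float(np.clip(true_yield + rng.normal(0.0, spec.noise_sd), 0.0, 1.0))
            total = rng.uniform(800.0, 1200.0)
            rows.append(
                (pair_id, f"R{p + 1}", f"A{p + 1}", rep, y * total, total, "pair")
            )
        labels.append(
            (pair_id, true_yield, true_yield > spec.control_mean + spec.significance_margin)
        )
    for rep in range(spec.control_n):
        y = float(np.clip(rng.normal(spec.control_mean, spec.control_sd), 0.0, 1.0))
        total = rng.uniform(800.0, 1200.0)
        rows.append(("control", "-", "-", rep, y * total, total, "control"))
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    truth = pd.DataFrame(labels, columns=["pair_id", "true_yield", "true_significant"])
    return table, truth


def simulate_trajectory(
    receptor: Structure,
    mobile: Structure,
    receptor_nose: "NoseDefinition",
    arrestin_nose: "NoseDefinition",
    angle_sds_deg: tuple[float, float, float] = (5.0, 5.0, 10.0),
    translation_sd: float = 0.5,
    n_frames: int = 100,
    seed: int = 0,
) -> tuple[TrajectoryEnsemble, pd.DataFrame]:
    """Ensemble of frames perturbing the mobile body's orientation.

    Per frame, target absolute relative-orientation angles
    (pitch, roll, yaw) are drawn as base + N(0, sd), where the base
    triple describes the input complex's own relative orientation, and
    the mobile body is rotated rigidly about its centroid so that the
    relative rotation between the two bodies' principal-axes frames
    (built with the supplied nose definitions) realizes exactly those
    angles; an isotropic normal translation jitter is added.  The
    planted per-frame table lists the absolute angles the orientation
    analysis should recover.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    from .structures import combine_structures  # local to avoid cycle at import
    from .orientation import euler_angles, frame_for_body

    complex_topo = combine_structures(receptor, mobile)
    n_rec_atoms = len(receptor.coords)
    centroid = mobile.ca_coordinates().mean(axis=0)

    rec_chain = receptor.chains[0]
    mob_chain = mobile.chains[0]
    X_rec = frame_for_body(complex_topo, rec_chain, receptor_nose).matrix
    X_arr0 = frame_for_body(complex_topo, mob_chain, arrestin_nose).matrix
    R_base = X_rec.T @ X_arr0
    base_angles = np.array(euler_angles(R_base).as_tuple())

    frames = np.empty((n_frames, len(complex_topo.coords), 3))
    planted = []
    sds = np.asarray(angle_sds_deg, dtype=float)
    for k in range(n_frames):
        pitch, roll, yaw = base_angles + rng.normal(0.0, sds)
        # measured relative rotation will be X_recᵀ · dR · X_arr0; solve
        # the body rotation dR realizing the target absolute angle triple
        R_target = rotation_from_angles(pitch, roll, yaw)
        dR = X_rec @ R_target @ X_arr0.T
        jitter = rng.normal(0.0, translation_sd, size=3)
        moved = (mobile.coords - centroid) @ dR.T + centroid + jitter
        frames[k, :n_rec_atoms] = receptor.coords
        frames[k, n_rec_atoms:] = moved
        planted.append((k, pitch, roll, yaw))
    table = pd.DataFrame(planted, columns=["frame", "pitch_deg", "roll_deg", "yaw_deg"])
    return TrajectoryEnsemble(complex_topo, frames), table
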