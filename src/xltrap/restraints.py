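"""Yield-weighted flat-bottom harmonic distance restraints and scoring.

Each validated crosslink (i, j) with mean yield B becomes a soft
flat-bottomed harmonic penalty on the anchor (Cβ–Cβ) distance d:

    E = sqrt(B) * [ max(d - hi, 0)^2 + max(lo - d, 0)^2 ]

with walls lo = 4.0 Å (penalizing atomic clash) and hi = 10.2 Å (the
adduct's published maximal Cβ–Cβ reach).  The penalty is zero on the
flat bottom, once-differentiable at both walls, and scales exactly as
sqrt(B), so quadrupling the yield doubles the energy.  B is stored as a
fraction in [0, 1] (densitometry ratio); energies are in weighted Å².

Satisfaction is additionally reported at 10.2 Å (strict adduct reach)
and 15.0 Å (reach plus a flexibility margin of a few Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import ResidueRef, Structure, pair_distances

__all__ = [
    "Restraint",
    "RestraintReport",
    "penalty_energy",
    "clash_energy",
    "score_model",
    "rank_models",
    "read_restraint_tsv",
    "restraints_to_frame",
    "DEFAULT_LOWER_WALL",
    "DEFAULT_UPPER_WALL",
    "DEFAULT_CUTOFFS",
]

DEFAULT_LOWER_WALL = 4.0
DEFAULT_UPPER_WALL = 10.2
DEFAULT_CUTOFFS = (10.2, 15.0)


@dataclass(frozen=True)
class Restraint:
    """One crosslink restraint: a residue pair, its weight and walls."""

    receptor: ResidueRef
    arrestin: ResidueRef
    weight: float
    lo: float = DEFAULT_LOWER_WALL
    hi: float = DEFAULT_UPPER_WALL

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("restraint weight B must be non-negative")
        if not 0 < self.lo < self.hi:
            raise ValueError("walls must satisfy 0 < lo < hi")

    @property
    def label(self) -> str:
        return f"{self.receptor}-{self.arrestin}"


def penalty_energy(
    d, B, lo: float = DEFAULT_LOWER_WALL, hi: float = DEFAULT_UPPER_WALL
):
    """Flat-bottom harmonic penalty sqrt(B)·[max(d−hi,0)² + max(lo−d,0)²].

    Accepts scalars or arrays (broadcast); exactly 0 for lo <= d <= hi.
    """
    d_arr = np.asarray(d, dtype=float)
    B_arr = np.asarray(B, dtype=float)
    if (d_arr < 0).any():
        raise ValueError("distance must be non-negative")
    if (B_arr < 0).any():
        raise ValueError("weight B must be non-negative")
    e = np.sqrt(B_arr) * (
        np.maximum(d_arr - hi, 0.0) ** 2 + np.maximum(lo - d_arr, 0.0) ** 2
    )
    if np.isscalar(d) and np.isscalar(B):
        return float(e)
    return e


def clash_energy(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    r_min: float = 4.0,
    weight: float = 1.0,
) -> float:
    """Soft-sphere overlap between two coordinate sets.

    Sum over inter-set pairs of weight·max(r_min − d, 0)²; a stand-in for
    repulsive non-bonded energetics at Cα resolution.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        raise ValueError("coordinate sets must be non-empty")
    d = cdist(a, b)
    overlap = np.maximum(r_min - d, 0.0)
    return float(weight * np.sum(overlap * overlap))


@dataclass
class RestraintReport:
    """Per-restraint distances/energies and aggregate satisfaction."""

    table: pd.DataFrame  # restraint, distance_A, yield_fraction, penalty, satisfied_*
    total_energy: float
    cutoffs: tuple[float, ...]
    counts_within: dict[float, int]

    @property
    def n_restraints(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def score_model(
    structure: Structure,
    restraints: list[Restraint],
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    fallback_calpha: bool = False,
) -> RestraintReport:
    """Score a complex model against a restraint list.

    Distances are anchor–anchor (Cβ, Cα for glycine); per-restraint and
    total flat-bottom energies are reported along with satisfaction
    counts at each cutoff.
    """
    pairs = [(r.receptor, r.arrestin) for r in restraints]
    dists = pair_distances(structure, pairs, fallback_calpha=fallback_calpha)
    weights = np.array([r.weight for r in restraints])
    energies = np.array(
        [penalty_energy(d, r.weight, r.lo, r.hi) for d, r in zip(dists, restraints)]
    ) if restraints else np.array([])
    data = {
        "restraint": [r.label for r in restraints],
        "distance_A": dists,
        "yield_fraction": weights,
        "penalty": energies,
    }
    counts = {}
    for c in cutoffs:
        flags = dists <= c
        data[f"satisfied_{c:g}A"] = flags
        counts[c] = int(flags.sum())
    return RestraintReport(
        table=pd.DataFrame(data),
        total_energy=float(energies.sum()),
        cutoffs=tuple(cutoffs),
        counts_within=counts,
    )


def rank_models(
    structures: list[Structure],
    restraints: list[Restraint],
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    fallback_calpha: bool = False,
) -> list[tuple[int, RestraintReport]]:
    """Order models by ascending total restraint energy.

    Ties are broken by satisfaction count at the first cutoff (more is
    better), then by input order.  Returns (original index, report).
    """
    if not structures:
        raise ValueError("need at least one structure to rank")
    reports = [
        score_model(s, restraints, cutoffs, fallback_calpha) for s in structures
    ]
    first_cut = cutoffs[0]
    order = sorted(
        range(len(structures)),
        key=lambda i: (
            reports[i].total_energy,
            -reports[i].counts_within[first_cut],
            i,
        ),
    )
    return [(i, reports[i]) for i in order]


def read_restraint_tsv(
    path: str,
    lo: float = DEFAULT_LOWER_WALL,
    hi: float = DEFAULT_UPPER_WALL,
) -> list[Restraint]:
    """Read a restraint list from TSV.

    Expected columns: receptor_chain, receptor_residue, arrestin_chain,
    arrestin_residue, yield (fraction in [0, 1]).
    """
    df = pd.read_csv(path, sep="\t")
    needed = {
        "receptor_chain", "receptor_residue", "arrestin_chain",
        "arrestin_residue", "yield",
    }
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"restraint table lacks columns: {sorted(missing)}")
    out = []
    for rc, rr, ac, ar, w in zip(
        df["receptor_chain"], df["receptor_residue"],
        df["arrestin_chain"], df["arrestin_residue"], df["yield"],
    ):
        out.append(
            Restraint(
                receptor=ResidueRef(str(rc), int(rr)),
                arrestin=ResidueRef(str(ac), int(ar)),
                weight=float(w),
                lo=lo,
                hi=hi,
            )
        )
    return out


def restraints_to_frame(restraints: list[Restraint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "receptor_chain": [r.receptor.chain for r in restraints],
            "receptor_residue": [r.receptor.number for r in restraints],
            "arrestin_chain": [r.arrestin.chain for r in restraints],
            "arrestin_residue": [r.arrestin.number for r in restraints],
            "yield": [r.weight for r in restraints],
        }
    )
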