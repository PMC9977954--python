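"""Replicate crosslinking quantifications and the significance filter.

A crosslinking *yield* is the densitometry intensity of the crosslinked
band divided by the total intensity of the arrestin signal (crosslinked
plus free), a fraction in [0, 1].  A pair of residues is accepted as a
proximity point when its replicate yields (n >= 3) are significantly
above a pooled background-noise control by BOTH a one-sided
equal-variance t-test (p < 0.02) and a one-sided Welch test (p < 0.05).

Both tests are one-sided (pair > control): the biology asks whether a
signal exceeds background, and requiring both tests to pass is the
conservative combination of the two thresholds.  No multiple-testing
correction is applied; the thresholds are used raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BlotMeasurement",
    "ControlSet",
    "CrosslinkPair",
    "crosslink_efficiency",
    "validate_pairs",
    "dataset_summary",
    "measurements_to_frame",
    "read_blot_table",
    "pairs_to_frame",
]

MEASUREMENT_COLUMNS = [
    "pair_id",
    "receptor_residue",
    "arrestin_residue",
    "replicate",
    "band",
    "total",
    "condition",
]


@dataclass(frozen=True)
class BlotMeasurement:
    """One quantified western-blot lane for one pair and replicate."""

    pair_id: str
    receptor_residue: str
    arrestin_residue: str
    replicate: int
    band: float
    total: float
    condition: str = "pair"  # "pair" or "control"

    def __post_init__(self) -> None:
        if self.band < 0:
            raise ValueError("band intensity must be non-negative")
        if self.total <= 0:
            raise ValueError("total intensity must be positive")


@dataclass
class ControlSet:
    """Pooled yield observations from non-specific-binding controls."""

    yields: np.ndarray

    def __post_init__(self) -> None:
        self.yields = np.asarray(self.yields, dtype=float).ravel()
        if self.yields.size == 0:
            raise ValueError("control set must be non-empty")
        if ((self.yields < 0) | (self.yields > 1)).any():
            raise ValueError("control yields must lie in [0, 1]")

    @classmethod
    def from_measurements(cls, measurements: pd.DataFrame | list) -> "ControlSet":
        df = measurements_to_frame(measurements)
        ctrl = df[df["condition"] == "control"]
        ys = [crosslink_efficiency(b, t) for b, t in zip(ctrl["band"], ctrl["total"])]
        return cls(np.array(ys))


@dataclass
class CrosslinkPair:
    """A residue pair with replicate yields and its significance verdict."""

    pair_id: str
    receptor_residue: str
    arrestin_residue: str
    yields: np.ndarray
    p_t: float = float("nan")
    p_welch: float = float("nan")
    verdict: str = "untested"  # significant | not-significant | untested

    def __post_init__(self) -> None:
        self.yields = np.asarray(self.yields, dtype=float).ravel()
        if self.yields.size < 1:
            raise ValueError("pair needs at least one replicate yield")
        if ((self.yields < 0) | (self.yields > 1)).any():
            raise ValueError("yields must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.yields.size)

    @property
    def mean_yield(self) -> float:
        """Mean yield B, the restraint weight entering the penalty as √B."""
        return float(self.yields.mean())


def crosslink_efficiency(band: float, total: float) -> float:
    """Crosslinked fraction: band intensity over total arrestin intensity.

    Clipped to [0, 1]; a band exceeding the total (quantification noise)
    is clipped to 1 with a logged warning.
    """
    if total <= 0:
        raise ValueError("total intensity must be positive")
    if band < 0:
        raise ValueError("band intensity must be non-negative")
    ratio = band / total
    if ratio > 1.0:
        logger.warning(
            "band intensity %.3g exceeds total %.3g; yield clipped to 1", band, total
        )
        return 1.0
    return float(ratio)


def measurements_to_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
        if missing:
            raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
        return measurements
    return pd.DataFrame([m.__dict__ for m in measurements], columns=MEASUREMENT_COLUMNS)


def read_blot_table(path: str, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    return measurements_to_frame(df)


def _one_sided_p(
    m1: np.ndarray, s1: np.ndarray, n1: np.ndarray, m2: float, s2: float, n2: int,
    equal_var: bool,
) -> np.ndarray:
    """Vectorized one-sided (greater) two-sample t-test p-values."""
    res = stats.ttest_ind_from_stats(
        mean1=m1, std1=s1, nobs1=n1,
        mean2=m2, std2=s2, nobs2=n2,
        equal_var=equal_var, alternative="greater",
    )
    return np.asarray(res.pvalue)


def validate_pairs(
    measurements,
    control: ControlSet,
    alpha_t: float = 0.02,
    alpha_welch: float = 0.05,
    min_n: int = 3,
) -> list[CrosslinkPair]:
    """Apply the two-test significance filter to replicate yields.

    Pair yields are tested against the pooled control by a one-sided
    equal-variance t-test and a one-sided Welch test; a pair is
    ``significant`` iff it has at least ``min_n`` replicates and both
    p-values fall strictly below their thresholds.  Pairs with fewer
    replicates are marked ``untested``.

    If both the pair and the control sample have zero variance the t
    statistic is undefined; the verdict then degenerates to an exact
    comparison of means (p = 0 if the pair mean exceeds the control
    mean, else p = 1).
    """
    df = measurements_to_frame(measurements)
    df = df[df["condition"] != "control"].copy()
    if df.empty:
        return []
    df["yield"] = [
        crosslink_efficiency(b, t) for b, t in zip(df["band"], df["total"])
    ]
    ctrl = control.yields
    c_mean = float(ctrl.mean())
    c_std = float(ctrl.std(ddof=1)) if ctrl.size > 1 else 0.0
    c_n = int(ctrl.size)

    grouped = df.groupby("pair_id", sort=False)
    agg = grouped.agg(
        receptor_residue=("receptor_residue", "first"),
        arrestin_residue=("arrestin_residue", "first"),
        n=("yield", "size"),
        mean=("yield", "mean"),
        std=("yield", lambda y: y.std(ddof=1) if len(y) > 1 else 0.0),
    )
    tested = agg["n"] >= min_n
    p_t = np.full(len(agg), np.nan)
    p_w = np.full(len(agg), np.nan)
    if tested.any():
        m1 = agg.loc[tested, "mean"].to_numpy()
        s1 = agg.loc[tested, "std"].to_numpy()
        n1 = agg.loc[tested, "n"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            pt = _one_sided_p(m1, s1, n1, c_mean, c_std, c_n, equal_var=True)
            pw = _one_sided_p(m1, s1, n1, c_mean, c_std, c_n, equal_var=False)
        degenerate = (s1 == 0.0) & (c_std == 0.0)
        if degenerate.any():
            exact = np.where(m1[degenerate] > c_mean, 0.0, 1.0)
            pt[degenerate] = exact
            pw[degenerate] = exact
        p_t[tested.to_numpy()] = pt
        p_w[tested.to_numpy()] = pw

    pairs: list[CrosslinkPair] = []
    yields_by_pair = grouped["yield"].apply(np.array)
    for i, (pair_id, row) in enumerate(agg.iterrows()):
        if tested.iloc[i]:
            significant = p_t[i] < alpha_t and p_w[i] < alpha_welch
            verdict = "significant" if significant else "not-significant"
        else:
            verdict = "untested"
        pairs.append(
            CrosslinkPair(
                pair_id=str(pair_id),
                receptor_residue=str(row["receptor_residue"]),
                arrestin_residue=str(row["arrestin_residue"]),
                yields=yields_by_pair.loc[pair_id],
                p_t=float(p_t[i]),
                p_welch=float(p_w[i]),
                verdict=verdict,
            )
        )
    return pairs


def dataset_summary(
    pairs: list[CrosslinkPair], detection_floor: float = 0.0
) -> tuple[int, int, int]:
    """Counts (tested, detectable, significant).

    ``detectable`` counts pairs whose mean yield strictly exceeds the
    detection floor (default 0: any nonzero quantified band).
    """
    tested = len(pairs)
    detectable = sum(1 for p in pairs if p.mean_yield > detection_floor)
    significant = sum(1 for p in pairs if p.verdict == "significant")
    return tested, detectable, significant


def pairs_to_frame(pairs: list[CrosslinkPair]) -> pd.DataFrame:
    """Tabulate validated pairs (yields as fractions, p-values raw)."""
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "receptor_residue": [p.receptor_residue for p in pairs],
            "arrestin_residue": [p.arrestin_residue for p in pairs],
            "n": [p.n for p in pairs],
            "mean_yield_fraction": [p.mean_yield for p in pairs],
            "p_t": [p.p_t for p in pairs],
            "p_welch": [p.p_welch for p in pairs],
            "verdict": [p.verdict for p in pairs],
        }
    )
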