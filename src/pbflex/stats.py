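"""Flexibility statistics over PB trajectories.

From a frames × positions PB label matrix this module derives the
per-position PB frequency vector f_x, the equivalent number of PBs

    N_eq = exp(−Σ_x f_x ln f_x),        x over the 16 PBs, 0·ln 0 := 0,

its between-system absolute difference ΔN_eq, the PB-profile L1 distance

    ΔPB = Σ_x |f¹_x − f²_x|  ∈ [0, 2],

a six-bin flexibility categorisation of N_eq, and Pearson correlations
between flexibility metrics (N_eq, RMSF, crystallographic B-factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pbflex.alphabet import PB_LABELS, UNASSIGNED, PBTrajectory

__all__ = [
    "FrequencyProfile",
    "FlexibilityProfile",
    "ComparisonProfile",
    "CATEGORY_ORDER",
    "frequency_map",
    "neq",
    "neq_profile",
    "delta_neq",
    "delta_pb",
    "categorize",
    "category_summary",
    "pearson",
    "logo_matrix",
]

_RIGID_EPS = 1e-6

CATEGORY_ORDER = (
    "rigid",
    "quite_rigid",
    "moderate",
    "flexible",
    "extremely_flexible",
    "disordered",
)

# (label, upper N_eq bound); bins are half-open (low, high] above "rigid",
# which is reserved for N_eq numerically equal to 1.
_CATEGORY_BINS = (
    ("quite_rigid", 2.0),
    ("moderate", 4.0),
    ("flexible", 6.0),
    ("extremely_flexible", 8.0),
    ("disordered", 16.0),
)


@dataclass
class FrequencyProfile:
    """Per-position 16-vector of PB frequencies f_x.

    ``freqs`` rows sum to 1 for positions with at least one assigned (non-Z)
    frame and are NaN for empty positions; ``counts`` holds the number of
    contributing frames per position.
    """

    freqs: np.ndarray  # (n_positions, 16)
    counts: np.ndarray  # (n_positions,)
    resids: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.resids = np.asarray(self.resids)
        if self.freqs.shape != (len(self.resids), 16):
            raise ValueError("freqs must be (n_positions, 16)")
        filled = self.counts > 0
        rows = self.freqs[filled]
        if rows.size and (np.any(rows < 0) or np.any(rows > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if rows.size and not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("non-empty frequency rows must sum to 1")

    @property
    def empty(self) -> np.ndarray:
        return self.counts == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freqs, index=pd.Index(self.resids, name="position"), columns=list(PB_LABELS)
        )


@dataclass
class FlexibilityProfile:
    """Per-position N_eq with category, optional RMSF and B-factor."""

    neq: np.ndarray
    category: np.ndarray  # dtype object/str, "" where N_eq undefined
    resids: np.ndarray
    rmsf: np.ndarray | None = None
    bfactor: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"position": self.resids, "neq": self.neq, "category": self.category}
        if self.rmsf is not None:
            data["rmsf"] = self.rmsf
        if self.bfactor is not None:
            data["bfactor"] = self.bfactor
        return pd.DataFrame(data)


@dataclass
class ComparisonProfile:
    """Per-position ΔN_eq and ΔPB between two systems (NaN = undefined)."""

    delta_neq: np.ndarray
    delta_pb: np.ndarray
    resids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.resids,
                "delta_neq": self.delta_neq,
                "delta_pb": self.delta_pb,
            }
        )


def frequency_map(pbtraj: PBTrajectory) -> FrequencyProfile:
    """Per-position PB frequencies over frames, excluding ``Z`` labels.

    f_x = (frames labelled x) / (frames with any non-Z label); positions
    where every frame is Z are flagged empty (NaN row), not a NaN-free zero
    row.
    """
    if pbtraj.n_frames == 0:
        raise ValueError("need at least one frame")
    counts = np.zeros((pbtraj.n_positions, 16), dtype=int)
    for k, label in enumerate(PB_LABELS):
        counts[:, k] = (pbtraj.labels == label).sum(axis=0)
    total = counts.sum(axis=1)
    freqs = np.full((pbtraj.n_positions, 16), np.nan)
    filled = total > 0
    freqs[filled] = counts[filled] / total[filled, None]
    return FrequencyProfile(freqs=freqs, counts=total, resids=pbtraj.resids)


def neq(freq_row) -> float:
    """Equivalent number of PBs: exp of the Shannon entropy (natural log).

    1 when a single PB has frequency 1; 16 for the uniform distribution.
    Empty (NaN) rows yield NaN.
    """
    row = np.asarray(freq_row, dtype=float)
    if np.isnan(row).any():
        return float("nan")
    if row.shape != (16,):
        raise ValueError("frequency row must have 16 components")
    if abs(row.sum() - 1.0) > 1e-6:
        raise ValueError("frequency row must sum to 1")
    pos = row[row > 0]
    return float(np.exp(-np.sum(pos * np.log(pos))))


def neq_profile(freqs: FrequencyProfile) -> np.ndarray:
    """Vectorised N_eq over all positions (NaN where empty)."""
    return np.array([neq(r) if c else np.nan for r, c in zip(freqs.freqs, freqs.counts)])


def delta_neq(neq1: np.ndarray, neq2: np.ndarray) -> np.ndarray:
    """Per-position |N_eq¹ − N_eq²|; NaN where either side is undefined."""
    a, b = np.asarray(neq1, dtype=float), np.asarray(neq2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the position axis")
    return np.abs(a - b)


def delta_pb(freqs1, freqs2) -> np.ndarray:
    """Per-position ΔPB = Σ_x |f¹_x − f²_x| ∈ [0, 2].

    0 means identical PB distributions; 2 means completely disjoint PB
    usage.  Undefined (empty) positions on either side give NaN.
    """
    f1 = freqs1.freqs if isinstance(freqs1, FrequencyProfile) else np.atleast_2d(freqs1)
    f2 = freqs2.freqs if isinstance(freqs2, FrequencyProfile) else np.atleast_2d(freqs2)
    if f1.shape != f2.shape:
        raise ValueError("profiles must share the position axis")
    return np.abs(f1 - f2).sum(axis=-1)


def categorize(neq_value: float) -> str:
    """Map an N_eq value to its flexibility category.

    ``rigid`` is reserved for N_eq numerically 1 (within 1e−6); above that
    the bins are half-open: (1,2] quite_rigid, (2,4] moderate, (4,6]
    flexible, (6,8] extremely_flexible, (8,16] disordered.
    """
    v = float(neq_value)
    if np.isnan(v):
        return ""
    if v < 1.0 - _RIGID_EPS or v > 16.0 + _RIGID_EPS:
        raise ValueError(f"N_eq {v} outside [1, 16] — upstream bug")
    if v <= 1.0 + _RIGID_EPS:
        return "rigid"
    for label, upper in _CATEGORY_BINS:
        if v <= upper:
            return label
    return "disordered"


def category_summary(flex: FlexibilityProfile | np.ndarray) -> pd.Series:
    """Percentage of positions per category, over categorised positions."""
    cats = flex.category if isinstance(flex, FlexibilityProfile) else np.asarray(flex)
    cats = cats[cats != ""]
    if len(cats) == 0:
        raise ValueError("no categorized positions")
    counts = pd.Series(cats).value_counts()
    out = pd.Series(0.0, index=list(CATEGORY_ORDER))
    out.update(100.0 * counts / counts.sum())
    return out


def pearson(series_a, series_b) -> float:
    """Pearson correlation with pairwise deletion of undefined positions.

    Returns NaN (undefined marker) when fewer than 3 pairs remain or either
    series has zero variance.
    """
    from scipy import stats as _sps

    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share the position axis")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 paired defined values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(_sps.pearsonr(a, b).statistic)


def logo_matrix(freqs: FrequencyProfile, position_range=None) -> pd.DataFrame:
    """Positions × 16 frequency matrix for sequence-logo rendering.

    `position_range` is an inclusive (start, end) pair in author numbering;
    a range entirely outside the profile returns an empty matrix with a
    warning.
    """
    df = freqs.to_frame()
    if position_range is not None:
        start, end = position_range
        df = df.loc[(df.index >= start) & (df.index <= end)]
        if df.empty:
            warnings.warn(
                f"position range {position_range} outside profile", stacklevel=2
            )
    return df
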