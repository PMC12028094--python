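"""The Protein Block structural alphabet and per-residue assignment.

Protein Blocks (PBs) are 16 local backbone prototypes, labelled ``a``..``p``,
each defined by 8 reference dihedrals spanning a 5-residue window.  A
conformation is encoded one letter per residue by matching the window of
φ/ψ angles centred on that residue to the nearest prototype under the RMSDA
(root mean square deviation of angles) pseudometric with periodic wrapping.
PB ``m`` is the α-helix core prototype and ``d`` the central β-strand.

The reference-angle table is not learned here; it is the canonical published
16×8 matrix, shipped as a versioned CSV whose SHA-256 checksum is validated
on load.  Window composition follows the reference assignment convention
(ψ_{i−2}, φ_{i−1}, ψ_{i−1}, φ_i, ψ_i, φ_{i+1}, ψ_{i+1}, φ_{i+2}) with
uniform weighting of the 8 angles.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from pbflex.geometry import DihedralSeries

__all__ = [
    "PB_LABELS",
    "WINDOW_SIZE",
    "UNASSIGNED",
    "PBAlphabet",
    "PBTrajectory",
    "load_alphabet",
    "window_vector",
    "rmsda",
    "assign_frame",
    "assign_ensemble",
]

PB_LABELS = tuple(chr(c) for c in range(ord("a"), ord("p") + 1))
WINDOW_SIZE = 5  # residues per assignment window
UNASSIGNED = "Z"

# Order of the 8 window dihedrals relative to the central residue i.
WINDOW_LAYOUT = (
    ("psi", -2),
    ("phi", -1),
    ("psi", -1),
    ("phi", 0),
    ("psi", 0),
    ("phi", +1),
    ("psi", +1),
    ("phi", +2),
)

_TABLE_SHA256 = "07344bd510dd451a51f908a37cd82e83dba9bb001e7e5c5edf229deab2627172"


@dataclass(frozen=True)
class PBAlphabet:
    """16 PB labels and their 16×8 reference dihedral matrix (degrees)."""

    labels: tuple
    reference_angles: np.ndarray
    checksum: str

    def __post_init__(self) -> None:
        if len(self.labels) != 16:
            raise ValueError("expected 16 PB labels")
        if self.reference_angles.shape != (16, 8):
            raise ValueError("reference angle matrix must be 16x8")
        if np.any(self.reference_angles <= -180) or np.any(self.reference_angles > 180):
            raise ValueError("reference angles must lie in (-180, 180]")

    @property
    def window_size(self) -> int:
        return WINDOW_SIZE


@dataclass
class PBTrajectory:
    """Frames × positions PB labels; ``Z`` where the window is incomplete."""

    labels: np.ndarray  # (n_frames, n_positions), dtype '<U1'
    resids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype="U1"))
        self.resids = np.asarray(self.resids)
        if self.labels.shape[1] != len(self.resids):
            raise ValueError("position axis mismatch")
        valid = set(PB_LABELS) | {UNASSIGNED}
        seen = set(np.unique(self.labels))
        if not seen <= valid:
            raise ValueError(f"invalid PB labels: {sorted(seen - valid)}")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_positions(self) -> int:
        return self.labels.shape[1]


@lru_cache(maxsize=1)
def load_alphabet() -> PBAlphabet:
    """Load and validate the canonical PB reference-angle table."""
    from importlib.resources import files

    raw = files("pbflex.data").joinpath("pb_reference_angles.csv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE_SHA256:
        raise RuntimeError(
            "PB reference table checksum mismatch — data file corrupted "
            f"(got {digest})"
        )
    import io as _io

    df = pd.read_csv(_io.BytesIO(raw))
    labels = tuple(df["pb"])
    if labels != PB_LABELS:
        raise RuntimeError("PB table rows must be labelled a..p in order")
    matrix = df.drop(columns="pb").to_numpy(dtype=float)
    return PBAlphabet(labels=labels, reference_angles=matrix, checksum=digest)


def window_vector(dihedrals: DihedralSeries, frame: int, position: int):
    """8 window dihedrals around `position` (0-based), or None if undefined.

    Order: ψ_{i−2}, φ_{i−1}, ψ_{i−1}, φ_i, ψ_i, φ_{i+1}, ψ_{i+1}, φ_{i+2}.
    Out-of-range positions and windows containing any undefined angle yield
    None rather than an error.
    """
    n = dihedrals.n_residues
    if position < 2 or position > n - 3:
        return None
    angles = {"phi": dihedrals.phi[frame], "psi": dihedrals.psi[frame]}
    vec = np.array([angles[kind][position + off] for kind, off in WINDOW_LAYOUT])
    if np.isnan(vec).any():
        return None
    return vec


def rmsda(v, w) -> float:
    """Root mean square deviation of angles with periodic wrapping (degrees).

    Differences are wrapped into [−180, 180] before squaring, so the result
    is invariant under adding multiples of 360° to either argument.
    """
    if v is None or w is None:
        return np.nan
    diff = (np.asarray(v, dtype=float) - np.asarray(w, dtype=float) + 180.0) % 360.0 - 180.0
    return float(np.sqrt(np.mean(diff**2)))


def _window_matrix(dihedrals: DihedralSeries) -> np.ndarray:
    """All window vectors at once: (n_frames, n_positions, 8), NaN rows undefined."""
    nf, nr = dihedrals.n_frames, dihedrals.n_residues
    out = np.full((nf, nr, 8), np.nan)
    if nr < WINDOW_SIZE:
        return out
    centre = np.arange(2, nr - 2)
    angles = {"phi": dihedrals.phi, "psi": dihedrals.psi}
    for k, (kind, off) in enumerate(WINDOW_LAYOUT):
        out[:, centre, k] = angles[kind][:, centre + off]
    return out


def assign_ensemble(dihedrals: DihedralSeries, alphabet: PBAlphabet | None = None) -> PBTrajectory:
    """Assign one PB per residue per frame by minimal RMSDA.

    Ties are broken toward the first label in a..p order; positions whose
    5-residue window is incomplete get ``Z``.
    """
    if alphabet is None:
        alphabet = load_alphabet()
    windows = _window_matrix(dihedrals)  # (nf, nr, 8)
    ref = alphabet.reference_angles  # (16, 8)
    diff = (windows[:, :, None, :] - ref[None, None, :, :] + 180.0) % 360.0 - 180.0
    with np.errstate(invalid="ignore"):
        dist = np.sqrt(np.mean(diff**2, axis=-1))  # (nf, nr, 16)
    # np.argmin returns the first minimum -> alphabetical tie-break for free
    best = np.argmin(dist, axis=-1)
    labels = np.array(alphabet.labels, dtype="U1")[best]
    undefined = np.isnan(windows).any(axis=-1)
    labels[undefined] = UNASSIGNED
    return PBTrajectory(labels=labels, resids=dihedrals.resids)


def assign_frame(dihedrals: DihedralSeries, frame: int, alphabet: PBAlphabet | None = None) -> str:
    """PB string for one frame (``Z`` at unassignable positions)."""
    sub = DihedralSeries(
        phi=dihedrals.phi[frame : frame + 1],
        psi=dihedrals.psi[frame : frame + 1],
        resids=dihedrals.resids,
    )
    return "".join(assign_ensemble(sub, alphabet).labels[0])
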