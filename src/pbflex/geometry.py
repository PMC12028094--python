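"""Backbone geometry: torsions, φ/ψ extraction, superposition, RMSD, RMSF.

All distance metrics operate on Cα atoms only.  Angles are reported in
degrees in the half-open interval (−180, 180], IUPAC sign convention
(cis = 0°, trans = 180°).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from pbflex.io import ConformationalEnsemble

__all__ = [
    "GeometryError",
    "DihedralSeries",
    "FluctuationProfile",
    "torsion",
    "dihedral_batch",
    "backbone_dihedrals",
    "superpose",
    "rmsd_series",
    "rmsf",
    "wrap_angle",
]


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear points)."""


def wrap_angle(angle):
    """Map angles (degrees) to the canonical interval (−180, 180]."""
    wrapped = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


@dataclass
class DihedralSeries:
    """Per-frame, per-residue backbone (φ, ψ) in degrees.

    NaN marks undefined angles: φ of the first and ψ of the last residue of a
    chain, and any angle touching an incomplete residue.
    """

    phi: np.ndarray  # (n_frames, n_residues)
    psi: np.ndarray
    resids: np.ndarray  # author numbering

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have identical shape")
        self.resids = np.asarray(self.resids)
        if self.phi.shape[1] != len(self.resids):
            raise ValueError("residue axis mismatch")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


@dataclass
class FluctuationProfile:
    """Per-residue Cα RMSF (Å), author numbering."""

    rmsf: np.ndarray
    resids: np.ndarray
    fitted: bool

    def __post_init__(self) -> None:
        defined = self.rmsf[~np.isnan(self.rmsf)]
        if (defined < 0).any():
            raise ValueError("RMSF must be non-negative")


_DEGENERACY_TOL = 1e-10


def torsion(p1, p2, p3, p4) -> float:
    """Dihedral angle (degrees) defined by four points, in (−180, 180].

    Sign follows the IUPAC convention: looking down the p2→p3 axis, the
    angle is positive when p4 is rotated clockwise from p1; cis = 0°,
    trans = 180°.

    Raises
    ------
    GeometryError
        If consecutive points coincide or three consecutive points are
        collinear (the plane normals vanish).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < _DEGENERACY_TOL:
            raise GeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERACY_TOL or np.linalg.norm(n2) < _DEGENERACY_TOL:
        raise GeometryError("collinear consecutive points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized torsion over leading axes; NaN inputs propagate to NaN."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    with np.errstate(invalid="ignore"):
        return wrap_angle(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(ensemble: ConformationalEnsemble) -> DihedralSeries:
    """Extract φ/ψ for every residue of every frame.

    φ_i = torsion(C_{i−1}, N_i, CA_i, C_i);
    ψ_i = torsion(N_i, CA_i, C_i, N_{i+1}).
    Chain termini and positions adjacent to incomplete residues are NaN.
    """
    n_idx = ensemble.backbone_index("N")
    ca_idx = ensemble.backbone_index("CA")
    c_idx = ensemble.backbone_index("C")
    nres = ensemble.n_residues
    nframes = ensemble.n_frames
    chains = ensemble.residues["chain"].to_numpy()

    def coords_of(idx):
        out = np.full((nframes, nres, 3), np.nan)
        have = idx >= 0
        out[:, have, :] = ensemble.coords[:, idx[have], :]
        return out

    N, CA, C = coords_of(n_idx), coords_of(ca_idx), coords_of(c_idx)

    phi = np.full((nframes, nres), np.nan)
    psi = np.full((nframes, nres), np.nan)
    same_prev = np.zeros(nres, dtype=bool)
    same_prev[1:] = chains[1:] == chains[:-1]
    same_next = np.zeros(nres, dtype=bool)
    same_next[:-1] = chains[:-1] == chains[1:]

    if nres >= 2:
        interior = np.where(same_prev)[0]
        if interior.size:
            phi[:, interior] = dihedral_batch(
                C[:, interior - 1], N[:, interior], CA[:, interior], C[:, interior]
            )
        interior = np.where(same_next)[0]
        if interior.size:
            psi[:, interior] = dihedral_batch(
                N[:, interior], CA[:, interior], C[:, interior], N[:, interior + 1]
            )
    incomplete = ~ensemble.residues["complete"].to_numpy()
    if incomplete.any():
        warnings.warn(
            "incomplete residues produce undefined dihedrals at affected positions",
            stacklevel=2,
        )
    return DihedralSeries(phi=phi, psi=psi, resids=ensemble.resids)


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits `reference`; the rotation
    is proper (det = +1).
    """
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(ensemble: ConformationalEnsemble, reference_frame: int = 0) -> np.ndarray:
    """Per-frame Cα RMSD (Å) to a reference frame, after superposition."""
    ca = ensemble.ca_coords()
    if not (0 <= reference_frame < ensemble.n_frames):
        raise IndexError(f"reference frame {reference_frame} out of range")
    ok = ~np.isnan(ca[0]).any(axis=1)
    ref = ca[reference_frame][ok]
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        _, _, out[f] = superpose(ca[f][ok], ref)
    return out


def rmsf(ensemble: ConformationalEnsemble, fit: bool = True) -> FluctuationProfile:
    """Per-residue Cα RMSF about the mean position.

    With ``fit=True`` every frame is first superposed onto frame 0 on Cα
    (one pass, no iterative mean refitting) before the mean structure and the
    fluctuations are computed.  ``fit=False`` uses raw coordinates, for which
    the isotropic-noise expectation RMSF = σ√3 is exact.
    """
    ca = ensemble.ca_coords()
    ok = ~np.isnan(ca).any(axis=(0, 2))
    work = ca.copy()
    if fit and ensemble.n_frames > 1:
        ref = ca[0][ok]
        for f in range(ensemble.n_frames):
            R, t, _ = superpose(ca[f][ok], ref)
            work[f] = ca[f] @ R.T + t
    mean = work.mean(axis=0)
    msd = np.mean(np.sum((work - mean) ** 2, axis=2), axis=0)
    values = np.sqrt(msd)
    values[~ok] = np.nan
    return FluctuationProfile(rmsf=values, resids=ensemble.resids, fitted=fit)
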