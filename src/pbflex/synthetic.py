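"""Synthetic conformational ensembles with known ground truth.

Real MD trajectories of the size analysed in kinase-flexibility studies are
rarely redistributable, so every pipeline stage here is validated against
generated ensembles whose expected statistics are known in closed form:

* template-mixture dihedral sampling — each frame is a full-length φ/ψ
  template drawn with known weights (plus optional wrapped-Gaussian angular
  noise), so the expected per-position N_eq is the exponential entropy of the
  mixture weights wherever the templates map to distinct PBs;
* internal-coordinate chain building (NeRF) — converts a dihedral series to
  backbone Cartesian coordinates with fixed bond lengths/angles, so torsion
  recomputation round-trips exactly;
* Gaussian positional ensembles — isotropic per-atom noise of known σ, for
  which the unfitted RMSF expectation is σ√3.

Mixtures are over whole-chain templates rather than independent per-position
PB draws: overlapping 5-residue windows make independent sampling
geometrically inconsistent, whereas template mixtures give exact,
self-consistent ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pbflex.geometry import DihedralSeries, wrap_angle
from pbflex.io import ConformationalEnsemble

__all__ = [
    "BOND_N_CA",
    "BOND_CA_C",
    "BOND_C_N",
    "ANGLE_N_CA_C",
    "ANGLE_CA_C_N",
    "ANGLE_C_N_CA",
    "OMEGA",
    "TemplateMixtureSpec",
    "MixtureSample",
    "GaussianEnsembleSpec",
    "helix_dihedrals",
    "strand_dihedrals",
    "sample_dihedral_frames",
    "build_chain",
    "backbone_atom_table",
    "ensemble_from_dihedrals",
    "gaussian_ensemble",
]

# Fixed idealized backbone geometry (synthetic chains only, not a modelling
# claim): bond lengths in Å, angles in degrees, peptide bond kept trans.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0


@dataclass
class TemplateMixtureSpec:
    """K full-length φ/ψ templates mixed with weights w_k.

    ``templates`` is a list of ``(phi, psi)`` array pairs of equal length
    (NaN at the chain termini as usual).  ``noise_sd`` is the standard
    deviation (degrees) of wrapped-Gaussian angular noise added per angle.
    With ``exact_counts`` the number of frames per template is fixed by
    largest-remainder apportionment of ``weights * n_frames`` (the frame
    order is still shuffled), so realized mixture proportions match the
    weights exactly; otherwise each frame draws its template independently.
    """

    templates: list
    weights: np.ndarray
    noise_sd: float = 0.0
    n_frames: int = 100
    seed: int = 0
    exact_counts: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.templates) != len(self.weights):
            raise ValueError("one weight per template required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        lengths = {len(t[0]) for t in self.templates} | {len(t[1]) for t in self.templates}
        if len(lengths) != 1:
            raise ValueError("all templates must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class MixtureSample:
    """A sampled dihedral series plus its frame→template ground truth."""

    dihedrals: DihedralSeries
    template_ids: np.ndarray
    spec: TemplateMixtureSpec

    def realized_weights(self) -> np.ndarray:
        counts = np.bincount(self.template_ids, minlength=len(self.spec.templates))
        return counts / counts.sum()


@dataclass
class GaussianEnsembleSpec:
    """Base coordinates plus isotropic per-atom positional noise of sd σ (Å)."""

    base_coords: np.ndarray
    atoms: pd.DataFrame
    sd: float | np.ndarray = 0.5
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_coords = np.asarray(self.base_coords, dtype=float)
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd must be non-negative")


def helix_dihedrals(n_residues: int, phi: float = -57.0, psi: float = -47.0):
    """Ideal repetitive α-helix (φ, ψ) arrays with NaN termini."""
    return _repetitive(n_residues, phi, psi)


def strand_dihedrals(n_residues: int, phi: float = -120.0, psi: float = 135.0):
    """Ideal repetitive β-strand (φ, ψ) arrays with NaN termini."""
    return _repetitive(n_residues, phi, psi)


def _repetitive(n: int, phi: float, psi: float):
    phis = np.full(n, float(phi))
    psis = np.full(n, float(psi))
    phis[0] = np.nan
    psis[-1] = np.nan
    return phis, psis


def sample_dihedral_frames(spec: TemplateMixtureSpec) -> MixtureSample:
    """Draw frames from the template mixture (seeded, reproducible).

    Each frame copies one template's full φ/ψ arrays and, when
    ``noise_sd > 0``, adds independent Gaussian angular noise re-wrapped to
    (−180, 180].  NaN (undefined) angles stay NaN.  The template of every
    frame is recorded as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    K = len(spec.templates)
    n = spec.n_frames
    if spec.exact_counts:
        raw = spec.weights * n
        counts = np.floor(raw).astype(int)
        remainder = n - counts.sum()
        if remainder:
            order = np.argsort(-(raw - counts))
            counts[order[:remainder]] += 1
        ids = np.repeat(np.arange(K), counts)
        rng.shuffle(ids)
    else:
        ids = rng.choice(K, size=n, p=spec.weights)
    phi_t = np.stack([np.asarray(t[0], dtype=float) for t in spec.templates])
    psi_t = np.stack([np.asarray(t[1], dtype=float) for t in spec.templates])
    phi = phi_t[ids].copy()
    psi = psi_t[ids].copy()
    if spec.noise_sd > 0:
        phi = wrap_angle(phi + rng.normal(0.0, spec.noise_sd, size=phi.shape))
        psi = wrap_angle(psi + rng.normal(0.0, spec.noise_sd, size=psi.shape))
    resids = np.arange(1, phi.shape[1] + 1)
    return MixtureSample(
        dihedrals=DihedralSeries(phi=phi, psi=psi, resids=resids),
        template_ids=ids,
        spec=spec,
    )


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: position d with |cd| = bond, ∠(b,c,d) = angle and
    torsion(a,b,c,d) = torsion_deg."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # z-component negated so the resulting torsion follows the IUPAC sign
    # convention used by `pbflex.geometry.torsion`
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            -bond * np.sin(theta) * np.sin(chi),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_chain(phi: np.ndarray, psi: np.ndarray, origin=None) -> np.ndarray:
    """Build N/CA/C backbone coordinates from φ/ψ by internal-coordinate
    chain extension.

    φ of the first residue and ψ of the last are ignored (they are undefined
    by construction); any other NaN raises.  Bond lengths, bond angles and
    the trans peptide ω are the fixed module constants, so recomputing
    torsions from the built chain reproduces the inputs.

    Returns an array of shape ``(3 * n_residues, 3)`` ordered
    N₁, CA₁, C₁, N₂, …
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if n < 1:
        raise ValueError("need at least one residue")
    if np.isnan(phi[1:]).any() or np.isnan(psi[:-1]).any():
        raise ValueError("undefined interior dihedral")

    coords = np.empty((3 * n, 3))
    N0 = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    coords[0] = N0
    coords[1] = N0 + np.array([BOND_N_CA, 0.0, 0.0])
    alpha = np.radians(ANGLE_N_CA_C)
    coords[2] = coords[1] + BOND_CA_C * np.array([-np.cos(alpha), np.sin(alpha), 0.0])
    for i in range(n - 1):
        Ni, CAi, Ci = coords[3 * i], coords[3 * i + 1], coords[3 * i + 2]
        Nn = _place_atom(Ni, CAi, Ci, BOND_C_N, ANGLE_CA_C_N, psi[i])
        CAn = _place_atom(CAi, Ci, Nn, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        Cn = _place_atom(Ci, Nn, CAn, BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])
        coords[3 * (i + 1)] = Nn
        coords[3 * (i + 1) + 1] = CAn
        coords[3 * (i + 1) + 2] = Cn
    return coords


def backbone_atom_table(
    n_residues: int, chain: str = "A", start_resid: int = 1, resname: str = "ALA"
) -> pd.DataFrame:
    """Atom table matching the N/CA/C layout of :func:`build_chain`."""
    resids = np.repeat(np.arange(start_resid, start_resid + n_residues), 3)
    names = np.tile(["N", "CA", "C"], n_residues)
    return pd.DataFrame(
        {
            "resid": resids,
            "resname": resname,
            "atom_name": names,
            "chain": chain,
        }
    )


def ensemble_from_dihedrals(
    dihedrals: DihedralSeries, chain: str = "A", start_resid: int = 1
) -> ConformationalEnsemble:
    """Build one backbone chain per frame and stack into an ensemble."""
    frames = np.stack(
        [build_chain(dihedrals.phi[f], dihedrals.psi[f]) for f in range(dihedrals.n_frames)]
    )
    atoms = backbone_atom_table(dihedrals.n_residues, chain=chain, start_resid=start_resid)
    return ConformationalEnsemble(frames, atoms)


def gaussian_ensemble(spec: GaussianEnsembleSpec) -> ConformationalEnsemble:
    """Base structure plus independent isotropic Gaussian offsets per atom.

    Every coordinate of every atom of every frame receives N(0, σ²) noise,
    so the unfitted RMSF of each atom converges to σ√3.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.base_coords.shape[0]
    sd = np.broadcast_to(np.asarray(spec.sd, dtype=float), (n_atoms,))
    noise = rng.normal(0.0, 1.0, size=(spec.n_frames, n_atoms, 3)) * sd[None, :, None]
    coords = spec.base_coords[None] + noise
    return ConformationalEnsemble(coords, spec.atoms)
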