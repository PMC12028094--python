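"""Reading and writing conformational ensembles and tabular profiles.

The central container is :class:`ConformationalEnsemble`: an ordered series of
coordinate frames sharing a single atom table.  The mandatory on-disk dialect
is multi-model PDB (one MODEL record per frame, file order preserved); binary
trajectory formats plus a topology are supported through an MDAnalysis-backed
adapter.  All public coordinates are author residue numbers — internal 0-based
indices never appear in outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConformationalEnsemble",
    "RegionAnnotation",
    "BFactorProfile",
    "EnsembleError",
    "read_ensemble",
    "write_ensemble",
    "read_bfactors",
    "read_regions",
    "write_regions",
    "default_jh1_regions",
    "write_profile",
    "read_profile",
    "write_frequency_map",
    "read_frequency_map",
    "write_pb_fasta",
    "read_pb_fasta",
]

BACKBONE_ATOMS = ("N", "CA", "C")

# Water residue names excluded alongside heteroatoms.
_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL", "H2O"}


class EnsembleError(ValueError):
    """Raised when an input violates the ensemble contract."""


@dataclass
class ConformationalEnsemble:
    """Frames x atoms Cartesian coordinates (Å) with per-atom metadata.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    atoms
        One row per atom with columns ``resid`` (author residue number),
        ``resname``, ``atom_name`` and ``chain``; identical for every frame.
    replicate_ids
        Optional per-frame tag identifying the source replicate, kept so that
        pooled multi-replicate ensembles can still be split for per-replicate
        statistics.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    replicate_ids: np.ndarray | None = None
    _residues: pd.DataFrame = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if len(self.atoms) != self.coords.shape[1]:
            raise EnsembleError(
                f"atom table has {len(self.atoms)} rows but frames have "
                f"{self.coords.shape[1]} atoms"
            )
        required = {"resid", "resname", "atom_name", "chain"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise EnsembleError(f"atom table missing columns: {sorted(missing)}")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if len(self.replicate_ids) != self.coords.shape[0]:
                raise EnsembleError("replicate_ids length must equal n_frames")
        for chain, sub in self.atoms.groupby("chain", sort=False):
            resids = sub["resid"].drop_duplicates().to_numpy()
            if np.any(np.diff(resids) <= 0):
                raise EnsembleError(
                    f"author residue numbers not strictly increasing in chain {chain!r}"
                )
        self._residues = self._build_residue_table()

    def _build_residue_table(self) -> pd.DataFrame:
        rows = []
        for (chain, resid), sub in self.atoms.groupby(["chain", "resid"], sort=False):
            names = set(sub["atom_name"])
            complete = all(a in names for a in BACKBONE_ATOMS)
            ca_rows = sub.index[sub["atom_name"] == "CA"]
            rows.append(
                {
                    "chain": chain,
                    "resid": resid,
                    "resname": sub["resname"].iloc[0],
                    "complete": complete,
                    "ca_index": int(ca_rows[0]) if len(ca_rows) else -1,
                }
            )
        table = pd.DataFrame(rows)
        if not table["complete"].all():
            bad = table.loc[~table["complete"], "resid"].tolist()
            warnings.warn(
                f"residues missing backbone atoms flagged incomplete: {bad}",
                stacklevel=3,
            )
        return table

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self._residues)

    @property
    def residues(self) -> pd.DataFrame:
        """Per-residue table: chain, resid, resname, complete, ca_index."""
        return self._residues

    @property
    def resids(self) -> np.ndarray:
        return self._residues["resid"].to_numpy()

    def backbone_index(self, atom_name: str) -> np.ndarray:
        """Atom-table row of `atom_name` per residue, -1 where absent."""
        out = np.full(self.n_residues, -1, dtype=int)
        lookup = {
            (c, r): i
            for i, (c, r, a) in enumerate(
                zip(self.atoms["chain"], self.atoms["resid"], self.atoms["atom_name"])
            )
            if a == atom_name
        }
        for j, (c, r) in enumerate(zip(self._residues["chain"], self._residues["resid"])):
            out[j] = lookup.get((c, r), -1)
        return out

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates, shape (n_frames, n_residues, 3); NaN where Cα absent."""
        idx = self._residues["ca_index"].to_numpy()
        out = np.full((self.n_frames, self.n_residues, 3), np.nan)
        have = idx >= 0
        out[:, have, :] = self.coords[:, idx[have], :]
        return out

    def slice_frames(self, selector) -> "ConformationalEnsemble":
        reps = self.replicate_ids[selector] if self.replicate_ids is not None else None
        return ConformationalEnsemble(self.coords[selector], self.atoms, reps)


@dataclass
class RegionAnnotation:
    """Named residue ranges (author numbering, both ends inclusive)."""

    entries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")
        for name, start, end in self.entries:
            if start > end:
                raise ValueError(f"region {name!r}: start {start} > end {end}")

    def members(self, name: str) -> tuple[int, int]:
        for n, s, e in self.entries:
            if n == name:
                return (s, e)
        raise KeyError(name)


@dataclass
class BFactorProfile:
    """Per-residue Cα B-factors (Å²) in author numbering; NaN = missing Cα."""

    values: pd.Series  # index = author resid

    def __post_init__(self) -> None:
        defined = self.values.dropna()
        if (defined < 0).any():
            raise ValueError("B-factors must be non-negative")


# ---------------------------------------------------------------------------
# Ensemble I/O
# ---------------------------------------------------------------------------

def _atoms_from_biotite(arr) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "resid": arr.res_id,
            "resname": arr.res_name,
            "atom_name": arr.atom_name,
            "chain": arr.chain_id,
        }
    )


def _filter_biotite(arr, chain: str | None):
    import biotite.structure as struc

    keep = ~arr.hetero
    keep &= ~np.isin(arr.res_name, list(_WATER_NAMES))
    keep &= arr.element != "H"
    arr = arr[keep]
    chains = np.unique(arr.chain_id)
    if chain is None:
        if len(chains) > 1:
            raise EnsembleError(
                f"input has multiple chains {list(chains)}; select one explicitly"
            )
    else:
        arr = arr[arr.chain_id == chain]
        if arr.array_length() == 0:
            raise EnsembleError(f"chain {chain!r} not found")
    return arr


def _read_pdb_ensemble(path, chain: str | None) -> ConformationalEnsemble:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    frames = []
    signature = None
    for model in range(1, n_models + 1):
        arr = pdb.get_structure(model=model, altloc="occupancy")
        arr = _filter_biotite(arr, chain)
        sig = list(zip(arr.chain_id, arr.res_id, arr.atom_name))
        if signature is None:
            signature = sig
            atoms = _atoms_from_biotite(arr)
        elif sig != signature:
            raise EnsembleError(
                f"model {model} has a different atom table than model 1 "
                f"(first divergence at atom {_first_divergence(signature, sig)})"
            )
        frames.append(arr.coord)
    return ConformationalEnsemble(np.stack(frames), atoms)


def _first_divergence(a: list, b: list) -> str:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return f"{i}: {x} vs {y}"
    return f"count {len(a)} vs {len(b)}"


def _read_binary_ensemble(path, topology, chain: str | None) -> ConformationalEnsemble:
    import MDAnalysis as mda

    if topology is None:
        raise EnsembleError("binary trajectory formats require a topology file")
    u = mda.Universe(str(topology), str(path))
    sel = "protein and not element H"
    ag = u.select_atoms(sel)
    if chain is not None:
        ag = ag.select_atoms(f"segid {chain} or chainID {chain}")
    if ag.n_atoms == 0:
        raise EnsembleError("no protein atoms selected")
    coords = np.stack([ag.positions.copy() for _ in u.trajectory])
    try:
        chains = ag.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        chains = ag.segids
    atoms = pd.DataFrame(
        {
            "resid": ag.resids,
            "resname": ag.resnames,
            "atom_name": ag.names,
            "chain": chains,
        }
    )
    uniq = atoms["chain"].unique()
    if chain is None and len(uniq) > 1:
        raise EnsembleError(f"input has multiple chains {list(uniq)}; select one explicitly")
    return ConformationalEnsemble(coords, atoms)


def read_ensemble(
    paths,
    format_hint: str | None = None,
    chain: str | None = None,
    topology=None,
) -> ConformationalEnsemble:
    """Read one or several trajectory files into a pooled ensemble.

    Multiple input files are pooled frame-wise into a single ensemble (the
    replicate of origin is retained in ``replicate_ids``).  Waters and
    heteroatoms are excluded; hydrogens are dropped.

    Parameters
    ----------
    paths
        A path or list of paths.  Multi-model PDB is detected from the
        extension unless `format_hint` says otherwise.
    format_hint
        ``"pdb"`` or ``"binary"``; by default inferred from the suffix.
    chain
        Chain identifier, required when the file holds several chains.
    topology
        Topology file, required for binary trajectory formats.
    """
    from pathlib import Path

    if isinstance(paths, (str, Path)):
        paths = [paths]
    parts, reps = [], []
    for rep, p in enumerate(paths):
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        hint = format_hint or ("pdb" if p.suffix.lower() in {".pdb", ".ent"} else "binary")
        if hint == "pdb":
            ens = _read_pdb_ensemble(p, chain)
        else:
            ens = _read_binary_ensemble(p, topology, chain)
        parts.append(ens)
        reps.extend([rep] * ens.n_frames)
    first = parts[0]
    for i, other in enumerate(parts[1:], start=2):
        if not first.atoms.equals(other.atoms):
            raise EnsembleError(f"input file {i} has a different atom table than file 1")
    coords = np.concatenate([p.coords for p in parts])
    return ConformationalEnsemble(coords, first.atoms, np.asarray(reps))


def write_ensemble(ensemble: ConformationalEnsemble, path) -> None:
    """Write a multi-model PDB, one MODEL per frame, frame order preserved."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = ensemble.n_atoms
    template = struc.AtomArray(n)
    template.chain_id = ensemble.atoms["chain"].to_numpy(dtype="U4")
    template.res_id = ensemble.atoms["resid"].to_numpy(dtype=int)
    template.res_name = ensemble.atoms["resname"].to_numpy(dtype="U5")
    template.atom_name = ensemble.atoms["atom_name"].to_numpy(dtype="U6")
    template.element = np.array(
        [name.strip()[:1] for name in ensemble.atoms["atom_name"]], dtype="U2"
    )
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([template] * ensemble.n_frames)
    stack.coord = ensemble.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_bfactors(path, chain: str | None = None) -> BFactorProfile:
    """Per-residue B-factors from the Cα atoms of a single-model PDB.

    Residues lacking a Cα get NaN (missing), never 0.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["b_factor"])
    arr = _filter_biotite(arr, chain)
    resids = np.unique(arr.res_id)
    values = pd.Series(np.nan, index=pd.Index(resids, name="position"), dtype=float)
    ca = arr[arr.atom_name == "CA"]
    for rid, b in zip(ca.res_id, ca.b_factor):
        values.loc[rid] = float(b)
    return BFactorProfile(values)


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

def read_regions(path) -> RegionAnnotation:
    """Read a region TSV: header line, then ``name<TAB>start<TAB>end`` rows."""
    entries = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            name, start, end = parts
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer bounds") from exc
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            entries.append((name, start, end))
    return RegionAnnotation(entries)


def write_regions(regions: RegionAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tstart\tend\n")
        for name, start, end in regions.entries:
            fh.write(f"{name}\t{start}\t{end}\n")


def default_jh1_regions() -> RegionAnnotation:
    """JAK2 JH1 annotation shipped with the package.

    Printed bounds: G-rich loop 858-860, activation loop 1010-1015, C-helix
    region 885-890.  Bounds marked "(approx)" are interpolated from the
    region descriptions and should be overridden with a user TSV when exact
    limits matter.
    """
    from importlib.resources import files

    return read_regions(files("pbflex.data").joinpath("jh1_regions.tsv"))


def write_profile(profile: pd.DataFrame, path) -> None:
    """Write a per-position profile CSV (``position`` column first)."""
    cols = list(profile.columns)
    if "position" not in cols:
        profile = profile.reset_index().rename(columns={profile.index.name or "index": "position"})
        cols = list(profile.columns)
    ordered = ["position"] + [c for c in cols if c != "position"]
    profile[ordered].to_csv(path, index=False)


def read_profile(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "position" not in df.columns:
        raise ValueError(f"{path}: missing 'position' column")
    return df


def write_frequency_map(freqs, path) -> None:
    """Write a positions x 16 frequency matrix CSV with columns a..p."""
    df = freqs.to_frame() if hasattr(freqs, "to_frame") else freqs
    df.to_csv(path, index=True, index_label="position")


def read_frequency_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="position")
    expected = [chr(c) for c in range(ord("a"), ord("p") + 1)]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected 16 columns labelled a..p")
    return df


def write_pb_fasta(pbtraj, path, width: int = 60) -> None:
    """Serialize a PB trajectory: one FASTA record of PB letters per frame."""
    with open(path, "w") as fh:
        for f in range(pbtraj.n_frames):
            seq = "".join(pbtraj.labels[f])
            fh.write(f">frame_{f}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pb_fasta(path, resids=None):
    """Read a PB-fasta written by :func:`write_pb_fasta`."""
    from pbflex.alphabet import PBTrajectory

    seqs, current = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
            else:
                current.append(line)
        if current:
            seqs.append("".join(current))
    if not seqs:
        raise ValueError(f"{path}: no records")
    labels = np.array([list(s) for s in seqs], dtype="U1")
    if resids is None:
        resids = np.arange(1, labels.shape[1] + 1)
    return PBTrajectory(labels=labels, resids=np.asarray(resids))
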