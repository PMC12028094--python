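"""End-to-end system analysis and system-vs-system comparison.

`analyze_system` chains dihedral extraction → PB assignment → frequency
map → N_eq / categories, alongside Cα RMSF and a per-frame RMSD series, into
one :class:`SystemResult`.  `compare_systems` turns two results into
per-position ΔN_eq / ΔPB / ΔRMSF, aggregates them over annotated regions
(e.g. the kinase G-rich loop or activation loop) and flags positions whose
ΔPB exceeds a threshold (default 0.4, the level at which a PB-composition
change is typically called notable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pbflex import alphabet as _alphabet
from pbflex import geometry as _geometry
from pbflex import stats as _stats
from pbflex.io import ConformationalEnsemble, RegionAnnotation

__all__ = [
    "SystemResult",
    "ComparisonReport",
    "analyze_system",
    "compare_systems",
    "interpret_delta_pb",
    "save_result",
    "load_result",
]


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class SystemResult:
    """All per-system outputs on a single author-numbered position axis."""

    name: str
    freq: _stats.FrequencyProfile
    flex: _stats.FlexibilityProfile
    rmsd: np.ndarray
    pb_traj: _alphabet.PBTrajectory | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def resids(self) -> np.ndarray:
        return self.freq.resids


@dataclass
class ComparisonReport:
    """Pairwise comparison: per-position deltas, region aggregates, flags."""

    system_a: str
    system_b: str
    profile: _stats.ComparisonProfile
    delta_rmsf: np.ndarray
    region_table: pd.DataFrame
    flagged: pd.DataFrame
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        df = self.profile.to_frame()
        df["delta_rmsf"] = self.delta_rmsf
        return df


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def analyze_system(
    ensemble: ConformationalEnsemble,
    name: str = "system",
    alphabet: _alphabet.PBAlphabet | None = None,
    fit: bool = True,
    stride: int = 1,
    bfactors=None,
    seed: int | None = None,
) -> SystemResult:
    """Run the full single-system analysis on an ensemble.

    Parameters
    ----------
    ensemble
        Frames to analyse (already pooled across replicates if desired).
    fit
        Superpose frames before RMSF (passed to :func:`pbflex.geometry.rmsf`).
    stride
        Keep every `stride`-th frame before any statistics.
    bfactors
        Optional :class:`pbflex.io.BFactorProfile` aligned by author numbering.
    seed
        Recorded in metadata when the ensemble is synthetic; not used here.
    """
    if alphabet is None:
        alphabet = _alphabet.load_alphabet()
    if stride > 1:
        ensemble = ensemble.slice_frames(slice(None, None, stride))
    dihedrals = _stage("backbone_dihedrals", _geometry.backbone_dihedrals, ensemble)
    pb_traj = _stage("pb_assignment", _alphabet.assign_ensemble, dihedrals, alphabet)
    freq = _stage("frequency_map", _stats.frequency_map, pb_traj)
    neq_values = _stage("neq", _stats.neq_profile, freq)
    categories = np.array([_stats.categorize(v) for v in neq_values], dtype=object)
    fluct = _stage("rmsf", _geometry.rmsf, ensemble, fit)
    rmsd = _stage("rmsd_series", _geometry.rmsd_series, ensemble, 0)
    bvals = None
    if bfactors is not None:
        bvals = np.array(
            [bfactors.values.get(r, np.nan) for r in freq.resids], dtype=float
        )
    flex = _stats.FlexibilityProfile(
        neq=neq_values,
        category=categories,
        resids=freq.resids,
        rmsf=fluct.rmsf,
        bfactor=bvals,
    )
    metadata = {
        "system": name,
        "n_frames": int(ensemble.n_frames),
        "n_residues": int(ensemble.n_residues),
        "fit_mode": "fitted" if fit else "unfitted",
        "stride": stride,
        "alphabet_checksum": alphabet.checksum,
        "seed": seed,
    }
    return SystemResult(
        name=name, freq=freq, flex=flex, rmsd=rmsd, pb_traj=pb_traj, metadata=metadata
    )


def compare_systems(
    result_a: SystemResult,
    result_b: SystemResult,
    regions: RegionAnnotation | None = None,
    delta_pb_threshold: float = 0.4,
) -> ComparisonReport:
    """Compare two analysed systems position by position and per region.

    Both results must share the author-numbered position axis; region
    aggregates (mean and max of ΔPB, ΔN_eq, ΔRMSF) are computed over the
    defined positions inside each annotated range.
    """
    ra, rb = result_a.resids, result_b.resids
    if len(ra) != len(rb) or np.any(ra != rb):
        bad = _first_axis_mismatch(ra, rb)
        raise ValueError(f"position axes differ (first mismatch at {bad})")
    dneq = _stats.delta_neq(result_a.flex.neq, result_b.flex.neq)
    dpb = _stats.delta_pb(result_a.freq, result_b.freq)
    drmsf = np.abs(result_a.flex.rmsf - result_b.flex.rmsf)
    profile = _stats.ComparisonProfile(delta_neq=dneq, delta_pb=dpb, resids=ra)

    rows = []
    if regions is not None:
        for name, start, end in regions.entries:
            mask = (ra >= start) & (ra <= end)
            rows.append(
                {
                    "region": name,
                    "start": start,
                    "end": end,
                    "mean_delta_pb": np.nanmean(dpb[mask]) if mask.any() else np.nan,
                    "max_delta_pb": np.nanmax(dpb[mask]) if mask.any() else np.nan,
                    "mean_delta_neq": np.nanmean(dneq[mask]) if mask.any() else np.nan,
                    "max_delta_neq": np.nanmax(dneq[mask]) if mask.any() else np.nan,
                    "mean_delta_rmsf": np.nanmean(drmsf[mask]) if mask.any() else np.nan,
                    "max_delta_rmsf": np.nanmax(drmsf[mask]) if mask.any() else np.nan,
                }
            )
    region_table = pd.DataFrame(
        rows,
        columns=[
            "region",
            "start",
            "end",
            "mean_delta_pb",
            "max_delta_pb",
            "mean_delta_neq",
            "max_delta_neq",
            "mean_delta_rmsf",
            "max_delta_rmsf",
        ],
    )

    over = ~np.isnan(dpb) & (dpb > delta_pb_threshold)
    flagged = pd.DataFrame({"position": ra[over], "delta_pb": dpb[over]})
    flagged = flagged.sort_values("delta_pb", ascending=False).reset_index(drop=True)
    return ComparisonReport(
        system_a=result_a.name,
        system_b=result_b.name,
        profile=profile,
        delta_rmsf=drmsf,
        region_table=region_table,
        flagged=flagged,
        threshold=delta_pb_threshold,
    )


def _first_axis_mismatch(a, b):
    for i in range(min(len(a), len(b))):
        if a[i] != b[i]:
            return f"index {i}: {a[i]} vs {b[i]}"
    return f"length {len(a)} vs {len(b)}"


def interpret_delta_pb(value: float) -> float:
    """Fraction of PB assignments that differ, i.e. ΔPB / 2.

    A ΔPB of 0.7 corresponds to 35% of the PB composition differing between
    the two systems; 2 means a completely disjoint composition.
    """
    v = float(value)
    if v < 0 or v > 2:
        raise ValueError(f"delta PB {v} outside [0, 2]")
    return v / 2.0


# ---------------------------------------------------------------------------
# Serialization — regeneration from disk is bit-identical to in-memory results
# ---------------------------------------------------------------------------

def save_result(result: SystemResult, directory) -> None:
    """Write a SystemResult as CSV/JSON files under `directory`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    freq_df = result.freq.to_frame()
    freq_df.insert(0, "count", result.freq.counts)
    freq_df.to_csv(directory / "frequencies.csv", float_format="%.17g")
    result.flex.to_frame().to_csv(directory / "flexibility.csv", index=False, float_format="%.17g")
    pd.DataFrame({"frame": np.arange(len(result.rmsd)), "rmsd": result.rmsd}).to_csv(
        directory / "rmsd.csv", index=False, float_format="%.17g"
    )
    with open(directory / "metadata.json", "w") as fh:
        json.dump({**result.metadata, "name": result.name}, fh, indent=2)


def load_result(directory) -> SystemResult:
    """Reload a SystemResult written by :func:`save_result`."""
    directory = Path(directory)
    freq_df = pd.read_csv(directory / "frequencies.csv", index_col="position")
    counts = freq_df.pop("count").to_numpy()
    freqs = freq_df.to_numpy(dtype=float)
    resids = freq_df.index.to_numpy()
    freq = _stats.FrequencyProfile(freqs=freqs, counts=counts, resids=resids)
    flex_df = pd.read_csv(directory / "flexibility.csv")
    flex = _stats.FlexibilityProfile(
        neq=flex_df["neq"].to_numpy(dtype=float),
        category=flex_df["category"].fillna("").to_numpy(dtype=object),
        resids=flex_df["position"].to_numpy(),
        rmsf=flex_df["rmsf"].to_numpy(dtype=float) if "rmsf" in flex_df else None,
        bfactor=flex_df["bfactor"].to_numpy(dtype=float) if "bfactor" in flex_df else None,
    )
    rmsd = pd.read_csv(directory / "rmsd.csv")["rmsd"].to_numpy(dtype=float)
    with open(directory / "metadata.json") as fh:
        metadata = json.load(fh)
    name = metadata.pop("name", "system")
    return SystemResult(name=name, freq=freq, flex=flex, rmsd=rmsd, metadata=metadata)
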