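"""Readers and writers for the pipeline's on-disk formats.

Trajectories come either from standard structure/trajectory files
(PDB/GRO + XTC/TRR/DCD, read through MDAnalysis with selection strings
supplied in a YAML annotation file) or from a self-contained long-format
CSV with columns

    frame, time_ps, atom_id, role, anchor, monolayer, x_nm, y_nm, z_nm, mass_amu

where ``role`` is one of ``phosphorus``, ``pd``, ``c2``, ``spine``,
``other``; ``anchor`` names an anchor role (e.g. ``arg281_ca``) or is
empty; and ``monolayer`` (``proximal``/``distal``) is set for phosphorus
atoms.  The protein selection is the union of all non-phosphorus atoms.

Electrophysiology sweeps are tidy CSVs (episode, time_ms, current_uA) with
a protocol YAML; fluorometry sweeps are tidy CSVs (voltage_mV, time_ms,
dF_over_F) with a metadata YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .enzyme_activity import EpisodicRecording, ProtocolMeta
from .errors import ConfigurationError, MissingAnnotationError
from .fluorometry import FluorescenceSweepSet, FVDataset
from .membrane_binding import ANCHOR_ROLES, AnnotatedTrajectory, Frame, SystemMeta

__all__ = [
    "load_trajectory_csv",
    "save_trajectory_csv",
    "load_trajectory_mdanalysis",
    "load_recording_csv",
    "save_recording_csv",
    "load_protocol_yaml",
    "load_fluorescence_csv",
    "save_fluorescence_csv",
    "load_fv_csv",
    "save_fv_csv",
]

_SELECTION_ROLES = ("pd", "c2", "spine", "other")


def load_trajectory_csv(path, resolution: str, bilayer: str) -> AnnotatedTrajectory:
    """Read the long-format trajectory CSV into an annotated trajectory."""
    df = pd.read_csv(path, dtype={"atom_id": str, "role": str})
    required = {"frame", "time_ps", "atom_id", "role", "x_nm", "y_nm", "z_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"trajectory CSV missing columns: {sorted(missing)}")
    for opt in ("anchor", "monolayer", "mass_amu"):
        if opt not in df.columns:
            df[opt] = np.nan

    first = df[df["frame"] == df["frame"].min()]
    atom_ids = list(first["atom_id"])
    index = {a: i for i, a in enumerate(atom_ids)}

    anchors: dict[str, str] = {}
    selections: dict[str, list[str]] = {r: [] for r in _SELECTION_ROLES}
    phosphorus: dict[str, list[str]] = {"proximal": [], "distal": []}
    masses: dict[str, float] = {}
    for _, row in first.iterrows():
        aid, role = row["atom_id"], row["role"]
        if role == "phosphorus":
            mono = row["monolayer"]
            if mono not in phosphorus:
                raise ConfigurationError(f"unknown monolayer {mono!r} for atom {aid}")
            phosphorus[mono].append(aid)
        elif role in _SELECTION_ROLES:
            selections[role].append(aid)
        else:
            raise ConfigurationError(f"unknown role {role!r} for atom {aid}")
        if isinstance(row["anchor"], str) and row["anchor"]:
            anchors[row["anchor"]] = aid
        if np.isfinite(row.get("mass_amu", np.nan)):
            masses[aid] = float(row["mass_amu"])

    protein = [a for r in _SELECTION_ROLES for a in selections[r]]
    meta = SystemMeta(
        resolution=resolution,
        bilayer=bilayer,
        anchors=anchors,
        selections={
            "pd": tuple(selections["pd"]),
            "c2": tuple(selections["c2"]),
            "spine": tuple(selections["spine"]) or tuple(selections["pd"][:1]),
            "protein": tuple(protein),
        },
        phosphorus={k: tuple(v) for k, v in phosphorus.items() if v},
        masses=masses if len(masses) == len(atom_ids) else None,
    )

    frames = []
    for fid, grp in df.groupby("frame", sort=True):
        grp = grp.set_index("atom_id")
        try:
            coords = grp.loc[atom_ids, ["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        except KeyError as exc:
            raise MissingAnnotationError(f"frame {fid} is missing atoms: {exc}") from None
        frames.append(Frame(float(grp["time_ps"].iloc[0]), coords, index, meta))
    return AnnotatedTrajectory(frames=frames, meta=meta)


def save_trajectory_csv(traj: AnnotatedTrajectory, path) -> None:
    """Write an annotated trajectory to the long-format CSV."""
    meta = traj.meta
    anchor_of = {aid: role for role, aid in meta.anchors.items()}
    role_of: dict[str, str] = {}
    mono_of: dict[str, str] = {}
    for mono, ids in meta.phosphorus.items():
        for a in ids:
            role_of[a] = "phosphorus"
            mono_of[a] = mono
    for label in ("spine", "pd", "c2"):  # spine first so pd/c2 take precedence
        for a in meta.selections.get(label, ()):
            role_of[a] = label if label != "spine" else role_of.get(a, "spine")
    for a in meta.selections.get("protein", ()):
        role_of.setdefault(a, "other")

    rows = []
    atom_ids = sorted(traj.frames[0].index, key=traj.frames[0].index.get)
    for fi, frame in enumerate(traj.frames):
        for a in atom_ids:
            x, y, z = frame.coords_nm[frame.index[a]]
            rows.append(
                {
                    "frame": fi,
                    "time_ps": frame.time_ps,
                    "atom_id": a,
                    "role": role_of.get(a, "other"),
                    "anchor": anchor_of.get(a, ""),
                    "monolayer": mono_of.get(a, ""),
                    "x_nm": x,
                    "y_nm": y,
                    "z_nm": z,
                    "mass_amu": meta.masses.get(a, np.nan) if meta.masses else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_trajectory_mdanalysis(
    structure,
    trajectory=None,
    annotations: Mapping | str | Path = None,
    resolution: str = "AT",
    bilayer: str = "POPC",
) -> AnnotatedTrajectory:
    """Build an annotated trajectory from structure/trajectory files.

    ``annotations`` is a YAML path or mapping with MDAnalysis selection
    strings::

        anchors:
          arg281_ca: "resid 281 and name CA"
          ...
        selections:
          pd: "resid 248:516"
          c2: "resid 517:576"
          spine: "resid 284 285"
        phosphorus:
          proximal: "name P and prop z < 50"
          distal: "name P and prop z >= 50"

    Coordinates are converted from MDAnalysis Å to nm.
    """
    import MDAnalysis as mda

    if annotations is None:
        raise ConfigurationError("an annotations mapping or YAML path is required")
    if not isinstance(annotations, Mapping):
        with open(annotations) as fh:
            annotations = yaml.safe_load(fh)

    u = mda.Universe(str(structure), *( [str(trajectory)] if trajectory else [] ))

    def ids_of(sel: str) -> tuple[str, ...]:
        group = u.select_atoms(sel)
        return tuple(str(ix) for ix in group.indices)

    anchors = {}
    for role in ANCHOR_ROLES:
        sel = annotations["anchors"].get(role)
        if sel is None:
            raise MissingAnnotationError(f"anchor selection for {role!r} missing")
        ids = ids_of(sel)
        if len(ids) != 1:
            raise MissingAnnotationError(f"anchor {role!r} selects {len(ids)} atoms, expected 1")
        anchors[role] = ids[0]

    sels = {label: ids_of(s) for label, s in annotations["selections"].items()}
    sels.setdefault("protein", tuple(sorted(set(sels.get("pd", ())) | set(sels.get("c2", ())))))
    phos = {mono: ids_of(s) for mono, s in annotations["phosphorus"].items()}

    try:
        masses = {str(ix): float(m) for ix, m in zip(u.atoms.indices, u.atoms.masses)}
    except mda.exceptions.NoDataError:
        masses = None

    meta = SystemMeta(
        resolution=resolution, bilayer=bilayer, anchors=anchors,
        selections={k: tuple(v) for k, v in sels.items()}, phosphorus=phos, masses=masses,
    )
    index = {str(ix): i for i, ix in enumerate(u.atoms.indices)}
    frames = []
    for ts in u.trajectory:
        frames.append(Frame(float(ts.time), u.atoms.positions.astype(float) / 10.0, index, meta))
    if len(frames) > 1:
        times = [f.time_ps for f in frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            for i, f in enumerate(frames):  # files without time stamps
                f.time_ps = float(i)
    return AnnotatedTrajectory(frames=frames, meta=meta)


# ---------------------------------------------------------------------------
# electrophysiology


def load_protocol_yaml(path) -> ProtocolMeta:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = {}
    for key in ("ramp_window_ms", "test_window_ms", "depol_window_ms"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("test_voltage_mV", "depol_voltage_mV", "holding_mV"):
        if key in raw:
            kwargs[key] = float(raw[key])
    return ProtocolMeta(**kwargs)


def load_recording_csv(path, protocol: ProtocolMeta) -> EpisodicRecording:
    df = pd.read_csv(path)
    episodes = []
    time_ms = None
    for _, grp in df.groupby("episode", sort=True):
        t = grp["time_ms"].to_numpy(dtype=float)
        if time_ms is None:
            time_ms = t
        episodes.append(grp["current_uA"].to_numpy(dtype=float))
    return EpisodicRecording(time_ms=time_ms, episodes=episodes, protocol=protocol)


def save_recording_csv(recording: EpisodicRecording, path) -> None:
    recording.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fluorometry


def load_fluorescence_csv(path, meta: Mapping | None = None) -> FluorescenceSweepSet:
    """Tidy CSV (voltage_mV, time_ms, dF_over_F) plus optional metadata."""
    df = pd.read_csv(path)
    meta = dict(meta or {})
    traces = {}
    time_ms = None
    for v, grp in df.groupby("voltage_mV", sort=True):
        t = grp["time_ms"].to_numpy(dtype=float)
        if time_ms is None:
            time_ms = t
        traces[float(v)] = grp["dF_over_F"].to_numpy(dtype=float)
    kwargs = {}
    for key in ("probe", "holding_mV"):
        if key in meta:
            kwargs[key] = meta[key]
    for key in ("pulse_window_ms", "baseline_window_ms"):
        if key in meta:
            kwargs[key] = tuple(meta[key])
    return FluorescenceSweepSet(time_ms=time_ms, traces=traces, **kwargs)


def save_fluorescence_csv(sweeps: FluorescenceSweepSet, path) -> None:
    frames = [
        pd.DataFrame({"voltage_mV": v, "time_ms": sweeps.time_ms, "dF_over_F": tr})
        for v, tr in sorted(sweeps.traces.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_fv_csv(path) -> FVDataset:
    df = pd.read_csv(path)
    return FVDataset(
        voltage_mV=df["voltage_mV"].to_numpy(dtype=float),
        f=df["f"].to_numpy(dtype=float),
        strategy=str(df["strategy"].iloc[0]) if "strategy" in df.columns else "file",
    )


def save_fv_csv(fv: FVDataset, path) -> None:
    pd.DataFrame(
        {"voltage_mV": fv.voltage_mV, "f": fv.f, "strategy": fv.strategy}
    ).to_csv(path, index=False)
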