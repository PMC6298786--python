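"""Frame-by-frame membrane-binding and orientation classification.

The cytoplasmic region of a voltage-sensing phosphatase (VSP) carries two
domains — the phosphatase domain (PD) and the C2 domain — that associate
peripherally with the inner leaflet of the plasma membrane.  This module
classifies, for every trajectory frame,

* whether each domain is *bound* to the bilayer, judged by the depth of the
  domain's highest atom (the "top atom") relative to the plane of lipid
  phosphorus atoms of the proximal monolayer (the "phosphorus layer"), with
  resolution- and composition-specific cutoffs; and
* whether the protein sits in the *productive orientation*, judged by the
  angle between the membrane normal (+z) and the cross product of two
  anchor-residue vectors drawn from the Arg-281 Cα to the midpoints of the
  Lys-516/Arg-520 and Lys-555/Lys-558 Cα pairs.

Per-frame results are collected in a :class:`BindingTrace` and summarized as
time fractions (percent of simulated time bound / productive), the quantities
conventionally tabulated per simulation run.

Coordinates are ingested in nm (the native unit of GRO/XTC files); all
reported depths are in Å, the unit in which binding cutoffs are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateOrientationError,
    MissingAnnotationError,
)

__all__ = [
    "ANCHOR_ROLES",
    "ORIENTATION_ANCHORS",
    "DEFAULT_BINDING_CUTOFFS_A",
    "ClassifierConfig",
    "SystemMeta",
    "Frame",
    "AnnotatedTrajectory",
    "BindingTrace",
    "BindingSummary",
    "phosphorus_plane_z",
    "rel_top_z",
    "binding_state",
    "orientation_vectors",
    "productive_angle",
    "classify_productive",
    "com_z",
    "catalytic_depth_asymmetry",
    "analyze_trajectory",
    "summarize_binding",
    "effective_time",
]

NM_TO_A = 10.0

#: Anchor roles that must be present in every annotated system.
ANCHOR_ROLES = (
    "arg281_ca",
    "lys516_ca",
    "arg520_ca",
    "lys555_ca",
    "lys558_ca",
    "his332_cb",
    "lys367_ca",
)

#: The five anchors entering the orientation vectors.
ORIENTATION_ANCHORS = ANCHOR_ROLES[:5]

#: Binding cutoffs in Å relative to the phosphorus layer, keyed by
#: (resolution, bilayer).  Boundary equality counts as bound.
DEFAULT_BINDING_CUTOFFS_A: Mapping[tuple[str, str], float] = {
    ("AT", "POPC"): 0.0,
    ("AT", "POPC_PIP3"): -4.0,
    ("CG", "POPC"): -2.0,
    ("CG", "POPC_PIP3"): -12.0,
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters of the binding/orientation classifier.

    Parameters
    ----------
    binding_cutoffs_A
        Depth cutoff of the top atom relative to the phosphorus layer, per
        (resolution, bilayer) pair.  ``rel_top_z >= cutoff`` counts as bound.
    productive_angle_deg
        Closed interval of angles (degrees) between the anchor cross product
        and +z that counts as the productive orientation.
    cg_time_factor
        Multiplier converting raw coarse-grained simulation time to effective
        time (the standard speed-up factor of the Martini force field).
    cross_order
        ``"v1xv2"`` (default) or ``"v2xv1"``.  The two differ by a reflection
        of the reference axis (angle θ vs 180° − θ).
    plane_estimator
        ``"mean"`` (default) or ``"median"`` z of the monolayer's phosphorus
        atoms.
    """

    binding_cutoffs_A: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BINDING_CUTOFFS_A)
    )
    productive_angle_deg: tuple[float, float] = (0.0, 30.0)
    cg_time_factor: float = 4.0
    cross_order: str = "v1xv2"
    plane_estimator: str = "mean"

    def __post_init__(self) -> None:
        lo, hi = self.productive_angle_deg
        if not (0.0 <= lo <= hi <= 180.0):
            raise ConfigurationError(
                f"productive angle bounds must satisfy 0 <= lo <= hi <= 180, got {self.productive_angle_deg}"
            )
        if self.cross_order not in ("v1xv2", "v2xv1"):
            raise ConfigurationError(f"unknown cross_order {self.cross_order!r}")
        if self.plane_estimator not in ("mean", "median"):
            raise ConfigurationError(f"unknown plane_estimator {self.plane_estimator!r}")


@dataclass
class SystemMeta:
    """Static annotation of a simulated system.

    ``anchors`` maps each role in :data:`ANCHOR_ROLES` to an atom id;
    ``selections`` maps labels (at least ``"pd"``, ``"c2"``; typically also
    ``"spine"`` and ``"protein"``) to atom-id tuples; ``phosphorus`` maps
    ``"proximal"``/``"distal"`` to the lipid phosphorus atom ids of each
    monolayer.  ``masses`` (amu) is optional — centers of mass fall back to
    uniform weights without it, which is the convention for coarse-grained
    beads of equal size.
    """

    resolution: str
    bilayer: str
    anchors: Mapping[str, str]
    selections: Mapping[str, tuple[str, ...]]
    phosphorus: Mapping[str, tuple[str, ...]]
    masses: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        missing = [r for r in ANCHOR_ROLES if r not in self.anchors]
        if missing:
            raise MissingAnnotationError(f"anchors missing roles: {missing}")
        for label in ("pd", "c2"):
            if label not in self.selections or not self.selections[label]:
                raise MissingAnnotationError(f"selection {label!r} missing or empty")
        overlap = set(self.selections["pd"]) & set(self.selections["c2"])
        if overlap:
            raise ConfigurationError(f"PD and C2 selections overlap: {sorted(overlap)[:5]}")


class Frame:
    """One trajectory frame: a time stamp plus nm coordinates for every atom.

    ``coords_nm`` is an (n_atoms, 3) array; ``index`` maps atom id to row.
    The z-axis is the membrane normal, pointing from the protein side toward
    the proximal monolayer.
    """

    __slots__ = ("time_ps", "coords_nm", "index", "meta")

    def __init__(
        self,
        time_ps: float,
        coords_nm: np.ndarray,
        index: Mapping[str, int],
        meta: SystemMeta,
    ):
        self.time_ps = float(time_ps)
        self.coords_nm = np.asarray(coords_nm, dtype=float)
        self.index = index
        self.meta = meta

    def xyz(self, atom_id: str) -> np.ndarray:
        try:
            return self.coords_nm[self.index[atom_id]]
        except KeyError:
            raise MissingAnnotationError(f"atom {atom_id!r} not present in frame") from None

    def rows(self, atom_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.fromiter((self.index[a] for a in atom_ids), dtype=np.intp, count=len(atom_ids))
        except KeyError as exc:
            raise MissingAnnotationError(f"atom {exc.args[0]!r} not present in frame") from None


@dataclass
class AnnotatedTrajectory:
    """An ordered list of frames sharing one atom roster and annotation."""

    frames: list[Frame]
    meta: SystemMeta

    def __post_init__(self) -> None:
        times = np.array([f.time_ps for f in self.frames])
        if len(times) and np.any(np.diff(times) <= 0):
            raise ConfigurationError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])


@dataclass
class BindingTrace:
    """Per-frame classifier output.

    ``records`` columns: ``time_ps``, ``pd_bound``, ``c2_bound``,
    ``productive``, ``angle_deg``, ``degenerate``, plus ``rel_top_z_<sel>_A``
    and ``com_z_<sel>_A`` for every selection label.
    """

    records: pd.DataFrame
    meta: SystemMeta

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class BindingSummary:
    """Time fractions (percent) of PD binding, C2 binding, and the productive
    orientation with both domains bound."""

    fraction_pd: float
    fraction_c2: float
    fraction_productive_both_bound: float
    n_frames: int

    def __post_init__(self) -> None:
        eps = 1e-9
        assert -eps <= self.fraction_pd <= 100 + eps
        assert self.fraction_productive_both_bound <= min(self.fraction_pd, self.fraction_c2) + eps

    def as_dict(self) -> dict:
        return {
            "fraction_pd_pct": self.fraction_pd,
            "fraction_c2_pct": self.fraction_c2,
            "fraction_productive_both_bound_pct": self.fraction_productive_both_bound,
            "n_frames": self.n_frames,
        }


# ---------------------------------------------------------------------------
# per-frame geometry


def phosphorus_plane_z(frame: Frame, monolayer: str = "proximal", estimator: str = "mean") -> float:
    """z-position (nm) of the phosphorus layer of ``monolayer``.

    The layer is the plane containing the lipid phosphorus atoms of the
    monolayer; its z is estimated as their mean (or median) z-coordinate.
    """
    ids = frame.meta.phosphorus.get(monolayer, ())
    if not ids:
        raise MissingAnnotationError(f"no phosphorus atoms annotated for monolayer {monolayer!r}")
    z = frame.coords_nm[frame.rows(ids), 2]
    return float(np.median(z) if estimator == "median" else np.mean(z))


def rel_top_z(frame: Frame, selection: Sequence[str], monolayer: str = "proximal",
              estimator: str = "mean") -> float:
    """Depth (Å) of the selection's top atom relative to the phosphorus layer.

    The top atom is the selection atom with the highest z-coordinate; negative
    values lie below the layer (toward the cytoplasm).
    """
    if len(selection) == 0:
        raise MissingAnnotationError("empty selection")
    plane = phosphorus_plane_z(frame, monolayer, estimator)
    top = float(np.max(frame.coords_nm[frame.rows(selection), 2]))
    return (top - plane) * NM_TO_A


def binding_state(rel_top_z_A: float, resolution: str, bilayer: str,
                  config: ClassifierConfig | None = None) -> bool:
    """Bound iff the top atom sits at or above the system-specific cutoff."""
    config = config or ClassifierConfig()
    key = (resolution, bilayer)
    try:
        cutoff = config.binding_cutoffs_A[key]
    except KeyError:
        raise ConfigurationError(
            f"no binding cutoff for system {key}; known: {sorted(config.binding_cutoffs_A)}"
        ) from None
    return bool(rel_top_z_A >= cutoff)


def orientation_vectors(frame: Frame) -> tuple[np.ndarray, np.ndarray]:
    """The two anchor vectors defining the protein's orientation.

    v1 runs from the Arg-281 Cα to the midpoint of the Lys-516/Arg-520 Cα
    pair (the C2 β6–7 loop); v2 from the Arg-281 Cα to the midpoint of the
    Lys-555/Lys-558 Cα pair (the β8–9 loop).  Units nm.
    """
    a = frame.meta.anchors
    try:
        origin = frame.xyz(a["arg281_ca"])
        m1 = 0.5 * (frame.xyz(a["lys516_ca"]) + frame.xyz(a["arg520_ca"]))
        m2 = 0.5 * (frame.xyz(a["lys555_ca"]) + frame.xyz(a["lys558_ca"]))
    except MissingAnnotationError as exc:
        raise MissingAnnotationError(f"orientation anchor unresolved: {exc}") from None
    return m1 - origin, m2 - origin


def productive_angle(v1: np.ndarray, v2: np.ndarray, cross_order: str = "v1xv2") -> float:
    """Angle (degrees, in [0, 180]) between the anchor cross product and +z.

    Raises :class:`DegenerateOrientationError` when v1 and v2 are collinear
    (the cross product vanishes and no orientation is defined).
    """
    c = np.cross(v1, v2) if cross_order == "v1xv2" else np.cross(v2, v1)
    norm = float(np.linalg.norm(c))
    if norm < 1e-12:
        raise DegenerateOrientationError("orientation vectors are collinear; cross product vanishes")
    cosang = np.clip(c[2] / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_productive(angle_deg: float, config: ClassifierConfig | None = None) -> bool:
    """Productive iff the angle lies within the configured closed interval."""
    config = config or ClassifierConfig()
    lo, hi = config.productive_angle_deg
    return bool(lo <= angle_deg <= hi)


def com_z(frame: Frame, selection: Sequence[str], monolayer: str = "proximal",
          estimator: str = "mean") -> float:
    """Center-of-mass z (Å) of the selection relative to the phosphorus layer.

    Mass-weighted when the system provides masses; uniform weights otherwise.
    """
    if len(selection) == 0:
        raise MissingAnnotationError("empty selection")
    rows = frame.rows(selection)
    z = frame.coords_nm[rows, 2]
    if frame.meta.masses is not None:
        w = np.array([frame.meta.masses[a] for a in selection], dtype=float)
        center = float(np.average(z, weights=w))
    else:
        center = float(np.mean(z))
    return (center - phosphorus_plane_z(frame, monolayer, estimator)) * NM_TO_A


def catalytic_depth_asymmetry(frame: Frame) -> float:
    """|Δz| (Å) between the His-332 Cβ and Lys-367 Cα catalytic-center atoms.

    In the productive pose both atoms sit at nearly equal depth (the
    difference stays below ~0.3 Å); reported as a diagnostic only.
    """
    a = frame.meta.anchors
    z1 = frame.xyz(a["his332_cb"])[2]
    z2 = frame.xyz(a["lys367_ca"])[2]
    return abs(z1 - z2) * NM_TO_A


# ---------------------------------------------------------------------------
# trajectory-level analysis


def analyze_trajectory(traj: AnnotatedTrajectory, config: ClassifierConfig | None = None) -> BindingTrace:
    """Apply the binding and orientation classifiers to every frame."""
    config = config or ClassifierConfig()
    meta = traj.meta
    key = (meta.resolution, meta.bilayer)
    if key not in config.binding_cutoffs_A:
        raise ConfigurationError(f"no binding cutoff for system {key}")
    labels = list(meta.selections)
    rows = []
    n_degenerate = 0
    for i, frame in enumerate(traj.frames):
        try:
            rec: dict = {"time_ps": frame.time_ps}
            for label in labels:
                sel = meta.selections[label]
                rec[f"rel_top_z_{label}_A"] = rel_top_z(frame, sel, estimator=config.plane_estimator)
                rec[f"com_z_{label}_A"] = com_z(frame, sel, estimator=config.plane_estimator)
            rec["pd_bound"] = binding_state(rec["rel_top_z_pd_A"], *key, config)
            rec["c2_bound"] = binding_state(rec["rel_top_z_c2_A"], *key, config)
            v1, v2 = orientation_vectors(frame)
            try:
                angle = productive_angle(v1, v2, config.cross_order)
                rec["angle_deg"] = angle
                rec["productive"] = classify_productive(angle, config)
                rec["degenerate"] = False
            except DegenerateOrientationError:
                n_degenerate += 1
                rec["angle_deg"] = np.nan
                rec["productive"] = False
                rec["degenerate"] = True
        except (MissingAnnotationError, ConfigurationError) as exc:
            raise type(exc)(f"frame {i} (t={frame.time_ps} ps): {exc}") from exc
        rows.append(rec)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} frame(s) had collinear orientation vectors; counted as non-productive",
            stacklevel=2,
        )
    return BindingTrace(records=pd.DataFrame(rows), meta=meta)


def _frame_weights(times_ps: np.ndarray) -> np.ndarray:
    """Uniform weights for evenly spaced frames, trapezoidal otherwise."""
    n = len(times_ps)
    if n == 1:
        return np.ones(1)
    dt = np.diff(times_ps)
    if np.allclose(dt, dt[0]):
        return np.full(n, 1.0 / n)
    w = np.empty(n)
    w[0] = dt[0] / 2
    w[-1] = dt[-1] / 2
    w[1:-1] = (dt[:-1] + dt[1:]) / 2
    return w / w.sum()


def summarize_binding(trace: BindingTrace, config: ClassifierConfig | None = None) -> BindingSummary:
    """Time fractions (percent) of PD binding, C2 binding, and the productive
    orientation restricted to frames where both domains are bound."""
    df = trace.records
    if df.empty:
        raise ConfigurationError("cannot summarize an empty binding trace")
    w = _frame_weights(df["time_ps"].to_numpy())
    pd_b = df["pd_bound"].to_numpy(dtype=bool)
    c2_b = df["c2_bound"].to_numpy(dtype=bool)
    prod = df["productive"].to_numpy(dtype=bool) & pd_b & c2_b
    return BindingSummary(
        fraction_pd=100.0 * float(w @ pd_b),
        fraction_c2=100.0 * float(w @ c2_b),
        fraction_productive_both_bound=100.0 * float(w @ prod),
        n_frames=len(df),
    )


def effective_time(raw_time, resolution: str, config: ClassifierConfig | None = None):
    """Effective simulation time: raw time × the CG speed-up factor for CG
    systems, unchanged for atomistic systems."""
    config = config or ClassifierConfig()
    factor = config.cg_time_factor if resolution == "CG" else 1.0
    return raw_time * factor
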