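"""Synthetic data with recorded ground truth for every pipeline stage.

Each generator emulates the geometry or signal structure of one experimental
input — scheduled membrane-binding trajectories under a planar bilayer,
episodic Kir recordings with exponentially decaying test-pulse amplitudes,
off-sensing transients with linear leak and P/N subsweeps, F–V curves built
from Boltzmann components, fluorescence sweeps with known kinetics, and in
vitro phosphate-release plates — and returns the dataset together with a
:class:`GroundTruth` from which the noiseless downstream result is
predictable in closed form.

Trajectory realism is deliberately minimal: rigid pseudo-atom blobs under a
flat phosphorus lattice.  The classifiers consume only geometry the
generator controls exactly, so scheduled occupancies are recovered exactly
at zero jitter and within sampling error under jitter (the jitter is
validated against the classification margins so that no scheduled state can
plausibly flip).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .enzyme_activity import EpisodicRecording, ProtocolMeta
from .errors import ConfigurationError
from .fluorometry import FluorescenceSweepSet, FVDataset, boltzmann_sum
from .membrane_binding import ANCHOR_ROLES, AnnotatedTrajectory, Frame, SystemMeta

__all__ = [
    "GroundTruth",
    "TrajectorySchedule",
    "TrajectoryGeometry",
    "gen_membrane_trajectory",
    "gen_kir_recording",
    "gen_sensing_sweeps",
    "gen_fv_dataset",
    "gen_fluorescence_sweeps",
    "gen_invitro_plate",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generator provenance: name, seed, and every generative parameter."""

    generator: str
    seed: int
    params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"generator": self.generator, "seed": self.seed, "params": self.params},
                      fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# membrane trajectories


@dataclass
class TrajectorySchedule:
    """Per-frame bound/productive states with closed-form occupancies.

    ``pd_bound``, ``c2_bound`` and ``productive`` are boolean arrays of equal
    length; the prescribed time fractions are their means (the productive
    column counts frames that are productive *and* have both domains bound,
    matching the reporting convention).
    """

    pd_bound: np.ndarray
    c2_bound: np.ndarray
    productive: np.ndarray
    dt_ps: float = 1000.0

    def __post_init__(self) -> None:
        self.pd_bound = np.asarray(self.pd_bound, dtype=bool)
        self.c2_bound = np.asarray(self.c2_bound, dtype=bool)
        self.productive = np.asarray(self.productive, dtype=bool)
        n = len(self.pd_bound)
        if not (len(self.c2_bound) == len(self.productive) == n) or n == 0:
            raise ConfigurationError("schedule arrays must be non-empty and equal length")

    def __len__(self) -> int:
        return len(self.pd_bound)

    @property
    def fractions(self) -> dict:
        """Exact occupancy fractions (percent) implied by the schedule."""
        both = self.pd_bound & self.c2_bound
        return {
            "fraction_pd_pct": 100.0 * float(self.pd_bound.mean()),
            "fraction_c2_pct": 100.0 * float(self.c2_bound.mean()),
            "fraction_productive_both_bound_pct": 100.0 * float((self.productive & both).mean()),
        }

    @classmethod
    def from_fractions(cls, n_frames: int, f_pd: float, f_c2: float, f_productive: float,
                       dt_ps: float = 1000.0) -> "TrajectorySchedule":
        """Deterministic block schedule hitting the requested fractions exactly.

        Fractions are in [0, 1]; ``f_productive`` (productive with both
        domains bound) cannot exceed min(f_pd, f_c2).  Counts are rounded to
        whole frames, so choose ``n_frames`` divisible by the fraction
        denominators for exactness.
        """
        if f_productive > min(f_pd, f_c2) + 1e-12:
            raise ConfigurationError("f_productive cannot exceed min(f_pd, f_c2)")
        n_p = round(n_frames * f_productive)
        n_pd = round(n_frames * f_pd)
        n_c2 = round(n_frames * f_c2)
        pd_b = np.zeros(n_frames, dtype=bool)
        c2_b = np.zeros(n_frames, dtype=bool)
        prod = np.zeros(n_frames, dtype=bool)
        pd_b[:n_pd] = True
        c2_b[:n_p] = True
        c2_b[n_pd : n_pd + max(n_c2 - n_p, 0)] = True
        # if c2 demand exceeds the room after the pd block, overlap with it
        placed = n_p + max(min(n_c2 - n_p, n_frames - n_pd), 0)
        if placed < n_c2:
            c2_b[n_p : n_p + (n_c2 - placed)] = True
        prod[:n_p] = True
        return cls(pd_bound=pd_b, c2_bound=c2_b, productive=prod, dt_ps=dt_ps)

    @classmethod
    def from_telegraph(cls, n_frames: int, p_on: Mapping[str, float], p_off: Mapping[str, float],
                       seed: int, dt_ps: float = 1000.0) -> "TrajectorySchedule":
        """Two-state (telegraph) Markov chains for each classification.

        ``p_on[name]`` / ``p_off[name]`` are per-frame transition
        probabilities for ``name`` in {"pd", "c2", "productive"}; the
        stationary occupancy is p_on/(p_on + p_off) and the chain starts from
        its stationary distribution.
        """
        rng = np.random.default_rng(seed)
        arrays = {}
        for name in ("pd", "c2", "productive"):
            pon, poff = p_on[name], p_off[name]
            stat = pon / (pon + poff)
            u = rng.random(n_frames)
            state = np.empty(n_frames, dtype=bool)
            state[0] = u[0] < stat
            for i in range(1, n_frames):
                state[i] = (u[i] < pon) if not state[i - 1] else (u[i] >= poff)
            arrays[name] = state
        return cls(pd_bound=arrays["pd"], c2_bound=arrays["c2"],
                   productive=arrays["productive"], dt_ps=dt_ps)


@dataclass(frozen=True)
class TrajectoryGeometry:
    """Geometric parameters of the synthetic membrane system (nm unless noted)."""

    proximal_plane_z: float = 5.0
    bilayer_thickness: float = 4.0
    lattice_n: int = 6          # phosphorus atoms per monolayer = lattice_n²
    lattice_spacing: float = 0.8
    blob_atoms: int = 10        # pseudo-atoms per domain blob
    blob_radius: float = 0.6
    bound_margin_A: float = 3.0   # |rel_top_z − cutoff| for scheduled states
    anchor_arm: float = 0.8       # length of the anchor vectors
    productive_angle_deg: float = 15.0
    nonproductive_angle_deg: float = 90.0


def _rot_x(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _canonical_anchors(arm: float) -> dict[str, np.ndarray]:
    """Rigid internal anchor frame whose v1 × v2 points along +z."""
    return {
        "arg281_ca": np.zeros(3),
        "lys516_ca": np.array([arm, -arm / 2, 0.0]),
        "arg520_ca": np.array([arm, arm / 2, 0.0]),   # v1 midpoint = (arm, 0, 0)
        "lys555_ca": np.array([-arm / 2, arm, 0.0]),
        "lys558_ca": np.array([arm / 2, arm, 0.0]),   # v2 midpoint = (0, arm, 0)
        "his332_cb": np.array([0.3, 0.3, 0.0]),
        "lys367_ca": np.array([-0.3, 0.3, 0.0]),
    }


def gen_membrane_trajectory(
    schedule: TrajectorySchedule,
    resolution: str = "CG",
    bilayer: str = "POPC",
    seed: int = 0,
    jitter_sd_nm: float = 0.0,
    geometry: TrajectoryGeometry | None = None,
    binding_cutoffs_A: Mapping[tuple[str, str], float] | None = None,
) -> tuple[AnnotatedTrajectory, GroundTruth]:
    """Build an annotated trajectory realizing a classification schedule.

    Two flat phosphorus lattices form the bilayer; PD and C2 pseudo-atom
    blobs are placed so their top atoms sit ``bound_margin_A`` above (bound)
    or below (unbound) the system's cutoff; anchors sit on a rigid internal
    frame tilted to the scheduled productive or non-productive angle, then
    rotated randomly about z (which leaves the angle invariant).  Gaussian
    jitter is rejected unless every classification margin is at least 3σ.
    """
    from .membrane_binding import DEFAULT_BINDING_CUTOFFS_A

    geom = geometry or TrajectoryGeometry()
    cutoffs = dict(binding_cutoffs_A or DEFAULT_BINDING_CUTOFFS_A)
    try:
        cutoff_A = cutoffs[(resolution, bilayer)]
    except KeyError:
        raise ConfigurationError(f"no cutoff for system {(resolution, bilayer)}") from None

    jitter_A = jitter_sd_nm * 10.0
    if jitter_sd_nm > 0:
        # binding margin: top atom vs cutoff.  angle margin: the anchors'
        # worst-case angular error ~ sqrt(2)·3σ/arm must stay inside the
        # distance from the scheduled angles to the 30° boundary.
        if 3.0 * np.sqrt(2.0) * jitter_A > geom.bound_margin_A:
            raise ConfigurationError("jitter too large for the binding margin (need >= 3 sigma)")
        ang_margin = np.radians(
            min(30.0 - geom.productive_angle_deg, geom.nonproductive_angle_deg - 30.0)
        )
        if 3.0 * np.sqrt(2.0) * jitter_sd_nm / geom.anchor_arm > ang_margin:
            raise ConfigurationError("jitter too large for the orientation margin (need >= 3 sigma)")

    rng = np.random.default_rng(seed)
    n = geom.lattice_n
    xy = (np.arange(n) - (n - 1) / 2) * geom.lattice_spacing
    gx, gy = np.meshgrid(xy, xy)
    lattice = np.column_stack([gx.ravel(), gy.ravel()])

    atom_ids: list[str] = []
    prox_ids = [f"P_prox_{i}" for i in range(n * n)]
    dist_ids = [f"P_dist_{i}" for i in range(n * n)]
    pd_ids = [f"PD_{i}" for i in range(geom.blob_atoms)]
    c2_ids = [f"C2_{i}" for i in range(geom.blob_atoms)]
    anchor_ids = {role: f"ANC_{role}" for role in ANCHOR_ROLES}
    atom_ids = prox_ids + dist_ids + pd_ids + c2_ids + list(anchor_ids.values())
    index = {a: i for i, a in enumerate(atom_ids)}

    meta = SystemMeta(
        resolution=resolution,
        bilayer=bilayer,
        anchors=anchor_ids,
        selections={
            "pd": tuple(pd_ids),
            "c2": tuple(c2_ids),
            "spine": tuple(pd_ids[:2]),
            "protein": tuple(pd_ids + c2_ids),
        },
        phosphorus={"proximal": tuple(prox_ids), "distal": tuple(dist_ids)},
    )

    # one fixed blob shape per domain: atoms below a designated top atom
    def blob_shape() -> np.ndarray:
        pts = rng.normal(scale=geom.blob_radius, size=(geom.blob_atoms, 3))
        pts[:, 2] = -np.abs(pts[:, 2])  # everything at or below the top atom
        pts[0] = 0.0                    # atom 0 is the top atom
        return pts

    pd_shape = blob_shape()
    c2_shape = blob_shape()
    anchors0 = _canonical_anchors(geom.anchor_arm)
    plane_z = geom.proximal_plane_z

    frames: list[Frame] = []
    n_atoms = len(atom_ids)
    for i in range(len(schedule)):
        coords = np.empty((n_atoms, 3))
        coords[: n * n, :2] = lattice
        coords[: n * n, 2] = plane_z
        coords[n * n : 2 * n * n, :2] = lattice
        coords[n * n : 2 * n * n, 2] = plane_z + geom.bilayer_thickness

        for shape, ids, bound, x0 in (
            (pd_shape, pd_ids, schedule.pd_bound[i], -1.2),
            (c2_shape, c2_ids, schedule.c2_bound[i], 1.2),
        ):
            top_rel_A = cutoff_A + (geom.bound_margin_A if bound else -geom.bound_margin_A)
            top_z = plane_z + top_rel_A / 10.0
            pos = shape + np.array([x0, 0.0, top_z])
            coords[[index[a] for a in ids]] = pos

        theta = geom.productive_angle_deg if schedule.productive[i] else geom.nonproductive_angle_deg
        rot = _rot_z(rng.uniform(0, 2 * np.pi)) @ _rot_x(np.radians(theta))
        origin = np.array([0.0, 0.0, plane_z - 1.5])
        for role, local in anchors0.items():
            coords[index[anchor_ids[role]]] = origin + rot @ local

        if jitter_sd_nm > 0:
            coords = coords + rng.normal(scale=jitter_sd_nm, size=coords.shape)
        frames.append(Frame(i * schedule.dt_ps, coords, index, meta))

    traj = AnnotatedTrajectory(frames=frames, meta=meta)
    truth = GroundTruth(
        generator="membrane_trajectory",
        seed=seed,
        params={
            "resolution": resolution,
            "bilayer": bilayer,
            "cutoff_A": cutoff_A,
            "jitter_sd_nm": jitter_sd_nm,
            "n_frames": len(schedule),
            **schedule.fractions,
        },
    )
    return traj, truth


# ---------------------------------------------------------------------------
# episodic Kir recordings


def gen_kir_recording(
    k_per_s: float,
    plateau: float = 0.0,
    noise_sd: float = 0.0,
    n_episodes: int = 20,
    depol_ms: float = 300.0,
    amp0_uA: float = -10.0,
    seed: int = 0,
    sample_interval_ms: float = 0.1,
) -> tuple[EpisodicRecording, GroundTruth]:
    """Episodic Kir recording whose test-pulse amplitudes decay exponentially.

    Episode i (1-based) has amplitude amp0·[(1 − C)·exp(−k·(i−1)·depol/1000)
    + C], perturbed by one Gaussian draw of SD ``noise_sd`` (on the
    normalized scale) per episode.  Twenty episodes of the 300 ms (or 50 ms)
    depolarization protocol are the experimental defaults.
    """
    if k_per_s <= 0 or n_episodes < 2:
        raise ConfigurationError("k must be positive and n_episodes >= 2")
    protocol = ProtocolMeta(
        ramp_window_ms=(0.0, 50.0),
        test_window_ms=(50.0, 100.0),
        depol_window_ms=(100.0, 100.0 + depol_ms),
    )
    rng = np.random.default_rng(seed)
    sweep_ms = 100.0 + depol_ms
    time_ms = np.arange(0.0, sweep_ms + sample_interval_ms / 2, sample_interval_ms)
    episodes = []
    t_acc = np.arange(n_episodes) * depol_ms / 1000.0
    amps_norm = (1.0 - plateau) * np.exp(-k_per_s * t_acc) + plateau
    amps_norm = amps_norm + rng.normal(scale=noise_sd, size=n_episodes) * np.array(
        [0.0] + [1.0] * (n_episodes - 1)
    )  # the first episode defines the normalization and stays exact
    for i in range(n_episodes):
        current = np.zeros_like(time_ms)
        ramp = (time_ms >= 0) & (time_ms < 50.0)
        current[ramp] = -0.5 * (time_ms[ramp] / 50.0)
        test = (time_ms >= 50.0) & (time_ms <= 100.0)
        current[test] = amp0_uA * amps_norm[i]
        depol = time_ms > 100.0
        current[depol] = 0.8
        episodes.append(current)
    rec = EpisodicRecording(time_ms=time_ms, episodes=episodes, protocol=protocol)
    truth = GroundTruth(
        generator="kir_recording",
        seed=seed,
        params={
            "k_per_s": k_per_s,
            "plateau": plateau,
            "noise_sd": noise_sd,
            "n_episodes": n_episodes,
            "depol_ms": depol_ms,
            "amp0_uA": amp0_uA,
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# sensing-charge sweeps


def gen_sensing_sweeps(
    q_off_nC: float = 25.0,
    tau_off_ms: float = 5.0,
    leak_G_uS: float = 0.02,
    pn_order: int = 4,
    seed: int = 0,
    step_onset_ms: float = 20.0,
    sweep_ms: float = 80.0,
    sample_interval_ms: float = 0.02,
    step_from_mV: float = 150.0,
    step_to_mV: float = -60.0,
    offset_uA: float = 0.1,
    noise_sd_uA: float = 0.0,
) -> tuple[dict, GroundTruth]:
    """Repolarization-step sweeps: exponential sensing transient plus leak.

    The main sweep steps from +150 mV to the holding potential; its current
    is G·V(t) + offset + (Q/τ)·exp(−(t−t₀)/τ) after the step.  Each of the
    ``pn_order`` subsweeps uses a 1/N-scaled voltage step and contains the
    scaled leak but no transient, the standard P/N construction.  Returns
    ``{"time_ms", "main", "pn"}``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, sweep_ms + sample_interval_ms / 2, sample_interval_ms)
    v_main = np.where(t < step_onset_ms, step_from_mV, step_to_mV)
    transient = np.where(
        t >= step_onset_ms,
        (q_off_nC / tau_off_ms) * np.exp(-(t - step_onset_ms) / tau_off_ms),
        0.0,
    )
    # leak_G_uS · V(mV) gives nA; express in μA
    main = leak_G_uS * v_main * 1e-3 + offset_uA + transient
    if noise_sd_uA:
        main = main + rng.normal(scale=noise_sd_uA, size=main.shape)
    pn = []
    for _ in range(pn_order):
        sub = leak_G_uS * v_main * 1e-3 / pn_order + offset_uA
        if noise_sd_uA:
            sub = sub + rng.normal(scale=noise_sd_uA, size=sub.shape)
        pn.append(sub)
    truth = GroundTruth(
        generator="sensing_sweeps",
        seed=seed,
        params={
            "q_off_nC": q_off_nC,
            "tau_off_ms": tau_off_ms,
            "leak_G_uS": leak_G_uS,
            "pn_order": pn_order,
            "step_onset_ms": step_onset_ms,
            "offset_uA": offset_uA,
        },
    )
    return {"time_ms": t, "main": main, "pn": pn}, truth


# ---------------------------------------------------------------------------
# F–V and fluorescence sweeps


def gen_fv_dataset(
    components: Sequence[tuple[float, float, float]],
    voltages_mV: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FVDataset, GroundTruth]:
    """F–V points from one or two Boltzmann components plus additive noise.

    ``components`` are (amplitude, V½ mV, slope mV) triples; default voltage
    grid is −100 to 200 mV in 10 mV steps, spanning both transitions of a
    wild-type-like curve (V½ near 27 and 83 mV).
    """
    if voltages_mV is None:
        voltages_mV = np.arange(-100.0, 201.0, 10.0)
    v = np.asarray(voltages_mV, dtype=float)
    rng = np.random.default_rng(seed)
    f = boltzmann_sum(v, components)
    if noise_sd:
        f = f + rng.normal(scale=noise_sd, size=f.shape)
    fv = FVDataset(voltage_mV=v, f=f, strategy="synthetic")
    truth = GroundTruth(
        generator="fv_dataset",
        seed=seed,
        params={"components": [list(c) for c in components], "noise_sd": noise_sd,
                "voltages_mV": list(map(float, v))},
    )
    return fv, truth


def gen_fluorescence_sweeps(
    fv_components: Sequence[tuple[float, float, float]],
    kinetics: Mapping[float, Sequence[tuple[float, float]]] | None = None,
    voltages_mV: Sequence[float] | None = None,
    probe: str = "TMRM_G214C",
    pulse_ms: float = 500.0,
    onset_ms: float = 10.0,
    sample_interval_ms: float = 0.5,
    noise_sd: float = 0.0,
    default_tau_ms: float = 30.0,
    seed: int = 0,
) -> tuple[FluorescenceSweepSet, GroundTruth]:
    """Fluorescence sweeps whose pulse-end values equal the generating F(V).

    Each trace rises (or falls) from the pre-pulse baseline as a sum of
    exponential components — ``kinetics[v]`` gives (fraction, tau_ms) pairs,
    one exponential of ``default_tau_ms`` otherwise — scaled so that the
    value at pulse end equals F(V) exactly at zero noise.
    """
    if voltages_mV is None:
        voltages_mV = np.arange(-60.0, 201.0, 20.0)
    v_grid = np.asarray(voltages_mV, dtype=float)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, onset_ms + pulse_ms + sample_interval_ms / 2, sample_interval_ms)
    f_end = boltzmann_sum(v_grid, fv_components)
    traces = {}
    kin_used = {}
    for v, fe in zip(v_grid, f_end):
        comps = list(kinetics.get(v, [(1.0, default_tau_ms)])) if kinetics else [(1.0, default_tau_ms)]
        kin_used[float(v)] = [list(c) for c in comps]
        tp = np.clip(t - onset_ms, 0.0, None)
        g = np.zeros_like(t)
        for frac, tau in comps:
            g += frac * (1.0 - np.exp(-tp / tau))
        g_end = g[-1]
        trace = fe * g / g_end if g_end != 0 else np.zeros_like(t)
        trace[t < onset_ms] = 0.0
        if noise_sd:
            trace = trace + rng.normal(scale=noise_sd, size=trace.shape)
        traces[float(v)] = trace
    sweeps = FluorescenceSweepSet(
        time_ms=t,
        traces=traces,
        probe=probe,
        pulse_window_ms=(onset_ms, onset_ms + pulse_ms),
        baseline_window_ms=(0.0, onset_ms),
    )
    truth = GroundTruth(
        generator="fluorescence_sweeps",
        seed=seed,
        params={
            "fv_components": [list(c) for c in fv_components],
            "kinetics": kin_used,
            "noise_sd": noise_sd,
            "onset_ms": onset_ms,
            "pulse_ms": pulse_ms,
        },
    )
    return sweeps, truth


# ---------------------------------------------------------------------------
# in vitro plates


def gen_invitro_plate(
    true_relative_activities: Mapping[str, float],
    cv: float = 0.1,
    replicates: int = 9,
    reference: str = "WT",
    reference_phosphate_nmol: float = 10.0,
    seed: int = 0,
) -> tuple[dict, GroundTruth]:
    """Replicate phosphate-release measurements with known relative activities.

    Each replicate of construct c is drawn as truth_c × scale × (1 + N(0, cv));
    the reference construct has truth 1.0 by convention.
    """
    if reference not in true_relative_activities:
        raise ConfigurationError(f"reference {reference!r} missing from activity table")
    rng = np.random.default_rng(seed)
    table = {}
    for construct, truth_val in true_relative_activities.items():
        base = truth_val * reference_phosphate_nmol
        table[construct] = list(base * (1.0 + rng.normal(scale=cv, size=replicates)))
    gt = GroundTruth(
        generator="invitro_plate",
        seed=seed,
        params={
            "true_relative_activities": dict(true_relative_activities),
            "cv": cv,
            "replicates": replicates,
            "reference": reference,
        },
    )
    return table, gt
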