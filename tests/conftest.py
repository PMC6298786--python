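"""Shared fixtures: an independent brute-force geometric oracle and small
canonical synthetic datasets."""

from __future__ import annotations

import math

import numpy as np
import pytest

from vspkit import synthetic as syn


def brute_force_classify(frame, cutoff_A, angle_lo=0.0, angle_hi=30.0):
    """Re-derive every classification from raw coordinates with plain loops.

    Deliberately independent of the package's geometry code: plane by
    summation, top atom by an explicit max loop, midpoints/cross/angle with
    the math module.  Returns (pd_bound, c2_bound, productive).
    """
    meta = frame.meta

    zsum, n = 0.0, 0
    for aid in meta.phosphorus["proximal"]:
        zsum += frame.xyz(aid)[2]
        n += 1
    plane = zsum / n

    def bound(selection):
        top = -math.inf
        for aid in selection:
            z = frame.xyz(aid)[2]
            if z > top:
                top = z
        return (top - plane) * 10.0 >= cutoff_A

    a = meta.anchors
    o = frame.xyz(a["arg281_ca"])
    p516, p520 = frame.xyz(a["lys516_ca"]), frame.xyz(a["arg520_ca"])
    p555, p558 = frame.xyz(a["lys555_ca"]), frame.xyz(a["lys558_ca"])
    v1 = [(p516[i] + p520[i]) / 2 - o[i] for i in range(3)]
    v2 = [(p555[i] + p558[i]) / 2 - o[i] for i in range(3)]
    cx = v1[1] * v2[2] - v1[2] * v2[1]
    cy = v1[2] * v2[0] - v1[0] * v2[2]
    cz = v1[0] * v2[1] - v1[1] * v2[0]
    norm = math.sqrt(cx * cx + cy * cy + cz * cz)
    if norm == 0:
        productive = False
    else:
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cz / norm))))
        productive = angle_lo <= angle <= angle_hi
    return bound(meta.selections["pd"]), bound(meta.selections["c2"]), productive


@pytest.fixture
def brute_force_oracle():
    return brute_force_classify


@pytest.fixture
def scheduled_trajectory():
    """200-frame zero-jitter CG/POPC trajectory with known occupancies."""
    schedule = syn.TrajectorySchedule.from_fractions(200, f_pd=0.45, f_c2=0.80, f_productive=0.25)
    traj, truth = syn.gen_membrane_trajectory(schedule, "CG", "POPC", seed=7)
    return traj, truth, schedule


@pytest.fixture
def random_schedule_trajectory():
    """300 frames of random scheduled states with mild jitter, for oracle
    equivalence checks."""
    rng = np.random.default_rng(11)
    schedule = syn.TrajectorySchedule(
        pd_bound=rng.random(300) < 0.5,
        c2_bound=rng.random(300) < 0.5,
        productive=rng.random(300) < 0.5,
    )
    traj, truth = syn.gen_membrane_trajectory(
        schedule, "AT", "POPC_PIP3", seed=13, jitter_sd_nm=0.02
    )
    return traj, truth, schedule
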