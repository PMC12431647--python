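"""Co-transcriptional folding scheme: moving wall and sequential release.

Transcription is mimicked by starting from the extended chain with every
residue tethered to its anchor by a harmonic potential U = k |r - r0|²
(k = 10 kcal/mol/Å², the Amber restraint convention).  At t = 0 the first
(5'-most) nucleotide is released and a rigid plane perpendicular to x is
placed just left of it; every Δt the plane moves one nucleotide to the left
and that nucleotide's tether is removed.  Released beads hitting the plane
undergo a perfectly elastic collision — the normal (x) velocity component
is reversed, the tangential components are untouched.  After (n-1)Δt all
tethers and the plane are gone and the run continues as free folding (FF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dynamics
from .dynamics import DynState, Trajectory, maxwell_boltzmann_velocities
from .forcefield import ForceFieldParams
from .rna_model import (
    DEFAULT_RISE,
    Conformation,
    HairpinSystem,
    build_extended_chain,
)

__all__ = [
    "TranscriptionSchedule",
    "WallState",
    "ScheduleForces",
    "make_schedule",
    "reflect",
    "restraint_forces",
    "run_ctf",
    "run_ff",
]

DEFAULT_K_RESTRAINT = 10.0  # kcal/mol/Å²
DEFAULT_GAP = 2.0  # Å between a released nucleotide and the plane


@dataclass(frozen=True)
class WallState:
    """The rigid plane: perpendicular to x, normal pointing +x."""

    active: bool
    plane_x: float


@dataclass(frozen=True)
class TranscriptionSchedule:
    """Release/plane events for one CTF run.

    ``events[k] = (time_ns, residue, plane_x)``: at ``time_ns`` the 1-based
    ``residue`` is released and the plane jumps to ``plane_x``.  The plane
    (and the last tether) disappears at ``plane_removal_time_ns`` =
    (n_residues - 1) Δt.  ``anchors`` are the extended-chain coordinates.
    """

    dt_ns: float
    events: tuple[tuple[float, int, float], ...]
    plane_removal_time_ns: float
    anchors: np.ndarray
    k_restraint: float
    gap: float

    @property
    def n_residues(self) -> int:
        return len(self.events)

    def released_count(self, t_ns: float) -> int:
        """Number of residues synthesized at time t (release at t counts)."""
        return sum(1 for ev in self.events if ev[0] <= t_ns + 1e-12)

    def wall(self, t_ns: float) -> WallState:
        if t_ns + 1e-12 >= self.plane_removal_time_ns:
            return WallState(False, -np.inf)
        rc = self.released_count(t_ns)
        return WallState(True, self.events[rc - 1][2] if rc else np.inf)

    def kernel_arrays(self, dt_ps: float) -> dict:
        """Schedule in integration-step units for the compiled integrator."""
        release_steps = np.array(
            [int(round(ev[0] * 1e3 / dt_ps)) for ev in self.events], dtype=np.int64
        )
        plane_x = np.array([ev[2] for ev in self.events])
        removal = np.int64(round(self.plane_removal_time_ns * 1e3 / dt_ps))
        return dict(
            release_steps=release_steps,
            plane_x_events=plane_x,
            removal_step=removal,
            wall_on=True,
            anchors=np.ascontiguousarray(self.anchors),
            k_restraint=float(self.k_restraint),
        )


def make_schedule(
    system: HairpinSystem,
    extended_conf: Conformation,
    dt_ns: float,
    k_restraint: float = DEFAULT_K_RESTRAINT,
    gap: float = DEFAULT_GAP,
) -> TranscriptionSchedule:
    """Build the release schedule from the anchor conformation and Δt.

    Residue i is released at (i-1)Δt with the plane just left of its
    anchored beads (their minimum x minus ``gap``); the plane is removed at
    (n-1)Δt together with the last tether.  Δt = 0 degenerates to free
    folding: everything released at t = 0, no wall.
    """
    if dt_ns < 0:
        raise ValueError("dt_ns must be non-negative")
    coords = extended_conf.coordinates
    n = system.n_residues
    events = []
    for i in range(1, n + 1):
        xmin = float(coords[list(system.residue_beads(i)), 0].min())
        events.append(((i - 1) * dt_ns, i, xmin - gap))
    return TranscriptionSchedule(
        dt_ns=float(dt_ns),
        events=tuple(events),
        plane_removal_time_ns=(n - 1) * dt_ns,
        anchors=coords.copy(),
        k_restraint=float(k_restraint),
        gap=float(gap),
    )


def reflect(positions, velocities, plane_x: float, released_beads):
    """Elastic reflection of released beads off the plane at ``plane_x``.

    Beads left of the plane are mirrored (x -> 2 plane_x - x) and an
    inward-moving normal velocity is reversed; tangential components are
    unchanged, so each bead's speed is preserved exactly.  Returns new
    (positions, velocities) arrays; unreleased beads are untouched.
    """
    pos = np.array(positions, dtype=np.float64, copy=True)
    vel = np.array(velocities, dtype=np.float64, copy=True)
    rel = np.asarray(released_beads)
    if rel.dtype == bool:
        rel = np.flatnonzero(rel)
    hit = rel[pos[rel, 0] < plane_x]
    pos[hit, 0] = 2.0 * plane_x - pos[hit, 0]
    flip = hit[vel[hit, 0] < 0.0]
    vel[flip, 0] = -vel[flip, 0]
    return pos, vel


def restraint_forces(
    positions, schedule: TranscriptionSchedule, t_ns: float
) -> np.ndarray:
    """Harmonic-anchor forces -2k (r - anchor) on not-yet-released beads.

    Zero for released residues and identically zero after the last release.
    """
    if t_ns < 0:
        raise ValueError("t_ns must be non-negative")
    pos = np.asarray(positions, dtype=np.float64)
    forces = np.zeros_like(pos)
    rc = schedule.released_count(t_ns)
    if rc >= schedule.n_residues:
        return forces
    first_bead = 3 * rc  # beads of residues rc+1..n (0-based slice)
    d = pos[first_bead:] - schedule.anchors[first_bead:]
    forces[first_bead:] = -2.0 * schedule.k_restraint * d
    return forces


class ScheduleForces:
    """`run_segment` external-forces adapter for a transcription schedule.

    Provides the additive tether forces and the post-step wall correction,
    mirroring exactly what the fused compiled path applies.
    """

    def __init__(self, schedule: TranscriptionSchedule, dt_ps: float = dynamics.DEFAULT_DT_PS):
        self.schedule = schedule
        self.dt_ps = dt_ps

    def forces(self, positions, t_ps: float) -> np.ndarray:
        return restraint_forces(positions, self.schedule, t_ps * 1e-3)

    def post_step(self, positions, velocities, t_ps: float) -> None:
        # state at the *start* of this step decides the wall, as in the
        # fused kernel
        t_prev_ns = (t_ps - self.dt_ps) * 1e-3
        wall = self.schedule.wall(max(t_prev_ns, 0.0))
        if not wall.active:
            return
        rc = self.schedule.released_count(max(t_prev_ns, 0.0))
        rel = np.arange(3 * rc)
        pos, vel = reflect(positions, velocities, wall.plane_x, rel)
        positions[:] = pos
        velocities[:] = vel


def _simulate(
    system: HairpinSystem,
    params: ForceFieldParams,
    dt_ns: float,
    length_ns: float,
    seed: int,
    mode: str,
    *,
    dt_ps: float,
    gamma_per_ps: float,
    T_K: float,
    stride: int,
    rise_per_nt: float,
    k_restraint: float,
    gap: float,
) -> Trajectory:
    params = params or ForceFieldParams()
    topology = params.topology(system)
    extended = build_extended_chain(system, rise_per_nt)
    schedule = make_schedule(system, extended, dt_ns, k_restraint, gap)

    rng = np.random.default_rng(seed)
    v0 = maxwell_boltzmann_velocities(topology, T_K, rng)
    state = DynState(extended.coordinates.copy(), v0, 0.0, rng)

    n_steps = int(round(length_ns * 1e3 / dt_ps))
    fx, fv, fg = dynamics._run_fused(
        state,
        topology,
        params,
        n_steps,
        dt_ps,
        gamma_per_ps,
        T_K,
        stride,
        schedule.kernel_arrays(dt_ps),
    )
    positions = np.concatenate([extended.coordinates[None], fx])
    velocities = np.concatenate([v0[None], fv])
    times = np.concatenate([[0.0], fg * dt_ps * 1e-3])

    metadata = {
        "mode": mode,
        "seed": int(seed),
        "length_ns": float(length_ns),
        "dt_ps": float(dt_ps),
        "gamma_per_ps": float(gamma_per_ps),
        "T_K": float(T_K),
        "stride": int(stride),
        "n_residues": system.n_residues,
        "sequence": system.sequence,
        "forcefield": params.to_dict(),
    }
    if mode == "ctf":
        metadata["dt_ns"] = float(dt_ns)
        metadata["k_restraint"] = float(k_restraint)
        metadata["gap"] = float(gap)
        metadata["plane_removal_time_ns"] = schedule.plane_removal_time_ns
        metadata["events"] = [
            {"time_ns": t, "residue": r, "plane_x": px} for t, r, px in schedule.events
        ]
    return Trajectory(positions, times, velocities, metadata)


def run_ctf(
    system: HairpinSystem,
    params: ForceFieldParams | None = None,
    dt_ns: float = 1.0,
    length_ns: float = 50.0,
    seed: int = 0,
    *,
    dt_ps: float = dynamics.DEFAULT_DT_PS,
    gamma_per_ps: float = dynamics.DEFAULT_GAMMA,
    T_K: float = dynamics.DEFAULT_T,
    stride: int = dynamics.DEFAULT_STRIDE,
    rise_per_nt: float = DEFAULT_RISE,
    k_restraint: float = DEFAULT_K_RESTRAINT,
    gap: float = DEFAULT_GAP,
) -> Trajectory:
    """Co-transcriptional run: wall + sequential release, then free folding.

    Starts from the extended chain; requires ``length_ns`` to exceed the
    transcription phase (n-1)Δt.  With Δt = 0 the trajectory is
    frame-by-frame identical to :func:`run_ff` under the same seed.
    """
    if length_ns <= (system.n_residues - 1) * dt_ns:
        raise ValueError(
            f"length_ns={length_ns} does not cover transcription "
            f"({(system.n_residues - 1) * dt_ns} ns)"
        )
    return _simulate(
        system, params, dt_ns, length_ns, seed, "ctf",
        dt_ps=dt_ps, gamma_per_ps=gamma_per_ps, T_K=T_K, stride=stride,
        rise_per_nt=rise_per_nt, k_restraint=k_restraint, gap=gap,
    )


def run_ff(
    system: HairpinSystem,
    params: ForceFieldParams | None = None,
    length_ns: float = 50.0,
    seed: int = 0,
    *,
    dt_ps: float = dynamics.DEFAULT_DT_PS,
    gamma_per_ps: float = dynamics.DEFAULT_GAMMA,
    T_K: float = dynamics.DEFAULT_T,
    stride: int = dynamics.DEFAULT_STRIDE,
    rise_per_nt: float = DEFAULT_RISE,
) -> Trajectory:
    """Free-folding run from the same extended start, no wall or tethers."""
    if length_ns <= 0:
        raise ValueError("length_ns must be positive")
    return _simulate(
        system, params, 0.0, length_ns, seed, "ff",
        dt_ps=dt_ps, gamma_per_ps=gamma_per_ps, T_K=T_K, stride=stride,
        rise_per_nt=rise_per_nt, k_restraint=DEFAULT_K_RESTRAINT, gap=DEFAULT_GAP,
    )
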