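"""Trajectory analysis: RMSD, RoG, base-pair chronology, pathway calls.

The analysis pipeline mirrors how folding is scored in hairpin MD studies:

* **stem RMSD** against the native reference, after optimal (Kabsch)
  superposition, over all beads of the paired (stem) residues; a sustained
  value below 2 Å marks a folded trajectory;
* **radius of gyration** of the whole molecule as the compactness axis;
* **base-pair chronology** — the first time each native pair is formed and
  stays formed for a persistence window — which orders the pairs into a
  folding pathway: PATH I when the loop-adjacent pair (4C-9G by default)
  forms first (zipper-like), PATH II when it forms only after distal pairs;
* **T_F alignment** — co-transcriptional runs are compared with free
  folding on the free-folding clock T_F = t - (n-1)Δt, i.e. time elapsed
  after transcription completes.

Hydrogen-bond detection on atomistic (multi-model PDB) input uses the
cpptraj-style geometric criterion: donor-acceptor distance ≤ 3.5 Å and
donor-H-acceptor angle ≥ 120°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .rna_model import Conformation, HairpinSystem, build_native_structure

__all__ = [
    "PairEvent",
    "PathwayCall",
    "LandscapePoint",
    "Landscape",
    "kabsch_rmsd",
    "rog",
    "detect_hbonds_atomistic",
    "detect_pairs",
    "formation_order",
    "folding_time",
    "classify_pathway",
    "analyze_trajectory",
    "tf_align",
    "ensemble_stats",
    "landscape",
    "pathway_report",
]

#: Folding criterion: stem RMSD below this many Å counts as native.
RMSD_THRESHOLD = 2.0
#: Frames a pair/folded state must persist before an event is recorded.
PERSISTENCE_FRAMES = 5
#: A pair is formed when its base-bead distance ≤ this factor times r0.
CUTOFF_FACTOR = 1.2
#: Geometric hydrogen-bond criterion (cpptraj defaults).
HBOND_DMAX = 3.5
HBOND_ANGLE_MIN = 120.0

PATH_I = "PATH_I"
PATH_II = "PATH_II"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class PairEvent:
    """First persistent formation of one native pair."""

    pair: tuple[int, int]
    formation_time_ns: float
    tied: bool = False


@dataclass(frozen=True)
class PathwayCall:
    """Per-trajectory folding verdict and pathway label."""

    trajectory_id: str
    folded: bool
    folding_time_ns: float | None
    formation_order: tuple[PairEvent, ...]
    label: str
    condition: str = ""

    def to_dict(self) -> dict:
        return {
            "trajectory_id": self.trajectory_id,
            "condition": self.condition,
            "folded": self.folded,
            "folding_time_ns": self.folding_time_ns,
            "formation_order": [
                {"pair": list(e.pair), "time_ns": e.formation_time_ns, "tied": e.tied}
                for e in self.formation_order
            ],
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayCall":
        events = tuple(
            PairEvent(tuple(e["pair"]), e["time_ns"], e.get("tied", False))
            for e in d["formation_order"]
        )
        return cls(
            d["trajectory_id"],
            d["folded"],
            d["folding_time_ns"],
            events,
            d["label"],
            d.get("condition", ""),
        )


@dataclass(frozen=True)
class LandscapePoint:
    """One frame projected on the (RMSD, RoG) reaction coordinates."""

    rmsd: float
    rog: float
    time_ns: float
    t_f_ns: float
    condition: str = ""


@dataclass
class Landscape:
    """Normalized 2D occupancy histogram over (RMSD, RoG)."""

    counts: np.ndarray
    rmsd_edges: np.ndarray
    rog_edges: np.ndarray
    n_points: int
    condition: str = ""


def _coords(conf) -> np.ndarray:
    return np.asarray(getattr(conf, "coordinates", conf), dtype=np.float64)


def kabsch_rmsd(conf_a, conf_b, subset=None, superpose: bool = True) -> float:
    """RMSD (Å) between two conformations over ``subset`` bead indices.

    With ``superpose`` (default) the subsets are centred and optimally
    rotated onto each other (Kabsch, proper rotation only) before the RMSD
    is evaluated; the result is symmetric in its arguments and invariant
    under rigid motion of either.  ``superpose=False`` evaluates the plain
    coordinate formula on the conformations as given.
    """
    a, b = _coords(conf_a), _coords(conf_b)
    if subset is not None:
        subset = np.asarray(subset, dtype=np.intp)
        a, b = a[subset], b[subset]
    if a.shape != b.shape:
        raise ValueError(f"subset shapes differ: {a.shape} vs {b.shape}")
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if np.linalg.matrix_rank(ac, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) subset; superposition ill-defined")
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ ac.T).T - bc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def rog(conf, masses=None) -> float:
    """Radius of gyration (Å): RMS distance to the mean point.

    The default is unweighted over beads; pass ``masses`` for the
    mass-weighted variant.
    """
    x = _coords(conf)
    if x.shape[0] < 1:
        raise ValueError("empty conformation")
    if masses is None:
        centre = x.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((x - centre) ** 2, axis=1))))
    m = np.asarray(masses, dtype=np.float64)
    centre = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((x - centre) ** 2, axis=1)).sum() / m.sum()))


def detect_hbonds_atomistic(
    frame,
    donors,
    hydrogens,
    acceptors,
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> set[tuple[int, int, int]]:
    """Hydrogen bonds by the geometric criterion on atomistic coordinates.

    ``donors``, ``hydrogens`` and ``acceptors`` are parallel sequences of
    atom indices describing the candidate D-H...A triples.  A bond is
    reported iff d(D,A) ≤ ``d_max`` and the D-H-A angle ≥ ``angle_min``
    degrees.  Returns the set of (donor, hydrogen, acceptor) triples.
    """
    x = _coords(frame)
    if not (len(donors) == len(hydrogens) == len(acceptors)):
        raise ValueError("donors, hydrogens, acceptors must be parallel lists")
    bonds = set()
    for d_i, h_i, a_i in zip(donors, hydrogens, acceptors):
        if h_i is None:
            raise ValueError(f"donor atom {d_i} has no hydrogen assigned")
        d_a = np.linalg.norm(x[d_i] - x[a_i])
        if d_a > d_max:
            continue
        u = x[d_i] - x[h_i]
        v = x[a_i] - x[h_i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= angle_min:
            bonds.add((int(d_i), int(h_i), int(a_i)))
    return bonds


def _pair_r0(system: HairpinSystem) -> np.ndarray:
    """Native base-bead distances of the pairs, from the native fixture."""
    native = build_native_structure(system).coordinates
    return np.array(
        [np.linalg.norm(native[bi] - native[bj]) for bi, bj in system.base_bead_of_pair]
    )


def detect_pairs(
    frame,
    system: HairpinSystem,
    mode: str = "cg",
    cutoff_factor: float = CUTOFF_FACTOR,
    pair_r0=None,
    hbond_map=None,
    present_bonds=None,
) -> set[tuple[int, int]]:
    """Native pairs "formed" in one frame.

    cg mode: a pair is formed iff its base-bead distance ≤ ``cutoff_factor``
    times the native distance r0.  atomistic mode: a pair is formed iff all
    of its native hydrogen bonds (``hbond_map``: pair -> list of D-H-A
    triples) are in ``present_bonds`` (e.g. from
    :func:`detect_hbonds_atomistic`).
    """
    if mode == "cg":
        x = _coords(frame)
        r0 = _pair_r0(system) if pair_r0 is None else np.asarray(pair_r0)
        formed = set()
        for (i, j), (bi, bj), r in zip(system.pairs, system.base_bead_of_pair, r0):
            if np.linalg.norm(x[bi] - x[bj]) <= cutoff_factor * r:
                formed.add((i, j))
        return formed
    if mode == "atomistic":
        if hbond_map is None or present_bonds is None:
            raise ValueError("atomistic mode needs hbond_map and present_bonds")
        formed = set()
        for pair, triples in hbond_map.items():
            if all(tuple(t) in present_bonds for t in triples):
                formed.add(tuple(pair))
        return formed
    raise ValueError(f"unknown mode {mode!r}")


def _pair_distance_series(traj: Trajectory, system: HairpinSystem) -> np.ndarray:
    """(n_frames, n_pairs) base-bead distances."""
    idx = np.array(system.base_bead_of_pair, dtype=np.intp)
    d = traj.positions[:, idx[:, 0], :] - traj.positions[:, idx[:, 1], :]
    return np.sqrt(np.sum(d * d, axis=2))


def _first_persistent(flags: np.ndarray, persistence: int) -> int | None:
    """Index of the first frame opening a run of ≥ persistence True flags."""
    run = 0
    for k, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= persistence:
            return k - persistence + 1
    return None


def formation_order(
    traj: Trajectory,
    system: HairpinSystem,
    persistence_frames: int = PERSISTENCE_FRAMES,
    cutoff_factor: float = CUTOFF_FACTOR,
) -> list[PairEvent]:
    """Chronology of persistent native-pair formation.

    For each pair, the formation time is the first frame at which the pair
    is formed and remains formed for ``persistence_frames`` consecutive
    frames; pairs that never persist are omitted.  Events are sorted by
    time, ties broken by ascending 5' residue index and flagged.
    """
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    dist = _pair_distance_series(traj, system)
    r0 = _pair_r0(system)
    events = []
    for p, pair in enumerate(system.pairs):
        k = _first_persistent(dist[:, p] <= cutoff_factor * r0[p], persistence_frames)
        if k is not None:
            events.append((float(traj.times_ns[k]), pair))
    events.sort(key=lambda e: (e[0], e[1][0]))
    times = [t for t, _ in events]
    return [
        PairEvent(pair, t, tied=times.count(t) > 1) for t, pair in events
    ]


def folding_time(
    traj: Trajectory,
    system: HairpinSystem,
    rmsd_threshold: float = RMSD_THRESHOLD,
    native_conf: Conformation | None = None,
    persistence_frames: int = PERSISTENCE_FRAMES,
    superpose: bool = True,
) -> float | None:
    """First time (ns) the stem RMSD stays below threshold, or None.

    The stem RMSD is the superposed Kabsch RMSD over all beads of the
    paired residues; the crossing must persist for ``persistence_frames``
    consecutive frames (set to 1 for a single-crossing criterion).
    ``superpose=False`` scores the raw coordinate formula instead (no
    fitting), which is only meaningful if the trajectory shares the
    native frame of reference.
    """
    if rmsd_threshold <= 0:
        raise ValueError("rmsd_threshold must be positive")
    native = native_conf or build_native_structure(system)
    subset = system.stem_bead_indices
    r = np.array(
        [
            kabsch_rmsd(traj.positions[k], native, subset, superpose=superpose)
            for k in range(traj.n_frames)
        ]
    )
    k = _first_persistent(r < rmsd_threshold, persistence_frames)
    return None if k is None else float(traj.times_ns[k])


def classify_pathway(
    trajectory_id: str,
    folded: bool,
    folding_time_ns: float | None,
    order: list[PairEvent] | tuple[PairEvent, ...],
    loop_adjacent_pair: tuple[int, int] = (4, 9),
    condition: str = "",
) -> PathwayCall:
    """Label a trajectory PATH I / PATH II / UNCLASSIFIED.

    PATH I: the trajectory folds and the loop-adjacent pair is first in the
    formation order (zipper-like).  PATH II: the trajectory folds and the
    loop-adjacent pair forms only after at least one distal pair.
    UNCLASSIFIED: the trajectory never folds, or the loop-adjacent pair
    never persistently forms.
    """
    order = tuple(order)
    formed_pairs = [e.pair for e in order]
    if not folded or tuple(loop_adjacent_pair) not in formed_pairs:
        label = UNCLASSIFIED
    elif formed_pairs[0] == tuple(loop_adjacent_pair):
        label = PATH_I
    else:
        label = PATH_II
    return PathwayCall(
        trajectory_id=trajectory_id,
        folded=bool(folded),
        folding_time_ns=folding_time_ns,
        formation_order=order,
        label=label,
        condition=condition,
    )


def analyze_trajectory(
    traj: Trajectory,
    system: HairpinSystem,
    trajectory_id: str = "",
    rmsd_threshold: float = RMSD_THRESHOLD,
    persistence_frames: int = PERSISTENCE_FRAMES,
    cutoff_factor: float = CUTOFF_FACTOR,
    loop_adjacent_pair: tuple[int, int] = (4, 9),
    native_conf: Conformation | None = None,
) -> PathwayCall:
    """Full per-trajectory pipeline: folding time, chronology, label."""
    t_fold = folding_time(traj, system, rmsd_threshold, native_conf, persistence_frames)
    order = formation_order(traj, system, persistence_frames, cutoff_factor)
    condition = _condition_label(traj.metadata)
    tid = trajectory_id or f"{condition}-seed{traj.metadata.get('seed', '?')}"
    return classify_pathway(
        tid, t_fold is not None, t_fold, order, loop_adjacent_pair, condition
    )


def _condition_label(metadata: dict) -> str:
    mode = metadata.get("mode", "?")
    if mode == "ctf":
        dt = metadata.get("dt_ns")
        return f"ctf-{dt:g}" if dt is not None else "ctf"
    return mode


def tf_align(traj: Trajectory) -> np.ndarray:
    """Free-folding time T_F (ns) per frame.

    FF: T_F = t.  CTF: T_F = t - (n-1)Δt, the time elapsed after the last
    release event; frames with T_F < 0 fall within the transcription phase
    and are excluded from T_F-indexed ensemble comparisons.
    """
    meta = traj.metadata
    if "mode" not in meta:
        raise KeyError("trajectory metadata lacks 'mode'")
    t = np.asarray(traj.times_ns, dtype=np.float64)
    if meta["mode"] == "ctf":
        if "dt_ns" not in meta:
            raise KeyError("ctf trajectory metadata lacks 'dt_ns'")
        n = meta.get("n_residues")
        if n is None:
            raise KeyError("ctf trajectory metadata lacks 'n_residues'")
        return t - (n - 1) * meta["dt_ns"]
    return t.copy()


def _frame_metrics(traj, system, native, subset):
    r = np.array(
        [kabsch_rmsd(traj.positions[k], native, subset) for k in range(traj.n_frames)]
    )
    g = np.array([rog(traj.positions[k]) for k in range(traj.n_frames)])
    return r, g


def ensemble_stats(
    trajs: list[Trajectory],
    t_f_targets,
    system: HairpinSystem,
    native_conf: Conformation | None = None,
) -> pd.DataFrame:
    """Mean ± SD of stem RMSD and RoG at selected T_F values, per condition.

    For each trajectory the frame nearest to the target T_F (within half a
    frame interval) enters the ensemble; sample SD uses the n-1
    denominator and is reported as 0 (flagged) for n = 1.
    """
    if not trajs:
        raise ValueError("no trajectories given")
    native = native_conf or build_native_structure(system)
    subset = system.stem_bead_indices
    rows = []
    by_condition: dict[str, list[Trajectory]] = {}
    for tr in trajs:
        by_condition.setdefault(_condition_label(tr.metadata), []).append(tr)
    for condition, group in sorted(by_condition.items()):
        for target in t_f_targets:
            rmsds, rogs = [], []
            for tr in group:
                tf = tf_align(tr)
                valid = np.flatnonzero(tf >= 0)
                if len(valid) == 0:
                    continue
                stride_ns = (
                    np.median(np.diff(tr.times_ns)) if tr.n_frames > 1 else np.inf
                )
                k = valid[np.argmin(np.abs(tf[valid] - target))]
                if abs(tf[k] - target) > stride_ns / 2 + 1e-9:
                    continue
                rmsds.append(kabsch_rmsd(tr.positions[k], native, subset))
                rogs.append(rog(tr.positions[k]))
            if not rmsds:
                raise ValueError(
                    f"no frame within half a stride of T_F={target} for {condition}"
                )
            n = len(rmsds)
            rows.append(
                {
                    "condition": condition,
                    "t_f_ns": float(target),
                    "rmsd_mean": float(np.mean(rmsds)),
                    "rmsd_sd": float(np.std(rmsds, ddof=1)) if n > 1 else 0.0,
                    "rog_mean": float(np.mean(rogs)),
                    "rog_sd": float(np.std(rogs, ddof=1)) if n > 1 else 0.0,
                    "n": n,
                    "single_sample": n == 1,
                }
            )
    return pd.DataFrame(rows)


def landscape(
    trajs: list[Trajectory],
    system: HairpinSystem,
    bins: int = 40,
    folded_only: bool = False,
    native_conf: Conformation | None = None,
    rmsd_threshold: float = RMSD_THRESHOLD,
    persistence_frames: int = PERSISTENCE_FRAMES,
) -> Landscape:
    """Normalized occupancy histogram over (stem RMSD, RoG).

    With ``folded_only`` the histogram is built only from trajectories that
    reach the folded state (an empty selection is an error).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2 per axis")
    native = native_conf or build_native_structure(system)
    subset = system.stem_bead_indices
    selected = []
    for tr in trajs:
        if folded_only:
            t_fold = folding_time(
                tr, system, rmsd_threshold, native, persistence_frames
            )
            if t_fold is None:
                continue
        selected.append(tr)
    if not selected:
        raise ValueError("empty selection (no folded trajectories?)")
    rmsds, rogs = [], []
    for tr in selected:
        r, g = _frame_metrics(tr, system, native, subset)
        rmsds.append(r)
        rogs.append(g)
    r_all = np.concatenate(rmsds)
    g_all = np.concatenate(rogs)
    counts, r_edges, g_edges = np.histogram2d(r_all, g_all, bins=bins)
    total = counts.sum()
    condition = _condition_label(selected[0].metadata) if selected else ""
    return Landscape(counts / total, r_edges, g_edges, int(total), condition)


def pathway_report(calls: list[PathwayCall]) -> pd.DataFrame:
    """PATH I / PATH II / UNCLASSIFIED counts and fractions per condition."""
    by_condition: dict[str, list[PathwayCall]] = {}
    for c in calls:
        by_condition.setdefault(c.condition or "all", []).append(c)
    rows = []
    if not by_condition:
        rows.append(
            {
                "condition": "all",
                "path_i": 0,
                "path_ii": 0,
                "unclassified": 0,
                "n": 0,
                "path_i_fraction": np.nan,
                "path_ii_fraction": np.nan,
            }
        )
    for condition, group in sorted(by_condition.items()):
        n1 = sum(c.label == PATH_I for c in group)
        n2 = sum(c.label == PATH_II for c in group)
        nu = sum(c.label == UNCLASSIFIED for c in group)
        folded = n1 + n2
        rows.append(
            {
                "condition": condition,
                "path_i": n1,
                "path_ii": n2,
                "unclassified": nu,
                "n": len(group),
                "path_i_fraction": n1 / folded if folded else np.nan,
                "path_ii_fraction": n2 / folded if folded else np.nan,
            }
        )
    return pd.DataFrame(rows)
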