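"""Coarse-grained RNA hairpin model: system definition, topology, fixtures.

The model represents each nucleotide by three beads — phosphate (P), sugar
(S) and base (B) — connected P(i)-S(i), S(i)-B(i), S(i)-P(i+1).  A
:class:`HairpinSystem` records the sequence and the native base-pair list
(with per-pair hydrogen-bond multiplicities: 3 for C-G, 2 for A-U and the
G-U wobble).  Two deterministic conformations are generated in code rather
than read from files: an extended chain laid out along +x with the 5' end at
the largest x (the start structure and restraint-anchor set for
co-transcriptional runs), and an idealized native hairpin (regular stem
helix plus a bridging loop) that serves as the RMSD reference and supplies
the native-contact distances of the Gō-type force field.

Units: Å, ps, kcal/mol, amu.  Residues are numbered 1-based as in the
standard pair naming (e.g. 4C-9G); bead indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB",
    "BEAD_ROLES",
    "DEFAULT_SEQUENCE",
    "DEFAULT_PAIRS",
    "HairpinSystem",
    "Topology",
    "Conformation",
    "build_system",
    "default_system",
    "native_hbond_count",
    "build_extended_chain",
    "build_native_structure",
    "build_topology",
]

#: Boltzmann constant in kcal/mol/K.
KB = 0.0019872041

BEAD_ROLES = ("P", "S", "B")

#: GNRA-tetraloop hairpin of PDB entry 1ZIH, 5'->3'.
DEFAULT_SEQUENCE = "GGGCGCAAGCCU"
#: Native stem: wobble 1G-12U plus Watson-Crick 2G-11C, 3G-10C, 4C-9G.
DEFAULT_PAIRS = ((1, 12), (2, 11), (3, 10), (4, 9))

# Fixed bond lengths (Å); equilibrium values of the harmonic bond terms and
# the lengths used by both deterministic conformation builders.
BOND_PS = 3.8  # P(i)-S(i)
BOND_SB = 4.3  # S(i)-B(i)
BOND_SP = 3.8  # S(i)-P(i+1)

#: Default 5'->3' advance per nucleotide of the extended chain (Å).
DEFAULT_RISE = 5.9

# Lumped bead masses (amu).
MASS = {"P": 95.0, "S": 100.0, "B": 120.0}

# Idealized stem-helix parameters of the native fixture (Å, radians).
_HELIX_TWIST = np.deg2rad(32.0)
_HELIX_RISE = 3.3
_R_SUGAR = 8.5
_R_BASE = 4.6
_R_PHOS = 9.5
_PAIR_SHIFT = np.deg2rad(75.0)
_LOOP_SPAN = 5.5  # target sugar-sugar span per loop step (Å)

#: Max native distance (Å) at which adjacent bases count as stacked.
STACK_CUTOFF = 6.5
#: Max native distance (Å) for the remaining tertiary Gō contacts.
CONTACT_CUTOFF = 6.5
#: Minimum native sin² of a dihedral's bond angles for the torsion to be
#: geometrically well defined.
DIHEDRAL_MIN_SIN2 = 0.05
#: Well position (Å) of non-native base-pair contacts.
NONNATIVE_R0 = 5.0
#: Minimum sequence separation for a non-native pair contact.
NONNATIVE_MIN_SEP = 3

_WC = ({"C", "G"}, {"A", "U"})
_WOBBLE = {"G", "U"}


class ModelError(ValueError):
    """Invalid sequence, pair list or hairpin geometry."""


@dataclass(frozen=True)
class HairpinSystem:
    """An RNA hairpin: sequence, native pairs and coarse-grained indexing."""

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    hbonds_per_pair: tuple[int, ...]
    stem_residues: tuple[int, ...]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return 3 * len(self.sequence)

    def bead_index(self, residue: int, role: str) -> int:
        """0-based bead index of ``role`` (P/S/B) in 1-based ``residue``."""
        if not 1 <= residue <= self.n_residues:
            raise ModelError(f"residue {residue} out of range")
        return 3 * (residue - 1) + BEAD_ROLES.index(role)

    def residue_beads(self, residue: int) -> tuple[int, int, int]:
        b = 3 * (residue - 1)
        return (b, b + 1, b + 2)

    @property
    def stem_bead_indices(self) -> np.ndarray:
        """All bead indices of the stem residues (RMSD subset)."""
        return np.array(
            [b for r in self.stem_residues for b in self.residue_beads(r)],
            dtype=np.intp,
        )

    @property
    def base_bead_of_pair(self) -> tuple[tuple[int, int], ...]:
        """(base-bead i, base-bead j) for each native pair."""
        return tuple(
            (self.bead_index(i, "B"), self.bead_index(j, "B"))
            for i, j in self.pairs
        )


@dataclass(frozen=True)
class Conformation:
    """Per-bead coordinates (Å) with a free-text label."""

    coordinates: np.ndarray
    label: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ModelError("coordinates must have shape (n_beads, 3)")
        if not np.all(np.isfinite(coords)):
            raise ModelError("non-finite coordinates")
        object.__setattr__(self, "coordinates", coords)


@dataclass
class Topology:
    """Bonded terms, native contacts and non-bonded pair list as arrays.

    ``contact_kind`` distinguishes base-pair contacts (1, one per native
    pair, well depth eps_hb x H-bond multiplicity) from adjacent-base
    stacking contacts (2, depth eps_stack).  ``ev_pairs`` lists the bead
    pairs subject to excluded volume: everything except 1-2/1-3 bonded
    neighbours and the attractive contacts themselves.
    """

    masses: np.ndarray
    bond_idx: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray
    angle_th0: np.ndarray
    angle_k: np.ndarray
    dihedral_idx: np.ndarray
    dihedral_phi0: np.ndarray
    dihedral_k: np.ndarray
    contact_idx: np.ndarray
    contact_r0: np.ndarray
    contact_eps: np.ndarray
    contact_kind: np.ndarray
    ev_pairs: np.ndarray
    bead_residue: np.ndarray = field(default=None)  # 1-based residue per bead

    @property
    def n_beads(self) -> int:
        return self.masses.shape[0]

    @property
    def beads(self) -> list[tuple[int, str, float]]:
        """(residue, role, mass) per bead, in bead order."""
        return [
            (int(self.bead_residue[i]), BEAD_ROLES[i % 3], float(self.masses[i]))
            for i in range(self.n_beads)
        ]

    @property
    def bonds(self) -> list[tuple[int, int, float, float]]:
        return [
            (int(i), int(j), float(r), float(k))
            for (i, j), r, k in zip(self.bond_idx, self.bond_r0, self.bond_k)
        ]

    @property
    def native_contacts(self) -> list[tuple[int, int, float, float]]:
        return [
            (int(i), int(j), float(r), float(e))
            for (i, j), r, e in zip(self.contact_idx, self.contact_r0, self.contact_eps)
        ]


def build_system(sequence, pairs) -> HairpinSystem:
    """Validate a sequence + native-pair list and assemble a system.

    H-bond multiplicities are assigned by pair type: C-G -> 3, A-U -> 2,
    wobble G-U -> 2.  The stem residue set (the RMSD subset) is the union of
    all paired residues.
    """
    sequence = str(sequence).upper()
    if not sequence:
        raise ModelError("empty sequence")
    bad = set(sequence) - set("ACGU")
    if bad:
        raise ModelError(f"invalid letters {sorted(bad)}; expected A/C/G/U")
    n = len(sequence)

    norm_pairs: list[tuple[int, int]] = []
    mult: list[int] = []
    used: set[int] = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if not (1 <= i < j <= n):
            raise ModelError(f"pair ({i},{j}) out of range or not i<j for n={n}")
        if i in used or j in used:
            raise ModelError(f"residue reused across pairs in ({i},{j})")
        used.update((i, j))
        letters = {sequence[i - 1], sequence[j - 1]}
        if letters in _WC:
            mult.append(3 if letters == {"C", "G"} else 2)
        elif letters == _WOBBLE:
            mult.append(2)
        else:
            raise ModelError(
                f"residues {i}{sequence[i-1]}-{j}{sequence[j-1]} cannot pair"
            )
        norm_pairs.append((i, j))

    return HairpinSystem(
        sequence=sequence,
        pairs=tuple(norm_pairs),
        hbonds_per_pair=tuple(mult),
        stem_residues=tuple(sorted(used)),
    )


def default_system() -> HairpinSystem:
    """The 12-nt GNRA hairpin with its four native stem pairs."""
    return build_system(DEFAULT_SEQUENCE, DEFAULT_PAIRS)


def native_hbond_count(system: HairpinSystem) -> int:
    """Total native hydrogen bonds: sum of per-pair multiplicities.

    For the default hairpin this is 11 (three C-G pairs contribute 9, the
    G-U wobble contributes 2).
    """
    return int(sum(system.hbonds_per_pair))


def build_extended_chain(system: HairpinSystem, rise_per_nt: float = DEFAULT_RISE) -> Conformation:
    """Deterministic extended chain along +x, 5' end at the largest x.

    Residue i is centred near x = (n - i) * rise.  The backbone zig-zags in
    y so that at the default rise the P-S and S-P' distances equal the
    harmonic bond lengths exactly; the base bead sits above the sugar.  The
    result doubles as the restraint-anchor set of the transcription scheme.
    """
    if rise_per_nt <= 0:
        raise ModelError("rise_per_nt must be positive")
    n = system.n_residues
    half = rise_per_nt / 2.0
    y_zig = float(np.sqrt(max(BOND_PS**2 - half**2, 0.0)))
    coords = np.empty((3 * n, 3))
    for i in range(1, n + 1):
        xc = (n - i) * rise_per_nt
        p, s, b = system.residue_beads(i)
        coords[p] = (xc + rise_per_nt / 4.0, 0.0, 0.0)
        coords[s] = (xc - rise_per_nt / 4.0, y_zig, 0.0)
        coords[b] = (xc - rise_per_nt / 4.0, y_zig + BOND_SB, 0.0)
    return Conformation(coords, label="extended")


def _stem_ranks(system: HairpinSystem) -> dict[int, tuple[int, int]]:
    """Map paired residue -> (rank k from the open end, strand 0|1).

    Requires the pairs to form one contiguous nested stack (a single
    hairpin); raises otherwise.
    """
    if not system.pairs:
        raise ModelError("system has no pairs; cannot build a hairpin")
    ordered = sorted(system.pairs)
    i0, j0 = ordered[0]
    for k, (i, j) in enumerate(ordered):
        if i != i0 + k or j != j0 - k:
            raise ModelError("pairs are not nestable into a single hairpin stem")
    i_last, j_last = ordered[-1]
    if i_last >= j_last:
        raise ModelError("stem strands overlap")
    ranks: dict[int, tuple[int, int]] = {}
    for k, (i, j) in enumerate(ordered):
        ranks[i] = (k, 0)
        ranks[j] = (k, 1)
    return ranks


def _native_targets(system: HairpinSystem) -> dict[int, dict[str, np.ndarray]]:
    """Guide positions per residue for the idealized native hairpin."""
    ranks = _stem_ranks(system)
    ordered = sorted(system.pairs)
    i_last, j_last = ordered[-1]
    k_top = len(ordered) - 1
    n = system.n_residues

    def cyl(r, phi, z):
        return np.array([r * np.cos(phi), r * np.sin(phi), z])

    targets: dict[int, dict[str, np.ndarray]] = {}
    for res in range(1, n + 1):
        if res in ranks:
            k, strand = ranks[res]
            phi = k * _HELIX_TWIST + (strand * _PAIR_SHIFT)
            z = k * _HELIX_RISE
            # P sits halfway back toward the 5' neighbour along the strand.
            dphi = -0.5 * _HELIX_TWIST if strand == 0 else 0.5 * _HELIX_TWIST
            dz = -0.5 * _HELIX_RISE if strand == 0 else 0.5 * _HELIX_RISE
            targets[res] = {
                "S": cyl(_R_SUGAR, phi, z),
                "B": cyl(_R_BASE, phi, z),
                "P": cyl(_R_PHOS, phi + dphi, z + dz),
            }
    # Loop residues bridge the strand tops along a circular arc bulging in
    # +z, sized so each step matches the natural sugar-sugar span; loop
    # bases point radially outward from the arc centre.
    loop = [r for r in range(i_last + 1, j_last) if r not in ranks]
    if loop:
        a = targets[i_last]["S"]
        b = targets[j_last]["S"]
        m = len(loop)
        chord = float(np.linalg.norm(b - a))
        u = (b - a) / chord
        w = np.array([0.0, 0.0, 1.0])
        w = w - np.dot(w, u) * u
        if np.linalg.norm(w) < 1e-6:
            w = np.array([1.0, 0.0, 0.0]) - u[0] * u
        w /= np.linalg.norm(w)
        span = _LOOP_SPAN * (m + 1) / chord  # arc length / chord ratio
        if span <= 1.0:
            theta = 0.2
        else:
            from scipy.optimize import brentq

            theta = brentq(
                lambda t: t / (2.0 * np.sin(t / 2.0)) - span, 1e-6, 2.0 * np.pi - 0.2
            )
        radius = chord / (2.0 * np.sin(theta / 2.0))
        centre = 0.5 * (a + b) - radius * np.cos(theta / 2.0) * w
        phi_start = np.pi / 2.0 + theta / 2.0

        def arc_point(s):
            phi = phi_start - s * theta
            return centre + radius * (np.cos(phi) * u + np.sin(phi) * w)

        prev_sugar = a
        for idx, res in enumerate(loop):
            s = (idx + 1) / (m + 1)
            sugar = arc_point(s)
            out = sugar - centre
            out /= np.linalg.norm(out)
            base = sugar + BOND_SB * out
            # P pushed well off the S..S chord so the S-P-S backbone angles
            # stay clearly bent (torsions around them remain well defined)
            mid = 0.5 * (prev_sugar + sugar)
            pout = mid - centre
            phos = mid + 2.5 * pout / np.linalg.norm(pout)
            targets[res] = {"S": sugar, "B": base, "P": phos}
            prev_sugar = sugar
    missing = [r for r in range(1, n + 1) if r not in targets]
    if missing:
        # dangling residues outside the outermost pair are not supported
        raise ModelError(f"residues {missing} lie outside the hairpin stem/loop")
    return targets


def build_native_structure(system: HairpinSystem) -> Conformation:
    """Deterministic idealized native hairpin used as the RMSD reference.

    The stem is a regular helix (paired bases facing each other across the
    axis), the loop bridges the strand tops.  Beads are placed sequentially
    with exact bond lengths, each step aiming at the idealized guide
    position, so the output is byte-reproducible and the harmonic bond
    terms are exactly relaxed.  Native-contact distances of the force field
    are measured from this conformation.
    """
    targets = _native_targets(system)
    n = system.n_residues
    coords = np.empty((3 * n, 3))

    def toward(origin, target, length):
        d = target - origin
        nrm = np.linalg.norm(d)
        if nrm < 1e-9:  # degenerate guide; displace along +z
            d, nrm = np.array([0.0, 0.0, 1.0]), 1.0
        return origin + (length / nrm) * d

    prev_sugar = None
    for res in range(1, n + 1):
        p, s, b = system.residue_beads(res)
        t = targets[res]
        if prev_sugar is None:
            coords[p] = t["P"]
        else:
            coords[p] = toward(prev_sugar, t["P"], BOND_SP)
        coords[s] = toward(coords[p], t["S"], BOND_PS)
        coords[b] = toward(coords[s], t["B"], BOND_SB)
        prev_sugar = coords[s]
    return Conformation(coords, label="native")


def _bonded_exclusions(system: HairpinSystem, bond_idx: np.ndarray) -> set:
    """1-2 and 1-3 bead pairs (as sorted tuples) along the bond graph."""
    adj: dict[int, set[int]] = {}
    for i, j in bond_idx:
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    skip = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            skip.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    skip.add((min(i, k), max(i, k)))
    return skip


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    sphi = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    return float(np.arctan2(sphi, np.dot(n1, n2)))


def build_topology(
    system: HairpinSystem,
    *,
    k_bond: float = 20.0,
    k_angle: float = 10.0,
    k_dihedral: float = 8.0,
    eps_hb: float = 2.0,
    eps_stack: float = 1.2,
    eps_other: float = 1.0,
    eps_nonnative: float = 0.6,
) -> Topology:
    """Assemble the Gō-type topology for a hairpin system.

    Bond equilibria are the fixed construction lengths; angle equilibria and
    native-contact distances are measured from the idealized native
    structure, which therefore minimizes every bonded and native-contact
    term simultaneously.  Base-pair contacts get depth eps_hb x H-bond
    multiplicity (so C-G wells are deeper than G-U); B(i)-B(i+1) stacking
    contacts get depth eps_stack.  Excluded volume applies to all remaining
    bead pairs except 1-2 and 1-3 bonded neighbours.
    """
    n = system.n_residues
    nb = 3 * n
    native = build_native_structure(system).coordinates

    masses = np.array([MASS[BEAD_ROLES[i % 3]] for i in range(nb)])
    bead_residue = np.array([i // 3 + 1 for i in range(nb)], dtype=np.intp)

    bonds: list[tuple[int, int, float]] = []
    for res in range(1, n + 1):
        p, s, b = system.residue_beads(res)
        bonds.append((p, s, BOND_PS))
        bonds.append((s, b, BOND_SB))
        if res < n:
            bonds.append((s, system.bead_index(res + 1, "P"), BOND_SP))
    bond_idx = np.array([(i, j) for i, j, _ in bonds], dtype=np.intp)
    bond_r0 = np.array([r for *_, r in bonds])
    bond_k = np.full(len(bonds), float(k_bond))

    triples: list[tuple[int, int, int]] = []
    for res in range(1, n + 1):
        p, s, b = system.residue_beads(res)
        triples.append((p, s, b))
        if res < n:
            p2, s2, _ = system.residue_beads(res + 1)
            triples.append((p, s, p2))
            triples.append((b, s, p2))
            triples.append((s, p2, s2))
    angle_idx = np.array(triples, dtype=np.intp)
    angle_th0 = np.array([_angle(native[a], native[b], native[c]) for a, b, c in triples])
    angle_k = np.full(len(triples), float(k_angle))

    # pseudo-dihedrals along the bond graph give the chain its torsional
    # rigidity; without them the strands spin freely about the backbone
    # and the stem cannot hold a helical geometry. A torsion whose native
    # bond angles are nearly collinear is ill-defined (and numerically
    # vicious), so such quads are dropped.
    def _min_sin2(a, b, c, d):
        b1, b2, b3 = native[b] - native[a], native[c] - native[b], native[d] - native[c]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        s1 = np.dot(n1, n1) / (np.dot(b1, b1) * np.dot(b2, b2))
        s2 = np.dot(n2, n2) / (np.dot(b2, b2) * np.dot(b3, b3))
        return min(s1, s2)

    quads: list[tuple[int, int, int, int]] = []
    for res in range(1, n):
        p, s, b = system.residue_beads(res)
        p2, s2, _ = system.residue_beads(res + 1)
        candidates = [(p, s, p2, s2), (b, s, p2, s2)]
        if res < n - 1:
            p3 = system.bead_index(res + 2, "P")
            candidates.append((s, p2, s2, p3))
        quads.extend(q for q in candidates if _min_sin2(*q) >= DIHEDRAL_MIN_SIN2)
    dihedral_idx = np.array(quads, dtype=np.intp)
    dihedral_phi0 = np.array(
        [_dihedral(native[a], native[b], native[c], native[d]) for a, b, c, d in quads]
    )
    dihedral_k = np.full(len(quads), float(k_dihedral))

    contacts: list[tuple[int, int, float, float, int]] = []
    for (i, j), mult in zip(system.pairs, system.hbonds_per_pair):
        bi, bj = system.bead_index(i, "B"), system.bead_index(j, "B")
        r0 = float(np.linalg.norm(native[bi] - native[bj]))
        contacts.append((bi, bj, r0, eps_hb * mult, 1))
    # stacking only where adjacent bases actually touch in the native
    # structure; a 12-6 well with a long r0 would be unphysically stiff
    stack_beads = set()
    for res in range(1, n):
        bi, bj = system.bead_index(res, "B"), system.bead_index(res + 1, "B")
        r0 = float(np.linalg.norm(native[bi] - native[bj]))
        if r0 <= STACK_CUTOFF:
            contacts.append((bi, bj, r0, float(eps_stack), 2))
            stack_beads.add((bi, bj))
    # non-native base pairing: weak wells between complementary bases that
    # are not native partners. Slow transcription can trap such mispaired
    # compact intermediates, which is what lets the loop-adjacent pair form
    # late; without this term the release order alone dictates chronology.
    if eps_nonnative > 0.0:
        native_set = set(system.pairs)
        for i in range(1, n + 1):
            for j in range(i + NONNATIVE_MIN_SEP, n + 1):
                if (i, j) in native_set:
                    continue
                letters = {system.sequence[i - 1], system.sequence[j - 1]}
                if letters in _WC:
                    mult = 3 if letters == {"C", "G"} else 2
                elif letters == _WOBBLE:
                    mult = 2
                else:
                    continue
                bi, bj = system.bead_index(i, "B"), system.bead_index(j, "B")
                r0 = float(np.linalg.norm(native[bi] - native[bj]))
                if r0 <= CONTACT_CUTOFF:
                    continue  # already a (deeper) tertiary native contact
                contacts.append((bi, bj, NONNATIVE_R0, eps_nonnative * mult, 4))

    # tertiary Gō contacts: every remaining non-bonded bead pair in contact
    # in the native structure. These pin the mutual orientation of the two
    # stem strands (base-base contacts alone act as a free hinge).
    bonded_skip = _bonded_exclusions(system, bond_idx)
    taken = {(min(int(i), int(j)), max(int(i), int(j))) for i, j, *_ in contacts}
    for i in range(nb):
        for j in range(i + 1, nb):
            key = (i, j)
            if key in bonded_skip or key in taken:
                continue
            r0 = float(np.linalg.norm(native[i] - native[j]))
            if r0 <= CONTACT_CUTOFF:
                contacts.append((i, j, r0, float(eps_other), 3))

    contact_idx = np.array([(i, j) for i, j, *_ in contacts], dtype=np.intp)
    contact_r0 = np.array([c[2] for c in contacts])
    contact_eps = np.array([c[3] for c in contacts])
    contact_kind = np.array([c[4] for c in contacts], dtype=np.intp)

    # excluded-volume pair list: skip 1-2, 1-3 neighbours and contacts
    skip = set(bonded_skip)
    for i, j in contact_idx:
        skip.add((min(int(i), int(j)), max(int(i), int(j))))
    ev = [(i, j) for i in range(nb) for j in range(i + 1, nb) if (i, j) not in skip]
    ev_pairs = np.array(ev, dtype=np.intp) if ev else np.empty((0, 2), dtype=np.intp)

    return Topology(
        masses=masses,
        bond_idx=bond_idx,
        bond_r0=bond_r0,
        bond_k=bond_k,
        angle_idx=angle_idx,
        angle_th0=angle_th0,
        angle_k=angle_k,
        dihedral_idx=dihedral_idx,
        dihedral_phi0=dihedral_phi0,
        dihedral_k=dihedral_k,
        contact_idx=contact_idx,
        contact_r0=contact_r0,
        contact_eps=contact_eps,
        contact_kind=contact_kind,
        ev_pairs=ev_pairs,
        bead_residue=bead_residue,
    )
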