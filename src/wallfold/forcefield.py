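"""Gō-type coarse-grained force field for the hairpin model.

Energy terms:

* harmonic bonds               U = k_bond (r - r0)^2
* harmonic angles              U = k_angle (theta - theta0)^2
* pseudo-dihedrals             U = k_dihedral (1 - cos(phi - phi0)), the
                               chain's torsional rigidity
* excluded volume (WCA)        purely repulsive LJ, cut and shifted at
                               2^(1/6) sigma, over the non-bonded pair list
* native contacts              12-6 well  U = eps [ (r0/r)^12 - 2 (r0/r)^6 ]
                               with depth eps = eps_hb x H-bond multiplicity
                               for base pairs, eps_stack for adjacent-base
                               stacking and eps_other for the remaining
                               tertiary contacts

Equilibrium geometry (angle/dihedral equilibria, contact distances) is
measured from the idealized native structure, so the native state is the
global minimum of the bonded + contact energy.

The native-contact bias encodes the known base-pair list, so the model asks
*in which order* the native pairs form, not whether the native structure is
predicted.  Forces are the exact analytic negative gradient of the energy;
heavy loops are JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .rna_model import HairpinSystem, Topology, build_topology

__all__ = ["ForceFieldParams", "energy_forces", "pair_well_depth"]


@dataclass(frozen=True)
class ForceFieldParams:
    """Tunable knobs of the coarse-grained model (Å, kcal/mol units)."""

    k_bond: float = 20.0       # kcal/mol/Å²
    k_angle: float = 10.0      # kcal/mol/rad²
    k_dihedral: float = 8.0    # kcal/mol (torsion barrier scale)
    sigma_ev: float = 4.0      # Å, excluded-volume diameter
    eps_ev: float = 1.0        # kcal/mol
    eps_hb: float = 2.0        # kcal/mol per native hydrogen bond
    eps_stack: float = 1.2     # kcal/mol per adjacent-base stack
    eps_other: float = 1.0     # kcal/mol per tertiary native contact
    eps_nonnative: float = 0.6  # kcal/mol per H-bond of a non-native pair

    _ZERO_OK = ("eps_hb", "eps_stack", "eps_other", "eps_nonnative")

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value < 0 or (name not in self._ZERO_OK and value <= 0):
                raise ValueError(f"{name} must be positive (got {value})")

    def topology(self, system: HairpinSystem) -> Topology:
        """Build the Gō topology for ``system`` under these parameters."""
        return build_topology(
            system,
            k_bond=self.k_bond,
            k_angle=self.k_angle,
            k_dihedral=self.k_dihedral,
            eps_hb=self.eps_hb,
            eps_stack=self.eps_stack,
            eps_other=self.eps_other,
            eps_nonnative=self.eps_nonnative,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        return cls(**d)


_ALL_TERMS = ("bonds", "angles", "dihedrals", "ev", "contacts")


def energy_forces(
    conf,
    topology: Topology,
    params: ForceFieldParams | None = None,
    terms=_ALL_TERMS,
):
    """Total potential energy (kcal/mol) and per-bead forces (kcal/mol/Å).

    ``conf`` may be a Conformation or an (n_beads, 3) array.  ``terms``
    selects which energy components are evaluated (useful for testing each
    gradient in isolation).  Forces are the exact negative gradient of the
    returned energy.
    """
    params = params or ForceFieldParams()
    coords = np.ascontiguousarray(
        getattr(conf, "coordinates", conf), dtype=np.float64
    )
    if coords.shape != (topology.n_beads, 3):
        raise ValueError(
            f"coordinates shape {coords.shape} does not match topology "
            f"({topology.n_beads} beads)"
        )
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    unknown = set(terms) - set(_ALL_TERMS)
    if unknown:
        raise ValueError(f"unknown energy terms {sorted(unknown)}")

    forces = np.zeros_like(coords)
    energy = 0.0
    if "bonds" in terms and len(topology.bond_idx):
        energy += _kernels.bond_ef(
            coords, topology.bond_idx, topology.bond_r0, topology.bond_k, forces
        )
    if "angles" in terms and len(topology.angle_idx):
        energy += _kernels.angle_ef(
            coords, topology.angle_idx, topology.angle_th0, topology.angle_k, forces
        )
    if "dihedrals" in terms and len(topology.dihedral_idx):
        energy += _kernels.dihedral_ef(
            coords,
            topology.dihedral_idx,
            topology.dihedral_phi0,
            topology.dihedral_k,
            forces,
        )
    if "ev" in terms and len(topology.ev_pairs):
        energy += _kernels.wca_ef(
            coords, topology.ev_pairs, params.sigma_ev, params.eps_ev, forces
        )
    if "contacts" in terms and len(topology.contact_idx):
        energy += _kernels.contact_ef(
            coords, topology.contact_idx, topology.contact_r0, topology.contact_eps, forces
        )
    return float(energy), forces


def pair_well_depth(
    system: HairpinSystem, params: ForceFieldParams, pair: tuple[int, int]
) -> float:
    """Depth (kcal/mol) of the native-contact well of one base pair.

    eps_hb times the pair's hydrogen-bond multiplicity: C-G pairs (3 bonds)
    are deeper than A-U or wobble G-U pairs (2 bonds) for any eps_hb > 0.
    """
    pair = (int(pair[0]), int(pair[1]))
    try:
        k = system.pairs.index(pair)
    except ValueError:
        raise KeyError(f"{pair} is not a native pair of this system") from None
    return params.eps_hb * system.hbonds_per_pair[k]
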