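"""Coarse-grained bead-spring polymer engine.

Chromatin is a chain of beads in reduced units: 1 length unit = one bead
diameter (10 nm at 200 bp/bead), energies in units of k_BT, temperature
T = 1.  The force field combines harmonic bonds (chain, loop anchors, gap
stretches), an angular stiffness, a soft DPD-style repulsion that permits
strand passage (essential for topological equilibration of loop arrays),
confinement walls (cylinder with caps, axial "spool" exclusion), end
tethers, constant lateral forces, and harmonic azimuthal pins that hold a
helical winding in place.

The reference integrator is overdamped Langevin (Brownian) dynamics:

    x(t+dt) = x(t) + F dt / gamma + sqrt(2 T dt / gamma) * N(0, 1)

It samples the same Boltzmann ensemble as the DPD thermostat used for
GPU-scale production runs, at sizes up to a few 10^4 beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Conformation",
    "ForceField",
    "IntegratorParams",
    "init_conformation",
    "integrate",
    "update_lef_bonds",
    "compute_forces",
]

#: nm per reduced length unit at the native 200 bp/bead resolution.
NM_PER_UNIT_NATIVE = 10.0


def nm_per_unit(bp_per_bead: float) -> float:
    """Length conversion for coarse-grained beads.

    Bead volume scales with its genomic content, so the bead diameter (one
    reduced length unit) scales as the cube root of bp per bead relative to
    the native 200 bp / 10 nm nucleosome bead.
    """
    return NM_PER_UNIT_NATIVE * (bp_per_bead / 200.0) ** (1.0 / 3.0)


@dataclass
class Conformation:
    """Ordered bead positions with genomic scale and chain topology.

    ``chains`` lists half-open bead index spans; consecutive beads within a
    chain are bonded.  ``category`` is an integer mask (0 generic,
    1 condensin anchor, 2 cohesin site).
    """

    positions: np.ndarray  # (N, 3) reduced units
    bp_per_bead: float
    chains: list = field(default_factory=list)
    category: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.n_beads < 2:
            raise ValueError("need at least two beads")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not self.chains:
            self.chains = [(0, self.n_beads)]
        if self.category is None:
            self.category = np.zeros(self.n_beads, dtype=np.int8)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def chain_bonds(self) -> np.ndarray:
        pairs = []
        for a, b in self.chains:
            idx = np.arange(a, b - 1)
            pairs.append(np.column_stack([idx, idx + 1]))
        return np.concatenate(pairs) if pairs else np.empty((0, 2), dtype=int)


@dataclass
class ForceField:
    """Force-field specification in reduced units (lengths in units, energies kT)."""

    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    bond_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    bond_l0: np.ndarray = field(default_factory=lambda: np.empty(0))
    lef_bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    lef_bond_k: float = 10.0
    lef_bond_l0: float = 1.0
    angle_k: float = 0.0
    repulsion_a: float = 3.0
    repulsion_cutoff: float = 1.0
    # cylindrical confinement: (radius, length, eps, sigma); axis = z in [0, L]
    cylinder: tuple | None = None
    # axial exclusion for backbone beads: (radius, eps, bead_indices)
    spool: tuple | None = None
    # constant forces: (n_forces, 4) rows of (bead, fx, fy, fz)
    constant_forces: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    # azimuthal pins about the cylinder axis: rows of (bead, target_angle, k)
    angular_pins: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    frozen: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    box: np.ndarray | None = None  # periodic box lengths, or None
    # bookkeeping for ghost particles / torsion quadruplets (cylinder_helix)
    ghost_beads: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    torsion_quadruplets: list = field(default_factory=list)

    def all_bonds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.lef_bonds.shape[0]:
            b = np.concatenate([self.bonds, self.lef_bonds])
            k = np.concatenate([self.bond_k, np.full(len(self.lef_bonds), self.lef_bond_k)])
            l0 = np.concatenate([self.bond_l0, np.full(len(self.lef_bonds), self.lef_bond_l0)])
            return b, k, l0
        return self.bonds, self.bond_k, self.bond_l0

    def with_chain(self, conformation: Conformation, k: float = 10.0, l0: float = 1.0
                   ) -> "ForceField":
        """Return a copy with the chain-connectivity bonds prepended."""
        cb = conformation.chain_bonds()
        return replace(
            self,
            bonds=np.concatenate([cb, self.bonds]).astype(int),
            bond_k=np.concatenate([np.full(len(cb), k), self.bond_k]),
            bond_l0=np.concatenate([np.full(len(cb), l0), self.bond_l0]),
        )


@dataclass
class IntegratorParams:
    """Brownian-dynamics parameters.

    dt defaults to 0.02 reduced time: the explicit Euler-Maruyama update is
    stable only while (stiffest force constant) * dt / gamma < 2, and the
    stiffest chain mode of k = 10 bonds sits at 4k dt = 2.0 for dt = 0.05
    (the step used by inertial DPD production runs), so the overdamped
    reference integrator runs below that boundary.
    """

    n_steps: int = 1000
    dt: float = 0.02
    temperature: float = 1.0
    gamma: float = 1.0
    seed: int = 0
    neighbor_every: int = 5
    diverge_limit: float = 1e6


def init_conformation(
    n_beads: int,
    mode: Literal["random_walk", "helix_backbone"] = "random_walk",
    seed: int = 0,
    bp_per_bead: float = 200.0,
    step_length: float = 1.0,
    **kwargs,
) -> Conformation:
    """Build an initial conformation.

    ``random_walk`` takes unit-length steps in uniformly random directions.
    ``helix_backbone`` delegates to the mitotic builder and requires
    ``loop_array`` and ``geometry`` keyword arguments.
    """
    if n_beads < 2:
        raise ValueError("need at least two beads")
    if mode == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n_beads - 1, 3))
        steps *= step_length / np.linalg.norm(steps, axis=1, keepdims=True)
        pos = np.concatenate([np.zeros((1, 3)), np.cumsum(steps, axis=0)])
        return Conformation(pos, bp_per_bead=bp_per_bead)
    if mode == "helix_backbone":
        from . import mitotic_builder

        loop_array = kwargs.get("loop_array")
        geometry = kwargs.get("geometry")
        if loop_array is None or geometry is None:
            raise ValueError("helix_backbone mode requires loop_array and geometry")
        return mitotic_builder.helix_conformation(
            loop_array, geometry, bp_per_bead=bp_per_bead, seed=seed)
    raise ValueError(f"unknown mode {mode!r}")


def _min_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def _scatter_add(f: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    # bincount-based scatter-add: much faster than np.add.at for large arrays
    n = f.shape[0]
    for k in range(3):
        f[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


def compute_forces(pos: np.ndarray, ff: ForceField, pairs: np.ndarray | None = None
                   ) -> np.ndarray:
    """Total force on every bead (kT per length unit)."""
    f = np.zeros_like(pos)
    box = ff.box

    bonds, bond_k, bond_l0 = ff.all_bonds()
    if len(bonds):
        d = _min_image(pos[bonds[:, 1]] - pos[bonds[:, 0]], box)
        r = np.linalg.norm(d, axis=1)
        r = np.where(r < 1e-12, 1e-12, r)
        fmag = (bond_k * (r - bond_l0) / r)[:, None] * d
        _scatter_add(f, bonds[:, 0], fmag)
        _scatter_add(f, bonds[:, 1], -fmag)

    if ff.angle_k > 0.0:
        # E = k (1 - cos theta), theta = angle between consecutive bond vectors
        trip = ff_triplets(ff, pos.shape[0])
        if len(trip):
            i, j, k_ = trip[:, 0], trip[:, 1], trip[:, 2]
            u = _min_image(pos[j] - pos[i], box)
            v = _min_image(pos[k_] - pos[j], box)
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            nu = np.where(nu < 1e-12, 1e-12, nu)
            nv = np.where(nv < 1e-12, 1e-12, nv)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            c = np.sum(uh * vh, axis=1)[:, None]
            # E = k (1 - cos); F = -dE/dr with cos = u.v / |u||v|
            fi = -ff.angle_k * (vh - c * uh) / nu[:, None]
            fk = ff.angle_k * (uh - c * vh) / nv[:, None]
            _scatter_add(f, i, fi)
            _scatter_add(f, k_, fk)
            _scatter_add(f, j, -(fi + fk))

    if ff.repulsion_a > 0.0 and pairs is not None and len(pairs):
        d = _min_image(pos[pairs[:, 1]] - pos[pairs[:, 0]], box)
        r = np.linalg.norm(d, axis=1)
        sel = (r < ff.repulsion_cutoff) & (r > 1e-12)
        if np.any(sel):
            d = d[sel]
            r = r[sel]
            # DPD soft core: F = A (1 - r/rc) along the pair vector
            fmag = (ff.repulsion_a * (1.0 - r / ff.repulsion_cutoff) / r)[:, None] * d
            p = pairs[sel]
            _scatter_add(f, p[:, 0], -fmag)
            _scatter_add(f, p[:, 1], fmag)

    if ff.cylinder is not None:
        radius, length, eps, sigma = ff.cylinder
        rho = np.linalg.norm(pos[:, :2], axis=1)
        inside = rho < radius
        d_wall = radius - rho
        # Gaussian wall: U = eps * exp(-d^2 / 2 sigma^2), repels from the wall
        g = eps * np.exp(-0.5 * np.minimum(d_wall, 6 * sigma) ** 2 / sigma**2) / sigma**2
        frad = np.where(inside, -g * d_wall, 0.0)
        # outside: harmonic restoring ramp continuous at the wall
        frad = np.where(~inside, -(eps / sigma**2) * (rho - radius) - eps / sigma**2 * 0.0, frad)
        rho_safe = np.where(rho < 1e-12, 1e-12, rho)
        f[:, 0] += frad * pos[:, 0] / rho_safe
        f[:, 1] += frad * pos[:, 1] / rho_safe
        # caps at z = 0 and z = length
        z = pos[:, 2]
        dz0 = z - 0.0
        dz1 = length - z
        g0 = eps * np.exp(-0.5 * np.clip(dz0, None, 6 * sigma) ** 2 / sigma**2) / sigma**2
        g1 = eps * np.exp(-0.5 * np.clip(dz1, None, 6 * sigma) ** 2 / sigma**2) / sigma**2
        f[:, 2] += np.where(dz0 > 0, g0 * dz0, eps / sigma**2 * -dz0)
        f[:, 2] -= np.where(dz1 > 0, g1 * dz1, eps / sigma**2 * -dz1)

    if ff.spool is not None:
        r_spool, eps, beads = ff.spool
        beads = np.asarray(beads, dtype=int)
        p = pos[beads, :2]
        rho = np.linalg.norm(p, axis=1)
        inside = rho < r_spool
        # quadratic ramp: U = eps (1 - rho / r_spool)^2 inside the spool core
        rho_safe = np.where(rho < 1e-12, 1e-12, rho)
        fmag = np.where(inside, 2.0 * eps * (1.0 - rho / r_spool) / r_spool, 0.0)
        f[beads, 0] += fmag * p[:, 0] / rho_safe
        f[beads, 1] += fmag * p[:, 1] / rho_safe

    if len(ff.constant_forces):
        idx = ff.constant_forces[:, 0].astype(int)
        _scatter_add(f, idx, ff.constant_forces[:, 1:4])

    if len(ff.angular_pins):
        idx = ff.angular_pins[:, 0].astype(int)
        target = ff.angular_pins[:, 1]
        kpin = ff.angular_pins[:, 2]
        x, y = pos[idx, 0], pos[idx, 1]
        rho = np.sqrt(x * x + y * y)
        rho = np.where(rho < 1e-9, 1e-9, rho)
        phi = np.arctan2(y, x)
        dphi = np.arctan2(np.sin(phi - target), np.cos(phi - target))
        # E = k/2 dphi^2; tangential force = -k dphi / rho
        ft = -kpin * dphi / rho
        f[idx, 0] += ft * (-y / rho)
        f[idx, 1] += ft * (x / rho)

    if len(ff.frozen):
        f[ff.frozen] = 0.0
    return f


def ff_triplets(ff: ForceField, n_beads: int) -> np.ndarray:
    """Consecutive-bead triplets for the angle force, from cached chains."""
    chains = getattr(ff, "_angle_chains", None)
    if chains is None:
        chains = [(0, n_beads)]
    out = []
    for a, b in chains:
        if b - a >= 3:
            i = np.arange(a, b - 2)
            out.append(np.column_stack([i, i + 1, i + 2]))
    return np.concatenate(out) if out else np.empty((0, 3), dtype=int)


def _neighbor_pairs(pos: np.ndarray, cutoff: float, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        wrapped = np.mod(pos, box)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def integrate(conformation: Conformation, ff: ForceField, params: IntegratorParams,
              include_chain_bonds: bool = True, chain_bond_k: float = 10.0,
              callback=None) -> Conformation:
    """Advance the conformation by overdamped Langevin dynamics.

    The chain-connectivity bonds of the conformation are added to the force
    field automatically unless ``include_chain_bonds`` is False.  Raises
    ``RuntimeError`` if any coordinate exceeds ``params.diverge_limit``.
    """
    pos = conformation.positions.copy()
    work_ff = ff.with_chain(conformation, k=chain_bond_k) if include_chain_bonds else ff
    work_ff._angle_chains = conformation.chains  # used by the angle force
    rng = np.random.default_rng(params.seed)
    mobile = np.ones(len(pos), dtype=bool)
    if len(work_ff.frozen):
        mobile[work_ff.frozen] = False

    skin = 0.5
    pairs = None
    noise_scale = np.sqrt(2.0 * params.temperature * params.dt / params.gamma)
    for step in range(params.n_steps):
        if work_ff.repulsion_a > 0 and step % params.neighbor_every == 0:
            pairs = _neighbor_pairs(pos, work_ff.repulsion_cutoff + skin, work_ff.box)
        f = compute_forces(pos, work_ff, pairs)
        disp = f * (params.dt / params.gamma)
        disp += noise_scale * rng.standard_normal(pos.shape)
        pos[mobile] += disp[mobile]
        if step % 50 == 0 and np.max(np.abs(pos)) > params.diverge_limit:
            raise RuntimeError(f"simulation diverged at step {step}")
        if callback is not None:
            callback(step, pos)
    if np.max(np.abs(pos)) > params.diverge_limit:
        raise RuntimeError("simulation diverged")
    return replace(conformation, positions=pos)


def update_lef_bonds(ff: ForceField, extrusion_state, bp_per_bead: float,
                     n_beads: int | None = None) -> ForceField:
    """Refresh the LEF harmonic bonds from a 1D extrusion state.

    Each bound complex contributes one bond between the beads containing its
    two leg positions (floor division of the bp coordinate); stale bonds are
    dropped wholesale.  Raises if a leg maps outside the polymer.
    """
    kb_per_bead = bp_per_bead / 1000.0
    kb = extrusion_state.lattice.kb_per_site
    pairs = []
    for lef in extrusion_state.lefs:
        if not lef.bound:
            continue
        a = int(lef.legs[0] * kb // kb_per_bead)
        b = int(lef.legs[1] * kb // kb_per_bead)
        if n_beads is not None and not (0 <= a < n_beads and 0 <= b < n_beads):
            raise ValueError(f"LEF leg bead ({a}, {b}) outside polymer of {n_beads} beads")
        if a != b:
            pairs.append((min(a, b), max(a, b)))
    new = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return replace(ff, lef_bonds=new)
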