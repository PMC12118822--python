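"""Construction of mitotic chromatid models.

A mitotic chromatid is modeled as a bottlebrush: the chromatin fiber is
folded by condensins into an array of loops whose anchors form a backbone,
the brush is packed into a cylinder at the measured volume density, and the
backbone is weakly nudged to follow a helical path with a fixed genomic
content per turn.  Three architectures are supported:

``cylinder_helix``
    consecutive loops + gaps, cylindrical confinement, helical backbone
    (condensin II-only chromosomes, and the nested two-layer variant with
    condensin I subloops);
``stretched_periodic``
    consecutive loops, no cylinder: the chromosome is stretched end-to-end
    to a target linear density inside a periodic box (condensin I-only
    "wiggling noodle" chromosomes);
``overlapping_helix``
    independently placed, mutually overlapping loops with per-anchor
    azimuthal pins and no continuous backbone (the condensin II
    bypassing scenario).

Free parameters are the loop size, the gap between consecutive loop
anchors, and the linear density (or equivalently the helical pitch); the
genomic turn length and the volume density are set from experiment.  All
other geometry is derived from five relations (see ``derive_geometry``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .polymer3d import Conformation, ForceField, nm_per_unit

__all__ = [
    "GeometryParams",
    "DerivedGeometry",
    "LoopArray",
    "sample_consecutive_loops",
    "sample_overlapping_loops",
    "subdivide_nested",
    "derive_geometry",
    "build_force_spec",
    "plant_cohesion",
    "helix_conformation",
    "stretched_conformation",
]

#: Length of the loop-anchor bond in nm at native bead size (1 length unit).
L_LOOPBOND_NM = 10.0


@dataclass(frozen=True)
class GeometryParams:
    """Free and measured geometric parameters of a chromatid model.

    Exactly one of ``rho_l_mb_per_um`` (linear density) and ``pitch_nm``
    must be given; they interconvert through the turn length,
    P = l_turn / rho_L.
    """

    l_chrom_mb: float
    l_loop_kb: float
    l_gap_nm: float
    l_turn_mb: float
    rho_v_mb_per_um3: float
    sigma_c_nm: float
    rho_l_mb_per_um: float | None = None
    pitch_nm: float | None = None
    mode: Literal["cylinder_helix", "stretched_periodic", "overlapping_helix"] = "cylinder_helix"

    def __post_init__(self):
        if (self.rho_l_mb_per_um is None) == (self.pitch_nm is None):
            raise ValueError("give exactly one of rho_l_mb_per_um and pitch_nm")
        for name in ("l_chrom_mb", "l_loop_kb", "l_turn_mb", "rho_v_mb_per_um3", "sigma_c_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.l_gap_nm < 0:
            raise ValueError("gap length must be nonnegative")

    @property
    def rho_l(self) -> float:
        """Linear density in Mb/um, whichever way it was specified."""
        if self.rho_l_mb_per_um is not None:
            return self.rho_l_mb_per_um
        return self.l_turn_mb / (self.pitch_nm / 1000.0)


@dataclass(frozen=True)
class DerivedGeometry:
    """Geometry derived from the five relations (all lengths in nm)."""

    l_cyl_nm: float
    r_cyl_nm: float
    pitch_nm: float
    n_loops: float
    l_bb_nm: float
    n_turns: float
    box_nm: tuple | None = None  # (wx, wy, lz) for stretched_periodic


def derive_geometry(params: GeometryParams) -> DerivedGeometry:
    """Evaluate the five geometric relations.

    L_cyl = l_chrom / rho_L;  R_cyl = sqrt(l_chrom / rho_V / L_cyl / pi);
    P = l_turn / rho_L;  N_loops = l_chrom / l_loop;
    L_bb = N_loops * (L_gap + L_loopbond).

    For ``stretched_periodic`` the box is L_stretch = l_chrom / rho_L long
    with square cross-section sized to the target volume density.
    """
    rho_l = params.rho_l  # Mb/um
    l_cyl_um = params.l_chrom_mb / rho_l
    r_cyl_um = math.sqrt(params.l_chrom_mb / params.rho_v_mb_per_um3 / l_cyl_um / math.pi)
    pitch_um = params.l_turn_mb / rho_l
    n_loops = params.l_chrom_mb * 1000.0 / params.l_loop_kb
    l_bb_nm = n_loops * (params.l_gap_nm + L_LOOPBOND_NM)
    box = None
    if params.mode == "stretched_periodic":
        volume_um3 = params.l_chrom_mb / params.rho_v_mb_per_um3
        width_um = math.sqrt(volume_um3 / l_cyl_um)
        box = (width_um * 1000.0, width_um * 1000.0, l_cyl_um * 1000.0)
    return DerivedGeometry(
        l_cyl_nm=l_cyl_um * 1000.0,
        r_cyl_nm=r_cyl_um * 1000.0,
        pitch_nm=pitch_um * 1000.0,
        n_loops=n_loops,
        l_bb_nm=l_bb_nm,
        n_turns=params.l_chrom_mb / params.l_turn_mb,
        box_nm=box,
    )


@dataclass
class LoopArray:
    """Loops on a bead lattice: list of (start_bead, end_bead, layer).

    Anchors are the ``start`` and ``end`` beads themselves (inclusive);
    consecutive root loops are separated by ``n_gap`` backbone beads.
    Layers are "root" and "nested".
    """

    loops: list
    n_beads: int
    bp_per_bead: float
    n_gap: int = 0
    n_gap_nested: int = 0
    overlap_allowed: bool = False

    def layer(self, name: str) -> list:
        return [(a, b) for a, b, lay in self.loops if lay == name]

    def backbone_beads(self) -> np.ndarray:
        """Root anchors plus the gap beads between them, in genomic order."""
        beads = []
        roots = sorted(self.layer("root"))
        for i, (a, b) in enumerate(roots):
            beads.append(a)
            beads.append(b)
            if i + 1 < len(roots):
                beads.extend(range(b + 1, roots[i + 1][0]))
        return np.unique(np.asarray(beads, dtype=int))

    def to_bed(self, chrom: str = "chrS") -> str:
        lines = [f"{chrom}\t{int(a * self.bp_per_bead)}\t{int((b + 1) * self.bp_per_bead)}\t{lay}"
                 for a, b, lay in self.loops]
        return "\n".join(lines) + "\n"


def _draw_sizes(rng: np.random.Generator, mean_beads: float, n_max: int) -> np.ndarray:
    sizes = rng.exponential(mean_beads, size=n_max)
    return np.maximum(1, np.rint(sizes)).astype(int)


def sample_consecutive_loops(
    l_chrom_mb: float,
    l_loop_kb: float,
    n_gap: int,
    seed: int = 0,
    bp_per_bead: float = 200.0,
) -> LoopArray:
    """Tile the chromosome with exponential loops separated by n_gap beads.

    Loop sizes are drawn independently from an exponential distribution with
    mean ``l_loop_kb``; the final loop is truncated at the chromosome end so
    that loops plus gaps cover the chromosome exactly.
    """
    if l_loop_kb * 1000.0 < bp_per_bead:
        raise ValueError("mean loop size below one bead")
    rng = np.random.default_rng(seed)
    n_beads = int(l_chrom_mb * 1e6 // bp_per_bead)
    mean_beads = l_loop_kb * 1000.0 / bp_per_bead
    loops = []
    cursor = 0
    while cursor < n_beads:
        size = max(1, int(round(rng.exponential(mean_beads))))
        end = min(cursor + size, n_beads - 1)
        if end <= cursor:
            break
        loops.append((cursor, end, "root"))
        cursor = end + 1 + n_gap
    return LoopArray(loops=loops, n_beads=n_beads, bp_per_bead=bp_per_bead, n_gap=n_gap)


def sample_overlapping_loops(
    l_chrom_mb: float,
    l_loop_kb: float,
    kb_per_loop_spacing: float,
    seed: int = 0,
    bp_per_bead: float = 200.0,
) -> LoopArray:
    """Independently positioned exponential loops (condensin bypassing mode).

    One loop per ``kb_per_loop_spacing`` of chromatin; left anchors are
    uniform on the chromosome, sizes exponential with mean ``l_loop_kb``,
    clipped at the chromosome end.  Overlaps and nesting occur freely.
    """
    rng = np.random.default_rng(seed)
    n_beads = int(l_chrom_mb * 1e6 // bp_per_bead)
    n_loops = int(l_chrom_mb * 1000.0 / kb_per_loop_spacing)
    mean_beads = l_loop_kb * 1000.0 / bp_per_bead
    starts = rng.integers(0, n_beads - 1, size=n_loops)
    sizes = _draw_sizes(rng, mean_beads, n_loops)
    loops = [(int(a), int(min(a + s, n_beads - 1)), "root")
             for a, s in zip(np.sort(starts), sizes)]
    return LoopArray(loops=loops, n_beads=n_beads, bp_per_bead=bp_per_bead,
                     overlap_allowed=True)


def subdivide_nested(
    root: LoopArray,
    l_loop_nested_kb: float,
    n_gap_nested: int,
    seed: int = 0,
) -> LoopArray:
    """Partition each root loop into exponential nested loops.

    Nested loops never cross root anchors.  With ``n_gap_nested = 0`` the
    nested loops of a root loop tile it exactly.  Warns when the nested mean
    is not smaller than the root mean (degenerate nesting).
    """
    if root.overlap_allowed:
        raise ValueError("nested subdivision requires a consecutive root array")
    mean_nested = l_loop_nested_kb * 1000.0 / root.bp_per_bead
    root_sizes = [b - a for a, b, lay in root.loops if lay == "root"]
    if root_sizes and mean_nested >= float(np.mean(root_sizes)):
        import warnings

        warnings.warn("nested mean >= root mean: degenerate nesting", stacklevel=2)
    rng = np.random.default_rng(seed)
    loops = list(root.loops)
    for a, b, lay in root.loops:
        if lay != "root":
            continue
        cursor = a
        while cursor < b:
            size = max(1, int(round(rng.exponential(mean_nested))))
            end = min(cursor + size, b)
            if end <= cursor:
                break
            loops.append((cursor, end, "nested"))
            cursor = end + n_gap_nested
    return LoopArray(loops=loops, n_beads=root.n_beads, bp_per_bead=root.bp_per_bead,
                     n_gap=root.n_gap, n_gap_nested=n_gap_nested)


def _units(geometry: DerivedGeometry, bp_per_bead: float) -> dict:
    u = nm_per_unit(bp_per_bead)
    d = {
        "nm_per_unit": u,
        "l_cyl": geometry.l_cyl_nm / u,
        "r_cyl": geometry.r_cyl_nm / u,
        "pitch": geometry.pitch_nm / u,
    }
    if geometry.box_nm is not None:
        d["box"] = np.asarray(geometry.box_nm) / u
    return d


# wall potential reaches 0.3 kT at the target surface when inflated by this
# overshoot (exp(-x^2/2) = 0.3 -> x = 1.552 sigma)
_WALL_OVERSHOOT_SIGMA = math.sqrt(-2.0 * math.log(0.3))


def build_force_spec(
    loop_array: LoopArray,
    geometry: DerivedGeometry,
    mode: str,
    bp_per_bead: float = 200.0,
    params: GeometryParams | None = None,
) -> ForceField:
    """Emit the force-field spec for one of the three architectures.

    Common to all modes: one anchor bond (L0 = 1, k = 10) per loop and, for
    consecutive arrays, one gap-stretch bond (L0 = n_gap + 1, k = 10)
    between the facing anchors of consecutive root loops.  Mode extras:

    * ``cylinder_helix`` -- cylindrical Gaussian wall (eps = 1 kT,
      sigma = 0.5, dimensions inflated so the potential is 0.3 kT at the
      target surface), end-pull tethers (force 1.0), axial spool exclusion
      (radius 2, eps = 6 kT) for backbone beads, two terminal torsion
      quadruplets through 4 ghost particles (k = 100 kT) realized as
      azimuthal pins, and one azimuthal pin per helical turn.
    * ``stretched_periodic`` -- periodic box from the geometry; terminal
      beads frozen at the box ends.
    * ``overlapping_helix`` -- per-anchor azimuthal pins at target angle
      theta_i = pi (x_left + x_right) / l_turn with stiffness tuned to
      1 kT at 1.2 rad; cylindrical wall; no backbone terms.
    """
    uc = _units(geometry, bp_per_bead)
    roots = sorted(loop_array.layer("root"))
    nested = sorted(loop_array.layer("nested"))
    if mode == "overlapping_helix" and not loop_array.overlap_allowed:
        raise ValueError("overlapping_helix requires an overlapping loop array")
    if mode != "overlapping_helix" and loop_array.overlap_allowed:
        raise ValueError(f"mode {mode} requires a consecutive loop array")

    bonds, k, l0 = [], [], []
    for a, b in roots + nested:
        bonds.append((a, b))
        k.append(10.0)
        l0.append(1.0)
    if not loop_array.overlap_allowed:
        for (a1, b1), (a2, b2) in zip(roots, roots[1:]):
            bonds.append((b1, a2))
            k.append(10.0)
            l0.append(float(a2 - b1))  # n_gap + 1 bead spacings
    ff = ForceField(
        bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
        bond_k=np.asarray(k),
        bond_l0=np.asarray(l0),
        angle_k=1.5,
        repulsion_a=3.0,
        repulsion_cutoff=1.0,
    )

    n = loop_array.n_beads
    sigma_wall = 0.5
    r_wall = uc["r_cyl"] + _WALL_OVERSHOOT_SIGMA * sigma_wall
    l_wall = uc["l_cyl"] + 2.0 * _WALL_OVERSHOOT_SIGMA * sigma_wall

    if mode == "cylinder_helix":
        ff.cylinder = (r_wall, l_wall, 1.0, sigma_wall)
        ff.spool = (2.0, 6.0, loop_array.backbone_beads())
        ff.constant_forces = np.asarray([
            [0, 0.0, 0.0, -1.0],
            [n - 1, 0.0, 0.0, 1.0],
        ])
        # ghost particles: A1, A2 on the axis ends; P1, P2 at the initial
        # terminal positions.  The torsional quadruplets T-A1-A2-P reduce to
        # azimuthal pins on the terminal beads because A1A2 is the z axis.
        ff.ghost_beads = np.arange(n, n + 4)
        ff.torsion_quadruplets = [(0, n, n + 1, n + 2), (n - 1, n, n + 1, n + 3)]
        pins = [[0, _helix_angle(0, loop_array, geometry), 100.0],
                [n - 1, _helix_angle(n - 1, loop_array, geometry), 100.0]]
        # one pinned anchor per turn
        l_turn_beads = loop_array.n_beads / geometry.n_turns
        for t in range(int(geometry.n_turns)):
            target_bead = int(t * l_turn_beads)
            anchor = min((a for a, b in roots), key=lambda a: abs(a - target_bead))
            pins.append([anchor, _helix_angle(anchor, loop_array, geometry), 100.0])
        ff.angular_pins = np.asarray(pins, dtype=float)
    elif mode == "stretched_periodic":
        ff.box = uc["box"].copy()
        ff.frozen = np.asarray([0, n - 1])
    elif mode == "overlapping_helix":
        ff.cylinder = (r_wall, l_wall, 1.0, sigma_wall)
        k_pin = 2.0 / 1.2**2  # 1 kT at 1.2 rad
        l_turn_beads = loop_array.n_beads / geometry.n_turns
        pins = []
        for a, b in roots:
            theta = math.pi * (a + b) / l_turn_beads
            theta = math.atan2(math.sin(theta), math.cos(theta))
            pins.append([a, theta, k_pin])
            pins.append([b, theta, k_pin])
        ff.angular_pins = np.asarray(pins, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ff


def _helix_angle(bead: int, loop_array: LoopArray, geometry: DerivedGeometry) -> float:
    """Azimuth of a bead on the regular helix (phase 0 at the chromosome start)."""
    l_turn_beads = loop_array.n_beads / geometry.n_turns
    phi = 2.0 * math.pi * bead / l_turn_beads
    return math.atan2(math.sin(phi), math.cos(phi))


def _bridge(rng: np.random.Generator, p0: np.ndarray, p1: np.ndarray, n_inner: int
            ) -> np.ndarray:
    """Brownian bridge of ``n_inner`` beads between two fixed points,
    with ~unit-length steps."""
    if n_inner <= 0:
        return np.empty((0, 3))
    n_steps = n_inner + 1
    steps = rng.normal(scale=1.0 / math.sqrt(3.0), size=(n_steps, 3))
    walk = np.cumsum(steps, axis=0)
    t = (np.arange(1, n_steps + 1) / n_steps)[:, None]
    walk = walk - t * walk[-1]
    return p0 + t[:-1] * (p1 - p0) + walk[:-1]


def helix_conformation(
    loop_array: LoopArray,
    geometry: DerivedGeometry,
    bp_per_bead: float = 200.0,
    seed: int = 0,
    backbone_radius: float | None = None,
) -> Conformation:
    """Initial conformation with loop anchors on a regular helix.

    Anchors and gap beads are laid on a helix of the derived pitch (phase 0
    at the chromosome start) at ``backbone_radius``; loop interiors are
    Brownian bridges between their anchors, reflected into the cylinder.
    The default radius is half the cylinder radius: the centerline of a
    helically wound tube that fills the cylinder cross-section runs midway
    between axis and wall.  Appends 4 frozen ghost beads for the terminal
    torsion quadruplets.
    """
    uc = _units(geometry, bp_per_bead)
    rng = np.random.default_rng(seed)
    n = loop_array.n_beads
    r_bb = backbone_radius if backbone_radius is not None else 0.5 * uc["r_cyl"]
    l_turn_beads = n / geometry.n_turns
    pos = np.zeros((n, 3))

    backbone = loop_array.backbone_beads()
    phi = 2.0 * math.pi * backbone / l_turn_beads
    z = uc["l_cyl"] * backbone / n
    pos[backbone, 0] = r_bb * np.cos(phi)
    pos[backbone, 1] = r_bb * np.sin(phi)
    pos[backbone, 2] = z

    on_backbone = np.zeros(n, dtype=bool)
    on_backbone[backbone] = True
    roots = sorted(loop_array.layer("root"))
    for a, b in roots:
        inner = b - a - 1
        if inner > 0:
            pos[a + 1:b] = _bridge(rng, pos[a], pos[b], inner)
    # any beads not yet placed (e.g. trailing gap) interpolate along the helix
    placed = on_backbone.copy()
    for a, b in roots:
        placed[a:b + 1] = True
    missing = np.nonzero(~placed)[0]
    if missing.size:
        phi = 2.0 * math.pi * missing / l_turn_beads
        pos[missing, 0] = r_bb * np.cos(phi)
        pos[missing, 1] = r_bb * np.sin(phi)
        pos[missing, 2] = uc["l_cyl"] * missing / n

    # reflect loop interiors into the cylinder
    rho = np.linalg.norm(pos[:, :2], axis=1)
    over = rho > uc["r_cyl"] - 1.0
    if np.any(over):
        scale = (2 * (uc["r_cyl"] - 1.0) - rho[over]) / rho[over]
        scale = np.clip(scale, 0.05, 1.0)
        pos[over, 0] *= scale
        pos[over, 1] *= scale
    pos[:, 2] = np.clip(pos[:, 2], 0.5, uc["l_cyl"] - 0.5)

    ghosts = np.asarray([
        [0.0, 0.0, 0.0],
        [0.0, 0.0, uc["l_cyl"]],
        pos[0],
        pos[n - 1],
    ])
    all_pos = np.vstack([pos, ghosts])
    cat = np.zeros(n + 4, dtype=np.int8)
    for a, b in roots:
        cat[[a, b]] = 1
    return Conformation(all_pos, bp_per_bead=bp_per_bead, chains=[(0, n)], category=cat)


def stretched_conformation(
    loop_array: LoopArray,
    geometry: DerivedGeometry,
    bp_per_bead: float = 200.0,
    seed: int = 0,
    backbone_kuhn: float | None = None,
) -> Conformation:
    """Initial conformation for the stretched periodic-box architecture.

    The backbone (anchors + gap beads) is a stretched random walk whose
    persistence equals the local brush diameter -- a bottlebrush's backbone
    cannot bend on scales below the thickness of its own loop corona, so
    the walk is generated at Kuhn segments of that length, bridged to the
    box length along z, and interpolated to bead resolution.  Loop
    interiors are Brownian bridges between their anchors.  Terminal beads
    sit at the two box ends on the axis.
    """
    uc = _units(geometry, bp_per_bead)
    rng = np.random.default_rng(seed)
    n = loop_array.n_beads
    box = uc["box"]
    pos = np.zeros((n, 3))

    backbone = loop_array.backbone_beads()
    nb = len(backbone)
    contour = max(1.0, nb - 1.0)
    # brush diameter from the volume density: the corona of loops around a
    # unit of backbone holds lam = n/contour beads at rho beads/unit^3
    rho_units = n / float(np.prod(box))
    lam = n / contour
    r_brush = math.sqrt(lam / (math.pi * rho_units))
    # a brush cannot bend below the thickness of its own corona: Kuhn
    # length of the axis walk = brush diameter
    l_k = backbone_kuhn if backbone_kuhn is not None else max(1.0, 2.0 * r_brush)
    n_k = max(2, int(round(contour / l_k)))
    steps = rng.normal(size=(n_k, 3))
    steps *= l_k / np.linalg.norm(steps, axis=1, keepdims=True)
    walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    walk -= np.linspace(0, 1, n_k + 1)[:, None] * walk[-1]  # close the ends
    walk[:, 2] += np.linspace(0, box[2], n_k + 1)  # stretch along z
    t = np.linspace(0, n_k, nb)
    bb_pos = np.column_stack([np.interp(t, np.arange(n_k + 1), walk[:, k])
                              for k in range(3)])
    bb_pos[1:-1] += rng.normal(scale=0.5, size=(nb - 2, 3))
    pos[backbone] = bb_pos

    roots = sorted(loop_array.layer("root"))
    for a, b in roots:
        inner = b - a - 1
        if inner > 0:
            pos[a + 1:b] = _bridge(rng, pos[a], pos[b], inner)
    placed = np.zeros(n, dtype=bool)
    placed[backbone] = True
    for a, b in roots:
        placed[a:b + 1] = True
    for i in np.nonzero(~placed)[0]:
        pos[i] = pos[i - 1] + rng.normal(scale=0.5, size=3)

    cat = np.zeros(n, dtype=np.int8)
    for a, b in roots:
        cat[[a, b]] = 1
    return Conformation(pos, bp_per_bead=bp_per_bead, chains=[(0, n)], category=cat)


def plant_cohesion(loop_array: LoopArray, f_coh_per_mb: float, seed: int = 0,
                   force_kt_per_nm: float = 0.1) -> dict:
    """Sample cohesion sites and relocate them to loop midpoints.

    Sites are Poisson-distributed at ``f_coh_per_mb`` along the chromosome;
    each is moved to the midpoint bead of the loop containing it (innermost
    layer; sites falling in gaps attach to the nearest loop).  Returns a
    spec with the midpoint beads and the constant lateral pinning force that
    presses them to the virtual sister interface, converted to kT per
    length unit.
    """
    l_chrom_mb = loop_array.n_beads * loop_array.bp_per_bead / 1e6
    rng = np.random.default_rng(seed)
    if f_coh_per_mb <= 0:
        return {"beads": np.empty(0, dtype=int), "force_kt_per_unit": 0.0}
    n_sites = rng.poisson(f_coh_per_mb * l_chrom_mb)
    sites = rng.integers(0, loop_array.n_beads, size=n_sites)
    loops = sorted(loop_array.loops, key=lambda t: t[1] - t[0])  # innermost first
    beads = []
    for s in sites:
        containing = [(a, b) for a, b, lay in loops if a <= s <= b]
        if containing:
            a, b = containing[0]
        else:
            a, b = min(((a, b) for a, b, _ in loops),
                       key=lambda ab: min(abs(ab[0] - s), abs(ab[1] - s)))
        beads.append((a + b) // 2)
    force = force_kt_per_nm * nm_per_unit(loop_array.bp_per_bead)
    return {"beads": np.asarray(beads, dtype=int),
            "force_kt_per_unit": float(force),
            "direction": np.asarray([1.0, 0.0, 0.0])}
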