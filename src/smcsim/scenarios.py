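"""End-to-end simulation scenarios at desk scale.

Each scenario wires the modules together the way the corresponding
biological experiment is analyzed:

* ``prophase_collision`` -- 1D lattice with extrusive cohesin (CTCF
  capture, finite lifetime) equilibrated to a G2 steady state, then
  synchronously loaded condensins sweep the lattice under a chosen
  collision policy; the number of CTCF-CTCF-anchored cohesins (the proxy
  for Hi-C dot strength) is tracked relative to G2.
* ``cohesion_sisters`` -- two sister chains with abundant condensin I
  extruders and diffusing cohesive cohesins bridging the sisters, coupled
  1D+3D in good solvent; yields synthetic fluorescence cross-section
  profiles.
* ``condensin2_only`` / ``condensin1_only`` / ``nested`` / ``overlapping``
  / ``cohesion_effect`` -- mitotic chromatid builder models, relaxed with
  the reference integrator and converted to P(s) curves.

Desk scales (chromosome sizes, bead sizes, step counts) are deliberately
reduced from the production GPU scale; the defaults below preserve the
models' dimensionless ratios (loop/turn/pitch/density) so the qualitative
observables -- helical second diagonal, -1.5 P(s) slope, policy ordering --
are reproduced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import extrusion1d as e1d
from . import fixtures, imaging_profiles, insilico_hic, mitotic_builder
from .polymer3d import Conformation, ForceField, IntegratorParams, integrate, update_lef_bonds

__all__ = [
    "prophase_collision",
    "cohesion_sisters",
    "condensin2_only",
    "condensin1_only",
    "nested_model",
    "overlapping_model",
    "cohesion_effect_model",
    "run_scenario",
]


# -- prophase cohesin-vs-condensin lattice scenario -------------------------

def _add_species(state: e1d.ExtrusionState, sp: e1d.LEFSpecies) -> None:
    """Load a new species into a running state (synchronous mid-run loading)."""
    state.species[sp.name] = sp
    n = e1d._n_lefs_for(sp, state.lattice)
    next_id = len(state.lefs)
    for _ in range(n):
        lef = e1d.LEF(lef_id=next_id, species=sp.name, legs=[0, 0])
        next_id += 1
        e1d._load_lef(state, lef)
        state.lefs.append(lef)


def prophase_collision(
    policy: str = "stall",
    seed: int = 0,
    scale: float = 1.0,
    g2_epochs: int = 3000,
    prophase_epochs: int = 1800,
    sample_every: int = 60,
    rebind: bool = True,
    rebind_on_unload: bool = False,
) -> dict:
    """G2 cohesin steady state, then condensin sweep under one policy.

    The lattice is 20,000 sites (1 kb each, scaled by ``scale``) with the
    CTCF barrier list at 90% capture.  Cohesin: lambda = 100 kb, d = 300 kb,
    10 kb/min (every 12th epoch); condensin: infinite lifetime, d = 700 kb,
    120 kb/min (every epoch), CTCF-transparent, loaded synchronously at the
    prophase start.  One epoch is 1 s of real time (condensin extrudes
    2 kb/epoch at 120 kb/min).  Cohesins unbinding by natural turnover
    rebind (continuous loading); cohesins displaced by a condensin (unload
    outcome, or a push against their captured leg) are lost from the pool
    by default (``rebind_on_unload``) -- with instant re-loading the
    anchored population re-equilibrates once condensins reach their static
    collision-limited state, and the policy contrast vanishes.  Returns the
    CTCF-anchored cohesin count time series normalized to its G2 mean.
    """
    n_sites = int(20_000 * scale)
    sites = fixtures.ctcf_sites()
    barriers = [(int(s), 0.9) for s in sites if s < n_sites]
    lattice = e1d.Lattice(n_sites=n_sites, kb_per_site=1.0, barriers=tuple(barriers))
    cohesin = e1d.LEFSpecies(
        name="extrusive_cohesin", separation_d_kb=300.0, processivity_lambda_kb=100.0,
        step_interval=12, loading="stochastic", barrier_mode="capturable",
        motion="extruding", rebind=rebind, rebind_on_unload=rebind_on_unload)
    pol = e1d.CollisionPolicy({
        ("condensin", "extrusive_cohesin"): policy,
        ("extrusive_cohesin", "condensin"): "stall",
    })
    state = e1d.initialize_state(lattice, [cohesin], pol, seed=seed)

    g2_counts = []
    for epoch in range(g2_epochs):
        e1d.step_epoch(state)
        if epoch >= g2_epochs // 2 and epoch % sample_every == 0:
            g2_counts.append(
                e1d.count_captured(state, "extrusive_cohesin", both_legs=False))
    g2_mean = float(np.mean(g2_counts)) if g2_counts else float("nan")

    condensin = e1d.LEFSpecies(
        name="condensin", separation_d_kb=700.0, processivity_lambda_kb=None,
        step_interval=1, loading="synchronous", barrier_mode="transparent",
        motion="extruding")
    _add_species(state, condensin)

    epochs, counts = [], []
    for epoch in range(prophase_epochs):
        e1d.step_epoch(state)
        if epoch % sample_every == 0:
            epochs.append(epoch)
            counts.append(
                e1d.count_captured(state, "extrusive_cohesin", both_legs=False))
    counts = np.asarray(counts, float)
    tail = counts[-5:] if len(counts) >= 5 else counts
    return {
        "policy": policy,
        "g2_anchored": g2_mean,
        "epochs": np.asarray(epochs),
        "anchored": counts,
        "normalized": counts / g2_mean if g2_mean > 0 else counts * np.nan,
        "final_normalized": float(tail.mean() / g2_mean) if g2_mean > 0 else float("nan"),
        "state": state,
    }


# -- two-sister cohesion scenario --------------------------------------------

def _mark_categories(conf: Conformation, state: e1d.ExtrusionState) -> None:
    conf.category[:] = 0
    for lef in state.lefs:
        if not lef.bound:
            continue
        code = 2 if state.species_of(lef).two_chain else 1
        for leg in lef.legs:
            conf.category[leg] = code


def cohesion_sisters(
    policy: str = "bypass",
    seed: int = 0,
    chain_kb: int = 1200,
    condensin_d_kb: float = 50.0,
    condensin_lambda_kb: float = 800.0,
    cohesin_d_kb: float = 200.0,
    n_cycles: int = 120,
    steps_per_cycle: int = 250,
    epochs_per_cycle: int = 4,
    n_profile_frames: int = 10,
    pre_epochs: int = 400,
) -> dict:
    """Two tethered sisters: condensin I bottlebrushes + diffusing cohesion.

    Two chains of ``chain_kb`` 1-kb beads start as overlapping random walks.
    Condensin I (dense: lambda = 800 kb, d = 50 kb, stalls against itself)
    extrudes on both chains while cohesive cohesins (two-legged diffusing
    walkers with one leg per sister) bridge them.  The condensin-cohesin
    collision outcome is ``policy`` ("bypass" or "stall").  1D extrusion and
    3D Brownian dynamics in good solvent alternate; condensin loop bonds and
    inter-sister cohesin bonds track the 1D state.  Returns radial-profile
    projections per monomer category, aggregated over the final
    conformations.
    """
    n = chain_kb
    lattice = e1d.Lattice(n_sites=2 * n, kb_per_site=1.0, chain_bounds=(n,))
    condensin = e1d.LEFSpecies(
        name="condensin_I", separation_d_kb=condensin_d_kb,
        processivity_lambda_kb=condensin_lambda_kb, step_interval=1,
        motion="extruding")
    cohesive = e1d.LEFSpecies(
        name="cohesive_cohesin", separation_d_kb=cohesin_d_kb,
        processivity_lambda_kb=None, step_interval=1, motion="diffusing",
        two_chain=True)
    pol = e1d.CollisionPolicy({
        ("condensin_I", "cohesive_cohesin"): policy,
        ("cohesive_cohesin", "condensin_I"): "stall",
    })
    state = e1d.initialize_state(lattice, [cohesive, condensin], pol, seed=seed)
    # bring the 1D loop array to steady state before coupling the 3D chain:
    # the imaged geometry is a dynamic steady state, not the folding transient
    e1d.run_epochs(state, pre_epochs)

    rng = np.random.default_rng(seed + 1)
    # both sisters start as the same random walk, slightly displaced
    walk = np.cumsum(rng.normal(scale=1.0 / math.sqrt(3.0), size=(n, 3)), axis=0)
    pos = np.vstack([walk, walk + [0.3, 0.0, 0.0]])
    conf = Conformation(pos, bp_per_bead=1000.0, chains=[(0, n), (n, 2 * n)])
    ff = ForceField(angle_k=1.5, repulsion_a=3.0, repulsion_cutoff=1.0)

    condensin_proj: list = []
    cohesin_proj: list = []
    chain_axis_split: list = []
    for cycle in range(n_cycles):
        for _ in range(epochs_per_cycle):
            e1d.step_epoch(state)
        ff = update_lef_bonds(ff, state, bp_per_bead=1000.0, n_beads=2 * n)
        params = IntegratorParams(n_steps=steps_per_cycle, seed=seed + 10 + cycle)
        conf = integrate(conf, ff, params)
        if cycle >= n_cycles - n_profile_frames:
            _mark_categories(conf, state)
            bonds = ff.lef_bonds
            same_chain = (bonds[:, 0] < n) == (bonds[:, 1] < n)
            bridges = bonds[same_chain]
            try:
                spine_a = imaging_profiles.extract_spine(conf, bridges, chain=0)
                spine_b = imaging_profiles.extract_spine(conf, bridges, chain=1)
                frames = imaging_profiles.pair_spines(spine_a, spine_b, conf)
            except ValueError:
                continue
            if not frames:
                continue
            condensin_proj.append(imaging_profiles.radial_profile(conf, frames, "condensin"))
            cohesin_proj.append(imaging_profiles.radial_profile(conf, frames, "cohesin"))
            # per-sister condensin axis positions along the section lines
            proj_all = imaging_profiles.radial_profile(conf, frames, "condensin")
            cond_beads = np.nonzero(conf.category == 1)[0]
            side = cond_beads < n
            if side.any() and (~side).any():
                chain_axis_split.append(
                    abs(float(np.mean(proj_all[side])) - float(np.mean(proj_all[~side]))))
    return {
        "policy": policy,
        "conformation": conf,
        "state": state,
        "condensin_proj": np.concatenate(condensin_proj) if condensin_proj else np.empty(0),
        "cohesin_proj": np.concatenate(cohesin_proj) if cohesin_proj else np.empty(0),
        "axis_separation": float(np.mean(chain_axis_split)) if chain_axis_split else float("nan"),
    }


# -- mitotic chromatid models ------------------------------------------------

@dataclass
class ChromatidModel:
    """Bundle of one builder model run end to end."""

    loop_array: mitotic_builder.LoopArray
    geometry: mitotic_builder.DerivedGeometry
    conformation: Conformation
    ff: ForceField
    ps: insilico_hic.PsCurve | None = None
    contacts: object = None
    ps_replicates: list = field(default_factory=list)


def condensin2_only(
    seed: int = 0,
    l_chrom_mb: float = 60.0,
    bp_per_bead: float = 4000.0,
    relax_steps: int = 1500,
    n_reps: int = 30,
    compute_ps: bool = True,
    n_replicates: int = 3,
) -> ChromatidModel:
    """Condensin II-only helical chromatid (desk scale).

    400 kb loops, 80 nm gaps, 400 nm pitch, 17 Mb per turn, 44 Mb/um^3,
    sigma_C = 48 nm -- the best-fit parameter set -- on a reduced 60 Mb
    chromosome at 4 kb beads (3.5 helical turns, enough genomic span for
    contacts two turns apart, i.e. a third diagonal).  P(s) is averaged over independently sampled
    loop-array replicates.
    """
    from .polymer3d import nm_per_unit

    u = nm_per_unit(bp_per_bead)
    params = mitotic_builder.GeometryParams(
        l_chrom_mb=l_chrom_mb, l_loop_kb=400.0, l_gap_nm=80.0,
        l_turn_mb=17.0, rho_v_mb_per_um3=44.0, sigma_c_nm=48.0,
        pitch_nm=400.0, mode="cylinder_helix")
    geom = mitotic_builder.derive_geometry(params)
    n_gap = max(0, round(params.l_gap_nm / u))
    model = None
    curves = []
    for rep in range(max(1, n_replicates if compute_ps else 1)):
        rep_seed = seed + 1000 * rep
        loops = mitotic_builder.sample_consecutive_loops(
            l_chrom_mb, params.l_loop_kb, n_gap, seed=rep_seed,
            bp_per_bead=bp_per_bead)
        conf = mitotic_builder.helix_conformation(loops, geom, bp_per_bead,
                                                  seed=rep_seed + 1)
        ff = mitotic_builder.build_force_spec(loops, geom, "cylinder_helix",
                                              bp_per_bead)
        ff.frozen = ff.ghost_beads
        if relax_steps > 0:
            conf = integrate(conf, ff,
                             IntegratorParams(n_steps=relax_steps, seed=rep_seed + 2))
        model = ChromatidModel(loops, geom, conf, ff)
        if compute_ps:
            contacts = insilico_hic.simulate_contacts(
                conf, sigma_c_nm=params.sigma_c_nm, n_reps=n_reps,
                seed=rep_seed + 3)
            model.contacts = contacts
            curves.append(insilico_hic.ps_from_contacts(contacts))
    if compute_ps:
        model.ps = _average_ps(curves)
        model.ps_replicates = curves
    return model


def condensin1_only(
    seed: int = 0,
    l_chrom_mb: float = 30.0,
    bp_per_bead: float = 1000.0,
    relax_steps: int = 1000,
    n_reps: int = 30,
    compute_ps: bool = True,
    n_replicates: int = 5,
) -> ChromatidModel:
    """Condensin I-only stretched chromatid (desk scale).

    100 kb loops, 20 nm gaps, linear density 25 Mb/um in a periodic box at
    77 Mb/um^3, sigma_C = 48 nm, on a reduced 30 Mb chromosome at 1 kb
    beads.  P(s) follows ~s^-1.5 over 2-8 Mb and shows no second diagonal.
    The periodic box maintains melt density during relaxation; cis contacts
    are computed on the unwrapped coordinates.  P(s) is averaged over
    ``n_replicates`` independently sampled and relaxed loop arrays, and the
    relaxation budget is the shortest that equilibrates bead-scale
    structure (bond statistics plateau by a few hundred steps).
    """
    from .polymer3d import nm_per_unit

    u = nm_per_unit(bp_per_bead)
    params = mitotic_builder.GeometryParams(
        l_chrom_mb=l_chrom_mb, l_loop_kb=100.0, l_gap_nm=20.0,
        l_turn_mb=l_chrom_mb, rho_v_mb_per_um3=77.0, sigma_c_nm=48.0,
        rho_l_mb_per_um=25.0, mode="stretched_periodic")
    geom = mitotic_builder.derive_geometry(params)
    n_gap = max(0, round(params.l_gap_nm / u))
    model = None
    curves = []
    for rep in range(max(1, n_replicates)):
        rep_seed = seed + 1000 * rep
        loops = mitotic_builder.sample_consecutive_loops(
            l_chrom_mb, params.l_loop_kb, n_gap, seed=rep_seed,
            bp_per_bead=bp_per_bead)
        conf = mitotic_builder.stretched_conformation(
            loops, geom, bp_per_bead, seed=rep_seed + 1)
        ff = mitotic_builder.build_force_spec(loops, geom, "stretched_periodic",
                                              bp_per_bead)
        if relax_steps > 0:
            conf = integrate(conf, ff,
                             IntegratorParams(n_steps=relax_steps, seed=rep_seed + 2))
        model = ChromatidModel(loops, geom, conf, ff)
        if compute_ps:
            contacts = insilico_hic.simulate_contacts(
                conf, sigma_c_nm=params.sigma_c_nm, n_reps=n_reps,
                seed=rep_seed + 3)
            model.contacts = contacts
            curves.append(insilico_hic.ps_from_contacts(contacts))
    if compute_ps:
        model.ps = _average_ps(curves)
        model.ps_replicates = curves
    return model


def _average_ps(curves: list) -> insilico_hic.PsCurve:
    """Arithmetic mean of replicate P(s) curves."""
    stack = np.asarray([c.values for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(stack, axis=0)
    return insilico_hic.PsCurve(curves[0].s_bp, vals)


def nested_model(seed: int = 0, l_chrom_mb: float = 30.0,
                 bp_per_bead: float = 4000.0, relax_steps: int = 0) -> ChromatidModel:
    """Two-layer (condensin II root + condensin I nested) helical chromatid.

    Root 400 kb loops with 80 nm gaps subdivided into 100 kb nested loops
    (no nested gaps at this bead size), 10 Mb per turn, 77 Mb/um^3.
    """
    from .polymer3d import nm_per_unit

    u = nm_per_unit(bp_per_bead)
    params = mitotic_builder.GeometryParams(
        l_chrom_mb=l_chrom_mb, l_loop_kb=400.0, l_gap_nm=80.0,
        l_turn_mb=10.0, rho_v_mb_per_um3=77.0, sigma_c_nm=43.0,
        pitch_nm=400.0, mode="cylinder_helix")
    geom = mitotic_builder.derive_geometry(params)
    roots = mitotic_builder.sample_consecutive_loops(
        l_chrom_mb, 400.0, max(0, round(80.0 / u)), seed=seed, bp_per_bead=bp_per_bead)
    loops = mitotic_builder.subdivide_nested(roots, 100.0, 0, seed=seed + 1)
    conf = mitotic_builder.helix_conformation(loops, geom, bp_per_bead, seed=seed + 2)
    ff = mitotic_builder.build_force_spec(loops, geom, "cylinder_helix", bp_per_bead)
    ff.frozen = ff.ghost_beads
    if relax_steps > 0:
        conf = integrate(conf, ff, IntegratorParams(n_steps=relax_steps, seed=seed + 3))
    return ChromatidModel(loops, geom, conf, ff)


def overlapping_model(seed: int = 0, l_chrom_mb: float = 30.0,
                      bp_per_bead: float = 4000.0, relax_steps: int = 0
                      ) -> ChromatidModel:
    """Overlapping condensin II loops (complete bypassing scenario).

    900 kb loops, one per 360 kb, 17.5 Mb per turn; no backbone: loop
    anchors are azimuthally pinned instead.
    """
    params = mitotic_builder.GeometryParams(
        l_chrom_mb=l_chrom_mb, l_loop_kb=900.0, l_gap_nm=0.0,
        l_turn_mb=17.5, rho_v_mb_per_um3=44.0, sigma_c_nm=48.0,
        pitch_nm=400.0, mode="overlapping_helix")
    geom = mitotic_builder.derive_geometry(params)
    loops = mitotic_builder.sample_overlapping_loops(
        l_chrom_mb, 900.0, 360.0, seed=seed, bp_per_bead=bp_per_bead)
    conf = _overlapping_conformation(loops, geom, bp_per_bead, seed + 1)
    ff = mitotic_builder.build_force_spec(loops, geom, "overlapping_helix", bp_per_bead)
    if relax_steps > 0:
        conf = integrate(conf, ff, IntegratorParams(n_steps=relax_steps, seed=seed + 2))
    return ChromatidModel(loops, geom, conf, ff)


def _overlapping_conformation(loops, geom, bp_per_bead, seed) -> Conformation:
    """Random-walk start confined to the cylinder (no backbone helix)."""
    from .polymer3d import init_conformation, nm_per_unit

    u = nm_per_unit(bp_per_bead)
    conf = init_conformation(loops.n_beads, "random_walk", seed=seed,
                             bp_per_bead=bp_per_bead)
    pos = conf.positions
    r_cyl = geom.r_cyl_nm / u
    l_cyl = geom.l_cyl_nm / u
    rho = np.linalg.norm(pos[:, :2], axis=1)
    scale = np.minimum(1.0, (0.9 * r_cyl) / np.maximum(rho, 1e-9))
    pos[:, :2] *= scale[:, None]
    pos[:, 2] = np.interp(np.arange(loops.n_beads), [0, loops.n_beads - 1],
                          [0.5, l_cyl - 0.5])
    cat = np.zeros(loops.n_beads, dtype=np.int8)
    for a, b, _ in loops.loops:
        cat[[a, b]] = 1
    return Conformation(pos, bp_per_bead=bp_per_bead, chains=[(0, loops.n_beads)],
                        category=cat)


def cohesion_effect_model(seed: int = 0, f_coh_per_mb: float = 1.0,
                          **kwargs) -> ChromatidModel:
    """Helical chromatid with cohesion sites pinned to one side.

    Cohesion sites at ~1/Mb are relocated to loop midpoints and pressed
    toward the virtual sister interface by a constant 0.1 kT/nm lateral
    force.
    """
    model = condensin2_only(seed=seed, compute_ps=False, relax_steps=0, **kwargs)
    spec = mitotic_builder.plant_cohesion(model.loop_array, f_coh_per_mb, seed=seed + 7)
    if len(spec["beads"]):
        rows = np.zeros((len(spec["beads"]), 4))
        rows[:, 0] = spec["beads"]
        rows[:, 1:4] = spec["force_kt_per_unit"] * spec["direction"]
        model.ff.constant_forces = np.vstack([model.ff.constant_forces, rows])
        model.conformation.category[spec["beads"]] = 2
    return model


_SCENARIOS = {
    "prophase_collision": prophase_collision,
    "cohesion_sisters": cohesion_sisters,
    "condensinII_only": condensin2_only,
    "condensinI_only": condensin1_only,
    "nested": nested_model,
    "overlapping": overlapping_model,
    "cohesion_effect": cohesion_effect_model,
}


def run_scenario(name: str, seed: int = 0, **kwargs):
    """Run a named scenario; see the module docstring for the catalogue."""
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    return _SCENARIOS[name](seed=seed, **kwargs)
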