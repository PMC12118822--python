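"""Stochastic 1D lattice simulation of SMC loop extrusion.

Loop-extruding factors (LEFs) are two-legged walkers on a discrete lattice
(1 site = 1 kb by default).  Extruding species (cohesin, condensin I/II)
move their legs apart one site per active epoch, enlarging a loop; diffusing
species (cohesive cohesin) step each leg +-1 with equal probability.  The
engine supports multiple species with independent update cadences, finite or
infinite residence times, bidirectional barrier sites with probabilistic
capture (CTCF), and a configurable policy for what happens when a moving leg
encounters a leg of another complex: stall, bypass, push, or unload.

Collisions within a species always stall: the legs halt until one complex
unbinds.  The four cross-species outcomes are the "rules of engagement"
whose consequences for chromatin architecture this package explores.

Cohesive cohesin is modeled as a two-legged diffusing walker whose legs live
on the two sister chromatids (two chains of the same lattice), linking them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Lattice",
    "LEFSpecies",
    "CollisionPolicy",
    "LEF",
    "ExtrusionState",
    "initialize_state",
    "step_epoch",
    "run_epochs",
    "gap_fraction",
    "theoretical_gap_fraction",
    "loop_size_stats",
    "loop_coverage",
    "count_captured",
    "lef_table",
]

Outcome = Literal["stall", "bypass", "push", "unload"]


@dataclass(frozen=True)
class Lattice:
    """A 1D chromatin lattice, optionally split into chains (sisters).

    Parameters
    ----------
    n_sites
        Total number of lattice sites.
    kb_per_site
        Genomic content of one site (default 1 kb).
    barriers
        Sequence of ``(site, capture_probability)`` pairs.  Barriers are
        bidirectional; capture is tested when a capturable leg steps onto
        the barrier site.
    chain_bounds
        Chain boundaries as in ``numpy.split``: ``[]`` means one chain
        covering all sites; ``[n]`` splits into ``[0, n)`` and ``[n, total)``.
    """

    n_sites: int
    kb_per_site: float = 1.0
    barriers: tuple = ()
    chain_bounds: tuple = ()

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("lattice must have at least one site")
        object.__setattr__(self, "barriers", tuple((int(s), float(p)) for s, p in self.barriers))
        object.__setattr__(self, "chain_bounds", tuple(int(b) for b in self.chain_bounds))
        for s, p in self.barriers:
            if not 0 <= s < self.n_sites:
                raise ValueError(f"barrier site {s} outside lattice")
            if not 0.0 <= p <= 1.0:
                raise ValueError("capture probability must be in [0, 1]")
        prev = 0
        for b in self.chain_bounds:
            if not prev < b < self.n_sites:
                raise ValueError("chain bounds must be increasing interior splits")
            prev = b

    @property
    def chain_spans(self) -> list[tuple[int, int]]:
        edges = (0, *self.chain_bounds, self.n_sites)
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def chain_of(self, site: int) -> int:
        return int(np.searchsorted(np.asarray(self.chain_bounds), site, side="right"))

    @property
    def total_kb(self) -> float:
        return self.n_sites * self.kb_per_site


@dataclass(frozen=True)
class LEFSpecies:
    """Kinetic parameters of one SMC species.

    ``separation_d_kb`` sets the loaded copy number as
    ``floor(chain_kb / d)`` per chain (the rounding rule is floor, tested).
    ``processivity_lambda_kb`` is the mean chromatin extruded before
    unbinding in the absence of obstacles; ``None`` means infinite lifetime.
    ``step_interval`` is the number of epochs between active updates, which
    encodes relative extrusion speeds (e.g. cohesin at 10 kb/min vs condensin
    at 120 kb/min -> intervals 12 and 1).
    """

    name: str
    separation_d_kb: float
    processivity_lambda_kb: float | None = None
    step_interval: int = 1
    loading: Literal["stochastic", "synchronous"] = "stochastic"
    barrier_mode: Literal["capturable", "transparent"] = "transparent"
    motion: Literal["extruding", "diffusing"] = "extruding"
    two_chain: bool = False  # cohesive cohesin: one leg per sister
    rebind: bool = True  # complexes unbinding by natural turnover rejoin the pool
    # whether a complex removed by a collision (unload outcome, or a push
    # against an immovable leg) reloads; False models net loss of displaced
    # cohesin during prophase
    rebind_on_unload: bool = True

    def __post_init__(self):
        if self.separation_d_kb <= 0:
            raise ValueError("separation d must be positive")
        if self.motion == "extruding" and self.processivity_lambda_kb is not None:
            if self.processivity_lambda_kb <= 0:
                raise ValueError("processivity must be positive for extruding species")
        if self.step_interval < 1:
            raise ValueError("step_interval must be >= 1")


class CollisionPolicy:
    """Outcome matrix for leg-leg encounters, keyed by (moving, blocking) species.

    Same-species encounters default to ``stall`` and cannot be overridden for
    condensin-condensin and cohesin-cohesin pairs per the model's rules.
    """

    def __init__(self, rules: dict[tuple[str, str], Outcome] | None = None,
                 default: Outcome = "stall", self_default: Outcome = "stall"):
        self.default: Outcome = default
        # self_default is "stall" for all SMC species; "bypass" yields
        # non-interacting extruders (the mean-field gap-formula regime)
        self.self_default: Outcome = self_default
        self.rules: dict[tuple[str, str], Outcome] = dict(rules or {})
        for (a, b), out in list(self.rules.items()) + [(("", ""), default),
                                                       (("", ""), self_default)]:
            if out not in ("stall", "bypass", "push", "unload"):
                raise ValueError(f"unknown outcome {out!r}")

    def outcome(self, moving: str, blocking: str) -> Outcome:
        if moving == blocking:
            return self.rules.get((moving, blocking), self.self_default)
        return self.rules.get((moving, blocking), self.default)


@dataclass
class LEF:
    """One two-legged complex.  ``legs`` are global site indices; for a
    two-chain (cohesive) complex each leg lives on its own chain."""

    lef_id: int
    species: str
    legs: list  # [left_site, right_site]
    captured: list = field(default_factory=lambda: [False, False])
    stalled: list = field(default_factory=lambda: [False, False])
    bound: bool = True

    def span_sites(self) -> int:
        return abs(self.legs[1] - self.legs[0])


@dataclass
class ExtrusionState:
    """Full mutable simulation state."""

    lattice: Lattice
    species: dict
    policy: CollisionPolicy
    lefs: list
    rng: np.random.Generator
    epoch: int = 0
    occupancy: dict = field(default_factory=dict)  # site -> lef_id

    def species_of(self, lef: LEF) -> LEFSpecies:
        return self.species[lef.species]

    def bound_lefs(self, species: str | Iterable[str] | None = None) -> list:
        names = _species_set(self, species)
        return [l for l in self.lefs if l.bound and l.species in names]


def _species_set(state: ExtrusionState, species) -> set:
    if species is None:
        return set(state.species)
    if isinstance(species, str):
        return {species}
    return set(species)


def theoretical_gap_fraction(lambda_kb: float, d_kb: float) -> float:
    """Mean-field steady-state gap fraction g = exp(-lambda/d)."""
    from . import kinetics

    return kinetics.theoretical_gap_fraction(lambda_kb, d_kb)


def _n_lefs_for(species: LEFSpecies, lattice: Lattice) -> int:
    if species.two_chain:
        # one complex bridges both sisters; count from one chain's length
        span_kb = (lattice.chain_spans[0][1] - lattice.chain_spans[0][0]) * lattice.kb_per_site
        return int(span_kb // species.separation_d_kb)
    return int(lattice.total_kb // species.separation_d_kb)


def initialize_state(
    lattice: Lattice,
    species: Sequence[LEFSpecies],
    policy: CollisionPolicy | None = None,
    seed: int = 0,
) -> ExtrusionState:
    """Load every species onto the lattice and return the initial state.

    Copy numbers are ``floor(total_kb / d)`` per species.  Both loading modes
    place complexes at uniformly random unoccupied sites with loop size 0
    (both legs on one site); they differ in turnover, not placement
    ("synchronous" species load once here and, with infinite lifetime, stay).
    Two-chain species require a two-chain lattice and load with one leg at
    the same offset on each sister.
    """
    rng = np.random.default_rng(seed)
    state = ExtrusionState(lattice=lattice, species={s.name: s for s in species},
                           policy=policy or CollisionPolicy(), lefs=[], rng=rng)
    if len({s.name for s in species}) != len(species):
        raise ValueError("duplicate species names")
    next_id = 0
    for sp in species:
        n = _n_lefs_for(sp, lattice)
        if n > lattice.n_sites - len(state.occupancy):
            raise ValueError(
                f"species {sp.name}: {n} complexes exceed free sites "
                f"(over-dense configuration)")
        for _ in range(n):
            lef = LEF(lef_id=next_id, species=sp.name, legs=[0, 0])
            next_id += 1
            _load_lef(state, lef)
            state.lefs.append(lef)
    return state


def _free_sites(state: ExtrusionState, lo: int, hi: int) -> np.ndarray:
    occ = np.fromiter(state.occupancy.keys(), dtype=np.int64, count=len(state.occupancy))
    mask = np.ones(hi - lo, dtype=bool)
    occ = occ[(occ >= lo) & (occ < hi)]
    mask[occ - lo] = False
    return np.nonzero(mask)[0] + lo


def _load_lef(state: ExtrusionState, lef: LEF) -> None:
    """Place ``lef`` at a random free site (loop size 0); two-chain species
    get one leg at the mirrored offset on the second chain."""
    sp = state.species_of(lef)
    if sp.two_chain:
        if len(state.lattice.chain_spans) < 2:
            raise ValueError("two-chain species require a two-chain lattice")
        (a0, a1), (b0, _b1) = state.lattice.chain_spans[:2]
        free = [s for s in _free_sites(state, a0, a1)
                if (s - a0 + b0) not in state.occupancy]
        if not free:
            raise ValueError("no free paired sites for cohesive complex")
        site = int(state.rng.choice(free))
        mate = site - a0 + b0
        lef.legs = [site, mate]
        state.occupancy[site] = lef.lef_id
        state.occupancy[mate] = lef.lef_id
    else:
        free = _free_sites(state, 0, state.lattice.n_sites)
        if free.size == 0:
            raise ValueError("no free sites to load complex")
        site = int(state.rng.choice(free))
        lef.legs = [site, site]
        state.occupancy[site] = lef.lef_id
    lef.captured = [False, False]
    lef.stalled = [False, False]
    lef.bound = True


def _unbind(state: ExtrusionState, lef: LEF, rebind: bool) -> None:
    for leg in set(lef.legs):
        if state.occupancy.get(leg) == lef.lef_id:
            del state.occupancy[leg]
    lef.bound = False
    if rebind:
        _load_lef(state, lef)


def _chain_span_of(state: ExtrusionState, site: int) -> tuple[int, int]:
    return state.lattice.chain_spans[state.lattice.chain_of(site)]


def _push_run(state: ExtrusionState, start: int, direction: int) -> tuple[list, bool]:
    """Collect the contiguous run of occupied sites from ``start`` in
    ``direction``; a complex whose both legs sit adjacently is carried as a
    unit.  Returns (sites, movable): movable is False when the run abuts a
    chain end or contains a captured leg."""
    lo, hi = _chain_span_of(state, start)
    sites = []
    s = start
    while lo <= s < hi and s in state.occupancy:
        lef = state.lefs[state.occupancy[s]]
        # captured and stalled legs are immovable
        for i, leg in enumerate(lef.legs):
            if leg == s and (lef.captured[i] or lef.stalled[i]):
                return sites, False
        sites.append(s)
        s += direction
    if not (lo <= s < hi):
        return sites, False
    return sites, True


def _resolve_move(state: ExtrusionState, lef: LEF, leg_idx: int, direction: int) -> None:
    """Attempt to move one leg of ``lef`` by one site; apply barrier capture
    and the collision policy."""
    sp = state.species_of(lef)
    site = lef.legs[leg_idx]
    lo, hi = _chain_span_of(state, site)
    target = site + direction
    if not lo <= target < hi:
        if sp.motion == "extruding":
            lef.stalled[leg_idx] = True
        return

    blocker_id = state.occupancy.get(target)
    if blocker_id is not None and blocker_id != lef.lef_id:
        blocker = state.lefs[blocker_id]
        out = state.policy.outcome(lef.species, blocker.species)
        if out == "stall":
            lef.stalled[leg_idx] = True
            return
        if out == "unload":
            bsp = state.species_of(blocker)
            _unbind(state, blocker, rebind=bsp.rebind and bsp.rebind_on_unload)
        elif out == "push":
            run, movable = _push_run(state, target, direction)
            if movable:
                for s in sorted(run, reverse=(direction > 0)):
                    rid = state.occupancy.pop(s)
                    r = state.lefs[rid]
                    for li, leg in enumerate(r.legs):
                        if leg == s:
                            r.legs[li] = s + direction
                    state.occupancy[s + direction] = rid
            else:
                # push against chain end / captured leg unloads the contacted complex
                bsp = state.species_of(blocker)
                _unbind(state, blocker, rebind=bsp.rebind and bsp.rebind_on_unload)
        elif out == "bypass":
            t = target
            while lo <= t < hi and t in state.occupancy:
                t += direction
            if not (lo <= t < hi):
                lef.stalled[leg_idx] = True
                return
            target = t
    if target in state.occupancy and state.occupancy[target] != lef.lef_id:
        # push freed the site only partially (should not happen) -> stall
        lef.stalled[leg_idx] = True
        return

    # barrier capture on the step onto the barrier site
    captured = False
    if sp.barrier_mode == "capturable":
        # crossing possibly several sites under bypass: test each traversed barrier
        for s in range(site + direction, target + direction, direction):
            p = _barrier_prob(state.lattice, s)
            if p and state.rng.random() < p:
                target = s
                if target in state.occupancy and state.occupancy[target] != lef.lef_id:
                    return  # cannot land on an occupied barrier; move aborted
                captured = True
                break

    if state.occupancy.get(site) == lef.lef_id and lef.legs.count(site) == 1:
        del state.occupancy[site]
    lef.legs[leg_idx] = target
    state.occupancy[target] = lef.lef_id
    lef.stalled[leg_idx] = False
    if captured:
        lef.captured[leg_idx] = True


def _barrier_prob(lattice: Lattice, site: int) -> float:
    for s, p in lattice.barriers:
        if s == site:
            return p
    return 0.0


def step_epoch(state: ExtrusionState) -> ExtrusionState:
    """Advance the state by one epoch in place (and return it).

    Complexes whose species is due this epoch are updated sequentially in a
    seeded random order: extruders attempt to move both legs outward by one
    site, diffusers move each leg +-1 with equal probability.  Captured legs
    do not move.  After the moves, finite-lifetime complexes unbind with
    probability (kb moved per active epoch)/lambda and, if the species
    rebinds, reload immediately at a random free site.
    """
    state.epoch += 1
    due = [l for l in state.lefs
           if l.bound and state.epoch % state.species_of(l).step_interval == 0]
    order = state.rng.permutation(len(due))
    for i in order:
        lef = due[i]
        if not lef.bound:
            continue  # unloaded by an earlier collision this epoch
        sp = state.species_of(lef)
        if sp.motion == "extruding":
            directions = (-1, +1) if lef.legs[0] <= lef.legs[1] else (+1, -1)
            for leg_idx in (0, 1):
                if not lef.captured[leg_idx]:
                    _resolve_move(state, lef, leg_idx, directions[leg_idx])
        else:
            for leg_idx in (0, 1):
                if not lef.captured[leg_idx]:
                    direction = -1 if state.rng.random() < 0.5 else +1
                    _resolve_move(state, lef, leg_idx, direction)
    # turnover
    for lef in due:
        if not lef.bound:
            continue
        sp = state.species_of(lef)
        if sp.processivity_lambda_kb is None:
            continue
        p_unbind = min(1.0, 2.0 * state.lattice.kb_per_site / sp.processivity_lambda_kb)
        if state.rng.random() < p_unbind:
            _unbind(state, lef, rebind=sp.rebind)
    return state


def run_epochs(state: ExtrusionState, n: int) -> ExtrusionState:
    for _ in range(n):
        step_epoch(state)
    return state


def loop_coverage(state: ExtrusionState, species=None) -> np.ndarray:
    """Boolean mask of sites covered by at least one loop of the class.

    Two-chain (cohesive) complexes do not form loops and are excluded.
    """
    names = _species_set(state, species)
    mask = np.zeros(state.lattice.n_sites, dtype=bool)
    for lef in state.lefs:
        if not lef.bound or lef.species not in names:
            continue
        if state.species_of(lef).two_chain:
            continue
        a, b = sorted(lef.legs)
        mask[a:b + 1] = True
    return mask


def gap_fraction(state: ExtrusionState, species=None) -> float:
    """Fraction of lattice sites not covered by any loop of the class."""
    return float(1.0 - loop_coverage(state, species).mean())


def loop_size_stats(state: ExtrusionState, species=None) -> dict:
    """Loop spans in kb for every bound complex of the class.

    Returns ``{"sizes_kb": array, "mean_kb": float | nan}``; the mean is NaN
    (flagged undefined) when no complex of the class is bound.
    """
    names = _species_set(state, species)
    sizes = [l.span_sites() * state.lattice.kb_per_site
             for l in state.lefs
             if l.bound and l.species in names and not state.species_of(l).two_chain]
    sizes = np.asarray(sizes, dtype=float)
    mean = float(sizes.mean()) if sizes.size else float("nan")
    return {"sizes_kb": sizes, "mean_kb": mean, "n": int(sizes.size)}


def count_captured(state: ExtrusionState, species: str, both_legs: bool = True) -> int:
    """Number of bound complexes captured at barrier sites.

    With ``both_legs=True`` counts fully barrier-anchored complexes
    (the proxy for CTCF-CTCF dot strength in Hi-C).
    """
    n = 0
    for lef in state.lefs:
        if lef.bound and lef.species == species:
            ok = all(lef.captured) if both_legs else any(lef.captured)
            n += bool(ok)
    return n


def lef_table(state: ExtrusionState) -> pd.DataFrame:
    """Per-complex table (one row per bound LEF) in kb coordinates."""
    rows = []
    for lef in state.lefs:
        if not lef.bound:
            continue
        a, b = sorted(lef.legs)
        rows.append({
            "epoch": state.epoch,
            "lef_id": lef.lef_id,
            "species": lef.species,
            "left_kb": a * state.lattice.kb_per_site,
            "right_kb": b * state.lattice.kb_per_site,
            "captured_left": lef.captured[0],
            "captured_right": lef.captured[1],
            "stalled_left": lef.stalled[0],
            "stalled_right": lef.stalled[1],
        })
    return pd.DataFrame(rows, columns=[
        "epoch", "lef_id", "species", "left_kb", "right_kb",
        "captured_left", "captured_right", "stalled_left", "stalled_right"])


def noncrossing_violations(state: ExtrusionState, species=None) -> int:
    """Count interleaved (crossing) loop pairs of the class.

    Two loops [a1,b1], [a2,b2] cross when a1 < a2 < b1 < b2.  Under a pure
    stall policy this must be zero; bypass permits crossings.
    """
    names = _species_set(state, species)
    loops = sorted(
        tuple(sorted(l.legs)) for l in state.lefs
        if l.bound and l.species in names and not state.species_of(l).two_chain)
    n = 0
    for i, (a1, b1) in enumerate(loops):
        for a2, b2 in loops[i + 1:]:
            if a2 >= b1:
                break
            if a1 < a2 < b1 < b2:
                n += 1
    return n
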