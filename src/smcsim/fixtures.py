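"""Synthetic test inputs: barrier lists, planted-feature matrices, toy shapes.

Everything a test or demo needs is generated here programmatically, so no
external data is required: the CTCF barrier coordinate list used by the
prophase lattice simulations (shipped verbatim as package data), dense
contact matrices with planted compartments / dots / TADs at known strength,
and toy conformations (ideal helix, random walk, two parallel sisters) with
closed-form expected observables.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .hic_features import BinnedMatrix
from .polymer3d import Conformation, init_conformation

__all__ = ["ctcf_sites", "planted_matrix", "helix_conformation_toy",
           "parallel_sisters", "generate_fixture"]


def ctcf_sites() -> np.ndarray:
    """CTCF barrier positions on the 20,000-site (1 kb/site) prophase lattice."""
    text = resources.files("smcsim").joinpath("data/ctcf_sites.txt").read_text()
    return np.asarray([int(line) for line in text.splitlines()
                       if line and not line.startswith("#")], dtype=int)


def planted_matrix(
    n_bins: int = 200,
    resolution: int = 100_000,
    compartment_block: int = 10,
    compartment_contrast: float = 1.0,
    dots: np.ndarray | None = None,
    dot_enrichment: float = 1.0,
    tad_boundaries: np.ndarray | None = None,
    tad_contrast: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
    decay_exponent: float = 1.0,
) -> tuple[BinnedMatrix, dict]:
    """Dense matrix with planted features and the ground truth that went in.

    The base signal decays as (1 + s/res)^(-decay_exponent).  Compartments
    multiply within-type pairs by ``compartment_contrast`` and between-type
    pairs by its inverse (alternating blocks of ``compartment_block`` bins);
    dots multiply single pixels; TADs multiply within-domain pixels by
    ``tad_contrast``.  Returns (matrix, truth).
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(n_bins)
    d = np.abs(np.subtract.outer(idx, idx))
    mat = (1.0 + d) ** (-decay_exponent)

    truth: dict = {}
    if compartment_contrast != 1.0:
        types = (idx // compartment_block) % 2  # 0 = B, 1 = A
        same = np.equal.outer(types, types)
        mat = mat * np.where(same, compartment_contrast, 1.0 / compartment_contrast)
        truth["compartment_types"] = types
        truth["expected_saddle"] = compartment_contrast ** 2

    if tad_boundaries is not None:
        tb = np.sort(np.asarray(tad_boundaries, int))
        domain = np.searchsorted(tb, idx, side="right")
        within = np.equal.outer(domain, domain)
        mat = mat * np.where(within, tad_contrast, 1.0)
        truth["tad_boundaries"] = tb

    if dots is not None:
        dots = np.asarray(dots, int).reshape(-1, 2)
        for b1, b2 in dots:
            mat[b1, b2] *= dot_enrichment
            mat[b2, b1] = mat[b1, b2]
        truth["dots_bp"] = dots * resolution
        truth["dot_enrichment"] = dot_enrichment

    if noise > 0:
        jitter = rng.lognormal(sigma=noise, size=mat.shape)
        mat = mat * np.triu(jitter) + mat * np.triu(jitter, 1).T
        mat = 0.5 * (mat + mat.T)

    return BinnedMatrix(matrix=mat, resolution=resolution), truth


def helix_conformation_toy(n_beads: int = 4000, beads_per_turn: int = 100,
                           rise_per_bead: float = 0.02, radius: float | None = None,
                           bp_per_bead: float = 1000.0) -> Conformation:
    """Ideal helix with unit bead spacing along the wire.

    Adjacent gyres sit ``beads_per_turn * rise_per_bead`` apart in z, so
    P(s) of this toy shows a contact peak at s = beads_per_turn *
    bp_per_bead (loci one full turn apart are spatial neighbors).
    """
    if radius is None:
        # choose radius so the in-plane step of one bead is ~1 length unit
        radius = 1.0 / (2.0 * np.sin(np.pi / beads_per_turn))
    t = np.arange(n_beads)
    phi = 2.0 * np.pi * t / beads_per_turn
    pos = np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                           rise_per_bead * t])
    return Conformation(pos, bp_per_bead=bp_per_bead)


def parallel_sisters(n_beads: int = 100, spacing: float = 5.0,
                     bp_per_bead: float = 1000.0) -> Conformation:
    """Two straight parallel chains ``spacing`` apart (sister-pair toy)."""
    z = np.arange(n_beads, dtype=float)
    a = np.column_stack([np.zeros(n_beads), np.zeros(n_beads), z])
    b = np.column_stack([np.full(n_beads, spacing), np.zeros(n_beads), z])
    pos = np.vstack([a, b])
    return Conformation(pos, bp_per_bead=bp_per_bead,
                        chains=[(0, n_beads), (n_beads, 2 * n_beads)])


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Dispatch fixture generation by kind.

    Kinds: ``ctcf_sites``, ``planted_matrix``, ``helix``, ``random_walk``,
    ``parallel_sisters``.
    """
    params = dict(params or {})
    if kind == "ctcf_sites":
        return ctcf_sites()
    if kind == "planted_matrix":
        return planted_matrix(seed=seed, **params)
    if kind == "helix":
        return helix_conformation_toy(**params)
    if kind == "random_walk":
        n = params.pop("n_beads", 1000)
        return init_conformation(n, "random_walk", seed=seed, **params)
    if kind == "parallel_sisters":
        return parallel_sisters(**params)
    raise ValueError(f"unknown fixture kind {kind!r}")
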