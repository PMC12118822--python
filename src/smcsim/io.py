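"""Readers and writers for the package's text and HDF5 formats.

All genomic coordinates are 0-based, half-open; the synthetic chromosome is
named "chrS".  Text formats round-trip byte-identically.
"""

from __future__ import annotations

import configparser
import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .extrusion1d import CollisionPolicy, LEFSpecies
from .insilico_hic import ContactList, PsCurve
from .polymer3d import Conformation

CHROM = "chrS"


# -- conformations -----------------------------------------------------------

def write_xyz(conformation: Conformation, path) -> None:
    """Plain XYZ-style text: header line, then one bead per line."""
    with open(path, "w") as f:
        f.write(f"{conformation.n_beads}\n")
        chains = json.dumps([list(c) for c in conformation.chains],
                            separators=(",", ":"))
        f.write(f"bp_per_bead={conformation.bp_per_bead:g} chains={chains}\n")
        for p, c in zip(conformation.positions, conformation.category):
            f.write(f"{int(c)}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")


def read_xyz(path) -> Conformation:
    with open(path) as f:
        n = int(f.readline())
        header = f.readline().split()
        bpb = float(header[0].split("=")[1])
        chains = [tuple(c) for c in json.loads(header[1].split("=", 1)[1])]
        cat = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        for k in range(n):
            parts = f.readline().split()
            cat[k] = int(parts[0])
            pos[k] = [float(x) for x in parts[1:4]]
    return Conformation(pos, bp_per_bead=bpb, chains=chains, category=cat)


def write_conformation_h5(conformation: Conformation, path, seed: int | None = None,
                          step: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=conformation.positions)
        f.create_dataset("category", data=conformation.category)
        f.attrs["bp_per_bead"] = conformation.bp_per_bead
        f.attrs["chains"] = json.dumps(conformation.chains)
        if seed is not None:
            f.attrs["seed"] = seed
        if step is not None:
            f.attrs["step"] = step


def read_conformation_h5(path) -> Conformation:
    with h5py.File(path, "r") as f:
        return Conformation(
            f["positions"][:],
            bp_per_bead=float(f.attrs["bp_per_bead"]),
            chains=[tuple(c) for c in json.loads(f.attrs["chains"])],
            category=f["category"][:],
        )


# -- contacts and P(s) -------------------------------------------------------

def write_pairs(contacts: ContactList, path) -> None:
    """4DN-pairs-like text: chr pos1 chr pos2 frequency."""
    with open(path, "w") as f:
        f.write(f"#bp_per_bead={contacts.bp_per_bead:g}\t"
                f"n_beads={contacts.n_beads}\tn_replicates={contacts.n_replicates}\n")
        f.write("#chrom1\tpos1\tchrom2\tpos2\tfrequency\n")
        bpb = contacts.bp_per_bead
        for i, j, q in zip(contacts.i, contacts.j, contacts.freq):
            f.write(f"{CHROM}\t{int(i * bpb)}\t{CHROM}\t{int(j * bpb)}\t{q:.6g}\n")


def read_pairs(path) -> ContactList:
    with open(path) as f:
        meta = dict(kv.split("=") for kv in f.readline().lstrip("#").split("\t"))
        f.readline()
        df = pd.read_csv(f, sep="\t", header=None,
                         names=["c1", "p1", "c2", "p2", "freq"])
    bpb = float(meta["bp_per_bead"])
    return ContactList(
        i=(df.p1.to_numpy() / bpb).astype(int),
        j=(df.p2.to_numpy() / bpb).astype(int),
        freq=df.freq.to_numpy(),
        n_beads=int(meta["n_beads"]),
        bp_per_bead=bpb,
        n_replicates=int(meta["n_replicates"]),
    )


def write_ps(ps: PsCurve, path) -> None:
    Path(path).write_text(ps.to_tsv())


def read_ps(path) -> PsCurve:
    df = pd.read_csv(path, sep="\t")
    slope = df["slope"].to_numpy() if "slope" in df else None
    return PsCurve(s_bp=df["s_bp"].to_numpy(), values=df["P"].to_numpy(), slope=slope)


# -- matrices, dots, boundaries ---------------------------------------------

def write_matrix_tsv(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.8g")


def read_matrix_tsv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_bed(intervals, path, chrom: str = CHROM) -> None:
    """BED-like 3+ column text from (start, end[, name]) rows."""
    with open(path, "w") as f:
        for row in intervals:
            f.write(chrom + "\t" + "\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list:
    rows = []
    with open(path) as f:
        for line in f:
            parts = line.rstrip("\n").split("\t")
            rows.append(tuple(int(x) if x.lstrip("-").isdigit() else x
                              for x in parts[1:]))
    return rows


# -- species / policy config -------------------------------------------------

def parse_species_config(text: str) -> tuple[list, CollisionPolicy]:
    """Parse the INI-style species + policy configuration.

    One section per species with keys d_kb, lambda_kb (or "inf"),
    step_interval, loading, barrier_mode, motion, two_chain, rebind; an
    optional [policy] section maps "moving->blocking" to an outcome.
    """
    cp = configparser.ConfigParser()
    cp.read_string(text)
    species = []
    rules = {}
    for name in cp.sections():
        sec = cp[name]
        if name == "policy":
            for key, outcome in sec.items():
                a, b = key.split("->")
                rules[(a.strip(), b.strip())] = outcome.strip()
            continue
        lam = sec.get("lambda_kb", "inf")
        species.append(LEFSpecies(
            name=name,
            separation_d_kb=sec.getfloat("d_kb"),
            processivity_lambda_kb=None if lam in ("inf", "infinite") else float(lam),
            step_interval=sec.getint("step_interval", 1),
            loading=sec.get("loading", "stochastic"),
            barrier_mode=sec.get("barrier_mode", "transparent"),
            motion=sec.get("motion", "extruding"),
            two_chain=sec.getboolean("two_chain", False),
            rebind=sec.getboolean("rebind", True),
        ))
    return species, CollisionPolicy(rules)
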