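"""Feature scores on binned contact matrices.

Implements the standard interphase Hi-C feature quantifications on dense
symmetric matrices: observed/expected normalization by diagonal,
compartment eigenvector and saddle compartmentalization strength, focal dot
(loop) deduplication and pileup enrichment, insulation score with boundary
calling and rescaled TAD pileups, and time-course normalization to a G2
reference.  Matrices are plain numpy arrays with a genomic resolution in
bp; masked bins (e.g. unmappable) are carried as a boolean mask.

All scores are invariant to global rescaling of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

__all__ = [
    "BinnedMatrix",
    "oe_matrix",
    "compartment_ev",
    "saddle_strength",
    "dedup_dots",
    "dot_strength",
    "insulation_track",
    "call_boundaries",
    "tad_pileup",
    "timecourse_norm",
]


@dataclass
class BinnedMatrix:
    """Dense symmetric cis contact matrix at fixed resolution (bp)."""

    matrix: np.ndarray
    resolution: int
    mask: np.ndarray | None = None  # True = bin is filtered out

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, rtol=1e-6, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if np.any(self.matrix < -1e-12):
            raise ValueError("matrix must be nonnegative")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def expected_by_diagonal(bm: BinnedMatrix) -> np.ndarray:
    """Mean contact frequency per diagonal (over unmasked bin pairs)."""
    n = bm.n_bins
    good = ~bm.mask
    exp = np.zeros(n)
    for d in range(n):
        vals = np.diagonal(bm.matrix, offset=d)
        ok = good[:n - d] & good[d:]
        exp[d] = vals[ok].mean() if np.any(ok) else np.nan
    return exp


def oe_matrix(bm: BinnedMatrix, expected: np.ndarray | None = None) -> BinnedMatrix:
    """Observed/expected matrix, normalizing each diagonal by its mean."""
    if expected is None:
        expected = expected_by_diagonal(bm)
    n = bm.n_bins
    if not np.any(np.nan_to_num(expected) > 0):
        raise ValueError("degenerate matrix: no positive expected values")
    oe = np.ones_like(bm.matrix)
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = expected[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(e > 0, bm.matrix / np.where(e > 0, e, 1.0), 1.0)
    return BinnedMatrix(matrix=oe, resolution=bm.resolution, mask=bm.mask.copy())


def compartment_ev(oe: BinnedMatrix, reference_track: np.ndarray | None = None
                   ) -> np.ndarray:
    """First eigenvector of (OE - 1), oriented to the reference track.

    The leading eigenvector (by absolute eigenvalue) of the mean-centered
    observed/expected matrix restricted to unmasked bins; its sign is
    flipped to correlate positively with ``reference_track`` (GC content in
    experimental practice).  Masked bins get NaN.  A zero-variance result
    (uniform matrix) is returned as all-zeros with a warning.
    """
    good = ~oe.mask
    sub = oe.matrix[np.ix_(good, good)] - 1.0
    if sub.shape[0] < 2:
        raise ValueError("not enough unmasked bins")
    w, v = np.linalg.eigh(sub)
    lead = int(np.argmax(np.abs(w)))
    ev = v[:, lead] * np.sqrt(np.abs(w[lead]))
    if np.allclose(ev, 0) or np.std(ev) < 1e-12:
        warnings.warn("degenerate eigenvector (zero variance)", stacklevel=2)
        ev = np.zeros_like(ev)
    if reference_track is not None and np.std(ev) > 0:
        ref = np.asarray(reference_track, float)[good]
        if np.corrcoef(ev, ref)[0, 1] < 0:
            ev = -ev
    out = np.full(oe.n_bins, np.nan)
    out[good] = ev
    return out


def saddle_strength(oe: BinnedMatrix, ev: np.ndarray, n_groups: int = 10,
                    trim: tuple = (2.5, 97.5)) -> float:
    """Compartmentalization score (AA + BB) / (AB + BA) from a saddle plot.

    Unmasked bins with finite eigenvector values inside the trim percentile
    range are sorted into ``n_groups`` equal-occupancy groups by eigenvector
    value; the saddle is the group-averaged OE matrix and the score uses the
    single extreme group on each side (corner pixels).
    """
    ev = np.asarray(ev, float)
    good = ~oe.mask & np.isfinite(ev)
    lo, hi = np.percentile(ev[good], trim)
    good &= (ev >= lo) & (ev <= hi)
    idx = np.nonzero(good)[0]
    if idx.size < n_groups:
        raise ValueError("fewer unmasked bins than groups")
    order = idx[np.argsort(ev[idx])]
    groups = np.array_split(order, n_groups)
    saddle = np.zeros((n_groups, n_groups))
    for a in range(n_groups):
        for b in range(n_groups):
            block = oe.matrix[np.ix_(groups[a], groups[b])]
            if a == b:
                off = ~np.eye(len(groups[a]), dtype=bool)
                saddle[a, b] = block[off].mean() if off.any() else block.mean()
            else:
                saddle[a, b] = block.mean()
    bb, aa = saddle[0, 0], saddle[-1, -1]
    ab, ba = saddle[0, -1], saddle[-1, 0]
    return float((aa + bb) / (ab + ba))


def dedup_dots(dots: np.ndarray, radius: float = 30_000.0) -> np.ndarray:
    """Collapse dots closer than ``radius`` (bp) into one representative.

    Dots are (pos1_bp, pos2_bp) rows; mutual-neighbor clusters (connected
    components of the within-radius graph) each keep their first member.
    """
    dots = np.asarray(dots, float).reshape(-1, 2)
    if len(dots) == 0:
        return dots
    tree = cKDTree(dots)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    parent = np.arange(len(dots))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.asarray([find(i) for i in range(len(dots))])
    keep = np.unique(roots)
    return dots[keep]


def dot_strength(bm: BinnedMatrix, dots: np.ndarray, flank_bp: float = 50_000.0,
                 expected: np.ndarray | None = None) -> float:
    """Mean O/E enrichment in the central 3x3 window of the dot pileup.

    Snippets of +-flank around each dot are cut from the observed/expected
    matrix and averaged; the strength is the mean of the 3x3 pixels around
    the pileup center.  Dots whose snippet would cross the matrix edge are
    excluded with a warning; returns NaN when no dot remains.
    """
    oe = oe_matrix(bm, expected)
    f = int(round(flank_bp / bm.resolution))
    dots = np.asarray(dots, float).reshape(-1, 2)
    snippets = []
    skipped = 0
    for p1, p2 in dots:
        b1 = int(p1 // bm.resolution)
        b2 = int(p2 // bm.resolution)
        if b1 - f < 0 or b2 - f < 0 or b1 + f >= bm.n_bins or b2 + f >= bm.n_bins:
            skipped += 1
            continue
        snippets.append(oe.matrix[b1 - f:b1 + f + 1, b2 - f:b2 + f + 1])
    if skipped:
        warnings.warn(f"{skipped} dot(s) too close to the matrix edge", stacklevel=2)
    if not snippets:
        return float("nan")
    pileup = np.mean(snippets, axis=0)
    c = f
    return float(pileup[c - 1:c + 2, c - 1:c + 2].mean())


def insulation_track(bm: BinnedMatrix, window_bp: float = 200_000.0) -> np.ndarray:
    """Diamond insulation score, log2 relative to its chromosome mean.

    For each bin, the mean contact frequency in the w x w diamond bridging
    the bin (rows i-w..i-1, columns i+1..i+w); NaN near the edges.
    """
    w = int(round(window_bp / bm.resolution))
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    n = bm.n_bins
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        raw[i] = bm.matrix[i - w:i, i + 1:i + w + 1].mean()
    mean = np.nanmean(raw[raw > 0]) if np.any(raw > 0) else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(raw / mean)


def call_boundaries(track: np.ndarray, min_strength: float = 0.1) -> np.ndarray:
    """Insulating boundaries: local minima with prominence >= min_strength.

    Boundary strength is the prominence of the insulation minimum (depth
    relative to the lower of the flanking maxima).  Returns bin indices.
    """
    t = np.asarray(track, float)
    filled = np.where(np.isfinite(t), t, np.nanmax(t) if np.any(np.isfinite(t)) else 0.0)
    peaks, props = find_peaks(-filled, prominence=min_strength)
    return peaks[np.isfinite(t[peaks])]


def tad_pileup(bm: BinnedMatrix, boundaries: np.ndarray,
               size_range_bp: tuple = (100_000.0, 700_000.0),
               out_size: int = 100, expected: np.ndarray | None = None
               ) -> np.ndarray:
    """Average rescaled O/E pileup over TADs between adjacent boundaries.

    TADs are the intervals between consecutive boundaries whose size falls
    in ``size_range_bp``.  For each TAD of size L (bins), the snippet of
    +-L around the TAD (3L x 3L) is rescaled to ``out_size`` squared and
    the snippets averaged; the TAD body occupies the central third.
    """
    oe = oe_matrix(bm, expected)
    bnd = np.sort(np.asarray(boundaries, int))
    lo = size_range_bp[0] / bm.resolution
    hi = size_range_bp[1] / bm.resolution
    snippets = []
    for a, b in zip(bnd, bnd[1:]):
        size = b - a
        if not lo <= size <= hi:
            continue
        s0, s1 = a - size, b + size
        if s0 < 0 or s1 > bm.n_bins:
            continue
        snip = oe.matrix[s0:s1, s0:s1]
        snippets.append(zoom(snip, out_size / snip.shape[0], order=1,
                             grid_mode=True, mode="nearest"))
    if not snippets:
        return np.full((out_size, out_size), np.nan)
    return np.mean(snippets, axis=0)


def timecourse_norm(values: np.ndarray, g2_value: float) -> np.ndarray:
    """Normalize a score time series to its G2 value (set to 1)."""
    if g2_value <= 0:
        raise ValueError("G2 reference value must be positive")
    return np.asarray(values, float) / g2_value
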