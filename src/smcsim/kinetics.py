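"""Closed-form estimators for loop-extrusion speed, geometry and stoichiometry.

These are the back-of-the-envelope calculations that connect observable
quantities -- loop sizes read off P(s) derivatives, helical periods read off
second-diagonal positions, gap fractions inferred from chromosome morphology,
and chromatin-bound protein abundances -- to extrusion kinetics of SMC
complexes (condensin I/II, cohesin) in vivo.

All estimators return full-precision floats; use :func:`display_round` to
reproduce the one-decimal kb/s convention used when quoting speeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


_SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class SpeedEstimate:
    """An extrusion-speed estimate with provenance.

    Attributes
    ----------
    value_kb_per_s
        Speed in kb/s (full precision).
    method
        Tag for the estimator that produced it.
    inputs
        Echo of the inputs for the run log.
    """

    value_kb_per_s: float
    method: str
    inputs: dict = field(default_factory=dict)

    @property
    def value_kb_per_min(self) -> float:
        return self.value_kb_per_s * _SECONDS_PER_MINUTE


def display_round(value: float, ndigits: int = 1) -> float:
    """Round for display (1 decimal by convention for kb/s speeds)."""
    return round(value, ndigits)


def speed_from_first_loops(loop_kb: float, minutes: float) -> SpeedEstimate:
    """Extrusion speed assuming loops of ``loop_kb`` grew from zero in ``minutes``.

    E.g. 400 kb condensin II loops appearing within 5 min of activation
    imply ~1.3 kb/s.
    """
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    v = loop_kb / (_SECONDS_PER_MINUTE * minutes)
    return SpeedEstimate(v, "first_loops", {"loop_kb": loop_kb, "minutes": minutes})


def speed_from_loop_growth(l0_kb: float, l1_kb: float, minutes: float) -> SpeedEstimate:
    """Speed from the growth of the mean loop size between two time points."""
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    growth = l1_kb - l0_kb
    if growth < 0:
        import warnings

        warnings.warn("negative loop growth; returning speed 0", stacklevel=2)
        growth = 0.0
    v = growth / (_SECONDS_PER_MINUTE * minutes)
    return SpeedEstimate(v, "loop_growth", {"l0_kb": l0_kb, "l1_kb": l1_kb, "minutes": minutes})


def theoretical_gap_fraction(lambda_kb: float, d_kb: float) -> float:
    """Steady-state gap fraction g = exp(-lambda/d) of an extruded loop array.

    lambda is the processivity (mean chromatin extruded per binding event)
    and d the mean genomic spacing between bound extruders.
    """
    if d_kb <= 0:
        raise ValueError("separation d must be positive")
    if lambda_kb < 0:
        raise ValueError("processivity must be nonnegative")
    return math.exp(-lambda_kb / d_kb)


def speed_from_gap_fraction(d_kb: float, g: float, seconds: float) -> SpeedEstimate:
    """Invert g = exp(-v*t/d) for the extrusion speed: v = -d ln(g) / t."""
    if not 0.0 < g < 1.0:
        raise ValueError("gap fraction must lie strictly between 0 and 1")
    if seconds <= 0:
        raise ValueError("seconds must be positive")
    v = -d_kb * math.log(g) / seconds
    return SpeedEstimate(v, "gap_fraction", {"d_kb": d_kb, "g": g, "seconds": seconds})


def speed_from_gap_multiplier(l_loop_kb: float, k: float, seconds: float) -> SpeedEstimate:
    """Speed when extruders must extrude k times the mean loop size to close gaps.

    Closing most gaps in a collision-limited array (d ~ l_loop) requires each
    extruder to process ~4-5x the mean loop size; with 400 kb loops closed in
    10 min that gives 2.5-3 kb/s.
    """
    if k <= 0:
        raise ValueError("multiplier must be positive")
    if seconds <= 0:
        raise ValueError("seconds must be positive")
    v = k * l_loop_kb / seconds
    return SpeedEstimate(v, "gap_multiplier", {"l_loop_kb": l_loop_kb, "k": k, "seconds": seconds})


def period_growth_rate(p0_mb: float, p1_mb: float, minutes: float) -> SpeedEstimate:
    """Growth rate of the helical period (second-diagonal position) in kb/s.

    The helical turn of a mitotic chromatid gains genomic content over time;
    e.g. 4.0 -> 6.1 Mb over 15 min is ~2.3 kb/s.
    """
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    v = (p1_mb - p0_mb) * 1000.0 / (_SECONDS_PER_MINUTE * minutes)
    return SpeedEstimate(v, "period_growth", {"p0_mb": p0_mb, "p1_mb": p1_mb, "minutes": minutes})


def effective_velocity(loop_kb: float, residence_min: float) -> float:
    """Effective extrusion velocity in kb/min from loop size and residence time.

    Cohesin with ~100 kb loops and ~10 min residence extrudes at ~10 kb/min.
    """
    if residence_min <= 0:
        raise ValueError("residence time must be positive")
    return loop_kb / residence_min


def md_step_interval(
    rouse_minutes: float,
    rouse_md_steps: float,
    v_kb_per_min: float,
    kb_per_bead: float,
    legs_per_step: int = 2,
) -> float:
    """MD steps between extrusion steps, from a Rouse-time calibration.

    A measured Rouse time in minutes and the matching Rouse time in MD steps
    fix the steps-per-minute conversion; dividing by the extrusion-event rate
    (each event advances ``legs_per_step`` legs by one bead) yields the LEF
    update interval in MD steps.  Returns ``math.inf`` when v is zero.
    """
    if min(rouse_minutes, rouse_md_steps, kb_per_bead) <= 0 or legs_per_step <= 0:
        raise ValueError("calibration inputs must be positive")
    if v_kb_per_min < 0:
        raise ValueError("velocity must be nonnegative")
    if v_kb_per_min == 0:
        return math.inf
    steps_per_minute = rouse_md_steps / rouse_minutes
    events_per_minute = v_kb_per_min / (kb_per_bead * legs_per_step)
    return steps_per_minute / events_per_minute


def nucleosome_cube_side(rho_v_mb_per_um3: float, bp_per_nucleosome: float = 200.0) -> float:
    """Side (nm) of the cube occupied per nucleosome at a given volume density.

    rho_V in Mb/um^3 converts to bp/nm^3 as rho_V * 1e-3; the specific volume
    per nucleosome is bp_per_nucleosome over that, and the cube side its cube
    root.  44 Mb/um^3 with 200 bp nucleosomes gives 16.5 nm.
    """
    if rho_v_mb_per_um3 <= 0:
        raise ValueError("density must be positive")
    bp_per_nm3 = rho_v_mb_per_um3 * 1e6 / 1e9
    volume_nm3 = bp_per_nucleosome / bp_per_nm3
    return volume_nm3 ** (1.0 / 3.0)


#: H4 copies per Mb of DNA at 2 H4 per 180 bp.
H4_PER_MB = 2e6 / 180.0


def complexes_per_mb(abundance_ratio_to_h4: float) -> float:
    """Chromatin-bound complexes per Mb from a molar ratio to histone H4.

    Uses the stoichiometric conversion that 2 histone H4 proteins correspond
    to 180 bp of DNA, i.e. ~11,111 H4 per Mb.
    """
    if abundance_ratio_to_h4 < 0:
        raise ValueError("abundance ratio must be nonnegative")
    return abundance_ratio_to_h4 * H4_PER_MB
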