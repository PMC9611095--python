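"""Monolayer thermodynamics: area readout, excess quantities, rigidity.

All operations act on clean compression branches (strictly decreasing
area; see :func:`monofilm.isotherm_io.extract_compression_branch`).

Sign convention: the compressibility modulus is computed as
``Cs^-1 = -A * (dpi/dA)`` so that values are positive on compression;
the bare derivative form without the minus sign would be negative.

Unit conversion: 1 mN/m * Å²/molecule corresponds to
N_A * 1e-23 J = 6.02214 J/mol; this constant converts the pressure-area
integral of the excess area into a molar excess Gibbs energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks, savgol_filter

from monofilm.errors import DomainError, InsufficientDataError, ValidationError
from monofilm.isotherm_io import Isotherm
from monofilm.synthetic_data import J_PER_MOL_PER_MNM_A2

DEFAULT_LIFTOFF_THRESHOLD = 0.3  # mN/m; 3x the 0.1 mN/m instrument noise floor
DEFAULT_GRID_STEP = 0.1  # mN/m integration step
DEFAULT_SG_WINDOW = 11
DEFAULT_SG_ORDER = 3

#: Phase bands for the compressibility modulus, mN/m (upper edges).
PHASE_BANDS = (
    (12.5, "gaseous"),
    (50.0, "LE"),
    (100.0, "LE-LC"),
    (250.0, "LC"),
)
PHASE_TOP = "solid"


@dataclass(frozen=True)
class AreaAtPressure:
    """Area readout at one target pressure; area is 0 when never attained."""

    pressure: float
    area: float
    attained: bool
    source_x2: float | None = None


@dataclass(frozen=True)
class ExcessRecord:
    """Excess quantities for one (fraction, pressure) pair."""

    x2: float
    pressure: float
    a12: float
    a_ideal: float
    a_excess: float
    dg_excess: float
    flags: frozenset = frozenset()


@dataclass
class CompressibilityCurve:
    """Cs^-1 sampled along a compression branch, ordered by pressure."""

    pressures: np.ndarray
    cs_inv: np.ndarray
    phases: list
    smoothing_window: int
    smoothing_order: int

    def __len__(self) -> int:
        return len(self.pressures)


def _require_branch(iso: Isotherm) -> None:
    if not iso.is_strictly_decreasing():
        raise ValidationError(
            "isotherm is not a clean compression branch "
            "(run extract_compression_branch first)"
        )


def areas_at_pressures(iso: Isotherm, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised first-upward-crossing area lookup.

    For each target the branch is scanned in compression order (areas
    decreasing) and the area at the first crossing of the target pressure
    is linearly interpolated; an exact grid hit returns the tabulated
    area.  Targets above the branch maximum come back unattained with
    area 0.  Negative pressure readings are clamped to 0 first.
    """
    _require_branch(iso)
    p = np.clip(iso.pressures, 0.0, None)
    a = iso.areas
    cm = np.maximum.accumulate(p)
    t = np.atleast_1d(np.asarray(targets, dtype=float))
    idx = np.searchsorted(cm, t, side="left")  # first i with running max >= t
    attained = idx < len(p)
    idx_safe = np.minimum(idx, len(p) - 1)

    areas = np.zeros_like(t)
    # crossing at the very first point (already above target)
    first = attained & (idx_safe == 0)
    areas[first] = a[0]
    inner = attained & (idx_safe > 0)
    i = idx_safe[inner]
    p_lo, p_hi = p[i - 1], p[i]
    # by construction p_lo < t <= p_hi, so the denominator is positive
    frac = (t[inner] - p_lo) / (p_hi - p_lo)
    areas[inner] = a[i - 1] + frac * (a[i] - a[i - 1])
    return areas, attained


def area_at_pressure(
    iso: Isotherm,
    pi_target: float,
    liftoff_threshold: float = DEFAULT_LIFTOFF_THRESHOLD,
) -> AreaAtPressure:
    """Area at ``pi_target`` on the compression branch.

    A film that never rises above ``liftoff_threshold`` (a non-spreading
    film) is reported unattained with area 0 regardless of noise wiggles.
    """
    if pi_target <= 0:
        raise ValidationError("pi_target must be > 0")
    if float(np.max(iso.pressures)) <= liftoff_threshold:
        return AreaAtPressure(pi_target, 0.0, False, iso.x2)
    areas, attained = areas_at_pressures(iso, np.array([pi_target]))
    if not attained[0]:
        return AreaAtPressure(pi_target, 0.0, False, iso.x2)
    return AreaAtPressure(pi_target, float(areas[0]), True, iso.x2)


def ideal_mixing_area(a1: float, a2: float, x2: float) -> float:
    """Mole-fraction additivity line: ``(1 - x2) a1 + x2 a2``."""
    if a1 < 0 or a2 < 0 or not (0.0 <= x2 <= 1.0):
        raise ValidationError("areas must be >= 0 and x2 in [0, 1]")
    return (1.0 - x2) * a1 + x2 * a2


def excess_area(a12: float, a1: float, a2: float, x2: float) -> float:
    """Deviation of the mixed-film area from the additivity line.

    Positive values indicate repulsive interactions between the film
    components, negative values attractive ones.
    """
    if a12 < 0:
        raise ValidationError("a12 must be >= 0")
    return a12 - ideal_mixing_area(a1, a2, x2)


def _liftoff_pressure(iso: Isotherm, threshold: float) -> float | None:
    """Pressure of the first point above the noise threshold, or None."""
    p = iso.pressures
    above = np.nonzero(p > threshold)[0]
    if len(above) == 0:
        return None
    return float(p[above[0]])


def excess_gibbs_energy(
    iso12: Isotherm,
    iso1: Isotherm,
    iso2: Isotherm,
    x2: float,
    pi_star: float,
    grid_step: float = DEFAULT_GRID_STEP,
    liftoff_threshold: float = DEFAULT_LIFTOFF_THRESHOLD,
) -> float:
    """Excess Gibbs free energy of mixing at ``pi_star``, in J/mol.

    Trapezoidal integration of ``A12 - ((1-x2) A1 + x2 A2)`` on a uniform
    pressure grid from 0 to ``pi_star``.  Below the common lift-off of the
    participating films the integrand is held constant at its lift-off
    value (the gaseous region carries an essentially constant deviation).
    A pure component that never attains a grid pressure contributes zero
    area there.
    """
    for iso in (iso12, iso1, iso2):
        _require_branch(iso)
    if not (0.0 <= x2 <= 1.0):
        raise ValidationError(f"x2={x2} outside [0, 1]")
    if pi_star <= 0 or grid_step <= 0:
        raise ValidationError("pi_star and grid_step must be > 0")
    if float(np.max(iso12.pressures)) < pi_star:
        raise DomainError(
            f"mixture reaches only {float(np.max(iso12.pressures)):.3f} mN/m, "
            f"below pi_star={pi_star}"
        )
    n = max(1, int(round(pi_star / grid_step)))
    grid = np.linspace(0.0, pi_star, n + 1)

    a12, _ = areas_at_pressures(iso12, grid)
    a1, att1 = areas_at_pressures(iso1, grid)
    a2, att2 = areas_at_pressures(iso2, grid)
    a1[~att1] = 0.0
    a2[~att2] = 0.0
    # a film that never leaves the noise floor contributes zero area
    if float(np.max(iso1.pressures)) <= liftoff_threshold:
        a1[:] = 0.0
    if float(np.max(iso2.pressures)) <= liftoff_threshold:
        a2[:] = 0.0

    f = a12 - ((1.0 - x2) * a1 + x2 * a2)

    liftoffs = [
        lo
        for iso in (iso12, iso1, iso2)
        if (lo := _liftoff_pressure(iso, liftoff_threshold)) is not None
    ]
    if liftoffs:
        pi_common = max(liftoffs)
        j = int(np.searchsorted(grid, min(pi_common, pi_star)))
        j = min(j, len(grid) - 1)
        f[:j] = f[j]

    return float(J_PER_MOL_PER_MNM_A2 * np.trapezoid(f, grid))


def classify_phase_state(cs_inv: float) -> str:
    """Map a compressibility-modulus value (mN/m) onto a 2D phase label."""
    if cs_inv < 0:
        raise DomainError(f"cs_inv must be >= 0, got {cs_inv}")
    for upper, label in PHASE_BANDS:
        if cs_inv < upper:
            return label
    return PHASE_TOP


def compressibility_curve(
    iso: Isotherm,
    window: int = DEFAULT_SG_WINDOW,
    order: int = DEFAULT_SG_ORDER,
) -> CompressibilityCurve:
    """Compressibility modulus ``Cs^-1 = -A * dpi/dA`` along the branch.

    The pressure record is resampled onto a uniform area grid and the
    derivative is taken by Savitzky-Golay local-polynomial filtering,
    which tolerates the +-0.1 mN/m sensor noise that makes raw finite
    differences useless.  Samples come back ordered by increasing
    pressure; negative noise excursions of Cs^-1 are clamped to 0.
    """
    _require_branch(iso)
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be odd and >= 3")
    if order >= window:
        raise ValidationError("order must be smaller than window")
    if iso.n_points < window:
        raise InsufficientDataError(
            f"branch has {iso.n_points} points, need at least window={window}"
        )
    # ascending-area view; shape-preserving resample onto a uniform area grid
    a_asc = iso.areas[::-1]
    p_asc = iso.pressures[::-1]
    n = iso.n_points
    a_grid = np.linspace(a_asc[0], a_asc[-1], n)
    da = a_grid[1] - a_grid[0]
    p_grid = PchipInterpolator(a_asc, p_asc)(a_grid)

    dpda = savgol_filter(p_grid, window, order, deriv=1, delta=da)
    p_smooth = savgol_filter(p_grid, window, order)
    cs = np.clip(-a_grid * dpda, 0.0, None)

    # report in compression order = increasing pressure (descending area)
    pressures = p_smooth[::-1]
    cs = cs[::-1]
    phases = [classify_phase_state(float(c)) for c in cs]
    return CompressibilityCurve(pressures, cs, phases, window, order)


DETECT_SMOOTH_WINDOW = 41  # samples; candidate-location smoothing
DETECT_REFINE_HALF = 2.5  # mN/m; half-width of the parabolic refinement


def detect_transition_pressure(
    curve: CompressibilityCurve, min_prominence: float = 5.0
) -> float | None:
    """Pressure of a phase transition read from the Cs^-1 curve.

    A transition shows as a dip of Cs^-1 between two stiffer branches
    (the flanking maxima may sit at the branch ends, e.g. the rigid
    branch climbing toward collapse).  Detection is two-stage to survive
    the sensor noise that Cs^-1 amplifies in the near-gaseous region:

    1. locate candidate dips on a heavily smoothed copy of the curve and
       keep the one with the largest prominence, gated at
       ``min_prominence``;
    2. refine the dip position by fitting a parabola to the original
       samples within ±2.5 mN/m of the candidate and taking its vertex.

    Returns None when no sufficiently prominent dip exists.
    """
    if len(curve) < 5:
        raise InsufficientDataError("need at least 5 samples to detect a transition")
    cs = np.asarray(curve.cs_inv, dtype=float)
    pr = np.asarray(curve.pressures, dtype=float)
    n = len(cs)
    w = min(DETECT_SMOOTH_WINDOW, n if n % 2 else n - 1)
    smooth = np.clip(savgol_filter(cs, w, 2), 0.0, None) if n >= 7 else cs
    dips, props = find_peaks(-smooth, prominence=min_prominence)
    if len(dips) == 0:
        return None
    cand = int(dips[np.argmax(props["prominences"])])
    sel = np.abs(pr - pr[cand]) <= DETECT_REFINE_HALF
    if np.count_nonzero(sel) >= 5:
        x = pr[sel] - pr[cand]
        coeff = np.polyfit(x, cs[sel], 2)
        if coeff[0] > 0:
            vertex = pr[cand] - coeff[1] / (2.0 * coeff[0])
            return float(np.clip(vertex, pr[sel].min(), pr[sel].max()))
    return float(pr[cand])
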