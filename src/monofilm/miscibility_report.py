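"""Study-level products: composition profiles, excess tables, verdicts.

A *study set* is a list of compression-branch isotherms whose metadata
``molar_fraction_x2`` spans both pure endpoints (0 and 1) plus at least
one mixture.  All outputs are sorted by fraction internally, so file
order never matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from monofilm.errors import ValidationError
from monofilm.isotherm_io import Isotherm
from monofilm.monolayer_thermo import (
    ExcessRecord,
    area_at_pressure,
    excess_gibbs_energy,
    ideal_mixing_area,
)

DEFAULT_EXCESS_TOL = 0.5  # Å²; below this a deviation is treated as zero

VERDICT_IDEAL = "ideal-or-immiscible"
VERDICT_REPULSIVE = "miscible-repulsive"
VERDICT_ATTRACTIVE = "miscible-attractive"
VERDICT_PARTIAL = "partially-miscible"


@dataclass(frozen=True)
class ProfileRow:
    x2: float
    a12: float
    a_ideal: float
    flags: frozenset = frozenset()


@dataclass
class CompositionProfile:
    """Mixed-film area vs. composition at one target pressure."""

    pressure: float
    rows: list = field(default_factory=list)


@dataclass
class Extremum:
    x2: float
    kind: str  # "max" | "min"
    value: float


@dataclass
class MiscibilityAssessment:
    verdict: str
    signs: dict  # pressure -> "positive" | "negative" | "mixed" | "none"
    extrema: dict  # pressure -> list[Extremum]
    tol: float

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "signs": {f"{p:g}": s for p, s in self.signs.items()},
            "extrema": {
                f"{p:g}": [
                    {"x2": e.x2, "kind": e.kind, "value": e.value} for e in exs
                ]
                for p, exs in self.extrema.items()
            },
            "tolerance_A2": self.tol,
        }


def _index_study(isotherms: list[Isotherm]) -> dict[float, Isotherm]:
    by_x2: dict[float, Isotherm] = {}
    for iso in isotherms:
        if iso.x2 is None:
            raise ValidationError(
                f"isotherm {iso.compound_id!r} lacks molar_fraction_x2 metadata"
            )
        if iso.x2 in by_x2:
            raise ValidationError(f"duplicate isotherm for x2={iso.x2}")
        by_x2[iso.x2] = iso
    for endpoint, name in ((0.0, "component 1 (x2=0)"), (1.0, "component 2 (x2=1)")):
        if endpoint not in by_x2:
            raise ValidationError(f"study set is missing the pure {name} isotherm")
    if len(by_x2) < 3:
        raise ValidationError("study set needs both pure components and >= 1 mixture")
    return by_x2


def composition_profile(
    isotherms: list[Isotherm], pressures: list[float]
) -> list[CompositionProfile]:
    """One area-vs-composition profile per target pressure.

    Films that never reach a target pressure are kept with area 0 and an
    ``unattained`` flag rather than dropped, so ideal lines remain
    well-defined for non-spreading or low-collapse components.
    """
    by_x2 = _index_study(isotherms)
    if any(p <= 0 for p in pressures):
        raise ValidationError("target pressures must be positive")
    profiles = []
    for pi in pressures:
        readouts = {x2: area_at_pressure(iso, pi) for x2, iso in sorted(by_x2.items())}
        a1 = readouts[0.0].area
        a2 = readouts[1.0].area
        rows = []
        for x2, r in readouts.items():
            flags = set()
            if not r.attained:
                flags.add("unattained")
            rows.append(
                ProfileRow(x2, r.area, ideal_mixing_area(a1, a2, x2), frozenset(flags))
            )
        profiles.append(CompositionProfile(pi, rows))
    return profiles


def excess_profile_table(
    isotherms: list[Isotherm],
    pressures: list[float],
    grid_step: float = 0.1,
) -> list[ExcessRecord]:
    """ExcessRecord per (fraction, pressure), x2 ascending then pressure."""
    by_x2 = _index_study(isotherms)
    iso1 = by_x2[0.0]
    iso2 = by_x2[1.0]
    records = []
    for x2 in sorted(by_x2):
        if x2 in (0.0, 1.0):
            continue
        iso12 = by_x2[x2]
        for pi in pressures:
            r12 = area_at_pressure(iso12, pi)
            r1 = area_at_pressure(iso1, pi)
            r2 = area_at_pressure(iso2, pi)
            a_ideal = ideal_mixing_area(r1.area, r2.area, x2)
            flags = set()
            for tag, r in (("mixture", r12), ("pure1", r1), ("pure2", r2)):
                if not r.attained:
                    flags.add(f"{tag}-unattained")
            dg = excess_gibbs_energy(iso12, iso1, iso2, x2, pi, grid_step=grid_step)
            records.append(
                ExcessRecord(
                    x2=x2,
                    pressure=pi,
                    a12=r12.area,
                    a_ideal=a_ideal,
                    a_excess=r12.area - a_ideal,
                    dg_excess=dg,
                    flags=frozenset(flags),
                )
            )
    return records


def find_extrema(
    xs: np.ndarray, ys: np.ndarray, min_prominence: float = 0.0
) -> list[Extremum]:
    """Interior local extrema of an ordered (x, y) sequence.

    Endpoints are never reported.  Prominence gating uses
    :func:`scipy.signal.find_peaks` on the sequence and its negation, so
    the output is invariant under uniform y-scaling combined with
    proportional prominence scaling.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3:
        raise ValidationError("need at least 3 points to find interior extrema")
    if min_prominence < 0:
        raise ValidationError("min_prominence must be >= 0")
    prom = min_prominence if min_prominence > 0 else None
    out: list[Extremum] = []
    for sign, kind in ((1.0, "max"), (-1.0, "min")):
        peaks, _ = find_peaks(sign * ys, prominence=prom)
        out.extend(Extremum(float(xs[i]), kind, float(ys[i])) for i in peaks)
    out.sort(key=lambda e: e.x2)
    return out


def _has_bimodal_pattern(extrema: list[Extremum]) -> bool:
    kinds = [e.kind for e in extrema]
    for i in range(len(kinds) - 2):
        if kinds[i] == "max" and kinds[i + 1] == "min" and kinds[i + 2] == "max":
            return True
    return False


def assess_miscibility(
    records: list[ExcessRecord], tol: float = DEFAULT_EXCESS_TOL
) -> MiscibilityAssessment:
    """Qualitative miscibility verdict from the excess-area table.

    Rules, in order: every deviation inside ``tol`` of zero means the
    additivity rule holds, which cannot distinguish ideal mixing from
    complete immiscibility; two prominence-gated maxima separated by a
    minimum in any per-pressure profile signal domain formation (partial
    miscibility); otherwise the dominant deviation sign decides between
    repulsive and attractive mixing (mixed signs across pressures also
    count as partial miscibility).
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    by_pressure: dict[float, list[ExcessRecord]] = {}
    for r in records:
        by_pressure.setdefault(r.pressure, []).append(r)
    fractions = {r.x2 for r in records}
    if len(fractions) < 3:
        raise ValidationError("need records for at least 3 fractions")

    signs: dict[float, str] = {}
    extrema: dict[float, list[Extremum]] = {}
    bimodal = False
    for pi, recs in sorted(by_pressure.items()):
        recs = sorted(recs, key=lambda r: r.x2)
        dev = np.array([r.a_excess for r in recs])
        has_pos = bool(np.any(dev > tol))
        has_neg = bool(np.any(dev < -tol))
        if has_pos and has_neg:
            signs[pi] = "mixed"
        elif has_pos:
            signs[pi] = "positive"
        elif has_neg:
            signs[pi] = "negative"
        else:
            signs[pi] = "none"
        xs = [r.x2 for r in recs]
        exs = (
            find_extrema(xs, dev, min_prominence=tol) if len(recs) >= 3 else []
        )
        extrema[pi] = exs
        if _has_bimodal_pattern(exs):
            bimodal = True

    labels = set(signs.values())
    if labels <= {"none"}:
        verdict = VERDICT_IDEAL
    elif bimodal or "mixed" in labels or ({"positive", "negative"} <= labels):
        verdict = VERDICT_PARTIAL
    elif "positive" in labels:
        verdict = VERDICT_REPULSIVE
    else:
        verdict = VERDICT_ATTRACTIVE
    return MiscibilityAssessment(verdict, signs, extrema, tol)


# -- serialisation -------------------------------------------------------------


def profiles_to_csv(profiles: list[CompositionProfile], path: str | Path) -> Path:
    path = Path(path)
    lines = ["pressure_mN_per_m,x2,a12_A2,a_ideal_A2,flags"]
    for prof in profiles:
        for row in sorted(prof.rows, key=lambda r: r.x2):
            flags = ";".join(sorted(row.flags))
            lines.append(
                f"{prof.pressure:.6g},{row.x2:.6g},{row.a12:.6g},"
                f"{row.a_ideal:.6g},{flags}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def excess_to_csv(records: list[ExcessRecord], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "x2,pressure_mN_per_m,a12_A2,a_ideal_A2,a_excess_A2,dg_excess_J_mol,flags"
    ]
    for r in sorted(records, key=lambda r: (r.x2, r.pressure)):
        flags = ";".join(sorted(r.flags))
        lines.append(
            f"{r.x2:.6g},{r.pressure:.6g},{r.a12:.6g},{r.a_ideal:.6g},"
            f"{r.a_excess:.6g},{r.dg_excess:.6g},{flags}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def assessment_to_json(assessment: MiscibilityAssessment, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(assessment.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return path


def plot_profiles(
    profiles: list[CompositionProfile], path: str | Path
) -> Path:
    """Area-vs-composition panels with dashed ideal-mixing lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(profiles), figsize=(4 * len(profiles), 3.2), squeeze=False
    )
    for ax, prof in zip(axes[0], profiles):
        rows = sorted(prof.rows, key=lambda r: r.x2)
        xs = [r.x2 for r in rows]
        ax.plot(xs, [r.a12 for r in rows], "o-", label="measured")
        ax.plot(xs, [r.a_ideal for r in rows], "k--", label="ideal")
        ax.set_title(f"{prof.pressure:g} mN/m")
        ax.set_xlabel("x2")
        ax.set_ylabel("area (A$^2$/molecule)")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
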