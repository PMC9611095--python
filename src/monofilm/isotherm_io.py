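"""Reading, validating and writing pressure-area isotherm files.

File dialect
------------
A plain-text, UTF-8 CSV with ``.`` as decimal separator:

* header lines start with ``#`` and carry ``key=value`` metadata;
* the first non-header line names the two columns, exactly
  ``area_A2,pressure_mN_per_m``;
* every following line is one ``area, pressure`` sample in acquisition
  order (areas in Å²/molecule, pressures in mN/m).

Values containing leading/trailing whitespace are double-quoted on write
and unquoted on read, so arbitrary metadata survives a round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from monofilm.errors import FormatError, InsufficientDataError, ValidationError

MIN_POINTS = 4
AREA_COLUMN = "area_A2"
PRESSURE_COLUMN = "pressure_mN_per_m"
DEFAULT_NOISE_SIGMA = 0.1  # mN/m, instrument noise floor
DEFAULT_AREA_JITTER_TOL = 0.05  # Å², barrier-position jitter

_FLOAT_META_KEYS = ("molar_fraction_x2", "temperature_C", "noise_sigma")


@dataclass
class Isotherm:
    """An ordered pressure-area compression record with metadata.

    Points are stored in acquisition order.  ``meta`` holds the known keys
    ``compound_id``, ``molar_fraction_x2``, ``temperature_C``,
    ``noise_sigma`` and ``source``; unknown keys are preserved verbatim.
    """

    areas: np.ndarray
    pressures: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.areas.ndim != 1 or self.areas.shape != self.pressures.shape:
            raise ValidationError("areas and pressures must be 1-D and equal length")
        if len(self.areas) < MIN_POINTS:
            raise InsufficientDataError(
                f"isotherm needs at least {MIN_POINTS} points, got {len(self.areas)}"
            )
        if not np.all(np.isfinite(self.areas)) or not np.all(np.isfinite(self.pressures)):
            raise ValidationError("non-finite values in isotherm")
        if np.any(self.areas <= 0):
            raise ValidationError("all areas must be > 0")
        floor = -3.0 * self.noise_sigma
        if np.any(self.pressures < floor - 1e-12):
            raise ValidationError(
                f"pressure below noise floor {floor:.3f} mN/m (3 sigma)"
            )
        x2 = self.meta.get("molar_fraction_x2")
        if x2 is not None and not (0.0 <= float(x2) <= 1.0):
            raise ValidationError(f"molar_fraction_x2={x2} outside [0, 1]")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.areas)

    @property
    def x2(self) -> float | None:
        v = self.meta.get("molar_fraction_x2")
        return None if v is None else float(v)

    @property
    def compound_id(self) -> str:
        return str(self.meta.get("compound_id", ""))

    @property
    def noise_sigma(self) -> float:
        """Instrument noise s.d.; defaults to the 0.1 mN/m floor if unset."""
        v = self.meta.get("noise_sigma")
        return DEFAULT_NOISE_SIGMA if v is None else float(v)

    def is_strictly_decreasing(self) -> bool:
        return bool(np.all(np.diff(self.areas) < 0))

    def copy_with(self, areas: np.ndarray, pressures: np.ndarray) -> "Isotherm":
        return Isotherm(np.array(areas), np.array(pressures), dict(self.meta))


@dataclass(frozen=True)
class MixtureSpec:
    """Identities of the two film components and the mole fraction of the second."""

    component1_id: str
    component2_id: str
    x2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x2 <= 1.0):
            raise ValidationError(f"x2={self.x2} outside [0, 1]")

    @property
    def x1(self) -> float:
        return 1.0 - self.x2


def _coerce_meta(meta: dict) -> dict:
    out = dict(meta)
    for key in _FLOAT_META_KEYS:
        if key in out:
            try:
                out[key] = float(out[key])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"metadata {key}={out[key]!r} is not numeric") from exc
    return out


def _quote(value: str) -> str:
    if value != value.strip() or value.startswith('"'):
        return '"' + value.replace('"', '""') + '"'
    return value


def _unquote(value: str) -> str:
    if len(value) >= 2 and value.startswith('"') and value.endswith('"'):
        return value[1:-1].replace('""', '"')
    return value


def read_isotherm(path: str | Path) -> Isotherm:
    """Parse an isotherm file.

    Raises :class:`FormatError` naming the offending line on malformed
    numeric rows, :class:`InsufficientDataError` below 4 points, and
    :class:`ValidationError` for out-of-range metadata.  Monotonicity is
    *not* enforced here; a non-monotone area column is accepted and noted
    in ``meta['source']``.
    """
    path = Path(path)
    meta: dict = {}
    areas: list[float] = []
    pressures: list[float] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise FormatError(f"{path}:{lineno}: header line without '=': {line!r}")
                key, _, value = body.partition("=")
                meta[key.strip()] = _unquote(value.strip())
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if fields[:2] != [AREA_COLUMN, PRESSURE_COLUMN]:
                    raise FormatError(
                        f"{path}:{lineno}: expected column header "
                        f"'{AREA_COLUMN},{PRESSURE_COLUMN}', got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {line!r}")
            try:
                areas.append(float(fields[0]))
                pressures.append(float(fields[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if len(areas) < MIN_POINTS:
        raise InsufficientDataError(
            f"{path}: only {len(areas)} data rows, need at least {MIN_POINTS}"
        )
    meta = _coerce_meta(meta)
    meta.setdefault("source", str(path))
    iso = Isotherm(np.array(areas), np.array(pressures), meta)
    if not iso.is_strictly_decreasing():
        note = "non-monotone area column"
        if note not in str(meta.get("source", "")):
            iso.meta["source"] = f"{meta['source']} [{note}]"
    return iso


def write_isotherm(iso: Isotherm, path: str | Path) -> Path:
    """Write ``iso`` to ``path``; the file re-reads to an equal isotherm.

    Numeric values use 9 significant digits, comfortably beyond the 1e-6
    relative round-trip guarantee.
    """
    path = Path(path)
    lines = []
    for key, value in iso.meta.items():
        if isinstance(value, float):
            text = f"{value:.9g}"
        else:
            text = _quote(str(value))
        lines.append(f"# {key}={text}")
    lines.append(f"{AREA_COLUMN},{PRESSURE_COLUMN}")
    for a, p in zip(iso.areas, iso.pressures):
        lines.append(f"{a:.9g},{p:.9g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def extract_compression_branch(
    iso: Isotherm, area_jitter_tol: float = DEFAULT_AREA_JITTER_TOL
) -> Isotherm:
    """Return the clean, strictly area-decreasing compression branch.

    The record is truncated at its global minimum area (everything after is
    expansion), then any point whose area exceeds the running minimum by
    more than ``area_jitter_tol`` is dropped.  Points within the tolerance
    are merged onto the running minimum so the result is strictly
    decreasing.  Idempotent; metadata is preserved unchanged.
    """
    if area_jitter_tol < 0:
        raise ValidationError("area_jitter_tol must be >= 0")
    end = int(np.argmin(iso.areas))  # first occurrence of the global minimum
    areas = iso.areas[: end + 1]
    pressures = iso.pressures[: end + 1]

    kept_a: list[float] = []
    kept_p: list[float] = []
    running_min = math.inf
    for a, p in zip(areas, pressures):
        if a < running_min:
            running_min = a
            kept_a.append(a)
            kept_p.append(p)
        elif a - running_min <= area_jitter_tol:
            # jitter point: merge onto the running minimum (average pressure)
            kept_p[-1] = 0.5 * (kept_p[-1] + p)
        # else: drop (area bounced back above tolerance)
    if len(kept_a) < MIN_POINTS:
        raise InsufficientDataError(
            f"only {len(kept_a)} points survive compression-branch extraction"
        )
    return iso.copy_with(np.array(kept_a), np.array(kept_p))
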