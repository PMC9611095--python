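"""Synthetic pressure-area isotherms with known ground truth.

Pure films follow a Volmer-type 2D equation of state with a cohesion
pressure, ``A(pi) = A0 + kT_term / (pi + pi_c)``, optionally carved by a
sigmoidal plateau (a liquid-expanded to liquid-condensed transition).
Mixed films obey mole-fraction additivity plus a symmetric first-order
regular-solution excess term

    A_ex(pi, x2) = 4 * x2 * (1 - x2) * a_ex * exp(-pi / pi_s)

whose pressure integral has the closed form used as analysis ground truth.
Instrument noise is i.i.d. Gaussian on pressure only, clamped at -3 sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from monofilm.errors import DomainError, ValidationError
from monofilm.isotherm_io import Isotherm, write_isotherm

#: 1 mN/m * Å²/molecule expressed per mole: N_A * 1e-23 J = 6.02214 J/mol.
J_PER_MOL_PER_MNM_A2 = 6.02214

#: k_B * 310.15 K in film units (mN/m * Å²); the 37 °C default.
KT_37C = 428.2

#: The study's molar-fraction grid for the second component.
STUDY_FRACTIONS = (0.015, 0.03, 0.045, 0.06, 0.09, 0.12, 0.25, 0.50)

#: Area ramp used for films that never spread (pressure stays at noise level).
NON_SPREADING_AREA_RANGE = (130.0, 20.0)


@dataclass(frozen=True)
class Plateau:
    """Sigmoidal area step modelling an LE-LC transition plateau."""

    pi_t: float  # transition pressure, mN/m
    delta_A: float  # area lost across the step, Å²
    width: float  # pressure width of the step, mN/m

    def __post_init__(self) -> None:
        if self.delta_A <= 0 or self.width <= 0:
            raise ValidationError("plateau delta_A and width must be > 0")


@dataclass(frozen=True)
class PureEOSParams:
    """Volmer-type equation-of-state parameters for one pure component."""

    id: str = "component"
    A0: float = 40.0  # excluded (limiting) area, Å²
    pi_c: float = 5.7  # cohesion pressure, mN/m
    kT_term: float = KT_37C  # thermal term, mN/m * Å²
    plateau: Plateau | None = None
    collapse_pi: float | None = None  # mN/m; pure film cannot be compressed beyond
    non_spreading: bool = False  # overrides everything: film never builds pressure

    def __post_init__(self) -> None:
        if self.A0 <= 0 or self.pi_c <= 0 or self.kT_term <= 0:
            raise ValidationError("A0, pi_c and kT_term must all be > 0")
        if self.plateau is not None and self.collapse_pi is not None:
            if not (0.0 < self.plateau.pi_t < self.collapse_pi):
                raise ValidationError("need 0 < plateau.pi_t < collapse_pi")

    @property
    def liftoff_area(self) -> float:
        """Area where pressure first leaves zero: A0 + kT_term / pi_c."""
        return self.A0 + self.kT_term / self.pi_c

    def area(self, pressures: np.ndarray) -> np.ndarray:
        """Noiseless area at each pressure; zeros for a non-spreading film."""
        pi = np.asarray(pressures, dtype=float)
        if self.non_spreading:
            return np.zeros_like(pi)
        a = self.A0 + self.kT_term / (pi + self.pi_c)
        if self.plateau is not None:
            z = (pi - self.plateau.pi_t) / self.plateau.width
            a = a - self.plateau.delta_A / (1.0 + np.exp(-z))
        return a


@dataclass(frozen=True)
class ExcessParams:
    """Symmetric regular-solution excess-area term with pressure decay.

    ``pi_s = inf`` gives a pressure-independent excess; ``a_ex = 0``
    reproduces ideal mixing exactly.
    """

    a_ex: float = 0.0  # amplitude, Å²; >0 repulsive, <0 attractive
    pi_s: float = math.inf  # pressure decay scale, mN/m

    def __post_init__(self) -> None:
        if not (self.pi_s > 0):
            raise ValidationError("pi_s must be > 0 (may be inf)")

    def area_excess(self, pressures: np.ndarray, x2: float) -> np.ndarray:
        pi = np.asarray(pressures, dtype=float)
        decay = np.ones_like(pi) if math.isinf(self.pi_s) else np.exp(-pi / self.pi_s)
        return 4.0 * x2 * (1.0 - x2) * self.a_ex * decay


@dataclass(frozen=True)
class PressureGrid:
    """Uniform target-pressure grid, inclusive of both ends."""

    min: float = 0.0
    max: float = 35.0
    step: float = 0.25

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("pressure grid step must be > 0")
        if self.max <= self.min:
            raise ValidationError("pressure grid max must exceed min")

    def pressures(self) -> np.ndarray:
        n = int(round((self.max - self.min) / self.step))
        return self.min + self.step * np.arange(n + 1)


@dataclass
class StudyConfig:
    """Full design of a two-component mixing study."""

    component1: PureEOSParams = field(default_factory=lambda: PureEOSParams(id="lipid"))
    component2: PureEOSParams = field(
        default_factory=lambda: PureEOSParams(id="compound", A0=25.0, pi_c=8.0)
    )
    fractions: tuple = STUDY_FRACTIONS
    excess: ExcessParams = field(default_factory=ExcessParams)
    noise_sigma: float = 0.0
    pressure_grid: PressureGrid = field(default_factory=PressureGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        self.fractions = tuple(float(f) for f in self.fractions)
        if len(set(self.fractions)) != len(self.fractions):
            raise ValidationError("duplicate fraction values in study config")
        if any(not (0.0 < f < 1.0) for f in self.fractions):
            raise ValidationError("fractions must lie strictly inside (0, 1)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def excess_gibbs_truth(ex: ExcessParams, x2: float, pi_star: float) -> float:
    """Closed-form excess Gibbs energy of the generator, in J/mol.

    Integral of the excess-area term from 0 to ``pi_star``:
    ``6.02214 * 4 x2 (1-x2) a_ex * pi_s * (1 - exp(-pi*/pi_s))``, with the
    constant-excess limit ``6.02214 * A_ex * pi*`` as pi_s -> inf.
    """
    amp = 4.0 * x2 * (1.0 - x2) * ex.a_ex
    if math.isinf(ex.pi_s):
        integral = amp * pi_star
    else:
        integral = amp * ex.pi_s * (1.0 - math.exp(-pi_star / ex.pi_s))
    return J_PER_MOL_PER_MNM_A2 * integral


def _emit_isotherm(
    areas: np.ndarray,
    pressures: np.ndarray,
    noise_sigma: float,
    seed: int,
    meta: dict,
) -> Isotherm:
    """Add pressure noise, clamp at -3 sigma, order by decreasing area."""
    rng = np.random.default_rng(seed)
    noisy = np.asarray(pressures, dtype=float).copy()
    if noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, noise_sigma, size=len(noisy))
        noisy = np.maximum(noisy, -3.0 * noise_sigma)
    order = np.argsort(areas)[::-1]  # compression order: large area first
    meta = dict(meta)
    meta["noise_sigma"] = float(noise_sigma)
    return Isotherm(np.asarray(areas)[order], noisy[order], meta)


def generate_pure_isotherm(
    p: PureEOSParams,
    grid: PressureGrid,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Isotherm:
    """Simulate one pure-component compression isotherm.

    Non-spreading films get a descending area ramp with pure-noise
    pressures.  A grid reaching past ``collapse_pi`` is a domain error.
    """
    if p.non_spreading:
        n = len(grid.pressures())
        areas = np.linspace(*NON_SPREADING_AREA_RANGE, n)
        base = np.zeros(n)
    else:
        if p.collapse_pi is not None and grid.max > p.collapse_pi:
            raise DomainError(
                f"grid max {grid.max} exceeds collapse pressure {p.collapse_pi}"
            )
        base = grid.pressures()
        areas = p.area(base)
    meta = {
        "compound_id": p.id,
        "molar_fraction_x2": 0.0,
        "temperature_C": 37.0,
        "source": "synthetic:pure",
    }
    return _emit_isotherm(areas, base, noise_sigma, seed, meta)


def generate_mixture_isotherm(
    p1: PureEOSParams,
    p2: PureEOSParams,
    x2: float,
    ex: ExcessParams,
    grid: PressureGrid,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Isotherm:
    """Simulate a mixed-film isotherm by additivity plus the excess term.

    The noiseless area at every grid pressure is
    ``(1-x2) A1(pi) + x2 A2(pi) + A_ex(pi, x2)``; a non-spreading component
    contributes zero area.  Collapse limits are not applied to mixtures
    (the mixed film is its own phase).  Metadata records ``x2`` and the
    ground-truth excess parameters.
    """
    if not (0.0 <= x2 <= 1.0):
        raise ValidationError(f"x2={x2} outside [0, 1]")
    if p1.non_spreading and p2.non_spreading:
        raise DomainError("both components are non-spreading; no film forms")
    pi = grid.pressures()
    areas = (1.0 - x2) * p1.area(pi) + x2 * p2.area(pi) + ex.area_excess(pi, x2)
    if np.any(areas <= 0):
        raise DomainError("composed mixture area is non-positive on the grid")
    meta = {
        "compound_id": f"{p1.id}/{p2.id}",
        "molar_fraction_x2": float(x2),
        "temperature_C": 37.0,
        "truth_a_ex_A2": float(ex.a_ex),
        "truth_pi_s_mN_m": float(ex.pi_s),
        "source": "synthetic:mixture",
    }
    return _emit_isotherm(areas, pi, noise_sigma, seed, meta)


def _pure_grid(p: PureEOSParams, grid: PressureGrid) -> PressureGrid:
    """Truncate the study grid at a pure component's collapse pressure."""
    if p.collapse_pi is None or grid.max <= p.collapse_pi:
        return grid
    top = grid.min + grid.step * math.floor((p.collapse_pi - grid.min) / grid.step)
    return PressureGrid(grid.min, top, grid.step)


def generate_study_dataset(cfg: StudyConfig, out_dir: str | Path) -> dict:
    """Write the whole synthetic study to ``out_dir``.

    Produces one file per pure component (x2 = 0 and 1), one per mixture
    fraction, plus ``ground_truth.csv`` holding the closed-form excess
    Gibbs energies at 10/20/30 mN/m.  Deterministic under a fixed seed:
    per-file seeds are spawned from ``cfg.seed`` in a fixed order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(cfg.fractions) + 2)
    files: list[Path] = []

    iso1 = generate_pure_isotherm(
        cfg.component1, _pure_grid(cfg.component1, cfg.pressure_grid),
        cfg.noise_sigma, int(seeds[0]),
    )
    files.append(write_isotherm(iso1, out_dir / f"pure_{cfg.component1.id}.csv"))

    iso2 = generate_pure_isotherm(
        cfg.component2, _pure_grid(cfg.component2, cfg.pressure_grid),
        cfg.noise_sigma, int(seeds[1]),
    )
    iso2.meta["molar_fraction_x2"] = 1.0
    files.append(write_isotherm(iso2, out_dir / f"pure_{cfg.component2.id}.csv"))

    for i, x2 in enumerate(cfg.fractions):
        iso = generate_mixture_isotherm(
            cfg.component1, cfg.component2, x2, cfg.excess,
            cfg.pressure_grid, cfg.noise_sigma, int(seeds[2 + i]),
        )
        files.append(write_isotherm(iso, out_dir / f"mix_x2_{x2:.3f}.csv"))

    truth_path = out_dir / "ground_truth.csv"
    lines = ["x2,a_ex_A2,pi_s_mN_m,dgex_10,dgex_20,dgex_30"]
    for x2 in cfg.fractions:
        dg = [excess_gibbs_truth(cfg.excess, x2, p) for p in (10.0, 20.0, 30.0)]
        lines.append(
            f"{x2:.6g},{cfg.excess.a_ex:.6g},{cfg.excess.pi_s:.6g},"
            f"{dg[0]:.6g},{dg[1]:.6g},{dg[2]:.6g}"
        )
    truth_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    return {
        "isotherms": [str(f) for f in files],
        "ground_truth": str(truth_path),
        "seed": cfg.seed,
        "noise_sigma": cfg.noise_sigma,
    }


# -- configuration files -------------------------------------------------------


def _params_to_dict(p: PureEOSParams) -> dict:
    d = {
        "id": p.id,
        "A0": p.A0,
        "pi_c": p.pi_c,
        "kT_term": p.kT_term,
        "non_spreading": p.non_spreading,
    }
    if p.plateau is not None:
        d["plateau"] = {
            "pi_t": p.plateau.pi_t,
            "delta_A": p.plateau.delta_A,
            "width": p.plateau.width,
        }
    if p.collapse_pi is not None:
        d["collapse_pi"] = p.collapse_pi
    return d


def _params_from_dict(d: dict) -> PureEOSParams:
    plateau = None
    if d.get("plateau"):
        plateau = Plateau(**d["plateau"])
    return PureEOSParams(
        id=str(d.get("id", "component")),
        A0=float(d.get("A0", 40.0)),
        pi_c=float(d.get("pi_c", 5.7)),
        kT_term=float(d.get("kT_term", KT_37C)),
        plateau=plateau,
        collapse_pi=None if d.get("collapse_pi") is None else float(d["collapse_pi"]),
        non_spreading=bool(d.get("non_spreading", False)),
    )


def study_config_to_dict(cfg: StudyConfig) -> dict:
    return {
        "component1": _params_to_dict(cfg.component1),
        "component2": _params_to_dict(cfg.component2),
        "fractions": list(cfg.fractions),
        "excess": {"a_ex": cfg.excess.a_ex, "pi_s": cfg.excess.pi_s},
        "noise_sigma": cfg.noise_sigma,
        "pressure_grid": {
            "min": cfg.pressure_grid.min,
            "max": cfg.pressure_grid.max,
            "step": cfg.pressure_grid.step,
        },
        "seed": cfg.seed,
    }


def study_config_from_dict(d: dict) -> StudyConfig:
    ex = d.get("excess", {})
    grid = d.get("pressure_grid", {})
    pi_s = ex.get("pi_s", math.inf)
    return StudyConfig(
        component1=_params_from_dict(d.get("component1", {"id": "lipid"})),
        component2=_params_from_dict(d.get("component2", {"id": "compound", "A0": 25.0, "pi_c": 8.0})),
        fractions=tuple(d.get("fractions", STUDY_FRACTIONS)),
        excess=ExcessParams(
            a_ex=float(ex.get("a_ex", 0.0)),
            pi_s=math.inf if pi_s in ("inf", ".inf", None) else float(pi_s),
        ),
        noise_sigma=float(d.get("noise_sigma", 0.0)),
        pressure_grid=PressureGrid(
            float(grid.get("min", 0.0)), float(grid.get("max", 35.0)),
            float(grid.get("step", 0.25)),
        ),
        seed=int(d.get("seed", 0)),
    )


def load_study_config(path: str | Path) -> StudyConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return study_config_from_dict(data)


def save_study_config(cfg: StudyConfig, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(study_config_to_dict(cfg), fh, sort_keys=False)
    return path


# -- presets emulating the study's components ---------------------------------

PRESETS: dict[str, PureEOSParams] = {
    # phospholipid: lift-off at 40 + 428.2/5.7 = 115.1 Å², fluid throughout
    "dmpc_like": PureEOSParams(id="DMPC", A0=40.0, pi_c=5.7, kT_term=KT_37C),
    # water-soluble drug: never builds surface pressure
    "cytarabine_like": PureEOSParams(id="AraC", non_spreading=True),
    # short-chain triacyl prodrug: low collapse plateau near 6 mN/m
    "trimyristoyl_like": PureEOSParams(
        id="tri-C14", A0=55.0, pi_c=5.5, kT_term=KT_37C, collapse_pi=6.0
    ),
    # long-chain triacyl prodrug: collapse near 8 mN/m
    "tristearoyl_like": PureEOSParams(
        id="tri-C18", A0=48.0, pi_c=6.0, kT_term=KT_37C, collapse_pi=8.0
    ),
    # generic well-behaved second component (full pressure range)
    "generic": PureEOSParams(id="compound", A0=25.0, pi_c=8.0, kT_term=KT_37C),
}


def preset_params(name: str) -> PureEOSParams:
    try:
        return PRESETS[name]
    except KeyError as exc:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from exc
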