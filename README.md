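# monofilm

Thermodynamic analysis of two-component Langmuir-monolayer compression
isotherms (surface pressure π in mN/m vs. mean molecular area A in
Å²/molecule), plus a synthetic isotherm generator with known ground
truth so the whole pipeline is testable without instrument data.

Implemented diagnostics:

- **Area-vs-composition profiles** at target pressures with the dashed
  ideal-mixing (mole-fraction additivity) line.
- **Excess molecular area** `A_ex = A12 − (x1·A1 + x2·A2)`; positive
  values indicate repulsive interactions between the film components.
- **Excess Gibbs free energy of mixing** `ΔG_ex = ∫₀^π* A_ex dπ` by
  trapezoidal integration on a common pressure grid, converted to J/mol
  with 6.02214 J·mol⁻¹ per mN/m·Å² (Avogadro × 1e−23 J). Below the
  common lift-off (first π > 0.3 mN/m, 3× the ±0.1 mN/m sensor noise)
  the integrand is extended constantly.
- **Compressibility modulus** `Cs⁻¹ = −A·(∂π/∂A)` (conventional sign,
  positive on compression) via Savitzky–Golay differentiation on a
  uniform area grid, with phase labels
  (gaseous < 12.5 ≤ LE < 50 ≤ LE-LC < 100 ≤ LC < 250 ≤ solid, mN/m)
  and plateau/transition detection.
- **Miscibility verdict** (`ideal-or-immiscible`, `miscible-repulsive`,
  `miscible-attractive`, `partially-miscible`) from the sign and shape
  of the excess-area profiles.

The generator uses a Volmer-type 2D equation of state
`A(π) = A0 + kT/(π + π_c)` with an optional sigmoidal LE–LC plateau,
non-spreading and collapse-limited components, a symmetric
regular-solution excess term `A_ex(π, x2) = 4·x2·(1−x2)·a_ex·e^(−π/π_s)`
(closed-form ΔG_ex ground truth), and Gaussian pressure noise.

## CLI

```sh
# write a study config (YAML) — see monofilm.synthetic_data.StudyConfig
monofilm simulate --config study.yaml --out study/          # isotherms + ground truth
monofilm analyze  --in study/ --out results/ --pressures 10,20,30
monofilm full     --config study.yaml --out run/ --seed 1   # both stages
```

`analyze` consumes any directory of isotherm CSVs (dialect below) that
contains both pure components (`molar_fraction_x2` 0 and 1) and at
least one mixture. Outputs: `profiles.csv`, `excess.csv`,
`compressibility/cs_*.csv`, `assessment.json` and a `manifest.json`
recording the full effective configuration. `--plots` adds a PNG of the
composition profiles.

Example config:

```yaml
component1: {id: DMPC, A0: 40.0, pi_c: 5.7, kT_term: 428.2}
component2: {id: compound, A0: 25.0, pi_c: 8.0}
fractions: [0.015, 0.03, 0.045, 0.06, 0.09, 0.12, 0.25, 0.50]
excess: {a_ex: 5.0, pi_s: 20.0}
noise_sigma: 0.1
pressure_grid: {min: 0.0, max: 35.0, step: 0.25}
seed: 1
```

## Isotherm file dialect

UTF-8 CSV; `#key=value` header lines; then exactly
`area_A2,pressure_mN_per_m` followed by numeric rows in acquisition
order. Recognised metadata: `compound_id`, `molar_fraction_x2`,
`temperature_C`, `noise_sigma`, `source`; unknown keys round-trip.

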