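# Methods

## Binding equilibrium

The chaperone–cargo interaction is modeled as a single-site 1:1 binding
equilibrium. With cargo total `C`, chaperone total `K`, and dissociation
constant `K_D` (all μM), the free cargo concentration `F` solves
`F² + b·F − K_D·C = 0` with `b = K_D + K − C`. The implementation uses the
branch-selected root

- `F = (−b + √(b² + 4·K_D·C)) / 2` when `b ≤ 0`,
- `F = 2·K_D·C / (b + √(b² + 4·K_D·C))` when `b > 0`,

so each branch only adds same-signed quantities; a single-branch form loses
up to ~6 significant digits in the tight-binding/excess-cargo corner (this
showed up as a phantom ~1e-12 μM complex at zero chaperone before the
branch split). The complex is clipped into `[0, min(C, K)]` so both
conservation laws hold to machine precision. `K_D = 0` is rejected at the
type level; the stoichiometric limit `max(C − K, 0)` is exposed as its own
helper. Tests check the closed form against an independent bisection root
finder on the mass-action residual over 1000 random parameter triples
(agreement to 1e-10).

Polyphasic linkage uses single-site binding polynomials `P = 1 + [L]/K_D`
per phase; `kd_dense` defaults to infinity (no dense-phase binding), the
preferential-dilute-binding case that raises the saturation concentration.
A free concentration exactly equal to `c_sat` classifies as subsaturated:
condensation requires strict supersaturation, and the conservative call
avoids false condensation claims on a measure-zero boundary.

## Size-distribution processing

MRPS tables are read as bin-center / density columns; edges are
reconstructed at midpoints of consecutive centers with symmetric end bins.
Rebinning redistributes per-bin particle content (density × width)
proportionally to overlap length — exact under the uniform-within-bin
assumption and count-conserving on the intersection of supports.

**Dual-cartridge merge.** The 70–400 nm and 250–2000 nm cartridges carry
independent concentration calibrations and no published reconciliation
recipe, so the merge is defined here as: per bootstrap draw, resample
`ceil(2/3·n)` replicates with replacement per cartridge and average; scale
the large-cartridge draw by the ratio of mean densities over the 250–400 nm
overlap; join the two windows at the small-cartridge bin edge nearest
325 nm (the overlap midpoint), keeping each cartridge's native grid on its
own side so degenerate constant-density inputs are reproduced exactly.
Mean and per-bin standard deviation over draws give the merged
distribution and its spread. Defaults: 1000 draws at the function level;
the packaged pipeline uses 200 draws with triplicate data, which a
Monte-Carlo convergence test shows is within ~1/√200 of the asymptotic
mean. The cartridge-window containment check allows 1% slack because grids
reconstructed from center tables overhang the nominal window by a fraction
of a bin.

**KL divergence.** Distributions are converted to probability mass
functions by flooring exact zeros at 1e-5 counts/ml/nm *before*
normalization (both arguments floored), then `KLD(P‖Q) = Σ P·ln(P/Q)` in
nats (natural log; base only rescales a descriptive quantity). Profile
comparisons are oriented query-vs-reference with the untreated
(no-chaperone) condition as reference Q. scipy's entropy is used as an
independent cross-check in tests only.

**Flatness.** The mesoscale "flattened regime" is quantified as the
absolute least-squares slope of `ln p(d)` vs `d` over 400–1100 nm
(probability density at bin centers); `|slope| < 1e-3 /nm` flags the
regime. The threshold is a package default, configurable — no quantitative
criterion exists in the literature for this feature.

## FCS

Single-component 3D-Gaussian model
`G(t) = 1 + (1/N)·(1 + t/τD)⁻¹·(1 + (t/τD)·r0²/z0²)^(−1/2)`. Fitting uses
trust-region least squares (lmfit) with N initialized from the first-lag
amplitude, τD from the half-amplitude lag, bounds N ∈ (1e-3, 1e6),
τD ∈ (0.1 μs, 10 s); traces with amplitude below a noise floor (default
1e-4) and fits landing on a bound are reported non-converged with a
diagnostic rather than raising. Hydrodynamic radii come from
`Rh = kB·T·τD / (6πη·D_ref·τD_ref)` — Stokes–Einstein with the sample
diffusion coefficient referenced to a calibration dye in the same focal
volume, making Rh linear in τD. Default calibration (T = 295.15 K,
η = 1.0e-3 Pa·s, D_ref = 4.14e-10 m²/s ≈ a small organic dye,
τD_ref = 30 μs) is config-exposed and must be replaced with instrument
values for real data. Multi-trace protocols report both median and mean
radii with interquartile range; polydispersity appears as spread across
traces, not as extra fit components.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes,
not any mechanistic kinetics. `p(d)` on 1–5000 nm is a mixture of:

- lognormal monomer peak (median 4 nm, σ_ln 0.15);
- truncated power-law cluster tail `d^(−α)·e^(−d/λ)` with α = 2.5 and
  λ = 500 nm at the 2 μM reference, coupled to free cargo as
  `λ ∝ cargo_free^0.5`;
- uniform plateau on 400–1100 nm (weight 0.05 at reference, ∝ cargo_free):
  the flattened regime is concentration-dependent and distributions become
  strictly decaying at low free cargo;
- lognormal condensate mode at 1500 nm, weight ∝ the degree of
  supersaturation above `c_sat`, zero below it.

Total assembly concentration is 1e10 /ml per μM free cargo; MRPS sampling
volume is 5 μl. These two, the λ exponent, and the weight couplings were
fixed once by a counting power analysis: the expected-shape KL between
adjacent study conditions (2 → 1.05 → 0.29 → 0.048 → 0.025 μM free cargo)
must exceed the Poisson noise floor of a triplicate measurement, otherwise
the matched-comparison design cannot distinguish neighboring conditions
even in principle. A 1/3-power λ coupling fails that requirement for the
two lowest conditions (shape KL ≈ 0.003 vs noise ≈ 0.004–0.02); the 0.5
exponent separates them (shape KL ≈ 0.013). All couplings are qualitative
modeling choices exposed in `LandscapeParams`; no quantitative
concentration law is claimed.

The linked-equilibrium hypothesis is embedded by construction: replicate
generation first solves the binding equilibrium and builds the landscape
from free cargo alone, so conditions with equal free cargo have identical
expected densities. Presets: `fus` (K_D 50 nM), `fus_p525l` (K_D 200 nM,
slightly heavier clustering), `hnrnpa2` (K_D 50 nM, clustering only above
`c_sat`, no plateau).

What the generator does **not** emulate: instrument size-dependent
detection efficiency, replicate-level calibration drift beyond the
cross-cartridge scale factor, non-Poisson count noise, aggregation
kinetics, and any fibril/amyloid states. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes from data
that contain it — not that real measurements satisfy those assumptions.

## Randomness and determinism

Every stochastic step takes a seed; substreams are derived from a master
seed with counter-based `SeedSequence` splitting (per condition, per
cartridge, per replicate) and recorded in outputs along with a config hash
and package version. Bootstrap-merge seeds derive from (pipeline seed,
condition label), so the same condition data always merges identically —
which also makes `KLD = 0` exact for self-comparison. Identical config and
seed reproduce every table byte-for-byte.

## Problem sizes

Default study grid: 2 μM cargo; chaperone 0, 1, 2, 4, 6 μM; K_D 50 nM;
triplicates per cartridge; 64 log-spaced bins per cartridge window; 200
bootstrap draws per merge. One full matched comparison takes well under a
second; the 20-seed reproducibility sweep in the test suite a few seconds.
FCS recovery tests use 50–100 traces of 50 log-spaced lags (1 μs–1 s).

## Known limitations

- Single-site, non-cooperative binding only; no Ran-GTP release kinetics.
- Single-component FCS fits; two-component data yields an effective τD
  between the components (tested as a bracketing property).
- The KL comparison is descriptive; no inferential statistics or
  multiplicity correction are attached (none would be meaningful for a
  divergence between two specific samples).
- The overlap reconciliation and bootstrap subset sizes of the merge are
  package conventions — alternatives (e.g. inverse-variance weighting in
  the overlap) would be equally defensible.
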