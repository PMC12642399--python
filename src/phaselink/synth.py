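"""Synthetic cluster-size landscapes and instrument observation models.

The generator encodes the working picture of prion-like RBP self-assembly:
a continuum of states from ~4 nm monomers through nano- and mesoscale
clusters (tens to hundreds of nm, heavy-tailed abundance) up to >1 μm
condensates that appear only above the saturation concentration csat.  The
size density p(d) is a mixture of

* a narrow lognormal monomer peak,
* a truncated power-law cluster tail p(d) ∝ d^(−α)·exp(−d/λ),
* an optional uniform "plateau" component over ~400–1100 nm emulating the
  flattened free-energy regime where mesoscale clusters of different sizes
  occur with comparable probability, and
* a lognormal condensate mode (>1 μm) switched on only above csat.

The central hypothesis being exercised — linked equilibria — is built in:
the landscape is a function of the *free* cargo concentration alone, so two
conditions with different total cargo/chaperone but equal free cargo have
identical expected size distributions.  Observation models (MRPS cartridge
windows with Poisson count noise; FCS autocorrelation traces with Gaussian
noise) turn landscapes into the data the analysis modules consume.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import binding
from .errors import DomainError, ValidationError
from .fcs import (
    BOLTZMANN_J_PER_K,
    AutocorrelationTrace,
    Calibration,
    InstrumentGeometry,
    model_autocorrelation,
)
from .sizedist import C400_WINDOW, C2000_WINDOW, ReplicateSet, SizeDistribution

__all__ = [
    "LandscapeParams",
    "Landscape",
    "MRPSInstrument",
    "ConditionSpec",
    "ConditionData",
    "ConditionGrid",
    "PRESETS",
    "generate_cluster_landscape",
    "apply_mrps_instrument",
    "generate_replicates",
    "generate_fcs_trace",
    "generate_condition_grid",
]

_D_MIN, _D_MAX = 1.0, 5000.0  # nm, landscape support
_GRID_POINTS = 4096
_REFERENCE_CARGO_UM = 2.0  # concentration at which tail_scale is quoted


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the generative cluster/condensate size landscape.

    ``concentration_per_uM`` (assemblies per ml per μM free cargo) and the
    power-law coupling of the tail cutoff to free cargo
    (λ_eff = tail_scale · (cargo_free / 2 μM)**tail_scale_exponent) encode
    the qualitative growth of particle counts and sizes with concentration;
    no quantitative law is claimed.  Defaults were sized once by a counting
    power analysis so that adjacent study conditions differ by more than the
    Poisson noise floor of a triplicate measurement (see the methods note).
    """

    monomer_diameter: float = 4.0  # nm
    monomer_sigma_ln: float = 0.15
    tail_exponent: float = 2.5  # α of d^-α
    tail_scale: float = 500.0  # λ (nm) at the 2 μM reference
    tail_scale_exponent: float = 0.5  # λ ∝ cargo_free**this
    tail_weight: float = 0.30
    plateau_range: tuple = (400.0, 1100.0)
    plateau_weight: float = 0.05
    csat: float = 1.0  # μM; condensate mode appears only above this
    condensate_mode_diameter: float = 1500.0  # nm
    condensate_sigma_ln: float = 0.2
    condensate_weight: float = 0.05
    concentration_per_uM: float = 1.0e10  # assemblies / ml / μM free cargo
    tail_only_above_csat: bool = False  # hnRNPA2-style: no subsaturated clustering

    def __post_init__(self) -> None:
        weights = (self.tail_weight, self.plateau_weight, self.condensate_weight)
        if any(not (0 <= w <= 1) for w in weights) or sum(weights) > 1:
            raise ValidationError("component weights must lie in [0,1] and sum to <= 1")
        if self.monomer_diameter <= 0 or self.condensate_mode_diameter <= 1000:
            raise ValidationError("monomer_diameter > 0 and condensate_mode_diameter > 1000 nm required")
        lo, hi = self.plateau_range
        if not (70.0 <= lo < hi <= 2000.0):
            raise ValidationError("plateau_range must be an increasing interval within [70, 2000] nm")
        if self.csat <= 0 or self.tail_scale <= 0 or self.concentration_per_uM <= 0:
            raise ValidationError("csat, tail_scale, concentration_per_uM must be > 0")


@dataclass(frozen=True)
class Landscape:
    """A normalized size density p(d) on [1, 5000] nm plus a concentration."""

    grid: np.ndarray  # nm
    pdf: np.ndarray  # 1/nm, integrates to 1 over grid
    total_concentration: float  # assemblies / ml
    cargo_free: float  # μM
    component_weights: dict

    def bin_masses(self, bin_edges: np.ndarray) -> np.ndarray:
        """Probability mass of p(d) inside each [e_i, e_{i+1}] bin."""
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(self.grid) * 0.5 * (self.pdf[:-1] + self.pdf[1:]))])
        at_edges = np.interp(np.clip(bin_edges, self.grid[0], self.grid[-1]), self.grid, cdf)
        return np.diff(at_edges)


@dataclass(frozen=True)
class MRPSInstrument:
    """MRPS cartridge model: detection window, sampled volume, bin grid."""

    name: str
    window: tuple  # (lo, hi) nm
    volume_ml: float = 5.0e-3  # 5 μl injection
    n_bins: int = 64

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (1.0 <= lo < hi <= 5000.0):
            raise ValidationError("window must be increasing and within [1, 5000] nm")
        if self.volume_ml <= 0:
            raise ValidationError("volume_ml must be > 0")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.geomspace(self.window[0], self.window[1], self.n_bins + 1)

    @classmethod
    def c400(cls, **kw) -> "MRPSInstrument":
        return cls("C400", C400_WINDOW, **kw)

    @classmethod
    def c2000(cls, **kw) -> "MRPSInstrument":
        return cls("C2000", C2000_WINDOW, **kw)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: totals, affinity, replication, seed."""

    cargo_total: float  # μM
    chaperone_total: float  # μM
    kd: float  # μM
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        binding.BindingSystem(self.cargo_total, self.chaperone_total, self.kd)
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    @property
    def cargo_free(self) -> float:
        return binding.solve_equilibrium(
            binding.BindingSystem(self.cargo_total, self.chaperone_total, self.kd)
        ).cargo_free


@dataclass(frozen=True)
class Preset:
    """Named cargo style: affinity for the chaperone plus clustering behavior."""

    name: str
    kd: float  # μM
    landscape: LandscapeParams


PRESETS = {
    "fus": Preset("fus", 0.05, LandscapeParams()),
    "fus_p525l": Preset("fus_p525l", 0.2, LandscapeParams(tail_weight=0.35)),
    "hnrnpa2": Preset("hnrnpa2", 0.05, LandscapeParams(plateau_weight=0.0, tail_only_above_csat=True)),
}


def _lognormal_pdf(d: np.ndarray, median: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((np.log(d) - math.log(median)) / sigma) ** 2) / (
        d * sigma * math.sqrt(2 * math.pi)
    )


def _normalize(grid: np.ndarray, f: np.ndarray) -> np.ndarray:
    area = np.trapezoid(f, grid)
    if area <= 0:
        raise DomainError("component density has zero mass on the support")
    return f / area


def generate_cluster_landscape(cargo_free: float, params: LandscapeParams) -> Landscape:
    """Build the mixture size density p(d) at a given free cargo concentration.

    Mixture weights: the condensate mode is present only for
    ``cargo_free > csat``; the cluster tail (and plateau) vanish at zero
    cargo and, for ``tail_only_above_csat`` presets, below csat; whatever
    weight remains sits in the monomer peak.  The tail cutoff scales as
    ``tail_scale · (cargo_free / 2 μM)**tail_scale_exponent`` and the total assembly
    concentration as ``concentration_per_uM · cargo_free``.
    """
    if cargo_free < 0 or not math.isfinite(cargo_free):
        raise DomainError(f"cargo_free must be >= 0 and finite, got {cargo_free!r}")
    grid = np.geomspace(_D_MIN, _D_MAX, _GRID_POINTS)

    clusters_active = cargo_free > 0 and not (
        params.tail_only_above_csat and cargo_free <= params.csat
    )
    w_tail = params.tail_weight if clusters_active else 0.0
    # the flattened mesoscale regime fades as free cargo drops (distributions
    # become strictly decaying), and condensate abundance grows with the
    # degree of supersaturation
    w_plateau = (
        params.plateau_weight * min(cargo_free / _REFERENCE_CARGO_UM, 1.0)
        if clusters_active
        else 0.0
    )
    w_cond = (
        params.condensate_weight * min((cargo_free - params.csat) / params.csat, 1.0)
        if cargo_free > params.csat
        else 0.0
    )
    w_mono = 1.0 - w_tail - w_plateau - w_cond

    pdf = w_mono * _normalize(grid, _lognormal_pdf(grid, params.monomer_diameter, params.monomer_sigma_ln))
    if w_tail > 0:
        lam = params.tail_scale * (cargo_free / _REFERENCE_CARGO_UM) ** params.tail_scale_exponent
        tail = np.where(
            grid >= params.monomer_diameter,
            grid ** (-params.tail_exponent) * np.exp(-grid / lam),
            0.0,
        )
        pdf = pdf + w_tail * _normalize(grid, tail)
    if w_plateau > 0:
        lo, hi = params.plateau_range
        pdf = pdf + w_plateau * _normalize(grid, ((grid >= lo) & (grid <= hi)).astype(float))
    if w_cond > 0:
        pdf = pdf + w_cond * _normalize(
            grid, _lognormal_pdf(grid, params.condensate_mode_diameter, params.condensate_sigma_ln)
        )
    pdf = _normalize(grid, pdf)  # remove residual quadrature error
    return Landscape(
        grid,
        pdf,
        params.concentration_per_uM * cargo_free,
        cargo_free,
        {"monomer": w_mono, "tail": w_tail, "plateau": w_plateau, "condensate": w_cond},
    )


def apply_mrps_instrument(
    landscape: Landscape,
    instrument: MRPSInstrument,
    seed=0,
    condition: str = "",
) -> SizeDistribution:
    """Observe a landscape through one MRPS cartridge.

    Integrates p(d) over the cartridge bin grid (which lies inside the
    detection window — sizes outside it are never reported), scales by
    assembly concentration × sampled volume, draws Poisson counts, and
    converts back to counts/ml/nm.  ``seed`` may be an int or a numpy
    Generator for stream splitting.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = instrument.bin_edges
    expected = landscape.bin_masses(edges) * landscape.total_concentration * instrument.volume_ml
    counts = rng.poisson(expected)
    density = counts / (instrument.volume_ml * np.diff(edges))
    return SizeDistribution(edges, density.astype(float), instrument.name, condition)


def generate_replicates(
    spec: ConditionSpec,
    params: LandscapeParams,
    instrument: MRPSInstrument,
    condition: str = "",
) -> ReplicateSet:
    """Replicate MRPS observations of one condition on one cartridge.

    The landscape is generated from the *free* cargo concentration obtained
    by solving the binding equilibrium — the linked-equilibrium hypothesis
    in executable form.  Per-replicate random streams are split from the
    spec seed with a counter so replicates are independent yet reproducible.
    """
    landscape = generate_cluster_landscape(spec.cargo_free, params)
    label = condition or f"cargo={spec.cargo_total}uM,chap={spec.chaperone_total}uM"
    reps = []
    cart_tag = zlib.crc32(instrument.name.encode())
    for i in range(spec.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), cart_tag, i]))
        reps.append(apply_mrps_instrument(landscape, instrument, rng, label))
    return ReplicateSet(tuple(reps), label)


def generate_fcs_trace(
    radii_mixture: Sequence,
    geometry: InstrumentGeometry,
    cal: Calibration,
    lags: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_particles: float = 5.0,
) -> AutocorrelationTrace:
    """Synthesize an autocorrelation trace from a mixture of particle sizes.

    Each (hydrodynamic radius, weight) pair is converted to a diffusion time
    by inverting the calibration relation (τD = Rh·6πη·D_ref·τD_ref/(kB·T)),
    the weighted single-component decays are summed amplitude-weighted, and
    Gaussian noise of ``noise_sd`` is added.
    """
    radii_mixture = list(radii_mixture)
    if not radii_mixture:
        raise ValidationError("radii_mixture must be non-empty")
    weights = np.array([w for _, w in radii_mixture], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValidationError("weights must be non-negative and sum to 1")
    lags = np.asarray(lags, dtype=float)
    g = np.zeros_like(lags)
    for rh, w in radii_mixture:
        if rh <= 0:
            raise DomainError(f"radius must be > 0, got {rh}")
        taud = (
            rh * 6.0 * math.pi * cal.viscosity * cal.d_ref * cal.taud_ref
            / (BOLTZMANN_J_PER_K * cal.temperature)
        )
        g = g + w * (model_autocorrelation(lags, n_particles, taud, geometry) - 1.0)
    g = 1.0 + g
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x666373]))
        g = g + rng.normal(0.0, noise_sd, size=g.shape)
    return AutocorrelationTrace(lags, g)


@dataclass(frozen=True)
class ConditionData:
    """Dual-cartridge replicate data for one condition."""

    label: str
    cargo_free: float  # μM
    small: ReplicateSet  # C400
    large: ReplicateSet  # C2000


@dataclass(frozen=True)
class ConditionGrid:
    """Mixture conditions plus the matched cargo-only library."""

    mixtures: tuple  # ConditionData per chaperone level
    library: tuple  # ConditionData per matched cargo-only concentration
    chaperone_levels: tuple  # μM
    matched_concentrations: tuple  # μM
    seed: int


def generate_condition_grid(
    cargo_total: float,
    chaperone_levels: Sequence[float],
    kd: float,
    params: LandscapeParams,
    seed: int = 0,
    n_replicates: int = 3,
    volume_ml: float = 5.0e-3,
) -> ConditionGrid:
    """Generate the matched-comparison design: mixtures and cargo-only library.

    For each chaperone level, emits a chaperone+cargo condition and a
    cargo-only condition at the calculated free cargo concentration (the
    concentration whose distribution the linked-equilibrium model predicts
    to match).  Independent sub-seeds per condition keep the library
    measurements independent of the mixtures they are compared with.
    """
    levels = [float(k) for k in chaperone_levels]
    c400 = MRPSInstrument.c400(volume_ml=volume_ml)
    c2000 = MRPSInstrument.c2000(volume_ml=volume_ml)
    mixtures, library, matched = [], [], []
    for i, level in enumerate(levels):
        spec = ConditionSpec(cargo_total, level, kd, n_replicates, seed=_subseed(seed, 2 * i))
        free = spec.cargo_free
        matched.append(free)
        mixtures.append(
            ConditionData(
                f"{cargo_total:g}uM+{level:g}uM_chaperone",
                free,
                generate_replicates(spec, params, c400),
                generate_replicates(spec, params, c2000),
            )
        )
        lib_spec = ConditionSpec(free, 0.0, kd, n_replicates, seed=_subseed(seed, 2 * i + 1))
        library.append(
            ConditionData(
                f"{free:.3g}uM_alone",
                free,
                generate_replicates(lib_spec, params, c400),
                generate_replicates(lib_spec, params, c2000),
            )
        )
    return ConditionGrid(tuple(mixtures), tuple(library), tuple(levels), tuple(matched), int(seed))


def _subseed(master: int, counter: int) -> int:
    """Counter-based substream seed derived from a master seed, < 2**31."""
    return int(np.random.SeedSequence([int(master), int(counter)]).generate_state(1)[0] % (2**31))
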