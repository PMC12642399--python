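"""1:1 chaperone–cargo binding equilibrium and polyphasic-linkage arithmetic.

A nuclear-import receptor (the chaperone, e.g. Kapβ2) binds a prion-like
RNA-binding-protein cargo (e.g. FUS) through a single high-affinity site,
forming a 1:1 complex.  Mass action plus the two conservation laws

    cargo_total     = cargo_free + complex
    chaperone_total = chaperone_free + complex
    kd              = cargo_free * chaperone_free / complex

reduce to a quadratic in the free cargo concentration F:

    F**2 + (kd + chaperone_total - cargo_total) * F - kd * cargo_total = 0

whose unique root in [0, cargo_total] is the physically admissible state.
The free-cargo concentration is the quantity that self-association cares
about: it sets whether the system sits above or below the saturation
concentration csat, and — via polyphasic linkage — binding that prefers the
dilute phase raises the apparent csat by the ratio of binding polynomials,
csat_L = csat_0 * P_dil / P_den with P = 1 + [L]/kd for a single site.

All public concentrations are in μM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "BindingSystem",
    "EquilibriumState",
    "PhaseLinkage",
    "TitrationCurve",
    "RegimeResult",
    "solve_equilibrium",
    "free_cargo_curve",
    "csat_shift",
    "classify_regime",
    "matched_cargo_concentration",
    "stoichiometric_limit",
]


def _check_concentration(name: str, value: float, *, positive: bool = False) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    if positive:
        if value <= 0:
            raise DomainError(f"{name} must be > 0, got {value!r}")
    elif value < 0:
        raise DomainError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations and dissociation constant of a 1:1 binding pair.

    Parameters
    ----------
    cargo_total : float
        Total cargo (RBP) concentration in μM.
    chaperone_total : float
        Total chaperone (NIR) concentration in μM.
    kd : float
        Dissociation constant of the 1:1 complex in μM. Must be strictly
        positive; the stoichiometric kd → 0 limit is available separately as
        :func:`stoichiometric_limit`.
    """

    cargo_total: float
    chaperone_total: float
    kd: float

    def __post_init__(self) -> None:
        _check_concentration("cargo_total", self.cargo_total)
        _check_concentration("chaperone_total", self.chaperone_total)
        _check_concentration("kd", self.kd, positive=True)


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations (μM) of free species and complex."""

    cargo_free: float
    chaperone_free: float
    complex: float

    @property
    def bound_fraction(self) -> float:
        """Fraction of total cargo sequestered in the complex."""
        total = self.cargo_free + self.complex
        return self.complex / total if total > 0 else 0.0


@dataclass(frozen=True)
class PhaseLinkage:
    """Saturation concentration and dilute/dense-phase ligand affinities.

    ``kd_dense = inf`` means the ligand does not bind the macromolecule in
    the dense phase (empty dense-phase binding polynomial), which is the
    preferential-dilute-binding case that raises csat.
    """

    csat0: float
    kd_dilute: float
    kd_dense: float = math.inf

    def __post_init__(self) -> None:
        _check_concentration("csat0", self.csat0, positive=True)
        _check_concentration("kd_dilute", self.kd_dilute, positive=True)
        if not (self.kd_dense > 0):  # inf allowed
            raise DomainError(f"kd_dense must be > 0 or inf, got {self.kd_dense!r}")


@dataclass(frozen=True)
class TitrationCurve:
    """Free-cargo concentration as a function of total chaperone."""

    chaperone_levels: tuple
    cargo_free_values: tuple
    kd: float
    cargo_total: float


@dataclass(frozen=True)
class RegimeResult:
    """Assembly-regime call with the supersaturation ratio that produced it."""

    regime: str  # "subsaturated" | "saturated"
    ratio: float  # cargo_free / csat

    @property
    def saturated(self) -> bool:
        return self.regime == "saturated"


def solve_equilibrium(system: BindingSystem) -> EquilibriumState:
    """Solve the 1:1 binding equilibrium for the free/bound species.

    Uses the cancellation-safe branch of the positive quadratic root with
    b = kd + K − C (C = cargo_total, K = chaperone_total):

        F = (−b + sqrt(b² + 4 kd C)) / 2          for b <= 0
        F = 2 kd C / (b + sqrt(b² + 4 kd C))      for b > 0

    Each branch adds quantities of one sign only, so precision is kept both
    when b ≫ kd·C (excess chaperone) and when b < 0 (excess cargo), where
    the respective naive forms cancel catastrophically.

    Returns
    -------
    EquilibriumState
        With ``0 <= cargo_free <= cargo_total`` and both conservation laws
        satisfied to machine precision.
    """
    c_tot = system.cargo_total
    k_tot = system.chaperone_total
    kd = system.kd
    if c_tot == 0.0 or k_tot == 0.0:
        return EquilibriumState(c_tot, k_tot, 0.0)
    b = kd + k_tot - c_tot
    disc = math.sqrt(b * b + 4.0 * kd * c_tot)
    cargo_free = 0.5 * (disc - b) if b <= 0 else 2.0 * kd * c_tot / (b + disc)
    complex_ = min(max(c_tot - cargo_free, 0.0), c_tot, k_tot)
    return EquilibriumState(c_tot - complex_, k_tot - complex_, complex_)


def free_cargo_curve(
    cargo_total: float,
    chaperone_levels: Sequence[float],
    kd: float,
) -> TitrationCurve:
    """Free cargo concentration over an ascending titration of chaperone.

    Element-wise application of :func:`solve_equilibrium`; the output is
    monotone non-increasing in the chaperone level.
    """
    levels = np.asarray(chaperone_levels, dtype=float)
    if levels.ndim != 1 or levels.size == 0:
        raise ValidationError("chaperone_levels must be a non-empty 1-D sequence")
    if np.any(np.diff(levels) < 0):
        raise ValidationError("chaperone_levels must be sorted ascending")
    values = tuple(
        solve_equilibrium(BindingSystem(cargo_total, float(k), kd)).cargo_free
        for k in levels
    )
    return TitrationCurve(tuple(levels.tolist()), values, float(kd), float(cargo_total))


def csat_shift(linkage: PhaseLinkage, ligand_free: float) -> float:
    """Apparent saturation concentration in the presence of free ligand.

    Polyphasic linkage for a single binding site:

        csat_L = csat_0 * (1 + L/kd_dilute) / (1 + L/kd_dense)

    Equal affinities in the two phases leave csat unchanged; preferential
    dilute-phase binding (kd_dilute < kd_dense) raises it.
    """
    ligand_free = _check_concentration("ligand_free", ligand_free)
    p_dil = 1.0 + ligand_free / linkage.kd_dilute
    p_den = 1.0 if math.isinf(linkage.kd_dense) else 1.0 + ligand_free / linkage.kd_dense
    return linkage.csat0 * p_dil / p_den


def classify_regime(cargo_free: float, csat: float) -> RegimeResult:
    """Classify whether condensates can form at a given free concentration.

    ``saturated`` requires strict exceedance of csat; exact equality is
    called ``subsaturated`` (condensation requires supersaturation, and the
    conservative call avoids false condensation claims at the boundary).
    """
    cargo_free = _check_concentration("cargo_free", cargo_free)
    csat = _check_concentration("csat", csat, positive=True)
    ratio = cargo_free / csat
    return RegimeResult("saturated" if cargo_free > csat else "subsaturated", ratio)


def matched_cargo_concentration(system: BindingSystem) -> float:
    """Cargo-only concentration whose assemblies should match the mixture's.

    Under the linked-equilibrium hypothesis the assembly landscape depends
    only on the free cargo concentration, so a chaperone-containing sample is
    predicted to match a cargo-only sample prepared at
    ``solve_equilibrium(system).cargo_free``.
    """
    return solve_equilibrium(system).cargo_free


def stoichiometric_limit(cargo_total: float, chaperone_total: float) -> float:
    """Free cargo in the infinitely tight binding (kd → 0) limit.

    Every chaperone molecule sequesters one cargo until one species runs
    out: ``max(cargo_total - chaperone_total, 0)``.
    """
    cargo_total = _check_concentration("cargo_total", cargo_total)
    chaperone_total = _check_concentration("chaperone_total", chaperone_total)
    return max(cargo_total - chaperone_total, 0.0)
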