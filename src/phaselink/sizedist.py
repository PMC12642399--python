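"""Binned particle-size distributions: ingest, rebin, merge, and compare.

Microfluidic resistive pulse sensing (MRPS) reports particle number density
(counts/ml/nm) on a grid of diameter bins.  Two cartridges with different
constriction widths cover complementary windows — C-400: 70–400 nm,
C-2000: 250–2000 nm — and each condition is measured in replicate on each
cartridge.  This module provides

* table ingest (diameter column plus one density column per replicate),
* count-conserving rebinning onto arbitrary grids,
* a bootstrap merge of the two cartridge windows into one 70–2000 nm
  distribution with a per-bin spread estimate,
* conversion to zero-floored probability mass functions, and
* the Kullback–Leibler divergence KLD(P‖Q) = Σ P ln(P/Q) used to quantify
  how a chaperone remodels the assembly size distribution, plus a local
  log-slope "flatness" metric for the mesoscale plateau regime
  (~400–1100 nm) where assembly sizes occur with comparable probability.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, ValidationError

__all__ = [
    "C400_WINDOW",
    "C2000_WINDOW",
    "FULL_WINDOW",
    "SizeDistribution",
    "ReplicateSet",
    "MergedDistribution",
    "ProbabilityMass",
    "ComparisonMatrix",
    "FlatnessResult",
    "read_distribution_table",
    "edges_from_centers",
    "rebin_to_common_grid",
    "merge_cartridges",
    "to_probability",
    "kl_divergence",
    "kl_profile",
    "flatness_metric",
]

C400_WINDOW = (70.0, 400.0)
C2000_WINDOW = (250.0, 2000.0)
FULL_WINDOW = (70.0, 2000.0)

_ZERO_FLOOR_DEFAULT = 1e-5  # counts/ml/nm substituted for exact zeros


@dataclass(frozen=True)
class SizeDistribution:
    """One binned size distribution: density (counts/ml/nm) per diameter bin."""

    bin_edges: np.ndarray  # nm, length n+1, strictly increasing
    density: np.ndarray  # counts/ml/nm, length n, >= 0
    cartridge: str = "synthetic"  # C400 | C2000 | merged | synthetic
    condition: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "density", dens)
        if edges.ndim != 1 or dens.ndim != 1 or edges.size != dens.size + 1:
            raise ValidationError(
                f"bin_edges (len {edges.size}) must be one longer than density (len {dens.size})"
            )
        if dens.size < 1:
            raise ValidationError("need at least one bin")
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin_edges must be strictly increasing")
        if np.any(~np.isfinite(dens)) or np.any(dens < 0):
            raise ValidationError("density must be finite and non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def counts(self) -> np.ndarray:
        """Per-bin particle concentration, counts/ml (density × width)."""
        return self.density * self.bin_widths

    def total_count(self) -> float:
        """Total particle concentration over the grid, counts/ml."""
        return float(self.counts.sum())


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate measurements of one condition on one cartridge, one grid."""

    replicates: tuple
    condition: str = ""

    def __post_init__(self) -> None:
        reps = tuple(self.replicates)
        object.__setattr__(self, "replicates", reps)
        if len(reps) < 1:
            raise ValidationError("need at least one replicate")
        edges0 = reps[0].bin_edges
        cart0 = reps[0].cartridge
        for r in reps[1:]:
            if r.bin_edges.shape != edges0.shape or not np.array_equal(r.bin_edges, edges0):
                raise ValidationError("replicates must share one bin grid")
            if r.cartridge != cart0:
                raise ValidationError("replicates must share one cartridge label")

    @property
    def bin_edges(self) -> np.ndarray:
        return self.replicates[0].bin_edges

    @property
    def cartridge(self) -> str:
        return self.replicates[0].cartridge

    @property
    def density_matrix(self) -> np.ndarray:
        """(n_replicates, n_bins) density array."""
        return np.stack([r.density for r in self.replicates])

    def __len__(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class MergedDistribution:
    """Bootstrap-merged full-range distribution with per-bin spread."""

    bin_edges: np.ndarray
    mean: np.ndarray
    spread: np.ndarray
    n_boot: int
    seed: int
    condition: str = ""

    def as_size_distribution(self) -> SizeDistribution:
        return SizeDistribution(self.bin_edges, self.mean, "merged", self.condition)

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame(
            {
                "diameter_nm": centers,
                "mean_counts_per_ml_per_nm": self.mean,
                "spread": self.spread,
            }
        )


@dataclass(frozen=True)
class ProbabilityMass:
    """Zero-floored, normalized per-bin probability mass on a diameter grid."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", p)
        if edges.size != p.size + 1:
            raise ValidationError("bin_edges must be one longer than probabilities")
        if np.any(p <= 0):
            raise ValidationError("probabilities must be strictly positive (zero-floored)")
        if abs(p.sum() - 1.0) > 1e-12 * max(1.0, p.size):
            raise ValidationError(f"probabilities must sum to 1, got {p.sum()!r}")


@dataclass(frozen=True)
class ComparisonMatrix:
    """KL-divergence values (nats) of query conditions against references."""

    row_labels: tuple
    col_labels: tuple
    values: np.ndarray  # shape (n_rows, n_cols), >= 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass(frozen=True)
class FlatnessResult:
    """Least-squares log-slope of the size distribution inside a window."""

    slope_per_nm: float  # signed slope of ln p(d) vs d
    window: tuple
    is_flat: bool
    threshold: float


# ---------------------------------------------------------------------------
# ingest


def edges_from_centers(centers: np.ndarray) -> np.ndarray:
    """Reconstruct contiguous bin edges from bin centers.

    Interior edges at midpoints of consecutive centers; end bins symmetric
    about their centers.  This matches instrument exports, which list bin
    centers only.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 1:
        # degenerate single bin: unit width centred on the lone centre
        return np.array([centers[0] - 0.5, centers[0] + 0.5])
    mids = 0.5 * (centers[:-1] + centers[1:])
    first = 2 * centers[0] - mids[0]
    last = 2 * centers[-1] - mids[-1]
    return np.concatenate([[first], mids, [last]])


def read_distribution_table(
    path, *, cartridge: str = "synthetic", condition: str = ""
) -> ReplicateSet:
    """Read a delimited distribution table into a :class:`ReplicateSet`.

    Expected layout: first column diameter (nm, bin centers), each further
    column one replicate's density in counts/ml/nm.  Comma or tab delimiters
    are auto-detected.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
        name = str(path)
    else:  # file-like
        text = path.read()
        name = getattr(path, "name", "<stream>")
    if not text.strip():
        raise ParseError(f"{name}: empty file")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep)
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise ParseError(f"{name}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{name}: need a diameter column and at least one density column")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # +1 header, +1 1-based
        raise ParseError(f"{name}: missing/ragged value at line {row}")
    diam = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(diam) <= 0):
        bad = int(np.argmax(np.diff(diam) <= 0)) + 3
        raise ParseError(f"{name}: diameters not strictly increasing at line {bad}")
    edges = edges_from_centers(diam)
    reps = []
    for col in df.columns[1:]:
        dens = df[col].to_numpy(dtype=float)
        if np.any(dens < 0):
            row = int(np.argmax(dens < 0)) + 2
            raise ParseError(f"{name}: negative density in column {col!r} at line {row}")
        reps.append(SizeDistribution(edges, dens, cartridge, condition))
    return ReplicateSet(tuple(reps), condition)


def write_distribution_table(rs: ReplicateSet, path) -> None:
    """Write a ReplicateSet back to the delimited layout read_distribution_table expects."""
    centers = 0.5 * (rs.bin_edges[:-1] + rs.bin_edges[1:])
    data = {"diameter_nm": centers}
    for i, rep in enumerate(rs.replicates, start=1):
        data[f"rep{i}"] = rep.density
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rebinning


def overlap_matrix(src_edges: np.ndarray, tgt_edges: np.ndarray) -> np.ndarray:
    """Fractional-overlap matrix W with W[i, j] = |src_i ∩ tgt_j| / |src_i|.

    Applying W.T to per-bin counts redistributes particle content
    proportionally to overlap length (uniform-within-bin assumption).
    """
    src_lo, src_hi = src_edges[:-1], src_edges[1:]
    tgt_lo, tgt_hi = tgt_edges[:-1], tgt_edges[1:]
    lo = np.maximum(src_lo[:, None], tgt_lo[None, :])
    hi = np.minimum(src_hi[:, None], tgt_hi[None, :])
    overlap = np.clip(hi - lo, 0.0, None)
    return overlap / (src_hi - src_lo)[:, None]


def rebin_to_common_grid(dist: SizeDistribution, target_edges: np.ndarray) -> SizeDistribution:
    """Rebin a distribution onto a new grid, conserving particle counts.

    Per-bin particle content (density × width) is redistributed to target
    bins proportionally to overlap length; the total count over the
    intersection of supports is conserved.
    """
    target_edges = np.asarray(target_edges, dtype=float)
    if np.any(np.diff(target_edges) <= 0):
        raise ValidationError("target_edges must be strictly increasing")
    if target_edges[-1] <= dist.bin_edges[0] or target_edges[0] >= dist.bin_edges[-1]:
        raise DomainError("target grid does not overlap the source support")
    w = overlap_matrix(dist.bin_edges, target_edges)
    tgt_counts = dist.counts @ w
    tgt_density = tgt_counts / np.diff(target_edges)
    return SizeDistribution(target_edges, tgt_density, dist.cartridge, dist.condition)


# ---------------------------------------------------------------------------
# dual-cartridge bootstrap merge


def _window_mean_density(edges: np.ndarray, density: np.ndarray, lo: float, hi: float) -> float:
    """Mean density over [lo, hi]: overlapped count divided by covered length."""
    seg_lo = np.maximum(edges[:-1], lo)
    seg_hi = np.minimum(edges[1:], hi)
    seg = np.clip(seg_hi - seg_lo, 0.0, None)
    covered = seg.sum()
    if covered <= 0:
        return math.nan
    return float((density * seg).sum() / covered)


def merge_cartridges(
    small: ReplicateSet,
    large: ReplicateSet,
    n_boot: int = 1000,
    subsample_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    condition: str | None = None,
) -> MergedDistribution:
    """Bootstrap-merge C-400 and C-2000 replicate sets into one 70–2000 nm distribution.

    Each bootstrap draw resamples ``ceil(subsample_fraction * n_replicates)``
    replicates (with replacement) per cartridge and averages their densities.
    Because the two cartridges carry independent concentration calibrations,
    the C-2000 draw is rescaled by the ratio of mean densities over the
    250–400 nm overlap before the two windows are joined at the C-400 bin
    edge nearest 325 nm (the overlap midpoint).  The merged mean and per-bin
    standard deviation ("spread") are taken over the accumulated draws.
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    if not (0 < subsample_fraction <= 1):
        raise ValidationError(f"subsample_fraction must be in (0, 1], got {subsample_fraction}")
    se, le = small.bin_edges, large.bin_edges
    # windows are nominal; allow 1% slack for grids reconstructed from
    # bin-center tables, whose end edges fall marginally outside
    if se[0] < C400_WINDOW[0] * 0.99 or se[-1] > C400_WINDOW[1] * 1.01:
        raise DomainError(f"small-cartridge grid must lie within {C400_WINDOW} nm")
    if le[0] < C2000_WINDOW[0] * 0.99 or le[-1] > C2000_WINDOW[1] * 1.01:
        raise DomainError(f"large-cartridge grid must lie within {C2000_WINDOW} nm")
    ov_lo, ov_hi = C2000_WINDOW[0], C400_WINDOW[1]
    if se[-1] <= ov_lo or le[0] >= ov_hi:
        raise DomainError("cartridge grids do not both cover the 250–400 nm overlap")

    # split at the C-400 edge nearest the overlap midpoint, join native grids
    split = float(se[np.argmin(np.abs(se - 0.5 * (ov_lo + ov_hi)))])
    lower_edges = se[se <= split + 1e-12]
    upper_edges = np.concatenate([[split], le[le > split + 1e-12]])
    merged_edges = np.concatenate([lower_edges, upper_edges[1:]])
    n_lower = lower_edges.size - 1
    w_upper = overlap_matrix(le, upper_edges)
    upper_widths = np.diff(upper_edges)

    dm_small = small.density_matrix
    dm_large = large.density_matrix
    k_small = math.ceil(subsample_fraction * dm_small.shape[0])
    k_large = math.ceil(subsample_fraction * dm_large.shape[0])

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6D657267]))
    draws = np.empty((n_boot, merged_edges.size - 1))
    for b in range(n_boot):
        ds = dm_small[rng.integers(0, dm_small.shape[0], size=k_small)].mean(axis=0)
        dl = dm_large[rng.integers(0, dm_large.shape[0], size=k_large)].mean(axis=0)
        ms = _window_mean_density(se, ds, ov_lo, ov_hi)
        ml = _window_mean_density(le, dl, ov_lo, ov_hi)
        scale = ms / ml if ml > 0 else 1.0
        upper_counts = (dl * np.diff(le) * scale) @ w_upper
        draws[b, :n_lower] = ds[:n_lower]
        draws[b, n_lower:] = upper_counts / upper_widths
    cond = condition if condition is not None else (small.condition or large.condition)
    return MergedDistribution(
        merged_edges,
        draws.mean(axis=0),
        draws.std(axis=0, ddof=0),
        n_boot,
        int(seed),
        cond,
    )


# ---------------------------------------------------------------------------
# probability conversion and KL comparison


def to_probability(dist: SizeDistribution, zero_floor: float = _ZERO_FLOOR_DEFAULT) -> ProbabilityMass:
    """Convert a size distribution to a zero-floored probability mass function.

    Zeros in the density are replaced by ``zero_floor`` (counts/ml/nm,
    applied *before* normalization), then per-bin mass = density × width is
    normalized to sum to one.  The floor keeps the KL divergence finite on
    bins one distribution never populated.
    """
    if zero_floor < 0:
        raise DomainError(f"zero_floor must be >= 0, got {zero_floor}")
    dens = dist.density.copy()
    dens[dens == 0.0] = zero_floor
    mass = dens * dist.bin_widths
    total = mass.sum()
    if total <= 0:
        raise DomainError("all-zero distribution with zero_floor = 0 cannot be normalized")
    return ProbabilityMass(dist.bin_edges, mass / total)


def kl_divergence(p: ProbabilityMass, q: ProbabilityMass) -> float:
    """Kullback–Leibler divergence KLD(P‖Q) = Σ P(d) ln(P(d)/Q(d)), in nats.

    Asymmetric; non-negative by Gibbs' inequality; zero iff P = Q.  Both
    arguments must live on the same bin grid (rebin first otherwise).
    """
    if p.bin_edges.shape != q.bin_edges.shape or not np.allclose(
        p.bin_edges, q.bin_edges, rtol=0, atol=1e-9
    ):
        raise DomainError("P and Q must share one bin grid; rebin before comparing")
    return float(np.sum(p.probabilities * np.log(p.probabilities / q.probabilities)))


def kl_profile(reference: ProbabilityMass, queries: Sequence[ProbabilityMass]) -> list:
    """KLD(query ‖ reference) for each query, in input order.

    The reference is conventionally the untreated (no-chaperone) condition,
    so the profile reads as "how far has the chaperone-treated distribution
    moved from the untreated one".
    """
    return [kl_divergence(q, reference) for q in queries]


def flatness_metric(
    dist: SizeDistribution,
    window: tuple = (400.0, 1100.0),
    threshold: float = 1e-3,
    zero_floor: float = _ZERO_FLOOR_DEFAULT,
) -> FlatnessResult:
    """Absolute log-slope of the size distribution inside a diameter window.

    The probability of a cluster of diameter d reflects the free energy of
    forming it (ΔG(d) ∝ -ln p(d)), so a near-zero slope of ln p(d) vs d over
    ~400–1100 nm is the signature of the flattened mesoscale regime where
    assemblies of those sizes occur with comparable probability.  Fits a
    least-squares line to ln p(d) at the bin centers inside ``window``;
    ``is_flat`` is true when |slope| < ``threshold`` (per nm).
    """
    lo, hi = window
    if not (lo < hi):
        raise ValidationError("window must be an increasing (lo, hi) interval")
    centers = dist.bin_centers
    mask = (centers >= lo) & (centers <= hi)
    if mask.sum() < 3:
        raise DomainError(
            f"need >= 3 bins inside window [{lo}, {hi}] nm, found {int(mask.sum())}"
        )
    pm = to_probability(dist, zero_floor=zero_floor)
    pdens = pm.probabilities / dist.bin_widths  # probability density, 1/nm
    slope = float(np.polyfit(centers[mask], np.log(pdens[mask]), 1)[0])
    return FlatnessResult(slope, (float(lo), float(hi)), abs(slope) < threshold, threshold)
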