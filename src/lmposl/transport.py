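"""Desk-scale 1-D proton transport surrogate: depth-dose and energy spectra.

A full Monte-Carlo condensed-history simulation is not needed by the
efficiency analysis: it only consumes (i) relative depth-dose curves and
(ii) per-depth kinetic-energy spectra summarised as median / IQR.  Both are
produced here with a continuous-slowing-down (CSDA) model built on the
Bragg-Kleeman range-energy relation

    R(E) = alpha * E**p            (R in cm, E in MeV)

with Gaussian range straggling sigma_R = k * R**m.  Per proton, the initial
energy is drawn from a truncated normal (mean 58.4 MeV, FWHM 1.4 MeV, hard
cutoff 58.55 MeV by default), the actual range from the straggling model,
and the residual energy at depth z follows from inverting the range-energy
relation at the residual range R - z.  Dose per 0.05 mm slab is scored as
the energy lost in the slab (stopped protons deposit their full residual
energy in their final slab), which makes the scoring exactly
energy-conserving by construction.

No nuclear interactions, lateral transport, Coulomb scattering or secondary
particles are modelled; a spread-out Bragg peak (SOBP) is composed by
range-shifting the pristine beam through PMMA degraders (WET 1.15) and
solving non-negative least-squares weights that flatten a chosen plateau.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: slab thickness of the scoring grid (mm water)
SLAB_MM = 0.05
#: FWHM of a normal distribution in units of its sigma
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
#: water-equivalent thickness factor of the PMMA degrader material
PMMA_WET = 1.15


@dataclasses.dataclass(frozen=True)
class BeamModel:
    """Parallel cylindrical proton beam entering the water phantom.

    Defaults describe a 58.8 MeV-range ocular-therapy beam: Gaussian energy
    spectrum of mean 58.4 MeV and FWHM 1.4 MeV with a hard cutoff at
    58.55 MeV (the accelerator cannot exceed it).
    """

    mean_energy: float = 58.4       # MeV
    fwhm_energy: float = 1.4        # MeV
    max_energy_cutoff: float = 58.55  # MeV
    n_protons: int = 1_000_000
    radius_cm: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_energy <= 0:
            raise ValueError("mean_energy must be positive")
        if self.fwhm_energy < 0:
            raise ValueError("fwhm_energy must be non-negative")
        if self.n_protons < 1:
            raise ValueError("n_protons must be at least 1")

    @property
    def sigma_energy(self) -> float:
        return self.fwhm_energy / FWHM_TO_SIGMA


@dataclasses.dataclass(frozen=True)
class RangeEnergyRelation:
    """Bragg-Kleeman range-energy relation with Gaussian range straggling.

    ``alpha`` (cm MeV^-p) and ``p`` are the standard literature values for
    protons in water; ``straggling_coeff`` k (cm^(1-m)) and
    ``straggling_exp`` m parameterise sigma_R = k * R**m (R in cm).
    """

    alpha: float = 2.2e-3
    p: float = 1.77
    straggling_coeff: float = 0.012
    straggling_exp: float = 0.935

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 1.0 < self.p < 2.0:
            raise ValueError("exponent p must lie in (1, 2)")
        if self.straggling_coeff < 0:
            raise ValueError("straggling coefficient must be non-negative")

    def calibrated(self, energy_mev: float, range_mm: float) -> "RangeEnergyRelation":
        """Rescale ``alpha`` so that R(``energy_mev``) equals ``range_mm``."""
        alpha = (range_mm / 10.0) / energy_mev**self.p
        return dataclasses.replace(self, alpha=alpha)


DEFAULT_RELATION = RangeEnergyRelation()


def range_from_energy(energy_mev, rel: RangeEnergyRelation = DEFAULT_RELATION):
    """CSDA range in mm of water for a proton of the given kinetic energy."""
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e < 0):
        raise ValueError("kinetic energy must be non-negative")
    r = 10.0 * rel.alpha * e**rel.p
    return float(r) if np.isscalar(energy_mev) else r


def energy_from_residual_range(range_mm, rel: RangeEnergyRelation = DEFAULT_RELATION):
    """Exact inverse of :func:`range_from_energy` (negative input clips to 0)."""
    r = np.maximum(np.asarray(range_mm, dtype=float), 0.0)
    e = (r / (10.0 * rel.alpha)) ** (1.0 / rel.p)
    return float(e) if np.isscalar(range_mm) else e


def stopping_power(energy_mev, rel: RangeEnergyRelation = DEFAULT_RELATION):
    """dE/dx (MeV/cm) implied by the range-energy relation, S = E^(1-p)/(alpha p)."""
    e = np.asarray(energy_mev, dtype=float)
    with np.errstate(divide="ignore"):
        s = e ** (1.0 - rel.p) / (rel.alpha * rel.p)
    return float(s) if np.isscalar(energy_mev) else s


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DepthDose:
    """Relative dose on an ascending depth grid (slab centres, mm water)."""

    depth_mm: np.ndarray
    dose: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depth_mm.shape != self.dose.shape:
            raise ValueError("depth and dose grids differ in length")
        if np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        if np.any(self.dose < -1e-12):
            raise ValueError("dose values must be non-negative")
        self.dose = np.maximum(self.dose, 0.0)

    def normalized(self, convention: str = "entrance",
                   entrance_window_mm: float = 5.0) -> "DepthDose":
        """Return a copy normalised to entrance mean = 1 or to max = 1."""
        if convention == "entrance":
            window = self.depth_mm <= entrance_window_mm
            if not window.any():
                raise ValueError("no slabs inside the entrance window")
            scale = float(self.dose[window].mean())
        elif convention == "max":
            scale = float(self.dose.max())
        else:
            raise ValueError(f"unknown normalization convention {convention!r}")
        if scale <= 0:
            raise ValueError("cannot normalise an all-zero dose curve")
        return DepthDose(self.depth_mm, self.dose / scale, normalization=convention)

    def at(self, depths_mm) -> np.ndarray:
        """Linear interpolation of the dose at the given depths."""
        return np.interp(np.asarray(depths_mm, dtype=float), self.depth_mm, self.dose,
                         left=0.0, right=0.0)

    def distal_depth_at(self, fraction: float = 0.9) -> float:
        """Depth (mm) where the dose falls to ``fraction`` of its maximum, distal side."""
        peak = int(np.argmax(self.dose))
        level = fraction * self.dose[peak]
        distal = self.dose[peak:]
        below = np.nonzero(distal < level)[0]
        if below.size == 0:
            return float(self.depth_mm[-1])
        j = peak + below[0]
        # linear interpolation between the last slab above and first below
        x0, x1 = self.depth_mm[j - 1], self.depth_mm[j]
        y0, y1 = self.dose[j - 1], self.dose[j]
        if y0 == y1:
            return float(x1)
        return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth_mm": self.depth_mm, "dose_rel": self.dose})


def _weighted_quantile(values: np.ndarray, q, weights: np.ndarray) -> np.ndarray:
    """Weighted quantile with linear interpolation of the midpoint CDF."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    if total <= 0:
        raise ValueError("weights sum to zero")
    cdf = (cw - 0.5 * w) / total
    return np.interp(np.asarray(q, dtype=float), cdf, v)


def _histogram_quantile(edges: np.ndarray, counts: np.ndarray, q) -> np.ndarray:
    """Quantile from a histogram with linear within-bin interpolation."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    cdf = np.concatenate([[0.0], np.cumsum(c)]) / total
    return np.interp(np.asarray(q, dtype=float), cdf, edges)


@dataclasses.dataclass
class EnergySpectrumAtDepth:
    """Kinetic-energy spectrum of surviving protons at one scoring depth.

    ``counts`` are (possibly weighted) proton counts over 600 equal bins on
    0-60 MeV.  Where the unbinned ``energies`` are available, median and
    IQR come from them (type-7 quantiles, or the midpoint-CDF rule when the
    sample is weighted); otherwise they come from the histogram with linear
    within-bin interpolation.
    """

    depth_mm: float
    bin_edges: np.ndarray
    counts: np.ndarray
    median: float
    iqr: float
    energies: np.ndarray | None = None
    weights: np.ndarray | None = None

    N_BINS = 600
    E_MAX = 60.0

    @classmethod
    def from_energies(cls, depth_mm: float, energies, weights=None,
                      n_bins: int = N_BINS, e_max: float = E_MAX,
                      keep_energies: bool = True) -> "EnergySpectrumAtDepth":
        e = np.asarray(energies, dtype=float)
        edges = np.linspace(0.0, e_max, n_bins + 1)
        w = None if weights is None else np.asarray(weights, dtype=float)
        counts, _ = np.histogram(e, bins=edges, weights=w)
        if e.size == 0 or (w is not None and w.sum() <= 0):
            median = iqr = float("nan")
        elif w is None:
            q25, median, q75 = np.percentile(e, [25.0, 50.0, 75.0])
            iqr = float(q75 - q25)
        else:
            q25, median, q75 = _weighted_quantile(e, [0.25, 0.50, 0.75], w)
            iqr = float(q75 - q25)
        return cls(depth_mm=float(depth_mm), bin_edges=edges, counts=counts,
                   median=float(median), iqr=float(iqr),
                   energies=e if keep_energies else None,
                   weights=w if keep_energies else None)

    @property
    def is_empty(self) -> bool:
        return not float(np.sum(self.counts)) > 0


def spectrum_summary(spec: EnergySpectrumAtDepth) -> tuple[float, float]:
    """(median, IQR) in MeV of a per-depth spectrum.

    Raises on an empty spectrum (no surviving protons: the depth lies
    beyond the beam range).
    """
    if spec.is_empty:
        raise ValueError(f"empty spectrum at {spec.depth_mm} mm: depth beyond proton range")
    if spec.energies is not None and spec.energies.size:
        if spec.weights is None:
            q25, med, q75 = np.percentile(spec.energies, [25.0, 50.0, 75.0])
        else:
            q25, med, q75 = _weighted_quantile(spec.energies, [0.25, 0.5, 0.75],
                                               spec.weights)
    else:
        q25, med, q75 = _histogram_quantile(spec.bin_edges, spec.counts,
                                            [0.25, 0.5, 0.75])
    return float(med), float(q75 - q25)


# ---------------------------------------------------------------------------
# pristine-beam simulation
# ---------------------------------------------------------------------------

def make_grid(max_depth_mm: float, slab_mm: float = SLAB_MM) -> np.ndarray:
    """Slab-edge grid from 0 to at least ``max_depth_mm`` (step ``slab_mm``)."""
    n = int(math.ceil(max_depth_mm / slab_mm))
    return np.arange(n + 1) * slab_mm


def default_grid(beam: BeamModel, rel: RangeEnergyRelation = DEFAULT_RELATION) -> np.ndarray:
    """Default scoring grid: ~10 % beyond the nominal range plus margin."""
    e_max = beam.max_energy_cutoff if beam.fwhm_energy > 0 else beam.mean_energy
    return make_grid(1.1 * range_from_energy(e_max, rel) + 2.0)


def _sample_initial_energies(beam: BeamModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if beam.sigma_energy == 0:
        return np.full(n, min(beam.mean_energy, beam.max_energy_cutoff))
    b = (beam.max_energy_cutoff - beam.mean_energy) / beam.sigma_energy
    return stats.truncnorm.rvs(-np.inf, b, loc=beam.mean_energy,
                               scale=beam.sigma_energy, size=n, random_state=rng)


def simulate_pristine(
    beam: BeamModel,
    rel: RangeEnergyRelation = DEFAULT_RELATION,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    score_depths: Sequence[float] = (),
    n_protons: int | None = None,
    range_offset_mm: float = 0.0,
    normalization: str = "entrance",
    keep_energies: bool = True,
) -> tuple[DepthDose, list[EnergySpectrumAtDepth]]:
    """Simulate a pristine Bragg curve and per-depth energy spectra.

    ``range_offset_mm`` shifts every sampled range upstream by a fixed
    water-equivalent degrader thickness (protons stopping inside the
    degrader are lost); this is how SOBP components are produced.
    ``normalization`` is "entrance", "max" or "raw" (MeV per slab).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n_protons if n_protons is not None else beam.n_protons)
    edges = default_grid(beam, rel) if grid is None else np.asarray(grid, dtype=float)

    e0 = _sample_initial_energies(beam, n, rng)
    r0 = range_from_energy(e0, rel)
    if rel.straggling_coeff > 0:
        sigma = 10.0 * rel.straggling_coeff * (r0 / 10.0) ** rel.straggling_exp
        ranges = r0 + sigma * rng.standard_normal(n)
    else:
        ranges = r0
    ranges = ranges - range_offset_mm
    ranges = ranges[ranges > 0]
    ranges.sort()
    if ranges.size and ranges[-1] > edges[-1]:
        raise ValueError(
            f"depth grid ends at {edges[-1]:.2f} mm, shorter than the deepest "
            f"sampled range {ranges[-1]:.2f} mm"
        )

    # S(z) = total residual energy of protons still alive at edge z;
    # the energy deposited in slab j is S(z_j) - S(z_j+1).
    surviving_energy = np.zeros(edges.size)
    for j, z in enumerate(edges):
        start = np.searchsorted(ranges, z, side="right")
        if start >= ranges.size:
            break
        surviving_energy[j] = energy_from_residual_range(ranges[start:] - z, rel).sum()
    dose = -np.diff(surviving_energy)
    dd = DepthDose((edges[:-1] + edges[1:]) / 2.0, dose, normalization="raw")
    if normalization != "raw":
        dd = dd.normalized(normalization)

    spectra = []
    for z in score_depths:
        start = np.searchsorted(ranges, z, side="right")
        energies = energy_from_residual_range(ranges[start:] - z, rel)
        spectra.append(EnergySpectrumAtDepth.from_energies(
            z, energies, keep_energies=keep_energies))
    return dd, spectra


# ---------------------------------------------------------------------------
# SOBP composition
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SobpSpec:
    """Weighted PMMA-degraded components forming a spread-out Bragg peak."""

    components: list[tuple[float, float]]  # (pmma_thickness_mm, weight)
    plateau: tuple[float, float]           # (start, end) mm water

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("SOBP needs at least one component")
        if any(w < 0 for _, w in self.components):
            raise ValueError("weights must be non-negative")
        if not any(t == 0 for t, _ in self.components):
            raise ValueError("at least one component must have zero degrader thickness")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    @property
    def pmma_thicknesses(self) -> np.ndarray:
        return np.array([t for t, _ in self.components])


def solve_sobp_weights(
    components: Sequence[DepthDose],
    pmma_thicknesses_mm: Sequence[float],
    plateau: tuple[float, float],
) -> SobpSpec:
    """Non-negative least-squares weights flattening the plateau.

    ``components`` are raw (un-normalised) pristine curves on a common grid,
    already range-shifted by their degraders.  The returned weights are
    scaled so the composite's plateau mean is exactly 1.
    """
    if len(components) != len(pmma_thicknesses_mm):
        raise ValueError("one degrader thickness per component required")
    grid = components[0].depth_mm
    for dd in components[1:]:
        if dd.depth_mm.shape != grid.shape or not np.allclose(dd.depth_mm, grid):
            raise ValueError("components must share a common depth grid")
    lo, hi = plateau
    window = (grid >= lo) & (grid <= hi)
    if not window.any():
        raise ValueError("plateau window contains no grid slabs")
    a = np.column_stack([dd.dose[window] for dd in components])
    if np.any(a.sum(axis=1) <= 0):
        raise ValueError("plateau infeasible: it extends beyond the deepest component range")
    if len(components) == 1:
        weights = np.array([1.0])
    else:
        weights, _ = optimize.nnls(a, np.ones(int(window.sum())))
    composite = a @ weights
    mean = float(composite.mean())
    if mean <= 0:
        raise ValueError("solver produced an all-zero composite on the plateau")
    weights = weights / mean
    return SobpSpec(
        components=[(float(t), float(w)) for t, w in zip(pmma_thicknesses_mm, weights)],
        plateau=(float(lo), float(hi)),
    )


def compose_sobp(
    spec: SobpSpec,
    components: Sequence[tuple[DepthDose, Sequence[EnergySpectrumAtDepth]]],
) -> tuple[DepthDose, list[EnergySpectrumAtDepth]]:
    """Weight-combine component depth-dose curves and pooled energy spectra.

    The pooled per-depth median/IQR are recomputed from the weighted union
    of the component samples, not averaged from the component summaries.
    """
    if len(components) != len(spec.components):
        raise ValueError("component count does not match the SOBP spec")
    grid = components[0][0].depth_mm
    n_depths = len(components[0][1])
    for dd, spectra in components[1:]:
        if dd.depth_mm.shape != grid.shape or not np.allclose(dd.depth_mm, grid):
            raise ValueError("mismatched depth grids between components")
        if len(spectra) != n_depths:
            raise ValueError("mismatched scoring depths between components")
    weights = spec.weights
    dose = np.zeros_like(grid)
    for w, (dd, _) in zip(weights, components):
        dose = dose + w * dd.dose
    composite = DepthDose(grid, dose, normalization="plateau")

    pooled: list[EnergySpectrumAtDepth] = []
    for k in range(n_depths):
        energies, wts = [], []
        depth = components[0][1][k].depth_mm
        for w, (_, spectra) in zip(weights, components):
            sp = spectra[k]
            if sp.energies is None:
                raise ValueError("components must retain unbinned energies for pooling")
            if w > 0 and sp.energies.size:
                energies.append(sp.energies)
                base = sp.weights if sp.weights is not None else np.ones(sp.energies.size)
                wts.append(w * base)
        if energies:
            pooled.append(EnergySpectrumAtDepth.from_energies(
                depth, np.concatenate(energies), weights=np.concatenate(wts)))
        else:
            pooled.append(EnergySpectrumAtDepth.from_energies(depth, []))
    return composite, pooled


def simulate_sobp(
    beam: BeamModel,
    rel: RangeEnergyRelation = DEFAULT_RELATION,
    pmma_thicknesses_mm: Sequence[float] | None = None,
    plateau: tuple[float, float] = (17.0, 28.0),
    grid: np.ndarray | None = None,
    seed: int = 0,
    score_depths: Sequence[float] = (),
    n_protons: int | None = None,
) -> tuple[SobpSpec, DepthDose, list[EnergySpectrumAtDepth]]:
    """Simulate components, solve flattening weights and compose the SOBP.

    Default modulator: 10 PMMA steps of ~1.13 mm (1.3 mm WET spacing),
    covering a 17-28 mm plateau for the default beam.
    """
    if pmma_thicknesses_mm is None:
        pmma_thicknesses_mm = [i * 1.3 / PMMA_WET for i in range(10)]
    edges = default_grid(beam, rel) if grid is None else np.asarray(grid, dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(len(pmma_thicknesses_mm))
    components = []
    for t, ss in zip(pmma_thicknesses_mm, seeds):
        dd, spectra = simulate_pristine(
            beam, rel, grid=edges, seed=np.random.default_rng(ss),
            score_depths=score_depths, n_protons=n_protons,
            range_offset_mm=PMMA_WET * t, normalization="raw",
        )
        components.append((dd, spectra))
    spec = solve_sobp_weights([dd for dd, _ in components], pmma_thicknesses_mm, plateau)
    composite, pooled = compose_sobp(spec, components)
    return spec, composite, pooled
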