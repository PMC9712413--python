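"""Synthetic peaks, mock shift/structure databases, and a mock predictor.

This module is the closed-loop test bed for the whole pipeline: it builds
heterogeneously broadened 4D cross-peaks as mixtures of conformer-specific
Gaussians, a mock shift/structure database with known class populations,
and a desk-scale shift→φ/ψ predictor, so both reconstruction branches can
be run against a known ground truth without any external tool or download.

The forward model ties simplified secondary-structure classes to shift
centroids with the canonical anti-correlated Cα/Cβ pattern (helix: Cα
upfield of nothing — high Cα / low Cβ; extended: low Cα / high Cβ) and
folds in homogeneous linewidths of about 0.5 / 0.3 / 0.5 ppm for ¹H / ¹⁵N /
¹³C, as expected at a 700–800 MHz field under fast magic-angle spinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dbmatch import DbEntry
from .ramachandran import (
    PHI_CENTERS_UNFOLDED,
    PSI_CENTERS,
    RamachandranMap,
    wrap_angle,
)
from .spectral_io import NUCLEI, PeakRegion, SpectralAxis

__all__ = [
    "ConformerSpec",
    "ForwardModel",
    "alanine_model",
    "default_axes",
    "simulate_peak",
    "class_cloud_ensemble",
    "generate_mock_database",
    "mock_predictor",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ConformerSpec:
    """One conformer population: dihedral angles, shift centroid, scatter."""

    phi: float
    psi: float
    population: float
    shift_centroid: tuple[float, float, float, float]  # (H, N, CA, CB) ppm
    shift_scatter: tuple[float, float, float, float] = (0.2, 0.8, 0.6, 0.6)

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be non-negative")
        if any(s < 0 for s in self.shift_scatter):
            raise ValueError("scatter must be non-negative")


@dataclass(frozen=True)
class ForwardModel:
    """Class → shift-centroid mapping with homogeneous linewidths.

    ``class_centroids`` maps a simplified class name to an (H, N, CA, CB)
    centroid; ``class_angles`` to the modal (φ, ψ); ``class_angle_scatter``
    is the angular spread (deg) of conformers within a class.
    ``linewidths`` are homogeneous FWHM contributions per nucleus (ppm).
    """

    class_centroids: dict[str, tuple[float, float, float, float]]
    class_angles: dict[str, tuple[float, float]]
    linewidths: tuple[float, float, float, float] = (0.5, 0.3, 0.5, 0.5)
    class_shift_scatter: tuple[float, float, float, float] = (0.2, 0.8, 0.6, 0.6)
    class_angle_scatter: float = 12.0

    def __post_init__(self) -> None:
        if {"helix", "extended"} <= set(self.class_centroids):
            h, e = self.class_centroids["helix"], self.class_centroids["extended"]
            if not ((h[2] - e[2]) > 0 and (h[3] - e[3]) < 0):
                raise ValueError(
                    "helix/extended Cα and Cβ centroids must be anti-correlated "
                    "(helix: high Cα / low Cβ)"
                )

    def conformer(self, cls: str, population: float) -> ConformerSpec:
        phi, psi = self.class_angles[cls]
        return ConformerSpec(phi, psi, population,
                             self.class_centroids[cls], self.class_shift_scatter)

    def sigma(self, conformer: ConformerSpec) -> np.ndarray:
        """Total Gaussian width per nucleus: scatter ⊕ homogeneous linewidth."""
        hom = np.asarray(self.linewidths) / _FWHM_TO_SIGMA
        return np.sqrt(np.asarray(conformer.shift_scatter) ** 2 + hom ** 2)


def alanine_model() -> ForwardModel:
    """Default forward model mimicking an alanine cross-peak layout.

    Helix: Cα ≈ 55 / Cβ ≈ 18 ppm; extended: Cα ≈ 50 / Cβ ≈ 23 ppm
    (approximate, configurable); amide H/N centroids differ modestly.
    """
    return ForwardModel(
        class_centroids={
            "helix": (8.0, 121.0, 55.0, 18.2),
            "extended": (8.5, 124.5, 50.2, 22.8),
            "other": (8.25, 122.5, 52.4, 20.3),
        },
        class_angles={
            "helix": (-63.0, -42.0),
            "extended": (-135.0, 140.0),
            "other": (-80.0, 60.0),
        },
    )


def default_axes(model: ForwardModel, n_points: tuple[int, int, int, int]
                 = (20, 24, 24, 24), pad_ppm: tuple[float, float, float, float]
                 = (1.5, 4.0, 3.0, 3.0)) -> tuple[SpectralAxis, ...]:
    """Spectral axes covering every class centroid ± padding, descending ppm."""
    cents = np.asarray(list(model.class_centroids.values()))
    axes = []
    for d, nuc in enumerate(NUCLEI):
        hi = cents[:, d].max() + pad_ppm[d]
        lo = cents[:, d].min() - pad_ppm[d]
        n = n_points[d]
        step = -(hi - lo) / (n - 1)
        axes.append(SpectralAxis(nuc, n, hi, step))
    return tuple(axes)


def simulate_peak(ensemble: list[ConformerSpec], model: ForwardModel,
                  axes: tuple[SpectralAxis, ...] | None = None,
                  noise_level: float = 0.0, seed: int = 0) -> PeakRegion:
    """Sum of population-weighted separable 4D Gaussians, plus white noise.

    Each conformer contributes a product of per-nucleus Gaussians centered
    at its shift centroid, with width scatter ⊕ homogeneous linewidth and
    volume proportional to its population.  ``noise_level`` is the white-
    noise standard deviation as a fraction of the noise-free maximum.
    """
    pops = np.asarray([c.population for c in ensemble])
    if not np.isclose(pops.sum(), 1.0, atol=1e-6):
        raise ValueError("conformer populations must sum to 1")
    if axes is None:
        axes = default_axes(model)
    for c in ensemble:
        for d, ax in enumerate(axes):
            if not ax.contains(c.shift_centroid[d]):
                raise ValueError(
                    f"conformer centroid {c.shift_centroid[d]} ppm outside "
                    f"the {ax.nucleus} axis range"
                )
    coords = [ax.ppm for ax in axes]
    arr = np.zeros(tuple(ax.n_points for ax in axes))
    # chunked sum of separable Gaussians (keeps memory flat for large ensembles)
    chunk = 256
    for lo in range(0, len(ensemble), chunk):
        block = ensemble[lo:lo + chunk]
        parts = []
        for d in range(4):
            mu = np.asarray([c.shift_centroid[d] for c in block])
            sig = np.asarray([model.sigma(c)[d] for c in block])
            g = np.exp(-0.5 * ((coords[d][None, :] - mu[:, None]) / sig[:, None]) ** 2)
            parts.append(g / (sig[:, None] * np.sqrt(2 * np.pi)))
        w = np.asarray([c.population for c in block])
        arr += np.einsum("i,ia,ib,ic,id->abcd", w, *parts, optimize=True)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise_level * arr.max(), size=arr.shape)
    return PeakRegion(arr, tuple(axes))


def class_cloud_ensemble(model: ForwardModel,
                         populations: dict[str, float],
                         half_widths: tuple[float, float, float, float]
                         = (0.7, 2.2, 1.8, 2.0),
                         n_per_dim: int = 6,
                         edge_softness: float = 0.55,
                         angle_seed: int = 0) -> list[ConformerSpec]:
    """Quasi-continuous conformer ensemble for a strongly heterogeneous peak.

    A glassy, conformationally arrested sample populates each secondary-
    structure class with a near-continuum of conformers whose shifts fill
    the class's characteristic region rather than clustering at its center.
    Each class here becomes a cell-centered regular grid of ``n_per_dim``⁴
    sub-conformers spanning centroid ± ``half_widths`` (ppm per nucleus),
    every sub-conformer a narrow Gaussian of width ``edge_softness`` ×
    grid spacing — together a plateau-like cloud with soft edges, totalling
    the class population.  Dihedral angles scatter around the class mode
    (seeded; the angles only matter for ground-truth bookkeeping).
    """
    hw = np.asarray(half_widths, dtype=float)
    rng = np.random.default_rng(angle_seed)
    spacing = 2.0 * hw / n_per_dim
    subscat = tuple(edge_softness * spacing)
    ens: list[ConformerSpec] = []
    for cls, p in populations.items():
        if p <= 0:
            continue
        c0 = np.asarray(model.class_centroids[cls])
        a0 = model.class_angles[cls]
        offs = [np.linspace(-hw[d] + spacing[d] / 2, hw[d] - spacing[d] / 2,
                            n_per_dim) for d in range(4)]
        mesh = np.stack(np.meshgrid(*offs, indexing="ij"), axis=-1).reshape(-1, 4)
        w = p / len(mesh)
        for off in mesh:
            phi, psi = rng.normal(a0, model.class_angle_scatter)
            ens.append(ConformerSpec(float(wrap_angle(phi)), float(wrap_angle(psi)),
                                     w, tuple(c0 + off), subscat))
    return ens


def generate_mock_database(class_populations: dict[str, float], n_entries: int,
                           model: ForwardModel, seed: int = 0,
                           piqc_fail_rate: float = 0.0,
                           residue_type: str = "A") -> list[DbEntry]:
    """Mock shift/structure database entries with known class composition.

    Entries draw (φ, ψ) from wrapped normals around the class modes and
    shifts from the forward model's class centroid plus scatter; STRIDE
    codes are assigned by class (helix→H, extended→E, other→T, coil→C) and
    PIQC failures are mixed in at ``piqc_fail_rate``.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be positive")
    classes = list(class_populations)
    p = np.asarray([class_populations[c] for c in classes], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("invalid class populations")
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    stride_for = {"helix": "H", "extended": "E", "other": "T", "coil": "C"}
    # coil entries have no conformer class in the forward model: their shifts
    # sit near the centroid average (conformational averaging in solution)
    # and their dihedral angles scatter broadly
    coil_centroid = np.mean(list(model.class_centroids.values()), axis=0)
    entries = []
    draws = rng.choice(len(classes), size=n_entries, p=p)
    for i, ci in enumerate(draws):
        cls = classes[ci]
        if cls == "coil":
            phi0, psi0 = -90.0, 130.0
            angle_scatter = 60.0
            cent = coil_centroid
        else:
            phi0, psi0 = model.class_angles[cls]
            angle_scatter = model.class_angle_scatter
            cent = np.asarray(model.class_centroids[cls])
        phi = float(wrap_angle(rng.normal(phi0, angle_scatter)))
        psi = float(wrap_angle(rng.normal(psi0, angle_scatter)))
        shifts = tuple(
            float(s) for s in rng.normal(cent, model.class_shift_scatter)
        )
        entries.append(DbEntry(
            protein_id=f"SYN{i // 100:03d}",
            residue_number=i,
            residue_type=residue_type,
            shifts=shifts,
            phi=phi if phi != -180.0 else 180.0,
            psi=psi if psi != -180.0 else 180.0,
            stride_class=stride_for[cls],
            piqc_pass=bool(rng.random() >= piqc_fail_rate),
        ))
    return entries


def _angular_kernel(phi0: float, psi0: float, scatter: float) -> np.ndarray:
    """Normalized wrapped-Gaussian bump on the unfolded 18×18 lattice."""
    dphi = wrap_angle(PHI_CENTERS_UNFOLDED[:, None] - phi0)
    dpsi = wrap_angle(PSI_CENTERS[None, :] - psi0)
    k = np.exp(-0.5 * ((dphi / scatter) ** 2 + (dpsi / scatter) ** 2))
    return k / k.sum()


def mock_predictor(shifts: tuple[float, float, float, float],
                   model: ForwardModel,
                   background_density: float = 1e-4) -> RamachandranMap:
    """Desk-scale shift→φ/ψ predictor: class-posterior mixture of kernels.

    The posterior probability of each class given the shift quadruple is
    computed under the forward model (Gaussian likelihood at the class
    centroid, width scatter ⊕ homogeneous linewidth, flat class prior); a
    flat background component with constant likelihood ``background_density``
    (per ppm⁴) captures shift combinations far from every centroid, where
    the returned map tends toward uniform.
    """
    x = np.asarray(shifts, dtype=float)
    hom = np.asarray(model.linewidths) / _FWHM_TO_SIGMA
    sig = np.sqrt(np.asarray(model.class_shift_scatter) ** 2 + hom ** 2)
    classes = list(model.class_centroids)
    like = []
    for cls in classes:
        mu = np.asarray(model.class_centroids[cls])
        z = (x - mu) / sig
        like.append(np.exp(-0.5 * float(z @ z)) / float(np.prod(sig * np.sqrt(2 * np.pi))))
    like.append(background_density)
    like = np.asarray(like)
    post = like / like.sum()
    dens = np.zeros((18, 18))
    for cls, w in zip(classes, post[:-1]):
        phi0, psi0 = model.class_angles[cls]
        dens += w * _angular_kernel(phi0, psi0, model.class_angle_scatter)
    dens += post[-1] / dens.size  # uniform background
    m = RamachandranMap(dens, folded=False, raw_density=dens.copy(),
                        meta={"posterior": dict(zip(classes + ["background"],
                                                    map(float, post)))})
    return m.normalize()
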