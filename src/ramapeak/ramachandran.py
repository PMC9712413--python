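"""Binned φ/ψ probability maps: parsing, aggregation, folding, projection.

The unfolded lattice is the 18 × 18 grid with 20° bins and bin centers at
−180°, −160°, …, 160° on each axis (324 φ/ψ combinations).  Because
left- and right-handed helices produce near-identical shift quadruples when
no Cβ stereochemistry distinguishes them, maps are "folded" by point
reflection about (0°, 0°): every bin with φ > 0 is added onto its reflected
partner (−φ, −ψ).  With this bin-center convention the reflection is closed
on the lattice (modulo 360°) and the folded map has exactly 10 φ-columns
(centers −180° … 0°) × 18 ψ-rows = 180 bins; the φ = −180° and φ = 0°
columns are self-paired and keep only their own mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PHI_CENTERS_UNFOLDED",
    "PSI_CENTERS",
    "PHI_CENTERS_FOLDED",
    "RamachandranMap",
    "MapStateError",
    "BinningError",
    "ParseError",
    "parse_ann_output",
    "write_ann_output",
    "aggregate",
    "fold",
    "project",
]

BIN_WIDTH = 20.0
PHI_CENTERS_UNFOLDED = np.arange(-180.0, 180.0, BIN_WIDTH)  # 18 centers
PSI_CENTERS = np.arange(-180.0, 180.0, BIN_WIDTH)           # 18 centers
PHI_CENTERS_FOLDED = np.arange(-180.0, 0.0 + 1e-9, BIN_WIDTH)  # 10 centers


class MapStateError(ValueError):
    """Operation applied to a map in the wrong folded/normalized state."""


class BinningError(ValueError):
    """Maps with incompatible lattices were combined."""


class ParseError(ValueError):
    """Predictor grid output could not be parsed."""


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle into (−180°, 180°]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def angle_to_bin(a: float | np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Index of the 20°-bin whose center is nearest (modulo 360°)."""
    a = np.asarray(a, dtype=float)
    idx = np.rint((a - centers[0]) / BIN_WIDTH).astype(int) % (360 // int(BIN_WIDTH))
    if centers.size < 18:
        raise BinningError("angle_to_bin expects an unfolded 18-center axis")
    return idx


@dataclass
class RamachandranMap:
    """Binned φ/ψ probability density D_k.

    ``density`` is indexed ``[phi_bin, psi_bin]``; shape (18, 18) unfolded
    or (10, 18) folded.  ``raw_density`` preserves the unnormalized values
    for diagnostics.
    """

    density: np.ndarray
    folded: bool = False
    normalized: bool = False
    raw_density: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        expect = (10, 18) if self.folded else (18, 18)
        if self.density.shape != expect:
            raise BinningError(
                f"{'folded' if self.folded else 'unfolded'} map must be "
                f"{expect}, got {self.density.shape}"
            )
        if (self.density < -1e-12).any():
            raise ValueError("negative probability density")
        self.density = np.clip(self.density, 0.0, None)
        if self.raw_density is None:
            self.raw_density = self.density.copy()

    @property
    def phi_centers(self) -> np.ndarray:
        return PHI_CENTERS_FOLDED if self.folded else PHI_CENTERS_UNFOLDED

    @property
    def psi_centers(self) -> np.ndarray:
        return PSI_CENTERS

    @property
    def n_bins(self) -> int:
        return self.density.size

    def total_mass(self) -> float:
        return float(self.density.sum())

    def normalize(self) -> "RamachandranMap":
        """Return a copy scaled to unit total mass."""
        s = self.total_mass()
        if s <= 0:
            raise ValueError("cannot normalize a zero-mass map")
        return RamachandranMap(
            self.density / s,
            folded=self.folded,
            normalized=True,
            raw_density=self.raw_density.copy(),
            meta=dict(self.meta),
        )

    def to_dataframe(self):
        """Long-format (phi, psi, density) table, for serialization."""
        import pandas as pd

        phis, psis = np.meshgrid(self.phi_centers, self.psi_centers, indexing="ij")
        return pd.DataFrame(
            {"phi": phis.ravel(), "psi": psis.ravel(), "density": self.density.ravel()}
        )


# ---------------------------------------------------------------------------
# predictor grid output I/O
# ---------------------------------------------------------------------------
# Two dialects of the 324-value per-residue probability grid are handled:
#   "table": whitespace-separated rows  PHI  PSI  PROB  (one bin per line,
#            header lines starting with VARS/FORMAT/REMARK/DATA/# ignored);
#   "grid":  18 numeric rows of 18 columns, row = φ center ascending,
#            column = ψ center ascending.
# Both are validated against the 18 × 18 lattice and normalized to unit sum.

def parse_ann_output(path: str | Path, dialect: str = "table") -> RamachandranMap:
    """Parse an external predictor's per-residue φ/ψ probability grid."""
    path = Path(path)
    text = path.read_text()
    lines = [
        ln
        for ln in text.splitlines()
        if ln.strip()
        and not ln.lstrip().startswith(("#", "REMARK", "VARS", "FORMAT", "DATA"))
    ]
    dens = np.zeros((18, 18))
    if dialect == "table":
        if len(lines) != 324:
            raise ParseError(f"{path}: expected 324 grid rows, got {len(lines)}")
        seen = np.zeros((18, 18), dtype=bool)
        for ln in lines:
            parts = ln.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: malformed row {ln!r}")
            phi, psi, prob = float(parts[0]), float(parts[1]), float(parts[2])
            i = int(angle_to_bin(phi, PHI_CENTERS_UNFOLDED))
            j = int(angle_to_bin(psi, PSI_CENTERS))
            if seen[i, j]:
                raise ParseError(f"{path}: duplicate bin ({phi}, {psi})")
            seen[i, j] = True
            dens[i, j] = prob
        if not seen.all():
            raise ParseError(f"{path}: grid does not cover all 324 bins")
    elif dialect == "grid":
        if len(lines) != 18:
            raise ParseError(f"{path}: expected 18 grid rows, got {len(lines)}")
        for i, ln in enumerate(lines):
            vals = [float(x) for x in ln.split()]
            if len(vals) != 18:
                raise ParseError(f"{path}: row {i} has {len(vals)} values, expected 18")
            dens[i, :] = vals
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    if (dens < 0).any():
        raise ValueError(f"{path}: negative probabilities")
    if dens.sum() <= 0:
        raise ValueError(f"{path}: all-zero probability grid")
    m = RamachandranMap(dens, folded=False, raw_density=dens.copy(),
                        meta={"source": str(path), "dialect": dialect})
    return m.normalize()


def write_ann_output(map_: RamachandranMap, path: str | Path,
                     dialect: str = "table") -> None:
    """Write a map in a predictor-grid dialect (round-trips with the parser)."""
    if map_.folded:
        raise MapStateError("predictor grids are unfolded 18×18 maps")
    path = Path(path)
    if dialect == "table":
        with open(path, "w") as f:
            f.write("VARS PHI PSI PROB\nFORMAT %8.1f %8.1f %12.6e\n")
            for i, phi in enumerate(PHI_CENTERS_UNFOLDED):
                for j, psi in enumerate(PSI_CENTERS):
                    f.write(f"{phi:8.1f} {psi:8.1f} {map_.density[i, j]:12.6e}\n")
    elif dialect == "grid":
        np.savetxt(path, map_.density, fmt="%.6e")
    else:
        raise ParseError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# aggregation, folding, projection
# ---------------------------------------------------------------------------

def aggregate(maps: list[RamachandranMap],
              intensities: np.ndarray | list[float]) -> RamachandranMap:
    """Intensity-weighted sum of per-grid-point maps, D_k = Σ_i D_ki · I_i.

    The result is normalized to unit mass; the unnormalized weighted sum is
    retained as ``raw_density``.
    """
    if not maps:
        raise ValueError("no maps to aggregate")
    w = np.asarray(intensities, dtype=float)
    if w.shape != (len(maps),):
        raise ValueError("need one intensity per map")
    if (w < 0).any():
        raise ValueError("intensities must be non-negative")
    if w.sum() <= 0:
        raise ValueError("all aggregation weights are zero")
    folded = maps[0].folded
    shape = maps[0].density.shape
    for m in maps:
        if m.folded != folded or m.density.shape != shape:
            raise BinningError("maps mix folded states or lattices")
    acc = np.zeros(shape)
    for m, wi in zip(maps, w):
        acc += m.density * wi
    out = RamachandranMap(acc, folded=folded, raw_density=acc.copy(),
                          meta={"n_aggregated": len(maps)})
    return out.normalize()


def fold(map_: RamachandranMap) -> RamachandranMap:
    """Merge handedness by point reflection about (0°, 0°).

    Mass at every bin with φ-center > 0 is added to the bin at
    (−φ, −ψ mod 360°); bins with φ ≤ 0 keep their own mass.  Total mass is
    conserved exactly.
    """
    if map_.folded:
        raise MapStateError("map is already folded")
    dens = np.zeros((10, 18))
    for i, phi in enumerate(PHI_CENTERS_UNFOLDED):
        for j, psi in enumerate(PSI_CENTERS):
            if phi <= 0:
                ti = int(np.rint((phi - (-180.0)) / BIN_WIDTH))
                tj = j
            else:
                rphi = wrap_angle(-phi)
                rpsi = wrap_angle(-psi)
                # wrap_angle maps 180 -> 180; the lattice stores -180
                if rphi > 160.0:
                    rphi -= 360.0
                if rpsi > 160.0:
                    rpsi -= 360.0
                ti = int(np.rint((rphi - (-180.0)) / BIN_WIDTH))
                tj = int(np.rint((rpsi - (-180.0)) / BIN_WIDTH))
            dens[ti, tj] += map_.density[i, j]
    raw = None
    if map_.raw_density is not None and not map_.normalized:
        raw = dens.copy()
    return RamachandranMap(dens, folded=True, normalized=map_.normalized,
                           raw_density=raw, meta=dict(map_.meta))


def project(map_: RamachandranMap, axis: str) -> np.ndarray:
    """Marginal distribution over φ or ψ (sums bins in each column / row)."""
    if not map_.normalized:
        raise MapStateError("project expects a normalized map")
    if axis == "phi":
        return map_.density.sum(axis=1)
    if axis == "psi":
        return map_.density.sum(axis=0)
    raise ValueError("axis must be 'phi' or 'psi'")


def plot_map(map_: RamachandranMap, ax=None, **imshow_kw):
    """Heatmap of a φ/ψ map (diagnostic helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pc = map_.phi_centers
    extent = [map_.psi_centers[0] - 10, map_.psi_centers[-1] + 10,
              pc[0] - 10, pc[-1] + 10]
    im = ax.imshow(map_.density, origin="lower", extent=extent,
                   aspect="auto", **imshow_kw)
    ax.set_xlabel("psi (deg)")
    ax.set_ylabel("phi (deg)")
    return im
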