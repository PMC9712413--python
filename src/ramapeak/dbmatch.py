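"""Database-driven reconstruction of the φ/ψ ensemble under a 4D peak.

Instead of running a shift→angle predictor per grid point, this branch
selects chemical-shift/structure database entries (per-residue shift
quadruples with known backbone dihedral angles and STRIDE secondary-
structure class) that fall inside the experimental 4D peak envelope.  Each
selected entry i is weighted by

    w_i = I_i · P_i⁻¹

where I_i is the interpolated peak intensity at the entry's shift quadruple
and P_i the local density of database entries in 4D shift space — the
inverse-density factor compensates the shift-combination-specific sparsity
of the database, so the reconstructed map reflects the peak shape rather
than database coverage.  The weighted entries are binned on the same 20°
φ/ψ lattice as the prediction branch, making the two branches directly
score-comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .ramachandran import (
    BIN_WIDTH,
    PHI_CENTERS_UNFOLDED,
    PSI_CENTERS,
    RamachandranMap,
    angle_to_bin,
)
from .spectral_io import PeakRegion, interpolate_intensity

logger = logging.getLogger(__name__)

STRIDE_CODES = frozenset("HGIETBbC")
SIMPLIFIED = {"H": "helix", "G": "helix", "I": "helix", "E": "extended",
              "T": "other", "B": "other", "b": "other", "C": "coil"}

DB_COLUMNS = ["protein_id", "residue_number", "residue_type",
              "shift_h", "shift_n", "shift_ca", "shift_cb",
              "phi", "psi", "stride_class", "piqc_pass"]

__all__ = [
    "DbEntry",
    "WeightedEntry",
    "DbFormatError",
    "DbValidityError",
    "LowConfidenceWarning",
    "load_database",
    "write_database",
    "filter_quality",
    "simplify_class",
    "select_in_envelope",
    "local_density",
    "entries_to_map",
    "reconstruct_map",
]


class DbFormatError(ValueError):
    """Database CSV does not match the documented schema."""


class DbValidityError(ValueError):
    """A database field holds an out-of-range or unknown value."""


class LowConfidenceWarning(UserWarning):
    """Too few database entries survived selection for a robust map."""


@dataclass(frozen=True)
class DbEntry:
    """One database residue: shift quadruple, dihedral angles, class, QC flag."""

    protein_id: str
    residue_number: int
    residue_type: str
    shifts: tuple[float, float, float, float]  # (H, N, CA, CB) ppm
    phi: float
    psi: float
    stride_class: str
    piqc_pass: bool

    def __post_init__(self) -> None:
        if self.stride_class not in STRIDE_CODES:
            raise DbValidityError(f"unknown STRIDE code {self.stride_class!r}")
        for name, a in (("phi", self.phi), ("psi", self.psi)):
            if not -180.0 < a <= 180.0:
                raise DbValidityError(f"{name} = {a} outside (−180, 180]")

    @property
    def simple_class(self) -> str:
        return SIMPLIFIED[self.stride_class]


@dataclass(frozen=True)
class WeightedEntry:
    """A selected entry with intensity I_i, local density P_i, weight w_i."""

    entry: DbEntry
    intensity: float
    density: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("local density must be positive")

    @property
    def weight(self) -> float:
        return self.intensity / self.density


def simplify_class(stride_class: str) -> str:
    """Collapse the STRIDE alphabet: H/G/I→helix, E→extended, T/B/b→other, C→coil."""
    try:
        return SIMPLIFIED[stride_class]
    except KeyError as e:
        raise DbValidityError(f"unknown STRIDE code {stride_class!r}") from e


def load_database(path: str | Path, residue_type: str | None = None) -> list[DbEntry]:
    """Load a shift/structure database CSV, optionally one residue type.

    Schema (documented, comment lines allowed): columns ``protein_id,
    residue_number, residue_type, shift_h, shift_n, shift_ca, shift_cb,
    phi, psi, stride_class, piqc_pass``.  Missing shifts are NaN.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as e:
        raise DbFormatError(f"{path}: unreadable CSV ({e})") from e
    missing = set(DB_COLUMNS) - set(df.columns)
    if missing:
        raise DbFormatError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for r in df.itertuples():
        if residue_type is not None and r.residue_type != residue_type:
            continue
        entries.append(DbEntry(
            protein_id=str(r.protein_id),
            residue_number=int(r.residue_number),
            residue_type=str(r.residue_type),
            shifts=(float(r.shift_h), float(r.shift_n),
                    float(r.shift_ca), float(r.shift_cb)),
            phi=float(r.phi),
            psi=float(r.psi),
            stride_class=str(r.stride_class),
            piqc_pass=bool(r.piqc_pass),
        ))
    return entries


def write_database(entries: list[DbEntry], path: str | Path) -> None:
    """Write entries back to the documented CSV schema."""
    rows = [{
        "protein_id": e.protein_id, "residue_number": e.residue_number,
        "residue_type": e.residue_type,
        "shift_h": e.shifts[0], "shift_n": e.shifts[1],
        "shift_ca": e.shifts[2], "shift_cb": e.shifts[3],
        "phi": e.phi, "psi": e.psi, "stride_class": e.stride_class,
        "piqc_pass": e.piqc_pass,
    } for e in entries]
    pd.DataFrame(rows, columns=DB_COLUMNS).to_csv(path, index=False)


def filter_quality(entries: list[DbEntry]) -> list[DbEntry]:
    """Drop residues from proteins that failed the PIQC quality check."""
    return [e for e in entries if e.piqc_pass]


def select_in_envelope(entries: list[DbEntry], peak: PeakRegion,
                       threshold_fraction: float = 0.2,
                       exclude_coil: bool = True) -> list[tuple[DbEntry, float]]:
    """Entries inside the populated 4D peak envelope, paired with I_i.

    An entry is inside the envelope when the interpolated peak intensity at
    its shift quadruple reaches ``threshold_fraction`` of the peak maximum.
    Coil-class entries are excluded by default: in a rigidified sample the
    shifts do not average to random-coil values.  Entries missing a shift
    (NaN) or lying outside the spectral region are skipped and counted.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    cutoff = threshold_fraction * peak.max_intensity
    kept: list[tuple[DbEntry, float]] = []
    n_skipped = 0
    for e in entries:
        if exclude_coil and e.simple_class == "coil":
            continue
        sh = np.asarray(e.shifts, dtype=float)
        if np.isnan(sh).any():
            n_skipped += 1
            continue
        if not all(ax.contains(s) for ax, s in zip(peak.axes, sh)):
            continue
        intensity = max(float(interpolate_intensity(peak, sh)), 0.0)
        if intensity >= cutoff:
            kept.append((e, intensity))
    if n_skipped:
        logger.info("select_in_envelope: skipped %d entries with missing shifts",
                    n_skipped)
    return kept


def local_density(entries: list[DbEntry],
                  bandwidths: tuple[float, float, float, float] = (0.4, 1.5, 1.0, 1.5),
                  method: str = "kde") -> np.ndarray:
    """Local 4D entry density P_i at each entry's shift quadruple.

    ``"kde"`` (default) is a product-Gaussian kernel density estimate with
    per-nucleus bandwidths (ppm, order H/N/CA/CB; defaults match the
    grid-sampling spacings), each entry contributing to its own density.
    ``"knn"`` uses the k-nearest-neighbor volume estimate (k = √n) in the
    bandwidth-scaled metric.  A single entry yields a uniform constant with
    a degeneracy warning.
    """
    bw = np.asarray(bandwidths, dtype=float)
    if bw.shape != (4,) or (bw <= 0).any():
        raise ValueError("need 4 positive bandwidths")
    x = np.asarray([e.shifts for e in entries], dtype=float)
    n = len(entries)
    if n == 0:
        raise ValueError("no entries")
    if n == 1:
        warnings.warn("single entry: degenerate density, using uniform constant",
                      LowConfidenceWarning)
        return np.ones(1)
    u = x / bw  # bandwidth-scaled coordinates
    if method == "kde":
        d2 = cdist(u, u, "sqeuclidean")
        k = np.exp(-0.5 * d2)
        norm = n * float(np.prod(bw)) * (2 * np.pi) ** 2
        return k.sum(axis=1) / norm
    if method == "knn":
        k = max(2, int(np.sqrt(n)))
        d = np.sort(cdist(u, u), axis=1)[:, k - 1]
        d = np.maximum(d, 1e-12)
        # density ∝ k / (n · r^4) in the scaled 4D metric
        return k / (n * d ** 4)
    raise ValueError(f"unknown density method {method!r}")


def entries_to_map(weighted: list[WeightedEntry],
                   bin_width: float = BIN_WIDTH) -> RamachandranMap:
    """Weighted 2-D histogram of (φ, ψ) on the unfolded 18×18 lattice.

    The result is normalized; fold with :func:`ramapeak.ramachandran.fold`
    before scoring.
    """
    if not weighted:
        raise ValueError("no weighted entries; cannot build a map")
    if bin_width != BIN_WIDTH:
        raise ValueError(
            f"only the {BIN_WIDTH}° lattice shared with the prediction branch "
            "is supported"
        )
    dens = np.zeros((18, 18))
    for we in weighted:
        i = int(angle_to_bin(we.entry.phi, PHI_CENTERS_UNFOLDED))
        j = int(angle_to_bin(we.entry.psi, PSI_CENTERS))
        dens[i, j] += we.weight
    m = RamachandranMap(dens, folded=False, raw_density=dens.copy(),
                        meta={"n_entries": len(weighted)})
    return m.normalize()


def reconstruct_map(entries: list[DbEntry], peak: PeakRegion,
                    threshold_fraction: float = 0.2,
                    bandwidths: tuple[float, float, float, float] = (0.4, 1.5, 1.0, 1.5),
                    density_method: str = "kde",
                    density_scope: str = "envelope",
                    min_entries: int = 20,
                    ) -> tuple[RamachandranMap, list[WeightedEntry]]:
    """Full database branch: filter → select → weight → bin.

    ``density_scope`` picks whether P_i is estimated from the entries inside
    the envelope (default) or from all quality-filtered entries.  Fewer than
    ``min_entries`` selected entries triggers a low-confidence warning (the
    map is still returned).
    """
    ok = filter_quality(entries)
    selected = select_in_envelope(ok, peak, threshold_fraction)
    if not selected:
        raise ValueError("no database entries inside the peak envelope")
    if len(selected) < min_entries:
        warnings.warn(
            f"only {len(selected)} entries selected (< {min_entries}); "
            "reconstruction is low-confidence", LowConfidenceWarning)
    sel_entries = [e for e, _ in selected]
    if density_scope == "envelope":
        dens = local_density(sel_entries, bandwidths, density_method)
    elif density_scope == "all":
        all_d = local_density(ok, bandwidths, density_method)
        index = {id(e): i for i, e in enumerate(ok)}
        dens = np.asarray([all_d[index[id(e)]] for e in sel_entries])
    else:
        raise ValueError(f"unknown density scope {density_scope!r}")
    weighted = [WeightedEntry(e, inten, float(p))
                for (e, inten), p in zip(selected, dens)]
    return entries_to_map(weighted), weighted
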