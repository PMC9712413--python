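"""Reading and grid-sampling of processed multidimensional NMR peak regions.

A :class:`PeakRegion` holds a real-valued 4D intensity hypercube over
ppm-calibrated axes in the fixed nucleus order (H, N, CA, CB).  The
heterogeneously broadened cross-peak is probed on a regular chemical-shift
lattice anchored at the peak maximum; every lattice point whose
(multilinearly interpolated) intensity reaches a relative threshold becomes a
:class:`GridPoint` carrying its intensity weight ``I_i``.

Two on-disk formats are supported:

* a self-describing portable HDF5 container (``/intensity`` dataset plus
  per-axis attributes) — the native interchange format of this package;
* single-file NMRPipe hypercubes (512-float32 header followed by a float32
  stream), via a minimal reader/writer for frequency-domain real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import itertools
import warnings

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator

NUCLEI = ("H", "N", "CA", "CB")

__all__ = [
    "NUCLEI",
    "SpectralAxis",
    "PeakRegion",
    "GridPoint",
    "SpectrumFormatError",
    "CalibrationError",
    "DimensionError",
    "EmptySelectionWarning",
    "read_spectrum",
    "write_spectrum",
    "sample_grid",
    "interpolate_intensity",
]


class SpectrumFormatError(ValueError):
    """File is not a readable hypercube in a supported format."""


class CalibrationError(ValueError):
    """Axis calibration metadata is missing or unusable."""


class DimensionError(ValueError):
    """Input does not have the expected four shift dimensions."""


class EmptySelectionWarning(UserWarning):
    """No lattice point reached the intensity threshold."""


@dataclass(frozen=True)
class SpectralAxis:
    """One ppm-calibrated spectral dimension.

    ``ppm_step`` is signed; NMR frequency axes conventionally run from high
    to low ppm, i.e. a negative step.
    """

    nucleus: str
    n_points: int
    ppm_start: float
    ppm_step: float

    def __post_init__(self) -> None:
        if self.nucleus not in NUCLEI:
            raise ValueError(f"unknown nucleus label {self.nucleus!r}")
        if self.n_points < 2:
            raise ValueError("axis needs at least 2 points")
        if self.ppm_step == 0:
            raise ValueError("ppm_step must be nonzero")

    @property
    def ppm(self) -> np.ndarray:
        """ppm coordinate of every index (affine, monotone)."""
        return self.ppm_start + self.ppm_step * np.arange(self.n_points)

    @property
    def ppm_min(self) -> float:
        return float(min(self.ppm_start, self.ppm[-1]))

    @property
    def ppm_max(self) -> float:
        return float(max(self.ppm_start, self.ppm[-1]))

    def contains(self, ppm: float) -> bool:
        return self.ppm_min <= ppm <= self.ppm_max


@dataclass
class PeakRegion:
    """A resolved 4D cross-peak: intensity hypercube plus its four axes."""

    intensity: np.ndarray
    axes: tuple[SpectralAxis, SpectralAxis, SpectralAxis, SpectralAxis]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 4:
            raise DimensionError(
                f"expected a 4-dim hypercube, got {self.intensity.ndim} dims"
            )
        if tuple(a.nucleus for a in self.axes) != NUCLEI:
            raise ValueError(f"axes must be ordered {NUCLEI}")
        for dim, ax in enumerate(self.axes):
            if self.intensity.shape[dim] != ax.n_points:
                raise ValueError(
                    f"axis {ax.nucleus}: n_points {ax.n_points} does not match "
                    f"array dim {self.intensity.shape[dim]}"
                )
        self._interp: RegularGridInterpolator | None = None

    @property
    def max_intensity(self) -> float:
        return float(self.intensity.max())

    @property
    def max_position(self) -> tuple[float, float, float, float]:
        """ppm coordinates of the global intensity maximum."""
        idx = np.unravel_index(int(np.argmax(self.intensity)), self.intensity.shape)
        return tuple(float(ax.ppm[i]) for ax, i in zip(self.axes, idx))

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            coords = []
            arr = self.intensity
            for dim, ax in enumerate(self.axes):
                c = ax.ppm
                if c[0] > c[-1]:  # RegularGridInterpolator needs ascending grids
                    c = c[::-1]
                    arr = np.flip(arr, axis=dim)
                coords.append(c)
            self._interp = RegularGridInterpolator(
                coords, arr, method="linear", bounds_error=True
            )
        return self._interp


@dataclass(frozen=True)
class GridPoint:
    """One sampled shift quadruple with its interpolated intensity weight."""

    index: int
    shifts: tuple[float, float, float, float]
    intensity: float


# ---------------------------------------------------------------------------
# portable HDF5 container
# ---------------------------------------------------------------------------

def _write_portable(peak: PeakRegion, path: Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("intensity", data=peak.intensity)
        ds.attrs["format"] = "ramapeak-hypercube-1"
        for i, ax in enumerate(peak.axes):
            g = f.create_group(f"axis{i}")
            g.attrs["nucleus"] = ax.nucleus
            g.attrs["n_points"] = ax.n_points
            g.attrs["ppm_start"] = ax.ppm_start
            g.attrs["ppm_step"] = ax.ppm_step


def _read_portable(path: Path) -> tuple[np.ndarray, list[SpectralAxis]]:
    with h5py.File(path, "r") as f:
        if "intensity" not in f:
            raise SpectrumFormatError(f"{path}: no /intensity dataset")
        arr = f["intensity"][()]
        axes = []
        for i in range(arr.ndim):
            key = f"axis{i}"
            if key not in f:
                raise CalibrationError(f"{path}: missing axis metadata for dim {i}")
            g = f[key]
            try:
                axes.append(
                    SpectralAxis(
                        nucleus=str(g.attrs["nucleus"]),
                        n_points=int(g.attrs["n_points"]),
                        ppm_start=float(g.attrs["ppm_start"]),
                        ppm_step=float(g.attrs["ppm_step"]),
                    )
                )
            except KeyError as e:
                raise CalibrationError(f"{path}: axis {i} lacks {e}") from e
    return arr, axes


# ---------------------------------------------------------------------------
# minimal NMRPipe single-file support
# ---------------------------------------------------------------------------
# Header: 512 float32 values.  Offsets below are the standard published FDATA
# locations for the parameters we need.  Only real, frequency-domain,
# single-file hypercubes are handled.

_FD = {
    "FDMAGIC": 0,
    "FDFLTFORMAT": 1,
    "FDFLTORDER": 2,
    "FDDIMCOUNT": 9,
    "FDDIMORDER": (24, 25, 26, 27),
    "FDPIPEFLAG": 57,
    "FDSIZE": 99,        # points in dim code 2 (x)
    "FDSPECNUM": 219,    # points in dim code 1 (y)
    "FDQUADFLAG": 106,
    "FDTRANSPOSED": 221,
    "FDFILECOUNT": 442,
    # per-dimension parameter blocks, keyed by NMRPipe dimension code 1..4
    1: {"SW": 229, "ORIG": 249, "OBS": 218, "FTFLAG": 222, "SIZE": 219},
    2: {"SW": 100, "ORIG": 101, "OBS": 119, "FTFLAG": 220, "SIZE": 99},
    3: {"SW": 11, "ORIG": 12, "OBS": 10, "FTFLAG": 13, "SIZE": 15},
    4: {"SW": 29, "ORIG": 30, "OBS": 28, "FTFLAG": 31, "SIZE": 32},
}

# array dims are stored slowest..fastest = dim codes given by FDDIMORDER
# reversed; for data written by this package the order is (4, 3, 1, 2),
# i.e. the x-axis (code 2) varies fastest.
_PIPE_DIM_CODES = (4, 3, 1, 2)


def _pipe_axis_ppm(size: int, sw: float, orig: float, obs: float) -> tuple[float, float]:
    """(ppm_start, ppm_step) for an NMRPipe frequency axis.

    Point ``N-1`` sits at ORIG Hz and point 0 at ``ORIG + SW·(N−1)/N`` Hz,
    so the ppm axis descends with step −SW/(N·OBS).
    """
    if obs <= 0 or sw <= 0:
        raise CalibrationError("NMRPipe axis missing OBS/SW calibration")
    step_hz = -sw / size
    start_hz = orig + sw * (size - 1) / size
    return start_hz / obs, step_hz / obs


def _read_nmrpipe(path: Path) -> tuple[np.ndarray, list[SpectralAxis]]:
    raw = np.fromfile(path, dtype=np.float32)
    if raw.size < 512:
        raise SpectrumFormatError(f"{path}: too short for an NMRPipe header")
    hdr = raw[:512].astype(float)
    # FDFLTORDER is 2.345 when byte order matches the reader
    if abs(hdr[_FD["FDFLTORDER"]] - 2.345) > 1e-3:
        swapped = raw.byteswap()
        hdr = swapped[:512].astype(float)
        if abs(hdr[_FD["FDFLTORDER"]] - 2.345) > 1e-3:
            raise SpectrumFormatError(f"{path}: not an NMRPipe file")
        raw = swapped
    ndim = int(round(hdr[_FD["FDDIMCOUNT"]]))
    if ndim != 4:
        raise DimensionError(f"{path}: NMRPipe file has {ndim} dims, expected 4")
    if int(round(hdr[_FD["FDFILECOUNT"]])) > 1:
        raise SpectrumFormatError(
            f"{path}: multi-file NMRPipe data streams are not supported; "
            "concatenate to a single file first"
        )
    sizes = []
    axinfo = []
    for code in _PIPE_DIM_CODES:
        loc = _FD[code]
        size = int(round(hdr[loc["SIZE"]]))
        if size < 2:
            raise SpectrumFormatError(f"{path}: bad size for dim code {code}")
        if int(round(hdr[loc["FTFLAG"]])) != 1:
            raise CalibrationError(
                f"{path}: dim code {code} is not frequency-domain data"
            )
        start, step = _pipe_axis_ppm(
            size, float(hdr[loc["SW"]]), float(hdr[loc["ORIG"]]), float(hdr[loc["OBS"]])
        )
        sizes.append(size)
        axinfo.append((start, step))
    data = raw[512:]
    expected = int(np.prod(sizes))
    if data.size != expected:
        raise SpectrumFormatError(
            f"{path}: data stream has {data.size} points, header implies {expected}"
        )
    arr = data.reshape(sizes).astype(float)
    axes = [
        SpectralAxis("H", sizes[i], axinfo[i][0], axinfo[i][1])  # placeholder label
        for i in range(4)
    ]
    return arr, axes


def write_nmrpipe(peak: PeakRegion, path: str | Path) -> None:
    """Write a PeakRegion as a single-file real NMRPipe hypercube.

    Observe frequencies are fixed nominal values (800 MHz field); the ppm
    calibration round-trips exactly through :func:`read_spectrum`.
    """
    obs_by_nuc = {"H": 800.0, "N": 81.08, "CA": 201.2, "CB": 201.2}
    hdr = np.zeros(512, dtype=np.float32)
    hdr[_FD["FDFLTFORMAT"]] = np.float32(
        np.frombuffer(np.uint32(0xEEEEEEEE).tobytes(), dtype=np.float32)[0]
    )
    hdr[_FD["FDFLTORDER"]] = 2.345
    hdr[_FD["FDDIMCOUNT"]] = 4
    for slot, code in zip(_FD["FDDIMORDER"], (2, 1, 3, 4)):
        hdr[slot] = code
    hdr[_FD["FDQUADFLAG"]] = 1  # real data
    hdr[_FD["FDFILECOUNT"]] = 1
    hdr[_FD["FDPIPEFLAG"]] = 0
    for dim, code in enumerate(_PIPE_DIM_CODES):
        ax = peak.axes[dim]
        loc = _FD[code]
        n = ax.n_points
        obs = obs_by_nuc[ax.nucleus]
        step_hz = ax.ppm_step * obs
        sw = abs(step_hz) * n
        if ax.ppm_step < 0:
            orig = ax.ppm[-1] * obs
        else:
            # ascending ppm storage: store as if descending from the far end
            orig = ax.ppm[0] * obs
        hdr[loc["SIZE"]] = n
        hdr[loc["SW"]] = sw
        hdr[loc["ORIG"]] = orig
        hdr[loc["OBS"]] = obs
        hdr[loc["FTFLAG"]] = 1
    arr = peak.intensity
    # the reader reconstructs a descending ppm axis; flip ascending axes
    for dim, ax in enumerate(peak.axes):
        if ax.ppm_step > 0:
            arr = np.flip(arr, axis=dim)
    with open(path, "wb") as f:
        f.write(hdr.tobytes())
        f.write(arr.astype(np.float32).tobytes())


# ---------------------------------------------------------------------------
# public reader / writer
# ---------------------------------------------------------------------------

def write_spectrum(peak: PeakRegion, path: str | Path, fmt: str = "portable") -> None:
    """Write a peak region to disk (``portable`` HDF5 or ``nmrpipe``)."""
    path = Path(path)
    if fmt == "portable":
        _write_portable(peak, path)
    elif fmt == "nmrpipe":
        write_nmrpipe(peak, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_spectrum(
    path: str | Path,
    axis_order: Sequence[str] | None = None,
) -> PeakRegion:
    """Read a processed 4D spectrum region and return it in (H, N, CA, CB) order.

    Parameters
    ----------
    path:
        Portable HDF5 container or single-file NMRPipe hypercube; the format
        is sniffed from the file signature.
    axis_order:
        Nucleus label of each stored dimension, in storage order.  Required
        for NMRPipe input (the minimal header carries no reliable labels);
        for portable containers it overrides the stored labels.
    """
    path = Path(path)
    if not path.is_file():
        raise SpectrumFormatError(f"{path}: not a readable file")
    if h5py.is_hdf5(path):
        arr, axes = _read_portable(path)
        if axis_order is not None:
            if len(axis_order) != len(axes):
                raise DimensionError("axis_order length does not match data dims")
            axes = [
                SpectralAxis(nuc, a.n_points, a.ppm_start, a.ppm_step)
                for nuc, a in zip(axis_order, axes)
            ]
    else:
        arr, axes = _read_nmrpipe(path)
        if axis_order is None:
            raise CalibrationError(
                "NMRPipe input requires axis_order (nucleus label per stored dim)"
            )
        if len(axis_order) != 4:
            raise DimensionError("axis_order must name 4 nuclei")
        axes = [
            SpectralAxis(nuc, a.n_points, a.ppm_start, a.ppm_step)
            for nuc, a in zip(axis_order, axes)
        ]
    if arr.ndim != 4:
        raise DimensionError(f"{path}: expected 4 dims, found {arr.ndim}")
    labels = [a.nucleus for a in axes]
    if sorted(labels) != sorted(NUCLEI):
        raise CalibrationError(f"{path}: axes {labels} do not cover {NUCLEI}")
    perm = [labels.index(n) for n in NUCLEI]
    arr = np.transpose(arr, perm)
    axes = [axes[p] for p in perm]
    return PeakRegion(arr, tuple(axes))


# ---------------------------------------------------------------------------
# interpolation and grid sampling
# ---------------------------------------------------------------------------

def interpolate_intensity(
    peak: PeakRegion, shifts: Sequence[float] | np.ndarray
) -> float | np.ndarray:
    """Multilinear interpolation of the hypercube at ppm coordinates.

    ``shifts`` is a quadruple (H, N, CA, CB) or an (n, 4) array of them.
    Coordinates outside the axis ranges raise a range error.
    """
    pts = np.atleast_2d(np.asarray(shifts, dtype=float))
    if pts.shape[-1] != 4:
        raise DimensionError("shifts must have 4 components (H, N, CA, CB)")
    try:
        vals = peak._interpolator()(pts)
    except ValueError as e:
        raise ValueError(f"shift coordinate outside the peak region: {e}") from e
    if np.asarray(shifts).ndim == 1:
        return float(vals[0])
    return vals


def _lattice_1d(ax: SpectralAxis, anchor: float, spacing: float) -> np.ndarray:
    """Regular 1-D lattice through ``anchor``, clipped to the axis range."""
    lo, hi = ax.ppm_min, ax.ppm_max
    n_down = int(np.floor((anchor - lo) / spacing + 1e-9))
    n_up = int(np.floor((hi - anchor) / spacing + 1e-9))
    # clip guards against epsilon overshoot at the axis boundaries
    return np.clip(anchor + spacing * np.arange(-n_down, n_up + 1), lo, hi)


def sample_grid(
    peak: PeakRegion,
    spacings: Sequence[float] = (0.4, 1.5, 1.0, 1.5),
    threshold_fraction: float = 0.2,
    mode: str = "interpolated",
) -> list[GridPoint]:
    """Probe the peak on a regular chemical-shift lattice.

    The lattice is anchored at the global peak-maximum ppm position and
    stepped outwards with the given per-nucleus spacings (ppm, in the fixed
    axis order H, N, CA, CB; the defaults are 0.4 / 1.5 / 1.0 / 1.5 ppm for
    H / N / Cα / Cβ).  Every lattice point whose intensity reaches
    ``threshold_fraction`` of the peak maximum is returned with its
    intensity ``I_i``.  Negative intensities (processing artifacts) are
    treated as zero so downstream weights stay non-negative.

    ``mode`` selects how intensity is probed: ``"interpolated"``
    (multilinear, default) or ``"nearest"`` (nearest-voxel value).
    """
    spacings = tuple(float(s) for s in spacings)
    if len(spacings) != 4 or any(s <= 0 for s in spacings):
        raise ValueError("need 4 positive spacings (H, N, CA, CB)")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if mode not in ("interpolated", "nearest"):
        raise ValueError(f"unknown probing mode {mode!r}")

    if peak.max_intensity <= 0:
        warnings.warn("peak has no positive intensity", EmptySelectionWarning)
        return []
    anchor = peak.max_position
    coords1d = [
        _lattice_1d(ax, a, s) for ax, a, s in zip(peak.axes, anchor, spacings)
    ]
    mesh = np.meshgrid(*coords1d, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)

    if mode == "interpolated":
        vals = np.asarray(interpolate_intensity(peak, pts))
    else:
        idx = []
        for d, ax in enumerate(peak.axes):
            i = np.rint((pts[:, d] - ax.ppm_start) / ax.ppm_step).astype(int)
            idx.append(np.clip(i, 0, ax.n_points - 1))
        vals = peak.intensity[tuple(idx)]
    vals = np.maximum(vals, 0.0)

    cutoff = threshold_fraction * peak.max_intensity
    keep = vals >= cutoff
    points = [
        GridPoint(index=i, shifts=tuple(float(x) for x in p), intensity=float(v))
        for i, (p, v) in enumerate(zip(pts[keep], vals[keep]))
    ]
    if not points:
        warnings.warn(
            "no lattice point reached the intensity threshold", EmptySelectionWarning
        )
    return points
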