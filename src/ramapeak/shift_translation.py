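"""Translate a grid point's shift quadruple into a full-sequence predictor input.

External φ/ψ predictors need chemical shifts for a stretch of consecutive
residues, but a heterogeneously broadened peak offers no way to tell which
section of a neighbor's peak belongs to the same conformer as a given
element of the residue-of-interest (ROI) peak.  Pinning neighbors at a
single shift (e.g. their peak maxima) would bias every prediction toward
the majority conformation.  Instead, the ROI's secondary-shift deviation

    r_i = (grid-point shifts) − (neighbor-corrected random-coil shifts of the ROI)

is rescaled per nucleus and residue type and propagated onto the j±1 and
j±2 neighbors on top of *their* neighbor-corrected random-coil shifts.  The
rescaling factor is the ratio of helix-minus-extended center-of-gravity
spans, which captures how strongly each residue type's shifts respond to
secondary structure.  Optionally the chain is padded at both termini (the
predictor's fragment search uses up to 7-mers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .spectral_io import GridPoint

NUCLEI = ("H", "N", "CA", "CB")
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "RandomCoilTable",
    "CoGTable",
    "PredictorInputTable",
    "TableCoverageError",
    "DegenerateSpanError",
    "AdapterError",
    "deviation_vector",
    "rescale_factor",
    "translate_to_neighbors",
    "write_predictor_input",
    "read_predictor_input",
]


class TableCoverageError(KeyError):
    """A residue type / nucleus is missing from a reference table."""


class DegenerateSpanError(ValueError):
    """The ROI's helix-extended shift span vanishes; rescaling undefined."""


class AdapterError(ValueError):
    """Unsupported external-predictor dialect."""


def _nuclei_for(restype: str) -> tuple[str, ...]:
    """Observable backbone nuclei for a residue type (Gly has no Cβ, Pro no amide H)."""
    if restype == "G":
        return ("H", "N", "CA")
    if restype == "P":
        return ("N", "CA", "CB")
    return NUCLEI


def _read_table_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _data_path(name: str) -> Path:
    return Path(resources.files("ramapeak").joinpath("data", name))


@dataclass
class RandomCoilTable:
    """Neighbor-corrected random-coil shifts.

    ``base[(residue, nucleus)]`` holds the context-free random-coil shift;
    ``corrections[(neighbor_type, position, nucleus)]`` the additive ppm
    correction applied to a residue whose ``prev``/``next`` neighbor has
    that type.  Pairs absent from the correction table contribute 0.
    """

    base: dict[tuple[str, str], float]
    corrections: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res in STANDARD_RESIDUES:
            for nuc in ("H", "N", "CA"):
                if nuc == "H" and res == "P":
                    continue
                if (res, nuc) not in self.base:
                    raise TableCoverageError(f"random-coil table lacks ({res}, {nuc})")
        if ("G", "CB") in self.base:
            raise ValueError("glycine must not carry a CB random-coil shift")

    @classmethod
    def from_csv(cls, base_path: str | Path,
                 corrections_path: str | Path | None = None) -> "RandomCoilTable":
        df = _read_table_csv(Path(base_path))
        base = {(r.residue, r.nucleus): float(r.shift) for r in df.itertuples()}
        corr: dict[tuple[str, str, str], float] = {}
        if corrections_path is not None:
            cdf = _read_table_csv(Path(corrections_path))
            corr = {
                (r.neighbor, r.position, r.nucleus): float(r.delta)
                for r in cdf.itertuples()
            }
        return cls(base, corr)

    @classmethod
    def default(cls) -> "RandomCoilTable":
        return cls.from_csv(
            _data_path("random_coil.csv"),
            _data_path("random_coil_corrections.csv"),
        )

    def shift(self, sequence: str, i: int, nucleus: str) -> float:
        """Neighbor-corrected random-coil shift of residue ``i`` in context."""
        res = sequence[i]
        if nucleus not in _nuclei_for(res):
            raise TableCoverageError(f"{res} has no {nucleus} shift")
        try:
            v = self.base[(res, nucleus)]
        except KeyError as e:
            raise TableCoverageError(f"random-coil table lacks ({res}, {nucleus})") from e
        if i > 0:
            v += self.corrections.get((sequence[i - 1], "prev", nucleus), 0.0)
        if i < len(sequence) - 1:
            v += self.corrections.get((sequence[i + 1], "next", nucleus), 0.0)
        return v


@dataclass
class CoGTable:
    """Conformation-specific shift centers of gravity.

    ``cog[(residue, nucleus, cls)]`` with ``cls`` in {"helix", "extended"}.
    The helix−extended span per (residue, nucleus) quantifies how strongly
    that shift responds to secondary structure.
    """

    cog: dict[tuple[str, str, str], float]

    def __post_init__(self) -> None:
        for res in STANDARD_RESIDUES:
            if res == "G":
                continue
            for nuc in ("CA", "CB"):
                h = self.cog.get((res, nuc, "helix"))
                e = self.cog.get((res, nuc, "extended"))
                if h is not None and e is not None and h == e:
                    raise ValueError(
                        f"degenerate helix/extended centers for ({res}, {nuc})"
                    )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoGTable":
        df = _read_table_csv(Path(path))
        return cls({
            (r.residue, r.nucleus, r.ss_class): float(r.shift)
            for r in df.itertuples()
        })

    @classmethod
    def default(cls) -> "CoGTable":
        return cls.from_csv(_data_path("cog.csv"))

    def span(self, restype: str, nucleus: str) -> float | None:
        """CoG_helix − CoG_extended, or None if the nucleus is absent."""
        if nucleus not in _nuclei_for(restype):
            return None
        try:
            return (self.cog[(restype, nucleus, "helix")]
                    - self.cog[(restype, nucleus, "extended")])
        except KeyError as e:
            raise TableCoverageError(f"CoG table lacks ({restype}, {nucleus})") from e


@dataclass
class PredictorInputTable:
    """Per-residue shift table ready for an external φ/ψ predictor."""

    sequence: str
    shifts: list[dict[str, float]]
    roi_index: int

    def __post_init__(self) -> None:
        if len(self.shifts) != len(self.sequence):
            raise ValueError("one shift record per residue required")
        if not 0 <= self.roi_index < len(self.sequence):
            raise ValueError("roi_index out of range")
        for res, rec in zip(self.sequence, self.shifts):
            allowed = set(_nuclei_for(res))
            extra = set(rec) - allowed
            if extra:
                raise ValueError(f"residue {res} cannot carry shifts for {extra}")


def deviation_vector(grid_point: GridPoint, sequence: str, roi_index: int,
                     rc: RandomCoilTable) -> dict[str, float]:
    """Secondary-shift deviation r_i of the ROI, per observed nucleus.

    r_i = grid-point shifts − neighbor-corrected random-coil shifts of the
    ROI residue in its sequence context.
    """
    if not 0 <= roi_index < len(sequence):
        raise ValueError("roi_index out of range")
    res = sequence[roi_index]
    obs = dict(zip(NUCLEI, grid_point.shifts))
    return {
        nuc: obs[nuc] - rc.shift(sequence, roi_index, nuc)
        for nuc in _nuclei_for(res)
        if nuc in obs
    }


def rescale_factor(roi_type: str, neighbor_type: str, nucleus: str,
                   cog: CoGTable) -> float:
    """Ratio of helix−extended CoG spans: span(neighbor) / span(ROI).

    Returns 0 when the neighbor type lacks the nucleus (e.g. Gly Cβ), so
    that nucleus simply stays at the neighbor's random-coil value.
    """
    nb_span = cog.span(neighbor_type, nucleus)
    if nb_span is None:
        return 0.0
    roi_span = cog.span(roi_type, nucleus)
    if roi_span is None or roi_span == 0.0:
        raise DegenerateSpanError(
            f"ROI type {roi_type} has no usable {nucleus} helix/extended span"
        )
    return nb_span / roi_span


def translate_to_neighbors(grid_point: GridPoint, sequence: str, roi_index: int,
                           rc: RandomCoilTable, cog: CoGTable,
                           pad: str = "G", n_pad: int = 1) -> PredictorInputTable:
    """Build the predictor input table for one grid point.

    The ROI keeps the grid point's shifts verbatim; residues at j±1 and j±2
    receive their own neighbor-corrected random-coil shifts plus the
    rescaled deviation r_i; farther residues (and padding) sit at plain
    neighbor-corrected random-coil shifts.
    """
    if n_pad < 0:
        raise ValueError("n_pad must be non-negative")
    if not 0 <= roi_index < len(sequence):
        raise ValueError("roi_index out of range")
    padded = pad * n_pad + sequence + pad * n_pad
    roi = roi_index + n_pad
    r_i = deviation_vector(grid_point, padded, roi, rc)
    roi_type = padded[roi]
    obs = dict(zip(NUCLEI, grid_point.shifts))

    records: list[dict[str, float]] = []
    for j, res in enumerate(padded):
        rec: dict[str, float] = {}
        offset = abs(j - roi)
        for nuc in _nuclei_for(res):
            if j == roi:
                if nuc in obs:
                    rec[nuc] = obs[nuc]
                continue
            v = rc.shift(padded, j, nuc)
            if 1 <= offset <= 2 and nuc in r_i:
                v += rescale_factor(roi_type, res, nuc, cog) * r_i[nuc]
            rec[nuc] = v
        records.append(rec)
    return PredictorInputTable(sequence=padded, shifts=records, roi_index=roi)


_ATOM_NAMES = {"H": "HN", "N": "N", "CA": "CA", "CB": "CB"}
_ATOM_TO_NUC = {v: k for k, v in _ATOM_NAMES.items()}


def write_predictor_input(table: PredictorInputTable, path: str | Path,
                          dialect: str = "talos") -> None:
    """Write a predictor-ready shift table (TALOS-style ``.tab`` dialect)."""
    if dialect != "talos":
        raise AdapterError(f"unsupported predictor dialect {dialect!r}")
    lines = [
        "REMARK predictor input written by ramapeak",
        f"REMARK ROI_INDEX {table.roi_index + 1}",
        "DATA FIRST_RESID 1",
        f"DATA SEQUENCE {table.sequence}",
        "",
        "VARS   RESID RESNAME ATOMNAME SHIFT",
        "FORMAT %4d   %1s     %4s      %8.3f",
        "",
    ]
    for i, (res, rec) in enumerate(zip(table.sequence, table.shifts), start=1):
        for nuc in NUCLEI:
            if nuc in rec:
                lines.append(f"{i:4d} {res:>1s} {_ATOM_NAMES[nuc]:>4s} {rec[nuc]:8.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictor_input(path: str | Path) -> PredictorInputTable:
    """Parse a TALOS-style shift table written by :func:`write_predictor_input`."""
    sequence = None
    roi_index = None
    records: dict[int, dict[str, float]] = {}
    for ln in Path(path).read_text().splitlines():
        s = ln.strip()
        if not s:
            continue
        if s.startswith("REMARK ROI_INDEX"):
            roi_index = int(s.split()[-1]) - 1
        elif s.startswith("DATA SEQUENCE"):
            sequence = s.split()[-1]
        elif s.startswith(("REMARK", "DATA", "VARS", "FORMAT")):
            continue
        else:
            parts = s.split()
            if len(parts) != 4:
                raise AdapterError(f"malformed shift line {ln!r}")
            resid, _, atom, shift = parts
            nuc = _ATOM_TO_NUC.get(atom)
            if nuc is None:
                raise AdapterError(f"unknown atom name {atom!r}")
            records.setdefault(int(resid) - 1, {})[nuc] = float(shift)
    if sequence is None:
        raise AdapterError(f"{path}: missing DATA SEQUENCE header")
    shifts = [records.get(i, {}) for i in range(len(sequence))]
    return PredictorInputTable(sequence=sequence, shifts=shifts,
                               roi_index=roi_index if roi_index is not None else 0)
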