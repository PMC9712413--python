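"""End-to-end orchestration of the prediction and database branches.

``run_prediction_branch`` samples the peak on the chemical-shift lattice,
obtains a per-grid-point φ/ψ probability map (from pre-computed external
predictor output files, or from the built-in mock predictor), aggregates
the maps weighted by grid-point intensity, folds, and scores.

``run_database_branch`` selects database entries under the peak envelope,
weights them by intensity over local entry density, bins the weighted
dihedral angles, folds, and scores.

Both return the folded map, its heterogeneity scores, and a manifest
(DataFrame) of the grid points / selected entries, plus a provenance record
sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import dbmatch, ramachandran, scores, spectral_io, synthetic
from .ramachandran import RamachandranMap
from .scores import HeterogeneityScores, default_masks
from .shift_translation import (
    CoGTable,
    RandomCoilTable,
    translate_to_neighbors,
    write_predictor_input,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "BranchResult", "run_prediction_branch",
           "run_database_branch", "make_predictor_inputs"]


@dataclass
class RunConfig:
    """Configuration for one single-peak analysis run."""

    peak_path: str | None = None
    axis_order: tuple[str, ...] | None = None
    branch: str = "both"
    spacings: tuple[float, float, float, float] = (0.4, 1.5, 1.0, 1.5)
    threshold_fraction: float = 0.2
    probe_mode: str = "interpolated"
    sequence: str = "GGAGG"
    roi_index: int = 2
    pad: str = "G"
    n_pad: int = 1
    predictor: str = "mock"          # "mock" or "files"
    predictor_dir: str | None = None  # per-grid-point output files
    predictor_dialect: str = "table"
    missing_prediction: str = "error"  # or "skip"
    database_path: str | None = None
    bandwidths: tuple[float, float, float, float] = (0.4, 1.5, 1.0, 1.5)
    density_method: str = "kde"
    density_scope: str = "envelope"
    min_entries: int = 20
    phi_convention: str = "raw"
    flatness_convention: str = "complement"
    h_mask_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (-120.0, -40.0), (-70.0, 10.0))
    e_mask_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (-180.0, -80.0), (100.0, 180.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.branch not in ("prediction", "database", "both"):
            raise ValueError(f"unknown branch {self.branch!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) and k != "axis_order"
                     else v for k, v in raw.items()})
        if cfg.axis_order is not None:
            cfg.axis_order = tuple(cfg.axis_order)
        return cfg

    def masks(self):
        h = scores.RegionMask.from_ranges("H", *self.h_mask_ranges)
        e = scores.RegionMask.from_ranges("E", *self.e_mask_ranges)
        return h, e

    def provenance(self) -> dict:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return {"config": d, "config_sha256": hashlib.sha256(blob).hexdigest(),
                "seed": self.seed}


@dataclass
class BranchResult:
    """Folded map, scores, and per-element manifest for one branch run."""

    map: RamachandranMap
    scores: HeterogeneityScores
    manifest: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _load_peak(config: RunConfig) -> spectral_io.PeakRegion:
    if config.peak_path is None:
        raise ValueError("config.peak_path is required")
    return spectral_io.read_spectrum(config.peak_path, config.axis_order)


def make_predictor_inputs(config: RunConfig, out_dir: str | Path,
                          rc: RandomCoilTable | None = None,
                          cog: CoGTable | None = None,
                          peak: spectral_io.PeakRegion | None = None,
                          ) -> pd.DataFrame:
    """Write one predictor input table per grid point; return the manifest."""
    rc = rc or RandomCoilTable.default()
    cog = cog or CoGTable.default()
    peak = peak if peak is not None else _load_peak(config)
    points = spectral_io.sample_grid(peak, config.spacings,
                                     config.threshold_fraction, config.probe_mode)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for gp in points:
        table = translate_to_neighbors(gp, config.sequence, config.roi_index,
                                       rc, cog, config.pad, config.n_pad)
        fname = out_dir / f"point_{gp.index:05d}.tab"
        write_predictor_input(table, fname)
        rows.append({"index": gp.index, "H": gp.shifts[0], "N": gp.shifts[1],
                     "CA": gp.shifts[2], "CB": gp.shifts[3],
                     "intensity": gp.intensity, "input_file": str(fname)})
    logger.info("wrote %d predictor input tables to %s", len(points), out_dir)
    return pd.DataFrame(rows)


def run_prediction_branch(config: RunConfig,
                          peak: spectral_io.PeakRegion | None = None,
                          model: synthetic.ForwardModel | None = None,
                          reference_map: RamachandranMap | None = None,
                          ) -> BranchResult:
    """Grid-sample the peak, predict per point, aggregate, fold, score."""
    peak = peak if peak is not None else _load_peak(config)
    points = spectral_io.sample_grid(peak, config.spacings,
                                     config.threshold_fraction, config.probe_mode)
    if not points:
        raise ValueError("no grid points above threshold")
    maps, weights, rows = [], [], []
    missing = []
    for gp in points:
        if config.predictor == "mock":
            m = synthetic.mock_predictor(gp.shifts, model or synthetic.alanine_model())
        elif config.predictor == "files":
            if config.predictor_dir is None:
                raise ValueError("predictor='files' requires predictor_dir")
            f = Path(config.predictor_dir) / f"point_{gp.index:05d}.tab"
            if not f.is_file():
                missing.append(gp.index)
                continue
            m = ramachandran.parse_ann_output(f, config.predictor_dialect)
        else:
            raise ValueError(f"unknown predictor {config.predictor!r}")
        maps.append(m)
        weights.append(gp.intensity)
        rows.append({"index": gp.index, "H": gp.shifts[0], "N": gp.shifts[1],
                     "CA": gp.shifts[2], "CB": gp.shifts[3],
                     "intensity": gp.intensity})
    if missing:
        msg = f"missing predictor output for {len(missing)} grid points: {missing[:10]}"
        if config.missing_prediction == "error":
            raise FileNotFoundError(msg)
        logger.warning("%s (skipped)", msg)
    agg = ramachandran.aggregate(maps, weights)
    folded = ramachandran.fold(agg)
    sc = scores.score_all(folded, reference_map=reference_map,
                          masks=config.masks(),
                          phi_convention=config.phi_convention,
                          flatness_convention=config.flatness_convention)
    logger.info("prediction branch: %d grid points aggregated", len(maps))
    return BranchResult(folded, sc, pd.DataFrame(rows),
                        {**config.provenance(), "n_grid_points": len(maps),
                         "branch": "prediction"})


def run_database_branch(config: RunConfig,
                        peak: spectral_io.PeakRegion | None = None,
                        entries: list | None = None,
                        reference_map: RamachandranMap | None = None,
                        ) -> BranchResult:
    """Select entries in the envelope, weight, bin, fold, score."""
    peak = peak if peak is not None else _load_peak(config)
    if entries is None:
        if config.database_path is None:
            raise ValueError("config.database_path is required")
        entries = dbmatch.load_database(config.database_path)
    unfolded, weighted = dbmatch.reconstruct_map(
        entries, peak,
        threshold_fraction=config.threshold_fraction,
        bandwidths=config.bandwidths,
        density_method=config.density_method,
        density_scope=config.density_scope,
        min_entries=config.min_entries,
    )
    folded = ramachandran.fold(unfolded)
    sc = scores.score_all(folded, reference_map=reference_map,
                          masks=config.masks(),
                          phi_convention=config.phi_convention,
                          flatness_convention=config.flatness_convention)
    rows = [{"protein_id": w.entry.protein_id,
             "residue_number": w.entry.residue_number,
             "phi": w.entry.phi, "psi": w.entry.psi,
             "stride_class": w.entry.stride_class,
             "intensity": w.intensity, "density": w.density,
             "weight": w.weight} for w in weighted]
    logger.info("database branch: %d entries selected", len(weighted))
    return BranchResult(folded, sc, pd.DataFrame(rows),
                        {**config.provenance(), "n_selected": len(weighted),
                         "branch": "database"})
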