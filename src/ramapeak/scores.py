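"""Heterogeneity scores for folded φ/ψ probability maps.

Four families of scores summarize how conformationally heterogeneous the
ensemble behind a reconstructed map is:

* **circular variance** V_θ = 1 − |mean resultant vector| per angular axis,
  computed on the map's marginal; 0 for a single populated angle, 1 for a
  distribution with vanishing resultant;
* **Shannon entropy** S = −Σ_k D_k ln D_k (nats) on the full folded map
  (180 bins) and on its φ (10 bins) and ψ (18 bins) marginals, with the
  excess entropy ΔS = S − S_ref relative to a confined-helix reference;
* **flatness**, built from the relative abundance of the highest-probability
  bin, max(D_k)/Σ D_k; both that peak fraction and its complement are
  reported because either may be quoted as "flatness" depending on
  convention — a delta map has peak fraction 1, a uniform map ≈ 1/n;
* **secondary-structure ratio** R = max(H, E)/min(H, E), the population
  ratio of the helical and extended Ramachandran regions, flagged infinite
  when the minor region carries no mass.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from .ramachandran import (
    RamachandranMap,
    MapStateError,
    PHI_CENTERS_FOLDED,
    PSI_CENTERS,
    project,
)

__all__ = [
    "RegionMask",
    "HeterogeneityScores",
    "default_masks",
    "circular_variance",
    "entropy",
    "excess_entropy",
    "flatness",
    "ss_ratio",
    "score_all",
]


@dataclass(frozen=True)
class RegionMask:
    """Named subset of folded-lattice bins (boolean (10, 18) array)."""

    name: str
    member: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.member, dtype=bool)
        if m.shape != (10, 18):
            raise ValueError("mask must cover the folded 10×18 lattice")
        object.__setattr__(self, "member", m)

    @classmethod
    def from_ranges(cls, name: str, phi_range: tuple[float, float],
                    psi_range: tuple[float, float]) -> "RegionMask":
        """Rectangular mask: bin centers inside the closed degree ranges."""
        phis, psis = np.meshgrid(PHI_CENTERS_FOLDED, PSI_CENTERS, indexing="ij")
        m = ((phis >= phi_range[0]) & (phis <= phi_range[1])
             & (psis >= psi_range[0]) & (psis <= psi_range[1]))
        return cls(name, m)


def default_masks() -> tuple[RegionMask, RegionMask]:
    """Approximate helical / extended region masks on the folded lattice.

    H covers the (folded) α-helical basin, E the β/extended basin.  These
    rectangles are deliberately conservative and fully user-replaceable;
    they must stay disjoint.
    """
    h = RegionMask.from_ranges("H", (-120.0, -40.0), (-70.0, 10.0))
    e = RegionMask.from_ranges("E", (-180.0, -80.0), (100.0, 180.0))
    return h, e


@dataclass
class HeterogeneityScores:
    """All heterogeneity scores for one folded map.

    ``flatness_convention`` records whether ``F`` holds the raw peak
    fraction max(D)/ΣD or its complement; ``phi_convention`` records the
    angular convention used for V_φ on the folded (180°-period) axis.
    """

    V_phi: float
    V_psi: float
    S_phi: float
    S_psi: float
    S_total: float
    dS_total: float
    F: float
    peak_fraction: float
    flatness_complement: float
    R: float
    R_infinite: bool
    dominant: str
    H_mass: float
    E_mass: float
    phi_convention: str = "raw"
    flatness_convention: str = "complement"

    def to_dict(self) -> dict:
        return asdict(self)


def _check_folded_normalized(map_: RamachandranMap) -> None:
    if not map_.folded:
        raise MapStateError("scores are defined on folded maps")
    if not map_.normalized:
        raise MapStateError("scores are defined on normalized maps")


def circular_variance(map_: RamachandranMap, axis: str,
                      phi_convention: str = "raw") -> float:
    """Circular variance V = 1 − |mean resultant| of the marginal on ``axis``.

    Every bin contributes a unit vector at its center angle θ_k weighted by
    D_k.  After folding the φ marginal only spans [−180°, 0°] (a 180°
    period); ``phi_convention`` selects how that is handled:

    * ``"raw"`` (default): θ_k taken verbatim as bin-center degrees;
    * ``"doubled"``: θ_k doubled before the resultant is formed, the usual
      treatment for axial data with a π period.

    The convention applies to the φ axis only; ψ always retains its full
    360° period.
    """
    _check_folded_normalized(map_)
    p = project(map_, axis)
    if axis == "phi":
        theta = np.deg2rad(PHI_CENTERS_FOLDED)
        if phi_convention == "doubled":
            theta = 2.0 * theta
        elif phi_convention != "raw":
            raise ValueError(f"unknown phi convention {phi_convention!r}")
    else:
        theta = np.deg2rad(PSI_CENTERS)
    c = float(np.sum(np.cos(theta) * p))
    s = float(np.sum(np.sin(theta) * p))
    return float(np.clip(1.0 - np.hypot(c, s), 0.0, 1.0))


def entropy(density: np.ndarray | RamachandranMap) -> float:
    """Shannon entropy −Σ D_k ln D_k (nats) of a normalized density.

    Accepts a folded map (180 bins) or a 1-D marginal; zero-probability
    bins contribute 0 by the 0·ln 0 := 0 convention.
    """
    if isinstance(density, RamachandranMap):
        _check_folded_normalized(density)
        d = density.density.ravel()
    else:
        d = np.asarray(density, dtype=float).ravel()
    if (d < 0).any():
        raise ValueError("negative density")
    s = d.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        raise ValueError(f"density must be normalized to unit sum (got {s})")
    nz = d[d > 0]
    return float(-(nz * np.log(nz)).sum())


def excess_entropy(S: float, S_ref: float) -> float:
    """ΔS = S − S_ref, the entropy in excess of a confined reference state."""
    return float(S - S_ref)


def flatness(map_: RamachandranMap) -> tuple[float, float]:
    """(peak_fraction, complement) of the highest-probability bin.

    peak_fraction = max(D_k) / Σ D_k; the complement 1 − peak_fraction grows
    with flatter distributions.  Which of the two is reported as the
    flatness score F is a convention choice handled by :func:`score_all`.
    """
    if not map_.folded:
        raise MapStateError("flatness is defined on folded maps")
    total = map_.density.sum()
    if total <= 0:
        raise ValueError("zero-mass map")
    pf = float(map_.density.max() / total)
    return pf, 1.0 - pf


def ss_ratio(map_: RamachandranMap,
             masks: tuple[RegionMask, RegionMask] | None = None
             ) -> tuple[float, bool, str, float, float]:
    """Population ratio of the helical and extended regions.

    Returns ``(R, is_infinite, dominant, H_mass, E_mass)`` with
    R = max(H, E)/min(H, E) ≥ 1; when the minor region holds no mass R is
    reported as ``inf`` with the infinite flag set.
    """
    _check_folded_normalized(map_)
    if masks is None:
        masks = default_masks()
    h_mask, e_mask = masks
    if (h_mask.member & e_mask.member).any():
        raise ValueError("H and E masks must be disjoint")
    H = float(map_.density[h_mask.member].sum())
    E = float(map_.density[e_mask.member].sum())
    if H == 0.0 and E == 0.0:
        raise ValueError("both region masses are zero; R undefined")
    dominant = "H" if H > E else "E"
    lo, hi = min(H, E), max(H, E)
    if lo == 0.0:
        return float("inf"), True, dominant, H, E
    return hi / lo, False, dominant, H, E


def score_all(map_: RamachandranMap,
              reference_map: RamachandranMap | None = None,
              masks: tuple[RegionMask, RegionMask] | None = None,
              phi_convention: str = "raw",
              flatness_convention: str = "complement",
              S_ref: float | None = None) -> HeterogeneityScores:
    """Compute every heterogeneity score for one folded, normalized map.

    The excess entropy uses ``reference_map``'s total entropy (typically a
    confined-helix prediction), or an explicit ``S_ref`` in nats; with
    neither given ΔS is reported as 0 relative to the map itself.
    """
    _check_folded_normalized(map_)
    if S_ref is None:
        if reference_map is not None:
            S_ref = entropy(reference_map)
        else:
            S_ref = None
    S_total = entropy(map_)
    S_phi = entropy(project(map_, "phi"))
    S_psi = entropy(project(map_, "psi"))
    pf, comp = flatness(map_)
    if flatness_convention == "complement":
        F = comp
    elif flatness_convention == "peak_fraction":
        F = pf
    else:
        raise ValueError(f"unknown flatness convention {flatness_convention!r}")
    R, inf_flag, dominant, H, E = ss_ratio(map_, masks)
    return HeterogeneityScores(
        V_phi=circular_variance(map_, "phi", phi_convention),
        V_psi=circular_variance(map_, "psi"),
        S_phi=S_phi,
        S_psi=S_psi,
        S_total=S_total,
        dS_total=excess_entropy(S_total, S_ref if S_ref is not None else S_total),
        F=F,
        peak_fraction=pf,
        flatness_complement=comp,
        R=R,
        R_infinite=inf_flag,
        dominant=dominant,
        H_mass=H,
        E_mass=E,
        phi_convention=phi_convention,
        flatness_convention=flatness_convention,
    )
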