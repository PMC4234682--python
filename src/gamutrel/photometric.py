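"""Mapping from luminance to blackness-whiteness coordinates.

Two vector-valued signals compose the brightness-mode representation of a
region:

* a *luminance vector*, anchored at the display's highest luminance, which
  places every region on the standard luminance gamut line; and
* a *contrast vector*, computed from log-luminance ratios between the region
  and the lower/higher-luminance components of its surround, which displaces
  the point off the luminance gamut (onto an increment, decrement or mixed
  gamut).

The brightness coordinates of a region are the component-wise sum of the
two.  Anchoring follows a highest-luminance rule with an absolute white
threshold: displays whose maximum luminance falls below ``L_white`` contain
no white surface and all points are shifted toward blackness by a fixed
dark-anchor offset.

The blackness axis is scaled more steeply than the whiteness axis (default
ratio 3 for both the gamut intercepts and the contrast gains): a unit change
in log luminance moves a point at least three times as far in blackness as
in whiteness.  This asymmetry is a load-bearing property of the model — it
is what biases predicted matches on black-and-white checkered test displays
toward higher luminances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .bw_space import BWVector, GamutLine
from .segmentation import region_adjacency

__all__ = [
    "RegionMap",
    "MappingConfig",
    "DisplayAnchor",
    "SurroundStats",
    "region_geometric_mean",
    "display_anchor",
    "luminance_vector",
    "surround_stats",
    "contrast_vector",
    "brightness_coordinates",
]

@dataclass
class RegionMap:
    """A luminance raster with integer region labels and region adjacency.

    luminance : 2-D array of cd/m^2, strictly positive (the log transform
        must be defined everywhere).
    labels : integer raster of the same shape; every pixel carries exactly
        one label.
    adjacency : mapping from each region label to the set of neighbouring
        labels; computed from the rasters (4-connectivity) when omitted.
    """

    luminance: np.ndarray
    labels: np.ndarray
    adjacency: dict[int, set[int]] | None = None
    connectivity: int = 4
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.luminance = np.asarray(self.luminance, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.luminance.size == 0:
            raise ValueError("empty luminance raster")
        if self.luminance.shape != self.labels.shape:
            raise ValueError(
                f"luminance shape {self.luminance.shape} != label shape {self.labels.shape}"
            )
        if not np.all(np.isfinite(self.luminance)) or np.any(self.luminance <= 0):
            raise ValueError("all luminances must be strictly positive and finite")
        if self.adjacency is None:
            self.adjacency = region_adjacency(self.labels, self.connectivity)

    @property
    def region_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels)]

    def region_mask(self, region) -> np.ndarray:
        members = _as_label_set(region)
        mask = np.isin(self.labels, sorted(members))
        if not mask.any():
            raise ValueError(f"region {region!r} has no member pixels")
        return mask

    def neighbours(self, region) -> set[int]:
        """Labels adjacent to a region (or to a group of regions, excluding
        the group itself)."""
        members = _as_label_set(region)
        out: set[int] = set()
        for m in members:
            if m not in self.adjacency:
                raise ValueError(f"unknown region label {m}")
            out |= self.adjacency[m]
        return out - members


def _as_label_set(region) -> set[int]:
    if isinstance(region, (int, np.integer)):
        return {int(region)}
    members = {int(r) for r in region}
    if not members:
        raise ValueError("empty region group")
    return members


@dataclass(frozen=True)
class MappingConfig:
    """Constants of the luminance and contrast mappings.

    w0, b0 : whiteness and blackness intercepts of the standard luminance
        gamut (b0/w0 >= 3 by default: the asymmetric scaling of the space).
    kappa : gamut-line parameter gain per unit log10 luminance below the
        anchor.
    k_w, k_b : contrast gains (whiteness per positive log10 ratio, blackness
        per negative-polarity log10 ratio; k_b/k_w >= 3 by default).
    L_white : absolute luminance threshold (cd/m^2) for the white-anchoring
        rule.
    dark_anchor_offset : fixed positive line-parameter offset applied when
        no luminance reaches L_white (such scenes contain no white surface).
    """

    w0: float = 1.0
    b0: float = 3.0
    kappa: float = 1.0
    k_w: float = 0.25
    k_b: float = 0.75
    L_white: float = 25.0
    dark_anchor_offset: float = 0.2

    def __post_init__(self) -> None:
        for name in ("w0", "b0", "kappa", "k_w", "k_b", "L_white"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MappingConfig.{name} must be > 0")
        if self.dark_anchor_offset < 0:
            raise ValueError("dark_anchor_offset must be >= 0")

    def standard_gamut(self) -> GamutLine:
        return GamutLine(self.w0, self.b0, role="standard-luminance")


@dataclass(frozen=True)
class DisplayAnchor:
    """Anchoring state of a display: its maximum luminance and whether that
    maximum qualifies as white."""

    L_max: float
    white_present: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.L_max) or self.L_max <= 0:
            raise ValueError(f"anchor luminance must be positive, got {self.L_max}")


@dataclass(frozen=True)
class SurroundStats:
    """Photometry of a target region and its surround.

    L_T : target geometric-mean luminance (cd/m^2).
    L_L / L_H : geometric-mean luminance of the lower-/higher-luminance
        surround component (each equals L_T when that component is absent).
    p : proportion of the surround with luminance higher than the target.
    q : polarity flag — 1 when the target is a decrement (surround geometric
        mean above target), 0 when it is an increment.
    """

    L_T: float
    L_L: float
    L_H: float
    p: float
    q: int

    def __post_init__(self) -> None:
        if not (0 < self.L_L <= self.L_T <= self.L_H):
            raise ValueError(
                f"surround stats must satisfy 0 < L_L <= L_T <= L_H, "
                f"got L_L={self.L_L}, L_T={self.L_T}, L_H={self.L_H}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.q not in (0, 1):
            raise ValueError(f"q must be 0 or 1, got {self.q}")


def region_geometric_mean(rm: RegionMap, region) -> float:
    """Geometric-mean luminance of a region (or group of regions), cd/m^2.

    The geometric mean (antilog of the mean log luminance) is the natural
    regional statistic under the model's logarithmic mapping, and is exact
    for the piecewise-constant and gradient displays the model targets.
    """
    values = rm.luminance[rm.region_mask(region)]
    return float(np.exp(np.mean(np.log(values))))


def display_anchor(rm: RegionMap, cfg: MappingConfig) -> DisplayAnchor:
    """Highest-luminance anchoring rule for a display."""
    L_max = float(rm.luminance.max())
    return DisplayAnchor(L_max=L_max, white_present=L_max >= cfg.L_white)


def luminance_vector(
    L: float,
    anchor: DisplayAnchor,
    cfg: MappingConfig,
    *,
    saturate: bool = True,
) -> BWVector:
    """Map a luminance to its point on the standard luminance gamut.

    With ``u = log10(L_max / L)``, the gamut-line parameter is
    ``t = kappa * u``, plus the dark-anchor offset when the display contains
    no white surface.  When ``saturate`` is true (the default, appropriate
    for presentation) ``t`` is clipped at 1 so the point stays inside the
    segment between the intercepts; the layer-decomposition pipeline uses
    the unsaturated (extended-line) coordinates so that illuminant shifts
    commute exactly with the mapping.
    """
    if not math.isfinite(L) or L <= 0:
        raise ValueError(f"luminance must be positive and finite, got {L}")
    if L > anchor.L_max * (1.0 + 1e-12):
        raise ValueError(
            f"luminance {L} exceeds the display anchor L_max={anchor.L_max}"
        )
    u = math.log10(anchor.L_max / min(L, anchor.L_max))
    t = cfg.kappa * u
    if not anchor.white_present:
        t += cfg.dark_anchor_offset
    if saturate:
        t = min(1.0, t)
    return BWVector(t * cfg.b0, (1.0 - t) * cfg.w0)


def surround_stats(
    rm: RegionMap,
    target,
    p_override: float | None = None,
) -> SurroundStats:
    """Photometric statistics of a target's surround.

    Adjacent regions are split into lower- and higher-than-target sets by
    their geometric-mean luminance; the component means are pixel-area
    weighted geometric means, and ``p`` is the area fraction of the surround
    occupied by the higher set (overridable, mirroring by-hand settings).
    """
    L_T = region_geometric_mean(rm, target)
    neighbours = rm.neighbours(target)
    if not neighbours:
        raise ValueError(
            f"region {target!r} has no neighbours; supply explicit SurroundStats"
        )
    lower_px: list[np.ndarray] = []
    higher_px: list[np.ndarray] = []
    for nb in sorted(neighbours):
        vals = rm.luminance[rm.labels == nb]
        gm = float(np.exp(np.mean(np.log(vals))))
        (higher_px if gm > L_T else lower_px).append(vals)
    n_low = sum(v.size for v in lower_px)
    n_high = sum(v.size for v in higher_px)
    L_L = float(np.exp(np.mean(np.log(np.concatenate(lower_px))))) if n_low else L_T
    L_H = float(np.exp(np.mean(np.log(np.concatenate(higher_px))))) if n_high else L_T
    # Guard against a component mean crossing the target due to within-region
    # spread: fold such a component into the target level (zero log ratio).
    L_L = min(L_L, L_T)
    L_H = max(L_H, L_T)
    p = float(p_override) if p_override is not None else n_high / (n_low + n_high)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p_override must lie in [0, 1], got {p}")
    surround_all = np.concatenate(lower_px + higher_px)
    surround_gm = float(np.exp(np.mean(np.log(surround_all))))
    q = 1 if surround_gm > L_T else 0
    return SurroundStats(L_T=L_T, L_L=L_L, L_H=L_H, p=p, q=q)


def contrast_vector(st: SurroundStats, cfg: MappingConfig) -> BWVector:
    """Contrast vector of a target given its surround statistics.

    Whiteness component ``k_w * (1 - p) * log10(L_T / L_L)`` and blackness
    component ``k_b * p * log10(L_H / L_T)``; both are always non-negative.
    A pure increment carries only whiteness, a pure decrement only
    blackness, and a mixed (bracketing) surround carries both.
    """
    cw = cfg.k_w * (1.0 - st.p) * math.log10(st.L_T / st.L_L)
    cb = cfg.k_b * st.p * math.log10(st.L_H / st.L_T)
    return BWVector(cb, cw)


def brightness_coordinates(
    rm: RegionMap,
    target,
    cfg: MappingConfig,
    anchor: DisplayAnchor | None = None,
    p_override: float | None = None,
    *,
    saturate: bool = True,
) -> BWVector:
    """Brightness-mode coordinates of a region: luminance + contrast vector."""
    if anchor is None:
        anchor = display_anchor(rm, cfg)
    st = surround_stats(rm, target, p_override=p_override)
    lv = luminance_vector(st.L_T, anchor, cfg, saturate=saturate)
    return lv + contrast_vector(st, cfg)
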