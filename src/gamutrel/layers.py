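"""Illuminant- and transmittance-shift layer decompositions.

Two vector decompositions turn brightness-mode coordinates into layered
representations:

* The **illuminant shift** discounts a perceived illumination difference.
  Regions assigned to the *dim* framework have a pure-blackness *shadow
  vector* subtracted from their luminance vectors, landing them on a
  comparison gamut line parallel to the standard one.  The pre-shift vector
  decomposes exactly into surface + shadow, so equal-reflectance surfaces
  across the two frameworks end up with identical blackness coordinates
  (lightness constancy), while the shadow itself is represented as a
  separate pure-blackness layer.

* The **transmittance shift** discounts a transparent medium.  Within a
  target region whose contrast polarity is preserved around its whole
  perimeter, each pixel's coordinates decompose into a *figure* vector
  (clamped to the constraint line through the plain-view anchor pixel) and
  an orthogonal *ground* vector representing the medium.  For increments
  (blackish medium) the shift acts on blackness; for decrements (whitish
  medium) on whiteness.

The two shifts are gated by ``tau`` (illumination) and ``delta``
(scission).  ``tau`` composes multiplicatively from a stimulus term (does
the display support a variable-illumination percept at all?) and a task
term (brightness vs lightness instructions): instructions can only matter
when the stimulus supports variable illumination.  Simultaneous variation
of both illumination and transmittance is not supported.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .bw_space import BWVector, GamutLine, distance
from .photometric import (
    DisplayAnchor,
    MappingConfig,
    RegionMap,
    contrast_vector,
    display_anchor,
    luminance_vector,
    region_geometric_mean,
    surround_stats,
)

__all__ = [
    "SceneParse",
    "LayeredRepresentation",
    "effective_tau",
    "shadow_vector",
    "comparison_gamut",
    "apply_illuminant_shift",
    "perimeter_polarity",
    "transmittance_decompose",
    "layering_inequality",
    "region_coordinates",
    "decompose_scene",
]


class OverDiscountingWarning(UserWarning):
    """Raised (as a warning) when a shift drives a coordinate below zero."""


@dataclass
class SceneParse:
    """Stimulus- and task-driven constraints on the decomposition of a scene.

    framework : per-region assignment to the 'bright' or 'dim' illumination
        framework.
    tau_stim : 0 or 1 — whether the display supports a variable-illumination
        percept at all.
    tau_task : in [0, 1] — 0 for brightness instructions, 1 for lightness
        instructions.
    delta : in [0, 1] — scission strength; 1 requires figural continuity and
        preserved contrast polarity around the whole target perimeter.
    plain_view_anchor : region label of the plain-view extremum within the
        target (whitest sub-region for increments, blackest for decrements).
    bright_anchor_region / dim_anchor_region : highest-luminance region
        within each framework.
    target_regions : labels forming the figural target (gradient targets are
        discretised into several constant sub-regions).
    polarity : 0 (increment) or 1 (decrement), or None to infer it from the
        target perimeter.
    """

    framework: dict[int, str] = field(default_factory=dict)
    tau_stim: int = 0
    tau_task: float = 0.0
    delta: float = 0.0
    plain_view_anchor: int | None = None
    bright_anchor_region: int | None = None
    dim_anchor_region: int | None = None
    target_regions: tuple[int, ...] = ()
    polarity: int | None = None

    def __post_init__(self) -> None:
        if self.tau_stim not in (0, 1):
            raise ValueError(f"tau_stim must be 0 or 1, got {self.tau_stim}")
        if not 0.0 <= self.tau_task <= 1.0:
            raise ValueError(f"tau_task must lie in [0, 1], got {self.tau_task}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        bad = {v for v in self.framework.values()} - {"bright", "dim"}
        if bad:
            raise ValueError(f"framework values must be 'bright' or 'dim', got {bad}")
        if self.tau_stim == 1 and self.framework:
            if not any(v == "dim" for v in self.framework.values()):
                raise ValueError(
                    "tau_stim=1 requires a non-empty dim framework"
                )
        self.target_regions = tuple(int(r) for r in self.target_regions)
        if self.polarity is not None and self.polarity not in (0, 1):
            raise ValueError(f"polarity must be 0, 1 or None, got {self.polarity}")

    def dim_regions(self) -> set[int]:
        return {r for r, f in self.framework.items() if f == "dim"}

    def bright_regions(self) -> set[int]:
        return {r for r, f in self.framework.items() if f == "bright"}

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["framework"] = {str(k): v for k, v in self.framework.items()}
        d["target_regions"] = list(self.target_regions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParse":
        d = dict(d)
        d["framework"] = {int(k): v for k, v in d.get("framework", {}).items()}
        d["target_regions"] = tuple(d.get("target_regions", ()))
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SceneParse":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class LayeredRepresentation:
    """Per-region layer vectors produced by a decomposition.

    ``surface`` holds the surface (illumination case) or figure
    (transmittance case) vector of each region; ``ground`` the transparent
    medium displacement anchored at the plain-view point (zero under the
    illuminant shift); ``shadow`` the shared pure-blackness shadow vector
    (zero under the transmittance shift); ``pre_shift`` the undecomposed
    coordinates, so conservation can be checked directly.
    """

    surface: dict[int, BWVector]
    shadow: BWVector = field(default_factory=lambda: BWVector(0.0, 0.0))
    ground: dict[int, BWVector] = field(default_factory=dict)
    pre_shift: dict[int, BWVector] = field(default_factory=dict)
    comparison_gamut: GamutLine | None = None
    plain_view: BWVector | None = None

    def to_json(self, path) -> None:
        rec = {
            "shadow": self.shadow.as_tuple(),
            "regions": {
                str(r): {
                    "figure": self.surface[r].as_tuple(),
                    "ground": self.ground.get(r, BWVector(0.0, 0.0)).as_tuple(),
                    "pre_shift": self.pre_shift.get(r, self.surface[r]).as_tuple(),
                }
                for r in self.surface
            },
        }
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=2, sort_keys=True)


def effective_tau(parse: SceneParse) -> float:
    """Illuminant-shift gate: tau = tau_stim * tau_task.

    The task term can only exert an influence when the stimulus supports a
    variable-illumination percept (tau_stim = 1)."""
    return parse.tau_stim * parse.tau_task


def shadow_vector(
    L_H_bright: float,
    L_H_dim: float,
    tau: float,
    cfg: MappingConfig,
) -> BWVector:
    """Pure-blackness shadow vector from the framework anchor ratio.

    blackness = tau * b0 * kappa * log10(L_H_bright / L_H_dim); whiteness 0.
    """
    if L_H_bright <= 0 or L_H_dim <= 0:
        raise ValueError("framework anchor luminances must be positive")
    if L_H_bright < L_H_dim * (1.0 - 1e-12):
        raise ValueError(
            "bright-framework anchor dimmer than dim-framework anchor: "
            "framework labelling inconsistent"
        )
    ratio = max(L_H_bright / L_H_dim, 1.0)
    return BWVector(tau * cfg.b0 * cfg.kappa * math.log10(ratio), 0.0)


def comparison_gamut(shadow: BWVector, cfg: MappingConfig) -> GamutLine:
    """The comparison luminance gamut introduced by a shadow vector.

    Represented as the standard gamut translated by minus the shadow vector:
    exactly parallel, with effective whiteness intercept
    ``w0 * (1 - shadow_blackness / b0)`` — strictly smaller than the
    standard's whenever the shadow is non-zero.
    """
    return GamutLine(
        cfg.w0,
        cfg.b0,
        offset=BWVector(-shadow.blackness, 0.0),
        role="comparison-luminance",
    )


def apply_illuminant_shift(
    coords: dict[int, BWVector],
    parse: SceneParse,
    shadow: BWVector,
    cfg: MappingConfig,
) -> LayeredRepresentation:
    """Subtract the shadow vector from dim-framework luminance vectors.

    ``coords`` are per-region luminance-vector parts (contrast vectors are
    added afterwards).  The shift is applied asymmetrically — only to
    regions in the dim framework — and touches blackness only.  For every
    dim region the identity ``pre_shift = surface + shadow`` holds exactly
    unless the shift drives blackness negative, in which case the surface is
    clamped at zero with a warning (over-discounting).
    """
    dim = parse.dim_regions()
    surface: dict[int, BWVector] = {}
    for r, v in coords.items():
        if r in dim:
            b = v.blackness - shadow.blackness
            if b < -1e-12:
                warnings.warn(
                    f"illuminant shift drove blackness of region {r} to {b:.4g}; "
                    "clamped to 0 (over-discounting)",
                    OverDiscountingWarning,
                    stacklevel=2,
                )
            # Snap rounding residue (the dim anchor lands at exactly zero).
            b = max(b, 0.0)
            surface[r] = BWVector(b, v.whiteness)
        else:
            surface[r] = v
    return LayeredRepresentation(
        surface=surface,
        shadow=shadow,
        pre_shift=dict(coords),
        comparison_gamut=comparison_gamut(shadow, cfg) if shadow.blackness > 0 else None,
    )


def perimeter_polarity(rm: RegionMap, target_regions) -> int:
    """Contrast polarity of a target against its whole perimeter.

    Returns 0 when every neighbouring region is dimmer than every target
    sub-region (figural increment) and 1 when every neighbour is brighter
    (figural decrement).  A mixed perimeter breaks the polarity-preservation
    gate for scission and raises instead; callers should then set delta = 0.
    """
    targets = set(int(r) for r in (target_regions if not isinstance(target_regions, (int, np.integer)) else [target_regions]))
    t_gms = [region_geometric_mean(rm, r) for r in sorted(targets)]
    nb_gms = [region_geometric_mean(rm, r) for r in sorted(rm.neighbours(targets))]
    if not nb_gms:
        raise ValueError("target has no perimeter neighbours")
    if max(nb_gms) < min(t_gms):
        return 0
    if min(nb_gms) > max(t_gms):
        return 1
    raise ValueError(
        "mixed-polarity target perimeter: scission gate not satisfied "
        "(set delta = 0)"
    )


def transmittance_decompose(
    pixels: dict[int, BWVector],
    P: BWVector,
    q: int,
    delta: float,
) -> tuple[dict[int, BWVector], dict[int, BWVector]]:
    """Decompose target coordinates into figure and ground layers.

    For an increment target (``q = 0``, blackish medium) the ground vector of
    pixel *i* is ``delta * (b_i - b_P, 0)`` and the figure vector is the
    remainder; for a decrement (``q = 1``, whitish medium) the shift acts on
    whiteness instead.  ``P`` is the coordinates of the plain-view anchor
    pixel (the whitest target pixel for q = 0, the blackest for q = 1).  At
    ``delta = 1`` the figure displacement from ``P`` and the ground vector
    are orthogonal components of ``pixel - P``, and all figure points line
    up on the constraint line through ``P``.
    """
    if q not in (0, 1):
        raise ValueError(f"polarity q must be 0 or 1, got {q}")
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    figure: dict[int, BWVector] = {}
    ground: dict[int, BWVector] = {}
    for i, v in pixels.items():
        shift = (v.blackness - P.blackness) if q == 0 else (v.whiteness - P.whiteness)
        if shift < -1e-9:
            raise ValueError(
                f"pixel {i} lies beyond the plain-view anchor "
                f"(shift {shift:.4g} < 0): P is not the extremal pixel"
            )
        shift = max(shift, 0.0)
        g = BWVector(delta * shift, 0.0) if q == 0 else BWVector(0.0, delta * shift)
        ground[i] = g
        figure[i] = v - g
    return figure, ground


def layering_inequality(figure_i: BWVector, pre_shift_i: BWVector, P: BWVector) -> bool:
    """True when the figure vector lies strictly closer to the plain-view
    anchor than the undecomposed (figure + ground) vector does.

    This inequality is what lets figure vectors group into a single surface
    layer anchored at the plain-view point, without interference from the
    medium components displaced onto the axes.
    """
    return distance(figure_i, P) < distance(pre_shift_i, P)


# ---------------------------------------------------------------------------
# Scene-level orchestration
# ---------------------------------------------------------------------------


def _framework_anchors(rm: RegionMap, parse: SceneParse) -> tuple[float, float]:
    """Geometric-mean luminances of the bright and dim framework anchors.

    Anchors default to the highest-geometric-mean region within each
    framework when the parse does not name them explicitly."""
    bright = parse.bright_regions()
    dim = parse.dim_regions()
    if not bright or not dim:
        raise ValueError("illuminant shift requires both bright and dim frameworks")

    def gm_of(region_set: set[int], named: int | None) -> float:
        if named is not None:
            return region_geometric_mean(rm, named)
        return max(region_geometric_mean(rm, r) for r in sorted(region_set))

    return gm_of(bright, parse.bright_anchor_region), gm_of(dim, parse.dim_anchor_region)


def region_coordinates(
    rm: RegionMap,
    region: int,
    parse: SceneParse,
    cfg: MappingConfig,
    anchor: DisplayAnchor | None = None,
    p_override: float | None = None,
) -> BWVector:
    """Full coordinates of a region under a scene parse.

    The luminance vector (shifted by the shadow vector when the region is in
    the dim framework and the illuminant-shift gate is open) plus the
    region's contrast vector.  This is the reference representation used for
    match prediction.
    """
    if anchor is None:
        anchor = display_anchor(rm, cfg)
    tau = effective_tau(parse)
    st = surround_stats(rm, region, p_override=p_override)
    lv = luminance_vector(st.L_T, anchor, cfg, saturate=False)
    if tau > 0 and region in parse.dim_regions():
        L_Hb, L_Hd = _framework_anchors(rm, parse)
        sh = shadow_vector(L_Hb, L_Hd, tau, cfg)
        b = lv.blackness - sh.blackness
        if b < -1e-12:
            warnings.warn(
                f"illuminant shift drove blackness of region {region} to {b:.4g}; "
                "clamped to 0 (over-discounting)",
                OverDiscountingWarning,
                stacklevel=2,
            )
        lv = BWVector(max(b, 0.0), lv.whiteness)
    return lv + contrast_vector(st, cfg)


def decompose_scene(
    rm: RegionMap,
    parse: SceneParse,
    cfg: MappingConfig | None = None,
) -> LayeredRepresentation:
    """Run the decomposition a scene parse calls for.

    With the illuminant-shift gate open (effective tau > 0) the per-region
    luminance vectors are decomposed into surface + shadow layers.  With
    scission cues present (delta > 0) the target sub-region coordinates are
    decomposed into figure + ground layers about the plain-view anchor.
    Simultaneous variation in both illumination and transmittance is
    rejected as unsupported.  With both gates closed the representation is
    the identity: surfaces equal brightness coordinates, zero shadow and
    ground.
    """
    cfg = cfg or MappingConfig()
    tau = effective_tau(parse)
    if tau > 0 and parse.delta > 0:
        raise ValueError(
            "simultaneous illumination (tau > 0) and transmittance "
            "(delta > 0) variation is unsupported"
        )
    anchor = display_anchor(rm, cfg)

    if tau > 0:
        coords = {
            r: luminance_vector(
                region_geometric_mean(rm, r), anchor, cfg, saturate=False
            )
            for r in rm.region_labels
        }
        L_Hb, L_Hd = _framework_anchors(rm, parse)
        sh = shadow_vector(L_Hb, L_Hd, tau, cfg)
        return apply_illuminant_shift(coords, parse, sh, cfg)

    if parse.target_regions:
        targets = parse.target_regions
        st = surround_stats(rm, targets)
        cv = contrast_vector(st, cfg)
        pixels = {
            r: luminance_vector(
                region_geometric_mean(rm, r), anchor, cfg, saturate=False
            )
            + cv
            for r in targets
        }
        q = parse.polarity
        if q is None:
            q = perimeter_polarity(rm, targets)
        if parse.delta > 0:
            if parse.plain_view_anchor is None:
                # Default: extremal sub-region of the target in luminance.
                key = max if q == 0 else min
                pv = key(targets, key=lambda r: region_geometric_mean(rm, r))
            else:
                pv = parse.plain_view_anchor
            # Guard the scission gate even when polarity was supplied.
            perimeter_polarity(rm, targets)
            P = pixels[pv]
            figure, ground = transmittance_decompose(pixels, P, q, parse.delta)
            return LayeredRepresentation(
                surface=figure,
                ground=ground,
                pre_shift=pixels,
                plain_view=P,
            )
        return LayeredRepresentation(
            surface=dict(pixels),
            ground={r: BWVector(0.0, 0.0) for r in pixels},
            pre_shift=dict(pixels),
        )

    # No gates open and no designated target: identity representation over
    # all regions at the region level.
    coords = {
        r: region_coordinates(rm, r, parse, cfg, anchor=anchor)
        if rm.neighbours(r)
        else luminance_vector(region_geometric_mean(rm, r), anchor, cfg)
        for r in rm.region_labels
    }
    return LayeredRepresentation(surface=coords, pre_shift=dict(coords))
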