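"""Parametric synthesis of the display families the model is tested on.

Three families are generated, each as a :class:`RegionMap` plus a
ground-truth :class:`SceneParse`:

* **checkerboard** — a two-framework checkerboard: the same reflectance
  palette rendered under a bright and a dim illumination level (luminance =
  reflectance x illumination pointwise), including an equal-luminance pair
  of checks with different reflectances across the shadow boundary.
* **paint_shadow** — a two-field display with a decrement target on the
  bright side and an equal-luminance increment target on the dim side; the
  Paint variants declare uniform illumination (the dim side is a darker
  'paint job'), the Trans/Shadow variants declare variable illumination.
* **anderson_winawer** — a gradient target of exact Michelson contrast
  embedded in a gradient surround that is everywhere darker (blackish,
  figural increment) or everywhere brighter (whitish, figural decrement);
  the rotated control keeps the photometry and forces delta = 0.

Targets and gradients are emitted as piecewise-constant bands (default 16)
rather than rendered pictures: the model consumes only region photometry,
so geometric realism is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .layers import SceneParse
from .photometric import RegionMap

__all__ = [
    "StimulusSpec",
    "make_checkerboard",
    "make_paint_shadow_display",
    "make_anderson_winawer",
    "PAINT_SHADOW_VARIANTS",
]

PAINT_SHADOW_VARIANTS = ("PaintL", "PaintR", "TransL", "TransR", "ShadowL", "ShadowR")


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a generated display.

    reflectances : diffuse reflectance palette in (0, 1], shared by both
        illumination frameworks of a checkerboard (None draws a seeded
        random palette).
    illumination_bright / illumination_dim : incident levels in cd/m^2; the
        ratio k = bright/dim is the illumination step.
    michelson : Michelson contrast of the gradient target texture, in (0,1).
    surround_polarity : 'blackish' (target is an increment) or 'whitish'
        (decrement) gradient surround.
    rotated : 90-degree background-rotation control; same luminances, but
        the parse carries delta = 0.
    target_center : mean luminance of the gradient target (cd/m^2).
    n_bands : number of constant bands a gradient is discretised into.
    check_size : pixels per check edge.
    seed : RNG seed for any stochastic choice (random palettes).
    """

    family: str = "checkerboard"
    reflectances: tuple[float, ...] | None = (0.2, 0.4, 0.6, 0.9)
    illumination_bright: float = 100.0
    illumination_dim: float = 100.0 / 3.0
    michelson: float = 0.5
    surround_polarity: str = "blackish"
    rotated: bool = False
    target_center: float = 40.0
    n_bands: int = 16
    check_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.illumination_bright <= 0 or self.illumination_dim <= 0:
            raise ValueError("illumination levels must be positive")
        if not 0.0 < self.michelson < 1.0:
            raise ValueError(f"michelson must lie in (0, 1), got {self.michelson}")
        if self.surround_polarity not in ("blackish", "whitish"):
            raise ValueError(
                f"surround_polarity must be 'blackish' or 'whitish', "
                f"got {self.surround_polarity!r}"
            )
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if self.reflectances is not None:
            refl = tuple(self.reflectances)
            if any(not 0.0 < r <= 1.0 for r in refl):
                raise ValueError(f"reflectances must lie in (0, 1], got {refl}")


def _palette(spec: StimulusSpec) -> tuple[float, ...]:
    if spec.reflectances is not None:
        return tuple(sorted(set(spec.reflectances)))
    rng = np.random.default_rng(spec.seed)
    vals = np.sort(rng.uniform(0.08, 0.95, size=4))
    return tuple(float(v) for v in vals)


def make_checkerboard(spec: StimulusSpec) -> tuple[RegionMap, SceneParse]:
    """A two-framework checkerboard with an equal-luminance check pair.

    The left half is rendered under the bright illumination level, the right
    half under the dim level, with an identical reflectance layout in both
    halves (so equal-reflectance check pairs exist across the boundary).  A
    low-reflectance check at ``r_max / k`` is added to the palette so that
    its bright-side rendering exactly equals the luminance of the dim-side
    ``r_max`` check (the classic equal-luminance A/B pair).  With k = 1 the
    whole display is a single bright framework and the parse carries
    ``tau_stim = 0``.
    """
    k = spec.illumination_bright / spec.illumination_dim
    if k < 1.0:
        raise ValueError("illumination_bright must be >= illumination_dim")
    palette = list(_palette(spec))
    r_max = palette[-1]
    r_pair = r_max / k
    if k > 1.0 and not any(abs(r - r_pair) < 1e-15 for r in palette):
        palette = sorted(palette + [r_pair])
    n = len(palette)

    # One half = 2 rows x n columns of checks; rows use the palette in
    # opposite orders so neighbouring checks differ in reflectance.
    half = np.empty((2, n), dtype=float)
    half[0, :] = palette
    half[1, :] = palette[::-1]
    refl_layout = np.hstack([half, half])  # right half repeats the layout

    cs = spec.check_size
    nrow, ncol = refl_layout.shape
    labels = np.arange(nrow * ncol, dtype=np.int64).reshape(nrow, ncol)
    labels = np.kron(labels, np.ones((cs, cs), dtype=np.int64))
    illum = np.where(
        np.arange(ncol) < n, spec.illumination_bright, spec.illumination_dim
    )
    luminance = np.kron(refl_layout * illum, np.ones((cs, cs)))

    reflectance_of = {
        int(labels[i * cs, j * cs]): float(refl_layout[i, j])
        for i in range(nrow)
        for j in range(ncol)
    }
    bright_ids = {int(v) for v in np.unique(labels[:, : n * cs])}
    dim_ids = {int(v) for v in np.unique(labels[:, n * cs :])}

    # The equal-luminance pair: bright-side r_max/k vs dim-side r_max.
    pair = None
    if k > 1.0:
        a = min(r for r in bright_ids if abs(reflectance_of[r] - r_pair) < 1e-15)
        b = min(r for r in dim_ids if reflectance_of[r] == r_max)
        pair = (a, b)

    # Equal-reflectance partners across the illumination boundary.
    partners = {}
    for i in range(nrow):
        for j in range(n):
            partners[int(labels[i * cs, j * cs])] = int(labels[i * cs, (j + n) * cs])

    rm = RegionMap(
        luminance,
        labels,
        meta={
            "reflectance": reflectance_of,
            "equal_luminance_pair": pair,
            "equal_reflectance_partners": partners,
            "k": k,
        },
    )
    if k > 1.0:
        framework = {r: "bright" for r in bright_ids}
        framework.update({r: "dim" for r in dim_ids})
        bright_anchor = max(bright_ids, key=lambda r: reflectance_of[r])
        dim_anchor = max(dim_ids, key=lambda r: reflectance_of[r])
        parse = SceneParse(
            framework=framework,
            tau_stim=1,
            bright_anchor_region=bright_anchor,
            dim_anchor_region=dim_anchor,
        )
    else:
        parse = SceneParse(
            framework={r: "bright" for r in bright_ids | dim_ids}, tau_stim=0
        )
    return rm, parse


def make_paint_shadow_display(
    variant: str, spec: StimulusSpec | None = None, target_luminance: float = 30.0
) -> tuple[RegionMap, SceneParse]:
    """The paint/transparency/shadow display with left/right target variants.

    Both targets share one luminance: the left target is a decrement against
    the bright-side background, the right target an equal-luminance
    increment against the dim-side background.  All six variants share the
    same luminance raster; they differ in which target is the reference
    (L/R) and in the parse: Paint variants declare uniform illumination
    (``tau_stim = 0``, the dim side is darker paint), Trans and Shadow
    variants declare variable illumination (``tau_stim = 1``) — the model
    treats a transparency overlay and a shadow identically.  The dim-side
    anchor is the increment target itself, the highest-luminance region in
    dim illumination.
    """
    if variant not in PAINT_SHADOW_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {PAINT_SHADOW_VARIANTS}"
        )
    spec = spec or StimulusSpec(family="paint_shadow")
    I_b = spec.illumination_bright
    I_d = spec.illumination_dim
    if I_b < I_d:
        raise ValueError("illumination_bright must be >= illumination_dim")
    r_bg = 0.5
    L_bg_bright = r_bg * I_b
    L_bg_dim = r_bg * I_d
    L_t = target_luminance
    if not L_bg_dim < L_t < L_bg_bright:
        raise ValueError(
            f"target luminance {L_t} must lie between the dim ({L_bg_dim}) and "
            f"bright ({L_bg_bright}) background luminances"
        )

    # Regions: 0 = bright background, 1 = dim background, 2 = left target
    # (decrement, bright side), 3 = right target (increment, dim side).
    h = w = 12
    labels = np.zeros((h, 2 * w), dtype=np.int64)
    labels[:, w:] = 1
    labels[4:8, 4:8] = 2
    labels[4:8, w + 4 : w + 8] = 3
    luminance = np.choose(labels, [L_bg_bright, L_bg_dim, L_t, L_t])

    rm = RegionMap(
        luminance,
        labels,
        meta={"variant": variant, "target_luminance": L_t, "k": I_b / I_d},
    )
    target = 2 if variant.endswith("L") else 3
    if variant.startswith("Paint"):
        parse = SceneParse(
            framework={0: "bright", 1: "bright", 2: "bright", 3: "bright"},
            tau_stim=0,
            target_regions=(target,),
        )
    else:
        parse = SceneParse(
            framework={0: "bright", 2: "bright", 1: "dim", 3: "dim"},
            tau_stim=1,
            bright_anchor_region=0,
            dim_anchor_region=3,  # the increment target is the dim-side maximum
            target_regions=(target,),
        )
    return rm, parse


def make_anderson_winawer(spec: StimulusSpec) -> tuple[RegionMap, SceneParse]:
    """A gradient target of exact Michelson contrast in a gradient surround.

    The target is a block of ``n_bands`` constant vertical bands spanning
    luminances ``target_center * (1 -/+ michelson)``, flanked by gradient
    surrounds that are everywhere dimmer (blackish polarity: the target is a
    figural increment, q = 0) or everywhere brighter (whitish: decrement,
    q = 1).  The two polarities share an identical target raster.  The parse
    marks the plain-view anchor (the whitest target band for increments, the
    blackest for decrements) and carries ``delta = 1``, or ``delta = 0``
    for the rotated-background control (identical luminances).
    """
    n = spec.n_bands
    m = spec.michelson
    L_lo = spec.target_center * (1.0 - m)
    L_hi = spec.target_center * (1.0 + m)
    target_bands = np.linspace(L_lo, L_hi, n)

    # The atmospheric gradient is a mild modulation hugging the target's
    # luminance range (it must stay strictly outside it on one side to
    # preserve contrast polarity around the whole perimeter).
    if spec.surround_polarity == "blackish":
        surround_bands = np.linspace(0.75 * L_lo, 0.95 * L_lo, n)
        q = 0
    else:
        surround_bands = np.linspace(1.05 * L_hi, 1.25 * L_hi, n)
        q = 1

    # Vertical-stripe layout: left surround | target block | right surround.
    h = 8
    left = np.tile(np.arange(n, dtype=np.int64), (h, 1))
    mid = np.tile(np.arange(n, 2 * n, dtype=np.int64), (h, 1))
    right = np.tile(np.arange(n, dtype=np.int64)[::-1], (h, 1))
    labels = np.hstack([left, mid, right])
    band_lum = np.concatenate([surround_bands, target_bands])
    luminance = band_lum[labels]

    target_ids = tuple(range(n, 2 * n))
    anchor_band = target_ids[-1] if q == 0 else target_ids[0]
    rm = RegionMap(
        luminance,
        labels,
        meta={
            "target_band_luminance": {
                tid: float(target_bands[i]) for i, tid in enumerate(target_ids)
            },
            "plain_view_luminance": float(L_hi if q == 0 else L_lo),
            "michelson": m,
            "polarity": q,
        },
    )
    parse = SceneParse(
        framework={int(r): "bright" for r in np.unique(labels)},
        tau_stim=0,
        delta=0.0 if spec.rotated else 1.0,
        plain_view_anchor=anchor_band,
        target_regions=target_ids,
        polarity=q,
    )
    return rm, parse
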