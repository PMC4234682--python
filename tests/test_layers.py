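"""Illuminant- and transmittance-shift decompositions."""

import math
from dataclasses import replace

import numpy as np
import pytest

from gamutrel.bw_space import BWVector, distance
from gamutrel.layers import (
    LayeredRepresentation,
    OverDiscountingWarning,
    SceneParse,
    apply_illuminant_shift,
    comparison_gamut,
    decompose_scene,
    effective_tau,
    layering_inequality,
    perimeter_polarity,
    shadow_vector,
    transmittance_decompose,
)
from gamutrel.photometric import MappingConfig
from gamutrel.stimuli import StimulusSpec, make_anderson_winawer, make_checkerboard


def checkerboard(k=3.0, **kw):
    spec = StimulusSpec(
        family="checkerboard",
        illumination_bright=100.0,
        illumination_dim=100.0 / k,
        **kw,
    )
    return make_checkerboard(spec)


def aw_display(m=0.5, polarity="blackish", rotated=False):
    spec = StimulusSpec(
        family="anderson_winawer",
        michelson=m,
        surround_polarity=polarity,
        rotated=rotated,
    )
    return make_anderson_winawer(spec)


class TestEffectiveTau:
    @pytest.mark.parametrize(
        "tau_stim,tau_task,expected",
        [(0, 0.0, 0.0), (0, 1.0, 0.0), (1, 1.0, 1.0), (1, 0.0, 0.0), (1, 0.4, 0.4)],
    )
    def test_multiplicative_gating(self, tau_stim, tau_task, expected):
        parse = SceneParse(
            framework={0: "bright", 1: "dim"} if tau_stim else {0: "bright"},
            tau_stim=tau_stim,
            tau_task=tau_task,
        )
        assert effective_tau(parse) == pytest.approx(expected)


class TestShadowVector:
    def test_zero_when_tau_zero_or_unit_ratio(self, cfg):
        assert shadow_vector(100.0, 10.0, 0.0, cfg).as_tuple() == (0.0, 0.0)
        assert shadow_vector(50.0, 50.0, 1.0, cfg).as_tuple() == (0.0, 0.0)

    def test_hand_evaluated_magnitude(self, cfg):
        # tau=1, ratio 10, b0=3, kappa=1 -> blackness 3, whiteness 0.
        v = shadow_vector(100.0, 10.0, 1.0, cfg)
        assert v.blackness == pytest.approx(cfg.b0 * cfg.kappa * 1.0)
        assert v.whiteness == 0.0

    def test_inconsistent_framework_errors(self, cfg):
        with pytest.raises(ValueError):
            shadow_vector(10.0, 100.0, 1.0, cfg)

    def test_comparison_gamut_parallel_smaller_intercept(self, cfg):
        sh = shadow_vector(100.0, 25.0, 1.0, cfg)
        comp = comparison_gamut(sh, cfg)
        std = cfg.standard_gamut()
        assert comp.slope == pytest.approx(std.slope)
        # Effective whiteness intercept where the line crosses blackness = 0.
        eff_w = cfg.w0 * (1.0 - sh.blackness / cfg.b0)
        assert eff_w < cfg.w0


class TestIlluminantShift:
    def test_equal_reflectance_pairs_share_blackness(self, cfg):
        rm, parse = checkerboard(k=3.0)
        lay = decompose_scene(rm, replace(parse, tau_task=1.0), cfg)
        for a, b in rm.meta["equal_reflectance_partners"].items():
            assert lay.surface[a].blackness == pytest.approx(
                lay.surface[b].blackness, abs=1e-9
            )

    def test_equal_luminance_pair_diverges(self, cfg):
        rm, parse = checkerboard(k=3.0)
        a, b = rm.meta["equal_luminance_pair"]
        lay = decompose_scene(rm, replace(parse, tau_task=1.0), cfg)
        # Same luminance, different reflectance: blackness differs by the
        # full shadow magnitude after discounting.
        diff = abs(lay.surface[a].blackness - lay.surface[b].blackness)
        assert diff == pytest.approx(lay.shadow.blackness, abs=1e-9)
        assert diff > 0.5

    def test_conservation_exact(self, cfg):
        rm, parse = checkerboard(k=5.0)
        lay = decompose_scene(rm, replace(parse, tau_task=1.0), cfg)
        for r in parse.dim_regions():
            recomposed = lay.surface[r] + lay.shadow
            assert distance(recomposed, lay.pre_shift[r]) < 1e-9

    def test_bright_framework_untouched(self, cfg):
        rm, parse = checkerboard(k=5.0)
        lay = decompose_scene(rm, replace(parse, tau_task=1.0), cfg)
        for r in parse.bright_regions():
            assert lay.surface[r].as_tuple() == lay.pre_shift[r].as_tuple()

    def test_whiteness_never_altered(self, cfg):
        rm, parse = checkerboard(k=2.0)
        lay = decompose_scene(rm, replace(parse, tau_task=1.0), cfg)
        for r in lay.surface:
            assert lay.surface[r].whiteness == lay.pre_shift[r].whiteness

    def test_over_discounting_clamps_and_warns(self, cfg):
        coords = {0: BWVector(0.2, 0.9), 1: BWVector(0.1, 0.95)}
        parse = SceneParse(framework={0: "bright", 1: "dim"}, tau_stim=1, tau_task=1.0)
        sh = BWVector(0.5, 0.0)
        with pytest.warns(OverDiscountingWarning):
            lay = apply_illuminant_shift(coords, parse, sh, cfg)
        assert lay.surface[1].blackness == 0.0


class TestTransmittanceShift:
    def test_delta_zero_is_identity(self, cfg):
        rm, parse = aw_display(rotated=True)
        assert parse.delta == 0.0
        lay = decompose_scene(rm, parse, cfg)
        for r in lay.surface:
            assert lay.surface[r].as_tuple() == lay.pre_shift[r].as_tuple()
            assert lay.ground[r].as_tuple() == (0.0, 0.0)

    @pytest.mark.parametrize("polarity,coord", [("blackish", "blackness"), ("whitish", "whiteness")])
    def test_constraint_line_alignment(self, cfg, polarity, coord):
        rm, parse = aw_display(polarity=polarity)
        lay = decompose_scene(rm, parse, cfg)
        P = lay.plain_view
        for r in lay.surface:
            assert getattr(lay.surface[r], coord) == pytest.approx(
                getattr(P, coord), abs=1e-9
            )

    @pytest.mark.parametrize("polarity", ["blackish", "whitish"])
    def test_conservation_and_orthogonality(self, cfg, polarity):
        rm, parse = aw_display(polarity=polarity)
        lay = decompose_scene(rm, parse, cfg)
        P = lay.plain_view
        for r in lay.surface:
            assert distance(lay.surface[r] + lay.ground[r], lay.pre_shift[r]) < 1e-9
            assert abs((lay.surface[r] - P).dot(lay.ground[r])) < 1e-9

    @pytest.mark.parametrize("polarity", ["blackish", "whitish"])
    def test_layering_inequality_all_pixels(self, cfg, polarity):
        rm, parse = aw_display(polarity=polarity)
        lay = decompose_scene(rm, parse, cfg)
        P = lay.plain_view
        for r in lay.surface:
            if r == parse.plain_view_anchor:
                continue  # zero self-shift: distances tie at the anchor
            assert layering_inequality(lay.surface[r], lay.pre_shift[r], P)

    def test_delta_interpolates_linearly(self, cfg):
        rm, parse = aw_display()
        full = decompose_scene(rm, parse, cfg)
        for delta in (0.25, 0.6):
            part = decompose_scene(rm, replace(parse, delta=delta), cfg)
            for r in part.surface:
                # figure(delta) = (1-delta)*BW + delta*figure(1)
                expected = (1 - delta) * full.pre_shift[r] + delta * full.surface[r]
                assert part.surface[r].as_tuple() == pytest.approx(
                    expected.as_tuple(), abs=1e-12
                )

    def test_mixed_perimeter_rejected(self, cfg):
        # Target bracketed by a darker and a brighter flank: polarity broken.
        lum = np.array([[2.0] * 4, [20.0] * 4, [90.0] * 4])
        labels = np.array([[0] * 4, [1] * 4, [2] * 4])
        from gamutrel.photometric import RegionMap

        rm = RegionMap(lum, labels)
        with pytest.raises(ValueError, match="mixed-polarity"):
            perimeter_polarity(rm, [1])

    def test_anchor_must_be_extremal(self):
        pixels = {0: BWVector(1.0, 0.5), 1: BWVector(2.0, 0.3)}
        with pytest.raises(ValueError, match="extremal"):
            transmittance_decompose(pixels, BWVector(1.5, 0.4), 0, 1.0)


class TestGating:
    def test_simultaneous_shifts_unsupported(self, cfg):
        rm, parse = aw_display()
        bad = replace(
            parse,
            framework={r: ("dim" if i % 2 else "bright") for i, r in enumerate(parse.framework)},
            tau_stim=1,
            tau_task=1.0,
        )
        with pytest.raises(ValueError, match="unsupported"):
            decompose_scene(rm, bad, cfg)

    def test_brightness_task_disables_discounting(self, cfg):
        rm, parse = checkerboard(k=3.0)
        lay = decompose_scene(rm, replace(parse, tau_task=0.0), cfg)
        assert lay.shadow.as_tuple() == (0.0, 0.0)
        for r in lay.surface:
            assert lay.surface[r].as_tuple() == lay.pre_shift[r].as_tuple()


class TestSceneParseIO:
    def test_json_round_trip(self, tmp_path):
        parse = SceneParse(
            framework={0: "bright", 3: "dim"},
            tau_stim=1,
            tau_task=0.5,
            delta=0.0,
            bright_anchor_region=0,
            dim_anchor_region=3,
            target_regions=(3,),
        )
        path = tmp_path / "parse.json"
        parse.to_json(path)
        loaded = SceneParse.from_json(path)
        assert loaded == parse

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SceneParse(tau_stim=2)
        with pytest.raises(ValueError):
            SceneParse(delta=1.5)
        with pytest.raises(ValueError):
            SceneParse(framework={0: "bright"}, tau_stim=1)  # no dim region
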