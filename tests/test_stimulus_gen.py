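"""Display generation: noise spectra, letter placement, design counts, rendering."""

import numpy as np
import pytest

from doublepass.stimulus_gen import (
    MIN_LETTER_DISTANCE,
    ORIENTATIONS,
    QUADRANTS,
    TB_LEVELS,
    Design,
    DisplaySpec,
    LetterSpec,
    PlacementError,
    EXP1_REGION,
    build_design,
    fit_spectral_exponent,
    generate_noise,
    letter_mask,
    place_letters,
    render_display,
    tb_contrast,
)


class TestNoise:
    def test_pink_spectral_exponent(self):
        img = generate_noise(512, 512, exponent=1.3, seed=7)
        assert abs(fit_spectral_exponent(img.pixels) - 1.3) < 0.15

    def test_white_noise_flat_spectrum(self):
        img = generate_noise(128, 128, exponent=0.0, seed=1)
        assert abs(fit_spectral_exponent(img.pixels)) < 0.1

    def test_seeded_determinism(self):
        a = generate_noise(256, 256, 1.3, 42)
        b = generate_noise(256, 256, 1.3, 42)
        assert np.array_equal(a.pixels, b.pixels)
        c = generate_noise(256, 256, 1.3, 43)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_range_and_mean(self):
        img = generate_noise(256, 256, 1.3, 3).pixels
        assert img.dtype == np.uint8
        assert img.min() == 0 and img.max() == 255
        assert abs(float(img.mean()) - 127.5) < 25

    def test_scale_invariance(self):
        # doubling the image size leaves the fitted exponent within tolerance
        for n in (256, 512):
            img = generate_noise(n, n, 1.3, 11)
            assert abs(fit_spectral_exponent(img.pixels) - 1.3) < 0.15

    @pytest.mark.parametrize("h,w,exp", [(16, 64, 1.3), (64, 16, 1.3), (64, 64, -1.0)])
    def test_bad_arguments(self, h, w, exp):
        with pytest.raises(ValueError):
            generate_noise(h, w, exp, 0)


class TestPlacement:
    def test_exp1_square(self):
        pts = place_letters(18, EXP1_REGION, 0.1, rng_seed=4)
        assert len(pts) == 18
        arr = np.array(pts)
        assert arr.min() >= 0.15 and arr.max() <= 0.85
        d = np.sqrt(((arr[:, None] - arr[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.1

    def test_single_point(self):
        (pt,) = place_letters(1, (0.2, 0.2, 0.4, 0.4), 0.1, rng_seed=0)
        assert 0.2 <= pt[0] <= 0.4 and 0.2 <= pt[1] <= 0.4

    def test_overpacked_region_fails(self):
        # at most ~9 points at distance 0.1 fit into a 0.2 x 0.2 box
        with pytest.raises(PlacementError, match="50"):
            place_letters(50, (0.0, 0.0, 0.2, 0.2), 0.1, rng_seed=0)

    def test_existing_points_respected(self):
        fixed = [(0.5, 0.5)]
        pts = place_letters(10, EXP1_REGION, 0.1, rng_seed=2, existing=fixed)
        arr = np.array(pts)
        assert len(pts) == 10
        assert np.all(np.hypot(arr[:, 0] - 0.5, arr[:, 1] - 0.5) > 0.1)


class TestDesigns:
    def test_exp1_counts(self, design_exp1):
        assert len(design_exp1.displays) == 300
        assert len(design_exp1.schedule) == 600
        assert design_exp1.block_size == 100
        # 75 displays per (set size x presence) cell
        from collections import Counter

        cells = Counter(
            (d.set_size, d.target_present) for d in design_exp1.displays.values()
        )
        assert all(v == 75 for v in cells.values()) and len(cells) == 4
        # each display scheduled exactly twice, copy 1 before copy 2
        seen = {}
        for t in design_exp1.schedule:
            seen.setdefault(t.display_id, []).append(t.copy)
        assert all(copies == [1, 2] for copies in seen.values())

    def test_exp2b_cell_balance(self, design_exp2b):
        assert len(design_exp2b.displays) == 256
        assert len(design_exp2b.schedule) == 512
        from collections import Counter

        cells = Counter(
            (d.target_present, d.set_size, d.tb_contrast, d.quadrant)
            for d in design_exp2b.displays.values()
        )
        assert len(cells) == 128
        assert all(v == 2 for v in cells.values())

    def test_exp3_cue_halves(self, design_exp3):
        groups = list(design_exp3.cue_assignment.values())
        assert groups.count("nocue_cue") == 128
        assert groups.count("nocue_nocue") == 128
        cued = [t for t in design_exp3.schedule if t.cued]
        assert len(cued) == 128
        assert all(t.copy == 2 for t in cued)
        assert all(
            design_exp3.cue_assignment[t.display_id] == "nocue_cue" for t in cued
        )

    def test_exp2a_counts_and_grayscales(self):
        design = build_design("exp2a", rng_seed=2)
        assert len(design.displays) == 300
        grays = [
            let.gray for d in design.displays.values() for let in d.letters
        ]
        # uniform over 0-255: both tails populated
        assert min(grays) < 32 and max(grays) > 223

    def test_unknown_dialect(self):
        with pytest.raises(ValueError, match="unknown experiment"):
            build_design("exp9", rng_seed=0)

    def test_display_invariants(self, design_exp1, design_exp2b):
        for design in (design_exp1, design_exp2b):
            for spec in design.displays.values():
                spec.validate()
                for let in spec.letters:
                    assert let.orientation in ORIENTATIONS
                    assert 0 <= let.gray <= 255
            mins = [
                d.min_pairwise_distance() for d in design.displays.values()
            ]
            assert min(mins) > MIN_LETTER_DISTANCE

    def test_exp2b_target_in_quadrant_and_level(self, design_exp2b):
        for d in design_exp2b.displays.values():
            assert d.tb_contrast in TB_LEVELS
            if d.target_present:
                (x0, x1), (y0, y1) = QUADRANTS[d.quadrant]
                assert x0 <= d.target.x <= x1 and y0 <= d.target.y <= y1
                assert d.target.gray - 128 == d.tb_contrast

    def test_design_json_roundtrip(self, design_exp2b, tmp_path):
        path = tmp_path / "design.json"
        design_exp2b.to_json(path)
        loaded = Design.from_json(path)
        assert set(loaded.displays) == set(design_exp2b.displays)
        assert loaded.schedule == design_exp2b.schedule
        assert loaded.displays["exp2b-p-s18-tb+15-UL-1"].letters == \
            design_exp2b.displays["exp2b-p-s18-tb+15-UL-1"].letters


def _spec(letters, present, set_size, bg=None):
    return DisplaySpec(
        display_id="t",
        letters=letters,
        target_present=present,
        set_size=set_size,
        background=bg or {"kind": "uniform", "gray": 128},
    )


class TestRendering:
    def test_upright_t_stroke_extents(self):
        from doublepass.stimulus_gen import _letter_segments, _paint_segment

        letter = LetterSpec(kind="T", x=0.5, y=0.5, orientation=360, gray=255)
        (h_a, h_b), (v_a, v_b) = _letter_segments(letter)
        size = 1000
        # horizontal bar: x-extent 0.03 x height = 30 px, within a pixel
        bar = np.zeros((size, size), dtype=bool)
        _paint_segment(bar, h_a, h_b, half_width_px=1.5, scale=size)
        _, xs = np.nonzero(bar)
        assert abs((xs.max() - xs.min() + 1) - 30) <= 1
        # vertical stem: y-extent 30 px, within a pixel
        stem = np.zeros((size, size), dtype=bool)
        _paint_segment(stem, v_a, v_b, half_width_px=1.5, scale=size)
        ys, _ = np.nonzero(stem)
        assert abs((ys.max() - ys.min() + 1) - 30) <= 1
        # and the full letter contains both strokes
        img = render_display(_spec([letter], True, 1), size=size)
        assert np.all(img[bar | stem] == 255)

    def test_empty_display_is_background(self):
        img = render_display(_spec([], False, 0), size=64)
        assert np.all(img == 128)

    def test_render_determinism(self):
        spec = _spec(
            [LetterSpec(kind="L", x=0.4, y=0.6, orientation=150, gray=200)],
            False, 1, bg={"kind": "noise", "seed": 9, "exponent": 1.3},
        )
        assert np.array_equal(render_display(spec, 256), render_display(spec, 256))

    def test_letter_outside_image_errors(self):
        letter = LetterSpec(kind="T", x=0.999, y=0.5, orientation=90, gray=255)
        with pytest.raises(ValueError, match="outside"):
            render_display(_spec([letter], True, 1), size=128)

    def test_rotated_letters_render_same_pixel_count(self):
        # stroke geometry is orientation-covariant; areas agree within AA-free tolerance
        counts = []
        for ori in (90, 180, 270, 360):
            letter = LetterSpec(kind="T", x=0.5, y=0.5, orientation=ori, gray=255)
            counts.append(int((render_display(_spec([letter], True, 1), 500) == 255).sum()))
        assert max(counts) - min(counts) <= 0.15 * max(counts)


class TestContrast:
    def test_uniform_background(self):
        letter = LetterSpec(kind="T", x=0.5, y=0.5, orientation=360, gray=200)
        img = render_display(_spec([letter], True, 1), size=500)
        assert tb_contrast(img, letter) == pytest.approx(72.0)

    def test_zero_contrast(self):
        letter = LetterSpec(kind="L", x=0.5, y=0.5, orientation=90, gray=128)
        img = render_display(_spec([letter], False, 1), size=500)
        assert tb_contrast(img, letter) == pytest.approx(0.0)

    def test_against_pixel_enumeration(self):
        # brute-force oracle: walk the patch pixel by pixel
        import math

        letter = LetterSpec(kind="T", x=0.5, y=0.5, orientation=120, gray=100)
        spec = _spec([letter], True, 1, bg={"kind": "noise", "seed": 11, "exponent": 1.3})
        img = render_display(spec, size=64)
        got = tb_contrast(img, letter, patch_scale=2.0)

        h = img.shape[0]
        side = 2.0 * letter.stroke_len * h
        x_lo = math.floor(letter.x * h - side / 2)
        x_hi = math.ceil(letter.x * h + side / 2)
        y_lo = math.floor(letter.y * h - side / 2)
        y_hi = math.ceil(letter.y * h + side / 2)
        own = letter_mask(letter, img.shape)
        total, count = 0.0, 0
        for row in range(y_lo, y_hi):
            for col in range(x_lo, x_hi):
                if not own[row, col]:
                    total += float(img[row, col])
                    count += 1
        expected = letter.gray - total / count
        assert got == pytest.approx(expected)

    def test_render_then_contrast_recovers_nominal_difference(self):
        for gray in (23, 128, 233):
            letter = LetterSpec(kind="L", x=0.3, y=0.7, orientation=240, gray=gray)
            img = render_display(_spec([letter], False, 1), size=400)
            assert tb_contrast(img, letter) == pytest.approx(gray - 128)

    def test_degenerate_patch(self):
        # patch fully clipped away (empty image) must error, not divide by zero
        letter = LetterSpec(kind="T", x=0.5, y=0.5, orientation=360, gray=10)
        with pytest.raises(ValueError, match="degenerate"):
            tb_contrast(np.zeros((0, 0), dtype=np.uint8), letter)


class TestLetterSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="X", x=0.5, y=0.5, orientation=90, gray=10),
            dict(kind="T", x=0.5, y=0.5, orientation=45, gray=10),
            dict(kind="T", x=0.5, y=0.5, orientation=90, gray=300),
            dict(kind="T", x=0.5, y=0.5, orientation=90, gray=10, stroke_len=1.5),
        ],
    )
    def test_invalid_letter(self, kwargs):
        with pytest.raises(ValueError):
            LetterSpec(**kwargs)

    def test_display_validation_catches_distance(self):
        letters = [
            LetterSpec(kind="L", x=0.5, y=0.5, orientation=90, gray=255),
            LetterSpec(kind="L", x=0.55, y=0.5, orientation=90, gray=255),
        ]
        with pytest.raises(ValueError, match="distance"):
            _spec(letters, False, 2).validate()
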