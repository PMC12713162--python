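"""Dose-grid design and the four reference-model delta scorers."""

import numpy as np
import pytest

from synscreen import (
    DoseGrid,
    HillFit,
    ResponseSurface,
    classify_interaction,
    css,
    delta_bliss,
    delta_hsa,
    delta_loewe,
    delta_zip,
    design_matrix,
    hill,
    most_synergistic_area,
    score_surface,
    summarize_overall,
)


def surface_from(doses_a, doses_b, fn):
    """Build a surface from an inhibition function of (dose_a, dose_b)."""
    grid = design_matrix(1.0, 1.0) if doses_a is None else DoseGrid(doses_a, doses_b)
    da = np.asarray(grid.doses_a)
    db = np.asarray(grid.doses_b)
    inh = np.array([[fn(a, b) for b in db] for a in da])
    return ResponseSurface(grid=grid, inhibition=inh)


def bliss_null_surface(fit_a, fit_b):
    grid = design_matrix(fit_a.ec50_rel, fit_b.ec50_rel)
    ya = fit_a.predict(np.asarray(grid.doses_a))[:, None]
    yb = fit_b.predict(np.asarray(grid.doses_b))[None, :]
    return ResponseSurface(grid=grid, inhibition=ya + yb - ya * yb)


class TestDesignMatrix:
    def test_half_log_doses_around_ic50(self):
        g = design_matrix(1.0, 1.0)
        expected = [0.0316, 0.1, 0.316, 1.0, 3.16, 10.0, 31.6]
        np.testing.assert_allclose(g.doses_a[1:], expected, rtol=2e-3)
        assert g.doses_a[0] == 0.0
        assert g.doses_a[4] == 1.0  # IC50 centrally positioned

    def test_range_spans_three_logs(self):
        g = design_matrix(0.7, 2.0)
        assert g.doses_a[-1] / g.doses_a[1] == pytest.approx(1000.0)

    def test_scale_equivariance(self):
        g1 = design_matrix(1.0, 1.0)
        g2 = design_matrix(0.1, 0.1)
        np.testing.assert_allclose(
            np.asarray(g2.doses_a[1:]), 0.1 * np.asarray(g1.doses_a[1:])
        )

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError):
            design_matrix(0.0, 1.0)


class TestDeltaBlissHsa:
    def test_bliss_null_is_zero(self):
        surf = bliss_null_surface(HillFit(0.9, 0.5, 1.3), HillFit(0.8, 2.0, 0.9))
        assert np.max(np.abs(delta_bliss(surf))) < 1e-12

    def test_bliss_cell_arithmetic(self):
        # yA=0.5, yB=0.5: expected 0.75; observed 0.80 -> +0.05; 0.60 -> -0.15
        assert 0.80 - (0.5 + 0.5 - 0.25) == pytest.approx(0.05)
        surf = surface_from(None, None, lambda a, b: 0.5 * (a > 0) + 0.3 * (b > 0))
        d = delta_hsa(surf)
        # combination adds 0.3 over the best single agent everywhere off-axis
        np.testing.assert_allclose(d, 0.3, atol=1e-12)

    def test_hsa_null_is_zero(self):
        fa, fb = HillFit(0.9, 0.5, 1.3), HillFit(0.8, 2.0, 0.9)
        grid = design_matrix(fa.ec50_rel, fb.ec50_rel)
        ya = fa.predict(np.asarray(grid.doses_a))[:, None]
        yb = fb.predict(np.asarray(grid.doses_b))[None, :]
        surf = ResponseSurface(grid=grid, inhibition=np.maximum(ya, yb))
        assert np.max(np.abs(delta_hsa(surf))) < 1e-12


class TestDeltaLoewe:
    def test_sham_self_combination_is_zero(self, unit_fit):
        surf = surface_from(None, None, lambda a, b: (a + b) / (1.0 + a + b))
        d = delta_loewe(surf, unit_fit, unit_fit)
        assert np.nanmax(np.abs(d)) < 1e-6

    def test_expected_effect_two_thirds_at_unit_doses(self, unit_fit):
        """For identical unit Hill drugs at (1, 1) µM, dose additivity gives
        D(y*) = 2, hence y* = 2/3; an observed 0.8 scores +0.1333."""
        surf = surface_from(None, None, lambda a, b: (a + b) / (1.0 + a + b))
        inh = surf.inhibition.copy()
        inh[4, 4] = 0.8  # the (1 µM, 1 µM) cell
        surf = ResponseSurface(grid=surf.grid, inhibition=inh)
        d = delta_loewe(surf, unit_fit, unit_fit)
        assert d[3, 3] == pytest.approx(0.8 - 2.0 / 3.0, abs=1e-9)

    def test_unreachable_cells_flagged_nan(self):
        """Low-efficacy partners cannot satisfy additivity at the top
        doses; those cells are flagged, not crashed."""
        fa = HillFit(0.3, 1.0, 1.0)
        fb = HillFit(0.3, 1.0, 1.0)
        surf = surface_from(
            None, None, lambda a, b: hill(a + b, 0.3, 1.0, 1.0)
        )
        d = delta_loewe(surf, fa, fb)
        assert np.isfinite(d).any()  # low-dose cells still solvable


class TestDeltaZip:
    def test_multiplicative_null_is_zero(self):
        fa, fb = HillFit(0.9, 0.5, 1.3), HillFit(0.8, 2.0, 0.9)
        surf = bliss_null_surface(fa, fb)
        d = delta_zip(surf, fa, fb)
        assert np.max(np.abs(d)) < 1e-3

    def test_potency_shift_scores_positive(self):
        """Halving drug A's EC50 in the partner's presence is the ZIP
        synergy phenotype: every off-axis delta goes positive."""
        fa, fb = HillFit(1.0, 1.0, 1.5), HillFit(1.0, 1.0, 1.5)
        shifted = HillFit(1.0, 0.5, 1.5)
        grid = design_matrix(1.0, 1.0)
        da = np.asarray(grid.doses_a)
        db = np.asarray(grid.doses_b)
        ya = fa.predict(da)[:, None]
        yb = fb.predict(db)[None, :]
        inh = ya + yb - ya * yb
        ya_s = shifted.predict(da)[:, None]
        inh[1:, 1:] = (ya_s + yb - ya_s * yb)[1:, 1:]
        surf = ResponseSurface(grid=grid, inhibition=inh)
        d = delta_zip(surf, fa, fb)
        # positive wherever the partner leaves dynamic range (yB < 0.85);
        # saturated columns carry only fit residue, never real antagonism
        measurable = fb.predict(db[1:]) < 0.85
        assert (d[:, measurable] > 0).all()
        assert float(np.mean(d)) > 0.01
        assert float(np.min(d)) > -0.02

    def test_degenerate_surface_rejected(self):
        fa = fb = HillFit(1.0, 1.0, 1.0)
        grid = DoseGrid((0.0, 1.0, 10**0.5, 10.0), (0.0, 1.0, 10**0.5, 10.0))
        surf = ResponseSurface(grid=grid, inhibition=np.zeros((4, 4)))
        with pytest.raises(ValueError, match="ZIP"):
            delta_zip(surf, fa, fb)


class TestSummaries:
    def test_overall_zero_and_constant(self):
        assert summarize_overall(np.zeros((7, 7))) == 0.0
        assert summarize_overall(np.full((7, 7), 0.05)) == pytest.approx(5.0)

    def test_overall_rowmajor_ramp(self):
        delta = (np.arange(49) / 100.0).reshape(7, 7)
        assert summarize_overall(delta) == pytest.approx(24.0)

    def test_overall_excludes_flagged(self):
        delta = np.full((7, 7), 0.05)
        delta[0, 0] = np.nan
        assert summarize_overall(delta) == pytest.approx(5.0)
        assert np.isnan(summarize_overall(np.full((7, 7), np.nan)))

    def test_msa_planted_block(self):
        delta = np.zeros((7, 7))
        delta[2:5, 3:6] = 0.10
        r = most_synergistic_area(delta)
        assert (r.row, r.col) == (2, 3)
        assert r.mean_delta == pytest.approx(10.0)

    def test_msa_uniform_tie_break(self):
        r = most_synergistic_area(np.full((7, 7), 0.02))
        assert (r.row, r.col) == (0, 0)
        assert r.mean_delta == pytest.approx(2.0)

    def test_msa_against_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            delta = rng.normal(0, 0.1, size=(7, 7))
            got = most_synergistic_area(delta)
            # independent oracle: enumerate all 25 windows directly
            best = max(
                ((float(delta[r:r+3, c:c+3].mean()), (r, c))
                 for r in range(5) for c in range(5)),
                key=lambda t: (t[0], (-t[1][0], -t[1][1])),
            )
            assert (got.row, got.col) == best[1]
            assert got.mean_delta == pytest.approx(100 * best[0])

    def test_msa_at_least_overall(self):
        rng = np.random.default_rng(11)
        delta = rng.normal(0, 0.05, size=(7, 7))
        assert most_synergistic_area(delta).mean_delta >= summarize_overall(delta)


class TestCss:
    def test_full_and_zero_inhibition(self, unit_fit):
        full = surface_from(None, None, lambda a, b: 1.0 if (a or b) else 0.0)
        assert css(full, unit_fit, unit_fit) == pytest.approx(100.0)
        # a surface of zeros: build without tripping the control invariant
        zero = surface_from(None, None, lambda a, b: 0.0 if (a == 0 and b == 0) else 1e-9)
        assert css(zero, unit_fit, unit_fit) == pytest.approx(0.0, abs=1e-6)

    def test_linear_log_ramp_gives_50(self, unit_fit):
        grid = design_matrix(1.0, 1.0)
        lo, hi = np.log10(grid.doses_a[1]), np.log10(grid.doses_a[-1])

        def r(d):
            return 0.0 if d == 0 else (np.log10(d) - lo) / (hi - lo)

        # each CSS line sees an affine-in-log-dose ramp with mean 0.5:
        # along the IC50 line (partner at 1 µM, r = 0.5) values run
        # linearly from 0.25 to 0.75
        surf = surface_from(None, None, lambda a, b: 0.5 * (r(a) + r(b)))
        assert css(surf, unit_fit, unit_fit) == pytest.approx(50.0, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize("scores,label", [
        ({"zip": 7.9, "hsa": 11.8, "bliss": 7.6, "loewe": 8.6}, "synergistic"),
        ({"zip": 4.1, "hsa": 7.8, "bliss": 3.4, "loewe": 0.5}, "additive"),
        ({"zip": -6, "hsa": -6, "bliss": -6, "loewe": -6}, "antagonistic"),
    ])
    def test_strict_rule(self, scores, label):
        assert classify_interaction(scores) == label

    def test_missing_model_partial(self):
        assert classify_interaction({"bliss": 8.0, "hsa": 9.0, "zip": 7.0,
                                     "loewe": float("nan")}) == "synergistic"

    def test_monotone_in_scores(self):
        base = {"zip": 6.0, "hsa": 6.0, "bliss": 6.0, "loewe": 6.0}
        order = {"antagonistic": 0, "additive": 1, "synergistic": 2}
        lab = classify_interaction(base)
        for model in base:
            raised = dict(base, **{model: base[model] + 10})
            assert order[classify_interaction(raised)] >= order[lab]


class TestTransposeInvariance:
    def test_all_models_swap_with_drug_roles(self):
        fa, fb = HillFit(0.95, 0.4, 1.2), HillFit(0.85, 1.5, 1.8)
        grid = design_matrix(fa.ec50_rel, fb.ec50_rel)
        ya = fa.predict(np.asarray(grid.doses_a))[:, None]
        yb = fb.predict(np.asarray(grid.doses_b))[None, :]
        inh = ya + yb - ya * yb
        inh[3:6, 3:6] += 0.08  # asymmetric interaction bump
        surf = ResponseSurface(grid=grid, inhibition=inh)
        t = surf.transpose()
        np.testing.assert_allclose(delta_bliss(t), delta_bliss(surf).T, atol=1e-12)
        np.testing.assert_allclose(delta_hsa(t), delta_hsa(surf).T, atol=1e-12)
        np.testing.assert_allclose(
            delta_loewe(t, fb, fa), delta_loewe(surf, fa, fb).T, atol=1e-9
        )
        np.testing.assert_allclose(
            delta_zip(t, fb, fa), delta_zip(surf, fa, fb).T, atol=1e-9
        )
        assert css(t, fb, fa) == pytest.approx(css(surf, fa, fb))


def test_score_surface_end_to_end():
    fa, fb = HillFit(0.95, 0.4, 1.2), HillFit(0.85, 1.5, 1.8)
    grid = design_matrix(fa.ec50_rel, fb.ec50_rel)
    ya = fa.predict(np.asarray(grid.doses_a))[:, None]
    yb = fb.predict(np.asarray(grid.doses_b))[None, :]
    inh = np.clip(ya + yb - ya * yb + 0.08 * ((ya > 0.2) & (yb > 0.2)), 0, 1.2)
    inh[0, 0] = 0.0
    scores = score_surface(ResponseSurface(grid=grid, inhibition=inh), fa, fb)
    assert set(scores.deltas) == {"bliss", "hsa", "loewe", "zip"}
    assert scores.overall["bliss"] > 0
    assert scores.label in {"synergistic", "additive", "antagonistic"}
    assert 0 <= scores.css <= 100
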