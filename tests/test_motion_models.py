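"""Unit and property tests for the capture-law models and gate optimisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualgate import motion_models as mo
from dualgate.errors import (
    DegenerateFitError,
    DomainError,
    InputError,
    InvalidGateCountError,
    NoFeasibleSchemeError,
    UnidentifiableParameterError,
)

SCANNER = mo.ScannerSpec()


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "c,n,expected",
    [(20.0, 2, 10.0), (12.5, 1, 0.0), (14.1, 5, 11.28)],
)
def test_single_model_values(c, n, expected):
    assert mo.eval_single_model(c, n) == pytest.approx(expected)


@pytest.mark.parametrize(
    "a,b,r,p,expected",
    [
        (10.0, 0.0, 3, 1, 20.0 / 3),
        (14.1, 3.8, 1, 1, 0.0),
        (14.1, 3.8, 5, 4, 14.13),
    ],
)
def test_dual_model_values(a, b, r, p, expected):
    assert mo.eval_dual_model(a, b, r, p) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "a,b,c_daw,r,expected",
    [(5.0, -5.0, 0.0, 3, 0.0), (0.0, 1.0, 1.0, 1, math.e)],
)
def test_dawood_model_values(a, b, c_daw, r, expected):
    assert mo.eval_dawood_model(a, b, c_daw, r) == pytest.approx(expected)


def test_dawood_model_limit_vanishes_when_offsets_cancel():
    assert mo.eval_dawood_model(10.0, -10.0, -1.0, 10_000) == pytest.approx(
        0.0, abs=1e-3
    )


def test_invalid_gate_counts_rejected():
    with pytest.raises(InvalidGateCountError):
        mo.eval_single_model(10.0, 0)
    with pytest.raises(InvalidGateCountError):
        mo.eval_dual_model(1.0, 1.0, 1, 0)


@settings(derandomize=True, max_examples=50)
@given(
    c=st.floats(0.0, 50.0),
    n1=st.integers(1, 30),
    n2=st.integers(1, 30),
)
def test_single_model_monotone_and_zero_at_one_gate(c, n1, n2):
    """f(1) = 0 and f is nondecreasing, bounded by the asymptote c."""
    assert mo.eval_single_model(c, 1) == 0.0
    lo, hi = sorted((n1, n2))
    f_lo = mo.eval_single_model(c, lo)
    f_hi = mo.eval_single_model(c, hi)
    assert f_lo <= f_hi + 1e-12
    assert f_hi <= c + 1e-12


@settings(derandomize=True, max_examples=50)
@given(
    a=st.floats(0.0, 30.0),
    b=st.floats(0.0, 30.0),
    r=st.integers(1, 20),
    p=st.integers(1, 20),
)
def test_dual_model_zero_at_single_gate_and_bounded(a, b, r, p):
    assert mo.eval_dual_model(a, b, 1, 1) == 0.0
    val = mo.eval_dual_model(a, b, r, p)
    assert -1e-12 <= val <= a + b + 1e-12


# ---------------------------------------------------------------------------
# fitting, with grid-search oracles
# ---------------------------------------------------------------------------


def _grid_search_single(samples, span=(0.0, 60.0), rounds=6, points=200):
    """Independent 1-D least-squares oracle: iteratively refined grid scan."""
    lo, hi = span
    best = None
    for _ in range(rounds):
        cs = np.linspace(lo, hi, points)
        sse = [
            sum((m - c * (n - 1) / n) ** 2 for n, m in samples) for c in cs
        ]
        best = cs[int(np.argmin(sse))]
        width = (hi - lo) / points
        lo, hi = best - 2 * width, best + 2 * width
    return best


def _grid_search_dual(samples, span=60.0, rounds=6, points=80):
    """Independent 2-D least-squares oracle for (a, b)."""
    a_lo, a_hi, b_lo, b_hi = 0.0, span, 0.0, span
    best = (0.0, 0.0)
    for _ in range(rounds):
        avals = np.linspace(a_lo, a_hi, points)
        bvals = np.linspace(b_lo, b_hi, points)
        wr = np.array([(s.scheme.n_resp - 1) / s.scheme.n_resp for s in samples])
        wp = np.array([(s.scheme.n_card - 1) / s.scheme.n_card for s in samples])
        y = np.array([s.motion_mm for s in samples])
        pred = (
            avals[:, None, None] * wr[None, None, :]
            + bvals[None, :, None] * wp[None, None, :]
        )
        sse = ((pred - y[None, None, :]) ** 2).sum(axis=2)
        ia, ib = np.unravel_index(int(np.argmin(sse)), sse.shape)
        best = (avals[ia], bvals[ib])
        wa = (a_hi - a_lo) / points
        wb = (b_hi - b_lo) / points
        a_lo, a_hi = best[0] - 2 * wa, best[0] + 2 * wa
        b_lo, b_hi = best[1] - 2 * wb, best[1] + 2 * wb
    return best


def test_fit_single_exact_points():
    fit = mo.fit_single_model([(2, 6.0), (3, 8.0), (4, 9.0)])
    assert fit.c == pytest.approx(12.0)
    assert fit.m_est == pytest.approx(12.0)
    assert mo.fit_single_model([(2, 5.0)]).c == pytest.approx(10.0)


def test_fit_single_matches_grid_oracle_under_noise():
    gen = np.random.default_rng(42)
    samples = [
        (n, mo.eval_single_model(14.1, n) + 0.3 * gen.standard_normal())
        for n in list(range(2, 12)) * 2
    ]
    fit = mo.fit_single_model(samples)
    assert abs(fit.c - 14.1) < 0.3
    assert fit.c == pytest.approx(_grid_search_single(samples), abs=1e-6)


def test_fit_single_unidentifiable():
    with pytest.raises(UnidentifiableParameterError):
        mo.fit_single_model([(1, 0.0), (1, 0.0)])


def test_fit_dual_exact_and_oracle():
    truth = (12.0, 10.0)
    samples = [
        mo.MotionSample(mo.GateScheme(r, p), mo.eval_dual_model(*truth, r, p))
        for r in range(1, 6)
        for p in (1, 4, 6)
    ]
    fit = mo.fit_dual_model(samples)
    assert (fit.a, fit.b) == (pytest.approx(12.0), pytest.approx(10.0))

    gen = np.random.default_rng(3)
    noisy = [
        mo.MotionSample(
            s.scheme, max(s.motion_mm + 0.3 * gen.standard_normal(), 0.0)
        )
        for s in samples * 2
    ]
    fit_n = mo.fit_dual_model(noisy)
    a_o, b_o = _grid_search_dual(noisy)
    assert fit_n.a == pytest.approx(a_o, abs=1e-6)
    assert fit_n.b == pytest.approx(b_o, abs=1e-6)


def test_fit_dual_needs_both_axes():
    samples = [
        mo.MotionSample(mo.GateScheme(r, 1), mo.eval_single_model(5.0, r))
        for r in range(1, 6)
    ]
    with pytest.raises(UnidentifiableParameterError):
        mo.fit_dual_model(samples)


def test_fit_dawood_roundtrip_and_preconditions():
    truth = (15.0, -15.0, -2.0)
    samples = [(n, mo.eval_dawood_model(*truth, n)) for n in (1, 2, 3, 4, 6, 8)]
    fit = mo.fit_dawood_model(samples)
    assert fit.a == pytest.approx(truth[0], abs=1e-4)
    assert fit.b == pytest.approx(truth[1], abs=1e-4)
    assert fit.c_daw == pytest.approx(truth[2], abs=1e-4)
    assert fit.m_est == pytest.approx(0.0, abs=1e-4)
    with pytest.raises(UnidentifiableParameterError):
        mo.fit_dawood_model(samples[:2])


def test_capture_law_and_exponential_model_agree_on_shared_data():
    """Both respiratory models deliver nearly the same asymptotic motion."""
    gen = np.random.default_rng(8)
    samples = [
        (n, mo.eval_single_model(14.1, n) + 0.2 * gen.standard_normal())
        for n in (2, 3, 4, 5, 6) * 3
    ]
    m_capture = mo.fit_single_model(samples).m_est
    m_exp = mo.fit_dawood_model(samples).m_est
    assert abs(m_capture - m_exp) < 1.0


# ---------------------------------------------------------------------------
# optimal gate numbers
# ---------------------------------------------------------------------------


def _brute_force_optimal(c: float, s: float) -> int:
    target = c - s / 2
    if target <= 1e-9:
        return 1
    n = 1
    while mo.eval_single_model(c, n) < target - 1e-9:
        n += 1
    return n


@pytest.mark.parametrize("c,expected", [(14.1, 6), (2.5, 1), (10.0, 4)])
def test_optimal_gates_single_examples(c, expected):
    fit = mo.MotionModelFit(kind="single_resp", c=c)
    assert mo.optimal_gates_single(fit, SCANNER) == expected
    assert _brute_force_optimal(c, 5.2) == expected


def test_optimal_gates_dual_examples():
    s = SCANNER
    dual = lambda a, b: mo.optimal_gates_dual(
        mo.MotionModelFit(kind="dual", a=a, b=b), s
    )
    assert dual(14.1, 3.8) == mo.GateScheme(6, 2)
    assert dual(2.5, 5.5) == mo.GateScheme(1, 3)
    assert dual(0.0, 0.0) == mo.GateScheme(1, 1)


def test_threshold_from_motion():
    assert mo.threshold_from_motion(14.1, 3.8, SCANNER) == pytest.approx(12.7)
    assert mo.threshold_from_motion(2.6, 2.6, SCANNER) == pytest.approx(0.0)
    assert mo.threshold_from_motion(12.0, 10.0, SCANNER) == pytest.approx(16.8)


def test_optimal_from_grid_reference_fixture():
    grid = mo.reference_motion_grid()
    assert mo.optimal_from_grid(grid, 12.7) == mo.GateScheme(5, 4)
    assert mo.optimal_from_grid(grid, 0.0) == mo.GateScheme(1, 1)
    with pytest.raises(NoFeasibleSchemeError):
        mo.optimal_from_grid(grid, 13.0)


def test_grid_csv_roundtrip(tmp_path):
    grid = mo.reference_motion_grid()
    path = tmp_path / "grid.csv"
    grid.to_csv(path)
    back = mo.GateGrid.from_csv(path)
    assert back.resp_counts == grid.resp_counts
    assert back.card_counts == grid.card_counts
    np.testing.assert_allclose(back.motion_mm, grid.motion_mm)


def test_resolve_gate_combination():
    assert mo.resolve_gate_combination(20, 5) == mo.GateScheme(5, 4)
    assert mo.resolve_gate_combination(7, 7) == mo.GateScheme(7, 1)
    assert mo.resolve_gate_combination(10, 3) == mo.GateScheme(3, 4)
    with pytest.raises(InvalidGateCountError):
        mo.resolve_gate_combination(4, 5)


# ---------------------------------------------------------------------------
# linear gates-versus-motion rules
# ---------------------------------------------------------------------------


def test_published_lines_reproduce_worked_example():
    n_total = mo.eval_gate_count_line(mo.DUAL_GATE_LINE, 22.0, rounding="up")
    n_resp = mo.eval_gate_count_line(
        mo.RESPIRATORY_GATE_LINE, 12.0, rounding="nearest"
    )
    assert n_total == 20
    assert n_resp == 5
    assert mo.resolve_gate_combination(n_total, n_resp) == mo.GateScheme(5, 4)


def test_line_domain_and_raw_value():
    assert mo.eval_gate_count_line(mo.CARDIAC_GATE_LINE, 0.0) == pytest.approx(
        0.718
    )
    with pytest.raises(DomainError):
        mo.eval_gate_count_line(mo.DUAL_GATE_LINE, 5.0)


def test_fit_gate_count_line():
    pts = [(m, 0.35 * m + 1.005) for m in (2.0, 5.0, 9.0, 14.0)]
    line = mo.fit_gate_count_line(pts)
    assert line.slope == pytest.approx(0.35)
    assert line.intercept == pytest.approx(1.005)
    assert line.r_squared == pytest.approx(1.0)
    two = mo.fit_gate_count_line([(0.0, 1.0), (10.0, 5.0)])
    assert (two.slope, two.intercept) == (pytest.approx(0.4), pytest.approx(1.0))
    with pytest.raises(DegenerateFitError):
        mo.fit_gate_count_line([(3.0, 1.0), (3.0, 2.0)])


# ---------------------------------------------------------------------------
# agreement metrics
# ---------------------------------------------------------------------------


def test_md_rmse_examples():
    assert mo.md([1, 2, 3], [1, 2, 3]) == 0.0
    assert mo.rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert mo.md([0, 0], [1, 3]) == pytest.approx(2.0)
    assert mo.rmse([0, 0], [1, 3]) == pytest.approx(math.sqrt(5))
    with pytest.raises(InputError):
        mo.md([1.0], [1.0, 2.0])
    with pytest.raises(InputError):
        mo.rmse([], [])


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.tuples(
            st.floats(-100, 100, allow_nan=False),
            st.floats(-100, 100, allow_nan=False),
        ),
        min_size=1,
        max_size=30,
    )
)
def test_rmse_dominates_md(pairs):
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    assert mo.rmse(x, y) >= mo.md(x, y) - 1e-12


def test_negative_fit_clamped_with_warning():
    samples = [mo.MotionSample(mo.GateScheme(r, p), 0.0)
               for r in (1, 2, 3) for p in (1, 2)]
    # inject motion explained entirely by the respiratory axis: b fits < 0
    samples = [
        mo.MotionSample(
            s.scheme,
            max(
                mo.eval_single_model(10.0, s.scheme.n_resp)
                - 0.5 * mo.eval_single_model(1.0, s.scheme.n_card),
                0.0,
            ),
        )
        for s in samples
    ]
    with pytest.warns(UserWarning, match="clamped"):
        fit = mo.fit_dual_model(samples)
    assert fit.b == 0.0
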