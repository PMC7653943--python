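"""Motion models for gated cardiac PET and optimal gate-number estimation.

The central idea: a cyclic motion of amplitude ``h`` observed through ``n``
gates is captured only partially.  The gate means divide the excursion into
``n - 1`` intervals, so the displacement measured between the two extreme
gates is ``h (n-1)/n``.  Fitting that law to measured motion-versus-gate-count
data yields the asymptotic amplitude ``m_est``; the optimal gate count is the
smallest one that captures the motion to within half the scanner resolution
``s``.  A two-factor version treats respiratory (``r`` gates, amplitude ``a``)
and cardiac (``p`` gates, amplitude ``b``) motion as additive, giving
``g(r, p) = a (r-1)/r + b (p-1)/p`` and componentwise optimal counts.

The module also provides the empirical exponential respiratory model of
Dawood et al. (``a + b e^{c/r}``) for comparison, published linear
gates-versus-motion rules, grid search over a measured motion table, and the
MD/RMSE agreement metrics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    DegenerateFitError,
    DomainError,
    FitFailureError,
    InputError,
    InvalidGateCountError,
    NoFeasibleSchemeError,
    UnidentifiableParameterError,
)

__all__ = [
    "ScannerSpec",
    "GateScheme",
    "MotionSample",
    "MotionModelFit",
    "GateGrid",
    "GateCountLine",
    "RESPIRATORY_GATE_LINE",
    "CARDIAC_GATE_LINE",
    "DUAL_GATE_LINE",
    "DAWOOD_REPORTED_LINE",
    "DAWOOD_MODEL_GATE_LINE",
    "eval_single_model",
    "eval_dual_model",
    "eval_dawood_model",
    "fit_single_model",
    "fit_dual_model",
    "fit_dawood_model",
    "optimal_gates_single",
    "optimal_gates_dual",
    "optimal_from_grid",
    "threshold_from_motion",
    "eval_gate_count_line",
    "fit_gate_count_line",
    "resolve_gate_combination",
    "md",
    "rmse",
    "read_single_samples",
    "read_motion_samples",
    "reference_motion_grid",
]

#: numeric slack used when comparing measured motion against thresholds, so
#: that decimal values such as 12.7 survive float round-trips
_EPS = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScannerSpec:
    """PET scanner geometry relevant to gating.

    Defaults follow a whole-body clinical system: effective resolution
    5.2 mm FWHM and a 192 x 192 x 47 reconstruction grid with
    1.82 x 1.82 x 3.27 mm voxels (35 cm transaxial FOV).
    """

    resolution_fwhm_mm: float = 5.2
    voxel_size_mm: tuple[float, float, float] = (1.82, 1.82, 3.27)
    volume_shape: tuple[int, int, int] = (192, 192, 47)

    def __post_init__(self):
        if not self.resolution_fwhm_mm > 0:
            raise InputError("scanner resolution must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InputError("voxel sizes must be positive")
        if any(int(n) < 1 for n in self.volume_shape):
            raise InputError("volume shape entries must be >= 1")


@dataclass(frozen=True, order=True)
class GateScheme:
    """A (respiratory, cardiac) gate-count pair."""

    n_resp: int
    n_card: int

    def __post_init__(self):
        if self.n_resp < 1 or self.n_card < 1:
            raise InvalidGateCountError(
                f"gate counts must be >= 1, got ({self.n_resp}, {self.n_card})"
            )

    @property
    def total(self) -> int:
        return self.n_resp * self.n_card


@dataclass(frozen=True)
class MotionSample:
    """A motion measurement (mm, between extreme gates) for one scheme."""

    scheme: GateScheme
    motion_mm: float

    def __post_init__(self):
        if self.motion_mm < 0:
            raise InputError("measured motion must be non-negative")


@dataclass(frozen=True)
class MotionModelFit:
    """Fitted motion-model parameters and the asymptotic amplitude m_est.

    ``kind`` selects the parameterisation: ``single_resp``/``single_card``
    use ``c`` (m_est = c); ``dual`` uses ``a`` (respiratory) and ``b``
    (cardiac) with m_est = a + b; ``dawood`` uses offset ``a``, scale ``b``
    and the dimensionless exponent ``c_daw`` with m_est = a + b (the
    r -> infinity limit of a + b e^{c/r}).
    """

    kind: Literal["single_resp", "single_card", "dual", "dawood"]
    c: float | None = None
    a: float | None = None
    b: float | None = None
    c_daw: float | None = None

    @property
    def m_est(self) -> float:
        if self.kind in ("single_resp", "single_card"):
            return float(self.c)
        return float(self.a) + float(self.b)

    def predict(self, scheme: GateScheme) -> float:
        """Model motion for a gate scheme (single models use their own axis)."""
        if self.kind == "single_resp":
            return eval_single_model(self.c, scheme.n_resp)
        if self.kind == "single_card":
            return eval_single_model(self.c, scheme.n_card)
        if self.kind == "dual":
            return eval_dual_model(self.a, self.b, scheme.n_resp, scheme.n_card)
        return eval_dawood_model(self.a, self.b, self.c_daw, scheme.n_resp)

    def to_json(self) -> dict:
        rec = {"kind": self.kind, "m_est": self.m_est}
        for key in ("c", "a", "b", "c_daw"):
            val = getattr(self, key)
            if val is not None:
                rec[key] = float(val)
        return rec


@dataclass(frozen=True)
class GateGrid:
    """Measured total motion (mm) on a grid of (respiratory, cardiac) counts.

    ``motion_mm`` is indexed ``[cardiac, respiratory]`` to match the printed
    layout of motion tables (cardiac counts down the rows).
    """

    resp_counts: tuple[int, ...]
    card_counts: tuple[int, ...]
    motion_mm: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.motion_mm, dtype=float)
        object.__setattr__(self, "motion_mm", m)
        if m.shape != (len(self.card_counts), len(self.resp_counts)):
            raise InputError(
                f"grid shape {m.shape} does not match counts "
                f"({len(self.card_counts)} cardiac x {len(self.resp_counts)} respiratory)"
            )
        if m.size == 0:
            raise InputError("empty motion grid")
        if (m < 0).any():
            raise InputError("motion entries must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "GateGrid":
        """Read the CSV layout: header row = respiratory counts, first
        column = cardiac counts."""
        df = pd.read_csv(path, index_col=0)
        return cls(
            resp_counts=tuple(int(c) for c in df.columns),
            card_counts=tuple(int(i) for i in df.index),
            motion_mm=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.motion_mm,
            index=pd.Index(self.card_counts, name="n_card"),
            columns=[str(c) for c in self.resp_counts],
        )
        df.to_csv(path)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.motion_mm,
            index=pd.Index(self.card_counts, name="n_card"),
            columns=pd.Index(self.resp_counts, name="n_resp"),
        )


@dataclass(frozen=True)
class GateCountLine:
    """A linear gates-versus-motion rule ``n(m) = slope * m + intercept``.

    ``m`` is a motion amplitude in mm; ``domain_min_mm`` is the smallest
    motion the rule was derived for.  ``r_squared`` is the squared Pearson
    correlation of the fit behind the rule (``None`` when not reported).
    """

    slope: float
    intercept: float
    r_squared: float | None = None
    domain_min_mm: float = 0.0

    def __post_init__(self):
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise InputError("r_squared must lie in [0, 1]")


#: published rule for the optimal number of respiratory gates vs motion
RESPIRATORY_GATE_LINE = GateCountLine(0.350, 1.005, r_squared=0.978)
#: published rule for the optimal number of cardiac gates vs motion
CARDIAC_GATE_LINE = GateCountLine(0.356, 0.718, r_squared=0.926)
#: published rule for the optimal total number of dual gates vs combined motion
DUAL_GATE_LINE = GateCountLine(1.717, -18.730, r_squared=0.951, domain_min_mm=12.0)
#: respiratory rule reported by Dawood et al. for their own data
DAWOOD_REPORTED_LINE = GateCountLine(0.488, -0.869)
#: respiratory rule obtained when the exponential model is fitted instead
DAWOOD_MODEL_GATE_LINE = GateCountLine(0.407, -0.408)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def _check_gate_count(n: int, name: str = "n") -> int:
    n_int = int(n)
    if n_int != n or n_int < 1:
        raise InvalidGateCountError(f"{name} must be an integer >= 1, got {n!r}")
    return n_int


def eval_single_model(c: float, n: int) -> float:
    """Motion captured by ``n`` gates of a single cyclic motion: c (n-1)/n."""
    n = _check_gate_count(n)
    if c < 0:
        raise InputError("amplitude c must be non-negative")
    return c * (n - 1) / n


def eval_dual_model(a: float, b: float, r: int, p: int) -> float:
    """Combined respiratory+cardiac motion seen by an (r, p) dual scheme.

    ``[a (r-1) p + b r (p-1)] / (r p)``, i.e. the two single-mode laws summed.
    """
    r = _check_gate_count(r, "r")
    p = _check_gate_count(p, "p")
    if a < 0 or b < 0:
        raise InputError("amplitudes a, b must be non-negative")
    return (a * (r - 1) * p + b * r * (p - 1)) / (r * p)


def eval_dawood_model(a: float, b: float, c_daw: float, r: int) -> float:
    """Empirical exponential respiratory model ``a + b e^{c/r}``.

    Note it does not vanish at r = 1 (motion a + b e^c), unlike the
    ``c (n-1)/n`` law which is exactly zero for a single gate.
    """
    r = _check_gate_count(r, "r")
    return a + b * math.exp(c_daw / r)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _clamp_nonneg(value: float, name: str) -> float:
    if value < 0:
        warnings.warn(
            f"fitted {name} = {value:.4g} mm is negative; clamped to 0 "
            "(motion amplitudes are physical lengths)",
            stacklevel=3,
        )
        return 0.0
    return float(value)


def fit_single_model(
    samples: Iterable[tuple[int, float]], kind: str = "single_resp"
) -> MotionModelFit:
    """Least-squares amplitude ``c`` for the single-mode law c (n-1)/n.

    The model is linear in ``c``: with weights w_i = (n_i - 1)/n_i the
    closed form is c = sum(w_i y_i) / sum(w_i^2).
    """
    pts = [( _check_gate_count(n), float(y)) for n, y in samples]
    if not pts:
        raise InputError("no samples")
    w = np.array([(n - 1) / n for n, _ in pts])
    y = np.array([m for _, m in pts])
    if not (w > 0).any():
        raise UnidentifiableParameterError(
            "all samples have n = 1; the amplitude c is unidentifiable"
        )
    c = float(w @ y / (w @ w))
    return MotionModelFit(kind=kind, c=_clamp_nonneg(c, "c"))


def fit_dual_model(samples: Iterable[MotionSample]) -> MotionModelFit:
    """Linear least squares for (a, b) of the additive dual-gating law.

    Design columns are (r-1)/r and (p-1)/p; identifiability requires at
    least one sample with r >= 2 and one with p >= 2.
    """
    samples = list(samples)
    if not samples:
        raise InputError("no samples")
    X = np.array(
        [
            [
                (s.scheme.n_resp - 1) / s.scheme.n_resp,
                (s.scheme.n_card - 1) / s.scheme.n_card,
            ]
            for s in samples
        ]
    )
    y = np.array([s.motion_mm for s in samples])
    if np.linalg.matrix_rank(X) < 2:
        raise UnidentifiableParameterError(
            "rank-deficient design: need samples with r >= 2 and with p >= 2"
        )
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    return MotionModelFit(
        kind="dual", a=_clamp_nonneg(a, "a"), b=_clamp_nonneg(b, "b")
    )


def fit_dawood_model(samples: Iterable[tuple[int, float]]) -> MotionModelFit:
    """Nonlinear least squares for the exponential model a + b e^{c/r}.

    Deterministic: the initial guess is (max motion, -max motion, -1) and the
    solver is capped at 500 function evaluations.
    """
    pts = [(_check_gate_count(n), float(y)) for n, y in samples]
    if len({n for n, _ in pts}) < 3:
        raise UnidentifiableParameterError(
            "the 3-parameter exponential model needs >= 3 distinct gate counts"
        )
    n = np.array([float(n) for n, _ in pts])
    y = np.array([m for _, m in pts])
    m0 = float(y.max()) or 1.0

    def residual(theta):
        a, b, c = theta
        return a + b * np.exp(c / n) - y

    result = optimize.least_squares(
        residual, x0=(m0, -m0, -1.0), max_nfev=500, method="lm"
    )
    if not result.success:
        raise FitFailureError(
            f"exponential motion-model fit did not converge: {result.message}",
            residuals=result.fun,
        )
    a, b, c_daw = (float(v) for v in result.x)
    return MotionModelFit(kind="dawood", a=a, b=b, c_daw=c_daw)


# ---------------------------------------------------------------------------
# optimal gate numbers
# ---------------------------------------------------------------------------


def _optimal_count(amplitude: float, s: float) -> int:
    """Smallest n with amplitude*(n-1)/n >= amplitude - s/2.

    Inverting the capture law gives n = 2*amplitude/s (ceiling).  Motion at
    or below half the scanner resolution needs no gating: the count is 1.
    """
    if amplitude <= s / 2 + _EPS:
        return 1
    return max(1, math.ceil(2 * amplitude / s - _EPS))


def optimal_gates_single(fit: MotionModelFit, scanner: ScannerSpec) -> int:
    """Optimal gate count for a single-mode fit (ceil of f^-1(m_est - s/2))."""
    if fit.kind not in ("single_resp", "single_card"):
        raise InputError("optimal_gates_single needs a single-mode fit")
    return _optimal_count(fit.m_est, scanner.resolution_fwhm_mm)


def optimal_gates_dual(fit: MotionModelFit, scanner: ScannerSpec) -> GateScheme:
    """Componentwise optimal (r, p) for a dual fit; each uses the s/2 rule."""
    if fit.kind != "dual":
        raise InputError("optimal_gates_dual needs a dual fit")
    s = scanner.resolution_fwhm_mm
    return GateScheme(_optimal_count(fit.a, s), _optimal_count(fit.b, s))


def threshold_from_motion(m_r: float, m_p: float, scanner: ScannerSpec) -> float:
    """Motion-minimisation threshold: the part of each motion above s/2.

    ``max(m_r - s/2, 0) + max(m_p - s/2, 0)`` — e.g. respiratory 14.1 mm and
    cardiac 3.8 mm at 5.2 mm resolution give 11.5 + 1.2 = 12.7 mm.
    """
    if m_r < 0 or m_p < 0:
        raise InputError("motion amplitudes must be non-negative")
    half = scanner.resolution_fwhm_mm / 2
    return max(m_r - half, 0.0) + max(m_p - half, 0.0)


def optimal_from_grid(grid: GateGrid, threshold_mm: float) -> GateScheme:
    """Smallest-product (r, p) whose measured motion reaches the threshold.

    Ties are broken toward fewer cardiac gates, then fewer respiratory gates
    (ECG gating discards less data than respiratory gating).
    """
    feasible = []
    for i, p in enumerate(grid.card_counts):
        for j, r in enumerate(grid.resp_counts):
            if grid.motion_mm[i, j] >= threshold_mm - _EPS:
                feasible.append((r * p, p, r))
    if not feasible:
        raise NoFeasibleSchemeError(
            f"no grid cell reaches {threshold_mm} mm "
            f"(max measured {grid.motion_mm.max():.1f} mm)"
        )
    _, p, r = min(feasible)
    return GateScheme(n_resp=r, n_card=p)


def resolve_gate_combination(n_total: int, n_resp: int) -> GateScheme:
    """Split a total gate budget into (r, p) with p = ceil(n_total / r)."""
    n_total = _check_gate_count(n_total, "n_total")
    n_resp = _check_gate_count(n_resp, "n_resp")
    if n_resp > n_total:
        raise InvalidGateCountError(
            f"n_resp={n_resp} exceeds the total gate count {n_total}"
        )
    return GateScheme(n_resp=n_resp, n_card=math.ceil(n_total / n_resp))


# ---------------------------------------------------------------------------
# general linear gates-vs-motion rules
# ---------------------------------------------------------------------------

Rounding = Literal["none", "nearest", "up"]


def eval_gate_count_line(
    line: GateCountLine, m: float, rounding: Rounding = "none"
) -> float | int:
    """Evaluate a linear gates-versus-motion rule at motion ``m`` (mm).

    ``rounding="up"`` (ceiling) is the convention for total dual-gate
    budgets; ``"nearest"`` (half-up) for per-mode gate counts; ``"none"``
    returns the raw line value.
    """
    if m < line.domain_min_mm - _EPS:
        raise DomainError(
            f"motion {m} mm is below the rule's domain (>= {line.domain_min_mm} mm)"
        )
    value = line.slope * m + line.intercept
    if rounding == "none":
        return value
    if rounding == "up":
        return math.ceil(value - _EPS)
    if rounding == "nearest":
        return math.floor(value + 0.5)
    raise InputError(f"unknown rounding mode {rounding!r}")


def fit_gate_count_line(points: Iterable[tuple[float, float]]) -> GateCountLine:
    """OLS line through (motion_mm, n_gates) points.

    R^2 is the squared Pearson correlation between fitted and observed gate
    counts.
    """
    pts = [(float(m), float(n)) for m, n in points]
    if len(pts) < 2:
        raise DegenerateFitError("need at least two points")
    m = np.array([x for x, _ in pts])
    n = np.array([y for _, y in pts])
    if np.ptp(m) == 0:
        raise DegenerateFitError("all motion values identical; slope undefined")
    slope, intercept = np.polyfit(m, n, 1)
    fitted = slope * m + intercept
    if np.ptp(n) == 0 or np.ptp(fitted) == 0:
        r2 = 1.0 if np.allclose(fitted, n) else 0.0
    else:
        r2 = float(np.corrcoef(fitted, n)[0, 1] ** 2)
    return GateCountLine(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        domain_min_mm=float(m.min()),
    )


# ---------------------------------------------------------------------------
# agreement metrics
# ---------------------------------------------------------------------------


def _paired(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise InputError("series must be non-empty and of equal length")
    return x, y


def md(x: Sequence[float], y: Sequence[float]) -> float:
    """Mean absolute difference between paired series."""
    x, y = _paired(x, y)
    return float(np.mean(np.abs(x - y)))


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root-mean-square difference between paired series (always >= md)."""
    x, y = _paired(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_single_samples(path) -> list[tuple[int, float]]:
    """Read a single-mode motion table CSV with columns ``n,motion_mm``."""
    df = pd.read_csv(path)
    _require_columns(df, ("n", "motion_mm"), path)
    return [(int(r.n), float(r.motion_mm)) for r in df.itertuples()]


def read_motion_samples(path) -> list[MotionSample]:
    """Read a dual motion table CSV with columns ``n_resp,n_card,motion_mm``."""
    df = pd.read_csv(path)
    _require_columns(df, ("n_resp", "n_card", "motion_mm"), path)
    return [
        MotionSample(GateScheme(int(r.n_resp), int(r.n_card)), float(r.motion_mm))
        for r in df.itertuples()
    ]


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")


def reference_motion_grid() -> GateGrid:
    """The package's bundled phantom motion grid (measured total motion in mm
    for respiratory counts 1-6 against cardiac counts 1, 4, 6, 8, 10)."""
    path = Path(__file__).parent / "data" / "phantom_motion_grid.csv"
    return GateGrid.from_csv(path)


def write_fit_json(path, fit: MotionModelFit, **extra) -> None:
    rec = fit.to_json()
    rec.update(extra)
    Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
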