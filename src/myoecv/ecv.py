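"""Partition coefficient and extracellular volume fraction.

The chain: T1 (ms) -> R1 = 1000/T1 (1/s) for septum and blood pool at each
acquisition time; detect the post-contrast window in which the myocardial
and blood enhancements change proportionally (the contrast equilibrium
state); regress myocardial R1 on blood R1 over the pre-contrast point plus
that window — the slope is the partition coefficient lambda; finally
ECV = lambda * (1 - hematocrit).

Points earlier than 5 min post-injection never enter the regression:
blood-myocardium equilibrium is not reached before then.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateFitError, NoEquilibriumError, RoiError
from .relaxometry import T1Map
from .synthetic.mri import LABELS

__all__ = [
    "R1TimePoint",
    "LambdaFit",
    "EcvResult",
    "r1_from_t1",
    "extract_roi_r1",
    "detect_equilibrium",
    "fit_lambda",
    "compute_ecv",
    "estimate_ecv",
]

#: earliest post-injection time (min) eligible for the equilibrium window
MIN_EQUILIBRIUM_TIME = 5.0


@dataclass(frozen=True)
class R1TimePoint:
    """Paired myocardial/blood R1 (1/s) at one post-injection time (min)."""

    t_min: float
    r1_blood: float
    r1_myo: float

    def __post_init__(self) -> None:
        if self.r1_blood <= 0 or self.r1_myo <= 0:
            raise ValueError("R1 values must be positive")


@dataclass(frozen=True)
class LambdaFit:
    lambda_: float  # regression slope, dimensionless
    intercept: float  # 1/s
    r_squared: float
    n_points: int
    window_start_min: float
    points_used: tuple[R1TimePoint, ...]


@dataclass(frozen=True)
class EcvResult:
    ecv: float
    lambda_: float
    hematocrit: float


def r1_from_t1(t1_ms: float) -> float:
    """R1 in 1/s from T1 in ms."""
    if t1_ms <= 0:
        raise ValueError("T1 must be positive")
    return 1000.0 / t1_ms


def extract_roi_r1(t1_map: T1Map, region: str) -> float:
    """Mean R1 (1/s) of a labelled region after one-pixel border erosion.

    Only ``septum`` and ``blood_pool`` are measurable; the free wall is
    refused because occasional artifacts there bias T1, which is why the
    analysis is restricted to the interventricular septum.
    """
    if region == "free_wall":
        raise RoiError(
            "free_wall refused: artifacts can corrupt free-wall T1; analysis is "
            "restricted to the interventricular septum"
        )
    if region not in ("septum", "blood_pool"):
        raise RoiError(f"region {region!r} is not measurable (expected septum or blood_pool)")
    mask = t1_map.labels == LABELS[region]
    eroded = ndimage.binary_erosion(mask)  # one-pixel border-zone avoidance
    valid = eroded & (t1_map.values > 0)
    if valid.sum() < 10:
        raise RoiError(
            f"region {region!r}: only {int(valid.sum())} valid pixels after erosion (need >= 10)"
        )
    return r1_from_t1(float(t1_map.values[valid].mean()))


def _split_pre_post(points: Sequence[R1TimePoint]) -> tuple[R1TimePoint, list[R1TimePoint]]:
    pre = [p for p in points if p.t_min == 0]
    post = sorted((p for p in points if p.t_min > 0), key=lambda p: p.t_min)
    if len(pre) != 1:
        raise ValueError("need exactly one pre-contrast (t=0) point")
    return pre[0], post


def detect_equilibrium(
    points: Sequence[R1TimePoint],
    rel_tol: float = 0.05,
    min_time: float = MIN_EQUILIBRIUM_TIME,
    min_confirming: int = 3,
) -> float:
    """Earliest time from which the enhancement ratio is stable.

    The instantaneous ratio (R1_myo - R1_myo,pre) / (R1_blood - R1_blood,pre)
    is computed per post-contrast point, smoothed with a 3-point running
    median, and fitted to the convergence model

        ratio(t) = c + d exp(-t / tau_r),

    i.e. a transient decaying toward the equilibrium plateau c. Equilibrium
    starts at the earliest eligible sample time (>= ``min_time`` min) where
    the modeled transient |d| exp(-t/tau_r) has fallen below
    ``rel_tol * |c|``, provided at least ``min_confirming`` samples follow.
    A course whose modeled transient is still above tolerance at the last
    sample never equilibrated: :class:`NoEquilibriumError`. Fitting the
    transient rather than thresholding raw point-to-point spread keeps the
    decision robust to measurement noise while still rejecting
    systematically drifting courses.
    """
    pre, post = _split_pre_post(points)
    if len(post) < 4:
        raise ValueError("need at least 4 post-contrast points")
    t = np.array([p.t_min for p in post])
    ratio = np.array(
        [(p.r1_myo - pre.r1_myo) / (p.r1_blood - pre.r1_blood) for p in post]
    )
    smooth = ndimage.median_filter(ratio, size=3, mode="nearest")
    ref = float(np.median(smooth[-3:]))
    if ref == 0:
        raise NoEquilibriumError("tail enhancement ratio is zero; no equilibrium")
    # the uptake phase before min_time is categorically pre-equilibrium and
    # would otherwise absorb the fitted transient
    eligible = np.nonzero(t >= min_time)[0]
    if eligible.size < 4:
        raise ValueError(f"need at least 4 post-contrast points at t >= {min_time} min")
    te, se = t[eligible], smooth[eligible]
    # ratio noise scales inversely with the blood enhancement (the ratio
    # denominator); weight the fit accordingly so late small-enhancement
    # points cannot distort the transient
    blood_delta = np.array([post[i].r1_blood - pre.r1_blood for i in eligible])
    sigma = 1.0 / np.maximum(np.abs(blood_delta), 1e-6)

    def model(tt, c, d, tau_r):
        return c + d * np.exp(-tt / tau_r)

    import warnings

    from scipy.optimize import curve_fit

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, te, se, sigma=sigma,
                p0=[ref, float(se[0] - ref), 5.0],
                # transients slower than the observation span are
                # indistinguishable from drift; bounding tau_r keeps the
                # amplitude d identifiable on noisy near-flat courses
                bounds=([-np.inf, -np.inf, 0.1], [np.inf, np.inf, float(te[-1])]),
                maxfev=5000,
            )
        c, d, tau_r = popt
        transient = np.abs(d) * np.exp(-te / tau_r)
    except Exception:
        # degenerate fit (e.g. perfectly flat ratio): no transient left
        c = ref
        transient = np.abs(se - ref)
    tol = rel_tol * abs(c) if c != 0 else rel_tol * abs(ref)
    for k, i in enumerate(eligible):
        if t.size - i < 1 + min_confirming:
            # a window this late cannot be confirmed; a course whose
            # transient is still above tolerance here never equilibrated
            break
        if transient[k] < tol:
            return float(t[i])
    raise NoEquilibriumError(
        f"enhancement ratio never stabilised within rel_tol={rel_tol} for t >= {min_time} min"
    )


def fit_lambda(points: Sequence[R1TimePoint], window_start_min: float) -> LambdaFit:
    """OLS of myocardial R1 on blood R1 over {pre-contrast} + {t >= window}.

    The pre-contrast point anchors the intercept; the slope is lambda.
    """
    pre, post = _split_pre_post(points)
    used = [pre] + [p for p in post if p.t_min >= window_start_min]
    if len(used) < 4:  # pre + >= 3 equilibrium points
        raise ValueError(
            f"need the pre-contrast point plus >= 3 points at t >= {window_start_min} min, "
            f"got {len(used) - 1}"
        )
    x = np.array([p.r1_blood for p in used])
    y = np.array([p.r1_myo for p in used])
    if np.ptp(x) < 1e-12:
        raise DegenerateFitError("blood R1 values are all equal; slope undefined")
    res = stats.linregress(x, y)
    return LambdaFit(
        lambda_=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(used),
        window_start_min=float(window_start_min),
        points_used=tuple(used),
    )


def compute_ecv(lambda_: float, hematocrit: float) -> EcvResult:
    """ECV = lambda * (1 - hematocrit)."""
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    if not (0.0 < hematocrit < 1.0):
        raise ValueError("hematocrit must lie in (0, 1)")
    return EcvResult(ecv=lambda_ * (1.0 - hematocrit), lambda_=lambda_, hematocrit=hematocrit)


def estimate_ecv(
    points: Sequence[R1TimePoint], hematocrit: float, rel_tol: float = 0.05
) -> tuple[EcvResult, LambdaFit]:
    """Convenience chain: detect equilibrium, fit lambda, compute ECV."""
    window = detect_equilibrium(points, rel_tol=rel_tol)
    fit = fit_lambda(points, window)
    return compute_ecv(fit.lambda_, hematocrit), fit
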