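"""MOLLI T1 estimation.

Magnitude inversion-recovery data lose the sign of the early, inverted limb,
so fitting proceeds in two steps: restore polarity (flip every point before
a candidate null index, keeping the assignment with the smallest fit
residual) and fit the three-parameter model

    S(TI) = A - B exp(-TI / T1*)

by nonlinear least squares, followed by the Look-Locker correction
T1 = T1* (B/A - 1). Non-convergent or unphysical fits are returned flagged
with a non-positive T1 sentinel rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "T1FitResult",
    "T1Map",
    "restore_polarity",
    "fit_molli",
    "fit_t1_map",
    "save_t1_map",
    "load_t1_map",
]

T1_FAILED = -1.0  # sentinel stored in maps for failed pixels


@dataclass(frozen=True)
class T1FitResult:
    a: float
    b: float
    t1_star: float  # ms, apparent
    t1: float  # ms, Look-Locker corrected; <= 0 flags failure
    residual_rms: float
    n_points: int
    converged: bool = True

    @property
    def failed(self) -> bool:
        return (not self.converged) or self.t1 <= 0


@dataclass(frozen=True)
class T1Map:
    """Raster of fitted T1 values (ms) with a co-registered region mask."""

    values: np.ndarray  # 2D float; non-positive = failed fit
    pixel_spacing: float  # mm/px
    labels: np.ndarray  # 2D uint8, see synthetic.mri.LABELS

    def __post_init__(self) -> None:
        if self.values.shape != self.labels.shape:
            raise ValueError("T1 raster and label mask shapes differ")


def _fit_signed(ti: np.ndarray, signed: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Least-squares fit of A - B exp(-TI/T1*) to signed signals."""
    a0 = float(np.max(signed))
    if a0 <= 0:
        a0 = float(np.max(np.abs(signed))) or 1.0
    b0 = 2.0 * a0
    # null-point heuristic for the apparent time constant
    t1s0 = float(ti[np.argmin(np.abs(signed))])
    t1s0 = max(t1s0, float(np.min(ti[ti > 0], initial=1.0)), 1.0)

    def resid(p):
        a, b, t1s = p
        return a - b * np.exp(-ti / max(t1s, 1e-3)) - signed

    def jac(p):
        a, b, t1s = p
        t1s = max(t1s, 1e-3)
        e = np.exp(-ti / t1s)
        return np.column_stack([np.ones_like(ti), -e, -b * e * ti / t1s**2])

    try:
        sol = least_squares(
            resid, x0=[a0, b0, t1s0], jac=jac, method="lm",
            xtol=1e-10, ftol=1e-12, gtol=1e-12, max_nfev=500,
        )
    except Exception:
        return np.array([a0, b0, t1s0]), np.inf, False
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return sol.x, rms, bool(sol.success)


def _polarity_search(
    ti_sorted: np.ndarray, mag_sorted: np.ndarray
) -> tuple[int, np.ndarray, float, bool]:
    """Best flip index plus the fit obtained with it.

    The null can only sit near the magnitude minimum, so only flip counts
    within two points of it are scored.
    """
    i_min = int(np.argmin(mag_sorted))
    best = None
    for k in range(max(0, i_min - 2), min(ti_sorted.size, i_min + 3)):
        signed = mag_sorted.copy()
        signed[:k] *= -1.0
        params, rms, ok = _fit_signed(ti_sorted, signed)
        if best is None or rms < best[2]:
            best = (k, params, rms, ok)
    return best


def restore_polarity(
    inversion_times: np.ndarray, magnitudes: np.ndarray
) -> np.ndarray:
    """Signed signals: flip all points before the best-fitting null index.

    Candidate null positions are scored by the residual of the
    three-parameter fit; near-constant inputs are returned unchanged.
    """
    ti = np.asarray(inversion_times, dtype=float)
    mag = np.asarray(magnitudes, dtype=float)
    if ti.size < 5:
        raise ValueError("need at least 5 points to restore polarity")
    order = np.argsort(ti)
    ti_s, mag_s = ti[order], mag[order]
    if np.ptp(mag_s) < 1e-12 * max(1.0, np.abs(mag_s).max()):
        return mag.copy()  # degenerate: constant signal, nothing to restore
    k, _, _, _ = _polarity_search(ti_s, mag_s)
    signed_sorted = mag_s.copy()
    signed_sorted[:k] *= -1.0
    signed = np.empty_like(signed_sorted)
    signed[order] = signed_sorted
    return signed


def fit_molli(inversion_times: np.ndarray, magnitudes: np.ndarray) -> T1FitResult:
    """Fit one MOLLI magnitude curve; returns a flagged result on failure."""
    ti = np.asarray(inversion_times, dtype=float)
    mag = np.asarray(magnitudes, dtype=float)
    if ti.size < 5:
        raise ValueError("need at least 5 points spanning the recovery")
    if ti.shape != mag.shape:
        raise ValueError("inversion_times and magnitudes must have equal length")
    order = np.argsort(ti)
    _, (a, b, t1_star), rms, ok = _polarity_search(ti[order], mag[order])
    if not ok or a <= 0 or b <= a:
        return T1FitResult(
            a=float(a), b=float(b), t1_star=float(t1_star), t1=T1_FAILED,
            residual_rms=rms, n_points=int(ti.size), converged=False,
        )
    t1 = t1_star * (b / a - 1.0)
    return T1FitResult(
        a=float(a), b=float(b), t1_star=float(t1_star), t1=float(t1),
        residual_rms=rms, n_points=int(ti.size), converged=True,
    )


def fit_t1_map(
    signal_stack: np.ndarray,
    inversion_times: np.ndarray,
    labels: np.ndarray | None = None,
    pixel_spacing: float = 1.8,
) -> T1Map:
    """Per-pixel MOLLI fit of a (n_TI, H, W) magnitude stack.

    Failed pixels carry the non-positive sentinel; the label mask is passed
    through unchanged. Background pixels (label 0) are skipped.
    """
    stack = np.asarray(signal_stack, dtype=float)
    ti = np.asarray(inversion_times, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != ti.size:
        raise ValueError("signal_stack must be (n_TI, H, W) matching inversion_times")
    h, w = stack.shape[1:]
    if labels is None:
        labels = np.ones((h, w), dtype=np.uint8)
    if labels.shape != (h, w):
        raise ValueError("labels shape does not match stack geometry")
    values = np.full((h, w), T1_FAILED, dtype=float)
    for i in range(h):
        for j in range(w):
            if labels[i, j] == 0:
                continue
            curve = stack[:, i, j]
            if np.ptp(curve) < 1e-12:
                continue  # flat (e.g. all-zero) pixel stays flagged
            res = fit_molli(ti, curve)
            if not res.failed:
                values[i, j] = res.t1
    return T1Map(values=values, pixel_spacing=pixel_spacing, labels=labels)


def save_t1_map(
    t1_map: T1Map, directory, stem: str, acquisition_time_min: float | None = None
) -> None:
    """Write a map as float32 TIFF + uint8 label TIFF + JSON sidecar."""
    import json
    from pathlib import Path

    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}_t1.tif", t1_map.values.astype(np.float32))
    tifffile.imwrite(directory / f"{stem}_labels.tif", t1_map.labels.astype(np.uint8))
    sidecar = {"pixel_spacing_mm": t1_map.pixel_spacing}
    if acquisition_time_min is not None:
        sidecar["acquisition_time_min"] = acquisition_time_min
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def load_t1_map(directory, stem: str) -> T1Map:
    """Read back a map written by :func:`save_t1_map`."""
    import json
    from pathlib import Path

    import tifffile

    directory = Path(directory)
    values = tifffile.imread(directory / f"{stem}_t1.tif").astype(float)
    labels = tifffile.imread(directory / f"{stem}_labels.tif").astype(np.uint8)
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    return T1Map(values=values, pixel_spacing=float(sidecar["pixel_spacing_mm"]), labels=labels)
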