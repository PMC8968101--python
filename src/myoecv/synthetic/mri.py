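"""MOLLI signal generation and short-axis T1-map phantoms.

MOLLI samples the inversion-recovery curve across heartbeats: an inversion
pulse is followed by single-shot readouts at fixed trigger delays, giving
one magnitude image per effective inversion time (TI). Two grouping schemes
are emulated: 4(7)3 pre-contrast (4 images after the first inversion, a
7-beat recovery pause, 3 after the second) and 4(3)3 post-contrast. The
readout train perturbs the recovery, so the sampled curve follows the
apparent constant T1* with the three-parameter model

    S(TI) = | A - B exp(-TI / T1*) |,   T1 = T1* (B/A - 1)

(the Look-Locker correction). The generator inverts that relation: given a
true T1 and an apparent-saturation ratio B/A it derives T1*, evaluates the
signed recovery, optionally adds Gaussian noise, and returns magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MolliSignalSet", "molli_inversion_times", "simulate_molli_signal", "render_t1_phantom"]

#: region labels shared by phantoms, T1 maps and ROI extraction
LABELS = {"background": 0, "septum": 1, "blood_pool": 2, "free_wall": 3}


@dataclass(frozen=True)
class MolliSignalSet:
    """Sampled MOLLI magnitudes with the generating ground truth."""

    inversion_times: np.ndarray  # ms, per acquired image
    signals: np.ndarray  # magnitude, a.u.
    true_t1: float  # ms
    true_a: float
    true_b: float

    @property
    def true_t1_star(self) -> float:
        return self.true_t1 / (self.true_b / self.true_a - 1.0)


def molli_inversion_times(
    schedule_kind: str, heart_rate: float, ti_first: float = 120.0, ti_second: float = 200.0
) -> np.ndarray:
    """Effective inversion times (ms) of a two-inversion MOLLI scheme.

    Images are triggered every two heartbeats; the pause between the two
    inversion blocks is 7 beats (``pre_4_7_3``) or 3 beats (``post_4_3_3``).
    The pause only separates the blocks in scanner time; each block's TIs
    restart from its own inversion pulse.
    """
    if schedule_kind not in ("pre_4_7_3", "post_4_3_3"):
        raise ValueError(f"unknown schedule_kind {schedule_kind!r}")
    rr = 60000.0 / heart_rate  # ms per beat
    spacing = 2.0 * rr  # trigger every two beats
    first = ti_first + spacing * np.arange(4)
    second = ti_second + spacing * np.arange(3)
    return np.sort(np.concatenate([first, second]))


def simulate_molli_signal(
    true_t1: float,
    schedule_kind: str = "post_4_3_3",
    heart_rate: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    a: float = 1.0,
    b_over_a: float = 1.9,
) -> MolliSignalSet:
    """Magnitude MOLLI signals for one tissue at one time point.

    Noise is Gaussian on the signed signal before taking the magnitude
    (the high-SNR approximation of Rician noise). Deterministic given seed.
    """
    if true_t1 <= 0:
        raise ValueError("true_t1 must be positive")
    if not (55.0 <= heart_rate <= 70.0):
        # outside the physiological trigger window used by the protocol; allow
        # but keep the default within [55, 70]
        pass
    ti = molli_inversion_times(schedule_kind, heart_rate)
    b = b_over_a * a
    t1_star = true_t1 / (b_over_a - 1.0)
    signed = a - b * np.exp(-ti / t1_star)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signed = signed + rng.normal(0.0, noise_sd, size=signed.shape)
    return MolliSignalSet(
        inversion_times=ti, signals=np.abs(signed), true_t1=float(true_t1), true_a=a, true_b=b
    )


def render_t1_phantom(
    septal_t1: float,
    blood_t1: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    size: int = 48,
    artifact: bool = False,
    free_wall_t1: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cartoon short-axis T1 map: annular myocardium around a central blood pool.

    Returns ``(t1_map, labels)`` where labels uses :data:`LABELS`. The septal
    half of the annulus is labelled ``septum``, the other half ``free_wall``;
    with ``artifact=True`` a multiplicative band corrupts the free wall only,
    mimicking the off-resonance artifacts that motivate restricting analysis
    to the interventricular septum.
    """
    if septal_t1 <= 0 or blood_t1 <= 0:
        raise ValueError("T1 values must be positive")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy)
    r_blood = size * 0.18
    r_outer = size * 0.42
    labels = np.zeros((size, size), dtype=np.uint8)
    labels[r <= r_blood] = LABELS["blood_pool"]
    ring = (r > r_blood + 1) & (r <= r_outer)
    labels[ring & (xx <= cx)] = LABELS["septum"]
    labels[ring & (xx > cx)] = LABELS["free_wall"]

    if free_wall_t1 is None:
        free_wall_t1 = septal_t1
    t1 = np.zeros((size, size), dtype=float)
    t1[labels == LABELS["septum"]] = septal_t1
    t1[labels == LABELS["free_wall"]] = free_wall_t1
    t1[labels == LABELS["blood_pool"]] = blood_t1
    if noise_sd > 0:
        noisy = labels != LABELS["background"]
        t1[noisy] += rng.normal(0.0, noise_sd, size=int(noisy.sum()))
    if artifact:
        band = (labels == LABELS["free_wall"]) & (np.abs(yy - cy) < size * 0.12)
        t1[band] *= 1.35
    return t1, labels
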