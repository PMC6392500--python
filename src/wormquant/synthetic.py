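"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Three generators emulate the raw material of the assays so the downstream
quantification is testable without any recording:

* :func:`gen_tap_experiment` — per-worm Bernoulli reversal outcomes whose
  per-tap probability decays exponentially from an initial level ``p0`` to
  an asymptote ``p_inf`` (the habituation curve), with independent per-tap
  tracking dropout mimicking a multi-worm tracker that does not follow every
  animal at every tap.
* :func:`gen_image_stack` — two-channel (CFP/YFP) stacks containing a
  drifting Gaussian cell body with a calcium transient, donor-to-acceptor
  spectral bleed-through, and Poisson–Gaussian pixel noise.
* :func:`gen_swim_traces` — sinusoidal swim bend-angle traces with optional
  paralysis onset.

All randomness derives from a single user seed via labelled streams
(see :mod:`wormquant._rng`); identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import ClassVar, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .behavior import PostureTrace
from .calcium import TwoChannelStack
from .errors import GenerationError, ParameterError

__all__ = [
    "HabituationModel",
    "TapProtocol",
    "StackParams",
    "SwimParams",
    "StackTruth",
    "SwimTruth",
    "gen_tap_experiment",
    "gen_image_stack",
    "gen_swim_traces",
    "linear_drift_path",
]


def _check_prob(name: str, p: float) -> None:
    if not (np.isfinite(p) and 0.0 <= p <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class HabituationModel:
    """Exponentially decaying per-tap reversal probability.

    p_t = p_inf + (p0 - p_inf) * exp(-lam * (t - 1)) for tap t = 1, 2, ...
    ``dropout`` is the per-(worm, tap) probability of being untracked.
    Habituating strains require p_inf <= p0; set ``sensitizing=True`` to
    allow an increasing curve.
    """

    p0: float
    p_inf: float
    lam: float
    dropout: float = 0.0
    sensitizing: bool = False

    def __post_init__(self):
        _check_prob("p0", self.p0)
        _check_prob("p_inf", self.p_inf)
        _check_prob("dropout", self.dropout)
        if not (np.isfinite(self.lam) and self.lam >= 0):
            raise ParameterError(f"lam must be >= 0, got {self.lam}")
        if self.p_inf > self.p0 and not self.sensitizing:
            raise ParameterError("p_inf > p0 requires sensitizing=True")

    def p_tap(self, taps: np.ndarray | int) -> np.ndarray:
        t = np.asarray(taps, dtype=float)
        return self.p_inf + (self.p0 - self.p_inf) * np.exp(-self.lam * (t - 1.0))


@dataclass(frozen=True)
class TapProtocol:
    """Tap-habituation stimulus schedule: 30 taps at 10 s ISI by default,
    after a 300 s acclimatization period."""

    n_taps: int = 30
    isi: float = 10.0
    acclimatization: float = 300.0

    def __post_init__(self):
        if self.n_taps < 1:
            raise ParameterError("n_taps must be >= 1")
        if not self.isi > 0:
            raise ParameterError("isi must be positive")
        if self.acclimatization < 0:
            raise ParameterError("acclimatization must be >= 0")

    @property
    def tap_times(self) -> np.ndarray:
        return self.acclimatization + self.isi * np.arange(self.n_taps)


def gen_tap_experiment(
    models: dict[str, HabituationModel],
    n_worms: int | dict[str, int],
    protocol: TapProtocol = TapProtocol(),
    seed: int = 0,
    day: int = 1,
    plate_prefix: str = "plate",
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Simulate per-worm, per-tap reversal outcomes for one or more strains.

    Returns a long-format event table with columns (worm_id, strain,
    plate_id, day, tap_index, tap_time, tracked, reversed) — ``reversed`` is
    a nullable boolean, missing where the worm was untracked — and the true
    per-tap probability curve per strain.
    """
    taps = np.arange(1, protocol.n_taps + 1)
    tap_times = protocol.tap_times
    frames = []
    truth: dict[str, np.ndarray] = {}
    for strain in sorted(models):
        model = models[strain]
        n = n_worms[strain] if isinstance(n_worms, dict) else int(n_worms)
        if n < 1:
            raise ParameterError(f"n_worms must be >= 1 for strain {strain}")
        rng = stream(seed, f"taps/{strain}")
        p_t = model.p_tap(taps)
        truth[strain] = p_t
        rev = rng.random((n, protocol.n_taps)) < p_t[None, :]
        tracked = rng.random((n, protocol.n_taps)) >= model.dropout
        df = pd.DataFrame(
            {
                "worm_id": np.repeat([f"{strain}-w{i:04d}" for i in range(n)], protocol.n_taps),
                "strain": strain,
                "plate_id": f"{plate_prefix}-{strain}",
                "day": day,
                "tap_index": np.tile(taps, n),
                "tap_time": np.tile(tap_times, n),
                "tracked": tracked.ravel(),
                "reversed": pd.array(rev.ravel(), dtype="boolean"),
            }
        )
        df.loc[~df["tracked"], "reversed"] = pd.NA
        frames.append(df)
    events = pd.concat(frames, ignore_index=True)
    return events, truth


# ---------------------------------------------------------------------------
# image stacks


def linear_drift_path(
    n_frames: int, start: tuple[float, float], velocity: tuple[float, float]
) -> np.ndarray:
    """Straight-line centroid path: start + t * velocity (px/frame)."""
    t = np.arange(n_frames)[:, None]
    return np.asarray(start, dtype=float)[None, :] + t * np.asarray(velocity, dtype=float)


@dataclass
class StackParams:
    """Parameters of a synthetic two-channel recording.

    The cell is a 2-D Gaussian spot (sigma = ``cell_radius``) whose peak
    emits ``baseline_Fc`` / ``baseline_Fy`` photons/pixel in the donor and
    acceptor channels.  A calcium transient multiplies the true YFP/CFP
    ratio by (1 + dRR0(t)/100) with a double-exponential time course rising
    with ``rise_tau`` and decaying with ``decay_tau``, peaking at
    ``transient_peak_dRR0`` percent.  The acceptor channel receives
    ``alpha_true`` of the donor signal as bleed-through.  Per-pixel noise is
    Poisson shot noise on the photon mean plus Gaussian read noise
    (``read_noise_sd``); both are disabled with ``noise=False``.
    """

    frame_rate: float = 10.0
    duration: float = 30.0
    image_shape: tuple[int, int] = (64, 64)
    cell_path: Optional[np.ndarray] = None  # (n_frames, 2); None = static centre
    cell_radius: float = 3.0
    baseline_Fc: float = 1000.0
    baseline_Fy: float = 1250.0
    transient_onset: float = 10.0
    transient_peak_dRR0: float = 30.0
    rise_tau: float = 0.5
    decay_tau: float = 3.0
    alpha_true: float = 0.0
    bg_level: float = 10.0
    read_noise_sd: float = 2.0
    noise: bool = True

    def __post_init__(self):
        if not self.frame_rate > 0:
            raise ParameterError("frame_rate must be positive")
        if not 0 <= self.transient_onset <= self.duration:
            raise ParameterError("transient_onset must lie within the recording")
        if not 0 <= self.alpha_true < 1:
            raise ParameterError("alpha_true must be in [0, 1)")
        if self.cell_radius <= 0 or self.baseline_Fc <= 0 or self.baseline_Fy <= 0:
            raise ParameterError("cell_radius and channel baselines must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class StackTruth:
    """Ground truth stored alongside a generated stack."""

    centroid_path: np.ndarray  # (n_frames, 2) true (row, col)
    dRR0: np.ndarray  # true percent ratio change per frame
    alpha_true: float
    params: Optional[StackParams] = field(repr=False, default=None)


def _transient_drr0(params: StackParams) -> np.ndarray:
    """Sampled true dRR0(t): double-exponential normalized to the stated peak."""
    t = np.arange(params.n_frames) / params.frame_rate
    dt = t - params.transient_onset
    rise, decay = params.rise_tau, params.decay_tau
    if params.transient_peak_dRR0 == 0:
        return np.zeros_like(t)
    if math.isclose(rise, decay):
        # alpha-function limit of the double exponential
        g = np.where(dt >= 0, (dt / rise) * np.exp(1.0 - dt / rise), 0.0)
    else:
        g = np.where(dt >= 0, np.exp(-dt / decay) - np.exp(-dt / rise), 0.0)
        t_peak = math.log(decay / rise) / (1.0 / rise - 1.0 / decay)
        g /= math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    return params.transient_peak_dRR0 * g


def gen_image_stack(
    params: StackParams | None = None, seed: int = 0
) -> tuple[TwoChannelStack, StackTruth]:
    """Render a two-channel stack of a drifting cell with a calcium transient.

    The donor (CFP) photon mean per pixel is ``baseline_Fc * G + bg`` where
    G is the unit-peak Gaussian spot; the acceptor (YFP) mean is
    ``baseline_Fy * (1 + dRR0(t)/100) * G + alpha_true * donor_signal + bg``.
    """
    if params is None:
        params = StackParams()
    n = params.n_frames
    rows, cols = params.image_shape
    if params.cell_path is None:
        path = np.tile([[(rows - 1) / 2.0, (cols - 1) / 2.0]], (n, 1))
    else:
        path = np.asarray(params.cell_path, dtype=float)
        if path.shape != (n, 2):
            raise ParameterError(f"cell_path must have shape ({n}, 2)")
    margin = 3.0 * params.cell_radius
    if (
        path[:, 0].min() < margin
        or path[:, 1].min() < margin
        or path[:, 0].max() > rows - 1 - margin
        or path[:, 1].max() > cols - 1 - margin
    ):
        raise GenerationError("cell leaves the frame (within 3 sigma of an edge)")

    drr0 = _transient_drr0(params)
    rr = np.arange(rows, dtype=float)[:, None]
    cc = np.arange(cols, dtype=float)[None, :]
    two_sig2 = 2.0 * params.cell_radius**2

    cyan_mean = np.empty((n, rows, cols))
    yellow_mean = np.empty((n, rows, cols))
    for t in range(n):
        g = np.exp(-((rr - path[t, 0]) ** 2 + (cc - path[t, 1]) ** 2) / two_sig2)
        c_sig = params.baseline_Fc * g
        y_sig = params.baseline_Fy * (1.0 + drr0[t] / 100.0) * g
        cyan_mean[t] = c_sig + params.bg_level
        yellow_mean[t] = y_sig + params.alpha_true * c_sig + params.bg_level

    if params.noise:
        rng = stream(seed, "stack")
        cyan = rng.poisson(cyan_mean).astype(float)
        yellow = rng.poisson(yellow_mean).astype(float)
        if params.read_noise_sd > 0:
            cyan = cyan + rng.normal(0.0, params.read_noise_sd, cyan.shape)
            yellow = yellow + rng.normal(0.0, params.read_noise_sd, yellow.shape)
        np.clip(cyan, 0.0, None, out=cyan)
        np.clip(yellow, 0.0, None, out=yellow)
    else:
        cyan, yellow = cyan_mean, yellow_mean

    stack = TwoChannelStack(cyan=cyan, yellow=yellow, frame_rate=params.frame_rate)
    truth = StackTruth(centroid_path=path, dRR0=drr0, alpha_true=params.alpha_true, params=params)
    return stack, truth


# ---------------------------------------------------------------------------
# swim traces


@dataclass(frozen=True)
class SwimParams:
    """Parameters of a synthetic swim bend-angle trace.

    ``paralysis_time`` (if set) is when thrashing stops; the sinusoid's
    amplitude ramps linearly to zero over 2 s from that moment, since a real
    worm never stops discontinuously.  ``noise_sd`` is measurement noise on
    the bend angle and persists after paralysis.
    """

    sample_rate: float = 10.0
    duration: float = 660.0
    thrash_freq: float = 1.0
    amplitude: float = 60.0
    paralysis_time: Optional[float] = None
    noise_sd: float = 0.0

    PARALYSIS_RAMP: ClassVar[float] = 2.0

    def __post_init__(self):
        if not self.sample_rate > 0 or not self.duration > 0:
            raise ParameterError("sample_rate and duration must be positive")
        if not self.amplitude > 0:
            raise ParameterError("amplitude must be positive")
        if self.sample_rate < 2.0 * self.thrash_freq:
            raise ParameterError(
                f"sample_rate {self.sample_rate} Hz aliases thrash_freq {self.thrash_freq} Hz"
            )
        if self.paralysis_time is not None and not 0 <= self.paralysis_time <= self.duration:
            raise ParameterError("paralysis_time must lie within the trace")


@dataclass(frozen=True)
class SwimTruth:
    thrash_freq: float
    paralysis_time: Optional[float]


def gen_swim_traces(
    params: SwimParams | Sequence[SwimParams],
    n_worms: int | None = None,
    seed: int = 0,
) -> list[tuple[PostureTrace, SwimTruth]]:
    """Simulate sinusoidal swim traces, one per worm.

    ``params`` may be a single :class:`SwimParams` applied to ``n_worms``
    worms, or one per worm (then ``n_worms`` is ignored).
    """
    if isinstance(params, SwimParams):
        if n_worms is None or n_worms < 1:
            raise ParameterError("n_worms must be >= 1 when a single SwimParams is given")
        per_worm = [params] * n_worms
    else:
        per_worm = list(params)
        if not per_worm:
            raise ParameterError("params sequence must be non-empty")

    out = []
    for i, p in enumerate(per_worm):
        rng = stream(seed, f"swim/{i}")
        n = int(round(p.duration * p.sample_rate)) + 1
        t = np.arange(n) / p.sample_rate
        angle = p.amplitude * np.sin(2.0 * math.pi * p.thrash_freq * t)
        if p.paralysis_time is not None:
            envelope = np.clip(1.0 - (t - p.paralysis_time) / p.PARALYSIS_RAMP, 0.0, 1.0)
            angle = angle * envelope
        if p.noise_sd > 0:
            angle = angle + rng.normal(0.0, p.noise_sd, n)
        trace = PostureTrace(time=t, bend_angle=angle, sample_rate=p.sample_rate)
        out.append((trace, SwimTruth(p.thrash_freq, p.paralysis_time)))
    return out
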