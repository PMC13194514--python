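"""Continuous-EEG to clean cue-locked epochs.

The pipeline, in order: average re-referencing, zero-phase band-pass
filtering (0.3–100 Hz by default, optional mains notch), event-locked epoch
extraction per cue, mean-baseline removal over the pre-stimulus interval,
and artifact rejection through a pluggable per-trial strategy.

ICA-based component cleaning is deliberately out of scope: it belongs to
separately published algorithms. The :func:`reject_artifacts` strategy
registry lets such a method be plugged in; the built-in fallback is a
per-trial peak-to-peak amplitude threshold (default 100 µV).

Conventions: sample indices are 0-based; epoch windows are half-open
``[t_start, t_end)`` in seconds relative to the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal

from .data_io import Cue, EpochSet, ValidationError

__all__ = [
    "ContinuousEEG",
    "FilterSpec",
    "RejectionReport",
    "average_reference",
    "bandpass_filter",
    "extract_epochs",
    "baseline_correct",
    "reject_artifacts",
    "register_rejection_strategy",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


class ContractError(ValueError):
    """A precondition of a preprocessing operation is violated."""


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording with cue events.

    data : [n_channels, n_samples_total] in microvolts
    events : (sample_index, cue) pairs, strictly increasing sample indices
    """

    data: np.ndarray
    fs: float
    events: List[Tuple[int, Cue]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("continuous data must be [channels, samples]")
        self.events = [(int(s), Cue(c)) for s, c in self.events]
        samples = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValidationError("event sample indices must be strictly increasing")
        n = self.data.shape[1]
        if any(not (0 <= s < n) for s in samples):
            raise ValidationError("event sample index outside the recording")


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: Butterworth, zero-phase by default.

    ``order`` is the order of the underlying one-pass design; zero-phase
    forward–backward application squares the magnitude response.
    """

    low_hz: float = 0.3
    high_hz: float = 100.0
    order: int = 4
    zero_phase: bool = True
    notch_hz: float | None = None

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ContractError(f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= fs / 2:
            raise ContractError(
                f"high_hz={self.high_hz} must be below the Nyquist frequency {fs / 2}"
            )


def average_reference(x):
    """Re-reference to the channel average (mean across channels removed).

    Accepts :class:`ContinuousEEG` (channel axis 0) or :class:`EpochSet`
    (channel axis 1) and returns the same type. Linear and idempotent.
    """
    if isinstance(x, ContinuousEEG):
        if x.data.shape[0] < 2:
            raise ContractError("average reference needs at least 2 channels")
        return replace(x, data=x.data - x.data.mean(axis=0, keepdims=True))
    if isinstance(x, EpochSet):
        if x.n_channels < 2:
            raise ContractError("average reference needs at least 2 channels")
        return replace(x, data=x.data - x.data.mean(axis=1, keepdims=True))
    raise TypeError(f"unsupported input type {type(x).__name__}")


def bandpass_filter(x: ContinuousEEG, spec: FilterSpec = FilterSpec()) -> ContinuousEEG:
    """Apply the band-pass (and optional notch) along time.

    Zero-phase specs are applied forward-backward (``sosfiltfilt``) so the
    output has no group delay and the same length as the input.
    """
    spec.validate(x.fs)
    sos = signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                        btype="bandpass", fs=x.fs, output="sos")
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, x.data, axis=-1)
    else:
        out = signal.sosfilt(sos, x.data, axis=-1)
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, Q=30.0, fs=x.fs)
        out = signal.filtfilt(b, a, out, axis=-1) if spec.zero_phase else signal.lfilter(b, a, out, axis=-1)
    return replace(x, data=out)


def extract_epochs(x: ContinuousEEG, window: Tuple[float, float] = (-0.1, 0.4),
                   subject_id: int = 0) -> Dict[Cue, EpochSet]:
    """Cut event-locked epochs and group them by cue.

    The window is half-open ``[t_start, t_end)``: an event at sample ``s``
    yields samples ``[s + round(t_start*fs), s + round(t_end*fs))``. Events
    too close to a recording edge are dropped with a warning, not fatally.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise ContractError(f"empty epoch window {window}")
    off0 = int(round(t_start * x.fs))
    off1 = int(round(t_end * x.fs))
    n_total = x.data.shape[1]
    grouped: Dict[Cue, list] = {}
    for s, cue in x.events:
        a, b = s + off0, s + off1
        if a < 0 or b > n_total:
            logger.warning("event at sample %d dropped: window [%d, %d) outside recording", s, a, b)
            continue
        grouped.setdefault(cue, []).append(x.data[:, a:b])
    return {
        cue: EpochSet(np.stack(trials), fs=x.fs, cue=cue,
                      subject_id=subject_id, t0=t_start)
        for cue, trials in grouped.items()
    }


def baseline_correct(es: EpochSet, interval: Tuple[float, float] = (-0.1, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline interval.

    The interval is ``[t0_s, t1_s)`` relative to the event and must lie
    inside the epoch window.
    """
    a = int(round((interval[0] - es.t0) * es.fs))
    b = int(round((interval[1] - es.t0) * es.fs))
    if a < 0 or b > es.n_samples or b <= a:
        raise ContractError(
            f"baseline interval {interval} outside epoch window "
            f"[{es.t0}, {es.t0 + es.n_samples / es.fs})"
        )
    baseline = es.data[:, :, a:b].mean(axis=2, keepdims=True)
    return replace(es, data=es.data - baseline)


# ---------------------------------------------------------------------------
# Artifact rejection strategies
# ---------------------------------------------------------------------------

@dataclass
class RejectionReport:
    rejected: List[int]
    reasons: Dict[int, str]
    n_input: int

    @property
    def n_retained(self) -> int:
        return self.n_input - len(self.rejected)


# A strategy maps an EpochSet to a boolean keep-mask plus per-trial reasons.
Strategy = Callable[[EpochSet], Tuple[np.ndarray, Dict[int, str]]]

_STRATEGIES: Dict[str, Callable[..., Strategy]] = {}


def register_rejection_strategy(name: str, factory: Callable[..., Strategy]) -> None:
    """Register a named artifact-rejection strategy factory."""
    _STRATEGIES[name] = factory


def _ptp_strategy(threshold_uv: float = 100.0) -> Strategy:
    def run(es: EpochSet):
        ptp = es.data.max(axis=2) - es.data.min(axis=2)  # (trials, channels)
        worst = ptp.max(axis=1)
        keep = worst <= threshold_uv
        reasons = {int(i): f"peak-to-peak {worst[i]:.1f} uV > {threshold_uv:g} uV"
                   for i in np.flatnonzero(~keep)}
        return keep, reasons

    return run


register_rejection_strategy("ptp", _ptp_strategy)


def reject_artifacts(es: EpochSet, method: str | Strategy = "ptp:100",
                     ) -> Tuple[EpochSet, RejectionReport]:
    """Drop artifact trials using a registered strategy.

    ``method`` is either a callable strategy or a spec string
    ``"name[:arg]"`` — e.g. ``"ptp:100"`` for the built-in peak-to-peak
    threshold at 100 µV. Rejecting every trial is an error.
    """
    if callable(method):
        strategy = method
    else:
        name, _, arg = str(method).partition(":")
        if name not in _STRATEGIES:
            raise ContractError(f"unknown rejection strategy {name!r}; registered: {sorted(_STRATEGIES)}")
        strategy = _STRATEGIES[name](float(arg)) if arg else _STRATEGIES[name]()
    keep, reasons = strategy(es)
    keep = np.asarray(keep, dtype=bool)
    if not keep.any():
        raise ValidationError("artifact rejection removed every trial (empty epoch set)")
    rejected = [int(i) for i in np.flatnonzero(~keep)]
    if rejected:
        logger.info("rejected %d/%d trials (%s)", len(rejected), es.n_trials, es.cue.value)
    return replace(es, data=es.data[keep]), RejectionReport(rejected, reasons, es.n_trials)


def preprocess_pipeline(x: ContinuousEEG, spec: FilterSpec = FilterSpec(),
                        window: Tuple[float, float] = (-0.1, 0.4),
                        baseline: Tuple[float, float] = (-0.1, 0.0),
                        reject: str | Strategy | None = "ptp:100",
                        subject_id: int = 0,
                        ) -> Tuple[Dict[Cue, EpochSet], Dict[Cue, RejectionReport]]:
    """Run the full pipeline: re-reference, filter, epoch, baseline, reject."""
    y = average_reference(x)
    y = bandpass_filter(y, spec)
    epochs = extract_epochs(y, window, subject_id=subject_id)
    out, reports = {}, {}
    for cue, es in epochs.items():
        es = baseline_correct(es, baseline)
        if reject is not None:
            es, reports[cue] = reject_artifacts(es, reject)
        out[cue] = es
    return out, reports
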