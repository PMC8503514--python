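"""Raw triaxial accelerometry to per-second relative exercise intensity.

The processing chain mirrors standard practice in accelerometry-based
load monitoring of court sports:

1. band-pass filter the raw acceleration (removes the gravity/DC component
   and high-frequency sensor noise),
2. compute the per-epoch average net force, ``AvF_NET = m * mean(|a|)``,
   from the filtered vector magnitude,
3. map AvF_NET to a percentage of oxygen-uptake reserve (%V̇O2R) through a
   per-player linear calibration obtained in the laboratory.

The calibration coefficients are inputs: this module does not model the
laboratory incremental test that produces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sps

#: Standard gravity used for the g -> m/s^2 conversion.
G_TO_MS2 = 9.80665

#: Default band edges (Hz) of the band-pass filter.
DEFAULT_LOW_HZ = 0.1
DEFAULT_HIGH_HZ = 15.0
#: Default overall transfer-function order of the band-pass.
DEFAULT_ORDER = 4


@dataclass
class AccelTrace:
    """Triaxial acceleration time series for one player.

    Parameters
    ----------
    data : ndarray of shape (n_samples, 3)
        Acceleration in g (ax, ay, az).
    sample_rate_hz : float
        Constant sampling rate; must exceed twice the band-pass upper
        cut-off so the 15 Hz edge is below Nyquist.
    player_id : str
        Identifier used to key per-player outputs.
    filtered : bool
        Whether the trace has been band-pass filtered. Force computation
        refuses unfiltered traces because gravity would inflate the result.
    """

    data: np.ndarray
    sample_rate_hz: float
    player_id: str = "player"
    filtered: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError(
                f"acceleration data must be (n, 3), got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("acceleration data contains non-finite values")
        if self.sample_rate_hz <= 2 * DEFAULT_HIGH_HZ:
            raise ValueError(
                f"sample rate {self.sample_rate_hz} Hz must exceed "
                f"{2 * DEFAULT_HIGH_HZ} Hz (Nyquist above the upper cut-off)"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class RelativeIntensitySeries:
    """Per-second relative exercise intensity (%V̇O2R) for one player.

    One value per whole match-clock second, no gaps.  ``avfnet`` optionally
    carries the intermediate average net force (N) on the same epochs.
    """

    values: np.ndarray
    player_id: str = "player"
    avfnet: np.ndarray | None = None
    epoch_s: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("intensity values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("intensity values contain non-finite entries")
        if (self.values < 0).any():
            raise ValueError("%V̇O2R values must be non-negative")
        if self.avfnet is not None:
            self.avfnet = np.asarray(self.avfnet, dtype=float)
            if self.avfnet.shape != self.values.shape:
                raise ValueError("avfnet must parallel the intensity values")

    def __len__(self) -> int:
        return self.values.size


def design_bandpass(
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
    sample_rate_hz: float = 100.0,
) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass.

    ``order`` is the overall transfer-function order of the band-pass
    (an order-4 band-pass has two poles at each band edge), so it must be
    even.
    """
    nyquist = sample_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"cut-offs must satisfy 0 < {low_hz} < {high_hz} < Nyquist ({nyquist})"
        )
    if order < 2 or order % 2:
        raise ValueError("band-pass order must be a positive even integer")
    return _sps.butter(
        order // 2, [low_hz, high_hz], btype="bandpass", fs=sample_rate_hz, output="sos"
    )


def bandpass_frequency_response(
    freqs_hz: np.ndarray,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
    sample_rate_hz: float = 100.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Magnitude gain of the filter at the given frequencies.

    With ``zero_phase`` the forward-backward application squares the
    magnitude response, which is what :func:`bandpass_filter` realises.
    """
    sos = design_bandpass(low_hz, high_hz, order, sample_rate_hz)
    _, h = _sps.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=sample_rate_hz)
    gain = np.abs(h)
    return gain**2 if zero_phase else gain


def bandpass_filter(
    trace: AccelTrace,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> AccelTrace:
    """Zero-phase Butterworth band-pass, each axis independently.

    The 0.1 Hz high-pass edge removes gravity, so no separate gravity
    subtraction is performed.  Applied forward-backward (``sosfiltfilt``)
    so detected activity boundaries are not delayed by the filter's group
    delay; the effective magnitude response is the square of the one-pass
    response.
    """
    if trace.filtered:
        raise ValueError("trace is already filtered")
    sos = design_bandpass(low_hz, high_hz, order, trace.sample_rate_hz)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if trace.n_samples <= 2 * padlen:
        raise ValueError(
            f"trace of {trace.n_samples} samples is too short for the filter "
            f"(needs more than {2 * padlen})"
        )
    filtered = _sps.sosfiltfilt(sos, trace.data, axis=0, padlen=padlen)
    return replace(trace, data=filtered, filtered=True)


def compute_avfnet(trace: AccelTrace, mass_kg: float, epoch_s: int = 1) -> np.ndarray:
    """Average net force (N) per epoch from a filtered trace.

    Per sample, the net acceleration magnitude is the Euclidean norm of the
    filtered axes converted to m/s²; AvF_NET for an epoch is body mass times
    the mean magnitude over the epoch's samples.  A trailing partial epoch
    is dropped.
    """
    if not trace.filtered:
        raise ValueError("AvF_NET requires a filtered trace (gravity would inflate force)")
    if mass_kg <= 0:
        raise ValueError("body mass must be positive")
    samples_per_epoch = int(round(trace.sample_rate_hz * epoch_s))
    if samples_per_epoch < 1:
        raise ValueError("epoch shorter than one sample")
    n_epochs = trace.n_samples // samples_per_epoch
    if n_epochs == 0:
        raise ValueError("trace shorter than one epoch")
    magnitude = np.linalg.norm(trace.data, axis=1) * G_TO_MS2
    trimmed = magnitude[: n_epochs * samples_per_epoch]
    return mass_kg * trimmed.reshape(n_epochs, samples_per_epoch).mean(axis=1)


def calibrate_to_vo2r(
    force_n: np.ndarray,
    slope: float,
    intercept: float,
    player_id: str = "player",
) -> RelativeIntensitySeries:
    """Map per-epoch AvF_NET to %V̇O2R via a per-player linear calibration.

    ``value = max(0, slope * AvF_NET + intercept)``.  Values are clamped
    below at zero but not above 100: supramaximal readings are
    physiologically meaningful.
    """
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("calibration coefficients must be finite")
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    force_n = np.asarray(force_n, dtype=float)
    values = np.clip(slope * force_n + intercept, 0.0, None)
    return RelativeIntensitySeries(values=values, player_id=player_id, avfnet=force_n)


def intensity_from_trace(
    trace: AccelTrace,
    mass_kg: float,
    slope: float,
    intercept: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> RelativeIntensitySeries:
    """Full chain: band-pass -> AvF_NET -> %V̇O2R for one raw trace."""
    filtered = bandpass_filter(trace, low_hz=low_hz, high_hz=high_hz, order=order)
    force = compute_avfnet(filtered, mass_kg)
    return calibrate_to_vo2r(force, slope, intercept, player_id=trace.player_id)
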