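"""Software correlator: autocorrelation curves from photon-count series.

The instrument normally performs this step in hardware; this module
provides a direct O(N·K) estimator (reference oracle) and a multi-tau
estimator with a quasi-logarithmic lag grid for long traces.  Both use
the symmetric normalization

    G(k·Δt) = <F(t)·F(t+kΔt)> / (<F(t)>·<F(t+kΔt)>) − 1,

where the two means run over the two shifted segments, which suppresses
bias from slow intensity drift.  Lag zero (shot-noise dominated) is
excluded; curves start at one bin time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import AcfCurve

__all__ = ["PhotonTrace", "direct_acf", "multitau_acf", "segment_and_average"]

_GSE_FLOOR = 1e-15  # keeps g_se strictly positive for degenerate (identical) segments


@dataclass
class PhotonTrace:
    """Binned photon counts: non-negative integers per bin of ``bin_time`` s."""

    counts: np.ndarray
    bin_time: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if self.counts.size and np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not (self.bin_time > 0):
            raise ValueError("bin_time must be > 0")

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_time

    def __len__(self) -> int:
        return self.counts.size


def _sym_g(f: np.ndarray, k: int) -> float:
    """Symmetrically normalized autocorrelation at integer lag k."""
    a = f[: f.size - k]
    b = f[k:]
    ma = a.mean()
    mb = b.mean()
    if ma == 0.0 or mb == 0.0:
        raise ZeroDivisionError("zero mean intensity: normalization undefined")
    return float(np.dot(a, b) / a.size / (ma * mb) - 1.0)


def direct_acf(trace: PhotonTrace, max_lag: float) -> AcfCurve:
    """Autocorrelation by the O(N·K) definition on a linear lag grid.

    Lags are integer multiples of the bin time, from one bin up to
    ``max_lag`` (which must be below half the trace duration).
    """
    n = len(trace)
    if n == 0:
        raise ValueError("empty trace")
    if not (max_lag < trace.duration / 2):
        raise ValueError("max_lag must be < duration/2")
    k_max = int(max_lag / trace.bin_time)
    if k_max < 1:
        raise ValueError("max_lag shorter than one bin")
    f = trace.counts.astype(float)
    if f.mean() == 0.0:
        raise ZeroDivisionError("zero mean intensity: normalization undefined")
    ks = np.arange(1, k_max + 1)
    g = np.array([_sym_g(f, int(k)) for k in ks])
    return AcfCurve(
        lags=ks * trace.bin_time,
        g=g,
        n_traces=1,
        trace_duration=trace.duration,
        meta=dict(trace.meta),
    )


def multitau_acf(trace: PhotonTrace, m: int = 16, max_lag: float | None = None) -> AcfCurve:
    """Multi-tau autocorrelation on a quasi-logarithmic lag grid.

    The first 2m lags are computed at the native bin time; thereafter the
    trace is coarsened by summing adjacent bin pairs and lags m+1..2m are
    evaluated at each doubled resolution.  On lags shared with the native
    grid the estimator is identical to :func:`direct_acf`.
    """
    if m < 8 or m % 2:
        raise ValueError("m must be even and >= 8")
    n = len(trace)
    if n == 0:
        raise ValueError("empty trace")
    if max_lag is None:
        max_lag = trace.duration / 4
    if not (max_lag < trace.duration / 2):
        raise ValueError("max_lag must be < duration/2")
    f = trace.counts.astype(float)
    if f.mean() == 0.0:
        raise ZeroDivisionError("zero mean intensity: normalization undefined")

    lags: list[float] = []
    g: list[float] = []
    dt = trace.bin_time
    level = 0
    while True:
        k_lo = 1 if level == 0 else m + 1
        for k in range(k_lo, 2 * m + 1):
            lag = k * dt
            if lag > max_lag or k >= f.size - 1:
                break
            lags.append(lag)
            g.append(_sym_g(f, k))
        # stop when the next octave cannot contribute new lags
        if (m + 1) * dt * 2 > max_lag or f.size // 2 < m + 2:
            break
        f = f[: (f.size // 2) * 2].reshape(-1, 2).sum(axis=1)
        dt *= 2
        level += 1
    if not lags:
        raise ValueError("max_lag shorter than one bin")
    return AcfCurve(
        lags=np.asarray(lags),
        g=np.asarray(g),
        n_traces=1,
        trace_duration=trace.duration,
        meta=dict(trace.meta),
    )


def segment_and_average(
    trace: PhotonTrace,
    n_segments: int = 10,
    m: int = 16,
    max_lag: float | None = None,
) -> AcfCurve:
    """Split a long trace into sub-traces, correlate each, and average.

    The default of 10 segments mirrors the acquisition convention of ten
    consecutive traces per measurement.  Returns the per-lag mean as ``g``
    and the per-lag standard error of the mean as ``g_se``.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    n = len(trace)
    seg_len = n // n_segments
    if seg_len < 100:
        raise ValueError("segments shorter than 100 bins")
    if max_lag is None:
        max_lag = seg_len * trace.bin_time / 4
    curves = []
    for i in range(n_segments):
        seg = PhotonTrace(
            counts=trace.counts[i * seg_len : (i + 1) * seg_len],
            bin_time=trace.bin_time,
        )
        curves.append(multitau_acf(seg, m=m, max_lag=max_lag))
    gs = np.vstack([c.g for c in curves])
    mean_g = gs.mean(axis=0)
    se = gs.std(axis=0, ddof=1) / np.sqrt(n_segments)
    return AcfCurve(
        lags=curves[0].lags,
        g=mean_g,
        g_se=np.maximum(se, _GSE_FLOOR),
        n_traces=n_segments,
        trace_duration=trace.duration,
        meta=dict(trace.meta),
    )
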