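"""Time-course conditioning: polynomial detrend, robust despike, low-pass.

The conditioning chain applied to every component time course before
connectivity estimation is detrend -> despike -> low-pass.  Any stage can
be disabled, in which case it acts as the identity.

The low-pass stage is a 5th-order Butterworth applied forward and backward
(zero phase), so filtering never shifts window timing.  Despiking clamps
samples whose robust z-score (median / 1.4826*MAD) exceeds a threshold to
the threshold boundary, iterating until no sample is flagged — which makes
the operation idempotent by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import ComponentTimecourses

__all__ = ["detrend", "despike", "lowpass", "PrepConfig", "preprocess"]

log = logging.getLogger(__name__)

_MAD_SCALE = 1.4826  # makes MAD a consistent sigma estimate for Gaussians


def detrend(tc: ComponentTimecourses, max_order: int = 3) -> ComponentTimecourses:
    """Remove the mean and polynomial trends up to ``max_order`` per column.

    All orders are fit jointly by least squares on a Legendre-style
    orthogonalized basis, leaving each column orthogonal to every
    polynomial of degree <= max_order.
    """
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2 or 3")
    T = tc.n_timepoints
    if T <= max_order + 1:
        raise ValueError(f"series of length {T} too short for order {max_order}")
    t = np.linspace(-1.0, 1.0, T)
    basis = np.vander(t, max_order + 1, increasing=True)
    Q, _ = np.linalg.qr(basis)
    resid = tc.data - Q @ (Q.T @ tc.data)
    return tc.with_data(resid)


def despike(tc: ComponentTimecourses, z_thresh: float = 4.0
            ) -> tuple[ComponentTimecourses, int]:
    """Clamp outlier samples to the robust-z boundary; returns replacement count.

    Per column, a sample with ``|x - median| > z_thresh * 1.4826 * MAD`` is
    replaced by the boundary value ``median +- z_thresh * 1.4826 * MAD``.
    The clamp is iterated (statistics recomputed) until no sample is
    flagged, so a despiked series is a fixed point.  Columns with zero MAD
    are passed through with a warning.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    data = tc.data.copy()
    n_replaced = 0
    for c in range(data.shape[1]):
        col = data[:, c]
        touched = np.zeros(col.size, dtype=bool)
        while True:
            med = np.median(col)
            mad = _MAD_SCALE * np.median(np.abs(col - med))
            if mad == 0:
                if not np.allclose(col, col[0]):
                    log.warning("despike: zero MAD in column %d of %s; passed through",
                                c, tc.subject_id)
                break
            lo, hi = med - z_thresh * mad, med + z_thresh * mad
            flag = (col < lo) | (col > hi)
            if not flag.any():
                break
            touched |= flag
            col = np.clip(col, lo, hi)
        n_replaced += int(touched.sum())
        data[:, c] = col
    return tc.with_data(data), n_replaced


def lowpass(tc: ComponentTimecourses, cutoff_hz: float = 0.15,
            order: int = 5) -> ComponentTimecourses:
    """Zero-phase Butterworth low-pass at ``cutoff_hz``.

    The filter runs forward and backward (``filtfilt``), squaring the
    magnitude response; at TR = 2 s and the default 0.15 Hz cutoff a
    0.05 Hz oscillation is passed essentially unchanged while a 0.24 Hz
    oscillation is attenuated below 10%.
    """
    nyquist = 1.0 / (2.0 * tc.tr_seconds)
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    b, a = signal.butter(order, cutoff_hz / nyquist, btype="low")
    filtered = signal.filtfilt(b, a, tc.data, axis=0)
    return tc.with_data(filtered)


@dataclass
class PrepConfig:
    """Which conditioning stages run, and with what parameters."""

    detrend_order: int = 3
    do_detrend: bool = True
    do_despike: bool = True
    despike_z: float = 4.0
    do_lowpass: bool = True
    cutoff_hz: float = 0.15


def preprocess(tc: ComponentTimecourses,
               config: PrepConfig | None = None) -> ComponentTimecourses:
    """Run detrend -> despike -> lowpass with disabled stages as identity."""
    config = config or PrepConfig()
    out = tc
    if config.do_detrend:
        out = detrend(out, config.detrend_order)
    if config.do_despike:
        out, n = despike(out, config.despike_z)
        if n:
            log.info("despiked %d samples in %s", n, tc.subject_id)
    if config.do_lowpass:
        out = lowpass(out, config.cutoff_hz)
    return out
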