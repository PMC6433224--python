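"""Waveform alignment, template estimation and per-electrode SNR.

The per-electrode signal-to-noise ratio is defined from the detected spike
waveforms alone: the waveforms are time-aligned, their mean is taken as
the estimated AP signal, and the noise is what remains after subtracting
that mean from each waveform. With A_signal the RMS amplitude of the mean
waveform and A_noise the RMS amplitude of the pooled residuals,

    SNR_dB = 10 log10[(A_signal / A_noise)^2] = 20 log10(A_signal / A_noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateEnsembleError, ParameterError


@dataclass
class WaveformEnsemble:
    """Aligned spike waveforms from one electrode with their SNR statistics."""

    waveforms: np.ndarray  # aligned, n_spikes x n_samples, uV
    lags: np.ndarray  # integer alignment shift applied to each waveform
    template: np.ndarray  # mean aligned waveform (estimated AP signal)
    residuals: np.ndarray  # waveforms - template
    a_signal: float  # RMS amplitude of the template, uV
    a_noise: float  # RMS amplitude of the pooled residuals, uV
    snr_db: float


def _shift(w: np.ndarray, s: int) -> np.ndarray:
    """Shift right by s samples (left for negative s), edge-padded."""
    if s == 0:
        return w.copy()
    out = np.empty_like(w)
    if s > 0:
        out[:s] = w[0]
        out[s:] = w[:-s]
    else:
        out[s:] = w[-1]
        out[:s] = w[-s:]
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _best_lag(w: np.ndarray, template: np.ndarray, max_lag: int) -> int:
    """Lag of w relative to the template: the shift-left amount that
    maximizes normalized cross-correlation. Ties go to the smaller |lag|."""
    best_lag, best_c = 0, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        c = _ncc(_shift(w, -lag), template)
        if c > best_c + 1e-12:
            best_lag, best_c = lag, c
    return best_lag


def _medoid(W: np.ndarray) -> np.ndarray:
    """Waveform minimizing summed Euclidean distance to the others."""
    sq = np.sum(W**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (W @ W.T)
    np.maximum(d2, 0.0, out=d2)
    return W[np.argmin(np.sqrt(d2).sum(axis=1))]


def align_waveforms(
    waveforms, max_lag: int = 20, max_iter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Align spike waveforms by integer-sample shifts.

    Each waveform is shifted by the integer lag that maximizes its
    normalized cross-correlation with the current template (initially the
    medoid waveform, then the mean of the aligned set), iterating until no
    lag changes or ``max_iter`` passes. Shifts are bounded by ``max_lag``
    samples; samples shifted in from outside the window are edge-padded.

    Returns ``(aligned, lags)`` where ``aligned[i] = shift(w_i, -lags[i])``.
    """
    W = np.atleast_2d(np.asarray(waveforms, dtype=float))
    n, length = W.shape
    if n == 0:
        raise ParameterError("need at least one waveform")
    if not 0 <= max_lag < length / 2:
        raise ParameterError("max_lag must satisfy 0 <= max_lag < n_samples / 2")
    lags = np.zeros(n, dtype=int)
    if n == 1:
        return W.copy(), lags
    zero_rows = ~W.any(axis=1)
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero waveform(s): lag fixed at 0",
            stacklevel=2,
        )
    template = _medoid(W)
    for _ in range(max_iter):
        new_lags = np.array(
            [
                0 if zero_rows[i] else _best_lag(W[i], template, max_lag)
                for i in range(n)
            ]
        )
        aligned = np.stack([_shift(W[i], -new_lags[i]) for i in range(n)])
        template = aligned.mean(axis=0)
        if np.array_equal(new_lags, lags):
            break
        lags = new_lags
    return aligned, lags


def estimate_template(aligned) -> np.ndarray:
    """Pointwise mean across aligned waveforms: the estimated AP signal."""
    W = np.atleast_2d(np.asarray(aligned, dtype=float))
    if W.shape[0] == 0:
        raise ParameterError("need at least one waveform")
    return W.mean(axis=0)


def compute_snr(aligned, template: np.ndarray | None = None) -> tuple[float, float, float]:
    """SNR of an aligned ensemble.

    Residuals are ``w_i - template``; ``A_noise`` is the RMS over all
    residual samples pooled across spikes, ``A_signal`` the RMS of the
    template, and ``SNR_dB = 20 log10(A_signal / A_noise)``. Returns
    ``(snr_db, a_signal, a_noise)``. Identical waveforms give zero
    residuals and raise :class:`~meakit.errors.DegenerateEnsembleError`
    rather than +inf.
    """
    W = np.atleast_2d(np.asarray(aligned, dtype=float))
    if W.shape[0] < 2:
        raise ParameterError("SNR needs at least 2 waveforms")
    if template is None:
        template = estimate_template(W)
    residuals = W - template
    a_noise = float(np.sqrt(np.mean(residuals**2)))
    a_signal = float(np.sqrt(np.mean(np.asarray(template, dtype=float) ** 2)))
    # identical waveforms leave only float dust in the residuals
    if a_noise <= 1e-12 * max(a_signal, 1.0):
        raise DegenerateEnsembleError(
            "degenerate ensemble: all waveforms identical, noise RMS is zero"
        )
    snr_db = 20.0 * np.log10(a_signal / a_noise)
    return float(snr_db), a_signal, a_noise


def waveform_ensemble(waveforms, max_lag: int = 20) -> WaveformEnsemble:
    """Align, average and score an ensemble of spike waveforms."""
    aligned, lags = align_waveforms(waveforms, max_lag=max_lag)
    template = estimate_template(aligned)
    snr_db, a_signal, a_noise = compute_snr(aligned, template)
    return WaveformEnsemble(
        waveforms=aligned,
        lags=lags,
        template=template,
        residuals=aligned - template,
        a_signal=a_signal,
        a_noise=a_noise,
        snr_db=snr_db,
    )


def snr_by_electrode(trains, max_lag: int = 20, min_spikes: int = 2) -> pd.DataFrame:
    """Per-electrode SNR table from detected spike trains.

    ``trains`` maps electrode id to a :class:`meakit.detect.SpikeTrain`
    whose events carry waveform snippets. Electrodes with fewer than
    ``min_spikes`` usable snippets are skipped. Returns a DataFrame with
    columns ``electrode_id, n_spikes, a_signal_uV, a_noise_uV, snr_db``.
    """
    rows = []
    for eid in sorted(trains):
        train = trains[eid]
        snippets = [e.waveform for e in train.events if e.waveform is not None and not e.padded]
        if len(snippets) < min_spikes:
            continue
        try:
            ens = waveform_ensemble(np.stack(snippets), max_lag=max_lag)
        except DegenerateEnsembleError:
            continue
        rows.append((eid, len(snippets), ens.a_signal, ens.a_noise, ens.snr_db))
    return pd.DataFrame(
        rows, columns=["electrode_id", "n_spikes", "a_signal_uV", "a_noise_uV", "snr_db"]
    )
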