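"""Recovering generator band-power shares from extracted band energies.

Band-energy features are *biased* estimators of a subject's relative
band-power shares: the conditioning band-pass (0.5-48 Hz) clips the outer
edges of delta and gamma, and each rhythm filter is applied zero-phase on
top of the generator's identical shaping, so band b retains only a
fraction of its nominal power and leaks a little into its neighbours.
Both effects are fully determined by the declared filter designs, so the
5 x 5 band transfer matrix M — M[i, j] = energy fraction of unit-variance
band-i source noise captured by analysis band j — can be computed in
closed form by integrating the filters' squared-magnitude responses
(|H|^2 per pass, |H|^4 for a forward-backward pass). Solving M^T p = e
for the measured epoch-mean energies e de-biases the estimate and
recovers the specified shares.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal

from .bands import DEFAULT_BANDS, Band
from .features import FeatureTable
from .filters import DEFAULT_ORDER, bandpass_sos, lowpass_sos

_GRID_POINTS = 40001


def _psd_response(sos: np.ndarray, fs_hz: float, f: np.ndarray) -> np.ndarray:
    """|H(f)|^4 of a zero-phase (filtfilt) pass, zero above Nyquist."""
    inside = f <= fs_hz / 2
    w = f[inside] * 2 * np.pi / fs_hz
    _, h = signal.sosfreqz(sos, worN=w)
    out = np.zeros_like(f)
    out[inside] = np.abs(h) ** 4
    return out


@lru_cache(maxsize=32)
def band_transfer_matrix(
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    gen_fs_hz: float = 500.0,
    ana_fs_hz: float = 250.0,
    bp_low_hz: float = 0.5,
    bp_high_hz: float = 48.0,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """M[i, j]: power fraction of band-i source noise seen in analysis band j.

    Source noise of band i has PSD proportional to |H_i|^4 at the
    generation rate (white noise shaped by a zero-phase pass of the band
    filter, variance-normalized). The analysis chain applies the
    anti-alias low-pass, the broadband conditioning filter and analysis
    band j's filter, each zero-phase.
    """
    f = np.linspace(0.0, gen_fs_hz / 2, _GRID_POINTS)
    lp = _psd_response(lowpass_sos(0.8 * ana_fs_hz / 2, gen_fs_hz), gen_fs_hz, f)
    bp = _psd_response(bandpass_sos(bp_low_hz, bp_high_hz, ana_fs_hz, order), ana_fs_hz, f)
    m = np.empty((len(bands), len(bands)))
    for i, src in enumerate(bands):
        shape = _psd_response(bandpass_sos(src.low_hz, src.high_hz, gen_fs_hz, order), gen_fs_hz, f)
        shape = shape / np.trapezoid(shape, f)
        for j, ana in enumerate(bands):
            resp = _psd_response(bandpass_sos(ana.low_hz, ana.high_hz, ana_fs_hz, order), ana_fs_hz, f)
            m[i, j] = np.trapezoid(shape * lp * bp * resp, f)
    return m


def recover_band_shares(
    table: FeatureTable,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    gen_fs_hz: float = 500.0,
    ana_fs_hz: float = 250.0,
    bp_low_hz: float = 0.5,
    bp_high_hz: float = 48.0,
    order: int = DEFAULT_ORDER,
) -> dict[str, dict[str, float]]:
    """Estimate each subject's relative band-power shares from the table.

    Epoch-mean band energies (averaged over channels) are de-biased by the
    band transfer matrix and normalized to shares summing to one.
    Returns {subject_id: {band name: share}}.
    """
    m = band_transfer_matrix(tuple(bands), gen_fs_hz, ana_fs_hz, bp_low_hz, bp_high_hz, order)
    out: dict[str, dict[str, float]] = {}
    for sid in dict.fromkeys(table.subject_ids):
        mask = (table.subject_ids == sid).to_numpy()
        sub = table.data.loc[mask]
        e = np.array([
            sub[[c for c in sub.columns if c.endswith(f"energy_{b.name}")]].to_numpy().mean()
            for b in bands
        ])
        p, *_ = np.linalg.lstsq(m.T, e, rcond=None)
        p = np.clip(p, 0.0, None)
        shares = p / p.sum()
        out[sid] = {b.name: float(s) for b, s in zip(bands, shares)}
    return out
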