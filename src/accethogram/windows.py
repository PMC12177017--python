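"""Segment labelled series into fixed-length single-behaviour windows and
decimate them to the target sampling frequencies."""

from __future__ import annotations

import numpy as np

from .types import (
    SUPPORTED_FREQUENCIES,
    SUPPORTED_WINDOWS,
    LabeledSeries,
    LabeledWindow,
)

__all__ = ["segment", "resample"]


def segment(series: LabeledSeries, window_s: float) -> list[LabeledWindow]:
    """Tile every labelled run into consecutive non-overlapping windows of
    ``window_s`` seconds at the native rate.

    Each run (a maximal stretch of samples sharing one bout) is tiled from
    its start; a trailing remainder shorter than one window is discarded, so
    a run of duration d yields floor(d / window_s) windows.  Behaviours
    whose bouts never reach the window length simply produce no windows.
    """
    if window_s not in SUPPORTED_WINDOWS:
        raise ValueError(f"window_s must be one of {SUPPORTED_WINDOWS}, got {window_s}")
    trace = series.trace
    fs = trace.sample_rate_hz
    n_per = int(round(window_s * fs))
    out: list[LabeledWindow] = []
    ids = series.bout_id
    n = len(ids)
    run_start = 0
    while run_start < n:
        if ids[run_start] < 0:
            run_start += 1
            continue
        run_end = run_start
        while run_end < n and ids[run_end] == ids[run_start]:
            run_end += 1
        n_win = (run_end - run_start) // n_per
        for w in range(n_win):
            i0 = run_start + w * n_per
            i1 = i0 + n_per
            out.append(
                LabeledWindow(
                    individual_id=trace.individual_id,
                    species=trace.species,
                    position=trace.position,
                    behaviour=str(series.label[run_start]),
                    window_s=window_s,
                    freq_hz=fs,
                    ax=trace.ax[i0:i1].copy(),
                    ay=trace.ay[i0:i1].copy(),
                    az=trace.az[i0:i1].copy(),
                    t0=float(trace.t[i0]),
                )
            )
        run_start = run_end
    return out


def resample(window: LabeledWindow, target_hz: float) -> LabeledWindow:
    """Decimate a window to ``target_hz`` by nearest-sample selection.

    Output sample k is the native sample nearest to t0 + k/target_hz for
    k = 0 .. round(window_s * target_hz) - 1.  No anti-alias filter is
    applied: the logger's quantised values are preserved verbatim, and the
    behaviours of interest oscillate well below the lowest Nyquist
    frequency used.  Upsampling is refused.
    """
    if target_hz not in SUPPORTED_FREQUENCIES:
        raise ValueError(
            f"target_hz must be one of {SUPPORTED_FREQUENCIES}, got {target_hz}"
        )
    if target_hz > window.freq_hz:
        raise ValueError(
            f"cannot upsample from {window.freq_hz} Hz to {target_hz} Hz"
        )
    if target_hz == window.freq_hz:
        return window
    n_out = int(round(window.window_s * target_hz))
    k = np.arange(n_out)
    idx = np.round(k * window.freq_hz / target_hz).astype(int)
    idx = np.clip(idx, 0, len(window) - 1)
    return LabeledWindow(
        individual_id=window.individual_id,
        species=window.species,
        position=window.position,
        behaviour=window.behaviour,
        window_s=window.window_s,
        freq_hz=target_hz,
        ax=window.ax[idx],
        ay=window.ay[idx],
        az=window.az[idx],
        t0=window.t0,
    )
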