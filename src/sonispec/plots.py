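"""PNG exports of the per-ROI audio spectrum and waveform displays."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .synth import AudioBuffer, SpectrumDisplay  # noqa: E402

__all__ = ["plot_spectrum", "plot_waveform"]


def plot_spectrum(display: SpectrumDisplay, path: str | Path,
                  max_hz: float | None = 5000.0, title: str = "") -> None:
    """Linear-magnitude audio spectrum, truncated to ``max_hz`` for legibility."""
    fig, ax = plt.subplots(figsize=(6, 3))
    f, m = display.frequencies_hz, display.magnitudes
    if max_hz is not None:
        keep = f <= max_hz
        f, m = f[keep], m[keep]
    ax.plot(f, m, lw=0.8)
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel("magnitude")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_waveform(buffer: AudioBuffer, path: str | Path,
                  max_s: float = 0.05, title: str = "") -> None:
    """Waveform display; only the first ``max_s`` seconds are drawn so the
    oscillation shape is visible."""
    fig, ax = plt.subplots(figsize=(6, 3))
    n = min(buffer.samples.size, int(max_s * buffer.sample_rate_hz))
    t = np.arange(n) / buffer.sample_rate_hz
    ax.plot(t, buffer.samples[:n], lw=0.8)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("amplitude")
    ax.set_ylim(-1.05, 1.05)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
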