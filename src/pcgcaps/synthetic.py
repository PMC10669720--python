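"""Synthetic phonocardiogram generator.

Emulates the signal structure the classifier assumes: quasi-periodic
cardiac cycles, each carrying a Gaussian-windowed low-frequency S1 tone
burst at the cycle start and an S2 burst later in the cycle, optional
systolic murmur energy (band-limited noise between S1 and S2, roughly
150-700 Hz) for the abnormal class, heart-rate variability, and additive
wideband noise.  The generator makes no claim of physiological realism;
it exists so the preprocessing, training, and evaluation pipeline can be
exercised end to end with a dataset whose labels are separable by
construction (a band-energy threshold already recovers them).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .preprocess import ABNORMAL, NORMAL, PCGRecording, write_wav

__all__ = ["SynthConfig", "generate_recording", "generate_dataset", "band_energy_score"]


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters.

    Frequencies in Hz, durations in seconds, amplitudes relative to the
    S1 peak.  murmur_amplitude applies to abnormal recordings only;
    normal recordings always get zero murmur.  hr_jitter is the
    per-cycle fractional perturbation of the cycle length (0 disables
    it).
    """

    sample_rate: float = 2000.0
    duration_s: float = 5.0
    heart_rate_bpm: tuple[float, float] = (55.0, 110.0)
    s1_freq: float = 70.0
    s2_freq: float = 120.0
    s1_s2_interval: float = 0.35  # fraction of the cycle, S1 onset to S2 onset
    burst_sd_s: float = 0.02  # Gaussian envelope width of S1/S2 bursts
    murmur_band: tuple[float, float] = (150.0, 700.0)
    murmur_amplitude: float = 0.4
    noise_sd: float = 0.02
    hr_jitter: float = 0.05
    peak: float = 0.95  # final peak amplitude after scaling
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.murmur_band
        if not (0.0 < lo < hi < self.sample_rate / 2.0):
            raise ValueError("murmur_band must lie inside (0, Nyquist)")
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample rate must be positive")


def _gauss_burst(t: np.ndarray, center: float, freq: float, sd: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / sd) ** 2)
    return env * np.sin(2.0 * np.pi * freq * (t - center))


def generate_recording(
    label: int,
    config: SynthConfig = SynthConfig(),
    rng: np.random.Generator | None = None,
    id: str = "",
) -> PCGRecording:
    """Generate one labeled recording.

    Deterministic given (label, config, seed).  The murmur noise stream
    is drawn for both classes so that an abnormal recording with
    murmur_amplitude = 0 is sample-identical to the normal recording
    produced under the same seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sr = config.sample_rate
    n = int(round(config.duration_s * sr))
    t = np.arange(n) / sr
    x = np.zeros(n)

    hr = rng.uniform(*config.heart_rate_bpm)
    base_period = 60.0 / hr

    sos = butter(4, config.murmur_band, btype="bandpass", fs=sr, output="sos")
    murmur_src = sosfiltfilt(sos, rng.standard_normal(n))
    murmur_src /= max(np.abs(murmur_src).max(), 1e-12)
    amp = config.murmur_amplitude if label == ABNORMAL else 0.0

    onset = 0.05 * base_period  # first S1 shortly after the start
    while onset < config.duration_s:
        jitter = 1.0 + config.hr_jitter * rng.uniform(-1.0, 1.0)
        period = base_period * jitter
        s2_onset = onset + config.s1_s2_interval * period
        x += _gauss_burst(t, onset, config.s1_freq, config.burst_sd_s)
        x += 0.8 * _gauss_burst(t, s2_onset, config.s2_freq, config.burst_sd_s)
        # systolic murmur: windowed between the S1 and S2 bursts
        mid = 0.5 * (onset + s2_onset)
        half = 0.5 * (s2_onset - onset) - 2.0 * config.burst_sd_s
        if half > 0:
            win = np.exp(-0.5 * ((t - mid) / (half / 2.0)) ** 2)
            x += amp * win * murmur_src
        onset += period

    x += config.noise_sd * rng.standard_normal(n)
    peak = np.abs(x).max()
    if peak > 0:
        x = config.peak * x / peak
    return PCGRecording(samples=x, sample_rate=sr, label=label, id=id or f"synth_{label}")


def generate_dataset(
    n_per_class: int,
    config: SynthConfig = SynthConfig(),
    out_dir: str | Path | None = None,
) -> list[PCGRecording]:
    """Generate a balanced labeled set of 2 * n_per_class recordings.

    Per-recording seeds are derived from the master seed, so the same
    master seed reproduces the dataset byte for byte.  If `out_dir` is
    given, WAV files and a `manifest.csv` (id, label, seed, heart_rate)
    are written there.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    recs: list[PCGRecording] = []
    rows = []
    children = np.random.SeedSequence(config.seed).spawn(2 * n_per_class)
    k = 0
    for label in (NORMAL, ABNORMAL):
        for i in range(n_per_class):
            child = children[k]
            rng = np.random.default_rng(child)
            rid = f"synth_{'ab' if label else 'nm'}_{i:04d}"
            rec = generate_recording(label, config, rng=rng, id=rid)
            recs.append(rec)
            hr_rng = np.random.default_rng(child)
            seed_key = f"{config.seed}.{child.spawn_key[0]}"
            rows.append((rid, label, seed_key, hr_rng.uniform(*config.heart_rate_bpm)))
            k += 1
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recs:
            write_wav(out_dir / f"{rec.id}.wav", rec)
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "label", "seed", "heart_rate_bpm"])
            for rid, label, seed, hr in rows:
                w.writerow([rid, label, seed, f"{hr:.3f}"])
    return recs


def band_energy_score(recording: PCGRecording, band: tuple[float, float] = (150.0, 700.0)) -> float:
    """Fraction of Welch spectral power inside `band`.

    A trivial reference feature: thresholding it separates the synthetic
    classes, which is what makes the learning tests well-posed.
    """
    from scipy.signal import welch

    x = recording.samples
    if x.ndim == 2:
        x = x.mean(axis=1)
    f, p = welch(x, fs=recording.sample_rate, nperseg=min(1024, len(x)))
    inside = p[(f >= band[0]) & (f <= band[1])].sum()
    return float(inside / p.sum())
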