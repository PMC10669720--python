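"""Phonocardiogram preprocessing: segmentation, downsampling, peak
normalization, and MFCC spectrum extraction.

The pipeline turns a raw heart-sound recording into fixed-size
mel-frequency cepstral coefficient (MFCC) matrices, the network input.
The four steps run in a fixed order — slice the recording into
non-overlapping clips, anti-alias resample to the model rate, scale each
clip to peak amplitude 1, then compute the MFCC spectrum — so that a 5-s
clip at 2 kHz always yields a 128 x 16 coefficient-by-frame matrix.

Heart sounds live almost entirely below 1 kHz (S1 and S2 below ~200 Hz,
murmurs roughly 150-700 Hz), so the 2 kHz model rate preserves the
clinically relevant band while cutting the data volume ~22x from typical
44.1 kHz recordings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.fft import dct
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

logger = logging.getLogger(__name__)

NORMAL, ABNORMAL = 0, 1

__all__ = [
    "PCGRecording",
    "Segment",
    "MFCCConfig",
    "MFCCSpectrum",
    "DEFAULT_MFCC_CONFIG",
    "MFCC_PRESETS",
    "segment",
    "downsample",
    "normalize",
    "mfcc_spectrum",
    "preprocess_recording",
    "read_wav",
    "write_wav",
    "load_physionet_dir",
    "write_spectra",
    "load_spectra",
]


@dataclass
class PCGRecording:
    """A labeled heart-sound waveform.

    samples : float array, shape (n,) mono or (n, 2) stereo, amplitude
        dimensionless.
    label : 0 = normal, 1 = abnormal, None = unlabeled.
    """

    samples: np.ndarray
    sample_rate: float
    label: int | None = None
    id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")
        if self.samples.ndim == 2 and self.samples.shape[1] not in (1, 2):
            raise ValueError("only mono or stereo recordings supported")
        if self.label not in (None, NORMAL, ABNORMAL):
            raise ValueError("label must be 0, 1 or None")

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sample_rate


@dataclass
class Segment:
    """A fixed-duration mono clip cut from a recording."""

    samples: np.ndarray
    sample_rate: float
    duration_s: float
    source_id: str = ""
    label: int | None = None
    index: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def id(self) -> str:
        return f"{self.source_id}#{self.index}"


@dataclass(frozen=True)
class MFCCConfig:
    """MFCC extraction convention.

    The framing is chosen so a clip tiles into exactly `expected_frames`
    full frames with no padding: for the 5-s default at 2 kHz,
    floor((10000 - 1000)/600) + 1 = 16.  128 triangular mel filters span
    20-1000 Hz (the band the 2 kHz rate preserves) and the DCT keeps all
    128 coefficients, giving the 128 x 16 network input.
    """

    sample_rate: float = 2000.0
    n_mels: int = 128
    n_coeff: int = 128
    frame_length: int = 1000
    hop_length: int = 600
    n_fft: int = 1024
    fmin: float = 20.0
    fmax: float = 1000.0
    expected_frames: int = 16
    window: str = "hann"
    log_floor: float = 1e-10


DEFAULT_MFCC_CONFIG = MFCCConfig()

#: Per-segment-length framing presets (clip seconds -> config). Frame and
#: hop are chosen so each duration tiles into full frames exactly.
MFCC_PRESETS: dict[float, MFCCConfig] = {
    5.0: DEFAULT_MFCC_CONFIG,
    10.0: replace(DEFAULT_MFCC_CONFIG, hop_length=612, expected_frames=32),
    3.0: replace(DEFAULT_MFCC_CONFIG, hop_length=555, expected_frames=10),
    1.0: replace(DEFAULT_MFCC_CONFIG, hop_length=333, expected_frames=4),
}


@dataclass
class MFCCSpectrum:
    """Coefficient-by-frame MFCC matrix for one segment."""

    values: np.ndarray  # (n_coeff, n_frames)
    segment_id: str = ""
    label: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MFCC spectrum contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------
def segment(recording: PCGRecording, duration_s: float = 5.0) -> list[Segment]:
    """Cut a recording into non-overlapping clips of `duration_s` seconds.

    Stereo input is mixed to mono by channel averaging first.  The
    trailing remainder shorter than one clip is discarded; a recording
    shorter than one clip yields an empty list.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    x = recording.samples
    if x.ndim == 2:
        x = x.mean(axis=1)
    seg_len = int(round(duration_s * recording.sample_rate))
    n = len(x) // seg_len
    return [
        Segment(
            samples=x[k * seg_len : (k + 1) * seg_len].copy(),
            sample_rate=recording.sample_rate,
            duration_s=duration_s,
            source_id=recording.id,
            label=recording.label,
            index=k,
        )
        for k in range(n)
    ]


def downsample(seg: Segment, target_rate: float = 2000.0) -> Segment:
    """Anti-aliased polyphase resampling to `target_rate`.

    The FIR low-pass applied by the polyphase filter keeps content below
    the new Nyquist (1 kHz at the 2 kHz default) intact, which covers
    the full heart-sound band.  Upsampling is not supported.
    """
    if target_rate > seg.sample_rate:
        raise ValueError(
            f"upsampling unsupported: target {target_rate} Hz > source {seg.sample_rate} Hz"
        )
    if target_rate == seg.sample_rate:
        return replace(seg, samples=seg.samples.copy())
    frac = Fraction(target_rate / seg.sample_rate).limit_denominator(10_000)
    y = resample_poly(seg.samples, frac.numerator, frac.denominator)
    want = int(round(seg.duration_s * target_rate))
    if len(y) > want:
        y = y[:want]
    elif len(y) < want:
        y = np.pad(y, (0, want - len(y)))
    return replace(seg, samples=y, sample_rate=target_rate)


def normalize(seg: Segment) -> Segment:
    """Scale a clip so its peak absolute amplitude is exactly 1.

    An all-zero clip is returned unchanged with a logged warning; a clip
    containing NaN or inf is rejected.
    """
    x = seg.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")
    peak = np.abs(x).max()
    if peak == 0.0:
        logger.warning("normalize: all-zero segment %s left unchanged", seg.id)
        return replace(seg, samples=x.copy())
    return replace(seg, samples=x / peak)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(config: MFCCConfig) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    n_bins = config.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, config.sample_rate / 2.0, n_bins)
    mel_pts = np.linspace(
        _hz_to_mel(config.fmin), _hz_to_mel(config.fmax), config.n_mels + 2
    )
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((config.n_mels, n_bins))
    for m in range(config.n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mfcc_spectrum(seg: Segment, config: MFCCConfig = DEFAULT_MFCC_CONFIG) -> MFCCSpectrum:
    """Compute the MFCC coefficient-by-frame matrix for one clip.

    Windowed power spectra of full frames (no padding) are pooled by the
    mel filterbank, log-compressed, and cosine-transformed (DCT-II,
    orthonormal).  The result is a pure function of (samples, config):
    identical bytes in, bit-identical matrix out.
    """
    x = seg.samples
    if seg.sample_rate != config.sample_rate:
        raise ValueError(
            f"segment rate {seg.sample_rate} Hz != config rate {config.sample_rate} Hz; "
            "downsample first"
        )
    if len(x) < config.frame_length:
        raise ValueError("segment shorter than one analysis frame")
    n_frames = (len(x) - config.frame_length) // config.hop_length + 1
    if n_frames != config.expected_frames:
        raise ValueError(
            f"framing mismatch: config expects {config.expected_frames} frames "
            f"but {len(x)} samples yield {n_frames}"
        )
    win = get_window(config.window, config.frame_length, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(x, config.frame_length)[
        :: config.hop_length
    ][:n_frames]
    spec = np.fft.rfft(frames * win, n=config.n_fft, axis=1)
    power = np.abs(spec) ** 2
    mel = power @ mel_filterbank(config).T  # (n_frames, n_mels)
    logmel = np.log10(np.maximum(mel, config.log_floor))
    coeffs = dct(logmel, type=2, norm="ortho", axis=1)[:, : config.n_coeff]
    return MFCCSpectrum(values=coeffs.T, segment_id=seg.id, label=seg.label)


def preprocess_recording(
    recording: PCGRecording,
    duration_s: float = 5.0,
    target_rate: float = 2000.0,
    config: MFCCConfig | None = None,
) -> list[MFCCSpectrum]:
    """Full pipeline: segment -> downsample -> normalize -> MFCC."""
    if config is None:
        config = MFCC_PRESETS.get(float(duration_s), DEFAULT_MFCC_CONFIG)
    return [
        mfcc_spectrum(normalize(downsample(s, target_rate)), config)
        for s in segment(recording, duration_s)
    ]


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------
def read_wav(path, label: int | None = None, id: str | None = None) -> PCGRecording:
    """Read a PCM or float WAV file into a recording scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    rid = id if id is not None else Path(path).stem
    return PCGRecording(samples=data, sample_rate=float(rate), label=label, id=rid)


def write_wav(path, recording: PCGRecording) -> None:
    """Write a recording as 16-bit PCM WAV (samples clipped to [-1, 1])."""
    x = np.clip(recording.samples, -1.0, 1.0)
    wavfile.write(path, int(recording.sample_rate), (x * 32767.0).astype(np.int16))


def load_physionet_dir(wav_dir, labels_csv) -> list[PCGRecording]:
    """Read a PhysioNet-2016-style layout: `*.wav` plus a CSV of
    `<record>,<label>` rows with labels {-1: normal, 1: abnormal}."""
    wav_dir = Path(wav_dir)
    recs = []
    with open(labels_csv, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            name, raw = row[0].strip(), int(row[1])
            label = NORMAL if raw == -1 else ABNORMAL
            path = wav_dir / f"{name}.wav"
            if not path.exists():
                logger.warning("missing WAV for record %s; skipped", name)
                continue
            recs.append(read_wav(path, label=label, id=name))
    return recs


def write_spectra(out_dir, spectra: list[MFCCSpectrum]) -> Path:
    """Write spectra as .npy matrices plus a manifest CSV; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["segment_id", "source", "label", "n_coeff", "n_frames", "file"])
        for i, sp in enumerate(spectra):
            fname = f"spectrum_{i:05d}.npy"
            np.save(out_dir / fname, sp.values)
            src = sp.segment_id.split("#")[0]
            lab = "" if sp.label is None else sp.label
            w.writerow([sp.segment_id, src, lab, sp.shape[0], sp.shape[1], fname])
    return manifest


def load_spectra(manifest_path) -> list[MFCCSpectrum]:
    """Load spectra written by :func:`write_spectra`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            values = np.load(base / row["file"])
            label = int(row["label"]) if row["label"] != "" else None
            out.append(MFCCSpectrum(values=values, segment_id=row["segment_id"], label=label))
    return out
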