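"""Call preprocessing and spectral-slope extraction.

The spectral slope (SS) summarises how a call's acoustic energy is distributed
over frequency: the whole call's power spectrum is divided into fixed-width
frequency bins, the amplitude peak (dB) of each bin is located, and an ordinary
least-squares line is fitted to those peaks as a function of frequency (kHz).
Calls with relatively more high-frequency energy have shallower (less
negative) slopes.

Preprocessing mirrors standard bioacoustic practice for comparative work:
recordings are anti-alias down-sampled to a common rate (default 40 kHz, i.e.
a 20 kHz Nyquist matching the hearing-threshold band) and scaled to a common
mean intensity (default 60 dB SPL, reference pressure 2e-5 with digital full
scale = 1, the Praat convention).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "CallWave",
    "SlopeResult",
    "P_REF",
    "read_wav",
    "preprocess",
    "binned_spectral_peaks",
    "spectral_slope",
    "analyze_call",
    "species_average_slope",
    "write_wav",
]

#: SPL reference pressure (Pa) with digital full scale = 1.
P_REF = 2e-5

#: dB floor, relative to the spectrum maximum, below which bins are discarded.
DB_FLOOR = -100.0


@dataclass(frozen=True)
class CallWave:
    """A mono call recording in memory."""

    samples: np.ndarray
    sample_rate_hz: int
    source_id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def intensity_db(self) -> float:
        """Mean intensity in dB SPL (re ``P_REF``)."""
        r = self.rms()
        if r == 0:
            raise ValueError("intensity undefined for an all-zero signal")
        return 20.0 * np.log10(r / P_REF)


@dataclass(frozen=True)
class SlopeResult:
    """Spectral slope of one call plus its provenance."""

    species: str
    source_id: str
    slope_db_per_khz: float
    intercept_db: float
    n_peaks: int
    peak_freqs_khz: np.ndarray
    peak_amps_db: np.ndarray


def read_wav(path, species: str = "", source_id: str | None = None) -> CallWave:
    """Read a PCM WAV file as a mono :class:`CallWave` scaled to [-1, 1].

    Multichannel files are averaged to mono.  Integer PCM (16/24/32-bit) is
    scaled by its full-scale value; float WAV is taken as already scaled.
    Compressed encodings are rejected by the WAV reader.
    """
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"unsupported or non-PCM WAV encoding in {path}: {exc}") from None
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    if samples.ndim > 1:
        samples = samples.mean(axis=1)
    sid = source_id if source_id is not None else str(path)
    return CallWave(samples=samples, sample_rate_hz=int(rate), source_id=sid, species=species)


def write_wav(path, w: CallWave, *, subtype: str = "float32") -> None:
    """Write a :class:`CallWave` as WAV.

    Default is 32-bit float (exact round trip); ``subtype="pcm16"`` writes
    16-bit integer PCM, whose quantization floor is audible in spectral-slope
    analyses of very steep spectra.
    """
    peak = np.max(np.abs(w.samples))
    x = w.samples / peak * 0.999 if peak > 1.0 else w.samples
    if subtype == "float32":
        wavfile.write(path, w.sample_rate_hz, x.astype(np.float32))
    elif subtype == "pcm16":
        wavfile.write(path, w.sample_rate_hz, (x * 32767).astype(np.int16))
    else:
        raise ValueError("subtype must be 'float32' or 'pcm16'")


def preprocess(
    w: CallWave, target_rate_hz: int = 40_000, target_db: float = 60.0
) -> CallWave:
    """Down-sample to ``target_rate_hz`` and set mean intensity to ``target_db``.

    Resampling is polyphase with a sharp Kaiser-designed anti-alias filter
    (120 dB stopband, transition band 2% of the target Nyquist) so that energy
    above the new Nyquist cannot fold into the analysis band; up-sampling is
    refused (the analysis only ever narrows the band).  The gain is uniform,
    chosen so that 20*log10(RMS / 2e-5) equals ``target_db`` — at the 60 dB
    default the output RMS is exactly 0.02.
    """
    if w.sample_rate_hz < target_rate_hz:
        raise ValueError(
            f"sample rate {w.sample_rate_hz} Hz below target {target_rate_hz} Hz; "
            "up-sampling is not supported"
        )
    if w.sample_rate_hz != target_rate_hz:
        frac = Fraction(target_rate_hz, w.sample_rate_hz)
        up, down = frac.numerator, frac.denominator
        fs_up = w.sample_rate_hz * up
        trans = 0.02 * (target_rate_hz / 2)
        numtaps, beta = signal.kaiserord(120.0, 2 * trans / fs_up)
        numtaps |= 1
        h = signal.firwin(
            numtaps, target_rate_hz / 2 - trans / 2, window=("kaiser", beta), fs=fs_up
        )
        x = signal.resample_poly(w.samples, up, down, window=h * up)
    else:
        x = w.samples
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("cannot set intensity of an all-zero (silent) recording")
    target_rms = P_REF * 10 ** (target_db / 20.0)
    x = x * (target_rms / rms)
    return CallWave(
        samples=x, sample_rate_hz=target_rate_hz, source_id=w.source_id, species=w.species
    )


def binned_spectral_peaks(
    w: CallWave, bin_hz: float = 100.0, f_max_hz: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin amplitude peaks of the whole-call power spectrum.

    A single Hann-windowed periodogram of the entire call (zero-padded to the
    next power of two) is partitioned into bins of width ``bin_hz`` from 0 to
    ``f_max_hz`` (default Nyquist).  Each bin contributes the frequency (kHz)
    and amplitude (dB, 10*log10 power re spectrum maximum) of its maximum.
    The DC bin is excluded and bins whose maximum sits at the -100 dB floor
    are dropped.
    """
    if bin_hz <= 0:
        raise ValueError("bin_hz must be positive")
    if w.duration_s < 2.0 / bin_hz:
        raise ValueError(
            f"call of {w.duration_s:.4f} s too short to resolve {bin_hz} Hz bins"
        )
    nyquist = w.sample_rate_hz / 2.0
    f_max = nyquist if f_max_hz is None else min(f_max_hz, nyquist)

    n = w.samples.size
    nfft = int(2 ** np.ceil(np.log2(n)))
    win = signal.get_window("hann", n)
    spec = np.fft.rfft(w.samples * win, n=nfft)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / w.sample_rate_hz)

    with np.errstate(divide="ignore"):
        amps = 10.0 * np.log10(power / power.max())
    amps = np.maximum(amps, DB_FLOOR)

    peak_f, peak_a = [], []
    edges = np.arange(0.0, f_max + bin_hz, bin_hz)
    idx = np.searchsorted(freqs, edges)
    for b in range(len(edges) - 1):
        lo, hi = idx[b], idx[b + 1]
        if b == 0:  # DC bin excluded
            continue
        if hi <= lo:
            continue
        seg = amps[lo:hi]
        k = int(np.argmax(seg))
        if seg[k] <= DB_FLOOR:
            continue
        peak_f.append(freqs[lo + k] / 1000.0)
        peak_a.append(seg[k])
    if len(peak_f) < 2:
        raise ValueError("fewer than 2 usable frequency bins above the floor")
    return np.asarray(peak_f), np.asarray(peak_a)


def spectral_slope(
    peak_freqs_khz: np.ndarray,
    peak_amps_db: np.ndarray,
    *,
    species: str = "",
    source_id: str = "",
) -> SlopeResult:
    """OLS fit of bin-peak amplitude (dB) on frequency (kHz).

    The fitted gradient is the spectral slope in dB/kHz; shallower (less
    negative) slopes indicate relatively more high-frequency energy.
    """
    f = np.asarray(peak_freqs_khz, dtype=float)
    a = np.asarray(peak_amps_db, dtype=float)
    if f.size < 2 or np.ptp(f) == 0:
        raise ValueError("spectral slope needs >= 2 distinct peak frequencies")
    slope, intercept = np.polyfit(f, a, 1)
    return SlopeResult(
        species=species,
        source_id=source_id,
        slope_db_per_khz=float(slope),
        intercept_db=float(intercept),
        n_peaks=int(f.size),
        peak_freqs_khz=f,
        peak_amps_db=a,
    )


def analyze_call(
    w: CallWave,
    *,
    bin_hz: float = 100.0,
    target_rate_hz: int = 40_000,
    target_db: float = 60.0,
) -> SlopeResult:
    """Preprocess one call and extract its spectral slope."""
    p = preprocess(w, target_rate_hz=target_rate_hz, target_db=target_db)
    f, a = binned_spectral_peaks(p, bin_hz=bin_hz)
    return spectral_slope(f, a, species=w.species, source_id=w.source_id)


def species_average_slope(results: Sequence[SlopeResult]) -> pd.DataFrame:
    """Unweighted per-species mean spectral slope.

    Returns a DataFrame indexed by species with columns ``slope_db_per_khz``
    (mean over recordings) and ``n_recordings``.
    """
    if not results:
        raise ValueError("no slope results to average")
    df = pd.DataFrame(
        {"species": [r.species for r in results], "slope": [r.slope_db_per_khz for r in results]}
    )
    g = df.groupby("species")["slope"]
    out = pd.DataFrame({"slope_db_per_khz": g.mean(), "n_recordings": g.size()})
    return out


def write_slopes_csv(results: Sequence[SlopeResult], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["source_id", "species", "slope_db_per_khz", "intercept_db", "n_peaks"])
        for r in results:
            w.writerow(
                [r.source_id, r.species, f"{r.slope_db_per_khz:.6g}",
                 f"{r.intercept_db:.6g}", r.n_peaks]
            )
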