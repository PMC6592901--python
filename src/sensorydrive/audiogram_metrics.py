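"""Hearing-sensitivity indices computed from audiograms.

An audiogram is the curve of the quietest detectable tone level (threshold, dB)
as a function of tone frequency; lower thresholds mean better hearing.  From it
we derive the comparative measures used throughout the package:

* **peak sensitivity (PS)** — the frequency (kHz) of minimum threshold; ties
  are resolved by averaging the tied frequencies;
* **band mean thresholds** — the mean threshold over the 0–20 kHz and
  10–20 kHz bands, computed from the measured sample points in the band plus
  log-frequency-interpolated band endpoints;
* **relative high-frequency hearing sensitivity (relHFHS)** — the 0–20 kHz
  mean minus the 10–20 kHz mean.  Subtracting the band mean from the overall
  mean removes study-to-study offsets in absolute threshold, so relHFHS is a
  standardized index: higher values indicate better high-frequency hearing.

Interpolation between measured tones is linear in threshold (dB) against
log2(frequency), the audiometric convention for octave-spaced test tones; a
``log_frequency=False`` switch selects linear-frequency interpolation instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Audiogram",
    "HearingMeasures",
    "CompositeAudiogram",
    "read_audiograms",
    "threshold_at",
    "peak_sensitivity",
    "band_mean_threshold",
    "rel_hf_sensitivity",
    "hearing_measures",
    "composite_audiogram",
    "write_measures_csv",
    "write_composite_csv",
]

_METHODS = ("behavioural", "abr", "synthetic")


@dataclass(frozen=True)
class Audiogram:
    """Per-species frequency → threshold curve.

    Parameters
    ----------
    species : str
        Taxon label.
    frequencies_khz : array-like
        Strictly increasing, positive test-tone frequencies in kHz.
    thresholds_db : array-like
        Detection thresholds in dB, one per frequency.
    method : {"behavioural", "abr", "synthetic"}
        How the audiogram was obtained.
    """

    species: str
    frequencies_khz: np.ndarray
    thresholds_db: np.ndarray
    method: str = "behavioural"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_khz, dtype=float)
        t = np.asarray(self.thresholds_db, dtype=float)
        if f.ndim != 1 or t.ndim != 1 or f.size != t.size:
            raise ValueError("frequencies and thresholds must be 1-D and equal length")
        if f.size < 2:
            raise ValueError(f"audiogram for {self.species!r} needs >= 2 points")
        if not np.all(f > 0):
            raise ValueError("frequencies must be positive")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(t))):
            raise ValueError("audiogram contains non-finite values")
        if self.method not in _METHODS:
            raise ValueError(f"unknown audiogram method {self.method!r}")
        object.__setattr__(self, "frequencies_khz", f)
        object.__setattr__(self, "thresholds_db", t)

    @property
    def f_min(self) -> float:
        return float(self.frequencies_khz[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies_khz[-1])


@dataclass(frozen=True)
class HearingMeasures:
    """The hearing indices for one species."""

    species: str
    peak_sensitivity_khz: float
    mean_threshold_0_20_db: float
    mean_threshold_10_20_db: float
    rel_hf_sensitivity_db: float


@dataclass(frozen=True)
class CompositeAudiogram:
    """Cross-species mean audiogram on a fixed frequency grid."""

    audiogram: Audiogram
    n_species: np.ndarray  # contributing species per grid point
    dropped: dict = field(default_factory=dict)  # grid freq -> species without coverage


def read_audiograms(path) -> list[Audiogram]:
    """Read a long-format audiogram CSV into one :class:`Audiogram` per species.

    The file must have a header with columns ``species``, ``frequency_khz``,
    ``threshold_db`` and optionally ``method``.  Rows are grouped by species and
    sorted by frequency; duplicated (species, frequency) pairs are an error.
    """
    rows: dict[str, list[tuple[float, float, str]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"species", "frequency_khz", "threshold_db"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"audiogram CSV must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            sp = row["species"].strip()
            try:
                f = float(row["frequency_khz"])
                t = float(row["threshold_db"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"non-numeric audiogram field at row {i}: {exc}") from None
            method = (row.get("method") or "behavioural").strip()
            rows.setdefault(sp, []).append((f, t, method))

    out = []
    for sp, pts in rows.items():
        freqs = [p[0] for p in pts]
        if len(set(freqs)) != len(freqs):
            dup = sorted({f for f in freqs if freqs.count(f) > 1})
            raise ValueError(f"duplicate (species, frequency) rows for {sp!r} at {dup} kHz")
        pts.sort(key=lambda p: p[0])
        out.append(
            Audiogram(
                species=sp,
                frequencies_khz=np.array([p[0] for p in pts]),
                thresholds_db=np.array([p[1] for p in pts]),
                method=pts[0][2],
            )
        )
    return out


def threshold_at(a: Audiogram, f_khz: float, *, log_frequency: bool = True) -> float:
    """Threshold (dB) at ``f_khz``, interpolating between measured tones.

    Exact at measured frequencies.  Between two bracketing tones the threshold
    is interpolated linearly against log2(frequency) (or raw frequency when
    ``log_frequency=False``).  Frequencies outside the measured range raise —
    thresholds beyond the tested tones are unknowable, so no extrapolation.
    """
    if not (a.f_min <= f_khz <= a.f_max):
        raise ValueError(
            f"{f_khz} kHz outside measured range [{a.f_min}, {a.f_max}] kHz "
            f"for {a.species!r}; extrapolation is not supported"
        )
    x = np.log2(a.frequencies_khz) if log_frequency else a.frequencies_khz
    xq = np.log2(f_khz) if log_frequency else f_khz
    return float(np.interp(xq, x, a.thresholds_db))


def peak_sensitivity(a: Audiogram, *, tol_db: float = 0.0) -> float:
    """Frequency of maximum hearing sensitivity (minimum threshold), in kHz.

    When the minimum is shared by several measured frequencies (within
    ``tol_db`` of the minimum), the arithmetic mean of the tied frequencies is
    returned.
    """
    tmin = float(np.min(a.thresholds_db))
    tied = a.frequencies_khz[a.thresholds_db <= tmin + tol_db]
    return float(np.mean(tied))


def band_mean_threshold(
    a: Audiogram, lo_khz: float, hi_khz: float, *, log_frequency: bool = True
) -> float:
    """Mean threshold (dB) over a frequency band.

    The mean is taken over the measured sample points inside [lo, hi],
    augmented by the interpolated threshold at ``hi_khz`` (and at ``lo_khz``
    when it exceeds the lowest measured frequency) if those endpoints are not
    themselves measured.  A band reaching below the lowest measured tone simply
    starts at that tone — no extrapolation toward 0 kHz.
    """
    if hi_khz <= lo_khz:
        raise ValueError("band upper edge must exceed lower edge")
    if hi_khz > a.f_max or lo_khz > a.f_max:
        raise ValueError(
            f"band {lo_khz}-{hi_khz} kHz not covered by audiogram for {a.species!r} "
            f"(measured up to {a.f_max} kHz)"
        )
    in_band = (a.frequencies_khz >= lo_khz) & (a.frequencies_khz <= hi_khz)
    vals = list(a.thresholds_db[in_band])
    measured = set(a.frequencies_khz[in_band].tolist())
    for edge in (lo_khz, hi_khz):
        if edge in measured:
            continue
        if edge < a.f_min:  # band extends below the tested range: start at f_min
            continue
        vals.append(threshold_at(a, edge, log_frequency=log_frequency))
    if not vals:
        raise ValueError(f"no measured or interpolable point in band {lo_khz}-{hi_khz} kHz")
    return float(np.mean(vals))


def rel_hf_sensitivity(a: Audiogram, *, log_frequency: bool = True) -> float:
    """Relative high-frequency hearing sensitivity (relHFHS), in dB.

    Overall mean threshold (0–20 kHz) minus the 10–20 kHz band mean.  Being a
    difference of means it is invariant to a constant offset in thresholds,
    which removes methodological differences between source studies.  Higher
    values indicate better high-frequency hearing.
    """
    if a.f_max < 20.0:
        raise ValueError(
            f"audiogram for {a.species!r} covers only up to {a.f_max} kHz; "
            "relHFHS needs coverage to 20 kHz"
        )
    overall = band_mean_threshold(a, 0.0, 20.0, log_frequency=log_frequency)
    high = band_mean_threshold(a, 10.0, 20.0, log_frequency=log_frequency)
    return overall - high


def hearing_measures(a: Audiogram, *, tol_db: float = 0.0) -> HearingMeasures:
    """All hearing indices for one audiogram."""
    m020 = band_mean_threshold(a, 0.0, 20.0)
    m1020 = band_mean_threshold(a, 10.0, 20.0)
    return HearingMeasures(
        species=a.species,
        peak_sensitivity_khz=peak_sensitivity(a, tol_db=tol_db),
        mean_threshold_0_20_db=m020,
        mean_threshold_10_20_db=m1020,
        rel_hf_sensitivity_db=m020 - m1020,
    )


def composite_audiogram(
    audiograms: Sequence[Audiogram], grid_khz: Iterable[float]
) -> CompositeAudiogram:
    """Cross-species mean audiogram on ``grid_khz``.

    At each grid frequency the mean of per-species interpolated thresholds is
    taken over the species whose audiograms cover that frequency; species
    lacking coverage are dropped from that point and recorded.
    """
    if not audiograms:
        raise ValueError("composite_audiogram needs at least one audiogram")
    grid = np.asarray(list(grid_khz), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("grid frequencies must be positive and non-empty")
    means = np.empty(grid.size)
    counts = np.zeros(grid.size, dtype=int)
    dropped: dict[float, list[str]] = {}
    for i, f in enumerate(grid):
        vals = []
        for a in audiograms:
            if a.f_min <= f <= a.f_max:
                vals.append(threshold_at(a, f))
            else:
                dropped.setdefault(float(f), []).append(a.species)
        if not vals:
            raise ValueError(f"no audiogram covers grid frequency {f} kHz")
        means[i] = np.mean(vals)
        counts[i] = len(vals)
    comp = Audiogram(
        species="composite", frequencies_khz=grid, thresholds_db=means, method="synthetic"
    )
    return CompositeAudiogram(audiogram=comp, n_species=counts, dropped=dropped)


def write_measures_csv(measures: Sequence[HearingMeasures], path) -> None:
    """Write hearing indices to CSV (one row per species)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["species", "peak_sensitivity_khz", "mean_0_20", "mean_10_20", "rel_hf_sensitivity"]
        )
        for m in measures:
            w.writerow(
                [
                    m.species,
                    f"{m.peak_sensitivity_khz:.6g}",
                    f"{m.mean_threshold_0_20_db:.6g}",
                    f"{m.mean_threshold_10_20_db:.6g}",
                    f"{m.rel_hf_sensitivity_db:.6g}",
                ]
            )


def write_composite_csv(comp: CompositeAudiogram, path) -> None:
    """Write a composite audiogram to CSV (frequency, mean threshold, n)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["frequency_khz", "mean_threshold_db", "n_species"])
        a = comp.audiogram
        for f, t, n in zip(a.frequencies_khz, a.thresholds_db, comp.n_species):
            w.writerow([f"{f:.6g}", f"{t:.6g}", int(n)])
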