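"""Synthetic trees, trait tables, audiograms and vocalizations.

Every generator is a pure function of its parameters and a seed, and produces
data with the statistical structure the analysis stages assume:

* :func:`gen_tree` — pure-birth (Yule) ultrametric trees rescaled to unit
  root-to-tip height, a stand-in for a time-calibrated supertree;
* :func:`gen_species_table` — Gaussian species traits with phylogenetic
  covariance plus binary-habitat and continuous-covariate fixed effects and an
  optional i.i.d. call-function grouping effect (seven levels);
* :func:`gen_audiogram` — U-shaped audiograms, quadratic in log2-frequency
  around a controllable peak (best) frequency;
* :func:`gen_call` — harmonic source-filter calls: a harmonic stack with a
  controlled spectral-energy slope (dB/kHz) passed through cascaded
  second-order formant resonators.

The default formant pattern tiles the recording band evenly (odd multiples of
a tenth of the 22.05 kHz generation Nyquist — the resonance pattern of a
uniform tube).  An evenly tiled all-pole cascade has an approximately flat
spectral envelope apart from formant ripple, so the slope measured from a
synthesized call reflects the source slope; the ripple is the residual error
source.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from io import StringIO

import dendropy
import numpy as np
import pandas as pd
from scipy import signal

from sensorydrive.audiogram_metrics import Audiogram
from sensorydrive.phylo_pglmm import PhyloCorrelation, phylo_correlation
from sensorydrive.spectral_acoustics import CallWave

__all__ = [
    "SimConfig",
    "SyntheticCallSpec",
    "CALL_FUNCTIONS",
    "gen_tree",
    "gen_species_table",
    "gen_audiogram",
    "gen_call",
    "formant_gain",
]

#: Presumed-call-function categories used as the grouping random effect.
CALL_FUNCTIONS = (
    "advertisement",
    "aggression",
    "alarm",
    "contact",
    "disturbance",
    "group_coordination",
    "various",
)

#: Octave-spaced audiogram test-tone grid (kHz), 125 Hz to 64 kHz.
DEFAULT_AUDIOGRAM_GRID = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the species-trait simulation.

    The response is y = beta0 + beta_habitat*habitat + beta_covariate*x + a +
    u + e with a ~ N(0, sigma2_a * A), u a call-function group effect and e
    i.i.d. residual.  Defaults correspond to a strong habitat effect with
    three-quarters of the non-fixed variance phylogenetic (H^2 = 0.75).
    """

    n_taxa: int = 200
    seed: int = 0
    beta0: float = 0.0
    beta_habitat: float = -5.0
    beta_covariate: float = 1.0
    sigma2_a: float = 3.0
    sigma2_u: float = 0.0
    sigma2_e: float = 1.0
    p_forest: float = 0.5
    habitat_mode: str = "iid"

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.sigma2_a < 0 or self.sigma2_u < 0 or self.sigma2_e <= 0:
            raise ValueError("variances must be non-negative (residual positive)")
        if not (0 < self.p_forest < 1):
            raise ValueError("p_forest must lie in (0, 1)")
        if self.habitat_mode not in ("iid", "phylo_threshold"):
            raise ValueError("habitat_mode must be 'iid' or 'phylo_threshold'")


def gen_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree on ``n_taxa`` tips, unit root-to-tip height.

    Deterministic given the seed: the same call yields a byte-identical
    Newick string.  Tips are labelled ``sp001``, ``sp002``, ...
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # start from the root split at time 0; lineages split at unit rate each,
    # so waiting times between events are Exp(k) for k active lineages
    t_now = 0.0
    birth: dict[int, float] = {}
    root = tree.seed_node
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        t_now += rng.expovariate(len(active))
        v = active.pop(rng.randrange(len(active)))
        v.edge.length = t_now - birth[id(v)]
        for _ in range(2):
            child = dendropy.Node()
            v.add_child(child)
            birth[id(child)] = t_now
            active.append(child)
    # let the final configuration persist for one more waiting time
    t_now += rng.expovariate(len(active))
    for v in active:
        v.edge.length = t_now - birth[id(v)]
    # label tips deterministically and rescale to unit root-to-tip height
    width = max(3, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"sp{i:0{width}d}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / t_now
    return tree


def gen_species_table(
    tree: dendropy.Tree, config: SimConfig, A: PhyloCorrelation | None = None
) -> pd.DataFrame:
    """Simulate a comparative trait table on ``tree``.

    Columns: ``species``, ``habitat`` ("forest"/"other"), ``covariate``
    (standard normal), ``call_function`` (one of seven categories), and
    ``response``.  Habitat is i.i.d. Bernoulli(p_forest) or, in
    ``phylo_threshold`` mode, obtained by thresholding a Brownian trait at its
    median so that habitat itself carries phylogenetic signal.
    """
    if A is None:
        A = phylo_correlation(tree)
    n = len(A.taxa)
    rng = np.random.default_rng(config.seed)
    L = np.linalg.cholesky(A.matrix + 1e-12 * np.eye(n))

    if config.habitat_mode == "iid":
        forest = rng.random(n) < config.p_forest
    else:
        z = L @ rng.standard_normal(n)
        forest = z <= np.quantile(z, config.p_forest)
    habitat = np.where(forest, "forest", "other")
    # forest = 0 (reference), other = 1
    h = (~forest).astype(float)

    covariate = rng.standard_normal(n)
    a = np.sqrt(config.sigma2_a) * (L @ rng.standard_normal(n)) if config.sigma2_a > 0 else 0.0
    groups = rng.integers(0, len(CALL_FUNCTIONS), size=n)
    u_levels = (
        np.sqrt(config.sigma2_u) * rng.standard_normal(len(CALL_FUNCTIONS))
        if config.sigma2_u > 0
        else np.zeros(len(CALL_FUNCTIONS))
    )
    e = np.sqrt(config.sigma2_e) * rng.standard_normal(n)

    y = (
        config.beta0
        + config.beta_habitat * h
        + config.beta_covariate * covariate
        + a
        + u_levels[groups]
        + e
    )
    return pd.DataFrame(
        {
            "species": list(A.taxa),
            "habitat": habitat,
            "covariate": covariate,
            "call_function": [CALL_FUNCTIONS[g] for g in groups],
            "response": y,
        }
    )


def gen_audiogram(
    peak_khz: float,
    floor_db: float = 10.0,
    curvature_db_per_octave2: float = 4.0,
    grid_khz=DEFAULT_AUDIOGRAM_GRID,
    seed: int = 0,
    noise_db: float = 0.0,
    species: str = "synthetic",
) -> Audiogram:
    """U-shaped audiogram, quadratic in octaves from the peak frequency.

    threshold(f) = floor + curvature * log2(f / peak)^2 + N(0, noise^2).
    With no noise the minimum sits exactly at ``peak_khz`` (when it is on the
    grid), and larger curvature gives a narrower sensitive band.
    """
    grid = np.asarray(list(grid_khz), dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid frequencies must be positive")
    if not (grid.min() <= peak_khz <= grid.max()):
        raise ValueError("peak frequency must lie within the grid span")
    rng = np.random.default_rng(seed)
    t = floor_db + curvature_db_per_octave2 * np.log2(grid / peak_khz) ** 2
    if noise_db > 0:
        t = t + rng.normal(0.0, noise_db, size=grid.size)
    return Audiogram(
        species=species, frequencies_khz=np.sort(grid), thresholds_db=t, method="synthetic"
    )


@dataclass(frozen=True)
class SyntheticCallSpec:
    """Parameters of a synthetic harmonic source-filter call."""

    f0_hz: float = 500.0
    formant_freqs_hz: tuple[float, ...] = (2205.0, 6615.0, 11025.0, 15435.0, 19845.0)
    formant_bandwidths_hz: tuple[float, ...] = (600.0, 600.0, 600.0, 600.0, 600.0)
    source_slope_db_per_khz: float = -2.0
    duration_s: float = 1.0
    sample_rate_hz: int = 44_100

    def __post_init__(self) -> None:
        nyq = self.sample_rate_hz / 2
        if not (0 < self.f0_hz < nyq):
            raise ValueError("f0 must lie below the Nyquist frequency")
        if len(self.formant_freqs_hz) != len(self.formant_bandwidths_hz):
            raise ValueError("one bandwidth per formant required")
        if any(f <= 0 or f >= nyq for f in self.formant_freqs_hz):
            raise ValueError("formants must lie below the Nyquist frequency")
        if any(b <= 0 for b in self.formant_bandwidths_hz):
            raise ValueError("formant bandwidths must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


def _resonator_sos(f_hz: float, bw_hz: float, fs: int) -> np.ndarray:
    """Impulse-invariant two-pole resonator section with unity DC gain."""
    r = np.exp(-np.pi * bw_hz / fs)
    theta = 2 * np.pi * f_hz / fs
    a1 = -2 * r * np.cos(theta)
    a2 = r * r
    b0 = 1 + a1 + a2  # unity gain at DC
    return np.array([b0, 0.0, 0.0, 1.0, a1, a2])


def formant_gain(spec: SyntheticCallSpec, freqs_hz: np.ndarray) -> np.ndarray:
    """|H(f)| of the cascaded formant filter (oracle for spectral maxima)."""
    w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) / spec.sample_rate_hz
    g = np.ones_like(w)
    for f, b in zip(spec.formant_freqs_hz, spec.formant_bandwidths_hz):
        sos = _resonator_sos(f, b, spec.sample_rate_hz)
        z = np.exp(-1j * w)
        num = sos[0]
        den = 1 + sos[4] * z + sos[5] * z**2
        g = g * np.abs(num / den)
    return g


def gen_call(spec: SyntheticCallSpec, seed: int = 0) -> CallWave:
    """Synthesize one call: harmonic stack through formant resonators.

    Harmonics at k*f0 up to Nyquist start with amplitude
    10^(source_slope * k*f0/1000 / 20) — a straight source spectrum of
    ``source_slope_db_per_khz`` in dB amplitude against kHz — with random
    phases drawn from the seed.  The stack is filtered through the cascaded
    second-order resonator sections and peak-normalized to 0.9 full scale.
    """
    nyq = spec.sample_rate_hz / 2
    if spec.f0_hz >= nyq:
        raise ValueError("f0 at or above Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    k_max = int(np.floor((nyq - 1e-9) / spec.f0_hz))
    x = np.zeros(n)
    for k in range(1, k_max + 1):
        f = k * spec.f0_hz
        amp = 10 ** (spec.source_slope_db_per_khz * (f / 1000.0) / 20.0)
        phase = rng.uniform(0, 2 * np.pi)
        x += amp * np.sin(2 * np.pi * f * t + phase)
    if spec.formant_freqs_hz:
        sos = np.vstack(
            [
                _resonator_sos(f, b, spec.sample_rate_hz)
                for f, b in zip(spec.formant_freqs_hz, spec.formant_bandwidths_hz)
            ]
        )
        x = signal.sosfilt(sos, x)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("synthesized call is silent")
    x = 0.9 * x / peak
    return CallWave(
        samples=x,
        sample_rate_hz=spec.sample_rate_hz,
        source_id=f"synthetic_seed{seed}",
        species="synthetic",
    )


def tree_to_newick(tree: dendropy.Tree) -> str:
    out = StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue()
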