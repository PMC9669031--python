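"""Core data containers shared across the pipeline.

The universal currency is the :class:`EmgEnvelopeSet`: a nonnegative
``muscles x (strides * 200)`` matrix of stride-normalized EMG envelopes,
with channel labels and the nominal stride duration ``T`` (seconds) that
anchors the cycle-based frequency axis (1/T units).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: samples per time-normalized stride cycle
CYCLE_SAMPLES = 200

#: default bilateral channel order: ipsilateral then contralateral leg
DEFAULT_MUSCLES = ("BF", "RF", "LG", "TA", "BF_CL", "RF_CL", "LG_CL", "TA_CL")


@dataclass
class EmgEnvelopeSet:
    """Stride-normalized EMG envelopes concatenated over strides.

    Parameters
    ----------
    data : ndarray, shape (n_muscles, n_strides * 200)
        Nonnegative envelope amplitudes.
    muscle_labels : tuple of str
        Channel names; the suffix ``_CL`` marks the contralateral leg.
    stride_duration : float
        Nominal (mean) stride duration T in seconds.
    source : {"experimental", "simulated", "shuffled"}
    normalized : bool
        True once per-cycle minimum subtraction and global-max scaling
        have been applied.
    """

    data: np.ndarray
    muscle_labels: tuple = DEFAULT_MUSCLES
    stride_duration: float = 3.2
    source: str = "experimental"
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (muscles x samples)")
        if self.data.shape[1] % CYCLE_SAMPLES:
            raise ValueError(
                f"sample count {self.data.shape[1]} not divisible by {CYCLE_SAMPLES}"
            )
        if np.any(self.data < 0):
            raise ValueError("envelope data must be nonnegative")
        self.muscle_labels = tuple(self.muscle_labels)
        if len(self.muscle_labels) != self.data.shape[0]:
            raise ValueError("muscle_labels length does not match data rows")

    @property
    def n_muscles(self) -> int:
        return self.data.shape[0]

    @property
    def n_strides(self) -> int:
        return self.data.shape[1] // CYCLE_SAMPLES

    def strides(self) -> np.ndarray:
        """Return data reshaped to (n_strides, n_muscles, 200)."""
        return (
            self.data.reshape(self.n_muscles, self.n_strides, CYCLE_SAMPLES)
            .transpose(1, 0, 2)
        )

    def copy_with(self, data: np.ndarray, **kw) -> "EmgEnvelopeSet":
        args = dict(
            muscle_labels=self.muscle_labels,
            stride_duration=self.stride_duration,
            source=self.source,
            normalized=self.normalized,
        )
        args.update(kw)
        return EmgEnvelopeSet(data, **args)


@dataclass
class GroundTruthModules:
    """Known modular structure used to generate synthetic envelopes."""

    n_modules: int
    synergies: np.ndarray  # (N, n_muscles), nonnegative
    patterns: np.ndarray  # (N, 200) one cycle, nonnegative
    jitter_mode: str = "none"  # none | timing | amplitude
    seed: int | None = None

    @property
    def n_muscles(self) -> int:
        return self.synergies.shape[1]


@dataclass
class SimulatedDataset:
    """Noiseless/noisy envelope pair from one simulation run."""

    noiseless: EmgEnvelopeSet
    noisy: EmgEnvelopeSet
    eta: float
    fidelity_r2: float
    modules: GroundTruthModules | None = None


@dataclass
class DecompositionResult:
    """Output of one factorization (one model, one algorithm, one N).

    ``synergies`` is (N, n_muscles) for spatial/space-by-time models and
    (n_strides, N, n_muscles) for the temporal model; ``patterns`` is
    (N, 200) when stride-invariant and (n_strides, N, 200) for the
    spatial model.  ``activation_coeffs`` (space-by-time only) is
    (n_strides, N, N) with entry [s, i, j] coupling pattern i to synergy j.
    """

    model: str
    algorithm: str
    n_modules: int
    synergies: np.ndarray
    patterns: np.ndarray
    vaf: float
    residuals: np.ndarray
    activation_coeffs: np.ndarray | None = None
    reconstruction: np.ndarray | None = None
    sorted: bool = False


@dataclass
class ConsistencyCurve:
    """Consistency values over N = 1..n_max with slope-based selection."""

    measure: str
    values: np.ndarray  # consistency at N = 1..n_max
    slopes: np.ndarray  # slope at N = 1..n_max-1
    selected_n: int
    fallback_used: bool = False
    vaf_values: np.ndarray | None = None


@dataclass
class SpectralPeak:
    center: float  # 1/T units
    power: float  # log-power above aperiodic
    bandwidth: float  # Gaussian sigma, 1/T units


@dataclass
class SpectralFit:
    """Parameterization of one muscle's PSD into periodic and aperiodic parts."""

    offset: float  # b, natural-log power
    knee: float  # k
    exponent: float  # chi
    peaks: list = field(default_factory=list)
    r_squared: float = np.nan
    spectral_entropy: float = np.nan
    corrected_defined: bool = True

    @property
    def corrected_offset(self) -> float:
        """b* = b - ln(k); undefined (nan) when k is at or below zero."""
        if not self.corrected_defined:
            return np.nan
        return self.offset - np.log(self.knee)

    @property
    def corrected_knee(self) -> float:
        """k* = k**(1/chi), the bend frequency of the aperiodic fit."""
        if not self.corrected_defined:
            return np.nan
        return self.knee ** (1.0 / self.exponent)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass
class ClusterResult:
    entity: str  # "synergies" | "patterns"
    k_values: np.ndarray
    ch_index: np.ndarray
    optimal_k: int
    assignments: np.ndarray
    silhouettes: np.ndarray
    retained: np.ndarray  # boolean mask, silhouette > threshold
    centroids: np.ndarray

    @property
    def retained_fraction(self) -> float:
        return float(np.mean(self.retained))


@dataclass
class CoherenceNetworkSet:
    """Pairwise magnitude-squared coherence and its modular decomposition."""

    pairs: list  # list of (label_a, label_b)
    frequencies: np.ndarray
    coherence: np.ndarray  # (n_pairs, n_freqs) in [0, 1]
    components: np.ndarray | None = None  # (F, n_freqs)
    loadings: np.ndarray | None = None  # (F, n_pairs)
    networks: np.ndarray | None = None  # (F, 8, 8) symmetric, zero diagonal
    vaf_curve: np.ndarray | None = None
    muscle_labels: tuple = DEFAULT_MUSCLES
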