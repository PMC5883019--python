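"""TCSPC data model and the multi-exponential forward (reconvolution) model.

Time-correlated single photon counting (TCSPC) builds a histogram of photon
arrival times relative to the laser pulse.  The fluorescence of a mixture of
emitters decays as a sum of exponentials; what the instrument records is that
sum convolved with the instrument response function (IRF) plus a constant
background of uncorrelated counts:

    I(t) = IRF * [ sum_i alpha_i exp(-t / tau_i) ] + C

``evaluate_model`` implements this forward model on a discrete time axis;
``mean_lifetime`` computes the amplitude-weighted mean lifetime
tau_m = sum_i alpha_i tau_i; ``integrate_intensity`` and ``snr`` provide the
intensity and quality-gate summaries used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TimeAxis",
    "DecayHistogram",
    "IRF",
    "ExpComponent",
    "MultiExpModel",
    "evaluate_model",
    "mean_lifetime",
    "integrate_intensity",
    "snr",
]

#: Default number of temporal bins per decay curve.
DEFAULT_N_BINS = 256
#: Default measurement window in ns (one 80 MHz Ti:sapphire repetition period).
DEFAULT_WINDOW_NS = 12.5


@dataclass(frozen=True)
class TimeAxis:
    """Discrete time axis of a TCSPC histogram.

    Parameters
    ----------
    n_bins
        Number of temporal bins (>= 8).
    bin_width
        Width of one bin in ns.
    """

    n_bins: int = DEFAULT_N_BINS
    bin_width: float = DEFAULT_WINDOW_NS / DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError(f"n_bins must be >= 8, got {self.n_bins}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")

    @property
    def window(self) -> float:
        """Total measurement window in ns."""
        return self.n_bins * self.bin_width

    @property
    def times(self) -> np.ndarray:
        """Bin start times in ns (t = 0 at the first bin)."""
        return np.arange(self.n_bins) * self.bin_width

    @classmethod
    def from_window(cls, window_ns: float, n_bins: int = DEFAULT_N_BINS) -> "TimeAxis":
        return cls(n_bins=n_bins, bin_width=window_ns / n_bins)


@dataclass
class DecayHistogram:
    """Photon counts per temporal bin.

    ``counts`` must be nonnegative and match ``axis.n_bins``.
    """

    counts: np.ndarray
    axis: TimeAxis
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) != self.axis.n_bins:
            raise ValueError(
                f"counts length {self.counts.shape} does not match axis n_bins "
                f"{self.axis.n_bins}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class IRF:
    """Instrument response function histogram.

    The stored values may be raw counts or a density; they are normalized to
    unit sum before convolution.  ``fwhm_ps`` is informational.
    """

    counts: np.ndarray
    axis: TimeAxis
    fwhm_ps: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) != self.axis.n_bins:
            raise ValueError("IRF length does not match axis n_bins")
        if np.any(self.counts < 0):
            raise ValueError("IRF values must be nonnegative")
        if self.counts.sum() <= 0:
            raise ValueError("IRF must have positive total")

    def normalized(self) -> np.ndarray:
        """IRF as a unit-sum probability vector."""
        return self.counts / self.counts.sum()

    @classmethod
    def delta(cls, axis: TimeAxis, peak_bin: int = 0) -> "IRF":
        """Discrete delta IRF (ideal instrument), peaked at ``peak_bin``."""
        counts = np.zeros(axis.n_bins)
        counts[peak_bin] = 1.0
        return cls(counts=counts, axis=axis, fwhm_ps=0.0)


@dataclass
class ExpComponent:
    """One exponential decay component: fractional amplitude and lifetime (ns)."""

    alpha: float
    tau: float
    fixed_tau: bool = False
    fixed_alpha: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass
class MultiExpModel:
    """Sum-of-exponentials decay model with constant background.

    ``components`` hold fractional amplitudes (normalized to unit sum) and
    lifetimes in ns, sorted ascending by lifetime.  ``background`` is the
    constant C in counts per bin.  ``shift`` translates the IRF relative to
    the decay by a (possibly fractional) number of bins.
    """

    components: list[ExpComponent]
    background: float = 0.0
    shift: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 3:
            raise ValueError("model must have 1-3 components")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        total = sum(c.alpha for c in self.components)
        if total <= 0:
            raise ValueError("amplitudes must have positive sum")
        # normalize amplitudes to unit sum, keep lifetimes sorted ascending
        self.components = sorted(
            (replace(c, alpha=c.alpha / total) for c in self.components),
            key=lambda c: c.tau,
        )

    @property
    def alphas(self) -> np.ndarray:
        return np.array([c.alpha for c in self.components])

    @property
    def taus(self) -> np.ndarray:
        return np.array([c.tau for c in self.components])

    @classmethod
    def from_arrays(
        cls,
        alphas,
        taus,
        background: float = 0.0,
        shift: float = 0.0,
    ) -> "MultiExpModel":
        alphas = np.asarray(alphas, dtype=float)
        if alphas.sum() <= 0:
            raise ValueError("amplitudes must have positive sum")
        alphas = alphas / alphas.sum()
        comps = [ExpComponent(alpha=a, tau=t) for a, t in zip(alphas, taus, strict=True)]
        return cls(components=comps, background=background, shift=shift)


def _shift_irf(irf_norm: np.ndarray, shift: float) -> np.ndarray:
    """Translate the IRF by a fractional number of bins via linear interpolation."""
    if shift == 0.0:
        return irf_norm
    n = len(irf_norm)
    x = np.arange(n, dtype=float)
    return np.interp(x - shift, x, irf_norm, left=0.0, right=0.0)


def evaluate_model(
    model: MultiExpModel,
    irf: IRF,
    axis: TimeAxis,
    amplitude_scale: float,
    periodic: bool = False,
) -> np.ndarray:
    """Expected counts per bin for a multi-exponential reconvolution model.

    The normalized (and optionally shifted) IRF is convolved with
    ``sum_i alpha_i exp(-t/tau_i)``, the result scaled so the decay term sums
    to ``amplitude_scale`` photons over the window, then the constant
    background C is added to every bin.

    Parameters
    ----------
    model
        Decay model (amplitudes, lifetimes, background, IRF shift).
    irf
        Instrument response on the same axis.
    axis
        Time axis; must match the IRF.
    amplitude_scale
        Expected total signal photons (excluding background).
    periodic
        If True, convolve circularly over the window ("incomplete decay"
        mode for lifetimes comparable to the repetition period); default is
        linear convolution truncated at the window.
    """
    if irf.axis.n_bins != axis.n_bins:
        raise ValueError("IRF and axis bin counts differ")
    if amplitude_scale < 0:
        raise ValueError("amplitude_scale must be >= 0")
    t = axis.times
    decay = np.zeros(axis.n_bins)
    for c in model.components:
        decay += c.alpha * np.exp(-t / c.tau)
    kernel = _shift_irf(irf.normalized(), model.shift)
    if periodic:
        conv = np.real(np.fft.ifft(np.fft.fft(kernel) * np.fft.fft(decay)))
        conv = np.clip(conv, 0.0, None)
    else:
        conv = np.convolve(kernel, decay)[: axis.n_bins]
    total = conv.sum()
    if total > 0:
        conv = conv * (amplitude_scale / total)
    return conv + model.background


def mean_lifetime(model: MultiExpModel) -> float:
    """Amplitude-weighted mean lifetime tau_m = sum_i alpha_i tau_i (ns).

    Amplitudes must already be normalized to unit sum (the ``MultiExpModel``
    constructor guarantees this).
    """
    alphas = model.alphas
    if not np.isclose(alphas.sum(), 1.0, atol=1e-9):
        raise ValueError("amplitudes must be normalized to unit sum")
    return float(np.dot(alphas, model.taus))


def integrate_intensity(hist: DecayHistogram) -> float:
    """Total photons: the decay curve integrated (summed) over all bins."""
    return hist.total


def snr(hist: DecayHistogram) -> float:
    """Signal-to-noise proxy: the peak (maximum) bin count.

    Used as the quality-gate statistic for fitting — whole-solution decays
    are gated at 3000 peak counts, 3x3-binned cellular decays at 15.
    """
    return float(np.max(hist.counts))
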