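"""Spike detection, ISI histograms, and the three-part ISI decomposition.

The ISI distribution of the stochastic Hodgkin-Huxley neuron resolves
into three parts:

* an initial narrow peak at the limit-cycle period — its mass is the
  probability that a spike is immediately followed by another spike
  ("run probability");
* one or more damped bumps spaced at the subthreshold orbital period
  2*pi/omega of the linearized dynamics (~12 ms), from firings after a
  small number of subthreshold orbits;
* an exponential tail, the escape-time distribution from the
  conditionally stationary subthreshold state; its rate is the "tail
  exponent".

The feature extractor locates a run cutoff ``t_cut`` (trough between the
main peak and the first bump) and a tail start ``t0`` (beyond the bump
region) from the data, then measures the run probability as the fraction
of ISIs below ``t_cut`` and the tail exponent by maximum likelihood on
the excesses above ``t0``.  Both cutoffs are reported with every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SpikeTrain",
    "ISIHistogram",
    "ISIFeatures",
    "detect_spikes",
    "compute_isis",
    "make_histogram",
    "fit_tail_exponent",
    "run_probability",
    "detect_bumps",
    "extract_features",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) with the detection threshold used."""

    times: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("spike times must be non-negative and strictly increasing")


@dataclass(frozen=True)
class ISIHistogram:
    """Normalized equal-width histogram: masses sum to 1."""

    edges: np.ndarray
    masses: np.ndarray
    n_total: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def counts(self) -> np.ndarray:
        return np.rint(self.masses * self.n_total)


@dataclass
class ISIFeatures:
    """The three-part decomposition of an ISI sample."""

    tail_exponent: float
    tail_se: float
    run_probability: float
    peak_location: float
    peak_mass: float
    bump_locations: np.ndarray
    bump_spacing: float | None
    t_cut: float
    t0: float
    n_isi: int
    n_tail: int


def detect_spikes(t, v, threshold: float = 0.0) -> np.ndarray:
    """Spike times from a sampled voltage trace.

    A spike is recorded at each downward crossing of ``threshold``
    (sample above followed by sample at or below), linearly interpolated
    between the two samples.  ``threshold`` must sit well above the
    subthreshold oscillation range (default 0 mV; rest is near -65 and
    spikes overshoot +40).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape:
        raise ValueError("time and voltage arrays must have the same shape")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    idx = np.nonzero((v[:-1] > threshold) & (v[1:] <= threshold))[0]
    if len(idx) == 0:
        return np.empty(0)
    frac = (v[idx] - threshold) / (v[idx] - v[idx + 1])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def compute_isis(spikes) -> np.ndarray:
    """Successive differences of a spike-time sequence (empty if < 2 spikes)."""
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, dtype=float)
    if len(times) < 2:
        return np.empty(0)
    return np.diff(times)


def make_histogram(isis, bin_width: float = 1.0) -> ISIHistogram:
    """Equal-width histogram from 0 to the maximum ISI, bars summing to 1."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) == 0:
        raise ValueError("cannot histogram an empty ISI sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(int(np.ceil(isis.max() / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(isis, bins=edges)
    return ISIHistogram(edges=edges, masses=counts / len(isis), n_total=len(isis))


def fit_tail_exponent(isis, t0: float, min_tail: int = 50) -> tuple[float, float]:
    """Maximum-likelihood exponential rate of the ISI tail beyond ``t0``.

    The excesses (ISI - t0 | ISI > t0) of an exponential tail are again
    exponential, so the MLE is 1/mean(excess) with standard error
    rate/sqrt(count).  Bin-free, and invariant to shifting the whole
    sample and ``t0`` together.
    """
    isis = np.asarray(isis, dtype=float)
    excess = isis[isis > t0] - t0
    if len(excess) < min_tail:
        raise ValueError(
            f"only {len(excess)} ISIs beyond t0={t0:.3g} (need >= {min_tail})"
        )
    rate = 1.0 / excess.mean()
    return float(rate), float(rate / np.sqrt(len(excess)))


def run_probability(isis, t_cut: float) -> float:
    """Fraction of ISIs below ``t_cut``: the probability that a spike is
    immediately followed by another spike."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) == 0:
        raise ValueError("empty ISI sample")
    return float(np.mean(isis < t_cut))


def _smooth_log_masses(hist: ISIHistogram, window: int) -> np.ndarray:
    lm = np.log(np.maximum(hist.masses, 0.5 / max(hist.n_total, 1)))
    if window <= 1:
        return lm
    kernel = np.ones(window) / window
    return np.convolve(lm, kernel, mode="same")


def detect_bumps(
    hist: ISIHistogram,
    smooth_window: int = 3,
    prominence: float = 0.35,
    min_count: int = 20,
) -> tuple[np.ndarray, float | None]:
    """Local maxima of the smoothed log-histogram after the main peak.

    Only bins with at least ``min_count`` observations are searched, so
    Poisson noise in the sparse far tail cannot masquerade as bumps
    (``prominence`` is in natural-log units of mass).  Returns the bump
    locations (bin centers, ms) and the mean spacing of consecutive
    bumps (None with fewer than two bumps).  An empty result is valid: a
    pure exponential histogram has no bumps.
    """
    lm = _smooth_log_masses(hist, smooth_window)
    peak_idx = int(np.argmax(hist.masses))
    counts = hist.masses * hist.n_total
    # search up to the last well-populated bin (the trough right after the
    # main peak may be nearly empty, so don't stop at the first sparse bin)
    populated = np.nonzero(counts >= min_count)[0]
    hi = populated[-1] if len(populated) else peak_idx
    region = lm[peak_idx + 1 : hi + 1]
    if len(region) < 3:
        return np.empty(0), None
    pk, _props = find_peaks(region, prominence=prominence)
    pk = pk[counts[peak_idx + 1 + pk] >= min_count]  # bumps must carry data
    locs = hist.centers[peak_idx + 1 + pk]
    spacing = float(np.mean(np.diff(locs))) if len(locs) >= 2 else None
    return locs, spacing


def _peak_half_width(hist: ISIHistogram, peak_idx: int) -> float:
    half = hist.masses[peak_idx] / 2.0
    j = peak_idx
    while j + 1 < len(hist.masses) and hist.masses[j + 1] >= half:
        j += 1
    return max((j - peak_idx + 1) * hist.bin_width, hist.bin_width)


def extract_features(
    isis,
    bin_width: float = 1.0,
    smooth_window: int = 3,
    prominence: float = 0.35,
    min_count: int = 20,
    min_tail: int = 50,
    min_n: int = 500,
    fallback_spacing: float = 12.0,
) -> ISIFeatures:
    """Full three-part decomposition of an ISI sample.

    ``t_cut`` is the trough of the smoothed log-histogram between the
    main peak and the first bump (fallback: peak + 2 x half-width);
    ``t0`` is the last bump plus one bump spacing (fallback: t_cut +
    2 x ``fallback_spacing``, the subthreshold orbital period from the
    linearization, ~12 ms, being the natural spacing scale).
    """
    isis = np.asarray(isis, dtype=float)
    if len(isis) < min_n:
        raise ValueError(f"need >= {min_n} ISIs for feature extraction, got {len(isis)}")
    hist = make_histogram(isis, bin_width)
    peak_idx = int(np.argmax(hist.masses))
    peak_loc = float(hist.centers[peak_idx])
    bump_locs, spacing = detect_bumps(hist, smooth_window, prominence, min_count)

    if len(bump_locs) > 0:
        first_bump_idx = int(np.searchsorted(hist.centers, bump_locs[0]))
        lm = _smooth_log_masses(hist, smooth_window)
        trough = peak_idx + 1 + int(np.argmin(lm[peak_idx + 1 : first_bump_idx + 1]))
        t_cut = float(hist.centers[trough])
    else:
        t_cut = peak_loc + 2.0 * _peak_half_width(hist, peak_idx)

    if len(bump_locs) >= 2:
        t0 = float(bump_locs[-1] + spacing)
    elif len(bump_locs) == 1:
        t0 = float(bump_locs[0] + fallback_spacing)
    else:
        t0 = t_cut + 2.0 * fallback_spacing

    rate, se = fit_tail_exponent(isis, t0, min_tail=min_tail)
    p_run = run_probability(isis, t_cut)
    return ISIFeatures(
        tail_exponent=rate,
        tail_se=se,
        run_probability=p_run,
        peak_location=peak_loc,
        peak_mass=p_run,  # mass under the initial peak == run probability
        bump_locations=bump_locs,
        bump_spacing=spacing,
        t_cut=t_cut,
        t0=t0,
        n_isi=len(isis),
        n_tail=int(np.sum(isis > t0)),
    )
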