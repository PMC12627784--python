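"""Single-molecule burst identification and corrected E/S analysis.

Photons from a confocal single-molecule experiment with alternating
donor/acceptor excitation arrive tagged by channel: donor emission after
donor excitation (DD), acceptor emission after donor excitation (DA) and
acceptor emission after acceptor excitation (AA).  Molecules diffusing
through the focus produce photon bursts, which an all-photon burst search
isolates by a sliding-window local count rate.  Per burst, the corrected
transfer efficiency and stoichiometry are

    E = I_A^D / (gamma I_D^D + I_A^D)
    S = (gamma I_D^D + I_A^D) / (gamma I_D^D + I_A^D + I_A^A)

where I_A^D has been corrected for donor leakage (alpha) and acceptor
direct excitation (delta), and gamma accounts for quantum-yield and
detection-efficiency differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CH_DD",
    "CH_DA",
    "CH_AA",
    "PhotonStream",
    "Burst",
    "CorrectionSet",
    "HistogramFit",
    "search_bursts",
    "estimate_background_rates",
    "burst_efficiency",
    "fit_populations",
]

# Channel codes: donor-after-donor, acceptor-after-donor, acceptor-after-acceptor.
CH_DD, CH_DA, CH_AA = 0, 1, 2

# E/S values outside this window (possible with shot noise after correction)
# are clipped before histogramming.
ES_CLIP = (-0.1, 1.1)


@dataclass
class PhotonStream:
    """Time-ordered photon arrivals (s) with per-photon channel codes."""

    times: np.ndarray
    channels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=np.int8)
        if self.times.shape != self.channels.shape:
            raise ValueError("times and channels must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("photon times must be nondecreasing")
        if self.times.size and not np.all(np.isin(self.channels, (CH_DD, CH_DA, CH_AA))):
            raise ValueError("unknown channel code")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class Burst:
    """One detected burst with background-corrected per-channel counts."""

    start: float
    stop: float
    n_photons: int
    i_dd: float
    i_da: float
    i_aa: float

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass(frozen=True)
class CorrectionSet:
    """Spectral correction factors for E/S computation.

    alpha: donor leakage into the acceptor channel; delta: acceptor direct
    excitation by the donor laser; gamma: detection/quantum-yield ratio.
    Defaults are the Alexa488/Alexa594 calibration used throughout.
    """

    alpha: float = 0.086
    delta: float = 0.046
    gamma: float = 0.323

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be nonnegative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def search_bursts(
    stream: PhotonStream,
    rate_threshold: int = 5,
    window_s: float = 1000e-6,
    min_photons: int = 50,
    background_rates=None,
) -> list[Burst]:
    """All-photon burst search with a sliding-window photon-count criterion.

    A photon qualifies when at least ``rate_threshold`` photons (itself
    included) fall inside a window of ``window_s`` centred on it.  Maximal
    runs of consecutive qualifying photons form candidate bursts — split
    additionally where successive qualifying photons are further apart than
    one window, since such photons share no window — and are retained when
    their total photon count reaches ``min_photons``.

    ``background_rates`` may be a (rate_dd, rate_da, rate_aa) tuple in Hz;
    when omitted it is estimated from the inter-burst photons.  The
    background expected in each channel over the burst duration is
    subtracted from the burst's raw counts (clipped at zero).
    """
    t = stream.times
    if t.size == 0:
        return []
    half = window_s / 2.0
    counts = np.searchsorted(t, t + half, side="right") - np.searchsorted(
        t, t - half, side="left"
    )
    qualify = counts >= rate_threshold

    runs = []
    for i0, i1 in _qualifying_runs(qualify):
        # break runs across time gaps wider than the window
        gaps = np.flatnonzero(np.diff(t[i0:i1]) > window_s) + i0 + 1
        bounds = [i0, *gaps.tolist(), i1]
        runs.extend(zip(bounds[:-1], bounds[1:]))
    kept = [(i0, i1) for i0, i1 in runs if i1 - i0 >= min_photons]

    if background_rates is None:
        background_rates = estimate_background_rates(stream, kept)
    bg = np.asarray(background_rates, dtype=float)

    bursts: list[Burst] = []
    for i0, i1 in kept:
        ch = stream.channels[i0:i1]
        dur = t[i1 - 1] - t[i0]
        raw = np.array(
            [np.sum(ch == CH_DD), np.sum(ch == CH_DA), np.sum(ch == CH_AA)], dtype=float
        )
        corr = np.clip(raw - bg * dur, 0.0, None)
        bursts.append(
            Burst(
                start=float(t[i0]),
                stop=float(t[i1 - 1]),
                n_photons=int(i1 - i0),
                i_dd=float(corr[0]),
                i_da=float(corr[1]),
                i_aa=float(corr[2]),
            )
        )
    return bursts


def _qualifying_runs(qualify: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal runs of True."""
    if not qualify.any():
        return []
    q = qualify.astype(np.int8)
    edges = np.diff(np.concatenate(([0], q, [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def estimate_background_rates(stream: PhotonStream, burst_ranges) -> np.ndarray:
    """Constant per-channel background rates (Hz) from inter-burst photons."""
    t = stream.times
    if t.size == 0:
        return np.zeros(3)
    in_burst = np.zeros(t.size, dtype=bool)
    burst_time = 0.0
    for i0, i1 in burst_ranges:
        in_burst[i0:i1] = True
        burst_time += t[i1 - 1] - t[i0]
    total_time = t[-1] - t[0]
    quiet_time = total_time - burst_time
    if quiet_time <= 0:
        return np.zeros(3)
    ch = stream.channels[~in_burst]
    return np.array(
        [np.sum(ch == CH_DD), np.sum(ch == CH_DA), np.sum(ch == CH_AA)], dtype=float
    ) / quiet_time


def burst_efficiency(burst: Burst, corr: CorrectionSet) -> tuple[float, float]:
    """Corrected (E, S) for one burst; returns (nan, nan) for undefined bursts.

    The acceptor-after-donor count is first corrected for donor leakage
    (alpha * I_D^D) and acceptor direct excitation (delta * I_A^A).  E and S
    are clipped to [-0.1, 1.1] to keep shot-noise excursions histogrammable.
    """
    i_da = burst.i_da - corr.alpha * burst.i_dd - corr.delta * burst.i_aa
    denom_e = corr.gamma * burst.i_dd + i_da
    denom_s = denom_e + burst.i_aa
    if denom_e <= 0 or denom_s <= 0:
        return (float("nan"), float("nan"))
    e = float(np.clip(i_da / denom_e, *ES_CLIP))
    s = float(np.clip(denom_e / denom_s, *ES_CLIP))
    return e, s


@dataclass
class HistogramFit:
    """Per-population summary of a 2D (E, S) Gaussian fit.

    ``means`` is (k, 2) with columns (E, S); ``widths`` holds per-population
    standard deviations along (E, S); ``fractions`` sums to 1.
    """

    means: np.ndarray
    widths: np.ndarray
    fractions: np.ndarray
    converged: bool = True
    boxes: list | None = field(default=None, repr=False)

    @property
    def mean_e(self) -> np.ndarray:
        return self.means[:, 0]


def fit_populations(
    e_values,
    s_values,
    n_components: int = 1,
    selection_boxes=None,
    seed: int = 0,
) -> HistogramFit:
    """Fit (E, S) burst coordinates with 2D Gaussian populations.

    Without ``selection_boxes`` a maximum-likelihood Gaussian mixture with
    ``n_components`` is fitted (diagonal covariances, seeded k-means init).
    With boxes — a list of (e_min, e_max, s_min, s_max) — each box is fitted
    independently with a single Gaussian, as in the nanocluster workflow
    where donor-only and FRET species are selected by hand; fractions are
    then burst fractions per box renormalised over the boxed bursts.
    """
    pts = np.column_stack(
        [np.asarray(e_values, dtype=float), np.asarray(s_values, dtype=float)]
    )
    pts = pts[np.all(np.isfinite(pts), axis=1)]

    if selection_boxes is not None:
        means, widths, counts = [], [], []
        for e0, e1, s0, s1 in selection_boxes:
            m = (
                (pts[:, 0] >= e0) & (pts[:, 0] <= e1)
                & (pts[:, 1] >= s0) & (pts[:, 1] <= s1)
            )
            sub = pts[m]
            if sub.shape[0] < 2:
                raise ValueError("selection box contains fewer than 2 bursts")
            means.append(sub.mean(axis=0))
            widths.append(sub.std(axis=0, ddof=1))
            counts.append(sub.shape[0])
        fr = np.asarray(counts, dtype=float)
        return HistogramFit(
            means=np.asarray(means),
            widths=np.asarray(widths),
            fractions=fr / fr.sum(),
            boxes=list(selection_boxes),
        )

    if pts.shape[0] < 50 * n_components:
        raise ValueError("need >= 50 bursts per fitted component")
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        random_state=seed,
        n_init=3,
        max_iter=500,
    ).fit(pts)
    if not gm.converged_:
        raise RuntimeError(
            f"2D Gaussian mixture did not converge (seed {seed}, k={n_components})"
        )
    order = np.argsort(gm.means_[:, 0])
    return HistogramFit(
        means=gm.means_[order],
        widths=np.sqrt(gm.covariances_[order]),
        fractions=gm.weights_[order],
    )
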