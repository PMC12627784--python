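"""Fluorescence correlation spectroscopy: correlation, diffusion fits, sizing.

The normalised intensity fluctuation autocorrelation

    G(tau) = <dI(t) dI(t+tau)> / <I>^2

of photons emitted from a 3D-Gaussian observation volume decays on the
diffusion timescale tau_D = w0^2 / 4D.  A single-component 3D diffusion
model

    G(tau) = (1/N) (1 + tau/tau_D)^-1 [1 + (tau/tau_D)(w0/wz)^2]^(-1/2)

yields the mean occupancy N and tau_D; the Stokes-Einstein relation converts
the diffusion coefficient into a hydrodynamic radius.  Repeated short
measurements give a distribution of diffusion coefficients whose bimodality
reveals coexisting monomers and multimolecular nanoclusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "CorrelationCurve",
    "DiffusionFit",
    "RepeatSeries",
    "autocorrelate",
    "multitau_correlate",
    "fit_diffusion",
    "diffusion_model",
    "stokes_einstein",
    "diffusion_coefficient",
    "repeat_distribution",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass
class CorrelationCurve:
    """Fluctuation autocorrelation G at lag times ``lags_ms`` (strictly increasing)."""

    lags_ms: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags_ms.shape != self.g.shape:
            raise ValueError("lags and G must have equal length")
        if np.any(np.diff(self.lags_ms) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("G must be finite")


def diffusion_model(tau_ms, n, tau_d_ms, structure_parameter):
    """Single-component 3D diffusion model G(tau)."""
    x = np.asarray(tau_ms, dtype=float) / tau_d_ms
    return (1.0 / n) / (1.0 + x) / np.sqrt(1.0 + x * structure_parameter**2)


def multitau_correlate(
    counts: np.ndarray,
    bin_width_s: float,
    n_per_level: int = 16,
    max_lag_s: float | None = None,
) -> CorrelationCurve:
    """Multi-tau autocorrelation of a binned intensity trace.

    Level 0 evaluates lags 1..m bins at the base width; each further level
    halves the time resolution by pairwise summing the trace and evaluates
    lags m/2+1..m, covering decades of lag time at logarithmic cost.  The
    estimator is the symmetrically normalised

        G(k) = <x_i x_{i+k}> / (<x_left><x_right>) - 1,

    identical to a direct correlator evaluated on the same coarsened traces.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2 * n_per_level:
        raise ValueError("trace too short for the requested correlator depth")
    lags, gs = [], []
    level = 0
    width = bin_width_s
    while True:
        ks = (
            range(1, n_per_level + 1) if level == 0
            else range(n_per_level // 2 + 1, n_per_level + 1)
        )
        done = False
        for k in ks:
            if k >= x.size:
                done = True
                break
            lag = k * width
            if max_lag_s is not None and lag > max_lag_s:
                done = True
                break
            lags.append(lag * 1e3)
            gs.append(_lag_estimate(x, k))
        if done:
            break
        # coarsen: pairwise sum, dropping a trailing odd bin
        n2 = (x.size // 2) * 2
        x = x[:n2:2] + x[1:n2:2]
        width *= 2.0
        level += 1
        if x.size < n_per_level + 1:
            break
    return CorrelationCurve(lags_ms=np.asarray(lags), g=np.asarray(gs))


def _lag_estimate(x: np.ndarray, k: int) -> float:
    left, right = x[: x.size - k], x[k:]
    ml, mr = left.mean(), right.mean()
    if ml == 0 or mr == 0:
        return 0.0
    return float(np.mean(left * right) / (ml * mr) - 1.0)


def autocorrelate(
    photon_times_s: np.ndarray,
    base_bin_s: float = 1e-6,
    n_per_level: int = 16,
    max_lag_s: float = 1.0,
) -> CorrelationCurve:
    """Multi-tau autocorrelation of a photon arrival-time stream.

    Photons are binned at ``base_bin_s`` and correlated with
    :func:`multitau_correlate`.  A trace shorter than ten times the maximum
    lag triggers an unreliable-tail warning.
    """
    t = np.asarray(photon_times_s, dtype=float)
    if t.size == 0:
        raise ValueError("empty photon stream")
    duration = t[-1] - t[0]
    if duration < 10.0 * max_lag_s:
        warnings.warn(
            f"trace duration {duration:.3g} s < 10 x max lag; correlation tail unreliable",
            RuntimeWarning,
        )
    n_bins = int(np.ceil(duration / base_bin_s)) + 1
    counts = np.bincount(
        np.minimum(((t - t[0]) / base_bin_s).astype(np.int64), n_bins - 1),
        minlength=n_bins,
    ).astype(float)
    return multitau_correlate(counts, base_bin_s, n_per_level, max_lag_s)


@dataclass
class DiffusionFit:
    """Single-component diffusion fit: occupancy N, diffusion time and geometry."""

    n: float
    tau_d_ms: float
    structure_parameter: float
    cov: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n <= 0 or self.tau_d_ms <= 0:
            raise ValueError("N and tau_D must be positive")

    def diffusion_coefficient(self, w0_um: float) -> float:
        """D (um^2/s) from tau_D given the lateral beam waist w0 (um)."""
        return diffusion_coefficient(self.tau_d_ms, w0_um)

    def hydrodynamic_radius(
        self, w0_um: float, temperature_k: float = 298.0, viscosity_pa_s: float = 0.00089
    ) -> float:
        return stokes_einstein(
            self.diffusion_coefficient(w0_um), temperature_k, viscosity_pa_s
        )


def diffusion_coefficient(tau_d_ms: float, w0_um: float) -> float:
    """D = w0^2 / (4 tau_D) in um^2/s."""
    return w0_um**2 / (4.0 * tau_d_ms * 1e-3)


def fit_diffusion(
    curve: CorrelationCurve,
    structure_parameter: float = 0.2,
    fit_structure: bool = False,
    p0: tuple | None = None,
) -> DiffusionFit:
    """Least-squares fit of the single-component 3D diffusion model.

    The structure parameter w0/wz defaults to the calibration value 0.2 and
    is fixed unless ``fit_structure`` is set.
    """
    lags, g = curve.lags_ms, curve.g
    if p0 is None:
        g0 = max(g.max(), 1e-6)
        half = g <= g0 / 2.0
        tau0 = float(lags[half][0]) if half.any() else float(lags[lags.size // 2])
        p0 = (1.0 / g0, tau0)
    try:
        if fit_structure:
            popt, pcov = optimize.curve_fit(
                diffusion_model, lags, g, p0=(*p0, structure_parameter),
                bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, 1.0]), maxfev=20000,
            )
            return DiffusionFit(n=float(popt[0]), tau_d_ms=float(popt[1]),
                                structure_parameter=float(popt[2]), cov=pcov)
        popt, pcov = optimize.curve_fit(
            lambda x, n, td: diffusion_model(x, n, td, structure_parameter),
            lags, g, p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        resid = "max |G| = %.3g" % np.max(np.abs(g))
        raise RuntimeError(f"diffusion fit did not converge ({resid})") from exc
    return DiffusionFit(n=float(popt[0]), tau_d_ms=float(popt[1]),
                        structure_parameter=structure_parameter, cov=pcov)


def stokes_einstein(d_um2_s: float, temperature_k: float, viscosity_pa_s: float) -> float:
    """Hydrodynamic radius (nm): r = k_B T / (6 pi eta D)."""
    if d_um2_s <= 0 or temperature_k <= 0 or viscosity_pa_s <= 0:
        raise ValueError("D, T and eta must all be positive")
    r_m = BOLTZMANN_J_PER_K * temperature_k / (
        6.0 * np.pi * viscosity_pa_s * d_um2_s * 1e-12
    )
    return r_m * 1e9


@dataclass
class RepeatSeries:
    """Per-window diffusion fits from repeated short acquisitions."""

    fits: list
    d_um2_s: np.ndarray
    n_failed: int

    def histogram(self, bins=20):
        return np.histogram(self.d_um2_s, bins=bins)


def repeat_distribution(
    photon_times_s: np.ndarray,
    window_s: float = 10.0,
    n_windows: int = 120,
    w0_um: float = 0.3,
    base_bin_s: float = 1e-6,
    structure_parameter: float = 0.2,
    max_lag_s: float | None = None,
) -> RepeatSeries:
    """Window-by-window diffusion fits for the repeat-measurement distribution.

    The stream is cut into ``n_windows`` consecutive windows of ``window_s``;
    each is correlated and fitted independently.  Windows whose fit fails are
    excluded and counted.  The distribution of mean diffusion coefficients is
    the nanocluster detection readout: a slow mode appearing alongside the
    monomer mode marks multimolecular assemblies.
    """
    t = np.asarray(photon_times_s, dtype=float)
    if max_lag_s is None:
        max_lag_s = window_s / 20.0
    t0 = t[0] if t.size else 0.0
    fits, ds, failed = [], [], 0
    for i in range(n_windows):
        sel = t[(t >= t0 + i * window_s) & (t < t0 + (i + 1) * window_s)]
        if sel.size < 100:
            failed += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                curve = autocorrelate(sel, base_bin_s=base_bin_s, max_lag_s=max_lag_s)
            fit = fit_diffusion(curve, structure_parameter=structure_parameter)
        except (RuntimeError, ValueError):
            failed += 1
            continue
        fits.append(fit)
        ds.append(fit.diffusion_coefficient(w0_um))
    return RepeatSeries(fits=fits, d_um2_s=np.asarray(ds), n_failed=failed)
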