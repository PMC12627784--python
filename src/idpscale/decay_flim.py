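"""Time-resolved donor decay modelling, MLE distance extraction and phasor analysis.

The donor fluorescence decay measured over one laser period T is modelled as
three additively mixed populations convolved with the instrument response
function (IRF):

    I(t) = { A_D exp(-t/tau_D)
           + A_FRET Int rho(r) exp(-(t/tau_D)[1 + (R0/r)^6]) dr
           + A_bg Sum_i alpha_i exp(-t/tau_bg_i) } (x) IRF,

with A_D + A_FRET + A_bg = 1 (amplitude fractions at t = 0) and rho(r) the
Gaussian-chain distance distribution.  Fitting the decay by Poisson maximum
likelihood yields the root-mean-square inter-dye distance R_E; global fits
across labelling variants share the scaling-law parameters (rho0, nu) with
R_E(N_res) = rho0 * N_res^nu.  Phasor coordinates (g, s) at the laser
repetition frequency provide a model-free representation of each decay,
calibrated so that the IRF maps to the zero-lifetime point (1, 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from idpscale.polymer_fret import DyePair, GaussianChainModel, pr_density

__all__ = [
    "DecayHistogram",
    "PolarizationSetup",
    "BackgroundModel",
    "DecayModel",
    "PhasorPoint",
    "combine_polarizations",
    "model_decay",
    "fit_background",
    "fit_decay_mle",
    "DecayFitResult",
    "postbleach_fit",
    "PostbleachResult",
    "bootstrap_global_nu",
    "GlobalNuResult",
    "phasor_transform",
    "phasor_outlier_filter",
]

_LOGEPS = 1e-300


@dataclass
class DecayHistogram:
    """Photon counts on a uniform time grid covering one laser period.

    ``bin_times`` are bin centres (ns) at (k + 1/2) * dt for k = 0..n-1 with
    n * dt = ``period_ns``.  ``counts`` may be float (expected counts, IRF)
    or integer (measured photons).
    """

    bin_times: np.ndarray
    counts: np.ndarray
    period_ns: float
    polarization: str = "combined"

    def __post_init__(self) -> None:
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_times.shape != self.counts.shape or self.bin_times.ndim != 1:
            raise ValueError("bin_times and counts must be equal-length 1D arrays")
        dt = np.diff(self.bin_times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("bin grid must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def dt(self) -> float:
        return self.period_ns / self.bin_times.size

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("cannot normalise a histogram with zero total counts")
        return self.counts / total

    @classmethod
    def on_grid(cls, n_bins: int, period_ns: float, counts=None, **kw) -> "DecayHistogram":
        dt = period_ns / n_bins
        t = (np.arange(n_bins) + 0.5) * dt
        c = np.zeros(n_bins) if counts is None else counts
        return cls(bin_times=t, counts=c, period_ns=period_ns, **kw)

    @classmethod
    def delta_irf(cls, n_bins: int, period_ns: float, bin_index: int = 0) -> "DecayHistogram":
        """Idealised single-bin IRF (useful as a zero-width reference)."""
        c = np.zeros(n_bins)
        c[bin_index] = 1.0
        return cls.on_grid(n_bins, period_ns, counts=c)


@dataclass(frozen=True)
class PolarizationSetup:
    """High-NA polarisation mixing factors L1, L2 and detection G factor (eta_perp/eta_par)."""

    l1: float = 0.16
    l2: float = 0.0
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.g_factor <= 0:
            raise ValueError("G factor must be positive")


def combine_polarizations(
    par: DecayHistogram, perp: DecayHistogram, setup: PolarizationSetup
) -> DecayHistogram:
    """Isotropic total intensity I(t) = (1-3L2) G I_par(t) + (2-3L1) I_perp(t)."""
    if par.bin_times.shape != perp.bin_times.shape or not np.allclose(
        par.bin_times, perp.bin_times
    ):
        raise ValueError("parallel and perpendicular histograms must share one bin grid")
    counts = (1.0 - 3.0 * setup.l2) * setup.g_factor * par.counts + (
        2.0 - 3.0 * setup.l1
    ) * perp.counts
    return DecayHistogram(
        bin_times=par.bin_times.copy(),
        counts=counts,
        period_ns=par.period_ns,
        polarization="combined",
    )


@dataclass(frozen=True)
class BackgroundModel:
    """Multi-exponential background: amplitude fractions alpha_i (sum 1) and lifetimes (ns)."""

    amplitudes: tuple
    lifetimes: tuple

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        tau = np.asarray(self.lifetimes, dtype=float)
        if a.shape != tau.shape:
            raise ValueError("amplitudes and lifetimes must have equal length")
        if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-6:
            raise ValueError("background amplitudes must be nonnegative and sum to 1")
        if np.any(tau <= 0):
            raise ValueError("background lifetimes must be positive")

    def intensity(self, t: np.ndarray, period_ns: float) -> np.ndarray:
        out = np.zeros_like(t)
        for a, tau in zip(self.amplitudes, self.lifetimes):
            out += a * _periodic_exp(t, tau, period_ns)
        return out


def _periodic_exp(t: np.ndarray, tau: float, period: float) -> np.ndarray:
    """exp(-t/tau) wrapped over all preceding excitation periods; value 1 at t=0."""
    return np.exp(-t / tau) / (1.0 - np.exp(-period / tau))


def _circular_convolve(signal: np.ndarray, irf_norm: np.ndarray) -> np.ndarray:
    out = np.fft.irfft(np.fft.rfft(signal) * np.fft.rfft(irf_norm), n=signal.size)
    # Counts are nonnegative; clip FFT round-off.
    return np.clip(out, 0.0, None)


@dataclass
class DecayModel:
    """Forward model of the three-population donor decay.

    Amplitude fractions refer to t = 0 intensities before IRF convolution.
    ``chain`` may be None only when a_fret == 0.
    """

    pair: DyePair
    tau_d: float
    a_d: float
    a_fret: float
    a_bg: float
    chain: GaussianChainModel | None
    background: BackgroundModel | None
    irf: DecayHistogram
    r_grid_size: int = 400

    def __post_init__(self) -> None:
        s = self.a_d + self.a_fret + self.a_bg
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"amplitude fractions must sum to 1, got {s}")
        if min(self.a_d, self.a_fret, self.a_bg) < -1e-12:
            raise ValueError("amplitude fractions must lie in [0, 1]")
        if self.a_fret > 0 and self.chain is None:
            raise ValueError("a FRET component requires a chain model")
        if self.a_bg > 0 and self.background is None:
            raise ValueError("a background component requires a background model")

    @property
    def period_ns(self) -> float:
        return self.irf.period_ns

    def with_re(self, re_nm: float) -> "DecayModel":
        return replace(self, chain=GaussianChainModel.from_re(re_nm))


def _fret_weights(chain: GaussianChainModel, pair: DyePair, tau_d: float, n_nodes: int):
    """Discretised distance distribution: log-spaced r-nodes, P(r)dr weights, lifetimes.

    Nodes span [0.05, 8] x R_E; weights are trapezoid masses of P(r)
    renormalised to 1 so the FRET component has unit t=0 amplitude.
    """
    re = chain.root_mean_sq
    r = np.geomspace(0.05 * re, 8.0 * re, n_nodes)
    p = pr_density(r, chain)
    w = np.zeros_like(r)
    dr = np.diff(r)
    w[:-1] += 0.5 * p[:-1] * dr
    w[1:] += 0.5 * p[1:] * dr
    w /= w.sum()
    rates = (1.0 + (pair.r0 / r) ** 6) / tau_d
    return w, 1.0 / rates


def model_decay(model: DecayModel, bin_times: np.ndarray | None = None) -> np.ndarray:
    """Expected counts per bin (up to scale) for ``model`` on its IRF grid.

    Components are periodically wrapped over the laser period and circularly
    convolved with the normalised IRF, matching high-repetition-rate
    acquisition where the decay does not complete between pulses.
    """
    t = model.irf.bin_times if bin_times is None else np.asarray(bin_times, dtype=float)
    if bin_times is not None and t.shape != model.irf.bin_times.shape:
        raise ValueError("evaluation grid must match the IRF grid")
    T = model.period_ns
    out = np.zeros_like(t)
    if model.a_d > 0:
        out += model.a_d * _periodic_exp(t, model.tau_d, T)
    if model.a_fret > 0:
        w, taus = _fret_weights(model.chain, model.pair, model.tau_d, model.r_grid_size)
        # (n_bins,) <- (n_nodes,) weighted sum of periodic exponentials
        out += model.a_fret * np.exp(
            -t[:, None] / taus[None, :]
        ) @ (w / (1.0 - np.exp(-T / taus)))
    if model.a_bg > 0:
        out += model.a_bg * model.background.intensity(t, T)
    return _circular_convolve(out, model.irf.normalized())


def _poisson_nll(counts: np.ndarray, expected: np.ndarray) -> float:
    """Negative log-likelihood of counts under the shape of ``expected``.

    The model is scaled to the observed total (multinomial conditioning), so
    only the decay shape matters.  A tiny uniform floor keeps the surface
    smooth where the model predicts empty bins.
    """
    p = expected / expected.sum()
    p = (1.0 - 1e-9) * p + 1e-9 / p.size
    return float(-np.sum(counts * np.log(p)))


# ---------------------------------------------------------------------------
# Background fitting


def fit_background(
    decays,
    irf: DecayHistogram,
    n_exp: int = 4,
    tau_bounds=(0.02, 20.0),
    seed_taus=None,
) -> BackgroundModel:
    """MLE multi-exponential fit of pooled acceptor-free (background) decays.

    Replicate decays are pooled by summing counts (Poisson additivity), then
    a ``n_exp``-exponential model convolved with the IRF is fitted by
    Nelder-Mead on (log tau_i, softmax amplitude logits).
    """
    if isinstance(decays, DecayHistogram):
        decays = [decays]
    counts = np.sum([d.counts for d in decays], axis=0)
    t = decays[0].bin_times
    T = decays[0].period_ns
    irf_n = irf.normalized()

    if seed_taus is None:
        seed_taus = np.geomspace(0.3, 4.0, n_exp)
    seed_taus = np.asarray(seed_taus, dtype=float)

    def unpack(x):
        taus = np.exp(x[:n_exp])
        logits = np.concatenate([x[n_exp:], [0.0]])
        amps = np.exp(logits - logits.max())
        return amps / amps.sum(), taus

    def nll(x):
        amps, taus = unpack(x)
        if np.any(taus < tau_bounds[0]) or np.any(taus > tau_bounds[1]):
            return 1e12
        m = (amps / (1.0 - np.exp(-T / taus))) @ np.exp(-t[None, :] / taus[:, None])
        return _poisson_nll(counts, _circular_convolve(m, irf_n))

    x0 = np.concatenate([np.log(seed_taus), np.zeros(n_exp - 1)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
    amps, taus = unpack(res.x)
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    if n_exp > 1 and np.any(np.diff(taus) / taus[:-1] < 0.05):
        warnings.warn(
            "background components nearly degenerate; consider fewer exponentials",
            RuntimeWarning,
        )
    return BackgroundModel(amplitudes=tuple(amps), lifetimes=tuple(taus))


# ---------------------------------------------------------------------------
# Distance extraction


@dataclass
class DecayFitResult:
    model: DecayModel
    re_nm: float | None
    nll: float
    ci_re: tuple | None = None
    identifiable: bool = True
    at_bound: bool = False


def fit_decay_mle(
    decay: DecayHistogram,
    template: DecayModel,
    free_amplitudes: tuple = (),
    re_bounds: tuple = (0.3, 30.0),
    profile_ci: bool = False,
) -> DecayFitResult:
    """Extract R_E (and optionally amplitude fractions) by Poisson MLE.

    ``template`` carries every fixed quantity (tau_D, IRF, background model,
    dye pair and the amplitude plan of the workflow in use).  R_E is always
    free; amplitudes named in ``free_amplitudes`` (subset of {"a_d",
    "a_fret", "a_bg"}) are re-mixed by softmax over the probability mass not
    claimed by the fixed ones, preserving A_D + A_FRET + A_bg = 1.
    """
    counts = decay.counts
    names = ("a_d", "a_fret", "a_bg")
    free = tuple(free_amplitudes)
    if any(n not in names for n in free):
        raise ValueError(f"unknown amplitude name in {free}")
    if template.a_fret == 0 and "a_fret" not in free:
        return DecayFitResult(model=template, re_nm=None,
                              nll=_poisson_nll(counts, model_decay(template)),
                              identifiable=False)

    fixed_mass = sum(getattr(template, n) for n in names if n not in free)
    free_mass = 1.0 - fixed_mass

    def build(log_re, logits):
        amps = {n: getattr(template, n) for n in names}
        if free:
            w = np.exp(np.concatenate([logits, [0.0]]))
            w = w / w.sum() * free_mass
            for n, wi in zip(free, w):
                amps[n] = wi
        m = replace(template, chain=GaussianChainModel.from_re(np.exp(log_re)), **amps)
        return m

    lo, hi = np.log(re_bounds[0]), np.log(re_bounds[1])

    if not free:
        res = optimize.minimize_scalar(
            lambda lr: _poisson_nll(counts, model_decay(build(lr, None))),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        best_x = np.array([res.x])
        best_nll = res.fun
    else:
        x0 = np.concatenate([[np.log(template.chain.root_mean_sq
                                     if template.chain else template.pair.r0)],
                             np.zeros(len(free) - 1)])

        def nll(x):
            if not lo <= x[0] <= hi:
                return 1e12
            return _poisson_nll(counts, model_decay(build(x[0], x[1:])))

        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 10000, "xatol": 1e-9, "fatol": 1e-10})
        best_x, best_nll = res.x, res.fun

    re_hat = float(np.exp(best_x[0]))
    fitted = build(best_x[0], best_x[1:] if free else None)
    at_bound = (
        re_hat < re_bounds[0] * 1.001 or re_hat > re_bounds[1] * 0.999
    )
    if at_bound:
        warnings.warn(f"fitted R_E = {re_hat:.3g} nm is at the search bound", RuntimeWarning)

    ci = None
    if profile_ci:
        ci = _profile_ci_re(counts, build, best_x, best_nll, (lo, hi), bool(free))
    return DecayFitResult(model=fitted, re_nm=re_hat, nll=float(best_nll),
                          ci_re=ci, at_bound=at_bound)


def _profile_ci_re(counts, build, best_x, best_nll, log_bounds, has_amps,
                   delta=1.92):
    """Profile-likelihood CI: R_E where the profiled NLL rises by 1.92 (95%)."""

    def profile(log_re):
        if not has_amps:
            return _poisson_nll(counts, model_decay(build(log_re, None)))
        res = optimize.minimize(
            lambda z: _poisson_nll(counts, model_decay(build(log_re, z))),
            best_x[1:], method="Nelder-Mead", options={"maxiter": 2000},
        )
        return res.fun

    def crossing(direction):
        lo_or_hi = log_bounds[0] if direction < 0 else log_bounds[1]
        a, b = best_x[0], lo_or_hi
        if profile(b) - best_nll < delta:
            return float(np.exp(b))  # CI open to the bound
        for _ in range(60):
            mid = 0.5 * (a + b)
            if profile(mid) - best_nll < delta:
                a = mid
            else:
                b = mid
            if abs(b - a) < 1e-4:
                break
        return float(np.exp(0.5 * (a + b)))

    return (crossing(-1), crossing(+1))


@dataclass
class PostbleachResult:
    tau_d: float
    a_d: float
    a_bg: float
    tau_d_pre: float
    consistent: bool


def postbleach_fit(
    decay_pre: DecayHistogram,
    decay_post: DecayHistogram,
    background: BackgroundModel,
    irf: DecayHistogram,
    tau_tolerance: float = 0.05,
) -> PostbleachResult:
    """Fit the post-photobleach donor decay for (tau_D, A_D, A_bg).

    After acceptor photobleaching the FRET term collapses into the donor
    exponential, leaving a donor + background model.  The pre-bleach decay is
    fitted with the same two-component model; agreement of the apparent donor
    lifetimes (within ``tau_tolerance`` relative) is the no-intermolecular-FRET
    control, and a shorter pre-bleach lifetime marks residual FRET.
    """

    def fit_two_component(decay):
        t, T = decay.bin_times, decay.period_ns
        irf_n = irf.normalized()

        def nll(x):
            tau_d, a_bg = np.exp(x[0]), 1.0 / (1.0 + np.exp(-x[1]))
            m = (1.0 - a_bg) * _periodic_exp(t, tau_d, T) + a_bg * background.intensity(t, T)
            return _poisson_nll(decay.counts, _circular_convolve(m, irf_n))

        res = optimize.minimize(nll, np.array([np.log(3.0), 0.0]), method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 10000})
        return float(np.exp(res.x[0])), float(1.0 / (1.0 + np.exp(-res.x[1])))

    tau_post, a_bg = fit_two_component(decay_post)
    tau_pre, _ = fit_two_component(decay_pre)
    consistent = tau_post >= tau_pre * (1.0 - tau_tolerance)
    if not consistent:
        warnings.warn(
            f"post-bleach lifetime {tau_post:.3f} ns below pre-bleach {tau_pre:.3f} ns: "
            "physically inconsistent", RuntimeWarning,
        )
    # The single donor exponential now absorbs the former FRET amplitude.
    return PostbleachResult(tau_d=tau_post, a_d=1.0 - a_bg, a_bg=a_bg,
                            tau_d_pre=tau_pre,
                            consistent=abs(tau_pre - tau_post) <= tau_tolerance * tau_post)


# ---------------------------------------------------------------------------
# Global scaling-law fit with bootstrap


@dataclass
class GlobalNuResult:
    nu_rounds: np.ndarray
    rho0_rounds: np.ndarray
    failed_rounds: int

    @property
    def nu_mean(self) -> float:
        return float(np.mean(self.nu_rounds))

    @property
    def nu_sd(self) -> float:
        return float(np.std(self.nu_rounds, ddof=1)) if self.nu_rounds.size > 1 else 0.0


def bootstrap_global_nu(
    decays_by_variant: dict,
    template: DecayModel,
    frac: float = 0.7,
    rounds: int = 10,
    seed: int = 0,
    nu_bounds: tuple = (0.05, 1.0),
    free_variant_amplitudes: bool = True,
) -> GlobalNuResult:
    """Bootstrap global fit of the scaling exponent across labelling variants.

    ``decays_by_variant`` maps variant id -> (N_res, [DecayHistogram, ...]),
    one histogram per cell.  Per round, a ``frac`` fraction of cells is drawn
    per variant (without replacement, cell-level resampling), the sampled
    decays are aggregated by summing counts, and all variants are fitted
    globally by Poisson MLE with shared (log rho0, nu) through
    R_E(N_res) = rho0 * N_res^nu.  With ``free_variant_amplitudes`` each
    variant additionally frees its FRET amplitude, the complement being
    split between donor-only and background in the template's ratio.
    """
    rng = np.random.default_rng(seed)
    variants = sorted(decays_by_variant)
    n_res = np.array([decays_by_variant[v][0] for v in variants], dtype=float)
    T = template.period_ns
    t = template.irf.bin_times
    irf_n = template.irf.normalized()
    # Convolution is linear, so pre-convolve the fixed component shapes and
    # combine amplitudes afterwards; only the FRET shape depends on R_E.
    rest_shape = np.zeros_like(t)
    rest = template.a_d + template.a_bg
    if rest > 0:
        d_frac = template.a_d / rest
        if d_frac > 0:
            rest_shape += d_frac * _periodic_exp(t, template.tau_d, T)
        if template.background is not None:
            rest_shape += (1.0 - d_frac) * template.background.intensity(t, T)
    rest_conv = _circular_convolve(rest_shape, irf_n) if rest > 0 else rest_shape

    def fret_conv_for(re):
        w, taus = _fret_weights(
            GaussianChainModel.from_re(re), template.pair, template.tau_d,
            template.r_grid_size,
        )
        shape = np.exp(-t[:, None] / taus[None, :]) @ (w / (1.0 - np.exp(-T / taus)))
        return _circular_convolve(shape, irf_n)

    def nll_round(counts_list):
        def nll(x):
            log_rho0, nu = x
            if not nu_bounds[0] <= nu <= nu_bounds[1]:
                return 1e12
            total = 0.0
            for k, counts in enumerate(counts_list):
                re = np.exp(log_rho0) * n_res[k] ** nu
                fc = fret_conv_for(re)
                if free_variant_amplitudes:
                    res = optimize.minimize_scalar(
                        lambda a: _poisson_nll(counts, a * fc + (1 - a) * rest_conv),
                        bounds=(1e-6, 1.0 - 1e-6), method="bounded",
                        options={"xatol": 1e-6},
                    )
                    total += res.fun
                else:
                    a = template.a_fret
                    total += _poisson_nll(counts, a * fc + (1 - a) * rest_conv)
            return total

        return nll

    x0 = np.array([np.log(template.pair.r0 / np.mean(n_res) ** 0.5), 0.5])
    nus, rho0s, failed = [], [], 0
    for _ in range(rounds):
        counts_list = []
        for v in variants:
            cells = decays_by_variant[v][1]
            k = max(1, int(round(frac * len(cells))))
            idx = rng.choice(len(cells), size=k, replace=False)
            counts_list.append(np.sum([cells[i].counts for i in idx], axis=0))
        res = optimize.minimize(
            nll_round(counts_list), x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9},
        )
        if not (np.isfinite(res.fun) and res.fun < 1e12 and res.success):
            failed += 1
            continue
        rho0s.append(float(np.exp(res.x[0])))
        nus.append(float(res.x[1]))
        x0 = res.x  # warm-start subsequent rounds
    if failed:
        warnings.warn(f"{failed} bootstrap round(s) failed to converge", RuntimeWarning)
    return GlobalNuResult(
        nu_rounds=np.asarray(nus), rho0_rounds=np.asarray(rho0s), failed_rounds=failed
    )


# ---------------------------------------------------------------------------
# Phasor analysis


@dataclass(frozen=True)
class PhasorPoint:
    """Phasor coordinates (g, s) at angular frequency omega (rad/ns)."""

    g: float
    s: float
    omega: float

    @property
    def z(self) -> complex:
        return complex(self.g, self.s)

    def semicircle_residual(self) -> float:
        """Distance from the universal semicircle (g - 1/2)^2 + s^2 = 1/4."""
        return abs(np.hypot(self.g - 0.5, self.s) - 0.5)


def phasor_transform(
    decay: DecayHistogram,
    calibration: "PhasorPoint | DecayHistogram",
    omega: float | None = None,
) -> PhasorPoint:
    """Phasor (g, s) of a decay, calibrated so the IRF maps to (1, 0).

    g and s are the cosine/sine Fourier coefficients of the decay at
    ``omega`` (default 2 pi / T, the laser repetition frequency), normalised
    by the total intensity.  Calibration divides the complex phasor by the
    IRF's uncalibrated phasor — a rotation plus scaling that designates the
    IRF as the zero-lifetime reference.
    """
    if omega is None:
        omega = 2.0 * np.pi / decay.period_ns
    z = _raw_phasor(decay, omega)
    if isinstance(calibration, DecayHistogram):
        z_cal = _raw_phasor(calibration, omega)
    else:
        z_cal = calibration.z
    if z_cal == 0:
        raise ValueError("calibration phasor is zero")
    z = z / z_cal
    return PhasorPoint(g=float(z.real), s=float(z.imag), omega=float(omega))


def _raw_phasor(decay: DecayHistogram, omega: float) -> complex:
    total = decay.counts.sum()
    if total <= 0:
        raise ValueError("undefined phasor: zero total intensity")
    phase = omega * decay.bin_times
    return complex(
        np.sum(decay.counts * np.cos(phase)) / total,
        np.sum(decay.counts * np.sin(phase)) / total,
    )


def phasor_outlier_filter(points, n_sd: float = 3.0):
    """Single-pass mean +/- n_sd filter on g and s; returns the retained subset."""
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 phasor points")
    g = np.array([p.g for p in pts])
    s = np.array([p.s for p in pts])
    keep = np.ones(len(pts), dtype=bool)
    for v in (g, s):
        sd = v.std(ddof=0)
        if sd > 0:
            keep &= np.abs(v - v.mean()) <= n_sd * sd
    return [p for p, k in zip(pts, keep) if k]
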