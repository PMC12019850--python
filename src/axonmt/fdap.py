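"""Reaction-diffusion modelling of fluorescence decay after photoactivation (FDAP).

A 6 um segment of a neurite is photoactivated and the fluorescence inside the
window is monitored over time.  Tagged tubulin exists in two pools: a freely
diffusing dimer pool (diffusion constant ``D``) and a polymer-bound pool that is
immobile on the time scale of the experiment.  Exchange between the pools is
pseudo-first-order::

    df/dt = D d2f/dx2 - k_on* f + k_off b
    db/dt = k_on* f - k_off b

with reflecting boundaries on a 1D domain much longer than the activation
window.  Before activation the system is at binding equilibrium, so the
activated material starts with a free fraction ``k_off / (k_on* + k_off)`` and
bound fraction ``k_on* / (k_on* + k_off)`` inside the window and zero outside.
The FDAP readout is the window integral of (free + bound), normalized to 1 at
the moment of activation.

The production solver expands the linear system in the Neumann cosine
eigenbasis of the reflecting domain and propagates each spatial mode with the
exact 2x2 matrix exponential; it is exact in time and spectrally accurate in
space.  :func:`crank_nicolson_reference` provides an independent
finite-difference solver used for cross-validation.

The polymer (bound) fraction of tubulin is ``k_on* / (k_on* + k_off)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import erf

__all__ = [
    "FDAPCurve",
    "ReactionDiffusionParams",
    "SimulationGrid",
    "KineticFitResult",
    "EffectiveDiffusionFit",
    "bound_fraction",
    "pure_diffusion_fdap",
    "simulate_fdap",
    "simulate_fdap_profiles",
    "crank_nicolson_reference",
    "fit_reaction_diffusion",
    "fit_effective_diffusion",
]

DEFAULT_WINDOW_UM = 6.0
DEFAULT_FRAME_INTERVAL_S = 1.0
DEFAULT_N_FRAMES = 112

#: optimizer bounds for the rate constants, 1/s
RATE_LOWER = 1e-5
RATE_UPPER = 10.0
#: 4x4 log-spaced multi-start grid spans this range, 1/s
START_RANGE = (1e-4, 1.0)


def bound_fraction(k_on_star_s: float, k_off_s: float) -> float:
    """Polymerized (bound) fraction ``k_on* / (k_on* + k_off)``.

    Defined as 0.0 when both rates are zero.  Negative rates are rejected.
    """
    if k_on_star_s < 0 or k_off_s < 0:
        raise ValueError(
            f"rate constants must be nonnegative, got k_on*={k_on_star_s}, k_off={k_off_s}"
        )
    total = k_on_star_s + k_off_s
    if total == 0:
        return 0.0
    return k_on_star_s / total


@dataclass
class ReactionDiffusionParams:
    """Kinetic parameters of the two-pool reaction-diffusion model."""

    D_um2_s: float
    k_on_star_s: float
    k_off_s: float

    def __post_init__(self) -> None:
        if self.D_um2_s < 0:
            raise ValueError(f"diffusion constant must be >= 0, got {self.D_um2_s}")
        # delegate sign checks
        bound_fraction(self.k_on_star_s, self.k_off_s)

    @property
    def bound_fraction(self) -> float:
        return bound_fraction(self.k_on_star_s, self.k_off_s)


@dataclass
class SimulationGrid:
    """Discretization of the reflecting 1D domain.

    ``dx_um`` sets the spatial resolution (the spectral solver uses
    ``domain_length_um / dx_um`` cosine modes, the finite-difference reference
    that many grid points).  ``dt_s`` is consumed by the finite-difference
    reference solver only; the spectral solver is exact in time.
    """

    domain_length_um: float = 120.0
    dx_um: float = 0.1
    dt_s: float = 0.05
    boundary: str = "reflecting"

    def validate(self, window_length_um: float) -> None:
        if self.boundary != "reflecting":
            raise ValueError("only reflecting boundaries are supported")
        if self.dx_um <= 0 or self.dt_s <= 0:
            raise ValueError("dx_um and dt_s must be positive")
        if self.dx_um > window_length_um / 30:
            raise ValueError(
                f"dx_um={self.dx_um} too coarse: must be <= window/30 = {window_length_um / 30}"
            )
        if self.domain_length_um < 10 * window_length_um:
            raise ValueError(
                f"domain_length_um={self.domain_length_um} too short: "
                f"must be >= 10x window = {10 * window_length_um}"
            )

    @property
    def n_modes(self) -> int:
        return int(round(self.domain_length_um / self.dx_um))


@dataclass
class FDAPCurve:
    """A normalized fluorescence-decay-after-photoactivation trace."""

    time_s: np.ndarray
    intensity: np.ndarray
    window_length_um: float = DEFAULT_WINDOW_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time_s and intensity must have the same length")
        if self.time_s.size < 2:
            raise ValueError("curve needs at least 2 time points")
        if self.time_s[0] != 0:
            raise ValueError("time axis must start at 0 (moment of activation)")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and >= 0")

    def normalized(self) -> "FDAPCurve":
        """Return a copy divided by the first post-activation frame."""
        first = self.intensity[0]
        if first <= 0:
            raise ValueError("cannot normalize: first intensity is not positive")
        return FDAPCurve(
            self.time_s.copy(),
            self.intensity / first,
            self.window_length_um,
            self.frame_interval_s,
            dict(self.meta),
        )

    @property
    def is_normalized(self) -> bool:
        return abs(self.intensity[0] - 1.0) <= 1e-9


@dataclass
class KineticFitResult:
    """Multi-start chi-square fit of (k_on*, k_off) at fixed D."""

    k_on_star_s: float
    k_off_s: float
    bound_fraction: float
    chi2: float
    converged: bool
    at_bound: bool
    n_starts: int
    residuals: np.ndarray
    diagnostics: list[str] = field(default_factory=list)


@dataclass
class EffectiveDiffusionFit:
    """Single-coefficient diffusion summary of a decay curve."""

    D_eff_um2_s: float
    chi2: float
    at_bound: bool = False


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------


def pure_diffusion_fdap(D_um2_s, window_length_um, time_s):
    """Closed-form FDAP of a purely diffusing species from a box profile.

    F(t) = erf(s) + (exp(-s^2) - 1) / (s sqrt(pi)),  s = L / (2 sqrt(D t))

    i.e. the window-average survival of an initially uniform box of length L
    spreading on an infinite 1D line.  F(0) = 1; F decreases monotonically in
    both t and D.
    """
    if D_um2_s <= 0:
        raise ValueError(f"D must be > 0, got {D_um2_s}")
    t = np.asarray(time_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.ones_like(t)
    pos = t > 0
    s = window_length_um / (2.0 * np.sqrt(D_um2_s * t[pos]))
    out[pos] = erf(s) + (np.exp(-(s**2)) - 1.0) / (s * np.sqrt(np.pi))
    return float(out[0]) if scalar else out


def _window_modes(window_length_um: float, domain_length_um: float, n_modes: int):
    """Cosine-series coefficients of the window indicator and window weights.

    Returns (q, c, w): wavenumbers q_m = m*pi/Ld for m = 0..M-1, the series
    coefficients c_m of the centered window indicator, and the weights w_m such
    that the window integral of a field with mode amplitudes a_m is sum(w*a).
    """
    Ld = domain_length_um
    L = window_length_um
    x1 = (Ld - L) / 2.0
    x2 = (Ld + L) / 2.0
    m = np.arange(n_modes)
    q = m * np.pi / Ld
    c = np.empty(n_modes)
    w = np.empty(n_modes)
    c[0] = L / Ld
    w[0] = L
    mm = m[1:].astype(float)
    sins = np.sin(mm * np.pi * x2 / Ld) - np.sin(mm * np.pi * x1 / Ld)
    c[1:] = 2.0 / (mm * np.pi) * sins
    w[1:] = Ld / (mm * np.pi) * sins
    return q, c, w


def _mode_evolution(d, k_on, k_off, a0, b0, times):
    """Exact per-mode evolution of (free, bound) amplitudes.

    ``d = D q^2`` is the per-mode diffusive decay rate (array of M), ``a0``/``b0``
    the initial free/bound amplitudes.  Returns arrays (T, M).
    """
    t = np.asarray(times, dtype=float)[:, None]
    d = np.asarray(d, dtype=float)[None, :]
    a0 = np.asarray(a0, dtype=float)[None, :]
    b0 = np.asarray(b0, dtype=float)[None, :]

    if k_off == 0.0:
        rate = d + k_on
        decay = np.exp(-rate * t)
        a = a0 * decay
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(rate > 0, k_on * a0 * (1.0 - decay) / np.where(rate > 0, rate, 1.0), 0.0)
        b = b0 + gain
        return a, b
    if k_on == 0.0:
        a = a0 * np.exp(-d * t)
        b = b0 * np.exp(-k_off * t)
        return a, b

    tr = -(d + k_on + k_off)
    disc = (d + k_on + k_off) ** 2 - 4.0 * d * k_off
    sq = np.sqrt(np.maximum(disc, 0.0))
    lam_p = (tr + sq) / 2.0
    lam_m = (tr - sq) / 2.0
    # eigenvectors (1, c_pm) from the free-species row
    c_p = (d + k_on + lam_p) / k_off
    c_m = (d + k_on + lam_m) / k_off
    denom = c_p - c_m  # = sq / k_off > 0 strictly when k_on > 0
    alpha_p = (b0 - a0 * c_m) / denom
    alpha_m = a0 - alpha_p
    ep = np.exp(lam_p * t)
    em = np.exp(lam_m * t)
    a = alpha_p * ep + alpha_m * em
    b = alpha_p * c_p * ep + alpha_m * c_m * em
    return a, b


def _equilibrium_fractions(k_on: float, k_off: float) -> tuple[float, float]:
    total = k_on + k_off
    if total == 0:
        return 1.0, 0.0
    return k_off / total, k_on / total


def _fdap_signal(
    D: float,
    k_on: float,
    k_off: float,
    times: np.ndarray,
    window_length_um: float,
    domain_length_um: float,
    n_modes: int,
) -> np.ndarray:
    """Window signal of the reaction-diffusion model, normalized to 1 at t=0.

    The t=0 window integral equals the window length exactly (uniform unit
    concentration inside), so normalization uses that analytic value.  The
    free pool diffuses, so its truncated series is spectrally accurate at
    t > 0; the bound pool keeps the sharp window edges, so the truncated-tail
    mass T = L - sum(w c) is restored analytically: tail modes have
    Dq^2 >> rates, where the free component vanishes immediately and the
    bound component decays as exp(-k_off t).
    """
    q, c, w = _window_modes(window_length_um, domain_length_um, n_modes)
    f_eq, b_eq = _equilibrium_fractions(k_on, k_off)
    a, b = _mode_evolution(D * q**2, k_on, k_off, f_eq * c, b_eq * c, times)
    times = np.asarray(times, dtype=float)
    tail = window_length_um - float(c @ w)
    signal = (a + b) @ w + tail * b_eq * np.exp(-k_off * times)
    signal = signal / window_length_um
    signal[times == 0.0] = 1.0
    return signal


def simulate_fdap(
    params: ReactionDiffusionParams,
    grid: SimulationGrid | None = None,
    window_length_um: float = DEFAULT_WINDOW_UM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    n_frames: int = DEFAULT_N_FRAMES,
) -> FDAPCurve:
    """Forward-simulate an FDAP curve from the equilibrium initial condition.

    The readout is the window integral of free + bound material normalized to
    its value at t = 0, sampled at ``n_frames`` frames ``frame_interval_s``
    apart starting at activation.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if grid is None:
        grid = SimulationGrid(domain_length_um=20.0 * window_length_um, dx_um=window_length_um / 60.0)
    grid.validate(window_length_um)
    times = np.arange(n_frames, dtype=float) * frame_interval_s
    if params.D_um2_s == 0.0:
        # nothing moves: bound is immobile by construction, free does not diffuse
        intensity = np.ones(n_frames)
    else:
        intensity = _fdap_signal(
            params.D_um2_s,
            params.k_on_star_s,
            params.k_off_s,
            times,
            window_length_um,
            grid.domain_length_um,
            grid.n_modes,
        )
    return FDAPCurve(
        times,
        np.clip(intensity, 0.0, None),
        window_length_um=window_length_um,
        frame_interval_s=frame_interval_s,
        meta={"params": params},
    )


def simulate_fdap_profiles(
    params: ReactionDiffusionParams,
    grid: SimulationGrid | None = None,
    window_length_um: float = DEFAULT_WINDOW_UM,
    times: Sequence[float] = (0.0, 10.0, 50.0, 111.0),
):
    """Spatial free/bound concentration profiles at the requested times.

    Returns ``(x_um, free, bound)`` with ``free``/``bound`` of shape
    (len(times), len(x)).  Used for mass-conservation checks: the integral of
    free + bound over the reflecting domain is constant in time.
    """
    if grid is None:
        grid = SimulationGrid(domain_length_um=20.0 * window_length_um, dx_um=window_length_um / 60.0)
    grid.validate(window_length_um)
    times = np.asarray(times, dtype=float)
    n = grid.n_modes
    q, c, _ = _window_modes(window_length_um, grid.domain_length_um, n)
    f_eq, b_eq = _equilibrium_fractions(params.k_on_star_s, params.k_off_s)
    a, b = _mode_evolution(params.D_um2_s * q**2, params.k_on_star_s, params.k_off_s, f_eq * c, b_eq * c, times)
    x = (np.arange(n) + 0.5) * grid.dx_um
    basis = np.cos(np.outer(q, x))  # (M, N)
    return x, a @ basis, b @ basis


def crank_nicolson_reference(
    params: ReactionDiffusionParams,
    grid: SimulationGrid,
    window_length_um: float = DEFAULT_WINDOW_UM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    n_frames: int = DEFAULT_N_FRAMES,
    return_profiles: bool = False,
):
    """Finite-difference (Crank-Nicolson) solver for cross-validation.

    Independent of the spectral solver: second-order in dx and dt, reflecting
    (zero-flux) boundaries via ghost mirroring.  A time step too large for the
    spatial step is rejected by the accuracy criterion dt <= dx^2 / (2 D).
    """
    if params.D_um2_s <= 0:
        raise ValueError("reference solver requires D > 0")
    grid.validate(window_length_um)
    D, k_on, k_off = params.D_um2_s, params.k_on_star_s, params.k_off_s
    dx, dt = grid.dx_um, grid.dt_s
    if dt > dx**2 / (2.0 * D):
        raise ValueError(
            "unstable solver configuration: accuracy criterion dt <= dx^2/(2 D) violated "
            f"(dt={dt}, dx^2/(2D)={dx**2 / (2 * D):.3g})"
        )
    n = int(round(grid.domain_length_um / dx))
    x = (np.arange(n) + 0.5) * dx
    in_window = np.abs(x - grid.domain_length_um / 2.0) <= window_length_um / 2.0
    f_eq, b_eq = _equilibrium_fractions(k_on, k_off)
    f = np.where(in_window, f_eq, 0.0)
    b = np.where(in_window, b_eq, 0.0)

    from scipy.sparse import diags, identity, bmat
    from scipy.sparse.linalg import splu

    lap = diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(n, n), format="lil")
    lap[0, 0] = -1.0  # zero-flux mirror
    lap[n - 1, n - 1] = -1.0
    lap = (D / dx**2) * lap.tocsr()
    I = identity(n, format="csr")
    A = bmat([[lap - k_on * I, k_off * I], [k_on * I, -k_off * I]], format="csc")
    M1 = (identity(2 * n, format="csc") - (dt / 2.0) * A).tocsc()
    M2 = (identity(2 * n, format="csc") + (dt / 2.0) * A).tocsr()
    lu = splu(M1)

    u = np.concatenate([f, b])
    times = np.arange(n_frames, dtype=float) * frame_interval_s
    steps_per_frame = max(1, int(round(frame_interval_s / dt)))
    signal = np.empty(n_frames)
    profiles = []
    for i in range(n_frames):
        if i > 0:
            for _ in range(steps_per_frame):
                u = lu.solve(M2 @ u)
        total = u[:n] + u[n:]
        signal[i] = total[in_window].sum() * dx
        if return_profiles:
            profiles.append((u[:n].copy(), u[n:].copy()))
    curve = FDAPCurve(
        times,
        signal / signal[0],
        window_length_um=window_length_um,
        frame_interval_s=frame_interval_s,
        meta={"solver": "crank-nicolson"},
    )
    if return_profiles:
        return curve, x, profiles
    return curve


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _noise_sigma(intensity: np.ndarray) -> float:
    """Noise scale from the last 10 frames after removing a linear trend."""
    tail = intensity[-10:]
    if tail.size < 3:
        return 1.0
    idx = np.arange(tail.size, dtype=float)
    coef = np.polyfit(idx, tail, 1)
    resid = tail - np.polyval(coef, idx)
    sigma = float(np.std(resid, ddof=2))
    if not np.isfinite(sigma) or sigma < 1e-12:
        return 1.0  # degenerate estimate: fall back to unweighted SSE
    return sigma


def fit_reaction_diffusion(
    curve: FDAPCurve,
    D_fixed_um2_s: float = 3.0,
    n_starts_per_axis: int = 4,
    grid: SimulationGrid | None = None,
) -> KineticFitResult:
    """Fit (k_on*, k_off) to a normalized FDAP curve at fixed D.

    Multi-start chi-square minimization: ``n_starts_per_axis**2`` log-spaced
    starting points over [1e-4, 1] 1/s, rates bounded to [1e-5, 10] 1/s, best
    chi-square wins with ties broken toward the slower-exchange solution.
    Joint fitting of D from a single curve is ill-posed, so D is supplied by
    the caller (obtained independently, e.g. via
    :func:`fit_effective_diffusion` on a freely diffusing construct).
    """
    if D_fixed_um2_s <= 0:
        raise ValueError("D_fixed_um2_s must be > 0")
    if curve.time_s.size < 10:
        raise ValueError("need at least 10 time points to fit")
    if not curve.is_normalized:
        curve = curve.normalized()
    if grid is None:
        grid = SimulationGrid(
            domain_length_um=20.0 * curve.window_length_um, dx_um=curve.window_length_um / 60.0
        )
    grid.validate(curve.window_length_um)

    times = curve.time_s
    data = curve.intensity
    sigma = _noise_sigma(data)

    def model(k_on: float, k_off: float) -> np.ndarray:
        return _fdap_signal(
            D_fixed_um2_s,
            k_on,
            k_off,
            times,
            curve.window_length_um,
            grid.domain_length_um,
            grid.n_modes,
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        k_on, k_off = 10.0**theta
        return (model(k_on, k_off) - data) / sigma

    lo, hi = np.log10(RATE_LOWER), np.log10(RATE_UPPER)
    starts = np.log10(np.geomspace(START_RANGE[0], START_RANGE[1], n_starts_per_axis))
    best = None
    for s_on in starts:
        for s_off in starts:
            res = optimize.least_squares(
                residuals, x0=[s_on, s_off], bounds=([lo, lo], [hi, hi]), xtol=1e-10, ftol=1e-10
            )
            chi2 = float(res.cost * 2.0)
            rate_sum = float((10.0**res.x).sum())
            if (
                best is None
                or chi2 < best[0] * (1 - 1e-9)
                or (abs(chi2 - best[0]) <= 1e-9 * max(best[0], 1e-300) and rate_sum < best[2])
            ):
                best = (chi2, res, rate_sum)
    chi2, res, _ = best
    k_on, k_off = (float(v) for v in 10.0**res.x)
    at_bound = bool(np.any(res.x < lo + 1e-3) or np.any(res.x > hi - 1e-3))
    diagnostics: list[str] = []
    frame_interval = float(np.median(np.diff(times)))
    if (k_on + k_off) * frame_interval > 10.0:
        diagnostics.append(
            "exchange-too-fast: k_on*+k_off exceeds the sampling rate 10-fold; "
            "rate estimates are not identifiable from this curve"
        )
    return KineticFitResult(
        k_on_star_s=k_on,
        k_off_s=k_off,
        bound_fraction=bound_fraction(k_on, k_off),
        chi2=chi2,
        converged=bool(res.status > 0),
        at_bound=at_bound,
        n_starts=n_starts_per_axis**2,
        residuals=res.fun * sigma,
        diagnostics=diagnostics,
    )


D_EFF_LOWER = 1e-4
D_EFF_UPPER = 1e3


def fit_effective_diffusion(curve: FDAPCurve) -> EffectiveDiffusionFit:
    """Fit a single effective diffusion constant with the 1D diffusion model.

    Uses :func:`pure_diffusion_fdap` as the model function.  The chi-square is
    reported so that curves poorly described by a single diffusing species
    (slow two-population exchange) are detectable by their large chi2.
    """
    if not curve.is_normalized:
        curve = curve.normalized()
    data = curve.intensity
    sigma = _noise_sigma(data)

    def residuals(log_d: np.ndarray) -> np.ndarray:
        model = pure_diffusion_fdap(10.0 ** log_d[0], curve.window_length_um, curve.time_s)
        return (model - data) / sigma

    lo, hi = np.log10(D_EFF_LOWER), np.log10(D_EFF_UPPER)
    best = None
    for start in (-1.0, 0.0, 1.0):
        res = optimize.least_squares(residuals, x0=[start], bounds=([lo], [hi]), xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    d_eff = float(10.0 ** best.x[0])
    at_bound = bool(best.x[0] < lo + 1e-3 or best.x[0] > hi - 1e-3)
    if at_bound:
        warnings.warn("effective-diffusion fit hit an optimizer bound (non-decaying curve?)")
    return EffectiveDiffusionFit(D_eff_um2_s=d_eff, chi2=float(best.cost * 2.0), at_bound=at_bound)
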