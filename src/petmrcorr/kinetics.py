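"""Extended Tofts compartmental modelling for DCE-MRI.

The tissue concentration model is

    C_t(t) = v_p * C_p(t) + Ktrans * int_0^t C_p(tau) exp(-k_ep (t - tau)) dtau

with efflux rate ``k_ep = Ktrans / v_e``; ``C_p`` is the arterial input
function (AIF).  The convolution is evaluated on a refined uniform time grid
with the exponential kernel integrated analytically per step (piecewise-
linear C_p), which is exact for the AIF representation used and stable for
large ``k_ep``.  Rates are min^-1; all public time arguments are seconds.

Also here: per-patient AIF fitting from a carotid curve, voxel/map/regional
Levenberg-Marquardt parameter estimation, dual-flip-angle (DESPOT1) T1
mapping, and the optional enhancement -> concentration conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .grids_io import DynamicSeries, ImageGrid, ParametricMap, ROIMask

__all__ = [
    "AIFModel",
    "ToftsParams",
    "ToftsFitConfig",
    "T1Map",
    "AIFFitError",
    "tofts_forward",
    "fit_aif",
    "fit_tofts_voxel",
    "fit_tofts_map",
    "fit_tofts_regional",
    "t1_from_dual_flip",
    "spgr_signal",
    "enhancement_to_concentration",
]


class AIFFitError(RuntimeError):
    """No usable bolus in the carotid curve; supply t0 manually."""


@dataclass(frozen=True)
class AIFModel:
    """Arterial input function C_p(t).

    form "bolus-biexp" (default): a biexponential decay gated by a brief
    exponential bolus rise,

        C_p(t) = (a1 e^{-m1 s} + a2 e^{-m2 s}) (1 - e^{-r s}),  s = (t - t0)/60

    with s in minutes, zero before the bolus arrival t0 (seconds).  a1, a2
    are concentration amplitudes (mM); m1 decays the first pass, m2 the slow
    washout, r sets the bolus rise time.  form "constant": C_p = a1 for
    t >= t0 (used for closed-form checks).
    """

    form: str = "bolus-biexp"
    a1: float = 5.0
    a2: float = 1.0
    m1: float = 3.0  # min^-1
    m2: float = 0.06  # min^-1
    r: float = 25.0  # min^-1
    t0: float = 0.0  # s

    def __post_init__(self):
        if self.form not in ("bolus-biexp", "constant"):
            raise ValueError(f"unknown AIF form {self.form!r}")
        vals = (self.a1, self.a2, self.m1, self.m2, self.r, self.t0)
        if not all(np.isfinite(vals)):
            raise ValueError("AIF parameters must be finite")
        if self.form == "bolus-biexp" and (self.a1 < 0 or self.a2 < 0):
            raise ValueError("AIF amplitudes must be nonnegative")

    def __call__(self, times_s: np.ndarray) -> np.ndarray:
        t = np.asarray(times_s, dtype=float)
        s = (t - self.t0) / 60.0  # minutes past bolus arrival
        if self.form == "constant":
            return np.where(s >= 0.0, self.a1, 0.0)
        s_pos = np.maximum(s, 0.0)
        cp = (self.a1 * np.exp(-self.m1 * s_pos)
              + self.a2 * np.exp(-self.m2 * s_pos)) * (-np.expm1(-self.r * s_pos))
        return np.where(s >= 0.0, cp, 0.0)


@dataclass
class ToftsParams:
    """Extended Tofts parameter triple with fit diagnostics."""

    ktrans: float  # min^-1
    ve: float  # EES volume fraction
    vp: float  # plasma volume fraction
    rss: float = np.nan
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        if self.ktrans < 0:
            raise ValueError(f"ktrans must be >= 0, got {self.ktrans}")
        if not (0.0 <= self.ve <= 1.0 and 0.0 <= self.vp <= 1.0):
            raise ValueError(f"ve, vp must lie in [0, 1], got {self.ve}, {self.vp}")
        if self.ve + self.vp > 1.0 + 1e-12:
            raise ValueError(f"ve + vp must be <= 1, got {self.ve + self.vp}")


# ---------------------------------------------------------------------------
# Exponential-kernel convolution on a uniform grid
# ---------------------------------------------------------------------------

def _exp_step_weights(kep: np.ndarray, dt_min: float):
    """Per-step quadrature weights for int Cp(tau) e^{-kep (t-tau)} dtau.

    With Cp piecewise linear between grid points and E = e^{-kep dt} the
    contribution of step n is  w0 * Cp[n-1] + w1 * Cp[n]; the recursion is
    I[n] = E I[n-1] + that contribution (exact for piecewise-linear Cp).
    """
    kep = np.asarray(kep, dtype=float)
    E = np.exp(-kep * dt_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        one_m_E = -np.expm1(-kep * dt_min)
        w0 = -E / kep + one_m_E / (kep ** 2 * dt_min)
        w1 = 1.0 / kep - one_m_E / (kep ** 2 * dt_min)
    small = kep * dt_min < 1e-8
    if np.any(small):
        half = 0.5 * dt_min
        w0 = np.where(small, half, w0)
        w1 = np.where(small, half, w1)
    return E, w0, w1


def exp_conv_uniform(cp: np.ndarray, dt_min: float, kep: float) -> np.ndarray:
    """int_0^{t_n} cp(tau) e^{-kep (t_n - tau)} dtau on a uniform grid (min)."""
    E, w0, w1 = _exp_step_weights(kep, dt_min)
    g = np.empty_like(cp)
    g[0] = 0.0
    g[1:] = w0 * cp[:-1] + w1 * cp[1:]
    return signal.lfilter([1.0], [1.0, -float(E)], g)


def tofts_curves_vectorized(ktrans: np.ndarray, ve: np.ndarray, vp: np.ndarray,
                            cp_ref: np.ndarray, dt_min: float) -> np.ndarray:
    """Tissue curves for many voxels sharing one AIF sampled on a uniform grid.

    Returns array (n_times, n_voxels).  Voxels with ktrans == 0 contribute
    only the plasma term; ktrans > 0 with ve == 0 is rejected.
    """
    ktrans = np.atleast_1d(np.asarray(ktrans, dtype=float))
    ve = np.atleast_1d(np.asarray(ve, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    bad = (ktrans > 0) & (ve <= 0)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"ktrans > 0 with ve = 0 at voxel {idx}: k_ep undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        kep = np.where(ktrans > 0, ktrans / np.where(ve > 0, ve, 1.0), 0.0)
    E, w0, w1 = _exp_step_weights(kep, dt_min)
    nt = cp_ref.shape[0]
    nv = ktrans.shape[0]
    out = np.empty((nt, nv))
    I = np.zeros(nv)
    out[0] = vp * cp_ref[0]
    for n in range(1, nt):
        I = E * I + w0 * cp_ref[n - 1] + w1 * cp_ref[n]
        out[n] = vp * cp_ref[n] + ktrans * I
    return out


def _refined_grid(times_s: np.ndarray, refine: int) -> tuple[np.ndarray, float]:
    times_s = np.asarray(times_s, dtype=float)
    if times_s.ndim != 1 or times_s.size < 2:
        raise ValueError("times must be a 1D vector of length >= 2")
    diffs = np.diff(times_s)
    if np.any(diffs <= 0):
        raise ValueError("times must be strictly ascending")
    dt = float(diffs.min()) / refine
    t_end = float(times_s[-1])
    n = int(np.ceil(t_end / dt - 1e-9)) + 1
    grid = np.linspace(0.0, t_end, n)
    return grid, (grid[1] - grid[0]) / 60.0  # step in minutes


def tofts_forward(params: ToftsParams, aif: AIFModel, times_s: np.ndarray,
                  refine: int = 10) -> np.ndarray:
    """Extended Tofts tissue concentration at the requested times (seconds).

    Evaluated on an internal uniform grid refined ``refine``-fold relative to
    the finest spacing of ``times_s`` then sampled back at ``times_s``.
    """
    if params.ktrans > 0 and params.ve <= 0:
        raise ValueError("ktrans > 0 with ve = 0: k_ep undefined")
    grid_s, dt_min = _refined_grid(times_s, refine)
    cp = aif(grid_s)
    ct = params.vp * cp
    if params.ktrans > 0:
        kep = params.ktrans / params.ve
        ct = ct + params.ktrans * exp_conv_uniform(cp, dt_min, kep)
    return np.interp(np.asarray(times_s, dtype=float), grid_s, ct)


# ---------------------------------------------------------------------------
# AIF fitting
# ---------------------------------------------------------------------------

def fit_aif(curve: np.ndarray, times_s: np.ndarray,
            form: str = "bolus-biexp") -> AIFModel:
    """Least-squares fit of an AIF model to a carotid enhancement curve.

    Needs at least 3 pre-bolus samples and a clear peak (max above the
    pre-bolus level by more than 3 pre-bolus standard deviations).  The
    fitted amplitude absorbs the global enhancement-per-concentration scale,
    so the curve may be in signal-enhancement units.
    """
    curve = np.asarray(curve, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if curve.shape != times_s.shape or curve.size < 8:
        raise ValueError("curve and times must be equal-length vectors (>= 8)")
    base_mean = float(np.mean(curve[:3]))
    base_std = float(np.std(curve[:3]))
    peak = float(np.max(curve))
    if peak <= base_mean + 3.0 * base_std or peak <= 1e-12:
        raise AIFFitError(
            "no detectable bolus in carotid curve; supply bolus arrival t0 manually"
        )
    if form != "bolus-biexp":
        raise ValueError(f"unsupported AIF fit form {form!r}")

    thresh = base_mean + 0.1 * (peak - base_mean)
    i_rise = int(np.argmax(curve > thresh))
    t0_init = float(times_s[max(i_rise - 1, 0)])
    dt_typ = float(np.median(np.diff(times_s)))

    def unpack(theta):
        a1, a2, m1, m2, r = np.exp(theta[:5])
        return a1, a2, m1, m2, r, theta[5]

    def residuals(theta):
        a1, a2, m1, m2, r, t0 = unpack(theta)
        model = AIFModel("bolus-biexp", a1, a2, m1, m2, r, t0)
        return model(times_s) - curve

    best = None
    for m1_0, m2_0 in ((3.0, 0.05), (1.5, 0.02), (6.0, 0.15)):
        x0 = np.array([np.log(max(peak, 1e-6)), np.log(max(0.2 * peak, 1e-6)),
                       np.log(m1_0), np.log(m2_0), np.log(20.0), t0_init])
        try:
            res = optimize.least_squares(residuals, x0, method="lm",
                                         max_nfev=4000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise AIFFitError("AIF fit failed to converge from all starts")
    a1, a2, m1, m2, r, t0 = unpack(best.x)
    # canonical ordering: m1 is the fast decay
    if m2 > m1:
        a1, a2, m1, m2 = a2, a1, m2, m1
    t0 = float(np.clip(t0, times_s[0] - dt_typ, times_s[-1]))
    return AIFModel("bolus-biexp", float(a1), float(a2), float(m1),
                    float(m2), float(r), t0)


# ---------------------------------------------------------------------------
# Voxel / map / regional Tofts fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToftsFitConfig:
    """Settings for Tofts map fitting.

    ``scale`` converts model concentration to the data's enhancement units
    (a single global factor; rank statistics downstream are invariant to
    it).  ``baseline_frames`` is the number of pre-injection frames used for
    baseline subtraction when fitting a raw signal series.
    """

    baseline_frames: int = 10
    scale: float = 1.0
    refine: int = 10
    init: tuple[float, float, float] = (0.1, 0.2, 0.02)
    multistart_rss_factor: float = 0.0025  # threshold = factor * n * peak^2
    max_nfev: int = 2000


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p):
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _theta_from_params(ktrans, ve, vp):
    a = np.log(max(ktrans, 1e-6))
    b = _logit(ve)
    c = _logit(vp / max(1.0 - ve, 1e-9))
    return np.array([a, b, c])


def _params_from_theta(theta):
    ktrans = float(np.exp(theta[0]))
    ve = float(_sigmoid(theta[1]))
    vp = float(_sigmoid(theta[2]) * (1.0 - ve))
    return ktrans, ve, vp


_EXTRA_STARTS = ((0.02, 0.1, 0.01), (0.4, 0.45, 0.06))


def fit_tofts_voxel(curve: np.ndarray, times_s: np.ndarray, aif: AIFModel,
                    scale: float = 1.0,
                    init: tuple[float, float, float] = (0.1, 0.2, 0.02),
                    refine: int = 10,
                    multistart_rss_factor: float = 0.0025,
                    max_nfev: int = 2000,
                    _cp_cache: tuple | None = None) -> ToftsParams:
    """Levenberg-Marquardt extended Tofts fit of one enhancement curve.

    Bounds (ktrans >= 0, 0 <= ve, vp, ve + vp <= 1) are enforced through a
    smooth log/sigmoid reparameterization, so the optimizer runs
    unconstrained and the convergence flag is honest.  A small multistart is
    triggered when the residual exceeds a noise-scaled threshold.
    """
    curve = np.asarray(curve, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if curve.shape != times_s.shape or curve.size < 10:
        raise ValueError("curve and times must be equal-length vectors (>= 10)")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if not np.all(np.isfinite(curve)):
        raise ValueError("non-finite values in curve; skip voxel upstream")

    if float(np.max(np.abs(curve))) < 1e-12:
        return ToftsParams(0.0, 0.0, 0.0, rss=0.0, converged=True, n_iter=0)

    if _cp_cache is None:
        grid_s, dt_min = _refined_grid(times_s, refine)
        cp_ref = aif(grid_s)
    else:
        grid_s, dt_min, cp_ref = _cp_cache
    sample_idx = np.interp(times_s, grid_s, np.arange(grid_s.size))

    def model(theta):
        ktrans, ve, vp = _params_from_theta(theta)
        ct = vp * cp_ref
        if ktrans > 0:
            ct = ct + ktrans * exp_conv_uniform(cp_ref, dt_min, ktrans / max(ve, 1e-12))
        return scale * np.interp(sample_idx, np.arange(grid_s.size), ct)

    def residuals(theta):
        return model(theta) - curve

    peak = float(np.max(np.abs(curve)))
    rss_threshold = multistart_rss_factor * curve.size * peak ** 2

    starts = [init]
    results = []
    for trial, p0 in enumerate(starts):
        x0 = _theta_from_params(*p0)
        res = optimize.least_squares(residuals, x0, method="lm", max_nfev=max_nfev)
        results.append(res)
        if 2 * res.cost <= rss_threshold:
            break
        if trial == 0:
            starts.extend(_EXTRA_STARTS)
    best = min(results, key=lambda r: r.cost)
    ktrans, ve, vp = _params_from_theta(best.x)
    return ToftsParams(ktrans, ve, vp, rss=float(2 * best.cost),
                       converged=bool(best.status > 0), n_iter=int(best.nfev))


def _enhancement_curves(series: DynamicSeries, n_baseline: int) -> np.ndarray:
    """(n_frames, *shape) baseline-subtracted frames."""
    if not (1 <= n_baseline < series.n_frames):
        raise ValueError(
            f"baseline_frames must be in [1, {series.n_frames - 1}], got {n_baseline}"
        )
    baseline = series.frames[:n_baseline].mean(axis=0)
    return series.frames - baseline


def fit_tofts_map(series: DynamicSeries, mask: ROIMask, aif: AIFModel,
                  config: ToftsFitConfig = ToftsFitConfig()):
    """Per-voxel extended Tofts fits inside a mask.

    Returns ``(ktrans_map, ve_map, vp_map, diagnostics)``; maps are NaN
    outside the mask and at skipped (non-finite) voxels.  ``diagnostics``
    carries an rss map, the non-converged fraction and skip counts; a
    non-converged fraction above 50% raises a loud warning.
    """
    if series.grid != mask.grid:
        raise ValueError("series and mask must share one grid")
    times = series.frame_starts
    enh = _enhancement_curves(series, config.baseline_frames)
    grid_s, dt_min = _refined_grid(times, config.refine)
    cp_cache = (grid_s, dt_min, aif(grid_s))

    shape = series.grid.shape
    kt = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    n_skipped = 0
    n_nonconv = 0
    idx = np.argwhere(mask.membership)
    for i, j, k in idx:
        curve = enh[:, i, j, k]
        if not np.all(np.isfinite(curve)):
            n_skipped += 1
            continue
        p = fit_tofts_voxel(curve, times, aif, scale=config.scale,
                            init=config.init, refine=config.refine,
                            multistart_rss_factor=config.multistart_rss_factor,
                            max_nfev=config.max_nfev, _cp_cache=cp_cache)
        kt[i, j, k] = p.ktrans
        ve[i, j, k] = p.ve
        vp[i, j, k] = p.vp
        rss[i, j, k] = p.rss
        if not p.converged:
            n_nonconv += 1
    n_fit = len(idx) - n_skipped
    frac_nonconv = n_nonconv / n_fit if n_fit else 0.0
    if frac_nonconv > 0.5:
        warnings.warn(
            f"{frac_nonconv:.0%} of voxel fits did not converge", RuntimeWarning
        )
    diagnostics = {
        "rss_map": ParametricMap(series.grid, rss, "enhancement^2", "tofts_rss"),
        "n_fit": n_fit,
        "n_skipped": n_skipped,
        "nonconverged_fraction": frac_nonconv,
    }
    g = series.grid
    return (
        ParametricMap(g, kt, "min^-1", "Ktrans"),
        ParametricMap(g, ve, "fraction", "ve"),
        ParametricMap(g, vp, "fraction", "vp"),
        diagnostics,
    )


def fit_tofts_regional(series: DynamicSeries, blocks, aif: AIFModel,
                       config: ToftsFitConfig = ToftsFitConfig()):
    """One extended Tofts fit per block of voxel indices.

    Enhancement curves are averaged over each block's voxels first, then
    fitted once, which is the regional-level counterpart of the voxel fits.
    Blocks must not overlap; empty blocks are skipped with a warning and
    reported as None to keep positional correspondence.
    """
    seen: set[tuple[int, int, int]] = set()
    for block in blocks:
        for v in np.asarray(block, dtype=int).reshape(-1, 3):
            t = tuple(v)
            if t in seen:
                raise ValueError(f"blocks overlap at voxel {t}")
            seen.add(t)
    times = series.frame_starts
    enh = _enhancement_curves(series, config.baseline_frames)
    grid_s, dt_min = _refined_grid(times, config.refine)
    cp_cache = (grid_s, dt_min, aif(grid_s))

    out: list[ToftsParams | None] = []
    for b, block in enumerate(blocks):
        block = np.asarray(block, dtype=int).reshape(-1, 3)
        if block.shape[0] == 0:
            warnings.warn(f"empty block {b} skipped", RuntimeWarning)
            out.append(None)
            continue
        curves = enh[:, block[:, 0], block[:, 1], block[:, 2]]
        finite = np.all(np.isfinite(curves), axis=0)
        if not finite.any():
            warnings.warn(f"block {b} has no valid voxels; skipped", RuntimeWarning)
            out.append(None)
            continue
        mean_curve = curves[:, finite].mean(axis=1)
        out.append(fit_tofts_voxel(mean_curve, times, aif, scale=config.scale,
                                   init=config.init, refine=config.refine,
                                   multistart_rss_factor=config.multistart_rss_factor,
                                   max_nfev=config.max_nfev, _cp_cache=cp_cache))
    return out


# ---------------------------------------------------------------------------
# T1 mapping and concentration conversion
# ---------------------------------------------------------------------------

@dataclass
class T1Map:
    """Native T1 (ms) and equilibrium magnetization M0 per voxel."""

    grid: ImageGrid
    t1: np.ndarray  # ms
    m0: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        for arr_name in ("t1", "m0", "valid"):
            arr = np.asarray(getattr(self, arr_name))
            if arr.shape != self.grid.shape:
                raise ValueError(f"{arr_name} shape does not match grid")
        self.valid = np.asarray(self.valid, dtype=bool)


def spgr_signal(m0, t1_ms, flip_deg: float, tr_ms: float):
    """Spoiled gradient-echo steady-state signal S = M0 sin a (1-E1)/(1-E1 cos a)."""
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    return np.asarray(m0, dtype=float) * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def t1_from_dual_flip(s1: ParametricMap, s2: ParametricMap,
                      flip_angles_deg: tuple[float, float],
                      tr_ms: float) -> T1Map:
    """DESPOT1 two-point T1 estimation from dual-flip-angle SPGR images.

    Linearizes S = M0 sin a (1-E1)/(1-E1 cos a) as y = E1 x + M0 (1-E1) with
    y = S/sin a, x = S/tan a; the two-point slope gives E1 = exp(-TR/T1).
    Voxels with E1 outside (0, 1) are flagged invalid rather than raising.
    """
    if s1.grid != s2.grid:
        raise ValueError("flip-angle images must share one grid")
    a1, a2 = (float(f) for f in flip_angles_deg)
    if abs(a1 - a2) < 1e-9:
        raise ValueError("flip angles must be distinct")
    if tr_ms <= 0:
        raise ValueError("TR must be positive")
    r1, r2 = np.deg2rad(a1), np.deg2rad(a2)
    with np.errstate(divide="ignore", invalid="ignore"):
        y1, x1 = s1.values / np.sin(r1), s1.values / np.tan(r1)
        y2, x2 = s2.values / np.sin(r2), s2.values / np.tan(r2)
        e1 = (y2 - y1) / (x2 - x1)
        t1 = -tr_ms / np.log(e1)
        m0 = (y1 - e1 * x1) / (1.0 - e1)
    valid = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0) & np.isfinite(t1)
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)
    return T1Map(s1.grid, t1, m0, valid)


def enhancement_to_concentration(enh: DynamicSeries, t1map: T1Map,
                                 relaxivity: float, tr_ms: float,
                                 flip_deg: float) -> DynamicSeries:
    """Convert a signal-enhancement series to contrast-agent concentration (mM).

    Assumes fast-exchange linear relaxivity, R1(t) = 1/T1 + r1 C(t), and
    inverts the SPGR signal equation frame by frame using the native T1/M0
    map.  Frame-voxel combinations outside the monotone branch of the signal
    equation come back NaN.  Optional path: the primary analysis correlates
    raw enhancement, to which rank statistics are insensitive.
    """
    if t1map.grid != enh.grid:
        raise ValueError("T1 map and series must share one grid")
    if relaxivity <= 0 or tr_ms <= 0:
        raise ValueError("relaxivity and TR must be positive")
    a = np.deg2rad(flip_deg)
    sin_a, cos_a = np.sin(a), np.cos(a)
    t1 = np.where(t1map.valid, t1map.t1, np.nan)
    m0 = np.where(t1map.valid, t1map.m0, np.nan)
    s_pre = spgr_signal(m0, t1, flip_deg, tr_ms)
    r1_0 = 1000.0 / t1  # s^-1
    frames_out = np.empty_like(enh.frames)
    for i in range(enh.n_frames):
        s = s_pre + enh.frames[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            e1 = (m0 * sin_a - s) / (m0 * sin_a - s * cos_a)
            ok = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0)
            r1 = np.where(ok, -np.log(np.where(ok, e1, 0.5)) / (tr_ms / 1000.0),
                          np.nan)
            conc = (r1 - r1_0) / relaxivity
        frames_out[i] = conc
    return DynamicSeries(enh.grid, frames_out, enh.frame_starts,
                         enh.frame_durations, unit="mM")
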