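"""Multi-modal phantom cohorts with known ground truth.

The generator uses a Gaussian-copula latent design: one latent field per
modality, jointly Gaussian with Pearson correlation rho_P = 2 sin(pi
rho_S / 6) so the population Spearman correlation equals the requested
target, then strictly monotone marginal transforms into modality-plausible
ranges.  Monotone transforms leave rank correlations untouched, so the
target Spearman structure survives every downstream normalization exactly.
All fields share one smoothing kernel (a shared linear filter preserves
pointwise cross-correlation of jointly stationary fields).

Dynamic data are generated forward from the truth maps: the DCE series from
the extended Tofts model driven by a known AIF (2.9 s frames, as in the
emulated acquisition), the FMISO wash-in as a perfusion-scaled
mono-exponential approach to saturation, and DW signals as monoexponential
decays over two b-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .grids_io import DynamicSeries, ImageGrid, ParametricMap, ROIMask
from .kinetics import AIFModel, tofts_curves_vectorized

__all__ = [
    "NoiseModel",
    "PhantomConfig",
    "PhantomDataset",
    "DEFAULT_MODALITIES",
    "default_target_spearman",
    "spearman_to_pearson",
    "make_correlated_fields",
    "make_phantom",
    "simulate_dce_series",
    "simulate_fmiso_washin",
    "simulate_dw_signals",
]

#: latent modality labels; "perfusion" drives the FMISO wash-in (hence
#: A-bar_FMISO) and "dce" drives the Tofts truth maps (hence dS_DCE).
DEFAULT_MODALITIES = ("fdg", "fmiso", "perfusion", "dce", "adc")


def default_target_spearman() -> np.ndarray:
    """Default inter-modality Spearman targets over DEFAULT_MODALITIES.

    The four flagship entries are the cohort medians of the emulated study
    (FDG/FMISO 0.56, FDG/wash-in 0.55, wash-in/DCE 0.46, ADC/FDG -0.39);
    the remaining pairs are set to moderate plausible values that keep the
    matched Pearson matrix positive definite.
    """
    labels = DEFAULT_MODALITIES
    m = np.eye(len(labels))

    def put(a, b, v):
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = v

    put("fdg", "fmiso", 0.56)
    put("fdg", "perfusion", 0.55)
    put("fdg", "adc", -0.39)
    put("perfusion", "dce", 0.46)
    put("fdg", "dce", 0.30)
    put("fmiso", "perfusion", 0.50)
    put("fmiso", "dce", 0.20)
    put("fmiso", "adc", -0.25)
    put("perfusion", "adc", -0.20)
    put("dce", "adc", -0.20)
    return m


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Pearson correlation giving the requested Spearman under Gaussianity."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


@dataclass(frozen=True)
class NoiseModel:
    """Post-transform voxel noise: gaussian/rician sigma or scaled-poisson factor."""

    kind: str  # "gaussian" | "rician" | "scaled-poisson"
    param: float

    def __post_init__(self):
        if self.kind not in ("gaussian", "rician", "scaled-poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.param < 0:
            raise ValueError("noise parameter must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.param == 0:
            return values
        if self.kind == "gaussian":
            return values + rng.normal(0.0, self.param, values.shape)
        if self.kind == "rician":
            re = values + rng.normal(0.0, self.param, values.shape)
            im = rng.normal(0.0, self.param, values.shape)
            return np.sqrt(re ** 2 + im ** 2)
        lam = np.clip(values, 0.0, None) / self.param
        return rng.poisson(lam).astype(float) * self.param


def _default_noise() -> dict:
    # placeholders at PET/MR-plausible relative magnitudes; the study
    # publishes no per-modality noise figures, so these are config, not claims
    return {
        "fdg": NoiseModel("gaussian", 0.30),       # SUV units
        "fmiso": NoiseModel("gaussian", 0.08),     # TBR units
        "adc": NoiseModel("rician", 5e-5),         # mm^2/s
        "dce_series": NoiseModel("gaussian", 2.0),  # signal units (baseline 100)
        "washin_series": NoiseModel("gaussian", 0.3),  # kBq/mL
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Everything the generator needs; a fixed seed reproduces the dataset bit-exactly."""

    seed: int = 0
    grid: ImageGrid = field(
        default_factory=lambda: ImageGrid((36, 36, 26), (2.8, 2.8, 2.0)))
    gtv_semiaxes_mm: tuple[float, float, float] = (21.0, 21.0, 17.0)  # ~31 cm^3
    gtv_center_mm: tuple[float, float, float] | None = None
    modalities: tuple[str, ...] = DEFAULT_MODALITIES
    target_spearman: np.ndarray | None = None  # default_target_spearman() if None
    smoothness_fwhm: float = 6.0  # mm
    noise: dict | None = field(default_factory=_default_noise)  # None => noiseless
    # marginal ranges of the truth maps
    suv_range: tuple[float, float] = (1.0, 15.0)
    tbr_range: tuple[float, float] = (0.8, 3.0)
    adc_range: tuple[float, float] = (0.6e-3, 2.0e-3)  # mm^2/s
    ktrans_range: tuple[float, float] = (0.01, 0.6)  # min^-1
    ve_range: tuple[float, float] = (0.05, 0.6)
    vp_range: tuple[float, float] = (0.01, 0.1)
    perfusion_range: tuple[float, float] = (2.0, 10.0)  # kBq/mL scale
    # acquisition emulation
    dce_time_step: float = 2.9  # s
    dce_duration: float = 300.0  # s
    dce_baseline_frames: int = 10
    dce_scale: float = 10.0  # enhancement per mM
    dce_baseline_signal: float = 100.0
    aif: AIFModel = field(default_factory=lambda: AIFModel(t0=29.0))
    washin_time_step: float = 15.0  # s
    washin_duration: float = 240.0  # s
    washin_tau: float = 60.0  # s
    # normalization context
    muscle_background: float = 10.0  # kBq/mL
    injected_activity_mbq: float = 357.0
    body_weight_kg: float = 75.0

    def resolved_target(self) -> np.ndarray:
        t = (default_target_spearman() if self.target_spearman is None
             else np.asarray(self.target_spearman, dtype=float))
        n = len(self.modalities)
        if t.shape != (n, n):
            raise ValueError(f"target matrix must be {n}x{n}")
        if not np.allclose(t, t.T, atol=1e-12):
            raise ValueError("target Spearman matrix must be symmetric")
        if not np.allclose(np.diag(t), 1.0):
            raise ValueError("target Spearman matrix must have unit diagonal")
        if np.any(np.abs(t) > 1):
            raise ValueError("target Spearman entries must lie in [-1, 1]")
        return t


@dataclass
class PhantomDataset:
    """One synthetic patient: noisy maps, dynamic series, masks, and the truth."""

    config: PhantomConfig
    maps: dict[str, ParametricMap]
    dce_series: DynamicSeries
    fmiso_washin_series: DynamicSeries
    masks: dict[str, ROIMask]
    truth: dict[str, ParametricMap]
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Latent correlated fields
# ---------------------------------------------------------------------------

def make_correlated_fields(n_fields: int, target_spearman: np.ndarray,
                           grid: ImageGrid, smoothness_fwhm: float,
                           seed) -> list[ParametricMap]:
    """Jointly Gaussian smooth fields with the requested pairwise Spearman.

    White Gaussian fields are mixed to Pearson 2 sin(pi rho_S/6), smoothed
    with one shared periodic Gaussian kernel (which preserves pointwise
    cross-correlation exactly) and standardized.  ``seed`` may be an int or
    a numpy Generator.
    """
    target = np.asarray(target_spearman, dtype=float)
    if target.shape != (n_fields, n_fields):
        raise ValueError(f"target matrix must be {n_fields}x{n_fields}")
    pearson = spearman_to_pearson(target)
    np.fill_diagonal(pearson, 1.0)
    evals, evecs = np.linalg.eigh(pearson)
    if evals.min() < -1e-10:
        v = evecs[:, 0]
        contrib = np.abs(np.outer(v, v) * pearson)
        np.fill_diagonal(contrib, 0.0)
        i, j = np.unravel_index(np.argmax(contrib), contrib.shape)
        raise ValueError(
            "matched Pearson matrix is not positive semi-definite "
            f"(min eigenvalue {evals.min():.3g}); pair ({i}, {j}) with target "
            f"Spearman {target[i, j]:+.2f} is the largest contributor"
        )
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((n_fields,) + grid.shape)
    mixed = np.tensordot(root, white, axes=(1, 0))
    if smoothness_fwhm > 0:
        sigma_vox = [smoothness_fwhm / 2.3548 / s for s in grid.spacing]
        mixed = np.stack([
            ndimage.gaussian_filter(f, sigma=sigma_vox, mode="wrap")
            for f in mixed
        ])
    out = []
    for i, f in enumerate(mixed):
        f = (f - f.mean()) / f.std()
        out.append(ParametricMap(grid, f, unit="z-score", name=f"latent_{i}"))
    return out


# ---------------------------------------------------------------------------
# Forward simulators
# ---------------------------------------------------------------------------

def _frame_schedule(time_step: float, duration: float):
    if time_step <= 0:
        raise ValueError("time_step must be > 0")
    n = int(np.floor(duration / time_step + 1e-9)) + 1
    starts = np.arange(n) * time_step
    return starts, np.full(n, time_step)


def simulate_dce_series(ktrans: ParametricMap, ve: ParametricMap,
                        vp: ParametricMap, aif: AIFModel,
                        time_step: float = 2.9, duration: float = 300.0,
                        baseline_frames: int = 10,
                        noise_sigma: float = 0.0,
                        scale: float = 10.0, baseline_signal: float = 100.0,
                        refine: int = 10,
                        rng: np.random.Generator | None = None) -> DynamicSeries:
    """Forward extended Tofts DCE signal series on the maps' grid.

    Per voxel: signal = baseline + scale * C_t(t) + Gaussian noise, with
    frames at multiples of ``time_step``.  Parameters outside physical
    bounds (negative, or v_e + v_p > 1) are rejected with the offending
    voxel index.
    """
    if not (ktrans.grid == ve.grid == vp.grid):
        raise ValueError("parameter maps must share one grid")
    kt, v_e, v_p = ktrans.values, ve.values, vp.values
    bad = (~np.isfinite(kt) | ~np.isfinite(v_e) | ~np.isfinite(v_p)
           | (kt < 0) | (v_e < 0) | (v_p < 0) | (v_e + v_p > 1.0 + 1e-12))
    if bad.any():
        idx = tuple(int(c) for c in np.argwhere(bad)[0])
        raise ValueError(f"non-physical Tofts parameters at voxel {idx}")
    starts, durations = _frame_schedule(time_step, duration)
    if baseline_frames >= 1 and starts[min(baseline_frames - 1, len(starts) - 1)] > aif.t0:
        raise ValueError(
            f"baseline frames extend past bolus arrival t0 = {aif.t0} s"
        )

    n_ref = (len(starts) - 1) * refine + 1
    grid_s = np.linspace(0.0, starts[-1], n_ref)
    dt_min = (grid_s[1] - grid_s[0]) / 60.0
    cp = aif(grid_s)

    frames = np.full((len(starts),) + ktrans.grid.shape, baseline_signal)
    active = (kt > 0) | (v_p > 0)
    if active.any():
        curves = tofts_curves_vectorized(kt[active], v_e[active], v_p[active],
                                         cp, dt_min)
        frames[:, active] += scale * curves[::refine]
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape)
    return DynamicSeries(ktrans.grid, frames, starts, durations, unit="signal")


def simulate_fmiso_washin(perfusion_surrogate: ParametricMap,
                          time_step: float = 15.0, duration: float = 240.0,
                          tau: float = 60.0,
                          noise: NoiseModel | None = None,
                          rng: np.random.Generator | None = None
                          ) -> DynamicSeries:
    """FMISO wash-in activity: perfusion-scaled (1 - exp(-t/tau)) per voxel.

    Frame values are exact frame averages of the analytic curve, so the
    0-4 min mean activity is precisely linear in the perfusion surrogate
    and inherits its rank order.
    """
    if duration < 240.0:
        raise ValueError("wash-in duration must cover the 0-4 min window")
    if tau <= 0:
        raise ValueError("tau must be positive")
    starts, durations = _frame_schedule(time_step, duration)
    ends = starts + durations
    # frame average of 1 - exp(-t/tau)
    frac = 1.0 - tau * (np.exp(-starts / tau) - np.exp(-ends / tau)) / durations
    frames = frac[:, None, None, None] * perfusion_surrogate.values[None]
    if noise is not None and noise.param > 0:
        if rng is None:
            rng = np.random.default_rng()
        frames = noise.apply(frames, rng)
    return DynamicSeries(perfusion_surrogate.grid, frames, starts, durations,
                         unit="kBq/mL")


def simulate_dw_signals(adc: ParametricMap, b_values: tuple[float, float],
                        s0: float = 1000.0
                        ) -> tuple[ParametricMap, ParametricMap]:
    """Monoexponential DW signals S(b) = s0 exp(-b ADC) at two b-values."""
    b1, b2 = (float(b) for b in b_values)
    if not b2 > b1 >= 0:
        raise ValueError(f"need b2 > b1 >= 0, got ({b1}, {b2})")
    if np.any(adc.values[np.isfinite(adc.values)] < 0):
        raise ValueError("ADC values must be >= 0")
    s_low = adc.with_values(s0 * np.exp(-b1 * adc.values), unit="signal",
                            name=f"S(b={b1:g})")
    s_high = adc.with_values(s0 * np.exp(-b2 * adc.values), unit="signal",
                             name=f"S(b={b2:g})")
    return s_low, s_high


# ---------------------------------------------------------------------------
# Phantom assembly
# ---------------------------------------------------------------------------

def _ellipsoid_mask(grid: ImageGrid, center_mm, semiaxes_mm) -> np.ndarray:
    xs, ys, zs = grid.world_coordinates()
    dx = (xs - center_mm[0]) / semiaxes_mm[0]
    dy = (ys - center_mm[1]) / semiaxes_mm[1]
    dz = (zs - center_mm[2]) / semiaxes_mm[2]
    return (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2) <= 1.0


def _box_mask(grid: ImageGrid, lo, hi) -> np.ndarray:
    m = np.zeros(grid.shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


def _to_range(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * u


def make_phantom(config: PhantomConfig) -> PhantomDataset:
    """Generate one synthetic patient dataset with known ground truth.

    Latent correlated fields are transformed through strictly monotone
    marginals into the modality ranges, masks are placed (ellipsoidal GTV,
    muscle box, carotid column), dynamic series are simulated forward from
    the truth maps, and per-modality noise is added last.
    """
    grid = config.grid
    target = config.resolved_target()
    labels = list(config.modalities)
    for required in ("fdg", "fmiso", "perfusion", "dce", "adc"):
        if required not in labels:
            raise ValueError(f"modalities must include {required!r}")

    ss = np.random.SeedSequence(config.seed)
    rng_fields, rng_noise, rng_dce, rng_washin = (
        np.random.default_rng(s) for s in ss.spawn(4))

    center = config.gtv_center_mm
    if center is None:
        center = tuple(grid.origin[a] + grid.spacing[a] * (grid.shape[a] - 1) / 2
                       for a in range(3))
    gtv_arr = _ellipsoid_mask(grid, center, config.gtv_semiaxes_mm)
    if not gtv_arr.any():
        raise ValueError("GTV ellipsoid contains no voxels on this grid")
    gtv = ROIMask(grid, gtv_arr, "GTV")

    # muscle box and carotid column in the corners, disjoint from the GTV
    muscle_arr = _box_mask(grid, (2, 2, 2), (8, 8, 8)) & ~gtv_arr
    carotid_arr = _box_mask(grid, (grid.shape[0] - 5, 3, 4),
                            (grid.shape[0] - 2, 6, grid.shape[2] - 4)) & ~gtv_arr
    muscle = ROIMask(grid, muscle_arr, "background-muscle")
    carotid = ROIMask(grid, carotid_arr, "carotid")

    warn_list: list[str] = []
    from .correlation import RegionSpec, partition_regions  # local: avoid cycle
    full_blocks = [r for r in partition_regions(gtv, RegionSpec(min_gtv_fraction=1.0))]
    if not full_blocks:
        msg = "GTV too small to contain one full 3x3x4 block"
        warnings.warn(msg, RuntimeWarning)
        warn_list.append(msg)

    fields = make_correlated_fields(len(labels), target, grid,
                                    config.smoothness_fwhm, rng_fields)
    u = {lab: ndtr(f.values) for lab, f in zip(labels, fields)}

    dose_per_g = config.injected_activity_mbq * 1e3 / (config.body_weight_kg * 1e3)
    b0 = config.muscle_background

    suv = _to_range(u["fdg"], *config.suv_range)
    fdg_act = np.where(gtv_arr, suv * dose_per_g, 1.0 * dose_per_g)

    tbr = _to_range(u["fmiso"], *config.tbr_range)
    fmiso_act = np.where(gtv_arr, tbr * b0, b0)

    adc = np.where(gtv_arr, _to_range(u["adc"], *config.adc_range), 1.0e-3)

    perf = np.where(gtv_arr, _to_range(u["perfusion"], *config.perfusion_range), 0.0)

    kt = np.where(gtv_arr, _to_range(u["dce"], *config.ktrans_range), 0.0)
    v_e = np.where(gtv_arr, _to_range(u["dce"], *config.ve_range), 0.0)
    v_p = np.where(gtv_arr, _to_range(u["dce"], *config.vp_range), 0.0)
    # carotid voxels carry pure plasma so the series contains the AIF itself
    v_p = np.where(carotid_arr, 1.0, v_p)
    kt = np.where(carotid_arr, 0.0, kt)
    v_e = np.where(carotid_arr, 0.0, v_e)

    truth = {
        "fdg_suv": ParametricMap(grid, np.where(gtv_arr, suv, 1.0), "SUV", "FDG_SUV"),
        "fmiso_tbr": ParametricMap(grid, np.where(gtv_arr, tbr, 1.0), "TBR",
                                   "FMISO_TBR"),
        "adc": ParametricMap(grid, adc, "mm^2/s", "ADC"),
        "perfusion": ParametricMap(grid, perf, "kBq/mL", "perfusion"),
        "ktrans": ParametricMap(grid, kt, "min^-1", "Ktrans"),
        "ve": ParametricMap(grid, v_e, "fraction", "ve"),
        "vp": ParametricMap(grid, v_p, "fraction", "vp"),
    }
    for lab, f in zip(labels, fields):
        truth[f"latent_{lab}"] = f

    noise = config.noise or {}

    def noisy(values, key):
        model = noise.get(key)
        if model is None:
            return np.array(values, copy=True)
        return model.apply(values, rng_noise)

    fdg_noisy = np.where(gtv_arr, noisy(suv, "fdg"), 1.0) * dose_per_g
    fmiso_noisy = np.where(gtv_arr, noisy(tbr, "fmiso"), 1.0) * b0
    adc_noisy = noisy(adc, "adc")
    maps = {
        "FDG": ParametricMap(grid, fdg_noisy, "kBq/mL", "FDG"),
        "FMISO": ParametricMap(grid, fmiso_noisy, "kBq/mL", "FMISO"),
        "ADC": ParametricMap(grid, adc_noisy, "mm^2/s", "ADC"),
        "Ktrans_truth": truth["ktrans"],
        "ve_truth": truth["ve"],
        "vp_truth": truth["vp"],
    }

    dce_noise = noise.get("dce_series")
    dce = simulate_dce_series(
        truth["ktrans"].with_values(kt), truth["ve"].with_values(v_e),
        truth["vp"].with_values(v_p), config.aif,
        time_step=config.dce_time_step, duration=config.dce_duration,
        baseline_frames=config.dce_baseline_frames,
        noise_sigma=dce_noise.param if dce_noise else 0.0,
        scale=config.dce_scale, baseline_signal=config.dce_baseline_signal,
        rng=rng_dce)

    washin = simulate_fmiso_washin(
        truth["perfusion"], time_step=config.washin_time_step,
        duration=config.washin_duration, tau=config.washin_tau,
        noise=noise.get("washin_series"), rng=rng_washin)

    return PhantomDataset(config=config, maps=maps, dce_series=dce,
                          fmiso_washin_series=washin,
                          masks={"GTV": gtv, "muscle": muscle, "carotid": carotid},
                          truth=truth, warnings=warn_list)
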