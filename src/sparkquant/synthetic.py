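"""Ground-truthed synthetic data for every pipeline stage.

Each generator emulates the statistical structure the downstream analysis
assumes, and records the ground truth needed to test the corresponding
estimator:

* nuclei holding a dilute phase plus condensates several-fold denser,
  appearing only above a saturation concentration (c_sat);
* two-droplet coalescence movies whose aspect ratio relaxes exponentially
  with timescale (eta/gamma) * ell;
* dissolution series that conserve per-cell total fluorescence;
* paired-channel puncta with a set colocalization probability;
* mitotic series coupling condensate dissolution to chromatin compaction;
* triplicate qPCR Ct tables under a target fold change;
* negative-binomial RNA-seq counts with a spiked differential set.

All randomness flows from ``numpy.random.default_rng`` seeded from the
ground-truth object, so identical seeds + parameters give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from sparkquant.images import ImageStack

# ---------------------------------------------------------------------------
# ground-truth parameter objects
# ---------------------------------------------------------------------------


@dataclass
class ImagingGroundTruth:
    """Parameters of the synthetic condensate-imaging model.

    Defaults reproduce the headline study conditions: c_sat of 40 nM and a
    condensed/dilute density contrast in the 5-10x range.
    """

    csat_nM: float = 40.0
    partition_ratio: float = 7.5
    condensate_radius_um: float = 0.5
    condensate_radius_sd_um: float = 0.1
    nucleus_radius_um: float = 4.0
    psf_sigma_um: float = 0.15
    pixel_size_um: float = 0.1
    intensity_per_nM: float = 10.0  # calibration slope, counts/pixel per nM
    background_counts: float = 100.0  # camera offset, counts/pixel
    photons_per_count: float = 0.25  # Poisson gain of the shot-noise model
    read_noise_sd: float = 2.0  # additive Gaussian read noise, counts
    max_condensate_fraction: float = 0.15  # nuclear area fraction at C >> c_sat
    seed: int = 0

    def __post_init__(self) -> None:
        if self.csat_nM <= 0:
            raise ValueError("csat_nM must be positive")
        if self.partition_ratio <= 1:
            raise ValueError("partition_ratio must exceed 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class FusionGroundTruth:
    """Parameters of the droplet-coalescence movie generator.

    ``inv_cap_velocity_s_per_um`` is the viscosity-to-surface-tension ratio
    eta/gamma; only this ratio (not eta and gamma separately) is
    identifiable from relaxation data, so only it is simulated.
    """

    inv_cap_velocity_s_per_um: float = 1.8
    n_events: int = 14
    radius_range_um: tuple[float, float] = (0.3, 1.0)
    initial_radii_um: list[tuple[float, float]] | None = None
    frame_interval_s: float = 0.5
    pixel_size_um: float = 0.05
    droplet_intensity: float = 1000.0
    background_counts: float = 50.0
    psf_sigma_um: float = 0.1
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inv_cap_velocity_s_per_um <= 0:
            raise ValueError("inv_cap_velocity_s_per_um must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


@dataclass
class CountsGroundTruth:
    """Parameters of the negative-binomial counts generator."""

    n_genes: int = 12000
    n_replicates: int = 3
    mean_log10_mu: float = 2.0  # baseline means lognormal around 100
    sd_log10_mu: float = 0.6
    dispersion: float = 0.05
    de_lfc: dict[str, float] = field(default_factory=dict)  # gene -> signed log2FC
    de_min_mean: float = 500.0  # floor on baseline mean of spiked genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")

    def gene_ids(self) -> list[str]:
        return [f"gene{i:05d}" for i in range(self.n_genes)]


@dataclass
class SyntheticCell:
    """One rendered cell: noisy stack, pre-noise arrays and truth masks."""

    stack: ImageStack
    clean: np.ndarray  # pre-noise, PSF-blurred image (incl. background)
    painted: np.ndarray  # pre-noise, pre-blur painted image (no background)
    nucleus_mask: np.ndarray
    condensate_mask: np.ndarray
    truth: dict


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in key]])


def _disc(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def _blur(img: np.ndarray, sigma_px: float) -> np.ndarray:
    if sigma_px <= 0:
        return img.astype(float)
    return ndimage.gaussian_filter(img.astype(float), sigma_px, mode="constant")


def _camera(clean: np.ndarray, gt, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on photon-scaled intensity + Gaussian read noise.

    Output is clipped to the 16-bit unsigned range (values above 65535
    saturate) but kept as float for downstream arithmetic.
    """
    ppc = gt.photons_per_count if hasattr(gt, "photons_per_count") else 0.0
    if ppc > 0:
        photons = rng.poisson(np.clip(clean, 0, None) * ppc)
        noisy = photons / ppc
    else:
        noisy = clean.astype(float)
    read_sd = getattr(gt, "read_noise_sd", getattr(gt, "noise_sd", 0.0))
    if read_sd > 0:
        noisy = noisy + rng.normal(0.0, read_sd, size=noisy.shape)
    return np.clip(noisy, 0.0, 65535.0)


def _place_condensates(
    rng: np.random.Generator,
    shape: tuple[int, int],
    nuc_center: tuple[float, float],
    nuc_radius_px: float,
    radii_px: np.ndarray,
) -> np.ndarray:
    """Non-overlapping discs inside the nucleus (best effort)."""
    mask = np.zeros(shape, dtype=bool)
    placed: list[tuple[float, float, float]] = []
    for r in radii_px:
        ok = False
        for _ in range(200):
            rho = (nuc_radius_px - r - 2) * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            cy = nuc_center[0] + rho * math.sin(theta)
            cx = nuc_center[1] + rho * math.cos(theta)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 1) ** 2 for py, px, pr in placed):
                ok = True
                break
        if not ok:  # crowded nucleus: accept the last position anyway
            pass
        placed.append((cy, cx, r))
        mask |= _disc(shape, (cy, cx), r)
    return mask


# ---------------------------------------------------------------------------
# condensate-bearing cells
# ---------------------------------------------------------------------------


def generate_cell_images(
    gt: ImagingGroundTruth, concentrations
) -> tuple[list[SyntheticCell], pd.DataFrame]:
    """Render one nucleus per concentration with recorded ground truth.

    Below ``gt.csat_nM`` the nucleus holds only the dilute phase; above it,
    condensates appear whose painted (pre-noise, pre-blur) mean intensity is
    exactly ``partition_ratio`` times the dilute mean. The condensate area
    fraction follows a lever-rule-like law ``f_max * (1 - c_sat / C)`` so
    the SPARK signal rises continuously from zero at c_sat. The dilute level
    is renormalised so the painted mean over the nucleus equals
    ``intensity_per_nM * C`` exactly — per-cell total intensity is
    proportional to concentration via the calibration slope.

    Returns the rendered cells and a truth table (one row per cell).
    """
    concentrations = np.asarray(list(concentrations), dtype=float)
    if concentrations.size == 0:
        raise ValueError("concentrations must be non-empty")
    if np.any(concentrations <= 0):
        raise ValueError("all concentrations must be positive")

    px = gt.pixel_size_um
    nuc_r_px = gt.nucleus_radius_um / px
    size = int(2 * nuc_r_px + 16)
    cells: list[SyntheticCell] = []
    rows = []
    for i, conc in enumerate(concentrations):
        rng = _rng(gt.seed, 101, i)
        center = (size / 2 + rng.uniform(-2, 2), size / 2 + rng.uniform(-2, 2))
        nucleus = _disc((size, size), center, nuc_r_px)
        n_nuc = int(nucleus.sum())

        cond_mask = np.zeros_like(nucleus)
        if conc > gt.csat_nM:
            frac = gt.max_condensate_fraction * (1.0 - gt.csat_nM / conc)
            target_area_um2 = frac * n_nuc * px**2
            mean_area = math.pi * gt.condensate_radius_um**2
            k = max(1, round(target_area_um2 / mean_area))
            radii_um = rng.normal(gt.condensate_radius_um, gt.condensate_radius_sd_um, k)
            radii_um = np.clip(radii_um, 2.5 * px, gt.nucleus_radius_um / 3)
            # shrink a lone condensate when the lever-rule area is tiny
            if k == 1 and target_area_um2 < mean_area:
                radii_um[:] = max(2.5 * px, math.sqrt(target_area_um2 / math.pi))
            cond_mask = _place_condensates(rng, (size, size), center, nuc_r_px, radii_um / px)
            cond_mask &= nucleus

        n_cond = int(cond_mask.sum())
        n_dil = n_nuc - n_cond
        # painted mean over nucleus == slope * C exactly
        dilute = gt.intensity_per_nM * conc * n_nuc / (n_dil + gt.partition_ratio * n_cond)
        dense = gt.partition_ratio * dilute

        painted = np.zeros((size, size))
        painted[nucleus] = dilute
        painted[cond_mask] = dense
        clean = _blur(painted, gt.psf_sigma_um / px) + gt.background_counts
        noisy = _camera(clean, gt, rng)

        spark_true = (dense * n_cond) / (dense * n_cond + dilute * n_dil) if n_cond else 0.0
        # count separated condensates in the rendered mask
        n_objects = int(ndimage.label(cond_mask)[1]) if n_cond else 0
        stack = ImageStack(noisy, "YX", pixel_size_um=px,
                           meta={"cell_id": i, "concentration_nM": float(conc)})
        cells.append(SyntheticCell(stack, clean, painted, nucleus, cond_mask,
                                   truth=dict(cell_id=i, concentration_nM=float(conc))))
        rows.append(dict(
            cell_id=i, concentration_nM=float(conc), n_condensates=n_objects,
            dilute_mean=dilute, condensate_mean=dense if n_cond else np.nan,
            spark_true=spark_true, condensate_area_fraction=n_cond / n_nuc,
        ))
    return cells, pd.DataFrame(rows)


def generate_dilution_table(
    gt: ImagingGroundTruth, concentrations_nM=None, noise_frac: float = 0.01
) -> pd.DataFrame:
    """Purified-fluorophore dilution series for the standard curve.

    Mean counts/pixel at each concentration follow the same slope and
    camera offset as the cell generator, with small multiplicative
    measurement noise.
    """
    if concentrations_nM is None:
        concentrations_nM = [5, 10, 20, 50, 100, 200, 500]
    rng = _rng(gt.seed, 202)
    conc = np.asarray(concentrations_nM, float)
    mean = gt.background_counts + gt.intensity_per_nM * conc
    mean = mean * (1.0 + rng.normal(0, noise_frac, size=conc.size))
    return pd.DataFrame({"concentration_nM": conc, "mean_intensity": mean})


# ---------------------------------------------------------------------------
# droplet fusion movies
# ---------------------------------------------------------------------------


def _ellipse(shape, center, a_px, b_px) -> np.ndarray:
    """Axis-aligned ellipse mask, major axis along x."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((xx - center[1]) / a_px) ** 2 + ((yy - center[0]) / b_px) ** 2 <= 1.0


def generate_fusion_movie(gt: FusionGroundTruth):
    """Render two-droplet coalescence movies with exponential AR relaxation.

    Each event starts with two separate droplets of radii (r1, r2) that
    approach and merge. From the onset frame the merged object is rendered
    as an area-conserving ellipse whose aspect ratio follows

        AR(t) = 1 + (AR0 - 1) * exp(-t / tau),   tau = (eta/gamma) * ell

    with ell the equivalent radius of the final fused droplet
    (volume-conserving, ``(r1^3 + r2^3)^(1/3)``) and AR0 = (r1+r2)/ell the
    elongation of the just-merged pair.

    Returns (movies, truth) where ``truth`` has one row per event with
    tau_s, ell_um, ar0 and the onset frame index.
    """
    rng = _rng(gt.seed, 303)
    if gt.initial_radii_um is not None:
        pairs = [tuple(map(float, p)) for p in gt.initial_radii_um]
    else:
        lo, hi = gt.radius_range_um
        pairs = [tuple(np.sort(rng.uniform(lo, hi, 2))[::-1]) for _ in range(gt.n_events)]

    px = gt.pixel_size_um
    movies: list[ImageStack] = []
    rows = []
    for ev, (r1, r2) in enumerate(pairs):
        if min(r1, r2) / px < 2.5:
            raise ValueError(
                f"event {ev}: radius {min(r1, r2):.3g} µm too small to render "
                f"at {px:.3g} µm pixels"
            )
        ell = (r1**3 + r2**3) ** (1.0 / 3.0)
        tau = gt.inv_cap_velocity_s_per_um * ell
        ar0 = (r1 + r2) / ell
        dt = gt.frame_interval_s

        n_pre = 3
        # run until the ellipse is within 2% of a sphere
        t_end = tau * math.log((ar0 - 1.0) / 0.02)
        n_post = max(6, int(math.ceil(t_end / dt)) + 2)

        span_um = 2.0 * (r1 + r2) + 3.0
        size = int(span_um / px)
        center = (size / 2.0, size / 2.0)
        frames = np.zeros((n_pre + n_post, size, size))
        ev_rng = _rng(gt.seed, 303, ev + 1)
        # keep approaching droplets separated by > 4 PSF widths so the
        # tracker sees two objects until the true onset frame
        gap_min = 4.0 * gt.psf_sigma_um + 2.0 * px
        for f in range(n_pre):
            gap = (r1 + r2) + gap_min * (n_pre - f)
            c1 = (center[0], center[1] - gap / 2 / px * 1.0)
            c2 = (center[0], center[1] + gap / 2 / px * 1.0)
            m = _disc(frames[f].shape, c1, r1 / px) | _disc(frames[f].shape, c2, r2 / px)
            frames[f][m] = gt.droplet_intensity
        for f in range(n_post):
            t = f * dt
            ar = 1.0 + (ar0 - 1.0) * math.exp(-t / tau)
            a = ell * math.sqrt(ar) / px
            b = ell / math.sqrt(ar) / px
            frames[n_pre + f][_ellipse(frames[0].shape, center, a, b)] = gt.droplet_intensity

        clean = np.stack([_blur(fr, gt.psf_sigma_um / px) for fr in frames])
        clean += gt.background_counts
        noisy = np.clip(clean + ev_rng.normal(0, gt.noise_sd, clean.shape), 0, 65535)
        movies.append(ImageStack(noisy, "TYX", pixel_size_um=px, frame_interval_s=dt,
                                 meta={"event_id": ev}))
        rows.append(dict(event_id=ev, r1_um=r1, r2_um=r2, ell_um=ell, tau_s=tau,
                         ar0=ar0, onset_frame=n_pre,
                         inv_cap_velocity_s_per_um=gt.inv_cap_velocity_s_per_um))
    return movies, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dissolution / mitosis time series
# ---------------------------------------------------------------------------


def generate_dissolution_series(
    gt: ImagingGroundTruth,
    concentration_nM: float = 200.0,
    decay_timescale_s: float = 60.0,
    n_frames: int = 20,
    frame_interval_s: float = 30.0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Time-lapse of condensate dissolution at constant total fluorescence.

    The condensate area fraction decays as ``f0 * exp(-t/tau_d)`` (an
    infinite timescale freezes the series); every frame the dilute level is
    renormalised so the painted per-cell total is constant to machine
    precision, mimicking dissolution without protein degradation.
    """
    if n_frames < 2:
        raise ValueError("series must cover >= 2 frames")
    if concentration_nM <= gt.csat_nM:
        raise ValueError("dissolution series needs a super-saturated cell")

    px = gt.pixel_size_um
    nuc_r_px = gt.nucleus_radius_um / px
    size = int(2 * nuc_r_px + 16)
    rng = _rng(gt.seed, 404)
    center = (size / 2, size / 2)
    nucleus = _disc((size, size), center, nuc_r_px)
    n_nuc = int(nucleus.sum())

    f0 = gt.max_condensate_fraction * (1.0 - gt.csat_nM / concentration_nM)
    mean_area = math.pi * gt.condensate_radius_um**2
    k = max(1, round(f0 * n_nuc * px**2 / mean_area))
    radii0_um = np.clip(
        rng.normal(gt.condensate_radius_um, gt.condensate_radius_sd_um, k),
        2.5 * px, gt.nucleus_radius_um / 3,
    )
    # fixed centres; radii shrink through time
    centres = []
    tmp = _place_condensates(rng, (size, size), center, nuc_r_px, radii0_um / px)
    lab, n = ndimage.label(tmp)
    for c in ndimage.center_of_mass(tmp, lab, range(1, n + 1)):
        centres.append(c)

    frames = np.zeros((n_frames, size, size))
    rows = []
    slope_total = gt.intensity_per_nM * concentration_nM * n_nuc
    for f in range(n_frames):
        t = f * frame_interval_s
        shrink = 1.0 if not np.isfinite(decay_timescale_s) else math.exp(-t / decay_timescale_s / 2.0)
        cond = np.zeros((size, size), bool)
        for c0, r0 in zip(centres, radii0_um[: len(centres)]):
            r = r0 / px * shrink
            if r >= 1.5:
                cond |= _disc((size, size), c0, r)
        cond &= nucleus
        n_cond = int(cond.sum())
        n_dil = n_nuc - n_cond
        dilute = slope_total / (n_dil + gt.partition_ratio * n_cond)
        dense = gt.partition_ratio * dilute
        frames[f][nucleus] = dilute
        frames[f][cond] = dense
        spark_true = dense * n_cond / slope_total
        rows.append(dict(frame=f, t_s=t, spark_true=spark_true,
                         total_painted=slope_total, n_condensate_px=n_cond))

    clean = np.stack([_blur(fr, gt.psf_sigma_um / px) for fr in frames]) + gt.background_counts
    noisy = _camera(clean, gt, rng)
    stack = ImageStack(noisy, "TYX", pixel_size_um=px, frame_interval_s=frame_interval_s)
    stack.meta["clean"] = clean
    return stack, pd.DataFrame(rows)


def generate_mitosis_series(
    gt: ImagingGroundTruth,
    dissolution_time_s: float,
    condensation_time_s: float,
    n_frames: int = 20,
    frame_interval_s: float = 60.0,
    interphase_radius_um: float = 4.0,
    mitotic_radius_um: float = 2.5,
) -> tuple[ImageStack, pd.DataFrame]:
    """Two-channel mitotic-entry movie: condensates (ch 0) + H2B (ch 1).

    Channel 0 condensates dissolve rapidly starting at
    ``dissolution_time_s``; channel 1 chromatin compacts (above-threshold
    area drops, total H2B conserved) at ``condensation_time_s``.
    """
    span = n_frames * frame_interval_s
    if not (0 <= dissolution_time_s <= span and 0 <= condensation_time_s <= span):
        raise ValueError("event times must lie within the series span")

    px = gt.pixel_size_um
    size = int(2 * interphase_radius_um / px + 16)
    rng = _rng(gt.seed, 505)
    center = (size / 2, size / 2)

    cond_ch = np.zeros((n_frames, size, size))
    h2b_ch = np.zeros((n_frames, size, size))
    nuc_r_px = interphase_radius_um / px
    nucleus = _disc((size, size), center, nuc_r_px)
    n_nuc = int(nucleus.sum())

    # static condensate layout, removed after the dissolution time
    k = 4
    radii_um = np.clip(rng.normal(gt.condensate_radius_um, gt.condensate_radius_sd_um, k),
                       2.5 * px, interphase_radius_um / 3)
    cond_mask = _place_condensates(rng, (size, size), center, nuc_r_px, radii_um / px) & nucleus
    n_cond = int(cond_mask.sum())

    conc = 4.0 * gt.csat_nM
    total = gt.intensity_per_nM * conc * n_nuc
    h2b_total = 500.0 * n_nuc

    rows = []
    for f in range(n_frames):
        t = f * frame_interval_s
        dissolved = t >= dissolution_time_s
        if dissolved:
            cond_ch[f][nucleus] = total / n_nuc
        else:
            n_dil = n_nuc - n_cond
            dilute = total / (n_dil + gt.partition_ratio * n_cond)
            cond_ch[f][nucleus] = dilute
            cond_ch[f][cond_mask] = gt.partition_ratio * dilute
        r_h2b = mitotic_radius_um if t >= condensation_time_s else interphase_radius_um
        h2b_mask = _disc((size, size), center, r_h2b / px)
        h2b_ch[f][h2b_mask] = h2b_total / h2b_mask.sum()
        rows.append(dict(frame=f, t_s=t, condensates_present=not dissolved,
                         chromatin_radius_um=r_h2b))

    sig = gt.psf_sigma_um / px
    clean = np.stack([
        np.stack([_blur(cond_ch[f], sig), _blur(h2b_ch[f], sig)]) for f in range(n_frames)
    ]) + gt.background_counts
    noisy = _camera(clean, gt, rng)
    stack = ImageStack(noisy, "TCYX", pixel_size_um=px, frame_interval_s=frame_interval_s)
    truth = pd.DataFrame(rows)
    truth.attrs["dissolution_time_s"] = dissolution_time_s
    truth.attrs["condensation_time_s"] = condensation_time_s
    return stack, truth


# ---------------------------------------------------------------------------
# two-channel colocalization fields
# ---------------------------------------------------------------------------


def generate_coloc_channels(
    n_cells: int,
    puncta_per_cell: int = 10,
    coloc_probability: float = 0.94,
    jitter_um: float = 0.2,
    seed: int = 0,
    n_extra_other: int = 2,
    gt: ImagingGroundTruth | None = None,
):
    """Paired-channel puncta fields with a set colocalization probability.

    Each reference (channel A) punctum receives a matched channel-B
    punctum, offset by at most ``jitter_um``, with probability
    ``coloc_probability``; ``n_extra_other`` unmatched B puncta per cell
    emulate the partner channel having its own population.

    Returns (stacks, truth): one two-channel ImageStack per cell and a
    truth table with per-cell matched counts.
    """
    if not 0.0 <= coloc_probability <= 1.0:
        raise ValueError("coloc_probability must lie in [0, 1]")
    gt = gt or ImagingGroundTruth(seed=seed)
    px = gt.pixel_size_um
    nuc_r_px = gt.nucleus_radius_um / px
    size = int(2 * nuc_r_px + 16)
    r_p = gt.condensate_radius_um / px

    stacks, rows = [], []
    for i in range(n_cells):
        rng = _rng(seed, 606, i)
        center = (size / 2, size / 2)
        nucleus = _disc((size, size), center, nuc_r_px)
        radii = np.full(puncta_per_cell, r_p)
        a_mask = np.zeros((size, size), bool)
        centres = []
        for _ in range(puncta_per_cell):
            for _try in range(300):
                rho = (nuc_r_px - r_p - 2) * math.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * math.pi)
                cy, cx = center[0] + rho * math.sin(th), center[1] + rho * math.cos(th)
                if all((cy - p[0]) ** 2 + (cx - p[1]) ** 2 > (3.0 * r_p) ** 2 for p in centres):
                    break
            centres.append((cy, cx))
            a_mask |= _disc((size, size), (cy, cx), r_p)

        b_mask = np.zeros((size, size), bool)
        n_matched = 0
        for cy, cx in centres:
            if rng.uniform() < coloc_probability:
                n_matched += 1
                rho = jitter_um / px * math.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * math.pi)
                b_mask |= _disc((size, size), (cy + rho * math.sin(th), cx + rho * math.cos(th)), r_p)
        for _ in range(n_extra_other):
            for _try in range(300):
                rho = (nuc_r_px - r_p - 2) * math.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * math.pi)
                cy, cx = center[0] + rho * math.sin(th), center[1] + rho * math.cos(th)
                if all((cy - p[0]) ** 2 + (cx - p[1]) ** 2 > (4.0 * r_p) ** 2 for p in centres):
                    break
            b_mask |= _disc((size, size), (cy, cx), r_p)

        frames = []
        for mask in (a_mask, b_mask):
            img = np.zeros((size, size))
            img[nucleus] = 200.0
            img[mask & nucleus] = 1600.0
            frames.append(_blur(img, gt.psf_sigma_um / px) + gt.background_counts)
        clean = np.stack(frames)
        noisy = _camera(clean, gt, rng)
        stacks.append(ImageStack(noisy, "CYX", pixel_size_um=px, meta={"cell_id": i}))
        rows.append(dict(cell_id=i, n_puncta=puncta_per_cell, n_matched=n_matched,
                         fraction_true=100.0 * n_matched / puncta_per_cell))
    return stacks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def generate_ct_table(
    fold_changes: dict[str, float],
    reference_gene: str = "ACTB",
    n_replicates: int = 3,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    conditions: tuple[str, str] = ("control", "treated"),
    base_ct: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Triplicate Ct tables under target fold changes.

    A fold change F of a target gene in the treated condition shifts its Ct
    by -log2(F) (ddCt = -log2(F)); replicate noise is Gaussian on each Ct.
    """
    for g, f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for {g} must be positive")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = _rng(seed, 707)
    base_ct = base_ct or {}
    ref_ct = base_ct.get(reference_gene, 18.0)

    rows = []
    for cond_i, cond in enumerate(conditions):
        for rep in range(n_replicates):
            sample = f"{cond}_{rep + 1}"
            rows.append(dict(sample=sample, condition=cond, gene=reference_gene,
                             ct=ref_ct + rng.normal(0, ct_noise_sd)))
            for gi, (gene, fc) in enumerate(sorted(fold_changes.items())):
                ct0 = base_ct.get(gene, 24.0 + gi)
                shift = -math.log2(fc) if cond_i == 1 else 0.0
                rows.append(dict(sample=sample, condition=cond, gene=gene,
                                 ct=ct0 + shift + rng.normal(0, ct_noise_sd)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, var = mu + disp*mu^2); Poisson when dispersion is 0."""
    mu = np.clip(mu, 1e-8, None)
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def generate_counts(gt: CountsGroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition NB counts matrix with a spiked differential set.

    Returns (counts, truth): counts is genes x samples with conditions
    named ``control`` / ``treated`` in the column names; truth records each
    gene's baseline mean and true signed log2FC (0 for nulls).
    """
    genes = gt.gene_ids()
    unknown = set(gt.de_lfc) - set(genes)
    if unknown:
        raise ValueError(f"de genes not in gene universe: {sorted(unknown)[:3]}...")
    rng = _rng(gt.seed, 808)
    mu0 = 10 ** rng.normal(gt.mean_log10_mu, gt.sd_log10_mu, gt.n_genes)
    lfc = np.zeros(gt.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, v in gt.de_lfc.items():
        i = gene_index[g]
        lfc[i] = v
        mu0[i] = max(mu0[i], gt.de_min_mean)

    mu_treat = mu0 * 2.0**lfc
    data = {}
    for rep in range(gt.n_replicates):
        data[f"control_{rep + 1}"] = _nb_draw(rng, mu0, gt.dispersion)
    for rep in range(gt.n_replicates):
        data[f"treated_{rep + 1}"] = _nb_draw(rng, mu_treat, gt.dispersion)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame({"gene": genes, "baseline_mean": mu0, "true_lfc": lfc,
                          "is_de": lfc != 0.0}).set_index("gene")
    return counts, truth


def generate_study_counts(
    n_genes: int = 12000,
    n_replicates: int = 3,
    dispersion: float = 0.05,
    n_responsive_up: int = 1226,
    n_responsive_down: int = 946,
    n_ps_up: int = 44,
    n_ps_down: int = 44,
    responsive_lfc: float = 2.0,
    ps_lfc: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Three-condition counts for the phase-separation transcriptome design.

    Conditions: ``control`` (no fusion protein), ``diffuse`` (protein
    present, condensates dissolved) and ``condensed`` (protein present and
    phase-separated). Responsive genes shift in both protein-bearing
    conditions vs control; the (much smaller) PS-regulated set additionally
    shifts between condensed and diffuse, emulating genes whose expression
    depends on condensate formation itself.

    Returns (counts, design, truth); design maps sample -> condition.
    """
    rng = _rng(seed, 909)
    base = CountsGroundTruth(n_genes=n_genes, n_replicates=n_replicates,
                             dispersion=dispersion, seed=seed)
    genes = base.gene_ids()
    mu0 = 10 ** rng.normal(base.mean_log10_mu, base.sd_log10_mu, n_genes)

    order = rng.permutation(n_genes)
    n_resp = n_responsive_up + n_responsive_down
    resp_idx = order[:n_resp]
    ps_idx = order[n_resp : n_resp + n_ps_up + n_ps_down]
    lfc_resp = np.zeros(n_genes)
    lfc_resp[resp_idx[:n_responsive_up]] = responsive_lfc
    lfc_resp[resp_idx[n_responsive_up:]] = -responsive_lfc
    lfc_ps = np.zeros(n_genes)
    lfc_ps[ps_idx[:n_ps_up]] = ps_lfc
    lfc_ps[ps_idx[n_ps_up:]] = -ps_lfc
    mu0[resp_idx] = np.maximum(mu0[resp_idx], 500.0)
    mu0[ps_idx] = np.maximum(mu0[ps_idx], 500.0)

    mu = {
        "control": mu0,
        "diffuse": mu0 * 2.0**lfc_resp,
        "condensed": mu0 * 2.0**lfc_resp * 2.0**lfc_ps,
    }
    data, design = {}, {}
    for cond in ("control", "diffuse", "condensed"):
        for rep in range(n_replicates):
            s = f"{cond}_{rep + 1}"
            data[s] = _nb_draw(rng, mu[cond], dispersion)
            design[s] = cond
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame({"gene": genes, "baseline_mean": mu0,
                          "responsive_lfc": lfc_resp, "ps_lfc": lfc_ps}).set_index("gene")
    return counts, pd.Series(design, name="condition"), truth
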