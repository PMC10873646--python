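"""Droplet-fusion tracking and inverse-capillary-velocity extraction.

Two coalescing liquid droplets relax to a sphere with an exponential
aspect-ratio law

    AR(t) = 1 + (AR0 - 1) * exp(-t / tau),

where the relaxation time scales with droplet size, tau = (eta/gamma) * ell.
Fitting tau per event and dividing by the event's length scale ell (the
equivalent radius of the final fused droplet) yields the inverse capillary
velocity eta/gamma in s/µm, a material property of the condensate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage import filters

from sparkquant.images import ImageStack

log = logging.getLogger(__name__)


@dataclass
class FusionEvent:
    event_id: int
    frames: np.ndarray  # frame indices (into the movie) from onset
    t_s: np.ndarray  # time since fusion onset, seconds
    aspect_ratio: np.ndarray
    ell_um: float  # equivalent radius of the final fused droplet

    def __post_init__(self) -> None:
        self.aspect_ratio = np.asarray(self.aspect_ratio, float)
        self.t_s = np.asarray(self.t_s, float)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(dict(event_id=self.event_id, frame=self.frames,
                                 t_s=self.t_s, aspect_ratio=self.aspect_ratio))


@dataclass(frozen=True)
class FusionFit:
    event_id: int
    tau_s: float
    ar0: float
    ell_um: float
    rms_residual: float

    @property
    def inv_cap_velocity_s_per_um(self) -> float:
        return self.tau_s / self.ell_um


def _frame_objects(frame: np.ndarray, threshold: float) -> np.ndarray:
    labels, _ = ndimage.label(frame > threshold, structure=np.ones((3, 3), int))
    return labels


def _aspect_ratio(frame: np.ndarray, mask: np.ndarray, background: float) -> float:
    """Major/minor axis ratio from intensity-weighted second moments."""
    w = np.clip(frame - background, 0, None) * mask
    total = w.sum()
    ys, xs = np.nonzero(mask)
    wv = w[ys, xs]
    cy = (wv * ys).sum() / total
    cx = (wv * xs).sum() / total
    dy, dx = ys - cy, xs - cx
    cov = np.array([[np.sum(wv * dy * dy), np.sum(wv * dy * dx)],
                    [np.sum(wv * dy * dx), np.sum(wv * dx * dx)]]) / total
    evals = np.linalg.eigvalsh(cov)
    evals = np.clip(evals, 1e-12, None)
    return float(np.sqrt(evals[1] / evals[0]))


def track_fusion_events(movie: ImageStack, min_object_px: int = 4) -> list[FusionEvent]:
    """Detect merge events and measure per-frame aspect ratio.

    An event opens at the first frame where two previously separate
    tracked objects form one connected component; the aspect ratio of the
    merged object is followed to the end of the movie (or the next
    topology change). Movies with no merges return an empty list.
    """
    if movie.n_frames < 3:
        raise ValueError("need >= 3 frames to track a fusion event")
    data = np.asarray(movie.data, float)
    thr = filters.threshold_otsu(data)
    background = float(np.median(data[data <= thr]))

    per_frame = [_frame_objects(f, thr) for f in data]
    counts = [int(l.max()) for l in per_frame]

    events: list[FusionEvent] = []
    t = movie.times_s() if movie.frame_interval_s else np.arange(movie.n_frames, dtype=float)
    f = 1
    while f < len(counts):
        if counts[f - 1] >= 2 and counts[f] == counts[f - 1] - 1:
            # find the merged component: overlaps >= 2 previous labels
            labels_prev, labels_now = per_frame[f - 1], per_frame[f]
            merged_label = None
            for lab in range(1, counts[f] + 1):
                prev_ids = np.unique(labels_prev[labels_now == lab])
                if (prev_ids > 0).sum() >= 2:
                    merged_label = lab
                    break
            if merged_label is None:
                f += 1
                continue
            frames, ars = [], []
            for g in range(f, len(counts)):
                lg = per_frame[g]
                if g > f and counts[g] != counts[f]:
                    break
                # follow the object overlapping the previous merged mask
                if g == f:
                    mask = lg == merged_label
                else:
                    ids, n_over = np.unique(lg[mask], return_counts=True)
                    sel = ids > 0
                    ids, n_over = ids[sel], n_over[sel]
                    if ids.size == 0:
                        break
                    mask = lg == ids[np.argmax(n_over)]
                if mask.sum() < min_object_px:
                    break
                frames.append(g)
                ars.append(_aspect_ratio(data[g], mask, background))
            ell = float(np.sqrt(mask.sum() / np.pi) * movie.pixel_size_um)
            ars = np.clip(np.asarray(ars), 1.0, None)
            events.append(FusionEvent(
                event_id=len(events), frames=np.asarray(frames),
                t_s=t[frames] - t[frames[0]], aspect_ratio=ars, ell_um=ell))
            f = frames[-1] + 1
        else:
            f += 1
    return events


def fit_relaxation(event: FusionEvent, rms_tolerance: float = 0.1) -> FusionFit:
    """Single-exponential fit AR(t) = 1 + (AR0 - 1) exp(-t/tau).

    Raises on degenerate traces (already-spherical objects) and on fits
    whose RMS residual exceeds ``rms_tolerance`` AR units — the automated
    analogue of discarding unusable events by eye.
    """
    if event.t_s.size < 4:
        raise ValueError("need >= 4 post-onset frames to fit relaxation")
    ar = event.aspect_ratio
    if ar.max() - 1.0 < 0.05:
        raise ValueError("degenerate trace: aspect ratio never leaves 1")

    def model(t, ar0, tau):
        return 1.0 + (ar0 - 1.0) * np.exp(-t / tau)

    t_half = max(event.t_s[-1] / 4.0, event.t_s[1] if event.t_s.size > 1 else 1.0)
    popt, _ = curve_fit(model, event.t_s, ar, p0=[max(ar[0], 1.05), t_half],
                        bounds=([1.0 + 1e-6, 1e-6], [np.inf, np.inf]), maxfev=10000)
    ar0, tau = float(popt[0]), float(popt[1])
    rms = float(np.sqrt(np.mean((model(event.t_s, *popt) - ar) ** 2)))
    if rms > rms_tolerance:
        raise ValueError(f"event {event.event_id}: RMS residual {rms:.3f} exceeds "
                         f"tolerance {rms_tolerance}")
    return FusionFit(event_id=event.event_id, tau_s=tau, ar0=ar0,
                     ell_um=event.ell_um, rms_residual=rms)


def fit_all(events: list[FusionEvent], rms_tolerance: float = 0.1) -> list[FusionFit]:
    """fit_relaxation over events, excluding (and logging) failures."""
    fits = []
    for ev in events:
        try:
            fits.append(fit_relaxation(ev, rms_tolerance))
        except (ValueError, RuntimeError) as exc:
            log.warning("excluding fusion event %d: %s", ev.event_id, exc)
    return fits


def summarize_inverse_capillary_velocity(fits: list[FusionFit]) -> dict:
    """Arithmetic mean and sample SD of tau/ell over events."""
    if len(fits) < 2:
        raise ValueError("need >= 2 successful fits to summarize")
    v = np.array([f.inv_cap_velocity_s_per_um for f in fits])
    return dict(mean_s_per_um=float(v.mean()), sd_s_per_um=float(v.std(ddof=1)),
                n_events=int(v.size))
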