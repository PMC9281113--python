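"""Hypointense plaque-candidate detection on the short-TE echo, with
long-TE false-positive elimination.

Stage one scans the detection echo (the shortest TE, where brain structure
and dark foci are both visible) slice by slice: a voxel seeds a candidate
when it is inside the brain mask and darker than ``alpha`` times the median
of its surrounding in-plane annulus (a window x window square with the 3x3
core removed).  Adjacent seed voxels merge into one candidate anchored at
its darkest voxel.

Stage two exploits SPIO physics: iron shortens T2*, so a genuine plaque's
contrast ratio to surrounding tissue deepens as exp(-delta_R2* * TE) with
echo time, whereas single-echo noise does not.  A candidate survives only
if (a) its contrast at the largest TE is deeper than at the detection TE by
at least ``depth_margin`` and (b) its site-mean intensity series is
decay-consistent (r-squared of the log-linear fit >= ``min_r2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phantom import MultiEchoVolume
from .relaxometry import DecayFit, fit_decay

__all__ = [
    "CandidateSite",
    "annulus_footprint",
    "make_brain_mask",
    "detect_candidates",
    "filter_by_long_te",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class CandidateSite:
    """One locally hypointense site and its per-echo contrast evidence."""

    voxel_index: tuple[int, int, int]  # (slice, row, col), darkest voxel
    member_voxels: list[tuple[int, int, int]]  # merged in-plane seed voxels
    contrast_per_echo: tuple[float, ...] = ()  # site mean / annulus median, per TE
    decay_fit: DecayFit | None = None
    status: str = "pending"  # pending | kept | rejected_noise | rejected_mask

    @property
    def n_voxels(self) -> int:
        return len(self.member_voxels)


def annulus_footprint(window: int, core: int = 3) -> np.ndarray:
    """window x window square footprint with the central core x core removed."""
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be odd and >= 5")
    fp = np.ones((window, window), dtype=bool)
    lo = (window - core) // 2
    fp[lo:lo + core, lo:lo + core] = False
    return fp


def make_brain_mask(volume: np.ndarray) -> np.ndarray:
    """Foreground (brain) mask of a short-TE volume.

    Otsu two-class split, largest 26-connected component, slice-wise hole
    filling and 3x3 in-plane morphological closing.  Deterministic; raises
    on constant input where no split exists.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.size == 0 or np.ptp(vol) == 0:
        raise ValueError("cannot mask an empty or constant volume")
    thr = threshold_otsu(vol)
    fg = vol > thr
    if not fg.any():
        raise ValueError("threshold produced an empty mask")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))) + 1
    mask = labels == largest
    for z in range(mask.shape[0]):
        mask[z] = ndimage.binary_fill_holes(mask[z])
        mask[z] = ndimage.binary_closing(mask[z], structure=_EIGHT)
    return mask


def _annulus_median_slices(volume: np.ndarray, window: int) -> np.ndarray:
    """Per-voxel in-plane annulus median for every slice of a 3-D stack."""
    fp = annulus_footprint(window)[None, :, :]
    return ndimage.median_filter(volume, footprint=fp, mode="nearest")


def _annulus_median_at(slice_img: np.ndarray, row: int, col: int, window: int) -> float:
    """Annulus median around one voxel (edge-replicated like the filtered path).

    The annulus holds an even number of voxels; the median is the rank
    ``n // 2`` order statistic, matching the rank-filter path exactly.
    """
    fp = annulus_footprint(window)
    h = window // 2
    rows = np.clip(np.arange(row - h, row + h + 1), 0, slice_img.shape[0] - 1)
    cols = np.clip(np.arange(col - h, col + h + 1), 0, slice_img.shape[1] - 1)
    vals = slice_img[np.ix_(rows, cols)][fp]
    return float(np.partition(vals, vals.size // 2)[vals.size // 2])


def detect_candidates(
    volume_te10: np.ndarray,
    mask: np.ndarray,
    window: int = 7,
    alpha: float = 0.6,
    mev: MultiEchoVolume | None = None,
) -> list[CandidateSite]:
    """Locate locally hypointense sites on the detection-echo volume.

    A voxel seeds a candidate iff it lies in ``mask`` and its intensity is
    strictly below ``alpha`` times its in-plane annulus median.  Seeds that
    are 8-connected within a slice merge into a single candidate whose
    anchor is the darkest member voxel (ties to the lowest
    ``(slice, row, col)``).  When ``mev`` is given, each candidate also gets
    its per-echo contrast ratios and site-mean decay fit, ready for
    :func:`filter_by_long_te`.
    """
    vol = np.asarray(volume_te10, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if window > min(vol.shape[1], vol.shape[2]):
        raise ValueError("window exceeds the slice dimensions")
    annulus_footprint(window)  # validates window
    if mask.shape != vol.shape:
        raise ValueError("mask shape must match the volume")

    med = _annulus_median_slices(vol, window)
    seeds = mask & (vol < alpha * med) & (med > 0)

    candidates: list[CandidateSite] = []
    for z in range(vol.shape[0]):
        labels, n = ndimage.label(seeds[z], structure=_EIGHT)
        for lab in range(1, n + 1):
            rr, cc = np.nonzero(labels == lab)
            members = [(z, int(r), int(c)) for r, c in zip(rr, cc)]
            vals = vol[z, rr, cc]
            dark = sorted(
                (v, m) for v, m in zip(vals, members)
            )[0][1]  # darkest voxel, lexicographic tie-break
            candidates.append(CandidateSite(voxel_index=dark, member_voxels=sorted(members)))
    candidates.sort(key=lambda c: c.voxel_index)

    if mev is not None:
        _attach_evidence(candidates, mev, window, _noise_floor(mev, mask))
    return candidates


def _noise_floor(mev: MultiEchoVolume, mask: np.ndarray) -> np.ndarray:
    """Per-echo magnitude noise floor, estimated from outside-mask (air) voxels.

    Magnitude MRI never decays to zero: air voxels carry Rayleigh-distributed
    noise whose level the per-site decay fit must not mistake for signal.
    Returns zeros when the mask leaves no air to measure.
    """
    outside = ~mask
    if not outside.any():
        return np.zeros(len(mev.volumes))
    return np.array([float(np.median(vol[outside])) for vol in mev.volumes])


def _attach_evidence(
    candidates: list[CandidateSite],
    mev: MultiEchoVolume,
    window: int,
    noise_floor: np.ndarray | None = None,
) -> None:
    """Fill per-echo contrast ratios and the site-mean decay fit in place.

    Echoes where the site mean has sunk below twice the air noise floor are
    excluded from the decay fit (standard practice in R2* estimation: the
    Rician floor flattens the tail and would spoil the log-linear fit), but
    always keeping at least the first two echoes.
    """
    floor = np.zeros(len(mev.volumes)) if noise_floor is None else noise_floor
    te = np.asarray(mev.te_list, dtype=float)
    for cand in candidates:
        z, r, c = cand.voxel_index
        zz = np.array([m[0] for m in cand.member_voxels])
        rr = np.array([m[1] for m in cand.member_voxels])
        cc = np.array([m[2] for m in cand.member_voxels])
        contrasts, means = [], []
        for vol in mev.volumes:
            site_mean = float(vol[zz, rr, cc].mean())
            med = _annulus_median_at(vol[z], r, c, window)
            contrasts.append(site_mean / med if med > 0 else np.inf)
            means.append(site_mean)
        cand.contrast_per_echo = tuple(contrasts)
        means = np.asarray(means)
        above = means >= 2.0 * floor
        above[:2] = True
        cand.decay_fit = fit_decay(means[above], te[above])


def filter_by_long_te(
    candidates: list[CandidateSite],
    mev: MultiEchoVolume,
    mask: np.ndarray,
    min_r2: float = 0.9,
    depth_margin: float = 0.05,
    window: int = 7,
) -> list[CandidateSite]:
    """Keep candidates whose hypointensity behaves like SPIO, reject the rest.

    Keeps a candidate iff its contrast ratio at the largest TE is at most
    its detection-TE contrast minus ``depth_margin`` (deepening
    hypointensity) AND its site-mean decay fit has r-squared >= ``min_r2``.
    Everything else is marked ``rejected_noise``.  The kept set is a subset
    of the input and independent of input order.
    """
    if len(mev.te_list) < 2:
        raise ValueError("long-TE filtering needs at least two echoes")
    floor = _noise_floor(mev, mask)
    kept = []
    for cand in candidates:
        if not cand.contrast_per_echo:
            _attach_evidence([cand], mev, window, floor)
        z, r, c = cand.voxel_index
        if not mask[z, r, c]:
            cand.status = "rejected_mask"
            continue
        deepens = cand.contrast_per_echo[-1] <= cand.contrast_per_echo[0] - depth_margin
        consistent = cand.decay_fit.r_squared >= min_r2
        if deepens and consistent:
            cand.status = "kept"
            kept.append(cand)
        else:
            cand.status = "rejected_noise"
    return kept
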