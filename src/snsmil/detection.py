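"""Candidate identification and shot-noise quality scoring.

Per frame: locally brightest pixels within the Airy radius become candidates;
non-isolated candidates (closer than one Airy radius to each other) are
discarded; each survivor gets a region of interest (ROI) of pixels inside the
theoretical PSF width whose value exceeds the local background, and is scored
with three statistics:

* ``SNR_eff`` — mean per-pixel signal-to-noise ratio over the ROI. A
  single-pixel spike maximises this but not CNR_eff.
* ``CNR_eff`` — total ROI signal over the shot noise of the *whole* PSF disk,
  ``ΣS / (F·√Σ_disk N_bg)``. A broad, diffuse signal maximises this but not
  SNR_eff.
* ``Q = min(SNR_eff, CNR_eff)`` — the single quality metric thresholded by the
  user; it penalises both spike-like and broadened false positives.

Acceptance requires the Rose criterion (CNR_eff strictly greater than 3, fixed)
and ``Q ≥ q_threshold`` (the one user parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .camera import CameraOpticsConfig

__all__ = [
    "Candidate",
    "find_local_maxima",
    "reject_nonisolated",
    "select_roi",
    "score_candidate",
    "filter_candidates",
    "ROSE_CNR_MIN",
]

ROSE_CNR_MIN = 3.0  # Rose criterion; not user-configurable


@dataclass
class Candidate:
    """A tentative emitter with its ROI and quality scores."""

    frame_index: int
    peak: tuple[int, int]
    roi_pixels: list[tuple[int, int]] = field(default_factory=list)
    disk_pixels: list[tuple[int, int]] = field(default_factory=list)
    signal_electrons: np.ndarray | None = None
    local_background: np.ndarray | None = None
    snr_eff: float = 0.0
    cnr_eff: float = 0.0
    q: float = 0.0
    status: str = "candidate"

    def reject(self, reason: str) -> None:
        # status transitions are monotone: a rejected candidate stays rejected
        if self.status in ("candidate", "accepted"):
            self.status = reason


def _disk_offsets(radius: float) -> np.ndarray:
    """Integer offsets (dr, dc) with Euclidean norm <= radius, excluding (0,0)."""
    r = int(ceil(radius))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    mask = (dr**2 + dc**2 <= radius**2) & ~((dr == 0) & (dc == 0))
    return np.stack([dr[mask], dc[mask]], axis=1)


def find_local_maxima(smoothed_frame: np.ndarray, airy_radius_px: float) -> list[tuple[int, int]]:
    """Pixels that are the maximum within one Airy radius of themselves.

    Only in-frame neighbours count.  An equal-valued connected plateau counts
    as one peak — represented by its lexicographically smallest member — and
    only when no pixel within the Airy radius of *any* member exceeds it, so a
    flat region bordering a brighter structure yields no peak at all.
    """
    if airy_radius_px < 1:
        raise ValueError("airy_radius_px must be >= 1")
    img = np.asarray(smoothed_frame, dtype=np.float64)
    r = int(ceil(airy_radius_px))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    footprint = dr**2 + dc**2 <= airy_radius_px**2
    local_max = ndimage.maximum_filter(img, footprint=footprint,
                                       mode="constant", cval=-np.inf)
    is_max = img == local_max  # no strictly greater pixel within the disk
    nrow, ncol = img.shape
    visited = np.zeros_like(is_max)
    peaks: list[tuple[int, int]] = []
    for rr, cc in np.argwhere(is_max):
        if visited[rr, cc]:
            continue
        # flood the equal-valued 8-connected plateau containing (rr, cc)
        v = img[rr, cc]
        members = [(int(rr), int(cc))]
        visited[rr, cc] = True
        stack = [(int(rr), int(cc))]
        all_max = True
        while stack:
            r0, c0 = stack.pop()
            all_max &= bool(is_max[r0, c0])
            for r2 in range(max(r0 - 1, 0), min(r0 + 2, nrow)):
                for c2 in range(max(c0 - 1, 0), min(c0 + 2, ncol)):
                    if not visited[r2, c2] and img[r2, c2] == v:
                        visited[r2, c2] = True
                        members.append((r2, c2))
                        stack.append((r2, c2))
        if all_max:
            peaks.append(min(members))
    return sorted(peaks)


def reject_nonisolated(peaks: list[tuple[int, int]],
                       airy_radius_px: float) -> list[tuple[int, int]]:
    """Discard every peak with another peak strictly closer than the Airy radius.

    Both members of a close pair go: an overlapping pair cannot be fitted as a
    single emitter.
    """
    if len(peaks) < 2:
        return list(peaks)
    pts = np.asarray(peaks, dtype=float)
    tree = cKDTree(pts)
    bad = set()
    for i, j in tree.query_pairs(airy_radius_px):
        if np.hypot(*(pts[i] - pts[j])) < airy_radius_px:
            bad.add(i)
            bad.add(j)
    return [p for k, p in enumerate(peaks) if k not in bad]


def select_roi(frame: np.ndarray, background_map: np.ndarray,
               peak: tuple[int, int], psf_sigma_px: float,
               frame_index: int = 0) -> Candidate:
    """Build the candidate ROI around a peak.

    The ROI is every pixel within ``ceil(psf_sigma_px)`` (Euclidean) of the
    peak whose value exceeds the local background; the peak itself is always a
    member. ``signal_electrons`` is frame − background over the ROI, clamped at
    zero. Peaks too close to the border for the disk to fit are rejected with
    status ``rejected_edge``.
    """
    img = np.asarray(frame, dtype=np.float64)
    bg = np.asarray(background_map, dtype=np.float64)
    r = int(ceil(psf_sigma_px))
    pr, pc = peak
    cand = Candidate(frame_index=frame_index, peak=(int(pr), int(pc)))
    nrow, ncol = img.shape
    if pr < r + 1 or pc < r + 1 or pr >= nrow - r - 1 or pc >= ncol - r - 1:
        cand.reject("rejected_edge")
        return cand
    disk = [(pr, pc)] + [(pr + dr, pc + dc) for dr, dc in _disk_offsets(r)]
    roi = [(rr, cc) for rr, cc in disk
           if (rr, cc) == (pr, pc) or img[rr, cc] > bg[rr, cc]]
    rows = np.array([p[0] for p in roi])
    cols = np.array([p[1] for p in roi])
    cand.roi_pixels = roi
    cand.disk_pixels = disk
    cand.signal_electrons = np.clip(img[rows, cols] - bg[rows, cols], 0.0, None)
    cand.local_background = bg[rows, cols]
    return cand


def score_candidate(candidate: Candidate, background_map: np.ndarray,
                    config: CameraOpticsConfig) -> Candidate:
    """Fill in SNR_eff, CNR_eff and Q for a candidate with a selected ROI.

    CNR_eff's denominator aggregates background shot noise over the *full*
    theoretical PSF disk, not only the ROI, so that narrowing the ROI (a spike)
    cannot inflate the contrast score.
    """
    if candidate.status != "candidate":
        return candidate
    if not candidate.roi_pixels:
        candidate.snr_eff = candidate.cnr_eff = candidate.q = 0.0
        candidate.reject("rejected_q")
        return candidate
    f = config.excess_noise_factor
    s = candidate.signal_electrons
    n_bg = candidate.local_background
    candidate.snr_eff = float(np.mean(s / (f * np.sqrt(n_bg))))
    bg = np.asarray(background_map, dtype=np.float64)
    rows = np.array([p[0] for p in candidate.disk_pixels])
    cols = np.array([p[1] for p in candidate.disk_pixels])
    disk_bg = float(np.sum(bg[rows, cols]))
    candidate.cnr_eff = float(np.sum(s) / (f * np.sqrt(disk_bg)))
    candidate.q = min(candidate.snr_eff, candidate.cnr_eff)
    return candidate


def filter_candidates(candidates: list[Candidate], q_threshold: float) -> list[Candidate]:
    """Apply the Rose criterion and the user's Q threshold.

    A candidate survives iff ``CNR_eff > 3`` (strict; the Rose criterion is
    fixed) and ``Q ≥ q_threshold``. Rejection reasons are recorded on the
    candidates; the returned list holds only the accepted ones.
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    accepted = []
    for cand in candidates:
        if cand.status != "candidate":
            continue
        if not cand.cnr_eff > ROSE_CNR_MIN:
            cand.reject("rejected_rose")
        elif cand.q < q_threshold:
            cand.reject("rejected_q")
        else:
            cand.status = "accepted"
            accepted.append(cand)
    return accepted
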