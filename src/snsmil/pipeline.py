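"""End-to-end orchestration: stack reading, per-frame processing, outputs.

Every frame is processed independently (the streaming design: convert to
photoelectrons, estimate the background, smooth, find and filter candidates,
score, threshold, fit, filter fits) and its accepted localizations appended to
the output table, so memory scales with the frame size, never the stack
length, and frames may be processed in any order.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .camera import CameraOpticsConfig, airy_radius_px, psf_sigma_px, to_photoelectrons
from .background import estimate_background, smooth_frame, DEFAULT_SMOOTH_SIGMA, DEFAULT_FLOOR
from .detection import (Candidate, find_local_maxima, reject_nonisolated,
                        select_roi, score_candidate, filter_candidates, ROSE_CNR_MIN)
from .fitting import GaussianModelSpec, fit_gaussian, width_filter, fit_quality_filter

__all__ = ["PipelineConfig", "read_stack", "localize_frames", "localize_file",
           "LOCALIZATION_COLUMNS", "CANDIDATE_COLUMNS", "load_config"]

log = logging.getLogger(__name__)

LOCALIZATION_COLUMNS = ["frame", "x_nm", "y_nm", "x_px", "y_px", "sigma_x_px",
                        "sigma_y_px", "amplitude_e", "offset_e", "photons_e",
                        "pearson_r", "q", "status"]
CANDIDATE_COLUMNS = ["frame", "row", "col", "snr_eff", "cnr_eff", "q", "status"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of a localization run."""

    camera: CameraOpticsConfig = field(default_factory=CameraOpticsConfig)
    q_threshold: float = 2.0         # the single mandatory user parameter
    model: int = 1                   # Gaussian fit model 1/2/3
    pwt: float = 3.0                 # PSF-width tolerance (models 2-3)
    pearson_r_min: float = 0.5
    smooth_sigma_px: float = DEFAULT_SMOOTH_SIGMA
    background_window_factor: float = 1.0
    background_floor: float = DEFAULT_FLOOR

    def model_spec(self) -> GaussianModelSpec:
        return GaussianModelSpec(model=self.model, pwt=self.pwt,
                                 theoretical_sigma_px=psf_sigma_px(self.camera))


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file plus overrides.

    Camera keys (``bias_offset``, ``effective_gain``, ``excess_noise_factor``,
    ``pixel_size_nm``, ``magnification``, ``numerical_aperture``,
    ``emission_wavelength_nm``) may appear at the top level or under
    ``camera:``; all other keys map onto :class:`PipelineConfig` fields.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    cam_fields = CameraOpticsConfig.__dataclass_fields__.keys()
    cam_kw = dict(data.pop("camera", {}))
    for k in list(data):
        if k in cam_fields:
            cam_kw[k] = data.pop(k)
    pipe_fields = PipelineConfig.__dataclass_fields__.keys()
    unknown = set(data) - set(pipe_fields)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(camera=CameraOpticsConfig(**cam_kw), **data)


def read_stack(path: str | Path) -> Iterator[np.ndarray]:
    """Yield frames of a multi-page grayscale TIFF one at a time (streaming)."""
    with tifffile.TiffFile(path) as tif:
        expected = None
        meta = tif.shaped_metadata
        if meta and "shape" in meta[0]:
            s = meta[0]["shape"]
            expected = s[0] if len(s) == 3 else 1 if len(s) == 2 else None
        shape = None
        n = 0
        for i, page in enumerate(tif.pages):
            try:
                frame = page.asarray()
            except Exception as exc:
                raise IOError(f"unreadable TIFF page {i} in {path}: {exc}") from exc
            if frame.ndim != 2:
                raise IOError(f"TIFF page {i} in {path} is not 2D grayscale")
            if shape is None:
                shape = frame.shape
            elif frame.shape != shape:
                raise IOError(f"ragged TIFF page {i} in {path}: "
                              f"{frame.shape} != {shape}")
            n += 1
            yield frame
        # a truncated IFD chain silently shortens the page list; the declared
        # frame count (when the file carries one) catches that
        if expected is not None and n != expected:
            raise IOError(f"truncated stack {path}: only {n} of {expected} "
                          f"pages readable (failed at page {n})")


def process_frame(raw_frame: np.ndarray, frame_index: int, config: PipelineConfig
                  ) -> tuple[list[dict], list[Candidate]]:
    """Run the full per-frame chain; returns localization rows and all candidates."""
    cam = config.camera
    r_airy = airy_radius_px(cam)
    sigma = psf_sigma_px(cam)
    spec = config.model_spec()

    pframe = to_photoelectrons(raw_frame, cam, frame_index)
    bg = estimate_background(pframe, cam, config.background_window_factor,
                             config.background_floor)
    smoothed = smooth_frame(pframe, config.smooth_sigma_px)

    peaks = find_local_maxima(smoothed, r_airy)
    isolated = set(reject_nonisolated(peaks, r_airy))
    candidates: list[Candidate] = []
    for peak in peaks:
        if peak not in isolated:
            cand = Candidate(frame_index=frame_index, peak=peak)
            cand.reject("rejected_nonisolated")
            candidates.append(cand)
            continue
        cand = select_roi(smoothed, bg.values, peak, sigma, frame_index)
        score_candidate(cand, bg.values, cam)
        candidates.append(cand)
    accepted = filter_candidates(candidates, config.q_threshold)

    rows = []
    for cand in accepted:
        loc = fit_gaussian(cand, pframe.pixels, spec, cam)
        width_filter(loc, spec)
        fit_quality_filter(loc, cand, pframe.pixels, spec, config.pearson_r_min)
        if loc.status == "accepted":
            rows.append(dict(frame=frame_index, x_nm=loc.x_nm, y_nm=loc.y_nm,
                             x_px=loc.x_px, y_px=loc.y_px,
                             sigma_x_px=loc.sigma_x_px, sigma_y_px=loc.sigma_y_px,
                             amplitude_e=loc.amplitude, offset_e=loc.offset,
                             photons_e=loc.photons, pearson_r=loc.pearson_r,
                             q=loc.q, status=loc.status))
        else:
            cand.status = loc.status
    return rows, candidates


def localize_frames(frames: Iterable[np.ndarray], config: PipelineConfig,
                    collect_candidates: bool = False
                    ) -> tuple[pd.DataFrame, dict, pd.DataFrame | None]:
    """Localize every frame of an iterable; returns (table, manifest, candidates)."""
    all_rows: list[dict] = []
    cand_rows: list[dict] = []
    per_frame_counts: list[dict] = []
    t0 = time.perf_counter()
    n_frames = 0
    for i, raw in enumerate(frames):
        try:
            rows, candidates = process_frame(raw, i, config)
        except (ValueError, FloatingPointError) as exc:
            log.error("frame %d failed (%s); skipping", i, exc)
            per_frame_counts.append(dict(frame=i, error=str(exc)))
            continue
        all_rows.extend(rows)
        n_frames += 1
        statuses = pd.Series([c.status for c in candidates])
        per_frame_counts.append(
            dict(frame=i, candidates=len(candidates), localized=len(rows),
                 **statuses.value_counts().to_dict()))
        if collect_candidates:
            cand_rows.extend(dict(frame=i, row=c.peak[0], col=c.peak[1],
                                  snr_eff=c.snr_eff, cnr_eff=c.cnr_eff,
                                  q=c.q, status=c.status) for c in candidates)
    table = pd.DataFrame(all_rows, columns=LOCALIZATION_COLUMNS)
    manifest = {
        "software": f"snsmil {__version__}",
        "config": {"camera": asdict(config.camera),
                   **{k: getattr(config, k) for k in
                      ("q_threshold", "model", "pwt", "pearson_r_min",
                       "smooth_sigma_px", "background_window_factor",
                       "background_floor")},
                   "rose_cnr_min": ROSE_CNR_MIN},
        "n_frames": n_frames,
        "n_localizations": len(table),
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "per_frame": per_frame_counts,
        "coordinates": "0-based px, pixel centers at integers; "
                       "nm = px * pixel_size_nm / magnification, origin at pixel (0,0) center",
    }
    cands = pd.DataFrame(cand_rows, columns=CANDIDATE_COLUMNS) if collect_candidates else None
    return table, manifest, cands


def localize_file(input_path: str | Path, config: PipelineConfig,
                  out_dir: str | Path) -> Path:
    """Localize a TIFF stack and write table, diagnostics and manifest.

    Writes ``localizations.csv`` (the primary output), ``candidates.csv``
    (per-candidate diagnostics, the input to Q-histogram quality checks),
    ``q_histogram.csv`` and ``manifest.yaml``. Returns the localization table
    path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, manifest, cands = localize_frames(read_stack(input_path), config,
                                             collect_candidates=True)
    loc_path = out / "localizations.csv"
    table.to_csv(loc_path, index=False)
    cands.to_csv(out / "candidates.csv", index=False)
    if len(table):
        counts, edges = np.histogram(table["q"], bins=50)
        pd.DataFrame({"q_low": edges[:-1], "q_high": edges[1:], "count": counts}
                     ).to_csv(out / "q_histogram.csv", index=False)
    manifest["input"] = str(input_path)
    # written last, in one call, so a complete manifest marks a complete run
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return loc_path
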