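"""Benchmark scoring of localizations against simulated ground truth.

Ground-truth (reference) and reconstructed emitter sets are matched within
each frame by greedy nearest-pair assignment: the globally closest unmatched
truth/found pair with distance ≤ the tolerance is matched, repeatedly, each
record used at most once.  Matched pairs are true positives; unmatched found
records are false positives; unmatched truth records are false negatives.

    Jaccard   = TP / (TP + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    RMSD      = sqrt(mean squared distance over matched pairs)   [nm]

The matching tolerance is a free parameter of the protocol and is always
reported alongside the scores; results at different tolerances are not
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["Matching", "EvaluationResult", "match_localizations", "compute_metrics",
           "evaluate"]

log = logging.getLogger(__name__)

DEFAULT_TOLERANCE_NM = 128.0  # 2 x the 64 nm simulation pixel


@dataclass
class Matching:
    tp: int
    fp: int
    fn: int
    distances_nm: np.ndarray = field(repr=False)
    tolerance_nm: float = DEFAULT_TOLERANCE_NM
    pairs: list[tuple[int, int]] = field(default_factory=list, repr=False)


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    jaccard: float
    precision: float
    recall: float
    rmsd_nm: float
    tolerance_nm: float

    def as_dict(self) -> dict:
        return dict(tp=self.tp, fp=self.fp, fn=self.fn, jaccard=self.jaccard,
                    precision=self.precision, recall=self.recall,
                    rmsd_nm=self.rmsd_nm, tolerance_nm=self.tolerance_nm)


def _greedy_match(a: np.ndarray, b: np.ndarray, tol: float) -> list[tuple[int, int, float]]:
    """Greedy nearest-pair matching between two (n,2) nm coordinate arrays."""
    if len(a) == 0 or len(b) == 0:
        return []
    dist = cKDTree(a).sparse_distance_matrix(cKDTree(b), tol, output_type="coo_matrix")
    order = np.argsort(dist.data, kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for k in order:
        i, j = int(dist.row[k]), int(dist.col[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, float(dist.data[k])))
    return out


def match_localizations(truth: pd.DataFrame, found: pd.DataFrame,
                        tolerance_nm: float = DEFAULT_TOLERANCE_NM,
                        per_frame: bool = True) -> Matching:
    """Match truth and found tables (columns ``frame``, ``x_nm``, ``y_nm``)."""
    if tolerance_nm <= 0:
        raise ValueError("tolerance_nm must be > 0")
    t_frames = set(truth["frame"].astype(int)) if len(truth) else set()
    f_frames = set(found["frame"].astype(int)) if len(found) else set()
    if per_frame and t_frames and f_frames and t_frames != f_frames:
        log.warning("frame ranges differ (truth %d frames, found %d); "
                    "evaluating the overlap", len(t_frames), len(f_frames))

    pairs: list[tuple[int, int]] = []
    dists: list[float] = []
    groups = (sorted(t_frames & f_frames) if per_frame else [None])
    for fr in groups:
        if fr is None:
            t_idx = truth.index.to_numpy()
            f_idx = found.index.to_numpy()
        else:
            t_idx = truth.index[truth["frame"] == fr].to_numpy()
            f_idx = found.index[found["frame"] == fr].to_numpy()
        a = truth.loc[t_idx, ["x_nm", "y_nm"]].to_numpy(float)
        b = found.loc[f_idx, ["x_nm", "y_nm"]].to_numpy(float)
        for i, j, d in _greedy_match(a, b, tolerance_nm):
            pairs.append((int(t_idx[i]), int(f_idx[j])))
            dists.append(d)
    tp = len(pairs)
    return Matching(tp=tp, fp=len(found) - tp, fn=len(truth) - tp,
                    distances_nm=np.asarray(dists), tolerance_nm=tolerance_nm,
                    pairs=pairs)


def compute_metrics(matching: Matching) -> EvaluationResult:
    """Jaccard / Precision / Recall / RMSD from a matching (0/0 defined as 0)."""
    tp, fp, fn = matching.tp, matching.fp, matching.fn

    def ratio(num: int, den: int) -> float:
        if den == 0:
            log.info("0/0 ratio encountered; reporting 0")
            return 0.0
        return num / den

    if tp == 0:
        log.info("no matched pairs; RMSD undefined (NaN)")
        rmsd = float("nan")
    else:
        rmsd = float(np.sqrt(np.mean(matching.distances_nm**2)))
    return EvaluationResult(
        tp=tp, fp=fp, fn=fn,
        jaccard=ratio(tp, tp + fp + fn),
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
        rmsd_nm=rmsd,
        tolerance_nm=matching.tolerance_nm)


def evaluate(truth: pd.DataFrame, found: pd.DataFrame,
             tolerance_nm: float = DEFAULT_TOLERANCE_NM,
             per_frame: bool = True) -> EvaluationResult:
    """Convenience: match then score."""
    return compute_metrics(match_localizations(truth, found, tolerance_nm, per_frame))
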