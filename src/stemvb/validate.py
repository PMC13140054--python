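"""Detection validation against simulator ground truth.

Detected bundles are matched to truth bundles by nearest centroid within
one true radius; from the matching we report recall, precision and the
least-squares R² of detected vs true areas — the section-level analogues of
a dataset-wide count/size validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .synthdata import GroundTruth


@dataclass(frozen=True)
class MatchResult:
    n_truth: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float
    true_areas_um2: np.ndarray
    detected_areas_um2: np.ndarray

    @property
    def area_r2(self) -> float:
        if self.n_matched < 3:
            return float("nan")
        return float(linregress(self.true_areas_um2,
                                self.detected_areas_um2).rvalue ** 2)


def match_bundles(truth: GroundTruth, bundles: pd.DataFrame) -> MatchResult:
    """Greedy one-to-one matching of accepted detections to truth disks.

    A detection matches the nearest truth bundle if their centroid distance
    is at most that bundle's radius; each truth bundle is matched at most
    once (closest detection wins), so split detections count against
    precision and missed bundles against recall.
    """
    det = bundles[bundles["accepted"].astype(bool)] if "accepted" in bundles else bundles
    n_truth = len(truth.bundles)
    n_det = len(det)
    if n_truth == 0 or n_det == 0:
        return MatchResult(n_truth, n_det, 0,
                           0.0 if n_truth else 1.0,
                           0.0 if n_det else 1.0,
                           np.empty(0), np.empty(0))
    tx = np.array([b.centroid_um[0] for b in truth.bundles])
    ty = np.array([b.centroid_um[1] for b in truth.bundles])
    tr = np.array([b.radius_um for b in truth.bundles])
    ta = np.array([b.area_um2 for b in truth.bundles])
    dx = det["centroid_x_um"].to_numpy()
    dy = det["centroid_y_um"].to_numpy()
    da = det["area_um2"].to_numpy()

    dist = np.hypot(dx[:, None] - tx[None, :], dy[:, None] - ty[None, :])
    order = np.argsort(dist.min(axis=1), kind="stable")
    taken = np.zeros(n_truth, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i in order:
        j = int(np.argmin(np.where(taken, np.inf, dist[i])))
        if not taken[j] and dist[i, j] <= tr[j]:
            taken[j] = True
            pairs.append((i, j))
    n_matched = len(pairs)
    det_idx = [i for i, _ in pairs]
    tru_idx = [j for _, j in pairs]
    return MatchResult(
        n_truth=n_truth, n_detected=n_det, n_matched=n_matched,
        recall=n_matched / n_truth, precision=n_matched / n_det,
        true_areas_um2=ta[tru_idx], detected_areas_um2=da[det_idx],
    )
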