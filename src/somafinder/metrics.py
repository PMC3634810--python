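"""Quantitative validation of soma detections against ground truth.

A detection is correct when its centroid lies strictly within ``match_dist``
(default 5 um, a quarter of the average soma diameter) of an unmatched true
centroid; matching is one-to-one, greedy on ascending distance. Recall is
correct detections over real somas, precision over all detections, both in
percent. Per-soma agreement between the automatically detected volume and
the reference volume is an overlap ratio — Jaccard |A∩M| / |A∪M| by
default, Dice 2|A∩M| / (|A|+|M|) on request — with missed somas scored 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DetectionReport", "match_detections", "precision_recall",
           "overlap_ratio", "masks_overlap", "evaluate"]


@dataclass
class DetectionReport:
    """Matching, recall/precision and per-soma overlap ratios."""

    n_real: int
    n_correct: int
    n_false: int
    recall: float       # percent, one decimal
    precision: float    # percent, one decimal
    matches: list[tuple[int, int, float]]            # (detected_id, truth_id, dist_um)
    per_soma_overlap: list[tuple[int, float]]        # (truth_id, ratio; 0 when missed)
    centroid_errors_um: list[float] = field(default_factory=list)

    @property
    def n_detected(self) -> int:
        return self.n_correct + self.n_false

    def overlap_fraction_above(self, bound: float) -> float:
        """Percent of correctly detected somas with overlap ratio > bound."""
        matched = {t for _, t, _ in self.matches}
        vals = [o for tid, o in self.per_soma_overlap if tid in matched]
        if not vals:
            return float("nan")
        return round(100.0 * sum(v > bound for v in vals) / len(vals), 1)

    def to_frame(self) -> pd.DataFrame:
        det_for = {t: d for d, t, _ in self.matches}
        dist_for = {t: x for _, t, x in self.matches}
        rows = [dict(truth_id=t, detected_id=det_for.get(t, -1),
                     distance_um=dist_for.get(t, np.nan), overlap=o)
                for t, o in self.per_soma_overlap]
        return pd.DataFrame(rows, columns=["truth_id", "detected_id", "distance_um", "overlap"])


def match_detections(detected, truth, match_dist: float = 5.0):
    """Greedy one-to-one matching on ascending centroid distance.

    Only pairs strictly closer than ``match_dist`` are eligible; ties break
    by (truth index, detected index). Returns (matches, false_positive
    detected indices, missed truth indices); ids are 0-based positions in
    the input lists.
    """
    if match_dist <= 0:
        raise ValueError("match_dist must be positive")
    det = np.asarray(detected, dtype=float).reshape(-1, 3)
    tru = np.asarray(truth, dtype=float).reshape(-1, 3)
    pairs = []
    for ti in range(len(tru)):
        d = np.linalg.norm(det - tru[ti], axis=1) if len(det) else np.empty(0)
        for di in np.nonzero(d < match_dist)[0]:
            pairs.append((float(d[di]), ti, int(di)))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_t, used_d, matches = set(), set(), []
    for dist, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matches.append((di, ti, dist))
    false_pos = [di for di in range(len(det)) if di not in used_d]
    missed = [ti for ti in range(len(tru)) if ti not in used_t]
    return matches, false_pos, missed


def precision_recall(n_real: int, n_correct: int, n_false: int) -> tuple[float, float]:
    """(precision %, recall %) to one decimal.

    precision = 100 * n_correct / (n_correct + n_false);
    recall = 100 * n_correct / n_real. With zero detections precision is
    undefined and reported as NaN with a warning.
    """
    if n_real <= 0:
        raise ValueError("n_real must be positive")
    if min(n_correct, n_false) < 0:
        raise ValueError("counts must be non-negative")
    recall = round(100.0 * n_correct / n_real, 1)
    n_det = n_correct + n_false
    if n_det == 0:
        warnings.warn("no detections: precision undefined", stacklevel=2)
        return float("nan"), recall
    return round(100.0 * n_correct / n_det, 1), recall


def overlap_ratio(auto_mask: np.ndarray, manual_mask: np.ndarray,
                  kind: str = "jaccard") -> float:
    """Volume overlap between two co-registered binary masks (same shape)."""
    a = np.asarray(auto_mask, bool)
    m = np.asarray(manual_mask, bool)
    if a.shape != m.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {m.shape}")
    return _ratio(int((a & m).sum()), int(a.sum()), int(m.sum()), kind)


def _ratio(inter: int, na: int, nm: int, kind: str) -> float:
    if na == 0 or nm == 0:
        return 0.0
    if kind == "jaccard":
        return inter / (na + nm - inter)
    if kind == "dice":
        return 2.0 * inter / (na + nm)
    raise ValueError(f"unknown overlap kind {kind!r}; use 'jaccard' or 'dice'")


def masks_overlap(mask_a: np.ndarray, lo_a, mask_b: np.ndarray, lo_b,
                  kind: str = "jaccard") -> float:
    """Overlap ratio of two bbox-cropped masks placed at global voxel offsets."""
    lo_a = np.asarray(lo_a, int)
    lo_b = np.asarray(lo_b, int)
    hi_a = lo_a + np.asarray(mask_a.shape)
    hi_b = lo_b + np.asarray(mask_b.shape)
    clo = np.maximum(lo_a, lo_b)
    chi = np.minimum(hi_a, hi_b)
    inter = 0
    if np.all(clo < chi):
        sl_a = tuple(slice(a - l, b - l) for a, b, l in zip(clo, chi, lo_a))
        sl_b = tuple(slice(a - l, b - l) for a, b, l in zip(clo, chi, lo_b))
        inter = int((np.asarray(mask_a, bool)[sl_a] & np.asarray(mask_b, bool)[sl_b]).sum())
    return _ratio(inter, int(np.asarray(mask_a, bool).sum()),
                  int(np.asarray(mask_b, bool).sum()), kind)


def evaluate(detected, truth, match_dist: float = 5.0,
             overlap_kind: str = "jaccard") -> DetectionReport:
    """Full report: matching, recall/precision and per-soma overlap ratios.

    ``detected`` are SomaRecord objects; ``truth`` is a phantom GroundTruth
    (or anything with ``somas`` carrying centroid_um / mask / mask_lo_vox).
    Only correctly located somas contribute an overlap ratio; missed somas
    score 0.
    """
    det_cents = [r.centroid_um for r in detected]
    tru_cents = [s.centroid_um for s in truth.somas]
    matches, false_pos, missed = match_detections(det_cents, tru_cents, match_dist)
    precision, recall = precision_recall(
        len(tru_cents), len(matches), len(false_pos)) if tru_cents else (np.nan, np.nan)

    per_soma = []
    id_matches = []
    errors = []
    match_by_truth = {ti: (di, dist) for di, ti, dist in matches}
    for ti, tsoma in enumerate(truth.somas):
        if ti in match_by_truth:
            di, dist = match_by_truth[ti]
            rec = detected[di]
            mask, lo = rec.best_mask()
            ov = masks_overlap(mask, lo, tsoma.mask, tsoma.mask_lo_vox, kind=overlap_kind)
            id_matches.append((getattr(rec, "soma_id", di), tsoma.soma_id, dist))
            errors.append(dist)
        else:
            ov = 0.0
        per_soma.append((tsoma.soma_id, float(ov)))
    return DetectionReport(
        n_real=len(tru_cents),
        n_correct=len(matches),
        n_false=len(false_pos),
        recall=recall,
        precision=precision,
        matches=id_matches,
        per_soma_overlap=per_soma,
        centroid_errors_um=errors,
    )
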