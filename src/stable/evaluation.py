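"""Similarity metrics, ROI correspondence analysis and dF/F trace extraction.

Image metrics follow their textbook global definitions: RMSE, MAE,
PSNR = 10·log10(max(x)²/RMSE²) with ``x`` the reference argument, SSIM from
whole-image statistics (a windowed variant is available behind a flag), and
Pearson correlation.  ROI analysis consumes integer label masks (an external
segmenter such as Cellpose, or :func:`segment_blobs` at desk scale): for each
reference ROI the nearest translated ROI by centroid distance is paired and
scored by L2 centroid distance and IoU of the two single-ROI binary masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "MetricReport",
    "image_metrics",
    "roi_centroids",
    "MatchResult",
    "match_and_score",
    "extract_traces",
    "dff",
    "segment_blobs",
    "evaluate_paired_translation",
]


@dataclass
class MetricReport:
    rmse: float
    mae: float
    psnr: float
    ssim: float
    pcc: float

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "psnr": self.psnr,
                "ssim": self.ssim, "pcc": self.pcc}


def image_metrics(x, y_reference, windowed_ssim: bool = False) -> MetricReport:
    """Similarity of ``x`` against the reference ``y``.

    PSNR uses ``max(x)`` of the first argument; identical images report
    ``psnr = inf``.  Zero-variance inputs make PCC undefined and are reported
    as ``nan`` (sentinel, no exception).  SSIM constants are C1 = (0.01·L)²,
    C2 = (0.03·L)² with L the joint data range.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y_reference, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty input")
    diff = x - y
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    psnr = math.inf if rmse == 0 else float(10.0 * np.log10(x.max() ** 2 / rmse**2))
    data_range = float(max(x.max(), y.max()) - min(x.min(), y.min()))
    if data_range == 0:
        data_range = 1.0
    if windowed_ssim:
        from skimage.metrics import structural_similarity

        ssim = float(structural_similarity(x, y, data_range=data_range))
    else:
        c1 = (0.01 * data_range) ** 2
        c2 = (0.03 * data_range) ** 2
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = float(np.mean((x - mx) * (y - my)))
        ssim = float(
            (2 * mx * my + c1) * (2 * cov + c2)
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        pcc = 1.0 if rmse == 0 else math.nan
    else:
        pcc = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return MetricReport(rmse, mae, psnr, ssim, pcc)


def roi_centroids(mask: np.ndarray):
    """Unweighted per-ROI centroids.

    Returns ``(labels, centroids)`` where centroids are ``(N, 2)`` in
    ``(row, col)`` pixel coordinates (the package-wide (y, x) convention).
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return labels, np.empty((0, 2))
    cents = ndi.center_of_mass(np.ones_like(mask, dtype=np.float64), mask, labels)
    return labels, np.asarray(cents, dtype=np.float64)


@dataclass
class MatchResult:
    """Reference→translated nearest-centroid pairing (reuse allowed)."""

    ref_labels: np.ndarray
    matched_labels: np.ndarray
    distances: np.ndarray  # L2 centroid distance per reference ROI (nan if no match)
    ious: np.ndarray
    n_ref: int
    n_trans: int

    def median_distance(self) -> float:
        ok = np.isfinite(self.distances)
        return float(np.median(self.distances[ok])) if ok.any() else math.nan

    def median_iou(self) -> float:
        ok = np.isfinite(self.ious)
        return float(np.median(self.ious[ok])) if ok.any() else math.nan


def match_and_score(mask_ref: np.ndarray, mask_trans: np.ndarray) -> MatchResult:
    """Pair every reference ROI with its nearest translated ROI and score it.

    Matching is one-directional (reference → translated) with reuse allowed;
    each pair is scored by centroid L2 distance and by the IoU of the two
    single-ROI binary masks.  An empty translated mask yields nan sentinels.
    """
    mask_ref = np.asarray(mask_ref)
    mask_trans = np.asarray(mask_trans)
    if mask_ref.shape != mask_trans.shape:
        raise ValueError("masks must have the same shape")
    ref_labels, ref_c = roi_centroids(mask_ref)
    tr_labels, tr_c = roi_centroids(mask_trans)
    n_ref, n_tr = len(ref_labels), len(tr_labels)
    if n_ref == 0 or n_tr == 0:
        nan = np.full(n_ref, np.nan)
        return MatchResult(ref_labels, np.zeros(n_ref, dtype=ref_labels.dtype if n_ref else int),
                           nan, nan.copy(), n_ref, n_tr)
    d = np.linalg.norm(ref_c[:, None, :] - tr_c[None, :, :], axis=-1)
    nearest = d.argmin(axis=1)
    distances = d[np.arange(n_ref), nearest]
    ious = np.empty(n_ref)
    for i, j in enumerate(nearest):
        a = mask_ref == ref_labels[i]
        b = mask_trans == tr_labels[j]
        union = np.logical_or(a, b).sum()
        ious[i] = np.logical_and(a, b).sum() / union if union else math.nan
    return MatchResult(ref_labels, tr_labels[nearest], distances, ious, n_ref, n_tr)


def extract_traces(stack: np.ndarray, mask: np.ndarray):
    """Per-ROI mean intensity per frame.

    Returns ``(labels, traces)`` with traces of shape ``(n_rois, T)``.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    mask = np.asarray(mask)
    if stack.shape[-2:] != mask.shape:
        raise ValueError("stack spatial dims must match mask")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    traces = np.empty((len(labels), stack.shape[0]))
    flat_mask = mask.ravel()
    flat = stack.reshape(stack.shape[0], -1)
    for i, lab in enumerate(labels):
        sel = flat_mask == lab
        traces[i] = flat[:, sel].mean(axis=1)
    return labels, traces


def dff(trace: np.ndarray, k: int, invert_sign: bool = False) -> np.ndarray:
    """ΔF/F against a trailing moving-average baseline of window ``k``.

    The baseline at sample n is the mean of the last k samples (a shrinking
    window for the first k−1 samples).  The conventional sign
    ``(p − MA)/MA`` is the default; ``invert_sign`` gives ``(MA − p)/MA``.
    Samples with baseline <= 0 are masked to nan.
    """
    if k < 1:
        raise ValueError("window length k must be >= 1")
    p = np.asarray(trace, dtype=np.float64)
    csum = np.concatenate([[0.0], np.cumsum(p)])
    n = len(p)
    idx = np.arange(n)
    lo = np.maximum(idx - k + 1, 0)
    ma = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)
    out = np.full(n, np.nan)
    ok = ma > 0
    out[ok] = (p[ok] - ma[ok]) / ma[ok]
    if invert_sign:
        out = -out
    return out


def segment_blobs(image: np.ndarray, min_size: int = 5,
                  threshold: float | None = None) -> np.ndarray:
    """Simple intensity segmentation: Otsu threshold + connected components.

    A desk-scale stand-in for a trained instance segmenter, adequate for the
    well-separated synthetic somata/nuclei; returns an integer label mask.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as cc_label

    image = np.asarray(image, dtype=np.float64)
    if threshold is None:
        if image.max() == image.min():
            return np.zeros(image.shape, dtype=np.int32)
        threshold = threshold_otsu(image)
    labeled = cc_label(image > threshold)
    labels, counts = np.unique(labeled, return_counts=True)
    keep = labels[(labels > 0) & (counts >= min_size)]
    out = np.zeros(image.shape, dtype=np.int32)
    for new, lab in enumerate(keep, start=1):
        out[labeled == lab] = new
    return out


def evaluate_paired_translation(gen_pair, dataset, config, direction: str = "a2b",
                                min_size: int = 5) -> dict:
    """Score a generator pair on the paired synthetic test set.

    Translates each test stack (A→B by default), segments the time-averaged
    translated image, and scores it against the ground-truth nuclear masks:
    median centroid distance, median IoU, ROI counts, and the median Pearson
    correlation between translated per-ROI traces and the latent ground-truth
    amplitude traces.
    """
    from .training import normalize_stack

    distances: list = []
    ious: list = []
    trace_pccs: list = []
    n_ref_total = 0
    n_trans_total = 0
    for pair in dataset.test:
        src = pair.stack_a if direction == "a2b" else pair.stack_b
        ref_mask = pair.mask_b if direction == "a2b" else pair.mask_a
        src = normalize_stack(src, config)
        translated = np.stack([
            gen_pair.translate(frame[None].astype(np.float32), direction).data[0]
            for frame in src
        ])
        mean_img = translated.mean(axis=0)
        seg = segment_blobs(mean_img, min_size=min_size)
        res = match_and_score(ref_mask, seg)
        distances.extend(res.distances[np.isfinite(res.distances)].tolist())
        finite_iou = res.ious[np.isfinite(res.ious)]
        ious.extend(finite_iou.tolist())
        n_ref_total += res.n_ref
        n_trans_total += res.n_trans
        labels, traces = extract_traces(translated, ref_mask)
        for lab, tr in zip(labels, traces):
            gt = pair.traces[int(lab) - 1]
            if tr.std() > 0 and gt.std() > 0:
                trace_pccs.append(float(np.corrcoef(tr, gt)[0, 1]))
    diag = math.hypot(*dataset.test[0].mask_a.shape) if dataset.test else math.nan
    return {
        "median_centroid_distance": float(np.median(distances)) if distances else diag,
        "median_iou": float(np.median(ious)) if ious else 0.0,
        "median_trace_pcc": float(np.median(trace_pccs)) if trace_pccs else math.nan,
        "n_rois_reference": int(n_ref_total),
        "n_rois_translated": int(n_trans_total),
    }
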