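"""Paraspeckle RNA-FISH quantification and ordinal 0-3 scoring.

Pipeline: maximum-intensity projection of each channel over z, automatic
(Otsu) thresholding of the DAPI projection to segment nuclei, per-nucleus
mean signal intensity, local-maximum focus detection inside each nucleus,
and a sample-level ordinal score 0-3 from the fraction of focus-positive
nuclei.  Samples scoring >= 1 are "NEAT1_2-positive".

Single-plane FFPE images are the z=1 degenerate case of the same pipeline.
Manually traced nucleus outlines can be supplied as an external label mask
in place of the automatic segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects


@dataclass
class NucleusRecord:
    """Measurements for one segmented nucleus."""

    nucleus_id: int
    area: int
    mean_signal_intensity: float
    foci_count: int = 0

    def __post_init__(self) -> None:
        if self.mean_signal_intensity < 0:
            raise ValueError("mean_signal_intensity must be >= 0")


@dataclass(frozen=True)
class ScoreCriteria:
    """Operational definition of the ordinal 0-3 score.

    A nucleus is *positive* when it carries at least ``positive_focus_min``
    detected foci; the sample score is set by where the positive-nucleus
    fraction falls relative to three ascending thresholds
    (score 0 below t1; 1 in [t1, t2); 2 in [t2, t3); 3 at or above t3).
    """

    positive_focus_min: int = 1
    fraction_thresholds: tuple[float, float, float] = (0.05, 0.25, 0.60)

    def __post_init__(self) -> None:
        t1, t2, t3 = self.fraction_thresholds
        if not (0 < t1 < t2 < t3 <= 1):
            raise ValueError("thresholds must satisfy 0 < t1 < t2 < t3 <= 1")
        if self.positive_focus_min < 1:
            raise ValueError("positive_focus_min must be >= 1")


@dataclass
class SampleScore:
    sample_id: str
    score: int
    positive_fraction: float
    n_nuclei: int

    @property
    def is_positive(self) -> bool:
        """Score >= 1 defines a NEAT1_2-positive sample."""
        return self.score >= 1


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack over z."""
    arr = np.asarray(stack)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError(f"expected a nonempty (z, y, x) stack, got shape {arr.shape}")
    return arr.max(axis=0)


def segment_nuclei(dapi_projection: np.ndarray, min_area: int = 100) -> np.ndarray:
    """Segment nuclei by Otsu thresholding of the projected DAPI channel.

    Binary mask -> hole filling -> removal of components below ``min_area``
    -> 8-connected labelling.  A constant image has no defined threshold
    and yields an empty mask with a warning.
    """
    img = np.asarray(dapi_projection, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        warnings.warn("constant DAPI image: Otsu threshold undefined, no nuclei segmented")
        return np.zeros(img.shape, dtype=np.int32)
    mask = img > threshold_otsu(img)
    mask = ndimage.binary_fill_holes(mask)
    # skimage >= 0.26 renamed the size threshold; fall back for older releases
    try:
        mask = remove_small_objects(mask, max_size=min_area - 1)
    except TypeError:
        mask = remove_small_objects(mask, min_size=min_area)
    return cc_label(mask, connectivity=2).astype(np.int32)


def measure_nuclei(labels: np.ndarray, signal_projection: np.ndarray) -> list[NucleusRecord]:
    """Per-nucleus area and mean signal intensity under each label."""
    labels = np.asarray(labels)
    signal = np.asarray(signal_projection, dtype=np.float64)
    if labels.shape != signal.shape:
        raise ValueError(f"shape mismatch: labels {labels.shape} vs signal {signal.shape}")
    return [
        NucleusRecord(
            nucleus_id=int(p.label),
            area=int(p.area),
            mean_signal_intensity=float(p.intensity_mean),
        )
        for p in regionprops(labels, intensity_image=signal)
    ]


def detect_foci(
    signal_projection: np.ndarray,
    labels: np.ndarray,
    amplitude_threshold_factor: float = 5.0,
    min_separation: int = 3,
) -> dict[int, int]:
    """Count punctate foci per nucleus as thresholded local maxima.

    Within each nucleus, the local background is summarized by the median
    and a robust spread (scaled median absolute deviation) of its pixels;
    peaks must exceed ``median + factor * spread`` and are deduplicated by
    non-maximum suppression at ``min_separation`` pixels.  Because foci are
    sparse, the bulk of nucleus pixels is background and the median/MAD are
    barely perturbed by the foci themselves.
    """
    signal = np.asarray(signal_projection, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape != signal.shape:
        raise ValueError("signal and label mask must share a shape")
    counts: dict[int, int] = {}
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        inside = labels == lbl
        pixels = signal[inside]
        bg_median = float(np.median(pixels))
        spread = 1.4826 * float(np.median(np.abs(pixels - bg_median)))
        # epsilon keeps flat (zero-signal) nuclei focus-free
        threshold = bg_median + max(amplitude_threshold_factor * spread, 1e-9)
        masked = np.where(inside, signal, 0.0)
        peaks = peak_local_max(
            masked,
            min_distance=min_separation,
            threshold_abs=threshold,
            exclude_border=False,
        )
        counts[int(lbl)] = len(peaks)
    return counts


def annotate_foci(
    nuclei: list[NucleusRecord],
    foci_counts: dict[int, int],
) -> list[NucleusRecord]:
    """Attach detected foci counts to nucleus records (in place) and return them."""
    for rec in nuclei:
        rec.foci_count = foci_counts.get(rec.nucleus_id, 0)
    return nuclei


def score_sample(
    nuclei: list[NucleusRecord],
    criteria: ScoreCriteria | None = None,
    sample_id: str = "sample",
) -> SampleScore:
    """Ordinal 0-3 score from the fraction of focus-positive nuclei."""
    if not nuclei:
        raise ValueError("cannot score a sample with no nuclei")
    if criteria is None:
        criteria = ScoreCriteria()
    positive = sum(1 for n in nuclei if n.foci_count >= criteria.positive_focus_min)
    fraction = positive / len(nuclei)
    score = sum(fraction >= t for t in criteria.fraction_thresholds)
    return SampleScore(
        sample_id=sample_id,
        score=score,
        positive_fraction=fraction,
        n_nuclei=len(nuclei),
    )


def quantify_stack(
    dapi: np.ndarray,
    signal: np.ndarray,
    min_area: int = 100,
    criteria: ScoreCriteria | None = None,
    labels: np.ndarray | None = None,
    sample_id: str = "sample",
    amplitude_threshold_factor: float = 5.0,
    min_separation: int = 3,
) -> tuple[list[NucleusRecord], SampleScore]:
    """Full pipeline: project, segment (or use given labels), measure, score."""
    dapi_proj = max_project(dapi)
    signal_proj = max_project(signal)
    if labels is None:
        labels = segment_nuclei(dapi_proj, min_area=min_area)
    nuclei = measure_nuclei(labels, signal_proj)
    foci = detect_foci(
        signal_proj, labels,
        amplitude_threshold_factor=amplitude_threshold_factor,
        min_separation=min_separation,
    )
    annotate_foci(nuclei, foci)
    return nuclei, score_sample(nuclei, criteria, sample_id=sample_id)


def mean_intensity_distribution(
    samples: dict[str, list[NucleusRecord]],
) -> "pd.DataFrame":
    """Per-line summary of per-nucleus mean intensities (mean, sd, n).

    With a single nucleus the sd is undefined and reported as 0 with the
    ``sd_undefined`` flag set; output feeds rank comparisons across lines.
    """
    import pandas as pd

    rows = []
    for line, nuclei in samples.items():
        if not nuclei:
            raise ValueError(f"line {line!r} has no nuclei")
        vals = np.array([n.mean_signal_intensity for n in nuclei])
        rows.append(
            {
                "line": line,
                "n_nuclei": len(vals),
                "mean_intensity": float(vals.mean()),
                "sd_intensity": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "sd_undefined": len(vals) < 2,
            }
        )
    return pd.DataFrame(rows)
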