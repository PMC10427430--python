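"""Quantitative analysis of polarimetric maps.

Covers the study's statistics layer: RMS contrast between imaging
channels, grid-unit region statistics with Mann–Whitney comparison,
linear-SVM classification of tissue units with ROC/AUC, and the
polarization-microscopy retardance index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from skimage.color import rgb2hsv

from .dofp import ParameterMap

__all__ = [
    "RoiGrid",
    "ClassificationReport",
    "RetardanceIndexResult",
    "rms_contrast_image",
    "rms_contrast_medians",
    "grid_unit_means",
    "mannwhitney_compare",
    "build_feature_table",
    "svm_classify",
    "hue_saturation_from_rgb",
    "retardance_index",
    "FEATURE_SUBSETS",
]


@dataclass
class RoiGrid:
    """Mean values over non-overlapping square grid units of an ROI."""

    unit_px: int
    means: np.ndarray  # (n_units,)
    origins: np.ndarray  # (n_units, 2) top-left pixel of each unit
    labels: np.ndarray | None = None


@dataclass
class ClassificationReport:
    feature_subset: str
    auc: float
    roc_points: np.ndarray  # (n, 2): fpr, tpr
    sensitivity: float
    specificity: float
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    extras: dict = field(default_factory=dict)


@dataclass
class RetardanceIndexResult:
    index: float
    n_retarding: int
    mask: np.ndarray


def rms_contrast_image(values, mask=None) -> float:
    """RMS contrast of a [0, 1]-scaled image over ``mask``: the sample
    standard deviation with the 1/(n−1) divisor."""
    values = np.asarray(values, dtype=float)
    x = values[np.asarray(mask, dtype=bool)] if mask is not None else values.ravel()
    if x.size < 2:
        raise ValueError("RMS contrast needs at least two pixels")
    if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
        raise ValueError("values must be scaled to [0, 1]")
    return float(np.std(x, ddof=1))


def rms_contrast_medians(m1: float, m2: float) -> float:
    """RMS contrast between two category medians in [0, 1]:
    ``sqrt(Σ (m_i − m̄)²)`` with ``m̄ = (m1+m2)/2``, i.e. ``|m1 − m2|/√2``."""
    for m in (m1, m2):
        if not 0 <= m <= 1:
            raise ValueError("medians must lie in [0, 1]")
    mbar = 0.5 * (m1 + m2)
    return float(np.sqrt((m1 - mbar) ** 2 + (m2 - mbar) ** 2))


def grid_unit_means(
    values,
    region_mask,
    unit_px: int = 16,
    valid=None,
) -> RoiGrid:
    """Mean value per ``unit_px``×``unit_px`` grid unit inside a region.

    The grid is tiled from the top-left corner of the region's bounding
    box (so a strip of height ``unit_px`` anywhere in the image yields
    one row of adjacent units). A unit contributes one mean if it lies
    entirely inside ``region_mask`` and contains no invalid pixel
    (under/overexposed areas are excluded wholesale). Unit means are
    treated downstream as statistically independent samples.
    """
    if unit_px < 1:
        raise ValueError("unit_px must be >= 1")
    if isinstance(values, ParameterMap):
        if valid is None:
            valid = values.valid
        values = values.values
    values = np.asarray(values, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    valid = np.ones_like(region_mask) if valid is None else np.asarray(valid, bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    rows_any = np.flatnonzero(region_mask.any(axis=1))
    cols_any = np.flatnonzero(region_mask.any(axis=0))
    r0, r1 = rows_any[0], rows_any[-1] + 1
    c0, c1 = cols_any[0], cols_any[-1] + 1
    means, origins = [], []
    for r in range(r0, r1 - unit_px + 1, unit_px):
        for c in range(c0, c1 - unit_px + 1, unit_px):
            rm = region_mask[r : r + unit_px, c : c + unit_px]
            vm = valid[r : r + unit_px, c : c + unit_px]
            if rm.all() and vm.all():
                means.append(values[r : r + unit_px, c : c + unit_px].mean())
                origins.append((r, c))
    if not means:
        raise ValueError("no grid unit survives the region/validity exclusion")
    return RoiGrid(
        unit_px=unit_px, means=np.array(means), origins=np.array(origins)
    )


def mannwhitney_compare(group_a, group_b) -> dict:
    """Two-sided Mann–Whitney U test between two groups of unit means.

    Uses the exact null distribution when both groups have n ≤ 20 and
    no ties across groups, otherwise the normal approximation with tie
    correction. Returns ``{"U", "p_two_sided", "method"}`` with U the
    statistic of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p_two_sided": float(res.pvalue), "method": method}


def build_feature_table(
    maps: dict,
    strip_masks,
    labels,
    unit_px: int = 30,
) -> pd.DataFrame:
    """Per-unit feature table along histology strips.

    ``maps`` holds the four channel images (keys ``ret``, ``dep``,
    ``hue``, ``sat``); each strip mask is tiled into a row of adjacent
    ``unit_px``×``unit_px`` units, and each unit yields one sample with
    its four channel means and a binary pathology label (1 = cancer or
    dysplasia, 0 = normal). ``labels`` gives one label per unit, listed
    strip by strip.
    """
    rows = []
    unit_count = 0
    for strip_id, mask in enumerate(strip_masks):
        grids = {
            k: grid_unit_means(maps[k], mask, unit_px=unit_px)
            for k in ("ret", "dep", "hue", "sat")
        }
        n_units = {k: g.means.size for k, g in grids.items()}
        if len(set(n_units.values())) != 1:
            raise ValueError("channel images disagree on surviving units")
        for unit_id in range(grids["ret"].means.size):
            rows.append(
                {
                    "strip_id": strip_id,
                    "unit_id": unit_id,
                    "ret": grids["ret"].means[unit_id],
                    "dep": grids["dep"].means[unit_id],
                    "hue": grids["hue"].means[unit_id],
                    "sat": grids["sat"].means[unit_id],
                }
            )
        unit_count += grids["ret"].means.size
    labels = np.asarray(labels)
    if labels.size != unit_count:
        raise ValueError(
            f"got {labels.size} labels for {unit_count} units"
        )
    table = pd.DataFrame(rows)
    table["label"] = labels.astype(int)
    return table


def unit_labels_from_truth(
    label_img, strip_masks, unit_px: int = 30, positive_codes=(2,)
) -> np.ndarray:
    """Majority-vote binary pathology label per grid unit, strip-major.

    A unit is positive (1) when more than half its pixels carry one of
    ``positive_codes`` in the ground-truth label image. Mirrors the
    unit tiling of :func:`grid_unit_means` so the labels align with
    :func:`build_feature_table` rows.
    """
    label_img = np.asarray(label_img)
    pos = np.isin(label_img, positive_codes).astype(float)
    out = []
    for mask in strip_masks:
        frac = grid_unit_means(pos, mask, unit_px=unit_px).means
        out.append((frac > 0.5).astype(int))
    return np.concatenate(out)


FEATURE_SUBSETS = {
    "colour": ["hue", "sat"],
    "ret": ["ret"],
    "dep": ["dep"],
    "ret+dep": ["ret", "dep"],
    "joint": ["ret", "dep", "hue", "sat"],
}


def svm_classify(
    table: pd.DataFrame,
    feature_subset: str = "joint",
    test_size: float = 0.4,
    seed: int = 0,
    C: float = 1.0,
    stratify: bool = False,
    max_resample: int = 10,
) -> ClassificationReport:
    """Linear-kernel SVM over unit features with a seeded 0.6/0.4 split.

    Features are z-standardized on the training split. The ROC curve is
    swept over the decision-function threshold on the test split;
    sensitivity/specificity are reported at threshold 0 (the fitted
    boundary). A split that leaves a single class in either half is
    resampled with the next seed, with a warning.
    """
    cols = FEATURE_SUBSETS[feature_subset]
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("need both classes present to classify")

    split_seed = seed
    for _ in range(max_resample):
        strat = y if stratify else None
        Xtr, Xte, ytr, yte, itr, ite = train_test_split(
            X, y, np.arange(len(y)), test_size=test_size,
            random_state=split_seed, stratify=strat,
        )
        if np.unique(ytr).size == 2 and np.unique(yte).size == 2:
            break
        warnings.warn(
            f"single-class split at seed {split_seed}; resampling", stacklevel=2
        )
        split_seed += 1
    else:
        raise ValueError("could not obtain a two-class split")

    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
    clf.fit(Xtr, ytr)
    score = clf.decision_function(Xte)
    fpr, tpr, _ = roc_curve(yte, score)
    auc_value = float(_sk_auc(fpr, tpr))
    pred = (score >= 0).astype(int)
    pos, neg = yte == 1, yte == 0
    sens = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    spec = float(np.mean(pred[neg] == 0)) if neg.any() else float("nan")
    return ClassificationReport(
        feature_subset=feature_subset,
        auc=auc_value,
        roc_points=np.stack([fpr, tpr], axis=1),
        sensitivity=sens,
        specificity=spec,
        train_indices=itr,
        test_indices=ite,
        seed=seed,
        extras={"C": C, "split_seed_used": split_seed, "stratified": stratify},
    )


def hue_saturation_from_rgb(rgb) -> dict:
    """Hue and saturation channels (both in [0, 1]) of an RGB image.

    Standard hexcone HSV conversion; inputs in [0, 255] are auto-scaled.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    hsv = rgb2hsv(rgb)
    return {"hue": hsv[..., 0], "saturation": hsv[..., 1]}


#: Grey-conversion weights of the standard luma transform.
GREY_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])


def retardance_index(
    rgb, hue_lo: float = 0.05, hue_hi: float = 0.45
) -> RetardanceIndexResult:
    """Mean grey level of the retarding pixels of a crossed-polarizer
    microscopy image.

    Birefringent fibres show golden/dark-green interference colours;
    pixels with hue in the closed interval [``hue_lo``, ``hue_hi``]
    (computed before any gamma adjustment) are classed as retarding.
    The index is the mean of ``0.2989 R + 0.5870 G + 0.1140 B`` over
    those pixels on the 0–255 scale, and 0 when none exist.
    """
    rgb = np.asarray(rgb, dtype=float)
    scale255 = rgb if rgb.max() > 1.0 else rgb * 255.0
    hue = hue_saturation_from_rgb(rgb)["hue"]
    mask = (hue >= hue_lo) & (hue <= hue_hi)
    # Pure black pixels have undefined hue (rgb2hsv returns 0, inside the
    # window); they carry no interference colour and are excluded.
    mask &= scale255.max(axis=-1) > 0
    n = int(mask.sum())
    if n == 0:
        return RetardanceIndexResult(index=0.0, n_retarding=0, mask=mask)
    grey = scale255 @ GREY_WEIGHTS
    return RetardanceIndexResult(index=float(grey[mask].mean()), n_retarding=n, mask=mask)
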