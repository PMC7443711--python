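"""From network output volumes to per-vessel-body mean sO2 and error stats.

The output-processing algorithm mirrors the standard connected-component
workflow: the soft segmentation V(x) is low-thresholded (default 0.2) to
isolate vessels from the faint inter-vessel background, the surviving
support is labeled into independent 26-connected bodies L(x), a confidence
threshold (default 1.0) keeps only voxels the segmentation network was sure
about, and the confident voxels inherit their original body labels Lv(x) —
so a body spatially split by the confidence cut still pools into one mean.
Mean sO2 per body is then read off the sO2-regression output (clipped to
[0, 1] by default) and compared with the ground truth.

Evaluation reports the mean and SD of the absolute error, the signed mean
and SD (all in percentage points), and a depth-binned error profile, either
with segmentation-derived voxels (``evaluate``) or with the ground-truth
vessel voxels (``evaluate_gt_masked``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "SegmentationVolumes",
    "EvalReport",
    "threshold_low",
    "threshold_confident",
    "label_bodies",
    "masked_labels",
    "segmentation_volumes",
    "mean_vessel_so2",
    "bodies_from_ground_truth",
    "evaluate",
    "evaluate_gt_masked",
    "depth_profile",
    "linear_unmixing_so2",
]

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def threshold_low(V: np.ndarray, t: float = 0.2) -> np.ndarray:
    """Zero voxels with intensity strictly below ``t`` (default 0.2)."""
    V = np.asarray(V, dtype=np.float64)
    out = V.copy()
    out[V < t] = 0.0
    return out


def threshold_confident(V1: np.ndarray, t: float = 1.0) -> np.ndarray:
    """Zero voxels below the confidence threshold (default 1.0).

    Voxels exactly at the threshold are kept ("< t set to zero").  An
    output with no confident voxel is legitimate; downstream processing
    yields an empty body table rather than an error.
    """
    return threshold_low(V1, t)


def label_bodies(V1: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label independent connected bodies of the nonzero support.

    26-connectivity by default (the 3D default of MATLAB-style bwlabeln);
    6 and 18 available for sensitivity checks.  Returns integer labels
    1..K, 0 on background.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    struct = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, _ = ndimage.label(np.asarray(V1) > 0, structure=struct)
    return labels.astype(np.int32)


def masked_labels(L: np.ndarray, V2: np.ndarray) -> np.ndarray:
    """Restrict labels to the confident support, keeping original ids.

    ``Lv(x) = L(x)`` where ``V2(x) > 0``, else 0.  A body split spatially
    by the confidence mask retains its single original label, so its
    surviving islands still pool into one body mean.
    """
    L = np.asarray(L)
    V2 = np.asarray(V2)
    if L.shape != V2.shape:
        raise ValueError("label and mask shapes differ")
    return np.where(V2 > 0, L, 0).astype(np.int32)


@dataclass
class SegmentationVolumes:
    """The intermediate volumes of the output-processing chain."""

    V: np.ndarray
    V1: np.ndarray
    L: np.ndarray
    V2: np.ndarray
    Lv: np.ndarray


def segmentation_volumes(
    V: np.ndarray,
    t_low: float = 0.2,
    t_confident: float = 1.0,
    connectivity: int = 26,
) -> SegmentationVolumes:
    """Run the full thresholding/labeling chain on a raw segmentation."""
    V = np.asarray(V, dtype=np.float64)
    V1 = threshold_low(V, t_low)
    L = label_bodies(V1, connectivity)
    V2 = threshold_confident(V1, t_confident)
    Lv = masked_labels(L, V2)
    return SegmentationVolumes(V=V, V1=V1, L=L, V2=V2, Lv=Lv)


def mean_vessel_so2(
    Lv: np.ndarray,
    so2_map: np.ndarray,
    so2_true: np.ndarray | None = None,
    dx_mm: float = 0.1,
    clip: bool = True,
    min_voxels: int = 1,
    image_id: int = 0,
) -> pd.DataFrame:
    """Per-body mean sO2 table from a labeled volume.

    For every integer label in ``Lv`` the arithmetic mean of ``so2_map``
    (clipped to [0, 1] unless ``clip=False``) over its voxels is computed;
    if ``so2_true`` is given the true mean over the same voxels is added.
    ``depth_mm`` is the mean voxel-center depth of the body below the
    sensor plane.  Bodies with fewer than ``min_voxels`` voxels are dropped
    (default keeps everything).
    """
    Lv = np.asarray(Lv)
    so2_map = np.asarray(so2_map, dtype=np.float64)
    if so2_map.shape != Lv.shape:
        raise ValueError("so2 map and label volume shapes differ")
    est = np.clip(so2_map, 0.0, 1.0) if clip else so2_map
    rows = []
    for k in np.unique(Lv[Lv > 0]):
        sel = Lv == k
        n_vox = int(sel.sum())
        if n_vox < min_voxels:
            continue
        zc = (np.nonzero(sel)[0] + 0.5) * dx_mm
        row = {
            "image_id": image_id,
            "body_id": int(k),
            "n_voxels": n_vox,
            "depth_mm": float(zc.mean()),
            "est_mean_so2": float(est[sel].mean()),
        }
        if so2_true is not None:
            row["true_mean_so2"] = float(np.asarray(so2_true)[sel].mean())
        rows.append(row)
    cols = [
        "image_id",
        "body_id",
        "n_voxels",
        "depth_mm",
        "est_mean_so2",
        "true_mean_so2",
    ]
    if so2_true is None:
        cols = cols[:-1]
    return pd.DataFrame(rows, columns=cols)


def bodies_from_ground_truth(
    body_id: np.ndarray,
    so2_map: np.ndarray,
    so2_true: np.ndarray,
    dx_mm: float = 0.1,
    clip: bool = True,
    image_id: int = 0,
) -> pd.DataFrame:
    """Per-body table using the voxels known to belong to each vessel."""
    return mean_vessel_so2(
        body_id,
        so2_map,
        so2_true=so2_true,
        dx_mm=dx_mm,
        clip=clip,
        image_id=image_id,
    )


@dataclass
class EvalReport:
    """Pooled error statistics over all bodies of a test set.

    All values in percentage points of sO2.  ``variant`` records whether
    the body voxels came from the segmentation network or the ground truth.
    """

    mae: float
    sd_abs: float
    mean_diff: float
    sd_diff: float
    n_bodies: int
    variant: str
    empty: bool = False
    bodies: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "mae_pp": self.mae,
            "sd_abs_pp": self.sd_abs,
            "mean_diff_pp": self.mean_diff,
            "sd_diff_pp": self.sd_diff,
            "n_bodies": self.n_bodies,
            "variant": self.variant,
            "empty": self.empty,
        }


def evaluate(
    bodies: pd.DataFrame | list[pd.DataFrame], variant: str = "seg-masked"
) -> EvalReport:
    """Pool body tables across a test set and compute the error statistics.

    The signed error per body is (estimated - true) mean sO2 in percentage
    points; the report carries the mean absolute error, the SD of the
    absolute error, and the signed mean and SD.
    """
    if isinstance(bodies, list):
        frames = [b for b in bodies if len(b)]
        table = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )
    else:
        table = bodies
    if len(table) == 0:
        return EvalReport(
            mae=float("nan"),
            sd_abs=float("nan"),
            mean_diff=float("nan"),
            sd_diff=float("nan"),
            n_bodies=0,
            variant=variant,
            empty=True,
        )
    diff = 100.0 * (
        table["est_mean_so2"].to_numpy() - table["true_mean_so2"].to_numpy()
    )
    abs_diff = np.abs(diff)
    return EvalReport(
        mae=float(abs_diff.mean()),
        sd_abs=float(abs_diff.std(ddof=1)) if len(diff) > 1 else 0.0,
        mean_diff=float(diff.mean()),
        sd_diff=float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
        n_bodies=int(len(diff)),
        variant=variant,
        bodies=table,
    )


def evaluate_gt_masked(
    so2_outputs: list[np.ndarray],
    body_ids: list[np.ndarray],
    so2_trues: list[np.ndarray],
    dx_mm: float = 0.1,
    clip: bool = True,
) -> EvalReport:
    """Evaluate using the ground-truth vessel voxels of each body."""
    tables = [
        bodies_from_ground_truth(
            b, o, t, dx_mm=dx_mm, clip=clip, image_id=i
        )
        for i, (o, b, t) in enumerate(zip(so2_outputs, body_ids, so2_trues))
    ]
    return evaluate(tables, variant="gt-masked")


def depth_profile(
    bodies: pd.DataFrame, n_bins: int = 5
) -> tuple[pd.DataFrame, float, float]:
    """Depth-binned mean absolute error and its Spearman depth trend.

    Returns ``(per-bin table, spearman rho, p-value)`` where the Spearman
    statistic is computed over individual bodies (|error| vs depth).
    """
    if len(bodies) == 0:
        raise ValueError("no bodies to profile")
    depth = bodies["depth_mm"].to_numpy()
    err = 100.0 * np.abs(
        bodies["est_mean_so2"].to_numpy() - bodies["true_mean_so2"].to_numpy()
    )
    edges = np.linspace(depth.min(), depth.max() + 1e-9, n_bins + 1)
    rows = []
    for i in range(n_bins):
        sel = (depth >= edges[i]) & (depth < edges[i + 1])
        rows.append(
            {
                "depth_lo_mm": edges[i],
                "depth_hi_mm": edges[i + 1],
                "n_bodies": int(sel.sum()),
                "mae_pp": float(err[sel].mean()) if sel.any() else float("nan"),
            }
        )
    if len(np.unique(depth)) > 1:
        rho, p = stats.spearmanr(depth, err)
    else:
        rho, p = float("nan"), float("nan")
    return pd.DataFrame(rows), float(rho), float(p)


def linear_unmixing_so2(
    image_set: np.ndarray,
    wavelengths: tuple[float, ...],
    alpha_hb: dict[float, float],
    alpha_hbo2: dict[float, float],
) -> np.ndarray:
    """Spectrally naive baseline: per-voxel linear unmixing of the raw image.

    Solves, voxelwise, the least-squares fit of the multiwavelength image
    amplitudes to ``a * alpha_Hb + b * alpha_HbO2`` — i.e. it pretends the
    image were proportional to blood absorption, ignoring the
    wavelength-dependent fluence and reconstruction artifacts — and returns
    sO2 = b / (a + b) clipped to [0, 1].  This is the accuracy floor the
    learned approach is compared against.
    """
    image_set = np.asarray(image_set, dtype=np.float64)
    if image_set.shape[0] != len(wavelengths):
        raise ValueError("channel count does not match wavelengths")
    A = np.stack(
        [[alpha_hb[l] for l in wavelengths], [alpha_hbo2[l] for l in wavelengths]],
        axis=1,
    )  # (n_lambda, 2)
    flat = image_set.reshape(len(wavelengths), -1)
    coef, *_ = np.linalg.lstsq(A, flat, rcond=None)
    total = coef.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(total != 0, coef[1] / total, 0.0)
    return np.clip(so2, 0.0, 1.0).reshape(image_set.shape[1:])
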