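"""Error metrics, relative-stiffness maps and region statistics.

The headline accuracy metric is the mean absolute relative error over
the volume, MARE = 100 * mean(|est - truth| / |truth|).  Region
statistics use medians, which are robust to the few voxels that
straddle region boundaries; those transition voxels are also reported
separately since reconstruction errors concentrate there.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "mare",
    "relative_stiffness_map",
    "inverse_axial_strain_map",
    "region_stats",
    "transition_mask",
    "evaluation_report",
]


def mare(est: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
         ) -> float:
    """Mean absolute relative error in percent over ``mask`` (default all)."""
    est, truth = np.asarray(est), np.asarray(truth)
    if est.shape != truth.shape:
        raise ValueError("estimate and truth shapes differ")
    if mask is None:
        mask = np.ones(est.shape, dtype=bool)
    if np.any(truth[mask] == 0):
        raise ValueError("truth contains zeros inside the mask")
    return 100.0 * float(np.mean(np.abs(est[mask] - truth[mask])
                                 / np.abs(truth[mask])))


def relative_stiffness_map(E: np.ndarray) -> np.ndarray:
    """Elastic-modulus field normalized by its maximum, in (0, 1]."""
    E = np.asarray(E, dtype=float)
    m = E.max()
    if m <= 0:
        raise ValueError("modulus field must have a positive maximum")
    return E / m


def inverse_axial_strain_map(eps_zz: np.ndarray) -> np.ndarray:
    """The conventional surrogate map: 1/|eps_axial| normalized by its
    maximum.  Voxels with zero axial strain are masked to NaN."""
    eps = np.asarray(eps_zz, dtype=float)
    zero = eps == 0.0
    if zero.any():
        warnings.warn(f"masking {int(zero.sum())} zero-axial-strain voxels")
    with np.errstate(divide="ignore"):
        inv = np.where(zero, np.nan, 1.0 / np.abs(eps))
    return inv / np.nanmax(inv)


def region_stats(values: np.ndarray, labels: np.ndarray,
                 background_label: int = 0) -> dict:
    """Per-region median / IQR and median ratio to the background median."""
    values, labels = np.asarray(values), np.asarray(labels)
    if not np.any(labels == background_label):
        raise ValueError(f"background label {background_label} not present")
    bg_median = float(np.nanmedian(values[labels == background_label]))
    out = {}
    for lab in np.unique(labels):
        sel = values[labels == lab]
        if sel.size == 0:
            raise ValueError(f"region {lab} is empty")
        q1, med, q3 = np.nanpercentile(sel, [25, 50, 75])
        out[int(lab)] = {
            "median": float(med),
            "iqr": [float(q1), float(q3)],
            "ratio_to_background": float(med / bg_median),
            "n_voxels": int(sel.size),
        }
    return out


def transition_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels within one voxel of a region boundary (6-connectivity)."""
    labels = np.asarray(labels)
    mask = np.zeros(labels.shape, dtype=bool)
    for axis in range(labels.ndim):
        diff = np.diff(labels, axis=axis) != 0
        lo = [slice(None)] * labels.ndim
        hi = [slice(None)] * labels.ndim
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        mask[tuple(lo)] |= diff
        mask[tuple(hi)] |= diff
    return mask


def evaluation_report(est_params: dict, truth: dict,
                      labels: np.ndarray | None = None,
                      background_label: int = 0) -> dict:
    """Assemble the JSON-serializable accuracy report.

    For every parameter present in both ``est_params`` and ``truth``:
    volume MARE, and — when region labels are given — tissue-only MARE
    (labels != background), per-region statistics of the estimate, and
    the MARE over / outside transition-zone voxels.
    """
    report: dict = {"params": {}}
    common = [k for k in truth if k in est_params]
    if not common:
        raise ValueError("no common parameter keys between estimate and truth")
    trans = transition_mask(labels) if labels is not None else None
    for k in common:
        est, tru = np.asarray(est_params[k]), np.asarray(truth[k])
        entry = {"mare_volume": mare(est, tru)}
        if labels is not None:
            tissue = np.asarray(labels) != background_label
            if tissue.any():
                entry["mare_tissue"] = mare(est, tru, tissue)
            entry["mare_transition"] = (mare(est, tru, trans)
                                        if trans.any() else None)
            entry["mare_interior"] = (mare(est, tru, ~trans)
                                      if (~trans).any() else None)
            entry["regions"] = region_stats(est, labels, background_label)
        report["params"][k] = entry
    report["mean_mare_volume"] = float(np.mean(
        [report["params"][k]["mare_volume"] for k in common]))
    if "E" in common and labels is not None:
        rel = relative_stiffness_map(np.asarray(est_params["E"]))
        report["relative_stiffness_regions"] = region_stats(
            rel, labels, background_label)
    return report
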