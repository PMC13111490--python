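"""Connectivity-matrix construction from streamline-probability volumes.

The connection probability ``p_ij`` between parcels i and j is the mean of
parcel i's streamline-probability map over the voxels of parcel j.  Volumes
are plain index-based 3-D arrays; registration and tractography happen
upstream and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ParameterError, ShapeError, ValidationError, WeightedNetwork


class DataError(ValueError):
    """Input data violates a physical constraint (e.g. count > n_samples)."""


@dataclass
class ProbabilityVolume:
    """Per-ROI streamline probability map: 3-D grid of values in [0, 1]."""

    values: np.ndarray
    source_roi: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ShapeError(f"expected a 3-D grid, got {v.ndim}-D")
        if not np.isfinite(v).all():
            raise ValidationError("probability volume contains non-finite values")
        if (v < 0).any() or (v > 1).any():
            raise ValidationError("probability volume values must lie in [0, 1]")
        self.values = v


@dataclass
class LabelVolume:
    """Integer parcellation: 0 = background, 1..n = ROI labels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ShapeError(f"expected a 3-D grid, got {v.ndim}-D")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.array_equal(v, v.astype(np.int64)):
                raise ValidationError("labels must be integers")
            v = v.astype(np.int64)
        if (v < 0).any():
            raise ValidationError("labels must be non-negative")
        self.values = v

    @property
    def n_rois(self) -> int:
        return int(self.values.max())


def normalize_streamline_counts(count_map, n_samples: int) -> ProbabilityVolume:
    """Streamline hit counts -> probabilities, dividing by the sample count
    (5000 samples per seed voxel in the reference tracking protocol)."""
    if n_samples <= 0:
        raise ParameterError("n_samples must be positive")
    counts = np.asarray(count_map)
    if (counts < 0).any():
        raise DataError("streamline counts must be non-negative")
    if (counts > n_samples).any():
        i = np.argwhere(counts > n_samples)[0]
        raise DataError(
            f"count {counts[tuple(i)]} at voxel {tuple(i)} exceeds "
            f"n_samples={n_samples} (probability would exceed 1)"
        )
    return ProbabilityVolume(counts / float(n_samples))


def union_probability_maps(
    maps: list[ProbabilityVolume], mode: str = "complement-product"
) -> ProbabilityVolume:
    """Voxelwise union of seed-voxel probability maps.

    ``complement-product`` (default) treats seeds as independent:
    ``1 - prod(1 - p_s)``.  ``max`` takes the voxelwise maximum.
    """
    if not maps:
        raise ParameterError("need at least one probability map")
    shape = maps[0].values.shape
    for m in maps[1:]:
        if m.values.shape != shape:
            raise ShapeError(
                f"grid mismatch: {m.values.shape} vs {shape}"
            )
    stack = np.stack([m.values for m in maps])
    if mode == "complement-product":
        out = 1.0 - np.prod(1.0 - stack, axis=0)
    elif mode == "max":
        out = stack.max(axis=0)
    else:
        raise ParameterError(f"unknown union mode {mode!r}")
    return ProbabilityVolume(np.clip(out, 0.0, 1.0), maps[0].source_roi)


def build_connectivity_matrix(
    maps: dict[int, ProbabilityVolume] | list,
    labels: LabelVolume,
    node_labels: list[str] | None = None,
) -> WeightedNetwork:
    """Assemble the weighted directed connectivity matrix.

    ``maps`` provides one probability volume per ROI (list in ROI order
    1..n, or dict keyed by ROI id).  Entry ``(i, j)`` of the result is the
    mean of map i over voxels labelled j+1; the diagonal is forced to zero.
    Background voxels (label 0) never contribute.
    """
    n = labels.n_rois
    if n < 2:
        raise ParameterError("need at least 2 ROIs")
    if isinstance(maps, dict):
        vol_by_roi = {int(k): v for k, v in maps.items()}
    else:
        vol_by_roi = {i + 1: v for i, v in enumerate(maps)}
    missing = [r for r in range(1, n + 1) if r not in vol_by_roi]
    if missing:
        raise ParameterError(f"missing probability maps for ROIs {missing}")

    lab = labels.values
    roi_voxels = []
    for j in range(1, n + 1):
        vox = lab == j
        if not vox.any():
            raise DataError(f"ROI {j} has zero voxels in the label volume")
        roi_voxels.append(vox)

    w = np.zeros((n, n))
    for i in range(1, n + 1):
        vol = vol_by_roi[i]
        if vol.values.shape != lab.shape:
            raise ShapeError(
                f"map for ROI {i} has shape {vol.values.shape}, "
                f"label volume has {lab.shape}"
            )
        for j in range(n):
            w[i - 1, j] = vol.values[roi_voxels[j]].mean()
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w, node_labels or [])
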