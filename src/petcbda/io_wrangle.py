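"""3D→1D recasting, DVR filtering and threshold/consistency voxel retention.

Flat ordering
-------------
Volumes indexed ``[i, j, k]`` are flattened x-fastest:
``flat = i + nx * j + nx * ny * k`` (NumPy Fortran order), so neighbouring
flat indices are neighbours along x.  :func:`unflatten` is the tested inverse.

Pipeline
--------
``flatten`` (mask, keep array length) → ``dvr_floor`` (zero DVR < 1.1 per
image) → ``apply_threshold`` (cohort-level retention: a voxel survives iff its
DVR exceeds the intensity threshold in at least ``consistency`` of the
images).  ``assemble_matrix*`` runs all three and attaches the binary outcome
(migraine = 1, healthy = 0) and per-row metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_pet import (
    MIGRAINE_GROUPS,
    MaskVolume,
    PETImage,
    read_cohort,
    read_mask,
)

DVR_FLOOR = 1.1

ROW_META_COLUMNS = ["subject_id", "tracer", "group", "state", "phase", "sex"]


@dataclass(frozen=True)
class ThresholdSpec:
    """Cohort-level voxel retention rule."""

    intensity_threshold: float
    consistency: float

    def __post_init__(self) -> None:
        if self.intensity_threshold <= 0:
            raise ValueError("intensity_threshold must be > 0 (DVR units)")
        if not 0.0 <= self.consistency <= 1.0:
            raise ValueError("consistency must be in [0, 1]")


def flatten(image: PETImage, mask: MaskVolume) -> np.ndarray:
    """Recast one volume into a 1D DVR array of unchanged length.

    Out-of-mask entries are exactly 0; in-mask entries are DVR = bpnd + 1.
    """
    if tuple(image.grid.dims) != tuple(mask.grid.dims):
        raise ValueError(
            f"grid mismatch: image {tuple(image.grid.dims)} vs mask {tuple(mask.grid.dims)}"
        )
    arr = np.where(mask.mask, image.dvr, 0.0)
    return arr.reshape(-1, order="F")


def unflatten(flat: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    """Inverse of the x-fastest flattening."""
    return np.asarray(flat).reshape(dims, order="F")


def flat_to_ijk(flat_index, dims: tuple[int, int, int]) -> np.ndarray:
    """Vectorised ``flat -> (i, j, k)`` for the documented ordering."""
    flat_index = np.asarray(flat_index)
    nx, ny, _ = dims
    i = flat_index % nx
    j = (flat_index // nx) % ny
    k = flat_index // (nx * ny)
    return np.stack([i, j, k], axis=-1)


def ijk_to_flat(ijk, dims: tuple[int, int, int]) -> np.ndarray:
    ijk = np.asarray(ijk)
    nx, ny, _ = dims
    return ijk[..., 0] + nx * ijk[..., 1] + nx * ny * ijk[..., 2]


def dvr_floor(array: np.ndarray, floor: float = DVR_FLOOR) -> np.ndarray:
    """Zero out entries with DVR < ``floor`` (per-image intensity filtering).

    Column *removal* is a cohort-level decision and belongs to
    :func:`apply_threshold`; zeroing keeps array lengths comparable across
    images.
    """
    out = np.array(array, dtype=float, copy=True)
    out[out < floor] = 0.0
    return out


def apply_threshold(
    X_full: np.ndarray, spec: ThresholdSpec, col_flat: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Retain columns whose DVR exceeds the threshold consistently.

    Column ``v`` is kept iff
    ``(# rows with DVR(v) > intensity_threshold) / n_rows >= consistency``
    ("above" is strict; "at least" is inclusive).  Column order is preserved
    and the returned flat indices are the survivors' original ones.
    """
    X_full = np.asarray(X_full, dtype=float)
    if X_full.ndim != 2 or X_full.shape[0] < 1:
        raise ValueError("need a 2D matrix with at least one row")
    if col_flat is None:
        col_flat = np.arange(X_full.shape[1])
    col_flat = np.asarray(col_flat)
    frac = (X_full > spec.intensity_threshold).mean(axis=0)
    keep = frac >= spec.consistency
    if not keep.any():
        raise ValueError(
            f"no voxel exceeds DVR {spec.intensity_threshold} in "
            f"{spec.consistency:.0%} of images; lower the threshold or consistency"
        )
    return X_full[:, keep], col_flat[keep]


@dataclass
class VoxelMatrix:
    """Images x retained-voxels design matrix with outcome and index maps."""

    X: np.ndarray
    y: np.ndarray
    row_meta: pd.DataFrame
    col_flat: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.col_flat = np.asarray(self.col_flat, dtype=int)
        if self.X.shape != (len(self.y), len(self.col_flat)):
            raise ValueError("X shape inconsistent with y / col_flat")
        if len(self.row_meta) != len(self.y):
            raise ValueError("row_meta length inconsistent with y")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("y must be binary")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if len(np.unique(self.col_flat)) != len(self.col_flat):
            raise ValueError("col_flat must be injective")

    @property
    def n_images(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def col_ijk(self) -> np.ndarray:
        return flat_to_ijk(self.col_flat, self.dims)

    def columns_of(self, flat_ids) -> np.ndarray:
        """Positions in ``X`` of the given original flat voxel ids."""
        lookup = {int(f): pos for pos, f in enumerate(self.col_flat)}
        try:
            return np.array([lookup[int(f)] for f in flat_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"flat voxel id {exc.args[0]} not in retained columns") from exc

    # -- persistence: dense array + TSV maps under one directory -------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "X.npy", self.X)
        meta = self.row_meta.copy()
        meta["y"] = self.y
        meta.to_csv(directory / "rows.tsv", sep="\t", index=False)
        ijk = self.col_ijk
        pd.DataFrame(
            {"flat": self.col_flat, "i": ijk[:, 0], "j": ijk[:, 1], "k": ijk[:, 2]}
        ).to_csv(directory / "cols.tsv", sep="\t", index=False)
        (directory / "grid.json").write_text(json.dumps({"dims": list(self.dims)}))

    @classmethod
    def load(cls, directory) -> "VoxelMatrix":
        directory = Path(directory)
        X = np.load(directory / "X.npy")
        rows = pd.read_csv(directory / "rows.tsv", sep="\t")
        cols = pd.read_csv(directory / "cols.tsv", sep="\t")
        dims = tuple(json.loads((directory / "grid.json").read_text())["dims"])
        y = rows.pop("y").to_numpy()
        return cls(X=X, y=y, row_meta=rows, col_flat=cols["flat"].to_numpy(), dims=dims)


def _outcome(group: str) -> int:
    return 1 if group in MIGRAINE_GROUPS else 0


def assemble_matrix_from_images(
    images: list[PETImage],
    mask: MaskVolume,
    spec: ThresholdSpec,
    interictal_only: bool = False,
) -> VoxelMatrix:
    """flatten → dvr_floor → apply_threshold over an in-memory cohort.

    ``interictal_only`` drops ictal sessions (healthy controls, whose state is
    ``none``, are kept) before thresholding.
    """
    if not images:
        raise ValueError("no images supplied")
    tracers = {im.tracer for im in images}
    if len(tracers) > 1:
        raise ValueError(f"mixed tracers in one matrix: {sorted(tracers)}")
    if interictal_only:
        images = [im for im in images if im.state != "ictal"]
    if not images:
        raise ValueError("no images left after interictal filtering")
    rows = [dvr_floor(flatten(im, mask)) for im in images]
    X_full = np.vstack(rows)
    X, col_flat = apply_threshold(X_full, spec)
    meta = pd.DataFrame(
        [
            [im.subject_id, im.tracer, im.group, im.state, im.phase, im.sex]
            for im in images
        ],
        columns=ROW_META_COLUMNS,
    )
    y = np.array([_outcome(im.group) for im in images])
    return VoxelMatrix(X=X, y=y, row_meta=meta, col_flat=col_flat, dims=tuple(mask.grid.dims))


def assemble_matrix(
    cohort_dir,
    mask_path,
    tracer: str,
    spec: ThresholdSpec,
    interictal_only: bool = False,
) -> VoxelMatrix:
    """Disk-backed assembly from a written cohort (manifest + NIfTI volumes)."""
    mask = read_mask(mask_path)
    images = read_cohort(cohort_dir, tracer=tracer)
    if not images:
        raise ValueError(f"no {tracer} images found in {cohort_dir}")
    return assemble_matrix_from_images(images, mask, spec, interictal_only=interictal_only)
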