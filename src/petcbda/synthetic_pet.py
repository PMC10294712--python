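"""Synthetic two-tracer PET BP_ND cohorts with a labelled atlas and masks.

Everything downstream (wrangling, stacking, subsample ranking, reporting) is
exercised against volumes produced here.  The generator emits parametric
DVR/BP_ND maps directly: a per-label baseline DVR, additive group effects in
configurable regions, an additive late-phase effect, and spatially smoothed
Gaussian noise.  Reference regions (occipital cortex for CFN, cerebellar grey
for RCL) are pinned at DVR = 1 exactly.

Conventions
-----------
- Voxel indices ``(i, j, k)`` are 0-based; ``i`` is the x axis.
- ``BP_ND = DVR - 1``; images store ``bpnd``.
- Sessions are one ``subject x tracer x state``; each yields two images
  (phases ``early`` and ``late``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

TRACERS = ("CFN", "RCL")
GROUPS = ("HC", "EM", "CM")
STATES = ("none", "interictal", "ictal")
PHASES = ("early", "late")
MIGRAINE_GROUPS = frozenset({"EM", "CM"})

#: per-tracer reference region (full label name); DVR pinned at 1 there
REFERENCE_LABELS = {"CFN": "occipital", "RCL": "cerebellar grey"}

#: basal-ganglia ROI names used for the RCL mask
BASAL_GANGLIA_ROIS = frozenset({"putamen", "caudate", "pallidum"})

GAUSSIAN_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BrainGrid:
    """Voxel grid with an affine mapping 0-based indices to millimetres."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 8 for d in self.dims):
            raise ValueError(f"grid dims must be >= (8, 8, 8), got {self.dims}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0]).astype(float)
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz


def default_test_grid() -> BrainGrid:
    """Desk-scale grid used throughout the test suite (24 x 28 x 24 @ 4 mm)."""
    return BrainGrid(dims=(24, 28, 24), voxel_size_mm=(4.0, 4.0, 4.0))


def full_scale_grid() -> BrainGrid:
    """Full-resolution 2 mm grid (91 x 109 x 91)."""
    return BrainGrid(dims=(91, 109, 91), voxel_size_mm=(2.0, 2.0, 2.0))


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def full_label_name(roi: str, subregion: str | None) -> str:
    return roi if subregion is None else f"{roi}({subregion})"


@dataclass
class LabeledAtlas:
    """Integer label volume plus a ``label -> (roi, subregion)`` table."""

    grid: BrainGrid
    labels: np.ndarray
    label_table: dict[int, tuple[str, str | None]]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels present in volume but not in table: {sorted(missing)}")

    def name_of(self, label: int) -> str:
        roi, sub = self.label_table[label]
        return full_label_name(roi, sub)

    def labels_named(self, name: str) -> list[int]:
        """All label values whose full name or bare ROI name matches ``name``."""
        out = []
        for lab, (roi, sub) in self.label_table.items():
            if name == full_label_name(roi, sub) or name == roi:
                out.append(lab)
        return out

    def mask_of(self, names) -> np.ndarray:
        """Boolean volume covering every label matching any of ``names``."""
        want: set[int] = set()
        for name in names:
            want.update(self.labels_named(name))
        return np.isin(self.labels, sorted(want))


# canonical box layout, in fractions of a 24 x 28 x 24 grid.  Bilateral
# entries give the LEFT box; the right copy is mirrored in x.  Fractions use
# half-open voxel ranges [lo, hi).
_CANON = (24.0, 28.0, 24.0)


def _frac(lo, hi):
    return tuple(l / c for l, c in zip(lo, _CANON)), tuple(h / c for h, c in zip(hi, _CANON))


# (roi, subregion, bilateral, box) — boxes must not overlap after mirroring
_ROI_BOXES: list[tuple[str, str | None, bool, tuple]] = [
    ("insula", "anterior", True, _frac((2, 16, 8), (4, 21, 12))),
    ("insula", "posterior", True, _frac((2, 10, 8), (4, 15, 12))),
    ("putamen", "anterior", True, _frac((4, 16, 9), (6, 20, 13))),
    ("putamen", "posterior", True, _frac((4, 11, 9), (6, 15, 13))),
    ("pallidum", None, True, _frac((6, 12, 9), (8, 16, 12))),
    ("thalamus", "pulvinar", True, _frac((8, 9, 10), (11, 12, 13))),
    ("thalamus", "medial dorsal", True, _frac((8, 12, 10), (11, 15, 13))),
    ("thalamus", "ventral lateral", True, _frac((8, 15, 10), (11, 18, 13))),
    ("thalamus", "VPL", True, _frac((8, 12, 7), (11, 15, 10))),
    ("thalamus", "VPM", True, _frac((8, 15, 7), (11, 18, 10))),
    ("caudate", None, True, _frac((8, 19, 10), (11, 22, 14))),
    ("occipital", None, False, _frac((6, 1, 8), (18, 4, 16))),
    ("cerebellar grey", None, False, _frac((7, 1, 2), (17, 5, 7))),
]

REQUIRED_LABEL_NAMES = tuple(
    sorted({full_label_name(r, s) for r, s, _, _ in _ROI_BOXES} | {"grey matter"})
)


def _box_voxels(grid: BrainGrid, box, jitter: np.ndarray) -> tuple[slice, slice, slice]:
    (flo, fhi) = box
    lo = [int(round(f * d)) + int(j) for f, d, j in zip(flo, grid.dims, jitter)]
    hi = [int(round(f * d)) + int(j) for f, d, j in zip(fhi, grid.dims, jitter)]
    return tuple(slice(l, h) for l, h in zip(lo, hi)), lo, hi


def build_default_atlas(grid: BrainGrid, seed: int = 0) -> LabeledAtlas:
    """Place every required ROI as a contiguous box on ``grid``.

    A rigid one-voxel jitter derived from ``seed`` shifts the whole layout so
    repeated builds with different seeds are not voxel-identical, while the
    relative geometry (and therefore non-overlap) is preserved.

    Raises
    ------
    ValueError
        If the grid is too small to place an ROI (the message names it).
    """
    rng = np.random.default_rng(seed)
    jitter = rng.integers(-1, 2, size=3)

    labels = np.zeros(grid.dims, dtype=np.int32)
    table: dict[int, tuple[str, str | None]] = {}
    next_label = 1

    def paint(roi: str, sub: str | None, sl, lo, hi) -> None:
        nonlocal next_label
        name = full_label_name(roi, sub)
        if any(l < 0 for l in lo) or any(h > d for h, d in zip(hi, grid.dims)) or any(
            h <= l for l, h in zip(lo, hi)
        ):
            raise ValueError(f"grid {grid.dims} too small to place ROI {name!r}")
        region = labels[sl]
        if np.any(region != 0):
            raise ValueError(f"grid {grid.dims} too small to place ROI {name!r} without overlap")
        labels[sl] = next_label
        table[next_label] = (roi, sub)
        next_label += 1

    for roi, sub, bilateral, box in _ROI_BOXES:
        sl, lo, hi = _box_voxels(grid, box, jitter)
        paint(roi, sub, sl, lo, hi)
        if bilateral:
            nx = grid.dims[0]
            mlo = [nx - hi[0]] + lo[1:]
            mhi = [nx - lo[0]] + hi[1:]
            msl = tuple(slice(l, h) for l, h in zip(mlo, mhi))
            paint(roi, sub, msl, mlo, mhi)

    # generic grey matter: brain ellipsoid minus everything painted so far
    centre = np.array([(d - 1) / 2.0 for d in grid.dims]) + jitter
    semi = np.array([0.46 * d for d in grid.dims])
    idx = np.indices(grid.dims)
    inside = sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3)) <= 1.0
    gm = inside & (labels == 0)
    if gm.sum() < 1:
        raise ValueError(f"grid {grid.dims} too small to place ROI 'grey matter'")
    labels[gm] = next_label
    table[next_label] = ("grey matter", None)

    return LabeledAtlas(grid=grid, labels=labels, label_table=table)


@dataclass
class MaskVolume:
    """Binary analysis mask on a :class:`BrainGrid`."""

    grid: BrainGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != tuple(self.grid.dims):
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid {self.grid.dims}"
            )
        if not self.mask.any():
            raise ValueError("mask is empty")


def build_masks(atlas: LabeledAtlas) -> dict[str, MaskVolume]:
    """Tracer-specific analysis masks.

    CFN: all grey-matter tissue except the cerebellum (whole-brain mask).
    RCL: basal ganglia only (putamen, caudate, pallidum).
    """
    cfn = (atlas.labels > 0) & ~atlas.mask_of(["cerebellar grey"])
    rcl = atlas.mask_of(sorted(BASAL_GANGLIA_ROIS))
    return {
        "CFN": MaskVolume(grid=atlas.grid, mask=cfn),
        "RCL": MaskVolume(grid=atlas.grid, mask=rcl),
    }


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stratum:
    """One cell of the cohort design.

    ``link_to`` names another stratum whose subjects this stratum re-uses
    (e.g. the ictal sessions of a subset of the interictal episodic
    migraineurs): the first ``n_female`` female and ``n_subjects - n_female``
    male subjects of the parent, in parent order, are selected.
    """

    name: str
    tracer: str
    group: str
    state: str
    n_subjects: int
    n_female: int
    link_to: str | None = None

    def __post_init__(self) -> None:
        if self.tracer not in TRACERS:
            raise ValueError(f"unknown tracer {self.tracer!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.n_subjects < 0 or not 0 <= self.n_female <= self.n_subjects:
            raise ValueError(f"bad counts in stratum {self.name!r}")


@dataclass(frozen=True)
class CohortSpec:
    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.strata]
        if len(set(names)) != len(names):
            raise ValueError("stratum names must be unique")


def default_cohort_spec() -> CohortSpec:
    """Two-tracer study composition.

    CFN: 23 HC, 7 CM (ictal), 31 EM (interictal), 8 of those EM also ictal.
    RCL: 10 of the HC, 12 of the EM (interictal), 8 of those also ictal —
    61 CFN subjects / 138 images and 22 RCL subjects / 60 images; the shared
    ictal subset is the same 8 episodic migraineurs under both tracers.
    """
    return CohortSpec(
        strata=(
            Stratum("cfn_hc", "CFN", "HC", "none", 23, 17),
            Stratum("cfn_cm_ictal", "CFN", "CM", "ictal", 7, 6),
            Stratum("cfn_em_interictal", "CFN", "EM", "interictal", 31, 23),
            Stratum("cfn_em_ictal", "CFN", "EM", "ictal", 8, 4, link_to="cfn_em_interictal"),
            Stratum("rcl_hc", "RCL", "HC", "none", 10, 5, link_to="cfn_hc"),
            Stratum("rcl_em_interictal", "RCL", "EM", "interictal", 12, 7, link_to="cfn_em_interictal"),
            Stratum("rcl_em_ictal", "RCL", "EM", "ictal", 8, 4, link_to="rcl_em_interictal"),
        )
    )


def mini_cohort_spec() -> CohortSpec:
    """Tiny single-tracer cohort for fast end-to-end runs (24 images)."""
    return CohortSpec(
        strata=(
            Stratum("cfn_hc", "CFN", "HC", "none", 4, 2),
            Stratum("cfn_em_interictal", "CFN", "EM", "interictal", 6, 3),
            Stratum("cfn_em_ictal", "CFN", "EM", "ictal", 2, 1, link_to="cfn_em_interictal"),
        )
    )


@dataclass(frozen=True)
class Session:
    subject_id: str
    tracer: str
    group: str
    state: str
    sex: str  # "F" | "M"


@dataclass(frozen=True)
class ImageRecord:
    subject_id: str
    tracer: str
    group: str
    state: str
    phase: str
    sex: str


def _subject_roster(stratum: Stratum, counters: dict[str, int]) -> list[tuple[str, str]]:
    """Fresh subjects for a root stratum: females first, then males."""
    roster = []
    for sex, count in (("F", stratum.n_female), ("M", stratum.n_subjects - stratum.n_female)):
        for _ in range(count):
            counters[stratum.group] = counters.get(stratum.group, 0) + 1
            roster.append((f"{stratum.group.lower()}{counters[stratum.group]:03d}", sex))
    return roster


def _linked_roster(stratum: Stratum, parent: list[tuple[str, str]]) -> list[tuple[str, str]]:
    females = [s for s in parent if s[1] == "F"]
    males = [s for s in parent if s[1] == "M"]
    n_male = stratum.n_subjects - stratum.n_female
    if stratum.n_female > len(females) or n_male > len(males):
        raise ValueError(
            f"linked stratum {stratum.name!r} ({stratum.n_female}F/{n_male}M) is larger "
            f"than its parent {stratum.link_to!r} ({len(females)}F/{len(males)}M)"
        )
    return females[: stratum.n_female] + males[:n_male]


def generate_cohort(spec: CohortSpec, seed: int = 0) -> list[Session]:
    """Expand a :class:`CohortSpec` into one session record per subject x state.

    Deterministic: the roster depends only on the spec (``seed`` is accepted
    for interface symmetry with the simulators and recorded by callers).
    """
    del seed  # roster construction is fully deterministic
    counters: dict[str, int] = {}
    rosters: dict[str, list[tuple[str, str]]] = {}
    sessions: list[Session] = []
    for stratum in spec.strata:
        if stratum.link_to is None:
            roster = _subject_roster(stratum, counters)
        else:
            if stratum.link_to not in rosters:
                raise ValueError(
                    f"stratum {stratum.name!r} links to unknown or later stratum "
                    f"{stratum.link_to!r}"
                )
            roster = _linked_roster(stratum, rosters[stratum.link_to])
        rosters[stratum.name] = roster
        for subject_id, sex in roster:
            sessions.append(
                Session(subject_id, stratum.tracer, stratum.group, stratum.state, sex)
            )
    return sessions


def list_images(sessions: list[Session]) -> list[ImageRecord]:
    """Two phase images (early, late) per session."""
    return [
        ImageRecord(s.subject_id, s.tracer, s.group, s.state, phase, s.sex)
        for s in sessions
        for phase in PHASES
    ]


# ---------------------------------------------------------------------------
# effects and image simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEffect:
    """Additive DVR shift applied to migraine-group images of one tracer."""

    tracer: str
    delta: float
    labels: tuple[str, ...] = ()
    voxels: tuple[tuple[int, int, int], ...] = ()


@dataclass(frozen=True)
class EffectSpec:
    """Deterministic signal plus smoothed-noise model for simulated DVR.

    ``baseline_dvr`` maps full label names to baseline DVR; the key
    ``"default"`` covers unlisted labels; background (label 0) is always 0.
    Reference labels are forced to 1.0 regardless of the table.
    """

    baseline_dvr: dict[str, float] = field(default_factory=dict)
    group_effects: tuple[GroupEffect, ...] = ()
    phase_effect: float = 0.0
    noise_sd: float = 0.0
    smoothing_fwhm_mm: tuple[float, float, float] = (3.0, 3.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(f < 0 for f in self.smoothing_fwhm_mm):
            raise ValueError("smoothing FWHM must be >= 0")


def default_effect_spec(seed: int = 0, noise_sd: float = 0.3) -> EffectSpec:
    """Receptor-rich baselines with group effects in the predictive ROIs.

    CFN: lowered mu-opioid availability in anterior insula, thalamic nuclei
    and anterior putamen of migraineurs; RCL: raised D2/D3 availability in
    anterior putamen.
    """
    baseline = {
        "default": 2.5,
        "putamen(anterior)": 2.8,
        "putamen(posterior)": 2.8,
        "caudate": 2.8,
        "pallidum": 2.8,
        "occipital": 1.0,
        "cerebellar grey": 1.0,
    }
    effects = (
        GroupEffect(
            tracer="CFN",
            delta=-0.4,
            labels=(
                "insula(anterior)",
                "thalamus(pulvinar)",
                "thalamus(medial dorsal)",
                "thalamus(ventral lateral)",
                "putamen(anterior)",
            ),
        ),
        GroupEffect(tracer="RCL", delta=0.4, labels=("putamen(anterior)",)),
    )
    return EffectSpec(
        baseline_dvr=baseline,
        group_effects=effects,
        phase_effect=0.05,
        noise_sd=noise_sd,
        seed=seed,
    )


def null_effect_spec(seed: int = 0, noise_sd: float = 0.3) -> EffectSpec:
    """Same baselines as the default spec but no group effects anywhere."""
    spec = default_effect_spec(seed=seed, noise_sd=noise_sd)
    return replace(spec, group_effects=())


@dataclass
class PETImage:
    """One subject x phase BP_ND volume with its acquisition metadata."""

    subject_id: str
    tracer: str
    group: str
    state: str
    phase: str
    sex: str
    grid: BrainGrid
    bpnd: np.ndarray

    @property
    def dvr(self) -> np.ndarray:
        return self.bpnd + 1.0

    @property
    def is_migraine(self) -> bool:
        return self.group in MIGRAINE_GROUPS


def _baseline_volume(effects: EffectSpec, atlas: LabeledAtlas) -> np.ndarray:
    default = float(effects.baseline_dvr.get("default", 0.0))
    per_label = np.zeros(max(atlas.label_table) + 1)
    for lab, (roi, sub) in atlas.label_table.items():
        name = full_label_name(roi, sub)
        value = effects.baseline_dvr.get(name, effects.baseline_dvr.get(roi, default))
        per_label[lab] = value
    for ref_name in REFERENCE_LABELS.values():
        for lab in atlas.labels_named(ref_name):
            per_label[lab] = 1.0
    return per_label[atlas.labels]


def _noise_sigma_voxels(effects: EffectSpec, grid: BrainGrid) -> tuple[float, ...]:
    return tuple(
        f / GAUSSIAN_FWHM_TO_SIGMA / v for f, v in zip(effects.smoothing_fwhm_mm, grid.voxel_size_mm)
    )


def simulate_image(
    record: ImageRecord,
    effects: EffectSpec,
    atlas: LabeledAtlas,
    rng: np.random.Generator,
) -> PETImage:
    """Simulate one BP_ND volume.

    DVR(v) = baseline(label(v)) + sum of matching group deltas
    + phase_effect (late images, in-atlas voxels) + smoothed Gaussian noise,
    clipped at 0; the tracer's reference region is then pinned at DVR = 1.
    """
    if not atlas.labels_named(REFERENCE_LABELS[record.tracer]):
        raise ValueError(
            f"atlas has no reference label {REFERENCE_LABELS[record.tracer]!r} "
            f"for tracer {record.tracer}"
        )
    dvr = _baseline_volume(effects, atlas).copy()

    if record.group in MIGRAINE_GROUPS:
        for eff in effects.group_effects:
            if eff.tracer != record.tracer:
                continue
            if eff.labels:
                dvr[atlas.mask_of(eff.labels)] += eff.delta
            for ijk in eff.voxels:
                dvr[tuple(ijk)] += eff.delta

    if record.phase == "late" and effects.phase_effect:
        dvr[atlas.labels > 0] += effects.phase_effect

    if effects.noise_sd > 0:
        noise = rng.normal(0.0, effects.noise_sd, size=atlas.grid.dims)
        sigma = _noise_sigma_voxels(effects, atlas.grid)
        if any(s > 0 for s in sigma):
            noise = gaussian_filter(noise, sigma=sigma)
        dvr = dvr + noise

    np.clip(dvr, 0.0, None, out=dvr)
    dvr[atlas.mask_of([REFERENCE_LABELS[record.tracer]])] = 1.0

    return PETImage(
        subject_id=record.subject_id,
        tracer=record.tracer,
        group=record.group,
        state=record.state,
        phase=record.phase,
        sex=record.sex,
        grid=atlas.grid,
        bpnd=(dvr - 1.0).astype(np.float64),
    )


def simulate_cohort(
    spec: CohortSpec, effects: EffectSpec, atlas: LabeledAtlas
) -> list[PETImage]:
    """Simulate every image of a cohort; bit-identical for identical inputs.

    One child RNG per image, spawned in a fixed order from ``effects.seed``,
    so per-image randomness does not depend on evaluation order.
    """
    records = list_images(generate_cohort(spec))
    streams = np.random.SeedSequence(effects.seed).spawn(len(records))
    return [
        simulate_image(rec, effects, atlas, np.random.default_rng(ss))
        for rec, ss in zip(records, streams)
    ]


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "tracer", "group", "state", "phase", "sex", "filename"]


def write_cohort(images: list[PETImage], directory) -> pd.DataFrame:
    """Write one float32 NIfTI per image plus a TSV manifest; returns the manifest."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        fname = f"{im.subject_id}_{im.tracer}_{im.state}_{im.phase}.nii.gz"
        path = directory / fname
        try:
            nib.save(nib.Nifti1Image(im.bpnd.astype(np.float32), im.grid.affine), path)
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed writing {path}: {exc}") from exc
        rows.append([im.subject_id, im.tracer, im.group, im.state, im.phase, im.sex, fname])
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_cohort(directory, tracer: str | None = None) -> list[PETImage]:
    """Read a cohort written by :func:`write_cohort` back into memory."""
    from pathlib import Path

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    images = []
    for row in manifest.itertuples(index=False):
        if tracer is not None and row.tracer != tracer:
            continue
        img = nib.load(directory / row.filename)
        data = np.asarray(img.dataobj, dtype=np.float64)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        grid = BrainGrid(dims=data.shape, voxel_size_mm=vox,
                         origin_mm=tuple(float(x) for x in img.affine[:3, 3]))
        images.append(
            PETImage(row.subject_id, row.tracer, row.group, row.state, row.phase,
                     row.sex, grid, data)
        )
    return images


def write_atlas(atlas: LabeledAtlas, directory) -> None:
    """Save the label volume and its table next to each other."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine),
        directory / "atlas.nii.gz",
    )
    rows = [
        [lab, roi, "" if sub is None else sub]
        for lab, (roi, sub) in sorted(atlas.label_table.items())
    ]
    pd.DataFrame(rows, columns=["label", "roi", "subregion"]).to_csv(
        directory / "atlas_labels.tsv", sep="\t", index=False
    )


def read_atlas(directory) -> LabeledAtlas:
    from pathlib import Path

    directory = Path(directory)
    img = nib.load(directory / "atlas.nii.gz")
    labels = np.asarray(img.dataobj).astype(np.int32)
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = BrainGrid(dims=labels.shape, voxel_size_mm=vox,
                     origin_mm=tuple(float(x) for x in img.affine[:3, 3]))
    table_df = pd.read_csv(directory / "atlas_labels.tsv", sep="\t", keep_default_na=False)
    table = {
        int(r.label): (r.roi, None if r.subregion == "" else r.subregion)
        for r in table_df.itertuples(index=False)
    }
    return LabeledAtlas(grid=grid, labels=labels, label_table=table)


def write_mask(mask: MaskVolume, path) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), mask.grid.affine), path)


def read_mask(path) -> MaskVolume:
    img = nib.load(path)
    data = np.asarray(img.dataobj).astype(bool)
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = BrainGrid(dims=data.shape, voxel_size_mm=vox,
                     origin_mm=tuple(float(x) for x in img.affine[:3, 3]))
    return MaskVolume(grid=grid, mask=data)


def summarize_counts(sessions: list[Session]) -> dict[str, int]:
    """Closed-form bookkeeping used by reports and acceptance checks."""
    images = list_images(sessions)
    counts = {
        "sessions": len(sessions),
        "images": len(images),
        "subjects": len({s.subject_id for s in sessions}),
        "migraine_images": sum(1 for im in images if im.group in MIGRAINE_GROUPS),
    }
    for tracer in TRACERS:
        tr_sessions = [s for s in sessions if s.tracer == tracer]
        tr_images = [im for im in images if im.tracer == tracer]
        counts[f"{tracer}_subjects"] = len({s.subject_id for s in tr_sessions})
        counts[f"{tracer}_images"] = len(tr_images)
        counts[f"{tracer}_em_interictal_images"] = sum(
            1 for im in tr_images if im.group == "EM" and im.state == "interictal"
        )
    return counts
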