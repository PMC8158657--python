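"""NIfTI study I/O, modality normalization, and hierarchical label mapping.

A study is four co-registered, skull-stripped scalar volumes (T1, T1c, T2,
FLAIR) on one voxel grid, with an integer sub-compartment segmentation.
Sub-compartment codes follow the BraTS convention (configurable):
0 = background, 1 = NCR/NET, 2 = ED, 4 = ET. The three hierarchical regions
are WT = ED | NCR/NET | ET, TC = NCR/NET | ET, ET = ET, nested ET <= TC <= WT.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

MODALITIES = ("t1", "t1c", "t2", "flair")

#: default BraTS-style label codes
DEFAULT_CODES: Mapping[str, int] = {"background": 0, "ncr_net": 1, "ed": 2, "et": 4}


class MissingModalityError(FileNotFoundError):
    """A required modality file is absent."""


class GridMismatchError(ValueError):
    """Modalities disagree on shape or affine."""


class ConstantImageError(ValueError):
    """Normalization domain has zero variance."""


class UnknownLabelError(ValueError):
    """Segmentation contains a code outside the declared set."""


class NestingError(ValueError):
    """Hierarchical masks violate ET <= TC <= WT."""


@dataclasses.dataclass
class MultiModalStudy:
    """One subject: four modality volumes on a shared grid."""

    t1: np.ndarray
    t1c: np.ndarray
    t2: np.ndarray
    flair: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    subject_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self):
        shapes = {m: getattr(self, m).shape for m in MODALITIES}
        if len(set(shapes.values())) != 1:
            raise GridMismatchError(f"modality shapes differ: {shapes}")

    @property
    def shape(self):
        return self.t1.shape

    def volumes(self):
        return {m: getattr(self, m) for m in MODALITIES}


@dataclasses.dataclass
class ModalityPairStack:
    pair_id: str  # "g1" (T1, T1c) or "g2" (T2, FLAIR)
    channels: np.ndarray  # (2, h, w, l)

    def __post_init__(self):
        if self.pair_id not in ("g1", "g2"):
            raise ValueError(f"pair_id must be g1 or g2, got {self.pair_id!r}")
        if self.channels.shape[0] != 2:
            raise ValueError("a modality pair has exactly two channels")


@dataclasses.dataclass
class SubCompartmentLabels:
    labels: np.ndarray
    codes: Mapping[str, int] = dataclasses.field(default_factory=lambda: dict(DEFAULT_CODES))

    def validate(self):
        allowed = set(self.codes.values())
        present = set(np.unique(self.labels).tolist())
        unknown = present - allowed
        if unknown:
            raise UnknownLabelError(f"unknown label code(s) {sorted(unknown)}; allowed {sorted(allowed)}")


@dataclasses.dataclass
class HierarchicalMasks:
    """Nested binary region masks (whole tumor, tumor core, enhancing tumor)."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    REGIONS = ("wt", "tc", "et")

    def validate(self):
        for name in self.REGIONS:
            m = getattr(self, name)
            vals = np.unique(m)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError(f"{name} mask is not binary")
        wt, tc, et = (np.asarray(getattr(self, n), bool) for n in self.REGIONS)
        if np.any(et & ~tc) or np.any(tc & ~wt):
            raise NestingError("nesting violated: require ET <= TC <= WT")

    def stack(self) -> np.ndarray:
        """(3, h, w, l) float array ordered (WT, TC, ET)."""
        return np.stack([self.wt, self.tc, self.et]).astype(np.float64)


def read_study(paths_per_modality: Mapping[str, str | Path],
               subject_id: str = "") -> MultiModalStudy:
    """Load four NIfTI modality files into one study.

    Raises :class:`MissingModalityError` if a modality key or file is absent and
    :class:`GridMismatchError` if shapes/affines disagree (affine tol 1e-4).
    """
    missing = [m for m in MODALITIES if m not in paths_per_modality]
    if missing:
        raise MissingModalityError(f"missing modalities: {missing}")
    images = {}
    for m in MODALITIES:
        path = Path(paths_per_modality[m])
        if not path.exists():
            raise MissingModalityError(f"missing file for {m}: {path}")
        images[m] = nib.load(str(path))
    ref = images["t1"]
    for m, img in images.items():
        if img.shape != ref.shape:
            raise GridMismatchError(f"shape mismatch: {m} {img.shape} vs t1 {ref.shape}")
        if not np.allclose(img.affine, ref.affine, atol=1e-4):
            raise GridMismatchError(f"affine mismatch between {m} and t1")
    spacing = tuple(float(z) for z in ref.header.get_zooms()[:3])
    vols = {m: np.asarray(img.get_fdata(), dtype=np.float64) for m, img in images.items()}
    return MultiModalStudy(spacing=spacing, subject_id=subject_id,
                           affine=np.array(ref.affine), **vols)


def read_labels(path: str | Path, codes: Mapping[str, int] | None = None) -> SubCompartmentLabels:
    img = nib.load(str(path))
    data = np.rint(np.asarray(img.get_fdata())).astype(np.int64)
    labels = SubCompartmentLabels(data, dict(codes or DEFAULT_CODES))
    labels.validate()
    return labels


def normalize_modality(volume: np.ndarray, domain_mask: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean / unit-variance over the domain mask; outside set to 0.

    The default domain is the nonzero (brain) voxels. Population standard
    deviation is used; a constant domain raises :class:`ConstantImageError`.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(volume).all():
        raise ValueError("volume contains non-finite values")
    mask = (volume != 0) if domain_mask is None else np.asarray(domain_mask, bool)
    if not mask.any():
        raise ValueError("normalization domain is empty")
    vals = volume[mask]
    mu = vals.mean()
    sd = vals.std()  # population std
    if sd < 1e-12:
        raise ConstantImageError(f"constant image inside domain (value {mu:g})")
    out = np.zeros_like(volume)
    out[mask] = (vals - mu) / sd
    return out


def normalize_study(study: MultiModalStudy) -> MultiModalStudy:
    """Normalize each modality over its own nonzero domain."""
    vols = {m: normalize_modality(v) for m, v in study.volumes().items()}
    return dataclasses.replace(study, **vols)


def map_labels(labels: SubCompartmentLabels) -> HierarchicalMasks:
    """Combine sub-compartments into the nested WT/TC/ET region masks."""
    labels.validate()
    codes = labels.codes
    arr = labels.labels
    et = arr == codes["et"]
    ncr = arr == codes["ncr_net"]
    ed = arr == codes["ed"]
    masks = HierarchicalMasks(
        wt=(ed | ncr | et).astype(np.uint8),
        tc=(ncr | et).astype(np.uint8),
        et=et.astype(np.uint8),
    )
    masks.validate()
    return masks


def split_modality_pairs(study: MultiModalStudy) -> tuple[ModalityPairStack, ModalityPairStack]:
    """(T1, T1c) -> g1; (T2, FLAIR) -> g2. Channel order is fixed as listed."""
    g1 = ModalityPairStack("g1", np.stack([study.t1, study.t1c]))
    g2 = ModalityPairStack("g2", np.stack([study.t2, study.flair]))
    return g1, g2


def write_masks(masks: HierarchicalMasks, reference_affine: np.ndarray | None,
                out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write WT/TC/ET masks as uint8 NIfTI files; refuses nesting violations."""
    masks.validate()
    affine = np.eye(4) if reference_affine is None else np.asarray(reference_affine)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in HierarchicalMasks.REGIONS:
        data = np.asarray(getattr(masks, name), dtype=np.uint8)
        path = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(data, affine), str(path))
        written[name] = path
    return written


def read_masks(out_dir: str | Path, prefix: str = "") -> HierarchicalMasks:
    out_dir = Path(out_dir)
    vols = {}
    for name in HierarchicalMasks.REGIONS:
        img = nib.load(str(out_dir / f"{prefix}{name}.nii.gz"))
        vols[name] = np.rint(np.asarray(img.get_fdata())).astype(np.uint8)
    masks = HierarchicalMasks(**vols)
    masks.validate()
    return masks


def write_study(study: MultiModalStudy, labels: SubCompartmentLabels | None,
                subject_dir: str | Path) -> None:
    """Emit the on-disk layout ``<subject>/{t1,t1c,t2,flair,seg}.nii.gz``."""
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if study.affine is None else study.affine
    for m, vol in study.volumes().items():
        nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), affine),
                 str(subject_dir / f"{m}.nii.gz"))
    if labels is not None:
        nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine),
                 str(subject_dir / "seg.nii.gz"))


def read_subject_dir(subject_dir: str | Path,
                     codes: Mapping[str, int] | None = None
                     ) -> tuple[MultiModalStudy, SubCompartmentLabels | None]:
    subject_dir = Path(subject_dir)
    paths = {m: subject_dir / f"{m}.nii.gz" for m in MODALITIES}
    study = read_study(paths, subject_id=subject_dir.name)
    seg_path = subject_dir / "seg.nii.gz"
    labels = read_labels(seg_path, codes) if seg_path.exists() else None
    return study, labels
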