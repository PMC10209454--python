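"""Reading and writing templates, cohort manifests, masks and BOLD scans.

All volumes are NIfTI-1 (via nibabel); manifests are UTF-8 CSV with a header
row; template metadata travels in a JSON sidecar.  Voxel indexing is 0-based
and flattening of 3-D grids into voxel vectors is C-order throughout the
package; a ``mask`` is a 3-D boolean array and "masked" data are the values at
``mask`` voxels in that C-order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Functional domain labels accepted in template manifests.  The seven-domain
#: scheme (cerebellum ... visual) is the conventional resting-state grouping;
#: "auditory" appears in some single-order templates.
ALLOWED_DOMAINS = (
    "auditory",
    "cerebellum",
    "cognitive control",
    "default mode",
    "somatomotor",
    "subcortical",
    "temporal",
    "visual",
)

#: Canonical display order of domains (matrix/connectogram layouts).
DOMAIN_ORDER = (
    "cerebellum",
    "cognitive control",
    "default mode",
    "somatomotor",
    "subcortical",
    "temporal",
    "visual",
    "auditory",
)


class GridMismatchError(ValueError):
    """Raised when images that must share a voxel grid do not."""


@dataclass(frozen=True)
class TemplateEntry:
    """One reference network: id, the ICA model order it came from, domain."""

    icn_id: str
    model_order: int | str
    domain: str


@dataclass
class TemplateSet:
    """A stack of reference spatial maps grouped by ICA model order.

    ``maps`` holds one row per entry, z-scored within ``mask`` (mean 0, sd 1
    over mask voxels), so the spatial-correspondence term of constrained ICA
    is scale-free.
    """

    entries: list[TemplateEntry]
    maps: np.ndarray          # n_entries x n_mask_voxels, z-scored
    mask: np.ndarray          # 3-D bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be 2-D (entries x mask voxels)")
        if self.maps.shape[0] != len(self.entries):
            raise ValueError("one map per entry required")
        if self.maps.shape[1] != int(self.mask.sum()):
            raise GridMismatchError(
                f"maps have {self.maps.shape[1]} voxels but mask has "
                f"{int(self.mask.sum())}"
            )
        ids = [e.icn_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("icn_ids must be unique")
        # per-order counts must partition the set
        assert sum(self.order_counts().values()) == len(self.entries)

    # -- structure ---------------------------------------------------------
    @property
    def icn_ids(self) -> list[str]:
        return [e.icn_id for e in self.entries]

    @property
    def orders(self) -> list[int | str]:
        """Distinct model orders, in first-appearance order."""
        seen: dict[int | str, None] = {}
        for e in self.entries:
            seen.setdefault(e.model_order, None)
        return list(seen)

    def order_counts(self) -> dict[int | str, int]:
        counts: dict[int | str, int] = {}
        for e in self.entries:
            counts[e.model_order] = counts.get(e.model_order, 0) + 1
        return counts

    def order_indices(self, order: int | str) -> np.ndarray:
        return np.array(
            [i for i, e in enumerate(self.entries) if e.model_order == order],
            dtype=int,
        )

    def __len__(self) -> int:
        return len(self.entries)

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        """Write maps as a 4-D NIfTI plus mask volume and JSON/CSV sidecars."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        vol = np.zeros(self.mask.shape + (len(self.entries),))
        vol[self.mask, :] = self.maps.T
        nib.save(nib.Nifti1Image(vol, self.affine), directory / "template.nii")
        nib.save(
            nib.Nifti1Image(self.mask.astype(np.uint8), self.affine),
            directory / "mask.nii",
        )
        pd.DataFrame(
            {
                "icn_id": [e.icn_id for e in self.entries],
                "model_order": [e.model_order for e in self.entries],
                "domain": [e.domain for e in self.entries],
                "volume": np.arange(len(self.entries)),
            }
        ).to_csv(directory / "template_manifest.csv", index=False)
        with open(directory / "template.json", "w") as fh:
            json.dump(
                {
                    "n_entries": len(self.entries),
                    "order_counts": {str(k): v for k, v in self.order_counts().items()},
                    "grid": list(self.mask.shape),
                },
                fh,
                indent=2,
            )
        return directory


def _zscore_within_mask(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=-1, keepdims=True)
    sd = values.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd


def _parse_order(value) -> int | str:
    try:
        return int(value)
    except (TypeError, ValueError):
        return str(value)


def load_template(
    path: str | Path,
    manifest: str | Path | pd.DataFrame | None = None,
    mask: np.ndarray | str | Path | None = None,
    allowed_domains: Sequence[str] = ALLOWED_DOMAINS,
) -> TemplateSet:
    """Load a reference template from a directory or a 4-D NIfTI.

    ``path`` may be a directory produced by :meth:`TemplateSet.save` (its
    manifest/mask are then found automatically) or a 4-D NIfTI whose volumes
    are indexed by the manifest's ``volume`` column (or ``filename`` column
    for per-map files).  Maps are z-scored within the mask at load time.  The
    default mask keeps voxels where the map stack has nonzero variance and no
    non-finite values.
    """
    path = Path(path)
    if path.is_dir():
        if manifest is None:
            manifest = path / "template_manifest.csv"
        if mask is None and (path / "mask.nii").exists():
            mask = path / "mask.nii"
        img_path = path / "template.nii"
    else:
        img_path = path
    if manifest is None:
        raise ValueError("a template manifest is required")
    mf = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)

    required = {"icn_id", "model_order", "domain"}
    missing = required - set(mf.columns)
    if missing:
        raise ValueError(f"template manifest missing columns: {sorted(missing)}")
    bad = set(mf["domain"]) - set(allowed_domains)
    if bad:
        raise ValueError(
            f"unknown domain labels {sorted(bad)}; allowed: {sorted(allowed_domains)}"
        )

    if "filename" in mf.columns:
        base = path if path.is_dir() else path.parent
        vols = []
        shape, affine = None, np.eye(4)
        for fname in mf["filename"]:
            img = nib.load(base / str(fname))
            arr = np.asarray(img.get_fdata())
            if shape is None:
                shape, affine = arr.shape, img.affine
            elif arr.shape != shape:
                raise GridMismatchError(
                    f"{fname}: grid {arr.shape} != {shape}"
                )
            vols.append(arr)
        stack = np.stack(vols, axis=-1)
    else:
        img = nib.load(img_path)
        stack = np.asarray(img.get_fdata())
        affine = img.affine
        if stack.ndim != 4:
            raise ValueError("expected a 4-D template image")
        idx = (
            mf["volume"].to_numpy(dtype=int)
            if "volume" in mf.columns
            else np.arange(len(mf))
        )
        if idx.max() >= stack.shape[-1]:
            raise ValueError("manifest volume index beyond template image")
        stack = stack[..., idx]

    if mask is None:
        finite = np.isfinite(stack).all(axis=-1)
        if stack.shape[-1] > 1:
            varying = stack.std(axis=-1) > 0
        else:                       # single map: variance across maps is moot
            varying = np.abs(stack[..., 0]) > 0
        mask_arr = finite & varying
    elif isinstance(mask, (str, Path)):
        mimg = nib.load(mask)
        mask_arr = np.asarray(mimg.get_fdata()) > 0
        if mask_arr.shape != stack.shape[:3]:
            raise GridMismatchError(
                f"mask grid {mask_arr.shape} != template grid {stack.shape[:3]}"
            )
    else:
        mask_arr = np.asarray(mask, dtype=bool)
        if mask_arr.shape != stack.shape[:3]:
            raise GridMismatchError(
                f"mask grid {mask_arr.shape} != template grid {stack.shape[:3]}"
            )

    maps = _zscore_within_mask(stack[mask_arr, :].T)
    entries = [
        TemplateEntry(str(r.icn_id), _parse_order(r.model_order), str(r.domain))
        for r in mf.itertuples()
    ]
    ts = TemplateSet(entries=entries, maps=maps, mask=mask_arr, affine=affine)
    logger.info(
        "loaded template: %d ICNs, order counts %s", len(ts), ts.order_counts()
    )
    return ts


# ---------------------------------------------------------------------------
# cohort manifests


MANIFEST_COLUMNS = ("subject_id", "group", "site", "tr", "n_volumes")
PANSS_COLUMNS = ("panss_total", "panss_positive", "panss_negative")
GROUPS = ("TC", "SZ")


@dataclass
class CohortManifest:
    """Typed cohort table: one row per subject, optional PANSS scores."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.table["subject_id"].duplicated().any():
            dups = self.table.loc[
                self.table["subject_id"].duplicated(), "subject_id"
            ].tolist()
            raise ValueError(f"duplicate subject_ids: {dups}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        if (self.table["tr"] <= 0).any():
            raise ValueError("TR must be positive")
        for col in PANSS_COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan
        # PANSS consistency: total = positive + negative where all present
        full = self.table[list(PANSS_COLUMNS)].notna().all(axis=1)
        if full.any():
            t = self.table.loc[full]
            off = ~np.isclose(
                t["panss_total"], t["panss_positive"] + t["panss_negative"]
            )
            if off.any():
                warnings.warn(
                    "PANSS total != positive + negative for subjects "
                    f"{t.loc[off, 'subject_id'].tolist()}",
                    stacklevel=2,
                )

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].astype(str).tolist()

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    def group_counts(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.table)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def load_manifest(path: str | Path | pd.DataFrame) -> CohortManifest:
    """Read a cohort manifest CSV into a validated :class:`CohortManifest`."""
    table = path.copy() if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    mf = CohortManifest(table)
    logger.info("loaded manifest: %s", mf.group_counts())
    return mf


# ---------------------------------------------------------------------------
# BOLD scans


@dataclass
class BoldScan:
    """One subject's masked BOLD series: voxels x time, with TR metadata."""

    subject_id: str
    data: np.ndarray   # n_mask_voxels x n_volumes
    tr: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("scan data must be voxels x time")
        if not np.isfinite(self.data).all():
            raise ValueError(f"scan {self.subject_id}: non-finite values inside mask")
        if self.mask is not None and self.data.shape[0] != int(np.sum(self.mask)):
            raise GridMismatchError("voxel count does not match mask size")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    def save(self, path: str | Path, affine: np.ndarray | None = None) -> Path:
        if self.mask is None:
            raise ValueError("cannot write a volume without the mask")
        vol = np.zeros(self.mask.shape + (self.n_volumes,))
        vol[np.asarray(self.mask, bool), :] = self.data
        img = nib.Nifti1Image(vol, np.eye(4) if affine is None else affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], float(self.tr)))
        nib.save(img, path)
        return Path(path)


def load_scan(
    path: str | Path,
    mask: np.ndarray,
    subject_id: str | None = None,
    tr_override: float | None = None,
) -> BoldScan:
    """Load a 4-D NIfTI and mask it into a voxels x time matrix.

    TR is taken from the NIfTI header unless ``tr_override`` (e.g. a manifest
    value) is given; the override wins and a mismatch is logged.
    """
    path = Path(path)
    img = nib.load(path)
    arr = np.asarray(img.get_fdata())
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected 4-D image, got {arr.ndim}-D")
    if arr.shape[-1] < 2:
        raise ValueError(f"{path}: needs at least 2 volumes")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape[:3]:
        raise GridMismatchError(
            f"{path}: mask grid {mask.shape} != image grid {arr.shape[:3]}"
        )
    data = arr[mask, :]
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: NaN/inf voxels inside mask")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    tr = tr_override if tr_override is not None else header_tr
    if tr_override is not None and header_tr > 0 and not np.isclose(header_tr, tr_override):
        logger.info(
            "%s: manifest TR %.3f overrides header TR %.3f", path, tr_override, header_tr
        )
    return BoldScan(
        subject_id=subject_id or path.stem.replace(".nii", ""),
        data=data,
        tr=float(tr),
        mask=mask,
    )
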