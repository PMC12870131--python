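"""Fixel fields and volume-fraction-weighted microstructure maps.

A *fixel* is a single fibre population within a voxel.  Multi-fixel models
resolve crossing fibres by estimating up to ``K`` populations per voxel, each
with its own orientation ``u_k``, volume fraction ``f_k`` and tensor-derived
metrics (FA, AD, RD, MD), plus an isotropic free-water compartment ``f_iso``.

Because fixel ordering carries no anatomical meaning, per-fixel maps of
different subjects cannot be compared voxel-by-voxel.  The whole-brain
analysis therefore collapses the fixel metrics into one scalar map per metric
using the relative volume-fraction weight

    wM = (sum_k f_k * M_k) / (sum_k f_k),

which is invariant to fixel permutation and ignores the isotropic fraction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Canonical tensor-derived metric names (diffusivities in mm^2/s, FA unitless).
METRIC_NAMES = ("FA", "AD", "RD", "MD")

#: Sentinel for voxels with no anisotropic fixel mass.
UNDEFINED = np.nan


@dataclass
class FixelField:
    """Per-voxel fibre populations on a regular grid.

    Parameters
    ----------
    affine : (4, 4) array
        Voxel-to-world (RAS mm) transform.
    orientations : (X, Y, Z, K, 3) array
        Unit fibre orientations; arbitrary where ``f_k == 0``.
    fractions : (X, Y, Z, K) array
        Anisotropic volume fractions, ``f_k >= 0``.
    metrics : dict of str -> (X, Y, Z, K) array
        Per-fixel scalar metrics keyed by name (``FA``, ``AD``, ``RD``, ``MD``).
    f_iso : (X, Y, Z) array
        Isotropic compartment fraction; ``sum_k f_k + f_iso <= 1``.
    """

    affine: np.ndarray
    orientations: np.ndarray
    fractions: np.ndarray
    metrics: dict[str, np.ndarray] = field(default_factory=dict)
    f_iso: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.f_iso is None:
            self.f_iso = np.zeros(self.fractions.shape[:3])
        self.f_iso = np.asarray(self.f_iso, dtype=float)

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[:3]

    @property
    def n_fixels(self) -> int:
        return self.fractions.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to (fractional) voxel indices."""
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(xyz)
        return (xyz @ inv[:3, :3].T) + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T) + self.affine[:3, 3]

    # -- derived quantities -------------------------------------------------
    @property
    def anisotropic_fraction(self) -> np.ndarray:
        """f1 + f2 (+ ...): total fibre volume fraction per voxel."""
        return self.fractions.sum(axis=3)

    def validate(self, atol: float = 1e-9) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        if np.any(self.fractions < -atol):
            raise ValueError("negative fixel volume fraction")
        total = self.anisotropic_fraction + self.f_iso
        if np.any(total > 1 + 1e-6):
            raise ValueError("volume fractions exceed unity")
        active = self.fractions > 0
        norms = np.linalg.norm(self.orientations, axis=4)
        if np.any(np.abs(norms[active] - 1.0) > 1e-6):
            raise ValueError("fixel orientations must be unit vectors where f_k > 0")
        if "FA" in self.metrics:
            fa = self.metrics["FA"][active]
            if np.any((fa < -atol) | (fa > 1 + atol)):
                raise ValueError("FA outside [0, 1]")
        for name in ("AD", "RD", "MD"):
            if name in self.metrics and np.any(self.metrics[name][active] < -atol):
                raise ValueError(f"negative diffusivity in {name}")

    def copy(self) -> "FixelField":
        return FixelField(
            affine=self.affine.copy(),
            orientations=self.orientations.copy(),
            fractions=self.fractions.copy(),
            metrics={k: v.copy() for k, v in self.metrics.items()},
            f_iso=self.f_iso.copy(),
        )

    # -- I/O ----------------------------------------------------------------
    def save(self, directory: str, prefix: str = "fixel") -> list[str]:
        """Write the field as one NIfTI per quantity; return written paths."""
        os.makedirs(directory, exist_ok=True)
        written = []

        def _w(name: str, data: np.ndarray) -> None:
            path = os.path.join(directory, f"{prefix}_{name}.nii.gz")
            nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), self.affine), path)
            written.append(path)

        for k in range(self.n_fixels):
            _w(f"dir{k + 1}", self.orientations[..., k, :])
            _w(f"frac{k + 1}", self.fractions[..., k])
            for m, arr in self.metrics.items():
                _w(f"{m}{k + 1}", arr[..., k])
        _w("fiso", self.f_iso)
        return written

    @classmethod
    def load(cls, directory: str, prefix: str = "fixel", n_fixels: int = 2,
             metric_names: tuple[str, ...] = METRIC_NAMES) -> "FixelField":
        def _r(name: str) -> tuple[np.ndarray, np.ndarray]:
            img = nib.load(os.path.join(directory, f"{prefix}_{name}.nii.gz"))
            return np.asarray(img.dataobj, dtype=float), img.affine

        dirs, fracs, mets = [], [], {m: [] for m in metric_names}
        affine = None
        for k in range(n_fixels):
            d, affine = _r(f"dir{k + 1}")
            dirs.append(d)
            fracs.append(_r(f"frac{k + 1}")[0])
            for m in metric_names:
                mets[m].append(_r(f"{m}{k + 1}")[0])
        f_iso = _r("fiso")[0]
        return cls(
            affine=affine,
            orientations=np.stack(dirs, axis=3),
            fractions=np.stack(fracs, axis=3),
            metrics={m: np.stack(v, axis=3) for m, v in mets.items()},
            f_iso=f_iso,
        )


@dataclass
class MetricVolume:
    """Scalar 3D map with grid geometry; NaN marks undefined voxels."""

    data: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.data)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str, name: str = "") -> "MetricVolume":
        img = nib.load(path)
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, name=name)


def weighted_metric_map(fld: FixelField, metric_name: str) -> MetricVolume:
    """Collapse a per-fixel metric into one volume-fraction-weighted map.

    wM = sum_k f_k M_k / sum_k f_k over the anisotropic fixels only; voxels
    with no fixel mass (f1 + f2 == 0) are undefined (NaN).  The isotropic
    fraction does not enter the weighting.
    """
    if metric_name not in fld.metrics:
        raise KeyError(f"metric {metric_name!r} not present in field")
    f = fld.fractions
    if np.any(f < 0):
        raise ValueError("negative fixel volume fraction")
    m = fld.metrics[metric_name]
    active = f > 0
    if not np.all(np.isfinite(m[active])):
        raise ValueError(f"metric {metric_name!r} missing (non-finite) on active fixels")
    denom = f.sum(axis=3)
    num = (f * np.where(active, m, 0.0)).sum(axis=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = num / denom
    w[denom == 0] = UNDEFINED
    return MetricVolume(w, fld.affine, name=f"w{metric_name}")


def mask_summary(volume: MetricVolume, mask: np.ndarray) -> dict[str, float]:
    """Mean / sample SD / count of defined voxels inside a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume grid")
    sel = mask & volume.defined
    n = int(sel.sum())
    if n == 0:
        raise ValueError("mask contains no defined voxels")
    vals = volume.data[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return {"mean": float(vals.mean()), "sd": sd, "n_defined": n}
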