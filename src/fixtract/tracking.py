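"""ROI-constrained streamline tracking on fixel fields and KDE cleaning.

Streamlines are generated with a deterministic best-aligned-fixel tracker:
seeds are drawn uniformly within the seed ROI, and bidirectional Euler
integration follows, at every step, the fixel orientation (antipodally
symmetrized) best aligned with the incoming direction.  Propagation stops
when the anisotropic volume fraction falls below the cutoff, when the
per-step turn exceeds the maximum angle, or when leaving the grid.  Accepted
streamlines must satisfy the length bounds, traverse every intermediary ROI,
and satisfy the termination ROIs.

This tracker is a deliberate stand-in for fODF-based probabilistic
tractography: the downstream tractometry consumes only streamline geometry,
and the amplitude cutoff is reinterpreted as a minimum anisotropic volume
fraction — the nearest quantity available in a fixel field.

Stray streamlines are removed with an unnormalized Gaussian kernel-density
filter: a streamline is discarded when any of its points has kernel-sum
density below ``threshold_factor`` times the density contributed by a single
isolated point (the kernel peak, i.e. 1).  The filter iterates to a fixed
point so that survivors' densities are evaluated on the cleaned set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

import nibabel as nib
from nibabel import streamlines as nibstream

from .fixel import FixelField


@dataclass
class TrackingParams:
    """Geometric tracking parameters (defaults follow the study protocol)."""

    step: float = 1.0            # mm
    max_angle: float = 15.0      # degrees per step
    cutoff: float = 0.1          # minimum anisotropic fraction f1+f2
    min_length: float = 10.0     # mm
    max_length: float = 200.0    # mm
    max_streamlines: int = 2000
    n_seeds: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not (0 < self.max_angle < 90):
            raise ValueError("max_angle must lie in (0, 90) degrees")
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be below max_length")
        if self.max_streamlines < 1 or self.n_seeds < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class Roi:
    """A region of interest with a tracking role."""

    mask: np.ndarray
    role: str                    # "seed" | "intermediary" | "termination"
    endpoint_only: bool = False  # termination: require an endpoint inside

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.role not in ("seed", "intermediary", "termination"):
            raise ValueError(f"unknown ROI role {self.role!r}")
        if not self.mask.any():
            raise ValueError("empty ROI mask")


@dataclass
class StreamlineSet:
    """Polylines in world mm with provenance."""

    streamlines: list[np.ndarray] = field(default_factory=list)
    affine: np.ndarray | None = None
    tract_name: str = ""
    params_hash: str = ""
    status: str = "ok"

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
                         for s in self.streamlines])

    def all_points(self) -> np.ndarray:
        if not self.streamlines:
            return np.empty((0, 3))
        return np.vstack(self.streamlines)

    def save(self, path: str) -> None:
        """Write as TCK (or TRK if the filename says so); world-mm RAS."""
        tractogram = nibstream.Tractogram(self.streamlines,
                                          affine_to_rasmm=np.eye(4))
        if path.endswith(".trk"):
            header = {}
            if self.affine is not None:
                header[nibstream.trk.Field.VOXEL_TO_RASMM] = self.affine
            nibstream.save(nibstream.trk.TrkFile(tractogram, header), path)
        else:
            nibstream.save(tractogram, path)

    @classmethod
    def load(cls, path: str, tract_name: str = "") -> "StreamlineSet":
        tf = nibstream.load(path)
        return cls(streamlines=[np.asarray(s) for s in tf.streamlines],
                   tract_name=tract_name)


def _params_hash(params: TrackingParams) -> str:
    text = repr(sorted(params.__dict__.items()))
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def track_streamlines(fld: FixelField, rois: list[Roi],
                      params: TrackingParams) -> StreamlineSet:
    """Deterministic ROI-constrained tracking on a fixel field."""
    seeds_rois = [r for r in rois if r.role == "seed"]
    if not seeds_rois:
        raise ValueError("at least one seed ROI is required")
    for r in rois:
        if r.mask.shape != fld.shape:
            raise ValueError("ROI grid does not match field grid")
    inter = [r for r in rois if r.role == "intermediary"]
    term = [r for r in rois if r.role == "termination"]

    seed_mask = np.zeros(fld.shape, dtype=bool)
    for r in seeds_rois:
        seed_mask |= r.mask
    seed_vox = np.argwhere(seed_mask)

    rng = np.random.default_rng(params.seed)
    inv_affine = np.linalg.inv(fld.affine)
    R, t0 = fld.affine[:3, :3], fld.affine[:3, 3]
    anis = fld.anisotropic_fraction
    cos_max = np.cos(np.radians(params.max_angle))
    max_steps = int(np.ceil(params.max_length / params.step)) + 2
    shape = np.array(fld.shape)

    def vox_of(pos: np.ndarray) -> np.ndarray | None:
        ijk = np.round(inv_affine[:3, :3] @ pos + inv_affine[:3, 3]).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= shape):
            return None
        return ijk

    def best_fixel(ijk: np.ndarray, direction: np.ndarray
                   ) -> tuple[np.ndarray, float] | None:
        f = fld.fractions[tuple(ijk)]
        active = np.flatnonzero(f > 0)
        if active.size == 0:
            return None
        u = fld.orientations[tuple(ijk)][active]        # (m, 3)
        dots = u @ direction
        j = int(np.argmax(np.abs(dots)))
        d = u[j] * np.sign(dots[j]) if dots[j] != 0 else u[j]
        return d, float(abs(dots[j]))

    def propagate(pos: np.ndarray, direction: np.ndarray) -> list[np.ndarray]:
        pts: list[np.ndarray] = []
        d = direction
        for _ in range(max_steps):
            nxt = pos + params.step * d
            ijk = vox_of(nxt)
            if ijk is None or anis[tuple(ijk)] < params.cutoff:
                break
            pts.append(nxt)
            chosen = best_fixel(ijk, d)
            if chosen is None:
                break
            d_new, cos = chosen
            if cos < cos_max:
                break
            pos, d = nxt, d_new
        return pts

    accepted: list[np.ndarray] = []
    n_draw = min(params.n_seeds, 10_000_000)
    for _ in range(n_draw):
        if len(accepted) >= params.max_streamlines:
            break
        vox = seed_vox[rng.integers(len(seed_vox))]
        offset = rng.uniform(-0.5, 0.5, 3)
        pos = R @ (vox + offset) + t0
        ijk = vox_of(pos)
        if ijk is None or anis[tuple(ijk)] < params.cutoff:
            continue
        start = best_fixel(ijk, np.array([1.0, 0.0, 0.0]))
        if start is None:
            continue
        # initial direction: orientation of the largest-fraction fixel
        f = fld.fractions[tuple(ijk)]
        d0 = fld.orientations[tuple(ijk)][int(np.argmax(f))]
        fwd = propagate(pos, d0)
        bwd = propagate(pos, -d0)
        sl = np.array(bwd[::-1] + [pos] + fwd)
        if len(sl) < 2:
            continue
        length = np.linalg.norm(np.diff(sl, axis=0), axis=1).sum()
        if not (params.min_length <= length <= params.max_length):
            continue
        if not _satisfies_rois(sl, inter, term, inv_affine, shape):
            continue
        accepted.append(sl)

    status = "ok" if accepted else "empty"
    return StreamlineSet(streamlines=accepted, affine=fld.affine,
                         params_hash=_params_hash(params), status=status)


def _satisfies_rois(sl: np.ndarray, inter: list[Roi], term: list[Roi],
                    inv_affine: np.ndarray, shape: np.ndarray) -> bool:
    ijk = np.round(sl @ inv_affine[:3, :3].T + inv_affine[:3, 3]).astype(int)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    ijk = ijk[inside]
    if len(ijk) == 0:
        return False
    vox = tuple(ijk.T)
    for r in inter:
        if not r.mask[vox].any():
            return False
    for r in term:
        if r.endpoint_only:
            ends = np.array([ijk[0], ijk[-1]])
            if not r.mask[tuple(ends.T)].any():
                return False
        elif not r.mask[vox].any():
            return False
    return True


def kde_clean(sset: StreamlineSet, bandwidth: float = 1.0,
              threshold_factor: float = 5.0,
              max_iter: int = 100) -> StreamlineSet:
    """Remove streamlines with isolated segments by Gaussian kernel density.

    Density at a point = sum over all streamline points p of
    exp(-|x - p|^2 / (2 h^2)); an isolated single point has density 1 (the
    kernel peak), so the removal threshold is ``threshold_factor`` * 1.
    Points are subsampled to at most one per mm of arc length before density
    evaluation.  Iterates until no streamline is removed (fixed point).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(sset) == 0:
        raise ValueError("empty streamline set")

    def subsample(s: np.ndarray) -> np.ndarray:
        seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        keep = [0]
        last = 0.0
        for i in range(1, len(s)):
            if arc[i] - last >= 1.0 - 1e-9:
                keep.append(i)
                last = arc[i]
        if keep[-1] != len(s) - 1:
            keep.append(len(s) - 1)
        return s[keep]

    current = list(sset.streamlines)
    radius = 4.0 * bandwidth   # kernel truncation; exp(-8) ~ 3e-4
    for _ in range(max_iter):
        pts_per = [subsample(s) for s in current]
        pts = np.vstack(pts_per)
        owner = np.repeat(np.arange(len(current)), [len(p) for p in pts_per])
        tree = cKDTree(pts)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        dens = np.ones(len(pts))   # self-contribution = kernel peak
        if len(pairs):
            d2 = ((pts[pairs[:, 0]] - pts[pairs[:, 1]]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2 * bandwidth**2))
            np.add.at(dens, pairs[:, 0], w)
            np.add.at(dens, pairs[:, 1], w)
        min_dens = np.full(len(current), np.inf)
        np.minimum.at(min_dens, owner, dens)
        keep = min_dens >= threshold_factor
        if keep.all():
            break
        current = [s for s, k in zip(current, keep) if k]
        if not current:
            break
    return StreamlineSet(streamlines=current, affine=sset.affine,
                         tract_name=sset.tract_name,
                         params_hash=sset.params_hash,
                         status="ok" if current else "empty")
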