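"""Seeded synthetic cohorts for the tractometry pipeline.

Real multi-shell diffusion MRI of patients cannot be shared, so every stage of
the analysis is exercised on synthetic cohorts that possess exactly the
statistical structure the downstream analysis assumes:

* a fixel-field *phantom*: geometric fibre bundles (tubes around polyline
  centerlines) on a common 2 mm grid, up to two crossing populations per voxel
  plus an isotropic compartment, with internally consistent tensor metrics
  generated from an axially symmetric (lambda_par, lambda_perp) pair;
* per-subject fields: group/session-specific effects applied to bundle metrics
  (globally or in arc-length sections), plus measurement noise whose standard
  deviation grows with 1/CNR, emulating motion-related noise contamination;
* two sessions (E1 admission, E2 after ~18 days) with a configurable
  within-subject correlation;
* clinical scores (BDI depression, OCDS craving, SAI anxiety) generated
  linearly from group, session and tract metric summaries.

Every generator is deterministic under a fixed seed, and every planted effect
is recorded in a machine-readable truth ledger so recovery tests are
self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .fixel import FixelField, METRIC_NAMES

__all__ = [
    "BundleSpec",
    "EffectSpec",
    "CohortConfig",
    "ClinicalModel",
    "SubjectRecord",
    "Phantom",
    "Cohort",
    "metrics_from_eigenvalues",
    "build_phantom",
    "simulate_subject",
    "simulate_clinical",
    "generate_cohort",
    "default_bundles",
    "default_effects",
]

N_SECTIONS = 8  # along-tract sections used by the effect model


def metrics_from_eigenvalues(lambda_par: float, lambda_perp: float) -> dict[str, float]:
    """Tensor metrics of an axially symmetric tensor (diffusivities in mm^2/s).

    AD = lambda_par, RD = lambda_perp, MD = (AD + 2 RD)/3 and
    FA = |l1 - l2| / sqrt(l1^2 + 2 l2^2), so the internal consistency
    relations hold by construction.
    """
    if lambda_par < lambda_perp or lambda_perp < 0:
        raise ValueError("require lambda_par >= lambda_perp >= 0")
    ad, rd = float(lambda_par), float(lambda_perp)
    md = (ad + 2 * rd) / 3.0
    denom = np.sqrt(ad**2 + 2 * rd**2)
    fa = 0.0 if denom == 0 else (ad - rd) / denom
    return {"FA": fa, "AD": ad, "RD": rd, "MD": md}


@dataclass
class BundleSpec:
    """Geometric surrogate of a white-matter bundle.

    ``centerline`` is an ordered polyline in world mm; a voxel belongs to the
    bundle when its centre lies within ``radius`` mm of the polyline.
    ``fraction_profile`` maps arc-length fraction s in [0, 1] to the bundle's
    anisotropic volume fraction (scalar for a flat profile).
    """

    name: str
    centerline: np.ndarray
    radius: float
    baseline_metrics: dict[str, float]
    fraction_profile: Callable[[np.ndarray], np.ndarray] | float = 0.5

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline needs >= 2 points in 3D")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        m = self.baseline_metrics
        ad, rd, md, fa = m["AD"], m["RD"], m["MD"], m["FA"]
        if not (ad >= rd >= 0):
            raise ValueError("require AD >= RD >= 0")
        if abs(md - (ad + 2 * rd) / 3.0) > 1e-12:
            raise ValueError("MD inconsistent with (AD + 2 RD)/3")
        denom = np.sqrt(ad**2 + 2 * rd**2)
        fa_expect = 0.0 if denom == 0 else (ad - rd) / denom
        if abs(fa - fa_expect) > 1e-9:
            raise ValueError("FA inconsistent with (AD, RD)")

    def fraction_at(self, s: np.ndarray) -> np.ndarray:
        if callable(self.fraction_profile):
            f = np.asarray(self.fraction_profile(np.asarray(s)), dtype=float)
        else:
            f = np.full(np.shape(s), float(self.fraction_profile))
        if np.any(f <= 0) or np.any(f > 1):
            raise ValueError("fraction profile must lie in (0, 1]")
        return f


@dataclass
class EffectSpec:
    """A planted group/session difference on one bundle metric.

    ``section_range`` is a subset of 1..8 (arc-length octants) or "whole".
    """

    bundle_name: str
    metric: str
    magnitude: float
    mode: str = "additive"  # or "multiplicative"
    section_range: tuple[int, ...] | str = "whole"
    applies_to: str = "AUD"
    applies_at: tuple[str, ...] = ("E1", "E2")

    def __post_init__(self) -> None:
        if not np.isfinite(self.magnitude):
            raise ValueError("effect magnitude must be finite")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        if self.section_range != "whole":
            secs = tuple(int(s) for s in self.section_range)
            if len(secs) == 0 or any(s < 1 or s > N_SECTIONS for s in secs):
                raise ValueError("section_range must be a non-empty subset of 1..8")
            self.section_range = secs
        if isinstance(self.applies_at, str):
            self.applies_at = (self.applies_at,)

    def matches(self, group: str, session: str) -> bool:
        return group == self.applies_to and session in self.applies_at

    def to_dict(self) -> dict:
        d = asdict(self)
        d["section_range"] = (list(self.section_range)
                              if self.section_range != "whole" else "whole")
        d["applies_at"] = list(self.applies_at)
        return d


@dataclass
class ClinicalModel:
    """Linear generative model of the questionnaire scores.

    score = intercept + beta_group * 1[AUD] + beta_time * 1[E2]
            + sum_j beta_j * (metric_j - mean(metric_j)) + N(0, sd).

    ``metric_betas`` maps score -> list of (tract, metric, beta).  Default
    signs plant the pattern reported clinically: lower FA and higher RD on the
    designated tracts predict higher depression.
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {"bdi": 5.4, "ocds": 1.3, "sai": 29.2})
    beta_group: dict[str, float] = field(
        default_factory=lambda: {"bdi": 17.0, "ocds": 13.3, "sai": 15.4})
    beta_time: dict[str, float] = field(
        default_factory=lambda: {"bdi": -8.0, "ocds": -6.4, "sai": -5.7})
    metric_betas: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {"bdi": 4.0, "ocds": 3.0, "sai": 5.0})

    SCORE_RANGES = {"bdi": (0.0, 63.0), "ocds": (0.0, 40.0), "sai": (20.0, 80.0)}


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_aud: int = 40
    n_control: int = 20
    sessions: tuple[str, ...] = ("E1", "E2")
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: float = 2.0           # mm isotropic
    iso_diffusivity: float = 3.0e-3   # mm^2/s, free water at 37 deg C
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"FA": 0.02, "AD": 5e-5, "RD": 5e-5, "MD": 5e-5})
    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: {"FA": 0.015, "AD": 4e-5, "RD": 4e-5, "MD": 4e-5})
    session_correlation: float = 0.5  # within-subject E1-E2 correlation of the offsets
    cnr_mean: float = 20.0
    cnr_sd: float = 4.0
    cnr_slope: float = 5.0            # noise sd multiplier = 1 + slope / CNR
    clinical: ClinicalModel = field(default_factory=ClinicalModel)
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"AUD": 47.6, "control": 51.3})
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"AUD": 10.5, "control": 15.1})
    p_male: dict[str, float] = field(
        default_factory=lambda: {"AUD": 42 / 53, "control": 13 / 20})
    units_mean: dict[str, float] = field(
        default_factory=lambda: {"M": 18.9, "F": 11.36})
    units_sd: dict[str, float] = field(
        default_factory=lambda: {"M": 11.7, "F": 7.67})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aud < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per group")
        for d in (self.noise_sd, self.between_subject_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.session_correlation <= 1):
            raise ValueError("session_correlation must lie in [0, 1]")


@dataclass
class SubjectRecord:
    """One subject at one session."""

    id: str
    group: str           # "AUD" | "control"
    session: str         # "E1" | "E2"
    age: float
    sex: str             # "M" | "F"
    units_per_day: float
    cnr: float
    bdi: float = np.nan
    ocds: float = np.nan
    sai: float = np.nan
    fixel_field_path: str = ""


@dataclass
class BundleVoxels:
    """Voxel membership of one bundle in the phantom grid."""

    indices: np.ndarray    # (M, 3) int voxel indices
    slots: np.ndarray      # (M,) fixel slot (0 or 1) carrying this bundle
    arc_fraction: np.ndarray  # (M,) arc-length fraction in [0, 1]

    def section_of(self) -> np.ndarray:
        """Arc-length octant (1..8) of each member voxel."""
        return np.clip((self.arc_fraction * N_SECTIONS).astype(int) + 1, 1, N_SECTIONS)


@dataclass
class Phantom:
    """Template fixel field, bundle membership, ROI masks and label atlas."""

    field: FixelField
    membership: dict[str, BundleVoxels]
    rois: dict[str, dict[str, np.ndarray]]  # bundle -> role -> bool mask
    atlas: np.ndarray                       # int labels, 0 = background
    atlas_names: dict[int, str]
    bundles: dict[str, BundleSpec]


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _distance_to_polyline(pts: np.ndarray, line: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact distance from each point to a polyline.

    Returns (distance, arc_fraction, tangent) per query point, where
    arc_fraction is the normalized arc-length of the closest polyline point
    and tangent the direction of the closest segment.
    """
    a = line[:-1]                      # (S, 3)
    b = line[1:]
    ab = b - a
    seg_len2 = (ab**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    arc = _polyline_arclength(line)
    total = arc[-1]

    # t of the projection of each point on each segment, clipped to [0, 1]
    diff = pts[:, None, :] - a[None, :, :]          # (N, S, 3)
    t = np.clip((diff * ab[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    n = np.arange(len(pts))
    dist = np.sqrt(d2[n, best])
    s = (arc[best] + t[n, best] * np.sqrt(seg_len2[best])) / total
    tangent = ab[best] / np.linalg.norm(ab[best], axis=1, keepdims=True)
    return dist, s, tangent


def build_phantom(config: CohortConfig, bundles: Sequence[BundleSpec]) -> Phantom:
    """Rasterize bundle tubes into a template fixel field with ROIs and atlas.

    Each voxel crossed by a bundle carries a fixel with the bundle's local
    tangent orientation and baseline metrics; voxels crossed by two bundles
    carry two fixels; the isotropic fraction closes the volume budget
    (f1 + f2 + f_iso = 1).  Per bundle, seed / intermediary / termination ROI
    masks (each at least two voxels thick along the tract) and an integer
    atlas labeling the corridor are emitted.
    """
    shape = tuple(config.grid_shape)
    vs = float(config.voxel_size)
    affine = np.diag([vs, vs, vs, 1.0])
    K = 2

    orientations = np.zeros(shape + (K, 3))
    orientations[..., 0] = 1.0  # placeholder unit vectors for empty fixels
    fractions = np.zeros(shape + (K,))
    metrics = {m: np.zeros(shape + (K,)) for m in METRIC_NAMES}
    # isotropic compartment carries the free-water diffusivity everywhere
    membership: dict[str, BundleVoxels] = {}
    rois: dict[str, dict[str, np.ndarray]] = {}
    atlas = np.zeros(shape, dtype=int)
    atlas_names: dict[int, str] = {}
    slot_taken = np.zeros(shape, dtype=int)

    names = [b.name for b in bundles]
    if len(set(names)) != len(names):
        raise ValueError("bundle names must be unique")

    grid_max = (np.array(shape) - 1) * vs
    for label, bundle in enumerate(bundles, start=1):
        if np.any(bundle.centerline < -vs / 2) or np.any(bundle.centerline > grid_max + vs / 2):
            raise ValueError(f"centerline of bundle {bundle.name!r} exits the grid")

        lo = np.maximum(np.floor((bundle.centerline.min(axis=0) - bundle.radius) / vs), 0).astype(int)
        hi = np.minimum(np.ceil((bundle.centerline.max(axis=0) + bundle.radius) / vs),
                        np.array(shape) - 1).astype(int)
        ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d] + 1) for d in range(3)],
                                 indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = idx * vs
        dist, s, tangent = _distance_to_polyline(centers, bundle.centerline)
        inside = dist <= bundle.radius
        idx, s, tangent = idx[inside], s[inside], tangent[inside]
        if len(idx) == 0:
            raise ValueError(f"bundle {bundle.name!r} covers no voxels")

        vi = tuple(idx.T)
        slots = slot_taken[vi]
        if np.any(slots >= K):
            raise ValueError(
                f"more than {K} bundles overlap in a voxel (adding {bundle.name!r})")
        frac = bundle.fraction_at(s)
        for k in range(K):
            sel = slots == k
            if not np.any(sel):
                continue
            sub = tuple(c[sel] for c in vi)
            orientations[sub + (k,)] = tangent[sel]
            fractions[sub + (k,)] = frac[sel]
            for m in METRIC_NAMES:
                metrics[m][sub + (k,)] = bundle.baseline_metrics[m]
        slot_taken[vi] = slots + 1
        membership[bundle.name] = BundleVoxels(idx, slots.copy(), s)

        # atlas: first bundle to claim a voxel keeps it
        claim = atlas[vi] == 0
        atlas[tuple(c[claim] for c in vi)] = label
        atlas_names[label] = bundle.name

        # ROIs from arc-length: >= 2 voxel-planes thick along the tract
        length = _polyline_arclength(bundle.centerline)[-1]
        thick = max(2.5 * vs / length, 0.05)
        rois[bundle.name] = {
            "seed": _mask_from(idx, s <= thick, shape),
            "intermediary": _mask_from(idx, np.abs(s - 0.5) <= thick / 2, shape),
            "termination": _mask_from(idx, s >= 1 - thick, shape),
        }

    total = fractions.sum(axis=3)
    if np.any(total > 1 + 1e-9):
        raise ValueError("overlapping bundle fractions exceed unity; reduce fraction profiles")
    f_iso = np.clip(1.0 - total, 0.0, 1.0)

    fld = FixelField(affine=affine, orientations=orientations,
                     fractions=fractions, metrics=metrics, f_iso=f_iso)
    fld.validate()
    return Phantom(field=fld, membership=membership, rois=rois,
                   atlas=atlas, atlas_names=atlas_names,
                   bundles={b.name: b for b in bundles})


def _mask_from(idx: np.ndarray, sel: np.ndarray, shape: tuple) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[tuple(idx[sel].T)] = True
    return m


def simulate_subject(phantom: Phantom, effects: Sequence[EffectSpec],
                     record: SubjectRecord, seed: int,
                     config: CohortConfig,
                     subject_offsets: dict[str, float] | None = None,
                     session_noise: dict[str, np.ndarray] | None = None,
                     ) -> FixelField:
    """Apply matching planted effects and CNR-scaled noise to the template.

    ``subject_offsets`` (per metric) model stable between-subject biology and
    are added to all bundle fixels; ``session_noise`` allows the caller to
    supply pre-correlated per-voxel noise for repeated sessions, otherwise
    independent Gaussian noise is drawn from ``seed``.
    """
    fld = phantom.field.copy()
    for eff in effects:
        if eff.bundle_name not in phantom.membership:
            raise KeyError(f"effect references unknown bundle {eff.bundle_name!r}")
        if eff.metric not in fld.metrics:
            raise KeyError(f"effect references unknown metric {eff.metric!r}")
        if not eff.matches(record.group, record.session):
            continue
        bv = phantom.membership[eff.bundle_name]
        if eff.section_range == "whole":
            sel = np.ones(len(bv.indices), dtype=bool)
        else:
            sel = np.isin(bv.section_of(), eff.section_range)
        sub = tuple(bv.indices[sel].T) + (bv.slots[sel],)
        if eff.mode == "additive":
            fld.metrics[eff.metric][sub] += eff.magnitude
        else:
            fld.metrics[eff.metric][sub] *= eff.magnitude

    rng = np.random.default_rng(seed)
    active = fld.fractions > 0
    noise_scale = 1.0 + config.cnr_slope / record.cnr
    for m in METRIC_NAMES:
        if subject_offsets and m in subject_offsets:
            fld.metrics[m][active] += subject_offsets[m]
        sd = config.noise_sd.get(m, 0.0) * noise_scale
        if session_noise is not None and m in session_noise:
            fld.metrics[m] += sd * session_noise[m]
        elif sd > 0:
            fld.metrics[m][active] += rng.normal(0.0, sd, size=int(active.sum()))
    # enforce physical ranges
    fld.metrics["FA"] = np.clip(fld.metrics["FA"], 0.0, 1.0)
    for m in ("AD", "RD", "MD"):
        fld.metrics[m] = np.clip(fld.metrics[m], 0.0, None)
    return fld


def simulate_clinical(records: pd.DataFrame, tract_summaries: pd.DataFrame | None,
                      model: ClinicalModel, seed: int,
                      clip_to_range: bool = True) -> pd.DataFrame:
    """Fill the questionnaire columns of a cohort record table.

    ``tract_summaries`` is a tidy table (subject, session, tract, metric,
    value); its values enter mean-centred, weighted by the model's
    ``metric_betas``.  Scores follow the linear model with Gaussian residuals
    and are clipped to instrument ranges unless ``clip_to_range`` is False.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    wide = None
    if tract_summaries is not None and len(tract_summaries):
        wide = tract_summaries.pivot_table(
            index=["subject", "session"], columns=["tract", "metric"],
            values="value")
        wide = wide - wide.mean(axis=0)

    for score, intercept in model.intercepts.items():
        vals = np.full(len(out), float(intercept))
        vals += model.beta_group.get(score, 0.0) * (out["group"] == "AUD").to_numpy(float)
        vals += model.beta_time.get(score, 0.0) * (out["session"] == "E2").to_numpy(float)
        for tract, metric, beta in model.metric_betas.get(score, []):
            if wide is None or (tract, metric) not in wide.columns:
                raise KeyError(
                    f"clinical model references missing tract summary ({tract}, {metric})")
            centred = wide[(tract, metric)]
            keys = list(zip(out["id"], out["session"]))
            vals += beta * centred.reindex(keys).to_numpy(float)
        sd = model.residual_sd.get(score, 0.0)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=len(out))
        if clip_to_range and score in model.SCORE_RANGES:
            lo, hi = model.SCORE_RANGES[score]
            vals = np.clip(vals, lo, hi)
        out[score] = vals
    return out


@dataclass
class Cohort:
    """A generated cohort: records, lazy per-session fixel fields, truth ledger.

    Fields are regenerated deterministically on demand from stored seeds to
    keep memory bounded.
    """

    config: CohortConfig
    phantom: Phantom
    effects: list[EffectSpec]
    records: pd.DataFrame            # one row per subject x session
    truth: dict
    _field_seeds: dict[tuple[str, str], int]
    _subject_offsets: dict[str, dict[str, float]]
    _session_noise_seeds: dict[tuple[str, str], tuple[int, int]]

    def field(self, subject: str, session: str) -> FixelField:
        """Deterministically (re)generate the fixel field of one scan."""
        row = self.records[(self.records["id"] == subject)
                           & (self.records["session"] == session)]
        if len(row) != 1:
            raise KeyError(f"no unique record for ({subject}, {session})")
        rec = SubjectRecord(**{k: row.iloc[0][k] for k in
                               ("id", "group", "session", "age", "sex",
                                "units_per_day", "cnr")})
        rho = self.config.session_correlation
        shared_seed, own_seed = self._session_noise_seeds[(subject, session)]
        active = self.phantom.field.fractions > 0
        noise = {}
        for m in METRIC_NAMES:
            z_shared = np.random.default_rng(shared_seed + _metric_tag(m)).normal(
                size=self.phantom.field.fractions.shape)
            z_own = np.random.default_rng(own_seed + _metric_tag(m)).normal(
                size=self.phantom.field.fractions.shape)
            z = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * z_own
            noise[m] = np.where(active, z, 0.0)
        return simulate_subject(
            self.phantom, self.effects, rec,
            seed=self._field_seeds[(subject, session)], config=self.config,
            subject_offsets=self._subject_offsets[subject],
            session_noise=noise)

    def save_clinical(self, path: str) -> None:
        cols = ["id", "group", "session", "age", "sex", "units_per_day",
                "cnr", "bdi", "ocds", "sai"]
        self.records[cols].to_csv(path, index=False)

    def save_truth(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2)


def _metric_tag(name: str) -> int:
    return METRIC_NAMES.index(name) + 1


def generate_cohort(config: CohortConfig, bundles: Sequence[BundleSpec],
                    effects: Sequence[EffectSpec],
                    tract_summaries: pd.DataFrame | None = None) -> Cohort:
    """Generate a full cohort (records + lazy fields + planted-truth ledger).

    Clinical scores are generated from ``tract_summaries`` when supplied (the
    usual pipeline order is: generate fields, run tractometry, then call
    :func:`simulate_clinical` with the measured summaries); without summaries
    the scores carry only group/time effects.
    """
    phantom = build_phantom(config, bundles)
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    rows = []
    field_seeds: dict[tuple[str, str], int] = {}
    offsets: dict[str, dict[str, float]] = {}
    noise_seeds: dict[tuple[str, str], tuple[int, int]] = {}
    counter = 0
    for group, n in (("AUD", config.n_aud), ("control", config.n_control)):
        for i in range(n):
            sid = f"{'aud' if group == 'AUD' else 'ctl'}{i + 1:03d}"
            age = float(np.clip(rng.normal(config.age_mean[group],
                                           config.age_sd[group]), 25, 75))
            sex = "M" if rng.random() < config.p_male[group] else "F"
            units = float(max(rng.normal(config.units_mean[sex],
                                         config.units_sd[sex]), 0.5))
            if group == "control":
                units = float(max(rng.normal(1.0, 1.0), 0.0))
            cnr = float(max(rng.normal(config.cnr_mean, config.cnr_sd), 1.0))
            offsets[sid] = {m: float(rng.normal(0.0, config.between_subject_sd.get(m, 0.0)))
                            for m in METRIC_NAMES}
            shared = int(rng.integers(2**24)) * 16
            for session in config.sessions:
                rows.append(dict(id=sid, group=group, session=session, age=age,
                                 sex=sex, units_per_day=units, cnr=cnr,
                                 bdi=np.nan, ocds=np.nan, sai=np.nan))
                field_seeds[(sid, session)] = int(rng.integers(2**31))
                noise_seeds[(sid, session)] = (shared, int(rng.integers(2**24)) * 16)
                counter += 1

    records = pd.DataFrame(rows)
    clin_seed = int(np.random.default_rng(root.spawn(2)[1]).integers(2**31))
    records = simulate_clinical(records, tract_summaries, config.clinical,
                                seed=clin_seed)

    truth = {
        "seed": config.seed,
        "n_aud": config.n_aud,
        "n_control": config.n_control,
        "effects": [e.to_dict() for e in effects],
        "clinical_metric_betas": {k: [list(t) for t in v] for k, v in
                                  config.clinical.metric_betas.items()},
        "bundles": {b.name: {"radius": b.radius,
                             "baseline_metrics": b.baseline_metrics}
                    for b in bundles},
    }
    return Cohort(config=config, phantom=phantom, effects=list(effects),
                  records=records, truth=truth, _field_seeds=field_seeds,
                  _subject_offsets=offsets, _session_noise_seeds=noise_seeds)


# ---------------------------------------------------------------------------
# Default study geometry: three-tube surrogate of the tracts of interest
# ---------------------------------------------------------------------------

def default_bundles(grid_shape: tuple[int, int, int] = (40, 40, 40),
                    voxel_size: float = 2.0) -> list[BundleSpec]:
    """Geometric surrogates for the study's bundles on the given grid.

    Three tubes: a straight anterior-posterior "cingulum", an arched
    "uncinate", and a straight left-right "callosum_genu" crossing the
    cingulum at 90 degrees.  Baseline tensors use a typical coherent-WM
    eigenvalue pair (1.7e-3, 0.4e-3) mm^2/s.
    """
    nx, ny, nz = grid_shape
    vs = voxel_size
    cx, cy, cz = ((nx - 1) * vs / 2, (ny - 1) * vs / 2, (nz - 1) * vs / 2)
    wm = metrics_from_eigenvalues(1.7e-3, 0.4e-3)
    wm_b = metrics_from_eigenvalues(1.5e-3, 0.45e-3)

    margin = 3 * vs
    y_line = np.linspace(margin, (ny - 1) * vs - margin, 20)
    cing = np.column_stack([np.full_like(y_line, cx), y_line,
                            np.full_like(y_line, cz)])

    x_line = np.linspace(margin, (nx - 1) * vs - margin, 20)
    genu = np.column_stack([x_line, np.full_like(x_line, cy),
                            np.full_like(x_line, cz)])

    # gentle arc: curvature radius large enough that the orientation change
    # across one voxel stays below the 15-degree per-step tracking limit
    r_arc = 0.52 * min(cx, cz)
    t = np.linspace(np.radians(-70), np.radians(70), 24)
    unc = np.column_stack([cx + r_arc * np.sin(t),
                           np.full_like(t, margin + 2 * vs),
                           (cz - 2 * vs) + r_arc * np.cos(t)])

    return [
        BundleSpec("cingulum", cing, radius=2.2 * vs, baseline_metrics=wm,
                   fraction_profile=0.55),
        BundleSpec("callosum_genu", genu, radius=2.2 * vs, baseline_metrics=wm_b,
                   fraction_profile=0.40),
        BundleSpec("uncinate", unc, radius=1.6 * vs, baseline_metrics=wm,
                   fraction_profile=0.40),
    ]


def simulate_tract_summaries(config: CohortConfig, bundles: Sequence[BundleSpec],
                             effects: Sequence[EffectSpec],
                             records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Analytic tract-mean summaries without rasterizing fields.

    A subject's tract mean is the bundle baseline, plus the arc-length
    fraction-weighted sum of matching effects, plus a stable between-subject
    offset shared across sessions, plus a measurement term whose sd is the
    per-voxel noise sd scaled by 1 + slope/CNR and attenuated by averaging
    over the bundle's voxels (sqrt(n_voxels)).  This is the reduced generator
    used by clinical-association studies that do not need images.
    """
    rng = np.random.default_rng(seed)
    by_name = {b.name: b for b in bundles}
    n_vox = {b.name: max(int(_polyline_arclength(b.centerline)[-1]
                             * np.pi * b.radius**2 / config.voxel_size**3), 4)
             for b in bundles}
    subjects = records["id"].unique()
    offsets = {(sid, b.name, m): rng.normal(0.0, config.between_subject_sd.get(m, 0.0))
               for sid in subjects for b in bundles for m in METRIC_NAMES}
    rows = []
    for _, rec in records.iterrows():
        scale = 1.0 + config.cnr_slope / rec["cnr"]
        for b in bundles:
            for m in METRIC_NAMES:
                val = b.baseline_metrics[m]
                for eff in effects:
                    if (eff.bundle_name == b.name and eff.metric == m
                            and eff.matches(rec["group"], rec["session"])):
                        frac = (1.0 if eff.section_range == "whole"
                                else len(eff.section_range) / N_SECTIONS)
                        if eff.mode == "additive":
                            val += eff.magnitude * frac
                        else:
                            val *= 1 + (eff.magnitude - 1) * frac
                val += offsets[(rec["id"], b.name, m)]
                sd = config.noise_sd.get(m, 0.0) * scale / np.sqrt(n_vox[b.name])
                val += rng.normal(0.0, sd)
                rows.append(dict(subject=rec["id"], session=rec["session"],
                                 tract=b.name, metric=m, value=val))
    return pd.DataFrame(rows)


def default_clinical_model(fa_tract: str = "cingulum",
                           rd_tract: str = "uncinate") -> ClinicalModel:
    """Clinical model with the default planted brain-behaviour pattern.

    Lower FA on ``fa_tract`` and higher RD on ``rd_tract`` predict higher
    depression, on top of group and time main effects.
    """
    model = ClinicalModel()
    model.metric_betas = {"bdi": [(fa_tract, "FA", -150.0),
                                  (rd_tract, "RD", 6.0e4)]}
    return model


def default_effects() -> list[EffectSpec]:
    """Planted group differences emulating the reported pattern.

    A diffuse AD decrease along the whole cingulum, a localized AD decrease in
    the middle sections of the uncinate, and a diffuse FA decrease in the
    cingulum; the callosal tube is an unaffected negative control.
    """
    return [
        EffectSpec("cingulum", "AD", -0.15e-3, section_range="whole"),
        EffectSpec("cingulum", "FA", -0.06, section_range="whole"),
        EffectSpec("uncinate", "AD", -0.15e-3, section_range=(4, 5)),
    ]
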