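"""End-to-end orchestration: synthesize -> maps -> clusters -> track ->
tractometry -> stats, from one config, with provenance and deterministic
reruns.

Each stage writes its artifacts under the output directory and records them
(with content hashes) in a run manifest; downstream stages load upstream
artifacts from disk, so partial reruns are possible and reruns with an
identical config reproduce identical hashes for the deterministic stages.
Streamline geometry is tracked once per tract on the cohort template: in the
synthetic setting all subjects share one grid and one anatomy, and
per-subject metric noise does not move fixel orientations.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fixel import METRIC_NAMES, MetricVolume, weighted_metric_map
from .synthetic import (CohortConfig, Cohort, default_bundles, default_effects,
                        generate_cohort, simulate_clinical)
from .clusters import (assign_atlas_labels, estimate_smoothness, label_clusters,
                       montecarlo_cluster_threshold, voxelwise_glm)
from .tracking import Roi, StreamlineSet, TrackingParams, kde_clean, track_streamlines
from .tractometry import along_tract_profile, residualize_cnr, tract_mean_metric
from . import stats as gstats

STAGES = ("synthesize", "maps", "clusters", "track", "tractometry", "stats")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "fixtract_out"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=lambda: {
        "voxel_alpha": 1e-4, "fw_alpha": 0.05, "n_montecarlo": 500,
        "connectivity": 26})
    stats: dict = field(default_factory=lambda: {"alpha": 0.05})
    metrics: tuple[str, ...] = METRIC_NAMES

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        ca = self.cluster
        for key in ("voxel_alpha", "fw_alpha"):
            if not (0 < ca[key] < 1):
                raise ValueError(f"cluster.{key} must lie in (0, 1)")
        CohortConfig(**{**self.cohort, "seed": self.seed})   # raises if invalid
        TrackingParams(**{**self.tracking, "seed": self.seed})

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(**{**self.cohort, "seed": self.seed})

    def tracking_params(self) -> TrackingParams:
        return TrackingParams(**{**self.tracking, "seed": self.seed})

    def hash(self) -> str:
        text = json.dumps({**asdict(self), "metrics": list(self.metrics)},
                          sort_keys=True, default=str)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


def _sha1(path: str) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner bound to one configuration."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = config.out_dir
        os.makedirs(self.out, exist_ok=True)
        self._cohort: Cohort | None = None
        self.manifest: dict = {
            "config_hash": config.hash(), "version": __version__,
            "seed": config.seed, "stages": {}, "artifacts": {},
            "planted_truth": None,
        }

    # -- helpers ------------------------------------------------------------
    def _dir(self, name: str) -> str:
        d = os.path.join(self.out, name)
        os.makedirs(d, exist_ok=True)
        return d

    def _record(self, stage: str, paths: list[str], elapsed: float) -> None:
        self.manifest["stages"][stage] = {"seconds": round(elapsed, 3)}
        for p in paths:
            self.manifest["artifacts"][os.path.relpath(p, self.out)] = _sha1(p)

    def _require(self, path: str, produced_by: str) -> str:
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"missing upstream artifact {path!r}: run the "
                f"{produced_by!r} stage first")
        return path

    def cohort(self) -> Cohort:
        """The cohort is deterministic under the config; regenerate on demand."""
        if self._cohort is None:
            self._cohort = generate_cohort(
                self.config.cohort_config(),
                default_bundles(tuple(self.config.cohort_config().grid_shape),
                                self.config.cohort_config().voxel_size),
                default_effects())
        return self._cohort

    def scans(self) -> list[tuple[str, str]]:
        rec = self.cohort().records
        return list(rec[["id", "session"]].itertuples(index=False, name=None))

    # -- stages -------------------------------------------------------------
    def stage_synthesize(self) -> list[str]:
        d = self._dir("cohort")
        cohort = self.cohort()
        clinical = os.path.join(d, "clinical.csv")
        truth = os.path.join(d, "truth.json")
        cohort.save_clinical(clinical)
        cohort.save_truth(truth)
        atlas_path = os.path.join(d, "atlas.nii.gz")
        nib.save(nib.Nifti1Image(cohort.phantom.atlas.astype(np.int16),
                                 cohort.phantom.field.affine), atlas_path)
        names_path = os.path.join(d, "atlas_labels.tsv")
        pd.DataFrame([{"label": k, "name": v} for k, v in
                      cohort.phantom.atlas_names.items()]
                     ).to_csv(names_path, sep="\t", index=False)
        self.manifest["planted_truth"] = cohort.truth
        return [clinical, truth, atlas_path, names_path]

    def stage_maps(self) -> list[str]:
        d = self._dir("maps")
        cohort = self.cohort()
        written = []
        for sid, session in self.scans():
            fld = cohort.field(sid, session)
            for m in self.config.metrics:
                vol = weighted_metric_map(fld, m)
                path = os.path.join(d, f"{sid}_{session}_w{m}.nii.gz")
                vol.save(path)
                written.append(path)
        return written

    def stage_clusters(self) -> list[str]:
        d = self._dir("clusters")
        cohort = self.cohort()
        rec = cohort.records
        e1 = rec[rec["session"] == "E1"]
        ca = self.config.cluster
        frames = []
        for m in self.config.metrics:
            maps, groups, ages = [], [], []
            for _, row in e1.iterrows():
                path = self._require(
                    os.path.join(self.out, "maps",
                                 f"{row['id']}_E1_w{m}.nii.gz"), "maps")
                maps.append(MetricVolume.load(path, name=f"w{m}"))
                groups.append(row["group"])
                ages.append(row["age"])
            statmap, resid = voxelwise_glm(maps, np.array(groups), np.array(ages))
            smooth = estimate_smoothness(resid, cohort.config.voxel_size)
            thr = montecarlo_cluster_threshold(
                shape=tuple(cohort.config.grid_shape), fwhm=smooth["fwhm"],
                voxel_size=cohort.config.voxel_size,
                voxel_alpha=ca["voxel_alpha"], fw_alpha=ca["fw_alpha"],
                n_iter=ca["n_montecarlo"], seed=self.config.seed,
                connectivity=ca["connectivity"], metric=f"w{m}")
            table = label_clusters(statmap, voxel_alpha=ca["voxel_alpha"],
                                   min_size=thr.min_cluster_size,
                                   connectivity=ca["connectivity"],
                                   metric=f"w{m}")
            table = assign_atlas_labels(table, cohort.phantom.atlas,
                                        cohort.phantom.atlas_names, statmap)
            df = table.to_frame()
            df["min_cluster_size"] = thr.min_cluster_size
            df["fwhm_mm"] = round(smooth["fwhm"], 3)
            frames.append(df)
        out_path = os.path.join(d, "clusters.tsv")
        pd.concat(frames, ignore_index=True).to_csv(out_path, sep="\t", index=False)
        return [out_path]

    def stage_track(self) -> list[str]:
        d = self._dir("tracts")
        cohort = self.cohort()
        params = self.config.tracking_params()
        written = []
        for name, roi_masks in cohort.phantom.rois.items():
            rois = [Roi(roi_masks["seed"], "seed"),
                    Roi(roi_masks["intermediary"], "intermediary"),
                    Roi(roi_masks["termination"], "termination")]
            sset = track_streamlines(cohort.phantom.field, rois, params)
            if len(sset):
                sset = kde_clean(sset)
            sset.tract_name = name
            path = os.path.join(d, f"{name}.tck")
            sset.save(path)
            written.append(path)
        return written

    def stage_tractometry(self) -> list[str]:
        d = self._dir("tractometry")
        cohort = self.cohort()
        tracts = {}
        for name in cohort.phantom.rois:
            path = self._require(os.path.join(self.out, "tracts", f"{name}.tck"),
                                 "track")
            tracts[name] = StreamlineSet.load(path, tract_name=name)
        rows = []
        rec = cohort.records
        for sid, session in self.scans():
            fld = cohort.field(sid, session)
            cnr = float(rec[(rec["id"] == sid)
                            & (rec["session"] == session)]["cnr"].iloc[0])
            for name, sset in tracts.items():
                if len(sset) == 0:
                    continue
                for m in self.config.metrics:
                    prof = along_tract_profile(sset, fld, m, tract=name)
                    whole = tract_mean_metric(sset, fld, m)
                    rows.append(dict(subject=sid, session=session, tract=name,
                                     metric=m, section=0, value=whole, cnr=cnr))
                    for s in range(len(prof.means)):
                        rows.append(dict(subject=sid, session=session,
                                         tract=name, metric=m, section=s + 1,
                                         value=prof.means[s], cnr=cnr))
        table = pd.DataFrame(rows)
        whole = table[table["section"] == 0].copy()
        whole = residualize_cnr(whole)
        table = table.merge(
            whole[["subject", "session", "tract", "metric", "value_resid"]],
            on=["subject", "session", "tract", "metric"], how="left")
        out_path = os.path.join(d, "tract_metrics.csv")
        table.to_csv(out_path, index=False)
        return [out_path]

    def stage_stats(self) -> list[str]:
        d = self._dir("stats")
        cohort = self.cohort()
        alpha = self.config.stats.get("alpha", 0.05)
        tm_path = self._require(
            os.path.join(self.out, "tractometry", "tract_metrics.csv"),
            "tractometry")
        table = pd.read_csv(tm_path)
        whole = table[table["section"] == 0].copy()

        # complete the clinical scores from the measured tract summaries
        summaries = whole.rename(columns={"value_resid": "value_r"})[
            ["subject", "session", "tract", "metric", "value"]]
        records = simulate_clinical(cohort.records, summaries,
                                    cohort.config.clinical,
                                    seed=self.config.seed + 1)
        clin_path = os.path.join(d, "clinical_scored.csv")
        records.to_csv(clin_path, index=False)

        merged = whole.merge(records, left_on=["subject", "session"],
                             right_on=["id", "session"])

        # Welch per tract x metric x session on CNR-residualized means
        rows = []
        for (tract, metric, session), sub in merged.groupby(
                ["tract", "metric", "session"]):
            a = sub[sub["group"] == "AUD"]["value_resid"].to_numpy()
            b = sub[sub["group"] == "control"]["value_resid"].to_numpy()
            res = gstats.welch_test(a, b)
            rows.append(dict(family=f"welch_{metric}_{session}", test=tract,
                             statistic=res.statistic, df=res.df, p=res.p,
                             method=res.method))
        welch = pd.DataFrame(rows)
        welch["p_adjusted_flag"] = False
        for fam, idx in welch.groupby("family").groups.items():
            welch.loc[idx, "p_adjusted_flag"] = gstats.bonferroni_gate(
                welch.loc[idx, "p"].to_numpy(), alpha=alpha)
        welch_path = os.path.join(d, "welch_tests.csv")
        welch.to_csv(welch_path, index=False)

        # longitudinal fixed-effects models
        rows = []
        for (tract, metric), sub in merged.groupby(["tract", "metric"]):
            res = gstats.longitudinal_fixed_model(sub, value_col="value_resid")
            for _, r in res.coefficients.iterrows():
                rows.append(dict(tract=tract, metric=metric, term=r["name"],
                                 B=r["B"], SE=r["SE"], t=r["t"], p=r["p"]))
        long_path = os.path.join(d, "longitudinal_models.csv")
        pd.DataFrame(rows).to_csv(long_path, index=False)

        # consumption regressions (AUD only; needs >= 4 consuming subjects)
        aud = merged[merged["group"] == "AUD"]
        if aud["subject"].nunique() >= 4:
            cons = gstats.consumption_regression(
                aud, value_col="value_resid", subject_col="subject",
                alpha=alpha)
        else:
            cons = pd.DataFrame(columns=["tract", "metric", "target", "R",
                                         "p", "n", "significant"])
        cons_path = os.path.join(d, "consumption_regressions.csv")
        cons.to_csv(cons_path, index=False)

        # normality-gated BDI correlations at E1 in the AUD group, BH-FDR
        rows = []
        e1aud = merged[(merged["session"] == "E1") & (merged["group"] == "AUD")]
        for (tract, metric), sub in e1aud.groupby(["tract", "metric"]):
            try:
                res = gstats.normality_gated_correlation(
                    sub["value_resid"].to_numpy(), sub["bdi"].to_numpy())
            except ValueError:
                continue
            rows.append(dict(family="bdi_corr_E1", test=f"{tract}:{metric}",
                             statistic=res.statistic, df=res.df, p=res.p,
                             method=res.method))
        corr = pd.DataFrame(rows)
        if len(corr):
            flags, crit = gstats.bh_fdr(corr["p"].to_numpy(), q=alpha)
            corr["p_adjusted_flag"] = flags
            corr["bh_critical"] = crit
        corr_path = os.path.join(d, "bdi_correlations.csv")
        corr.to_csv(corr_path, index=False)

        # mixed-effects depression model per metric family
        rows = []
        for metric in self.config.metrics:
            sub = merged[merged["metric"] == metric]
            wide = sub.pivot_table(index=["subject", "session"],
                                   columns="tract", values="value_resid")
            meta = sub.groupby(["subject", "session"]).first()[
                ["group", "bdi"]].join(wide).reset_index()
            meta = meta.rename(columns={"subject": "id"}).dropna()
            tracts = [c for c in wide.columns]
            res = gstats.depression_model(meta, tracts, mixed=True)
            for _, r in res.coefficients.iterrows():
                rows.append(dict(metric_family=metric, term=r["name"],
                                 B=r["B"], SE=r["SE"], t=r["t"], p=r["p"],
                                 vif=res.vif.get(r["name"], np.nan),
                                 method=res.method))
        dep_path = os.path.join(d, "depression_models.csv")
        pd.DataFrame(rows).to_csv(dep_path, index=False)

        return [clin_path, welch_path, long_path, cons_path, corr_path, dep_path]


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] | None = None) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    stages = tuple(stages) if stages else STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    pipe = Pipeline(config)
    order = [s for s in STAGES if s in stages]
    for stage in order:
        start = time.perf_counter()
        paths = getattr(pipe, f"stage_{stage}")()
        pipe._record(stage, paths, time.perf_counter() - start)
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(pipe.manifest, fh, indent=2, default=str)
    return pipe.manifest


def smoke_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """A 6-subject configuration that exercises every stage quickly."""
    return PipelineConfig(
        out_dir=out_dir, seed=seed,
        cohort={"n_aud": 3, "n_control": 3, "grid_shape": (24, 24, 24)},
        tracking={"n_seeds": 3000, "max_streamlines": 60},
        cluster={"voxel_alpha": 1e-3, "fw_alpha": 0.05, "n_montecarlo": 200,
                 "connectivity": 26},
    )
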