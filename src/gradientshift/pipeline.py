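"""End-to-end pipeline: simulate/load -> score -> project -> fit -> predict.

A single :class:`RunConfig` (YAML-loadable) drives every stage; all outputs
are plain CSV/JSON/NIfTI files under ``output_dir`` and each run emits a
:class:`RunReport` listing per-stage status and a content-hashed manifest.
Stages are isolated: each one reads the previous stage's files, so any stage
can be rerun on its own.  With a fixed seed two runs produce numerically
identical outputs.

The three-sample structure of a multi-study analysis (discovery sample,
replication sample, their union) is configuration, not code: ``samples``
maps sample names to study-ID lists and a "joint" union sample is added
automatically when two or more samples are declared.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import decoding as dec
from . import inference as inf
from . import prediction as pred
from . import projection as proj
from . import simulate as sim
from .io import (ActivationMap, AnalysisMask, Condition, RegionAtlas,
                 build_common_mask, load_atlas, load_volume, save_volume,
                 scatter_back, vectorize)
from .model import GradientShiftModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "ALL_STAGES",
            "demo_config"]

ALL_STAGES = ("simulate", "score", "project", "describe", "fit", "predict",
              "supplemental", "regions", "tmap", "decode", "report")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML round-trippable."""

    output_dir: str = "gradientshift_run"
    seed: int = 0
    K: int = 5
    n_perm: int = pred.DEFAULT_N_PERM
    shuffle_scope: str = "all"
    outlier_sd: float = 3.0
    voxel_p: float = 0.001
    min_cluster: int = 10
    fdr_q: float = 0.05
    samples: dict = field(default_factory=dict)   # name -> [study ids]
    # stage toggles
    run_esm: bool = True
    run_erq: bool = True
    run_interactions: bool = True
    run_ed: bool = True
    run_regions: bool = True
    run_tmap: bool = True
    run_decoding: bool = True
    run_cross_sample: bool = True
    # synthetic-cohort block; when None, external paths must be given
    simulate: dict | None = None
    n_voxels: int = 2000
    grid_shape: tuple = (10, 10, 20)
    n_terms: int = 25
    # external inputs (used when simulate is None)
    gradient_paths: list = field(default_factory=list)
    maps_manifest: str | None = None
    trials_csv: str | None = None
    covariates_csv: str | None = None
    esm_csv: str | None = None
    atlas_paths: dict = field(default_factory=dict)   # family -> nii path
    term_manifest: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.simulate is None:
            missing = [name for name, p in [
                ("gradient_paths", self.gradient_paths),
                ("maps_manifest", self.maps_manifest),
                ("trials_csv", self.trials_csv),
            ] if not p]
            if missing:
                raise ValueError(
                    f"no simulate block and missing inputs: {missing}")
            for p in list(self.gradient_paths) + [self.maps_manifest,
                                                  self.trials_csv]:
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"configured path missing: {p}")


def demo_config(output_dir: str | Path, seed: int = 0,
                n_perm: int = 199, **overrides) -> RunConfig:
    """The small self-contained demo world (~50 subjects, 2,000 voxels).

    ``n_perm`` is scaled down from the paper-faithful default of 5,000 so the
    demo finishes in minutes on one CPU.
    """
    return RunConfig(
        output_dir=str(output_dir), seed=seed, n_perm=n_perm,
        simulate={},
        samples={"DS": ["studyA1", "studyA2"], "RS": ["studyB1", "studyB2"]},
        **overrides,
    )


@dataclass
class RunReport:
    """Per-stage status plus a hashed output manifest."""

    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    started: str = ""
    version: str = ""

    def ok(self) -> bool:
        return all(str(v).startswith(("ok", "skipped"))
                   for v in self.stages.values())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.12g", lineterminator="\n")


class _Runner:
    """Holds per-run state; each stage reads files written by earlier ones."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.report = RunReport(config=asdict(config),
                                started=time.strftime("%Y-%m-%dT%H:%M:%S"),
                                version=_pkg_version())

    # ---------- input loading -------------------------------------------
    def _load_inputs(self):
        cfg = self.cfg
        if cfg.simulate is not None:
            grads = sorted((self.out / "gradients").glob("g*.nii*"))
        else:
            grads = [Path(p) for p in cfg.gradient_paths]
        grad_imgs = [load_volume(p) for p in grads]
        manifest = pd.read_csv(self.out / "maps_manifest.csv"
                               if cfg.simulate is not None else cfg.maps_manifest)
        map_imgs = [load_volume(Path(p) if Path(p).is_absolute()
                                else self.out / p, name=str(p))
                    for p in manifest["path"]]
        mask = build_common_mask(grad_imgs, map_imgs)
        basis = sim.GradientBasis.from_images(grad_imgs, mask)
        maps = [ActivationMap(str(r.subject_id), Condition(r.condition),
                              vectorize(img, mask), mask)
                for (_, r), img in zip(manifest.iterrows(), map_imgs)]
        return basis, maps, mask

    def _trials_path(self) -> Path:
        return (self.out / "trials.csv" if self.cfg.simulate is not None
                else Path(self.cfg.trials_csv))

    # ---------- stages ---------------------------------------------------
    def stage_simulate(self):
        cfg = self.cfg
        if cfg.simulate is None:
            return "skipped (external inputs)"
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        cohort_cfg = sim.CohortConfig(**sim_kwargs)
        basis = sim.make_gradient_basis(cfg.n_voxels, cfg.K,
                                        seed=cfg.seed + 1,
                                        grid_shape=cfg.grid_shape)
        cohort = sim.simulate_cohort(cohort_cfg, basis)
        gdir = self.out / "gradients"
        gdir.mkdir(exist_ok=True)
        for k in range(basis.K):
            save_volume(scatter_back(basis.maps[:, k], basis.mask, fill=0.0),
                        gdir / f"g{k + 1}.nii.gz")
        mdir = self.out / "maps"
        mdir.mkdir(exist_ok=True)
        rows = []
        for amap in cohort.maps:
            fname = f"maps/{amap.subject_id}_{amap.condition.value}.nii.gz"
            save_volume(scatter_back(amap.vector, basis.mask, fill=np.nan),
                        self.out / fname)
            rows.append({"subject_id": amap.subject_id,
                         "condition": amap.condition.value, "path": fname})
        _write_csv(pd.DataFrame(rows), self.out / "maps_manifest.csv")
        _write_csv(cohort.trials, self.out / "trials.csv")
        _write_csv(cohort.covariates, self.out / "covariates.csv")
        _write_csv(cohort.esm, self.out / "esm.csv")
        truth = {
            "realized_dG": cohort.truth.realized_dG.tolist(),
            "subject_ids": cohort.truth.subject_ids,
            "study_intercepts": cohort.truth.study_intercepts,
            "latent_success": cohort.truth.latent_success.tolist(),
        }
        (self.out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        # synthetic parcellation for the region-wise stage
        atlas_c, atlas_s = sim.make_synthetic_atlases(basis.mask)
        save_volume(_atlas_image(atlas_c), self.out / "atlas_cortical.nii.gz")
        save_volume(_atlas_image(atlas_s), self.out / "atlas_subcortical.nii.gz")
        return f"ok ({len(cohort.truth.subject_ids)} subjects, {cfg.n_voxels} voxels)"

    def stage_score(self):
        trials = pd.read_csv(self._trials_path())
        cov_path = (self.out / "covariates.csv" if self.cfg.simulate is not None
                    else self.cfg.covariates_csv)
        esm_path = (self.out / "esm.csv" if self.cfg.simulate is not None
                    else self.cfg.esm_csv)
        cov = pd.read_csv(cov_path) if cov_path and Path(cov_path).exists() else None
        esm = pd.read_csv(esm_path) if esm_path and Path(esm_path).exists() else None
        table = beh.build_behavior_table(trials, covariates=cov, esm=esm,
                                         outlier_threshold=self.cfg.outlier_sd)
        _write_csv(table.reset_index(), self.out / "behavior.csv")
        n_exc = int(table["excluded"].sum())
        return f"ok ({len(table)} subjects, {n_exc} excluded)"

    def stage_project(self):
        basis, maps, _ = self._load_inputs()
        projections = proj.projection_table(maps, basis)
        _write_csv(projections, self.out / "projections.csv")
        shifts = proj.shift_table(projections)
        _write_csv(shifts, self.out / "shifts.csv")
        return f"ok ({shifts.shape[0]} subjects x {basis.K} gradients)"

    def _samples(self, data: pd.DataFrame) -> dict[str, pd.DataFrame]:
        samples = dict(self.cfg.samples)
        if not samples:
            samples = {"all": sorted(data["study_id"].unique())}
        out = {name: data[data["study_id"].isin(studies)]
               for name, studies in samples.items()}
        if len(samples) >= 2:
            out["joint"] = data
        return out

    def _model_data(self) -> pd.DataFrame:
        shifts = pd.read_csv(self.out / "shifts.csv")
        behavior = pd.read_csv(self.out / "behavior.csv")
        data = shifts.merge(behavior, on="subject_id", how="inner")
        return data[~data["excluded"].astype(bool)].reset_index(drop=True)

    def stage_describe(self):
        projections = pd.read_csv(self.out / "projections.csv")
        behavior = pd.read_csv(self.out / "behavior.csv")
        projections = projections.merge(
            behavior[["subject_id", "study_id", "excluded"]], on="subject_id")
        projections = projections[~projections["excluded"].astype(bool)]
        samples = self._samples(projections)
        K = int(projections["gradient_id"].max())
        fam_zero = K * len(samples) * 2
        fam_paired = K * len(samples)
        rows = []
        for name, df in samples.items():
            for k, gdf in df.groupby("gradient_id"):
                wide = gdf.pivot(index="subject_id", columns="condition",
                                 values="z")
                for cond in (Condition.LOOK.value, Condition.REGULATE.value):
                    t = inf.wilcoxon_vs_zero(
                        wide[cond].to_numpy(),
                        family=f"{cond} vs 0", family_size=fam_zero)
                    rows.append({"sample": name, "gradient": k, "test": f"{cond} vs 0",
                                 "mean_z": wide[cond].mean(), "W": t.statistic,
                                 "p_raw": t.p_raw, "p_bonf": t.p_adjusted,
                                 "n": t.n, "method": t.method})
                t = inf.wilcoxon_paired(
                    wide[Condition.LOOK.value].to_numpy(),
                    wide[Condition.REGULATE.value].to_numpy(),
                    family="Regulate vs Look", family_size=fam_paired)
                rows.append({"sample": name, "gradient": k,
                             "test": "Regulate vs Look",
                             "mean_z": (wide[Condition.REGULATE.value]
                                        - wide[Condition.LOOK.value]).mean(),
                             "W": t.statistic, "p_raw": t.p_raw,
                             "p_bonf": t.p_adjusted, "n": t.n,
                             "method": t.method})
        _write_csv(pd.DataFrame(rows), self.out / "wilcoxon.csv")
        return f"ok ({len(rows)} tests)"

    def stage_fit(self):
        data = self._model_data()
        results = {}
        coef_rows = []
        for name, df in self._samples(data).items():
            model = GradientShiftModel(df)
            res = model.fit()
            results[name] = _result_json(res.result)
            tab = res.coefficient_table()
            tab.insert(0, "sample", name)
            coef_rows.append(tab)
        (self.out / "results.json").write_text(json.dumps(results, indent=1))
        _write_csv(pd.concat(coef_rows, ignore_index=True),
                   self.out / "coefficients.csv")
        return f"ok ({len(results)} sample fits)"

    def stage_predict(self):
        data = self._model_data()
        samples = self._samples(data)
        fam = len(samples)
        summary = {}
        pair_rows, null_rows = [], []
        for i, (name, df) in enumerate(samples.items()):
            r = pred.permutation_test(
                df, n_perm=self.cfg.n_perm, seed=self.cfg.seed + 100 + i,
                shuffle_scope=self.cfg.shuffle_scope, family_size=fam)
            summary[name] = {"r": r.accuracy, "p_perm": r.p_perm,
                             "p_bonf": r.p_adjusted, "n": r.n_subjects,
                             "n_perm": r.n_perm}
            pp = r.pairs.copy()
            pp.insert(0, "sample", name)
            pair_rows.append(pp)
            null_rows.append(pd.DataFrame({"sample": name,
                                           "null_accuracy": r.null_accuracies}))
        if self.cfg.run_cross_sample and len(self.cfg.samples) >= 2:
            names = list(self.cfg.samples)
            train = data[data["study_id"].isin(self.cfg.samples[names[0]])]
            test = data[data["study_id"].isin(self.cfg.samples[names[1]])]
            r = pred.cross_sample_predict(
                train, test, n_perm=self.cfg.n_perm, seed=self.cfg.seed + 200)
            summary[f"{names[0]}->{names[1]}"] = {
                "r": r.accuracy, "p_perm": r.p_perm, "n": r.n_subjects,
                "n_perm": r.n_perm}
        (self.out / "prediction_summary.json").write_text(
            json.dumps(summary, indent=1))
        _write_csv(pd.concat(pair_rows, ignore_index=True),
                   self.out / "predictions.csv")
        _write_csv(pd.concat(null_rows, ignore_index=True),
                   self.out / "null_accuracies.csv")
        return f"ok ({len(summary)} prediction analyses)"

    def stage_supplemental(self):
        data = self._model_data()
        done = []
        out = {}
        if self.cfg.run_ed:
            for cols, tag in ((["ed5"], "ed5"), (["ed3"], "ed3")):
                res = inf.fit_mixed_model(
                    data, "success_z", cols + ["reactivity", "age", "sex"])
                out[f"ed_model_{tag}"] = _result_json(res)
            done.append("ed")
        if self.cfg.run_esm and "esm_mean" in data.columns \
                and data["esm_mean"].notna().sum() >= 15:
            sub = data[data["esm_mean"].notna()]
            res = inf.fit_mixed_model(sub, "esm_mean", inf.MAIN_PREDICTORS)
            out["esm_model"] = _result_json(res)
            done.append("esm")
        if self.cfg.run_erq:
            for col in ("erq_reappraisal", "erq_suppression"):
                if col in data.columns and data[col].notna().sum() >= 15:
                    res = inf.fit_mixed_model(
                        data, col, [c for c in inf.MAIN_PREDICTORS])
                    out[f"{col}_model"] = _result_json(res)
            done.append("erq")
        if self.cfg.run_interactions:
            ladder = inf.compare_interaction_models(data)
            _write_csv(ladder, self.out / "aic_ladder.csv")
            done.append("interactions")
        (self.out / "supplemental_models.json").write_text(
            json.dumps(out, indent=1))
        return f"ok ({', '.join(done) or 'nothing enabled'})"

    def stage_regions(self):
        if not self.cfg.run_regions:
            return "skipped"
        basis, maps, mask = self._load_inputs()
        behavior = pd.read_csv(self.out / "behavior.csv").set_index("subject_id")
        behavior = behavior[~behavior["excluded"].astype(bool)]
        frames = []
        for family in ("cortical", "subcortical"):
            apath = (self.out / f"atlas_{family}.nii.gz"
                     if self.cfg.simulate is not None
                     else self.cfg.atlas_paths.get(family))
            if not apath or not Path(apath).exists():
                continue
            atlas = load_atlas(apath, family=family)
            frames.append(proj.region_shift_table(maps, basis, atlas,
                                                  family=family))
        if not frames:
            return "skipped (no atlases)"
        region_shifts = pd.concat(frames, ignore_index=True)
        table = inf.regionwise_analysis(region_shifts, behavior,
                                        q=self.cfg.fdr_q)
        _write_csv(table, self.out / "regionwise.csv")
        return f"ok ({table.shape[0]} regions)"

    def stage_tmap(self):
        if not self.cfg.run_tmap:
            return "skipped"
        basis, maps, mask = self._load_inputs()
        data = self._model_data().set_index("subject_id")
        vecs = {m.subject_id: {} for m in maps}
        for m in maps:
            vecs[m.subject_id][m.condition.value] = m.vector
        sids = [s for s in data.index if len(vecs.get(s, {})) == 2]
        contrasts = np.array([vecs[s][Condition.REGULATE.value]
                              - vecs[s][Condition.LOOK.value] for s in sids])
        for covariate in ("success_z", "dG1"):
            res = inf.group_covariate_tmap(
                contrasts, data.loc[sids, covariate].to_numpy(), mask,
                voxel_p=self.cfg.voxel_p, min_cluster=self.cfg.min_cluster)
            save_volume(scatter_back(res.t, mask, fill=0.0),
                        self.out / f"tmap_{covariate}.nii.gz")
            _write_csv(res.clusters, self.out / f"clusters_{covariate}.csv")
        return f"ok ({len(sids)} subjects)"

    def stage_decode(self):
        if not self.cfg.run_decoding:
            return "skipped"
        basis, maps, mask = self._load_inputs()
        if self.cfg.term_manifest:
            terms = dec.load_term_maps(self.cfg.term_manifest, mask)
        else:
            terms = sim.make_term_maps(basis, n_terms=self.cfg.n_terms,
                                       seed=self.cfg.seed + 7)
        inputs = {"g1": basis.maps[:, 0]}
        tmap_path = self.out / "tmap_success_z.nii.gz"
        if tmap_path.exists():
            inputs["success_tmap"] = vectorize(load_volume(tmap_path), mask)
        for tag, vec in inputs.items():
            result = dec.decode_map(vec, terms)
            _write_csv(result.table, self.out / f"decoding_{tag}.csv")
        return f"ok ({terms.n_terms} terms, {len(inputs)} maps)"

    def stage_report(self):
        for p in sorted(self.out.rglob("*")):
            if p.is_file() and p.name != "report.json":
                self.report.manifest[str(p.relative_to(self.out))] = _sha256(p)
        (self.out / "report.json").write_text(
            json.dumps(asdict(self.report), indent=1))
        return f"ok ({len(self.report.manifest)} files)"


def _atlas_image(atlas: RegionAtlas):
    from .io import VoxelImage
    affine = atlas.affine if atlas.affine is not None else np.eye(4)
    return VoxelImage(values=atlas.labels.astype(np.float64), affine=affine,
                      name=f"atlas_{atlas.family}")


def _result_json(res: inf.MixedModelResult) -> dict:
    return {
        "formula": res.formula,
        "criterion": res.criterion,
        "loglik": res.loglik,
        "aic": res.aic,
        "r2_marginal": res.r2_marginal,
        "r2_conditional": res.r2_conditional,
        "n_obs": res.n_obs,
        "n_groups": res.n_groups,
        "coefficients": {
            str(name): {k: float(row[k]) for k in
                        ("estimate", "se", "t", "ci_low", "ci_high", "p")}
            for name, row in res.params.iterrows()
        },
    }


def _pkg_version() -> str:
    try:
        from importlib.metadata import version
        return version("gradientshift")
    except Exception:
        return "unknown"


def run_pipeline(config: RunConfig, stages=None) -> RunReport:
    """Run the requested stages (default: all) and return the report.

    A stage failure aborts with :class:`PipelineError`; the partial report
    (stages completed so far) is attached to the exception as ``report``.
    """
    config.validate()
    runner = _Runner(config)
    stage_fns = {
        "simulate": runner.stage_simulate,
        "score": runner.stage_score,
        "project": runner.stage_project,
        "describe": runner.stage_describe,
        "fit": runner.stage_fit,
        "predict": runner.stage_predict,
        "supplemental": runner.stage_supplemental,
        "regions": runner.stage_regions,
        "tmap": runner.stage_tmap,
        "decode": runner.stage_decode,
        "report": runner.stage_report,
    }
    selected = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(selected) - set(stage_fns)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for name in ALL_STAGES:
        if name not in selected:
            continue
        logger.info("stage %s ...", name)
        try:
            runner.report.stages[name] = stage_fns[name]()
        except Exception as err:
            runner.report.stages[name] = f"failed: {err}"
            exc = PipelineError(name, str(err))
            exc.report = runner.report
            raise exc from err
    return runner.report
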