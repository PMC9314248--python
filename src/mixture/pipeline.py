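"""End-to-end pipeline orchestration.

Runs the full chain — synthesize cohorts, tile, train the feature
extractor, cluster, render montages, integrate clusters, fine-tune finding
classifiers, classify the utility tiles, aggregate per case, predict UIP
and analyse survival — from a single config with per-stage seeds and a run
manifest recording every artifact hash. Two modes exist:

* ``integrated`` — the full human-in-the-loop chain (on synthetic data the
  pathologist's cluster review is stood in for by the oracle integration
  map built from the ground-truth masks, unless an explicit map file is
  supplied);
* ``non_integrated`` — the ablation: no integration and no transfer
  learning; case features are nearest-centroid cluster frequencies, swept
  over a list of cluster counts.

Artifacts live under ``workdir``: ``cohort_pretrain/``, ``cohort_utility/``,
``tiles/``, ``encoder/``, ``clusters/``, ``montages/``, ``integration/``,
``classifiers/``, ``predictions/``, ``profiles/``, ``diagnosis/``,
``survival/``, ``non_integrated/`` plus ``run_manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import case_diagnosis as cd
from . import cluster_montage as cm
from . import integration as integ
from . import ssl_encoder as ssl
from . import survival as surv
from . import synthetic_cohort as synth
from . import tiler
from .finding_classifier import (ClassifierConfig, FindingClassifier,
                                 classify_tiles, default_palette,
                                 render_finding_map, train_classifier)

logger = logging.getLogger("mixture.pipeline")

__all__ = ["PipelineConfig", "MissingDependencyError", "run",
           "run_non_integrated", "STAGE_ORDER"]

STAGE_ORDER = ["synth", "tile", "train-elex", "cluster", "montage",
               "integrate", "train-classifier", "classify", "aggregate",
               "predict", "survival"]


class MissingDependencyError(RuntimeError):
    """An upstream stage's artifact is absent."""


@dataclasses.dataclass
class PipelineConfig:
    workdir: str = "mixture_run"
    seed: int = 0
    mode: str = "integrated"
    # cohort
    n_cases: int = 20
    n_pretrain_cases: int = 16
    n_texture_classes: int = 4
    stain_jitter: float = 0.35
    base_size: int = 256
    region_grid: int = 4
    # tiling / levels
    levels: tuple = ("20x",)
    tile_size: int = 32
    # encoder
    ssl: ssl.SSLConfig = None
    # clustering / integration
    k: int = 16
    purity_threshold: float = 0.7       # oracle map: impure clusters EXCLUDED
    montage: cm.MontageConfig = None
    integration_maps: dict = None        # level -> explicit map path (optional)
    # classifier
    classifier: ClassifierConfig = None
    # diagnosis / survival
    diagnosis: cd.DiagnosisConfig = None
    k_list: tuple = (4, 8, 10, 20)
    r_threshold: float = 0.7
    cox_penalizer: float = 0.1

    def __post_init__(self):
        if self.mode not in ("integrated", "non_integrated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        seeds = np.random.SeedSequence(self.seed).generate_state(8) % (2**31)
        self._stage_seeds = {name: int(s) for name, s in zip(
            ["cohort", "tile", "elex", "cluster", "classifier",
             "diagnosis", "montage", "misc"], seeds)}
        if self.ssl is None:
            self.ssl = ssl.SSLConfig(queue_size=256, crop_size=self.tile_size,
                                     input_size=32, epochs=8, batch_size=64,
                                     seed=self._stage_seeds["elex"])
        if self.montage is None:
            self.montage = cm.MontageConfig(tiles_per_montage=120, grid_cols=12,
                                            thumbnail_size=32,
                                            seed=self._stage_seeds["montage"])
        if self.classifier is None:
            self.classifier = ClassifierConfig(epochs=12,
                                               seed=self._stage_seeds["classifier"])
        if self.diagnosis is None:
            self.diagnosis = cd.DiagnosisConfig(seed=self._stage_seeds["diagnosis"],
                                                n_trees=200, n_bootstrap=1000)
        if self.integration_maps is None:
            self.integration_maps = {}

    @property
    def root(self) -> Path:
        return Path(self.workdir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sub = {}
        if "ssl" in raw:
            sub["ssl"] = ssl.SSLConfig(**raw.pop("ssl"))
        if "classifier" in raw:
            sub["classifier"] = ClassifierConfig(**raw.pop("classifier"))
        if "diagnosis" in raw:
            sub["diagnosis"] = cd.DiagnosisConfig(**raw.pop("diagnosis"))
        if "montage" in raw:
            sub["montage"] = cm.MontageConfig(**raw.pop("montage"))
        for key in ("levels", "k_list"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw, **sub)


# ---------------------------------------------------------------------------
# manifest helpers

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record_stage(cfg: PipelineConfig, stage: str, seed: int,
                  artifacts: list, t0: float) -> None:
    mpath = cfg.root / "run_manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else []
    manifest = [e for e in manifest if e["stage"] != stage]
    manifest.append({
        "stage": stage, "seed": seed,
        "duration_s": round(time.time() - t0, 3),
        "artifacts": {str(Path(p).relative_to(cfg.root)): _sha256(Path(p))
                      for p in sorted(map(str, artifacts))}})
    mpath.write_text(json.dumps(manifest, indent=1))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise MissingDependencyError(
            f"stage {needed_by!r} needs {path.name} from stage {stage!r}; "
            f"run that stage first")
    return path


def _level_tag(level: str) -> str:
    return level.replace(".", "_")


# ---------------------------------------------------------------------------
# slide / tile IO

def _load_slide_level(cohort_dir: Path, slide_id: str, level: str) -> np.ndarray:
    p = cohort_dir / f"{slide_id}_{_level_tag(level)}.png"
    return np.asarray(Image.open(p).convert("RGB"))


def _load_mask(cohort_dir: Path, slide_id: str) -> np.ndarray:
    return np.asarray(Image.open(cohort_dir / f"{slide_id}_mask.png")).astype(np.int32)


def _load_tiles(cfg: PipelineConfig, subset: str, level: str) -> tiler.TileSet:
    """Rehydrate a TileSet (with images) from its manifest + slide PNGs."""
    man = _require(cfg.root / "tiles" / f"{subset}_{_level_tag(level)}.tsv",
                   "tile", "downstream")
    ts = tiler.read_manifest(man)
    cohort_dir = cfg.root / f"cohort_{subset}"
    cache = {}
    size = ts.config.tile_size
    for t in ts:
        if t.slide_id not in cache:
            cache[t.slide_id] = _load_slide_level(cohort_dir, t.slide_id, level)
        img = cache[t.slide_id]
        t.image = img[t.origin_y:t.origin_y + size, t.origin_x:t.origin_x + size]
    return ts


# ---------------------------------------------------------------------------
# stages

def _stage_synth(cfg: PipelineConfig) -> list:
    rng = np.random.default_rng(cfg._stage_seeds["cohort"])
    arts = []
    for subset, n in (("pretrain", cfg.n_pretrain_cases), ("utility", cfg.n_cases)):
        ccfg = synth.SyntheticCohortConfig(
            n_cases=n, classes=synth.default_texture_classes(cfg.n_texture_classes),
            stain_jitter=cfg.stain_jitter, base_size=cfg.base_size,
            region_grid=cfg.region_grid, seed=int(rng.integers(2**31)))
        slides, truth = synth.make_cohort(ccfg)
        outdir = synth.write_cohort(slides, truth, cfg.root / f"cohort_{subset}")
        arts.extend(outdir.glob("*"))
    return arts


def _stage_tile(cfg: PipelineConfig) -> list:
    arts = []
    for subset in ("pretrain", "utility"):
        cohort_dir = _require(cfg.root / f"cohort_{subset}" / "manifest.json",
                              "synth", "tile").parent
        manifest = json.loads((cohort_dir / "manifest.json").read_text())
        mode_cfg = (tiler.TilingConfig(tile_size=cfg.tile_size,
                                       max_background_fraction=0.9,
                                       max_tiles_per_slide=300,
                                       seed=cfg._stage_seeds["tile"])
                    if subset == "pretrain" else
                    tiler.TilingConfig(tile_size=cfg.tile_size,
                                       max_background_fraction=0.7,
                                       max_tiles_per_slide=None,
                                       seed=cfg._stage_seeds["tile"]))
        for level in cfg.levels:
            tiles = []
            for entry in manifest:
                img = _load_slide_level(cohort_dir, entry["slide_id"], level)
                ts = tiler.tile_slide(img, entry["slide_id"], level, mode_cfg)
                tiles.extend(ts.tiles)
            tset = tiler.TileSet(tiles, mode_cfg)
            out = cfg.root / "tiles" / f"{subset}_{_level_tag(level)}.tsv"
            arts.append(tiler.write_manifest(tset, out))
    return arts


def _stage_train_elex(cfg: PipelineConfig) -> list:
    arts = []
    for level in cfg.levels:
        ts = _load_tiles(cfg, "pretrain", level)
        enc = ssl.train_elex(ts, cfg.ssl)
        base = cfg.root / "encoder" / f"elex_{_level_tag(level)}"
        enc.save(base)
        arts += [base.with_suffix(".npz"), base.with_suffix(".json")]
    return arts


def _embed(cfg: PipelineConfig, subset: str, level: str):
    base = _require(cfg.root / "encoder" / f"elex_{_level_tag(level)}.json",
                    "train-elex", "cluster/classify").with_suffix("")
    enc = ssl.Encoder.load(base)
    ts = _load_tiles(cfg, subset, level)
    return enc, ts, ssl.extract_features(enc, ts)


def _stage_cluster(cfg: PipelineConfig) -> list:
    arts = []
    for level in cfg.levels:
        _, ts, feats = _embed(cfg, "pretrain", level)
        model = cm.fit_kmeans(feats, cfg.k, seed=cfg._stage_seeds["cluster"])
        base = cfg.root / "clusters" / f"kmeans_{_level_tag(level)}"
        model.save(base)
        np.savez(base.parent / f"features_{_level_tag(level)}.npz",
                 values=feats.values,
                 keys=np.array(["|".join(map(str, k)) for k in feats.tile_keys]))
        arts += [base.with_suffix(".json"), base.with_suffix(".centroids.npy"),
                 base.with_suffix(".assignments.tsv"),
                 base.parent / f"features_{_level_tag(level)}.npz"]
    return arts


def _stage_montage(cfg: PipelineConfig) -> list:
    arts = []
    for level in cfg.levels:
        base = _require(cfg.root / "clusters" / f"kmeans_{_level_tag(level)}.json",
                        "cluster", "montage").with_suffix("")
        model = cm.ClusterModel.load(base)
        ts = _load_tiles(cfg, "pretrain", level)
        outdir = cfg.root / "montages" / _level_tag(level)
        outdir.mkdir(parents=True, exist_ok=True)
        for c in range(model.k):
            img, legend = cm.build_montage(ts, model.assignments, c, cfg.montage)
            if img.size == 0:
                continue
            p = outdir / f"cluster_{c:03d}.png"
            Image.fromarray(img).save(p)
            lp = outdir / f"cluster_{c:03d}_legend.tsv"
            pd.DataFrame({"tile_key": ["|".join(map(str, k)) for k in legend]}
                         ).to_csv(lp, sep="\t", index=False)
            arts += [p, lp]
    return arts


def _synthetic_scheme(cfg: PipelineConfig, level: str) -> tuple:
    names = [c.name for c in synth.default_texture_classes(cfg.n_texture_classes)]
    return integ.FindingScheme(level, tuple(names + ["other"])), names


def _stage_integrate(cfg: PipelineConfig) -> list:
    arts = []
    for level in cfg.levels:
        base = _require(cfg.root / "clusters" / f"kmeans_{_level_tag(level)}.json",
                        "cluster", "integrate").with_suffix("")
        model = cm.ClusterModel.load(base)
        scheme, names = _synthetic_scheme(cfg, level)
        if level in cfg.integration_maps:
            imap = integ.load_integration_map(cfg.integration_maps[level],
                                              model, scheme)
        else:
            # oracle stand-in for the pathologist: majority ground-truth class
            ts = _load_tiles(cfg, "pretrain", level)
            cohort_dir = cfg.root / "cohort_pretrain"
            truth_labels = np.empty(len(ts), dtype=int)
            masks = {}
            f = synth.LEVEL_FACTORS[level]
            size = ts.config.tile_size
            for i, t in enumerate(ts):
                if t.slide_id not in masks:
                    masks[t.slide_id] = _load_mask(cohort_dir, t.slide_id)
                patch = masks[t.slide_id][t.origin_y * f:(t.origin_y + size) * f,
                                          t.origin_x * f:(t.origin_x + size) * f]
                truth_labels[i] = np.bincount(patch.ravel()).argmax()
            imap = integ.oracle_integration_map(
                model.assignments, truth_labels, scheme, class_names=names,
                purity_threshold=cfg.purity_threshold)
        out = cfg.root / "integration" / f"map_{_level_tag(level)}.json"
        arts.append(integ.save_integration_map(imap, out))
    return arts


def _stage_train_classifier(cfg: PipelineConfig) -> list:
    arts = []
    for level in cfg.levels:
        base = _require(cfg.root / "clusters" / f"kmeans_{_level_tag(level)}.json",
                        "cluster", "train-classifier").with_suffix("")
        model = cm.ClusterModel.load(base)
        scheme, _ = _synthetic_scheme(cfg, level)
        imap = integ.load_integration_map(
            _require(cfg.root / "integration" / f"map_{_level_tag(level)}.json",
                     "integrate", "train-classifier"), model, scheme)
        ts = _load_tiles(cfg, "pretrain", level)
        dataset = integ.build_labeled_dataset(ts, model.assignments, imap)
        enc = ssl.Encoder.load(cfg.root / "encoder" / f"elex_{_level_tag(level)}")
        clf = train_classifier(enc, dataset, cfg.classifier)
        out = cfg.root / "classifiers" / f"classifier_{_level_tag(level)}"
        clf.save(out)
        arts += [out.with_suffix(".npz"), out.with_suffix(".json")]
    return arts


def _stage_classify(cfg: PipelineConfig) -> list:
    arts = []
    for level in cfg.levels:
        clf = FindingClassifier.load(
            _require(cfg.root / "classifiers" / f"classifier_{_level_tag(level)}.json",
                     "train-classifier", "classify").with_suffix(""))
        ts = _load_tiles(cfg, "utility", level)
        labels, probs = classify_tiles(clf, ts)
        rows = []
        for t, lbl, p in zip(ts, labels, probs):
            rows.append({"case_id": t.slide_id.rsplit("_s", 1)[0],
                         "slide_id": t.slide_id, "grid_row": t.grid_row,
                         "grid_col": t.grid_col, "label": lbl,
                         **{f"p_{c}": float(v)
                            for c, v in zip(clf.scheme.class_names, p)}})
        out = cfg.root / "predictions" / f"tiles_{_level_tag(level)}.tsv"
        out.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
        arts.append(out)
        # one finding map per slide
        palette = default_palette(clf.scheme)
        mapdir = cfg.root / "predictions" / f"maps_{_level_tag(level)}"
        mapdir.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(rows)
        for slide_id, grp in df.groupby("slide_id"):
            idx = grp.index.to_numpy()
            fmap = render_finding_map(ts.subset(idx), list(grp["label"]), palette)
            p = mapdir / f"{slide_id}.png"
            Image.fromarray(fmap.image).save(p)
            arts.append(p)
    return arts


def _stage_aggregate(cfg: PipelineConfig) -> list:
    arts = []
    for level in cfg.levels:
        pred = pd.read_csv(
            _require(cfg.root / "predictions" / f"tiles_{_level_tag(level)}.tsv",
                     "classify", "aggregate"), sep="\t")
        scheme, _ = _synthetic_scheme(cfg, level)
        profiles = cd.aggregate_case(pred, level, scheme)
        rows = []
        for p in profiles:
            rows.append({"case_id": p.case_id, "valid": p.valid,
                         "n_tiles_total": p.n_tiles_total,
                         "n_tiles_retained": p.n_tiles_retained,
                         **{f"count_{c}": v for c, v in p.counts.items()},
                         **{f"prop_{c}": v for c, v in p.proportions.items()}})
        out = cfg.root / "profiles" / f"profiles_{_level_tag(level)}.csv"
        out.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out, index=False)
        arts.append(out)
    return arts


def _case_features(cfg: PipelineConfig, levels=None) -> pd.DataFrame:
    levels = levels or cfg.levels
    frames = []
    for level in levels:
        df = pd.read_csv(
            _require(cfg.root / "profiles" / f"profiles_{_level_tag(level)}.csv",
                     "aggregate", "predict"), index_col="case_id")
        df = df[df["valid"]]
        props = df[[c for c in df.columns if c.startswith("prop_")]]
        props.columns = [f"{level}:{c[5:]}" for c in props.columns]
        frames.append(props)
    return pd.concat(frames, axis=1, join="inner").sort_index()


def _stage_predict(cfg: PipelineConfig) -> list:
    feats = _case_features(cfg)
    truth = pd.read_csv(
        _require(cfg.root / "cohort_utility" / "case_truth.csv",
                 "synth", "predict"), index_col="case_id")
    common = feats.index.intersection(truth.index)
    X = feats.loc[common]
    y = truth.loc[common, "uip_label"].to_numpy()
    tr, va = cd.split_cases(y, cfg.diagnosis)
    scorer = cd.train_uip_model(X.iloc[tr], y[tr], cfg.diagnosis)
    scores = cd.predict_scores(scorer, X)
    roc = cd.roc_auc(scores[va], y[va])
    sens, spec = cd.threshold_metrics(scores[va], y[va],
                                      cfg.diagnosis.score_threshold)
    outdir = cfg.root / "diagnosis"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"case_id": common, "score": scores, "uip_label": y,
                  "split": ["train" if i in set(tr) else "val"
                            for i in range(len(common))]}
                 ).to_csv(outdir / "scores.csv", index=False)
    (outdir / "roc.json").write_text(json.dumps({
        "auc": roc.auc, "ci": [roc.ci_lower, roc.ci_upper],
        "ci_method": roc.method, "sensitivity": sens, "specificity": spec,
        "threshold": cfg.diagnosis.score_threshold,
        "n_train": int(len(tr)), "n_val": int(len(va))}, indent=1))
    return [outdir / "scores.csv", outdir / "roc.json"]


def _stage_survival(cfg: PipelineConfig) -> list:
    scores = pd.read_csv(_require(cfg.root / "diagnosis" / "scores.csv",
                                  "predict", "survival"), index_col="case_id")
    truth = pd.read_csv(cfg.root / "cohort_utility" / "case_truth.csv",
                        index_col="case_id")
    df = scores.join(truth[["time_days", "event"]], how="inner")
    df["predicted_uip"] = np.where(df["score"] >= cfg.diagnosis.score_threshold,
                                   "UIP", "non-UIP")
    records = df.rename(columns={"time_days": "time"})[
        ["time", "event", "predicted_uip"]].reset_index()
    outdir = cfg.root / "survival"
    outdir.mkdir(parents=True, exist_ok=True)
    arts = []
    result = {}
    groups = records["predicted_uip"].unique()
    km = surv.km_estimate(records, group_by="predicted_uip")
    rows = []
    for grp, cur in km.items():
        for t, s in zip(cur["times"], cur["survival"]):
            rows.append({"group": grp, "time": t, "survival": s})
        result[f"os_5y_{grp}"] = cur["at_horizon"][surv.FIVE_YEARS_DAYS]
    pd.DataFrame(rows).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    arts.append(outdir / "km_curves.tsv")
    if len(groups) == 2 and records["event"].sum() >= 1:
        stat, p = surv.logrank_test(records, group_by="predicted_uip")
        result["logrank_chi2"], result["logrank_p"] = stat, p
    feats = _case_features(cfg)
    covs, drop_report = surv.filter_collinear(feats, cfg.r_threshold)
    cox_df = covs.join(truth[["time_days", "event"]], how="inner").rename(
        columns={"time_days": "time"})
    try:
        cox = surv.cox_fit(cox_df.reset_index(drop=True),
                           covariate_cols=list(covs.columns),
                           penalizer=cfg.cox_penalizer)
        cox.summary.to_csv(outdir / "cox_summary.csv")
        arts.append(outdir / "cox_summary.csv")
        result["cox_n"], result["cox_events"] = cox.n, cox.n_events
    except (ValueError, RuntimeError) as exc:
        logger.warning("Cox fit skipped: %s", exc)
        result["cox_skipped"] = str(exc)
    drop_report.to_csv(outdir / "collinearity_report.csv", index=False)
    (outdir / "survival.json").write_text(json.dumps(result, indent=1))
    arts += [outdir / "collinearity_report.csv", outdir / "survival.json"]
    return arts


_STAGES = {"synth": _stage_synth, "tile": _stage_tile,
           "train-elex": _stage_train_elex, "cluster": _stage_cluster,
           "montage": _stage_montage, "integrate": _stage_integrate,
           "train-classifier": _stage_train_classifier,
           "classify": _stage_classify, "aggregate": _stage_aggregate,
           "predict": _stage_predict, "survival": _stage_survival}


def run(config: PipelineConfig, stages=("all",)) -> dict:
    """Execute the requested stages in pipeline order; returns the manifest."""
    if "all" in stages:
        stages = STAGE_ORDER
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    config.root.mkdir(parents=True, exist_ok=True)
    for name in STAGE_ORDER:
        if name not in stages:
            continue
        t0 = time.time()
        logger.info("stage %s starting (seed %d)", name, config.seed)
        arts = _STAGES[name](config)
        _record_stage(config, name, config.seed, arts, t0)
        logger.info("stage %s done: %d artifacts in %.1fs", name, len(arts),
                    time.time() - t0)
    return json.loads((config.root / "run_manifest.json").read_text())


def central_claim_experiment(seed: int = 0, n_reps: int = 5, n_cases: int = 100,
                             n_pretrain_slides: int = 40,
                             n_supplemental_slides: int = 12, k: int = 16,
                             k_per_case: int = 6, k_list=(4, 8, 20),
                             stain_jitter: float = 0.35,
                             tile_size: int = 32, base_size: int = 256,
                             ssl_epochs: int = 12, classifier_epochs: int = 20,
                             purity_threshold: float = 0.7,
                             cohort_kwargs: dict | None = None) -> pd.DataFrame:
    """Integrated vs non-integrated pipelines on jittered synthetic cohorts.

    One frozen pretraining chain (encoder, clustering, oracle-integrated
    classifier) is built once, as in the original design where a single
    pipeline is evaluated on held-out cohorts. The integrated chain includes
    supplemental per-case enrichment: the rare decisive class is seldom
    majority in any whole-set cluster, so a small cohort enriched for it is
    clustered case by case and the resulting (purer) clusters are added to
    the labeled data. Each replicate then draws a fresh utility cohort, runs
    both routes and records the validation AUC of the integrated
    finding-frequency model against the best-k AUC of the nearest-centroid
    cluster-frequency model. All computation is in memory.

    Returns one row per replicate: ``auc_integrated``, ``auc_non_integrated``
    (best over ``k_list``) and ``integrated_wins``.
    """
    rng = np.random.default_rng(seed)
    classes = synth.default_texture_classes(4)
    names = [c.name for c in classes]
    level = "20x"
    tile_cfg = tiler.TilingConfig(tile_size=tile_size,
                                  max_background_fraction=0.9,
                                  max_tiles_per_slide=300,
                                  seed=int(rng.integers(2**31)))

    def cohort_tiles(slides):
        tiles, labels, case_ids = [], [], []
        for s in slides:
            ts = tiler.tile_slide(s.levels[level], s.slide_id, level, tile_cfg)
            tiles.extend(t.image for t in ts)
            labels.extend(synth.tile_true_labels(s, ts.tiles, level, tile_size))
            case_ids.extend([s.case_id] * len(ts))
        return np.stack(tiles), np.array(labels), np.array(case_ids)

    # -- one-time pretraining chain ----------------------------------------
    pre_cfg = synth.SyntheticCohortConfig(
        n_cases=n_pretrain_slides, classes=classes, stain_jitter=stain_jitter,
        base_size=base_size, seed=int(rng.integers(2**31)))
    pre_slides, _ = synth.make_cohort(pre_cfg)
    pre_tiles, pre_labels, _ = cohort_tiles(pre_slides)
    ssl_cfg = ssl.SSLConfig(queue_size=256, crop_size=tile_size, input_size=32,
                            epochs=ssl_epochs, batch_size=64,
                            seed=int(rng.integers(2**31)))
    enc = ssl.train_elex(pre_tiles, ssl_cfg)
    pre_feats = enc.embed(pre_tiles)
    km = cm.fit_kmeans(pre_feats, k, seed=int(rng.integers(2**31)))
    scheme = integ.FindingScheme(level, tuple(names + ["other"]))
    imap = integ.oracle_integration_map(km.assignments, pre_labels, scheme,
                                        class_names=names,
                                        purity_threshold=purity_threshold)
    keep = [i for i in range(len(pre_tiles))
            if imap.entries[km.assignments[i]] != integ.EXCLUDED]
    dataset = integ.LabeledTileDataset(
        [f"t{i}" for i in keep], pre_tiles[keep],
        [imap.entries[km.assignments[i]] for i in keep],
        ["principal"] * len(keep), scheme)

    # supplemental enrichment of the rare class via per-case clustering
    if n_supplemental_slides > 0:
        supp_cfg = synth.SyntheticCohortConfig(
            n_cases=n_supplemental_slides, classes=classes,
            composition_prior=np.array([[8.0, 2.0, 2.0, 2.0]]),
            stain_jitter=stain_jitter, base_size=base_size,
            seed=int(rng.integers(2**31)))
        supp_slides, _ = synth.make_cohort(supp_cfg)
        supp_tile_cfg = tiler.TilingConfig(
            tile_size=tile_size, overlap_fraction=0.5,
            max_background_fraction=0.7, max_tiles_per_slide=None,
            seed=tile_cfg.seed)
        supp_sets = {s.case_id: tiler.tile_slide(s.levels[level], s.slide_id,
                                                 level, supp_tile_cfg)
                     for s in supp_slides}
        truth_by_case = {s.case_id: synth.tile_true_labels(
            s, supp_sets[s.case_id].tiles, level, tile_size)
            for s in supp_slides}
        models, _ = integ.enrich_per_case(supp_sets, enc, k_per_case=k_per_case,
                                          seed=int(rng.integers(2**31)))
        for case_id, model in models.items():
            cmap = integ.oracle_integration_map(
                model.assignments, truth_by_case[case_id], scheme,
                class_names=names, purity_threshold=purity_threshold)
            part = integ.build_labeled_dataset(supp_sets[case_id],
                                               model.assignments, cmap,
                                               source="supplemental")
            dataset = dataset.merged_with(part)

    clf = train_classifier(enc, dataset, ClassifierConfig(
        epochs=classifier_epochs, seed=int(rng.integers(2**31))))
    km_by_k = {kk: cm.fit_kmeans(pre_feats, kk, seed=int(rng.integers(2**31)))
               for kk in k_list}

    # -- replicated utility cohorts ----------------------------------------
    rows = []
    for rep in range(n_reps):
        ut_cfg = synth.SyntheticCohortConfig(
            n_cases=n_cases, classes=classes, stain_jitter=stain_jitter,
            base_size=base_size, seed=int(rng.integers(2**31)),
            **(cohort_kwargs or {}))
        ut_slides, ut_truth = synth.make_cohort(ut_cfg)
        ut_tiles, _, ut_cases = cohort_tiles(ut_slides)
        y_by_case = ut_truth.set_index("case_id")["uip_label"]
        diag_cfg = cd.DiagnosisConfig(seed=int(rng.integers(2**31)), n_trees=200)

        # integrated: classifier -> finding frequencies
        pred_labels, _ = clf.predict(ut_tiles)
        pred_df = pd.DataFrame({"case_id": ut_cases, "label": pred_labels})
        profiles = cd.aggregate_case(pred_df, level, scheme)
        feats_int = cd.profiles_to_features(profiles)
        y = y_by_case.loc[feats_int.index].to_numpy()
        tr, va = cd.split_cases(y, diag_cfg)
        scorer = cd.train_uip_model(feats_int.iloc[tr], y[tr], diag_cfg)
        auc_int = cd.roc_auc(cd.predict_scores(scorer, feats_int)[va], y[va]).auc

        # non-integrated: nearest-centroid cluster frequencies, best k
        ut_feats = enc.embed(ut_tiles)
        best = 0.0
        for kk, model in km_by_k.items():
            lab = cm.assign_nearest(model, ut_feats)
            freq = (pd.crosstab(ut_cases, lab)
                    .reindex(columns=range(kk), fill_value=0))
            freq = freq.div(freq.sum(axis=1), axis=0).sort_index()
            yk = y_by_case.loc[freq.index].to_numpy()
            trk, vak = cd.split_cases(yk, diag_cfg)
            sc_k = cd.train_uip_model(freq.iloc[trk], yk[trk], diag_cfg)
            best = max(best, cd.roc_auc(
                cd.predict_scores(sc_k, freq)[vak], yk[vak]).auc)
        rows.append({"rep": rep, "auc_integrated": auc_int,
                     "auc_non_integrated": best,
                     "integrated_wins": auc_int > best})
    return pd.DataFrame(rows)


def run_non_integrated(config: PipelineConfig, k_list=None) -> pd.DataFrame:
    """The ablation: cluster-frequency case features, swept over k.

    Requires the trained encoder and tiled cohorts on disk. For each k the
    pretraining tiles are clustered, utility tiles are assigned to nearest
    centroids, per-case cluster frequencies are the features, and the same
    diagnosis stage (split + scorer + AUC) is applied. Returns one row per
    k with the validation AUC.
    """
    k_list = list(k_list or config.k_list)
    rows = []
    truth = pd.read_csv(
        _require(config.root / "cohort_utility" / "case_truth.csv",
                 "synth", "non-integrated"), index_col="case_id")
    for level in config.levels:
        _, _, pre_feats = _embed(config, "pretrain", level)
        _, util_ts, util_feats = _embed(config, "utility", level)
        case_ids = np.array([t.slide_id.rsplit("_s", 1)[0] for t in util_ts])
        for k in k_list:
            model = cm.fit_kmeans(pre_feats, k, seed=config._stage_seeds["cluster"])
            labels = cm.assign_nearest(model, util_feats)
            freq = (pd.crosstab(case_ids, labels)
                    .reindex(columns=range(k), fill_value=0))
            freq = freq.div(freq.sum(axis=1), axis=0).sort_index()
            y = truth.loc[freq.index, "uip_label"].to_numpy()
            tr, va = cd.split_cases(y, config.diagnosis)
            scorer = cd.train_uip_model(freq.iloc[tr], y[tr], config.diagnosis)
            scores = cd.predict_scores(scorer, freq)
            roc = cd.roc_auc(scores[va], y[va])
            rows.append({"level": level, "k": k, "auc": roc.auc,
                         "ci_lower": roc.ci_lower, "ci_upper": roc.ci_upper})
    out = pd.DataFrame(rows)
    outdir = config.root / "non_integrated"
    outdir.mkdir(parents=True, exist_ok=True)
    out.to_csv(outdir / "auc_per_k.csv", index=False)
    return out
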