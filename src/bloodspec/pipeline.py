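"""End-to-end experiment orchestration with deterministic provenance.

``run_experiment`` composes the whole analysis — simulate (or load) ->
preprocess -> Kennard-Stone split -> grid-searched SVM per region and
labelling -> three-method biomarker extraction -> subject-level intensity
comparisons — and returns a versioned, JSON-serialisable :class:`RunReport`.
Identical config + seed yields an identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .biomarkers import (
    DEFAULT_CONTRASTS,
    cluster_vector_track,
    detect_peaks,
    ffs_track,
    merge_panels,
    subject_intensity_analysis,
    ttest_track,
)
from .chemometrics import pca_lda_fit
from .classify import SVMConfig, make_labels, run_classification
from .exceptions import ConfigError, DesignError, SchemaError
from .io import SpectralDataset, average_replicates, read_dataset, select_region
from .preprocess import VARIANT_A, VARIANT_B, PreprocessRecipe, apply_recipe
from .simulate import SimConfig, default_config, generate

SCHEMA_VERSION = "bloodspec-report-1"

log = logging.getLogger("bloodspec.pipeline")


@dataclass
class RunConfig:
    """Configuration of one end-to-end experiment."""

    sim: SimConfig | None = None
    dataset_path: str | None = None
    dataset_format: str = "wide_table"
    recipe: PreprocessRecipe = field(default_factory=PreprocessRecipe)
    regions: tuple = ("fingerprint", "high")
    labellings: tuple = ("two_class", "three_class")
    svm: SVMConfig = field(default_factory=SVMConfig)
    train_fraction: float = 2.0 / 3.0
    ffs_rounds: int = 50
    n_peaks: int = 6
    min_separation: float = 10.0
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        kw = dict(raw)
        if "sim" in kw and kw["sim"] is not None and not isinstance(kw["sim"], SimConfig):
            sim_raw = dict(kw["sim"])
            from .simulate import BandSpec, ClassEffect

            if "band_library" in sim_raw:
                sim_raw["band_library"] = tuple(BandSpec(**b) for b in sim_raw["band_library"])
            if "effects" in sim_raw:
                sim_raw["effects"] = tuple(ClassEffect(**e) for e in sim_raw["effects"])
            kw["sim"] = SimConfig(**sim_raw)
        if "recipe" in kw and not isinstance(kw["recipe"], PreprocessRecipe):
            kw["recipe"] = PreprocessRecipe(**kw["recipe"])
        if "svm" in kw and not isinstance(kw["svm"], SVMConfig):
            svm_raw = dict(kw["svm"])
            for g in ("c_grid", "gamma_grid"):
                if g in svm_raw:
                    svm_raw[g] = tuple(float(v) for v in svm_raw[g])
            kw["svm"] = SVMConfig(**svm_raw)
        for tup in ("regions", "labellings"):
            if tup in kw:
                kw[tup] = tuple(kw[tup])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Machine-readable results of one experiment."""

    schema_version: str
    provenance: dict
    metrics: dict          # "region/labelling" -> metrics dict
    biomarkers: dict       # region -> panel dict
    comparisons: list      # GroupComparison rows as dicts

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"unknown report schema {d.get('schema_version')!r}; "
                f"expected {SCHEMA_VERSION!r}"
            )
        return cls(**d)


def _config_hash(cfg: RunConfig) -> str:
    d = cfg.to_dict()
    d.pop("out_dir", None)  # where results land is not part of the experiment
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _panel_to_dict(panel) -> dict:
    return {
        "peaks": [
            {
                "wavenumber": p.wavenumber,
                "method": p.method,
                "methods": list(p.methods),
                "score": p.score,
                "p_value": p.p_value,
                "direction": p.direction,
                "corroborated": p.corroborated,
            }
            for p in panel.peaks
        ],
        "omitted": [
            {"wavenumber": p.wavenumber, "method": p.method, "rule": rule}
            for p, rule in panel.omitted
        ],
    }


def _check_axis_consistency(cfg: RunConfig, axis: np.ndarray) -> None:
    if cfg.sim is None:
        return
    step = float(np.diff(axis).mean()) if axis.size >= 2 else 1.0
    lo, hi = axis[0] - step / 2, axis[-1] + step / 2
    for e in cfg.sim.effects:
        if not lo <= e.wavenumber <= hi:
            raise ConfigError(
                f"configured effect wavenumber {e.wavenumber} cm^-1 is off-axis"
            )


def run_experiment(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline described by ``cfg``.

    Classification runs per (region, labelling) on recipe-preprocessed
    spectra; biomarker extraction runs per region on the two-class training
    subjects; intensity comparisons use rubber-band + vector-normalised data.
    """
    t0 = time.perf_counter()
    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        ds, truth = generate(sim)
        log.info("simulated dataset: %d spectra x %d points", ds.n_spectra, ds.axis.size)
    elif cfg.dataset_path is not None:
        ds = read_dataset(cfg.dataset_path, cfg.dataset_format)
        truth = None
        log.info("loaded dataset: %d spectra x %d points", ds.n_spectra, ds.axis.size)
    else:
        raise ConfigError("run config needs either a sim config or a dataset path")
    _check_axis_consistency(cfg, ds.axis)

    metrics: dict = {}
    biomarker_out: dict = {}
    comparisons: list = []

    for region in cfg.regions:
        for labelling in cfg.labellings:
            stage = f"{region}/{labelling}"
            t = time.perf_counter()
            bundle = run_classification(
                ds, cfg.recipe, region, labelling,
                dataclasses.replace(cfg.svm, seed=cfg.seed),
                fraction=cfg.train_fraction,
            )
            rep = bundle.report
            metrics[stage] = {
                "c": bundle.c,
                "gamma": bundle.gamma,
                "cv_accuracy": bundle.cv_accuracy,
                "test_accuracy": rep.accuracy,
                "per_class_rate": rep.per_class_rate,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "counts": rep.counts.to_dict(),
                "train_subjects": sorted(bundle.split.train_subjects),
                "test_subjects": sorted(bundle.split.test_subjects),
            }
            log.info("classification %s done in %.1fs", stage, time.perf_counter() - t)

        # biomarker extraction on two-class training subjects of this region
        t = time.perf_counter()
        pre = select_region(apply_recipe(ds, cfg.recipe), region)
        averaged = average_replicates(pre)
        split = metrics[f"{region}/two_class"]
        train_subjects = set(split["train_subjects"])
        tr_mask = np.array([r.subject_id in train_subjects for r in averaged.records])
        train_avg = averaged.subset(tr_mask)
        labels = make_labels(train_avg.records, "two_class")
        tt = ttest_track(train_avg, labels, subject_level=True)
        model = pca_lda_fit(train_avg, labels, cv=None)
        cvt = cluster_vector_track(model, train_avg.axis)
        fft = ffs_track(
            train_avg, labels, rounds=cfg.ffs_rounds, seed=cfg.seed,
            subject_level=True,
        )
        panels = [
            detect_peaks(trk, k=cfg.n_peaks, min_separation=cfg.min_separation)
            for trk in (tt, cvt, fft)
        ]
        merged = merge_panels(panels, min_separation=cfg.min_separation)
        biomarker_out[region] = {
            "per_method": {p.peaks[0].method if p.peaks else m: _panel_to_dict(p)
                           for m, p in zip(("ttest", "cluster_vector", "ffs"), panels)},
            "merged": _panel_to_dict(merged),
        }
        # intensity analysis on intensity-preserving preprocessing
        ds_a = select_region(
            apply_recipe(ds, PreprocessRecipe(variant=VARIANT_A)), region
        )
        for gc in subject_intensity_analysis(ds_a, merged, DEFAULT_CONTRASTS):
            row = dataclasses.asdict(gc)
            row["region"] = region
            comparisons.append(row)
        log.info("biomarkers %s done in %.1fs", region, time.perf_counter() - t)

    report = RunReport(
        schema_version=SCHEMA_VERSION,
        provenance={
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "bloodspec_version": __version__,
            "ground_truth": truth,
            "runtime_s": round(time.perf_counter() - t0, 3),
        },
        metrics=metrics,
        biomarkers=biomarker_out,
        comparisons=comparisons,
    )
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _write_report(report: RunReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    # runtime varies between identical runs; metrics.json must not
    stable = {k: v for k, v in d.items()}
    stable["provenance"] = {
        k: v for k, v in d["provenance"].items() if k != "runtime_s"
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(stable, fh, indent=2, sort_keys=True, default=_json_default)


def load_report(path) -> RunReport:
    with open(Path(path) / "metrics.json") as fh:
        return RunReport.from_dict(json.load(fh))


def _flatten(prefix: str, obj, out: dict) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, out)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _flatten(f"{prefix}[{i}]", v, out)
    elif isinstance(obj, (int, float)) and not isinstance(obj, bool):
        out[prefix] = float(obj)


def compare_reports(a: RunReport, b: RunReport, tolerance: float = 0.0) -> dict:
    """Numeric diff of two reports' metrics.

    Returns ``{"ok": bool, "differences": {path: (a, b)}}`` listing metric
    leaves whose absolute difference exceeds ``tolerance``.  Reports with
    different schema versions are rejected.
    """
    if a.schema_version != b.schema_version:
        raise SchemaError("cannot compare reports with different schema versions")
    fa: dict = {}
    fb: dict = {}
    _flatten("metrics", a.metrics, fa)
    _flatten("metrics", b.metrics, fb)
    diffs = {}
    for k in sorted(set(fa) | set(fb)):
        va, vb = fa.get(k), fb.get(k)
        if va is None or vb is None:
            diffs[k] = (va, vb)
        elif not (np.isnan(va) and np.isnan(vb)) and abs(va - vb) > tolerance:
            diffs[k] = (va, vb)
    return {"ok": not diffs, "differences": diffs}
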