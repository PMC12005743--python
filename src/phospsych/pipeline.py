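"""Configuration-driven orchestration of the full experiment.

A run executes, in order: synthetic-face generation, phosphene rendering
over the configured PIQ grid and modes, recognition-model training and
scoring, simulated (or loaded) human psychophysics, accuracy aggregation,
and model-to-human extrapolation.  Every stage writes its artifacts under
the configured output directory and records file hashes, seeds and
timings in a JSON manifest, making a run reproducible from config + code
and resumable stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import prediction as pr
from . import psychophysics as psy
from .faces import generate_dataset
from .models import ModelSpec, TrainConfig, predict_probs, train_model
from .phosphenes import GRAY_LEVELS, MODES, PIXEL_COUNTS, PIQLevel, phosphenize, piq_grid

STAGES = ("generate", "phosphenize", "train", "humans", "evaluate", "predict")


@dataclass
class ExperimentConfig:
    """Everything a run needs; fully serializable to YAML."""

    seed: int = 0
    n_classes: int = 4
    train_per_class: int = 36
    modes: list[str] = field(default_factory=lambda: ["ngb"])
    grid: str = "human"  # "human" (9 levels) or "full" (25)
    models: list[dict] = field(
        default_factory=lambda: [{"arch": "CNN_SHALLOW", "loss": "cel", "n_instances": 2}]
    )
    train: dict = field(default_factory=dict)
    psychometric: dict = field(default_factory=dict)
    n_subjects: int = 36
    piq_levels: list | None = None  # explicit (P, G) pairs; default = grid subset
    outdir: str = "phospsych_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)


def validate_config(config: ExperimentConfig) -> list[str]:
    """Report-only configuration check; returns a list of violations."""
    v: list[str] = []
    if config.grid not in ("human", "full"):
        v.append(f"unknown PIQ grid subset {config.grid!r}")
    if config.n_classes < 2:
        v.append("n_classes must be at least 2")
    elif config.n_classes < 4:
        v.append("the 4-way human protocol needs n_classes >= 4")
    if config.train_per_class < 8:
        v.append("train_per_class < 8 leaves no validation images per class")
    for m in config.modes:
        if m not in MODES:
            v.append(f"unknown phosphene mode {m!r}")
    for spec in config.models:
        try:
            ModelSpec(arch=spec.get("arch", "CNN_SHALLOW"), loss=spec.get("loss", "cel"))
        except ValueError as e:
            v.append(str(e))
    try:
        TrainConfig(**config.train)
    except (TypeError, ValueError) as e:
        v.append(f"train config: {e}")
    if config.n_subjects % psy.N_GROUPS:
        v.append(f"n_subjects must divide into {psy.N_GROUPS} groups")
    if config.piq_levels:
        for p, g in config.piq_levels:
            if p not in PIXEL_COUNTS:
                v.append(f"pixel count {p} not in {PIXEL_COUNTS}")
            if g not in GRAY_LEVELS:
                v.append(f"grayscale level {g} not in {GRAY_LEVELS}")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: ExperimentConfig, resume: bool = False) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    With ``resume=True`` stages whose outputs already exist are skipped.
    On a stage failure the manifest records the stages completed so far and
    the error, then the exception propagates.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}
    manifest_path = out / "manifest.json"

    def done(stage: str, t0: float, files: list[Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **(extra or {})}
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        # -- generate --------------------------------------------------
        t0 = time.time()
        dataset = generate_dataset(config.n_classes, config.train_per_class, config.seed)
        man_csv = out / "dataset_manifest.csv"
        if not (resume and man_csv.exists()):
            dataset.manifest().to_csv(man_csv, index=False)
        done("generate", t0, [man_csv], {"n_images": len(dataset)})

        # -- phosphenize ----------------------------------------------
        t0 = time.time()
        test = dataset.subset("test")
        if config.piq_levels:
            grid = [PIQLevel(p, g) for p, g in config.piq_levels]
        else:
            grid = piq_grid(config.grid)
        stimuli: dict[tuple, np.ndarray] = {}
        for mode in config.modes:
            for piq in grid:
                stimuli[(mode, piq)] = np.stack(
                    [phosphenize(im, piq, mode) for im in test.images]
                )
        n_stim = sum(len(v) for v in stimuli.values())
        done("phosphenize", t0, [], {"n_stimuli_per_mode": n_stim // len(config.modes)})

        # -- train + score --------------------------------------------
        t0 = time.time()
        records = []
        tcfg = TrainConfig(**config.train)
        for mspec in config.models:
            n_inst = mspec.get("n_instances", 2)
            for i in range(n_inst):
                spec = ModelSpec(
                    arch=mspec.get("arch", "CNN_SHALLOW"),
                    loss=mspec.get("loss", "cel"),
                    n_classes=config.n_classes,
                    instance_seed=config.seed * 1000 + i,
                )
                model, _hist = train_model(spec, dataset, tcfg)
                for (mode, piq), imgs in stimuli.items():
                    meta = pd.DataFrame(
                        {
                            "class_id": test.labels,
                            "viewpoint_deg": [c.viewpoint_deg for c in test.conditions],
                            "expression": [c.expression for c in test.conditions],
                        }
                    )
                    rec = predict_probs(model, imgs, meta)
                    rec["arch"] = spec.arch
                    rec["instance"] = i
                    rec["mode"] = mode
                    rec["pixels"] = piq.pixels
                    rec["grayscales"] = piq.grayscales
                    records.append(rec)
        model_records = ev.score_model_records(pd.concat(records, ignore_index=True))
        rec_csv = out / "model_records.csv"
        model_records.to_csv(rec_csv, index=False)
        done("train", t0, [rec_csv], {"n_records": len(model_records)})

        # -- humans ----------------------------------------------------
        t0 = time.time()
        plan = psy.human_design(config.n_subjects, config.n_classes, seed=config.seed)
        params = psy.PsychometricParams(**config.psychometric)
        trials = psy.simulate_human_responses(plan, params, seed=config.seed + 1)
        trials_csv = out / "human_trials.csv"
        psy.write_trials(trials, trials_csv)
        done("humans", t0, [trials_csv], {"n_trials": len(trials)})

        # -- evaluate --------------------------------------------------
        t0 = time.time()
        tables = []
        for k in (1, 2):
            for mode in config.modes:
                mrec = model_records[model_records["mode"] == mode]
                per_inst = ev.accuracy_by_observer(mrec, "instance", k=k)
                mt = ev.mean_with_exclusion(per_inst)
                mt["source"], mt["mode"], mt["k"] = "model", mode, k
                tables.append(mt)
                hrec = trials[trials["mode"] == mode]
                if len(hrec):
                    per_subj = ev.accuracy_by_observer(hrec, "subject_id", k=k)
                    ht = ev.mean_with_exclusion(per_subj)
                    ht["source"], ht["mode"], ht["k"] = "human", mode, k
                    tables.append(ht)
        acc = pd.concat(tables, ignore_index=True)
        acc_csv = out / "accuracy_tables.csv"
        acc.to_csv(acc_csv, index=False)
        done("evaluate", t0, [acc_csv])

        # -- predict ---------------------------------------------------
        t0 = time.time()
        human_levels = {(p.pixels, p.grayscales) for p in piq_grid("human")}
        est_rows = []
        for k in (1, 2):
            for mode in config.modes:
                sel = (acc["mode"] == mode) & (acc["k"] == k)
                mtab = acc[sel & (acc["source"] == "model")]
                htab = acc[sel & (acc["source"] == "human")]
                m_tested = mtab[
                    mtab.apply(lambda r: (r.pixels, r.grayscales) in human_levels, axis=1)
                ]
                if len(htab) == 0 or len(m_tested) == 0:
                    continue
                lmap = pr.fit_linear_map(m_tested, htab, k=k, mode=mode)
                measured = htab[["pixels", "grayscales", "mean"]].copy()
                measured["provenance"] = "measured"
                fitted = m_tested[["pixels", "grayscales"]].copy()
                fitted["mean"] = lmap(m_tested["mean"].to_numpy())
                fitted["provenance"] = "linear_fit"
                parts = [measured, fitted]
                m_untested = mtab[
                    mtab.apply(lambda r: (r.pixels, r.grayscales) not in human_levels, axis=1)
                ]
                if len(m_untested):
                    parts.append(pr.predict_linear(lmap, m_untested))
                block = pd.concat(parts, ignore_index=True)
                block["k"], block["mode"] = k, mode
                block["slope"], block["intercept"], block["r"] = (
                    lmap.slope,
                    lmap.intercept,
                    lmap.r,
                )
                est_rows.append(block)
        est = pd.concat(est_rows, ignore_index=True) if est_rows else pd.DataFrame()
        est_csv = out / "estimated_accuracy.csv"
        est.to_csv(est_csv, index=False)
        done("predict", t0, [est_csv], {"n_rows": len(est)})
    except Exception as e:  # record partial completion, then re-raise
        manifest["error"] = f"{type(e).__name__}: {e}"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    manifest["completed"] = True
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
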