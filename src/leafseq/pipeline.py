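"""End-to-end orchestration: simulate -> preprocess -> train -> predict
-> sequence -> evaluate, with a single serializable run configuration and
one global seed fanned out deterministically to every stage.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cgan, preprocessing, sequencing, simulation
from .core import Grid3, LeafSeqError, MachineModel
from .evaluation import (GammaCriteria, dose_diff_table, evaluate_predicted_plan,
                         gamma_table)

log = logging.getLogger("leafseq")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    seed: int = 0
    out_dir: str = "runs/demo"
    # cohort
    n_patients: int = 10
    n_fractions: int = 5
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    grid_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_segments_range: tuple[int, int] = (1, 6)
    mu_range: tuple[float, float] = (20.0, 200.0)
    # machine / engine
    leaf_width: float = 7.15
    sigma_mm: float = 3.0
    attenuation: float = 0.005
    # model
    image_size: int = 128
    train: cgan.TrainConfig = field(default_factory=cgan.TrainConfig)
    # evaluation
    gamma_subsample: int = 5
    gamma_max: float = 1.1
    # which LOOCV folds to run (None = all patients)
    holdouts: list[str] | None = None

    def machine(self) -> MachineModel:
        return MachineModel(leaf_width=self.leaf_width)

    def grid(self) -> Grid3:
        shape = tuple(self.grid_shape)
        spacing = tuple(self.grid_spacing)
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return Grid3(shape=shape, spacing=spacing, origin=origin)

    def gamma_criteria(self) -> GammaCriteria:
        return GammaCriteria(subsample=self.gamma_subsample,
                             max_gamma=self.gamma_max)

    def engine_kwargs(self) -> dict:
        return {"sigma_mm": self.sigma_mm, "mu_attenuation": self.attenuation}

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text)
        train = cgan.TrainConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.pop("train", {}).items()})
        for key in ("grid_shape", "grid_spacing", "n_segments_range",
                    "mu_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(train=train, **d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def provenance(config: RunConfig, stage: str) -> dict:
    return {"stage": stage, "config_hash": config.config_hash(),
            "version": __version__}


def stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 fanned out from one
    global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
               stage: str) -> None:
    prov = provenance(config, stage)
    with open(path, "w") as f:
        f.write(f"# leafseq {prov['version']} stage={stage} "
                f"config={prov['config_hash']}\n")
        df.to_csv(f, index=False)


class _Timer:
    def __init__(self, stage: str):
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: started", self.stage)
        return self

    def __exit__(self, *exc):
        log.info("stage %s: %.1f s", self.stage, time.perf_counter() - self.t0)


def run_pipeline(config: RunConfig) -> dict:
    """Run every requested leave-one-out fold end to end and write the
    per-fold gamma and dose-difference tables.

    Returns a summary dict: per fold the per-fraction gamma pass rates,
    the ROI dose differences, and the training loss tail.  A failing fold
    is logged and skipped; the other folds continue.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    machine = config.machine()
    seeds = stage_seeds(config.seed, 3)

    with _Timer("simulate"):
        cohort = simulation.sample_cohort(
            seeds[0], machine, n_patients=config.n_patients,
            n_fractions=config.n_fractions, grid_spec=config.grid(),
            n_segments_range=tuple(config.n_segments_range),
            mu_range=tuple(config.mu_range))

    with _Timer("preprocess"):
        pairs = preprocessing.build_training_pairs(
            cohort, shape=(config.image_size, config.image_size),
            engine_kwargs=config.engine_kwargs())

    splits = cgan.make_loocv_splits(pairs.meta)
    wanted = (config.holdouts if config.holdouts
              else [s.held_out_patient for s in splits])
    summary: dict = {"folds": {}, "config_hash": config.config_hash()}

    for fold_i, split in enumerate(s for s in splits
                                   if s.held_out_patient in wanted):
        pid = split.held_out_patient
        try:
            summary["folds"][pid] = _run_fold(
                config, machine, cohort, pairs, split,
                train_seed=stage_seeds(seeds[1] + fold_i, 1)[0], out_dir=out)
        except LeafSeqError as exc:
            log.error("fold %s failed: %s", pid, exc)
            summary["folds"][pid] = {"error": str(exc)}

    (out / "summary.json").write_text(json.dumps(
        {**summary, "provenance": provenance(config, "summary")},
        indent=2, default=str))
    return summary


def _run_fold(config: RunConfig, machine, cohort, pairs, split,
              train_seed: int, out_dir: Path) -> dict:
    pid = split.held_out_patient
    phantom = cohort.phantoms[pid]
    tcfg = cgan.TrainConfig(**{**asdict(config.train),
                               "image_size": config.image_size,
                               "seed": train_seed})

    with _Timer(f"train[{pid}]"):
        model = cgan.train(pairs, split, tcfg)

    with _Timer(f"predict+sequence+evaluate[{pid}]"):
        reports = evaluate_fold(model, pairs, split, cohort, machine, config)

    gt = gamma_table(reports)
    dd = dose_diff_table(reports)
    _write_csv(gt, out_dir / f"gamma_{pid}.csv", config, f"evaluate[{pid}]")
    _write_csv(dd, out_dir / f"dose_diff_{pid}.csv", config,
               f"evaluate[{pid}]")
    return {
        "gamma_pass_rates": {str(int(f)): float(g) for f, g in
                             zip(gt["fraction"][:-1],
                                 gt["gamma_pass_rate"][:-1])},
        "gamma_mean": float(gt["gamma_pass_rate"].iloc[-1]),
        "dose_diff": dd.to_dict(orient="records"),
        "final_losses": {"d": float(model.history["d_loss"].iloc[-1]),
                         "g": float(model.history["g_loss"].iloc[-1])},
    }


def scaled_learning_config(seed: int = 0) -> RunConfig:
    """The fixed reduced-scale study used for the self-contained learning
    check: 6 patients x 5 fractions (286 training beams in the first
    leave-one-out fold) on a 48^3, 4 mm grid, 64 x 64 images, 16 base
    filters, 40 epochs with snapshot selection on training delivery
    fidelity every 2 epochs."""
    return RunConfig(
        seed=seed, n_patients=6, n_fractions=5,
        grid_shape=(48, 48, 48), grid_spacing=(4.0, 4.0, 4.0),
        image_size=64,
        train=cgan.TrainConfig(epochs=40, gen_filters=16, disc_filters=16,
                               image_size=64, checkpoint_every=2,
                               ema_decay=0.9995),
        gamma_subsample=5, gamma_max=1.1)


def scaled_learning_check(seed: int = 0, config: RunConfig | None = None,
                          log: bool = False) -> dict:
    """Train the cGAN at reduced scale and compare sequenced predicted
    plans against an untrained (randomly initialized) model on the first
    fold's held-out fractions.

    Returns mean gamma pass rates for both models, their margin in
    percentage points, and the trained model's per-fraction reports.
    """
    config = config or scaled_learning_config(seed)
    machine = config.machine()
    seeds = stage_seeds(seed, 3)
    with _Timer("scaled:simulate+preprocess"):
        cohort = simulation.sample_cohort(
            seeds[0], machine, n_patients=config.n_patients,
            n_fractions=config.n_fractions, grid_spec=config.grid(),
            n_segments_range=tuple(config.n_segments_range),
            mu_range=tuple(config.mu_range))
        pairs = preprocessing.build_training_pairs(
            cohort, shape=(config.image_size, config.image_size),
            engine_kwargs=config.engine_kwargs())
    split = cgan.make_loocv_splits(pairs.meta)[0]
    tcfg = cgan.TrainConfig(**{**asdict(config.train), "seed": seeds[1]})
    with _Timer("scaled:train"):
        model = cgan.train(pairs, split, tcfg,
                           log_every=5 if log else 0)
    untrained = cgan.build_model(
        cgan.TrainConfig(**{**asdict(tcfg), "seed": seeds[2]}))
    with _Timer("scaled:evaluate"):
        trained_reports = evaluate_fold(model, pairs, split, cohort,
                                        machine, config)
        untrained_reports = evaluate_fold(untrained, pairs, split, cohort,
                                          machine, config)
    t_mean = float(np.mean([r.gamma.pass_rate
                            for r in trained_reports.values()]))
    u_mean = float(np.mean([r.gamma.pass_rate
                            for r in untrained_reports.values()]))
    return {"trained_gamma_mean": t_mean,
            "untrained_gamma_mean": u_mean,
            "margin_pp": t_mean - u_mean,
            "n_train_beams": int(split.train_idx.size),
            "n_test_beams": int(split.test_idx.size),
            "trained_reports": trained_reports,
            "history": model.history}


def evaluate_fold(model, pairs, split, cohort, machine,
                  config: RunConfig) -> dict:
    """Predict, sequence and evaluate every held-out fraction of a fold's
    patient.  Returns {fraction: PlanReport}."""
    pid = split.held_out_patient
    phantom = cohort.phantoms[pid]
    template = next(p for p in cohort.plans_for(pid)
                    if p.fraction_index == split.retained_fraction)
    meta = pairs.meta
    reports = {}
    test_fractions = sorted(
        meta.iloc[split.test_idx]["fraction"].unique())
    for fx in test_fractions:
        sel = np.flatnonzero((meta["patient"] == pid).to_numpy()
                             & (meta["fraction"] == fx).to_numpy())
        stacks = {}
        for i in sel:
            dm = preprocessing.DoseMap2D(pairs.inputs[i, :, :, 0].astype(float),
                                         scale=float(meta["scale"].iloc[i]))
            stacks[int(meta["beam"].iloc[i])] = cgan.predict(
                model, dm, mu_scale=float(meta["mu_scale"].iloc[i]))
        pred_plan = sequencing.sequence_plan(stacks, template, machine)
        gt_plan = next(p for p in cohort.plans_for(pid)
                       if p.fraction_index == fx)
        reports[int(fx)] = evaluate_predicted_plan(
            pred_plan, gt_plan, phantom, machine,
            criteria=config.gamma_criteria(),
            engine_kwargs=config.engine_kwargs())
    return reports
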