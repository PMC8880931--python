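"""End-to-end experiment orchestration.

``run_pipeline`` executes synth -> preprocess -> pretrain -> embed ->
probe -> compare from a single config (a dict or YAML file), writing
versioned artifacts into one directory. Every stage writes a manifest
entry with the hash of the config slice and the seed that produced it;
re-running an unchanged config reuses completed stages.

This is deliberately desk-scale plumbing: it exists so the whole
mechanism — patient-contrastive pre-training improving small-label
linear probes — can be reproduced with one call.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .architecture import EncoderConfig, load_encoder, save_encoder
from .contrastive import LossConfig
from .errors import PipelineConfigError
from .linear_eval import (compare_models, evaluate_probe, extract_features,
                          fit_probe)
from .preprocess import preprocess_cohort
from .pretrain import TrainConfig, pretrain
from .synthetic import CohortParams, generate_cohort, read_cohort, write_cohort

KNOWN_LABELS = ("sex_like", "hypertrophy_like", "af_active", "age")


@dataclass
class RunConfig:
    out_dir: str
    experiment: str = "demo"
    seed: int = 0
    n_patients: int = 120
    min_visits: int = 2
    max_visits: int = 3
    input_length: int = 256           # resampled desk-scale model input
    encoder: dict = field(default_factory=dict)
    epochs: int = 6
    initial_lr: float = 0.01
    batch_patients: int = 64
    temperature: float = 0.1
    probe_label: str = "sex_like"
    n_probe_train: int = 64
    n_bootstraps: int = 200

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))

    def validate(self) -> None:
        if self.probe_label not in KNOWN_LABELS:
            raise PipelineConfigError(
                f"unknown probe label {self.probe_label!r}; "
                f"choose one of {KNOWN_LABELS}")
        if self.n_patients < 4:
            raise PipelineConfigError("n_patients must be >= 4")
        if self.n_probe_train < 8:
            raise PipelineConfigError("n_probe_train must be >= 8")


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: str):
        self.path = path
        self.entries = {}
        if os.path.exists(path):
            with open(path) as f:
                self.entries = json.load(f)

    def fresh(self, stage: str, config_hash: str, outputs: list) -> bool:
        e = self.entries.get(stage)
        return (e is not None and e["config_hash"] == config_hash
                and all(os.path.exists(p) for p in outputs))

    def record(self, stage: str, config_hash: str, seed: int,
               outputs: list) -> None:
        self.entries[stage] = {"config_hash": config_hash, "seed": seed,
                               "outputs": outputs}
        with open(self.path, "w") as f:
            json.dump(self.entries, f, indent=2)


def _tiny_encoder_config(cfg: RunConfig) -> EncoderConfig:
    base = dict(input_length=cfg.input_length, conv_filter_size=8,
                channels_per_stage=(8, 8, 16), representation_dim=16,
                downsample_per_block=4)
    base.update(cfg.encoder)
    if "channels_per_stage" in base:
        base["channels_per_stage"] = tuple(base["channels_per_stage"])
    return EncoderConfig(**base)


def run_pipeline(config: RunConfig | dict | str) -> str:
    """Run all stages; returns the artifact directory.

    Stage outputs: ``cohort/`` (HDF5 + CSV), ``encoder.npz``,
    ``features.csv``, ``probe.json``, ``comparison.json``,
    ``manifest.json``.
    """
    if isinstance(config, str):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    config.validate()
    out = os.path.join(config.out_dir, config.experiment)
    os.makedirs(out, exist_ok=True)
    manifest = _Manifest(os.path.join(out, "manifest.json"))
    cfg_d = asdict(config)

    # --- synth ------------------------------------------------------------
    cohort_dir = os.path.join(out, "cohort")
    h = _hash({k: cfg_d[k] for k in
               ("seed", "n_patients", "min_visits", "max_visits")})
    if not manifest.fresh("synth", h, [cohort_dir]):
        cohort = generate_cohort(
            config.n_patients, (config.min_visits, config.max_visits),
            seed=config.seed,
            params=CohortParams(min_visits=config.min_visits,
                                max_visits=config.max_visits))
        write_cohort(cohort, cohort_dir)
        manifest.record("synth", h, config.seed, [cohort_dir])
    cohort = read_cohort(cohort_dir)

    # --- preprocess + pretrain --------------------------------------------
    enc_cfg = _tiny_encoder_config(config)
    groups = preprocess_cohort(cohort, resample_to=config.input_length)
    ckpt = os.path.join(out, "encoder.npz")
    h = _hash({k: cfg_d[k] for k in
               ("seed", "n_patients", "min_visits", "max_visits",
                "input_length", "encoder", "epochs", "initial_lr",
                "batch_patients", "temperature")})
    if not manifest.fresh("pretrain", h, [ckpt]):
        result = pretrain(
            groups, encoder_config=enc_cfg,
            loss_config=LossConfig(temperature=config.temperature),
            train_config=TrainConfig(
                epochs=config.epochs, schedule_period=config.epochs,
                initial_lr=config.initial_lr, seed=config.seed,
                batch_patients=config.batch_patients))
        save_encoder(ckpt, result.encoder)
        with open(os.path.join(out, "training_log.jsonl"), "w") as f:
            for row in result.history:
                f.write(json.dumps(row) + "\n")
        manifest.record("pretrain", h, config.seed, [ckpt])
    encoder = load_encoder(ckpt)

    # --- embed -------------------------------------------------------------
    records = [t for g in groups for t in g.records]
    labels_by_rid = {r.record_id: r.labels for r in cohort.all_records()}
    feat_path = os.path.join(out, "features.csv")
    table = extract_features(encoder, records)
    table.to_frame().to_csv(feat_path, index=False)
    manifest.record("embed", h, config.seed, [feat_path])

    # --- probe + compare ---------------------------------------------------
    task = "regression" if config.probe_label == "age" else "classification"
    y = np.array([labels_by_rid[rid][config.probe_label]
                  for rid in table.record_ids])
    rng = np.random.default_rng([config.seed, 31])
    perm = rng.permutation(len(y))
    tr, ho = perm[:config.n_probe_train], perm[config.n_probe_train:]
    if ho.size < 16:
        raise PipelineConfigError(
            "cohort too small for the requested probe training size")

    def _probe_with(enc):
        t = extract_features(enc, records)
        tr_tab = _subset(t, tr).normalized()
        ho_tab = _subset(t, ho).normalized(tr_tab.stats)
        probe = fit_probe(tr_tab, y[tr], task, seed=config.seed)
        return evaluate_probe(probe, ho_tab, y[ho],
                              n_bootstraps=config.n_bootstraps,
                              seed=config.seed)

    from .architecture import build_encoder
    res_pclr = _probe_with(encoder)
    res_rand = _probe_with(build_encoder(enc_cfg, seed=config.seed + 123))
    with open(os.path.join(out, "probe.json"), "w") as f:
        json.dump({"pretrained": _result_dict(res_pclr),
                   "random_encoder": _result_dict(res_rand)}, f, indent=2)
    ranking = compare_models({"pretrained": res_pclr,
                              "random_encoder": res_rand},
                             n_bootstraps=config.n_bootstraps,
                             seed=config.seed)
    with open(os.path.join(out, "comparison.json"), "w") as f:
        json.dump([asdict(r) for r in ranking], f, indent=2)
    manifest.record("probe", h, config.seed,
                    [os.path.join(out, "probe.json")])
    return out


def _subset(table, idx):
    from .linear_eval import FeatureTable
    return FeatureTable(record_ids=[table.record_ids[i] for i in idx],
                        features=table.features[idx])


def _result_dict(r) -> dict:
    return {"task": r.task, "metric": r.metric,
            "point_estimate": r.point_estimate,
            "bootstrap_sd": r.bootstrap_sd,
            "selected_penalty": r.selected_penalty,
            "n_bootstraps": r.n_bootstraps}
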