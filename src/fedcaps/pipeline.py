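"""End-to-end orchestration: phantoms -> preprocessing -> segmentation ->
features -> selection -> federated training with ledger -> evaluation.

One nested config dict (YAML-friendly) drives every stage; a master seed
fans out to per-stage seeds through a documented hash so stages rerun in
isolation reproducibly.  The run manifest records per-stage wall-clock and
SHA-256 digests of every produced file.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import features as feat
from .capsules import ClassifierConfig, build_classifier, deep_features, predict
from .evaluation import confusion, dice_iou, metrics
from .federated import DPConfig, FLConfig, run_simulation
from .hgboa import HGBOAParams, select_features
from .io import export_dataset
from .ledger import Ledger
from .preprocessing import DiffusionParams, anisotropic_diffusion, skull_strip
from .segmentation import segment, train_segmenter
from .synthetic_data import (
    FEDERATED_TYPE_CYCLE,
    PartitionShortage,
    PhantomSpec,
    default_client_profiles,
    derive_seed,
    generate_dataset,
    partition_clients,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "fedcaps-run",
    "data": {
        "n": 120,
        "tumor_fraction": 0.5,
        "height": 64,
        "width": 64,
        "noise_sigma": 0.02,
        "eval_fraction": 0.25,
        "export_png": False,
    },
    "preprocess": {
        "enabled": True,
        "diffusion": {"n_iter": 5, "kappa": 0.1, "lam": 0.2},
    },
    "segmentation": {"enabled": True, "preset": "tiny", "epochs": 3, "lr": 3e-3},
    "features": {"levels": 8, "alpha": 1.0, "beta": 1.0, "backbone_seed": 0},
    "selection": {"enabled": True, "T": 25, "M": 12, "w": 0.9},
    "federated": {
        "n_clients": 5,
        "rounds": 10,
        "local_epochs": 3,
        "lr": 3e-3,
        "dropout_rate": 0.0,
        "noise_rate": 0.0,
        "dp_enabled": False,
    },
}


def _merge(base: Mapping, override: Mapping) -> dict:
    out = copy.deepcopy(dict(base))
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: Mapping | None) -> list[str]:
    """Return a list of violations (empty means the config is acceptable)."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    violations: list[str] = []
    d = cfg["data"]
    if d["n"] <= 0:
        violations.append("data.n: must be positive")
    if not 0.0 <= d["tumor_fraction"] <= 1.0:
        violations.append("data.tumor_fraction: must be in [0, 1]")
    fl = cfg["federated"]
    for key in ("dropout_rate", "noise_rate"):
        if not 0.0 <= fl[key] <= 1.0:
            violations.append(f"federated.{key}: must be in [0, 1]")
    diff = cfg["preprocess"]["diffusion"]
    if not 0.0 < diff["lam"] <= 0.25:
        violations.append("preprocess.diffusion.lam: must be in (0, 0.25]")
    seg = cfg["segmentation"]
    if seg["preset"] not in ("tiny", "paper-like"):
        violations.append("segmentation.preset: unknown preset")
    depth_divisor = 2**3  # tiny preset depth
    if d["height"] % depth_divisor or d["width"] % depth_divisor:
        violations.append(
            "data.height/width: must be divisible by 2^depth of the tiny preset (8)"
        )
    return violations


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Mapping | None = None) -> dict:
    """Execute all enabled stages in order; returns the run manifest."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": cfg, "stages": {}, "files": {}}

    def stage(name: str):
        manifest["stages"][name] = {"t_start": time.time()}
        return time.time()

    def done(name: str, **info):
        rec = manifest["stages"][name]
        rec["wall_clock_s"] = time.time() - rec.pop("t_start")
        rec.update(info)

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    d = cfg["data"]
    spec = PhantomSpec(
        height=d["height"], width=d["width"], noise_sigma=d["noise_sigma"]
    )
    dataset = generate_dataset(
        d["n"], d["tumor_fraction"], spec_template=spec,
        seed=derive_seed(seed, "data"),
        type_cycle=FEDERATED_TYPE_CYCLE,
    )
    rng = np.random.default_rng(derive_seed(seed, "split"))
    order = rng.permutation(len(dataset))
    n_eval = int(round(d["eval_fraction"] * len(dataset)))
    eval_idx = set(order[:n_eval].tolist())
    train_scans = [s for i, s in enumerate(dataset) if i not in eval_idx]
    eval_scans = [s for i, s in enumerate(dataset) if i in eval_idx]
    if d.get("export_png"):
        mpath = export_dataset(dataset, out_dir / "images")
        manifest["files"]["manifest.tsv"] = _digest_file(mpath)
    done("simulate", n_train=len(train_scans), n_eval=len(eval_scans))

    # --- preprocess -------------------------------------------------------
    stage("preprocess")
    if cfg["preprocess"]["enabled"]:
        params = DiffusionParams(**cfg["preprocess"]["diffusion"])
        for s in train_scans + eval_scans:
            s.image = np.clip(anisotropic_diffusion(s.image, params), 0.0, 1.0)
    done("preprocess", enabled=cfg["preprocess"]["enabled"])

    # --- segmentation -----------------------------------------------------
    stage("segmentation")
    seg_model = None
    seg_dice = None
    if cfg["segmentation"]["enabled"]:
        seg_model, _trace = train_segmenter(
            train_scans,
            config=cfg["segmentation"]["preset"],
            epochs=cfg["segmentation"]["epochs"],
            lr=cfg["segmentation"]["lr"],
            seed=derive_seed(seed, "seg"),
        )
        dices = [
            dice_iou(segment(seg_model, s.image)[0], s.tumor_mask)[0]
            for s in eval_scans
            if s.label == "tumor"
        ]
        seg_dice = float(np.mean(dices)) if dices else None
    done("segmentation", heldout_dice=seg_dice)

    # --- features ---------------------------------------------------------
    stage("features")
    backbone = build_classifier(
        ClassifierConfig(mode="image", seed=int(cfg["features"]["backbone_seed"]))
    )

    def featurize(s):
        if seg_model is not None:
            roi, _ = segment(seg_model, s.image)
        else:
            roi = np.zeros_like(s.brain_mask)
        if not roi.any():
            roi = skull_strip(s.image)
        if not roi.any():
            roi = np.ones_like(roi)
        hc = feat.extract_handcrafted(s.image, roi, levels=cfg["features"]["levels"])
        deep = deep_features(backbone, s.image)
        return feat.fuse_features(
            deep, hc, alpha=cfg["features"]["alpha"], beta=cfg["features"]["beta"]
        )

    train_fv = [featurize(s) for s in train_scans]
    eval_fv = [featurize(s) for s in eval_scans]
    names = train_fv[0].names
    X_train = np.stack([f.values for f in train_fv])
    X_eval = np.stack([f.values for f in eval_fv])
    y_train = np.array([1 if s.label == "tumor" else 0 for s in train_scans])
    y_eval = np.array([1 if s.label == "tumor" else 0 for s in eval_scans])
    # standardize on training statistics only
    mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
    sd[sd == 0] = 1.0
    X_train = (X_train - mu) / sd
    X_eval = (X_eval - mu) / sd
    done("features", n_features=len(names))

    # --- selection --------------------------------------------------------
    stage("selection")
    sel = cfg["selection"]
    if sel["enabled"]:
        result = select_features(
            X_train, y_train,
            params=HGBOAParams(T=sel["T"], M=sel["M"], seed=derive_seed(seed, "sel")),
            w=sel["w"],
        )
        mask = result.mask
        sel_info = {
            "frr_percent": result.frr,
            "fitness_score": result.fitness_score,
            "cv_accuracy": result.cv_accuracy,
            "selected": [names[i] for i in np.where(mask)[0]],
        }
    else:
        mask = np.ones(X_train.shape[1], dtype=bool)
        sel_info = {"bypassed": True, "frr_percent": 0.0}
    Xs_train, Xs_eval = X_train[:, mask], X_eval[:, mask]
    done("selection", **sel_info)

    # --- federated --------------------------------------------------------
    stage("federated")
    flc = cfg["federated"]
    # shrink the per-client quota until the heterogeneous mix is feasible
    # for the realized tumor-type composition of the training pool
    parts = None
    for total in range(len(train_scans), 0, -5):
        profiles = default_client_profiles(total_ct=total)[: flc["n_clients"]]
        try:
            parts = partition_clients(
                train_scans, profiles, seed=derive_seed(seed, "part"),
                tumor_fraction_per_client=d["tumor_fraction"],
            )
            break
        except PartitionShortage:
            continue
    if parts is None:
        raise PartitionShortage({"all": len(train_scans)})
    sid_pos = {s.scan_id: i for i, s in enumerate(train_scans)}
    client_data = {}
    for cid, scans in parts.items():
        # the partition re-wraps scans, so match rows by scan_id
        idx = [sid_pos[s.scan_id] for s in scans if s.scan_id in sid_pos]
        client_data[cid] = (Xs_train[idx], y_train[idx])
    clf_config = ClassifierConfig(
        mode="features", in_dim=int(mask.sum()), seed=derive_seed(seed, "clf")
    )
    fl_config = FLConfig(
        n_clients=flc["n_clients"], rounds=flc["rounds"],
        local_epochs=flc["local_epochs"], lr=flc["lr"],
        dropout_rate=flc["dropout_rate"], noise_rate=flc["noise_rate"],
        dp=DPConfig(enabled=flc["dp_enabled"]),
        seed=derive_seed(seed, "fl"),
    )
    ledger = Ledger()
    history, global_w, ledger = run_simulation(
        fl_config, client_data,
        model_factory=lambda: build_classifier(clf_config),
        eval_set=(Xs_eval, y_eval), ledger=ledger,
    )
    ledger_path = out_dir / "ledger.jsonl"
    ledger_path.write_text(ledger.to_jsonl() + "\n")
    manifest["files"]["ledger.jsonl"] = _digest_file(ledger_path)
    hist_path = out_dir / "rounds.jsonl"
    hist_path.write_text(
        "\n".join(
            json.dumps(
                {
                    "round": r.round,
                    "participants": r.participants,
                    "dropped": r.dropped,
                    "poisoned": r.poisoned,
                    "global_digest": r.global_digest,
                    "eval_metrics": r.eval_metrics,
                }
            )
            for r in history
        )
        + "\n"
    )
    manifest["files"]["rounds.jsonl"] = _digest_file(hist_path)
    done("federated", final_accuracy=history[-1].eval_metrics.get("accuracy"))

    # --- evaluate ---------------------------------------------------------
    stage("evaluate")
    model = build_classifier(clf_config)
    model.set_flat(global_w)
    labels, _conf = predict(model, Xs_eval)
    counts = confusion(labels.tolist(), y_eval.tolist(), positive=1)
    final_metrics = metrics(counts)
    done("evaluate", **{k: v for k, v in final_metrics.items()})
    manifest["metrics"] = final_metrics

    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
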