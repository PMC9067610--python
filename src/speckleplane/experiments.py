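"""Experiment orchestration: the full condition matrix from one spec.

Each experiment pairs two arms that differ ONLY in the image-plane distance
d — "object" (the SLM plane is conjugate to the camera) versus "diffuser"
(the D2 surface is conjugate) — with identical digit objects and identical
frozen diffuser screens, so the image plane is the only varying factor.
Per seed: generate the paired datasets, train one reconstruction network
per arm, evaluate SSIM/ACC/PCC on the held-out test split, and write
curves, per-image tables, aggregates and a manifest.

Conditions:
  one_diffuser           strong diffuser behind the object, nothing in front
  between_two_diffusers  weak diffuser before the object, strong behind
  swapped_diffusers      strong before, weak behind
  two_front_diffusers    two diffusers between object and collecting lens
  plane_sweep            no training; PCC(truth, speckle) versus d
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffusers import DiffuserSpec
from .metrics import (
    MetricsReport,
    pcc_sweep,
    summarize,
    train_digit_classifier,
)
from .objects import generate_digits, to_slm_pattern
from .reconstructor import (
    ErrorCurves,
    TrainConfig,
    build_unet,
    convergence_epoch,
    desk_unet_config,
    reconstruct_batch,
    train,
)
from .system import (
    desk_config,
    generate_dataset,
    paper_config,
    truth_on_camera,
)

__all__ = [
    "ExperimentSpec",
    "ArmResult",
    "ExperimentResult",
    "run",
    "compare",
    "arm_distance",
    "diffusers_for_condition",
]

CONDITIONS = (
    "one_diffuser",
    "between_two_diffusers",
    "swapped_diffusers",
    "two_front_diffusers",
    "plane_sweep",
)

# Desk-scale nominal diffusion angles (far-field marginal FWHM, degrees)
WEAK_ANGLE = 1.0
STRONG_ANGLE = 4.0


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    condition: str
    preset: str = "desk"
    image_plane: str = "both"  # "object" | "diffuser" | "both"
    n_objects: int = 180
    seeds: tuple = (0, 1, 2)
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    early_stop_patience: int | None = 8
    d_values_mm: tuple | None = None  # plane_sweep only
    sweep_n_objects: int = 20
    recon_side: int = 32

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition != "plane_sweep" and self.image_plane not in (
            "object",
            "diffuser",
            "both",
        ):
            raise ValueError("image_plane must be object, diffuser or both")
        if not self.seeds:
            raise ValueError("seeds must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("seeds", "d_values_mm"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class ArmResult:
    seed: int
    arm: str  # "object" | "diffuser"
    report: MetricsReport
    curves: ErrorCurves

    @property
    def min_val_loss(self) -> float:
        return self.curves.min_val

    @property
    def convergence(self) -> int:
        return convergence_epoch(self.curves)


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    arms: list[ArmResult] = field(default_factory=list)
    sweep: pd.DataFrame | None = None

    def arm(self, seed: int, arm: str) -> ArmResult:
        for a in self.arms:
            if a.seed == seed and a.arm == arm:
                return a
        raise KeyError((seed, arm))


def _base_config(preset: str, d: float | None = None):
    if preset == "desk":
        return desk_config() if d is None else desk_config(d=d)
    if preset == "paper":
        return paper_config() if d is None else paper_config(d=d)
    raise ValueError(f"unknown preset {preset!r}")


def diffusers_for_condition(condition: str, seed: int):
    """Frozen diffuser specs for one experiment seed.  Returns a dict with
    keys d1, d2, d_mid (DiffuserSpec or None)."""
    weak = DiffuserSpec(WEAK_ANGLE, seed=seed + 101, name="weak")
    strong = DiffuserSpec(STRONG_ANGLE, seed=seed + 11, name="strong")
    if condition == "one_diffuser":
        return {"d1": None, "d2": strong, "d_mid": None}
    if condition == "between_two_diffusers":
        return {"d1": weak, "d2": strong, "d_mid": None}
    if condition == "swapped_diffusers":
        return {"d1": strong, "d2": weak, "d_mid": None}
    if condition == "two_front_diffusers":
        return {"d1": None, "d2": strong, "d_mid": weak}
    raise ValueError(condition)


def arm_distance(cfg, arm: str) -> float:
    if arm == "object":
        return cfg.d_object_conjugate
    if arm == "diffuser":
        return cfg.d_diffuser_conjugate
    raise ValueError(arm)


def _camera_frame_renderer(cfg):
    def render(obj):
        return truth_on_camera(to_slm_pattern(obj, cfg.slm_active, cfg.grid), cfg).astype(
            np.float64
        )

    return render


def _manifest(spec: ExperimentSpec, cfg) -> dict:
    digest = hashlib.sha256(cfg.digest_fields().encode()).hexdigest()[:16]
    return {
        "package_version": __version__,
        "spec": asdict(spec),
        "config_digest_excluding_d": digest,
        "seeds": list(spec.seeds),
    }


def run(spec: ExperimentSpec, outdir, classifier=None, log=print) -> ExperimentResult:
    """Execute an experiment spec; write reports under ``outdir/spec.name``.

    Paired arms share objects and diffuser screens; only d differs (checked
    via a config digest over all other fields).  Any failing seed is logged
    and skipped; remaining seeds continue.
    """
    out = Path(outdir) / spec.name
    out.mkdir(parents=True, exist_ok=True)
    cfg = _base_config(spec.preset)
    (out / "manifest.json").write_text(json.dumps(_manifest(spec, cfg), indent=2))
    result = ExperimentResult(spec=spec)

    if spec.condition == "plane_sweep":
        d_mm = spec.d_values_mm or (3.6, 4.8, 6.0, 7.2, 8.4)
        objs = generate_digits(spec.sweep_n_objects, size=48, seed=997)
        strong = DiffuserSpec(STRONG_ANGLE, seed=0, name="strong")
        table = pcc_sweep(
            objs, cfg, [d * 1e-3 for d in d_mm], d2=strong, seeds=spec.seeds
        )
        table.to_csv(out / "pcc_sweep.csv", index=False, float_format="%.17g")
        _plot_sweep(table, cfg, out / "pcc_sweep.png")
        result.sweep = table
        return result

    arms = ["object", "diffuser"] if spec.image_plane == "both" else [spec.image_plane]
    if classifier is None:
        clf_objs = generate_digits(480, size=48, seed=7001)
        classifier = train_digit_classifier(
            clf_objs, seed=7, side=spec.recon_side, renderer=_camera_frame_renderer(cfg)
        )
    (out / "classifier.json").write_text(
        json.dumps(
            {
                "holdout_accuracy": classifier.holdout_accuracy,
                "train_accuracy": classifier.train_accuracy,
            }
        )
    )

    for seed in spec.seeds:
        try:
            objs = generate_digits(spec.n_objects, size=48, seed=1000 + seed)
            diff = diffusers_for_condition(spec.condition, seed)
            digests = set()
            for arm in arms:
                acfg = cfg.with_d(arm_distance(cfg, arm))
                digests.add(acfg.digest_fields())
                pairs = generate_dataset(
                    objs,
                    acfg,
                    d1=diff["d1"],
                    d2=diff["d2"],
                    d_mid=diff["d_mid"],
                    master_seed=seed,
                )
                tcfg = TrainConfig(
                    epochs=spec.epochs,
                    batch_size=spec.batch_size,
                    learning_rate=spec.learning_rate,
                    seed=seed,
                    early_stop_patience=spec.early_stop_patience,
                )
                model = build_unet(desk_unet_config(spec.recon_side), seed=seed)
                model, curves = train(model, pairs, tcfg)
                test = [p for p in pairs if p.condition["split"] == "test"]
                recons = reconstruct_batch(model, np.stack([p.speckle for p in test]))
                report = summarize(
                    list(recons),
                    [p.target.astype(np.float64) for p in test],
                    [p.truth.label for p in test],
                    classifier,
                    condition={
                        "arm": arm,
                        "seed": seed,
                        "condition": spec.condition,
                        "d_mm": acfg.d * 1e3,
                    },
                )
                adir = out / f"seed{seed}" / arm
                adir.mkdir(parents=True, exist_ok=True)
                curves.to_csv(adir / "curves.csv")
                report.to_csv(adir / "per_image.csv")
                agg = report.to_json_dict()
                agg["min_val_npcc"] = curves.min_val
                agg["convergence_epoch"] = convergence_epoch(curves)
                (adir / "aggregate.json").write_text(json.dumps(agg, indent=2))
                result.arms.append(
                    ArmResult(seed=seed, arm=arm, report=report, curves=curves)
                )
            assert len(digests) == 1, "paired arms differ in more than d"
        except Exception as exc:  # keep remaining seeds alive
            log(f"[{spec.name}] seed {seed} failed: {exc!r}")
            continue

    if spec.image_plane == "both" and result.arms:
        table = compare(
            [a for a in result.arms if a.arm == "object"],
            [a for a in result.arms if a.arm == "diffuser"],
        )
        table.to_csv(out / "comparison.csv", index=False, float_format="%.17g")
    return result


def compare(arms_a: list[ArmResult], arms_b: list[ArmResult]) -> pd.DataFrame:
    """Side-by-side per-seed comparison of two paired condition arms."""
    if {a.seed for a in arms_a} != {b.seed for b in arms_b}:
        raise ValueError("mismatched seeds between compared arms")
    amap = {a.seed: a for a in arms_a}
    bmap = {b.seed: b for b in arms_b}
    rows = []
    for seed in sorted(amap):
        a, b = amap[seed], bmap[seed]
        rows.append(
            {
                "seed": seed,
                "arm_a": a.arm,
                "arm_b": b.arm,
                "ssim_a": a.report.mean_ssim,
                "ssim_b": b.report.mean_ssim,
                "delta_ssim": b.report.mean_ssim - a.report.mean_ssim,
                "acc_a": a.report.acc,
                "acc_b": b.report.acc,
                "delta_acc": b.report.acc - a.report.acc,
                "min_val_npcc_a": a.min_val_loss,
                "min_val_npcc_b": b.min_val_loss,
                "convergence_a": a.convergence,
                "convergence_b": b.convergence,
            }
        )
    return pd.DataFrame(rows)


def _plot_sweep(table: pd.DataFrame, cfg, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for seed, grp in table.groupby("seed"):
        ax.errorbar(grp["d_mm"], grp["mean_pcc"], yerr=grp["sd_pcc"], label=f"seed {seed}")
    ax.axvline(cfg.d_object_conjugate * 1e3, ls=":", c="gray", label="object plane")
    ax.axvline(cfg.d_diffuser_conjugate * 1e3, ls="--", c="k", label="diffuser plane")
    ax.set_xlabel("d (mm)")
    ax.set_ylabel("PCC(truth, speckle)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
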