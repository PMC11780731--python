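"""Experiment orchestration, MD-stability classification and reporting.

``run_experiment`` ties the pipeline together: generate labelled synthetic
conformers, train the toy potential (keeping checkpoints, including the
untrained initialisation), extract walk relevances on held-out conformers at
every checkpoint, and write interaction-range, pair-strength, many-bodyness,
decay-fit and element-matrix tables plus a machine-readable run manifest.
Tracking the interaction range across checkpoints supports trained-versus-
untrained comparisons.

``classify_stability`` implements the trajectory stability criterion used for
molecular-dynamics screening: a trajectory is unstable as soon as its
potential energy leaves a fixed window (default −200..200 kcal/mol, the
typical signature of an atom dissociating).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conformer import write_extxyz
from .lrp import RuleConfig, walk_relevances
from .metrics import (
    decay_fit,
    element_pair_matrix,
    many_bodyness,
    pair_interaction_strength,
    summarize_ranges,
    walk_importance,
)
from .model import MessagePassingPotential, ModelConfig, save_checkpoint
from .synthetic import (
    GeneratorSpec,
    PairPotentialParams,
    ThreeBodyParams,
    generate_conformers,
    label_conformers,
)

__all__ = [
    "StabilityVerdict",
    "classify_stability",
    "ExperimentConfig",
    "ladder_configs",
    "run_experiment",
    "ExperimentError",
]

DEFAULT_STABILITY_BOUNDS = (-200.0, 200.0)  # kcal/mol


class ExperimentError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class StabilityVerdict:
    label: str  # "stable" | "unstable"
    first_violation_index: int | None
    bounds: tuple[float, float]
    non_finite: bool = False

    @property
    def stable(self) -> bool:
        return self.label == "stable"


def classify_stability(
    energies, bounds: tuple[float, float] = DEFAULT_STABILITY_BOUNDS
) -> StabilityVerdict:
    """Classify a potential-energy series (kcal/mol) as stable or unstable.

    Unstable iff any sample falls outside ``bounds`` (or is non-finite); the
    index of the first violation is reported.
    """
    e = np.asarray(energies, dtype=float)
    if e.ndim != 1 or len(e) == 0:
        raise ValueError("energy series must be a nonempty 1-D array")
    lower, upper = bounds
    bad = ~np.isfinite(e) | (e < lower) | (e > upper)
    if bad.any():
        first = int(np.argmax(bad))
        return StabilityVerdict(
            label="unstable",
            first_violation_index=first,
            bounds=(float(lower), float(upper)),
            non_finite=bool(~np.isfinite(e[first])),
        )
    return StabilityVerdict(
        label="stable", first_violation_index=None, bounds=(float(lower), float(upper))
    )


def ladder_configs(
    depths, product: float = 15.0, base: ModelConfig | None = None
) -> list[ModelConfig]:
    """Depth ladder with constant depth·cutoff product (default 15 Å).

    Each depth L gets cutoff = product / L and the default n_rbf coupling
    (round(4·cutoff)), so the radial-basis spacing is identical across the
    ladder.
    """
    if product <= 0:
        raise ValueError("ladder product must be > 0")
    base = base or ModelConfig()
    out = []
    for L in depths:
        d = base.to_dict()
        d.update(depth=int(L), cutoff=product / L, n_rbf=None)
        out.append(ModelConfig.from_dict(d))
    return out


@dataclass
class ExperimentConfig:
    """Everything one reproducible run needs."""

    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    pair_potential: PairPotentialParams = field(default_factory=PairPotentialParams)
    three_body: ThreeBodyParams | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    epochs: int = 200
    lr: float = 5e-3
    checkpoint_epochs: tuple[int, ...] = (0,)
    n_explain: int = 10  # held-out conformers explained per checkpoint
    p_min: float = 0.001
    a: float = 4.0
    bin_width: float = 0.5
    min_count: int = 20
    split_distance: float = 1.6
    epsilon: float = 1e-6
    seed: int = 0
    outdir: str = "walklrp_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        d["model"] = self.model.to_dict()
        d["three_body"] = None if self.three_body is None else asdict(self.three_body)
        d["checkpoint_epochs"] = list(self.checkpoint_epochs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorSpec.from_dict(d["generator"])
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        if "pair_potential" in d and isinstance(d["pair_potential"], dict):
            pp = dict(d["pair_potential"])
            pp["overrides"] = {
                tuple(k.split("-")): tuple(v) for k, v in pp.get("overrides", {}).items()
            }
            d["pair_potential"] = PairPotentialParams(**pp)
        if d.get("three_body"):
            d["three_body"] = ThreeBodyParams(**d["three_body"])
        if "checkpoint_epochs" in d:
            d["checkpoint_epochs"] = tuple(d["checkpoint_epochs"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["pair_potential"]["overrides"] = {
            "-".join(k): list(v) for k, v in self.pair_potential.overrides.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full pipeline and persist every table under ``config.outdir``.

    Returns a dict with the in-memory results (estimator, per-checkpoint range
    summaries, final metric objects).  Any stage failure raises
    :class:`ExperimentError` naming the stage; outputs written before the
    failure stay on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        conformers = generate_conformers(config.generator)
        label_conformers(conformers, config.pair_potential, config.three_body)
        write_extxyz(outdir / "dataset.xyz", conformers)

        stage = "split"
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(len(conformers))
        n_explain = min(config.n_explain, max(1, len(conformers) // 5))
        explain_set = [conformers[i] for i in perm[:n_explain]]
        train_set = [conformers[i] for i in perm[n_explain:]]
        if not train_set:
            raise ValueError("no conformers left for training")

        stage = "train"
        ckpt_epochs = tuple(sorted(set(config.checkpoint_epochs) | {0}))
        est = MessagePassingPotential(
            depth=config.model.depth,
            cutoff=config.model.cutoff,
            n_rbf=config.model.n_rbf,
            embedding_dim=config.model.embedding_dim,
            filter_hidden=config.model.filter_hidden,
            readout_hidden=config.model.readout_hidden,
            elements=config.model.elements,
            activation=config.model.activation,
            cosine_cutoff_enabled=config.model.cosine_cutoff_enabled,
            epochs=config.epochs,
            lr=config.lr,
            seed=config.seed,
            checkpoint_epochs=ckpt_epochs,
        ).fit(train_set, [c.energy for c in train_set])
        est.history_.to_csv(outdir / "training_history.csv", index=False)
        save_checkpoint(outdir / "model.json", est.params_, est.config_)

        stage = "explain"
        rule = RuleConfig(epsilon=config.epsilon)
        range_rows = []
        per_epoch_maps = {}
        for epoch in sorted(est.checkpoints_):
            params = est.checkpoints_[epoch]
            maps = [
                walk_relevances(params, est.config_, c, rule) for c in explain_set
            ]
            per_epoch_maps[epoch] = maps
            summ = summarize_ranges(
                [walk_importance(m) for m in maps], p_min=config.p_min, a=config.a
            )
            t = summ.table.copy()
            t.insert(0, "checkpoint_epoch", epoch)
            range_rows.append(t)
        range_table = pd.concat(range_rows, ignore_index=True)
        range_table.to_csv(outdir / "interaction_range.csv", index=False)

        stage = "metrics"
        final_epoch = max(est.checkpoints_)
        final_maps = per_epoch_maps[final_epoch]
        strength_tables = [
            pair_interaction_strength(m, mode="inclusive") for m in final_maps
        ]
        strengths = pd.concat(strength_tables, ignore_index=True)
        strengths.to_csv(outdir / "pair_strengths.csv", index=False)

        mats = element_pair_matrix(strengths, split=config.split_distance)
        mats.bonded.to_csv(outdir / "element_matrix_bonded.csv")
        mats.nonbonded.to_csv(outdir / "element_matrix_nonbonded.csv")

        results: dict = dict(
            estimator=est,
            range_table=range_table,
            strengths=strengths,
            element_matrices=mats,
            per_epoch_maps=per_epoch_maps,
        )
        try:
            profile = many_bodyness(
                strengths, bin_width=config.bin_width, min_count=config.min_count
            )
            profile.table.to_csv(outdir / "many_bodyness.csv", index=False)
            results["many_bodyness"] = profile
        except ValueError:
            results["many_bodyness"] = None
        try:
            fit = decay_fit(strengths, bin_width=config.bin_width)
            results["decay_fit"] = fit
            (outdir / "decay_fit.json").write_text(
                json.dumps(
                    {
                        k: getattr(fit, k)
                        for k in (
                            "exp_rate",
                            "exp_prefactor",
                            "exp_residual",
                            "pow_exponent",
                            "pow_prefactor",
                            "pow_residual",
                            "preferred",
                            "degenerate",
                        )
                    },
                    indent=1,
                )
            )
        except ValueError:
            results["decay_fit"] = None

        stage = "manifest"
        manifest = dict(
            config=config.to_dict(),
            config_hash=config.config_hash(),
            seed=config.seed,
            walklrp_version=__version__,
            numpy_version=np.__version__,
            n_train=len(train_set),
            n_explain=len(explain_set),
            checkpoints=sorted(est.checkpoints_),
            final_val_rmse=(
                float(est.history_["val_rmse"].iloc[-1]) if len(est.history_) else None
            ),
        )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return results
    except ExperimentError:
        raise
    except Exception as exc:
        raise ExperimentError(f"stage {stage!r} failed: {exc}") from exc
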