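"""Configuration-driven orchestration: clean → pretrain → finetune → explain → report.

Each stage writes its artifacts plus a manifest (config digest, input
digests, seed, package version) under the experiment's output directory,
so deterministic stages are reproducible byte for byte.  The shipped demo
is fully synthetic: a seeded corpus with a planted nitro structural alert,
a tiny trained classifier and a randomly initialised control, all eight
attribution methods, and the robustness report comparing them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis_stats import bootstrap_metrics, carbon_dependence
from .chem_data import (
    AlertSet,
    MoleculeRecord,
    NITRO_ALERT_SMARTS,
    clean_structures,
    generate_synthetic_molecules,
    match_alerts,
    read_molecule_table,
    scaffold_split,
    random_split,
    tokenize,
    write_records_csv,
)
from .transformer_models import (
    ModelConfig,
    Seq2SeqModel,
    build_model,
    load_checkpoint,
    pretrain,
    randomize_model,
    save_checkpoint,
    transfer_learn,
)
from .tta_robustness import (
    attribute_augmented_multi,
    attribution_entropy,
    cross_group_distances,
    pairwise_cosine_matrix,
    relative_importance,
    tta_average,
    AlignedAtomAttribution,
)
from .xai_methods import METHODS, compute_attribution, normalize_attribution

logger = logging.getLogger(__name__)

STAGES = ("clean", "pretrain", "finetune", "explain", "report")


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, serialisable to YAML."""

    output_dir: str = "results/demo"
    seed: int = 0
    # data
    data_csv: str | None = None  # None -> synthetic corpus
    n_synthetic: int = 500
    planted_alert: str = NITRO_ALERT_SMARTS
    label_noise: float = 0.1
    alerts: list[list[str]] = field(
        default_factory=lambda: [["nitro", NITRO_ALERT_SMARTS]]
    )
    # model
    model: dict = field(
        default_factory=lambda: dict(
            max_len=100, embed_dim=64, heads=4, layers=2, ff_mult=2
        )
    )
    architecture: str = "encoder_only"
    head_type: str = "maxpool_mlp"
    # training
    do_pretrain: bool = False
    regimen: str = "ME2C"
    pretrain_epochs: int = 10
    finetune_epochs: int = 40
    finetune_lr: float = 1e-3  # head-only training on a tiny corpus
    split: str = "scaffold"
    freeze: bool = True
    # explanation
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    n_explain: int = 50
    n_augment: int = 10
    ig_steps: int = 64
    shap_budget: int = 8
    class_index: int | None = None  # None -> predicted class
    rollout_literal: bool = False
    signed_importance: bool = False
    include_random_control: bool = True
    bootstrap_reps: int = 1000

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            head_type=self.head_type, architecture="encoder_only", **self.model
        )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        self.model_config()
        if self.split not in ("scaffold", "random"):
            raise ValueError(f"unknown split {self.split!r}")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")
        if self.n_augment < 1:
            raise ValueError("n_augment must be >= 1")
        AlertSet(entries=tuple((n, s) for n, s in self.alerts))


def make_demo_config(seed: int, output_dir: str = "results/demo") -> ExperimentConfig:
    """The shipped desk-scale demo: 500 synthetic molecules with one
    planted alert, an L=2 / E=64 encoder, all eight attribution methods on
    50 test molecules, and a randomized-model control."""
    cfg = ExperimentConfig(seed=seed, output_dir=output_dir, n_augment=3)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# manifests


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, stage: str, config: ExperimentConfig,
                    inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "inputs": {p.name: _file_digest(p) for p in inputs if p.exists()},
        "outputs": {p.name: _file_digest(p) for p in outputs if p.exists()},
    }
    path = out / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


class MissingStageError(RuntimeError):
    """An upstream artifact is missing; message names the stage to run."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"missing artifact {path.name}: run stage '{stage}' first"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def run_stage(config: ExperimentConfig, stage: str) -> dict:
    """Run one pipeline stage; returns a small summary dict."""
    config.validate()
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "clean": _stage_clean,
        "pretrain": _stage_pretrain,
        "finetune": _stage_finetune,
        "explain": _stage_explain,
        "report": _stage_report,
    }[stage](config, out)


def _stage_clean(config: ExperimentConfig, out: Path) -> dict:
    if config.data_csv is not None:
        smiles, labels, ids = read_molecule_table(config.data_csv)
        result = clean_structures(smiles, labels, ids, source=config.data_csv)
        records = result.records
        n_failed = len(result.failures)
    else:
        records = generate_synthetic_molecules(
            config.n_synthetic,
            seed=config.seed,
            planted_alert=config.planted_alert,
            noise=config.label_noise,
        )
        n_failed = 0
    cleaned = out / "cleaned.csv"
    write_records_csv(records, cleaned)
    _write_manifest(out, "clean", config, [], [cleaned])
    return {"records": len(records), "failures": n_failed, "path": str(cleaned)}


def _load_records(out: Path) -> list[MoleculeRecord]:
    smiles, labels, ids = read_molecule_table(_require(out / "cleaned.csv", "clean"))
    return [
        MoleculeRecord(id=i, smiles_canonical=s, label=l, source="cleaned")
        for s, l, i in zip(smiles, labels, ids)
    ]


def _stage_pretrain(config: ExperimentConfig, out: Path) -> dict:
    records = _load_records(out)
    mc = config.model_config()
    mc.architecture = config.architecture
    model = Seq2SeqModel(mc, seed=config.seed)
    model, history = pretrain(
        model, records, config.regimen,
        seed=config.seed, epochs=config.pretrain_epochs,
    )
    save_checkpoint(model, out / "pretrained")
    history.to_jsonl(out / "pretrain_history.jsonl")
    _write_manifest(out, "pretrain", config, [out / "cleaned.csv"],
                    [out / "pretrained.npz", out / "pretrain_history.jsonl"])
    return {"epochs": len(history.epochs), "final": history.epochs[-1]}


def _stage_finetune(config: ExperimentConfig, out: Path) -> dict:
    records = _load_records(out)
    mc = config.model_config()
    model = build_model(mc, seed=config.seed)
    if config.do_pretrain:
        _require(out / "pretrained.npz", "pretrain")
        pretrained = load_checkpoint(out / "pretrained")
        model.encoder = pretrained.encoder
    model, metrics = transfer_learn(
        model, records, freeze=config.freeze, split=config.split,
        seed=config.seed, epochs=config.finetune_epochs, lr=config.finetune_lr,
    )
    save_checkpoint(model, out / "model")
    outputs = [out / "model.npz"]
    if config.include_random_control:
        control = randomize_model(mc, seed=config.seed + 1)
        save_checkpoint(control, out / "control")
        outputs.append(out / "control.npz")
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    _write_manifest(out, "finetune", config, [out / "cleaned.csv"],
                    outputs + [out / "metrics.json"])
    return metrics


def _test_molecules(config: ExperimentConfig, records) -> list[MoleculeRecord]:
    splitter = scaffold_split if config.split == "scaffold" else random_split
    _, _, test = splitter(records, seed=config.seed)
    return test[: config.n_explain]


def _stage_explain(config: ExperimentConfig, out: Path) -> dict:
    records = _load_records(out)
    molecules = _test_molecules(config, records)
    _require(out / "model.npz", "finetune")
    models = {"trained": load_checkpoint(out / "model")}
    if config.include_random_control:
        _require(out / "control.npz", "finetune")
        models["random"] = load_checkpoint(out / "control")
    rows = []
    for model_name, model in models.items():
        for mol_idx, mol in enumerate(molecules):
            per_method = attribute_augmented_multi(
                model, config.methods, mol,
                n_augment=config.n_augment,
                seed=config.seed + 7919 * mol_idx,
                class_index=config.class_index,
                rollout_literal=config.rollout_literal,
                ig_steps=config.ig_steps,
                shap_budget=config.shap_budget,
            )
            for method, atts in per_method.items():
                for variant_idx, att in enumerate(atts):
                    for rank, value in enumerate(att.values):
                        rows.append(
                            (model_name, method, mol.id, variant_idx,
                             att.source_smiles, rank, value,
                             att.normalization_base)
                        )
    frame = pd.DataFrame(
        rows,
        columns=["model", "method", "molecule_id", "variant", "source_smiles",
                 "atom_rank", "value", "normalization_base"],
    )
    path = out / "attributions.csv"
    frame.to_csv(path, index=False)
    _write_manifest(out, "explain", config,
                    [out / "cleaned.csv", out / "model.npz"], [path])
    return {"rows": len(frame), "molecules": len(molecules),
            "models": list(models), "path": str(path)}


def _aligned_from_frame(group: pd.DataFrame) -> AlignedAtomAttribution:
    group = group.sort_values("atom_rank")
    return AlignedAtomAttribution(
        molecule_id=group["molecule_id"].iloc[0],
        source_smiles=group["source_smiles"].iloc[0],
        values=group["value"].to_numpy(),
        normalization_base=float(group["normalization_base"].iloc[0]),
    )


def _stage_report(config: ExperimentConfig, out: Path) -> dict:
    frame = pd.read_csv(_require(out / "attributions.csv", "explain"))
    records = _load_records(out)
    smiles_of = {r.id: r.smiles_canonical for r in records}
    alert_set = AlertSet(entries=tuple((n, s) for n, s in config.alerts))

    # in-between sample robustness: mean pairwise cosine distance across
    # the canonical + augmented strings of each molecule
    sample_rows = []
    aligned_store: dict[tuple, dict[str, AlignedAtomAttribution]] = {}
    averaged_store: dict[tuple, dict[str, AlignedAtomAttribution]] = {}
    for (model_name, method, mol_id), sub in frame.groupby(
        ["model", "method", "molecule_id"]
    ):
        atts = [
            _aligned_from_frame(v) for _, v in sub.groupby("variant", sort=True)
        ]
        try:
            _, score = pairwise_cosine_matrix(atts)
        except ValueError:
            continue
        sample_rows.append(
            {"model": model_name, "method": method, "molecule_id": mol_id,
             "robustness_score": score}
        )
        aligned_store.setdefault((model_name, method), {})[mol_id] = atts[0]
        averaged_store.setdefault((model_name, method), {})[mol_id] = tta_average(atts)
    sample_frame = pd.DataFrame(sample_rows)
    sample_frame.to_csv(out / "in_between_sample.csv", index=False)

    # in-between method distances, canonical vs TTA-averaged
    def method_distance(store) -> tuple[pd.DataFrame, float]:
        frames = []
        for model_name in frame["model"].unique():
            groups = {
                method: store[(model_name, method)]
                for method in config.methods
                if (model_name, method) in store
            }
            report = cross_group_distances(groups, axis="method")
            tidy = report.distances
            tidy["model"] = model_name
            frames.append(tidy)
        all_d = pd.concat(frames, ignore_index=True)
        return all_d, float(all_d["distance"].mean())

    canon_d, canon_mean = method_distance(aligned_store)
    avg_d, avg_mean = method_distance(averaged_store)
    canon_d.to_csv(out / "in_between_method_canonical.csv", index=False)
    avg_d.to_csv(out / "in_between_method_averaged.csv", index=False)

    # entropy and alert importance on canonical strings
    entropy_rows = []
    alert_rows = []
    for (model_name, method), per_mol in aligned_store.items():
        for mol_id, att in per_mol.items():
            entropy_rows.append(
                {"model": model_name, "method": method, "molecule_id": mol_id,
                 "entropy_bits": attribution_entropy(att.values)}
            )
            smiles = smiles_of[mol_id]
            matched = match_alerts(smiles, alert_set)
            seq = tokenize(smiles)
            # aligned values are already normalised w.r.t. the full string:
            # alert importance is the |value| mass on matched atoms
            ranks_of_alert = set()
            from .chem_data import canonical_atom_ranks as _ranks
            ranks = _ranks(smiles)
            for atom in matched.atom_union:
                ranks_of_alert.add(ranks[atom])
            mass = sum(
                abs(v) for r, v in enumerate(att.values) if r in ranks_of_alert
            )
            alert_rows.append(
                {"model": model_name, "method": method, "molecule_id": mol_id,
                 "alert_importance": mass, "has_alert": bool(matched.matches)}
            )
    pd.DataFrame(entropy_rows).to_csv(out / "entropy.csv", index=False)
    pd.DataFrame(alert_rows).to_csv(out / "alert_importance.csv", index=False)

    # carbon dependence of the trained model's IG in-between-sample scores
    probe_method = "IG" if "IG" in config.methods else config.methods[0]
    probe = sample_frame[
        (sample_frame["model"] == "trained")
        & (sample_frame["method"] == probe_method)
    ]
    carbon = carbon_dependence(
        dict(zip(probe["molecule_id"], probe["robustness_score"])),
        smiles_of,
    )

    summary = {
        "in_between_sample_mean": {
            f"{m}/{meth}": float(g["robustness_score"].mean())
            for (m, meth), g in sample_frame.groupby(["model", "method"])
        },
        "in_between_method_mean_canonical": canon_mean,
        "in_between_method_mean_averaged": avg_mean,
        "tta_averaging_reduces_method_distance": bool(avg_mean < canon_mean),
        "entropy_mean_bits": {
            f"{m}/{meth}": float(g["entropy_bits"].mean())
            for (m, meth), g in pd.DataFrame(entropy_rows).groupby(["model", "method"])
        },
        "alert_importance_mean": {
            f"{m}/{meth}": float(g["alert_importance"].mean())
            for (m, meth), g in pd.DataFrame(alert_rows).groupby(["model", "method"])
        },
        "carbon_spearman_rho": carbon["spearman_rho"],
    }
    (out / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    _write_manifest(out, "report", config, [out / "attributions.csv"],
                    [out / "report.json"])
    return summary


def run_demo(seed: int, output_dir: str = "results/demo") -> dict:
    """End-to-end synthetic demo; returns the report summary + metrics."""
    config = make_demo_config(seed, output_dir=output_dir)
    clean_info = run_stage(config, "clean")
    metrics = run_stage(config, "finetune")
    run_stage(config, "explain")
    summary = run_stage(config, "report")
    summary["clean"] = clean_info
    summary["test_metrics"] = {
        k: v for k, v in metrics.items() if isinstance(v, float)
    }
    return summary
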