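"""End-to-end run orchestration: similarity -> train -> evaluate/rank.

A run is a pure function of (input files, configuration, seed).  Every run
directory contains the integrated and row-normalized similarity networks,
the trained factors, the full score matrix, the requested evaluation report,
and a manifest with the echoed configuration, SHA-256 checksums of every
output and the library versions — enough to verify an exact re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, data_io, similarity as sim_mod
from .data_io import build_weight_matrix, merge_association_lists
from .evaluation import ablation_network, global_loocv, local_loocv, top_k_candidates
from .model import ModelConfig, predict_scores, save_model, train_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    association_paths: list[str]
    out_dir: str
    functional_similarity_path: str | None = None
    expression_path: str | None = None
    gip_only: bool = False
    rm_prime: float = 1.0
    bandwidth_convention: str = "divide"
    weight_mode: str = "per_mirna"
    model: ModelConfig = field(default_factory=ModelConfig)
    protocol: str = "global"  # global | local
    n_repeats: int = 1
    fast: bool = True
    ablation: bool = False
    rank_disease: str | None = None
    top_k: int = 50
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        model_cfg = ModelConfig(**raw.pop("model", {}))
        cfg = cls(model=model_cfg, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.association_paths:
            raise ValueError("at least one association path is required")
        for p in self.association_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"association file not found: {p}")
        for p in (self.functional_similarity_path, self.expression_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.functional_similarity_path is None and not self.gip_only:
            raise ValueError(
                "no functional similarity given: set gip_only to proceed with "
                "the interaction-profile kernel alone"
            )
        if self.protocol not in ("global", "local"):
            raise ValueError("protocol must be 'global' or 'local'")
        # one seed drives every stochastic stage
        self.model = self.model.replace(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_file = out / "run.log"
    handler = logging.FileHandler(log_file)
    logging.getLogger("imdn").addHandler(handler)
    outputs: dict[str, Path] = {}

    try:
        # ---- inputs -------------------------------------------------------
        assoc = _stage("read-associations")(merge_association_lists)(
            config.association_paths
        )
        logger.info(
            "associations: %d miRNAs x %d diseases, %d positives",
            assoc.n_mirnas, assoc.n_diseases, assoc.n_positives,
        )
        if config.expression_path is not None:
            expr = _stage("read-expression")(data_io.read_expression_table)(
                config.expression_path
            )
            weights = _stage("build-weights")(build_weight_matrix)(
                assoc, expr, mode=config.weight_mode
            )
        else:
            W = np.ones_like(assoc.R)
            weights = data_io.WeightMatrix(
                assoc.mirna_ids, assoc.disease_ids, W, background=W.copy()
            )

        # ---- similarity ---------------------------------------------------
        @_stage("similarity")
        def _similarity():
            rm = sim_mod.gip_bandwidth(
                assoc, rm_prime=config.rm_prime,
                convention=config.bandwidth_convention,
            )
            gs = sim_mod.gip_kernel(assoc, rm)
            if config.functional_similarity_path is not None:
                fs_full = data_io.read_similarity_matrix(
                    config.functional_similarity_path
                )
                keep = [m for m in fs_full.mirna_ids if m in set(assoc.mirna_ids)]
                dropped = set(fs_full.mirna_ids) - set(keep)
                if dropped:
                    logger.warning(
                        "dropping %d similarity miRNA(s) absent from R", len(dropped)
                    )
                # align FS onto R's miRNA axis; unmatched rows stay undefined
                fs_vals = np.zeros((assoc.n_mirnas, assoc.n_mirnas))
                fs_index = {m: j for j, m in enumerate(fs_full.mirna_ids)}
                present = [u for u, m in enumerate(assoc.mirna_ids) if m in fs_index]
                src = [fs_index[assoc.mirna_ids[u]] for u in present]
                fs_vals[np.ix_(present, present)] = fs_full.values[np.ix_(src, src)]
                fs = sim_mod.SimilarityMatrix(
                    assoc.mirna_ids, fs_vals, kind="functional"
                )
                mask = sim_mod.fs_mask(fs)
            else:
                fs, mask = gs, np.zeros_like(gs.values, dtype=bool)
            integrated = sim_mod.integrate_similarity(fs, mask, gs)
            return integrated, sim_mod.row_normalize(integrated)

        integrated, simnet = _similarity()
        outputs["simnet_integrated"] = out / "simnet_integrated.tsv"
        outputs["simnet_row_normalized"] = out / "simnet_row_normalized.tsv"
        data_io.write_matrix(integrated, outputs["simnet_integrated"])
        data_io.write_matrix(simnet, outputs["simnet_row_normalized"])

        # ---- training & scoring ------------------------------------------
        model = _stage("train")(train_model)(assoc, weights, simnet, config.model)
        logger.info(
            "trained %d epochs, final loss %.6f",
            len(model.loss_history) - 1, model.loss_history[-1],
        )
        save_model(model, out / "model")
        for part in ("M.tsv", "D.tsv", "model.json"):
            outputs[f"model/{part}"] = out / "model" / part
        scores = predict_scores(model)
        outputs["scores"] = out / "scores.tsv"
        data_io.write_matrix(
            data_io.WeightMatrix(assoc.mirna_ids, assoc.disease_ids,
                                 scores, background=None),
            outputs["scores"],
        )

        # ---- evaluation ---------------------------------------------------
        @_stage("evaluate")
        def _evaluate() -> dict:
            if config.ablation:
                res = ablation_network(
                    assoc, weights, simnet, config.model,
                    protocol=config.protocol, n_repeats=config.n_repeats,
                    fast=config.fast,
                )
                return {
                    "protocol": res.with_network.protocol,
                    "auc_with_network": res.with_network.auc,
                    "auc_without_network": res.without_network.auc,
                    "auc_difference": res.auc_difference,
                    "auprc_with_network": res.with_network.auprc,
                    "auprc_without_network": res.without_network.auprc,
                    "n_repeats": config.n_repeats,
                }
            run = global_loocv if config.protocol == "global" else local_loocv
            res = run(
                assoc, weights, simnet, config.model,
                n_repeats=config.n_repeats, fast=config.fast,
            )
            return {
                "protocol": res.protocol,
                "auc": res.auc,
                "auprc": res.auprc,
                "n_repeats": res.n_repeats,
                "per_repeat_auc": res.per_repeat_auc,
                "per_fold": [
                    {"mirna": m, "disease": d, "rank": r, "candidates": n}
                    for (m, d), r, n in res.per_fold
                ],
            }

        eval_report = _evaluate()
        outputs["evaluation"] = out / "evaluation.json"
        outputs["evaluation"].write_text(
            json.dumps(eval_report, indent=2, sort_keys=True)
        )

        # ---- candidate ranking -------------------------------------------
        if config.rank_disease is not None:
            ranked = _stage("rank")(top_k_candidates)(
                model, assoc, config.rank_disease, config.top_k
            )
            outputs["candidates"] = out / "candidates.tsv"
            with open(outputs["candidates"], "w", encoding="utf-8") as fh:
                fh.write("# rank\tmirna_id\tscore\n")
                for rank, (m, s) in enumerate(ranked, start=1):
                    fh.write(f"{rank}\t{m}\t{s!r}\n")

        # ---- manifest -----------------------------------------------------
        manifest = {
            "imdn_version": __version__,
            "numpy_version": np.__version__,
            "config": config.to_dict(),
            "checksums": {k: _sha256(p) for k, p in sorted(outputs.items())},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    finally:
        logging.getLogger("imdn").removeHandler(handler)
        handler.close()
    return out
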