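"""Synthetic miRNA-disease worlds with known ground truth.

The generator emulates the statistical structure the factorization model
assumes: associations arise from low-rank latent factors through a logistic
link, the functional similarity network is informative about latent
proximity (it is a noisy, partially observed rescaled cosine of the true
miRNA factors), and expression values correlate with how many diseases a
miRNA is associated with.  Every other module can therefore be exercised —
and its recovery of held-out associations measured — without downloading
anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import data_io
from .data_io import AssociationMatrix, ExpressionTable, build_weight_matrix
from .model import ModelConfig, fit, predict_scores, sigmoid
from .evaluation import roc_auc
from .similarity import (
    SimilarityMatrix,
    gip_bandwidth,
    gip_kernel,
    integrate_similarity,
    row_normalize,
)

__all__ = ["WorldParams", "SyntheticWorld", "generate_world", "recovery_experiment",
           "write_world", "build_simnet", "RecoverySummary"]


@dataclass(frozen=True)
class WorldParams:
    """Knobs of the generative world.

    ``tau`` thresholds the link probability g(M_u . D_i) into a binary
    association; ``rho`` is the fraction of unordered miRNA pairs whose
    functional similarity is observed; ``eps`` is Gaussian noise on the
    observed functional similarities; ``eta`` is the fraction of association
    entries flipped after thresholding.  ``expr_assoc`` in [0, 1] sets how
    strongly expression tracks a miRNA's association count (0 = pure noise).
    """

    nm: int = 80
    nd: int = 60
    nl: int = 5
    tau: float = 0.9
    rho: float = 0.5
    eps: float = 0.0
    eta: float = 0.0
    factor_scale: float = 1.0
    expr_assoc: float = 0.7
    held_out_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.nm < 2 or self.nd < 2:
            raise ValueError("nm and nd must both be >= 2")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie strictly between 0 and 1")
        for name in ("rho", "eta", "expr_assoc", "held_out_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")

    def replace(self, **changes) -> "WorldParams":
        return replace(self, **changes)


@dataclass
class SyntheticWorld:
    """One generated instance: truth, observables, and held-out positives."""

    m_true: np.ndarray
    d_true: np.ndarray
    assoc: AssociationMatrix
    fs: SimilarityMatrix
    fs_mask: np.ndarray
    expression: ExpressionTable
    held_out: list[tuple[int, int]]
    seed: int
    params: WorldParams


def _rescaled_cosine(m_true: np.ndarray) -> np.ndarray:
    """Cosine similarity of the true miRNA factors mapped onto [0, 1]."""
    norms = np.linalg.norm(m_true, axis=1, keepdims=True)
    unit = m_true / np.where(norms == 0, 1.0, norms)
    cos = unit @ unit.T
    cos = 0.5 * (cos + cos.T)  # exact symmetry (BLAS is 1-ulp asymmetric)
    return (cos + 1.0) / 2.0


def generate_world(params: WorldParams, seed: int) -> SyntheticWorld:
    """Draw one fully deterministic world from the given seed."""
    rng = np.random.default_rng(seed)
    nm, nd, nl = params.nm, params.nd, params.nl

    m_true = rng.normal(0.0, params.factor_scale, size=(nm, nl))
    d_true = rng.normal(0.0, params.factor_scale, size=(nd, nl))
    link_prob = sigmoid(m_true @ d_true.T)
    R = (link_prob > params.tau).astype(float)
    if R.sum() == 0 or R.sum() == R.size:
        raise ValueError(
            f"tau={params.tau} yields a degenerate all-"
            f"{'one' if R.sum() else 'zero'} association matrix; choose a tau "
            "closer to the bulk of the link probabilities"
        )
    if params.eta > 0:
        n_flip = round(params.eta * R.size)
        flat = rng.choice(R.size, size=n_flip, replace=False)
        R.flat[flat] = 1.0 - R.flat[flat]
        if R.sum() == 0 or R.sum() == R.size:
            raise ValueError("flip noise eta degenerated the association matrix")

    mirna_ids = tuple(f"mirna-{u:04d}" for u in range(nm))
    disease_ids = tuple(f"disease-{i:04d}" for i in range(nd))
    assoc = AssociationMatrix(mirna_ids, disease_ids, R)

    # functional similarity: noisy rescaled cosine, observed on rho of pairs
    n_pairs = nm * (nm - 1) // 2
    n_obs = math.ceil(params.rho * n_pairs)
    chosen = rng.choice(n_pairs, size=n_obs, replace=False) if n_obs else []
    iu = np.triu_indices(nm, k=1)
    mask = np.zeros((nm, nm), dtype=bool)
    mask[iu[0][chosen], iu[1][chosen]] = True
    mask |= mask.T

    fs_values = _rescaled_cosine(m_true)
    if params.eps > 0:
        noise = rng.normal(0.0, params.eps, size=(nm, nm))
        noise = np.triu(noise, k=1)
        fs_values = np.clip(fs_values + noise + noise.T, 0.0, 1.0)
    fs_values = np.where(mask, fs_values, 0.0)
    np.fill_diagonal(fs_values, 1.0)
    fs = SimilarityMatrix(mirna_ids, fs_values, kind="functional")

    # expression tracks association counts, mixed with uniform noise
    row_sums = R.sum(axis=1)
    base = row_sums / max(row_sums.max(), 1.0)
    noise = rng.uniform(0.0, 1.0, size=nm)
    expr_values = params.expr_assoc * base + (1.0 - params.expr_assoc) * noise
    expression = ExpressionTable.from_records(
        [(mirna_ids[u], None, float(100.0 * expr_values[u])) for u in range(nm)]
    )

    positives = assoc.positive_pairs()
    n_hold = 0
    if params.held_out_fraction > 0:
        n_hold = max(1, math.ceil(params.held_out_fraction * len(positives)))
    order = rng.permutation(len(positives))
    held_out = [positives[j] for j in order[:n_hold]]

    return SyntheticWorld(
        m_true=m_true,
        d_true=d_true,
        assoc=assoc,
        fs=fs,
        fs_mask=mask,
        expression=expression,
        held_out=held_out,
        seed=seed,
        params=params,
    )


def build_simnet(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix | None,
    mask: np.ndarray | None,
    rm_prime: float = 1.0,
    convention: str = "divide",
) -> SimilarityMatrix:
    """Integrated + row-normalized similarity network from R and optional FS."""
    rm = gip_bandwidth(assoc, rm_prime=rm_prime, convention=convention)
    gs = gip_kernel(assoc, rm)
    if fs is None or mask is None:
        integrated = gs
    else:
        integrated = integrate_similarity(fs, mask, gs)
    return row_normalize(integrated)


@dataclass
class RecoverySummary:
    """Held-out recovery AUCs across seeds, with and without the network."""

    auc_with: float
    auc_without: float
    sd_with: float
    sd_without: float
    per_seed_with: list[float] = field(default_factory=list)
    per_seed_without: list[float] = field(default_factory=list)

    @property
    def auc_difference(self) -> float:
        return self.auc_with - self.auc_without


def _held_out_auc(world: SyntheticWorld, model) -> float:
    """AUC of the held-out positives against the true-negative cells."""
    scores = predict_scores(model)
    R = world.assoc.R
    neg = scores[R == 0]
    pos = np.array([scores[u, i] for u, i in world.held_out])
    return roc_auc(np.r_[pos, neg], np.r_[np.ones(len(pos)), np.zeros(len(neg))])


def recovery_experiment(
    params: WorldParams,
    model_config: ModelConfig,
    n_seeds: int = 5,
    base_seed: int = 0,
    shuffle_fs: bool = False,
) -> RecoverySummary:
    """Measure recovery of held-out associations across fresh worlds.

    For each seed: generate a world, remove the held-out positives from R,
    build the weight matrix and the similarity network from the training
    data, train with the configured lambda_s and with lambda_s = 0, and rank
    held-out positives against true negatives.  ``shuffle_fs`` permutes the
    miRNA labels of the functional similarity before use — a negative
    control that destroys its information content while preserving its
    marginal distribution.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    aucs_with: list[float] = []
    aucs_without: list[float] = []
    for s in range(n_seeds):
        seed = base_seed + s
        world = generate_world(params, seed=seed)
        if not world.held_out:
            raise ValueError("recovery experiment requires held-out positives")
        R_train = world.assoc.R.copy()
        for u, i in world.held_out:
            R_train[u, i] = 0.0
        assoc_train = AssociationMatrix(
            world.assoc.mirna_ids, world.assoc.disease_ids, R_train
        )
        weights = build_weight_matrix(assoc_train, world.expression, mode="per_mirna")
        fs, mask = world.fs, world.fs_mask
        if shuffle_fs:
            perm = np.random.default_rng(seed + 10_000).permutation(params.nm)
            fs = SimilarityMatrix(
                fs.mirna_ids, fs.values[np.ix_(perm, perm)], kind="functional"
            )
            mask = mask[np.ix_(perm, perm)]
        simnet = build_simnet(assoc_train, fs, mask)
        cfg = model_config.replace(seed=model_config.seed + s)
        model_with = fit(R_train, weights.W, simnet.values, cfg)
        model_without = fit(R_train, weights.W, None, cfg.replace(lambda_s=0.0))
        aucs_with.append(_held_out_auc(world, model_with))
        aucs_without.append(_held_out_auc(world, model_without))

    def sd(xs: list[float]) -> float:
        return float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0

    return RecoverySummary(
        auc_with=float(np.mean(aucs_with)),
        auc_without=float(np.mean(aucs_without)),
        sd_with=sd(aucs_with),
        sd_without=sd(aucs_without),
        per_seed_with=aucs_with,
        per_seed_without=aucs_without,
    )


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Serialize the observable part of a world in the package's TSV dialect.

    The true factors go into a ``truth`` subdirectory; the association list,
    functional similarity and expression table round-trip through data_io.
    """
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": out / "associations.tsv",
        "association_matrix": out / "association_matrix.tsv",
        "functional_similarity": out / "functional_similarity.tsv",
        "expression": out / "expression.tsv",
    }
    data_io.write_association_list(world.assoc, paths["associations"])
    # matrix form keeps miRNAs/diseases with no associations
    data_io.write_matrix(world.assoc, paths["association_matrix"])
    data_io.write_matrix(world.fs, paths["functional_similarity"])
    data_io.write_expression_table(world.expression, paths["expression"])
    np.savetxt(out / "truth" / "m_true.tsv", world.m_true, delimiter="\t")
    np.savetxt(out / "truth" / "d_true.tsv", world.d_true, delimiter="\t")
    with open(out / "truth" / "held_out.tsv", "w", encoding="utf-8") as fh:
        fh.write("# mirna_id\tdisease_id\n")
        for u, i in world.held_out:
            fh.write(f"{world.assoc.mirna_ids[u]}\t{world.assoc.disease_ids[i]}\n")
    return paths
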