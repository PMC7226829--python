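"""Network-regularized weighted sigmoid matrix factorization.

The model factors the binary association matrix R (Nm x Nd) into miRNA
latent vectors M (Nm x Nl) and disease latent vectors D (Nd x Nl), linking
the inner product to association probability through the logistic function
g.  The objective combines four terms:

    L = 1/2 sum_{u,i} W[u,i] (R[u,i] - g(M_u . D_i))^2
      + lambda_M/2 ||M||_F^2 + lambda_D/2 ||D||_F^2
      + lambda_S/2 sum_u || M_u - sum_{v in E_u} S[u,v] M_v ||^2

W is the expression-derived confidence weight (soft observation weight over
all cells, so unobserved pairs still contribute according to how plausible
their expression makes them), and S is the row-normalized miRNA similarity
network.  The last term is a social-regularization-style penalty: each
miRNA's latent vector is pulled toward the similarity-weighted average of
its direct neighbors, which is what lets rare miRNAs (few known disease
links) borrow statistical strength from the network.

The MAP derivation: observed entries are Gaussian around g(M_u . D_i) with
variance sigma_R^2, M and D carry zero-mean Gaussian priors, and M
additionally carries a Gaussian prior centered on the neighbor average.
Maximizing the log-posterior is minimizing L with lambda_* equal to the
variance ratios sigma_R^2 / sigma_*^2.

Training is full-batch gradient descent with a monotonicity guard: any step
that would increase the loss halves the learning rate and retries, so the
recorded loss history is non-increasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelConfig",
    "LatentModel",
    "sigmoid",
    "sigmoid_deriv",
    "predict_scores",
    "loss",
    "grad_M",
    "grad_D",
    "neighbor_estimate",
    "fit",
    "train_model",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the factorization.

    ``lambda_m``/``lambda_d`` are the ridge strengths on the latent matrices,
    ``lambda_s`` the strength of the network-regularization pull toward the
    neighbor average; all three are the noise-to-prior variance ratios of the
    underlying probabilistic model.  ``tol`` stops training when the relative
    loss change per epoch falls below it.
    """

    latent_dim: int = 10
    lambda_m: float = 0.01
    lambda_d: float = 0.01
    lambda_s: float = 0.1
    learning_rate: float = 0.05
    max_epochs: int = 2000
    tol: float = 1e-6
    seed: int = 0
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if min(self.lambda_m, self.lambda_d, self.lambda_s) < 0:
            raise ValueError("regularization strengths must be non-negative")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")

    def replace(self, **changes) -> "ModelConfig":
        return replace(self, **changes)


@dataclass
class LatentModel:
    """Trained factors: M (miRNA latent space) and D (disease latent space)."""

    M: np.ndarray
    D: np.ndarray
    config: ModelConfig
    loss_history: list[float] = field(default_factory=list)
    mirna_ids: tuple[str, ...] | None = None
    disease_ids: tuple[str, ...] | None = None


def sigmoid(x):
    """Logistic link g(x) = 1 / (1 + e^-x), stable for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def sigmoid_deriv(x):
    """g'(x) = g(x) (1 - g(x))."""
    g = sigmoid(x)
    return g * (1.0 - g)


def predict_scores(model: LatentModel) -> np.ndarray:
    """Association scores in (0, 1): g(M_u . D_i) for every cell."""
    return sigmoid(model.M @ model.D.T)


def _network_residual(M: np.ndarray, S_norm: np.ndarray | None) -> np.ndarray:
    """M_u minus the neighbor-weighted average; zero when no network given."""
    if S_norm is None:
        return np.zeros_like(M)
    return M - S_norm @ M


def neighbor_estimate(M: np.ndarray, S_norm: np.ndarray) -> np.ndarray:
    """Estimated latent vector of each miRNA from its direct neighbors.

    M_hat_u = sum_{v in E_u} S[u,v] M_v — a convex combination because
    S_norm rows sum to 1; isolated miRNAs get the zero vector.
    """
    return np.asarray(S_norm) @ np.asarray(M)


def _check_finite(value: np.ndarray | float, term: str):
    if not np.all(np.isfinite(value)):
        raise FloatingPointError(f"non-finite value in {term}")
    return value


def loss(
    R: np.ndarray,
    W: np.ndarray,
    S_norm: np.ndarray | None,
    M: np.ndarray,
    D: np.ndarray,
    config: ModelConfig,
) -> float:
    """Weighted squared-error data term plus ridge and network penalties."""
    logits = _check_finite(M @ D.T, "logits M D^T")
    resid = R - sigmoid(logits)
    data = 0.5 * float((W * resid**2).sum())
    ridge_m = 0.5 * config.lambda_m * float((M**2).sum())
    ridge_d = 0.5 * config.lambda_d * float((D**2).sum())
    net = 0.5 * config.lambda_s * float((_network_residual(M, S_norm) ** 2).sum())
    for name, term in (
        ("data term", data),
        ("miRNA ridge term", ridge_m),
        ("disease ridge term", ridge_d),
        ("network term", net),
    ):
        _check_finite(term, name)
    return data + ridge_m + ridge_d + net


def _data_error(R, W, M, D):
    logits = M @ D.T
    g = sigmoid(logits)
    return W * g * (1.0 - g) * (g - R)


def grad_M(R, W, S_norm, M, D, config: ModelConfig) -> np.ndarray:
    """Gradient of the loss with respect to the miRNA factors.

    Data term plus lambda_M M_u, plus the network term's two parts: the
    direct pull of M_u toward its own neighbor average, and the back-
    propagated pull from every miRNA v that counts u among its neighbors.
    """
    E = _check_finite(_data_error(R, W, M, D), "data-error matrix")
    g = E @ D + config.lambda_m * M
    if config.lambda_s > 0 and S_norm is not None:
        P = _network_residual(M, S_norm)
        g = g + config.lambda_s * (P - S_norm.T @ P)
    return _check_finite(g, "grad_M")


def grad_D(R, W, M, D, config: ModelConfig) -> np.ndarray:
    """Gradient with respect to the disease factors: data term + ridge."""
    E = _check_finite(_data_error(R, W, M, D), "data-error matrix")
    return _check_finite(E.T @ M + config.lambda_d * D, "grad_D")


def fit(
    R: np.ndarray,
    W: np.ndarray,
    S_norm: np.ndarray | None,
    config: ModelConfig,
    mirna_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> LatentModel:
    """Train the factors by guarded full-batch gradient descent.

    Factors are initialized i.i.d. zero-mean normal with scale
    ``config.init_scale`` from ``config.seed`` (zero init is a saddle point
    of the data term).  Each epoch takes one simultaneous step on M and D;
    if the step would increase the loss, the learning rate is halved and the
    step retried, which makes the loss history non-increasing.  Training
    stops on ``max_epochs``, on relative loss change below ``config.tol``,
    or when the learning rate underflows (a local minimum to within float
    precision).
    """
    R = np.asarray(R, dtype=float)
    W = np.asarray(W, dtype=float)
    if R.shape != W.shape:
        raise ValueError("R and W must share dimensions")
    if S_norm is not None:
        S_norm = np.asarray(S_norm, dtype=float)
        if S_norm.shape != (R.shape[0], R.shape[0]):
            raise ValueError("S_norm must be Nm x Nm")
    nm, nd = R.shape
    rng = np.random.default_rng(config.seed)
    M = rng.normal(0.0, config.init_scale, size=(nm, config.latent_dim))
    D = rng.normal(0.0, config.init_scale, size=(nd, config.latent_dim))

    lr = config.learning_rate
    current = loss(R, W, S_norm, M, D, config)
    history = [current]
    for _ in range(config.max_epochs):
        gM = grad_M(R, W, S_norm, M, D, config)
        gD = grad_D(R, W, M, D, config)
        while True:
            M_new = M - lr * gM
            D_new = D - lr * gD
            try:
                new_loss = loss(R, W, S_norm, M_new, D_new, config)
            except FloatingPointError:
                new_loss = np.inf
            if np.isfinite(new_loss) and new_loss <= current:
                break
            lr *= 0.5
            if lr < 1e-300:
                if not np.isfinite(new_loss):
                    raise RuntimeError(
                        "training diverged (non-finite loss even at a "
                        "vanishing step); use a smaller learning_rate"
                    )
                # no descent direction at float precision: converged
                new_loss = current
                M_new, D_new = M, D
                break
        M, D = M_new, D_new
        history.append(new_loss)
        if lr < 1e-300:
            break
        if current > 0 and abs(current - new_loss) / current < config.tol:
            current = new_loss
            break
        current = new_loss

    return LatentModel(
        M=M,
        D=D,
        config=config,
        loss_history=history,
        mirna_ids=tuple(mirna_ids) if mirna_ids is not None else None,
        disease_ids=tuple(disease_ids) if disease_ids is not None else None,
    )


def train_model(assoc, weights, simnet, config: ModelConfig) -> LatentModel:
    """Convenience wrapper: fit from the domain containers, keeping the IDs.

    ``simnet`` is the row-normalized similarity (or None to train without
    the network term).
    """
    S = simnet.values if simnet is not None else None
    return fit(
        assoc.R,
        weights.W,
        S,
        config,
        mirna_ids=assoc.mirna_ids,
        disease_ids=assoc.disease_ids,
    )


def save_model(model: LatentModel, out_dir: str | Path) -> None:
    """Write M.tsv, D.tsv and a JSON config sidecar into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"f{k}" for k in range(model.config.latent_dim)]
    m_index = model.mirna_ids or [f"row{u}" for u in range(model.M.shape[0])]
    d_index = model.disease_ids or [f"row{i}" for i in range(model.D.shape[0])]
    pd.DataFrame(model.M, index=list(m_index), columns=cols).to_csv(
        out / "M.tsv", sep="\t", index_label="id", float_format="%.17g"
    )
    pd.DataFrame(model.D, index=list(d_index), columns=cols).to_csv(
        out / "D.tsv", sep="\t", index_label="id", float_format="%.17g"
    )
    sidecar = {
        "config": asdict(model.config),
        "loss_history": [float(v) for v in model.loss_history],
        "has_ids": model.mirna_ids is not None,
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(model_dir: str | Path) -> LatentModel:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    config = ModelConfig(**sidecar["config"])
    m_df = pd.read_csv(model_dir / "M.tsv", sep="\t", index_col=0)
    d_df = pd.read_csv(model_dir / "D.tsv", sep="\t", index_col=0)
    has_ids = sidecar.get("has_ids", True)
    return LatentModel(
        M=m_df.to_numpy(dtype=float),
        D=d_df.to_numpy(dtype=float),
        config=config,
        loss_history=list(sidecar["loss_history"]),
        mirna_ids=tuple(str(i) for i in m_df.index) if has_ids else None,
        disease_ids=tuple(str(i) for i in d_df.index) if has_ids else None,
    )
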