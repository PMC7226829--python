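"""miRNA similarity network construction.

Two similarity sources are combined into one network over the miRNAs:

* a precomputed *functional* similarity (FS), available only for a subset of
  pairs, derived externally from the semantic similarity of the diseases each
  miRNA is associated with;
* a *Gaussian interaction profile* (GIP) kernel similarity computed here from
  the binary association matrix: two miRNAs are similar if their disease
  interaction profiles (rows of R) are close, with similarity decaying as
  exp(-rm * ||IP(u) - IP(v)||^2).

The integrated network uses FS wherever it is defined and the GIP kernel
everywhere else, and is finally row-normalized so each miRNA's neighbor
weights form a convex combination — the form the network regularizer needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import AssociationMatrix

__all__ = [
    "SimilarityMatrix",
    "interaction_profiles",
    "gip_bandwidth",
    "gip_kernel",
    "fs_mask",
    "integrate_similarity",
    "row_normalize",
]

SimilarityKind = Literal["functional", "gip", "integrated", "row_normalized"]

_SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square miRNA-by-miRNA similarity with a declared kind.

    kinds: ``functional`` (external FS; NaN allowed for undefined pairs),
    ``gip`` (Gaussian interaction profile kernel; unit diagonal, entries in
    (0, 1]), ``integrated`` (FS overlaid on GIP), ``row_normalized`` (zero
    diagonal, each non-isolated row summing to 1).
    """

    mirna_ids: tuple[str, ...]
    values: np.ndarray
    kind: SimilarityKind = "functional"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.mirna_ids)
        if values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {values.shape} != ({n}, {n})")
        if self.kind in ("functional", "gip", "integrated"):
            with np.errstate(invalid="ignore"):
                asym = np.abs(values - values.T)
            # NaN-vs-NaN counts as symmetric (undefined pair on both sides)
            asym = np.where(np.isnan(values) & np.isnan(values.T), 0.0, asym)
            if np.nanmax(asym, initial=0.0) > _SYMMETRY_TOL:
                raise ValueError(f"{self.kind} similarity must be symmetric")
        if self.kind == "gip":
            if not np.allclose(np.diag(values), 1.0, rtol=0, atol=0):
                raise ValueError("GIP kernel must have an exact unit diagonal")
            if (values <= 0).any() or (values > 1).any():
                raise ValueError("GIP kernel entries must lie in (0, 1]")
        if self.kind == "row_normalized":
            if np.diag(values).any():
                raise ValueError("row-normalized similarity must have zero diagonal")
            sums = values.sum(axis=1)
            bad = (sums > 0) & ~np.isclose(sums, 1.0, atol=1e-9)
            if bad.any():
                raise ValueError("non-isolated rows must sum to 1")
        object.__setattr__(self, "values", values)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    def neighbor_sets(self) -> list[np.ndarray]:
        """E_u = indices v != u with positive similarity to u."""
        out = []
        for u in range(self.n_mirnas):
            row = self.values[u].copy()
            row[u] = 0.0
            out.append(np.flatnonzero(np.nan_to_num(row) > 0))
        return out


def interaction_profiles(assoc: AssociationMatrix) -> np.ndarray:
    """Interaction profile of each miRNA: its row of R as a binary vector."""
    return assoc.R.astype(float).copy()


def gip_bandwidth(
    assoc: AssociationMatrix,
    rm_prime: float = 1.0,
    convention: Literal["divide", "multiply"] = "divide",
) -> float:
    """Kernel bandwidth rm from the raw parameter rm' and the profiles.

    ``divide`` (default): rm = rm' / mean_u ||IP(u)||^2 — the bandwidth is
    normalized by the average interaction density, the standard construction
    for this kernel family, so the kernel scale is invariant to how densely
    annotated the dataset is.  ``multiply`` uses rm = rm' * mean ||IP||^2.
    """
    if rm_prime <= 0:
        raise ValueError("rm_prime must be positive")
    profiles = interaction_profiles(assoc)
    mean_sq_norm = float((profiles**2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise ValueError(
            "all interaction profiles are zero: bandwidth is undefined "
            "(division by zero)"
        )
    if convention == "divide":
        return rm_prime / mean_sq_norm
    if convention == "multiply":
        return rm_prime * mean_sq_norm
    raise ValueError(f"unknown bandwidth convention {convention!r}")


def gip_kernel(assoc: AssociationMatrix, rm: float) -> SimilarityMatrix:
    """Gaussian kernel over interaction profiles: exp(-rm ||IP_u - IP_v||^2)."""
    if rm <= 0:
        raise ValueError("bandwidth rm must be positive")
    profiles = interaction_profiles(assoc)
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-rm * sq_dists)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(assoc.mirna_ids, values, kind="gip")


def fs_mask(fs: SimilarityMatrix) -> np.ndarray:
    """Boolean mask of pairs where functional similarity is defined.

    Undefined pairs are encoded as NaN or 0 in FS exports, so "defined"
    means finite and strictly positive.
    """
    with np.errstate(invalid="ignore"):
        return np.isfinite(fs.values) & (fs.values > 0)


def integrate_similarity(
    fs: SimilarityMatrix,
    mask: np.ndarray,
    gs: SimilarityMatrix,
) -> SimilarityMatrix:
    """Overlay functional similarity on the GIP kernel.

    S[u, v] = FS[u, v] where the mask marks the pair as functionally
    annotated, else GS[u, v].  The mask must be symmetric so the result is.
    """
    if fs.mirna_ids != gs.mirna_ids:
        raise ValueError("FS and GS must share the same miRNA ID order")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fs.values.shape:
        raise ValueError("mask shape does not match similarity matrices")
    if (mask != mask.T).any():
        raise ValueError("fs mask must be symmetric")
    values = np.where(mask, fs.values, gs.values)
    if np.isnan(values).any():
        raise ValueError("mask selects undefined (NaN) functional similarities")
    return SimilarityMatrix(fs.mirna_ids, values, kind="integrated")


def row_normalize(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Normalize each row over its neighbors so weights sum to 1.

    The diagonal is zeroed first (a miRNA is not its own neighbor), then each
    row with any positive off-diagonal weight is divided by its sum; rows of
    isolated miRNAs stay all-zero.  The output drives both the neighbor
    average estimate and the network regularizer.
    """
    values = np.asarray(sim.values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("cannot row-normalize a similarity with NaN entries")
    if (values < 0).any():
        raise ValueError("cannot row-normalize negative similarities")
    out = values.copy()
    np.fill_diagonal(out, 0.0)
    sums = out.sum(axis=1, keepdims=True)
    nonzero = sums[:, 0] > 0
    out[nonzero] /= sums[nonzero]
    return SimilarityMatrix(sim.mirna_ids, out, kind="row_normalized")
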