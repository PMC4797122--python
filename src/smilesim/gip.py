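"""WNN-GIP drug-target interaction prediction.

The predictor combines three sources of information:

* a chemical similarity kernel over drugs (any kernel from this
  package, or a precomputed 2D matrix),
* a genomic similarity kernel over targets (e.g. normalized
  Smith-Waterman scores, consumed precomputed),
* Gaussian Interaction Profile (GIP) kernels built from the rows and
  columns of the binary drug-target adjacency matrix.

For a *new* drug (no known interactions) the GIP profile is undefined;
the Weighted Nearest Neighbor (WNN) step imputes it as a geometrically
decaying weighted sum of the profiles of chemically similar training
drugs.  Drug and target kernels are then merged with a Kronecker
product and scores come from regularized least squares (RLS), solved
through the per-kernel eigendecompositions so the Kronecker matrix is
never materialized: with K_d = U L U^T and K_t = V M V^T,

    scores = U [ (L_i M_j / (L_i M_j + sigma)) o (U^T Y V) ] V^T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .matrix import SimilarityMatrix, make_kernel

logger = logging.getLogger(__name__)


@dataclass
class InteractionNetwork:
    """Bipartite drug-target interaction network (binary adjacency)."""

    drug_ids: list[str]
    target_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.target_ids)} targets"
            )
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = self.adjacency.astype(np.float64)


def read_adjacency_tsv(path: str | Path) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return InteractionNetwork(
        [str(x) for x in df.index], [str(x) for x in df.columns], df.to_numpy()
    )


def write_adjacency_tsv(path: str | Path, network: InteractionNetwork) -> None:
    df = pd.DataFrame(
        network.adjacency.astype(int),
        index=network.drug_ids,
        columns=network.target_ids,
    )
    df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class GipConfig:
    """Hyperparameters of the WNN-GIP predictor.

    gamma_scale : bandwidth multiplier of the GIP Gaussian kernel; the
        effective gamma is ``gamma_scale / mean_i ||y_i||^2``.
    alpha : mixing weight between the chemical/genomic kernel (alpha)
        and the GIP kernel (1 - alpha).
    sigma : RLS regularization strength.
    wnn_decay : geometric decay of the weighted-nearest-neighbor
        profile imputation for new drugs.
    """

    gamma_scale: float = 1.0
    alpha: float = 0.5
    sigma: float = 1.0
    wnn_decay: float = 0.7
    wnn_enabled: bool = True

    def __post_init__(self) -> None:
        if self.gamma_scale <= 0:
            raise ValueError("gamma_scale must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.wnn_decay <= 1.0:
            raise ValueError("wnn_decay must be in (0, 1]")


def gip_kernel(
    profiles: np.ndarray,
    gamma_scale: float = 1.0,
    labels: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Gaussian kernel on interaction profiles (rows of ``profiles``).

    ``K[i, j] = exp(-gamma * ||y_i - y_j||^2)`` with the bandwidth
    normalized by the mean squared profile norm, taken over profiles
    with nonzero norm so that imputation-free all-zero rows do not
    deflate the bandwidth.
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.size == 0:
        raise ValueError("profiles must be non-empty")
    norms_sq = (profiles**2).sum(axis=1)
    nonzero = norms_sq[norms_sq > 0]
    if nonzero.size == 0:
        raise ValueError("all interaction profiles are all-zero; GIP bandwidth undefined")
    gamma = gamma_scale / float(nonzero.mean())
    n = profiles.shape[0]
    if n == 1:
        d2 = np.zeros((1, 1))
    else:
        d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * d2)
    np.fill_diagonal(values, 1.0)
    if labels is None:
        labels = [str(i) for i in range(n)]
    return SimilarityMatrix(list(labels), values, {"kernel": "gip", "gamma": gamma})


def wnn_impute(
    sim_to_train: np.ndarray, train_adjacency: np.ndarray, decay: float
) -> np.ndarray:
    """Impute an interaction profile for a new drug.

    Training drugs are ranked by descending similarity (ties broken by
    training order, which keeps the result deterministic); the imputed
    profile is ``sum_r decay^(r-1) * profile_of_rank_r`` clipped to
    [0, 1].
    """
    sim = np.asarray(sim_to_train, dtype=np.float64)
    train = np.asarray(train_adjacency, dtype=np.float64)
    if train.shape[0] == 0:
        raise ValueError("wnn_impute requires at least one training drug")
    if sim.shape[0] != train.shape[0]:
        raise ValueError("similarity vector length must match training set size")
    order = np.argsort(-sim, kind="stable")
    weights = decay ** np.arange(len(order), dtype=np.float64)
    profile = weights @ train[order]
    return np.clip(profile, 0.0, 1.0)


def combine_kernels(
    K_sim: SimilarityMatrix, K_gip: SimilarityMatrix, alpha: float
) -> SimilarityMatrix:
    """Convex combination ``alpha * K_sim + (1 - alpha) * K_gip``."""
    if K_sim.labels != K_gip.labels:
        raise ValueError("kernel label mismatch")
    values = alpha * K_sim.values + (1.0 - alpha) * K_gip.values
    meta = {"kernel": "combined", "alpha": alpha, "left": K_sim.meta.get("kernel"),
            "right": K_gip.meta.get("kernel")}
    return SimilarityMatrix(list(K_sim.labels), values, meta)


def kron_rls(
    K_drug: SimilarityMatrix | np.ndarray,
    K_target: SimilarityMatrix | np.ndarray,
    Y: np.ndarray,
    sigma: float = 1.0,
) -> np.ndarray:
    """Kronecker RLS scores ``vec^-1[K (K + sigma I)^-1 vec(Y)]``.

    Solved via the eigendecomposition identity, never materializing the
    Kronecker product ``K = K_target (x) K_drug``.  Inputs must be
    symmetric PSD (run :func:`smilesim.matrix.make_kernel` first).
    """
    Kd = K_drug.values if isinstance(K_drug, SimilarityMatrix) else np.asarray(K_drug)
    Kt = K_target.values if isinstance(K_target, SimilarityMatrix) else np.asarray(K_target)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape != (Kd.shape[0], Kt.shape[0]):
        raise ValueError("Y shape must be (n_drugs, n_targets)")
    for name, K in (("drug", Kd), ("target", Kt)):
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError(f"{name} kernel is not symmetric; run make_kernel first")
    lam_d, U = np.linalg.eigh(Kd)
    lam_t, V = np.linalg.eigh(Kt)
    if lam_d[0] < -1e-8 or lam_t[0] < -1e-8:
        raise ValueError("kernel has negative eigenvalues; run make_kernel first")
    outer = np.outer(lam_d, lam_t)
    filt = outer / (outer + sigma)
    return U @ (filt * (U.T @ Y @ V)) @ V.T


def predict(
    network: InteractionNetwork,
    K_drug_chem: SimilarityMatrix,
    K_target_gen: SimilarityMatrix,
    config: GipConfig | None = None,
    test_drugs: Sequence[str] = (),
) -> pd.DataFrame:
    """End-to-end WNN-GIP prediction for a set of held-out drugs.

    The adjacency rows of ``test_drugs`` are treated as unknown: they
    are replaced by WNN-imputed profiles (or zeros when WNN is
    disabled) before the GIP kernels are formed, so no interaction
    information of the test drugs leaks into training.  Returns a
    DataFrame of scores, one row per test drug, one column per target.
    """
    config = config or GipConfig()
    unknown = [d for d in test_drugs if d not in network.drug_ids]
    if unknown:
        raise KeyError(f"unknown test drug ids: {unknown}")
    if len(test_drugs) == 0:
        return pd.DataFrame(columns=network.target_ids)

    K_chem = K_drug_chem.reorder(network.drug_ids)
    K_gen = K_target_gen.reorder(network.target_ids)

    test_idx = [network.drug_ids.index(d) for d in test_drugs]
    train_mask = np.ones(len(network.drug_ids), dtype=bool)
    train_mask[test_idx] = False
    if not train_mask.any():
        raise ValueError("cannot predict with an empty training set")

    Y = network.adjacency.copy()
    train_Y = Y[train_mask]
    for i in test_idx:
        if config.wnn_enabled:
            Y[i] = wnn_impute(
                K_chem.values[i, train_mask], train_Y, config.wnn_decay
            )
        else:
            Y[i] = 0.0

    gip_d = gip_kernel(Y, config.gamma_scale, network.drug_ids)
    gip_t = gip_kernel(Y.T, config.gamma_scale, network.target_ids)
    K_d = make_kernel(combine_kernels(K_chem, gip_d, config.alpha))
    K_t = make_kernel(combine_kernels(K_gen, gip_t, config.alpha))
    scores = kron_rls(K_d, K_t, Y, config.sigma)
    return pd.DataFrame(
        scores[test_idx], index=list(test_drugs), columns=network.target_ids
    )
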