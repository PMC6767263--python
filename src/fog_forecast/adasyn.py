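"""ADASYN oversampling of the minority (FoG) class.

ADASYN extends SMOTE by generating synthetic minority samples
preferentially near the class boundary.  The number of new samples,

    G = (|S_maj| - |S_min|) * beta,        beta in [0, 1],

is distributed across minority points in proportion to the fraction of
*majority* points among each point's k nearest neighbours (its boundary
density); each synthetic point is a convex combination
``x_i + lambda * (x_z - x_i)`` of a minority point and one of its
minority neighbours, with lambda ~ U(0, 1).

beta = 0 creates nothing; beta = 1 balances the set exactly (the
largest-remainder allocation makes the per-point counts sum to G, so the
50 % target is met up to the single rounding of G itself).

Oversampling is applied to training data only; generated rows carry a
``synthetic`` flag that the evaluation protocols assert on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .sample_builder import SampleSet

__all__ = ["AdasynConfig", "adasyn_oversample"]


@dataclass(frozen=True)
class AdasynConfig:
    beta: float = 0.2
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must lie in [0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be at least 1")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``,
    exact by assigning rounding residue to the largest fractional parts
    (ties to the larger weight, then lower index)."""
    ideal = weights / weights.sum() * total
    base = np.floor(ideal).astype(int)
    residue = total - int(base.sum())
    if residue > 0:
        frac = ideal - base
        order = np.lexsort((-weights, -frac))
        base[order[:residue]] += 1
    return base


def adasyn_oversample(train: SampleSet, cfg: AdasynConfig) -> SampleSet:
    """Augment ``train`` with synthetic minority samples per ADASYN.

    Neighbour search uses Euclidean distance on per-dimension z-scored
    feature vectors (fit on ``train``); the features mix very different
    scales (entropy vs band power), so raw Euclidean distance would be
    dominated by the largest-scale dimensions.  Synthetic coordinates
    are produced in the original feature space.
    """
    if cfg.beta == 0:
        return train

    n_min, n_maj = train.n_minority, train.n_majority
    counts = {0: train.n_ng, 1: train.n_fog}
    if min(counts.values()) == 0:
        raise ValueError("ADASYN with beta > 0 requires both classes in the training set")
    minority_label = min(counts, key=counts.get)
    if n_min < cfg.k_neighbors + 1:
        raise ValueError(
            f"need at least k+1={cfg.k_neighbors + 1} minority samples, got {n_min}"
        )

    G = int(round((n_maj - n_min) * cfg.beta))
    if G == 0:
        return train

    rng = np.random.default_rng(cfg.seed)
    mu = train.X.mean(axis=0)
    sd = train.X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (train.X - mu) / sd

    min_idx = np.flatnonzero(train.y == minority_label)
    Z_min = Z[min_idx]

    # boundary density: fraction of majority points among k NN in the full set
    nn_all = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Z)
    _, neigh = nn_all.kneighbors(Z_min)
    neigh = neigh[:, 1:]  # drop self
    r = (train.y[neigh] != minority_label).sum(axis=1) / cfg.k_neighbors

    if r.sum() == 0:
        warnings.warn(
            "no minority sample has majority neighbours; falling back to "
            "uniform allocation of synthetic samples",
            stacklevel=2,
        )
        r = np.ones_like(r, dtype=float)
    g = _largest_remainder(r.astype(float), G)

    # minority-only neighbourhoods for interpolation partners
    k_min = min(cfg.k_neighbors, len(min_idx) - 1)
    nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(Z_min)
    _, neigh_min = nn_min.kneighbors(Z_min)
    neigh_min = neigh_min[:, 1:]

    new_rows = []
    for i, gi in enumerate(g):
        for _ in range(gi):
            z = int(rng.integers(k_min))
            partner = min_idx[neigh_min[i, z]]
            lam = rng.uniform()
            xi = train.X[min_idx[i]]
            new_rows.append(xi + lam * (train.X[partner] - xi))

    X_new = np.vstack([train.X, np.array(new_rows)])
    y_new = np.concatenate([train.y, np.full(G, minority_label, dtype=np.int8)])
    t_new = np.concatenate([train.t, np.full(G, np.nan)])
    syn_new = np.concatenate([train.synthetic, np.ones(G, dtype=bool)])
    subject = None
    if train.subject is not None:
        pad = np.full(G, train.subject[0])
        subject = np.concatenate([train.subject, pad])
    return SampleSet(X=X_new, y=y_new, t=t_new, synthetic=syn_new, subject=subject)
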