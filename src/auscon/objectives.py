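"""Contrastive objectives over projected embeddings.

Two losses are provided, both operating on L2-normalized projection vectors
with cosine similarity and a temperature T:

* NT-Xent (normalized temperature-scaled cross entropy): one positive j per
  anchor i, contrasted against every other view a in the candidate set A(i),

      l_i = -log[ exp(sim(z_i, z_j)/T) / sum_{a in A(i)} exp(sim(z_i, z_a)/T) ]

* Supervised contrastive (in-batch weak labels): multiple positives P(i),
  with the average over positives taken inside the logarithm,

      L_i = -log[ (1/|P(i)|) sum_{p in P(i)} exp(sim(z_i, z_p)/T)
                  / sum_{a in A(i)} exp(sim(z_i, z_a)/T) ]

With |P(i)| = 1 the supervised form reduces exactly to NT-Xent.  The batch
loss is the mean over anchors, with both views of each pair serving as
anchors.  Analytic gradients with respect to the (unit) embeddings are
provided for the pure-NumPy training loop and are checked against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_TEMPERATURE = 0.5


@dataclass
class ProjectedBatch:
    """Unit-normalized projections plus per-anchor candidate/positive sets.

    ``z`` is (n_views, dim).  ``candidate_sets[i]`` is A(i) (all indices but
    i, by convention) and ``positive_sets[i]`` is P(i) ⊆ A(i), non-empty.
    """

    z: np.ndarray
    positive_sets: list[list[int]]
    candidate_sets: list[list[int]]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 2:
            raise ValueError("z must be (n_views, dim)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        n = self.z.shape[0]
        if not (len(self.positive_sets) == len(self.candidate_sets) == n):
            raise ValueError("need one positive and one candidate set per view")
        for i, (P, A) in enumerate(zip(self.positive_sets, self.candidate_sets)):
            if not P:
                raise ValueError(f"anchor {i} has an empty positive set")
            if i in A:
                raise ValueError(f"anchor {i} appears in its own candidate set")
            if not set(P) <= set(A):
                raise ValueError(f"P({i}) must be a subset of A({i})")


def default_candidate_sets(n_views: int) -> list[list[int]]:
    """A(i) = every view except i."""
    return [[j for j in range(n_views) if j != i] for i in range(n_views)]


def similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; symmetric and scale-invariant; errors on zero vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def l2_normalize(z: np.ndarray, axis: int = -1, eps: float = 1e-12) -> np.ndarray:
    norm = np.linalg.norm(z, axis=axis, keepdims=True)
    return z / np.maximum(norm, eps)


def _anchor_loss(z: np.ndarray, i: int, P: Sequence[int], A: Sequence[int],
                 T: float) -> float:
    zn = l2_normalize(z)
    A = list(A)
    P = list(P)
    sims_A = zn[A] @ zn[i] / T
    sims_P = zn[P] @ zn[i] / T
    # log-sum-exp stabilized
    m = sims_A.max()
    log_den = m + np.log(np.exp(sims_A - m).sum())
    log_num = m + np.log(np.exp(sims_P - m).sum() / len(P))
    return float(log_den - log_num)


def nt_xent(z: np.ndarray, i: int, j: int, candidate_set: Sequence[int],
            temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Per-anchor NT-Xent loss for anchor i with single positive j."""
    if j not in candidate_set:
        raise ValueError("the positive must be a member of the candidate set")
    return _anchor_loss(np.asarray(z, dtype=np.float64), i, [j], candidate_set,
                        temperature)


def sup_con(z: np.ndarray, i: int, positive_set: Sequence[int],
            candidate_set: Sequence[int],
            temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Per-anchor supervised-contrastive loss (average inside the log)."""
    if len(positive_set) == 0:
        raise ValueError("positive set must be non-empty")
    if not set(positive_set) <= set(candidate_set):
        raise ValueError("positives must be members of the candidate set")
    return _anchor_loss(np.asarray(z, dtype=np.float64), i, positive_set,
                        candidate_set, temperature)


def batch_loss(batch: ProjectedBatch) -> float:
    """Mean per-anchor loss over all views of the batch."""
    losses = [_anchor_loss(batch.z, i, batch.positive_sets[i],
                           batch.candidate_sets[i], batch.temperature)
              for i in range(batch.z.shape[0])]
    return float(np.mean(losses))


def batch_loss_and_grad(batch: ProjectedBatch) -> tuple[float, np.ndarray]:
    """Batch loss and its gradient w.r.t. the raw (pre-normalization) z.

    The gradient chains through the L2 normalization so callers can feed it
    straight into the projection head's backward pass.
    """
    z = batch.z
    n, d = z.shape
    T = batch.temperature
    zn = l2_normalize(z)
    grad_zn = np.zeros_like(zn)
    total = 0.0
    for i in range(n):
        A = batch.candidate_sets[i]
        P = batch.positive_sets[i]
        sims_A = zn[A] @ zn[i] / T
        sims_P = zn[P] @ zn[i] / T
        m = sims_A.max()
        expA = np.exp(sims_A - m)
        expP = np.exp(sims_P - m)
        total += (m + np.log(expA.sum())) - (m + np.log(expP.sum() / len(P)))
        beta = expA / expA.sum()      # softmax over A(i)
        alpha = expP / expP.sum()     # softmax restricted to P(i)
        # d l_i / d sims: +beta on A, -alpha on P
        coef = np.zeros(n)
        np.add.at(coef, A, beta)
        np.add.at(coef, P, -alpha)
        grad_zn[i] += (coef[:, None] * zn).sum(axis=0) / T
        grad_zn += np.outer(coef, zn[i]) / T
    total /= n
    grad_zn /= n
    # back through z -> z/||z||: (I - zn zn^T)/||z||
    norms = np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)
    grad_z = (grad_zn - (grad_zn * zn).sum(axis=1, keepdims=True) * zn) / norms
    return float(total), grad_z
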