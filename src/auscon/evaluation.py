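"""Split construction, AUROC, bootstrap confidence intervals, paired testing.

The evaluation protocol reserves class-balanced test and validation sets,
leaves the remainder as the pre-train set, and draws a class-balanced
fine-tune set from the pre-train set.  Test AUROC is reported with a
percentile bootstrap interval (1,000 resamples of the test set by default),
and models are compared with a two-sided paired t test — paired over
bootstrap replicates computed on shared resample indices by default, or over
parallel replicate models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Reserved-set sizes; each reserved set is drawn with a 1:1 class ratio."""

    test_size: int = 400
    val_size: int = 400
    finetune_size: int = 400

    def __post_init__(self) -> None:
        for n in (self.test_size, self.val_size, self.finetune_size):
            if n < 2 or n % 2 != 0:
                raise ValueError("reserved set sizes must be even and >= 2")


@dataclass
class Splits:
    pretrain: np.ndarray
    finetune: np.ndarray
    validation: np.ndarray
    test: np.ndarray


@dataclass
class EvalResult:
    """AUROC point estimate with percentile bootstrap CI."""

    auroc: float
    ci_low: float
    ci_high: float
    bootstrap_values: np.ndarray
    per_replicate_model_values: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auroc <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def binarize_labels(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Map label strings to {0: normal, 1: abnormal}; anything not 'normal'
    counts as abnormal (the multi-class lung task collapses this way)."""
    arr = np.asarray(labels)
    return (arr != "normal").astype(int)


def make_splits(labels, spec: SplitSpec | None = None, seed: int = 0) -> Splits:
    """Disjoint pre-train / fine-tune / validation / test index sets.

    ``labels`` are per-recording binary labels (0/1 or normal/abnormal).
    Test and validation each take spec.*_size examples with exactly half per
    class; the remainder is the pre-train set; the fine-tune set (again 1:1)
    is drawn from the pre-train set and remains part of it.
    """
    spec = spec or SplitSpec()
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = binarize_labels(y)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    need = (spec.test_size + spec.val_size + spec.finetune_size) // 2
    for cls, idx in (("abnormal", pos), ("normal", neg)):
        if len(idx) < need:
            raise ValueError(f"need {need} {cls} examples for the reserved "
                             f"sets, have {len(idx)}")
    pos = rng.permutation(pos)
    neg = rng.permutation(neg)
    ht, hv, hf = spec.test_size // 2, spec.val_size // 2, spec.finetune_size // 2
    test = np.concatenate([pos[:ht], neg[:ht]])
    val = np.concatenate([pos[ht:ht + hv], neg[ht:ht + hv]])
    rest_pos, rest_neg = pos[ht + hv:], neg[ht + hv:]
    pretrain = np.concatenate([rest_pos, rest_neg])
    finetune = np.concatenate([rest_pos[:hf], rest_neg[:hf]])
    for arr in (test, val, pretrain, finetune):
        rng.shuffle(arr)
    assert len(set(test) & set(val)) == 0
    assert len(set(test) & set(pretrain)) == 0
    assert len(set(val) & set(pretrain)) == 0
    assert set(finetune) <= set(pretrain)
    return Splits(pretrain=pretrain, finetune=finetune, validation=val, test=test)


def make_patient_splits(metadata: pd.DataFrame, spec: SplitSpec | None = None,
                        seed: int = 0) -> Splits:
    """Patient-grouped splits: no patient spans two of test/val/pre-train.

    For cohorts with several recordings per patient and patient-level labels,
    recording-level splitting would let a model recognize test patients seen
    during supervised training.  Here whole patients are assigned to the
    reserved sets; each reserved set still holds exactly half its recordings
    per class (surplus recordings of a reserved patient are dropped).  The
    fine-tune set is drawn, again patient-grouped, from the pre-train pool.
    """
    spec = spec or SplitSpec()
    meta = metadata.reset_index(drop=True)
    y = binarize_labels(meta["label"])
    rng = np.random.default_rng(seed)

    by_patient: dict[str, list[int]] = {}
    for i, pid in enumerate(meta["patient_id"]):
        by_patient.setdefault(str(pid), []).append(i)
    patients = {0: [], 1: []}
    for pid, idx in by_patient.items():
        cls = int(y[idx[0]])
        if not all(y[i] == cls for i in idx):
            raise ValueError(f"patient {pid} has mixed labels")
        patients[cls].append(pid)
    for cls in (0, 1):
        patients[cls] = list(rng.permutation(sorted(patients[cls])))

    def take(n_per_class: int) -> list[int]:
        chosen: list[int] = []
        for cls in (0, 1):
            got = 0
            while got < n_per_class:
                if not patients[cls]:
                    raise ValueError(
                        f"not enough class-{cls} patients for a reserved set "
                        f"needing {n_per_class} recordings per class")
                pid = patients[cls].pop()
                idx = by_patient[pid]
                keep = idx[:n_per_class - got]
                chosen.extend(keep)
                got += len(keep)
        return chosen

    test = np.array(take(spec.test_size // 2))
    val = np.array(take(spec.val_size // 2))
    finetune = np.array(take(spec.finetune_size // 2))
    reserved_patients = set(meta.loc[np.concatenate([test, val]), "patient_id"])
    pretrain = np.array([i for i in range(len(meta))
                         if meta.at[i, "patient_id"] not in reserved_patients])
    assert set(finetune) <= set(pretrain)
    return Splits(pretrain=pretrain, finetune=finetune, validation=val, test=test)


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative.

    Mann-Whitney form: ties count one half.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_indices(n: int, replicates: int, seed: int) -> np.ndarray:
    """Shared resample-index matrix so two models can be paired replicate-wise."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(replicates, n))


def bootstrap_ci(scores, labels, replicates: int = 1000, level: float = 0.95,
                 seed: int = 0, indices: np.ndarray | None = None) -> EvalResult:
    """Percentile bootstrap CI for AUROC by resampling the test set.

    A replicate that draws a single class is redrawn (and logged); a redraw
    rate above 10% triggers a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = binarize_labels(y)
    n = len(scores)
    rng = np.random.default_rng(seed + 1)
    if indices is None:
        indices = bootstrap_indices(n, replicates, seed)
    values = np.empty(indices.shape[0])
    redraws = 0
    for r in range(indices.shape[0]):
        idx = indices[r]
        while len(np.unique(y[idx])) < 2:
            redraws += 1
            idx = rng.integers(0, n, size=n)
        values[r] = auroc(scores[idx], y[idx])
    if redraws:
        logger.info("redrew %d single-class bootstrap replicates", redraws)
        if redraws > 0.1 * indices.shape[0]:
            logger.warning("bootstrap redraw rate above 10%% (%d/%d)",
                           redraws, indices.shape[0])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    point = auroc(scores, y)
    return EvalResult(auroc=point, ci_low=float(min(lo, point)),
                      ci_high=float(max(hi, point)), bootstrap_values=values)


def paired_t_test(values_a, values_b) -> tuple[float, float]:
    """Classical two-sided paired t test on per-replicate differences."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D arrays with >= 2 entries")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("differences have zero variance; the paired t "
                         "statistic is undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
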