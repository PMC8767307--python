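"""Contrastive view and batch construction under metadata schemes.

Twelve pretraining schemes are supported: five augmentation schemes (views =
two independent augmentations of one recording) and seven metadata schemes
in which a positive pair is two distinct recordings of the same patient,
optionally constrained by auscultation location, and negatives are sharpened
by constraining every batch member to share a trait (age band, sex, location
or combinations).  Metadata schemes use no augmentation at all, so any gain
is attributable to the pair-selection rule.

Batches are built from distinct patients, sampled with replacement across
batches but without replacement within a batch; trait-constrained batches
draw a trait value with probability proportional to its number of eligible
patients, then fill the batch from that cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .augment import AUGMENTATION_SCHEMES
from .signal_io import Spectrogram, SpectrogramDataset

logger = logging.getLogger(__name__)

METADATA_SCHEMES = ("pos_sim_age", "neg_sim_age", "neg_sim_sex",
                    "neg_sim_age_sex", "pos_same_loc", "pos_dif_loc",
                    "pos_same_loc_neg_same_loc")
ALL_SCHEMES = AUGMENTATION_SCHEMES + METADATA_SCHEMES


@dataclass(frozen=True)
class SchemeConfig:
    """Declarative description of one pretraining scheme."""

    name: str
    mode: str                      # 'augmentation' | 'metadata'
    positive_rule: str = "any"     # 'any' | 'same_location' | 'different_location'
    negative_trait: tuple[str, ...] = ()
    weak_label_field: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("augmentation", "metadata"):
            raise ValueError("mode must be 'augmentation' or 'metadata'")
        if (self.weak_label_field is not None) != (self.name == "pos_sim_age"):
            raise ValueError("weak_label_field is set iff the scheme is pos_sim_age")

    @classmethod
    def from_name(cls, name: str) -> "SchemeConfig":
        if name in AUGMENTATION_SCHEMES:
            return cls(name=name, mode="augmentation")
        table = {
            "pos_sim_age": dict(weak_label_field="age_band"),
            "neg_sim_age": dict(negative_trait=("age_band",)),
            "neg_sim_sex": dict(negative_trait=("sex",)),
            "neg_sim_age_sex": dict(negative_trait=("age_band", "sex")),
            "pos_same_loc": dict(positive_rule="same_location"),
            "pos_dif_loc": dict(positive_rule="different_location"),
            "pos_same_loc_neg_same_loc": dict(positive_rule="same_location",
                                              negative_trait=("location",)),
        }
        if name not in table:
            raise ValueError(f"unknown scheme {name!r}; the 12 valid schemes are "
                             f"{list(ALL_SCHEMES)}")
        return cls(name=name, mode="metadata", **table[name])


@dataclass
class ContrastiveBatch:
    """2*batch_size views with per-anchor candidate set A(i) and positives P(i).

    Views are ordered [first views of the B pairs, second views of the B
    pairs], so view i's same-pair partner is i +/- batch_size.
    """

    views: list[Spectrogram]
    recording_indices: list[int]          # dataset index per view
    metadata: pd.DataFrame                # one row per view
    trait_value: tuple | None = None
    positive_sets: list[list[int]] = field(default_factory=list)
    candidate_sets: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.views)
        if n % 2 != 0:
            raise ValueError("a contrastive batch holds 2 x batch_size views")
        if not self.candidate_sets:
            self.candidate_sets = [[j for j in range(n) if j != i]
                                   for i in range(n)]
        if not self.positive_sets:
            self.positive_sets = [[self.partner(i)] for i in range(n)]

    @property
    def batch_size(self) -> int:
        return len(self.views) // 2

    def partner(self, i: int) -> int:
        b = self.batch_size
        return i + b if i < b else i - b


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def _pair_ok(rule: str, loc_a, loc_b) -> bool:
    if rule == "any":
        return True
    if pd.isna(loc_a) or pd.isna(loc_b):
        return False
    if rule == "same_location":
        return loc_a == loc_b
    if rule == "different_location":
        return loc_a != loc_b
    raise ValueError(f"unknown positive rule {rule!r}")


def eligible_pairs(dataset: SpectrogramDataset, scheme: SchemeConfig
                   ) -> dict[str, list[tuple[int, int]]]:
    """All same-patient recording pairs satisfying the scheme's positive rule."""
    meta = dataset.metadata
    out: dict[str, list[tuple[int, int]]] = {}
    for patient, rows in meta.groupby("patient_id", sort=True):
        idx = list(rows.index)
        pairs = [(i, j) for i, j in combinations(idx, 2)
                 if _pair_ok(scheme.positive_rule,
                             meta.at[i, "location"], meta.at[j, "location"])]
        out[str(patient)] = pairs
    return out


def _trait_value(meta: pd.DataFrame, row: int, trait: tuple[str, ...]) -> tuple:
    return tuple(meta.at[row, f] for f in trait)


def _eligible_patients_by_trait(dataset: SpectrogramDataset, scheme: SchemeConfig
                                ) -> dict[tuple, dict[str, list[tuple[int, int]]]]:
    """trait value -> {patient -> eligible pairs consistent with that value}."""
    meta = dataset.metadata
    pairs = eligible_pairs(dataset, scheme)
    cells: dict[tuple, dict[str, list[tuple[int, int]]]] = {}
    for patient, plist in pairs.items():
        for (i, j) in plist:
            vi = _trait_value(meta, i, scheme.negative_trait)
            vj = _trait_value(meta, j, scheme.negative_trait)
            if vi != vj or any(pd.isna(x) for x in vi):
                continue
            cells.setdefault(vi, {}).setdefault(patient, []).append((i, j))
    return cells


# ---------------------------------------------------------------------------
# Positive-view streams and batches
# ---------------------------------------------------------------------------

def positive_views_same_patient(dataset: SpectrogramDataset, scheme: SchemeConfig,
                                rng: np.random.Generator
                                ) -> Iterator[tuple[int, int]]:
    """One eligible same-patient pair per patient, in shuffled patient order.

    Patients with no pair satisfying the positive rule are skipped with a
    logged warning; a dataset with zero eligible patients is an error.
    """
    pairs = eligible_pairs(dataset, scheme)
    eligible = {p: v for p, v in pairs.items() if v}
    if not eligible:
        raise ValueError(f"no patient has an eligible pair under scheme "
                         f"{scheme.name!r}")
    for p in sorted(pairs):
        if p not in eligible:
            logger.warning("patient %s has no eligible pair under %s; skipped",
                           p, scheme.name)
    order = sorted(eligible)
    rng.shuffle(order)
    for p in order:
        plist = eligible[p]
        yield plist[int(rng.integers(len(plist)))]


def build_negative_constrained_batches(dataset: SpectrogramDataset,
                                       scheme: SchemeConfig, batch_size: int,
                                       rng: np.random.Generator,
                                       n_batches: int | None = None
                                       ) -> Iterator[ContrastiveBatch]:
    """Batches in which every member shares the negative-selection trait.

    A trait value with at least ``batch_size`` eligible patients is drawn
    with probability proportional to its eligible-patient count; the batch
    is then ``batch_size`` distinct patients from that cell, each
    contributing one eligible same-patient pair (uniform among its pairs).
    """
    if not scheme.negative_trait:
        raise ValueError("scheme has no negative-selection trait")
    cells = _eligible_patients_by_trait(dataset, scheme)
    feasible = {v: pat for v, pat in cells.items() if len(pat) >= batch_size}
    if not feasible:
        counts = {str(v): len(pat) for v, pat in sorted(cells.items())}
        raise ValueError(
            f"no trait value has >= {batch_size} eligible patients under "
            f"{scheme.name!r}; per-value counts: {counts}")
    values = sorted(feasible)
    weights = np.array([len(feasible[v]) for v in values], dtype=np.float64)
    weights /= weights.sum()
    count = 0
    while n_batches is None or count < n_batches:
        v = values[int(rng.choice(len(values), p=weights))]
        patients = sorted(feasible[v])
        chosen = rng.choice(len(patients), size=batch_size, replace=False)
        first, second, rows = [], [], []
        for ci in chosen:
            plist = feasible[v][patients[ci]]
            i, j = plist[int(rng.integers(len(plist)))]
            first.append(i)
            second.append(j)
        indices = first + second
        batch = ContrastiveBatch(
            views=[dataset.spectrograms[k] for k in indices],
            recording_indices=indices,
            metadata=dataset.metadata.iloc[indices].reset_index(drop=True),
            trait_value=v,
        )
        yield batch
        count += 1


def build_unconstrained_batches(dataset: SpectrogramDataset, scheme: SchemeConfig,
                                batch_size: int, rng: np.random.Generator,
                                n_batches: int | None = None,
                                view_fn: Callable[[Spectrogram, np.random.Generator],
                                                  Spectrogram] | None = None
                                ) -> Iterator[ContrastiveBatch]:
    """Batches without a trait constraint (augmentation mode and pos_* schemes).

    In augmentation mode each of ``batch_size`` distinct patients contributes
    one recording, and the two views are independent applications of
    ``view_fn``.  In metadata mode the two views are an eligible same-patient
    recording pair, un-augmented.
    """
    meta = dataset.metadata
    if scheme.mode == "augmentation":
        if view_fn is None:
            raise ValueError("augmentation mode needs a view_fn")
        by_patient = {str(p): list(rows.index)
                      for p, rows in meta.groupby("patient_id", sort=True)}
        patients = sorted(by_patient)
        if len(patients) < batch_size:
            raise ValueError(f"need >= {batch_size} patients, have {len(patients)}")
        count = 0
        while n_batches is None or count < n_batches:
            chosen = rng.choice(len(patients), size=batch_size, replace=False)
            recs = [by_patient[patients[c]][int(rng.integers(
                len(by_patient[patients[c]])))] for c in chosen]
            views = ([view_fn(dataset.spectrograms[r], rng) for r in recs]
                     + [view_fn(dataset.spectrograms[r], rng) for r in recs])
            yield ContrastiveBatch(
                views=views, recording_indices=recs + recs,
                metadata=meta.iloc[recs + recs].reset_index(drop=True))
            count += 1
        return

    pairs = eligible_pairs(dataset, scheme)
    eligible = {p: v for p, v in pairs.items() if v}
    if len(eligible) < batch_size:
        raise ValueError(f"need >= {batch_size} patients with eligible pairs, "
                         f"have {len(eligible)}")
    patients = sorted(eligible)
    count = 0
    while n_batches is None or count < n_batches:
        chosen = rng.choice(len(patients), size=batch_size, replace=False)
        first, second = [], []
        for c in chosen:
            plist = eligible[patients[c]]
            i, j = plist[int(rng.integers(len(plist)))]
            first.append(i)
            second.append(j)
        indices = first + second
        batch = ContrastiveBatch(
            views=[dataset.spectrograms[k] for k in indices],
            recording_indices=indices,
            metadata=meta.iloc[indices].reset_index(drop=True))
        if scheme.weak_label_field:
            batch.positive_sets = weak_label_positives(batch,
                                                       scheme.weak_label_field)
        yield batch
        count += 1


def batch_stream(dataset: SpectrogramDataset, scheme: SchemeConfig,
                 batch_size: int, rng: np.random.Generator,
                 n_batches: int | None = None,
                 view_fn=None) -> Iterator[ContrastiveBatch]:
    """Dispatch to constrained or unconstrained batch generation."""
    if scheme.negative_trait:
        return build_negative_constrained_batches(dataset, scheme, batch_size,
                                                  rng, n_batches)
    return build_unconstrained_batches(dataset, scheme, batch_size, rng,
                                       n_batches, view_fn=view_fn)


def weak_label_positives(batch: ContrastiveBatch, fld: str) -> list[list[int]]:
    """P(i) = same-field views plus, always, the same-pair partner."""
    values = batch.metadata[fld]
    if values.isna().any():
        raise ValueError(f"field {fld!r} missing for some batch members")
    n = len(batch.views)
    out = []
    for i in range(n):
        P = {j for j in range(n) if j != i and values.iloc[j] == values.iloc[i]}
        P.add(batch.partner(i))
        out.append(sorted(P))
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_batch(batch: ContrastiveBatch, scheme: SchemeConfig) -> list[dict]:
    """Machine-readable check of batch invariants and scheme constraints."""
    violations: list[dict] = []
    n = len(batch.views)
    meta = batch.metadata

    if n != 2 * batch.batch_size:
        violations.append({"check": "view_count", "detail": n})
    for i in range(n):
        A = batch.candidate_sets[i]
        P = batch.positive_sets[i]
        if sorted(A) != [j for j in range(n) if j != i]:
            violations.append({"check": "candidate_set", "index": i})
        if not P:
            violations.append({"check": "empty_positive_set", "index": i})
        elif not set(P) <= set(A):
            violations.append({"check": "positives_not_in_candidates", "index": i})

    b = batch.batch_size
    pairs = [(i, i + b) for i in range(b)]
    for i, j in pairs:
        if meta.at[i, "patient_id"] != meta.at[j, "patient_id"]:
            violations.append({"check": "pair_not_same_patient", "index": i})
        if scheme.mode == "metadata":
            if batch.recording_indices[i] == batch.recording_indices[j]:
                violations.append({"check": "pair_not_distinct_recordings",
                                   "index": i})
            if not _pair_ok(scheme.positive_rule, meta.at[i, "location"],
                            meta.at[j, "location"]):
                violations.append({"check": "positive_rule", "index": i})

    first_patients = [meta.at[i, "patient_id"] for i in range(b)]
    if len(set(first_patients)) != b:
        violations.append({"check": "patients_not_distinct",
                           "detail": first_patients})

    if scheme.negative_trait:
        values = [tuple(meta.at[i, f] for f in scheme.negative_trait)
                  for i in range(n)]
        for i, v in enumerate(values):
            if v != values[0]:
                violations.append({"check": "trait_mismatch", "index": i,
                                   "detail": {"expected": values[0], "got": v}})
    return violations
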