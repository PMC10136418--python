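"""Endotype-stratified 50-50 train/test partitionings.

The stability protocol needs repeated, disjoint half-splits of the cohort
in which every endotype (and the unlabeled group, treated as one stratum)
is equally represented on both sides.  Three independent partitionings are
drawn by default; each shuffles every stratum with a seeded generator and
splits it half/half, alternating across partitionings which side receives
the odd stratum's extra patient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitSet", "stratified_splits"]


@dataclass
class SplitSet:
    """Stratified partitionings: pairs of (train, test) positional indices."""

    partitionings: list[tuple[np.ndarray, np.ndarray]]
    strata: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.partitionings)

    def validate(self) -> None:
        n = len(self.strata)
        for train, test in self.partitionings:
            if np.intersect1d(train, test).size:
                raise ValueError("train and test overlap")
            union = np.union1d(train, test)
            if union.size != n or union[0] != 0 or union[-1] != n - 1:
                raise ValueError("train and test do not cover all patients")

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "partitionings": [
                {"train": train.tolist(), "test": test.tolist()}
                for train, test in self.partitionings
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path, strata=None) -> "SplitSet":
        with open(path) as fh:
            doc = json.load(fh)
        parts = [
            (np.asarray(p["train"], dtype=int), np.asarray(p["test"], dtype=int))
            for p in doc["partitionings"]
        ]
        n = max(int(max(t.max(), s.max())) for t, s in parts) + 1
        strata = np.zeros(n, dtype=object) if strata is None else np.asarray(strata)
        return cls(partitionings=parts, strata=strata, seed=doc["seed"])


def stratified_splits(
    labels, n_partitionings: int = 3, seed: int = 0
) -> SplitSet:
    """Draw independent stratified 50-50 partitionings of the cohort.

    ``labels`` covers every patient; the unlabeled sentinel forms its own
    stratum.  Within each partitioning every stratum is shuffled (seeded)
    and split half/half, so per-stratum train and test counts differ by at
    most one.  For odd strata the side receiving the extra patient
    alternates across partitionings (and across strata, so a single
    partitioning is not systematically train-heavy).  A stratum of size 1
    triggers a warning and goes to the training side.
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    n = len(labels)
    rng = np.random.default_rng(seed)
    strata_names = sorted(labels.unique())
    partitionings = []
    for j in range(n_partitionings):
        train_parts, test_parts = [], []
        for s_idx, name in enumerate(strata_names):
            members = np.flatnonzero((labels == name).to_numpy())
            if members.size == 1:
                warnings.warn(
                    f"stratum {name!r} has a single patient; assigned to train"
                )
                train_parts.append(members)
                continue
            shuffled = rng.permutation(members)
            half = members.size // 2
            if members.size % 2 == 1 and (j + s_idx) % 2 == 1:
                cut = half  # extra patient to the test side this round
            else:
                cut = members.size - half  # extra (if any) to train
            train_parts.append(shuffled[:cut])
            test_parts.append(shuffled[cut:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], int)
        partitionings.append((train, test))
    out = SplitSet(
        partitionings=partitionings, strata=labels.to_numpy(), seed=seed
    )
    out.validate()
    return out
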