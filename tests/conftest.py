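"""Shared fixtures: small synthetic tables and independent metric oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tinnibench import ColumnSchema, PatientTable


def make_mixed_table(n: int = 60, seed: int = 0) -> PatientTable:
    """Small fully observed mixed table with mild correlated structure."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    data = pd.DataFrame(
        {
            "score_a": 50 + 10 * z + rng.normal(0, 3, n),
            "score_b": 20 - 5 * z + rng.normal(0, 2, n),
            "score_c": rng.normal(0, 1, n),
            "flag": np.where(z > 0.3, "yes", "no"),
            "grade": rng.choice(["low", "mid", "high"], size=n),
        }
    )
    schema = {
        "score_a": ColumnSchema("quantitative"),
        "score_b": ColumnSchema("quantitative"),
        "score_c": ColumnSchema("quantitative"),
        "flag": ColumnSchema("categorical", ("yes", "no")),
        "grade": ColumnSchema("categorical", ("low", "mid", "high")),
    }
    return PatientTable(data, schema)


@pytest.fixture
def mixed_table() -> PatientTable:
    return make_mixed_table()


def mc_expected_mi(
    u, v, n_perm: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo permutation estimate of E{MI} with its standard error.

    Independent oracle for the closed-form expected mutual information:
    shuffles one labeling relative to the other (the fixed-marginal
    permutation null) and averages the contingency MI.
    """
    rng = np.random.default_rng(seed)
    u = np.asarray(u)
    v = np.asarray(v)
    n = u.size
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    ku, kv = ui.max() + 1, vi.max() + 1
    u_onehot = np.zeros((n, ku))
    u_onehot[np.arange(n), ui] = 1.0
    v_onehot = np.zeros((n, kv))
    v_onehot[np.arange(n), vi] = 1.0
    outer = np.outer(u_onehot.sum(0), v_onehot.sum(0))
    mis = np.empty(n_perm)
    batch = 4000
    for start in range(0, n_perm, batch):
        m = min(batch, n_perm - start)
        idx = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
        counts = np.einsum("ni,mnj->mij", u_onehot, v_onehot[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts / n * (np.log(counts * n) - np.log(outer))
        terms = np.where(counts > 0, terms, 0.0)
        mis[start : start + m] = terms.sum(axis=(1, 2))
    return float(mis.mean()), float(mis.std(ddof=1) / np.sqrt(n_perm))


def mca_row_coordinates(indicator: np.ndarray, n_components: int) -> np.ndarray:
    """Row principal coordinates of a correspondence analysis of an
    indicator matrix — the textbook MCA, used as an independent oracle."""
    grand = indicator.sum()
    P = indicator / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, _ = np.linalg.svd(S, full_matrices=False)
    coords = (U * s) / np.sqrt(r)[:, None]
    return coords[:, :n_components]
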