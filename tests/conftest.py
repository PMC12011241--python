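"""Shared fixtures and the independent brute-force ANOVA oracle.

The oracle computes every repeated-measures sum of squares directly from
textbook marginal-mean formulas with explicit Python loops — deliberately
a different code path from the package's projection-based engine.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gaitlat.synthetic_gait import SyntheticConfig


def brute_force_rm_anova_2way(y: np.ndarray) -> dict[str, tuple[float, float]]:
    """(N, a, b) cube -> {effect: (SS_effect, SS_error)} by direct formulas."""
    N, a, b = y.shape
    m = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_i = y.mean(axis=(0, 2))
    m_j = y.mean(axis=(0, 1))
    m_si = y.mean(axis=2)
    m_sj = y.mean(axis=1)
    m_ij = y.mean(axis=0)
    ss_a = N * b * sum((m_i[i] - m) ** 2 for i in range(a))
    ss_as = b * sum((m_si[s, i] - m_s[s] - m_i[i] + m) ** 2
                    for s in range(N) for i in range(a))
    ss_b = N * a * sum((m_j[j] - m) ** 2 for j in range(b))
    ss_bs = a * sum((m_sj[s, j] - m_s[s] - m_j[j] + m) ** 2
                    for s in range(N) for j in range(b))
    ss_ab = N * sum((m_ij[i, j] - m_i[i] - m_j[j] + m) ** 2
                    for i in range(a) for j in range(b))
    ss_abs = sum((y[s, i, j] - m_si[s, i] - m_sj[s, j] - m_ij[i, j]
                  + m_s[s] + m_i[i] + m_j[j] - m) ** 2
                 for s in range(N) for i in range(a) for j in range(b))
    return {"A": (ss_a, ss_as), "B": (ss_b, ss_bs), "AB": (ss_ab, ss_abs)}


def brute_force_rm_anova_3way(y: np.ndarray) -> dict[str, tuple[float, float]]:
    """(N, a, b, c) cube -> {effect: (SS_effect, SS_error)} by direct formulas."""
    N, a, b, c = y.shape
    m = y.mean()
    m_s = y.mean(axis=(1, 2, 3))
    m_i = y.mean(axis=(0, 2, 3))
    m_j = y.mean(axis=(0, 1, 3))
    m_k = y.mean(axis=(0, 1, 2))
    m_si = y.mean(axis=(2, 3))
    m_sj = y.mean(axis=(1, 3))
    m_sk = y.mean(axis=(1, 2))
    m_ij = y.mean(axis=(0, 3))
    m_ik = y.mean(axis=(0, 2))
    m_jk = y.mean(axis=(0, 1))
    m_sij = y.mean(axis=3)
    m_sik = y.mean(axis=2)
    m_sjk = y.mean(axis=1)
    m_ijk = y.mean(axis=0)
    out = {}
    out["A"] = (
        N * b * c * sum((m_i[i] - m) ** 2 for i in range(a)),
        b * c * sum((m_si[s, i] - m_s[s] - m_i[i] + m) ** 2
                    for s in range(N) for i in range(a)))
    out["B"] = (
        N * a * c * sum((m_j[j] - m) ** 2 for j in range(b)),
        a * c * sum((m_sj[s, j] - m_s[s] - m_j[j] + m) ** 2
                    for s in range(N) for j in range(b)))
    out["C"] = (
        N * a * b * sum((m_k[k] - m) ** 2 for k in range(c)),
        a * b * sum((m_sk[s, k] - m_s[s] - m_k[k] + m) ** 2
                    for s in range(N) for k in range(c)))
    out["AB"] = (
        N * c * sum((m_ij[i, j] - m_i[i] - m_j[j] + m) ** 2
                    for i in range(a) for j in range(b)),
        c * sum((m_sij[s, i, j] - m_si[s, i] - m_sj[s, j] - m_ij[i, j]
                 + m_s[s] + m_i[i] + m_j[j] - m) ** 2
                for s in range(N) for i in range(a) for j in range(b)))
    out["AC"] = (
        N * b * sum((m_ik[i, k] - m_i[i] - m_k[k] + m) ** 2
                    for i in range(a) for k in range(c)),
        b * sum((m_sik[s, i, k] - m_si[s, i] - m_sk[s, k] - m_ik[i, k]
                 + m_s[s] + m_i[i] + m_k[k] - m) ** 2
                for s in range(N) for i in range(a) for k in range(c)))
    out["BC"] = (
        N * a * sum((m_jk[j, k] - m_j[j] - m_k[k] + m) ** 2
                    for j in range(b) for k in range(c)),
        a * sum((m_sjk[s, j, k] - m_sj[s, j] - m_sk[s, k] - m_jk[j, k]
                 + m_s[s] + m_j[j] + m_k[k] - m) ** 2
                for s in range(N) for j in range(b) for k in range(c)))
    out["ABC"] = (
        N * sum((m_ijk[i, j, k] - m_ij[i, j] - m_ik[i, k] - m_jk[j, k]
                 + m_i[i] + m_j[j] + m_k[k] - m) ** 2
                for i in range(a) for j in range(b) for k in range(c)),
        sum((y[s, i, j, k]
             - m_sij[s, i, j] - m_sik[s, i, k] - m_sjk[s, j, k] - m_ijk[i, j, k]
             + m_si[s, i] + m_sj[s, j] + m_sk[s, k]
             + m_ij[i, j] + m_ik[i, k] + m_jk[j, k]
             - m_s[s] - m_i[i] - m_j[j] - m_k[k] + m) ** 2
            for s, i, j, k in itertools.product(
                range(N), range(a), range(b), range(c))))
    return out


@pytest.fixture(scope="session")
def fast_config() -> SyntheticConfig:
    """Small, quick cohort configuration for structural tests."""
    return SyntheticConfig(n_participants=4, trial_s=16.0, master_seed=321)


@pytest.fixture(scope="session")
def noise_free_config() -> SyntheticConfig:
    """No measurement noise: pipeline output should match ground truth."""
    return SyntheticConfig(n_participants=4, trial_s=16.0, noise_sd=0.0,
                           master_seed=99)
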