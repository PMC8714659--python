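"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: seed
sites by per-position base comparison with modular arithmetic, t-tail
probabilities by numeric integration of the density, hypergeometric tails
by enumeration over binomial coefficients, and BH by a from-scratch
step-up. Tests compare the package against these.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pandas as pd
import pytest

from cernet import ExpressionMatrix, SimulationConfig, generate_dataset

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def oracle_seed_sites(mirna: str, target_seq: str, circular: bool) -> list[tuple[int, str]]:
    """Naive per-position seed scan; (start, site_type), sorted."""
    mirna = mirna.upper().replace("T", "U")
    seq = target_seq.upper().replace("T", "U")
    L = len(seq)

    def base(i: int) -> str | None:
        if circular:
            return seq[i % L]
        return seq[i] if 0 <= i < L else None

    out = []
    for c in range(L if circular else max(L - 5, 0)):
        # target positions c..c+5 pair miRNA positions 7..2 antiparallel
        if any(base(c + j) != _COMP[mirna[6 - j]] for j in range(6)):
            continue
        m8 = base(c - 1) == _COMP[mirna[7]]
        a1 = base(c + 6) == "A"
        if m8 and a1 and L >= 8:
            start, stype = c - 1, "8mer"
        elif m8 and L >= 7:
            start, stype = c - 1, "7mer-m8"
        elif a1 and L >= 7:
            start, stype = c, "7mer-A1"
        else:
            start, stype = c, "6mer"
        out.append((start % L if circular else start, stype))
    return sorted(out)


def oracle_pooled_t(case: list[float], control: list[float]) -> tuple[float, float, int]:
    """Pooled-variance t statistic, two-tailed p by numeric integration."""
    from scipy.integrate import quad

    n1, n0 = len(case), len(control)
    m1, m0 = sum(case) / n1, sum(control) / n0
    ss = sum((x - m1) ** 2 for x in case) + sum((x - m0) ** 2 for x in control)
    df = n1 + n0 - 2
    se = math.sqrt(ss / df * (1 / n1 + 1 / n0))
    t = (m1 - m0) / se
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(x: float) -> float:
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(density, abs(t), np.inf)
    return t, 2 * tail, df


def oracle_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by summing hypergeometric point masses."""
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


def oracle_bh(p: list[float]) -> list[float]:
    """From-scratch Benjamini-Hochberg step-up with monotonicity."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def random_rna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(length))


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 features x 4 samples, hand-enterable values."""
    values = pd.DataFrame(
        {
            "case_1": [10.0, 8.0, 5.0, 7.0],
            "case_2": [10.5, 8.2, 5.1, 7.1],
            "control_1": [8.0, 8.1, 5.0, 7.2],
            "control_2": [8.4, 8.0, 5.2, 7.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    kinds = pd.Series(["mRNA", "mRNA", "lncRNA", "circRNA"], index=values.index)
    groups = pd.Series(
        ["case", "case", "control", "control"], index=values.columns
    )
    return ExpressionMatrix(values, kinds, groups)


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Default-shape synthetic study at zero noise, 5 planted triples."""
    cfg = SimulationConfig(n_triples=5, noise_sd=0.0, rng_seed=7)
    return cfg, *generate_dataset(cfg)
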