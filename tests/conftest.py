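import numpy as np
import pytest

from triagekit import CohortTable, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """Seeded synthetic cohort small enough for fast unit tests."""
    return generate_cohort(SimulationConfig(n_cu=120, n_ci=180, seed=42))


@pytest.fixture
def toy_scores():
    """The 20-subject toy: negatives 1..10, positives 8..17 (3 overlaps)."""
    neg = np.arange(1.0, 11.0)
    pos = np.arange(8.0, 18.0)
    scores = np.concatenate([neg, pos])
    labels = np.concatenate([np.zeros(10, int), np.ones(10, int)])
    return scores, labels


def brute_force_auc(scores, labels) -> float:
    """Pair-counting oracle: fraction of (pos, neg) pairs won, ties credited 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def delong_components_oracle(scores, labels):
    """O(n^2) placement-value oracle for the DeLong variance."""
    pos = np.asarray([s for s, y in zip(scores, labels) if y == 1])
    neg = np.asarray([s for s, y in zip(scores, labels) if y == 0])
    m, n = len(pos), len(neg)
    psi = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            psi[i, j] = 1.0 if pos[i] > neg[j] else (0.5 if pos[i] == neg[j] else 0.0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    auc = psi.mean()
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return auc, var, v10, v01


def exhaustive_cutoff_scan(scores, labels, objective, constraint, floor):
    """Enumeration oracle over midpoint thresholds (+-inf sentinels).

    objective/constraint in {"sens", "spec"}; returns (threshold, sens, spec)
    of the objective-maximising feasible threshold, ties broken towards the
    smallest constraint value.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    u = np.unique(scores)
    thresholds = [np.inf] + [(a + b) / 2 for a, b in zip(u[:-1], u[1:])] + [-np.inf]
    best = None
    for t in thresholds:
        pred = scores >= t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        vals = {"sens": sens, "spec": spec}
        if vals[constraint] < floor - 1e-12:
            continue
        key = (vals[objective], -vals[constraint])
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]
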