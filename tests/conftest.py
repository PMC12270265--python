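import numpy as np
import pytest

from grsim import (
    SimulationConfig,
    build_fixture_bundle,
    default_fixture_spec,
    simulate_array,
)


def pearson_oracle(x, y) -> float:
    """Textbook covariance/variance Pearson formula, implemented independently
    of the package's code paths (plain Python loop)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def auc_oracle(cases, controls) -> float:
    """O(n^2) pairwise Mann-Whitney AUC with ties counted 1/2."""
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


class UnionFind:
    """Independent connected-components oracle."""

    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for item in self.parent:
            groups.setdefault(self.find(item), set()).add(item)
        return {frozenset(g) for g in groups.values()}


@pytest.fixture(scope="session")
def default_bundle():
    """The standard 8-SNP truth bundle (N=2000, seed 7)."""
    spec = default_fixture_spec()
    X_truth, stats, corr, model = build_fixture_bundle(spec)
    return spec, X_truth, stats, corr, model


@pytest.fixture(scope="session")
def default_simulation(default_bundle):
    """One simulation of the default bundle at the default configuration."""
    _, _, stats, corr, _ = default_bundle
    config = SimulationConfig(n_samples=2000, seed=11)
    X_sim, report = simulate_array(stats, corr, config)
    return config, X_sim, report
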