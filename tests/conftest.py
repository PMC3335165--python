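import numpy as np
import pandas as pd
import pytest

from cnax.simulate import AberrationEvent, SimulationConfig, make_clone_map, simulate_acgh


def small_events():
    """Events on low-numbered chromosomes so tiny genomes carry signal."""
    return (
        AberrationEvent("chr1", 5, 20, +0.6, 0.5),
        AberrationEvent("chr2", 10, 30, -0.6, 0.4),
        AberrationEvent("chr3", 0, 12, +0.9, 0.2),
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples=20, n_chromosomes=3, clones_per_chrom=40,
        aberration_spec=small_events(), n_expr_clones=120,
        missing_rate=0.03, seed=11,
    )


@pytest.fixture(scope="session")
def small_acgh(small_config):
    cm = make_clone_map(small_config)
    matrix, truth = simulate_acgh(cm, small_config)
    return cm, matrix, truth


@pytest.fixture()
def tiny_map():
    rows = []
    for chrom, n in (("chr1", 6), ("chr2", 4)):
        for i in range(n):
            rows.append((f"{chrom}_c{i}", chrom, i * 1000, (i + 1) * 1000,
                         "p" if i < n // 2 else "q"))
    cm = pd.DataFrame(rows, columns=["clone_id", "chromosome", "start", "end", "arm"])
    cm["position"] = (cm["start"] + cm["end"]) / 2.0
    return cm


def brute_force_bh(p):
    """Independent step-up BH oracle: q_(i) = min_{j>=i} (m/j) p_(j), clipped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, m / (rank + 1) * p[order[rank]])
        q_sorted[rank] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
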