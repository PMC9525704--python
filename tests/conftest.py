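import itertools

import numpy as np
import pytest

from panelminer import PlantedRule, SimConfig, generate_cohort

# ---------------------------------------------------------------------------
# shared cohorts


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_features=80,
        class_sizes=(12, 8, 5),
        n_redundant_blocks=2,
        block_size=3,
        n_constant=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def planted_config() -> SimConfig:
    """Mid-size three-subtype cohort with a planted high/high class-1 rule."""
    return SimConfig(
        n_features=300,
        class_sizes=(60, 32, 10),
        class_names=("KIRC", "KIRP", "KICH"),
        n_redundant_blocks=3,
        block_size=4,
        n_constant=5,
        planted_rules=(
            PlantedRule(("planted_a", "planted_b"), ("high", "high"), "KIRC"),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    return generate_cohort(planted_config)


# ---------------------------------------------------------------------------
# independent oracles


def apriori_oracle(transactions, min_support, max_length):
    """Brute-force frequent-itemset enumeration (independent of FP-Growth)."""
    n = len(transactions)
    items = sorted({it for t in transactions for it in t})
    out = {}
    for size in range(1, max_length + 1):
        any_frequent = False
        for combo in itertools.combinations(items, size):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t)
            if count / n >= min_support - 1e-12:
                out[s] = count
                any_frequent = True
        if not any_frequent:
            break
    return out


def brute_force_mis_size(adj: np.ndarray) -> int:
    """Maximum independent set size by exhaustive subset enumeration."""
    m = adj.shape[0]
    best = 0
    for mask in range(1 << m):
        nodes = [i for i in range(m) if mask >> i & 1]
        if all(not adj[i, j] for i, j in itertools.combinations(nodes, 2)):
            best = max(best, len(nodes))
    return best


def random_transaction_db(rng: np.random.Generator, n_items=None, n_txn=None):
    """Random small transaction database over single-letter items."""
    n_items = n_items or rng.integers(3, 13)
    n_txn = n_txn or rng.integers(5, 41)
    alphabet = [("item", chr(97 + i)) for i in range(n_items)]
    txns = []
    for _ in range(n_txn):
        p = rng.uniform(0.2, 0.7)
        chosen = [it for it in alphabet if rng.random() < p]
        if not chosen:
            chosen = [alphabet[int(rng.integers(n_items))]]
        txns.append(frozenset(chosen))
    return txns
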