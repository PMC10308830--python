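import numpy as np
import pytest

from chembib.corpus import CitationRecord, Corpus
from chembib.synthetic import SyntheticConfig, generate, synthetic_casrns


@pytest.fixture
def toy_corpus() -> Corpus:
    """Three-year toy corpus with known hand-computable aggregates.

    A: 1999 (x2 records), 2001; B: 2001, 2005; C: 2005.
    """
    return Corpus(
        [
            CitationRecord("r1", 1999, {"ANST", "POL"}, {"50-00-0"}),
            CitationRecord("r2", 1999, {"ANST", "POL"}, {"50-00-0", "71-43-2"}),
            CitationRecord("r3", 2001, {"ANST"}, {"50-00-0", "71-43-2"}),
            CitationRecord("r4", 2005, {"BIOL"}, {"71-43-2", "7439-92-1"}),
            CitationRecord("r5", 2005, {"ANST", "POL", "BIOL"}, {"7439-92-1"}),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small generated corpus + ground truth shared across tests."""
    cfg = SyntheticConfig(
        n_substances=300,
        years=(2000, 2011),
        base_records_per_year=40,
        annual_growth_rate=1.05,
        seed=42,
    )
    return cfg, *generate(cfg)


def random_corpus(rng: np.random.Generator, n_substances: int = 20, n_records: int = 40) -> Corpus:
    """Arbitrary valid corpus for property tests."""
    casrns = synthetic_casrns(n_substances)
    records = []
    for i in range(n_records):
        k = int(rng.integers(1, 5))
        chosen = rng.choice(n_substances, size=k, replace=False)
        year = int(rng.integers(1995, 2006))
        roles = frozenset(rng.choice(["ANST", "POL", "BIOL"], size=int(rng.integers(1, 4)), replace=False))
        records.append(CitationRecord(f"r{i}", year, roles, frozenset(casrns[j] for j in chosen)))
    return Corpus(records)
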