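import numpy as np
import pytest
from hypothesis import settings

from plbreed.rankings import Ranking, RankingSet

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def abc_rankings() -> RankingSet:
    """A small strongly connected 3-item set."""
    return RankingSet(
        [
            Ranking("f1", ("A", "B", "C")),
            Ranking("f2", ("A", "C", "B")),
            Ranking("f3", ("B", "A", "C")),
            Ranking("f4", ("C", "A", "B")),
            Ranking("f5", ("A", "B", "C")),
            Ranking("f6", ("B", "C", "A")),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def simulate_rankings(
    log_worths: np.ndarray,
    items: list[str],
    n_records: int,
    set_size: int,
    rng: np.random.Generator,
    season_of=None,
) -> RankingSet:
    """Sample grouped Luce rankings of random item subsets (test helper)."""
    n = len(items)
    records = []
    for i in range(n_records):
        subset = rng.choice(n, size=set_size, replace=False)
        scores = log_worths[subset] + rng.gumbel(size=set_size)
        order = subset[np.argsort(-scores)]
        records.append(
            Ranking(
                group=f"f{i:05d}",
                ordering=tuple(items[j] for j in order),
                season=None if season_of is None else season_of(i),
            )
        )
    return RankingSet(records, items=items)
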