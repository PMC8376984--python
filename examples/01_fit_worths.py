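"""Fit Plackett-Luce worths to a handful of farmer rankings.

Builds six rankings of three genotypes, fits worths by maximum
likelihood, and prints each genotype's worth -- its probability of
winning against all the others (Eq.-style sum-to-one gauge).
"""

import numpy as np

from plbreed import fit_pl
from plbreed.rankings import Ranking, RankingSet

rankings = RankingSet(
    [
        Ranking("farm1", ("landrace_A", "landrace_B", "improved_C")),
        Ranking("farm2", ("landrace_A", "improved_C", "landrace_B")),
        Ranking("farm3", ("landrace_B", "landrace_A", "improved_C")),
        Ranking("farm4", ("landrace_A", "landrace_B", "improved_C")),
        Ranking("farm5", ("improved_C", "landrace_A", "landrace_B")),
        Ranking("farm6", ("landrace_B", "improved_C", "landrace_A")),
    ]
)

fit = fit_pl(rankings)
print("worths (win probability vs the whole set):")
print(fit.worths.as_series().round(3).to_string())
print(f"log-likelihood {fit.log_likelihood:.3f}, "
      f"converged={fit.converged} in {fit.n_iterations} iterations")
# landrace_A wins most often, so its worth is largest; the worths sum to 1.
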