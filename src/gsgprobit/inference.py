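"""Posterior summaries: gene rankings from retained chain draws."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import ChainResult

__all__ = ["GeneRanking", "inclusion_probabilities", "select_top"]


@dataclass
class GeneRanking:
    """Posterior inclusion probabilities with a deterministic order.

    ``probabilities[j]`` is the exact draw frequency with which gene j
    was selected, (number of retained draws with gamma_j = 1) / M.
    ``order`` lists gene indices by probability descending, ties
    broken by original gene index ascending, so ranked output is
    reproducible.
    """

    probabilities: np.ndarray
    order: np.ndarray
    gene_ids: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.probabilities.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.gene_ids or [f"g{j}" for j in range(self.p)]
        return pd.DataFrame({
            "rank": np.arange(1, self.p + 1),
            "gene_id": [ids[j] for j in self.order],
            "inclusion_probability": self.probabilities[self.order],
        })

    def save_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def inclusion_probabilities(res: ChainResult) -> GeneRanking:
    """Monte-Carlo inclusion frequencies over the retained draws.

    The posterior probability that gene i belongs in the model is
    estimated by the fraction of retained (post burn-in, thinned)
    draws in which gamma_i = 1.
    """
    if res.M < 1:
        raise ValueError("empty draw set")
    G = res.gamma_matrix()
    probs = G.sum(axis=0) / float(res.M)
    p = probs.shape[0]
    order = np.lexsort((np.arange(p), -probs))
    return GeneRanking(probabilities=probs, order=order,
                       gene_ids=list(res.gene_ids))


def select_top(ranking: GeneRanking, p_star: int) -> np.ndarray:
    """Indices of the ``p_star`` most probable genes, best first."""
    if p_star > ranking.p:
        raise ValueError(f"p_star={p_star} exceeds p={ranking.p}")
    if p_star < 0:
        raise ValueError("p_star must be >= 0")
    return ranking.order[:p_star].copy()
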