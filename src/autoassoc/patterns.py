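"""Random stimulus-pattern sets and per-pair coactivation statistics."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .network import NetworkConfig

__all__ = ["PatternSet", "PairCounts", "generate_pattern_set", "count_pair_activity"]


@dataclass(frozen=True)
class PatternSet:
    """A list of stored memories; each is a set of distinct neuron indices."""

    patterns: tuple[tuple[int, ...], ...]
    n_exc: int
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.patterns)

    def membership_matrix(self) -> np.ndarray:
        """Boolean (n_patterns, n_exc) matrix of pattern membership."""
        mat = np.zeros((len(self.patterns), self.n_exc), dtype=bool)
        for p, members in enumerate(self.patterns):
            mat[p, list(members)] = True
        return mat

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_exc": self.n_exc,
                    "seed": self.seed,
                    "patterns": [list(p) for p in self.patterns],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "PatternSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            tuple(tuple(p) for p in data["patterns"]), data["n_exc"], data.get("seed")
        )


@dataclass(frozen=True)
class PairCounts:
    """Per ordered pair (i presyn, j postsyn): joint and independent tallies.

    ``n11[i, j]`` counts stored patterns containing both i and j;
    ``n10``/``n01`` count patterns containing only the pre- or only the
    postsynaptic neuron.  Entries without an anatomical synapse are zeroed.
    """

    n11: np.ndarray
    n10: np.ndarray
    n01: np.ndarray
    n_patterns: int


def generate_pattern_set(
    n_patterns: int, config: NetworkConfig, seed: int | None = None
) -> PatternSet:
    """Sample ``n_patterns`` memories of ``pattern_size`` neurons each.

    Patterns are drawn independently, uniformly without replacement within
    each pattern; overlaps across patterns arise by chance only.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    if config.pattern_size > config.n_exc:
        raise ValueError("pattern_size cannot exceed n_exc")
    if seed is None:
        seed = config.pattern_seed
    rng = np.random.default_rng(seed)
    pats = tuple(
        tuple(
            sorted(
                int(i)
                for i in rng.choice(config.n_exc, size=config.pattern_size, replace=False)
            )
        )
        for _ in range(n_patterns)
    )
    return PatternSet(pats, config.n_exc, seed)


def count_pair_activity(patterns: PatternSet, adjacency: np.ndarray) -> PairCounts:
    """Count joint/independent activations per ordered connected pair.

    n11 is the co-membership Gram matrix of the pattern set; n10 and n01
    follow from each neuron's total membership count.  All three arrays
    are masked to the anatomical adjacency.
    """
    member = patterns.membership_matrix().astype(np.int32)
    n11 = member.T @ member
    totals = member.sum(axis=0)
    n10 = totals[:, None] - n11
    n01 = totals[None, :] - n11
    mask = adjacency.astype(bool)
    return PairCounts(
        n11=np.where(mask, n11, 0),
        n10=np.where(mask, n10, 0),
        n01=np.where(mask, n01, 0),
        n_patterns=len(patterns),
    )
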