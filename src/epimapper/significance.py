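"""Empirical significance of path-alignment scores.

A path score is rated against a background of best-path scores obtained by
running the same search engine on random peptides of the same length over
the same graph.  The empirical P-value uses add-one smoothing,

    p = (1 + #{background >= score}) / (n_samples + 1),

so p is always in (0, 1].  Backgrounds are cached per (graph, peptide
length): a panel containing several peptides of one length pays for a single
background per graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peptide_align import AA_ALPHABET

DEFAULT_N_SAMPLES = 999
DEFAULT_P_CUTOFF = 0.05

_ALPHABET = np.array(list(AA_ALPHABET))


@dataclass
class BackgroundDistribution:
    """Sorted best-path scores of random same-length peptides on one graph."""

    peptide_length: int
    n_samples: int
    sorted_scores: np.ndarray
    seed: object = None

    def __post_init__(self):
        self.sorted_scores = np.sort(np.asarray(self.sorted_scores, dtype=float))
        if self.n_samples < 1:
            raise ValueError("background needs at least one sample")

    def empirical_p(self, score: float) -> float:
        return empirical_p(score, self)


def _random_peptides(length, n, rng, null_model="uniform", query=None):
    if null_model == "shuffle":
        if query is None:
            raise ValueError("composition-preserving null needs the query sequence")
        letters = np.array(list(query))
        return ["".join(rng.permutation(letters)) for _ in range(n)]
    draws = rng.integers(0, len(_ALPHABET), size=(n, length))
    return ["".join(row) for row in _ALPHABET[draws]]


def build_background(
    graph,
    length: int,
    n_samples: int,
    engine,
    seed=None,
    null_model: str = "uniform",
    query: str | None = None,
) -> BackgroundDistribution:
    """Score ``n_samples`` random peptides of ``length`` with ``engine``.

    ``engine`` is any callable mapping a peptide sequence to the best-path
    score on the graph of interest.  The default null draws letters i.i.d.
    uniformly over the 20-letter alphabet; ``null_model="shuffle"`` instead
    permutes the query sequence, preserving its composition.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = _random_peptides(length, n_samples, rng, null_model, query)
    scores = np.array([engine(s) for s in seqs], dtype=float)
    return BackgroundDistribution(
        peptide_length=length, n_samples=n_samples, sorted_scores=scores, seed=seed
    )


def empirical_p(score: float, bg: BackgroundDistribution) -> float:
    """Add-one empirical P-value; monotonically non-increasing in score."""
    n_ge = bg.n_samples - int(np.searchsorted(bg.sorted_scores, score, side="left"))
    return (1 + n_ge) / (bg.n_samples + 1)


class BackgroundCache:
    """Per-run cache of backgrounds keyed by (graph identity, length)."""

    def __init__(self):
        self._store: dict[tuple, BackgroundDistribution] = {}
        self.n_builds = 0

    def get_or_build(
        self,
        graph,
        length: int,
        n_samples: int,
        engine,
        seed=None,
        null_model: str = "uniform",
        query: str | None = None,
    ) -> BackgroundDistribution:
        # the shuffle null is composition-specific, so the query joins the key
        key = (graph.token, length, null_model, query if null_model == "shuffle" else None)
        if key not in self._store:
            self.n_builds += 1
            self._store[key] = build_background(
                graph, length, n_samples, engine, seed=seed,
                null_model=null_model, query=query,
            )
        return self._store[key]
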