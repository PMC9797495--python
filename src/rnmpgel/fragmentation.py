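"""Forward model of genomic fragmentation by uniformly positioned breaks.

Alkaline hydrolysis converts every residual ribonucleotide in genomic DNA
into a single-strand break.  If breaks occur at positions drawn uniformly
along a linear genome of ``m0`` nucleotides, the fragment lengths between
consecutive breaks follow (for many breaks) an exponential distribution
whose mean ``m`` satisfies ``m0 / m ~ number of breaks``.  This module
provides the exact combinatorial sampler used by the gel simulator and the
closed-form relations the downstream estimator inverts.

Break positions are integers sampled *without replacement* from the
``m0 - 1`` internal phosphodiester bonds, so fragment lengths are positive
integers and always sum to ``m0`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FragmentSet",
    "sample_fragments",
    "expected_mean_length",
    "breaks_from_mean",
]


@dataclass(frozen=True)
class FragmentSet:
    """Fragments produced by breaking one linear genome.

    Attributes
    ----------
    lengths : numpy.ndarray
        Fragment lengths in nucleotides (positive integers). For a linear
        genome with ``k`` breaks there are ``k + 1`` fragments and the
        lengths sum to ``genome_size`` exactly.
    genome_size : int
        Original genome size ``m0`` in nucleotides.
    n_breaks : int
        Number of break events.
    seed : int
        Seed used to draw the break positions (-1 for sets not produced by
        :func:`sample_fragments`, e.g. loaded from disk).
    """

    lengths: np.ndarray
    genome_size: int
    n_breaks: int
    seed: int = -1

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=np.int64)
        object.__setattr__(self, "lengths", lengths)
        if lengths.size == 0:
            raise ValueError("FragmentSet needs at least one fragment")
        if (lengths < 1).any():
            raise ValueError("all fragment lengths must be >= 1")
        if int(lengths.sum()) != int(self.genome_size):
            raise ValueError(
                f"fragment lengths sum to {int(lengths.sum())}, "
                f"expected genome_size={self.genome_size}"
            )
        if lengths.size != self.n_breaks + 1:
            raise ValueError(
                f"{lengths.size} fragments inconsistent with "
                f"n_breaks={self.n_breaks} on a linear genome"
            )

    @property
    def mean_length(self) -> float:
        """Sample mean fragment length (nucleotides)."""
        return float(self.lengths.mean())

    def to_csv(self, path: str | Path) -> None:
        """Write fragments as CSV with columns ``fragment_index,length_nt``."""
        df = pd.DataFrame(
            {"fragment_index": np.arange(self.lengths.size), "length_nt": self.lengths}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FragmentSet":
        """Load a fragment set written by :meth:`to_csv`."""
        df = pd.read_csv(path)
        lengths = df["length_nt"].to_numpy(dtype=np.int64)
        return cls(
            lengths=lengths,
            genome_size=int(lengths.sum()),
            n_breaks=int(lengths.size - 1),
        )


def _draw_distinct_positions(n_internal: int, n_breaks: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_breaks`` distinct integers from ``1 .. n_internal`` (inclusive)."""
    if n_breaks == 0:
        return np.empty(0, dtype=np.int64)
    # Rejection sampling keeps memory O(n_breaks) when the genome is huge;
    # fall back to an explicit permutation-based draw when the sampling
    # fraction is large enough that collisions would dominate.
    if n_breaks < 0.01 * n_internal:
        positions = np.unique(rng.integers(1, n_internal + 1, size=int(1.1 * n_breaks) + 16))
        while positions.size < n_breaks:
            extra = rng.integers(1, n_internal + 1, size=n_breaks)
            positions = np.unique(np.concatenate([positions, extra]))
        return rng.permutation(positions)[:n_breaks].astype(np.int64)
    return (rng.choice(n_internal, size=n_breaks, replace=False) + 1).astype(np.int64)


def sample_fragments(genome_size: int, n_breaks: int, seed: int) -> FragmentSet:
    """Fragment a linear genome by breaks at uniform random positions.

    Break positions are drawn uniformly without replacement from the
    ``genome_size - 1`` internal bonds; the returned lengths are the
    consecutive inter-break gaps.  Deterministic for a fixed ``seed``.

    Parameters
    ----------
    genome_size : int
        Genome size ``m0`` in nucleotides (>= 1).
    n_breaks : int
        Number of breaks (>= 0, < ``genome_size``).
    seed : int
        RNG seed (mandatory; there is no global RNG state).

    Returns
    -------
    FragmentSet
    """
    genome_size = int(genome_size)
    n_breaks = int(n_breaks)
    if genome_size < 1:
        raise ValueError("genome_size must be >= 1")
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    if n_breaks >= genome_size:
        raise ValueError(
            f"n_breaks={n_breaks} must be < genome_size={genome_size}: a genome "
            f"of m0 nucleotides has only m0 - 1 breakable bonds"
        )
    rng = np.random.default_rng(seed)
    cuts = np.sort(_draw_distinct_positions(genome_size - 1, n_breaks, rng))
    bounds = np.concatenate([[0], cuts, [genome_size]])
    return FragmentSet(
        lengths=np.diff(bounds), genome_size=genome_size, n_breaks=n_breaks, seed=seed
    )


def expected_mean_length(genome_size: float, n_breaks: int) -> float:
    """Expected mean fragment length ``m0 / (k + 1)`` for ``k`` breaks.

    A linear genome with ``k`` breaks yields exactly ``k + 1`` fragments, so
    the mean length is ``m0 / (k + 1)`` regardless of where the breaks fall.
    For large ``k`` this converges to the ``m0 / k`` used when inverting the
    breakage statistic ``k = m0 / m``.
    """
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    return float(genome_size) / (int(n_breaks) + 1)


def breaks_from_mean(genome_size: float, mean_length: float) -> float:
    """Breaks per genome ``m0 / m`` from the mean fragment length.

    This is the breakage statistic: under uniformly positioned breaks the
    fragment-length distribution is (asymptotically) exponential with mean
    ``m``, and the number of break events — hence incorporated
    ribonucleotides — per genome is ``m0 / m``.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if mean_length <= 0:
        raise ValueError("mean_length must be > 0")
    return float(genome_size) / float(mean_length)
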