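"""Closed-form droplet-campaign and sequence-space arithmetic.

Everything here is deterministic bookkeeping around a sorting campaign:
how many clones a droplet run interrogates, Poisson occupancy
probabilities, gate fractions, library oversampling and coverage, and the
size of protein sequence space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "DropletRun",
    "clones_screened",
    "occupied_droplets",
    "occupancy_pmf",
    "sorted_fraction",
    "oversampling_and_coverage",
    "sequence_space_exponent",
    "campaign_summary",
]


@dataclass(frozen=True)
class DropletRun:
    """One droplet-sorting run: droplets made, mean occupancy, droplets
    sorted, and the nominal library size being screened."""

    n_droplets: float
    lam: float
    n_sorted: float
    library_size: float

    def __post_init__(self) -> None:
        if min(self.n_droplets, self.n_sorted, self.library_size) < 0 or self.lam < 0:
            raise ValueError("all run quantities must be non-negative")
        if self.n_sorted > self.n_droplets:
            raise ValueError("cannot sort more droplets than screened")


def clones_screened(run: DropletRun) -> float:
    """Total cells interrogated: n_droplets x lambda (counts every cell,
    including co-encapsulated ones)."""
    return run.n_droplets * run.lam


def occupied_droplets(run: DropletRun) -> float:
    """Droplets containing at least one cell: n x (1 - e^-lambda)."""
    return run.n_droplets * (1.0 - math.exp(-run.lam))


def occupancy_pmf(lam: float, k: int) -> float:
    """Poisson probability of exactly k cells in a droplet."""
    if lam <= 0 or k < 0:
        raise ValueError("need lambda > 0 and k >= 0")
    return float(stats.poisson.pmf(k, lam))


def sorted_fraction(run: DropletRun) -> float:
    """Gate fraction as a percentage of screened droplets."""
    return 100.0 * run.n_sorted / run.n_droplets


def oversampling_and_coverage(run: DropletRun) -> tuple[float, float]:
    """Library oversampling fold and the fraction of members sampled at
    least once under Poisson sampling (1 - e^-fold)."""
    if run.library_size <= 0:
        raise ValueError("library_size must be positive")
    fold = clones_screened(run) / run.library_size
    return fold, 1.0 - math.exp(-fold)


def sequence_space_exponent(length: int, alphabet_size: int = 20) -> tuple[float, int]:
    """Base-10 exponent of alphabet_size**length.

    Returns the exact exponent (length x log10(alphabet)) and the integer
    exponent of the scientific-notation form (its floor).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    exact = length * math.log10(alphabet_size)
    return exact, math.floor(exact)


def campaign_summary(run: DropletRun) -> dict:
    """All run statistics in one JSON-friendly record."""
    fold, coverage = oversampling_and_coverage(run)
    return {
        "n_droplets": run.n_droplets,
        "lambda": run.lam,
        "clones_screened": clones_screened(run),
        "occupied_droplets": occupied_droplets(run),
        "p_empty": occupancy_pmf(run.lam, 0),
        "p_multiple_given_occupied": float(
            1.0 - occupancy_pmf(run.lam, 1) / (1.0 - occupancy_pmf(run.lam, 0))
        ),
        "n_sorted": run.n_sorted,
        "sorted_fraction_pct": sorted_fraction(run),
        "library_size": run.library_size,
        "oversampling_fold": fold,
        "coverage": coverage,
    }
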