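"""Probability-proportional-to-size (PPS) sampling with replacement.

Within a respondent's region, each block's probability of selection is
proportional to the count of people in the respondent's demographic
stratum living in that block.  Sampling is with replacement: every draw
is an independent categorical draw from the same weight vector, so a
block may be selected repeatedly or not at all, and every draw has the
same marginal distribution.  The draws are implemented by inverse-CDF
lookup on the cumulative weights, which is equivalent to a draw-and-
replace loop.

Reproducibility: each consumer takes its randomness from a named
substream of one master seed (:func:`rng_stream`), so cohorts re-sample
freshly per respondent while whole runs replay exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .geo_model import Block, Region, StratumKey

_WEIGHT_TOL = 1e-12


class ZeroStratumError(ValueError):
    """The region holds nobody in the respondent's stratum: sampling is impossible."""


@dataclass
class WeightVector:
    block_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.block_ids) != len(self.weights):
            raise ValueError("block_ids and weights differ in length")
        if (self.weights < 0).any():
            raise ValueError("negative weight")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")


def rng_stream(master_seed: int, substream_key: str) -> np.random.Generator:
    """Deterministic, independent RNG substream.

    Identical ``(master_seed, substream_key)`` pairs yield identical draw
    sequences; distinct keys yield statistically independent streams.
    """
    digest = hashlib.sha256(substream_key.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed)] + words))


def selection_weights(region: Region, blocks: Mapping[str, Block],
                      stratum: StratumKey) -> WeightVector:
    """Normalized block selection weights for one region and stratum.

    weight_i = count_i / sum(counts); raises :class:`ZeroStratumError`
    when the region holds no one in the stratum.
    """
    ids = tuple(region.block_ids)
    counts = np.array([blocks[b].pop.get(stratum.column, 0) for b in ids],
                      dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ZeroStratumError(
            f"region {region.region_code}: no population in stratum "
            f"{stratum.column}")
    return WeightVector(block_ids=ids, weights=counts / total)


def pps_sample_with_replacement(weight_vector: WeightVector, n: int,
                                rng: np.random.Generator) -> list[str]:
    """Draw ``n`` block IDs i.i.d. with probability proportional to weight."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    cum = np.cumsum(weight_vector.weights)
    cum[-1] = 1.0  # guard against 1 - eps from float accumulation
    idx = np.searchsorted(cum, rng.random(n), side="right")
    return [weight_vector.block_ids[i] for i in idx]
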