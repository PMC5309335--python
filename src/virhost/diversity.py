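"""Richness and phylogenetic diversity from read placements.

Three statistics summarise how a sample's placed reads spread over a
reference tree:

* ``node50`` — the minimal number of most-abundant tree nodes whose read
  counts account for at least half of the sample's reads.  A sample dominated
  by one lineage has node50 = 1; an even sample over k nodes has node50 ≈ k/2.

* ``MPD`` — the mean patristic distance between all pairs of placed reads
  ("hits").  Reads are counted with multiplicity: two reads placed on the
  same node contribute a pair at distance zero, so dominance pulls MPD down.

* ``sesMPD`` — the standardized effect size of MPD against a pooled-
  subsampling null: draw, many times, a random subsample of the same size
  (without replacement) from the hits of all samples mixed together, and
  report ``(observed MPD − mean null MPD) / SD(null MPD)``.  Values near 0
  mean the sample looks like a random slice of the whole survey; negative
  values indicate phylogenetic clustering (low evenness).

MPD is evaluated through node-level counts: with counts ``c`` over the
distinct occupied nodes and patristic matrix ``D`` (zero diagonal),
``MPD = cᵀ D c / (n (n − 1))`` where ``n = Σc``, which equals the all-pairs
mean because same-node pairs contribute zero.  Null subsamples are drawn as
multivariate hypergeometric counts over the pooled node counts — exactly a
simple random sample of reads without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import UndefinedMetricError, ValidationError
from .tree import ReferenceTree

__all__ = ["DiversityResult", "node50", "mpd", "ses_mpd"]

DEFAULT_N_RAND = 100  # randomized subsamples used for the null


@dataclass
class DiversityResult:
    """Per-sample diversity summary with its null-model context."""

    site_id: str | None
    node50: int | None
    mpd_observed: float
    null_mean: float
    null_sd: float
    ses_mpd: float  # NaN when the null SD is zero
    n_randomizations: int
    seed: int | None


def _as_counts(hits: Mapping[str, int] | Iterable[str] | pd.Series) -> dict[str, int]:
    """Normalize a multiset of node hits to a {node: count} map (zeros dropped)."""
    if isinstance(hits, pd.Series):
        items = hits.items()
    elif isinstance(hits, Mapping):
        items = hits.items()
    else:
        counts: dict[str, int] = {}
        for node in hits:
            counts[str(node)] = counts.get(str(node), 0) + 1
        items = counts.items()
    out: dict[str, int] = {}
    for node, c in items:
        c = int(c)
        if c < 0:
            raise ValidationError(f"negative hit count for node {node!r}")
        if c > 0:
            out[str(node)] = out.get(str(node), 0) + c
    return out


def node50(counts: Mapping[str, int] | pd.Series) -> int:
    """Minimal number of most-abundant nodes holding >= 50% of the reads.

    Deterministic under ties: equal counts are interchangeable, so the tie
    ordering cannot change the minimal k.
    """
    clean = _as_counts(counts)
    if not clean:
        raise UndefinedMetricError("node50 undefined: all counts are zero")
    values = np.sort(np.fromiter(clean.values(), dtype=np.int64))[::-1]
    total = values.sum()
    cumulative = np.cumsum(values)
    # smallest k with cumulative[k-1] >= total/2, under integer-exact arithmetic
    k = int(np.searchsorted(2 * cumulative, total, side="left")) + 1
    return k


def _quad_mpd(c: np.ndarray, dist: np.ndarray) -> float:
    """Multiplicity-weighted MPD from node counts ``c`` and distances ``dist``."""
    n = int(c.sum())
    return float(c @ dist @ c) / (n * (n - 1))


def mpd(
    tree: ReferenceTree,
    hits: Mapping[str, int] | Iterable[str],
    presence_only: bool = False,
) -> float:
    """Mean pairwise patristic distance between placed reads.

    With ``presence_only=True`` the multiplicities are ignored and the mean is
    taken over pairs of distinct occupied nodes instead (requires >= 2 nodes).
    """
    counts = _as_counts(hits)
    nodes = sorted(counts)
    dist = tree.distance_matrix(nodes)
    if presence_only:
        if len(nodes) < 2:
            raise UndefinedMetricError("presence-only MPD needs >= 2 distinct nodes")
        k = len(nodes)
        return float(dist.sum()) / (k * (k - 1))
    c = np.array([counts[n] for n in nodes], dtype=float)
    if c.sum() < 2:
        raise UndefinedMetricError("MPD needs at least 2 placed reads")
    return _quad_mpd(c, dist)


def ses_mpd(
    tree: ReferenceTree,
    sample_hits: Mapping[str, int] | Iterable[str],
    pooled_hits: Mapping[str, int] | Iterable[str],
    n_rand: int = DEFAULT_N_RAND,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    presence_only: bool = False,
    with_replacement: bool = False,
    site_id: str | None = None,
) -> DiversityResult:
    """Standardized effect size of MPD under the pooled-subsampling null.

    ``pooled_hits`` must be the union, with multiplicity, of the hits of all
    samples in the survey (the focal sample included).  ``n_rand`` subsamples
    of the focal sample's size are drawn from the pool without replacement
    (or with, if ``with_replacement``); the observed MPD is standardized by
    the null mean and SD.  A degenerate null (SD = 0) yields ``ses_mpd=NaN``
    with the remaining fields still filled.  Fixing ``seed`` fixes every draw.
    """
    sample = _as_counts(sample_hits)
    pool = _as_counts(pooled_hits)
    n_sample = sum(sample.values())
    n_pool = sum(pool.values())
    if n_sample < 2:
        raise UndefinedMetricError("sesMPD needs a sample of >= 2 placed reads")
    if n_pool < n_sample:
        raise ValidationError(f"pool ({n_pool} hits) smaller than sample ({n_sample} hits)")
    missing = set(sample) - set(pool)
    if missing:
        raise ValidationError(f"sample hits absent from pool: {sorted(missing)!r}")

    nodes = sorted(pool)
    dist = tree.distance_matrix(nodes)
    pool_c = np.array([pool[n] for n in nodes], dtype=np.int64)
    sample_c = np.array([sample.get(n, 0) for n in nodes], dtype=float)

    if presence_only:
        observed = mpd(tree, sample, presence_only=True)
    else:
        observed = _quad_mpd(sample_c, dist)

    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(n_rand, dtype=float)
    for i in range(n_rand):
        if with_replacement:
            draw = rng.multinomial(n_sample, pool_c / n_pool)
        else:
            draw = rng.multivariate_hypergeometric(pool_c, n_sample)
        if presence_only:
            present = np.flatnonzero(draw)
            if present.size < 2:
                null[i] = 0.0
                continue
            sub = dist[np.ix_(present, present)]
            null[i] = float(sub.sum()) / (present.size * (present.size - 1))
        else:
            null[i] = _quad_mpd(draw.astype(float), dist)

    null_mean = float(np.mean(null))
    null_sd = float(np.std(null, ddof=1)) if n_rand > 1 else 0.0
    ses = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    return DiversityResult(
        site_id=site_id,
        node50=None,
        mpd_observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        ses_mpd=float(ses),
        n_randomizations=int(n_rand),
        seed=seed,
    )
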