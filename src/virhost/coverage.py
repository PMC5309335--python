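"""Coverage-aware read downsampling for assembly normalization.

Regions of a contig piled high with reads inflate assembly graphs without
adding information.  The normalization step removes reads at random from
positions whose per-base depth exceeds ``mean + k·SD`` of the initial
coverage profile (k = 2 by default), until no position exceeds that
threshold.  The threshold is computed once from the initial profile and
frozen — removals never move the target.  Statistics are per contig by
default (``scope="per_contig"``); ``scope="global"`` pools the positions of
all contigs into one mean/SD.  The SD is the population SD over every
position of the contig, zero-depth positions included.

Removal proceeds greedily: the position with the largest excess over the
threshold is handled first (ties broken toward the leftmost position on the
lexicographically smallest contig) by deleting one uniformly random read
covering it.  Each step removes a read, so termination is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import ReadAlignment

__all__ = ["CoverageProfile", "NormalizationParams", "DownsampleReport", "coverage_profile", "downsample"]


@dataclass
class CoverageProfile:
    contig_id: str
    depth: np.ndarray  # int depth per base position
    contig_length: int

    @property
    def max_depth(self) -> int:
        return int(self.depth.max()) if self.contig_length else 0


@dataclass
class NormalizationParams:
    """Threshold and scope of the downsampling step.

    ``k_sd`` is the number of coverage SDs above the mean tolerated;
    ``scope`` chooses whether mean/SD come from each contig separately or
    from all contigs pooled.
    """

    k_sd: float = 2.0
    scope: str = "per_contig"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValidationError(f"k_sd must be > 0, got {self.k_sd}")
        if self.scope not in ("per_contig", "global"):
            raise ValidationError(f"scope must be 'per_contig' or 'global', got {self.scope!r}")


@dataclass
class DownsampleReport:
    removed_read_ids: list[str]
    thresholds: dict[str, float]  # contig -> frozen threshold T
    initial_max_depth: dict[str, int]
    final_max_depth: dict[str, int]
    n_input: int
    n_retained: int


def _validate_bounds(alignments: Sequence[ReadAlignment], contig_lengths: Mapping[str, int]) -> None:
    for a in alignments:
        if a.contig_id not in contig_lengths:
            raise ValidationError(f"alignment {a.read_id!r}: unknown contig {a.contig_id!r}")
        if a.end > contig_lengths[a.contig_id]:
            raise ValidationError(
                f"alignment {a.read_id!r} ends at {a.end} beyond contig "
                f"{a.contig_id!r} length {contig_lengths[a.contig_id]}"
            )


def coverage_profile(
    alignments: Sequence[ReadAlignment],
    contig_lengths: Mapping[str, int],
) -> list[CoverageProfile]:
    """Per-base read depth for every contig (contigs without reads included)."""
    _validate_bounds(alignments, contig_lengths)
    depths = {c: np.zeros(length, dtype=np.int64) for c, length in contig_lengths.items()}
    for a in alignments:
        depths[a.contig_id][a.start : a.end] += 1
    return [
        CoverageProfile(contig_id=c, depth=depths[c], contig_length=contig_lengths[c])
        for c in sorted(contig_lengths)
    ]


def downsample(
    alignments: Sequence[ReadAlignment],
    contig_lengths: Mapping[str, int],
    params: NormalizationParams | None = None,
) -> tuple[list[ReadAlignment], DownsampleReport]:
    """Randomly remove reads until depth is within ``mean + k_sd·SD`` everywhere.

    Returns the retained alignments (input order preserved) and a report
    naming every removed read; removing exactly those reads from the input
    and re-profiling reproduces the final coverage.  Seeded runs are
    bit-reproducible.
    """
    if params is None:
        params = NormalizationParams()
    if not alignments:
        raise ValidationError("downsample requires at least one alignment")
    _validate_bounds(alignments, contig_lengths)
    rng = np.random.default_rng(params.seed)

    contigs = sorted(contig_lengths)
    depth = {c: np.zeros(contig_lengths[c], dtype=np.int64) for c in contigs}
    for a in alignments:
        depth[a.contig_id][a.start : a.end] += 1

    # Threshold frozen from the initial profile.
    thresholds: dict[str, float] = {}
    if params.scope == "global":
        pooled = np.concatenate([depth[c] for c in contigs]) if contigs else np.zeros(0)
        t_global = float(pooled.mean() + params.k_sd * pooled.std()) if pooled.size else 0.0
        thresholds = {c: t_global for c in contigs}
    else:
        for c in contigs:
            d = depth[c]
            thresholds[c] = float(d.mean() + params.k_sd * d.std()) if d.size else 0.0
    initial_max = {c: int(depth[c].max()) if depth[c].size else 0 for c in contigs}

    retained_mask = np.ones(len(alignments), dtype=bool)
    by_contig: dict[str, list[int]] = {c: [] for c in contigs}
    for i, a in enumerate(alignments):
        by_contig[a.contig_id].append(i)

    removed: list[str] = []
    while True:
        # position with maximal excess; ties -> leftmost on smallest contig id
        best: tuple[str, int, float] | None = None
        for c in contigs:
            d = depth[c]
            if d.size == 0:
                continue
            pos = int(np.argmax(d))  # leftmost maximum
            excess = float(d[pos]) - thresholds[c]
            if excess > 0 and (best is None or excess > best[2]):
                best = (c, pos, excess)
        if best is None:
            break
        contig, pos, _ = best
        covering = [
            i
            for i in by_contig[contig]
            if retained_mask[i] and alignments[i].start <= pos < alignments[i].end
        ]
        if not covering:  # cannot happen while depth[pos] > 0, kept as a guard
            break
        victim = covering[int(rng.integers(len(covering)))]
        retained_mask[victim] = False
        a = alignments[victim]
        depth[contig][a.start : a.end] -= 1
        removed.append(a.read_id)

    retained = [a for i, a in enumerate(alignments) if retained_mask[i]]
    final_max = {c: int(depth[c].max()) if depth[c].size else 0 for c in contigs}
    report = DownsampleReport(
        removed_read_ids=removed,
        thresholds=thresholds,
        initial_max_depth=initial_max,
        final_max_depth=final_max,
        n_input=len(alignments),
        n_retained=len(retained),
    )
    return retained, report
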