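"""Virus-to-bacterium ratio (VBR) and the infection-potential score.

VBR at a site is the relative abundance of sequences annotated as viruses of
bacteria divided by the relative abundance of bacterial sequences; because
both share the site total as denominator this reduces to the plain count
ratio.  Infection potential is VBR divided by node50 — many viruses relative
to few dominant host lineages means a high score.  The pipeline assembles a
per-site table of VBR, node50, MPD, sesMPD (pooled-subsampling null over all
placement sites) and infection potential, reporting — never silently
dropping — sites that fail a precondition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

from ._rng import substream
from .diversity import DEFAULT_N_RAND, mpd as _mpd, node50 as _node50, ses_mpd as _ses_mpd
from .errors import UndefinedMetricError, ValidationError
from .io import VIRUS_DOMAINS, PlacementTable, TaxonCountTable
from .tree import ReferenceTree

__all__ = ["SiteMetrics", "PipelineResult", "vbr", "infection_potential", "site_metrics_pipeline"]

logger = logging.getLogger("virhost")


@dataclass
class SiteMetrics:
    site_id: str
    vbr: float
    node50: int
    mpd: float
    ses_mpd: float  # NaN when the null SD is zero
    infection_potential: float  # NaN when vbr == 0


@dataclass
class PipelineResult:
    metrics: list[SiteMetrics]
    skipped: list[tuple[str, str]]  # (site_id, reason)

    @property
    def sites(self) -> list[str]:
        return [m.site_id for m in self.metrics]


def vbr(
    taxa: TaxonCountTable,
    site_id: str,
    virus_domains: Iterable[str] = VIRUS_DOMAINS,
) -> float:
    """Viral relative abundance over bacterial relative abundance at a site.

    Only taxa whose domain is in ``virus_domains`` (default: bacteriophage,
    i.e. annotations implying a bacterial host) count as viral.  A site with
    no viral counts returns 0.0 with a warning; a site with no bacterial
    counts has no defined ratio and raises.
    """
    if site_id not in set(taxa.sites):
        raise ValidationError(f"site {site_id!r} absent from taxon count table")
    bacterial = taxa.domain_total(site_id, {"bacteria"})
    if bacterial <= 0:
        raise UndefinedMetricError(f"VBR undefined at {site_id!r}: zero bacterial count")
    viral = taxa.domain_total(site_id, virus_domains)
    if viral == 0:
        logger.warning("ZERO_VBR site=%s: no viral counts; VBR = 0", site_id)
        return 0.0
    return viral / bacterial


def infection_potential(vbr_value: float, node50_value: int) -> float:
    """VBR per node50: virus pressure normalized by dominant-host richness."""
    if node50_value < 1:
        raise ValidationError(f"node50 must be >= 1, got {node50_value}")
    if vbr_value <= 0:
        raise UndefinedMetricError("infection potential requires VBR > 0")
    return vbr_value / node50_value


def site_metrics_pipeline(
    tree: ReferenceTree,
    placements: PlacementTable,
    taxa: TaxonCountTable,
    n_rand: int = DEFAULT_N_RAND,
    seed: int = 0,
    virus_domains: Iterable[str] = VIRUS_DOMAINS,
    presence_only: bool = False,
) -> PipelineResult:
    """Compute per-site metrics for every site present in both input tables.

    The sesMPD null pool is the union of placement hits across ALL placement
    sites (not only the overlap).  Each site draws its null from a substream
    of ``seed`` keyed by the site id, so results do not depend on site order.
    Sites failing a precondition (absent placements, < 2 placed reads, zero
    bacterial count) are returned in ``skipped`` with a reason.
    """
    placements.validate_against(tree)
    taxa_sites = set(taxa.sites)
    placement_sites = placements.sites
    overlap = [s for s in placement_sites if s in taxa_sites]
    extra_taxa_sites = [s for s in taxa.sites if s not in set(placement_sites)]
    if not overlap:
        raise ValidationError("no site occurs in both the placement and taxon tables")

    pool = placements.pooled_counts()
    metrics: list[SiteMetrics] = []
    skipped: list[tuple[str, str]] = []
    for site in extra_taxa_sites:
        skipped.append((site, "absent from placement table"))
        logger.warning("SKIPPED_SITE site=%s reason=absent_from_placements", site)
    for site in placement_sites:
        if site not in taxa_sites:
            skipped.append((site, "absent from taxon count table"))
            logger.warning("SKIPPED_SITE site=%s reason=absent_from_taxa", site)
            continue
        counts = placements.site_counts(site)
        total = int(counts.sum())
        if total == 0:
            skipped.append((site, "no placed reads"))
            logger.warning("SKIPPED_SITE site=%s reason=no_placed_reads", site)
            continue
        if total < 2:
            skipped.append((site, "fewer than 2 placed reads (MPD undefined)"))
            logger.warning("SKIPPED_SITE site=%s reason=single_read", site)
            continue
        try:
            site_vbr = vbr(taxa, site, virus_domains=virus_domains)
        except UndefinedMetricError as exc:
            skipped.append((site, str(exc)))
            logger.warning("SKIPPED_SITE site=%s reason=undefined_vbr", site)
            continue
        k50 = _node50(counts)
        div = _ses_mpd(
            tree,
            counts,
            pool,
            n_rand=n_rand,
            rng=substream(seed, f"ses:{site}"),
            presence_only=presence_only,
            site_id=site,
        )
        if math.isnan(div.ses_mpd):
            logger.warning("NA_SESMPD site=%s: null SD is zero", site)
        if site_vbr > 0:
            potential = infection_potential(site_vbr, k50)
        else:
            potential = float("nan")
        metrics.append(
            SiteMetrics(
                site_id=site,
                vbr=site_vbr,
                node50=k50,
                mpd=div.mpd_observed,
                ses_mpd=div.ses_mpd,
                infection_potential=potential,
            )
        )
    return PipelineResult(metrics=metrics, skipped=skipped)
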