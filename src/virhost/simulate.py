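"""Synthetic communities with a shared evenness driver for viruses and hosts.

The generator emulates the statistical structure the site-level analysis
assumes: each site has a latent evenness level that simultaneously shapes
how its reads spread over the reference tree (hence node50 and sesMPD) and
how large its virus load is relative to bacteria (hence VBR).

Per site *s*:

1. a Dirichlet concentration ``alpha_s`` is drawn log-uniformly from
   ``alpha_range``; small alpha collapses the community onto few lineages,
   large alpha spreads it evenly;
2. ``z_s`` is the standardized log-concentration across sites — the single
   latent evenness driver;
3. leaf proportions are drawn from ``Dirichlet(alpha_s, …, alpha_s)`` over
   the tree's leaves and ``reads_per_site`` reads fall multinomially on them;
4. the site's virus-to-bacterium ratio follows
   ``log VBR_s = mean_log_vbr − beta·z_s + Normal(0, sigma)``, so ``beta > 0``
   couples high virus load to low evenness — the regime in which infection
   potential and host diversity are negatively associated.

The reference tree is a pure-birth topology (uniform random leaf splitting)
with i.i.d. exponential branch lengths.  Reads are placed on leaves only;
the diversity code handles internal-node hits, which hand-built fixtures
cover elsewhere.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ValidationError
from .io import (
    PlacementTable,
    TaxonCountTable,
    write_newick,
    write_placement_table,
    write_taxon_counts,
)
from .tree import ReferenceTree

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_tree", "simulate_site_placements", "simulate_taxon_counts", "simulate_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic survey.

    Defaults mirror the scale of a ~20-station brackish-sea transect with a
    few thousand placed core-gene reads per station: 64 reference leaves,
    20 sites, 2000 reads per site, Dirichlet concentrations spanning
    0.05–5 (strongly clustered to near-even), a mean VBR of 0.1 on bacteria
    pools of 10 000 counts, and a virus–evenness coupling ``beta`` strong
    enough to produce the negative diversity–infection association with
    moderate log-normal noise ``sigma``.
    """

    seed: int = 0
    n_leaves: int = 64
    n_sites: int = 20
    reads_per_site: int = 2000
    alpha_range: tuple[float, float] = (0.05, 5.0)
    beta: float = 1.5
    sigma: float = 0.2
    mean_log_vbr: float = math.log(0.1)
    bacteria_per_site: int = 10000
    overdispersion: float | None = None  # Dirichlet-multinomial extra scatter; off by default

    def __post_init__(self) -> None:
        lo, hi = self.alpha_range
        if not (0 < lo <= hi):
            raise ValidationError(f"alpha_range must satisfy 0 < lo <= hi, got {self.alpha_range}")
        if self.reads_per_site < 2:
            raise ValidationError("reads_per_site must be >= 2")
        if self.n_sites < 3:
            raise ValidationError("n_sites must be >= 3")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.n_leaves < 2:
            raise ValidationError("n_leaves must be >= 2")


@dataclass
class SyntheticDataset:
    tree: ReferenceTree
    placements: PlacementTable
    taxa: TaxonCountTable
    truth: pd.DataFrame  # site_id, alpha, z, log_vbr, vbr


def simulate_tree(n_leaves: int, seed: int) -> ReferenceTree:
    """Pure-birth tree: split a uniformly random leaf until ``n_leaves`` leaves.

    Branch lengths are i.i.d. exponential with mean 0.1 tree units.  Leaves
    are named ``L<k>`` in preorder; internal nodes ``N<k>`` by preorder index.
    Deterministic for a fixed seed.
    """
    if n_leaves < 2:
        raise ValidationError("a tree needs at least 2 leaves")
    rng = substream(seed, "tree")
    # grow topology on integer ids; node 0 is the root
    children: dict[int, list[int]] = {0: []}
    leaves = [0]
    next_id = 1
    while len(leaves) < n_leaves:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        kids = [next_id, next_id + 1]
        next_id += 2
        children[node] = kids
        for k in kids:
            children[k] = []
        leaves.extend(kids)

    # preorder naming
    order: list[int] = []
    stack = [0]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children[node]))
    names: dict[int, str] = {}
    leaf_counter = 0
    for pre_idx, node in enumerate(order):
        if children[node]:
            names[node] = f"N{pre_idx}"
        else:
            leaf_counter += 1
            names[node] = f"L{leaf_counter:03d}"

    parent: dict[str, str | None] = {names[0]: None}
    blen: dict[str, float] = {names[0]: 0.0}
    child_names: dict[str, list[str]] = {}
    for node in order:
        child_names[names[node]] = [names[k] for k in children[node]]
        for k in children[node]:
            parent[names[k]] = names[node]
            blen[names[k]] = float(rng.exponential(0.1))
    return ReferenceTree(parent, blen, child_names, names[0])


def simulate_site_placements(
    tree: ReferenceTree, config: SimulationConfig
) -> tuple[PlacementTable, pd.DataFrame]:
    """Draw per-site leaf placements driven by a log-uniform Dirichlet concentration.

    Returns the placement table (leaf × site) and the per-site truth frame
    with columns ``site_id``, ``alpha`` and the standardized driver ``z``.
    """
    rng = substream(config.seed, "placements")
    leaves = tree.leaves
    sites = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    lo, hi = config.alpha_range
    log_alpha = rng.uniform(math.log(lo), math.log(hi), size=config.n_sites)
    sd = float(np.std(log_alpha))
    z = (log_alpha - log_alpha.mean()) / sd if sd > 0 else np.zeros_like(log_alpha)

    counts = np.zeros((len(leaves), config.n_sites), dtype=np.int64)
    for j, alpha in enumerate(np.exp(log_alpha)):
        props = rng.dirichlet(np.full(len(leaves), alpha))
        if config.overdispersion is not None:
            props = rng.dirichlet(props * config.overdispersion)
        counts[:, j] = rng.multinomial(config.reads_per_site, props)
    table = PlacementTable(pd.DataFrame(counts, index=pd.Index(leaves, name="node_id"), columns=sites))
    truth = pd.DataFrame({"site_id": sites, "alpha": np.exp(log_alpha), "z": z})
    return table, truth


def simulate_taxon_counts(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[TaxonCountTable, pd.DataFrame]:
    """Couple each site's virus load to its evenness driver.

    ``log VBR = mean_log_vbr − beta·z + Normal(0, sigma)``; the bacteriophage
    count is ``round(VBR · bacteria_per_site)`` against a fixed bacterial
    pool, so the realized count ratio recovers VBR up to rounding.
    """
    rng = substream(config.seed, "taxa")
    z = truth["z"].to_numpy()
    noise = rng.normal(0.0, config.sigma, size=len(z)) if config.sigma > 0 else np.zeros(len(z))
    log_vbr = config.mean_log_vbr - config.beta * z + noise
    vbr = np.exp(log_vbr)
    phage = np.rint(vbr * config.bacteria_per_site).astype(np.int64)
    if (phage < 0).any():
        raise AssertionError("negative phage count; impossible by construction")
    rows = []
    for site, n_phage in zip(truth["site_id"], phage):
        rows.append((site, "bacteria_pool", "bacteria", config.bacteria_per_site))
        rows.append((site, "phage_pool", "bacteriophage", int(n_phage)))
    taxa = TaxonCountTable(pd.DataFrame(rows, columns=["site_id", "taxon_id", "domain", "count"]))
    truth = truth.assign(log_vbr=log_vbr, vbr=vbr)
    return taxa, truth


def simulate_dataset(config: SimulationConfig, out_dir: str | os.PathLike | None = None) -> SyntheticDataset:
    """Full synthetic survey: tree, placements, taxon counts, per-site truth.

    With ``out_dir`` set, writes ``tree.nwk``, ``placements.tsv``,
    ``taxa.tsv`` and ``truth.tsv`` there; the returned object round-trips
    through the readers in :mod:`virhost.io`.
    """
    tree = simulate_tree(config.n_leaves, config.seed)
    placements, truth = simulate_site_placements(tree, config)
    taxa, truth = simulate_taxon_counts(truth, config)
    dataset = SyntheticDataset(tree=tree, placements=placements, taxa=taxa, truth=truth)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_newick(tree, os.path.join(out_dir, "tree.nwk"))
        write_placement_table(placements, os.path.join(out_dir, "placements.tsv"))
        write_taxon_counts(taxa, os.path.join(out_dir, "taxa.tsv"))
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return dataset
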