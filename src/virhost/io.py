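"""On-disk formats: placement tables, taxon counts, site metrics, alignments.

Every tabular artifact is UTF-8 TSV; lines starting with ``#`` are comments;
undefined floats are written as the literal ``NA``.  Alignment intervals are
0-based half-open on the contig; the minimal SAM reader converts from SAM's
1-based coordinates and keeps only mapped reads.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .tree import ReferenceTree, read_newick, write_newick  # re-exported

__all__ = [
    "DOMAINS",
    "VIRUS_DOMAINS",
    "PlacementTable",
    "TaxonCountTable",
    "ReadAlignment",
    "read_newick",
    "write_newick",
    "read_placement_table",
    "write_placement_table",
    "read_taxon_counts",
    "write_taxon_counts",
    "write_site_metrics",
    "read_site_metrics",
    "read_alignments_tsv",
    "write_alignments_tsv",
    "read_alignments_sam",
    "read_contig_lengths",
    "METRICS_COLUMNS",
]

#: Accepted values for the ``domain`` column of a taxon count table.
DOMAINS = frozenset({"bacteria", "bacteriophage", "other_virus", "other"})
#: Domains counted as "viral" by default when forming the virus-to-bacterium ratio.
VIRUS_DOMAINS = frozenset({"bacteriophage"})

METRICS_COLUMNS = ["site", "vbr", "node50", "mpd", "ses_mpd", "infection_potential"]


def _read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


@dataclass
class PlacementTable:
    """Per-site read counts assigned to reference-tree nodes.

    ``counts`` is a node × site integer DataFrame (index = node id, one column
    per site).  Cells absent from the source file are zero.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate node ids in placement table: {dups!r}")
        if not np.issubdtype(df.to_numpy().dtype, np.integer):
            raise FormatError("placement counts must be integers")
        if (df.to_numpy() < 0).any():
            raise ValidationError("placement counts must be >= 0")

    @property
    def sites(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    @property
    def node_ids(self) -> list[str]:
        return [str(i) for i in self.counts.index]

    def site_counts(self, site: str) -> pd.Series:
        """Node counts for one site, restricted to nodes with count > 0."""
        if site not in self.counts.columns:
            raise ValidationError(f"unknown site {site!r}")
        col = self.counts[site]
        return col[col > 0]

    def pooled_counts(self) -> pd.Series:
        """Hits of all sites mixed together (node -> summed count)."""
        pooled = self.counts.sum(axis=1)
        return pooled[pooled > 0]

    def validate_against(self, tree: ReferenceTree) -> None:
        unknown = [n for n in self.node_ids if n not in tree]
        if unknown:
            raise ValidationError(f"placement table references nodes absent from the tree: {unknown!r}")


def read_placement_table(path: str | os.PathLike, tree: ReferenceTree) -> PlacementTable:
    """Read a node × site count table and verify node ids against ``tree``."""
    df = _read_tsv(path)
    if len(df.columns) == 0 or df.columns[0] != "node_id":
        raise FormatError(f"first column of {path} must be 'node_id'")
    df["node_id"] = df["node_id"].astype(str)
    df = df.set_index("node_id")
    df = df.fillna(0)
    try:
        arr = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    if not (arr.to_numpy() == np.floor(arr.to_numpy())).all():
        raise FormatError(f"non-integer count in {path}")
    table = PlacementTable(arr.astype(np.int64))
    table.validate_against(tree)
    return table


def write_placement_table(table: PlacementTable, path: str | os.PathLike) -> None:
    out = table.counts.copy()
    out.index.name = "node_id"
    out.to_csv(path, sep="\t")


@dataclass
class TaxonCountTable:
    """Long-format per-site taxon counts with a domain label per taxon.

    Columns: ``site_id``, ``taxon_id``, ``domain`` (one of :data:`DOMAINS`),
    ``count`` (nonnegative integer).  ``(site_id, taxon_id)`` pairs are unique.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in ("site_id", "taxon_id", "domain", "count") if c not in df.columns]
        if missing:
            raise FormatError(f"taxon count table lacks columns {missing!r}")
        bad_domains = sorted(set(df["domain"]) - DOMAINS)
        if bad_domains:
            raise ValidationError(
                f"unsupported domain labels {bad_domains!r}; expected one of {sorted(DOMAINS)}"
            )
        counts = df["count"].to_numpy()
        if not np.issubdtype(counts.dtype, np.integer):
            if not (counts == np.floor(counts)).all():
                raise FormatError("taxon counts must be integers")
            df["count"] = df["count"].astype(np.int64)
        if (df["count"].to_numpy() < 0).any():
            raise ValidationError("taxon counts must be >= 0")
        dup = df.duplicated(subset=["site_id", "taxon_id"])
        if dup.any():
            pairs = df.loc[dup, ["site_id", "taxon_id"]].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (site, taxon) rows: {pairs!r}")

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.rows["site_id"]:
            seen.setdefault(str(s))
        return list(seen)

    def domain_total(self, site: str, domains: Iterable[str]) -> int:
        domains = set(domains)
        mask = (self.rows["site_id"] == site) & self.rows["domain"].isin(domains)
        return int(self.rows.loc[mask, "count"].sum())

    def site_total(self, site: str) -> int:
        return int(self.rows.loc[self.rows["site_id"] == site, "count"].sum())


def read_taxon_counts(path: str | os.PathLike) -> TaxonCountTable:
    df = _read_tsv(path, dtype={"site_id": str, "taxon_id": str, "domain": str})
    return TaxonCountTable(df)


def write_taxon_counts(table: TaxonCountTable, path: str | os.PathLike) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def _fmt(value: float) -> str:
    """Six significant digits; NA for undefined."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{value:.6g}"


def write_site_metrics(metrics: Sequence, path: str | os.PathLike) -> None:
    """Write per-site metrics as TSV (columns fixed, floats at 6 sig. digits)."""
    if not metrics:
        raise ValidationError("refusing to write an empty metrics table")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(METRICS_COLUMNS) + "\n")
        for m in metrics:
            fh.write(
                "\t".join(
                    [
                        str(m.site_id),
                        _fmt(m.vbr),
                        str(int(m.node50)),
                        _fmt(m.mpd),
                        _fmt(m.ses_mpd),
                        _fmt(m.infection_potential),
                    ]
                )
                + "\n"
            )


def read_site_metrics(path: str | os.PathLike) -> pd.DataFrame:
    """Read a site-metrics TSV back into a DataFrame (NA -> NaN)."""
    df = _read_tsv(path, dtype={"site": str}, na_values=["NA"], keep_default_na=False)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metrics table lacks columns {missing!r}")
    return df


@dataclass(frozen=True)
class ReadAlignment:
    """A read aligned to ``contig_id`` over the 0-based half-open ``[start, end)``."""

    read_id: str
    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"alignment {self.read_id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )


def read_alignments_tsv(path: str | os.PathLike) -> list[ReadAlignment]:
    df = _read_tsv(path, dtype={"read_id": str, "contig_id": str})
    missing = [c for c in ("read_id", "contig_id", "start", "end") if c not in df.columns]
    if missing:
        raise FormatError(f"alignment table lacks columns {missing!r}")
    if df["read_id"].duplicated().any():
        dups = sorted(df.loc[df["read_id"].duplicated(), "read_id"].unique())
        raise ValidationError(f"duplicate read ids: {dups!r}")
    return [
        ReadAlignment(str(r.read_id), str(r.contig_id), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_alignments_tsv(alignments: Iterable[ReadAlignment], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tcontig_id\tstart\tend\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.contig_id}\t{a.start}\t{a.end}\n")


def read_alignments_sam(path: str | os.PathLike) -> tuple[list[ReadAlignment], dict[str, int]]:
    """Minimal SAM reader: mapped reads only, aligned reference span per read.

    Returns the alignments (converted to 0-based half-open intervals) and the
    contig lengths declared in the header.  Flags beyond "unmapped" and CIGAR
    details beyond the aligned span are ignored.
    """
    import pysam

    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    alignments: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = {str(name): int(length) for name, length in zip(sam.references, sam.lengths)}
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None or rec.reference_end is None:
                continue
            alignments.append(
                ReadAlignment(
                    str(rec.query_name),
                    str(rec.reference_name),
                    int(rec.reference_start),
                    int(rec.reference_end),
                )
            )
    ids = [a.read_id for a in alignments]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate read ids in SAM input")
    return alignments, lengths


def read_contig_lengths(path: str | os.PathLike) -> dict[str, int]:
    df = _read_tsv(path, dtype={"contig_id": str})
    missing = [c for c in ("contig_id", "length") if c not in df.columns]
    if missing:
        raise FormatError(f"contig length table lacks columns {missing!r}")
    lengths = {str(r.contig_id): int(r.length) for r in df.itertuples(index=False)}
    if any(v <= 0 for v in lengths.values()):
        raise ValidationError("contig lengths must be positive")
    return lengths
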