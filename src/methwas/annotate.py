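"""Probe annotation, CpG-island collapsing and closest-TSS gene assignment.

Probes are annotated with a genomic position (1-based, MAPINFO convention), a
CpG-density class (HC = high-density island, IC = intermediate-density island,
ICshore = intermediate-density border of an HC, nonisland), an optional island
name such as ``chr19_IC:17905037-17906698``, the closest-TSS gene symbol and
the signed distance to that TSS. Probes sharing an island name are collapsed
to a single "interrogated location" whose M-value per sample is the arithmetic
mean of the member probes; free-standing probes pass through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import IslandNameError

ANNOTATION_COLUMNS = (
    "chromosome", "position", "island_name", "hil_class",
    "closest_tss_gene", "distance_to_tss", "snp_flag", "crossreactive_flag",
)

HIL_CLASSES = ("HC", "IC", "ICshore", "nonisland")

_ISLAND_RE = re.compile(r"^(chr[0-9XYMxym]+)_([A-Za-z]+):(\d+)-(\d+)$")


@dataclass(frozen=True)
class IslandSpan:
    chromosome: str
    class_token: str
    start: int
    end: int


def parse_island_name(name: str) -> IslandSpan:
    """Parse ``chrN_CLASS:start-end`` island names (1-based, inclusive).

    Compound names joined by ";" (as printed for shores annotated under two
    density classes) are accepted; the first span is returned. En-dashes are
    tolerated in place of hyphens. Site-style strings such as
    ``chr2:113521873`` (no class token) raise :class:`IslandNameError` so the
    caller can route them to free-standing-site handling.
    """
    if not isinstance(name, str) or not name.strip():
        raise IslandNameError(str(name), "empty")
    first = name.split(";")[0].strip().replace("–", "-")
    match = _ISLAND_RE.match(first)
    if match is None:
        raise IslandNameError(name, "expected chrN_CLASS:start-end")
    chrom, cls, start, end = match.groups()
    start, end = int(start), int(end)
    if start > end:
        raise IslandNameError(name, f"start {start} > end {end}")
    return IslandSpan(chrom, cls, start, end)


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Normalize an annotation frame: fill flags, default hil_class to nonisland."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns and c != "island_name"]
    if missing:
        raise ValueError(f"annotation is missing columns {missing}")
    annot = annot.copy()
    if "island_name" not in annot.columns:
        annot["island_name"] = ""
    annot["island_name"] = annot["island_name"].fillna("").astype(str)
    annot["hil_class"] = annot["hil_class"].replace("", np.nan).fillna("nonisland")
    for flag in ("snp_flag", "crossreactive_flag"):
        annot[flag] = annot[flag].fillna(0).astype(float).astype(bool)
    return annot


def _has_island(annot: pd.DataFrame) -> pd.Series:
    return annot["island_name"].fillna("").astype(str).str.strip() != ""


def _representative_member(members: pd.DataFrame) -> pd.Series:
    """Member annotation row carrying the island's gene fields: the probe with
    the smallest |distance_to_tss|, ties broken by lexicographically smallest
    probe ID."""
    key = members.assign(_absd=members["distance_to_tss"].abs(), _pid=members.index.astype(str))
    key = key.sort_values(["_absd", "_pid"], kind="mergesort")
    return members.loc[key.index[0]]


def assign_gene(row: pd.Series) -> str:
    """Closest-TSS gene symbol for a location row; empty fields become "NA"."""
    gene = row.get("closest_tss_gene", "")
    if gene is None or (isinstance(gene, float) and np.isnan(gene)) or str(gene).strip() == "":
        return "NA"
    return str(gene).strip()


def build_location_table(annot: pd.DataFrame, probe_order: pd.Index) -> pd.DataFrame:
    """Location metadata for the given retained probes, islands collapsed.

    Locations are ordered by first member occurrence in ``probe_order``.
    Returns a frame indexed by location_id with columns kind, n_members,
    member_probe_ids, chromosome, start, end, hil_class, closest_tss_gene,
    distance_to_tss, tss_position and (if present in the input) gene_id.
    """
    annot = annot.loc[probe_order]
    has_island = _has_island(annot)
    island_key = annot["island_name"].astype(str).str.strip()
    member_groups = {
        name: sub for name, sub in annot[has_island].groupby(island_key[has_island], sort=False)
    }
    rows = []
    seen: set[str] = set()
    has_gene_id = "gene_id" in annot.columns
    for pid in probe_order:
        a = annot.loc[pid]
        if has_island.loc[pid]:
            name = island_key.loc[pid]
            if name in seen:
                continue
            seen.add(name)
            members = member_groups[name]
            rep = _representative_member(members)
            try:
                span = parse_island_name(name)
                chrom, start, end, cls = span.chromosome, span.start, span.end, span.class_token
            except IslandNameError:
                chrom = str(rep["chromosome"])
                start, end = int(members["position"].min()), int(members["position"].max())
                cls = str(rep["hil_class"])
            row = {
                "location_id": name, "kind": "island", "n_members": len(members),
                "member_probe_ids": ";".join(members.index.astype(str)),
                "chromosome": chrom, "start": start, "end": end, "hil_class": cls,
                "closest_tss_gene": assign_gene(rep),
                "distance_to_tss": int(rep["distance_to_tss"]),
                "tss_position": int(rep["position"]) + int(rep["distance_to_tss"]),
            }
            if has_gene_id:
                row["gene_id"] = rep["gene_id"]
        else:
            row = {
                "location_id": str(pid), "kind": "site", "n_members": 1,
                "member_probe_ids": str(pid),
                "chromosome": str(a["chromosome"]), "start": int(a["position"]),
                "end": int(a["position"]), "hil_class": str(a["hil_class"]),
                "closest_tss_gene": assign_gene(a),
                "distance_to_tss": int(a["distance_to_tss"]),
                "tss_position": int(a["position"]) + int(a["distance_to_tss"]),
            }
            if has_gene_id:
                row["gene_id"] = a["gene_id"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("location_id")
    return table


def genomic_position_string(row: pd.Series) -> str:
    """Display string for a location: the island name span for islands,
    ``chrN:pos`` for free-standing sites."""
    if row["kind"] == "island":
        return f"{row['chromosome']}_{row['hil_class']}:{row['start']}-{row['end']}"
    return f"{row['chromosome']}:{row['start']}"


def collapse_islands(m: pd.DataFrame, annot: pd.DataFrame):
    """Collapse island-member probes of a probe x sample M-value matrix.

    Probes sharing a (verbatim, non-empty) island name are replaced by one
    location whose per-sample value is the arithmetic mean of the members;
    free-standing probes pass through. Returns ``(location_matrix,
    location_table)`` with locations ordered by first member occurrence.
    For S retained sites of which m are members of I distinct islands the
    output has S - m + I rows.
    """
    missing = m.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"annotation does not cover probes {list(missing[:5])!r}")
    annot = annot.loc[m.index]
    table = build_location_table(annot, m.index)
    has_island = _has_island(annot)
    group_key = np.where(has_island, annot["island_name"].astype(str).str.strip(), m.index.astype(str))
    grouped = m.groupby(group_key, sort=False).mean()
    grouped = grouped.loc[table.index]
    grouped.index.name = "location_id"
    return grouped, table


class IslandCollapser(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer collapsing island members to their mean.

    Operates on samples x probes matrices (the transpose of the pipeline's
    probe x sample frames). ``annotation`` is the probe annotation frame;
    ``fit`` records the grouping for the probes seen, ``transform`` averages
    member columns. Fitted attributes: ``location_table_``, ``probe_ids_``.
    """

    def __init__(self, annotation: pd.DataFrame | None = None):
        self.annotation = annotation

    def fit(self, X: pd.DataFrame, y=None):
        if self.annotation is None:
            raise ValueError("IslandCollapser requires an annotation frame")
        if not isinstance(X, pd.DataFrame):
            raise ValueError("X must be a samples x probes DataFrame with probe-ID columns")
        self.probe_ids_ = X.columns
        _, self.location_table_ = collapse_islands(X.T, self.annotation)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "location_table_")
        if not isinstance(X, pd.DataFrame) or not X.columns.equals(self.probe_ids_):
            raise ValueError("X must carry the probe columns seen at fit time")
        collapsed, _ = collapse_islands(X.T, self.annotation)
        return collapsed.T
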