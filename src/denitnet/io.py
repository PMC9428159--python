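"""Readers and writers for the pipeline's artifacts.

Conventions: UTF-8 throughout, tab-separated OTU tables (rows = OTUs,
columns = samples, amplicon convention), comma-separated sample metadata,
``.`` decimal mark. Networks are exported as edge-list CSV, GraphML or GEXF
so they can be laid out in Gephi.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import TRAITS

GENE_TAGS = ("nirK", "nirS", "nosZ")


class ParseError(ValueError):
    """Malformed input file; the message carries the 1-based line number."""


@dataclass
class OtuTable:
    """An OTU x sample count table for one denitrification marker gene.

    Attributes
    ----------
    counts : DataFrame, index = OTU ids, columns = sample ids, values >= 0.
    genus : Series mapping OTU id -> genus label ("unclassified" allowed).
    gene_tag : which functional gene the amplicons target (nirK/nirS/nosZ).
    """

    counts: pd.DataFrame
    genus: pd.Series
    gene_tag: str

    def __post_init__(self) -> None:
        if self.gene_tag not in GENE_TAGS:
            raise ValueError(f"gene_tag must be one of {GENE_TAGS}, got {self.gene_tag!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate OTU id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.genus = self.genus.reindex(self.counts.index)
        if self.genus.isna().any():
            missing = self.genus.index[self.genus.isna()][0]
            raise ValueError(f"missing genus label for OTU {missing!r}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValueError(f"sample {bad!r} has zero total count")
        return self.counts / totals

    def subset(self, otu_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(otu_ids)].copy(),
                        self.genus.loc[list(otu_ids)].copy(), self.gene_tag)


def read_otu_table(path, gene_tag: str) -> OtuTable:
    """Read a tab-delimited OTU table: header ``OTU_ID<TAB>genus<TAB>samples...``.

    All-zero rows are retained; filtering is a pipeline stage, not an I/O
    side effect. Raises :class:`ParseError` with a line number on ragged
    rows or non-numeric cells, and names duplicated ids.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "OTU_ID" or header[1] != "genus":
        raise ParseError(f"{path}:1: expected header 'OTU_ID\\tgenus\\t<sample ids>'")
    sample_ids = header[2:]
    otu_ids, genera, rows = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}")
        otu_ids.append(cells[0])
        genera.append(cells[1])
        try:
            rows.append([float(c) for c in cells[2:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric count cell ({exc})") from None
    seen: set[str] = set()
    for oid in otu_ids:
        if oid in seen:
            raise ParseError(f"{path}: duplicated OTU id {oid!r}")
        seen.add(oid)
    counts = pd.DataFrame(rows, index=otu_ids, columns=sample_ids)
    genus = pd.Series(genera, index=otu_ids, name="genus")
    return OtuTable(counts, genus, gene_tag)


def write_otu_table(table: OtuTable, path) -> None:
    path = Path(path)
    out = table.counts.copy()
    out.insert(0, "genus", table.genus)
    out.index.name = "OTU_ID"
    out.to_csv(path, sep="\t", encoding="utf-8")


REQUIRED_META_COLUMNS = ("sample_id", "treatment", "replicate") + TRAITS


def validate_sample_frame(frame: pd.DataFrame, design=None) -> pd.DataFrame:
    """Check a sample-metadata frame against the expected schema.

    One row per sample; treatment labels must belong to the design when one
    is given. Optional columns ``PDA`` (ng N2O-N g-1 h-1) and ``N2O``
    (cumulative, kg ha-1) are passed through.
    """
    missing = [c for c in REQUIRED_META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"sample frame missing columns {missing}")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    if design is not None:
        bad = set(frame["treatment"]) - set(design.treatments)
        if bad:
            raise ValueError(f"treatments not in design: {sorted(bad)}")
    return frame


def read_sample_frame(path, design=None) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    return validate_sample_frame(frame, design)


def write_sample_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, encoding="utf-8")


def write_ground_truth(truth, path) -> None:
    """Serialize a :class:`denitnet.simulate.GroundTruth` as JSON."""
    payload = {
        "otu_module": dict(truth.otu_module),
        "keystones": sorted(truth.keystones),
        "trait_correlation_signs": {m: dict(v) for m, v in truth.trait_correlation_signs.items()},
        "true_fluxes": truth.true_fluxes,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


NETWORK_FORMATS = ("csv", "graphml", "gexf")


def write_network(net, path, format: str = "graphml") -> None:
    """Export a validated network for Gephi or spreadsheet use.

    ``net`` is a :class:`denitnet.network.ValidatedNetwork` or a bare
    networkx graph. Node attributes carried: genus, module, keystone;
    edge attributes: r, p_param, p_perm, boot_support, sign.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {NETWORK_FORMATS}")
    graph = net if isinstance(net, nx.Graph) else net.graph
    path = Path(path)
    if format == "csv":
        rows = [
            {"source": u, "target": v, **{k: data.get(k) for k in
             ("r", "p_param", "p_perm", "boot_support", "sign")}}
            for u, v, data in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "r", "p_param",
                                    "p_perm", "boot_support", "sign"]).to_csv(
            path, index=False, encoding="utf-8")
    elif format == "graphml":
        nx.write_graphml(_scrub(graph), path)
    else:
        nx.write_gexf(_scrub(graph), path)


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def _scrub(graph: nx.Graph) -> nx.Graph:
    """Coerce attribute values to GraphML/GEXF-safe scalars."""
    out = graph.copy()
    for _, data in out.nodes(data=True):
        for k, v in list(data.items()):
            data[k] = _coerce(v)
    for _, _, data in out.edges(data=True):
        for k, v in list(data.items()):
            data[k] = _coerce(v)
    return out


def _coerce(value):
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.bool_, bool)):
        return bool(value)
    if value is None:
        return ""
    return value
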