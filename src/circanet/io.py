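"""Readers, writers and run configuration.

Formats handled: expression matrices as TSV (first column the gene id,
remaining columns ``CT0..CT47`` or numeric hours), interaction edge lists
as PSI-MI TAB 2.5, simple 3+-column TSV or SIF, annotation TSVs, reporter
trace TSVs (``time_h`` plus one column per well), GraphML network exports,
and a YAML run configuration serialized verbatim into output directories.
All times are hours, decimal separator '.', UTF-8.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .network import InteractionNetwork
from .phenotype import LuminescenceSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_interactions",
    "write_interactions_tsv",
    "write_sif",
    "write_network_graphml",
    "read_annotation_tsv",
    "read_reporter_tsv",
    "write_reporter_tsv",
]

INTERACTION_DIALECTS = ("psimitab", "tsv", "sif")


@dataclass
class RunConfig:
    """Thresholds, permutation counts and seeds for one pipeline run.

    Unknown keys in a YAML file are rejected so that typos cannot silently
    fall back to defaults; the config is serialized verbatim into every
    output directory.
    """

    seed: int = 0
    fdr_threshold: float = 1e-5
    rhythm_fdr_threshold: float = 0.05
    pcc_threshold: float = 0.5
    hub_degree: int = 20
    dynamic_degree_cut: int = 5
    phase_grid_step: float = 0.1
    arrhythmic_r: float = 0.8
    n_permutations: int = 200
    n_networks: int = 1000
    n_background: int = 1000
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _parse_time_column(name: str) -> float:
    m = re.fullmatch(r"(?:CT|ZT|T)?\s*([0-9]+(?:\.[0-9]+)?)", str(name).strip())
    if not m:
        raise ValueError(f"cannot parse timepoint column {name!r} as hours")
    return float(m.group(1))


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x timepoint TSV matrix; columns become hours (float).

    Duplicate gene rows are dropped keeping the first occurrence (logged);
    ragged rows and non-numeric cells raise with the offending line number
    (1-based, header = line 1).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    n_cols = len(header)
    times = [_parse_time_column(c) for c in header[1:]]
    genes, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}"
            )
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        genes.append(parts[0])
    df = pd.DataFrame(rows, index=genes, columns=times)
    n_dup = df.index.duplicated().sum()
    if n_dup:
        logger.warning("%s: %d duplicate gene rows dropped (first kept)", path, n_dup)
        df = df[~df.index.duplicated(keep="first")]
    logger.info("%s: read %d genes x %d timepoints", path, *df.shape)
    return df


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix with CT-style headers when hours are integral."""
    cols = []
    for c in expression.columns:
        h = float(c)
        cols.append(f"CT{int(h)}" if h == int(h) else f"CT{h}")
    out = expression.copy()
    out.columns = cols
    out.to_csv(path, sep="\t", index_label="gene_id")


def _detect_dialect(path: Path) -> str:
    if path.suffix.lower() == ".sif":
        return "sif"
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                n = len(line.rstrip("\n").split("\t"))
                return "psimitab" if n >= 15 else "tsv"
    return "tsv"


_MITAB_ID = re.compile(r"^[^:]+:(.+)$")


def _mitab_identifier(fieldval: str) -> str:
    first = fieldval.split("|")[0].strip()
    m = _MITAB_ID.match(first)
    ident = m.group(1) if m else first
    return ident.strip('"')


def read_interactions(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read an interaction edge list as (id_a, id_b, source).

    Dialects: ``psimitab`` (PSI-MI TAB 2.5; identifiers from columns 1-2,
    column 7 retained as the source annotation), ``tsv`` (3+ columns:
    id_a, id_b, source), ``sif`` ("A relation B", whitespace separated,
    the relation kept as source).  Undirected duplicates are collapsed
    with their source labels merged; malformed lines are skipped and
    counted.
    """
    path = Path(path)
    if dialect is None:
        dialect = _detect_dialect(path)
    if dialect not in INTERACTION_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: {', '.join(INTERACTION_DIALECTS)}"
        )
    edges: dict[tuple[str, str], set[str]] = {}
    n_bad = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if dialect == "psimitab":
                parts = line.split("\t")
                if len(parts) < 15:
                    n_bad += 1
                    continue
                a, b = _mitab_identifier(parts[0]), _mitab_identifier(parts[1])
                source = _mitab_identifier(parts[6]) if parts[6] != "-" else "EXT"
            elif dialect == "sif":
                parts = line.split()
                if len(parts) < 3:
                    n_bad += 1
                    continue
                a, source, b = parts[0], parts[1], parts[2]
            else:
                parts = line.split("\t")
                if len(parts) < 2:
                    n_bad += 1
                    continue
                a, b = parts[0], parts[1]
                if (a, b) == ("id_a", "id_b"):  # header row of our own writer
                    continue
                source = parts[2] if len(parts) >= 3 and parts[2] else "EXT"
            if not a or not b:
                n_bad += 1
                continue
            key = tuple(sorted((a, b)))
            edges.setdefault(key, set()).add(source)
    if n_bad:
        logger.warning("%s: skipped %d malformed lines", path, n_bad)
    rows = [
        {"id_a": a, "id_b": b, "source": "|".join(sorted(srcs))}
        for (a, b), srcs in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=["id_a", "id_b", "source"])


def write_interactions_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_sif(edges: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for row in edges.itertuples(index=False):
            src = getattr(row, "source", "pp") or "pp"
            fh.write(f"{row.id_a}\t{src.split('|')[0]}\t{row.id_b}\n")


def write_network_graphml(
    net: InteractionNetwork,
    path: str | Path,
    edge_attributes: pd.DataFrame | None = None,
) -> None:
    """GraphML export with node class/degree and optional per-edge attributes.

    ``edge_attributes`` (columns id_a, id_b, then numeric/text attributes,
    e.g. a dynamic-edge table with phase) is merged onto matching edges.
    """
    g = net.graph.copy()
    for n, d in g.nodes(data=True):
        d.setdefault("node_class", "neighborhood")
        d["degree"] = g.degree(n)
    for _, _, d in g.edges(data=True):
        if "sources" in d:
            d["source"] = "|".join(sorted(d.pop("sources")))
    if edge_attributes is not None:
        cols = [c for c in edge_attributes.columns if c not in ("id_a", "id_b")]
        for row in edge_attributes.itertuples(index=False):
            if g.has_edge(row.id_a, row.id_b):
                for c in cols:
                    v = getattr(row, c)
                    if isinstance(v, (np.floating, np.integer, np.bool_)):
                        v = v.item()
                    if isinstance(v, float) and np.isnan(v):
                        continue
                    g.edges[row.id_a, row.id_b][c] = v
    nx.write_graphml(g, str(path))


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene -> category table (gene, category_id[, category_name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "category_id"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation file needs columns {sorted(required)}")
    if "category_name" not in df.columns:
        df["category_name"] = df["category_id"]
    return df


def read_reporter_tsv(path: str | Path) -> list[LuminescenceSeries]:
    """Read traces from a TSV with a time_h column plus one column per well."""
    df = pd.read_csv(path, sep="\t")
    if "time_h" not in df.columns:
        raise ValueError("reporter file needs a 'time_h' column")
    t = df["time_h"].to_numpy(dtype=float)
    return [
        LuminescenceSeries(id=str(c), t=t, y=df[c].to_numpy(dtype=float))
        for c in df.columns
        if c != "time_h"
    ]


def write_reporter_tsv(traces: list[LuminescenceSeries], path: str | Path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    t0 = traces[0].t
    for tr in traces[1:]:
        if not np.array_equal(tr.t, t0):
            raise ValueError("traces must share one time grid")
    df = pd.DataFrame({"time_h": t0})
    for tr in traces:
        df[tr.id] = tr.y
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
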