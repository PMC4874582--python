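"""Readers and writers for the external formats, plus dataset configuration.

Internal coordinates are 1-based points.  BED input (0-based, half-open)
is converted at the boundary, using the interval midpoint when a record
spans more than one base.  Chromosome names are kept verbatim -- "chr1"
and "1" are deliberately *not* unified, because silent normalisation
hides dataset mix-ups.  All writers order records by (chrom, position,
id), so identical inputs always produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import (
    DEFAULT_THRESHOLD,
    CIS,
    CISGraph,
    IntegrationSite,
    TranscriptionalElement,
)

KNOWN_ELEMENT_TYPES = {"protein_coding", "miRNA", "lincRNA", "snoRNA"}


@dataclass(frozen=True)
class DatasetConfig:
    """Dataset-level analysis parameters.

    ``k_classes`` is the number of source classes used to normalise
    entropy; it is explicit configuration and never inferred from the
    CIS at hand.  ``ga_threshold`` defaults to the proximity threshold
    but may be raised (200 kb is typical for sparse loci).
    """

    threshold: int = DEFAULT_THRESHOLD
    k_classes: int | None = None
    ga_threshold: int | None = None
    min_order_entropy: int = 4

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.ga_threshold is not None and self.ga_threshold <= 0:
            raise ValueError("ga_threshold must be positive")
        if self.k_classes is not None and self.k_classes < 2:
            raise ValueError("k_classes must be >= 2 when set")

    @property
    def effective_ga_threshold(self) -> int:
        return self.ga_threshold if self.ga_threshold is not None else self.threshold

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return "bed"
    if suffix in (".gff", ".gff3", ".gtf"):
        return "gff"
    return "tsv"


def _data_rows(path: Path) -> list[tuple[int, list[str]]]:
    """(1-based line number, fields) for each non-comment, non-empty line."""
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        rows.append((lineno, line.rstrip("\n").split("\t")))
    return rows


def _parse_int(value: str, what: str, path: Path, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: malformed {what} {value!r}"
        ) from None


def _bed_midpoint(start0: int, end0: int) -> int:
    """1-based midpoint of a 0-based half-open interval."""
    return (start0 + end0 - 1) // 2 + 1


def read_is_table(
    path: str | Path, dialect: str | None = None
) -> list[IntegrationSite]:
    """Read integration sites from a headered TSV or a BED3+/BED6 file.

    TSV columns: chrom, position (1-based), optional source, optional id.
    BED intervals are converted to their midpoint; the name field, when
    present, becomes the id.  Missing ids are generated as IS_000000...
    in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    rows = _data_rows(path)
    sites: list[IntegrationSite] = []
    if dialect == "tsv":
        if not rows:
            return []
        (_, header), *body = rows
        cols = [c.strip().lower() for c in header]
        if "chrom" not in cols or "position" not in cols:
            raise ValueError(
                f"{path}: IS TSV needs 'chrom' and 'position' columns, "
                f"got {cols}"
            )
        idx = {c: i for i, c in enumerate(cols)}
        for k, (lineno, fields) in enumerate(body):
            if len(fields) < len(cols):
                raise ValueError(f"{path}:{lineno}: expected {len(cols)} fields")
            chrom = fields[idx["chrom"]]
            pos = _parse_int(fields[idx["position"]], "position", path, lineno)
            source = fields[idx["source"]] if "source" in idx else ""
            site_id = fields[idx["id"]] if "id" in idx else ""
            sites.append(
                IntegrationSite(
                    id=site_id or f"IS_{k:06d}",
                    chrom=chrom,
                    position=pos,
                    source=source or None,
                )
            )
    elif dialect == "bed":
        for k, (lineno, fields) in enumerate(rows):
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 fields")
            chrom = fields[0]
            start0 = _parse_int(fields[1], "start", path, lineno)
            end0 = _parse_int(fields[2], "end", path, lineno)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            sites.append(
                IntegrationSite(
                    id=name or f"IS_{k:06d}",
                    chrom=chrom,
                    position=_bed_midpoint(start0, end0),
                )
            )
    else:
        raise ValueError(f"unsupported IS dialect {dialect!r}")
    return sites


def read_te_table(
    path: str | Path, dialect: str | None = None
) -> list[TranscriptionalElement]:
    """Read transcriptional elements from TSV, BED or GFF3-like input.

    TSV columns: chrom, tss (1-based), name, optional element_type
    (defaults to "other"), optional strand.  For stranded interval
    records (BED6, GFF) the TSS is the start on "+" and the end on "-".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    elements: list[TranscriptionalElement] = []
    if dialect == "tsv":
        rows = _data_rows(path)
        if not rows:
            return []
        (_, header), *body = rows
        cols = [c.strip().lower() for c in header]
        if not {"chrom", "tss", "name"} <= set(cols):
            raise ValueError(
                f"{path}: TE TSV needs 'chrom', 'tss' and 'name' columns, "
                f"got {cols}"
            )
        idx = {c: i for i, c in enumerate(cols)}
        for k, (lineno, fields) in enumerate(body):
            if len(fields) < len(cols):
                raise ValueError(f"{path}:{lineno}: expected {len(cols)} fields")
            etype = (
                fields[idx["element_type"]] if "element_type" in idx else ""
            )
            elements.append(
                TranscriptionalElement(
                    id=f"TE_{k:06d}",
                    chrom=fields[idx["chrom"]],
                    tss=_parse_int(fields[idx["tss"]], "tss", path, lineno),
                    name=fields[idx["name"]],
                    element_type=etype or "other",
                    strand=fields[idx["strand"]] if "strand" in idx else None,
                )
            )
    elif dialect == "bed":
        for k, (lineno, fields) in enumerate(_data_rows(path)):
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: TE BED needs a name field (>= 4 cols)"
                )
            start0 = _parse_int(fields[1], "start", path, lineno)
            end0 = _parse_int(fields[2], "end", path, lineno)
            strand = fields[5] if len(fields) > 5 else None
            tss = end0 if strand == "-" else start0 + 1
            elements.append(
                TranscriptionalElement(
                    id=f"TE_{k:06d}",
                    chrom=fields[0],
                    tss=tss,
                    name=fields[3],
                    strand=strand,
                )
            )
    elif dialect == "gff":
        elements = _read_gff(path)
    else:
        raise ValueError(f"unsupported TE dialect {dialect!r}")
    return elements


def _read_gff(path: Path) -> list[TranscriptionalElement]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats = list(db.features_of_type("gene"))
    if not feats:
        feats = list(db.all_features())
    elements = []
    for k, f in enumerate(feats):
        name = (
            f.attributes.get("Name", [None])[0]
            or f.attributes.get("gene_name", [None])[0]
            or f.id
        )
        biotype = (
            f.attributes.get("biotype", [None])[0]
            or f.attributes.get("gene_biotype", [None])[0]
            or "other"
        )
        elements.append(
            TranscriptionalElement(
                id=f"TE_{k:06d}",
                chrom=f.seqid,
                tss=f.end if f.strand == "-" else f.start,
                name=name,
                element_type=(
                    biotype if biotype in KNOWN_ELEMENT_TYPES else "other"
                ),
                strand=f.strand,
            )
        )
    return elements


# ---------------------------------------------------------------------------
# Table writers
# ---------------------------------------------------------------------------

def write_is_table(
    sites: Sequence[IntegrationSite], path: str | Path
) -> None:
    """Write IS as the package TSV dialect (1-based, headered)."""
    ordered = sorted(sites, key=lambda s: (s.chrom, s.position, s.id))
    frame = pd.DataFrame(
        {
            "chrom": [s.chrom for s in ordered],
            "position": [s.position for s in ordered],
            "source": [s.source or "" for s in ordered],
            "id": [s.id for s in ordered],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_bed(
    intervals: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def cis_table_frame(cis_list: Sequence[CIS]) -> pd.DataFrame:
    """Per-CIS table: chrom, start, dimension, order, composition, bridged."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in cis_list],
            "start": [c.start for c in cis_list],
            "dimension": [c.dimension for c in cis_list],
            "order": [c.order for c in cis_list],
            "composition": [
                ",".join(
                    f"{lab}:{cnt}"
                    for lab, cnt in sorted(c.composition.items())
                )
                for c in cis_list
            ],
            "atmosphere": [
                ",".join(sorted(t.name for t in c.atmosphere))
                for c in cis_list
            ],
            "bridged": [int(c.bridged) for c in cis_list],
        }
    )


def parse_composition(text: str) -> dict[str, int]:
    """Inverse of the ``lab:count,...`` serialization in the CIS table."""
    out: dict[str, int] = {}
    for part in str(text).split(","):
        if not part:
            continue
        lab, _, cnt = part.rpartition(":")
        out[lab] = int(cnt)
    return out


# ---------------------------------------------------------------------------
# Graph writers
# ---------------------------------------------------------------------------

def _sorted_nodes(g: nx.Graph) -> list[str]:
    return sorted(
        g.nodes,
        key=lambda n: (
            g.nodes[n]["chrom"],
            g.nodes[n]["position"],
            g.nodes[n]["category"],
            n,
        ),
    )


def write_graph(
    cis_graph: CISGraph, path: str | Path, format: str = "graphml"
) -> None:
    """Write the graph as GraphML or SIF (Cytoscape-compatible).

    GraphML keeps node attributes (category, chrom, position, label,
    source) and edge weights and round-trips losslessly through
    :func:`read_graphml`.  SIF encodes edges as ``idA near idB`` and
    isolated nodes as bare id lines.
    """
    g = cis_graph.graph
    order = _sorted_nodes(g)
    if format == "graphml":
        clean = nx.Graph(threshold=cis_graph.threshold)
        for n in order:
            data = {k: v for k, v in g.nodes[n].items() if k != "obj"}
            clean.add_node(n, **data)
        for a, b in sorted(
            (tuple(sorted((u, v))) for u, v in g.edges), key=tuple
        ):
            clean.add_edge(a, b, weight=int(g.edges[a, b]["weight"]))
        nx.write_graphml(clean, path)
    elif format == "sif":
        with open(path, "w") as fh:
            seen_in_edge = set()
            lines = []
            for a, b in sorted(
                tuple(sorted((u, v))) for u, v in g.edges
            ):
                lines.append(f"{a}\tnear\t{b}")
                seen_in_edge.update((a, b))
            for n in order:
                if n not in seen_in_edge:
                    lines.append(n)
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unsupported graph format {format!r}")


def read_graphml(path: str | Path) -> CISGraph:
    """Read back a GraphML file written by :func:`write_graph`."""
    g = nx.read_graphml(path)
    threshold = int(g.graph.get("threshold", DEFAULT_THRESHOLD))
    for n, data in g.nodes(data=True):
        data["position"] = int(data["position"])
        if data["category"] == "IS":
            data["obj"] = IntegrationSite(
                id=n,
                chrom=data["chrom"],
                position=data["position"],
                source=data.get("source") or None,
            )
        else:
            data["obj"] = TranscriptionalElement(
                id=n,
                chrom=data["chrom"],
                tss=data["position"],
                name=data.get("label", n),
                element_type=data.get("source") or "other",
            )
    for _, _, data in g.edges(data=True):
        data["weight"] = int(data["weight"])
    return CISGraph(graph=g, threshold=threshold)
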