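"""Domain types and file I/O shared by every pipeline stage.

Conventions
-----------
* Expression matrices are features x samples, log2 scale, one TSV per RNA
  class (lncRNA / miRNA / mRNA).  The scale is declared, never sniffed.
* Feature ids are case-sensitive and namespaced by RNA class: the same
  name may legitimately occur as both a lncRNA and an mRNA.
* Sample sheets are two-column TSVs (sample_id, condition) with
  condition in {induced, control}.
* Gene sets use the standard GMT dialect.
* Networks export to SIF, GraphML or a TSV edge list, all of which
  Cytoscape can ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import networkx as nx
import pandas as pd

from cernet.errors import FormatError, ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from cernet.network import CeRNANetwork

logger = logging.getLogger(__name__)

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")
CONDITIONS = ("induced", "control")

#: SIF relation labels for the two tripartite edge types.
EDGE_RELATIONS = ("lncRNA_miRNA", "miRNA_mRNA")


@dataclass(frozen=True)
class SampleSheet:
    """Ordered sample ids with their two-class condition labels."""

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.conditions):
            raise ValidationError("sample sheet: ids and conditions differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample sheet: duplicate sample ids")
        bad = sorted(set(self.conditions) - set(CONDITIONS))
        if bad:
            raise ValidationError(f"sample sheet: unknown condition labels {bad}; expected {CONDITIONS}")
        for cond in CONDITIONS:
            if cond not in self.conditions:
                raise ValidationError(f"sample sheet: condition '{cond}' has no samples")

    def mask(self, condition: str) -> list[bool]:
        return [c == condition for c in self.conditions]


@dataclass
class ExpressionBundle:
    """Three aligned log2 expression matrices plus the sample design.

    Each matrix is a pandas DataFrame with feature ids as the index and
    the shared ordered sample list as columns.
    """

    lncrna: pd.DataFrame
    mirna: pd.DataFrame
    mrna: pd.DataFrame
    sheet: SampleSheet

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        samples = list(self.sheet.sample_ids)
        for cond in CONDITIONS:
            if sum(self.sheet.mask(cond)) < 2:
                raise ValidationError(f"bundle: condition '{cond}' has fewer than 2 samples")
        for cls, mat in self.matrices().items():
            if list(mat.columns) != samples:
                raise ValidationError(f"bundle: {cls} matrix columns do not match the sample sheet order")
            if mat.index.has_duplicates:
                dups = sorted(mat.index[mat.index.duplicated()].unique())
                raise ValidationError(f"bundle: duplicate {cls} feature ids {dups[:5]}")
            values = mat.to_numpy()
            if values.size and not pd.notna(values).all():
                raise ValidationError(f"bundle: {cls} matrix contains missing values")
            import numpy as np

            if values.size and not np.isfinite(values.astype(float)).all():
                raise ValidationError(f"bundle: {cls} matrix contains non-finite values")

    def matrices(self) -> dict[str, pd.DataFrame]:
        return {"lncRNA": self.lncrna, "miRNA": self.mirna, "mRNA": self.mrna}

    def matrix(self, rna_class: str) -> pd.DataFrame:
        try:
            return self.matrices()[rna_class]
        except KeyError:
            raise ValidationError(f"unknown RNA class '{rna_class}'; expected one of {RNA_CLASSES}") from None

    @property
    def samples(self) -> tuple[str, ...]:
        return self.sheet.sample_ids

    def values_for(self, rna_class: str, feature_id: str):
        mat = self.matrix(rna_class)
        if feature_id not in mat.index:
            raise ValidationError(f"feature '{feature_id}' not present in {rna_class} matrix")
        return mat.loc[feature_id].to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GO terms, pathways, ...)."""

    terms: list["GeneSet"] = field(default_factory=list)

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def get(self, term_id: str) -> "GeneSet":
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]
    namespace: str = "geneset"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set '{self.term_id}' has no members")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a two-column TSV (sample_id, condition) with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "condition"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample sheet must have columns {sorted(required)}, got {list(df.columns)}")
    return SampleSheet(tuple(df["sample_id"]), tuple(df["condition"]))


def _read_matrix(path: str | Path, rna_class: str, sheet: SampleSheet) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    missing = [s for s in sheet.sample_ids if s not in df.columns]
    if missing:
        raise FormatError(f"{path}: samples {missing} from the sheet are absent from the matrix header")
    df = df[list(sheet.sample_ids)]  # reorder columns to sheet order
    out = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(f"{path}: non-numeric value {df.loc[row, col]!r} at feature '{row}', sample '{col}'")
        out[col] = converted.astype(float)
    out.index.name = None
    if out.index.has_duplicates:
        dups = sorted(out.index[out.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate {rna_class} feature ids {dups[:5]}")
    return out


def read_expression(
    lncrna_path: str | Path,
    mirna_path: str | Path,
    mrna_path: str | Path,
    sheet: SampleSheet | str | Path,
) -> ExpressionBundle:
    """Read the three per-class expression TSVs into a validated bundle.

    Columns are reordered to the sample-sheet order; values are taken as
    log2 abundance verbatim (no re-logging, no imputation: a missing or
    non-numeric cell is an error).
    """
    if not isinstance(sheet, SampleSheet):
        sheet = read_sample_sheet(sheet)
    return ExpressionBundle(
        lncrna=_read_matrix(lncrna_path, "lncRNA", sheet),
        mirna=_read_matrix(mirna_path, "miRNA", sheet),
        mrna=_read_matrix(mrna_path, "mRNA", sheet),
        sheet=sheet,
    )


def write_expression(bundle: ExpressionBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle back to the TSV dialect ``read_expression`` accepts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    names = {"lncRNA": "lncrna", "miRNA": "mirna", "mRNA": "mrna"}
    for cls, mat in bundle.matrices().items():
        p = directory / f"{names[cls]}_expression.tsv"
        mat.to_csv(p, sep="\t", index_label="feature_id")
        paths[cls] = p
    sheet_path = directory / "samples.tsv"
    pd.DataFrame(
        {"sample_id": bundle.sheet.sample_ids, "condition": bundle.sheet.conditions}
    ).to_csv(sheet_path, sep="\t", index=False)
    paths["sheet"] = sheet_path
    return paths


def read_gmt(path: str | Path, namespace: str = "geneset") -> GeneSetCollection:
    """Read a GMT file: ``term<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are dropped with a warning; term
    order is preserved.
    """
    terms: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            term_id, term_name, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("%s:%d: term %s repeats %d member(s); deduplicated",
                               path, lineno, term_id, len(members) - len(unique))
            terms.append(GeneSet(term_id, term_name, frozenset(unique), namespace))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in collection:
            fh.write("\t".join([term.term_id, term.term_name, *sorted(term.members)]) + "\n")


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def write_network(network: "CeRNANetwork", path: str | Path, format: str = "sif") -> None:
    """Export a ceRNA network for Cytoscape-style viewers.

    SIF rows are ``source<TAB>relation<TAB>target`` with relation in
    {lncRNA_miRNA, miRNA_mRNA}; GraphML carries node attributes ``rna_class``
    and ``direction`` and the edge attribute ``relation``; the TSV edge
    list mirrors SIF with a header.  Edges are written in deterministic
    lexicographic order.
    """
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format '{format}'; expected one of {NETWORK_FORMATS}")
    rows = sorted(
        (src, rel, dst) for src, dst, rel in network.typed_edges()
    )
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for src, rel, dst in rows:
                fh.write(f"{src}\t{rel}\t{dst}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\trelation\ttarget\n")
            for src, rel, dst in rows:
                fh.write(f"{src}\t{rel}\t{dst}\n")
    else:
        graph = nx.Graph()
        for node, attrs in sorted(network.node_attributes().items()):
            graph.add_node(node, rna_class=attrs["rna_class"], direction=attrs["direction"])
        for src, rel, dst in rows:
            graph.add_edge(src, dst, relation=rel)
        nx.write_graphml(graph, path)


def read_network_edges(path: str | Path, format: str = "sif") -> set[tuple[str, str, str]]:
    """Read back (source, relation, target) rows from an exported network."""
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format '{format}'")
    edges: set[tuple[str, str, str]] = set()
    if fmt in ("sif", "tsv"):
        with open(path) as fh:
            lines: Iterable[str] = fh
            if fmt == "tsv":
                lines = list(fh)[1:]
            for line in lines:
                line = line.rstrip("\n")
                if not line:
                    continue
                src, rel, dst = line.split("\t")
                edges.add((src, rel, dst))
    else:
        graph = nx.read_graphml(path)
        # canonical orientation: lncRNA -> miRNA, miRNA -> mRNA
        src_class = {"lncRNA_miRNA": "lncRNA", "miRNA_mRNA": "miRNA"}
        for u, v, attrs in graph.edges(data=True):
            rel = attrs["relation"]
            if graph.nodes[u]["rna_class"] == src_class[rel]:
                edges.add((u, rel, v))
            else:
                edges.add((v, rel, u))
    return edges
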