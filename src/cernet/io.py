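"""Core data model and readers/writers for every external artifact.

The pipeline revolves around a small set of typed containers:

* :class:`ExpressionMatrix` — features x samples intensities plus the sample
  design (genotype, cell state, line).
* feature annotation — a validated :class:`pandas.DataFrame` mapping each
  feature to its RNA class, gene symbol, host gene, chromosome and
  X-inactivation-escape status.
* :class:`GeneSetCollection` — named gene sets (GMT).
* target tables — miRNA -> transcript interactions as a validated DataFrame.
* :class:`CeRNACircuit` — a sponge/miRNA-set/mRNA triplet with its
  co-expression evidence.

All on-disk formats are plain text (TSV, GMT, SIF, GraphML, JSON) and all
writers are deterministic: identical objects produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, UserError, ValidationError

GENOTYPES = ("WT", "TS")
STATES = ("iPSC", "CM")
RNA_CLASSES = ("mRNA", "lncRNA", "circRNA")
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer", "imported")

#: Intensities are strictly positive after normalization, so the package
#: converts scales with a plain log2(x) / 2**x pair (no pseudo-count); this
#: keeps linear ratios and log2 differences exactly interconvertible.

#: printf-style float format used by every TSV writer (determinism).
FLOAT_FMT = "%.6g"

ANNOTATION_COLUMNS = (
    "feature_id",
    "rna_class",
    "gene_symbol",
    "host_gene",
    "chromosome",
    "xci_escape",
)

TARGET_COLUMNS = ("mirna_id", "target_id", "site_type", "position", "score", "source")


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with sample-group metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    sample_groups
        DataFrame indexed by sample id with columns ``genotype`` (WT/TS),
        ``state`` (iPSC/CM) and ``line_id``. Must cover every sample.
    scale
        ``"linear"`` for raw/normalized intensities, ``"log2"`` for
        log2(x + 1)-transformed values.
    """

    values: pd.DataFrame
    sample_groups: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at feature {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale tag: {self.scale!r}")
        g = self.sample_groups
        missing = [s for s in v.columns if s not in g.index]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing}")
        for col in ("genotype", "state", "line_id"):
            if col not in g.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        bad_g = set(g["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise ValidationError(f"unknown genotype value(s): {sorted(bad_g)}")
        bad_s = set(g["state"]) - set(STATES)
        if bad_s:
            raise ValidationError(f"unknown state value(s): {sorted(bad_s)}")

    # -- basic accessors ----------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples(self, genotype: str | None = None, state: str | None = None) -> list[str]:
        """Sample ids matching a genotype and/or state, in matrix order."""
        g = self.sample_groups
        keep = pd.Series(True, index=g.index)
        if genotype is not None:
            keep &= g["genotype"] == genotype
        if state is not None:
            keep &= g["state"] == state
        chosen = set(g.index[keep])
        return [s for s in self.values.columns if s in chosen]

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise UserError(f"features not in matrix: {missing[:5]}")
        return replace(self, values=self.values.loc[list(feature_ids)])

    # -- scale conversions --------------------------------------------------

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2 view; a no-op if already log2."""
        if self.scale == "log2":
            return self
        if (self.values.to_numpy() <= 0).any():
            raise UserError("non-positive intensities cannot be log2-transformed")
        return replace(self, values=np.log2(self.values), scale="log2")

    def to_linear(self) -> "ExpressionMatrix":
        """Invert :meth:`to_log2`; a no-op if already linear."""
        if self.scale == "linear":
            return self
        return replace(self, values=2.0 ** self.values, scale="linear")


def concat_matrices(matrices) -> ExpressionMatrix:
    """Stack matrices over features; all must share samples and scale."""
    matrices = list(matrices)
    if not matrices:
        raise UserError("nothing to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if list(m.values.columns) != list(first.values.columns):
            raise UserError("matrices have different sample columns")
        if m.scale != first.scale:
            raise UserError("matrices mix linear and log2 scales")
    values = pd.concat([m.values for m in matrices], axis=0)
    return ExpressionMatrix(values, first.sample_groups, scale=first.scale)


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet I/O
# ---------------------------------------------------------------------------

_SEP = {"tsv": "\t", "csv": ","}


def read_expression_matrix(
    path, sample_sheet, dialect: str = "tsv", scale: str = "linear"
) -> ExpressionMatrix:
    """Read a features x samples table plus its sidecar sample sheet.

    The matrix file has feature ids in the first column and sample ids in the
    header; the sample sheet is a TSV with columns
    ``sample_id, genotype, state, line_id``.
    """
    if dialect not in _SEP:
        raise UserError(f"unknown dialect {dialect!r}; expected tsv or csv")
    df = pd.read_csv(path, sep=_SEP[dialect], index_col=0)
    if df.index.hasnans or df.isna().any().any():
        raise ParseError(f"{path}: missing values are not supported")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[~df[col].map(np.isreal)][:1]
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r}"
                + (f", row {bad[0]!r}" if len(bad) else "")
            )
    groups = read_sample_sheet(sample_sheet)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, groups, scale=scale)


def write_expression_matrix(m: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    if dialect not in _SEP:
        raise UserError(f"unknown dialect {dialect!r}; expected tsv or csv")
    m.values.to_csv(
        path, sep=_SEP[dialect], index_label="feature_id", float_format=FLOAT_FMT,
        lineterminator="\n",
    )


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "state", "line_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample id in sample sheet: {dup!r}")
    return df.set_index("sample_id")


def write_sample_sheet(groups: pd.DataFrame, path) -> None:
    groups.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------


def validate_feature_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalize) a feature annotation table.

    Required columns: feature_id, rna_class, gene_symbol, host_gene,
    chromosome, xci_escape. ``xci_escape`` must be False everywhere off
    chromosome X.
    """
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"annotation missing columns {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        dup = df["feature_id"][df["feature_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate feature id in annotation: {dup!r}")
    bad = set(df["rna_class"]) - set(RNA_CLASSES)
    if bad:
        raise ValidationError(f"unknown rna_class value(s): {sorted(bad)}")
    df = df.copy()
    if df["xci_escape"].dtype != bool:
        df["xci_escape"] = (
            df["xci_escape"].astype(str).str.lower().isin(("true", "1", "yes"))
        )
    off_x = df[(df["chromosome"] != "X") & df["xci_escape"]]
    if len(off_x):
        raise ValidationError(
            f"xci_escape set on non-X feature: {off_x['feature_id'].iloc[0]!r}"
        )
    return df


def read_feature_annotation(path) -> pd.DataFrame:
    return validate_feature_annotation(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_feature_annotation(df: pd.DataFrame, path) -> None:
    validate_feature_annotation(df)[list(ANNOTATION_COLUMNS)].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def collapse_probes(
    m: ExpressionMatrix, probe_to_gene: dict, method: str = "max_mean"
) -> ExpressionMatrix:
    """Collapse multiple probes per gene to one row per gene.

    ``max_mean`` keeps the probe with the highest mean intensity;
    ``mean`` averages probes. Probes absent from the map are kept as-is.
    """
    if method not in ("max_mean", "mean"):
        raise UserError(f"unknown collapse method {method!r}")
    genes = m.values.index.map(lambda f: probe_to_gene.get(f, f))
    df = m.values.copy()
    df.index = genes
    if method == "mean":
        out = df.groupby(level=0, sort=False).mean()
    else:
        means = df.mean(axis=1).to_numpy()
        order = pd.DataFrame({"gene": genes, "mean": means})
        keep = order.groupby("gene", sort=False)["mean"].idxmax().to_numpy()
        out = df.iloc[np.sort(keep)]
    return ExpressionMatrix(out, m.sample_groups, scale=m.scale)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict = field(default_factory=dict)  # name -> list of members
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str):
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member...

    Members on one line are deduplicated preserving first occurrence.
    """
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {i}: expected >=3 tab-separated fields")
        name, desc = parts[0], parts[1]
        if name in sets:
            raise ValidationError(f"{path}: duplicate gene set name {name!r}")
        members = list(dict.fromkeys(p for p in parts[2:] if p))
        if not members:
            raise ParseError(f"{path}: line {i}: gene set {name!r} has no members")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


# ---------------------------------------------------------------------------
# Target tables
# ---------------------------------------------------------------------------


def validate_target_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("mirna_id", "target_id", "site_type", "source"):
        if col not in df.columns:
            raise ValidationError(f"target table missing column {col!r}")
    df = df.copy()
    if "position" not in df.columns:
        df["position"] = pd.NA
    if "score" not in df.columns:
        df["score"] = np.nan
    bad = set(df["site_type"]) - set(SITE_TYPES)
    if bad:
        raise ValidationError(f"unknown site_type value(s): {sorted(bad)}")
    key = df[["mirna_id", "target_id", "position", "source"]].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        offender = df.loc[key.duplicated(), ["mirna_id", "target_id"]].iloc[0]
        raise ValidationError(
            "duplicate target record: "
            f"({offender['mirna_id']}, {offender['target_id']})"
        )
    return df[list(TARGET_COLUMNS)]


def read_target_table(path) -> pd.DataFrame:
    return validate_target_table(pd.read_csv(path, sep="\t"))


def write_target_table(df: pd.DataFrame, path) -> None:
    validate_target_table(df).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Networks (SIF / GraphML)
# ---------------------------------------------------------------------------


def _sorted_graph(net: nx.Graph) -> nx.Graph:
    """Copy with nodes/edges in sorted order so writers are byte-stable."""
    out = nx.DiGraph() if net.is_directed() else nx.Graph()
    for n in sorted(net.nodes):
        out.add_node(n, **{k: v for k, v in net.nodes[n].items() if v is not None})
    edges = net.edges if net.is_directed() else (
        tuple(sorted(e, key=str)) for e in net.edges
    )
    for u, v in sorted(edges, key=lambda e: (str(e[0]), str(e[1]))):
        out.add_edge(u, v, **{k: w for k, w in net.edges[u, v].items() if w is not None})
    return out


def write_network(net: nx.Graph, path, format: str = "sif") -> None:
    """Export a network for Cytoscape-style tooling.

    SIF rows are ``source <tab> edge_kind <tab> target``; GraphML carries all
    node and edge attributes. Both outputs are byte-stable.
    """
    g = _sorted_graph(net)
    if format == "sif":
        with open(path, "w", newline="\n") as fh:
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{data.get('edge_kind', 'interacts')}\t{v}\n")
            # Cytoscape convention: isolated nodes appear as bare rows.
            for n in g.nodes:
                if g.degree(n) == 0:
                    fh.write(f"{n}\n")
    elif format == "graphml":
        nx.write_graphml_xml(g, path)
    else:
        raise UserError(f"unknown network format {format!r}; expected sif or graphml")


def read_network(path) -> nx.Graph:
    """Read back a GraphML export (round-trip partner of write_network)."""
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# ceRNA circuits: TSV + Sankey JSON
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CeRNACircuit:
    """A sponge (lnc/circRNA) -> shared miRNAs -> mRNA regulatory circuit.

    ``shared_mirna_ids`` is the exhaustive set of miRNAs predicted to target
    both endpoints; ``pcc``/``pcc_p`` are copied from the co-expression edge
    that seeded the circuit.
    """

    sponge_feature_id: str
    mrna_feature_id: str
    shared_mirna_ids: tuple
    pcc: float
    pcc_p: float
    contrast: str = ""
    shared_mirna_enrichment_p: float | None = None
    sponge_host_escapes_xci: bool | None = None
    mrna_in_filter_set: bool | None = None

    def __post_init__(self) -> None:
        if not self.shared_mirna_ids:
            raise ValidationError(
                f"circuit ({self.sponge_feature_id}, {self.mrna_feature_id}) "
                "has no shared miRNAs"
            )
        if not -1.0 <= self.pcc <= 1.0:
            raise ValidationError(f"pcc out of range: {self.pcc}")

    @property
    def pair(self) -> tuple:
        return (self.sponge_feature_id, self.mrna_feature_id)


def write_circuits(circuits, path) -> None:
    """Flat TSV: one row per circuit, miRNAs semicolon-joined."""
    rows = [
        {
            "sponge_feature_id": c.sponge_feature_id,
            "mrna_feature_id": c.mrna_feature_id,
            "shared_mirna_ids": ";".join(sorted(c.shared_mirna_ids)),
            "n_shared_mirnas": len(c.shared_mirna_ids),
            "pcc": c.pcc,
            "pcc_p": c.pcc_p,
            "contrast": c.contrast,
            "shared_mirna_enrichment_p": c.shared_mirna_enrichment_p,
            "sponge_host_escapes_xci": c.sponge_host_escapes_xci,
            "mrna_in_filter_set": c.mrna_in_filter_set,
        }
        for c in sorted(circuits, key=lambda c: c.pair)
    ]
    cols = [
        "sponge_feature_id", "mrna_feature_id", "shared_mirna_ids",
        "n_shared_mirnas", "pcc", "pcc_p", "contrast",
        "shared_mirna_enrichment_p", "sponge_host_escapes_xci",
        "mrna_in_filter_set",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n"
    )


def sankey_data(circuits) -> dict:
    """Two-layer Sankey links (sponge->miRNA, miRNA->mRNA) with counts.

    Nodes are emitted once each; link values count the circuits carrying
    that link.
    """
    links: dict = {}
    nodes: dict = {}
    for c in circuits:
        nodes.setdefault(c.sponge_feature_id, "sponge")
        nodes.setdefault(c.mrna_feature_id, "mRNA")
        for m in c.shared_mirna_ids:
            nodes.setdefault(m, "miRNA")
            for pair in ((c.sponge_feature_id, m), (m, c.mrna_feature_id)):
                links[pair] = links.get(pair, 0) + 1
    return {
        "nodes": [{"id": n, "kind": k} for n, k in sorted(nodes.items())],
        "links": [
            {"source": s, "target": t, "value": v}
            for (s, t), v in sorted(links.items())
        ],
    }


def write_sankey(circuits, path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(sankey_data(circuits), fh, indent=1, sort_keys=True)
        fh.write("\n")
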