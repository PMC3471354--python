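"""Readers and writers for pathways, expression matrices, phenotype labels,
universe gene lists and screen-result tables.

File dialects
-------------
Pathways are SIF-style whitespace/tab-delimited edge lists, one pathway per
file: two columns are source/target; three or more columns are treated as
classic SIF (``source  interaction-type  target [target ...]``) and the type
column is skipped; single-column lines declare isolated genes.  Interactions
are undirected, self-loops and duplicates are dropped with a logged warning.

Expression matrices are GCT 1.2 (``#1.2`` header, dims line, Name/Description
columns) or plain headered TSV with the gene identifier in the first column.
Phenotype labels are categorical CLS (three lines, positional) or two-column
TSV (sample id, class label).
"""

from __future__ import annotations

import io as _stdio
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyPathwayError,
    ExpressionFormatError,
    PathwayFormatError,
    PhenotypeFormatError,
)

log = logging.getLogger(__name__)

#: An undirected interaction, stored with endpoints in sorted order.
Edge = tuple[str, str]


def canonical_edge(u: str, v: str) -> Edge:
    """Return the unordered gene pair ``{u, v}`` as a sorted tuple."""
    u, v = str(u).strip(), str(v).strip()
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Pathway:
    """An undirected pathway graph P = (G, I).

    ``genes`` may contain isolated nodes; ``interactions`` are canonical
    (sorted) unordered pairs with no self-loops.  The graph may be
    disconnected.
    """

    name: str
    genes: frozenset[str]
    interactions: frozenset[Edge]

    def __post_init__(self) -> None:
        for u, v in self.interactions:
            if u == v:
                raise PathwayFormatError(f"self-loop on {u!r} in pathway {self.name!r}")
            if u > v:
                raise PathwayFormatError(f"non-canonical edge ({u!r}, {v!r})")
            if u not in self.genes or v not in self.genes:
                raise PathwayFormatError(
                    f"edge ({u!r}, {v!r}) has endpoint outside the gene set"
                )

    @classmethod
    def from_edges(
        cls, name: str, edges: Iterable[tuple[str, str]], isolated: Iterable[str] = ()
    ) -> "Pathway":
        """Build a pathway from raw (possibly unordered, duplicated) pairs.

        Self-loops are dropped with a warning; endpoints and isolated genes
        form the node set.
        """
        canon: set[Edge] = set()
        genes: set[str] = {str(g).strip() for g in isolated}
        n_loops = 0
        for u, v in edges:
            e = canonical_edge(u, v)
            if e[0] == e[1]:
                n_loops += 1
                genes.add(e[0])
                continue
            canon.add(e)
            genes.update(e)
        if n_loops:
            log.warning("pathway %s: dropped %d self-loop(s)", name, n_loops)
        return cls(name=name, genes=frozenset(genes), interactions=frozenset(canon))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def sorted_interactions(self) -> list[Edge]:
        return sorted(self.interactions)


def read_interaction_file(path: str | Path, name: str | None = None) -> Pathway:
    """Read an undirected pathway from a SIF-style edge-list file.

    Lines beginning with ``#`` are ignored.  Raises
    :class:`PathwayFormatError` on unparseable content and
    :class:`EmptyPathwayError` if no valid interaction survives.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:
                isolated.append(fields[0])
            elif len(fields) == 2:
                edges.append((fields[0], fields[1]))
            else:
                # classic SIF: source, interaction type, one or more targets
                src = fields[0]
                for tgt in fields[2:]:
                    edges.append((src, tgt))
    pw = Pathway.from_edges(name, edges, isolated)
    if not pw.interactions:
        raise EmptyPathwayError(f"{path}: no valid interactions")
    return pw


def write_pathway(pathway: Pathway, path: str | Path) -> None:
    """Write a pathway as a two-column TSV edge list (round-trippable).

    Isolated genes are written as single-column lines.
    """
    connected = {g for e in pathway.interactions for g in e}
    with open(path, "w") as fh:
        for u, v in pathway.sorted_interactions():
            fh.write(f"{u}\t{v}\n")
        for g in sorted(pathway.genes - connected):
            fh.write(f"{g}\n")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of expression values.

    Wraps a :class:`pandas.DataFrame` (index = gene ids, columns = sample
    ids); identifiers must be unique and every value finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate gene ids: {dup[:5]}")
        if df.columns.has_duplicates:
            raise ExpressionFormatError("duplicate sample ids")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ExpressionFormatError(f"non-numeric expression value: {exc}") from exc
        if not np.isfinite(values).all():
            raise ExpressionFormatError("expression matrix contains NaN/inf entries")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def drop_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        drop = set(sample_ids)
        keep = [s for s in self.data.columns if s not in drop]
        return ExpressionMatrix(self.data[keep])


def _read_gct(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ExpressionFormatError(f"{path}: not a GCT 1.2 file")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ExpressionFormatError(f"{path}: malformed GCT dims line")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise ExpressionFormatError(f"{path}: malformed GCT dims line") from exc
        body = fh.read()
    try:
        df = pd.read_csv(_stdio.StringIO(body), sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas raises varied types
        raise ExpressionFormatError(f"{path}: unreadable GCT body: {exc}") from exc
    if df.columns[0].lower() != "description":
        raise ExpressionFormatError(f"{path}: GCT missing Description column")
    df = df.drop(columns=df.columns[0])
    if df.shape != (n_genes, n_samples):
        raise ExpressionFormatError(
            f"{path}: GCT dims line says {n_genes}x{n_samples} "
            f"but body is {df.shape[0]}x{df.shape[1]}"
        )
    return _finalize_frame(df, path)


def _finalize_frame(df: pd.DataFrame, path: Path) -> ExpressionMatrix:
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    try:
        df = df.apply(pd.to_numeric)
    except (TypeError, ValueError) as exc:
        raise ExpressionFormatError(f"{path}: non-numeric cell: {exc}") from exc
    return ExpressionMatrix(df)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a GCT 1.2 or headered-TSV expression matrix (auto-detected)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        return _read_gct(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return _finalize_frame(df, path)


def write_gct(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in GCT 1.2 format."""
    df = expr.data
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in df.iterrows():
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{gene}\t{gene}\t{vals}\n")


@dataclass(frozen=True)
class PhenotypeLabels:
    """Sample -> class-label assignments.

    CLS files carry labels positionally (in the expression matrix's sample
    order); such labels are stored in ``positional`` and bound to sample ids
    via :meth:`resolve`.
    """

    assignments: Mapping[str, str] | None = None
    positional: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if (self.assignments is None) == (self.positional is None):
            raise ConfigurationError(
                "exactly one of assignments/positional must be given"
            )

    def resolve(self, sample_ids: Sequence[str]) -> dict[str, str]:
        """Return a sample-id -> label mapping for the given sample order."""
        if self.assignments is not None:
            return {str(s): str(l) for s, l in self.assignments.items()}
        if len(self.positional) != len(sample_ids):
            raise PhenotypeFormatError(
                f"CLS carries {len(self.positional)} labels but the matrix "
                f"has {len(sample_ids)} samples"
            )
        return {str(s): l for s, l in zip(sample_ids, self.positional)}

    def classes(self) -> set[str]:
        if self.assignments is not None:
            return set(map(str, self.assignments.values()))
        return set(self.positional)


def read_phenotype_labels(path: str | Path) -> PhenotypeLabels:
    """Read categorical CLS or two-column TSV phenotype labels."""
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip()
    ]
    if not lines:
        raise PhenotypeFormatError(f"{path}: empty label file")
    head = lines[0].split()
    is_cls = (
        len(lines) >= 3
        and len(head) == 3
        and all(tok.lstrip("-").isdigit() for tok in head)
        and lines[1].startswith("#")
    )
    if is_cls:
        n_samples, n_classes = int(head[0]), int(head[1])
        class_names = lines[1].lstrip("#").split()
        tokens = lines[2].split()
        if len(tokens) != n_samples:
            raise PhenotypeFormatError(
                f"{path}: CLS count line says {n_samples} samples but the "
                f"label line has {len(tokens)}"
            )
        if all(t.isdigit() for t in tokens):
            if len(class_names) < n_classes:
                raise PhenotypeFormatError(f"{path}: CLS class-name line too short")
            labels = tuple(class_names[int(t)] for t in tokens)
        else:
            labels = tuple(tokens)
        if len(set(labels)) != n_classes:
            log.warning(
                "%s: CLS declares %d classes but %d distinct labels found",
                path, n_classes, len(set(labels)),
            )
        return PhenotypeLabels(positional=labels)
    assignments: dict[str, str] = {}
    for ln in lines:
        if ln.startswith("#"):
            continue
        fields = ln.split("\t") if "\t" in ln else ln.split()
        if len(fields) != 2:
            raise PhenotypeFormatError(f"{path}: expected 2 columns, got {ln!r}")
        assignments[fields[0].strip()] = fields[1].strip()
    return PhenotypeLabels(assignments=assignments)


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    """Write positional labels as a 3-line categorical CLS file."""
    classes = list(dict.fromkeys(labels))  # first-appearance order
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(labels) + "\n")


def load_universe(path: str | Path) -> frozenset[str]:
    """Read a one-gene-per-line universe file."""
    genes = {
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    }
    if not genes:
        raise ConfigurationError(f"{path}: empty universe file")
    return frozenset(genes)


def restrict_to_measured(pathway: Pathway, expr: ExpressionMatrix) -> Pathway:
    """Drop pathway genes (and incident interactions) without expression rows.

    Raises :class:`EmptyPathwayError` when no interaction has both endpoints
    measured.  Idempotent.
    """
    measured = set(expr.gene_ids)
    genes = pathway.genes & measured
    edges = frozenset(
        e for e in pathway.interactions if e[0] in measured and e[1] in measured
    )
    n_gdrop = len(pathway.genes) - len(genes)
    n_edrop = len(pathway.interactions) - len(edges)
    if n_gdrop or n_edrop:
        log.info(
            "pathway %s: dropped %d unmeasured gene(s), %d interaction(s)",
            pathway.name, n_gdrop, n_edrop,
        )
    if not edges:
        raise EmptyPathwayError(
            f"pathway {pathway.name!r}: no interaction has both endpoints measured"
        )
    return Pathway(name=pathway.name, genes=frozenset(genes), interactions=edges)


@dataclass(frozen=True)
class ScreenResult:
    """One pathway x condition record of the perturbation screen."""

    pathway_name: str
    condition: str
    z_best: float
    z_full: float
    p_empirical: float
    p_adjusted: float
    best_edges: frozenset[Edge]
    k_permutations: int
    seed: int


RESULT_COLUMNS = [
    "pathway", "condition", "z_full", "z_best", "p_empirical",
    "p_adjusted", "n_best_edges", "k_permutations", "seed",
]


def write_results(
    results: Sequence[ScreenResult],
    out_dir: str | Path,
    alpha: float = 0.05,
) -> None:
    """Write the screen's result tables under ``out_dir``.

    Produces ``results.tsv`` (one row per pathway x condition),
    ``adjusted_pvalue_matrix.tsv`` (pathways x conditions), and one edge-list
    file per pair significant at ``alpha`` under ``edges/``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "pathway": r.pathway_name,
            "condition": r.condition,
            "z_full": r.z_full,
            "z_best": r.z_best,
            "p_empirical": r.p_empirical,
            "p_adjusted": r.p_adjusted,
            "n_best_edges": len(r.best_edges),
            "k_permutations": r.k_permutations,
            "seed": r.seed,
        }
        for r in results
    ]
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table.to_csv(out_dir / "results.tsv", sep="\t", index=False)

    if rows:
        matrix = table.pivot(index="pathway", columns="condition", values="p_adjusted")
    else:
        matrix = pd.DataFrame()
    matrix.to_csv(out_dir / "adjusted_pvalue_matrix.tsv", sep="\t")

    edges_dir = out_dir / "edges"
    for r in results:
        if r.p_adjusted <= alpha:
            edges_dir.mkdir(parents=True, exist_ok=True)
            fname = f"{r.pathway_name}__{r.condition}.tsv".replace("/", "_")
            with open(edges_dir / fname, "w") as fh:
                for u, v in sorted(r.best_edges):
                    fh.write(f"{u}\t{v}\n")


def write_run_metadata(metadata: Mapping, path: str | Path) -> None:
    """Dump run metadata (seed, parameters, versions) as JSON."""
    with open(path, "w") as fh:
        json.dump(dict(metadata), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
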