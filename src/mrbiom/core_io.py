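"""Domain types and TSV readers/writers shared by every pipeline stage.

All tabular files are plain TSV. Expression tables are features-in-rows,
samples-in-columns (the dominant GDC/limma convention); a ``transpose``
flag is available for the opposite orientation. Protein-protein
interaction (PPI) edge lists follow the STRING export dialect
(``protein1``, ``protein2``, ``combined_score``), with combined scores
stored internally on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FeatureAnnotation",
    "SampleTable",
    "PPINetwork",
    "FormatError",
    "AlignmentError",
    "RNA_CLASSES",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_samples",
    "write_samples",
    "read_ppi",
    "write_ppi",
    "align",
    "subset_features",
]

RNA_CLASSES = ("mRNA", "miRNA", "lncRNA")


class FormatError(ValueError):
    """An input file violates its format contract."""


class AlignmentError(ValueError):
    """Identifiers in two inputs cannot be reconciled."""


@dataclass
class ExpressionMatrix:
    """Nonnegative feature-by-sample expression values.

    The expression unit (normalized counts, FPKM, TPM, ...) is
    deliberately unconstrained: every downstream statistic is either
    unit-free (correlations, entropies) or applied to whatever unit the
    table carries.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise FormatError(f"duplicate {name} identifiers: {dupes}")
        if np.isnan(self.values).any():
            rows, cols = np.nonzero(np.isnan(self.values))
            raise FormatError(
                "missing value at "
                f"feature {self.feature_ids[rows[0]]!r}, sample {self.sample_ids[cols[0]]!r}"
            )
        if (self.values < 0).any():
            rows, cols = np.nonzero(self.values < 0)
            raise FormatError(
                "negative expression value at "
                f"feature {self.feature_ids[rows[0]]!r}, sample {self.sample_ids[cols[0]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def row(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None
        return self.values[i]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(list(self.feature_ids), list(sample_ids), self.values[:, cols])


@dataclass
class FeatureAnnotation:
    """Maps each feature to an RNA class (mRNA/miRNA/lncRNA) and a gene symbol."""

    table: pd.DataFrame  # columns: feature_id, rna_class, symbol

    def __post_init__(self) -> None:
        required = {"feature_id", "rna_class", "symbol"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["feature_id"].duplicated().any():
            dupes = self.table.loc[self.table["feature_id"].duplicated(), "feature_id"]
            raise FormatError(f"duplicate feature ids in annotation: {sorted(set(dupes))}")
        bad = set(self.table["rna_class"]) - set(RNA_CLASSES)
        if bad:
            raise FormatError(f"unknown rna_class values: {sorted(bad)}")

    def ids_of_class(self, rna_class: str) -> list[str]:
        if rna_class not in RNA_CLASSES:
            raise ValueError(f"rna_class must be one of {RNA_CLASSES}")
        mask = self.table["rna_class"] == rna_class
        return list(self.table.loc[mask, "feature_id"])

    def symbol_of(self, feature_id: str) -> str:
        hit = self.table.loc[self.table["feature_id"] == feature_id, "symbol"]
        if hit.empty:
            raise KeyError(f"feature {feature_id!r} not annotated")
        return str(hit.iloc[0])

    def symbol_map(self) -> dict[str, str]:
        return dict(zip(self.table["feature_id"], self.table["symbol"].astype(str)))


@dataclass
class SampleTable:
    """Per-sample metadata: condition and optional survival outcome.

    Columns: ``sample_id``, ``condition`` (case/control), optional
    ``patient_id``, ``os_days`` (overall survival, days), ``os_event``
    (1 = death observed, 0 = censored) and ``cohort``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad = set(self.table["condition"]) - {"case", "control"}
        if bad:
            raise FormatError(f"condition must be case/control, got: {sorted(bad)}")
        if "os_days" in self.table.columns:
            if "os_event" not in self.table.columns:
                raise FormatError("os_days present without os_event")
            has_time = self.table["os_days"].notna()
            if self.table.loc[has_time, "os_event"].isna().any():
                raise FormatError("os_event missing for a sample with os_days")
            if (self.table.loc[has_time, "os_days"] < 0).any():
                raise FormatError("negative survival time")
            events = set(self.table.loc[has_time, "os_event"].astype(int)) - {0, 1}
            if events:
                raise FormatError(f"os_event must be 0/1, got {sorted(events)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"].astype(str))

    def ids_of(self, condition: str) -> list[str]:
        mask = self.table["condition"] == condition
        return list(self.table.loc[mask, "sample_id"].astype(str))

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        wanted = set(sample_ids)
        return SampleTable(self.table[self.table["sample_id"].isin(wanted)].copy())


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network with scores in [0, 1].

    Backed by a :class:`networkx.Graph`; at most one edge per unordered
    symbol pair, no self-edges.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise FormatError(f"self-edge on {a!r}")
            s = data.get("score")
            if s is None or not (0.0 <= s <= 1.0):
                raise FormatError(f"edge ({a!r}, {b!r}) score {s} outside [0, 1]")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "PPINetwork":
        """Build from (symbol_a, symbol_b, score) records.

        Duplicate unordered pairs are collapsed keeping the maximum score.
        """
        g = nx.Graph()
        for a, b, s in edges:
            a, b, s = str(a), str(b), float(s)
            if a == b:
                raise FormatError(f"self-edge on {a!r}")
            if not (0.0 <= s <= 1.0):
                raise FormatError(f"edge ({a!r}, {b!r}) score {s} outside [0, 1]")
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], s)
            else:
                g.add_edge(a, b, score=s)
        return cls(g)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            lo, hi = sorted((a, b))
            out.append((lo, hi, data["score"]))
        return sorted(out)

    def neighbor_scores(self, symbol: str) -> dict[str, float]:
        if symbol not in self.graph:
            return {}
        return {n: self.graph[symbol][n]["score"] for n in self.graph.neighbors(symbol)}


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a feature-by-sample expression TSV.

    First column is ``feature_id``; the remaining columns are sample ids
    and must be numeric. ``transpose=True`` reads samples-in-rows tables.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if transpose:
        frame = frame.T
    body = frame.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any() and not frame.isna().any().any():
        bad = np.nonzero(body.isna().to_numpy())
        raise FormatError(
            f"non-numeric cell at feature {frame.index[bad[0][0]]!r}, "
            f"sample {frame.columns[bad[1][0]]!r} in {path}"
        )
    return ExpressionMatrix.from_frame(body)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.to_frame()
    frame.index.name = "feature_id"
    # %.17g round-trips IEEE doubles bit-exactly
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation(path: str | Path) -> FeatureAnnotation:
    return FeatureAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(annot: FeatureAnnotation, path: str | Path) -> None:
    annot.table.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> SampleTable:
    frame = pd.read_csv(path, sep="\t")
    frame["sample_id"] = frame["sample_id"].astype(str)
    return SampleTable(frame)


def write_samples(samples: SampleTable, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ppi(path: str | Path, score_scale: str = "string1000") -> PPINetwork:
    """Read a STRING-dialect edge list (protein1, protein2, combined_score).

    ``score_scale='string1000'`` divides scores by 1000 (STRING exports
    integer combined scores on 0-1000); ``'unit'`` takes them as is.
    Duplicate unordered pairs keep the maximum score.
    """
    if score_scale not in ("unit", "string1000"):
        raise ValueError("score_scale must be 'unit' or 'string1000'")
    frame = pd.read_csv(path, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"PPI file missing columns: {sorted(missing)}")
    scores = frame["combined_score"].astype(float)
    if score_scale == "string1000":
        scores = scores / 1000.0
    if ((scores < 0) | (scores > 1)).any():
        bad = scores[(scores < 0) | (scores > 1)].iloc[0]
        raise FormatError(f"combined score {bad} outside [0, 1] after scaling")
    return PPINetwork.from_edges(
        zip(frame["protein1"].astype(str), frame["protein2"].astype(str), scores)
    )


def write_ppi(ppi: PPINetwork, path: str | Path, score_scale: str = "unit") -> None:
    rows = ppi.edges()
    frame = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    if score_scale == "string1000":
        frame["combined_score"] = (frame["combined_score"] * 1000).round().astype(int)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment / subsetting


def align(expr: ExpressionMatrix, samples: SampleTable) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split an expression matrix into (case, control) sample views.

    Column order within each condition is preserved from ``expr``; every
    expression column must be present in the sample table.
    """
    cond = dict(zip(samples.table["sample_id"].astype(str), samples.table["condition"]))
    missing = [s for s in expr.sample_ids if s not in cond]
    if missing:
        raise AlignmentError(f"samples absent from metadata: {missing}")
    case_ids = [s for s in expr.sample_ids if cond[s] == "case"]
    control_ids = [s for s in expr.sample_ids if cond[s] == "control"]
    return expr.subset_samples(case_ids), expr.subset_samples(control_ids)


def subset_features(expr: ExpressionMatrix, ids: Sequence[str]) -> ExpressionMatrix:
    """Row-subset (and reorder) an expression matrix to the given feature ids."""
    index = {f: i for i, f in enumerate(expr.feature_ids)}
    missing = [f for f in ids if f not in index]
    if missing:
        raise KeyError(f"features not in matrix: {missing}")
    rows = [index[f] for f in ids]
    return ExpressionMatrix(list(ids), list(expr.sample_ids), expr.values[rows])
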