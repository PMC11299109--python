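"""Tabular data loading and the ordered transform pipeline.

Every view in a specification draws the output of a small dataflow: a table is
read from TSV/CSV/JSON/BED and pushed through an ordered list of transform
steps (``filter``, ``formula``, ``flattenSequence``, ``coverage``,
``semanticZoom``).  Transform expressions are written in a closed, side-effect
free expression language (field references, arithmetic, comparisons, boolean
operators and a handful of math functions) that is compiled through Python's
``ast`` module with a strict node whitelist — no arbitrary code ever runs.

Missing-value semantics, applied uniformly: arithmetic on a missing operand is
missing, a predicate on a missing operand is false, and division by zero
yields missing rather than an error.
"""

from __future__ import annotations

import ast
import json
import math
import operator
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DataTable",
    "Expression",
    "compile_expression",
    "read_table",
    "apply_filter",
    "apply_formula",
    "flatten_sequence",
    "coverage",
    "apply_transforms",
    "write_bedgraph",
]

MISSING = None

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class DataflowError(ValueError):
    """Raised for malformed tables, unknown columns, or bad transform steps."""


# ---------------------------------------------------------------------------
# DataTable


class DataTable:
    """Ordered records with a shared column set, backed by a DataFrame.

    Row order is significant and deterministic given the input order; the
    wrapper exists so transforms can enforce the pipeline's missing-value
    semantics and error reporting without leaking pandas details upward.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, Any]],
                     columns: Sequence[str] | None = None) -> "DataTable":
        records = list(records)
        df = pd.DataFrame.from_records(records, columns=columns)
        return cls(df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DataTable) and self.df.equals(other.df)

    def rows(self) -> list[dict[str, Any]]:
        """Rows as plain dicts; NaN normalized to None."""
        out = []
        for rec in self.df.to_dict("records"):
            out.append({k: (None if _is_missing(v) else v) for k, v in rec.items()})
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DataTable({len(self.df)} rows × {len(self.df.columns)} cols)"


def _is_missing(v: Any) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return v is pd.NA or v is pd.NaT


# ---------------------------------------------------------------------------
# Expression language

_ALLOWED_FUNCS: dict[str, Callable[..., Any]] = {
    "abs": abs,
    "log2": lambda x: math.log2(x) if x > 0 else None,
    "pow2": lambda x: 2.0 ** x,
    "min": min,
    "max": max,
}

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
}

_CMPOPS = {
    ast.Eq: operator.eq,
    ast.NotEq: operator.ne,
    ast.Lt: operator.lt,
    ast.LtE: operator.le,
    ast.Gt: operator.gt,
    ast.GtE: operator.ge,
}


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class Expression:
    """A compiled, validated expression over fields and named parameters."""

    source: str
    tree: ast.expression
    names: frozenset[str]

    def evaluate(self, row: Mapping[str, Any], params: Mapping[str, Any] | None = None) -> Any:
        env = dict(params or {})
        env.update({k: v for k, v in row.items()})
        return _eval_node(self.tree.body, env)


def compile_expression(source: str) -> Expression:
    """Parse and validate an expression; rejects anything outside the subset."""
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"syntax error in expression {source!r}: {exc.msg}") from None
    names = _validate_node(tree.body, source)
    return Expression(source, tree, frozenset(names))


def _validate_node(node: ast.AST, source: str) -> set[str]:
    names: set[str] = set()
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float, str, bool)):
            raise ExpressionError(f"literal {node.value!r} not allowed in {source!r}")
    elif isinstance(node, ast.Name):
        names.add(node.id)
    elif isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        names |= _validate_node(node.left, source)
        names |= _validate_node(node.right, source)
    elif isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd, ast.Not)):
        names |= _validate_node(node.operand, source)
    elif isinstance(node, ast.BoolOp):
        for v in node.values:
            names |= _validate_node(v, source)
    elif isinstance(node, ast.Compare):
        names |= _validate_node(node.left, source)
        for op in node.ops:
            if type(op) not in _CMPOPS:
                raise ExpressionError(f"operator {type(op).__name__} not allowed in {source!r}")
        for c in node.comparators:
            names |= _validate_node(c, source)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
            raise ExpressionError(
                f"only {sorted(_ALLOWED_FUNCS)} may be called (in {source!r})"
            )
        if node.keywords:
            raise ExpressionError(f"keyword arguments not allowed in {source!r}")
        for a in node.args:
            names |= _validate_node(a, source)
    else:
        raise ExpressionError(
            f"construct {type(node).__name__} not allowed in expression {source!r}"
        )
    return names


def _eval_node(node: ast.AST, env: Mapping[str, Any]) -> Any:
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.Name):
        v = env[node.id]
        return None if _is_missing(v) else v
    if isinstance(node, ast.BinOp):
        left = _eval_node(node.left, env)
        right = _eval_node(node.right, env)
        if left is None or right is None:
            return None
        if isinstance(node.op, ast.Div) and right == 0:
            return None
        return _BINOPS[type(node.op)](left, right)
    if isinstance(node, ast.UnaryOp):
        v = _eval_node(node.operand, env)
        if isinstance(node.op, ast.Not):
            return not _truthy(v)
        if v is None:
            return None
        return -v if isinstance(node.op, ast.USub) else +v
    if isinstance(node, ast.BoolOp):
        if isinstance(node.op, ast.And):
            return all(_truthy(_eval_node(v, env)) for v in node.values)
        return any(_truthy(_eval_node(v, env)) for v in node.values)
    if isinstance(node, ast.Compare):
        left = _eval_node(node.left, env)
        for op, comparator in zip(node.ops, node.comparators):
            right = _eval_node(comparator, env)
            if left is None or right is None:
                return False
            try:
                if not _CMPOPS[type(op)](left, right):
                    return False
            except TypeError:
                return False
            left = right
        return True
    if isinstance(node, ast.Call):
        args = [_eval_node(a, env) for a in node.args]
        if any(a is None for a in args):
            return None
        try:
            return _ALLOWED_FUNCS[node.func.id](*args)  # type: ignore[union-attr]
        except (ValueError, OverflowError):
            return None
    raise AssertionError(f"unvalidated node {type(node).__name__}")  # pragma: no cover


def _truthy(v: Any) -> bool:
    # predicates on missing are false
    return bool(v) if v is not None else False


def _check_names(expr: Expression, table: DataTable, params: Mapping[str, Any]) -> None:
    unknown = expr.names - set(table.columns) - set(params)
    if unknown:
        raise DataflowError(
            f"expression {expr.source!r} references unknown column(s): "
            + ", ".join(sorted(unknown))
        )


# ---------------------------------------------------------------------------
# Readers


def read_table(path: Union[str, Path], format: str | None = None,
               one_based: bool = False,
               start_columns: Sequence[str] = ("start", "pos")) -> DataTable:
    """Read a TSV/CSV/JSON/BED file into a :class:`DataTable`.

    ``one_based=True`` shifts the listed start/position columns by −1 so the
    rest of the pipeline can assume 0-based half-open coordinates throughout.
    BED input is always 0-based already and yields columns
    ``chrom/start/end(/name/score/strand)``.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".json": "json", ".bed": "bed"}.get(
            path.suffix.lower(), "tsv")
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise DataflowError(f"{path}: BED requires at least 3 columns")
        df = df.iloc[:, :6]
        df.columns = _BED_COLUMNS[: df.shape[1]]
        return DataTable(df)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.ParserError as exc:
            raise DataflowError(f"{path}: {exc}") from None
        _check_ragged(path, sep)
    elif format == "json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise DataflowError(f"{path}: JSON table must be an array of objects")
        df = pd.DataFrame.from_records(data)
    else:
        raise DataflowError(f"unknown table format {format!r}")
    if one_based:
        for col in start_columns:
            if col in df.columns:
                df[col] = df[col] - 1
    return DataTable(df)


def _check_ragged(path: Path, sep: str) -> None:
    # pandas silently NaN-fills short rows; fail loud with the line number
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return
        ncols = header.rstrip("\n").count(sep) + 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if line.rstrip("\n").count(sep) + 1 != ncols:
                raise DataflowError(f"{path}:{lineno}: ragged row (expected {ncols} fields)")


def inline_table(values: Sequence[Mapping[str, Any]]) -> DataTable:
    """Table from inline ``data.values`` in a specification."""
    return DataTable.from_records(values)


# ---------------------------------------------------------------------------
# Transforms


def _as_expr(expr: Union[str, Expression]) -> Expression:
    return expr if isinstance(expr, Expression) else compile_expression(expr)


def apply_filter(table: DataTable, expr: Union[str, Expression],
                 params: Mapping[str, Any] | None = None) -> DataTable:
    """Keep rows where the predicate is true; order preserved."""
    expr = _as_expr(expr)
    params = params or {}
    _check_names(expr, table, params)
    keep = [bool(_truthy(expr.evaluate(row, params))) for row in table.rows()]
    return DataTable(table.df.loc[keep])


def apply_formula(table: DataTable, expr: Union[str, Expression], as_: str,
                  params: Mapping[str, Any] | None = None) -> DataTable:
    """Add (or overwrite) a column computed per row; row count unchanged."""
    expr = _as_expr(expr)
    params = params or {}
    _check_names(expr, table, params)
    values = []
    for i, row in enumerate(table.rows()):
        try:
            values.append(expr.evaluate(row, params))
        except TypeError as exc:
            raise DataflowError(f"type error in {expr.source!r} at row {i}: {exc}") from None
    df = table.df.copy()
    df[as_] = pd.Series(values, dtype=object) if any(v is None for v in values) else values
    return DataTable(df)


def flatten_sequence(table: DataTable, field: str, start_field: str,
                     pos_field: str = "pos", as_field: str = "base") -> DataTable:
    """Explode a text column into one row per character with its coordinate.

    Each input row with sequence ``s`` starting at ``start`` yields
    ``len(s)`` rows whose ``pos_field`` is ``start + index`` and whose
    ``as_field`` is the character; other columns are copied through.
    """
    for col in (field, start_field):
        if col not in table.columns:
            raise DataflowError(f"flattenSequence: unknown column {col!r}")
    out: list[dict[str, Any]] = []
    for i, row in enumerate(table.rows()):
        seq = row[field]
        start = row[start_field]
        if start is None:
            raise DataflowError(f"flattenSequence: missing start at row {i}")
        if seq is None:
            continue
        for j, ch in enumerate(str(seq)):
            rec = dict(row)
            rec[as_field] = ch
            rec[pos_field] = int(start) + j
            out.append(rec)
    columns = [c for c in table.columns if c not in (as_field, pos_field)]
    columns += [as_field, pos_field]
    return DataTable.from_records(out, columns=columns)


def coverage(table: DataTable, start_field: str = "start", end_field: str = "end",
             weight_field: str | None = None, as_: str = "coverage",
             chrom_field: str | None = None) -> DataTable:
    """Piecewise-constant sum of interval weights (weighted coverage).

    Output intervals partition the covered domain, are sorted, omit
    zero-coverage gaps, and adjacent intervals with equal value are merged —
    the canonical minimal representation of the step function.
    """
    for col in filter(None, (start_field, end_field, weight_field, chrom_field)):
        if col not in table.columns:
            raise DataflowError(f"coverage: unknown column {col!r}")
    rows = table.rows()
    for i, row in enumerate(rows):
        if row[start_field] is None or row[end_field] is None:
            raise DataflowError(f"coverage: missing interval bound at row {i}")
        if row[start_field] >= row[end_field]:
            raise DataflowError(
                f"coverage: start >= end at row {i} "
                f"({row[start_field]} >= {row[end_field]})"
            )
    groups: dict[Any, list[tuple[int, int, float]]] = {}
    for row in rows:
        key = row[chrom_field] if chrom_field else None
        w = 1.0 if weight_field is None else row[weight_field]
        if w is None:
            continue
        groups.setdefault(key, []).append(
            (int(row[start_field]), int(row[end_field]), float(w)))
    out: list[dict[str, Any]] = []
    for key in sorted(groups, key=lambda k: (str(k),)) if chrom_field else list(groups):
        for start, end, value in _sweep(groups[key]):
            rec: dict[str, Any] = {}
            if chrom_field:
                rec[chrom_field] = key
            rec[start_field] = start
            rec[end_field] = end
            rec[as_] = value
            out.append(rec)
    columns = ([chrom_field] if chrom_field else []) + [start_field, end_field, as_]
    return DataTable.from_records(out, columns=columns)


def _sweep(intervals: list[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    """Event-point sweep; returns merged, sorted, nonzero segments."""
    events: dict[int, float] = {}
    for start, end, w in intervals:
        events[start] = events.get(start, 0.0) + w
        events[end] = events.get(end, 0.0) - w
    points = sorted(events)
    segments: list[tuple[int, int, float]] = []
    level = 0.0
    for i, p in enumerate(points[:-1]):
        level += events[p]
        if abs(level) > 1e-12:
            segments.append((p, points[i + 1], level))
    # merge adjacent equal-valued segments
    merged: list[tuple[int, int, float]] = []
    for seg in segments:
        if merged and merged[-1][1] == seg[0] and merged[-1][2] == seg[2]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def apply_transforms(table: DataTable, steps: Sequence[Mapping[str, Any]],
                     params: Mapping[str, Any] | None = None) -> DataTable:
    """Run an ordered list of transform-step dicts (grammar ``transform``)."""
    from .zoomfilter import ScoredItem, visible_items  # local import: avoid cycle

    params = params or {}
    for i, step in enumerate(steps):
        kind = step.get("type")
        try:
            if kind == "filter":
                table = apply_filter(table, step["expr"], params)
            elif kind == "formula":
                table = apply_formula(table, step["expr"], step["as"], params)
            elif kind == "flattenSequence":
                table = flatten_sequence(
                    table, step["field"], step.get("startField", "start"),
                    step.get("posField", "pos"), step.get("asField", "base"))
            elif kind == "coverage":
                table = coverage(
                    table, step.get("startField", "start"), step.get("endField", "end"),
                    step.get("weightField"), step.get("as", "coverage"),
                    step.get("chromField"))
            elif kind == "semanticZoom":
                score_field = step["scoreField"]
                pos_field = step.get("posField", "pos")
                budget = int(step.get("budget", 10))
                zoom = float(params.get("zoomLevel", step.get("zoomLevel", 1.0)))
                items = [
                    ScoredItem(id=j, position=row[pos_field], score=row[score_field])
                    for j, row in enumerate(table.rows())
                ]
                keep_ids = {it.id for it in visible_items(items, zoom, budget)}
                table = DataTable(table.df.loc[[j in keep_ids for j in range(len(table))]])
            else:
                raise DataflowError(f"unknown transform type {kind!r}")
        except KeyError as exc:
            raise DataflowError(f"transform[{i}] ({kind}): missing property {exc}") from None
    return table


def write_bedgraph(table: DataTable, path: Union[str, Path],
                   chrom_field: str = "chrom", start_field: str = "start",
                   end_field: str = "end", value_field: str = "coverage") -> None:
    """Write intervals + value as a 4-column bedGraph (deterministic bytes)."""
    with open(path, "w") as fh:
        for row in table.rows():
            fh.write(f"{row[chrom_field]}\t{row[start_field]}\t{row[end_field]}"
                     f"\t{row[value_field]:g}\n")
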