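"""Data model and I/O for quantitative bipartite interaction networks.

A :class:`BipartiteNetwork` is a labelled nonnegative count matrix whose rows
are host plants (phorophytes, or the plant guild generally) and whose columns
are the dependent partner guild (epiphytes, pollinators, seed dispersers,
ants).  All network-level metrics downstream are orientation-symmetric;
species-level metrics record the axis a species lives on.

Counts are stored as floats but validated as integers by default (tolerance
1e-9) because source matrices are visitation/occurrence counts and the
entropy-bound algorithms in :mod:`epinet.specialization` operate on integer
margins.  Pass ``allow_noninteger=True`` to keep genuinely continuous
weights.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("EP", "SD", "PO", "AM")

_INT_TOL = 1e-9


class NetworkError(ValueError):
    """Raised for malformed or degenerate network inputs."""


@dataclass(frozen=True)
class NetworkMetadata:
    """Per-network study metadata.

    ``interaction_type`` is one of EP (epiphyte-phorophyte), SD (seed
    dispersal), PO (pollination), AM (ant-myrmecophyte).  ``locality`` is the
    grouping factor for the random intercept in the comparative stage, so both
    fields are mandatory wherever the network enters a comparison.
    """

    interaction_type: str = "EP"
    locality: str = "unknown"
    habitat: str | None = None
    sampling: str | None = None
    source: str | None = None
    lat: float | None = None
    long: float | None = None

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise NetworkError(
                f"interaction_type must be one of {INTERACTION_TYPES}, "
                f"got {self.interaction_type!r}"
            )


@dataclass(frozen=True)
class BipartiteNetwork:
    """Labelled quantitative bipartite interaction matrix.

    Invariants enforced at construction: unique labels per axis, all weights
    nonnegative and finite, positive grand total, shape consistent with the
    label lists.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    weights: np.ndarray
    meta: NetworkMetadata = field(default_factory=NetworkMetadata)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "row_labels", tuple(str(x) for x in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(x) for x in self.col_labels))
        if w.ndim != 2:
            raise NetworkError("weights must be a 2-D matrix")
        if w.shape != (len(self.row_labels), len(self.col_labels)):
            raise NetworkError(
                f"weights shape {w.shape} does not match labels "
                f"({len(self.row_labels)} rows, {len(self.col_labels)} cols)"
            )
        if len(set(self.row_labels)) != len(self.row_labels):
            raise NetworkError("row labels are not unique")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise NetworkError("column labels are not unique")
        if not np.all(np.isfinite(w)):
            raise NetworkError("weights contain non-finite values")
        if (w < 0).any():
            i, j = np.argwhere(w < 0)[0]
            raise NetworkError(
                f"negative count at cell ({self.row_labels[i]!r}, "
                f"{self.col_labels[j]!r}): {w[i, j]}"
            )
        if w.sum() <= 0:
            raise NetworkError("network has no interactions (grand total is 0)")

    # -- basic views ---------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.weights.shape[0]

    @property
    def n_cols(self) -> int:
        return self.weights.shape[1]

    @property
    def total(self) -> float:
        """Grand total of interaction counts (m)."""
        return float(self.weights.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    def is_integer(self, tol: float = _INT_TOL) -> bool:
        return bool(np.all(np.abs(self.weights - np.round(self.weights)) <= tol))

    def has_empty_margins(self) -> bool:
        return bool((self.row_totals == 0).any() or (self.col_totals == 0).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def with_weights(self, weights: np.ndarray) -> "BipartiteNetwork":
        return replace(self, weights=np.asarray(weights, dtype=float))


def _validate_counts(
    net: BipartiteNetwork, allow_noninteger: bool
) -> BipartiteNetwork:
    if not allow_noninteger and not net.is_integer():
        bad = np.argwhere(
            np.abs(net.weights - np.round(net.weights)) > _INT_TOL
        )[0]
        raise NetworkError(
            "non-integer count at cell "
            f"({net.row_labels[bad[0]]!r}, {net.col_labels[bad[1]]!r}); "
            "pass allow_noninteger=True to accept continuous weights"
        )
    return net


def read_network(
    path: str | Path,
    format: Literal["matrix_csv", "edge_list"] = "matrix_csv",
    meta: NetworkMetadata | None = None,
    allow_noninteger: bool = False,
) -> BipartiteNetwork:
    """Read a network from a labelled CSV matrix or a 3-column edge list.

    ``matrix_csv``: one header row of column labels (first cell ignored) and a
    leading column of row labels; comma-separated, UTF-8.

    ``edge_list``: columns (row_label, col_label, count), comma- or
    tab-separated, header optional; duplicate (row, col) entries are summed.
    """
    path = Path(path)
    if not path.exists():
        raise NetworkError(f"network file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise NetworkError(f"empty network file: {path}")
    if format == "matrix_csv":
        net = _parse_matrix_csv(text, source=str(path))
    elif format == "edge_list":
        net = _parse_edge_list(text, source=str(path))
    else:
        raise NetworkError(f"unknown format {format!r}")
    if meta is not None:
        net = replace(net, meta=meta)
    return _validate_counts(net, allow_noninteger)


def _parse_cell(token: str, where: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise NetworkError(f"non-numeric cell at {where}: {token!r}") from None
    if value < 0:
        raise NetworkError(f"negative count at {where}: {value}")
    return value


def _parse_matrix_csv(text: str, source: str) -> BipartiteNetwork:
    rows = [r for r in csv.reader(io.StringIO(text)) if any(c.strip() for c in r)]
    if len(rows) < 2:
        raise NetworkError(f"matrix CSV needs a header and at least one row: {source}")
    col_labels = [c.strip() for c in rows[0][1:]]
    row_labels: list[str] = []
    data: list[list[float]] = []
    for r in rows[1:]:
        label = r[0].strip()
        row_labels.append(label)
        if len(r) - 1 != len(col_labels):
            raise NetworkError(
                f"row {label!r} has {len(r) - 1} cells, expected {len(col_labels)}"
            )
        data.append(
            [_parse_cell(c, f"({label!r}, {col_labels[j]!r})") for j, c in enumerate(r[1:])]
        )
    return BipartiteNetwork(tuple(row_labels), tuple(col_labels), np.array(data))


def _parse_edge_list(text: str, source: str) -> BipartiteNetwork:
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    records: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 3:
            raise NetworkError(f"edge list line {lineno} has fewer than 3 columns")
        if lineno == 1:
            try:
                float(parts[2])
            except ValueError:
                continue  # header line
        records.append(
            (parts[0], parts[1], _parse_cell(parts[2], f"line {lineno} ({parts[0]}, {parts[1]})"))
        )
    if not records:
        raise NetworkError(f"edge list has no data rows: {source}")
    row_labels = list(dict.fromkeys(r for r, _, _ in records))
    col_labels = list(dict.fromkeys(c for _, c, _ in records))
    w = np.zeros((len(row_labels), len(col_labels)))
    ri = {r: i for i, r in enumerate(row_labels)}
    ci = {c: j for j, c in enumerate(col_labels)}
    for r, c, v in records:
        w[ri[r], ci[c]] += v
    return BipartiteNetwork(tuple(row_labels), tuple(col_labels), w)


def write_network(
    net: BipartiteNetwork,
    path: str | Path,
    format: Literal["matrix_csv", "edge_list"] = "matrix_csv",
) -> None:
    """Write a network so that :func:`read_network` round-trips it exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if format == "matrix_csv":
            writer = csv.writer(fh)
            writer.writerow([""] + list(net.col_labels))
            for label, row in zip(net.row_labels, net.weights):
                writer.writerow([label] + [_fmt_count(v) for v in row])
        elif format == "edge_list":
            writer = csv.writer(fh)
            writer.writerow(["row_label", "col_label", "count"])
            for i, rl in enumerate(net.row_labels):
                for j, cl in enumerate(net.col_labels):
                    if net.weights[i, j] > 0:
                        writer.writerow([rl, cl, _fmt_count(net.weights[i, j])])
        else:
            raise NetworkError(f"unknown format {format!r}")


def _fmt_count(v: float) -> str:
    return str(int(round(v))) if abs(v - round(v)) <= _INT_TOL else repr(v)


def prune_empty(net: BipartiteNetwork) -> BipartiteNetwork:
    """Drop all-zero rows and columns; idempotent.

    Raises :class:`NetworkError` if the pruned matrix is smaller than 2x2,
    which is degenerate for every metric in the pipeline.
    """
    keep_r = net.row_totals > 0
    keep_c = net.col_totals > 0
    dropped_r = [l for l, k in zip(net.row_labels, keep_r) if not k]
    dropped_c = [l for l, k in zip(net.col_labels, keep_c) if not k]
    if dropped_r or dropped_c:
        logger.info("pruned %d empty rows %s and %d empty columns %s",
                    len(dropped_r), dropped_r, len(dropped_c), dropped_c)
    w = net.weights[np.ix_(keep_r, keep_c)]
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise NetworkError(
            f"network degenerate after pruning ({w.shape[0]}x{w.shape[1]}); "
            "metrics require at least 2 rows and 2 columns"
        )
    return BipartiteNetwork(
        tuple(l for l, k in zip(net.row_labels, keep_r) if k),
        tuple(l for l, k in zip(net.col_labels, keep_c) if k),
        w,
        net.meta,
    )


def binarize(net: BipartiteNetwork | np.ndarray) -> np.ndarray:
    """0/1 incidence matrix: entry 1 iff the count is positive."""
    w = net.weights if isinstance(net, BipartiteNetwork) else np.asarray(net)
    return (w > 0).astype(int)


def network_size(net: BipartiteNetwork) -> int:
    """Number of species: rows plus columns (both guilds pooled)."""
    return net.n_rows + net.n_cols


# -- manifests ---------------------------------------------------------

MANIFEST_COLUMNS = [
    "network_id", "path", "interaction_type", "locality",
    "habitat", "sampling", "lat", "long",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a study-level manifest TSV listing networks and their metadata."""
    path = Path(path)
    if not path.exists():
        raise NetworkError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"network_id": str})
    missing = {"network_id", "path", "interaction_type", "locality"} - set(df.columns)
    if missing:
        raise NetworkError(f"manifest missing columns: {sorted(missing)}")
    if df.empty:
        raise NetworkError(f"manifest is empty: {path}")
    return df


def load_manifest_networks(
    manifest: pd.DataFrame, base_dir: str | Path | None = None,
    format: str = "matrix_csv",
) -> Iterable[tuple[str, BipartiteNetwork | None, str | None]]:
    """Yield (network_id, network-or-None, error message) per manifest row.

    Unreadable networks yield ``None`` with the reason, mirroring surveys
    where a matrix was never published; callers decide whether to skip.
    """
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        meta = NetworkMetadata(
            interaction_type=str(row["interaction_type"]),
            locality=str(row["locality"]),
            habitat=_opt(row, "habitat"),
            sampling=_opt(row, "sampling"),
            lat=_opt_float(row, "lat"),
            long=_opt_float(row, "long"),
        )
        try:
            yield str(row["network_id"]), read_network(p, format=format, meta=meta), None
        except NetworkError as exc:
            yield str(row["network_id"]), None, str(exc)


def _opt(row: pd.Series, key: str) -> str | None:
    v = row.get(key)
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else str(v)


def _opt_float(row: pd.Series, key: str) -> float | None:
    v = row.get(key)
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f
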