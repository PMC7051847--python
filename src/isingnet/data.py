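"""Binary item-response data: containers, CSV I/O, validation, descriptives.

The pipeline's sole empirical input is an n x p matrix of {0,1} responses,
one row per respondent and one column per questionnaire item.  The 40-item
Narcissistic Personality Inventory (NPI) item metadata ships as a packaged
fixture so NPI-style analyses and simulations need no external files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinaryDataset",
    "ItemMetadata",
    "read_binary_items",
    "write_binary_items",
    "npi_metadata",
    "npi_domain_blocks",
    "summarize_total_scores",
]

NPI_DOMAINS = (
    "Authority",
    "Exhibitionism",
    "Superiority",
    "Entitlement",
    "Exploitativeness",
    "Self-sufficiency",
    "Vanity",
)


class BinaryDataValidationError(ValueError):
    """A cell is outside {0, 1}, or the table shape is unusable."""


@dataclass(frozen=True)
class BinaryDataset:
    """Validated n x p matrix of {0,1} item responses with unique item labels.

    Parameters
    ----------
    values
        Integer array of shape (n, p); every entry must be 0 or 1.
    labels
        p unique item labels, e.g. ``["A1", "Exh2", ...]``.
    """

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise BinaryDataValidationError(
                f"expected a 2-D response matrix, got shape {values.shape}"
            )
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise BinaryDataValidationError(
                f"non-binary entry {values[r, c]!r} at row {r}, column "
                f"{c} ({self.labels[c] if c < len(self.labels) else c})"
            )
        if values.shape[1] < 2:
            raise BinaryDataValidationError("need at least 2 items (columns)")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != values.shape[1]:
            raise BinaryDataValidationError(
                f"{len(labels)} labels for {values.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            raise BinaryDataValidationError("item labels must be unique")
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "BinaryDataset":
        return cls(frame.to_numpy(), tuple(str(c) for c in frame.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), columns=list(self.labels))

    def total_scores(self) -> np.ndarray:
        """Per-respondent sum score, in [0, p]."""
        return self.values.sum(axis=1)

    def subset(self, rows: np.ndarray) -> "BinaryDataset":
        """Dataset restricted to the given row indices (order preserved)."""
        return BinaryDataset(self.values[np.asarray(rows)], self.labels)

    def constant_columns(self) -> list[int]:
        """Indices of columns that are all 0 or all 1 (estimation refuses these)."""
        means = self.values.mean(axis=0)
        return [int(j) for j in np.flatnonzero((means == 0.0) | (means == 1.0))]


@dataclass(frozen=True)
class ItemMetadata:
    """One NPI item: number, narcissism domain, short label, statement pair."""

    item_number: int
    domain: str
    label: str
    statement_0: str  # non-narcissistic statement (coded 0)
    statement_1: str  # narcissistic statement (coded 1)


def read_binary_items(
    path: str | Path,
    delimiter: str = ",",
    has_header: bool = True,
    ignore_columns: Sequence[str] = (),
) -> BinaryDataset:
    """Read a delimited text file of {0,1} responses into a `BinaryDataset`.

    Row order is preserved.  Cells outside {0, 1} (including missing values)
    raise :class:`BinaryDataValidationError` naming the offending row and
    column: the estimand is defined on complete binary data, so nothing is
    imputed silently.

    Parameters
    ----------
    path
        CSV/TSV file, UTF-8.
    delimiter
        Field separator.
    has_header
        Whether the first row holds item labels.  Without a header, columns
        are labelled ``V1..Vp``.
    ignore_columns
        Header names (e.g. demographic columns) to drop before validation.
        Requires ``has_header=True``.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise BinaryDataValidationError(f"{path} is empty")
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if has_header else None,
            dtype="object",
            keep_default_na=False,
            engine="python",
            on_bad_lines="error",
        )
    except pd.errors.ParserError as exc:
        raise BinaryDataValidationError(f"could not parse {path}: {exc}") from exc
    if frame.shape[0] == 0:
        raise BinaryDataValidationError(f"{path} has a header but no data rows")
    if ignore_columns:
        if not has_header:
            raise BinaryDataValidationError("ignore_columns requires has_header=True")
        frame = frame.drop(columns=list(ignore_columns), errors="ignore")
    if not has_header:
        frame.columns = [f"V{j + 1}" for j in range(frame.shape[1])]
    values = np.empty(frame.shape, dtype=np.int8)
    raw = frame.to_numpy()
    for (r, c), cell in np.ndenumerate(raw):
        text = str(cell).strip()
        if text not in ("0", "1"):
            raise BinaryDataValidationError(
                f"non-binary cell {cell!r} at row {r}, column {frame.columns[c]!r}"
            )
        values[r, c] = int(text)
    return BinaryDataset(values, tuple(str(c) for c in frame.columns))


def write_binary_items(data: BinaryDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a dataset in the same dialect `read_binary_items` reads (round-trips bit-exactly)."""
    data.to_dataframe().to_csv(path, sep=delimiter, index=False)


def npi_metadata() -> list[ItemMetadata]:
    """The 40 NPI items: number, domain, label, and both statements.

    Domains and block sizes: Authority (8), Exhibitionism (7), Superiority (5),
    Entitlement (6), Exploitativeness (5), Self-sufficiency (6), Vanity (3).
    """
    ref = importlib.resources.files("isingnet.resources").joinpath("npi_items.csv")
    with importlib.resources.as_file(ref) as fp:
        frame = pd.read_csv(fp)
    return [
        ItemMetadata(
            item_number=int(row.item_number),
            domain=str(row.domain),
            label=str(row.label),
            statement_0=str(row.statement_0),
            statement_1=str(row.statement_1),
        )
        for row in frame.itertuples(index=False)
    ]


def npi_domain_blocks() -> dict[str, list[int]]:
    """0-based item indices per NPI domain, in questionnaire order."""
    blocks: dict[str, list[int]] = {d: [] for d in NPI_DOMAINS}
    for item in npi_metadata():
        blocks[item.domain].append(item.item_number - 1)
    return blocks


def summarize_total_scores(data: BinaryDataset) -> tuple[float, float]:
    """Mean and sample (n-1 denominator) SD of per-respondent total scores."""
    if data.n == 0:
        raise ValueError("no rows: total-score summary undefined")
    if data.n == 1:
        raise ValueError("single row: sample standard deviation undefined")
    scores = data.total_scores().astype(float)
    return float(scores.mean()), float(scores.std(ddof=1))
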