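"""Result persistence: a schema-stable table in RAM or a CSV file.

Every iteration stores the objective value(s), the full parameter
vector, optionally the simulated series and a chain id.  Column order
is fixed:

    like1..likeK, par<name>... (setup order), simulation_1..simulation_T, chain

The CSV dialect is comma-separated, '.' decimal, one header row, no
index column, UTF-8, ``\\n`` line endings, floats written at ``repr``
precision — so a round-trip through disk preserves values to full
double precision and the file loads directly in R, pandas or any
spreadsheet.
"""

from __future__ import annotations

import io
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ResultStore", "load_csv"]


class ResultStore:
    """Ordered collection of per-iteration sample records."""

    def __init__(
        self,
        objective_names: Sequence[str] = ("like1",),
        parameter_names: Sequence[str] = (),
        n_simulation: int = 0,
        backend: str = "ram",
        path: str | None = None,
    ):
        if backend not in ("ram", "csv"):
            raise DataError(f"backend must be ram|csv, got {backend!r}")
        if backend == "csv" and not path:
            raise DataError("csv backend requires a file path")
        self.objective_names = list(objective_names)
        self.parameter_names = list(parameter_names)
        self.n_simulation = int(n_simulation)
        self.backend = backend
        self.path = path
        self.columns = (
            self.objective_names
            + [f"par{n}" for n in self.parameter_names]
            + [f"simulation_{i + 1}" for i in range(self.n_simulation)]
            + ["chain"]
        )
        self._rows: list[list[float]] = []
        self._fh: io.TextIOBase | None = None
        if backend == "csv":
            self._fh = open(path, "w", encoding="utf-8", newline="\n")
            self._fh.write(",".join(self.columns) + "\n")

    # ------------------------------------------------------------------
    def append(self, likes, par, simulation=None, chain: int = 0) -> None:
        """Append one record; raises :class:`DataError` on schema mismatch."""
        likes = [float(v) for v in np.atleast_1d(np.asarray(likes, dtype=float))]
        par = [float(v) for v in np.asarray(par, dtype=float).ravel()]
        if len(likes) != len(self.objective_names):
            raise DataError(
                f"expected {len(self.objective_names)} objective value(s), got {len(likes)}"
            )
        if len(par) != len(self.parameter_names):
            raise DataError(
                f"expected {len(self.parameter_names)} parameter(s), got {len(par)}"
            )
        row = likes + par
        if self.n_simulation:
            sim = [] if simulation is None else [
                float(v) for v in np.asarray(simulation, dtype=float).ravel()
            ]
            if len(sim) != self.n_simulation:
                raise DataError(
                    f"expected simulation of length {self.n_simulation}, got {len(sim)}"
                )
            row += sim
        row.append(float(chain))
        if self.backend == "csv":
            self._fh.write(",".join(repr(v) for v in row) + "\n")
        else:
            self._rows.append(row)

    def finalize(self) -> None:
        """Flush and close the CSV file handle (no-op for RAM)."""
        if self._fh is not None and not self._fh.closed:
            self._fh.close()

    def __len__(self) -> int:
        if self.backend == "ram":
            return len(self._rows)
        return len(self.getdata())

    # ------------------------------------------------------------------
    def getdata(self) -> pd.DataFrame:
        """Complete schema-stable table of all records, insertion order."""
        if self.backend == "csv":
            self.finalize()
            try:
                df = pd.read_csv(self.path)
            except OSError as exc:
                raise DataError(f"cannot read result file {self.path!r}: {exc}") from exc
            if list(df.columns) != self.columns:
                raise DataError(
                    f"result file {self.path!r} has unexpected columns {list(df.columns)}"
                )
            return df
        return pd.DataFrame(self._rows, columns=self.columns)


def load_csv(path: str) -> pd.DataFrame:
    """Load a result CSV written by any run for external analysis."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot read result file {path!r}: {exc}") from exc
    return df
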