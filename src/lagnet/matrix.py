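"""Containers for time-course expression matrices.

The on-disk layout is the conventional tab-separated gene-by-time table:
first column gene identifier, header row of numeric time labels (minutes
on the lifeline), one row per gene.  Two containers are provided:
:class:`ExpressionMatrix` for observed (possibly irregular) time courses
and :class:`InterpolatedMatrix` for the uniform-grid form that delay
shifts operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SCALES = ("raw", "log2", "log2_ratio")

#: Relative tolerance for checking grid uniformity.
_GRID_RTOL = 1e-9


@dataclass
class ExpressionMatrix:
    """A genes x time-points expression matrix.

    Parameters
    ----------
    gene_ids:
        Unique probe or gene identifiers, one per row.
    time_points:
        Strictly increasing time labels in minutes.
    values:
        Matrix of expression values, shape ``(len(gene_ids), len(time_points))``.
    scale:
        One of ``raw``, ``log2``, ``log2_ratio``.  ``log2_ratio`` means
        log2 values relative to the first-time-point baseline.
    """

    gene_ids: list[str]
    time_points: np.ndarray
    values: np.ndarray
    scale: str = "raw"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.time_points.ndim != 1:
            raise ValueError("time_points must be one-dimensional")
        if self.values.shape != (len(self.gene_ids), self.time_points.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.time_points.size} time points"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dups = {g for g in self.gene_ids if g in seen or seen.add(g)}
            raise ValueError(f"duplicate gene ids: {sorted(dups)}")
        if self.time_points.size > 1 and np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time_points must be strictly increasing")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic queries ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return int(self.time_points.size)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def row(self, gene_id: str) -> np.ndarray:
        """Return the expression series of one gene (a view)."""
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene id not in matrix: {gene_id!r}") from None

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), self.time_points.copy(), self.values[idx].copy(), self.scale
        )

    # -- pandas / disk round trips ---------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.time_points
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "raw") -> "ExpressionMatrix":
        times = np.asarray([float(c) for c in df.columns], dtype=float)
        return cls(list(df.index.astype(str)), times, df.to_numpy(dtype=float), scale)

    @classmethod
    def read_tsv(cls, path: str | Path, scale: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df, scale=scale)

    def write_tsv(self, path: str | Path) -> None:
        # %.10g keeps at least 6 significant digits and round-trips cleanly
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class InterpolatedMatrix(ExpressionMatrix):
    """An :class:`ExpressionMatrix` on a uniform time grid.

    ``grid_spacing`` is the constant step between adjacent grid times in
    minutes and ``n_grid`` the number of grid columns.  Both are inferred
    from ``time_points`` when not given.
    """

    grid_spacing: float = float("nan")
    n_grid: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_times < 2:
            raise ValueError("an interpolated matrix needs at least 2 grid points")
        steps = np.diff(self.time_points)
        spacing = float(steps[0])
        if not np.allclose(steps, spacing, rtol=_GRID_RTOL, atol=0.0):
            raise ValueError("time_points are not a uniform grid")
        if np.isnan(self.grid_spacing):
            self.grid_spacing = spacing
        elif not np.isclose(self.grid_spacing, spacing, rtol=_GRID_RTOL, atol=0.0):
            raise ValueError(
                f"declared grid_spacing {self.grid_spacing} does not match "
                f"observed spacing {spacing}"
            )
        if self.n_grid == 0:
            self.n_grid = self.n_times
        elif self.n_grid != self.n_times:
            raise ValueError("n_grid does not equal the number of grid columns")

    @classmethod
    def read_tsv(cls, path: str | Path, scale: str = "raw") -> "InterpolatedMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        times = np.asarray([float(c) for c in df.columns], dtype=float)
        return cls(list(df.index.astype(str)), times, df.to_numpy(dtype=float), scale)
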