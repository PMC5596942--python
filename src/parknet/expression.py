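"""Two-group expression study container.

An :class:`ExpressionStudy` holds a genes × samples matrix together with a
control/disease label per sample and the intensity scale. Microarray
pipelines normalise to log2 intensities (GCRMA and friends emit log2), so
``scale='log2'`` is the default; fold changes are computed accordingly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

CONTROL = "control"
DISEASE = "disease"


@dataclass
class ExpressionStudy:
    """Genes × samples expression matrix with a two-group design.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Rows are genes, columns are samples. Values must be finite.
    groups : pandas.Series
        Maps sample id to ``'control'`` or ``'disease'``. Must cover every
        column of ``matrix`` and both groups need at least two samples.
    scale : str
        ``'log2'`` (default, microarray convention) or ``'linear'``.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.matrix.index.hasnans or self.matrix.columns.hasnans:
            raise InputError("expression matrix has missing gene or sample ids")
        if self.matrix.index.duplicated().any():
            raise InputError("duplicate gene ids in expression matrix")
        if self.matrix.columns.duplicated().any():
            raise InputError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise InputError("expression matrix contains non-finite values")
        if self.scale not in ("log2", "linear"):
            raise InputError(f"unknown scale {self.scale!r}; use 'log2' or 'linear'")
        self.groups = pd.Series(self.groups)
        missing = self.matrix.columns.difference(self.groups.index)
        if len(missing):
            raise InputError(f"samples without group label: {list(missing)[:5]}")
        self.groups = self.groups.loc[self.matrix.columns]
        bad = set(self.groups.unique()) - {CONTROL, DISEASE}
        if bad:
            raise InputError(f"group labels must be control/disease, got {sorted(bad)}")
        for g in (CONTROL, DISEASE):
            if (self.groups == g).sum() < 2:
                raise InputError(f"group {g!r} has fewer than 2 samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.columns

    @property
    def control_samples(self) -> pd.Index:
        return self.matrix.columns[self.groups.to_numpy() == CONTROL]

    @property
    def disease_samples(self) -> pd.Index:
        return self.matrix.columns[self.groups.to_numpy() == DISEASE]

    def values_by_group(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (control, disease) value arrays, genes × group-samples."""
        x = self.matrix[self.control_samples].to_numpy(dtype=float)
        y = self.matrix[self.disease_samples].to_numpy(dtype=float)
        return x, y

    def subset_genes(self, genes) -> "ExpressionStudy":
        genes = pd.Index(genes)
        unknown = genes.difference(self.matrix.index)
        if len(unknown):
            raise InputError(f"unknown genes requested: {list(unknown)[:5]}")
        return ExpressionStudy(self.matrix.loc[genes], self.groups, self.scale)


def read_expression(path) -> pd.DataFrame:
    """Read a genes × samples TSV (first column = gene id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise InputError(f"{path}: expression table has no sample columns")
    return df


def read_groups(path) -> pd.Series:
    """Read a two-column (sample, group) TSV into a sample→group Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"{path}: group table needs columns (sample, group)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="group")


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def write_groups(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )
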