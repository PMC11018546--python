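"""Expression-matrix container and loaders.

The whole pipeline operates on a genes x samples matrix of normalized
expression values (e.g. log-transformed TPM).  Normalization is assumed to
have happened upstream; this module only validates shape, uniqueness and
missingness, and optionally drops constant genes (which carry no
co-expression signal and would produce undefined correlations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers (rows).
    sample_ids : list of str
        Unique sample identifiers (columns).
    values : ndarray of shape (n_genes, n_samples)
        Expression values, no missing entries.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = values.shape
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise ValueError("identifier lists do not match matrix shape")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample identifiers")
        # a case matrix may hold a single sample; control-fitting paths
        # enforce their own >= 3-sample floors
        if n_genes < 3 or n_samples < 1:
            raise ValueError("need at least 3 genes and 1 sample")
        if np.isnan(values).any():
            raise ValueError("missing values present; use from_dataframe to drop them")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index()[gene]]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, drop_constant: bool = False
    ) -> "ExpressionMatrix":
        """Build from a genes-as-rows DataFrame, dropping incomplete rows.

        Rows containing any missing value are dropped and logged; with
        ``drop_constant`` rows with zero variance are dropped as well.
        """
        df = df.astype(float)
        n_missing = int(df.isna().any(axis=1).sum())
        if n_missing:
            logger.warning("dropping %d gene rows with missing values", n_missing)
            df = df.dropna(axis=0)
        if drop_constant:
            var = df.var(axis=1, ddof=0)
            n_const = int((var == 0).sum())
            if n_const:
                logger.warning("dropping %d constant-expression gene rows", n_const)
                df = df.loc[var > 0]
        return cls(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(),
        )

    @classmethod
    def read_table(
        cls, path, *, sep: str | None = None, drop_constant: bool = False
    ) -> "ExpressionMatrix":
        """Read a TSV/CSV file: first column gene ids, header row sample ids."""
        if sep is None:
            sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls.from_dataframe(df, drop_constant=drop_constant)

    def write_table(self, path, *, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="gene")
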