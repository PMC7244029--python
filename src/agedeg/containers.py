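"""In-memory containers shared across the pipeline.

The central object is :class:`ExpressionSet`, a log2 expression matrix
(probes x samples) paired with a per-sample annotation table.  Values are
stored as a plain :class:`pandas.DataFrame` so every downstream operation can
use ordinary pandas/numpy idioms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionSet"]


@dataclass
class ExpressionSet:
    """A log2 expression matrix with sample annotations.

    Parameters
    ----------
    values
        Probes x samples matrix of log2 intensities.  Index holds probe ids,
        columns hold sample ids; both must be unique and the values finite.
    samples
        Per-sample table indexed by sample id.  Must contain a ``group``
        column for any two-group operation; may carry a ``mv`` column with
        maximum-velocity measurements (mm/sec).
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if len(self.samples) == 0:
            self.samples = pd.DataFrame(index=self.values.columns)
        missing = self.values.columns.difference(self.samples.index)
        if len(missing) > 0:
            raise ValueError(f"samples missing from annotation: {list(missing[:5])}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        """Group label per sample, aligned to the matrix column order."""
        if "group" not in self.samples.columns:
            raise ValueError("sample annotation has no 'group' column")
        return self.samples.loc[self.values.columns, "group"]

    def group_of(self, sample: str) -> str:
        return str(self.groups.loc[sample])

    def samples_in_group(self, group: str) -> list[str]:
        g = self.groups
        return list(g.index[g == group])

    def with_values(self, values: pd.DataFrame) -> "ExpressionSet":
        """Return a copy of this set carrying a new value matrix."""
        return ExpressionSet(values=values, samples=self.samples.copy())
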