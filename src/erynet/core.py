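"""Shared in-memory containers for the two-strain time-course pipeline.

The central object is :class:`ExpressionMatrix`, a gene x sample table of
log2 expression values with per-sample metadata (strain, time point,
biological replicate).  All downstream stages (differential expression,
enrichment, co-expression) consume this container.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRAINS = ("WT", "HP")
TIME_POINTS = ("t1", "t2", "t3", "t4")

#: correlation contexts: pooled data, wild-type only, high-producer only
CONTEXTS = ("ALL", "WT", "HP")


@dataclass
class ExpressionMatrix:
    """Gene-level log2 expression with sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); index = gene ids, columns =
        sample ids, entries = log2 expression.
    samples
        DataFrame indexed by sample id with columns ``strain``, ``time``
        and ``replicate``.
    excluded
        Optional record of features removed during preprocessing, with
        columns ``feature`` and ``reason``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature", "reason"])
    )

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns must match sample metadata index")
        for col in ("strain", "time", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")

    # -- convenience selectors -------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def select_samples(self, strain: str | None = None, time: str | None = None) -> list[str]:
        """Sample ids matching the given strain and/or time point."""
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if strain is not None:
            mask &= meta["strain"] == strain
        if time is not None:
            mask &= meta["time"] == time
        return list(meta.index[mask])

    def context_samples(self, context: str) -> list[str]:
        """Sample ids for a correlation context (ALL / WT / HP)."""
        if context == "ALL":
            return self.sample_ids
        if context in STRAINS:
            return self.select_samples(strain=context)
        raise ValueError(f"unknown context {context!r}")

    def group_values(self, strain: str, time: str) -> pd.DataFrame:
        return self.values[self.select_samples(strain=strain, time=time)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values[ids].copy(),
            samples=self.samples.loc[ids].copy(),
            excluded=self.excluded.copy(),
        )

    def times(self) -> list[str]:
        seen: list[str] = []
        for t in self.samples["time"]:
            if t not in seen:
                seen.append(t)
        return seen


def make_sample_table(
    strains: Iterable[str] = STRAINS,
    time_points: Iterable[str] = TIME_POINTS,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Full-factorial sample metadata table (strain x time x replicate)."""
    rows = []
    for strain in strains:
        for time in time_points:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{strain}_{time}_r{rep}",
                        "strain": strain,
                        "time": time,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def check_finite(values: np.ndarray, what: str = "matrix") -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what} contains non-finite values")
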