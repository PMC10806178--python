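"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARCHETYPES = (
    "early_up",
    "mid_up",
    "late_up",
    "transient_up",
    "early_down",
    "mid_down",
    "late_down",
    "transient_down",
)
NULL_ARCHETYPE = "null"


@dataclass
class CountMatrix:
    """Raw integer RNA-seq counts (genes x samples) with a sample design.

    ``counts`` is a genes-by-samples DataFrame of non-negative integers;
    ``design`` is indexed by sample id with columns ``donor`` and ``day``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.design.index):
            # allow same set in different order; realign
            if set(self.counts.columns) != set(self.design.index):
                raise ValueError("design rows must match count-matrix samples")
            self.design = self.design.loc[self.counts.columns]
        if self.design.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        for col in ("donor", "day"):
            if col not in self.design.columns:
                raise ValueError(f"design is missing required column {col!r}")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.design.loc[list(samples)])


@dataclass
class RegulatoryNetwork:
    """Directed TF/motif -> target-gene network with per-node degrees.

    ``edges`` has columns ``source``, ``target``, ``score``; duplicate
    (source, target) pairs are forbidden.  ``W`` is the total edge count,
    conserved as the sum of out-degrees and of in-degrees.
    """

    edges: pd.DataFrame
    out_degree: pd.Series = field(init=False)
    in_degree: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        required = {"source", "target"}
        if not required.issubset(self.edges.columns):
            raise ValueError("edges need 'source' and 'target' columns")
        if self.edges.duplicated(["source", "target"]).any():
            raise ValueError("duplicate edges are not allowed")
        self.out_degree = self.edges.groupby("source").size()
        self.in_degree = self.edges.groupby("target").size()

    @property
    def W(self) -> int:
        return len(self.edges)

    def targets_of(self, source) -> set:
        sub = self.edges.loc[self.edges["source"] == source, "target"]
        return set(sub)
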