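"""Core in-memory containers shared by all pipeline stages.

An :class:`ExpressionMatrix` wraps a probes-or-genes × samples
:class:`pandas.DataFrame` together with the scale of its values
(``"linear"`` intensities or ``"log2"`` intensities) and a two-class
phenotype labeling of the samples (disease vs. control).  The scale tag
matters because the nonspecific filter applies an intensity floor on the
linear track and a coefficient-of-variation window on the log2 track,
and fold changes are always ratios of linear-scale means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ProbeAnnotation", "GeneSet", "GeneSetCollection"]

VALID_SCALES = ("linear", "log2")


@dataclass
class ExpressionMatrix:
    """Expression values with a scale tag and per-sample phenotype labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe or gene identifier, columns are sample
        identifiers.
    scale
        ``"linear"`` (intensity, arbitrary units, strictly positive) or
        ``"log2"`` (log2 intensity).
    phenotype
        Mapping of sample id to class label.  Exactly two classes; the
        *disease* class is the first element of :attr:`classes`.
    classes
        Ordered pair ``(disease_label, control_label)``.  If omitted, the
        two labels are taken in order of first appearance.
    """

    values: pd.DataFrame
    scale: str
    phenotype: pd.Series
    classes: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate row identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and np.any(arr <= 0):
            raise ValueError("linear-scale values must be strictly positive")
        self.phenotype = pd.Series(self.phenotype)
        missing = self.values.columns.difference(self.phenotype.index)
        if len(missing):
            raise ValueError(f"samples without phenotype label: {list(missing)[:5]}")
        self.phenotype = self.phenotype.loc[self.values.columns]
        labels = list(dict.fromkeys(self.phenotype))
        if len(labels) != 2:
            raise ValueError(f"phenotype must have exactly two classes, got {labels}")
        if self.classes is None:
            self.classes = (labels[0], labels[1])
        elif set(self.classes) != set(labels):
            raise ValueError(f"classes {self.classes} do not match labels {labels}")

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def class_columns(self, label: str) -> pd.Index:
        return self.values.columns[(self.phenotype == label).to_numpy()]

    def class_matrix(self, label: str) -> np.ndarray:
        """Values restricted to the samples of one phenotype class."""
        return self.values.loc[:, self.class_columns(label)].to_numpy()

    def subset_rows(self, row_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[row_ids], self.scale, self.phenotype, self.classes
        )


@dataclass
class ProbeAnnotation:
    """Probe → gene-symbol map; probes absent from the map are unmapped."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.mapping.items():
            if not gene or not isinstance(gene, str):
                raise ValueError(f"probe {probe!r} maps to invalid symbol {gene!r}")

    def gene_of(self, probe: str) -> str | None:
        return self.mapping.get(probe)

    def is_mapped(self, probe: str) -> bool:
        return probe in self.mapping

    def genes(self) -> set[str]:
        return set(self.mapping.values())

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        # preserve order, drop duplicate symbols
        self.members = tuple(dict.fromkeys(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene-set names in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def restrict(self, universe, min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        """Intersect every set with *universe* and apply a size window."""
        uni = set(universe)
        kept = []
        for s in self.sets:
            members = tuple(g for g in s.members if g in uni)
            if len(members) < min_size:
                continue
            if max_size is not None and len(members) > max_size:
                continue
            kept.append(GeneSet(s.name, s.description, members))
        return GeneSetCollection(kept)
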