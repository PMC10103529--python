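"""Shared in-memory containers for the cross-platform scoring pipeline.

Expression data travels as a :class:`CountMatrix` (genes as rows, samples as
columns, with an optional per-gene probe code class such as ``Endogenous`` or
``Housekeeping``).  Gene sets travel as a :class:`SignatureCollection`, and
per-signature, per-sample scores as a :class:`ScoreTable`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")


@dataclass
class CountMatrix:
    """Genes x samples count matrix with optional probe-class annotation.

    Parameters
    ----------
    counts
        Non-negative counts, genes as the index, sample ids as columns.
    code_class
        Optional per-gene probe class, aligned to ``counts.index``.
    platform
        Free-text platform tag (e.g. ``"panel"`` or ``"wts"``).
    """

    counts: pd.DataFrame
    code_class: pd.Series | None = None
    platform: str = ""

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.code_class is not None:
            self.code_class = self.code_class.reindex(self.counts.index)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def genes_of_class(self, klass: str) -> list[str]:
        if self.code_class is None:
            return []
        return list(self.code_class.index[self.code_class == klass])

    @property
    def endogenous(self) -> pd.DataFrame:
        """Counts restricted to endogenous probes (all rows if unannotated)."""
        if self.code_class is None:
            return self.counts
        keep = self.code_class == "Endogenous"
        return self.counts.loc[keep[keep].index]

    def subset_genes(self, genes) -> "CountMatrix":
        missing = [g for g in genes if g not in self.counts.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        cc = self.code_class.loc[genes] if self.code_class is not None else None
        return CountMatrix(self.counts.loc[list(genes)], cc, self.platform)

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(),
            None if self.code_class is None else self.code_class.copy(),
            self.platform,
        )


class SignatureCollection:
    """Ordered collection of named gene sets.

    Member lists are de-duplicated on construction (with a warning), empty
    sets and duplicate names are rejected.
    """

    def __init__(self, sets: dict[str, list[str]] | None = None,
                 descriptions: dict[str, str] | None = None):
        self._sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for name, members in (sets or {}).items():
            self.add(name, members, self.descriptions.get(name, ""))

    def add(self, name: str, members, description: str = "") -> None:
        if name in self._sets:
            raise ValueError(f"duplicate signature name: {name!r}")
        seen: list[str] = []
        for m in members:
            if m in seen:
                warnings.warn(f"signature {name!r}: duplicate member {m!r} dropped")
            else:
                seen.append(m)
        if not seen:
            raise ValueError(f"signature {name!r} has no members")
        self._sets[name] = seen
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def items(self):
        return self._sets.items()

    def names(self) -> list[str]:
        return list(self._sets)

    def sizes(self) -> pd.Series:
        return pd.Series({n: len(g) for n, g in self._sets.items()}, dtype=int)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SignatureCollection({len(self)} sets)"


@dataclass
class ScoreTable:
    """Signatures x samples table of single-sample scores in [0, 1]."""

    scores: pd.DataFrame
    platform: str = ""
    method: str = ""
    sizes: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if vals.size and ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
            raise ValueError("scores must lie in [0, 1]")

    @property
    def signatures(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns
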