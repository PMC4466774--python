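"""Marker/trait table I/O for genomic selection.

Marker files are plain delimited text (comma or tab): one row per
individual, a header row of marker identifiers, and a first column of
sample identifiers.  Genotypes are integer-coded — allele counts 0/1/2
for codominant SNP/SSR markers, presence/absence 0/1 or 0/2 for dominant
markers such as DArT.  Trait files share the layout with one column per
continuous trait.

Missing genotypes are rejected rather than imputed: imputation belongs
to dataset preparation (BEAGLE and similar tools), not to the model
library, and silent imputation would make results irreproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed genotype codes per encoding.
ENCODINGS: dict[str, frozenset[int]] = {
    "codominant-012": frozenset({0, 1, 2}),
    "dominant-01": frozenset({0, 1}),
    "dominant-02": frozenset({0, 2}),
}


@dataclass(frozen=True)
class MarkerMatrix:
    """An ``n x p`` genotype matrix with identifiers and encoding metadata."""

    values: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    encoding: str = "codominant-012"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        object.__setattr__(self, "values", values)
        n, p = values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if len(self.sample_ids) != n or len(self.marker_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker_ids")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        codes = ENCODINGS[self.encoding]
        bad = ~np.isin(values, sorted(codes))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype {values[i, j]!r} for sample {self.sample_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r} is outside the "
                f"{self.encoding!r} code set {sorted(codes)}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TraitVector:
    """Per-individual continuous trait values.

    ``nonnegative`` records whether the vector is safe for NDCG use
    (gains must be nonnegative for NDCG to stay in [0, 1]).
    """

    values: np.ndarray
    trait_name: str = "trait"
    nonnegative: bool = field(default=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("trait values must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"trait {self.trait_name!r} has non-finite values")
        object.__setattr__(self, "nonnegative", bool(values.min() >= 0))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Dataset:
    """Aligned markers and traits: identical sample order throughout."""

    markers: MarkerMatrix
    traits: list[TraitVector]

    def __post_init__(self) -> None:
        for t in self.traits:
            if len(t) != self.markers.n:
                raise ValueError(
                    f"trait {t.trait_name!r} length {len(t)} does not match "
                    f"marker sample count {self.markers.n}"
                )


def _read_table(path) -> pd.DataFrame:
    """Read a delimited table, auto-detecting comma vs tab; header mandatory."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    return df


def read_marker_matrix(path, encoding: str = "codominant-012") -> MarkerMatrix:
    """Load a genotype table and validate it against the declared encoding."""
    df = _read_table(path)
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing genotype for sample {df.index[i]!r}, "
            f"marker {df.columns[j]!r} in {path}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric genotype codes in {path}")
    if not np.all(values == np.round(values)):
        raise ValueError(f"non-integer genotype codes in {path}")
    return MarkerMatrix(
        values=values.astype(np.int64),
        sample_ids=list(df.index),
        marker_ids=[str(c) for c in df.columns],
        encoding=encoding,
    )


def write_marker_matrix(markers: MarkerMatrix, path, sep: str = ",") -> None:
    df = pd.DataFrame(
        markers.values, index=markers.sample_ids, columns=markers.marker_ids
    )
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


def read_traits(path) -> list[TraitVector]:
    """Load a trait table; one :class:`TraitVector` per column."""
    df = _read_table(path)
    traits = []
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if np.isnan(values).any():
            i = int(np.argwhere(np.isnan(values))[0][0])
            raise ValueError(
                f"non-numeric or missing value for sample {df.index[i]!r}, "
                f"trait {col!r} in {path}"
            )
        traits.append(TraitVector(values=values, trait_name=str(col)))
    # attach sample ids for later alignment
    for t in traits:
        object.__setattr__(t, "sample_ids", list(df.index))
    return traits


def write_traits(traits: list[TraitVector], sample_ids: list[str], path,
                 sep: str = ",") -> None:
    df = pd.DataFrame(
        {t.trait_name: t.values for t in traits}, index=sample_ids
    )
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


def shift_nonnegative(y: TraitVector) -> TraitVector:
    """Shift trait values so the smallest is exactly zero.

    A constant offset leaves every pair-based measure, Pearson r and
    NDCG ratio ordering untouched; it only rescales raw DCG.  Shifting
    is done once per dataset (not per CV split).
    """
    return replace(y, values=y.values - y.values.min(), nonnegative=True)


def align(markers: MarkerMatrix, traits: list[TraitVector]) -> Dataset:
    """Reorder traits to the marker file's sample order.

    Samples absent from either side are dropped (with a log warning);
    fewer than two shared samples is an error.
    """
    aligned = []
    marker_index = {s: i for i, s in enumerate(markers.sample_ids)}
    keep_rows: list[int] | None = None
    for t in traits:
        ids = getattr(t, "sample_ids", None)
        if ids is None:
            if len(t) != markers.n:
                raise ValueError(
                    f"trait {t.trait_name!r} has no sample ids and length "
                    f"{len(t)} != {markers.n}"
                )
            aligned.append(t)
            continue
        shared = [s for s in markers.sample_ids if s in set(ids)]
        if len(shared) < 2:
            raise ValueError(
                f"fewer than 2 samples shared between markers and trait "
                f"{t.trait_name!r}"
            )
        dropped = set(ids) - set(shared)
        if dropped:
            logger.warning(
                "align: dropping %d sample(s) absent from marker file for "
                "trait %r", len(dropped), t.trait_name,
            )
        pos = {s: i for i, s in enumerate(ids)}
        aligned.append(
            TraitVector(
                values=np.asarray([t.values[pos[s]] for s in shared]),
                trait_name=t.trait_name,
            )
        )
        rows = [marker_index[s] for s in shared]
        if keep_rows is None:
            keep_rows = rows
        elif rows != keep_rows:
            raise ValueError("traits cover different sample subsets")
    if keep_rows is not None and len(keep_rows) != markers.n:
        if len(set(markers.sample_ids)) - len(keep_rows):
            logger.warning(
                "align: dropping %d marker sample(s) without trait records",
                markers.n - len(keep_rows),
            )
        markers = MarkerMatrix(
            values=markers.values[keep_rows],
            sample_ids=[markers.sample_ids[i] for i in keep_rows],
            marker_ids=markers.marker_ids,
            encoding=markers.encoding,
        )
    return Dataset(markers=markers, traits=aligned)
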