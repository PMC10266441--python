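"""PCA-based ordinal encoding of chemical categoricals.

A set of candidate reagents (here: the nine amine/pyridine bases) is
described by a table of physicochemical descriptors — molecular weight,
density, refractive index, melting and boiling point, logP, dipole moment,
polar topological surface area and pKaH.  Because the descriptors have
incommensurate units, the table is standardized column-wise and a principal
component analysis is run on the result (i.e. correlation-matrix PCA).  The
first principal component, on which all descriptors load, defines a
chemically meaningful 1-D ordering; items are ranked along PC1 and assigned
consecutive integers 1..n.  A user-named reference item (triethylamine in
the benzoylation study) fixes the otherwise arbitrary sign of PC1 by being
forced to rank 1.

Feeding the surrogate a *meaningful* integer ordering, instead of arbitrary
labels, is what lets a GP with a distance-based kernel generalize across
similar reagents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger("rxnloop")


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class DescriptorTable:
    """Items × descriptors matrix of real-valued physicochemical descriptors."""

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data).astype(float)
        if df.isna().any().any():
            raise EncodingError("descriptor table contains missing entries")
        if df.shape[0] < 2:
            raise EncodingError("need at least 2 items")
        if df.shape[1] < 1:
            raise EncodingError("need at least 1 descriptor")
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise EncodingError("duplicate item or descriptor labels")
        object.__setattr__(self, "data", df)

    @property
    def items(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptors(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorTable":
        return cls(pd.read_csv(path, index_col=0))


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame  # descriptors × components
    scores: pd.DataFrame  # items × components
    explained_variance_ratio: np.ndarray


def standardize(table: DescriptorTable) -> DescriptorTable:
    """Column-wise zero-mean / unit sample-sd scaling.

    Zero-variance columns carry no information and are dropped with a
    warning rather than producing NaNs.
    """
    df = table.data
    sd = df.std(ddof=1)
    constant = sd[sd == 0.0].index.tolist()
    if constant:
        logger.warning("dropping constant descriptor column(s): %s", constant)
        df = df.drop(columns=constant)
        sd = sd.drop(constant)
        if df.shape[1] == 0:
            raise EncodingError("all descriptor columns are constant")
    return DescriptorTable((df - df.mean()) / sd)


def pca(table: DescriptorTable, pre_standardized: bool = False) -> PCAResult:
    """PCA of the standardized descriptor matrix (all components kept).

    Deterministic up to the per-component sign ambiguity, which is resolved
    downstream by :func:`assign_integers`'s reference-item orientation rule.
    """
    if not pre_standardized:
        table = standardize(table)
    X = table.data.to_numpy()
    n_comp = min(X.shape)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        loadings=pd.DataFrame(
            model.components_.T, index=table.descriptors, columns=comp_names
        ),
        scores=pd.DataFrame(scores, index=table.items, columns=comp_names),
        explained_variance_ratio=np.asarray(model.explained_variance_ratio_),
    )


def assign_integers(
    pca_result: PCAResult, items: list[str] | None = None, reference_first: str = None
) -> dict[str, int]:
    """Rank items along PC1 and assign consecutive integers 1..n.

    The PC1 sign is oriented so that ``reference_first`` receives rank 1.
    Exact score ties are broken lexicographically by item label (logged).
    """
    scores = pca_result.scores["PC1"]
    if items is not None:
        scores = scores.loc[list(items)]
    if reference_first is None:
        raise EncodingError("a reference item is required to orient PC1")
    if reference_first not in scores.index:
        raise EncodingError(f"reference item {reference_first!r} not among items")
    s = scores.to_numpy(dtype=float)
    labels = list(scores.index)
    ref = labels.index(reference_first)
    # orient so the reference sits at the low end of PC1
    if s[ref] > s.min() + (s.max() - s[ref]):
        s = -s
    if np.any((s == s[ref]) & (np.arange(len(s)) != ref)) or len(np.unique(s)) < len(s):
        logger.warning("exact PC1 ties resolved lexicographically by label")
    order = sorted(range(len(s)), key=lambda i: (s[i], labels[i]))
    mapping = {labels[i]: rank + 1 for rank, i in enumerate(order)}
    if mapping[reference_first] != 1:
        logger.warning(
            "reference item %r is not extreme on PC1 (rank %d)",
            reference_first,
            mapping[reference_first],
        )
    return mapping


def encode_reagents(
    table: DescriptorTable, reference_first: str
) -> tuple[dict[str, int], PCAResult]:
    """Convenience: standardize → PCA → integer assignment, with a report."""
    result = pca(table)
    mapping = assign_integers(result, reference_first=reference_first)
    logger.info(
        "PC1 explains %.1f%% of descriptor variance; integer map: %s",
        100 * result.explained_variance_ratio[0],
        mapping,
    )
    return mapping, result
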