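"""Risk-band categorization and categorical agreement.

CRP-based cardiovascular risk stratification uses the conventional bands
<1, 1-3 and >3 mg/l (low / intermediate / high).  Agreement between two
methods' band assignments is summarized by the overall concordance rate
(fraction on the cross-tabulation diagonal) and Cohen's kappa, the
chance-corrected version.  Tables may hold counts or percentages; published
percentage tables are normalized by their own grand total so that rounding
error in the printed cells is absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "RiskCategoryScheme",
    "CRP_RISK_SCHEME",
    "ContingencyTable",
    "KappaResult",
    "categorize",
    "crosstab",
    "cohens_kappa",
    "concordance",
]


@dataclass(frozen=True)
class RiskCategoryScheme:
    """Ordered risk bands defined by strictly increasing cut points.

    Boundary convention: the lowest band is open above (v < cut_1), the
    highest band is open below (v > cut_k), so values equal to either
    printed cut point fall in the band between them (CRP 1.0 and 3.0 mg/l
    are both "intermediate").
    """

    analyte: str
    cut_points: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cut_points)
        object.__setattr__(self, "cut_points", cuts)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(cuts) + 1:
            raise ConfigurationError("need exactly one more label than cut points")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ConfigurationError("cut points must be strictly increasing")


CRP_RISK_SCHEME = RiskCategoryScheme(
    analyte="CRP",
    cut_points=(1.0, 3.0),
    labels=("low", "intermediate", "high"),
)


def categorize(values, scheme: RiskCategoryScheme) -> pd.Categorical:
    """Assign each value to its risk band label.

    Values strictly below the first cut get the first label; values strictly
    above the last cut get the last label; interior cut points belong to the
    band above them except the last cut, which belongs to the band below it
    (so both boundary values of a three-band scheme land in the middle band).
    """
    v = np.asarray(values, dtype=float)
    if v.size and not np.isfinite(v).all():
        bad = np.where(~np.isfinite(v))[0]
        raise DomainError(f"non-finite values at positions {bad[:10].tolist()}")
    cuts = np.asarray(scheme.cut_points)
    idx = np.searchsorted(cuts, v, side="right")
    idx[v == cuts[-1]] = len(cuts) - 1  # last cut belongs below the top band
    codes = idx.astype(int)
    return pd.Categorical.from_codes(
        codes, categories=list(scheme.labels), ordered=True
    )


@dataclass
class ContingencyTable:
    """Square cross-tabulation over the same ordered categories.

    ``basis`` records whether the cells are subject counts or percentages of
    the grand total; every statistic normalizes by the grand total, so both
    bases give identical kappa/concordance.
    """

    table: pd.DataFrame
    basis: str = "counts"  # "counts" | "percent"

    def __post_init__(self) -> None:
        t = self.table
        if list(t.index) != list(t.columns):
            raise ConfigurationError("row and column categories must match in order")
        if (t.to_numpy() < 0).any():
            raise ConfigurationError("cells must be non-negative")
        if self.basis not in ("counts", "percent"):
            raise ConfigurationError(f"unknown basis {self.basis!r}")

    @property
    def grand_total(self) -> float:
        return float(self.table.to_numpy().sum())

    def proportions(self) -> np.ndarray:
        total = self.grand_total
        if total <= 0:
            raise DomainError("empty contingency table")
        return self.table.to_numpy(dtype=float) / total

    @classmethod
    def from_cells(
        cls, cells, labels: Sequence[str], basis: str = "counts"
    ) -> "ContingencyTable":
        frame = pd.DataFrame(
            np.asarray(cells, dtype=float), index=list(labels), columns=list(labels)
        )
        return cls(frame, basis)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path, basis: str = "counts") -> "ContingencyTable":
        return cls(pd.read_csv(path, index_col=0), basis)


def crosstab(labels_a, labels_b, scheme: RiskCategoryScheme) -> ContingencyTable:
    """Counts of each (row, column) band pair; all bands kept even if empty."""
    a = pd.Categorical(labels_a, categories=list(scheme.labels), ordered=True)
    b = pd.Categorical(labels_b, categories=list(scheme.labels), ordered=True)
    if len(a) != len(b):
        raise ConfigurationError("label vectors must have equal length")
    for name, cat in (("a", a), ("b", b)):
        if np.asarray(cat.codes).min(initial=0) < 0:
            raise ConfigurationError(f"labels_{name} contains labels outside the scheme")
    table = pd.crosstab(a, b, dropna=False)
    table = table.reindex(
        index=list(scheme.labels), columns=list(scheme.labels), fill_value=0
    )
    table.index.name = None
    table.columns.name = None
    return ContingencyTable(table.astype(float), basis="counts")


@dataclass
class KappaResult:
    observed_agreement: float
    expected_agreement: float
    kappa: float


def cohens_kappa(
    table: ContingencyTable, weights: str | None = None
) -> KappaResult:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``weights`` of ``"linear"`` or ``"quadratic"`` give the weighted variant
    (partial credit for near-diagonal cells); the default is the unweighted
    statistic.
    """
    p = table.proportions()
    k = p.shape[0]
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    if weights is None:
        wmat = np.eye(k)
    elif weights in ("linear", "quadratic"):
        i, j = np.indices((k, k))
        dist = np.abs(i - j) / (k - 1)
        wmat = 1.0 - (dist if weights == "linear" else dist**2)
    else:
        raise ConfigurationError(f"unknown kappa weights {weights!r}")
    p_o = float((wmat * p).sum())
    p_e = float((wmat * np.outer(row, col)).sum())
    if p_e >= 1.0 - 1e-15:
        raise DomainError("kappa undefined: expected agreement is 1 (single category)")
    return KappaResult(
        observed_agreement=p_o,
        expected_agreement=p_e,
        kappa=(p_o - p_e) / (1.0 - p_e),
    )


def concordance(table: ContingencyTable) -> float:
    """Fraction of subjects assigned the same band by both methods."""
    p = table.proportions()
    return float(np.trace(p))
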