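"""Binning genotypes into SIIG classes and summarizing groups.

Groups are lower-closed intervals of the SIIG scale, numbered 1 (best)
downward. The default scheme cuts at 0.70 / 0.60 / 0.50 / 0.40, giving
five classes: [0.70, 1.00], [0.60, 0.70), [0.50, 0.60), [0.40, 0.50)
and [0.00, 0.40). Genotypes in the top two classes (SIIG >= 0.60) are
the conventional "superior" selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SIIGResult, TraitMatrix

__all__ = ["GroupScheme", "GroupTable", "assign_groups", "group_summary", "threshold_count"]

DEFAULT_BREAKS = (0.70, 0.60, 0.50, 0.40)


@dataclass(frozen=True)
class GroupScheme:
    """Ordered SIIG breakpoints defining lower-closed bins on [0, 1].

    ``breakpoints`` are strictly decreasing values in (0, 1). With k
    breakpoints there are k+1 groups labelled 1..k+1; a score equal to a
    breakpoint belongs to the higher (better) group.
    """

    breakpoints: tuple[float, ...] = field(default=DEFAULT_BREAKS)

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        if not bp:
            raise ValueError("at least one breakpoint required")
        if any(not (0.0 < b < 1.0) for b in bp):
            raise ValueError("breakpoints must lie strictly inside (0, 1)")
        if any(b2 >= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly decreasing")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def n_groups(self) -> int:
        return len(self.breakpoints) + 1

    def labels(self) -> list[int]:
        return list(range(1, self.n_groups + 1))

    def interval_strings(self) -> list[str]:
        """Human-readable bin descriptions, best group first."""
        edges = [1.0, *self.breakpoints, 0.0]
        out = []
        for g, (hi, lo) in enumerate(zip(edges, edges[1:]), start=1):
            closer = "<=" if g == 1 else "<"
            out.append(f"{lo:.2f} <= SIIG {closer} {hi:.2f}")
        return out


@dataclass(frozen=True)
class GroupTable:
    """Per-group membership, counts and trait means.

    ``summary`` has one row per group label with columns ``count`` and the
    trait means (NaN for empty groups); ``members`` maps each label to its
    genotype IDs.
    """

    summary: pd.DataFrame
    members: dict[int, list[str]]

    @property
    def counts(self) -> pd.Series:
        return self.summary["count"]


def assign_groups(
    result: SIIGResult | pd.Series | Sequence[float],
    scheme: GroupScheme = GroupScheme(),
) -> pd.Series:
    """Group label (1 = best) for each genotype's SIIG score.

    A score lands in the first bin whose lower bound it meets; boundary
    values go to the higher group (SIIG = 0.70 is group 1 under the
    default scheme).
    """
    if isinstance(result, SIIGResult):
        siig = result.siig
    elif isinstance(result, pd.Series):
        siig = result
    else:
        siig = pd.Series(np.asarray(result, dtype=float))
    values = siig.to_numpy(dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("SIIG values must lie in [0, 1]")
    # descending breakpoints: label = 1 + number of breakpoints above value
    bp = np.asarray(scheme.breakpoints)
    labels = 1 + (values[:, None] < bp[None, :]).sum(axis=1)
    return pd.Series(labels, index=siig.index, name="group")


def group_summary(
    groups: pd.Series,
    matrix: TraitMatrix,
    scheme: GroupScheme = GroupScheme(),
    drop_empty: bool = False,
) -> GroupTable:
    """Counts and unweighted trait means per SIIG group.

    ``groups`` and ``matrix`` must share genotype IDs. Empty groups are
    reported with count 0 and NaN means unless ``drop_empty`` is set.
    """
    if set(map(str, groups.index)) != set(matrix.genotype_ids):
        raise ValueError("group assignment and trait matrix genotype IDs differ")
    aligned = groups.reindex(matrix.data.index)
    rows = []
    members: dict[int, list[str]] = {}
    for label in scheme.labels():
        mask = aligned == label
        ids = [str(g) for g in matrix.data.index[mask]]
        members[label] = ids
        if mask.any():
            means = matrix.data.loc[mask].mean(axis=0)
        else:
            means = pd.Series(np.nan, index=matrix.data.columns)
        rows.append({"group": label, "count": int(mask.sum()), **means.to_dict()})
    summary = pd.DataFrame(rows).set_index("group")
    if drop_empty:
        keep = summary["count"] > 0
        summary = summary[keep]
        members = {k: v for k, v in members.items() if v}
    return GroupTable(summary=summary, members=members)


def threshold_count(
    siig_values: pd.Series | Sequence[float],
    tau: float,
) -> tuple[int, list[str]]:
    """Count and IDs of genotypes with SIIG >= tau (inclusive).

    Returns ``(count, ids)`` with IDs ordered by descending SIIG so the
    best genotype comes first.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    siig = (
        siig_values
        if isinstance(siig_values, pd.Series)
        else pd.Series(np.asarray(siig_values, dtype=float))
    )
    selected = siig[siig >= tau].sort_values(ascending=False, kind="stable")
    ids = [str(g) for g in selected.index]
    return len(ids), ids
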