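"""Hit calling from a ranked functional screen.

A high-content screen assigns every perturbation (here: a miRNA mimic, or
an siRNA pool) a single composite readout score.  Candidate modulators are
the entities in the extreme tails of the score distribution: with 2555
miRNAs and a 1% tail on each side this yields the canonical 25 + 25 = 50
candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectedSet", "select_extremes", "validate_screen_table"]


@dataclass(frozen=True)
class SelectedSet:
    """Top/bottom tail selection from a screen table.

    ``top_ids`` is ordered by decreasing score, ``bottom_ids`` by
    increasing score; ties are broken by entity id so the selection is a
    pure function of the table contents.
    """

    top_ids: tuple[str, ...]
    bottom_ids: tuple[str, ...]
    tail_fraction: float

    def __post_init__(self) -> None:
        if set(self.top_ids) & set(self.bottom_ids):
            raise ValueError("top and bottom tails must be disjoint")

    @property
    def candidate_ids(self) -> frozenset[str]:
        """Union of both tails: the screen's candidate set."""
        return frozenset(self.top_ids) | frozenset(self.bottom_ids)

    @property
    def n_selected(self) -> int:
        return len(self.top_ids) + len(self.bottom_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entity_id": list(self.top_ids) + list(self.bottom_ids),
                "tail": ["top"] * len(self.top_ids) + ["bottom"] * len(self.bottom_ids),
            }
        )


def validate_screen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (entity_id, score) contract: unique ids, finite scores, n >= 2."""
    if not {"entity_id", "score"}.issubset(table.columns):
        raise ValueError("screen table requires columns 'entity_id' and 'score'")
    if len(table) < 2:
        raise ValueError("screen table needs at least 2 rows")
    if table["entity_id"].duplicated().any():
        dup = table.loc[table["entity_id"].duplicated(), "entity_id"].iloc[0]
        raise ValueError(f"duplicate entity_id: {dup!r}")
    scores = pd.to_numeric(table["score"], errors="raise")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("screen scores must be finite")
    return table


def select_extremes(table: pd.DataFrame, tail_fraction: float = 0.01) -> SelectedSet:
    """Select the top and bottom ``tail_fraction`` of a screen table.

    Each tail holds ``floor(tail_fraction * n)`` entities — the rounding
    rule under which a 2555-entity screen at 1% yields exactly 50
    candidates.  Ordering is a stable sort on (score, entity_id), so tied
    boundary scores resolve deterministically and the selection is
    invariant under row permutation of the input.

    Parameters
    ----------
    table : DataFrame with columns ``entity_id`` and ``score``.
    tail_fraction : fraction per tail, in [0, 0.5).

    Raises
    ------
    ValueError : if ``tail_fraction`` >= 0.5 (tails would overlap) or the
        table violates its invariants.
    """
    validate_screen_table(table)
    if not 0.0 <= tail_fraction < 0.5:
        raise ValueError(f"tail_fraction must be in [0, 0.5), got {tail_fraction}")
    n = len(table)
    m = math.floor(tail_fraction * n)
    if 2 * m > n:  # unreachable for tail_fraction < 0.5, kept as a guard
        raise ValueError("tails would overlap")

    order = table.sort_values(
        ["score", "entity_id"], kind="mergesort"
    )["entity_id"].to_list()
    bottom = tuple(order[:m])
    top = tuple(reversed(order[n - m:]))
    return SelectedSet(top_ids=top, bottom_ids=bottom, tail_fraction=tail_fraction)
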