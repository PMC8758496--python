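"""Synaptic connectivity from 3D pre/postsynaptic puncta centroids.

Segmented presynaptic (e.g. Synaptophysin) and postsynaptic (e.g. Homer)
puncta are reduced to centroids in µm.  Each postsynaptic punctum is
assigned to its nearest presynaptic punctum when that distance is within
``d_max`` (default 1 µm); a presynaptic punctum may collect several
postsynaptic partners.  The connectivity readout is the percentage of
presynaptic puncta left with no assignment — higher means fewer putative
synaptic contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["PunctaSet", "ConnectivityResult", "synaptic_connectivity"]


@dataclass
class PunctaSet:
    """3D puncta centroids for one channel ('pre' or 'post').

    ``coords`` is (n, 3) in µm; ``volumes`` (µm³) is carried through but
    unused by the connectivity readout.
    """

    channel: str
    ids: list[str]
    coords: np.ndarray
    volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.ids) != len(self.coords):
            raise ValueError("ids and coords length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("punctum ids must be unique within a channel")
        if self.coords.size and not np.isfinite(self.coords).all():
            raise ValueError("puncta coordinates must be finite")
        if self.volumes is not None:
            self.volumes = np.asarray(self.volumes, dtype=float)
            if len(self.volumes) != len(self.ids):
                raise ValueError("volumes length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, channel: str) -> "PunctaSet":
        required = {"punctum_id", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ValueError(f"puncta table requires columns {sorted(required)}")
        return cls(
            channel=channel,
            ids=[str(i) for i in df["punctum_id"]],
            coords=df[["x", "y", "z"]].to_numpy(dtype=float),
            volumes=df["volume"].to_numpy(dtype=float) if "volume" in df.columns else None,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "punctum_id": self.ids,
                "x": self.coords[:, 0] if len(self) else [],
                "y": self.coords[:, 1] if len(self) else [],
                "z": self.coords[:, 2] if len(self) else [],
            }
        )
        if self.volumes is not None:
            out["volume"] = self.volumes
        return out


@dataclass
class ConnectivityResult:
    """Nearest-neighbour assignment map and the unassigned-presynaptic readout."""

    assignments: dict[str, str]        # post_id -> pre_id
    pre_counts: dict[str, int]         # pre_id -> number of assigned posts
    n_pre: int
    n_post: int
    unassigned_pre_percent: float
    d_max: float


def synaptic_connectivity(
    pre: PunctaSet, post: PunctaSet, d_max: float = 1.0
) -> ConnectivityResult:
    """Assign each postsynaptic punctum to its nearest presynaptic punctum.

    An assignment happens iff the centroid-to-centroid Euclidean distance
    to the nearest presynaptic punctum is <= ``d_max`` (boundary
    inclusive).  Distance ties resolve to the lexicographically smallest
    presynaptic id.  The readout is
    100 * (#presynaptic puncta with zero assignments) / n_pre.

    An empty postsynaptic set is valid (100% unassigned); an empty
    presynaptic set is an error.
    """
    if len(pre) == 0:
        raise ValueError("presynaptic set must be nonempty")
    if d_max <= 0:
        raise ValueError("d_max must be positive")

    # lexicographic order so argmin's first-index tie rule = lowest pre id
    order = sorted(range(len(pre)), key=lambda i: pre.ids[i])
    pre_ids = [pre.ids[i] for i in order]
    pre_xyz = pre.coords[order]

    counts = dict.fromkeys(pre_ids, 0)
    assignments: dict[str, str] = {}
    if len(post):
        d = cdist(post.coords, pre_xyz)
        nearest = d.argmin(axis=1)
        within = d[np.arange(len(post)), nearest] <= d_max
        for j in np.flatnonzero(within):
            pid = pre_ids[nearest[j]]
            assignments[post.ids[j]] = pid
            counts[pid] += 1

    n_unassigned = sum(1 for c in counts.values() if c == 0)
    return ConnectivityResult(
        assignments=assignments,
        pre_counts=counts,
        n_pre=len(pre),
        n_post=len(post),
        unassigned_pre_percent=100.0 * n_unassigned / len(pre),
        d_max=d_max,
    )
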