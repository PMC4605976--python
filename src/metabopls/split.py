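"""Deterministic, balanced model/test partitioning via Kennard-Stone.

The model set is chosen with the Kennard-Stone max-min-distance algorithm
applied separately to each diagnostic group on that group's autoscaled data
(Euclidean distance), taking ``floor(fraction * smaller group size)`` samples
per group so the model set is balanced.  With the default 18 vs 28 cohort and
fraction 0.75 this yields a 13 + 13 model set and a 5 + 15 test set.  The
module is free of randomness; ties are broken by the lowest row index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import apply_scaling, fit_scaling
from .table import MetaboliteTable

__all__ = ["SplitPlan", "kennard_stone", "balanced_split", "random_split"]


@dataclass
class SplitPlan:
    """Model-set and test-set sample ids, per group."""

    model_ids: dict[str, list[str]]
    test_ids: dict[str, list[str]]
    fraction: float

    def __post_init__(self) -> None:
        sizes = {len(v) for v in self.model_ids.values()}
        if len(sizes) != 1:
            raise ValueError("model set must be balanced across groups")
        for g in self.model_ids:
            overlap = set(self.model_ids[g]) & set(self.test_ids.get(g, []))
            if overlap:
                raise ValueError(f"model/test overlap in group {g}: {sorted(overlap)}")

    @property
    def model_samples(self) -> list[str]:
        return [s for g in sorted(self.model_ids) for s in self.model_ids[g]]

    @property
    def test_samples(self) -> list[str]:
        return [s for g in sorted(self.test_ids) for s in self.test_ids[g]]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fraction": self.fraction,
                    "model_ids": self.model_ids,
                    "test_ids": self.test_ids,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["model_ids"], d["test_ids"], d["fraction"])


def kennard_stone(X: np.ndarray, k: int) -> list[int]:
    """Kennard-Stone selection of ``k`` representative rows of ``X``.

    The first two picks are the mutually most distant pair; every further
    pick maximizes the minimum Euclidean distance to the rows already
    selected.  Distance ties are broken by the lowest row index, making the
    selection fully deterministic.  Returns indices in selection order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    sq = np.sum(X**2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)

    # most distant pair; np.argmax on the flattened matrix gives the
    # lexicographically first (lowest-index) pair among ties
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    if k == 1:
        return [min(i, j)]
    selected = [min(i, j), max(i, j)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < k:
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))  # argmax returns the lowest index among ties
        selected.append(nxt)
        remaining[nxt] = False
        np.minimum(min_dist, D[nxt], out=min_dist)
    return selected


def balanced_split(
    table: MetaboliteTable, fraction: float = 0.75, scale: str = "per-group"
) -> SplitPlan:
    """Balanced model/test partition of a two-group table.

    ``k = floor(fraction * smaller group size)`` samples are picked per group
    by Kennard-Stone on the group's autoscaled data; the remainder form the
    test set.  ``scale`` is ``"per-group"`` (default: autoscaling fitted on
    each group's own rows) or ``"global"`` (fitted once on the full table).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if scale not in ("per-group", "global"):
        raise ValueError("scale must be 'per-group' or 'global'")
    groups = table.classes
    sizes = {g: table.group_indices(g).size for g in groups}
    k = math.floor(fraction * min(sizes.values()))
    if k < 2:
        raise ValueError(
            f"degenerate split: floor({fraction} * {min(sizes.values())}) = {k} < 2"
        )
    global_params = (
        fit_scaling(table.values, table.variable_names) if scale == "global" else None
    )
    model_ids: dict[str, list[str]] = {}
    test_ids: dict[str, list[str]] = {}
    for g in groups:
        idx = table.group_indices(g)
        Xg = table.values[idx]
        params = global_params or fit_scaling(Xg, table.variable_names)
        picked = kennard_stone(apply_scaling(Xg, params), k)
        chosen = {int(idx[i]) for i in picked}
        model_ids[g] = [table.sample_ids[i] for i in sorted(chosen)]
        test_ids[g] = [table.sample_ids[int(i)] for i in idx if int(i) not in chosen]
    return SplitPlan(model_ids=model_ids, test_ids=test_ids, fraction=fraction)


def random_split(table: MetaboliteTable, fraction: float, seed: int) -> SplitPlan:
    """Seeded uniform balanced split; reference baseline for property checks."""
    rng = np.random.default_rng(seed)
    groups = table.classes
    k = math.floor(fraction * min(table.group_indices(g).size for g in groups))
    model_ids: dict[str, list[str]] = {}
    test_ids: dict[str, list[str]] = {}
    for g in groups:
        idx = table.group_indices(g)
        picked = set(rng.choice(idx, size=k, replace=False).tolist())
        model_ids[g] = [table.sample_ids[int(i)] for i in idx if int(i) in picked]
        test_ids[g] = [table.sample_ids[int(i)] for i in idx if int(i) not in picked]
    return SplitPlan(model_ids=model_ids, test_ids=test_ids, fraction=fraction)
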