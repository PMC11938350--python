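"""Repertoire statistics: Chao1 richness, division-label gating,
clone-size summaries and a permutation two-group comparison."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd


def chao1(counts: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 species-richness estimate from a clone abundance vector.

    Bias-corrected form (default): ``S_obs + f1(f1-1) / (2(f2+1))`` with
    f1/f2 the singleton/doubleton counts; defined even when f2 = 0.
    The classic form ``S_obs + f1^2 / (2 f2)`` requires f2 > 0.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("abundance vector is empty")
    if any(c < 1 or int(c) != c for c in counts):
        raise ValueError("abundances must be positive integers")
    s_obs = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ValueError("classic Chao1 is undefined when there are no doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def clone_abundances(table: pd.DataFrame) -> list[int]:
    """Clone sizes (cells per clone_id) for richness estimation."""
    return sorted(Counter(table["clone_id"]).values(), reverse=True)


def gate_label(
    table: pd.DataFrame, lo_threshold: float, hi_threshold: float
) -> pd.DataFrame:
    """Two-gate division-label sort: ``lo`` (well-divided, label <=
    lo_threshold), ``hi`` (at most one division, label >= hi_threshold),
    intermediate cells ``excluded`` -- mirroring two-gate flow sorting."""
    if not lo_threshold < hi_threshold:
        raise ValueError(
            f"lo_threshold must be < hi_threshold, got {lo_threshold} >= {hi_threshold}"
        )
    out = table.copy()
    lab = out["label_dilution"].astype(float)
    out["gate"] = np.where(lab <= lo_threshold, "lo",
                           np.where(lab >= hi_threshold, "hi", "excluded"))
    return out


def resample_diff(
    group_a: Sequence[float],
    group_b: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in a group statistic.

    ``p = (1 + #{|d_perm| >= |d_obs|}) / (n_perm + 1)``; deterministic
    given the seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    observed = abs(statistic(a) - statistic(b))
    pooled = np.concatenate([a, b])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(statistic(perm[: len(a)]) - statistic(perm[len(a):]))
        if d >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


@dataclass
class CloneSizeSummary:
    expanded_fraction: float  # fraction of cells in clones of size >= 2
    sizes: list[int]
    n_cells: int


def clone_size_summary(table: pd.DataFrame, by_gate: bool = False):
    """Expanded-clone statistics (expanded = clone size >= 2, vs singlets).

    With ``by_gate=True`` returns a dict keyed by the ``gate`` column.
    """
    if by_gate:
        return {
            gate: clone_size_summary(sub)
            for gate, sub in table.groupby("gate")
            if gate != "excluded"
        }
    sizes = clone_abundances(table)
    n = len(table)
    expanded_cells = sum(s for s in sizes if s >= 2)
    return CloneSizeSummary(
        expanded_fraction=expanded_cells / n if n else float("nan"),
        sizes=sizes,
        n_cells=n,
    )
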