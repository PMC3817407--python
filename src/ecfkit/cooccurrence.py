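"""Co-occurrence statistics for ECF subgroups across genomes.

The partner count of a subgroup is the mean, over the genomes that contain
it, of how many *other* subgroups those genomes also contain. Insulated
(non-crosstalking) subgroups are hypothesised to tolerate — and therefore
accumulate — more co-occurring partners than crosstalking ones; the
comparison here is a two-sided label-permutation test on the difference in
group mean partner counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class PresenceMatrix:
    """Boolean subgroup x genome occurrence table."""

    subgroup_ids: List[str]
    genome_ids: List[str]
    present: np.ndarray  # shape (n_subgroups, n_genomes), bool

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.subgroup_ids), len(self.genome_ids)):
            raise ValidationError("presence matrix shape does not match id lists")

    def row(self, subgroup: str) -> np.ndarray:
        try:
            return self.present[self.subgroup_ids.index(subgroup)]
        except ValueError:
            raise ValidationError(f"unknown subgroup {subgroup!r}") from None

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.present.astype(int), index=self.subgroup_ids, columns=self.genome_ids
        ).to_csv(path, sep="\t", index_label="subgroup")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="subgroup")
        return cls(
            subgroup_ids=list(df.index),
            genome_ids=list(df.columns),
            present=df.values.astype(bool),
        )


@dataclass(frozen=True)
class GroupComparison:
    group_a_mean: float
    group_b_mean: float
    difference: float
    p_value: float
    n_perm: int

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p_value outside [0, 1]")

    def summary(self) -> str:
        return (
            f"group A mean partners {self.group_a_mean:.3g} vs "
            f"group B {self.group_b_mean:.3g} (diff {self.difference:+.3g}, "
            f"two-sided permutation P={self.p_value:.4g}, {self.n_perm} permutations)"
        )


def partner_count(matrix: PresenceMatrix, subgroup: str) -> float:
    """Mean number of co-occurring other subgroups, over the genomes that
    contain ``subgroup``. Errors if the subgroup occurs nowhere."""
    row = matrix.row(subgroup)
    if not row.any():
        raise ValidationError(f"subgroup {subgroup!r} absent from every genome")
    per_genome = matrix.present[:, row].sum(axis=0) - 1  # exclude the subgroup itself
    return float(per_genome.mean())


def partner_counts(matrix: PresenceMatrix) -> Dict[str, float]:
    return {sg: partner_count(matrix, sg) for sg in matrix.subgroup_ids}


def compare_groups(
    matrix: PresenceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    exact: bool = False,
) -> GroupComparison:
    """Two-sided permutation test on the difference in mean partner counts.

    Group labels are reshuffled over the union of the two groups; partner
    counts include all subgroups in the matrix, not only the tested ones.
    ``exact=True`` enumerates every label assignment instead of sampling
    (feasible for small unions). The sampled p-value uses the add-one
    (phipson-smyth) convention.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValidationError("groups must be disjoint")
    counts = np.array([partner_count(matrix, sg) for sg in [*a, *b]])
    na = len(a)
    mean_a, mean_b = counts[:na].mean(), counts[na:].mean()
    obs = mean_a - mean_b

    m = len(counts)
    if exact:
        stats = []
        idx = np.arange(m)
        for combo in combinations(idx, na):
            mask = np.zeros(m, dtype=bool)
            mask[list(combo)] = True
            stats.append(counts[mask].mean() - counts[~mask].mean())
        stats = np.array(stats)
        p = float(np.mean(np.abs(stats) >= abs(obs) - 1e-12))
        n_used = len(stats)
    else:
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(np.arange(m), (n_perm, 1)), axis=1)
        shuffled = counts[perms]
        stats = shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
        exceed = int(np.sum(np.abs(stats) >= abs(obs) - 1e-12))
        p = (1 + exceed) / (n_perm + 1)
        n_used = n_perm
    return GroupComparison(
        group_a_mean=float(mean_a),
        group_b_mean=float(mean_b),
        difference=float(obs),
        p_value=float(p),
        n_perm=n_used,
    )
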