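"""Isospace grouping: hierarchical clustering and rule-based niche assignment.

Fox trophic niches are defined by closed δ15N windows (high, intermediate,
low); these threshold rules are the canonical reproduction path, while Ward
clustering on the raw (δ13C, δ15N) coordinates serves as an advisory
cross-check that the same memberships fall out of the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .samples import CollagenSample, isotope_array

__all__ = [
    "IsotopeGroup",
    "NicheRule",
    "DEFAULT_FOX_NICHE_RULES",
    "FOX_TAXA",
    "LARGE_CARNIVORE_TAXA",
    "cluster_isospace",
    "assign_niches",
    "build_prey_groups",
    "group_from_points",
]

#: Taxa pooled as "fox" (red fox, Arctic fox, and indeterminate Vulpes).
FOX_TAXA = ("Vulpes vulpes", "Vulpes lagopus", "Vulpes sp.")

#: Taxa forming the large-carnivore comparison groups in the study data.
LARGE_CARNIVORE_TAXA = ("Canis lupus", "Gulo gulo", "Lynx lynx")


@dataclass(frozen=True)
class IsotopeGroup:
    """A named set of samples with mean vector and covariance in isospace."""

    label: str
    member_ids: frozenset[str]
    points: np.ndarray           # (n, 2), column order (d13C, d15N)
    mean: np.ndarray             # (2,)
    cov: np.ndarray              # (2, 2); zeros and degenerate=True when n == 1
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.points)


def group_from_points(label: str, points: np.ndarray,
                      member_ids: Iterable[str] = ()) -> IsotopeGroup:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError(f"group {label!r} has no members")
    mean = pts.mean(axis=0)
    if len(pts) == 1:
        return IsotopeGroup(label, frozenset(member_ids), pts, mean,
                            np.zeros((2, 2)), degenerate=True)
    cov = np.cov(pts.T, ddof=1)
    return IsotopeGroup(label, frozenset(member_ids), pts, mean, cov)


@dataclass(frozen=True)
class NicheRule:
    """Closed interval rule assigning samples to a trophic niche by δ15N.

    An optional δ13C interval further restricts membership.
    """

    niche: str
    d15N_range: tuple[float, float]
    d13C_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.d15N_range
        if not lo <= hi:
            raise ValueError(f"{self.niche}: empty d15N range")
        if self.d13C_range is not None and not self.d13C_range[0] <= self.d13C_range[1]:
            raise ValueError(f"{self.niche}: empty d13C range")

    def matches(self, sample: CollagenSample) -> bool:
        lo, hi = self.d15N_range
        if not lo <= sample.d15N <= hi:
            return False
        if self.d13C_range is not None:
            clo, chi = self.d13C_range
            if not clo <= sample.d13C <= chi:
                return False
        return True


#: δ15N windows of the three fox niche types observed in the study area.
DEFAULT_FOX_NICHE_RULES = (
    NicheRule("high", (7.1, 10.0)),
    NicheRule("intermediate", (3.7, 6.7)),
    NicheRule("low", (1.0, 3.0)),
)


def _check_disjoint(rules: Sequence[NicheRule]) -> None:
    iv = sorted((r.d15N_range, r.niche) for r in rules)
    for (r1, n1), (r2, n2) in zip(iv, iv[1:]):
        if r2[0] <= r1[1]:  # closed intervals overlap
            raise ValueError(f"niche d15N ranges overlap: {n1} and {n2}")


def assign_niches(samples: Sequence[CollagenSample],
                  rules: Sequence[NicheRule] = DEFAULT_FOX_NICHE_RULES,
                  ) -> dict[str, str | None]:
    """Map each sample's lab_id to its niche; unmatched samples map to None.

    The rules' δ15N ranges must be disjoint, so assignment is unambiguous,
    idempotent and independent of sample order.
    """
    _check_disjoint(rules)
    out: dict[str, str | None] = {}
    for s in samples:
        hits = [r.niche for r in rules if r.matches(s)]
        if len(hits) > 1:
            raise ValueError(f"{s.lab_id} matches multiple niches: {hits}")
        out[s.lab_id] = hits[0] if hits else None
    return out


def cluster_isospace(points: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative Ward clustering of isospace points, cut to k clusters.

    Euclidean distance on the raw ‰ coordinates (no axis standardization:
    the larger δ15N spread deliberately dominates). Returns integer labels
    0..k-1, relabelled in order of first appearance, so the labelling is
    deterministic for a given input order.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if not 1 <= k <= len(pts):
        raise ValueError(f"need 1 <= k <= n points, got k={k}, n={len(pts)}")
    if k == len(pts):
        return np.arange(len(pts))
    Z = linkage(pts, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        labels[i] = relabel.setdefault(r, len(relabel))
    return labels


def build_prey_groups(samples: Sequence[CollagenSample],
                      assignment: Mapping[str, str]) -> list[IsotopeGroup]:
    """Build labelled isotope groups from an explicit lab_id → label table.

    Group order follows first appearance of each label in ``assignment``.
    """
    by_id = {s.lab_id: s for s in samples}
    missing = [lid for lid in assignment if lid not in by_id]
    if missing:
        raise ValueError(f"assignment references unknown lab_ids: {missing}")
    members: dict[str, list[CollagenSample]] = {}
    for lid, label in assignment.items():
        members.setdefault(label, []).append(by_id[lid])
    groups = []
    for label, ss in members.items():
        groups.append(group_from_points(label, isotope_array(ss),
                                        [s.lab_id for s in ss]))
    return groups
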