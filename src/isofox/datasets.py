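"""Packaged study data: Swabian Jura collagen isotope tables and the
published prey-group / niche summary statistics.

Two CSV fixtures ship with the package: ``carnivores.csv`` (70 newly
analysed foxes and large carnivores from Middle Palaeolithic, Aurignacian
and Gravettian layers) and ``small_mammals.csv`` (44 rodents and hares
from the same deposits).  The four prey-group source distributions and
the per-period large-carnivore group statistics are the published
summary values; the raw isotope values behind the literature-derived
large-carnivore members are not distributed here and are reconstructed
on demand (see :mod:`isofox.synthetic_members`).
"""
from __future__ import annotations

from importlib import resources
from functools import lru_cache

import numpy as np

from .niches import (FOX_TAXA, LARGE_CARNIVORE_TAXA, IsotopeGroup,
                     group_from_points)
from .samples import CollagenSample, Period, isotope_array, read_samples
from .mixing import SourceDistribution, TrophicEnrichment

__all__ = [
    "load_carnivores",
    "load_small_mammals",
    "prey_group_sources",
    "fox_samples",
    "rodent_samples",
    "hare_samples",
    "fox_niche_points",
    "large_carnivore_group",
    "LARGE_CARNIVORE_PRINTED_STATS",
    "DEFAULT_TEF",
]

#: Default trophic enrichment factor used throughout the study.
DEFAULT_TEF = TrophicEnrichment()

#: Published per-period large-carnivore group statistics:
#: (n_total, mean d13C, mean d15N, sd d13C, sd d15N, SEA).  n_total counts
#: the newly analysed members plus the literature-derived ones.
LARGE_CARNIVORE_PRINTED_STATS = {
    Period.MP: dict(n=7, mean=(-19.7, 8.6), sd=(0.4, 1.2), sea=1.41),
    Period.AURIGNACIAN: dict(n=23, mean=(-19.5, 9.3), sd=(0.6, 0.9), sea=1.57),
    Period.GRAVETTIAN: dict(n=11, mean=(-19.4, 8.8), sd=(0.7, 0.8), sea=1.87),
}


def _load(name: str) -> list[CollagenSample]:
    with resources.as_file(resources.files("isofox.data") / name) as path:
        return read_samples(path)


@lru_cache(maxsize=None)
def load_carnivores() -> tuple[CollagenSample, ...]:
    """The 70 newly analysed carnivore samples (foxes, wolves, lynx, ...)."""
    return tuple(_load("carnivores.csv"))


@lru_cache(maxsize=None)
def load_small_mammals() -> tuple[CollagenSample, ...]:
    """The 44 newly analysed small-mammal samples (rodents and hares)."""
    return tuple(_load("small_mammals.csv"))


def prey_group_sources() -> list[SourceDistribution]:
    """The four isotope-defined prey groups (published summary statistics).

    Groups were formed by clustering the herbivore isospace and are named
    after the most abundant taxon; each carries mean ± SD per isotope and
    the number of raw values the summary is based on.
    """
    return [
        SourceDistribution("Horse", -20.8, 0.3, 6.4, 0.7, n=31),
        SourceDistribution("Mammoth", -21.1, 0.3, 8.74, 0.5, n=14),
        SourceDistribution("Reindeer", -19.3, 0.5, 3.8, 0.7, n=18),
        SourceDistribution("Rodents", -22.5, 1.0, 4.4, 2.3, n=35),
    ]


def fox_samples(period: Period | None = None) -> list[CollagenSample]:
    """Red + Arctic fox samples (species pooled), optionally per period."""
    out = [s for s in load_carnivores() if s.taxon in FOX_TAXA]
    if period is not None:
        out = [s for s in out if s.period is period]
    return out


def rodent_samples(period: Period | None = None) -> list[CollagenSample]:
    """Rodent samples (lemmings and voles; hares excluded)."""
    out = [s for s in load_small_mammals() if not s.taxon.startswith("Lepus")]
    if period is not None:
        out = [s for s in out if s.period is period]
    return out


def hare_samples() -> list[CollagenSample]:
    return [s for s in load_small_mammals() if s.taxon.startswith("Lepus")]


def fox_niche_points(niche: str, period: Period | None = None) -> np.ndarray:
    """(n, 2) isospace coordinates of the foxes in one niche.

    Niche membership follows the default δ15N window rules.
    """
    from .niches import DEFAULT_FOX_NICHE_RULES, assign_niches

    foxes = fox_samples(period)
    assignment = assign_niches(foxes, DEFAULT_FOX_NICHE_RULES)
    members = [s for s in foxes if assignment[s.lab_id] == niche]
    if not members:
        raise ValueError(f"no fox samples in niche {niche!r}"
                         + (f" for period {period}" if period else ""))
    return isotope_array(members)


def large_carnivore_group(period: Period,
                          include_reconstructed: bool = True) -> IsotopeGroup:
    """Per-period large-carnivore isotope group.

    The newly analysed wolves, wolverines and lynx come from the packaged
    table; the remaining literature-derived members (brown bear, hyena,
    cave lion) are, when ``include_reconstructed``, filled in by the
    synthetic least-squares reconstruction that matches the published
    group statistics.
    """
    new = [s for s in load_carnivores()
           if s.period is period and s.taxon in LARGE_CARNIVORE_TAXA]
    pts = isotope_array(new)
    ids = [s.lab_id for s in new]
    if include_reconstructed:
        from .synthetic_members import reconstruct_members

        stats = LARGE_CARNIVORE_PRINTED_STATS[period]
        extra = reconstruct_members(pts, stats["n"], stats["mean"],
                                    stats["sd"], stats["sea"])
        pts = np.vstack([pts, extra])
        ids += [f"synthetic-{period.value}-{i}" for i in range(len(extra))]
    return group_from_points(f"large_carnivores_{period.value}", pts, ids)
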