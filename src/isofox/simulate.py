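"""Synthetic datasets with the statistical structure the analysis assumes.

Two generating mechanisms cover every pipeline stage:

* **Source / niche clouds** — independent bivariate-normal draws per group
  (zero δ13C–δ15N correlation by default), used for QC, clustering,
  niche-assignment and ellipse-geometry tests.  Defaults are the published
  prey-group and fox-niche statistics, so synthetic scenarios are
  study-realistic.
* **Forward-model consumers** — consumer isotope values drawn from the
  mixing model's predictive normal at a *known* diet proportion vector,
  with optional extra residual SD; the generating truth is recorded so
  posterior recovery can be checked end-to-end.

All generated records carry QC chemistry values that pass the default
collagen criteria by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .mixing import SourceDistribution, TrophicEnrichment, forward_mix
from .samples import CollagenSample, Period

__all__ = [
    "ConsumerGroupSpec",
    "NicheCloudSpec",
    "SyntheticScenario",
    "TruthRecord",
    "StudyFixture",
    "default_scenario",
    "simulate_sources",
    "simulate_consumers",
    "make_study_fixture",
]


@dataclass(frozen=True)
class ConsumerGroupSpec:
    """A consumer group generated from the forward mixing model."""

    label: str
    proportions: tuple[float, ...]      # true diet over the scenario sources
    n: int
    residual_sd: tuple[float, float] = (0.0, 0.0)   # extra per-isotope SD

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.label}: proportions must lie on the simplex")
        if self.n < 1:
            raise ValueError(f"{self.label}: n must be >= 1")


@dataclass(frozen=True)
class NicheCloudSpec:
    """A bivariate-normal point cloud at a fixed isospace centroid."""

    label: str
    mean: tuple[float, float]           # (d13C, d15N)
    sd: tuple[float, float]
    n: int


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int
    sources: tuple[SourceDistribution, ...]
    consumer_groups: tuple[ConsumerGroupSpec, ...]
    niche_clouds: tuple[NicheCloudSpec, ...] = ()
    tef: TrophicEnrichment = TrophicEnrichment()


@dataclass(frozen=True)
class TruthRecord:
    """Generating truth of each forward-model consumer group."""

    proportions: dict[str, tuple[float, ...]]
    source_names: tuple[str, ...]
    seed: int

    def as_text(self) -> str:
        lines = [f"seed = {self.seed}",
                 "sources = " + ", ".join(self.source_names)]
        for label, p in self.proportions.items():
            lines.append(f"{label} = " + ", ".join(f"{x:.6f}" for x in p))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class StudyFixture:
    """End-to-end synthetic study: prey samples, fox niche clouds,
    large-carnivore cloud, forward-model consumers, and the truth."""

    prey: tuple[CollagenSample, ...]
    niche_foxes: tuple[CollagenSample, ...]
    large_carnivores: tuple[CollagenSample, ...]
    consumers: dict[str, tuple[CollagenSample, ...]]
    truth: TruthRecord


# source order: Horse, Mammoth, Reindeer, Rodents (as in prey_group_sources)
_DEFAULT_CONSUMERS = (
    ConsumerGroupSpec("high", (0.24, 0.22, 0.25, 0.29), n=26),
    ConsumerGroupSpec("intermediate", (0.04, 0.03, 0.46, 0.47), n=10),
    ConsumerGroupSpec("low", (0.06, 0.05, 0.09, 0.80), n=2),
)

# fox niche clouds at the published niche centroids (pooled across periods)
_DEFAULT_NICHES = (
    NicheCloudSpec("high_fox", (-20.0, 8.7), (0.4, 0.4), n=26),
    NicheCloudSpec("intermediate_fox", (-19.9, 5.4), (0.3, 0.4), n=10),
    NicheCloudSpec("low_fox", (-21.3, 2.0), (0.2, 0.3), n=2),
    NicheCloudSpec("large_carnivore", (-19.5, 9.0), (0.5, 1.0), n=20),
)


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """Study-shaped scenario: the published prey groups and TEF, fox niche
    clouds at the published centroids (26/10/2 group sizes), and
    forward-model consumer groups with niche-like true diets (the low
    niche is rodent-dominated at 0.80)."""
    from .datasets import prey_group_sources

    return SyntheticScenario(seed=seed,
                             sources=tuple(prey_group_sources()),
                             consumer_groups=_DEFAULT_CONSUMERS,
                             niche_clouds=_DEFAULT_NICHES)


def _as_samples(label: str, taxon: str, period: Period,
                xy: np.ndarray) -> list[CollagenSample]:
    out = []
    for i, (x, y) in enumerate(xy):
        out.append(CollagenSample(
            lab_id=f"{label}-{i:03d}", period=period, site="SYN",
            taxon=taxon, element="synthetic",
            pct_N_bone=3.0, yield_mg_g=80.0, pct_C_coll=40.0,
            pct_N_coll=14.0, cn_ratio=3.3,
            d13C=float(x), d15N=float(y)))
    return out


def simulate_sources(scenario: SyntheticScenario,
                     per_group_n: int | None = None) -> list[CollagenSample]:
    """Bivariate-normal draws per prey group (independent isotopes).

    ``per_group_n`` overrides each source's own n.  QC fields are filled
    with passing values.
    """
    rng = np.random.default_rng(scenario.seed)
    out: list[CollagenSample] = []
    for src in scenario.sources:
        n = per_group_n if per_group_n is not None else src.n
        xy = np.column_stack([
            rng.normal(src.mean_d13C, src.sd_d13C, n),
            rng.normal(src.mean_d15N, src.sd_d15N, n),
        ])
        out.extend(_as_samples(f"prey-{src.name}", src.name, Period.MP, xy))
    return out


def simulate_consumers(scenario: SyntheticScenario,
                       group_label: str) -> tuple[list[CollagenSample], TruthRecord]:
    """Forward-model consumer draws for one group, with the truth record.

    Each consumer's isotope pair is normal at the forward-mix mean and
    variance (plus the group's residual SD, if any).
    """
    spec = next((g for g in scenario.consumer_groups if g.label == group_label),
                None)
    if spec is None:
        raise ValueError(f"unknown consumer group {group_label!r}")
    # per-group deterministic stream, independent of other groups
    labels = [g.label for g in scenario.consumer_groups]
    stream = np.random.SeedSequence(scenario.seed).spawn(len(labels) + 1)
    rng = np.random.default_rng(stream[1 + labels.index(group_label)])
    mean, var = forward_mix(np.asarray(spec.proportions), scenario.sources,
                            scenario.tef)
    sd = np.sqrt(var + np.asarray(spec.residual_sd, dtype=float) ** 2)
    xy = rng.normal(mean, sd, size=(spec.n, 2))
    samples = _as_samples(f"cons-{group_label}", "Vulpes vulpes", Period.MP, xy)
    truth = TruthRecord(
        proportions={g.label: g.proportions for g in scenario.consumer_groups},
        source_names=tuple(s.name for s in scenario.sources),
        seed=scenario.seed)
    return samples, truth


def make_study_fixture(seed: int = 0,
                       scenario: SyntheticScenario | None = None) -> StudyFixture:
    """Full synthetic study emulating the packaged tables' structure.

    Prey samples for the four groups, fox niche clouds at the published
    centroids (so threshold assignment yields the 26/10/2 split), a
    large-carnivore cloud, and forward-model consumer groups with a known
    truth for posterior-recovery tests.
    """
    if scenario is None:
        scenario = default_scenario(seed)
    elif scenario.seed != seed:
        scenario = replace(scenario, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    prey = simulate_sources(scenario)
    niche_foxes: list[CollagenSample] = []
    carnivores: list[CollagenSample] = []
    for cloud in scenario.niche_clouds:
        xy = np.column_stack([
            rng.normal(cloud.mean[0], cloud.sd[0], cloud.n),
            rng.normal(cloud.mean[1], cloud.sd[1], cloud.n),
        ])
        taxon = "Canis lupus" if cloud.label == "large_carnivore" else "Vulpes vulpes"
        samples = _as_samples(f"niche-{cloud.label}", taxon, Period.MP, xy)
        if cloud.label == "large_carnivore":
            carnivores.extend(samples)
        else:
            niche_foxes.extend(samples)
    consumers: dict[str, tuple[CollagenSample, ...]] = {}
    truth = None
    for g in scenario.consumer_groups:
        ss, truth = simulate_consumers(scenario, g.label)
        consumers[g.label] = tuple(ss)
    assert truth is not None
    return StudyFixture(prey=tuple(prey), niche_foxes=tuple(niche_foxes),
                        large_carnivores=tuple(carnivores),
                        consumers=consumers, truth=truth)
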