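"""File-based analysis pipeline: QC → grouping → niche metrics → diet.

Stages communicate via CSV artifacts in the run's output directory so
every table is re-derivable and auditable from inputs + config + seed:

========  =============================================================
stage     artifacts
========  =============================================================
qc        ``qc_report.csv``, ``samples_kept.csv``
group     ``group_summaries.csv``, ``niche_assignment.csv``
niche     ``niche_metrics.csv`` (TA/SEA/SEAc per group), ``overlap.csv``
diet      ``diet_posterior.csv`` (mean/SD/quantiles per source),
          ``convergence.csv``
all       all of the above plus ``run_log.json``
========  =============================================================

Configuration is a plain YAML mapping; :func:`validate_config` fills
defaults (QC 2.9/3.6/5%, TEF 1.1±1.1 / 3.2±1.8, scaled-down MCMC) and
rejects unknown keys.  Two MCMC presets ship: ``full`` (the study-scale
3 chains of 1,000,000 iterations, 500,000 burn-in) and ``ci``
(3 × 100,000 / 50,000).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .ellipses import StandardEllipse, convex_hull_area
from .mixing import (DietMixingModel, MixingModelConfig, SourceDistribution,
                     TrophicEnrichment)
from .niches import (DEFAULT_FOX_NICHE_RULES, NicheRule, assign_niches)
from .samples import (CollagenSample, Period, QCCriteria, apply_qc,
                      read_samples, samples_to_frame, summarize_group,
                      write_samples)

__all__ = ["RunConfig", "RunArtifacts", "validate_config", "run_stage",
           "PROFILES", "STAGES"]

STAGES = ("qc", "group", "niche", "diet", "all")

PROFILES = {
    "full": dict(chains=3, iterations=1_000_000, burn_in=500_000, thin=10),
    "ci": dict(chains=3, iterations=100_000, burn_in=50_000, thin=1),
}


@dataclass
class RunConfig:
    """Normalized pipeline configuration."""

    input_path: str | None = None       # None -> packaged study tables
    small_mammal_path: str | None = None
    out_dir: str = "isofox_run"
    seed: int = 0
    profile: str = "ci"
    qc: QCCriteria = field(default_factory=QCCriteria)
    tef: TrophicEnrichment = field(default_factory=TrophicEnrichment)
    niche_rules: tuple[NicheRule, ...] = DEFAULT_FOX_NICHE_RULES
    sources: tuple[SourceDistribution, ...] | None = None   # None -> packaged
    mcmc: MixingModelConfig | None = None   # None -> profile defaults
    verbosity: str = "info"

    def resolved_mcmc(self) -> MixingModelConfig:
        if self.mcmc is not None:
            return self.mcmc
        prof = PROFILES[self.profile]
        return MixingModelConfig(seed=self.seed, **prof)

    def resolved_sources(self) -> list[SourceDistribution]:
        if self.sources is not None:
            return list(self.sources)
        return datasets.prey_group_sources()

    def to_mapping(self) -> dict:
        cfg = {
            "input_path": self.input_path,
            "small_mammal_path": self.small_mammal_path,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "profile": self.profile,
            "verbosity": self.verbosity,
            "qc": dataclasses.asdict(self.qc),
            "tef": dataclasses.asdict(self.tef),
            "niche_rules": [
                {"niche": r.niche, "d15N_range": list(r.d15N_range),
                 **({"d13C_range": list(r.d13C_range)} if r.d13C_range else {})}
                for r in self.niche_rules],
        }
        if self.sources is not None:
            cfg["sources"] = [dataclasses.asdict(s) for s in self.sources]
        if self.mcmc is not None:
            cfg["mcmc"] = dataclasses.asdict(self.mcmc)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_mapping(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_KNOWN_KEYS = {"input_path", "small_mammal_path", "out_dir", "seed", "profile",
               "verbosity", "qc", "tef", "niche_rules", "sources", "mcmc"}


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and normalize a YAML config file or mapping.

    Unknown keys, type mismatches and inconsistent MCMC settings raise
    ``ValueError`` naming the offending key.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key in ("input_path", "small_mammal_path", "out_dir", "verbosity"):
        if raw.get(key) is not None:
            kwargs[key] = str(raw[key])
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            raise ValueError("seed: expected an integer")
        kwargs["seed"] = raw["seed"]
    if "profile" in raw:
        if raw["profile"] not in PROFILES:
            raise ValueError(f"profile: expected one of {sorted(PROFILES)}")
        kwargs["profile"] = raw["profile"]
    try:
        if "qc" in raw:
            kwargs["qc"] = QCCriteria(**raw["qc"])
        if "tef" in raw:
            kwargs["tef"] = TrophicEnrichment(**raw["tef"])
        if "niche_rules" in raw:
            kwargs["niche_rules"] = tuple(
                NicheRule(niche=r["niche"],
                          d15N_range=tuple(r["d15N_range"]),
                          d13C_range=tuple(r["d13C_range"]) if r.get("d13C_range") else None)
                for r in raw["niche_rules"])
        if "sources" in raw:
            kwargs["sources"] = tuple(SourceDistribution(**s) for s in raw["sources"])
        if "mcmc" in raw:
            kwargs["mcmc"] = MixingModelConfig(**raw["mcmc"])
    except TypeError as exc:
        raise ValueError(f"config type mismatch: {exc}") from None
    return RunConfig(**kwargs)


@dataclass
class RunArtifacts:
    """Paths of the tables written by a pipeline run."""

    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)

    def path(self, name: str) -> Path:
        return self.tables[name]


def _load_inputs(config: RunConfig) -> tuple[list[CollagenSample], list[CollagenSample]]:
    if config.input_path is None:
        carn = list(datasets.load_carnivores())
    else:
        carn = read_samples(config.input_path)
    if config.small_mammal_path is None:
        small = list(datasets.load_small_mammals()) if config.input_path is None else []
    else:
        small = read_samples(config.small_mammal_path)
    return carn, small


def _stage_qc(config: RunConfig, out: Path, art: RunArtifacts) -> None:
    carn, small = _load_inputs(config)
    result = apply_qc(carn + small, config.qc)
    report = result.report_frame()
    art.tables["qc_report"] = out / "qc_report.csv"
    report.to_csv(art.tables["qc_report"], index=False)
    art.tables["samples_kept"] = out / "samples_kept.csv"
    write_samples(result.kept, art.tables["samples_kept"])


def _kept_samples(config: RunConfig, art: RunArtifacts) -> list[CollagenSample]:
    path = art.tables.get("samples_kept")
    if path is None or not Path(path).exists():
        raise RuntimeError("stage 'qc' must run before later stages")
    return read_samples(path)


def _fox_niche_members(samples: Sequence[CollagenSample],
                       config: RunConfig) -> dict[str, list[CollagenSample]]:
    from .niches import FOX_TAXA

    foxes = [s for s in samples if s.taxon in FOX_TAXA]
    assignment = assign_niches(foxes, config.niche_rules)
    members: dict[str, list[CollagenSample]] = {}
    for s in foxes:
        niche = assignment[s.lab_id]
        if niche is not None:
            members.setdefault(niche, []).append(s)
    return members


def _stage_group(config: RunConfig, out: Path, art: RunArtifacts) -> None:
    samples = _kept_samples(config, art)
    members = _fox_niche_members(samples, config)
    rows = []
    assign_rows = []
    for niche in ("high", "intermediate", "low"):
        for period in (None, Period.MP, Period.AURIGNACIAN, Period.GRAVETTIAN):
            sel = [s for s in members.get(niche, [])
                   if period is None or s.period is period]
            if not sel:
                continue
            label = f"{niche}_fox" + ("" if period is None else f"_{period.value}")
            g = summarize_group(sel, label)
            rows.append({"label": g.label, "n": g.n,
                         "mean_d13C": g.mean_d13C, "sd_d13C": g.sd_d13C,
                         "mean_d15N": g.mean_d15N, "sd_d15N": g.sd_d15N})
    for niche, sel in members.items():
        for s in sel:
            assign_rows.append({"lab_id": s.lab_id, "period": s.period.value,
                                "niche": niche})
    art.tables["group_summaries"] = out / "group_summaries.csv"
    pd.DataFrame(rows).to_csv(art.tables["group_summaries"], index=False)
    art.tables["niche_assignment"] = out / "niche_assignment.csv"
    pd.DataFrame(assign_rows).to_csv(art.tables["niche_assignment"], index=False)


def _stage_niche(config: RunConfig, out: Path, art: RunArtifacts) -> None:
    samples = _kept_samples(config, art)
    members = _fox_niche_members(samples, config)
    metric_rows, overlap_rows = [], []
    for period in (Period.MP, Period.AURIGNACIAN, Period.GRAVETTIAN):
        high = [s for s in members.get("high", []) if s.period is period]
        if len(high) < 3:
            continue
        pts = np.array([s.isotopes for s in high])
        fox = StandardEllipse().fit(pts)
        metric_rows.append({
            "group": f"high_fox_{period.value}", "n": fox.n_,
            "TA": convex_hull_area(pts), "SEA": fox.sea_, "SEAc": fox.seac_})
        try:
            carn_group = datasets.large_carnivore_group(period)
        except Exception:
            continue
        carn = StandardEllipse().fit(carn_group.points)
        metric_rows.append({
            "group": carn_group.label, "n": carn.n_,
            "TA": convex_hull_area(carn_group.points),
            "SEA": carn.sea_, "SEAc": carn.seac_})
        ov = carn.overlap(fox)
        overlap_rows.append({
            "period": period.value, "overlap_area": ov.area,
            "pct_of_large_carnivores": ov.pct_of_a, "pct_of_high_fox": ov.pct_of_b})
    art.tables["niche_metrics"] = out / "niche_metrics.csv"
    pd.DataFrame(metric_rows).to_csv(art.tables["niche_metrics"], index=False)
    art.tables["overlap"] = out / "overlap.csv"
    pd.DataFrame(overlap_rows).to_csv(art.tables["overlap"], index=False)


def _stage_diet(config: RunConfig, out: Path, art: RunArtifacts) -> None:
    samples = _kept_samples(config, art)
    members = _fox_niche_members(samples, config)
    sources = config.resolved_sources()
    mcmc = config.resolved_mcmc()
    post_rows, conv_rows = [], []
    for niche in ("high", "intermediate", "low"):
        sel = members.get(niche, [])
        if not sel:
            continue
        X = np.array([s.isotopes for s in sel])
        model = DietMixingModel(
            sources=sources, tef=config.tef, chains=mcmc.chains,
            iterations=mcmc.iterations, burn_in=mcmc.burn_in, thin=mcmc.thin,
            dirichlet_alpha=mcmc.dirichlet_alpha, error_model=mcmc.error_model,
            random_state=mcmc.seed).fit(X)
        pct = model.posterior_.summary_percent()
        for src_name, row in pct.iterrows():
            post_rows.append({"group": f"{niche}_fox", "n": len(sel),
                              "source": src_name, **row.to_dict()})
        for conv in model.convergence_.to_rows():
            conv_rows.append({"group": f"{niche}_fox", **conv})
    art.tables["diet_posterior"] = out / "diet_posterior.csv"
    pd.DataFrame(post_rows).to_csv(art.tables["diet_posterior"], index=False)
    art.tables["convergence"] = out / "convergence.csv"
    pd.DataFrame(conv_rows).to_csv(art.tables["convergence"], index=False)


_STAGE_FUNCS = {"qc": _stage_qc, "group": _stage_group,
                "niche": _stage_niche, "diet": _stage_diet}


def run_stage(stage: str, config: RunConfig) -> RunArtifacts:
    """Execute one stage (or ``all``) and write its artifacts.

    Later stages require the QC stage's artifacts to exist in the output
    directory; ``all`` runs every stage in order and writes a run log with
    the seed, config hash and per-stage wall time.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art = RunArtifacts(out_dir=out)
    # re-attach prior artifacts so single stages can resume a directory
    kept = out / "samples_kept.csv"
    if kept.exists():
        art.tables["samples_kept"] = kept
    order = ("qc", "group", "niche", "diet") if stage == "all" else (stage,)
    timings: dict[str, float] = {}
    for name in order:
        t0 = time.perf_counter()
        _STAGE_FUNCS[name](config, out, art)
        timings[name] = round(time.perf_counter() - t0, 3)
    if stage == "all":
        from . import __version__

        log = {"tool_version": __version__, "seed": config.seed,
               "config_hash": config.config_hash(), "stage_seconds": timings}
        art.tables["run_log"] = out / "run_log.json"
        art.tables["run_log"].write_text(json.dumps(log, indent=2))
    return art
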