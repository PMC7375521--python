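"""Collagen sample records, file ingest, quality control, and group statistics.

A sample is one bone: provenance (lab id, period, site, taxon, skeletal
element), the collagen-chemistry indicators used for quality control
(%N of whole bone, collagen yield, %C and %N of the extract, atomic C:N),
and the isotope pair (δ13C vs V-PDB, δ15N vs AIR, both in ‰).

Diagenesis screening follows the conventional collagen criteria: atomic
C:N between 2.9 and 3.6 (inclusive) and collagen nitrogen above 5%.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Period",
    "CollagenSample",
    "QCCriteria",
    "QCReason",
    "QCResult",
    "GroupSummary",
    "TTestResult",
    "CANONICAL_COLUMNS",
    "read_samples",
    "write_samples",
    "samples_to_frame",
    "frame_to_samples",
    "delta_from_ratio",
    "apply_qc",
    "summarize_group",
    "two_sample_t_test",
    "isotope_array",
]

CANONICAL_COLUMNS = (
    "lab_id", "period", "site", "taxon", "element",
    "pct_N_bone", "yield_mg_g", "pct_C_coll", "pct_N_coll",
    "cn_ratio", "d13C", "d15N",
)

#: Known archaeological site codes of the study area (Ach and Lone valleys).
SITE_CODES = frozenset({"BS", "HS", "HF", "GK", "Si", "VH"})


class Period(enum.Enum):
    """Chronological unit of a sample (all pre-LGM)."""

    MP = "MP"            # Middle Palaeolithic
    AURIGNACIAN = "A"
    GRAVETTIAN = "G"

    @classmethod
    def parse(cls, code: str) -> "Period":
        code = str(code).strip()
        aliases = {
            "MP": cls.MP, "Middle Palaeolithic": cls.MP, "Middle Paleolithic": cls.MP,
            "A": cls.AURIGNACIAN, "Aurignacian": cls.AURIGNACIAN,
            "G": cls.GRAVETTIAN, "Gravettian": cls.GRAVETTIAN,
        }
        try:
            return aliases[code]
        except KeyError:
            raise ValueError(f"unknown period code: {code!r}") from None


@dataclass(frozen=True)
class CollagenSample:
    """One bone's provenance, QC chemistry and isotope values."""

    lab_id: str
    period: Period
    site: str
    taxon: str
    element: str = ""
    pct_N_bone: float | None = None
    yield_mg_g: float | None = None
    pct_C_coll: float | None = None
    pct_N_coll: float | None = None
    cn_ratio: float | None = None
    d13C: float = math.nan
    d15N: float = math.nan

    def __post_init__(self) -> None:
        if self.cn_ratio is not None and self.cn_ratio <= 0:
            raise ValueError(f"{self.lab_id}: cn_ratio must be > 0")
        if not (-35.0 < self.d13C < -5.0):
            raise ValueError(f"{self.lab_id}: d13C {self.d13C} outside (-35, -5) per-mil")
        if not (-10.0 < self.d15N < 25.0):
            raise ValueError(f"{self.lab_id}: d15N {self.d15N} outside (-10, 25) per-mil")

    @property
    def isotopes(self) -> tuple[float, float]:
        """(δ13C, δ15N) coordinate in isospace."""
        return (self.d13C, self.d15N)


class QCReason(enum.Enum):
    CN_LOW = "CN_LOW"
    CN_HIGH = "CN_HIGH"
    NLOW = "NLOW"
    MISSING = "MISSING"


@dataclass(frozen=True)
class QCCriteria:
    """Collagen-preservation thresholds.

    C:N bounds are inclusive; the nitrogen threshold is strict
    (``pct_N_coll > n_coll_min``).
    """

    cn_min: float = 2.9
    cn_max: float = 3.6
    n_coll_min: float = 5.0

    def __post_init__(self) -> None:
        if not self.cn_min < self.cn_max:
            raise ValueError("cn_min must be < cn_max")
        if self.n_coll_min < 0:
            raise ValueError("n_coll_min must be >= 0")


@dataclass(frozen=True)
class QCResult:
    kept: tuple[CollagenSample, ...]
    rejected: tuple[tuple[CollagenSample, QCReason], ...]

    def report_frame(self) -> pd.DataFrame:
        """Per-sample QC outcome as a table (lab_id, status, reason)."""
        rows = [(s.lab_id, "kept", "") for s in self.kept]
        rows += [(s.lab_id, "rejected", r.value) for s, r in self.rejected]
        return pd.DataFrame(rows, columns=["lab_id", "status", "reason"])


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± sample SD (n−1) of each isotope for a labelled group."""

    label: str
    n: int
    mean_d13C: float
    sd_d13C: float | None
    mean_d15N: float
    sd_d15N: float | None


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def delta_from_ratio(r_sample: float, r_reference: float) -> float:
    """δ-notation: (R_sample / R_reference − 1) × 1000, in ‰.

    Both arguments are raw heavy/light isotope abundance ratios and must be
    positive.
    """
    if r_sample <= 0 or r_reference <= 0:
        raise ValueError("isotope ratios must be positive")
    return (r_sample / r_reference - 1.0) * 1000.0


def _coerce_float(value, row_no: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"row {row_no}: malformed value {value!r} in column {column!r}") from None


def read_samples(path: str | Path,
                 schema: Mapping[str, str] | None = None) -> list[CollagenSample]:
    """Read collagen samples from a comma-separated file.

    Parameters
    ----------
    path:
        CSV file with a header row; decimal point ".".
    schema:
        Optional column map ``{file column -> canonical column}`` for files
        whose headers deviate from :data:`CANONICAL_COLUMNS`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = {"lab_id", "period", "d13C", "d15N"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return frame_to_samples(df)


def frame_to_samples(df: pd.DataFrame) -> list[CollagenSample]:
    samples: list[CollagenSample] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=2):  # header = row 1
        lab_id = str(row.get("lab_id", "")).strip()
        if not lab_id:
            raise ValueError(f"row {i}: empty lab_id")
        if lab_id in seen:
            raise ValueError(f"row {i}: duplicate lab_id {lab_id!r}")
        seen.add(lab_id)
        d13C = _coerce_float(row.get("d13C"), i, "d13C")
        d15N = _coerce_float(row.get("d15N"), i, "d15N")
        if d13C is None or d15N is None:
            raise ValueError(f"row {i}: missing isotope value")
        try:
            sample = CollagenSample(
                lab_id=lab_id,
                period=Period.parse(row["period"]),
                site=str(row.get("site", "")).strip(),
                taxon=str(row.get("taxon", "")).strip(),
                element=str(row.get("element", "")).strip(),
                pct_N_bone=_coerce_float(row.get("pct_N_bone"), i, "pct_N_bone"),
                yield_mg_g=_coerce_float(row.get("yield_mg_g"), i, "yield_mg_g"),
                pct_C_coll=_coerce_float(row.get("pct_C_coll"), i, "pct_C_coll"),
                pct_N_coll=_coerce_float(row.get("pct_N_coll"), i, "pct_N_coll"),
                cn_ratio=_coerce_float(row.get("cn_ratio"), i, "cn_ratio"),
                d13C=d13C,
                d15N=d15N,
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        samples.append(sample)
    return samples


def samples_to_frame(samples: Iterable[CollagenSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        rows.append({
            "lab_id": s.lab_id, "period": s.period.value, "site": s.site,
            "taxon": s.taxon, "element": s.element,
            "pct_N_bone": s.pct_N_bone, "yield_mg_g": s.yield_mg_g,
            "pct_C_coll": s.pct_C_coll, "pct_N_coll": s.pct_N_coll,
            "cn_ratio": s.cn_ratio, "d13C": s.d13C, "d15N": s.d15N,
        })
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def write_samples(samples: Iterable[CollagenSample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def isotope_array(samples: Sequence[CollagenSample]) -> np.ndarray:
    """(n, 2) array of (δ13C, δ15N) coordinates."""
    return np.array([s.isotopes for s in samples], dtype=float).reshape(-1, 2)


def apply_qc(samples: Sequence[CollagenSample],
             criteria: QCCriteria = QCCriteria()) -> QCResult:
    """Partition samples into QC-passing and rejected (with reason codes).

    A sample is kept when ``cn_min <= cn_ratio <= cn_max`` and
    ``pct_N_coll > n_coll_min``; samples lacking either QC field are
    rejected with reason ``MISSING``.
    """
    kept: list[CollagenSample] = []
    rejected: list[tuple[CollagenSample, QCReason]] = []
    for s in samples:
        if s.cn_ratio is None or s.pct_N_coll is None:
            rejected.append((s, QCReason.MISSING))
        elif s.cn_ratio < criteria.cn_min:
            rejected.append((s, QCReason.CN_LOW))
        elif s.cn_ratio > criteria.cn_max:
            rejected.append((s, QCReason.CN_HIGH))
        elif not s.pct_N_coll > criteria.n_coll_min:
            rejected.append((s, QCReason.NLOW))
        else:
            kept.append(s)
    return QCResult(kept=tuple(kept), rejected=tuple(rejected))


def summarize_group(samples: Sequence[CollagenSample], label: str) -> GroupSummary:
    """Arithmetic mean and sample SD (n−1 denominator) per isotope.

    SDs are reported as missing (``None``) for a single-sample group.
    """
    if len(samples) == 0:
        raise ValueError("cannot summarize an empty group")
    xy = isotope_array(samples)
    n = len(samples)
    mean = xy.mean(axis=0)
    if n == 1:
        sd13 = sd15 = None
    else:
        sd = xy.std(axis=0, ddof=1)
        sd13, sd15 = float(sd[0]), float(sd[1])
    return GroupSummary(label=label, n=n,
                        mean_d13C=float(mean[0]), sd_d13C=sd13,
                        mean_d15N=float(mean[1]), sd_d15N=sd15)


def two_sample_t_test(a: Sequence[float], b: Sequence[float],
                      variant: str = "pooled") -> TTestResult:
    """Two-sample t-test on isotope values (two-sided).

    ``variant="pooled"`` uses the pooled-variance statistic with
    ``df = n_a + n_b − 2``; ``variant="welch"`` uses the Welch statistic
    with Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue), variant=variant)
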