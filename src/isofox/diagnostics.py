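"""MCMC convergence diagnostics: Gelman–Rubin R̂ and Geweke z-scores."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from statsmodels.regression.linear_model import yule_walker

__all__ = ["gelman_rubin", "geweke", "spectrum0_ar", "ConvergenceReport"]


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor R̂ for one scalar parameter.

    Classic between/within-chain variance form: with m chains of length n,
    W = mean within-chain variance, B/n = variance of the chain means, and

        R̂ = sqrt( ((n−1)/n · W + B/n) / W ).

    Identical chains give R̂ slightly below 1 (the (n−1)/n shrinkage), so
    values are reported floored at 1 up to numerical tolerance.
    """
    arrs = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(arrs) < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    n = len(arrs[0])
    if n < 10 or any(len(a) != n for a in arrs):
        raise ValueError("chains must have equal lengths >= 10")
    mat = np.stack(arrs)                       # (m, n)
    within = mat.var(axis=1, ddof=1)
    w = float(within.mean())
    b_over_n = float(mat.mean(axis=1).var(ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def spectrum0_ar(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of a series at frequency zero via an AR fit.

    Fits AR(p) models by Yule-Walker for p = 0..max_order, picks the order
    with minimum AIC, and returns S(0) = σ² / (1 − Σφ)².  This is the
    conventional long-run variance estimator used in the Geweke diagnostic.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    v = float(x.var())
    # numerically-constant series: variance at rounding level of the mean
    if v <= 1e-14 * max(1.0, float(x.mean()) ** 2):
        return 0.0
    if max_order is None:
        max_order = min(20, n - 1, int(10 * np.log10(n)))
    best_aic, best = np.inf, v
    for p in range(max_order + 1):
        if p == 0:
            sigma2, dens = v, v
        else:
            try:
                rho, sigma = yule_walker(x, order=p, method="mle")
            except np.linalg.LinAlgError:
                continue
            sigma2 = float(sigma) ** 2
            denom = (1.0 - rho.sum()) ** 2
            if denom <= 1e-12 or sigma2 <= 0:
                continue
            dens = sigma2 / denom
        aic = n * np.log(max(sigma2, 1e-300)) + 2.0 * (p + 1)
        if aic < best_aic:
            best_aic, best = aic, dens
    return float(best)


def geweke(chain: np.ndarray, first_frac: float = 0.1,
           last_frac: float = 0.5) -> float:
    """Geweke stationarity z-score for a single chain.

    Compares the mean of the first ``first_frac`` of the chain against the
    mean of the last ``last_frac``:

        z = (m₁ − m₂) / sqrt(S₁(0)/n₁ + S₂(0)/n₂),

    with segment long-run variances from :func:`spectrum0_ar`.  |z| < 1.96
    is consistent with stationarity; a constant chain returns z = 0.
    """
    x = np.asarray(chain, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("Geweke needs a chain of length >= 100")
    if not (0 < first_frac < 1 and 0 < last_frac < 1 and first_frac + last_frac <= 1):
        raise ValueError("invalid segment fractions")
    n1 = int(np.floor(first_frac * len(x)))
    n2 = int(np.floor(last_frac * len(x)))
    a, b = x[:n1], x[len(x) - n2:]
    var = spectrum0_ar(a) / n1 + spectrum0_ar(b) / n2
    if var == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter R̂ and per-chain Geweke z, with pass flags.

    ``rhat`` maps parameter name → R̂; ``geweke_z`` maps parameter name →
    one z-score per chain.
    """

    rhat: Mapping[str, float]
    geweke_z: Mapping[str, tuple[float, ...]]
    rhat_acceptable_threshold: float = 1.1
    rhat_strict_threshold: float = 1.01
    geweke_threshold: float = 1.96

    @property
    def rhat_acceptable(self) -> bool:
        return all(r <= self.rhat_acceptable_threshold for r in self.rhat.values())

    @property
    def rhat_strict(self) -> bool:
        return all(r <= self.rhat_strict_threshold for r in self.rhat.values())

    @property
    def geweke_stationary(self) -> bool:
        return all(abs(z) < self.geweke_threshold
                   for zs in self.geweke_z.values() for z in zs)

    def to_rows(self) -> list[dict]:
        rows = []
        for name, r in self.rhat.items():
            row = {"parameter": name, "rhat": r,
                   "rhat_le_1.1": r <= self.rhat_acceptable_threshold,
                   "rhat_le_1.01": r <= self.rhat_strict_threshold}
            for i, z in enumerate(self.geweke_z.get(name, ()), start=1):
                row[f"geweke_z_chain{i}"] = z
            rows.append(row)
        return rows
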