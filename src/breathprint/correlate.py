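"""Rank correlation between sensor responses and liver-function tests.

Hepatocellular failure suppresses sensor responses concordantly, so
responses are expected to correlate negatively with markers that rise in
failure (serum bilirubin, INR) and weakly positively with albumin, which
falls.  The module computes Spearman's rho (average ranks, two-sided p
from the t-approximation with n-2 degrees of freedom) for every
(sensor, temperature) response against each covariate, with
pairwise-complete handling of missing covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bp_core import SENSORS, TEMPERATURES
from .errors import InsufficientPairsError, UndefinedCorrelationError

__all__ = ["SpearmanResult", "spearman", "correlation_table", "DEFAULT_COVARIATES"]

#: Covariate columns correlated by default (liver-function tests).
DEFAULT_COVARIATES: tuple[str, ...] = ("bilirubin_mg_dl", "albumin_g_dl", "inr")

MIN_PAIRS = 4


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation on pairwise-complete observations.

    Pairs with a missing value in either variable are dropped; at least
    4 complete pairs are required.  Rho is Pearson's correlation of the
    average ranks; p is two-sided from the t-approximation.

    Raises
    ------
    InsufficientPairsError
        Fewer than 4 complete pairs.
    UndefinedCorrelationError
        Zero variance in the ranks of either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < MIN_PAIRS:
        raise InsufficientPairsError(
            f"insufficient pairs: {x.size} complete, need >= {MIN_PAIRS}"
        )
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedCorrelationError(
            "rho undefined: zero variance in ranks of a variable"
        )
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p=float(p), n=int(x.size))


def correlation_table(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Sensor-by-covariate Spearman correlation grid.

    One row per (sensor, temperature, covariate) in canonical order with
    columns ``rho``, ``p``, ``n``, ``significant`` (p below ``alpha``,
    mirroring the convention of printing "ns" dashes otherwise) and
    ``reliable`` (False when fewer than 4 pairs support the cell).

    ``bh_correct=True`` applies a Benjamini-Hochberg adjustment across
    all cells before the significance flag; the default leaves p-values
    unadjusted, matching how such grids are conventionally reported.
    """
    rows = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise UndefinedCorrelationError(f"unknown covariate column {cov!r}")
        cov_values = pd.to_numeric(cohort[cov], errors="coerce").to_numpy()
        finite = cov_values[np.isfinite(cov_values)]
        if finite.size >= MIN_PAIRS and np.unique(finite).size < 2:
            raise UndefinedCorrelationError(
                f"covariate {cov!r} is constant across the cohort; rho undefined"
            )
        for t in TEMPERATURES:
            for s in SENSORS:
                col = f"s{s}_t{t}"
                res = spearman(cohort[col].to_numpy(dtype=float), cov_values)
                rows.append(
                    {
                        "sensor": s,
                        "temperature": t,
                        "covariate": cov,
                        "rho": res.rho,
                        "p": res.p,
                        "n": res.n,
                        "reliable": res.n >= MIN_PAIRS,
                    }
                )
    table = pd.DataFrame(rows)
    if bh_correct:
        p = table["p"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, p[i] * m / (rank_pos + 1))
            adj[i] = running
        table["p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return table
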