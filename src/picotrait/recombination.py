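"""Recombination-versus-mutation summary statistics.

ClonalFrame-style inference describes homologous recombination with three
primitives per genomic region: the per-site import initiation rate relative
to mutation (R/theta), the mean import tract length delta (bp), and the
per-site divergence nu of imported DNA.  Two derived quantities summarize
the process:

* rho/theta = 2 (R/theta) — the population recombination rate relative to
  the population mutation rate (rho = 2R);
* r/m = (R/theta) * delta * nu — the relative impact of recombination
  versus mutation on the per-site substitution rate.

This module recomputes the derived columns from the primitives (never
storing them stale), and checks them against the realized event counts of
the forward simulator in :mod:`picotrait.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "RecombinationParams",
    "r_over_m",
    "rho_over_theta",
    "realized_rm_from_log",
    "derived_report",
    "load_prochlorococcus_params",
]


def r_over_m(R_over_theta: float, delta: float, nu: float) -> float:
    """Relative impact of recombination vs mutation: (R/theta) * delta * nu."""
    if R_over_theta < 0 or delta < 0 or nu < 0:
        raise ValueError("inputs must be >= 0")
    return R_over_theta * delta * nu


def rho_over_theta(R_over_theta: float) -> float:
    """Population recombination relative to mutation rate: 2 * (R/theta)."""
    if R_over_theta < 0:
        raise ValueError("input must be >= 0")
    return 2.0 * R_over_theta


@dataclass
class RecombinationParams:
    """Primitive recombination parameters for one genomic region.

    Derived values are recomputed on access, never stored.
    """

    kappa: float
    delta: float
    nu: float
    R_over_theta: float
    region: str = ""

    def __post_init__(self) -> None:
        for name in ("kappa", "delta", "nu", "R_over_theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def rho_over_theta(self) -> float:
        return rho_over_theta(self.R_over_theta)

    @property
    def r_over_m(self) -> float:
        return r_over_m(self.R_over_theta, self.delta, self.nu)


def realized_rm_from_log(event_log: pd.DataFrame) -> float:
    """Realized r/m from a forward-simulation event log.

    Counts substituted sites inside imports over point mutations, across all
    branches.  NaN (flagged undefined) when there are no point mutations.
    """
    mutations = int(
        event_log.loc[event_log["event"] == "mutation", "n_substituted"].sum()
    )
    imported = int(
        event_log.loc[event_log["event"] == "import", "n_substituted"].sum()
    )
    if mutations == 0:
        return float("nan")
    return imported / mutations


def derived_report(
    params: list[RecombinationParams],
    published: Optional[pd.DataFrame] = None,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Recompute rho/theta and r/m per region, optionally checking published
    values.

    ``published`` (indexed by region, columns ``rho_over_theta`` and
    ``r_over_m``) adds percent-deviation columns and a consistency flag; the
    default 5% tolerance absorbs the rounding of 3-significant-figure
    primitives.
    """
    rows = []
    for p in params:
        row = {
            "region": p.region,
            "kappa": p.kappa,
            "delta": p.delta,
            "nu": p.nu,
            "R_over_theta": p.R_over_theta,
            "rho_over_theta": p.rho_over_theta,
            "r_over_m": p.r_over_m,
        }
        if published is not None and p.region in published.index:
            for col in ("rho_over_theta", "r_over_m"):
                pub = float(published.loc[p.region, col])
                dev = abs(row[col] - pub) / pub if pub else float("nan")
                row[f"published_{col}"] = pub
                row[f"{col}_pct_deviation"] = 100.0 * dev
                row[f"{col}_consistent"] = bool(dev <= tolerance)
        rows.append(row)
    return pd.DataFrame(rows)


def load_prochlorococcus_params() -> pd.DataFrame:
    """Published ClonalFrameML parameter estimates for five genomic regions
    spanning the nitrate assimilation gene clusters of high- and low-light
    adapted Prochlorococcus and their core flanking regions."""
    with resources.files("picotrait.data").joinpath(
        "prochlorococcus_recombination.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
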