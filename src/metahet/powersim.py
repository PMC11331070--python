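"""Monte-Carlo power analysis for heterozygosity effects.

Two questions are addressed, per survey year and for all years pooled:

* nest mortality: if overwinter survival follows S = S0*exp(-B*Fh) with
  B haploid lethal equivalents and Fh the heterozygosity-based inbreeding
  of each nest, what is the probability that a logistic regression of
  simulated survival on nest He detects the effect at P <= alpha?
* patch extinction: if extinction probability is logistic in population
  heterozygosity, log odds L = intercept + slope*H (defaults 1.58 - 6.14*H,
  spanning extinction probabilities 0.6 at the lowest observed H down to
  0.25 at the highest), what is the probability of detecting the H effect?

Heterozygosity values are held fixed across replicates; only the binary
outcomes are resampled.  Power is the fraction of ``n_reps`` replicates
with a converged fit and a Wald p-value <= alpha; non-converged or
separated fits count as non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitcore import fit_logistic
from .inbreedload import fh

__all__ = [
    "PowerScenario",
    "PowerResult",
    "power_nest_mortality",
    "power_extinction",
    "power_report",
]


@dataclass(frozen=True)
class PowerScenario:
    kind: str = "nest_mortality"  # or "extinction"
    b: float = 1.0
    s0: float = 0.7
    ext_intercept: float = 1.58
    ext_slope: float = -6.14
    alpha: float = 0.05
    n_reps: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("nest_mortality", "extinction"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class PowerResult:
    scenario: PowerScenario
    stratum: str  # a year label or "all"
    power: float
    n_reps: int
    n_units: int
    n_nonconverged: int = 0


def _power_one_stratum(
    he: np.ndarray,
    prob: np.ndarray,
    scenario: PowerScenario,
    rng: np.random.Generator,
    stratum: str,
) -> PowerResult:
    n = len(he)
    X = np.column_stack([np.ones(n), he])
    n_sig = 0
    n_nc = 0
    for _ in range(scenario.n_reps):
        y = (rng.random(n) < prob).astype(float)
        if y.min() == y.max():  # degenerate outcome, never significant
            n_nc += 1
            continue
        fit = fit_logistic(X, y, terms=["intercept", "he"], max_iter=25, tol=1e-6)
        if not fit.converged:
            n_nc += 1
            continue
        if fit.pvalues[1] <= scenario.alpha:
            n_sig += 1
    return PowerResult(
        scenario=scenario,
        stratum=stratum,
        power=n_sig / scenario.n_reps,
        n_reps=scenario.n_reps,
        n_units=n,
        n_nonconverged=n_nc,
    )


def _strata(het: pd.DataFrame, min_units: int):
    """Yield (label, he-array) per year plus the pooled set, largest last."""
    out = []
    for year, grp in het.groupby("year"):
        if len(grp) < min_units:
            import warnings

            warnings.warn(f"stratum {year} has <{min_units} units; omitted")
            continue
        out.append((str(year), grp["he"].to_numpy(dtype=float)))
    out.append(("all", het["he"].to_numpy(dtype=float)))
    return out


def power_nest_mortality(
    nest_het: pd.DataFrame, scenario: PowerScenario, min_units: int = 10
) -> list[PowerResult]:
    """Power to detect the He-survival association per year and pooled.

    ``nest_het`` needs columns he and year (one row per nest).  Fh is
    computed against the maximum nest He in the whole table; survival
    probabilities are S0*exp(-B*Fh) and outcomes are re-drawn each
    replicate.
    """
    if scenario.kind != "nest_mortality":
        raise ValueError("scenario kind must be nest_mortality")
    h0 = float(nest_het["he"].max())
    ss = np.random.SeedSequence(scenario.seed)
    results = []
    strata = _strata(nest_het, min_units)
    children = ss.spawn(len(strata))
    for (label, he), child in zip(strata, children):
        f = fh(he, h0)
        prob = scenario.s0 * np.exp(-scenario.b * f)
        rng = np.random.default_rng(child)
        results.append(_power_one_stratum(he, prob, scenario, rng, label))
    return results


def power_extinction(
    pop_het: pd.DataFrame, scenario: PowerScenario, min_units: int = 10
) -> list[PowerResult]:
    """Power to detect the He-extinction association per year and pooled."""
    if scenario.kind != "extinction":
        raise ValueError("scenario kind must be extinction")
    ss = np.random.SeedSequence(scenario.seed)
    results = []
    strata = _strata(pop_het, min_units)
    children = ss.spawn(len(strata))
    for (label, he), child in zip(strata, children):
        logit = scenario.ext_intercept + scenario.ext_slope * he
        prob = 1.0 / (1.0 + np.exp(-logit))
        rng = np.random.default_rng(child)
        results.append(_power_one_stratum(he, prob, scenario, rng, label))
    return results


def power_report(results: list[PowerResult]) -> pd.DataFrame:
    """Tabulate power per stratum (one column per scenario label)."""
    if not results:
        raise ValueError("no power results to report")
    rows = []
    for r in results:
        if r.scenario.kind == "nest_mortality":
            label = f"nest_mortality_b{r.scenario.b:g}"
        else:
            label = "extinction"
        rows.append({"stratum": r.stratum, "scenario": label, "power": r.power,
                     "n_units": r.n_units, "n_reps": r.n_reps})
    long = pd.DataFrame(rows)
    table = long.pivot_table(index="stratum", columns="scenario", values="power")
    # order: years ascending then "all"
    idx = sorted([i for i in table.index if i != "all"]) + (
        ["all"] if "all" in table.index else []
    )
    return table.loc[idx]
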