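"""Heterozygosity-based inbreeding and lethal-equivalents estimation.

A nest's inbreeding measure is its proportional heterozygosity deficit
relative to the most heterozygous nest in the metapopulation (assumed
non-inbred):

    Fh = (H0 - H) / H0,        H0 = max observed nest He.

Overwinter survival under inbreeding load follows the classic
exponential model

    S(Fh) = S0 * exp(-B * Fh),

where B is the number of haploid lethal equivalents and S0 the survival of
non-inbred nests.  B is recovered from survival at the Fh extremes:

    B = -ln( S(Fh_max) / S(Fh=0) ) / Fh_max.

Two estimators of the endpoint survivals are provided: ``fitted_logistic``
(default) smooths binary nest outcomes with a logistic regression of
survival on Fh and evaluates it at Fh = 0 and Fh = Fh_max; ``raw_extremes``
uses the empirical survival of the nests at the minimum and maximum
observed Fh (sensible only when several nests share each extreme, or when
``nest_survival`` holds exact probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitcore import fit_logistic

__all__ = ["LoadEstimate", "fh", "survival_under_load", "estimate_b"]


@dataclass
class LoadEstimate:
    """Haploid lethal equivalents B and the endpoint survivals behind it."""

    b_hat: float
    fh_max: float
    s_at_f0: float
    s_at_fmax: float
    method: str
    n_nests: int = 0

    def to_dict(self) -> dict:
        return {
            "b_hat": self.b_hat,
            "fh_max": self.fh_max,
            "s_at_f0": self.s_at_f0,
            "s_at_fmax": self.s_at_fmax,
            "method": self.method,
            "n_nests": self.n_nests,
        }


def fh(h_snp, h_snp_0: float):
    """Proportional heterozygosity deficit relative to the reference H0."""
    h = np.asarray(h_snp, dtype=float)
    if not (0 < h_snp_0 <= 1):
        raise ValueError(f"reference heterozygosity must be in (0, 1], got {h_snp_0}")
    if np.any(h > h_snp_0 + 1e-12):
        raise ValueError("h_snp exceeds the reference; the reference must be the maximum")
    if np.any(h < 0):
        raise ValueError("heterozygosity must be non-negative")
    out = (h_snp_0 - h) / h_snp_0
    return float(out) if np.isscalar(h_snp) else out


def survival_under_load(f, b: float, s0: float):
    """S = S0 * exp(-B * F), clipped to [0, 1]."""
    farr = np.asarray(f, dtype=float)
    if np.any((farr < 0) | (farr > 1)):
        raise ValueError("inbreeding measure must be in [0, 1]")
    if not (0 < s0 <= 1):
        raise ValueError("baseline survival must be in (0, 1]")
    if b < 0:
        raise ValueError("lethal equivalents must be non-negative")
    out = np.clip(s0 * np.exp(-b * farr), 0.0, 1.0)
    return float(out) if np.isscalar(f) else out


def estimate_b(nest_survival, fh_values, method: str = "fitted_logistic") -> LoadEstimate:
    """Estimate haploid lethal equivalents B from nest outcomes.

    ``nest_survival`` may be binary outcomes or exact survival
    probabilities; ``fh_values`` are the matching Fh per nest.
    """
    y = np.asarray(nest_survival, dtype=float)
    f = np.asarray(fh_values, dtype=float)
    if y.shape != f.shape:
        raise ValueError("survival and Fh arrays must have matching shape")
    if len(np.unique(f)) < 2:
        raise ValueError("need at least two distinct Fh values")
    fmax = float(f.max())
    if fmax <= 0:
        raise ValueError("no inbreeding variation (Fh_max = 0)")

    if method == "fitted_logistic":
        X = np.column_stack([np.ones_like(f), f])
        fit = fit_logistic(X, y, terms=["intercept", "fh"])
        b0, b1 = fit.coef
        s0_hat = 1.0 / (1.0 + np.exp(-b0))
        smax_hat = 1.0 / (1.0 + np.exp(-(b0 + b1 * fmax)))
    elif method == "raw_extremes":
        fmin = float(f.min())
        s0_hat = float(y[np.isclose(f, fmin)].mean())
        smax_hat = float(y[np.isclose(f, fmax)].mean())
        if s0_hat <= 0 or smax_hat <= 0:
            raise ValueError(
                "empirical extreme survival is zero; raw_extremes is degenerate here"
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    b_hat = -np.log(smax_hat / s0_hat) / fmax
    return LoadEstimate(
        b_hat=float(b_hat),
        fh_max=fmax,
        s_at_f0=float(s0_hat),
        s_at_fmax=float(smax_hat),
        method=method,
        n_nests=len(y),
    )
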