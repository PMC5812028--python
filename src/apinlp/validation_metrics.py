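"""Criterion validity (agreement, Cohen's kappa, sensitivity/specificity/
PPV/NPV, stratified) and construct validity (2x2 odds ratios and
univariate logistic regression with Wald 95% confidence intervals).

All statistics are returned unrounded; rounding to display precision is
a formatting concern (see :func:`format_or`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .api_classifier import APIResult
from .corpus_model import GoldLabel

__all__ = [
    "Confusion2x2",
    "OddsRatioResult",
    "confusion",
    "kappa_and_indices",
    "stratified_validity",
    "odds_ratio",
    "logistic_or_univariate",
    "construct_validity_table",
    "format_or",
]

Z_95 = 1.96  # normal quantile for two-sided 95% intervals


@dataclass(frozen=True)
class Confusion2x2:
    """Agreement table of predicted vs reference binary status."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def ppv(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> Optional[float]:
        d = self.tn + self.fn
        return self.tn / d if d else None

    @property
    def agreement(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def chance_agreement(self) -> float:
        n = self.n
        return (
            (self.tp + self.fn) * (self.tp + self.fp)
            + (self.tn + self.fp) * (self.tn + self.fn)
        ) / (n * n)

    @property
    def kappa(self) -> Optional[float]:
        """Cohen's kappa; undefined (None) for a degenerate table where
        chance agreement is exactly 1 (one class absent for both raters)."""
        pe = self.chance_agreement
        if pe == 1.0:
            return None
        return (self.agreement - pe) / (1.0 - pe)

    def __add__(self, other: "Confusion2x2") -> "Confusion2x2":
        return Confusion2x2(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class OddsRatioResult:
    """Cross-product odds ratio with Wald 95% CI on the log scale."""

    a: float  # exposed cases
    b: float  # unexposed cases
    c: float  # exposed controls
    d: float  # unexposed controls
    odds_ratio: float
    ci_low: float
    ci_high: float
    se_log: float
    p_value: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to all cells
    method: str = "cross_product_wald"


def confusion(
    pred: Sequence[APIResult], gold: Sequence[GoldLabel]
) -> Confusion2x2:
    """Build the 2x2 agreement table; patient id sets must match exactly."""
    pmap = {r.patient_id: r.status for r in pred}
    gmap = {g.patient_id: g.status for g in gold}
    if set(pmap) != set(gmap):
        only_pred = sorted(set(pmap) - set(gmap))
        only_gold = sorted(set(gmap) - set(pmap))
        raise ValueError(
            f"patient id mismatch: only in predictions {only_pred[:10]}, "
            f"only in gold {only_gold[:10]}"
        )
    tp = fp = fn = tn = 0
    for pid, p in pmap.items():
        g = gmap[pid]
        if p == "positive" and g == "positive":
            tp += 1
        elif p == "positive":
            fp += 1
        elif g == "positive":
            fn += 1
        else:
            tn += 1
    return Confusion2x2(tp, fp, fn, tn)


def kappa_and_indices(c: Confusion2x2) -> dict[str, Optional[float]]:
    """Kappa plus the validity indices, unrounded (proportions in [0,1])."""
    return {
        "kappa": c.kappa,
        "agreement": c.agreement,
        "sensitivity": c.sensitivity,
        "specificity": c.specificity,
        "ppv": c.ppv,
        "npv": c.npv,
    }


def stratified_validity(
    pred: Sequence[APIResult],
    gold: Sequence[GoldLabel],
    strata: Mapping[str, str] | Callable[[str], str],
) -> dict[str, dict]:
    """Per-stratum agreement tables and indices.

    ``strata`` maps patient_id -> stratum label (unknown labels form
    their own stratum).  The per-stratum cells always sum to the pooled
    table (conservation).
    """
    label_of = strata if callable(strata) else lambda pid: strata.get(pid, "unknown")
    gmap = {g.patient_id: g for g in gold}
    groups: dict[str, tuple[list[APIResult], list[GoldLabel]]] = {}
    for r in pred:
        lab = label_of(r.patient_id)
        groups.setdefault(lab, ([], []))
        groups[lab][0].append(r)
        groups[lab][1].append(gmap[r.patient_id])
    out: dict[str, dict] = {}
    for lab in sorted(groups):
        table = confusion(*groups[lab])
        out[lab] = {"confusion": table, **kappa_and_indices(table)}
    return out


def odds_ratio(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Cross-product OR = (a*d)/(b*c) with Wald 95% CI.

    Any zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell) and sets ``corrected``.  A table with two empty rows or
    columns is undefined and raises.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    if 0 in (a + b, c + d, a + c, b + d):
        raise ValueError("odds ratio undefined: empty row or column")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - Z_95 * se)
    ci_high = math.exp(log_or + Z_95 * se)
    z = log_or / se
    p = math.erfc(abs(z) / math.sqrt(2))  # two-sided Wald z-test
    return OddsRatioResult(a, b, c, d, or_, ci_low, ci_high, se, p, corrected)


def logistic_or_univariate(
    outcome: Sequence[int], covariate: Sequence[float]
) -> dict:
    """Univariate logistic regression OR per unit of the covariate.

    Maximum-likelihood Newton fit (tolerance 1e-10, max 100 iterations)
    via statsmodels; the exponentiated slope with its Wald 95% CI.  For a
    binary covariate this equals the closed-form cross-product OR.
    Non-convergence or (quasi-)separation is flagged, never returned as a
    silent value.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcome and covariate must be equal-length 1-d vectors")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    X = sm.add_constant(x)
    model = sm.Logit(y, X)
    converged = True
    try:
        fit = model.fit(method="newton", tol=1e-10, maxiter=100, disp=0)
        converged = bool(fit.mle_retvals.get("converged", True))
        beta = float(fit.params[1])
        se = float(fit.bse[1])
    except Exception:
        converged = False
        beta = float("nan")
        se = float("nan")
    separated = not np.isfinite(se) or se > 50 or not np.isfinite(beta)
    flagged = (not converged) or separated
    return {
        "or_per_unit": math.exp(beta) if np.isfinite(beta) else float("nan"),
        "ci_low": math.exp(beta - Z_95 * se) if not flagged else float("nan"),
        "ci_high": math.exp(beta + Z_95 * se) if not flagged else float("nan"),
        "se_log": se,
        "converged": converged,
        "flagged": flagged,
    }


def _binary_2x2(outcome: np.ndarray, covariate: np.ndarray) -> tuple[int, int, int, int]:
    a = int(np.sum((outcome == 1) & (covariate == 1)))  # exposed cases
    b = int(np.sum((outcome == 1) & (covariate == 0)))  # unexposed cases
    c = int(np.sum((outcome == 0) & (covariate == 1)))  # exposed controls
    d = int(np.sum((outcome == 0) & (covariate == 0)))  # unexposed controls
    return a, b, c, d


def construct_validity_table(
    results: Sequence[APIResult],
    gold: Sequence[GoldLabel],
    covariates: pd.DataFrame,
    covariate_order: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Side-by-side covariate-association table under NLP vs manual labels.

    ``covariates`` is indexed by patient_id with one column per risk
    factor; binary (0/1) columns get the closed-form cross-product OR,
    other numeric columns a univariate logistic OR per unit.  Patients
    with a missing value are excluded per covariate and counted.
    """
    pmap = {r.patient_id: 1 if r.status == "positive" else 0 for r in results}
    gmap = {g.patient_id: 1 if g.status == "positive" else 0 for g in gold}
    ids = [pid for pid in covariates.index if pid in pmap and pid in gmap]
    cols = list(covariate_order) if covariate_order else list(covariates.columns)

    rows = []
    for cov_name in cols:
        series = covariates.loc[ids, cov_name]
        mask = series.notna()
        used = series[mask].astype(float)
        used_ids = list(used.index)
        x = used.to_numpy()
        row: dict = {"covariate": cov_name, "n_missing": int((~mask).sum())}
        for label, lab_map in (("nlp", pmap), ("manual", gmap)):
            y = np.array([lab_map[pid] for pid in used_ids], dtype=float)
            is_binary = set(np.unique(x)) <= {0.0, 1.0}
            try:
                if is_binary:
                    res = odds_ratio(*_binary_2x2(y, x))
                    or_, lo, hi = res.odds_ratio, res.ci_low, res.ci_high
                else:
                    fit = logistic_or_univariate(y, x)
                    or_, lo, hi = fit["or_per_unit"], fit["ci_low"], fit["ci_high"]
            except ValueError:
                or_ = lo = hi = float("nan")
            row[f"or_{label}"] = or_
            row[f"ci_low_{label}"] = lo
            row[f"ci_high_{label}"] = hi
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")


def format_or(res: OddsRatioResult) -> str:
    """Display formatting at one-decimal precision, e.g. '5.8 (2.8, 12.0)'."""
    return f"{res.odds_ratio:.1f} ({res.ci_low:.1f}, {res.ci_high:.1f})"
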