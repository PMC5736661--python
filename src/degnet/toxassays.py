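"""Apical toxicology endpoints.

Log-probit LC estimation on log10 dose, reproduction percent decrease
with ANOVA/Tukey or Welch group tests, ddCt relative expression
normalized to a housekeeping gene (amplification efficiency assumed 2),
total-area normalization of metabolite profiles, and the two-sided
>1.5-fold / p<0.05 metabolite filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import ndtri

from .errors import NonIdentifiableError, SchemaError

logger = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny
# Slope below this (probit units per log10 dose decade) means the dose
# term carries no information and sigma = 1/slope diverges.
_MIN_SLOPE = 1e-6


@dataclass
class ProbitFit:
    """Log10-normal tolerance fit: P(death | dose) = Phi((log10 d - mu) / sigma)."""

    mu: float
    sigma: float
    loglik: float
    warning: str | None = None

    @property
    def lc50(self) -> float:
        return 10.0 ** self.mu


@dataclass
class MetaboliteMatrix:
    """Metabolite x sample concentrations with a sample -> condition design."""

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate metabolite IDs")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate sample IDs")
        if (self.values.to_numpy() < 0).any():
            raise SchemaError("metabolite concentrations must be non-negative")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise SchemaError(f"samples missing from design: {missing}")
        self.design = self.design.loc[self.values.columns]

    def samples_for(self, condition: str) -> list[str]:
        out = [s for s, c in self.design.items() if c == condition]
        if not out:
            raise SchemaError(f"condition {condition!r} absent from design")
        return out


def _check_dose_table(d: pd.DataFrame) -> pd.DataFrame:
    required = {"dose_mg_per_L", "n_exposed", "n_dead"}
    if not required.issubset(d.columns):
        raise SchemaError(f"dose-response table needs columns {sorted(required)}")
    if (d["n_dead"] > d["n_exposed"]).any():
        raise SchemaError("n_dead exceeds n_exposed")
    if (d["n_exposed"] <= 0).any():
        raise SchemaError("n_exposed must be positive")
    if d["dose_mg_per_L"].duplicated().any():
        raise SchemaError("doses must be unique")
    return d[d["dose_mg_per_L"] > 0]


def fit_probit(d: pd.DataFrame) -> ProbitFit:
    """Maximum-likelihood probit fit of binomial mortality on log10 dose.

    Zero-dose rows are excluded (no natural-mortality parameter). The
    binomial GLM with probit link is fit by iteratively reweighted
    least squares to parameter tolerance 1e-8; the intercept/slope
    parameterization (a + b*log10 d) maps to mu = -a/b, sigma = 1/b.
    A flat or decreasing response has no finite sigma and raises
    ``NonIdentifiableError``; a non-monotone but increasing overall
    response is returned with a warning flag.
    """
    pos = _check_dose_table(d).sort_values("dose_mg_per_L")
    if len(pos) < 2:
        raise NonIdentifiableError("need >= 2 positive doses")
    dead = pos["n_dead"].to_numpy(float)
    n = pos["n_exposed"].to_numpy(float)
    partial = (dead > 0) & (dead < n)
    if dead.sum() == 0 or (n - dead).sum() == 0 or not partial.any():
        raise NonIdentifiableError(
            "response is all-or-nothing at every dose; no partial mortality to "
            "anchor the tolerance distribution"
        )
    x = np.log10(pos["dose_mg_per_L"].to_numpy(float))
    endog = np.column_stack([dead, n - dead])
    exog = sm.add_constant(x)
    model = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
    res = model.fit(tol=1e-10, maxiter=200)
    a, b = res.params
    if not np.isfinite([a, b]).all() or b < _MIN_SLOPE:
        raise NonIdentifiableError(
            "fitted mortality does not increase with dose; sigma is unbounded"
        )
    warning = None
    frac = dead / n
    if (np.diff(frac) < 0).any():
        warning = "observed death fractions are non-monotone in dose"
        logger.warning("probit fit: %s", warning)
    return ProbitFit(mu=float(-a / b), sigma=float(1.0 / b), loglik=float(res.llf), warning=warning)


def lc_point(f: ProbitFit, p: float) -> float:
    """Dose lethal to fraction ``p``: LCp = 10^(mu + sigma * Phi^-1(p))."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return float(10.0 ** (f.mu + f.sigma * ndtri(p)))


def _offspring(t: pd.DataFrame, condition: str) -> np.ndarray:
    vals = t.loc[t["condition"] == condition, "offspring"].to_numpy(float)
    if len(vals) == 0:
        raise SchemaError(f"condition {condition!r} absent from reproduction table")
    return vals


def percent_decrease(t: pd.DataFrame, treatment: str, reference: str) -> float:
    """100 * (1 - mean offspring of treatment / mean of reference).

    Negative values indicate an increase relative to the reference.
    """
    ref_mean = _offspring(t, reference).mean()
    if ref_mean == 0:
        raise SchemaError(f"reference condition {reference!r} has zero mean offspring")
    return float(100.0 * (1.0 - _offspring(t, treatment).mean() / ref_mean))


def group_tests(t: pd.DataFrame, mode: str = "anova_tukey") -> dict:
    """Group comparisons of offspring counts.

    ``anova_tukey``: one-way ANOVA omnibus p plus Tukey HSD pairwise
    p-values. ``t_test``: two-tailed Welch t per condition pair. Groups
    with zero variance everywhere and equal means give p = 1.
    Returns {"omnibus_p": float or None, "pairwise": {(a, b): p}}.
    """
    conditions = list(dict.fromkeys(t["condition"]))
    groups = [_offspring(t, c) for c in conditions]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise SchemaError("need >= 2 groups with >= 2 worms each")
    all_equal = all(np.ptp(g) == 0 for g in groups) and np.ptp(
        [g.mean() for g in groups]
    ) == 0
    pairs = [
        (conditions[i], conditions[j])
        for i in range(len(conditions))
        for j in range(i + 1, len(conditions))
    ]
    if mode == "anova_tukey":
        if all_equal:
            return {"omnibus_p": 1.0, "pairwise": {p: 1.0 for p in pairs}}
        with np.errstate(invalid="ignore"):
            omnibus = stats.f_oneway(*groups).pvalue
        omnibus = 1.0 if np.isnan(omnibus) else float(omnibus)
        hsd = stats.tukey_hsd(*groups)
        pairwise = {
            (conditions[i], conditions[j]): float(hsd.pvalue[i, j])
            for i in range(len(conditions))
            for j in range(i + 1, len(conditions))
        }
        return {"omnibus_p": omnibus, "pairwise": pairwise}
    if mode == "t_test":
        pairwise = {}
        for a, b in pairs:
            ga, gb = _offspring(t, a), _offspring(t, b)
            if np.ptp(ga) == 0 and np.ptp(gb) == 0:
                pairwise[(a, b)] = 1.0 if ga.mean() == gb.mean() else _TINY_P
                continue
            pairwise[(a, b)] = float(
                stats.ttest_ind(ga, gb, equal_var=False).pvalue
            )
        return {"omnibus_p": None, "pairwise": pairwise}
    raise SchemaError(f"unknown mode {mode!r}")


def ddct(
    ct: pd.DataFrame, control_condition: str, housekeeping: str = "pmp-3"
) -> pd.DataFrame:
    """Relative expression 2^(-ddCt) per gene and condition, Control = 1 exactly.

    Per replicate, dCt = Ct_gene - Ct_housekeeping; ddCt is the
    difference of condition-mean dCt from the control-mean dCt.
    Amplification efficiency is assumed to be 2 (100%).
    """
    required = {"gene", "condition", "replicate", "ct"}
    if not required.issubset(ct.columns):
        raise SchemaError(f"Ct table needs columns {sorted(required)}")
    hk = ct[ct["gene"] == housekeeping].set_index(["condition", "replicate"])["ct"]
    targets = ct[ct["gene"] != housekeeping]
    pairs = targets.set_index(["condition", "replicate"]).index.unique()
    missing = [key for key in pairs if key not in hk.index]
    if missing:
        raise SchemaError(
            f"housekeeping gene {housekeeping!r} missing for condition/replicate {missing}"
        )
    if control_condition not in set(ct["condition"]):
        raise SchemaError(f"control condition {control_condition!r} absent")
    dct = targets.assign(
        dct=targets["ct"].to_numpy()
        - hk.loc[list(zip(targets["condition"], targets["replicate"]))].to_numpy()
    )
    mean_dct = dct.groupby(["gene", "condition"], sort=True)["dct"].mean().unstack()
    dd = mean_dct.sub(mean_dct[control_condition], axis=0)
    rel = 2.0 ** (-dd)
    rel.columns.name = "condition"
    return rel


def normalize_total_area(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Scale each sample's profile to unit total, preserving proportions."""
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise SchemaError(f"samples with non-positive total area: {list(zero.index)}")
    return MetaboliteMatrix(values=m.values / totals, design=m.design.copy())


def filter_metabolites(
    m: MetaboliteMatrix,
    treatment: str,
    reference: str,
    fc_min: float = 1.5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Retain metabolites with >fc_min fold change (either direction) and Welch p < p_max.

    Both thresholds are strict; direction is ``accumulation`` when the
    treatment mean exceeds the reference and ``depletion`` otherwise.
    Metabolites with a zero reference mean are skipped with a warning.
    Returns columns fold_change, p, direction for the retained set.
    """
    t_cols = m.samples_for(treatment)
    r_cols = m.samples_for(reference)
    if len(t_cols) < 2 or len(r_cols) < 2:
        raise SchemaError("need >= 2 replicates per condition")
    rows = []
    for metab in m.values.index:
        tv = m.values.loc[metab, t_cols].to_numpy(float)
        rv = m.values.loc[metab, r_cols].to_numpy(float)
        if rv.mean() == 0:
            logger.warning("metabolite %r skipped: zero reference mean", metab)
            continue
        fc = tv.mean() / rv.mean()
        if np.ptp(tv) == 0 and np.ptp(rv) == 0:
            p = 1.0 if tv.mean() == rv.mean() else _TINY_P
        else:
            p = float(stats.ttest_ind(tv, rv, equal_var=False).pvalue)
        if (fc > fc_min or fc < 1.0 / fc_min) and p < p_max:
            direction = "accumulation" if fc > 1 else "depletion"
            rows.append((metab, float(fc), p, direction))
    return pd.DataFrame(
        rows, columns=["metabolite", "fold_change", "p", "direction"]
    ).set_index("metabolite")
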