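"""Statistical layer: group contrasts, breakpoint regression, associations.

All analyses operate on a long-format analysis table (a pandas DataFrame)
with one row per subject — or per subject x region for regional analyses —
carrying the outcome, diagnostic ``group`` (gene_negative / carrier / ftd),
``age``, ``site``, ``gene``, ``years_to_expected_onset`` (negative before the
family's expected onset age) and, for regional rows, ``hub_flag``.

Group contrasts fit  outcome ~ group + age  with crossed random intercepts
for scan site and gene, on all three groups (the gene-negative group anchors
the age effect), and test a pairwise contrast with Satterthwaite degrees of
freedom.  The breakpoint model allows both a slope change and a level
discontinuity at the expected-onset knot and tests them jointly.  No
multiple-comparison correction is applied anywhere; network measures are not
independent, and the package reports raw p values (recorded in run metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import (
    LmmFit,
    fit_variance_components,
    satterthwaite_contrast,
    satterthwaite_joint,
)

__all__ = [
    "GROUP_LEVELS",
    "ContrastResult",
    "BreakpointResult",
    "AssociationResult",
    "fit_group_contrast",
    "fit_breakpoint_model",
    "hub_gap_interaction",
    "association_by_group",
]

GROUP_LEVELS = ("gene_negative", "carrier", "ftd")
RANDOM_FACTORS = ("site", "gene")


@dataclass
class ContrastResult:
    contrast: str
    estimate: float
    se: float
    satterthwaite_df: float
    t: float
    p: float
    degenerate: bool = False
    model: str = ""


@dataclass
class BreakpointResult:
    outcome: str
    knot: float
    pre_slope: float
    post_slope: float
    slope_change: float
    level_change: float
    p_breakpoint: float
    term_p: dict = field(default_factory=dict)
    model: str = ""

    def __post_init__(self) -> None:
        assert abs(self.slope_change - (self.post_slope - self.pre_slope)) < 1e-9


@dataclass
class AssociationResult:
    x: str
    y: str
    per_group: dict  # group -> (r, p, n); r is NaN when undefined
    interaction_estimate: float
    interaction_p: float


def _check_table(table: pd.DataFrame, outcome: str) -> None:
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} missing from analysis table")
    if table[outcome].isna().any():
        raise ValueError(f"missing values in outcome {outcome!r}")
    bad = set(table["group"]) - set(GROUP_LEVELS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUP_LEVELS}")


def _design_group_age(table: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Intercept": np.ones(len(table)),
            "group_carrier": (table["group"] == "carrier").astype(float).to_numpy(),
            "group_ftd": (table["group"] == "ftd").astype(float).to_numpy(),
            "age": table["age"].to_numpy(dtype=float),
        }
    )


def _random_factors(table: pd.DataFrame) -> dict:
    return {f: table[f].to_numpy() for f in RANDOM_FACTORS if f in table.columns}


def fit_group_contrast(
    table: pd.DataFrame,
    outcome: str,
    contrast: tuple[str, str] = ("carrier", "ftd"),
) -> ContrastResult:
    """Mixed-model pairwise group contrast with Satterthwaite df.

    Model: outcome ~ group + age + (1|site) + (1|gene), fitted to all three
    groups; the requested pairwise difference (group_a minus group_b) is then
    tested.  A constant outcome is reported as a degenerate zero contrast
    rather than an error.
    """
    _check_table(table, outcome)
    present = set(table["group"])
    if present != set(GROUP_LEVELS):
        raise ValueError(
            f"all three groups must be present to anchor the age effect; got {sorted(present)}"
        )
    a, b = contrast
    if a not in GROUP_LEVELS or b not in GROUP_LEVELS or a == b:
        raise ValueError(f"invalid contrast {contrast!r}")
    label = f"{a}-vs-{b}"
    y = table[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return ContrastResult(label, 0.0, 0.0, np.nan, 0.0, np.nan,
                              degenerate=True, model="constant-outcome")
    X = _design_group_age(table)
    fit = fit_variance_components(y, X, _random_factors(table))
    coef = {"gene_negative": None, "carrier": "group_carrier", "ftd": "group_ftd"}
    c = np.zeros(X.shape[1])
    for g, sign in ((a, 1.0), (b, -1.0)):
        if coef[g] is not None:
            c[X.columns.get_loc(coef[g])] += sign
    est, se, df, t, p = satterthwaite_contrast(fit, c)
    return ContrastResult(label, est, se, df, t, p, model=fit.method)


def _breakpoint_design(t: np.ndarray, knot: float, age: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Intercept": np.ones(len(t)),
            "t": t,
            "hinge": np.where(t > knot, t - knot, 0.0),
            "post": (t > knot).astype(float),
            "age": age,
        }
    )


def fit_breakpoint_model(
    table: pd.DataFrame,
    outcome: str,
    knot: float = 0.0,
    include_gene_negative: bool = False,
) -> BreakpointResult:
    """Discontinuous piecewise regression of an outcome on years to onset.

    Fits  outcome ~ t + (t - knot)_+ + 1{t > knot} + age  (random intercepts
    for site and gene where estimable) on carrier and FTD rows — years to
    expected onset is not meaningful for non-carriers, so the gene-negative
    group is excluded unless explicitly requested.  The headline p value is a
    joint test of the slope-change and level-change terms: the exact F test
    in the OLS path, a 2-df likelihood-ratio test with ML refits otherwise.
    """
    _check_table(table, outcome)
    groups = set(GROUP_LEVELS) if include_gene_negative else {"carrier", "ftd"}
    sub = table[table["group"].isin(groups)].reset_index(drop=True)
    t = sub["years_to_expected_onset"].to_numpy(dtype=float)
    if not ((t <= knot).any() and (t > knot).any()):
        raise ValueError(
            f"years to onset must span both sides of the knot {knot}; "
            f"range observed [{t.min():.2f}, {t.max():.2f}]"
        )
    y = sub[outcome].to_numpy(dtype=float)
    age = sub["age"].to_numpy(dtype=float)
    X_full = _breakpoint_design(t, knot, age)
    factors = _random_factors(sub)

    fit = fit_variance_components(y, X_full, factors)
    pre = float(fit.params["t"])
    schg = float(fit.params["hinge"])
    lchg = float(fit.params["post"])

    term_p = {}
    for term in ("hinge", "post"):
        c = np.zeros(X_full.shape[1])
        c[X_full.columns.get_loc(term)] = 1.0
        term_p[term] = satterthwaite_contrast(fit, c)[4]

    C = np.zeros((2, X_full.shape[1]))
    C[0, X_full.columns.get_loc("hinge")] = 1.0
    C[1, X_full.columns.get_loc("post")] = 1.0
    _, _, _, p_joint = satterthwaite_joint(fit, C)
    model = "ols-F" if fit.method == "ols" else "lmm-waldF"

    return BreakpointResult(
        outcome=outcome,
        knot=knot,
        pre_slope=pre,
        post_slope=pre + schg,
        slope_change=schg,
        level_change=lchg,
        p_breakpoint=p_joint,
        term_p={"slope_change": term_p["hinge"], "level_change": term_p["post"]},
        model=model,
    )


def hub_gap_interaction(
    regional_table: pd.DataFrame,
    groups: tuple[str, str] = ("carrier", "ftd"),
) -> ContrastResult:
    """Does the hub-minus-nonhub gap differ between two groups?

    Under the model  outcome ~ hub_flag * group + age + (1|subject)  the
    within-subject difference of hub-mean minus nonhub-mean outcome is the
    sufficient statistic for the hub x group interaction: differencing
    cancels the subject intercept exactly (and any subject-level site/gene
    intercept with it) and leaves homoscedastic per-subject gaps, so the
    interaction is tested as the group effect in  gap ~ group + age  with
    site/gene random intercepts where estimable.
    """
    if "hub_flag" not in regional_table.columns:
        raise ValueError("regional table lacks a hub_flag column")
    _check_table(regional_table, "outcome")
    if not regional_table["hub_flag"].any():
        raise ValueError(
            "hub set is empty; re-run hub identification (identify_hubs) on the "
            "gene-negative reference strengths before testing the hub gap"
        )
    a, b = groups
    sub = regional_table[regional_table["group"].isin(groups)]
    for g in groups:
        gg = sub[sub["group"] == g]
        if not (gg["hub_flag"].any() and (~gg["hub_flag"]).any()):
            raise ValueError(f"group {g!r} needs both hub and non-hub rows")

    carry = [c for c in ("age", "site", "gene") if c in sub.columns]
    per_subj = (
        sub.groupby(["subject_id", "group", "hub_flag"], as_index=False)
        .agg({"outcome": "mean", **{c: "first" for c in carry}})
        .pivot_table(
            index=["subject_id", "group"] + carry,
            columns="hub_flag",
            values="outcome",
        )
        .reset_index()
    )
    gap = (per_subj[True] - per_subj[False]).to_numpy(dtype=float)
    is_b = (per_subj["group"] == b).astype(float).to_numpy()
    X = pd.DataFrame({"Intercept": np.ones(len(gap)), "hub_x_group": is_b})
    if "age" in per_subj:
        X["age"] = per_subj["age"].to_numpy(dtype=float)
    factors = {f: per_subj[f].to_numpy() for f in RANDOM_FACTORS if f in per_subj.columns}
    fit = fit_variance_components(gap, X, factors)
    c = np.zeros(X.shape[1])
    c[X.columns.get_loc("hub_x_group")] = 1.0
    est, se, df, t, p = satterthwaite_contrast(fit, c)
    return ContrastResult(f"hub-gap:{b}-minus-{a}", est, se, df, t, p, model=fit.method)


def association_by_group(
    table: pd.DataFrame,
    x: str,
    y: str,
    groups: tuple[str, str] = ("carrier", "ftd"),
) -> AssociationResult:
    """Per-group Pearson correlation plus a slope-difference interaction test.

    Pearson r and p are computed within each group; the interaction p comes
    from the OLS model  y ~ x * group + age  on the two groups pooled (age is
    kept as a covariate so that age differences between the groups cannot
    masquerade as an association difference).
    """
    import statsmodels.api as sm

    for col in (x, y):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from analysis table")
    per_group = {}
    for g in groups:
        gg = table[table["group"] == g]
        if len(gg) == 0:
            raise ValueError(f"group {g!r} is empty")
        xv = gg[x].to_numpy(dtype=float)
        yv = gg[y].to_numpy(dtype=float)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0 or len(gg) < 3:
            per_group[g] = (np.nan, np.nan, len(gg))
        else:
            r, p = stats.pearsonr(xv, yv)
            per_group[g] = (float(r), float(p), len(gg))

    a, b = groups
    sub = table[table["group"].isin(groups)]
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    is_b = (sub["group"] == b).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(sub)), xv, is_b, xv * is_b, sub["age"].to_numpy(float)])
    res = sm.OLS(yv, X).fit()
    return AssociationResult(
        x=x,
        y=y,
        per_group=per_group,
        interaction_estimate=float(res.params[3]),
        interaction_p=float(res.pvalues[3]),
    )
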