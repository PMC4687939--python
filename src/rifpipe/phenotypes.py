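"""Fatty-acid composition indices and two-group phenotype comparison.

Fatty acids are named in the field's shorthand ``C<carbons>:<double bonds>``
optionally followed by the omega family (``n-3``, ``n-6``, ``n-7``,
``n-9``), e.g. ``C18:2 n-6`` (linoleic acid).  Percentages are g/100 g of
total fatty acids.  The unsaturation index weights each fatty acid's
percentage by its number of double bonds:

    UI = 1*(% monoenoics) + 2*(% dienoics) + ... + 6*(% hexaenoics)

Group comparisons use ordinary least squares with an optional covariate
(e.g. carcass weight) dropped when itself insignificant at p > 0.05.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_FA_NAME = re.compile(r"^C(\d+):(\d+)(?:\s*n-(\d+))?$")


@dataclass(frozen=True)
class FattyAcidClass:
    saturation: str  # SFA | MUFA | PUFA
    double_bonds: int
    family: str  # n-3 | n-6 | n-7 | n-9 | none


def classify_fatty_acid(name: str) -> FattyAcidClass:
    """Parse a fatty-acid name into saturation class, bonds and family."""
    m = _FA_NAME.match(name.strip())
    if not m:
        raise ValueError(f"unparseable fatty-acid name: {name!r}")
    bonds = int(m.group(2))
    family = f"n-{m.group(3)}" if m.group(3) else "none"
    saturation = "SFA" if bonds == 0 else ("MUFA" if bonds == 1 else "PUFA")
    return FattyAcidClass(saturation=saturation, double_bonds=bonds, family=family)


def summary_indices(percentages: dict[str, float] | pd.Series) -> dict[str, float]:
    """Saturation-class sums, family sums, unsaturation index and ratios.

    Sums cover only the supplied components.  Ratios with a zero
    denominator raise ``ZeroDivisionError``.
    """
    p = pd.Series(percentages, dtype=float)
    if (p < 0).any():
        raise ValueError("percentages must be non-negative")
    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0, "n-3": 0.0, "n-6": 0.0}
    ui = 0.0
    for name, pct in p.items():
        cls = classify_fatty_acid(name)
        sums[cls.saturation] += pct
        if cls.family in ("n-3", "n-6"):
            sums[cls.family] += pct
        ui += min(cls.double_bonds, 6) * pct
    out = {
        "sum_sfa": sums["SFA"],
        "sum_mufa": sums["MUFA"],
        "sum_pufa": sums["PUFA"],
        "sum_n3": sums["n-3"],
        "sum_n6": sums["n-6"],
        "ui": ui,
    }
    out["n6_n3_ratio"] = _ratio(sums["n-6"], sums["n-3"], "n-6/n-3")
    out["mufa_sfa_ratio"] = _ratio(sums["MUFA"], sums["SFA"], "MUFA/SFA")
    return out


def _ratio(num: float, den: float, label: str) -> float:
    # partial profiles legitimately lack whole classes; an undefined ratio
    # is reported as NaN rather than aborting the remaining indices
    return num / den if den > 0 else float("nan")


# ----------------------------------------------------------------------
@dataclass
class GroupComparison:
    means: dict[str, float]  # adjusted group means
    sem: float
    p_value: float
    covariate_used: bool
    covariate_p: float | None = None


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    covariate: pd.Series | None = None,
    covariate_alpha: float = 0.05,
) -> GroupComparison:
    """Two-group linear-model comparison with an optional covariate.

    Fits OLS with a group effect; the covariate is kept only when its own
    p-value is <= ``covariate_alpha`` (otherwise the model is refit
    without it).  Returns adjusted group means, a pooled SEM based on the
    residual mean square and the harmonic mean group size, and the
    two-sided group p-value.
    """
    import statsmodels.api as sm

    values = pd.Series(values, dtype=float)
    groups = pd.Series(groups).reindex(values.index)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("expected exactly two groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals")

    ind = (groups == labels[1]).astype(float).to_numpy()
    x_cols = {"const": np.ones(len(values)), "group": ind}
    cov_p = None
    use_cov = False
    if covariate is not None:
        cov = pd.Series(covariate, dtype=float).reindex(values.index).to_numpy()
        x_full = pd.DataFrame({**x_cols, "covariate": cov})
        if np.linalg.matrix_rank(x_full.to_numpy()) < x_full.shape[1]:
            raise ValueError("singular fit: covariate collinear with the design")
        fit_full = sm.OLS(values.to_numpy(), x_full).fit()
        cov_p = float(fit_full.pvalues["covariate"])
        use_cov = cov_p <= covariate_alpha
        if use_cov:
            fit = fit_full
            x_used = x_full
    if not use_cov:
        x_used = pd.DataFrame(x_cols)
        fit = sm.OLS(values.to_numpy(), x_used).fit()

    beta = fit.params
    # Adjusted means: evaluate at the mean covariate value when retained.
    base = float(beta["const"])
    if use_cov:
        base += float(beta["covariate"]) * float(np.mean(x_used["covariate"]))
    means = {labels[0]: base, labels[1]: base + float(beta["group"])}
    n1, n2 = int((groups == labels[0]).sum()), int((groups == labels[1]).sum())
    n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
    mse = float(fit.mse_resid) if fit.df_resid > 0 else 0.0
    sem = float(np.sqrt(mse / n_harm))
    if fit.df_resid > 0 and mse > 0:
        p = float(fit.pvalues["group"])
    else:  # zero residual variance
        p = 1.0 if np.isclose(beta["group"], 0.0) else 0.0
    return GroupComparison(
        means=means, sem=sem, p_value=p, covariate_used=use_cov, covariate_p=cov_p
    )


def profile_table_summaries(
    profiles: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """Per-group means of per-animal summary indices.

    ``profiles`` holds one row per animal: a group column plus fatty-acid
    percentage columns.  Indices are computed per animal and then averaged
    within group (matching SEM-style reporting of animal-level summaries).
    """
    fa_cols = [c for c in profiles.columns if c != group_col and _FA_NAME.match(c)]
    rows = []
    for _, row in profiles.iterrows():
        idx = summary_indices(row[fa_cols])
        idx[group_col] = row[group_col]
        rows.append(idx)
    return pd.DataFrame(rows).groupby(group_col).mean()
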