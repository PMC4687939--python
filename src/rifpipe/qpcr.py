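"""Efficiency-corrected qPCR relative expression.

Quantification cycles are transformed with the per-gene amplification
efficiency, y = -log2(E^-Cp) = Cp * log2(E), and analysed jointly for
target and reference genes with the linear mixed model

    y_gikr = TG_gi + B_gk + D_ik + e_gikr

(fixed gene x genotype effects, random pig-within-gene effects, random
sample effects common to all genes, residual).  The genotype contrast of a
target, normalised by the reference genes, is

    diff_TG = (TG_t,A - TG_t,B) - mean_ref (TG_r,A - TG_r,B)

with fold change FC = 2^(-diff_TG).  The module also provides a
geNorm-style reference-gene stability statistic M and Lin's concordance
correlation coefficient for cross-platform validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("gene", "animal", "group", "replicate", "cp")


def transform_cp(cp, efficiency):
    """y = -log2(E^-Cp) = Cp * log2(E); requires 1 < E <= 2."""
    e = np.asarray(efficiency, dtype=float)
    if np.any(e <= 1) or np.any(e > 2):
        raise ValueError("efficiency must lie in (1, 2]")
    y = np.asarray(cp, dtype=float) * np.log2(e)
    return y if y.ndim else float(y)


@dataclass
class QpcrDataset:
    """Cp replicates with per-gene efficiencies and target/reference roles.

    ``data`` columns: gene, animal, group, replicate, cp.
    """

    data: pd.DataFrame
    efficiency: pd.Series
    role: pd.Series  # gene -> "target" | "reference"

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
        genes = self.data["gene"].unique()
        self.efficiency = self.efficiency.reindex(genes)
        if self.efficiency.isna().any():
            raise ValueError("every gene needs an amplification efficiency")
        if ((self.efficiency <= 1) | (self.efficiency > 2)).any():
            raise ValueError("efficiencies must lie in (1, 2]")
        self.role = self.role.reindex(genes).fillna("target")
        if self.data["group"].nunique() != 2:
            raise ValueError("expected exactly two groups")

    @property
    def groups(self) -> tuple[str, str]:
        return tuple(sorted(self.data["group"].unique()))

    @property
    def target_genes(self) -> list[str]:
        return list(self.role.index[self.role == "target"])

    @property
    def reference_genes(self) -> list[str]:
        return list(self.role.index[self.role == "reference"])

    def transformed(self, mean_cp: bool = False) -> pd.DataFrame:
        """Records with the y column; optionally Cp pre-averaged per well."""
        df = self.data.copy()
        if mean_cp:
            df = (
                df.groupby(["gene", "animal", "group"], as_index=False)["cp"]
                .mean()
                .assign(replicate=1)
            )
        df["y"] = transform_cp(
            df["cp"].to_numpy(), self.efficiency.loc[df["gene"]].to_numpy()
        )
        return df

    def write(self, cp_csv, efficiency_csv) -> None:
        self.data.to_csv(cp_csv, index=False)
        pd.DataFrame(
            {"gene": self.efficiency.index, "E": self.efficiency.values,
             "role": self.role.values}
        ).to_csv(efficiency_csv, index=False)

    @classmethod
    def read(cls, cp_csv, efficiency_csv) -> "QpcrDataset":
        data = pd.read_csv(cp_csv)
        eff = pd.read_csv(efficiency_csv)
        return cls(
            data=data,
            efficiency=pd.Series(eff["E"].values, index=eff["gene"]),
            role=pd.Series(eff["role"].values, index=eff["gene"]),
        )


# ----------------------------------------------------------------------
@dataclass
class QpcrModelFit:
    """Fixed gene x genotype estimates with covariance and fit metadata."""

    params: pd.Series  # index: (gene, group)
    cov: pd.DataFrame
    n_animals: int
    variance_components: dict[str, float]
    method: str  # "reml" or "ols"
    groups: tuple[str, str]

    def tg(self, gene: str, group: str) -> float:
        return float(self.params[(gene, group)])


def fit_qpcr_model(data: QpcrDataset, mean_cp: bool = False) -> QpcrModelFit:
    """Fit the joint mixed model to the transformed Cp values.

    REML via a variance-components mixed model (random animal intercept =
    sample effect D, per-gene variance component within animal = pig effect
    B).  Replicates enter as repeated measures unless ``mean_cp`` pools
    them first.  Falls back to ordinary least squares on degenerate data
    (zero residual variance or non-convergence), in which case the random
    effects are dropped.
    """
    df = data.transformed(mean_cp=mean_cp)
    counts = df.groupby("gene")["group"].nunique()
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValueError(f"singular design: genes observed in one group: {bad}")
    df = df.sort_values(["gene", "group", "animal", "replicate"]).reset_index(drop=True)
    n_animals = df["animal"].nunique()
    groups = tuple(sorted(df["group"].unique()))

    resid_sd = df.groupby(["gene", "animal"])["y"].std(ddof=1).fillna(0.0)
    degenerate = float(df["y"].var(ddof=1)) < 1e-12 or (
        not mean_cp and float(resid_sd.max()) < 1e-10 and n_animals <= 2
    )

    fit = None
    if not degenerate:
        fit = _fit_mixedlm(df)
    if fit is None:
        fit = _fit_ols(df)
    params, cov, vc, method = fit
    return QpcrModelFit(
        params=params,
        cov=cov,
        n_animals=n_animals,
        variance_components=vc,
        method=method,
        groups=groups,
    )


def _cell_index(df: pd.DataFrame) -> list[tuple[str, str]]:
    return sorted({(g, grp) for g, grp in zip(df["gene"], df["group"])})


def _design_matrix(df: pd.DataFrame, cells) -> np.ndarray:
    pos = {c: j for j, c in enumerate(cells)}
    x = np.zeros((len(df), len(cells)))
    for i, (g, grp) in enumerate(zip(df["gene"], df["group"])):
        x[i, pos[(g, grp)]] = 1.0
    return x


def _fit_mixedlm(df: pd.DataFrame):
    import statsmodels.formula.api as smf

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "y ~ 0 + C(gene):C(group)",
                data=df,
                groups="animal",
                re_formula="1",
                vc_formula={"pig_gene": "0 + C(gene)"},
            )
            res = model.fit(reml=True, method="lbfgs")
        if not np.all(np.isfinite(res.params)) or not np.isfinite(res.scale):
            return None
        if not np.all(np.isfinite(res.cov_params().to_numpy())):
            return None
    except (ValueError, np.linalg.LinAlgError):
        return None

    fe = res.fe_params
    index, keep = [], []
    for name in fe.index:
        # statsmodels labels cells as "C(gene)[g]:C(group)[grp]"
        g = name.split("C(gene)[")[1].split("]")[0]
        grp = name.split("C(group)[")[1].split("]")[0]
        index.append((g, grp))
        keep.append(name)
    params = pd.Series(fe.values, index=pd.MultiIndex.from_tuples(index))
    cov = pd.DataFrame(
        res.cov_params().loc[keep, keep].to_numpy(),
        index=params.index,
        columns=params.index,
    )
    vc = {
        "sample": float(res.cov_re.iloc[0, 0]),
        "pig_gene": float(res.vcomp[0]) if len(res.vcomp) else 0.0,
        "residual": float(res.scale),
    }
    return params, cov, vc, "reml"


def _fit_ols(df: pd.DataFrame):
    cells = _cell_index(df)
    x = _design_matrix(df, cells)
    y = df["y"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = max(len(y) - len(cells), 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    idx = pd.MultiIndex.from_tuples(cells)
    params = pd.Series(beta, index=idx)
    cov = pd.DataFrame(sigma2 * xtx_inv, index=idx, columns=idx)
    vc = {"sample": 0.0, "pig_gene": 0.0, "residual": sigma2}
    return params, cov, vc, "ols"


# ----------------------------------------------------------------------
@dataclass
class QpcrDEResult:
    """Normalised genotype contrast of one target gene."""

    gene: str
    diff_tg: float
    se: float
    t_stat: float
    p_value: float
    fc: float
    df: int

    def __post_init__(self) -> None:
        if not np.isclose(self.fc, 2.0 ** (-self.diff_tg), rtol=1e-12):
            raise ValueError("fc must equal 2^(-diff_tg)")


def estimate_diff_tg(
    fit: QpcrModelFit,
    target: str,
    references,
    contrast: tuple[str, str] | None = None,
) -> QpcrDEResult:
    """Reference-normalised genotype contrast with t-test and fold change.

    The t degrees of freedom follow the containment rule, n_animals - 2.
    """
    references = list(references)
    if not references:
        raise ValueError("need at least one reference gene")
    if target in references:
        raise ValueError("target gene cannot be its own reference")
    ga, gb = contrast if contrast is not None else fit.groups
    c = pd.Series(0.0, index=fit.params.index)
    c[(target, ga)] += 1.0
    c[(target, gb)] -= 1.0
    for r in references:
        c[(r, ga)] -= 1.0 / len(references)
        c[(r, gb)] += 1.0 / len(references)
    diff = float(c @ fit.params)
    var = float(c @ fit.cov @ c)
    if not np.isfinite(var):
        var = 0.0
    se = float(np.sqrt(max(var, 0.0)))
    dof = max(fit.n_animals - 2, 1)
    if se > 0:
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), dof))
    else:  # degenerate noiseless fit
        t = np.inf if diff != 0 else 0.0
        p = 0.0 if diff != 0 else 1.0
    return QpcrDEResult(
        gene=target,
        diff_tg=diff,
        se=se,
        t_stat=t,
        p_value=p,
        fc=float(2.0 ** (-diff)),
        df=dof,
    )


# ----------------------------------------------------------------------
def reference_stability(quantities: pd.DataFrame):
    """geNorm-style stability M and normalisation factors.

    ``quantities`` holds efficiency-corrected relative quantities, genes in
    rows, samples in columns.  M_g is the mean over other genes h of the SD
    across samples of log2(q_g / q_h); lower M = more stable.  Returns
    (M per gene, the two most stable genes, per-sample normalisation factor
    = geometric mean of the selected genes' quantities).
    """
    if quantities.shape[0] < 2:
        raise ValueError("need at least 2 candidate reference genes")
    if (quantities.to_numpy() <= 0).any():
        raise ValueError("quantities must be strictly positive")
    logq = np.log2(quantities.to_numpy(dtype=float))
    genes = list(quantities.index)
    m = np.zeros(len(genes))
    for i in range(len(genes)):
        sds = [
            np.std(logq[i] - logq[j], ddof=1)
            for j in range(len(genes))
            if j != i
        ]
        m[i] = float(np.mean(sds))
    m_series = pd.Series(m, index=genes, name="M")
    selected = list(m_series.nsmallest(2).index)
    nf = pd.Series(
        np.exp2(np.log2(quantities.loc[selected].to_numpy()).mean(axis=0)),
        index=quantities.columns,
        name="normalization_factor",
    )
    return m_series, selected, nf


def concordance_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2 cov(x,y) / (var(x) + var(y) + (mean x - mean y)^2), with 1/n
    moments; penalises both location and scale departures from y = x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: zero variance and equal means")
    return float(2 * cov / denom)
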