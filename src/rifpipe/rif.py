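"""Regulatory Impact Factors (RIF1/RIF2) with a bootstrap null.

For candidate regulator i and the n_de differentially expressed genes j:

    RIF1_i = (1/n_de) * sum_j  a_j * d_j * (r1_ij - r2_ij)^2
    RIF2_i = (1/n_de) * sum_j [ (e1_j * r1_ij)^2 - (e2_j * r2_ij)^2 ]

where e1_j/e2_j are the gene's mean expression in each genotype on the
log2(FPKM + offset) scale, a_j = (e1_j + e2_j)/2, d_j = e2_j - e1_j, and
r1_ij/r2_ij are within-group co-expression correlations between regulator
and gene.  RIF1 is extreme for regulators most differentially co-expressed
with abundant, strongly DE genes; RIF2 for regulators whose ability to
predict DE-gene abundance changes most between genotypes.  Raw scores are
z-standardised over regulators, and significance is judged against
percentile confidence intervals of a bootstrap null in which random
expressed non-regulator gene sets stand in for the DE genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rifpipe.datasets import ExpressionDataset
from rifpipe.expression import DEFAULT_LOG_OFFSET, DEGeneSet

DEFAULT_LEVELS = (95, 99)


# ----------------------------------------------------------------------
@dataclass
class CoexpressionProfile:
    """Within-group regulator x DE-gene correlation matrices.

    Undefined correlations (zero-variance profiles) carry the sentinel 0.
    """

    r1: pd.DataFrame
    r2: pd.DataFrame
    n_samples_per_group: dict[str, int]

    def __post_init__(self) -> None:
        if self.r1.shape != self.r2.shape:
            raise ValueError("r1 and r2 must share dimensions")
        for r in (self.r1, self.r2):
            v = r.to_numpy()
            if np.nanmax(np.abs(v), initial=0.0) > 1 + 1e-9:
                raise ValueError("correlations must lie in [-1, 1]")


def _unit_rows(x: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; zero-variance rows become 0."""
    c = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(norm > 0, c / norm, 0.0)
    return u


def coexpression_correlations(
    expr: ExpressionDataset,
    trf_ids,
    de_ids,
    offset: float = DEFAULT_LOG_OFFSET,
    method: str = "pearson",
) -> CoexpressionProfile:
    """Per-group correlations between each regulator and each DE gene.

    Pearson (default) or Spearman correlation of log2(FPKM + offset),
    computed within each genotype separately; constant profiles give 0.
    """
    trf_ids, de_ids = list(trf_ids), list(de_ids)
    missing = (set(trf_ids) | set(de_ids)) - set(expr.gene_ids)
    if missing:
        raise KeyError(f"gene ids absent from dataset: {sorted(missing)[:5]} ...")
    logf = expr.log_fpkm(offset)
    out = {}
    n_per = {}
    for key, group in zip(("r1", "r2"), expr.groups):
        cols = expr.samples_in(group)
        if len(cols) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 samples")
        n_per[group] = len(cols)
        x = logf.loc[trf_ids, cols].to_numpy(dtype=float)
        y = logf.loc[de_ids, cols].to_numpy(dtype=float)
        if method == "spearman":
            x = stats.rankdata(x, axis=1)
            y = stats.rankdata(y, axis=1)
        elif method != "pearson":
            raise ValueError("method must be 'pearson' or 'spearman'")
        r = np.clip(_unit_rows(x) @ _unit_rows(y).T, -1.0, 1.0)
        out[key] = pd.DataFrame(r, index=trf_ids, columns=de_ids)
    return CoexpressionProfile(out["r1"], out["r2"], n_per)


# ----------------------------------------------------------------------
def _rif_from_arrays(
    a: np.ndarray,
    d: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    rif1 = ((r1 - r2) ** 2 * (a * d)).mean(axis=1)
    rif2 = ((e1 * r1) ** 2 - (e2 * r2) ** 2).mean(axis=1)
    return rif1, rif2


def compute_rif(de: DEGeneSet, co: CoexpressionProfile) -> pd.DataFrame:
    """Raw RIF1/RIF2 per regulator from the DE set and its correlations."""
    if de.n_de == 0:
        raise ValueError("DE gene set is empty")
    genes = de.gene_ids
    if list(co.r1.columns) != genes:
        co = CoexpressionProfile(
            co.r1[genes], co.r2[genes], co.n_samples_per_group
        )
    t = de.table
    rif1, rif2 = _rif_from_arrays(
        t["a"].to_numpy(),
        t["d"].to_numpy(),
        t["e1"].to_numpy(),
        t["e2"].to_numpy(),
        co.r1.to_numpy(),
        co.r2.to_numpy(),
    )
    return pd.DataFrame(
        {"rif1_raw": rif1, "rif2_raw": rif2}, index=co.r1.index.rename("trf")
    )


def standardize(raw) -> pd.Series:
    """z-scores: subtract the mean, divide by the sample (n-1) SD.

    Degenerate input (all values equal) yields all-zero z-scores and a
    warning flag via ``UserWarning``.
    """
    x = pd.Series(raw, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("all raw values identical; z-scores set to 0")
        return pd.Series(0.0, index=x.index)
    return (x - x.mean()) / sd


# ----------------------------------------------------------------------
@dataclass
class BootstrapCI:
    """Percentile confidence bounds of the pooled bootstrap null z-scores."""

    bounds: dict[tuple[str, int], tuple[float, float]]  # (metric, level) -> (lo, hi)
    reps: int
    n_de_drawn: int
    seed: int | None
    levels: tuple[int, ...] = DEFAULT_LEVELS
    pooled_z1: np.ndarray | None = field(default=None, repr=False)
    pooled_z2: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for metric in ("rif1", "rif2"):
            lo95, hi95 = self.bounds[(metric, 95)]
            if lo95 >= hi95:
                raise ValueError("lower bound must lie below upper bound")
            if 99 in self.levels:
                lo99, hi99 = self.bounds[(metric, 99)]
                if not (lo99 <= lo95 and hi99 >= hi95):
                    raise ValueError("99% interval must contain the 95% interval")

    def interval(self, metric: str, level: int) -> tuple[float, float]:
        return self.bounds[(metric, level)]

    def to_dict(self) -> dict:
        return {
            "reps": self.reps,
            "n_de_drawn": self.n_de_drawn,
            "seed": self.seed,
            "intervals": {
                f"{metric}_{level}": list(self.bounds[(metric, level)])
                for metric, level in self.bounds
            },
        }


def bootstrap_null_ci(
    expr: ExpressionDataset,
    expressed_ids,
    trf_ids,
    n_de_drawn: int,
    reps: int = 10000,
    seed: int | None = None,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
    offset: float = DEFAULT_LOG_OFFSET,
    keep_pooled: bool = True,
) -> BootstrapCI:
    """Bootstrap null for RIF z-scores.

    Each repetition draws ``n_de_drawn`` genes uniformly *without*
    replacement from the expressed non-regulator pool, treats them as the
    DE set (recomputing their a, d, e1, e2), computes RIF1/RIF2 z-scores
    of all regulators, and pools the z-scores over regulators and
    repetitions.  Interval bounds are percentiles of the pooled
    distribution (2.5/97.5 at the 95% level, 0.5/99.5 at 99%).
    """
    if reps < 100:
        warnings.warn("fewer than 100 bootstrap repetitions; CIs will be crude")
    trf_ids = list(trf_ids)
    pool = sorted(set(expressed_ids) - set(trf_ids))
    if n_de_drawn > len(pool):
        raise ValueError(
            f"n_de_drawn={n_de_drawn} exceeds the expressed non-TRF pool ({len(pool)})"
        )
    rng = np.random.default_rng(seed)

    logf = expr.log_fpkm(offset)
    ga, gb = expr.groups
    cols_a, cols_b = expr.samples_in(ga), expr.samples_in(gb)
    la = logf.loc[pool, cols_a].to_numpy(dtype=float)
    lb = logf.loc[pool, cols_b].to_numpy(dtype=float)
    e1_all, e2_all = la.mean(axis=1), lb.mean(axis=1)
    a_all = (e1_all + e2_all) / 2.0
    d_all = e2_all - e1_all
    za_pool, zb_pool = _unit_rows(la), _unit_rows(lb)
    za_trf = _unit_rows(logf.loc[trf_ids, cols_a].to_numpy(dtype=float))
    zb_trf = _unit_rows(logf.loc[trf_ids, cols_b].to_numpy(dtype=float))

    n_trf = len(trf_ids)
    z1_pooled = np.empty((reps, n_trf))
    z2_pooled = np.empty((reps, n_trf))
    for rep in range(reps):
        idx = rng.choice(len(pool), size=n_de_drawn, replace=False)
        r1 = za_trf @ za_pool[idx].T
        r2 = zb_trf @ zb_pool[idx].T
        rif1, rif2 = _rif_from_arrays(
            a_all[idx], d_all[idx], e1_all[idx], e2_all[idx], r1, r2
        )
        z1_pooled[rep] = _z(rif1)
        z2_pooled[rep] = _z(rif2)

    z1_flat, z2_flat = z1_pooled.ravel(), z2_pooled.ravel()
    bounds = {}
    for metric, flat in (("rif1", z1_flat), ("rif2", z2_flat)):
        for level in levels:
            tail = (100 - level) / 2.0
            lo, hi = np.percentile(flat, [tail, 100 - tail])
            bounds[(metric, level)] = (float(lo), float(hi))
    return BootstrapCI(
        bounds=bounds,
        reps=reps,
        n_de_drawn=n_de_drawn,
        seed=seed,
        levels=tuple(levels),
        pooled_z1=z1_flat if keep_pooled else None,
        pooled_z2=z2_flat if keep_pooled else None,
    )


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ----------------------------------------------------------------------
@dataclass
class RIFResult:
    """Per-regulator RIF scores, z-scores and CI significance calls.

    ``table`` columns: rif1_raw, rif2_raw, z1, z2, sig95_1, sig99_1,
    sig95_2, sig99_2.
    """

    table: pd.DataFrame
    ci: BootstrapCI | None = None

    def significant(self, metric: str = "rif1", level: int = 95) -> list[str]:
        col = f"sig{level}_{1 if metric == 'rif1' else 2}"
        return list(self.table.index[self.table[col]])

    def write(self, path) -> None:
        self.table.rename_axis("trf").to_csv(path, sep="\t")


def classify_trf(raw: pd.DataFrame, ci: BootstrapCI) -> RIFResult:
    """Attach z-scores and strict outside-the-interval significance flags."""
    z1 = standardize(raw["rif1_raw"])
    z2 = standardize(raw["rif2_raw"])
    table = raw.copy()
    table["z1"], table["z2"] = z1, z2
    for level in ci.levels:
        lo1, hi1 = ci.interval("rif1", level)
        lo2, hi2 = ci.interval("rif2", level)
        table[f"sig{level}_1"] = (z1 < lo1) | (z1 > hi1)
        table[f"sig{level}_2"] = (z2 < lo2) | (z2 > hi2)
    return RIFResult(table=table, ci=ci)
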