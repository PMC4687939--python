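"""FPKM computation, expressed-gene and differential-expression filtering.

The DE caller applies the study's three filters — group-mean FPKM strictly
above 0.5 in at least one group, |signed fold change| >= 1.5, and p <= 0.01
— to per-gene p-values from a negative-binomial exact test.  The test is an
in-repo engine (moderated common + tagwise method-of-moments dispersion on
library-size-normalised counts, conditional two-group exact test on group
sums); it is intentionally edgeR-like in spirit but not numerically
equivalent to edgeR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rifpipe.datasets import ExpressionDataset

DEFAULT_LOG_OFFSET = 0.25
DEFAULT_FC_PSEUDOCOUNT = 1e-3


# ----------------------------------------------------------------------
def compute_fpkm(
    counts: pd.DataFrame,
    gene_length_bp: pd.Series,
    total_mapped: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    fpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * total_mapped[s]).
    When ``total_mapped`` is omitted the per-sample column sums are used,
    which makes ``sum_g fpkm * length_kb == 1e6`` hold per sample.
    """
    lengths = gene_length_bp.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be positive for every gene")
    if total_mapped is None:
        total_mapped = counts.sum(axis=0)
    else:
        total_mapped = pd.Series(total_mapped).reindex(counts.columns)
    if (total_mapped <= 0).any():
        raise ValueError("total mapped reads must be positive for every sample")
    return counts * 1e9 / np.outer(lengths.to_numpy(), total_mapped.to_numpy())


def expressed_gene_set(
    fpkm: pd.DataFrame, design: pd.Series, threshold: float = 0.5
) -> set[str]:
    """Genes whose mean FPKM strictly exceeds ``threshold`` in >= 1 group."""
    groups = pd.unique(design.reindex(fpkm.columns))
    if len(groups) != 2:
        raise ValueError("design must define exactly two groups")
    keep = np.zeros(fpkm.shape[0], dtype=bool)
    for g in groups:
        cols = design.index[design == g]
        keep |= (fpkm[cols].mean(axis=1) > threshold).to_numpy()
    return set(fpkm.index[keep])


def signed_fold_change(mean_a, mean_b, pseudocount: float = DEFAULT_FC_PSEUDOCOUNT):
    """Signed fold change between group means.

    Returns +(mb/ma) when group B is at least as high as group A and
    -(ma/mb) otherwise, after adding ``pseudocount`` to both means.  With
    A = IB, a negative value means higher expression in the purebred
    Iberian group.  Accepts scalars or aligned arrays.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ma = np.asarray(mean_a, dtype=float) + pseudocount
    mb = np.asarray(mean_b, dtype=float) + pseudocount
    fc = np.where(mb >= ma, mb / ma, -(ma / mb))
    return fc if fc.ndim else float(fc)


def _signed_fc_guard_zeros(mean_a, mean_b, pseudocount: float):
    """Signed FC that is exact for positive means; the pseudocount only
    replaces zero means, keeping quoted ratio boundaries (e.g. 1.5) sharp."""
    ma = np.asarray(mean_a, dtype=float)
    mb = np.asarray(mean_b, dtype=float)
    ma = np.where(ma <= 0, pseudocount, ma)
    mb = np.where(mb <= 0, pseudocount, mb)
    return np.where(mb >= ma, mb / ma, -(ma / mb))


def bh_fdr(p_values: pd.Series) -> pd.Series:
    """Benjamini–Hochberg step-up q-values."""
    p = pd.Series(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or p.isna().any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
    return pd.Series(q, index=p.index, name="q_value")


# ----------------------------------------------------------------------
# Negative-binomial exact test
# ----------------------------------------------------------------------
def estimate_dispersions(
    counts: pd.DataFrame,
    design: pd.Series,
    lib_sizes: pd.Series | None = None,
    prior_df: float = 40.0,
) -> pd.Series:
    """Moderated NB dispersions by method of moments.

    Counts are scaled to a common library size.  The common dispersion
    solves the pseudo-likelihood moment equation (mean within-group Pearson
    chi-square per residual degree of freedom equals one), which is far
    less biased than averaging per-gene moment estimates; per-gene
    dispersions are then shrunk toward it with ``prior_df`` pseudo-degrees
    of freedom, mirroring the common+tagwise scheme of count-based DE
    tools.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    scale = lib.mean() / lib
    z = counts.to_numpy(dtype=float) * scale  # normalised counts

    groups = pd.unique(design.reindex(counts.columns))
    masks = []
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    df = 0.0
    for g in groups:
        cols = (design.reindex(counts.columns) == g).to_numpy()
        n = int(cols.sum())
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        masks.append(cols)
        zg = z[:, cols]
        m = zg.mean(axis=1)
        v = zg.var(axis=1, ddof=1)
        # MoM: var = mu + phi mu^2  =>  phi = (v - m) / m^2
        num += v - m
        den += m**2
        df += n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_gene = np.where(den > 0, num / den, 0.0)
    phi_gene = np.clip(phi_gene, 0.0, None)
    phi_common = _common_dispersion_ql(z, masks)
    phi = (prior_df * phi_common + df * phi_gene) / (prior_df + df)
    return pd.Series(np.clip(phi, 1e-6, None), index=counts.index, name="dispersion")


def _common_dispersion_ql(z: np.ndarray, masks: list[np.ndarray]) -> float:
    """Common dispersion from the Pearson chi-square moment equation."""
    from scipy.optimize import brentq

    def mean_chi2(phi: float) -> float:
        s, df = 0.0, 0
        for cols in masks:
            zg = z[:, cols]
            mu = zg.mean(axis=1, keepdims=True)
            ok = mu[:, 0] > 0
            r = (zg[ok] - mu[ok]) ** 2 / (mu[ok] + phi * mu[ok] ** 2)
            s += r.sum()
            df += int(ok.sum()) * (zg.shape[1] - 1)
        return s / max(df, 1)

    if mean_chi2(0.0) <= 1.0:  # under-dispersed relative to Poisson
        return 1e-6
    try:
        return float(brentq(lambda p: mean_chi2(p) - 1.0, 1e-8, 50.0))
    except ValueError:
        return max(float(np.clip(mean_chi2(0.0) - 1.0, 1e-6, 50.0)), 1e-6)


def _nb_conditional_pvalue(
    y1: int, s: int, mu1: float, mu2: float, size1: float, size2: float
) -> float:
    """Two-sided exact p-value for the split of ``s`` into group sums.

    Conditions the NB group sums on their total and sums the probability of
    every outcome no more likely than the observed one (the "double tail"
    convention).  Support is truncated at +-12 conditional SDs; the omitted
    mass is far below double precision.
    """
    if s == 0:
        return 1.0
    # Conditional mean/SD of Y1 given the total, for the support window.
    frac = mu1 / (mu1 + mu2)
    mean1 = s * frac
    var1 = mu1 + mu1**2 / size1
    var2 = mu2 + mu2**2 / size2
    sd = np.sqrt(max(var1 * var2 / (var1 + var2), 1.0))
    lo = max(0, int(np.floor(mean1 - 12 * sd)))
    hi = min(s, int(np.ceil(mean1 + 12 * sd)))
    k = np.arange(lo, hi + 1)
    logp = stats.nbinom.logpmf(k, size1, size1 / (size1 + mu1)) + stats.nbinom.logpmf(
        s - k, size2, size2 / (size2 + mu2)
    )
    logp -= logp.max()
    p = np.exp(logp)
    total = p.sum()
    if y1 < lo or y1 > hi:
        return min(1.0, 2.0 * min(frac, 1 - frac))  # far tail; negligible mass
    obs = p[y1 - lo]
    return float(min(1.0, p[p <= obs * (1 + 1e-10)].sum() / total))


def de_test(
    counts: pd.DataFrame,
    design: pd.Series,
    dispersion: pd.Series | float | None = None,
    lib_sizes: pd.Series | None = None,
) -> pd.Series:
    """Per-gene two-sided p-values from the NB exact test on group sums.

    Under the null of equal relative abundance the group sums Y1, Y2 are
    negative binomial with means proportional to the group library-size
    totals; the observed split of the total is scored against its exact
    conditional distribution.
    """
    design = design.reindex(counts.columns)
    groups = pd.unique(design)
    if len(groups) != 2:
        raise ValueError("design must define exactly two groups")
    for g in groups:
        if (design == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if dispersion is None:
        dispersion = estimate_dispersions(counts, design, lib_sizes)
    if np.isscalar(dispersion):
        dispersion = pd.Series(float(dispersion), index=counts.index)
    phi = np.clip(dispersion.reindex(counts.index).to_numpy(dtype=float), 1e-6, None)

    mask1 = (design == groups[0]).to_numpy()
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    N1, N2 = lib[mask1].sum(), lib[~mask1].sum()
    y1 = counts.to_numpy()[:, mask1].sum(axis=1)
    y2 = counts.to_numpy()[:, ~mask1].sum(axis=1)
    s = y1 + y2
    lam = s / (N1 + N2)  # common relative abundance under H0
    mu1, mu2 = lam * N1, lam * N2
    # Sum of n iid NB(mu, phi) is NB(n mu, phi / n); size = n / phi.
    size1, size2 = n1 / phi, n2 / phi

    p = np.ones(counts.shape[0])
    for i in range(counts.shape[0]):
        if s[i] == 0:
            continue
        p[i] = _nb_conditional_pvalue(
            int(y1[i]), int(s[i]), mu1[i], mu2[i], size1[i], size2[i]
        )
    return pd.Series(p, index=counts.index, name="p_value")


# ----------------------------------------------------------------------
@dataclass
class DEGeneSet:
    """Filtered DE genes with the per-gene quantities the RIF stage needs.

    ``table`` columns: e1, e2 (group mean log2 expression), a = (e1+e2)/2,
    d = e2-e1, fc (signed fold change on the FPKM scale), p, q.
    """

    table: pd.DataFrame
    log_offset: float = DEFAULT_LOG_OFFSET

    def __post_init__(self) -> None:
        required = {"e1", "e2", "a", "d", "fc", "p", "q"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")

    @property
    def n_de(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def write(self, path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "DEGeneSet":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


def de_summary_table(
    expr: ExpressionDataset,
    p_values: pd.Series,
    gene_ids,
    log_offset: float = DEFAULT_LOG_OFFSET,
    fc_pseudocount: float = DEFAULT_FC_PSEUDOCOUNT,
    q_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene e1/e2/a/d/fc/p/q rows for an arbitrary gene subset.

    e1/e2 are group means of log2(FPKM + offset); the signed fold change is
    computed on the linear FPKM group means.
    """
    gene_ids = list(gene_ids)
    ga, gb = expr.groups
    logf = expr.log_fpkm(log_offset)
    e1 = logf.loc[gene_ids, expr.samples_in(ga)].mean(axis=1)
    e2 = logf.loc[gene_ids, expr.samples_in(gb)].mean(axis=1)
    means = expr.group_mean_fpkm().loc[gene_ids]
    fc = _signed_fc_guard_zeros(means[ga], means[gb], fc_pseudocount)
    p = p_values.reindex(gene_ids)
    q = (
        q_values.reindex(gene_ids)
        if q_values is not None
        else bh_fdr(p_values).reindex(gene_ids)
    )
    return pd.DataFrame(
        {
            "e1": e1,
            "e2": e2,
            "a": (e1 + e2) / 2.0,
            "d": e2 - e1,
            "fc": fc,
            "p": p,
            "q": q,
        },
        index=pd.Index(gene_ids, name="gene"),
    )


def filter_de(
    expr: ExpressionDataset,
    p_values: pd.Series,
    min_fpkm: float = 0.5,
    min_abs_fc: float = 1.5,
    max_p: float = 0.01,
    log_offset: float = DEFAULT_LOG_OFFSET,
    fc_pseudocount: float = DEFAULT_FC_PSEUDOCOUNT,
) -> DEGeneSet:
    """Apply the three DE filters and assemble the DE gene set.

    A gene is retained iff its group-mean FPKM is strictly greater than
    ``min_fpkm`` in at least one group, |signed FC| >= ``min_abs_fc``, and
    p <= ``max_p`` (expression strict, FC and p inclusive).
    """
    means = expr.group_mean_fpkm()
    ga, gb = expr.groups
    expressed = (means[ga] > min_fpkm) | (means[gb] > min_fpkm)
    fc = pd.Series(
        _signed_fc_guard_zeros(means[ga], means[gb], fc_pseudocount),
        index=means.index,
    )
    p = p_values.reindex(means.index)
    q = bh_fdr(p_values)
    # inclusive FC boundary with a float guard: the pseudocount nudges an
    # exact ratio (e.g. 3/2 = 1.5) infinitesimally below the threshold
    keep = expressed & (fc.abs() >= min_abs_fc * (1 - 1e-12)) & (p <= max_p)
    genes = list(means.index[keep.fillna(False)])
    table = de_summary_table(
        expr, p_values, genes, log_offset, fc_pseudocount, q_values=q
    )
    return DEGeneSet(table, log_offset=log_offset)
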