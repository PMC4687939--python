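"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the study design — two genotypes x six muscle
samples, negative-binomial RNA-seq counts over 10^3-10^4 genes with a
candidate-regulator (TRF) subset, triplicate qPCR Cp values with pig and
sample random effects, pooled-read variant tables with group-specific
fixation, and per-animal fatty-acid profiles — so the whole pipeline is
testable without any external download.  A single integer seed drives one
root generator; each generator derives its own deterministic sub-stream,
making every output byte-identical for equal seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rifpipe.datasets import ExpressionDataset
from rifpipe.qpcr import QpcrDataset
from rifpipe.variants import TranscriptModel

DEFAULT_GROUPS = ("IB", "IBxDU")


# ----------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Conditions for the synthetic two-genotype expression study.

    Defaults mirror the study design: 6 animals per genetic type, DE fold
    changes spanning the 1.9-12 range reported for the upregulated genes,
    and bulk-RNA-seq-like negative-binomial noise.  ``n_planted_regulators``
    TRFs are given targets among the DE genes whose co-expression exists in
    group A only.
    """

    n_genes: int = 2000
    n_trf: int = 100
    n_planted_regulators: int = 3
    n_de_true: int = 100
    samples_per_group: int = 6
    fc_range: tuple[float, float] = (1.9, 12.0)
    dispersion: float = 0.1
    library_size_mean: int = 500_000
    seed: int = 0
    groups: tuple[str, str] = DEFAULT_GROUPS
    targets_per_regulator: int = 30
    latent_sd: float = 1.2  # log2-scale regulator->target coupling

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_trf, self.samples_per_group) <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_planted_regulators < 0 or self.n_de_true < 0:
            raise ValueError("counts must be non-negative")
        if self.n_planted_regulators > self.n_trf:
            raise ValueError("planted regulators cannot exceed the TRF count")
        if self.n_trf > self.n_genes:
            raise ValueError("TRFs cannot exceed the gene count")
        if self.n_de_true > self.n_genes - self.n_trf:
            raise ValueError("DE genes must fit among the non-TRF genes")
        if self.fc_range[0] <= 1:
            raise ValueError("fc_range lower bound must exceed 1")
        if self.dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion and library size must be positive")


@dataclass
class GroundTruth:
    """What was planted: DE genes, their signed FCs, regulators, targets."""

    de_gene_ids: set[str]
    planted_regulator_ids: set[str]
    true_fc: dict[str, float]
    regulator_targets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reg, targets in self.regulator_targets.items():
            if not targets <= self.de_gene_ids:
                raise ValueError(f"targets of {reg} must be DE genes")


def _fixed_spread(x: np.ndarray, sd: float) -> np.ndarray:
    """Center and rescale a draw to mean 0 and standard deviation ``sd``."""
    c = x - x.mean()
    s = c.std()
    return c / s * sd if s > 0 else c


def _rng_stream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-generator sub-stream of the root seed."""
    import zlib

    key = zlib.crc32(label.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ----------------------------------------------------------------------
def generate_expression_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Negative-binomial count matrix with planted DE genes and regulators.

    Gene means are log-normal; DE genes have group-B mean = group-A mean x
    |FC| (direction by sign); each planted regulator and its targets share
    a per-sample latent factor in group A only, so their within-group
    correlations differ between genotypes (r1 != r2).
    """
    c = config
    rng = _rng_stream(c.seed, "expression")
    n_s = c.samples_per_group

    trf_ids = [f"TF{i + 1:04d}" for i in range(c.n_trf)]
    gene_ids = trf_ids + [f"G{i + 1:05d}" for i in range(c.n_genes - c.n_trf)]
    non_trf = gene_ids[c.n_trf:]

    # Relative abundances, log-normal over genes.
    base = rng.lognormal(mean=1.0, sigma=1.3, size=c.n_genes)

    de_idx = rng.choice(len(non_trf), size=c.n_de_true, replace=False)
    de_ids = [non_trf[i] for i in de_idx]
    lo, hi = c.fc_range
    fc_mag = np.exp(rng.uniform(np.log(lo), np.log(hi), size=c.n_de_true))
    fc_sign = rng.choice([-1.0, 1.0], size=c.n_de_true)
    true_fc = {g: s * m for g, s, m in zip(de_ids, fc_sign, fc_mag)}

    reg_pick = rng.choice(c.n_trf, size=c.n_planted_regulators, replace=False)
    regulators = [trf_ids[i] for i in reg_pick]
    regulator_targets: dict[str, set[str]] = {}
    unused = set(de_ids)
    for reg in regulators:
        # A regulator drives a disjoint block of same-direction targets;
        # mixed directions would cancel in the signed abundance x DE
        # weighting, and shared targets would dilute both regulators.
        sign = rng.choice([-1.0, 1.0])
        pool = sorted(
            (g for g in unused if np.sign(true_fc[g]) == sign) or unused
        )
        k = min(c.targets_per_regulator, len(pool))
        if k == 0:
            regulator_targets[reg] = set()
            continue
        t_idx = rng.choice(len(pool), size=k, replace=False)
        regulator_targets[reg] = {pool[i] for i in t_idx}
        unused -= regulator_targets[reg]

    pos = {g: i for i, g in enumerate(gene_ids)}
    mu_a = np.tile(base[:, None], (1, n_s)).astype(float)
    mu_b = mu_a.copy()
    for g, fc in true_fc.items():
        i = pos[g]
        if fc > 0:  # higher in group B (IBxDU)
            mu_b[i] *= fc
        else:  # higher in group A (IB)
            mu_a[i] *= -fc

    # Latent coupling: regulator and targets share a per-sample factor in
    # group A; in group B the targets' coupling flips sign, so the
    # regulator correlates positively with its targets in one genotype and
    # negatively in the other (r1 != r2 by construction).  The factor is
    # rescaled to its nominal spread so the realised coupling strength
    # does not fluctuate with the small per-group sample count.
    for reg in regulators:
        z_a = _fixed_spread(rng.normal(size=n_s), c.latent_sd)
        z_b = _fixed_spread(rng.normal(size=n_s), c.latent_sd)
        mu_a[pos[reg]] *= 2.0**z_a
        mu_b[pos[reg]] *= 2.0**z_b
        for g in regulator_targets[reg]:
            mu_a[pos[g]] *= 2.0**z_a
            mu_b[pos[g]] *= 2.0**-z_b

    lib = rng.normal(
        c.library_size_mean, 0.05 * c.library_size_mean, size=2 * n_s
    ).clip(min=c.library_size_mean * 0.5)
    sample_ids = [f"{grp}_{k + 1}" for grp in c.groups for k in range(n_s)]
    design = pd.Series(
        [c.groups[0]] * n_s + [c.groups[1]] * n_s, index=sample_ids, name="group"
    )

    mu = np.concatenate([mu_a, mu_b], axis=1)
    mu = mu / mu.sum(axis=0, keepdims=True) * lib[None, :]
    mu = np.clip(mu, 1e-8, None)
    size = 1.0 / c.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    lengths = rng.integers(300, 10001, size=c.n_genes)
    expr = ExpressionDataset(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        gene_length_bp=pd.Series(lengths, index=gene_ids, name="length_bp"),
        design=design,
        is_trf=pd.Series(
            [g in set(trf_ids) for g in gene_ids], index=gene_ids, name="is_trf"
        ),
    )
    truth = GroundTruth(
        de_gene_ids=set(de_ids),
        planted_regulator_ids=set(regulators),
        true_fc=true_fc,
        regulator_targets=regulator_targets,
    )
    return expr, truth


# ----------------------------------------------------------------------
def generate_qpcr_dataset(
    n_targets: int,
    n_reference: int,
    animals_per_group: int,
    replicates: int,
    true_diff: dict[str, float] | None = None,
    efficiencies: dict[str, float] | None = None,
    sigma_pig: float = 0.3,
    sigma_sample: float = 0.2,
    sigma_resid: float = 0.2,
    seed: int = 0,
    groups: tuple[str, str] = DEFAULT_GROUPS,
) -> QpcrDataset:
    """Cp replicates from the generative mixed model.

    y = TG + B + D + e with the stated variances, then Cp = y / log2(E).
    Reference genes have zero genotype contrast; ``true_diff`` maps target
    genes to their normalised genotype contrast on the y scale (group A
    minus group B).
    """
    if min(n_targets, n_reference, animals_per_group, replicates) <= 0:
        raise ValueError("dimensions must be positive")
    if sigma_resid <= 0 and (sigma_pig < 0 or sigma_sample < 0):
        raise ValueError("variances must be non-negative")
    rng = _rng_stream(seed, "qpcr")

    targets = [f"TGT{i + 1}" for i in range(n_targets)]
    refs = [f"REF{i + 1}" for i in range(n_reference)]
    genes = targets + refs
    if true_diff is None:
        true_diff = {g: 0.0 for g in targets}
    eff = dict(efficiencies or {})
    for g in genes:
        eff.setdefault(g, 2.0)
    if any(e <= 1 or e > 2 for e in eff.values()):
        raise ValueError("efficiencies must lie in (1, 2]")

    baseline = {g: rng.uniform(16.0, 26.0) for g in genes}
    ga, gb = groups
    animals = {
        ga: [f"{ga}_a{k + 1}" for k in range(animals_per_group)],
        gb: [f"{gb}_a{k + 1}" for k in range(animals_per_group)],
    }
    b_eff = {
        (g, a): rng.normal(0.0, sigma_pig)
        for g in genes
        for grp in groups
        for a in animals[grp]
    }
    d_eff = {a: rng.normal(0.0, sigma_sample) for grp in groups for a in animals[grp]}

    rows = []
    for g in genes:
        diff = true_diff.get(g, 0.0) if g in targets else 0.0
        for grp in groups:
            tg = baseline[g] + (diff if grp == ga else 0.0)
            for a in animals[grp]:
                for r in range(1, replicates + 1):
                    y = tg + b_eff[(g, a)] + d_eff[a] + rng.normal(0.0, sigma_resid)
                    rows.append(
                        {
                            "gene": g,
                            "animal": a,
                            "group": grp,
                            "replicate": r,
                            "cp": y / np.log2(eff[g]),
                        }
                    )
    data = pd.DataFrame(rows)
    return QpcrDataset(
        data=data,
        efficiency=pd.Series({g: eff[g] for g in genes}),
        role=pd.Series(
            {g: ("target" if g in targets else "reference") for g in genes}
        ),
    )


# ----------------------------------------------------------------------
def generate_toy_gene_models(
    n_transcripts: int = 2,
    contig_length: int = 6000,
    cds_codons: int = 300,
    seed: int = 0,
) -> tuple[dict[str, TranscriptModel], dict[str, str]]:
    """Toy genome and single-exon transcript models (one per contig).

    Transcripts alternate strand; each has a 5'/3' UTR flanking an
    ATG-initiated CDS whose length is a multiple of three with no internal
    stop codons.
    """
    rng = _rng_stream(seed, "gene_models")
    models: dict[str, TranscriptModel] = {}
    genome: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    stop = {"TAA", "TAG", "TGA"}
    codon_pool = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in stop
    ]
    for t in range(n_transcripts):
        chrom = f"contig{t + 1}"
        seq = list(rng.choice(bases, size=contig_length))
        strand = "+" if t % 2 == 0 else "-"
        tx_start, utr5 = 1001, 200
        cds_start = tx_start + utr5
        codons = ["ATG"] + [
            codon_pool[i]
            for i in rng.integers(0, len(codon_pool), size=cds_codons - 2)
        ] + ["TAA"]
        cds_seq = "".join(codons)
        if strand == "-":
            from rifpipe.variants import _revcomp

            cds_seq = _revcomp(cds_seq)
        cds_end = cds_start + len(cds_seq) - 1
        seq[cds_start - 1 : cds_end] = list(cds_seq)
        tx_end = cds_end + 200
        genome[chrom] = "".join(seq)
        tid = f"tx{t + 1}"
        models[tid] = TranscriptModel(
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            exons=[(tx_start, tx_end)],
            cds=[(cds_start, cds_end)],
        )
    return models, genome


def write_gene_models(
    models: dict[str, TranscriptModel],
    genome: dict[str, str],
    gff3_path: str | Path,
    fasta_path: str | Path,
) -> None:
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid, m in models.items():
            s, e = m.span
            gid = f"gene_{tid}"
            fh.write(
                f"{m.chrom}\ttoy\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.chrom}\ttoy\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={gid}\n"
            )
            for xs, xe in m.exons:
                fh.write(
                    f"{m.chrom}\ttoy\texon\t{xs}\t{xe}\t.\t{m.strand}\t.\t"
                    f"Parent={tid}\n"
                )
            for cs, ce in m.cds:
                fh.write(
                    f"{m.chrom}\ttoy\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t0\t"
                    f"Parent={tid}\n"
                )
    with open(fasta_path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ----------------------------------------------------------------------
def generate_variant_dataset(
    n_loci: int,
    p_fixed_group_a: float,
    p_shared: float,
    toy_gene_models: dict[str, TranscriptModel] | None = None,
    genome: dict[str, str] | None = None,
    seed: int = 0,
    p_fixed_group_b: float | None = None,
    cds_fraction: float = 0.5,
    mean_coverage: float = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two per-group variant tables over a shared locus space.

    Fixed loci draw allele frequencies in [0.9, 1]; segregating loci in
    [0.05, 0.9).  ``p_shared`` of loci appear in both groups, the rest are
    split evenly between group-specific loci.  When gene models are given,
    ``cds_fraction`` of loci fall inside their CDS so consequence
    annotation is exercised; ref alleles match the genome at those sites.
    """
    for name, frac in (
        ("p_fixed_group_a", p_fixed_group_a),
        ("p_shared", p_shared),
        ("cds_fraction", cds_fraction),
    ):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if p_fixed_group_b is None:
        p_fixed_group_b = p_fixed_group_a
    if cds_fraction > 0 and toy_gene_models is not None and not toy_gene_models:
        raise ValueError("empty gene model collection with CDS loci requested")
    rng = _rng_stream(seed, "variants")
    bases = "ACGT"

    cds_sites: list[tuple[str, int]] = []
    if toy_gene_models:
        for m in toy_gene_models.values():
            for s, e in m.cds:
                # avoid the start codon and allow room for small indels
                cds_sites.extend((m.chrom, p) for p in range(s + 3, e - 6))
    contigs = sorted({m.chrom for m in (toy_gene_models or {}).values()}) or [
        "contig1"
    ]
    if genome:
        spans = {c: len(genome[c]) for c in contigs}
    else:
        spans = {c: 100_000 for c in contigs}

    # sample locus positions without replacement; the CDS quota is capped
    # by the available CDS interior
    cds_sites = sorted(set(cds_sites))
    n_cds = min(int(round(cds_fraction * n_loci)), len(cds_sites))
    picked = [cds_sites[i] for i in rng.choice(len(cds_sites), n_cds, replace=False)]
    other = [
        (c, p)
        for c in contigs
        for p in range(1, spans[c] - 10)
        if (c, p) not in set(picked)
    ]
    n_other = n_loci - n_cds
    if n_other > len(other):
        raise ValueError("n_loci exceeds the available locus space")
    picked += [other[i] for i in rng.choice(len(other), n_other, replace=False)]

    loci = []
    for chrom, pos in picked:
        ref_base = genome[chrom][pos - 1] if genome else bases[rng.integers(0, 4)]
        kind = rng.choice(
            ["SNV", "MNV", "insertion", "deletion", "replacement"],
            p=[0.65, 0.1, 0.1, 0.1, 0.05],
        )
        if kind == "SNV":
            ref = ref_base
            alt = bases[(bases.index(ref_base) + int(rng.integers(1, 4))) % 4]
        elif kind == "MNV":
            nxt = genome[chrom][pos] if genome else bases[rng.integers(0, 4)]
            ref = ref_base + nxt
            alt = "".join(
                bases[(bases.index(b) + int(rng.integers(1, 4))) % 4] for b in ref
            )
        elif kind == "insertion":
            ref = ref_base
            ins_len = int(rng.choice([3, 1, 2], p=[0.5, 0.25, 0.25]))
            alt = ref + "".join(
                bases[rng.integers(0, 4)] for _ in range(ins_len)
            )
        elif kind == "deletion":
            del_len = int(rng.choice([3, 1, 2], p=[0.5, 0.25, 0.25]))
            if genome:
                ref = genome[chrom][pos - 1 : pos + del_len]
            else:
                ref = ref_base + "".join(
                    bases[rng.integers(0, 4)] for _ in range(del_len)
                )
            alt = ref[0]
        else:  # replacement: neighbouring substitution + length change
            nxt = genome[chrom][pos] if genome else bases[rng.integers(0, 4)]
            ref = ref_base + nxt
            sub = bases[(bases.index(nxt) + int(rng.integers(1, 4))) % 4]
            alt = ref_base + sub + bases[rng.integers(0, 4)]
        loci.append((chrom, pos, ref, alt))

    rows_a, rows_b = [], []
    for chrom, pos, ref, alt in loci:
        u = rng.uniform()
        in_a = in_b = u < p_shared
        if not in_a:
            if rng.uniform() < 0.5:
                in_a = True
            else:
                in_b = True
        for present, rows, p_fixed in (
            (in_a, rows_a, p_fixed_group_a),
            (in_b, rows_b, p_fixed_group_b),
        ):
            if not present:
                continue
            fixed = rng.uniform() < p_fixed
            af = rng.uniform(0.9, 1.0) if fixed else rng.uniform(0.05, 0.9)
            # ~10% low-coverage calls so the coverage filter has work to do
            lam = mean_coverage if rng.uniform() < 0.9 else mean_coverage / 4.0
            cov = int(rng.poisson(lam))
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "coverage": cov,
                    "af": round(float(af), 4),
                }
            )
    cols = list(("chrom", "pos", "ref", "alt", "coverage", "af"))
    return (
        pd.DataFrame(rows_a, columns=cols).sort_values(["chrom", "pos"]).reset_index(drop=True),
        pd.DataFrame(rows_b, columns=cols).sort_values(["chrom", "pos"]).reset_index(drop=True),
    )


# ----------------------------------------------------------------------
def generate_fatty_acid_profiles(
    animals_per_group: int,
    group_means: dict[str, dict[str, float]],
    sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal fatty-acid percentages, renormalised to sum to 100.

    ``group_means`` maps group label -> {fatty acid -> mean percentage}.
    Gaussian noise with standard deviation ``sd`` is added per component
    (clipped at zero) before renormalisation.
    """
    if animals_per_group <= 0:
        raise ValueError("animals_per_group must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = _rng_stream(seed, "fatty_acids")
    rows = []
    for group, means in group_means.items():
        names = list(means)
        mu = np.array([means[n] for n in names], dtype=float)
        if (mu < 0).any():
            raise ValueError("group means must be non-negative")
        for k in range(animals_per_group):
            x = np.clip(mu + rng.normal(0.0, sd, size=len(mu)), 0.0, None)
            x = x / x.sum() * 100.0
            row = {"animal": f"{group}_a{k + 1}", "group": group}
            row.update(dict(zip(names, x)))
            rows.append(row)
    return pd.DataFrame(rows)
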