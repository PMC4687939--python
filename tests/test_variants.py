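import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from rifpipe.simulate import (
    generate_toy_gene_models,
    generate_variant_dataset,
    write_gene_models,
)
from rifpipe.variants import (
    annotate_consequence,
    classify_frequency,
    classify_variant_type,
    compare_groups,
    filter_variants,
    load_gene_models,
    load_genome,
    read_vcf,
    write_vcf,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "coverage", "af"])


# ------------------------------------------------------------ filtering
def test_filter_boundaries():
    """Records with coverage *under* 30 or frequency *under* 5% are
    removed, so the boundary values themselves survive."""
    rows = [
        ("c1", 10, "A", "G", 29, 0.50),   # removed: coverage under 30
        ("c1", 20, "A", "G", 30, 0.05),   # kept: both at boundary
        ("c1", 30, "A", "G", 100, 0.049), # removed: frequency under 5%
        ("c1", 40, "A", "G", 60, 0.60),   # kept
    ]
    out = filter_variants(_records(rows))
    assert list(out["pos"]) == [20, 40]
    with pytest.raises(ValueError):
        filter_variants(_records(rows), min_coverage=-1)


def test_filter_monotone_in_thresholds():
    rng = np.random.default_rng(1)
    rows = [
        ("c1", int(p), "A", "G", int(c), float(a))
        for p, c, a in zip(
            range(1, 301), rng.integers(5, 100, 300), rng.uniform(0, 1, 300)
        )
    ]
    df = _records(rows)
    base = len(filter_variants(df))
    assert len(filter_variants(df, min_coverage=50)) <= base
    assert len(filter_variants(df, min_freq=0.2)) <= base


# ------------------------------------------------- frequency classes
@pytest.mark.parametrize(
    "af,expected",
    [(0.90, "fixed"), (0.899, "segregating"), (1.0, "fixed"), (0.05, "segregating")],
)
def test_fixed_vs_segregating(af, expected):
    assert classify_frequency(af) == expected


# ------------------------------------------------- variant types
@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("A", "G", "SNV"),
        ("AT", "GC", "MNV"),
        ("ACGA", "A", "deletion"),
        ("A", "ACG", "insertion"),
        ("AT", "GCC", "replacement"),
    ],
)
def test_variant_type(ref, alt, expected):
    assert classify_variant_type(ref, alt) == expected


def test_variant_type_rejects_bad_alleles():
    with pytest.raises(ValueError):
        classify_variant_type("", "A")
    with pytest.raises(ValueError):
        classify_variant_type("A", "A")


# ------------------------------------------------- group comparison
def test_compare_groups_toy_enumeration():
    """3-locus toy: (fixed/fixed), (fixed/seg), (absent/seg)."""
    a = _records([("c1", 1, "A", "G", 50, 0.95), ("c1", 2, "C", "T", 50, 0.99)])
    b = _records(
        [
            ("c1", 1, "A", "G", 50, 0.92),
            ("c1", 2, "C", "T", 50, 0.60),
            ("c1", 3, "G", "A", 50, 0.40),
        ]
    )
    res = compare_groups(a, b)
    loci = res.loci.set_index("pos")
    assert list(loci.loc[[1, 2, 3], "flag_fixedA_segB"]) == [False, True, False]
    assert res.summary["categories"] == {"shared": 2, "unique_to_B": 1}
    assert res.summary["fixedA_segB"] == 1
    # differential segregation example: gamma_A=0.95, gamma_B=0.60
    assert loci.loc[2, "class_a"] == "fixed" and loci.loc[2, "class_b"] == "segregating"


def test_compare_groups_additivity_and_duplicates(toy_models):
    models, genome = toy_models
    va, vb = generate_variant_dataset(
        400, 0.5, 0.6, models, genome, seed=13, p_fixed_group_b=0.2
    )
    fa, fb = filter_variants(va), filter_variants(vb)
    res = compare_groups(fa, fb)
    for grp, table in (("IB", fa), ("IBxDU", fb)):
        s = res.summary[grp]
        assert s["fixed"] + s["segregating"] == s["total"] == len(table)
        assert (
            s["SNV"] + s["MNV"] + s["insertion"] + s["deletion"] + s["replacement"]
            == s["total"]
        )
    assert sum(res.summary["categories"].values()) == len(res.loci)
    dup = pd.concat([fa, fa.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        compare_groups(dup, fb)


# ------------------------------------------------- consequences
def _codon_site(model):
    """Genomic position of a codon-aligned CDS triplet on a plus-strand
    single-exon transcript."""
    start = model.cds[0][0]
    return start + 3  # second codon


def test_snv_consequences_against_codon_table(toy_models):
    models, genome = toy_models
    tx = models["tx1"]  # plus strand
    p = _codon_site(tx)
    codon = genome[tx.chrom][p - 1 : p + 2]
    aa = str(Seq(codon).translate())
    # build a synonymous change if one exists in the codon family
    for alt_base in "ACGT":
        if alt_base == codon[2]:
            continue
        alt_codon = codon[:2] + alt_base
        c = annotate_consequence(
            tx.chrom, p + 2, codon[2], alt_base, tx, genome
        )
        expected = (
            "synonymous" if str(Seq(alt_codon).translate()) == aa else "missense"
        )
        assert c.kind == expected


def test_inframe_deletion_reports_lost_residue(toy_models):
    """Deleting one codon-aligned triplet removes exactly one residue —
    the GCA-deletion/alanine pattern."""
    models, genome = toy_models
    tx = models["tx1"]
    p = _codon_site(tx) - 1  # anchor = last base of codon 1
    ref = genome[tx.chrom][p - 1 : p + 3]  # anchor + codon 2
    c = annotate_consequence(tx.chrom, p, ref, ref[0], tx, genome)
    assert c.kind == "inframe_indel"
    lost_codon = genome[tx.chrom][p : p + 3]
    assert c.residues_lost == str(Seq(lost_codon).translate())
    assert c.residues_gained == ""


def test_frameshift_and_utr(toy_models):
    models, genome = toy_models
    tx = models["tx1"]
    p = _codon_site(tx)
    ref = genome[tx.chrom][p - 1 : p + 1]  # 2-bp deletion -> frameshift
    c = annotate_consequence(tx.chrom, p, ref, ref[0], tx, genome)
    assert c.kind == "frameshift"
    utr_pos = tx.exons[0][0] + 5  # inside 5' UTR
    base = genome[tx.chrom][utr_pos - 1]
    alt = "A" if base != "A" else "G"
    c = annotate_consequence(tx.chrom, utr_pos, base, alt, tx, genome)
    assert c.kind == "UTR"
    with pytest.raises(ValueError):
        annotate_consequence(tx.chrom, 10, "A", "G", tx, genome)  # outside


def _oracle_consequence(tx, genome, pos, ref, alt):
    """Independent oracle: apply the edit to the raw chromosome, re-extract
    the (single-exon) CDS with shifted coordinates, translate fully."""
    seq = genome[tx.chrom]
    edited = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    shift = len(alt) - len(ref)
    s, e = tx.cds[0]
    # edits at/after the CDS start shift only the end coordinate
    e2 = e + shift if pos <= e else e
    ref_cds = seq[s - 1 : e]
    alt_cds = edited[s - 1 : e2]
    if tx.strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
    if len(alt_cds) % 3 != 0:
        return "frameshift"
    p_ref = str(Seq(ref_cds).translate())
    p_alt = str(Seq(alt_cds).translate())
    if len(ref_cds) == len(alt_cds):
        return "synonymous" if p_ref == p_alt else "missense"
    return "inframe_indel"


def test_consequences_agree_with_translation_oracle(toy_models):
    """100 random CDS-interior variants, both strands, checked against an
    independent whole-CDS re-extraction and translation oracle."""
    models, genome = toy_models
    rng = np.random.default_rng(99)
    bases = "ACGT"
    checked = 0
    for _ in range(400):
        tx = models["tx1"] if rng.uniform() < 0.5 else models["tx2"]
        s, e = tx.cds[0]
        pos = int(rng.integers(s + 3, e - 6))  # strict CDS interior
        ref_base = genome[tx.chrom][pos - 1]
        kind = rng.choice(["SNV", "MNV", "ins", "del"])
        if kind == "SNV":
            ref = ref_base
            alt = bases[(bases.index(ref_base) + int(rng.integers(1, 4))) % 4]
        elif kind == "MNV":
            ref = genome[tx.chrom][pos - 1 : pos + 1]
            alt = "".join(
                bases[(bases.index(b) + int(rng.integers(1, 4))) % 4] for b in ref
            )
        elif kind == "ins":
            ref = ref_base
            n = int(rng.integers(1, 5))
            alt = ref + "".join(bases[rng.integers(0, 4)] for _ in range(n))
        else:
            n = int(rng.integers(1, 5))
            ref = genome[tx.chrom][pos - 1 : pos + n]
            alt = ref[0]
        got = annotate_consequence(tx.chrom, pos, ref, alt, tx, genome).kind
        want = _oracle_consequence(tx, genome, pos, ref, alt)
        assert got == want, (tx.transcript_id, pos, ref, alt)
        checked += 1
        if checked >= 100:
            break
    assert checked >= 100


# ------------------------------------------------- file round trips
def test_vcf_and_gff_round_trips(toy_models, tmp_path):
    models, genome = toy_models
    va, _ = generate_variant_dataset(100, 0.4, 1.0, models, genome, seed=3)
    contigs = {c: len(s) for c, s in genome.items()}
    write_vcf(va, tmp_path / "a.vcf", contigs)
    back = read_vcf(tmp_path / "a.vcf")
    key = ["chrom", "pos", "ref", "alt"]
    merged = va.merge(back, on=key, suffixes=("", "_rt"))
    assert len(merged) == len(va)
    assert np.allclose(merged["af"], merged["af_rt"], atol=1e-4)
    assert (merged["coverage"] == merged["coverage_rt"]).all()

    write_gene_models(models, genome, tmp_path / "m.gff3", tmp_path / "g.fa")
    m2 = load_gene_models(tmp_path / "m.gff3")
    g2 = load_genome(tmp_path / "g.fa")
    assert g2 == genome
    for tid, m in models.items():
        assert m2[tid].strand == m.strand
        assert m2[tid].cds == m.cds
        assert m2[tid].exons == m.exons
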