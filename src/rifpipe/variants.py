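"""Variant filtering, fixed/segregating classification and consequences.

Per-genotype variant tables (pooled-read calls with coverage and allele
frequency) are filtered (records with coverage under the minimum or allele
frequency under 5% are removed), classified as potentially fixed (allele
frequency >= 90%) or segregating, compared across genotypes on the exact
(chrom, pos, ref, alt) key, typed (SNV/MNV/insertion/deletion/replacement),
and projected onto toy gene models (GFF3 + FASTA) for coding-consequence
annotation with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "coverage", "af")
LOCUS_KEY = ["chrom", "pos", "ref", "alt"]


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def read_vcf(path: str | Path, group: str | None = None) -> pd.DataFrame:
    """Load a VCF 4.2 file into a variant table (INFO DP -> coverage, AF -> af)."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        for alt in v.ALT:
            rows.append(
                {
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": alt,
                    "coverage": int(v.INFO.get("DP", 0)),
                    "af": float(v.INFO.get("AF", 0.0)),
                }
            )
    df = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    if group is not None:
        df["group"] = group
    return df


def write_vcf(df: pd.DataFrame, path: str | Path, contigs: dict[str, int]) -> None:
    """Write a variant table as minimal VCF 4.2 with DP and AF INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in df.sort_values(["chrom", "pos"]).itertuples():
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"DP={int(row.coverage)};AF={row.af:.4f}\n"
            )


def read_variant_tsv(path: str | Path, group: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    if group is not None:
        df["group"] = group
    return df


# ----------------------------------------------------------------------
# Filtering and classification
# ----------------------------------------------------------------------
def filter_variants(
    records: pd.DataFrame, min_coverage: int = 30, min_freq: float = 0.05
) -> pd.DataFrame:
    """Remove records with coverage under ``min_coverage`` or allele
    frequency under ``min_freq`` (strict removals, so boundary values
    survive)."""
    if min_coverage < 0 or min_freq < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (records["coverage"] >= min_coverage) & (records["af"] >= min_freq)
    return records.loc[keep].reset_index(drop=True)


def classify_frequency(af, fixed_threshold: float = 0.90):
    """'fixed' iff allele frequency >= threshold (default 90%), else
    'segregating'.  Accepts a scalar, array, or a record with an ``af``
    field."""
    if isinstance(af, pd.DataFrame):
        af = af["af"]
    a = np.asarray(af, dtype=float)
    out = np.where(a >= fixed_threshold, "fixed", "segregating")
    return out if out.ndim else str(out)


def classify_variant_type(ref: str, alt: str) -> str:
    """SNV / MNV / insertion / deletion / replacement from anchored alleles."""
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    shorter, longer = (ref, alt) if len(ref) < len(alt) else (alt, ref)
    if longer.startswith(shorter):  # shared anchor, pure length change
        return "insertion" if len(alt) > len(ref) else "deletion"
    return "replacement"


# ----------------------------------------------------------------------
# Cross-genotype comparison
# ----------------------------------------------------------------------
@dataclass
class VariantComparison:
    """Per-locus cross-genotype classes plus Table-style summaries.

    ``loci`` columns: the locus key, class_a/class_b (fixed | segregating |
    absent), category (shared | unique_to_A | unique_to_B), and
    flag_fixedA_segB marking differential segregation (fixed in group A,
    segregating in group B).
    """

    loci: pd.DataFrame
    group_a: str
    group_b: str
    summary: dict = field(default_factory=dict)

    def differentially_segregating(self) -> pd.DataFrame:
        return self.loci.loc[self.loci["flag_fixedA_segB"]]


def _summarize_group(table: pd.DataFrame, fixed_threshold: float) -> dict:
    out = {"total": int(len(table))}
    cls = classify_frequency(table["af"].to_numpy(), fixed_threshold)
    out["fixed"] = int((cls == "fixed").sum())
    out["segregating"] = int((cls == "segregating").sum())
    if "region" in table.columns:
        out["utr"] = int((table["region"] == "UTR").sum())
        out["cds"] = int((table["region"] == "CDS").sum())
    if "consequence" in table.columns:
        out["aa_change"] = int(
            table["consequence"].isin(
                ["missense", "inframe_indel", "frameshift"]
            ).sum()
        )
    types = [classify_variant_type(r, a) for r, a in zip(table["ref"], table["alt"])]
    for t in ("SNV", "MNV", "insertion", "deletion", "replacement"):
        out[t] = int(sum(x == t for x in types))
    return out


def compare_groups(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    group_a: str = "IB",
    group_b: str = "IBxDU",
    fixed_threshold: float = 0.90,
) -> VariantComparison:
    """Join two filtered per-group tables on (chrom, pos, ref, alt).

    Classifies each locus in each group, assigns shared/unique categories,
    and flags loci potentially fixed in group A while segregating in
    group B.
    """
    for name, t in ((group_a, table_a), (group_b, table_b)):
        if t.duplicated(LOCUS_KEY).any():
            raise ValueError(f"duplicate locus keys within group {name!r}")
    a = table_a.set_index(LOCUS_KEY)
    b = table_b.set_index(LOCUS_KEY)
    merged = a[["af"]].join(b[["af"]], how="outer", lsuffix="_a", rsuffix="_b")

    def _cls(af):
        if pd.isna(af):
            return "absent"
        return str(classify_frequency(float(af), fixed_threshold))

    loci = merged.reset_index()
    loci["class_a"] = [_cls(v) for v in loci["af_a"]]
    loci["class_b"] = [_cls(v) for v in loci["af_b"]]
    loci["category"] = np.select(
        [loci["class_b"] == "absent", loci["class_a"] == "absent"],
        ["unique_to_A", "unique_to_B"],
        default="shared",
    )
    loci["flag_fixedA_segB"] = (loci["class_a"] == "fixed") & (
        loci["class_b"] == "segregating"
    )
    summary = {
        group_a: _summarize_group(table_a, fixed_threshold),
        group_b: _summarize_group(table_b, fixed_threshold),
        "categories": loci["category"].value_counts().to_dict(),
        "fixedA_segB": int(loci["flag_fixedA_segB"].sum()),
    }
    return VariantComparison(
        loci=loci, group_a=group_a, group_b=group_b, summary=summary
    )


# ----------------------------------------------------------------------
# Gene models and coding consequences
# ----------------------------------------------------------------------
@dataclass
class TranscriptModel:
    """A single transcript: exons and CDS segments on one strand.

    Coordinates are 1-based inclusive (GFF3 convention).  CDS length must
    be divisible by three.
    """

    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        n = sum(e - s + 1 for s, e in self.cds)
        if n % 3 != 0:
            raise ValueError(
                f"CDS length of {self.transcript_id} not divisible by 3"
            )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_positions(self) -> list[int]:
        """Genomic positions of the coding sequence in 5'->3' transcript
        order (descending for minus-strand transcripts)."""
        pos = [p for s, e in self.cds for p in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def region_of(self, pos: int) -> str:
        """CDS, UTR (exonic non-coding), intron, or intergenic."""
        if any(s <= pos <= e for s, e in self.cds):
            return "CDS"
        if any(s <= pos <= e for s, e in self.exons):
            return "UTR"
        if self.contains(pos):
            return "intron"
        return "intergenic"


def load_gene_models(gff3_path: str | Path) -> dict[str, TranscriptModel]:
    """Parse transcript models (mRNA + exon + CDS features) from GFF3."""
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "mRNA":
                meta[attr["ID"]] = (chrom, strand)
            elif ftype in ("exon", "CDS"):
                parent = attr.get("Parent")
                store = exons if ftype == "exon" else cds
                store.setdefault(parent, []).append((int(start), int(end)))
    models = {}
    for tid, (chrom, strand) in meta.items():
        models[tid] = TranscriptModel(
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            exons=exons.get(tid, []),
            cds=cds.get(tid, []),
        )
    return models


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Chromosome id -> uppercase sequence string."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


@dataclass
class Consequence:
    kind: str  # none | UTR | synonymous | missense | inframe_indel | frameshift
    detail: str = ""
    residues_lost: str = ""
    residues_gained: str = ""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _edited_cds(
    transcript: TranscriptModel, genome: dict[str, str], pos: int, ref: str, alt: str
) -> tuple[str, str]:
    """Reference and alternate coding sequences (transcript orientation).

    Handles any allele pair: the shared prefix is trimmed, the remaining
    reference bases mapped onto the CDS are removed, and the remaining
    alternate bases (reverse-complemented on the minus strand) are spliced
    in at the edit point.  Edits entirely outside the CDS leave it
    unchanged.
    """
    chrom_seq = genome[transcript.chrom]
    cds_pos = transcript.cds_positions()  # 5'->3' transcript order
    base = [chrom_seq[p - 1] for p in cds_pos]
    if transcript.strand == "-":
        base = [_revcomp(b) for b in base]
    ref_cds = "".join(base)
    for off, b in enumerate(ref):  # sanity: VCF ref must match the genome
        gpos = pos + off
        if 0 <= gpos - 1 < len(chrom_seq) and chrom_seq[gpos - 1] != b:
            raise ValueError(f"ref allele mismatch at {transcript.chrom}:{gpos}")

    # trim the shared prefix (the VCF anchor and any common leading bases)
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    p0 = pos + k
    ref_rem, alt_rem = ref[k:], alt[k:]
    if not ref_rem and not alt_rem:
        return ref_cds, ref_cds
    removed = {p0 + i for i in range(len(ref_rem))}
    kept = [(p, b) for p, b in zip(cds_pos, base) if p not in removed]
    if len(kept) == len(cds_pos) and not any(
        any(s <= p <= e for s, e in transcript.cds) for p in removed
    ) and not _insertion_inside_cds(transcript, p0, ref_rem):
        return ref_cds, ref_cds  # edit entirely outside the CDS

    if transcript.strand == "+":
        splice = sum(1 for p, _ in kept if p < p0)
        ins = alt_rem
    else:
        splice = sum(1 for p, _ in kept if p >= p0 + len(ref_rem))
        ins = _revcomp(alt_rem) if alt_rem else ""
    bases = [b for _, b in kept]
    return ref_cds, "".join(bases[:splice] + [ins] + bases[splice:])


def _insertion_inside_cds(
    transcript: TranscriptModel, p0: int, ref_rem: str
) -> bool:
    """True when a pure insertion (no reference bases consumed) lands
    strictly inside a CDS segment."""
    if ref_rem:
        return False
    return any(s < p0 <= e for s, e in transcript.cds)


def _diff_residues(p_ref: str, p_alt: str) -> tuple[str, str]:
    """Lost/gained residues after trimming the common prefix and suffix."""
    i = 0
    while i < min(len(p_ref), len(p_alt)) and p_ref[i] == p_alt[i]:
        i += 1
    j = 0
    while (
        j < min(len(p_ref), len(p_alt)) - i
        and p_ref[len(p_ref) - 1 - j] == p_alt[len(p_alt) - 1 - j]
    ):
        j += 1
    return p_ref[i : len(p_ref) - j], p_alt[i : len(p_alt) - j]


def annotate_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    transcript: TranscriptModel,
    genome: dict[str, str],
) -> Consequence:
    """Coding consequence of one variant on one transcript.

    Substitutions are translated codon-by-codon (synonymous/missense);
    indels inside the CDS are in-frame when the length change is a
    multiple of three (reporting lost/gained residues) and frameshift
    otherwise; exonic non-coding positions report UTR.
    """
    if chrom != transcript.chrom:
        raise ValueError("variant and transcript are on different sequences")
    if not transcript.contains(pos):
        raise ValueError(
            f"variant {chrom}:{pos} outside transcript {transcript.transcript_id}"
        )
    ref, alt = ref.upper(), alt.upper()
    ref_cds, alt_cds = _edited_cds(transcript, genome, pos, ref, alt)
    if alt_cds == ref_cds:  # coding sequence untouched
        k = 0
        while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
            k += 1
        affected = [pos + k + i for i in range(max(len(ref) - k, 1))]
        regions = {transcript.region_of(p) for p in affected}
        if "UTR" in regions:
            return Consequence(kind="UTR")
        return Consequence(kind="none", detail="intronic or flanking")

    if len(ref_cds) != len(alt_cds) and (len(ref_cds) - len(alt_cds)) % 3 != 0:
        return Consequence(kind="frameshift")
    p_ref = str(Seq(ref_cds).translate())
    n_alt = len(alt_cds) - len(alt_cds) % 3
    p_alt = str(Seq(alt_cds[:n_alt]).translate())
    if len(ref_cds) == len(alt_cds):
        if p_ref == p_alt:
            return Consequence(kind="synonymous")
        lost, gained = _diff_residues(p_ref, p_alt)
        return Consequence(
            kind="missense",
            detail=f"{lost}->{gained}",
            residues_lost=lost,
            residues_gained=gained,
        )
    lost, gained = _diff_residues(p_ref, p_alt)
    return Consequence(
        kind="inframe_indel",
        detail=f"-[{lost}]+[{gained}]",
        residues_lost=lost,
        residues_gained=gained,
    )
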