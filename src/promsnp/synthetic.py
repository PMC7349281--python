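"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates every artefact the analysis consumes: annotated genomes with
core-promoter motifs planted at fixed offsets from the TSS, GBS-like
contigs cut from the genome in one of four random orientations, an inbred
cohort (default 6 low / 14 high phenotype lines) with homozygous biallelic
SNPs whose quality scores follow a bimodal mixture straddling 400, one
causal promoter SNP placed inside a planted binding-site motif and
segregating with the phenotype (all low lines carry the reference allele;
a configurable number of "exception" high lines do too), and a TRANSFAC
matrix library with near-consensus matrices for the planted motifs plus
decoys.

Everything is deterministic under a fixed seed, and every stochastic choice
is recorded in sidecar tables (contig provenance, motif registry, causal
truth) so tests can verify the pipeline against planted ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import GeneAnnotation, relative_window
from .pwm import PWM
from .sequtils import TRANSFORMS, apply_transform, map_position_back, random_dna, reverse_complement

logger = logging.getLogger(__name__)

#: Default core-promoter elements: a TATA box at -30, a CAAT box at -75 and
#: a GC box at -120 (5' start offsets in no-position-0 relative coordinates).
DEFAULT_PROMOTER_MOTIFS = (
    ("TATAAA", -30, 0.9),
    ("CCAAT", -75, 0.7),
    ("GGGCGG", -120, 0.5),
)

#: Slightly AT-rich plant-like background composition (A, C, G, T).
DEFAULT_BACKGROUND = (0.29, 0.21, 0.21, 0.29)


class SizingError(ValueError):
    """Requested genome geometry cannot accommodate the gene density."""


class ConfigurationError(ValueError):
    """Causal-SNP configuration inconsistent with the planted genome."""


@dataclass
class SyntheticGenomeSpec:
    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_genes: int = 40
    promoter_motifs: Sequence[tuple[str, int, float]] = DEFAULT_PROMOTER_MOTIFS
    background_composition: Sequence[float] = DEFAULT_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        for motif, offset, prob in self.promoter_motifs:
            if not -200 <= offset <= 50 or offset == 0:
                raise ValueError(f"motif offset {offset} outside [-200, +50] (0 excluded)")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("inclusion probability must be in [0, 1]")
            if not motif or set(motif) - set("ACGT"):
                raise ValueError(f"motif {motif!r} must be non-empty ACGT")
        bg = np.asarray(self.background_composition, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
            raise ValueError("background composition must be a probability 4-vector")


@dataclass
class CausalConfig:
    """Where the causal SNP sits and how it segregates.

    ``within_motif_offset`` is the 0-based position of the SNP inside the
    planted motif occurrence; ``exceptions`` is the number of high-phenotype
    lines that nevertheless carry the reference allele (the alternate allele
    never appears in low lines).
    """

    gene_id: str | None = None
    motif: str | None = None
    within_motif_offset: int = 2
    exceptions: int = 1


@dataclass
class SyntheticCohortSpec:
    n_lines: int = 20
    n_low: int = 6
    n_high: int = 14
    n_snps: int = 60
    qual_mixture: tuple[float, float, float, float, float] = (0.636, 200.0, 60.0, 800.0, 120.0)
    """(low-component weight, low mean, low sd, high mean, high sd); the two
    modes straddle the 400 quality threshold."""
    causal_config: CausalConfig = field(default_factory=CausalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low + self.n_high != self.n_lines:
            raise ValueError("n_low + n_high must equal n_lines")
        if self.n_snps < 1:
            raise ValueError("need at least one SNP (the causal one)")
        w = self.qual_mixture[0]
        if not 0.0 <= w <= 1.0:
            raise ValueError("mixture weight must be in [0, 1]")
        if not 0 <= self.causal_config.exceptions <= self.n_high:
            raise ValueError("exception count must be within the high-line count")


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    genes: list[GeneAnnotation]
    motif_registry: pd.DataFrame
    """One row per planted motif occurrence: gene_id, motif, chrom, strand,
    start, end (0-based half-open genomic, identity orientation)."""


def generate_annotated_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Random chromosomes with genes whose promoters carry planted motifs.

    Genes are laid out in evenly spaced slots with jitter; every gene's
    [-200, +50] window (and its downstream/exclusion territory) fits inside
    its chromosome, or a :class:`SizingError` is raised.  Motifs are written
    into the promoter at their stated offset on the gene's strand with their
    stated per-gene inclusion probability.
    """
    rng = np.random.default_rng(spec.seed)
    margin = 1_100  # keeps [-1000, +1000] of every TSS inside the chromosome
    min_spacing = 2_300
    per_chrom = [spec.n_genes // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_genes % spec.n_chromosomes):
        per_chrom[i] += 1
    usable = spec.chrom_length - 2 * margin
    for count in per_chrom:
        if count and usable / count < min_spacing:
            raise SizingError(
                f"chromosome of {spec.chrom_length} bp too short for {count} genes "
                f"(needs >= {count * min_spacing + 2 * margin} bp)"
            )

    chromosomes: dict[str, str] = {}
    genes: list[GeneAnnotation] = []
    registry_rows = []
    gene_no = 0
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = bytearray(random_dna(rng, spec.chrom_length, spec.background_composition), "ascii")
        count = per_chrom[ci]
        slot = usable / count if count else 0
        for gi in range(count):
            gene_no += 1
            jitter = int(rng.integers(0, max(int(slot - min_spacing), 1)))
            tss = margin + int(gi * slot) + jitter + 1  # 1-based
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneAnnotation(f"gene{gene_no:04d}", chrom, strand, tss)
            genes.append(gene)
            for motif, offset, prob in spec.promoter_motifs:
                if rng.random() >= prob:
                    continue
                rel_end = offset + len(motif) - 1
                if offset < 0 <= rel_end:  # relative coords skip 0
                    rel_end += 1
                start0, end0 = relative_window(tss, strand, offset, rel_end)
                planted = motif if strand == "+" else reverse_complement(motif)
                seq[start0:end0] = planted.encode("ascii")
                registry_rows.append(
                    {"gene_id": gene.gene_id, "motif": motif, "chrom": chrom,
                     "strand": strand, "start": start0, "end": end0}
                )
        chromosomes[chrom] = seq.decode("ascii")
    registry = pd.DataFrame(
        registry_rows, columns=["gene_id", "motif", "chrom", "strand", "start", "end"]
    )
    return SyntheticGenome(chromosomes, genes, registry)


def generate_contigs(
    genome: Mapping[str, str],
    n_contigs: int,
    length_range: tuple[int, int] = (400, 800),
    seed: int = 0,
    must_cover: Sequence[tuple[str, int, int]] = (),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Contigs cut from the genome, each in a uniformly chosen orientation.

    Each contig is a substring of a chromosome transformed by one of
    identity / complement / reverse / reverse-complement.  ``must_cover``
    intervals (chrom, start, end; 0-based) are guaranteed to be contained
    in the first contigs, with at least 30 bp of margin, so planted features
    are recoverable.  Provenance (source interval + transform) is returned
    as a sidecar table.
    """
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError("invalid length range")
    max_chrom = max((len(s) for s in genome.values()), default=0)
    if hi > max_chrom:
        raise SizingError(f"contig length up to {hi} exceeds longest chromosome ({max_chrom})")
    if len(must_cover) > n_contigs:
        raise ValueError("more must_cover intervals than contigs")
    rng = np.random.default_rng(seed)
    chrom_names = sorted(genome)
    weights = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    weights /= weights.sum() if weights.sum() else 1.0

    contigs: dict[str, str] = {}
    rows = []

    def add(chrom: str, start: int, length: int) -> None:
        i = len(contigs)
        transform = TRANSFORMS[int(rng.integers(0, 4))]
        sub = genome[chrom][start : start + length]
        contigs[f"contig{i + 1:05d}"] = apply_transform(sub, transform)
        rows.append(
            {"contig_id": f"contig{i + 1:05d}", "chrom": chrom, "start": start,
             "end": start + length, "transform": transform}
        )

    pad = 30
    for chrom, s, e in must_cover:
        span = e - s
        if span + 2 * pad > hi:
            raise SizingError(f"must_cover interval of {span} bp exceeds contig length range")
        length = int(rng.integers(max(lo, span + 2 * pad), hi + 1))
        left_min = max(0, e + pad - length)
        left_max = min(s - pad, len(genome[chrom]) - length)
        if left_max < left_min:
            raise SizingError("cannot place covering contig inside the chromosome")
        start = int(rng.integers(left_min, left_max + 1))
        add(chrom, start, length)

    for _ in range(n_contigs - len(must_cover)):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        add(chrom, start, length)

    provenance = pd.DataFrame(
        rows, columns=["contig_id", "chrom", "start", "end", "transform"]
    )
    return contigs, provenance


@dataclass
class CohortData:
    """Generated cohort: VCF-shaped SNP records, phenotypes, planted truth."""

    snps: pd.DataFrame
    """snp_id, contig, pos (1-based, identity orientation), ref, alt, qual."""
    genotypes: pd.DataFrame  # snp_id x line_id alternate-allele dosage (0/2)
    phenotype: pd.Series  # line_id -> 'low'/'high'
    causal: dict  # snp_id, contig, pos, gene_id, motif, expected consequence


def _sample_qualities(rng: np.random.Generator, n: int, mixture) -> np.ndarray:
    w, mu_lo, sd_lo, mu_hi, sd_hi = mixture
    low = rng.random(n) < w
    q = np.where(
        low,
        rng.normal(mu_lo, sd_lo, size=n),
        rng.normal(mu_hi, sd_hi, size=n),
    )
    return np.clip(q, 1.0, None)  # truncated at zero (scores are positive)


def generate_cohort(
    spec: SyntheticCohortSpec,
    contigs: Mapping[str, str],
    provenance: pd.DataFrame,
    motif_registry: pd.DataFrame,
) -> CohortData:
    """Homozygous biallelic SNPs for an inbred cohort, with one causal SNP.

    The causal SNP is placed inside a planted motif occurrence that is fully
    contained in a contig; its reference allele is the motif-consensus base
    (so the binding site exists only with the reference allele) and its
    genotypes follow the segregation pattern: all low lines homozygous
    reference, ``exceptions`` high lines homozygous reference, the remaining
    high lines homozygous alternate.  Non-causal SNPs segregate
    independently of phenotype; quality scores are drawn from the bimodal
    mixture, except the causal SNP which draws from the high-quality
    component (it must survive the quality filter to be discoverable).
    """
    rng = np.random.default_rng(spec.seed)
    cc = spec.causal_config

    lines = [f"VF{i + 1:02d}" for i in range(spec.n_lines)]
    phenotype = pd.Series(
        ["low"] * spec.n_low + ["high"] * spec.n_high, index=lines, name="phenotype"
    )
    low_lines = lines[: spec.n_low]
    high_lines = lines[spec.n_low :]

    # --- locate the causal site: a motif occurrence inside a contig -------
    reg = motif_registry
    if cc.gene_id is not None:
        reg = reg[reg["gene_id"] == cc.gene_id]
    if cc.motif is not None:
        reg = reg[reg["motif"] == cc.motif]
    causal_row = None
    contig_row = None
    for _, occ in reg.iterrows():
        cover = provenance[
            (provenance["chrom"] == occ["chrom"])
            & (provenance["start"] <= occ["start"] - 25)
            & (provenance["end"] >= occ["end"] + 25)
        ]
        if len(cover):
            causal_row = occ
            contig_row = cover.iloc[0]
            break
    if causal_row is None:
        raise ConfigurationError(
            "causal position is not covered by any planted motif occurrence "
            "inside a contig (with 25 bp flanking margin)"
        )
    if not 0 <= cc.within_motif_offset < causal_row["end"] - causal_row["start"]:
        raise ConfigurationError("within_motif_offset outside the planted motif")

    genomic_pos = int(causal_row["start"]) + cc.within_motif_offset  # 0-based
    contig_id = contig_row["contig_id"]
    contig_seq = contigs[contig_id]
    ident_pos = genomic_pos - int(contig_row["start"])  # identity orientation
    # the contig FASTA stores the transformed sequence; VCF positions refer
    # to the sequence as assembled, i.e. the transformed coordinates
    pos0 = map_position_back(ident_pos, len(contig_seq), contig_row["transform"])
    ref_base = contig_seq[pos0]
    alt_base = str(rng.choice(sorted(set("ACGT") - {ref_base})))

    snp_rows = []
    geno_rows = {}

    causal_id = f"SNP_{contig_id}_{pos0 + 1}"
    exception_lines = list(rng.choice(high_lines, size=cc.exceptions, replace=False))
    causal_geno = {ln: 0 for ln in low_lines}
    causal_geno.update({ln: (0 if ln in exception_lines else 2) for ln in high_lines})
    w, mu_lo, sd_lo, mu_hi, sd_hi = spec.qual_mixture
    causal_qual = float(np.clip(rng.normal(mu_hi, sd_hi), 401.0, None))
    snp_rows.append(
        {"snp_id": causal_id, "contig": contig_id, "pos": pos0 + 1,
         "ref": ref_base, "alt": alt_base, "qual": causal_qual}
    )
    geno_rows[causal_id] = causal_geno

    # --- background SNPs ---------------------------------------------------
    contig_ids = sorted(contigs)
    lengths = np.array([len(contigs[c]) for c in contig_ids], dtype=float)
    probs = lengths / lengths.sum()
    quals = _sample_qualities(rng, spec.n_snps - 1, spec.qual_mixture)
    made = 0
    used_positions = {(contig_id, pos0)}
    while made < spec.n_snps - 1:
        cid = contig_ids[int(rng.choice(len(contig_ids), p=probs))]
        p = int(rng.integers(0, len(contigs[cid])))
        if (cid, p) in used_positions:
            continue
        used_positions.add((cid, p))
        ref = contigs[cid][p]
        if ref not in "ACGT":
            continue
        alt = str(rng.choice(sorted(set("ACGT") - {ref})))
        maf = rng.uniform(0.05, 0.5)
        geno = {ln: (2 if rng.random() < maf else 0) for ln in lines}
        snp_id = f"SNP_{cid}_{p + 1}"
        snp_rows.append(
            {"snp_id": snp_id, "contig": cid, "pos": p + 1,
             "ref": ref, "alt": alt, "qual": float(quals[made])}
        )
        geno_rows[snp_id] = geno
        made += 1

    snps = pd.DataFrame(snp_rows).set_index("snp_id", drop=False)
    genotypes = pd.DataFrame.from_dict(geno_rows, orient="index")[lines]
    genotypes.index.name = "snp_id"
    causal = {
        "snp_id": causal_id,
        "contig": contig_id,
        "pos": pos0 + 1,
        "gene_id": causal_row["gene_id"],
        "motif": causal_row["motif"],
        "genomic_chrom": causal_row["chrom"],
        "genomic_pos": genomic_pos,
        "ref": ref_base,
        "alt": alt_base,
        "expected_consequence": "loss",
        "exception_lines": exception_lines,
    }
    return CohortData(snps=snps, genotypes=genotypes, phenotype=phenotype, causal=causal)


def generate_pwm_library(
    motifs: Sequence[str],
    pseudocount: float = 0.0,
    n_decoys: int = 5,
    seed: int = 0,
    n_sites: int = 100,
) -> list[PWM]:
    """Near-consensus matrices for the planted motifs, plus random decoys.

    Each planted matrix is built from ``n_sites`` hypothetical sites of
    which 97% carry the consensus base at every position, so the argmax
    column spells the motif.  Decoys are matrices of random consensus
    sequences (length 6-10) with the same construction.
    """
    rng = np.random.default_rng(seed)

    def near_consensus(name: str, consensus: str) -> PWM:
        counts = np.ones((len(consensus), 4)) * (n_sites * 0.01)
        for i, b in enumerate(consensus):
            counts[i] = n_sites * 0.01
            counts[i, "ACGT".index(b)] = n_sites * 0.97
        return PWM(name=name, counts=counts, pseudocount=pseudocount)

    pwms = [near_consensus(f"P${m}_01", m) for m in motifs]
    for k in range(n_decoys):
        length = int(rng.integers(6, 11))
        cons = "".join(rng.choice(list("ACGT"), size=length))
        pwms.append(near_consensus(f"P$DECOY{k + 1}_01", cons))
    return pwms


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_vcf(cohort: CohortData, contigs: Mapping[str, str], path: str | Path) -> None:
    """VCF v4.2 with contig header lines, QUAL scores and GT genotypes."""
    lines = ["##fileformat=VCFv4.2", "##source=promsnp-synthetic"]
    for cid in sorted(contigs):
        lines.append(f"##contig=<ID={cid},length={len(contigs[cid])}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = list(cohort.genotypes.columns)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    order = cohort.snps.sort_values(["contig", "pos"]).index
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for snp_id in order:
        row = cohort.snps.loc[snp_id]
        gts = [gt_map[int(cohort.genotypes.loc[snp_id, s])] for s in samples]
        lines.append(
            f"{row['contig']}\t{row['pos']}\t{snp_id}\t{row['ref']}\t{row['alt']}"
            f"\t{row['qual']:.1f}\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_phenotype(phenotype: pd.Series, path: str | Path) -> None:
    phenotype.rename_axis("line_id").reset_index().to_csv(str(path), sep="\t", index=False)


def write_provenance(provenance: pd.DataFrame, path: str | Path) -> None:
    provenance.to_csv(str(path), sep="\t", index=False)
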