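"""Labeled promoter / non-promoter training sets from a genome + annotation.

Window conventions
------------------
Relative coordinates around a transcription start site (TSS) have no
position 0: they run ..., -2, -1, +1, +2, ... with the TSS base itself at
+1.  The core promoter window [-200, +50] therefore contains exactly 250
bases (200 upstream + the TSS + 49 downstream), the length the classifier
consumes.  Downstream non-promoter windows cover [+751, +1000]; random
genomic non-promoters avoid the zone [TSS-1000, TSS+500] of every gene.
All windows are strand-aware: minus-strand windows are reverse-complemented
so the returned sequence reads 5'->3' on the gene's strand.

Internally all coordinates are 0-based half-open; GFF3 I/O (1-based
inclusive) converts at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtils import one_hot, decode_one_hot, reverse_complement

logger = logging.getLogger(__name__)

PROMOTER_WINDOW = (-200, 50)
DOWNSTREAM_WINDOW = (751, 1000)
EXCLUSION_ZONE = (-1000, 500)
WINDOW_LENGTH = 250

LABELS = ("promoter", "non_promoter")
SOURCES = ("core_promoter", "downstream_gene", "random_genomic", "transcriptome")


class CapacityError(RuntimeError):
    """Not enough eligible genomic territory to draw the requested windows."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to what promoter extraction needs: its TSS and strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based genomic coordinate of the first transcribed base
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError("tss must be a positive 1-based coordinate")


@dataclass(frozen=True)
class LabeledSequence:
    id: str
    seq: str
    label: str
    source: str
    species_tag: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")


def relative_window(tss: int, strand: str, rel_start: int, rel_end: int) -> tuple[int, int]:
    """Genomic 0-based half-open interval for relative positions [rel_start, rel_end].

    Relative coordinates skip 0 (the TSS is +1).  On the minus strand the
    interval is mirrored; the caller reverse-complements the slice.
    """
    if rel_start == 0 or rel_end == 0 or rel_start > rel_end:
        raise ValueError("relative bounds must be non-zero and ordered")

    def to_genomic_plus(r: int) -> int:  # 1-based
        return tss + r if r < 0 else tss + r - 1

    if strand == "+":
        first, last = to_genomic_plus(rel_start), to_genomic_plus(rel_end)
    else:
        # mirror: relative +k maps to tss-(k-1), relative -k maps to tss+k
        first = tss - rel_end + 1 if rel_end > 0 else tss - rel_end
        last = tss - rel_start if rel_start < 0 else tss - rel_start + 1
    return first - 1, last  # 0-based half-open


def window_length(rel_start: int = PROMOTER_WINDOW[0], rel_end: int = PROMOTER_WINDOW[1]) -> int:
    """Number of bases in a relative window under the no-position-0 convention."""
    s, e = relative_window(1000, "+", rel_start, rel_end)
    return e - s


def _extract_windows(
    genome: Mapping[str, str],
    annotations: Iterable[GeneAnnotation],
    rel: tuple[int, int],
    label: str,
    source: str,
    species_tag: str,
) -> list[LabeledSequence]:
    out: list[LabeledSequence] = []
    seen: set[tuple[str, int, str]] = set()
    n_dropped = 0
    for gene in annotations:
        chrom_seq = genome.get(gene.chrom)
        if chrom_seq is None:
            n_dropped += 1
            logger.info("gene %s: chromosome %s absent, dropped", gene.gene_id, gene.chrom)
            continue
        start, end = relative_window(gene.tss, gene.strand, *rel)
        if start < 0 or end > len(chrom_seq):
            n_dropped += 1
            logger.info("gene %s: window [%d,%d) exits chromosome, dropped", gene.gene_id, start, end)
            continue
        key = (gene.chrom, start, gene.strand)
        if key in seen:  # genes sharing a TSS would leak between splits
            continue
        seen.add(key)
        window = chrom_seq[start:end]
        if gene.strand == "-":
            window = reverse_complement(window)
        out.append(LabeledSequence(gene.gene_id, window, label, source, species_tag))
    if n_dropped:
        logger.info("%s extraction: %d genes dropped (out of bounds)", source, n_dropped)
    return out


def extract_promoter_windows(
    genome: Mapping[str, str],
    annotations: Iterable[GeneAnnotation],
    species_tag: str = "",
) -> list[LabeledSequence]:
    """Core promoter windows [-200, +50] around each TSS, label=promoter."""
    return _extract_windows(
        genome, annotations, PROMOTER_WINDOW, "promoter", "core_promoter", species_tag
    )


def extract_downstream_nonpromoters(
    genome: Mapping[str, str],
    annotations: Iterable[GeneAnnotation],
    species_tag: str = "",
) -> list[LabeledSequence]:
    """Gene-body windows [+751, +1000], label=non_promoter."""
    return _extract_windows(
        genome, annotations, DOWNSTREAM_WINDOW, "non_promoter", "downstream_gene", species_tag
    )


def sample_random_nonpromoters(
    genome: Mapping[str, str],
    annotations: Iterable[GeneAnnotation],
    n: int,
    seed: int = 0,
    species_tag: str = "",
    exclusion: tuple[int, int] = EXCLUSION_ZONE,
    window: int = WINDOW_LENGTH,
) -> list[LabeledSequence]:
    """Random genomic windows avoiding [TSS-1000, TSS+500] of every gene.

    A window is eligible only if its full 250 bp extent avoids the union of
    exclusion zones.  Raises :class:`CapacityError` if fewer than ``n``
    distinct eligible start positions exist.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    zones: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for gene in annotations:
        if gene.chrom in zones:
            zones[gene.chrom].append(relative_window(gene.tss, gene.strand, *exclusion))

    eligible: list[tuple[str, int]] = []
    for chrom, seq in genome.items():
        L = len(seq)
        if L < window:
            continue
        blocked = np.zeros(L + 1, dtype=np.int32)
        for s, e in zones[chrom]:
            blocked[max(s, 0)] += 1
            blocked[min(e, L)] -= 1
        blocked = np.cumsum(blocked[:-1]) > 0
        # a start s is eligible iff no blocked base in [s, s+window)
        bad = np.convolve(blocked.astype(np.int32), np.ones(window, dtype=np.int32), "valid")
        starts = np.flatnonzero(bad == 0)
        eligible.extend((chrom, int(s)) for s in starts)

    if len(eligible) < n:
        raise CapacityError(
            f"requested {n} random non-promoter windows but only "
            f"{len(eligible)} eligible start positions exist "
            f"(shortfall {n - len(eligible)})"
        )
    picks = rng.choice(len(eligible), size=n, replace=False)
    out = []
    for i, k in enumerate(sorted(int(p) for p in picks)):
        chrom, s = eligible[k]
        out.append(
            LabeledSequence(
                f"rand_{chrom}_{s}", genome[chrom][s : s + window],
                "non_promoter", "random_genomic", species_tag,
            )
        )
    return out


def sample_transcriptome_nonpromoters(
    transcripts: Mapping[str, str],
    n: int,
    seed: int = 0,
    species_tag: str = "",
    window: int = WINDOW_LENGTH,
) -> list[LabeledSequence]:
    """250-mers sampled from transcript sequences, label=non_promoter."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    eligible = [(tid, s) for tid, seq in transcripts.items() for s in range(len(seq) - window + 1)]
    if len(eligible) < n:
        raise CapacityError(
            f"requested {n} transcriptome windows but only {len(eligible)} exist"
        )
    picks = rng.choice(len(eligible), size=n, replace=False)
    return [
        LabeledSequence(
            f"tx_{eligible[int(k)][0]}_{eligible[int(k)][1]}",
            transcripts[eligible[int(k)][0]][eligible[int(k)][1] : eligible[int(k)][1] + window],
            "non_promoter", "transcriptome", species_tag,
        )
        for k in sorted(int(p) for p in picks)
    ]


_ACGT_RE = re.compile(r"^[ACGT]+$")


def filter_sequences(
    seqs: Sequence[LabeledSequence],
    scaffold_pattern: str | None = None,
) -> list[LabeledSequence]:
    """Drop sequences with ambiguous bases or from unplaced scaffolds.

    ``scaffold_pattern`` is a regex matched against the sequence id (which
    carries provenance); matching entries are removed.  Order is preserved.
    """
    pat = re.compile(scaffold_pattern) if scaffold_pattern else None
    kept: list[LabeledSequence] = []
    n_ambig = n_scaffold = 0
    for s in seqs:
        if pat is not None and pat.search(s.id):
            n_scaffold += 1
            continue
        if not _ACGT_RE.match(s.seq):
            n_ambig += 1
            continue
        kept.append(s)
    if n_ambig or n_scaffold:
        logger.info(
            "filter_sequences: removed %d ambiguous, %d unplaced-scaffold sequences",
            n_ambig, n_scaffold,
        )
    return kept


def one_hot_encode(seq: str) -> np.ndarray:
    """One-hot encode a filtered ACGT sequence as a (len, 4) matrix."""
    return one_hot(seq)


def decode(mat: np.ndarray) -> str:
    return decode_one_hot(mat)


def encode_set(seqs: Sequence[LabeledSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a labeled set into (X: (n, L, 4), y: promoter=1)."""
    X = np.stack([one_hot(s.seq) for s in seqs])
    y = np.array([1 if s.label == "promoter" else 0 for s in seqs], dtype=np.int64)
    return X, y


def split_train_test(
    seqs: Sequence[LabeledSequence],
    train_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Disjoint, exhaustive split stratified by label (within 1 per stratum)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[LabeledSequence] = []
    test: list[LabeledSequence] = []
    for label in LABELS:
        idx = [i for i, s in enumerate(seqs) if s.label == label]
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        train.extend(seqs[i] for i in idx[:n_train])
        test.extend(seqs[i] for i in idx[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# I/O: FASTA / GFF3 / labeled-set files
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path: str | Path, feature: str = "gene") -> list[GeneAnnotation]:
    """Gene-level GFF3 reader: TSS = start on '+', end on '-' strand."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(str(path), sep="\t", comment="#", header=None, names=cols, dtype=str)
    df = df[df["type"] == feature]
    genes = []
    for _, row in df.iterrows():
        attrs = dict(
            kv.split("=", 1) for kv in row["attributes"].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID", attrs.get("gene_id", f"{row['seqid']}:{row['start']}"))
        tss = int(row["start"]) if row["strand"] == "+" else int(row["end"])
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=row["seqid"],
                strand=row["strand"],
                tss=tss,
                biotype=attrs.get("biotype", "protein_coding"),
            )
        )
    return genes


def write_gff3(
    genes: Iterable[GeneAnnotation],
    path: str | Path,
    gene_length: int = 1000,
) -> None:
    """Write gene records (1-based inclusive).  Genes span ``gene_length`` bp
    downstream of the TSS on their strand."""
    lines = ["##gff-version 3"]
    for g in genes:
        if g.strand == "+":
            start, end = g.tss, g.tss + gene_length - 1
        else:
            start, end = g.tss - gene_length + 1, g.tss
        lines.append(
            "\t".join(
                [g.chrom, "promsnp", "gene", str(start), str(end), ".", g.strand, ".",
                 f"ID={g.gene_id};biotype={g.biotype}"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_labeled_fasta(seqs: Iterable[LabeledSequence], path: str | Path) -> None:
    """FASTA with structured headers ``id|label|source|species``."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}|{s.label}|{s.source}|{s.species_tag}\n{s.seq}\n")


def read_labeled_fasta(path: str | Path) -> list[LabeledSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 4:
            raise ValueError(f"malformed labeled-FASTA header: {rec.description!r}")
        out.append(LabeledSequence(parts[0], str(rec.seq).upper(), parts[1], parts[2], parts[3]))
    return out


def write_manifest(seqs: Sequence[LabeledSequence], path: str | Path) -> None:
    pd.DataFrame(
        [(s.id, s.label, s.source, s.species_tag, len(s.seq)) for s in seqs],
        columns=["id", "label", "source", "species", "length"],
    ).to_csv(str(path), sep="\t", index=False)
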