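"""Apply a trained promoter classifier to assembled contigs.

Because GBS-derived contigs have unknown reading direction, every contig is
examined in four orientation variants — identity, complement (base-paired,
direction kept), reverse (direction flipped, bases kept) and reverse
complement — and tiled into 250 bp windows at a configurable stride.
Windows whose promoter probability passes the threshold become
:class:`PromoterCall` records; SNP positions (always given on the identity
orientation of the contig) are intersected with the calls after mapping
call coordinates back through the transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequtils import TRANSFORMS, apply_transform, map_interval_back

logger = logging.getLogger(__name__)

WINDOW = 250


@dataclass(frozen=True)
class OrientationVariant:
    transform: str
    seq: str


@dataclass(frozen=True)
class PromoterCall:
    """A window classified as promoter.  ``start``/``end`` are 0-based
    half-open on the *transformed* contig sequence."""

    contig_id: str
    start: int
    end: int
    transform: str
    probability: float


def orientation_variants(seq: str) -> list[OrientationVariant]:
    """The four direction/strand readings of an assembled sequence."""
    return [OrientationVariant(t, apply_transform(seq, t)) for t in TRANSFORMS]


def scan_contigs(
    contigs: Mapping[str, str],
    classifier,
    stride: int = 50,
    threshold: float = 0.5,
    window: int = WINDOW,
    featurizer=None,
    batch_size: int = 2048,
) -> tuple[list[PromoterCall], dict]:
    """Tile every orientation variant of every contig and classify windows.

    Contigs shorter than the window are skipped (and counted).  The summary
    reports the fraction of scanned contigs with at least one passing window
    — the per-sequence "classified as promoter" convention.
    """
    if not hasattr(classifier, "weights_"):
        raise RuntimeError("classifier must be trained before scanning")
    windows: list[str] = []
    meta: list[tuple[str, int, int, str]] = []
    n_skipped = 0
    n_scanned = 0
    for cid, seq in contigs.items():
        if len(seq) < window:
            n_skipped += 1
            logger.info("contig %s shorter than %d bp, skipped", cid, window)
            continue
        n_scanned += 1
        for variant in orientation_variants(seq):
            starts = list(range(0, len(seq) - window + 1, stride))
            # always include the final full window so contig ends are covered
            last = len(seq) - window
            if starts[-1] != last:
                starts.append(last)
            for s in starts:
                windows.append(variant.seq[s : s + window])
                meta.append((cid, s, s + window, variant.transform))

    calls: list[PromoterCall] = []
    promoter_contigs: set[str] = set()
    for start in range(0, len(windows), batch_size):
        batch = windows[start : start + batch_size]
        aux = featurizer.transform(batch) if featurizer is not None else None
        probs = classifier.decision_probabilities(batch, aux=aux)
        for (cid, s, e, t), p in zip(meta[start : start + batch_size], probs):
            if p >= threshold:
                calls.append(PromoterCall(cid, s, e, t, float(p)))
                promoter_contigs.add(cid)

    summary = {
        "n_contigs": len(contigs),
        "n_scanned": n_scanned,
        "n_skipped_short": n_skipped,
        "n_windows": len(windows),
        "n_calls": len(calls),
        "n_promoter_contigs": len(promoter_contigs),
        "promoter_fraction": len(promoter_contigs) / n_scanned if n_scanned else 0.0,
        "window_call_fraction": len(calls) / len(windows) if windows else 0.0,
    }
    return calls, summary


def load_vcf_records(vcf_path: str | Path) -> pd.DataFrame:
    """Biallelic SNP records from a VCF: id, contig, 1-based pos, ref, alt, qual."""
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(vcf_path))
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        snp_id = var.ID or f"{var.CHROM}_{var.POS}"
        rows.append((snp_id, var.CHROM, var.POS, var.REF, var.ALT[0], var.QUAL))
    vcf.close()
    return pd.DataFrame(rows, columns=["snp_id", "contig", "pos", "ref", "alt", "qual"])


def snps_in_promoters(
    calls: Sequence[PromoterCall],
    snps: pd.DataFrame | str | Path,
    contig_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """SNPs located inside any promoter call on their contig.

    SNP positions are 1-based on the identity orientation; call windows are
    mapped back through their transform before the containment test.  The
    result carries the number of covering calls and the best probability.
    """
    if not isinstance(snps, pd.DataFrame):
        snps = load_vcf_records(snps)
    by_contig: dict[str, list[tuple[int, int, float]]] = {}
    for call in calls:
        L = contig_lengths[call.contig_id]
        s, e = map_interval_back(call.start, call.end, L, call.transform)
        by_contig.setdefault(call.contig_id, []).append((s, e, call.probability))

    keep_rows = []
    for _, row in snps.iterrows():
        intervals = by_contig.get(row["contig"], ())
        pos0 = row["pos"] - 1
        covering = [iv for iv in intervals if iv[0] <= pos0 < iv[1]]
        if covering:
            keep_rows.append(
                {**row.to_dict(), "n_calls": len(covering),
                 "best_probability": max(c[2] for c in covering)}
            )
    return pd.DataFrame(
        keep_rows,
        columns=[*snps.columns, "n_calls", "best_probability"],
    )


def write_calls_bed(calls: Iterable[PromoterCall], path: str | Path,
                    contig_lengths: Mapping[str, int]) -> None:
    """BED output in identity coordinates, with transform and probability."""
    lines = []
    for c in sorted(calls, key=lambda c: (c.contig_id, c.start)):
        s, e = map_interval_back(c.start, c.end, contig_lengths[c.contig_id], c.transform)
        lines.append(f"{c.contig_id}\t{s}\t{e}\t{c.transform}\t{c.probability:.4f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
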