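"""Position weight matrices, TRANSFAC-format I/O, matrix similarity scoring,
and per-SNP binding-site consequence calling.

The matrix similarity score (MSS) follows the MATCH convention: each position
contributes its information-vector weight times the frequency of the observed
base, and the sum is min-max normalised over the attainable range so that the
consensus scores 1 and the anti-consensus scores 0.  A SNP's consequence on a
binding site is judged by comparing the MSS of the reference-allele and
alternate-allele flanking sequences at identical (matrix, position, strand)
sites: ``no_effect``, ``score_change``, ``loss`` (site passes the threshold
only with the reference allele) or ``gain`` (only with the alternate allele).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequtils import BASES, BASE_INDEX, reverse_complement

MSS_THRESHOLD_DEFAULT = 0.85

CONSEQUENCE_TYPES = ("no_effect", "score_change", "loss", "gain")


class TransfacParseError(ValueError):
    """Raised on malformed TRANSFAC matrix records; carries the line number."""


@dataclass
class PWM:
    """A positional nucleotide weight matrix.

    Parameters
    ----------
    name:
        Matrix identifier (e.g. ``P$MYB4_01``).
    counts:
        ``(L, 4)`` array of per-position base counts or weights, columns
        ordered A, C, G, T.
    pseudocount:
        Added to every cell before normalisation; avoids zero frequencies
        (and hence ``-inf`` information terms) for matrices built from few
        sites.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) array")
        if len(self.counts) < 1:
            raise ValueError("matrix must have at least one position")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self._freqs = None
        self._info = None

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def freqs(self) -> np.ndarray:
        """Per-position base frequencies after pseudocount normalisation."""
        if self._freqs is None:
            c = self.counts + self.pseudocount
            rows = c.sum(axis=1, keepdims=True)
            if (rows == 0).any():
                raise ValueError("a matrix row has zero total weight")
            self._freqs = c / rows
        return self._freqs

    @property
    def information(self) -> np.ndarray:
        """Information vector I(i) = sum_b f(i,b) ln(4 f(i,b)); 0 ln 0 := 0."""
        if self._info is None:
            f = self.freqs
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(f > 0, f * np.log(4.0 * np.where(f > 0, f, 1.0)), 0.0)
            self._info = term.sum(axis=1)
        return self._info

    @property
    def min_score(self) -> float:
        return float((self.information * self.freqs.min(axis=1)).sum())

    @property
    def max_score(self) -> float:
        return float((self.information * self.freqs.max(axis=1)).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def mss(self, window: str) -> float:
        """Matrix similarity score of a window of length L, in [0, 1].

        Degenerate matrices where every window scores alike (min == max,
        e.g. the uniform matrix) score 1: any window is trivially optimal.
        """
        if len(window) != len(self):
            raise ValueError(
                f"window length {len(window)} != matrix length {len(self)}"
            )
        idx = [BASE_INDEX[b] for b in window]
        current = float((self.information * self.freqs[np.arange(len(self)), idx]).sum())
        lo, hi = self.min_score, self.max_score
        if hi - lo < 1e-12:
            return 1.0
        return (current - lo) / (hi - lo)


@dataclass(frozen=True)
class TFBSHit:
    """A putative binding site found on a scanned sequence.

    ``offset`` is the 0-based start of the site on the *given* sequence
    (plus-strand coordinates) regardless of the strand matched.
    """

    pwm_id: str
    offset: int
    strand: str  # '+' or '-'
    mss: float


@dataclass
class SNPContext:
    """A SNP with its +/-25 bp flanking sequence in both allele versions."""

    snp_id: str
    ref_seq: str
    alt_seq: str
    snp_offset: int = 25

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError("ref and alt flanks must have equal length")
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq)) if a != b]
        if diffs != [self.snp_offset]:
            raise ValueError(
                f"ref and alt must differ exactly at offset {self.snp_offset}, "
                f"got differences at {diffs}"
            )


@dataclass(frozen=True)
class ConsequenceCall:
    snp_id: str
    pwm_id: str
    offset: int
    strand: str
    mss_ref: float | None
    mss_alt: float | None
    type: str

    def __post_init__(self) -> None:
        if self.type not in CONSEQUENCE_TYPES:
            raise ValueError(f"unknown consequence type {self.type!r}")


# ---------------------------------------------------------------------------
# TRANSFAC plain-matrix I/O
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^(\d\d+|\d)\s+")


def parse_transfac(source: str | Path, pseudocount: float = 0.0) -> list[PWM]:
    """Parse a plain TRANSFAC matrix file into a list of :class:`PWM`.

    Supports the DE / P0 / 01..NN / XX / ``//`` record structure.  ``source``
    may be a path or the file content itself.
    """
    if isinstance(source, Path) or ("\n" not in str(source) and Path(str(source)).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)

    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []
    in_record = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line == "XX":
            continue
        if line.startswith("DE"):
            if in_record:
                raise TransfacParseError(
                    f"line {lineno}: new DE record before '//' terminator"
                )
            fields = line.split()
            if len(fields) < 2:
                raise TransfacParseError(f"line {lineno}: DE line without a name")
            name = fields[1]
            rows = []
            in_record = True
        elif line.startswith("P0") or line.startswith("PO"):
            continue
        elif line == "//":
            if not in_record or name is None:
                raise TransfacParseError(f"line {lineno}: '//' outside a record")
            if not rows:
                raise TransfacParseError(f"line {lineno}: record {name!r} has no rows")
            pwms.append(PWM(name=name, counts=np.array(rows), pseudocount=pseudocount))
            name, rows, in_record = None, [], False
        elif _ROW_RE.match(line):
            fields = line.split()
            try:
                values = [float(v) for v in fields[1:5]]
            except (ValueError, IndexError) as exc:
                raise TransfacParseError(
                    f"line {lineno}: malformed position row {line!r}"
                ) from exc
            if len(values) != 4:
                raise TransfacParseError(
                    f"line {lineno}: position row needs 4 base columns"
                )
            rows.append(values)
        elif in_record:
            # tolerate auxiliary tags (ID, AC, BF, CC ...) inside a record
            continue
    if in_record:
        raise TransfacParseError("unexpected end of file: missing '//' terminator")
    return pwms


def write_transfac(pwms: Iterable[PWM], path: str | Path | None = None) -> str:
    """Serialise matrices in the plain TRANSFAC dialect; returns the text."""
    lines: list[str] = []
    for pwm in pwms:
        lines.append(f"DE  {pwm.name}")
        lines.append("P0" + "".join(f"{b:>12}" for b in BASES))
        cons = pwm.consensus
        for i, row in enumerate(pwm.counts, start=1):
            lines.append(
                f"{i:02d}" + "".join(f"{v:>12g}" for v in row) + f"{cons[i - 1]:>7}"
            )
        lines.append("XX")
        lines.append("//")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Scanning and consequence calling
# ---------------------------------------------------------------------------

def scan(
    pwms: Sequence[PWM],
    seq: str,
    threshold: float = MSS_THRESHOLD_DEFAULT,
) -> list[TFBSHit]:
    """Slide every matrix over both strands of ``seq``; report MSS >= threshold.

    Minus-strand matches are found by scanning the reverse complement and are
    reported with coordinates on the given sequence: a match starting at
    ``o`` on the reverse complement occupies ``[len(seq)-o-L, len(seq)-o)``
    on the forward coordinates.
    """
    hits: list[TFBSHit] = []
    rc = reverse_complement(seq)
    n = len(seq)
    for pwm in pwms:
        L = len(pwm)
        if L > n:
            continue
        for strand, s in (("+", seq), ("-", rc)):
            for o in range(n - L + 1):
                score = pwm.mss(s[o : o + L])
                if score >= threshold:
                    offset = o if strand == "+" else n - o - L
                    hits.append(TFBSHit(pwm.name, offset, strand, score))
    return hits


def classify_consequence(
    pwms: Sequence[PWM],
    context: SNPContext,
    threshold: float = MSS_THRESHOLD_DEFAULT,
    score_tol: float = 1e-9,
    overlap_only: bool = True,
) -> list[ConsequenceCall]:
    """Compare binding sites between the two allele versions of a SNP flank.

    Sites are identified by (matrix, offset, strand).  Sites present for both
    alleles are ``no_effect`` when the scores agree within ``score_tol`` and
    ``score_change`` otherwise; reference-only sites are ``loss`` and
    alternate-only sites are ``gain``.  By default only sites whose window
    overlaps the SNP base are reported — sites elsewhere cannot differ
    between alleles.
    """
    def keyed(hits: Iterable[TFBSHit]) -> dict[tuple[str, int, str], TFBSHit]:
        out = {}
        for h in hits:
            out[(h.pwm_id, h.offset, h.strand)] = h
        return out

    lengths = {p.name: len(p) for p in pwms}
    ref_hits = keyed(scan(pwms, context.ref_seq, threshold))
    alt_hits = keyed(scan(pwms, context.alt_seq, threshold))

    def overlaps(key: tuple[str, int, str]) -> bool:
        pwm_id, offset, _ = key
        return offset <= context.snp_offset < offset + lengths[pwm_id]

    calls: list[ConsequenceCall] = []
    for key in sorted(set(ref_hits) | set(alt_hits)):
        if overlap_only and not overlaps(key):
            continue
        pwm_id, offset, strand = key
        r = ref_hits.get(key)
        a = alt_hits.get(key)
        if r is not None and a is not None:
            kind = "no_effect" if abs(r.mss - a.mss) <= score_tol else "score_change"
            calls.append(
                ConsequenceCall(context.snp_id, pwm_id, offset, strand, r.mss, a.mss, kind)
            )
        elif r is not None:
            calls.append(
                ConsequenceCall(context.snp_id, pwm_id, offset, strand, r.mss, None, "loss")
            )
        else:
            calls.append(
                ConsequenceCall(context.snp_id, pwm_id, offset, strand, None, a.mss, "gain")
            )
    return calls


def rsnp_filter(calls: Iterable[ConsequenceCall]) -> list[str]:
    """SNP ids with at least one call affecting binding affinity.

    A SNP qualifies as regulatory if any of its calls is a score change,
    a loss, or a gain of a binding site.
    """
    ids = {c.snp_id for c in calls if c.type in ("score_change", "loss", "gain")}
    return sorted(ids)
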