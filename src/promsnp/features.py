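"""Sequence-composition and information-theoretic promoter features.

Five feature families characterise a 250 bp window alongside its one-hot
encoding: dinucleotide/motif frequencies (CA, CG, TATA-like motifs), CG skew,
k-mer spectra, horizontal mutual information (HMI) and generalized
topological entropy (GTE).

HMI at distance d is the mutual information between the bases at positions
(i, i+d), estimated from all |s|-d overlapping position pairs:

    HMI(d) = sum_{m,n in {A,C,G,T}} p_mn(d) log( p_mn(d) / (p_m(d) p_n(d)) )

with 0 log(.) terms contributing 0.  The logarithm base defaults to 2
(bits); it only rescales the feature.

GTE measures substring diversity.  For a sequence w of length |w|, let n_w
be the largest integer with 4^n + n - 1 <= |w| (see :func:`gte_order`) and let
p_w(i) be the number of distinct contiguous substrings of length i.  With
k = n_w (all sub-sequence lengths considered):

    GTE(w) = (1/k) * sum_{i=n_w-k+1}^{n_w} log4(p_w(i)) / i

Since p_w(i) <= 4^i, each summand is at most 1 and GTE lies in [0, 1].
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .sequtils import BASES, BASE_INDEX

logger = logging.getLogger(__name__)


def motif_frequency(seq: str, motif: str) -> float:
    """Overlapping occurrence count of ``motif`` divided by the number of
    possible positions, |seq| - |motif| + 1."""
    if len(motif) > len(seq):
        logger.warning("motif %r longer than sequence; frequency set to 0", motif)
        return 0.0
    n_pos = len(seq) - len(motif) + 1
    count = sum(1 for i in range(n_pos) if seq[i : i + len(motif)] == motif)
    return count / n_pos


def cg_skew(seq: str) -> float:
    """(#C - #G) / (#C + #G); 0 (with a warning) when the sequence has no C or G."""
    c = seq.count("C")
    g = seq.count("G")
    if c + g == 0:
        logger.warning("cg_skew: sequence without C or G, returning 0")
        return 0.0
    return (c - g) / (c + g)


def kmer_frequencies(seq: str, k: int) -> dict[str, float]:
    """All 4^k k-mer frequencies (lexicographic order), overlapping counts.

    Frequencies sum to 1 for any pure-ACGT sequence with |seq| >= k.
    """
    if k < 1 or k > len(seq):
        raise ValueError(f"k={k} out of range for sequence of length {len(seq)}")
    n_pos = len(seq) - k + 1
    counts: dict[str, int] = {}
    for i in range(n_pos):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return {
        "".join(p): counts.get("".join(p), 0) / n_pos
        for p in itertools.product(BASES, repeat=k)
    }


def hmi(seq: str, d: int, log_base: float = 2.0) -> float:
    """Horizontal mutual information at distance ``d`` (see module docstring)."""
    if not 1 <= d < len(seq):
        raise ValueError(f"distance d={d} must satisfy 1 <= d < |seq|={len(seq)}")
    idx = np.array([BASE_INDEX[b] for b in seq])
    first, second = idx[:-d], idx[d:]
    joint = np.zeros((4, 4))
    np.add.at(joint, (first, second), 1.0)
    joint /= joint.sum()
    pm = joint.sum(axis=1)
    pn = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / np.outer(pm, pn)
        terms = np.where(joint > 0, joint * np.log(np.where(joint > 0, ratio, 1.0)), 0.0)
    return float(terms.sum() / math.log(log_base))


def gte_order(length: int) -> int:
    """The largest n with 4^n + n - 1 <= length.

    Equivalently the unique n with 4^n + n - 1 <= length < 4^(n+1) + n + 1,
    the standard bracket of the topological-entropy literature (the length
    must admit all 4^n n-mers).  A 250 bp window has n = 3.
    """
    if length < 4:
        raise ValueError("sequence must be at least 4 bases long")
    n = 1
    while 4 ** (n + 1) + (n + 1) - 1 <= length:
        n += 1
    return n


def gte(seq: str) -> float:
    """Generalized topological entropy with k = n_w (all substring lengths)."""
    n = gte_order(len(seq))
    k = n
    total = 0.0
    for i in range(n - k + 1, n + 1):
        distinct = len({seq[j : j + i] for j in range(len(seq) - i + 1)})
        total += math.log(distinct, 4) / i
    return total / k


@dataclass(frozen=True)
class FeatureConfig:
    """Which auxiliary features to compute, and with what parameters.

    An empty config (``FeatureConfig.none()``) yields the one-hot-only mode.
    Defaults: 2-mers, HMI at distances 1..5, the TATAA / CA / CG motif
    frequencies, CG skew and GTE (26 values).
    """

    kmer_k: tuple[int, ...] = (2,)
    hmi_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    motifs: tuple[str, ...] = ("TATAA", "CA", "CG")
    include_cg_skew: bool = True
    include_gte: bool = True
    hmi_log_base: float = 2.0

    @classmethod
    def none(cls) -> "FeatureConfig":
        return cls(kmer_k=(), hmi_distances=(), motifs=(),
                   include_cg_skew=False, include_gte=False)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for k in self.kmer_k:
            names.extend("".join(p) for p in itertools.product(BASES, repeat=k))
        names.extend(f"hmi_d{d}" for d in self.hmi_distances)
        names.extend(f"freq_{m}" for m in self.motifs)
        if self.include_cg_skew:
            names.append("cg_skew")
        if self.include_gte:
            names.append("gte")
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names())


def feature_vector(seq: str, config: FeatureConfig | None = None) -> np.ndarray:
    """Concatenated feature values in the stable order of ``feature_names``."""
    if config is None:
        config = FeatureConfig()
    values: list[float] = []
    for k in config.kmer_k:
        values.extend(kmer_frequencies(seq, k).values())
    for d in config.hmi_distances:
        values.append(hmi(seq, d, config.hmi_log_base))
    for m in config.motifs:
        values.append(motif_frequency(seq, m))
    if config.include_cg_skew:
        values.append(cg_skew(seq))
    if config.include_gte:
        values.append(gte(seq))
    return np.asarray(values, dtype=np.float64)


class SequenceFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn transformer: DNA strings -> z-normalised feature matrix.

    Normalisation statistics are fit on training data only, so the features
    can be concatenated to a classifier's flattening layer without any one
    feature dominating by scale.  Constant features get unit scale.
    """

    def __init__(self, config: FeatureConfig | None = None):
        self.config = config

    def _config(self) -> FeatureConfig:
        return self.config if self.config is not None else FeatureConfig()

    def _raw(self, X: Sequence[str]) -> np.ndarray:
        cfg = self._config()
        if cfg.n_features == 0:
            return np.zeros((len(X), 0))
        return np.stack([feature_vector(s, cfg) for s in X])

    def fit(self, X: Sequence[str], y=None) -> "SequenceFeaturizer":
        raw = self._raw(X)
        self.n_features_in_ = raw.shape[1]
        self.mean_ = raw.mean(axis=0) if len(raw) else np.zeros(raw.shape[1])
        std = raw.std(axis=0) if len(raw) else np.ones(raw.shape[1])
        self.scale_ = np.where(std > 1e-12, std, 1.0)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "mean_")
        raw = self._raw(X)
        return (raw - self.mean_) / self.scale_

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self._config().feature_names(), dtype=object)


def write_feature_matrix(
    seqs: Sequence[str],
    ids: Sequence[str],
    path,
    config: FeatureConfig | None = None,
) -> None:
    """TSV feature matrix, one row per sequence, stable column order."""
    import pandas as pd

    cfg = config if config is not None else FeatureConfig()
    mat = np.stack([feature_vector(s, cfg) for s in seqs]) if seqs else np.zeros((0, cfg.n_features))
    pd.DataFrame(mat, index=list(ids), columns=cfg.feature_names()).rename_axis("id").to_csv(
        path, sep="\t"
    )
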