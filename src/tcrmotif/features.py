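"""Peptide sequence featurization.

Encoders that turn fixed-length peptides into named numeric feature
vectors: amino-acid / dipeptide / tripeptide composition (overlapping
windows, denominators L, L-1, L-2), combined N-gram vectors over the
full fixed vocabularies (20 / 400 / 8000 entries), an adapter for
external global physicochemical descriptors, and a min-max normalizer
that is fitted on training rows only so that test information never
leaks into the scaling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical one-letter amino-acid alphabet, in fixed order. Column
#: identity of every feature matrix depends on this ordering.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Feature-name prefixes by encoder family and k-mer order.
COMPOSITION_PREFIX = {1: "AAC_", 2: "DPC_", 3: "TPC_"}
NGRAM_PREFIX = {1: "NG1_", 2: "NG2_", 3: "NG3_"}


def validate_sequence(seq: str) -> str:
    """Check that ``seq`` is a nonempty string over the canonical alphabet.

    Raises ``ValueError`` naming the first offending character and its
    1-based position.
    """
    if not isinstance(seq, str) or len(seq) == 0:
        raise ValueError("peptide sequence must be a nonempty string")
    for pos, ch in enumerate(seq, start=1):
        if ch not in AA_TO_INDEX:
            raise ValueError(
                f"non-canonical residue {ch!r} at position {pos} in sequence {seq!r}"
            )
    return seq


@lru_cache(maxsize=None)
def kmer_vocabulary(k: int) -> tuple[str, ...]:
    """All 20**k k-mers over the canonical alphabet, in alphabet order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return tuple("".join(p) for p in itertools.product(ALPHABET, repeat=k))


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer counts of ``seq`` as a dense vector of length 20**k."""
    validate_sequence(seq)
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} has no {k}-mers")
    counts = np.zeros(20**k, dtype=float)
    idx = [AA_TO_INDEX[c] for c in seq]
    for s in range(len(seq) - k + 1):
        code = 0
        for j in range(k):
            code = code * 20 + idx[s + j]
        counts[code] += 1.0
    return counts


def _composition(seq: str, k: int, prefix: str) -> pd.Series:
    counts = _kmer_counts(seq, k)
    n_windows = len(seq) - k + 1
    names = [prefix + kmer for kmer in kmer_vocabulary(k)]
    return pd.Series(counts / n_windows, index=names)


def aa_composition(seq: str) -> pd.Series:
    """Fraction of each amino-acid type: entry i is N_i / L (20 entries, sum 1)."""
    return _composition(seq, 1, COMPOSITION_PREFIX[1])


def dipeptide_composition(seq: str) -> pd.Series:
    """Fraction of each dipeptide over overlapping windows: N_ij / (L-1) (400 entries)."""
    return _composition(seq, 2, COMPOSITION_PREFIX[2])


def tripeptide_composition(seq: str) -> pd.Series:
    """Fraction of each tripeptide over overlapping windows: N_ijk / (L-2) (8000 entries)."""
    return _composition(seq, 3, COMPOSITION_PREFIX[3])


@dataclass(frozen=True)
class EncoderSpec:
    """Configuration of the N-gram encoder.

    orders
        Subset of {1, 2, 3}: unigrams, bigrams, trigrams.
    mode
        ``"frequency"`` divides each block by its window count, matching
        the composition encoders blockwise; ``"count"`` keeps raw counts.
    include_descriptor_adapter
        Whether pipeline-level encoding also pulls external global
        descriptors (see :func:`descriptor_features`).
    """

    orders: tuple[int, ...] = (1, 2, 3)
    mode: str = "frequency"
    include_descriptor_adapter: bool = False

    def __post_init__(self) -> None:
        orders = tuple(sorted(set(self.orders)))
        if not orders:
            raise ValueError("orders must be nonempty")
        if any(k not in (1, 2, 3) for k in orders):
            raise ValueError("orders must be a subset of {1, 2, 3}")
        if self.mode not in ("frequency", "count"):
            raise ValueError("mode must be 'frequency' or 'count'")
        object.__setattr__(self, "orders", orders)


def ngram_features(seq: str, spec: EncoderSpec = EncoderSpec()) -> pd.Series:
    """Concatenated per-order N-gram vector over the full fixed vocabularies.

    In frequency mode each order-k block reproduces the corresponding
    composition encoder elementwise (under NG-prefixed names); in count
    mode blocks hold raw overlapping-window counts.
    """
    validate_sequence(seq)
    if len(seq) < max(spec.orders):
        raise ValueError(
            f"sequence of length {len(seq)} too short for order {max(spec.orders)}"
        )
    blocks = []
    for k in spec.orders:
        counts = _kmer_counts(seq, k)
        if spec.mode == "frequency":
            counts = counts / (len(seq) - k + 1)
        names = [NGRAM_PREFIX[k] + kmer for kmer in kmer_vocabulary(k)]
        blocks.append(pd.Series(counts, index=names))
    return pd.concat(blocks)


# ---------------------------------------------------------------------------
# External global-descriptor adapter
# ---------------------------------------------------------------------------

_warned_no_backend = False


def descriptor_features(seq: str) -> pd.Series:
    """Global physicochemical descriptors via the propy package when available.

    Descriptor names are passed through verbatim so that selected
    features remain reportable by their published identifiers. When the
    propy backend is not importable the adapter falls back to the
    composition-based descriptor families it defines (20 amino-acid
    composition + 400 dipeptide composition descriptors, as percentages,
    under propy's names) and logs a warning once; autocorrelation, CTD
    and sequence-order descriptor math is not reimplemented here.
    """
    global _warned_no_backend
    validate_sequence(seq)
    try:
        from propy.PyPro import GetProDes  # type: ignore

        des = GetProDes(seq).GetALL()
        return pd.Series(des, dtype=float)
    except ImportError:
        if not _warned_no_backend:
            logger.warning(
                "propy descriptor backend not available; using built-in "
                "composition descriptors (AAC + DPC) only"
            )
            _warned_no_backend = True
    aac = _kmer_counts(seq, 1) / len(seq) * 100.0
    dpc = _kmer_counts(seq, 2) / (len(seq) - 1) * 100.0
    names = list(kmer_vocabulary(1)) + list(kmer_vocabulary(2))
    return pd.Series(np.concatenate([aac, dpc]), index=names)


# ---------------------------------------------------------------------------
# Library-level encoding
# ---------------------------------------------------------------------------

#: Feature categories evaluated side by side downstream.
FEATURE_CATEGORIES = ("descriptor", "tripeptide", "ngram")


def encode_sequences(
    sequences: Sequence[str],
    category: str = "ngram",
    spec: EncoderSpec | None = None,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Encode a list of peptides into a FeatureMatrix (rows = peptides).

    ``category`` selects the encoder family: ``"descriptor"`` (external
    adapter), ``"tripeptide"`` (8000-entry composition), or ``"ngram"``
    (combined unigram+bigram+trigram frequencies, 8420 columns by
    default). Row index is ``ids`` when given, else 0..n-1.
    """
    if category not in FEATURE_CATEGORIES:
        raise ValueError(f"unknown feature category {category!r}")
    if category == "descriptor":
        rows = [descriptor_features(s) for s in sequences]
    elif category == "tripeptide":
        rows = [tripeptide_composition(s) for s in sequences]
    else:
        rows = [ngram_features(s, spec or EncoderSpec()) for s in sequences]
    mat = pd.DataFrame(rows)
    if ids is not None:
        mat.index = pd.Index(ids)
    else:
        mat.index = pd.RangeIndex(len(sequences))
    return mat


# ---------------------------------------------------------------------------
# Min-max normalization (train-only fit)
# ---------------------------------------------------------------------------


@dataclass
class NormalizationParams:
    """Per-feature extrema learned from training rows only."""

    z_min: pd.Series
    z_max: pd.Series

    def __post_init__(self) -> None:
        if not self.z_min.index.equals(self.z_max.index):
            raise ValueError("z_min and z_max must share a feature index")
        if (self.z_min > self.z_max).any():
            raise ValueError("z_min must be <= z_max per feature")


def fit_normalizer(train: pd.DataFrame) -> NormalizationParams:
    """Learn per-feature min/max from the training matrix."""
    if train.shape[0] == 0:
        raise ValueError("training matrix must be nonempty")
    return NormalizationParams(z_min=train.min(axis=0), z_max=train.max(axis=0))


def apply_normalizer(params: NormalizationParams, m: pd.DataFrame) -> pd.DataFrame:
    """Rescale each feature to [0,1] with the training extrema.

    ẑ = (z − z_min) / (z_max − z_min); values outside the training range
    are clipped to [0,1]; features constant in training map to 0.
    """
    missing = m.columns.difference(params.z_min.index)
    if len(missing):
        raise KeyError(f"unknown features at apply time: {list(missing)[:5]}")
    zmin = params.z_min[m.columns]
    zmax = params.z_max[m.columns]
    span = zmax - zmin
    constant = span == 0
    safe_span = span.where(~constant, 1.0)
    out = (m - zmin) / safe_span
    out = out.clip(lower=0.0, upper=1.0)
    if constant.any():
        out.loc[:, constant[constant].index] = 0.0
    return out
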