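"""Contact-energy scoring and binder labeling.

A TCR-peptide complex is reduced to a residue-level contact map (pairs
of TCR residue and peptide position within r_max, default 8.5 Å) and a
20x20 pairwise energy matrix J indexed (TCR residue type, peptide
residue type). The binding energy of a peptide is the sum of J entries
over the contacts; higher energy means stronger predicted binding.
Energies are standardized against a decoy ensemble (Z-scores), a
class-separating threshold is read off the Z-score histograms as the
midpoint between the class peaks, mapped back to a read-count
threshold, and the library is labeled and class-balanced by
undersampling the weak binders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import ALPHABET, AA_TO_INDEX, validate_sequence

logger = logging.getLogger(__name__)

DEFAULT_R_MAX = 8.5
DEFAULT_N_DECOYS = 1000
DEFAULT_BINS = 50


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------


@dataclass
class EnergyMatrix:
    """20x20 pairwise energies, rows = TCR residue type, cols = peptide residue type.

    Not assumed symmetric: J[t, p] is the energy of TCR residue type t
    contacting peptide residue type p.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError(f"energy matrix must be 20x20, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("energy matrix entries must be finite")

    def __getitem__(self, key: tuple[str, str]) -> float:
        t, p = key
        return float(self.values[AA_TO_INDEX[t], AA_TO_INDEX[p]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(ALPHABET), columns=list(ALPHABET))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnergyMatrix":
        if list(df.index) != list(ALPHABET) or list(df.columns) != list(ALPHABET):
            raise ValueError("energy matrix axes must be the canonical alphabet order")
        return cls(df.to_numpy())

    @classmethod
    def zeros(cls) -> "EnergyMatrix":
        return cls(np.zeros((20, 20)))


@dataclass(frozen=True)
class Contact:
    """One TCR-residue / peptide-position contact (both indices 1-based)."""

    tcr_index: int
    tcr_residue: str
    peptide_position: int


@dataclass
class ContactMap:
    """Set of TCR-residue/peptide-position contacts with the distance cutoff used."""

    contacts: tuple[Contact, ...]
    r_max: float = DEFAULT_R_MAX

    def __post_init__(self) -> None:
        self.contacts = tuple(self.contacts)
        seen: set[tuple[int, int]] = set()
        for c in self.contacts:
            if c.tcr_residue not in AA_TO_INDEX:
                raise ValueError(f"unknown TCR residue type {c.tcr_residue!r}")
            if c.peptide_position < 1:
                raise ValueError("peptide positions are 1-based (>= 1)")
            key = (c.tcr_index, c.peptide_position)
            if key in seen:
                raise ValueError(f"duplicate contact (tcr {c.tcr_index}, position {c.peptide_position})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.contacts)

    def contact_set(self) -> set[tuple[int, int]]:
        return {(c.tcr_index, c.peptide_position) for c in self.contacts}

    def contacted_positions(self) -> set[int]:
        return {c.peptide_position for c in self.contacts}


@dataclass
class ZScoreSet:
    """Query energies standardized against a decoy ensemble."""

    energies: np.ndarray
    z: np.ndarray
    decoy_mean: float
    decoy_sd: float


@dataclass
class ThresholdResult:
    """Midpoint-between-peaks Z threshold and its read-count image."""

    z_threshold: float
    peak_strong: float
    peak_weak: float
    read_threshold: int | None = None


# ---------------------------------------------------------------------------
# Contact maps from coordinates
# ---------------------------------------------------------------------------

COORD_COLUMNS = ("chain", "residue_index", "residue_type", "x", "y", "z")


def compute_contact_map(coords: pd.DataFrame, r_max: float = DEFAULT_R_MAX) -> ContactMap:
    """Contacts = cross-chain residue pairs at Euclidean distance <= r_max (inclusive).

    ``coords`` holds one representative point per residue with columns
    chain ('tcr' | 'peptide'), residue_index, residue_type, x, y, z.
    """
    missing = set(COORD_COLUMNS) - set(coords.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns {sorted(missing)}")
    tcr = coords[coords["chain"] == "tcr"]
    pep = coords[coords["chain"] == "peptide"]
    if tcr.empty or pep.empty:
        raise ValueError("coordinate table must contain both 'tcr' and 'peptide' chains")
    for sub, name in ((tcr, "tcr"), (pep, "peptide")):
        if sub["residue_index"].duplicated().any():
            raise ValueError(f"duplicate residue_index in chain {name!r}")
    dists = cdist(tcr[["x", "y", "z"]].to_numpy(float), pep[["x", "y", "z"]].to_numpy(float))
    contacts = []
    for i, (_, trow) in enumerate(tcr.iterrows()):
        for j, (_, prow) in enumerate(pep.iterrows()):
            if dists[i, j] <= r_max:
                contacts.append(
                    Contact(
                        tcr_index=int(trow["residue_index"]),
                        tcr_residue=str(trow["residue_type"]),
                        peptide_position=int(prow["residue_index"]),
                    )
                )
    return ContactMap(tuple(contacts), r_max=r_max)


# ---------------------------------------------------------------------------
# Energies, decoys, Z-scores
# ---------------------------------------------------------------------------


def binding_energy(peptide: str, cmap: ContactMap, J: EnergyMatrix) -> float:
    """E = sum over contacts of J[TCR residue type, peptide residue at position].

    Higher E = stronger predicted binding.
    """
    validate_sequence(peptide)
    e = 0.0
    for c in cmap.contacts:
        if c.peptide_position > len(peptide):
            raise ValueError(
                f"contact at position {c.peptide_position} beyond peptide length {len(peptide)}"
            )
        e += J[c.tcr_residue, peptide[c.peptide_position - 1]]
    return e


def binding_energies(peptides: list[str], cmap: ContactMap, J: EnergyMatrix) -> np.ndarray:
    """Vectorized :func:`binding_energy` over a list of equal-length peptides."""
    if not peptides:
        return np.zeros(0)
    L = len(peptides[0])
    for c in cmap.contacts:
        if c.peptide_position > L:
            raise ValueError(
                f"contact at position {c.peptide_position} beyond peptide length {L}"
            )
    codes = np.array([[AA_TO_INDEX[ch] for ch in validate_sequence(p)] for p in peptides])
    e = np.zeros(len(peptides))
    for c in cmap.contacts:
        e += J.values[AA_TO_INDEX[c.tcr_residue], codes[:, c.peptide_position - 1]]
    return e


def generate_decoys(
    peptide: str, n: int = DEFAULT_N_DECOYS, seed: int | np.random.Generator = 0
) -> list[str]:
    """n random sequences of the same length, each position i.i.d. uniform over the alphabet."""
    validate_sequence(peptide)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    draws = rng.integers(0, 20, size=(n, len(peptide)))
    return ["".join(letters[row]) for row in draws]


def z_scores(energies: np.ndarray, decoy_energies: np.ndarray) -> ZScoreSet:
    """Standardize query energies against the decoy ensemble.

    Uses the decoys' mean and population standard deviation:
    Z = (E - mu) / sigma.
    """
    energies = np.asarray(energies, dtype=float)
    decoy_energies = np.asarray(decoy_energies, dtype=float)
    if decoy_energies.size < 2:
        raise ValueError("need at least 2 decoy energies")
    mu = float(decoy_energies.mean())
    sd = float(decoy_energies.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate decoy ensemble: zero energy spread")
    return ZScoreSet(energies=energies, z=(energies - mu) / sd, decoy_mean=mu, decoy_sd=sd)


# ---------------------------------------------------------------------------
# Thresholding and labeling
# ---------------------------------------------------------------------------


def find_threshold(
    z_strong: np.ndarray, z_weak: np.ndarray, bins: int = DEFAULT_BINS
) -> ThresholdResult:
    """Midpoint between the class histogram peaks on a shared binning.

    Both samples are histogrammed over the pooled range with ``bins``
    common bins; each class's peak is the center of its highest bin
    (lowest such bin on ties) and the threshold is the mean of the two
    peaks.
    """
    z_strong = np.asarray(z_strong, dtype=float)
    z_weak = np.asarray(z_weak, dtype=float)
    if z_strong.size == 0 or z_weak.size == 0:
        raise ValueError("both Z-score samples must be nonempty")
    pooled = np.concatenate([z_strong, z_weak])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        raise ValueError("all pooled Z-scores identical: no histogram structure")
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_strong = float(centers[np.argmax(np.histogram(z_strong, bins=edges)[0])])
    peak_weak = float(centers[np.argmax(np.histogram(z_weak, bins=edges)[0])])
    return ThresholdResult(
        z_threshold=0.5 * (peak_strong + peak_weak),
        peak_strong=peak_strong,
        peak_weak=peak_weak,
    )


def map_threshold_to_reads(
    cases: list[tuple[float, int]], z_threshold: float
) -> int:
    """Map a Z threshold to a read-count threshold.

    Among cases (Z, reads) with Z >= z_threshold, take the case with the
    smallest Z (ties broken by lower read count) and return its reads.
    """
    eligible = [(z, r) for z, r in cases if z >= z_threshold]
    if not eligible:
        raise ValueError("no case at or above the Z threshold")
    z_min, reads = min(eligible, key=lambda zr: (zr[0], zr[1]))
    return int(reads)


def label_peptides(records: list, read_threshold: int) -> list:
    """Label 1 (strong) iff reads >= read_threshold, else 0. Returns new records."""
    from dataclasses import replace

    return [replace(r, label=1 if r.reads >= read_threshold else 0) for r in records]


def undersample(records: list, seed: int | np.random.Generator = 0) -> list:
    """Balance classes: keep all strong binders, sample an equal-size weak subset.

    If the weak class is already the smaller one, all weak records are
    kept and a warning is logged (no oversampling).
    """
    strong = [r for r in records if r.label == 1]
    weak = [r for r in records if r.label == 0]
    if not strong:
        raise ValueError("no strong binders to balance against")
    if not weak:
        raise ValueError("no weak binders present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(weak) < len(strong):
        logger.warning(
            "weak class (%d) smaller than strong class (%d); keeping all weak records",
            len(weak),
            len(strong),
        )
        subset = weak
    else:
        idx = rng.choice(len(weak), size=len(strong), replace=False)
        subset = [weak[i] for i in sorted(idx)]
    return strong + subset
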