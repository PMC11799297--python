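"""Synthetic peptide libraries and matched energy systems with planted structure.

Emulates the post-selection structure of a yeast-display screen: a pool
of fixed-length (default 13-mer) peptides in which strong binders are
enriched for short di/tripeptide motifs at fixed positions and carry
heavy-tailed read counts, while weak binders are background sequences
whose reads are almost all zero or one. A matching energy system (20x20
pairwise matrix + contact map) is constructed so that exactly the
planted motif residues at the planted positions score high, giving
every downstream stage a ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import Contact, ContactMap, EnergyMatrix, DEFAULT_R_MAX
from .features import ALPHABET, AA_TO_INDEX, validate_sequence
from .io import PeptideRecord

logger = logging.getLogger(__name__)

#: Collinear peptide-backbone spacing (Å) used when synthesizing coordinates.
_BACKBONE_SPACING = 6.0
#: Distance margin (Å) separating contacting from non-contacting pairs.
_CONTACT_MARGIN = 0.5


@dataclass(frozen=True)
class PlantedMotif:
    """A short motif planted at a fixed 1-based start position with some probability."""

    motif: str
    start: int
    plant_prob: float = 1.0

    def __post_init__(self) -> None:
        validate_sequence(self.motif)
        if self.start < 1:
            raise ValueError("motif start is 1-based (>= 1)")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob must lie in [0, 1]")

    @property
    def positions(self) -> range:
        return range(self.start, self.start + len(self.motif))


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic library.

    Read counts follow the sparsity regime of a post-selection screen:
    strong binders draw negative-binomial reads around ``strong_read_mean``
    while weak binders draw Bernoulli 0/1 reads with mean ``weak_read_mean``
    (excluded real peptides had reads of zero or one).
    ``energy_boost`` is the per-contact energy delta awarded to a planted
    motif residue in the matched energy system.
    """

    n_strong: int
    n_weak: int
    length: int = 13
    planted_motifs: tuple[PlantedMotif, ...] = (PlantedMotif("AFF", 3, 0.9),)
    background: np.ndarray | None = None
    strong_read_mean: float = 150.0
    weak_read_mean: float = 0.5
    energy_boost: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strong < 0 or self.n_weak < 0:
            raise ValueError("class sizes must be non-negative")
        if self.length < 1:
            raise ValueError("peptide length must be positive")
        self.planted_motifs = tuple(self.planted_motifs)
        for pm in self.planted_motifs:
            if pm.start + len(pm.motif) - 1 > self.length:
                raise ValueError(
                    f"motif {pm.motif!r} at start {pm.start} does not fit length {self.length}"
                )
        if self.background is None:
            self.background = np.full(20, 1.0 / 20.0)
        else:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (20,):
                raise ValueError("background must have 20 probabilities")
            if np.any(self.background < 0) or not math.isclose(
                float(self.background.sum()), 1.0, abs_tol=1e-9
            ):
                raise ValueError("background must be a distribution (sums to 1)")
        if self.strong_read_mean <= 0:
            raise ValueError("strong_read_mean must be positive")
        if self.weak_read_mean < 0 or self.weak_read_mean > 1:
            raise ValueError("weak_read_mean is a Bernoulli mean in [0, 1]")
        if self.energy_boost <= 0:
            raise ValueError("energy_boost must be positive")


@dataclass
class EnergySystem:
    """A matched pairwise energy matrix, contact map, and wild-type peptide."""

    energy_matrix: EnergyMatrix
    contact_map: ContactMap
    wt_peptide: str


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _random_sequence(rng: np.random.Generator, length: int, background: np.ndarray) -> list[str]:
    letters = rng.choice(list(ALPHABET), size=length, p=background)
    return list(letters)


def generate_library(spec: SyntheticSpec) -> list[PeptideRecord]:
    """Generate n_strong + n_weak peptide records, reproducible from ``spec.seed``.

    Strong records carry each planted motif at its start position with
    probability ``plant_prob`` (remaining positions i.i.d. background);
    weak records are fully i.i.d. background. Strong read counts are
    negative binomial around ``strong_read_mean``; weak reads are 0/1.
    """
    rng = _child_rng(spec.seed, 0)
    records: list[PeptideRecord] = []
    # NB dispersion fixed at 2 successes: heavy-tailed but positive-mode reads.
    nb_n = 2.0
    nb_p = nb_n / (nb_n + spec.strong_read_mean)
    for i in range(spec.n_strong):
        seq = _random_sequence(rng, spec.length, spec.background)
        for pm in spec.planted_motifs:
            if rng.random() < pm.plant_prob:
                seq[pm.start - 1 : pm.start - 1 + len(pm.motif)] = list(pm.motif)
        reads = int(rng.negative_binomial(nb_n, nb_p))
        records.append(PeptideRecord(id=f"strong_{i:05d}", sequence="".join(seq), reads=reads))
    for i in range(spec.n_weak):
        seq = _random_sequence(rng, spec.length, spec.background)
        reads = int(rng.random() < spec.weak_read_mean)
        records.append(PeptideRecord(id=f"weak_{i:05d}", sequence="".join(seq), reads=reads))
    return records


def generate_energy_system(spec: SyntheticSpec, n_tcr_residues: int) -> EnergySystem:
    """Energy matrix + contact map under which exactly the planted motifs score high.

    Each planted motif position is linked to one dedicated TCR residue of
    a distinct residue type, and the single matrix entry (that TCR type,
    the motif residue at that position) is set to ``energy_boost``; the
    matrix is zero elsewhere. The returned wild-type peptide is a
    background sequence carrying every planted motif, so its energy is
    energy_boost x (number of motif-position contacts).
    """
    if not spec.planted_motifs:
        raise ValueError("energy system requires at least one planted motif")
    motif_residue: dict[int, str] = {}
    for pm in spec.planted_motifs:
        for offset, aa in enumerate(pm.motif):
            motif_residue[pm.start + offset] = aa
    positions = sorted(motif_residue)
    if n_tcr_residues < len(positions):
        raise ValueError(
            f"need at least {len(positions)} TCR residues to contact every motif position"
        )
    if len(positions) > 20:
        raise ValueError("at most 20 motif positions supported (distinct TCR residue types)")
    J = np.zeros((20, 20))
    contacts = []
    for k, pos in enumerate(positions):
        tcr_type = ALPHABET[k]  # distinct per contacted position
        J[AA_TO_INDEX[tcr_type], AA_TO_INDEX[motif_residue[pos]]] = spec.energy_boost
        contacts.append(Contact(tcr_index=k + 1, tcr_residue=tcr_type, peptide_position=pos))
    rng = _child_rng(spec.seed, 1)
    wt = _random_sequence(rng, spec.length, spec.background)
    for pm in spec.planted_motifs:
        wt[pm.start - 1 : pm.start - 1 + len(pm.motif)] = list(pm.motif)
    return EnergySystem(
        energy_matrix=EnergyMatrix(J),
        contact_map=ContactMap(tuple(contacts), r_max=DEFAULT_R_MAX),
        wt_peptide="".join(wt),
    )


def generate_coordinates(
    cmap: ContactMap,
    r_max: float = DEFAULT_R_MAX,
    length: int | None = None,
    peptide_seq: str | None = None,
) -> pd.DataFrame:
    """Synthesize a coordinate table whose contact map at ``r_max`` is exactly ``cmap``.

    Peptide residues are laid out collinearly at 6 Å spacing; each TCR
    residue is placed off-axis above the centroid of its contacted
    positions, at a height chosen so contacted pairs sit at most
    r_max - 0.5 away and every other pair at least r_max + 0.5 away.
    Requests with no off-axis solution (e.g. one TCR residue contacting
    two positions that straddle an uncontacted one) raise a ValueError
    rather than silently violating the map.
    """
    if len(cmap) == 0:
        raise ValueError("contact map must be nonempty")
    L = length if length is not None else max(cmap.contacted_positions())
    if max(cmap.contacted_positions()) > L:
        raise ValueError("contacted position beyond requested peptide length")
    if peptide_seq is not None:
        validate_sequence(peptide_seq)
        if len(peptide_seq) != L:
            raise ValueError("peptide_seq length must match the coordinate table length")
    else:
        peptide_seq = "A" * L

    x_of = {p: p * _BACKBONE_SPACING for p in range(1, L + 1)}
    rows = [
        {
            "chain": "peptide",
            "residue_index": p,
            "residue_type": peptide_seq[p - 1],
            "x": x_of[p],
            "y": 0.0,
            "z": 0.0,
        }
        for p in range(1, L + 1)
    ]

    by_tcr: dict[int, list[Contact]] = {}
    for c in cmap.contacts:
        by_tcr.setdefault(c.tcr_index, []).append(c)
    near = r_max - _CONTACT_MARGIN
    far = r_max + _CONTACT_MARGIN
    for tcr_index in sorted(by_tcr):
        group = by_tcr[tcr_index]
        types = {c.tcr_residue for c in group}
        if len(types) > 1:
            raise ValueError(f"TCR residue {tcr_index} listed with multiple residue types")
        targets = sorted(c.peptide_position for c in group)
        cx = 0.5 * (x_of[targets[0]] + x_of[targets[-1]])
        a2 = max((x_of[p] - cx) ** 2 for p in targets)
        others = [p for p in range(1, L + 1) if p not in targets]
        b2 = min(((x_of[p] - cx) ** 2 for p in others), default=math.inf)
        y2_hi = near**2 - a2
        y2_lo = max(0.0, far**2 - b2) if math.isfinite(b2) else 0.0
        if y2_lo > y2_hi:
            raise ValueError(
                f"geometrically infeasible contact set {targets} for TCR residue {tcr_index}"
            )
        y = math.sqrt(0.5 * (y2_lo + y2_hi))
        rows.append(
            {
                "chain": "tcr",
                "residue_index": tcr_index,
                "residue_type": group[0].tcr_residue,
                "x": cx,
                "y": y,
                "z": 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["chain", "residue_index", "residue_type", "x", "y", "z"])
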