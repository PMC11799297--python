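"""In-silico positional mutation scan of selected motifs.

Each selected di/tripeptide motif is substituted (overwriting, fixed
length) at every feasible start position of a baseline peptide; the
mutant's contact energy is compared against the wild-type baseline.
Positive energy gains localize where a motif enhances predicted
binding, and placements are aggregated — optionally weighted by the
motif's selection weight |w| — into a 20 x L amino-acid-by-position
heatmap normalized to a unit maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import ContactMap, EnergyMatrix, binding_energy
from .features import ALPHABET, AA_TO_INDEX, validate_sequence

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Per-start energy deltas for one motif scanned along one baseline peptide."""

    wt_peptide: str
    wt_energy: float
    motif: str
    table: pd.DataFrame  # columns: motif, start, mutant_energy, delta_e


def scan_motif(
    wt_peptide: str, motif: str, cmap: ContactMap, J: EnergyMatrix
) -> ScanResult:
    """Substitute ``motif`` at every start 1..L-len(motif)+1 and record energy deltas."""
    validate_sequence(wt_peptide)
    validate_sequence(motif)
    if len(motif) not in (2, 3):
        raise ValueError("scanned motifs are dipeptides or tripeptides (length 2 or 3)")
    L = len(wt_peptide)
    if L < len(motif):
        raise ValueError("peptide shorter than motif")
    wt_energy = binding_energy(wt_peptide, cmap, J)
    rows = []
    for start in range(1, L - len(motif) + 2):
        mutant = wt_peptide[: start - 1] + motif + wt_peptide[start - 1 + len(motif) :]
        e = binding_energy(mutant, cmap, J)
        rows.append(
            {"motif": motif, "start": start, "mutant_energy": e, "delta_e": e - wt_energy}
        )
    return ScanResult(
        wt_peptide=wt_peptide,
        wt_energy=wt_energy,
        motif=motif,
        table=pd.DataFrame(rows),
    )


def aggregate_heatmap(
    results: list[ScanResult],
    motif_weights: dict[str, float] | None,
    length: int,
    mode: str = "weighted",
) -> pd.DataFrame:
    """Fold positive-gain placements into a 20 x L heatmap (rows = amino acids).

    H[a, p] sums, over placements (motif, start) with delta_e > 0 whose
    residue a lands at position p, |w_motif| * delta_e ("weighted" mode)
    or plain delta_e ("indicator" mode, all motifs weighted equally).
    The matrix is divided by its maximum when positive.
    """
    if mode not in ("weighted", "indicator"):
        raise ValueError("mode must be 'weighted' or 'indicator'")
    H = np.zeros((20, length))
    for res in results:
        w = 1.0
        if mode == "weighted":
            if motif_weights is None or res.motif not in motif_weights:
                raise ValueError(f"no selection weight supplied for motif {res.motif!r}")
            w = abs(motif_weights[res.motif])
        for row in res.table.itertuples():
            if row.delta_e <= 0:
                continue
            for offset, aa in enumerate(res.motif):
                pos = row.start + offset
                if pos <= length:
                    H[AA_TO_INDEX[aa], pos - 1] += w * row.delta_e
    peak = H.max()
    if peak > 0:
        H /= peak
    return pd.DataFrame(H, index=list(ALPHABET), columns=range(1, length + 1))


def scan_profile(result: ScanResult) -> pd.Series:
    """delta_e as a function of start position (length L - len(motif) + 1)."""
    return pd.Series(
        result.table["delta_e"].to_numpy(),
        index=result.table["start"].to_numpy(),
        name=result.motif,
    )


def write_scan_profiles(results: list[ScanResult], path) -> pd.DataFrame:
    """Export per-motif position curves as CSV (rows = start, one column per motif)."""
    profiles = pd.DataFrame({r.motif: scan_profile(r) for r in results})
    profiles.index.name = "start"
    profiles.to_csv(path)
    return profiles


def motif_features_to_scan(ranked_features: list[str], weights: pd.Series, top_k: int = 10):
    """Pull scannable di/tri motifs (and their |w|) out of ranked feature names.

    Recognizes the dipeptide/tripeptide composition and bigram/trigram
    N-gram naming schemes; other features (unigrams, global descriptors)
    have no positional substitution and are skipped.
    """
    prefixes = ("DPC_", "TPC_", "NG2_", "NG3_")
    motifs: dict[str, float] = {}
    for name in ranked_features:
        for pre in prefixes:
            if name.startswith(pre):
                motif = name[len(pre):]
                if motif not in motifs:
                    motifs[motif] = abs(float(weights[name]))
                break
        if len(motifs) >= top_k:
            break
    return motifs
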