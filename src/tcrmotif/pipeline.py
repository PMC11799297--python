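"""End-to-end pipeline driver.

Chains the stages in method order: library (synthetic or loaded) ->
contact-energy Z-scores against decoys -> midpoint threshold -> read
threshold -> labels -> undersampling -> featurization -> L1 selection ->
balanced logistic evaluation -> positional mutation scan and heatmap.
One global seed fans out deterministically to per-stage child seeds so
each stage is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import energy as en
from . import evaluate as ev
from . import features as feat
from . import scan as sc
from . import select as sel
from .io import PeptideRecord
from .synthetic import EnergySystem, SyntheticSpec, generate_energy_system, generate_library

logger = logging.getLogger(__name__)

_STAGES = ("library", "decoys", "undersample", "selection", "evaluation")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (all < 2**31) from one global seed."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(len(_STAGES)) % (2**31)
    return {name: int(s) for name, s in zip(_STAGES, states)}


@dataclass
class LabelingOutcome:
    """Labeled library plus the thresholding evidence behind the labels."""

    records: list[PeptideRecord]
    balanced: list[PeptideRecord]
    threshold: en.ThresholdResult
    case_z: pd.DataFrame  # columns: id, reads, energy, z, presumed_strong
    decoy_mean: float
    decoy_sd: float


def label_library(
    records: list[PeptideRecord],
    cmap: en.ContactMap,
    J: en.EnergyMatrix,
    n_top: int = 500,
    n_strong_train: int = 140,
    n_decoys: int = en.DEFAULT_N_DECOYS,
    bins: int = en.DEFAULT_BINS,
    seed: int = 0,
) -> LabelingOutcome:
    """Label a read-count library as strong/weak binders via decoy Z-scores.

    The ``n_top`` highest-read peptides form the threshold-calibration
    cases; the top ``n_strong_train`` of those are presumed strong. Each
    presumed-strong peptide contributes ``n_decoys`` randomized decoys to
    the energy ensemble used for standardization. The Z threshold is the
    midpoint between the class histogram peaks, mapped back to a read
    count; the whole library is then labeled (reads >= threshold -> 1)
    and balanced by undersampling the weak class.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to label")
    seeds = stage_seeds(seed)
    by_reads = sorted(records, key=lambda r: (-r.reads, r.id))
    cases = by_reads[: min(n_top, len(by_reads))]
    n_train = min(n_strong_train, max(1, len(cases) - 1))
    presumed = cases[:n_train]

    rng = np.random.default_rng(seeds["decoys"])
    decoys: list[str] = []
    for rec in presumed:
        decoys.extend(en.generate_decoys(rec.sequence, n=n_decoys, seed=rng))
    decoy_e = en.binding_energies(decoys, cmap, J)
    case_e = en.binding_energies([r.sequence for r in cases], cmap, J)
    zset = en.z_scores(case_e, decoy_e)

    presumed_mask = np.zeros(len(cases), dtype=bool)
    presumed_mask[:n_train] = True
    thr = en.find_threshold(zset.z[presumed_mask], zset.z[~presumed_mask], bins=bins)
    # Rank-aligned mapping: the cases are ranked by Z and the partition is
    # carried over to the same rank in the read ordering, so one chance
    # high-Z outlier with low reads cannot collapse the read threshold.
    z_sorted = np.sort(zset.z)[::-1]
    reads_sorted = sorted((r.reads for r in cases), reverse=True)
    read_thr = en.map_threshold_to_reads(
        list(zip(z_sorted, reads_sorted)), thr.z_threshold
    )
    thr.read_threshold = read_thr

    labeled = en.label_peptides(records, read_thr)
    balanced = en.undersample(labeled, seed=seeds["undersample"])
    case_table = pd.DataFrame(
        {
            "id": [r.id for r in cases],
            "reads": [r.reads for r in cases],
            "energy": case_e,
            "z": zset.z,
            "presumed_strong": presumed_mask,
        }
    )
    logger.info(
        "labeling: z threshold %.3f (peaks %.3f / %.3f) -> read threshold %d",
        thr.z_threshold,
        thr.peak_strong,
        thr.peak_weak,
        read_thr,
    )
    return LabelingOutcome(
        records=labeled,
        balanced=balanced,
        threshold=thr,
        case_z=case_table,
        decoy_mean=zset.decoy_mean,
        decoy_sd=zset.decoy_sd,
    )


def weakest_homopolymer(length: int, cmap: en.ContactMap, J: en.EnergyMatrix) -> str:
    """The minimum-energy homopolymer: a motif-free scan baseline."""
    candidates = [aa * length for aa in feat.ALPHABET]
    energies = en.binding_energies(candidates, cmap, J)
    return candidates[int(np.argmin(energies))]


@dataclass
class StudyResult:
    """Everything one end-to-end run produces."""

    spec: SyntheticSpec
    system: EnergySystem
    labeling: LabelingOutcome
    selection: dict[str, sel.LassoResult]
    metrics: pd.DataFrame
    scan_results: list[sc.ScanResult]
    heatmap: pd.DataFrame
    baseline_peptide: str


def run_study(
    spec: SyntheticSpec,
    n_tcr_residues: int | None = None,
    categories=("ngram",),
    fixed_lambda: float | None = 0.01,
    lasso_config: sel.LassoConfig | None = None,
    split_spec: ev.SplitSpec | None = None,
    n_top: int = 500,
    n_strong_train: int = 140,
    n_decoys: int = en.DEFAULT_N_DECOYS,
    scan_top_k: int = 10,
    heatmap_mode: str = "weighted",
) -> StudyResult:
    """Synthetic end-to-end study: simulate, label, select, evaluate, scan.

    The mutation scan runs the top selected di/tri motifs along a
    motif-free baseline (weakest homopolymer), so positive energy gains
    localize the planted positions.
    """
    seeds = stage_seeds(spec.seed)
    motif_positions = {
        p for pm in spec.planted_motifs for p in pm.positions
    }
    n_tcr = n_tcr_residues if n_tcr_residues is not None else len(motif_positions)
    system = generate_energy_system(spec, n_tcr)
    records = generate_library(spec)
    labeling = label_library(
        records,
        system.contact_map,
        system.energy_matrix,
        n_top=n_top,
        n_strong_train=n_strong_train,
        n_decoys=n_decoys,
        seed=spec.seed,
    )

    labels = np.array([r.label for r in labeling.balanced])
    sequences = [r.sequence for r in labeling.balanced]
    selection: dict[str, sel.LassoResult] = {}
    for category in categories:
        X = feat.encode_sequences(sequences, category=category)
        params = feat.fit_normalizer(X)
        Xn = feat.apply_normalizer(params, X)
        if fixed_lambda is not None:
            selection[category] = sel.fit_at_lambda(Xn, labels, fixed_lambda)
        else:
            selection[category] = sel.cv_lambda(
                Xn, labels, lasso_config or sel.LassoConfig(seed=seeds["selection"])
            )

    metrics = ev.run_evaluation(
        labeling.balanced,
        categories=categories,
        lasso_config=lasso_config,
        split_spec=split_spec or ev.SplitSpec(seed=seeds["evaluation"]),
        fixed_lambda=fixed_lambda,
    )

    primary = selection[categories[0]]
    motifs = sc.motif_features_to_scan(primary.ranked_features, primary.weights, top_k=scan_top_k)
    baseline = weakest_homopolymer(spec.length, system.contact_map, system.energy_matrix)
    scan_results = [
        sc.scan_motif(baseline, m, system.contact_map, system.energy_matrix) for m in motifs
    ]
    heatmap = sc.aggregate_heatmap(scan_results, motifs, spec.length, mode=heatmap_mode)
    return StudyResult(
        spec=spec,
        system=system,
        labeling=labeling,
        selection=selection,
        metrics=metrics,
        scan_results=scan_results,
        heatmap=heatmap,
        baseline_peptide=baseline,
    )
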