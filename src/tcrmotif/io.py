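"""File formats: peptide libraries, energy matrices, contact maps, coordinates.

Plain-text layouts:

* peptide CSV — header ``id,sequence,reads[,label]``
* peptide FASTA — headers ``id|reads`` (label, when present, as a third field)
* energy matrix TSV — 21x21 grid, first row/column the residue letters
  in canonical alphabet order
* contact map TSV — columns ``tcr_index  tcr_residue  peptide_position``
* coordinate TSV — columns ``chain  residue_index  residue_type  x  y  z``
* feature matrices — dense CSV, or MTX with a feature-name sidecar
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy import COORD_COLUMNS, Contact, ContactMap, EnergyMatrix, DEFAULT_R_MAX
from .features import ALPHABET, AA_TO_INDEX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: identifier, sequence, post-selection read count, optional label."""

    id: str
    sequence: str
    reads: int
    label: int | None = None

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise ValueError(f"record {self.id!r}: reads must be non-negative")
        if self.label not in (None, 0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0, 1 or None")


def _validate_records(records: list[PeptideRecord], source: str) -> list[PeptideRecord]:
    if not records:
        raise ValueError(f"{source}: no peptide records found")
    bad = []
    for lineno, rec in enumerate(records, start=1):
        for pos, ch in enumerate(rec.sequence, start=1):
            if ch not in AA_TO_INDEX:
                bad.append(f"record {lineno} ({rec.id}): bad symbol {ch!r} at position {pos}")
                break
    if bad:
        raise ValueError(f"{source}: invalid sequences:\n" + "\n".join(bad))
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        offenders = [r.id for r in records if len(r.sequence) != len(records[0].sequence)]
        raise ValueError(
            f"{source}: mixed sequence lengths {sorted(lengths)}; offenders: {offenders[:10]}"
        )
    return records


def read_peptides(path: str | Path, format: str = "csv") -> list[PeptideRecord]:
    """Read a peptide library from CSV (``id,sequence,reads[,label]``) or FASTA."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, dtype={"id": str, "sequence": str})
        required = {"id", "sequence", "reads"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: CSV must have columns {sorted(required)}")
        records = []
        for i, row in df.iterrows():
            label = None
            if "label" in df.columns and not pd.isna(row["label"]):
                label = int(row["label"])
            try:
                records.append(
                    PeptideRecord(
                        id=str(row["id"]),
                        sequence=str(row["sequence"]),
                        reads=int(row["reads"]),
                        label=label,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
    elif format == "fasta":
        records = []
        for seqrec in SeqIO.parse(str(path), "fasta"):
            fields = seqrec.id.split("|")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: FASTA header {seqrec.id!r} must be 'id|reads[|label]'"
                )
            label = int(fields[2]) if len(fields) > 2 else None
            records.append(
                PeptideRecord(
                    id=fields[0], sequence=str(seqrec.seq), reads=int(fields[1]), label=label
                )
            )
    else:
        raise ValueError(f"unknown peptide format {format!r}")
    return _validate_records(records, str(path))


def write_peptides(records: list[PeptideRecord], path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(
            {
                "id": [r.id for r in records],
                "sequence": [r.sequence for r in records],
                "reads": [r.reads for r in records],
                "label": [r.label if r.label is not None else "" for r in records],
            }
        )
        df.to_csv(path, index=False)
    elif format == "fasta":
        seqrecs = []
        for r in records:
            header = f"{r.id}|{r.reads}" + (f"|{r.label}" if r.label is not None else "")
            seqrecs.append(SeqRecord(Seq(r.sequence), id=header, description=""))
        SeqIO.write(seqrecs, str(path), "fasta")
    else:
        raise ValueError(f"unknown peptide format {format!r}")


# ---------------------------------------------------------------------------
# Energy system formats
# ---------------------------------------------------------------------------


def read_energy_matrix(path: str | Path) -> EnergyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape != (20, 20):
        raise ValueError(f"{path}: energy matrix must be 20x20, got {df.shape}")
    if list(df.index) != list(ALPHABET) or list(df.columns) != list(ALPHABET):
        raise ValueError(f"{path}: residue axes must be in canonical order {ALPHABET}")
    return EnergyMatrix(df.to_numpy(float))


def write_energy_matrix(J: EnergyMatrix, path: str | Path) -> None:
    J.to_frame().to_csv(path, sep="\t")


def read_contact_map(path: str | Path, r_max: float = DEFAULT_R_MAX) -> ContactMap:
    df = pd.read_csv(path, sep="\t")
    required = {"tcr_index", "tcr_residue", "peptide_position"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: contact map must have columns {sorted(required)}")
    contacts = tuple(
        Contact(int(row.tcr_index), str(row.tcr_residue), int(row.peptide_position))
        for row in df.itertuples()
    )
    return ContactMap(contacts, r_max=r_max)


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "tcr_index": [c.tcr_index for c in cmap.contacts],
            "tcr_residue": [c.tcr_residue for c in cmap.contacts],
            "peptide_position": [c.peptide_position for c in cmap.contacts],
        }
    ).to_csv(path, sep="\t", index=False)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: coordinate table missing columns {sorted(missing)}")
    return df


def write_coordinates(coords: pd.DataFrame, path: str | Path) -> None:
    coords.loc[:, COORD_COLUMNS].to_csv(path, sep="\t", index=False)


def coordinates_from_pdb(path: str | Path, peptide_chain: str, tcr_chains: list[str]) -> pd.DataFrame:
    """One representative point (C-alpha) per residue from a PDB file.

    Residues of ``peptide_chain`` become the 'peptide' chain (positions
    renumbered 1..L in order); residues of ``tcr_chains`` become 'tcr'
    rows with a running 1-based index.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", str(path))
    model = next(structure.get_models())
    rows = []
    tcr_counter = 0
    for chain in model:
        if chain.id == peptide_chain:
            role = "peptide"
        elif chain.id in tcr_chains:
            role = "tcr"
        else:
            continue
        pep_counter = 0
        for residue in chain:
            if "CA" not in residue:
                continue
            try:
                letter = protein_letters_3to1[residue.get_resname().upper()]
            except KeyError:
                continue
            ca = residue["CA"].coord
            if role == "peptide":
                pep_counter += 1
                idx = pep_counter
            else:
                tcr_counter += 1
                idx = tcr_counter
            rows.append(
                {
                    "chain": role,
                    "residue_index": idx,
                    "residue_type": letter,
                    "x": float(ca[0]),
                    "y": float(ca[1]),
                    "z": float(ca[2]),
                }
            )
    return pd.DataFrame(rows, columns=list(COORD_COLUMNS))


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------


def write_feature_matrix(m: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Dense CSV, or sparse MTX plus ``<stem>.features.txt``/``<stem>.rows.txt`` sidecars."""
    path = Path(path)
    if format == "csv":
        m.to_csv(path)
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(m.to_numpy()))
        path.with_suffix(".features.txt").write_text("\n".join(map(str, m.columns)) + "\n")
        path.with_suffix(".rows.txt").write_text("\n".join(map(str, m.index)) + "\n")
    else:
        raise ValueError(f"unknown feature-matrix format {format!r}")


def read_feature_matrix(path: str | Path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path, index_col=0)
    if format == "mtx":
        mat = scipy.io.mmread(str(path)).toarray()
        cols = path.with_suffix(".features.txt").read_text().splitlines()
        rows = path.with_suffix(".rows.txt").read_text().splitlines()
        return pd.DataFrame(mat, index=rows, columns=cols)
    raise ValueError(f"unknown feature-matrix format {format!r}")
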