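"""Reading, writing and validation of labeled protein datasets.

A dataset couples a FASTA file of amino-acid sequences with a sidecar
metadata table (TSV with a header row) carrying, per record id, the source
species, the optimal growth temperature (OGT, degrees Celsius) of that
species where known, and the binary thermophilicity label (1 = thermophilic,
i.e. OGT at or above 60 degrees C; 0 = nonthermophilic, OGT at or below 30).
Labels and OGT may be absent at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 proteinogenic amino acids, alphabetical one-letter codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: metadata table columns; ``evidence`` is optional
META_COLUMNS = ("id", "species", "ogt", "label")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its metadata.

    Attributes
    ----------
    id : str
        Unique accession-like token.
    sequence : str
        Amino-acid sequence over the 20-letter alphabet (uppercase).
    species : str
        Source species name.
    ogt : float or None
        Optimal growth temperature of the source species in degrees C.
    label : int or None
        1 = thermophilic, 0 = nonthermophilic; None when unknown.
    """

    id: str
    sequence: str
    species: str = ""
    ogt: float | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_valid_alphabet(self) -> bool:
        return set(self.sequence) <= _AA_SET


class Dataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    def __init__(self, records: Iterable[ProteinRecord], provenance: str = ""):
        self.records: list[ProteinRecord] = list(records)
        self.provenance = provenance
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
        self._by_id = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> ProteinRecord:
        return self._by_id[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def sequences(self) -> list[str]:
        return [rec.sequence for rec in self.records]

    @property
    def labels(self) -> list[int | None]:
        return [rec.label for rec in self.records]

    @property
    def species_set(self) -> set[str]:
        return {rec.species for rec in self.records}

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {0: 0, 1: 0}
        for rec in self.records:
            if rec.label is not None:
                counts[rec.label] += 1
        return counts

    def subset(self, ids: Iterable[str], provenance: str | None = None) -> "Dataset":
        """Records with the given ids, in this dataset's order."""
        wanted = set(ids)
        missing = wanted - set(self._by_id)
        if missing:
            raise KeyError(f"ids not in dataset: {sorted(missing)[:5]}")
        return Dataset(
            [rec for rec in self.records if rec.id in wanted],
            provenance=provenance if provenance is not None else self.provenance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "species": [r.species for r in self.records],
                "ogt": [r.ogt for r in self.records],
                "label": [r.label for r in self.records],
                "length": [len(r) for r in self.records],
            }
        )


def read_fasta_with_metadata(fasta_path: str | Path, meta_path: str | Path) -> Dataset:
    """Join a FASTA file with its metadata table on record id.

    Every FASTA record must have a metadata row; ``ogt``/``label`` fields may
    be empty. Input order of the FASTA file is preserved. Sequences are
    case-folded to uppercase before any validation.
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype={"id": str, "species": str})
    for col in ("id", "species"):
        if col not in meta.columns:
            raise ValueError(f"metadata table {meta_path} lacks required column {col!r}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in metadata: {dupes[:5]}")
    meta = meta.set_index("id")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid = seq_rec.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        if rid not in meta.index:
            raise KeyError(f"FASTA record {rid!r} has no row in metadata table {meta_path}")
        row = meta.loc[rid]
        ogt = row.get("ogt")
        label = row.get("label")
        ogt = None if pd.isna(ogt) else float(ogt)
        label = None if pd.isna(label) else int(label)
        records.append(
            ProteinRecord(
                id=rid,
                sequence=str(seq_rec.seq).upper(),
                species="" if pd.isna(row["species"]) else str(row["species"]),
                ogt=ogt,
                label=label,
            )
        )
    return Dataset(records, provenance=str(fasta_path))


def write_fasta_with_metadata(ds: Dataset, fasta_path: str | Path, meta_path: str | Path) -> None:
    """Inverse of :func:`read_fasta_with_metadata` (missing fields → empty)."""
    seq_records = [SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in ds]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    ds.to_dataframe().drop(columns="length").to_csv(meta_path, sep="\t", index=False)


def validate_alphabet(ds: Dataset) -> Dataset:
    """Keep only records whose sequences use the 20 proteinogenic amino acids.

    Filtering semantics: invalid records are dropped (with a logged count),
    never raised on. Idempotent.
    """
    kept = [rec for rec in ds if rec.is_valid_alphabet]
    n_dropped = len(ds) - len(kept)
    if n_dropped:
        logger.info("validate_alphabet: dropped %d of %d records", n_dropped, len(ds))
    return Dataset(kept, provenance=ds.provenance)


def filter_evidence(ds: Dataset, meta_path: str | Path | None = None) -> Dataset:
    """Drop records marked as predicted / inferred by homology.

    Homology-inferred entries cannot be recognised from sequence alone, so
    this honours an optional ``evidence`` metadata column (dropping rows whose
    value contains "predicted" or "inferred"); without that column it is a
    no-op.
    """
    if meta_path is None:
        return ds
    meta = pd.read_csv(meta_path, sep="\t", dtype={"id": str})
    if "evidence" not in meta.columns:
        return ds
    bad = {
        str(row["id"])
        for _, row in meta.iterrows()
        if isinstance(row["evidence"], str)
        and any(tok in row["evidence"].lower() for tok in ("predicted", "inferred"))
    }
    kept = [rec for rec in ds if rec.id not in bad]
    if len(kept) != len(ds):
        logger.info("filter_evidence: dropped %d records", len(ds) - len(kept))
    return Dataset(kept, provenance=ds.provenance)


def write_predictions(ds: Dataset, scores, out_path: str | Path, threshold: float = 0.5) -> None:
    """Write per-record thermophilicity scores as TSV.

    Columns: id, species, score, predicted_label. The decision boundary maps
    to the positive class (score >= threshold → 1). Row order = input order.
    """
    scores = list(scores)
    if len(scores) != len(ds):
        raise ValueError(f"{len(scores)} scores for {len(ds)} records")
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score {s} outside [0, 1]")
    df = pd.DataFrame(
        {
            "id": ds.ids,
            "species": [r.species for r in ds],
            "score": [f"{s:.6f}" for s in scores],
            "predicted_label": [int(s >= threshold) for s in scores],
        }
    )
    df.to_csv(out_path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def relabel(rec: ProteinRecord, **changes) -> ProteinRecord:
    """Functional update of a frozen record."""
    return replace(rec, **changes)
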