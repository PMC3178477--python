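"""Domain types and file I/O for spectral-count matrices and sample metadata.

A spectral-count matrix holds one nonnegative integer per (protein, LC-MS/MS
run): the number of peptide fragment spectra confidently assigned to that
protein in that run. Runs are annotated with the cancer group, patient and
replicate index they came from. Non-detection is a count of zero, never a
missing cell — spectral counting treats absence of evidence as zero evidence.

Files are UTF-8, tab-separated, with a header row. The counts file has an
``accession`` column followed by one column per run; the metadata file has
``sample_id``, ``group``, ``patient_id`` and ``replicate`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleInfo",
    "CountMatrix",
    "PatientRecord",
    "SchemaError",
    "read_count_matrix",
    "write_count_matrix",
    "read_patient_table",
]


class SchemaError(ValueError):
    """A file's columns do not match the expected layout."""


@dataclass(frozen=True)
class SampleInfo:
    """One LC-MS/MS run: which patient, group and technical replicate."""

    sample_id: str
    group: str
    patient_id: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")


# TNM strings like T1N0M0; stage vocabulary of resectable lung cancer.
_STAGES = {"IA", "IB", "IIA", "IIB", "IIIA", "IIIB"}


@dataclass(frozen=True)
class PatientRecord:
    """One row of the patient characteristics table."""

    group: str
    patient_no: int
    gender: str
    age: int
    tnm: str
    stage: str

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be M or F, got {self.gender!r}")
        t = self.tnm
        if not (
            len(t) == 6
            and t[0] == "T"
            and t[2] == "N"
            and t[4] == "M"
            and t[1].isdigit()
            and t[3].isdigit()
            and t[5].isdigit()
        ):
            raise ValueError(f"malformed TNM string: {t!r}")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class CountMatrix:
    """Spectral counts for ``protein_ids`` (rows) across ``samples`` (columns).

    Parameters
    ----------
    protein_ids
        Unique protein accessions, row order of ``counts``.
    samples
        One :class:`SampleInfo` per column of ``counts``.
    counts
        Integer array of shape ``(n_proteins, n_samples)``, all cells >= 0.
    protein_names
        Optional human-readable name (entry name and/or description) per
        protein; defaults to the accession.
    """

    protein_ids: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray
    protein_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.all(np.equal(np.mod(as_int, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = as_int.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.shape != (len(self.protein_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.samples)} samples"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids")
        pr = [(s.patient_id, s.replicate) for s in self.samples]
        if len(set(pr)) != len(pr):
            raise ValueError("duplicate (patient_id, replicate) pairs")
        if not self.protein_names:
            self.protein_names = list(self.protein_ids)
        elif len(self.protein_names) != len(self.protein_ids):
            raise ValueError("protein_names length mismatch")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.protein_ids == other.protein_ids
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    """Read a count matrix and its sample metadata from tab-separated files.

    Every counts column after ``accession`` must be described in the metadata
    file; unknown columns are rejected rather than silently dropped. Column
    order of the counts file is preserved.
    """
    cdf = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if cdf.columns[0] != "accession":
        raise SchemaError(
            f"first counts column must be 'accession', got {cdf.columns[0]!r}"
        )
    mdf = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "group", "patient_id", "replicate"}
    missing = required - set(mdf.columns)
    if missing:
        raise SchemaError(f"metadata file lacks columns: {sorted(missing)}")
    meta = {
        row.sample_id: SampleInfo(
            sample_id=row.sample_id,
            group=row.group,
            patient_id=row.patient_id,
            replicate=int(row.replicate),
        )
        for row in mdf.itertuples()
    }
    sample_cols = list(cdf.columns[1:])
    unknown = [s for s in sample_cols if s not in meta]
    if unknown:
        raise SchemaError(f"counts columns without metadata: {unknown}")
    raw = cdf[sample_cols].to_numpy() if sample_cols else np.zeros((len(cdf), 0))
    if raw.size and not np.issubdtype(np.asarray(raw).dtype, np.integer):
        arr = np.asarray(raw, dtype=float)
        if not np.all(np.mod(arr, 1) == 0):
            raise ValueError("non-integer count cell")
        raw = arr.astype(np.int64)
    return CountMatrix(
        protein_ids=list(cdf["accession"]),
        samples=[meta[s] for s in sample_cols],
        counts=np.asarray(raw, dtype=np.int64).reshape(len(cdf), len(sample_cols)),
    )


def write_count_matrix(matrix: CountMatrix, counts_path, metadata_path) -> None:
    """Write ``matrix`` so that :func:`read_count_matrix` round-trips exactly."""
    cdf = pd.DataFrame(
        matrix.counts, columns=[s.sample_id for s in matrix.samples]
    )
    cdf.insert(0, "accession", matrix.protein_ids)
    cdf.to_csv(counts_path, sep="\t", index=False)
    mdf = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "group": [s.group for s in matrix.samples],
            "patient_id": [s.patient_id for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
        }
    )
    mdf.to_csv(metadata_path, sep="\t", index=False)


def read_patient_table(path) -> list[PatientRecord]:
    """Read a patient characteristics table (group, patient_no, gender, age, TNM, stage)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    required = ["group", "patient_no", "gender", "age", "tnm", "stage"]
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"patient table lacks columns: {sorted(missing)}")
    return [
        PatientRecord(
            group=r.group,
            patient_no=int(r.patient_no),
            gender=r.gender,
            age=int(r.age),
            tnm=r.tnm,
            stage=r.stage,
        )
        for r in df.itertuples()
    ]
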