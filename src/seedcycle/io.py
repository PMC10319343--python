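"""Tabular input/output for the analysis suite.

The central container is :class:`IntensityTable`, a protein-group × sample
matrix of label-free quantification (LFQ) intensities in the dialect of a
MaxQuant ``proteinGroups.txt`` export: one row per protein group, one
intensity column per sample, and ``0`` encoding a missing quantification.
Gene sets are consumed from standard GMT files.  All other inputs and
outputs are plain CSV.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Row-identifier prefixes conventionally used for decoy and contaminant
#: entries in search-engine output; such rows are dropped on read.
EXCLUDED_ID_PREFIXES = ("CON__", "REV__")


@dataclass
class IntensityTable:
    """Protein-group intensity matrix with sample→condition design.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein ID with one column per sample.
        Values are non-negative raw intensities; ``0`` means the protein
        was not quantified in that sample.
    peptide_counts
        Series of peptide counts per protein (``>= 1``), aligned to the
        intensity index.
    condition_of
        Mapping from sample label to condition label.  Every sample column
        must be present.
    """

    intensities: pd.DataFrame
    peptide_counts: pd.Series
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein IDs: {dupes}")
        self.intensities = self.intensities.astype(float)
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed (0 = missing)")
        self.peptide_counts = self.peptide_counts.reindex(idx)
        if self.peptide_counts.isna().any():
            missing = idx[self.peptide_counts.isna()].tolist()
            raise ValueError(f"peptide counts missing for proteins: {missing}")
        self.peptide_counts = self.peptide_counts.astype(int)
        if (self.peptide_counts < 1).any():
            raise ValueError("peptide counts must be >= 1")
        self.condition_of = dict(self.condition_of)
        unmapped = [s for s in self.samples if s not in self.condition_of]
        if unmapped:
            raise ValueError(f"samples without a condition: {unmapped}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order of the sample columns."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.samples if self.condition_of[s] == condition]
        if not out:
            raise KeyError(f"no samples for condition {condition!r}")
        return out

    def subset(
        self,
        proteins: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "IntensityTable":
        """Return a copy restricted to the given proteins and/or samples."""
        mat = self.intensities
        if proteins is not None:
            mat = mat.loc[list(proteins)]
        if samples is not None:
            mat = mat[list(samples)]
        cond = {s: self.condition_of[s] for s in mat.columns}
        return IntensityTable(mat.copy(), self.peptide_counts.loc[mat.index].copy(), cond)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of unquantified (zero) entries."""
        return self.intensities == 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTable):
            return NotImplemented
        return (
            self.intensities.equals(other.intensities)
            and self.peptide_counts.equals(other.peptide_counts)
            and self.condition_of == other.condition_of
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as read from a GMT file."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, name: str, description: str, members: Sequence[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        # collapse duplicate members, preserving first-appearance order
        deduped = tuple(dict.fromkeys(members))
        self.sets[name] = GeneSet(name, description, deduped)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def _normalize_intensity(values: pd.Series) -> pd.Series:
    """Coerce empty cells and NaN literals to 0 (missing); reject negatives."""
    numeric = pd.to_numeric(values, errors="coerce").fillna(0.0)
    if (numeric < 0).any():
        raise ValueError(f"negative intensity in column {values.name!r}")
    return numeric


def read_protein_groups(
    path,
    intensity_prefix: str = "Intensity ",
    id_column: str = "Protein IDs",
    peptides_column: str = "Peptides",
    condition_of: Mapping[str, str] | None = None,
) -> IntensityTable:
    """Read a proteinGroups-style tab-separated table.

    Only three pieces of the (wide, version-dependent) format are used: the
    protein identifier column, the peptide-count column, and the per-sample
    intensity columns identified by ``intensity_prefix``.  Decoy and
    contaminant rows (IDs starting with ``REV__`` / ``CON__``) are dropped.
    Zeros, empty cells, and ``NaN`` literals in intensity columns all
    normalize to 0 (missing).

    When ``condition_of`` is ``None`` every sample becomes its own
    condition; pass the experimental design to group replicates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [id_column, peptides_column]
    absent = [c for c in required if c not in df.columns]
    intensity_cols = [c for c in df.columns if c.startswith(intensity_prefix) and c != intensity_prefix.rstrip()]
    if not intensity_cols:
        absent.append(f"{intensity_prefix}<sample>")
    if absent:
        raise ValueError(f"missing required columns: {absent}")

    ids = df[id_column].astype(str)
    keep = ~ids.str.startswith(EXCLUDED_ID_PREFIXES)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d decoy/contaminant rows", n_dropped)
    df = df.loc[keep]
    ids = ids.loc[keep]
    if ids.duplicated().any():
        raise ValueError(f"duplicate protein IDs: {ids[ids.duplicated()].unique().tolist()}")

    samples = [c[len(intensity_prefix):] for c in intensity_cols]
    mat = pd.DataFrame(
        {s: _normalize_intensity(df[c]).to_numpy() for s, c in zip(samples, intensity_cols)},
        index=pd.Index(ids, name="protein_id"),
    )
    peptides = pd.to_numeric(df[peptides_column], errors="raise").astype(int)
    peptides.index = mat.index
    if condition_of is None:
        condition_of = {s: s for s in samples}
    return IntensityTable(mat, peptides, dict(condition_of))


def write_protein_groups(
    table: IntensityTable,
    path,
    intensity_prefix: str = "Intensity ",
    id_column: str = "Protein IDs",
    peptides_column: str = "Peptides",
) -> None:
    """Write an :class:`IntensityTable` in the dialect `read_protein_groups` reads."""
    out = pd.DataFrame({id_column: table.protein_ids})
    out[peptides_column] = table.peptide_counts.to_numpy()
    for s in table.samples:
        out[f"{intensity_prefix}{s}"] = table.intensities[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_design(path) -> dict[str, str]:
    """Read a two-column sample→condition design CSV (header: sample,condition)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"design file lacks column {col!r}")
    return dict(zip(df["sample"], df["condition"]))


def write_design(condition_of: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(condition_of), "condition": list(condition_of.values())}
    ).to_csv(path, index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then members, tab-separated."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT lines need >= 3 tab-separated fields")
            collection.add(fields[0], fields[1], [m for m in fields[2:] if m])
    if len(collection) == 0:
        logger.warning("GMT file %s contained no gene sets", path)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def write_results_table(records: Sequence[Mapping], path) -> None:
    """Write a list of homogeneous record dicts as CSV.

    Column order follows the first record; missing values serialize as
    empty fields and booleans as ``true``/``false`` literals so the file
    round-trips without pandas-specific conventions.
    """
    df = pd.DataFrame.from_records(list(records))
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def read_results_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna()) <= {"true", "false"}:
            df[col] = df[col].map({"true": True, "false": False})
    return df


# ---------------------------------------------------------------------------
# Schema'd CSV readers for the physiology assays
# ---------------------------------------------------------------------------

GERMINATION_COLUMNS = ["group", "replicate", "time_days", "new_germinations", "n_seeds"]
COMET_COLUMNS = ["slide", "group", "c0", "c1", "c2", "c3", "c4"]
QPCR_COLUMNS = ["reaction", "gene", "sample", "cycle", "fluorescence"]


def _read_schema_csv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    absent = [c for c in columns if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: missing required columns {absent}")
    return df


def read_germination_counts(path) -> pd.DataFrame:
    """Long-format germination counts: group, replicate, time_days, new_germinations, n_seeds."""
    return _read_schema_csv(path, GERMINATION_COLUMNS)


def read_comet_counts(path) -> pd.DataFrame:
    """Comet nucleoid class counts: slide, group, c0..c4."""
    df = _read_schema_csv(path, COMET_COLUMNS)
    counts = df[["c0", "c1", "c2", "c3", "c4"]].to_numpy()
    if (counts < 0).any():
        raise ValueError("comet class counts must be non-negative")
    return df


def read_qpcr_curves(path) -> pd.DataFrame:
    """Background-subtracted amplification curves: reaction, gene, sample, cycle, fluorescence."""
    return _read_schema_csv(path, QPCR_COLUMNS)
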