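"""OTU tables, sample metadata and the depth/rarefaction primitives.

The exchange objects of the whole pipeline live here: :class:`OtuTable`
(taxa x samples integer counts) and :class:`SampleMetadata` (per-sample
host, family, body site and demographic annotations in the style of a
QIIME mapping file).  Count tables are read and written as classic
tab-separated OTU tables or as BIOM (JSON v1 or HDF5 v2.1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "AgeClass",
    "BODY_SITES",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "filter_low_depth",
    "rarefy",
    "assign_age_class",
]

BODY_SITES = ("palm", "forehead", "stool", "tongue")

# canonical field -> default mapping-file column name; callers can override
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "host_id": "host_subject_id",
    "family_id": "family_id",
    "body_site": "body_site",
    "hand_side": "hand_side",
    "age_years": "age",
    "gender": "sex",
    "is_parent": "parent",
    "has_dog": "dog",
}


class FormatError(ValueError):
    """A file does not parse in the declared dialect."""


class ValidationError(ValueError):
    """Parsed data violates a table or metadata invariant."""


class DepthError(ValueError):
    """A sample is too shallow for the requested subsampling depth."""


class AgeClass(Enum):
    """Age groups used throughout the cohort analyses."""

    INFANT = "infant"  # age < 2 years
    CHILD = "child"    # 2 <= age < 18 years
    ADULT = "adult"    # age >= 18 years


@dataclass
class OtuTable:
    """A taxa x samples table of non-negative integer read counts.

    Parameters
    ----------
    taxon_ids
        Row labels (opaque OTU identifiers), unique.
    sample_ids
        Column labels, unique.
    counts
        ``(len(taxon_ids), len(sample_ids))`` array of non-negative ints.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        if counts.size and np.any(counts < 0):
            raise ValidationError("negative counts present")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if counts.size and np.any(np.abs(counts - rounded) > 1e-9):
                raise ValidationError("non-integer counts present")
            counts = rounded
        self.counts = counts.astype(np.int64)

    # -- convenience accessors -------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """Count vector over taxa for one sample."""
        return self.counts[:, self.sample_index(sample_id)].copy()

    def depths(self) -> np.ndarray:
        """Per-sample column sums (library sizes)."""
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return OtuTable(list(self.taxon_ids), [self.sample_ids[i] for i in idx],
                        self.counts[:, idx].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample annotations driving sink/source roles and grouping.

    Wraps a DataFrame indexed by sample ID with the canonical columns
    ``host_id, family_id, body_site, hand_side, age_years, gender,
    is_parent, has_dog``.  ``body_site`` is always present; ``hand_side``
    is non-missing only for palms.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dups[:5]}")
        for col in ("host_id", "family_id", "body_site"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        for col in ("hand_side", "age_years", "gender", "is_parent", "has_dog"):
            if col not in df.columns:
                df[col] = pd.NA
        bad = set(df["body_site"].dropna()) - set(BODY_SITES)
        if bad:
            raise ValidationError(f"unknown body_site values: {sorted(bad)}")
        if df["body_site"].isna().any():
            missing = df.index[df["body_site"].isna()].tolist()
            raise ValidationError(f"body_site missing for samples: {missing[:5]}")
        nonpalm = df["body_site"] != "palm"
        df.loc[nonpalm, "hand_side"] = pd.NA
        self.frame = df

    # -- lookups ----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.frame.index

    def body_site(self, sample_id: str) -> str:
        return self.frame.at[sample_id, "body_site"]

    def host_of(self, sample_id: str) -> str:
        return self.frame.at[sample_id, "host_id"]

    def family_of(self, sample_id: str) -> str:
        return self.frame.at[sample_id, "family_id"]

    def palms(self) -> list[str]:
        return list(self.frame.index[self.frame["body_site"] == "palm"])

    def non_palms(self) -> list[str]:
        return list(self.frame.index[self.frame["body_site"] != "palm"])

    def samples_of_site(self, site: str) -> list[str]:
        return list(self.frame.index[self.frame["body_site"] == site])

    def samples_of_host(self, host_id: str, site: str | None = None) -> list[str]:
        mask = self.frame["host_id"] == host_id
        if site is not None:
            mask &= self.frame["body_site"] == site
        return list(self.frame.index[mask])

    def relation(self, source_id: str, palm_id: str) -> str:
        """'self', 'family' or 'unrelated' of a source's host to a palm's owner."""
        if self.host_of(source_id) == self.host_of(palm_id):
            return "self"
        if self.family_of(source_id) == self.family_of(palm_id):
            return "family"
        return "unrelated"

    def age_class(self, sample_id: str) -> AgeClass | None:
        age = self.frame.at[sample_id, "age_years"]
        if pd.isna(age):
            return None
        return assign_age_class(float(age))

    def restrict(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, format: str = "auto") -> OtuTable:
    """Read an OTU table from classic TSV or BIOM (JSON or HDF5).

    ``format='auto'`` sniffs: HDF5 magic bytes -> biom-hdf5, leading '{'
    -> biom-json, otherwise classic TSV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        head = path.open("rb").read(8)
        if head.startswith(b"\x89HDF"):
            format = "biom"
        elif head.lstrip().startswith(b"{"):
            format = "biom"
        else:
            format = "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        head = path.open("rb").read(4)
        if head.startswith(b"\x89HDF"):
            return _read_biom_hdf5(path)
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> OtuTable:
    """Classic QIIME-style OTU table: '#' comments, header row of sample IDs,
    first column taxon ID.  The header is the last '#'-prefixed line before the
    data (e.g. '#OTU ID\\t...') or, failing that, the first line."""
    lines = path.read_text().splitlines()
    header_idx = None
    first_data = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#"):
            header_idx = i
        else:
            first_data = i
            break
    if first_data is None and header_idx is None:
        raise FormatError(f"{path}: empty file")
    if header_idx is None:
        header_idx = first_data
        first_data += 1
    header = lines[header_idx].lstrip("#").rstrip("\n").split("\t")
    sample_ids = header[1:]
    taxon_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[first_data or len(lines):], start=(first_data or len(lines)) + 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
            )
        taxon_ids.append(fields[0])
        row = []
        for colname, val in zip(sample_ids, fields[1:]):
            try:
                x = float(val)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric count {val!r} in column {colname!r}") from None
            if x < 0 or x != int(x):
                raise ValidationError(
                    f"{path}:{lineno}: count {val!r} in column {colname!r} is negative or non-integer"
                )
            row.append(int(x))
        rows.append(row)
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(sample_ids)), dtype=np.int64)
    return OtuTable(taxon_ids, sample_ids, counts)


def _read_biom_json(path: Path) -> OtuTable:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    try:
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        counts = np.zeros(shape, dtype=np.float64)
        if doc.get("matrix_type", "sparse") == "dense":
            counts = np.asarray(doc["data"], dtype=np.float64)
        else:
            for r, c, v in doc["data"]:
                counts[int(r), int(c)] = v
    except (KeyError, TypeError, IndexError) as exc:
        raise FormatError(f"{path}: malformed BIOM JSON ({exc})") from exc
    return OtuTable(taxon_ids, sample_ids, counts)


def _read_biom_hdf5(path: Path) -> OtuTable:
    with h5py.File(path, "r") as f:
        try:
            taxon_ids = [x.decode() if isinstance(x, bytes) else str(x)
                         for x in f["observation/ids"][...]]
            sample_ids = [x.decode() if isinstance(x, bytes) else str(x)
                          for x in f["sample/ids"][...]]
            data = f["observation/matrix/data"][...]
            indices = f["observation/matrix/indices"][...]
            indptr = f["observation/matrix/indptr"][...]
        except KeyError as exc:
            raise FormatError(f"{path}: malformed BIOM HDF5 ({exc})") from exc
    counts = np.zeros((len(taxon_ids), len(sample_ids)))
    # CSR over observations (rows)
    for r in range(len(taxon_ids)):
        sl = slice(indptr[r], indptr[r + 1])
        counts[r, indices[sl]] = data[sl]
    return OtuTable(taxon_ids, sample_ids, counts)


def write_otu_table(table: OtuTable, path: str | Path, format: str = "tsv") -> None:
    """Write a table as classic TSV or BIOM JSON (dense)."""
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("# Constructed by handtracer\n")
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
            for t, row in zip(table.taxon_ids, table.counts):
                fh.write(t + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    elif format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "handtracer",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.tolist(),
        }
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown format {format!r}")


_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


def _parse_bool(val) -> object:
    if pd.isna(val):
        return pd.NA
    if isinstance(val, (bool, np.bool_)):
        return bool(val)
    s = str(val).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    return pd.NA


def read_metadata(path: str | Path,
                  column_map: Mapping[str, str] | None = None) -> SampleMetadata:
    """Read a QIIME-style tab-delimited mapping file.

    The first column must be the sample ID (conventionally ``#SampleID``).
    ``column_map`` maps canonical field names to the file's column names;
    defaults cover the common conventions and only need overriding when the
    deposited file uses different headers.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    lower = {c.lower(): c for c in df.columns}
    out = pd.DataFrame(index=df.index)
    for canon, col in cmap.items():
        # mapped name first, then the canonical name itself (round-trips
        # files written by write_metadata)
        src = lower.get(col.lower(), lower.get(canon.lower()))
        out[canon] = df[src] if src is not None else pd.NA
    if out["body_site"].notna().any():
        out["body_site"] = out["body_site"].str.strip().str.lower()
    if out["hand_side"].notna().any():
        out["hand_side"] = out["hand_side"].str.strip().str.lower().replace({"na": pd.NA})
    out["age_years"] = pd.to_numeric(out["age_years"], errors="coerce")
    out["is_parent"] = out["is_parent"].map(_parse_bool)
    out["has_dog"] = out["has_dog"].map(_parse_bool)
    return SampleMetadata(out)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.frame.copy()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# depth filter / rarefaction / age classes
# ---------------------------------------------------------------------------

def filter_low_depth(table: OtuTable, min_reads: int = 1000) -> OtuTable:
    """Drop samples with fewer than ``min_reads`` total reads.

    The 1,000-read default is the depth cut applied to the cohort table
    before any source tracking.  Taxon rows are left untouched even if
    they become all-zero.
    """
    keep = table.depths() >= min_reads
    ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuTable(list(table.taxon_ids), ids, table.counts[:, keep].copy())


def rarefy(counts: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    A multivariate hypergeometric draw over the read multiset; bit-identical
    across calls with the same seed.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth <= 0:
        raise ValueError("depth must be positive")
    if total < depth:
        raise DepthError(f"sample has {total} reads < requested depth {depth}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def assign_age_class(age_years: float) -> AgeClass:
    """Map an age in years to infant (<2), child (2..<18) or adult (>=18).

    Ages exactly 2 and 18 fall on the open boundaries of the published
    groupings; they are resolved upward (2 -> child, 18 -> adult).
    """
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        raise ValueError("age is missing")
    if age_years < 0:
        raise ValueError("age must be non-negative")
    if age_years < 2:
        return AgeClass.INFANT
    if age_years < 18:
        return AgeClass.CHILD
    return AgeClass.ADULT
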