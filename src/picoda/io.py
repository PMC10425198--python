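"""Reading and writing PICRUSt2-style abundance tables and sample metadata.

PICRUSt2 writes predicted functional profiles as ``pred_metagenome_unstrat.tsv``:
a header row, a first column of feature identifiers (KO, EC or MetaCyc
pathway IDs) and one column of non-negative predicted abundances per sample.
This module reads that dialect (TSV, CSV or TXT) without reformatting,
houses the in-memory containers used by every downstream stage, and writes
all outputs back as headered TSV.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("picoda")

__all__ = [
    "Namespace",
    "FeatureTable",
    "SampleMetadata",
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "align",
    "DataError",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


class Namespace(str, enum.Enum):
    """Feature identifier namespace of an abundance table."""

    KO = "KO"
    EC = "EC"
    METACYC = "METACYC"
    KEGG_PATHWAY = "KEGG_PATHWAY"
    UNKNOWN = "UNKNOWN"


_KO_RE = re.compile(r"K\d{5}")
_KEGG_PATHWAY_RE = re.compile(r"ko\d{5}")
_EC_RE = re.compile(r"(EC:)?\d+\.\d+\.\d+(\.\d+)?(\.-)?")


@dataclass
class FeatureTable:
    """Feature-by-sample matrix of non-negative predicted abundances.

    Rows are features (KOs, enzymes or pathways), columns are samples.
    ``values`` has shape ``(len(feature_ids), len(sample_ids))``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    namespace: Namespace = Namespace.UNKNOWN
    comments: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = _duplicates(self.feature_ids)
            raise DataError(f"duplicate feature IDs: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise DataError(f"duplicate sample IDs: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("abundance values must be finite")
        if np.any(self.values < 0):
            raise DataError("abundance values must be non-negative")
        if self.values.size == 0:
            raise DataError("empty abundance table")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="function"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        namespace: Namespace = Namespace.UNKNOWN,
        comments: tuple[str, ...] = (),
    ) -> "FeatureTable":
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            namespace=namespace,
            comments=comments,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self, sample_ids=list(sample_ids), values=self.values[:, idx]
        )

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return replace(
            self, feature_ids=list(feature_ids), values=self.values[idx, :]
        )


@dataclass
class SampleMetadata:
    """Sample-to-group assignments (plus optional covariates) for DA contrasts."""

    sample_ids: list[str]
    group: pd.Series  # indexed by sample_id
    reference_group: str
    covariates: Optional[pd.DataFrame] = None  # indexed by sample_id

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample IDs in metadata")
        self.group = self.group.reindex(self.sample_ids)
        if self.group.isna().any():
            missing = list(self.group.index[self.group.isna()])
            raise DataError(f"samples without a group label: {missing[:5]}")
        if self.reference_group not in set(self.group):
            raise DataError(
                f"reference group {self.reference_group!r} is not a group level"
            )
        if self.covariates is not None:
            self.covariates = self.covariates.reindex(self.sample_ids)

    @property
    def levels(self) -> list[str]:
        """Group levels, reference first, the rest in sorted order."""
        others = sorted(set(self.group) - {self.reference_group})
        return [self.reference_group] + others

    def samples_in(self, level: str) -> list[str]:
        return [s for s in self.sample_ids if self.group[s] == level]

    def validate_for_da(self) -> None:
        levels = self.levels
        if len(levels) < 2:
            raise DataError("differential abundance needs >= 2 group levels")
        for lev in levels:
            n = len(self.samples_in(lev))
            if n < 2:
                raise DataError(f"group {lev!r} has {n} sample(s); need >= 2")

    def select_samples(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        keep = list(sample_ids)
        cov = self.covariates.loc[keep] if self.covariates is not None else None
        return SampleMetadata(
            sample_ids=keep,
            group=self.group.loc[keep],
            reference_group=self.reference_group,
            covariates=cov,
        )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table_file(path: Path) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Read a delimited file, peeling off leading ``# ...`` comment lines.

    A first header cell such as ``#OTU ID`` is *not* a comment: only lines
    starting with ``#`` followed by whitespace are treated as comments.
    """
    if not path.exists():
        raise DataError(f"file not found: {path}")
    comments: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    for line in lines:
        if re.match(r"^#\s", line):
            comments.append(line.rstrip("\n"))
            start += 1
        else:
            break
    if start >= len(lines):
        raise DataError(f"empty table: {path}")
    from io import StringIO

    frame = pd.read_csv(
        StringIO("".join(lines[start:])), sep=_delimiter_for(path), dtype=str
    )
    return frame, tuple(comments)


def infer_namespace(feature_ids: Sequence[str], metacyc_ids: Optional[set[str]] = None) -> Namespace:
    """Infer the identifier namespace from ID patterns.

    All IDs must match a pattern for it to win; KEGG pathway IDs (``ko``
    prefix, lowercase) are checked before KO gene-family IDs (``K`` prefix).
    """
    ids = list(feature_ids)
    if all(_KEGG_PATHWAY_RE.fullmatch(i) for i in ids):
        return Namespace.KEGG_PATHWAY
    if all(_KO_RE.fullmatch(i) for i in ids):
        return Namespace.KO
    if all(_EC_RE.fullmatch(i) for i in ids):
        return Namespace.EC
    if metacyc_ids is None:
        from .ko2kegg import load_reference_map

        metacyc_ids = set(load_reference_map().metacyc_info)
    if any(i in metacyc_ids for i in ids):
        return Namespace.METACYC
    return Namespace.UNKNOWN


def read_abundance(
    path: str | Path, namespace_hint: Optional[Namespace | str] = None
) -> FeatureTable:
    """Read a PICRUSt2-style abundance table.

    The first column holds feature IDs regardless of its header string
    (PICRUSt2 writes ``function``; ``#OTU ID``, ``NAME`` and others are
    tolerated).  The delimiter is inferred from the extension: ``.csv`` is
    comma-separated, anything else tab-separated.
    """
    path = Path(path)
    frame, comments = _read_table_file(path)
    if frame.shape[1] < 2:
        raise DataError(f"no sample columns in {path}")
    feature_ids = [str(v) for v in frame.iloc[:, 0]]
    dupes = _duplicates(feature_ids)
    if dupes:
        raise DataError(f"duplicate feature IDs: {sorted(dupes)[:5]}")
    body = frame.iloc[:, 1:]
    try:
        values = body.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric abundance value in {path}: {exc}") from exc
    if len(feature_ids) == 0:
        raise DataError(f"empty table: {path}")
    if namespace_hint is not None:
        ns = Namespace(namespace_hint)
    else:
        ns = infer_namespace(feature_ids)
    table = FeatureTable(
        feature_ids=feature_ids,
        sample_ids=[str(c) for c in body.columns],
        values=values,
        namespace=ns,
        comments=comments,
    )
    logger.info(
        "read %d features x %d samples from %s (namespace %s)",
        table.n_features, table.n_samples, path, ns.value,
    )
    return table


def write_abundance(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as headered TSV, feature-ID column first."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in table.comments:
            fh.write(line + "\n")
        fh.write("function\t" + "\t".join(table.sample_ids) + "\n")
        for fid, row in zip(table.feature_ids, table.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_metadata(
    path: str | Path,
    sample_col: str,
    group_col: str,
    reference: Optional[str] = None,
    covariate_cols: Optional[Sequence[str]] = None,
) -> SampleMetadata:
    """Read a sample metadata table mapping samples to groups.

    If ``reference`` is omitted, the alphabetically first group level is the
    reference.
    """
    path = Path(path)
    frame, _ = _read_table_file(path)
    for col in (sample_col, group_col, *(covariate_cols or [])):
        if col not in frame.columns:
            raise DataError(f"column {col!r} not found in {path}")
    sample_ids = [str(v) for v in frame[sample_col]]
    dupes = _duplicates(sample_ids)
    if dupes:
        raise DataError(f"duplicate sample IDs in metadata: {sorted(dupes)[:5]}")
    group = pd.Series(
        [str(v) for v in frame[group_col]], index=sample_ids, name=group_col
    )
    levels = sorted(set(group))
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise DataError(f"reference group {ref!r} is not among levels {levels}")
    covariates = None
    if covariate_cols:
        covariates = frame[list(covariate_cols)].copy()
        covariates.index = pd.Index(sample_ids)
        for col in covariate_cols:
            try:
                covariates[col] = pd.to_numeric(covariates[col])
            except (TypeError, ValueError):
                pass  # categorical covariate, keep as strings
    return SampleMetadata(
        sample_ids=sample_ids, group=group, reference_group=ref,
        covariates=covariates,
    )


def align(
    table: FeatureTable, meta: SampleMetadata
) -> tuple[FeatureTable, SampleMetadata]:
    """Restrict table and metadata to their shared samples.

    The abundance table's sample order is canonical; metadata is reordered
    to match.  Samples dropped on either side are logged as a warning.
    """
    table_set = set(table.sample_ids)
    meta_set = set(meta.sample_ids)
    shared = [s for s in table.sample_ids if s in meta_set]
    if not shared:
        raise DataError("no samples shared between abundance table and metadata")
    dropped_table = sorted(table_set - meta_set)
    dropped_meta = sorted(meta_set - table_set)
    if dropped_table or dropped_meta:
        logger.warning(
            "align dropped samples: %s (table only), %s (metadata only)",
            dropped_table, dropped_meta,
        )
    return table.select_samples(shared), meta.select_samples(shared)
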