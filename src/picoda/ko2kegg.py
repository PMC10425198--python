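"""KO gene-family abundances -> KEGG pathway abundances.

PICRUSt2 predicts KO (KEGG Orthology) gene-family abundances but, unlike
its predecessor, no longer rolls them up into KEGG pathway abundances.
This module performs that aggregation: the abundance of a pathway in a
sample is the unweighted sum of the abundances of its member KOs.  A KO
belonging to several pathways counts fully in each (no fractional
assignment).

The KO->pathway membership map and the pathway/KO/EC/MetaCyc annotation
tables ship with the package as a pinned snapshot whose version string is
propagated into output headers for reproducibility.  The packaged snapshot
is synthetic (KEGG-style identifiers, generated memberships); a custom map
in the same two-column TSV format can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .io import DataError, FeatureTable, Namespace

logger = logging.getLogger("picoda")

__all__ = ["ReferenceMap", "load_reference_map", "ko2kegg_abundance"]


@dataclass
class ReferenceMap:
    """KO->KEGG-pathway membership plus feature annotation tables."""

    members: dict[str, set[str]]  # pathway_id -> member KO ids
    pathway_info: dict[str, dict[str, str]]  # id -> {name, description, class, map_link}
    ko_info: dict[str, str] = field(default_factory=dict)
    ec_info: dict[str, str] = field(default_factory=dict)
    metacyc_info: dict[str, str] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError("empty reference map")
        for pid, kos in self.members.items():
            if not kos:
                raise DataError(f"pathway {pid} has no member KOs")

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.members)

    @property
    def ko_universe(self) -> list[str]:
        return sorted(set().union(*self.members.values()))


def _read_two_col(text: str, what: str) -> tuple[dict[str, str], str]:
    version = "unversioned"
    out: dict[str, str] = {}
    lines = text.splitlines()
    body = []
    for line in lines:
        if line.startswith("# "):
            if "ref_map_version:" in line:
                version = line.split("ref_map_version:", 1)[1].strip()
            continue
        body.append(line)
    for i, line in enumerate(body):
        if not line.strip():
            continue
        parts = line.split("\t")
        if i == 0 and parts[0].lower() in ("id", "function", "#otu id", "name"):
            continue
        if len(parts) != 2:
            raise DataError(f"malformed {what} row: {line!r}")
        out[parts[0]] = parts[1]
    return out, version


def _packaged(name: str) -> str:
    return resources.files("picoda").joinpath("data", name).read_text()


def load_reference_map(path: Optional[str | Path] = None) -> ReferenceMap:
    """Load the packaged reference snapshot, or a user map from ``path``.

    A user map is a two-column TSV (pathway_id, ko_id); leading ``# ``
    lines are comments and may carry a ``ref_map_version:`` tag.  When a
    user map is given, the packaged annotation tables still back the
    annotation lookups.
    """
    if path is None:
        map_text = _packaged("ko_pathway_map.synthetic.tsv")
    else:
        path = Path(path)
        if not path.exists():
            raise DataError(f"reference map not found: {path}")
        map_text = path.read_text()

    version = "unversioned"
    members: dict[str, set[str]] = {}
    for line in map_text.splitlines():
        if line.startswith("# "):
            if "ref_map_version:" in line:
                version = line.split("ref_map_version:", 1)[1].strip()
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataError(f"malformed map row: {line!r}")
        pid, ko = parts
        members.setdefault(pid, set()).add(ko)
    if not members:
        raise DataError("empty reference map")

    pw_info: dict[str, dict[str, str]] = {}
    pw_text = _packaged("kegg_pathway_info.synthetic.tsv")
    for i, line in enumerate(l for l in pw_text.splitlines() if not l.startswith("# ")):
        if i == 0 or not line.strip():
            continue
        pid, name, desc, cls, link = line.split("\t")
        pw_info[pid] = {
            "name": name, "description": desc, "class": cls, "map_link": link,
        }
    # Pathways absent from the info table get minimal records so that the
    # members/pathway_info invariant holds for user-supplied maps.
    for pid in members:
        pw_info.setdefault(
            pid, {"name": "", "description": "", "class": "", "map_link": ""}
        )

    ko_info, _ = _read_two_col(_packaged("ko_info.synthetic.tsv"), "KO info")
    ec_info, _ = _read_two_col(_packaged("ec_info.synthetic.tsv"), "EC info")
    mc_info, _ = _read_two_col(_packaged("metacyc_info.synthetic.tsv"), "MetaCyc info")

    return ReferenceMap(
        members=members,
        pathway_info=pw_info,
        ko_info=ko_info,
        ec_info=ec_info,
        metacyc_info=mc_info,
        version=version,
    )


def ko2kegg_abundance(
    table: FeatureTable,
    ref_map: Optional[ReferenceMap] = None,
    drop_zero: bool = True,
) -> FeatureTable:
    """Aggregate a KO abundance table into KEGG pathway abundances.

    ``abundance(pathway, sample) = sum over member KOs present in the
    table``; member KOs absent from the table contribute zero.  With
    ``drop_zero`` (the default), pathways with all-zero abundance across
    samples are removed.  Output features are sorted pathway IDs; the
    sample set and order are unchanged.
    """
    if table.namespace != Namespace.KO:
        raise DataError(
            f"ko2kegg_abundance needs a KO table, got namespace {table.namespace.value}"
        )
    if ref_map is None:
        ref_map = load_reference_map()
    ko_pos = {k: i for i, k in enumerate(table.feature_ids)}
    pathway_ids = ref_map.pathway_ids
    out = np.zeros((len(pathway_ids), table.n_samples))
    any_hit = False
    for r, pid in enumerate(pathway_ids):
        idx = [ko_pos[k] for k in ref_map.members[pid] if k in ko_pos]
        if idx:
            any_hit = True
            out[r] = table.values[idx, :].sum(axis=0)
    if not any_hit:
        raise DataError("no KO in the table maps to any pathway in the reference map")
    if drop_zero:
        keep = out.sum(axis=1) > 0
        pathway_ids = [p for p, k in zip(pathway_ids, keep) if k]
        out = out[keep]
    logger.info(
        "converted %d KOs into %d KEGG pathways (ref map %s)",
        table.n_features, len(pathway_ids), ref_map.version,
    )
    return FeatureTable(
        feature_ids=pathway_ids,
        sample_ids=list(table.sample_ids),
        values=out,
        namespace=Namespace.KEGG_PATHWAY,
        comments=(f"# ref_map_version: {ref_map.version}",),
    )
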