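"""Annotation of KO/EC/MetaCyc/KEGG-pathway features from packaged tables.

Annotation is a pure left-join: every input row is kept, statistical
fields and ordering are untouched, and unmatched identifiers simply leave
their annotation fields empty.  KEGG pathway rows additionally receive
``pathway_name``, ``pathway_class`` and ``pathway_map``.  An online KEGG
fetch hook exists behind a flag but is a stub: all lookups are served from
the packaged offline snapshot.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import pandas as pd

from .daa import DAResult, results_to_frame
from .io import DataError, FeatureTable, Namespace
from .ko2kegg import ReferenceMap, load_reference_map

logger = logging.getLogger("picoda")

__all__ = ["pathway_annotation"]


def _description_lookup(ref_map: ReferenceMap, namespace: Namespace) -> dict[str, str]:
    if namespace == Namespace.KO:
        return ref_map.ko_info
    if namespace == Namespace.EC:
        return ref_map.ec_info
    if namespace == Namespace.METACYC:
        return ref_map.metacyc_info
    if namespace == Namespace.KEGG_PATHWAY:
        return {
            pid: info.get("description", "")
            for pid, info in ref_map.pathway_info.items()
        }
    raise DataError(f"cannot annotate namespace {namespace.value}")


def pathway_annotation(
    rows: Union[Sequence[DAResult], FeatureTable, pd.DataFrame],
    namespace: Namespace | str,
    ref_map: Optional[ReferenceMap] = None,
    online: bool = False,
) -> pd.DataFrame:
    """Annotate DA results or an abundance table with feature descriptions.

    Accepts a list of :class:`~picoda.daa.DAResult`, a
    :class:`~picoda.io.FeatureTable`, or a data frame with a ``feature``
    (or first) column of IDs.  Returns a data frame with a ``description``
    column appended (plus ``pathway_name``/``pathway_class``/
    ``pathway_map`` for the KEGG pathway namespace).  Row count and order
    are preserved exactly.
    """
    if online:
        raise NotImplementedError(
            "online KEGG annotation is a stub; packaged snapshot tables are used"
        )
    namespace = Namespace(namespace)
    if namespace == Namespace.UNKNOWN:
        raise DataError("cannot annotate the UNKNOWN namespace")
    if ref_map is None:
        ref_map = load_reference_map()

    if isinstance(rows, FeatureTable):
        frame = rows.to_frame().reset_index()
        id_col = "function"
    elif isinstance(rows, pd.DataFrame):
        frame = rows.copy()
        id_col = "feature" if "feature" in frame.columns else frame.columns[0]
    else:
        frame = results_to_frame(rows)
        id_col = "feature"

    lookup = _description_lookup(ref_map, namespace)
    ids = frame[id_col].astype(str)
    frame["description"] = [lookup.get(i, "") for i in ids]
    matched = int(sum(i in lookup for i in ids))
    if namespace == Namespace.KEGG_PATHWAY:
        info = ref_map.pathway_info
        frame["pathway_name"] = [info.get(i, {}).get("name", "") for i in ids]
        frame["pathway_class"] = [info.get(i, {}).get("class", "") for i in ids]
        frame["pathway_map"] = [info.get(i, {}).get("map_link", "") for i in ids]
    logger.info(
        "annotated %d/%d %s feature(s); %d unmatched",
        matched, len(ids), namespace.value, len(ids) - matched,
    )
    return frame
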