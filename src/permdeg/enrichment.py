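"""One-sided Fisher's-exact enrichment of a query gene list against gene
sets, and the major-TF selection rule.

Enrichment is tested on the 2x2 table

    [[overlap, query - overlap],
     [set - overlap, universe - query - set + overlap]]

with the ``greater`` alternative (the hypergeometric upper tail). A
transcription factor is flagged *major* when its target set overlaps the
differentially expressed genes in at least ``min_targets`` genes (default 5)
with p < alpha (default 0.05).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping as MappingABC
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ParameterError

logger = logging.getLogger(__name__)

#: smallest representable positive p, used to keep p in (0, 1]
_P_FLOOR = 5e-324


class GeneSetCollection(MappingABC):
    """Named gene sets with optional descriptions (the GMT model).

    Members are deduplicated preserving order; empty sets are rejected.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self._sets: dict[str, tuple[str, ...]] = {}
        self._descriptions: dict[str, str] = {}
        descriptions = descriptions or {}
        for set_id, members in sets.items():
            unique = tuple(dict.fromkeys(members))
            if not unique:
                raise ParameterError(f"gene set {set_id!r} is empty")
            self._sets[set_id] = unique
            self._descriptions[set_id] = descriptions.get(set_id, "")

    def __getitem__(self, set_id: str) -> tuple[str, ...]:
        return self._sets[set_id]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def description(self, set_id: str) -> str:
        return self._descriptions[set_id]


@dataclass(frozen=True)
class EnrichmentRow:
    """Fisher's-exact result for one gene set or one TF's target set."""

    set_or_tf_id: str
    n_universe: int
    n_query: int
    n_set: int
    n_overlap: int
    odds_ratio: float
    p_value: float
    neg_log10_p: float
    overlap_genes: tuple[str, ...]
    significant: bool


def fisher_enrich(
    query: Iterable[str],
    annotation: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
    set_id: str = "",
) -> EnrichmentRow:
    """One-sided (greater) Fisher's exact test of query/annotation overlap.

    The annotation is intersected with the universe before testing; genes in
    the query outside the universe are ignored.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ParameterError("universe must be non-empty")
    query_set = set(query) & universe_set
    annot_set = set(annotation) & universe_set
    overlap = sorted(query_set & annot_set)
    a = len(overlap)
    n_q, n_s, n_u = len(query_set), len(annot_set), len(universe_set)
    b = n_q - a
    c = n_s - a
    # hypergeom.sf(a-1, N, K, n) is P[overlap >= a]
    p = float(hypergeom.sf(a - 1, n_u, n_s, n_q))
    p = min(1.0, max(p, _P_FLOOR))
    d = n_u - n_q - n_s + a
    if b * c > 0:
        odds = a * d / (b * c)
    else:
        odds = math.inf if a > 0 else 0.0
    return EnrichmentRow(
        set_or_tf_id=set_id,
        n_universe=n_u,
        n_query=n_q,
        n_set=n_s,
        n_overlap=a,
        odds_ratio=odds,
        p_value=p,
        neg_log10_p=-math.log10(p),
        overlap_genes=tuple(overlap),
        significant=p < alpha,
    )


def _rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    columns = [
        "set_id",
        "query_label",
        "n_universe",
        "n_query",
        "n_set",
        "n_overlap",
        "odds_ratio",
        "p_value",
        "neg_log10_p",
        "significant",
        "overlap_genes",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    if len(frame):
        frame = frame.sort_values(
            ["p_value", "set_id"], kind="mergesort"
        ).reset_index(drop=True)
    return frame


def enrich_gene_sets(
    degs: Sequence[str] | Mapping[str, Sequence[str]],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
    bh_fdr: bool = False,
) -> pd.DataFrame:
    """Test every set in the collection against the DEG list.

    ``degs`` may be a single gene list or a mapping of labels to lists
    (e.g. ``{"up": [...], "down": [...]}``) tested separately. Sets disjoint
    from the universe are skipped with a warning. With ``bh_fdr`` the
    significance flag uses Benjamini-Hochberg adjusted p-values instead of
    raw ones.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ParameterError("universe must be non-empty")
    queries: dict[str, Sequence[str]]
    if isinstance(degs, Mapping):
        queries = dict(degs)
    else:
        queries = {"all": list(degs)}
    rows: list[dict] = []
    for label, query in queries.items():
        for set_id in collection:
            members = set(collection[set_id]) & universe_set
            if not members:
                logger.warning(
                    "gene set %s is disjoint from the universe; skipped", set_id
                )
                continue
            row = fisher_enrich(query, members, universe_set, alpha, set_id)
            record = {"set_id": set_id, "query_label": label}
            record.update(
                {
                    k: getattr(row, k)
                    for k in (
                        "n_universe",
                        "n_query",
                        "n_set",
                        "n_overlap",
                        "odds_ratio",
                        "p_value",
                        "neg_log10_p",
                        "significant",
                    )
                }
            )
            record["overlap_genes"] = ";".join(row.overlap_genes)
            rows.append(record)
    frame = _rows_to_frame(rows)
    if bh_fdr and len(frame):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(frame["p_value"], method="fdr_bh")
        frame["q_value"] = q
        frame["significant"] = q < alpha
    return frame


def select_major_tfs(
    tf_map: Mapping[str, Iterable[str]],
    degs: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
    min_targets: int = 5,
) -> pd.DataFrame:
    """Flag TFs whose targets are enriched for DEGs.

    A TF is *major* iff its Fisher p-value is below ``alpha`` AND it targets
    at least ``min_targets`` DEGs. TFs whose target sets are disjoint from
    the universe are skipped with a warning.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ParameterError("universe must be non-empty")
    deg_list = list(degs)
    rows: list[dict] = []
    for tf_id in sorted(tf_map):
        targets = set(tf_map[tf_id]) & universe_set
        if not targets:
            logger.warning(
                "TF %s has no targets in the universe; skipped", tf_id
            )
            continue
        row = fisher_enrich(deg_list, targets, universe_set, alpha, tf_id)
        rows.append(
            {
                "tf_id": tf_id,
                "n_universe": row.n_universe,
                "n_query": row.n_query,
                "n_set": row.n_set,
                "n_overlap": row.n_overlap,
                "odds_ratio": row.odds_ratio,
                "p_value": row.p_value,
                "neg_log10_p": row.neg_log10_p,
                "major": row.p_value < alpha and row.n_overlap >= min_targets,
                "overlap_genes": ";".join(row.overlap_genes),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "tf_id",
            "n_universe",
            "n_query",
            "n_set",
            "n_overlap",
            "odds_ratio",
            "p_value",
            "neg_log10_p",
            "major",
            "overlap_genes",
        ],
    )
    if len(frame):
        frame = frame.sort_values(
            ["p_value", "tf_id"], kind="mergesort"
        ).reset_index(drop=True)
    return frame
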