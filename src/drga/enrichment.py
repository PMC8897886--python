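"""Over-representation analysis of a driver-gene list against gene sets.

For each gene set the overlap with the query list is scored by the
one-sided hypergeometric tail probability

    p = P[Overlap >= k | N, K, n]

where N is the universe size, K the set size within the universe, n
the query size, and k the observed overlap — equivalently the
one-sided Fisher exact test on the 2x2 overlap table. Benjamini-
Hochberg q-values are computed across the returned sets; a set is
called enriched at q <= 0.05.

The universe defaults to all genes in the expression matrix and is
taken as the background a gene had a chance of appearing in the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom

from .association import ALPHA, bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    set_id: str
    description: str
    set_size: int
    overlap: int
    overlap_genes: tuple[str, ...]
    p_value: float
    q_value: float

    @property
    def significant(self) -> bool:
        return self.q_value <= ALPHA


def ora(
    query: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query and set members are intersected with the universe first; sets
    with zero overlap are omitted. Rows come back sorted by q then p.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    q_genes = [g for g in dict.fromkeys(query) if g in uni_set]
    dropped = len(set(query)) - len(q_genes)
    if dropped:
        logger.warning("%d query gene(s) outside the universe were dropped", dropped)
    if not q_genes:
        raise ValueError("no query genes remain after intersecting with the universe")
    big_n, n = len(uni), len(q_genes)
    q_set = set(q_genes)
    rows: list[EnrichmentRow] = []
    for sid, (desc, members) in sets.sets.items():
        in_uni = [g for g in members if g in uni_set]
        big_k = len(in_uni)
        hits = tuple(g for g in in_uni if g in q_set)
        k = len(hits)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(EnrichmentRow(sid, desc, big_k, k, hits, min(p, 1.0), 1.0))
    if rows:
        qvals = bh_adjust([r.p_value for r in rows])
        for r, qv in zip(rows, qvals):
            r.q_value = float(qv)
    rows.sort(key=lambda r: (r.q_value, r.p_value, r.set_id))
    return rows


def write_enrichment(rows: list[EnrichmentRow], path: str | Path) -> None:
    """Tab-delimited enrichment report (one row per overlapping set)."""
    table = pd.DataFrame(
        [
            {"set_id": r.set_id, "description": r.description, "set_size": r.set_size,
             "overlap": r.overlap, "p": r.p_value, "q": r.q_value,
             "significant": r.significant, "genes": ",".join(r.overlap_genes)}
            for r in rows
        ],
        columns=["set_id", "description", "set_size", "overlap", "p", "q",
                 "significant", "genes"],
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
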