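"""Co-expression candidate mining.

Per tissue, genes are correlated (Pearson), grouped into modules, and every
within-module gene pair is treated as potentially interacting; pairs must
recur in at least two tissues and then pass the same asymmetry and exclusion-
list protocol as the interaction filter (the publication-evidence clause is
vacuous here — co-expression pairs carry no publication field).  A per-gene
ranked co-expression signature (mean Pearson r across tissues) is also
provided.

The module detector is pluggable; the default declares each connected
component of the ``|r| >= r_min`` gene graph with at least ``min_module_size``
genes a module.  Expression values are taken as given — no normalisation or
variance stabilisation is applied here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .ppi import filter_ddr_asymmetry, filter_lists, InteractionRecord

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.6
DEFAULT_MIN_MODULE_SIZE = 5


@dataclass(frozen=True)
class CoexpressionModule:
    tissue: str
    module_id: str
    genes: frozenset


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation of a genes x samples matrix.

    Zero-variance genes are dropped with a warning (their correlation is
    undefined).  The result is symmetric with unit diagonal.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = expr.to_numpy(dtype=float)
    var = values.var(axis=1)
    keep = var > 0
    dropped = expr.index[~keep]
    if len(dropped):
        logger.warning("dropping %d zero-variance genes: %s", len(dropped),
                       list(dropped[:5]))
    values = values[keep]
    genes = expr.index[keep]
    r = np.atleast_2d(np.corrcoef(values))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=genes, columns=genes)


def detect_modules(expr: pd.DataFrame, tissue: str = "",
                   r_min: float = DEFAULT_R_MIN,
                   min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                   detector=None) -> list[CoexpressionModule]:
    """Detect correlated gene modules in one tissue.

    The default detector returns the connected components of the
    ``|r| >= r_min`` graph with at least ``min_module_size`` genes, as
    disjoint gene sets.  A custom ``detector(corr: DataFrame) -> iterable of
    gene sets`` may be supplied behind the same interface.
    """
    corr = pearson_matrix(expr)
    if detector is None:
        def detector(c):
            genes = list(c.index)
            a = np.abs(c.to_numpy()) >= r_min
            np.fill_diagonal(a, False)
            g = nx.Graph()
            g.add_nodes_from(genes)
            ii, jj = np.nonzero(np.triu(a, 1))
            g.add_edges_from((genes[i], genes[j]) for i, j in zip(ii, jj))
            return [comp for comp in nx.connected_components(g)]
    modules = []
    comps = [frozenset(c) for c in detector(corr) if len(c) >= min_module_size]
    comps.sort(key=lambda c: min(c))
    for k, comp in enumerate(comps):
        modules.append(CoexpressionModule(tissue=tissue, module_id=f"M{k + 1}",
                                          genes=comp))
    return modules


def module_pairs(modules) -> set:
    """All unordered within-module gene pairs, tagged by tissue."""
    pairs = set()
    for mod in modules:
        for a, b in combinations(sorted(mod.genes), 2):
            pairs.add(((a, b), mod.tissue))
    return pairs


def cross_tissue_filter(pairs_with_tissue, min_tissues: int = 2) -> set:
    """Keep pairs occurring in at least ``min_tissues`` distinct tissues."""
    if min_tissues < 1:
        raise ValueError("min_tissues must be >= 1")
    tissues_per_pair: dict[tuple, set] = {}
    for pair, tissue in pairs_with_tissue:
        tissues_per_pair.setdefault(pair, set()).add(tissue)
    return {p for p, ts in tissues_per_pair.items() if len(ts) >= min_tissues}


def filter_coexpr_pairs(pairs, annots, housekeeping_ids, contaminant_ids):
    """Apply the interaction-filter protocol to co-expression pairs.

    The asymmetry and exclusion-list clauses apply unchanged; the
    experimental-evidence clause is vacuous because co-expression pairs carry
    no publication metadata.  Returns ``(candidate gene list, attrition)``;
    candidates are co-expression-derived.
    """
    records = [InteractionRecord(a, b, frozenset(), 0) for a, b in sorted(pairs)]
    attrition = {"input": len(records)}
    tagged = filter_ddr_asymmetry(records, annots)
    attrition["after_asymmetry"] = len(tagged)
    tagged, candidates = filter_lists(tagged, housekeeping_ids, contaminant_ids)
    attrition["after_lists"] = len(tagged)
    attrition["candidates"] = len(candidates)
    return candidates, attrition


def rank_coexpressed(expr_by_tissue: dict, query_gene: str,
                     top_k: int = 50) -> list:
    """Rank genes by mean Pearson r to ``query_gene`` across tissues.

    Genes are sorted by descending mean r, ties broken by gene id; the query
    itself is excluded.  Duplicate gene rows are collapsed (first occurrence)
    with a warning.  Raises ``KeyError`` if the query is absent everywhere.
    """
    sums: Counter = Counter()
    counts: Counter = Counter()
    found = False
    for tissue, expr in expr_by_tissue.items():
        if expr.index.has_duplicates:
            logger.warning("duplicate gene ids in %s collapsed", tissue)
            expr = expr[~expr.index.duplicated(keep="first")]
        if query_gene not in expr.index:
            continue
        found = True
        corr = pearson_matrix(expr)
        if query_gene not in corr.index:
            continue
        col = corr[query_gene].drop(index=query_gene)
        for g, r in col.items():
            sums[g] += float(r)
            counts[g] += 1
    if not found:
        raise KeyError(f"query gene {query_gene!r} not present")
    means = [(g, sums[g] / counts[g]) for g in sums]
    means.sort(key=lambda t: (-t[1], t[0]))
    return means[:max(top_k, 0)]


def modules_to_frame(modules) -> pd.DataFrame:
    rows = [(m.tissue, m.module_id, g) for m in modules for g in sorted(m.genes)]
    return pd.DataFrame(rows, columns=["tissue", "module_id", "gene"])
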