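"""Ontology and pathway over-representation analysis.

The term-level test is the one-sided Fisher exact (hypergeometric
upper-tail) probability of seeing at least the observed number of selected
genes in a term's annotation.  To keep the enriched list short and
non-redundant, terms are organised into *levels* by the percentage of
their annotated genes that are selected (level 1 = 98-100%, level 2 =
96-98%, ... in 2%-wide bands) and visited from level 1 downwards; whenever
a term tests significant, its current annotated genes are removed from the
annotation of every term in a strictly lower-percentage level before those
levels are tested.  This elim-style penalization stops a specific enriched
term from dragging all of its ancestors along.

Enriched terms are then grouped: terms connected by an ancestor/descendant
path form one group, labelled by the most general member.  A final pass
tests each (cluster, group) pair for over-representation of the cluster's
genes among the group's genes, within the selected-gene universe.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import string
from collections.abc import Mapping
from fractions import Fraction

import networkx as nx
import pandas as pd
from scipy import stats

from .ontology import AnnotationMap, OntologyDAG

__all__ = [
    "EnrichmentResult",
    "GOGroup",
    "fisher_enrichment",
    "assign_levels",
    "elim_enrichment",
    "pathway_enrichment",
    "group_enriched_terms",
    "cluster_group_enrichment",
    "DEFAULT_ALPHA",
    "DEFAULT_LEVEL_WIDTH",
]

logger = logging.getLogger(__name__)

#: Stringent per-term significance level compensating for the absence of an
#: explicit multiple-testing correction in the elim pass.
DEFAULT_ALPHA = 0.0025
#: Width of the selected-percentage bands defining levels.
DEFAULT_LEVEL_WIDTH = 0.02


def fisher_enrichment(
    annotated_in_term: int,
    selected_in_term: int,
    universe: int,
    selected_total: int,
) -> float:
    """One-sided over-representation p-value P(X >= selected_in_term).

    X is hypergeometric: draw ``annotated_in_term`` genes from a universe
    of ``universe`` genes of which ``selected_total`` are selected.
    """
    if not (
        0 <= selected_in_term <= min(annotated_in_term, selected_total)
        and annotated_in_term <= universe
        and selected_total <= universe
    ):
        raise ValueError(
            "invalid contingency bounds: "
            f"annotated={annotated_in_term}, selected={selected_in_term}, "
            f"universe={universe}, selected_total={selected_total}"
        )
    if selected_in_term == 0:
        return 1.0
    return float(
        stats.hypergeom.sf(
            selected_in_term - 1, universe, selected_total, annotated_in_term
        )
    )


def assign_levels(
    annotations: AnnotationMap,
    selected: set[str],
    level_width: float = DEFAULT_LEVEL_WIDTH,
) -> dict[str, int]:
    """Band each term by its selected-annotation percentage.

    Level 1 covers percentages in [1 - w, 1] (closed above), level l the
    band [1 - l*w, 1 - (l-1)*w); a term with no selected genes lands in
    the deepest band.  Terms with zero annotated genes are excluded with a
    log entry.  Exact rational arithmetic avoids boundary misclassification.
    """
    w = Fraction(level_width).limit_denominator(10**6)
    levels: dict[str, int] = {}
    for term, genes in annotations.term_to_genes.items():
        a = len(genes)
        if a == 0:
            logger.info("term %s has zero annotations; excluded from levels", term)
            continue
        s = len(genes & selected)
        # level = ceil((1 - s/a) / w), floored at 1
        lvl = math.ceil(Fraction(a - s, a) / w)
        levels[term] = max(1, lvl)
    return levels


@dataclasses.dataclass
class EnrichmentResult:
    """Per-term test outcome with post-elim counts."""

    term: str
    name: str
    annotated: int  # universe genes annotated at test time
    selected: int  # selected genes annotated at test time
    p_value: float
    level: int
    enriched: bool


def elim_enrichment(
    dag: OntologyDAG,
    annotations: AnnotationMap,
    selected: set[str],
    alpha: float = DEFAULT_ALPHA,
    level_width: float = DEFAULT_LEVEL_WIDTH,
) -> list[EnrichmentResult]:
    """Level-ordered elim-style over-representation scan of all terms.

    Levels are computed once from the initial (ancestor-closed)
    annotations.  Visiting levels in increasing order, each term is tested
    with its *current* annotation set; every term with p < alpha marks its
    current genes for removal from all strictly lower-percentage levels
    before those are tested.  The universe (all annotated genes) and the
    selected total stay fixed throughout.  Returns one result per tested
    term.
    """
    universe = annotations.genes
    selected = set(selected) & universe
    n_universe = len(universe)
    n_selected = len(selected)
    term_genes = {t: set(g) for t, g in annotations.term_to_genes.items() if g}
    levels = assign_levels(annotations, selected, level_width)

    by_level: dict[int, list[str]] = {}
    for term, lvl in levels.items():
        by_level.setdefault(lvl, []).append(term)

    results: list[EnrichmentResult] = []
    for lvl in sorted(by_level):
        to_remove: set[str] = set()
        for term in sorted(by_level[lvl]):
            genes = term_genes[term]
            a = len(genes)
            s = len(genes & selected)
            p = fisher_enrichment(a, s, n_universe, n_selected) if a else 1.0
            enriched = p < alpha
            results.append(
                EnrichmentResult(
                    term=term,
                    name=dag.names.get(term, term),
                    annotated=a,
                    selected=s,
                    p_value=p,
                    level=lvl,
                    enriched=enriched,
                )
            )
            if enriched:
                to_remove |= genes
        if to_remove:
            for later_lvl in by_level:
                if later_lvl > lvl:
                    for term in by_level[later_lvl]:
                        term_genes[term] -= to_remove
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "annotated": r.annotated,
                "selected": r.selected,
                "p_value": r.p_value,
                "level": r.level,
                "enriched": int(r.enriched),
            }
            for r in sorted(results, key=lambda r: (r.p_value, r.term))
        ]
    )


def pathway_enrichment(
    gene_sets: Mapping[str, set[str]],
    selected: set[str],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Plain one-sided Fisher over-representation test per gene set.

    Member lists are intersected with the universe first; sets with empty
    intersection are skipped with a log entry.
    """
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & set(universe)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & set(universe)
        if not members:
            logger.info("gene set %s has no members in the universe; skipped", name)
            continue
        s = len(members & selected)
        p = fisher_enrichment(len(members), s, len(universe), len(selected))
        rows.append(
            {
                "pathway": name,
                "annotated": len(members),
                "selected": s,
                "p_value": p,
                "enriched": int(p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "annotated", "selected", "p_value", "enriched"])


# ---------------------------------------------------------------------------
# grouping of enriched terms


def _letter_tag(i: int) -> str:
    """A, B, ..., Z, AA, AB, ... tags for report columns."""
    letters = string.ascii_uppercase
    tag = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        tag = letters[rem] + tag
    return tag


@dataclasses.dataclass
class GOGroup:
    """Connected component of enriched terms under ancestor paths."""

    tag: str
    label: str  # most general member term
    members: list[str]

    def genes(self, annotations: AnnotationMap) -> set[str]:
        out: set[str] = set()
        for t in self.members:
            out |= annotations.term_to_genes.get(t, set())
        return out


def group_enriched_terms(dag: OntologyDAG, enriched: set[str]) -> list[GOGroup]:
    """Group enriched terms connected by an ancestor/descendant path.

    The auxiliary graph joins two enriched terms when one is an ancestor
    of the other in the DAG; groups are its connected components.  The
    label is the member that is an ancestor of every other member if one
    exists, otherwise the member of minimal depth (ties broken
    lexicographically).  Tags are capital letters assigned in
    (label depth, label id) order.
    """
    enriched = set(enriched)
    missing = enriched - dag.terms
    if missing:
        raise ValueError(f"enriched terms not in ontology: {sorted(missing)}")
    aux = nx.Graph()
    aux.add_nodes_from(enriched)
    for t in enriched:
        for anc in dag.ancestors(t) & enriched:
            aux.add_edge(t, anc)
    raw_groups = []
    for comp in nx.connected_components(aux):
        members = sorted(comp)
        dominating = [
            t for t in members if all(u == t or dag.is_ancestor(t, u) for u in members)
        ]
        if dominating:
            label = min(dominating)
        else:
            label = min(members, key=lambda t: (dag.depth(t), t))
        raw_groups.append((label, members))
    raw_groups.sort(key=lambda g: (dag.depth(g[0]), g[0]))
    return [
        GOGroup(tag=_letter_tag(i), label=label, members=members)
        for i, (label, members) in enumerate(raw_groups)
    ]


def groups_to_frame(groups: list[GOGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group": g.tag, "label": g.label, "members": ",".join(g.members)}
            for g in groups
        ],
        columns=["group", "label", "members"],
    )


def cluster_group_enrichment(
    groups: list[GOGroup],
    annotations: AnnotationMap,
    selected: set[str],
    assignment: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cluster x group over-representation within the selected genes.

    For each cluster c and group g, a one-sided Fisher test on the
    selected, clustered genes: rows = in c vs not, columns = annotated to
    any member of g vs not.  Emits the p-value, 1 - p (for significance
    profiles) and a flag at *alpha*.  Clusters with zero genes get p = 1.
    """
    clustered = {g: c for g, c in assignment.items() if g in selected and c >= 0}
    universe = set(clustered)
    n_universe = len(universe)
    clusters = sorted(set(clustered.values()))
    rows = []
    for c in clusters:
        in_cluster = {g for g, cc in clustered.items() if cc == c}
        for grp in groups:
            grp_genes = grp.genes(annotations) & universe
            overlap = len(in_cluster & grp_genes)
            if n_universe == 0 or not in_cluster:
                p = 1.0
            else:
                p = fisher_enrichment(len(grp_genes), overlap, n_universe, len(in_cluster))
            rows.append(
                {
                    "cluster": c,
                    "group": grp.tag,
                    "overlap": overlap,
                    "group_size": len(grp_genes),
                    "cluster_size": len(in_cluster),
                    "p_value": p,
                    "one_minus_p": 1.0 - p,
                    "significant": int(p < alpha),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "group", "overlap", "group_size",
            "cluster_size", "p_value", "one_minus_p", "significant",
        ],
    )
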