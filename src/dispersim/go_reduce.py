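"""Hypergeometric GO enrichment and two-level term redundancy reduction.

An ontology is a DAG of ``is_a`` edges; annotations are propagated upward
so every gene annotated to a term is annotated to all of its ancestors.
Information content is computed from the supplied annotation corpus itself.
Within-dataset redundancy reduction clusters enriched terms by relevance
semantic similarity and keeps the best-p member; cross-dataset merging
pools reduced term lists, clusters again and represents each cluster by the
maximal-IC common ancestor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from dispersim.multiple_testing import adjust

__all__ = [
    "OntologyGraph",
    "AnnotationMap",
    "TermCluster",
    "parse_obo",
    "load_annotations",
    "hypergeometric_enrichment",
    "relevance_similarity",
    "reduce_within_dataset",
    "merge_across_datasets",
]

logger = logging.getLogger(__name__)


@dataclass
class OntologyGraph:
    """DAG of terms with ``is_a`` edges pointing from child to parent."""

    graph: nx.DiGraph
    root: str

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")
        if self.root not in self.graph:
            raise ValueError(f"root term {self.root!r} not in graph")
        for t in self.graph.nodes:
            if t != self.root and not nx.has_path(self.graph, t, self.root):
                raise ValueError(f"term {t} does not reach the root")

    def ancestors(self, term: str) -> set:
        """Term itself plus every reachable parent."""
        return {term} | nx.descendants(self.graph, term)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)


def parse_obo(path: str | Path) -> OntologyGraph:
    """Minimal OBO parser: [Term] stanzas, ``id``, ``name`` and ``is_a`` only.

    Obsolete terms are skipped.  The root is the unique term without
    parents (when several exist the one reached by every other term).
    """
    graph = nx.DiGraph()
    term_id: Optional[str] = None
    in_term = False
    fields: dict[str, list[str]] = {}

    def flush() -> None:
        nonlocal term_id, fields
        if term_id and "true" not in fields.get("is_obsolete", []):
            name = fields.get("name", [term_id])[0]
            graph.add_node(term_id, name=name)
            for parent in fields.get("is_a", []):
                graph.add_edge(term_id, parent)
        term_id, fields = None, {}

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            continue
        if not in_term or ":" not in line:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        if key == "id":
            term_id = value
        elif key == "name":
            fields.setdefault("name", []).append(value)
        elif key == "is_a":
            fields.setdefault("is_a", []).append(value.split("!")[0].strip())
        elif key == "is_obsolete":
            fields.setdefault("is_obsolete", []).append(value)
    flush()

    roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
    if not roots:
        raise ValueError("ontology has no root term")
    if len(roots) > 1:
        counts = {r: len(nx.ancestors(graph, r)) for r in roots}
        roots.sort(key=lambda r: -counts[r])
    return OntologyGraph(graph=graph, root=roots[0])


@dataclass
class AnnotationMap:
    """Gene-to-term annotations propagated upward, with term probabilities."""

    ontology: OntologyGraph
    direct: Mapping[str, set]
    term_genes: dict[str, set] = field(init=False)
    probability: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        term_genes: dict[str, set] = {t: set() for t in self.ontology.terms}
        for gene, terms in self.direct.items():
            for t in terms:
                if t not in term_genes:
                    logger.warning("annotation to unknown term %s skipped", t)
                    continue
                for anc in self.ontology.ancestors(t):
                    term_genes[anc].add(gene)
        self.term_genes = term_genes
        universe = term_genes[self.ontology.root]
        n = max(len(universe), 1)
        self.probability = {t: len(g) / n for t, g in term_genes.items()}

    @property
    def genes(self) -> set:
        return self.term_genes[self.ontology.root]

    def ic(self, term: str) -> float:
        """Information content -log p(term); infinite for unannotated terms."""
        p = self.probability.get(term, 0.0)
        return -np.log(p) if p > 0 else np.inf


def load_annotations(path: str | Path, ontology: OntologyGraph) -> AnnotationMap:
    """Two-column gene/term TSV (a GAF-like column subset is accepted:
    any table whose first two used columns are gene id and term id)."""
    table = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
    if table.shape[1] < 2:
        raise ValueError("annotation table needs at least 2 columns")
    direct: dict[str, set] = {}
    for gene, term in zip(table.iloc[:, 0], table.iloc[:, 1]):
        direct.setdefault(gene, set()).add(term)
    return AnnotationMap(ontology=ontology, direct=direct)


def hypergeometric_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    annotations: AnnotationMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment over propagated terms.

    For each term with at least one gene in the set: p = P(X >= k) with
    N = |universe|, K = |universe genes of the term|, n = |gene set|.
    BH adjustment; rows with adjusted p < alpha are returned sorted by p.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set or not universe:
        raise ValueError("gene set and universe must be non-empty")
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    n = len(gene_set)
    N = len(universe)
    rows = []
    for term, genes in annotations.term_genes.items():
        K = len(genes & universe)
        if K == 0:
            continue
        k = len(genes & gene_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": annotations.ontology.name(term),
                "k": k,
                "K": K,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = adjust(table["p"].to_numpy(), "bh")
    table = table[table["q"] < alpha].sort_values(["p", "term"]).reset_index(drop=True)
    return table


def relevance_similarity(
    t1: str, t2: str, annotations: AnnotationMap
) -> float:
    """Relevance semantic similarity in [0, 1).

    ``max`` over common ancestors ``a`` of
    ``2 IC(a) / (IC(t1) + IC(t2)) * (1 - p(a))``; identical terms use
    ``a = t``; two roots give 0.
    """
    ont = annotations.ontology
    for t in (t1, t2):
        if annotations.probability.get(t, 0.0) <= 0:
            raise ValueError(f"term {t} has no annotations")
    denom = annotations.ic(t1) + annotations.ic(t2)
    if denom == 0:
        return 0.0
    common = ont.ancestors(t1) & ont.ancestors(t2)
    best = 0.0
    for a in common:
        p_a = annotations.probability.get(a, 0.0)
        if p_a <= 0:
            continue
        val = 2.0 * annotations.ic(a) / denom * (1.0 - p_a)
        best = max(best, val)
    return best


@dataclass(frozen=True)
class TermCluster:
    """A set of related terms with one representative."""

    members: tuple
    representative: str
    p_values: dict = field(default_factory=dict)  # per dataset (or single "p")


def _similarity_matrix(terms: Sequence[str], annotations: AnnotationMap) -> np.ndarray:
    n = len(terms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = relevance_similarity(
                terms[i], terms[j], annotations
            )
    return sim


def _cluster_terms(
    terms: Sequence[str], annotations: AnnotationMap, sim_threshold: float
) -> list[list[str]]:
    """Average-linkage clustering on 1 - similarity, cut at the threshold."""
    if len(terms) == 1:
        return [[terms[0]]]
    sim = _similarity_matrix(terms, annotations)
    dist = squareform(1.0 - sim, checks=False)
    tree = linkage(dist, method="average")
    labels = fcluster(tree, t=1.0 - sim_threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for term, lab in zip(terms, labels):
        clusters.setdefault(lab, []).append(term)
    return list(clusters.values())


def reduce_within_dataset(
    enriched: pd.DataFrame,
    annotations: AnnotationMap,
    sim_threshold: float = 0.8,
) -> list[TermCluster]:
    """Cluster enriched terms by similarity; representative = smallest p.

    Ties on p are broken by term id.  ``enriched`` must have columns
    ``term`` and ``p``.
    """
    if not 0.0 < sim_threshold <= 1.0:
        raise ValueError("sim_threshold must be in (0, 1]")
    if enriched.empty:
        return []
    pvals = dict(zip(enriched["term"], enriched["p"]))
    out = []
    for members in _cluster_terms(list(enriched["term"]), annotations, sim_threshold):
        rep = min(members, key=lambda t: (pvals[t], t))
        out.append(
            TermCluster(
                members=tuple(sorted(members)),
                representative=rep,
                p_values={"p": pvals[rep]},
            )
        )
    return out


def _common_ancestor_representative(
    members: Sequence[str], annotations: AnnotationMap
) -> str:
    ont = annotations.ontology
    common = set.intersection(*(ont.ancestors(t) for t in members))
    annotated = [a for a in common if annotations.probability.get(a, 0.0) > 0]
    if not annotated or annotated == [ont.root]:
        if len(annotated) <= 1:
            logger.info("cluster %s has no common ancestor beyond root", members)
    if not annotated:
        return ont.root
    return max(annotated, key=lambda a: (annotations.ic(a), a))


def merge_across_datasets(
    per_dataset: Mapping[str, Sequence[TermCluster]],
    annotations: AnnotationMap,
    sim_threshold: float = 0.8,
) -> pd.DataFrame:
    """Pool reduced term lists across datasets and merge to generic terms.

    Every dataset's representative terms are pooled and clustered at the
    threshold; each cluster is represented by the maximal-IC common ancestor
    of its members, and per dataset the minimum enrichment p among the
    dataset's members is recorded.  Output rows are ordered by decreasing
    dataset count and then increasing mean p.
    """
    if not per_dataset:
        raise ValueError("at least one dataset is required")
    term_p: dict[str, dict[str, float]] = {}
    for ds, clusters in per_dataset.items():
        for cl in clusters:
            p = cl.p_values.get("p", np.nan)
            d = term_p.setdefault(cl.representative, {})
            d[ds] = min(d.get(ds, np.inf), p)
    pooled = sorted(term_p)
    rows = []
    for members in _cluster_terms(pooled, annotations, sim_threshold):
        rep = (
            members[0]
            if len(members) == 1
            else _common_ancestor_representative(members, annotations)
        )
        per_ds: dict[str, float] = {}
        for t in members:
            for ds, p in term_p[t].items():
                per_ds[ds] = min(per_ds.get(ds, np.inf), p)
        rows.append(
            {
                "representative": rep,
                "name": annotations.ontology.name(rep),
                "members": "|".join(sorted(members)),
                "n_datasets": len(per_ds),
                "mean_p": float(np.mean(list(per_ds.values()))),
                **{f"p_{ds}": p for ds, p in sorted(per_ds.items())},
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["n_datasets", "mean_p", "representative"], ascending=[False, True, True]
    ).reset_index(drop=True)
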