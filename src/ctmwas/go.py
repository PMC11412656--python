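"""Gene-ontology enrichment of MWAS findings and term clustering.

CpGs are linked to genes when they fall inside the gene body or within a
fixed window (default 10 kb) upstream of the transcription start site
(strand-aware, to capture promoter methylation).  Term enrichment keeps the
permutation at the CpG level: the selection indicator is circularly shifted
along the genome order and genes are re-linked at every shift, which
preserves gene length and CpG-density biases in the null.  Significant
terms are clustered by shared overlapping genes with Louvain community
detection, and each gene is marked as "defining" for the single cluster
that best claims it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_BP = 10_000


@dataclass(frozen=True)
class GeneSet:
    """One gene-set term (GO term): id, display name, category, member genes."""

    term_id: str
    name: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"term {self.term_id} is empty")


@dataclass
class GeneSetCollection:
    """An ordered collection of gene-set terms (GMT-compatible)."""

    terms: list[GeneSet]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.terms == other.terms

    def get(self, term_id: str) -> GeneSet:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out.update(t.genes)
        return out


@dataclass
class TermClusterGraph:
    """Gene-overlap graph of significant terms with Louvain communities."""

    graph: nx.Graph
    clusters: dict[str, int]
    table: pd.DataFrame  # filtered enrichment table indexed by term_id

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))


# ---------------------------------------------------------------------------
# CpG -> gene linking
# ---------------------------------------------------------------------------

def _validate_annotation(annotation: pd.DataFrame) -> None:
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annotation["gene_id"].duplicated().any():
        dups = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene IDs: {dups[:5]}")
    if (annotation["start"] > annotation["end"]).any():
        bad = annotation.loc[annotation["start"] > annotation["end"], "gene_id"]
        raise ValueError(f"start > end for genes: {bad.tolist()[:5]}")
    if not annotation["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-' for every gene")


def _extended_interval(start: int, end: int, strand: str, upstream: int) -> tuple[int, int]:
    """Gene body plus the upstream promoter window, 1-based inclusive."""
    if strand == "+":
        return max(1, start - upstream), end
    return start, end + upstream


def link_cpgs_to_genes(
    cpgs: Sequence[tuple[str, int]],
    annotation: pd.DataFrame,
    upstream: int = DEFAULT_UPSTREAM_BP,
) -> dict[tuple[str, int], list[str]]:
    """Map each CpG to the genes it is linked to (body or upstream window).

    A CpG at position ``pos`` links to a gene iff pos lies in [start, end],
    or within ``upstream`` bp upstream of the TSS (before ``start`` on '+',
    after ``end`` on '-').  Multi-gene links are allowed; coordinates are
    1-based inclusive.
    """
    if upstream < 0:
        raise ValueError("upstream must be nonnegative")
    _validate_annotation(annotation)
    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples(index=False):
        lo, hi = _extended_interval(int(row.start), int(row.end), row.strand, upstream)
        trees.setdefault(str(row.chrom), IntervalTree()).addi(lo, hi + 1, row.gene_id)
    out: dict[tuple[str, int], list[str]] = {}
    for chrom, pos in cpgs:
        tree = trees.get(str(chrom))
        hits = sorted(iv.data for iv in tree[int(pos)]) if tree is not None else []
        out[(str(chrom), int(pos))] = hits
    return out


# ---------------------------------------------------------------------------
# selection of CpGs feeding the GO analysis
# ---------------------------------------------------------------------------

def select_go_input(
    primary: pd.DataFrame,
    replication: pd.DataFrame,
    thr_primary: float = 1e-6,
    thr_replication: float = 0.05,
    require_nominal_replication: bool = True,
) -> set[tuple[str, int]]:
    """CpGs suggestive in any primary analysis unit that also replicate.

    A CpG qualifies when its primary p-value is below ``thr_primary`` in
    some analysis unit and, in the same unit, the replication p-value is
    below ``thr_replication`` (or is merely present, with
    ``require_nominal_replication=False``).  The union over analysis units
    is returned.
    """
    key = ["chrom", "pos", "analysis_unit"]
    sugg = primary.loc[primary["p"] < thr_primary, key + ["p"]]
    if len(sugg) == 0:
        logger.warning("no suggestive CpGs in the primary results")
        return set()
    rep = replication[key + ["p"]].rename(columns={"p": "p_rep"})
    merged = sugg.merge(rep, on=key, how="left")
    if require_nominal_replication:
        ok = merged["p_rep"] < thr_replication
    else:
        ok = merged["p_rep"].notna()
    hits = merged.loc[ok.fillna(False)]
    return {(str(c), int(p)) for c, p in zip(hits["chrom"], hits["pos"])}


# ---------------------------------------------------------------------------
# permutation term enrichment
# ---------------------------------------------------------------------------

def go_term_enrichment(
    selected_cpgs: set[tuple[str, int]],
    universe_cpgs: Sequence[tuple[str, int]],
    annotation: pd.DataFrame,
    collection: GeneSetCollection,
    n_permutations: int = 10_000,
    seed: int = 0,
    upstream: int = DEFAULT_UPSTREAM_BP,
    continuity: float = 0.5,
) -> pd.DataFrame:
    """Per-term enrichment of genes linked to selected CpGs, by CpG-level shifts.

    The gene universe is every annotated gene belonging to at least one
    term.  For each term the 2x2 table over that universe compares genes
    linked to the selected CpGs with the term's members; the null
    distribution of the odds ratio comes from circularly shifting the
    CpG-level selection indicator along the genome-ordered universe and
    re-linking genes at each shift.

    Returns a table with one row per testable term: term_id, name,
    category, overlap, odds_ratio, p, genes (tuple of overlapping genes).
    """
    from .enrichment import chromosome_sort_key

    universe = sorted(
        {(str(c), int(p)) for c, p in universe_cpgs},
        key=lambda k: (chromosome_sort_key(k[0]), k[1]),
    )
    n = len(universe)
    cols = [
        "term_id", "name", "category", "overlap", "odds_ratio", "p", "genes",
    ]
    if len(selected_cpgs) == 0 or n == 0:
        return pd.DataFrame(columns=cols)

    links = link_cpgs_to_genes(universe, annotation, upstream=upstream)
    term_gene_universe = sorted(
        collection.all_genes() & set(annotation["gene_id"])
    )
    gene_index = {g: i for i, g in enumerate(term_gene_universe)}
    n_genes = len(term_gene_universe)
    if n_genes == 0:
        logger.warning("no annotated genes belong to any term")
        return pd.DataFrame(columns=cols)

    link_matrix = np.zeros((n, n_genes), dtype=bool)
    for i, key in enumerate(universe):
        for g in links[key]:
            gi = gene_index.get(g)
            if gi is not None:
                link_matrix[i, gi] = True

    terms = [t for t in collection if any(g in gene_index for g in t.genes)]
    for t in collection:
        if t not in terms:
            logger.info("term %s has no genes in the universe; skipped", t.term_id)
    term_matrix = np.zeros((n_genes, len(terms)), dtype=bool)
    for ti, t in enumerate(terms):
        for g in t.genes:
            gi = gene_index.get(g)
            if gi is not None:
                term_matrix[gi, ti] = True

    sel_idx = np.array(
        [i for i, key in enumerate(universe) if key in selected_cpgs], dtype=np.int64
    )
    if len(sel_idx) == 0:
        logger.warning("no selected CpG lies in the universe")
        return pd.DataFrame(columns=cols)

    def _or_per_term(gene_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = (gene_mask.astype(float) @ term_matrix).astype(float)
        g_size = float(gene_mask.sum())
        t_size = term_matrix.sum(axis=0).astype(float)
        b = g_size - a
        c = t_size - a
        d = n_genes - g_size - t_size + a
        stacked = np.stack([a, b, c, d])
        any_zero = (stacked == 0).any(axis=0)
        st = stacked + continuity * any_zero
        return (st[0] * st[3]) / (st[1] * st[2]), a

    obs_mask = link_matrix[sel_idx].any(axis=0)
    or_obs, a_obs = _or_per_term(obs_mask)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=np.int64)
    offsets = rng.integers(1, n, size=n_permutations)
    for d in offsets:
        shifted = (sel_idx + d) % n
        mask = link_matrix[shifted].any(axis=0)
        or_perm, _ = _or_per_term(mask)
        exceed += or_perm >= or_obs
    pvals = (exceed + 1.0) / (n_permutations + 1.0)

    gene_arr = np.array(term_gene_universe)
    rows = []
    for ti, t in enumerate(terms):
        overlap_genes = tuple(sorted(gene_arr[obs_mask & term_matrix[:, ti]]))
        rows.append(
            {
                "term_id": t.term_id,
                "name": t.name,
                "category": t.category,
                "overlap": int(a_obs[ti]),
                "odds_ratio": float(or_obs[ti]),
                "p": float(pvals[ti]),
                "genes": overlap_genes,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def filter_significant_terms(
    table: pd.DataFrame, p_threshold: float = 0.05, min_overlap: int = 3
) -> pd.DataFrame:
    """Keep terms with p below threshold and at least ``min_overlap`` genes."""
    if len(table) == 0:
        return table.copy()
    keep = (table["p"] < p_threshold) & (table["overlap"] >= min_overlap)
    return table.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# term clustering and defining genes
# ---------------------------------------------------------------------------

def cluster_terms(
    filtered: pd.DataFrame, seed: int = 0, weight: str = "count"
) -> TermClusterGraph:
    """Cluster significant terms by overlapping-gene sharing (Louvain).

    Edge weight between two terms is the number of shared overlapping genes
    (``weight="jaccard"`` uses the Jaccard index instead); terms sharing no
    gene are unconnected and become singleton clusters.  Louvain modularity
    optimization runs at resolution 1.0 with a fixed seed and deterministic
    node order; cluster labels are assigned in table row order.
    """
    if len(filtered) == 0:
        raise ValueError("need at least one significant term to cluster")
    g = nx.Graph()
    term_ids = filtered["term_id"].tolist()
    genes = {t: set(gs) for t, gs in zip(filtered["term_id"], filtered["genes"])}
    for t in term_ids:
        g.add_node(t)
    for i, t1 in enumerate(term_ids):
        for t2 in term_ids[i + 1 :]:
            shared = genes[t1] & genes[t2]
            if shared:
                if weight == "count":
                    w = float(len(shared))
                elif weight == "jaccard":
                    w = len(shared) / len(genes[t1] | genes[t2])
                else:
                    raise ValueError(f"unknown weight {weight!r}")
                g.add_edge(t1, t2, weight=w)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=1.0, seed=seed
    )
    # deterministic labels: clusters numbered by their first term in row order
    order = {t: i for i, t in enumerate(term_ids)}
    communities = sorted(communities, key=lambda c: min(order[t] for t in c))
    clusters = {t: ci for ci, comm in enumerate(communities) for t in comm}
    table = filtered.set_index("term_id", drop=False)
    return TermClusterGraph(graph=g, clusters=clusters, table=table)


def assign_defining_genes(tcg: TermClusterGraph) -> pd.DataFrame:
    """Mark, for every gene x term pair, whether the gene defines the cluster.

    A gene is *defining* for the cluster whose terms contain it most often;
    ties are broken toward the cluster holding the gene's most significant
    term (smallest p).  In every other cluster where the gene appears it is
    non-defining (the grey boxes of an overlap heat map).

    Returns a long table: gene, term_id, cluster, defining.
    """
    term_cluster = tcg.clusters
    term_p = tcg.table["p"].to_dict()
    gene_terms: dict[str, list[str]] = {}
    for term_id, gs in zip(tcg.table["term_id"], tcg.table["genes"]):
        for gene in gs:
            gene_terms.setdefault(gene, []).append(term_id)

    rows = []
    for gene, terms in sorted(gene_terms.items()):
        counts: dict[int, int] = {}
        best_p: dict[int, float] = {}
        for t in terms:
            c = term_cluster[t]
            counts[c] = counts.get(c, 0) + 1
            best_p[c] = min(best_p.get(c, np.inf), term_p[t])
        defining_cluster = min(
            counts, key=lambda c: (-counts[c], best_p[c], c)
        )
        for t in terms:
            c = term_cluster[t]
            rows.append(
                {
                    "gene": gene,
                    "term_id": t,
                    "cluster": c,
                    "defining": c == defining_cluster,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "term_id", "cluster", "defining"])
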