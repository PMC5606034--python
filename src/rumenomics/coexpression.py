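"""Spearman co-expression networks with exact small-n permutation p-values.

With six samples per group design, asymptotic p-values for rank correlations
are meaningless; here the two-sided p attached to a Spearman coefficient is,
for n up to ``exact_limit``, the exact proportion of all n! permutations of
one vector whose tie-aware coefficient is at least as extreme as the observed
one.  Above the limit a t-approximation is used and tagged as such.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .errors import UndefinedCorrelationError, ValidationError
from .expression import ExpressionMatrix, expressed_genes

DEFAULT_EXACT_LIMIT = 8

#: Hard ceiling for full enumeration (9! = 362,880 permutations); beyond
#: this the permutation matrix no longer fits comfortably in memory.
MAX_EXACT_N = 9


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    method: str  # "exact" | "approximate"


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Thresholded Spearman graph over expressed genes."""

    graph: nx.Graph
    rho_min: float
    p_max: float
    absolute: bool
    exact_limit: int

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"gene1": u, "gene2": v, **data} for u, v, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene1", "gene2", "rho", "p", "method"])


def _ranks(x: np.ndarray) -> np.ndarray:
    return rankdata(np.asarray(x, float))


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman coefficient: Pearson correlation of average ranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValidationError("vectors must have equal length")
    if len(x) < 3:
        raise ValidationError("Spearman correlation needs length >= 3")
    rx, ry = _ranks(x), _ranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


@lru_cache(maxsize=64)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


@lru_cache(maxsize=4096)
def _null_abs_rho(rx_sorted: tuple, ry_sorted: tuple) -> np.ndarray:
    """|rho| over all n! permutations of one rank vector against the other.

    The null distribution depends only on the two rank multisets, so results
    are cached on the sorted rank tuples.
    """
    rx = np.array(rx_sorted, float)
    ry = np.array(ry_sorted, float)
    n = len(rx)
    perms = _permutation_matrix(n)
    permuted = ry[perms]  # (n!, n); ranks of a permuted vector = permuted ranks
    rho = (permuted - ry.mean()) @ (rx - rx.mean()) / (n * rx.std() * ry.std())
    return np.abs(rho)


def spearman_test(x, y, exact_limit: int = DEFAULT_EXACT_LIMIT) -> SpearmanResult:
    """Spearman coefficient with a two-sided p-value.

    Exact enumeration for n <= exact_limit (p = proportion of permutations
    with |rho| >= |observed|, observed included so p > 0); t-approximation
    otherwise, tagged in ``method``.
    """
    rho = spearman_rho(x, y)
    n = len(np.asarray(x))
    if n <= exact_limit:
        if n > MAX_EXACT_N:
            raise ValidationError(
                f"exact enumeration requested for n={n}; the ceiling is {MAX_EXACT_N}"
            )
        rx, ry = _ranks(x), _ranks(y)
        null = _null_abs_rho(tuple(sorted(rx)), tuple(sorted(ry)))
        p = float((null >= abs(rho) - 1e-12).mean())
        return SpearmanResult(rho=rho, p_value=p, method="exact")
    res = spearmanr(x, y)
    return SpearmanResult(rho=rho, p_value=float(res.pvalue), method="approximate")


def spearman_exact_p(x, y, exact_limit: int = DEFAULT_EXACT_LIMIT) -> float:
    """Two-sided p-value of :func:`spearman_test`."""
    return spearman_test(x, y, exact_limit=exact_limit).p_value


def coexpression_network(
    e: ExpressionMatrix,
    rho_min: float = 0.85,
    p_max: float = 0.01,
    absolute: bool = False,
    min_rpkm: float = 1.0,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> CoexpressionNetwork:
    """All-pairs Spearman network over expressed genes.

    An edge requires rho > ``rho_min`` (signed by default; set ``absolute``
    to threshold |rho| instead) and p < ``p_max``.  Constant genes have no
    defined correlation and can carry no edges.
    """
    genes = sorted(expressed_genes(e, min_rpkm))
    x = e.rpkm.loc[genes].to_numpy(float)
    n = x.shape[1]
    if n < 3:
        raise ValidationError("co-expression needs at least 3 samples")
    ranks = np.apply_along_axis(rankdata, 1, x) if len(genes) else np.empty((0, n))
    sd = ranks.std(axis=1)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    if len(genes) >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_matrix = np.corrcoef(ranks)
        rho_matrix[sd == 0, :] = np.nan
        rho_matrix[:, sd == 0] = np.nan
        iu = np.triu_indices(len(genes), k=1)
        rho_flat = rho_matrix[iu]
        magnitude = np.abs(rho_flat) if absolute else rho_flat
        with np.errstate(invalid="ignore"):
            candidates = np.flatnonzero(magnitude > rho_min)
        for idx in candidates:
            i, j = iu[0][idx], iu[1][idx]
            rho = float(rho_flat[idx])
            if n <= exact_limit:
                null = _null_abs_rho(tuple(sorted(ranks[i])), tuple(sorted(ranks[j])))
                p = float((null >= abs(rho) - 1e-12).mean())
                method = "exact"
            else:
                p = float(spearmanr(x[i], x[j]).pvalue)
                method = "approximate"
            if p < p_max:
                graph.add_edge(genes[i], genes[j], rho=rho, p=p, method=method)
    return CoexpressionNetwork(
        graph=graph, rho_min=rho_min, p_max=p_max, absolute=absolute, exact_limit=exact_limit
    )


def seed_neighborhood(
    net: CoexpressionNetwork, seeds, de: pd.DataFrame
) -> nx.Graph:
    """First-neighbour subnetwork of the seed genes, keeping only
    differentially expressed neighbours and seed-neighbour edges.

    ``de`` is the frame from :func:`~rumenomics.expression.differential_expression`
    (indexed by gene, with a ``significant`` column).  Seeds missing from the
    network are skipped with a warning; nodes two hops away never appear.
    """
    significant = set(de.index[de["significant"]]) if len(de) else set()
    sub = nx.Graph()
    for seed in seeds:
        if seed not in net.graph:
            warnings.warn(f"seed gene {seed!r} absent from network; skipped", stacklevel=2)
            continue
        sub.add_node(seed, role="seed")
        for nb in net.graph.neighbors(seed):
            if nb in significant:
                if nb not in sub or sub.nodes[nb].get("role") != "seed":
                    sub.add_node(nb, role=sub.nodes.get(nb, {}).get("role", "neighbor"))
                sub.add_edge(seed, nb, **net.graph.edges[seed, nb])
    return sub


def annotate_network(sub: nx.Graph, pathway_map: dict) -> nx.Graph:
    """Join pathway/function tags onto nodes.

    ``pathway_map`` maps gene id to a tag or iterable of tags; duplicates are
    de-duplicated and unmapped nodes receive the single tag ``unannotated``.
    Returns a copy; the input graph is untouched.
    """
    out = sub.copy()
    for node in out.nodes:
        tags = pathway_map.get(node)
        if tags is None:
            out.nodes[node]["tags"] = ("unannotated",)
        else:
            if isinstance(tags, str):
                tags = [tags]
            out.nodes[node]["tags"] = tuple(sorted(set(tags)))
    return out
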