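"""Hypergeometric GO-BP over-representation analysis.

Upper-tail hypergeometric test per term, Benjamini-Hochberg adjustment,
term-size filtering, and a non-redundancy pass that drops any significant
term which is an ancestor of another significant term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig


class StructureError(ValueError):
    """Raised on malformed term structure (e.g. a cyclic parent relation)."""


@dataclass
class GOStructure:
    """Term -> gene sets plus a parent (is_a) relation between terms.

    ``parent_of`` maps a child term to its *direct* parents; transitive
    ancestors are derived on demand.  The relation must be acyclic.
    """

    term_to_genes: dict[str, frozenset]
    parent_of: dict[str, set] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_to_genes = {
            t: frozenset(g) for t, g in self.term_to_genes.items()
        }
        self.parent_of = {t: set(p) for t, p in self.parent_of.items()}
        for t in self.term_to_genes:
            self.ancestors(t)  # raises on cycles

    @property
    def universe(self) -> frozenset:
        """All annotated genes (the enrichment background)."""
        out: set = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return frozenset(out)

    def ancestors(self, term: str) -> frozenset:
        """Transitive parents of a term; raises StructureError on a cycle."""
        seen: set = set()
        stack = list(self.parent_of.get(term, ()))
        while stack:
            t = stack.pop()
            if t == term:
                raise StructureError(f"cycle in parent relation at {term!r}")
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self.parent_of.get(t, ()))
        return frozenset(seen)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def hypergeom_enrich(
    query: Iterable[str],
    structure: GOStructure,
    cfg: PipelineConfig | None = None,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test a query gene set against every sufficiently large term.

    For each term of size >= ``cfg.go_min_genes`` (within the background),
    the p-value is the hypergeometric upper tail P(X >= k) with X ~
    Hypergeom(N, K, n): N background genes, K in the term, n in the query,
    k overlapping.  BH adjustment runs over all tested terms.

    Returns a frame with columns term, k, n, K, N, p, p_adjust and a
    kept_nonredundant placeholder (set by :func:`nonredundant_filter`),
    sorted by adjusted then raw p-value.
    """
    cfg = cfg or PipelineConfig()
    bg = frozenset(universe) if universe is not None else structure.universe
    q = frozenset(query) & bg
    columns = ["term", "k", "n", "K", "N", "p", "p_adjust", "kept_nonredundant"]
    if not q:
        warnings.warn("query is empty after intersecting with the background")
        return pd.DataFrame(columns=columns)
    N, n = len(bg), len(q)
    rows = []
    for term in sorted(structure.term_to_genes):
        term_genes = structure.term_to_genes[term] & bg
        K = len(term_genes)
        if K < cfg.go_min_genes:
            continue
        k = len(term_genes & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=columns[:-2])
    if df.empty:
        return pd.DataFrame(columns=columns)
    df["p_adjust"] = bh_adjust(df["p"].to_numpy())
    df["kept_nonredundant"] = False
    return df.sort_values(
        ["p_adjust", "p", "term"], kind="stable"
    ).reset_index(drop=True)


def nonredundant_filter(
    rows: pd.DataFrame,
    structure: GOStructure,
    cfg: PipelineConfig | None = None,
    transitive: bool = True,
) -> pd.DataFrame:
    """Flag the non-redundant significant terms.

    Among terms with p_adjust <= ``cfg.go_fdr_max``, any term that is a
    parent of another significant term is dropped; parenthood is read
    transitively (ancestors) by default, so no kept term subsumes another.
    """
    cfg = cfg or PipelineConfig()
    out = rows.copy()
    if out.empty:
        return out
    significant = set(out.loc[out["p_adjust"] <= cfg.go_fdr_max, "term"])
    redundant: set = set()
    for term in significant:
        parents = (
            structure.ancestors(term)
            if transitive
            else frozenset(structure.parent_of.get(term, ()))
        )
        redundant |= parents & significant
    out["kept_nonredundant"] = out["term"].map(
        lambda t: t in significant and t not in redundant
    )
    return out
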