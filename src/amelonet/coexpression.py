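"""Weighted gene co-expression network construction.

Implements the unsigned-network core: soft-threshold selection via the
scale-free fit index, |Pearson r|^beta adjacency, the topological overlap
measure (TOM), average-linkage module detection on 1 - TOM with a static
cut height, module eigengenes (first principal component per module),
module-trait correlation, and kME module-membership tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import PipelineConfig

GREY = "grey"

#: Candidate soft powers scanned by default (the usual WGCNA grid).
DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with a binary tissue trait.

    ``trait`` is 0 for normal and 1 for tumor samples, aligned to the
    column order of ``matrix``.
    """

    matrix: pd.DataFrame  # index: gene ids, columns: sample ids
    trait: np.ndarray

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=int)
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ExpressionError(f"duplicated gene ID: {dup}")
        if len(self.trait) != self.matrix.shape[1]:
            raise ExpressionError(
                "trait length does not match number of samples"
            )
        if not set(np.unique(self.trait)) <= {0, 1}:
            raise ExpressionError("trait must be binary (0=normal, 1=tumor)")
        if self.matrix.isna().any().any():
            raise ExpressionError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def drop_zero_variance(self) -> "ExpressionDataset":
        keep = self.matrix.std(axis=1, ddof=1) > 0
        return ExpressionDataset(self.matrix.loc[keep], self.trait)


@dataclass
class NetworkModel:
    """A fitted co-expression network over one expression dataset."""

    power: int
    gene_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    module_of: dict[str, str]  # gene -> module label; GREY = unassigned
    eigengenes: pd.DataFrame  # samples x modules
    kme: pd.DataFrame  # genes x modules
    module_trait: pd.DataFrame  # module, r, p

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def genes_in_module(self, module: str) -> list[str]:
        return [g for g in self.gene_ids if self.module_of[g] == module]

    @property
    def anchor_module(self) -> str:
        """Module with the largest |module-trait correlation|."""
        mt = self.module_trait
        if mt.empty:
            raise ExpressionError("no modules detected")
        return mt.loc[mt["r"].abs().idxmax(), "module"]


def _check_expression(expr: ExpressionDataset) -> np.ndarray:
    x = expr.matrix.to_numpy(dtype=float)
    if expr.n_samples < 4:
        raise ExpressionError("need >= 4 samples")
    if np.any(x.std(axis=1, ddof=1) == 0):
        raise ExpressionError(
            "zero-variance gene present; filter with drop_zero_variance()"
        )
    return x


def adjacency(expr: ExpressionDataset, power: int) -> np.ndarray:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^power with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    x = _check_expression(expr)
    r = np.corrcoef(x)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return np.clip(a, 0.0, 1.0)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Bins k, regresses log10(frequency) on log10(mean k) across occupied
    bins and returns R^2 signed negative when the slope is positive (a
    power-law decay must have negative slope).  NaN when fewer than three
    occupied bins or too few distinct values.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(np.unique(np.round(k, 12))) < 5:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        freqs.append(mask.sum() / len(k))
        means.append(k[mask].mean())
    if len(freqs) < 3:
        return np.nan
    lx = np.log10(np.asarray(means))
    ly = np.log10(np.asarray(freqs))
    slope, _, r_value, _, _ = stats.linregress(lx, ly)
    r2 = r_value**2
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    expr: ExpressionDataset,
    candidate_powers: tuple[int, ...] = DEFAULT_POWERS,
    fit_target: float = 0.85,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by the scale-free topology criterion.

    Returns the smallest candidate power whose signed fit index reaches
    ``fit_target`` — or, when none does (e.g. pure noise), the power with
    the maximal signed fit — together with the per-power fit table
    (columns power, fit_r2, mean_k).
    """
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    x = _check_expression(expr)
    absr = np.abs(np.corrcoef(x))
    np.fill_diagonal(absr, 0.0)
    rows = []
    for beta in candidate_powers:
        a = absr**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append(
            {"power": beta, "fit_r2": scale_free_fit(k), "mean_k": k.mean()}
        )
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["fit_r2"])
    if ok.empty:
        raise ExpressionError("scale-free fit undefined for every power")
    reaching = ok[ok["fit_r2"] >= fit_target]
    if len(reaching):
        chosen = int(reaching["power"].iloc[0])
    else:
        chosen = int(ok.loc[ok["fit_r2"].idxmax(), "power"])
    return chosen, table


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Topological overlap measure of an adjacency matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    L_ij = sum_u a_iu a_uj counts shared-neighbor strength and k is the
    connectivity; TOM_ii = 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    cfg: PipelineConfig | None = None,
) -> dict[str, str]:
    """Average-linkage hierarchical clustering on 1 - TOM with a static cut.

    The dendrogram is cut at ``cfg.cut_height``; clusters smaller than
    ``cfg.min_module_size`` are relabelled grey; surviving modules are named
    M1, M2, ... by decreasing size.
    """
    cfg = cfg or PipelineConfig()
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match gene_ids")
    if n == 1:
        return {gene_ids[0]: GREY}
    dissim = np.clip(1.0 - tom, 0.0, None)
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    if cfg.cut_height <= 0:
        labels = np.arange(1, n + 1)  # cutting at the leaves: singletons
    else:
        labels = fcluster(z, t=cfg.cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= cfg.min_module_size]
    # deterministic naming: by decreasing size, ties by first gene index
    first_idx = {c: int(np.argmax(labels == c)) for c in kept}
    kept.sort(key=lambda c: (-sizes[c], first_idx[c]))
    rename = {c: f"M{i + 1}" for i, c in enumerate(kept)}
    module_of = {
        g: rename.get(c, GREY) for g, c in zip(gene_ids, labels)
    }
    if not kept:
        warnings.warn("all genes unassigned (grey): no module survived")
    return module_of


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return (x - mu) / sd


def module_eigengene(
    expr: ExpressionDataset, module_genes: list[str]
) -> np.ndarray:
    """First principal component of a module's gene-standardized submatrix.

    Scaled to unit variance across samples; the sign is fixed so the
    eigengene correlates positively with the mean standardized expression
    of the module, which makes "module down in tumor" map to a negative
    tumor shift of the eigengene.
    """
    if not module_genes:
        raise ExpressionError("module is empty")
    if expr.n_samples < 2:
        raise ExpressionError("eigengene undefined for a single sample")
    x = _standardize(expr.matrix.loc[module_genes].to_numpy(dtype=float))
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    me = vt[0]
    mean_profile = x.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return me / me.std(ddof=1)


def module_trait_correlation(
    me: np.ndarray, trait: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of an eigengene with the binary trait and its
    two-sided p-value from the t distribution on n - 2 df."""
    me = np.asarray(me, dtype=float)
    trait = np.asarray(trait, dtype=float)
    n = len(me)
    if n < 4:
        raise ExpressionError("need >= 4 samples")
    if np.all(trait == trait[0]):
        raise ExpressionError("trait is constant; correlation undefined")
    r = float(np.corrcoef(me, trait)[0, 1])
    p = correlation_p_value(r, n)
    return r, p


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation r at sample size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def kme_table(
    expr: ExpressionDataset, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """Signed module membership: kME_{g,m} = cor(x_g, ME_m).

    Hub genes of a module are its members with maximal |kME|; the sign is
    kept so anti-correlated hubs are visible as such.
    """
    x = _standardize(expr.matrix.to_numpy(dtype=float))
    out = {}
    for m in eigengenes.columns:
        me = eigengenes[m].to_numpy(dtype=float)
        me_std = (me - me.mean()) / me.std(ddof=1)
        out[m] = x @ me_std / (len(me) - 1)
    return pd.DataFrame(out, index=expr.gene_ids)


def build_network(
    expr: ExpressionDataset,
    cfg: PipelineConfig | None = None,
    power: int | None = None,
) -> NetworkModel:
    """Fit the full network model: adjacency, TOM, modules, eigengenes,
    kME and module-trait statistics, at ``power`` (default cfg.soft_power).
    """
    cfg = cfg or PipelineConfig()
    power = int(power if power is not None else cfg.soft_power)
    expr = expr.drop_zero_variance()
    a = adjacency(expr, power)
    tom = topological_overlap(a)
    module_of = detect_modules(tom, expr.gene_ids, cfg)
    modules = sorted(
        {m for m in module_of.values() if m != GREY},
        key=lambda m: int(m[1:]),
    )
    mes = {}
    for m in modules:
        genes = [g for g in expr.gene_ids if module_of[g] == m]
        mes[m] = module_eigengene(expr, genes)
    eigengenes = pd.DataFrame(mes, index=expr.sample_ids)
    rows = []
    for m in modules:
        r, p = module_trait_correlation(eigengenes[m].to_numpy(), expr.trait)
        rows.append({"module": m, "r": r, "p": p})
    module_trait = pd.DataFrame(rows, columns=["module", "r", "p"])
    kme = (
        kme_table(expr, eigengenes)
        if modules
        else pd.DataFrame(index=expr.gene_ids)
    )
    return NetworkModel(
        power=power,
        gene_ids=expr.gene_ids,
        adjacency=a,
        tom=tom,
        module_of=module_of,
        eigengenes=eigengenes,
        kme=kme,
        module_trait=module_trait,
    )
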