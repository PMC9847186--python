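"""Weighted co-expression network analysis, implemented from scratch.

The stage follows the classic weighted-network recipe: a soft-threshold
adjacency (correlation raised to a power beta), the topological overlap
similarity TOM crediting shared neighbours, average-linkage clustering of
1 - TOM, a static branch cut with a minimum module size, iterative merging
of modules whose eigengenes are closer than ``merge_cut_height`` (1 - r),
and module-trait correlation against a binary genotype-class trait
(parental inbred lines coded 0, hybrids 1).  Defaults follow the study
settings: beta = 18 for genes and 17 for metabolites, mergeCutHeight =
0.25, and a module-trait relation is significant at |r| > 0.6 and P < 0.05.

Dynamic hybrid tree cutting is deliberately simplified to a static-height
branch cut followed by eigengene merging; the cut is deterministic and
directly testable against planted-block constructions.  Module labels use
the conventional color names ordered by module size, with "grey" reserved
for unassigned features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .core import TriomicsError

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]
GREY = "grey"


@dataclass
class NetworkConfig:
    """Network construction parameters.

    ``beta`` is the soft-threshold power (18 for the gene network, 17 for
    metabolites in the reference design); ``static_cut_height`` is the
    branch-cut height as a fraction of the tallest dendrogram merge.
    """

    beta: int = 18
    network_type: str = "unsigned"
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    static_cut_height: float = 0.99

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise TriomicsError("beta must be >= 1")
        if self.network_type not in ("unsigned", "signed"):
            raise TriomicsError(f"network_type must be unsigned|signed, got {self.network_type}")
        if not (0 <= self.merge_cut_height < 1):
            raise TriomicsError("merge_cut_height must be in [0, 1)")


@dataclass
class ModuleResult:
    labels: pd.Series          # feature -> module color ("grey" = unassigned)
    eigengenes: pd.DataFrame   # module x sample
    sizes: dict[str, int] = field(default_factory=dict)


def soft_adjacency(expr: pd.DataFrame, cfg: NetworkConfig) -> pd.DataFrame:
    """Soft-threshold adjacency of a feature x sample expression matrix.

    unsigned: |cor|^beta; signed: ((1 + cor)/2)^beta; unit diagonal.
    Zero-variance features are dropped with a warning.
    """
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)", stacklevel=2)
        X = X[keep]
    if X.shape[1] < 3:
        raise TriomicsError("need >=3 samples for a co-expression network")
    cor = np.corrcoef(X)
    cor = np.clip(cor, -1.0, 1.0)
    if cfg.network_type == "unsigned":
        a = np.abs(cor) ** cfg.beta
    else:
        a = ((1.0 + cor) / 2.0) ** cfg.beta
    np.fill_diagonal(a, 1.0)
    ids = [f for f, k in zip(expr.index, keep) if k]
    return pd.DataFrame(a, index=ids, columns=ids)


def tom_similarity(a: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu, and TOM_ii = 1.
    """
    A = a.to_numpy(dtype=float) if isinstance(a, pd.DataFrame) else np.asarray(a, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise TriomicsError("adjacency must be symmetric (tolerance 1e-10)")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise TriomicsError("adjacency entries must lie in [0, 1]")
    n = A.shape[0]
    k = A.sum(axis=1) - np.diag(A)
    # shared-neighbour sums excluding i and j themselves; diag(A)=1 so
    # (A @ A)_ij counts a_ii a_ij + a_ij a_jj = 2 a_ij extra off-diagonal
    num = A @ A - 2.0 * A + A
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if isinstance(a, pd.DataFrame):
        return pd.DataFrame(tom, index=a.index, columns=a.columns)
    return tom


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized member matrix.

    The eigengene is the leading right singular vector over samples (unit
    norm), sign-oriented so that its mean correlation with the module's
    member features is nonnegative.  A single-feature module falls back to
    that feature standardized (then normalized).
    """
    modules = [m for m in dict.fromkeys(labels) if m != GREY]
    rows = []
    for mod in modules:
        members = labels.index[labels == mod]
        X = expr.loc[members].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.any():
            raise TriomicsError(f"module {mod!r} has only zero-variance members")
        Xs = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
        if Xs.shape[0] == 1:
            v = Xs[0] / np.linalg.norm(Xs[0])
        else:
            _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
            v = Vt[0]
        # orient: mean correlation with members >= 0
        cors = np.array([np.corrcoef(v, row)[0, 1] for row in Xs])
        if cors.mean() < 0:
            v = -v
        rows.append(v)
    return pd.DataFrame(rows, index=modules, columns=expr.columns)


def _size_ordered_relabel(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    mapping = {old: MODULE_COLORS[i % len(MODULE_COLORS)]
               for i, old in enumerate(sizes.index)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def cut_modules(
    dissimilarity: pd.DataFrame,
    cfg: NetworkConfig,
    expr: pd.DataFrame | None = None,
) -> ModuleResult:
    """Average-linkage clustering of a dissimilarity (1 - TOM) into modules.

    Branches are cut at ``static_cut_height`` x (tallest merge height);
    branches smaller than ``min_module_size`` become grey.  When ``expr`` is
    given, modules whose eigengenes are closer than ``merge_cut_height``
    (dissimilarity 1 - r) are merged iteratively until stable, and the
    eigengene matrix is returned.
    """
    D = dissimilarity.to_numpy(dtype=float)
    ids = list(dissimilarity.index)
    n = len(ids)
    if n < 2:
        raise TriomicsError("need >=2 features")
    Z = average(squareform(np.clip((D + D.T) / 2, 0, None), checks=False))
    hmax = Z[:, 2].max()
    cut = cfg.static_cut_height * hmax if hmax > 0 else 0.0
    assign = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series([str(c) for c in assign], index=ids)
    counts = labels.value_counts()
    small = counts.index[counts < cfg.min_module_size]
    labels[labels.isin(small)] = GREY
    if (labels == GREY).all():
        warnings.warn("all features unassigned (grey)", stacklevel=2)
        return ModuleResult(labels=_size_ordered_relabel(labels),
                            eigengenes=pd.DataFrame(), sizes={GREY: n})

    if expr is not None and cfg.merge_cut_height > 0:
        labels = _merge_close_modules(expr, labels, cfg.merge_cut_height)
    labels = _size_ordered_relabel(labels)
    eig = module_eigengene(expr, labels) if expr is not None else pd.DataFrame()
    sizes = labels.value_counts().to_dict()
    return ModuleResult(labels=labels, eigengenes=eig, sizes=sizes)


def _merge_close_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut_height: float
) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = [m for m in dict.fromkeys(labels) if m != GREY]
        if len(mods) < 2:
            break
        eig = module_eigengene(expr, labels)
        E = eig.to_numpy()
        cor = np.corrcoef(E)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_cut_height:
            break
        a, b = eig.index[i], eig.index[j]
        labels[labels == b] = a
    return labels


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: pd.Series | np.ndarray,
    r_cut: float = 0.6, p_cut: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a binary trait vector.

    The trait codes genotype class per sample (parents 0, hybrids 1).
    Returns module, r, p, and a significance flag at |r| > r_cut and p < p_cut.
    """
    t = np.asarray(trait, dtype=float)
    if len(set(t)) < 2:
        raise TriomicsError("trait vector must have both levels")
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        if e.std() == 0:
            warnings.warn(f"constant eigengene for module {mod!r}; r undefined", stacklevel=2)
            rows.append((mod, float("nan"), float("nan"), False))
            continue
        r, p = stats.pearsonr(e, t)
        rows.append((mod, float(r), float(p), bool(abs(r) > r_cut and p < p_cut)))
    return pd.DataFrame(rows, columns=["module", "r", "p", "significant"])


def scale_free_fit(expr: pd.DataFrame, betas: list[int],
                   network_type: str = "unsigned", n_bins: int = 10) -> pd.DataFrame:
    """R^2 of the scale-free topology fit per candidate beta (helper, never auto-applied).

    For each beta, connectivity k is binned into ``n_bins`` degree bins and
    log10 p(k) regressed on log10 mean(k); the squared correlation is the
    scale-free fit index.
    """
    rows = []
    for beta in betas:
        cfg = NetworkConfig(beta=beta, network_type=network_type, min_module_size=1)
        a = soft_adjacency(expr, cfg).to_numpy()
        k = a.sum(axis=1) - 1.0
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            sel = idx == b
            if sel.sum() == 0 or k[sel].mean() <= 0:
                continue
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.mean()))
        if len(xs) < 3:
            rows.append((beta, float("nan")))
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        rows.append((beta, float(r**2)))
    return pd.DataFrame(rows, columns=["beta", "r2"])
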