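"""Replicate-concordance and global-structure diagnostics.

Three diagnostics mirror standard bulk-omics quality control: mean pairwise
Pearson correlation among the biological replicates of each genotype x
condition group, PCA of the samples, and average-linkage clustering of the
sample profiles on the 1 - r correlation distance.

Correlations and distances are computed by default on log2(x+1) of the
matrix the caller supplies (variance stabilization for FPKM/abundance
layers); pass ``log=False`` to use the layer as-is.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .core import OmicsMatrix, SampleSheet, TriomicsError, log2p1


@dataclass
class CorrelationSummary:
    group: str                       # "genotype|condition"
    mean_r: float
    pair_r: dict[tuple[str, str], float]
    mean_r2: float                   # squared correlations, reported alongside r


@dataclass
class PCAResult:
    scores: pd.DataFrame             # samples x components
    variance_fraction: np.ndarray    # per retained component


def _maybe_log(m: OmicsMatrix, log: bool) -> np.ndarray:
    return log2p1(m).values if log else m.values


def replicate_correlation(
    m: OmicsMatrix, sheet: SampleSheet, log: bool = True
) -> list[CorrelationSummary]:
    """Mean pairwise Pearson r among replicates of each genotype x condition group.

    Both r and r^2 are reported: published replicate-agreement figures are
    often labelled R^2 while plotting correlation-sized values, so the two
    are emitted explicitly rather than guessed at.
    """
    X = _maybe_log(m, log)
    cols = {s: i for i, s in enumerate(m.sample_ids)}
    out: list[CorrelationSummary] = []
    for genotype, condition, samples in sheet.groups():
        if len(samples) < 2:
            raise TriomicsError(
                f"group {genotype}/{condition} has <2 replicates; cannot correlate"
            )
        pair_r: dict[tuple[str, str], float] = {}
        for a, b in itertools.combinations(samples, 2):
            x, y = X[:, cols[a]], X[:, cols[b]]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                warnings.warn(
                    f"zero-variance sample in pair ({a}, {b}); r undefined, excluded",
                    stacklevel=2,
                )
                continue
            pair_r[(a, b)] = float(np.corrcoef(x, y)[0, 1])
        rs = np.array(list(pair_r.values()))
        out.append(
            CorrelationSummary(
                group=f"{genotype}|{condition}",
                mean_r=float(rs.mean()) if rs.size else float("nan"),
                pair_r=pair_r,
                mean_r2=float((rs**2).mean()) if rs.size else float("nan"),
            )
        )
    return out


def pca_samples(m: OmicsMatrix, n_components: int = 2, log: bool = True) -> PCAResult:
    """PCA of samples: center features, project on leading eigenvectors."""
    X = _maybe_log(m, log).T  # samples x features
    n, p = X.shape
    if n_components > min(n, p):
        raise TriomicsError(f"n_components={n_components} exceeds min(dims)={min(n, p)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    total = (Xc**2).sum()
    if total == 0:
        raise TriomicsError("no variance: matrix is constant across samples")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    frac = (s[:n_components] ** 2) / total
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=m.sample_ids, columns=[f"PC{i+1}" for i in range(n_components)]
        ),
        variance_fraction=frac,
    )


def correlation_distance(m: OmicsMatrix, log: bool = True) -> pd.DataFrame:
    """Pairwise sample distance d = 1 - Pearson r of profiles."""
    X = _maybe_log(m, log)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [s for s, v in zip(m.sample_ids, sd) if v == 0]
        raise TriomicsError(f"zero-variance samples, correlation undefined: {bad}")
    D = 1.0 - np.corrcoef(X.T)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    return pd.DataFrame(D, index=m.sample_ids, columns=m.sample_ids)


def cluster_samples(m: OmicsMatrix, log: bool = True) -> np.ndarray:
    """Average-linkage dendrogram (scipy linkage matrix) on 1 - r distance."""
    if m.shape[1] < 2:
        raise TriomicsError("need >=2 samples to cluster")
    D = correlation_distance(m, log=log).to_numpy()
    return average(squareform(D, checks=False))
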