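"""Hypergeometric term enrichment against a GMT annotation.

For a study set of n features drawn from a universe of N, a term with K
members and k study hits gets the upper-tail probability
P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N, n).
Following the reporting convention of the study design, filtering is on the
raw p (GO at P < 0.05, KEGG pathways at P < 0.01, both strict); BH-adjusted
values are emitted alongside.  The default universe should be the features
that survived the expression filter, not the whole annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .core import TriomicsError
from .differential import bh_adjust


@dataclass
class Annotation:
    """term id -> (name, member set), restricted to a background universe."""

    terms: dict[str, tuple[str, frozenset]]
    universe: frozenset

    def __post_init__(self) -> None:
        self.terms = {
            t: (name, frozenset(members) & self.universe)
            for t, (name, members) in self.terms.items()
        }
        self.terms = {t: v for t, v in self.terms.items() if v[1]}


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> Annotation:
    """Read a GMT file (term, description, members...); universe defaults to the union."""
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = (parts[1], frozenset(p for p in parts[2:] if p))
    if universe is None:
        uni = frozenset().union(*(m for _, m in terms.values())) if terms else frozenset()
    else:
        uni = frozenset(universe)
    return Annotation(terms=terms, universe=uni)


def write_gmt(annot: Annotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (name, members) in annot.terms.items():
            fh.write("\t".join([term, name, *sorted(members)]) + "\n")


def hypergeom_enrich(study: Iterable[str], annot: Annotation) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a study set, one row per term hit.

    Features outside the universe are dropped with a warning; only terms
    with at least one study hit are tested; BH across tested terms.
    """
    study_set = set(study)
    outside = study_set - annot.universe
    if outside:
        warnings.warn(
            f"{len(outside)} study feature(s) outside the universe dropped", stacklevel=2
        )
        study_set -= outside
    if not study_set:
        raise TriomicsError("study set empty after intersecting with the universe")
    N = len(annot.universe)
    n = len(study_set)
    rows = []
    for term, (name, members) in annot.terms.items():
        K = len(members)
        k = len(study_set & members)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, name, k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "name", "k", "n", "K", "N", "p"])
    df["fdr"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def filter_enrichment(results: pd.DataFrame, p_cut: float) -> pd.DataFrame:
    """Terms with raw p strictly below the cut, sorted ascending by p."""
    if results.empty:
        return results.copy()
    out = results.loc[results["p"] < p_cut].sort_values("p", kind="mergesort")
    return out.reset_index(drop=True)
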