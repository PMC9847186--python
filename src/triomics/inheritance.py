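"""Mid-parent construction and the 12-type inheritance-pattern classifier.

For each feature in a female parent / hybrid / male parent (F-H-M) trio,
three pairwise differential contrasts (H vs F, H vs M, F vs M) and the
group means are reduced to one of twelve inheritance types:

========  =================================================================
type      pattern
========  =================================================================
I, II     additive: H differs from both parents and sits strictly between
          them, and the parents differ (I when the female parent is the
          higher parent, II when the male parent is)
III, IV   expression-level dominance toward the male parent (ELD-M): H is
          indistinguishable from M and differs from F (III when M is the
          higher parent, IV when F is)
V, VI     ELD toward the female parent (ELD-F): H indistinguishable from F,
          different from M (V when F is the higher parent, VI when M is)
VII-IX    low-parent overdominance: H significantly below both parents
          (VII male parent higher, IX female parent higher, VIII parents
          indistinguishable)
X-XII     high-parent overdominance: H significantly above both parents
          (X male parent higher, XII female parent higher, XI parents
          indistinguishable)
========  =================================================================

Anything else is *unclassified*.  Types I-II form the additive category,
III-VI the dominance (ELD) category, VII-XII the overdominance category;
ELD plus overdominance together constitute the non-additive fraction.

The ELD sub-splits are keyed to whether the parent the hybrid matches is
the higher-expressed parent.  That convention makes the classifier exactly
label-equivariant — swapping the parental roles maps I<->II, III<->V,
IV<->VI, VII<->IX and X<->XII while fixing VIII and XI — so a gene whose
hybrid tracks the same inbred line in both reciprocal crosses lands in the
mirrored type pair (e.g. type V in one cross and type III in the other).

"Similar to a parent" is operationalized as the corresponding pairwise
contrast being non-significant at the same FC/FDR thresholds used for the
differential calls; it is an absence-of-call criterion, not an equivalence
test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import OmicsMatrix, ThresholdConfig, TrioDesign, TriomicsError
from .differential import bh_adjust, make_calls, nb_test, welch_t_test

TYPES = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]

TYPE_CATEGORY: dict[str, str] = {
    "I": "additive", "II": "additive",
    "III": "ELD_M", "IV": "ELD_M",
    "V": "ELD_F", "VI": "ELD_F",
    "VII": "overdominant", "VIII": "overdominant", "IX": "overdominant",
    "X": "overdominant", "XI": "overdominant", "XII": "overdominant",
    "unclassified": "unclassified",
}

_VALID_CALLS = {"up", "down", "ns"}


@dataclass
class MidParentProfile:
    """Pseudo-replicate mid-parent values with the pairing that produced them."""

    values: pd.DataFrame                       # feature x pseudo-replicate
    provenance: list[tuple[str, str]]          # (female sample, male sample) per column


def midparent_profile(norm: OmicsMatrix, trio: TrioDesign) -> MidParentProfile:
    """Pseudo-replicate MPV matrix: column i = (female rep i + male rep i) / 2.

    Parental replicates are paired by replicate order; the number of
    pseudo-replicates is the smaller of the two parental replicate counts.
    """
    if norm.layer == "counts":
        raise TriomicsError("midparent_profile expects a normalized layer, not raw counts")
    k = min(len(trio.female_samples), len(trio.male_samples))
    fem = trio.female_samples[:k]
    male = trio.male_samples[:k]
    F = norm.subset_samples(fem).values
    M = norm.subset_samples(male).values
    mpv = (F + M) / 2.0
    cols = [f"MPV_{trio.cross}_{trio.condition}_{i+1}" for i in range(k)]
    return MidParentProfile(
        values=pd.DataFrame(mpv, index=norm.feature_ids, columns=cols),
        provenance=list(zip(fem, male)),
    )


def f1_vs_mpv(
    norm: OmicsMatrix,
    trio: TrioDesign,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Welch t-test of hybrid replicates against MPV pseudo-replicates.

    Values are compared on the log2(x+1) scale; log2 fold change is
    log2(hybrid mean / MPV mean) of the raw normalized values (0.5
    pseudocount only for zero means); BH across features; calls at
    FC >= fc_cut (or <= 1/fc_cut) and FDR < fdr_genes.
    """
    cfg = cfg or ThresholdConfig()
    mpv = midparent_profile(norm, trio)
    if len(trio.hybrid_samples) < 2 or mpv.values.shape[1] < 2:
        raise TriomicsError("need >=2 hybrid replicates and >=2 MPV pseudo-replicates")
    H = norm.subset_samples(trio.hybrid_samples).values
    A = mpv.values.to_numpy()
    lH, lA = np.log2(H + 1.0), np.log2(A + 1.0)
    p = np.array([welch_t_test(lA[g], lH[g])[2] for g in range(H.shape[0])])
    fdr = bh_adjust(p)
    mh, ma = H.mean(axis=1), A.mean(axis=1)
    ph = np.where(mh == 0, 0.5, mh)
    pa = np.where(ma == 0, 0.5, ma)
    log2fc = np.log2(ph / pa)
    return pd.DataFrame(
        {
            "feature_id": norm.feature_ids,
            "mean_a": ma,      # mid-parent
            "mean_b": mh,      # hybrid
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "call": make_calls(log2fc, fdr, cfg.fc_cut, cfg.fdr_genes),
        }
    )


# ---------------------------------------------------------------------------
# The 12-type classifier
# ---------------------------------------------------------------------------

def classify_inheritance(
    call_hf: str,
    call_hm: str,
    call_fm: str,
    means: tuple[float, float, float],
) -> tuple[str, str]:
    """Classify one feature from its three contrasts and (F̄, H̄, M̄) means.

    ``call_hf``/``call_hm`` are directional calls of the hybrid against each
    parent ('up' = hybrid significantly higher); ``call_fm`` compares the
    parents ('up' = female significantly higher).  Returns (type, category).
    """
    for name, c in (("call_hf", call_hf), ("call_hm", call_hm), ("call_fm", call_fm)):
        if c not in _VALID_CALLS:
            raise TriomicsError(f"{name} must be one of {_VALID_CALLS}, got {c!r}")
    fbar, hbar, mbar = (float(v) for v in means)

    sig_f = call_hf != "ns"
    sig_m = call_hm != "ns"

    if sig_f and sig_m:
        if call_hf == "down" and call_hm == "down":        # below both parents
            if call_fm == "down":
                return "VII", TYPE_CATEGORY["VII"]          # male parent higher
            if call_fm == "up":
                return "IX", TYPE_CATEGORY["IX"]            # female parent higher
            return "VIII", TYPE_CATEGORY["VIII"]
        if call_hf == "up" and call_hm == "up":            # above both parents
            if call_fm == "down":
                return "X", TYPE_CATEGORY["X"]
            if call_fm == "up":
                return "XII", TYPE_CATEGORY["XII"]
            return "XI", TYPE_CATEGORY["XI"]
        # opposite directions: hybrid between the parents
        if call_fm != "ns" and (min(fbar, mbar) < hbar < max(fbar, mbar)):
            return ("I", "additive") if fbar > mbar else ("II", "additive")
        return "unclassified", "unclassified"
    if sig_f and not sig_m:                                # hybrid tracks the male parent
        return ("III", "ELD_M") if mbar > fbar else ("IV", "ELD_M")
    if sig_m and not sig_f:                                # hybrid tracks the female parent
        return ("V", "ELD_F") if fbar > mbar else ("VI", "ELD_F")
    return "unclassified", "unclassified"


def classify_from_tables(
    res_hf: pd.DataFrame, res_hm: pd.DataFrame, res_fm: pd.DataFrame
) -> pd.DataFrame:
    """Vector classification from three contrast tables (same feature order).

    ``res_hf`` must be the contrast hybrid-vs-female (group_a = female),
    ``res_hm`` hybrid-vs-male (group_a = male), ``res_fm`` female-vs-male
    (group_a = male, group_b = female, so 'up' = female higher).
    """
    for a, b in ((res_hf, res_hm), (res_hf, res_fm)):
        if list(a["feature_id"]) != list(b["feature_id"]):
            raise TriomicsError("contrast tables must share feature order")
    rows = []
    for i in range(len(res_hf)):
        typ, cat = classify_inheritance(
            res_hf["call"].iat[i],
            res_hm["call"].iat[i],
            res_fm["call"].iat[i],
            (res_hf["mean_a"].iat[i], res_hf["mean_b"].iat[i], res_hm["mean_a"].iat[i]),
        )
        rows.append((res_hf["feature_id"].iat[i], typ, cat))
    out = pd.DataFrame(rows, columns=["feature_id", "type", "category"])
    for tag, res in (("hf", res_hf), ("hm", res_hm), ("fm", res_fm)):
        out[f"log2fc_{tag}"] = res["log2fc"].to_numpy()
        out[f"fdr_{tag}"] = res["fdr"].to_numpy()
        out[f"call_{tag}"] = res["call"].to_numpy()
    return out


def classify_trio(
    counts: OmicsMatrix,
    trio: TrioDesign,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Run the three NB contrasts for a trio and classify every feature."""
    cfg = cfg or ThresholdConfig()
    res_hf = nb_test(counts, trio.female_samples, trio.hybrid_samples, cfg)
    res_hm = nb_test(counts, trio.male_samples, trio.hybrid_samples, cfg)
    res_fm = nb_test(counts, trio.male_samples, trio.female_samples, cfg)
    return classify_from_tables(res_hf, res_hm, res_fm)


def categorize(calls: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Histogram per type and per category, plus the non-additive roll-up."""
    by_type = {t: 0 for t in TYPES + ["unclassified"]}
    for t in calls["type"]:
        by_type[t] += 1
    by_cat = {c: 0 for c in ("additive", "ELD_F", "ELD_M", "overdominant", "unclassified")}
    for c in calls["category"]:
        by_cat[c] += 1
    by_cat["non_additive"] = by_cat["ELD_F"] + by_cat["ELD_M"] + by_cat["overdominant"]
    return {"type": by_type, "category": by_cat}


# ---------------------------------------------------------------------------
# Set overlaps (UpSet-style) and up/down asymmetry
# ---------------------------------------------------------------------------

def set_overlaps(named_sets: Mapping[str, set]) -> pd.DataFrame:
    """Exclusive intersection-signature counts plus pairwise Venn counts.

    Returns a DataFrame with columns ``signature`` (set names joined by
    ``&``), ``kind`` (``exclusive`` or ``pairwise``) and ``count``.  The
    exclusive counts partition the union of all sets.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise TriomicsError("need >=2 sets")
    universe = set().union(*named_sets.values())
    sig_counts: dict[str, int] = {}
    for item in universe:
        members = [n for n in names if item in named_sets[n]]
        sig = "&".join(members)
        sig_counts[sig] = sig_counts.get(sig, 0) + 1
    rows = [(sig, "exclusive", c) for sig, c in sorted(sig_counts.items())]
    for a, b in itertools.combinations(names, 2):
        rows.append((f"{a}&{b}", "pairwise", len(named_sets[a] & named_sets[b])))
    return pd.DataFrame(rows, columns=["signature", "kind", "count"])


def updown_asymmetry(n_up: int, n_down: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square of an up/down split against 50:50 (df = 1)."""
    if n_up < 0 or n_down < 0:
        raise TriomicsError("counts must be nonnegative")
    n = n_up + n_down
    if n == 0:
        raise TriomicsError("both counts are zero")
    exp = n / 2.0
    chi2 = (n_up - exp) ** 2 / exp + (n_down - exp) ** 2 / exp
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
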