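"""Core data model, TSV I/O, normalization and expression filtering.

The central container is :class:`OmicsMatrix`, a feature x sample matrix of
nonnegative numbers carrying a *layer* tag that records what the numbers are
(raw counts, CPM, FPKM, metabolite abundances, or log abundances).  Samples
are described by a :class:`SampleSheet`; the parent/hybrid structure of a
cross under one condition is resolved into a :class:`TrioDesign`.

All files are plain TSV: matrices have a ``feature_id`` header cell followed
by sample ids, sample sheets have fixed columns, gene lengths are two
columns.  Round trips are bit-stable up to float formatting (values are
written with ``repr`` precision).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("counts", "cpm", "fpkm", "abundance", "log_abundance")
ROLES = ("femaleParent", "maleParent", "hybrid")

#: Default mapping of cross label -> (female genotype, male genotype) for the
#: reciprocal B73/Mo17 design; callers can supply their own registry.
DEFAULT_CROSSES: dict[str, tuple[str, str]] = {
    "BM": ("B73", "Mo17"),
    "MB": ("Mo17", "B73"),
}


class TriomicsError(ValueError):
    """Raised for violated data contracts (duplicate ids, negative values...)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TriomicsError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """Feature x sample numeric matrix with a layer tag.

    Parameters
    ----------
    data:
        DataFrame with feature ids as index and sample ids as columns.
    layer:
        One of ``counts | cpm | fpkm | abundance | log_abundance``.  The
        ``counts`` layer must hold nonnegative integers; all other layers
        hold finite reals (nonnegative except ``log_abundance``).
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise TriomicsError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        _check_unique(list(self.data.index), "feature")
        _check_unique(list(self.data.columns), "sample")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float)).all():
            raise TriomicsError("matrix contains non-finite values")
        if self.layer != "log_abundance" and vals.size and (vals.astype(float) < 0).any():
            r, c = np.argwhere(vals.astype(float) < 0)[0]
            raise TriomicsError(
                f"negative value at feature {self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        if self.layer == "counts" and vals.size:
            f = vals.astype(float)
            if not np.allclose(f, np.round(f)):
                raise TriomicsError("counts layer must contain integers")

    # -- conveniences -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise TriomicsError(f"unknown sample ids: {missing}")
        return OmicsMatrix(self.data.loc[:, list(sample_ids)].copy(), self.layer)

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise TriomicsError(f"unknown feature ids: {missing}")
        return OmicsMatrix(self.data.loc[list(feature_ids), :].copy(), self.layer)


@dataclass
class SampleSheet:
    """Sample metadata: id, genotype, parental/hybrid role, cross, condition, replicate."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "genotype", "role", "cross", "condition", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise TriomicsError(f"sample sheet missing columns: {missing}")
        _check_unique(list(self.table["sample_id"]), "sample")
        bad = set(self.table["role"]) - set(ROLES)
        if bad:
            raise TriomicsError(f"unknown roles: {sorted(bad)}; expected {ROLES}")
        reps = self.table["replicate"].astype(int)
        if (reps < 1).any():
            raise TriomicsError("replicate indices must be positive")
        # replicate indices 1..k without gaps within each genotype x condition group
        for (g, c), grp in self.table.groupby(["genotype", "condition"]):
            r = sorted(grp["replicate"].astype(int))
            if r != list(range(1, len(r) + 1)):
                raise TriomicsError(
                    f"replicates for genotype {g!r} condition {c!r} are {r}, expected 1..{len(r)}"
                )

    def samples_for(self, genotype: str, condition: str) -> list[str]:
        sel = (self.table["genotype"] == genotype) & (self.table["condition"] == condition)
        sub = self.table.loc[sel].sort_values("replicate")
        return list(sub["sample_id"])

    def groups(self) -> list[tuple[str, str, list[str]]]:
        """(genotype, condition, sample ids) per replicate group, in sheet order."""
        out = []
        for (g, c), grp in self.table.groupby(["genotype", "condition"], sort=False):
            out.append((g, c, list(grp.sort_values("replicate")["sample_id"])))
        return out

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def min_group_size(self) -> int:
        return int(self.table.groupby(["genotype", "condition"]).size().min())


@dataclass
class TrioDesign:
    """Resolved female/male/hybrid sample lists for one cross under one condition."""

    cross: str
    condition: str
    female_samples: list[str]
    male_samples: list[str]
    hybrid_samples: list[str]

    def __post_init__(self) -> None:
        lists = [self.female_samples, self.male_samples, self.hybrid_samples]
        for name, lst in zip(("female", "male", "hybrid"), lists):
            if not lst:
                raise TriomicsError(f"trio {self.cross}/{self.condition}: {name} sample list empty")
        allids = self.female_samples + self.male_samples + self.hybrid_samples
        if len(set(allids)) != len(allids):
            raise TriomicsError(f"trio {self.cross}/{self.condition}: sample lists overlap")


def build_trio(
    sheet: SampleSheet,
    cross: str,
    condition: str,
    crosses: Mapping[str, tuple[str, str]] = DEFAULT_CROSSES,
) -> TrioDesign:
    """Resolve a TrioDesign from the sheet via the cross registry.

    The registry maps the cross label to its (female genotype, male genotype);
    hybrid samples are the ones whose genotype equals the cross label.
    """
    if cross not in crosses:
        raise TriomicsError(f"unknown cross {cross!r}; registry has {sorted(crosses)}")
    fem_g, male_g = crosses[cross]
    trio = TrioDesign(
        cross=cross,
        condition=condition,
        female_samples=sheet.samples_for(fem_g, condition),
        male_samples=sheet.samples_for(male_g, condition),
        hybrid_samples=sheet.samples_for(cross, condition),
    )
    return trio


@dataclass
class ThresholdConfig:
    """Calling thresholds.

    Defaults follow the study design: genes are called at fold change > 1.5
    with BH-FDR < 0.3, metabolites at VIP > 1 with BH-FDR < 0.05, the
    low-expression filter uses CPM >= 10, GO terms are reported at P < 0.05
    and KEGG pathways at P < 0.01.
    """

    fc_cut: float = 1.5
    fdr_genes: float = 0.3
    vip_cut: float = 1.0
    fdr_metab: float = 0.05
    cpm_min: float = 10.0
    go_p: float = 0.05
    kegg_p: float = 0.01

    def __post_init__(self) -> None:
        if not self.fc_cut > 1:
            raise TriomicsError("fc_cut must be > 1")
        for name in ("fdr_genes", "fdr_metab", "go_p", "kegg_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise TriomicsError(f"{name} must be in (0,1), got {v}")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, layer: str) -> OmicsMatrix:
    """Read a feature x sample TSV (header: ``feature_id`` then sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise TriomicsError(
                f"non-numeric cell in column {col!r}, row {bad[0]!r}" if len(bad)
                else f"non-numeric column {col!r}"
            )
    return OmicsMatrix(df, layer)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write an OmicsMatrix as TSV with repr-precision floats."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        is_int = m.layer == "counts"
        for fid, row in zip(m.feature_ids, m.values):
            if is_int:
                cells = [str(int(round(v))) for v in row]
            else:
                cells = [repr(float(v)) for v in row]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Two-column TSV (feature_id, length_bp) -> Series of positive ints."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    s = pd.Series(df.iloc[:, 1].astype(int).to_numpy(), index=df.iloc[:, 0].astype(str))
    if (s <= 0).any():
        bad = s.index[s <= 0][0]
        raise TriomicsError(f"nonpositive gene length for {bad!r}")
    return s


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"feature_id": lengths.index, "length_bp": lengths.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def _library_sizes(m: OmicsMatrix) -> np.ndarray:
    lib = m.values.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise TriomicsError(f"zero library size for sample {m.sample_ids[zero[0]]!r}")
    return lib


def cpm_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Counts-per-million: counts * 1e6 / library size (raw column sum)."""
    if m.layer != "counts":
        raise TriomicsError(f"cpm_normalize expects counts, got {m.layer}")
    lib = _library_sizes(m)
    out = m.values * 1e6 / lib
    return OmicsMatrix(pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), "cpm")


def fpkm_normalize(m: OmicsMatrix, lengths: pd.Series) -> OmicsMatrix:
    """Fragments per kilobase per million: counts * 1e9 / (library * length_bp)."""
    if m.layer != "counts":
        raise TriomicsError(f"fpkm_normalize expects counts, got {m.layer}")
    missing = [f for f in m.feature_ids if f not in lengths.index]
    if missing:
        raise TriomicsError(f"gene length missing for feature {missing[0]!r}")
    lib = _library_sizes(m)
    L = lengths.loc[m.feature_ids].to_numpy(dtype=float)[:, None]
    out = m.values * 1e9 / (lib[None, :] * L)
    return OmicsMatrix(pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), "fpkm")


def filter_low_expression(
    m: OmicsMatrix,
    cfg: ThresholdConfig | None = None,
    min_samples: int = 1,
) -> OmicsMatrix:
    """Drop genes whose CPM never reaches ``cfg.cpm_min`` in ``min_samples`` samples.

    A gene is kept iff CPM >= cpm_min (inclusive boundary) in at least
    ``min_samples`` samples.  ``min_samples`` defaults to 1; pass the smallest
    replicate-group size of the design for a group-aware filter.
    """
    cfg = cfg or ThresholdConfig()
    if min_samples < 1:
        raise TriomicsError("min_samples must be >= 1")
    cpm = cpm_normalize(m)
    keep = (cpm.values >= cfg.cpm_min).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    kept = [f for f, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(m.data.loc[kept, :].copy(), m.layer)


def log2p1(m: OmicsMatrix) -> OmicsMatrix:
    """log2(x + 1) transform, tagged log_abundance."""
    out = np.log2(m.values + 1.0)
    return OmicsMatrix(
        pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), "log_abundance"
    )
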