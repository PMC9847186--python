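"""Seeded generators for reciprocal-cross trio omics experiments.

The generators emulate the reference design: two inbred parents (B73,
Mo17) and their reciprocal F1 hybrids (BM, MB) under four light conditions
(darkness Dk, far-red FR, red R, blue B), with 3 RNA-seq replicates and 6
metabolome replicates per genotype x condition.  Every feature carries a
planted inheritance mode recorded in a truth table:

- ``additive``: hybrid mean at the mid-parent value, parents 2^effect apart
- ``ELD_F`` / ``ELD_M``: hybrid mean equal to one parent, parents apart
- ``over_high`` / ``over_low``: hybrid 2^effect above the high parent /
  below the low parent
- ``null``: all three genotype means equal

Counts are negative binomial (gene means scaled to the target library
size); metabolite abundances are log-normal with a given coefficient of
variation.  Reciprocal hybrids share the hybrid mean (no parent-of-origin
effect) unless one is configured.  All draws come from one
``numpy.random.default_rng`` stream, so a design plus a seed reproduces its
output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import OmicsMatrix, SampleSheet, TriomicsError

MODES = ("additive", "ELD_F", "ELD_M", "over_high", "over_low", "null")

#: inheritance category each planted mode should be recovered as
MODE_CATEGORY = {
    "additive": "additive",
    "ELD_F": "ELD_F",
    "ELD_M": "ELD_M",
    "over_high": "overdominant",
    "over_low": "overdominant",
    "null": "unclassified",
}

def expected_category(mode: str, female_genotype: str = "B73") -> str:
    """Category a planted mode should classify as, given which parent is female.

    Truth modes are stated in the orientation of the BM cross (B73 female).
    In the reciprocal cross the same hybrid-matches-B73 gene is dominance
    toward the *male* parent, so the two ELD labels swap — the reciprocal
    mirror of the type pairs (V in one cross, III in the other).
    """
    cat = MODE_CATEGORY[mode]
    if female_genotype != FEMALE and cat in ("ELD_F", "ELD_M"):
        return "ELD_M" if cat == "ELD_F" else "ELD_F"
    return cat


FEMALE, MALE = "B73", "Mo17"
HYBRIDS = ("BM", "MB")
ROLE_OF = {FEMALE: "femaleParent", MALE: "maleParent", "BM": "hybrid", "MB": "hybrid"}

DEFAULT_METABOLITE_CLASSES = (
    "lipids", "organoheterocyclic", "acids", "benzenoids",
    "oxygen", "phenylpropanoids", "nucleosides", "not annotated",
)


@dataclass
class SimulationDesign:
    """Parameters of one simulated trio-omics experiment."""

    n_genes: int = 2000
    n_metabolites: int = 500
    conditions: tuple[str, ...] = ("Dk", "FR", "R", "B")
    rna_reps: int = 3
    metab_reps: int = 6
    mode_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "additive": 0.1, "ELD_F": 0.15, "ELD_M": 0.15,
            "over_high": 0.05, "over_low": 0.05, "null": 0.5,
        }
    )
    mode_counts: dict[str, int] | None = None   # exact per-mode counts; overrides proportions
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    base_mean_log2_range: tuple[float, float] = (4.0, 10.0)
    library_size: float = 1e6
    metab_cv: float = 0.2
    condition_effect_sd: float = 0.15
    module_spec: tuple[tuple[int, float, float], ...] = ()  # (size, within-cor, hybrid shift SDs)
    parent_of_origin_log2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode_counts is None:
            tot = sum(self.mode_proportions.values())
            if abs(tot - 1.0) > 1e-9:
                raise TriomicsError(f"mode proportions must sum to 1, got {tot}")
        bad = (set(self.mode_counts or self.mode_proportions)) - set(MODES)
        if bad:
            raise TriomicsError(f"unknown modes: {sorted(bad)}")
        for name in ("n_genes", "rna_reps", "metab_reps", "library_size"):
            if getattr(self, name) <= 0:
                raise TriomicsError(f"{name} must be positive")


def _assign_modes(design: SimulationDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    if design.mode_counts is not None:
        modes = np.repeat(
            list(design.mode_counts), list(design.mode_counts.values())
        )
        if modes.size != n:
            raise TriomicsError(
                f"mode_counts sum to {modes.size}, expected {n} features"
            )
        return rng.permutation(modes)
    names = list(design.mode_proportions)
    p = np.array([design.mode_proportions[m] for m in names])
    return rng.choice(names, size=n, p=p)


def _genotype_means(
    design: SimulationDesign, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-feature (muF, muM, muH) plus the truth table skeleton."""
    lo, hi = design.base_mean_log2_range
    base = 2.0 ** rng.uniform(lo, hi, size=n)
    modes = _assign_modes(design, n, rng)
    sign = rng.choice([-1.0, 1.0], size=n)          # which parent is the higher one
    e = design.effect_log2fc
    half = 2.0 ** (sign * e / 2.0)
    muF = base * half
    muM = base / half
    muH = np.empty(n)
    for i, mode in enumerate(modes):
        if mode == "null":
            muF[i] = muM[i] = muH[i] = base[i]
        elif mode == "additive":
            muH[i] = (muF[i] + muM[i]) / 2.0
        elif mode == "ELD_F":
            muH[i] = muF[i]
        elif mode == "ELD_M":
            muH[i] = muM[i]
        elif mode == "over_high":
            muH[i] = max(muF[i], muM[i]) * 2.0**e
        elif mode == "over_low":
            muH[i] = min(muF[i], muM[i]) / 2.0**e
    parental_l2 = np.where(modes == "null", 0.0, sign * e)   # log2(F/M)
    mid = (muF + muM) / 2.0
    truth = pd.DataFrame(
        {
            "mode": modes,
            "parental_log2fc": parental_l2,
            "hybrid_log2_dev": np.log2(muH / mid),
            "mu_female": muF,
            "mu_male": muM,
            "mu_hybrid": muH,
            "module": "none",
        }
    )
    return muF, muM, muH, truth


def _sample_frame(
    design: SimulationDesign, reps: int, prefix: str
) -> pd.DataFrame:
    rows = []
    for cond in design.conditions:
        for g in (FEMALE, MALE, *HYBRIDS):
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "sample_id": f"{prefix}_{g}_{cond}_r{r}",
                        "genotype": g,
                        "role": ROLE_OF[g],
                        "cross": g if g in HYBRIDS else "",
                        "condition": cond,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


def simulate_trio_counts(
    design: SimulationDesign,
) -> tuple[OmicsMatrix, SampleSheet, pd.DataFrame]:
    """Simulate the RNA count matrix for the full genotype x condition design."""
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    muF, muM, muH, truth = _genotype_means(design, n, rng)
    truth.index = [f"gene{i+1:05d}" for i in range(n)]

    # per-gene x condition multiplicative effect shared by all genotypes
    cond_fac = 2.0 ** rng.normal(
        0.0, design.condition_effect_sd, size=(n, len(design.conditions))
    )

    # optional co-expression modules: latent per-sample factor on the log2 mean
    module_of = np.full(n, -1)
    pos = 0
    for mi, (size, _, _) in enumerate(design.module_spec):
        module_of[pos : pos + size] = mi
        truth.iloc[pos : pos + size, truth.columns.get_loc("module")] = f"M{mi+1}"
        pos += size

    sheet_df = _sample_frame(design, design.rna_reps, "rna")
    mu_geno = {FEMALE: muF, MALE: muM, "BM": muH, "MB": muH}
    if design.parent_of_origin_log2:
        # shift alternating genes so the effect survives library scaling
        poe = np.ones(n)
        poe[::2] = 2.0 ** design.parent_of_origin_log2
        mu_geno = dict(mu_geno)
        mu_geno["MB"] = muH * poe

    cols, data = [], []
    alpha = design.nb_dispersion
    for _, row in sheet_df.iterrows():
        ci = design.conditions.index(row["condition"])
        mu = mu_geno[row["genotype"]] * cond_fac[:, ci]
        if design.module_spec:
            z = rng.normal()
            shift = np.zeros(n)
            for mi, (size, rho, hyb_shift) in enumerate(design.module_spec):
                sel = module_of == mi
                lat = np.sqrt(rho) * z * 0.5          # latent log2 swing ~0.5 SD units
                sh = -hyb_shift * 0.5 if ROLE_OF[row["genotype"]] == "hybrid" else 0.0
                shift[sel] = lat + sh
            mu = mu * 2.0**shift
        mu = mu / mu.sum() * design.library_size
        if alpha > 0:
            r_nb = 1.0 / alpha
            counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        else:
            counts = rng.poisson(mu)
        cols.append(row["sample_id"])
        data.append(counts)
    mat = pd.DataFrame(np.array(data, dtype=np.int64).T, index=truth.index, columns=cols)
    return OmicsMatrix(mat, "counts"), SampleSheet(sheet_df), truth


def simulate_metabolites(
    design: SimulationDesign,
    classes: Sequence[str] = DEFAULT_METABOLITE_CLASSES,
    class_mph: Mapping[str, float] | None = None,
) -> tuple[OmicsMatrix, SampleSheet, pd.DataFrame]:
    """Simulate log-normal metabolite abundances with planted modes.

    ``class_mph`` optionally pins the hybrid mean of every metabolite of a
    class to mid-parent x (1 + MPH/100), planting a class-level mid-parent
    heterosis signal on top of the mode machinery.
    """
    rng = np.random.default_rng(design.seed + 1)
    n = design.n_metabolites
    muF, muM, muH, truth = _genotype_means(design, n, rng)
    truth.index = [f"met{i+1:05d}" for i in range(n)]
    truth["class"] = rng.choice(list(classes), size=n)
    if class_mph:
        for cls, target in class_mph.items():
            sel = (truth["class"] == cls).to_numpy()
            mid = (muF[sel] + muM[sel]) / 2.0
            muH[sel] = mid * (1.0 + target / 100.0)
            truth.loc[sel, "hybrid_log2_dev"] = np.log2(muH[sel] / mid)

    cond_fac = 2.0 ** rng.normal(
        0.0, design.condition_effect_sd, size=(n, len(design.conditions))
    )
    sheet_df = _sample_frame(design, design.metab_reps, "met")
    mu_geno = {FEMALE: muF, MALE: muM, "BM": muH, "MB": muH}
    cv = design.metab_cv
    sigma = np.sqrt(np.log1p(cv * cv))               # lognormal sigma for the target CV
    cols, data = [], []
    for _, row in sheet_df.iterrows():
        ci = design.conditions.index(row["condition"])
        mu = mu_geno[row["genotype"]] * cond_fac[:, ci]
        if sigma > 0:
            vals = mu * np.exp(rng.normal(0.0, sigma, size=n) - sigma * sigma / 2.0)
        else:
            vals = mu.copy()
        cols.append(row["sample_id"])
        data.append(vals)
    mat = pd.DataFrame(np.array(data).T, index=truth.index, columns=cols)
    return OmicsMatrix(mat, "abundance"), SampleSheet(sheet_df), truth


def simulate_biomass(
    target_mph: Mapping[str, Mapping[str, float]],
    noise_cv: float = 0.05,
    reps: int = 6,
    seed: int = 0,
    parent_means: Mapping[str, float] = {FEMALE: 0.9, MALE: 1.1},
) -> pd.DataFrame:
    """Simulate a biomass table with planted per-cross, per-condition MPH.

    ``target_mph[cross][condition]`` is the planted MPH percentage (> -100).
    Fresh weights are drawn around fixed parental means (grams); dry weight
    is a fixed tenth of the fresh-weight mean with its own noise.  Replicate
    noise is multiplicative normal with the given CV; CV 0 reproduces the
    targets exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    conditions = sorted({c for m in target_mph.values() for c in m})
    means = dict(parent_means)
    for cross, per_cond in target_mph.items():
        for cond, t in per_cond.items():
            if t <= -100:
                raise TriomicsError(f"target MPH must exceed -100%, got {t}")
    for cond in conditions:
        geno_mean = dict(means)
        for cross, per_cond in target_mph.items():
            if cond in per_cond:
                mid = (means[FEMALE] + means[MALE]) / 2.0
                geno_mean[cross] = mid * (1.0 + per_cond[cond] / 100.0)
        for g, m in geno_mean.items():
            for r in range(1, reps + 1):
                f = m * (1.0 + noise_cv * rng.normal()) if noise_cv > 0 else m
                d = 0.1 * m * (1.0 + noise_cv * rng.normal()) if noise_cv > 0 else 0.1 * m
                rows.append(
                    {
                        "genotype": g,
                        "condition": cond,
                        "replicate": r,
                        "fresh_weight_g": max(f, 1e-6),
                        "dry_weight_g": max(d, 1e-6),
                    }
                )
    return pd.DataFrame(rows)


def simulate_module_expression(
    blocks: Sequence[tuple[int, float, float]],
    n_background: int = 0,
    n_parent_samples: int = 12,
    n_hybrid_samples: int = 12,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian expression with planted correlated blocks, for network tests.

    Each block is (size, within-correlation, hybrid shift in SD units); the
    shift is subtracted from the hybrid samples, planting a
    hybrid-suppressed module.  Returns the feature x sample matrix and the
    binary trait vector (parents 0, hybrids 1).
    """
    rng = np.random.default_rng(seed)
    n_samples = n_parent_samples + n_hybrid_samples
    trait = np.array([0] * n_parent_samples + [1] * n_hybrid_samples)
    rows, names = [], []
    for bi, (size, rho, shift) in enumerate(blocks):
        z = rng.normal(size=n_samples)
        for g in range(size):
            eps = rng.normal(size=n_samples)
            x = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
            x = x - shift * trait
            rows.append(x)
            names.append(f"blk{bi+1}_g{g+1}")
    for g in range(n_background):
        rows.append(rng.normal(size=n_samples))
        names.append(f"bg_g{g+1}")
    cols = [f"P{i+1}" for i in range(n_parent_samples)] + [
        f"H{i+1}" for i in range(n_hybrid_samples)
    ]
    return pd.DataFrame(rows, index=names, columns=cols), trait
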