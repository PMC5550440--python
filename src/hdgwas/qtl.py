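"""QTL characterization: genotype-class structure, dominance behaviour,
variance explained, and superior-allele provenance.

Each QTL (lead SNP) is classified by its F1 genotype-class counts: if all
three classes (AA, Aa, aa) reach a minimum count (default 15), it is a
*three-genotype* QTL and gets a joint additive+dominance regression; with
fewer, it is a *two-genotype* QTL and the heterozygote mean is compared
directly against the observed homozygote class (hetero- vs homo-superior).

Conventions (standard F2 parametrization): a is the half-difference of the
homozygote class means, with the minor-allele homozygote as the high
coding; d is the heterozygote deviation from the homozygote midpoint.  The
degree of dominance |d/a| is binned into the Stuber classes: additive
[0, 0.2), partial dominance [0.2, 0.8], dominance (0.8, 1.2],
overdominance > 1.2; the sign of d/a is reported alongside.

Whether higher or lower values are favorable is per-trait configuration:
yield traits favour higher values, heading date favours earlier (lower).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, CrossDesign

__all__ = [
    "FAVORABLE_DIRECTIONS",
    "favorable_direction",
    "genotype_class",
    "stuber_class",
    "da_effects",
    "DaEffects",
    "superiority_class",
    "variance_explained",
    "aic_forward_backward",
    "superior_allele_accounting",
    "SuperiorAlleleReport",
]

# traits where a LOWER value is the breeding-favorable direction
FAVORABLE_DIRECTIONS: dict[str, str] = {"HD": "lower"}


def favorable_direction(trait: str) -> str:
    return FAVORABLE_DIRECTIONS.get(trait, "higher")


def genotype_class(
    lead_calls: np.ndarray, min_class_n: int = 15
) -> tuple[str, dict[int, int]]:
    """three_genotype iff every class (0, 1, 2) has >= ``min_class_n``
    non-missing F1s; counts are returned alongside.  A locus with a single
    class is not a QTL and raises."""
    if min_class_n < 1:
        raise ValueError("min_class_n must be >= 1")
    calls = np.asarray(lead_calls)
    calls = calls[calls >= 0]
    counts = {g: int(np.sum(calls == g)) for g in (0, 1, 2)}
    present = [g for g, c in counts.items() if c > 0]
    if len(present) <= 1:
        raise ValueError("only one genotype class present; not a QTL")
    cls = "three_genotype" if all(c >= min_class_n for c in counts.values()) else "two_genotype"
    return cls, counts


def stuber_class(d_over_a: float) -> str:
    """Stuber degree-of-dominance bins on |d/a|."""
    r = abs(d_over_a)
    if r < 0.2:
        return "additive"
    if r <= 0.8:
        return "partial_dominance"
    if r <= 1.2:
        return "dominance"
    return "overdominance"


@dataclass
class DaEffects:
    a: float
    d: float
    d_over_a: float  # signed; nan when undefined
    stuber: str
    flagged: bool = False


def da_effects(
    pheno: np.ndarray,
    lead_calls: np.ndarray,
    pc_covariates: np.ndarray | None = None,
) -> DaEffects:
    """Joint linear regression of the phenotype on the additive coding
    (0, 1, 2) and dominance coding (0, 1, 0) of the lead SNP, with genomic
    PCs as optional fixed covariates; a and d are the two coefficients."""
    y = np.asarray(pheno, dtype=float)
    g = np.asarray(lead_calls, dtype=float)
    ok = np.isfinite(y) & (g >= 0)
    if pc_covariates is not None:
        P = np.asarray(pc_covariates, dtype=float)
        ok &= np.all(np.isfinite(P), axis=1)
        P = P[ok]
    y, g = y[ok], g[ok]
    x_add = g
    x_dom = (g == 1).astype(float)
    cols = [np.ones_like(y), x_add, x_dom]
    if pc_covariates is not None:
        cols.append(P)
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    a, d = float(beta[1]), float(beta[2])
    if abs(a) < 1e-8:
        # additive effect indistinguishable from 0: d/a undefined
        resid = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(X.T @ X)
        se_d = float(np.sqrt(max(sigma2 * XtX_inv[2, 2], 0.0)))
        significant = se_d > 0 and stats.t.sf(abs(d) / se_d, dof) * 2 < 0.05
        return DaEffects(
            a=a, d=d, d_over_a=float("nan"),
            stuber="overdominance" if significant else "unclassified",
            flagged=True,
        )
    ratio = d / a
    return DaEffects(a=a, d=d, d_over_a=ratio, stuber=stuber_class(ratio))


def superiority_class(
    pheno: np.ndarray, lead_calls: np.ndarray, direction: str = "higher"
) -> tuple[str, bool]:
    """Two-genotype QTL call: hetero_superior iff the heterozygote mean is
    favorable relative to the observed homozygote class mean; exact ties go
    to homo_superior (conservative) with a flag."""
    y = np.asarray(pheno, dtype=float)
    g = np.asarray(lead_calls)
    ok = np.isfinite(y) & (g >= 0)
    y, g = y[ok], g[ok]
    het_mean = y[g == 1].mean()
    homs = [c for c in (0, 2) if np.any(g == c)]
    if not homs or not np.any(g == 1):
        raise ValueError("two-genotype comparison needs a het class and a hom class")
    hom_mean = y[np.isin(g, homs)].mean()
    delta = het_mean - hom_mean
    if direction == "lower":
        delta = -delta
    if delta > 0:
        return "hetero_superior", False
    return "homo_superior", delta == 0


def aic_forward_backward(y: np.ndarray, X: np.ndarray) -> list[int]:
    """Stepwise forward-backward column selection by AIC (OLS)."""
    n = len(y)

    def aic(cols: list[int]) -> float:
        M = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        rss = float(np.sum((y - M @ beta) ** 2))
        rss = max(rss, 1e-300)
        k = M.shape[1] + 1
        return n * np.log(rss / n) + 2 * k

    current: list[int] = []
    best_aic = aic(current)
    improved = True
    while improved:
        improved = False
        # forward
        best_add, best_add_aic = None, best_aic
        for c in range(X.shape[1]):
            if c in current:
                continue
            val = aic(current + [c])
            if val < best_add_aic - 1e-9:
                best_add, best_add_aic = c, val
        if best_add is not None:
            current.append(best_add)
            best_aic = best_add_aic
            improved = True
        # backward
        best_drop, best_drop_aic = None, best_aic
        for c in list(current):
            val = aic([x for x in current if x != c])
            if val < best_drop_aic - 1e-9:
                best_drop, best_drop_aic = c, val
        if best_drop is not None:
            current.remove(best_drop)
            best_aic = best_drop_aic
            improved = True
    return current


def variance_explained(
    pheno: np.ndarray,
    lead_calls: np.ndarray | list[np.ndarray],
    pc_covariates: np.ndarray | None = None,
    multi: bool = False,
) -> float | tuple[float, list[int]]:
    """Phenotype variance explained by QTL lead SNPs.

    Single QTL (``multi=False``, one call vector): R² of the additive-coded
    lead-SNP regression.  Multi-QTL: the phenotype is first residualized on
    the top genomic PCs (family-effect removal), lead SNPs are filtered by
    AIC forward-backward selection, and the joint R² of the retained SNPs
    on the residualized phenotype is reported with the retained indices.
    """
    y = np.asarray(pheno, dtype=float)
    if not multi:
        g = np.asarray(lead_calls, dtype=float)
        ok = np.isfinite(y) & (g >= 0)
        y, g = y[ok], g[ok]
        if len(y) < 11:
            raise ValueError("too few samples for variance estimation")
        X = np.column_stack([np.ones_like(y), g])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - rss / tss if tss > 0 else 0.0

    G = np.column_stack([np.asarray(g, dtype=float) for g in lead_calls])
    ok = np.isfinite(y) & np.all(G >= 0, axis=1)
    y, G = y[ok], G[ok]
    if len(y) < G.shape[1] + 10:
        raise ValueError("need n >= n_predictors + 10 samples")
    if pc_covariates is not None:
        P = np.asarray(pc_covariates, dtype=float)[ok]
        M = np.column_stack([np.ones(len(y)), P])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        y = y - M @ beta
    kept = aic_forward_backward(y, G)
    if not kept:
        return 0.0, []
    M = np.column_stack([np.ones(len(y))] + [G[:, c] for c in kept])
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    rss = float(np.sum((y - M @ beta) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return (1.0 - rss / tss if tss > 0 else 0.0), kept


# ---------------------------------------------------------------------------
# superior-allele provenance
# ---------------------------------------------------------------------------


@dataclass
class SuperiorAlleleReport:
    superior_call: int  # 0 or 2: the call carrying two superior alleles
    superior_allele: str  # allele label
    ratio_maternal: float
    ratio_paternal: float
    ratio_f1: float
    contribution: str  # female_only | male_only | both
    maternal_derived_fraction: float
    paternal_derived_fraction: float


def _superior_call(
    pheno: np.ndarray, calls: np.ndarray, direction: str
) -> int:
    """The homozygote call (0 or 2) whose allele is superior.

    Three-genotype QTLs: the better homozygote class.  Two-genotype QTLs:
    when the heterozygote is the favorable class, the superior allele is
    the one absent from the observed homozygote class (the rare allele that
    creates the heterozygote).
    """
    y = np.asarray(pheno, dtype=float)
    g = np.asarray(calls)
    ok = np.isfinite(y) & (g >= 0)
    y, g = y[ok], g[ok]
    sign = -1.0 if direction == "lower" else 1.0
    means = {c: sign * y[g == c].mean() for c in (0, 1, 2) if np.any(g == c)}
    homs = [c for c in (0, 2) if c in means]
    if len(homs) == 2:
        return 0 if means[0] >= means[2] else 2
    if len(homs) == 1:
        hom = homs[0]
        if 1 in means and means[1] > means[hom]:
            return 2 - hom  # het superior: the allele missing from the hom class
        return hom
    raise ValueError("no homozygote class observed at QTL")


def superior_allele_accounting(
    lead_id: str,
    pheno: pd.Series,
    parents: GenotypeMatrix,
    f1: GenotypeMatrix,
    design: CrossDesign,
    direction: str = "higher",
) -> SuperiorAlleleReport:
    """Frequency of the superior allele in each parental group and among F1
    allele copies, with each F1 copy assigned a parental origin (parents
    are inbred, so the origin of every copy is unambiguous).

    ``pheno`` is indexed by F1 id (the phenotype the superiority call is
    made on — for derived categories, that derived phenotype itself).
    """
    j = int(f1.markers.index[f1.markers["id"] == lead_id][0])
    f1_ids = [s for s in f1.samples if s in pheno.index]
    calls = f1.calls[f1.sample_index(f1_ids), j]
    y = pheno.reindex(f1_ids).to_numpy(dtype=float)
    sup = _superior_call(y, calls, direction)

    jp = int(parents.markers.index[parents.markers["id"] == lead_id][0])
    mat_idx = parents.sample_index(design.maternal_lines)
    pat_idx = parents.sample_index(design.paternal_lines)

    def group_freq(idx: np.ndarray) -> float:
        c = parents.calls[idx, jp]
        c = c[c >= 0]
        if c.size == 0:
            return float("nan")
        return float(np.mean(c == sup) + 0.5 * np.mean(c == 1))

    ratio_mat = group_freq(mat_idx)
    ratio_pat = group_freq(pat_idx)
    if (ratio_mat == 0 or np.isnan(ratio_mat)) and (ratio_pat == 0 or np.isnan(ratio_pat)):
        raise ValueError("superior allele absent from both parental groups")
    contribution = (
        "both" if ratio_mat > 0 and ratio_pat > 0
        else ("female_only" if ratio_mat > 0 else "male_only")
    )

    # per-F1 allele copies by origin (parents inbred: copy = parent call / 2)
    pcalls = parents.calls[:, jp]
    lookup = {s: i for i, s in enumerate(parents.samples)}
    mat_sup = pat_sup = total_sup = total_copies = 0
    for _, row in design.crosses.iterrows():
        if row["f1"] not in pheno.index:
            continue
        cm = pcalls[lookup[row["mother"]]]
        cf = pcalls[lookup[row["father"]]]
        if cm == 1 or cf == 1 or cm < 0 or cf < 0:
            continue
        m_is = int(cm == sup)
        f_is = int(cf == sup)
        mat_sup += m_is
        pat_sup += f_is
        total_sup += m_is + f_is
        total_copies += 2
    ratio_f1 = total_sup / total_copies if total_copies else float("nan")
    mat_frac = mat_sup / total_sup if total_sup else float("nan")
    pat_frac = pat_sup / total_sup if total_sup else float("nan")
    allele = parents.markers.loc[jp, "a1"] if sup == 0 else parents.markers.loc[jp, "a2"]
    return SuperiorAlleleReport(
        superior_call=int(sup),
        superior_allele=str(allele),
        ratio_maternal=ratio_mat,
        ratio_paternal=ratio_pat,
        ratio_f1=ratio_f1,
        contribution=contribution,
        maternal_derived_fraction=mat_frac,
        paternal_derived_fraction=pat_frac,
    )
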