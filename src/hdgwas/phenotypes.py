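"""Heterosis phenotype derivation from plot-level trait tables.

Works on long-format trait tables (sample, role, environment, replicate,
trait, value).  Replicates are averaged per sample × environment before any
derivation; environments are never pooled.

Derived quantities, per F1 hybrid and trait:

* BPaV — better paternal value, ``F1 − Pat`` (the breeding-relevant
  heterosis measure when the maternal line is sterile);
* MPV — mid-parent heterosis, ``F1 − (Pat + Mat)/2``;
* GCA/SCA — the method-of-moments diallel decomposition on cross means,
  ``GCA_i = ȳ_i. − ȳ..`` and ``SCA_ij = ȳ_ij − ȳ.. − GCA_i − GCA_j``, with
  the grand mean taken as the unweighted mean of observed cross means.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import CrossDesign

__all__ = [
    "replicate_means",
    "snpp",
    "bpav",
    "mpv",
    "gca_sca",
    "derive_heterosis",
    "normalize_phenotype",
    "yield_component_regression",
]


def replicate_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate values per sample × environment × trait."""
    return (
        table.groupby(["sample", "role", "environment", "trait"], as_index=False)["value"]
        .mean()
    )


def snpp(gypp, pn, tgw):
    """Seed number per panicle: GYPP / (PN × TGW/1000).

    TGW is the 1000-grain weight in grams; dividing by 1000 converts it to a
    per-grain weight so SNPP comes out in grains, not thousands of grains.
    Zero or missing divisors yield NaN (flagged, not zero).
    """
    gypp = np.asarray(gypp, dtype=float)
    pn = np.asarray(pn, dtype=float)
    tgw = np.asarray(tgw, dtype=float)
    denom = pn * tgw / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, gypp / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def bpav(f1_value, paternal_value):
    """Better paternal value: F1 − Pat (missing parent → missing result)."""
    return np.asarray(f1_value, dtype=float) - np.asarray(paternal_value, dtype=float)


def mpv(f1_value, paternal_value, maternal_value):
    """Mid-parent heterosis: F1 − (Pat + Mat)/2."""
    return np.asarray(f1_value, dtype=float) - (
        np.asarray(paternal_value, dtype=float) + np.asarray(maternal_value, dtype=float)
    ) / 2.0


def gca_sca(f1_means: pd.Series, design: CrossDesign) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Combining-ability decomposition on cross means.

    Parameters
    ----------
    f1_means
        One phenotype value per F1 id (replicates already averaged, one
        environment).
    design
        The cross table.

    Returns
    -------
    (gca, sca, f1_sca)
        ``gca`` indexed by parent id, ``sca`` indexed by (mother, father)
        cross, and ``f1_sca`` the SCA value assigned to every F1 of that
        cross.
    """
    crosses = design.crosses.copy()
    crosses["value"] = crosses["f1"].map(f1_means)
    crosses = crosses.dropna(subset=["value"])
    if crosses.empty:
        raise ValueError("no phenotyped crosses")
    cross_means = crosses.groupby(["mother", "father"])["value"].mean()
    grand = cross_means.mean()  # unweighted over observed cross means

    gca = {}
    for parent_col in ("mother", "father"):
        long = cross_means.reset_index()
        for parent, sub in long.groupby(parent_col):
            gca[parent] = sub["value"].mean() - grand
    for parent in set(design.maternal_lines) | set(design.paternal_lines):
        if parent not in gca:
            raise ValueError(f"parent {parent!r} has no phenotyped crosses; GCA undefined")
    n_crosses = pd.concat(
        [crosses.groupby("mother").size(), crosses.groupby("father").size()]
    )
    if (n_crosses < 2).any():
        warnings.warn("some parents appear in fewer than 2 crosses; GCA estimates unstable")

    gca = pd.Series(gca, name="GCA")
    sca = pd.Series(
        {
            (m, f): v - grand - gca[m] - gca[f]
            for (m, f), v in cross_means.items()
        },
        name="SCA",
    )
    f1_sca = pd.Series(
        [
            sca.get((row["mother"], row["father"]), np.nan)
            for _, row in design.crosses.iterrows()
        ],
        index=design.crosses["f1"].to_list(),
        name="SCA",
    )
    return gca, sca, f1_sca


def derive_heterosis(
    table: pd.DataFrame, design: CrossDesign, trait: str, environment: str
) -> pd.DataFrame:
    """Per-F1 derived phenotypes (F1 value, BPaV, MPV where the maternal
    value exists, SCA) for one trait in one environment."""
    means = replicate_means(table)
    means = means[(means["trait"] == trait) & (means["environment"] == environment)]
    vals = means.set_index("sample")["value"]
    crosses = design.crosses
    f1_vals = crosses["f1"].map(vals)
    pat_vals = crosses["father"].map(vals)
    mat_vals = crosses["mother"].map(vals)
    _, _, f1_sca = gca_sca(pd.Series(f1_vals.values, index=crosses["f1"].values), design)
    out = pd.DataFrame(
        {
            "f1": crosses["f1"].values,
            "mother": crosses["mother"].values,
            "father": crosses["father"].values,
            "F1": f1_vals.values,
            "BPaV": bpav(f1_vals.values, pat_vals.values),
            "MPV": mpv(f1_vals.values, pat_vals.values, mat_vals.values),
            "SCA": f1_sca.reindex(crosses["f1"].values).values,
        }
    )
    out.insert(0, "environment", environment)
    out.insert(0, "trait", trait)
    return out


def normalize_phenotype(values: pd.Series | np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset:
    Φ⁻¹((r − 3/8)/(n + 1/4)), ties receiving average ranks.

    Monotone and distribution-free; maps any continuous phenotype onto an
    approximately standard-normal scale, the Gaussian-residual premise of
    the mixed-model score test.  NaNs are preserved in place.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 20:
        raise ValueError("need >= 20 non-missing values for normalization")
    v = x[obs]
    if np.all(v == v[0]):
        raise ValueError("constant phenotype cannot be normalized")
    ranks = stats.rankdata(v, method="average")
    out = np.full_like(x, np.nan)
    out[obs] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def yield_component_regression(
    table: pd.DataFrame,
    environment: str,
    yield_trait: str = "GYPP",
    components: tuple[str, ...] = ("PN", "SNPP", "TGW"),
    role: str = "F1",
) -> pd.DataFrame:
    """Pairwise correlation and single-predictor regression R² of the yield
    trait on each component, per environment (for a single predictor the R²
    is the squared Pearson correlation)."""
    means = replicate_means(table)
    means = means[(means["environment"] == environment) & (means["role"] == role)]
    wide = means.pivot_table(index="sample", columns="trait", values="value")
    if yield_trait not in wide:
        raise ValueError(f"{yield_trait} absent from trait table")
    rows = []
    for comp in components:
        if comp not in wide:
            continue
        sub = wide[[yield_trait, comp]].dropna()
        r = sub[yield_trait].corr(sub[comp])
        rows.append({"component": comp, "r": r, "r2": r * r, "n": len(sub)})
    return pd.DataFrame(rows)
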