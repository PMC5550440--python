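"""Sliding-window Tajima's D selection scan on parental groups.

Inbred lines contribute one haplotype each (one allele per line).  Per
window the scan reports the segregating-site count S, Watterson's
theta_W = S/a1, the mean pairwise difference pi, and

    D = (pi - theta_W) / sqrt(e1*S + e2*S*(S-1))

with the standard constants a1, a2, b1, b2, c1, c2, e1, e2 derived from
the haplotype count n (Tajima 1989).  D is undefined (NaN) when the window
has fewer than 3 segregating sites or the group fewer than 4 haplotypes.
Strongly negative D flags an excess of rare variants — the footprint of a
selective sweep or strong directional breeding, the signature expected in
male-sterile maternal lines.

Defaults follow the scan design the analysis assumes: 240-kb windows with
a 20-kb step (each interior position covered by 12 windows), regions
called below the group-specific 10th percentile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["tajima_constants", "tajimas_d_value", "tajimas_d", "low_d_regions", "qtl_overlap"]


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n sampled haplotypes."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_value(haps: np.ndarray) -> tuple[float, int, float, float]:
    """Tajima's D for one window of haplotypes (rows) × sites (columns),
    alleles in {0, 1}, negatives treated as missing.

    A site enters the computation when at least 4 haplotypes are observed
    there; pi sums per-site pairwise-difference terms with the per-site
    observed count.  The variance constants use the mean observed haplotype
    count over segregating sites (exact n when there is no missingness).
    Returns (D, S, pi, theta_w); D is NaN when S < 3.
    """
    h = np.asarray(haps)
    if h.ndim != 2:
        raise ValueError("haplotype window must be 2-D")
    obs = h >= 0
    n_obs = obs.sum(axis=0)
    usable = n_obs >= 4
    if not usable.any():
        return float("nan"), 0, float("nan"), float("nan")
    h = h[:, usable]
    obs = obs[:, usable]
    n_obs = n_obs[usable]
    ones = np.where(obs, h, 0).sum(axis=0)
    zeros = n_obs - ones
    seg = (ones > 0) & (zeros > 0)
    S = int(seg.sum())
    pi = float(np.sum(2.0 * ones[seg] * zeros[seg] / (n_obs[seg] * (n_obs[seg] - 1.0)))) if S else 0.0
    if S < 3:
        return float("nan"), S, pi, float("nan")
    n_eff = int(round(float(n_obs[seg].mean())))
    c = tajima_constants(n_eff)
    theta_w = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    d = (pi - theta_w) / np.sqrt(var)
    return float(d), S, pi, float(theta_w)


def tajimas_d(
    parents: GenotypeMatrix,
    sample_ids: list[str],
    group: str,
    window: int = 240_000,
    step: int = 20_000,
) -> pd.DataFrame:
    """Sliding-window Tajima's D for one parental group.

    Inbred lines are collapsed to single haplotypes (call/2); residual
    heterozygous calls are excluded per site with a warning.  Terminal
    windows shorter than ``window`` are retained and flagged.
    """
    if len(sample_ids) < 4:
        raise ValueError("group must have at least 4 lines for Tajima's D")
    idx = parents.sample_index(sample_ids)
    calls = parents.calls[idx]
    if np.any(calls == 1):
        warnings.warn("residual heterozygous parental calls excluded per site")
    haps = np.where(calls == 0, 0, np.where(calls == 2, 1, -1)).astype(np.int8)

    rows = []
    for chrom, sub in parents.markers.groupby("chrom", sort=True):
        cols = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        chrom_end = int(pos.max())
        start = 1
        while start <= chrom_end:
            end = start + window
            in_w = cols[(pos >= start) & (pos < end)]
            d, s, pi, tw = tajimas_d_value(haps[:, in_w]) if in_w.size else (float("nan"), 0, float("nan"), float("nan"))
            rows.append(
                {
                    "chrom": int(chrom),
                    "start": start,
                    "end": end,
                    "truncated": end > chrom_end + 1,
                    "n_sites": int(in_w.size),
                    "n_segregating": s,
                    "pi": pi,
                    "theta_w": tw,
                    "tajimas_d": d,
                    "group": group,
                }
            )
            start += step
    return pd.DataFrame(rows)


def low_d_regions(scan: pd.DataFrame, percentile: float = 10.0) -> pd.DataFrame:
    """Windows at or below the group-specific Tajima's D percentile, merged
    when overlapping or adjacent (half-open intervals)."""
    if scan.empty:
        raise ValueError("empty scan")
    out = []
    for group, sub in scan.groupby("group"):
        defined = sub.dropna(subset=["tajimas_d"])
        if defined.empty:
            continue
        cutoff = np.percentile(defined["tajimas_d"], percentile)
        hits = defined[defined["tajimas_d"] <= cutoff].sort_values(["chrom", "start"])
        cur = None
        for _, row in hits.iterrows():
            if cur is not None and row["chrom"] == cur["chrom"] and row["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], row["end"])
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    out.append(cur)
                cur = {
                    "group": group,
                    "chrom": int(row["chrom"]),
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "n_windows": 1,
                    "cutoff": float(cutoff),
                }
        if cur is not None:
            out.append(cur)
    return pd.DataFrame(out, columns=["group", "chrom", "start", "end", "n_windows", "cutoff"])


def qtl_overlap(qtls: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Flag each QTL interval that intersects any low-D region, per group
    (half-open interval intersection: a.start < b.end and b.start < a.end)."""
    groups = sorted(regions["group"].unique()) if not regions.empty else []
    out = qtls.copy()
    for g in groups:
        sub = regions[regions["group"] == g]
        flags = []
        for _, q in qtls.iterrows():
            hit = (
                (sub["chrom"] == q["chrom"])
                & (sub["start"] < q["end"])
                & (q["start"] < sub["end"])
            ).any()
            flags.append(bool(hit))
        out[f"overlap_{g}"] = flags
    return out
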