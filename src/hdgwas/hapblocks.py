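"""Haplotype blocks from pairwise D' confidence intervals.

Inbred parental lines are trivially phased (each line is one haplotype), so
two-locus haplotype counts come straight from the calls.  For each marker
pair the likelihood of |D'| given the haplotype counts is profiled on a
grid (allele frequencies held at their MLEs), giving a one-sided 90%
confidence interval [CL, CU].  A pair is in *strong LD* when CL >= 0.70 and
CU >= 0.98, and shows *strong recombination* when CU < 0.90; other pairs
are uninformative.  A candidate interval of markers is accepted as a block
when its outermost pair is in strong LD and at least 95% of its informative
pairs are strong.  The QTL interval for a lead SNP is the widest accepted
block containing it, else the degenerate single-position interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["dprime_ci", "hapblock_interval", "BlockResult"]

STRONG_LOW = 0.70
STRONG_HIGH = 0.98
RECOMB_HIGH = 0.90
STRONG_FRACTION = 0.95


def dprime_ci(
    hap_a: np.ndarray, hap_b: np.ndarray, grid_points: int = 101
) -> tuple[float, float] | None:
    """One-sided 90% likelihood interval [CL, CU] for |D'| between two
    biallelic sites, given haplotype alleles in {0, 1} (negatives treated
    as missing).  Returns None when either site is monomorphic among the
    jointly observed haplotypes (uninformative pair)."""
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok].astype(int), b[ok].astype(int)
    n = a.size
    if n < 4:
        return None
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = n - n11 - n10 - n01
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    d = n11 / n - pa * pb
    if d < 0:
        # flip B's allele labels so D >= 0; |D'| is label-invariant
        b = 1 - b
        n11, n10, n01, n00 = n10, n11, n00, n01
        pb = 1.0 - pb
        d = -d
    dmax = min(pa * (1 - pb), (1 - pa) * pb)
    if dmax <= 0:
        return None
    grid = np.linspace(0.0, 1.0, grid_points)
    f11 = np.clip(pa * pb + grid * dmax, 1e-12, 1.0)
    f10 = np.clip(pa * (1 - pb) - grid * dmax, 1e-12, 1.0)
    f01 = np.clip((1 - pa) * pb - grid * dmax, 1e-12, 1.0)
    f00 = np.clip((1 - pa) * (1 - pb) + grid * dmax, 1e-12, 1.0)
    ll = n11 * np.log(f11) + n10 * np.log(f10) + n01 * np.log(f01) + n00 * np.log(f00)
    lik = np.exp(ll - ll.max())
    cum = np.cumsum(lik)
    cum /= cum[-1]
    cl = float(grid[int(np.searchsorted(cum, 0.05))])
    cu = float(grid[int(np.searchsorted(cum, 0.95))])
    return cl, cu


@dataclass
class BlockResult:
    chrom: int
    start: int
    end: int
    marker_ids: list[str]
    degenerate: bool


def _pair_status(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strong-LD and informative boolean matrices over all marker pairs of a
    (haplotypes x markers) window."""
    m = haps.shape[1]
    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            ci = dprime_ci(haps[:, i], haps[:, j])
            if ci is None:
                continue
            cl, cu = ci
            if cl >= STRONG_LOW and cu >= STRONG_HIGH:
                strong[i, j] = strong[j, i] = True
                informative[i, j] = informative[j, i] = True
            elif cu < RECOMB_HIGH:
                informative[i, j] = informative[j, i] = True
    return strong, informative


def hapblock_interval(
    lead_id: str,
    parents: GenotypeMatrix,
    max_flank_markers: int = 50,
) -> BlockResult:
    """QTL interval for a lead SNP: the widest D'-confidence block of the
    parental haplotypes containing it (search restricted to
    ``max_flank_markers`` markers on each side), else the lead SNP's own
    position as a degenerate interval."""
    rows = parents.markers.index[parents.markers["id"] == lead_id]
    if len(rows) == 0:
        raise KeyError(f"lead SNP {lead_id!r} not in parental markers")
    j0 = int(rows[0])
    chrom = int(parents.markers.loc[j0, "chrom"])
    on_chrom = parents.markers.index[parents.markers["chrom"] == chrom].to_numpy()
    k0 = int(np.flatnonzero(on_chrom == j0)[0])
    lo = max(0, k0 - max_flank_markers)
    hi = min(len(on_chrom), k0 + max_flank_markers + 1)
    window = on_chrom[lo:hi]
    lead_k = k0 - lo

    # inbred parents: haplotype allele = call / 2; het or missing → -1
    calls = parents.calls[:, window]
    haps = np.where(calls == 0, 0, np.where(calls == 2, 1, -1)).astype(np.int8)
    if np.any(calls == 1):
        warnings.warn("residual heterozygous parental calls treated as missing haplotypes")

    pos = parents.markers.loc[window, "pos"].to_numpy()
    ids = parents.markers.loc[window, "id"].to_list()
    lead_pos = int(pos[lead_k])

    col = haps[:, lead_k]
    obs = col[col >= 0]
    if obs.size == 0 or np.all(obs == obs[0]):
        warnings.warn(f"lead SNP {lead_id} monomorphic in parents; degenerate interval")
        return BlockResult(chrom, lead_pos, lead_pos, [lead_id], degenerate=True)

    strong, informative = _pair_status(haps)

    best: tuple[int, int] | None = None
    m = haps.shape[1]
    # widest span first so the first accepted candidate wins
    candidates = sorted(
        ((i, j) for i in range(0, lead_k + 1) for j in range(max(lead_k, i + 1), m)),
        key=lambda ij: (-(pos[ij[1]] - pos[ij[0]]), -(ij[1] - ij[0])),
    )
    for i, j in candidates:
        if not strong[i, j]:
            continue
        sub_s = strong[i : j + 1, i : j + 1]
        sub_i = informative[i : j + 1, i : j + 1]
        n_inf = sub_i.sum() // 2
        n_str = sub_s.sum() // 2
        if n_inf > 0 and n_str / n_inf >= STRONG_FRACTION:
            best = (i, j)
            break
    if best is None:
        return BlockResult(chrom, lead_pos, lead_pos, [lead_id], degenerate=True)
    i, j = best
    return BlockResult(chrom, int(pos[i]), int(pos[j]), ids[i : j + 1], degenerate=False)
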