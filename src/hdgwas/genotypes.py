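"""Genotype containers, I/O and core population-genetic computations.

The central object is :class:`GenotypeMatrix`: samples × biallelic markers
with genome coordinates, calls coded ``0`` (homozygous reference/major),
``1`` (heterozygous), ``2`` (homozygous alternate/minor) and ``-1``
(missing).  Parents of a two-line hybrid panel are (near-)inbred, so their
calls are expected to be homozygous; F1 hybrids are assembled from the two
parental homozygotes and carry the heterozygosity the analysis is about.

Coordinates are 1-based; windows are half-open ``[start, start + W)``,
matching MAP/VCF convention and preventing double counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "CrossDesign",
    "KinshipMatrix",
    "FilterReport",
    "filter_markers",
    "polymorphic_filter",
    "maf_filter",
    "knn_impute",
    "combine_f1",
    "heterozygosity",
    "kinship",
    "pca",
    "maf_by_group",
    "read_vcf",
    "read_ped_map",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples × biallelic markers.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``calls``.
    markers
        DataFrame with columns ``chrom`` (int), ``pos`` (int, 1-based),
        ``id`` (str), ``a1``/``a2`` (allele labels; ``a1`` is the allele
        counted as 0, ``a2`` as 2).  Positions must be strictly increasing
        within each chromosome.
    calls
        ``int8`` array of shape (n_samples, n_markers) with values in
        {0, 1, 2, -1}.
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        self.markers = self.markers.reset_index(drop=True)
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(list(ids), self.markers.copy(), self.calls[idx].copy())

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            list(self.samples), self.markers.iloc[idx].reset_index(drop=True), self.calls[:, idx].copy()
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.markers.copy(), self.calls.copy())

    # -- per-marker statistics ----------------------------------------------

    def missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def het_rate(self) -> np.ndarray:
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, (self.calls == 1).sum(axis=0) / np.maximum(n, 1), np.nan)

    def alt_freq(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Frequency of the a2 allele among non-missing calls."""
        calls = self.calls if sample_ids is None else self.calls[self.sample_index(sample_ids)]
        obs = calls != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)

    def maf(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        f = self.alt_freq(sample_ids)
        return np.minimum(f, 1.0 - f)

    # -- I/O -----------------------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write an uncompressed VCF 4.2 with GT-only records."""
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            chroms = self.markers["chrom"].drop_duplicates()
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.samples) + "\n")
            mk = self.markers
            for j in range(self.n_markers):
                row = mk.iloc[j]
                gts = "\t".join(gt_map[int(g)] for g in self.calls[:, j])
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['a1']}\t{row['a2']}"
                    f"\t.\t.\t.\tGT\t{gts}\n"
                )

    def to_ped_map(self, prefix) -> None:
        """Write PLINK text PED/MAP (missing allele coded 0)."""
        prefix = str(prefix)
        with open(prefix + ".map", "w") as fh:
            for _, row in self.markers.iterrows():
                fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
        a1 = self.markers["a1"].to_numpy()
        a2 = self.markers["a2"].to_numpy()
        with open(prefix + ".ped", "w") as fh:
            for i, s in enumerate(self.samples):
                alleles = []
                for j, g in enumerate(self.calls[i]):
                    if g == MISSING:
                        alleles.append("0 0")
                    elif g == 0:
                        alleles.append(f"{a1[j]} {a1[j]}")
                    elif g == 1:
                        alleles.append(f"{a1[j]} {a2[j]}")
                    else:
                        alleles.append(f"{a2[j]} {a2[j]}")
                fh.write(f"{s} {s} 0 0 0 -9 " + " ".join(alleles) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF (uncompressed, GT-based) into a GenotypeMatrix."""
    samples: list[str] = []
    chroms, poss, ids, a1s, a2s, rows = [], [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            if "," in parts[4]:
                raise ValueError(f"multi-allelic record at {parts[0]}:{parts[1]} not supported")
            chroms.append(int(parts[0]))
            poss.append(int(parts[1]))
            ids.append(parts[2])
            a1s.append(parts[3])
            a2s.append(parts[4])
            row = np.empty(len(samples), dtype=np.int8)
            for i, fieldv in enumerate(parts[9:]):
                gt = fieldv.split(":", 1)[0].replace("|", "/")
                if "." in gt:
                    row[i] = MISSING
                else:
                    a, b = gt.split("/")
                    row[i] = int(a) + int(b)
            rows.append(row)
    markers = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids, "a1": a1s, "a2": a2s})
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, markers, calls)


def read_ped_map(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    markers = pd.read_csv(
        prefix + ".map", sep="\t", header=None, names=["chrom", "id", "cm", "pos"]
    )[["chrom", "pos", "id"]]
    samples: list[str] = []
    geno_rows: list[list[tuple[str, str]]] = []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            samples.append(parts[1])
            alleles = parts[6:]
            geno_rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(len(alleles) // 2)])
    n, m = len(samples), len(markers)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    a1s, a2s = [], []
    for j in range(m):
        # PED carries no reference allele: code the major allele as 0
        # (frequency ties break lexicographically), PLINK-style
        counts: dict[str, int] = {}
        for i in range(n):
            for a in geno_rows[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        seen = sorted(counts, key=lambda a: (-counts[a], a))
        if not seen:
            seen = ["A"]
        a1 = seen[0]
        a2 = seen[1] if len(seen) > 1 else ("B" if a1 != "B" else "A")
        a1s.append(a1)
        a2s.append(a2)
        for i in range(n):
            x, y = geno_rows[i][j]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x == a2) + (y == a2)
    markers = markers.assign(a1=a1s, a2=a2s)
    return GenotypeMatrix(samples, markers, calls)


@dataclass
class CrossDesign:
    """Mapping of F1 hybrids to their maternal (male-sterile) and paternal
    (restorer) inbred lines.

    ``crosses`` columns: ``f1``, ``mother``, ``father``, ``family`` (the RIL
    family of the paternal line).
    """

    crosses: pd.DataFrame

    def __post_init__(self) -> None:
        self.crosses = self.crosses.reset_index(drop=True)
        mothers = set(self.crosses["mother"])
        fathers = set(self.crosses["father"])
        if mothers & fathers:
            raise ValueError("maternal and paternal line sets must be disjoint")

    @property
    def f1_ids(self) -> list[str]:
        return list(self.crosses["f1"])

    @property
    def maternal_lines(self) -> list[str]:
        return list(dict.fromkeys(self.crosses["mother"]))

    @property
    def paternal_lines(self) -> list[str]:
        return list(dict.fromkeys(self.crosses["father"]))

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.crosses["father"], self.crosses["family"]))

    def validate_against(self, geno: GenotypeMatrix) -> None:
        present = set(geno.samples)
        for _, row in self.crosses.iterrows():
            if row["mother"] not in present or row["father"] not in present:
                raise KeyError(
                    f"cross {row['f1']} = {row['mother']} x {row['father']} references a parent "
                    "absent from the genotype matrix"
                )

    def to_tsv(self, path) -> None:
        self.crosses.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path) -> "CrossDesign":
        return CrossDesign(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class KinshipMatrix:
    """Realized-relationship (GRM) matrix with its sample order."""

    samples: list[str]
    values: np.ndarray

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([lookup[s] for s in ids], dtype=int)
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    n_input: int
    n_removed_missing: int
    n_removed_het: int
    n_output: int


def filter_markers(
    geno: GenotypeMatrix, max_missing: float = 0.2, max_het: float = 0.15
) -> tuple[GenotypeMatrix, FilterReport]:
    """Sequential marker QC: drop markers with missing rate > ``max_missing``,
    then drop survivors with heterozygous-call rate > ``max_het``.

    Both thresholds are inclusive (a marker exactly at the threshold is
    retained).  The two steps are applied in this order so the removal counts
    match a sequential-reporting convention.
    """
    if not (0 <= max_missing <= 1 and 0 <= max_het <= 1):
        raise ValueError("rates must be in [0, 1]")
    n0 = geno.n_markers
    keep1 = geno.missing_rate() <= max_missing
    g1 = geno.subset_markers(keep1)
    het = g1.het_rate()
    keep2 = np.where(np.isnan(het), True, het <= max_het)
    g2 = g1.subset_markers(keep2)
    report = FilterReport(
        n_input=n0,
        n_removed_missing=int(n0 - keep1.sum()),
        n_removed_het=int(keep1.sum() - keep2.sum()),
        n_output=g2.n_markers,
    )
    if g2.n_markers == 0:
        warnings.warn("all markers removed by QC filters")
    return g2, report


def polymorphic_filter(geno: GenotypeMatrix, sample_ids: Sequence[str] | None = None) -> GenotypeMatrix:
    """Remove markers monomorphic on the given sample set (default: all)."""
    calls = geno.calls if sample_ids is None else geno.calls[geno.sample_index(sample_ids)]
    n_classes = sum((calls == g).any(axis=0) for g in (0, 1, 2))
    return geno.subset_markers(n_classes >= 2)


def maf_filter(
    geno: GenotypeMatrix, min_maf: float = 0.05, sample_ids: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Keep markers with MAF >= ``min_maf`` (inclusive) on the given samples."""
    maf = geno.maf(sample_ids)
    keep = np.where(np.isnan(maf), False, maf >= min_maf)
    return geno.subset_markers(keep)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _pairwise_call_distance(calls: np.ndarray) -> np.ndarray:
    """Mean absolute call difference over shared non-missing markers.

    Computed from one-hot indicator products so the whole distance matrix is
    a handful of BLAS calls; pairs with no shared observed marker get inf.
    """
    i0 = (calls == 0).astype(np.float32)
    i1 = (calls == 1).astype(np.float32)
    i2 = (calls == 2).astype(np.float32)
    obs = (calls != MISSING).astype(np.float32)
    shared = obs @ obs.T
    diff1 = i0 @ i1.T + i1 @ i0.T + i1 @ i2.T + i2 @ i1.T
    diff2 = i0 @ i2.T + i2 @ i0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (diff1 + 2.0 * diff2) / shared
    d[shared == 0] = np.inf
    return d


def knn_impute(
    geno: GenotypeMatrix, reference_panel: GenotypeMatrix | None = None, k: int = 5
) -> GenotypeMatrix:
    """Replace each missing call by the majority (mode) call of the ``k``
    nearest samples, by allele-sharing distance over non-missing markers.

    The reference panel (if given) must share the marker set; panel samples
    contribute neighbours but are not imputed or returned.  Neighbour ranking
    ties break by sample order and mode ties by the smaller call code, so the
    result is deterministic.  Observed calls are never changed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if reference_panel is not None:
        if not reference_panel.markers["id"].equals(geno.markers["id"]):
            raise ValueError("reference panel must share the marker set")
        pool = np.vstack([geno.calls, reference_panel.calls])
    else:
        pool = geno.calls
    n = geno.n_samples
    if np.any((pool != MISSING).sum(axis=1) == 0):
        raise ValueError("sample with all-missing genotype cannot be imputed")
    dist = _pairwise_call_distance(pool)
    np.fill_diagonal(dist, np.inf)
    out = geno.calls.copy()
    for i in range(n):
        miss = np.flatnonzero(out[i] == MISSING)
        if miss.size == 0:
            continue
        order = np.argsort(dist[i], kind="stable")
        cand = pool[order][:, miss]  # neighbours (ranked) x missing markers
        observed = cand != MISSING
        rank = np.cumsum(observed, axis=0)
        use = observed & (rank <= k)
        for col, j in enumerate(miss):
            votes = cand[use[:, col], col]
            if votes.size == 0:
                continue  # no informative neighbour; leave missing
            counts = np.bincount(votes, minlength=3)
            out[i, j] = int(np.argmax(counts))  # argmax takes smaller code on ties
    return GenotypeMatrix(list(geno.samples), geno.markers.copy(), out)


# ---------------------------------------------------------------------------
# F1 assembly and heterozygosity
# ---------------------------------------------------------------------------


def combine_f1(parents: GenotypeMatrix, design: CrossDesign) -> GenotypeMatrix:
    """Assemble F1 genotypes as the union of one allele from each inbred
    parent: hom x hom-different → het; identical homozygotes → that
    homozygote; a heterozygous or missing parental call → missing F1 call.
    """
    design.validate_against(parents)
    mi = parents.sample_index(design.crosses["mother"])
    fi = parents.sample_index(design.crosses["father"])
    m = parents.calls[mi].astype(np.int16)
    f = parents.calls[fi].astype(np.int16)
    bad = (m == 1) | (f == 1) | (m == MISSING) | (f == MISSING)
    out = ((m + f) // 2).astype(np.int8)
    out[bad] = MISSING
    return GenotypeMatrix(design.f1_ids, parents.markers.copy(), out)


def heterozygosity(
    geno: GenotypeMatrix, window: int | None = None
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-sample heterozygous-call fraction, and (optionally) the mean
    heterozygosity in non-overlapping windows of ``window`` bp, averaged
    over samples."""
    obs = geno.calls != MISSING
    het = geno.calls == 1
    n_obs = obs.sum(axis=1)
    per_sample = pd.Series(
        np.where(n_obs > 0, het.sum(axis=1) / np.maximum(n_obs, 1), np.nan),
        index=geno.samples,
        name="heterozygosity",
    )
    if window is None:
        return per_sample, None
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom, sub in geno.markers.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        start = 1
        last = pos.max()
        while start <= last:
            in_w = idx[(pos >= start) & (pos < start + window)]
            if in_w.size:
                o = obs[:, in_w].sum()
                h = het[:, in_w].sum()
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + window,
                        "n_markers": int(in_w.size),
                        "heterozygosity": h / o if o else np.nan,
                    }
                )
            start += window
    return per_sample, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinship and PCA
# ---------------------------------------------------------------------------


def _centered_standardized(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    if np.any(geno.calls == MISSING):
        raise ValueError("kinship/PCA require a complete (imputed) matrix")
    X = geno.calls.astype(np.float64)
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} monomorphic markers skipped in kinship/PCA")
    X = X[:, keep]
    p = p[keep]
    Z = X - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return Z, np.array([denom])


def kinship(geno: GenotypeMatrix, bend_floor: float = 1e-6) -> KinshipMatrix:
    """VanRaden frequency-weighted GRM: K = ZZ' / (2 Σ p(1-p)), with
    eigenvalues floored at ``bend_floor`` for solver stability."""
    Z, denom = _centered_standardized(geno)
    K = (Z @ Z.T) / denom[0]
    w, V = np.linalg.eigh(K)
    if w.min() < bend_floor:
        w = np.maximum(w, bend_floor)
        K = (V * w) @ V.T
        K = (K + K.T) / 2.0
    return KinshipMatrix(list(geno.samples), K)


def pca(geno: GenotypeMatrix, n_components: int = 10) -> pd.DataFrame:
    """Principal components of the frequency-standardized GRM; scores are
    eigenvectors scaled by the square-rooted eigenvalues.  Sign is fixed so
    each component's largest-magnitude loading is positive."""
    Z, denom = _centered_standardized(geno)
    K = (Z @ Z.T) / denom[0]
    w, V = np.linalg.eigh(K)
    order = np.argsort(w)[::-1][:n_components]
    w = np.maximum(w[order], 0.0)
    V = V[:, order]
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = V * np.sqrt(w)
    return pd.DataFrame(scores, index=geno.samples, columns=[f"PC{i+1}" for i in range(len(order))])


def maf_by_group(
    geno: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    around: str,
    flank: int,
) -> pd.DataFrame:
    """Per-marker MAF within each sample group across a window of ``flank``
    bp on either side of the focal marker ``around``."""
    for name, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"group {name!r} is empty")
    row = geno.markers.index[geno.markers["id"] == around]
    if len(row) == 0:
        raise KeyError(f"marker {around!r} not found")
    focal = geno.markers.loc[row[0]]
    mask = (geno.markers["chrom"] == focal["chrom"]) & (
        (geno.markers["pos"] - focal["pos"]).abs() <= flank
    )
    sub = geno.subset_markers(mask.to_numpy())
    out = sub.markers[["chrom", "pos", "id"]].copy()
    out["offset"] = out["pos"] - focal["pos"]
    for name, ids in groups.items():
        out[f"maf_{name}"] = sub.maf(list(ids))
    return out
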