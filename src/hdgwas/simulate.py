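"""Synthetic partial-diallel populations with known QTL architecture.

The generator emulates the statistical structure of a two-line hybrid rice
panel: a small set of male-sterile maternal lines descended from few
ancestors, several RIL families of restorer paternal lines (each family a
recombinant mosaic of two founder genomes), and the F1 hybrids of every
maternal × paternal cross.  Defaults mirror the study design the analysis
assumes: 14 maternal lines, 3 paternal RIL families of 13 lines
(14 × 39 = 546 F1s), 12 chromosomes, a chip-like raw panel of ~51.6k
biallelic markers of which the polymorphic MAF-filtered subset survives QC.

Phenotypes follow the standard F2 parametrization at each simulated QTL
(genotypic values −a, d, +a for 0/1/2 copies of the alternate allele) plus
an optional infinitesimal polygenic background and i.i.d. replicate noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, CrossDesign, combine_f1

__all__ = ["QtlSpec", "SimulationConfig", "GroundTruth", "simulate_parents", "simulate_f1_phenotypes", "simulate_diallel"]


@dataclass
class QtlSpec:
    """One simulated QTL.

    ``additive_effect`` (a, >= 0 by convention: the sign is absorbed into
    allele labels) and ``dominance_effect`` (d) are in trait units.
    ``fixed_in`` fixes one parental group for the reference allele, which
    makes the locus a two-genotype QTL in the F1s and leaves the alternate
    (trait-increasing) allele segregating only in the other group.
    """

    chromosome: int
    position: int
    additive_effect: float
    dominance_effect: float
    fixed_in: str = "none"  # none | maternal | paternal
    # radius (bp) of the hitchhiking region dragged toward the focal
    # haplotype in the fixed group: markers within the span copy the first
    # founder's allele with probability 0.9, leaving the rare variants that
    # give a selective sweep its negative Tajima's D footprint
    sweep_span: int = 0

    def __post_init__(self) -> None:
        if self.additive_effect < 0:
            raise ValueError("additive_effect must be >= 0 (sign convention)")
        if self.fixed_in not in ("none", "maternal", "paternal"):
            raise ValueError(f"invalid fixed_in: {self.fixed_in!r}")


@dataclass
class SimulationConfig:
    n_maternal: int = 14
    n_paternal_families: int = 3
    lines_per_family: int = 13
    n_chromosomes: int = 12
    markers_per_chromosome: int = 4300
    chrom_length: int = 30_000_000
    qtl_specs: list[QtlSpec] = field(default_factory=list)
    h2_polygenic: float = 0.3
    residual_sd: float = 1.0
    n_replicates: int = 3
    seed: int = 0
    trait: str = "GYPP"
    environment: str = "E1"
    mean: float = 0.0
    # number of founder haplotypes the maternal pool is resampled from
    n_maternal_founders: int = 3
    # expected crossovers per chromosome per mosaic draw
    crossover_rate: float = 1.0
    # fraction of sites where every founder haplotype copies a shared
    # ancestral consensus haplotype; models the common elite breeding
    # background of both parental groups.  The default is set so that
    # per-F1 heterozygosity on the polymorphic MAF-filtered panel falls in
    # the observed 17.5-28.4% range.
    shared_ancestry: float = 0.9

    def __post_init__(self) -> None:
        if min(self.n_maternal, self.n_paternal_families, self.lines_per_family) < 1:
            raise ValueError("line counts must be positive")
        if min(self.n_chromosomes, self.markers_per_chromosome) < 1:
            raise ValueError("need at least one chromosome and one marker")
        if not 0 <= self.h2_polygenic < 1:
            raise ValueError("h2_polygenic must be in [0, 1)")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for q in self.qtl_specs:
            if not (1 <= q.chromosome <= self.n_chromosomes):
                raise ValueError(f"QTL chromosome {q.chromosome} out of range")
            if not (1 <= q.position <= self.chrom_length):
                raise ValueError(f"QTL position {q.position} outside chromosome")

    @property
    def n_paternal(self) -> int:
        return self.n_paternal_families * self.lines_per_family

    @property
    def n_f1(self) -> int:
        return self.n_maternal * self.n_paternal


@dataclass
class GroundTruth:
    """Planted architecture, recoverable bit-identically from the seed."""

    qtl_markers: list[str]
    qtl_positions: list[tuple[int, int]]  # (chrom, pos of assigned marker)
    additive_effects: list[float]
    dominance_effects: list[float]
    d_over_a: list[float]
    genetic_values: pd.Series  # per sample (parents and F1s)
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "qtl_markers": self.qtl_markers,
            "qtl_positions": [list(t) for t in self.qtl_positions],
            "additive_effects": self.additive_effects,
            "dominance_effects": self.dominance_effects,
            "d_over_a": self.d_over_a,
            "genetic_values": self.genetic_values.to_dict(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------


def _marker_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    spacing = config.chrom_length / (config.markers_per_chromosome + 1)
    for c in range(1, config.n_chromosomes + 1):
        for j in range(config.markers_per_chromosome):
            pos = int(round((j + 1) * spacing))
            rows.append((c, max(pos, 1), f"M{c:02d}_{j:05d}", "A", "G"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "a1", "a2"])
    return df


def _mosaic(rng: np.random.Generator, hapA: np.ndarray, hapB: np.ndarray,
            markers: pd.DataFrame, chrom_length: int, rate: float) -> np.ndarray:
    """One recombinant haplotype: Poisson crossovers per chromosome at
    uniform positions, alternating between the two founder haplotypes."""
    out = np.empty_like(hapA)
    for chrom, sub in markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        n_x = rng.poisson(rate)
        cuts = np.sort(rng.uniform(0, chrom_length, size=n_x))
        current = rng.integers(2)
        seg = current + np.searchsorted(cuts, pos)  # parity of crossovers passed
        take_a = (seg % 2) == 0
        out[idx] = np.where(take_a, hapA[idx], hapB[idx])
    return out


def _nearest_marker(markers: pd.DataFrame, chrom: int, pos: int) -> int:
    sub = markers[markers["chrom"] == chrom]
    i = (sub["pos"] - pos).abs().idxmin()
    if int(markers.loc[i, "pos"]) != pos:
        warnings.warn(
            f"QTL position {chrom}:{pos} is not a marker; assigned to nearest "
            f"marker {markers.loc[i, 'id']} at {int(markers.loc[i, 'pos'])}"
        )
    return int(i)


def make_design(config: SimulationConfig) -> CrossDesign:
    """Full partial-diallel cross table: every paternal line × every
    maternal line, paternal lines grouped into RIL families."""
    rows = []
    for f in range(config.n_paternal_families):
        fam = f"G{f+1}"
        for l in range(config.lines_per_family):
            father = f"P_{fam}_{l+1:02d}"
            for m in range(config.n_maternal):
                mother = f"M{m+1:02d}"
                rows.append((f"F1_{mother}_x_{father}", mother, father, fam))
    return CrossDesign(pd.DataFrame(rows, columns=["f1", "mother", "father", "family"]))


def simulate_parents(config: SimulationConfig) -> tuple[GenotypeMatrix, CrossDesign]:
    """Simulate inbred parental genotypes with the assumed group structure.

    Founder allele frequencies are Beta(0.5, 0.5) truncated to [0.05, 0.95].
    Each paternal RIL family is a set of recombinant mosaics of two family
    founder haplotypes; maternal lines are mosaics of a narrow pool of
    ``n_maternal_founders`` haplotypes, which yields the elevated
    allele-frequency divergence of a few-ancestor group.  Loci listed in a
    QtlSpec with ``fixed_in`` are forced monomorphic (reference allele) in
    that group and forced to segregate in the other.
    """
    markers = _marker_table(config)
    m = len(markers)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1A]))

    # founder allele frequencies, shared by both parental groups
    p = np.empty(m)
    todo = np.ones(m, dtype=bool)
    while todo.any():
        draw = rng.beta(0.5, 0.5, size=int(todo.sum()))
        ok = (draw >= 0.05) & (draw <= 0.95)
        idx = np.flatnonzero(todo)
        p[idx[ok]] = draw[ok]
        todo[idx[ok]] = False

    qtl_idx = [_nearest_marker(markers, q.chromosome, q.position) for q in config.qtl_specs]

    # shared ancestral consensus: both groups descend from one elite pool
    consensus = (rng.random(m) < p).astype(np.int8)

    def founder() -> np.ndarray:
        h = (rng.random(m) < p).astype(np.int8)
        shared = rng.random(m) < config.shared_ancestry
        return np.where(shared, consensus, h).astype(np.int8)

    # paternal families: two founder haplotypes each
    pat_founders = [(founder(), founder()) for _ in range(config.n_paternal_families)]
    # maternal pool: few founder haplotypes
    mat_founders = [founder() for _ in range(config.n_maternal_founders)]

    # enforce fixed_in / segregation constraints at planted QTLs
    for q, j in zip(config.qtl_specs, qtl_idx):
        if q.fixed_in == "maternal":
            for h in mat_founders:
                h[j] = 0
            for hA, hB in pat_founders:
                hA[j], hB[j] = 0, 1
        elif q.fixed_in == "paternal":
            for hA, hB in pat_founders:
                hA[j], hB[j] = 0, 0
            for i, h in enumerate(mat_founders):
                h[j] = i % 2
        else:
            for hA, hB in pat_founders:
                hA[j], hB[j] = 0, 1
            for i, h in enumerate(mat_founders):
                h[j] = i % 2
        if q.fixed_in != "none" and q.sweep_span > 0:
            near = (
                (markers["chrom"] == q.chromosome)
                & ((markers["pos"] - markers.loc[j, "pos"]).abs() <= q.sweep_span)
            ).to_numpy()
            swept = (
                mat_founders
                if q.fixed_in == "maternal"
                else [h for pair in pat_founders for h in pair]
            )
            ref = swept[0]
            for h in swept[1:]:
                drag = near & (rng.random(m) < 0.9)
                h[drag] = ref[drag]

    samples: list[str] = []
    haplos: list[np.ndarray] = []
    design = make_design(config)
    for f in range(config.n_paternal_families):
        hA, hB = pat_founders[f]
        for l in range(config.lines_per_family):
            samples.append(f"P_G{f+1}_{l+1:02d}")
            haplos.append(_mosaic(rng, hA, hB, markers, config.chrom_length, config.crossover_rate))
    for i in range(config.n_maternal):
        a, b = rng.choice(len(mat_founders), size=2, replace=False)
        samples.append(f"M{i+1:02d}")
        haplos.append(
            _mosaic(rng, mat_founders[a], mat_founders[b], markers, config.chrom_length, config.crossover_rate)
        )
    calls = (2 * np.stack(haplos)).astype(np.int8)  # fully inbred: hom at every locus

    # re-impose fixation after recombination (mosaics of constrained founders
    # already satisfy it; kept as an explicit guarantee)
    for q, j in zip(config.qtl_specs, qtl_idx):
        if q.fixed_in == "maternal":
            for i, s in enumerate(samples):
                if s.startswith("M"):
                    calls[i, j] = 0
        elif q.fixed_in == "paternal":
            for i, s in enumerate(samples):
                if s.startswith("P_"):
                    calls[i, j] = 0

    geno = GenotypeMatrix(samples, markers, calls)
    return geno, design


def _genetic_values(calls_at_qtls: np.ndarray, specs: list[QtlSpec]) -> np.ndarray:
    g = np.zeros(calls_at_qtls.shape[0])
    for k, q in enumerate(specs):
        x = calls_at_qtls[:, k].astype(float)
        g += q.additive_effect * (x - 1.0) + q.dominance_effect * (x == 1.0)
    return g


def simulate_f1_phenotypes(
    parents: GenotypeMatrix,
    design: CrossDesign,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth, GenotypeMatrix]:
    """Simulate one trait for all F1s and parents.

    phenotype = mean + Σ_q [a_q·(x−1) + d_q·1(x=1)] + polygenic + N(0, residual_sd²)
    per replicate.  The polygenic term is multivariate normal on the GRM of
    all samples with variance h2_polygenic/(1−h2_polygenic)·residual_sd², so
    ``h2_polygenic`` is the polygenic share of the non-QTL variance.
    Parental phenotypes come from the same model (no heterozygotes, hence no
    dominance deviations).  Returns the long-format trait table, the ground
    truth, and the assembled F1 genotype matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFE1]))
    f1 = combine_f1(parents, design)
    markers = parents.markers
    qtl_idx = [_nearest_marker(markers, q.chromosome, q.position) for q in config.qtl_specs]

    all_samples = list(parents.samples) + list(f1.samples)
    all_calls = np.vstack([parents.calls, f1.calls])
    if qtl_idx:
        g = _genetic_values(all_calls[:, qtl_idx], config.qtl_specs)
    else:
        g = np.zeros(len(all_samples))

    if config.h2_polygenic > 0 and config.residual_sd > 0:
        # infinitesimal model: i.i.d. small effects on every marker, applied
        # to parents and F1s alike, so the F1 polygenic covariance is exactly
        # proportional to the realized-relationship matrix of the analyzed
        # markers (the covariance the mixed model assumes)
        sigma_poly = config.residual_sd * np.sqrt(config.h2_polygenic / (1 - config.h2_polygenic))
        Z = all_calls.astype(float)
        Z -= Z.mean(axis=0)
        beta = rng.standard_normal(Z.shape[1])
        u = Z @ beta
        sd = u[len(parents.samples):].std()  # scale on the F1 subpanel
        u *= sigma_poly / sd if sd > 0 else 0.0
    else:
        u = np.zeros(len(all_samples))

    base = config.mean + g + u
    role = ["paternal" if s.startswith("P_") else "maternal" for s in parents.samples] + [
        "F1"
    ] * f1.n_samples
    rows = []
    for rep in range(1, config.n_replicates + 1):
        noise = (
            rng.standard_normal(len(all_samples)) * config.residual_sd
            if config.residual_sd > 0
            else np.zeros(len(all_samples))
        )
        vals = base + noise
        for i, s in enumerate(all_samples):
            rows.append((s, role[i], config.environment, rep, config.trait, vals[i]))
    table = pd.DataFrame(
        rows, columns=["sample", "role", "environment", "replicate", "trait", "value"]
    )

    truth = GroundTruth(
        qtl_markers=[markers.loc[j, "id"] for j in qtl_idx],
        qtl_positions=[(int(markers.loc[j, "chrom"]), int(markers.loc[j, "pos"])) for j in qtl_idx],
        additive_effects=[q.additive_effect for q in config.qtl_specs],
        dominance_effects=[q.dominance_effect for q in config.qtl_specs],
        d_over_a=[
            (q.dominance_effect / q.additive_effect) if q.additive_effect != 0 else float("inf")
            for q in config.qtl_specs
        ],
        genetic_values=pd.Series(g, index=all_samples),
        seed=config.seed,
    )
    return table, truth, f1


def simulate_diallel(config: SimulationConfig):
    """Convenience wrapper: parents + design + F1 genotypes + one trait."""
    parents, design = simulate_parents(config)
    table, truth, f1 = simulate_f1_phenotypes(parents, design, config)
    return parents, design, f1, table, truth
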