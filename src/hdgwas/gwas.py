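"""Forward-selection resampling GWAS with a kinship-aware score test.

The engine repeatedly (default 300 times at full scale, 50 in scaled mode)
draws a random 80% subsample of the panel without replacement, runs a
forward-selection mixed-model GWAS on it under each of four inheritance
models, and reports per marker the resample model inclusion probability
(RMIP, on a 0–100 scale): the percentage of subsamples whose forward
selection included that marker.  Aggregating over subsamples suppresses the
spurious long-range signals that a single highly structured panel produces.

Inheritance models recode the genotype calls (0 = hom major, 1 = het,
2 = hom minor) before testing:

========================  =============
additive                  (0, 1, 2)
dominance                 (0, 0, 2)
recessive                 (0, 2, 2)
overdominance             (0, 1, 0)
========================  =============

The association test is a 1-df chi-square score test on phenotype residuals
whitened by the fitted polygenic covariance (sigma_g^2 K + sigma_e^2 I);
with identity kinship it reduces exactly to the ordinary least-squares
score test.  Scans are whitened per chromosome by leave-one-chromosome-out
kinship (LOCO) so a marker's own LD block cannot absorb its signal.  The
genome-wide significance threshold per trait is a lower quantile of the
per-permutation minimum p (minimum across markers and inheritance models)
from permutations of the whitened model residuals; by default the quantile
is calibrated so the reported RMIP-thresholded SNP list, not just a single
scan, is a 5%-level decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .genotypes import GenotypeMatrix, KinshipMatrix

__all__ = [
    "MODELS",
    "recode",
    "PolygenicFit",
    "fit_polygenic",
    "score_test_batch",
    "permutation_threshold",
    "procedure_alpha",
    "forward_select",
    "resample_rmip",
    "AssociationResult",
    "Signal",
    "significant_snps",
    "merge_signals",
]

# (value for het, value for hom-minor); hom-major is always 0
MODELS: dict[str, tuple[float, float]] = {
    "additive": (1.0, 2.0),
    "dominance": (0.0, 2.0),
    "recessive": (2.0, 2.0),
    "overdominance": (1.0, 0.0),
}


def recode(calls: np.ndarray, model: str) -> np.ndarray:
    """Recode a call matrix under an inheritance model (missing → column
    mean of the coded values, which contributes zero score)."""
    het, hom = MODELS[model]
    X = het * (calls == 1) + hom * (calls == 2)
    miss = calls == -1
    if miss.any():
        X = X.astype(float)
        obs = ~miss
        colmean = np.where(obs.sum(0) > 0, (X * obs).sum(0) / np.maximum(obs.sum(0), 1), 0.0)
        X = np.where(miss, colmean, X)
    return np.asarray(X, dtype=np.float64)


# ---------------------------------------------------------------------------
# polygenic model
# ---------------------------------------------------------------------------


@dataclass
class PolygenicFit:
    """ML fit of y = Xb + u + e with u ~ N(0, sigma_g^2 K).

    ``whiten`` maps vectors/matrices into the space where the fitted
    covariance is the identity (up to total scale), so downstream score
    tests are ordinary projections.
    """

    h2: float
    sigma_g2: float
    sigma_e2: float
    eigvecs: np.ndarray  # U of K = U diag(l) U'
    weights: np.ndarray  # h2 * l + (1 - h2)
    loglik: float

    def whiten(self, M: np.ndarray) -> np.ndarray:
        r = self.eigvecs.T @ M
        if r.ndim == 1:
            return r / np.sqrt(self.weights)
        return r / np.sqrt(self.weights)[:, None]


def fit_polygenic(
    y: np.ndarray,
    K: np.ndarray | KinshipMatrix,
    X: np.ndarray | None = None,
    bend_floor: float = 1e-6,
) -> PolygenicFit:
    """ML variance components by 1-D optimization of the heritability ratio
    on the kinship eigenbasis (non-PSD kinship is bent by eigenvalue
    flooring, with a warning)."""
    if isinstance(K, KinshipMatrix):
        K = K.values
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 30:
        warnings.warn(f"polygenic fit on only {n} samples; variance components unstable")
    if X is None:
        X = np.ones((n, 1))
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-8:
        warnings.warn("kinship matrix not PSD; bending by eigenvalue flooring")
    lam = np.maximum(lam, bend_floor)
    ystar = U.T @ y
    Xstar = U.T @ X

    def negll(h2: float) -> float:
        w = h2 * lam + (1.0 - h2)
        sw = np.sqrt(w)
        Xw = Xstar / sw[:, None]
        yw = ystar / sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        sigma2 = rss / n
        return 0.5 * (n * np.log(2 * np.pi * sigma2) + float(np.sum(np.log(w))) + n)

    res = optimize.minimize_scalar(negll, bounds=(1e-6, 1 - 1e-6), method="bounded")
    h2 = float(res.x)
    if h2 > 1 - 1e-3 or h2 < 1e-3:
        warnings.warn(f"heritability ratio at boundary (h2={h2:.4f}); proceeding")
    w = h2 * lam + (1.0 - h2)
    sw = np.sqrt(w)
    Xw = Xstar / sw[:, None]
    yw = ystar / sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    sigma2 = float(np.sum((yw - Xw @ beta) ** 2)) / n
    return PolygenicFit(
        h2=h2,
        sigma_g2=h2 * sigma2,
        sigma_e2=(1.0 - h2) * sigma2,
        eigvecs=U,
        weights=w,
        loglik=-float(res.fun),
    )


# ---------------------------------------------------------------------------
# score test
# ---------------------------------------------------------------------------


def _null_projection(Xw: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(Xw)
    return Q


def score_test_batch(
    yw: np.ndarray, Xw: np.ndarray, Gw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score test of every column of ``Gw`` against ``yw`` with fixed
    covariates ``Xw``, all pre-whitened.  Returns (p-values, effect sizes).

    Residualizes phenotype and predictors on the covariates; the statistic
    (g'r)^2 / (g'g sigma0^2) is chi-square with 1 df under the null.
    Columns collinear with the covariates (monomorphic after residualizing)
    get p = 1 and effect 0.
    """
    n, p = Xw.shape
    Q = _null_projection(Xw)
    ry = yw - Q @ (Q.T @ yw)
    RG = Gw - Q @ (Q.T @ Gw)
    gss = np.einsum("ij,ij->j", RG, RG)
    gy = RG.T @ ry
    sigma2 = float(ry @ ry) / max(n - p, 1)
    total = np.einsum("ij,ij->j", Gw, Gw)
    degenerate = gss <= 1e-10 * np.maximum(total, 1.0)
    safe_gss = np.where(degenerate, 1.0, gss)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = gy**2 / (safe_gss * sigma2) if sigma2 > 0 else np.zeros_like(gy)
    stat = np.where(degenerate, 0.0, stat)
    pvals = stats.chi2.sf(stat, df=1)
    pvals = np.where(degenerate, 1.0, pvals)
    betas = np.where(degenerate, 0.0, gy / safe_gss)
    return pvals, betas


def permutation_threshold(
    y: np.ndarray,
    coded: dict[str, np.ndarray],
    fit: PolygenicFit,
    X: np.ndarray | None = None,
    n_perm: int = 100,
    fdr: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Per-trait genome-wide p threshold from residual permutations.

    The exchangeable quantities under the fitted polygenic null are the
    whitened, covariate-residualized phenotype residuals, so those are what
    get permuted (permuting raw labels would compare a structured scan
    against an unstructured null and inflate the threshold's error rate).
    For every permutation the minimum p across all markers and all
    inheritance models is recorded; the threshold is the ``fdr`` quantile
    of those minima, so a fraction ~``fdr`` of null genome scans produce
    any hit.  Returns (threshold, minima).
    """
    if n_perm < 50:
        warnings.warn(f"n_perm={n_perm} is low; threshold estimate unstable")
    rng = rng or np.random.default_rng(0)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    Xw = fit.whiten(X)
    Q = _null_projection(Xw)
    yw = fit.whiten(y)
    ry = yw - Q @ (Q.T @ yw)
    perms = np.stack([rng.permutation(ry) for _ in range(n_perm)], axis=1)
    # re-residualize permuted residuals on the covariates (Freedman-Lane)
    RY = perms - Q @ (Q.T @ perms)
    sig2 = np.einsum("ij,ij->j", RY, RY) / max(n - X.shape[1], 1)
    minima = np.full(n_perm, 1.0)
    for model, G in coded.items():
        Gw = fit.whiten(G)
        RG = Gw - Q @ (Q.T @ Gw)
        gss = np.einsum("ij,ij->j", RG, RG)
        ok = gss > 1e-10 * np.maximum(np.einsum("ij,ij->j", Gw, Gw), 1.0)
        gy = RG.T @ RY  # markers x perms
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = gy**2 / (gss[:, None] * sig2[None, :])
        stat[~ok, :] = 0.0
        pmin = stats.chi2.sf(stat.max(axis=0), df=1)
        minima = np.minimum(minima, pmin)
    k = max(int(np.floor(fdr * n_perm)), 1)
    threshold = float(np.sort(minima)[k - 1])
    return threshold, minima


def procedure_alpha(n_resamples: int, rmip_threshold: float, fdr: float) -> float:
    """Scan-level significance quantile that controls the procedure-level
    familywise error at ``fdr``.

    A marker is reported when it enters the forward selection in at least
    k = ceil(rmip_threshold/100 * n_resamples) of the subsamples.  Because
    null hits concentrate on the same borderline marker across overlapping
    subsamples, the worst case is full concentration, giving a run-level
    error of P(Binom(n_resamples, q) >= k) for per-scan hit rate q.  The
    returned q solves that equation at ``fdr``, so the permutation
    threshold built from it keeps the fraction of null runs reporting any
    RMIP-significant SNP at or below ``fdr``.
    """
    k = max(int(np.ceil(rmip_threshold / 100.0 * n_resamples)), 1)

    def excess(q: float) -> float:
        return float(stats.binom.sf(k - 1, n_resamples, q)) - fdr

    if excess(1e-12) >= 0:
        return 1e-12
    return float(optimize.brentq(excess, 1e-12, 1.0))


def forward_select(
    yw: np.ndarray,
    Xw: np.ndarray,
    Gw: np.ndarray,
    threshold: float,
    max_steps: int = 20,
) -> list[tuple[int, float, float]]:
    """Forward selection on whitened data: repeatedly scan all markers with
    the score test, add the lowest-p marker as a fixed covariate while it
    passes ``threshold``; stop when none does or ``max_steps`` is reached.

    Markers collinear with the current covariate set are skipped (they test
    at p = 1).  Returns [(marker index, p at selection, effect), ...] in
    selection order.
    """
    selected: list[tuple[int, float, float]] = []
    taken: set[int] = set()
    X_cur = Xw
    for _ in range(max_steps):
        pvals, betas = score_test_batch(yw, X_cur, Gw)
        if taken:
            pvals = pvals.copy()
            pvals[list(taken)] = 1.0
        best = int(np.argmin(pvals))
        if pvals[best] >= threshold:
            break
        selected.append((best, float(pvals[best]), float(betas[best])))
        taken.add(best)
        X_cur = np.column_stack([X_cur, Gw[:, best]])
    return selected


# ---------------------------------------------------------------------------
# resampling engine
# ---------------------------------------------------------------------------


@dataclass
class _ScanGroup:
    """Markers scanned under one whitening covariance.

    With LOCO (leave-one-chromosome-out) kinship there is one group per
    chromosome, whitened by the kinship built from all other chromosomes,
    which prevents the tested markers' own relatedness contribution from
    absorbing their association signal (proximal contamination).
    """

    name: str
    cols: np.ndarray  # marker column indices
    K: np.ndarray  # kinship for whitening, on all analyzed samples


def _loco_groups(calls: np.ndarray, chroms: np.ndarray) -> list[_ScanGroup]:
    Z = calls.astype(np.float64)
    p = Z.mean(axis=0) / 2.0
    Z -= 2.0 * p
    d = 2.0 * p * (1.0 - p)
    uniq = list(dict.fromkeys(chroms.tolist()))
    parts = {}
    d_tot = float(d.sum())
    P_tot = Z @ Z.T
    groups = []
    for c in uniq:
        cols = np.flatnonzero(chroms == c)
        Zc = Z[:, cols]
        Pc = Zc @ Zc.T
        denom = d_tot - float(d[cols].sum())
        if denom <= 0:
            raise ValueError("LOCO kinship needs polymorphic markers on other chromosomes")
        groups.append(_ScanGroup(name=str(c), cols=cols, K=(P_tot - Pc) / denom))
    return groups


def _chol_whitener(K: np.ndarray, h2: float, row_idx: np.ndarray):
    V = h2 * K[np.ix_(row_idx, row_idx)] + (1.0 - h2) * np.eye(len(row_idx))
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(V + 1e-6 * np.eye(len(row_idx)))
    return L


def _prep_group(L, y, X, i1, i2, cols):
    from scipy.linalg import solve_triangular

    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    i1w = solve_triangular(L, i1[:, cols], lower=True)
    i2w = solve_triangular(L, i2[:, cols], lower=True)
    return {"L": L, "yw": yw, "Xw": Xw, "i1w": i1w, "i2w": i2w, "cols": cols}


def _coded(i1m: np.ndarray, i2m: np.ndarray, model: str) -> np.ndarray:
    het, hom = MODELS[model]
    return het * i1m + hom * i2m


def _forward_select_groups(
    prepped: list[dict],
    model: str,
    raw_coded: np.ndarray,
    row_idx: np.ndarray,
    threshold: float,
    max_steps: int,
) -> list[tuple[int, float, float]]:
    """Forward selection scanning every group per step; the selected marker
    (global column index) joins the covariates of every group, whitened by
    that group's factor."""
    from scipy.linalg import solve_triangular

    state = [
        {"X": g["Xw"], "G": _coded(g["i1w"], g["i2w"], model), "cols": g["cols"]}
        for g in prepped
    ]
    selected: list[tuple[int, float, float]] = []
    taken: set[int] = set()
    for _ in range(max_steps):
        best = (1.1, -1, 0.0)  # (p, global column, beta)
        for g, st in zip(prepped, state):
            pvals, betas = score_test_batch(g["yw"], st["X"], st["G"])
            if taken:
                pvals = pvals.copy()
                local_taken = [i for i, c in enumerate(st["cols"]) if int(c) in taken]
                pvals[local_taken] = 1.1
            local = int(np.argmin(pvals))
            if pvals[local] < best[0]:
                best = (float(pvals[local]), int(st["cols"][local]), float(betas[local]))
        p_best, j_best, b_best = best
        if j_best < 0 or p_best >= threshold:
            break
        selected.append((j_best, p_best, b_best))
        taken.add(j_best)
        v = raw_coded[row_idx, j_best]
        for g, st in zip(prepped, state):
            vw = solve_triangular(g["L"], v, lower=True)
            st["X"] = np.column_stack([st["X"], vw])
    return selected


def _perm_threshold_groups(
    prepped: list[dict],
    models: tuple[str, ...],
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
    n_cov: int,
) -> float:
    """Permutation threshold on whitened covariate-residualized residuals,
    with the same permutation orders applied in every scan group so the
    across-group dependence of the genome-wide minimum is preserved."""
    n = prepped[0]["yw"].shape[0]
    orders = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
    minima = np.full(n_perm, 1.0)
    for g in prepped:
        Q = _null_projection(g["Xw"])
        ry = g["yw"] - Q @ (Q.T @ g["yw"])
        RY = ry[orders]  # n x n_perm
        RY = RY - Q @ (Q.T @ RY)
        sig2 = np.einsum("ij,ij->j", RY, RY) / max(n - n_cov, 1)
        for model in models:
            Gw = _coded(g["i1w"], g["i2w"], model)
            RG = Gw - Q @ (Q.T @ Gw)
            gss = np.einsum("ij,ij->j", RG, RG)
            ok = gss > 1e-10 * np.maximum(np.einsum("ij,ij->j", Gw, Gw), 1.0)
            gy = RG.T @ RY
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = gy**2 / (gss[:, None] * sig2[None, :])
            stat[~ok, :] = 0.0
            pmin = stats.chi2.sf(stat.max(axis=0), df=1)
            minima = np.minimum(minima, pmin)
    k = max(int(np.floor(alpha * n_perm)), 1)
    return float(np.sort(minima)[k - 1])


@dataclass
class AssociationResult:
    """Per-marker RMIP under each inheritance model plus selection detail."""

    marker_ids: list[str]
    rmip: pd.DataFrame  # index marker id, one column per model, 0-100 scale
    rmip_max: pd.Series  # max over models
    selected: pd.DataFrame  # marker, model, count, best_p, mean_effect
    threshold: float
    n_resamples: int
    models: tuple[str, ...]

    def significant(self, rmip_threshold: float = 5.0) -> pd.DataFrame:
        keep = self.rmip_max[self.rmip_max >= rmip_threshold]
        best_model = self.rmip.loc[keep.index].idxmax(axis=1)
        out = pd.DataFrame({"rmip": keep, "best_model": best_model})
        det = self.selected.groupby("marker")["best_p"].min()
        out["best_p"] = det.reindex(out.index)
        return out


def resample_rmip(
    pheno: pd.Series,
    geno: GenotypeMatrix,
    kin: KinshipMatrix,
    n_resamples: int = 50,
    subsample_frac: float = 0.8,
    models: tuple[str, ...] = ("additive", "dominance", "recessive", "overdominance"),
    n_permutations: int = 100,
    fdr: float = 0.05,
    rmip_threshold: float = 5.0,
    covariates: pd.DataFrame | None = None,
    n_pcs: int = 0,
    seed: int = 0,
    max_steps: int = 20,
    threshold: float | None = None,
    calibration: str = "procedure",
    loco: bool = True,
) -> AssociationResult:
    """The resampling forward-selection GWAS.

    ``pheno`` is indexed by sample id; samples present in both the phenotype
    and ``geno`` are analyzed.  ``covariates`` (optional, indexed by sample)
    are carried as fixed effects in every scan — passing the matching F1
    phenotype here is the pleiotropy re-run.  ``n_pcs`` optionally adds top
    genomic PCs (from the kinship eigenvectors) as fixed covariates.

    The heritability ratio is estimated per sub-dataset on the subset of
    the full-panel kinship (against the intercept/user-covariate model:
    fitting it jointly with PC fixed effects is ill-posed because the PCs
    span the top kinship eigendirections).  Each chromosome is scanned
    under a leave-one-chromosome-out kinship by default (``loco=True``),
    so a tested marker's own LD block does not absorb its association
    signal into the polygenic term; ``loco=False`` whitens everything with
    the single full kinship (and reduces to plain forward-selection
    regression when that kinship is the identity).

    The per-trait significance threshold is computed once on the full
    dataset from permutations of the whitened covariate-residualized
    residuals and reused across sub-datasets.  With
    ``calibration="procedure"`` (default) the permutation quantile is
    :func:`procedure_alpha`, controlling the fraction of null runs that
    report any RMIP >= ``rmip_threshold`` SNP at ``fdr``;
    ``calibration="scan"`` uses ``fdr`` directly as the per-scan quantile.
    Resample r draws its RNG from a counter-based child seed, so any
    single resample is reproducible in isolation.
    """
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    if not models:
        raise ValueError("need at least one inheritance model")
    if n_resamples < 20:
        warnings.warn(f"n_resamples={n_resamples} gives unstable RMIP estimates")

    # canonical (sorted) sample order so RMIP depends only on the seed and
    # the sample set, not on input ordering
    ids = sorted(s for s in geno.samples if s in pheno.index and np.isfinite(pheno[s]))
    y = pheno.reindex(ids).to_numpy(dtype=float)
    sub = geno.subset_samples(ids)
    Ksub = kin.subset(ids).values
    n = len(ids)

    X = np.ones((n, 1))
    if covariates is not None:
        C = covariates.reindex(ids).to_numpy(dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if np.isnan(C).any():
            raise ValueError("covariates contain missing values for analyzed samples")
        X = np.column_stack([X, C])
    # variance components are estimated against the intercept/user-covariate
    # model only: the genomic PCs span the top kinship eigendirections, and
    # fitting h2 jointly with them is ill-posed (the fixed effects absorb
    # the strongest relatedness signal, collapsing h2 toward zero and
    # under-whitening the scans).  The PCs still enter every scan as fixed
    # effects.
    X_vc = X
    if n_pcs > 0:
        lam, U = np.linalg.eigh(Ksub)
        order = np.argsort(lam)[::-1][: min(n_pcs, n - X.shape[1] - 2)]
        X = np.column_stack([X, U[:, order] * np.sqrt(np.maximum(lam[order], 0.0))])

    i1 = (sub.calls == 1).astype(np.float64)
    i2 = (sub.calls == 2).astype(np.float64)
    raw_coded = {mname: _coded(i1, i2, mname) for mname in models}

    chroms = sub.markers["chrom"].to_numpy()
    if loco and len(set(chroms.tolist())) > 1:
        groups = _loco_groups(sub.calls, chroms)
    else:
        groups = [_ScanGroup(name="all", cols=np.arange(sub.n_markers), K=Ksub)]

    master = np.random.SeedSequence(seed)
    ss_thresh, *ss_resample = master.spawn(n_resamples + 1)

    if calibration == "procedure":
        scan_alpha = procedure_alpha(n_resamples, rmip_threshold, fdr)
    elif calibration == "scan":
        scan_alpha = fdr
    else:
        raise ValueError(f"unknown calibration {calibration!r}")

    all_rows = np.arange(n)

    def prep_all(h2: float, row_idx: np.ndarray) -> list[dict]:
        out = []
        for g in groups:
            L = _chol_whitener(g.K, h2, row_idx)
            out.append(_prep_group(L, y[row_idx], X[row_idx], i1[row_idx], i2[row_idx], g.cols))
        return out

    full_fit = fit_polygenic(y, Ksub, X_vc)
    if threshold is None:
        prepped_full = prep_all(full_fit.h2, all_rows)
        threshold = _perm_threshold_groups(
            prepped_full, tuple(models), n_permutations, scan_alpha,
            np.random.default_rng(ss_thresh), n_cov=X.shape[1],
        )

    m = sub.n_markers
    counts = {mname: np.zeros(m, dtype=int) for mname in models}
    detail: dict[tuple[int, str], list[tuple[float, float]]] = {}
    n_take = int(round(subsample_frac * n))

    for r in range(n_resamples):
        rng = np.random.default_rng(ss_resample[r])
        idx = np.sort(rng.choice(n, size=n_take, replace=False))
        fit_r = fit_polygenic(y[idx], Ksub[np.ix_(idx, idx)], X_vc[idx])
        prepped = prep_all(fit_r.h2, idx)
        for mname in models:
            picks = _forward_select_groups(
                prepped, mname, raw_coded[mname], idx, threshold, max_steps
            )
            for j, p, beta in picks:
                counts[mname][j] += 1
                detail.setdefault((j, mname), []).append((p, beta))

    rmip = pd.DataFrame(
        {mname: 100.0 * counts[mname] / n_resamples for mname in models},
        index=sub.markers["id"].to_list(),
    )
    rows = [
        {
            "marker": sub.markers.loc[j, "id"],
            "model": mname,
            "count": len(v),
            "best_p": min(p for p, _ in v),
            "mean_effect": float(np.mean([b for _, b in v])),
        }
        for (j, mname), v in sorted(detail.items())
    ]
    selected = pd.DataFrame(rows, columns=["marker", "model", "count", "best_p", "mean_effect"])
    return AssociationResult(
        marker_ids=sub.markers["id"].to_list(),
        rmip=rmip,
        rmip_max=rmip.max(axis=1),
        selected=selected,
        threshold=float(threshold),
        n_resamples=n_resamples,
        models=tuple(models),
    )


def disappeared_signals(
    before: AssociationResult, after: AssociationResult, rmip_threshold: float = 5.0
) -> list[str]:
    """Markers significant in ``before`` but not in ``after``.

    Running the engine a second time with the original F1 phenotype as a
    fixed covariate and diffing with this function classifies pleiotropy:
    a derived-phenotype (BPaV/SCA) signal that disappears was mediated by
    the F1 phenotype itself.
    """
    sig_before = set(before.rmip_max.index[before.rmip_max >= rmip_threshold])
    sig_after = set(after.rmip_max.index[after.rmip_max >= rmip_threshold])
    return sorted(sig_before - sig_after)


# ---------------------------------------------------------------------------
# signal merging
# ---------------------------------------------------------------------------


@dataclass
class Signal:
    """A merged association signal: chained significant SNPs and its lead."""

    chrom: int
    start: int
    end: int
    lead: str
    lead_pos: int
    rmip: float
    best_model: str
    members: list[str] = field(default_factory=list)


def significant_snps(
    result: AssociationResult, geno: GenotypeMatrix, rmip_threshold: float = 5.0
) -> pd.DataFrame:
    """Table of SNPs meeting the RMIP threshold, with coordinates."""
    sig = result.significant(rmip_threshold)
    mk = geno.markers.set_index("id")
    out = sig.join(mk[["chrom", "pos"]])
    return out.reset_index(names="id").sort_values(["chrom", "pos"]).reset_index(drop=True)


def merge_signals(
    snps: pd.DataFrame,
    geno: GenotypeMatrix,
    max_distance: int = 800_000,
    min_r2: float = 0.2,
) -> list[Signal]:
    """Single-linkage chaining of significant SNPs: two SNPs join one signal
    when they are on the same chromosome, less than ``max_distance`` apart,
    and their genotype regression R² is >= ``min_r2``; membership is the
    transitive closure.  The lead is the member with the highest RMIP (ties:
    lower p, then lower position)."""
    if snps.empty:
        return []
    snps = snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
    idx_of = {mid: j for j, mid in enumerate(geno.markers["id"])}
    calls = geno.calls.astype(float)
    parent = list(range(len(snps)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            if snps.loc[j, "chrom"] != snps.loc[i, "chrom"]:
                break
            if snps.loc[j, "pos"] - snps.loc[i, "pos"] >= max_distance:
                break
            gi = calls[:, idx_of[snps.loc[i, "id"]]]
            gj = calls[:, idx_of[snps.loc[j, "id"]]]
            ok = (gi >= 0) & (gj >= 0)
            if ok.sum() < 3:
                continue
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(gi[ok], gj[ok])[0, 1]
            if np.isfinite(r) and r * r >= min_r2:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(snps)):
        groups.setdefault(find(i), []).append(i)

    signals = []
    for members in groups.values():
        subdf = snps.loc[members]
        best_p = subdf["best_p"].fillna(1.0)
        order = sorted(
            members,
            key=lambda i: (-snps.loc[i, "rmip"], best_p[i], snps.loc[i, "pos"]),
        )
        lead = order[0]
        signals.append(
            Signal(
                chrom=int(snps.loc[lead, "chrom"]),
                start=int(subdf["pos"].min()),
                end=int(subdf["pos"].max()),
                lead=str(snps.loc[lead, "id"]),
                lead_pos=int(snps.loc[lead, "pos"]),
                rmip=float(snps.loc[lead, "rmip"]),
                best_model=str(snps.loc[lead, "best_model"]),
                members=[str(x) for x in subdf["id"]],
            )
        )
    signals.sort(key=lambda s: (s.chrom, s.start))
    return signals
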