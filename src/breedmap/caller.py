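"""Intensity-based genotype calling.

The caller uses prior-free intensity clustering: quantile-normalize raw
two-channel intensities within each chip, summarize each SNP's (A, B) cloud
by a per-SNP principal component analysis, cluster the PC coordinates with
an EM-fitted mixture of bivariate t distributions (fixed degrees of
freedom), and map each component to a dosage code 0/1/2 through the allele
contrast of its back-projected centre. Calls below a posterior-confidence threshold are set
missing, and cohort-level QC removes low-call-rate SNPs, low-call-rate
samples, and low-MAF SNPs, in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.special import gammaln

from .containers import MISSING, CallSet, GenotypeMatrix, IntensityMatrix


@dataclass
class CallerConfig:
    k: int = 3
    df: float = 5.0
    max_iter: int = 200
    tol: float = 1e-6            # log-likelihood change per sample
    no_call_threshold: float = 0.95
    min_call_rate_flag: float = 0.5   # SNPs below this call rate get flagged

    def validate(self) -> None:
        if self.k not in (2, 3):
            raise ValueError("k must be 2 or 3")
        if self.df <= 2:
            raise ValueError("df must exceed 2")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def _rank_match(values: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Replace a value vector by the profile entries at its (average) ranks.

    Depends on ``values`` only through its ranks; ties get the interpolated
    profile value, so within-vector rank order is preserved exactly.
    """
    grid = np.arange(len(profile), dtype=float)
    ranks = rankdata(values, method="average") - 1.0
    return np.interp(ranks, grid, profile)


def quantile_normalize_per_chip(intens: IntensityMatrix,
                                align_chips: bool = True) -> IntensityMatrix:
    """Quantile-normalize each chip's samples, then align chips.

    Within each chip, each sample's pooled A+B intensity vector is replaced
    by the rank-matched mean of the sorted vectors across that chip's
    samples. With ``align_chips`` (default) every sample is then rank-matched
    into the grand mean of the per-chip profiles, so chip-level batch effects
    (e.g. multiplicative scale) cancel across chips as well as within; with a
    single chip the grand profile equals the chip profile and the second step
    is the identity. Single-sample chips pass through with a warning (their
    profile is the sample itself).
    """
    values = intens.values.copy()
    chips = intens.samples["chip"].to_numpy()
    n_vals = intens.n_snps * 2
    profiles = {}
    for chip in pd.unique(chips):
        idx = np.flatnonzero(chips == chip)
        if idx.size < 2:
            warnings.warn(f"chip {chip!r} has a single sample; "
                          "within-chip quantile normalization skipped",
                          stacklevel=2)
            profiles[chip] = np.sort(values[idx[0]].reshape(n_vals))
            continue
        X = values[idx].reshape(idx.size, n_vals)
        profiles[chip] = np.sort(X, axis=1).mean(axis=0)
    grand = None
    if align_chips:
        # average chip profiles on a unit-mean scale so a chip-level
        # multiplicative batch factor cancels exactly, then restore the
        # average absolute scale (identity for a single chip)
        means = {c: p.mean() for c, p in profiles.items()}
        grand = (np.mean([profiles[c] / means[c] for c in profiles], axis=0)
                 * np.mean(list(means.values())))
    for i in range(intens.n_samples):
        target = grand if align_chips else profiles[chips[i]]
        x = intens.values[i].reshape(n_vals)
        values[i] = _rank_match(x, target).reshape(intens.n_snps, 2)
    return IntensityMatrix(values, intens.snps, intens.samples)


# ---------------------------------------------------------------------------
# per-SNP PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Per-SNP principal-axis summary of the (A, B) intensity cloud."""

    scores: np.ndarray       # (n, 2) PC coordinates
    explained: np.ndarray    # variance fractions of PC1, PC2
    flagged: bool            # zero-variance cloud
    mean: np.ndarray         # (2,) cloud centroid in (A, B)
    components: np.ndarray   # (2, 2) rows = oriented principal axes

    def backproject(self, score_points: np.ndarray) -> np.ndarray:
        """Map PC coordinates back to the (A, B) plane."""
        return np.atleast_2d(score_points) @ self.components + self.mean


def snp_pca(xy: np.ndarray) -> PCAResult:
    """Principal-axis coordinates of one SNP's (A, B) cloud.

    PC1 is oriented so that increasing PC1 correlates with increasing
    A-channel intensity; PC2's sign is fixed against the B channel for
    determinism. A zero-variance cloud yields all-zero scores and a flag.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) intensity array")
    if xy.shape[0] < 3:
        raise ValueError("per-SNP PCA needs at least 3 samples")
    mean = xy.mean(axis=0)
    centered = xy - mean
    total = float((centered ** 2).sum())
    if total < 1e-24:
        return PCAResult(np.zeros_like(xy), np.array([0.0, 0.0]), True,
                         mean, np.eye(2))
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = centered @ vt.T
    explained = s ** 2 / (s ** 2).sum()
    for pc, channel in ((0, 0), (1, 1)):
        cov = float(scores[:, pc] @ centered[:, channel])
        if cov < 0:
            scores[:, pc] = -scores[:, pc]
            vt[pc] = -vt[pc]
    return PCAResult(scores, explained, False, mean, vt)


# ---------------------------------------------------------------------------
# EM for a mixture of bivariate t distributions
# ---------------------------------------------------------------------------

def _t_logpdf(x, mean, cov, df):
    """Log density of a bivariate t with fixed df at rows of x."""
    d = 2
    diff = x - mean
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    const = (gammaln((df + d) / 2.0) - gammaln(df / 2.0)
             - 0.5 * d * np.log(df * np.pi) - 0.5 * logdet)
    return const - 0.5 * (df + d) * np.log1p(maha / df), maha


@dataclass
class TMixtureFit:
    means: np.ndarray        # (k, 2)
    covs: np.ndarray         # (k, 2, 2)
    weights: np.ndarray      # (k,)
    df: float
    loglik: list
    converged: bool
    flagged: bool
    posteriors: np.ndarray   # (n, k)


def _optimal_1d_kmeans_bounds(xs: np.ndarray, k: int) -> list[int]:
    """Split points of the globally optimal k-means partition of sorted xs.

    Dynamic programming over contiguous segments (the 1-D optimum is always
    contiguous); returns the k-1 split indices for np.split.
    """
    n = len(xs)
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def seg_cost(i, j):
        # SSE of xs[i..j] inclusive, vectorized over array-valued i
        cnt = j - i + 1
        tot = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - tot ** 2 / cnt

    idx = np.arange(n)
    D = seg_cost(np.zeros(n, dtype=int), idx)
    splits = np.zeros((k, n), dtype=int)
    for m in range(1, k):
        Dnew = np.empty(n)
        Dnew[:m] = 0.0
        for j in range(m, n):
            i = np.arange(m, j + 1)
            cand = D[i - 1] + seg_cost(i, j)
            best = int(np.argmin(cand))
            Dnew[j] = cand[best]
            splits[m, j] = m + best
        D = Dnew
    bounds = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = int(splits[m, j])
        bounds.append(i)
        j = i - 1
    return sorted(bounds)


def _init_by_pc1_split(x: np.ndarray, k: int):
    """Initialize components by the optimal k-way 1-D k-means split of PC1."""
    pc1 = x[:, 0]
    order = np.argsort(pc1, kind="stable")
    bounds = _optimal_1d_kmeans_bounds(pc1[order], k)
    groups = np.split(order, bounds)
    means = np.array([x[g].mean(axis=0) if len(g) else x.mean(axis=0)
                      for g in groups])
    covs = []
    gvar = x.var(axis=0).mean() + 1e-6
    for g in groups:
        c = np.cov(x[g].T) if len(g) > 2 else np.eye(2) * gvar
        c = np.atleast_2d(c)
        if c.shape != (2, 2):
            c = np.eye(2) * gvar
        covs.append(c + 1e-6 * gvar * np.eye(2))
    weights = np.array([len(g) / len(x) for g in groups])
    return means, np.array(covs), weights


def fit_t_mixture(x: np.ndarray, k: int = 3, df: float = 5.0,
                  max_iter: int = 200, tol: float = 1e-6,
                  seed: int = 0) -> TMixtureFit:
    """EM fit of a k-component bivariate t mixture with fixed df.

    The log-likelihood is non-decreasing across iterations; an emptied
    component triggers one re-initialization (jittered split), after which
    the SNP is flagged. Non-convergence within ``max_iter`` returns the best
    iterate, flagged.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    means, covs, weights = _init_by_pc1_split(x, k)
    flagged = False
    converged = False
    logliks: list[float] = []
    reinit_done = False
    floor = 1e-8 * (x.var(axis=0).mean() + 1e-12)
    resp = np.full((n, k), 1.0 / k)
    it = 0
    while it < max_iter:
        it += 1
        # E-step
        logp = np.empty((n, k))
        u = np.empty((n, k))
        for j in range(k):
            lp, maha = _t_logpdf(x, means[j], covs[j], df)
            logp[:, j] = np.log(weights[j] + 1e-300) + lp
            u[:, j] = (df + d) / (df + maha)
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        logliks.append(ll)
        if len(logliks) > 1:
            # per-sample change: invariant to global rescaling of the data
            # (which shifts the log-likelihood additively)
            if abs(ll - logliks[-2]) <= tol * n:
                converged = True
                break
        # M-step
        nj = resp.sum(axis=0)
        if nj.min() < 1e-3:
            if not reinit_done:
                reinit_done = True
                rng = np.random.default_rng(seed)
                jitter = 0.05 * x.std(axis=0) * rng.standard_normal((k, 2))
                means, covs, weights = _init_by_pc1_split(x, k)
                means = means + jitter
                logliks = []
                continue
            flagged = True
            nj = np.maximum(nj, 1e-3)
        weights = nj / n
        for j in range(k):
            zu = resp[:, j] * u[:, j]
            mu = (zu[:, None] * x).sum(axis=0) / (zu.sum() + 1e-300)
            diff = x - mu
            cov = (resp[:, j, None, None] * u[:, j, None, None]
                   * diff[:, :, None] * diff[:, None, :]).sum(axis=0) / nj[j]
            cov = cov + floor * np.eye(2)
            means[j] = mu
            covs[j] = cov
    if not converged:
        flagged = True
    return TMixtureFit(means, covs, weights, df, logliks, converged, flagged, resp)


def _contrast_bucket(ab: np.ndarray) -> int:
    """Genotype implied by a cluster centre's allele contrast.

    The contrast (A - B)/(A + B) is scale-free: a hom-ref cluster hugs the
    A axis (contrast near +1), het sits near the diagonal (0), hom-alt hugs
    B (-1). Thirds of the range partition the three genotypes.
    """
    a, b = float(ab[0]), float(ab[1])
    denom = abs(a) + abs(b)
    c = (a - b) / denom if denom > 1e-12 else 0.0
    if c > 1.0 / 3.0:
        return 0
    if c < -1.0 / 3.0:
        return 2
    return 1


def em_t_mixture_call(scores: np.ndarray, k: int = 3, df: float = 5.0,
                      max_iter: int = 200, tol: float = 1e-6,
                      no_call_threshold: float = 0.95, seed: int = 0,
                      pca: PCAResult | None = None):
    """Genotype one SNP from its PC coordinates.

    With the (A, B) back-projection available (``pca``), each component is
    assigned the dosage implied by its allele contrast; components whose
    contrasts land in the same bucket model the same genotype cluster (a
    k=3 fit of a SNP with fewer than three genotype classes splits one
    cluster between two components) and their posteriors pool. Without a
    back-projection, components are ordered by decreasing PC1 location
    (high A signal = more reference alleles), ties broken by weight
    (heavier component = common homozygote). Calls with maximum pooled
    posterior below ``no_call_threshold`` are set missing.

    Returns (genotypes, confidence, fit).
    """
    fit = fit_t_mixture(scores, k=k, df=df, max_iter=max_iter, tol=tol, seed=seed)
    if pca is not None:
        comp_dosage = [_contrast_bucket(pca.backproject(fit.means[i])[0])
                       for i in range(k)]
    else:
        order = sorted(range(k), key=lambda i: (-fit.means[i, 0],
                                                -fit.weights[i]))
        comp_dosage = [0] * k
        for dosage, i in enumerate(order):
            comp_dosage[i] = dosage
    dosage_post = np.zeros((len(scores), 3))
    for i in range(k):
        dosage_post[:, comp_dosage[i]] += fit.posteriors[:, i]
    best = dosage_post.argmax(axis=1)
    conf = dosage_post[np.arange(len(best)), best]
    geno = np.where(conf < no_call_threshold, MISSING, best).astype(np.int8)
    return geno, conf, fit


def call_genotypes(intens: IntensityMatrix,
                   config: CallerConfig | None = None) -> CallSet:
    """Full calling pass over an intensity matrix."""
    config = config or CallerConfig()
    config.validate()
    normed = quantile_normalize_per_chip(intens)
    n_s, n_p = normed.n_samples, normed.n_snps
    geno = np.full((n_s, n_p), MISSING, dtype=np.int8)
    conf = np.zeros((n_s, n_p))
    params: dict[int, dict] = {}
    for j in range(n_p):
        pca = snp_pca(normed.values[:, j, :])
        if pca.flagged:
            params[j] = {"flagged": True, "reason": "zero-variance"}
            continue
        g, c, fit = em_t_mixture_call(
            pca.scores, k=config.k, df=config.df, max_iter=config.max_iter,
            tol=config.tol, no_call_threshold=config.no_call_threshold, seed=j,
            pca=pca)
        geno[:, j] = g
        conf[:, j] = c
        call_rate = float((g != MISSING).mean())
        params[j] = {
            "means": fit.means, "scales": fit.covs, "weights": fit.weights,
            "df": fit.df, "converged": fit.converged,
            "flagged": bool(fit.flagged or call_rate < config.min_call_rate_flag),
            "explained": pca.explained,
        }
    return CallSet(geno, conf, intens.snps, intens.samples, params,
                   config.no_call_threshold)


# ---------------------------------------------------------------------------
# cohort QC
# ---------------------------------------------------------------------------

def qc_filter(gm: GenotypeMatrix, snp_call_rate: float = 0.90,
              sample_call_rate: float = 0.25, maf: float = 0.05,
              apply_maf: bool = True):
    """PLINK-style cohort QC in the fixed order SNP rate, sample rate, MAF.

    Removes SNPs with call rate <= ``snp_call_rate``, then samples with call
    rate <= ``sample_call_rate`` (recomputed), then SNPs with MAF <= ``maf``
    (recomputed). Returns (filtered GenotypeMatrix, removal report).
    """
    if gm.n_snps == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = []
    rate = gm.snp_call_rate()
    keep_snps = rate > snp_call_rate
    for j in np.flatnonzero(~keep_snps):
        report.append({"kind": "snp", "id": gm.snps["id"].iat[j],
                       "reason": "call_rate", "value": float(rate[j])})
    gm = gm.subset(snp_idx=np.flatnonzero(keep_snps))
    if gm.n_snps == 0:
        raise ValueError("QC removed every SNP")

    srate = gm.sample_call_rate()
    keep_samples = srate > sample_call_rate
    for i in np.flatnonzero(~keep_samples):
        report.append({"kind": "sample", "id": gm.samples["sample"].iat[i],
                       "reason": "call_rate", "value": float(srate[i])})
    if not keep_samples.any():
        raise ValueError("QC removed every sample")
    gm = gm.subset(sample_idx=np.flatnonzero(keep_samples))

    if apply_maf:
        m = gm.maf()
        keep_snps = np.nan_to_num(m, nan=0.0) > maf
        for j in np.flatnonzero(~keep_snps):
            report.append({"kind": "snp", "id": gm.snps["id"].iat[j],
                           "reason": "maf", "value": float(m[j])})
        gm = gm.subset(snp_idx=np.flatnonzero(keep_snps))
    return gm, pd.DataFrame(report, columns=["kind", "id", "reason", "value"])


def concordance(calls: GenotypeMatrix, truth: GenotypeMatrix) -> dict:
    """Agreement between called and true genotypes over non-missing calls."""
    if calls.genotypes.shape != truth.genotypes.shape:
        raise ValueError("call and truth matrices differ in shape")
    called = (calls.genotypes != MISSING) & (truth.genotypes != MISSING)
    agree = (calls.genotypes == truth.genotypes) & called
    n_called = int(called.sum())
    return {
        "concordance": float(agree.sum() / n_called) if n_called else float("nan"),
        "call_rate": float(called.mean()),
        "n_called": n_called,
    }
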