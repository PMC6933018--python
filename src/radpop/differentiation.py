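"""Population differentiation: Weir-Cockerham Fst and AMOVA.

The pairwise fixation index is the Weir & Cockerham method-of-moments
estimator theta-hat, built from per-locus variance components *a* (among
populations), *b* (among individuals within populations) and *c* (within
individuals), combined as a ratio of sums over loci. Confidence intervals
and p-values come from bootstrapping loci.

AMOVA partitions the total molecular variance (squared Euclidean distance
on alt-allele dosage) into among- and within-population components, with
significance of Phi_ST assessed by permuting population labels.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


class DifferentiationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (two populations)
# ---------------------------------------------------------------------------

def _pair_locus_stats(panel: GenotypePanel, rows_a: np.ndarray, rows_b: np.ndarray):
    """Per-locus sample sizes, alt frequencies and het proportions per pop."""
    out = []
    for rows in (rows_a, rows_b):
        G = panel.genotypes[rows]
        called = G != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, G, 0).sum(axis=0) / (2 * np.maximum(n, 1))
            h = (G == 1).sum(axis=0) / np.maximum(n, 1)
        out.append((n, p, h))
    return out


def wc_theta_components(
    panel: GenotypePanel, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Per-locus Weir-Cockerham components a, b, c for one population pair.

    Loci monomorphic across the pair, untyped in either population, or with
    mean sample size <= 1 are excluded (the latter with a log entry).
    Returns a DataFrame indexed by snp_id with columns a, b, c.
    """
    idx = panel.pop_indices()
    for p in (pop_a, pop_b):
        if p not in idx:
            raise DifferentiationError(f"unknown population {p!r}")
    (n1, p1, h1), (n2, p2, h2) = _pair_locus_stats(panel, idx[pop_a], idx[pop_b])

    typed = (n1 > 0) & (n2 > 0)
    nbar = (n1 + n2) / 2.0
    small = typed & (nbar <= 1)
    if small.any():
        logger.info(
            "skipping %d loci with mean sample size <= 1 for pair (%s, %s)",
            int(small.sum()), pop_a, pop_b,
        )
    usable = typed & (nbar > 1)
    if not usable.any():
        raise DifferentiationError(
            f"populations {pop_a!r} and {pop_b!r} share no typed loci"
        )

    n1, n2, p1, p2, h1, h2, nbar = (
        x[usable] for x in (n1, n2, p1, p2, h1, h2, nbar)
    )
    # r = 2 populations
    nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
    pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # (r-1)=1 denominator
    hbar = (n1 * h1 + n2 * h2) / (2 * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 / 2.0 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0

    poly = (pbar > 0) & (pbar < 1)
    snp_ids = panel.snp_ids[usable][poly]
    return pd.DataFrame(
        {"a": a[poly], "b": b[poly], "c": c[poly]}, index=pd.Index(snp_ids, name="snp_id")
    )


def wc_theta_pair(
    panel: GenotypePanel, pop_a: str, pop_b: str
) -> tuple[float, pd.DataFrame]:
    """Weir-Cockerham theta-hat for a population pair (ratio of sums)."""
    comp = wc_theta_components(panel, pop_a, pop_b)
    denom = float((comp["a"] + comp["b"] + comp["c"]).sum())
    if denom == 0:
        raise DifferentiationError(
            f"zero total variance between {pop_a!r} and {pop_b!r}"
        )
    return float(comp["a"].sum()) / denom, comp


# ---------------------------------------------------------------------------
# Pairwise matrix with bootstrap
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FstResult:
    """Pairwise theta matrix with bootstrap CIs, p-values, and audit trail."""

    populations: list[str]
    theta: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    p_value: pd.DataFrame
    n_bootstraps: int
    components: dict  # (popA, popB) -> per-locus a,b,c DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: Population1, Population2, LowerCI, UpperCI, Fst, p."""
        rows = []
        pops = self.populations
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                p = self.p_value.loc[a, b]
                rows.append(
                    {
                        "Population1": a,
                        "Population2": b,
                        "LowerCI": self.ci_low.loc[a, b],
                        "UpperCI": self.ci_high.loc[a, b],
                        "Fst": self.theta.loc[a, b],
                        "p": f"<{1.0 / self.n_bootstraps:g}" if p == 0 else f"{p:g}",
                    }
                )
        return pd.DataFrame(rows)


def fst_matrix(
    panel: GenotypePanel,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
) -> FstResult:
    """All pairwise theta-hats with percentile bootstrap CIs and p-values.

    The bootstrap resamples loci with replacement and recomputes theta from
    the resampled (a, b, c) sums; the p-value is the one-sided bootstrap mass
    at theta* <= 0 (test of deviation from zero). A p-value of exactly zero
    is rendered as ``< 1/n_boot`` in the output table.
    """
    if n_boot < 1:
        raise DifferentiationError("n_boot must be >= 1")
    pops = panel.pop_names
    if len(pops) < 2:
        raise DifferentiationError("need at least 2 populations")
    shape = (len(pops), len(pops))
    theta = np.full(shape, np.nan)
    lo = np.full(shape, np.nan)
    hi = np.full(shape, np.nan)
    pv = np.full(shape, np.nan)
    comps: dict = {}
    alpha = (1.0 - ci) / 2.0
    ss = np.random.SeedSequence(seed)
    for (i, j), child in zip(
        [(i, j) for i in range(len(pops)) for j in range(i + 1, len(pops))],
        ss.spawn(len(pops) * (len(pops) - 1) // 2),
    ):
        th, comp = wc_theta_pair(panel, pops[i], pops[j])
        comps[(pops[i], pops[j])] = comp
        rng = np.random.default_rng(child)
        L = len(comp)
        abc = comp.to_numpy()
        idx = rng.integers(0, L, size=(n_boot, L))
        a_sum = abc[idx, 0].sum(axis=1)
        tot = abc[idx].sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = np.where(tot != 0, a_sum / tot, 0.0)
        theta[i, j] = theta[j, i] = th
        lo[i, j] = lo[j, i] = float(np.quantile(boot, alpha))
        hi[i, j] = hi[j, i] = float(np.quantile(boot, 1 - alpha))
        pv[i, j] = pv[j, i] = float(np.mean(boot <= 0))
    as_df = lambda m: pd.DataFrame(m, index=pops, columns=pops)
    return FstResult(
        populations=pops,
        theta=as_df(theta),
        ci_low=as_df(lo),
        ci_high=as_df(hi),
        p_value=as_df(pv),
        n_bootstraps=n_boot,
        components=comps,
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AmovaResult:
    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_among: float       # raw (may be negative)
    sigma2_within: float
    pct_among: float          # computed with negative sigma2_among truncated to 0
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    degenerate: bool = False  # True when total variance is zero (Phi undefined)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among populations", "within populations"],
                "df": [self.df_among, self.df_within],
                "SSD": [self.ssd_among, self.ssd_within],
                "variance": [self.sigma2_among, self.sigma2_within],
                "pct": [self.pct_among, self.pct_within],
            }
        )


def _pairwise_d2(panel: GenotypePanel, rescale: bool = True) -> np.ndarray:
    """Squared Euclidean dosage distances with pairwise deletion of missing.

    With ``rescale`` the sum over shared loci is scaled by L/shared so all
    pairs are on a common denominator.
    """
    G = panel.genotypes.astype(float)
    mask = (panel.genotypes != MISSING).astype(float)
    A = np.where(panel.genotypes != MISSING, G, 0.0)
    A2 = A * A
    shared = mask @ mask.T
    S = A2 @ mask.T + mask @ A2.T - 2.0 * (A @ A.T)
    L = panel.n_loci
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = S * (L / shared) if rescale else S
    d2 = np.where(shared > 0, d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    return d2


def _ssd_partition(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    N = d2.shape[0]
    iu = np.triu_indices(N, 1)
    ssd_total = float(d2[iu].sum()) / N
    ssd_within = 0.0
    for pop in np.unique(labels):
        rows = np.flatnonzero(labels == pop)
        if len(rows) < 2:
            continue
        sub = d2[np.ix_(rows, rows)]
        ssd_within += float(np.triu(sub, 1).sum()) / len(rows)
    return ssd_total - ssd_within, ssd_within


def amova(
    panel: GenotypePanel,
    n_perm: int = 100,
    seed: int | None = None,
    rescale_missing: bool = True,
) -> AmovaResult:
    """Two-level AMOVA (among vs within populations) with permutation test.

    Variance components follow the standard one-way AMOVA estimators:
    ``sigma2_w = MS_within`` and ``sigma2_a = (MS_among - MS_within)/n0``
    with ``n0 = (N - sum(n_p^2)/N)/(P-1)``. The permutation p-value carries
    the +1 correction, so it is never exactly zero.
    """
    labels = panel.populations.to_numpy()
    pops, counts = np.unique(labels, return_counts=True)
    if len(pops) < 2:
        raise DifferentiationError("AMOVA needs at least 2 populations")
    if (counts < 2).any():
        raise DifferentiationError("AMOVA needs >= 2 individuals per population")
    N = panel.n_samples
    P = len(pops)
    d2 = _pairwise_d2(panel, rescale=rescale_missing)

    ssd_among, ssd_within = _ssd_partition(d2, labels)
    df_among, df_within = P - 1, N - P
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within
    n0 = (N - float((counts**2).sum()) / N) / (P - 1)
    sigma2_w = ms_within
    sigma2_a = (ms_among - ms_within) / n0

    sigma2_a_trunc = max(sigma2_a, 0.0)
    total = sigma2_a_trunc + sigma2_w
    degenerate = total <= 0
    if degenerate:
        pct_among = pct_within = phi = np.nan
    else:
        pct_among = 100.0 * sigma2_a_trunc / total
        pct_within = 100.0 * sigma2_w / total
        phi = sigma2_a / (sigma2_a + sigma2_w)

    rng = np.random.default_rng(seed)
    if degenerate:
        p_value = np.nan
    else:
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            sa, sw = _ssd_partition(d2, perm)
            pa = (sa / df_among - sw / df_within) / n0
            pw = sw / df_within
            phi_perm = pa / (pa + pw) if (pa + pw) > 0 else 0.0
            if phi_perm >= phi:
                exceed += 1
        p_value = (1.0 + exceed) / (1.0 + n_perm)

    return AmovaResult(
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        df_among=df_among,
        df_within=df_within,
        sigma2_among=sigma2_a,
        sigma2_within=sigma2_w,
        pct_among=pct_among,
        pct_within=pct_within,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_perm,
        degenerate=bool(degenerate),
    )
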