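"""Bayesian admixture inference (STRUCTURE's admixture model) and Evanno ΔK.

Each individual i carries ancestry proportions q_i over K clusters; each
allele copy at locus l originates from cluster k with probability q_ik and
is then the alternate allele with probability p_kl. Priors are uncorrelated
cluster frequencies p_kl ~ Beta(λ, λ) and q_i ~ Dirichlet(α, ..., α). The
Gibbs sweep alternates:

1. sample the cluster of origin z of every non-missing allele copy,
   z ∝ q_ik · p_kl (alt copy) or q_ik · (1 - p_kl) (ref copy);
2. p_kl ~ Beta(λ + alt copies assigned to k, λ + ref copies assigned to k);
3. q_i ~ Dirichlet(α + copies of i assigned to each cluster).

The per-K model score is STRUCTURE's evidence surrogate
L(K) = mean(lnL) − var(lnL)/2 over the post-burn-in trace, and the number
of clusters is chosen by the Evanno ΔK criterion over replicate runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


class AdmixtureError(ValueError):
    pass


@dataclasses.dataclass
class AdmixtureRun:
    """One MCMC run at a fixed K: posterior means and the lnL trace."""

    K: int
    Q: pd.DataFrame            # individuals x K, posterior mean, rows sum to 1
    P: np.ndarray              # K x loci, posterior mean alt frequencies
    lnL_trace: np.ndarray      # recorded every `thin` sweeps after warm-up
    settings: dict

    @property
    def L_of_K(self) -> float:
        """Model score mean(lnL) - var(lnL)/2 over the retained trace."""
        t = self.lnL_trace
        return float(np.mean(t) - np.var(t) / 2.0)

    def to_frame(self) -> pd.DataFrame:
        """STRUCTURE-like wide table: individual, population, q_1..q_K."""
        df = self.Q.copy()
        df.columns = [f"q_{k + 1}" for k in range(self.K)]
        df.insert(0, "population", self.settings.get("populations"))
        df.index.name = "individual"
        return df


def _categorical(rng: np.random.Generator, W: np.ndarray) -> np.ndarray:
    """Sample along the last axis of a nonnegative weight array."""
    cum = np.cumsum(W, axis=-1)
    total = cum[..., -1:]
    u = rng.random(W.shape[:-1] + (1,)) * total
    return (cum < u).sum(axis=-1)


def gibbs_admixture(
    panel: GenotypePanel,
    K: int,
    iters: int = 4000,
    burn_in: int = 2000,
    thin: int = 10,
    lam: float = 1.0,
    alpha: float = 1.0,
    seed: int | None = None,
) -> AdmixtureRun:
    """Run the admixture-model Gibbs sampler at a fixed number of clusters."""
    if K < 1:
        raise AdmixtureError("K must be >= 1")
    if K > panel.n_samples:
        raise AdmixtureError(f"K={K} exceeds the {panel.n_samples} individuals")
    if iters <= burn_in:
        raise AdmixtureError("iters must exceed burn_in")

    rng = np.random.default_rng(seed)
    G = panel.genotypes
    N, L = G.shape
    obs = G != MISSING
    # the two allele copies of each genotype: g=0 -> (ref,ref), 1 -> (alt,ref), 2 -> (alt,alt)
    alt1 = G >= 1
    alt2 = G == 2

    # initialize from the prior/data
    Q = np.full((N, K), 1.0 / K)
    alt_tot = np.where(obs, G, 0).sum(axis=0)
    cop_tot = 2.0 * obs.sum(axis=0)
    base = (alt_tot + lam) / (cop_tot + 2 * lam)
    P = np.clip(
        base[None, :] + rng.normal(0.0, 0.05, size=(K, L)), 1e-4, 1 - 1e-4
    )

    q_sum = np.zeros((N, K))
    p_sum = np.zeros((K, L))
    lnl: list[float] = []
    n_kept = 0
    tiny = 1e-300

    for sweep in range(iters):
        z = []
        for alt in (alt1, alt2):
            # weights (N, L, K): q_ik times the allele-frequency term
            term = np.where(alt[:, :, None], P.T[None, :, :], 1.0 - P.T[None, :, :])
            W = Q[:, None, :] * term
            z.append(_categorical(rng, W))
        z1, z2 = z

        cnt_alt = np.empty((K, L))
        cnt_ref = np.empty((K, L))
        n_ik = np.empty((N, K))
        for k in range(K):
            in1 = (z1 == k) & obs
            in2 = (z2 == k) & obs
            cnt_alt[k] = (in1 & alt1).sum(axis=0) + (in2 & alt2).sum(axis=0)
            cnt_ref[k] = (in1 & ~alt1).sum(axis=0) + (in2 & ~alt2).sum(axis=0)
            n_ik[:, k] = in1.sum(axis=1) + in2.sum(axis=1)

        P = np.clip(rng.beta(lam + cnt_alt, lam + cnt_ref), 1e-12, 1 - 1e-12)
        gam = rng.gamma(alpha + n_ik)
        Q = gam / gam.sum(axis=1, keepdims=True)

        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            q_sum += Q
            p_sum += P
            n_kept += 1
            p_alt = Q @ P            # N x L mixture alt-probability
            p_ref = Q @ (1.0 - P)
            ll = (
                np.where(alt1, np.log(p_alt + tiny), np.log(p_ref + tiny))
                + np.where(alt2, np.log(p_alt + tiny), np.log(p_ref + tiny))
            )
            lnl.append(float(ll[obs].sum()))

    Q_mean = q_sum / n_kept
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    run = AdmixtureRun(
        K=K,
        Q=pd.DataFrame(
            Q_mean, index=panel.samples, columns=[f"cluster_{k + 1}" for k in range(K)]
        ),
        P=p_sum / n_kept,
        lnL_trace=np.asarray(lnl),
        settings={
            "iters": iters,
            "burn_in": burn_in,
            "thin": thin,
            "lambda": lam,
            "alpha": alpha,
            "seed": seed,
            "populations": panel.populations.to_numpy().tolist(),
        },
    )
    return run


# ---------------------------------------------------------------------------
# K scan and Evanno delta-K
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvannoTable:
    """Per-K replicate model scores and the Evanno second-order statistics."""

    table: pd.DataFrame  # K, mean_L, sd_L, L_prime, abs_L_second, delta_K
    selected_k: int

    def to_frame(self) -> pd.DataFrame:
        return self.table


def evanno_table(L_by_k: dict[int, list[float]]) -> EvannoTable:
    """Evanno statistics from replicate model scores L(K).

    ΔK = mean over replicates of |L''(K)| divided by the across-replicate
    standard deviation of L(K); defined for interior K only. The selected K
    maximizes ΔK, ties broken by the higher mean L(K) (the model-evidence
    criterion).
    """
    ks = sorted(L_by_k)
    reps = {k: np.asarray(v, dtype=float) for k, v in L_by_k.items()}
    n_rep = {k: len(v) for k, v in reps.items()}
    if min(n_rep.values()) < 2:
        raise AdmixtureError("Evanno delta-K needs >= 2 replicates per K (sd required)")
    mean_L = {k: float(np.mean(reps[k])) for k in ks}
    sd_L = {k: float(np.std(reps[k], ddof=1)) for k in ks}
    rows = []
    for i, k in enumerate(ks):
        lp = mean_L[k] - mean_L[ks[i - 1]] if i > 0 else np.nan
        if 0 < i < len(ks) - 1 and ks[i - 1] == k - 1 and ks[i + 1] == k + 1:
            r = min(n_rep[k - 1], n_rep[k], n_rep[k + 1])
            l2 = reps[k + 1][:r] - 2 * reps[k][:r] + reps[k - 1][:r]
            abs_l2 = float(np.mean(np.abs(l2)))
            dk = abs_l2 / sd_L[k] if sd_L[k] > 0 else np.nan
        else:
            abs_l2 = np.nan
            dk = np.nan
        rows.append(
            {
                "K": k,
                "mean_L": mean_L[k],
                "sd_L": sd_L[k],
                "L_prime": lp,
                "abs_L_second": abs_l2,
                "delta_K": dk,
            }
        )
    table = pd.DataFrame(rows)
    dk_vals = table["delta_K"]
    if dk_vals.notna().any():
        best = dk_vals.max()
        cand = table.loc[dk_vals == best]
        selected = int(cand.sort_values("mean_L", ascending=False)["K"].iloc[0])
    else:
        # no interior K: fall back to the model-evidence criterion
        selected = int(table.sort_values("mean_L", ascending=False)["K"].iloc[0])
    return EvannoTable(table=table, selected_k=selected)


def run_k_scan(
    panel: GenotypePanel,
    k_range=range(1, 10),
    replicates: int = 3,
    iters: int = 4000,
    burn_in: int = 2000,
    thin: int = 10,
    lam: float = 1.0,
    alpha: float = 1.0,
    seed: int | None = None,
) -> tuple[dict[int, list[AdmixtureRun]], EvannoTable]:
    """Replicate Gibbs runs across a K range plus the Evanno table."""
    ks = list(k_range)
    if replicates < 2:
        raise AdmixtureError(
            "replicates must be >= 2: delta-K needs an across-replicate sd"
        )
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(ks) * replicates))
    runs: dict[int, list[AdmixtureRun]] = {}
    for k in ks:
        runs[k] = [
            gibbs_admixture(
                panel, k, iters=iters, burn_in=burn_in, thin=thin,
                lam=lam, alpha=alpha, seed=next(children),
            )
            for _ in range(replicates)
        ]
    table = evanno_table({k: [r.L_of_K for r in rs] for k, rs in runs.items()})
    return runs, table


# ---------------------------------------------------------------------------
# Label alignment across replicate runs (display only)
# ---------------------------------------------------------------------------

def _column_score(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, falling back to -MSE for constant columns."""
    sx, sy = x.std(), y.std()
    if sx > 0 and sy > 0:
        return float(np.corrcoef(x, y)[0, 1])
    return -float(np.mean((x - y) ** 2))


def align_runs(runs: list[AdmixtureRun]) -> list[tuple[int, ...]]:
    """Greedy column permutations matching each run's Q to the first run's.

    Used only for averaged-Q display; never for L(K) or delta-K. Returns,
    per run, a tuple ``perm`` such that ``Q[:, perm]`` matches run 0.
    """
    if len(runs) < 2:
        return [tuple(range(r.K)) for r in runs]
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise AdmixtureError("all runs must share the same K to be aligned")
    ref = runs[0].Q.to_numpy()
    perms: list[tuple[int, ...]] = [tuple(range(K))]
    for run in runs[1:]:
        q = run.Q.to_numpy()
        score = np.array(
            [[_column_score(ref[:, i], q[:, j]) for j in range(K)] for i in range(K)]
        )
        perm = [-1] * K
        used_i, used_j = set(), set()
        flat = sorted(
            ((score[i, j], i, j) for i in range(K) for j in range(K)), reverse=True
        )
        for _, i, j in flat:
            if i in used_i or j in used_j:
                continue
            perm[i] = j
            used_i.add(i)
            used_j.add(j)
            if len(used_i) == K:
                break
        perms.append(tuple(perm))
    return perms


def mean_aligned_q(runs: list[AdmixtureRun]) -> pd.DataFrame:
    """Average Q over replicate runs after greedy label alignment."""
    perms = align_runs(runs)
    stack = [run.Q.to_numpy()[:, list(p)] for run, p in zip(runs, perms)]
    out = runs[0].Q.copy()
    out.loc[:, :] = np.mean(stack, axis=0)
    return out
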