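"""Synthetic diploid SNP panels with known population structure.

The generative model is a two-level Balding-Nichols hierarchy. An ancestral
allele frequency ``pi_l`` is drawn per locus from a (truncated) spectrum;
each *cluster* k drifts away from it with coefficient ``F_k`` via

    c_kl ~ Beta(pi (1-F)/F, (1-pi)(1-F)/F),

so E[c] = pi and Var[c] = F pi (1-pi); each *population* within a cluster
drifts again with its own ``f_pop``. Individuals of a pure population draw
both allele copies from their population frequency; individuals of an
admixed population have per-individual ancestry proportions
``q_i ~ Dirichlet(concentration)`` and each allele copy picks a cluster of
origin with probability ``q_ik`` before picking an allele from ``c_kl``
(the admixture model of STRUCTURE, so the admixture module is estimated
under its own truth). Within-population inbreeding ``Fis`` is realized by
letting the second allele copy duplicate the first (cluster of origin and
allelic state) with probability Fis, which yields genotype probabilities

    P(hom-ref) = (1-p)^2 + Fis p(1-p)
    P(het)     = 2 p (1-p) (1 - Fis)
    P(hom-alt) = p^2 + Fis p(1-p)

with p the individual's marginal alt-allele probability. Genotypes are then
set missing completely at random with probability ``missing_rate``.
Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import dataclasses
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel


class ScenarioError(ValueError):
    """Invalid simulation scenario."""


AdmixtureSpec = Union[str, dict]  # "pure" or {cluster: dirichlet concentration}


@dataclasses.dataclass
class SimScenario:
    """Full description of one simulated study design."""

    pop_names: list[str]
    n_per_pop: list[int]
    n_loci: int
    ancestral_spectrum: tuple  # ("beta", (a, b)) or ("uniform", ())
    clusters: dict             # cluster label -> F_cluster in [0, 1)
    cluster_assignments: dict  # pure population -> cluster label
    f_pop: dict                # population -> within-cluster drift in [0, 1)
    admixture_spec: dict       # population -> "pure" | {cluster: conc > 0}
    fis: dict                  # population -> Fis in [0, 1)
    missing_rate: float = 0.0
    maf_floor: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci <= 0:
            raise ScenarioError("n_loci must be positive")
        if len(self.pop_names) != len(self.n_per_pop):
            raise ScenarioError("pop_names and n_per_pop length mismatch")
        if any(n <= 0 for n in self.n_per_pop):
            raise ScenarioError("n_per_pop entries must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ScenarioError("missing_rate must be in [0, 1)")
        if not 0 <= self.maf_floor < 0.5:
            raise ScenarioError("maf_floor must be in [0, 0.5)")
        for k, f in self.clusters.items():
            if not 0 <= f < 1:
                raise ScenarioError(f"cluster {k!r} drift F={f} outside [0, 1)")
        for pop in self.pop_names:
            spec = self.admixture_spec.get(pop, "pure")
            if spec == "pure":
                cl = self.cluster_assignments.get(pop)
                if cl not in self.clusters:
                    raise ScenarioError(
                        f"pure population {pop!r} references unknown cluster {cl!r}"
                    )
                f = self.f_pop.get(pop, 0.0)
                if not 0 <= f < 1:
                    raise ScenarioError(f"f_pop for {pop!r} outside [0, 1)")
            else:
                if not spec:
                    raise ScenarioError(f"empty admixture spec for {pop!r}")
                for cl, conc in spec.items():
                    if cl not in self.clusters:
                        raise ScenarioError(
                            f"admixed population {pop!r} references unknown "
                            f"cluster {cl!r}"
                        )
                    if conc <= 0:
                        raise ScenarioError(
                            f"Dirichlet concentration for {pop!r}/{cl!r} must be > 0"
                        )
            fis = self.fis.get(pop, 0.0)
            if not 0 <= fis < 1:
                raise ScenarioError(f"Fis for {pop!r} outside [0, 1)")

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def cluster_names(self) -> list[str]:
        return list(self.clusters)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SimTruth:
    """Ground truth accompanying a simulated panel."""

    pop_freqs: pd.DataFrame    # populations x loci marginal alt frequencies
    q_true: pd.DataFrame       # individuals x clusters ancestry proportions
    realized_fst: pd.DataFrame # pairwise Hudson Fst from pop_freqs
    labels: pd.Series          # individual -> population


def hudson_fst_from_freqs(p1: np.ndarray, p2: np.ndarray) -> float:
    """Hudson-style Fst (1 - sum Hw / sum Hb) from two frequency vectors."""
    hw = p1 * (1 - p1) + p2 * (1 - p2)
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    denom = float(hb.sum())
    if denom == 0:
        return np.nan
    return 1.0 - float(hw.sum()) / denom


def _draw_ancestral(rng: np.random.Generator, scenario: SimScenario) -> np.ndarray:
    """Ancestral frequencies from the spectrum truncated to [floor, 1-floor]."""
    family, params = scenario.ancestral_spectrum
    lo, hi = scenario.maf_floor, 1.0 - scenario.maf_floor
    if family == "uniform":
        return rng.uniform(lo, hi, size=scenario.n_loci)
    if family == "beta":
        a, b = params
        dist = stats.beta(a, b)
        u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=scenario.n_loci)
        return dist.ppf(u)
    raise ScenarioError(f"unknown ancestral spectrum family {family!r}")


def _drift(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols drift; F = 0 is an exact copy (no degenerate Beta).

    Loci already fixed (p = 0 or 1) stay fixed: further drift cannot
    resurrect a lost allele.
    """
    if F == 0:
        return p.copy()
    interior = (p > 0) & (p < 1)
    out = p.copy()
    a = p[interior] * (1 - F) / F
    b = (1 - p[interior]) * (1 - F) / F
    out[interior] = np.clip(rng.beta(a, b), 0.0, 1.0)
    return out


def simulate_panel(scenario: SimScenario) -> tuple[GenotypePanel, SimTruth]:
    """Draw one genotype panel and its ground truth from a scenario."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    L = scenario.n_loci
    clusters = scenario.cluster_names
    K = len(clusters)

    pi = _draw_ancestral(rng, scenario)
    c = np.stack([_drift(rng, pi, scenario.clusters[k]) for k in clusters])  # K x L

    samples: list[str] = []
    labels: list[str] = []
    geno_rows: list[np.ndarray] = []
    q_rows: list[np.ndarray] = []
    pop_freq_rows: dict[str, np.ndarray] = {}

    for pop, n in zip(scenario.pop_names, scenario.n_per_pop):
        spec = scenario.admixture_spec.get(pop, "pure")
        fis = scenario.fis.get(pop, 0.0)
        if spec == "pure":
            k = clusters.index(scenario.cluster_assignments[pop])
            p_pop = _drift(rng, c[k], scenario.f_pop.get(pop, 0.0))  # L
            p_ind = np.broadcast_to(p_pop, (n, L))
            q = np.zeros((n, K))
            q[:, k] = 1.0
            pop_freq_rows[pop] = p_pop
        else:
            conc = np.array([spec.get(k, 0.0) for k in clusters])
            active = conc > 0
            q = np.zeros((n, K))
            q[:, active] = rng.dirichlet(conc[active], size=n)
            p_ind = q @ c  # n x L marginal alt probability per individual
            pop_freq_rows[pop] = p_ind.mean(axis=0)

        copy1 = rng.random((n, L)) < p_ind
        dup = rng.random((n, L)) < fis
        copy2_fresh = rng.random((n, L)) < p_ind
        copy2 = np.where(dup, copy1, copy2_fresh)
        g = copy1.astype(np.int8) + copy2.astype(np.int8)
        if scenario.missing_rate > 0:
            g[rng.random((n, L)) < scenario.missing_rate] = MISSING
        geno_rows.append(g)
        q_rows.append(q)
        samples.extend(f"{pop}_{i + 1:03d}" for i in range(n))
        labels.extend([pop] * n)

    genotypes = np.vstack(geno_rows)
    labels_s = pd.Series(labels, index=samples, name="population")
    locus_ids = [str(10_000 + j) for j in range(L)]
    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "snp_id": [f"{lid}_{(j % 130) + 5}" for j, lid in enumerate(locus_ids)],
            "chrom": "1",
            "pos": np.arange(1, L + 1) * 100,
        }
    )
    panel = GenotypePanel(
        samples=samples, populations=labels_s, loci=loci, genotypes=genotypes
    )

    pop_freqs = pd.DataFrame(pop_freq_rows).T
    pop_freqs = pop_freqs.loc[scenario.pop_names]
    pop_freqs.columns = loci["snp_id"]
    fst = pd.DataFrame(
        np.nan, index=scenario.pop_names, columns=scenario.pop_names
    )
    for i, a in enumerate(scenario.pop_names):
        for b in scenario.pop_names[i + 1:]:
            v = hudson_fst_from_freqs(
                pop_freqs.loc[a].to_numpy(), pop_freqs.loc[b].to_numpy()
            )
            fst.loc[a, b] = fst.loc[b, a] = v
    q_true = pd.DataFrame(np.vstack(q_rows), index=samples, columns=clusters)
    truth = SimTruth(
        pop_freqs=pop_freqs, q_true=q_true, realized_fst=fst, labels=labels_s
    )
    return panel, truth


def two_pop_scenario(
    F: float = 0.2,
    n_per_pop: int = 50,
    n_loci: int = 2000,
    fis: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimScenario:
    """Two pure populations drifted symmetrically at ``F`` from one ancestor."""
    return SimScenario(
        pop_names=["A", "B"],
        n_per_pop=[n_per_pop, n_per_pop],
        n_loci=n_loci,
        ancestral_spectrum=("uniform", ()),
        clusters={"root": 0.0},
        cluster_assignments={"A": "root", "B": "root"},
        f_pop={"A": F, "B": F},
        admixture_spec={"A": "pure", "B": "pure"},
        fis={"A": fis, "B": fis},
        missing_rate=missing_rate,
        maf_floor=0.05,
        seed=seed,
    )


def k_cluster_scenario(
    n_clusters: int = 3,
    F: float = 0.3,
    n_per_pop: int = 20,
    n_loci: int = 300,
    seed: int = 0,
) -> SimScenario:
    """``n_clusters`` well-separated pure populations, one per cluster."""
    names = [f"P{i + 1}" for i in range(n_clusters)]
    return SimScenario(
        pop_names=names,
        n_per_pop=[n_per_pop] * n_clusters,
        n_loci=n_loci,
        ancestral_spectrum=("uniform", ()),
        clusters={f"C{i + 1}": F for i in range(n_clusters)},
        cluster_assignments={n: f"C{i + 1}" for i, n in enumerate(names)},
        f_pop={n: 0.0 for n in names},
        admixture_spec={n: "pure" for n in names},
        fis={n: 0.0 for n in names},
        missing_rate=0.0,
        maf_floor=0.1,
        seed=seed,
    )


def study_scenario(seed: int = 2019) -> SimScenario:
    """Default study-design scenario: 7 populations x 20 diploid individuals.

    One low-divergence cluster of four populations around a Lake-Victoria-like
    source (pairwise Fst in the few-percent range), one strongly isolated
    population (realized Fst > 0.4 against the cluster), and two-to-three
    admixed farm populations with elevated inbreeding (Fis 0.26-0.5).
    Roughly 2,500 pre-filter loci with a low-MAF-skewed ancestral spectrum
    (Beta(0.6, 7), most mass just above the 5% filtering threshold) and 10%
    MCAR missingness. With homogeneous genome-wide drift the strong
    between-group divergence necessarily leaves a heavier pooled-MAF tail
    than real ddRAD panels show; see the methods documentation.
    """
    return SimScenario(
        pop_names=[
            "Victoria", "FETA", "Igunga", "Kunduchi", "TAFIRI", "Karanga", "Ruhila",
        ],
        n_per_pop=[20] * 7,
        n_loci=2500,
        ancestral_spectrum=("beta", (0.6, 7.0)),
        clusters={"victoria": 0.60, "isolate": 0.20, "south": 0.60, "ruhila": 0.50},
        cluster_assignments={
            "Victoria": "victoria",
            "FETA": "victoria",
            "Igunga": "victoria",
            "TAFIRI": "isolate",
        },
        f_pop={"Victoria": 0.035, "FETA": 0.045, "Igunga": 0.035, "TAFIRI": 0.02},
        admixture_spec={
            "Victoria": "pure",
            "FETA": "pure",
            "Igunga": "pure",
            "TAFIRI": "pure",
            "Kunduchi": {"victoria": 8.0, "south": 2.0},
            "Karanga": {"south": 8.0, "victoria": 2.0},
            "Ruhila": {"ruhila": 5.0, "isolate": 2.0, "victoria": 2.0, "south": 1.0},
        },
        fis={
            "Victoria": 0.005,
            "FETA": 0.006,
            "Igunga": 0.01,
            "TAFIRI": 0.02,
            "Kunduchi": 0.50,
            "Karanga": 0.26,
            "Ruhila": 0.28,
        },
        missing_rate=0.10,
        maf_floor=0.02,
        seed=seed,
    )
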