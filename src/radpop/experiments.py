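"""Calibration and parameter-recovery experiments.

Each function runs one self-contained experiment on simulated data with
known truth — estimator bias, bootstrap CI coverage, permutation-test
calibration, MCMC recovery, cluster-number selection, assignment rates —
and returns a small dict of summary numbers. They are the package's own
validation battery: the test suite asserts on them and the reproduction
script reports them.

Problem sizes are desk-scale: large enough for the statistical checks to
be well-powered, small enough that the full battery runs in minutes on one
CPU (exact sizes are each function's defaults).
"""

from __future__ import annotations

import numpy as np

from .admixture import gibbs_admixture, run_k_scan
from .assign import crossval_assignment
from .differentiation import amova, fst_matrix, wc_theta_pair
from .diversity import diversity_table
from .filtering import filter_panel
from .panel import GenotypePanel, MISSING
from .sim import (
    SimScenario,
    k_cluster_scenario,
    study_scenario,
    simulate_panel,
    two_pop_scenario,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def fst_recovery(
    F: float = 0.2,
    n_per_pop: int = 50,
    n_loci: int = 2000,
    n_seeds: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Bias and bootstrap-CI coverage of theta-hat at a known drift level.

    Simulates two populations drifted symmetrically at F, estimates the
    pairwise Weir-Cockerham theta with a locus bootstrap, and checks how
    often the 95% CI covers the realized (truth-level) Fst.
    """
    thetas, covered = [], 0
    for s in _child_seeds(seed, n_seeds):
        panel, truth = simulate_panel(
            two_pop_scenario(F=F, n_per_pop=n_per_pop, n_loci=n_loci, seed=s)
        )
        res = fst_matrix(panel, n_boot=n_boot, seed=s + 1)
        th = float(res.theta.iloc[0, 1])
        thetas.append(th)
        realized = float(truth.realized_fst.iloc[0, 1])
        if res.ci_low.iloc[0, 1] <= realized <= res.ci_high.iloc[0, 1]:
            covered += 1
    return {
        "mean_theta": float(np.mean(thetas)),
        "ci_coverage": covered / n_seeds,
        "n_seeds": n_seeds,
    }


def fis_recovery(
    fis_values=(0.0, 0.25, 0.5),
    n_per_pop: int = 20,
    n_loci: int = 2000,
    seed: int = 0,
) -> dict:
    """Error of the Fis estimator at known simulated inbreeding levels."""
    errors = {}
    for fis, s in zip(fis_values, _child_seeds(seed, len(fis_values))):
        sc = SimScenario(
            pop_names=["P"],
            n_per_pop=[n_per_pop],
            n_loci=n_loci,
            ancestral_spectrum=("uniform", ()),
            clusters={"root": 0.0},
            cluster_assignments={"P": "root"},
            f_pop={"P": 0.1},
            admixture_spec={"P": "pure"},
            fis={"P": fis},
            missing_rate=0.0,
            maf_floor=0.1,
            seed=s,
        )
        panel, _ = simulate_panel(sc)
        est = float(diversity_table(panel)["Fis"].iloc[0])
        errors[fis] = est - fis
    return {
        "errors": errors,
        "max_abs_error": float(max(abs(e) for e in errors.values())),
    }


def amova_null_calibration(
    n_seeds: int = 50,
    n_per_pop: int = 20,
    n_loci: int = 500,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Permutation-p calibration on a panmictic panel split in two labels."""
    n_ok = 0
    for s in _child_seeds(seed, n_seeds):
        panel, _ = simulate_panel(
            two_pop_scenario(F=0.0, n_per_pop=n_per_pop, n_loci=n_loci, seed=s)
        )
        res = amova(panel, n_perm=n_perm, seed=s + 1)
        if res.p_value > 0.05:
            n_ok += 1
    return {"frac_p_above_05": n_ok / n_seeds, "n_seeds": n_seeds}


def fixed_difference_panel(n_per_pop: int = 10, n_loci: int = 50) -> GenotypePanel:
    """Two populations fixed for opposite alleles at every locus."""
    import pandas as pd

    geno = np.vstack(
        [
            np.zeros((n_per_pop, n_loci), dtype=np.int8),
            np.full((n_per_pop, n_loci), 2, dtype=np.int8),
        ]
    )
    samples = [f"A_{i}" for i in range(n_per_pop)] + [
        f"B_{i}" for i in range(n_per_pop)
    ]
    pops = pd.Series(["A"] * n_per_pop + ["B"] * n_per_pop, index=samples)
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j}" for j in range(n_loci)],
            "snp_id": [f"L{j}_1" for j in range(n_loci)],
            "chrom": "1",
            "pos": np.arange(1, n_loci + 1),
        }
    )
    return GenotypePanel(samples=samples, populations=pops, loci=loci, genotypes=geno)


def admixture_q_rmse(
    F: float = 0.3,
    n_per_pop: int = 20,
    n_loci: int = 500,
    iters: int = 4000,
    burn_in: int = 2000,
    seed: int = 0,
) -> dict:
    """Q-matrix recovery for two well-separated populations (best label perm)."""
    panel, truth = simulate_panel(
        k_cluster_scenario(n_clusters=2, F=F, n_per_pop=n_per_pop,
                           n_loci=n_loci, seed=seed)
    )
    run = gibbs_admixture(panel, K=2, iters=iters, burn_in=burn_in, seed=seed + 1)
    Q = run.Q.to_numpy()
    qt = truth.q_true.to_numpy()
    rmse = min(
        float(np.sqrt(np.mean((Q - qt) ** 2))),
        float(np.sqrt(np.mean((Q[:, ::-1] - qt) ** 2))),
    )
    return {"q_rmse": rmse, "mean_max_q": float(Q.max(axis=1).mean())}


def evanno_k_selection(
    n_clusters: int = 3,
    F: float = 0.3,
    n_per_pop: int = 20,
    n_loci: int = 300,
    k_values=range(1, 6),
    replicates: int = 3,
    iters: int = 1500,
    burn_in: int = 750,
    n_seeds: int = 10,
    seed: int = 0,
) -> dict:
    """How often Evanno delta-K picks the true cluster number."""
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        panel, _ = simulate_panel(
            k_cluster_scenario(
                n_clusters=n_clusters, F=F, n_per_pop=n_per_pop,
                n_loci=n_loci, seed=s,
            )
        )
        _, evanno = run_k_scan(
            panel, k_range=k_values, replicates=replicates,
            iters=iters, burn_in=burn_in, seed=s + 1,
        )
        if evanno.selected_k == n_clusters:
            hits += 1
    return {"n_correct": hits, "n_seeds": n_seeds, "rate": hits / n_seeds}


def assignment_battery(seed: int = 0) -> dict:
    """The cross-validation experiment on the study-design scenario plus its
    negative and positive controls.

    Returns the pooled confusion total and overall rate on the default
    7-population design, the chance-level rate when population labels are
    randomly permuted before cross-validation, and the rate on a fully
    separable (fixed-difference) two-population panel.
    """
    import pandas as pd

    panel, truth = simulate_panel(study_scenario(seed=seed))
    filtered, _ = filter_panel(panel)
    report = crossval_assignment(filtered, seed=seed + 1)

    # errors inside the simulated low-divergence cluster (incl. the
    # cluster-admixed Kunduchi), mirroring where misassignments should fall
    cluster = ["Victoria", "FETA", "Igunga", "Kunduchi"]
    C = report.confusion
    total_err = int(C.to_numpy().sum() - np.trace(C.to_numpy()))
    within = int(sum(C.loc[a, b] for a in cluster for b in cluster if a != b))

    rng = np.random.default_rng(seed + 2)
    permuted = GenotypePanel(
        samples=filtered.samples,
        populations=pd.Series(
            rng.permutation(filtered.populations.to_numpy()),
            index=filtered.samples,
        ),
        loci=filtered.loci,
        genotypes=filtered.genotypes,
    )
    chance = crossval_assignment(permuted, seed=seed + 3)

    separable = fixed_difference_panel(n_per_pop=20, n_loci=100)
    sep = crossval_assignment(separable, seed=seed + 4)

    return {
        "confusion_total": report.total,
        "overall_rate": report.overall_rate,
        "error_frac_within_cluster": within / total_err if total_err else 1.0,
        "permuted_rate": chance.overall_rate,
        "separable_rate": sep.overall_rate,
    }
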