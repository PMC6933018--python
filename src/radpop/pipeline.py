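"""End-to-end orchestration: filter -> diversity -> Fst -> AMOVA ->
admixture scan -> DAPC -> cross-validated assignment.

A :class:`RunConfig` (built in code or loaded from a YAML file) names the
input (a VCF/TSV plus popmap, or the built-in simulated study design), the
stages to run and every tunable. ``run_pipeline`` writes one TSV per stage
plus a ``manifest.json`` recording inputs, parameter values, seeds and the
package version, so any output is re-derivable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from . import __version__
from .admixture import run_k_scan
from .assign import crossval_assignment
from .dapc import find_clusters, fit_dapc, fit_pca
from .differentiation import amova, fst_matrix
from .diversity import diversity_table
from .filtering import filter_panel
from .io import read_panel, write_popmap, write_tsv, write_vcf
from .sim import study_scenario, simulate_panel

ALL_STAGES = ("filter", "diversity", "fst", "amova", "structure", "dapc", "assign")


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any computation)."""


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    genotypes: str | None = None        # VCF or TSV path
    popmap: str | None = None
    simulate: bool = False              # use the built-in study-design scenario
    stages: tuple = ALL_STAGES
    seed: int = 1
    maf_min: float = 0.05
    call_rate_min: float = 0.75
    maf_scope: str = "overall"
    n_boot: int = 1000
    n_perm: int = 100
    k_min: int = 1
    k_max: int = 9
    replicates: int = 3
    iters: int = 4000
    burn_in: int = 2000
    thin: int = 10
    holdout_frac: float = 0.25
    repeats: int = 10
    n_pca: int | None = None

    def validate(self) -> None:
        if not self.simulate and (self.genotypes is None or self.popmap is None):
            raise ConfigError("either simulate=true or genotypes+popmap required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        if not 0 < self.maf_min < 0.5:
            raise ConfigError("maf_min must be in (0, 0.5)")
        if not 0 < self.call_rate_min <= 1:
            raise ConfigError("call_rate_min must be in (0, 1]")
        if self.iters <= self.burn_in:
            raise ConfigError("iters must exceed burn_in")
        if self.n_boot < 1 or self.n_perm < 1:
            raise ConfigError("n_boot and n_perm must be >= 1")
        if self.seed is None:
            self.seed = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw and isinstance(raw["stages"], str):
            raw["stages"] = tuple(s.strip() for s in raw["stages"].split(","))
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    if config.simulate:
        scenario = study_scenario(seed=config.seed)
        panel, truth = simulate_panel(scenario)
        write_vcf(panel, out / "simulated.vcf")
        write_popmap(panel.populations, out / "simulated.popmap.tsv")
        truth.realized_fst.to_csv(out / "truth_realized_fst.tsv", sep="\t")
        truth.q_true.to_csv(out / "truth_q.tsv", sep="\t")
        manifest["input"] = {"simulated": True, "scenario_seed": scenario.seed}
    else:
        panel = read_panel(config.genotypes, config.popmap)
        manifest["input"] = {"genotypes": config.genotypes, "popmap": config.popmap}

    stages = list(config.stages)
    filtered = panel
    if "filter" in stages:
        filtered, report = filter_panel(
            panel,
            maf_min=config.maf_min,
            call_rate_min=config.call_rate_min,
            maf_scope=config.maf_scope,
        )
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        write_tsv(filtered, out / "filtered_genotypes.tsv")
        manifest["stages"]["filter"] = {
            "output": "filter_report.tsv",
            "n_retained": report.n_retained,
        }
    if "diversity" in stages:
        div = diversity_table(filtered)
        div.to_csv(out / "diversity.tsv", sep="\t")
        manifest["stages"]["diversity"] = {"output": "diversity.tsv"}
    if "fst" in stages:
        fst = fst_matrix(filtered, n_boot=config.n_boot, seed=config.seed)
        fst.to_frame().to_csv(out / "fst_pairwise.tsv", sep="\t", index=False)
        manifest["stages"]["fst"] = {
            "output": "fst_pairwise.tsv",
            "n_bootstraps": config.n_boot,
        }
    if "amova" in stages:
        am = amova(filtered, n_perm=config.n_perm, seed=config.seed)
        am.to_frame().to_csv(out / "amova.tsv", sep="\t", index=False)
        manifest["stages"]["amova"] = {
            "output": "amova.tsv",
            "phi_st": am.phi_st,
            "p_value": am.p_value,
        }
    if "structure" in stages:
        runs, evanno = run_k_scan(
            filtered,
            k_range=range(config.k_min, config.k_max + 1),
            replicates=config.replicates,
            iters=config.iters,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=config.seed,
        )
        evanno.to_frame().to_csv(out / "evanno.tsv", sep="\t", index=False)
        best_k = evanno.selected_k
        runs[best_k][0].to_frame().to_csv(out / f"q_matrix_K{best_k}.tsv", sep="\t")
        with open(out / "structure_runs.json", "w") as fh:
            json.dump(
                {
                    str(k): [
                        {"L_of_K": r.L_of_K, "settings": {
                            kk: vv for kk, vv in r.settings.items()
                            if kk != "populations"
                        }}
                        for r in rs
                    ]
                    for k, rs in runs.items()
                },
                fh,
                indent=2,
                default=str,
            )
        manifest["stages"]["structure"] = {
            "output": "evanno.tsv",
            "selected_k": best_k,
        }
    if "dapc" in stages:
        _, scores = fit_pca(filtered)
        scan = find_clusters(
            filtered, k_max=min(config.k_max, filtered.n_samples - 1),
            n_pca=config.n_pca, seed=config.seed,
        )
        scan.table.to_csv(out / "cluster_bic.tsv", sep="\t", index=False)
        model = fit_dapc(filtered, n_pca=config.n_pca)
        model.var_contrib.sort_values(ascending=False).to_csv(
            out / "snp_contributions.tsv", sep="\t"
        )
        manifest["stages"]["dapc"] = {
            "output": "snp_contributions.tsv",
            "selected_k": scan.selected_k,
            "n_pca": model.n_pca,
        }
    if "assign" in stages:
        rep = crossval_assignment(
            filtered,
            holdout_frac=config.holdout_frac,
            repeats=config.repeats,
            n_pca=config.n_pca,
            seed=config.seed,
        )
        rep.confusion.to_csv(out / "confusion_matrix.tsv", sep="\t")
        manifest["stages"]["assign"] = {
            "output": "confusion_matrix.tsv",
            "overall_rate": rep.overall_rate,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
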