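"""SNP filtering for ddRAD panels.

Three rules are applied, in a fixed order that mirrors the usual reduced-
representation workflow (the order matters for the bookkeeping, so it is
part of the contract):

1. **one SNP per ddRAD locus** — of the SNPs sharing a ddRAD tag, keep the
   one with the highest overall MAF (ties broken by smallest position);
2. **per-population call rate** — keep a SNP only if it is genotyped in at
   least ``call_rate_min`` of the samples of *every* population;
3. **minor allele frequency** — keep a SNP only if its MAF (by default
   computed across all samples; per-population mode available) is at least
   ``maf_min``.

The returned :class:`FilterReport` satisfies a conservation invariant:
the per-rule removal counts always sum back to the input count.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclasses.dataclass
class FilterReport:
    """Bookkeeping of a filtering run (removals are sequential)."""

    n_input: int
    n_removed_multisnp: int = 0
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    per_rule_ids: dict = dataclasses.field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        """Retained count implied by conservation of SNPs across rules."""
        return (
            self.n_input
            - self.n_removed_multisnp
            - self.n_removed_missing
            - self.n_removed_maf
        )

    def check(self) -> None:
        if self.n_retained < 0:
            raise ValueError("filter report removes more SNPs than it was given")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "one_snp_per_locus", "call_rate", "maf", "retained"],
                "n": [
                    self.n_input,
                    self.n_removed_multisnp,
                    self.n_removed_missing,
                    self.n_removed_maf,
                    self.n_retained,
                ],
            }
        )

    def log_lines(self) -> list[str]:
        return [
            f"{self.n_input} SNPs in",
            f"{self.n_removed_multisnp} removed by one-SNP-per-locus rule",
            f"{self.n_removed_missing} removed by per-population call-rate rule",
            f"{self.n_removed_maf} removed by MAF rule",
            f"{self.n_retained} SNPs retained",
        ]


def allele_counts(
    panel: GenotypePanel, rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (alt copies, total called copies) over the given sample rows."""
    G = panel.genotypes if rows is None else panel.genotypes[rows]
    called = G != MISSING
    alt = np.where(called, G, 0).sum(axis=0).astype(float)
    total = 2.0 * called.sum(axis=0)
    return alt, total


def maf(panel: GenotypePanel, scope: str = "overall"):
    """Per-SNP minor allele frequency.

    ``scope="overall"`` returns a 1-D array over all samples;
    ``scope="population"`` returns a DataFrame (populations x SNPs).
    SNPs with no called copies in scope are NaN.
    """
    if scope == "overall":
        alt, total = allele_counts(panel)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        return np.minimum(p, 1.0 - p)
    if scope == "population":
        rows = {}
        for pop, idx in panel.pop_indices().items():
            alt, total = allele_counts(panel, idx)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
            rows[pop] = np.minimum(p, 1.0 - p)
        return pd.DataFrame(rows, index=panel.snp_ids).T
    raise ValueError(f"unknown MAF scope {scope!r}")


def one_snp_per_locus(panel: GenotypePanel) -> tuple[GenotypePanel, dict]:
    """Keep, per ddRAD locus, the SNP with the highest overall MAF.

    Ties are broken by smallest position. Returns the reduced panel and a
    report fragment ``{"n_removed": int, "removed_ids": [...]}``.
    """
    overall_maf = maf(panel, scope="overall")
    loci = panel.loci.assign(
        _maf=np.nan_to_num(overall_maf, nan=-1.0), _col=np.arange(panel.n_loci)
    )
    keep: list[int] = []
    for _, grp in loci.groupby("locus_id", sort=False):
        best = grp.sort_values(["_maf", "pos"], ascending=[False, True]).iloc[0]
        keep.append(int(best["_col"]))
    keep = sorted(keep)
    removed = sorted(set(range(panel.n_loci)) - set(keep))
    fragment = {
        "n_removed": len(removed),
        "removed_ids": panel.loci["snp_id"].iloc[removed].tolist(),
    }
    return panel.subset_loci(np.array(keep, dtype=int)), fragment


def filter_panel(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    call_rate_min: float = 0.75,
    maf_scope: str = "overall",
) -> tuple[GenotypePanel, FilterReport]:
    """Apply the one-per-locus, call-rate and MAF rules in order.

    ``maf_scope="overall"`` keeps SNPs with MAF >= ``maf_min`` across all
    samples; ``maf_scope="population"`` keeps SNPs reaching the threshold in
    at least one population.
    """
    n_input = panel.n_loci
    panel1, frag = one_snp_per_locus(panel)

    # call-rate rule: non-missing fraction >= threshold in EVERY population
    called = panel1.genotypes != MISSING
    keep_cr = np.ones(panel1.n_loci, dtype=bool)
    for _, idx in panel1.pop_indices().items():
        rate = called[idx].mean(axis=0)
        keep_cr &= rate >= call_rate_min
    removed_cr = panel1.loci["snp_id"].to_numpy(object)[~keep_cr].tolist()
    panel2 = panel1.subset_loci(keep_cr)

    if maf_scope == "overall":
        snp_maf = maf(panel2, scope="overall")
        keep_maf = np.nan_to_num(snp_maf, nan=-1.0) >= maf_min
    elif maf_scope == "population":
        pop_maf = maf(panel2, scope="population").to_numpy()
        with np.errstate(invalid="ignore"):
            keep_maf = np.nanmax(pop_maf, axis=0) >= maf_min
    else:
        raise ValueError(f"unknown MAF scope {maf_scope!r}")
    removed_maf = panel2.loci["snp_id"].to_numpy(object)[~keep_maf].tolist()
    panel3 = panel2.subset_loci(keep_maf)

    report = FilterReport(
        n_input=n_input,
        n_removed_multisnp=frag["n_removed"],
        n_removed_missing=len(removed_cr),
        n_removed_maf=len(removed_maf),
        per_rule_ids={
            "one_snp_per_locus": frag["removed_ids"],
            "call_rate": removed_cr,
            "maf": removed_maf,
        },
    )
    report.check()
    assert report.n_retained == panel3.n_loci
    return panel3, report
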