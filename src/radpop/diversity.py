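"""Per-population diversity statistics: He, Ho, Fis and mean MAF.

Expected heterozygosity at a biallelic locus is ``He = 2 p (1 - p)`` with
``p`` the sample allele frequency from non-missing calls (optionally with
the ``2n/(2n-1)`` small-sample correction); observed heterozygosity is the
proportion of heterozygous calls. The population inbreeding coefficient is
``Fis = 1 - mean(Ho) / mean(He)`` (ratio of means by default, per-locus
averaging available), measuring the deficit of heterozygotes relative to
Hardy-Weinberg expectation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .filtering import maf
from .panel import MISSING, GenotypePanel


def het_per_locus(
    genotypes: np.ndarray, unbiased: bool = False
) -> tuple[float, float]:
    """(Ho, He) for a 1-D genotype vector (codes 0/1/2/-1) in one population.

    Raises ``ValueError`` if every call is missing.
    """
    g = np.asarray(genotypes)
    called = g != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError("all genotypes missing at locus")
    ho = float((g[called] == 1).mean())
    p = float(g[called].sum()) / (2.0 * n)
    he = 2.0 * p * (1.0 - p)
    if unbiased and n > 0:
        he *= 2.0 * n / (2.0 * n - 1.0)
    return ho, he


def _pop_het_arrays(
    G: np.ndarray, unbiased: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-locus (Ho, He, n_called) for one population block."""
    called = G != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, (G == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        p = np.where(n > 0, np.where(called, G, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n > 0, he * 2 * n / np.maximum(2 * n - 1, 1), np.nan)
    return ho, he, n


def diversity_table(
    panel: GenotypePanel,
    fis_mode: str = "ratio_of_means",
    unbiased: bool = False,
) -> pd.DataFrame:
    """Per-population He, Ho, Fis, mean MAF and sample counts.

    Loci monomorphic across the whole panel are excluded from all means
    (statistics are reported on variant sites only). ``fis_mode`` is
    ``"ratio_of_means"`` (``1 - mean(Ho)/mean(He)``, robust to near-zero-He
    loci) or ``"per_locus"`` (mean over loci of ``1 - Ho_l/He_l``).
    Populations whose mean He is zero get ``Fis = NaN``.
    """
    if fis_mode not in ("ratio_of_means", "per_locus"):
        raise ValueError(f"unknown fis_mode {fis_mode!r}")
    overall = maf(panel, scope="overall")
    polymorphic = np.nan_to_num(overall, nan=0.0) > 0
    pop_maf = maf(panel, scope="population")
    rows = []
    for pop, idx in panel.pop_indices().items():
        if len(idx) < 2:
            warnings.warn(
                f"population {pop!r} has {len(idx)} sample(s); "
                "diversity statistics are low-confidence"
            )
        G = panel.genotypes[idx][:, polymorphic]
        ho, he, n_called = _pop_het_arrays(G, unbiased)
        ok = n_called > 0
        mean_ho = float(np.mean(ho[ok])) if ok.any() else np.nan
        mean_he = float(np.mean(he[ok])) if ok.any() else np.nan
        if fis_mode == "ratio_of_means":
            fis = 1.0 - mean_ho / mean_he if mean_he and mean_he > 0 else np.nan
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                per_locus = 1.0 - ho / he
            valid = ok & (he > 0)
            fis = float(np.mean(per_locus[valid])) if valid.any() else np.nan
        pm = pop_maf.loc[pop].to_numpy()[polymorphic]
        rows.append(
            {
                "population": pop,
                "He": mean_he,
                "Ho": mean_ho,
                "Fis": fis,
                "mean_maf": float(np.nanmean(pm)) if np.isfinite(pm).any() else np.nan,
                "n_polymorphic_loci": int(polymorphic.sum()),
                "n_samples": int(len(idx)),
            }
        )
    return pd.DataFrame(rows).set_index("population")
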