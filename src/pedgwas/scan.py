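"""Genome-wide additive and dominance scans, thresholds, FDR and regions.

Each marker is tested one at a time in the mixed model; genome-wide
significance uses the Bonferroni correction 0.05 / (number of tests),
optionally rounded to the nearest power of ten, with configurable
suggestive fallbacks.  The false discovery rate of a scan stage is the
closed-form ratio

    %FDR = P (1 - S/T) / ((S/T) (1 - P)) * 100

for p-value threshold ``P``, ``S`` significant out of ``T`` tests; it can
exceed 100% when the hit rate is below the threshold.  Per-marker variance
contributions are sigma_a^2 = 2pq a^2 and sigma_d^2 = 4 p^2 q^2 d^2,
reported as percentages of the phenotypic variance from the null model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel, code_additive, code_dominance
from .mixed_model import (
    NOT_TESTABLE,
    MixedModelEngine,
    SnpTestResult,
    VarianceComponents,
    fit_snp,
)
from .pedigree import RelationshipMatrix

__all__ = [
    "ScanResult",
    "bonferroni_threshold",
    "fdr_percent",
    "run_scan",
    "variance_fraction",
    "merge_regions",
    "write_manhattan",
]

FDR_UNDEFINED = float("nan")


def bonferroni_threshold(
    alpha: float, n_tests: int, magnitude_rounding: bool = False
) -> float:
    """Genome-wide threshold alpha / n_tests.

    With ``magnitude_rounding`` the threshold is rounded to the nearest power of
    ten (0.05/408,255 = 1.22e-7 becomes 1e-7), the convention used when a
    round threshold is quoted for a scan.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n_tests
    if magnitude_rounding:
        thr = 10.0 ** round(np.log10(thr))
    return thr


def fdr_percent(p_threshold: float, S: int, T: int) -> float:
    """Closed-form percent FDR of a scan stage; may exceed 100."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    if T <= 0 or S > T:
        raise ValueError("need 0 < S <= T")
    if S == 0:
        warnings.warn(
            "no significant tests: FDR undefined, returning NaN", stacklevel=2
        )
        return FDR_UNDEFINED
    rate = S / T
    return p_threshold * (1.0 - rate) / (rate * (1.0 - p_threshold)) * 100.0


@dataclass
class ScanResult:
    """Per-marker test results plus stage bookkeeping (threshold, S, T, FDR)."""

    table: pd.DataFrame  # snp,chrom,pos,effect_name,estimate,se,p,neglog10p,maf,variant,flags
    variant: str
    threshold: float
    n_tests: int  # T: testable markers (or pairs)
    n_significant: int  # S: p < threshold
    fdr: float

    @property
    def significant(self) -> pd.DataFrame:
        ok = self.table["flags"] == ""
        return self.table[ok & (self.table["p"] < self.threshold)]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "threshold": self.threshold,
            "T": self.n_tests,
            "S": self.n_significant,
            "fdr_percent": None if np.isnan(self.fdr) else self.fdr,
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def run_scan(
    panel: GenotypePanel,
    stats: pd.DataFrame,
    response: pd.DataFrame,
    vc: VarianceComponents,
    A: RelationshipMatrix | None,
    variant: str = "additive",
    *,
    threshold: float | None = None,
    alpha: float = 0.05,
    magnitude_rounding: bool = False,
    mode: str = "fixed-vc",
) -> ScanResult:
    """Scan every marker of the panel for additive or dominance effects.

    The additive variant tests ``a_j`` from ``y ~ mu + x_a(j)``; the
    dominance variant tests ``d_j`` from the joint model
    ``y ~ mu + x_a(j) + x_d(j)``.  Monomorphic or collinear markers are
    flagged not-testable and excluded from ``T``.  The response must be
    restricted to genotyped animals; records map to panel rows by animal id.
    """
    if variant not in ("additive", "dominance"):
        raise ValueError(f"unknown scan variant: {variant!r}")
    sub = panel.subset_animals(
        [a for a in dict.fromkeys(response["animal"].astype(str))]
    )
    rec_row = (
        response["animal"]
        .astype(str)
        .map({a: i for i, a in enumerate(sub.animal_ids)})
        .to_numpy()
    )
    engine = MixedModelEngine(response, A, vc) if mode == "fixed-vc" else None
    rows = []
    for j in range(sub.n_snps):
        snp = sub.snps["snp"].iloc[j]
        chrom = sub.snps["chrom"].iloc[j]
        pos = int(sub.snps["pos"].iloc[j])
        st = stats.loc[snp]
        p_freq = float(st["p"])
        maf = float(st["maf"])
        if not 0.0 < p_freq < 1.0:
            res = SnpTestResult(
                snp_ids=(snp,), effect_name="a_j", estimate=np.nan,
                se=np.nan, p=np.nan, maf=maf, variant=variant,
                flags=NOT_TESTABLE,
            )
        else:
            codes = sub.codes[:, j][rec_row]
            xa = code_additive(codes, p_freq)
            if variant == "additive":
                covs = {"a_j": xa}
                focal = "a_j"
            else:
                covs = {"a_j": xa, "d_j": code_dominance(codes, p_freq)}
                focal = "d_j"
            res = fit_snp(
                covs, focal, response, A, vc, mode=mode, engine=engine,
                variant=variant, snp_ids=(snp,), maf=maf,
            )
        rows.append(
            {
                "snp": snp,
                "chrom": chrom,
                "pos": pos,
                "effect_name": res.effect_name,
                "estimate": res.estimate,
                "se": res.se,
                "p": res.p,
                "neglog10p": res.neglog10p if res.testable else np.nan,
                "maf": maf,
                "variant": variant,
                "flags": res.flags,
            }
        )
    table = pd.DataFrame(rows)
    testable = table["flags"] == ""
    T = int(testable.sum())
    if threshold is None:
        threshold = bonferroni_threshold(alpha, max(T, 1), magnitude_rounding)
    S = int((table.loc[testable, "p"] < threshold).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fdr = fdr_percent(threshold, S, T) if T and S else FDR_UNDEFINED
    return ScanResult(
        table=table, variant=variant, threshold=threshold,
        n_tests=T, n_significant=S, fdr=fdr,
    )


def variance_fraction(
    estimate: float,
    p: float,
    vc: VarianceComponents,
    kind: str = "additive",
) -> tuple[float, float]:
    """Marker variance and its percentage of phenotypic variance.

    sigma_a^2 = 2pq a^2 for an additive estimate, sigma_d^2 = 4 p^2 q^2 d^2
    for a dominance estimate; the denominator is the null-model phenotypic
    variance sigma_g^2 + sigma_pe^2 + sigma_e^2.
    """
    q = 1.0 - p
    if kind == "additive":
        sigma2 = 2.0 * p * q * estimate**2
    elif kind == "dominance":
        sigma2 = 4.0 * p**2 * q**2 * estimate**2
    else:
        raise ValueError(f"unknown variance kind: {kind!r}")
    return sigma2, 100.0 * sigma2 / vc.sigma_p2


def merge_regions(
    significant: pd.DataFrame, gap_bp: int = 1_000_000
) -> pd.DataFrame:
    """Single-linkage merge of significant markers within ``gap_bp``.

    Markers on the same chromosome closer than ``gap_bp`` join one region;
    boundaries are the min/max member positions and the top marker is the
    smallest p (ties to the smaller bp).  Returns one row per region:
    chrom, start_bp, end_bp, n_snps, snps, top_snp.
    """
    if significant.empty:
        raise ValueError("no significant markers to merge")
    out = []
    df = significant.sort_values(["chrom", "pos", "snp"], kind="stable")
    for chrom, grp in df.groupby("chrom", sort=False):
        start = None
        members: list[pd.Series] = []
        prev = None
        for _, row in grp.iterrows():
            if prev is not None and row["pos"] - prev > gap_bp:
                out.append(_region_row(chrom, members))
                members = []
            members.append(row)
            prev = row["pos"]
        if members:
            out.append(_region_row(chrom, members))
    return pd.DataFrame(out)


def _region_row(chrom, members) -> dict:
    tab = pd.DataFrame(members)
    top = tab.sort_values(["p", "pos"], kind="stable").iloc[0]
    return {
        "chrom": chrom,
        "start_bp": int(tab["pos"].min()),
        "end_bp": int(tab["pos"].max()),
        "n_snps": len(tab),
        "snps": ",".join(tab["snp"]),
        "top_snp": top["snp"],
    }


def write_manhattan(result: ScanResult, path: str | Path) -> None:
    """Plot-ready TSV (chrom, pos, snp, neglog10p, variant)."""
    cols = ["chrom", "pos", "snp", "neglog10p", "variant"]
    result.table[cols].to_csv(path, sep="\t", index=False)
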