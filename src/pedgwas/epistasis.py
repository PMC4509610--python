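"""Pairwise additive-by-additive screens and the LD-artifact re-test.

All unordered pairs among the markers with significant additive effects are
tested for an interaction term (product of the two allele-frequency-centred
additive contrasts) fitted jointly with both main effects; n markers give
n(n-1)/2 pairs.  A "significant" interaction can be an artifact of linkage
disequilibrium: when a strong, purely additive causal variant is tagged
imperfectly by several markers, two-marker haplotype combinations can track
the causal allele better than either marker alone and the product term
absorbs the difference.  The conditional re-scan adds the additive covariate
of a designated tag (the strongest peak in the implicated region) to every
pair model; interactions that vanish were proxies for that single effect.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel, code_additive, code_epistasis
from .mixed_model import MixedModelEngine, VarianceComponents
from .pedigree import RelationshipMatrix
from .scan import ScanResult, bonferroni_threshold

__all__ = [
    "n_pairs",
    "select_pairs",
    "test_pair",
    "scan_pairs",
    "conditional_rescan",
    "pairwise_threshold",
]


def n_pairs(n: int) -> int:
    """Number of unordered marker pairs, n(n-1)/2."""
    return n * (n - 1) // 2


def pairwise_threshold(
    alpha: float, n_sig: int, magnitude_rounding: bool = False
) -> float:
    """Bonferroni threshold for the n(n-1)/2 pairwise interaction tests."""
    return bonferroni_threshold(alpha, max(n_pairs(n_sig), 1), magnitude_rounding)


def select_pairs(
    additive_scan: ScanResult, threshold: float | None = None
) -> list[tuple[str, str]]:
    """All unordered pairs of additively significant markers, in map order."""
    if additive_scan.variant != "additive":
        raise ValueError("pair selection requires an additive scan")
    tab = additive_scan.table[additive_scan.table["flags"] == ""]
    thr = additive_scan.threshold if threshold is None else threshold
    sig = tab[tab["p"] < thr]["snp"].tolist()
    if len(sig) < 2:
        warnings.warn(
            f"only {len(sig)} significant marker(s): no pairs to test",
            stacklevel=2,
        )
        return []
    return [(sig[j], sig[k]) for j in range(len(sig)) for k in range(j + 1, len(sig))]


def _pair_covariates(
    panel: GenotypePanel,
    stats: pd.DataFrame,
    rec_row: np.ndarray,
    pair: tuple[str, str],
    conditioning: list[str] | None,
) -> dict[str, np.ndarray] | None:
    covs: dict[str, np.ndarray] = {}
    for tag, snp in zip(("a_j", "a_k"), pair):
        p = float(stats.loc[snp, "p"])
        if not 0.0 < p < 1.0:
            return None  # monomorphic member: not tested
        covs[tag] = code_additive(panel.snp_codes(snp)[rec_row], p)
    covs["a_jk"] = code_epistasis(covs["a_j"], covs["a_k"])
    for snp in conditioning or []:
        p = float(stats.loc[snp, "p"])
        if not 0.0 < p < 1.0:
            return None
        covs[f"cond_{snp}"] = code_additive(panel.snp_codes(snp)[rec_row], p)
    return covs


def test_pair(
    pair: tuple[str, str],
    panel: GenotypePanel,
    stats: pd.DataFrame,
    response: pd.DataFrame,
    vc: VarianceComponents,
    A: RelationshipMatrix | None,
    *,
    conditioning: list[str] | None = None,
    engine: MixedModelEngine | None = None,
):
    """Fit both main additive effects plus the product term; test a_jk.

    Optional ``conditioning`` markers contribute their additive covariates
    to the fixed part (the conditional re-test).  Collinear designs — e.g.
    a conditioning marker that is one of the pair, or a pair in complete
    LD — come back flagged not-testable.
    """
    j, k = pair
    if j == k:
        raise ValueError("a pair must consist of two distinct markers")
    if engine is None:
        engine = MixedModelEngine(response, A, vc)
    sub = panel.subset_animals(
        [a for a in dict.fromkeys(response["animal"].astype(str))]
    )
    rec_row = (
        response["animal"]
        .astype(str)
        .map({a: i for i, a in enumerate(sub.animal_ids)})
        .to_numpy()
    )
    covs = _pair_covariates(sub, stats, rec_row, pair, conditioning)
    if covs is None:
        from .mixed_model import NOT_TESTABLE, SnpTestResult

        return SnpTestResult(
            snp_ids=pair, effect_name="a_jk", estimate=np.nan, se=np.nan,
            p=np.nan, variant="epistasis", flags=NOT_TESTABLE + ":monomorphic",
        )
    return engine.test_effect(
        covs, "a_jk", variant="epistasis", snp_ids=pair
    )


def scan_pairs(
    pairs: list[tuple[str, str]],
    panel: GenotypePanel,
    stats: pd.DataFrame,
    response: pd.DataFrame,
    vc: VarianceComponents,
    A: RelationshipMatrix | None,
    *,
    conditioning: list[str] | None = None,
) -> pd.DataFrame:
    """Test every pair; returns snp_j,snp_k,est_int,se_int,p_int,flags."""
    engine = MixedModelEngine(response, A, vc)
    rows = []
    for pair in pairs:
        res = test_pair(
            pair, panel, stats, response, vc, A,
            conditioning=conditioning, engine=engine,
        )
        rows.append(
            {
                "snp_j": pair[0],
                "snp_k": pair[1],
                "est_int": res.estimate,
                "se_int": res.se,
                "p_int": res.p,
                "flags": res.flags,
            }
        )
    return pd.DataFrame(
        rows, columns=["snp_j", "snp_k", "est_int", "se_int", "p_int", "flags"]
    )


def conditional_rescan(
    significant_pairs: pd.DataFrame,
    tag_snp: str,
    panel: GenotypePanel,
    stats: pd.DataFrame,
    response: pd.DataFrame,
    vc: VarianceComponents,
    A: RelationshipMatrix | None,
    *,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Re-test significant pairs with the tag marker's additive effect added.

    Returns the before/after table (p_int, p_int_conditioned, flags and,
    when ``threshold`` is given, a still_significant column).  An empty
    input yields an empty table.
    """
    cols = [
        "snp_j", "snp_k", "est_int", "se_int", "p_int",
        "p_int_conditioned", "flags",
    ]
    if threshold is not None:
        cols.append("still_significant")
    if significant_pairs.empty:
        return pd.DataFrame(columns=cols)
    pairs = list(
        significant_pairs[["snp_j", "snp_k"]].itertuples(index=False, name=None)
    )
    after = scan_pairs(
        pairs, panel, stats, response, vc, A, conditioning=[tag_snp]
    )
    out = significant_pairs[["snp_j", "snp_k", "est_int", "se_int", "p_int"]].copy()
    out = out.reset_index(drop=True)
    out["p_int_conditioned"] = after["p_int"].to_numpy()
    out["flags"] = after["flags"].to_numpy()
    if threshold is not None:
        ok = out["flags"] == ""
        out["still_significant"] = ok & (out["p_int_conditioned"] < threshold)
    return out[cols]


def write_pairs(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
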