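"""Cross-population confirmation of discovery hits.

Markers significant in the discovery population are re-examined in an
independent validation population in two ways: *individually* (the same
marker must be significant at the validation threshold) and by *segment*
(any significant validation marker within a symmetric bp window, default
500 kb each side, counts — accommodating populations that tag the same
causal variant through different markers).  Effect-direction concordance is
recorded for individually validated markers, and each stage gets the
closed-form FDR.  Panels must share allele labelling (the same counted
allele per marker) for the sign comparison to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import FDR_UNDEFINED, ScanResult, fdr_percent

__all__ = ["ValidationReport", "validate_individual", "validate_segment"]


@dataclass
class ValidationReport:
    """Per-discovery-hit validation outcomes plus stage summary."""

    table: pd.DataFrame
    mode: str  # "individual" | "segment"
    v_threshold: float
    window_bp: int
    n_significant: int  # S of the validation stage
    n_tests: int  # T of the validation stage (definition depends on mode)
    fdr: float

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "v_threshold": self.v_threshold,
            "window_bp": self.window_bp,
            "S": self.n_significant,
            "T": self.n_tests,
            "fdr_percent": None if np.isnan(self.fdr) else self.fdr,
        }


def _stage_fdr(p: float, S: int, T: int) -> float:
    if T == 0 or S == 0 or not 0.0 < p < 1.0:
        return FDR_UNDEFINED
    return fdr_percent(p, S, T)


def validate_individual(
    discovery: ScanResult,
    validation: ScanResult,
    v_threshold: float,
) -> ValidationReport:
    """Marker-by-marker validation of discovery hits.

    A discovery hit validates when the same marker is testable in the
    validation scan with p below ``v_threshold``; direction concordance
    compares the signs of the two effect estimates.  ``T`` for the stage
    FDR is the number of discovery hits actually tested in the validation
    population; hits absent there are reported as not tested.
    """
    if discovery.variant != validation.variant:
        raise ValueError("discovery and validation scans test different effects")
    vtab = validation.table.set_index("snp")
    rows = []
    for _, hit in discovery.significant.iterrows():
        row = {
            "disc_snp": hit["snp"],
            "chrom": hit["chrom"],
            "pos": hit["pos"],
            "p_disc": hit["p"],
            "est_disc": hit["estimate"],
            "tested": False,
            "validated_ind": False,
            "same_dir": pd.NA,
            "p_valid": np.nan,
            "est_valid": np.nan,
        }
        if hit["snp"] in vtab.index and vtab.loc[hit["snp"], "flags"] == "":
            v = vtab.loc[hit["snp"]]
            row.update(tested=True, p_valid=v["p"], est_valid=v["estimate"])
            if v["p"] < v_threshold:
                row["validated_ind"] = True
                row["same_dir"] = bool(
                    np.sign(hit["estimate"]) == np.sign(v["estimate"])
                )
        rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=[
            "disc_snp", "chrom", "pos", "p_disc", "est_disc", "tested",
            "validated_ind", "same_dir", "p_valid", "est_valid",
        ],
    )
    S = int(table["validated_ind"].sum()) if len(table) else 0
    T = int(table["tested"].sum()) if len(table) else 0
    return ValidationReport(
        table=table, mode="individual", v_threshold=v_threshold, window_bp=0,
        n_significant=S, n_tests=T, fdr=_stage_fdr(v_threshold, S, T),
    )


def validate_segment(
    discovery: ScanResult,
    validation: ScanResult,
    v_threshold: float,
    window_bp: int = 500_000,
) -> ValidationReport:
    """Segment validation within +/- ``window_bp`` of each discovery hit.

    A hit is segment-validated when at least one testable validation marker
    on the same chromosome within the window (inclusive) has p below
    ``v_threshold``.  The stage ``S`` counts distinct significant validation
    markers falling in the union of windows (each once); ``T`` counts all
    distinct testable validation markers in that union.
    """
    if discovery.variant != validation.variant:
        raise ValueError("discovery and validation scans test different effects")
    vt = validation.table[validation.table["flags"] == ""]
    rows = []
    in_union: set[str] = set()
    sig_union: set[str] = set()
    for _, hit in discovery.significant.iterrows():
        near = vt[
            (vt["chrom"].astype(str) == str(hit["chrom"]))
            & ((vt["pos"] - hit["pos"]).abs() <= window_bp)
        ]
        in_union.update(near["snp"])
        sig = near[near["p"] < v_threshold]
        sig_union.update(sig["snp"])
        rows.append(
            {
                "disc_snp": hit["snp"],
                "chrom": hit["chrom"],
                "pos": hit["pos"],
                "p_disc": hit["p"],
                "est_disc": hit["estimate"],
                "validated_seg": len(sig) > 0,
                "match_snps": ",".join(sig["snp"]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "disc_snp", "chrom", "pos", "p_disc", "est_disc",
            "validated_seg", "match_snps",
        ],
    )
    S, T = len(sig_union), len(in_union)
    return ValidationReport(
        table=table, mode="segment", v_threshold=v_threshold,
        window_bp=window_bp, n_significant=S, n_tests=T,
        fdr=_stage_fdr(v_threshold, S, T),
    )
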