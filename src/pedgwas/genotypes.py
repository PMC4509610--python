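"""Genotype ingestion, allele statistics, class filtering, and model codings.

Genotypes are dosage codes 0/1/2 = aa/Aa/AA (copies of the A allele).
For a marker with A-allele frequency ``p`` (and ``q = 1 - p``) the scan
covariates are the allele-frequency-corrected contrasts

* additive:  aa -> -2p,   Aa -> q - p,  AA -> 2q
* dominance: aa -> -2p^2, Aa -> 2pq,   AA -> -2q^2

which are exactly mean-zero and mutually orthogonal under Hardy-Weinberg
genotype-class proportions (q^2, 2pq, p^2).  The pairwise additive-by-additive
epistasis covariate is the elementwise product of the two additive contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "GenotypeError",
    "DegenerateSnpError",
    "MISSING",
    "read_genotypes",
    "allele_stats",
    "filter_by_genotype_class",
    "code_additive",
    "code_dominance",
    "code_epistasis",
]

MISSING = -1  # sentinel for a missing genotype call


class GenotypeError(ValueError):
    """Malformed genotype input."""


class DegenerateSnpError(GenotypeError):
    """Monomorphic marker (p in {0, 1}) cannot be coded."""


def _chrom_key(label: str) -> tuple[int, str]:
    try:
        return (int(label), "")
    except ValueError:
        return (10**9, str(label))  # non-numeric labels (X, ...) sort last


@dataclass
class GenotypePanel:
    """Animals x SNPs dosage matrix plus map, sorted by (chromosome, bp)."""

    animal_ids: list[str]
    snps: pd.DataFrame  # columns: snp, chrom, pos
    codes: np.ndarray  # int8, shape (n_animals, n_snps), MISSING for no-call

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.animal_ids), len(self.snps)):
            raise GenotypeError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snps)} snps"
            )
        dup = self.snps["snp"][self.snps["snp"].duplicated()]
        if len(dup):
            raise GenotypeError(f"duplicate snp id: {dup.iloc[0]!r}")
        if (self.snps["pos"] <= 0).any():
            bad = self.snps.loc[self.snps["pos"] <= 0, "snp"].iloc[0]
            raise GenotypeError(f"non-positive bp position at snp {bad!r}")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid genotype code {self.codes[i, j]} for animal "
                f"{self.animal_ids[i]!r} at snp {self.snps['snp'].iloc[j]!r}"
            )
        # internal per-chromosome position sort (vectorized, stable)
        chroms = self.snps["chrom"].astype(str)
        numeric = pd.to_numeric(chroms, errors="coerce")
        chrom_num = numeric.fillna(10**9).to_numpy()
        chrom_str = np.where(numeric.isna(), chroms, "").astype(str)
        order = np.lexsort(
            (self.snps["pos"].to_numpy(), chrom_str, chrom_num)
        )
        if not np.array_equal(order, np.arange(len(self.snps))):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.codes = np.ascontiguousarray(self.codes[:, order])
        self._snp_index = {s: i for i, s in enumerate(self.snps["snp"])}

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_codes(self, snp: str) -> np.ndarray:
        return self.codes[:, self.snp_pos(snp)]

    def snp_pos(self, snp: str) -> int:
        try:
            return self._snp_index[snp]
        except KeyError:
            raise GenotypeError(f"unknown snp id: {snp!r}") from None

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            animal_ids=list(self.animal_ids),
            snps=self.snps.iloc[keep].reset_index(drop=True),
            codes=np.ascontiguousarray(self.codes[:, keep]),
        )

    def subset_animals(self, ids: list[str]) -> "GenotypePanel":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise GenotypeError(f"animals not in panel: {missing[:10]}")
        take = np.array([index[a] for a in ids])
        return GenotypePanel(
            animal_ids=list(ids),
            snps=self.snps.copy(),
            codes=np.ascontiguousarray(self.codes[take]),
        )

    def to_csv(self, matrix_path: str | Path, map_path: str | Path) -> None:
        self.snps.to_csv(map_path, index=False)
        out = pd.DataFrame(
            self.codes, index=pd.Index(self.animal_ids, name="animal"),
            columns=self.snps["snp"],
        )
        out.replace(MISSING, "NA").to_csv(matrix_path)


def read_genotypes(
    matrix_path: str | Path,
    map_path: str | Path,
    dialect: str = "csv",
) -> GenotypePanel:
    """Read a genotype matrix + map.

    ``dialect="csv"``: matrix CSV with first column ``animal`` then one
    column per SNP id (values 0/1/2 or NA); map CSV with columns
    ``snp,chrom,pos``.  ``dialect="plink-raw"``: whitespace ``.raw`` file
    (FID IID PAT MAT SEX PHENOTYPE then ``<snp>_<allele>`` columns of
    additive allele counts) with a 4-column headerless ``.map``
    (chrom, snp, cM, pos).
    """
    if dialect == "csv":
        snp_map = pd.read_csv(map_path, dtype={"snp": str, "chrom": str})
        mat = pd.read_csv(matrix_path, index_col=0)
        animals = [str(a) for a in mat.index]
        snp_ids = [str(c) for c in mat.columns]
    elif dialect == "plink-raw":
        snp_map = pd.read_csv(
            map_path, sep=r"\s+", header=None,
            names=["chrom", "snp", "cm", "pos"], dtype={"snp": str, "chrom": str},
        )[["snp", "chrom", "pos"]]
        raw = pd.read_csv(matrix_path, sep=r"\s+")
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        animals = [str(a) for a in raw["IID"]]
        mat = raw.drop(columns=[c for c in meta if c in raw.columns])
        # strip the _<counted allele> suffix PLINK appends to snp ids
        snp_ids = [c.rsplit("_", 1)[0] for c in mat.columns]
    else:
        raise GenotypeError(f"unknown genotype dialect: {dialect!r}")

    if set(snp_ids) != set(snp_map["snp"]):
        raise GenotypeError(
            "snp ids in matrix and map disagree "
            f"({len(snp_ids)} in matrix vs {len(snp_map)} in map)"
        )
    snp_map = snp_map.set_index("snp").loc[snp_ids].reset_index()
    values = mat.to_numpy()
    codes = np.full(values.shape, MISSING, dtype=np.int8)
    ok = pd.notna(pd.DataFrame(values)).to_numpy()
    vals = np.where(ok, values, 0).astype(float)
    if not np.isin(vals[ok], [0.0, 1.0, 2.0]).all():
        raise GenotypeError("genotype codes must be 0, 1, 2 or missing")
    codes[ok] = vals[ok].astype(np.int8)
    snp_map["pos"] = snp_map["pos"].astype(int)
    return GenotypePanel(animal_ids=animals, snps=snp_map, codes=codes)


def allele_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Per-SNP allele and genotype-class frequencies in one population.

    Returns a DataFrame indexed by snp id with columns ``p`` (A-allele
    frequency), ``q``, ``f_aa``, ``f_Aa``, ``f_AA``, ``maf``,
    ``min_class_freq`` and ``n_called``.  All-missing SNPs get NaN
    frequencies and are excluded downstream.
    """
    codes = panel.codes
    called = codes != MISSING
    n_called = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_aa = ((codes == 0) & called).sum(axis=0)
        n_het = (codes == 1).sum(axis=0)
        n_AA = (codes == 2).sum(axis=0)
        p = np.where(n_called > 0, (2 * n_AA + n_het) / (2 * n_called), np.nan)
        f = np.stack(
            [n_aa / n_called, n_het / n_called, n_AA / n_called], axis=1
        )
    stats = pd.DataFrame(
        {
            "p": p,
            "q": 1.0 - p,
            "f_aa": f[:, 0],
            "f_Aa": f[:, 1],
            "f_AA": f[:, 2],
            "maf": np.minimum(p, 1.0 - p),
            "min_class_freq": f.min(axis=1),
            "n_called": n_called.astype(int),
        },
        index=pd.Index(panel.snps["snp"], name="snp"),
    )
    return stats


def filter_by_genotype_class(
    panel: GenotypePanel,
    stats: pd.DataFrame | Mapping[str, pd.DataFrame],
    min_class_frequency: float = 0.01,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Drop SNPs whose rarest genotype class is below ``min_class_frequency``.

    Testing dominance (and epistasis) contrasts needs observations in all
    three genotype classes, so a SNP is removed when its minor genotype-class
    frequency falls below the threshold in *any* of the supplied populations
    (pass a mapping of population name -> allele_stats frame to filter
    jointly, e.g. discovery and validation).  All-missing SNPs are removed.
    Returns the filtered panel and a per-SNP report.
    """
    if not 0 < min_class_frequency <= 1 / 3:
        raise GenotypeError("min_class_frequency must be in (0, 1/3]")
    stats_map = stats if isinstance(stats, Mapping) else {"all": stats}
    snp_ids = panel.snps["snp"]
    removed = np.zeros(panel.n_snps, dtype=bool)
    rows = []
    for pop, st in stats_map.items():
        st = st.loc[snp_ids]
        mcf = st["min_class_freq"].to_numpy()
        fail = ~(mcf >= min_class_frequency)  # NaN (all-missing) also fails
        removed |= fail
        rows.append(
            pd.DataFrame(
                {
                    "snp": snp_ids.to_numpy(),
                    "population": pop,
                    "minor_class_freq": mcf,
                    "removed_flag": fail,
                }
            )
        )
    report = pd.concat(rows, ignore_index=True)
    if removed.all():
        raise GenotypeError("no SNP survives the genotype-class filter")
    return panel.subset_snps(~removed), report


def _code(codes: np.ndarray, p: float, mapping: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    if not 0.0 < p < 1.0:
        raise DegenerateSnpError(f"monomorphic marker (p = {p}) cannot be coded")
    out = np.where(codes == MISSING, 0.0, mapping[np.clip(codes, 0, 2)])
    miss = codes == MISSING
    if miss.any():
        if miss.all():
            raise DegenerateSnpError("all genotype calls missing")
        # mean-impute on the coded scale: missing animals carry no information
        out[miss] = out[~miss].mean()
    return out


def code_additive(codes: np.ndarray, p: float) -> np.ndarray:
    """Additive contrast: 0 -> -2p, 1 -> q - p, 2 -> 2q."""
    q = 1.0 - p
    return _code(codes, p, np.array([-2 * p, q - p, 2 * q]))


def code_dominance(codes: np.ndarray, p: float) -> np.ndarray:
    """Dominance contrast: 0 -> -2p^2, 1 -> 2pq, 2 -> -2q^2."""
    q = 1.0 - p
    return _code(codes, p, np.array([-2 * p**2, 2 * p * q, -2 * q**2]))


def code_epistasis(xa_j: np.ndarray, xa_k: np.ndarray) -> np.ndarray:
    """Pairwise additive-by-additive covariate: elementwise product.

    Note the hazard documented with the scan: for two markers in complete
    LD at p = 0.5 this product equals the square of the additive contrast
    and is collinear with the dominance contrast.
    """
    xa_j = np.asarray(xa_j, dtype=float)
    xa_k = np.asarray(xa_k, dtype=float)
    if xa_j.shape != xa_k.shape:
        raise GenotypeError("epistasis covariates must have equal length")
    return xa_j * xa_k
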