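"""Synthetic herd generator with known genetic architecture.

Emulates the data structure of a pedigreed dairy-cattle association study:
multi-generation pedigrees with discrete generations and random matings;
LD-structured SNP genotypes obtained by dropping founder haplotypes (mosaics
of a few ancestral templates, so correlation decays with map distance)
through the pedigree with recombination; and repeated phenotype records
built from herd-year-season / parity / age-class / month fixed effects,
configured additive, dominance and pairwise additive-by-additive causal
marker effects, a pedigree polygenic term, cow-level permanent-environment
effects and record-level noise.

An optional *hidden causal variant* block places a strong, purely additive
causal allele off the genotyping panel and engineers nearby panel markers to
tag it at prescribed r-squared values — the scenario in which imperfect
tagging of a single large effect (a DGAT1-like variant) generates spurious
pairwise interactions among its tags.

Every run emits a truth ledger (true effects, realized variance components,
realized tag r-squared, true breeding values) for parameter-recovery tests.
Defaults are the desk-scale preset: ~2,000 phenotyped cows with 1-4 records
each and 5,000 SNPs on 5 chromosomes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypePanel, code_additive, code_dominance
from .pedigree import Pedigree, build_A

__all__ = [
    "HiddenCausalConfig",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "simulate_population_pair",
    "write_dataset",
]


@dataclass
class HiddenCausalConfig:
    """A strong additive causal variant kept off the genotyping panel.

    ``variance_fraction`` sizes the additive effect so the variant explains
    that share of phenotypic variance (given its realized frequency); the
    ``n_tags`` panel markers nearest to it are rebuilt to tag it at the
    ``r2_targets`` (within ``r2_tolerance``, by resampling up to
    ``max_retries`` times).  The LD structure is nested, as for a recent
    mutation that arose on a single haplotype background: the best tag (the
    *hub*, largest target) is a noisy copy of the causal allele, and every
    other tag is a noisy copy of the hub, so their information about the
    causal variant flows through the hub.  The default frequency 0.2 is
    typical of a large-effect allele under recent selection; it also keeps
    the three-locus haplotype moment that drives spurious pairwise
    interactions away from its sign change at frequency 1/2.
    """

    chrom: str = "1"
    pos: int = 25_000_000
    freq: float = 0.2
    variance_fraction: float = 0.04
    n_tags: int = 10
    r2_targets: tuple[float, ...] = (0.9,) + tuple(
        float(x) for x in np.round(np.linspace(0.3, 0.7, 9), 3)
    )
    r2_tolerance: float = 0.1
    max_retries: int = 400


@dataclass
class SimulationConfig:
    """All knobs of one simulated population; fixed seed => identical output."""

    seed: int = 0
    # pedigree: discrete generations, random sire/dam per offspring
    n_founders: int = 200
    n_generations: int = 3
    n_offspring_per_generation: int = 1400
    n_cows: int | None = 2000  # phenotyped (non-founder) females; None = all
    # genome & haplotypes
    n_snps: int = 5000
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    n_founder_haplotypes: int = 30
    n_ancestral_haplotypes: int = 4
    mosaic_block_bp: float = 2_000_000.0
    mutation_rate: float = 0.02
    recomb_rate_per_bp: float = 1e-8  # ~1 cM/Mb
    # causal architecture (panel indices refer to map order)
    causal_additive: tuple[tuple[int, float, float], ...] = ()  # (snp_idx, a, d)
    causal_pairs: tuple[tuple[tuple[int, int], float], ...] = ()  # ((j,k), aa)
    hidden_causal: HiddenCausalConfig | None = None
    # variance targets (default: high-heritability, milk-yield-like trait)
    sigma_g2: float = 0.3
    sigma_pe2: float = 0.1
    sigma_e2: float = 0.6
    # records & fixed effects
    records_min: int = 1
    records_max: int = 4
    mu: float = 0.0
    n_hys: int = 25
    n_parity: int = 4
    n_age_classes: int = 5
    n_months: int = 12
    fixed_effect_sd: float = 0.5
    id_prefix: str = "A"  # animal ids: <prefix>1, <prefix>2, ...

    @classmethod
    def low_heritability(cls, **overrides) -> "SimulationConfig":
        """Fertility-like preset: h2 ~ 0.04 with a sizeable pe component."""
        base = dict(sigma_g2=0.04, sigma_pe2=0.16, sigma_e2=0.80)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        hidden = raw.pop("hidden_causal", None)
        cfg = cls(**_tuplify(raw))
        if hidden is not None:
            cfg.hidden_causal = HiddenCausalConfig(**_tuplify(hidden))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d))


def _tuplify(d: dict) -> dict:
    return {
        k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
        if isinstance(v, list)
        else v
        for k, v in d.items()
    }


@dataclass
class SimulationTruth:
    """Ledger of what was planted and what was realized."""

    causal_effects: list[dict]  # per locus: snp, a, d (+pairs as aa entries)
    hidden_causal: dict | None
    variance_targets: dict
    realized_components: dict  # empirical variances of u, pe, e, fixed, causal
    true_breeding_values: dict[str, float]
    realized_heritability: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    sexes: dict[str, str]
    panel: GenotypePanel  # phenotyped cows only
    phenotypes: pd.DataFrame  # animal,value,hys,parity,age_class,month
    truth: SimulationTruth
    hidden_codes: np.ndarray | None = None  # causal dosages of panel animals


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Pedigree, dict[str, str]]:
    """Discrete generations; each offspring gets a random sire and dam."""
    if config.n_founders < 2 or config.n_generations < 1:
        raise ValueError("need >= 2 founders and >= 1 generation")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    records: list[tuple[str, str | None, str | None]] = []
    sexes: dict[str, str] = {}
    counter = 0

    def new_ids(k: int) -> list[str]:
        nonlocal counter
        ids = [f"{config.id_prefix}{counter + i + 1}" for i in range(k)]
        counter += k
        return ids

    def assign_sex(ids: list[str]) -> None:
        sex = np.array(["M"] * (len(ids) // 2) + ["F"] * (len(ids) - len(ids) // 2))
        rng.shuffle(sex)
        for a, s in zip(ids, sex):
            sexes[a] = s

    founders = new_ids(config.n_founders)
    assign_sex(founders)
    records += [(a, None, None) for a in founders]
    prev = founders
    for _ in range(config.n_generations):
        males = [a for a in prev if sexes[a] == "M"]
        females = [a for a in prev if sexes[a] == "F"]
        if not males or not females:
            raise ValueError("a generation lacks one sex; cannot mate")
        offspring = new_ids(config.n_offspring_per_generation)
        assign_sex(offspring)
        sires = rng.choice(males, size=len(offspring))
        dams = rng.choice(females, size=len(offspring))
        records += [(a, s, d) for a, s, d in zip(offspring, sires, dams)]
        prev = offspring
    return Pedigree.from_records(records), sexes


# ---------------------------------------------------------------------------
# genotypes


def _make_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per[: config.n_snps % config.n_chromosomes] += 1
    rows = []
    k = 0
    for c in range(config.n_chromosomes):
        pos = np.array([], dtype=np.int64)
        while len(pos) < per[c]:
            draw = rng.integers(1, config.chrom_length_bp, size=2 * per[c])
            pos = np.unique(np.concatenate([pos, draw]))
        pos = np.sort(rng.choice(pos, size=per[c], replace=False))
        for pp in pos:
            k += 1
            rows.append({"snp": f"snp{k}", "chrom": str(c + 1), "pos": int(pp)})
    return pd.DataFrame(rows)


def _mosaic_pool(
    snp_map: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Founder haplotype pool: mosaics of a few ancestral templates."""
    L = len(snp_map)
    freq = rng.uniform(0.08, 0.92, size=L)
    anc = (
        rng.random((config.n_ancestral_haplotypes, L)) < freq
    ).astype(np.int8)
    pool = np.empty((config.n_founder_haplotypes, L), dtype=np.int8)
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    gap = np.diff(pos).astype(float)
    new_chrom = chrom[1:] != chrom[:-1]
    p_switch = np.where(new_chrom, 1.0, 1.0 - np.exp(-gap / config.mosaic_block_bp))
    for h in range(config.n_founder_haplotypes):
        switches = np.concatenate(([True], rng.random(L - 1) < p_switch))
        seg = np.cumsum(switches) - 1
        templates = rng.integers(0, config.n_ancestral_haplotypes, size=seg[-1] + 1)
        hap = anc[templates[seg], np.arange(L)]
        flip = rng.random(L) < config.mutation_rate
        pool[h] = np.where(flip, 1 - hap, hap)
    return pool


def _drop_origins(
    ped: Pedigree,
    snp_map: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    founder_pool_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Gene-drop pool-haplotype origins through the pedigree.

    Returns int8 origins of shape (n_animals, 2, L): which pool haplotype
    each animal's maternal/paternal haplotype copies at each locus.
    Founders carry a single pool haplotype per gamete; descendants carry
    recombinant mosaics of their parents' origins.
    """
    ids = ped.ids
    idx = {a: i for i, a in enumerate(ids)}
    L = len(snp_map)
    n = len(ids)
    if config.n_founder_haplotypes > 120:
        raise ValueError("founder haplotype pool too large for int8 origins")
    origins = np.empty((n, 2, L), dtype=np.int8)
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    chrom_bounds = [0] + list(np.flatnonzero(chrom[1:] != chrom[:-1]) + 1) + [L]
    spans = list(zip(chrom_bounds[:-1], chrom_bounds[1:]))
    rate = config.recomb_rate_per_bp
    for i, (animal, sire, dam) in enumerate(ped.records):
        for g, parent in enumerate((sire, dam)):
            if parent is None:
                if founder_pool_ids is not None:
                    origins[i, g, :] = founder_pool_ids[i, g]
                else:
                    origins[i, g, :] = rng.integers(
                        0, config.n_founder_haplotypes
                    )
                continue
            ph = origins[idx[parent]]
            for lo, hi in spans:
                span_pos = pos[lo:hi]
                length = int(span_pos[-1] - span_pos[0] + 1)
                k = rng.poisson(rate * length)
                phase = rng.integers(0, 2)
                if k == 0:
                    src = np.full(hi - lo, phase)
                else:
                    cx = np.sort(rng.integers(span_pos[0], span_pos[-1] + 1, size=k))
                    src = (phase + np.searchsorted(cx, span_pos, side="right")) % 2
                origins[i, g, lo:hi] = np.where(
                    src == 0, ph[0, lo:hi], ph[1, lo:hi]
                )
    return origins


def _solve_flip_rate(p_causal: float, r2: float) -> float:
    """Flip probability eps so that XOR-noised copies hit target r^2."""

    def r2_of(eps: float) -> float:
        pt = p_causal * (1 - eps) + (1 - p_causal) * eps
        cov = p_causal * (1 - eps) - p_causal * pt
        denom = p_causal * (1 - p_causal) * pt * (1 - pt)
        return cov**2 / denom if denom > 0 else 0.0

    lo, hi = 0.0, 0.5
    for _ in range(80):
        mid = (lo + hi) / 2
        if r2_of(mid) > r2:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_genotypes(
    ped: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    panel_animals: list[str] | None = None,
    pool: np.ndarray | None = None,
    snp_map: pd.DataFrame | None = None,
) -> tuple[GenotypePanel, dict]:
    """LD-structured genotypes for ``panel_animals`` (default: all animals).

    Returns the panel plus a partial truth dict with the hidden-causal
    dosages and realized tag r-squared (empty when no hidden causal is
    configured).  ``pool``/``snp_map`` allow sharing haplotype structure
    across populations.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if snp_map is None:
        snp_map = _make_map(config, rng)
    snp_map = snp_map.copy()
    hidden = config.hidden_causal
    causal_col = None
    if hidden is not None:
        causal_row = pd.DataFrame(
            [{"snp": "__causal__", "chrom": str(hidden.chrom), "pos": int(hidden.pos)}]
        )
        full_map = (
            pd.concat([snp_map, causal_row], ignore_index=True)
            .sort_values(["chrom", "pos"], key=_sort_key, kind="stable")
            .reset_index(drop=True)
        )
        causal_col = int(np.flatnonzero(full_map["snp"] == "__causal__")[0])
    else:
        full_map = snp_map
    if pool is None:
        pool = _mosaic_pool(full_map, config, rng)
    pool = pool.copy()

    truth: dict = {}
    if hidden is not None:
        # exact carrier count keeps the realized frequency on target
        K = config.n_founder_haplotypes
        n_car = max(1, round(hidden.freq * K))
        carriers = rng.choice(K, size=n_car, replace=False)
        col = np.zeros(K, dtype=np.int8)
        col[carriers] = 1
        pool[:, causal_col] = col

    origins = _drop_origins(ped, full_map, config, rng)
    ids = ped.ids
    if panel_animals is None:
        panel_animals = list(ids)
    id_index = {a: i for i, a in enumerate(ids)}
    take = np.array([id_index[a] for a in panel_animals])
    sub_origins = origins[take]  # (na, 2, L)

    def genotypes_at(col: int) -> np.ndarray:
        al = pool[:, col]
        return (al[sub_origins[:, 0, col]] + al[sub_origins[:, 1, col]]).astype(
            np.int8
        )

    if hidden is not None:
        causal_codes = genotypes_at(causal_col)
        if causal_codes.std() == 0:
            raise ValueError("hidden causal variant is monomorphic; reseed")
        # engineer the nearest panel markers to tag the causal variant
        same_chrom = (full_map["chrom"] == str(hidden.chrom)).to_numpy()
        dist = np.abs(full_map["pos"].to_numpy() - int(hidden.pos)).astype(float)
        dist[~same_chrom] = np.inf
        dist[causal_col] = np.inf
        tag_cols = np.argsort(dist)[: hidden.n_tags]
        targets = list(hidden.r2_targets[: len(tag_cols)])
        hub_slot = int(np.argmax(targets))
        # nested carrier sets: the mutation arose on the haplotypes in C;
        # the hub marks a slightly larger ancestral set H containing C, and
        # every other tag marks a set containing H.  Tag alleles are then
        # conditionally independent of the causal allele given the hub, and
        # two-tag allele combinations localize H better than single tags —
        # the haplotype-LD configuration that breeds spurious interactions.
        order = [hub_slot] + [i for i in range(len(targets)) if i != hub_slot]
        realized = [0.0] * len(targets)
        tags = [""] * len(targets)
        K = config.n_founder_haplotypes
        causal_set = np.flatnonzero(pool[:, causal_col] == 1)
        p_c = len(causal_set) / K
        hub_set = None

        def nested_size(r2_target: float) -> float:
            # for nested sets C subset T: r2 = p_c (1 - p_t) / (q_c p_t)
            return K * p_c / (r2_target * (1 - p_c) + p_c)

        def engineer(col, base_set, r2_target, snp_name):
            best = None
            want = nested_size(r2_target)
            outside = np.setdiff1d(np.arange(K), base_set)
            for trial in range(hidden.max_retries):
                size = int(np.floor(want) if trial % 2 else np.ceil(want))
                n_extra = max(size - len(base_set), 0)
                extra = rng.choice(
                    outside, size=min(n_extra, len(outside)), replace=False
                )
                members = np.concatenate([base_set, extra])
                alleles = np.zeros(K, dtype=np.int8)
                alleles[members] = 1
                g = (
                    alleles[sub_origins[:, 0, col]]
                    + alleles[sub_origins[:, 1, col]]
                ).astype(np.int8)
                if g.std() == 0:
                    continue
                r2 = float(np.corrcoef(g, causal_codes)[0, 1] ** 2)
                err = abs(r2 - r2_target)
                if best is None or err < best[0]:
                    best = (err, alleles, r2, members)
                if err <= hidden.r2_tolerance / 3:
                    break
            if best is None or best[0] > hidden.r2_tolerance:
                achieved = best[2] if best else float("nan")
                raise ValueError(
                    f"could not reach r2 target {r2_target} for tag "
                    f"{snp_name!r} (achieved {achieved:.3f})"
                )
            return best

        for slot in order:
            col = tag_cols[slot]
            name = str(full_map["snp"].iloc[col])
            base = causal_set if slot == hub_slot else hub_set
            _, alleles, r2, members = engineer(col, base, targets[slot], name)
            if slot == hub_slot:
                hub_set = members
            pool[:, col] = alleles
            realized[slot] = r2
            tags[slot] = name
        truth["hidden_causal"] = {
            "chrom": str(hidden.chrom),
            "pos": int(hidden.pos),
            "freq_target": hidden.freq,
            "freq_realized": float(causal_codes.mean() / 2),
            "tags": tags,
            "hub_tag": tags[hub_slot],
            "r2_targets": targets,
            "r2_realized": realized,
        }
        truth["_causal_codes"] = causal_codes

    panel_cols = np.flatnonzero(full_map["snp"] != "__causal__")
    codes = np.empty((len(panel_animals), len(panel_cols)), dtype=np.int8)
    for out_j, col in enumerate(panel_cols):
        codes[:, out_j] = genotypes_at(col)
    panel = GenotypePanel(
        animal_ids=list(panel_animals),
        snps=full_map.iloc[panel_cols][["snp", "chrom", "pos"]].reset_index(
            drop=True
        ),
        codes=codes,
    )
    truth["_pool"] = pool
    truth["_map"] = snp_map
    return panel, truth


def _sort_key(s: pd.Series) -> pd.Series:
    if s.name == "chrom":
        return s.map(lambda v: int(v) if str(v).isdigit() else 10**9)
    return s


# ---------------------------------------------------------------------------
# phenotypes


def _coded_or_zero(codes: np.ndarray, coder) -> np.ndarray:
    p = float(codes.mean() / 2)
    if not 0.0 < p < 1.0:
        return np.zeros(len(codes))
    return coder(codes, p)


def simulate_phenotypes(
    ped: Pedigree,
    panel: GenotypePanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    sexes: dict[str, str] | None = None,
    hidden_codes: np.ndarray | None = None,
    hidden_truth: dict | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Repeated records for the panel animals with the configured architecture."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    cows = list(panel.animal_ids)
    nc = len(cows)

    # marker genetic values (animal level), using realized frequencies
    gen = np.zeros(nc)
    add_gen = np.zeros(nc)
    causal_entries = []
    for snp_idx, a, d in config.causal_additive:
        codes = panel.codes[:, snp_idx]
        xa = _coded_or_zero(codes, code_additive)
        xd = _coded_or_zero(codes, code_dominance)
        gen += a * xa + d * xd
        add_gen += a * xa
        causal_entries.append(
            {"snp": panel.snps["snp"].iloc[snp_idx], "a": a, "d": d}
        )
    for (j, k), aa in config.causal_pairs:
        xa_j = _coded_or_zero(panel.codes[:, j], code_additive)
        xa_k = _coded_or_zero(panel.codes[:, k], code_additive)
        gen += aa * xa_j * xa_k
        causal_entries.append(
            {
                "snp": f"{panel.snps['snp'].iloc[j]}x{panel.snps['snp'].iloc[k]}",
                "aa": aa,
            }
        )
    hidden_entry = None
    if hidden_codes is not None:
        hc = config.hidden_causal
        xa = _coded_or_zero(hidden_codes, code_additive)
        p = float(hidden_codes.mean() / 2)
        sigma_p2 = config.sigma_g2 + config.sigma_pe2 + config.sigma_e2
        a_h = float(
            np.sqrt(hc.variance_fraction * sigma_p2 / (2 * p * (1 - p)))
        )
        gen += a_h * xa
        add_gen += a_h * xa
        hidden_entry = dict(hidden_truth or {})
        hidden_entry.update(
            additive_effect=a_h, variance_fraction=hc.variance_fraction
        )

    # polygenic breeding values via the pedigree relationship matrix
    if config.sigma_g2 > 0:
        A = build_A(ped)
        chol = np.linalg.cholesky(
            A.values + 1e-10 * np.eye(len(A.ids))
        )
        u_all = chol @ rng.normal(0.0, np.sqrt(config.sigma_g2), size=len(A.ids))
        aidx = {a: i for i, a in enumerate(A.ids)}
        u = np.array([u_all[aidx[a]] for a in cows])
    else:
        u = np.zeros(nc)

    pe = rng.normal(0.0, np.sqrt(config.sigma_pe2), size=nc)
    n_rec = rng.integers(config.records_min, config.records_max + 1, size=nc)

    effects = {
        "hys": rng.normal(0, config.fixed_effect_sd, config.n_hys),
        "parity": rng.normal(0, config.fixed_effect_sd, config.n_parity),
        "age_class": rng.normal(0, config.fixed_effect_sd, config.n_age_classes),
        "month": rng.normal(0, config.fixed_effect_sd, config.n_months),
    }
    levels = {
        "hys": [f"h{i}" for i in range(config.n_hys)],
        "parity": [str(i + 1) for i in range(config.n_parity)],
        "age_class": [f"age{i}" for i in range(config.n_age_classes)],
        "month": [str(i + 1) for i in range(config.n_months)],
    }
    rows = []
    resid_all = []
    fixed_all = []
    for i, cow in enumerate(cows):
        for _ in range(n_rec[i]):
            lev = {
                f: int(rng.integers(0, len(levels[f]))) for f in effects
            }
            fixed = sum(effects[f][lev[f]] for f in effects)
            e = rng.normal(0.0, np.sqrt(config.sigma_e2))
            value = config.mu + fixed + gen[i] + u[i] + pe[i] + e
            rows.append(
                {
                    "animal": cow,
                    "value": value,
                    **{f: levels[f][lev[f]] for f in effects},
                }
            )
            resid_all.append(e)
            fixed_all.append(fixed)
    table = pd.DataFrame(rows)[["animal", "value", "hys", "parity", "age_class", "month"]]

    tbv = add_gen + u
    var_g = float(np.var(u))
    var_sig = float(np.var(gen + u))
    var_pe = float(np.var(np.repeat(pe, n_rec)))
    var_e = float(np.var(resid_all))
    realized = {
        "var_polygenic": var_g,
        "var_genetic_total": var_sig,
        "var_pe": var_pe,
        "var_e": var_e,
        "var_fixed": float(np.var(fixed_all)),
        "mean_records_per_cow": float(np.mean(n_rec)),
    }
    denom = var_sig + var_pe + var_e
    truth = SimulationTruth(
        causal_effects=causal_entries,
        hidden_causal=hidden_entry,
        variance_targets={
            "sigma_g2": config.sigma_g2,
            "sigma_pe2": config.sigma_pe2,
            "sigma_e2": config.sigma_e2,
        },
        realized_components=realized,
        true_breeding_values={a: float(v) for a, v in zip(cows, tbv)},
        realized_heritability=var_sig / denom if denom > 0 else 0.0,
    )
    return table, truth


# ---------------------------------------------------------------------------
# one-call dataset + two-population mode


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Pedigree + genotypes + phenotypes + truth in one deterministic call."""
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    ped_rng, gen_rng, phe_rng = (np.random.default_rng(s) for s in seeds)
    ped, sexes = simulate_pedigree(config, ped_rng)
    founders = {a for a, s, d in ped.records if s is None and d is None}
    cows = [a for a in ped.ids if sexes[a] == "F" and a not in founders]
    if config.n_cows is not None:
        if config.n_cows > len(cows):
            raise ValueError(
                f"requested {config.n_cows} cows but only {len(cows)} "
                "non-founder females exist"
            )
        order = {a: i for i, a in enumerate(ped.ids)}
        cows = sorted(
            ped_rng.choice(cows, size=config.n_cows, replace=False).tolist(),
            key=order.get,
        )
    panel, gtruth = simulate_genotypes(ped, config, gen_rng, panel_animals=cows)
    hidden_codes = gtruth.pop("_causal_codes", None)
    phen, truth = simulate_phenotypes(
        ped, panel, config, phe_rng, sexes=sexes,
        hidden_codes=hidden_codes, hidden_truth=gtruth.get("hidden_causal"),
    )
    return SimulatedDataset(
        pedigree=ped, sexes=sexes, panel=panel, phenotypes=phen,
        truth=truth, hidden_codes=hidden_codes,
    )


def simulate_population_pair(
    config_a: SimulationConfig,
    config_b: SimulationConfig | None = None,
    *,
    pool_overlap: float = 0.5,
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Two "breeds" with partially shared founder haplotype pools.

    Both populations share the SNP map and ancestral LD structure; a
    fraction ``pool_overlap`` of the second pool's haplotypes is copied
    from the first, so some causal variants segregate in both populations
    and some in only one.  The hidden-causal block (when configured on
    ``config_a``) is carried to the shared structure.
    """
    if config_b is None:
        config_b = dataclasses.replace(
            config_a, seed=config_a.seed + 104729, id_prefix="B"
        )
    seeds_a = np.random.SeedSequence(config_a.seed).spawn(3)
    seeds_b = np.random.SeedSequence(config_b.seed).spawn(3)
    rng_a = [np.random.default_rng(s) for s in seeds_a]
    rng_b = [np.random.default_rng(s) for s in seeds_b]

    shared_rng = np.random.default_rng(
        np.random.SeedSequence((config_a.seed, 7919)).generate_state(1)[0]
    )
    snp_map = _make_map(config_a, shared_rng)
    base_map = snp_map
    hidden = config_a.hidden_causal
    if hidden is not None:
        causal_row = pd.DataFrame(
            [{"snp": "__causal__", "chrom": str(hidden.chrom), "pos": int(hidden.pos)}]
        )
        full_map = (
            pd.concat([snp_map, causal_row], ignore_index=True)
            .sort_values(["chrom", "pos"], key=_sort_key, kind="stable")
            .reset_index(drop=True)
        )
    else:
        full_map = snp_map
    pool_a = _mosaic_pool(full_map, config_a, shared_rng)
    n_shared = int(round(pool_overlap * config_b.n_founder_haplotypes))
    pool_b = _mosaic_pool(full_map, config_b, shared_rng)
    if n_shared > 0:
        pick = shared_rng.choice(
            config_a.n_founder_haplotypes, size=n_shared, replace=False
        )
        pool_b[:n_shared] = pool_a[pick]

    out = []
    for cfg, rngs, pool in ((config_a, rng_a, pool_a), (config_b, rng_b, pool_b)):
        ped, sexes = simulate_pedigree(cfg, rngs[0])
        founders = {a for a, s, d in ped.records if s is None and d is None}
        cows = [a for a in ped.ids if sexes[a] == "F" and a not in founders]
        if cfg.n_cows is not None:
            if cfg.n_cows > len(cows):
                raise ValueError("not enough non-founder females")
            order = {a: i for i, a in enumerate(ped.ids)}
            cows = sorted(
                rngs[0].choice(cows, size=cfg.n_cows, replace=False).tolist(),
                key=order.get,
            )
        panel, gtruth = simulate_genotypes(
            ped, cfg, rngs[1], panel_animals=cows, pool=pool, snp_map=base_map
        )
        hidden_codes = gtruth.pop("_causal_codes", None)
        phen, truth = simulate_phenotypes(
            ped, panel, cfg, rngs[2], sexes=sexes,
            hidden_codes=hidden_codes,
            hidden_truth=gtruth.get("hidden_causal"),
        )
        out.append(
            SimulatedDataset(
                pedigree=ped, sexes=sexes, panel=panel, phenotypes=phen,
                truth=truth, hidden_codes=hidden_codes,
            )
        )
    return out[0], out[1]


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write the same files the pipeline readers consume, plus the ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (a, s if s is not None else "0", d if d is not None else "0")
            for a, s, d in ds.pedigree.records
        ],
        columns=["animal", "sire", "dam"],
    ).to_csv(outdir / "pedigree.csv", index=False)
    ds.panel.to_csv(outdir / "genotypes.csv", outdir / "map.csv")
    ds.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    ds.truth.to_json(outdir / "truth.json")
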