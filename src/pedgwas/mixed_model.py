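"""Mixed linear model engine for single-marker association tests.

The scan model for record ``i`` of cow ``c`` is

    y = 1*mu + X b + Z u + W pe + e,
    u ~ N(0, A*sigma_g^2),  pe ~ N(0, I*sigma_pe^2),  e ~ N(0, I*sigma_e^2)

with ``A`` the pedigree numerator relationship matrix, ``u`` the polygenic
breeding values, ``pe`` cow-level permanent-environment effects shared by a
cow's repeated records, and ``X b`` the marker covariates under test
(additive; additive + dominance; or the two additive terms plus their
product for pairwise epistasis).

Variance components are estimated by average-information REML with an EM
fallback on the SNP-free null model; marker effects are then generalized
least squares solutions of Henderson's mixed-model equations.  Because ``u``
and ``pe`` share the record-to-cow incidence ``Z``, the two random terms are
absorbed jointly through the cow-level coefficient matrix
``M = Z'Z + sigma_e^2 * (A*sigma_g^2 + I*sigma_pe^2)^{-1}``, so each marker
fit costs two cheap aggregations and a small solve.  The explicit inverse of
the record-level covariance ``V`` appears only in test oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .pedigree import RelationshipMatrix

__all__ = [
    "VarianceComponents",
    "SnpTestResult",
    "MixedModelEngine",
    "RemlError",
    "reml",
    "reml_null",
    "fit_snp",
]

NOT_TESTABLE = "not-testable"


class RemlError(RuntimeError):
    """REML failed to converge."""


@dataclass
class VarianceComponents:
    """REML variance components of the SNP-free null model."""

    sigma_g2: float
    sigma_pe2: float
    sigma_e2: float
    loglik: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    ai_singular: bool = False

    @property
    def sigma_p2(self) -> float:
        """Phenotypic variance sigma_g^2 + sigma_pe^2 + sigma_e^2."""
        return self.sigma_g2 + self.sigma_pe2 + self.sigma_e2

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / self.sigma_p2


@dataclass
class SnpTestResult:
    """Effect estimate, SE and Wald-F p-value for one tested marker effect."""

    snp_ids: tuple[str, ...]
    effect_name: str  # "a_j", "d_j" or "a_jk"
    estimate: float
    se: float
    p: float
    maf: float = float("nan")
    variant: str = "additive"
    flags: str = ""
    coefficients: dict = field(default_factory=dict, repr=False)

    @property
    def testable(self) -> bool:
        return NOT_TESTABLE not in self.flags

    @property
    def neglog10p(self) -> float:
        return -np.log10(self.p) if self.p > 0 else np.inf


def _prepare(response: pd.DataFrame, A: RelationshipMatrix | None):
    """Map records to a 0..m-1 animal index and the matching A block."""
    animals = list(dict.fromkeys(response["animal"].astype(str)))
    index = {a: i for i, a in enumerate(animals)}
    idx = response["animal"].astype(str).map(index).to_numpy()
    y = response["residual"].to_numpy(dtype=float)
    if A is None:
        Ab = np.eye(len(animals))
    else:
        Ab = A.subset(animals).values
    return y, idx, animals, Ab


class MixedModelEngine:
    """Per-marker GLS solver with the random effects absorbed once.

    Parameters
    ----------
    response : DataFrame with columns ``animal`` and ``residual`` (one row
        per record, pre-corrected response).
    A : RelationshipMatrix covering all animals with records (``None`` for
        unrelated animals, A = I).
    vc : VarianceComponents from the null model; ``sigma_e2`` must be > 0.
    """

    def __init__(
        self,
        response: pd.DataFrame,
        A: RelationshipMatrix | None,
        vc: VarianceComponents,
    ):
        if vc.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive to solve the MME")
        self.vc = vc
        self.y, self.animal_idx, self.animals, Ab = _prepare(response, A)
        self.n = len(self.y)
        self.m = len(self.animals)
        g, pe, e = vc.sigma_g2, vc.sigma_pe2, vc.sigma_e2
        self._random = g > 0 or pe > 0
        if self._random:
            Gstar = g * Ab + pe * np.eye(self.m)  # cow-level covariance
            counts = np.bincount(self.animal_idx, minlength=self.m)
            M = e * linalg.inv(Gstar, check_finite=False)
            M[np.diag_indices(self.m)] += counts
            self._Minv = linalg.inv(M, check_finite=False)
            self._MinvZty = self._Minv @ self._agg(self.y)
        self._Zty = self._agg(self.y) if self._random else None

    def _agg(self, v: np.ndarray) -> np.ndarray:
        """Z' v : sum records per animal."""
        return np.bincount(self.animal_idx, weights=v, minlength=self.m)

    def fit_fixed(self, F: np.ndarray):
        """GLS solution and covariance of the fixed-effect block.

        Returns ``(beta, cov, ddf)`` or ``None`` when ``F`` is rank
        deficient (collinear covariates).
        """
        F = np.asarray(F, dtype=float)
        n, k = F.shape
        # rank check via QR; catches constant/collinear marker covariates
        r = np.abs(np.diag(np.linalg.qr(F, mode="r")))
        if r.size == 0 or r.min() < 1e-8 * max(r.max(), 1.0):
            return None
        e = self.vc.sigma_e2
        FtF = F.T @ F
        Fty = F.T @ self.y
        if self._random:
            U = np.stack([self._agg(F[:, j]) for j in range(k)])  # k x m
            S = (FtF - U @ self._Minv @ U.T) / e
            rhs = (Fty - U @ self._MinvZty) / e
        else:
            S = FtF / e
            rhs = Fty / e
        try:
            cS = linalg.cho_factor(S, check_finite=False)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve(cS, rhs, check_finite=False)
        cov = linalg.cho_solve(cS, np.eye(k), check_finite=False)
        return beta, cov, n - k

    def test_effect(
        self,
        covariates: dict[str, np.ndarray],
        focal: str,
        *,
        variant: str = "additive",
        snp_ids: tuple[str, ...] = (),
        maf: float = float("nan"),
    ) -> SnpTestResult:
        """Fit intercept + covariates; Wald F-test (1 df) on ``focal``."""
        names = ["mu", *covariates]
        F = np.column_stack([np.ones(self.n), *covariates.values()])
        fit = self.fit_fixed(F)
        if fit is None:
            return SnpTestResult(
                snp_ids=snp_ids, effect_name=focal, estimate=np.nan,
                se=np.nan, p=np.nan, maf=maf, variant=variant,
                flags=NOT_TESTABLE,
            )
        beta, cov, ddf = fit
        j = names.index(focal)
        est = float(beta[j])
        se = float(np.sqrt(cov[j, j]))
        fstat = (est / se) ** 2
        p = float(stats.f.sf(fstat, 1, ddf))
        coeffs = {
            nm: (float(beta[i]), float(np.sqrt(cov[i, i])))
            for i, nm in enumerate(names)
        }
        return SnpTestResult(
            snp_ids=snp_ids, effect_name=focal, estimate=est, se=se,
            p=max(p, np.finfo(float).tiny), maf=maf, variant=variant,
            coefficients=coeffs,
        )


def reml(
    y: np.ndarray,
    F: np.ndarray,
    animal_idx: np.ndarray,
    A_block: np.ndarray,
    *,
    fit_pe: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> VarianceComponents:
    """AI-REML for (sigma_g2, sigma_pe2, sigma_e2) with EM fallback.

    Average-information Newton steps on the REML log-likelihood, halved
    until the likelihood does not decrease and all components stay
    non-negative; when the AI matrix is near singular (e.g. polygenic and
    residual structures indistinguishable) a classical EM-REML step is taken
    instead and the condition is flagged on the result.  Convergence:
    log-likelihood change < ``tol`` and relative parameter change < ``tol``.
    """
    y = np.asarray(y, dtype=float)
    F = np.asarray(F, dtype=float)
    n = len(y)
    m = A_block.shape[0]
    vy = float(np.var(y))
    if vy == 0.0:
        return VarianceComponents(0.0, 0.0, 0.0, loglik=float("nan"))
    counts = np.bincount(animal_idx, minlength=m)
    if fit_pe and not (counts >= 2).any():
        warnings.warn(
            "no animal has repeated records; sigma_pe2 is unidentifiable "
            "and fixed at 0",
            stacklevel=2,
        )
        fit_pe = False

    Kg = A_block[np.ix_(animal_idx, animal_idx)]
    Ks = [Kg]
    qs = [m]
    if fit_pe:
        Ks.append((animal_idx[:, None] == animal_idx[None, :]).astype(float))
        qs.append(m)
    Ks.append(np.eye(n))
    qs.append(n)
    k = len(Ks)
    theta = np.full(k, vy / k)
    floor = 1e-10 * vy

    def evaluate(th):
        V = sum(t * K for t, K in zip(th, Ks))
        cV, low = linalg.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(cV)))
        Vinv = linalg.cho_solve((cV, low), np.eye(n), check_finite=False)
        VF = Vinv @ F
        FtVF = F.T @ VF
        cW = linalg.cho_factor(FtVF, check_finite=False)
        logdetW = 2.0 * np.sum(np.log(np.diag(cW[0])))
        P = Vinv - VF @ linalg.cho_solve(cW, VF.T, check_finite=False)
        Py = P @ y
        ll = -0.5 * (logdetV + logdetW + float(y @ Py))
        return ll, P, Py

    ll, P, Py = evaluate(theta)
    ai_singular = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = [K @ Py for K in Ks]
        yPKPy = np.array([float(Py @ wi) for wi in w])
        trPK = np.array([float(np.sum(P * K)) for K in Ks])
        score = 0.5 * (yPKPy - trPK)
        Pw = [P @ wi for wi in w]
        AI = 0.5 * np.array([[float(wi @ pj) for pj in Pw] for wi in w])
        use_em = False
        if np.linalg.cond(AI) > 1e8:
            if not ai_singular:
                warnings.warn(
                    "near-singular average-information matrix; variance "
                    "components may be poorly identified (EM fallback used)",
                    stacklevel=2,
                )
            ai_singular = True
            use_em = True
        if use_em:
            delta = theta**2 * (yPKPy - trPK) / np.array(qs, dtype=float)
        else:
            delta = np.linalg.solve(AI, score)
        # step halving: keep components >= 0 and never decrease the loglik
        step = 1.0
        for _ in range(40):
            prop = theta + step * delta
            if (prop >= 0).all():
                try:
                    ll_new, P_new, Py_new = evaluate(np.maximum(prop, floor))
                except linalg.LinAlgError:
                    step *= 0.5
                    continue
                if ll_new >= ll - 1e-12:
                    break
            step *= 0.5
        else:
            # no acceptable step: already at a (possibly boundary) optimum
            break
        prop = np.maximum(theta + step * delta, 0.0)
        change = np.max(np.abs(prop - theta)) / vy
        dll = ll_new - ll
        theta, ll, P, Py = prop, ll_new, P_new, Py_new
        if abs(dll) < tol and change < tol:
            break
    else:
        raise RemlError(
            f"REML did not converge in {max_iter} iterations "
            f"(last loglik {ll:.6f}, theta {theta})"
        )

    theta = np.where(theta < 10 * floor, 0.0, theta)
    if fit_pe:
        g, pe, e = theta
    else:
        g, e = theta
        pe = 0.0
    return VarianceComponents(
        sigma_g2=float(g), sigma_pe2=float(pe), sigma_e2=float(e),
        loglik=float(ll), converged=True, n_iter=n_iter,
        ai_singular=ai_singular,
    )


def reml_null(
    response: pd.DataFrame,
    A: RelationshipMatrix | None,
    **kwargs,
) -> VarianceComponents:
    """REML of the SNP-free model y = 1*mu + Zu + Wpe + e."""
    y, idx, _, Ab = _prepare(response, A)
    return reml(y, np.ones((len(y), 1)), idx, Ab, **kwargs)


def fit_snp(
    covariates: dict[str, np.ndarray],
    focal: str,
    response: pd.DataFrame,
    A: RelationshipMatrix | None,
    vc: VarianceComponents,
    *,
    mode: str = "fixed-vc",
    engine: MixedModelEngine | None = None,
    variant: str = "additive",
    snp_ids: tuple[str, ...] = (),
    maf: float = float("nan"),
) -> SnpTestResult:
    """Single-marker test, one SNP (or pair) at a time.

    ``mode="fixed-vc"`` (default) reuses the null-model variance components
    for every marker; ``mode="per-snp-reml"`` re-estimates them with the
    marker covariates in the fixed part before solving, mirroring a full
    per-marker REML refit.  An ``engine`` built from the same response and
    components may be passed to amortize the absorption across markers.
    """
    if mode == "per-snp-reml":
        y, idx, _, Ab = _prepare(response, A)
        F = np.column_stack([np.ones(len(y)), *covariates.values()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = reml(y, F, idx, Ab)
        engine = None
    elif mode != "fixed-vc":
        raise ValueError(f"unknown fit mode: {mode!r}")
    if engine is None:
        engine = MixedModelEngine(response, A, vc)
    return engine.test_effect(
        covariates, focal, variant=variant, snp_ids=snp_ids, maf=maf
    )
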