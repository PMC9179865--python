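"""Model-based ancestry estimation and genotype PCA.

The admixture model treats each alt-allele dosage as
g_ij ~ Binomial(2, p_ij) with p_ij = sum_k q_ik f_kj: individual i draws
a fraction q_ik of its genome from ancestral population k, whose allele
frequency at site j is f_kj.  The model is fitted by plain EM block
updates (monotone in log-likelihood), K is chosen by masking a fraction
of genotype entries and scoring the refit's predictions by binomial
deviance, and PCA uses the conventional dosage standardisation
(center by 2p, scale by sqrt(2p(1-p)), missing set to zero after
centering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matrix import MISSING, GenotypeMatrix

_EPS = 1e-6


class AdmixtureModel:
    """EM-fitted admixture model with K ancestral populations.

    Parameters mirror the conventional tooling: ``tol`` stops when the
    log-likelihood gain per iteration falls below it, ``seed`` fixes the
    Dirichlet initialisation of Q (K = 1 has a closed form).  Fitted
    attributes: ``Q_`` (individuals x K ancestry fractions, rows sum to
    1), ``F_`` (K x sites allele frequencies, clamped to
    [1e-6, 1 - 1e-6]), ``log_likelihood_``, ``n_iter_``.
    """

    def __init__(self, K: int, seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 2000):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = K
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter

    def _loglik(self, G, M, Q, F, const) -> float:
        P = np.clip(Q @ F, _EPS, 1.0 - _EPS)
        ll = np.where(M, G * np.log(P) + (2.0 - G) * np.log1p(-P), 0.0)
        return float(ll.sum() + const)

    def fit(self, dosages: np.ndarray | GenotypeMatrix) -> "AdmixtureModel":
        if isinstance(dosages, GenotypeMatrix):
            dosages = dosages.dosages
        G = np.asarray(dosages, dtype=np.float64)
        M = G != MISSING
        G = np.where(M, G, 0.0)
        n, L = G.shape
        if self.K > n:
            raise ValueError("K cannot exceed the number of individuals")
        # binomial coefficient term: log C(2, g), constant in the parameters
        const = float(np.where(M & (G == 1), np.log(2.0), 0.0).sum())
        rng = np.random.default_rng(self.seed)
        if self.K == 1:
            Q = np.ones((n, 1))
        else:
            Q = rng.dirichlet(np.ones(self.K), size=n)
        F = np.clip(rng.uniform(0.05, 0.95, size=(self.K, L)), _EPS, 1 - _EPS)
        ll_prev = -np.inf
        history: list[float] = []
        for it in range(1, self.max_iter + 1):
            P = np.clip(Q @ F, _EPS, 1.0 - _EPS)
            # expected alt/ref allele copies attributed to each ancestry
            GA = np.where(M, G / P, 0.0)               # n x L
            GB = np.where(M, (2.0 - G) / (1.0 - P), 0.0)
            A = (GA @ F.T) * Q                         # n x K, alt copies
            B = (GB @ (1.0 - F).T) * Q                 # n x K, ref copies
            f_num = (Q.T @ GA) * F                     # K x L
            f_den = f_num + (Q.T @ GB) * (1.0 - F)
            with np.errstate(invalid="ignore", divide="ignore"):
                F = np.where(f_den > 0, f_num / f_den, F)
            F = np.clip(F, _EPS, 1.0 - _EPS)
            denom = 2.0 * M.sum(axis=1, keepdims=True)
            Q = (A + B) / np.where(denom > 0, denom, 1.0)
            Q = Q / Q.sum(axis=1, keepdims=True)
            ll = self._loglik(G, M, Q, F, const)
            history.append(ll)
            if ll - ll_prev < self.tol and it > 1:
                ll_prev = ll
                break
            ll_prev = ll
        self.Q_ = Q
        self.F_ = F
        self.log_likelihood_ = ll_prev
        self.loglik_history_ = history
        self.n_iter_ = len(history)
        return self

    def predict_dosage(self) -> np.ndarray:
        """Expected dosage 2 * p_ij under the fitted model."""
        return 2.0 * np.clip(self.Q_ @ self.F_, _EPS, 1.0 - _EPS)


def fit_admixture(matrix: GenotypeMatrix | np.ndarray, K: int,
                  seed: int = 0, tol: float = 1e-6,
                  max_iter: int = 2000) -> AdmixtureModel:
    return AdmixtureModel(K, seed=seed, tol=tol, max_iter=max_iter).fit(matrix)


@dataclass
class CVResult:
    """Cross-validation errors per K (box-plot data)."""

    errors: dict[int, list[float]] = field(default_factory=dict)

    def mean_errors(self) -> dict[int, float]:
        return {k: float(np.mean(v)) for k, v in self.errors.items()}

    @property
    def best_k(self) -> int:
        means = self.mean_errors()
        return min(means, key=lambda k: (means[k], k))

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, i, e) for k, v in sorted(self.errors.items())
                for i, e in enumerate(v)]
        return pd.DataFrame(rows, columns=["K", "replicate", "error"])


def _binomial_deviance(g: np.ndarray, p: np.ndarray) -> float:
    """Mean scaled deviance between observed dosages and predicted
    alt-allele probabilities (saturated model at p = g/2)."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    ph = np.clip(g / 2.0, _EPS, 1.0 - _EPS)
    dev = 2.0 * (g * (np.log(ph) - np.log(p))
                 + (2.0 - g) * (np.log1p(-ph) - np.log1p(-p)))
    return float(np.mean(dev))


def cv_error(matrix: GenotypeMatrix | np.ndarray, K: int,
             fold_fraction: float = 0.1, n_replicates: int = 10,
             seed: int = 0, tol: float = 1e-5,
             max_iter: int = 500) -> list[float]:
    """Masked-entry cross-validation error for one K.

    Each replicate masks a random ``fold_fraction`` of the non-missing
    entries, refits the model on the remainder, and scores the masked
    dosages against the predicted 2 * p_ij by mean binomial deviance.
    """
    if not (0.0 < fold_fraction < 0.5):
        raise ValueError("fold_fraction must be in (0, 0.5)")
    if isinstance(matrix, GenotypeMatrix):
        dosages = matrix.dosages
    else:
        dosages = np.asarray(matrix)
    called = np.argwhere(dosages != MISSING)
    rng = np.random.default_rng(seed)
    errors: list[float] = []
    for rep in range(n_replicates):
        n_mask = max(1, int(round(fold_fraction * len(called))))
        pick = rng.choice(len(called), size=n_mask, replace=False)
        rows, cols = called[pick, 0], called[pick, 1]
        train = dosages.astype(np.int8).copy()
        train[rows, cols] = MISSING
        model = AdmixtureModel(K, seed=int(rng.integers(0, 2 ** 31 - 1)),
                               tol=tol, max_iter=max_iter).fit(train)
        pred = np.clip(model.Q_ @ model.F_, _EPS, 1.0 - _EPS)
        obs = dosages[rows, cols].astype(np.float64)
        errors.append(_binomial_deviance(obs, pred[rows, cols]))
    return errors


def scan_k(matrix: GenotypeMatrix | np.ndarray,
           k_values=range(1, 6), fold_fraction: float = 0.1,
           n_replicates: int = 10, seed: int = 0,
           tol: float = 1e-5, max_iter: int = 500) -> CVResult:
    """CV error across candidate K; the optimum is the argmin mean."""
    result = CVResult()
    for i, k in enumerate(k_values):
        result.errors[int(k)] = cv_error(matrix, int(k), fold_fraction,
                                         n_replicates, seed + 7919 * i,
                                         tol, max_iter)
    return result


def align_q_columns(q_matrices: list[np.ndarray]) -> list[np.ndarray]:
    """Greedy column matching of replicate ancestry matrices.

    Ancestry labels are arbitrary per EM run; each replicate's columns
    are permuted to best match the first replicate (greedy on column
    correlation), making replicate Q matrices directly comparable.
    """
    if not q_matrices:
        return []
    ref = q_matrices[0]
    out = [ref]
    for q in q_matrices[1:]:
        K = ref.shape[1]
        sim_mat = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                sim_mat[a, b] = -np.abs(ref[:, a] - q[:, b]).sum()
        perm = [-1] * K
        used = set()
        for a in np.argsort(sim_mat.max(axis=1))[::-1]:
            b = max((b for b in range(K) if b not in used),
                    key=lambda b: sim_mat[a, b])
            perm[a] = b
            used.add(b)
        out.append(q[:, perm])
    return out


@dataclass
class PCAResult:
    scores: np.ndarray               # (n_ind, n_components)
    explained_variance_ratio: np.ndarray
    samples: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        idx = self.samples or range(self.scores.shape[0])
        return pd.DataFrame(self.scores, index=idx, columns=cols)


def pca(matrix: GenotypeMatrix | np.ndarray,
        n_components: int = 10) -> PCAResult:
    """Genotype PCA with the standard dosage scaling.

    Each site is centered by twice its pooled allele frequency and
    scaled by the binomial standard deviation sqrt(2 p (1-p)); missing
    entries become zero after centering (i.e. imputed at the mean).
    Monomorphic sites carry no information and are dropped.
    """
    samples = None
    if isinstance(matrix, GenotypeMatrix):
        samples = list(matrix.samples)
        dosages = matrix.dosages
    else:
        dosages = np.asarray(matrix)
    if dosages.shape[0] < 2:
        raise ValueError("PCA needs at least 2 individuals")
    G = dosages.astype(np.float64)
    Mmask = G != MISSING
    n_called = Mmask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0,
                     np.where(Mmask, G, 0.0).sum(axis=0) / (2.0 * n_called), 0.0)
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("matrix has no polymorphic sites")
    G = G[:, keep]
    Mmask = Mmask[:, keep]
    p = p[keep]
    X = np.where(Mmask, (G - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p)), 0.0)
    U, s, _Vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("zero-variance matrix")
    k = min(n_components, len(s))
    return PCAResult(U[:, :k] * s[:k],
                     var[:k] / total,
                     samples)
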