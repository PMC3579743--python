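"""REML estimation of SNP heritability from case-control status.

``GREML`` is a variance-components model for y ~ Normal(X beta, sum_c
sigma2_c A_c + sigma2_e I) fitted by average-information REML with an
expectation-maximization warm start. ``GREMLResults`` carries the variance
components, their average-information standard errors, the observed-scale
heritability, and the transform to the liability scale at a stated
population prevalence. ``estimate_h2_cc`` runs the full case-control
pipeline (QC, per-chromosome GRMs, combination, PCs, REML, transform) and
``per_chromosome_h2`` partitions heritability by chromosome.

The observed-to-liability transform is the ascertainment-corrected
formula: h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)), with K the
population prevalence, P the sample case proportion and z the standard
normal density at the liability threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from ._chromlen import CHROM_LENGTHS_BP
from .panels import Cohort, SnpPanel, concat_cohorts
from .qc import QcThresholds, run_qc
from .relatedness import Grm, combine_grms, compute_grm, grm_pca, relatedness_prune


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class LiabilityEstimate:
    """Heritability moved from the observed 0/1 scale to the liability scale."""

    K: float  # population prevalence
    P: float  # sample case proportion
    z: float  # standard-normal density at the liability threshold
    h2_obs: float
    se_obs: float
    h2_liab: float
    se_liab: float

    @property
    def multiplier(self) -> float:
        return self.K**2 * (1 - self.K) ** 2 / (self.z**2 * self.P * (1 - self.P))

    def __str__(self) -> str:
        return (f"h2(liability) = {self.h2_liab:.4f} (se {self.se_liab:.4f}) "
                f"[K={self.K}, P={self.P:.3f}, observed {self.h2_obs:.4f}]")


def observed_to_liability(h2_obs: float, se_obs: float, K: float, P: float
                          ) -> LiabilityEstimate:
    """Rescale an observed-scale estimate to the liability scale at prevalence K."""
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must lie strictly in (0, 1)")
    z = float(stats.norm.pdf(stats.norm.isf(K)))
    mult = K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P))
    return LiabilityEstimate(K=K, P=P, z=z, h2_obs=h2_obs, se_obs=se_obs,
                             h2_liab=h2_obs * mult, se_liab=se_obs * mult)


class GREML:
    """Variance-components model with one or more GRMs plus residual.

    Parameters
    ----------
    y : (n,) phenotype vector (0/1 affection status for the case-control
        contrast, but any quantitative trait works).
    X : (n, p) fixed-effect design. ``None`` means intercept only; an
        intercept column is prepended if absent.
    grms : list of Grm (or raw symmetric arrays) defining the genetic
        covariance components.
    names : optional component names for reporting.
    """

    def __init__(self, y, X=None, grms=(), names=None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = len(self.y)
        mats = []
        for g in grms if isinstance(grms, (list, tuple)) else [grms]:
            A = g.A if isinstance(g, Grm) else np.asarray(g, dtype=float)
            if A.shape != (n, n):
                raise ValueError("GRM dimension does not match the phenotype")
            mats.append(A)
        if not mats:
            raise ValueError("at least one GRM is required")
        self.grms = mats
        if X is None:
            X = np.ones((n, 1))
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] != n:
                X = X.T
            if not np.any(np.all(X == X[0, :], axis=0) & (X[0, :] != 0)):
                X = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        self.X = X
        self.names = list(names) if names else [f"G{i + 1}" for i in range(len(mats))]

    # -- internals ---------------------------------------------------------

    def _vmats(self):
        return self.grms + [np.eye(len(self.y))]

    def _identifiable(self) -> bool:
        vecs = np.array([m.ravel() for m in self._vmats()])
        gram = vecs @ vecs.T
        return np.linalg.cond(gram) < 1e10

    def _ops(self):
        if not hasattr(self, "_ops_cache"):
            if len(self.grms) == 1:
                self._ops_cache = _EigenOps(self.y, self.X, self.grms[0])
            else:
                self._ops_cache = _DenseOps(self.y, self.X, self.grms)
        return self._ops_cache

    def restricted_loglik(self, theta) -> float:
        """Restricted log-likelihood at the given variance components."""
        return self._ops().loglik(np.asarray(theta, dtype=float))

    def fit(self, method: str = "ai", maxiter: int = 100, tol: float = 1e-8,
            em_steps: int = 3, constrain: bool = True, start=None,
            verbose: bool = False) -> "GREMLResults":
        """Maximize the restricted likelihood by AI-REML with EM fallback.

        The first ``em_steps`` iterations use monotone EM updates as a warm
        start, then average-information (quasi-Newton) steps with halving
        when a step would decrease the likelihood. Variance components are
        floored at 1e-8 * var(y) when ``constrain`` is set; convergence is
        declared when the restricted log-likelihood changes by less than
        ``tol``. With a single GRM the problem is rotated once into the
        GRM's eigenbasis, making each iteration linear in n.
        """
        n = len(self.y)
        ncomp = len(self.grms) + 1
        vary = float(np.var(self.y))
        if vary == 0:
            raise ValueError("phenotype has zero variance")
        floor = 1e-8 * vary if constrain else -np.inf
        identifiable = self._identifiable()
        if not identifiable:
            warnings.warn("variance components are not identifiable "
                          "(GRM indistinguishable from the residual)",
                          ConvergenceWarning, stacklevel=2)

        theta = (np.asarray(start, dtype=float) if start is not None
                 else np.full(ncomp, vary / ncomp))
        ops = self._ops()

        ll, grad, AI, quad, tr, beta, cov_beta = ops.iteration(theta)
        history = [ll]
        n_em = 0
        converged = False
        for it in range(maxiter):
            use_em = (method == "em") or (it < em_steps)
            new = None
            if not use_em:
                try:
                    step = np.linalg.solve(AI, grad)
                except np.linalg.LinAlgError:
                    step = None
                if step is not None:
                    frac = 1.0
                    for _ in range(8):  # step halving on likelihood decrease
                        cand = np.maximum(theta + frac * step, floor)
                        try:
                            ll_c = ops.loglik(cand)
                        except np.linalg.LinAlgError:
                            ll_c = -np.inf
                        if ll_c >= ll - 1e-10:
                            new, ll_new = cand, ll_c
                            break
                        frac *= 0.5
            if new is None:  # EM update (monotone, slow, always safe)
                n_em += 1
                new = np.maximum(theta + theta**2 / n * (quad - tr), floor)
                ll_new = ops.loglik(new)
            delta = ll_new - ll
            theta = new
            ll, grad, AI, quad, tr, beta, cov_beta = ops.iteration(theta)
            history.append(ll)
            if verbose:
                print(f"iter {it + 1}: logL={ll:.6f} theta={theta}")
            if abs(delta) < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"REML did not converge in {maxiter} iterations",
                          ConvergenceWarning, stacklevel=2)

        try:
            vcov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            vcov = np.full((ncomp, ncomp), np.nan)
        return GREMLResults(model=self, theta=theta, vcov_theta=vcov, beta=beta,
                            cov_beta=cov_beta, loglik=float(ll),
                            niter=it + 1, n_em_steps=n_em, converged=converged,
                            identifiable=identifiable, history=np.array(history))


class _DenseOps:
    """Direct REML linear algebra for an arbitrary number of components."""

    def __init__(self, y, X, grms):
        self.y, self.X = y, X
        self.vmats = list(grms) + [np.eye(len(y))]

    def _parts(self, theta):
        y, X = self.y, self.X
        n = len(y)
        V = sum(t * A for t, A in zip(theta, self.vmats))
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
        Vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)
        XtVi = X.T @ Vinv
        XtViX = XtVi @ X
        cho_x = linalg.cho_factor(XtViX, check_finite=False)
        beta = linalg.cho_solve(cho_x, XtVi @ y, check_finite=False)
        P = Vinv - XtVi.T @ linalg.cho_solve(cho_x, XtVi, check_finite=False)
        Py = P @ y
        logdet_v = 2 * np.sum(np.log(np.diag(cho[0])))
        logdet_x = 2 * np.sum(np.log(np.diag(cho_x[0])))
        ll = -0.5 * (logdet_v + logdet_x + y @ Py)
        return ll, P, Py, beta, XtViX

    def loglik(self, theta) -> float:
        return float(self._parts(theta)[0])

    def iteration(self, theta):
        ll, P, Py, beta, XtViX = self._parts(theta)
        u = np.column_stack([A @ Py for A in self.vmats])
        quad = Py @ u
        tr = np.array([np.sum(P * A) for A in self.vmats])
        grad = -0.5 * (tr - quad)
        AI = 0.5 * (u.T @ P @ u)
        return (float(ll), grad, AI, quad, tr, beta, np.linalg.inv(XtViX))


class _EigenOps:
    """Single-GRM REML in the GRM's eigenbasis: O(n) per iteration.

    With A = U diag(lam) U', V = sigma_g A + sigma_e I is diagonal after
    rotating y and X by U', so determinants, solves and traces reduce to
    vector operations.
    """

    def __init__(self, y, X, A):
        lam, U = np.linalg.eigh(A)
        self.lam = lam
        self.yr = U.T @ y
        self.Xr = U.T @ X

    def _d(self, theta):
        d = theta[0] * self.lam + theta[1]
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("V not positive definite")
        return d

    def _parts(self, theta):
        d = self._d(theta)
        yr, Xr = self.yr, self.Xr
        Xd = Xr / d[:, None]
        XtViX = Xd.T @ Xr
        cho_x = linalg.cho_factor(XtViX, check_finite=False)
        beta = linalg.cho_solve(cho_x, Xd.T @ yr, check_finite=False)
        resid = yr - Xr @ beta
        Py = resid / d  # rotated P y (X' V^-1 resid = 0 at beta-hat)
        logdet_x = 2 * np.sum(np.log(np.diag(cho_x[0])))
        ll = -0.5 * (np.sum(np.log(d)) + logdet_x + yr @ Py)
        return ll, d, Py, beta, XtViX, cho_x

    def loglik(self, theta) -> float:
        return float(self._parts(theta)[0])

    def _project(self, v, d, cho_x):
        # rotated P @ v for an arbitrary vector v
        vd = v / d
        return vd - (self.Xr / d[:, None]) @ linalg.cho_solve(
            cho_x, self.Xr.T @ vd, check_finite=False)

    def iteration(self, theta):
        ll, d, Py, beta, XtViX, cho_x = self._parts(theta)
        lam = self.lam
        Xd = self.Xr / d[:, None]
        C = np.linalg.inv(XtViX)
        q = np.einsum("ij,jk,ik->i", self.Xr, C, self.Xr)  # x_i' C x_i
        tr = np.array([np.sum(lam / d) - np.sum(lam / d**2 * q),
                       np.sum(1.0 / d) - np.sum(q / d**2)])
        u = np.column_stack([lam * Py, Py])
        quad = Py @ u
        grad = -0.5 * (tr - quad)
        Pu = np.column_stack([self._project(u[:, j], d, cho_x) for j in range(2)])
        AI = 0.5 * (u.T @ Pu)
        return (float(ll), grad, AI, quad, tr, beta, C)


@dataclass
class GREMLResults:
    """Fitted variance components with average-information uncertainties."""

    model: GREML
    theta: np.ndarray  # genetic components then residual
    vcov_theta: np.ndarray
    beta: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    niter: int
    n_em_steps: int
    converged: bool
    identifiable: bool
    history: np.ndarray

    @property
    def sigma2_g(self) -> np.ndarray:
        return self.theta[:-1]

    @property
    def sigma2_e(self) -> float:
        return float(self.theta[-1])

    @property
    def sigma2_p(self) -> float:
        return float(self.theta.sum())

    @property
    def se_theta(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.vcov_theta), 0))

    @property
    def h2_obs(self) -> float:
        """Total genetic fraction of phenotypic variance (observed scale)."""
        return float(self.sigma2_g.sum() / self.sigma2_p)

    def h2_obs_per_component(self) -> np.ndarray:
        return self.sigma2_g / self.sigma2_p

    @property
    def se_h2_obs(self) -> float:
        return float(self._se_ratio(np.arange(len(self.theta) - 1)))

    def _se_ratio(self, gen_idx) -> float:
        # delta method for (sum_{i in gen} theta_i) / sum(theta)
        t, tot = self.theta, self.sigma2_p
        g = t[gen_idx].sum()
        grad = np.full(len(t), -g / tot**2)
        grad[gen_idx] += 1 / tot
        var = float(grad @ self.vcov_theta @ grad)
        return np.sqrt(max(var, 0.0))

    def se_h2_component(self, i: int) -> float:
        return float(self._se_ratio(np.array([i])))

    def to_liability(self, K: float, P: float | None = None) -> LiabilityEstimate:
        """Transform h2_obs to the liability scale at population prevalence K."""
        if P is None:
            P = float(np.mean(self.model.y))
        return observed_to_liability(self.h2_obs, self.se_h2_obs, K, P)

    def summary(self) -> str:
        """GCTA-style variance table (Source / Variance / SE)."""
        lines = ["Source\tVariance\tSE"]
        for name, t, se in zip(self.model.names, self.sigma2_g, self.se_theta):
            lines.append(f"V({name})\t{t:.6f}\t{se:.6f}")
        lines.append(f"V(e)\t{self.sigma2_e:.6f}\t{self.se_theta[-1]:.6f}")
        lines.append(f"Vp\t{self.sigma2_p:.6f}")
        for i, name in enumerate(self.model.names):
            lines.append(f"V({name})/Vp\t{self.h2_obs_per_component()[i]:.6f}"
                         f"\t{self.se_h2_component(i):.6f}")
        if len(self.model.names) > 1:
            lines.append(f"Sum V(G)/Vp\t{self.h2_obs:.6f}\t{self.se_h2_obs:.6f}")
        lines.append(f"logL\t{self.loglik:.4f}")
        lines.append(f"n\t{len(self.model.y)}")
        lines.append(f"iterations\t{self.niter}\tconverged\t{self.converged}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# End-to-end case-control pipeline
# ---------------------------------------------------------------------------


def estimate_h2_cc(cases: Cohort, controls: Cohort, panel: SnpPanel,
                   K: float = 0.01, k_pcs: int = 10,
                   thresholds: QcThresholds | None = None,
                   qc: bool = True, per_chromosome_grms: bool = True,
                   rel_cutoff: float = 0.05
                   ) -> tuple[LiabilityEstimate, GREMLResults]:
    """Case-control SNP heritability on the liability scale.

    Merges the cohorts (cases phenotype 1, controls 0), applies the QC
    chain, builds per-chromosome GRMs and combines them, prunes
    cross-family relatedness, computes k principal components as ancestry
    covariates and fits REML, then transforms the estimate to the liability
    scale at prevalence K. Relabeling which cohort is "affected" (parents,
    siblings, pseudo-controls vs controls) realizes the relative contrasts.
    """
    merged = concat_cohorts([cases, controls])
    merged.phenotype[: cases.n_individuals] = 1
    merged.phenotype[cases.n_individuals:] = 0
    work_panel = panel
    if qc:
        merged, work_panel, _ = run_qc(merged, panel, thresholds)

    if per_chromosome_grms:
        chroms = [str(c) for c in dict.fromkeys(work_panel.chromosome.astype(str))]
        grm = combine_grms([compute_grm(merged, work_panel, [c]) for c in chroms])
    else:
        grm = compute_grm(merged, work_panel)

    keep = relatedness_prune(grm, cutoff=rel_cutoff,
                             family_ids=merged.family_id)
    if len(keep) < grm.n:
        merged = merged.subset(individuals=keep)
        grm = Grm(ids=[grm.ids[i] for i in keep],
                  A=grm.A[np.ix_(keep, keep)], m=grm.m)

    pcs = grm_pca(grm, k=min(k_pcs, grm.n - 2))
    model = GREML(merged.phenotype.astype(float), pcs.vectors, [grm])
    fit = model.fit()
    return fit.to_liability(K), fit


@dataclass
class ChromPartition:
    """Per-chromosome heritability estimates and the length correlation."""

    chromosomes: list[str]
    h2_obs: np.ndarray
    se: np.ndarray
    lengths_bp: np.ndarray
    r: float
    p_value: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"chromosome": self.chromosomes, "h2_obs": self.h2_obs,
                             "se": self.se, "length_bp": self.lengths_bp})

    def plot(self, ax=None):
        """Scatter of per-chromosome h2 against chromosome length."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.lengths_bp / 1e6, self.h2_obs)
        for c, x, y in zip(self.chromosomes, self.lengths_bp / 1e6, self.h2_obs):
            ax.annotate(c, (x, y), fontsize=8)
        ax.set_xlabel("chromosome length (Mb)")
        ax.set_ylabel("h2 per chromosome (observed scale)")
        ax.set_title(f"r = {self.r:.2f} (P = {self.p_value:.3g})")
        return ax


def per_chromosome_h2(cohort: Cohort, panel: SnpPanel, y=None, X=None,
                      mode: str = "joint") -> ChromPartition:
    """Partition heritability by chromosome and correlate with length.

    ``joint`` fits, per chromosome, a two-component model (that
    chromosome's GRM plus a rest-of-genome GRM); ``marginal`` fits each
    chromosome's GRM alone. Requires at least five chromosomes.
    """
    chroms = [str(c) for c in dict.fromkeys(panel.chromosome.astype(str))]
    if len(chroms) < 5:
        raise ValueError("need at least five chromosomes for the partition")
    y = cohort.phenotype.astype(float) if y is None else np.asarray(y, float)
    per_chr = {c: compute_grm(cohort, panel, [c]) for c in chroms}
    ests, ses = [], []
    for c in chroms:
        if mode == "joint":
            rest = combine_grms([per_chr[d] for d in chroms if d != c])
            fit = GREML(y, X, [per_chr[c], rest], names=[f"chr{c}", "rest"]).fit()
        elif mode == "marginal":
            fit = GREML(y, X, [per_chr[c]], names=[f"chr{c}"]).fit()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        ests.append(float(fit.h2_obs_per_component()[0]))
        ses.append(fit.se_h2_component(0))
    lengths = np.array([CHROM_LENGTHS_BP[c] for c in chroms], dtype=float)
    r, p = stats.pearsonr(ests, lengths)
    return ChromPartition(chromosomes=chroms, h2_obs=np.array(ests),
                          se=np.array(ses), lengths_bp=lengths,
                          r=float(r), p_value=float(p))
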