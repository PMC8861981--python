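"""Entropy-penalized EM clustering of temporal expression profiles.

The model
---------
Each profile ``y_i`` (one gene in one sex, replicate-averaged and
standardized, observed at T ages) is drawn from a K-component mixture of
Gaussian linear mixed-effects models.  Component k has a cluster-level cubic
mean curve and profile-level quadratic random effects::

    y_i | (c_i = k)  ~  N( X beta_k,  Z D_k Z' + sigma2 I_T )

with ``X`` the (T x 4) cubic and ``Z`` the (T x 3) quadratic polynomial basis
on the age grid scaled to [-1, 1].  ``D_k`` captures within-cluster
heterogeneity of trajectory shape; ``sigma2`` is a residual variance shared
across clusters (five time points cannot identify a per-cluster residual
variance alongside a full 3x3 ``D_k``).

The algorithm
-------------
EM on the penalized objective::

    J = sum_i log sum_k pi_k f_k(y_i)  +  lambda * N * sum_k pi_k log pi_k

The negative-entropy reward drives superfluous components' weights toward
zero; components whose expected membership ``pi_k * N`` falls below
``prune_threshold`` are annihilated, so the cluster count is selected
automatically from an over-specified ``K_max``.  ``lambda`` is annealed
linearly to zero over the first half of the iterations: penalize early to
prune, finish with pure maximum likelihood.  The mixing-weight update is a
closed-form mass-reallocation fixed point, safeguarded by backtracking so the
penalized objective never decreases; beta is updated by responsibility-
weighted GLS and (D_k, sigma2) by one inner EM step over the random effects,
making each iteration a generalized-EM ascent step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .io import ValidationError
from .profiles import ProfileSet, design_matrices

__all__ = [
    "EPEMConfig",
    "ClusterModel",
    "AssignmentTable",
    "TemporalMixture",
    "TemporalMixtureResults",
    "profile_loglik",
    "fit_epem",
    "assign_labels",
]


class NumericalError(RuntimeError):
    """A covariance matrix lost positive definiteness beyond repair."""


@dataclass
class EPEMConfig:
    """Algorithmic constants for the entropy-penalized EM fit.

    k_max : starting (maximum) number of mixture components.
    lambda_penalty : weight of the negative-entropy reward; annealed linearly
        to zero over the first half of ``max_iter`` when ``anneal`` is set.
    prune_threshold : minimum expected membership pi_k * N below which a
        component is annihilated.
    tol : relative objective-change convergence tolerance, scaled by
        1 + |J| (checked only once lambda has reached its final value).
    n_restarts : independent seeded starts; the best final objective wins.
    variance_floor : lower bound applied to sigma2 and to eigenvalues of D_k.
    """

    k_max: int = 10
    lambda_penalty: float = 0.5
    anneal: bool = True
    prune_threshold: float = 1.0
    tol: float = 1e-6
    max_iter: int = 200
    n_restarts: int = 10
    variance_floor: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValidationError("k_max must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.lambda_penalty < 0:
            raise ValidationError("lambda_penalty must be non-negative")
        if self.variance_floor <= 0:
            raise ValidationError("variance_floor must be positive")


@dataclass
class ClusterModel:
    """Fitted mixture parameters, canonically ordered by descending size."""

    K: int
    pi: np.ndarray                 # (K,)
    beta: np.ndarray               # (K, 4)
    D: np.ndarray                  # (K, 3, 3)
    sigma2: float
    X: np.ndarray                  # (T, 4)
    Z: np.ndarray                  # (T, 3)
    age_grid: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    lambda_penalty: float = 0.0
    seed: int | None = None

    def mean_curves(self) -> np.ndarray:
        """Cluster mean trajectories on the age grid, shape (K, T)."""
        return self.beta @ self.X.T

    def to_json(self, path) -> None:
        obj = {
            "K": self.K,
            "pi": self.pi.tolist(),
            "beta": self.beta.tolist(),
            "D": self.D.tolist(),
            "sigma2": float(self.sigma2),
            "age_grid": self.age_grid.tolist(),
            "objective_trace": [float(v) for v in self.objective_trace],
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "lambda_penalty": float(self.lambda_penalty),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(Path(path)) as fh:
            obj = json.load(fh)
        X, Z = design_matrices(obj["age_grid"])
        return cls(
            K=int(obj["K"]),
            pi=np.array(obj["pi"]),
            beta=np.array(obj["beta"]),
            D=np.array(obj["D"]),
            sigma2=float(obj["sigma2"]),
            X=X, Z=Z,
            age_grid=np.array(obj["age_grid"], dtype=float),
            objective_trace=list(obj.get("objective_trace", [])),
            converged=bool(obj.get("converged", True)),
            n_iter=int(obj.get("n_iter", 0)),
            lambda_penalty=float(obj.get("lambda_penalty", 0.0)),
            seed=obj.get("seed"),
        )


@dataclass
class AssignmentTable:
    """Per-object responsibilities and hard labels (1..K)."""

    object_ids: list[tuple[str, str]]
    responsibilities: np.ndarray   # (N, K), rows sum to 1
    labels: np.ndarray             # (N,), int in 1..K

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.object_ids, names=["gene_id", "sex"])
        K = self.responsibilities.shape[1]
        df = pd.DataFrame(self.responsibilities, index=idx,
                          columns=[f"resp_{k}" for k in range(1, K + 1)])
        df.insert(0, "label", self.labels)
        df["max_resp"] = self.responsibilities.max(axis=1)
        return df

    def label_map(self, sex: str) -> dict[str, int]:
        """gene_id -> label for one sex."""
        return {g: int(l) for (g, s), l in zip(self.object_ids, self.labels)
                if s == sex}


def profile_loglik(y, beta_k, D_k, sigma2, X, Z) -> float:
    """Marginal Gaussian log-density of one profile under one component.

    ``y ~ N(X beta_k, Z D_k Z' + sigma2 I)``, evaluated exactly via a
    Cholesky factorization of the T x T marginal covariance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    T = len(y)
    V = Z @ np.asarray(D_k, dtype=float) @ Z.T + sigma2 * np.eye(T)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"marginal covariance not positive definite: {exc}")
    r = y - X @ np.asarray(beta_k, dtype=float)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = r @ cho_solve((c, low), r)
    return float(-0.5 * (T * np.log(2.0 * np.pi) + logdet + quad))


def _component_logliks(Y, beta, D, sigma2, Z_base, X) -> np.ndarray:
    """Log-density of every profile under every component, shape (N, K)."""
    N, T = Y.shape
    K = beta.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        V = Z_base @ D[k] @ Z_base.T + sigma2 * np.eye(T)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"cluster {k + 1}: covariance not positive definite: {exc}")
        R = Y - X @ beta[k]
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        quad = np.einsum("it,it->i", R, cho_solve((c, low), R.T).T)
        out[:, k] = -0.5 * (T * np.log(2.0 * np.pi) + logdet + quad)
    return out


def _penalty(pi, lam, N) -> float:
    p = pi[pi > 0]
    return float(lam * N * np.sum(p * np.log(p)))


def _pi_objective(pi, n_k, lam, N) -> float:
    if np.any((pi <= 0) & (n_k > 1e-12)):
        return -np.inf
    ok = pi > 0
    val = float(np.sum(n_k[ok] * np.log(pi[ok])))
    return val + _penalty(pi, lam, N)


def _update_pi(pi, n_k, lam, N) -> np.ndarray:
    """Safeguarded entropy-penalized mixing-weight update.

    Candidate fixed point ``pi_k <- n_k/N + lam * pi_k (log pi_k - s)`` with
    ``s = sum_j pi_j log pi_j`` sums to one by construction and drains mass
    from components smaller than the entropy-weighted average.  Backtracking
    toward the incumbent guarantees the penalized M-step objective does not
    decrease.
    """
    if lam == 0.0 or len(pi) == 1:
        return n_k / N
    logpi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), 0.0)
    s = float(np.sum(pi * logpi))
    cand = n_k / N + lam * pi * (logpi - s)
    cand = np.maximum(cand, 0.0)
    tot = cand.sum()
    if tot <= 0:
        return pi
    cand /= tot
    f_old = _pi_objective(pi, n_k, lam, N)
    step = 1.0
    for _ in range(40):
        trial = pi + step * (cand - pi)
        trial = np.maximum(trial, 0.0)
        trial /= trial.sum()
        if _pi_objective(trial, n_k, lam, N) >= f_old - 1e-12:
            return trial
        step *= 0.5
    return pi


def _floor_psd(D, floor) -> np.ndarray:
    w, V = np.linalg.eigh(D)
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def _init_params(Y, K, X, Z, floor, seed):
    """k-means partition of the profiles, then per-cluster OLS curves."""
    N, T = Y.shape
    km = KMeans(n_clusters=K, n_init=4, random_state=int(seed) % (2**31))
    labels = km.fit_predict(Y)
    pi = np.bincount(labels, minlength=K).astype(float)
    pi = np.maximum(pi, 1.0)
    pi /= pi.sum()
    beta = np.empty((K, X.shape[1]))
    resid_var = []
    for k in range(K):
        members = Y[labels == k]
        center = members.mean(axis=0) if len(members) else Y.mean(axis=0)
        beta[k] = np.linalg.lstsq(X, center, rcond=None)[0]
        if len(members):
            resid_var.append(np.mean((members - X @ beta[k]) ** 2))
    sigma2 = max(float(np.mean(resid_var)) if resid_var else 1.0, floor)
    D = np.tile(0.01 * np.eye(Z.shape[1]), (K, 1, 1))
    return pi, beta, D, sigma2


def fit_epem(profiles: ProfileSet, config: EPEMConfig) -> tuple[ClusterModel, AssignmentTable]:
    """Fit the entropy-penalized mixture; best of ``n_restarts`` by final J."""
    model, assign = TemporalMixture(profiles, config=config).fit()._parts()
    return model, assign


class TemporalMixture:
    """Mixture-of-mixed-effects model for temporal expression profiles.

    Parameters
    ----------
    profiles : ProfileSet
        Standardized (fit-ready) profiles.
    config : EPEMConfig, optional
        Algorithmic constants; keyword arguments override its fields.
    """

    def __init__(self, profiles: ProfileSet, config: EPEMConfig | None = None,
                 **kwargs):
        if not profiles.standardized:
            raise ValidationError("profiles must be standardized before fitting")
        if config is None:
            config = EPEMConfig(**kwargs)
        elif kwargs:
            config = EPEMConfig(**{**config.__dict__, **kwargs})
        if profiles.n_objects < config.k_max:
            raise ValidationError(
                f"need at least k_max={config.k_max} objects, "
                f"got {profiles.n_objects}")
        if profiles.n_times < 3:
            raise ValidationError("need >= 3 time points")
        self.profiles = profiles
        self.config = config
        self.X, self.Z = design_matrices(profiles.age_grid)

    @classmethod
    def from_study(cls, matrix, annot, config: EPEMConfig | None = None, **kwargs):
        """Build directly from an expression matrix + annotation table."""
        from .profiles import collapse_replicates, standardize_profiles
        prof = standardize_profiles(collapse_replicates(matrix, annot))
        return cls(prof, config=config, **kwargs)

    # ---------------------------------------------------------------- fitting

    def fit(self) -> "TemporalMixtureResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        restart_seeds = [int(s.generate_state(1)[0] % (2**31))
                         for s in ss.spawn(cfg.n_restarts)]
        best = None
        for rs in restart_seeds:
            run = self._single_run(rs)
            if best is None or run["objective"] > best["objective"]:
                best = run
        model, assign = self._finalize(best)
        return TemporalMixtureResults(self, model, assign)

    def _single_run(self, seed: int) -> dict:
        cfg = self.config
        Y = self.profiles.values
        X, Z = self.X, self.Z
        N = Y.shape[0]
        pi, beta, D, sigma2 = _init_params(Y, cfg.k_max, X, Z,
                                           cfg.variance_floor, seed)
        lam_final = 0.0 if cfg.anneal else cfg.lambda_penalty
        half = max(1, cfg.max_iter // 2)
        trace: list[float] = []
        history: list[float] = []
        converged = False
        J_prev = None
        n_iter = 0
        for t in range(cfg.max_iter):
            n_iter = t + 1
            lam = (cfg.lambda_penalty * max(0.0, 1.0 - t / half)
                   if cfg.anneal else cfg.lambda_penalty)
            ll = _component_logliks(Y, beta, D, sigma2, Z, X)
            with np.errstate(divide="ignore"):
                logw = ll + np.log(np.maximum(pi, 1e-300))[None, :]
            logZ = logsumexp(logw, axis=1)
            J = float(np.sum(logZ)) + _penalty(pi, lam, N)
            trace.append(J)
            history.append(J)
            if (J_prev is not None and lam == lam_final
                    and abs(J - J_prev) < cfg.tol * (1.0 + abs(J))):
                converged = True
                break
            J_prev = J if lam == lam_final else None
            resp = np.exp(logw - logZ[:, None])
            n_k = resp.sum(axis=0)
            # --- pi update (safeguarded entropy-penalized fixed point)
            pi = _update_pi(pi, n_k, lam, N)
            # --- annihilation of starved components
            keep = pi * N >= cfg.prune_threshold
            if keep.sum() == 0:
                keep[np.argmax(pi)] = True
            if not keep.all():
                pi = pi[keep]
                pi /= pi.sum()
                beta, D = beta[keep], D[keep]
                resp = resp[:, keep]
                resp /= resp.sum(axis=1, keepdims=True)
                n_k = resp.sum(axis=0)
                trace = []        # objective not comparable across K
                J_prev = None
            K = len(pi)
            # --- beta: responsibility-weighted GLS per cluster
            sse = 0.0
            new_D = np.empty_like(D)
            for k in range(K):
                V = Z @ D[k] @ Z.T + sigma2 * np.eye(Y.shape[1])
                c, low = cho_factor(V, lower=True)
                Vinv_X = cho_solve((c, low), X)
                ybar = resp[:, k] @ Y / max(n_k[k], 1e-12)
                beta[k] = np.linalg.solve(X.T @ Vinv_X, Vinv_X.T @ ybar)
                # --- one inner EM step over random effects for (D_k, sigma2)
                R = Y - X @ beta[k]                      # (N, T)
                G = D[k] @ Z.T @ cho_solve((c, low), np.eye(Y.shape[1]))
                B = R @ G.T                              # (N, 3) posterior means
                C = D[k] - G @ Z @ D[k]                  # shared posterior cov
                new_D[k] = ((resp[:, k, None, None]
                             * np.einsum("ia,ib->iab", B, B)).sum(axis=0)
                            / max(n_k[k], 1e-12)) + C
                new_D[k] = _floor_psd(0.5 * (new_D[k] + new_D[k].T),
                                      cfg.variance_floor)
                E = R - B @ Z.T
                sse += float(resp[:, k] @ np.einsum("it,it->i", E, E)
                             + n_k[k] * np.trace(Z @ C @ Z.T))
            D = new_D
            sigma2 = max(sse / (N * Y.shape[1]), cfg.variance_floor)
        if not converged:
            # evaluate the objective at the final parameters
            lam = lam_final
            ll = _component_logliks(Y, beta, D, sigma2, Z, X)
            with np.errstate(divide="ignore"):
                logw = ll + np.log(np.maximum(pi, 1e-300))[None, :]
            J = float(np.sum(logsumexp(logw, axis=1))) + _penalty(pi, lam, N)
            trace.append(J)
            history.append(J)
        return {"pi": pi, "beta": beta, "D": D, "sigma2": sigma2,
                "objective": trace[-1] if trace else history[-1],
                "trace": trace, "history": history,
                "converged": converged, "n_iter": n_iter, "seed": seed}

    def _finalize(self, run: dict) -> tuple[ClusterModel, AssignmentTable]:
        cfg = self.config
        Y = self.profiles.values
        pi, beta, D = run["pi"], run["beta"], run["D"]
        sigma2 = run["sigma2"]
        # merge numerically identical components (unidentifiable duplicates)
        pi, beta, D = _merge_duplicates(pi, beta, D)
        # hard labels for canonical ordering
        ll = _component_logliks(Y, beta, D, sigma2, self.Z, self.X)
        logw = ll + np.log(np.maximum(pi, 1e-300))[None, :]
        hard = np.argmax(logw, axis=1)
        counts = np.bincount(hard, minlength=len(pi))
        order = sorted(range(len(pi)), key=lambda k: (-counts[k], beta[k, 0]))
        pi, beta, D = pi[order], beta[order], D[order]
        model = ClusterModel(
            K=len(pi), pi=pi, beta=beta, D=D, sigma2=sigma2,
            X=self.X, Z=self.Z, age_grid=self.profiles.age_grid,
            objective_trace=run["trace"], objective_history=run["history"],
            converged=run["converged"], n_iter=run["n_iter"],
            lambda_penalty=cfg.lambda_penalty, seed=cfg.seed)
        assign = assign_labels(model, self.profiles)
        return model, assign


def _merge_duplicates(pi, beta, D, atol: float = 1e-6):
    """Pool components whose (beta, D) coincide within ``atol``.

    Identical components are unidentifiable (any weight split gives the same
    mixture density); they arise only on degenerate inputs such as a set of
    identical profiles.
    """
    K = len(pi)
    groups: list[list[int]] = []
    for k in range(K):
        for g in groups:
            j = g[0]
            if (np.allclose(beta[k], beta[j], atol=atol)
                    and np.allclose(D[k], D[j], atol=atol)):
                g.append(k)
                break
        else:
            groups.append([k])
    if len(groups) == K:
        return pi, beta, D
    new_pi = np.array([pi[g].sum() for g in groups])
    new_beta = np.stack([beta[g[0]] for g in groups])
    new_D = np.stack([D[g[0]] for g in groups])
    new_pi /= new_pi.sum()
    return new_pi, new_beta, new_D


def assign_labels(model: ClusterModel, profiles: ProfileSet) -> AssignmentTable:
    """Posterior responsibilities and hard labels under a fitted model.

    ``resp_ik \\propto pi_k f_k(y_i)``; the hard label is the argmax with ties
    broken toward the lowest cluster index.
    """
    ll = _component_logliks(profiles.values, model.beta, model.D, model.sigma2,
                            model.Z, model.X)
    with np.errstate(divide="ignore"):
        logw = ll + np.log(np.maximum(model.pi, 1e-300))[None, :]
    logZ = logsumexp(logw, axis=1)
    resp = np.exp(logw - logZ[:, None])
    resp /= resp.sum(axis=1, keepdims=True)
    labels = np.argmax(resp, axis=1) + 1   # argmax takes the first maximum
    return AssignmentTable(list(profiles.object_ids), resp, labels)


class TemporalMixtureResults:
    """Fitted-model container: parameters, assignments, diagnostics."""

    def __init__(self, model_obj: TemporalMixture, cluster_model: ClusterModel,
                 assignments: AssignmentTable):
        self.model = model_obj
        self.cluster_model = cluster_model
        self.assignments = assignments

    def _parts(self):
        return self.cluster_model, self.assignments

    @property
    def K(self) -> int:
        return self.cluster_model.K

    @property
    def converged(self) -> bool:
        return self.cluster_model.converged

    def summary(self) -> pd.DataFrame:
        """Per-cluster table: size, mixing weight, mean-curve coefficients."""
        cm = self.cluster_model
        counts = np.bincount(self.assignments.labels - 1, minlength=cm.K)
        rows = []
        for k in range(cm.K):
            rows.append({
                "cluster": k + 1,
                "n_profiles": int(counts[k]),
                "pi": cm.pi[k],
                "beta0": cm.beta[k, 0], "beta1": cm.beta[k, 1],
                "beta2": cm.beta[k, 2], "beta3": cm.beta[k, 3],
                "tr_D": float(np.trace(cm.D[k])),
            })
        df = pd.DataFrame(rows).set_index("cluster")
        df.attrs["sigma2"] = cm.sigma2
        df.attrs["converged"] = cm.converged
        df.attrs["n_iter"] = cm.n_iter
        return df

    def label_maps(self) -> tuple[dict[str, int], dict[str, int]]:
        """(male, female) gene -> cluster label dictionaries."""
        return self.assignments.label_map("M"), self.assignments.label_map("F")

    def save(self, model_path, labels_path=None) -> None:
        self.cluster_model.to_json(model_path)
        if labels_path is not None:
            self.assignments.to_frame().to_csv(labels_path, sep="\t",
                                               float_format="%.6g")
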