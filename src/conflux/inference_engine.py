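"""Damped loopy belief propagation with counting-factor messages.

The schedule is two-tier, reflecting how fast different message groups
change: each outer sweep updates the variant-level messages (X, Y, Q) once,
then relaxes the tightly-coupled gene/phenotype subgraph (G, H, pheno,
network and sparsity factors) for up to ``inner_loop_max`` damped sweeps or
until its local convergence.

Factors whose value depends only on the *count* of active inputs (the
noisy-OR phenotype factor and the geometric sparsity factor) get special
treatment.  The generic machinery is a binary sum tree over count
distributions (:func:`counting_factor_messages`), checked against a direct
convolution oracle (:func:`counting_factor_messages_naive`).  Both model
potentials happen to be affine in ``r**count``, for which the exact
factor-to-variable messages collapse to a closed form
(:func:`exponential_count_messages`); the engine uses that closed form,
which is tested to agree with the sum tree.

Messages are kept normalized; products of many messages are accumulated as
sums of logs (binary messages as log-odds) for numerical stability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.special import expit, logit

from .model_core import FactorGraph, phi2_cpt, phi4_potential
from .network_prior import max_contribution_log_odds

__all__ = [
    "InferenceConfig",
    "MarginalTable",
    "BeliefPropagation",
    "run_inference",
    "damped_update",
    "counting_factor_messages",
    "counting_factor_messages_naive",
    "exponential_count_messages",
    "exact_marginals_bruteforce",
    "rank_patient_aberrations",
]

_CLAMP_LOG_ODDS = 50.0  # effectively 0/1 while keeping arithmetic finite


@dataclass(frozen=True)
class InferenceConfig:
    """Loopy-BP schedule parameters.

    alpha:
        damping weight on the old message (convex combination in
        probability space); 0 disables damping.
    inner_loop_max:
        sweeps of the gene/phenotype subgraph per outer sweep.
    outer_max_iterations / convergence_tol:
        the outer loop stops when no posterior marginal moves by more than
        the tolerance between sweeps.
    seed:
        accepted for interface stability; the schedule is deterministic
        (synchronous updates in fixed input/lexicographic order), so the
        seed has no effect on results.
    """

    alpha: float = 0.5
    inner_loop_max: int = 10
    outer_max_iterations: int = 200
    convergence_tol: float = 1e-4
    inner_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0,1), got {self.alpha}")
        if self.convergence_tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class MarginalTable:
    """Posterior marginals: the method's output.

    gene_posterior:
        P(H_g = 1) per gene -- the headline ranking.
    g_posterior:
        per (gene, individual) distribution over G in {0,1,2}.
    x_posterior:
        P(X_i = 1) per variant.
    y_posterior:
        per carried (variant, individual): P(Y >= 1), the basis of the
        per-patient aberration ranking.
    """

    gene_posterior: pd.Series
    g_posterior: pd.DataFrame
    x_posterior: pd.Series
    y_posterior: pd.DataFrame
    converged: bool = True
    n_iterations: int = 0


def damped_update(old: np.ndarray, new: np.ndarray, alpha: float) -> np.ndarray:
    """Convex combination alpha*old + (1-alpha)*new, renormalized per row."""
    old = np.asarray(old, dtype=float)
    new = np.asarray(new, dtype=float)
    if old.shape != new.shape:
        raise ValueError(f"message support mismatch: {old.shape} vs {new.shape}")
    mixed = alpha * old + (1.0 - alpha) * new
    norm = mixed.sum(axis=-1, keepdims=True)
    return mixed / norm


# ---------------------------------------------------------------------------
# counting-factor (cardinality potential) messages
# ---------------------------------------------------------------------------


def _as_potential_array(potential, n: int) -> np.ndarray:
    if callable(potential):
        f = np.array([float(potential(c)) for c in range(n + 1)])
    else:
        f = np.asarray(potential, dtype=float)
        if len(f) < n + 1:
            raise ValueError(f"potential must cover counts 0..{n}")
        f = f[: n + 1]
    if (f < 0).any():
        raise ValueError("potential values must be non-negative")
    return f


def _conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if len(a) + len(b) > 1024:
        out = fftconvolve(a, b)
        return np.clip(out, 0.0, None)
    return np.convolve(a, b)


def counting_factor_messages(incoming: Sequence, potential
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Messages through a factor that depends only on the active count.

    ``incoming`` is a sequence of n binary messages (pairs summing to 1);
    ``potential`` is a function (or array) over counts 0..n.  Returns the
    (n, 2) outgoing messages and the factor's belief over the count.

    Internally a balanced binary tree over partial-sum distributions is
    used: an upward pass convolves child count distributions, a downward
    pass pushes expected-potential weights back, so each leaf receives its
    exact cavity message.  With FFT convolutions at the larger internal
    nodes the cost is O(n log^2 n).
    """
    msgs = np.atleast_2d(np.asarray(incoming, dtype=float))
    n = len(msgs) if msgs.size else 0
    f = _as_potential_array(potential, n)
    if n == 0:
        z = float(f[0])
        return np.zeros((0, 2)), np.array([1.0 if z > 0 else 0.0])

    up_cache: dict[tuple[int, int], np.ndarray] = {}

    def upward(lo: int, hi: int) -> np.ndarray:
        key = (lo, hi)
        if key not in up_cache:
            if hi - lo == 1:
                up_cache[key] = msgs[lo].copy()
            else:
                mid = (lo + hi) // 2
                up_cache[key] = _conv(upward(lo, mid), upward(mid, hi))
        return up_cache[key]

    root = upward(0, n)
    outgoing = np.empty((n, 2))

    def downward(lo: int, hi: int, d: np.ndarray) -> None:
        # d[c] = sum over outside configurations of P(outside) * f(c + outside)
        if hi - lo == 1:
            outgoing[lo] = d[:2]
            return
        mid = (lo + hi) // 2
        u_left, u_right = up_cache[(lo, mid)], up_cache[(mid, hi)]
        # d_left(a) = sum_b u_right(b) d(a+b): correlation, then slice
        full = _conv(d, u_right[::-1])
        d_left = full[len(u_right) - 1: len(u_right) - 1 + len(u_left)]
        full = _conv(d, u_left[::-1])
        d_right = full[len(u_left) - 1: len(u_left) - 1 + len(u_right)]
        # rescale to dodge under/overflow; messages are normalized at the end
        downward(lo, mid, d_left / max(d_left.max(), 1e-300))
        downward(mid, hi, d_right / max(d_right.max(), 1e-300))

    downward(0, n, f.copy())
    norm = outgoing.sum(axis=1, keepdims=True)
    if (norm <= 0).any():
        raise FloatingPointError("counting factor produced a zero message")
    outgoing /= norm
    count_belief = root * f
    z = count_belief.sum()
    if z <= 0:
        raise FloatingPointError("counting factor has zero partition function")
    return outgoing, count_belief / z


def counting_factor_messages_naive(incoming: Sequence, potential,
                                   max_n: int = 20
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Direct O(n^2) convolution reference for the sum-tree messages."""
    msgs = np.atleast_2d(np.asarray(incoming, dtype=float))
    n = len(msgs) if msgs.size else 0
    if n > max_n:
        raise ValueError(f"naive counting messages refused for n={n} > {max_n}")
    f = _as_potential_array(potential, n)
    if n == 0:
        return np.zeros((0, 2)), np.array([1.0])
    prefix = [np.array([1.0])]
    for k in range(n):
        prefix.append(np.convolve(prefix[-1], msgs[k]))
    suffix = [np.array([1.0])]
    for k in range(n - 1, -1, -1):
        suffix.append(np.convolve(msgs[k], suffix[-1]))
    suffix.reverse()
    outgoing = np.empty((n, 2))
    for k in range(n):
        cav = np.convolve(prefix[k], suffix[k + 1])  # counts 0..n-1
        outgoing[k, 0] = float(cav @ f[: n])
        outgoing[k, 1] = float(cav @ f[1: n + 1])
    outgoing /= outgoing.sum(axis=1, keepdims=True)
    count_belief = prefix[-1] * f
    return outgoing, count_belief / count_belief.sum()


def exponential_count_messages(incoming: Sequence, u: float, v: float,
                               r: float) -> np.ndarray:
    """Closed-form counting messages for f(c) = u + v * r**c.

    The cavity expectation factorizes: E[f(c_other + x)] =
    u + v * r**x * prod_{j != i}(m_j0 + m_j1 * r), giving exact O(n)
    messages.  Used for the noisy-OR phenotype factor
    (u = 1, v = -(1 - eps_bg), r = 1 - p_pen; case side) and the geometric
    sparsity factor (u = 0, v = 1, r = gamma).
    """
    msgs = np.atleast_2d(np.asarray(incoming, dtype=float))
    n = len(msgs) if msgs.size else 0
    if n == 0:
        return np.zeros((0, 2))
    w = msgs[:, 0] + r * msgs[:, 1]
    log_w = np.log(w)
    cav = np.exp(log_w.sum() - log_w)  # prod over j != i
    out = np.stack([u + v * cav, u + v * r * cav], axis=1)
    if (out < 0).any():
        raise FloatingPointError("exponential count potential went negative")
    return out / out.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------


class BeliefPropagation:
    """Vectorized two-tier loopy BP state over a :class:`FactorGraph`.

    ``clamp_h`` fixes chosen H variables to 0/1 (used for diagnostics such
    as the network-ceiling check).
    """

    def __init__(self, graph: FactorGraph, config: InferenceConfig | None = None,
                 clamp_h: dict[str, int] | None = None):
        self.graph = graph
        self.config = config or InferenceConfig()
        mc, pc = graph.model_config, graph.prior_config
        self._tau_lo = float(logit(pc.tau))
        self._rho_lo = math.log(mc.gamma)
        self._cap_lo = max_contribution_log_odds(pc)
        self._A = 1.0 - mc.eps_bg
        self._r = 1.0 - mc.p_pen
        self._cpt = phi2_cpt(mc)
        self._log_cpt = np.log(self._cpt)
        n_pairs, n_y = graph.n_q_nodes, graph.n_y_nodes
        n_genes, n_var = graph.n_h_nodes, graph.n_x_nodes
        self._xp_lo = logit(graph.x_prior)
        # stored (damped) messages, all normalized
        self.msg_phi2_to_q = np.full((n_pairs, 3), 1.0 / 3.0)
        self.msg_phi2_to_y = np.full((n_y, 2), 0.5)  # states: Y=0, Y=dose
        self.msg_phi3_to_q = np.full((n_pairs, 3), 1.0 / 3.0)
        self.msg_phi3_to_h_lo = np.zeros(n_pairs)
        self.msg_phi4_to_g = np.full((n_pairs, 2), 0.5)  # states: G=0, G>=1
        self.msg_phi3_to_g = np.full((n_pairs, 3), 1.0 / 3.0)
        self.x_log_odds = self._xp_lo.copy()
        self._y_cavity = np.full((n_y, 2), 0.5)
        self._clamp_idx = np.array([], dtype=np.int64)
        self._clamp_lo = np.array([], dtype=float)
        if clamp_h:
            gene_pos = {g: k for k, g in enumerate(graph.genes)}
            idx, vals = [], []
            for gene, state in clamp_h.items():
                idx.append(gene_pos[gene])
                vals.append(_CLAMP_LOG_ODDS if state else -_CLAMP_LOG_ODDS)
            self._clamp_idx = np.asarray(idx, dtype=np.int64)
            self._clamp_lo = np.asarray(vals, dtype=float)
        self.h_log_odds = np.full(n_genes, self._tau_lo + self._rho_lo)
        self._apply_clamp()
        # pairs with more than one carried variant need the capped-sum DP
        sizes = graph.pair_y_stop - graph.pair_y_start
        self._single = np.flatnonzero(sizes == 1)
        self._multi = np.flatnonzero(sizes >= 2)
        self.n_outer_iterations = 0
        self.last_inner_sweeps = 0
        self.converged = False

    # -- helpers ---------------------------------------------------------

    def _apply_clamp(self) -> None:
        if len(self._clamp_idx):
            self.h_log_odds[self._clamp_idx] = self._clamp_lo

    def _damp(self, old: np.ndarray, new: np.ndarray) -> np.ndarray:
        return damped_update(old, new, self.config.alpha)

    @staticmethod
    def _member_dist(msg: np.ndarray, dose: np.ndarray) -> np.ndarray:
        """Y message as a distribution over capped-sum states {0,1,2}."""
        out = np.zeros((len(msg), 3))
        out[:, 0] = msg[:, 0]
        out[np.arange(len(msg)), dose] = msg[:, 1]
        return out

    # -- tier 1: variant-level messages ---------------------------------

    def _sweep_variant_tier(self) -> None:
        g = self.graph
        if g.n_y_nodes == 0:
            return
        lam = np.log(self.msg_phi2_to_y[:, 1]) - np.log(self.msg_phi2_to_y[:, 0])
        self.x_log_odds = self._xp_lo + np.bincount(
            g.y_variant, weights=lam, minlength=g.n_x_nodes)
        cav_lo = self.x_log_odds[g.y_variant] - lam
        m_y1 = expit(cav_lo)
        self._y_cavity = np.stack([1.0 - m_y1, m_y1], axis=1)
        if not np.isfinite(self._y_cavity).all():
            raise FloatingPointError("non-finite message at the Y = X*D link factor")

        new_to_q = np.empty_like(self.msg_phi2_to_q)
        new_to_y = np.empty_like(self.msg_phi2_to_y)
        # single-variant pairs: the capped sum IS the member state
        if len(self._single):
            t = g.pair_y_start[self._single]
            dose = g.y_dose[t]
            s_dist = self._member_dist(self._y_cavity[t], dose)
            new_to_q[self._single] = s_dist @ self._cpt
            m_q = self.msg_phi3_to_q[self._single]
            new_to_y[t, 0] = (m_q * self._cpt[0]).sum(axis=1)
            new_to_y[t, 1] = (m_q * self._cpt[dose]).sum(axis=1)
        for p in self._multi:
            sl = slice(g.pair_y_start[p], g.pair_y_stop[p])
            member = self._member_dist(self._y_cavity[sl], g.y_dose[sl])
            k = member.shape[0]
            prefix = np.zeros((k + 1, 3))
            prefix[0, 0] = 1.0
            for m in range(k):
                prefix[m + 1] = _capped_conv(prefix[m], member[m])
            suffix = np.zeros((k + 1, 3))
            suffix[k, 0] = 1.0
            for m in range(k - 1, -1, -1):
                suffix[m] = _capped_conv(member[m], suffix[m + 1])
            new_to_q[p] = prefix[k] @ self._cpt
            m_q = self.msg_phi3_to_q[p]
            q_weight = self._cpt @ m_q  # by capped-sum state
            for m in range(k):
                cav = _capped_conv(prefix[m], suffix[m + 1])
                t = g.pair_y_start[p] + m
                dose = g.y_dose[t]
                shifted = np.zeros(3)
                shifted[dose:] = cav[: 3 - dose]
                shifted[2] += cav[3 - dose:].sum()
                new_to_y[t, 0] = cav @ q_weight
                new_to_y[t, 1] = shifted @ q_weight
        new_to_q /= new_to_q.sum(axis=1, keepdims=True)
        new_to_y /= new_to_y.sum(axis=1, keepdims=True)
        self.msg_phi2_to_q = self._damp(self.msg_phi2_to_q, new_to_q)
        self.msg_phi2_to_y = self._damp(self.msg_phi2_to_y, new_to_y)

    # -- tier 2: gene/phenotype subgraph --------------------------------

    def _sweep_gene_tier_once(self) -> float:
        g = self.graph
        n_pairs = g.n_q_nodes
        h_old = expit(self.h_log_odds)
        if n_pairs:
            # phi3 -> G
            cav_lo = self.h_log_odds[g.pair_gene] - self.msg_phi3_to_h_lo
            mh1 = expit(cav_lo)
            mh0 = 1.0 - mh1
            m_q = self.msg_phi2_to_q
            new_g = np.stack([mh0 + mh1 * m_q[:, 0],
                              mh1 * m_q[:, 1],
                              mh1 * m_q[:, 2]], axis=1)
            new_g /= new_g.sum(axis=1, keepdims=True)
            self.msg_phi3_to_g = self._damp(self.msg_phi3_to_g, new_g)

            # phi4 -> G (closed-form exponential count messages per individual)
            b1 = self.msg_phi3_to_g[:, 1] + self.msg_phi3_to_g[:, 2]
            w = self.msg_phi3_to_g[:, 0] + self._r * b1
            log_z = np.bincount(g.pair_indiv, weights=np.log(w),
                                minlength=len(g.individuals))
            z_cav = np.exp(log_z[g.pair_indiv] - np.log(w))
            is_case = g.pheno[g.pair_indiv] == 1
            mu0 = np.where(is_case, 1.0 - self._A * z_cav, 1.0)
            mu1 = np.where(is_case, 1.0 - self._A * self._r * z_cav, self._r)
            new_phi4 = np.stack([mu0, mu1], axis=1)
            if (new_phi4 <= 0).any() or not np.isfinite(new_phi4).all():
                raise FloatingPointError("non-finite/zero message at a phi4 factor")
            new_phi4 /= new_phi4.sum(axis=1, keepdims=True)
            self.msg_phi4_to_g = self._damp(self.msg_phi4_to_g, new_phi4)

            # phi3 -> H and phi3 -> Q use the ternary expansion of phi4 -> G
            tern = np.stack([self.msg_phi4_to_g[:, 0],
                             self.msg_phi4_to_g[:, 1],
                             self.msg_phi4_to_g[:, 1]], axis=1)
            tern /= tern.sum(axis=1, keepdims=True)
            mu_h1 = (tern * m_q).sum(axis=1)
            mu_h0 = tern[:, 0]
            p1 = mu_h1 / (mu_h0 + mu_h1)
            p1_old = expit(self.msg_phi3_to_h_lo)
            p1 = self.config.alpha * p1_old + (1.0 - self.config.alpha) * p1
            self.msg_phi3_to_h_lo = logit(np.clip(p1, 1e-15, 1.0 - 1e-15))

            new_q = np.stack([mh0 * tern[:, 0] + mh1 * tern[:, 0],
                              mh0 * tern[:, 0] + mh1 * tern[:, 1],
                              mh0 * tern[:, 0] + mh1 * tern[:, 2]], axis=1)
            new_q /= new_q.sum(axis=1, keepdims=True)
            self.msg_phi3_to_q = self._damp(self.msg_phi3_to_q, new_q)

        # Theta contributions from current source beliefs, capped per target
        theta = np.zeros(g.n_h_nodes)
        if g.n_theta_factors:
            b_src = expit(self.h_log_odds[g.theta_source])
            delta = g.theta_delta
            num = 0.5 * (1.0 - b_src) + delta * b_src
            den = 0.5 * (1.0 - b_src) + (1.0 - delta) * b_src
            contrib = np.log(num) - np.log(den)
            theta = np.bincount(g.theta_target, weights=contrib,
                                minlength=g.n_h_nodes)
            theta = np.minimum(theta, self._cap_lo)
        data_lo = (np.bincount(g.pair_gene, weights=self.msg_phi3_to_h_lo,
                               minlength=g.n_h_nodes)
                   if n_pairs else np.zeros(g.n_h_nodes))
        self.h_log_odds = self._tau_lo + self._rho_lo + theta + data_lo
        self._apply_clamp()
        if not np.isfinite(self.h_log_odds).all():
            raise FloatingPointError("non-finite H belief after Theta/phi3 update")
        return float(np.abs(expit(self.h_log_odds) - h_old).max(initial=0.0))

    # -- schedule --------------------------------------------------------

    def two_tier_sweep(self) -> float:
        """One outer sweep; returns the max marginal change it produced."""
        x_old = expit(self.x_log_odds)
        h_old = expit(self.h_log_odds)
        self._sweep_variant_tier()
        self.last_inner_sweeps = 0
        for _ in range(self.config.inner_loop_max):
            delta = self._sweep_gene_tier_once()
            self.last_inner_sweeps += 1
            if delta < self.config.inner_tol:
                break
        dx = np.abs(expit(self.x_log_odds) - x_old).max(initial=0.0)
        dh = np.abs(expit(self.h_log_odds) - h_old).max(initial=0.0)
        return float(max(dx, dh))

    def run(self) -> MarginalTable:
        self.converged = False
        for it in range(1, self.config.outer_max_iterations + 1):
            delta = self.two_tier_sweep()
            self.n_outer_iterations = it
            if delta < self.config.convergence_tol:
                self.converged = True
                break
        return self.marginals()

    def marginals(self) -> MarginalTable:
        g = self.graph
        gene_post = pd.Series(expit(self.h_log_odds), index=g.genes,
                              name="posterior")
        x_post = pd.Series(expit(self.x_log_odds), index=g.variants,
                           name="posterior")
        tern = np.stack([self.msg_phi4_to_g[:, 0],
                         self.msg_phi4_to_g[:, 1],
                         self.msg_phi4_to_g[:, 1]], axis=1)
        g_belief = self.msg_phi3_to_g * tern
        norm = g_belief.sum(axis=1, keepdims=True)
        g_belief = np.divide(g_belief, norm, out=np.full_like(g_belief, 1 / 3),
                             where=norm > 0)
        g_post = pd.DataFrame({
            "gene": [g.genes[k] for k in g.pair_gene],
            "individual": [g.individuals[k] for k in g.pair_indiv],
            "p0": g_belief[:, 0], "p1": g_belief[:, 1], "p2": g_belief[:, 2],
        })
        y_belief1 = self._y_cavity[:, 1] * self.msg_phi2_to_y[:, 1]
        y_belief0 = self._y_cavity[:, 0] * self.msg_phi2_to_y[:, 0]
        p_active = y_belief1 / (y_belief0 + y_belief1)
        y_post = pd.DataFrame({
            "variant": [g.variants[k] for k in g.y_variant],
            "individual": [g.individuals[k] for k in g.pair_indiv[g.y_pair]],
            "p_active": p_active,
        })
        return MarginalTable(gene_posterior=gene_post, g_posterior=g_post,
                             x_posterior=x_post, y_posterior=y_post,
                             converged=self.converged,
                             n_iterations=self.n_outer_iterations)


def _capped_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Convolution of two capped-sum distributions over {0, 1, 2+}."""
    full = np.convolve(a, b)
    out = full[:3].copy()
    out[2] += full[3:].sum()
    return out


def run_inference(graph: FactorGraph, config: InferenceConfig | None = None,
                  clamp_h: dict[str, int] | None = None) -> MarginalTable:
    """Run damped two-tier loopy BP and return posterior marginals."""
    return BeliefPropagation(graph, config, clamp_h=clamp_h).run()


def rank_patient_aberrations(table: MarginalTable, individual: str) -> list[str]:
    """Carried variants of one individual, most-likely-damaging first.

    Sorted by posterior P(Y >= 1) descending, ties broken by variant id.
    """
    known = set(table.g_posterior["individual"]) | set(table.y_posterior["individual"])
    if individual not in known:
        raise KeyError(f"unknown individual (or no carried variants): {individual!r}")
    sub = table.y_posterior[table.y_posterior["individual"] == individual]
    ordered = sub.sort_values(["p_active", "variant"],
                              ascending=[False, True], kind="mergesort")
    return list(ordered["variant"])


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle
# ---------------------------------------------------------------------------


def exact_marginals_bruteforce(graph: FactorGraph,
                               clamp_h: dict[str, int] | None = None,
                               max_states: int = 2_000_000) -> MarginalTable:
    """Exact marginals by enumerating the full joint of the model.

    The directed network factors enter the joint as ordinary pairwise
    potentials and no runtime capping is applied, so this is the literal
    distribution the factor tables define.  Intended as a test oracle on
    tiny graphs only.
    """
    g = graph
    mc, pc = g.model_config, g.prior_config
    n_v, n_g, n_p = g.n_x_nodes, g.n_h_nodes, g.n_q_nodes
    total = (2 ** n_v) * (2 ** n_g) * (3 ** n_p)
    if total > max_states:
        raise ValueError(f"state space {total} exceeds {max_states}")

    log_cpt = np.log(phi2_cpt(mc))
    # enumerate H configurations (respecting clamps)
    h_configs = np.array(list(itertools.product([0, 1], repeat=n_g)), dtype=np.int8)
    if clamp_h:
        for gene, state in clamp_h.items():
            k = g.genes.index(gene)
            h_configs = h_configs[h_configs[:, k] == state]
    q_configs = (np.array(list(itertools.product([0, 1, 2], repeat=n_p)),
                          dtype=np.int8) if n_p else np.zeros((1, 0), dtype=np.int8))

    # per-H-config log prior terms (tau, rho, Theta)
    log_tau = (h_configs * math.log(pc.tau)
               + (1 - h_configs) * math.log1p(-pc.tau)).sum(axis=1)
    log_rho = h_configs.sum(axis=1) * math.log(mc.gamma)
    log_theta = np.zeros(len(h_configs))
    for e in range(g.n_theta_factors):
        hs = h_configs[:, g.theta_source[e]]
        ht = h_configs[:, g.theta_target[e]]
        d = g.theta_delta[e]
        val = np.where(hs == 0, 0.5, np.where(ht == 1, d, 1.0 - d))
        log_theta += np.log(val)
    log_h_terms = log_tau + log_rho + log_theta

    # per-individual phi4 lookup tables over counts 0..n_p
    phi4_tables = np.array(
        [[phi4_potential(int(g.pheno[j]), c, mc) for c in range(n_p + 1)]
         for j in range(len(g.individuals))])
    pair_active = q_configs > 0  # (B, P)

    # accumulators
    blocks = []  # (shift, Z, sums dict)
    x_iter = itertools.product([0, 1], repeat=n_v) if n_v else iter([()])
    for x in x_iter:
        x = np.asarray(x, dtype=np.int8)
        log_px = float((x * np.log(g.x_prior)
                        + (1 - x) * np.log1p(-g.x_prior)).sum()) if n_v else 0.0
        # capped sum per pair given X
        s_pair = np.zeros(n_p, dtype=np.int64)
        for p in range(n_p):
            sl = slice(g.pair_y_start[p], g.pair_y_stop[p])
            s_pair[p] = min(2, int((g.y_dose[sl] * x[g.y_variant[sl]]).sum()))
        # phi2 term per Q config
        lp2 = (log_cpt[s_pair[None, :], q_configs].sum(axis=1)
               if n_p else np.zeros(1))
        # phi4 term per (H config, Q config)
        lp_hq = np.zeros((len(h_configs), len(q_configs)))
        for j in range(len(g.individuals)):
            pj = np.flatnonzero(g.pair_indiv == j)
            if len(pj) == 0:
                lp_hq += math.log(phi4_tables[j][0])
                continue
            # counts: (A, B)
            act = (h_configs[:, g.pair_gene[pj]][:, None, :]
                   * pair_active[None, :, pj]).sum(axis=2)
            lp_hq += np.log(phi4_tables[j][act])
        log_l = (log_px + log_h_terms[:, None] + lp2[None, :] + lp_hq)
        shift = float(log_l.max())
        w = np.exp(log_l - shift)
        z = float(w.sum())
        sums = {
            "h": w.sum(axis=1) @ h_configs,                      # (n_g,)
            "x": z * x.astype(float),                            # (n_v,)
            "g_state": np.zeros((n_p, 3)),
            "y": np.zeros(len(g.y_variant)),
        }
        if n_p:
            g_state = (h_configs[:, g.pair_gene][:, None, :]
                       * q_configs[None, :, :])  # (A, B, P)
            for s in range(3):
                sums["g_state"][:, s] = (w[:, :, None] * (g_state == s)).sum(axis=(0, 1))
        if n_v and len(g.y_variant):
            sums["y"] = z * (x[g.y_variant] * g.y_dose > 0).astype(float)
        blocks.append((shift, z, sums))

    shift_max = max(s for s, _, _ in blocks)
    z_total = sum(z * math.exp(s - shift_max) for s, z, _ in blocks)
    h_marg = sum(b["h"] * math.exp(s - shift_max) for s, _, b in blocks) / z_total
    x_marg = (sum(b["x"] * math.exp(s - shift_max) for s, _, b in blocks) / z_total
              if n_v else np.zeros(0))
    g_marg = sum(b["g_state"] * math.exp(s - shift_max)
                 for s, _, b in blocks) / z_total
    y_marg = sum(b["y"] * math.exp(s - shift_max) for s, _, b in blocks) / z_total

    gene_post = pd.Series(h_marg, index=g.genes, name="posterior")
    x_post = pd.Series(x_marg, index=g.variants, name="posterior")
    g_post = pd.DataFrame({
        "gene": [g.genes[k] for k in g.pair_gene],
        "individual": [g.individuals[k] for k in g.pair_indiv],
        "p0": g_marg[:, 0] if n_p else [],
        "p1": g_marg[:, 1] if n_p else [],
        "p2": g_marg[:, 2] if n_p else [],
    })
    y_post = pd.DataFrame({
        "variant": [g.variants[k] for k in g.y_variant],
        "individual": [g.individuals[k] for k in g.pair_indiv[g.y_pair]],
        "p_active": y_marg,
    })
    return MarginalTable(gene_posterior=gene_post, g_posterior=g_post,
                         x_posterior=x_post, y_posterior=y_post,
                         converged=True, n_iterations=0)
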