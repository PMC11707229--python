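"""Trait-association statistics on genomes and phylogenies.

Three questions, three tests:

* Are two categorical traits (pathway repertoire, O2 metabolism) associated
  across genomes?  A permutation test on the G statistic (likelihood-ratio
  chi-square of the cross-table), permuting one trait's labels.
* Does a categorical trait carry phylogenetic signal?  A randomization test
  on the Fitch parsimony score: traits that track the tree need fewer state
  changes than tip-shuffled versions.
* Do two binary traits evolve *dependently* on the tree?  The classic
  likelihood-ratio test comparing an independent model (two 2-state Markov
  processes, 4 free rates) with a dependent model (a 4-state chain over the
  joint states 00/01/10/11 with 8 single-change rates; simultaneous double
  changes forbidden), 2*dlogL ~ chi-square with 4 df.

Likelihoods use Felsenstein pruning with closed-form 2-state transition
probabilities, or an eigendecomposition of the 4-state rate matrix.  Rates
are optimized in log space with box bounds and multiple starts; the dependent
model is always additionally started from the fitted independent model, which
makes the nesting inequality (dependent logL >= independent logL) hold by
construction up to optimizer tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import xlogy
from scipy.stats import chi2

__all__ = [
    "TestResult",
    "TreeIndex",
    "g_statistic",
    "permutation_association_test",
    "fitch_parsimony",
    "phylo_signal_test",
    "mk_loglik",
    "fit_mk",
    "dependent_loglik",
    "pagel_discrete_lrt",
    "metabolism_by_repertoire",
    "subsample_species",
    "METABOLISM_CATEGORIES",
    "DEPENDENT_RATE_NAMES",
]

METABOLISM_CATEGORIES = ("aerobic", "facultative", "microaerophilic", "anaerobic")

#: Dependent-model rate names over joint states 1=00, 2=01, 3=10, 4=11
#: (first bit = trait A, second bit = trait B; qXY = instantaneous rate X->Y).
DEPENDENT_RATE_NAMES = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")

_TRANSITIONS = {  # rate name -> (from state index, to state index)
    "q12": (0, 1), "q13": (0, 2), "q21": (1, 0), "q24": (1, 3),
    "q31": (2, 0), "q34": (2, 3), "q42": (3, 1), "q43": (3, 2),
}


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    statistic: float
    p_value: float
    null: str
    n_permutations: int | None = None
    df: int | None = None
    details: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, for printing in examples
        extra = f", df={self.df}" if self.df is not None else ""
        extra += f", n_perm={self.n_permutations}" if self.n_permutations else ""
        return (
            f"TestResult(statistic={self.statistic:.4g}, "
            f"p_value={self.p_value:.4g}{extra})"
        )


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------

def g_statistic(table: np.ndarray | pd.DataFrame) -> float:
    """Likelihood-ratio chi-square G = 2 sum O ln(O/E) over non-empty cells.

    Expected counts come from the row/column margins; G >= 0 with equality
    exactly for a table proportional to its margins.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    total = obs.sum()
    if total == 0:
        return 0.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(obs > 0, obs / expected, 1.0)
    return float(2.0 * np.sum(xlogy(obs, ratio)))


def _align_traits(
    trait_a: Mapping[str, object] | pd.Series, trait_b: Mapping[str, object] | pd.Series
) -> tuple[np.ndarray, np.ndarray, list]:
    sa = pd.Series(dict(trait_a) if not isinstance(trait_a, pd.Series) else trait_a)
    sb = pd.Series(dict(trait_b) if not isinstance(trait_b, pd.Series) else trait_b)
    shared = sorted(set(sa.index) & set(sb.index))
    if not shared:
        raise ValueError("traits are defined on disjoint genome sets")
    a = pd.Categorical(sa.loc[shared]).codes.astype(np.int64)
    b = pd.Categorical(sb.loc[shared]).codes.astype(np.int64)
    return a, b, shared


def permutation_association_test(
    trait_a: Mapping[str, object] | pd.Series,
    trait_b: Mapping[str, object] | pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
    statistic: Callable[[np.ndarray], float] | None = None,
) -> TestResult:
    """Permutation test of association between two categorical traits.

    The observed statistic (G by default, pluggable) is compared with its
    distribution under ``n_perm`` random relabellings of ``trait_b``; the
    p-value uses the +1 correction, so it is bounded below by 1/(n_perm+1).
    """
    stat_fn = statistic or g_statistic
    a, b, shared = _align_traits(trait_a, trait_b)
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    rng = np.random.default_rng(seed)

    def table(bv: np.ndarray) -> np.ndarray:
        return np.bincount(a * kb + bv, minlength=ka * kb).reshape(ka, kb)

    obs = stat_fn(table(b))
    n_ge = 0
    bv = b.copy()
    for _ in range(n_perm):
        rng.shuffle(bv)
        if stat_fn(table(bv)) >= obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return TestResult(
        statistic=obs,
        p_value=p,
        null=f"{n_perm} permutations of trait_b labels",
        n_permutations=n_perm,
        details={"n_genomes": len(shared)},
    )


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------

class TreeIndex:
    """Array view of a rooted dendropy tree for fast repeated traversals."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.postorder = list(range(self.n_nodes))
        self.children: list[list[int]] = [[] for _ in nodes]
        self.edge_length = np.zeros(self.n_nodes)
        self.tip_index: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            self.edge_length[i] = nd.edge.length or 0.0
            for ch in nd.child_nodes():
                self.children[i].append(index[id(ch)])
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else str(nd)
                if label in self.tip_index:
                    raise ValueError(f"duplicate tip label {label!r}")
                self.tip_index[label] = i
        self.root = self.n_nodes - 1
        self.n_tips = len(self.tip_index)
        self.is_binary = all(
            len(c) in (0, 2) for c in self.children
        )
        self.tip_ids = np.array(sorted(self.tip_index.values()), dtype=np.int64)
        self.internal_ids = np.array(
            [i for i in self.postorder if self.children[i]], dtype=np.int64
        )
        if self.is_binary:
            self._c0 = np.array(
                [self.children[i][0] for i in self.internal_ids], dtype=np.int64
            )
            self._c1 = np.array(
                [self.children[i][1] for i in self.internal_ids], dtype=np.int64
            )

    def tip_state_array(self, trait: Mapping[str, int], n_states: int) -> np.ndarray:
        """States indexed by node id for tips (-1 elsewhere)."""
        out = np.full(self.n_nodes, -1, dtype=np.int64)
        missing = [t for t in self.tip_index if t not in trait]
        if missing:
            raise ValueError(f"trait missing for tips: {sorted(missing)[:5]} ...")
        for label, i in self.tip_index.items():
            s = int(trait[label])
            if not (0 <= s < n_states):
                raise ValueError(f"state {s} out of range for tip {label!r}")
            out[i] = s
        return out

    @classmethod
    def ensure(cls, tree: "dendropy.Tree | TreeIndex") -> "TreeIndex":
        return tree if isinstance(tree, TreeIndex) else cls(tree)

    def tip_states(self, trait: Mapping[str, int], n_states: int) -> np.ndarray:
        """Tip likelihood matrix (n_nodes, n_states); internal rows untouched."""
        part = np.zeros((self.n_nodes, n_states))
        missing = [t for t in self.tip_index if t not in trait]
        if missing:
            raise ValueError(f"trait missing for tips: {sorted(missing)[:5]} ...")
        for label, i in self.tip_index.items():
            s = int(trait[label])
            if not (0 <= s < n_states):
                raise ValueError(f"state {s} out of range for tip {label!r}")
            part[i, s] = 1.0
        return part


# ---------------------------------------------------------------------------
# parsimony and phylogenetic signal
# ---------------------------------------------------------------------------

def fitch_parsimony(
    tree: "dendropy.Tree | TreeIndex", trait: Mapping[str, object]
) -> int:
    """Minimum number of state changes under unit cost (Fitch two-pass).

    Accepts arbitrary hashable states; multifurcations are folded pairwise,
    which equals the Sankoff unit-cost minimum on binary trees (the generated
    trees here are binary).
    """
    ti = TreeIndex.ensure(tree)
    states = sorted({trait[t] for t in ti.tip_index}, key=repr)
    code = {s: 1 << k for k, s in enumerate(states)}
    masks = np.zeros(ti.n_nodes, dtype=np.int64)
    changes = 0
    for i in ti.postorder:
        kids = ti.children[i]
        if not kids:
            label = next(lbl for lbl, j in ti.tip_index.items() if j == i)
            masks[i] = code[trait[label]]
            continue
        acc = masks[kids[0]]
        for k in kids[1:]:
            inter = acc & masks[k]
            if inter:
                acc = inter
            else:
                acc |= masks[k]
                changes += 1
        masks[i] = acc
    return changes


def _fitch_fast(children: list[list[int]], postorder, tip_ids, tip_masks) -> int:
    """Inner loop of the randomization test: Fitch on precoded bit masks."""
    masks = [0] * len(children)
    for t, m in zip(tip_ids, tip_masks):
        masks[t] = m
    changes = 0
    for i in postorder:
        kids = children[i]
        if not kids:
            continue
        acc = masks[kids[0]]
        for k in kids[1:]:
            inter = acc & masks[k]
            if inter:
                acc = inter
            else:
                acc |= masks[k]
                changes += 1
        masks[i] = acc
    return changes


def phylo_signal_test(
    tree: "dendropy.Tree | TreeIndex",
    trait: Mapping[str, object],
    n_rand: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Randomization test of phylogenetic signal for a categorical trait.

    The statistic is the Fitch parsimony score; the null shuffles trait
    values across tips ``n_rand`` times.  Signal means *fewer* changes than
    random, so the one-sided p-value is
    ``(1 + #{score_rand <= score_obs}) / (1 + n_rand)``.
    """
    ti = TreeIndex.ensure(tree)
    states = sorted({trait[t] for t in ti.tip_index}, key=repr)
    code = {s: 1 << k for k, s in enumerate(states)}
    tips = sorted(ti.tip_index)
    tip_ids = [ti.tip_index[t] for t in tips]
    obs_masks = [code[trait[t]] for t in tips]
    obs = _fitch_fast(ti.children, ti.postorder, tip_ids, obs_masks)
    rng = np.random.default_rng(seed)
    masks = np.array(obs_masks, dtype=np.int64)
    n_le = 0
    for _ in range(n_rand):
        rng.shuffle(masks)
        if _fitch_fast(ti.children, ti.postorder, tip_ids, masks.tolist()) <= obs:
            n_le += 1
    return TestResult(
        statistic=float(obs),
        p_value=(1 + n_le) / (1 + n_rand),
        null=f"{n_rand} tip-label shuffles",
        n_permutations=n_rand,
        details={"n_tips": ti.n_tips, "n_states": len(states)},
    )


# ---------------------------------------------------------------------------
# Mk likelihoods
# ---------------------------------------------------------------------------

def _p2(t: np.ndarray, q01: float, q10: float) -> np.ndarray:
    """Closed-form 2-state transition matrices, shape (len(t), 2, 2)."""
    t = np.asarray(t, dtype=float)
    q = q01 + q10
    out = np.empty((len(t), 2, 2))
    if q == 0:
        out[:] = np.eye(2)
        return out
    e = np.exp(-q * t)
    pi0, pi1 = q10 / q, q01 / q
    out[:, 0, 0] = pi0 + pi1 * e
    out[:, 0, 1] = pi1 - pi1 * e
    out[:, 1, 0] = pi0 - pi0 * e
    out[:, 1, 1] = pi1 + pi0 * e
    return out


def _root_prior(kind, n_states: int, pi: np.ndarray | None = None) -> np.ndarray:
    if isinstance(kind, (list, tuple, np.ndarray)):
        prior = np.asarray(kind, dtype=float)
        if prior.shape != (n_states,) or not math.isclose(prior.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("root prior must be a probability vector")
        return prior
    if kind == "uniform":
        return np.full(n_states, 1.0 / n_states)
    if kind == "stationary":
        if pi is None:
            raise ValueError("stationary prior needs the stationary distribution")
        return pi
    raise ValueError(f"unknown root prior {kind!r}")


def _prune(ti: TreeIndex, tip_part: np.ndarray, P: np.ndarray, prior: np.ndarray) -> float:
    """Pruning log-likelihood given per-edge transition matrices P[i] (child edge)."""
    part = tip_part.copy()
    log_scale = 0.0
    for i in ti.postorder:
        kids = ti.children[i]
        if not kids:
            continue
        acc = np.ones(part.shape[1])
        for k in kids:
            acc = acc * (P[k] @ part[k])
        s = acc.max()
        if s <= 0:
            return -np.inf
        part[i] = acc / s
        log_scale += math.log(s)
    like = float(prior @ part[ti.root])
    if like <= 0:
        return -np.inf
    return math.log(like) + log_scale


def _prune_onehot(
    ti: TreeIndex, tip_states: np.ndarray, P: np.ndarray, prior: np.ndarray
) -> float:
    """Pruning specialised to one-hot tip data on a binary tree.

    Tip messages are gathered in one vectorized step (a tip's message is a
    column of its edge's transition matrix); internal nodes combine children
    in a tight loop.  Falls back to the generic path for non-binary trees.
    """
    if not ti.is_binary:
        n_states = P.shape[1]
        tip_part = np.zeros((ti.n_nodes, n_states))
        tip_part[ti.tip_ids, tip_states[ti.tip_ids]] = 1.0
        return _prune(ti, tip_part, P, prior)
    n_states = P.shape[1]
    msg = np.empty((ti.n_nodes, n_states))
    tips = ti.tip_ids
    msg[tips] = P[tips, :, tip_states[tips]]
    log_scale = 0.0
    c0, c1, internals = ti._c0, ti._c1, ti.internal_ids
    root = ti.root
    for k in range(len(internals)):
        i = internals[k]
        acc = msg[c0[k]] * msg[c1[k]]
        s = acc.max()
        if s <= 0:
            return -np.inf
        log_scale += math.log(s)
        acc /= s
        if i == root:
            like = float(prior @ acc)
            if like <= 0:
                return -np.inf
            return math.log(like) + log_scale
        msg[i] = P[i] @ acc
    raise AssertionError("root not reached in postorder")  # pragma: no cover


def mk_loglik(
    tree: "dendropy.Tree | TreeIndex",
    trait: Mapping[str, int],
    q01: float,
    q10: float,
    root_prior="uniform",
) -> float:
    """Log-likelihood of a binary trait under the 2-state Markov (Mk) model.

    Felsenstein pruning with exact 2-state transition probabilities; the root
    prior is uniform by default, or ``"stationary"`` / an explicit vector.
    """
    ti = TreeIndex.ensure(tree)
    tip_states = ti.tip_state_array(trait, 2)
    P = _p2(ti.edge_length, q01, q10)
    q = q01 + q10
    pi = np.array([q10 / q, q01 / q]) if q > 0 else np.array([0.5, 0.5])
    prior = _root_prior(root_prior, 2, pi)
    return _prune_onehot(ti, tip_states, P, prior)


def fit_mk(
    tree: "dendropy.Tree | TreeIndex",
    trait: Mapping[str, int],
    n_starts: int = 4,
    seed: int | None = None,
    rate_bounds: tuple[float, float] = (1e-6, 100.0),
    root_prior="uniform",
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood 2-state rates ``(q01, q10)`` and the achieved logL.

    Optimizes in log-rate space (L-BFGS-B, box bounds) from ``n_starts``
    starting points: a moderate default plus seeded log-uniform draws.
    """
    ti = TreeIndex.ensure(tree)
    tip_states = ti.tip_state_array(trait, 2)
    prior_kind = root_prior
    lo, hi = rate_bounds

    def neg(logq: np.ndarray) -> float:
        q01, q10 = np.exp(logq)
        P = _p2(ti.edge_length, q01, q10)
        q = q01 + q10
        pi = np.array([q10 / q, q01 / q])
        prior = _root_prior(prior_kind, 2, pi)
        return -_prune_onehot(ti, tip_states, P, prior)

    rng = np.random.default_rng(seed)
    total_len = ti.edge_length.sum()
    base = math.log(max(ti.n_tips / max(total_len, 1e-9), lo * 2))
    starts = [np.array([base, base])]
    while len(starts) < n_starts:
        starts.append(rng.uniform(math.log(lo), math.log(hi), size=2))
    best_x, best_f = None, np.inf
    bounds = [(math.log(lo), math.log(hi))] * 2
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    return np.exp(best_x), -best_f


def build_dependent_q(rates: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """4-state rate matrix over joint states (00, 01, 10, 11).

    ``rates`` is a mapping over :data:`DEPENDENT_RATE_NAMES` or a sequence in
    that order; double transitions (00<->11, 01<->10) have rate zero.
    """
    if not isinstance(rates, Mapping):
        rates = dict(zip(DEPENDENT_RATE_NAMES, rates))
    Q = np.zeros((4, 4))
    for name, (i, j) in _TRANSITIONS.items():
        Q[i, j] = float(rates[name])
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _transition_matrices(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """P(t) for every branch length, via eigendecomposition with expm fallback."""
    try:
        lam, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        E = np.exp(np.multiply.outer(t, lam))
        P = np.einsum("ij,nj,jk->nik", U, E, Uinv)
        P = np.real(P)
    except np.linalg.LinAlgError:
        P = np.stack([linalg.expm(Q * ti) for ti in t])
    return np.clip(P, 0.0, None)


def dependent_loglik(
    tree: "dendropy.Tree | TreeIndex",
    joint_trait: Mapping[str, int],
    rates: Mapping[str, float] | Sequence[float],
    root_prior="uniform",
) -> float:
    """Log-likelihood of joint binary traits under the dependent 4-state model.

    ``joint_trait`` maps tips to joint states 0..3 encoding (A, B) as
    ``2*A + B``.
    """
    ti = TreeIndex.ensure(tree)
    tip_states = ti.tip_state_array(joint_trait, 4)
    Q = build_dependent_q(rates)
    P = _transition_matrices(Q, ti.edge_length)
    prior = _root_prior(root_prior, 4, _stationary(Q))
    return _prune_onehot(ti, tip_states, P, prior)


def _stationary(Q: np.ndarray) -> np.ndarray:
    A = np.vstack([Q.T, np.ones(Q.shape[0])])
    b = np.zeros(Q.shape[0] + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0, None) / max(np.clip(pi, 0, None).sum(), 1e-300)


def joint_states(
    trait_a: Mapping[str, int], trait_b: Mapping[str, int]
) -> dict[str, int]:
    """Encode two binary traits as joint states 2*A + B on shared tips."""
    shared = set(trait_a) & set(trait_b)
    return {t: 2 * int(trait_a[t]) + int(trait_b[t]) for t in shared}


def pagel_discrete_lrt(
    tree: "dendropy.Tree | TreeIndex",
    trait_a: Mapping[str, int],
    trait_b: Mapping[str, int],
    n_starts: int = 10,
    seed: int | None = None,
    rate_bounds: tuple[float, float] = (1e-6, 100.0),
    root_prior="uniform",
) -> TestResult:
    """Likelihood-ratio test of correlated evolution of two binary traits.

    Independent model: two separate 2-state Mk processes (4 free rates),
    whose joint log-likelihood factorizes as the sum of the marginal
    likelihoods.  Dependent model: 4-state chain with 8 single-change rates.
    The statistic 2*(logL_dep - logL_indep) is referred to chi-square with
    4 df.  The dependent optimizer always starts from the embedded
    independent MLE (plus ``n_starts - 1`` random starts), so the nesting
    inequality holds within optimizer tolerance.
    """
    ti = TreeIndex.ensure(tree)
    rng = np.random.default_rng(seed)
    shared = set(trait_a) & set(trait_b)
    if not shared >= set(ti.tip_index):
        missing = set(ti.tip_index) - shared
        raise ValueError(f"traits missing for tips: {sorted(missing)[:5]} ...")

    sub_starts = max(2, n_starts // 2)
    (qa01, qa10), ll_a = fit_mk(
        ti, trait_a, n_starts=sub_starts, seed=int(rng.integers(2**31)),
        rate_bounds=rate_bounds, root_prior=root_prior,
    )
    (qb01, qb10), ll_b = fit_mk(
        ti, trait_b, n_starts=sub_starts, seed=int(rng.integers(2**31)),
        rate_bounds=rate_bounds, root_prior=root_prior,
    )
    ll_indep = ll_a + ll_b

    joint = joint_states(trait_a, trait_b)
    tip_states = ti.tip_state_array(joint, 4)
    lo, hi = rate_bounds
    bounds = [(math.log(lo), math.log(hi))] * 8
    prior_kind = root_prior

    def neg(logr: np.ndarray) -> float:
        Q = build_dependent_q(np.exp(logr))
        P = _transition_matrices(Q, ti.edge_length)
        prior = _root_prior(prior_kind, 4, _stationary(Q))
        return -_prune_onehot(ti, tip_states, P, prior)

    # embedding: q12=B gain|A=0, q13=A gain|B=0, q21=B loss|A=0,
    # q24=A gain|B=1, q31=A loss|B=0, q34=B gain|A=1, q42=A loss|B=1,
    # q43=B loss|A=1
    embed = np.log(np.clip(
        [qb01, qa01, qb10, qa01, qa10, qb01, qa10, qb10], lo, hi
    ))
    starts = [embed]
    while len(starts) < n_starts:
        starts.append(rng.uniform(math.log(lo), math.log(hi), size=8))
    best_x, best_f = embed, neg(embed)
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    ll_dep = -best_f

    stat = 2.0 * (ll_dep - ll_indep)
    p = float(chi2.sf(max(stat, 0.0), df=4))
    return TestResult(
        statistic=stat,
        p_value=p,
        null="independent 2-trait Mk evolution (chi-square, 4 df)",
        df=4,
        details={
            "loglik_independent": ll_indep,
            "loglik_dependent": ll_dep,
            "rates_independent": {
                "qA01": qa01, "qA10": qa10, "qB01": qb01, "qB10": qb10
            },
            "rates_dependent": dict(zip(DEPENDENT_RATE_NAMES, np.exp(best_x))),
        },
    )


# ---------------------------------------------------------------------------
# repertoire x metabolism tabulation
# ---------------------------------------------------------------------------

def metabolism_by_repertoire(
    presence: pd.DataFrame,
    metabolism: Mapping[str, str] | pd.Series,
    categories: Sequence[str] = METABOLISM_CATEGORIES,
    min_genomes_sorted: int = 10,
) -> pd.DataFrame:
    """Per pathway combination, the proportion of each O2-metabolism class.

    Rows are repertoire combinations; proportions sum to 1 per row.
    Combinations with more than ``min_genomes_sorted`` genomes come first,
    sorted by descending aerobe proportion; the rest follow by size.
    """
    met = pd.Series(dict(metabolism) if not isinstance(metabolism, pd.Series) else metabolism)
    shared = presence.index.intersection(met.index)
    cols = list(presence.columns)
    combos = presence.loc[shared].apply(
        lambda row: "+".join(c for c in cols if row[c]) or "(none)", axis=1
    )
    extra = [c for c in pd.unique(met.loc[shared]) if c not in categories]
    cats = list(categories) + sorted(extra)
    rows = []
    for combo, idx in combos.groupby(combos).groups.items():
        sub = met.loc[idx]
        n = len(sub)
        props = {c: float((sub == c).sum()) / n for c in cats}
        rows.append({"combination": combo, "n_species": n, **props})
    df = pd.DataFrame(rows)
    big = df[df["n_species"] > min_genomes_sorted].sort_values(
        categories[0], ascending=False
    )
    small = df[df["n_species"] <= min_genomes_sorted].sort_values(
        "n_species", ascending=False
    )
    return pd.concat([big, small], ignore_index=True)


def subsample_species(ids: Sequence[str], n: int, seed: int) -> list[str]:
    """Seeded uniform subsample without replacement (order-independent)."""
    pool = sorted(ids)
    if n > len(pool):
        raise ValueError(f"cannot sample {n} from {len(pool)} ids")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(pick)]
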