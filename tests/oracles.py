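"""Independent brute-force oracles used by the test suite.

Each function here recomputes a quantity by a method unrelated to the
package's implementation path: explicit enumeration, an alternative dynamic
program, or a closed form.  They are deliberately slow and simple.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from quinrep.phylostats import TreeIndex


def sankoff_min_changes(tree, trait: dict) -> int:
    """Unit-cost Sankoff dynamic program: minimum number of state changes."""
    ti = TreeIndex.ensure(tree)
    states = sorted({trait[t] for t in ti.tip_index}, key=repr)
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    INF = 10**9
    cost = np.zeros((ti.n_nodes, k), dtype=np.int64)
    label_of = {i: lbl for lbl, i in ti.tip_index.items()}
    for i in ti.postorder:
        kids = ti.children[i]
        if not kids:
            cost[i] = INF
            cost[i, idx[trait[label_of[i]]]] = 0
            continue
        for s in range(k):
            total = 0
            for c in kids:
                total += min(cost[c, t] + (s != t) for t in range(k))
            cost[i, s] = total
    return int(cost[ti.root].min())


def mk_loglik_enumeration(tree, trait: dict, q01: float, q10: float,
                          root_prior=(0.5, 0.5)) -> float:
    """Binary-trait tree likelihood by summation over all internal states."""
    ti = TreeIndex.ensure(tree)
    q = q01 + q10

    def ptrans(t):
        if q == 0:
            return np.eye(2)
        e = math.exp(-q * t)
        pi0, pi1 = q10 / q, q01 / q
        return np.array(
            [[pi0 + pi1 * e, pi1 - pi1 * e], [pi0 - pi0 * e, pi1 + pi0 * e]]
        )

    P = [ptrans(t) for t in ti.edge_length]
    internal = [i for i in ti.postorder if ti.children[i]]
    label_of = {i: lbl for lbl, i in ti.tip_index.items()}
    tipstate = {i: int(trait[label_of[i]]) for i in ti.tip_index.values()}
    total = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        state.update(tipstate)
        like = root_prior[state[ti.root]]
        for i in internal:
            for c in ti.children[i]:
                like *= P[c][state[i], state[c]]
        total += like
    return math.log(total)


def pwm_pvalues_bruteforce(pwm_probs: np.ndarray, background: np.ndarray,
                           bin_size: float) -> dict[int, float]:
    """Survival function of the discretized log-odds score by enumerating
    every word of the motif's width (per-column floored scores, matching the
    definition of the discretized statistic).  Only feasible for tiny widths.
    """
    w = pwm_probs.shape[0]
    lod = np.log2(pwm_probs / background)
    binned = np.floor(lod / bin_size).astype(int)
    sf: dict[int, float] = {}
    items = []
    for word in itertools.product(range(4), repeat=w):
        score = sum(int(binned[i, b]) for i, b in enumerate(word))
        prob = math.prod(background[b] for b in word)
        items.append((score, prob))
    # survival: P(binned score >= s)
    acc = 0.0
    for s, p in sorted(items, reverse=True):
        acc += p
        sf[s] = acc
    return sf
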