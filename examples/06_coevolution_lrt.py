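"""Dependent-vs-independent coevolution test for two binary pathways.

Simulates two binary traits on a Yule tree -- once independently, once with
the gain rate of trait B raised 20-fold when trait A is present -- and runs
the likelihood-ratio test (8-rate dependent model vs 4-rate independent
model, chi-square with 4 df) on both datasets.
"""

from quinrep.phylostats import TreeIndex, build_dependent_q, pagel_discrete_lrt
from quinrep.simulate import make_yule_tree, simulate_discrete_trait

tree = make_yule_tree(150, seed=10)
ti = TreeIndex(tree)

# independent evolution
a, _ = simulate_discrete_trait(tree, rates=(0.4, 0.4), seed=11)
b, _ = simulate_discrete_trait(tree, rates=(0.4, 0.4), seed=12)
res_ind = pagel_discrete_lrt(ti, a, b, n_starts=4, seed=0)
print(f"independent simulation:  LRT = {res_ind.statistic:6.2f}, "
      f"p = {res_ind.p_value:.3f}")

# dependent evolution: B gains 20x faster when A is present
Q = build_dependent_q(dict(q12=0.1, q13=0.4, q21=0.5, q24=0.4,
                           q31=0.4, q34=2.0, q42=0.4, q43=0.5))
joint, _ = simulate_discrete_trait(tree, q_matrix=Q, seed=13)
a2 = {k: v // 2 for k, v in joint.items()}
b2 = {k: v % 2 for k, v in joint.items()}
res_dep = pagel_discrete_lrt(ti, a2, b2, n_starts=4, seed=0)
print(f"dependent simulation:    LRT = {res_dep.statistic:6.2f}, "
      f"p = {res_dep.p_value:.3g}")
print(f"fitted dependent gain rates for B: "
      f"q(B gain | A absent) = {res_dep.details['rates_dependent']['q12']:.2f}, "
      f"q(B gain | A present) = {res_dep.details['rates_dependent']['q34']:.2f}")

# Under independence the statistic stays near its chi-square(4) null; under
# strong dependence it is large and the fitted conditional gain rates for B
# recover the planted asymmetry.
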