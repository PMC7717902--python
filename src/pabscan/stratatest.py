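"""Strata-formation rate test and generation-time branch rescaling.

Recombination-suppression events ("evolutionary strata") are modelled as a
Poisson process along a phylogeny: on a subtree with total branch length
Δt, the number of new strata S is Poisson(λΔt).  To ask whether two clades
formed strata at different rates without knowing λ, condition on the total
count: under a common rate, S1 | (S1+S2 = k1+k2) is Binomial(k1+k2, p) with
p = Δt1/(Δt1+Δt2), and the one-tailed upper tail of that binomial is the
test p-value — tossing an unbalanced coin k1+k2 times and asking for at
least k1 heads.

Because generation times differ enormously between clades, the test can be
run per-generation instead of per-year: branch lengths are rescaled by the
generation time, assumed to vary linearly along each branch between its
endpoint values, which integrates to the closed form

    g(t_d) − g(t_a) = (t_d − t_a)/(γ_d − γ_a) · ln(γ_d/γ_a).

Endpoint generation times come from tip values (age at first reproduction
as a proxy) and maximum-likelihood Brownian-motion ancestral reconstruction
for internal nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "TimedTree",
    "StrataObservation",
    "poisson_strata_pmf",
    "conditional_binomial_test",
    "generations_on_branch",
    "bm_ancestral_states",
    "rescale_tree_to_generations",
    "strata_rate_analysis",
]

SUBTREE1 = "subtree1"
SUBTREE2 = "subtree2"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class StrataObservation:
    """Observed strata counts and subtree branch-length totals.

    ``dt1``/``dt2`` are total branch lengths of the two subtrees, in
    whatever common time unit the analysis uses (My or millions of
    generations); only their ratio enters the test.
    """

    s1: int
    s2: int
    dt1: float
    dt2: float
    timescale: str = "years"

    def __post_init__(self) -> None:
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("strata counts must be non-negative")
        if self.dt1 < 0 or self.dt2 < 0:
            raise ValueError("branch-length totals must be non-negative")
        if self.dt1 + self.dt2 <= 0:
            raise ValueError("dt1 + dt2 must be positive")


def poisson_strata_pmf(k: int, lam: float, dt: float) -> float:
    """P(S = k) for strata count S ~ Poisson(lam * dt)."""
    if k < 0:
        raise ValueError("count must be non-negative")
    if lam < 0 or dt < 0:
        raise ValueError("rate and interval must be non-negative")
    return float(stats.poisson.pmf(k, lam * dt))


def conditional_binomial_test(
    s1: int,
    s2: int,
    dt1: float,
    dt2: float,
    alternative: str = "greater",
) -> float:
    """Conditional test for unequal strata-formation rates on two subtrees.

    Under a common Poisson rate, conditionally on the total S1+S2 the count
    S1 is Binomial(S1+S2, p) with p = dt1/(dt1+dt2); the rate cancels.  The
    default one-tailed p-value is P(S1 >= s1 | total), i.e. the upper tail;
    ``alternative="two-sided"`` doubles the smaller tail (capped at 1).
    With no events at all there is no evidence and the p-value is 1.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("strata counts must be non-negative")
    if dt1 < 0 or dt2 < 0:
        raise ValueError("branch-length totals must be non-negative")
    total = s1 + s2
    if dt1 + dt2 <= 0:
        raise ValueError("dt1 + dt2 must be positive")
    if total == 0:
        return 1.0
    p = dt1 / (dt1 + dt2)
    upper = float(stats.binom.sf(s1 - 1, total, p))  # P(S1 >= s1)
    if alternative == "greater":
        return upper
    if alternative == "two-sided":
        lower = float(stats.binom.cdf(s1, total, p))  # P(S1 <= s1)
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown alternative {alternative!r}")


def generations_on_branch(
    t_a: float, t_d: float, gamma_a: float, gamma_d: float, rel_tol: float = 1e-9
) -> float:
    """Generations elapsed on a branch with linearly varying generation time.

    Integrates dg = dt/γ(t) with γ linear from γ_a at the ancestor (time
    t_a) to γ_d at the descendant (t_d > t_a), giving
    ``(t_d − t_a)/(γ_d − γ_a) · ln(γ_d/γ_a)``.  When the endpoint values
    differ by less than ``rel_tol`` relatively, the constant-γ limit
    ``(t_d − t_a)/γ_a`` is used to avoid catastrophic cancellation.

    Time units propagate: t in years with γ in years/generation gives
    generations; t in My with γ in years/generation gives millions of
    generations.
    """
    if gamma_a <= 0 or gamma_d <= 0:
        raise ValueError("generation times must be positive")
    if t_d <= t_a:
        raise ValueError("t_d must exceed t_a")
    span = t_d - t_a
    if abs(gamma_d - gamma_a) <= rel_tol * max(gamma_a, gamma_d):
        return span / gamma_a
    return span / (gamma_d - gamma_a) * math.log(gamma_d / gamma_a)


class TimedTree:
    """Rooted phylogeny with branch lengths in My and per-tip generation times.

    Wraps a ``dendropy.Tree``.  ``tip_ages`` maps taxon labels to age at
    first reproduction (years, the generation-time proxy); ``clade_labels``
    maps taxon labels to "subtree1"/"subtree2"/"excluded" — each branch
    inherits the label shared by all its descendant tips and must not mix
    the two subtrees (an unlabeled or mixed branch is "excluded" only if
    every descendant is).
    """

    def __init__(
        self,
        tree: dendropy.Tree | str,
        tip_ages: Mapping[str, float] | None = None,
        clade_labels: Mapping[str, str] | None = None,
    ) -> None:
        if isinstance(tree, str):
            tree = dendropy.Tree.get(
                data=tree, schema="newick", preserve_underscores=True
            )
        self.tree = tree
        self.tip_ages = dict(tip_ages or {})
        self.clade_labels = dict(clade_labels or {})
        for leaf in self.tree.leaf_node_iter():
            if leaf.edge.length is None:
                raise ValueError("all branches must have lengths")

    # -- helpers -----------------------------------------------------------
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def node_times(self) -> dict[dendropy.Node, float]:
        """Time of each node measured from the root (root = 0), in branch-length units."""
        times: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                times[node] = 0.0
            else:
                times[node] = times[node.parent_node] + (node.edge.length or 0.0)
        return times

    def branch_clade_label(self, node: dendropy.Node) -> str:
        """Clade label of the branch above ``node`` from its descendant tips."""
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        labels = {self.clade_labels.get(t, EXCLUDED) for t in tips}
        active = labels - {EXCLUDED}
        if len(active) > 1:
            return EXCLUDED  # spans the partition point: not inside either subtree
        if not active:
            return EXCLUDED
        return active.pop()

    def subtree_lengths(self) -> dict[str, float]:
        """Total branch length per clade label, in the tree's length unit."""
        totals = {SUBTREE1: 0.0, SUBTREE2: 0.0, EXCLUDED: 0.0}
        unlabeled = [t for t in self.tip_labels() if t not in self.clade_labels]
        if unlabeled and self.clade_labels:
            raise ValueError(f"unlabeled tips: {unlabeled}")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            totals[self.branch_clade_label(node)] += node.edge.length or 0.0
        return totals


def bm_ancestral_states(
    tree: TimedTree | dendropy.Tree, tip_values: Mapping[str, float]
) -> dict[dendropy.Node, float]:
    """Maximum-likelihood ancestral states under Brownian motion.

    Solves the joint-ML normal equations: the estimates minimise
    Σ_edges (x_child − x_parent)²/length, so each internal node is the
    branch-length-harmonic weighted average of its neighbours.  For a
    Gaussian process the joint mode coincides with the per-node marginal
    (GLS / re-rooting) estimates, so this matches the classic
    ``fastAnc``-style reconstruction.  Returns a map from internal node to
    value; tips keep their observed values.
    """
    dtree = tree.tree if isinstance(tree, TimedTree) else tree
    internal = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in dtree.leaf_node_iter()]
    for lf in leaves:
        if lf.taxon.label not in tip_values:
            raise ValueError(f"missing tip value for {lf.taxon.label!r}")
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None and (node.edge.length or 0.0) <= 0:
            raise ValueError("all branch lengths must be positive for BM reconstruction")

    index = {n: i for i, n in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        w = 1.0 / node.edge.length
        parent = node.parent_node
        pi = index[parent]
        if node.is_leaf():
            A[pi, pi] += w
            b[pi] += w * tip_values[node.taxon.label]
        else:
            ci = index[node]
            A[pi, pi] += w
            A[ci, ci] += w
            A[pi, ci] -= w
            A[ci, pi] -= w
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular ancestral-state system: {err}") from err
    return {n: float(x[index[n]]) for n in internal}


def rescale_tree_to_generations(tree: TimedTree) -> TimedTree:
    """Rescale branch lengths from My to millions of generations.

    Node generation times: tips take their ``tip_ages`` value; internal
    nodes the BM-reconstructed value.  Each branch length is replaced by
    :func:`generations_on_branch` using the endpoint values and node times
    measured from the root.  Topology and tip set are preserved.
    """
    missing = [t for t in tree.tip_labels() if t not in tree.tip_ages]
    if missing:
        raise ValueError(f"missing age_at_first_reproduction for tips: {missing}")
    anc = bm_ancestral_states(tree, tree.tip_ages)

    def gamma_of(node: dendropy.Node) -> float:
        if node.is_leaf():
            return float(tree.tip_ages[node.taxon.label])
        return anc[node]

    times = tree.node_times()
    new_tree = tree.tree.clone(depth=1)
    # clone(depth=1) shares Node objects? dendropy deep-clones with depth=1.
    # Walk both trees in parallel preorder to transfer rescaled lengths.
    for orig, copy in zip(tree.tree.preorder_node_iter(), new_tree.preorder_node_iter()):
        if orig.parent_node is None:
            continue
        t_a = times[orig.parent_node]
        t_d = times[orig]
        copy.edge.length = generations_on_branch(
            t_a, t_d, gamma_of(orig.parent_node), gamma_of(orig)
        )
    out = TimedTree(new_tree, tip_ages=tree.tip_ages, clade_labels=tree.clade_labels)
    return out


def strata_rate_analysis(
    s1: int,
    s2: int,
    dt1: float | None = None,
    dt2: float | None = None,
    tree: TimedTree | None = None,
    timescale: str = "years",
    alternative: str = "greater",
) -> tuple[StrataObservation, float]:
    """Full strata-rate comparison between two labelled subtrees.

    Either pass precomputed subtree totals ``dt1``/``dt2`` (e.g. published
    values) or a labelled :class:`TimedTree`, from which totals are summed
    per clade label — in My for ``timescale="years"`` or in millions of
    generations (via :func:`rescale_tree_to_generations`) for
    ``timescale="generations"``.  Returns the observation and the
    conditional binomial p-value.
    """
    if timescale not in ("years", "generations"):
        raise ValueError(f"unknown timescale {timescale!r}")
    if dt1 is None or dt2 is None:
        if tree is None:
            raise ValueError("either dt1/dt2 or a labelled tree is required")
        if not tree.clade_labels:
            raise ValueError("tree branches must be labelled by clade")
        work = tree if timescale == "years" else rescale_tree_to_generations(tree)
        totals = work.subtree_lengths()
        dt1, dt2 = totals[SUBTREE1], totals[SUBTREE2]
    obs = StrataObservation(s1=s1, s2=s2, dt1=dt1, dt2=dt2, timescale=timescale)
    pval = conditional_binomial_test(s1, s2, dt1, dt2, alternative=alternative)
    return obs, pval
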