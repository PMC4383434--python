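"""Discrete Bayesian networks learned by conditional-independence testing.

Structure learning is the constraint-based (PC-style) procedure: start
from the complete undirected graph, delete the edge (a, b) whenever some
conditioning set S drawn from the neighbourhoods of a and b renders them
conditionally independent, then orient v-structures and close under the
Meek propagation rules.  Edges that remain undirected after propagation
are oriented from the lower to the higher column index so runs are
reproducible; the result is always a DAG.

Conditional independence is decided by the G² (likelihood-ratio) test
summed over the strata of S, with degrees of freedom
(|a|-1)(|b|-1) x (number of nonempty strata).  Tests with fewer than
5 x df records (df taken over the full stratification) are declared
independent without testing — the standard small-sample rule for sparse
contingency tables.

Inference is exact enumeration, which is adequate here because queries
either supply evidence on every non-target variable (the usual case in
the reasoning engine) or concern small fixture networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .case_model import EncodedFrame


class DomainError(ValueError):
    """Evidence value outside a variable's domain."""


class BinningError(ValueError):
    """Longevity bins do not cover the observed values."""


@dataclass
class DiscreteData:
    """All-discrete records: integer codes with per-column level counts."""

    codes: np.ndarray          # (n, p) int
    names: list[str]
    levels: list[int]

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def col(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_frame(cls, frame: EncodedFrame) -> "DiscreteData":
        if frame.real_names:
            raise ValueError("frame still has continuous columns; use the bn encoding")
        return cls(frame.cat.copy(), list(frame.cat_names), list(frame.cat_levels))

    def with_columns(self, cols: list[tuple[str, np.ndarray, int]]) -> "DiscreteData":
        codes = np.hstack([self.codes] + [c[1].reshape(self.n, 1) for c in cols])
        return DiscreteData(
            codes, self.names + [c[0] for c in cols], self.levels + [c[2] for c in cols]
        )


@dataclass(frozen=True)
class CITestResult:
    a: str
    b: str
    S: tuple[str, ...]
    statistic: float
    p_value: float
    independent: bool
    insufficient_data: bool = False


def ci_test(data: DiscreteData, a: str, b: str, S, alpha: float = 0.05) -> CITestResult:
    """G² conditional-independence test of a and b given the set S."""
    S = tuple(S)
    if a == b or a in S or b in S:
        raise ValueError("a, b and S must be distinct")
    ia, ib = data.col(a), data.col(b)
    iS = [data.col(s) for s in S]
    la, lb = data.levels[ia], data.levels[ib]
    full_df = (la - 1) * (lb - 1) * int(np.prod([data.levels[i] for i in iS], dtype=np.int64))
    if data.n < 5 * full_df:
        return CITestResult(a, b, S, 0.0, 1.0, True, insufficient_data=True)

    ca, cb = data.codes[:, ia], data.codes[:, ib]
    if iS:
        strata = np.ravel_multi_index(
            data.codes[:, iS].T, [data.levels[i] for i in iS]
        )
    else:
        strata = np.zeros(data.n, dtype=np.int64)
    g2 = 0.0
    n_strata = 0
    for s_val in np.unique(strata):
        mask = strata == s_val
        ns = int(mask.sum())
        if ns == 0:
            continue
        n_strata += 1
        table = np.bincount(ca[mask] * lb + cb[mask], minlength=la * lb).reshape(la, lb).astype(float)
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows * cols / ns
        nz = table > 0
        g2 += 2.0 * float((table[nz] * np.log(table[nz] / expected[nz])).sum())
    df = (la - 1) * (lb - 1) * n_strata
    p = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0
    return CITestResult(a, b, S, g2, p, independent=(p > alpha))


@dataclass
class BayesNet:
    """A DAG over discrete variables with per-node conditional tables.

    ``cpts[node]`` is ``(parents, table)`` where ``table`` has shape
    (prod of parent level counts, node levels) and row-stochastic rows.
    """

    names: list[str]
    levels: dict[str, int]
    dag: nx.DiGraph
    cpts: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "levels": dict(self.levels),
            "edges": sorted(self.dag.edges()),
            "cpts": {
                node: {"parents": parents, "table": table.tolist()}
                for node, (parents, table) in self.cpts.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BayesNet":
        dag = nx.DiGraph()
        dag.add_nodes_from(d["names"])
        dag.add_edges_from([tuple(e) for e in d["edges"]])
        cpts = {
            node: (list(v["parents"]), np.asarray(v["table"], dtype=float))
            for node, v in d["cpts"].items()
        }
        return cls(list(d["names"]), dict(d["levels"]), dag, cpts)


def _meek_rules(directed: set, undirected: set, names: list[str]) -> None:
    """Close the partially directed graph under Meek's orientation rules."""
    def adjacent(x, y):
        return (x, y) in directed or (y, x) in directed or frozenset((x, y)) in undirected

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=lambda fs: tuple(sorted(fs))):
            x, y = sorted(e)
            for a, b in ((x, y), (y, x)):
                # R1: c -> a, a - b, c and b nonadjacent  =>  a -> b
                r1 = any((c, a) in directed and not adjacent(c, b) for c in names if c not in (a, b))
                # R2: a -> c -> b and a - b  =>  a -> b
                r2 = any((a, c) in directed and (c, b) in directed for c in names if c not in (a, b))
                # R3: a - c1 -> b, a - c2 -> b, c1 and c2 nonadjacent  =>  a -> b
                r3 = False
                mids = [
                    c
                    for c in names
                    if c not in (a, b)
                    and frozenset((a, c)) in undirected
                    and (c, b) in directed
                ]
                for c1, c2 in itertools.combinations(mids, 2):
                    if not adjacent(c1, c2):
                        r3 = True
                        break
                if r1 or r2 or r3:
                    undirected.discard(e)
                    directed.add((a, b))
                    changed = True
                    break
            if changed:
                break


def learn_structure(data: DiscreteData, alpha: float = 0.05, max_cond: int = 3) -> BayesNet:
    """PC-style skeleton search plus v-structure/Meek orientation.

    Conditioning subsets are enumerated in column-index order, so placing
    a variable early in the data makes it the first candidate separator.
    """
    names = list(data.names)
    if len(names) < 1:
        raise ValueError("at least one variable required")
    if max_cond < 0:
        raise ValueError("max_cond must be >= 0")
    order = {v: i for i, v in enumerate(names)}
    adj: dict[str, set] = {v: set(names) - {v} for v in names}
    sepset: dict[frozenset, set] = {}

    for level in range(max_cond + 1):
        removed_any = False
        for a, b in itertools.combinations(names, 2):
            if b not in adj[a]:
                continue
            candidates = sorted((adj[a] | adj[b]) - {a, b}, key=order.get)
            if len(candidates) < level:
                continue
            for S in itertools.combinations(candidates, level):
                if ci_test(data, a, b, S, alpha=alpha).independent:
                    adj[a].discard(b)
                    adj[b].discard(a)
                    sepset[frozenset((a, b))] = set(S)
                    removed_any = True
                    break
        if not removed_any and level > 0:
            break

    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset] = {
        frozenset((a, b)) for a in names for b in adj[a] if order[a] < order[b]
    }

    # v-structures: a - c - b with a, b nonadjacent and c outside sepset(a, b)
    for c in names:
        nbrs = sorted(adj[c], key=order.get)
        for a, b in itertools.combinations(nbrs, 2):
            if b in adj[a]:
                continue
            if c not in sepset.get(frozenset((a, b)), set()):
                for tail in (a, b):
                    e = frozenset((tail, c))
                    if e in undirected and (c, tail) not in directed:
                        undirected.discard(e)
                        directed.add((tail, c))

    _meek_rules(directed, undirected, names)

    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    dag.add_edges_from(directed)
    if not nx.is_directed_acyclic_graph(dag):
        raise RuntimeError("orientation produced a cycle")  # pragma: no cover
    for e in sorted(undirected, key=lambda fs: tuple(sorted(fs, key=order.get))):
        x, y = sorted(e, key=order.get)
        dag.add_edge(x, y)
        if not nx.is_directed_acyclic_graph(dag):
            dag.remove_edge(x, y)
            dag.add_edge(y, x)
    assert nx.is_directed_acyclic_graph(dag)
    return BayesNet(names, dict(zip(data.names, data.levels)), dag)


def fit_cpts(bn: BayesNet, data: DiscreteData, laplace_alpha: float = 1.0) -> BayesNet:
    """Laplace-smoothed conditional frequency tables for every node."""
    order = {v: i for i, v in enumerate(bn.names)}
    for node in bn.names:
        parents = sorted(bn.dag.predecessors(node), key=order.get)
        L = bn.levels[node]
        par_levels = [bn.levels[p] for p in parents]
        n_cfg = int(np.prod(par_levels, dtype=np.int64)) if parents else 1
        counts = np.zeros((n_cfg, L))
        node_codes = data.codes[:, data.col(node)]
        if parents:
            cfg = np.ravel_multi_index(
                data.codes[:, [data.col(p) for p in parents]].T, par_levels
            )
        else:
            cfg = np.zeros(data.n, dtype=np.int64)
        np.add.at(counts, (cfg, node_codes), 1.0)
        counts += laplace_alpha
        rowsum = counts.sum(axis=1, keepdims=True)
        table = np.where(rowsum > 0, counts / np.where(rowsum == 0, 1, rowsum), 1.0 / L)
        zero_rows = rowsum[:, 0] == 0
        if zero_rows.any():
            table[zero_rows] = 1.0 / L  # unseen parent configuration
        bn.cpts[node] = (parents, table)
    return bn


def _node_logp(bn: BayesNet, node: str, assignment: dict[str, int]) -> float:
    parents, table = bn.cpts[node]
    if parents:
        cfg = int(np.ravel_multi_index([assignment[p] for p in parents], [bn.levels[p] for p in parents]))
    else:
        cfg = 0
    return float(np.log(table[cfg, assignment[node]] + 1e-300))


def bn_posterior(bn: BayesNet, evidence: dict[str, int], target: str) -> np.ndarray:
    """Exact posterior over the target by enumeration of free variables."""
    if target in evidence:
        raise ValueError("target must not appear in the evidence")
    for var, val in evidence.items():
        if var not in bn.levels:
            raise DomainError(f"unknown variable {var!r}")
        if not 0 <= val < bn.levels[var]:
            raise DomainError(f"value {val} outside the domain of {var!r}")
    free = [v for v in bn.names if v not in evidence and v != target]
    if len(free) > 12:
        raise ValueError(f"{len(free)} free variables is too many for enumeration")
    post = np.zeros(bn.levels[target])
    assignment = dict(evidence)
    free_levels = [range(bn.levels[v]) for v in free]
    for t_val in range(bn.levels[target]):
        assignment[target] = t_val
        total = 0.0
        for combo in itertools.product(*free_levels):
            assignment.update(zip(free, combo))
            total += np.exp(sum(_node_logp(bn, node, assignment) for node in bn.names))
        post[t_val] = total
    s = post.sum()
    if s <= 0:
        return np.full(bn.levels[target], 1.0 / bn.levels[target])
    return post / s


def bn_expected_longevity(
    bn: BayesNet, evidence: dict[str, int], bin_edges: np.ndarray, target: str = "longevity_bin"
) -> float:
    """Posterior-weighted midpoint of the discretized longevity variable.

    ``bin_edges`` are the finite edges (the last bin is open-ended and is
    represented by its lower edge plus one year).
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(bin_edges)  # len(edges)-1 closed bins + 1 open bin
    if bn.levels.get(target) != n_bins:
        raise BinningError(
            f"target has {bn.levels.get(target)} levels but {n_bins} bins were given"
        )
    mids = np.append((bin_edges[:-1] + bin_edges[1:]) / 2.0, bin_edges[-1] + 1.0)
    post = bn_posterior(bn, evidence, target)
    return float(post @ mids)
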