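import numpy as np
import pandas as pd
import pytest

import commstruct as cs


@pytest.fixture
def cherry():
    return cs.read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return cs.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def abc_dist():
    """d(A,B)=2, d(A,C)=4, d(B,C)=4 — the three-tip tree's cophenetic matrix."""
    return pd.DataFrame([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]],
                        index=list("ABC"), columns=list("ABC"))


def random_distance_matrix(rng: np.random.Generator, labels) -> pd.DataFrame:
    n = len(labels)
    m = rng.random((n, n)) * 5
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return pd.DataFrame(m, index=labels, columns=labels)


def random_community(rng: np.random.Generator, labels, k=None) -> pd.Series:
    n = len(labels)
    k = k or int(rng.integers(2, n + 1))
    idx = rng.choice(n, size=k, replace=False)
    ab = np.zeros(n)
    ab[idx] = rng.integers(1, 20, size=k)
    return pd.Series(ab, index=labels)


# -- naive oracles (independent of the implementation paths they check) ----

def mpd_oracle(ab: pd.Series, dist: pd.DataFrame, weighted: bool) -> float:
    sp = [s for s in ab.index if ab[s] > 0]
    if weighted:
        f = {s: ab[s] / sum(ab[t] for t in sp) for s in sp}
        num = den = 0.0
        for i in sp:
            for j in sp:
                if i != j:
                    num += dist.loc[i, j] * f[i] * f[j]
                    den += f[i] * f[j]
        return num / den
    vals = [dist.loc[i, j] for a, i in enumerate(sp) for j in sp[a + 1:]]
    return float(np.mean(vals))


def mntd_oracle(ab: pd.Series, dist: pd.DataFrame, weighted: bool) -> float:
    sp = [s for s in ab.index if ab[s] > 0]
    mins = {i: min(dist.loc[i, j] for j in sp if j != i) for i in sp}
    if weighted:
        tot = sum(ab[s] for s in sp)
        return sum(ab[i] / tot * mins[i] for i in sp)
    return float(np.mean(list(mins.values())))


def dpw_oracle(a1: pd.Series, a2: pd.Series, dist: pd.DataFrame) -> float:
    s1 = [s for s in a1.index if a1[s] > 0]
    s2 = [s for s in a2.index if a2[s] > 0]
    f1 = {s: a1[s] / sum(a1[t] for t in s1) for s in s1}
    f2 = {s: a2[s] / sum(a2[t] for t in s2) for s in s2}
    return sum(dist.loc[i, j] * f1[i] * f2[j] for i in s1 for j in s2)


def dnn_oracle(a1: pd.Series, a2: pd.Series, dist: pd.DataFrame,
               convention: str = "literal") -> float:
    s1 = [s for s in a1.index if a1[s] > 0]
    s2 = [s for s in a2.index if a2[s] > 0]
    f1 = {s: a1[s] / sum(a1[t] for t in s1) for s in s1}
    f2 = {s: a2[s] / sum(a2[t] for t in s2) for s in s2}
    t1 = sum(min(dist.loc[i, j] for j in s2) * f1[i] for i in s1)
    t2 = sum(min(dist.loc[i, j] for i in s1) * f2[j] for j in s2)
    total = t1 + t2
    return total / 2 if convention == "halved" else total


def patristic_oracle(phy: cs.Phylogeny) -> pd.DataFrame:
    """Brute-force path-sum distances via root paths."""
    paths = {}
    for leaf in phy.tree.leaf_node_iter():
        edges, node = [], leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    labels = sorted(paths)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            if a == b:
                continue
            ids_a = {i for i, _ in paths[a]}
            ids_b = {i for i, _ in paths[b]}
            shared = ids_a & ids_b
            out.loc[a, b] = (sum(l for i, l in paths[a] if i not in shared)
                             + sum(l for i, l in paths[b] if i not in shared))
    return out
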