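import numpy as np
import pandas as pd
import pytest

import mcltools as m

COHORT_SEED = 1
PIPELINE_SEED = 0


@pytest.fixture(scope="session")
def default_cfg():
    return m.default_config(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """Default synthetic cohort: (AnnData counts, GroundTruth)."""
    return m.generate_expression(default_cfg)


@pytest.fixture(scope="session")
def bcr_table(default_cfg):
    return m.generate_bcr(default_cfg)


@pytest.fixture(scope="session")
def variant_tables(default_cfg):
    return m.generate_variant_tables(default_cfg)


@pytest.fixture(scope="session")
def normalized(cohort):
    adata, _ = cohort
    return m.normalize_log(m.apply_qc(adata))


@pytest.fixture(scope="session")
def pipeline_result(cohort, bcr_table):
    adata, _ = cohort
    return m.identify_malignant(adata, bcr_table, seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def pipeline_result_repeat(cohort, bcr_table):
    adata, _ = cohort
    return m.identify_malignant(adata, bcr_table, seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def truth_cells(cohort, normalized):
    _, truth = cohort
    return truth.cells.loc[normalized.obs_names]


def f1_malignant(result, truth) -> float:
    pred = result.labels == "malignant"
    tru = truth.cells.loc[result.labels.index, "cell_type"] == "malignantB"
    tp = int((pred & tru).sum())
    fp = int((pred & ~tru).sum())
    fn = int((~pred & tru).sum())
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def prufer_trees(nodes):
    """All labeled trees over ``nodes`` via Prüfer sequences (oracle)."""
    import itertools

    n = len(nodes)
    if n == 1:
        yield {}
        return
    if n == 2:
        yield {frozenset(nodes)}
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for s in seq:
            degree[s] += 1
        edges = set()
        seq_list = list(seq)
        avail = sorted(range(n))
        work_deg = degree[:]
        for s in seq_list:
            for leaf in avail:
                if work_deg[leaf] == 1:
                    edges.add(frozenset((nodes[leaf], nodes[s])))
                    work_deg[leaf] -= 1
                    work_deg[s] -= 1
                    avail.remove(leaf)
                    break
        last = [i for i in range(n) if work_deg[i] == 1]
        edges.add(frozenset((nodes[last[0]], nodes[last[1]])))
        yield edges


def oracle_valid_trees(ccf: pd.DataFrame, epsilon: float, founder):
    """Brute-force valid parent maps by orienting every labeled tree."""
    nodes = list(ccf.index)
    valid = []
    seen = set()
    for edges in prufer_trees(nodes):
        adj = {c: set() for c in nodes}
        for e in edges:
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
        parents = {founder: None}
        stack = [founder]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in parents:
                    parents[nb] = node
                    stack.append(nb)
        key = tuple(sorted((str(c), str(p)) for c, p in parents.items()))
        if key in seen:
            continue
        seen.add(key)
        ok = True
        for c, p in parents.items():
            if p is not None and (ccf.loc[c] > ccf.loc[p] + epsilon).any():
                ok = False
                break
        if ok:
            kids = {c: [] for c in nodes}
            for c, p in parents.items():
                if p is not None:
                    kids[p].append(c)
            for node, ks in kids.items():
                if ks and (
                    sum(ccf.loc[k] for k in ks) > ccf.loc[node] + epsilon
                ).any():
                    ok = False
                    break
        if ok:
            valid.append(parents)
    return valid
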