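import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirnet import diffexpr as de
from mirnet.simulate import SimulationConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One planted-signal dataset shared across read-only tests."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def de_results(default_dataset):
    """Fitted DE tables (gene and miRNA) for the shared dataset."""
    ds = default_dataset
    groups = ds.samples.set_index("sample_id")["group"]
    lognorm = de.log_normalize(ds.counts)
    gene_table, _ = de.moderated_t_table(lognorm, groups)
    mirna_table, _ = de.moderated_t_table(ds.mirna_intensity, groups)
    return {
        "lognorm": lognorm,
        "groups": groups,
        "gene_table": gene_table,
        "mirna_table": mirna_table,
        "de_genes": de.select_de(gene_table, "gene"),
        "de_mirnas": de.select_de(mirna_table, "mirna"),
    }


def spearman_oracle(x, y):
    """Independent rank-then-Pearson Spearman oracle (hand-built ranks)."""
    def average_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = average_ranks(x), average_ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def cluster_oracle(elements: pd.DataFrame, max_gap_bp: int):
    """O(n^2) union-find over the pairwise interval-gap join relation."""
    parts = []
    for chrom, group in elements.groupby("chrom"):
        rows = list(group.itertuples(index=False))
        n = len(rows)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in range(i + 1, n):
                a, b = rows[i], rows[j]
                if a.start < b.end and b.start < a.end:
                    gap = 0
                else:
                    gap = max(a.start, b.start) - min(a.end, b.end)
                if gap <= max_gap_bp:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(rows[i].element_id)
        parts.extend(
            frozenset(members) for members in comps.values() if len(members) >= 2
        )
    return set(parts)
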