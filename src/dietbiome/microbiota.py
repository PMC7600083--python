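"""OTU-table processing and diversity metrics.

Count tables are pandas DataFrames with samples as rows and OTUs as
columns (the on-disk TSV convention is transposed: OTUs x samples).
Rarefaction subsamples reads without replacement; alpha metrics use
natural logs; UniFrac is computed by a single post-order traversal of
the tree that accumulates per-branch descendant read proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import TreeNode


class ShallowSampleError(ValueError):
    """Samples whose total count is below the requested rarefaction depth."""

    def __init__(self, samples, depth):
        self.samples = list(samples)
        self.depth = depth
        super().__init__(
            f"samples below rarefaction depth {depth}: {self.samples[:10]}"
        )


def min_depth(table: pd.DataFrame) -> int:
    """Smallest per-sample read total (the paper's rarefaction depth rule)."""
    if table.shape[0] == 0:
        raise ValueError("empty OTU table")
    return int(table.sum(axis=1).min())


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    Uses a multivariate hypergeometric draw per sample (equivalent to
    drawing ``depth`` reads from the sample's read multiset). Samples
    below ``depth`` raise :class:`ShallowSampleError` — never silently
    dropped.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sums = table.sum(axis=1)
    shallow = sums[sums < depth]
    if len(shallow):
        raise ShallowSampleError(shallow.index.tolist(), depth)
    rng = np.random.default_rng(seed)
    counts = table.to_numpy(dtype=np.int64)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def alpha_diversity(table: pd.DataFrame, base: float = np.e) -> pd.DataFrame:
    """Shannon index, observed OTU count and evenness J per sample.

    H = -sum p log p over nonzero proportions (natural log by default);
    J = H / log(observed), defined as 0 when only one OTU is observed.
    """
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = table.index[totals <= 0].tolist()
        raise ValueError(f"all-zero samples: {bad[:10]}")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1) / np.log(base)
    observed = (counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(
            observed > 1, shannon / (np.log(observed) / np.log(base)), 0.0
        )
    return pd.DataFrame(
        {"shannon": shannon, "observed_otus": observed, "evenness": j},
        index=table.index,
    )


def _branch_matrix(
    table: pd.DataFrame, tree: TreeNode
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descendant proportions.

    Returns ``(lengths, P)`` where ``lengths`` has one entry per branch
    with positive length and ``P[b, s]`` is the fraction of sample s's
    reads that descend through branch b. One post-order pass.
    """
    col_index = {otu: k for k, otu in enumerate(table.columns)}
    counts = table.to_numpy(dtype=float)
    present = counts.sum(axis=0) > 0
    leaf_names = set(tree.leaf_names())
    unmapped = [o for o, k in col_index.items() if present[k] and o not in leaf_names]
    if unmapped:
        raise KeyError(f"OTUs with reads but no tree leaf: {unmapped[:10]}")
    totals = counts.sum(axis=1)
    n = counts.shape[0]

    lengths: list[float] = []
    rows: list[np.ndarray] = []
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            k = col_index.get(node.name)
            vec = counts[:, k].copy() if k is not None else np.zeros(n)
        else:
            vec = np.zeros(n)
            for child in node.children:
                vec += partial.pop(id(child))
        partial[id(node)] = vec
        if node.length is not None and node.length > 0 and node is not tree:
            lengths.append(node.length)
            rows.append(vec / totals)
    return np.asarray(lengths), np.asarray(rows)


def unifrac(
    table: pd.DataFrame,
    tree: TreeNode,
    mode: str = "weighted",
    normalized: bool = True,
) -> pd.DataFrame:
    """Pairwise UniFrac distances between samples.

    unweighted: sum of branch lengths where presence of descendants
    differs, over the total branch length covered by either sample.
    weighted (normalized): sum l |pA - pB| / sum l (pA + pB), with p the
    proportion of a sample's reads descending through the branch.
    ``normalized=False`` gives the raw weighted numerator.
    """
    if mode not in {"weighted", "unweighted"}:
        raise ValueError(f"unknown mode {mode!r}")
    lengths, P = _branch_matrix(table, tree)
    n = table.shape[0]
    dist = np.zeros((n, n))
    if mode == "unweighted":
        present = P > 0
        for i in range(n):
            for j in range(i + 1, n):
                union = present[:, i] | present[:, j]
                diff = present[:, i] ^ present[:, j]
                denom = float(lengths @ union)
                dist[i, j] = dist[j, i] = (
                    float(lengths @ diff) / denom if denom > 0 else 0.0
                )
    else:
        for i in range(n):
            for j in range(i + 1, n):
                num = float(lengths @ np.abs(P[:, i] - P[:, j]))
                if normalized:
                    denom = float(lengths @ (P[:, i] + P[:, j]))
                    dist[i, j] = dist[j, i] = num / denom if denom > 0 else 0.0
                else:
                    dist[i, j] = dist[j, i] = num
    return pd.DataFrame(dist, index=table.index, columns=table.index)


def filter_top_otus(
    table: pd.DataFrame,
    n: int = 100,
    min_median_rel: float = 1e-4,
) -> tuple[list[str], float]:
    """Most-abundant OTUs passing a median relative-abundance floor.

    Ranks OTUs by mean relative abundance (ties broken by OTU id), takes
    the top ``n``, then drops any whose median relative abundance across
    samples is below ``min_median_rel``. Returns the retained ids and
    the fraction of all reads they carry.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rel = table.div(table.sum(axis=1), axis=0)
    mean_rel = rel.mean(axis=0)
    ranked = mean_rel.sort_values(ascending=False, kind="mergesort")
    # stable sort on (-abundance, id): sort ids first, then by value
    order = sorted(ranked.index)
    ranked = mean_rel.loc[order].sort_values(ascending=False, kind="mergesort")
    top = ranked.index[:n]
    median_rel = rel[top].median(axis=0)
    keep = [otu for otu in top if median_rel[otu] >= min_median_rel]
    retained = float(table[keep].to_numpy().sum()) / float(table.to_numpy().sum())
    return keep, retained


def class_profile(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    other_label: str = "Other",
) -> pd.DataFrame:
    """Per-sample relative abundance by taxonomic class.

    OTUs without taxonomy are labelled ``unclassified``; classes whose
    cohort-wide median relative abundance is zero are pooled into
    ``Other``. Rows sum to 1.
    """
    cls = taxonomy.set_index("otu_id")["class"]
    labels = [cls.get(otu, "unclassified") for otu in table.columns]
    rel = table.div(table.sum(axis=1), axis=0)
    prof = rel.T.groupby(pd.Index(labels, name="class")).sum().T
    medians = prof.median(axis=0)
    pooled = medians[medians <= 0].index
    if len(pooled):
        other = prof[pooled].sum(axis=1)
        prof = prof.drop(columns=pooled)
        prof[other_label] = prof.get(other_label, 0.0) + other
    return prof


def read_otu_table(path) -> pd.DataFrame:
    """Read an OTUs x samples TSV into the samples x OTUs convention."""
    df = pd.read_csv(path, sep="\t", index_col=0).T.rename_axis("person_id")
    df.columns.name = None
    return df
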