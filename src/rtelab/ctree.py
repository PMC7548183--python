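"""Permutation-based conditional inference trees and a small forest.

A tree node splits only when a covariate-response independence test,
Bonferroni-adjusted across the covariates tried at that node, rejects at
``alpha``.  The association statistic is the Pearson chi-square on the
contingency table for a categorical response and the between-level sum of
squares for a numeric response; its null distribution is obtained by
permuting the covariate — exhaustively when the number of distinct
arrangements is small, by Monte Carlo otherwise.  Within the selected
covariate the binary level partition maximizing the statistic is retained.

The forest grows each tree on a bootstrap resample with a random covariate
subset per node and scores variable importance as the mean drop in
out-of-bag prediction accuracy when a covariate's values are permuted.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rtelab.errors import ConfigError, DataError

EXACT_LIMIT = 10_000
DEFAULT_N_PERM = 9_999


# ---------------------------------------------------------------------------
# Independence test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndependenceTest:
    statistic: float
    p_value: float
    exact: bool
    n_null: int
    degenerate: bool = False


def _chi2_stat(cov_codes: np.ndarray, y_onehot: np.ndarray, level_counts: np.ndarray) -> float:
    n = len(cov_codes)
    col = y_onehot.sum(axis=0)
    stat = 0.0
    for l, nl in enumerate(level_counts):
        obs = y_onehot[cov_codes == l].sum(axis=0)
        exp = nl * col / n
        nz = exp > 0
        stat += float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    return stat


def _bss_stat(cov_codes: np.ndarray, y: np.ndarray, level_counts: np.ndarray) -> float:
    grand = y.mean()
    stat = 0.0
    for l, nl in enumerate(level_counts):
        if nl:
            stat += nl * (y[cov_codes == l].mean() - grand) ** 2
    return float(stat)


def _multiset_permutations(items: tuple):
    """Yield distinct permutations of a sorted tuple of small integers."""
    counts = Counter(items)
    keys = sorted(counts)
    n = len(items)
    out = [0] * n

    def rec(pos):
        if pos == n:
            yield tuple(out)
            return
        for k in keys:
            if counts[k]:
                counts[k] -= 1
                out[pos] = k
                yield from rec(pos + 1)
                counts[k] += 1

    yield from rec(0)


def _n_arrangements(level_counts: Sequence[int]) -> int:
    n = int(sum(level_counts))
    total = math.factorial(n)
    for c in level_counts:
        total //= math.factorial(int(c))
    return total


def independence_test(
    response: Sequence,
    covariate: Sequence,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    force_monte_carlo: bool = False,
) -> IndependenceTest:
    """Permutation test of independence between a response (categorical or
    numeric) and a categorical covariate.

    Exhaustive enumeration over the distinct covariate arrangements is used
    when there are at most 10,000 of them; otherwise ``n_perm`` Monte Carlo
    permutations with the add-one convention, so the p-value is never 0.
    A constant response or single-level covariate gives p = 1, flagged via
    ``degenerate``.
    """
    y = np.asarray(response)
    cov = np.asarray(covariate)
    if len(y) != len(cov):
        raise ConfigError("response and covariate lengths differ")
    if len(y) < 2:
        raise ConfigError("need at least two observations")
    numeric = np.issubdtype(y.dtype, np.number)
    cov_levels, cov_codes = np.unique(cov.astype(str), return_inverse=True)
    level_counts = np.bincount(cov_codes, minlength=len(cov_levels))
    if len(cov_levels) < 2 or len(np.unique(y)) < 2:
        return IndependenceTest(0.0, 1.0, exact=True, n_null=1, degenerate=True)

    if numeric:
        yv = y.astype(float)

        def stat(codes):
            return _bss_stat(codes, yv, level_counts)

        # vectorized Monte Carlo uses level-sum formulation below
        y_num = yv
        y_onehot = None
    else:
        _, yc = np.unique(y.astype(str), return_inverse=True)
        y_onehot = np.eye(yc.max() + 1)[yc]

        def stat(codes):
            return _chi2_stat(codes, y_onehot, level_counts)

        y_num = None

    observed = stat(cov_codes)
    total = _n_arrangements(level_counts)
    if total <= EXACT_LIMIT and not force_monte_carlo:
        count = 0
        for perm in _multiset_permutations(tuple(sorted(cov_codes.tolist()))):
            if stat(np.asarray(perm)) >= observed - 1e-12:
                count += 1
        return IndependenceTest(observed, count / total, exact=True, n_null=total)

    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(cov_codes)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    cov_perm = cov_codes[order]  # (n_perm, n)
    stats = np.zeros(n_perm)
    if y_onehot is not None:
        colcounts = y_onehot.sum(axis=0)
        for l, nl in enumerate(level_counts):
            obs = (cov_perm == l).astype(float) @ y_onehot  # (n_perm, C)
            exp = nl * colcounts / n
            nz = exp > 0
            stats += ((obs[:, nz] - exp[nz]) ** 2 / exp[nz]).sum(axis=1)
    else:
        grand = y_num.mean()
        for l, nl in enumerate(level_counts):
            sums = (cov_perm == l).astype(float) @ y_num
            stats += nl * (sums / nl - grand) ** 2
    count = int((stats >= observed - 1e-12).sum())
    p = (1 + count) / (1 + n_perm)
    return IndependenceTest(observed, p, exact=False, n_null=n_perm)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """One node of a conditional inference tree (leaf iff ``split_var`` is
    None).  ``summary`` holds class counts (categorical response) or
    ``{"n": ..., "mean": ..., "sd": ...}`` (numeric)."""

    node_id: int
    n: int
    summary: dict
    split_var: str | None = None
    left_levels: tuple[str, ...] = ()
    right_levels: tuple[str, ...] = ()
    p_adj: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()
            yield from self.right.leaves()

    def node_count(self) -> int:
        return 1 if self.is_leaf else 1 + self.left.node_count() + self.right.node_count()


def _summarize(y: np.ndarray, numeric: bool) -> dict:
    if numeric:
        yv = y.astype(float)
        return {
            "n": int(len(yv)),
            "mean": float(yv.mean()),
            "sd": float(yv.std(ddof=1)) if len(yv) > 1 else 0.0,
        }
    return {str(k): int(v) for k, v in sorted(Counter(y.astype(str).tolist()).items())}


def _best_partition(
    y: np.ndarray,
    cov: np.ndarray,
    numeric: bool,
    min_obs: int,
) -> tuple[tuple[str, ...], tuple[str, ...]] | None:
    """Binary level partition of ``cov`` maximizing the association
    statistic, subject to at least ``min_obs`` rows per side."""
    levels = sorted(np.unique(cov.astype(str)))
    if numeric:
        yv = y.astype(float)
    else:
        _, yc = np.unique(y.astype(str), return_inverse=True)
        onehot = np.eye(yc.max() + 1)[yc]
    best = None
    best_stat = -1.0
    m = len(levels)
    # subsets always containing levels[0] on the left, mirrors skipped
    for mask in range(2 ** (m - 1)):
        left = (levels[0],) + tuple(
            levels[i] for i in range(1, m) if (mask >> (i - 1)) & 1
        )
        if len(left) == m:
            continue
        right = tuple(l for l in levels if l not in left)
        side = np.isin(cov.astype(str), left)
        n_left = int(side.sum())
        if n_left < min_obs or len(y) - n_left < min_obs:
            continue
        codes = (~side).astype(int)
        counts = np.bincount(codes, minlength=2)
        s = _bss_stat(codes, yv, counts) if numeric else _chi2_stat(codes, onehot, counts)
        if s > best_stat + 1e-12:
            best_stat = s
            best = (left, right)
    return best


def grow_tree(
    data: pd.DataFrame,
    covariates: Sequence[str],
    response: str,
    alpha: float = 0.05,
    min_obs: int = 2,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """Grow a conditional inference tree by recursive binary splitting.

    At each node the per-covariate permutation p-values are Bonferroni
    multiplied by the number of covariates tried there; the node becomes a
    leaf when the smallest adjusted p exceeds ``alpha`` or no partition
    leaves ``min_obs`` rows on each side.  Ties in adjusted p are broken by
    covariate order in ``covariates``.  With ``mtry`` set, each node tries
    a random subset of covariates (forest mode).
    """
    if len(data) == 0:
        raise DataError("cannot grow a tree on empty data")
    for c in [response, *covariates]:
        if c not in data.columns:
            raise ConfigError(f"column {c!r} not present in data")
    if mtry is not None and not (1 <= mtry <= len(covariates)):
        raise ConfigError(f"mtry={mtry} out of range 1..{len(covariates)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    y_all = data[response].to_numpy()
    numeric = np.issubdtype(y_all.dtype, np.number)
    cov_arrays = {c: data[c].astype(str).to_numpy() for c in covariates}
    counter = [0]

    def build(idx: np.ndarray) -> TreeNode:
        counter[0] += 1
        node = TreeNode(
            node_id=counter[0], n=len(idx), summary=_summarize(y_all[idx], numeric)
        )
        if len(idx) < 2 * min_obs:
            return node
        tried = list(covariates)
        if mtry is not None and mtry < len(covariates):
            keep = rng.choice(len(covariates), size=mtry, replace=False)
            tried = [covariates[i] for i in sorted(keep)]
        best_var, best_p = None, math.inf
        for c in tried:
            res = independence_test(
                y_all[idx], cov_arrays[c][idx], n_perm=n_perm, rng=rng
            )
            p_adj = min(1.0, res.p_value * len(tried))
            if p_adj < best_p - 1e-15:
                best_p, best_var = p_adj, c
        if best_var is None or best_p > alpha:
            return node
        part = _best_partition(y_all[idx], cov_arrays[best_var][idx], numeric, min_obs)
        if part is None:
            return node
        left_levels, right_levels = part
        side = np.isin(cov_arrays[best_var][idx], left_levels)
        node.split_var = best_var
        node.left_levels = left_levels
        node.right_levels = right_levels
        node.p_adj = best_p
        node.left = build(idx[side])
        node.right = build(idx[~side])
        return node

    return build(np.arange(len(data)))


def predict_node(tree: TreeNode, record: Mapping[str, object]) -> tuple[TreeNode, bool]:
    """Route one record to its leaf; returns ``(leaf, flagged)`` where
    ``flagged`` is True when an unseen covariate level was routed to the
    child with more training samples."""
    node = tree
    flagged = False
    while not node.is_leaf:
        if node.split_var not in record:
            raise ConfigError(f"record lacks covariate {node.split_var!r}")
        value = str(record[node.split_var])
        if value in node.left_levels:
            node = node.left
        elif value in node.right_levels:
            node = node.right
        else:
            flagged = True
            node = node.left if node.left.n >= node.right.n else node.right
    return node, flagged


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def tree_to_text(node: TreeNode, indent: str = "") -> str:
    lines = []

    def fmt_summary(s: dict) -> str:
        if "mean" in s:
            return f"n={s['n']} mean={s['mean']:.3f} sd={s['sd']:.3f}"
        total = sum(s.values())
        parts = " ".join(f"{k}:{v}" for k, v in s.items())
        return f"n={total} [{parts}]"

    def rec(n: TreeNode, prefix: str):
        if n.is_leaf:
            lines.append(f"{prefix}[{n.node_id}] leaf {fmt_summary(n.summary)}")
        else:
            lines.append(
                f"{prefix}[{n.node_id}] {n.split_var} (p_adj={n.p_adj:.4g}) {fmt_summary(n.summary)}"
            )
            lines.append(f"{prefix}  {{{', '.join(n.left_levels)}}}:")
            rec(n.left, prefix + "    ")
            lines.append(f"{prefix}  {{{', '.join(n.right_levels)}}}:")
            rec(n.right, prefix + "    ")

    rec(node, indent)
    return "\n".join(lines)


def tree_to_dot(node: TreeNode, name: str = "ctree") -> str:
    lines = [f"digraph {name} {{", "  node [shape=box];"]

    def rec(n: TreeNode):
        if n.is_leaf:
            label = "\\n".join(f"{k}={v}" for k, v in n.summary.items())
            lines.append(f'  n{n.node_id} [label="[{n.node_id}]\\n{label}"];')
        else:
            lines.append(
                f'  n{n.node_id} [label="[{n.node_id}] {n.split_var}\\np_adj={n.p_adj:.4g}\\nn={n.n}"];'
            )
            rec(n.left)
            rec(n.right)
            lines.append(
                f'  n{n.node_id} -> n{n.left.node_id} [label="{",".join(n.left_levels)}"];'
            )
            lines.append(
                f'  n{n.node_id} -> n{n.right.node_id} [label="{",".join(n.right_levels)}"];'
            )

    rec(node)
    lines.append("}")
    return "\n".join(lines)


def tree_to_dict(node: TreeNode) -> dict:
    d = {
        "node_id": node.node_id,
        "n": node.n,
        "summary": node.summary,
        "split_var": node.split_var,
        "left_levels": list(node.left_levels),
        "right_levels": list(node.right_levels),
        "p_adj": node.p_adj,
    }
    if not node.is_leaf:
        d["left"] = tree_to_dict(node.left)
        d["right"] = tree_to_dict(node.right)
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        node_id=d["node_id"],
        n=d["n"],
        summary=d["summary"],
        split_var=d.get("split_var"),
        left_levels=tuple(d.get("left_levels", ())),
        right_levels=tuple(d.get("right_levels", ())),
        p_adj=d.get("p_adj"),
    )
    if "left" in d:
        node.left = tree_from_dict(d["left"])
        node.right = tree_from_dict(d["right"])
    return node


def tree_to_json(node: TreeNode) -> str:
    return json.dumps(tree_to_dict(node), indent=1)


def tree_from_json(s: str) -> TreeNode:
    return tree_from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Forest importance
# ---------------------------------------------------------------------------


@dataclass
class ForestImportance:
    """Per-covariate mean decrease in out-of-bag prediction accuracy under
    covariate permutation (numeric responses score negative MSE, so the
    drop is an MSE increase)."""

    importances: dict
    per_tree_accuracy: list
    n_trees: int


def _predict_frame(tree: TreeNode, data: pd.DataFrame, numeric: bool) -> np.ndarray:
    preds = []
    for _, row in data.iterrows():
        leaf, _ = predict_node(tree, row)
        if numeric:
            preds.append(leaf.summary["mean"])
        else:
            preds.append(max(leaf.summary, key=leaf.summary.get))
    return np.asarray(preds)


def _accuracy(y: np.ndarray, pred: np.ndarray, numeric: bool) -> float:
    if numeric:
        return -float(np.mean((y.astype(float) - pred.astype(float)) ** 2))
    return float(np.mean(y.astype(str) == pred.astype(str)))


def forest_importance(
    data: pd.DataFrame,
    covariates: Sequence[str],
    response: str,
    n_trees: int = 100,
    mtry: int | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
    min_obs: int = 2,
    n_perm: int = 999,
) -> ForestImportance:
    """Bootstrap forest with per-node covariate subsampling and
    permutation variable importance computed on out-of-bag rows only."""
    if n_trees < 1:
        raise ConfigError("n_trees must be >= 1")
    covariates = list(covariates)
    if mtry is None:
        mtry = max(1, int(round(math.sqrt(len(covariates)))))
    if not (1 <= mtry <= len(covariates)):
        raise ConfigError(f"mtry={mtry} out of range 1..{len(covariates)}")
    rng = np.random.default_rng(seed)
    y_all = data[response].to_numpy()
    numeric = np.issubdtype(y_all.dtype, np.number)
    n = len(data)
    importances = {c: [] for c in covariates}
    per_tree_acc = []
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[np.unique(boot)] = False
        tree = grow_tree(
            data.iloc[boot].reset_index(drop=True),
            covariates,
            response,
            alpha=alpha,
            min_obs=min_obs,
            n_perm=n_perm,
            mtry=mtry,
            rng=rng,
        )
        oob = data.loc[oob_mask].reset_index(drop=True)
        if len(oob) == 0:
            per_tree_acc.append(float("nan"))
            continue
        y_oob = oob[response].to_numpy()
        acc = _accuracy(y_oob, _predict_frame(tree, oob, numeric), numeric)
        per_tree_acc.append(acc)
        for c in covariates:
            shuffled = oob.copy()
            shuffled[c] = rng.permutation(shuffled[c].to_numpy())
            acc_perm = _accuracy(y_oob, _predict_frame(tree, shuffled, numeric), numeric)
            importances[c].append(acc - acc_perm)
    return ForestImportance(
        importances={
            c: (float(np.mean(v)) if v else 0.0) for c, v in importances.items()
        },
        per_tree_accuracy=per_tree_acc,
        n_trees=n_trees,
    )
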