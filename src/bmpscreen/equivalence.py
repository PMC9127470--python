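"""Ligand equivalence groups from interaction profiles.

Two ligands are functionally equivalent in a cell context when they have
similar individual strength and the same *type* of interaction with every
other ligand.  Each ligand is summarized by a feature vector of its IC
values with every other ligand, its self-pair IC, and twice its RLS -- the
doubling calibrates the scales so that a Euclidean distance of 1
corresponds either to a unit IC difference (one full interaction regime) or
to an RLS difference of 0.5 (a strong vs a weak activator).  Ligands are
then clustered agglomeratively with complete linkage; groups merge only
strictly below the distance threshold (default 1), and any group whose
members disagree on the interaction category with an outside ligand is
split along its linkage tree until every group is "monochromatic".

For the cross-context (global) analysis the per-context vectors are
concatenated and the cut raised (default Euclidean distance 7 for seven
contexts); global groups are not forced to be monochromatic, so that no
single pairwise call can separate ligands globally.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "build_feature_vectors",
    "EquivalenceClustering",
    "cluster_equivalence",
    "global_equivalence",
    "EquivalenceMap",
    "sequence_distance_matrix",
    "correlate_profiles",
]


def build_feature_vectors(
    rls: pd.Series | dict,
    interactions: pd.DataFrame,
    contexts: list[str] | None = None,
) -> pd.DataFrame:
    """Per-ligand feature matrix: ICs with all ligands, self-IC, and 2x RLS.

    ``rls`` maps (context, ligand) -> RLS (a Series with a 2-level index, or
    for a single context a plain ligand -> RLS mapping).  ``interactions``
    is the summary table with columns context_id, ligand_a, ligand_b,
    summary_ic (one row per pair per context is enough).  Feature order is
    deterministic: contexts in declared order, ligands in canonical (sorted
    panel) order.  A missing pair is an error, never imputed.

    Returns a DataFrame indexed by ligand with one column per feature;
    for N ligands and one context the row length is N+1.
    """
    inter = interactions.drop_duplicates(["context_id", "ligand_a", "ligand_b"])
    if contexts is None:
        contexts = list(dict.fromkeys(inter["context_id"]))
    ligands = sorted(set(inter["ligand_a"]) | set(inter["ligand_b"]))
    ic = {}
    for rec in inter.itertuples(index=False):
        ic[(rec.context_id, rec.ligand_a, rec.ligand_b)] = rec.summary_ic
        ic[(rec.context_id, rec.ligand_b, rec.ligand_a)] = rec.summary_ic
    if not isinstance(rls, (pd.Series, dict)):
        raise TypeError("rls must be a Series or dict")
    if isinstance(rls, dict):
        rls = pd.Series(rls)
    if not isinstance(rls.index, pd.MultiIndex):
        if len(contexts) != 1:
            raise ValueError("flat RLS mapping requires a single context")
        rls = pd.Series({(contexts[0], l): v for l, v in rls.items()})

    rows = {}
    cols = []
    for ctx in contexts:
        for other in ligands:
            cols.append(f"{ctx}:ic_{other}")
        cols.append(f"{ctx}:2rls")
    for lig in ligands:
        feats = []
        for ctx in contexts:
            for other in ligands:
                key = (ctx, lig, other)
                if key not in ic:
                    raise ValueError(f"missing interaction for pair ({lig}, {other}) in context {ctx}")
                feats.append(ic[key])
            if (ctx, lig) not in rls.index:
                raise ValueError(f"missing RLS for ligand {lig} in context {ctx}")
            feats.append(2.0 * rls.loc[(ctx, lig)])
        rows[lig] = feats
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).loc[ligands]


@dataclass
class EquivalenceMap:
    """Partition of the ligand set into equivalence groups."""

    groups: list[list[str]]
    linkage: np.ndarray
    ligands: list[str]
    mean_rls: dict[int, float] = field(default_factory=dict)

    @property
    def labels(self) -> dict[str, int]:
        return {lig: gi for gi, grp in enumerate(self.groups) for lig in grp}


class EquivalenceClustering(BaseEstimator, ClusterMixin):
    """Complete-linkage equivalence clustering with optional monochromaticity.

    Parameters
    ----------
    threshold : float
        Flat-cut distance; merges happen strictly below it, so two ligands
        exactly at the threshold distance stay separate.
    enforce_monochromatic : bool
        When True, any flat group whose members disagree on the interaction
        category with some ligand outside the group is split top-down along
        its linkage subtree until all groups satisfy the predicate.

    Attributes
    ----------
    labels_ : ndarray of group indices in input order
    linkage_ : condensed scipy linkage matrix (complete linkage, Euclidean)
    groups_ : list of ligand-name lists (when fit with a DataFrame)
    """

    def __init__(self, threshold: float = 1.0, enforce_monochromatic: bool = True):
        self.threshold = threshold
        self.enforce_monochromatic = enforce_monochromatic

    def fit(self, X, y=None, categories: dict | None = None):
        """Cluster feature vectors.

        ``categories`` maps (ligand_a, ligand_b) -> interaction category
        label (symmetric access is handled); it is required only when
        monochromaticity is enforced and there is more than one ligand.
        """
        if isinstance(X, pd.DataFrame):
            names = list(X.index)
            M = X.to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            names = [str(i) for i in range(M.shape[0])]
        if M.shape[0] == 1:
            self.labels_ = np.zeros(1, dtype=int)
            self.linkage_ = np.empty((0, 4))
            self.groups_ = [[names[0]]]
            return self
        Z = linkage(M, method="complete", metric="euclidean")
        self.linkage_ = Z
        root = to_tree(Z)
        cat = _SymmetricCategories(categories) if categories is not None else None

        groups: list[list[int]] = []

        def monochromatic(leaves: list[int]) -> bool:
            if cat is None or len(leaves) == 1:
                return True
            inside = set(leaves)
            outside = [i for i in range(M.shape[0]) if i not in inside]
            for o in outside:
                seen = {cat.get(names[i], names[o]) for i in leaves}
                if len(seen) > 1:
                    return False
            return True

        def descend(node):
            leaves = node.pre_order(lambda l: l.id)
            if node.is_leaf():
                groups.append(leaves)
                return
            if node.dist < self.threshold and (
                not self.enforce_monochromatic or monochromatic(leaves)
            ):
                groups.append(leaves)
                return
            descend(node.left)
            descend(node.right)

        descend(root)
        if self.enforce_monochromatic and cat is None and M.shape[0] > 1:
            raise ValueError("categories are required to enforce monochromaticity")
        labels = np.empty(M.shape[0], dtype=int)
        # deterministic group numbering by first member's input order
        groups.sort(key=lambda g: min(g))
        for gi, g in enumerate(groups):
            labels[g] = gi
        self.labels_ = labels
        self.groups_ = [[names[i] for i in sorted(g)] for g in groups]
        return self


class _SymmetricCategories:
    def __init__(self, mapping: dict):
        self._m = dict(mapping)

    def get(self, a: str, b: str):
        if (a, b) in self._m:
            return self._m[(a, b)]
        if (b, a) in self._m:
            return self._m[(b, a)]
        raise KeyError(f"no interaction category for pair ({a}, {b})")


def _to_map(est: EquivalenceClustering, features: pd.DataFrame,
            rls: pd.Series | None = None) -> EquivalenceMap:
    groups = est.groups_
    emap = EquivalenceMap(groups=groups, linkage=est.linkage_, ligands=list(features.index))
    if rls is not None:
        for gi, grp in enumerate(groups):
            vals = [float(rls.get(l, np.nan)) for l in grp]
            emap.mean_rls[gi] = float(np.nanmean(vals))
    return emap


def cluster_equivalence(
    features: pd.DataFrame,
    categories: dict | None = None,
    threshold: float = 1.0,
    rls: pd.Series | None = None,
) -> EquivalenceMap:
    """Per-context equivalence groups (monochromaticity enforced)."""
    est = EquivalenceClustering(threshold=threshold, enforce_monochromatic=True)
    est.fit(features, categories=categories)
    return _to_map(est, features, rls)


def global_equivalence(features: pd.DataFrame, threshold: float = 7.0) -> EquivalenceMap:
    """Cross-context groups on concatenated features; no monochromaticity."""
    est = EquivalenceClustering(threshold=threshold, enforce_monochromatic=False)
    est.fit(features)
    return _to_map(est, features)


# ---------------------------------------------------------------------------
# sequence similarity


def _read_fasta(source) -> list[tuple[str, str]]:
    from Bio import SeqIO

    if isinstance(source, (str, Path)):
        records = list(SeqIO.parse(str(source), "fasta"))
        return [(r.id, str(r.seq).upper()) for r in records]
    return [(name, seq.upper()) for name, seq in source]


def _msa(seqs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Progressive multiple alignment via mafft with default parameters."""
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.fa"
        fin.write_text("".join(f">{n}\n{s}\n" for n, s in seqs))
        out = subprocess.run(
            ["mafft", "--auto", "--anysymbol", str(fin)],
            capture_output=True, text=True, check=True,
        ).stdout
    aligned = []
    name, chunks = None, []
    for line in out.splitlines():
        if line.startswith(">"):
            if name is not None:
                aligned.append((name, "".join(chunks).upper()))
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    aligned.append((name, "".join(chunks).upper()))
    order = {n: i for i, (n, _) in enumerate(seqs)}
    return sorted(aligned, key=lambda p: order[p[0]])


def sequence_distance_matrix(
    sequences, aligned: bool | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """BLOSUM50 distances over gap-free alignment columns + average-linkage tree.

    ``sequences`` is a FASTA path or a list of (name, sequence) pairs.  A
    multiple alignment is computed unless the input sequences are already of
    equal length (or ``aligned=True``).  Over the columns with no gap in any
    sequence, the similarity s_ij is the summed BLOSUM50 score; the distance
    is d_ij = 1 - s_ij / min(s_ii, s_jj), zero for identical sequences.

    Returns ``(distance matrix DataFrame, average-linkage matrix)``.
    """
    from Bio.Align import substitution_matrices

    seqs = _read_fasta(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    blosum = substitution_matrices.load("BLOSUM50")
    valid = set(blosum.alphabet) | {"-"}
    for name, s in seqs:
        bad = set(s) - valid
        if bad:
            raise ValueError(f"sequence {name} contains non-amino-acid symbols: {sorted(bad)}")
    if aligned is None:
        aligned = len({len(s) for _, s in seqs}) == 1
    if not aligned:
        seqs = _msa(seqs)
    L = len(seqs[0][1])
    cols = [
        c for c in range(L)
        if all(s[c] != "-" for _, s in seqs)
    ]
    if not cols:
        raise ValueError("alignment has no gap-free columns")
    names = [n for n, _ in seqs]
    n = len(seqs)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            si, sj = seqs[i][1], seqs[j][1]
            sim[i, j] = sim[j, i] = sum(blosum[si[c], sj[c]] for c in cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = 1.0 - sim[i, j] / min(sim[i, i], sim[j, j])
    np.fill_diagonal(d, 0.0)
    dm = pd.DataFrame(d, index=names, columns=names)
    Z = linkage(squareform(d, checks=False), method="average")
    return dm, Z


def correlate_profiles(
    seq_dist: pd.DataFrame,
    feature_dist: pd.DataFrame,
    n_subsets: int = 0,
    contexts: list[str] | None = None,
    feature_by_context: dict[str, pd.DataFrame] | None = None,
    seed: int = 0,
):
    """Pearson correlation between sequence and interaction-profile distances.

    Correlates the off-diagonal (condensed) entries of the two matrices over
    matched ligand sets.  When ``n_subsets`` > 0 and per-context feature
    matrices are provided, also samples random context subsets, recomputes
    the profile distances on the concatenated subset features, and reports
    each subset's r plus the maximum found.
    """
    ligands = list(seq_dist.index)
    if list(feature_dist.index) != ligands:
        feature_dist = feature_dist.loc[ligands, ligands]
    x = squareform(seq_dist.to_numpy(), checks=False)
    y = squareform(feature_dist.to_numpy(), checks=False)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "constant_input": True}
    r, _ = pearsonr(x, y)
    result = {"r": float(r), "constant_input": False}
    if n_subsets > 0:
        if feature_by_context is None:
            raise ValueError("subset sweep requires per-context feature matrices")
        rng = np.random.default_rng(seed)
        names = contexts or list(feature_by_context)
        subset_r = []
        for _ in range(n_subsets):
            k = int(rng.integers(1, len(names) + 1))
            pick = sorted(rng.choice(len(names), size=k, replace=False))
            F = pd.concat([feature_by_context[names[i]].loc[ligands] for i in pick], axis=1)
            yd = pdist(F.to_numpy())
            if np.std(yd) == 0:
                continue
            subset_r.append((tuple(names[i] for i in pick), float(pearsonr(x, yd)[0])))
        result["subsets"] = subset_r
        result["max_subset_r"] = max((r for _, r in subset_r), default=float("nan"))
    return result
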