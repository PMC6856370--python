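"""Pairwise nucleotide distances and Neighbor-Joining tree construction.

Distances are computed after *complete deletion* (every alignment column
containing a gap or ambiguous base is discarded) under one of four models:

* ``p``       — proportion of differing sites.
* ``jc``      — Jukes-Cantor, d = -(3/4) ln(1 - 4p/3).
* ``tn93``    — Tamura-Nei 1993 closed-form per-pair estimator (distinct
  purine/pyrimidine transition rates, unequal base frequencies).
* ``mcl-tn93`` — composite-likelihood TN93: the two transition/transversion
  rate ratios are shared across *all* pairs and chosen, together with the
  pairwise distances, to maximize the summed pairwise log-likelihood
  (the "maximum composite likelihood" style of distance estimation).

Trees are built with the Saitou-Nei Neighbor-Joining agglomeration with a
deterministic tie-break (smallest taxon-index pair on equal Q); negative
branch lengths are clamped to zero with the raw value logged.  The final
three-taxon star is resolved exactly by the three-point formulas.  A
two-taxon input becomes a single edge split evenly between the two leaves,
so the leaf-to-leaf path length equals the input distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .promoter_io import AlignedPromoterSet, GAP, PromoterIOError

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
# indices: A=0, C=1, G=2, T=3; purines {A,G}, pyrimidines {C,T}


class PhyloError(ValueError):
    pass


def complete_deletion(aligned: AlignedPromoterSet) -> tuple[AlignedPromoterSet, int]:
    """Drop every column containing a gap or an ambiguous base (N).

    Returns the column-filtered (gap-free) alignment and the number of
    retained columns (the usable-sites count reported with distances).
    """
    if len(aligned.members) < 2:
        raise PhyloError("complete deletion needs >= 2 members")
    seqs = {sp: s for sp, s in aligned.members.items()}
    arr = np.array([list(s) for s in seqs.values()])
    keep = np.all(np.isin(arr, list(BASES)), axis=0)
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise PhyloError("no columns retained after complete deletion")
    filtered = {sp: "".join(np.array(list(s))[keep]) for sp, s in seqs.items()}
    return AlignedPromoterSet(members=filtered), n_kept


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise distances in substitutions/site over an ordered taxon list."""

    taxa: tuple[str, ...]
    d: np.ndarray
    usable_sites: int
    saturated: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise PhyloError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise PhyloError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                row = "\t".join(f"{x:.8f}" for x in self.d[i])
                fh.write(f"{t}\t{row}\n")


def p_distance(s1: str, s2: str) -> float:
    if len(s1) != len(s2) or not s1:
        raise PhyloError("sequences must be equal nonzero length")
    diffs = sum(a != b for a, b in zip(s1, s2))
    return diffs / len(s1)


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction; undefined (saturated) at p >= 3/4."""
    if p < 0 or p >= 0.75:
        raise PhyloError(f"JC distance undefined at p = {p}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _pair_counts(s1: str, s2: str) -> np.ndarray:
    """Symmetrized 4x4 site-pattern count matrix."""
    counts = np.zeros((4, 4))
    for a, b in zip(s1, s2):
        counts[_BASE_IDX[a], _BASE_IDX[b]] += 1
    return (counts + counts.T) / 2.0


def tn93_distance(s1: str, s2: str, freqs: Sequence[float] | None = None) -> float:
    """Closed-form Tamura-Nei (1993) distance for one pair.

    ``freqs`` (A,C,G,T) default to the empirical frequencies of the pair.
    """
    n = len(s1)
    counts = _pair_counts(s1, s2)
    if freqs is None:
        f = (counts.sum(axis=0) + counts.sum(axis=1)) / (2.0 * n)
    else:
        f = np.asarray(freqs, dtype=float)
        f = f / f.sum()
    pA, pC, pG, pT = f
    pR, pY = pA + pG, pC + pT
    P1 = (counts[0, 2] + counts[2, 0]) / n  # A<->G transitions
    P2 = (counts[1, 3] + counts[3, 1]) / n  # C<->T transitions
    Q = (counts[0, 1] + counts[1, 0] + counts[0, 3] + counts[3, 0]
         + counts[2, 1] + counts[1, 2] + counts[2, 3] + counts[3, 2]) / n
    k1 = 2.0 * pA * pG / pR
    k2 = 2.0 * pC * pT / pY
    k3 = 2.0 * (pR * pY - pA * pG * pY / pR - pC * pT * pR / pY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * pR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * pY)
    w3 = 1.0 - Q / (2.0 * pR * pY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise PhyloError("TN93 distance undefined (saturated pair)")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def tn93_rate_matrix(kappa1: float, kappa2: float, freqs: Sequence[float]) -> np.ndarray:
    """TN93 rate matrix normalized to one expected substitution per unit time.

    ``kappa1``/``kappa2`` are the purine/pyrimidine transition rates relative
    to the transversion rate.
    """
    pA, pC, pG, pT = np.asarray(freqs, dtype=float) / np.sum(freqs)
    Q = np.zeros((4, 4))
    for i, j in itertools.product(range(4), range(4)):
        if i == j:
            continue
        pj = (pA, pC, pG, pT)[j]
        purines = {0, 2}
        if {i, j} == {0, 2}:
            Q[i, j] = kappa1 * pj
        elif {i, j} == {1, 3}:
            Q[i, j] = kappa2 * pj
        else:
            Q[i, j] = pj
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = np.array([pA, pC, pG, pT])
    mu = -float(pi @ np.diag(Q))
    return Q / mu


def _pair_loglik(counts: np.ndarray, pi: np.ndarray, Qrate: np.ndarray, d: float) -> float:
    P = expm(Qrate * d)
    joint = pi[:, None] * P
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(joint[mask])))


def mcl_tn93_distances(
    aligned: AlignedPromoterSet,
    freqs: Sequence[float] | None = None,
    tol: float = 1e-8,
) -> tuple[DistanceMatrix, dict]:
    """Composite-likelihood TN93 distances with globally shared rate ratios.

    The two transition/transversion ratios (and, unless supplied, the base
    frequencies pooled over all sequences) are shared across pairs; the
    summed pairwise log-likelihood is maximized jointly over the ratios and
    all pairwise distances (L-BFGS-B in log-parameter space, tolerance
    ``tol``).  Returns the distances and the fitted shared parameters.
    """
    taxa = tuple(aligned.members)
    seqs = [aligned.members[t] for t in taxa]
    n = len(taxa)
    L = len(seqs[0])
    if freqs is None:
        all_bases = "".join(seqs)
        pi = np.array([all_bases.count(b) for b in BASES], dtype=float)
        pi /= pi.sum()
    else:
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
    pairs = list(itertools.combinations(range(n), 2))
    counts = {pr: _pair_counts(seqs[pr[0]], seqs[pr[1]]) for pr in pairs}

    # start from closed-form estimates
    d0 = []
    for i, j in pairs:
        try:
            d0.append(max(tn93_distance(seqs[i], seqs[j], freqs=pi), 1e-8))
        except PhyloError:
            d0.append(max(p_distance(seqs[i], seqs[j]), 1e-8))
    x0 = np.log(np.array(d0 + [1.0, 1.0]))

    def negloglik(x: np.ndarray) -> float:
        ds = np.exp(x[:-2])
        k1, k2 = np.exp(x[-2]), np.exp(x[-1])
        Qr = tn93_rate_matrix(k1, k2, pi)
        return -sum(_pair_loglik(counts[pr], pi, Qr, d)
                    for pr, d in zip(pairs, ds))

    res = minimize(negloglik, x0, method="L-BFGS-B",
                   options={"ftol": tol * 1e-4, "gtol": tol, "maxiter": 2000})
    ds = np.exp(res.x[:-2])
    k1, k2 = float(np.exp(res.x[-2])), float(np.exp(res.x[-1]))
    D = np.zeros((n, n))
    for (i, j), d in zip(pairs, ds):
        D[i, j] = D[j, i] = d
    dm = DistanceMatrix(taxa=taxa, d=D, usable_sites=L)
    return dm, {"kappa1": k1, "kappa2": k2, "freqs": pi.tolist(),
                "loglik": -float(res.fun), "converged": bool(res.success)}


def pairwise_distances(
    aligned: AlignedPromoterSet,
    model: str = "mcl-tn93",
    freqs: Sequence[float] | None = None,
) -> DistanceMatrix:
    """Distance matrix under the chosen model on a complete-deletion alignment.

    The alignment must already be gap/N free (apply :func:`complete_deletion`
    first).  JC-saturated pairs (p >= 3/4) are flagged in ``saturated`` and
    reported as +inf rather than silently dropped.
    """
    model = model.lower()
    taxa = tuple(aligned.members)
    if len(taxa) < 2:
        raise PhyloError("need >= 2 taxa")
    seqs = [aligned.members[t] for t in taxa]
    for t, s in zip(taxa, seqs):
        bad = set(s) - set(BASES)
        if bad:
            raise PhyloError(
                f"{t} contains {sorted(bad)}: apply complete_deletion before distances"
            )
    L = len(seqs[0])
    if model == "mcl-tn93":
        dm, _ = mcl_tn93_distances(aligned, freqs=freqs)
        return dm
    n = len(taxa)
    D = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n), 2):
        if model == "p":
            d = p_distance(seqs[i], seqs[j])
        elif model == "jc":
            p = p_distance(seqs[i], seqs[j])
            try:
                d = jc_distance(p)
            except PhyloError:
                d = math.inf
                saturated.append((taxa[i], taxa[j]))
        elif model == "tn93":
            try:
                d = tn93_distance(seqs[i], seqs[j], freqs=freqs)
            except PhyloError:
                d = math.inf
                saturated.append((taxa[i], taxa[j]))
        else:
            raise PhyloError(f"unknown model {model!r}")
        D[i, j] = D[j, i] = d
    return DistanceMatrix(taxa=taxa, d=D, usable_sites=L, saturated=tuple(saturated))


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths, wrapping a dendropy Tree.

    ``clamp_log`` records any NJ branch whose raw estimate was negative
    (clamped to zero), as ``(leaf-set description, raw value)``.
    """

    tree: dendropy.Tree
    clamp_log: tuple[tuple[str, float], ...] = ()

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(lf.taxon.label for lf in self.tree.leaf_node_iter()))

    @property
    def sum_branch_lengths(self) -> float:
        return float(sum(e.length for e in self.tree.edges() if e.length is not None))

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length metric between leaves (for additivity checks)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = self.taxa
        tax_objs = {t.label: t for t in self.tree.taxon_namespace}
        n = len(taxa)
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            D[i, j] = D[j, i] = pdm.patristic_distance(tax_objs[taxa[i]], tax_objs[taxa[j]])
        return DistanceMatrix(taxa=taxa, d=D, usable_sites=0)

    def branch_length_of(self, leaf_label: str) -> float:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == leaf_label:
                return float(lf.edge.length or 0.0)
        raise PhyloError(f"no leaf {leaf_label!r}")


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbor-Joining on a distance matrix.

    Ties on the Q criterion break to the smallest (i, j) pair in the current
    taxon order, making the agglomeration deterministic.  Negative branch
    lengths are clamped to zero and logged.
    """
    if not np.all(np.isfinite(D.d)):
        raise PhyloError("non-finite distances (saturated pairs?) — cannot build tree")
    n0 = len(D.taxa)
    if n0 < 2:
        raise PhyloError("need >= 2 taxa")
    tns = dendropy.TaxonNamespace(list(D.taxa))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for t in D.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(t))
        nodes.append(nd)
    clamp_log: list[tuple[str, float]] = []

    def clamp(node: dendropy.Node, raw: float) -> float:
        if raw < 0:
            label = node.taxon.label if node.taxon else "internal"
            clamp_log.append((label, raw))
            return 0.0
        return raw

    if n0 == 2:
        # single edge by convention, split evenly so the path length is d
        half = D.d[0, 1] / 2.0
        root = dendropy.Node()
        for nd in nodes:
            root.add_child(nd)
            nd.edge.length = half
        tree.seed_node = root
        tree.is_rooted = False
        return PhyloTree(tree=tree, clamp_log=tuple(clamp_log))

    active = list(range(n0))
    dist = D.d.astype(float).copy()
    # grow dist as nodes are added
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        bi = dist[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = dist[i, j] - bi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(nodes[i], bi)
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(nodes[j], bj)
        new_idx = dist.shape[0]
        newrow = np.zeros((1, dist.shape[0]))
        dist = np.vstack([np.hstack([dist, newrow.T]), np.hstack([newrow, [[0.0]]])])
        for k in active:
            if k in (i, j):
                continue
            dist[new_idx, k] = dist[k, new_idx] = (dist[i, k] + dist[j, k] - dist[i, j]) / 2.0
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    root = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        a = (dist[i, j] + dist[i, k] - dist[j, k]) / 2.0
        b = (dist[i, j] + dist[j, k] - dist[i, k]) / 2.0
        c = (dist[i, k] + dist[j, k] - dist[i, j]) / 2.0
        for idx, length in zip((i, j, k), (a, b, c)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = clamp(nodes[idx], length)
    else:  # two subtrees remain (can only happen for n0 == 2, handled above)
        i, j = active
        root.add_child(nodes[i])
        nodes[i].edge.length = dist[i, j] / 2.0
        root.add_child(nodes[j])
        nodes[j].edge.length = dist[i, j] / 2.0
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, clamp_log=tuple(clamp_log))


def nj_leaf_branch_bootstrap(
    aligned: AlignedPromoterSet,
    model: str = "jc",
    n_boot: int = 100,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Site-bootstrap standard errors for NJ pendant branch lengths.

    Columns of the (gap-free) alignment are resampled with replacement
    ``n_boot`` times; distances (``p`` or ``jc``) and the NJ tree are
    recomputed on each replicate.  Returns, per leaf, the point estimate
    from the original alignment and the bootstrap standard error.  The
    bootstrap respects the between-pair correlation induced by shared
    sites, which a per-distance binomial formula would ignore.
    """
    if model not in ("p", "jc"):
        raise PhyloError("bootstrap supports p / jc distances")
    taxa = tuple(aligned.members)
    n = len(taxa)
    L = len(next(iter(aligned.members.values())))
    arr = np.array([list(aligned.members[t]) for t in taxa])
    pairs = list(itertools.combinations(range(n), 2))
    mismatch = np.stack([arr[i] != arr[j] for i, j in pairs])  # (n_pairs, L)

    def tree_from_p(pvec: np.ndarray) -> PhyloTree:
        D = np.zeros((n, n))
        for (i, j), p in zip(pairs, pvec):
            d = jc_distance(float(p)) if model == "jc" else float(p)
            D[i, j] = D[j, i] = d
        return nj_tree(DistanceMatrix(taxa=taxa, d=D, usable_sites=L))

    point = tree_from_p(mismatch.mean(axis=1))
    estimates = {t: point.branch_length_of(t) for t in taxa}
    rng = np.random.default_rng(seed)
    boots: dict[str, list[float]] = {t: [] for t in taxa}
    for _ in range(n_boot):
        idx = rng.integers(L, size=L)
        t_b = tree_from_p(mismatch[:, idx].mean(axis=1))
        for t in taxa:
            boots[t].append(t_b.branch_length_of(t))
    return {t: (estimates[t], float(np.std(boots[t], ddof=1))) for t in taxa}


def to_newick(ptree: PhyloTree, precision: int = 10) -> str:
    """Serialize with branch lengths at >= 6 significant digits."""
    s = ptree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}g",
    )
    return s.strip() + ("\n" if not s.endswith("\n") else "")


def parse_newick(text: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def write_newick(ptree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(ptree))


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())
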