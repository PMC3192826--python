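"""Census of signed structural motifs among the hub nodes of a network.

Two motif families are counted, with up to five nodes:

* cyclic motifs — the nodes form a directed cycle, either with single
  connections (one direction per edge) or with reciprocal connections
  (both directions per edge, feedforward and feedback);
* radial motifs — a center node reciprocally linked to each leaf; the
  connections among the leaves are not considered.

Only the sign of each connection matters (functional excitation E / inhibition
I). Two equivalence rules reduce the sign patterns to classes: (i) within a
reciprocal loop the direction of excitation vs inhibition is not
distinguished, so a loop is one of {EE, EI, II}; (ii) motifs obtained by
permuting the reciprocal loops are the same motif, so a reciprocal motif
class is the multiset of its loop classes. Single-connection cycles are
canonicalized up to rotation of the cycle.

The census is presence-based: a motif occurrence requires its edges to be
present; any additional connections among the chosen nodes are ignored (as
the leaf-leaf rule above makes explicit). A motif's probability is
P = 100 * F / M, with F the number of occurrences and M the number of
possible placements of that topology and size — so summing F over the sign
classes of one topology/size gives the number of placements with all edges
present.

The "counterbalanced" classes — every feedforward excitatory connection
paired with feedback inhibition, i.e. all loops EI — are the ones whose
prevalence distinguishes the healthy-rhythm networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytics import tns_and_hierarchy

__all__ = [
    "SignedAdjacency",
    "hub_subset",
    "signed_adjacency",
    "motif_census",
    "combine_censuses",
]

_LOOP_CLASSES = ("EE", "EI", "II")
_SIGN_CHAR = {1: "E", -1: "I"}


@dataclass(frozen=True)
class SignedAdjacency:
    """Sign pattern of the connections within a node subset.

    ``signs`` is a square matrix over ``nodes`` with entries in {+1, -1, 0}
    and zero diagonal; an entry is nonzero when the corresponding weight
    magnitude exceeds ``threshold`` (absolute units of W).
    """

    nodes: np.ndarray
    signs: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        s = np.asarray(self.signs, dtype=int)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("signs must be square")
        if np.any(np.diag(s) != 0):
            raise ValueError("diagonal must be zero")
        if not np.isin(s, (-1, 0, 1)).all():
            raise ValueError("signs must be in {-1, 0, +1}")
        object.__setattr__(self, "signs", s)
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=int))

    @property
    def n(self) -> int:
        return self.signs.shape[0]


def hub_subset(W: np.ndarray) -> np.ndarray:
    """Most strongly connected nodes: those at or below the 50th percentile
    of ranked TNS (the ranks that jointly account for half the total nodal
    strength)."""
    W = np.asarray(W, dtype=float)
    table, hier = tns_and_hierarchy(W, C=np.eye(W.shape[0]))
    return np.sort(table.loc[table["rank"] <= hier.half_rank, "node"].to_numpy())


def signed_adjacency(
    W: np.ndarray, subset: np.ndarray, rel_threshold: float = 0.05
) -> SignedAdjacency:
    """Threshold the weights within a subset into a sign matrix.

    A connection is deemed present when its magnitude exceeds
    ``rel_threshold`` times the largest off-diagonal magnitude within the
    subset; its sign is then the sign of the weight.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset is empty")
    sub = np.asarray(W, dtype=float)[np.ix_(subset, subset)]
    off = np.abs(sub.copy())
    np.fill_diagonal(off, 0.0)
    scale = off.max()
    thr = rel_threshold * scale
    signs = np.where(off > thr, np.sign(sub).astype(int), 0)
    np.fill_diagonal(signs, 0)
    return SignedAdjacency(nodes=subset, signs=signs, threshold=float(thr))


# ---------------------------------------------------------------------------
# Canonical sign classes
# ---------------------------------------------------------------------------

def _loop_class(s_fwd: int, s_back: int) -> str:
    # rule (i): (E, I) and (I, E) are the same loop
    return "".join(sorted(_SIGN_CHAR[s_fwd] + _SIGN_CHAR[s_back]))


def _canon_loops(loops: tuple[str, ...]) -> str:
    # rule (ii): permutations of reciprocal loops are equivalent
    return ",".join(sorted(loops))


def _canon_cycle_signs(signs: tuple[int, ...]) -> str:
    # rotations of the sign sequence around the cycle are the same motif
    chars = [_SIGN_CHAR[s] for s in signs]
    n = len(chars)
    return min("".join(chars[i:] + chars[:i]) for i in range(n))


def _catalogue(max_nodes: int) -> list[tuple[str, int, str, str]]:
    """All (topology, size, style, pattern) classes, sizes 2..max_nodes."""
    rows: list[tuple[str, int, str, str]] = []
    for n in range(2, max_nodes + 1):
        n_loops = 1 if n == 2 else n
        for combo in itertools.combinations_with_replacement(_LOOP_CLASSES, n_loops):
            rows.append(("cyclic", n, "reciprocal", _canon_loops(combo)))
        if n >= 3:
            seen: set[str] = set()
            for signs in itertools.product((1, -1), repeat=n):
                seen.add(_canon_cycle_signs(signs))
            rows.extend(("cyclic", n, "single", p) for p in sorted(seen))
            for combo in itertools.combinations_with_replacement(_LOOP_CLASSES, n - 1):
                rows.append(("radial", n, "reciprocal", _canon_loops(combo)))
    return rows


def motif_census(
    signedA: SignedAdjacency,
    max_nodes: int = 5,
    max_subset_size: int = 40,
) -> pd.DataFrame:
    """Exhaustive signed motif census of a hub sign matrix.

    Returns a DataFrame with one row per motif class (including classes that
    never occur): topology, size, style, pattern, occurrence count F, number
    of possible placements M, and probability P = 100 * F / M (percent).
    """
    A = signedA.signs
    h = signedA.n
    if h < 2:
        raise ValueError("need at least 2 nodes for a motif census")
    if h > max_subset_size:
        raise ValueError(
            f"subset of {h} nodes exceeds the exhaustive-enumeration cap "
            f"({max_subset_size}); raise max_subset_size explicitly"
        )
    counts: dict[tuple[str, int, str, str], int] = {}
    placements: dict[tuple[str, int, str], int] = {}
    max_nodes = min(max_nodes, h)

    for n in range(2, max_nodes + 1):
        key_rec = ("cyclic", n, "reciprocal")
        key_sin = ("cyclic", n, "single")
        key_rad = ("radial", n, "reciprocal")
        placements[key_rec] = 0
        if n >= 3:
            placements[key_sin] = 0
            placements[key_rad] = 0
        for combo in itertools.combinations(range(h), n):
            if n == 2:
                i, j = combo
                placements[key_rec] += 1
                if A[i, j] != 0 and A[j, i] != 0:
                    cls = (key_rec[0], n, key_rec[2], _canon_loops((_loop_class(A[i, j], A[j, i]),)))
                    counts[cls] = counts.get(cls, 0) + 1
                continue
            first = combo[0]
            rest = combo[1:]
            for perm in itertools.permutations(rest):
                cyc = (first, *perm)
                nxt = cyc[1:] + (first,)
                # single-connection directed cycle (every ordering = one
                # distinct directed cycle; both orientations counted)
                placements[key_sin] += 1
                # connection a -> b sits at A[b, a] (row = target node)
                fwd = [A[b, a] for a, b in zip(cyc, nxt)]
                if all(s != 0 for s in fwd):
                    cls = ("cyclic", n, "single", _canon_cycle_signs(tuple(fwd)))
                    counts[cls] = counts.get(cls, 0) + 1
                # reciprocal cycle: orientation is irrelevant, keep one
                if perm[0] < perm[-1]:
                    placements[key_rec] += 1
                    bwd = [A[a, b] for a, b in zip(cyc, nxt)]
                    if all(s != 0 for s in fwd) and all(s != 0 for s in bwd):
                        loops = tuple(
                            _loop_class(f, b) for f, b in zip(fwd, bwd)
                        )
                        cls = ("cyclic", n, "reciprocal", _canon_loops(loops))
                        counts[cls] = counts.get(cls, 0) + 1
            # radial: each member may be the center; leaf-leaf edges ignored
            for center in combo:
                placements[key_rad] += 1
                leaves = [v for v in combo if v != center]
                if all(A[center, l] != 0 and A[l, center] != 0 for l in leaves):
                    loops = tuple(_loop_class(A[center, l], A[l, center]) for l in leaves)
                    cls = ("radial", n, "reciprocal", _canon_loops(loops))
                    counts[cls] = counts.get(cls, 0) + 1

    rows = []
    for topology, size, style, pattern in _catalogue(max_nodes):
        key = (topology, size, style)
        M = placements.get(key, 0)
        F = counts.get((topology, size, style, pattern), 0)
        P = 100.0 * F / M if M else 0.0
        rows.append(
            {
                "topology": topology,
                "size": size,
                "style": style,
                "pattern": pattern,
                "F": F,
                "M": M,
                "P": P,
            }
        )
    return pd.DataFrame(rows)


def combine_censuses(censuses: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-matrix censuses into a group census.

    F and M are summed over the matrices (the group's placements are counted
    jointly over all its virtual brains) and P is recomputed.
    """
    if not censuses:
        raise ValueError("no censuses to combine")
    keys = ["topology", "size", "style", "pattern"]
    out = (
        pd.concat(censuses, ignore_index=True)
        .groupby(keys, as_index=False, sort=False)[["F", "M"]]
        .sum()
    )
    out["P"] = np.where(out["M"] > 0, 100.0 * out["F"] / out["M"], 0.0)
    return out
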