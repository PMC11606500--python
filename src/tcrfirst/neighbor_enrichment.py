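"""Sequence-neighbor enrichment against a shuffled-junction background.

Each clone is asked whether it has more sequence neighbors (CDR3s within a
fixed distance radius) in the repertoire than expected by chance.  The null is
estimated from a size-matched background built by recombining junction
prefixes and suffixes of the observed repertoire, preserving the V-gene and
CDR3-length marginals (and, when a pgen source is supplied, the
generation-probability profile).  Significance is a hypergeometric tail
probability with Bonferroni correction.

The CDR3 distance is a tcrdist-family mismatch score: BLOSUM62-discounted
substitution costs capped at 4, a gap penalty of 4 per length difference with
the shorter sequence padded by a central gap block, and an overall CDR3 weight
of 3 — under which the conventional neighbor radius is 12.5.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom

logger = logging.getLogger("tcrfirst")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP_CODE = 20  # sentinel row/column of zeros in the cost table


@dataclass
class DistanceParams:
    """Parameters of the CDR3 mismatch distance."""

    mismatch_cap: int = 4
    gap_cost: int = 4
    cdr3_weight: int = 3
    radius: float = 12.5
    substitution_matrix: Optional[np.ndarray] = None  # 20x20, AMINO_ACIDS order

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.substitution_matrix is None:
            self.substitution_matrix = _blosum62_table()
        S = np.asarray(self.substitution_matrix)
        if S.shape != (20, 20) or not np.array_equal(S, S.T):
            raise ValueError("substitution matrix must be a symmetric 20x20 table")

    def cost_table(self) -> np.ndarray:
        """21x21 per-position substitution cost; index 20 is the gap sentinel."""
        S = np.asarray(self.substitution_matrix, dtype=float)
        cost = np.minimum(self.mismatch_cap, self.mismatch_cap - S)
        cost = np.maximum(cost, 0.0)
        np.fill_diagonal(cost, 0.0)
        full = np.zeros((21, 21))
        full[:20, :20] = cost
        return full


def _blosum62_table() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    table = np.zeros((20, 20), dtype=int)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            table[i, j] = int(blosum[a][b])
    return table


def encode_cdr3(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-amino-acid character {exc} in CDR3 {seq!r}") from exc


def _pad_central(codes: np.ndarray, target_len: int) -> np.ndarray:
    """Insert a central gap block so the sequence reaches ``target_len``."""
    d = target_len - len(codes)
    if d == 0:
        return codes
    split = (len(codes) + 1) // 2
    return np.concatenate([codes[:split], np.full(d, _GAP_CODE, np.uint8), codes[split:]])


def cdr3_distance(a: str, b: str, params: Optional[DistanceParams] = None) -> float:
    """Weighted mismatch distance between two CDR3 amino-acid strings.

    ``cdr3_weight * (sum of per-position substitution costs + gap_cost * |len
    difference|)`` with the shorter sequence padded by a central gap block and
    substitution cost ``min(cap, cap - S(x, y))`` for x != y (0 for matches).
    Symmetric; zero iff the sequences are identical.
    """
    params = params or DistanceParams()
    ca, cb = encode_cdr3(a), encode_cdr3(b)
    if len(ca) > len(cb):
        ca, cb = cb, ca
    d = len(cb) - len(ca)
    ca = _pad_central(ca, len(cb))
    table = params.cost_table()
    sub = table[ca, cb].sum()
    return params.cdr3_weight * (sub + params.gap_cost * d)


# ---------------------------------------------------------------------------
# vectorized neighbor counting
# ---------------------------------------------------------------------------


class NeighborCounter:
    """Counts pool sequences within the distance radius of a query.

    The pool is encoded once, grouped by CDR3 length; queries are compared
    against a length group only when the gap penalty alone cannot already
    exceed the radius (``|len difference| * gap_cost * cdr3_weight > radius``
    skips the group).
    """

    def __init__(self, pool: Sequence[str], params: Optional[DistanceParams] = None):
        self.params = params or DistanceParams()
        self._table = self.params.cost_table()
        self._groups: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
        by_len: Dict[int, List[Tuple[int, np.ndarray]]] = defaultdict(list)
        for idx, seq in enumerate(pool):
            by_len[len(seq)].append((idx, encode_cdr3(seq)))
        for L, entries in by_len.items():
            ids = np.array([e[0] for e in entries], dtype=np.int64)
            mat = np.stack([e[1] for e in entries])
            self._groups[L] = (ids, mat)

    def count(self, query: str, exclude_index: Optional[int] = None) -> int:
        p = self.params
        q = encode_cdr3(query)
        lq = len(q)
        total = 0
        for L, (ids, mat) in self._groups.items():
            d = abs(L - lq)
            base = p.cdr3_weight * p.gap_cost * d
            if base > p.radius:
                continue
            if L >= lq:
                qpad = _pad_central(q, L)
                pmat = mat
            else:
                qpad = q
                split = (L + 1) // 2
                gap_block = np.full((mat.shape[0], lq - L), _GAP_CODE, np.uint8)
                pmat = np.concatenate([mat[:, :split], gap_block, mat[:, split:]], axis=1)
            dist = base + p.cdr3_weight * self._table[qpad[None, :], pmat].sum(axis=1)
            within = dist <= p.radius
            total += int(within.sum())
            if exclude_index is not None and within.any():
                if (ids[within] == exclude_index).any():
                    total -= 1
        return total


def count_neighbors(
    query: str,
    pool: Sequence[str],
    params: Optional[DistanceParams] = None,
    exclude_index: Optional[int] = None,
) -> int:
    """Number of pool sequences within the radius of ``query``.

    Self-matches are excluded by pool index (item identity), not by sequence
    equality: a distinct clone carrying the same CDR3 is a genuine neighbor.
    """
    return NeighborCounter(pool, params).count(query, exclude_index=exclude_index)


# ---------------------------------------------------------------------------
# shuffled-junction background
# ---------------------------------------------------------------------------


@dataclass
class BackgroundSet:
    """Size-matched shuffled-junction null repertoire."""

    sequences: List[Tuple[str, str, str]]  # (v_gene, j_gene, cdr3_aa)
    fold: int
    match_report: dict = field(default_factory=dict)


def _tv_distance(p: Counter, q: Counter) -> float:
    tp, tq = sum(p.values()), sum(q.values())
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p[k] / tp - q[k] / tq) for k in keys)


def shuffle_background(
    clones: Sequence[Tuple[str, str, str]],
    fold: int = 50,
    seed: Optional[int] = None,
    pgen_fn: Optional[Callable[[str, str, str], float]] = None,
    min_clones: int = 20,
    exclusion_radius: float = 12.5,
) -> BackgroundSet:
    """Build a ``fold``-times background by junction-level shuffling.

    Candidates recombine two distinct equal-length clones A and B at an
    internal cut (A's prefix joined to B's suffix, keeping at least 4 residues
    of each parent), inheriting A's V gene and B's J gene.  A candidate is
    discarded when it equals any observed junction or remains within
    ``exclusion_radius`` of either parent: such a draw has not left its
    parent's similarity neighborhood, and keeping it would let any real
    sequence cluster partially reconstruct itself inside its own null.
    Sampling is stratified on (v_gene, CDR3 length) so the joint distribution
    matches the input exactly up to integer rounding (the final size is
    exactly ``fold * len(clones)``).  With a ``pgen_fn``, candidates are
    additionally quota-matched to the input's pgen-decile profile within each
    stratum.

    ``seed`` is mandatory for reproducible analyses; ``clones`` must contain
    at least ``min_clones`` unique entries.
    """
    clones = list(clones)
    n = len(clones)
    if n < min_clones:
        raise ValueError(
            f"only {n} unique clones; need >= {min_clones} to stratify a shuffled "
            "background — pool chains or samples"
        )
    if seed is None:
        raise ValueError("seed is mandatory for background construction")
    rng = np.random.default_rng(seed)

    input_cdr3 = {c[2] for c in clones}
    by_len: Dict[int, List[Tuple[str, str, str]]] = defaultdict(list)
    strata: Dict[Tuple[str, int], List[Tuple[str, str, str]]] = defaultdict(list)
    for clone in clones:
        by_len[len(clone[2])].append(clone)
        strata[(clone[0], len(clone[2]))].append(clone)

    decile_edges = None
    input_decile_profile: Dict[Tuple, Counter] = {}
    if pgen_fn is not None:
        pgens = np.array([pgen_fn(*c) for c in clones])
        pgens = np.maximum(pgens, 1e-300)
        decile_edges = np.quantile(np.log10(pgens), np.linspace(0.1, 0.9, 9))
        for clone, pg in zip(clones, pgens):
            key = (clone[0], len(clone[2]))
            binned = int(np.searchsorted(decile_edges, math.log10(pg)))
            input_decile_profile.setdefault(key, Counter())[binned] += 1

    dist_params = DistanceParams(radius=exclusion_radius)

    def make_candidate(stratum_key) -> Optional[Tuple[str, str, str]]:
        v, L = stratum_key
        members = strata[stratum_key]
        peers = by_len[L]
        for attempt in range(200):
            a = members[rng.integers(len(members))]
            # keep >= 4 residues from each parent: cuts hugging either end
            # yield near-copies of one parent, not shuffled junctions
            if L >= 9:
                cut = int(rng.integers(4, L - 3))  # [4, L-4]
            else:
                cut = int(rng.integers(2, L - 1))  # [2, L-2]
            if len(peers) >= 2 and attempt < 100:
                b = a
                while b is a:
                    b = peers[rng.integers(len(peers))]
                cdr3 = a[2][:cut] + b[2][cut:]
            else:
                # degenerate stratum (single clone of this length, or a short
                # length whose equal-length chimeras all hug a parent): let
                # any other clone donate a J-side tail of the required length
                tail_len = L - cut
                donors = [c for c in clones
                          if c is not a and len(c[2]) >= tail_len + 4]
                if not donors:
                    continue
                b = donors[rng.integers(len(donors))]
                cdr3 = a[2][:cut] + b[2][-tail_len:]
            j_gene = b[1]
            parents = (a[2], b[2])
            if cdr3 in input_cdr3:
                continue
            if any(cdr3_distance(cdr3, p, dist_params) <= exclusion_radius
                   for p in parents):
                continue
            return (v, j_gene, cdr3)
        return None

    sequences: List[Tuple[str, str, str]] = []
    dropped_strata = 0
    for key in sorted(strata):
        target = fold * len(strata[key])
        if pgen_fn is None:
            got = 0
            while got < target:
                cand = make_candidate(key)
                if cand is None:
                    dropped_strata += 1
                    break
                sequences.append(cand)
                got += 1
        else:
            # oversample, then fill per-decile quotas mirroring the stratum input
            cands = []
            attempts = 0
            while len(cands) < 3 * target and attempts < 10 * target:
                cand = make_candidate(key)
                attempts += 1
                if cand is not None:
                    cands.append(cand)
            profile = input_decile_profile[key]
            quota = {
                b: int(round(target * cnt / sum(profile.values())))
                for b, cnt in profile.items()
            }
            chosen, leftover = [], []
            for cand in cands:
                pg = max(pgen_fn(*cand), 1e-300)
                b = int(np.searchsorted(decile_edges, math.log10(pg)))
                if quota.get(b, 0) > 0:
                    chosen.append(cand)
                    quota[b] -= 1
                else:
                    leftover.append(cand)
                if len(chosen) == target:
                    break
            chosen.extend(leftover[: target - len(chosen)])
            sequences.extend(chosen[:target])

    if dropped_strata:
        logger.warning(
            "shuffle_background: %d strata could not be filled (all candidates "
            "collided with input junctions)", dropped_strata
        )

    report = {
        "v_gene_tv": _tv_distance(
            Counter(c[0] for c in clones), Counter(s[0] for s in sequences)
        ),
        "length_tv": _tv_distance(
            Counter(len(c[2]) for c in clones), Counter(len(s[2]) for s in sequences)
        ),
        "size": len(sequences),
        "pgen_matched": pgen_fn is not None,
    }
    return BackgroundSet(sequences=sequences, fold=fold, match_report=report)


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    clone_key: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    k_rep: int
    k_bg: int
    p_raw: float
    p_adj: float
    significant: bool


def enrich_clones(
    clones: Sequence[Tuple[str, str, str]],
    background: BackgroundSet,
    params: Optional[DistanceParams] = None,
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Hypergeometric neighbor-enrichment test per unique clone.

    For clone i among N unique clones with an M-sequence background, let
    k = neighbors among the other N-1 repertoire clones and K = k plus the
    clone's neighbors in the background.  Drawing N-1 sequences from the
    pooled N-1+M, the tail probability P(X >= k) of the hypergeometric is the
    chance of seeing at least k repertoire neighbors if neighbors were
    distributed at random between repertoire and background.  Bonferroni
    multiplies by N; a clone is significant at ``p_adj < alpha``.
    """
    params = params or DistanceParams()
    clones = list(clones)
    if not background.sequences:
        raise ValueError("background is empty; build it with shuffle_background first")
    N = len(clones)
    M = len(background.sequences)
    rep_counter = NeighborCounter([c[2] for c in clones], params)
    bg_counter = NeighborCounter([s[2] for s in background.sequences], params)
    results = []
    for i, (v, j, cdr3) in enumerate(clones):
        k = rep_counter.count(cdr3, exclude_index=i)
        k_bg = bg_counter.count(cdr3)
        K = k + k_bg
        # P(X >= k), X ~ Hypergeom(population N-1+M, K successes, N-1 draws)
        p_raw = float(hypergeom.sf(k - 1, N - 1 + M, K, N - 1))
        p_raw = min(1.0, max(0.0, p_raw))
        p_adj = min(1.0, p_raw * N)
        results.append(
            EnrichmentResult(
                clone_key=f"{v}.{j}_{cdr3}",
                v_gene=v,
                j_gene=j,
                cdr3_aa=cdr3,
                k_rep=k,
                k_bg=k_bg,
                p_raw=p_raw,
                p_adj=p_adj,
                significant=bool(p_adj < alpha and k >= 1),
            )
        )
    return results
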