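"""Assembly-line order prediction from docking-domain compatibility.

Multi-gene cis-AT PKS assembly lines are frequently non-colinear: the order in
which proteins dock and hand off the growing chain can differ from the gene
order on the cluster.  Short terminal docking regions decide which proteins
interact.  This module:

* extracts per-gene head (N-terminal, 100 aa) and tail (C-terminal, 50 aa)
  docking regions;
* scores sequence similarity with a Smith-Waterman bit-score (BLOSUM62,
  gap open 11 / extend 1, standard gapped constants);
* builds pairwise-nearest-neighbor (PNN) features for a head-tail pair: the
  similarity of the pair to its n most similar interacting and n most similar
  non-interacting training pairs (n = 3 by default);
* trains a logistic regression interaction model on class-balanced training
  pairs;
* scores a gene permutation as the sum of its consecutive-pair interaction
  scores, with pairs that are adjacent in the cluster (forward or backward)
  weighted by configurable factors (both 1 by default, rewarding nothing; a
  weight > 1 rewards colinearity);
* ranks candidate orders by exhaustive permutation enumeration (up to 9
  genes) or best-first branch-and-bound beyond that.
"""

from __future__ import annotations

import heapq
import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .bgc_model import BGC

# Karlin-Altschul constants for BLOSUM62 with affine gaps 11/1
BITSCORE_LAMBDA = 0.267
BITSCORE_K = 0.041

DEFAULT_HEAD_LEN = 100
DEFAULT_TAIL_LEN = 50
DEFAULT_EXHAUSTIVE_LIMIT = 9


class AssemblyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Docking-region extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DockingSite:
    """Head/tail docking regions of one gene, with pathway-terminal flags."""

    gene_id: str
    head_seq: str
    tail_seq: str
    head_excluded: bool = False
    tail_excluded: bool = False


@dataclass(frozen=True)
class DockingPair:
    """An (upstream tail, downstream head) pair; labelled when training data."""

    tail_seq: str
    head_seq: str
    label: bool | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if not self.tail_seq or not self.head_seq:
            raise AssemblyError(f"docking pair {self.id!r}: empty sequence")


def find_pathway_anchors(bgc: BGC) -> tuple[str | None, str | None]:
    """(start gene id, end gene id) inferred from domain content.

    The gene carrying a TE domain anchors the pathway end; a gene whose first
    module lacks a KS anchors the start (nothing upstream to accept a chain
    from).  Either may be undetectable (None).
    """
    start = end = None
    for g in bgc.genes:
        if any(m.get("TE") is not None for m in g.modules):
            end = g.id
        if g.modules and g.modules[0].get("KS") is None:
            start = g.id
    if start is not None and start == end:
        # single multi-module gene covering both ends: no anchoring needed
        return start, end
    return start, end


def extract_docking(
    bgc: BGC,
    head_len: int = DEFAULT_HEAD_LEN,
    tail_len: int = DEFAULT_TAIL_LEN,
) -> dict[str, DockingSite]:
    """Per-gene docking regions: head = leading ``head_len`` residues, tail =
    trailing ``tail_len`` residues.  The pathway-start gene's head and the
    pathway-end gene's tail are marked excluded (they dock nothing)."""
    start, end = find_pathway_anchors(bgc)
    sites = {}
    for g in bgc.genes:
        protein = g.protein
        if len(protein) < head_len + tail_len:
            warnings.warn(
                f"gene {g.id}: protein length {len(protein)} < "
                f"{head_len + tail_len}; head/tail truncated to whole protein"
            )
            head = tail = protein
        else:
            head = protein[:head_len]
            tail = protein[-tail_len:]
        sites[g.id] = DockingSite(
            gene_id=g.id,
            head_seq=head,
            tail_seq=tail,
            head_excluded=(g.id == start),
            tail_excluded=(g.id == end),
        )
    return sites


# ---------------------------------------------------------------------------
# Bit-score similarity
# ---------------------------------------------------------------------------

def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _local_aligner()


@lru_cache(maxsize=200_000)
def _raw_sw_score(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    return float(_ALIGNER.score(a, b))


def bitscore(a: str, b: str) -> float:
    """Smith-Waterman bit-score between two sequences.

    Raw local-alignment score S (BLOSUM62, open 11 / extend 1) converted via
    (lambda*S - ln K) / ln 2.  Symmetric; 0 for empty input.  Pluggable: pass
    a different scorer to the PNN functions to use an external aligner.
    """
    if not a or not b:
        return 0.0
    if b < a:
        a, b = b, a  # canonical order for the cache; SW is symmetric
    s = _raw_sw_score(a, b)
    return (BITSCORE_LAMBDA * s - math.log(BITSCORE_K)) / math.log(2.0)


def pair_distance(p: DockingPair, q: DockingPair, scorer=bitscore) -> float:
    """Similarity of two head-tail pairs: head-head plus tail-tail bit-score.

    Called a "distance" in the docking literature, but larger = more similar.
    """
    return scorer(p.head_seq, q.head_seq) + scorer(p.tail_seq, q.tail_seq)


# ---------------------------------------------------------------------------
# PNN features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborConfig:
    n: int = 3
    feature_mode: str = "per_score"  # or "summed"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise AssemblyError("NeighborConfig.n must be >= 1")
        if self.feature_mode not in ("per_score", "summed"):
            raise AssemblyError(f"unknown feature_mode {self.feature_mode!r}")

    @property
    def n_features(self) -> int:
        return 4 * self.n if self.feature_mode == "per_score" else 2 * self.n


def pnn_features(
    query: DockingPair,
    training: list[DockingPair],
    cfg: NeighborConfig = NeighborConfig(),
    scorer=bitscore,
    exclude: DockingPair | None = None,
) -> np.ndarray:
    """Pairwise-nearest-neighbor feature vector for a head-tail pair.

    The n most similar interacting and n most similar non-interacting
    training pairs are selected by :func:`pair_distance` (descending, ties by
    id).  Mode ``per_score`` emits (head bit-score, tail bit-score) per
    neighbor (4n features); mode ``summed`` emits the summed similarity per
    neighbor (2n features).
    """
    pool = [p for p in training if p is not exclude]
    by_class: dict[bool, list[tuple[float, str, DockingPair]]] = {True: [], False: []}
    for p in pool:
        if p.label is None:
            raise AssemblyError(f"training pair {p.id!r} lacks a label")
        by_class[p.label].append((pair_distance(query, p, scorer), p.id, p))
    feats: list[float] = []
    for cls in (True, False):
        ranked = sorted(by_class[cls], key=lambda t: (-t[0], t[1]))
        if len(ranked) < cfg.n:
            name = "interacting" if cls else "non-interacting"
            raise AssemblyError(
                f"need >= {cfg.n} {name} training pairs, have {len(ranked)}"
            )
        for dist, _pid, p in ranked[: cfg.n]:
            if cfg.feature_mode == "per_score":
                feats.append(scorer(query.head_seq, p.head_seq))
                feats.append(scorer(query.tail_seq, p.tail_seq))
            else:
                feats.append(dist)
    return np.array(feats, dtype=float)


# ---------------------------------------------------------------------------
# Interaction model
# ---------------------------------------------------------------------------

@dataclass
class InteractionModel:
    estimator: object  # sklearn pipeline: scaler + logistic regression
    training: list[DockingPair]
    cfg: NeighborConfig
    seed: int = 0

    def predict_proba(self, pair: DockingPair, scorer=bitscore) -> float:
        """Probability that the pair interacts (open interval (0, 1))."""
        x = pnn_features(pair, self.training, self.cfg, scorer).reshape(1, -1)
        return float(self.estimator.predict_proba(x)[0, 1])


def train_interaction_model(
    pairs: list[DockingPair],
    cfg: NeighborConfig = NeighborConfig(),
    seed: int = 0,
    scorer=bitscore,
) -> InteractionModel:
    """Fit the logistic interaction model on labelled docking pairs.

    Negatives are randomly subsampled (seeded) to the positive count to
    balance the classes; each training pair's PNN features are computed
    against the training set excluding itself.
    """
    pos = [p for p in pairs if p.label is True]
    neg = [p for p in pairs if p.label is False]
    if not pos or not neg:
        raise AssemblyError("both interacting and non-interacting pairs required")
    rng = np.random.default_rng(seed)
    if len(neg) > len(pos):
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in sorted(idx)]
    training = pos + neg
    X = np.vstack(
        [pnn_features(p, training, cfg, scorer, exclude=p) for p in training]
    )
    y = np.array([1 if p.label else 0 for p in training])
    est = make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
    )
    est.fit(X, y)
    return InteractionModel(estimator=est, training=training, cfg=cfg, seed=seed)


# ---------------------------------------------------------------------------
# Pathway scoring (consecutive-pair sum with colinearity weights)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayScoreParams:
    w_forward: float = 1.0
    w_backward: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.w_forward) and math.isfinite(self.w_backward)):
            raise AssemblyError("pathway weights must be finite")


@dataclass
class PathwayOrder:
    permutation: list[str]
    score: float
    pair_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    rank: int = 0
    probability: float | None = None


def classify_pair(upstream_rank: int, downstream_rank: int) -> str:
    if downstream_rank == upstream_rank + 1:
        return "forward"
    if downstream_rank == upstream_rank - 1:
        return "backward"
    return "non_adj"


def score_pathway(
    order: list[str],
    pair_score: dict[tuple[str, str], float],
    bgc: BGC,
    params: PathwayScoreParams = PathwayScoreParams(),
) -> float:
    """Weighted sum of consecutive-pair interaction scores.

    Each consecutive pair is classed by its genomic adjacency: forward
    (downstream gene immediately follows upstream on the cluster), backward
    (immediately precedes), or non-adjacent.  Forward/backward terms are
    multiplied by their weights; with unit weights this is the plain sum.
    """
    rank = {g.id: g.genomic_rank for g in bgc.genes}
    total = 0.0
    for a, b in zip(order, order[1:]):
        if (a, b) not in pair_score:
            raise AssemblyError(f"missing pair score for ({a}, {b})")
        s = pair_score[(a, b)]
        cls = classify_pair(rank[a], rank[b])
        if cls == "forward":
            total += s * params.w_forward
        elif cls == "backward":
            total += s * params.w_backward
        else:
            total += s
    return total


# ---------------------------------------------------------------------------
# Permutation ranking
# ---------------------------------------------------------------------------

@dataclass
class RankingResult:
    orders: list[PathwayOrder]
    n_candidates: int
    pair_scores: dict[tuple[str, str], float]


def compute_pair_scores(
    bgc: BGC,
    model: InteractionModel,
    head_len: int = DEFAULT_HEAD_LEN,
    tail_len: int = DEFAULT_TAIL_LEN,
    scorer=bitscore,
) -> dict[tuple[str, str], float]:
    """Interaction score for every ordered gene pair (upstream, downstream)."""
    sites = extract_docking(bgc, head_len, tail_len)
    scores: dict[tuple[str, str], float] = {}
    for a in bgc.gene_ids:
        for b in bgc.gene_ids:
            if a == b:
                continue
            pair = DockingPair(
                tail_seq=sites[a].tail_seq, head_seq=sites[b].head_seq,
                id=f"{a}->{b}",
            )
            scores[(a, b)] = model.predict_proba(pair, scorer)
    return scores


def _weighted_matrix(
    bgc: BGC, pair_score: dict[tuple[str, str], float], params: PathwayScoreParams
) -> tuple[list[str], np.ndarray]:
    ids = bgc.gene_ids
    rank = {g.id: g.genomic_rank for g in bgc.genes}
    g = len(ids)
    W = np.full((g, g), -np.inf)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            s = pair_score[(a, b)]
            cls = classify_pair(rank[a], rank[b])
            if cls == "forward":
                s *= params.w_forward
            elif cls == "backward":
                s *= params.w_backward
            W[i, j] = s
    return ids, W


def rank_pathways(
    bgc: BGC,
    pair_score: dict[tuple[str, str], float] | None = None,
    model: InteractionModel | None = None,
    params: PathwayScoreParams = PathwayScoreParams(),
    cap: int = 100,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    anchor: bool = True,
) -> RankingResult:
    """Rank candidate assembly orders by pathway score, best first.

    Up to ``exhaustive_limit`` genes (default 9, 362,880 orders) every
    permutation is scored; beyond that a best-first branch-and-bound with an
    admissible per-slot-maximum bound returns the top ``cap`` orders.  Ties
    are broken lexicographically by the gene-id sequence.  When ``anchor`` is
    set, genes detected as pathway start/end are pinned to those positions.
    """
    if cap < 1:
        raise AssemblyError("cap must be >= 1")
    ids = bgc.gene_ids
    g = len(ids)
    if g == 1:
        return RankingResult(
            orders=[PathwayOrder(permutation=list(ids), score=0.0, rank=1)],
            n_candidates=1,
            pair_scores={},
        )
    if pair_score is None:
        if model is None:
            raise AssemblyError("either pair_score or model is required")
        pair_score = compute_pair_scores(bgc, model)
    _, W = _weighted_matrix(bgc, pair_score, params)
    start_id = end_id = None
    if anchor:
        start_id, end_id = find_pathway_anchors(bgc)
    fixed_first = ids.index(start_id) if start_id is not None else None
    fixed_last = ids.index(end_id) if end_id is not None else None
    if fixed_first is not None and fixed_first == fixed_last:
        fixed_last = None

    free = [i for i in range(g) if i not in (fixed_first, fixed_last)]
    idrank = {i: r for r, i in enumerate(sorted(range(g), key=lambda i: ids[i]))}
    if len(free) <= exhaustive_limit:
        perms_scored = _exhaustive(free, fixed_first, fixed_last, W, idrank, cap)
    else:
        perms_scored = _branch_and_bound(free, fixed_first, fixed_last, W, cap)
    n_candidates = math.factorial(len(free))

    # sort: score descending, then gene-id sequence lexicographically
    perms_scored.sort(key=lambda t: (-t[1], tuple(ids[i] for i in t[0])))
    orders = []
    for r, (perm, score) in enumerate(perms_scored[:cap], start=1):
        gene_seq = [ids[i] for i in perm]
        orders.append(
            PathwayOrder(
                permutation=gene_seq,
                score=float(score),
                pair_scores={
                    (a, b): pair_score[(a, b)] for a, b in zip(gene_seq, gene_seq[1:])
                },
                rank=r,
            )
        )
    total = sum(math.exp(o.score) for o in orders)
    for o in orders:
        o.probability = math.exp(o.score) / total if total > 0 else None
    return RankingResult(orders=orders, n_candidates=n_candidates,
                         pair_scores=pair_score)


def _assemble(perm_mid: tuple[int, ...], first: int | None, last: int | None):
    out = list(perm_mid)
    if first is not None:
        out = [first] + out
    if last is not None:
        out = out + [last]
    return tuple(out)


def _exhaustive(free, first, last, W, idrank, cap):
    """Score every permutation (vectorized) and return the top ``cap``."""
    k = len(free)
    if k == 0:
        perm = _assemble((), first, last)
        s = sum(W[a, b] for a, b in zip(perm, perm[1:]))
        return [(perm, float(s))]
    mids = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(free)),
        dtype=np.intp,
    ).reshape(-1, k)
    cols = [np.full(len(mids), first, dtype=np.intp)] if first is not None else []
    cols.append(mids.T)
    if last is not None:
        cols.append(np.full(len(mids), last, dtype=np.intp))
    perms = np.vstack([c if c.ndim == 2 else c[None, :] for c in cols]).T
    scores = W[perms[:, :-1], perms[:, 1:]].sum(axis=1)
    # lexsort: primary key last -> -scores, then gene-id rank column-by-column
    rank_cols = np.vectorize(idrank.get)(perms)
    keys = [rank_cols[:, j] for j in range(perms.shape[1] - 1, -1, -1)]
    keys.append(-scores)
    top = np.lexsort(keys)[:cap]
    return [(tuple(int(x) for x in perms[i]), float(scores[i])) for i in top]


def _branch_and_bound(free, first, last, W, cap):
    """Best-first search over partial orders with an admissible bound.

    Bound: partial score + (number of edges still to place) x (maximum edge
    weight in the matrix), which never underestimates any completion.
    Completed orders re-enter the heap keyed by their actual score, so the
    first ``cap`` completed orders popped are the true optima.
    """
    finite_max = float(np.nanmax(np.where(np.isfinite(W), W, np.nan)))
    results = []
    counter = itertools.count()
    init = (first,) if first is not None else ()
    # state: (-key, tiebreak, partial, used, complete)
    heap = [(-math.inf, next(counter), init, frozenset(init), False)]
    while heap and len(results) < cap:
        neg_key, _, partial, used, complete = heapq.heappop(heap)
        if complete:
            results.append((partial, -neg_key))
            continue
        remaining = [i for i in free if i not in used]
        if not remaining:
            perm = partial + ((last,) if last is not None else ())
            s = float(sum(W[a, b] for a, b in zip(perm, perm[1:])))
            heapq.heappush(heap, (-s, next(counter), perm, used, True))
            continue
        for nxt in remaining:
            new_partial = partial + (nxt,)
            s = sum(W[a, b] for a, b in zip(new_partial, new_partial[1:]))
            edges_left = len(remaining) - 1 + (1 if last is not None else 0)
            ub = s + edges_left * finite_max
            heapq.heappush(
                heap, (-ub, next(counter), new_partial, used | {nxt}, False)
            )
    return results
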