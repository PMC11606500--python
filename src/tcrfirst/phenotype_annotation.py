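"""Cell annotation from TCR sequence rules and marker-signature gating.

Two complementary label sources:

* **TCR rules** — deterministic receptor-level definitions: MAIT cells carry
  the semi-invariant TRAV1-2 alpha chain joined to TRAJ33/TRAJ20/TRAJ12;
  gamma-delta T cells carry a TRG/TRD chain; the TRAV13-2 x TRBV4-1 pairing
  is flagged as a CD1b/c-restriction candidate; everything else is a plain
  alpha-beta T cell.
* **Signature gating** — a semi-supervised hierarchy of marker gene sets.
  Each cell gets a rank-based signature score in [0, 1] (a capped-U /
  UCell-style statistic); a gate passes when some positive signature scores
  at or above ``tau_pos`` and every negative signature stays below
  ``tau_neg``; the cell's label is the deepest gate passed.  This replaces
  unsupervised cluster labeling with explicit, auditable marker logic.

Shipped gene sets are illustrative placeholders — gating trees are meant to
be supplied as configuration.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .repertoire_io import Clonotype, FormatError, GexMatrix, Repertoire

logger = logging.getLogger("tcrfirst")


# ---------------------------------------------------------------------------
# TCR-rule classification
# ---------------------------------------------------------------------------


@dataclass
class TcrRule:
    """One receptor-level annotation rule; lower priority value wins first.

    ``required_v``/``required_j`` must be satisfied on a single chain;
    ``required_pairing`` constrains the (AG-chain V, BD-chain V) combination;
    ``required_locus`` demands that some chain use one of the listed loci.
    """

    label: str
    priority: int
    required_v: Optional[frozenset] = None
    required_j: Optional[frozenset] = None
    required_pairing: Optional[Tuple[str, str]] = None
    required_locus: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if not any((self.required_v, self.required_j, self.required_pairing,
                    self.required_locus)):
            raise ValueError(f"rule {self.label!r} has no requirements")

    def matches(self, clonotype: Clonotype) -> bool:
        chains = [c for c in (clonotype.chain_ag, clonotype.chain_bd) if c is not None]
        if self.required_locus is not None:
            if not any(c.locus in self.required_locus for c in chains):
                return False
        if self.required_v is not None or self.required_j is not None:
            ok = False
            for c in chains:
                if self.required_v is not None and c.v_gene not in self.required_v:
                    continue
                if self.required_j is not None and c.j_gene not in self.required_j:
                    continue
                ok = True
                break
            if not ok:
                return False
        if self.required_pairing is not None:
            v_ag, v_bd = self.required_pairing
            if clonotype.chain_ag is None or clonotype.chain_bd is None:
                return False
            if clonotype.chain_ag.v_gene != v_ag or clonotype.chain_bd.v_gene != v_bd:
                return False
        return True


def default_tcr_rules() -> List[TcrRule]:
    """MAIT, gamma-delta, CD1b/c-candidate rules in priority order."""
    return [
        TcrRule(
            label="MAIT",
            priority=0,
            required_v=frozenset({"TRAV1-2"}),
            required_j=frozenset({"TRAJ33", "TRAJ20", "TRAJ12"}),
        ),
        TcrRule(
            label="gamma_delta",
            priority=1,
            required_locus=frozenset({"TRG", "TRD"}),
        ),
        TcrRule(
            label="CD1bc_candidate",
            priority=2,
            required_pairing=("TRAV13-2", "TRBV4-1"),
        ),
    ]


def classify_by_tcr(
    clonotype: Clonotype,
    rules: Optional[Sequence[TcrRule]] = None,
    fallback: str = "alpha_beta",
) -> str:
    """First matching rule (by ascending priority) wins; total — always labels."""
    rules = sorted(rules if rules is not None else default_tcr_rules(),
                   key=lambda r: r.priority)
    for rule in rules:
        if rule.matches(clonotype):
            return rule.label
    return fallback


# ---------------------------------------------------------------------------
# rank-based signature scoring
# ---------------------------------------------------------------------------


def _capped_ranks(counts: np.ndarray, r_max: int) -> np.ndarray:
    """Per-cell gene ranks by decreasing count (ties averaged), capped at r_max+1."""
    ranks = rankdata(-counts, axis=1, method="average")
    return np.minimum(ranks, r_max + 1)


def signature_score(
    cell_counts: np.ndarray,
    gene_idx: Sequence[int],
    r_max: int = 1500,
) -> float:
    """Rank-based signature score of one cell, in [0, 1].

    Genes are ranked by decreasing count (ties get the average rank, so
    unexpressed genes share the bottom ranks); ranks are capped at
    ``r_max + 1``.  With n signature genes whose capped ranks sum to R, the
    score ``1 - (R - n(n+1)/2) / (n * r_max)`` (clipped to [0, 1]) is 1 when
    the signature occupies the top n ranks and 0 when it sits wholly beyond
    the cap — a normalized Mann-Whitney U of the signature against the rest
    of the transcriptome.
    """
    gene_idx = list(gene_idx)
    if not gene_idx:
        raise ValueError("signature has no genes present in the feature list")
    ranks = _capped_ranks(np.asarray(cell_counts, float)[None, :], r_max)[0]
    n = len(gene_idx)
    R = ranks[gene_idx].sum()
    score = 1.0 - (R - n * (n + 1) / 2.0) / (n * r_max)
    return float(min(1.0, max(0.0, score)))


def _resolve_signature(gene_set: Iterable[str], features: Sequence[str]) -> List[int]:
    index = {g: i for i, g in enumerate(features)}
    idx = [index[g] for g in gene_set if g in index]
    if not idx:
        missing = sorted(set(gene_set))
        raise ValueError(f"signature genes absent from features: {missing}")
    return idx


# ---------------------------------------------------------------------------
# hierarchical gating
# ---------------------------------------------------------------------------


@dataclass
class GatingNode:
    """One gate of the annotation hierarchy."""

    name: str
    positive_signatures: List[List[str]] = field(default_factory=list)
    negative_signatures: List[List[str]] = field(default_factory=list)
    children: List["GatingNode"] = field(default_factory=list)
    tau_pos: Optional[float] = None  # None -> inherit the gate_cells default
    tau_neg: Optional[float] = None


@dataclass
class CellLabel:
    barcode: str
    gex_label: str
    tcr_label: str = "unassigned"
    scores: Dict[str, float] = field(default_factory=dict)


UNKNOWN_LABEL = "non-T/unknown"


def _check_acyclic(node: GatingNode, seen: Optional[set] = None) -> None:
    seen = seen if seen is not None else set()
    if id(node) in seen:
        raise ValueError(f"gating tree contains a cycle at node {node.name!r}")
    seen.add(id(node))
    for child in node.children:
        _check_acyclic(child, seen)


def gate_cells(
    gex: GexMatrix,
    tree: GatingNode,
    tau_pos: float = 0.2,
    tau_neg: float = 0.2,
    r_max: int = 1500,
    batch_size: int = 5000,
) -> List[CellLabel]:
    """Assign each cell the deepest gate it passes in the signature hierarchy.

    A cell passes a node iff the best positive-signature score reaches the
    node's ``tau_pos`` and every negative-signature score stays below
    ``tau_neg``.  When several children pass, descent follows the child with
    the highest positive score (first child on ties).  Cells failing the root
    are labeled ``"non-T/unknown"``.  Cells are processed in batches purely
    for memory; results are independent of ``batch_size``.
    """
    _check_acyclic(tree)

    # resolve every signature once, keyed by node name and polarity
    resolved: Dict[str, List[int]] = {}

    def resolve(node: GatingNode) -> None:
        for tag, sigs in (("pos", node.positive_signatures),
                          ("neg", node.negative_signatures)):
            for i, genes in enumerate(sigs):
                resolved[f"{node.name}/{tag}{i}"] = _resolve_signature(genes, gex.features)
        for child in node.children:
            resolve(child)

    resolve(tree)

    labels: List[CellLabel] = []
    n = gex.n_cells
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        block = np.asarray(gex.counts[start:stop].todense(), dtype=float)
        ranks = _capped_ranks(block, r_max)

        def sig_scores(key: str) -> np.ndarray:
            idx = resolved[key]
            m = len(idx)
            R = ranks[:, idx].sum(axis=1)
            return np.clip(1.0 - (R - m * (m + 1) / 2.0) / (m * r_max), 0.0, 1.0)

        node_cache: Dict[Tuple[str, str], np.ndarray] = {}

        def node_eval(node: GatingNode) -> Tuple[np.ndarray, np.ndarray]:
            """(passes, best positive score) per cell in the batch."""
            key = ("eval", node.name)
            if key not in node_cache:
                tp = node.tau_pos if node.tau_pos is not None else tau_pos
                tn = node.tau_neg if node.tau_neg is not None else tau_neg
                if node.positive_signatures:
                    pos = np.max(
                        [sig_scores(f"{node.name}/pos{i}")
                         for i in range(len(node.positive_signatures))], axis=0)
                else:
                    pos = np.ones(stop - start)
                ok = pos >= tp
                for i in range(len(node.negative_signatures)):
                    ok &= sig_scores(f"{node.name}/neg{i}") < tn
                node_cache[key] = (ok, pos)
            return node_cache[key]

        batch_labels = np.full(stop - start, "", dtype=object)
        batch_scores: List[Dict[str, float]] = [{} for _ in range(stop - start)]

        def descend(node: GatingNode, active: np.ndarray, depth: int) -> None:
            ok, pos = node_eval(node)
            passed = active & ok
            for ci in np.flatnonzero(active):
                batch_scores[ci][node.name] = float(pos[ci])
            if depth == 0:
                batch_labels[passed] = node.name
                batch_labels[active & ~ok] = UNKNOWN_LABEL
            else:
                batch_labels[passed] = node.name
            if not node.children or not passed.any():
                return
            child_evals = [node_eval(c) for c in node.children]
            child_pass = np.stack([e[0] for e in child_evals])
            child_pos = np.stack([e[1] for e in child_evals])
            scored = np.where(child_pass, child_pos, -np.inf)
            best = scored.argmax(axis=0)  # first child wins ties (argmax rule)
            any_pass = child_pass.any(axis=0)
            for k, child in enumerate(node.children):
                descend(child, passed & any_pass & (best == k), depth + 1)

        descend(tree, np.ones(stop - start, dtype=bool), 0)
        for i in range(stop - start):
            labels.append(
                CellLabel(
                    barcode=gex.barcodes[start + i],
                    gex_label=str(batch_labels[i]),
                    scores=batch_scores[i],
                )
            )
    return labels


def example_gating_tree() -> GatingNode:
    """Illustrative T -> CD4/CD8 tree with placeholder marker sets.

    The gene sets are examples for synthetic data and documentation; real
    analyses should load a curated tree from configuration.
    """
    return GatingNode(
        name="T",
        positive_signatures=[["CD3D", "CD3E", "CD3G", "CD2"]],
        children=[
            GatingNode(name="CD4", positive_signatures=[["CD4", "IL7R", "CCR7", "TCF7"]]),
            GatingNode(name="CD8", positive_signatures=[["CD8A", "CD8B", "GZMK", "NKG7"]]),
        ],
    )


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def gating_tree_from_dict(d: dict) -> GatingNode:
    """Build a gating tree from a plain mapping (YAML-friendly form)."""
    known = {"name", "positive_signatures", "negative_signatures", "children",
             "tau_pos", "tau_neg"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown gating node keys: {sorted(unknown)}")
    return GatingNode(
        name=d["name"],
        positive_signatures=[list(s) for s in d.get("positive_signatures", [])],
        negative_signatures=[list(s) for s in d.get("negative_signatures", [])],
        children=[gating_tree_from_dict(c) for c in d.get("children", [])],
        tau_pos=d.get("tau_pos"),
        tau_neg=d.get("tau_neg"),
    )


def tcr_rules_from_dicts(rows: Iterable[dict]) -> List[TcrRule]:
    rules = []
    for d in rows:
        rules.append(TcrRule(
            label=d["label"],
            priority=int(d["priority"]),
            required_v=frozenset(d["required_v"]) if d.get("required_v") else None,
            required_j=frozenset(d["required_j"]) if d.get("required_j") else None,
            required_pairing=tuple(d["required_pairing"]) if d.get("required_pairing") else None,
            required_locus=frozenset(d["required_locus"]) if d.get("required_locus") else None,
        ))
    return rules


def load_gating_tree(path) -> GatingNode:
    """Load a gating hierarchy from a YAML file."""
    import yaml

    with open(path) as fh:
        return gating_tree_from_dict(yaml.safe_load(fh))


def load_tcr_rules(path) -> List[TcrRule]:
    """Load an ordered TCR rule list from a YAML file."""
    import yaml

    with open(path) as fh:
        return tcr_rules_from_dicts(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# external epitope annotations
# ---------------------------------------------------------------------------


def join_external_epitopes(
    repertoire: Repertoire,
    table_path,
    score_threshold: float = 0.2,
) -> Dict[str, Tuple[str, float]]:
    """Left-join externally predicted epitope annotations onto clone keys.

    The table is a TSV with columns ``clone_key``, ``epitope``, ``score``
    (exports of external predictors).  Rows at or below the score threshold
    are dropped (logged); clones absent from the table stay unannotated.
    Returns clone_key -> (epitope, score) for the repertoire's clones.
    """
    annotations: Dict[str, Tuple[str, float]] = {}
    dropped = 0
    with open(table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return {}
        required = {"clone_key", "epitope", "score"}
        if not required.issubset(set(reader.fieldnames)):
            raise FormatError(
                f"epitope table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            try:
                score = float(row["score"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"malformed score in row {row}") from exc
            if score > score_threshold:
                annotations[row["clone_key"]] = (row["epitope"], score)
            else:
                dropped += 1
    if dropped:
        logger.info("join_external_epitopes: %d rows below threshold dropped", dropped)
    keys = {c.clone_key for c in repertoire.clonotypes}
    return {k: v for k, v in annotations.items() if k in keys}
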