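"""Clonal frequencies, treatment dynamics, marker enrichment, and the pipeline.

Expansion is always expressed as a within-sample frequency (count over the
sample's TCR-bearing cells) so that samples of different depth are
comparable.  Treatment-responsive clones are those reaching at least 1% of
the repertoire in either timepoint with at least a twofold frequency change;
clone-versus-background transcriptional signatures use a two-sided rank-sum
test with the conventional log-fold-change 0.25 and p < 0.05 thresholds,
reported as the top 30 genes by significance.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import PermutationMethod, mannwhitneyu

from . import __version__ as _pkg_version
from .repertoire_io import GexMatrix, Repertoire

logger = logging.getLogger("tcrfirst")


# ---------------------------------------------------------------------------
# frequencies and paired dynamics
# ---------------------------------------------------------------------------


def clone_frequencies(repertoire: Repertoire, sample_id: str) -> pd.DataFrame:
    """Per-clone cell counts and within-sample frequencies for one sample."""
    cells = repertoire.for_sample(sample_id)
    if not cells:
        raise ValueError(f"sample {sample_id!r} is empty or absent")
    counts: Dict[str, int] = {}
    for c in cells:
        counts[c.clone_key] = counts.get(c.clone_key, 0) + 1
    total = len(cells)
    rows = [
        {"clone_key": k, "sample_id": sample_id, "count": v, "frequency": v / total}
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class DynamicsCall:
    clone_key: str
    freq_pre: float
    freq_post: float
    count_pre: int
    count_post: int
    fold_change: float
    direction: str
    selected: bool


def paired_dynamics(
    table_pre: pd.DataFrame,
    table_post: pd.DataFrame,
    min_freq: float = 0.01,
    min_fold: float = 2.0,
    pseudo: int = 1,
) -> List[DynamicsCall]:
    """Select treatment-responsive clones across a pre/post sample pair.

    A clone is selected when it reaches ``min_freq`` of the repertoire in
    either sample and its frequency changes at least ``min_fold``-fold.  For
    clones absent from one timepoint, the fold change uses a pseudo-frequency
    of ``pseudo`` counts over that sample's total (reported alongside the raw
    zero count); the 1% filter uses raw frequencies only.
    """
    pre_ids = set(table_pre["sample_id"])
    post_ids = set(table_post["sample_id"])
    if pre_ids & post_ids:
        raise ValueError(f"pre and post tables share sample ids: {pre_ids & post_ids}")
    total_pre = int(table_pre["count"].sum())
    total_post = int(table_post["count"].sum())
    pre = table_pre.set_index("clone_key")
    post = table_post.set_index("clone_key")
    calls = []
    for key in sorted(set(pre.index) | set(post.index)):
        c_pre = int(pre.loc[key, "count"]) if key in pre.index else 0
        c_post = int(post.loc[key, "count"]) if key in post.index else 0
        f_pre = c_pre / total_pre
        f_post = c_post / total_post
        fp_pre = f_pre if c_pre > 0 else pseudo / total_pre
        fp_post = f_post if c_post > 0 else pseudo / total_post
        fold = max(fp_pre, fp_post) / min(fp_pre, fp_post)
        selected = (max(f_pre, f_post) >= min_freq) and (fold >= min_fold)
        if f_post > f_pre:
            direction = "expanded"
        elif f_post < f_pre:
            direction = "contracted"
        else:
            direction = "stable"
        calls.append(
            DynamicsCall(
                clone_key=key,
                freq_pre=f_pre,
                freq_post=f_post,
                count_pre=c_pre,
                count_post=c_post,
                fold_change=fold,
                direction=direction,
                selected=selected,
            )
        )
    return calls


DEFAULT_EXPANSION_BINS = (
    ("single", 1, 1),
    ("small", 2, 5),
    ("medium", 6, 20),
    ("large", 21, 100),
    ("hyperexpanded", 101, None),
)


def expansion_bins(
    counts: Sequence[int],
    bins: Sequence[Tuple[str, int, Optional[int]]] = DEFAULT_EXPANSION_BINS,
):
    """Categorize clone cell counts into expansion classes.

    Returns ``(labels, metadata)``; the bin edges used are recorded in the
    metadata because the defaults are conventions, not measured values.
    """
    labels = []
    for c in counts:
        c = int(c)
        if c <= 0:
            raise ValueError(f"clone count must be positive, got {c}")
        for name, lo, hi in bins:
            if c >= lo and (hi is None or c <= hi):
                labels.append(name)
                break
        else:
            raise ValueError(f"count {c} not covered by the bin definition")
    meta = {"bins": [
        {"label": name, "min": lo, "max": hi} for name, lo, hi in bins
    ]}
    return labels, meta


# ---------------------------------------------------------------------------
# marker enrichment (rank-sum differential expression)
# ---------------------------------------------------------------------------


def _normalize_log1p(counts: np.ndarray, target: float = 1e4) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * target)


def rank_sum_markers(
    gex: GexMatrix,
    group_barcodes: Sequence[str],
    background_barcodes: Sequence[str],
    lfc_min: float = 0.25,
    p_max: float = 0.05,
    top_n: int = 30,
) -> pd.DataFrame:
    """Clone/cluster-versus-background marker genes by two-sided rank-sum test.

    Counts are library-size normalized to 10,000 and log1p-transformed; per
    gene a two-sided Wilcoxon rank-sum test compares group against
    background.  For tiny comparisons (at most ~20,000 distinct group
    assignments) the permutation distribution is enumerated exactly — the
    normal approximation is unreliable at such sizes with the heavy zero-ties
    of count data; larger comparisons use the normal approximation with tie
    correction, as rank-sum differential expression conventionally does.
    Genes passing ``|log2 fold change| >= lfc_min`` and ``p < p_max`` are
    reported, top ``top_n`` by ascending p (then |lfc|).  Each side needs at
    least 3 cells — below that there are insufficient cells for statistics.
    """
    index = {b: i for i, b in enumerate(gex.barcodes)}
    gi = [index[b] for b in group_barcodes]
    bi = [index[b] for b in background_barcodes]
    if set(gi) & set(bi):
        raise ValueError("group and background barcodes overlap")
    if len(gi) < 3 or len(bi) < 3:
        raise ValueError(
            f"insufficient cells for statistical analysis "
            f"(group {len(gi)}, background {len(bi)}; need >= 3 each)"
        )
    X = np.asarray(gex.counts[gi].todense(), dtype=float)
    Y = np.asarray(gex.counts[bi].todense(), dtype=float)
    Xn = _normalize_log1p(X)
    Yn = _normalize_log1p(Y)
    if math.comb(len(gi) + len(bi), len(gi)) <= 20_000:
        method = PermutationMethod(n_resamples=20_000, rng=0)
    else:
        method = "asymptotic"
    res = mannwhitneyu(Xn, Yn, axis=0, alternative="two-sided", method=method)
    pvals = np.asarray(res.pvalue).ravel()
    eps = 1e-9
    lfc = np.log2((Xn.mean(axis=0) + eps) / (Yn.mean(axis=0) + eps))
    table = pd.DataFrame(
        {
            "gene": gex.features,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "pct_in_group": (X > 0).mean(axis=0),
            "pct_in_background": (Y > 0).mean(axis=0),
        }
    )
    table = table[(table["log2_fold_change"].abs() >= lfc_min) & (table["p_value"] < p_max)]
    table = table.sort_values(
        ["p_value", "log2_fold_change"],
        key=lambda s: s if s.name == "p_value" else -s.abs(),
    ).head(top_n)
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


def run_pipeline(config: dict) -> dict:
    """Execute io -> clustering -> enrichment -> annotation -> dynamics.

    The config lists the input source (synthetic spec or contig/GEx paths),
    chain scope, seed, and thresholds; every module's TSV output plus a run
    manifest (version, seeds, thresholds, per-stage counts) is written to
    ``outdir``.  Fully deterministic for a fixed config and seed.
    """
    from . import cdr3_clustering as cc
    from . import neighbor_enrichment as ne
    from . import phenotype_annotation as pa
    from . import vdj_synthetic as vs
    from .repertoire_io import (build_repertoire, parse_contigs, read_gex_triplet,
                                resolve_cell_chains, write_repertoire_tsv)

    known_keys = {"seed", "outdir", "input", "cluster", "enrich", "annotate",
                  "dynamics"}
    unknown = set(config) - known_keys
    if unknown:
        raise PipelineError("config", ValueError(
            f"unknown config keys {sorted(unknown)}; expected {sorted(known_keys)}"))
    if "outdir" not in config:
        raise PipelineError("config", ValueError("config requires 'outdir'"))

    outdir = config["outdir"]
    seed = int(config.get("seed", 0))
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "version": _pkg_version,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "outdir"},
        "stages": {},
    }

    # -- stage 1: input ----------------------------------------------------
    stage = "io"
    try:
        source = config.get("input", {})
        kind = source.get("kind", "synthetic")
        if kind == "synthetic":
            model = vs.default_model()
            planted = [
                vs.PlantedCluster(**p) for p in source.get("planted", [])
            ]
            spec = vs.SyntheticSpec(
                n_clones=int(source.get("n_clones", 300)),
                seed=seed,
                planted_clusters=planted,
                samples=[tuple(s) if not isinstance(s, dict)
                         else (s["sample_id"], s.get("condition", ""), s.get("shifts", {}))
                         for s in source.get("samples", [{"sample_id": "S1"}])],
            )
            repertoire, truth = vs.simulate_repertoire(model, spec)
            manifest["stages"][stage] = {
                "kind": "synthetic", "cells": len(repertoire),
                "unique_clones": len(repertoire.unique_clones()),
            }
        elif kind == "files":
            if "contigs" not in source:
                raise ValueError("input.kind='files' requires input.contigs")
            records = parse_contigs(source["contigs"])
            clonotypes, report = resolve_cell_chains(
                records, sample_id=source.get("sample_id", "S1"))
            if "gex_dir" in source:
                gex = read_gex_triplet(source["gex_dir"])
                repertoire, overlap = build_repertoire(
                    clonotypes, gex, sample_id=source.get("sample_id", "S1"),
                    strip_suffix=source.get("strip_suffix", False))
                report.update(overlap)
            else:
                repertoire = Repertoire(clonotypes=clonotypes)
            manifest["stages"][stage] = {"kind": "files", "cells": len(repertoire), **report}
        else:
            raise ValueError(f"unknown input kind {kind!r}")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc
    write_repertoire_tsv(repertoire, os.path.join(outdir, "repertoire.tsv"))

    # -- stage 2: clustering ----------------------------------------------
    stage = "clustering"
    try:
        ccfg = config.get("cluster", {})
        chains = ccfg.get("chains", ["A", "B", "G", "D"])
        split = cc.cluster_chain_split(repertoire)
        cluster_rows = []
        n_clusters = 0
        for chain in chains:
            clusters, _singletons = cc.cluster_chain(
                split[chain],
                inflation=float(ccfg.get("inflation", 2.0)),
                require_same_v=bool(ccfg.get("edge_require_v", False)),
            )
            by_id = {it.item_id: it for it in split[chain]}
            for cl in clusters:
                n_clusters += 1
                for mid in cl.member_ids:
                    it = by_id[mid]
                    cluster_rows.append({
                        "chain": chain, "cluster_id": f"{chain}{cl.cluster_id}",
                        "name": cl.name, "junction_length": cl.junction_length,
                        "consensus": cl.consensus, "v_gene": it.v_gene,
                        "j_gene": it.j_gene, "cdr3_aa": it.cdr3_aa,
                        "multiplicity": it.multiplicity,
                    })
        pd.DataFrame(cluster_rows).to_csv(
            os.path.join(outdir, "clusters.tsv"), sep="\t", index=False)
        manifest["stages"][stage] = {"clusters": n_clusters, "members": len(cluster_rows)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- stage 3: neighbor enrichment ---------------------------------------
    stage = "enrichment"
    try:
        ecfg = config.get("enrich", {})
        params = ne.DistanceParams(radius=float(ecfg.get("radius", 12.5)))
        fold = int(ecfg.get("fold", 50))
        alpha = float(ecfg.get("alpha", 0.05))
        enr_rows = []
        n_sig = 0
        for ci, chain in enumerate(chains):
            items = split[chain]
            if len(items) < 20:
                continue
            clones = [(it.v_gene, it.j_gene, it.cdr3_aa) for it in items]
            bg = ne.shuffle_background(clones, fold=fold, seed=seed + 101 + ci)
            for r in ne.enrich_clones(clones, bg, params, alpha=alpha):
                n_sig += r.significant
                enr_rows.append({
                    "chain": chain, "clone_key": r.clone_key, "v_gene": r.v_gene,
                    "j_gene": r.j_gene, "cdr3_aa": r.cdr3_aa, "k_rep": r.k_rep,
                    "k_bg": r.k_bg, "p_raw": r.p_raw, "p_adj": r.p_adj,
                    "significant": r.significant,
                })
        pd.DataFrame(enr_rows).to_csv(
            os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
        manifest["stages"][stage] = {"tested": len(enr_rows), "significant": int(n_sig)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- stage 4: annotation -------------------------------------------------
    stage = "annotation"
    try:
        rows = []
        label_counts: Dict[str, int] = {}
        for c in repertoire.clonotypes:
            label = pa.classify_by_tcr(c)
            label_counts[label] = label_counts.get(label, 0) + 1
            rows.append({"barcode": c.barcode, "sample_id": c.sample_id,
                         "clone_key": c.clone_key, "tcr_label": label})
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, "annotation.tsv"), sep="\t", index=False)
        manifest["stages"][stage] = {"labels": dict(sorted(label_counts.items()))}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- stage 5: dynamics ---------------------------------------------------
    stage = "dynamics"
    try:
        dcfg = config.get("dynamics", {})
        sample_ids = sorted({c.sample_id for c in repertoire.clonotypes})
        freq_tables = {
            sid: clone_frequencies(repertoire, sid) for sid in sample_ids
        }
        pd.concat(freq_tables.values()).to_csv(
            os.path.join(outdir, "frequencies.tsv"), sep="\t", index=False)
        d_meta: dict = {"samples": sample_ids}
        pre, post = dcfg.get("pre"), dcfg.get("post")
        if pre is None and post is None and len(sample_ids) == 2:
            pre, post = sample_ids
        if pre is not None and post is not None:
            calls = paired_dynamics(
                freq_tables[pre], freq_tables[post],
                min_freq=float(dcfg.get("min_freq", 0.01)),
                min_fold=float(dcfg.get("min_fold", 2.0)),
            )
            pd.DataFrame([vars(c) for c in calls]).to_csv(
                os.path.join(outdir, "dynamics.tsv"), sep="\t", index=False)
            d_meta.update({
                "pre": pre, "post": post,
                "selected": int(sum(c.selected for c in calls)),
            })
        manifest["stages"][stage] = d_meta
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
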