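"""Toy V(D)J recombination model and synthetic data generation.

A miniature amino-acid-level generative model of junction formation: a V
segment contributes a CDR3 prefix, a J segment a suffix, both may be trimmed,
and an insert of i.i.d. residues joins them.  The model serves three roles:

* generating synthetic repertoires (with optional planted near-identical
  sequence clusters and clonal expansion) in the exact file formats the IO
  layer reads, so the whole pipeline is testable without any download;
* estimating generation probabilities (pgen) by Monte Carlo, with an
  exact-enumeration oracle on miniature models;
* geometric-mean pgen banding (flagging sequences within one SD of the
  geometric mean on the log scale), the standard screen for high-probability
  "public" recombination products.

There is no nucleotide layer, D segment, or thymic selection: the model is a
desk-scale stand-in for full IGoR/OLGA-style machinery, sufficient to exercise
background stratification and pgen banding, not a biological claim.
"""

from __future__ import annotations

import csv
import itertools
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .neighbor_enrichment import AMINO_ACIDS, _blosum62_table
from .repertoire_io import Chain, Clonotype, GexMatrix, Repertoire

logger = logging.getLogger("tcrfirst")


@dataclass
class RecombinationModel:
    """Amino-acid-level junction model: V prefix + insert + J suffix with trims."""

    v_segments: List[Tuple[str, float, str]]  # (name, frequency, cdr3 prefix)
    j_segments: List[Tuple[str, float, str]]  # (name, frequency, cdr3 suffix)
    insert_length_dist: np.ndarray  # P(insert length = 0..L_max)
    insert_residue_dist: np.ndarray  # P(residue), AMINO_ACIDS order
    trim_dist: np.ndarray  # P(trim = 0..T_max), prefix and suffix independently
    min_length: int = 5

    def __post_init__(self) -> None:
        self.insert_length_dist = np.asarray(self.insert_length_dist, float)
        self.insert_residue_dist = np.asarray(self.insert_residue_dist, float)
        self.trim_dist = np.asarray(self.trim_dist, float)
        for name, vec in (
            ("insert_length_dist", self.insert_length_dist),
            ("insert_residue_dist", self.insert_residue_dist),
            ("trim_dist", self.trim_dist),
        ):
            if abs(vec.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {vec.sum()})")
        if len(self.insert_residue_dist) != 20:
            raise ValueError("insert_residue_dist must cover the 20 amino acids")
        for name, freq, _ in self.v_segments + self.j_segments:
            if freq <= 0:
                raise ValueError(f"segment {name} has non-positive frequency")
        vtot = sum(f for _, f, _ in self.v_segments)
        jtot = sum(f for _, f, _ in self.j_segments)
        self.v_segments = [(n, f / vtot, p) for n, f, p in self.v_segments]
        self.j_segments = [(n, f / jtot, s) for n, f, s in self.j_segments]
        t_max = len(self.trim_dist) - 1
        shortest = min(len(s) for _, _, s in self.v_segments + self.j_segments)
        if t_max > shortest:
            raise ValueError(
                "maximum trim exceeds the shortest segment contribution; "
                "trim probabilities would not be well defined"
            )

    @property
    def v_freqs(self) -> np.ndarray:
        return np.array([f for _, f, _ in self.v_segments])

    @property
    def j_freqs(self) -> np.ndarray:
        return np.array([f for _, f, _ in self.j_segments])


def default_model() -> RecombinationModel:
    """Illustrative 12-V / 8-J beta-chain-like model.

    Frequencies are loosely shaped like human TRB usage (TRBV20-1 the most
    common V); they are documented as illustrative, not biological truth.
    """
    v = [
        ("TRBV20-1", 0.17, "CSARD"),
        ("TRBV5-1", 0.11, "CASSL"),
        ("TRBV28", 0.10, "CASSF"),
        ("TRBV19", 0.09, "CASSI"),
        ("TRBV6-5", 0.09, "CASSY"),
        ("TRBV7-9", 0.08, "CASSP"),
        ("TRBV4-1", 0.08, "CASSQ"),
        ("TRBV9", 0.07, "CASSV"),
        ("TRBV27", 0.06, "CASSW"),
        ("TRBV2", 0.06, "CASSE"),
        ("TRBV12-3", 0.05, "CASSG"),
        ("TRBV30", 0.04, "CAWSM"),
    ]
    j = [
        ("TRBJ2-1", 0.18, "NEQFF"),
        ("TRBJ2-7", 0.17, "SYEQYF"),
        ("TRBJ2-3", 0.14, "STDTQYF"),
        ("TRBJ1-1", 0.13, "NTEAFF"),
        ("TRBJ2-5", 0.12, "QETQYF"),
        ("TRBJ1-2", 0.10, "NYGYTF"),
        ("TRBJ1-5", 0.09, "SNQPQHF"),
        ("TRBJ2-2", 0.07, "NTGELFF"),
    ]
    # insert lengths centred near 3: real beta junctions carry substantial
    # N-region insertion, and without it the toy repertoire would be so
    # low-diversity that chance Hamming-1 neighbours swamp any real structure
    return RecombinationModel(
        v_segments=v,
        j_segments=j,
        insert_length_dist=np.array([0.05, 0.10, 0.20, 0.25, 0.20, 0.12, 0.08]),
        insert_residue_dist=np.full(20, 0.05),
        trim_dist=np.array([0.5, 0.35, 0.15]),
    )


@dataclass
class JunctionDraw:
    v_name: str
    j_name: str
    cdr3_aa: str
    path_probability: float
    choices: dict


def generate_junction(model: RecombinationModel, rng: np.random.Generator,
                      max_retries: int = 200) -> JunctionDraw:
    """Sample one junction: V, J, trims, insert length, insert residues.

    ``path_probability`` is the product of every choice probability along the
    sampled path (one path only; the sequence's full pgen sums over paths).
    Draws shorter than ``model.min_length`` are resampled, with a bounded
    retry count.
    """
    for _ in range(max_retries):
        vi = int(rng.choice(len(model.v_segments), p=model.v_freqs))
        ji = int(rng.choice(len(model.j_segments), p=model.j_freqs))
        v_name, v_p, prefix = model.v_segments[vi]
        j_name, j_p, suffix = model.j_segments[ji]
        tp = int(rng.choice(len(model.trim_dist), p=model.trim_dist))
        ts = int(rng.choice(len(model.trim_dist), p=model.trim_dist))
        ins_len = int(rng.choice(len(model.insert_length_dist), p=model.insert_length_dist))
        ins_idx = rng.choice(20, size=ins_len, p=model.insert_residue_dist)
        insert = "".join(AMINO_ACIDS[i] for i in ins_idx)
        cdr3 = prefix[: len(prefix) - tp] + insert + suffix[ts:]
        if len(cdr3) < model.min_length:
            continue
        prob = (
            v_p * j_p * model.trim_dist[tp] * model.trim_dist[ts]
            * model.insert_length_dist[ins_len]
            * float(np.prod(model.insert_residue_dist[ins_idx]))
        )
        return JunctionDraw(
            v_name=v_name,
            j_name=j_name,
            cdr3_aa=cdr3,
            path_probability=float(prob),
            choices={
                "v": v_name, "j": j_name, "trim_prefix": tp, "trim_suffix": ts,
                "insert": insert,
            },
        )
    raise RuntimeError(
        f"could not generate a junction of length >= {model.min_length} "
        f"in {max_retries} attempts; check segment lengths"
    )


# ---------------------------------------------------------------------------
# generation probability
# ---------------------------------------------------------------------------


def estimate_pgen_mc(
    model: RecombinationModel,
    cdr3_aa: str,
    v_name: Optional[str] = None,
    n_samples: int = 10_000,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Monte-Carlo pgen: fraction of sampled junctions equal to the target.

    Returns ``(estimate, binomial standard error)``.  With ``v_name`` the hit
    must also use that V segment.
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be at least 10^4 for a usable estimate")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_samples):
        draw = generate_junction(model, rng)
        if draw.cdr3_aa == cdr3_aa and (v_name is None or draw.v_name == v_name):
            hits += 1
    p = hits / n_samples
    se = math.sqrt(p * (1 - p) / n_samples)
    return p, se


def _enumeration_size(model: RecombinationModel) -> float:
    n_ins = sum(20 ** L for L in range(len(model.insert_length_dist)))
    return len(model.v_segments) * len(model.j_segments) * len(model.trim_dist) ** 2 * n_ins


def exact_pgen_small(
    model: RecombinationModel,
    cdr3_aa: str,
    v_name: Optional[str] = None,
    max_paths: float = 1e6,
) -> float:
    """Exact pgen by summing path probabilities over all emitting paths.

    Every (V, J, prefix trim, suffix trim) combination consistent with the
    target determines the insert string uniquely; the probabilities of all
    such paths are summed.  Only feasible on miniature models (path space
    bounded by ``max_paths``); larger models should use the MC estimator.
    """
    space = (
        len(model.v_segments) * len(model.j_segments) * len(model.trim_dist) ** 2
    )
    if space > max_paths:
        raise ValueError(
            f"path space {space:.3g} exceeds {max_paths:.0g}; use estimate_pgen_mc"
        )
    if len(cdr3_aa) < model.min_length:
        return 0.0
    L = len(cdr3_aa)
    max_ins = len(model.insert_length_dist) - 1
    total = 0.0
    for v_name_i, v_p, prefix in model.v_segments:
        if v_name is not None and v_name_i != v_name:
            continue
        for j_name_i, j_p, suffix in model.j_segments:
            for tp in range(len(model.trim_dist)):
                if tp > len(prefix):
                    continue
                pre = prefix[: len(prefix) - tp]
                if not cdr3_aa.startswith(pre):
                    continue
                for ts in range(len(model.trim_dist)):
                    if ts > len(suffix):
                        continue
                    suf = suffix[ts:]
                    ins_len = L - len(pre) - len(suf)
                    if ins_len < 0 or ins_len > max_ins:
                        continue
                    if not cdr3_aa.endswith(suf):
                        continue
                    insert = cdr3_aa[len(pre): L - len(suf)]
                    p_ins = model.insert_length_dist[ins_len]
                    for ch in insert:
                        p_ins *= model.insert_residue_dist[AMINO_ACIDS.index(ch)]
                    total += v_p * j_p * model.trim_dist[tp] * model.trim_dist[ts] * p_ins
    return float(total)


def enumerate_reachable(model: RecombinationModel, max_paths: float = 1e6) -> Dict[str, float]:
    """All reachable junctions of a miniature model with their exact pgen.

    Only valid when no emission can fall below ``min_length`` (otherwise the
    generator's resampling renormalizes and the enumeration would not sum
    to 1).
    """
    if _enumeration_size(model) > max_paths:
        raise ValueError("enumeration space too large; this oracle is for miniature models")
    out: Dict[str, float] = {}
    max_ins = len(model.insert_length_dist) - 1
    inserts_by_len = {
        L: ["".join(c) for c in itertools.product(AMINO_ACIDS, repeat=L)]
        for L in range(max_ins + 1)
    }
    for _, v_p, prefix in model.v_segments:
        for _, j_p, suffix in model.j_segments:
            for tp in range(min(len(model.trim_dist), len(prefix) + 1)):
                pre = prefix[: len(prefix) - tp]
                for ts in range(min(len(model.trim_dist), len(suffix) + 1)):
                    suf = suffix[ts:]
                    base = v_p * j_p * model.trim_dist[tp] * model.trim_dist[ts]
                    for ins_len in range(max_ins + 1):
                        p_len = model.insert_length_dist[ins_len]
                        if p_len == 0:
                            continue
                        for insert in inserts_by_len[ins_len]:
                            p_ins = p_len
                            for ch in insert:
                                p_ins *= model.insert_residue_dist[AMINO_ACIDS.index(ch)]
                            seq = pre + insert + suf
                            if len(seq) < model.min_length:
                                raise ValueError(
                                    "model can emit junctions below min_length; "
                                    "enumeration would not normalize"
                                )
                            out[seq] = out.get(seq, 0.0) + base * p_ins
    return out


def pgen_band(pgen_values: Sequence[float]):
    """Geometric-mean banding of pgen values on the log10 scale.

    Returns ``(geometric_mean, log10_sd, flags)`` where a value is flagged
    when its log10 lies within one SD of the mean of logs (inclusive at the
    boundary).
    """
    vals = np.asarray(list(pgen_values), dtype=float)
    if vals.size == 0:
        raise ValueError("pgen_band requires at least one value")
    if (vals <= 0).any():
        raise ValueError("pgen values must be strictly positive")
    logs = np.log10(vals)
    mean = float(logs.mean())
    sd = float(logs.std(ddof=0))
    flags = np.abs(logs - mean) <= sd + 1e-12
    return 10.0 ** mean, sd, flags.tolist()


# ---------------------------------------------------------------------------
# synthetic repertoires
# ---------------------------------------------------------------------------


@dataclass
class PlantedCluster:
    """A seed junction plus near-identical variants, emulating antigen-driven
    convergence: variants substitute biochemically similar residues
    (BLOSUM62 similarity >= 2), as epitope-focused TCR clusters do."""

    seed_cdr3: str
    v_gene: str
    j_gene: str
    size: int
    max_mutations: int = 1

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("planted cluster size must be >= 2")


@dataclass
class SyntheticSpec:
    n_clones: int
    seed: int
    clone_size_geom_p: float = 0.7  # geometric cell-count distribution, mean 1/p
    planted_clusters: List[PlantedCluster] = field(default_factory=list)
    #: list of (sample_id, condition, {clone_key_prefix or "*": multiplier})
    samples: List[Tuple[str, str, dict]] = field(
        default_factory=lambda: [("S1", "baseline", {})]
    )
    #: reject background junctions Hamming-1-adjacent to each other or to a
    #: planted member, so the only sequence clusters are the planted ones
    background_singletons: bool = False


_CONSERVATIVE_PARTNERS: Dict[str, List[str]] = {}


def _conservative_partners() -> Dict[str, List[str]]:
    """Residues exchangeable at BLOSUM62 similarity >= 2, per residue.

    Residues with no such partner (e.g. N, G, P) map to an empty list and are
    never mutated: two low-similarity substitutions in one cluster would push
    member pairs beyond the conventional neighbor radius, which is not what
    an epitope-focused cluster looks like.
    """
    if not _CONSERVATIVE_PARTNERS:
        S = _blosum62_table()
        for i, a in enumerate(AMINO_ACIDS):
            _CONSERVATIVE_PARTNERS[a] = [
                AMINO_ACIDS[jj] for jj in range(20) if jj != i and S[i, jj] >= 2
            ]
    return _CONSERVATIVE_PARTNERS


def _mutate_conservative(seed: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute ``n_mut`` internal positions with high-similarity residues."""
    partners = _conservative_partners()
    eligible = [p for p in range(1, len(seed) - 1) if partners[seed[p]]]
    if len(eligible) < n_mut:
        raise ValueError(
            f"seed {seed!r} has only {len(eligible)} positions with conservative "
            f"substitutions available; cannot place {n_mut} mutations"
        )
    positions = rng.choice(np.asarray(eligible), size=n_mut, replace=False)
    chars = list(seed)
    for pos in positions:
        options = partners[chars[pos]]
        chars[pos] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def conservative_sites(seq: str) -> int:
    """Number of internal positions with a conservative substitution available."""
    partners = _conservative_partners()
    return sum(1 for p in range(1, len(seq) - 1) if partners[seq[p]])


def conservative_variant_capacity(seq: str) -> int:
    """Number of distinct single conservative substitutions of ``seq``."""
    partners = _conservative_partners()
    return sum(len(partners[seq[p]]) for p in range(1, len(seq) - 1))


def sample_planted_clusters(
    model: RecombinationModel,
    sizes: Sequence[int],
    rng: np.random.Generator,
    length: int = 14,
    max_mutations: int = 1,
    max_draws: int = 50_000,
) -> List[PlantedCluster]:
    """Draw cluster seeds from the model, one per V gene, at a fixed length.

    Seeds must offer enough distinct conservative variants (capacity at least
    ``size + 6``) and distinct V genes keep the clusters' (v_gene, length)
    background strata from overlapping.  The fixed common length keeps each
    cluster a small fraction of its length stratum.
    """
    planted: List[PlantedCluster] = []
    used_v: set = set()
    used_seq: set = set()
    for size in sizes:
        for _ in range(max_draws):
            d = generate_junction(model, rng)
            if (
                len(d.cdr3_aa) == length
                and conservative_variant_capacity(d.cdr3_aa) >= size + 6
                and d.cdr3_aa not in used_seq
                and d.v_name not in used_v
            ):
                used_seq.add(d.cdr3_aa)
                used_v.add(d.v_name)
                break
        else:
            raise RuntimeError(
                f"no eligible cluster seed of length {length} found in "
                f"{max_draws} draws"
            )
        planted.append(
            PlantedCluster(
                seed_cdr3=d.cdr3_aa, v_gene=d.v_name, j_gene=d.j_name,
                size=size, max_mutations=max_mutations,
            )
        )
    return planted


def simulate_repertoire(
    model: RecombinationModel,
    spec: SyntheticSpec,
    locus: str = "TRB",
):
    """Draw a clonal repertoire from the model, plant clusters, expand clones.

    Returns ``(repertoire, truth)``.  ``truth`` maps clone_key to a dict with
    the planted-cluster label (or None), the junction, and a single-path pgen
    proxy (the recorded path probability; exact pgen is available through
    :func:`exact_pgen_small` on miniature models).
    """
    rng = np.random.default_rng(spec.seed)

    # planted members first, so the background can be rejected against them
    planted_label: Dict[Tuple[str, str], int] = {}
    planted_clones: List[Tuple[str, str, str]] = []
    for ci, pc in enumerate(spec.planted_clusters):
        members = [pc.seed_cdr3]
        attempts = 0
        while len(members) < pc.size:
            n_mut = int(rng.integers(1, pc.max_mutations + 1))
            var = _mutate_conservative(pc.seed_cdr3, n_mut, rng)
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError("cannot generate enough distinct planted variants")
            if var in members:
                continue
            members.append(var)
        for m in members:
            planted_clones.append((pc.v_gene, pc.j_gene, m))
            planted_label[(pc.v_gene, m)] = ci

    # wildcard keys give O(L) adjacency lookups (same-length Hamming <= 1)
    hash_keys: set = set()

    def keys_of(seq: str):
        L = len(seq)
        yield (L, -1, seq)
        for pos in range(L):
            yield (L, pos, seq[:pos] + seq[pos + 1:])

    def is_adjacent(seq: str) -> bool:
        return any(k in hash_keys for k in keys_of(seq))

    for _, _, m in planted_clones:
        hash_keys.update(keys_of(m))

    clones: List[Tuple[str, str, str]] = []
    pgen_proxy: Dict[str, float] = {}
    seen = {(v, c) for v, _, c in planted_clones}
    rejected_adjacent = 0
    while len(clones) < spec.n_clones:
        draw = generate_junction(model, rng)
        key = (draw.v_name, draw.cdr3_aa)
        if key in seen:
            continue
        if spec.background_singletons and is_adjacent(draw.cdr3_aa):
            rejected_adjacent += 1
            if rejected_adjacent > 100 * max(spec.n_clones, 100):
                raise RuntimeError(
                    "cannot draw a singleton background; model too low-diversity"
                )
            continue
        seen.add(key)
        clones.append((draw.v_name, draw.j_name, draw.cdr3_aa))
        pgen_proxy[draw.cdr3_aa] = draw.path_probability
        if spec.background_singletons:
            hash_keys.update(keys_of(draw.cdr3_aa))
    if rejected_adjacent:
        logger.info(
            "simulate_repertoire: %d junctions rejected to keep the background "
            "singleton-only", rejected_adjacent
        )

    clones = clones + planted_clones
    for _, _, m in planted_clones:
        pgen_proxy.setdefault(m, float("nan"))

    clonotypes: List[Clonotype] = []
    truth: Dict[str, dict] = {}
    cell_i = 0
    for sample_id, condition, shifts in spec.samples:
        for v, j, cdr3 in clones:
            size = int(rng.geometric(spec.clone_size_geom_p))
            chain = Chain(locus=locus, v_gene=v, j_gene=j, cdr3_aa=cdr3)
            proto = (Clonotype(barcode="x", chain_bd=chain)
                     if locus in ("TRB", "TRD")
                     else Clonotype(barcode="x", chain_ag=chain))
            mult = shifts.get(proto.clone_key, shifts.get("*", 1.0))
            size = int(round(size * mult))
            for _ in range(size):
                barcode = f"CELL{cell_i:07d}-1"
                cell_i += 1
                if locus in ("TRB", "TRD"):
                    ct = Clonotype(barcode=barcode, chain_bd=chain, sample_id=sample_id)
                else:
                    ct = Clonotype(barcode=barcode, chain_ag=chain, sample_id=sample_id)
                clonotypes.append(ct)
                truth.setdefault(ct.clone_key, {
                    "v_gene": v, "j_gene": j, "cdr3_aa": cdr3,
                    "planted": planted_label.get((v, cdr3)),
                    "pgen_proxy": pgen_proxy.get(cdr3, float("nan")),
                })

    samples_meta = {
        sid: {"id": sid, "condition": cond} for sid, cond, _ in spec.samples
    }
    return Repertoire(clonotypes=clonotypes, samples=samples_meta), truth


# ---------------------------------------------------------------------------
# synthetic gene expression
# ---------------------------------------------------------------------------


def simulate_counts(
    cell_phenotypes: Sequence[str],
    signatures: Dict[str, Sequence[str]],
    n_genes: int = 5000,
    nb_mean: float = 0.3,
    nb_dispersion: float = 2.0,
    effect: float = 8.0,
    seed: Optional[int] = None,
    barcodes: Optional[Sequence[str]] = None,
):
    """Negative-binomial count matrix with phenotype-specific marker boosts.

    Every gene draws from NB(mean ``nb_mean``, dispersion ``nb_dispersion``);
    the marker genes of a cell's own phenotype have their mean multiplied by
    ``effect``.  The low baseline mean emulates single-cell dropout: a
    signature that is not boosted is mostly zeros, which is what makes
    rank-based gating scores separate.  Marker sets may overlap across
    phenotypes (warned, allowed).  Returns ``(GexMatrix, labels)``.
    """
    phenos = list(cell_phenotypes)
    missing = {p for p in phenos if p not in signatures}
    if missing:
        raise ValueError(f"phenotypes without signatures: {sorted(missing)}")
    all_markers: List[str] = []
    seen_markers = set()
    overlap = False
    for p in sorted(signatures):
        for g in signatures[p]:
            if g in seen_markers:
                overlap = True
            else:
                seen_markers.add(g)
                all_markers.append(g)
    if overlap:
        logger.warning("simulate_counts: marker sets overlap across phenotypes")
    if len(all_markers) > n_genes:
        raise ValueError("n_genes smaller than the union of marker sets")
    features = all_markers + [f"GENE{i:05d}" for i in range(n_genes - len(all_markers))]
    feat_index = {g: i for i, g in enumerate(features)}

    rng = np.random.default_rng(seed)
    n_cells = len(phenos)
    means = np.full((n_cells, n_genes), nb_mean)
    for i, p in enumerate(phenos):
        idx = [feat_index[g] for g in signatures[p]]
        means[i, idx] *= effect
    r = nb_dispersion
    p_nb = r / (r + means)
    counts = rng.negative_binomial(r, p_nb)
    if barcodes is None:
        barcodes = [f"CELL{i:07d}-1" for i in range(n_cells)]
    gex = GexMatrix(barcodes=list(barcodes), features=features,
                    counts=sp.csr_matrix(counts))
    return gex, phenos


# ---------------------------------------------------------------------------
# fixture writers (formats the IO layer reads)
# ---------------------------------------------------------------------------


def write_contigs_csv(repertoire: Repertoire, path, sample_id: Optional[str] = None) -> None:
    """Write a 10x-style filtered_contig.csv (one row per chain)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["barcode", "chain", "v_gene", "j_gene", "cdr3", "umis", "productive"])
        for c in repertoire.clonotypes:
            if sample_id is not None and c.sample_id != sample_id:
                continue
            for ch in (c.chain_ag, c.chain_bd):
                if ch is None:
                    continue
                w.writerow([c.barcode, ch.locus, ch.v_gene, ch.j_gene, ch.cdr3_aa, 1, "True"])


def write_fixture_dir(repertoire: Repertoire, gex: GexMatrix, dirpath) -> None:
    """Write a complete paired fixture: contig CSV plus Matrix Market triplet."""
    from .repertoire_io import write_gex_triplet

    os.makedirs(dirpath, exist_ok=True)
    write_contigs_csv(repertoire, os.path.join(dirpath, "filtered_contig.csv"))
    write_gex_triplet(gex, dirpath)
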