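"""Synthetic inputs with the statistical structure the analysis assumes.

Emulates, at reduced scale, the three data layers the pipeline consumes:

* a sparse directed interactome with hub-skewed degrees (directed
  preferential attachment), designated receptor and transcription-factor
  node sets, and "planted" receptor->TF signaling chains that serve as
  recoverable ground truth;
* gene-level RNA-seq counts: negative-binomial draws (variance mu +
  alpha*mu^2) whose means are elevated by a fold change on planted-path
  nodes in the active condition, with a multiplicative batch effect on
  half of each condition's samples (batch balanced against condition);
* a genomic-locus fixture: SNP association table with a known number of
  hits below 1e-5, binding-site intervals with a known overlap count, a
  block-structured r^2 matrix, and a phenotype table drawn from a
  logistic model with a chosen gene-by-vitamin-D interaction effect.

All randomness flows from one root seed through named substreams, so
generating one layer never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .prep import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "LocusFixture",
    "generate_ppi",
    "plant_paths",
    "generate_expression",
    "generate_locus_fixture",
    "simulate_all",
    "write_simulation",
]

CONTROL = "control"
TREATMENT = "treatment"

_STREAMS = {"ppi": 0, "plant": 1, "expression": 2, "locus": 3, "receptors": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one root seed."""
    if name not in _STREAMS:
        raise ValueError(f"unknown stream {name!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults are the conditions the recovery experiments assume: a
    300-node hub-skewed network, three planted 4-node receptor->TF chains
    with a 2-fold expression increase in the treated condition, six
    samples per condition, NB dispersion 0.1 and a 1.5x batch effect on
    half of each condition's samples.
    """

    n_nodes: int = 300
    edge_attach: int = 3
    n_receptors: int = 10
    n_tfs: int = 10
    n_planted_paths: int = 3
    planted_len: int = 4
    fold_change: float = 2.0
    base_mean: float = 100.0
    dispersion: float = 0.1
    n_samples_per_condition: int = 6
    batch_effect: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        positive_int = ["n_nodes", "edge_attach", "n_receptors", "n_tfs",
                        "n_samples_per_condition"]
        for name in positive_int:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_planted_paths < 0:
            raise ValueError("n_planted_paths must be nonnegative")
        if self.planted_len < 2:
            raise ValueError("planted_len must be >= 2")
        for name in ("base_mean", "dispersion", "batch_effect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.n_receptors + self.n_tfs > self.n_nodes:
            raise ValueError("n_receptors + n_tfs must not exceed n_nodes")
        if self.planted_len > self.n_nodes:
            raise ValueError("planted_len must not exceed n_nodes")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedTruth:
    """Ground-truth active signaling chains injected by the simulator."""

    paths: list[tuple[str, ...]] = field(default_factory=list)
    fold_change: float = 1.0
    active_condition: str = TREATMENT

    @property
    def nodes(self) -> set[str]:
        return {n for p in self.paths for n in p}

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {e for p in self.paths for e in zip(p[:-1], p[1:])}


def _node_name(i: int) -> str:
    return f"GENE{i:04d}"


def generate_ppi(config: SimConfig,
                 ) -> tuple[nx.DiGraph, list[str], list[str]]:
    """Directed preferential-attachment interactome with receptors and TFs.

    Nodes join one at a time, each forming ``edge_attach`` edges with
    existing nodes chosen with probability proportional to (degree + 1),
    mimicking the hub-skewed degree distribution of curated interactomes.
    Each edge's direction is drawn uniformly (new->old or old->new):
    consensus-oriented interactions carry signal both into and out of
    hubs, and a one-way orientation would make the network acyclic and
    starve receptor->TF reachability. Receptors are then guaranteed
    out-degree >= 1 and TFs in-degree >= 1 (edges added where needed), and
    at least one receptor-TF pair is made reachable.
    """
    rng = substream(config.seed, "ppi")
    n, m = config.n_nodes, config.edge_attach
    g = nx.DiGraph()
    names = [_node_name(i) for i in range(n)]
    g.add_nodes_from(names)
    seed_size = min(m + 1, n)
    # small fully-connected kernel to attach to
    for i in range(seed_size):
        for j in range(seed_size):
            if i != j:
                g.add_edge(names[i], names[j])
    degree = np.zeros(n)
    for i in range(seed_size):
        degree[i] = g.degree(names[i])
    for i in range(seed_size, n):
        k = min(m, i)
        probs = degree[:i] + 1.0
        probs = probs / probs.sum()
        targets = rng.choice(i, size=k, replace=False, p=probs)
        for t in targets:
            if rng.random() < 0.5:
                g.add_edge(names[i], names[int(t)])
            else:
                g.add_edge(names[int(t)], names[i])
            degree[int(t)] += 1
            degree[i] += 1

    rng_rt = substream(config.seed, "receptors")
    special = rng_rt.choice(n, size=config.n_receptors + config.n_tfs,
                            replace=False)
    receptors = sorted(names[int(i)] for i in special[:config.n_receptors])
    tfs = sorted(names[int(i)] for i in special[config.n_receptors:])
    others = [x for x in names if x not in set(receptors) | set(tfs)]
    for r in receptors:
        if g.out_degree(r) == 0:
            tgt = others[int(rng_rt.integers(len(others)))]
            g.add_edge(r, tgt)
    for t in tfs:
        if g.in_degree(t) == 0:
            src = others[int(rng_rt.integers(len(others)))]
            g.add_edge(src, t)
    if not any(nx.has_path(g, r, t)
               for r in receptors for t in tfs if r != t):
        g.add_edge(receptors[0], tfs[0])
        logger.info("generate_ppi: added fallback edge %s->%s for "
                    "reachability", receptors[0], tfs[0])
    return g, receptors, tfs


def plant_paths(g: nx.DiGraph, receptors: list[str], tfs: list[str],
                config: SimConfig) -> PlantedTruth:
    """Inject ground-truth receptor->TF chains of exactly ``planted_len``
    nodes, adding any missing edges (mutates ``g``).

    Receptor-TF pairs are chosen so the chain becomes a genuine shortest
    path: candidate pairs must be at BFS distance >= planted_len - 1 (or
    unreachable) before planting, and the distance is re-checked after
    edge insertion. Intermediate nodes are drawn without reuse across
    paths where possible, giving node-disjoint interiors.
    """
    if not receptors or not tfs:
        raise ValueError("receptor and TF lists must be nonempty")
    if config.planted_len < 2:
        raise ValueError("planted_len must be >= 2")
    truth = PlantedTruth(paths=[], fold_change=config.fold_change,
                         active_condition=TREATMENT)
    if config.n_planted_paths == 0:
        return truth
    rng = substream(config.seed, "plant")
    target_hops = config.planted_len - 1
    interior_pool = [x for x in sorted(g.nodes)
                     if x not in set(receptors) | set(tfs)]
    used_nodes: set[str] = set()
    used_endpoints: set[str] = set()

    def distance(u: str, v: str) -> float:
        try:
            return nx.shortest_path_length(g, u, v)
        except nx.NetworkXNoPath:
            return float("inf")

    for _ in range(config.n_planted_paths):
        pairs = [(r, t) for r in receptors for t in tfs if r != t
                 and r not in used_endpoints and t not in used_endpoints]
        if not pairs:  # fewer distinct endpoints than requested paths
            pairs = [(r, t) for r in receptors for t in tfs if r != t]
        rng.shuffle(pairs)
        chosen = None
        for r, t in pairs:
            if distance(r, t) >= target_hops:
                chosen = (r, t)
                break
        if chosen is None:  # no pair far enough apart; take any pair
            chosen = pairs[0]
        r, t = chosen
        n_interior = config.planted_len - 2
        fresh = [x for x in interior_pool if x not in used_nodes]
        if len(fresh) < n_interior:
            fresh = interior_pool
        interior = [fresh[int(i)] for i in
                    rng.choice(len(fresh), size=n_interior, replace=False)]
        chain = [r, *interior, t]
        for u, v in zip(chain[:-1], chain[1:]):
            if not g.has_edge(u, v):
                g.add_edge(u, v)
        if nx.shortest_path_length(g, r, t) != target_hops:
            logger.warning("plant_paths: %s->%s has a shorter route than the "
                           "planted chain (%d hops)", r, t, target_hops)
        truth.paths.append(tuple(chain))
        used_nodes.update(interior)
        used_endpoints.update((r, t))
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape=shape, scale=mean / shape)
    return rng.poisson(lam)


def generate_expression(g: nx.DiGraph, truth: PlantedTruth,
                        config: SimConfig) -> CountMatrix:
    """Negative-binomial counts: one gene per node, two conditions.

    Planted-path nodes have mean ``base_mean * fold_change`` in the active
    condition and ``base_mean`` everywhere else. The second half of each
    condition's samples is labeled batch "B" and has all means multiplied
    by ``batch_effect`` — batch is balanced across conditions, so it is
    removable without touching the condition contrast.
    """
    genes = sorted(g.nodes)
    if not genes:
        raise ValueError("graph has no nodes")
    rng = substream(config.seed, "expression")
    n_per = config.n_samples_per_condition
    conditions = [CONTROL] * n_per + [TREATMENT] * n_per
    sample_ids = [f"{c}_{i + 1}" for c in (CONTROL, TREATMENT)
                  for i in range(n_per)]
    half = n_per // 2
    batches = (["A"] * (n_per - half) + ["B"] * half) * 2
    planted = truth.nodes
    base = np.full((len(genes), 2 * n_per), config.base_mean)
    for gi, gene in enumerate(genes):
        if gene in planted:
            for sj, cond in enumerate(conditions):
                if cond == truth.active_condition:
                    base[gi, sj] *= truth.fold_change
    for sj, b in enumerate(batches):
        if b == "B":
            base[:, sj] *= config.batch_effect
    counts = _nb_draw(rng, base, config.dispersion)
    df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=sample_ids)
    meta = pd.DataFrame({"condition": conditions, "batch": batches},
                        index=sample_ids)
    return CountMatrix(counts=df, meta=meta)


@dataclass
class LocusFixture:
    """Inputs for the locus statistics with recorded ground truth."""

    snps: pd.DataFrame          # id, chrom, pos, pvalue, trait
    intervals: pd.DataFrame     # chrom, start, end, name (0-based half-open)
    r2: pd.DataFrame            # symmetric, SNP ids on both axes
    phenotypes: pd.DataFrame    # outcome, IKZF1, IKZF3, vitd_ngml, covariates
    truth: dict


def generate_locus_fixture(n_snps: int = 40, n_intervals: int = 5,
                           block_spec: list[list[int]] | None = None,
                           glm_coefficients: dict[str, float] | None = None,
                           n_subjects: int = 1000, seed: int = 0,
                           n_significant: int | None = None,
                           n_overlapping_snps: int | None = None,
                           ) -> LocusFixture:
    """Locus fixture: SNPs, intervals, r^2 matrix and logistic phenotypes.

    ``block_spec`` partitions a subset of 0-based SNP indices into intended
    LD blocks (within-block r^2 drawn in [0.9, 1.0], between-block in
    [0, 0.2]). ``glm_coefficients`` maps design-column names (``intercept``,
    ``IKZF1``, ``IKZF3``, ``vitd``, ``IKZF1:IKZF3``, ``IKZF3:vitd``,
    ``maternal_asthma``, ``race_B``, ``race_C``) to true log-odds effects;
    unnamed columns get 0. ``n_significant`` SNPs (default a third) receive
    p-values below 1e-5; intervals are placed to cover exactly
    ``n_overlapping_snps`` SNP positions (default ``min(7, n_snps)``,
    mirroring a binding-site-in-locus count).
    """
    if n_snps <= 0 or n_intervals <= 0 or n_subjects <= 0:
        raise ValueError("n_snps, n_intervals and n_subjects must be positive")
    rng = substream(seed, "locus")
    block_spec = block_spec if block_spec is not None else []
    seen: set[int] = set()
    for b, block in enumerate(block_spec):
        if not block:
            raise ValueError(f"block_spec[{b}] is empty")
        for idx in block:
            if not 0 <= idx < n_snps:
                raise ValueError(f"block_spec[{b}] index {idx} out of range")
            if idx in seen:
                raise ValueError(f"block_spec assigns SNP {idx} twice")
            seen.add(idx)

    if n_significant is None:
        n_significant = n_snps // 3
    if not 0 <= n_significant <= n_snps:
        raise ValueError("n_significant out of range")
    if n_overlapping_snps is None:
        n_overlapping_snps = min(7, n_snps)
    if not 0 <= n_overlapping_snps <= n_snps:
        raise ValueError("n_overlapping_snps out of range")

    ids = [f"rs{1000 + i}" for i in range(n_snps)]
    positions = np.sort(rng.choice(np.arange(37_900_000, 38_140_000),
                                   size=n_snps, replace=False))
    sig_idx = set(int(i) for i in
                  rng.choice(n_snps, size=n_significant, replace=False))
    pvals = np.empty(n_snps)
    for i in range(n_snps):
        if i in sig_idx:
            pvals[i] = 10.0 ** rng.uniform(-12, -5.2)  # strictly < 1e-5
        else:
            pvals[i] = rng.uniform(1e-4, 1.0)
    traits = rng.choice(["asthma", "allergy", "autoimmune"], size=n_snps)
    snps = pd.DataFrame({"id": ids, "chrom": "chr17", "pos": positions,
                         "pvalue": pvals, "trait": traits})

    # intervals: a run of consecutive SNPs (by sorted position) is tiled by
    # overlap intervals — a span over a contiguous index run covers exactly
    # those SNPs — and the remaining intervals are placed in gaps so they
    # cover none
    records = []
    covered: set[int] = set()
    if n_overlapping_snps:
        start_idx = int(rng.integers(0, n_snps - n_overlapping_snps + 1))
        overlap_idx = list(range(start_idx, start_idx + n_overlapping_snps))
        covered = set(overlap_idx)
        n_overlap_intervals = min(len(overlap_idx),
                                  max(1, n_intervals - 1))
        per = -(-len(overlap_idx) // n_overlap_intervals)  # ceil division
        chunks = [overlap_idx[i:i + per]
                  for i in range(0, len(overlap_idx), per)]
        for ci, ch in enumerate(chunks):
            lo = int(positions[ch[0]]) - 1   # 0-based start covering 1st SNP
            hi = int(positions[ch[-1]])      # half-open end covering last
            records.append(("chr17", lo, hi, f"site_{ci}"))
    pos_set = set(int(p) for p in positions)
    while len(records) < n_intervals:
        start = int(rng.integers(37_900_000, 38_139_000))
        end = start + int(rng.integers(50, 500))
        if any(start <= p - 1 < end for p in pos_set):
            continue
        records.append(("chr17", start, end, f"empty_{len(records)}"))
    intervals = pd.DataFrame(records,
                             columns=["chrom", "start", "end", "name"])

    member = {idx: b for b, block in enumerate(block_spec) for idx in block}
    m = rng.uniform(0.0, 0.2, size=(n_snps, n_snps))
    m = (m + m.T) / 2
    for i in range(n_snps):
        for j in range(i + 1, n_snps):
            bi, bj = member.get(i), member.get(j)
            if bi is not None and bi == bj:
                v = rng.uniform(0.9, 1.0)
                m[i, j] = m[j, i] = v
        m[i, i] = 1.0
    r2 = pd.DataFrame(m, index=ids, columns=ids)

    coef = dict(glm_coefficients or {})
    ikzf1 = rng.normal(0.0, 1.0, size=n_subjects)
    ikzf3 = rng.normal(0.0, 1.0, size=n_subjects)
    vitd_ngml = rng.normal(30.0, 10.0, size=n_subjects).clip(min=1.0)
    vitd = (vitd_ngml >= 30.0).astype(float)
    maternal = rng.binomial(1, 0.3, size=n_subjects).astype(float)
    race = rng.choice(["A", "B", "C"], size=n_subjects)
    lp = (coef.get("intercept", 0.0)
          + coef.get("IKZF1", 0.0) * ikzf1
          + coef.get("IKZF3", 0.0) * ikzf3
          + coef.get("vitd", 0.0) * vitd
          + coef.get("IKZF1:IKZF3", 0.0) * ikzf1 * ikzf3
          + coef.get("IKZF3:vitd", 0.0) * ikzf3 * vitd
          + coef.get("maternal_asthma", 0.0) * maternal
          + coef.get("race_B", 0.0) * (race == "B")
          + coef.get("race_C", 0.0) * (race == "C"))
    outcome = rng.binomial(1, expit(lp))
    pheno = pd.DataFrame({
        "subject": [f"S{i:05d}" for i in range(n_subjects)],
        "outcome": outcome, "IKZF1": ikzf1, "IKZF3": ikzf3,
        "vitd_ngml": vitd_ngml, "maternal_asthma": maternal.astype(int),
        "race": race,
    })
    truth = {
        "n_significant": n_significant,
        "overlap_snp_indices": sorted(covered),
        "n_overlapping_snps": len(covered),
        "blocks": [sorted(ids[i] for i in block) for block in block_spec],
        "coefficients": coef,
    }
    return LocusFixture(snps=snps, intervals=intervals, r2=r2,
                        phenotypes=pheno, truth=truth)


def simulate_all(config: SimConfig) -> dict:
    """Run all network+expression generators; returns graph, node lists,
    planted truth and the count matrix in one bundle."""
    g, receptors, tfs = generate_ppi(config)
    truth = plant_paths(g, receptors, tfs, config)
    counts = generate_expression(g, truth, config)
    return {"graph": g, "receptors": receptors, "tfs": tfs,
            "truth": truth, "counts": counts, "config": config}


def write_simulation(bundle: dict, outdir: str | Path,
                     mouse_prefix: str = "gene") -> dict[str, Path]:
    """Write every simulator output as plain text files.

    The count matrix is written under mouse-style lowercase IDs together
    with a two-column mouse->human mapping table, so the preprocessing
    stage exercises the ID-mapping step; the edge list and node lists use
    the human-style IDs the network carries.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g: nx.DiGraph = bundle["graph"]
    counts: CountMatrix = bundle["counts"]
    files: dict[str, Path] = {}

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        files[name.split(".")[0]] = path

    from .network import write_edge_list
    _write("edges.tsv", lambda p: write_edge_list(g, p))
    _write("receptors.txt", lambda p: p.write_text(
        "\n".join(bundle["receptors"]) + "\n"))
    _write("tfs.txt", lambda p: p.write_text("\n".join(bundle["tfs"]) + "\n"))

    def mouse_id(human: str) -> str:
        return human.replace("GENE", mouse_prefix)

    mouse_counts = counts.counts.rename(index=mouse_id)
    _write("counts.tsv", lambda p: mouse_counts.to_csv(
        p, sep="\t", index_label="gene"))
    _write("samples.tsv", lambda p: counts.meta.to_csv(
        p, sep="\t", index_label="sample"))
    mapping = pd.DataFrame({"mouse_id": [mouse_id(h) for h in counts.genes],
                            "human_id": counts.genes})
    _write("idmap.tsv", lambda p: mapping.to_csv(p, sep="\t", index=False))
    truth: PlantedTruth = bundle["truth"]
    truth_df = pd.DataFrame({
        "path": ["|".join(p) for p in truth.paths],
        "fold_change": truth.fold_change,
        "active_condition": truth.active_condition,
    })
    _write("planted_truth.tsv", lambda p: truth_df.to_csv(
        p, sep="\t", index=False))
    return files


def write_locus_fixture(fx: LocusFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the locus fixture as SNP TSV, BED intervals, r^2 TSV and
    phenotype TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    p = outdir / "snps.tsv"
    fx.snps.to_csv(p, sep="\t", index=False)
    files["snps"] = p
    p = outdir / "sites.bed"
    fx.intervals[["chrom", "start", "end", "name"]].to_csv(
        p, sep="\t", index=False, header=False)
    files["sites"] = p
    p = outdir / "r2.tsv"
    fx.r2.to_csv(p, sep="\t", index_label="id")
    files["r2"] = p
    p = outdir / "phenotypes.tsv"
    fx.phenotypes.to_csv(p, sep="\t", index=False)
    files["phenotypes"] = p
    return files
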