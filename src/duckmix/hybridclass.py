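"""Simulate hybrid pedigrees, build per-generation assignment bins, classify.

The core procedure: from two genetically vetted parental gene pools
(allele-frequency vectors), simulate F1 hybrids by drawing one gamete from
each pool, then serial backcrosses (one Mendelian gamete from the previous
hybrid, one gamete from the recipient pool) for up to nine generations in
independent lineages toward each parental side. Running the admixture
estimator over the simulated cohorts (with parental reference genotypes
included) yields, per pedigree class, the distribution of interspecific
assignment probability; its mean and min/max across replicate simulations
and replicate fits form generation "bins". Empirical individuals are then
assigned to the generation whose bin contains their interspecific
assignment, or to the hybrid swarm when they fall between bins.

Interspecific assignment is always measured on the two-taxon scale: the
assignment probability to the taxon that is NOT the individual's majority
(for simulated backcrosses, the donor taxon). The expected value halves
with each backcross: class F_g carries expected donor ancestry 0.5^g
(F1 = 0.5, F2 = 0.25, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from duckmix._rng import substream
from duckmix.ancestry import (AncestryMatrix, align_replicates, fit_admixture,
                              merge_cluster_assignments)
from duckmix.genofilter import GenotypeMatrix
from duckmix.synthio import AlleleFrequencyPool, PoolSpec, simulate_parental_pools

TAXON_A = "A"
TAXON_B = "B"


class BinMonotonicityError(RuntimeError):
    """Raised when bin means are not strictly ordered by generation."""


@dataclass
class PedigreeSpec:
    """Design of one hybridization/backcross simulation."""

    n_f1: int = 10
    n_backcross_lineages_per_side: int = 5
    max_backcross_generations: int = 9
    n_replicate_simulations: int = 10

    def __post_init__(self) -> None:
        for name in ("n_f1", "n_backcross_lineages_per_side",
                     "max_backcross_generations", "n_replicate_simulations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_backcross_lineages_per_side > self.n_f1:
            raise ValueError("more lineages per side than F1 founders")


@dataclass
class SimulatedPedigree:
    """Simulated genotypes with true pedigree classes and ancestry fractions.

    ``table`` columns: individual_id, pedigree_class (pure_A, pure_B, F1,
    F2_A..F{g}_A, F2_B..), direction (toward_A / toward_B / none), lineage,
    true_donor_fraction (expected ancestry from the non-recipient taxon),
    realized_donor_fraction (tracked fraction of donor-origin alleles),
    replicate_id.

    ``haplotypes``/``origins`` optionally carry the phased allele arrays
    (n, 2, L) and their taxon of origin (0 = A, 1 = B), which makes serial
    backcrossing and realized-ancestry tracking exact.
    """

    genotypes: np.ndarray
    table: pd.DataFrame
    haplotypes: np.ndarray | None = None
    origins: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.genotypes.shape[0] != len(self.table):
            raise ValueError("genotype rows and table rows differ")

    def to_matrix(self, locus_prefix: str = "L") -> GenotypeMatrix:
        ids = list(self.table["individual_id"])
        loci = [f"{locus_prefix}{j:05d}" for j in range(self.genotypes.shape[1])]
        return GenotypeMatrix(self.genotypes, ids, loci,
                              metadata=self.table.set_index("individual_id"))

    @staticmethod
    def concat(parts: list["SimulatedPedigree"]) -> "SimulatedPedigree":
        geno = np.vstack([p.genotypes for p in parts])
        table = pd.concat([p.table for p in parts], ignore_index=True)
        return SimulatedPedigree(geno, table)  # phased arrays not carried over


# ---------------------------------------------------------------------------
# Parental vetting
# ---------------------------------------------------------------------------


def interspecific_assignment(Q: np.ndarray, cluster_taxa: list[str]
                             ) -> pd.DataFrame:
    """Two-taxon assignment summary from a (possibly K>2) Q matrix.

    ``cluster_taxa`` labels each Q column with its taxon; same-taxon
    columns are summed (e.g., the two island Mallard clusters at K=3).
    Returns columns ``q_A``, ``q_B``, ``majority``, ``interspecific``
    (assignment to the non-majority taxon).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[1] != len(cluster_taxa):
        raise ValueError("cluster_taxa length must equal K")
    q_a = Q[:, [i for i, t in enumerate(cluster_taxa) if t == TAXON_A]].sum(axis=1)
    q_b = Q[:, [i for i, t in enumerate(cluster_taxa) if t == TAXON_B]].sum(axis=1)
    majority = np.where(q_a >= q_b, TAXON_A, TAXON_B)
    inter = np.minimum(q_a, q_b)
    return pd.DataFrame({"q_A": q_a, "q_B": q_b, "majority": majority,
                         "interspecific": inter})


def vet_parentals(ancestry: AncestryMatrix, cluster_taxa: list[str],
                  threshold: float = 0.05) -> dict[str, list[str]]:
    """Individuals with interspecific assignment <= threshold, by taxon.

    These are the putatively pure individuals whose genotypes define the
    parental gene pools. Raises if either taxon ends up empty (no gene
    pool can be built).
    """
    summary = interspecific_assignment(ancestry.Q, cluster_taxa)
    summary.index = ancestry.individual_ids
    pure = summary[summary["interspecific"] <= threshold]
    out = {t: list(pure.index[pure["majority"] == t]) for t in (TAXON_A, TAXON_B)}
    for t, ids in out.items():
        if not ids:
            raise ValueError(f"no putatively pure individuals for taxon {t}")
    return out


def pool_from_matrix(matrix: GenotypeMatrix, individual_ids: list[str],
                     pool_id: str) -> AlleleFrequencyPool:
    """Allele-frequency pool from the genotypes of vetted pure individuals."""
    idx = [matrix.individual_ids.index(i) for i in individual_ids]
    sub = matrix.take_individuals(idx)
    return AlleleFrequencyPool(pool_id, np.nan_to_num(sub.allele_frequencies(),
                                                      nan=0.0))


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def _gametes_from_pool(freqs: np.ndarray, n: int, rng: np.random.Generator
                       ) -> np.ndarray:
    return (rng.random((n, len(freqs))) < freqs).astype(np.int8)


def make_f1(pool_a: AlleleFrequencyPool, pool_b: AlleleFrequencyPool,
            n: int, seed: int = 0, replicate_id: int = 0) -> SimulatedPedigree:
    """Simulate F1 hybrids: one gamete from each parental gene pool.

    Every F1 carries exactly one A-origin and one B-origin haplotype, so
    the realized donor fraction is 0.5 by construction.
    """
    if pool_a.n_loci != pool_b.n_loci:
        raise ValueError("pools are defined over different loci")
    rng = substream(seed, "f1")
    L = pool_a.n_loci
    hap = np.empty((n, 2, L), dtype=np.int8)
    hap[:, 0, :] = _gametes_from_pool(pool_a.freqs, n, rng)
    hap[:, 1, :] = _gametes_from_pool(pool_b.freqs, n, rng)
    origins = np.zeros((n, 2, L), dtype=np.int8)
    origins[:, 1, :] = 1
    table = pd.DataFrame({
        "individual_id": [f"sim{replicate_id}_F1_{i:02d}" for i in range(n)],
        "pedigree_class": "F1",
        "direction": "none",
        "lineage": np.arange(n),
        "true_donor_fraction": 0.5,
        "realized_donor_fraction": 0.5,
        "replicate_id": replicate_id,
    })
    return SimulatedPedigree(hap.sum(axis=1, dtype=np.int8), table,
                             haplotypes=hap, origins=origins)


def backcross(parents: SimulatedPedigree, recipient_pool: AlleleFrequencyPool,
              generations: int, lineages_per_side: int, seed: int = 0,
              replicate_id: int = 0) -> SimulatedPedigree:
    """Serial backcrosses of F1 lineages into one recipient gene pool.

    Each of the first ``lineages_per_side`` parent individuals founds a
    lineage; at every generation the offspring receives one Mendelian
    gamete from the previous-generation individual (loci unlinked) and one
    gamete drawn from the recipient pool's allele frequencies
    (infinite-pool approximation). After g backcross events the offspring
    (class F{g+1}) carries expected donor ancestry 0.5^(g+1); the realized
    fraction of donor-origin alleles is tracked per individual.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if lineages_per_side > parents.genotypes.shape[0]:
        raise ValueError("not enough parents for the requested lineages")
    if parents.haplotypes is None or parents.origins is None:
        raise ValueError("parents must carry phased haplotypes/origins")
    recipient_code = 0 if recipient_pool.pool_id == TAXON_A else 1
    donor_code = 1 - recipient_code
    direction = f"toward_{recipient_pool.pool_id}"
    rng = substream(seed, f"backcross:{recipient_pool.pool_id}")
    L = parents.haplotypes.shape[2]
    out_geno, rows = [], []
    for lin in range(lineages_per_side):
        hap = parents.haplotypes[lin].copy()
        orig = parents.origins[lin].copy()
        donor_frac = float(parents.table["true_donor_fraction"].iloc[lin])
        for g in range(1, generations + 1):
            pick = rng.integers(0, 2, size=L)
            gamete = hap[pick, np.arange(L)]
            gamete_orig = orig[pick, np.arange(L)]
            pool_gamete = _gametes_from_pool(recipient_pool.freqs, 1, rng)[0]
            hap = np.stack([gamete, pool_gamete]).astype(np.int8)
            orig = np.stack([gamete_orig,
                             np.full(L, recipient_code, dtype=np.int8)])
            donor_frac = donor_frac / 2.0
            realized = float((orig == donor_code).mean())
            klass = f"F{g + 1}_{recipient_pool.pool_id}"
            rows.append({
                "individual_id": f"sim{replicate_id}_{klass}_lin{lin}",
                "pedigree_class": klass,
                "direction": direction,
                "lineage": lin,
                "true_donor_fraction": donor_frac,
                "realized_donor_fraction": realized,
                "replicate_id": replicate_id,
            })
            out_geno.append(hap.sum(axis=0, dtype=np.int8))
    return SimulatedPedigree(np.array(out_geno, dtype=np.int8),
                             pd.DataFrame(rows))


def simulate_replicate(pool_a: AlleleFrequencyPool, pool_b: AlleleFrequencyPool,
                       spec: PedigreeSpec, n_ref: int = 50, seed: int = 0,
                       replicate_id: int = 0) -> SimulatedPedigree:
    """One full simulation: parental references, F1s, both backcross chains."""
    from duckmix.synthio import sample_genotypes

    refs = []
    for pool, klass in ((pool_a, "pure_A"), (pool_b, "pure_B")):
        m = sample_genotypes(pool, n_ref, seed=seed * 1000 + replicate_id,
                             id_prefix=f"sim{replicate_id}_{klass}")
        refs.append(SimulatedPedigree(
            m.genotypes,
            pd.DataFrame({
                "individual_id": m.individual_ids,
                "pedigree_class": klass,
                "direction": "none",
                "lineage": -1,
                "true_donor_fraction": 0.0,
                "realized_donor_fraction": 0.0,
                "replicate_id": replicate_id,
            })))
    f1 = make_f1(pool_a, pool_b, spec.n_f1,
                 seed=seed * 1000 + replicate_id, replicate_id=replicate_id)
    bx = [backcross(f1, pool, spec.max_backcross_generations,
                    spec.n_backcross_lineages_per_side,
                    seed=seed * 1000 + replicate_id, replicate_id=replicate_id)
          for pool in (pool_a, pool_b)]
    return SimulatedPedigree.concat(refs + [f1] + bx)


# ---------------------------------------------------------------------------
# Fitting simulated cohorts and building bins
# ---------------------------------------------------------------------------


def _fit_replicate(sim: SimulatedPedigree, K: int, runs: int, seed: int,
                   supervised: bool = False, tol: float = 1e-4,
                   max_iter: int = 2000) -> pd.DataFrame:
    """Fit K-cluster admixture ``runs`` times, align, and summarize.

    Cluster-to-taxon mapping comes from the parental reference rows: each
    cluster belongs to the taxon whose references load on it more heavily;
    at K=3 the two same-taxon clusters are merged on that basis. With
    ``supervised`` the parental reference rows are pinned to their
    clusters, which anchors the two-taxon axis and sharpens near-boundary
    estimates. Returns the simulation table with q_A/q_B/interspecific
    columns appended.
    """
    matrix = sim.to_matrix()
    labels = None
    if supervised:
        labels = {}
        for ind, klass in zip(sim.table["individual_id"],
                              sim.table["pedigree_class"]):
            if klass == "pure_A":
                labels[ind] = 0
            elif klass == "pure_B":
                labels[ind] = 1
    fits = [fit_admixture(matrix, K, seed=seed + r, supervised_labels=labels,
                          tol=tol, max_iter=max_iter) for r in range(runs)]
    consensus = align_replicates(fits).consensus_Q

    is_a = (sim.table["pedigree_class"] == "pure_A").to_numpy()
    is_b = (sim.table["pedigree_class"] == "pure_B").to_numpy()
    cluster_taxa = [TAXON_A if consensus[is_a, k].mean() >= consensus[is_b, k].mean()
                    else TAXON_B for k in range(K)]
    if len(set(cluster_taxa)) < 2:
        raise RuntimeError("admixture fit did not separate the parental taxa")
    summary = interspecific_assignment(consensus, cluster_taxa)
    return pd.concat([sim.table.reset_index(drop=True), summary], axis=1)


@dataclass
class HybridClassBins:
    """Per-class interspecific-assignment bins from replicate simulations.

    ``table`` columns: pedigree_class, direction, mean, lower, upper, n.
    Lower/upper are the min/max over all aligned replicate fits.
    """

    table: pd.DataFrame
    K: int
    n_replicates: int

    def for_direction(self, taxon: str) -> pd.DataFrame:
        keep = self.table["direction"].isin([f"toward_{taxon}", "none"])
        own_pure = self.table["pedigree_class"] == f"pure_{taxon}"
        other_pure = self.table["pedigree_class"] == (
            f"pure_{TAXON_B if taxon == TAXON_A else TAXON_A}")
        return self.table[(keep & ~other_pure) | own_pure]

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path, K: int = 2, n_replicates: int = 0) -> "HybridClassBins":
        return cls(pd.read_csv(path, sep="\t"), K, n_replicates)


def _generation_rank(klass: str) -> int:
    if klass == "F1":
        return 1
    if klass.startswith("pure"):
        return 999
    return int(klass.split("_")[0][1:])


def _check_monotone(table: pd.DataFrame, plateau_floor: float = 0.06) -> None:
    """Require strictly decreasing bin means by generation, above a floor.

    Assignment to the recipient cluster plateaus near 100% after a few
    backcross generations, so interspecific means in the plateau region sit
    at the estimator's boundary-noise floor and can tie or jitter. Strict
    ordering is therefore enforced while means exceed ``plateau_floor``
    (default 0.06, the scale of the pure-vetting threshold); once a class
    mean drops below the floor, all deeper classes — and the pure classes —
    must stay below it. Real inversions (e.g., an F2 mean above F1) raise
    :class:`BinMonotonicityError`.
    """
    for taxon in (TAXON_A, TAXON_B):
        classes = ["F1"] + [c for c in table["pedigree_class"]
                            if c.endswith(f"_{taxon}") and c.startswith("F")]
        classes = sorted(set(classes), key=_generation_rank)
        means = [float(table.loc[table["pedigree_class"] == c, "mean"].iloc[0])
                 for c in classes]
        for i in range(len(means) - 1):
            if means[i] >= plateau_floor and means[i] <= means[i + 1]:
                raise BinMonotonicityError(
                    f"bin means not strictly decreasing toward {taxon}: "
                    f"{dict(zip(classes, np.round(means, 4)))}")
            if means[i] < plateau_floor and means[i + 1] >= plateau_floor:
                raise BinMonotonicityError(
                    f"bin mean re-emerges above the plateau floor toward "
                    f"{taxon}: {dict(zip(classes, np.round(means, 4)))}")
        pure = table.loc[table["pedigree_class"] == f"pure_{taxon}", "mean"]
        if len(pure) and float(pure.iloc[0]) >= plateau_floor:
            raise BinMonotonicityError(
                f"pure_{taxon} bin mean not inside the plateau region")


def build_generation_bins(pool_a: AlleleFrequencyPool,
                          pool_b: AlleleFrequencyPool,
                          spec: PedigreeSpec | None = None,
                          K: int = 2, runs_per_sim: int = 25,
                          n_ref: int = 50, seed: int = 0,
                          supervised: bool = False
                          ) -> tuple[HybridClassBins, pd.DataFrame]:
    """Build per-generation assignment bins from replicate simulations.

    Runs ``spec.n_replicate_simulations`` independent pedigree simulations;
    each is fitted ``runs_per_sim`` times with the K-cluster admixture
    estimator and replicate-aligned. Per pedigree class, the bin is the
    mean and min/max of interspecific assignment over all simulated
    individuals and simulations. Bin means must decrease strictly with
    backcross generation (hard error otherwise). Returns the bins plus the
    full per-individual assignment table.
    """
    spec = spec or PedigreeSpec()
    frames = []
    for rep in range(spec.n_replicate_simulations):
        sim = simulate_replicate(pool_a, pool_b, spec, n_ref=n_ref,
                                 seed=seed, replicate_id=rep)
        frames.append(_fit_replicate(sim, K, runs_per_sim,
                                     seed=seed * 10000 + rep * 100,
                                     supervised=supervised))
    allfits = pd.concat(frames, ignore_index=True)
    agg = (allfits.groupby(["pedigree_class", "direction"])["interspecific"]
           .agg(mean="mean", lower="min", upper="max", n="size").reset_index())
    bins = HybridClassBins(agg, K=K, n_replicates=spec.n_replicate_simulations)
    _check_monotone(agg)
    return bins, allfits


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify(Q: np.ndarray, cluster_taxa: list[str], bins: HybridClassBins,
             individual_ids: list[str] | None = None,
             overlap: str = "nearest") -> pd.DataFrame:
    """Assign individuals to hybrid generations or the hybrid swarm.

    For each individual the two-taxon interspecific assignment is compared
    with the bins of the classes compatible with its majority taxon
    (its own pure class, backcrosses toward it, and F1). If exactly one
    bin's [lower, upper] contains the value, that class is assigned; under
    ``overlap='nearest'`` several containing bins resolve to the nearest
    mean (ties to the earlier generation), under ``overlap='strict'`` they
    resolve to the hybrid swarm. A value outside every bin is a hybrid
    swarm backcross whose direction is the majority taxon.
    """
    if overlap not in ("nearest", "strict"):
        raise ValueError("overlap must be 'nearest' or 'strict'")
    summary = interspecific_assignment(Q, cluster_taxa)
    if individual_ids is None:
        individual_ids = [f"ind_{i}" for i in range(len(summary))]
    records = []
    for i, row in summary.iterrows():
        taxon = row["majority"]
        value = row["interspecific"]
        cands = bins.for_direction(taxon)
        inside = cands[(cands["lower"] <= value) & (value <= cands["upper"])]
        if len(inside) == 1 or (len(inside) > 1 and overlap == "nearest"):
            inside = inside.assign(dist=(inside["mean"] - value).abs(),
                                   rank=inside["pedigree_class"].map(_generation_rank))
            best = inside.sort_values(["dist", "rank"]).iloc[0]
            klass = best["pedigree_class"]
            if klass == "F1" or klass.startswith("pure"):
                direction = "none"
            else:
                direction = best["direction"]
        else:  # empty, or overlap under strict mode
            klass = "hybrid_swarm"
            if row["q_A"] == row["q_B"]:
                direction = "none"
            else:
                direction = f"toward_{taxon}"
        records.append({"individual_id": individual_ids[i],
                        "assigned_class": klass, "direction": direction,
                        "interspecific": float(value)})
    return pd.DataFrame(records)


def summarize_classes(records: pd.DataFrame,
                      groups: pd.Series | None = None) -> dict:
    """Counts, percentages, and swarm directionality from classifications.

    ``groups`` optionally maps individual_id to a grouping label (island
    or site); per-group tables are then included. Percentages are kept at
    full precision alongside a nearest-integer display column.
    """
    if len(records) == 0:
        return {"total": 0, "by_class": pd.DataFrame(),
                "swarm_direction": pd.DataFrame(), "by_group": pd.DataFrame()}
    total = len(records)
    counts = records["assigned_class"].value_counts()
    by_class = pd.DataFrame({
        "count": counts,
        "percent": 100.0 * counts / total,
    })
    by_class["percent_display"] = by_class["percent"].round(0).astype(int)
    if int(by_class["count"].sum()) != total:
        raise AssertionError("class counts do not sum to the record total")

    swarm = records[records["assigned_class"] == "hybrid_swarm"]
    if len(swarm):
        sc = swarm["direction"].value_counts()
        swarm_dir = pd.DataFrame({
            "count": sc,
            "percent": 100.0 * sc / len(swarm),
        })
        swarm_dir["percent_display"] = swarm_dir["percent"].round(0).astype(int)
    else:
        swarm_dir = pd.DataFrame(columns=["count", "percent", "percent_display"])

    by_group = pd.DataFrame()
    if groups is not None:
        g = records.assign(group=records["individual_id"].map(groups))
        by_group = (g.groupby(["group", "assigned_class"]).size()
                    .rename("count").reset_index())
        gt = by_group.groupby("group")["count"].transform("sum")
        by_group["percent"] = 100.0 * by_group["count"] / gt
    return {"total": total, "by_class": by_class,
            "swarm_direction": swarm_dir, "by_group": by_group}


# ---------------------------------------------------------------------------
# The backcross-plateau experiment
# ---------------------------------------------------------------------------


def backcross_plateau_experiment(seed: int = 1, n_loci: int = 1000,
                                 fst: float = 0.11, n_ref: int = 50,
                                 spec: PedigreeSpec | None = None,
                                 K: int = 2, runs_per_sim: int = 3,
                                 plateau_from_generation: int = 6,
                                 supervised: bool = True,
                                 tol: float = 1e-5,
                                 max_iter: int = 4000) -> dict:
    """Recipient-cluster assignment of deep backcrosses, full design.

    Simulates two parental pools at the target differentiation, runs the
    replicate pedigree design, fits the K=2 admixture estimator with the
    parental reference genotypes included (pinned to their clusters by
    default, which anchors the two-taxon axis), aligns replicate fits, and
    averages the recipient-cluster assignment (1 - interspecific) over all
    simulated individuals at >= ``plateau_from_generation`` backcross
    events (i.e., classes F{g+1} and deeper).

    Returns per-backcross-generation means and the plateau mean in percent.
    """
    spec = spec or PedigreeSpec()
    pools = simulate_parental_pools(PoolSpec(n_loci=n_loci, fst_target=fst,
                                             seed=seed))
    frames = []
    for rep in range(spec.n_replicate_simulations):
        sim = simulate_replicate(pools[0], pools[1], spec, n_ref=n_ref,
                                 seed=seed, replicate_id=rep)
        frames.append(_fit_replicate(sim, K, runs_per_sim,
                                     seed=seed * 10000 + rep * 100,
                                     supervised=supervised, tol=tol,
                                     max_iter=max_iter))
    allfits = pd.concat(frames, ignore_index=True)
    bx = allfits[allfits["pedigree_class"].str.match(r"F\d+_[AB]")].copy()
    bx["backcross_generation"] = (
        bx["pedigree_class"].str.extract(r"F(\d+)_")[0].astype(int) - 1)
    per_gen = (bx.groupby("backcross_generation")["interspecific"]
               .mean().rename("mean_interspecific").to_frame())
    per_gen["mean_recipient_pct"] = 100.0 * (1.0 - per_gen["mean_interspecific"])
    plateau = bx[bx["backcross_generation"] >= plateau_from_generation]
    plateau_pct = 100.0 * (1.0 - plateau["interspecific"].mean())
    return {
        "per_generation": per_gen,
        "plateau_mean_recipient_pct": float(plateau_pct),
        "n_plateau_individuals": int(len(plateau)),
        "n_total_simulated": int(len(allfits)),
    }
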