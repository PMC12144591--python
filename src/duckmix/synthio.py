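"""Synthetic inputs with the statistical structure the pipeline assumes.

The study system is a pair of hybridizing duck taxa: a native gene pool
(Gray Duck-like, "A") and an introduced one (Mallard-like, "B") separated
by modest autosomal differentiation (Phi-ST ~ 0.11). This module generates:

* two parental allele-frequency pools at a target fixation index via the
  Balding-Nichols construction,
* diploid genotype matrices sampled from a pool (with uniform missingness),
* mtDNA control-region-like sequence sets around haplogroup references
  (Gray Duck groups I/II, Mallard Old World A / New World B),
* per-individual sequencing-depth profiles carrying the avian ZW sex
  signature (males ZZ: Z ~ autosomal, W ~ 0; females ZW: both ~ half),
* genotype-environment datasets where a subset of adaptive loci track an
  environmental gradient through a logistic link, plus a matching
  environmental grid for landscape transformation and offset mapping.

All generators are deterministic given their seed; one top-level seed can
drive all of them through named substreams (:func:`duckmix._rng.substream`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from duckmix._rng import substream
from duckmix.genofilter import MISSING, GenotypeMatrix
from duckmix.popgen import SequenceSet

# ---------------------------------------------------------------------------
# Parental pools (Balding-Nichols)
# ---------------------------------------------------------------------------


@dataclass
class PoolSpec:
    """Specification of a pair of drifted parental allele-frequency pools."""

    n_loci: int
    fst_target: float
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0 <= self.ancestral_low < self.ancestral_high <= 1:
            raise ValueError("invalid ancestral frequency bounds")


@dataclass
class AlleleFrequencyPool:
    """Per-locus alternate-allele frequencies of one parental gene pool."""

    pool_id: str
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1:
            raise ValueError("freqs must be 1-D")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.freqs)


def simulate_parental_pools(spec: PoolSpec) -> tuple[AlleleFrequencyPool,
                                                     AlleleFrequencyPool]:
    """Draw two parental pools around shared ancestral frequencies.

    Ancestral frequencies are uniform on the spec's bounds. Each pool's
    frequency at a locus is an independent Beta draw with mean equal to the
    ancestral frequency and drift parameter ``(1 - F) / F`` (the
    Balding-Nichols model), so a pair of pools realizes Hudson-type FST
    close to ``fst_target``. ``fst_target = 0`` is the zero-drift limit:
    both pools equal the ancestral draw exactly.
    """
    rng = substream(spec.seed, "pools")
    anc = rng.uniform(spec.ancestral_low, spec.ancestral_high, spec.n_loci)
    f = spec.fst_target
    if f == 0:
        return (AlleleFrequencyPool("A", anc.copy()),
                AlleleFrequencyPool("B", anc.copy()))
    scale = (1.0 - f) / f
    p_a = rng.beta(anc * scale, (1.0 - anc) * scale)
    p_b = rng.beta(anc * scale, (1.0 - anc) * scale)
    return AlleleFrequencyPool("A", p_a), AlleleFrequencyPool("B", p_b)


def sample_genotypes(pool: AlleleFrequencyPool, n_individuals: int,
                     missing_rate: float = 0.0, seed: int = 0,
                     id_prefix: str | None = None,
                     site_ids: list[str] | None = None) -> GenotypeMatrix:
    """Sample diploid genotypes from a pool's allele frequencies.

    Each genotype is the sum of two independent Bernoulli allele draws at
    the locus frequency (Hardy-Weinberg within the pool); missing entries
    are flagged uniformly at random at ``missing_rate``.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = substream(seed, f"genotypes:{pool.pool_id}")
    geno = rng.binomial(2, pool.freqs, size=(n_individuals, pool.n_loci))
    geno = geno.astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING
    prefix = id_prefix or pool.pool_id
    ids = [f"{prefix}_{i:04d}" for i in range(n_individuals)]
    locus_ids = [f"L{j:05d}" for j in range(pool.n_loci)]
    meta = None
    if site_ids is not None:
        if len(site_ids) != n_individuals:
            raise ValueError("site_ids length mismatch")
        meta = pd.DataFrame({"site_id": site_ids}, index=ids)
    return GenotypeMatrix(geno, ids, locus_ids, metadata=meta)


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------

HAPLOGROUPS = ("grayduck_I", "grayduck_II", "mallard_OW_A", "mallard_NW_B")


def make_haplogroup_references(seed: int = 0, length: int = 655,
                               min_separation: int = 20,
                               groups: tuple[str, ...] = HAPLOGROUPS
                               ) -> SequenceSet:
    """Generate well-separated synthetic haplogroup reference sequences.

    A random base sequence is mutated at ``min_separation`` distinct
    positions per group (disjoint position blocks), so inter-reference
    Hamming distances are at least ``2 * min_separation``... in fact exactly
    ``2 * min_separation`` between any pair, which keeps nearest-reference
    assignment unambiguous for simulated sequences a few steps from their
    own reference.
    """
    rng = substream(seed, "mtdna-refs")
    bases = np.array(list("ACGT"))
    if len(groups) * min_separation > length:
        raise ValueError("sequence too short for requested separation")
    root = rng.choice(bases, size=length)
    positions = rng.choice(length, size=len(groups) * min_separation, replace=False)
    seqs = []
    for gi, g in enumerate(groups):
        s = root.copy()
        block = positions[gi * min_separation:(gi + 1) * min_separation]
        for p in block:
            choices = [b for b in "ACGT" if b != s[p]]
            s[p] = rng.choice(choices)
        seqs.append("".join(s))
    return SequenceSet(list(groups), seqs, list(groups))


def simulate_mtdna(references: SequenceSet, counts: dict[str, int],
                   mutation_steps: int = 3, seed: int = 0) -> SequenceSet:
    """Generate sequences as mutated copies of haplogroup references.

    Each simulated sequence copies its group's reference and substitutes
    exactly ``mutation_steps`` positions, drawn without replacement, to a
    different base (transition/transversion bias is not modelled).
    """
    if mutation_steps > references.length:
        raise ValueError("mutation_steps exceeds sequence length")
    rng = substream(seed, "mtdna")
    ref_by_group = dict(zip(references.groups or references.ids,
                            references.sequences))
    ids, seqs, groups = [], [], []
    for group, n in counts.items():
        if group not in ref_by_group:
            raise KeyError(f"no reference for group {group!r}")
        ref = ref_by_group[group]
        for i in range(n):
            s = list(ref)
            if mutation_steps > 0:
                pos = rng.choice(len(s), size=mutation_steps, replace=False)
                for p in pos:
                    choices = [b for b in "ACGT" if b != s[p]]
                    s[p] = choices[rng.integers(len(choices))]
            ids.append(f"{group}_{i:03d}")
            seqs.append("".join(s))
            groups.append(group)
    return SequenceSet(ids, seqs, groups)


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------


def simulate_depth_profiles(sexes: list[str], base_depth: float = 100.0,
                            noise_cv: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Per-individual mean depths for autosomal, Z-, and W-linked loci.

    Males (ZZ) have Z depth ~ autosomal and W depth ~ 0; females (ZW) have
    both sex-linked depths at ~ half autosomal. Multiplicative noise at the
    stated coefficient of variation is dominated by a per-individual
    library-size factor shared across locus classes (as in real sequencing
    libraries), plus a smaller independent per-class jitter (cv/4); shared
    noise cancels in the depth ratios the sex caller uses, so ratios stay
    tightly clustered around their sex-specific targets. Depths are
    truncated at 0.
    """
    bad = set(sexes) - {"male", "female"}
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    rng = substream(seed, "depth")
    rows = []
    for i, sex in enumerate(sexes):
        if sex == "male":
            targets = (base_depth, base_depth, 0.0)
        else:
            targets = (base_depth, base_depth / 2, base_depth / 2)
        shared = 1.0 + noise_cv * rng.standard_normal()
        noisy = [max(t * shared * (1.0 + 0.25 * noise_cv
                                   * rng.standard_normal()), 0.0)
                 if t > 0 else 0.0 for t in targets]
        rows.append({"individual_id": f"ind_{i:04d}", "sex_true": sex,
                     "mean_depth_autosomal": noisy[0],
                     "mean_depth_z": noisy[1],
                     "mean_depth_w": noisy[2]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genotype-environment datasets
# ---------------------------------------------------------------------------


@dataclass
class EnvScenario:
    """Parameters of a synthetic genotype-environment landscape.

    ``effect_slope`` is the change in the logit of allele frequency per
    unit of (standardized) environment for adaptive loci; ``noise_sd`` is
    additive logit-scale noise applied per site and locus.
    """

    n_sites: int = 20
    n_variables: int = 8
    n_loci: int = 500
    n_adaptive_loci: int = 50
    n_individuals_per_site: int = 10
    effect_slope: float = 2.0
    noise_sd: float = 0.2
    grid_dims: tuple[int, int] = (10, 10)

    def __post_init__(self) -> None:
        if self.n_adaptive_loci > self.n_loci:
            raise ValueError("n_adaptive_loci exceeds total loci")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_sites < 2 or self.n_variables < 1:
            raise ValueError("need >= 2 sites and >= 1 variable")


def _env_variables(n: int) -> list[str]:
    return [f"env{i + 1}" for i in range(n)]


def simulate_env_dataset(scenario: EnvScenario, seed: int = 0
                         ) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate genotypes whose site frequencies track an environment.

    Sites are scattered over a unit square; ``env1`` is a smooth east-west
    gradient (plus noise) and the remaining variables are independent
    spatial noise, standardized. The first ``n_adaptive_loci`` loci have
    site allele frequencies ``logistic(a_l + slope * env1 + eps)``; the
    rest get site frequencies ``logistic(a_l + eps)`` independent of the
    environment. Returns (genotypes with site labels, per-site environment
    table, environment grid covering the variable ranges).
    """
    rng = substream(seed, "env")
    sc = scenario
    variables = _env_variables(sc.n_variables)

    lon = rng.uniform(0, 1, sc.n_sites)
    lat = rng.uniform(0, 1, sc.n_sites)
    env = pd.DataFrame(index=[f"site_{i:02d}" for i in range(sc.n_sites)])
    env.index.name = "site_id"
    env["lon"] = lon
    env["lat"] = lat
    raw = np.column_stack(
        [lon + 0.1 * rng.standard_normal(sc.n_sites)]
        + [rng.standard_normal(sc.n_sites) for _ in range(sc.n_variables - 1)]
    )
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    for k, v in enumerate(variables):
        env[v] = raw[:, k]

    base_logit = rng.normal(0.0, 0.8, sc.n_loci)
    site_freqs = np.empty((sc.n_sites, sc.n_loci))
    for l in range(sc.n_loci):
        eps = rng.normal(0.0, sc.noise_sd, sc.n_sites)
        logit = base_logit[l] + eps
        if l < sc.n_adaptive_loci:
            logit = logit + sc.effect_slope * env["env1"].to_numpy()
        site_freqs[:, l] = 1.0 / (1.0 + np.exp(-logit))

    n_total = sc.n_sites * sc.n_individuals_per_site
    geno = np.empty((n_total, sc.n_loci), dtype=np.int8)
    ids, sites = [], []
    for s in range(sc.n_sites):
        rows = slice(s * sc.n_individuals_per_site, (s + 1) * sc.n_individuals_per_site)
        geno[rows] = rng.binomial(2, site_freqs[s],
                                  size=(sc.n_individuals_per_site, sc.n_loci))
        for i in range(sc.n_individuals_per_site):
            ids.append(f"site{s:02d}_ind{i:02d}")
            sites.append(env.index[s])
    meta = pd.DataFrame({"site_id": sites}, index=ids)
    matrix = GenotypeMatrix(geno, ids, [f"L{j:05d}" for j in range(sc.n_loci)],
                            metadata=meta)

    rows_, cols_ = sc.grid_dims
    gl = np.linspace(0, 1, cols_)
    gt = np.linspace(0, 1, rows_)
    glon, glat = np.meshgrid(gl, gt)
    grid = pd.DataFrame({
        "cell_id": [f"cell_{r}_{c}" for r in range(rows_) for c in range(cols_)],
        "lon": glon.ravel(),
        "lat": glat.ravel(),
    })
    for k, v in enumerate(variables):
        lo, hi = env[v].min(), env[v].max()
        if k == 0:
            grid[v] = lo + (hi - lo) * grid["lon"]
        else:
            smooth = np.cos(2 * np.pi * (glat + (k / sc.n_variables) * glon))
            vals = smooth.ravel()
            vals = (vals - vals.min()) / max(vals.max() - vals.min(), 1e-12)
            grid[v] = lo + (hi - lo) * vals
    return matrix, env.reset_index(), grid


def write_env_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
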