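"""Genotype container, I/O, the SNP filtering cascade, and depth-ratio sexing.

Genotypes are diploid bi-allelic alternate-allele counts (0/1/2) with a
distinct missing state. Every locus carries a chromosome class (autosomal,
Z, or W) because downstream statistics are computed per marker partition
and because sex is called from depth ratios between those classes.

The filtering cascade mirrors the standard ddRAD workflow: position
presence (fraction of alleles called), minor-allele frequency, per-SNP
missingness, and window-based LD pruning. Each filter returns the surviving
matrix plus a per-locus removal report so that counts always reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING = -1
CHROM_CLASSES = ("autosomal", "Z", "W")


@dataclass
class GenotypeMatrix:
    """Diploid bi-allelic genotypes for a set of individuals.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_loci)`` int8 array of alternate-allele counts,
        with ``-1`` marking a missing genotype.
    individual_ids, locus_ids
        Row and column labels.
    chromosome_class
        Per-locus class, one of ``autosomal``, ``Z``, ``W``.
    metadata
        Optional per-individual table (``site_id``, ``island``, ``group``),
        indexed by individual id.
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    chromosome_class: np.ndarray | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n, m = self.genotypes.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match genotypes")
        if len(self.locus_ids) != m:
            raise ValueError("locus_ids length does not match genotypes")
        if self.chromosome_class is None:
            self.chromosome_class = np.full(m, "autosomal", dtype=object)
        self.chromosome_class = np.asarray(self.chromosome_class, dtype=object)
        if self.chromosome_class.shape != (m,):
            raise ValueError("chromosome_class length does not match loci")
        bad = set(self.chromosome_class) - set(CHROM_CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome class(es): {sorted(bad)}")
        vals = self.genotypes
        if not np.isin(vals, (MISSING, 0, 1, 2)).all():
            raise ValueError("genotypes must be in {0,1,2} or -1 (missing)")
        if self.metadata is not None and len(self.metadata) != n:
            raise ValueError("metadata rows do not match individuals")

    # -- basic properties ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.genotypes != MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus alternate-allele frequency over non-missing alleles.

        Loci with no observed genotypes yield NaN.
        """
        obs = self.observed()
        alt = np.where(obs, self.genotypes, 0).sum(axis=0).astype(float)
        tot = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan)

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing genotype calls."""
        return (~self.observed()).mean(axis=0)

    # -- subsetting ---------------------------------------------------------
    def take_loci(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.arange(self.n_loci)[mask_or_idx]
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            chromosome_class=self.chromosome_class[idx],
        )

    def take_individuals(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.arange(self.n_individuals)[mask_or_idx]
        meta = self.metadata.iloc[idx] if self.metadata is not None else None
        return replace(
            self,
            genotypes=self.genotypes[idx, :],
            individual_ids=[self.individual_ids[i] for i in idx],
            metadata=meta,
        )

    def subset_class(self, chrom_class: str) -> "GenotypeMatrix":
        return self.take_loci(self.chromosome_class == chrom_class)


@dataclass
class FilterParams:
    """Thresholds for the SNP filtering cascade (ddRAD defaults)."""

    min_allele_presence: float = 0.8
    maf_min: float = 0.002
    max_missing_per_snp: float = 0.2
    ld_window: int = 2
    ld_step: int = 1
    ld_r2_max: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_allele_presence <= 1:
            raise ValueError("min_allele_presence must be in (0, 1]")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.max_missing_per_snp <= 1:
            raise ValueError("max_missing_per_snp must be in [0, 1]")
        if self.ld_window < 2 or self.ld_step < 1:
            raise ValueError("ld_window >= 2 and ld_step >= 1 required")
        if not 0 <= self.ld_r2_max <= 1:
            raise ValueError("ld_r2_max must be in [0, 1]")


def _removal_report(matrix: GenotypeMatrix, removed_mask: np.ndarray, reason: str,
                    value: np.ndarray) -> pd.DataFrame:
    idx = np.flatnonzero(removed_mask)
    return pd.DataFrame(
        {
            "locus_id": [matrix.locus_ids[i] for i in idx],
            "reason": reason,
            "value": value[idx],
        }
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_position_presence(matrix: GenotypeMatrix, threshold: float = 0.8
                             ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci whose fraction of called alleles falls below ``threshold``.

    A missing diploid genotype contributes two uncalled alleles, so the
    presence fraction equals one minus the missing-genotype fraction.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    presence = 1.0 - matrix.missing_fraction()
    removed = presence < threshold
    report = _removal_report(matrix, removed, "position_presence", presence)
    return matrix.take_loci(~removed), report


def filter_maf(matrix: GenotypeMatrix, maf_min: float = 0.002
               ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci with minor-allele frequency below ``maf_min``.

    Frequencies use non-missing alleles only. Monomorphic loci (MAF 0) are
    always removed for any positive threshold; the boundary is exclusive for
    retention (``maf >= maf_min`` survives), mirroring ``--maf`` semantics.
    """
    p = matrix.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    removed = ~(maf >= maf_min) | (maf <= 0)  # NaN (all-missing) also removed
    report = _removal_report(matrix, removed, "maf", maf)
    return matrix.take_loci(~removed), report


def filter_missing_snp(matrix: GenotypeMatrix, max_missing: float = 0.2
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci missing in at least ``max_missing`` of individuals.

    The boundary is inclusive for removal (a locus missing exactly 20% of
    calls is dropped at the 0.2 default), mirroring ``--geno`` semantics.
    """
    miss = matrix.missing_fraction()
    removed = miss >= max_missing
    report = _removal_report(matrix, removed, "missingness", miss)
    return matrix.take_loci(~removed), report


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two 0/1/2 genotype vectors.

    Composite (genotypic) LD over pairwise-complete individuals; phase is
    not required. Returns 0.0 when either vector is constant or fewer than
    two complete pairs exist.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(matrix: GenotypeMatrix, window: int = 2, step: int = 1,
             r2_max: float = 0.5, seed: int = 0
             ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Window-based LD pruning within each chromosome class.

    A window of ``window`` SNPs is slid in increments of ``step`` over loci
    in matrix order (assumed positional order within class). Whenever an
    in-window pair exceeds ``r2_max``, one member of the pair is removed
    uniformly at random (seeded). The scan repeats until no surviving
    in-window pair violates the threshold, so the result is a fixed point.
    """
    rng = np.random.default_rng(seed)
    keep = np.ones(matrix.n_loci, dtype=bool)
    removed_idx: list[int] = []
    partner: list[int] = []

    for cls in CHROM_CLASSES:
        cls_idx = np.flatnonzero(matrix.chromosome_class == cls)
        if len(cls_idx) < 2:
            continue
        changed = True
        while changed:
            changed = False
            alive = [i for i in cls_idx if keep[i]]
            for start in range(0, max(len(alive) - window + 1, 1), step):
                win = alive[start:start + window]
                for a in range(len(win)):
                    if not keep[win[a]]:
                        continue
                    for b in range(a + 1, len(win)):
                        if not keep[win[b]]:
                            continue
                        r2 = genotype_r2(matrix.genotypes[:, win[a]],
                                         matrix.genotypes[:, win[b]])
                        if r2 > r2_max:
                            drop = win[a] if rng.random() < 0.5 else win[b]
                            keep[drop] = False
                            removed_idx.append(drop)
                            other = win[b] if drop == win[a] else win[a]
                            partner.append(other)
                            changed = True

    report = pd.DataFrame(
        {
            "locus_id": [matrix.locus_ids[i] for i in removed_idx],
            "reason": "ld",
            "value": [matrix.locus_ids[j] for j in partner],
        }
    )
    return matrix.take_loci(keep), report


def apply_filter_cascade(matrix: GenotypeMatrix, params: FilterParams | None = None,
                         seed: int = 0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Run presence -> MAF -> missingness -> LD pruning, collecting reports.

    The cascade is idempotent: re-running it on its own output removes
    nothing (each filter's survivors satisfy its own criterion, and LD
    pruning iterates to a fixed point).
    """
    params = params or FilterParams()
    reports = []
    m, r = filter_position_presence(matrix, params.min_allele_presence)
    reports.append(r)
    m, r = filter_maf(m, params.maf_min)
    reports.append(r)
    m, r = filter_missing_snp(m, params.max_missing_per_snp)
    reports.append(r)
    m, r = ld_prune(m, params.ld_window, params.ld_step, params.ld_r2_max, seed)
    reports.append(r)
    report = pd.concat(reports, ignore_index=True)
    if len(report) + m.n_loci != matrix.n_loci:
        raise AssertionError("filter accounting error: removed + retained != input")
    return m, report


# ---------------------------------------------------------------------------
# Bi-allelic SNP extraction from per-locus alignments
# ---------------------------------------------------------------------------

def extract_biallelic_snps(alignments: dict[str, "object"],
                           allele_delim: str = "|") -> GenotypeMatrix:
    """Extract bi-allelic SNP columns from per-locus allele alignments.

    ``alignments`` maps locus id to a :class:`~duckmix.popgen.SequenceSet`
    holding two aligned allele sequences per individual, with sequence ids
    ``<individual><allele_delim><1|2>``. Columns with exactly two observed
    nucleotides (ignoring N and gaps) become SNPs; columns with one, three,
    or four become monomorphic/multi-allelic and are skipped. The major
    allele is the reference; genotypes count minor (alternate) alleles.
    """
    geno_cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    individuals: list[str] | None = None

    for locus, seqset in alignments.items():
        lens = {len(s) for s in seqset.sequences}
        if len(lens) > 1:
            raise ValueError(f"unequal sequence lengths within locus {locus!r}")
        by_ind: dict[str, list[str]] = {}
        for sid, seq in zip(seqset.ids, seqset.sequences):
            ind = sid.rsplit(allele_delim, 1)[0]
            by_ind.setdefault(ind, []).append(seq.upper())
        if individuals is None:
            individuals = list(by_ind)
        elif list(by_ind) != individuals:
            raise ValueError("individuals differ between loci")
        arr = np.array([[list(a) for a in alleles] for alleles in by_ind.values()])
        # arr shape: (n_ind, 2, length)
        for col in range(arr.shape[2]):
            column = arr[:, :, col]
            bases = column[np.isin(column, list("ACGT"))]
            alleles, counts = np.unique(bases, return_counts=True)
            if len(alleles) != 2:
                continue
            minor = alleles[np.argmin(counts)]
            g = np.full(arr.shape[0], MISSING, dtype=np.int8)
            for i in range(arr.shape[0]):
                pair = column[i]
                if np.isin(pair, list("ACGT")).all():
                    g[i] = int(pair[0] == minor) + int(pair[1] == minor)
            geno_cols.append(g)
            locus_ids.append(f"{locus}:{col}")

    if individuals is None:
        raise ValueError("no loci supplied")
    geno = (np.stack(geno_cols, axis=1) if geno_cols
            else np.empty((len(individuals), 0), dtype=np.int8))
    return GenotypeMatrix(geno, list(individuals), locus_ids)


# ---------------------------------------------------------------------------
# Depth-ratio sex assignment
# ---------------------------------------------------------------------------

def call_sex(profiles: pd.DataFrame, z_ratio_split: float = 0.75,
             w_ratio_split: float = 0.25) -> pd.Series:
    """Assign sex from Z/autosomal and W/autosomal depth ratios.

    In birds males are the homogametic sex (ZZ): Z depth tracks autosomal
    depth and W depth is near zero. Females (ZW) carry one copy of each sex
    chromosome, so both ratios sit near 0.5. An individual is called male
    when Z/A > ``z_ratio_split`` and W/A < ``w_ratio_split``; female when
    Z/A < ``z_ratio_split`` and W/A > ``w_ratio_split``; anything else
    (including a ratio sitting exactly on a split) is ``unresolved``. Zero
    autosomal depth yields ``unassignable``.
    """
    labels = []
    for _, row in profiles.iterrows():
        a = row["mean_depth_autosomal"]
        if a <= 0:
            labels.append("unassignable")
            continue
        rz = row["mean_depth_z"] / a
        rw = row["mean_depth_w"] / a
        if rz > z_ratio_split and rw < w_ratio_split:
            labels.append("male")
        elif rz < z_ratio_split and rw > w_ratio_split:
            labels.append("female")
        else:
            labels.append("unresolved")
    return pd.Series(labels, index=profiles["individual_id"].values, name="sex")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CLASS_CONTIGS = {"autosomal": "autosomal", "Z": "Z", "W": "W"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as an uncompressed VCF (GT-only; contigs per class).

    Loci are laid out on one contig per chromosome class with sequential
    positions; REF/ALT are placeholder A/C since only counts are modelled.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for cls in CHROM_CLASSES:
        n = int((matrix.chromosome_class == cls).sum())
        if n:
            lines.append(f"##contig=<ID={_CLASS_CONTIGS[cls]},length={n + 1}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individual_ids))
    pos_counter = {cls: 0 for cls in CHROM_CLASSES}
    gt_code = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    for j in range(matrix.n_loci):
        cls = matrix.chromosome_class[j]
        pos_counter[cls] += 1
        gts = "\t".join(gt_code[int(g)] for g in matrix.genotypes[:, j])
        lines.append(f"{_CLASS_CONTIGS[cls]}\t{pos_counter[cls]}\t"
                     f"{matrix.locus_ids[j]}\tA\tC\t.\t.\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, strict_biallelic: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Contig names ``autosomal``/``Z``/``W`` map to chromosome classes; any
    other contig is treated as autosomal. Under ``strict_biallelic`` a
    record with more than one ALT allele raises a format error naming the
    site; otherwise such records are skipped.
    """
    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    classes: list[str] = []
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) > 1:
            if strict_biallelic:
                raise ValueError(
                    f"non-bi-allelic site {rec.id or rec.chrom + ':' + str(rec.pos)}"
                )
            continue
        g = np.full(len(individuals), MISSING, dtype=np.int8)
        for i, sample in enumerate(individuals):
            alleles = rec.samples[sample]["GT"]
            if alleles is None or any(a is None for a in alleles):
                continue
            g[i] = sum(int(a > 0) for a in alleles)
        cols.append(g)
        locus_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        classes.append(rec.chrom if rec.chrom in CHROM_CLASSES else "autosomal")
    geno = (np.stack(cols, axis=1) if cols
            else np.empty((len(individuals), 0), dtype=np.int8))
    return GenotypeMatrix(geno, individuals, locus_ids, np.array(classes, dtype=object))


def write_table(matrix: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the delimited genotype dialect.

    Individuals as rows and loci as columns, ``NA`` for missing; the second
    header line (``#class``) records each locus's chromosome class.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual_id" + sep + sep.join(matrix.locus_ids) + "\n")
        fh.write("#class" + sep + sep.join(matrix.chromosome_class) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            row = ["NA" if g == MISSING else str(int(g))
                   for g in matrix.genotypes[i]]
            fh.write(ind + sep + sep.join(row) + "\n")


def read_table(path: str | Path, sep: str = "\t") -> GenotypeMatrix:
    """Read the delimited genotype dialect written by :func:`write_table`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        class_line = fh.readline().rstrip("\n").split(sep)
        if class_line[0] != "#class":
            raise ValueError("missing '#class' line in genotype table")
        body = pd.read_csv(fh, sep=sep, header=None, na_values=["NA"])
    locus_ids = header[1:]
    classes = np.array(class_line[1:], dtype=object)
    individuals = body.iloc[:, 0].astype(str).tolist()
    geno = body.iloc[:, 1:].to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(geno, individuals, locus_ids, classes)


def read_genotypes(path: str | Path, fmt: str | None = None,
                   strict_biallelic: bool = True) -> GenotypeMatrix:
    """Read genotypes from VCF or the delimited table, inferring by suffix."""
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix.lower() == ".vcf" else "table")
    if fmt == "vcf":
        return read_vcf(path, strict_biallelic=strict_biallelic)
    if fmt == "table":
        return read_table(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path,
                    fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix.lower() == ".vcf" else "table")
    if fmt == "vcf":
        write_vcf(matrix, path)
    elif fmt == "table":
        write_table(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
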