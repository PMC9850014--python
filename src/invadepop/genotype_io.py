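"""Genotype container, VCF I/O, and the SNP filtering cascade.

The cascade mirrors common RAD-seq practice: iterative missingness
filtering (alternating locus/individual passes with tightening
thresholds), a minor-allele-count screen, HDplot paralog detection from
per-genotype allele depths, and one-SNP-per-locus thinning by minor
allele frequency.  All filters are pure: they return a new matrix and
record every removal with a reason in a provenance log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("invadepop")

MISSING = -1  # genotype code for a missing diploid genotype


class InvadepopError(Exception):
    """Base class for errors raised by this package."""


@dataclass
class LocusQC:
    """Per-locus quality metrics used by the filtering cascade.

    H is the heterozygote proportion among non-missing genotypes; D is
    the allele-balance z-score of summed read depths over heterozygotes
    (positive = reference-biased).  Together they separate true SNPs
    from collapsed paralogs (HDplot).
    """

    het_proportion: float
    read_ratio_deviation: float
    minor_allele_count: int
    minor_allele_frequency: float
    missing_fraction: float


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for ``n_samples`` × ``n_loci``.

    ``codes`` counts the alternate allele (0, 1, 2) with -1 for missing.
    ``locus_ids`` are formatted ``"<locus_tag>:<position>"`` so that
    multiple SNPs on one RAD locus share a tag.  Depth arrays are
    optional and only required for HDplot.
    """

    codes: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    ref_depth: np.ndarray | None = None
    alt_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise InvadepopError("genotype codes must be 2-D (samples x loci)")
        n, m = self.codes.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != m:
            raise InvadepopError("id lists inconsistent with genotype shape")
        for d in (self.ref_depth, self.alt_depth):
            if d is not None and d.shape != self.codes.shape:
                raise InvadepopError("depth arrays must match genotype shape")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return self.codes == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.codes.copy(),
            list(self.sample_ids),
            list(self.locus_ids),
            None if self.ref_depth is None else self.ref_depth.copy(),
            None if self.alt_depth is None else self.alt_depth.copy(),
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.codes[idx],
            [self.sample_ids[i] for i in idx],
            list(self.locus_ids),
            None if self.ref_depth is None else self.ref_depth[idx],
            None if self.alt_depth is None else self.alt_depth[idx],
        )

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.codes[:, idx],
            list(self.sample_ids),
            [self.locus_ids[i] for i in idx],
            None if self.ref_depth is None else self.ref_depth[:, idx],
            None if self.alt_depth is None else self.alt_depth[:, idx],
        )

    # -- per-locus summaries ---------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing genotypes."""
        ok = ~self.missing
        n = ok.sum(axis=0)
        alt = np.where(ok, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def mac(self) -> np.ndarray:
        """Minor-allele count per locus over non-missing genotypes."""
        ok = ~self.missing
        alt = np.where(ok, self.codes, 0).sum(axis=0)
        total = 2 * ok.sum(axis=0)
        return np.minimum(alt, total - alt)

    def locus_missingness(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return self.missing.mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return self.missing.mean(axis=1)

    def locus_tags(self) -> list[str]:
        return [lid.rsplit(":", 1)[0] for lid in self.locus_ids]

    def locus_positions(self) -> np.ndarray:
        out = []
        for lid in self.locus_ids:
            parts = lid.rsplit(":", 1)
            out.append(int(parts[1]) if len(parts) == 2 else 0)
        return np.asarray(out, dtype=int)


@dataclass
class FilterLog:
    """Provenance of a filtering run: every removal with a reason."""

    removed_loci: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    passes: list[str] = field(default_factory=list)

    def drop_loci(self, ids: list[str], reason: str) -> None:
        self.removed_loci.extend((i, reason) for i in ids)

    def drop_samples(self, ids: list[str], reason: str) -> None:
        self.removed_samples.extend((i, reason) for i in ids)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic SNP VCF into a :class:`GenotypeMatrix`.

    GT is parsed to alternate-allele counts (missing -> -1); AD is
    parsed to ref/alt depth matrices when present.  Non-biallelic
    records are excluded with a logged count.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise InvadepopError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    codes_cols: list[np.ndarray] = []
    ref_cols: list[np.ndarray] = []
    alt_cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_skipped = 0
    has_ad = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gt = var.gt_types  # 0=hom_ref 1=het 2=unknown 3=hom_alt (cyvcf2)
        col = np.choose(gt, [0, 1, MISSING, 2]).astype(np.int16)
        codes_cols.append(col)
        locus_ids.append(f"{var.CHROM}:{var.POS}")
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            has_ad = True
            ad = np.asarray(ad)
            ad = np.where(ad < 0, 0, ad)
            ref_cols.append(ad[:, 0])
            alt_cols.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(gt)))
        else:
            ref_cols.append(np.zeros(len(gt)))
            alt_cols.append(np.zeros(len(gt)))
    vcf.close()
    if n_skipped:
        logger.warning("read_vcf: excluded %d non-biallelic records", n_skipped)
    n = len(samples)
    codes = (
        np.column_stack(codes_cols) if codes_cols else np.zeros((n, 0), dtype=np.int16)
    )
    ref = alt = None
    if has_ad:
        ref = np.column_stack(ref_cols).astype(np.int32)
        alt = np.column_stack(alt_cols).astype(np.int32)
    return GenotypeMatrix(codes, samples, locus_ids, ref, alt)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT (and AD when depths are present)."""
    with_ad = g.ref_depth is not None and g.alt_depth is not None
    tags = g.locus_tags()
    positions = g.locus_positions()
    contigs = list(dict.fromkeys(tags))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invadepop\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_ad:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        fmt = "GT:AD" if with_ad else "GT"
        for j in range(g.n_loci):
            fields = [tags[j], str(positions[j]), ".", "A", "T", ".", "PASS", ".", fmt]
            for i in range(g.n_samples):
                s = _GT_STR[int(g.codes[i, j])]
                if with_ad:
                    s += f":{int(g.ref_depth[i, j])},{int(g.alt_depth[i, j])}"
                fields.append(s)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

def iterative_missingness_filter(
    g: GenotypeMatrix,
    locus_threshold: float = 0.30,
    individual_threshold: float = 0.30,
    step_schedule: tuple[float, ...] = (0.9, 0.7, 0.5, 0.3),
    log: FilterLog | None = None,
) -> GenotypeMatrix:
    """Alternately drop loci then individuals exceeding a tightening
    missingness cut-off until the final thresholds hold simultaneously.

    The step schedule starts lenient and tightens towards the final
    thresholds; within each step loci are filtered first, then
    individuals.  Idempotent once both final rules hold.
    """
    for t in (locus_threshold, individual_threshold):
        if not 0 < t <= 1:
            raise InvadepopError("missingness thresholds must be in (0, 1]")
    log = log if log is not None else FilterLog()
    out = g
    schedule = [t for t in step_schedule if t >= max(locus_threshold, individual_threshold)]
    steps = schedule + [max(locus_threshold, individual_threshold)]
    for step in steps:
        lt = max(step, locus_threshold)
        it = max(step, individual_threshold)
        keep_l = out.locus_missingness() <= lt
        if not keep_l.all():
            log.drop_loci(
                [out.locus_ids[i] for i in np.flatnonzero(~keep_l)],
                f"locus missingness > {lt:g}",
            )
            out = out.take_loci(np.flatnonzero(keep_l))
        log.passes.append(f"loci@{lt:g}")
        keep_s = out.sample_missingness() <= it
        if not keep_s.all():
            log.drop_samples(
                [out.sample_ids[i] for i in np.flatnonzero(~keep_s)],
                f"individual missingness > {it:g}",
            )
            out = out.take_samples(np.flatnonzero(keep_s))
        log.passes.append(f"individuals@{it:g}")
    # final tightening may re-expose violations; iterate to a fixed point
    while True:
        keep_l = out.locus_missingness() <= locus_threshold
        if not keep_l.all():
            log.drop_loci(
                [out.locus_ids[i] for i in np.flatnonzero(~keep_l)],
                f"locus missingness > {locus_threshold:g}",
            )
            out = out.take_loci(np.flatnonzero(keep_l))
            continue
        keep_s = out.sample_missingness() <= individual_threshold
        if not keep_s.all():
            log.drop_samples(
                [out.sample_ids[i] for i in np.flatnonzero(~keep_s)],
                f"individual missingness > {individual_threshold:g}",
            )
            out = out.take_samples(np.flatnonzero(keep_s))
            continue
        break
    if out.n_samples == 0:
        raise InvadepopError("missingness filter removed all individuals")
    return out


def mac_filter(
    g: GenotypeMatrix, min_mac: int = 2, log: FilterLog | None = None
) -> GenotypeMatrix:
    """Drop loci whose minor-allele count is below ``min_mac``.

    Monomorphic loci always fall (their MAC is 0).
    """
    if min_mac < 1:
        raise InvadepopError("min_mac must be >= 1")
    keep = g.mac() >= min_mac
    if log is not None and not keep.all():
        log.drop_loci(
            [g.locus_ids[i] for i in np.flatnonzero(~keep)], f"MAC < {min_mac}"
        )
    return g.take_loci(np.flatnonzero(keep))


def hdplot(g: GenotypeMatrix) -> list[LocusQC]:
    """Per-locus H (heterozygote proportion) and D (read-ratio z-score).

    D = (A - B)/sqrt(A + B) where A, B are total ref and alt read counts
    summed over heterozygous individuals — a z-score of allele balance
    against binomial(0.5).  A locus with zero heterozygotes has D = 0.
    """
    if g.ref_depth is None or g.alt_depth is None:
        raise InvadepopError("HDplot requires per-genotype allele depths (AD)")
    het = g.codes == 1
    ok = ~g.missing
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_ok > 0, het.sum(axis=0) / n_ok, 0.0)
    a = np.where(het, g.ref_depth, 0).sum(axis=0).astype(float)
    b = np.where(het, g.alt_depth, 0).sum(axis=0).astype(float)
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, (a - b) / np.sqrt(np.where(tot > 0, tot, 1.0)), 0.0)
    n_nohet = int((het.sum(axis=0) == 0).sum())
    if n_nohet:
        logger.info("hdplot: %d loci without heterozygotes (D set to 0)", n_nohet)
    maf = g.maf()
    mac = g.mac()
    miss = g.locus_missingness()
    return [
        LocusQC(float(h[j]), float(d[j]), int(mac[j]), float(maf[j]), float(miss[j]))
        for j in range(g.n_loci)
    ]


def filter_hdplot(
    g: GenotypeMatrix,
    h_max: float = 0.55,
    d_max: float = 7.0,
    log: FilterLog | None = None,
) -> GenotypeMatrix:
    """Remove putative paralogs: loci with H > h_max or \\|D\\| > d_max."""
    qc = hdplot(g)
    h = np.array([q.het_proportion for q in qc])
    d = np.array([q.read_ratio_deviation for q in qc])
    keep = ~((h > h_max) | (np.abs(d) > d_max))
    if log is not None and not keep.all():
        log.drop_loci(
            [g.locus_ids[i] for i in np.flatnonzero(~keep)],
            f"HDplot H > {h_max:g} or |D| > {d_max:g}",
        )
    return g.take_loci(np.flatnonzero(keep))


def select_one_snp_per_locus(
    g: GenotypeMatrix, log: FilterLog | None = None
) -> GenotypeMatrix:
    """Keep one SNP per locus tag: maximal MAF, ties to lowest position."""
    tags = g.locus_tags()
    maf = g.maf()
    pos = g.locus_positions()
    best: dict[str, int] = {}
    for j, tag in enumerate(tags):
        i = best.get(tag)
        if i is None or (maf[j], -pos[j]) > (maf[i], -pos[i]):
            best[tag] = j
    keep_idx = sorted(best.values())
    if log is not None:
        dropped = sorted(set(range(g.n_loci)) - set(keep_idx))
        log.drop_loci(
            [g.locus_ids[i] for i in dropped], "not the highest-MAF SNP on locus"
        )
    return g.take_loci(np.asarray(keep_idx, dtype=int))


def filter_cascade(
    g: GenotypeMatrix,
    locus_threshold: float = 0.30,
    individual_threshold: float = 0.30,
    min_mac: int = 2,
    h_max: float = 0.55,
    d_max: float = 7.0,
    use_hdplot: bool | None = None,
    log: FilterLog | None = None,
) -> GenotypeMatrix:
    """Run the full cascade: missingness -> MAC -> HDplot -> one SNP/locus."""
    log = log if log is not None else FilterLog()
    out = iterative_missingness_filter(
        g, locus_threshold, individual_threshold, log=log
    )
    out = mac_filter(out, min_mac, log=log)
    if use_hdplot is None:
        use_hdplot = out.ref_depth is not None
    if use_hdplot:
        out = filter_hdplot(out, h_max, d_max, log=log)
    out = select_one_snp_per_locus(out, log=log)
    return out


# ---------------------------------------------------------------------------
# Relatedness screen
# ---------------------------------------------------------------------------

def pairwise_relatedness(g: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments pairwise relatedness r (GCTA-style correlation).

    r_ij = mean over loci of (x_i - 2p)(x_j - 2p) / (2p(1-p)), using the
    loci non-missing in both individuals.  E[r] = 0 for unrelated pairs,
    0.5 for parent-offspring and full sibs.  The diagonal is set to NaN
    and values are clipped to [-1, 1].
    """
    if g.n_samples < 2:
        raise InvadepopError("relatedness needs at least 2 individuals")
    p = g.alt_freq()
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    if not usable.any():
        raise InvadepopError("no polymorphic loci for relatedness")
    x = g.codes[:, usable].astype(float)
    p = p[usable]
    miss = x < 0
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    z[miss] = 0.0
    ok = (~miss).astype(float)
    num = z @ z.T
    den = ok @ ok.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, np.nan)
    return r


def qc_report(g: GenotypeMatrix):
    """Per-locus and per-individual QC tables (pandas DataFrames)."""
    import pandas as pd

    per_locus = pd.DataFrame(
        {
            "locus_id": g.locus_ids,
            "maf": g.maf(),
            "mac": g.mac(),
            "missing_fraction": g.locus_missingness(),
        }
    )
    if g.ref_depth is not None:
        qc = hdplot(g)
        per_locus["H"] = [q.het_proportion for q in qc]
        per_locus["D"] = [q.read_ratio_deviation for q in qc]
    per_ind = pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "missing_fraction": g.sample_missingness(),
        }
    )
    if g.ref_depth is not None:
        depth = (g.ref_depth + g.alt_depth).astype(float)
        depth[g.missing] = np.nan
        with np.errstate(invalid="ignore"):
            per_ind["mean_depth"] = np.nanmean(depth, axis=1)
    return per_locus, per_ind
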