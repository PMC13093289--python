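"""Aligned mitochondrial sequence data: loading, trimming, haplotypes, diversity.

Sequences are held as an integer-coded matrix (A,C,G,T -> 0..3; ambiguity
codes including N -> 4; gaps -> 5).  After :func:`trim_to_common_region` an
:class:`Alignment` contains only states 0..3, which is what the coalescent
simulator and the summary statistics expect.

Diversity and differentiation follow the standard haplotype-frequency
estimators: Nei's gene diversity with the n/(n-1) small-sample correction,
hypergeometric rarefaction for allelic richness, and the Gst / G'st /
Jost's D family computed from within-population (Hs) and total (Ht)
heterozygosity, in both plug-in and Nei–Chesser sample-size-corrected
variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.special import gammaln

logger = logging.getLogger(__name__)

# nucleotide codes
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "-": 5, ".": 5}
_DECODE = np.array(list("ACGTN-"))
A, C, G, T = 0, 1, 2, 3
AMBIG, GAP = 4, 5


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal lengths, empty trim region)."""


class MetadataError(ValueError):
    """Raised when FASTA records and the metadata table do not match 1:1."""


def encode_sequences(seq_strings: list[str]) -> np.ndarray:
    """Encode equal-length nucleotide strings into an int8 matrix."""
    lengths = {len(s) for s in seq_strings}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
    (L,) = lengths
    if L < 1:
        raise AlignmentError("alignment length must be >= 1")
    mat = np.empty((len(seq_strings), L), dtype=np.int8)
    for i, s in enumerate(seq_strings):
        mat[i] = [_CODE.get(ch.upper(), AMBIG) for ch in s]
    return mat


def decode_sequences(seqs: np.ndarray) -> list[str]:
    return ["".join(_DECODE[row]) for row in seqs]


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with population labels and ages.

    ``sample_ages`` are in generations before present (0 = modern).  Within a
    population all sample ages must be equal: serially sampled individuals
    get their own analysis population.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    sample_ages: np.ndarray
    seqs: np.ndarray
    lon: np.ndarray | None = None
    lat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ages = np.asarray(self.sample_ages, dtype=int)
        self.seqs = np.asarray(self.seqs, dtype=np.int8)
        n = len(self.sample_ids)
        if not (len(self.pop_labels) == len(self.sample_ages) == self.seqs.shape[0] == n):
            raise AlignmentError("sample_ids, pop_labels, sample_ages, seqs disagree in length")
        if self.seqs.ndim != 2 or self.seqs.shape[1] < 1:
            raise AlignmentError("seqs must be an n x L matrix with L >= 1")
        if np.any(self.sample_ages < 0):
            raise AlignmentError("sample ages must be non-negative")
        for pop in set(self.pop_labels):
            ages = {int(a) for a, p in zip(self.sample_ages, self.pop_labels) if p == pop}
            if len(ages) > 1:
                raise AlignmentError(
                    f"population {pop!r} mixes sampling ages {sorted(ages)}; "
                    "all samples within a population must share one age"
                )

    @property
    def n_samples(self) -> int:
        return self.seqs.shape[0]

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    @property
    def is_clean(self) -> bool:
        """True when no gap/ambiguity states remain."""
        return bool(np.all(self.seqs <= T))

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.pop_labels))

    def subset(self, idx: np.ndarray) -> "Alignment":
        idx = np.asarray(idx)
        return Alignment(
            sample_ids=[self.sample_ids[i] for i in idx],
            pop_labels=[self.pop_labels[i] for i in idx],
            sample_ages=self.sample_ages[idx],
            seqs=self.seqs[idx],
            lon=None if self.lon is None else self.lon[idx],
            lat=None if self.lat is None else self.lat[idx],
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.sample_ids, self.seqs):
                fh.write(f">{sid}\n{''.join(_DECODE[row])}\n")

    def metadata_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.sample_ids,
                "population": self.pop_labels,
                "lon": np.full(self.n_samples, np.nan) if self.lon is None else self.lon,
                "lat": np.full(self.n_samples, np.nan) if self.lat is None else self.lat,
                "age_generations": self.sample_ages,
            }
        )
        return df


@dataclass
class HaplotypeTable:
    """Distinct sequences with a haplotype x population count matrix."""

    haplotype_seqs: np.ndarray  # n_haplotypes x L
    counts: pd.DataFrame  # index: haplotype id, columns: populations
    n_segregating_sites: int

    @property
    def n_haplotypes(self) -> int:
        return self.haplotype_seqs.shape[0]

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    def frequencies(self) -> pd.DataFrame:
        """Per-population haplotype frequencies (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def sample_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class DiversityStats:
    """Per-population diversity and/or pairwise differentiation results.

    ``variant`` records whether Hs/Ht were plug-in or Nei–Chesser corrected.
    Bias-corrected Gst/D may be slightly negative on weakly differentiated
    data; values are reported as computed, never clipped.
    """

    gene_diversity: pd.Series | None = None
    allelic_richness: pd.Series | None = None
    rarefaction_size: int | None = None
    hs: float | None = None
    ht: float | None = None
    gst: pd.DataFrame | None = None
    gst_prime: pd.DataFrame | None = None
    jost_d: pd.DataFrame | None = None
    variant: str = "nei_chesser"
    flags: dict = field(default_factory=dict)


def load_alignment(fasta_path, metadata_path) -> Alignment:
    """Read a FASTA alignment plus its TSV metadata (id, population, lon, lat,
    age_generations), matched 1:1 by sequence id."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str, "population": str})
    required = {"id", "population", "lon", "lat", "age_generations"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise MetadataError(f"metadata missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("id")
    if meta.index.duplicated().any():
        dups = meta.index[meta.index.duplicated()].tolist()
        raise MetadataError(f"duplicate metadata ids: {dups}")

    ids = [r.id for r in records]
    absent = [i for i in ids if i not in meta.index]
    if absent:
        raise MetadataError(f"FASTA ids absent from metadata: {absent}")
    rows = meta.loc[ids]
    no_pop = rows.index[rows["population"].isna()].tolist()
    if no_pop:
        raise MetadataError(f"samples with missing population label rejected: {no_pop}")

    seqs = encode_sequences([str(r.seq) for r in records])
    return Alignment(
        sample_ids=ids,
        pop_labels=rows["population"].tolist(),
        sample_ages=rows["age_generations"].to_numpy(dtype=int),
        seqs=seqs,
        lon=rows["lon"].to_numpy(dtype=float),
        lat=rows["lat"].to_numpy(dtype=float),
    )


def trim_to_common_region(
    alignment: Alignment, drop_threshold: float | None = None
) -> Alignment:
    """Trim to the maximal contiguous column block free of gaps/ambiguity.

    Indels cannot be represented in the coalescent simulator, so columns with
    a gap or ambiguity code in any retained sequence are excluded and the
    longest clean contiguous block is kept.  If ``drop_threshold`` is given,
    sequences whose fraction of unclean sites exceeds it are first dropped
    (logged), which can lengthen the common block.
    """
    aln = alignment
    if drop_threshold is not None:
        bad_frac = np.mean(aln.seqs > T, axis=1)
        drop = np.where(bad_frac > drop_threshold)[0]
        if drop.size:
            dropped_ids = [aln.sample_ids[i] for i in drop]
            logger.warning("dropping %d sequences with >%g%% unclean sites: %s",
                           drop.size, 100 * drop_threshold, dropped_ids)
            warnings.warn(f"dropped sequences with ambiguous sites: {dropped_ids}")
            keep = np.setdiff1d(np.arange(aln.n_samples), drop)
            aln = aln.subset(keep)

    clean_col = np.all(aln.seqs <= T, axis=0)
    if not clean_col.any():
        raise AlignmentError("no gap/ambiguity-free column block of length >= 1")
    # longest run of True
    best_start, best_len = 0, 0
    run_start = None
    for j, ok in enumerate(np.append(clean_col, False)):
        if ok and run_start is None:
            run_start = j
        elif not ok and run_start is not None:
            if j - run_start > best_len:
                best_start, best_len = run_start, j - run_start
            run_start = None
    trimmed = aln.subset(np.arange(aln.n_samples))
    trimmed.seqs = aln.seqs[:, best_start : best_start + best_len].copy()
    return trimmed


def collapse_haplotypes(alignment: Alignment) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes and count segregating sites.

    A column is segregating when >= 2 distinct non-missing states occur.
    Haplotypes are ordered lexicographically by sequence so the table is
    invariant to sample order.
    """
    if not alignment.is_clean:
        raise AlignmentError("collapse_haplotypes requires a trimmed (clean) alignment")
    uniq, inverse = np.unique(alignment.seqs, axis=0, return_inverse=True)
    pops = alignment.populations
    counts = np.zeros((uniq.shape[0], len(pops)), dtype=int)
    pop_index = {p: j for j, p in enumerate(pops)}
    for hap_i, pop in zip(inverse, alignment.pop_labels):
        counts[hap_i, pop_index[pop]] += 1
    n_seg = int(np.sum([len(np.unique(col)) >= 2 for col in alignment.seqs.T]))
    table = pd.DataFrame(counts, columns=pops,
                         index=[f"H{i+1}" for i in range(uniq.shape[0])])
    return HaplotypeTable(haplotype_seqs=uniq, counts=table, n_segregating_sites=n_seg)


def gene_diversity(counts: np.ndarray) -> float:
    """Nei's gene diversity H = (n/(n-1)) (1 - sum p_i^2); needs n >= 2."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity undefined for n < 2")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected number of distinct haplotypes in a subsample of size g
    (hypergeometric rarefaction)."""
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if g > n:
        raise ValueError(f"rarefaction size {g} exceeds sample size {n}")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    total = 0.0
    for ni in counts:
        if n - ni >= g:
            total += 1.0 - np.exp(log_comb(n - ni, g) - log_comb(n, g))
        else:
            total += 1.0
    return float(total)


def diversity_stats(table: HaplotypeTable, rarefaction_size: int | None = None) -> DiversityStats:
    """Per-population gene diversity and rarefied allelic richness.

    ``rarefaction_size`` defaults to the smallest population sample size.
    Populations of size 1 get NaN diversity and are flagged rather than
    raising, so mixed tables can still be summarised.
    """
    sizes = table.sample_sizes()
    if rarefaction_size is None:
        rarefaction_size = int(sizes.min())
    H = {}
    rich = {}
    flagged = []
    for pop in table.populations:
        c = table.counts[pop].to_numpy()
        if c.sum() < 2:
            H[pop] = np.nan
            flagged.append(pop)
        else:
            H[pop] = gene_diversity(c)
        rich[pop] = rarefied_richness(c, min(rarefaction_size, int(c.sum())))
    stats = DiversityStats(
        gene_diversity=pd.Series(H),
        allelic_richness=pd.Series(rich),
        rarefaction_size=rarefaction_size,
    )
    if flagged:
        stats.flags["undefined_H"] = flagged
    return stats


def _hs_ht(counts1: np.ndarray, counts2: np.ndarray, variant: str) -> tuple[float, float]:
    """Within (Hs) and total (Ht) heterozygosity for a pair of populations.

    plug-in: Hs = mean_k (1 - sum_i p_ki^2), Ht = 1 - sum_i pbar_i^2.
    nei_chesser: Hs_hat = (nt/(nt-1)) Hs with nt the harmonic mean sample
    size, Ht_hat = Ht + Hs_hat/(nt k).
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    n1, n2 = c1.sum(), c2.sum()
    p1, p2 = c1 / n1, c2 / n2
    hs_plug = 1.0 - 0.5 * (np.sum(p1**2) + np.sum(p2**2))
    pbar = 0.5 * (p1 + p2)
    ht_plug = 1.0 - np.sum(pbar**2)
    if variant == "plugin":
        return float(hs_plug), float(ht_plug)
    if variant == "nei_chesser":
        nt = 2.0 / (1.0 / n1 + 1.0 / n2)  # harmonic mean
        hs_hat = nt / (nt - 1.0) * hs_plug
        ht_hat = ht_plug + hs_hat / (2.0 * nt)
        return float(hs_hat), float(ht_hat)
    raise ValueError(f"unknown variant {variant!r}")


def differentiation_pair(
    counts1: np.ndarray, counts2: np.ndarray, variant: str = "nei_chesser"
) -> dict:
    """Gst, Hedrick's G'st and Jost's D for one population pair (k = 2).

    Gst  = (Ht - Hs) / Ht
    G'st = Gst (k - 1 + Hs) / ((k - 1)(1 - Hs))
    D    = (k/(k-1)) (Ht - Hs) / (1 - Hs)

    Ht = 0 (both populations monomorphic for the same haplotype) gives all
    three statistics 0 with a flag.
    """
    hs, ht = _hs_ht(counts1, counts2, variant)
    k = 2.0
    out = {"hs": hs, "ht": ht, "variant": variant, "flag_ht_zero": False}
    if ht <= 0.0:
        out.update(gst=0.0, gst_prime=0.0, jost_d=0.0, flag_ht_zero=True)
        return out
    gst = (ht - hs) / ht
    if hs >= 1.0:
        gst_prime = np.nan
        d = np.nan
    else:
        gst_prime = gst * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs))
        d = (k / (k - 1.0)) * (ht - hs) / (1.0 - hs)
    out.update(gst=float(gst), gst_prime=float(gst_prime), jost_d=float(d))
    return out


def differentiation_stats(table: HaplotypeTable, variant: str = "nei_chesser") -> DiversityStats:
    """Pairwise Gst / G'st / Jost's D matrices over all population pairs."""
    pops = table.populations
    if len(pops) < 2:
        raise ValueError("differentiation requires >= 2 populations")
    sizes = table.sample_sizes()
    small = [p for p in pops if sizes[p] < 2]
    if small:
        raise ValueError(f"populations with n < 2: {small}")
    m = len(pops)
    mats = {name: np.zeros((m, m)) for name in ("gst", "gst_prime", "jost_d")}
    flags = {}
    for i in range(m):
        for j in range(i + 1, m):
            res = differentiation_pair(
                table.counts[pops[i]].to_numpy(), table.counts[pops[j]].to_numpy(), variant
            )
            for name in mats:
                mats[name][i, j] = mats[name][j, i] = res[name]
            if res["flag_ht_zero"]:
                flags.setdefault("ht_zero_pairs", []).append((pops[i], pops[j]))
    frames = {k: pd.DataFrame(v, index=pops, columns=pops) for k, v in mats.items()}
    return DiversityStats(
        gst=frames["gst"], gst_prime=frames["gst_prime"], jost_d=frames["jost_d"],
        variant=variant, flags=flags,
    )
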