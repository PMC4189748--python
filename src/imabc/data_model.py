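"""Core containers for multilocus segregating-site data.

The package works on phased haplotype data from two populations sampled at
a handful of unlinked, non-coding loci.  Each locus is reduced to a binary
haplotype x segregating-site matrix (:class:`SiteMatrix`); the study design
(locus lengths, per-locus mutation rates, sample sizes, generation time)
lives in :class:`StudyDesign`; a :class:`MultilocusDataset` bundles the two.

Encoding convention: sites are biallelic (infinite-sites assumption) and
coded 0/1 with 0 the major allele in the pooled sample (ties broken by
alphabetical allele order).  No outgroup polarisation is attempted, and all
statistics shipped with the package are invariant to folding, so the
convention is purely a canonical form.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from Bio import SeqIO

__all__ = [
    "StudyDesign",
    "SiteMatrix",
    "MultilocusDataset",
    "read_fasta_locus",
    "read_genotype_table",
    "write_genotype_table",
    "shared_private_fixed_counts",
]

POP1, POP2 = 1, 2


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Sampling and mutational design of a multilocus resequencing study.

    Parameters
    ----------
    n_loci : int
        Number of unlinked loci.
    locus_lengths : tuple of int
        Length of each locus in base pairs.
    mu_per_locus : tuple of float
        Whole-locus mutation rate per year for each locus.  Multilocus
        analyses use the geometric mean of these rates.
    n_chrom_pop1, n_chrom_pop2 : int
        Number of sampled chromosomes (haplotypes) per population.
    generation_time : float
        Years per generation (default 25 for humans).
    inheritance_scalar : float
        Relative effective copy number (1.0 for autosomes).
    """

    n_loci: int
    locus_lengths: tuple
    mu_per_locus: tuple
    n_chrom_pop1: int
    n_chrom_pop2: int
    generation_time: float = 25.0
    inheritance_scalar: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "locus_lengths", tuple(int(x) for x in self.locus_lengths))
        object.__setattr__(self, "mu_per_locus", tuple(float(x) for x in self.mu_per_locus))
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if len(self.locus_lengths) != self.n_loci or len(self.mu_per_locus) != self.n_loci:
            raise ValueError("locus_lengths and mu_per_locus must have n_loci entries")
        if any(l <= 0 for l in self.locus_lengths):
            raise ValueError("all locus lengths must be positive")
        if any(m <= 0 for m in self.mu_per_locus):
            raise ValueError("all mutation rates must be positive")
        if self.n_chrom_pop1 < 2 or self.n_chrom_pop2 < 2:
            raise ValueError("need >= 2 chromosomes per population")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")

    @property
    def n_chrom_total(self) -> int:
        return self.n_chrom_pop1 + self.n_chrom_pop2

    @property
    def total_length(self) -> int:
        return sum(self.locus_lengths)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDesign":
        return cls(**d)

    def save(self, path) -> None:
        """Write the design as YAML (JSON also accepted on load)."""
        d = self.to_dict()
        d["locus_lengths"] = list(d["locus_lengths"])
        d["mu_per_locus"] = list(d["mu_per_locus"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path) -> "StudyDesign":
        text = Path(path).read_text()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = yaml.safe_load(text)
        return cls.from_dict(d)


class SiteMatrix:
    """Binary haplotype x segregating-site matrix for one locus.

    Rows are haplotypes (population 1 rows need not precede population 2
    rows, but a consistent ordering is kept).  Every column is segregating
    (both alleles present in the pooled sample) and positions are strictly
    increasing 1-based coordinates within the locus.
    """

    def __init__(self, locus_id, alleles, positions, pop_labels, locus_length,
                 haplotype_ids=None, validate=True):
        self.locus_id = str(locus_id)
        self.alleles = np.ascontiguousarray(np.asarray(alleles, dtype=np.int8))
        if self.alleles.ndim != 2:
            self.alleles = self.alleles.reshape(self.alleles.shape[0], -1)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.pop_labels = np.asarray(pop_labels, dtype=np.int8)
        self.locus_length = int(locus_length)
        if haplotype_ids is None:
            haplotype_ids = [f"{self.locus_id}.h{i}" for i in range(self.alleles.shape[0])]
        self.haplotype_ids = list(haplotype_ids)
        if validate:
            self._validate()

    def _validate(self):
        n, s = self.alleles.shape
        if self.positions.shape != (s,):
            raise ValueError("positions length must equal number of columns")
        if self.pop_labels.shape != (n,):
            raise ValueError("pop_labels length must equal number of rows")
        if len(self.haplotype_ids) != n:
            raise ValueError("haplotype_ids length must equal number of rows")
        if not set(np.unique(self.pop_labels)) <= {POP1, POP2}:
            raise ValueError("pop_labels must be 1 or 2")
        if s:
            if np.any(self.positions[1:] <= self.positions[:-1]):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 1 or self.positions[-1] > self.locus_length:
                raise ValueError("positions must lie in [1, locus_length]")
            colsum = self.alleles.sum(axis=0)
            if np.any(colsum == 0) or np.any(colsum == n):
                raise ValueError("every column must be segregating in the pooled sample")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def rows_for_pop(self, pop: int) -> np.ndarray:
        return np.flatnonzero(self.pop_labels == pop)

    def submatrix(self, rows=None, sites=None) -> "SiteMatrix":
        """Row/column subset; columns monomorphic in the subset are kept
        (callers that need the segregating invariant should follow with
        :meth:`drop_monomorphic`)."""
        rows = np.arange(self.n_haplotypes) if rows is None else np.asarray(rows)
        sites = np.arange(self.n_sites) if sites is None else np.asarray(sites)
        return SiteMatrix(
            self.locus_id,
            self.alleles[np.ix_(rows, sites)],
            self.positions[sites],
            self.pop_labels[rows],
            self.locus_length,
            [self.haplotype_ids[i] for i in rows],
            validate=False,
        )

    def drop_monomorphic(self) -> "SiteMatrix":
        n = self.n_haplotypes
        colsum = self.alleles.sum(axis=0)
        keep = np.flatnonzero((colsum > 0) & (colsum < n))
        return self.submatrix(sites=keep)

    def to_major_allele(self) -> "SiteMatrix":
        """Canonical form: recode each column so 0 is the major allele
        (ties keep the current coding)."""
        a = self.alleles.copy()
        n = a.shape[0]
        flip = a.sum(axis=0) * 2 > n
        a[:, flip] = 1 - a[:, flip]
        return SiteMatrix(self.locus_id, a, self.positions, self.pop_labels,
                          self.locus_length, self.haplotype_ids, validate=False)

    def __eq__(self, other):
        if not isinstance(other, SiteMatrix):
            return NotImplemented
        return (
            self.locus_id == other.locus_id
            and self.locus_length == other.locus_length
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.pop_labels, other.pop_labels)
        )

    def __repr__(self):
        return (f"SiteMatrix({self.locus_id!r}, {self.n_haplotypes} haplotypes x "
                f"{self.n_sites} sites, L={self.locus_length})")


@dataclasses.dataclass
class MultilocusDataset:
    """A study design plus one :class:`SiteMatrix` per locus."""

    design: StudyDesign
    loci: list

    def __post_init__(self):
        if len(self.loci) != self.design.n_loci:
            raise ValueError("one SiteMatrix per design locus required")
        for m, L in zip(self.loci, self.design.locus_lengths):
            if m.locus_length != L:
                raise ValueError(f"locus {m.locus_id}: length {m.locus_length} != design {L}")

    @property
    def total_segregating_sites(self) -> int:
        return sum(m.n_sites for m in self.loci)

    def __eq__(self, other):
        if not isinstance(other, MultilocusDataset):
            return NotImplemented
        return self.design == other.design and all(
            a == b for a, b in zip(self.loci, other.loci)
        )


def _encode_binary_columns(seq_array, ids, locus_id):
    """Drop monomorphic columns, 0/1-encode biallelic ones (major allele = 0,
    alphabetical tie-break), error on >2 alleles."""
    n, L = seq_array.shape
    cols, positions = [], []
    for j in range(L):
        column = seq_array[:, j]
        alleles, counts = np.unique(column, return_counts=True)
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            raise ValueError(
                f"locus {locus_id}: column {j + 1} has alleles "
                f"{sorted(a.decode() if isinstance(a, bytes) else str(a) for a in alleles)}; "
                "more than two alleles violates the infinite-sites assumption"
            )
        # major allele -> 0; counts tie -> alphabetically first allele is 0
        if counts[0] > counts[1]:
            zero = alleles[0]
        elif counts[1] > counts[0]:
            zero = alleles[1]
        else:
            zero = min(alleles)
        cols.append((column != zero).astype(np.int8))
        positions.append(j + 1)
    if cols:
        mat = np.column_stack(cols)
    else:
        mat = np.zeros((n, 0), dtype=np.int8)
    return mat, np.asarray(positions, dtype=np.int64)


def read_fasta_locus(path, pop_assignment: Mapping[str, int], locus_id=None,
                     locus_length=None) -> SiteMatrix:
    """Read one aligned FASTA file into a :class:`SiteMatrix`.

    Parameters
    ----------
    path : path-like
        FASTA of aligned, equal-length haplotype sequences.
    pop_assignment : mapping
        record id -> population (1 or 2); every id must be present.
    locus_id : str, optional
        Defaults to the file stem.
    locus_length : int, optional
        Defaults to the alignment length.
    """
    path = Path(path)
    locus_id = locus_id or path.stem
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"{path}: unequal sequence lengths {sorted(lengths)}; not an alignment")
    ids = [r.id for r in records]
    missing = [i for i in ids if i not in pop_assignment]
    if missing:
        raise ValueError(f"{path}: no population assignment for {missing}")
    arr = np.array([list(str(r.seq).upper()) for r in records])
    mat, positions = _encode_binary_columns(arr, ids, locus_id)
    labels = np.array([pop_assignment[i] for i in ids], dtype=np.int8)
    L = int(locus_length) if locus_length is not None else int(lengths.pop())
    return SiteMatrix(locus_id, mat, positions, labels, L, haplotype_ids=ids)


# ---------------------------------------------------------------------------
# Genotype-table dialect: tab-separated, header row
#   individual_id  population  locus:pos  locus:pos ...
# with diploid genotypes written as "A/C".  Haplotype matrices are encoded
# with 0 -> 'A' and 1 -> 'C'; re-reading applies the major-allele convention.
# ---------------------------------------------------------------------------

_ZERO_CHAR, _ONE_CHAR = "A", "C"


def write_genotype_table(dataset: MultilocusDataset, path) -> None:
    """Write a dataset in the package's genotype-table dialect.

    Consecutive haplotype pairs within each population form one diploid
    individual, so each population must hold an even number of haplotypes.
    """
    rows_by_pop = {}
    for pop in (POP1, POP2):
        idx = dataset.loci[0].rows_for_pop(pop)
        if len(idx) % 2:
            raise ValueError(f"population {pop} has an odd number of haplotypes")
        rows_by_pop[pop] = idx
    header = ["individual_id", "population"]
    for m in dataset.loci:
        header += [f"{m.locus_id}:{p}" for p in m.positions]
    lines = ["\t".join(header)]
    counter = 0
    for pop in (POP1, POP2):
        idx = rows_by_pop[pop]
        for k in range(0, len(idx), 2):
            counter += 1
            a, b = idx[k], idx[k + 1]
            fields = [f"ind{counter}", f"pop{pop}"]
            for m in dataset.loci:
                ra, rb = m.alleles[a], m.alleles[b]
                for j in range(m.n_sites):
                    ca = _ONE_CHAR if ra[j] else _ZERO_CHAR
                    cb = _ONE_CHAR if rb[j] else _ZERO_CHAR
                    fields.append(f"{ca}/{cb}")
            lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_table(path, design: StudyDesign | None = None, phased: bool = True,
                        seed: int | None = None) -> MultilocusDataset:
    """Read a genotype table (see module docstring for the dialect).

    Each individual expands to two haplotype rows.  With ``phased=False``
    heterozygous genotypes are pseudo-phased by random allele assignment
    using ``seed`` (recorded nowhere else, so pass one for reproducibility).

    If ``design`` is omitted, a design is inferred: locus lengths default to
    the largest observed position per locus and per-locus rates default to
    the 1.47e-6 / year multilocus geometric mean.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "individual_id" or header[1] != "population":
        raise ValueError("genotype table must start with individual_id and population columns")
    site_cols = header[2:]
    loci_order: list[str] = []
    sites_by_locus: dict[str, list[int]] = {}
    for col in site_cols:
        try:
            locus, pos = col.rsplit(":", 1)
            pos = int(pos)
        except ValueError as exc:
            raise ValueError(f"bad site column name {col!r}; expected locus:position") from exc
        if locus not in sites_by_locus:
            loci_order.append(locus)
            sites_by_locus[locus] = []
        sites_by_locus[locus].append(pos)

    ids, pops, genos = [], [], []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"row {fields[0] if fields else '?'}: expected "
                             f"{len(header)} fields, got {len(fields)}")
        ids.append(fields[0])
        pops.append(fields[1])
        genos.append(fields[2:])

    pop_values = []
    for p in pops:
        if p not in pop_values:
            pop_values.append(p)
    if len(pop_values) != 2:
        raise ValueError(f"expected exactly two population labels, got {pop_values}")
    if set(pop_values) == {"pop1", "pop2"}:
        pop_map = {"pop1": POP1, "pop2": POP2}
    else:  # first-appearance order
        pop_map = {pop_values[0]: POP1, pop_values[1]: POP2}

    rng = np.random.default_rng(seed)
    # expand to haplotypes: character matrix (2 * n_ind) x n_sites
    n_ind = len(ids)
    hap_chars = np.empty((2 * n_ind, len(site_cols)), dtype="U1")
    hap_ids, hap_pops = [], []
    for i, (iid, pop, row) in enumerate(zip(ids, pops, genos)):
        hap_ids += [f"{iid}.a", f"{iid}.b"]
        hap_pops += [pop_map[pop]] * 2
        for j, g in enumerate(row):
            try:
                a, b = g.split("/")
            except ValueError as exc:
                raise ValueError(f"individual {iid}, column {site_cols[j]}: "
                                 f"bad genotype {g!r}") from exc
            if not phased and a != b and rng.random() < 0.5:
                a, b = b, a
            hap_chars[2 * i, j] = a
            hap_chars[2 * i + 1, j] = b
    hap_pops = np.asarray(hap_pops, dtype=np.int8)

    loci = []
    col_index = {c: j for j, c in enumerate(site_cols)}
    lengths, rates = [], []
    for locus in loci_order:
        positions = sites_by_locus[locus]
        if sorted(positions) != positions or len(set(positions)) != len(positions):
            raise ValueError(f"locus {locus}: site positions must be strictly increasing")
        block = hap_chars[:, [col_index[f"{locus}:{p}"] for p in positions]]
        mat, kept = _encode_binary_columns(block, hap_ids, locus)
        kept_positions = np.asarray(positions, dtype=np.int64)[kept - 1]
        if design is not None:
            L = design.locus_lengths[loci_order.index(locus)]
        else:
            L = max(positions) if positions else 1
        loci.append(SiteMatrix(locus, mat, kept_positions, hap_pops, L, haplotype_ids=hap_ids))
        lengths.append(L)
        rates.append(1.47e-6)

    if design is None:
        design = StudyDesign(
            n_loci=len(loci),
            locus_lengths=tuple(lengths),
            mu_per_locus=tuple(rates),
            n_chrom_pop1=int((hap_pops == POP1).sum()),
            n_chrom_pop2=int((hap_pops == POP2).sum()),
        )
    return MultilocusDataset(design, loci)


def classify_site(column: np.ndarray, pop_labels: np.ndarray) -> str:
    """Classify one pooled-segregating column as shared / private1 /
    private2 / fixed (fixed = alternative alleles fixed in the two pops)."""
    c1 = column[pop_labels == POP1]
    c2 = column[pop_labels == POP2]
    poly1 = 0 < c1.sum() < len(c1)
    poly2 = 0 < c2.sum() < len(c2)
    if poly1 and poly2:
        return "shared"
    if poly1:
        return "private1"
    if poly2:
        return "private2"
    return "fixed"  # both monomorphic; pooled segregation forces different alleles


def shared_private_fixed_counts(dataset: MultilocusDataset) -> dict:
    """Count segregating sites by sharing category over all loci.

    Returns a dict with keys ``shared``, ``private1``, ``private2``,
    ``fixed``; the values always sum to the total number of segregating
    sites in the dataset.
    """
    counts = {"shared": 0, "private1": 0, "private2": 0, "fixed": 0}
    for m in dataset.loci:
        for j in range(m.n_sites):
            counts[classify_site(m.alleles[:, j], m.pop_labels)] += 1
    return counts
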