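"""Genotype data model, PLINK 1 binary I/O, and pedigree handling.

The central container is :class:`GenotypeDataset`: an ordered sample table,
an ordered variant table, and a samples x variants call matrix counting
copies of the A1 allele (0/1/2, ``-1`` for missing).  Datasets may carry
phased haplotypes, in which case the two per-sample haplotype rows always
sum to the unphased call at every non-missing site.

PLINK 1 binary layout (SNP-major ``.bed``):

* three header bytes ``0x6c 0x1b 0x01``;
* one block of ``ceil(n_samples / 4)`` bytes per variant;
* two bits per sample, least-significant pair first:
  ``00`` = two copies of A1, ``10`` = heterozygote, ``11`` = zero copies
  of A1, ``01`` = missing.  Padding bits are zero.

Sample-major files (third byte ``0x00``) are rejected, not transposed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

MISSING = -1

_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = 0x01

#: allowed chromosome labels: ovine autosomes 1..26, sex chromosomes, unknown
AUTOSOMES = tuple(str(i) for i in range(1, 27))
SEX_CHROMOSOMES = ("X", "Y")
UNKNOWN_CHROMOSOME = "0"
CHROMOSOMES = AUTOSOMES + SEX_CHROMOSOMES + (UNKNOWN_CHROMOSOME,)

# 2-bit code -> call, indexed by code value
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}

# byte -> 4 calls lookup table, built once
_DECODE_LUT = np.empty((256, 4), dtype=np.int8)
for _byte in range(256):
    for _k in range(4):
        _DECODE_LUT[_byte, _k] = _CODE_TO_CALL[(_byte >> (2 * _k)) & 0x3]


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK 1 binary input."""


class AlleleMismatchError(ValueError):
    """Raised when the same variant id carries irreconcilable alleles."""


@dataclasses.dataclass
class GenotypeDataset:
    """Samples x diallelic SNPs with 0/1/2/missing calls and optional phase.

    Parameters
    ----------
    samples
        One row per sample with columns ``id``, ``population``, ``sire_id``,
        ``dam_id`` (``"0"`` = unknown) and optional ``birth_year``.
    variants
        One row per SNP with columns ``chrom``, ``id``, ``cm``, ``pos``,
        ``a1``, ``a2``.  Positions are 1-based base pairs as in ``.bim``.
    calls
        ``(n_samples, n_variants)`` int8 matrix counting A1 copies;
        ``-1`` marks a missing call.
    haplotypes
        Optional ``(n_samples, 2, n_variants)`` int8 array of per-haplotype
        A1 copies (0/1); haplotype sums must equal non-missing calls.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray
    haplotypes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on breach."""
        if self.calls.shape != (self.n_samples, self.n_variants):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{self.n_samples} samples x {self.n_variants} variants"
            )
        if self.samples["id"].duplicated().any():
            dup = self.samples["id"][self.samples["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, -1}")
        unknown = set(self.variants["chrom"].astype(str)) - set(CHROMOSOMES)
        if unknown:
            raise ValueError(f"chromosome labels outside 1..26/X/Y/0: {sorted(unknown)}")
        if (np.asarray(self.variants["pos"]) < 0).any():
            raise ValueError("positions must be >= 0")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (self.n_samples, 2, self.n_variants):
                raise ValueError("haplotype array shape mismatch")
            sums = self.haplotypes.sum(axis=1, dtype=np.int8)
            ok = (self.calls == MISSING) | (sums == self.calls)
            if not ok.all():
                raise ValueError("haplotype sums disagree with calls")

    # -- construction helpers -------------------------------------------------

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.samples.copy(),
            self.variants.copy(),
            self.calls.copy(),
            None if self.haplotypes is None else self.haplotypes.copy(),
        )

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        """Return a new dataset restricted to the given index arrays."""
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        haps = None
        if self.haplotypes is not None:
            haps = self.haplotypes[s][:, :, v]
        return GenotypeDataset(
            self.samples.iloc[s].reset_index(drop=True),
            self.variants.iloc[v].reset_index(drop=True),
            self.calls[np.ix_(s, v)],
            haps,
        )

    def for_population(self, label: str) -> "GenotypeDataset":
        idx = np.flatnonzero((self.samples["population"] == label).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples in population {label!r}")
        return self.subset(sample_idx=idx)

    def sort_variants(self) -> "GenotypeDataset":
        """Normalize variant order to (chromosome, position)."""
        chrom_rank = {c: i for i, c in enumerate(CHROMOSOMES)}
        key = [
            (chrom_rank[str(c)], int(p))
            for c, p in zip(self.variants["chrom"], self.variants["pos"])
        ]
        order = np.argsort(np.array(key, dtype=[("c", int), ("p", int)]), order=("c", "p"))
        return self.subset(variant_idx=order)


def make_dataset(
    calls,
    pos=None,
    chrom=None,
    populations=None,
    sample_ids=None,
    variant_ids=None,
    a1="A",
    a2="B",
    haplotypes=None,
    birth_year=None,
) -> GenotypeDataset:
    """Build a dataset from plain arrays; convenient for fixtures and tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if chrom is None:
        chrom = ["1"] * m
    elif np.isscalar(chrom):
        chrom = [str(chrom)] * m
    if populations is None:
        populations = ["POP"] * n
    elif isinstance(populations, str):
        populations = [populations] * n
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if variant_ids is None:
        variant_ids = [f"snp{j}" for j in range(m)]
    if isinstance(a1, str):
        a1 = [a1] * m
    if isinstance(a2, str):
        a2 = [a2] * m
    samples = pd.DataFrame(
        {
            "id": list(sample_ids),
            "population": list(populations),
            "sire_id": "0",
            "dam_id": "0",
            "birth_year": birth_year if birth_year is not None else pd.NA,
        }
    )
    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in chrom],
            "id": list(variant_ids),
            "cm": 0.0,
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": list(a1),
            "a2": list(a2),
        }
    )
    if haplotypes is not None:
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
    ds = GenotypeDataset(samples, variants, calls, haplotypes)
    ds.validate()
    return ds


# -- PLINK 1 binary -----------------------------------------------------------


def read_plink1(prefix) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset ``prefix.{bed,bim,fam}``.

    The population label is taken from the family-ID column of ``.fam``.
    Sample and variant order are preserved exactly as on disk.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "id", "sire_id", "dam_id", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "cm": float, "pos": np.int64, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: sample-major layout (third byte {raw[2]:#04x}) is unsupported"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise IOError(
            f"{prefix}.bed: {len(raw)} bytes, expected {expected} "
            f"({m} variants x {bytes_per_snp} bytes + 3)"
        )
    if m == 0 or n == 0:
        calls = np.zeros((n, m), dtype=np.int8)
    else:
        blocks = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, bytes_per_snp)
        decoded = _DECODE_LUT[blocks].reshape(m, bytes_per_snp * 4)[:, :n]
        calls = np.ascontiguousarray(decoded.T)
    samples = pd.DataFrame(
        {
            "id": fam["id"],
            "population": fam["fid"],
            "sire_id": fam["sire_id"],
            "dam_id": fam["dam_id"],
            "birth_year": pd.NA,
        }
    )
    ds = GenotypeDataset(samples, bim, calls)
    ds.validate()
    return ds


def write_plink1(data: GenotypeDataset, prefix) -> None:
    """Write ``prefix.{bed,bim,fam}`` in SNP-major PLINK 1 binary layout."""
    data.validate()
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = data.n_samples, data.n_variants

    fam = pd.DataFrame(
        {
            "fid": data.samples["population"],
            "id": data.samples["id"],
            "sire_id": data.samples.get("sire_id", "0").fillna("0"),
            "dam_id": data.samples.get("dam_id", "0").fillna("0"),
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    data.variants[["chrom", "id", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )

    bytes_per_snp = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        if m == 0 or n == 0:
            return
        codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
        codes[:] = 0  # padding bits zero
        call_codes = np.select(
            [data.calls == 2, data.calls == 1, data.calls == 0, data.calls == MISSING],
            [0, 2, 3, 1],
        ).astype(np.uint8)
        codes[:, :n] = call_codes.T
        shifted = codes.reshape(m, bytes_per_snp, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = shifted[..., 0] | shifted[..., 1] | shifted[..., 2] | shifted[..., 3]
        fh.write(packed.astype(np.uint8).tobytes())


# -- allele alignment and merging ---------------------------------------------


def flip_calls(calls: np.ndarray) -> np.ndarray:
    """Swap the reference allele: 0 <-> 2, heterozygote and missing unchanged."""
    out = calls.copy()
    nonmiss = out != MISSING
    out[nonmiss] = 2 - out[nonmiss]
    return out


def align_alleles(reference: GenotypeDataset, other: GenotypeDataset):
    """Restrict both datasets to shared variant ids and align A1/A2.

    Returns ``(ref_subset, other_aligned, flip_log)`` where ``flip_log`` is
    the list of variant ids whose calls were flipped (A1/A2 swapped) in
    ``other`` to match ``reference``.
    """
    ref_ids = reference.variants["id"]
    oth_ids = other.variants["id"]
    shared = ref_ids[ref_ids.isin(set(oth_ids))]
    ref_idx = ref_ids[ref_ids.isin(set(shared))].index.to_numpy()
    pos_in_other = pd.Series(oth_ids.index.values, index=oth_ids.values)
    oth_idx = pos_in_other[shared.values].to_numpy()

    a = reference.subset(variant_idx=ref_idx)
    b = other.subset(variant_idx=oth_idx)

    same = (a.variants["a1"].values == b.variants["a1"].values) & (
        a.variants["a2"].values == b.variants["a2"].values
    )
    swapped = (a.variants["a1"].values == b.variants["a2"].values) & (
        a.variants["a2"].values == b.variants["a1"].values
    )
    bad = ~(same | swapped)
    if bad.any():
        vid = a.variants["id"].values[bad][0]
        raise AlleleMismatchError(f"variant {vid!r}: alleles cannot be reconciled")

    flip_log = list(a.variants["id"].values[swapped & ~same])
    if flip_log:
        w = np.flatnonzero(swapped & ~same)
        b.calls[:, w] = flip_calls(b.calls[:, w])
        if b.haplotypes is not None:
            b.haplotypes[:, :, w] = 1 - b.haplotypes[:, :, w]
        b.variants.loc[b.variants.index[w], ["a1", "a2"]] = a.variants.iloc[w][
            ["a1", "a2"]
        ].values
    return a, b, flip_log


def merge_populations(datasets: list[GenotypeDataset]):
    """Merge datasets over their variant intersection with alleles aligned.

    Samples are concatenated (ids must be unique across inputs); variants
    are the id-intersection in the first dataset's order; A1/A2 swaps in
    later datasets flip calls 0 <-> 2 and are recorded in the returned
    per-dataset flip log.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    ref = datasets[0]
    aligned = []
    flip_logs = []
    for other in datasets[1:]:
        ref, b, log = align_alleles(ref, other)
        aligned = [d.subset(variant_idx=_variant_index(d, ref.variants["id"])) for d in aligned]
        aligned.append(b)
        flip_logs.append(log)
    parts = [ref] + aligned
    samples = pd.concat([d.samples for d in parts], ignore_index=True)
    calls = np.vstack([d.calls for d in parts])
    haps = None
    if all(d.haplotypes is not None for d in parts):
        haps = np.vstack([d.haplotypes for d in parts])
    merged = GenotypeDataset(samples, ref.variants.reset_index(drop=True), calls, haps)
    merged.validate()
    return merged, flip_logs


def _variant_index(data: GenotypeDataset, ids) -> np.ndarray:
    pos = pd.Series(np.arange(data.n_variants), index=data.variants["id"].values)
    return pos[list(ids)].to_numpy()


def require_min_population(data: GenotypeDataset, min_n: int = 50) -> GenotypeDataset:
    """Drop populations with fewer than ``min_n`` genotyped samples.

    Small-sample populations bias diversity metrics; studies typically
    gate them out at load time.
    """
    counts = data.samples["population"].value_counts()
    keep = set(counts[counts >= min_n].index)
    idx = np.flatnonzero(data.samples["population"].isin(keep).to_numpy())
    return data.subset(sample_idx=idx)


# -- pedigree -----------------------------------------------------------------

UNKNOWN_PARENT = "0"


@dataclasses.dataclass
class Pedigree:
    """Sire/dam records as a 3-column table (id, sire, dam; ``"0"`` unknown)."""

    records: pd.DataFrame  # columns: id, sire, dam (strings)

    def __post_init__(self):
        self.records = self.records.astype(str).reset_index(drop=True)
        if self.records["id"].duplicated().any():
            dup = self.records["id"][self.records["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate pedigree id {dup!r}")

    @property
    def ids(self) -> list[str]:
        return list(self.records["id"])

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.records["id"])
        for _, row in self.records.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent != UNKNOWN_PARENT:
                    g.add_edge(parent, row["id"])
        return g

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph()):
            cycle = nx.find_cycle(self.graph())
            raise ValueError(f"pedigree contains a cycle: {cycle}")

    def topological_order(self) -> list[str]:
        """All ids (including parents absent from the id column), parents first."""
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("pedigree contains a cycle")
        return list(nx.topological_sort(g))

    def parent_arrays(self):
        """Return (ids, sire_idx, dam_idx) in topological order, -1 = founder.

        Parents that never appear in the id column are treated as founders
        with unknown parents.
        """
        order = self.topological_order()
        index = {iid: k for k, iid in enumerate(order)}
        sire = np.full(len(order), -1, dtype=np.int64)
        dam = np.full(len(order), -1, dtype=np.int64)
        rec = self.records.set_index("id")
        for iid, k in index.items():
            if iid in rec.index:
                s, d = rec.loc[iid, "sire"], rec.loc[iid, "dam"]
                if s != UNKNOWN_PARENT:
                    sire[k] = index[s]
                if d != UNKNOWN_PARENT:
                    dam[k] = index[d]
        return order, sire, dam


def read_pedigree(path) -> Pedigree:
    """Read a whitespace-delimited 3-column pedigree file (id sire dam)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["id", "sire", "dam"], dtype=str)
    ped = Pedigree(df)
    ped.validate()
    return ped


def write_pedigree(ped: Pedigree, path) -> None:
    ped.records[["id", "sire", "dam"]].to_csv(path, sep="\t", header=False, index=False)
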