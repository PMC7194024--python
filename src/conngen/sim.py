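"""Forward-in-time Wright-Fisher simulator with recombination and pedigree.

The simulator emulates the data backing a multi-population SNP-array
study of livestock connectedness: diallelic autosomal markers on up to 26
chromosomes, several populations branching from a common ancestral
population at configurable times, effective sizes controlling LD and
drift, and a recorded pedigree over the final generations so that
pedigree-, marker- and ROH-based inbreeding can be validated against the
simulated truth.

Model
-----
* Founders are drawn in linkage equilibrium at frequencies sampled from a
  uniform founder-MAF distribution (standing variation only -- array
  markers, no new mutations).
* Each generation, individuals are paired monogamously at random (first
  half of a shuffled list are sires, second half dams; selfing is
  impossible) and every offspring draws a random couple, giving
  approximately Poisson litter sizes.
* Gametes recombine under the Haldane (no-interference) model: the
  crossover process is Poisson on the genetic map, realised as
  independent Bernoulli phase switches between adjacent markers with the
  map-distance recombination fraction.  A uniform map (bp proportional to
  Morgans) is used.
* Population splits copy nothing: each daughter population draws its
  first generation of parents from the ancestral pool and then evolves
  independently at its own effective size.

Every haplotype carries, alongside its alleles, the founder-haplotype id
at each marker; a diploid individual is autozygous wherever its two
ancestry tracks coincide.  These truth tracts make ROH and inbreeding
estimators exactly checkable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, Pedigree, make_dataset


@dataclasses.dataclass
class PopulationConfig:
    """A sampled (leaf) population: name, effective size, samples drawn."""

    name: str
    n_e: int = 200
    n_sampled: int = 100


@dataclasses.dataclass
class SimConfig:
    """Simulation scenario.

    ``topology`` is a nested tuple over population names giving split
    times in generations before present, e.g. ``(60, (20, "A", "B"), "C")``
    for C diverging 60 generations ago and A/B 20 generations ago.  A bare
    name simulates a single population.  ``burn_in_generations`` of
    ancestral drift before the root split let LD build up from the
    linkage-equilibrium founders; with the default marker density
    (200 SNPs per 1-Morgan chromosome) and ancestral size 200 the
    adjacent-marker r^2 settles near 1/(1 + 4 N c) ~ 0.2, the moderate
    level typical of HD-panel livestock data.
    """

    populations: list[PopulationConfig]
    topology: object
    n_chromosomes: int = 26
    snps_per_chromosome: int = 200
    chromosome_length_morgans: float = 1.0
    chromosome_length_bp: int = 100_000_000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    ancestral_n_e: int = 200
    burn_in_generations: int = 150
    pedigree_generations: int = 5
    seed: int = 0

    def population(self, name: str) -> PopulationConfig:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclasses.dataclass
class SimOutput:
    """Simulated genotypes, recorded pedigree, and ground truth.

    ``truth`` holds per-sampled-individual autozygosity tracts (IBD of the
    two haplotypes relative to the founder haplotypes) as
    ``{individual: [(chrom, start_bp, end_bp), ...]}``, and the final
    per-population A1 allele frequencies per SNP.
    """

    genotypes: GenotypeDataset
    pedigree: Pedigree
    truth: dict


class _PopState:
    """Haplotypes + founder-ancestry of one population, one generation."""

    def __init__(self, haps, anc, ids):
        self.haps = haps  # list per chromosome of (2N, L) int8
        self.anc = anc  # list per chromosome of (2N, L) int32
        self.ids = ids  # list of N individual id strings

    @property
    def n(self) -> int:
        return len(self.ids)


def _recomb_fractions(positions_bp, length_bp, length_morgans):
    """Haldane adjacent-marker recombination fractions on a uniform map."""
    d_morgans = np.diff(positions_bp) * (length_morgans / length_bp)
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def _snp_positions(config: SimConfig) -> list[np.ndarray]:
    """Evenly spaced 1-based positions per chromosome."""
    spacing = config.chromosome_length_bp // config.snps_per_chromosome
    pos = (np.arange(config.snps_per_chromosome, dtype=np.int64) * spacing) + 1
    return [pos.copy() for _ in range(config.n_chromosomes)]


def _gametes(haps_c, anc_c, parent_idx, r_adj, rng):
    """Vectorised recombinant gametes from one chromosome.

    ``parent_idx``: (G,) individual indices; returns (G, L) allele and
    ancestry arrays.  Phase is a start haplotype plus Bernoulli(r) switch
    at each inter-marker interval (Haldane model).
    """
    g = parent_idx.size
    length = haps_c.shape[1]
    start = rng.integers(0, 2, size=(g, 1))
    switches = rng.random((g, length - 1)) < r_adj
    parity = np.empty((g, length), dtype=np.int8)
    parity[:, 0] = start[:, 0]
    parity[:, 1:] = (start + np.cumsum(switches, axis=1)) % 2
    rows = 2 * parent_idx[:, None] + parity
    cols = np.arange(length)[None, :]
    return haps_c[rows, cols], anc_c[rows, cols]


def _next_generation(state: _PopState, n_offspring, r_adjs, rng, ids=None):
    """One generation of monogamous random mating; returns a new state.

    Returns the new state plus (sire_id, dam_id) per offspring.
    """
    n = state.n
    if n < 2:
        raise ValueError("population of one cannot reproduce without selfing")
    perm = rng.permutation(n)
    half = n // 2
    sires, dams = perm[:half], perm[half : 2 * half]
    couple = rng.integers(0, half, size=n_offspring)
    sire_idx, dam_idx = sires[couple], dams[couple]

    haps, anc = [], []
    for haps_c, anc_c, r_adj in zip(state.haps, state.anc, r_adjs):
        pat_h, pat_a = _gametes(haps_c, anc_c, sire_idx, r_adj, rng)
        mat_h, mat_a = _gametes(haps_c, anc_c, dam_idx, r_adj, rng)
        h = np.empty((2 * n_offspring, haps_c.shape[1]), dtype=np.int8)
        a = np.empty((2 * n_offspring, anc_c.shape[1]), dtype=np.int32)
        h[0::2], h[1::2] = pat_h, mat_h
        a[0::2], a[1::2] = pat_a, mat_a
        haps.append(h)
        anc.append(a)
    new_ids = ids if ids is not None else [None] * n_offspring
    parents = [(state.ids[s], state.ids[d]) for s, d in zip(sire_idx, dam_idx)]
    return _PopState(haps, anc, new_ids), parents


def _founder_state(config: SimConfig, rng) -> _PopState:
    n = config.ancestral_n_e
    low, high = config.founder_maf_range
    haps, anc = [], []
    next_anc = 0
    for c in range(config.n_chromosomes):
        length = config.snps_per_chromosome
        freqs = rng.uniform(low, high, size=length)
        h = (rng.random((2 * n, length)) < freqs).astype(np.int8)
        a = np.tile(
            np.arange(next_anc, next_anc + 2 * n, dtype=np.int32)[:, None], (1, length)
        )
        haps.append(h)
        anc.append(a)
    # ancestry ids are shared across chromosomes: haplotype k of founder i
    return _PopState(haps, anc, [f"anc_{i}" for i in range(n)])


def _leaf_events(topology, depth=None):
    """Flatten the topology into (name, split_time) leaves + split list."""
    if isinstance(topology, str):
        return [(topology, None)]
    t, left, right = topology
    out = []
    for child in (left, right):
        if isinstance(child, str):
            out.append((child, t))
        else:
            out.extend(
                (name, t if inner is None else inner) for name, inner in _leaf_events(child)
            )
    return out


def simulate(config: SimConfig) -> SimOutput:
    """Run the scenario and return phased genotypes, pedigree, and truth."""
    rng = np.random.default_rng(config.seed)
    positions = _snp_positions(config)
    r_adjs = [
        _recomb_fractions(p, config.chromosome_length_bp, config.chromosome_length_morgans)
        for p in positions
    ]

    root = _founder_state(config, rng)
    for _ in range(config.burn_in_generations):
        root, _ = _next_generation(root, config.ancestral_n_e, r_adjs, rng)

    leaf_states: dict[str, _PopState] = {}
    pedigree_rows: list[tuple[str, str, str]] = []

    def descend(node, state: _PopState, time_now: int):
        if isinstance(node, str):
            _evolve_leaf(node, state, time_now)
            return
        t_split, left, right = node
        # ancestral drift from time_now down to the split
        for _ in range(time_now - t_split):
            state, _ = _next_generation(state, config.ancestral_n_e, r_adjs, rng)
        descend(left, state, t_split)
        descend(right, state, t_split)

    def _evolve_leaf(name: str, state: _PopState, t: int):
        pop = config.population(name)
        recorded_from = config.pedigree_generations  # generations before present
        if t == 0:
            leaf_states[name] = state
            return
        for gen_before in range(t, 0, -1):
            gen_index = t - gen_before + 1
            record = gen_before <= recorded_from
            ids = [f"{name}_g{gen_index}_{i}" for i in range(pop.n_e)] if record else None
            state, parents = _next_generation(state, pop.n_e, r_adjs, rng, ids=ids)
            if record:
                for iid, (s, d) in zip(ids, parents):
                    known = s is not None and d is not None
                    pedigree_rows.append((iid, s if known else "0", d if known else "0"))
        leaf_states[name] = state

    root_time = 0 if isinstance(config.topology, str) else config.topology[0]
    descend(config.topology, root, root_time)

    return _assemble_output(config, positions, leaf_states, pedigree_rows, rng)


def _assemble_output(config, positions, leaf_states, pedigree_rows, rng) -> SimOutput:
    sample_haps, sample_anc, sample_ids, sample_pops = [], [], [], []
    parent_of = {iid: (s, d) for iid, s, d in pedigree_rows}
    allele_freqs = {}
    used: dict[int, set] = {}  # keyed by state object: two leaves split at t=0
    for pop_cfg in config.populations:  # share a pool and must sample disjointly
        state = leaf_states[pop_cfg.name]
        taken = used.setdefault(id(state), set())
        avail = np.array([i for i in range(state.n) if i not in taken])
        take = rng.choice(avail, size=min(pop_cfg.n_sampled, avail.size), replace=False)
        take.sort()
        taken.update(take.tolist())
        hap_rows = np.stack([2 * take, 2 * take + 1], axis=1).ravel()
        sample_haps.append([h[hap_rows] for h in state.haps])
        sample_anc.append([a[hap_rows] for a in state.anc])
        ids = [
            state.ids[i] if state.ids[i] is not None else f"{pop_cfg.name}_s{i}"
            for i in take
        ]
        sample_ids.extend(ids)
        sample_pops.extend([pop_cfg.name] * len(ids))
        freqs = np.concatenate([h.mean(axis=0) for h in state.haps])
        allele_freqs[pop_cfg.name] = freqs

    n_total = len(sample_ids)
    length = config.n_chromosomes * config.snps_per_chromosome
    haps = np.empty((n_total, 2, length), dtype=np.int8)
    anc = np.empty((n_total, 2, length), dtype=np.int32)
    row = 0
    for hs, ans in zip(sample_haps, sample_anc):
        k = hs[0].shape[0] // 2
        flat_h = np.hstack(hs)  # (2k, length)
        flat_a = np.hstack(ans)
        haps[row : row + k, 0, :] = flat_h[0::2]
        haps[row : row + k, 1, :] = flat_h[1::2]
        anc[row : row + k, 0, :] = flat_a[0::2]
        anc[row : row + k, 1, :] = flat_a[1::2]
        row += k

    chrom = np.repeat(
        [str(c + 1) for c in range(config.n_chromosomes)], config.snps_per_chromosome
    )
    pos = np.concatenate(positions)
    variant_ids = [f"chr{c}_{p}" for c, p in zip(chrom, pos)]
    calls = haps.sum(axis=1, dtype=np.int8)
    data = make_dataset(
        calls,
        pos=pos,
        chrom=chrom,
        populations=sample_pops,
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        haplotypes=haps,
    )
    # attach recorded parents where known
    sire = [parent_of.get(i, ("0", "0"))[0] for i in sample_ids]
    dam = [parent_of.get(i, ("0", "0"))[1] for i in sample_ids]
    data.samples["sire_id"] = sire
    data.samples["dam_id"] = dam

    ped = _close_pedigree(pedigree_rows)
    tracts = {
        iid: autozygous_tracts(anc[i], chrom, pos) for i, iid in enumerate(sample_ids)
    }
    truth = {"autozygosity": tracts, "allele_frequencies": allele_freqs}
    return SimOutput(data, ped, truth)


def _close_pedigree(rows) -> Pedigree:
    """Pedigree over recorded rows; referenced-but-unrecorded parents become founders."""
    known = {r[0] for r in rows}
    extra = []
    for _, s, d in rows:
        for p in (s, d):
            if p not in ("0", None) and p not in known:
                known.add(p)
                extra.append((p, "0", "0"))
    df = pd.DataFrame(extra + list(rows), columns=["id", "sire", "dam"])
    return Pedigree(df)


def autozygous_tracts(anc_pair: np.ndarray, chrom: np.ndarray, pos: np.ndarray):
    """Maximal runs where the two ancestry tracks agree, as (chrom, start, end) bp."""
    same = anc_pair[0] == anc_pair[1]
    tracts = []
    for c in pd.unique(chrom):
        sel = chrom == c
        s, p = same[sel], pos[sel]
        if s.size == 0:
            continue
        edges = np.flatnonzero(np.diff(s.astype(np.int8)))
        starts = np.r_[0, edges + 1]
        ends = np.r_[edges, s.size - 1]
        for a, b in zip(starts, ends):
            if s[a]:
                tracts.append((str(c), int(p[a]), int(p[b])))
    return tracts


def autozygous_fraction(tracts, chrom, pos, min_length_bp: int = 0) -> float:
    """Fraction of the SNP-covered genome inside truth tracts (optionally >= a length)."""
    spans = {}
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        spans[str(c)] = int(p.max() - p.min())
    total = sum(spans.values())
    covered = sum(
        e - s for c, s, e in tracts if e - s >= min_length_bp and spans.get(str(c), 0) > 0
    )
    return covered / total if total else 0.0


def plant_roh(
    data: GenotypeDataset,
    individual: str,
    chrom: str,
    start_bp: int,
    end_bp: int,
    truth: list | None = None,
) -> GenotypeDataset:
    """Force a homozygous tract by copying one haplotype over the other.

    Requires a phased dataset; flanking markers are untouched.  The tract
    is appended to ``truth`` (a list of ``(individual, chrom, start, end)``)
    when provided.  Raises ``ValueError`` if the span contains no SNP or
    lies outside the chromosome.
    """
    if not data.phased:
        raise ValueError("plant_roh requires a phased dataset")
    out = data.copy()
    srow = out.samples.index[out.samples["id"] == individual]
    if len(srow) != 1:
        raise KeyError(f"individual {individual!r} not found")
    i = int(srow[0])
    chrom_arr = out.variants["chrom"].astype(str).to_numpy()
    pos = out.variants["pos"].to_numpy()
    on_c = chrom_arr == str(chrom)
    if not on_c.any() or start_bp < pos[on_c].min() - 1 or end_bp > pos[on_c].max() + 1:
        raise ValueError("span outside chromosome")
    span = on_c & (pos >= start_bp) & (pos <= end_bp)
    if not span.any():
        raise ValueError("span contains no SNP")
    out.haplotypes[i, 1, span] = out.haplotypes[i, 0, span]
    out.calls[i, span] = 2 * out.haplotypes[i, 0, span]
    if truth is not None:
        truth.append((individual, str(chrom), int(start_bp), int(end_bp)))
    return out


def hwe_genotypes(n: int, m: int, maf_range=(0.05, 0.5), seed=0, rng=None) -> GenotypeDataset:
    """Random-mating Hardy-Weinberg genotypes: calls ~ Binomial(2, p_j).

    A direct sampling shortcut for calibration checks that do not need
    linkage or pedigree structure (all SNPs independent, no missingness).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    p = rng.uniform(*maf_range, size=m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return make_dataset(calls, pos=np.arange(1, m + 1) * 10_000)


def gene_drop(
    pedigree: Pedigree,
    n_chromosomes: int = 2,
    snps_per_chromosome: int = 200,
    chromosome_length_morgans: float = 1.0,
    chromosome_length_bp: int = 100_000_000,
    founder_maf_range=(0.05, 0.5),
    seed: int = 0,
):
    """Drop recombinant gametes through an arbitrary pedigree.

    Founders receive fresh linkage-equilibrium haplotypes with unique
    ancestry labels; every non-founder receives one recombinant gamete
    from each parent.  Returns ``(GenotypeDataset, truth_tracts)`` where
    the tracts are autozygosity truth per individual, enabling scripted
    matings (e.g. a full-sib cross with expected autozygous fraction 1/4).
    """
    rng = np.random.default_rng(seed)
    order, sire, dam = pedigree.parent_arrays()
    n = len(order)
    length = snps_per_chromosome
    spacing = chromosome_length_bp // length
    pos_c = (np.arange(length, dtype=np.int64) * spacing) + 1
    r_adj = _recomb_fractions(pos_c, chromosome_length_bp, chromosome_length_morgans)

    haps = np.empty((n, 2, n_chromosomes * length), dtype=np.int8)
    anc = np.empty((n, 2, n_chromosomes * length), dtype=np.int32)
    next_label = 0
    for c in range(n_chromosomes):
        freqs = rng.uniform(*founder_maf_range, size=length)
        sl = slice(c * length, (c + 1) * length)
        for k in range(n):  # parent_arrays already yields parents-first order
            for side, parent in ((0, sire[k]), (1, dam[k])):
                if parent < 0:
                    haps[k, side, sl] = (rng.random(length) < freqs).astype(np.int8)
                    anc[k, side, sl] = next_label
                    next_label += 1
                else:
                    h, a = _transmit(
                        haps[parent, :, sl], anc[parent, :, sl], r_adj, rng
                    )
                    haps[k, side, sl] = h
                    anc[k, side, sl] = a

    chrom = np.repeat([str(c + 1) for c in range(n_chromosomes)], length)
    pos = np.concatenate([pos_c] * n_chromosomes)
    data = make_dataset(
        haps.sum(axis=1, dtype=np.int8),
        pos=pos,
        chrom=chrom,
        sample_ids=order,
        variant_ids=[f"chr{c}_{p}" for c, p in zip(chrom, pos)],
        haplotypes=haps,
    )
    tracts = {iid: autozygous_tracts(anc[k], chrom, pos) for k, iid in enumerate(order)}
    return data, tracts


def study_config(seed: int = 0) -> SimConfig:
    """Reference three-population scenario used by the analysis scripts.

    Emulates the shape of a multi-breed sheep panel study: a large main
    composite population (NWS-like), a small bottlenecked breed that
    diverged early (FIN-like, high LD and inbreeding), and a large
    composite that split recently (PRI-like, low LD).  Four 30-Mb
    chromosomes carry a dense 15-kb raw marker grid; running
    :func:`ascertain_panel` afterwards keeps the jointly common markers,
    emulating array design and leaving a panel whose spacing supports the
    kb-scale ROH density rules.  Effective sizes are desk-scale, so LD
    and drift levels sit above a real HD-panel study; the orderings
    between populations (LD, phase consistency, inbreeding) are the
    features this scenario preserves.
    """
    return SimConfig(
        populations=[
            PopulationConfig("NWS", n_e=200, n_sampled=80),
            PopulationConfig("FIN", n_e=40, n_sampled=50),
            PopulationConfig("PRI", n_e=300, n_sampled=80),
        ],
        topology=(80, (30, "NWS", "PRI"), "FIN"),
        n_chromosomes=4,
        snps_per_chromosome=2000,
        chromosome_length_morgans=1.0,
        chromosome_length_bp=30_000_000,
        founder_maf_range=(0.05, 0.5),
        ancestral_n_e=150,
        burn_in_generations=150,
        pedigree_generations=8,
        seed=seed,
    )


def ascertain_panel(data: GenotypeDataset, maf_min: float = 0.05) -> GenotypeDataset:
    """Emulate SNP-array design: keep markers common in the pooled sample.

    Array SNPs are chosen to segregate across the target breeds; applying
    this pooled-MAF screen to raw simulated markers removes the variants
    drift has fixed, which a chip would never have carried.
    """
    calls = data.calls
    called = calls != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called, calls, 0).sum(axis=0) / (2.0 * called.sum(axis=0))
    maf = np.minimum(freq, 1 - freq)
    return data.subset(variant_idx=np.flatnonzero(maf >= maf_min))


def _transmit(hap_pair, anc_pair, r_adj, rng):
    """One recombinant gamete from a (2, L) haplotype/ancestry pair."""
    length = hap_pair.shape[1]
    parity = np.empty(length, dtype=np.int8)
    parity[0] = rng.integers(0, 2)
    switches = rng.random(length - 1) < r_adj
    parity[1:] = (parity[0] + np.cumsum(switches)) % 2
    cols = np.arange(length)
    return hap_pair[parity, cols], anc_pair[parity, cols]
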