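"""Synthetic colonies, nest maps and mtDNA transects.

The generator produces data with the statistical structure the downstream
analyses assume: strictly monogynous colonies headed by a queen mated to one
or more males with fixed offspring contributions, haploid males (queen sons
or, in queenless nests, worker sons), sexually produced alate females, nest
coordinates in a square plot, and two-group mtDNA haplotype transects.

Every simulated colony carries a hidden-truth record (queen genotype, father
haplotypes, per-offspring father index) so recovery tests can score inference
against ground truth without leaking it into the analysis-facing tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import GenotypeTable, HaplotypeAlignment, table_from_records, MISSING

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusSpec:
    """A codominant locus: integer allele sizes (bp) and their frequencies."""

    name: str
    alleles: tuple[int, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(int(a) for a in self.alleles))
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        if len(self.alleles) != len(self.frequencies):
            raise ValueError(f"locus {self.name}: alleles/frequencies length mismatch")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name}: allele sizes not distinct")
        if any(f < 0 for f in self.frequencies):
            raise ValueError(f"locus {self.name}: negative frequency")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError(f"locus {self.name}: frequencies sum to {sum(self.frequencies)}")


@dataclass(frozen=True)
class ColonySpec:
    """Pedigree layout of one monogynous colony.

    ``contributions`` are per-father offspring counts covering workers and
    alate females (both sexually produced).  Worker-son males require the
    colony to be queenless (laying workers).
    """

    n_workers: int
    contributions: tuple[int, ...]
    queenless: bool = False
    n_queen_son_males: int = 0
    n_worker_son_males: int = 0
    n_alate_females: int = 0
    n_thelytokous_females: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "contributions", tuple(int(c) for c in self.contributions))
        if not self.contributions or any(c <= 0 for c in self.contributions):
            raise ValueError("contributions must be a non-empty vector of positive counts")
        if sum(self.contributions) != self.n_workers + self.n_alate_females:
            raise ValueError(
                "contributions must sum to n_workers + n_alate_females "
                f"({sum(self.contributions)} != {self.n_workers + self.n_alate_females})"
            )
        if self.n_worker_son_males and not self.queenless:
            raise ValueError("worker-son males only allowed in queenless colonies")
        if self.n_workers < 0 or min(
            self.n_queen_son_males, self.n_worker_son_males, self.n_alate_females,
            self.n_thelytokous_females,
        ) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_fathers(self) -> int:
        return len(self.contributions)


@dataclass(frozen=True)
class PlotSpec:
    side_length: float
    n_nests: int
    placement: str = "random"
    seed: int = 0
    cluster_parents: int = 5
    cluster_sigma_frac: float = 0.05  # displacement sd as a fraction of side

    def __post_init__(self) -> None:
        if self.n_nests < 2:
            raise ValueError("n_nests must be >= 2")
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.placement not in ("random", "grid", "clustered"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class TransectSpec:
    n_sites: int
    site_spacing: float  # km between neighbouring sites
    n_groups: int = 2
    samples_per_site: int = 2
    mutation_steps_within: int = 1
    mutation_steps_between: int = 14
    seq_length: int = 622
    haplotypes_per_group: int = 3

    def __post_init__(self) -> None:
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        if self.mutation_steps_between < self.mutation_steps_within:
            raise ValueError("between-group steps must be >= within-group steps")
        if self.n_sites < self.n_groups:
            raise ValueError("need at least one site per group")
        total_steps = (
            (self.n_groups - 1) * self.mutation_steps_between
            + self.n_groups * (self.haplotypes_per_group - 1) * self.mutation_steps_within
        )
        if total_steps > self.seq_length:
            raise ValueError("requested mutation steps exceed sequence length")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class ColonyTruth:
    """Hidden ground truth for one simulated colony (sidecar, not analysis input)."""

    queen: dict[str, tuple[int, int]]
    fathers: list[dict[str, int]]
    father_of: dict[str, int]  # offspring id -> father index
    worker_mother_of: dict[str, str]  # worker-son male id -> mother worker id

    def to_jsonable(self) -> dict:
        return {
            "queen": {l: list(g) for l, g in self.queen.items()},
            "fathers": [dict(f) for f in self.fathers],
            "father_of": dict(self.father_of),
            "worker_mother_of": dict(self.worker_mother_of),
        }


@dataclass
class Colony:
    colony_id: str
    table: GenotypeTable
    truth: ColonyTruth
    x: float = 0.0
    y: float = 0.0
    queenless: bool = False


@dataclass
class TransectSample:
    alignment: HaplotypeAlignment
    site_of: dict[str, int]
    group_of: dict[str, int]
    site_positions_km: np.ndarray
    distance_km: np.ndarray  # per-sequence pairwise geographic distances


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------


def make_locus_panel(
    n_loci: int,
    allele_count_range: tuple[int, int] = (4, 13),
    seed: int | None = None,
    concentration: float = 1.0,
) -> list[LocusSpec]:
    """Draw a microsatellite-like locus panel.

    Allele counts are uniform over ``allele_count_range``; frequencies come
    from a symmetric Dirichlet.  Allele sizes are distinct even integers in a
    per-locus band, mimicking size ranges in bp (the sizes are pure labels).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    lo, hi = allele_count_range
    if not (2 <= lo <= hi <= 30):
        raise ValueError(f"allele_count_range must lie within [2, 30], got {allele_count_range}")
    rng = np.random.default_rng(seed)
    panel = []
    for j in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        base = 90 + 40 * j
        alleles = tuple(base + 2 * i for i in range(k))
        freqs = rng.dirichlet(np.full(k, concentration))
        panel.append(LocusSpec(name=f"L{j + 1:02d}", alleles=alleles, frequencies=tuple(freqs)))
    return panel


def draw_haploid(panel: list[LocusSpec], rng: np.random.Generator) -> dict[str, int]:
    return {
        spec.name: int(rng.choice(spec.alleles, p=spec.frequencies)) for spec in panel
    }


def draw_diploid(panel: list[LocusSpec], rng: np.random.Generator) -> dict[str, tuple[int, int]]:
    geno = {}
    for spec in panel:
        a, b = rng.choice(spec.alleles, size=2, replace=True, p=spec.frequencies)
        geno[spec.name] = (int(a), int(b))
    return geno


# ---------------------------------------------------------------------------
# Colony simulation
# ---------------------------------------------------------------------------


def simulate_colony(
    panel: list[LocusSpec],
    spec: ColonySpec,
    seed: int | np.random.Generator | None = None,
    colony_id: str = "C01",
    x: float = 0.0,
    y: float = 0.0,
    missing_rate: float = 0.0,
) -> Colony:
    """Simulate one monogynous colony under Mendelian transmission.

    Diploid offspring get one uniformly chosen queen allele plus their
    father's allele at every locus.  Queen-son males get one queen allele per
    locus; worker-son males get one allele of a randomly chosen worker.
    Thelytokous females copy the queen exactly.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = [s.name for s in panel]

    queen = draw_diploid(panel, rng)
    fathers = [draw_haploid(panel, rng) for _ in range(spec.n_fathers)]

    father_idx = np.repeat(np.arange(spec.n_fathers), spec.contributions)
    rng.shuffle(father_idx)

    records: list[dict] = []
    truth_father: dict[str, int] = {}
    truth_worker_mother: dict[str, str] = {}

    def offspring_genotype(fidx: int) -> dict[str, tuple[int, int]]:
        geno = {}
        for locus in loci:
            qa = queen[locus][int(rng.integers(2))]
            geno[locus] = tuple(sorted((qa, fathers[fidx][locus])))
        return geno

    if not spec.queenless:
        records.append(
            {"id": f"{colony_id}-Q", "colony": colony_id, "caste": "queen", "ploidy": 2,
             "genotype": {l: tuple(sorted(queen[l])) for l in loci}}
        )

    worker_ids = []
    for i in range(spec.n_workers):
        wid = f"{colony_id}-W{i + 1:03d}"
        fidx = int(father_idx[i])
        records.append(
            {"id": wid, "colony": colony_id, "caste": "worker", "ploidy": 2,
             "genotype": offspring_genotype(fidx)}
        )
        truth_father[wid] = fidx
        worker_ids.append(wid)

    for i in range(spec.n_alate_females):
        aid = f"{colony_id}-F{i + 1:03d}"
        fidx = int(father_idx[spec.n_workers + i])
        records.append(
            {"id": aid, "colony": colony_id, "caste": "alate_female", "ploidy": 2,
             "genotype": offspring_genotype(fidx)}
        )
        truth_father[aid] = fidx

    for i in range(spec.n_thelytokous_females):
        records.append(
            {"id": f"{colony_id}-T{i + 1:03d}", "colony": colony_id, "caste": "alate_female",
             "ploidy": 2, "genotype": {l: tuple(sorted(queen[l])) for l in loci}}
        )

    for i in range(spec.n_queen_son_males):
        geno = {l: (queen[l][int(rng.integers(2))],) for l in loci}
        records.append(
            {"id": f"{colony_id}-M{i + 1:03d}", "colony": colony_id, "caste": "male",
             "ploidy": 1, "genotype": geno}
        )

    for i in range(spec.n_worker_son_males):
        mother = worker_ids[int(rng.integers(len(worker_ids)))]
        mother_geno = next(r["genotype"] for r in records if r["id"] == mother)
        geno = {l: (mother_geno[l][int(rng.integers(2))],) for l in loci}
        mid = f"{colony_id}-WM{i + 1:03d}"
        records.append(
            {"id": mid, "colony": colony_id, "caste": "male", "ploidy": 1, "genotype": geno}
        )
        truth_worker_mother[mid] = mother

    if missing_rate > 0:
        for rec in records:
            for locus in loci:
                if rng.random() < missing_rate:
                    rec["genotype"][locus] = (MISSING,) * rec["ploidy"]

    table = table_from_records(records, loci)
    truth = ColonyTruth(
        queen={l: tuple(sorted(queen[l])) for l in loci},
        fathers=fathers,
        father_of=truth_father,
        worker_mother_of=truth_worker_mother,
    )
    return Colony(colony_id=colony_id, table=table, truth=truth, x=x, y=y,
                  queenless=spec.queenless)


# ---------------------------------------------------------------------------
# Plot simulation
# ---------------------------------------------------------------------------


def place_nests(plot: PlotSpec) -> np.ndarray:
    """Nest coordinates under the requested placement model, shape (n, 2)."""
    rng = np.random.default_rng(plot.seed)
    n, side = plot.n_nests, plot.side_length
    if plot.placement == "random":
        return rng.uniform(0, side, size=(n, 2))
    if plot.placement == "grid":
        m = math.ceil(math.sqrt(n))
        spacing = side / m
        pts = [
            ((i + 0.5) * spacing, (j + 0.5) * spacing)
            for j in range(m)
            for i in range(m)
        ]
        return np.array(pts[:n])
    # clustered: Thomas-style parents with Gaussian offspring displacement
    parents = rng.uniform(0, side, size=(plot.cluster_parents, 2))
    idx = rng.integers(plot.cluster_parents, size=n)
    pts = parents[idx] + rng.normal(0, plot.cluster_sigma_frac * side, size=(n, 2))
    return np.clip(pts, 0, side)


def simulate_plot(
    panel: list[LocusSpec],
    plot: PlotSpec,
    colony_template: ColonySpec,
    missing_rate: float = 0.0,
) -> list[Colony]:
    """Independent colonies (no spatial genetic autocorrelation) on a plot."""
    coords = place_nests(plot)
    rng = np.random.default_rng(plot.seed + 1)
    colonies = []
    for i, (x, y) in enumerate(coords):
        colonies.append(
            simulate_colony(
                panel, colony_template, seed=rng, colony_id=f"N{i + 1:03d}",
                x=float(x), y=float(y), missing_rate=missing_rate,
            )
        )
    return colonies


def combine_colonies(colonies: list[Colony]) -> GenotypeTable:
    """Stack per-colony tables into one GenotypeTable."""
    import pandas as pd

    loci = colonies[0].table.loci
    df = pd.concat([c.table.data for c in colonies], ignore_index=True)
    return GenotypeTable(df, loci)


# ---------------------------------------------------------------------------
# mtDNA transect simulation
# ---------------------------------------------------------------------------


def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for s in sites:
        alternatives = _BASES[_BASES != out[s]]
        out[s] = rng.choice(alternatives)
    return out


def simulate_transect_mtdna(spec: TransectSpec, seed: int | None = None) -> TransectSample:
    """Two-or-more-group haplotype transect with built-in isolation by distance.

    Group ancestors diverge sequentially by ``mutation_steps_between`` exact
    substitutions at fresh sites; within-group haplotypes add
    ``mutation_steps_within`` private substitutions each.  Per-site samples
    are drawn from the site's group haplotype pool.
    """
    rng = np.random.default_rng(seed)
    L = spec.seq_length
    ancestral = rng.choice(_BASES, size=L)

    free_sites = rng.permutation(L)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        sites = free_sites[cursor:cursor + k]
        cursor += k
        return sites

    group_pools: list[list[np.ndarray]] = []
    anc = ancestral
    for g in range(spec.n_groups):
        if g > 0:
            anc = _mutate(anc, take(spec.mutation_steps_between), rng)
        pool = [anc]
        for _ in range(spec.haplotypes_per_group - 1):
            pool.append(_mutate(anc, take(spec.mutation_steps_within), rng))
        group_pools.append(pool)

    # contiguous site blocks per group along the transect
    bounds = np.linspace(0, spec.n_sites, spec.n_groups + 1).astype(int)
    group_of_site = np.zeros(spec.n_sites, dtype=int)
    for g in range(spec.n_groups):
        group_of_site[bounds[g]:bounds[g + 1]] = g

    positions = np.arange(spec.n_sites) * spec.site_spacing
    ids, seqs, site_of, group_of = [], [], {}, {}
    for s in range(spec.n_sites):
        g = int(group_of_site[s])
        pool = group_pools[g]
        for i in range(spec.samples_per_site):
            sid = f"S{s + 1:02d}-{i + 1}"
            hap = pool[int(rng.integers(len(pool)))]
            ids.append(sid)
            seqs.append("".join(hap))
            site_of[sid] = s
            group_of[sid] = g

    aln = HaplotypeAlignment(ids=tuple(ids), sequences=tuple(seqs))
    pos = np.array([positions[site_of[i]] for i in ids])
    dist = np.abs(pos[:, None] - pos[None, :])
    return TransectSample(
        alignment=aln,
        site_of=site_of,
        group_of=group_of,
        site_positions_km=positions,
        distance_km=dist,
    )
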