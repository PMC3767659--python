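"""Pedigree inference inside monogynous colonies.

Queen reconstruction, matriline/patriline assignment, mating-frequency
estimators and their non-detection probabilities, male/female parentage
classification and Queller–Goodnight relatedness with jackknife errors.

Genotypes are dicts mapping locus name to an allele tuple: length 2 for
diploids (sorted), length 1 for haploid males; the allele value 0 means
missing and the locus is then skipped for that individual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io import GenotypeTable, MISSING

Genotype = dict[str, tuple[int, ...]]


class MonogynyViolation(ValueError):
    """No single queen genotype can explain all workers at some locus."""

    def __init__(self, locus: str, message: str | None = None):
        self.locus = locus
        super().__init__(message or f"monogyny violated at locus {locus!r}")


class MendelError(ValueError):
    """An offspring shares no allele with the queen at an informative locus."""


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class QueenReconstruction:
    genotype: Genotype
    co_optimal: list[Genotype]
    m_p: int
    observed: bool

    @property
    def ambiguous(self) -> bool:
        return len(self.co_optimal) > 1


@dataclass
class PatrilineResult:
    fathers: list[dict[str, int]]  # haploid genotypes, lexicographically ordered
    assignment: dict[str, int]  # worker id -> father index
    contributions: tuple[int, ...]
    status: str = "ok"  # "ok" | "not_solved"

    @property
    def m_p(self) -> int:
        return len(self.fathers)


@dataclass
class RelatednessEstimate:
    r: float
    se_jackknife: float
    n_groups: int
    status: str = "ok"  # "ok" | "undefined"


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _typed(geno: Genotype, locus: str) -> bool:
    return locus in geno and geno[locus][0] != MISSING


def shares_queen_allele(offspring: Genotype, queen: Genotype, locus: str) -> bool:
    return bool(set(offspring[locus]) & set(queen[locus]))


def paternal_allele_sets(
    worker: Genotype, queen: Genotype, loci: list[str]
) -> dict[str, frozenset[int] | None]:
    """Per-locus candidate paternal alleles of a diploid offspring.

    ``None`` marks an uninformative locus (missing data).  When the worker
    shares both alleles with the queen the paternal allele is ambiguous
    within the worker's own pair; the ambiguity is resolved later, inside the
    patriline minimisation.
    """
    out: dict[str, frozenset[int] | None] = {}
    for locus in loci:
        if not _typed(worker, locus) or not _typed(queen, locus):
            out[locus] = None
            continue
        w1, w2 = worker[locus]
        q = set(queen[locus])
        in1, in2 = w1 in q, w2 in q
        if in1 and in2:
            out[locus] = frozenset((w1, w2))
        elif in1:
            out[locus] = frozenset((w2,))
        elif in2:
            out[locus] = frozenset((w1,))
        else:
            raise MendelError(
                f"offspring shares no allele with queen at locus {locus!r}"
            )
    return out


# ---------------------------------------------------------------------------
# Patriline inference (exact minimum father cover)
# ---------------------------------------------------------------------------


def infer_patrilines(
    workers: dict[str, Genotype],
    queen: Genotype,
    max_nodes: int = 2_000_000,
) -> PatrilineResult:
    """Minimum number of haploid fathers explaining all workers (exact search).

    Branch and bound over worker→father assignments: a father is a per-locus
    allele constraint set (intersection of his workers' candidate paternal
    alleles); a worker joins a father only if every locus intersection stays
    non-empty.  The search is exhaustive with admissible pruning, so the
    returned father count is the true minimum.  Ties are broken
    deterministically (first optimum in a fixed DFS order; father haplotypes
    reported with the smallest allele of each final constraint set, ordered
    lexicographically).
    """
    loci = sorted({l for g in workers.values() for l in g})
    ids = sorted(workers)
    psets = {wid: paternal_allele_sets(workers[wid], queen, loci) for wid in ids}

    # most-constrained workers first: stronger pruning, still deterministic
    def ambiguity(wid: str) -> tuple:
        s = psets[wid]
        return (-sum(1 for l in loci if s[l] is not None and len(s[l]) == 1), wid)

    order = sorted(ids, key=ambiguity)

    best_k = len(order) + 1
    best_assignment: list[int] | None = None
    best_fathers: list[dict[str, frozenset[int] | None]] | None = None
    nodes = 0
    overflow = False

    fathers: list[dict[str, frozenset[int] | None]] = []
    assignment: list[int] = []

    def compatible(father, wset):
        merged = {}
        for locus in loci:
            f, w = father[locus], wset[locus]
            if f is None:
                merged[locus] = w
            elif w is None:
                merged[locus] = f
            else:
                inter = f & w
                if not inter:
                    return None
                merged[locus] = inter
        return merged

    def dfs(i: int) -> None:
        nonlocal best_k, best_assignment, best_fathers, nodes, overflow
        if overflow:
            return
        nodes += 1
        if nodes > max_nodes:
            overflow = True
            return
        if len(fathers) >= best_k:
            return
        if i == len(order):
            best_k = len(fathers)
            best_assignment = list(assignment)
            best_fathers = [dict(f) for f in fathers]
            return
        wset = psets[order[i]]
        for j in range(len(fathers)):
            merged = compatible(fathers[j], wset)
            if merged is not None:
                saved = fathers[j]
                fathers[j] = merged
                assignment.append(j)
                dfs(i + 1)
                assignment.pop()
                fathers[j] = saved
        if len(fathers) + 1 < best_k:
            fathers.append(dict(wset))
            assignment.append(len(fathers) - 1)
            dfs(i + 1)
            assignment.pop()
            fathers.pop()

    dfs(0)

    if best_assignment is None:
        return PatrilineResult(fathers=[], assignment={}, contributions=(), status="not_solved")

    # materialise father haplotypes: smallest allele of each constraint set
    raw = []
    for j, f in enumerate(best_fathers):
        hap = {}
        for locus in loci:
            s = f[locus]
            if s is None:
                hap[locus] = MISSING  # unconstrained at this locus
            else:
                hap[locus] = min(s)
        raw.append((hap, [order[i] for i, a in enumerate(best_assignment) if a == j]))

    raw.sort(key=lambda item: ([item[0][l] for l in loci], item[1]))
    fathers_out = [hap for hap, _ in raw]
    assignment_out = {}
    for j, (_, members) in enumerate(raw):
        for wid in members:
            assignment_out[wid] = j
    contributions = tuple(len(members) for _, members in raw)
    # an overflowed search may have returned a feasible but non-minimal cover
    status = "not_solved" if overflow else "ok"
    return PatrilineResult(
        fathers=fathers_out, assignment=assignment_out, contributions=contributions,
        status=status,
    )


# ---------------------------------------------------------------------------
# Queen reconstruction
# ---------------------------------------------------------------------------


def reconstruct_queen(
    workers: dict[str, Genotype],
    observed: Genotype | None = None,
    max_combinations: int = 4096,
) -> QueenReconstruction:
    """Reconstruct the (single) queen genotype from diploid worker genotypes.

    If a queen was observed, her genotype is verified against every worker
    (each must share at least one allele per typed locus) and returned.
    Otherwise all per-locus queen allele pairs consistent with every worker
    are enumerated and the cross-locus combination minimising the resulting
    minimum father count is selected; co-optimal solutions are returned with
    a deterministic tie-break (lexicographically smallest allele pairs).
    """
    if len(workers) < 2 and observed is None:
        raise ValueError("need at least 2 workers to reconstruct a queen")
    loci = sorted({l for g in workers.values() for l in g})

    if observed is not None:
        for wid, geno in workers.items():
            for locus in loci:
                if not _typed(geno, locus) or not _typed(observed, locus):
                    continue
                if not shares_queen_allele(geno, observed, locus):
                    raise MonogynyViolation(
                        locus,
                        f"worker {wid!r} shares no allele with the observed queen at "
                        f"locus {locus!r} (monogyny violated)",
                    )
        res = infer_patrilines(workers, observed)
        return QueenReconstruction(
            genotype=observed, co_optimal=[observed], m_p=res.m_p, observed=True
        )

    candidates_per_locus: dict[str, list[tuple[int, int]]] = {}
    for locus in loci:
        typed = [g[locus] for g in workers.values() if _typed(g, locus)]
        if not typed:
            candidates_per_locus[locus] = [(MISSING, MISSING)]
            continue
        alleles = sorted({a for pair in typed for a in pair})
        cands = []
        for x, y in itertools.combinations_with_replacement(alleles, 2):
            q = {x, y}
            if all(set(pair) & q for pair in typed):
                cands.append((x, y))
        if not cands:
            raise MonogynyViolation(locus)
        candidates_per_locus[locus] = cands

    def forced_paternal_count(locus: str, pair: tuple[int, int]) -> int:
        # lower bound on distinct paternal alleles this queen pair forces
        q = set(pair)
        forced = set()
        for g in workers.values():
            if not _typed(g, locus):
                continue
            w1, w2 = g[locus]
            in1, in2 = w1 in q, w2 in q
            if in1 and in2:
                continue
            forced.add(w2 if in1 else w1)
        return len(forced)

    # keep search tractable: prefilter to per-locus minimal forced paternal counts
    total = 1
    for locus in loci:
        total *= len(candidates_per_locus[locus])
    if total > max_combinations:
        for locus in loci:
            cands = candidates_per_locus[locus]
            scored = [(forced_paternal_count(locus, c), c) for c in cands]
            m = min(s for s, _ in scored)
            candidates_per_locus[locus] = [c for s, c in scored if s == m]
        total = 1
        for locus in loci:
            total *= len(candidates_per_locus[locus])
    if total > max_combinations:
        # final truncation, documented fallback: lexicographically first pairs
        for locus in loci:
            candidates_per_locus[locus] = candidates_per_locus[locus][:2]

    def ambiguity_count(queen: Genotype) -> int:
        # (worker, locus) pairs whose paternal allele stays ambiguous: a
        # heterozygous worker sharing both alleles with the queen.  Among
        # co-optimal queens the true genotype leaves the fewest such pairs
        # (an alternative that swaps a paternal allele into the queen pair
        # turns that patriline's workers ambiguous), so this is the primary
        # deterministic tie-break.
        total = 0
        for g in workers.values():
            for locus in loci:
                if not _typed(g, locus):
                    continue
                w1, w2 = g[locus]
                q = set(queen[locus])
                if w1 != w2 and w1 in q and w2 in q:
                    total += 1
        return total

    best_mp: int | None = None
    best_lb = None
    co_optimal: list[Genotype] = []

    def forced_lower_bound(queen: Genotype) -> int:
        return max(forced_paternal_count(l, queen[l]) for l in loci)

    combos = [
        {l: pair for l, pair in zip(loci, combo)}
        for combo in itertools.product(*(candidates_per_locus[l] for l in loci))
    ]
    combos.sort(key=lambda q: _queen_tie_key(q, loci, ambiguity_count))
    for queen in combos:
        if best_mp is not None and forced_lower_bound(queen) > best_mp:
            continue
        try:
            res = infer_patrilines(workers, queen)
        except MendelError:  # pragma: no cover - filtered candidates are consistent
            continue
        if res.status != "ok":
            continue
        if best_mp is None or res.m_p < best_mp:
            best_mp = res.m_p
            co_optimal = [queen]
        elif res.m_p == best_mp:
            co_optimal.append(queen)
    if best_mp is None:
        raise MonogynyViolation(loci[0], "no consistent queen genotype found")
    co_optimal.sort(key=lambda q: _queen_tie_key(q, loci, ambiguity_count))
    return QueenReconstruction(
        genotype=co_optimal[0], co_optimal=co_optimal, m_p=best_mp, observed=False
    )


def _queen_tie_key(queen: Genotype, loci: list[str], ambiguity_count) -> tuple:
    """Deterministic ordering of co-optimal queen genotypes.

    Primary: fewest ambiguous (worker, locus) paternal assignments — swapping
    a paternal allele into the queen pair makes a whole patriline ambiguous
    while the true queen explains those workers without any ambiguity.
    Secondary: fewest heterozygous queen loci — a heterozygous alternative at
    a homozygous-queen locus requires independent fathers to coincide in
    allele, the less parsimonious explanation.  Final: lexicographic pairs.
    """
    n_het = sum(queen[l][0] != queen[l][1] for l in loci)
    return (ambiguity_count(queen), n_het, [queen[l] for l in loci])


# ---------------------------------------------------------------------------
# Matriline assignment
# ---------------------------------------------------------------------------


def assign_matrilines(
    offspring: dict[str, Genotype], queen: Genotype
) -> dict[str, str]:
    """Flag each individual as same_matriline / different_matriline / uninformative.

    An individual belongs to a different matriline iff it shares zero alleles
    with the queen at one or more typed loci; loci with missing data are
    skipped, and individuals with no typed locus are uninformative.
    """
    out = {}
    for oid, geno in offspring.items():
        informative = False
        different = False
        for locus in geno:
            if not _typed(geno, locus) or not _typed(queen, locus):
                continue
            informative = True
            if not shares_queen_allele(geno, queen, locus):
                different = True
                break
        if not informative:
            out[oid] = "uninformative"
        else:
            out[oid] = "different_matriline" if different else "same_matriline"
    return out


# ---------------------------------------------------------------------------
# Mating-frequency estimators
# ---------------------------------------------------------------------------


def effective_paternity(contributions) -> float:
    """Skew-corrected effective number of matings from offspring counts.

    ``contributions`` are the per-father offspring counts (or proportions,
    in which case the total offspring number cannot be recovered and counts
    are required instead).  Uses the sample-size-corrected estimator

        M_e,p = (n-1)^2 / [ sum(p_i^2) (n+1)(n-2) + 3 - n ]

    which is unbiased under unequal male contributions and exceeds the raw
    father count k when correcting small-sample bias.
    """
    counts = np.asarray(list(contributions), dtype=float)
    if counts.size == 0:
        raise ValueError("empty contribution vector")
    if (counts < 0).any():
        raise ValueError("negative contributions")
    n = counts.sum()
    if n < 3:
        raise ValueError(f"effective paternity undefined for n={int(n)} (< 3 offspring)")
    p = counts / n
    denom = (p ** 2).sum() * (n + 1) * (n - 2) + 3 - n
    return float((n - 1) ** 2 / denom)


def nondetect_two_males(frequencies_by_locus) -> float:
    """Probability that two independent mates share alleles at every locus.

    ``frequencies_by_locus`` is an iterable of per-locus frequency vectors
    (each summing to 1).  Equals the product over loci of the haploid
    identity-by-chance sum(f^2).
    """
    prob = 1.0
    for freqs in frequencies_by_locus:
        f = np.asarray(list(freqs), dtype=float)
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequencies sum to {f.sum()}, not 1")
        prob *= float((f ** 2).sum())
    return prob


def nondetect_worker_son(proportions, informative_loci) -> float:
    """Probability a worker's son shows only queen alleles by chance.

    ``proportions`` are patriline contributions p_i (summing to 1) and
    ``informative_loci`` the per-patriline counts l_i of loci at which the
    patriline's paternal allele is distinguishable from the queen's:

        P = sum_i p_i (1/2)^{l_i}
    """
    p = np.asarray(list(proportions), dtype=float)
    l = np.asarray(list(informative_loci), dtype=float)
    if p.size != l.size:
        raise ValueError("proportions / informative loci length mismatch")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    if (l < 0).any() or not np.allclose(l, np.round(l)):
        raise ValueError("informative locus counts must be non-negative integers")
    return float((p * 0.5 ** l).sum())


def informative_locus_counts(
    fathers: list[dict[str, int]], queen: Genotype
) -> list[int]:
    """l_i per patriline: loci where the paternal allele is not a queen allele."""
    counts = []
    for hap in fathers:
        li = 0
        for locus, allele in hap.items():
            if allele == MISSING or not _typed(queen, locus):
                continue
            if allele not in queen[locus]:
                li += 1
        counts.append(li)
    return counts


# ---------------------------------------------------------------------------
# Male / female parentage classification
# ---------------------------------------------------------------------------


@dataclass
class MaleClassification:
    classes: dict[str, str]  # male id -> "queen_son" | "worker_son" | "uninformative"
    group_criterion_ok: bool
    group_violating_loci: list[str]


def classify_males(males: dict[str, Genotype], queen: Genotype) -> MaleClassification:
    """Classify haploid males as queen sons or worker sons.

    A male is a worker's son iff he carries a non-queen allele at one or more
    typed loci.  As a group, putative queen sons must not display more than
    two alleles at any single locus (they all come from one diploid queen);
    violations are reported but do not reclassify individuals.
    """
    classes: dict[str, str] = {}
    for mid, geno in males.items():
        typed_any = False
        non_queen = False
        for locus, alleles in geno.items():
            a = alleles[0]
            if a == MISSING or not _typed(queen, locus):
                continue
            typed_any = True
            if a not in queen[locus]:
                non_queen = True
        if not typed_any:
            classes[mid] = "uninformative"
        else:
            classes[mid] = "worker_son" if non_queen else "queen_son"

    violating = []
    qs = [geno for mid, geno in males.items() if classes[mid] == "queen_son"]
    loci = sorted({l for g in males.values() for l in g})
    for locus in loci:
        alleles = {g[locus][0] for g in qs if _typed(g, locus)}
        if len(alleles) > 2:
            violating.append(locus)
    return MaleClassification(
        classes=classes, group_criterion_ok=not violating, group_violating_loci=violating
    )


def thelytoky_check(
    females: dict[str, Genotype],
    queen: Genotype,
    nondetection_probability: float | None = None,
) -> dict[str, dict]:
    """Classify diploid females as sexually produced or thelytoky-compatible.

    A female is sexual iff she carries at least one allele absent from the
    queen's genotype at a typed locus; otherwise she is compatible with
    thelytokous (clonal) production, with the supplied non-detection
    probability attached.
    """
    out = {}
    for fid, geno in females.items():
        sexual = False
        for locus, alleles in geno.items():
            if not _typed(geno, locus) or not _typed(queen, locus):
                continue
            if any(a not in queen[locus] for a in alleles):
                sexual = True
                break
        entry: dict = {"class": "sexual" if sexual else "thelytoky_compatible"}
        if not sexual and nondetection_probability is not None:
            entry["p_nondetect"] = nondetection_probability
        out[fid] = entry
    return out


# ---------------------------------------------------------------------------
# Queller–Goodnight relatedness
# ---------------------------------------------------------------------------


def _qg_terms(
    x: tuple[int, ...], y: tuple[int, ...], freqs: dict[int, float]
) -> tuple[float, float]:
    """One-directional numerator/denominator contribution for a dyad at a locus."""
    a, b = x
    c, d = y
    pa = freqs.get(a, 0.0)
    pb = freqs.get(b, 0.0)
    match = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
    num = match - pa - pb
    den = 1.0 + (a == b) - pa - pb
    return num, den


def _representative_allele_counts(
    table: GenotypeTable, seed: int | None = None
) -> dict[str, dict[str, dict[int, int]]]:
    """Per-colony allele counts of one seeded random diploid representative."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, dict[int, int]]] = {}
    for colony in table.colonies:
        sub = table.by_colony(colony).diploids()
        if len(sub) == 0:
            continue
        row = sub.data.iloc[int(rng.integers(len(sub)))]
        geno = sub._row_genotype(row)
        out[colony] = {
            locus: {a: pair.count(a) for a in set(pair) if a != MISSING}
            for locus, pair in geno.items()
        }
    return out


def _freqs_excluding(
    rep_counts: dict[str, dict[str, dict[int, int]]],
    loci: tuple[str, ...] | list[str],
    exclude_colony: str | None,
) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for locus in loci:
        counts: dict[int, int] = {}
        for colony, per_locus in rep_counts.items():
            if colony == exclude_colony:
                continue
            for a, c in per_locus.get(locus, {}).items():
                counts[a] = counts.get(a, 0) + c
        total = sum(counts.values())
        out[locus] = {a: c / total for a, c in counts.items()} if total else {}
    return out


def reference_frequencies(
    table: GenotypeTable,
    seed: int | None = None,
    exclude_colony: str | None = None,
) -> dict[str, dict[int, float]]:
    """Population allele frequencies from one random diploid per colony.

    One individual per colony avoids family pseudo-replication; the focal
    colony can be excluded for bias correction.  The per-colony choice is
    seeded and therefore reproducible.
    """
    rep_counts = _representative_allele_counts(table, seed=seed)
    return _freqs_excluding(rep_counts, table.loci, exclude_colony)


def qg_relatedness(
    dyads_by_colony: dict[str, list[tuple[Genotype, Genotype]]],
    freqs_by_colony: dict[str, dict[str, dict[int, float]]],
    loci: list[str] | None = None,
) -> RelatednessEstimate:
    """Symmetric Queller–Goodnight relatedness, colonies equally weighted.

    ``dyads_by_colony`` maps colony id to its list of genotype dyads;
    ``freqs_by_colony`` supplies the reference frequencies used for that
    colony's dyads (typically computed with the colony excluded).  Numerators
    and denominators are summed over both dyad orientations and all loci,
    averaged per colony (equal colony weights), and combined as a ratio of
    sums.  The standard error is a delete-one-colony jackknife.
    """
    colonies = sorted(c for c, d in dyads_by_colony.items() if d)
    nums, dens = [], []
    for colony in colonies:
        freqs = freqs_by_colony[colony]
        num_c = den_c = 0.0
        n_dyads = 0
        for gx, gy in dyads_by_colony[colony]:
            shared = [
                l for l in (loci or freqs.keys())
                if _typed(gx, l) and _typed(gy, l) and freqs.get(l)
            ]
            if not shared:
                continue
            n_dyads += 1
            for l in shared:
                n1, d1 = _qg_terms(gx[l], gy[l], freqs[l])
                n2, d2 = _qg_terms(gy[l], gx[l], freqs[l])
                num_c += n1 + n2
                den_c += d1 + d2
        if n_dyads:
            nums.append(num_c / n_dyads)
            dens.append(den_c / n_dyads)
    g = len(nums)
    if g == 0 or sum(dens) == 0:
        return RelatednessEstimate(r=float("nan"), se_jackknife=float("nan"),
                                   n_groups=g, status="undefined")
    nums_a, dens_a = np.array(nums), np.array(dens)
    total_n, total_d = nums_a.sum(), dens_a.sum()
    r = total_n / total_d
    if g < 2:
        return RelatednessEstimate(r=float(r), se_jackknife=float("nan"), n_groups=g)
    loo_d = total_d - dens_a
    if (loo_d == 0).any():
        return RelatednessEstimate(r=float(r), se_jackknife=float("nan"),
                                   n_groups=g, status="undefined")
    loo = (total_n - nums_a) / loo_d
    se = np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
    return RelatednessEstimate(r=float(r), se_jackknife=float(se), n_groups=g)


def relatedness_between_castes(
    table: GenotypeTable,
    caste_a: str,
    caste_b: str,
    seed: int = 0,
    haploid_as_diploid: bool = False,
) -> RelatednessEstimate:
    """Convenience wrapper: all caste_a × caste_b dyads within each colony.

    ``caste_a == caste_b`` yields all unordered within-caste pairs.  Haploid
    individuals are excluded unless ``haploid_as_diploid`` duplicates their
    single allele into a pseudo-diploid genotype.
    """
    dyads: dict[str, list[tuple[Genotype, Genotype]]] = {}
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    for colony in table.colonies:
        sub = table.by_colony(colony)
        def genos(caste: str) -> list[Genotype]:
            out = []
            for _, row in sub.data[sub.data["caste"] == caste].iterrows():
                g = sub._row_genotype(row)
                if int(row["ploidy"]) == 1:
                    if not haploid_as_diploid:
                        continue
                    g = {l: (a[0], a[0]) for l, a in g.items()}
                out.append(g)
            return out

        ga, gb = genos(caste_a), genos(caste_b)
        if caste_a == caste_b:
            pairs = [(ga[i], ga[j]) for i in range(len(ga)) for j in range(i + 1, len(ga))]
        else:
            pairs = [(x, y) for x in ga for y in gb]
        if pairs:
            dyads[colony] = pairs
    rep_counts = _representative_allele_counts(table, seed=seed)
    for colony in dyads:
        freqs[colony] = _freqs_excluding(rep_counts, table.loci, colony)
    return qg_relatedness(dyads, freqs, loci=list(table.loci))


# ---------------------------------------------------------------------------
# Per-colony pedigree report
# ---------------------------------------------------------------------------


@dataclass
class PedigreeResult:
    colony: str
    queen: Genotype
    queen_observed: bool
    queen_ambiguous: bool
    patrilines: PatrilineResult
    m_p: int
    m_e_p: float | None
    p_nondetect_two_males: float | None
    p_nondetect_worker_son: float | None
    male_classes: dict[str, str]
    male_group_criterion_ok: bool
    female_classes: dict[str, str]
    matrilines: dict[str, str]

    def to_jsonable(self) -> dict:
        return {
            "colony": self.colony,
            "queen": {l: list(p) for l, p in self.queen.items()},
            "queen_observed": self.queen_observed,
            "queen_ambiguous": self.queen_ambiguous,
            "m_p": self.m_p,
            "m_e_p": self.m_e_p,
            "contributions": list(self.patrilines.contributions),
            "p_nondetect_two_males": self.p_nondetect_two_males,
            "p_nondetect_worker_son": self.p_nondetect_worker_son,
            "male_classes": self.male_classes,
            "male_group_criterion_ok": self.male_group_criterion_ok,
            "female_classes": self.female_classes,
            "matrilines": self.matrilines,
            "status": self.patrilines.status,
        }


def analyse_colony_pedigree(
    table: GenotypeTable,
    colony: str,
    population_frequencies: dict[str, dict[int, float]] | None = None,
) -> PedigreeResult:
    """Full pedigree analysis of one colony: queen, patrilines, classifications."""
    sub = table.by_colony(colony)
    workers = {}
    for _, row in sub.data[sub.data["caste"] == "worker"].iterrows():
        workers[str(row["id"])] = sub._row_genotype(row)
    queens = sub.data[sub.data["caste"] == "queen"]
    observed = sub._row_genotype(queens.iloc[0]) if len(queens) else None

    rec = reconstruct_queen(workers, observed=observed)
    pat = infer_patrilines(workers, rec.genotype)
    m_e_p = None
    if pat.status == "ok" and sum(pat.contributions) >= 3:
        m_e_p = effective_paternity(pat.contributions)

    p_two = None
    if population_frequencies is not None:
        p_two = nondetect_two_males(
            [list(population_frequencies[l].values()) for l in table.loci
             if population_frequencies.get(l)]
        )

    p_ws = None
    if pat.status == "ok" and pat.contributions:
        props = np.array(pat.contributions, dtype=float)
        props = props / props.sum()
        l_counts = informative_locus_counts(pat.fathers, rec.genotype)
        p_ws = nondetect_worker_son(props, l_counts)

    males = {}
    for _, row in sub.data[sub.data["caste"] == "male"].iterrows():
        males[str(row["id"])] = sub._row_genotype(row)
    male_cls = classify_males(males, rec.genotype)

    females = {}
    for _, row in sub.data[sub.data["caste"] == "alate_female"].iterrows():
        females[str(row["id"])] = sub._row_genotype(row)
    fem = thelytoky_check(females, rec.genotype, nondetection_probability=p_ws)

    offspring = dict(workers)
    offspring.update(females)
    matr = assign_matrilines(offspring, rec.genotype)

    return PedigreeResult(
        colony=colony,
        queen=rec.genotype,
        queen_observed=rec.observed,
        queen_ambiguous=rec.ambiguous,
        patrilines=pat,
        m_p=pat.m_p,
        m_e_p=m_e_p,
        p_nondetect_two_males=p_two,
        p_nondetect_worker_son=p_ws,
        male_classes=male_cls.classes,
        male_group_criterion_ok=male_cls.group_criterion_ok,
        female_classes={fid: d["class"] for fid, d in fem.items()},
        matrilines=matr,
    )
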