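"""Haplotype-level analyses: collapsing, distances, median-joining networks,
hierarchical analysis of molecular variance (AMOVA)."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import GenotypeTable, HaplotypeAlignment, MISSING


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeSet:
    labels: dict[str, str]  # sequence id -> haplotype label
    representatives: dict[str, str]  # haplotype label -> representative sequence
    frequencies: dict[str, int]  # haplotype label -> count
    n_only_columns: list[int] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.representatives)


def _match_ignoring_n(a: str, b: str) -> bool:
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def collapse_haplotypes(alignment: HaplotypeAlignment) -> HaplotypeSet:
    """Merge sequences identical at all mutually non-N sites.

    Haplotypes are labelled H1..Hk in order of first occurrence; the
    representative of each haplotype is its first member.  Columns that are
    N in every sequence are flagged.
    """
    labels: dict[str, str] = {}
    reps: list[tuple[str, str]] = []  # (label, representative sequence)
    freq: dict[str, int] = {}
    for sid, seq in alignment:
        assigned = None
        for label, rep in reps:
            if _match_ignoring_n(seq, rep):
                assigned = label
                break
        if assigned is None:
            assigned = f"H{len(reps) + 1}"
            reps.append((assigned, seq))
            freq[assigned] = 0
        labels[sid] = assigned
        freq[assigned] += 1
    n_only = [
        i for i in range(alignment.length)
        if all(seq[i] == "N" for seq in alignment.sequences)
    ]
    return HaplotypeSet(
        labels=labels, representatives=dict(reps), frequencies=freq,
        n_only_columns=n_only,
    )


def haplotype_site_frequencies(
    hset: HaplotypeSet, site_of: dict[str, object]
) -> pd.DataFrame:
    """Haplotype x site count table."""
    rows: dict[tuple[str, object], int] = {}
    for sid, label in hset.labels.items():
        key = (label, site_of[sid])
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [{"haplotype": h, "site": s, "count": c} for (h, s), c in rows.items()]
    )
    return df.pivot_table(index="haplotype", columns="site", values="count",
                          fill_value=0, aggfunc="sum")


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------


@dataclass
class PDistanceResult:
    substitutions: pd.DataFrame  # integer difference counts
    percent: pd.DataFrame  # uncorrected p-distance in %, full precision
    compared_sites: pd.DataFrame

    def percent_rounded(self, decimals: int = 2) -> pd.DataFrame:
        return self.percent.round(decimals)


def pairwise_p_distance(sequences: dict[str, str]) -> PDistanceResult:
    """Pairwise substitution counts and uncorrected percent distances.

    Sites where either sequence is N are excluded pairwise; a pair with no
    comparable site gets NaN percent distance.
    """
    names = list(sequences)
    if len({len(s) for s in sequences.values()}) > 1:
        raise ValueError("sequences must have equal length")
    arr = {n: np.frombuffer(sequences[n].encode(), dtype="S1") for n in names}
    subs = pd.DataFrame(0, index=names, columns=names, dtype=int)
    comp = pd.DataFrame(0, index=names, columns=names, dtype=int)
    pct = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        sa, sb = arr[a], arr[b]
        ok = (sa != b"N") & (sb != b"N")
        n_comp = int(ok.sum())
        n_diff = int((sa[ok] != sb[ok]).sum())
        subs.loc[a, b] = subs.loc[b, a] = n_diff
        comp.loc[a, b] = comp.loc[b, a] = n_comp
        val = 100.0 * n_diff / n_comp if n_comp else float("nan")
        pct.loc[a, b] = pct.loc[b, a] = val
    return PDistanceResult(substitutions=subs, percent=pct, compared_sites=comp)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------


def minimum_spanning_network(seqs: dict[str, str]) -> nx.Graph:
    """Union of all minimum spanning trees under Hamming distance.

    Kruskal by weight class: all edges of a given weight joining components
    that were distinct *before* that weight class are retained.
    """
    names = sorted(seqs)
    g = nx.Graph()
    g.add_nodes_from(names)
    edges = sorted(
        (hamming(seqs[a], seqs[b]), a, b)
        for a, b in itertools.combinations(names, 2)
    )
    comp = {n: n for n in names}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    i = 0
    while i < len(edges):
        w = edges[i][0]
        batch = []
        while i < len(edges) and edges[i][0] == w:
            batch.append(edges[i])
            i += 1
        keep = [(a, b, w) for w_, a, b in batch if find(a) != find(b)]
        for a, b, w_ in keep:
            g.add_edge(a, b, weight=w_)
        for a, b, w_ in keep:
            ra, rb = find(a), find(b)
            if ra != rb:
                comp[rb] = ra
    return g


def _median_sequence(u: str, v: str, w: str) -> str:
    """Per-site majority consensus; ties (all three distinct) take u's state."""
    out = []
    for x, y, z in zip(u, v, w):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def median_joining_network(
    haplotypes: dict[str, str], epsilon: int = 0, max_iter: int = 20
) -> nx.Graph:
    """Median-joining network over equal-length haplotype sequences.

    Iterates minimum-spanning-network construction; for every triple with at
    least two pairs linked in the current network, the consensus (median)
    vector is a candidate node.  With epsilon = 0 only medians achieving the
    minimal connection cost are added each round.  Unsampled nodes that end
    up with degree <= 2 are pruned as obsolete.  Node attribute ``observed``
    marks sampled haplotypes; edges carry Hamming ``weight``.
    """
    if len(haplotypes) < 2:
        raise ValueError("need at least 2 haplotypes")
    lengths = {len(s) for s in haplotypes.values()}
    if len(lengths) > 1:
        raise ValueError("haplotypes must have equal length")

    seqs: dict[str, str] = dict(haplotypes)
    observed = set(haplotypes)
    seq_to_name = {s: n for n, s in seqs.items()}
    median_count = 0

    for _ in range(max_iter):
        msn = minimum_spanning_network(seqs)
        candidates: dict[str, int] = {}
        for u, v, w in itertools.combinations(sorted(seqs), 3):
            linked = sum(
                1 for x, y in ((u, v), (u, w), (v, w)) if msn.has_edge(x, y)
            )
            if linked < 2:
                continue
            m = _median_sequence(seqs[u], seqs[v], seqs[w])
            if m in seq_to_name:
                continue
            cost = hamming(m, seqs[u]) + hamming(m, seqs[v]) + hamming(m, seqs[w])
            if m not in candidates or cost < candidates[m]:
                candidates[m] = cost
        if not candidates:
            break
        best = min(candidates.values())
        added = False
        for m, cost in sorted(candidates.items()):
            if cost <= best + epsilon:
                median_count += 1
                name = f"mv{median_count}"
                seqs[name] = m
                seq_to_name[m] = name
                added = True
        if not added:  # pragma: no cover
            break

    # prune obsolete (unsampled, degree <= 2) median vectors
    while True:
        msn = minimum_spanning_network(seqs)
        removable = sorted(
            n for n in seqs
            if n not in observed and msn.degree(n) <= 2
        )
        if not removable:
            break
        del seqs[removable[0]]

    net = minimum_spanning_network(seqs)
    for n in net.nodes:
        net.nodes[n]["sequence"] = seqs[n]
        net.nodes[n]["observed"] = n in observed
    return net


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    components: dict[str, float]  # variance components by level
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    df: dict[str, int]
    n_perms: int


def _ssd_within(groups: list[np.ndarray], d2: np.ndarray) -> float:
    """Sum over blocks of (sum of squared distances within block) / block size."""
    total = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2 * len(idx))
    return total


def _amova_components(
    d2: np.ndarray, pops: np.ndarray, groups: np.ndarray | None
) -> tuple[dict[str, float], dict[str, int]]:
    n = len(pops)
    all_idx = np.arange(n)
    ssd_total = d2.sum() / (2 * n)
    pop_ids = np.unique(pops)
    pop_idx = [all_idx[pops == p] for p in pop_ids]
    n_p = np.array([len(i) for i in pop_idx], dtype=float)
    ssd_wp = _ssd_within(pop_idx, d2)

    if groups is None:
        P = len(pop_ids)
        df_ap, df_wp = P - 1, n - P
        sigma_c = ssd_wp / df_wp if df_wp > 0 else float("nan")
        n_c = (n - (n_p ** 2).sum() / n) / (P - 1)
        msd_ap = (ssd_total - ssd_wp) / df_ap
        sigma_a = (msd_ap - sigma_c) / n_c
        comps = {"among_populations": float(sigma_a), "within_populations": float(sigma_c)}
        return comps, {"among_populations": df_ap, "within_populations": df_wp}

    group_ids = np.unique(groups)
    G = len(group_ids)
    P = len(pop_ids)
    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    group_idx = [all_idx[groups == g] for g in group_ids]
    n_g = np.array([len(i) for i in group_idx], dtype=float)
    ssd_wg = _ssd_within(group_idx, d2)
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    # size coefficients for unequal sample sizes
    sum_np2_over_ng = 0.0
    for g, gi in zip(group_ids, group_idx):
        sizes = np.array([ (pops[gi] == p).sum() for p in np.unique(pops[gi]) ], dtype=float)
        sum_np2_over_ng += (sizes ** 2).sum() / len(gi)
    n1 = (n - sum_np2_over_ng) / df_ap if df_ap > 0 else float("nan")
    n2 = (sum_np2_over_ng - (n_p ** 2).sum() / n) / df_ag
    n3 = (n - (n_g ** 2).sum() / n) / df_ag

    sigma_c = ssd_wp / df_wp if df_wp > 0 else float("nan")
    sigma_b = ((ssd_ap_wg / df_ap) - sigma_c) / n1 if df_ap > 0 else float("nan")
    sigma_a = ((ssd_ag / df_ag) - sigma_c - n2 * sigma_b) / n3
    comps = {
        "among_groups": float(sigma_a),
        "among_populations_within_groups": float(sigma_b),
        "within_populations": float(sigma_c),
    }
    return comps, {
        "among_groups": df_ag,
        "among_populations_within_groups": df_ap,
        "within_populations": df_wp,
    }


def amova(
    squared_distances: np.ndarray,
    populations,
    groups=None,
    n_perms: int = 1000,
    seed: int | None = None,
    truncate_negative: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA on a squared-distance matrix.

    Two levels (populations / individuals) when ``groups`` is None, three
    otherwise.  p-values permute the appropriate exchangeable units:
    individuals among populations for the within/among-population
    components, whole populations among groups for the group component.
    Negative components are reported as computed unless truncated.
    """
    d2 = np.asarray(squared_distances, dtype=float)
    pops = np.asarray(populations)
    if d2.shape[0] != d2.shape[1] or len(pops) != d2.shape[0]:
        raise ValueError("distance matrix / population labels mismatch")
    if len(np.unique(pops)) < 2:
        raise ValueError("need at least 2 populations")
    grp = None if groups is None else np.asarray(groups)
    if grp is not None and len(np.unique(grp)) < 2:
        raise ValueError("need at least 2 groups (or pass groups=None)")

    comps, dfs = _amova_components(d2, pops, grp)

    reported = dict(comps)
    if truncate_negative:
        reported = {k: max(v, 0.0) for k, v in reported.items()}
    total = sum(reported.values())
    percentages = {k: 100.0 * v / total for k, v in reported.items()}

    phi: dict[str, float] = {}
    if grp is None:
        sa, sc = comps["among_populations"], comps["within_populations"]
        phi["phi_st"] = sa / (sa + sc)
    else:
        sa = comps["among_groups"]
        sb = comps["among_populations_within_groups"]
        sc = comps["within_populations"]
        tot = sa + sb + sc
        phi["phi_ct"] = sa / tot
        phi["phi_sc"] = sb / (sb + sc)
        phi["phi_st"] = (sa + sb) / tot

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if n_perms > 0:
        if grp is None:
            obs = comps["among_populations"]
            hits = 0
            for _ in range(n_perms):
                perm = rng.permutation(len(pops))
                c, _ = _amova_components(d2, pops[perm], None)
                if c["among_populations"] >= obs - 1e-12:
                    hits += 1
            p_values["among_populations"] = (hits + 1) / (n_perms + 1)
        else:
            obs_b = comps["among_populations_within_groups"]
            hits_b = 0
            # permute individuals among populations within their group
            for _ in range(n_perms):
                new_pops = pops.copy()
                for g in np.unique(grp):
                    idx = np.where(grp == g)[0]
                    new_pops[idx] = pops[idx][rng.permutation(len(idx))]
                c, _ = _amova_components(d2, new_pops, grp)
                if c["among_populations_within_groups"] >= obs_b - 1e-12:
                    hits_b += 1
            p_values["among_populations_within_groups"] = (hits_b + 1) / (n_perms + 1)

            # permute whole populations among groups
            pop_ids = np.unique(pops)
            group_of_pop = {p: grp[pops == p][0] for p in pop_ids}
            obs_a = comps["among_groups"]
            hits_a = 0
            labels = np.array([group_of_pop[p] for p in pop_ids])
            for _ in range(n_perms):
                shuffled = labels[rng.permutation(len(labels))]
                mapping = dict(zip(pop_ids, shuffled))
                new_grp = np.array([mapping[p] for p in pops])
                c, _ = _amova_components(d2, pops, new_grp)
                if c["among_groups"] >= obs_a - 1e-12:
                    hits_a += 1
            p_values["among_groups"] = (hits_a + 1) / (n_perms + 1)

    return AmovaResult(
        components=reported, percentages=percentages, phi=phi,
        p_values=p_values, df=dfs, n_perms=n_perms,
    )


def haplotype_distance_matrix(alignment: HaplotypeAlignment) -> np.ndarray:
    """Pairwise difference counts between individual sequences (N-aware)."""
    res = pairwise_p_distance({sid: seq for sid, seq in alignment})
    return res.substitutions.to_numpy(dtype=float)


def genotype_distance_matrix(table: GenotypeTable) -> np.ndarray:
    """Pairwise allele-difference counts between diploid multilocus genotypes.

    Per locus the distance is 2 minus the multiset allele intersection size;
    loci with missing data in either individual are skipped.
    """
    dip = table.diploids()
    genos = [dip._row_genotype(row) for _, row in dip.data.iterrows()]
    n = len(genos)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total = 0
            for locus in table.loci:
                gi, gj = genos[i][locus], genos[j][locus]
                if gi[0] == MISSING or gj[0] == MISSING:
                    continue
                shared = 0
                used = list(gj)
                for a in gi:
                    if a in used:
                        used.remove(a)
                        shared += 1
                total += 2 - shared
            d[i, j] = d[j, i] = total
    return d
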