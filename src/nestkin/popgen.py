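"""Classic population-genetic statistics on colony-structured genotype tables.

Diversity summaries, exact Hardy–Weinberg and linkage tests under the
one-individual-per-colony resampling design, Weir & Cockerham F-statistics
with jackknife/bootstrap errors over loci, pairwise differentiation tests
and the second-order rate-of-change summary for admixture likelihood tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeTable, MISSING


# ---------------------------------------------------------------------------
# Diversity summaries
# ---------------------------------------------------------------------------


@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    n_alleles: int
    h_obs: float
    h_exp: float


def locus_summaries(table: GenotypeTable) -> tuple[list[LocusSummary], dict[str, float]]:
    """Observed heterozygosity and Nei's unbiased gene diversity per locus.

    H_E uses the small-sample correction (2n/(2n-1))(1 - sum f^2) computed on
    the diploid individuals typed at the locus.  The overall entry is the
    unweighted mean across loci.
    """
    dip = table.diploids()
    if len(dip) == 0:
        raise ValueError("no diploid individuals")
    summaries = []
    for locus in table.loci:
        a1 = dip.data[locus + ".1"].to_numpy()
        a2 = dip.data[locus + ".2"].to_numpy()
        typed = a1 != MISSING
        n = int(typed.sum())
        if n == 0:
            summaries.append(LocusSummary(locus, 0, 0, float("nan"), float("nan")))
            continue
        het = float((a1[typed] != a2[typed]).mean())
        alleles, counts = np.unique(np.concatenate([a1[typed], a2[typed]]), return_counts=True)
        f = counts / counts.sum()
        he = (2 * n / (2 * n - 1)) * (1 - (f ** 2).sum()) if n > 0 else float("nan")
        summaries.append(LocusSummary(locus, n, len(alleles), het, float(he)))
    valid = [s for s in summaries if s.n_typed > 0]
    overall = {
        "h_obs": float(np.mean([s.h_obs for s in valid])),
        "h_exp": float(np.mean([s.h_exp for s in valid])),
    }
    return summaries, overall


# ---------------------------------------------------------------------------
# Exact Hardy–Weinberg tests
# ---------------------------------------------------------------------------


def _hwe_exact_biallelic_impl(n_het: int, n_a: int, n: int) -> float:
    """Exact two-sided HWE p-value for a biallelic locus (full enumeration).

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one.
    """
    from scipy.special import gammaln

    n_b = 2 * n - n_a
    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    n_aa = (n_a - hs) // 2
    n_bb = (n_b - hs) // 2
    logw = hs * math.log(2.0) - gammaln(n_aa + 1) - gammaln(hs + 1) - gammaln(n_bb + 1)
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    p_obs = probs[hs == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_exact(
    genotypes: list[tuple[int, int]],
    n_mc: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float | None:
    """Exact HWE test on diploid genotypes at one locus.

    Biallelic configurations are fully enumerated; multi-allelic ones use a
    Monte-Carlo version of the conditional exact test (alleles reshuffled
    into genotypes, statistic = conditional probability of the genotype
    array).  Returns None for monomorphic or empty input.
    """
    genos = [
        (int(g[0]), int(g[1]))
        for g in genotypes
        if g[0] != MISSING and g[1] != MISSING
    ]
    if not genos:
        return None
    alleles = sorted({a for g in genos for a in g})
    if len(alleles) < 2:
        return None
    n = len(genos)
    if len(alleles) == 2:
        a = alleles[0]
        n_a = sum((g[0] == a) + (g[1] == a) for g in genos)
        n_het = sum(g[0] != g[1] for g in genos)
        return _hwe_exact_biallelic_impl(n_het, n_a, n)

    from scipy.special import gammaln

    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)

    def log_cond_prob(pairs: np.ndarray) -> float:
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        codes = lo * k + hi
        _, counts = np.unique(codes, return_counts=True)
        n_het = int((lo != hi).sum())
        return n_het * math.log(2.0) - float(gammaln(counts + 1).sum())

    obs_pairs = np.array([[index[g[0]], index[g[1]]] for g in genos])
    obs_stat = log_cond_prob(obs_pairs)
    pool = obs_pairs.ravel().copy()
    rng = rng or np.random.default_rng()
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        if log_cond_prob(pool.reshape(-1, 2)) <= obs_stat + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def resample_one_per_colony(
    table: GenotypeTable, rng: np.random.Generator
) -> GenotypeTable:
    """One random diploid individual per colony (family-structure control)."""
    picks = []
    for colony in table.colonies:
        sub = table.by_colony(colony).diploids()
        if len(sub) == 0:
            continue
        picks.append(sub.data.iloc[int(rng.integers(len(sub)))])
    if not picks:
        raise ValueError("no diploid individuals to resample")
    return GenotypeTable(pd.DataFrame(picks).reset_index(drop=True), table.loci)


def hwe_exact_resampled(
    table: GenotypeTable,
    n_replicates: int = 20,
    alpha: float = 0.05,
    seed: int | None = None,
    n_mc: int = 10_000,
) -> tuple[pd.DataFrame, dict]:
    """HWE exact tests on resampled one-per-colony datasets.

    Returns a tidy frame (replicate, locus, p) with NaN for inapplicable
    (monomorphic) cases and a summary with the count of significant tests.
    """
    if len(table.colonies) < 2:
        raise ValueError("need at least 2 colonies for the resampling design")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        sub = resample_one_per_colony(table, rng)
        for locus in table.loci:
            genos = [
                (int(r[locus + ".1"]), int(r[locus + ".2"]))
                for _, r in sub.data.iterrows()
            ]
            p = hwe_exact(genos, n_mc=n_mc, rng=rng)
            rows.append({"replicate": rep, "locus": locus,
                         "p": float("nan") if p is None else p})
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    summary = {
        "n_tests": int(tested.sum()),
        "n_significant": int((df.loc[tested, "p"] < alpha).sum()),
        "alpha": alpha,
    }
    return df, summary


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def _g_statistic(obs: np.ndarray) -> float:
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.size == 0:
        return 0.0
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    mask = obs > 0
    return float(2 * (obs[mask] * np.log(obs[mask] / exp[mask])).sum())


def _genotype_codes(sub: GenotypeTable, locus: str) -> np.ndarray:
    a1 = sub.data[locus + ".1"].to_numpy()
    a2 = sub.data[locus + ".2"].to_numpy()
    lo, hi = np.minimum(a1, a2), np.maximum(a1, a2)
    codes = np.where(a1 == MISSING, -1, lo * 10_000 + hi)
    return codes


def _contingency_g_perm(
    codes_a: np.ndarray, codes_b: np.ndarray, n_perms: int, rng: np.random.Generator
) -> float | None:
    keep = (codes_a >= 0) & (codes_b >= 0)
    ca, cb = codes_a[keep], codes_b[keep]
    if len(np.unique(ca)) < 2 or len(np.unique(cb)) < 2:
        return None

    def table_of(a, b):
        ia = np.unique(a, return_inverse=True)[1]
        ib = np.unique(b, return_inverse=True)[1]
        t = np.zeros((ia.max() + 1, ib.max() + 1))
        np.add.at(t, (ia, ib), 1)
        return t

    obs = _g_statistic(table_of(ca, cb))
    hits = 0
    b = cb.copy()
    for _ in range(n_perms):
        rng.shuffle(b)
        if _g_statistic(table_of(ca, b)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perms + 1)


def ld_test_resampled(
    table: GenotypeTable,
    pairs: list[tuple[str, str]] | None = None,
    n_replicates: int = 20,
    n_perms: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Permutation genotypic-association tests per locus pair per replicate."""
    if len(table.colonies) < 2:
        raise ValueError("need at least 2 colonies for the resampling design")
    rng = np.random.default_rng(seed)
    pairs = pairs or list(itertools.combinations(table.loci, 2))
    rows = []
    for rep in range(n_replicates):
        sub = resample_one_per_colony(table, rng)
        codes = {l: _genotype_codes(sub, l) for l in table.loci}
        for la, lb in pairs:
            p = _contingency_g_perm(codes[la], codes[lb], n_perms, rng)
            rows.append({"replicate": rep, "locus_a": la, "locus_b": lb,
                         "p": float("nan") if p is None else p})
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    summary = {
        "n_tests": int(tested.sum()),
        "n_significant": int((df.loc[tested, "p"] < alpha).sum()),
        "expected_false_positives": float(alpha * tested.sum()),
        "alpha": alpha,
    }
    return df, summary


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics
# ---------------------------------------------------------------------------


@dataclass
class FStatResult:
    f_is: float
    f_st: float
    se_f_is: float
    se_f_st: float
    ci95_f_is: tuple[float, float]
    ci95_f_st: tuple[float, float]
    per_locus: pd.DataFrame  # columns: locus, a, bc, c (summed components)


def _wc_components_locus(
    table: GenotypeTable, locus: str, demes: list[str], deme_col: str
) -> tuple[float, float, float] | None:
    """Summed (a, b, c) variance components over alleles at one locus."""
    data = []
    for deme in demes:
        sub = table.data[(table.data[deme_col] == deme) & (table.data["ploidy"] == 2)]
        a1 = sub[locus + ".1"].to_numpy()
        a2 = sub[locus + ".2"].to_numpy()
        typed = a1 != MISSING
        if typed.sum() == 0:
            continue
        data.append((a1[typed], a2[typed]))
    r = len(data)
    if r < 2:
        return None
    alleles = sorted({int(a) for a1, a2 in data for a in np.concatenate([a1, a2])})
    if len(alleles) < 2:
        return None
    n_i = np.array([len(a1) for a1, _ in data], dtype=float)
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
    if n_c == 0:
        return None
    A = B = C = 0.0
    for allele in alleles:
        p_i = np.array([((a1 == allele).sum() + (a2 == allele).sum()) / (2 * len(a1))
                        for a1, a2 in data])
        h_i = np.array([(((a1 == allele) ^ (a2 == allele))).mean() for a1, a2 in data])
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        if n_bar <= 1:
            return None
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
        A += a
        B += b
        C += c
    return A, B, C


def weir_cockerham_fstats(
    table: GenotypeTable,
    deme_col: str = "colony",
    n_bootstrap: int = 10_000,
    seed: int | None = None,
) -> FStatResult:
    """Multi-locus Weir & Cockerham (1984) theta (F_ST) and f (F_IS).

    Components are summed over alleles and loci; SEs are jackknife over loci
    and the 95% CI a seeded percentile bootstrap over loci.
    """
    demes = list(dict.fromkeys(table.data[deme_col]))
    if len(demes) < 2:
        raise ValueError("F_ST undefined with a single deme")
    rows = []
    for locus in table.loci:
        comp = _wc_components_locus(table, locus, demes, deme_col)
        if comp is not None:
            rows.append({"locus": locus, "a": comp[0], "b": comp[1], "c": comp[2]})
    if not rows:
        raise ValueError("no informative loci for F-statistics")
    per_locus = pd.DataFrame(rows)
    a = per_locus["a"].to_numpy()
    b = per_locus["b"].to_numpy()
    c = per_locus["c"].to_numpy()

    def theta(ai, bi, ci):
        tot = (ai + bi + ci).sum()
        return np.nan if tot == 0 else ai.sum() / tot

    def f_is(ai, bi, ci):
        tot = (bi + ci).sum()
        return np.nan if tot == 0 else 1 - ci.sum() / tot

    th = theta(a, b, c)
    fi = f_is(a, b, c)

    L = len(per_locus)
    if L > 1:
        loo_th = np.array([theta(np.delete(a, i), np.delete(b, i), np.delete(c, i))
                           for i in range(L)])
        loo_fi = np.array([f_is(np.delete(a, i), np.delete(b, i), np.delete(c, i))
                           for i in range(L)])
        se_th = math.sqrt((L - 1) / L * np.nansum((loo_th - np.nanmean(loo_th)) ** 2))
        se_fi = math.sqrt((L - 1) / L * np.nansum((loo_fi - np.nanmean(loo_fi)) ** 2))
        rng = np.random.default_rng(seed)
        idx = rng.integers(L, size=(n_bootstrap, L))
        boot_th = np.array([theta(a[i], b[i], c[i]) for i in idx])
        boot_fi = np.array([f_is(a[i], b[i], c[i]) for i in idx])
        ci_th = tuple(np.nanpercentile(boot_th, [2.5, 97.5]))
        ci_fi = tuple(np.nanpercentile(boot_fi, [2.5, 97.5]))
    else:
        se_th = se_fi = float("nan")
        ci_th = ci_fi = (float("nan"), float("nan"))

    return FStatResult(
        f_is=float(fi), f_st=float(th), se_f_is=float(se_fi), se_f_st=float(se_th),
        ci95_f_is=ci_fi, ci95_f_st=ci_th, per_locus=per_locus,
    )


def pairwise_fst(table: GenotypeTable, deme_col: str = "colony") -> pd.DataFrame:
    """Weir–Cockerham theta for every deme pair; symmetric with zero diagonal."""
    demes = list(dict.fromkeys(table.data[deme_col]))
    if len(demes) < 2:
        raise ValueError("need at least 2 demes")
    mat = pd.DataFrame(0.0, index=demes, columns=demes)
    for da, db in itertools.combinations(demes, 2):
        sub = table.subset(table.data[deme_col].isin((da, db)))
        theta = float("nan")
        tot_a = tot = 0.0
        for locus in table.loci:
            comp = _wc_components_locus(sub, locus, [da, db], deme_col)
            if comp is not None:
                tot_a += comp[0]
                tot += comp[0] + comp[1] + comp[2]
        if tot > 0:
            theta = tot_a / tot
        mat.loc[da, db] = mat.loc[db, da] = theta
    return mat


# ---------------------------------------------------------------------------
# Pairwise differentiation (G-based, Fisher-combined)
# ---------------------------------------------------------------------------


def gtest_pairwise_differentiation(
    table: GenotypeTable,
    alpha: float = 0.05,
    n_perms: int = 2000,
    seed: int | None = None,
    caste: str | None = "worker",
) -> pd.DataFrame:
    """Per colony pair: Monte-Carlo G tests per locus, Fisher-combined p.

    The significance column applies a Bonferroni threshold alpha / n_pairs
    (the number of pairs actually tested).
    """
    rng = np.random.default_rng(seed)
    sub = table.diploids()
    if caste is not None:
        sub = sub.of_caste(caste)
    colonies = list(dict.fromkeys(sub.data["colony"]))
    if len(colonies) < 2:
        raise ValueError("need at least 2 colonies")
    codes = {l: _genotype_codes(sub, l) for l in table.loci}
    colony_arr = sub.data["colony"].to_numpy()
    rows = []
    pairs = list(itertools.combinations(colonies, 2))
    for ca, cb in pairs:
        mask = (colony_arr == ca) | (colony_arr == cb)
        labels = (colony_arr[mask] == cb).astype(int)
        pvals = []
        for locus in table.loci:
            g = codes[locus][mask]
            keep = g >= 0
            if keep.sum() == 0 or len(np.unique(g[keep])) < 2:
                continue  # monomorphic across the pair: excluded from combination
            p = _contingency_g_perm(labels[keep], g[keep], n_perms, rng)
            if p is not None:
                pvals.append(p)
        if pvals:
            x = -2 * sum(math.log(p) for p in pvals)
            combined = float(stats.chi2.sf(x, 2 * len(pvals)))
        else:
            combined = float("nan")
        rows.append({"colony_a": ca, "colony_b": cb, "n_loci": len(pvals),
                     "p_combined": combined})
    df = pd.DataFrame(rows)
    threshold = alpha / len(pairs)
    df["significant"] = df["p_combined"] < threshold
    df.attrs["bonferroni_threshold"] = threshold
    return df


# ---------------------------------------------------------------------------
# Second-order rate of change of clustering likelihoods (Delta K)
# ---------------------------------------------------------------------------


def evanno_delta_k(lnp: pd.DataFrame) -> pd.DataFrame:
    """Delta-K summary of a runs-by-K log-likelihood table.

    ``lnp`` columns are consecutive K values (ints), rows independent runs.
    Delta K(K) = mean over runs |L(K+1) - 2 L(K) + L(K-1)| / sd over runs of
    L(K); endpoints are undefined, as is any K with zero run-to-run sd.
    Returns a frame with columns K, delta_k, defined; the argmax over defined
    rows is stored in ``df.attrs['best_k']``.
    """
    ks = sorted(int(k) for k in lnp.columns)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    if len(lnp) < 2:
        raise ValueError("need at least 2 runs per K")
    rows = []
    for k in ks[1:-1]:
        second = (lnp[k + 1] - 2 * lnp[k] + lnp[k - 1]).abs().mean()
        sd = lnp[k].std(ddof=1)
        if sd == 0:
            rows.append({"K": k, "delta_k": float("nan"), "defined": False})
        else:
            rows.append({"K": k, "delta_k": float(second / sd), "defined": True})
    df = pd.DataFrame(rows)
    defined = df[df["defined"]]
    df.attrs["best_k"] = int(defined.loc[defined["delta_k"].idxmax(), "K"]) if len(defined) else None
    return df
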